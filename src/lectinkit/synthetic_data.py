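"""Deterministic synthetic fixtures for every pipeline stage.

Three generators, all seeded and byte-reproducible:

* toy crystal structures — an idealized extended polypeptide (correct backbone
  atom names, 3.8 Å residue spacing) with optional designed ligand hydrogen
  bonds, a methyl–π probe above a tryptophan indole, a metal site with
  coordinating waters, and a crystal cell with symmetry operators placing a
  designed inter-chain contact;
* simulated single-site ITC titrations under the standard microcalorimeter
  protocol (280 µl cell, 18 × 2 µl injections, 25 °C);
* log-linear SEC standards from the Bio-Rad marker masses.

Each generator records its ground truth so detectors and fitters can be
checked for exact recovery.  The toy chains make no attempt at a real
β-prism fold: the downstream detectors are geometry-level and fold-agnostic.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hbond_geometry import ContactRecord, QualifiedAtom
from .itc_binding import ITCData, TitrationProtocol, simulate_titration
from .sasa_interfaces import atom_radius
from .sec_calibration import BIORAD_STANDARD_MASSES_KDA
from .structure_io import AtomRecord, CrystalStructure, UnitCell, write_pdb

__all__ = [
    "FixtureSpec",
    "ToyCrystal",
    "ITCDatasetFixture",
    "SECStandardsFixture",
    "make_toy_crystal",
    "make_itc_dataset",
    "make_sec_standards",
    "make_fixture",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Seeded recipe for one synthetic fixture."""

    kind: str  # "toy_crystal" | "itc_curve" | "sec_standards"
    seed: int = 0
    parameters: dict = field(default_factory=dict)


@dataclass
class ToyCrystal:
    structure: CrystalStructure
    pdb_text: str
    hbond_truth: list[ContactRecord]
    me_pi_truth: list[ContactRecord]
    metal_truth: list[ContactRecord]

    @property
    def protein_atoms(self) -> list[AtomRecord]:
        return [a for a in self.structure.atoms if not a.is_hetero]

    @property
    def ligand_atoms(self) -> list[AtomRecord]:
        return [a for a in self.structure.atoms
                if a.is_hetero and a.residue_name == _LIGAND_CODE]


@dataclass
class ITCDatasetFixture:
    data: ITCData
    truth: dict


@dataclass
class SECStandardsFixture:
    table: pd.DataFrame
    truth: dict


_LIGAND_CODE = "MPY"  # synthetic methyl-pyranoside-like ligand
_BACKBONE_OFFSETS = (("N", "N", (0.0, 0.0, 0.0)),
                     ("CA", "C", (1.2, 1.0, 0.0)),
                     ("C", "C", (2.4, 0.3, 0.0)),
                     ("O", "O", (2.5, -0.9, 0.0)))
_RESIDUE_SPACING = 3.8

# Idealized planar indole template (xy-plane): six-ring regular hexagon of
# edge 1.39 Å centered at the origin, fused five-ring on the +x side.
_HEX_R = 1.39
_PENT_R = 1.39 / (2.0 * math.sin(math.radians(36.0)))
_PENT_CX = _HEX_R * math.cos(math.radians(30.0)) + _PENT_R * math.cos(math.radians(36.0))
_INDOLE_TEMPLATE = {
    "CE2": (_HEX_R * math.cos(math.radians(30)), _HEX_R * math.sin(math.radians(30))),
    "CZ2": (_HEX_R * math.cos(math.radians(90)), _HEX_R * math.sin(math.radians(90))),
    "CH2": (_HEX_R * math.cos(math.radians(150)), _HEX_R * math.sin(math.radians(150))),
    "CZ3": (_HEX_R * math.cos(math.radians(210)), _HEX_R * math.sin(math.radians(210))),
    "CE3": (_HEX_R * math.cos(math.radians(270)), _HEX_R * math.sin(math.radians(270))),
    "CD2": (_HEX_R * math.cos(math.radians(330)), _HEX_R * math.sin(math.radians(330))),
    "NE1": (_PENT_CX + _PENT_R * math.cos(math.radians(72)),
            _PENT_R * math.sin(math.radians(72))),
    "CD1": (_PENT_CX + _PENT_R, 0.0),
    "CG": (_PENT_CX + _PENT_R * math.cos(math.radians(-72)),
           _PENT_R * math.sin(math.radians(-72))),
}
_PYRANOSIDE_ATOMS = ("C1", "C2", "C3", "C4", "C5", "O5",
                     "O1", "O2", "O3", "O4", "O6", "C7")


def _check_designed_distance(d: float, elem_a: str, elem_b: str) -> None:
    floor = atom_radius(elem_a) + atom_radius(elem_b) - 0.5
    if d < floor:
        raise ValueError(
            f"designed {elem_a}···{elem_b} distance {d} Å is below the physical "
            f"floor {floor:.2f} Å (sum of vdW radii − 0.5)")


def make_toy_crystal(spec: FixtureSpec) -> ToyCrystal:
    """Build a toy crystal with designed, exactly-known contacts.

    Recognized ``spec.parameters``:

    ``n_residues`` (20), ``cell`` (60,60,60,90,90,90), ``space_group`` ("P 1"),
    ``origin`` ((10, 0, 0)), ``hbond_contacts`` (list of (ligand atom, Å) —
    each pairs a backbone N with a designed ligand atom), ``hbond_target_start``
    (5), ``me_pi_distance`` (None → no probe), ``metal_waters`` (0) and
    ``metal_distance`` (2.3), ``symmetry_contact`` (None or
    {"op": "X,-Y,-Z", "distance": Å} — offsets the chain so that operator's
    mate touches at the designed distance; defaults the space group to C222₁).
    """
    p = dict(spec.parameters)
    n_res = int(p.get("n_residues", 20))
    if n_res < 2:
        raise ValueError("toy chain needs at least 2 residues")
    cell = UnitCell(*p.get("cell", (60.0, 60.0, 60.0, 90.0, 90.0, 90.0)))
    hbonds: list[tuple[str, float]] = list(p.get("hbond_contacts", []))
    target_start = int(p.get("hbond_target_start", 5))
    me_pi_distance = p.get("me_pi_distance")
    metal_waters = int(p.get("metal_waters", 0))
    metal_distance = float(p.get("metal_distance", 2.3))
    sym_contact = p.get("symmetry_contact")

    space_group = p.get("space_group")
    origin = np.array(p.get("origin", (10.0, 0.0, 0.0)), dtype=float)
    if sym_contact is not None:
        space_group = space_group or "C 2 2 21"
        # chain offset so the mate under (x,-y,-z) touches at the designed gap
        origin = np.array(p.get("origin",
                                (10.0, 0.9 + float(sym_contact["distance"]) / 2.0, 0.0)))
    space_group = space_group or "P 1"

    rng = np.random.default_rng(spec.seed)
    atoms: list[AtomRecord] = []
    serial = 1

    trp_index = n_res - 3 if me_pi_distance is not None else None
    n_positions: dict[int, np.ndarray] = {}
    for i in range(n_res):
        resname = "TRP" if i == trp_index else "GLY"
        base = origin + np.array([_RESIDUE_SPACING * i, 0.0, 0.0])
        for name, elem, off in _BACKBONE_OFFSETS:
            pos = base + np.array(off)
            if name == "N":
                n_positions[i] = pos
            atoms.append(AtomRecord(serial=serial, name=name, element=elem,
                                    residue_name=resname, residue_number=i + 1,
                                    chain_id="A", position=pos,
                                    b_factor=round(float(rng.uniform(10.0, 40.0)), 2)))
            serial += 1
        if i == trp_index:
            ring_center = base + np.array([1.2, 4.5, 0.0])
            for name, (tx, ty) in _INDOLE_TEMPLATE.items():
                elem = "N" if name.startswith("N") else "C"
                atoms.append(AtomRecord(serial=serial, name=name, element=elem,
                                        residue_name="TRP", residue_number=i + 1,
                                        chain_id="A",
                                        position=ring_center + np.array([tx, ty, 0.0]),
                                        b_factor=round(float(rng.uniform(10.0, 40.0)), 2)))
                serial += 1

    # --- designed ligand hydrogen bonds -------------------------------
    hbond_truth: list[ContactRecord] = []
    ligand_positions: dict[str, np.ndarray] = {}
    for k, (lig_atom, dist) in enumerate(hbonds):
        dist = float(dist)
        _check_designed_distance(dist, "N", lig_atom[0])
        j = target_start + k
        if j >= n_res - 4:
            raise ValueError("too many designed contacts for chain length")
        target = n_positions[j]
        # tilted off the backbone plane so no other polar atom comes in range
        pos = target + np.array([0.5, 0.8, math.sqrt(dist * dist - 0.89)])
        ligand_positions[lig_atom] = pos
        hbond_truth.append(ContactRecord(
            "hbond",
            QualifiedAtom("A", "GLY", j + 1, "N"),
            QualifiedAtom("A", _LIGAND_CODE, 201, lig_atom),
            dist))

    me_pi_truth: list[ContactRecord] = []
    if me_pi_distance is not None:
        h = float(me_pi_distance)
        hex_center = (origin + np.array([_RESIDUE_SPACING * trp_index, 0.0, 0.0])
                      + np.array([1.2, 4.5, 0.0]))
        c7 = hex_center + np.array([-0.5, 0.0, h])  # shifted off the 5-ring
        ligand_positions["C7"] = c7
        five_centroid = hex_center + np.array([_PENT_CX, 0.0, 0.0])
        if np.linalg.norm(c7 - five_centroid) <= 4.55:
            raise ValueError("methyl probe too close to the fused five-ring")
        me_pi_truth.append(ContactRecord(
            "me_pi",
            QualifiedAtom("A", _LIGAND_CODE, 201, "C7"),
            QualifiedAtom("A", "TRP", trp_index + 1, "ring6"),
            float(np.linalg.norm(np.array([-0.5, 0.0, h]))),
            extra="ring6"))

    if hbonds or me_pi_distance is not None:
        # park the remaining pyranoside atoms on a shelf 4.8 Å above the chain
        shelf_center = (n_positions[target_start] if hbonds
                        else origin + np.array([0.0, 0.0, 0.0]))
        placed = 0
        for name in _PYRANOSIDE_ATOMS:
            if name in ligand_positions:
                continue
            angle = 2.0 * math.pi * placed / len(_PYRANOSIDE_ATOMS)
            ligand_positions[name] = shelf_center + np.array(
                [2.2 * math.cos(angle), 2.2 * math.sin(angle), 4.8])
            placed += 1
        for name in _PYRANOSIDE_ATOMS:
            if name not in ligand_positions:
                continue
            atoms.append(AtomRecord(serial=serial, name=name,
                                    element=name[0],
                                    residue_name=_LIGAND_CODE, residue_number=201,
                                    chain_id="A", position=ligand_positions[name],
                                    b_factor=round(float(rng.uniform(20.0, 60.0)), 2),
                                    is_hetero=True))
            serial += 1

    metal_truth: list[ContactRecord] = []
    if metal_waters > 0:
        if metal_distance < 1.8:
            raise ValueError("designed metal coordination distance below 1.8 Å")
        metal_pos = origin + np.array([_RESIDUE_SPACING * (n_res // 2), -7.0, 0.0])
        atoms.append(AtomRecord(serial=serial, name="CD", element="Cd",
                                residue_name="CD", residue_number=301, chain_id="A",
                                position=metal_pos,
                                b_factor=round(float(rng.uniform(15.0, 35.0)), 2),
                                is_hetero=True))
        metal_qual = QualifiedAtom("A", "CD", 301, "CD")
        serial += 1
        directions = [(0, -1, 0), (1, 0, 0), (-1, 0, 0), (0, 0, 1), (0, 0, -1), (0, 1, 0)]
        if metal_waters > len(directions):
            raise ValueError("at most 6 coordinating waters supported")
        for w, direction in enumerate(directions[:metal_waters]):
            pos = metal_pos + metal_distance * np.array(direction, dtype=float)
            atoms.append(AtomRecord(serial=serial, name="O", element="O",
                                    residue_name="HOH", residue_number=302 + w,
                                    chain_id="A", position=pos,
                                    b_factor=round(float(rng.uniform(20.0, 50.0)), 2),
                                    is_hetero=True))
            metal_truth.append(ContactRecord(
                "metal_coord", metal_qual,
                QualifiedAtom("A", "HOH", 302 + w, "O"),
                metal_distance, extra=f"CN={metal_waters}"))
            serial += 1

    structure = CrystalStructure(atoms=atoms, cell=cell, space_group=space_group)
    return ToyCrystal(structure=structure, pdb_text=write_pdb(structure),
                      hbond_truth=hbond_truth, me_pi_truth=me_pi_truth,
                      metal_truth=metal_truth)


def make_itc_dataset(spec: FixtureSpec) -> ITCDatasetFixture:
    """Simulated one-site titration under the default microcalorimeter protocol.

    Parameters: ``ka`` (7.04e3 M⁻¹), ``n`` (1.0), ``dh`` (−5.56 kcal/mol),
    ``noise_frac`` (0; Gaussian sd as a fraction of the first noise-free
    injection heat), plus any :class:`TitrationProtocol` field override.
    """
    p = dict(spec.parameters)
    ka = float(p.pop("ka", 7.04e3))
    n = float(p.pop("n", 1.0))
    dh = float(p.pop("dh", -5.56))
    noise_frac = float(p.pop("noise_frac", 0.0))
    proto_kwargs = {"cell_conc_mM": 1.0, "syringe_conc_mM": 25.0}
    proto_kwargs.update(p)
    protocol = TitrationProtocol(**proto_kwargs)
    clean = simulate_titration(ka, n, dh, protocol)
    noise_sd = noise_frac * abs(float(clean.heats_ucal[0]))
    data = (clean if noise_sd == 0.0 else
            simulate_titration(ka, n, dh, protocol, noise_sd_ucal=noise_sd,
                               seed=spec.seed))
    return ITCDatasetFixture(data=data,
                             truth={"K_A": ka, "n": n, "dH": dh,
                                    "noise_sd_ucal": noise_sd})


def make_sec_standards(spec: FixtureSpec) -> SECStandardsFixture:
    """Marker table from a truth line log10(kDa) = intercept + slope·V.

    Parameters: ``slope`` (−0.0423 /ml), ``intercept`` (5.1333 log10 kDa),
    ``noise_ml`` (0; Gaussian sd on elution volumes), ``masses`` (Bio-Rad set).
    """
    p = dict(spec.parameters)
    slope = float(p.get("slope", -0.0423))
    intercept = float(p.get("intercept", 5.1333))
    noise_ml = float(p.get("noise_ml", 0.0))
    masses = tuple(p.get("masses", BIORAD_STANDARD_MASSES_KDA))
    if slope >= 0:
        raise ValueError("a physical SEC column has a negative slope")
    rng = np.random.default_rng(spec.seed)
    volumes = [(math.log10(m) - intercept) / slope for m in masses]
    if noise_ml > 0:
        volumes = [v + float(rng.normal(0.0, noise_ml)) for v in volumes]
    table = pd.DataFrame({"mass_kda": masses, "elution_ml": volumes})
    return SECStandardsFixture(table=table,
                               truth={"slope": slope, "intercept": intercept,
                                      "noise_ml": noise_ml})


def make_fixture(spec: FixtureSpec):
    """Dispatch on ``spec.kind``."""
    makers = {"toy_crystal": make_toy_crystal,
              "itc_curve": make_itc_dataset,
              "sec_standards": make_sec_standards}
    if spec.kind not in makers:
        raise ValueError(f"unknown fixture kind {spec.kind!r}; "
                         f"expected one of {sorted(makers)}")
    return makers[spec.kind](spec)
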