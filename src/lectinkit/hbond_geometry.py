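"""Heavy-atom contact detection: hydrogen bonds, methyl–π, metal coordination.

Deposited structures carry no hydrogens, so hydrogen bonds are called on a
distance-only donor/acceptor criterion (default 3.5 Å).  Methyl–π (CH–π)
contacts use the ring-centroid distance plus an elevation-angle filter, and
metal coordination counts O/N atoms within a tight shell.  Distances are kept
at full precision internally and rounded to 0.1 Å only for reporting.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .sasa_interfaces import METAL_ELEMENTS
from .structure_io import AtomRecord

__all__ = [
    "QualifiedAtom",
    "ContactRecord",
    "DonorAcceptorDictionary",
    "DEFAULT_DICTIONARY",
    "find_hbonds",
    "find_me_pi",
    "find_metal_coordination",
    "contact_table",
    "AROMATIC_RINGS",
]


class QualifiedAtom(NamedTuple):
    chain: str
    residue_name: str
    residue_number: int
    name: str

    @property
    def label(self) -> str:
        return f"{self.residue_name.capitalize()}{self.residue_number}{self.name}"

    @classmethod
    def of(cls, atom: AtomRecord) -> "QualifiedAtom":
        return cls(atom.chain_id, atom.residue_name, atom.residue_number, atom.name)


@dataclass(frozen=True)
class ContactRecord:
    """One geometric contact; ``distance`` is exact, rounding is for display."""

    kind: str  # "hbond" | "me_pi" | "metal_coord"
    atom_1: QualifiedAtom
    atom_2: QualifiedAtom
    distance: float
    extra: str = ""

    @property
    def distance_rounded(self) -> float:
        return round(self.distance, 1)

    @property
    def signature(self) -> tuple:
        """Comparison key at reporting precision (0.1 Å)."""
        return (self.kind, self.atom_1, self.atom_2, self.distance_rounded)

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("contact distance must be positive")


_BACKBONE_DONORS = {"N"}
_BACKBONE_ACCEPTORS = {"O", "OXT"}
_SIDECHAIN: dict[str, tuple[set[str], set[str]]] = {
    # residue: (donor atom names, acceptor atom names), side chain only
    "SER": ({"OG"}, {"OG"}),
    "THR": ({"OG1"}, {"OG1"}),
    "TYR": ({"OH"}, {"OH"}),
    "CYS": ({"SG"}, {"SG"}),
    "ASN": ({"ND2"}, {"OD1"}),
    "GLN": ({"NE2"}, {"OE1"}),
    "ASP": (set(), {"OD1", "OD2"}),
    "GLU": (set(), {"OE1", "OE2"}),
    "HIS": ({"ND1", "NE2"}, {"ND1", "NE2"}),
    "LYS": ({"NZ"}, set()),
    "ARG": ({"NE", "NH1", "NH2"}, set()),
    "TRP": ({"NE1"}, set()),
    "MET": (set(), {"SD"}),
    "ALA": (set(), set()), "GLY": (set(), set()), "VAL": (set(), set()),
    "LEU": (set(), set()), "ILE": (set(), set()), "PRO": (set(), set()),
    "PHE": (set(), set()),
}
_WATER_CODES = {"HOH", "WAT", "DOD", "H2O"}

# Methyl pyranosides: hydroxyls O2/O3/O4/O6 donate and accept, the glycosidic
# O1 and ring O5 accept only.  Known ligand codes plus an atom-name fallback.
_PYRANOSIDE_DONORS = {"O2", "O3", "O4", "O6"}
_PYRANOSIDE_ACCEPTORS = {"O1", "O2", "O3", "O4", "O5", "O6"}
_PYRANOSIDE_CODES = {"MMA", "AMG", "MGC", "MGL", "GYP", "MPY", "MBG", "MGA"}


class DonorAcceptorDictionary:
    """Maps residue/ligand codes to donor and acceptor atom names.

    Standard residues always expose the backbone N donor and backbone O
    acceptor.  Residues that look like pyranosides (ring O5 plus hydroxyl
    oxygens) fall back to the sugar template; anything else unknown is
    reported via a warning and skipped.
    """

    def __init__(self, extra: dict[str, tuple[set[str], set[str]]] | None = None):
        self._extra = extra or {}

    def resolve(self, residue_name: str,
                atom_names: set[str]) -> tuple[set[str], set[str]] | None:
        code = residue_name.upper()
        if code in self._extra:
            return self._extra[code]
        if code in _SIDECHAIN:
            d, a = _SIDECHAIN[code]
            return (d | _BACKBONE_DONORS, a | _BACKBONE_ACCEPTORS)
        if code in _WATER_CODES:
            return ({"O", "OW"}, {"O", "OW"})
        if code in _PYRANOSIDE_CODES or self._looks_like_pyranoside(atom_names):
            return (set(_PYRANOSIDE_DONORS), set(_PYRANOSIDE_ACCEPTORS))
        return None

    @staticmethod
    def _looks_like_pyranoside(atom_names: set[str]) -> bool:
        oxygens = {n for n in atom_names if n in {"O1", "O2", "O3", "O4", "O5", "O6"}}
        return "O5" in oxygens and len(oxygens) >= 3


DEFAULT_DICTIONARY = DonorAcceptorDictionary()


def _classify(atoms: list[AtomRecord],
              dictionary: DonorAcceptorDictionary) -> list[tuple[AtomRecord, bool, bool]]:
    """Tag each atom as (atom, is_donor, is_acceptor); warn on unknown residues."""
    by_residue: dict[tuple, list[AtomRecord]] = {}
    for a in atoms:
        by_residue.setdefault((a.chain_id, a.residue_number, a.residue_name), []).append(a)
    out: list[tuple[AtomRecord, bool, bool]] = []
    warned: set[str] = set()
    for (chain, num, name), res_atoms in by_residue.items():
        names = {a.name for a in res_atoms}
        resolved = dictionary.resolve(name, names)
        if resolved is None:
            if name not in warned:
                warnings.warn(f"residue {name!r} missing from donor/acceptor dictionary; skipped",
                              stacklevel=3)
                warned.add(name)
            continue
        donors, acceptors = resolved
        for a in res_atoms:
            d, acc = a.name in donors, a.name in acceptors
            if d or acc:
                out.append((a, d, acc))
    return out


def find_hbonds(group_a: list[AtomRecord], group_b: list[AtomRecord],
                cutoff: float = 3.5,
                dictionary: DonorAcceptorDictionary = DEFAULT_DICTIONARY,
                exclude_adjacent: bool = True) -> list[ContactRecord]:
    """Donor–acceptor pairs (either direction) within ``cutoff`` Å.

    Pairs within one residue are never reported; by default pairs between
    sequence-adjacent residues of the same chain are also excluded, since
    covalently linked backbone N/O pairs sit inside hydrogen-bond range.
    Records are sorted by (residue number, atom name) of the ``group_a`` atom.
    """
    if not group_a or not group_b:
        return []
    keys_a = {(a.chain_id, a.residue_number, a.name) for a in group_a}
    keys_b = {(b.chain_id, b.residue_number, b.name) for b in group_b}
    if keys_a & keys_b:
        raise ValueError("selections must be disjoint")
    polar_a = _classify(group_a, dictionary)
    polar_b = _classify(group_b, dictionary)
    if not polar_a or not polar_b:
        return []
    coords_b = np.array([t[0].position for t in polar_b])
    tree = cKDTree(coords_b)
    records: list[ContactRecord] = []
    for a, a_don, a_acc in polar_a:
        for j in tree.query_ball_point(a.position, cutoff):
            b, b_don, b_acc = polar_b[j]
            if a.chain_id == b.chain_id:
                if a.residue_number == b.residue_number:
                    continue
                if exclude_adjacent and abs(a.residue_number - b.residue_number) == 1:
                    continue
            if not ((a_don and b_acc) or (a_acc and b_don)):
                continue
            d = float(np.linalg.norm(a.position - b.position))
            if d <= cutoff:
                records.append(ContactRecord("hbond", QualifiedAtom.of(a),
                                             QualifiedAtom.of(b), d))
    records.sort(key=lambda r: (r.atom_1.residue_number, r.atom_1.name,
                                r.atom_2.residue_number, r.atom_2.name))
    return records


#: Aromatic ring atom names; Trp contributes both its 5- and 6-membered rings.
AROMATIC_RINGS: dict[str, list[tuple[str, list[str]]]] = {
    "PHE": [("ring6", ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"])],
    "TYR": [("ring6", ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"])],
    "TRP": [("ring5", ["CG", "CD1", "NE1", "CE2", "CD2"]),
            ("ring6", ["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"])],
    "HIS": [("ring5", ["CG", "ND1", "CD2", "CE1", "NE2"])],
}


def _ring_geometry(atoms: list[AtomRecord]) -> tuple[np.ndarray, np.ndarray]:
    coords = np.array([a.position for a in atoms])
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid)
    return centroid, vt[2]  # normal = least-variance direction


def find_me_pi(methyl_carbons: list[AtomRecord], aromatic_atoms: list[AtomRecord],
               cutoff: float = 4.5, min_elevation: float = 30.0) -> list[ContactRecord]:
    """Methyl-carbon…aromatic-ring contacts (CH–π geometry).

    A contact requires carbon–centroid distance ≤ ``cutoff`` Å and an
    elevation of at least ``min_elevation`` degrees above the ring plane.
    """
    by_residue: dict[tuple, list[AtomRecord]] = {}
    for a in aromatic_atoms:
        by_residue.setdefault((a.chain_id, a.residue_number, a.residue_name.upper()), []).append(a)
    rings: list[tuple[QualifiedAtom, str, np.ndarray, np.ndarray]] = []
    for (chain, num, resname), res_atoms in by_residue.items():
        for ring_id, names in AROMATIC_RINGS.get(resname, []):
            sel = [a for a in res_atoms if a.name in names]
            if len(sel) != len(names):
                continue
            centroid, normal = _ring_geometry(sel)
            rings.append((QualifiedAtom(chain, resname, num, ring_id), ring_id,
                          centroid, normal))
    records: list[ContactRecord] = []
    for carbon in methyl_carbons:
        for qual, ring_id, centroid, normal in rings:
            if (carbon.chain_id, carbon.residue_number) == (qual.chain, qual.residue_number):
                continue
            v = carbon.position - centroid
            d = float(np.linalg.norm(v))
            if d == 0.0 or d > cutoff:
                continue
            elevation = math.degrees(math.asin(min(1.0, abs(float(np.dot(v / d, normal))))))
            if elevation >= min_elevation:
                records.append(ContactRecord("me_pi", QualifiedAtom.of(carbon),
                                             qual, d, extra=ring_id))
    records.sort(key=lambda r: (r.atom_1.residue_number, r.atom_1.name,
                                r.atom_2.residue_number, r.extra))
    return records


def find_metal_coordination(atoms: list[AtomRecord],
                            metals: list[AtomRecord] | None = None,
                            cutoff: float = 3.0) -> list[ContactRecord]:
    """O/N atoms within ``cutoff`` Å of each metal, with coordination number.

    Metals default to every atom whose element is a known metal.  Each record
    carries ``extra = "CN=<n>"`` for its metal's coordination number.
    """
    if metals is None:
        metals = [a for a in atoms if a.element.upper() in METAL_ELEMENTS]
    records: list[ContactRecord] = []
    for metal in metals:
        ligating: list[tuple[AtomRecord, float]] = []
        for a in atoms:
            if a is metal or a.element.upper() not in {"O", "N"}:
                continue
            if (a.chain_id, a.residue_number) == (metal.chain_id, metal.residue_number):
                continue
            d = float(np.linalg.norm(a.position - metal.position))
            if d <= cutoff:
                ligating.append((a, d))
        cn = len(ligating)
        for a, d in sorted(ligating, key=lambda t: t[1]):
            records.append(ContactRecord("metal_coord", QualifiedAtom.of(metal),
                                         QualifiedAtom.of(a), d, extra=f"CN={cn}"))
    return records


def contact_table(records: dict[str, list[ContactRecord]] | list[ContactRecord]) -> pd.DataFrame:
    """Tabulate contacts: rows = protein atoms, columns = complex, cells =
    ``"<partner>, <d> Å"``.  Serialize with ``df.to_csv(sep="\\t")``."""
    if isinstance(records, list):
        records = {"contacts": records}
    cells: dict[str, dict[str, str]] = {}
    row_order: list[str] = []
    for column, recs in records.items():
        for rec in recs:
            row = rec.atom_1.label
            if row not in row_order:
                row_order.append(row)
            entry = f"{rec.atom_2.label}, {rec.distance_rounded:.1f} Å"
            cell = cells.setdefault(row, {})
            cell[column] = f"{cell[column]}; {entry}" if column in cell else entry
    df = pd.DataFrame(
        [[cells.get(row, {}).get(col, "-") for col in records] for row in row_order],
        index=row_order, columns=list(records),
    )
    df.index.name = "protein_atom"
    return df
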