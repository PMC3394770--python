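"""Shrake–Rupley solvent-accessible surface area and buried interfaces.

SASA is computed by the point-counting method: each atom's sphere of radius
``r_vdw + probe`` is sampled with a deterministic Fibonacci lattice and a
point counts as accessible when it lies outside every neighbour's expanded
sphere.  Points that fall exactly on a neighbour boundary contribute half,
which makes the area of k coincident identical spheres equal the area of one
(the analytic union).  Interface areas follow the PISA convention: half of
the total SASA lost upon complexation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import AtomRecord

__all__ = [
    "VDW_RADII",
    "METAL_ELEMENTS",
    "SasaResult",
    "InterfaceReport",
    "fibonacci_sphere",
    "atom_radius",
    "sasa",
    "buried_interface",
    "select_heavy_atoms",
]

#: NACCESS-style van der Waals radii (Å).
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "CD": 1.58,
}

METAL_ELEMENTS = {"CD", "ZN", "FE", "MG", "MN", "NA", "K", "CA", "NI", "CU",
                  "CO", "HG", "SR", "CS", "RB", "LI"}

_DEFAULT_METAL_RADIUS = 1.70


def atom_radius(element: str, radii: dict[str, float] | None = None) -> float:
    """vdW radius for an element; unknown metals default to 1.70 Å, anything
    else raises naming the element."""
    table = VDW_RADII if radii is None else {**VDW_RADII, **radii}
    key = element.upper()
    if key in table:
        return table[key]
    if key in METAL_ELEMENTS:
        return _DEFAULT_METAL_RADIUS
    raise ValueError(f"no van der Waals radius for element {element!r}")


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Quasi-uniform unit-sphere lattice (golden-angle spiral); deterministic."""
    i = np.arange(n_points)
    z = 1.0 - (2.0 * i + 1.0) / n_points
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@dataclass
class SasaResult:
    per_atom: np.ndarray
    per_residue: dict[tuple[str, int, str], float]
    total: float
    probe_radius: float
    n_points: int


@dataclass
class InterfaceReport:
    chain_pair: tuple[str, str]
    buried_area: float
    interface_residues: dict[str, list[tuple[int, float]]]
    n_interface_hbonds: int | None = None


def select_heavy_atoms(atoms: list[AtomRecord], exclude_water: bool = True,
                       exclude_hetero: bool = False) -> list[AtomRecord]:
    """Drop hydrogens (and optionally waters / all hetero atoms) before SASA."""
    out = []
    for a in atoms:
        if a.element.upper() == "H":
            continue
        if exclude_water and a.is_water:
            continue
        if exclude_hetero and a.is_hetero:
            continue
        out.append(a)
    return out


def sasa(atoms: list[AtomRecord], probe: float = 1.4, n_points: int = 960,
         radii: dict[str, float] | None = None) -> SasaResult:
    """Shrake–Rupley SASA (Ų) with a deterministic Fibonacci sphere lattice."""
    if not atoms:
        return SasaResult(np.empty(0), {}, 0.0, probe, n_points)
    coords = np.array([a.position for a in atoms])
    er = np.array([atom_radius(a.element, radii) for a in atoms]) + probe
    sphere = fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    er_max = er.max()
    per_atom = np.zeros(len(atoms))
    for i in range(len(atoms)):
        nbrs = tree.query_ball_point(coords[i], er[i] + er_max)
        nbrs = [j for j in nbrs if j != i
                and np.linalg.norm(coords[j] - coords[i]) < er[i] + er[j]]
        area_full = 4.0 * math.pi * er[i] ** 2
        if not nbrs:
            per_atom[i] = area_full
            continue
        pts = coords[i] + er[i] * sphere
        d2 = ((pts[:, None, :] - coords[nbrs][None, :, :]) ** 2).sum(axis=2)
        r2 = er[np.asarray(nbrs)] ** 2
        tol = 1e-6 * r2
        inside = (d2 < r2 - tol).any(axis=1)
        boundary = (np.abs(d2 - r2) <= tol).any(axis=1) & ~inside
        weight = np.where(inside, 0.0, np.where(boundary, 0.5, 1.0))
        per_atom[i] = weight.mean() * area_full
    per_residue: dict[tuple[str, int, str], float] = {}
    for a, area in zip(atoms, per_atom):
        key = (a.chain_id, a.residue_number, a.residue_name)
        per_residue[key] = per_residue.get(key, 0.0) + float(area)
    return SasaResult(per_atom=per_atom, per_residue=per_residue,
                      total=float(per_atom.sum()), probe_radius=probe,
                      n_points=n_points)


def buried_interface(chain_a: list[AtomRecord], chain_b: list[AtomRecord],
                     probe: float = 1.4, n_points: int = 960,
                     residue_threshold: float = 0.1,
                     protein_only: bool = True,
                     radii: dict[str, float] | None = None) -> InterfaceReport:
    """PISA-style buried interface between two chains.

    ``buried_area = (SASA(A) + SASA(B) - SASA(A ∪ B)) / 2``; interface
    residues are those losing more than ``residue_threshold`` Ų of SASA upon
    complexation.  Waters, ions and sugars are excluded by default so the
    area refers to the protein–protein interface.
    """
    if not chain_a or not chain_b:
        raise ValueError("both chains must be non-empty")
    ids_a = {a.chain_id for a in chain_a}
    ids_b = {b.chain_id for b in chain_b}
    if ids_a & ids_b:
        raise ValueError(f"chains share identifiers: {sorted(ids_a & ids_b)}")
    a_sel = select_heavy_atoms(chain_a, exclude_hetero=protein_only)
    b_sel = select_heavy_atoms(chain_b, exclude_hetero=protein_only)
    sa = sasa(a_sel, probe, n_points, radii)
    sb = sasa(b_sel, probe, n_points, radii)
    sab = sasa(a_sel + b_sel, probe, n_points, radii)
    buried = max(0.0, (sa.total + sb.total - sab.total) / 2.0)

    complexed: dict[tuple[str, int, str], float] = sab.per_residue
    interface: dict[str, list[tuple[int, float]]] = {}
    for result, chain_ids in ((sa, ids_a), (sb, ids_b)):
        for key, free_area in result.per_residue.items():
            delta = free_area - complexed.get(key, 0.0)
            if delta > residue_threshold:
                interface.setdefault(key[0], []).append((key[1], float(delta)))
    for lst in interface.values():
        lst.sort()
    pair = (sorted(ids_a)[0], sorted(ids_b)[0])
    return InterfaceReport(chain_pair=pair, buried_area=buried,
                           interface_residues=interface)
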