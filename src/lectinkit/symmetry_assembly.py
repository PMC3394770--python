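"""Crystallographic symmetry expansion and contact-based oligomer assembly.

Symmetry operators act in the fractional frame: a mate of chain atoms at
orthogonal positions ``x`` is ``orth(R @ frac(x) + t + shift)`` where
``shift`` is an integer lattice translation.  Oligomers are the connected
components of the inter-chain contact graph over all mates generated within a
small lattice-shift search range, deduplicated under crystal symmetry.
"""
from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .structure_io import AtomRecord, CrystalStructure, SymOp, UnitCell

__all__ = [
    "SymmetryMate",
    "Assembly",
    "parse_symop_string",
    "format_symop",
    "fractionalize",
    "orthogonalize",
    "apply_symop",
    "assemble_oligomers",
]


def parse_symop_string(text: str) -> SymOp:
    """Parse an operator triplet such as ``"-X-1, -Y, Z"`` into a :class:`SymOp`."""
    return SymOp.from_string(text)


def format_symop(op: SymOp) -> str:
    """Render an operator in ``"x,y,z"``-style notation."""
    return op.to_string()


def fractionalize(cell: UnitCell, coords: np.ndarray) -> np.ndarray:
    """Orthogonal (Å) → fractional coordinates; accepts (3,) or (n, 3)."""
    return np.asarray(coords, dtype=float) @ cell.fractionalization_matrix.T


def orthogonalize(cell: UnitCell, frac: np.ndarray) -> np.ndarray:
    """Fractional → orthogonal (Å) coordinates; accepts (3,) or (n, 3)."""
    return np.asarray(frac, dtype=float) @ cell.orthogonalization_matrix.T


@dataclass
class SymmetryMate:
    """A chain copy generated by one operator plus an integer lattice shift."""

    source_chain: str
    op: SymOp
    lattice_shift: tuple[int, int, int]
    atoms: list[AtomRecord]

    @property
    def is_identity(self) -> bool:
        return self.op.is_identity and self.lattice_shift == (0, 0, 0)


@dataclass
class Assembly:
    """A connected set of symmetry mates (identity mates included)."""

    members: list[SymmetryMate]
    contact_graph: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return len(self.members)

    @property
    def member_ops(self) -> list[str]:
        return [format_symop(m.op) for m in self.members]


def apply_symop(op: SymOp, shift, structure: CrystalStructure, chain: str) -> SymmetryMate:
    """Generate the mate of ``chain`` under ``op`` plus lattice ``shift``.

    B-factors, occupancies and names are preserved.  The identity operator with
    zero shift reproduces the source coordinates exactly (no round trip through
    the fractional frame).
    """
    cell = structure.require_cell()
    shift = tuple(int(s) for s in np.asarray(shift).reshape(3))
    atoms = structure.chain(chain)
    if not atoms:
        raise ValueError(f"chain {chain!r} not present in structure")
    if op.is_identity and shift == (0, 0, 0):
        new_atoms = [a.copy_with_position(a.position) for a in atoms]
        return SymmetryMate(chain, op, shift, new_atoms)
    coords = np.array([a.position for a in atoms])
    frac = fractionalize(cell, coords)
    moved = orthogonalize(cell, op.apply(frac) + np.array(shift, dtype=float))
    new_atoms = [a.copy_with_position(p) for a, p in zip(atoms, moved)]
    return SymmetryMate(chain, op, shift, new_atoms)


def _contact_coords(atoms: list[AtomRecord]) -> np.ndarray:
    """Protein heavy atoms only: waters, ions and other ligands are excluded
    from contact-graph construction (ligands follow their protein chain)."""
    sel = [a.position for a in atoms if not a.is_hetero and a.element.upper() != "H"]
    return np.array(sel) if sel else np.empty((0, 3))


def _mate_signature(mate: SymmetryMate, reference: SymmetryMate) -> tuple:
    ref_affine = SymOp(reference.op.rotation,
                       reference.op.translation + np.array(reference.lattice_shift, float))
    m_affine = SymOp(mate.op.rotation,
                     mate.op.translation + np.array(mate.lattice_shift, float))
    rel = ref_affine.inverse().compose(m_affine)
    return (mate.source_chain, rel.key())


def _canonical_signature(members: list[SymmetryMate]) -> tuple:
    """Signature invariant under left-multiplication by any symmetry operator:
    sorted multiset of member (chain, op) relative to a reference member, with
    the reference chosen to minimize the signature."""
    min_chain = min(m.source_chain for m in members)
    candidates = []
    for ref in members:
        if ref.source_chain != min_chain:
            continue
        sig = tuple(sorted(_mate_signature(m, ref) for m in members))
        candidates.append(sig)
    return min(candidates)


def assemble_oligomers(structure: CrystalStructure,
                       contact_cutoff: float = 5.0,
                       shift_range: int = 1,
                       min_contacts: int = 1) -> list[Assembly]:
    """Assemble oligomers from symmetry mates by inter-chain atomic contact.

    Two mates are in contact when any inter-chain heavy-atom distance is below
    ``contact_cutoff`` (at least ``min_contacts`` such pairs).  Mates are
    generated for every operator and integer lattice shift in
    ``[-shift_range, +shift_range]³``; connected components are deduplicated
    under crystal symmetry and returned sorted by size (largest first).
    Components that are sub-multisets of a larger component (partners lost at
    the edge of the shift search) are dropped.
    """
    if not structure.atoms:
        return []
    structure.require_cell()
    chains = [c for c in structure.chain_ids
              if any(not a.is_hetero for a in structure.chain(c))]
    if not chains:
        return []

    mates: list[SymmetryMate] = []
    coords: list[np.ndarray] = []
    shifts = list(itertools.product(range(-shift_range, shift_range + 1), repeat=3))
    for chain in chains:
        for op in structure.operators:
            for shift in shifts:
                mate = apply_symop(op, shift, structure, chain)
                xyz = _contact_coords(mate.atoms)
                if xyz.size == 0:
                    continue
                mates.append(mate)
                coords.append(xyz)

    n = len(mates)
    centers = np.array([c.mean(axis=0) for c in coords])
    radii = np.array([np.linalg.norm(c - ctr, axis=1).max()
                      for c, ctr in zip(coords, centers)])
    trees = [cKDTree(c) for c in coords]

    rows, cols = [], []
    for i in range(n):
        for j in range(i + 1, n):
            gap = np.linalg.norm(centers[i] - centers[j])
            if gap > radii[i] + radii[j] + contact_cutoff:
                continue
            pairs = trees[i].query_ball_tree(trees[j], contact_cutoff)
            n_pairs = sum(len(p) for p in pairs)
            if n_pairs >= min_contacts:
                rows.append(i)
                cols.append(j)
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)

    edge_list: dict[int, list[tuple[int, int]]] = {}
    for i, j in zip(rows, cols):
        edge_list.setdefault(labels[i], []).append((i, j))

    assemblies: dict[tuple, Assembly] = {}
    for comp in range(n_comp):
        idx = [i for i in range(n) if labels[i] == comp]
        members = [mates[i] for i in idx]
        sig = _canonical_signature(members)
        if sig in assemblies:
            continue
        remap = {i: k for k, i in enumerate(idx)}
        edges = [(remap[i], remap[j]) for i, j in edge_list.get(comp, [])]
        assemblies[sig] = Assembly(members=members, contact_graph=edges)

    # Drop sub-multisets of larger assemblies (shift-boundary artifacts).
    kept: list[tuple[tuple, Assembly]] = []
    for sig, asm in sorted(assemblies.items(), key=lambda kv: -kv[1].n_chains):
        counter = Counter(sig)
        if any(counter <= Counter(other_sig) for other_sig, _ in kept):
            continue
        kept.append((sig, asm))
    return [asm for _, asm in kept]
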