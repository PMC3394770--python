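"""Fixed-column PDB input/output and crystal-cell arithmetic.

Coordinates are kept in ångströms in the orthogonal frame throughout the
package; fractionalization happens on demand in :mod:`lectinkit.symmetry_assembly`.
Cell-level quantities (volume, Matthews coefficient ``Vm``, solvent content)
follow the standard crystallographic conventions: ``Vm = V / (n_chains * M)``
and solvent fraction ``1 - 1.66 * v_bar / Vm`` with a protein partial specific
volume ``v_bar`` of 0.74 cm³/g.
"""
from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "UnitCell",
    "SymOp",
    "CrystalStructure",
    "CrystalSummary",
    "PDBParseError",
    "SpaceGroupError",
    "parse_pdb",
    "write_pdb",
    "cell_volume",
    "matthews",
    "solvent_content",
    "chain_mass",
    "summarize_crystal",
    "space_group_operators",
    "supported_space_groups",
    "RESIDUE_MASSES",
    "WATER_MASS",
    "SOLVENT_CONSTANT",
]


class PDBParseError(ValueError):
    """Raised for malformed fixed-column PDB records; names the offending line."""


class SpaceGroupError(ValueError):
    """Raised for space-group symbols outside the supported table."""


# Average masses of the free amino acids (Da).  A peptide bond releases one
# water, so a chain of n residues weighs sum(residues) - (n - 1) * WATER_MASS.
RESIDUE_MASSES: dict[str, float] = {
    "ALA": 89.09, "ARG": 174.20, "ASN": 132.12, "ASP": 133.10,
    "CYS": 121.16, "GLN": 146.15, "GLU": 147.13, "GLY": 75.07,
    "HIS": 155.15, "ILE": 131.17, "LEU": 131.17, "LYS": 146.19,
    "MET": 149.21, "PHE": 165.19, "PRO": 115.13, "SER": 105.09,
    "THR": 119.12, "TRP": 204.23, "TYR": 181.19, "VAL": 117.15,
}
WATER_MASS = 18.02

#: 1.66 Da·ų⁻¹ conversion times v_bar = 0.74 cm³/g.  Using the unrounded
#: product reproduces printed solvent contents to ±0.3 percentage points.
SOLVENT_CONSTANT = 1.66 * 0.74  # = 1.2284

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}
_TWO_LETTER_ELEMENTS = {
    "CD", "ZN", "FE", "MG", "MN", "NA", "CL", "BR", "SE", "NI", "CU", "CO",
    "HG", "CA", "SR", "CS", "RB", "LI",
}


@dataclass
class AtomRecord:
    """One ATOM/HETATM record: a heavy atom with crystallographic metadata."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_hetero: bool = False
    altloc: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"atom {self.serial}: occupancy {self.occupancy} not in [0, 1]")
        if not self.element:
            raise ValueError(f"atom {self.serial}: empty element symbol")

    @property
    def is_water(self) -> bool:
        return self.residue_name in _WATER_NAMES

    def copy_with_position(self, position: np.ndarray) -> "AtomRecord":
        return AtomRecord(
            serial=self.serial, name=self.name, element=self.element,
            residue_name=self.residue_name, residue_number=self.residue_number,
            chain_id=self.chain_id, position=np.array(position, dtype=float),
            occupancy=self.occupancy, b_factor=self.b_factor,
            is_hetero=self.is_hetero, altloc=self.altloc,
        )


@dataclass(frozen=True)
class UnitCell:
    """Crystal unit cell: edge lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")
        if self.volume <= 0 or not math.isfinite(self.volume):
            raise ValueError("degenerate cell: non-positive volume")

    @property
    def volume(self) -> float:
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if arg <= 0:
            return 0.0
        return self.a * self.b * self.c * math.sqrt(arg)

    @property
    def orthogonalization_matrix(self) -> np.ndarray:
        """Matrix M with x_orth = M @ x_frac (PDB standard convention)."""
        a, b, c = self.a, self.b, self.c
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        v = self.volume
        return np.array([
            [a, b * cg, c * cb],
            [0.0, b * sg, c * (ca - cb * cg) / sg],
            [0.0, 0.0, v / (a * b * sg)],
        ])

    @property
    def fractionalization_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.orthogonalization_matrix)


class SymOp:
    """Space-group operator in the fractional frame: x' = R @ x + t."""

    __slots__ = ("rotation", "translation")

    def __init__(self, rotation, translation) -> None:
        self.rotation = np.asarray(rotation, dtype=int).reshape(3, 3)
        self.translation = np.asarray(translation, dtype=float).reshape(3)
        det = round(float(np.linalg.det(self.rotation)))
        if det not in (-1, 1):
            raise ValueError(f"rotation determinant must be ±1, got {det}")

    # -- construction -------------------------------------------------
    _TOKEN = re.compile(r"([+-]?)\s*([XYZ]|\d+(?:/\d+)?|\d*\.\d+)", re.IGNORECASE)

    @classmethod
    def identity(cls) -> "SymOp":
        return cls(np.eye(3, dtype=int), np.zeros(3))

    @classmethod
    def from_string(cls, text: str) -> "SymOp":
        """Parse a triplet such as ``"-X-1, -Y, Z"`` or ``"X+1/2, -Y, Z"``."""
        parts = [p.strip() for p in text.split(",")]
        if len(parts) != 3:
            raise ValueError(f"expected 3 comma-separated components, got {text!r}")
        rot = np.zeros((3, 3), dtype=int)
        tr = np.zeros(3)
        axes = {"X": 0, "Y": 1, "Z": 2}
        for row, part in enumerate(parts):
            consumed = 0
            for m in cls._TOKEN.finditer(part):
                gap = part[consumed:m.start()].strip()
                if gap:
                    raise ValueError(f"unparsable token {gap!r} in {part!r}")
                sign = -1 if m.group(1) == "-" else 1
                tok = m.group(2)
                if tok.upper() in axes:
                    rot[row, axes[tok.upper()]] += sign
                elif "/" in tok:
                    num, den = tok.split("/")
                    tr[row] += sign * float(num) / float(den)
                else:
                    tr[row] += sign * float(tok)
                consumed = m.end()
            tail = part[consumed:].strip()
            if tail:
                raise ValueError(f"unparsable token {tail!r} in {part!r}")
            if not np.any(rot[row]):
                raise ValueError(f"component {part!r} references no axis")
        return cls(rot, tr)

    def to_string(self) -> str:
        axes = "xyz"
        parts = []
        for row in range(3):
            s = ""
            for col in range(3):
                coef = self.rotation[row, col]
                if coef == 0:
                    continue
                s += ("-" if coef < 0 else ("+" if s else "")) + axes[col]
            t = Fraction(self.translation[row]).limit_denominator(12)
            if t != 0:
                s += ("+" if t > 0 else "") + str(t)
            parts.append(s)
        return ",".join(parts)

    # -- algebra ------------------------------------------------------
    def apply(self, frac: np.ndarray) -> np.ndarray:
        frac = np.asarray(frac, dtype=float)
        return frac @ self.rotation.T + self.translation

    def compose(self, other: "SymOp") -> "SymOp":
        """Return self ∘ other (apply ``other`` first)."""
        return SymOp(self.rotation @ other.rotation,
                     self.rotation @ other.translation + self.translation)

    def inverse(self) -> "SymOp":
        rinv = np.round(np.linalg.inv(self.rotation)).astype(int)
        return SymOp(rinv, -rinv @ self.translation)

    @property
    def is_identity(self) -> bool:
        return bool(np.array_equal(self.rotation, np.eye(3, dtype=int))
                    and np.allclose(self.translation, 0.0))

    def key(self, mod_lattice: bool = False) -> tuple:
        t = self.translation % 1.0 if mod_lattice else self.translation
        return (tuple(int(x) for x in self.rotation.flat),
                tuple(round(float(x), 6) for x in t))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SymOp) and self.key() == other.key()

    def __hash__(self) -> int:
        return hash(self.key())

    def __repr__(self) -> str:
        return f"SymOp({self.to_string()!r})"


# ---------------------------------------------------------------------------
# Hard-coded space-group tables (the groups occurring in the study, plus P1).
# Operators generated from the International Tables general positions, with
# centering translations applied explicitly.
# ---------------------------------------------------------------------------
_SG_TABLE: dict[str, tuple[list[str], tuple[float, float, float] | None]] = {
    "P 1": (["X,Y,Z"], None),
    "P 1 21 1": (["X,Y,Z", "-X,Y+1/2,-Z"], None),
    "I 2 2 2": (["X,Y,Z", "-X,-Y,Z", "-X,Y,-Z", "X,-Y,-Z"], (0.5, 0.5, 0.5)),
    "C 2 2 21": (["X,Y,Z", "-X,-Y,Z+1/2", "-X,Y,-Z+1/2", "X,-Y,-Z"], (0.5, 0.5, 0.0)),
    "P 21 21 21": (["X,Y,Z", "X+1/2,-Y+1/2,-Z", "-X,Y+1/2,-Z+1/2", "-X+1/2,-Y,Z+1/2"], None),
}

_SG_ALIASES = {
    "P1": "P 1",
    "P21": "P 1 21 1",
    "P1211": "P 1 21 1",
    "I222": "I 2 2 2",
    "C2221": "C 2 2 21",
    "P212121": "P 21 21 21",
}


def supported_space_groups() -> list[str]:
    return sorted(_SG_TABLE)


def _normalize_sg(symbol: str) -> str:
    compact = symbol.upper().replace(" ", "").replace("_", "")
    if compact not in _SG_ALIASES:
        raise SpaceGroupError(
            f"unsupported space group {symbol!r}; supported: {', '.join(supported_space_groups())}"
        )
    return _SG_ALIASES[compact]


def space_group_operators(symbol: str) -> list[SymOp]:
    """Full operator list (general positions × centering) for a supported group."""
    canonical = _normalize_sg(symbol)
    base_strings, centering = _SG_TABLE[canonical]
    ops = [SymOp.from_string(s) for s in base_strings]
    if centering is not None:
        ops += [SymOp(op.rotation, op.translation + np.array(centering)) for op in ops]
    return ops


@dataclass
class CrystalStructure:
    """Atoms plus crystal metadata (cell, space group, operators)."""

    atoms: list[AtomRecord]
    cell: UnitCell | None = None
    space_group: str | None = None
    operators: list[SymOp] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.cell is not None and not self.operators:
            if self.space_group:
                self.operators = space_group_operators(self.space_group)
            else:
                self.operators = [SymOp.identity()]

    @property
    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for atom in self.atoms:
            if atom.chain_id not in seen:
                seen.append(atom.chain_id)
        return seen

    def chain(self, chain_id: str) -> list[AtomRecord]:
        return [a for a in self.atoms if a.chain_id == chain_id]

    @property
    def protein_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if not a.is_hetero]

    def require_cell(self) -> UnitCell:
        if self.cell is None:
            raise ValueError("cell required for symmetry: structure has no CRYST1 record")
        return self.cell

    @property
    def multiplicity(self) -> int:
        return len(self.operators)


@dataclass(frozen=True)
class CrystalSummary:
    """Cell-level summary: volume, Matthews coefficient and solvent content."""

    cell_volume: float
    n_chains_asym: int
    multiplicity: int
    monomer_mass: float
    matthews: float
    solvent_fraction: float


# ---------------------------------------------------------------------------
# Parsing / writing
# ---------------------------------------------------------------------------

def _parse_float(line: str, ln: int, lo: int, hi: int, what: str, required: bool = True,
                 default: float = 0.0) -> float:
    fieldtxt = line[lo:hi].strip()
    if not fieldtxt:
        if required:
            raise PDBParseError(f"line {ln}: blank {what} field in record {line.rstrip()!r}")
        return default
    try:
        return float(fieldtxt)
    except ValueError:
        raise PDBParseError(f"line {ln}: bad {what} {fieldtxt!r} in record {line.rstrip()!r}") from None


def _parse_int(line: str, ln: int, lo: int, hi: int, what: str) -> int:
    fieldtxt = line[lo:hi].strip()
    try:
        return int(fieldtxt)
    except ValueError:
        raise PDBParseError(f"line {ln}: bad {what} {fieldtxt!r} in record {line.rstrip()!r}") from None


def _infer_element(name: str, residue_name: str, is_hetero: bool) -> str:
    stripped = "".join(ch for ch in name if ch.isalpha())
    if is_hetero and residue_name.strip() == stripped and stripped.upper() in _TWO_LETTER_ELEMENTS:
        return stripped.capitalize()
    return stripped[:1].upper() if stripped else ""


def _select_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep the highest-occupancy conformer; ties go to the first altloc label."""
    best: dict[tuple, AtomRecord] = {}
    order: list[tuple] = []
    for atom in atoms:
        key = (atom.chain_id, atom.residue_number, atom.residue_name, atom.name)
        if key not in best:
            best[key] = atom
            order.append(key)
        else:
            cur = best[key]
            if (atom.occupancy, _altloc_rank(atom)) > (cur.occupancy, _altloc_rank(cur)):
                best[key] = atom
    return [best[k] for k in order]


def _altloc_rank(atom: AtomRecord) -> float:
    # Higher rank wins ties; empty altloc first, then alphabetical ascending.
    if not atom.altloc:
        return 0.0
    return -ord(atom.altloc)


def parse_pdb(text: str, keep_altlocs: bool = False) -> CrystalStructure:
    """Parse ATOM/HETATM/CRYST1 records from fixed-column PDB text.

    Missing CRYST1 yields a structure without a cell; cell-dependent
    operations then refuse it.  Malformed records raise
    :class:`PDBParseError` naming the line.
    """
    atoms: list[AtomRecord] = []
    cell: UnitCell | None = None
    space_group: str | None = None
    for ln, raw in enumerate(text.splitlines(), start=1):
        rec = raw[:6].strip().upper()
        line = raw.ljust(80)
        if rec in ("ATOM", "HETATM"):
            serial = _parse_int(line, ln, 6, 11, "serial")
            name = line[12:16].strip()
            altloc = line[16].strip()
            residue_name = line[17:20].strip()
            chain_id = line[21].strip() or " "
            residue_number = _parse_int(line, ln, 22, 26, "residue number")
            x = _parse_float(line, ln, 30, 38, "x coordinate")
            y = _parse_float(line, ln, 38, 46, "y coordinate")
            z = _parse_float(line, ln, 46, 54, "z coordinate")
            occupancy = _parse_float(line, ln, 54, 60, "occupancy")
            b_factor = _parse_float(line, ln, 60, 66, "B-factor", required=False)
            element = line[76:78].strip().capitalize()
            is_hetero = rec == "HETATM"
            if not element:
                element = _infer_element(name, residue_name, is_hetero)
            if not element:
                raise PDBParseError(f"line {ln}: cannot determine element for {raw.rstrip()!r}")
            try:
                atoms.append(AtomRecord(
                    serial=serial, name=name, element=element,
                    residue_name=residue_name, residue_number=residue_number,
                    chain_id=chain_id, position=np.array([x, y, z]),
                    occupancy=occupancy, b_factor=b_factor,
                    is_hetero=is_hetero, altloc=altloc,
                ))
            except ValueError as exc:
                raise PDBParseError(f"line {ln}: {exc}") from None
        elif rec == "CRYST1":
            a = _parse_float(line, ln, 6, 15, "cell a")
            b = _parse_float(line, ln, 15, 24, "cell b")
            c = _parse_float(line, ln, 24, 33, "cell c")
            alpha = _parse_float(line, ln, 33, 40, "cell alpha")
            beta = _parse_float(line, ln, 40, 47, "cell beta")
            gamma = _parse_float(line, ln, 47, 54, "cell gamma")
            sg = line[55:66].strip()
            cell = UnitCell(a, b, c, alpha, beta, gamma)
            space_group = sg or "P 1"
    if not keep_altlocs:
        atoms = _select_altlocs(atoms)
    return CrystalStructure(atoms=atoms, cell=cell, space_group=space_group)


def write_pdb(structure: CrystalStructure) -> str:
    """Serialize to standard 80-column PDB records (CRYST1 + ATOM/HETATM + END)."""
    lines: list[str] = []
    if structure.cell is not None:
        c = structure.cell
        sg = structure.space_group or "P 1"
        lines.append(
            f"CRYST1{c.a:9.3f}{c.b:9.3f}{c.c:9.3f}"
            f"{c.alpha:7.2f}{c.beta:7.2f}{c.gamma:7.2f} {sg:<11s}{1:4d}".ljust(80)
        )
    for atom in structure.atoms:
        rec = "HETATM" if atom.is_hetero else "ATOM"
        name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
        lines.append(
            f"{rec:<6s}{atom.serial:5d} {name:<4s}{atom.altloc or ' ':1s}"
            f"{atom.residue_name:>3s} {atom.chain_id:1s}{atom.residue_number:4d}    "
            f"{atom.position[0]:8.3f}{atom.position[1]:8.3f}{atom.position[2]:8.3f}"
            f"{atom.occupancy:6.2f}{atom.b_factor:6.2f}          {atom.element.upper():>2s}".ljust(80)
        )
    lines.append("END".ljust(80))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Cell-level quantities
# ---------------------------------------------------------------------------

def cell_volume(cell: UnitCell) -> float:
    """Unit-cell volume in ų (general triclinic formula)."""
    v = cell.volume
    if v <= 0:
        raise ValueError("degenerate cell: non-positive volume")
    return v


def matthews(V: float, n_total_chains: int, M: float) -> float:
    """Matthews coefficient Vm = V / (n_total_chains × M) in ų/Da.

    ``n_total_chains`` counts chains in the whole unit cell, i.e. chains per
    asymmetric unit × space-group multiplicity.
    """
    if V <= 0:
        raise ValueError("cell volume must be positive")
    if n_total_chains <= 0:
        raise ValueError("chain count must be positive")
    if M <= 0:
        raise ValueError("monomer mass must be positive")
    return V / (n_total_chains * M)


def solvent_content(Vm: float) -> float:
    """Solvent fraction 1 − 1.2284/Vm; errors for non-physical Vm."""
    if Vm <= SOLVENT_CONSTANT:
        raise ValueError(f"solvent fraction non-positive for Vm = {Vm} ų/Da")
    return 1.0 - SOLVENT_CONSTANT / Vm


def chain_mass(residues: Iterable) -> float:
    """Average mass (Da) of a polypeptide from residue codes or AtomRecords.

    Unknown residue codes are reported via a warning and excluded from the sum.
    """
    codes: list[str] = []
    seen_residues: set[tuple] = set()
    for item in residues:
        if isinstance(item, AtomRecord):
            key = (item.chain_id, item.residue_number)
            if key in seen_residues:
                continue
            seen_residues.add(key)
            codes.append(item.residue_name.upper())
        else:
            codes.append(str(item).upper())
    known = [c for c in codes if c in RESIDUE_MASSES]
    unknown = sorted({c for c in codes if c not in RESIDUE_MASSES})
    if unknown:
        warnings.warn(f"unknown residue codes excluded from mass: {', '.join(unknown)}",
                      stacklevel=2)
    if not known:
        return 0.0
    total = sum(RESIDUE_MASSES[c] for c in known)
    return total - (len(known) - 1) * WATER_MASS


def summarize_crystal(structure: CrystalStructure,
                      monomer_mass: float | None = None,
                      n_chains_asym: int | None = None) -> CrystalSummary:
    """Matthews/solvent summary for a structure with a cell.

    The monomer mass defaults to :func:`chain_mass` of the longest protein
    chain; it is exposed as a parameter because deposited headers rarely state
    the mass used for the printed Vm.
    """
    cell = structure.require_cell()
    protein = structure.protein_atoms
    chains: dict[str, list[AtomRecord]] = {}
    for atom in protein:
        chains.setdefault(atom.chain_id, []).append(atom)
    if n_chains_asym is None:
        n_chains_asym = len(chains)
    if n_chains_asym <= 0:
        raise ValueError("no protein chains in asymmetric unit")
    if monomer_mass is None:
        longest = max(chains.values(), key=len)
        monomer_mass = chain_mass(longest)
    V = cell_volume(cell)
    vm = matthews(V, n_chains_asym * structure.multiplicity, monomer_mass)
    return CrystalSummary(
        cell_volume=V, n_chains_asym=n_chains_asym,
        multiplicity=structure.multiplicity, monomer_mass=monomer_mass,
        matthews=vm, solvent_fraction=solvent_content(vm),
    )
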