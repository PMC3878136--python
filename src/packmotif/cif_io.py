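"""Minimal CIF 1.1 reading/writing and unit-cell metrics.

The dialect supported is the one small-molecule deposits and CSD exports actually use:
cell lengths/angles, symmetry operators as xyz strings (either the older
``_symmetry_equiv_pos_as_xyz`` or the newer ``_space_group_symop_operation_xyz`` loop
tag), and an atom-site loop with label, type symbol and fractional coordinates.
Macromolecular mmCIF, anisotropic displacement parameters and reflection blocks are
out of scope.

Cell metrics follow the standard crystallographic relations

    V   = a b c sqrt(1 - cos^2(alpha) - cos^2(beta) - cos^2(gamma)
                       + 2 cos(alpha) cos(beta) cos(gamma))
    D_c = Z M / (N_A V)

with M the formula weight per formula unit and Z the number of formula units per
cell.  When a deposit does not state Z it is inferred by an exhaustive scan against a
physically plausible density window for organics ([0.5, 3.5] g/cm^3, preferring the
value closest to 1.4 g/cm^3).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from fractions import Fraction

import gemmi
import numpy as np

from .errors import CifParseError, GeometryError, InferenceError
from .tables import AMU_PER_A3_TO_G_PER_CM3, atomic_weight, normalize_element

__all__ = [
    "UnitCell",
    "SymmetryOperator",
    "AtomSite",
    "CellContents",
    "parse_cif",
    "write_cif",
    "cell_volume",
    "calc_density",
    "infer_z",
    "formula_weight",
]

DENSITY_WINDOW = (0.5, 3.5)  # g/cm^3, plausible for molecular organics
DENSITY_ANCHOR = 1.4  # g/cm^3, typical organic crystal density
AMBIGUITY_GAP = 0.15  # g/cm^3


# --------------------------------------------------------------------------- types

@dataclass(frozen=True)
class UnitCell:
    """Unit-cell lengths (Angstrom) and angles (degrees)."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise GeometryError(f"cell lengths must be positive: {self}")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise GeometryError(f"cell angles must lie in (0, 180): {self}")

    @property
    def lengths(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    @property
    def angles(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.gamma)

    @property
    def metric_tensor(self) -> np.ndarray:
        """G with G_ij = e_i . e_j (symmetric positive definite for a valid cell)."""
        a, b, c = self.lengths
        ca, cb, cg = (math.cos(math.radians(x)) for x in self.angles)
        return np.array(
            [
                [a * a, a * b * cg, a * c * cb],
                [a * b * cg, b * b, b * c * ca],
                [a * c * cb, b * c * ca, c * c],
            ]
        )


@dataclass(frozen=True)
class SymmetryOperator:
    """Space-group operator on fractional coordinates: x -> rot @ x + tran (mod 1).

    ``rot`` is a 3x3 integer matrix, ``tran`` a triple of exact rational fractions
    in [0, 1).
    """

    rot: tuple[tuple[int, int, int], ...]
    tran: tuple[Fraction, Fraction, Fraction]

    def __post_init__(self):
        det = self.determinant
        if det not in (1, -1):
            raise GeometryError(f"operator rotation determinant must be +-1, got {det}")
        object.__setattr__(self, "tran", tuple(t % 1 for t in self.tran))

    # -- construction ------------------------------------------------------
    @classmethod
    def identity(cls) -> "SymmetryOperator":
        return cls(((1, 0, 0), (0, 1, 0), (0, 0, 1)), (Fraction(0),) * 3)

    @classmethod
    def from_xyz(cls, triplet: str) -> "SymmetryOperator":
        try:
            op = gemmi.Op(triplet)
        except (RuntimeError, ValueError) as exc:
            raise CifParseError(f"malformed symmetry operator string {triplet!r}") from exc
        den = gemmi.Op.DEN
        rot_rows = []
        for row in op.rot:
            if any(v % den for v in row):
                raise CifParseError(f"non-crystallographic rotation in {triplet!r}")
            rot_rows.append(tuple(v // den for v in row))
        tran = tuple(Fraction(t, den) for t in op.tran)
        return cls(tuple(rot_rows), tran)

    # -- views -------------------------------------------------------------
    @property
    def rot_array(self) -> np.ndarray:
        return np.array(self.rot, dtype=int)

    @property
    def tran_array(self) -> np.ndarray:
        return np.array([float(t) for t in self.tran])

    @property
    def determinant(self) -> int:
        return round(np.linalg.det(np.array(self.rot, dtype=float)))

    @property
    def is_identity_rotation(self) -> bool:
        return self.rot == ((1, 0, 0), (0, 1, 0), (0, 0, 1))

    @property
    def is_pure_translation(self) -> bool:
        return self.is_identity_rotation

    # -- algebra -----------------------------------------------------------
    def apply(self, fract) -> np.ndarray:
        """Image of a fractional coordinate (not wrapped)."""
        return self.rot_array @ np.asarray(fract, dtype=float) + self.tran_array

    def compose(self, other: "SymmetryOperator") -> "SymmetryOperator":
        """self o other, reduced modulo lattice translations."""
        r1, r2 = self.rot_array, other.rot_array
        rot = tuple(tuple(int(v) for v in row) for row in (r1 @ r2))
        tran = tuple(
            (sum(Fraction(int(r1[i][j])) * other.tran[j] for j in range(3)) + self.tran[i]) % 1
            for i in range(3)
        )
        return SymmetryOperator(rot, tran)

    def to_xyz(self) -> str:
        terms = []
        names = "xyz"
        for i in range(3):
            s = ""
            for j in range(3):
                v = self.rot[i][j]
                if v == 0:
                    continue
                sign = "-" if v < 0 else ("+" if s else "")
                coef = "" if abs(v) == 1 else str(abs(v)) + "*"
                s += f"{sign}{coef}{names[j]}"
            t = self.tran[i]
            if t:
                s += f"+{t.numerator}/{t.denominator}"
            terms.append(s or "0")
        return ", ".join(terms)


@dataclass(frozen=True)
class AtomSite:
    """One site of the asymmetric unit, in fractional coordinates."""

    label: str
    element: str
    fract: tuple[float, float, float]
    occupancy: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.occupancy <= 1.0:
            raise CifParseError(
                f"site {self.label}: occupancy must be in (0, 1], got {self.occupancy}"
            )

    @property
    def fract_array(self) -> np.ndarray:
        return np.array(self.fract)


@dataclass
class CellContents:
    """A parsed crystal structure: cell, operators and asymmetric-unit sites."""

    structure_id: str
    cell: UnitCell
    operators: list[SymmetryOperator]
    sites: list[AtomSite]
    formula_weight: float | None = None
    z_value: int | None = None
    stated_volume: float | None = None
    comment: str | None = None

    def __post_init__(self):
        labels = [s.label for s in self.sites]
        if len(labels) != len(set(labels)):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise CifParseError(f"{self.structure_id}: duplicate site labels {dupes}")

    @property
    def n_operators(self) -> int:
        return len(self.operators)

    def with_sites(self, sites) -> "CellContents":
        return replace(self, sites=list(sites))


# --------------------------------------------------------------------------- metrics

def cell_volume(cell: UnitCell) -> float:
    """Unit-cell volume in cubic Angstrom."""
    ca, cb, cg = (math.cos(math.radians(x)) for x in cell.angles)
    arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
    if arg <= 0:
        raise GeometryError(f"cell metric not positive definite: {cell}")
    return cell.a * cell.b * cell.c * math.sqrt(arg)


def calc_density(cell: UnitCell, formula_weight: float, z_value: int) -> float:
    """Calculated crystal density D = Z M / (N_A V) in g/cm^3."""
    if z_value < 1:
        raise ValueError(f"z_value must be >= 1, got {z_value}")
    if formula_weight <= 0:
        raise ValueError(f"formula_weight must be positive, got {formula_weight}")
    return z_value * formula_weight * AMU_PER_A3_TO_G_PER_CM3 / cell_volume(cell)


def infer_z(
    cell: UnitCell,
    formula_weight: float,
    n_operators: int | None = None,
    z_max: int = 32,
) -> int:
    """Infer the number of formula units per cell from a density-plausibility scan.

    Scans candidate Z values up to ``z_max``, keeps those whose calculated density
    lies in the organic window [0.5, 3.5] g/cm^3 and returns the one closest to
    1.4 g/cm^3.  When ``n_operators`` (the space-group order) is given, Z is
    restricted to crystallographically possible values: integer multiples of the
    operator count, plus half the operator count for formula units sitting on a
    special position.  Raises :class:`InferenceError` if the window is empty or if
    two candidates lie within 0.15 g/cm^3 of each other (ambiguous; pass an
    explicit Z instead).
    """
    lo, hi = DENSITY_WINDOW
    if n_operators is not None:
        allowed = [n_operators * k for k in range(1, z_max // n_operators + 1)]
        if n_operators % 2 == 0:
            allowed = [n_operators // 2] + allowed
    else:
        allowed = list(range(1, z_max + 1))
    candidates = []
    for z in allowed:
        d = calc_density(cell, formula_weight, z)
        if lo <= d <= hi:
            candidates.append((abs(d - DENSITY_ANCHOR), z, d))
    if not candidates:
        raise InferenceError(
            f"no Z in 1..{z_max} gives a density in {DENSITY_WINDOW} g/cm^3 "
            f"(M={formula_weight}, V={cell_volume(cell):.2f})"
        )
    candidates.sort()
    if len(candidates) > 1 and abs(candidates[0][2] - candidates[1][2]) < AMBIGUITY_GAP:
        raise InferenceError(
            "ambiguous Z: densities "
            f"{candidates[0][2]:.3f} (Z={candidates[0][1]}) and "
            f"{candidates[1][2]:.3f} (Z={candidates[1][1]}) are both plausible"
        )
    return candidates[0][1]


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


def formula_weight(formula: str) -> float:
    """Molecular weight (g/mol) of an empirical formula such as ``"C15H12BrNO2"``.

    Spaces between element-count pairs (the CIF ``_chemical_formula_sum``
    convention) are accepted.
    """
    s = formula.replace(" ", "")
    pos, total = 0, 0.0
    while pos < len(s):
        m = _FORMULA_TOKEN.match(s, pos)
        if not m or not m.group(1):
            raise CifParseError(f"cannot parse formula {formula!r} at {s[pos:]!r}")
        count = float(m.group(2)) if m.group(2) else 1.0
        total += atomic_weight(m.group(1)) * count
        pos = m.end()
    if total == 0.0:
        raise CifParseError(f"empty formula {formula!r}")
    return total


# --------------------------------------------------------------------------- parsing

_SU_RE = re.compile(r"\((\d+)\)\s*$")


def _as_number(value: str, tag: str) -> float:
    """CIF numeric value; tolerates a trailing standard-uncertainty '(n)'."""
    try:
        return float(_SU_RE.sub("", value.strip()))
    except ValueError as exc:
        raise CifParseError(f"malformed numeric value {value!r} for {tag}") from exc


_CELL_TAGS = {
    "a": "_cell_length_a",
    "b": "_cell_length_b",
    "c": "_cell_length_c",
    "alpha": "_cell_angle_alpha",
    "beta": "_cell_angle_beta",
    "gamma": "_cell_angle_gamma",
}
_SYMOP_TAGS = ("_space_group_symop_operation_xyz", "_symmetry_equiv_pos_as_xyz")


def _element_from_label(label: str) -> str:
    """Element symbol from an atom label when no type-symbol column exists.

    Strips trailing digits/primes then tries the two-letter prefix before the
    one-letter one (``"Br1"`` -> Br, ``"C12"`` -> C).
    """
    stem = re.sub(r"[\d'\"*]+$", "", label.strip())
    for n in (2, 1):
        if len(stem) >= n:
            cand = normalize_element(stem[:n])
            from .tables import ATOMIC_WEIGHT

            if cand in ATOMIC_WEIGHT:
                return cand
    raise CifParseError(f"cannot infer element from label {label!r}")


def parse_cif(text: str, structure_id: str | None = None) -> CellContents:
    """Parse one data block of a CIF 1.1 document into :class:`CellContents`.

    Fractional coordinates are wrapped into [0, 1); missing occupancies default to
    1.0; the identity operator is guaranteed present (and first) in the returned
    operator list.
    """
    try:
        doc = gemmi.cif.read_string(text)
        block = doc.sole_block()
    except (RuntimeError, ValueError) as exc:
        raise CifParseError(f"unreadable CIF document: {exc}") from exc

    sid = structure_id or block.name or "unnamed"

    cell_vals = {}
    for key, tag in _CELL_TAGS.items():
        raw = block.find_value(tag)
        if raw is None:
            raise CifParseError(f"{sid}: missing mandatory tag {tag}")
        cell_vals[key] = _as_number(raw, tag)
    cell = UnitCell(**cell_vals)

    operators: list[SymmetryOperator] = []
    for tag in _SYMOP_TAGS:
        col = block.find_loop(tag)
        strings = list(col) if col else []
        if not strings:
            one = block.find_value(tag)
            if one is not None:
                strings = [one]
        if strings:
            operators = [SymmetryOperator.from_xyz(gemmi.cif.as_string(s)) for s in strings]
            break
    if not operators:
        raise CifParseError(
            f"{sid}: missing mandatory tag {_SYMOP_TAGS[0]} (or {_SYMOP_TAGS[1]})"
        )
    ident = SymmetryOperator.identity()
    operators = [ident] + [op for op in dict.fromkeys(operators) if op != ident]

    table = block.find(
        "_atom_site_",
        ["label", "?type_symbol", "fract_x", "fract_y", "fract_z", "?occupancy"],
    )
    if len(table) == 0:
        raise CifParseError(f"{sid}: missing mandatory tag _atom_site_label loop")
    sites = []
    for row in table:
        label = gemmi.cif.as_string(row[0])
        if table.has_column(1):
            element = normalize_element(re.sub(r"[\d+-]+$", "", gemmi.cif.as_string(row[1])))
        else:
            element = _element_from_label(label)
        fract = tuple(
            _as_number(row[2 + i], f"_atom_site_fract_{ax}") % 1.0
            for i, ax in enumerate("xyz")
        )
        occ = 1.0
        if table.has_column(5):
            raw = gemmi.cif.as_string(row[5])
            if raw not in (".", "?"):
                occ = _as_number(raw, "_atom_site_occupancy")
        sites.append(AtomSite(label, element, fract, occ))

    fw = block.find_value("_chemical_formula_weight")
    zval = block.find_value("_cell_formula_units_Z")
    vol = block.find_value("_cell_volume")
    return CellContents(
        structure_id=sid,
        cell=cell,
        operators=operators,
        sites=sites,
        formula_weight=_as_number(fw, "_chemical_formula_weight") if fw else None,
        z_value=int(_as_number(zval, "_cell_formula_units_Z")) if zval else None,
        stated_volume=_as_number(vol, "_cell_volume") if vol else None,
    )


def write_cif(contents: CellContents) -> str:
    """Serialize :class:`CellContents` to the same minimal dialect parse_cif reads.

    Output is deterministic: fixed tag order, 6-decimal coordinates.
    """
    lines = [f"data_{contents.structure_id}"]
    if contents.comment:
        for ln in contents.comment.splitlines():
            lines.append(f"# {ln}")
    cell = contents.cell
    for tag, val in [
        ("_cell_length_a", cell.a),
        ("_cell_length_b", cell.b),
        ("_cell_length_c", cell.c),
        ("_cell_angle_alpha", cell.alpha),
        ("_cell_angle_beta", cell.beta),
        ("_cell_angle_gamma", cell.gamma),
    ]:
        lines.append(f"{tag}  {val:.6f}")
    lines.append(f"_cell_volume  {cell_volume(cell):.4f}")
    if contents.formula_weight is not None:
        lines.append(f"_chemical_formula_weight  {contents.formula_weight:.2f}")
    if contents.z_value is not None:
        lines.append(f"_cell_formula_units_Z  {contents.z_value}")
    lines.append("loop_")
    lines.append("_space_group_symop_operation_xyz")
    for op in contents.operators:
        lines.append(f"  '{op.to_xyz()}'")
    lines.append("loop_")
    for sub in ("label", "type_symbol", "fract_x", "fract_y", "fract_z", "occupancy"):
        lines.append(f"_atom_site_{sub}")
    for s in contents.sites:
        x, y, z = s.fract
        lines.append(
            f"{s.label}  {s.element}  {x:.6f}  {y:.6f}  {z:.6f}  {s.occupancy:.4f}"
        )
    return "\n".join(lines) + "\n"
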