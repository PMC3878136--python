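"""From cell contents to molecules in Cartesian space.

The chain is: orthogonalize fractional coordinates (standard setting, *a* along x,
*b* in the xy-plane), perceive covalent bonds from summed covalent radii, and collect
connected components into :class:`Molecule` objects, unwrapping each across cell
boundaries so it is spatially contiguous.  Symmetry and lattice-translation images of
any molecule are produced on demand with full provenance (operator index + integer
lattice shift), which is what the cluster builder and the similarity engine consume.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .cif_io import AtomSite, CellContents, UnitCell, cell_volume
from .errors import GeometryError
from .tables import covalent_radius

__all__ = [
    "Provenance",
    "Molecule",
    "CrystalStructure",
    "orthogonalization_matrix",
    "frac_to_cart",
    "perceive_bonds",
    "assemble_molecules",
    "select_major_conformer",
    "classify_cc_geometry",
    "torsion_angle",
]

BOND_TOLERANCE = 0.40  # Angstrom, added to the covalent-radius sum
SPECIAL_POSITION_TOL = 0.30  # Angstrom, image-coincidence threshold


def orthogonalization_matrix(cell: UnitCell) -> np.ndarray:
    """Fractional -> Cartesian matrix M (columns are the cell vectors).

    Standard crystallographic convention: a along x, b in the xy-plane.
    Satisfies M.T @ M == metric tensor.
    """
    a, b, c = cell.lengths
    ca, cb, cg = (math.cos(math.radians(x)) for x in cell.angles)
    sg = math.sin(math.radians(cell.gamma))
    v = cell_volume(cell)
    return np.array(
        [
            [a, b * cg, c * cb],
            [0.0, b * sg, c * (ca - cb * cg) / sg],
            [0.0, 0.0, v / (a * b * sg)],
        ]
    )


def frac_to_cart(cell: UnitCell, fract) -> np.ndarray:
    """Cartesian position (Angstrom) of fractional coordinates (vector or array)."""
    return np.asarray(fract, dtype=float) @ orthogonalization_matrix(cell).T


# ------------------------------------------------------------------- provenance

@dataclass(frozen=True)
class Provenance:
    """How a molecule image was generated from its asymmetric-unit representative."""

    mol_index: int = 0
    op_index: int = 0
    shift: tuple[int, int, int] = (0, 0, 0)

    @property
    def is_identity(self) -> bool:
        return self.op_index == 0 and self.shift == (0, 0, 0)

    def key(self) -> tuple:
        return (self.mol_index, self.op_index, self.shift)


# ------------------------------------------------------------------- molecule

@dataclass
class Molecule:
    """A chemically connected unit in Cartesian space."""

    labels: list[str]
    elements: list[str]
    coords: np.ndarray  # (n, 3) Angstrom
    occupancies: np.ndarray
    bonds: list[tuple[int, int]]
    provenance: Provenance = field(default_factory=Provenance)
    fract: np.ndarray | None = None  # unwrapped fractional coords of the representative

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.occupancies = np.asarray(self.occupancies, dtype=float)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def centroid(self) -> np.ndarray:
        """Unweighted mean of all atom positions."""
        return self.coords.mean(axis=0)

    @property
    def is_water(self) -> bool:
        heavy = [e for e in self.elements if e != "H"]
        return heavy == ["O"] and len(self) <= 3

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"no atom labelled {label!r} in molecule") from None

    def subset_coords(self, labels) -> np.ndarray:
        return self.coords[[self.index_of(l) for l in labels]]

    def transformed(self, rot: np.ndarray | None = None, trans=None,
                    provenance: Provenance | None = None) -> "Molecule":
        coords = self.coords
        if rot is not None:
            coords = coords @ np.asarray(rot).T
        if trans is not None:
            coords = coords + np.asarray(trans)
        return replace(self, coords=coords,
                       provenance=provenance if provenance is not None else self.provenance)


# ------------------------------------------------------------------- bonds

def perceive_bonds(elements, coords, tolerance: float = BOND_TOLERANCE):
    """Covalent bonds from the distance criterion d <= r_i + r_j + tolerance.

    H-H bonds are never formed and each hydrogen keeps only the bond to its nearest
    heavy atom.  Isolated atoms are allowed.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(elements)
    radii = np.array([covalent_radius(e) for e in elements])
    bonds: list[tuple[int, int]] = []
    if n < 2:
        return bonds
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    cut = radii[:, None] + radii[None, :] + tolerance
    cand = [(i, j) for i in range(n) for j in range(i + 1, n)
            if dist[i, j] <= cut[i, j] and dist[i, j] > 1e-6]
    h_best: dict[int, tuple[float, int]] = {}
    plain = []
    for i, j in cand:
        hi, hj = elements[i] == "H", elements[j] == "H"
        if hi and hj:
            continue
        if hi or hj:
            h, heavy = (i, j) if hi else (j, i)
            d = dist[i, j]
            if h not in h_best or d < h_best[h][0]:
                h_best[h] = (d, heavy)
        else:
            plain.append((i, j))
    bonds = plain + [tuple(sorted((h, heavy))) for h, (_, heavy) in h_best.items()]
    return sorted(bonds)


def _periodic_bond_edges(cell, fracts, elements, tolerance):
    """Bond edges (i, j, shift) meaning atom i bonds the image of atom j at +shift."""
    M = orthogonalization_matrix(cell)
    radii = np.array([covalent_radius(e) for e in elements])
    n = len(elements)
    edges = []
    shifts = list(itertools.product((-1, 0, 1), repeat=3))
    carts = {s: (fracts + np.array(s)) @ M.T for s in shifts}
    base = carts[(0, 0, 0)]
    for s in shifts:
        d = np.linalg.norm(base[:, None, :] - carts[s][None, :, :], axis=-1)
        cut = radii[:, None] + radii[None, :] + tolerance
        for i in range(n):
            for j in range(n):
                if d[i, j] <= cut[i, j] and d[i, j] > 1e-6:
                    if elements[i] == "H" and elements[j] == "H":
                        continue
                    edges.append((i, j, s, d[i, j]))
    # hydrogen: keep only the nearest heavy atom
    h_best = {}
    kept = []
    for i, j, s, d in edges:
        if elements[i] == "H":
            if i not in h_best or d < h_best[i][0]:
                h_best[i] = (d, j, s)
        else:
            kept.append((i, j, s))
    for i, (_, j, s) in h_best.items():
        kept.append((i, j, s))
        kept.append((j, i, tuple(-x for x in s)))
    # drop heavy->H edges not retained by the hydrogen rule
    final = []
    for i, j, s in kept:
        if elements[j] == "H":
            if j in h_best and h_best[j][1] == i and h_best[j][2] == tuple(-x for x in s):
                final.append((i, j, s))
        else:
            final.append((i, j, s))
    return final


def assemble_molecules(contents: CellContents, tolerance: float = BOND_TOLERANCE,
                       major_conformer: bool = True):
    """Connected components of the asymmetric unit, unwrapped to contiguity.

    Returns ``(molecules, flagged)`` where ``flagged`` lists components that cannot
    be unwrapped to a finite contiguous unit (polymeric / catenated); these are
    excluded from ``molecules``.
    """
    sites = list(contents.sites)
    if major_conformer:
        sites = select_major_conformer(sites, contents.cell)
    if not sites:
        return [], []
    fracts = np.array([s.fract for s in sites])
    elements = [s.element for s in sites]
    edges = _periodic_bond_edges(contents.cell, fracts, elements, tolerance)
    adj: dict[int, list[tuple[int, tuple[int, int, int]]]] = {i: [] for i in range(len(sites))}
    for i, j, s in edges:
        adj[i].append((j, s))

    M = orthogonalization_matrix(contents.cell)
    unassigned = set(range(len(sites)))
    molecules, flagged = [], []
    while unassigned:
        seed = min(unassigned)
        offset = {seed: np.zeros(3)}
        queue, polymeric = [seed], False
        while queue:
            i = queue.pop()
            for j, s in adj[i]:
                cand = offset[i] + np.array(s)
                if j in offset:
                    if not np.allclose(offset[j], cand):
                        polymeric = True
                else:
                    offset[j] = cand
                    queue.append(j)
        members = sorted(offset)
        unassigned -= set(members)
        unwrapped = np.array([fracts[i] + offset[i] for i in members])
        coords = unwrapped @ M.T
        local = {g: k for k, g in enumerate(members)}
        bonds = sorted({tuple(sorted((local[i], local[j])))
                        for i, j, _ in edges if i in local and j in local})
        mol = Molecule(
            labels=[sites[i].label for i in members],
            elements=[sites[i].element for i in members],
            coords=coords,
            occupancies=np.array([sites[i].occupancy for i in members]),
            bonds=bonds,
            provenance=Provenance(mol_index=len(molecules)),
            fract=unwrapped,
        )
        (flagged if polymeric else molecules).append(mol)
    for k, m in enumerate(molecules):
        m.provenance = Provenance(mol_index=k)
    return molecules, flagged


# ------------------------------------------------------------------- disorder

def select_major_conformer(sites, cell: UnitCell):
    """Resolve occupancy disorder: keep the highest-occupancy alternative per group.

    Two partially occupied sites of the same element closer than 0.8 Angstrom, or
    partially occupied sites sharing a label stem (``C5A``/``C5B``), belong to one
    disorder group.  Ties break deterministically by label sort order.  Fully
    occupied input is returned unchanged.
    """
    partial = [i for i, s in enumerate(sites) if s.occupancy < 1.0]
    if not partial:
        return list(sites)
    carts = frac_to_cart(cell, np.array([s.fract for s in sites]))
    parent = {i: i for i in partial}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    def stem(label):
        return label.rstrip("ABab'")

    for a, b in itertools.combinations(partial, 2):
        sa, sb = sites[a], sites[b]
        same_stem = stem(sa.label) == stem(sb.label) and sa.label != sb.label
        close = (sa.element == sb.element
                 and np.linalg.norm(carts[a] - carts[b]) < 0.8)
        if same_stem or close:
            union(a, b)
    groups: dict[int, list[int]] = {}
    for i in partial:
        groups.setdefault(find(i), []).append(i)
    drop = set()
    for members in groups.values():
        if len(members) < 2:
            continue
        members.sort(key=lambda i: (-sites[i].occupancy, sites[i].label))
        drop.update(members[1:])
    return [s for i, s in enumerate(sites) if i not in drop]


# ------------------------------------------------------------------- geometry helpers

def torsion_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1 @ n2
    y = m1 @ n2
    return math.degrees(math.atan2(y, x))


def classify_cc_geometry(molecule: Molecule, bond: tuple[str, str],
                         references: tuple[str, str]) -> str:
    """E/Z label of a double bond from the reference-atom torsion.

    Convention (fixed): torsion(reference1 - atom1 = atom2 - reference2) in
    [-90, 90] degrees -> ``"Z"``, otherwise ``"E"``.  With the carbonyl-side
    carbon as reference1 and the aryl ipso carbon as reference2 this reproduces
    the E/Z nomenclature of the 3-benzylidene-oxindoles.
    """
    try:
        r1, a1, a2, r2 = (molecule.coords[molecule.index_of(l)]
                          for l in (references[0], bond[0], bond[1], references[1]))
    except KeyError as exc:
        raise GeometryError(f"E/Z classification: {exc}") from exc
    tau = torsion_angle(r1, a1, a2, r2)
    return "Z" if -90.0 <= tau <= 90.0 else "E"


# ------------------------------------------------------------------- structure

class CrystalStructure:
    """Cell contents plus assembled molecules and an image generator.

    Parameters
    ----------
    contents:
        Parsed CIF contents.
    bond_tolerance:
        Added to covalent-radius sums during bond perception.
    """

    def __init__(self, contents: CellContents, bond_tolerance: float = BOND_TOLERANCE,
                 major_conformer: bool = True):
        self.contents = contents
        self.cell = contents.cell
        self.ortho = orthogonalization_matrix(contents.cell)
        self.bond_tolerance = bond_tolerance
        self.molecules_asym, self.flagged = assemble_molecules(
            contents, tolerance=bond_tolerance, major_conformer=major_conformer)

    # -- identity ----------------------------------------------------------
    @property
    def structure_id(self) -> str:
        return self.contents.structure_id

    @property
    def operators(self):
        return self.contents.operators

    def __repr__(self):
        return (f"CrystalStructure({self.structure_id!r}, "
                f"{len(self.molecules_asym)} molecules, "
                f"{len(self.operators)} operators)")

    # -- hosts / waters ----------------------------------------------------
    def host_molecules(self):
        hosts = [m for m in self.molecules_asym if not m.is_water]
        return hosts if hosts else list(self.molecules_asym)

    def host(self) -> Molecule:
        """The largest non-water molecule (the kernel default)."""
        return max(self.host_molecules(), key=len)

    # -- images ------------------------------------------------------------
    def image_fract(self, mol: Molecule, op_index: int, shift) -> np.ndarray:
        op = self.operators[op_index]
        return mol.fract @ op.rot_array.T + op.tran_array + np.asarray(shift, dtype=float)

    def image_molecule(self, mol_index: int, op_index: int, shift) -> Molecule:
        """Symmetry/translation image of an asymmetric-unit molecule."""
        mol = self.molecules_asym[mol_index]
        fr = self.image_fract(mol, op_index, shift)
        return replace(
            mol,
            coords=fr @ self.ortho.T,
            fract=fr,
            provenance=Provenance(mol_index, op_index, tuple(int(x) for x in shift)),
        )

    def iter_images(self, window: int = 1, include_identity: bool = True):
        """All molecule images for ops x integer shifts in [-window, window]^3."""
        for mi in range(len(self.molecules_asym)):
            for oi in range(len(self.operators)):
                for shift in itertools.product(range(-window, window + 1), repeat=3):
                    prov = Provenance(mi, oi, shift)
                    if not include_identity and prov.is_identity:
                        continue
                    yield self.image_molecule(mi, oi, shift)

    def expanded_positions(self, dedup_tol: float = SPECIAL_POSITION_TOL):
        """All atom positions in one cell generated from the asymmetric unit.

        Applies every operator to every site, wraps into [0,1) and removes
        special-position duplicates closer than ``dedup_tol``.
        Returns (labels, elements, fractional array).
        """
        fr = np.array([s.fract for s in self.contents.sites])
        labels = [s.label for s in self.contents.sites]
        elements = [s.element for s in self.contents.sites]
        out_l, out_e, out_f = [], [], []
        for op in self.operators:
            img = (fr @ op.rot_array.T + op.tran_array) % 1.0
            for l, e, f in zip(labels, elements, img):
                dup = False
                for g in out_f:
                    d = f - np.asarray(g)
                    d -= np.round(d)
                    if np.linalg.norm(d @ self.ortho.T) < dedup_tol:
                        dup = True
                        break
                if not dup:
                    out_l.append(l)
                    out_e.append(e)
                    out_f.append(f)
        return out_l, out_e, np.array(out_f)
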