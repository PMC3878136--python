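"""Per-structure geometric analysis: hydrogen bonds, sub-vdW contacts, mean planes.

All searches run over symmetry *and* lattice-translation images of the assembled
molecules, so every interaction of the asymmetric unit with the surrounding crystal
is seen exactly once.  Distances are in Angstrom, angles in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .crystal_model import CrystalStructure, Molecule, Provenance
from .errors import GeometryError
from .tables import vdw_radius

__all__ = [
    "HBondCriteria",
    "HydrogenBond",
    "CloseContact",
    "MeanPlane",
    "find_hydrogen_bonds",
    "find_close_contacts",
    "mean_plane",
    "interplanar_angle",
    "translation_window",
]


# ------------------------------------------------------------------ criteria

@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond acceptance criteria.

    Defaults (D...A <= 3.5 A, D-H...A >= 120 deg, N/O donors and acceptors) are wide
    enough to capture the 2.68-2.90 A / 151-177 deg interactions typical of amide and
    water donors in molecular crystals, with headroom.
    """

    max_da: float = 3.5
    min_angle: float = 120.0
    donor_elements: frozenset = frozenset({"N", "O"})
    acceptor_elements: frozenset = frozenset({"N", "O"})


@dataclass(frozen=True)
class HydrogenBond:
    donor_label: str
    hydrogen_label: str | None
    acceptor_label: str
    donor_mol: int
    acceptor_provenance: Provenance
    d_da: float
    angle_dha: float | None

    def __str__(self):
        h = f"-{self.hydrogen_label}" if self.hydrogen_label else ""
        ang = f", {self.angle_dha:.1f} deg" if self.angle_dha is not None else ""
        return (f"{self.donor_label}{h}...{self.acceptor_label} "
                f"[{self.d_da:.3f} A{ang}]")


@dataclass(frozen=True)
class CloseContact:
    label_a: str
    label_b: str
    mol_a: int
    provenance_b: Provenance
    distance: float
    vdw_sum: float

    @property
    def gap(self) -> float:
        """distance - vdW sum; negative means a sub-vdW close contact."""
        return self.distance - self.vdw_sum

    def __str__(self):
        return (f"{self.label_a}...{self.label_b} {self.distance:.3f} A "
                f"(vdW sum {self.vdw_sum:.2f}, gap {self.gap:+.3f})")


@dataclass(frozen=True)
class MeanPlane:
    """Least-squares plane through a point set (minimal perpendicular rms)."""

    normal: tuple[float, float, float]
    centroid: tuple[float, float, float]
    rms: float

    @property
    def normal_array(self) -> np.ndarray:
        return np.array(self.normal)


# ------------------------------------------------------------------ image window

def translation_window(structure: CrystalStructure, radius: float) -> tuple[int, int, int]:
    """Integer lattice window guaranteeing coverage of all images within ``radius``.

    Uses the perpendicular interplanar spacings of the cell, enlarged by the
    largest molecular radius so that long molecules reaching in from distant cells
    are not missed.
    """
    M = structure.ortho
    a1, a2, a3 = M[:, 0], M[:, 1], M[:, 2]
    vol = abs(np.dot(a1, np.cross(a2, a3)))
    widths = [vol / np.linalg.norm(np.cross(a2, a3)),
              vol / np.linalg.norm(np.cross(a3, a1)),
              vol / np.linalg.norm(np.cross(a1, a2))]
    mol_radius = 0.0
    for m in structure.molecules_asym:
        mol_radius = max(mol_radius, np.linalg.norm(m.coords - m.centroid, axis=1).max())
    reach = radius + 2.0 * mol_radius
    return tuple(int(math.ceil(reach / w)) for w in widths)


def _iter_neighbour_images(structure: CrystalStructure, radius: float):
    """Images of all molecules with any chance of lying within ``radius`` of the
    asymmetric unit.  The shift grid is re-centred per (molecule, operator) so
    that images whose base copy sits cells away are not missed."""
    import itertools
    wx, wy, wz = translation_window(structure, radius)
    targets = [m.fract.mean(axis=0) for m in structure.molecules_asym]
    grid = list(itertools.product(range(-wx, wx + 1), range(-wy, wy + 1),
                                  range(-wz, wz + 1)))
    for mi, mol in enumerate(structure.molecules_asym):
        cf = mol.fract.mean(axis=0)
        for oi, op in enumerate(structure.operators):
            base = op.rot_array @ cf + op.tran_array
            centres = {tuple(int(x) for x in np.round(t - base)) for t in targets}
            shifts = {tuple(c + g for c, g in zip(n0, off))
                      for n0 in centres for off in grid}
            for shift in sorted(shifts):
                yield structure.image_molecule(mi, oi, shift)


# ------------------------------------------------------------------ hydrogen bonds

def find_hydrogen_bonds(structure: CrystalStructure,
                        criteria: HBondCriteria = HBondCriteria()):
    """All intermolecular D-H...A interactions, deduplicated by symmetry.

    Returns ``(hbonds, da_only)``: full D-H...A hits with the angle criterion
    applied, and a separate D...A-only candidate list for donors whose hydrogen is
    not modelled (e.g. unrefined water H atoms).
    """
    hbonds, da_only = [], []
    seen = set()
    images = list(_iter_neighbour_images(structure, criteria.max_da))
    for mol in structure.molecules_asym:
        donors = _donor_atoms(mol, criteria)
        if not donors:
            continue
        for img in images:
            # skip self (identity image of the same molecule) == intramolecular
            if img.provenance.is_identity and img.provenance.mol_index == mol.provenance.mol_index:
                continue
            acc_idx = [k for k, e in enumerate(img.elements)
                       if e in criteria.acceptor_elements]
            if not acc_idx:
                continue
            for d_idx, h_idx in donors:
                d_pos = mol.coords[d_idx]
                for k in acc_idx:
                    a_pos = img.coords[k]
                    d_da = float(np.linalg.norm(a_pos - d_pos))
                    if d_da > criteria.max_da or d_da < 0.5:
                        continue
                    if h_idx is None:
                        rec = HydrogenBond(mol.labels[d_idx], None, img.labels[k],
                                           mol.provenance.mol_index, img.provenance,
                                           d_da, None)
                        key = ("da", rec.donor_label, rec.acceptor_label, round(d_da, 4))
                        if key not in seen:
                            seen.add(key)
                            da_only.append(rec)
                        continue
                    h_pos = mol.coords[h_idx]
                    angle = _angle_at(h_pos, d_pos, a_pos)
                    if angle < criteria.min_angle:
                        continue
                    rec = HydrogenBond(mol.labels[d_idx], mol.labels[h_idx],
                                       img.labels[k], mol.provenance.mol_index,
                                       img.provenance, d_da, angle)
                    key = ("dha", rec.donor_label, rec.hydrogen_label,
                           rec.acceptor_label, round(d_da, 4), round(angle, 2))
                    if key not in seen:
                        seen.add(key)
                        hbonds.append(rec)
    hbonds.sort(key=lambda r: (r.d_da, r.donor_label, r.acceptor_label))
    da_only.sort(key=lambda r: (r.d_da, r.donor_label, r.acceptor_label))
    return hbonds, da_only


def _donor_atoms(mol: Molecule, criteria: HBondCriteria):
    """(donor_index, hydrogen_index | None) pairs for a molecule."""
    out = []
    for i, e in enumerate(mol.elements):
        if e not in criteria.donor_elements:
            continue
        hs = [j for a, b in mol.bonds for j in ((b,) if a == i else (a,) if b == i else ())
              if mol.elements[j] == "H"]
        if hs:
            out.extend((i, h) for h in hs)
        else:
            out.append((i, None))
    return out


def _angle_at(apex, p1, p2) -> float:
    v1 = np.asarray(p1) - np.asarray(apex)
    v2 = np.asarray(p2) - np.asarray(apex)
    c = np.clip(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1.0, 1.0)
    return math.degrees(math.acos(c))


# ------------------------------------------------------------------ close contacts

def find_close_contacts(structure_or_cluster, margin: float = 0.0):
    """Intermolecular atom pairs closer than the vdW-radius sum plus ``margin``.

    Accepts either a :class:`CrystalStructure` (search over all symmetry and
    translation images) or a :class:`~packmotif.clusters.Cluster` (pairs within the
    cluster).  Each contact is reported once, in canonical label order.
    """
    from .clusters import Cluster  # local import to avoid a cycle

    if isinstance(structure_or_cluster, Cluster):
        return _cluster_contacts(structure_or_cluster, margin)
    structure = structure_or_cluster
    max_vdw = max(vdw_radius(e) for m in structure.molecules_asym for e in m.elements)
    reach = 2 * max_vdw + max(margin, 0.0)
    contacts, seen = [], set()
    for mol in structure.molecules_asym:
        for img in _iter_neighbour_images(structure, reach):
            if img.provenance.is_identity and img.provenance.mol_index == mol.provenance.mol_index:
                continue
            contacts_ij = _pair_contacts(mol, img, margin)
            for rec in contacts_ij:
                key = (tuple(sorted((rec.label_a, rec.label_b))), round(rec.distance, 4))
                if key not in seen:
                    seen.add(key)
                    contacts.append(rec)
    contacts.sort(key=lambda r: (r.distance, r.label_a, r.label_b))
    return contacts


def _pair_contacts(mol_a: Molecule, mol_b: Molecule, margin: float):
    ra = np.array([vdw_radius(e) for e in mol_a.elements])
    rb = np.array([vdw_radius(e) for e in mol_b.elements])
    d = np.linalg.norm(mol_a.coords[:, None, :] - mol_b.coords[None, :, :], axis=-1)
    lim = ra[:, None] + rb[None, :] + margin
    out = []
    for i, j in zip(*np.nonzero(d < lim)):
        if d[i, j] < 1e-6:
            continue
        la, lb = mol_a.labels[i], mol_b.labels[j]
        if la > lb:
            la, lb = lb, la
        out.append(CloseContact(la, lb, mol_a.provenance.mol_index,
                                mol_b.provenance, float(d[i, j]),
                                float(ra[i] + rb[j])))
    return out


def _cluster_contacts(cluster, margin: float):
    mols = [cluster.kernel] + list(cluster.shell)
    contacts, seen = [], set()
    for x in range(len(mols)):
        for y in range(x + 1, len(mols)):
            for rec in _pair_contacts(mols[x], mols[y], margin):
                key = (tuple(sorted((rec.label_a, rec.label_b))), round(rec.distance, 4))
                if key not in seen:
                    seen.add(key)
                    contacts.append(rec)
    contacts.sort(key=lambda r: (r.distance, r.label_a, r.label_b))
    return contacts


# ------------------------------------------------------------------ planes

def mean_plane(points) -> MeanPlane:
    """Least-squares plane minimizing the sum of squared perpendicular distances.

    The normal is the singular vector of the centred point matrix belonging to its
    smallest singular value; its sign is fixed so the first non-zero component is
    positive.  Raises :class:`GeometryError` for fewer than three points or a
    collinear set.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 3:
        raise GeometryError("mean_plane needs >= 3 points in 3D")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[1] < 1e-8 * max(1.0, s[0]):
        raise GeometryError("mean_plane: points are collinear or coincident")
    normal = vt[2]
    for comp in normal:
        if abs(comp) > 1e-12:
            if comp < 0:
                normal = -normal
            break
    rms = float(s[2] / math.sqrt(pts.shape[0]))
    return MeanPlane(tuple(normal), tuple(centroid), rms)


def interplanar_angle(p1: MeanPlane, p2: MeanPlane) -> float:
    """Acute angle between two planes, in [0, 90] degrees."""
    c = abs(float(p1.normal_array @ p2.normal_array))
    return math.degrees(math.acos(np.clip(c, -1.0, 1.0)))
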