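"""Coordination-sphere clusters: the comparison unit of the similarity engine.

A cluster is a kernel molecule plus every symmetry/translation image of every
symmetry-distinct molecule that makes an atom-atom contact with the kernel within
the van der Waals sum plus a margin.  The vdW criterion (rather than a fixed
centroid radius) keeps elongated molecules from being missed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .crystal_model import CrystalStructure, Molecule, Provenance
from .geometry import translation_window
from .tables import vdw_radius

__all__ = ["Cluster", "build_cluster", "cluster_fingerprint"]

DEFAULT_MARGIN = 1.5  # Angstrom beyond the vdW sum for shell membership


@dataclass
class Cluster:
    """Kernel molecule and its coordination shell, with full provenance."""

    structure: CrystalStructure
    kernel: Molecule
    shell: list[Molecule]
    margin: float

    def __len__(self) -> int:
        return len(self.shell)

    @property
    def shell_provenances(self):
        return [m.provenance for m in self.shell]


def _in_contact(mol_a: Molecule, mol_b: Molecule, margin: float,
                ra: np.ndarray, rb: np.ndarray) -> bool:
    # cheap bounding-sphere reject first
    ca, cb = mol_a.centroid, mol_b.centroid
    rad_a = np.linalg.norm(mol_a.coords - ca, axis=1).max()
    rad_b = np.linalg.norm(mol_b.coords - cb, axis=1).max()
    max_vdw = ra.max() + rb.max() + margin
    if np.linalg.norm(ca - cb) > rad_a + rad_b + max_vdw:
        return False
    d = np.linalg.norm(mol_a.coords[:, None, :] - mol_b.coords[None, :, :], axis=-1)
    return bool((d <= ra[:, None] + rb[None, :] + margin).any())


def build_cluster(structure: CrystalStructure, kernel: Molecule | None = None,
                  margin: float = DEFAULT_MARGIN,
                  include_waters: bool = True) -> Cluster:
    """Build the coordination-sphere cluster around ``kernel``.

    ``kernel`` defaults to the largest non-water molecule of the asymmetric unit
    and must be one of the structure's assembled molecules (identity provenance).
    The translation search window is derived from the cell geometry and expanded
    until no further shell member appears.
    """
    if kernel is None:
        kernel = structure.host()
    if not any(kernel is m for m in structure.molecules_asym):
        matches = [m for m in structure.molecules_asym
                   if m.labels == kernel.labels and np.allclose(m.coords, kernel.coords)]
        if not matches:
            raise ValueError("kernel is not a molecule of this structure")
        kernel = matches[0]

    max_vdw = max(vdw_radius(e) for m in structure.molecules_asym for e in m.elements)
    ra = np.array([vdw_radius(e) for e in kernel.elements])
    rad_k = float(np.linalg.norm(kernel.coords - kernel.centroid, axis=1).max())

    kernel_cf = kernel.fract.mean(axis=0)

    def sweep(window) -> dict[tuple, Molecule]:
        found: dict[tuple, Molecule] = {}
        grid = np.array(list(itertools.product(*(range(-w, w + 1) for w in window))))
        for mi, mol in enumerate(structure.molecules_asym):
            if not include_waters and mol.is_water and mi != kernel.provenance.mol_index:
                continue
            rad_m = float(np.linalg.norm(mol.coords - mol.centroid, axis=1).max())
            cutoff = rad_k + rad_m + 2 * max_vdw + margin
            rb = np.array([vdw_radius(e) for e in mol.elements])
            cf = mol.fract.mean(axis=0)
            for oi, op in enumerate(structure.operators):
                base_f = op.rot_array @ cf + op.tran_array
                n0 = np.round(kernel_cf - base_f)  # recentre grid on the kernel
                cgrid = grid + n0.astype(int)
                base = structure.ortho @ base_f
                lattice = cgrid @ structure.ortho.T
                dist = np.linalg.norm(base + lattice - kernel.centroid, axis=1)
                for gi in np.nonzero(dist <= cutoff)[0]:
                    shift = tuple(int(x) for x in cgrid[gi])
                    prov = Provenance(mi, oi, shift)
                    if prov.is_identity and mi == kernel.provenance.mol_index:
                        continue
                    img = structure.image_molecule(mi, oi, shift)
                    if _in_contact(kernel, img, margin, ra, rb):
                        found[prov.key()] = img
        return found

    window = [max(2, w) for w in translation_window(structure, 2 * max_vdw + margin)]
    found = sweep(window)
    while True:
        window = [w + 1 for w in window]
        bigger = sweep(window)
        if set(bigger) == set(found):
            break
        found = bigger
    shell = list(found.values())
    shell.sort(key=lambda m: (round(float(np.linalg.norm(m.centroid - kernel.centroid)), 6),
                              m.provenance.op_index, m.provenance.shift,
                              m.provenance.mol_index))
    return Cluster(structure=structure, kernel=kernel, shell=shell, margin=margin)


def _provenance_class(structure: CrystalStructure, prov: Provenance) -> str:
    op = structure.operators[prov.op_index]
    if op.determinant < 0:
        return "improper"
    if op.is_pure_translation:
        return "translation"
    return "proper"


def cluster_fingerprint(cluster: Cluster):
    """Sorted (centroid distance, provenance class) list -- a cheap pre-filter.

    Two clusters whose fingerprints disagree beyond the distance tolerance on any
    prefix cannot produce a full match.
    """
    out = []
    ck = cluster.kernel.centroid
    for m in cluster.shell:
        d = float(np.linalg.norm(m.centroid - ck))
        out.append((d, _provenance_class(cluster.structure, m.provenance)))
    return sorted(out)
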