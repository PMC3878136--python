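"""Hydrogen bonds, close contacts and mean planes, checked against
brute-force all-images oracles and exact constructions."""

import itertools
import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from packmotif import (AtomSite, CellContents, CrystalStructure, HBondCriteria,
                       SymmetryOperator, UnitCell, find_close_contacts,
                       find_hydrogen_bonds, interplanar_angle, mean_plane)
from packmotif.errors import GeometryError
from packmotif.synthetic import MotifSpec, build_crystal
from packmotif.tables import vdw_radius

P1 = [SymmetryOperator.identity()]


def _structure_from_molecules(cell, molecules):
    """molecules: list of (label, element, cart) lists; converts to a P1 cell."""
    from packmotif.crystal_model import orthogonalization_matrix

    minv = np.linalg.inv(orthogonalization_matrix(cell))
    sites = []
    for atoms in molecules:
        for lab, el, xyz in atoms:
            sites.append(AtomSite(lab, el, tuple((minv @ xyz) % 1.0)))
    return CrystalStructure(CellContents("toy", cell, list(P1), sites))


def _linear_ohо(cell_edge=30.0, d_oo=2.80, angle=180.0):
    """Two waters with an O-H...O contact of given O...O distance and angle."""
    cell = UnitCell(cell_edge, cell_edge, cell_edge, 90, 90, 90)
    # donor O at origin, H along +x; acceptor placed so the O-H...O angle at H
    # is `angle`
    oh = 0.96
    h = np.array([oh, 0, 0])
    theta = math.radians(180.0 - angle)
    acc = h + (d_oo - oh if angle == 180.0 else None) * np.array([1, 0, 0]) \
        if angle == 180.0 else None
    if acc is None:
        r = math.sqrt(d_oo ** 2 - 2 * oh * d_oo * math.cos(math.radians(angle))
                      + oh ** 2)
        # place acceptor at distance d_oo from donor forming given angle at H
        acc = h + r * np.array([math.cos(theta), math.sin(theta), 0])
    mols = [
        [("O1", "O", np.zeros(3)), ("H1", "H", h)],
        [("O2", "O", acc), ("H3", "H", acc + np.array([0, 0.96, 0])),
         ("H4", "H", acc + np.array([0.93, -0.24, 0]))],
    ]
    return _structure_from_molecules(cell, mols)


class TestHydrogenBonds:
    def test_linear_contact_found(self):
        st = _linear_ohо(d_oo=2.80, angle=180.0)
        hbonds, _ = find_hydrogen_bonds(st)
        assert any(b.donor_label == "O1" and b.acceptor_label == "O2"
                   and b.d_da == pytest.approx(2.80, abs=1e-6)
                   and b.angle_dha == pytest.approx(180.0, abs=1e-6)
                   for b in hbonds)

    def test_angle_filter_rejects_bent(self):
        st = _linear_ohо(d_oo=2.80, angle=90.0)
        hbonds, _ = find_hydrogen_bonds(st)
        assert not any(b.donor_label == "O1" and b.acceptor_label == "O2"
                       for b in hbonds)

    def test_distance_filter(self):
        st = _linear_ohо(d_oo=3.8, angle=180.0)
        hbonds, _ = find_hydrogen_bonds(st)
        assert not any(b.donor_label == "O1" and b.acceptor_label == "O2"
                       for b in hbonds)

    def test_dimer_bond_geometry(self, dimer_structure):
        hbonds, _ = find_hydrogen_bonds(dimer_structure)
        nho = [b for b in hbonds if b.donor_label == "N1"
               and b.acceptor_label == "O1"]
        assert len(nho) == 1
        assert nho[0].d_da == pytest.approx(2.87, abs=1e-6)
        assert nho[0].angle_dha == pytest.approx(180.0, abs=1e-4)

    def test_hydrate_water_donates_to_carbonyl(self, hydrate_structure):
        st, truth = hydrate_structure
        hbonds, _ = find_hydrogen_bonds(st)
        expected = {(h["donor"], h["acceptor"]): h["d_da"]
                    for h in truth["hbonds"]}
        found = {(b.donor_label, b.acceptor_label): b.d_da for b in hbonds}
        for key, d in expected.items():
            assert key in found
            assert found[key] == pytest.approx(d, abs=0.01)

    def test_missing_water_h_reported_separately(self):
        # bare O near a carbonyl-less acceptor: only the D...A list sees it
        cell = UnitCell(20, 20, 20, 90, 90, 90)
        st = _structure_from_molecules(cell, [
            [("O1", "O", np.zeros(3))],
            [("O2", "O", np.array([2.9, 0, 0])),
             ("H2", "H", np.array([3.4, 0.8, 0]))],
        ])
        hbonds, da_only = find_hydrogen_bonds(st)
        assert any(b.donor_label == "O1" and b.hydrogen_label is None
                   for b in da_only)

    def test_brute_force_image_oracle(self, dimer_structure):
        """Detection equals exhaustive enumeration over operator x translation
        images in a wide window."""
        st = dimer_structure
        crit = HBondCriteria()
        hbonds, _ = find_hydrogen_bonds(st, crit)
        got = {(b.donor_label, b.hydrogen_label, b.acceptor_label,
                round(b.d_da, 4), round(b.angle_dha, 2)) for b in hbonds}
        oracle = set()
        mol = st.molecules_asym[0]
        donors = [(i, j) for i, e in enumerate(mol.elements) if e in "NO"
                  for a, b in mol.bonds
                  for j in ([b] if a == i else [a] if b == i else [])
                  if mol.elements[j] == "H"]
        for oi in range(len(st.operators)):
            for shift in itertools.product(range(-4, 5), repeat=3):
                img = st.image_molecule(0, oi, shift)
                if img.provenance.is_identity:
                    continue
                for di, hi in donors:
                    for k, e in enumerate(img.elements):
                        if e not in "NO":
                            continue
                        d_da = float(np.linalg.norm(img.coords[k] - mol.coords[di]))
                        if not 0.5 < d_da <= crit.max_da:
                            continue
                        v1 = mol.coords[di] - mol.coords[hi]
                        v2 = img.coords[k] - mol.coords[hi]
                        ang = math.degrees(math.acos(
                            np.clip(v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2),
                                    -1, 1)))
                        if ang >= crit.min_angle:
                            oracle.add((mol.labels[di], mol.labels[hi],
                                        img.labels[k], round(d_da, 4),
                                        round(ang, 2)))
        assert got == oracle


class TestCloseContacts:
    def test_separated_molecules_no_contacts(self):
        cell = UnitCell(30, 30, 30, 90, 90, 90)
        st = _structure_from_molecules(cell, [
            [("C1", "C", np.zeros(3))],
            [("C2", "C", np.array([3.9, 0, 0]))],  # vdW sum 3.4 + 0.5
        ])
        assert find_close_contacts(st, margin=0.0) == []

    def test_gap_arithmetic(self):
        cell = UnitCell(30, 30, 30, 90, 90, 90)
        st = _structure_from_molecules(cell, [
            [("C1", "C", np.zeros(3))],
            [("H2", "H", np.array([2.80, 0, 0]))],
        ])
        (contact,) = find_close_contacts(st, margin=0.0)
        assert contact.vdw_sum == pytest.approx(2.90)
        assert contact.gap == pytest.approx(-0.10)

    def test_brute_force_oracle(self, dimer_structure):
        st = dimer_structure
        margin = 0.0
        got = {(tuple(sorted((c.label_a, c.label_b))), round(c.distance, 4))
               for c in find_close_contacts(st, margin=margin)}
        oracle = set()
        mol = st.molecules_asym[0]
        for oi in range(len(st.operators)):
            for shift in itertools.product(range(-4, 5), repeat=3):
                img = st.image_molecule(0, oi, shift)
                if img.provenance.is_identity:
                    continue
                d = np.linalg.norm(mol.coords[:, None] - img.coords[None], axis=-1)
                for i, j in zip(*np.nonzero(
                        d < np.array([[vdw_radius(a) + vdw_radius(b)
                                       for b in img.elements]
                                      for a in mol.elements]) + margin)):
                    if d[i, j] > 1e-6:
                        oracle.add((tuple(sorted((mol.labels[i], img.labels[j]))),
                                    round(float(d[i, j]), 4)))
        assert got == oracle


class TestMeanPlane:
    def test_coplanar_points_zero_rms(self):
        pts = [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]]
        assert mean_plane(pts).rms == pytest.approx(0.0, abs=1e-12)

    def test_xy_plane_normal(self):
        pts = [[0, 0, 0], [1, 0, 0], [0, 1, 0], [2, 3, 0]]
        assert mean_plane(pts).normal == pytest.approx((0, 0, 1))

    def test_collinear_rejected(self):
        with pytest.raises(GeometryError):
            mean_plane([[0, 0, 0], [1, 1, 1], [2, 2, 2], [3, 3, 3]])

    def test_rms_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            pts = rng.normal(size=(10, 3)) * [4, 3, 0.3]
            got = mean_plane(pts).rms
            centred = pts - pts.mean(axis=0)
            evals = np.linalg.eigvalsh(centred.T @ centred)
            assert got == pytest.approx(math.sqrt(max(evals[0], 0.0) / len(pts)),
                                        abs=1e-9)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(8, 3)) * [5, 2, 0.2]
        p1 = mean_plane(pts)
        rot = Rotation.random(random_state=3).as_matrix()
        moved = pts @ rot.T + np.array([3.0, -2.0, 7.0])
        p2 = mean_plane(moved)
        assert p2.rms == pytest.approx(p1.rms, abs=1e-9)


class TestInterplanarAngle:
    def test_identical_planes(self):
        p = mean_plane([[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        assert interplanar_angle(p, p) == pytest.approx(0.0)

    def test_perpendicular(self):
        p1 = mean_plane([[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        p2 = mean_plane([[0, 0, 0], [1, 0, 0], [0, 0, 1]])
        assert interplanar_angle(p1, p2) == pytest.approx(90.0)

    def test_symmetric_and_sign_invariant(self):
        rng = np.random.default_rng(1)
        a = mean_plane(rng.normal(size=(6, 3)) * [3, 3, 0.1])
        b = mean_plane(rng.normal(size=(6, 3)) * [3, 0.1, 3])
        assert interplanar_angle(a, b) == pytest.approx(interplanar_angle(b, a))
        flipped = type(a)(tuple(-x for x in a.normal), a.centroid, a.rms)
        assert interplanar_angle(flipped, b) == pytest.approx(
            interplanar_angle(a, b))

    def test_host_template_tilt(self):
        """The toy host is built with a 42 deg core/aryl interplanar angle."""
        from packmotif.synthetic import make_toy_molecule

        mol = make_toy_molecule("host", "Br")
        core = mol.subset_coords(["N1", "C2", "C3", "C3A", "C4", "C5", "C6",
                                  "C7", "C7A"])
        aryl = mol.subset_coords(["C10", "C11", "C12", "C13", "C14", "C15"])
        angle = interplanar_angle(mean_plane(core), mean_plane(aryl))
        assert angle == pytest.approx(42.0, abs=0.1)

    def test_rigid_motion_of_whole_model(self, dimer_structure):
        """All geometry outputs are invariant under a global rigid motion."""
        mol = dimer_structure.molecules_asym[0]
        core = mol.subset_coords(["N1", "C2", "C3", "C3A", "C4", "C5", "C6",
                                  "C7", "C7A"])
        aryl = mol.subset_coords(["C10", "C11", "C12", "C13", "C14", "C15"])
        before = interplanar_angle(mean_plane(core), mean_plane(aryl))
        rot = Rotation.random(random_state=11).as_matrix()
        t = np.array([1.0, -4.0, 2.5])
        after = interplanar_angle(mean_plane(core @ rot.T + t),
                                  mean_plane(aryl @ rot.T + t))
        assert after == pytest.approx(before, abs=1e-6)
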