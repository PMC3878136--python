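"""Orthogonalization, bond perception, molecule assembly, disorder, E/Z."""

import numpy as np
import pytest
from hypothesis import given, seed, settings
from hypothesis import strategies as st

from packmotif import (AtomSite, CellContents, CrystalStructure,
                       SymmetryOperator, UnitCell, cell_volume,
                       classify_cc_geometry, frac_to_cart,
                       orthogonalization_matrix, perceive_bonds,
                       select_major_conformer)
from packmotif.crystal_model import assemble_molecules
from packmotif.synthetic import MotifSpec, build_crystal, make_toy_molecule
from packmotif.tables import covalent_radius

P1 = [SymmetryOperator.identity()]
PM1 = [SymmetryOperator.identity(), SymmetryOperator.from_xyz("-x,-y,-z")]


class TestOrthogonalization:
    def test_orthogonal_cell(self):
        assert frac_to_cart(UnitCell(10, 20, 30, 90, 90, 90),
                            (0.5, 0.5, 0.5)) == pytest.approx([5, 10, 15])

    def test_cell_edge_lengths_and_gamma(self, table1):
        cell = table1["3c"]["cell"]
        ea = frac_to_cart(cell, (1, 0, 0))
        eb = frac_to_cart(cell, (0, 1, 0))
        assert np.linalg.norm(ea) == pytest.approx(cell.a)
        assert np.linalg.norm(eb) == pytest.approx(cell.b)
        cosg = ea @ eb / (cell.a * cell.b)
        assert np.degrees(np.arccos(cosg)) == pytest.approx(cell.gamma)

    def test_determinant_equals_volume(self, table1):
        cell = table1["3c"]["cell"]
        m = orthogonalization_matrix(cell)
        assert np.linalg.det(m) == pytest.approx(cell_volume(cell), abs=0.1)
        assert np.allclose(m.T @ m, cell.metric_tensor)


class TestBondPerception:
    def test_typical_cc_bond(self):
        assert perceive_bonds(["C", "C"], [[0, 0, 0], [1.5, 0, 0]]) == [(0, 1)]

    def test_long_cc_not_bonded(self):
        assert perceive_bonds(["C", "C"], [[0, 0, 0], [3.0, 0, 0]]) == []

    def test_no_hh_bond(self):
        assert perceive_bonds(["H", "H"], [[0, 0, 0], [0.7, 0, 0]]) == []

    def test_h_keeps_only_nearest_heavy(self):
        bonds = perceive_bonds(["O", "H", "N"],
                               [[0, 0, 0], [1.0, 0, 0], [2.1, 0, 0]])
        assert bonds == [(0, 1)]

    @seed(20260920)
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_matches_brute_force_oracle(self, rng_seed):
        """Random clouds: perception equals the all-pairs distance criterion
        (hydrogen rules applied on top)."""
        rng = np.random.default_rng(rng_seed)
        n = 20
        elements = list(rng.choice(["C", "N", "O", "H"], size=n))
        coords = rng.uniform(0, 8, size=(n, 3))
        got = set(perceive_bonds(elements, coords))
        naive = set()
        for i in range(n):
            for j in range(i + 1, n):
                d = np.linalg.norm(coords[i] - coords[j])
                if d <= covalent_radius(elements[i]) + covalent_radius(elements[j]) + 0.40:
                    naive.add((i, j))
        # every perceived bond satisfies the distance criterion
        assert got <= naive
        # only hydrogen rules may remove pairs
        for i, j in naive - got:
            assert "H" in (elements[i], elements[j])


class TestAssembly:
    def test_p1_hydrate_two_molecules(self, hydrate_structure):
        st_, truth = hydrate_structure
        assert len(st_.molecules_asym) == 2
        assert sum(m.is_water for m in st_.molecules_asym) == 1

    def test_molecule_unwrapped_across_boundary(self):
        sites = [AtomSite("O1", "O", (0.98, 0.25, 0.25)),
                 AtomSite("H1", "H", (0.04, 0.27, 0.25)),
                 AtomSite("H2", "H", (0.93, 0.30, 0.30))]
        cc = CellContents("t", UnitCell(12, 13, 14, 90, 95, 90), P1, sites)
        mols, flagged = assemble_molecules(cc)
        assert not flagged
        (mol,) = mols
        assert len(mol) == 3
        assert max(np.linalg.norm(mol.coords[i] - mol.coords[0])
                   for i in range(3)) < 1.7  # contiguous, not wrapped apart

    def test_centroid_is_unweighted_mean(self, dimer_structure):
        mol = dimer_structure.molecules_asym[0]
        assert np.allclose(mol.centroid, mol.coords.mean(axis=0))

    def test_image_count_matches_operator_count(self, dimer_structure):
        """General-position expansion: ops x sites positions, none closer
        than 0.3 A."""
        labels, elements, fr = dimer_structure.expanded_positions()
        n_sites = len(dimer_structure.contents.sites)
        assert len(labels) == 2 * n_sites
        cart = fr @ dimer_structure.ortho.T
        d = np.linalg.norm(cart[:, None] - cart[None, :], axis=-1)
        np.fill_diagonal(d, 9.9)
        assert d.min() > 0.3

    def test_c2c_special_position_deduplicated(self):
        contents, truth = build_crystal(
            MotifSpec("hydrate_channel", spacegroup="C2/c", seed=2))
        st_ = CrystalStructure(contents)
        labels, elements, fr = st_.expanded_positions()
        # water on the twofold axis: multiplicity 4, not 8
        assert len(labels) == truth["molecules_per_cell"] * 3

    def test_site_order_invariance(self):
        contents, _ = build_crystal(MotifSpec("inversion_dimer", seed=5))
        mols_fwd, _ = assemble_molecules(contents)
        reversed_contents = contents.with_sites(list(reversed(contents.sites)))
        mols_rev, _ = assemble_molecules(reversed_contents)
        assert len(mols_fwd) == len(mols_rev)
        assert sorted(mols_fwd[0].labels) == sorted(mols_rev[0].labels)
        # same geometry up to lattice translation of the whole molecule
        a = mols_fwd[0].coords[np.argsort(mols_fwd[0].labels)]
        b = mols_rev[0].coords[np.argsort(mols_rev[0].labels)]
        shift = (a - b).mean(axis=0)
        assert np.allclose(a - b, shift, atol=1e-8)


class TestDisorder:
    CELL = UnitCell(10, 10, 10, 90, 90, 90)

    def test_fully_occupied_unchanged(self):
        sites = [AtomSite("C1", "C", (0.1, 0.1, 0.1))]
        assert select_major_conformer(sites, self.CELL) == sites

    def test_major_site_kept(self):
        sites = [AtomSite("C5A", "C", (0.10, 0.10, 0.10), 0.7),
                 AtomSite("C5B", "C", (0.12, 0.10, 0.10), 0.3)]
        kept = select_major_conformer(sites, self.CELL)
        assert [s.label for s in kept] == ["C5A"]

    def test_two_conformer_ring_resolves_to_connected_molecule(self):
        """A synthetic ring with an alternate conformer: keeping the major
        sites must yield one connected molecule."""
        contents, _ = build_crystal(MotifSpec("inversion_dimer", seed=7))
        # add a displaced minor-conformer copy of the pendant-ring atoms
        minor = []
        for s in contents.sites:
            if s.label in ("C11", "C12", "C14", "C15"):
                minor.append(AtomSite(s.label + "B", s.element,
                                      tuple((f + 0.015) % 1 for f in s.fract),
                                      0.35))
        majored = [AtomSite(s.label, s.element, s.fract,
                            0.65 if s.label in ("C11", "C12", "C14", "C15")
                            else 1.0)
                   for s in contents.sites] + minor
        cc = contents.with_sites(majored)
        mols, flagged = assemble_molecules(cc, major_conformer=True)
        assert not flagged
        assert len(mols) == 1
        assert not any(l.endswith("B") for l in mols[0].labels)


class TestEZClassification:
    def test_e_template(self):
        mol = make_toy_molecule("host", "Br", conformer="E")
        assert classify_cc_geometry(mol, ("C3", "C9"), ("C2", "C10")) == "E"

    def test_z_template(self):
        mol = make_toy_molecule("host", "Br", conformer="Z")
        assert classify_cc_geometry(mol, ("C3", "C9"), ("C2", "C10")) == "Z"

    def test_missing_reference(self):
        mol = make_toy_molecule("host", "Br")
        from packmotif.errors import GeometryError
        with pytest.raises(GeometryError):
            classify_cc_geometry(mol, ("C3", "C9"), ("C2", "C99"))
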