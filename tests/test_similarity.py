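"""Descriptors, cluster matching, dimensionality and family-level SC extraction."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from packmotif import (CrystalStructure, MatchTolerances, build_cluster,
                       compare_family, compare_pair, derive_dimensionality,
                       dissimilarity_index, make_correspondence,
                       match_clusters, pair_descriptor)
from packmotif.errors import CorrespondenceError
from packmotif.similarity import cluster_descriptors
from packmotif.synthetic import (MotifSpec, build_crystal, build_pair,
                                 make_dimer_family, make_family,
                                 make_letter_family)


def _structures(pair):
    return [CrystalStructure(c) for c, _ in pair]


class TestCorrespondence:
    def test_identical_structures_full_core(self, dimer_structure):
        corr = make_correspondence(dimer_structure, dimer_structure)
        host = dimer_structure.host()
        non_h = {l for l, e in zip(host.labels, host.elements) if e != "H"}
        assert set(corr.labels) == non_h

    def test_substituent_labels_excluded(self):
        pair = build_pair("isostructural_pair", seed=9)
        a, b = _structures(pair)
        corr = make_correspondence(a, b)
        assert "BR1" not in corr.labels and "CL1" not in corr.labels
        assert len(corr) == 17

    def test_disjoint_labels_error(self, dimer_structure, hydrate_structure):
        water_only, _ = build_crystal(
            MotifSpec("hydrate_channel", spacegroup="C2/c", seed=3))
        with pytest.raises(CorrespondenceError):
            make_correspondence(dimer_structure, CrystalStructure(water_only))


class TestDescriptors:
    def test_pure_translation_descriptor(self, stack_structure):
        corr = make_correspondence(stack_structure, stack_structure)
        cluster = build_cluster(stack_structure)
        idx = next(i for i, m in enumerate(cluster.shell)
                   if m.provenance.op_index == 0
                   and m.provenance.shift == (1, 0, 0))
        d = pair_descriptor(cluster, idx, corr)
        assert d.proper
        assert d.d == pytest.approx(4.07, abs=1e-6)
        assert Rotation.from_quat(d.quat).magnitude() == pytest.approx(0, abs=1e-6)

    def test_inversion_partner_flagged_improper(self, dimer_structure):
        corr = make_correspondence(dimer_structure, dimer_structure)
        cluster = build_cluster(dimer_structure)
        descriptors = cluster_descriptors(cluster, corr)
        improper = [d for d in descriptors if d is not None and not d.proper]
        assert improper  # the dimer partner and its images

    def test_rigid_motion_invariance(self, dimer_structure):
        """Descriptors are identical after any global rotation+translation."""
        corr = make_correspondence(dimer_structure, dimer_structure)
        cluster = build_cluster(dimer_structure)
        base = [d for d in cluster_descriptors(cluster, corr) if d is not None]
        rng = np.random.default_rng(5)
        for _ in range(3):
            rot = Rotation.random(random_state=int(rng.integers(1 << 16)))
            t = rng.uniform(-20, 20, 3)
            moved_kernel = cluster.kernel.transformed(rot.as_matrix(), t)
            moved_shell = [m.transformed(rot.as_matrix(), t)
                           for m in cluster.shell]
            from packmotif.similarity import _descriptor
            moved = [_descriptor(moved_kernel, m, corr) for m in moved_shell]
            for d0, d1 in zip(base, [d for d in moved if d is not None]):
                assert d1.d == pytest.approx(d0.d, abs=1e-6)
                assert np.allclose(d1.u, d0.u, atol=1e-6)
                gap = (Rotation.from_quat(d0.quat).inv()
                       * Rotation.from_quat(d1.quat)).magnitude()
                assert gap == pytest.approx(0.0, abs=1e-6)
                assert d0.proper == d1.proper


class TestMatching:
    def test_self_match_complete(self, dimer_structure):
        """A cluster matched against itself matches every shell member."""
        corr = make_correspondence(dimer_structure, dimer_structure)
        cluster = build_cluster(dimer_structure)
        m = match_clusters(cluster, cluster, corr)
        n_matchable = sum(d is not None
                         for d in cluster_descriptors(cluster, corr))
        assert len(m.pairs) == n_matchable
        assert dissimilarity_index(m) == pytest.approx(0.0, abs=1e-7)

    def test_self_is_isostructural_with_cell_base_vectors(self):
        contents, _ = build_crystal(MotifSpec("isostructural_pair", seed=13))
        st = CrystalStructure(contents)
        corr = make_correspondence(st, st)
        c = build_cluster(st)
        m = match_clusters(c, c, corr)
        dim, base_a, base_b = derive_dimensionality(m)
        assert dim == 3
        # base vectors generate the cell lattice: each is an integer
        # combination of the cell vectors with determinant +-1
        frac = np.array([np.linalg.solve(st.ortho, v) for v in base_a])
        assert np.allclose(frac, np.round(frac), atol=1e-5)
        assert abs(round(np.linalg.det(np.round(frac)))) == 1

    def test_noisy_isostructural_full_match(self):
        pair = build_pair("isostructural_pair", seed=31, noise_sigma=0.05)
        a, b = _structures(pair)
        match, dim, base_a, _ = compare_pair(a, b)
        assert dim == 3
        assert len(match.pairs) >= 5

    def test_symmetry_of_comparison(self):
        pair = build_pair("sheared_tape", seed=17, noise_sigma=0.03)
        a, b = _structures(pair)
        m_ab, dim_ab, base_ab, _ = compare_pair(a, b)
        m_ba, dim_ba, base_ba, _ = compare_pair(b, a)
        assert dim_ab == dim_ba
        assert sorted(np.linalg.norm(v) for v in base_ab) == pytest.approx(
            sorted(np.linalg.norm(v) for v in base_ba), abs=1e-6)
        assert len(m_ab.pairs) == len(m_ba.pairs)

    def test_tolerance_monotonicity(self):
        """Enlarging tolerances never reduces the matched-pair count."""
        pair = build_pair("translation_stack", seed=19, noise_sigma=0.08)
        a, b = _structures(pair)
        corr = make_correspondence(a, b)
        ca, cb = build_cluster(a), build_cluster(b)
        counts = [len(match_clusters(ca, cb, corr,
                                     MatchTolerances(d=d, ang=ang)).pairs)
                  for d, ang in [(0.1, 3), (0.25, 6), (0.5, 12), (1.0, 24)]]
        assert counts == sorted(counts)

    def test_dissimilarity_monotone_in_noise(self):
        """Across seeded replicates, low-noise pairs score below high-noise
        pairs nearly always."""
        wins = 0
        n = 15
        for s in range(n):
            idx = {}
            for sigma in (0.02, 0.10):
                pair = build_pair("translation_stack", seed=100 + s,
                                  noise_sigma=sigma)
                a, b = _structures(pair)
                match, _, _, _ = compare_pair(a, b)
                idx[sigma] = dissimilarity_index(match)
            wins += idx[0.02] < idx[0.10]
        assert wins >= int(0.9 * n)

    def test_empty_match_index_undefined(self, dimer_structure):
        corr = make_correspondence(dimer_structure, dimer_structure)
        cluster = build_cluster(dimer_structure)
        m = match_clusters(cluster, cluster, corr,
                           MatchTolerances(d=1e-9, ang=1e-9))
        # even degenerate tolerances keep the self-match; force empty instead
        m.pairs = []
        with pytest.raises(ValueError):
            dissimilarity_index(m)

    def test_accepted_match_index_below_one(self):
        pair = build_pair("translation_stack", seed=41, noise_sigma=0.1)
        a, b = _structures(pair)
        match, _, _, _ = compare_pair(a, b)
        assert 0.0 < dissimilarity_index(match) <= 1.0


class TestDimensionality:
    @pytest.mark.parametrize("kind,expected_dim", [
        ("inversion_dimer", 0),
        ("translation_stack", 1),
        ("sheared_tape", 1),
        ("layer", 2),
        ("isostructural_pair", 3),
        ("catamer", 1),
    ])
    def test_designed_motifs_recovered(self, kind, expected_dim):
        pair = build_pair(kind, seed=23, noise_sigma=0.03)
        (ca, ta), (cb, tb) = pair
        a, b = CrystalStructure(ca), CrystalStructure(cb)
        match, dim, base_a, base_b = compare_pair(a, b)
        assert dim == expected_dim
        expected = ta["sibling_motif"]["base_mags"]
        got = sorted(round(float(np.linalg.norm(v)), 3) for v in base_a)
        assert got == pytest.approx(expected, abs=0.06)


class TestFamily:
    def test_table_pattern_reproduced(self):
        family, expected = make_family(seed=3)
        res = compare_family([CrystalStructure(c) for c in family])
        by_id = {sc.sc_id: sc for sc in res.constructs}
        assert set(by_id) == {"A01", "A11", "A12", "A13", "A31"}
        for sc_id, exp in expected.items():
            if sc_id == "dependencies":
                continue
            assert by_id[sc_id].dimensionality == exp["dim"]
            assert by_id[sc_id].members == exp["members"]
        for sc_id, deps in expected["dependencies"].items():
            assert by_id[sc_id].dependencies == deps

    def test_dimer_only_family(self):
        structures = [CrystalStructure(c) for c in make_dimer_family(4, seed=3)]
        res = compare_family(structures)
        assert len(res.constructs) == 1
        sc = res.constructs[0]
        assert sc.dimensionality == 0
        assert sc.n_structures == 4

    def test_two_isostructural_toys(self):
        pair = build_pair("isostructural_pair", seed=27, noise_sigma=0.03)
        res = compare_family(_structures(pair))
        dims = sorted(sc.dimensionality for sc in res.constructs)
        assert dims == [0, 1, 3]
        sc3 = next(sc for sc in res.constructs if sc.dimensionality == 3)
        sub_dims = {next(s for s in res.constructs if s.sc_id == x).dimensionality
                    for x in sc3.sub_constructs}
        assert sub_dims == {0, 1}

    def test_family_letters(self):
        res = compare_family([CrystalStructure(c)
                              for c in make_letter_family(seed=3)])
        ids = {sc.sc_id for sc in res.constructs}
        assert ids == {"A01", "A11", "A31", "B11"}
        b11 = next(sc for sc in res.constructs if sc.sc_id == "B11")
        assert b11.dependencies == []  # primary SC, unrelated to the dimer

    def test_single_structure_empty(self, dimer_structure):
        res = compare_family([dimer_structure])
        assert res.constructs == []

    def test_base_vector_labels_shared_across_scs(self):
        family, _ = make_family(seed=3)
        res = compare_family([CrystalStructure(c) for c in family])
        a11 = res.construct("A11")
        a31 = res.construct("A31")
        assert a11.base_vector_labels == ["t1"]
        assert a31.base_vector_labels[0] == "t1"
        assert len(set(a31.base_vector_labels)) == 3
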