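"""Elastic network model: Hessian, slow modes, correlations, deformation."""

import numpy as np
import pytest
import scipy.linalg as sla

from tfdyn.enm import (
    build_enm,
    cross_correlation,
    deform_along,
    dynamic_domains,
    label_agreement,
    slow_modes,
    ModeSet,
    CorrelationMap,
)
from tfdyn.errors import DisconnectedNetworkError
from tfdyn.structures import pairwise_rmsd

from conftest import make_structure, random_structure


def _all_modes(structure, cutoff=13.0):
    """Dense reference eigensolution (oracle path)."""
    model = build_enm(structure, cutoff=cutoff)
    vals, vecs = sla.eigh(model.hessian.toarray())
    return model, vals, vecs


class TestHessian:
    def test_two_nodes_single_spring_analytic(self):
        s = make_structure([[0, 0, 0], [5, 0, 0]])
        model = build_enm(s, cutoff=13.0)
        assert len(model.contacts) == 1
        vals, vecs = sla.eigh(model.hessian.toarray())
        assert np.allclose(vals[:5], 0.0, atol=1e-10)
        assert vals[5] == pytest.approx(2.0)       # 2*gamma for a pair
        mode = vecs[:, 5].reshape(2, 3)
        # counter-motion along the connecting x axis
        assert abs(mode[0, 0]) == pytest.approx(abs(mode[1, 0]), abs=1e-10)
        assert np.allclose(mode[:, 1:], 0.0, atol=1e-10)

    def test_out_of_range_pair_gives_zero_hessian(self):
        s = make_structure([[0, 0, 0], [20, 0, 0]])
        model = build_enm(s, cutoff=13.0)
        assert model.contacts.shape[0] == 0
        assert model.hessian.nnz == 0

    def test_symmetry_and_superblock_row_sums(self):
        s = random_structure(20, seed=0, scale=8.0)
        h = build_enm(s).hessian.toarray()
        assert np.allclose(h, h.T, atol=1e-10)
        blocks = h.reshape(20, 3, 20, 3)
        assert np.allclose(blocks.sum(axis=2), 0.0, atol=1e-10)

    def test_translation_invariance_zero_energy(self):
        s = random_structure(15, seed=1, scale=8.0)
        model = build_enm(s)
        for axis in range(3):
            t = np.zeros((15, 3))
            t[:, axis] = 1.0
            assert model.energy(t) < 1e-10

    def test_matches_finite_difference_of_network_energy(self):
        rng = np.random.default_rng(2)
        s = random_structure(20, seed=2, scale=8.0)
        model = build_enm(s)
        ref = s.coords.copy()
        pairs = model.contacts
        d0 = np.linalg.norm(ref[pairs[:, 0]] - ref[pairs[:, 1]], axis=1)

        def energy(x):
            xc = x.reshape(-1, 3)
            d = np.linalg.norm(xc[pairs[:, 0]] - xc[pairs[:, 1]], axis=1)
            return 0.5 * np.sum((d - d0) ** 2)

        x0 = ref.ravel()
        h = 1e-5
        idx = rng.choice(60, size=12, replace=False)
        dense = model.hessian.toarray()
        for i in idx:
            for j in idx:
                ei = np.zeros(60); ei[i] = h
                ej = np.zeros(60); ej[j] = h
                fd = (energy(x0 + ei + ej) - energy(x0 + ei)
                      - energy(x0 + ej) + energy(x0)) / h ** 2
                assert dense[i, j] == pytest.approx(fd, rel=1e-5, abs=1e-5)


class TestSlowModes:
    def test_exactly_six_zero_modes_removed(self, tf_like):
        _, s, _ = tf_like
        modes = slow_modes(build_enm(s), 10)
        assert modes.n_modes == 10
        assert np.all(modes.eigenvalues > 0)
        assert np.all(np.diff(modes.eigenvalues) >= -1e-15)

    def test_rigid_body_rayleigh_quotient_vanishes(self, tf_like):
        _, s, _ = tf_like
        model = build_enm(s)
        n = s.n_nodes
        com = s.coords - s.coords.mean(axis=0)
        for axis in np.eye(3):
            rot = np.cross(np.tile(axis, (n, 1)), com)
            rot /= np.linalg.norm(rot)
            assert model.energy(rot) < 1e-10

    def test_sparse_agrees_with_dense_oracle(self):
        import tfdyn.enm as enm_mod

        s = random_structure(50, seed=3, scale=12.0)
        model, dvals, dvecs = _all_modes(s)
        nz = dvals > 1e-8 * dvals.max()
        dense_vals = dvals[nz][:10]
        # force the sparse (shift-invert) path
        old = enm_mod._DENSE_LIMIT
        enm_mod._DENSE_LIMIT = 0
        try:
            modes = slow_modes(model, 10)
        finally:
            enm_mod._DENSE_LIMIT = old
        assert np.allclose(modes.eigenvalues, dense_vals, atol=1e-8)
        # subspace agreement via principal angles
        q1 = np.linalg.qr(modes.eigenvectors)[0]
        q2 = np.linalg.qr(dvecs[:, nz][:, :10])[0]
        sv = np.linalg.svd(q1.T @ q2, compute_uv=False)
        assert np.all(np.arccos(np.clip(sv, -1, 1)) < 1e-6)

    def test_orthonormal_eigenvectors(self, tf_like):
        _, s, _ = tf_like
        modes = slow_modes(build_enm(s), 10)
        gram = modes.eigenvectors.T @ modes.eigenvectors
        assert np.allclose(gram, np.eye(10), atol=1e-8)

    def test_disconnected_network_reports_components(self):
        coords = np.vstack([random_structure(10, seed=4, scale=5.0).coords,
                            random_structure(6, seed=5, scale=5.0).coords + 100.0])
        s = make_structure(coords)
        with pytest.raises(DisconnectedNetworkError) as err:
            slow_modes(build_enm(s), 5)
        assert sorted(err.value.component_sizes) == [6, 10]

    def test_hinge_toy_slowest_mode_anticorrelated(self, two_domain):
        _, s, dm = two_domain
        modes = slow_modes(build_enm(s), 10)
        cmap = cross_correlation(modes, 0)
        a = dm.resolve(s, "BD")
        b = dm.resolve(s, "HD")
        assert cmap.matrix[np.ix_(a, b)].mean() < -0.5


class TestCrossCorrelation:
    def test_diagonal_is_one(self, tf_like):
        _, s, _ = tf_like
        modes = slow_modes(build_enm(s), 10)
        for k in (0, "weighted"):
            cmap = cross_correlation(modes, k)
            assert np.allclose(np.diag(cmap.matrix), 1.0, atol=1e-10)
            assert np.allclose(cmap.matrix, cmap.matrix.T, atol=1e-10)
            assert cmap.matrix.min() >= -1.0 and cmap.matrix.max() <= 1.0

    def test_two_node_spring_perfectly_anticorrelated(self):
        s = make_structure([[0, 0, 0], [5, 0, 0]])
        vals, vecs = sla.eigh(build_enm(s).hessian.toarray())
        modes = ModeSet(vals[-1:], vecs[:, -1:], s)
        cmap = cross_correlation(modes, 0)
        assert cmap.matrix[0, 1] == pytest.approx(-1.0)

    def test_weighted_with_single_mode_reduces_to_per_mode(self, tf_like):
        _, s, _ = tf_like
        modes = slow_modes(build_enm(s), 10)
        single = ModeSet(modes.eigenvalues[:1], modes.eigenvectors[:, :1],
                         modes.structure)
        assert np.allclose(cross_correlation(single, "weighted").matrix,
                           cross_correlation(single, 0).matrix, atol=1e-12)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(6)
        s = random_structure(12, seed=6)
        vecs = np.linalg.qr(rng.standard_normal((36, 4)))[0]
        vals = np.sort(rng.uniform(0.1, 2.0, 4))
        modes = ModeSet(vals, vecs, s)
        for k in range(4):
            got = cross_correlation(modes, k).matrix
            disp = vecs[:, k].reshape(12, 3)
            for i in range(12):
                for j in range(12):
                    expect = disp[i] @ disp[j] / (
                        np.linalg.norm(disp[i]) * np.linalg.norm(disp[j]))
                    assert got[i, j] == pytest.approx(np.clip(expect, -1, 1),
                                                      abs=1e-12)
        got_w = cross_correlation(modes, "weighted").matrix
        w = 1.0 / vals
        expect_w = sum(w[k] * cross_correlation(modes, k).matrix
                       for k in range(4)) / w.sum()
        assert np.allclose(got_w, np.clip(expect_w, -1, 1), atol=1e-12)

    def test_weighted_map_bounded_by_per_mode_extrema(self, tf_like):
        _, s, _ = tf_like
        modes = slow_modes(build_enm(s), 10)
        per_mode = np.stack([cross_correlation(modes, k).matrix
                             for k in range(10)])
        weighted = cross_correlation(modes, "weighted").matrix
        assert np.all(weighted <= per_mode.max(axis=0) + 1e-10)
        assert np.all(weighted >= per_mode.min(axis=0) - 1e-10)


class TestDynamicDomains:
    def test_exact_two_block_map(self):
        m = np.ones((8, 8))
        m[:4, 4:] = -1
        m[4:, :4] = -1
        labels = dynamic_domains(CorrelationMap(m, "test"), 2)
        assert len(np.unique(labels)) == 2
        assert len(np.unique(labels[:4])) == 1
        assert len(np.unique(labels[4:])) == 1
        assert labels[0] != labels[4]

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        m = np.ones((12, 12))
        m[:6, 6:] = m[6:, :6] = -0.8
        m += rng.normal(0, 0.02, m.shape)
        m = np.clip((m + m.T) / 2, -1, 1)
        np.fill_diagonal(m, 1.0)
        labels = dynamic_domains(CorrelationMap(m, "t"), 2)
        perm = rng.permutation(12)
        labels_p = dynamic_domains(CorrelationMap(m[np.ix_(perm, perm)], "t"), 2)
        assert label_agreement(labels[perm], labels_p) == 1.0

    def test_degenerate_all_positive_map_single_domain(self):
        with pytest.warns(UserWarning):
            labels = dynamic_domains(CorrelationMap(np.ones((5, 5)), "t"))
        assert len(np.unique(labels)) == 1

    def test_three_domain_toy_recovers_generator_truth(self, tf_like):
        _, s, dm = tf_like
        modes = slow_modes(build_enm(s), 10)
        cmap = cross_correlation(modes, "weighted")
        idxs = [dm.resolve(s, n) for n in ("BD", "CD", "HD")]
        nodes = np.concatenate(idxs)
        truth = np.concatenate([np.full(i.size, g) for g, i in enumerate(idxs)])
        labels = dynamic_domains(cmap)[nodes]
        assert len(np.unique(labels)) == 3
        assert label_agreement(labels, truth) >= 0.9


class TestDeformAlong:
    def test_child_sits_exactly_at_target_drms(self, two_domain):
        _, s, _ = two_domain
        modes = slow_modes(build_enm(s), 5)
        child = deform_along(modes, np.array([1.0, -1.0, 0.0, 1.0, 0.0]), 2.0)
        assert pairwise_rmsd(child, s, align=False) == pytest.approx(2.0, abs=1e-9)

    def test_opposite_coefficients_mirror(self, two_domain):
        _, s, _ = two_domain
        modes = slow_modes(build_enm(s), 5)
        plus = deform_along(modes, np.array([1.0, 0, 0, 0, 0]), 2.0)
        minus = deform_along(modes, np.array([-1.0, 0, 0, 0, 0]), 2.0)
        assert np.allclose(plus.coords - s.coords,
                           -(minus.coords - s.coords), atol=1e-10)
        assert pairwise_rmsd(plus, s, align=False) == pytest.approx(
            pairwise_rmsd(minus, s, align=False), abs=1e-10)

    def test_zero_coefficients_rejected(self, two_domain):
        _, s, _ = two_domain
        modes = slow_modes(build_enm(s), 5)
        with pytest.raises(ValueError):
            deform_along(modes, np.zeros(5), 2.0)
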