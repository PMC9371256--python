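"""Gradient, structure-function coupling, and expression statistics."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from crossmodalfc.context import (
    depth_profile_association,
    differential_stability,
    expression_map_association,
    principal_gradient,
    robust_sigmoid,
    structure_function_coupling,
    unit_rescale,
)
from crossmodalfc.datatypes import ConnectivityMatrix
from crossmodalfc.nulls import generate_spins, spin_pvalue
from crossmodalfc.synthetic import (
    DepthProfileSet,
    ExpressionPanel,
    SyntheticConfig,
    make_context_maps,
    make_geometry,
)


def _two_block_fc(n=40, seed=0, within=0.8, between=0.1, noise=0.02):
    rng = np.random.default_rng(seed)
    half = n // 2
    m = np.full((n, n), between)
    m[:half, :half] = within
    m[half:, half:] = within
    e = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    e[iu] = rng.normal(0, noise, size=iu[0].size)
    m = m + e + e.T
    np.fill_diagonal(m, 0.0)
    return ConnectivityMatrix(values=m), np.array([0] * half + [1] * half)


class TestPrincipalGradient:
    def test_two_block_structure_recovered(self):
        fc, labels = _two_block_fc()
        grad = principal_gradient(fc)
        signs = grad.scores > np.median(grad.scores)
        agreement = max((signs == labels).mean(), (signs == (1 - labels)).mean())
        assert agreement == 1.0

    def test_permutation_equivariance(self):
        fc, _ = _two_block_fc(seed=3)
        anchor = np.arange(40, dtype=float)
        grad = principal_gradient(fc, anchor=anchor)
        rng = np.random.default_rng(4)
        perm = rng.permutation(40)
        fc_p = ConnectivityMatrix(values=fc.values[np.ix_(perm, perm)])
        grad_p = principal_gradient(fc_p, anchor=anchor[perm])
        # relative tolerance: the eigenvalue-scaled scores can be large when
        # the affinity graph is nearly disconnected
        scale = np.abs(grad.scores).max()
        assert np.abs(grad_p.scores - grad.scores[perm]).max() < 1e-6 * scale

    def test_affinity_matches_bruteforce_on_toy(self):
        """Thresholded-row cosine affinity against a direct computation."""
        from crossmodalfc.context import _threshold_rows

        rng = np.random.default_rng(5)
        m = rng.uniform(0.1, 1.0, size=(5, 5))
        m = 0.5 * (m + m.T)
        np.fill_diagonal(m, 0.0)
        thr = _threshold_rows(m, keep_frac=0.5)
        for i in range(5):
            row = m[i].copy()
            row[i] = -np.inf
            k = max(1, int(np.ceil(0.5 * 4)))
            keep = np.argsort(-row, kind="stable")[:k]
            expected = np.zeros(5)
            expected[keep] = m[i, keep]
            assert np.abs(thr[i] - expected).max() < 1e-15
        for i in range(5):
            for j in range(5):
                num = thr[i] @ thr[j]
                den = np.linalg.norm(thr[i]) * np.linalg.norm(thr[j])
                cos = num / den
                affinity = (thr / np.linalg.norm(thr, axis=1)[:, None])
                assert abs((affinity @ affinity.T)[i, j] - cos) < 1e-10


class TestStructureFunctionCoupling:
    def _toy(self):
        n = 10
        rng = np.random.default_rng(6)
        sc = rng.uniform(0.1, 1.0, size=(n, n))
        sc = 0.5 * (sc + sc.T)
        sc[sc < 0.35] = 0.0
        np.fill_diagonal(sc, 0.0)
        return ConnectivityMatrix(values=sc, modality="structural")

    def test_monotone_transform_gives_unity(self):
        sc = self._toy()
        fc = ConnectivityMatrix(values=np.tanh(sc.values) + sc.values**2)
        coupling = structure_function_coupling(sc, fc)
        nz_counts = [(sc.row_profile(i) != 0).sum() for i in range(sc.n)]
        for i, c in enumerate(coupling):
            if nz_counts[i] >= 3:
                assert c == pytest.approx(1.0, abs=1e-12)

    def test_reversed_ranks_give_minus_one(self):
        sc = self._toy()
        fc = ConnectivityMatrix(values=-sc.values)
        coupling = structure_function_coupling(sc, fc)
        valid = ~np.isnan(coupling)
        assert np.allclose(coupling[valid], -1.0)

    def test_zero_entries_excluded_via_bruteforce_oracle(self):
        sc = self._toy()
        rng = np.random.default_rng(7)
        f = rng.normal(size=(sc.n, sc.n))
        f = 0.5 * (f + f.T)
        np.fill_diagonal(f, 0.0)
        fc = ConnectivityMatrix(values=f)
        coupling = structure_function_coupling(sc, fc)
        for i in range(sc.n):
            s_row = sc.row_profile(i)
            f_row = fc.row_profile(i)
            nz = s_row != 0
            if nz.sum() < 3:
                assert np.isnan(coupling[i])
            else:
                expected = spearmanr(s_row[nz], f_row[nz]).statistic
                assert coupling[i] == pytest.approx(expected, abs=1e-12)


class TestDepthAssociation:
    def test_shapes_and_self_depth(self, small_geometry, rng):
        n = small_geometry.n
        profiles = rng.normal(size=(n, 50))
        target = rng.normal(size=n)
        profiles[:, 20] = target
        spins = generate_spins(small_geometry, 100, seed=12)
        res = depth_profile_association(target, DepthProfileSet(profiles, 20), spins)
        assert res.correlations.shape == (50,)
        assert res.p_spin.shape == (50,)
        assert res.fdr_mask.shape == (50,)
        assert res.correlations[20] == pytest.approx(1.0, abs=1e-12)

    def test_consistent_with_direct_spin_pvalue(self, small_geometry, rng):
        n = small_geometry.n
        profiles = rng.normal(size=(n, 5))
        target = rng.normal(size=n)
        spins = generate_spins(small_geometry, 80, seed=13)
        res = depth_profile_association(target, DepthProfileSet(profiles, 0), spins)
        for d in range(5):
            direct = spin_pvalue(target, profiles[:, d], spins)
            assert res.correlations[d] == pytest.approx(direct.r, abs=1e-12)
            assert res.p_spin[d] == pytest.approx(direct.p_spin, abs=1e-12)


class TestNormalization:
    def test_median_maps_to_half(self):
        x = np.array([1.0, 2.0, 3.0, 10.0, 50.0])
        out = robust_sigmoid(x)
        assert out[2] == pytest.approx(0.5, abs=1e-15)

    def test_monotone_and_bounded(self, rng):
        x = np.sort(rng.normal(size=100))
        out = robust_sigmoid(x)
        assert (np.diff(out) > 0).all()
        assert (out > 0).all() and (out < 1).all()

    def test_hand_computed_values(self):
        x = np.array([0.0, 5.0, 10.0])
        iqr = (7.5 - 2.5) / 1.349
        expected = 1.0 / (1.0 + np.exp(-(x - 5.0) / iqr))
        assert np.abs(robust_sigmoid(x) - expected).max() < 1e-12

    def test_zero_iqr_rejected(self):
        with pytest.raises(ValueError):
            robust_sigmoid(np.array([1.0, 1.0, 1.0, 1.0, 9.0]))

    def test_unit_rescale_examples(self):
        out = unit_rescale(np.array([2.0, 4.0, 8.0]))
        assert np.abs(out - np.array([0.0, 1.0 / 3.0, 1.0])).max() < 1e-12
        x = np.array([1.0, 3.0, 7.0, 2.0])
        assert np.abs(unit_rescale(5 * x + 11) - unit_rescale(x)).max() < 1e-12
        with pytest.raises(ValueError):
            unit_rescale(np.ones(4))


class TestDifferentialStability:
    def test_reversed_two_donor_ranks(self):
        pattern = np.arange(10.0)
        values = np.stack([pattern[:, None], pattern[::-1][:, None]])
        panel = ExpressionPanel(values=values, genes=["g"], donors=["a", "b"])
        assert differential_stability(panel, "g") == pytest.approx(-1.0)

    def test_four_donors_match_allpairs_oracle(self, rng):
        values = rng.normal(size=(4, 15, 1))
        panel = ExpressionPanel(values=values, genes=["g"], donors=list("abcd"))
        got = differential_stability(panel, "g")
        pairs = []
        for i in range(3):
            for j in range(i + 1, 4):
                pairs.append(spearmanr(values[i, :, 0], values[j, :, 0]).statistic)
        assert got == pytest.approx(np.mean(pairs), abs=1e-12)
        assert -1.0 <= got <= 1.0

    def test_missing_gene_rejected(self, rng):
        panel = ExpressionPanel(
            values=rng.normal(size=(2, 5, 1)), genes=["g"], donors=["a", "b"]
        )
        with pytest.raises(KeyError):
            differential_stability(panel, "nope")


class TestExpressionAssociation:
    def test_planted_negative_association_recovered(self, geometry200, config200):
        anchor = np.asarray(geometry200.coords[:, 2])
        _, panel, _ = make_context_maps(
            geometry200, anchor, config200, designated_correlation=-0.6
        )
        spins = generate_spins(geometry200, 200, seed=14)
        res = expression_map_association(anchor, panel, "NPY1R", spins)
        assert -0.7 <= res.r <= -0.5

    def test_self_copy_is_perfect(self, small_geometry, rng):
        n = small_geometry.n
        m = rng.normal(size=n)
        values = np.stack([m[:, None], m[:, None]])
        panel = ExpressionPanel(values=values, genes=["g"], donors=["a", "b"])
        spins = generate_spins(small_geometry, 50, seed=15)
        res = expression_map_association(m, panel, "g", spins)
        assert res.r == pytest.approx(1.0, abs=1e-12)

    def test_consistent_with_direct_spin_pvalue(self, small_geometry, rng):
        n = small_geometry.n
        m = rng.normal(size=n)
        expr = rng.normal(size=n)
        values = np.stack([expr[:, None], expr[:, None]])
        panel = ExpressionPanel(values=values, genes=["g"], donors=["a", "b"])
        spins = generate_spins(small_geometry, 60, seed=16)
        res = expression_map_association(m, panel, "g", spins)
        from crossmodalfc.context import robust_sigmoid as rs, unit_rescale as ur

        direct = spin_pvalue(m, ur(rs(expr)), spins)
        assert res.r == pytest.approx(direct.r, abs=1e-12)
        assert res.p_spin == pytest.approx(direct.p_spin, abs=1e-12)
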