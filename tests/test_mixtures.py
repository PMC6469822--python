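"""MCR bounds, SNMU correctness against a brute-force oracle, and
MCR-filtered mixture selection."""

import numpy as np
import pandas as pd
import pytest

from _snmu_oracle import brute_force_rank_one, underapprox_objective
from aggexpo.mixtures import compute_mcr, select_mixtures, snmu


def as_df(M, cols=None):
    M = np.asarray(M, dtype=float)
    cols = cols or [f"c{j}" for j in range(M.shape[1])]
    return pd.DataFrame(M, columns=cols)


def component_objective(X: np.ndarray, mix) -> float:
    """Frobenius reduction achieved by a reported mixture, recomputed from
    the matrix (weights determine the direction h up to scale)."""
    h = np.zeros(X.shape[1])
    cols = [f"c{j}" for j in range(X.shape[1])]
    for comp, wgt in mix.components:
        h[cols.index(comp)] = wgt
    return underapprox_objective(X, h)


class TestMCR:
    def test_simple_ratio(self):
        assert compute_mcr(as_df([[3.0, 1.0]])).iloc[0] == pytest.approx(4 / 3)

    def test_single_compound_lower_bound(self):
        assert compute_mcr(as_df([[0.0, 5.0]])).iloc[0] == 1.0

    def test_equal_entries_upper_bound(self):
        assert compute_mcr(as_df([[2.0, 2.0, 2.0]])).iloc[0] == pytest.approx(3.0)

    def test_zero_rows_undefined(self):
        mcr = compute_mcr(as_df([[0.0, 0.0], [1.0, 2.0]]))
        assert np.isnan(mcr.iloc[0]) and mcr.iloc[1] == pytest.approx(1.5)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            compute_mcr(as_df([[0.0, 0.0]]))

    def test_bounds_random_rows(self):
        """MCR in [1, #positive entries] for 10,000 random rows."""
        rng = np.random.default_rng(123)
        M = rng.random((10_000, 8)) * (rng.random((10_000, 8)) < 0.5)
        M[M.sum(axis=1) == 0, 0] = 1.0
        mcr = compute_mcr(as_df(M))
        npos = (M > 0).sum(axis=1)
        assert (mcr >= 1.0 - 1e-12).all()
        assert (mcr <= npos + 1e-12).all()


class TestSNMU:
    def test_rank_one_recovered_exactly(self):
        u = np.array([1.0, 2.0, 0.5, 3.0])
        v = np.array([0.2, 0.5, 0.3])
        mixes = snmu(as_df(np.outer(u, v)), k=1, sparsity=0.0)
        assert mixes[0].variance_explained >= 0.999
        np.testing.assert_allclose(
            [w for _, w in sorted(mixes[0].components)], v / v.sum(), atol=1e-6
        )

    def test_identity_matrix_half_variance(self):
        """Best rank-one underapproximation of I_2 is one axis: exactly half
        the squared norm (verified against the brute-force oracle)."""
        X = np.eye(2)
        mixes = snmu(as_df(X), k=1, sparsity=0.0)
        assert mixes[0].variance_explained == pytest.approx(0.5, abs=1e-9)
        X3 = np.eye(3)
        assert brute_force_rank_one(X3) == pytest.approx(1.0, abs=1e-6)

    def test_underapproximation_constraint(self):
        rng = np.random.default_rng(7)
        X = rng.random((20, 6))
        mix = snmu(as_df(X), k=1, sparsity=0.0)[0]
        # rebuild w h^T from the oracle's optimal w for the reported h
        h = np.zeros(6)
        for comp, wgt in mix.components:
            h[int(comp[1:])] = wgt
        hh = h @ h
        w = np.clip(X @ h / hh, 0.0, None)
        sup = h > 0
        w = np.minimum(w, (X[:, sup] / h[sup]).min(axis=1))
        assert (np.outer(w, h) <= X + 1e-9).all()

    def test_matches_brute_force_on_coarse_grids(self):
        """Component-1 objective equals the brute-force grid optimum on 3x3
        matrices with entries on a coarse grid."""
        rng = np.random.default_rng(11)
        for _ in range(12):
            X = rng.integers(0, 7, size=(3, 3)).astype(float) / 2.0
            if (X == 0).all():
                continue
            norm2 = (X * X).sum()
            ours = component_objective(X, snmu(as_df(X), k=1, sparsity=0.0)[0])
            oracle = brute_force_rank_one(X)
            assert ours >= oracle - 1e-3 * norm2
            assert abs(ours - oracle) <= 1e-3 * norm2

    def test_column_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        X = rng.random((15, 5))
        perm = [3, 0, 4, 1, 2]
        a = snmu(as_df(X), k=2, sparsity=0.0)
        b = snmu(as_df(X[:, perm], cols=[f"c{j}" for j in perm]), k=2, sparsity=0.0)
        for ma, mb in zip(a, b):
            assert ma.weights() == pytest.approx(mb.weights())
            assert ma.variance_explained == pytest.approx(mb.variance_explained)

    def test_scale_invariance(self):
        rng = np.random.default_rng(6)
        X = rng.random((10, 4))
        a = snmu(as_df(X), k=2, sparsity=0.1)
        b = snmu(as_df(7.5 * X), k=2, sparsity=0.1)
        for ma, mb in zip(a, b):
            assert ma.weights() == pytest.approx(mb.weights())
            assert ma.variance_explained == pytest.approx(mb.variance_explained)

    def test_variance_explained_decreasing_and_bounded(self):
        rng = np.random.default_rng(8)
        X = rng.random((30, 6)) * (rng.random((30, 6)) < 0.6)
        mixes = snmu(as_df(X), k=4, sparsity=0.0)
        ve = [m.variance_explained for m in mixes]
        assert all(ve[i] >= ve[i + 1] - 1e-9 for i in range(len(ve) - 1))
        assert sum(ve) <= 1.0 + 1e-9

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            snmu(as_df(np.zeros((3, 3))), k=1)

    def test_invalid_parameters(self):
        X = as_df(np.eye(2))
        with pytest.raises(ValueError):
            snmu(X, k=0)
        with pytest.raises(ValueError):
            snmu(X, k=1, sparsity=1.0)


class TestSelectMixtures:
    def test_no_threshold_equals_plain_snmu(self):
        rng = np.random.default_rng(9)
        X = as_df(rng.random((25, 5)))
        plain = snmu(X, k=2, sparsity=0.0)
        selected = select_mixtures(X, k=2, sparsity=0.0, mcr_threshold=None)
        for a, b in zip(plain, selected):
            assert a.weights() == pytest.approx(b.weights())

    def test_single_compound_population_errors(self):
        """Everyone exposed to one compound has MCR 1 everywhere; a
        threshold of 2 leaves no rows."""
        X = as_df(np.column_stack([np.ones(10), np.zeros(10)]))
        with pytest.raises(ValueError, match="0 of 10"):
            select_mixtures(X, k=1, mcr_threshold=2.0)

    def test_planted_coexposure_block_recovered(self):
        """A planted 3-compound co-exposure block is the top mixture."""
        rng = np.random.default_rng(10)
        n, m = 200, 6
        X = 0.01 * rng.random((n, m))
        block = rng.lognormal(0, 0.2, size=60)
        X[:60, 0] += 5.0 * block
        X[:60, 1] += 4.0 * block
        X[:60, 2] += 3.0 * block
        mixes = select_mixtures(as_df(X), k=1, sparsity=0.0, mcr_threshold=2.0)
        top3 = {c for c, _ in mixes[0].components[:3]}
        assert top3 == {"c0", "c1", "c2"}

    def test_summaries_not_rpf_scaled(self):
        """Component summaries come from the raw matrix when provided."""
        rng = np.random.default_rng(12)
        raw = as_df(rng.random((50, 3)) + 0.5)
        rpf = np.array([2.0, 0.5, 1.0])
        X = as_df(raw.to_numpy() * rpf)
        mixes = select_mixtures(X, k=1, sparsity=0.0, mcr_threshold=None,
                                raw_exposure=raw)
        s = mixes[0].summaries.set_index("compound")
        for comp in s.index:
            assert s.loc[comp, "mean"] == pytest.approx(raw[comp].mean())
            assert s.loc[comp, "p95"] == pytest.approx(raw[comp].quantile(0.95))

    def test_invalid_threshold(self):
        with pytest.raises(ValueError, match="threshold"):
            select_mixtures(as_df(np.eye(2)), mcr_threshold=1.0)
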