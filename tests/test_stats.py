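"""Ordination, permutation tests and differential-abundance statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as hst
from scipy.spatial.distance import pdist, squareform

from magprof import stats as st


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        m = pd.DataFrame([[0.5, 0.5], [0.5, 0.5]])
        assert st.bray_curtis(m).iloc[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        m = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]])
        assert st.bray_curtis(m).iloc[0, 1] == pytest.approx(1.0)

    def test_hand_example(self):
        m = pd.DataFrame([[0.6, 0.4], [0.2, 0.8]])
        assert st.bray_curtis(m).iloc[0, 1] == pytest.approx(0.4)

    def test_two_zero_rows_raise(self):
        m = pd.DataFrame([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError):
            st.bray_curtis(m)

    @given(hst.lists(
        hst.lists(hst.floats(min_value=0.0, max_value=100.0), min_size=3,
                  max_size=3),
        min_size=2, max_size=6,
    ))
    def test_metric_properties_on_arbitrary_rows(self, rows):
        """Symmetry, zero diagonal and [0,1] range for non-negative rows."""
        m = pd.DataFrame(rows)
        if int((m.sum(axis=1) == 0).sum()) >= 2:
            with pytest.raises(ValueError):
                st.bray_curtis(m)
            return
        d = st.bray_curtis(m).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert np.nanmax(d) <= 1.0 + 1e-12 and np.nanmin(d) >= 0.0

    def test_symmetric_zero_diagonal_bounded(self, rel_matrix):
        d = st.bray_curtis(rel_matrix)
        arr = d.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 0)
        assert arr.max() <= 1.0 and arr.min() >= 0.0


class TestPCoA:
    def test_all_zero_distances_zero_coordinates(self):
        d = pd.DataFrame(np.zeros((4, 4)))
        res = st.pcoa(d)
        assert np.allclose(res.coordinates.to_numpy(), 0)

    def test_euclidean_round_trip(self):
        """Embedding of a Euclidean distance matrix reproduces it exactly."""
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(6, 2))
        d = squareform(pdist(pts))
        res = st.pcoa(pd.DataFrame(d), n_axes=6)
        re_d = squareform(pdist(res.coordinates.to_numpy()))
        assert np.allclose(re_d, d, atol=1e-9)

    def test_eigenvalues_non_increasing(self, rel_matrix):
        res = st.pcoa(st.bray_curtis(rel_matrix))
        assert (np.diff(res.eigenvalues) <= 1e-10).all()

    def test_non_symmetric_raises(self):
        d = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError):
            st.pcoa(d)

    def test_agrees_with_skbio(self):
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(1)
        x = rng.lognormal(size=(8, 5))
        d = squareform(pdist(x, metric="braycurtis"))
        ours = st.pcoa(pd.DataFrame(d), n_axes=3)
        ref = skbio_pcoa(d, number_of_dimensions=3)
        assert np.allclose(
            np.sort(ours.eigenvalues)[::-1][:3], ref.eigvals.to_numpy()[:3], atol=1e-8
        )
        assert np.allclose(
            np.abs(ours.coordinates.to_numpy()),
            np.abs(ref.samples.to_numpy()[:, :3]), atol=1e-6,
        )


class TestPermanova:
    def test_within_group_constant_r2_one(self):
        x = pd.DataFrame([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float)
        d = st.bray_curtis(x)
        res = st.permanova(d, ["a", "a", "b", "b"], n_perm=99, rng_seed=0)
        assert res.r2 == pytest.approx(1.0)
        assert np.isinf(res.pseudo_f)

    def test_duplicated_samples_hit_permutation_floor(self):
        x = pd.DataFrame([[1, 0]] * 10 + [[0, 1]] * 10, dtype=float)
        d = st.bray_curtis(x)
        res = st.permanova(d, ["a"] * 10 + ["b"] * 10, n_perm=200, rng_seed=1)
        assert res.p_perm == pytest.approx(1 / 201)

    def test_small_group_raises(self):
        d = st.bray_curtis(pd.DataFrame(np.eye(3)))
        with pytest.raises(ValueError):
            st.permanova(d, ["a", "a", "b"], n_perm=10)

    def test_agrees_with_skbio(self, rel_matrix, small_cohort):
        from skbio import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova

        d = st.bray_curtis(rel_matrix)
        ours = st.permanova(d, small_cohort.labels, n_perm=99, rng_seed=2)
        ref = skbio_permanova(
            DistanceMatrix(d.to_numpy(), ids=list(d.index)),
            grouping=small_cohort.labels.to_list(), permutations=99,
        )
        assert ours.pseudo_f == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_null_p_values_roughly_uniform(self):
        """Rejection rate at alpha=0.05 near nominal under exchangeable labels."""
        rng = np.random.default_rng(3)
        labels = ["a"] * 10 + ["b"] * 10
        rej = 0
        n_sim = 200
        for i in range(n_sim):
            x = rng.lognormal(0, 1, size=(20, 30))
            res = st.permanova(st.bray_curtis(pd.DataFrame(x)), labels,
                               n_perm=199, rng_seed=1000 + i)
            rej += res.p_perm < 0.05
        assert 0.02 <= rej / n_sim <= 0.09


class TestMantel:
    @pytest.fixture
    def dist(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(10, 4))
        return pd.DataFrame(squareform(pdist(x)))

    def test_self_correlation_one(self, dist):
        res = st.mantel(dist, dist, n_perm=99, rng_seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_perm == pytest.approx(1 / 100)

    def test_scale_invariance(self, dist):
        assert st.mantel(dist, 2 * dist, n_perm=49, rng_seed=0).r == pytest.approx(1.0)

    def test_dimension_mismatch_raises(self, dist):
        with pytest.raises(ValueError):
            st.mantel(dist, dist.iloc[:5, :5], n_perm=10)

    def test_agrees_with_skbio(self, dist):
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(5)
        other = pd.DataFrame(squareform(pdist(rng.normal(size=(10, 4)))))
        ours = st.mantel(dist, other, n_perm=99, rng_seed=1)
        r_ref, _, _ = skbio_mantel(dist.to_numpy(), other.to_numpy(),
                                   permutations=0)
        assert ours.r == pytest.approx(r_ref, abs=1e-12)

    def test_null_rejection_near_nominal(self):
        rng = np.random.default_rng(6)
        rej, n_sim = 0, 300
        for i in range(n_sim):
            a = squareform(pdist(rng.normal(size=(12, 3))))
            b = squareform(pdist(rng.normal(size=(12, 3))))
            res = st.mantel(a, b, n_perm=99, rng_seed=2000 + i)
            rej += res.p_perm < 0.05
        assert 0.02 <= rej / n_sim <= 0.09


class TestBH:
    def brute_force_bh(self, p: np.ndarray) -> np.ndarray:
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        q = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            idx = order[rank - 1]
            running = min(running, p[idx] * m / rank)
            q[idx] = running
        return q

    def test_hand_example(self):
        q = st.bh_qvalues([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            p = rng.uniform(size=rng.integers(1, 21))
            assert np.allclose(st.bh_qvalues(p), self.brute_force_bh(p), atol=1e-12)

    @given(hst.lists(hst.floats(min_value=0.0, max_value=1.0), min_size=1,
                     max_size=20))
    def test_bh_bounds_and_rank_monotone(self, p):
        """q-values stay in [0,1] and are non-decreasing along sorted p."""
        q = st.bh_qvalues(p)
        assert ((q >= 0) & (q <= 1)).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_matches_statsmodels(self):
        """Independent cross-check against statsmodels' fdr_bh."""
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(17)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(2, 200))
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(st.bh_qvalues(p), ref, atol=1e-12)


class TestDifferentialFeatures:
    @pytest.fixture
    def labels40(self):
        return pd.Series(["PE"] * 20 + ["HC"] * 20,
                         index=[f"s{i}" for i in range(40)])

    def test_null_false_positive_control(self, labels40):
        """~5% raw p<0.05 and (almost) none at q<0.05 on 200 null features."""
        rng = np.random.default_rng(8)
        data = pd.DataFrame(rng.lognormal(0, 1, size=(40, 200)),
                            index=labels40.index)
        res = st.differential_features(data, labels40, case="PE")
        frac_p = (res["p"] < 0.05).mean()
        assert 0.005 <= frac_p <= 0.12
        assert (res["q"] < 0.05).sum() <= 2

    def test_planted_effect_detected(self, rel_matrix, small_cohort):
        res = st.differential_features(rel_matrix, small_cohort.labels, case="PE")
        assert res.loc["s0", "q"] < 0.05
        assert res.loc["s0", "direction"] == "PE-enriched"
        assert res.loc["s0", "log2fc"] > 0

    def test_antisymmetric_under_label_swap(self, rel_matrix, small_cohort):
        """Swapping case/control flips fold-change signs but not the p-values
        or the name of the enriched group."""
        a = st.differential_features(rel_matrix, small_cohort.labels, case="PE")
        b = st.differential_features(rel_matrix, small_cohort.labels, case="HC")
        assert np.allclose(a["p"], b["p"])
        assert np.allclose(a["log2fc"], -b["log2fc"])
        assert list(b["direction"]) == list(a["direction"])

    def test_constant_feature_flagged(self, labels40):
        rng = np.random.default_rng(9)
        data = pd.DataFrame({"flat": np.ones(40),
                             "var": rng.uniform(size=40)}, index=labels40.index)
        res = st.differential_features(data, labels40, case="PE")
        assert res.loc["flat", "p"] == 1.0
        assert bool(res.loc["flat", "constant"])

    def test_exact_and_asymptotic_agree_reasonably(self, labels40):
        rng = np.random.default_rng(10)
        data = pd.DataFrame(rng.normal(5, 1, size=(40, 5)), index=labels40.index)
        exact = st.differential_features(data, labels40, case="PE", exact_max_n=25)
        asym = st.differential_features(data, labels40, case="PE", exact_max_n=0)
        assert np.allclose(exact["p"], asym["p"], atol=0.02)
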