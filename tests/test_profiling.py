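import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from phasemet.profiling import (
    DEFAULT_TIME_GRID,
    CorrelationMatrix,
    aggregate_replicates,
    categorize,
    classify_trend,
    classify_trends,
    compare_metabolite_sets,
    correlation_matrix,
    nominate_biomarkers,
    normalize_matrix,
    profile_dataset,
    threshold_clusters,
    to_matrix,
)
from phasemet.synth import NoiseSpec, default_reference_study


def long_frame(values: dict[str, list[float]], replicates=1) -> pd.DataFrame:
    rows = []
    for mid, series in values.items():
        for rep in range(1, replicates + 1):
            for t, v in zip(DEFAULT_TIME_GRID, series):
                rows.append((mid, t, rep, v))
    return pd.DataFrame(rows, columns=["metabolite_id", "time_h", "replicate", "intensity"])


class TestAggregate:
    def test_mean_of_three(self):
        df = pd.DataFrame(
            {
                "metabolite_id": ["a"] * 3,
                "time_h": [1.0] * 3,
                "replicate": [1, 2, 3],
                "intensity": [1.0, 2.0, 3.0],
            }
        )
        agg = aggregate_replicates(to_matrix(df))
        assert agg.loc["a", 1.0] == 2.0

    def test_single_replicate_identity(self):
        df = long_frame({"a": [1, 2, 3, 4, 5, 6]})
        agg = aggregate_replicates(to_matrix(df))
        assert list(agg.loc["a"]) == [1, 2, 3, 4, 5, 6]

    def test_matches_hand_means_on_seeded_replicates(self):
        study = default_reference_study("5F-ADB-PINACA", seed=7)
        agg = aggregate_replicates(to_matrix(study.intensities))
        raw = study.intensities
        for mid in ("P", "M_defluoro"):
            for t in study.times:
                vals = raw[(raw.metabolite_id == mid) & (raw.time_h == t)]["intensity"]
                assert agg.loc[mid, t] == pytest.approx(vals.mean())


class TestNormalize:
    def test_global_max_cell_is_one(self):
        m = pd.DataFrame([[1.0, 10.0], [3.0, 4.0]])
        n = normalize_matrix(m, "global_max")
        assert n.to_numpy().max() == 1.0
        assert (n.to_numpy() == 1.0).sum() == 1

    def test_per_metabolite_row_max_one(self):
        m = pd.DataFrame([[1.0, 10.0], [3.0, 4.0]])
        n = normalize_matrix(m, "per_metabolite")
        assert list(n.max(axis=1)) == [1.0, 1.0]

    def test_idempotent(self):
        m = pd.DataFrame(np.random.default_rng(0).uniform(0, 5, (4, 6)))
        once = normalize_matrix(m, "global_max")
        twice = normalize_matrix(once, "global_max")
        pd.testing.assert_frame_equal(once, twice)

    def test_rank_order_preserved(self):
        m = pd.DataFrame(np.random.default_rng(1).uniform(0, 5, (3, 6)))
        n = normalize_matrix(m, "global_max")
        assert (m.to_numpy().argsort(axis=None) == n.to_numpy().argsort(axis=None)).all()

    def test_all_zero_error(self):
        with pytest.raises(ValueError):
            normalize_matrix(pd.DataFrame([[0.0, 0.0]]), "global_max")


class TestClassifyTrend:
    def test_constant_is_stable(self):
        assert classify_trend(np.full(6, 3.0)).label == "stable"

    def test_early_peak_decaying_example(self):
        # peak at 2 h, final value 10% of max -> early peak, low persistence
        tc = classify_trend(np.array([0.2, 1.0, 0.6, 0.3, 0.2, 0.1]))
        assert tc.label == "early_peak_decaying"
        assert tc.peak_time == 2.0
        assert tc.persistence == pytest.approx(0.1)

    def test_doubling_series_is_rising(self):
        tc = classify_trend(np.array([1, 2, 4, 8, 16, 32], dtype=float))
        assert tc.label == "rising"
        assert tc.fold >= 2 and tc.persistence == 1.0

    def test_short_series_undetermined(self):
        assert classify_trend(np.array([1.0, 2.0, 3.0])).label == "undetermined"

    def test_fluctuating_fallback(self):
        # late peak, low persistence, high cv: matches no earlier rule
        tc = classify_trend(np.array([1.0, 1.0, 1.0, 6.0, 1.0, 2.0]))
        assert tc.label == "fluctuating"


class TestCorrelation:
    def test_identical_rows_rho_one(self):
        m = pd.DataFrame([[1, 2, 3, 4, 5, 6]] * 2, index=["a", "b"],
                         columns=DEFAULT_TIME_GRID, dtype=float)
        corr = correlation_matrix(m)
        assert corr.rho.loc["a", "b"] == pytest.approx(1.0)

    def test_negated_rho_minus_one(self):
        x = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        m = pd.DataFrame([x, 2 * x.mean() - x], index=["a", "b"],
                         columns=DEFAULT_TIME_GRID)
        corr = correlation_matrix(m)
        assert corr.rho.loc["a", "b"] == pytest.approx(-1.0)

    def test_hand_computed_three_series(self):
        # rho(a,b) via the textbook formula on 4 points
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 1.0, 4.0, 3.0])
        expected = (
            np.sum((a - a.mean()) * (b - b.mean()))
            / np.sqrt(np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2))
        )
        m = pd.DataFrame([a, b], index=["a", "b"], columns=[1.0, 2.0, 4.0, 8.0])
        corr = correlation_matrix(m)
        assert corr.rho.loc["a", "b"] == pytest.approx(expected)
        assert expected == pytest.approx(0.6)

    def test_zero_variance_excluded_with_warning(self):
        m = pd.DataFrame(
            [[1, 2, 3, 4, 5, 6], [2.0] * 6], index=["a", "flat"],
            columns=DEFAULT_TIME_GRID, dtype=float,
        )
        with pytest.warns(UserWarning, match="zero variance"):
            corr = correlation_matrix(m)
        assert "flat" in corr.excluded and "flat" not in corr.rho.index

    @given(
        arrays(
            np.float64, (5, 6),
            elements=st.floats(0.01, 100.0, allow_nan=False),
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_invariants_random_matrices(self, x):
        m = pd.DataFrame(x, index=[f"m{i}" for i in range(5)],
                         columns=DEFAULT_TIME_GRID)
        corr = correlation_matrix(m)
        rho = corr.rho.to_numpy()
        assert np.allclose(rho, rho.T, equal_nan=True)
        assert np.allclose(np.diag(rho), 1.0)
        finite = rho[np.isfinite(rho)]
        assert (finite >= -1 - 1e-12).all() and (finite <= 1 + 1e-12).all()


class TestClusters:
    def corr_from(self, rho: np.ndarray, ids) -> CorrelationMatrix:
        return CorrelationMatrix(
            rho=pd.DataFrame(rho, index=ids, columns=ids), n_timepoints=6
        )

    def test_all_high_one_component(self):
        rho = np.full((3, 3), 0.95)
        np.fill_diagonal(rho, 1.0)
        cl = threshold_clusters(self.corr_from(rho, list("abc")), 0.8)
        assert cl.components == (("a", "b", "c"),)

    def test_block_diagonal(self):
        rho = np.eye(4)
        rho[0, 1] = rho[1, 0] = 0.9
        rho[2, 3] = rho[3, 2] = -0.9  # |rho| edges count too
        cl = threshold_clusters(self.corr_from(rho, list("abcd")), 0.8)
        assert set(cl.components) == {("a", "b"), ("c", "d")}

    def test_partition(self):
        rng = np.random.default_rng(3)
        rho = rng.uniform(-1, 1, (6, 6))
        rho = (rho + rho.T) / 2
        np.fill_diagonal(rho, 1.0)
        ids = [f"m{i}" for i in range(6)]
        cl = threshold_clusters(self.corr_from(rho, ids), 0.8)
        members = [m for comp in cl.components for m in comp]
        assert sorted(members) == sorted(ids)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(4)
        rho = rng.uniform(-1, 1, (8, 8))
        rho = (rho + rho.T) / 2
        np.fill_diagonal(rho, 1.0)
        ids = [f"m{i}" for i in range(8)]
        corr = self.corr_from(rho, ids)
        low = threshold_clusters(corr, 0.5)
        high = threshold_clusters(corr, 0.9)
        # raising the threshold only refines: every high component is a
        # subset of some low component
        for comp in high.components:
            assert any(set(comp) <= set(c) for c in low.components)


class TestCategorizeAndNominate:
    @pytest.fixture()
    def noiseless(self):
        study = default_reference_study(
            "5F-ADB-PINACA", seed=0,
            noise=NoiseSpec(sigma=0.0, mz_ppm_sigma=0.0, seed=0),
        )
        return profile_dataset(study.intensities)

    def test_dominant_stable_is_sink(self, noiseless):
        assert noiseless["categories"]["M_defluoro"] == "dominant_stable"

    def test_transient_rapidly_decaying(self, noiseless):
        assert noiseless["categories"]["M_oh"] == "rapidly_decaying"

    def test_parent_never_rising(self, noiseless):
        assert noiseless["trends"]["P"].label in ("early_peak_decaying", "undetermined")

    def test_sink_never_early_peak(self, noiseless):
        assert noiseless["trends"]["M_defluoro"].label != "early_peak_decaying"
        assert noiseless["trends"]["M_deep"].label != "early_peak_decaying"

    def test_top_nominee_is_sink(self, noiseless):
        assert noiseless["nomination"].top == "M_defluoro"

    def test_scores_in_unit_interval(self, noiseless):
        scores = noiseless["nomination"].ranking["score"]
        assert ((scores >= 0) & (scores <= 1 + 1e-12)).all()

    def test_order_invariance(self):
        study = default_reference_study("5F-ADB-PINACA", seed=5)
        df = study.intensities
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = profile_dataset(df)
        b = profile_dataset(shuffled)
        assert a["categories"] == b["categories"]
        assert list(a["nomination"].ranking.index) == list(b["nomination"].ranking.index)

    def test_single_metabolite_nominated(self):
        df = long_frame({"only": [1, 2, 3, 4, 5, 6]})
        res = profile_dataset(df)
        assert res["nomination"].top == "only"

    def test_singleton_low_correlation_is_independent(self):
        values = {
            "a": [1, 2, 4, 8, 12, 24],
            "b": [1.1, 2.1, 4.2, 8.1, 12.2, 24.1],
            "lone": [5, 1, 6, 2, 7, 1],
        }
        res = profile_dataset(long_frame(values))
        assert res["categories"]["lone"] == "fluctuating_independent"


class TestCompareSets:
    def test_identical(self):
        rep = compare_metabolite_sets({"a", "b"}, {"a", "b"})
        assert rep["jaccard"] == 1.0 and rep["a_only"] == []

    def test_disjoint(self):
        rep = compare_metabolite_sets({"a"}, {"b"})
        assert rep["jaccard"] == 0.0

    def test_subset(self):
        a = {f"M{i}" for i in range(1, 22)}
        b = set(list(a)[:19])
        rep = compare_metabolite_sets(a, b)
        assert len(rep["a_only"]) == 2 and rep["b_only"] == []
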