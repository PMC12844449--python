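"""Temporal metabolic profiling: replicate aggregation, normalization,
trend classification, Pearson correlation clustering and biomarker
nomination.

Input is a long-format intensity table (metabolite_id, time_h,
replicate, intensity) sampled on the 1/2/4/8/12/24 h grid with three
replicates by default.  Replicates are mean-aggregated before
correlation analysis; metabolites with |rho| above the threshold
(default 0.8) form strongly correlated clusters, read as connected
components of the thresholded correlation graph.

Trend classes are a rule-based formalization of the qualitative
patterns (rising / early-peak decaying / stable / fluctuating); the
numeric thresholds are repo defaults exposed in :class:`TrendThresholds`
and are not a published procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_TIME_GRID",
    "TrendThresholds",
    "TrendClass",
    "CorrelationMatrix",
    "ClusterSet",
    "BiomarkerNomination",
    "load_intensity_csv",
    "to_matrix",
    "aggregate_replicates",
    "normalize_matrix",
    "classify_trend",
    "classify_trends",
    "correlation_matrix",
    "threshold_clusters",
    "categorize",
    "nominate_biomarkers",
    "compare_metabolite_sets",
    "profile_dataset",
]

DEFAULT_TIME_GRID = (1.0, 2.0, 4.0, 8.0, 12.0, 24.0)

TREND_CLASSES = ("rising", "early_peak_decaying", "stable", "fluctuating")
CATEGORIES = (
    "dominant_stable",
    "rapidly_decaying",
    "core_cluster",
    "fluctuating_independent",
)


@dataclass(frozen=True)
class TrendThresholds:
    """Repo-default cutoffs for the rule-based trend classifier."""

    rising_fold: float = 2.0  # final/first
    rising_persistence: float = 0.8  # final/max
    early_peak_time_h: float = 4.0
    early_peak_persistence: float = 0.5
    stable_cv: float = 0.3


@dataclass(frozen=True)
class TrendClass:
    label: str  # one of TREND_CLASSES or "undetermined"
    peak_time: float | None = None
    persistence: float | None = None
    fold: float | None = None
    cv: float | None = None


@dataclass(frozen=True)
class CorrelationMatrix:
    rho: pd.DataFrame  # symmetric, unit diagonal
    n_timepoints: int
    excluded: tuple[str, ...] = ()  # zero-variance / too-sparse rows


@dataclass(frozen=True)
class ClusterSet:
    threshold: float
    components: tuple[tuple[str, ...], ...]  # sorted component member tuples

    def component_of(self, metabolite: str) -> tuple[str, ...]:
        for comp in self.components:
            if metabolite in comp:
                return comp
        raise KeyError(metabolite)

    @property
    def largest(self) -> tuple[str, ...]:
        return self.components[0] if self.components else ()


@dataclass(frozen=True)
class BiomarkerNomination:
    ranking: pd.DataFrame  # metabolite, score, auc, persistence, centrality, category
    top: str
    per_category: dict = field(default_factory=dict)


# -- input / shaping --------------------------------------------------------


def load_intensity_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ["metabolite_id", "time_h", "replicate", "intensity"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"intensity table: missing column(s) {missing}")
    if (df["intensity"].dropna() < 0).any():
        raise ValueError("intensity table: negative intensities")
    return df


def to_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Long table -> metabolite x (time, replicate) wide matrix."""
    wide = df.pivot_table(
        index="metabolite_id",
        columns=["time_h", "replicate"],
        values="intensity",
        aggfunc="mean",
    )
    return wide.sort_index(axis=0).sort_index(axis=1)


def aggregate_replicates(matrix: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean over present replicates per (metabolite, time).

    Accepts the wide matrix from :func:`to_matrix`; cells where every
    replicate is missing stay missing.
    """
    if isinstance(matrix.columns, pd.MultiIndex):
        return matrix.T.groupby(level="time_h").mean().T
    return matrix


def normalize_matrix(matrix: pd.DataFrame, mode: str = "global_max") -> pd.DataFrame:
    """Scale to the most abundant value, globally or per metabolite."""
    if mode == "global_max":
        peak = np.nanmax(matrix.to_numpy(dtype=float))
        if not np.isfinite(peak) or peak <= 0:
            raise ValueError("cannot normalize: matrix maximum is not positive")
        return matrix / peak
    if mode == "per_metabolite":
        peaks = matrix.max(axis=1)
        if (peaks <= 0).any():
            raise ValueError("cannot normalize: some rows have non-positive maxima")
        return matrix.div(peaks, axis=0)
    raise ValueError(f"unknown normalization mode {mode!r}")


# -- trend classification ---------------------------------------------------


def classify_trend(
    series: pd.Series | np.ndarray,
    times: np.ndarray | None = None,
    thresholds: TrendThresholds = TrendThresholds(),
) -> TrendClass:
    """Rule-based trend class for one metabolite's aggregated time series.

    Rules are applied in order: rising, early-peak-decaying, stable,
    else fluctuating.  Fewer than 4 finite points -> "undetermined".
    """
    if isinstance(series, pd.Series):
        if times is None:
            times = np.asarray(series.index, dtype=float)
        series = series.to_numpy(dtype=float)
    else:
        series = np.asarray(series, dtype=float)
        if times is None:
            times = np.asarray(DEFAULT_TIME_GRID[: len(series)], dtype=float)
    times = np.asarray(times, dtype=float)
    mask = np.isfinite(series)
    if mask.sum() < 4:
        return TrendClass(label="undetermined")
    x, t = series[mask], times[mask]
    peak = float(np.max(x))
    if peak <= 0:  # flat-zero series
        return TrendClass(label="stable", peak_time=float(t[0]), persistence=1.0,
                          fold=1.0, cv=0.0)
    peak_time = float(t[int(np.argmax(x))])
    persistence = float(x[-1] / peak)
    fold = float(x[-1] / x[0]) if x[0] > 0 else float("inf")
    mean = float(np.mean(x))
    cv = float(np.std(x) / mean) if mean > 0 else 0.0
    diag = dict(peak_time=peak_time, persistence=persistence, fold=fold, cv=cv)
    th = thresholds
    if fold >= th.rising_fold and persistence >= th.rising_persistence:
        return TrendClass(label="rising", **diag)
    if peak_time <= th.early_peak_time_h and persistence <= th.early_peak_persistence:
        return TrendClass(label="early_peak_decaying", **diag)
    if cv <= th.stable_cv:
        return TrendClass(label="stable", **diag)
    return TrendClass(label="fluctuating", **diag)


def classify_trends(
    aggregated: pd.DataFrame, thresholds: TrendThresholds = TrendThresholds()
) -> dict[str, TrendClass]:
    times = np.asarray(aggregated.columns, dtype=float)
    return {
        mid: classify_trend(aggregated.loc[mid].to_numpy(dtype=float), times, thresholds)
        for mid in aggregated.index
    }


# -- correlation & clustering ----------------------------------------------


def correlation_matrix(
    aggregated: pd.DataFrame, max_missing: int = 2
) -> CorrelationMatrix:
    """Pairwise Pearson rho over the aggregated time series.

    Rows with zero variance or with more than ``max_missing`` missing
    time points are excluded with a warning.
    """
    excluded = []
    keep = []
    for mid in aggregated.index:
        x = aggregated.loc[mid].to_numpy(dtype=float)
        n_missing = int((~np.isfinite(x)).sum())
        if n_missing > max_missing:
            excluded.append(mid)
            warnings.warn(
                f"{mid}: {n_missing} missing time points, excluded from correlation"
            )
            continue
        if np.nanstd(x) == 0:
            excluded.append(mid)
            warnings.warn(f"{mid}: zero variance, excluded from correlation")
            continue
        keep.append(mid)
    sub = aggregated.loc[keep]
    if len(keep) >= 2 and sub.shape[1] < 3:
        raise ValueError("need at least 3 time points for correlation")
    rho = sub.T.corr(method="pearson")
    np.fill_diagonal(rho.values, 1.0)
    return CorrelationMatrix(
        rho=rho, n_timepoints=sub.shape[1], excluded=tuple(excluded)
    )


def threshold_clusters(corr: CorrelationMatrix, threshold: float = 0.8) -> ClusterSet:
    """Connected components of the |rho| > threshold graph.

    Component ordering is deterministic: by size descending, then by
    lexicographically smallest member id.
    """
    g = nx.Graph()
    ids = list(corr.rho.index)
    g.add_nodes_from(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            rho = corr.rho.loc[a, b]
            if np.isfinite(rho) and abs(rho) > threshold:
                g.add_edge(a, b)
    comps = [tuple(sorted(c)) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c))
    return ClusterSet(threshold=threshold, components=tuple(comps))


# -- categorization & nomination -------------------------------------------


def categorize(
    trends: dict[str, TrendClass],
    clusters: ClusterSet,
    aggregated: pd.DataFrame,
) -> dict[str, str]:
    """Assign each metabolite one of the four profile categories.

    Precedence: dominant_stable > rapidly_decaying > core_cluster >
    fluctuating_independent.  The dominant metabolite is the one with the
    highest mean normalized abundance, provided its trend is stable or
    rising.
    """
    norm = normalize_matrix(aggregated, "global_max")
    mean_abundance = norm.mean(axis=1)
    dominant = None
    for mid in mean_abundance.sort_values(ascending=False).index:
        if trends[mid].label in ("stable", "rising"):
            dominant = mid
        break  # only the single most abundant metabolite may qualify
    core = set(clusters.largest) if len(clusters.largest) > 1 else set()
    out: dict[str, str] = {}
    for mid in aggregated.index:
        if mid == dominant:
            out[mid] = "dominant_stable"
        elif trends[mid].label == "early_peak_decaying":
            out[mid] = "rapidly_decaying"
        elif mid in core:
            out[mid] = "core_cluster"
        else:
            out[mid] = "fluctuating_independent"
    return out


def _minmax(x: pd.Series) -> pd.Series:
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return pd.Series(1.0, index=x.index)
    return (x - lo) / (hi - lo)


def nominate_biomarkers(
    categories: dict[str, str],
    trends: dict[str, TrendClass],
    clusters: ClusterSet,
    corr: CorrelationMatrix,
    aggregated: pd.DataFrame,
) -> BiomarkerNomination:
    """Rank metabolites by 0.5*AUC + 0.3*persistence + 0.2*centrality.

    Components are min-max scaled across metabolites; centrality is the
    mean |rho| to the metabolite's own cluster component (0 for
    singletons).  Ties break by higher raw AUC, then metabolite id.
    """
    ids = list(aggregated.index)
    times = np.asarray(aggregated.columns, dtype=float)
    auc = pd.Series(
        {
            mid: float(
                np.trapezoid(
                    np.nan_to_num(aggregated.loc[mid].to_numpy(dtype=float)), times
                )
            )
            for mid in ids
        }
    )
    persistence = pd.Series(
        {mid: trends[mid].persistence if trends[mid].persistence is not None else 0.0
         for mid in ids}
    )
    centrality = {}
    for mid in ids:
        try:
            comp = [m for m in clusters.component_of(mid) if m != mid]
        except KeyError:
            comp = []
        if comp and mid in corr.rho.index:
            centrality[mid] = float(
                np.mean([abs(corr.rho.loc[mid, o]) for o in comp if o in corr.rho.index])
            )
        else:
            centrality[mid] = 0.0
    centrality = pd.Series(centrality)
    score = 0.5 * _minmax(auc) + 0.3 * _minmax(persistence) + 0.2 * _minmax(centrality)
    table = pd.DataFrame(
        {
            "score": score,
            "auc": auc,
            "persistence": persistence,
            "centrality": centrality,
            "trend": pd.Series({mid: trends[mid].label for mid in ids}),
            "category": pd.Series(categories),
        }
    )
    table = table.sort_values(
        by=["score", "auc"], ascending=False, kind="mergesort"
    )
    # stable deterministic tie-break on id for exactly equal (score, auc)
    table = table.loc[
        sorted(table.index, key=lambda m: (-table.loc[m, "score"],
                                           -table.loc[m, "auc"], m))
    ]
    per_category = {}
    for cat in CATEGORIES:
        members = [m for m in table.index if categories.get(m) == cat]
        if members:
            per_category[cat] = members[0]
    return BiomarkerNomination(
        ranking=table, top=str(table.index[0]), per_category=per_category
    )


def compare_metabolite_sets(a: set[str], b: set[str]) -> dict:
    """Overlap report between two metabolite id sets (e.g. two models)."""
    a, b = set(a), set(b)
    union = a | b
    inter = a & b
    return {
        "intersection": sorted(inter),
        "a_only": sorted(a - b),
        "b_only": sorted(b - a),
        "jaccard": (len(inter) / len(union)) if union else 1.0,
    }


# -- end-to-end -------------------------------------------------------------


def profile_dataset(
    long_df: pd.DataFrame,
    threshold: float = 0.8,
    normalization: str = "global_max",
    thresholds: TrendThresholds = TrendThresholds(),
) -> dict:
    """Full profiling pass over a long-format intensity table."""
    wide = to_matrix(long_df)
    aggregated = aggregate_replicates(wide)
    norm = normalize_matrix(aggregated, normalization)
    trends = classify_trends(aggregated, thresholds)
    corr = correlation_matrix(aggregated)
    clusters = threshold_clusters(corr, threshold)
    categories = categorize(trends, clusters, aggregated)
    nomination = nominate_biomarkers(categories, trends, clusters, corr, aggregated)
    return {
        "aggregated": aggregated,
        "normalized": norm,
        "trends": trends,
        "correlation": corr,
        "clusters": clusters,
        "categories": categories,
        "nomination": nomination,
    }
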