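"""Concordance between image metrics and the psychovisual decision.

Can a metric — or a combination of metrics — stand in for the human
real-vs-generated judgement?  The module enumerates every non-empty subset of
the metric panel (2^6 - 1 = 63 for the six-metric panel), collapses each
subset to a single per-image score (standardise, then project on the first
principal direction), compares score distributions between image groups by
KL divergence, and ranks the combinations by the strength of their Pearson /
Kendall correlation with the normalised error rate and the mean decision
time across groups.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "enumerate_combinations",
    "combo_feature",
    "kl_divergence",
    "feature_histograms",
    "group_kl_map",
    "correlate_combinations",
]

#: number of equal-width histogram bins over the pooled feature range
DEFAULT_BINS = 16
#: additive smoothing applied to histograms before KL
KL_EPS = 1e-6


def enumerate_combinations(metric_names: Sequence[str]) -> list[tuple[str, ...]]:
    """All non-empty subsets, ordered by size then lexicographically."""
    names = list(metric_names)
    if not names:
        raise ValueError("need at least one metric name")
    if len(set(names)) != len(names):
        raise ValueError("duplicate metric names")
    ordered = sorted(names)
    subsets: list[tuple[str, ...]] = []
    for k in range(1, len(ordered) + 1):
        subsets.extend(itertools.combinations(ordered, k))
    return subsets


def combo_feature(metric_table: pd.DataFrame, subset: Sequence[str]) -> np.ndarray:
    """Collapse a metric subset to one score per image.

    Each metric column is standardised to zero mean / unit variance
    (population convention, ddof=0); a single metric returns its z-scores,
    larger subsets are projected on the first principal direction of the
    standardised block (sign fixed so the leading loading is positive).
    Zero-variance metrics are dropped with a warning.
    """
    cols = []
    kept = []
    for name in subset:
        if name not in metric_table.columns:
            raise KeyError(f"metric {name!r} not in table")
        col = metric_table[name].to_numpy(dtype=float)
        if not np.all(np.isfinite(col)):
            raise ValueError(f"metric {name!r} contains non-finite values")
        sd = col.std()
        if sd == 0:
            warnings.warn(f"metric {name!r} has zero variance; dropped from subset")
            continue
        cols.append((col - col.mean()) / sd)
        kept.append(name)
    if not cols:
        raise ValueError("no usable metrics left in subset")
    Z = np.column_stack(cols)
    if Z.shape[1] == 1:
        return Z[:, 0]
    corr = (Z.T @ Z) / Z.shape[0]
    eigvals, eigvecs = np.linalg.eigh(corr)
    v = eigvecs[:, -1]
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    return Z @ v


def kl_divergence(p_hist, q_hist) -> float:
    """KL(p || q) in nats between two histograms on a shared binning.

    Histograms are additively smoothed (:data:`KL_EPS`) and renormalised, so
    the divergence is finite, >= 0, and zero only for identical (smoothed)
    distributions.  Asymmetric: the first argument is the "data" side.
    """
    p = np.asarray(p_hist, dtype=float)
    q = np.asarray(q_hist, dtype=float)
    if p.shape != q.shape:
        raise ValueError("histograms must share a binning")
    if p.sum() <= 0 or q.sum() <= 0:
        raise ValueError("histograms must have positive mass")
    p = (p + KL_EPS) / (p + KL_EPS).sum()
    q = (q + KL_EPS) / (q + KL_EPS).sum()
    return float(np.sum(p * np.log(p / q)))


def feature_histograms(
    features: np.ndarray, groups: Sequence[str], bins: int = DEFAULT_BINS
) -> dict[str, np.ndarray]:
    """Per-group histograms of a feature on equal-width pooled-range bins."""
    features = np.asarray(features, dtype=float)
    groups = np.asarray(groups)
    lo, hi = features.min(), features.max()
    if lo == hi:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, bins + 1)
    return {
        g: np.histogram(features[groups == g], bins=edges)[0]
        for g in pd.unique(groups)
    }


def group_kl_map(
    features: np.ndarray,
    groups: Sequence[str],
    reference_group: str,
    bins: int = DEFAULT_BINS,
) -> dict[str, float]:
    """KL of each group's feature distribution against a reference group."""
    groups = np.asarray(groups)
    if reference_group not in groups:
        raise ValueError(f"reference group {reference_group!r} not present")
    sizes = pd.Series(groups).value_counts()
    if (sizes < 5).any():
        warnings.warn("some groups have < 5 images; widening histogram bins")
        bins = max(4, bins // 4)
    hists = feature_histograms(features, groups, bins=bins)
    ref = hists[reference_group]
    return {g: kl_divergence(h, ref) for g, h in hists.items()}


def _corr(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r = stats.pearsonr(x, y).statistic
    tau = stats.kendalltau(x, y).statistic
    return float(r), float(tau)


def correlate_combinations(
    metric_table: pd.DataFrame,
    groups: Sequence[str],
    ner: Mapping[str, float],
    times: Mapping[str, float],
    combinations: Sequence[Sequence[str]] | None = None,
    per_image_ner: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Rank metric combinations by agreement with the psychovisual outcome.

    Each combination's per-image feature is averaged per group and correlated
    (Pearson r, Kendall tau) against the per-group NER and mean decision
    time.  Ranking is by \\|r\\| with NER, ties broken by \\|tau\\|.  Constant
    features yield NaN correlations and sink to the bottom.

    Returns a DataFrame sorted by rank with one row per combination.
    """
    groups = np.asarray(groups)
    if combinations is None:
        combinations = enumerate_combinations(list(metric_table.columns))
    group_names = [g for g in pd.unique(groups) if g in ner]
    if len(group_names) < 3:
        raise ValueError("need >= 3 groups with NER values for correlation")
    ner_vec = np.array([ner[g] for g in group_names])
    time_vec = np.array([times[g] for g in group_names])

    rows = []
    for subset in combinations:
        feature = combo_feature(metric_table, subset)
        per_group = np.array(
            [feature[groups == g].mean() for g in group_names]
        )
        r_ner, tau_ner = _corr(per_group, ner_vec)
        r_time, tau_time = _corr(per_group, time_vec)
        rows.append(
            {
                "subset": "+".join(subset),
                "k": len(subset),
                "pearson_ner": r_ner,
                "kendall_ner": tau_ner,
                "pearson_time": r_time,
                "kendall_time": tau_time,
            }
        )
    df = pd.DataFrame(rows)
    key = df["pearson_ner"].abs().fillna(-1.0)
    tie = df["kendall_ner"].abs().fillna(-1.0)
    df = df.assign(_key=key, _tie=tie).sort_values(
        ["_key", "_tie"], ascending=False, kind="mergesort"
    )
    df = df.drop(columns=["_key", "_tie"]).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
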