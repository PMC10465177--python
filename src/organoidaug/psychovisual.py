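"""Analysis of expert real-vs-generated decision sessions.

Decisions on original images are scored as true positives (answered "real")
or false negatives; decisions on synthetic images as false positives
(answered "real") or true negatives.  From the per-group confusion counts the
module derives error and positive rates, decision-time-weighted normalised
error rates (NER), decision-time summaries, vote histograms, and a routed
statistical test report (Shapiro -> Bartlett/Levene -> ANOVA/Kruskal-Wallis
with Tukey/Holm post-hocs).

Pass answers are, by default, excluded from the four confusion counts and
tallied separately — that reading makes each group's four counts sum to
``experts x group size`` exactly; a policy flag instead counts a pass as a
"generated" answer.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .synthetic import DecisionRecord, ORIGINAL_GROUP

__all__ = [
    "ConfusionCounts",
    "label_decisions",
    "er_overall",
    "er_original",
    "er_generated",
    "positive_rate_original",
    "ner_overall",
    "ner_original",
    "ner_generated",
    "error_times",
    "decision_time_summary",
    "votes_histogram",
    "stats_report",
    "percent",
]

PassPolicy = Literal["exclude", "count_as_generated"]


@dataclass
class ConfusionCounts:
    """Per-group decision tallies."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    pass_count: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def label_decisions(
    records: Iterable[DecisionRecord], pass_policy: PassPolicy = "exclude"
) -> dict[str, ConfusionCounts]:
    """Tally confusion counts per image group.

    Originals: "real" -> TP, "generated" -> FN.  Synthetic groups: "real" ->
    FP, "generated" -> TN.  Passes follow ``pass_policy``.
    """
    counts: dict[str, ConfusionCounts] = {}
    for rec in records:
        c = counts.setdefault(rec.group, ConfusionCounts())
        answer = rec.answer
        if answer == "pass":
            if pass_policy == "exclude":
                c.pass_count += 1
                continue
            answer = "generated"
        if rec.group == ORIGINAL_GROUP:
            if answer == "real":
                c.tp += 1
            else:
                c.fn += 1
        else:
            if answer == "real":
                c.fp += 1
            else:
                c.tn += 1
    return counts


def _ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: zero denominator; returning NaN")
        return float("nan")
    return num / den


def er_overall(c: ConfusionCounts) -> float:
    """Error rate: false decisions over all (non-pass) decisions."""
    return _ratio(c.fp + c.fn, c.total, "er_overall")


def er_original(c: ConfusionCounts) -> float:
    """Error rate restricted to original images: FN / (FN + TP)."""
    return _ratio(c.fn, c.fn + c.tp, "er_original")


def er_generated(c: ConfusionCounts) -> float:
    """Error rate restricted to synthetic images: FP / (FP + TN)."""
    return _ratio(c.fp, c.fp + c.tn, "er_generated")


def positive_rate_original(c: ConfusionCounts) -> float:
    """PR of originals = 1 - ER_O = TP / (FN + TP)."""
    return _ratio(c.tp, c.fn + c.tp, "positive_rate_original")


def ner_overall(c: ConfusionCounts, t_fp: float, t_fn: float) -> float:
    """Time-weighted error rate: ``(FP t_FP + FN t_FN) / (FP+FN+TP+TN)``."""
    if t_fp < 0 or t_fn < 0:
        raise ValueError("times must be >= 0")
    return _ratio(c.fp * t_fp + c.fn * t_fn, c.total, "ner_overall")


def ner_original(c: ConfusionCounts, t_fn: float) -> float:
    """``FN t_FN / (FN + TP)``."""
    if t_fn < 0:
        raise ValueError("times must be >= 0")
    return _ratio(c.fn * t_fn, c.fn + c.tp, "ner_original")


def ner_generated(c: ConfusionCounts, t_fp: float) -> float:
    """``FP t_FP / (FP + TN)``."""
    if t_fp < 0:
        raise ValueError("times must be >= 0")
    return _ratio(c.fp * t_fp, c.fp + c.tn, "ner_generated")


def _decision_category(rec: DecisionRecord) -> str:
    if rec.answer == "pass":
        return "pass"
    if rec.group == ORIGINAL_GROUP:
        return "TP" if rec.answer == "real" else "FN"
    return "FP" if rec.answer == "real" else "TN"


def error_times(records: Iterable[DecisionRecord], group: str | None = None):
    """Mean decision time of FP and FN answers (within ``group`` if given).

    These are the ``t_FP`` / ``t_FN`` weights of the normalised error rates;
    they are means over the relevant error category, not global means.
    Categories with no observations yield NaN.
    """
    t_fp, t_fn = [], []
    for rec in records:
        if group is not None and rec.group != group:
            continue
        cat = _decision_category(rec)
        if cat == "FP":
            t_fp.append(rec.time_s)
        elif cat == "FN":
            t_fn.append(rec.time_s)
    mean = lambda xs: float(np.mean(xs)) if xs else float("nan")
    return mean(t_fp), mean(t_fn)


def decision_time_summary(
    records: Sequence[DecisionRecord],
    by: Literal["group", "decision", "group_x_decision"] = "group",
) -> pd.DataFrame:
    """Mean, sd (ddof=1) and n of decision times per requested cell."""
    df = pd.DataFrame(
        {
            "group": [r.group for r in records],
            "decision": [_decision_category(r) for r in records],
            "time_s": [r.time_s for r in records],
        }
    )
    keys = {
        "group": ["group"],
        "decision": ["decision"],
        "group_x_decision": ["group", "decision"],
    }[by]
    out = (
        df.groupby(keys)["time_s"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    return out


def votes_histogram(records: Sequence[DecisionRecord]):
    """Vote histogram and per-expert positive counts.

    Returns ``(hist, per_expert)`` where ``hist[k]`` is the number of images
    that received exactly ``k`` "real" answers (k = 0..n_experts) and
    ``per_expert`` maps expert id to its total count of "real" answers.
    Raises if any (expert, image) cell is missing.
    """
    experts = sorted({r.expert_id for r in records})
    images = sorted({r.image_id for r in records})
    seen = {(r.expert_id, r.image_id) for r in records}
    missing = [(e, i) for e in experts for i in images if (e, i) not in seen]
    if missing:
        raise ValueError(f"missing expert-image decisions: {missing[:10]}")
    positives_per_image = {i: 0 for i in images}
    per_expert = {e: 0 for e in experts}
    for r in records:
        if r.answer == "real":
            positives_per_image[r.image_id] += 1
            per_expert[r.expert_id] += 1
    hist = np.zeros(len(experts) + 1, dtype=int)
    for k in positives_per_image.values():
        hist[k] += 1
    return hist, per_expert


def percent(x: float) -> int:
    """Round a rate to whole percent, half away from zero (0.41875 -> 42)."""
    return int(math.floor(abs(x) * 100 + 0.5)) * (1 if x >= 0 else -1)


def stats_report(
    values: Mapping[str, Sequence[float]] | None = None,
    *,
    alpha: float = 0.05,
) -> dict:
    """Routed group-comparison report.

    Parameters
    ----------
    values : mapping group -> sample
        Groups with fewer than 3 observations are excluded with a warning.

    Routing: Shapiro normality per group; homoscedasticity by Bartlett when
    all groups are normal, Levene otherwise; then one-way ANOVA with a Tukey
    HSD post-hoc on the parametric branch, or Kruskal-Wallis with pairwise
    Mann-Whitney tests under Holm correction on the nonparametric branch.
    Every routing decision is logged in the returned report.
    """
    routing: list[str] = []
    groups = {}
    for name, sample in values.items():
        sample = np.asarray(sample, dtype=float)
        if len(sample) < 3:
            warnings.warn(f"group {name!r} has n < 3; excluded from the report")
            routing.append(f"excluded group {name} (n={len(sample)} < 3)")
            continue
        groups[name] = sample
    if len(groups) < 2:
        raise ValueError("need at least 2 groups with n >= 3")

    normality = {}
    for name, sample in groups.items():
        if np.ptp(sample) == 0:
            normality[name] = {"stat": float("nan"), "p": 0.0}
            routing.append(f"Shapiro {name}: constant sample, treated as non-normal")
            continue
        stat, p = stats.shapiro(sample)
        normality[name] = {"stat": float(stat), "p": float(p)}
    all_normal = all(v["p"] > alpha for v in normality.values())
    routing.append(f"normality: {'all groups pass' if all_normal else 'failed'} Shapiro at alpha={alpha}")

    samples = list(groups.values())
    if all_normal:
        hstat, hp = stats.bartlett(*samples)
        homo_test = "bartlett"
    else:
        hstat, hp = stats.levene(*samples)
        homo_test = "levene"
    homoscedastic = hp > alpha
    routing.append(f"homoscedasticity by {homo_test}: p={hp:.4g} -> {homoscedastic}")

    parametric = all_normal and homoscedastic
    if parametric:
        ostat, op = stats.f_oneway(*samples)
        if not np.isfinite(op) and ostat <= 1e-10:
            # identical groups: F underflows slightly negative, p degenerates
            ostat, op = 0.0, 1.0
        omnibus = {"test": "anova", "stat": float(ostat), "p": float(op)}
        routing.append("parametric branch: one-way ANOVA + Tukey HSD")
        flat = np.concatenate(samples)
        labels = np.concatenate([[n] * len(s) for n, s in groups.items()])
        tk = pairwise_tukeyhsd(flat, labels, alpha=alpha)
        posthoc = pd.DataFrame(
            tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
        )
    else:
        ostat, op = stats.kruskal(*samples)
        omnibus = {"test": "kruskal", "stat": float(ostat), "p": float(op)}
        routing.append("nonparametric branch: Kruskal-Wallis + Holm-corrected pairwise")
        names = list(groups)
        rows = []
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                u, p = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
                rows.append({"group1": a, "group2": b, "stat": float(u), "p_raw": float(p)})
        posthoc = pd.DataFrame(rows)
        if not posthoc.empty:
            reject, p_adj, _, _ = multipletests(posthoc["p_raw"], alpha=alpha, method="holm")
            posthoc["p_holm"] = p_adj
            posthoc["reject"] = reject

    return {
        "alpha": alpha,
        "normality": normality,
        "homoscedasticity": {"test": homo_test, "stat": float(hstat), "p": float(hp)},
        "omnibus": omnibus,
        "posthoc": posthoc,
        "parametric": parametric,
        "routing": routing,
    }
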