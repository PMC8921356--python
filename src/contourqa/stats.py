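"""Rank-based group statistics for skewed metric distributions.

Segmentation metrics are bounded and heavily skewed, so per-group
location is summarized by the median with 25th/75th quartiles, and the
metric–consensus association is tested with the Kruskal–Wallis H test
(ranks with midrank ties and the tie correction, H referred to a
chi-square with k−1 degrees of freedom).  The H statistic is implemented
from the rank formula so it is directly oracle-testable; quartiles use
linear interpolation between order statistics (type-7), the same rule as
the HD95 percentile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .consensus import ANSWER_LETTERS, ConsensusLabel
from .masks import METRIC_NAMES, MetricRecord

__all__ = [
    "GroupSummary",
    "KWResult",
    "median_iqr",
    "kruskal_wallis",
    "chi2_critical",
    "group_summaries",
]


def median_iqr(values: Sequence[float]) -> tuple:
    """(median, q25, q75) by linear interpolation between order statistics."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("median_iqr needs at least one value")
    q25, med, q75 = np.percentile(v, [25, 50, 75])
    return float(med), float(q25), float(q75)


@dataclass
class KWResult:
    """Kruskal–Wallis H test result with its chi-square reference."""

    H: float
    df: int
    p_value: float
    chi2_critical: float
    significant: bool
    all_identical: bool = False

    def to_dict(self) -> dict:
        return {
            "H": float(self.H),
            "df": int(self.df),
            "p_value": float(self.p_value),
            "chi2_critical": float(self.chi2_critical),
            "significant": bool(self.significant),
            "all_identical": bool(self.all_identical),
        }


def kruskal_wallis(groups: Sequence[Sequence[float]], alpha: float = 0.05) -> KWResult:
    """Ties-corrected Kruskal–Wallis H test across k groups.

    H = [12/(N(N+1)) · Σ nᵢ(R̄ᵢ − (N+1)/2)²] / [1 − ΣT/(N³−N)], with
    midranks for ties and T = t³ − t per tie group; p is the upper-tail
    chi-square probability at df = k − 1.  All values identical gives
    H = 0, p = 1, flagged.
    """
    if len(groups) < 2:
        raise ValueError(f"need at least 2 groups, got {len(groups)}")
    arrays = []
    for i, g in enumerate(groups):
        a = np.asarray(g, dtype=float)
        if a.size == 0:
            raise ValueError(f"group {i} is empty")
        arrays.append(a)
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    if n_total < 3:
        raise ValueError("need at least 3 observations in total")
    df = len(arrays) - 1
    crit = chi2_critical(df, alpha)
    ranks = sps.rankdata(pooled)  # midranks for ties
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(tie_counts**3 - tie_counts))
    correction = 1.0 - tie_sum / (n_total**3 - n_total)
    if correction <= 0.0:  # every value identical
        return KWResult(0.0, df, 1.0, crit, False, all_identical=True)
    grand = (n_total + 1) / 2.0
    h = 0.0
    start = 0
    for a in arrays:
        r = ranks[start : start + a.size]
        start += a.size
        h += a.size * (r.mean() - grand) ** 2
    h *= 12.0 / (n_total * (n_total + 1))
    h /= correction
    p = float(sps.chi2.sf(h, df))
    return KWResult(float(h), df, p, crit, bool(h > crit))


def chi2_critical(df: int, alpha: float = 0.05) -> float:
    """Upper critical value: the (1−alpha) quantile of chi-square(df)."""
    if not (isinstance(df, (int, np.integer)) and df >= 1):
        raise ValueError(f"df must be an integer >= 1, got {df}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return float(sps.chi2.ppf(1.0 - alpha, df))


@dataclass
class GroupSummary:
    """Median and quartiles of one metric within one consensus group."""

    group_label: str
    metric_name: str
    n: int
    median: float
    q25: float
    q75: float
    n_excluded: int = 0

    def to_dict(self) -> dict:
        return {
            "group_label": self.group_label,
            "metric_name": self.metric_name,
            "n": int(self.n),
            "median": float(self.median),
            "q25": float(self.q25),
            "q75": float(self.q75),
            "n_excluded": int(self.n_excluded),
        }


def _group_key(label: ConsensusLabel, grouping: str) -> str:
    if grouping == "four_level":
        return label.consensus_answer
    if grouping == "binary":
        return "accepted" if label.accepted else "rejected"
    raise ValueError(f"grouping must be 'four_level' or 'binary', got {grouping!r}")


def group_summaries(
    records: Sequence[MetricRecord],
    labels: Sequence[ConsensusLabel],
    grouping: str = "four_level",
) -> List[GroupSummary]:
    """Per-group, per-metric medians and quartiles.

    Records and labels are matched on slice_id.  Undefined (nan) metric
    values are excluded per group with a reported tally (``n_excluded``);
    groups with no slices produce no rows.
    """
    by_id: Dict[str, MetricRecord] = {r.slice_id: r for r in records}
    order = list(ANSWER_LETTERS) if grouping == "four_level" else ["rejected", "accepted"]
    grouped: Dict[str, List[MetricRecord]] = {g: [] for g in order}
    for lab in labels:
        rec = by_id.get(lab.slice_id)
        if rec is None:
            raise ValueError(f"no metric record for slice_id {lab.slice_id!r}")
        grouped[_group_key(lab, grouping)].append(rec)
    out: List[GroupSummary] = []
    for g in order:
        recs = grouped[g]
        if not recs:
            continue
        for m_idx, name in enumerate(METRIC_NAMES):
            vals = np.array([r.values()[m_idx] for r in recs], dtype=float)
            ok = vals[~np.isnan(vals)]
            n_excl = int(np.isnan(vals).sum())
            if ok.size == 0:
                continue
            med, q25, q75 = median_iqr(ok)
            out.append(GroupSummary(g, name, int(ok.size), med, q25, q75, n_excl))
    return out
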