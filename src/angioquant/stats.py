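"""Group summaries, pairwise significance testing and fold-change tables.

Replicate values (one field = one replicate) are summarized as mean ± SD
(sample SD, n−1 denominator) with SEM alongside.  Pairwise comparisons use
the unpaired, two-tailed Student's t-test with pooled variance
(Welch's correction available behind a flag), and significance stars follow
the conventional thresholds: * p<0.05, ** p<0.01, *** p<0.001,
**** p<0.0001.  No multiple-testing correction is applied by default; a
Holm adjustment is available for callers that want it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass
class GroupSummary:
    label: object
    n: int
    mean: float
    sd: float        # nan when n == 1
    sem: float       # nan when n == 1


@dataclass
class Comparison:
    group_a: object
    group_b: object
    t: float
    p: float
    stars: str
    df: float
    flags: dict | None = None


def star_code(p: float) -> str:
    """Map a p-value to its significance stars ('ns' when p >= 0.05)."""
    for cut, stars in STAR_THRESHOLDS:
        if p < cut:
            return stars
    return "ns"


def summarize(values, label=None) -> GroupSummary:
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty group")
    mean = float(x.mean())
    if x.size == 1:
        return GroupSummary(label, 1, mean, float("nan"), float("nan"))
    sd = float(x.std(ddof=1))
    return GroupSummary(label, int(x.size), mean, sd, sd / math.sqrt(x.size))


def compare_groups(a, b, equal_var: bool = True,
                   label_a=None, label_b=None) -> Comparison:
    """Unpaired two-tailed t-test between two replicate groups.

    Pooled-variance Student's t by default; ``equal_var=False`` switches to
    Welch.  Zero pooled variance is handled as a degenerate case: equal
    means give p = 1, unequal means p = 0 with a flag.
    """
    x = np.asarray(list(a), dtype=float)
    y = np.asarray(list(b), dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    df = x.size + y.size - 2 if equal_var else float("nan")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        if x.mean() == y.mean():
            return Comparison(label_a, label_b, 0.0, 1.0, "ns", df,
                              {"degenerate": "zero variance, equal means"})
        sign = math.copysign(1.0, x.mean() - y.mean())
        return Comparison(label_a, label_b, sign * float("inf"), 0.0, "****",
                          df, {"degenerate": "zero variance, unequal means"})
    res = sstats.ttest_ind(x, y, equal_var=equal_var)
    t, p = float(res.statistic), float(res.pvalue)
    if not equal_var:
        df = float(res.df)
    return Comparison(label_a, label_b, t, p, star_code(p), df)


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; off by default in the
    pipeline to match per-comparison starring)."""
    p = np.asarray(list(pvalues), dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def fold_change_table(groups: dict, control_label=0,
                      equal_var: bool = True) -> pd.DataFrame:
    """Per-group mean / control mean, with t-test comparisons vs control.

    ``groups`` maps label (e.g. dose in Gy) → list of replicate values; the
    control group must be present.  A zero control mean flags the fold as
    undefined (NaN).
    """
    if control_label not in groups:
        raise ValueError(f"control group {control_label!r} missing")
    control = list(groups[control_label])
    cmean = summarize(control, control_label).mean
    rows = []
    for label, values in groups.items():
        s = summarize(values, label)
        fold = s.mean / cmean if cmean != 0 else float("nan")
        if label == control_label:
            t, p, stars = 0.0, 1.0, "ns"
        else:
            comp = compare_groups(values, control, equal_var=equal_var,
                                  label_a=label, label_b=control_label)
            t, p, stars = comp.t, comp.p, comp.stars
        rows.append({"label": label, "n": s.n, "mean": s.mean, "sd": s.sd,
                     "sem": s.sem, "fold_vs_control": fold,
                     "t_vs_control": t, "p_vs_control": p, "stars": stars})
    table = pd.DataFrame(rows)
    if cmean == 0:
        table.attrs["fold_undefined"] = True
    return table
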