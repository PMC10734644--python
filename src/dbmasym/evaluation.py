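"""Registration-accuracy metrics and cross-strategy comparison.

Three metrics quantify how well a registration aligned two brains:
per-label Dice overlap, per-label absolute relative volume difference
|(|A| - |B|) / |A||, and per-landmark Euclidean distance in mm.  Strategy
pairs are compared subject-by-subject with exact Wilcoxon signed-rank
tests, mirroring the post-hoc analysis design of a registration
evaluation study.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .grid import GeometryError, LabelVolume, LandmarkSet

STRATEGIES = ("fet2neo", "fetal2template", "neonatal2template")
METRICS = ("dice", "volume_difference", "landmark_mm")


def dice_per_label(a: LabelVolume, b: LabelVolume) -> dict:
    """Dice overlap 2|A∩B| / (|A|+|B|) per non-background label.

    Labels absent from both volumes are omitted (undefined), not zero.
    """
    if a.shape != b.shape:
        raise GeometryError("label volumes must share geometry")
    out = {}
    for lbl in sorted(set(a.legend) | set(b.legend)):
        if lbl == 0:
            continue
        sa = a.labels == lbl
        sb = b.labels == lbl
        na, nb = int(sa.sum()), int(sb.sum())
        if na + nb == 0:
            continue
        out[lbl] = 2.0 * int((sa & sb).sum()) / (na + nb)
    return out


def volume_difference_per_label(a: LabelVolume, b: LabelVolume) -> dict:
    """Absolute relative volume difference |(|A| - |B|)/|A|| per label.

    The first argument is the reference ("segment image 1"); the metric is
    therefore not symmetric in its arguments.  Labels with |A| = 0 and
    |B| > 0 are reported as NaN (undefined).
    """
    if a.shape != b.shape:
        raise GeometryError("label volumes must share geometry")
    out = {}
    for lbl in sorted(set(a.legend) | set(b.legend)):
        if lbl == 0:
            continue
        na = int((a.labels == lbl).sum())
        nb = int((b.labels == lbl).sum())
        if na == 0 and nb == 0:
            continue
        out[lbl] = abs((na - nb) / na) if na > 0 else float("nan")
    return out


def landmark_error(moved: LandmarkSet, target: LandmarkSet) -> dict:
    """Per-landmark Euclidean distance in mm between name-matched points.

    Names present in only one set map to NaN.  The per-subject mean over
    defined distances is available via :func:`mean_landmark_error`.
    """
    out = {}
    for name in target.names:
        if name in moved.names:
            out[name] = float(np.linalg.norm(moved[name] - target[name]))
        else:
            out[name] = float("nan")
    for name in moved.names:
        if name not in target.names:
            out[name] = float("nan")
    return out


def mean_landmark_error(moved: LandmarkSet, target: LandmarkSet) -> float:
    errs = [v for v in landmark_error(moved, target).values()
            if np.isfinite(v)]
    return float(np.mean(errs)) if errs else float("nan")


def accuracy_table(records) -> pd.DataFrame:
    """Long-format AccuracyTable: one row per (subject, strategy, metric,
    label-or-landmark, value)."""
    df = pd.DataFrame(records,
                      columns=["subject_id", "strategy", "metric",
                               "label_or_landmark", "value"])
    bad = df[(df.metric == "dice") & ((df.value < 0) | (df.value > 1))]
    if len(bad):
        raise ValueError("dice outside [0, 1]")
    return df


def compare_strategies(table: pd.DataFrame, holm: bool = False) -> pd.DataFrame:
    """Pairwise Wilcoxon signed-rank tests on per-subject mean metrics.

    For each metric and each pair of strategies, the per-subject means are
    compared with a two-sided Wilcoxon signed-rank test (exact null
    distribution for n <= 25, zero differences dropped).  All-zero
    differences yield p = 1 with a ``degenerate`` flag.  ``holm`` adds a
    Holm-adjusted column across the comparisons of each metric.
    """
    means = (table.dropna(subset=["value"])
             .groupby(["subject_id", "strategy", "metric"])["value"]
             .mean().reset_index())
    rows = []
    for metric in means.metric.unique():
        sub = means[means.metric == metric].pivot(
            index="subject_id", columns="strategy", values="value")
        for s1, s2 in combinations(sorted(sub.columns), 2):
            paired = sub[[s1, s2]].dropna()
            x, y = paired[s1].to_numpy(), paired[s2].to_numpy()
            if len(x) < 2:
                continue
            degenerate = bool(np.all(x == y))
            if degenerate:
                p = 1.0
            else:
                method = "exact" if len(x) <= 25 else "approx"
                p = float(stats.wilcoxon(x, y, zero_method="wilcox",
                                         method=method).pvalue)
            rows.append({"metric": metric, "strategy_a": s1,
                         "strategy_b": s2, "n": len(x), "p_value": p,
                         "degenerate": degenerate})
    df = pd.DataFrame(rows)
    if holm and len(df):
        adj = []
        for metric, grp in df.groupby("metric"):
            p = grp.p_value.to_numpy()
            order = np.argsort(p)
            m = len(p)
            stepped = np.empty(m)
            running = 0.0
            for rank, i in enumerate(order):
                running = max(running, (m - rank) * p[i])
                stepped[i] = min(1.0, running)
            adj.append(pd.Series(stepped, index=grp.index))
        df["p_holm"] = pd.concat(adj).sort_index()
    return df
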