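"""Structural characterization: length and exon-number summaries per
transcript group, and two-group t statistics (Welch by default).

The same operations serve lncRNAs and mRNAs; the group is whatever
transcript set the caller passes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .iolib import TranscriptModel


@dataclass
class GroupStats:
    label: str
    n: int
    median_length: float
    mean_exon_count: float
    single_exon_pct: float
    length_hist: tuple[np.ndarray, np.ndarray]  # (counts, bin edges)


@dataclass
class Comparison:
    group_a: str
    group_b: str
    t: float
    df: float
    p: float
    significant: str  # 'n.s.', '*', '**'


def summarize_group(
    transcripts: Sequence[TranscriptModel],
    label: str = "",
    bins: int | Sequence[float] = 20,
) -> GroupStats:
    """Median spliced length, mean exon count and single-exon fraction."""
    if not transcripts:
        raise ValueError("cannot summarize an empty transcript set")
    lengths = np.array([t.length for t in transcripts], dtype=float)
    exons = np.array([t.exon_count for t in transcripts], dtype=float)
    counts, edges = np.histogram(lengths, bins=bins)
    return GroupStats(
        label=label,
        n=len(transcripts),
        median_length=float(np.median(lengths)),
        mean_exon_count=float(exons.mean()),
        single_exon_pct=100.0 * float((exons == 1).mean()),
        length_hist=(counts, edges),
    )


def _mark(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    label_a: str = "A",
    label_b: str = "B",
    welch: bool = True,
) -> Comparison:
    """Two-sided t test between two value vectors.

    Welch's unequal-variance form is the default; ``welch=False`` gives the
    pooled-variance Student form.  Two identical constant groups return
    t = 0, p = 1 rather than an error.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return Comparison(label_a, label_b, 0.0, a.size + b.size - 2.0,
                              1.0, "n.s.")
        return Comparison(label_a, label_b, np.inf if a.mean() > b.mean()
                          else -np.inf, a.size + b.size - 2.0, 0.0, "**")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = float(getattr(res, "df", a.size + b.size - 2))
    p = float(res.pvalue)
    return Comparison(label_a, label_b, float(res.statistic), df, p, _mark(p))


def stats_to_frame(groups: Sequence[GroupStats]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "group": g.label, "n": g.n,
            "median_length": g.median_length,
            "mean_exon_count": round(g.mean_exon_count, 4),
            "single_exon_pct": round(g.single_exon_pct, 2),
        }
        for g in groups
    ])


def histogram_frame(g: GroupStats) -> pd.DataFrame:
    counts, edges = g.length_hist
    return pd.DataFrame({
        "bin_left": edges[:-1], "bin_right": edges[1:], "count": counts,
    })
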