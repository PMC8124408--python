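"""Mutant-vs-wild-type trait statistics and summary-table rendering.

Each mutant trait sample is compared against its wild type by a two-sided
pooled-variance Student's t test (Welch behind a flag); the summary cell
reads ``mean ± SD`` with a significance mark (* p<0.05, ** p<0.01, n.s.
otherwise) and a direction arrow when significant.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class TraitSample:
    line: str
    trait: str
    unit: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class TraitSummary:
    line: str
    trait: str
    unit: str
    mean: float
    sd: float
    n: int
    t: float
    p: float
    mark: str   # 'n.s.', '*', '**'
    arrow: str  # '↑', '↓' or ''


def _mark(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def compare_trait(
    wildtype: TraitSample,
    mutant: TraitSample,
    welch: bool = False,
) -> TraitSummary:
    """Student's t comparison of a mutant line against its wild type.

    Mismatched trait names are a hard error; both samples need n >= 2.
    The arrow reflects the sign of (mutant mean − wild-type mean) and is
    shown only for significant comparisons.
    """
    if wildtype.trait != mutant.trait:
        raise ValueError(
            f"trait mismatch: {wildtype.trait!r} vs {mutant.trait!r}"
        )
    if wildtype.n < 2 or mutant.n < 2:
        raise ValueError("both samples need n >= 2")
    a, b = wildtype.values, mutant.values
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        t, p = 0.0, 1.0
    else:
        res = stats.ttest_ind(b, a, equal_var=not welch)
        t, p = float(res.statistic), float(res.pvalue)
    mark = _mark(p)
    diff = float(mutant.values.mean() - wildtype.values.mean())
    arrow = "" if mark == "n.s." else ("↑" if diff > 0 else "↓")
    return TraitSummary(
        line=mutant.line, trait=mutant.trait, unit=mutant.unit,
        mean=float(mutant.values.mean()), sd=float(mutant.values.std(ddof=1)),
        n=mutant.n, t=t, p=p, mark=mark, arrow=arrow,
    )


def summarize_wildtype(sample: TraitSample) -> TraitSummary:
    """Plain mean ± SD summary for a wild-type column (no test)."""
    return TraitSummary(
        line=sample.line, trait=sample.trait, unit=sample.unit,
        mean=float(sample.values.mean()),
        sd=float(sample.values.std(ddof=1)),
        n=sample.n, t=np.nan, p=np.nan, mark="", arrow="",
    )


def format_cell(s: TraitSummary) -> str:
    """``mean ± SD(mark arrow)``, e.g. ``51.38 ± 3.87(**↓)`` or
    ``16.62 ± 2.04(n.s.)``; wild-type cells carry no suffix."""
    base = f"{s.mean:.2f} ± {s.sd:.2f}"
    if not s.mark:
        return base
    return f"{base}({s.mark}{s.arrow})"


_CELL_RE = re.compile(
    r"^(?P<mean>-?\d+(?:\.\d+)?) ± (?P<sd>\d+(?:\.\d+)?)"
    r"(?:\((?P<mark>n\.s\.|\*{1,2})(?P<arrow>[↑↓]?)\))?$"
)


def parse_cell(cell: str) -> tuple[float, float, str, str]:
    """Inverse of :func:`format_cell` (round-trip check helper)."""
    m = _CELL_RE.match(cell)
    if m is None:
        raise ValueError(f"unparseable trait cell {cell!r}")
    return (float(m["mean"]), float(m["sd"]), m["mark"] or "", m["arrow"] or "")


def render_table(summaries: Iterable[TraitSummary]) -> pd.DataFrame:
    """Summary table: one row per line, one column per trait."""
    rows: dict[str, dict[str, str]] = {}
    trait_order: list[str] = []
    for s in summaries:
        rows.setdefault(s.line, {})[s.trait] = format_cell(s)
        if s.trait not in trait_order:
            trait_order.append(s.trait)
    df = pd.DataFrame.from_dict(rows, orient="index")
    if not df.empty:
        df = df.reindex(columns=trait_order)
    else:
        df = pd.DataFrame(columns=trait_order)
    df.index.name = "line"
    return df.reset_index()


def samples_from_table(df: pd.DataFrame) -> dict[tuple[str, str], TraitSample]:
    """Group a long-format trait table (line, trait, unit, value) into
    :class:`TraitSample` objects keyed by (line, trait)."""
    out = {}
    for (line, trait), grp in df.groupby(["line", "trait"], sort=False):
        unit = str(grp["unit"].iloc[0]) if "unit" in grp else ""
        out[(line, trait)] = TraitSample(line, trait, unit,
                                         grp["value"].to_numpy())
    return out


def mutant_table(
    df: pd.DataFrame,
    wildtype_of: dict[str, str] | None = None,
    welch: bool = False,
) -> pd.DataFrame:
    """End-to-end: long trait table → rendered summary table.

    ``wildtype_of`` maps mutant line → wild-type line; defaults to the
    table's own ``wildtype`` column.
    """
    samples = samples_from_table(df)
    if wildtype_of is None:
        wildtype_of = {
            str(line): str(wt)
            for line, wt in df[df.get("wildtype", "").astype(bool)][
                ["line", "wildtype"]].drop_duplicates().to_numpy()
        } if "wildtype" in df else {}
    summaries: list[TraitSummary] = []
    for (line, trait), sample in samples.items():
        wt_line = wildtype_of.get(line)
        if wt_line is None:
            summaries.append(summarize_wildtype(sample))
        else:
            wt = samples.get((wt_line, trait))
            if wt is None:
                raise KeyError(f"no wild-type sample for {line}/{trait}")
            summaries.append(compare_trait(wt, sample, welch=welch))
    return render_table(summaries)
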