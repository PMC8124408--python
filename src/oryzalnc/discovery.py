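"""lncRNA identification cascade and known/novel classification.

Candidates pass four gates, applied in a fixed order: (1) not annotated
protein-coding, (2) spliced length strictly above 200 nt, (3) maximum FPKM
across the transcript's samples at or above 0.1, (4) both coding-potential
scores strictly below 0.  The retained *set* is order-independent; the
order only determines which gate an audit records as the first failure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .iolib import CODING, TranscriptModel

logger = logging.getLogger("oryzalnc")


@dataclass(frozen=True)
class FilterThresholds:
    """Gate thresholds.  ``min_length`` = 201 encodes "longer than 200 nt";
    ``max_coding_score`` is an exclusive ceiling applied to every scorer."""

    min_length: int = 201
    min_fpkm: float = 0.1
    max_coding_score: float = 0.0

    def __post_init__(self) -> None:
        if self.min_length < 1 or self.min_fpkm < 0:
            raise ValueError("invalid thresholds")


GATE_ORDER = ("biotype", "length", "expression", "coding_potential")


@dataclass
class FilterAudit:
    """Per-candidate verdict with the value seen at each gate."""

    transcript_id: str
    retained: bool
    first_failed_filter: str  # 'none' or one of GATE_ORDER
    length: int
    max_fpkm: float
    scores: tuple[float, ...]
    biotype: str


def filter_lncrnas(
    candidates: Sequence[TranscriptModel],
    fpkm: pd.DataFrame,
    scores: pd.DataFrame,
    thresholds: FilterThresholds | None = None,
) -> tuple[list[TranscriptModel], list[FilterAudit]]:
    """Run the identification cascade.

    ``fpkm``: transcript_id-indexed (or with a transcript_id column) frame
    of per-sample FPKM.  ``scores``: same indexing, one column per scorer.
    A candidate missing either row is a hard error naming the id.
    """
    th = thresholds or FilterThresholds()
    fpkm = _indexed(fpkm)
    scores = _indexed(scores)
    retained: list[TranscriptModel] = []
    audits: list[FilterAudit] = []
    for t in candidates:
        if t.id not in fpkm.index:
            raise KeyError(f"candidate {t.id} has no expression row")
        if t.id not in scores.index:
            raise KeyError(f"candidate {t.id} has no coding-score row")
        max_fpkm = float(fpkm.loc[t.id].max())
        score_vals = tuple(float(v) for v in scores.loc[t.id])
        failed = "none"
        if t.biotype == CODING:
            failed = "biotype"
        elif t.length < th.min_length:
            failed = "length"
        elif max_fpkm < th.min_fpkm:
            failed = "expression"
        elif not all(s < th.max_coding_score for s in score_vals):
            failed = "coding_potential"
        ok = failed == "none"
        if ok:
            retained.append(t)
        audits.append(FilterAudit(t.id, ok, failed, t.length, max_fpkm,
                                  score_vals, t.biotype))
    return retained, audits


def _indexed(df: pd.DataFrame) -> pd.DataFrame:
    if "transcript_id" in df.columns:
        df = df.set_index("transcript_id")
    return df.select_dtypes("number")


# ---------------------------------------------------------------------------
# known / novel
# ---------------------------------------------------------------------------

def classify_known(
    lncrnas: Sequence[TranscriptModel],
    reference: Sequence[TranscriptModel] | None,
    min_overlap: int = 1,
) -> dict[str, bool]:
    """Mark a lncRNA *known* when it shares >= ``min_overlap`` exonic nt,
    same strand, with any reference lncRNA transcript.

    With no reference annotation every lncRNA is novel.  A reference on a
    disjoint chromosome namespace yields a warning and all-novel calls.
    """
    if not reference:
        return {t.id: False for t in lncrnas}
    ref_chroms = {t.chrom for t in reference}
    if lncrnas and not ({t.chrom for t in lncrnas} & ref_chroms):
        logger.warning("reference annotation shares no chromosome names; "
                       "classifying all lncRNAs as novel")
        return {t.id: False for t in lncrnas}
    trees: dict[tuple[str, str], IntervalTree] = {}
    for rt in reference:
        for e in rt.exons:
            trees.setdefault((e.chrom, e.strand), IntervalTree()).addi(
                e.start, e.end + 1
            )
    result = {}
    for t in lncrnas:
        overlap = 0
        tree = trees.get((t.chrom, t.strand))
        if tree is not None:
            for e in t.exons:
                for iv in tree.overlap(e.start, e.end + 1):
                    overlap += min(e.end + 1, iv.end) - max(e.start, iv.begin)
                    if overlap >= min_overlap:
                        break
                if overlap >= min_overlap:
                    break
        result[t.id] = overlap >= min_overlap
    return result


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def percent(part: int, whole: int) -> float:
    """100*part/whole, two decimals, half-up (matches printed percentages)."""
    if whole == 0:
        return 0.0
    frac = Decimal(part) * 100 / Decimal(whole)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def summarize_discovery(
    retained: Mapping[str, Sequence[TranscriptModel]],
    known_flags: Mapping[str, Mapping[str, bool]],
) -> pd.DataFrame:
    """Per-genome counts of retained/known/novel lncRNAs with percentages."""
    rows = []
    for genome, txs in retained.items():
        flags = known_flags.get(genome, {})
        n = len(txs)
        n_known = sum(1 for t in txs if flags.get(t.id, False))
        rows.append({
            "genome": genome,
            "n_lncrna": n,
            "n_known": n_known,
            "n_novel": n - n_known,
            "pct_known": percent(n_known, n),
        })
    return pd.DataFrame(rows)


def audits_to_frame(audits: Iterable[FilterAudit]) -> pd.DataFrame:
    rows = []
    for a in audits:
        row = {
            "transcript_id": a.transcript_id,
            "verdict": "retained" if a.retained else "rejected",
            "first_failed_filter": a.first_failed_filter,
            "biotype": a.biotype,
            "length": a.length,
            "max_fpkm": a.max_fpkm,
        }
        for i, s in enumerate(a.scores, 1):
            row[f"score_{i}"] = s
        rows.append(row)
    return pd.DataFrame(rows)
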