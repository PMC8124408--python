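"""Positional-conservation calling from flanking-gene collinearity.

For each lncRNA the context is its 5 nearest protein-coding genes (by
genomic midpoint distance).  A cross-genome lncRNA pair is positionally
conserved when at least 4 of the 5 context genes are "close" in the
partner genome: the gene's ortholog lies inside the partner lncRNA's own
context, or within a configurable number of coding-gene ranks of the
partner lncRNA on the same chromosome.  Triples are pairs conserved along
all three pairwise comparisons.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .iolib import CODING, TranscriptModel
from .homology import AlignParams, local_align

logger = logging.getLogger("oryzalnc")


@dataclass
class FlankContext:
    """The 5 nearest coding genes around one lncRNA."""

    lncrna_id: str
    genome: str
    chrom: str
    midpoint: float
    genes: list[str]            # ordered by distance, nearest first
    sides: list[str]            # 'upstream' / 'downstream' per gene
    distances: list[float]
    complete: bool = True


@dataclass
class PositionalCall:
    lncrna_a: str
    lncrna_b: str
    close_count: int
    conserved: bool


def flank_context(
    lncrna: TranscriptModel,
    coding_genes: Sequence[TranscriptModel],
    n_flank: int = 5,
) -> FlankContext:
    """Nearest ``n_flank`` coding genes by |midpoint distance|.

    Distance ties break toward the lower start coordinate.  Contexts with
    fewer than ``n_flank`` genes on the chromosome are marked incomplete
    and excluded from calling.
    """
    mid = lncrna.midpoint
    same_chrom = [g for g in coding_genes if g.chrom == lncrna.chrom]
    ranked = sorted(same_chrom, key=lambda g: (abs(g.midpoint - mid), g.start))
    chosen = ranked[:n_flank]
    complete = len(chosen) == n_flank
    if not complete:
        logger.warning("lncRNA %s: only %d coding genes on %s; context incomplete",
                       lncrna.id, len(chosen), lncrna.chrom)
    return FlankContext(
        lncrna_id=lncrna.id,
        genome=str(lncrna.genome),
        chrom=lncrna.chrom,
        midpoint=mid,
        genes=[g.id for g in chosen],
        sides=["upstream" if g.midpoint < mid else "downstream" for g in chosen],
        distances=[abs(g.midpoint - mid) for g in chosen],
        complete=complete,
    )


def contexts_for(
    lncrnas: Iterable[TranscriptModel],
    annotation: Sequence[TranscriptModel],
    n_flank: int = 5,
) -> dict[str, FlankContext]:
    """Complete contexts for every lncRNA in one genome (incomplete ones
    are dropped)."""
    coding = [t for t in annotation if t.biotype == CODING]
    out = {}
    for t in lncrnas:
        ctx = flank_context(t, coding, n_flank)
        if ctx.complete:
            out[t.id] = ctx
    return out


# ---------------------------------------------------------------------------
# orthology
# ---------------------------------------------------------------------------

def rbh_orthologs(
    seqs_a: Mapping[str, str],
    seqs_b: Mapping[str, str],
    params: AlignParams | None = None,
) -> pd.DataFrame:
    """Reciprocal-best-hit ortholog pairs under local-alignment score.

    A gene with two equally scoring best partners is ambiguous and
    excluded (logged).  Columns: gene_a, gene_b, score.
    """
    if not seqs_a or not seqs_b:
        raise ValueError("both gene sets must be nonempty")
    params = params or AlignParams()
    scores: dict[tuple[str, str], float] = {}
    for ga, sa in seqs_a.items():
        for gb, sb in seqs_b.items():
            seg = local_align(sa, sb, params)
            scores[(ga, gb)] = seg.score if seg else 0.0

    def best(keys: Sequence[str], other: Sequence[str], flip: bool):
        result = {}
        for k in keys:
            ranked = sorted(
                other,
                key=lambda o: scores[(o, k)] if flip else scores[(k, o)],
                reverse=True,
            )
            if not ranked:
                continue
            top = scores[(ranked[0], k)] if flip else scores[(k, ranked[0])]
            if top <= 0:
                continue
            second = (
                scores[(ranked[1], k)] if flip else scores[(k, ranked[1])]
            ) if len(ranked) > 1 else None
            if second is not None and second == top:
                logger.warning("ambiguous best hit for %s (tied score %.1f); excluded",
                               k, top)
                continue
            result[k] = ranked[0]
        return result

    best_ab = best(list(seqs_a), list(seqs_b), flip=False)
    best_ba = best(list(seqs_b), list(seqs_a), flip=True)
    rows = [
        {"gene_a": ga, "gene_b": gb, "score": scores[(ga, gb)]}
        for ga, gb in best_ab.items()
        if best_ba.get(gb) == ga
    ]
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"])


def ortholog_map(pairs: pd.DataFrame, a_col: str = "gene_a",
                 b_col: str = "gene_b") -> dict[str, str]:
    return dict(zip(pairs[a_col], pairs[b_col]))


# ---------------------------------------------------------------------------
# positional calls
# ---------------------------------------------------------------------------

class _GeneRanks:
    """Coding-gene rank coordinates per chromosome of one genome."""

    def __init__(self, annotation: Sequence[TranscriptModel]):
        self.by_chrom: dict[str, list[tuple[float, str]]] = {}
        self.rank: dict[str, tuple[str, int]] = {}
        for t in annotation:
            if t.biotype == CODING:
                self.by_chrom.setdefault(t.chrom, []).append((t.midpoint, t.id))
        for chrom, genes in self.by_chrom.items():
            genes.sort()
            for r, (_, gid) in enumerate(genes):
                self.rank[gid] = (chrom, r)

    def rank_of_position(self, chrom: str, midpoint: float) -> int | None:
        genes = self.by_chrom.get(chrom)
        if not genes:
            return None
        return bisect.bisect_left(genes, (midpoint, ""))


def call_positional(
    contexts_a: Mapping[str, FlankContext],
    contexts_b: Mapping[str, FlankContext],
    orthologs: Mapping[str, str],
    annotation_b: Sequence[TranscriptModel],
    window: int = 10,
    min_close: int = 4,
    candidate_pairs: Iterable[tuple[str, str]] | None = None,
) -> list[PositionalCall]:
    """Evaluate lncRNA pairs a→b with the 4-of-5 collinearity rule.

    A context gene is *close* when its ortholog is inside the partner's
    context, or lies within ``window`` coding-gene ranks of the partner
    lncRNA on the partner's chromosome.  Missing orthologs count as
    not-close.  All a x b pairs are evaluated unless ``candidate_pairs``
    restricts them; only pairs with close_count >= 1 are returned.
    """
    ranks = _GeneRanks(annotation_b)
    b_items = list(contexts_b.items())
    calls: list[PositionalCall] = []
    if candidate_pairs is None:
        pair_iter = (
            (aid, bid) for aid in contexts_a for bid, _ in b_items
        )
    else:
        pair_iter = iter(candidate_pairs)
    for aid, bid in pair_iter:
        ctx_a = contexts_a.get(aid)
        ctx_b = contexts_b.get(bid)
        if ctx_a is None or ctx_b is None:
            continue
        b_genes = set(ctx_b.genes)
        b_rank = ranks.rank_of_position(ctx_b.chrom, ctx_b.midpoint)
        close = 0
        for gene in ctx_a.genes:
            ortho = orthologs.get(gene)
            if ortho is None:
                continue
            if ortho in b_genes:
                close += 1
                continue
            loc = ranks.rank.get(ortho)
            if loc is None or b_rank is None:
                continue
            chrom, r = loc
            if chrom == ctx_b.chrom and abs(r - b_rank) <= window:
                close += 1
        if close >= 1:
            calls.append(PositionalCall(aid, bid, close, close >= min_close))
    return calls


def conserved_pairs(calls: Iterable[PositionalCall]) -> set[tuple[str, str]]:
    return {(c.lncrna_a, c.lncrna_b) for c in calls if c.conserved}


def intersect_triples(
    calls_wa: Iterable[PositionalCall],
    calls_wb: Iterable[PositionalCall],
    calls_ab: Iterable[PositionalCall],
) -> list[tuple[str, str, str]]:
    """Triples (w, a, b) conserved along all three pairwise comparisons."""
    wa = conserved_pairs(calls_wa)
    wb = conserved_pairs(calls_wb)
    ab = conserved_pairs(calls_ab)
    a_of_w: dict[str, list[str]] = {}
    for w, a in wa:
        a_of_w.setdefault(w, []).append(a)
    b_of_w: dict[str, list[str]] = {}
    for w, b in wb:
        b_of_w.setdefault(w, []).append(b)
    triples = []
    for w in sorted(set(a_of_w) & set(b_of_w)):
        for a in a_of_w[w]:
            for b in b_of_w[w]:
                if (a, b) in ab:
                    triples.append((w, a, b))
    return sorted(set(triples))


def calls_to_frame(calls: Iterable[PositionalCall], window: int,
                   min_close: int) -> pd.DataFrame:
    df = pd.DataFrame([
        {"lncrna_a": c.lncrna_a, "lncrna_b": c.lncrna_b,
         "close_count": c.close_count, "conserved": c.conserved}
        for c in calls
    ], columns=["lncrna_a", "lncrna_b", "close_count", "conserved"])
    df.attrs["window"] = window
    df.attrs["min_close"] = min_close
    return df
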