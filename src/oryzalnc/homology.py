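"""Sequence-conservation screen between lncRNA sets.

The screen replaces a BLAST search with exact Smith–Waterman local alignment
(affine gaps, both strands), then applies the strict conservation filter:
aligned segment longer than 100 columns AND percent identity above 90.
Cross-genome links are assembled into conserved families as connected
components of the undirected link graph; families with a member in every
genome are the sequence-conserved set, and families with many copies in one
genome are flagged as transposable-element-like.

Scoring convention: match +1, mismatch −2, a gap of length L costs
``gap_open + L * gap_extend`` (defaults 4 + L).  ``N`` is never an identity
and scores as a mismatch against every base, including ``N`` itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq


_ALPHABET = "ACGTN"


@dataclass(frozen=True)
class AlignParams:
    """Alignment scoring and screening thresholds.

    ``min_segment_length`` and ``min_identity`` are strict lower bounds:
    a segment passes only with aligned_length > 100 and identity > 90%.
    """

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -4.0
    gap_extend: float = -1.0
    min_segment_length: int = 100
    min_identity: float = 90.0
    both_strands: bool = True
    seed_kmer: int = 11  # 0 disables k-mer prefiltering in screens

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 100):
            raise ValueError("min_identity must be in (0, 100]")


@dataclass
class HomologySegment:
    """One local-alignment hit between two transcript sequences.

    Coordinates are 1-based inclusive on the forward transcript sequences;
    reverse-strand hits carry ``strand='-'`` with subject coordinates mapped
    back to the forward strand.  ``identity_pct`` uses the BLAST-style
    denominator (all alignment columns, gaps included).
    """

    query_id: str = ""
    query_genome: str = ""
    subject_id: str = ""
    subject_genome: str = ""
    query_start: int = 0
    query_end: int = 0
    subject_start: int = 0
    subject_end: int = 0
    strand: str = "+"
    aligned_length: int = 0
    identities: int = 0
    score: float = 0.0

    @property
    def identity_pct(self) -> float:
        if self.aligned_length == 0:
            return 0.0
        return 100.0 * self.identities / self.aligned_length


def _make_aligner(params: AlignParams) -> Align.PairwiseAligner:
    matrix = np.full((5, 5), params.mismatch)
    for i in range(4):  # N (index 4) mismatches everything, itself included
        matrix[i, i] = params.match
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.Array(_ALPHABET, 2, matrix)
    # Biopython charges open_gap_score for the first gap column; fold one
    # extension step into it so a gap of length L costs gap_open + L*extend.
    aligner.open_gap_score = params.gap_open + params.gap_extend
    aligner.extend_gap_score = params.gap_extend
    return aligner


_ALIGNER_CACHE: dict[AlignParams, Align.PairwiseAligner] = {}


def _aligner_for(params: AlignParams) -> Align.PairwiseAligner:
    if params not in _ALIGNER_CACHE:
        _ALIGNER_CACHE[params] = _make_aligner(params)
    return _ALIGNER_CACHE[params]


def _clean(seq: str) -> str:
    return "".join(c if c in _ALPHABET else "N" for c in seq.upper())


def _segment_from_alignment(aln, a: str, b: str) -> tuple[int, int, int, int, int, int]:
    """Column count, identity count and 1-based endpoints of one alignment."""
    qblocks, sblocks = aln.aligned
    columns = 0
    identities = 0
    prev_q = prev_s = None
    for (qs, qe), (ss, se) in zip(qblocks, sblocks):
        if prev_q is not None:  # gap columns between consecutive blocks
            columns += (qs - prev_q) + (ss - prev_s)
        for i, j in zip(range(qs, qe), range(ss, se)):
            columns += 1
            if a[i] == b[j] and a[i] != "N":
                identities += 1
        prev_q, prev_s = qe, se
    q_start = int(qblocks[0][0]) + 1
    q_end = int(qblocks[-1][1])
    s_start = int(sblocks[0][0]) + 1
    s_end = int(sblocks[-1][1])
    return columns, identities, q_start, q_end, s_start, s_end


def local_align(
    a: str,
    b: str,
    params: AlignParams | None = None,
    min_score: float | None = None,
) -> HomologySegment | None:
    """Best local alignment of ``a`` (query) against ``b`` (subject).

    Both strands of the subject are searched when enabled; the higher score
    wins, forward preferred on ties.  Returns ``None`` when either sequence
    is empty, no positive-scoring alignment exists, or the optimal score
    falls below ``min_score`` (traceback is skipped in that case).
    """
    params = params or AlignParams()
    if not a or not b:
        return None
    a, b = _clean(a), _clean(b)
    aligner = _aligner_for(params)
    candidates: list[tuple[float, str, str]] = []
    fwd = aligner.score(a, b)
    if fwd > 0:
        candidates.append((fwd, "+", b))
    if params.both_strands:
        rc = str(Seq(b).reverse_complement())
        rev = aligner.score(a, rc)
        if rev > 0 and rev > fwd:
            candidates = [(rev, "-", rc)]
    if not candidates:
        return None
    score, strand, subject = max(candidates, key=lambda c: c[0])
    if min_score is not None and score < min_score:
        return None
    aln = aligner.align(a, subject)[0]
    columns, idents, qs, qe, ss, se = _segment_from_alignment(aln, a, subject)
    if strand == "-":  # map subject coordinates back to the forward strand
        ss, se = len(b) - se + 1, len(b) - ss + 1
    return HomologySegment(
        query_start=qs, query_end=qe, subject_start=ss, subject_end=se,
        strand=strand, aligned_length=columns, identities=idents, score=score,
    )


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

def _kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if "N" not in km:
            out.setdefault(km, []).append(i)
    return out


_DIAG_BAND = 50  # diagonal bucket width for seed clustering (nt)


class _SeedIndex:
    """Exact k-mer index over the subject set, both strands.

    A query/subject pair becomes an alignment candidate when at least
    ``min_seeds`` shared k-mers fall into one diagonal band on either
    strand — cheap evidence of a contiguous homologous stretch.
    """

    def __init__(self, subjects: Mapping[str, str], k: int, both_strands: bool):
        self.k = k
        self.index: dict[str, list[tuple[str, str, int]]] = {}
        for sid, seq in subjects.items():
            seq = _clean(seq)
            strands = [("+", seq)]
            if both_strands:
                strands.append(("-", str(Seq(seq).reverse_complement())))
            for strand, s in strands:
                for km, positions in _kmer_positions(s, k).items():
                    bucket = self.index.setdefault(km, [])
                    for p in positions:
                        bucket.append((sid, strand, p))

    def candidates(self, query: str, min_seeds: int) -> set[str]:
        hits: dict[tuple[str, str, int], int] = {}
        for km, qpos_list in _kmer_positions(_clean(query), self.k).items():
            entries = self.index.get(km)
            if not entries:
                continue
            for qp in qpos_list:
                for sid, strand, sp in entries:
                    band = (qp - sp) // _DIAG_BAND
                    hits[(sid, strand, band)] = hits.get((sid, strand, band), 0) + 1
        out = set()
        for (sid, strand, band), n in hits.items():
            if n >= min_seeds or n + hits.get((sid, strand, band + 1), 0) >= min_seeds:
                out.add(sid)
        return out


def _passes(seg: HomologySegment, params: AlignParams) -> bool:
    return (
        seg.aligned_length > params.min_segment_length
        and seg.identity_pct > params.min_identity
    )


def screen_homologs(
    set_a: Mapping[str, str],
    set_b: Mapping[str, str],
    params: AlignParams | None = None,
    genome_a: str = "A",
    genome_b: str = "B",
) -> list[HomologySegment]:
    """All-vs-all screen of two lncRNA sequence sets.

    Pairs are prefiltered by a shared exact k-mer (either strand) before
    alignment; segments are kept only when strictly longer than
    ``min_segment_length`` columns and strictly above ``min_identity``.
    """
    params = params or AlignParams()
    if not set_a or not set_b:
        raise ValueError("both sequence sets must be nonempty")
    # any passing segment scores at least this much, so weaker optima can
    # skip traceback entirely (gap columns only lower the bound further)
    frac = params.min_identity / 100.0
    floor = params.min_segment_length * (
        frac * params.match + (1.0 - frac) * params.mismatch
    )
    k = params.seed_kmer
    seed_index = _SeedIndex(set_b, k, params.both_strands) if k else None
    hits: list[HomologySegment] = []
    for aid, aseq in set_a.items():
        if seed_index is not None:
            partners = seed_index.candidates(aseq, min_seeds=2)
        else:
            partners = set(set_b)
        for bid in sorted(partners):
            seg = local_align(aseq, set_b[bid], params, min_score=floor)
            if seg is None or not _passes(seg, params):
                continue
            seg.query_id, seg.query_genome = aid, genome_a
            seg.subject_id, seg.subject_genome = bid, genome_b
            hits.append(seg)
    return hits


# ---------------------------------------------------------------------------
# conserved families
# ---------------------------------------------------------------------------

@dataclass
class ConservedFamily:
    """Connected group of transcripts linked by passing homology segments."""

    family_id: str
    members: dict[str, list[str]]  # genome → transcript ids
    segments: list[HomologySegment] = field(default_factory=list)
    te_like: bool = False

    @property
    def copy_profile(self) -> dict[str, int]:
        return {g: len(ids) for g, ids in self.members.items()}

    @property
    def size(self) -> int:
        return sum(len(ids) for ids in self.members.values())

    def is_three_way(self, genomes: Sequence[str]) -> bool:
        return all(self.members.get(g) for g in genomes)


def build_families(
    segments: Iterable[HomologySegment],
    genomes: Sequence[str],
) -> list[ConservedFamily]:
    """Group linked transcripts into families (graph connected components).

    Families are ordered by size (largest first), then lexicographically,
    and numbered ``FAM0001`` onward.
    """
    graph = nx.Graph()
    segs = list(segments)
    for seg in segs:
        graph.add_edge(
            (seg.query_genome, seg.query_id), (seg.subject_genome, seg.subject_id)
        )
    components = [sorted(c) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: (-len(c), c))
    families = []
    for i, comp in enumerate(components, 1):
        members: dict[str, list[str]] = {g: [] for g in genomes}
        node_set = set(comp)
        for genome, tid in comp:
            members.setdefault(genome, []).append(tid)
        fam_segs = [
            s for s in segs
            if (s.query_genome, s.query_id) in node_set
        ]
        families.append(ConservedFamily(f"FAM{i:04d}", members, fam_segs))
    return families


def conserved_families(
    families: Iterable[ConservedFamily], genomes: Sequence[str]
) -> list[ConservedFamily]:
    """Keep only families represented in every genome (the three-way rule)."""
    return [f for f in families if f.is_three_way(genomes)]


def flag_multicopy(
    families: Iterable[ConservedFamily],
    threshold: int = 5,
    wild: str | None = None,
) -> list[dict[str, object]]:
    """Flag TE-like families: any genome holding >= ``threshold`` copies.

    Returns one report row per family with the flag and, when a wild genome
    is named, the wild→cultivar contraction ratio (wild copies over the mean
    copy count of the other genomes).
    """
    report = []
    for fam in families:
        profile = fam.copy_profile
        flagged = any(n >= threshold for n in profile.values())
        fam.te_like = flagged
        row: dict[str, object] = {
            "family_id": fam.family_id,
            "te_like": flagged,
            **{f"copies_{g}": n for g, n in profile.items()},
        }
        if wild is not None and wild in profile:
            others = [n for g, n in profile.items() if g != wild]
            mean_others = float(np.mean(others)) if others else 0.0
            row["contraction_ratio"] = (
                profile[wild] / mean_others if mean_others > 0 else float("inf")
            )
        report.append(row)
    return report


def segments_to_rows(segments: Iterable[HomologySegment]) -> list[dict[str, object]]:
    """Flatten segments for TSV export."""
    return [
        {
            "query_id": s.query_id, "query_genome": s.query_genome,
            "subject_id": s.subject_id, "subject_genome": s.subject_genome,
            "query_start": s.query_start, "query_end": s.query_end,
            "subject_start": s.subject_start, "subject_end": s.subject_end,
            "strand": s.strand, "aligned_length": s.aligned_length,
            "identities": s.identities,
            "identity_pct": round(s.identity_pct, 4), "score": s.score,
        }
        for s in segments
    ]
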