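"""Synthetic three-genome dataset generator with planted ground truth.

Emulates the study design behind the pipeline: a wild progenitor genome and
two cultivar genomes, each with its own lncRNA length/exon-structure
profile, tissue-biased expression (panicle over seedling), planted
homologous lncRNA families (including high-copy TE-like families and decoy
families designed to fail the conservation screen), planted collinear
coding-gene blocks around orthologous lncRNAs, coding-potential score
tables, a reference lncRNA annotation for one genome, and per-plant trait
measurements for mutant lines.  Every planted element is recorded in a
truth table so downstream stages are testable without any sequencing data.

All randomness flows from a single integer seed; two runs with the same
config produce byte-identical output bundles.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .iolib import (
    CODING,
    LNC_CANDIDATE,
    Exon,
    GenomeLabel,
    TranscriptModel,
    write_annotation,
    write_fasta,
    write_table,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def mutate_stratified(seq: str, identity: float, rng: np.random.Generator) -> str:
    """Substitute bases so the copy sits at exactly the target identity.

    The divergence budget ``(100 - identity)/100`` is spent as an exact
    count of substitutions placed one per equal-length window (stratified),
    so realized identity is controlled and no long unmutated run survives.
    """
    n = len(seq)
    k = int(round(n * (100.0 - identity) / 100.0))
    if k == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    bounds = np.linspace(0, n, k + 1).astype(int)
    idx = {65: 0, 67: 1, 71: 2, 84: 3}
    for w in range(k):
        lo, hi = bounds[w], bounds[w + 1]
        pos = int(rng.integers(lo, max(hi, lo + 1)))
        orig = idx.get(arr[pos], 0)
        arr[pos] = _BASES[(orig + int(rng.integers(1, 4))) % 4]
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilySpec:
    """A planted homologous lncRNA family: per-genome copy numbers, shared
    segment length (nt) and target pairwise identity (%)."""

    copies: tuple[int, ...]
    segment_length: int = 150
    identity: float = 96.0
    decoy: bool = False

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.copies):
            raise ValueError("family copy numbers must be >= 0")
        if not (50.0 < self.identity <= 100.0):
            raise ValueError("family identity must be in (50, 100]")


@dataclass(frozen=True)
class BlockSpec:
    """A planted collinear block: ``n_genes`` orthologous coding genes in
    identical order around one lncRNA, in each listed genome.  Decoy blocks
    place non-orthologous genes, so the collinearity test must reject them."""

    genomes: tuple[str, ...]
    n_genes: int = 5
    with_lncrna: bool = True
    decoy: bool = False


#: Trait summary parameters (mean, SD) per line, mirroring a published
#: mutant-phenotype table; used as sampling parameters for per-plant values.
TRAIT_UNITS: dict[str, str] = {
    "plant_height": "cm",
    "panicle_length": "cm",
    "primary_branches": "count",
    "seed_setting_rate": "%",
    "thousand_grain_weight": "g",
    "grain_length": "mm",
    "grain_width": "mm",
    "grain_thickness": "mm",
    "xoo_lesion_length": "cm",
    "xoc_lesion_length": "cm",
}

#: traits measured on >30 grains vs >10 plants vs >8 infected leaves
GRAIN_TRAITS = {"thousand_grain_weight", "grain_length", "grain_width", "grain_thickness"}
LESION_TRAITS = {"xoo_lesion_length", "xoc_lesion_length"}

DEFAULT_TRAIT_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "Dongjin": {
        "plant_height": (64.38, 3.56), "panicle_length": (16.80, 0.56),
        "primary_branches": (6.57, 0.82), "seed_setting_rate": (90.52, 5.05),
        "thousand_grain_weight": (25.56, 0.56), "grain_length": (7.64, 0.33),
        "grain_width": (3.49, 0.14), "grain_thickness": (2.33, 0.09),
        "xoo_lesion_length": (6.56, 1.99), "xoc_lesion_length": (2.11, 0.76),
    },
    "1B-19117": {
        "plant_height": (51.38, 3.87), "panicle_length": (16.62, 2.04),
        "primary_branches": (6.06, 1.57), "seed_setting_rate": (90.61, 5.01),
        "thousand_grain_weight": (20.66, 2.93), "grain_length": (6.93, 0.27),
        "grain_width": (2.72, 0.17), "grain_thickness": (2.08, 0.19),
        "xoo_lesion_length": (4.73, 1.68), "xoc_lesion_length": (2.30, 0.22),
    },
    "2D-40249": {
        "plant_height": (59.62, 4.45), "panicle_length": (15.76, 1.14),
        "primary_branches": (6.67, 0.85), "seed_setting_rate": (67.53, 5.08),
        "thousand_grain_weight": (26.40, 1.34), "grain_length": (8.28, 0.26),
        "grain_width": (3.43, 0.14), "grain_thickness": (2.31, 0.06),
        "xoo_lesion_length": (5.71, 2.97), "xoc_lesion_length": (0.47, 0.18),
    },
    "Hwayoung": {
        "plant_height": (64.50, 4.54), "panicle_length": (16.35, 1.44),
        "primary_branches": (5.82, 0.57), "seed_setting_rate": (95.00, 4.57),
        "thousand_grain_weight": (24.75, 1.21), "grain_length": (7.94, 0.29),
        "grain_width": (3.56, 0.12), "grain_thickness": (2.18, 0.08),
        "xoo_lesion_length": (5.31, 2.29), "xoc_lesion_length": (1.15, 0.76),
    },
    "1C-07927": {
        "plant_height": (56.92, 3.04), "panicle_length": (15.73, 1.32),
        "primary_branches": (6.57, 0.82), "seed_setting_rate": (11.01, 3.93),
        "thousand_grain_weight": (24.80, 0.64), "grain_length": (8.02, 0.25),
        "grain_width": (3.61, 0.16), "grain_thickness": (2.14, 0.08),
        "xoo_lesion_length": (9.10, 2.99), "xoc_lesion_length": (2.19, 0.83),
    },
}

WILDTYPE_OF: dict[str, str] = {
    "1B-19117": "Dongjin",
    "2D-40249": "Dongjin",
    "1C-07927": "Hwayoung",
}


#: shield genes per block side; exceeds the collinearity caller's default
#: rank window (10) so nothing outside a block can borrow its orthologs
SHIELDS_PER_SIDE = 12


def _default_families() -> tuple[FamilySpec, ...]:
    return (
        FamilySpec((41, 1, 3), 150, 96.0),
        FamilySpec((21, 1, 2), 150, 96.0),
    )


def _default_decoys() -> tuple[FamilySpec, ...]:
    return (
        FamilySpec((3, 1, 1), 150, 85.0, decoy=True),  # fails identity > 90
        FamilySpec((3, 1, 1), 90, 96.0, decoy=True),   # fails length > 100
    )


def _default_blocks() -> tuple[BlockSpec, ...]:
    wild, cult_a, cult_b = "rufipogon", "japonica", "indica"
    blocks = [BlockSpec((wild, cult_a, cult_b)) for _ in range(8)]
    blocks += [BlockSpec((wild, cult_a)) for _ in range(3)]
    blocks += [BlockSpec((wild, cult_b)) for _ in range(6)]
    blocks += [BlockSpec((cult_a, cult_b)) for _ in range(3)]
    blocks += [
        BlockSpec((wild, cult_a), decoy=True),
        BlockSpec((wild, cult_b), decoy=True),
        BlockSpec((cult_a, cult_b), decoy=True),
        BlockSpec((wild, cult_b), decoy=True),
    ]
    return tuple(blocks)


@dataclass(frozen=True)
class TrioConfig:
    """Full specification of one synthetic trio dataset.

    Defaults encode the study conditions the pipeline was characterized
    under: lncRNA length medians 370/670/508 nt, single-exon fractions
    65.8/50.4/62.0 %, mean exon counts 1.61/2.37/1.76, TE-like planted
    families with copy profiles (41,1,3) and (21,1,2) at 96% identity, and
    panicle-biased expression.
    """

    seed: int = 1
    genomes: tuple[str, ...] = ("rufipogon", "japonica", "indica")
    n_chromosomes: int = 4
    lnc_per_genome: tuple[int, ...] = (2000, 2000, 2000)
    length_median: tuple[float, ...] = (370.0, 670.0, 508.0)
    length_log_sd: float = 0.6
    length_bounds: tuple[int, int] = (201, 10000)
    single_exon_prob: tuple[float, ...] = (0.658, 0.504, 0.620)
    mean_exon_count: tuple[float, ...] = (1.61, 2.37, 1.76)
    coding_per_chrom: int = 60
    coding_length_median: tuple[float, ...] = (1178.0, 1425.0, 912.0)
    families: tuple[FamilySpec, ...] = field(default_factory=_default_families)
    decoy_families: tuple[FamilySpec, ...] = field(default_factory=_default_decoys)
    blocks: tuple[BlockSpec, ...] = field(default_factory=_default_blocks)
    ortholog_identity: float = 95.0
    nb_mean: float = 50.0
    nb_dispersion: float = 0.1
    coding_nb_mean: float = 200.0
    panicle_multiplier: float = 4.0
    null_fraction: float = 0.4
    de_up_fraction: float = 0.85
    short_fraction: float = 0.03
    silent_fraction: float = 0.03
    codingscore_fraction: float = 0.03
    lnc_score_mean: float = -2.0
    coding_score_mean: float = 2.0
    score_sd: float = 0.4
    reference_genome: str = "japonica"
    known_fraction: float = 0.5
    tissues: tuple[str, str] = ("panicle", "seedling")
    n_architecture: int = 12
    n_grain: int = 31
    n_lesion: int = 9
    trait_params: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: DEFAULT_TRAIT_PARAMS
    )

    def validate(self) -> None:
        if len(set(self.genomes)) != len(self.genomes) or len(self.genomes) < 2:
            raise ValueError("genomes must be >= 2 unique labels")
        for tup in (self.lnc_per_genome, self.length_median,
                    self.single_exon_prob, self.mean_exon_count):
            if len(tup) != len(self.genomes):
                raise ValueError("per-genome tuples must match genome count")
        for fam in (*self.families, *self.decoy_families):
            if len(fam.copies) != len(self.genomes):
                raise ValueError("family copy tuple must match genome count")
            if fam.segment_length + 40 > self.length_bounds[1]:
                raise ValueError("family segment longer than any transcript")
        for blk in self.blocks:
            unknown = set(blk.genomes) - set(self.genomes)
            if unknown:
                raise ValueError(f"block names unknown genomes {unknown}")
            if blk.n_genes < 1:
                raise ValueError("block must contain at least one gene")
        if self.reference_genome not in self.genomes:
            raise ValueError("reference_genome must be one of the genomes")
        if self.nb_mean <= 0 or self.nb_dispersion <= 0:
            raise ValueError("negative-binomial mean and dispersion must be > 0")


@dataclass
class TruthTable:
    """Ground truth for every planted element, emitted as TSVs."""

    families: pd.DataFrame
    positional: pd.DataFrame
    orthologs: pd.DataFrame
    de: pd.DataFrame
    known: pd.DataFrame
    filter_fate: pd.DataFrame


@dataclass
class TrioBundle:
    """In-memory handles plus on-disk paths for one generated dataset."""

    config: TrioConfig
    outdir: Path
    transcripts: dict[str, list[TranscriptModel]]
    genome_seqs: dict[str, dict[str, str]]
    counts: dict[str, pd.DataFrame]
    scores: dict[str, pd.DataFrame]
    traits: pd.DataFrame
    truth: TruthTable
    paths: dict[str, Path]

    def lnc_sequences(self, genome: str) -> dict[str, str]:
        """Spliced sequences of this genome's lnc-candidate transcripts."""
        from .iolib import extract_spliced

        seqs = self.genome_seqs[genome]
        return {
            t.id: extract_spliced(seqs, t)
            for t in self.transcripts[genome]
            if t.biotype != CODING
        }


# ---------------------------------------------------------------------------
# planting primitives
# ---------------------------------------------------------------------------

def plant_te_family(
    genomes: Sequence[str],
    copies: Sequence[int],
    consensus_length: int,
    identity: float,
    rng: np.random.Generator,
) -> dict[str, list[str]]:
    """Derive family-member segments from one consensus by point mutation.

    Each copy is mutated at half the divergence budget so the expected
    *pairwise* identity between copies equals ``identity``.  Returns
    genome → list of segment sequences; empty when all copies are zero.
    """
    if any(c < 0 for c in copies):
        raise ValueError("copies must be >= 0")
    if not (50.0 < identity <= 100.0):
        raise ValueError("identity must be in (50, 100]")
    consensus = _random_seq(rng, consensus_length)
    total = int(sum(copies))
    arrs = [
        np.frombuffer(consensus.encode(), dtype=np.uint8).copy()
        for _ in range(total)
    ]
    # per-copy budget is half the pairwise divergence; within each stratum
    # every copy mutates a distinct position (when the stratum is wide
    # enough), so pairwise identity is exactly the configured value rather
    # than drifting upward through coincident substitutions
    k = int(round(consensus_length * (100.0 - identity) / 200.0))
    if k and total:
        bounds = np.linspace(0, consensus_length, k + 1).astype(int)
        idx = {65: 0, 67: 1, 71: 2, 84: 3}
        for w in range(k):
            lo, width = bounds[w], max(1, bounds[w + 1] - bounds[w])
            if width >= total:
                positions = lo + rng.choice(width, size=total, replace=False)
            else:
                positions = lo + rng.integers(0, width, size=total)
            for arr, pos in zip(arrs, positions):
                orig = idx.get(int(arr[pos]), 0)
                arr[pos] = _BASES[(orig + int(rng.integers(1, 4))) % 4]
    members: dict[str, list[str]] = {}
    start = 0
    for genome, n in zip(genomes, copies):
        members[genome] = [a.tobytes().decode() for a in arrs[start : start + n]]
        start += n
    return members


def simulate_counts(
    n_transcripts: int,
    mean: float,
    dispersion: float,
    multiplier: float,
    rng: np.random.Generator,
    de_flags: np.ndarray | None = None,
    up_flags: np.ndarray | None = None,
    tissues: Sequence[str] = ("panicle", "seedling"),
) -> pd.DataFrame:
    """Negative-binomial counts for one genome, two tissues.

    Planted-DE transcripts have expected count ``multiplier × mean`` in the
    favored tissue; null transcripts share one mean in both.
    """
    if mean <= 0 or dispersion <= 0:
        raise ValueError("mean and dispersion must be > 0")
    if de_flags is None:
        de_flags = np.zeros(n_transcripts, dtype=bool)
    if up_flags is None:
        up_flags = np.ones(n_transcripts, dtype=bool)
    mu = {t: np.full(n_transcripts, mean) for t in tissues}
    pan, seed = tissues
    mu[pan][de_flags & up_flags] *= multiplier
    mu[seed][de_flags & ~up_flags] *= multiplier
    size = 1.0 / dispersion
    data = {
        t: rng.negative_binomial(size, size / (size + mu[t]))
        for t in tissues
    }
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# per-genome structural sampling
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _lognormal_mu(target_median: float, log_sd: float, lo: int, hi: int) -> float:
    """Log-scale location such that the [lo, hi]-truncated log-normal has
    median ``target_median`` (plain log(median) would overshoot after left
    truncation for short-median genomes)."""
    from scipy.optimize import brentq

    llo, lhi, lt = math.log(lo), math.log(hi), math.log(target_median)

    def offset(mu: float) -> float:
        flo = ndtr((llo - mu) / log_sd)
        fhi = ndtr((lhi - mu) / log_sd)
        med = mu + log_sd * ndtri((flo + fhi) / 2.0)
        return med - lt

    return float(brentq(offset, lt - 5 * log_sd, lt + 5 * log_sd))


def _truncated_lognormal(
    median: float, log_sd: float, lo: int, hi: int, rng: np.random.Generator
) -> int:
    mu = _lognormal_mu(median, log_sd, lo, hi)
    flo = ndtr((math.log(lo) - mu) / log_sd)
    fhi = ndtr((math.log(hi) - mu) / log_sd)
    u = flo + (fhi - flo) * rng.random()
    val = int(round(math.exp(mu + log_sd * ndtri(u))))
    return min(max(val, lo), hi)


def _sample_length(cfg: TrioConfig, gi: int, rng: np.random.Generator) -> int:
    lo, hi = cfg.length_bounds
    return _truncated_lognormal(cfg.length_median[gi], cfg.length_log_sd, lo, hi, rng)


def _sample_exon_count(cfg: TrioConfig, gi: int, rng: np.random.Generator) -> int:
    p1 = cfg.single_exon_prob[gi]
    if rng.random() < p1:
        return 1
    lam = max(0.0, (cfg.mean_exon_count[gi] - p1) / (1.0 - p1) - 2.0)
    return 2 + int(rng.poisson(lam))


def _split_exons(total: int, k: int, rng: np.random.Generator) -> list[int]:
    """Partition ``total`` nt into ``k`` exon lengths of at least 30 nt."""
    k = max(1, min(k, total // 30))
    if k == 1:
        return [total]
    # stick-breaking with a 30 nt floor per exon
    extra = total - 30 * k
    weights = rng.dirichlet(np.ones(k))
    alloc = np.floor(weights * extra).astype(int)
    alloc[0] += extra - alloc.sum()
    return [30 + int(a) for a in alloc]


# internal placement spec for one transcript before coordinates are known
@dataclass
class _TxSpec:
    id: str
    gene_id: str
    biotype: str
    spliced: str
    exon_count: int
    strand: str
    role: str  # background | family | family_decoy | block_lnc | short | silent | coding_like | coding | block_gene
    meta: dict = field(default_factory=dict)


@dataclass
class _BlockUnit:
    """A block's members in one genome, placed contiguously.

    ``shields`` are genome-specific (ortholog-free) coding genes placed on
    both sides of the block so that only the block's own lncRNA sees the
    orthologous genes among its nearest coding neighbours; any other
    lncRNA outside the block hits shields first and scores zero "close"
    genes.
    """

    block_id: str
    genes: list[_TxSpec]
    lnc: _TxSpec | None
    shields_left: list[_TxSpec] = field(default_factory=list)
    shields_right: list[_TxSpec] = field(default_factory=list)


def _build_transcript(
    spec: _TxSpec,
    chrom: str,
    cursor: int,
    rng: np.random.Generator,
    pieces: list[str],
) -> tuple[TranscriptModel, int]:
    """Append exon/intron sequence pieces starting at ``cursor`` and return
    the transcript model plus the new cursor (all 1-based inclusive)."""
    genomic = _revcomp(spec.spliced) if spec.strand == "-" else spec.spliced
    exon_lengths = _split_exons(len(genomic), spec.exon_count, rng)
    exons = []
    pos = cursor
    offset = 0
    for i, ln in enumerate(exon_lengths):
        if i > 0:
            intron = int(rng.integers(60, 400))
            pieces.append(_random_seq(rng, intron))
            pos += intron
        pieces.append(genomic[offset : offset + ln])
        exons.append(Exon(chrom, pos, pos + ln - 1, spec.strand))
        pos += ln
        offset += ln
    model = TranscriptModel(spec.id, spec.gene_id, GenomeLabel(""), exons, spec.biotype)
    return model, pos


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

def generate_trio(config: TrioConfig, outdir: str | Path) -> TrioBundle:
    """Generate and write the full dataset bundle; see module docstring."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(6)
    rng_plant = np.random.default_rng(streams[0])
    rng_layout = np.random.default_rng(streams[1])
    rng_expr = np.random.default_rng(streams[2])
    rng_scores = np.random.default_rng(streams[3])
    rng_traits = np.random.default_rng(streams[4])
    rng_known = np.random.default_rng(streams[5])

    genomes = list(config.genomes)
    gi_of = {g: i for i, g in enumerate(genomes)}

    fam_rows: list[dict] = []
    specs: dict[str, list[_TxSpec]] = {g: [] for g in genomes}
    blocks_of: dict[str, list[_BlockUnit]] = {g: [] for g in genomes}

    # --- planted homologous families (incl. decoys) ---
    all_fams = [*config.families, *config.decoy_families]
    for fx, fam in enumerate(all_fams, 1):
        fam_id = f"{'DEC' if fam.decoy else 'FAM'}{fx:03d}"
        members = plant_te_family(
            genomes, fam.copies, fam.segment_length, fam.identity, rng_plant
        )
        for g in genomes:
            gi = gi_of[g]
            for ci, segment in enumerate(members[g], 1):
                total = max(_sample_length(config, gi, rng_plant),
                            fam.segment_length + 60)
                left = int(rng_plant.integers(20, total - fam.segment_length - 19))
                seq = (
                    _random_seq(rng_plant, left)
                    + segment
                    + _random_seq(rng_plant, total - fam.segment_length - left)
                )
                tid = f"{g}.{fam_id}.{ci}"
                specs[g].append(_TxSpec(
                    tid, tid, LNC_CANDIDATE, seq, 1,
                    "+" if rng_plant.random() < 0.5 else "-",
                    "family_decoy" if fam.decoy else "family",
                ))
                fam_rows.append({
                    "family_id": fam_id, "genome": g, "transcript_id": tid,
                    "decoy": fam.decoy, "segment_length": fam.segment_length,
                    "identity": fam.identity,
                    "segment_start": left + 1,  # 1-based on the transcript
                    "segment_end": left + fam.segment_length,
                })

    # --- planted collinear blocks ---
    pos_rows: list[dict] = []
    ortho_rows: list[dict] = []
    for bx, blk in enumerate(config.blocks, 1):
        block_id = f"{'DBLK' if blk.decoy else 'BLK'}{bx:03d}"
        gene_cores = None
        if not blk.decoy:
            gene_cores = [
                _random_seq(rng_plant, int(rng_plant.integers(900, 1400)))
                for _ in range(blk.n_genes)
            ]
        gene_ids: dict[str, list[str]] = {}
        for g in blk.genomes:
            gi = gi_of[g]
            genes = []
            for k in range(blk.n_genes):
                gid = f"{g}.{block_id}.g{k + 1}"
                if blk.decoy:
                    core = _random_seq(rng_plant, int(rng_plant.integers(900, 1400)))
                else:
                    per_copy = 100.0 - (100.0 - config.ortholog_identity) / 2.0
                    core = mutate_stratified(gene_cores[k], per_copy, rng_plant)
                genes.append(_TxSpec(gid, gid, CODING, core, 1, "+", "block_gene"))
            gene_ids[g] = [s.id for s in genes]
            lnc = None
            if blk.with_lncrna:
                lid = f"{g}.{block_id}.lnc"
                lnc = _TxSpec(
                    lid, lid, LNC_CANDIDATE,
                    _random_seq(rng_plant, _sample_length(config, gi, rng_plant)),
                    1, "+", "block_lnc",
                )
                pos_rows.append({
                    "block_id": block_id, "genome": g, "lncrna_id": lid,
                    "genomes": ",".join(blk.genomes), "decoy": blk.decoy,
                })
            shields = {"L": [], "R": []}
            for side in ("L", "R"):
                for k in range(SHIELDS_PER_SIDE):
                    sid = f"{g}.{block_id}.shield{side}{k + 1}"
                    shields[side].append(_TxSpec(
                        sid, sid, CODING,
                        _random_seq(rng_plant, int(rng_plant.integers(900, 1400))),
                        1, "+", "shield_gene",
                    ))
            blocks_of[g].append(
                _BlockUnit(block_id, genes, lnc, shields["L"], shields["R"])
            )
        if not blk.decoy:
            # emit each pair once, oriented by config genome order
            ordered = sorted(blk.genomes, key=gi_of.get)
            for x in range(len(ordered)):
                for y in range(x + 1, len(ordered)):
                    a, b = ordered[x], ordered[y]
                    for ga, gb in zip(gene_ids[a], gene_ids[b]):
                        ortho_rows.append({
                            "genome_a": a, "gene_a": ga,
                            "genome_b": b, "gene_b": gb,
                        })

    # --- background lncRNAs, filter decoys, background coding genes ---
    fate_rows: list[dict] = []
    for g in genomes:
        gi = gi_of[g]
        planted_lnc = sum(1 for s in specs[g] if s.biotype == LNC_CANDIDATE)
        planted_lnc += sum(1 for b in blocks_of[g] if b.lnc is not None)
        n_bg = max(0, config.lnc_per_genome[gi] - planted_lnc)
        for i in range(n_bg):
            tid = f"{g}.LNC{i + 1:05d}"
            total = _sample_length(config, gi, rng_layout)
            specs[g].append(_TxSpec(
                tid, tid, LNC_CANDIDATE, _random_seq(rng_layout, total),
                _sample_exon_count(config, gi, rng_layout),
                "+" if rng_layout.random() < 0.5 else "-", "background",
            ))
        n_lnc = config.lnc_per_genome[gi]
        for role, frac in (
            ("short", config.short_fraction),
            ("silent", config.silent_fraction),
            ("coding_like", config.codingscore_fraction),
        ):
            for i in range(int(round(frac * n_lnc))):
                tid = f"{g}.{role.upper()}{i + 1:04d}"
                if role == "short":
                    total = int(rng_layout.integers(80, 200))
                else:
                    total = _sample_length(config, gi, rng_layout)
                specs[g].append(_TxSpec(
                    tid, tid, LNC_CANDIDATE, _random_seq(rng_layout, total),
                    1, "+", role,
                ))
                fate_rows.append({"genome": g, "transcript_id": tid,
                                  "planted_fate": role})
        n_coding = config.coding_per_chrom * config.n_chromosomes
        lam_cod = 4.0  # background coding genes: 2 + Poisson exons
        for i in range(n_coding):
            tid = f"{g}.CDS{i + 1:05d}"
            total = _truncated_lognormal(
                config.coding_length_median[gi], 0.6, 300, 12000, rng_layout)
            specs[g].append(_TxSpec(
                tid, tid, CODING, _random_seq(rng_layout, total),
                2 + int(rng_layout.poisson(lam_cod)),
                "+" if rng_layout.random() < 0.5 else "-", "coding",
            ))

    # --- layout: distribute elements across chromosomes, emit sequences ---
    transcripts: dict[str, list[TranscriptModel]] = {}
    genome_seqs: dict[str, dict[str, str]] = {}
    for g in genomes:
        elements: list[tuple[str, object]] = [("tx", s) for s in specs[g]]
        elements += [("block", b) for b in blocks_of[g]]
        order = rng_layout.permutation(len(elements))
        chrom_elems: list[list[tuple[str, object]]] = [
            [] for _ in range(config.n_chromosomes)
        ]
        for j, ei in enumerate(order):
            chrom_elems[j % config.n_chromosomes].append(elements[ei])
        tx_models: list[TranscriptModel] = []
        seqs: dict[str, str] = {}
        for ci, elems in enumerate(chrom_elems, 1):
            chrom = f"chr{ci}"
            pieces: list[str] = []
            cursor = 1
            lead = int(rng_layout.integers(2000, 5000))
            pieces.append(_random_seq(rng_layout, lead))
            cursor += lead
            for kind, obj in elems:
                if kind == "tx":
                    gap = int(rng_layout.integers(1500, 4000))
                    pieces.append(_random_seq(rng_layout, gap))
                    cursor += gap
                    model, cursor = _build_transcript(obj, chrom, cursor, rng_layout, pieces)
                    tx_models.append(model)
                else:
                    # block: [margin][shields][offset][genes+lnc][offset]
                    # [shields][margin] — the offsets keep the orthologous
                    # genes strictly nearest to the block lncRNA, and the
                    # shields strictly nearest to anything outside
                    margin, offset = 15000, 8000
                    unit: _BlockUnit = obj

                    def _place_run(specs_run, first_gap):
                        nonlocal cursor
                        pieces.append(_random_seq(rng_layout, first_gap))
                        cursor += first_gap
                        for m in specs_run:
                            gap = int(rng_layout.integers(300, 800))
                            pieces.append(_random_seq(rng_layout, gap))
                            cursor += gap
                            model, c2 = _build_transcript(
                                m, chrom, cursor, rng_layout, pieces)
                            cursor = c2
                            tx_models.append(model)

                    n = len(unit.genes)
                    mid = (n + 1) // 2  # lncRNA sits between mid and mid+1
                    core = unit.genes[:mid] + (
                        [unit.lnc] if unit.lnc else []) + unit.genes[mid:]
                    _place_run(unit.shields_left, margin)
                    _place_run(core, offset)
                    _place_run(unit.shields_right, offset)
                    pieces.append(_random_seq(rng_layout, margin))
                    cursor += margin
            tail = int(rng_layout.integers(2000, 5000))
            pieces.append(_random_seq(rng_layout, tail))
            seqs[chrom] = "".join(pieces)
        label = GenomeLabel(g)
        for t in tx_models:
            t.genome = label
        transcripts[g] = tx_models
        genome_seqs[g] = seqs

    # --- expression counts ---
    counts: dict[str, pd.DataFrame] = {}
    de_rows: list[dict] = []
    for g in genomes:
        txs = transcripts[g]
        ids = [t.id for t in txs]
        n = len(ids)
        is_lnc = np.array([t.biotype != CODING for t in txs])
        roles = _roles_by_id(specs[g], blocks_of[g])
        eligible = np.array([
            is_lnc[i] and roles[ids[i]] not in ("short", "silent") for i in range(n)
        ])
        de_flags = np.zeros(n, dtype=bool)
        de_flags[eligible] = rng_expr.random(eligible.sum()) > config.null_fraction
        up_flags = rng_expr.random(n) < config.de_up_fraction
        mean_vec = np.where(is_lnc, config.nb_mean, config.coding_nb_mean)
        size = 1.0 / config.nb_dispersion
        data = {}
        pan, sd = config.tissues
        mu_pan = mean_vec * np.where(de_flags & up_flags, config.panicle_multiplier, 1.0)
        mu_sd = mean_vec * np.where(de_flags & ~up_flags, config.panicle_multiplier, 1.0)
        data[pan] = rng_expr.negative_binomial(size, size / (size + mu_pan))
        data[sd] = rng_expr.negative_binomial(size, size / (size + mu_sd))
        cdf = pd.DataFrame(data, index=pd.Index(ids, name="transcript_id"))
        silent = np.array([roles[i] == "silent" for i in ids])
        cdf.loc[silent, :] = 0
        cdf["length"] = [t.length for t in txs]
        counts[g] = cdf.reset_index()
        for i, tid in enumerate(ids):
            if is_lnc[i]:
                de_rows.append({
                    "genome": g, "transcript_id": tid,
                    "planted_de": bool(de_flags[i] & ~silent[i]),
                    "direction": "up" if up_flags[i] else "down",
                })

    # --- coding-potential score tables ---
    scores: dict[str, pd.DataFrame] = {}
    for g in genomes:
        txs = transcripts[g]
        roles = _roles_by_id(specs[g], blocks_of[g])
        rows = []
        for t in txs:
            if t.biotype == CODING:
                m = config.coding_score_mean
                s1 = rng_scores.normal(m, config.score_sd)
                s2 = rng_scores.normal(m, config.score_sd)
            elif roles[t.id] == "coding_like":
                s1 = abs(rng_scores.normal(1.5, config.score_sd))
                s2 = (rng_scores.normal(config.lnc_score_mean, config.score_sd)
                      if rng_scores.random() < 0.5
                      else abs(rng_scores.normal(1.5, config.score_sd)))
            else:
                m = config.lnc_score_mean
                s1 = rng_scores.normal(m, config.score_sd)
                s2 = rng_scores.normal(m, config.score_sd)
            rows.append({"transcript_id": t.id,
                         "cpc_like": round(float(s1), 4),
                         "cnci_like": round(float(s2), 4)})
        scores[g] = pd.DataFrame(rows)

    # --- reference lncRNA annotation (known/novel ground truth) ---
    ref_g = config.reference_genome
    ref_lncs = [t for t in transcripts[ref_g] if t.biotype != CODING]
    roles_ref = _roles_by_id(specs[ref_g], blocks_of[ref_g])
    eligible_ref = [t for t in ref_lncs
                    if roles_ref[t.id] not in ("short", "silent", "coding_like")]
    k_known = int(round(config.known_fraction * len(eligible_ref)))
    perm = rng_known.permutation(len(eligible_ref))
    known_set = {eligible_ref[i].id for i in perm[:k_known]}
    known_rows = [
        {"genome": ref_g, "transcript_id": t.id, "known": t.id in known_set}
        for t in eligible_ref
    ]
    ref_models = [
        TranscriptModel(f"REF.{j + 1:05d}", f"REF.{j + 1:05d}", GenomeLabel(ref_g),
                        list(t.exons), "lncRNA")
        for j, t in enumerate(t for t in eligible_ref if t.id in known_set)
    ]

    # --- traits ---
    trait_rows = []
    for line, params in config.trait_params.items():
        for trait, (mean, sd) in params.items():
            if trait in GRAIN_TRAITS:
                n = config.n_grain
            elif trait in LESION_TRAITS:
                n = config.n_lesion
            else:
                n = config.n_architecture
            vals = rng_traits.normal(mean, sd, size=n)
            for v in vals:
                trait_rows.append({
                    "line": line, "trait": trait,
                    "unit": TRAIT_UNITS[trait],
                    "wildtype": WILDTYPE_OF.get(line, ""),
                    "value": round(float(v), 4),
                })
    traits = pd.DataFrame(trait_rows)

    truth = TruthTable(
        families=pd.DataFrame(fam_rows),
        positional=pd.DataFrame(pos_rows),
        orthologs=pd.DataFrame(ortho_rows),
        de=pd.DataFrame(de_rows),
        known=pd.DataFrame(known_rows),
        filter_fate=pd.DataFrame(fate_rows),
    )

    # --- write everything ---
    paths: dict[str, Path] = {}

    def _emit(name: str, writer, *args) -> None:
        path = outdir / name
        writer(path, *args)
        paths[name] = path

    for g in genomes:
        _emit(f"{g}.genome.fasta", write_fasta, genome_seqs[g])
        _emit(f"{g}.gff3", write_annotation, transcripts[g])
        _emit(f"{g}.counts.tsv", write_table, counts[g])
        _emit(f"{g}.scores.tsv", write_table, scores[g])
    _emit(f"{ref_g}.reference_lncrnas.gff3", write_annotation, ref_models)
    _emit("traits.tsv", write_table, traits)
    _emit("truth_families.tsv", write_table, truth.families)
    _emit("truth_positional.tsv", write_table, truth.positional)
    _emit("truth_orthologs.tsv", write_table, truth.orthologs)
    _emit("truth_de.tsv", write_table, truth.de)
    _emit("truth_known.tsv", write_table, truth.known)
    _emit("truth_filter_fate.tsv", write_table, truth.filter_fate)
    manifest = pd.DataFrame(
        [{"file": name, "sha256": _sha256(path)} for name, path in sorted(paths.items())]
    )
    write_table(outdir / "MANIFEST.tsv", manifest)
    paths["MANIFEST.tsv"] = outdir / "MANIFEST.tsv"

    return TrioBundle(
        config=config, outdir=outdir, transcripts=transcripts,
        genome_seqs=genome_seqs, counts=counts, scores=scores,
        traits=traits, truth=truth, paths=paths,
    )


def _roles_by_id(specs: list[_TxSpec], blocks: list[_BlockUnit]) -> dict[str, str]:
    roles = {s.id: s.role for s in specs}
    for b in blocks:
        for gspec in (*b.genes, *b.shields_left, *b.shields_right):
            roles[gspec.id] = gspec.role
        if b.lnc is not None:
            roles[b.lnc.id] = b.lnc.role
    return roles


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def shuffle_gene_positions(
    transcripts: Iterable[TranscriptModel], rng: np.random.Generator
) -> list[TranscriptModel]:
    """Negative control: permute coding-gene loci among themselves.

    Gene content is unchanged but neighborhoods are randomized, so any
    collinearity signal must vanish.
    """
    txs = [t for t in transcripts]
    coding = [t for t in txs if t.biotype == CODING]
    slots = [(list(t.exons)) for t in coding]
    order = rng.permutation(len(coding))
    out = []
    for t in txs:
        if t.biotype != CODING:
            out.append(t)
    for i, t in enumerate(coding):
        new_exons = slots[order[i]]
        out.append(TranscriptModel(t.id, t.gene_id, t.genome, list(new_exons), t.biotype))
    return out
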