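"""Readers, writers and coordinate conventions shared by the whole pipeline.

All genomic coordinates are 1-based inclusive internally (GFF3 convention);
an interval ``start..end`` spans ``end - start + 1`` bases.  BED export
converts to 0-based half-open at the boundary.  Transcript *length* always
means spliced length — the sum of exon lengths — not genomic span.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("oryzalnc")

VALID_STRANDS = {"+", "-"}

#: canonical biotype labels used throughout the pipeline
CODING = "coding"
LNC_CANDIDATE = "lnc_candidate"
LNCRNA = "lncRNA"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeLabel:
    """Short identifier for one genome of the comparison (e.g. the wild
    progenitor and two cultivars).  Labels are unique within a run and their
    order is fixed; results are reported per ordered label."""

    name: str

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.name


@dataclass(frozen=True)
class Exon:
    """One exon, 1-based inclusive on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid exon coordinates {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class TranscriptModel:
    """A stranded, exon-structured transcript on one chromosome of one genome.

    Exons are kept sorted by start and non-overlapping; ``length`` is the
    spliced length (sum of exon lengths).
    """

    id: str
    gene_id: str
    genome: GenomeLabel
    exons: list[Exon]
    biotype: str = LNC_CANDIDATE

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.id} has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"transcript {self.id} mixes chromosomes or strands"
            )
        self.exons = _repair_exons(self.id, self.exons)

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


def _repair_exons(tid: str, exons: Sequence[Exon]) -> list[Exon]:
    """Sort exons by start and merge overlapping/adjacent-overlap ones.

    Overlap repair is the only silent coercion readers perform; it is logged.
    """
    ordered = sorted(exons, key=lambda e: (e.start, e.end))
    merged: list[Exon] = [ordered[0]]
    repaired = list(ordered) != list(exons)
    for e in ordered[1:]:
        last = merged[-1]
        if e.start <= last.end:  # overlap: merge
            merged[-1] = Exon(last.chrom, last.start, max(last.end, e.end), last.strand)
            repaired = True
        else:
            merged.append(e)
    if repaired:
        logger.warning("transcript %s: exons sorted/merged during repair", tid)
    return merged


def transcript_length(t: TranscriptModel) -> int:
    """Spliced length in nucleotides: sum of inclusive exon lengths."""
    return t.length


# ---------------------------------------------------------------------------
# annotation reading (GFF3 / GTF)
# ---------------------------------------------------------------------------

_CODING_TYPES = {"mRNA", "CDS"}
_CODING_BIOTYPES = {"coding", "protein_coding", "mRNA"}
_LNC_BIOTYPES = {"lncRNA", "lnc_RNA", "lincRNA"}


def _prescan_annotation(path: Path) -> None:
    """Validate coordinates/strands line by line so errors can name the line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 8:
                raise ValueError(f"{path}:{lineno}: fewer than 8 GFF columns")
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 1 or end < start:
                raise ValueError(
                    f"{path}:{lineno}: malformed coordinate {start}..{end}"
                )
            if cols[2] == "exon" and cols[6] not in VALID_STRANDS:
                raise ValueError(f"{path}:{lineno}: unknown strand {cols[6]!r}")


def _attr_first(feature: gffutils.Feature, *keys: str) -> str | None:
    for key in keys:
        if key in feature.attributes:
            values = feature.attributes[key]
            if values:
                return values[0]
    return None


def _biotype_of(feature: gffutils.Feature | None) -> str | None:
    if feature is None:
        return None
    val = _attr_first(feature, "biotype", "transcript_biotype", "gene_biotype")
    if val is None:
        if feature.featuretype in _CODING_TYPES:
            return CODING
        return None
    if val in _CODING_BIOTYPES:
        return CODING
    if val in _LNC_BIOTYPES:
        return LNCRNA
    return LNC_CANDIDATE


def read_annotation(path: str | Path, genome: GenomeLabel) -> list[TranscriptModel]:
    """Read a GFF3 or GTF file into :class:`TranscriptModel` records.

    Exons are grouped by ``transcript_id`` (GTF) or ``Parent``/``ID`` (GFF3).
    Malformed coordinates or strands raise with the offending line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prescan_annotation(path)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )
    # transcript-level features, if present, carry biotype and gene ids
    tx_meta: dict[str, gffutils.Feature] = {}
    for ftype in ("transcript", "mRNA", "lnc_RNA", "ncRNA"):
        try:
            for f in db.features_of_type(ftype):
                key = _attr_first(f, "transcript_id", "ID") or f.id
                tx_meta[key] = f
        except Exception:  # pragma: no cover - featuretype absent
            continue

    groups: dict[str, list[Exon]] = {}
    order: list[str] = []
    for exon in db.features_of_type("exon"):
        tid = _attr_first(exon, "transcript_id", "Parent", "ID")
        if tid is None:
            raise ValueError(f"{path}: exon without transcript_id/Parent")
        if tid not in groups:
            groups[tid] = []
            order.append(tid)
        groups[tid].append(Exon(exon.seqid, exon.start, exon.end, exon.strand))

    transcripts = []
    for tid in order:
        meta = tx_meta.get(tid)
        gene_id = tid
        if meta is not None:
            gene_id = _attr_first(meta, "gene_id", "Parent") or tid
        biotype = _biotype_of(meta) or LNC_CANDIDATE
        transcripts.append(
            TranscriptModel(tid, gene_id, genome, groups[tid], biotype)
        )
    return transcripts


def write_annotation(path: str | Path, transcripts: Iterable[TranscriptModel]) -> None:
    """Write transcripts as GFF3 (gene/transcript/exon rows, biotype attr)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in transcripts:
            attrs = f"ID={t.id};gene_id={t.gene_id};biotype={t.biotype}"
            fh.write(
                f"{t.chrom}\toryzalnc\ttranscript\t{t.start}\t{t.end}\t.\t"
                f"{t.strand}\t.\t{attrs}\n"
            )
            for i, e in enumerate(t.exons, 1):
                fh.write(
                    f"{e.chrom}\toryzalnc\texon\t{e.start}\t{e.end}\t.\t"
                    f"{e.strand}\t.\tID={t.id}.exon{i};Parent={t.id};"
                    f"transcript_id={t.id}\n"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an id→sequence dict, uppercase-normalized.

    Duplicate identifiers are a hard error.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate sequence identifier {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    recs = [
        SeqRecord(Seq(seq.upper()), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


def extract_spliced(genome_seqs: Mapping[str, str], t: TranscriptModel) -> str:
    """Spliced transcript sequence; minus-strand transcripts are
    reverse-complemented so the result reads 5'→3'."""
    chrom = genome_seqs[t.chrom]
    parts = [chrom[e.start - 1 : e.end] for e in t.exons]
    seq = "".join(parts)
    if t.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq.upper()


# ---------------------------------------------------------------------------
# tables, BED, link files
# ---------------------------------------------------------------------------

def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_bed(path: str | Path, transcripts: Iterable[TranscriptModel]) -> None:
    """BED6 export of transcript spans (0-based half-open)."""
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(
                f"{t.chrom}\t{t.start - 1}\t{t.end}\t{t.id}\t0\t{t.strand}\n"
            )


LINK_COLUMNS = [
    "genome_a", "chrom_a", "start_a", "end_a", "id_a",
    "genome_b", "chrom_b", "start_b", "end_b", "id_b",
]


def write_links(path: str | Path, matches: Iterable[Mapping[str, object]]) -> int:
    """Circos-style link export: one two-interval record per match.

    Returns the number of records written; an empty match set yields a
    header-only file.
    """
    rows = list(matches)
    df = pd.DataFrame(rows, columns=LINK_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    return len(rows)


def read_links(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
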