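"""Readers and writers for the external formats the pipeline touches.

Coordinate contract: everything in memory is 0-based, half-open. GTF/GFF3 on
disk are 1-based, inclusive; the conversion happens here and nowhere else.
The only tabular dialect is TSV (no CSV autodetection), so tables round-trip
bit-exactly.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")

# IUPAC nucleotide one-letter codes (RNA alphabet after T->U transliteration).
IUPAC_NT = set("ACGUNRYSWKMBDHV")

LAYERS = ("lncRNA", "miRNA", "mRNA", "metabolite")
UNITS = ("raw_count", "FPKM", "TPM", "intensity")


class FormatError(ValueError):
    """Raised on malformed input files."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Positional overlap; intervals on different chroms never overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset, self.strand)


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as a sorted chain of non-overlapping exons on one strand."""

    transcript_id: str
    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    biotype: str = "unknown"  # {coding, noncoding, unknown}

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")
        if self.biotype not in ("coding", "noncoding", "unknown"):
            raise ValueError(f"bad biotype {self.biotype!r}")
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.interval.chrom or ex.strand != self.interval.strand:
                raise ValueError(f"{self.transcript_id}: exon off transcript chrom/strand")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"{self.transcript_id}: exons overlap or are unsorted")
            prev_end = ex.end
        if self.exons[0].start != self.interval.start or self.exons[-1].end != self.interval.end:
            raise ValueError(f"{self.transcript_id}: span does not equal exon hull")

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Ordered intron coordinates (0-based half-open), the splice chain."""
        return tuple(
            (a.end, b.start)
            for a, b in zip(self.exons, self.exons[1:])
            if b.start > a.end
        )

    @property
    def exonic_length(self) -> int:
        return sum(len(ex) for ex in self.exons)

    @property
    def tss(self) -> int:
        """Transcription start coordinate (strand-aware)."""
        return self.interval.start if self.interval.strand == "+" else self.interval.end

    def shifted(self, offset: int) -> "TranscriptModel":
        return TranscriptModel(
            self.transcript_id,
            self.gene_id,
            self.interval.shifted(offset),
            tuple(ex.shifted(offset) for ex in self.exons),
            self.biotype,
        )


@dataclass(frozen=True)
class CodingPotentialRecord:
    """One transcript's coding-potential scores from the two callers."""

    transcript_id: str
    cnci_score: float
    cpc2_probability: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.cpc2_probability <= 1.0:
            raise ValueError(
                f"{self.transcript_id}: CPC2 probability {self.cpc2_probability} not in [0,1]"
            )


@dataclass
class AbundanceMatrix:
    """Feature x sample abundance table with layer/unit metadata.

    ``data`` holds features on rows and samples on columns.  ``library_sizes``
    (total mapped fragments per sample) is mandatory for raw counts because
    FPKM needs it.
    """

    layer: str
    unit: str
    data: pd.DataFrame
    sample_to_group: Mapping[str, str]
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"layer must be one of {LAYERS}, got {self.layer!r}")
        if self.unit not in UNITS:
            raise ValueError(f"unit must be one of {UNITS}, got {self.unit!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")
        missing = [s for s in self.data.columns if s not in self.sample_to_group]
        if missing:
            raise ValueError(f"samples without a group assignment: {missing}")
        if self.unit == "raw_count":
            if self.library_sizes is None:
                raise ValueError("library_sizes required for raw counts")
            ls = self.library_sizes.reindex(self.data.columns)
            if ls.isna().any() or (ls <= 0).any():
                raise ValueError("library_sizes must be positive for every sample")
            self.library_sizes = ls

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def samples_of(self, group: str) -> list[str]:
        return [s for s in self.data.columns if self.sample_to_group[s] == group]

    def with_values(self, data: pd.DataFrame, unit: str) -> "AbundanceMatrix":
        return AbundanceMatrix(self.layer, unit, data, dict(self.sample_to_group), None)


# ---------------------------------------------------------------------------
# GTF / GFF3
# ---------------------------------------------------------------------------

_GTF_ATTR = re.compile(r'(\S+)\s+"([^"]*)"')


def _parse_attrs(field9: str, dialect: str) -> dict[str, str]:
    if dialect == "gtf":
        return dict(_GTF_ATTR.findall(field9))
    out = {}
    for part in field9.strip().split(";"):
        part = part.strip()
        if part and "=" in part:
            k, _, v = part.partition("=")
            out[k.strip()] = v.strip()
    return out


def _biotype_of(attrs: Mapping[str, str]) -> str:
    raw = (
        attrs.get("transcript_biotype")
        or attrs.get("gene_biotype")
        or attrs.get("biotype")
        or ""
    ).lower()
    if raw in ("protein_coding", "coding", "mrna"):
        return "coding"
    if raw in ("lncrna", "lincrna", "noncoding", "ncrna", "antisense"):
        return "noncoding"
    return "unknown"


def read_gtf(path: str | Path, dialect: str = "gtf") -> list[TranscriptModel]:
    """Parse transcript models from a GTF or GFF3 file.

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    Only ``exon`` rows build the chains; GFF3 ``mRNA``/``transcript`` rows are
    used to resolve Parent chains.  Unknown feature rows are skipped (count
    logged).  A '.' strand on an exon is an error: strand is semantically
    required downstream.
    """
    if dialect not in ("gtf", "gff3"):
        raise ValueError(f"dialect must be gtf or gff3, got {dialect!r}")
    path = Path(path)
    exons: dict[str, list[GenomicInterval]] = {}
    tx_gene: dict[str, str] = {}
    tx_biotype: dict[str, str] = {}
    declared_tx: list[str] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated fields")
            chrom, _, ftype, start_s, end_s, _, strand, _, attr_s = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end1 < start1:
                raise FormatError(f"{path}:{lineno}: end < start")
            attrs = _parse_attrs(attr_s, dialect)
            ftype_l = ftype.lower()
            if ftype_l == "exon":
                if strand not in STRANDS:
                    raise FormatError(
                        f"{path}:{lineno}: exon strand {strand!r} (strand is required)"
                    )
                if dialect == "gtf":
                    tid = attrs.get("transcript_id")
                    gid = attrs.get("gene_id")
                    if not tid or not gid:
                        raise FormatError(
                            f"{path}:{lineno}: exon lacks transcript_id/gene_id"
                        )
                else:
                    tid = attrs.get("Parent") or attrs.get("transcript_id")
                    if not tid:
                        raise FormatError(f"{path}:{lineno}: exon lacks Parent")
                    gid = tx_gene.get(tid, tid)
                exons.setdefault(tid, []).append(
                    GenomicInterval(chrom, start1 - 1, end1, strand)
                )
                tx_gene.setdefault(tid, gid)
                if tid not in tx_biotype or tx_biotype[tid] == "unknown":
                    tx_biotype[tid] = _biotype_of(attrs)
            elif ftype_l in ("transcript", "mrna"):
                if dialect == "gff3":
                    tid = attrs.get("ID")
                    gid = attrs.get("Parent") or attrs.get("gene_id") or tid
                else:
                    tid = attrs.get("transcript_id")
                    gid = attrs.get("gene_id") or tid
                if tid:
                    tx_gene[tid] = gid
                    declared_tx.append(tid)
                    bt = _biotype_of(attrs)
                    if bt != "unknown":
                        tx_biotype[tid] = bt
            else:
                skipped += 1
    if skipped:
        logger.info("read_gtf(%s): skipped %d non-transcript feature rows", path, skipped)
    for tid in declared_tx:
        if tid not in exons:
            raise FormatError(f"{path}: transcript {tid} has zero exon rows")
    models = []
    for tid, exs in exons.items():
        exs.sort(key=lambda e: e.start)
        span = GenomicInterval(exs[0].chrom, exs[0].start, exs[-1].end, exs[0].strand)
        models.append(
            TranscriptModel(tid, tx_gene[tid], span, tuple(exs), tx_biotype.get(tid, "unknown"))
        )
    return models


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    """Serialize transcript models as GTF exon rows (1-based inclusive)."""
    with open(path, "w") as fh:
        for tx in transcripts:
            for ex in tx.exons:
                attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
                if tx.biotype != "unknown":
                    bt = "protein_coding" if tx.biotype == "coding" else "lncRNA"
                    attrs += f' transcript_biotype "{bt}";'
                fh.write(
                    f"{ex.chrom}\tcernet\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{ex.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read sequences as uppercase RNA (T transliterated to U).

    Duplicate ids and non-IUPAC characters are errors.  N is legal; the
    interaction models treat it as never pairable and never seed-matching.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seq = str(rec.seq).upper().replace("T", "U")
        bad = set(seq) - IUPAC_NT
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} has non-IUPAC characters {sorted(bad)}"
            )
        out[rec.id] = seq
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Tabular
# ---------------------------------------------------------------------------


def read_abundance(
    path: str | Path,
    layer: str,
    unit: str,
    sample_to_group: Mapping[str, str],
    library_sizes: Mapping[str, float] | None = None,
) -> AbundanceMatrix:
    """Read a feature x sample TSV (header row of sample ids, first column id).

    Group assignment comes from the sidecar ``sample_to_group`` map; a header
    sample absent from the map, or a negative cell, is an error.  For raw
    counts the library sizes default to the column sums.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric abundance cell") from exc
    if (df.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative abundance value")
    ls = None
    if unit == "raw_count":
        if library_sizes is not None:
            ls = pd.Series({s: float(library_sizes[s]) for s in df.columns})
        else:
            ls = df.sum(axis=0)
    return AbundanceMatrix(layer, unit, df, dict(sample_to_group), ls)


def write_abundance(matrix: AbundanceMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="feature_id")


def read_coding_potential(path: str | Path) -> list[CodingPotentialRecord]:
    """Read a TSV with columns transcript_id, cnci_score, cpc2_probability."""
    df = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "cnci_score", "cpc2_probability"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: needs columns {sorted(required)}")
    return [
        CodingPotentialRecord(str(r.transcript_id), float(r.cnci_score), float(r.cpc2_probability))
        for r in df.itertuples(index=False)
    ]


def write_coding_potential(records: Iterable[CodingPotentialRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tcnci_score\tcpc2_probability\n")
        for r in records:
            fh.write(f"{r.transcript_id}\t{r.cnci_score:.6g}\t{r.cpc2_probability:.6g}\n")


@dataclass(frozen=True)
class NetworkEdge:
    """A typed edge for the serialized network table."""

    source: str
    source_layer: str
    target: str
    target_layer: str
    stat_name: str
    stat_value: float
    p: float | None = None
    q: float | None = None


def _fmt(x: float | None) -> str:
    return "NA" if x is None else format(float(x), ".6g")


def write_network_table(edges: Iterable[NetworkEdge], path: str | Path) -> None:
    """Write edges as TSV with a fixed column order and deterministic row order.

    The output is a pure function of the edge multiset: rows are sorted by
    every column, so shuffled input produces byte-identical files.
    """
    rows = [
        (
            e.source,
            e.source_layer,
            e.target,
            e.target_layer,
            e.stat_name,
            _fmt(e.stat_value),
            _fmt(e.p),
            _fmt(e.q),
        )
        for e in edges
    ]
    rows.sort()
    with open(path, "w") as fh:
        fh.write("source\tsource_layer\ttarget\ttarget_layer\tstat_name\tstat_value\tp\tq\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")
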