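"""Transcript class codes, novel-transcript filters, lncRNA calling, and the
five-way positional classification of lncRNAs against protein-coding genes.

Class codes follow the cuffcompare convention: a query transcript assembled
from RNA-seq is compared against the reference annotation and assigned the
single most specific spatial relation.  Novel transcripts are those with a
code in {u, i, j, x, c, e, o} that are longer than 200 nt (exonic) and have
more than one exon.  Candidates are called lncRNAs when both coding-potential
scores fall below their cutoffs (CNCI-style score < 0 AND CPC2-style coding
probability < 0.5); the two single-criterion sets are kept for Venn reporting.

Positional categories (relative to protein-coding genes, PCGs):

* intronic      - same strand, fully inside one intron of a PCG
* sense         - same strand, overlapping a PCG's exons/introns
* bidirectional - opposite strand, transcription start within a promoter
                  window upstream of a PCG's transcription start, no exonic
                  overlap (a divergent pair)
* antisense     - opposite strand, exonic overlap with a PCG
* intergenic    - no PCG overlap, flanked by PCGs on both sides
* unclassified  - anything else (e.g. a chromosome end with no flanking PCG)

Both classifiers resolve ambiguity with a fixed precedence (most specific
spatial relation first), so the output is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import CodingPotentialRecord, TranscriptModel

NOVEL_CODES = frozenset("uijxceo")

POSITION_CATEGORIES = (
    "intergenic",
    "bidirectional",
    "intronic",
    "antisense",
    "sense",
    "unclassified",
)


@dataclass(frozen=True)
class ClassCode:
    """A cuffcompare-style class code; '=' carries the matched reference id,
    'u' never does."""

    code: str
    reference_transcript_id: str | None = None

    def __post_init__(self) -> None:
        if self.code == "=" and self.reference_transcript_id is None:
            raise ValueError("code '=' requires a reference transcript id")
        if self.code == "u" and self.reference_transcript_id is not None:
            raise ValueError("code 'u' admits no reference transcript id")


@dataclass(frozen=True)
class LncRNAClass:
    category: str
    anchor_gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.category not in POSITION_CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category in ("intergenic", "unclassified") and self.anchor_gene_id:
            raise ValueError(f"{self.category} carries no anchor gene")
        if self.category not in ("intergenic", "unclassified") and not self.anchor_gene_id:
            raise ValueError(f"{self.category} requires an anchor gene")


@dataclass(frozen=True)
class LncRNARecord:
    transcript_id: str
    model: TranscriptModel
    lnc_class: LncRNAClass
    scores: CodingPotentialRecord


# ---------------------------------------------------------------------------
# class codes
# ---------------------------------------------------------------------------


def _exonic_overlap(a: TranscriptModel, b: TranscriptModel) -> bool:
    return any(ea.overlaps(eb) for ea in a.exons for eb in b.exons)


def _is_subchain(sub: tuple, full: tuple) -> bool:
    """True when ``sub`` is a contiguous subsequence of ``full`` (empty: yes)."""
    if not sub:
        return True
    n, m = len(sub), len(full)
    return any(full[i : i + n] == sub for i in range(m - n + 1))


def assign_class_code(
    query: TranscriptModel, reference: list[TranscriptModel]
) -> ClassCode:
    """Assign the most specific class code of ``query`` against a reference set.

    Precedence (first match wins): '=' exact intron chain, 'c' contained with
    compatible chain, 'j' shared splice junction, 'e' single-exon exonic
    overlap running into the adjacent intron, 'o' generic same-strand exonic
    overlap, 'x' opposite-strand exonic overlap, 'i' fully intronic,
    'u' no overlap at all, else 'other'.  References are scanned in input
    order within each precedence level, so the result is deterministic.
    """
    qspan = query.interval
    qintrons = query.introns
    same = [
        r
        for r in reference
        if r.interval.chrom == qspan.chrom and r.interval.strand == qspan.strand
    ]
    anti = [
        r
        for r in reference
        if r.interval.chrom == qspan.chrom and r.interval.strand != qspan.strand
    ]

    for r in same:  # '='
        if qspan.overlaps(r.interval) and qintrons == r.introns:
            return ClassCode("=", r.transcript_id)
    for r in same:  # 'c': intron-compatible containment (no retained intron)
        if (
            r.interval.contains(qspan)
            and _is_subchain(qintrons, r.introns)
            and all(any(re.contains(qe) for re in r.exons) for qe in query.exons)
        ):
            return ClassCode("c", r.transcript_id)
    for r in same:  # 'j'
        if set(qintrons) & set(r.introns):
            return ClassCode("j", r.transcript_id)
    if len(query.exons) == 1:  # 'e'
        for r in same:
            for k, ex in enumerate(r.exons):
                if qspan.overlaps(ex):
                    left_intron = k > 0 and qspan.start < ex.start
                    right_intron = k < len(r.exons) - 1 and qspan.end > ex.end
                    if left_intron or right_intron:
                        return ClassCode("e", r.transcript_id)
    for r in same:  # 'o'
        if _exonic_overlap(query, r):
            return ClassCode("o", r.transcript_id)
    for r in anti:  # 'x'
        if _exonic_overlap(query, r):
            return ClassCode("x", r.transcript_id)
    for r in same:  # 'i'
        for istart, iend in r.introns:
            if qspan.start >= istart and qspan.end <= iend:
                return ClassCode("i", r.transcript_id)
    if not any(qspan.overlaps(r.interval) for r in reference):  # 'u'
        return ClassCode("u", None)
    return ClassCode("other", None)


def filter_novel(
    transcripts: list[TranscriptModel],
    class_codes: dict[str, ClassCode],
    min_length: int = 200,
    min_exons: int = 1,
) -> list[TranscriptModel]:
    """Keep transcripts with a novel-eligible code, exonic length strictly
    above ``min_length`` and exon count strictly above ``min_exons``."""
    out = []
    for tx in transcripts:
        code = class_codes[tx.transcript_id]
        if (
            code.code in NOVEL_CODES
            and tx.exonic_length > min_length
            and len(tx.exons) > min_exons
        ):
            out.append(tx)
    return out


# ---------------------------------------------------------------------------
# lncRNA calling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LncRNACallResult:
    """The called set plus the two single-criterion sets for Venn reporting."""

    called: frozenset[str]
    cnci_set: frozenset[str]
    cpc2_set: frozenset[str]

    def venn_summary(self) -> dict[str, int]:
        return {
            "cnci_only": len(self.cnci_set - self.cpc2_set),
            "cpc2_only": len(self.cpc2_set - self.cnci_set),
            "both": len(self.called),
        }


def call_lncrnas(
    candidates: list[str],
    scores: list[CodingPotentialRecord],
    cnci_max: float = 0.0,
    cpc2_max: float = 0.5,
) -> LncRNACallResult:
    """Call lncRNAs as the intersection of the two coding-potential criteria
    (strict inequalities).  Every candidate must have a score record."""
    by_id = {s.transcript_id: s for s in scores}
    missing = [c for c in candidates if c not in by_id]
    if missing:
        raise ValueError(f"candidates without coding-potential scores: {missing[:10]}")
    cnci = frozenset(c for c in candidates if by_id[c].cnci_score < cnci_max)
    cpc2 = frozenset(c for c in candidates if by_id[c].cpc2_probability < cpc2_max)
    return LncRNACallResult(cnci & cpc2, cnci, cpc2)


# ---------------------------------------------------------------------------
# positional classification
# ---------------------------------------------------------------------------


def _tss_upstream_within(lnc: TranscriptModel, pcg: TranscriptModel, window: int) -> bool:
    """lnc TSS within ``window`` bp upstream of the PCG TSS (PCG orientation)."""
    if pcg.interval.strand == "+":
        return pcg.tss - window <= lnc.tss <= pcg.tss
    return pcg.tss <= lnc.tss <= pcg.tss + window


def classify_lncrna_position(
    lnc: TranscriptModel,
    pcgs: list[TranscriptModel],
    promoter_window: int = 1000,
) -> LncRNAClass:
    """Classify a lncRNA by position relative to protein-coding genes.

    Precedence: intronic > sense > bidirectional > antisense > intergenic >
    unclassified.  The classification is invariant under translating all
    coordinates by a constant.
    """
    span = lnc.interval
    here = [p for p in pcgs if p.interval.chrom == span.chrom]
    same = [p for p in here if p.interval.strand == span.strand]
    anti = [p for p in here if p.interval.strand != span.strand]

    for p in same:  # intronic
        if any(span.start >= s and span.end <= e for s, e in p.introns):
            return LncRNAClass("intronic", p.gene_id)
    for p in same:  # sense
        if span.overlaps(p.interval):
            return LncRNAClass("sense", p.gene_id)
    for p in anti:  # bidirectional
        if _tss_upstream_within(lnc, p, promoter_window) and not _exonic_overlap(lnc, p):
            return LncRNAClass("bidirectional", p.gene_id)
    for p in anti:  # antisense
        if _exonic_overlap(lnc, p):
            return LncRNAClass("antisense", p.gene_id)
    if not any(span.overlaps(p.interval) for p in here):
        has_left = any(p.interval.end <= span.start for p in here)
        has_right = any(p.interval.start >= span.end for p in here)
        if has_left and has_right:
            return LncRNAClass("intergenic", None)
    return LncRNAClass("unclassified", None)
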