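"""The three direct lncRNA-to-mRNA acting models.

* antisense - an opposite-strand lncRNA hybridizes with its host mRNA; the
  evidence is a minimum-free-energy RNA-RNA duplex.
* cis       - the lncRNA sits near a protein-coding gene on the chromosome;
  the evidence is genomic distance.
* trans     - the lncRNA is tightly co-expressed with a distant gene; the
  evidence is a Pearson correlation above a stringent cutoff (r > 0.999, a
  deliberately extreme threshold that at n = 9 essentially demands an exact
  monotone-linear relationship).

The duplex energy model is a compact stacking-free table (GC -3, AU -2,
GU -1, in arbitrary units) with a +2 penalty per single-nucleotide bulge and
no intramolecular structure; it is injectable, and the downstream analysis
only thresholds relative energies.  The dynamic program is a local
hybridization recurrence over antiparallel alignments, so flanking
unpairable sequence never changes the optimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_formats import AbundanceMatrix, TranscriptModel
from .lncrna_identification import LncRNARecord

logger = logging.getLogger(__name__)

_INF = float("inf")


def _symmetric(pairs: Mapping[tuple[str, str], float]) -> dict[tuple[str, str], float]:
    out = dict(pairs)
    for (a, b), e in pairs.items():
        out[(b, a)] = e
    return out


@dataclass(frozen=True)
class EnergyModel:
    """Pair energies (negative = favorable) and the bulge penalty."""

    pair_energies: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: _symmetric({("G", "C"): -3.0, ("A", "U"): -2.0, ("G", "U"): -1.0})
    )
    bulge_penalty: float = 2.0
    max_bulge: int = 1

    def __post_init__(self) -> None:
        if any(e >= 0 for e in self.pair_energies.values()):
            raise ValueError("pair energies must be negative")
        if self.bulge_penalty <= 0:
            raise ValueError("bulge penalty must be positive")

    def energy(self, a: str, b: str) -> float:
        """Pairing energy, +inf when unpairable (N pairs with nothing)."""
        return self.pair_energies.get((a, b), _INF)


DEFAULT_ENERGY = EnergyModel()


@dataclass(frozen=True)
class DuplexResult:
    query_id: str
    target_id: str
    mfe: float
    query_span: tuple[int, int] | None  # 0-based half-open on the query
    target_span: tuple[int, int] | None  # 0-based half-open on the target
    n_pairs: int
    paired_fraction: float


@dataclass(frozen=True)
class ActingEdge:
    lncrna_id: str
    gene_id: str
    model: str  # {antisense, cis, trans}
    statistic: float  # mfe | signed distance bp | Pearson r


def duplex_mfe(
    seq_a: str,
    seq_b: str,
    model: EnergyModel = DEFAULT_ENERGY,
    query_id: str = "",
    target_id: str = "",
) -> DuplexResult:
    """Best local antiparallel duplex between two RNAs under the pair table.

    With b' = reverse(seq_b), H(i, j) is the best energy of a duplex ending
    in the pair (a_i, b'_j), extended by a stack (i-1, j-1) or a 1-nt bulge
    on either side at +bulge_penalty, or started fresh.  The overall MFE is
    min(0, min H): 0 means no favorable duplex exists.  Ties in the traceback
    prefer the longer stack, then the smaller query index, then the smaller
    (reversed) target index.
    """
    if not seq_a or not seq_b:
        raise ValueError("duplex_mfe requires non-empty sequences")
    a = seq_a
    br = seq_b[::-1]
    n, m = len(a), len(br)
    beta = model.bulge_penalty
    H = np.full((n, m), _INF)
    npairs = np.zeros((n, m), dtype=int)  # pairs on the optimal path into (i,j)
    start = np.empty((n, m, 2), dtype=int)  # duplex start cell for traceback
    for i in range(n):
        for j in range(m):
            e = model.energy(a[i], br[j])
            if e == _INF:
                continue
            # candidates: (prev_energy, -pairs, is_not_stack, i, j) for tie-breaks
            best_prev = 0.0
            best_key = (0.0, 0, 1, i, j)  # fresh start
            best_cell = (i, j)
            best_np = 1
            options = []
            if i >= 1 and j >= 1 and H[i - 1, j - 1] < _INF:
                options.append((H[i - 1, j - 1], i - 1, j - 1, 0))
            if i >= 2 and j >= 1 and H[i - 2, j - 1] < _INF:
                options.append((H[i - 2, j - 1] + beta, i - 2, j - 1, 1))
            if i >= 1 and j >= 2 and H[i - 1, j - 2] < _INF:
                options.append((H[i - 1, j - 2] + beta, i - 1, j - 2, 1))
            for prev_e, pi, pj, bulged in options:
                key = (prev_e, -npairs[pi, pj], bulged, pi, pj)
                if key < best_key:
                    best_key = key
                    best_prev = prev_e
                    best_cell = tuple(start[pi, pj])
                    best_np = npairs[pi, pj] + 1
            H[i, j] = e + best_prev
            npairs[i, j] = best_np
            start[i, j] = best_cell
    # pick the global optimum with deterministic tie-breaking
    best = (0.0, 0, -1, -1)  # (energy, -pairs, i, j); energy 0 = empty duplex
    for i in range(n):
        for j in range(m):
            if H[i, j] < _INF:
                cand = (H[i, j], -npairs[i, j], i, j)
                if cand < best:
                    best = cand
    mfe, negp, bi, bj = best
    if bi < 0 or mfe >= 0:
        return DuplexResult(query_id, target_id, 0.0, None, None, 0, 0.0)
    si, sj = start[bi, bj]
    qspan = (int(si), int(bi) + 1)
    # j indexes reversed b; map back to the original orientation
    tspan = (int(m - 1 - bj), int(m - 1 - sj) + 1)
    k = int(-negp)
    return DuplexResult(
        query_id, target_id, float(mfe), qspan, tspan, k, k / min(n, m)
    )


# ---------------------------------------------------------------------------
# edge builders
# ---------------------------------------------------------------------------


def antisense_edges(
    lncrnas: Sequence[LncRNARecord],
    lnc_seqs: Mapping[str, str],
    mrna_seqs: Mapping[str, str],
    mfe_max: float = -10.0,
    min_paired_fraction: float = 0.5,
    model: EnergyModel = DEFAULT_ENERGY,
) -> list[ActingEdge]:
    """Duplex-supported edges from antisense lncRNAs to their anchor genes.

    An edge is emitted when the lncRNA-mRNA duplex MFE is <= ``mfe_max`` and
    the number of paired bases reaches ``min_paired_fraction`` of the shorter
    of the lncRNA and a 50-nt window.
    """
    edges = []
    for rec in lncrnas:
        if rec.lnc_class.category != "antisense":
            continue
        gene = rec.lnc_class.anchor_gene_id
        lseq = lnc_seqs.get(rec.transcript_id)
        gseq = mrna_seqs.get(gene)
        if lseq is None or gseq is None:
            logger.warning(
                "antisense_edges: missing sequence for %s / %s, skipped",
                rec.transcript_id,
                gene,
            )
            continue
        d = duplex_mfe(lseq, gseq, model, rec.transcript_id, gene)
        need = min_paired_fraction * min(len(lseq), 50)
        if d.mfe <= mfe_max and d.n_pairs >= need:
            edges.append(ActingEdge(rec.transcript_id, gene, "antisense", d.mfe))
    return edges


def _signed_distance(lnc: TranscriptModel, pcg: TranscriptModel) -> int:
    """Gap between spans; 0 when overlapping, positive when the PCG lies
    downstream of the lncRNA (higher coordinates), negative upstream."""
    if lnc.interval.overlaps(pcg.interval):
        return 0
    if pcg.interval.start >= lnc.interval.end:
        return pcg.interval.start - lnc.interval.end
    return -(lnc.interval.start - pcg.interval.end)


def cis_edges(
    lncrnas: Sequence[TranscriptModel],
    pcgs: Sequence[TranscriptModel],
    window: int = 10_000,
) -> list[ActingEdge]:
    """Neighborhood edges: every PCG within ``window`` bp of (or overlapping)
    a lncRNA span on the same chromosome, any strand."""
    edges = []
    for lnc in lncrnas:
        for pcg in pcgs:
            if pcg.interval.chrom != lnc.interval.chrom:
                continue
            d = _signed_distance(lnc, pcg)
            if abs(d) <= window:
                edges.append(ActingEdge(lnc.transcript_id, pcg.gene_id, "cis", float(d)))
    return edges


def trans_edges(
    lnc_expr: AbundanceMatrix,
    mrna_expr: AbundanceMatrix,
    r_min: float = 0.999,
    exclude_pairs: set[tuple[str, str]] | None = None,
    sign: str = "positive",
) -> list[ActingEdge]:
    """Co-expression edges with Pearson r strictly above ``r_min``.

    ``sign='negative'`` reports instead the pairs with r < -r_min (kept
    separate: only positive co-expression is a trans call).  Pairs already
    explained by a cis edge can be excluded via ``exclude_pairs``.
    Zero-variance features are skipped (count logged).
    """
    if list(lnc_expr.sample_ids) != list(mrna_expr.sample_ids):
        raise ValueError("matrices must share identical sample columns")
    if len(lnc_expr.sample_ids) < 3:
        raise ValueError("trans correlation needs >= 3 samples")
    if sign not in ("positive", "negative"):
        raise ValueError("sign must be 'positive' or 'negative'")
    X = lnc_expr.data.to_numpy(float)
    Y = mrna_expr.data.to_numpy(float)
    xs = X.std(axis=1)
    ys = Y.std(axis=1)
    skipped = int((xs == 0).sum() + (ys == 0).sum())
    if skipped:
        logger.info("trans_edges: skipped %d zero-variance features", skipped)
    n = X.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        Xz = (X - X.mean(axis=1, keepdims=True)) / np.where(xs == 0, np.nan, xs)[:, None]
        Yz = (Y - Y.mean(axis=1, keepdims=True)) / np.where(ys == 0, np.nan, ys)[:, None]
    R = Xz @ Yz.T / n
    lnc_ids = lnc_expr.feature_ids
    gene_ids = mrna_expr.feature_ids
    hits = np.argwhere(R > r_min) if sign == "positive" else np.argwhere(R < -r_min)
    edges = []
    for i, j in hits:
        pair = (lnc_ids[i], gene_ids[j])
        if exclude_pairs and pair in exclude_pairs:
            continue
        edges.append(ActingEdge(pair[0], pair[1], "trans", float(R[i, j])))
    return edges
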