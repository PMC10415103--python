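"""Independent brute-force reference implementations used as test oracles.

Everything here deliberately avoids the package's own algorithmic routes:
duplex energies come from exhaustive structure enumeration, BH from a
quadratic scan, interval relations from explicit base-position sets, and
hypergeometric tails from direct pmf summation.
"""

from __future__ import annotations

import math

from cernet.interaction_models import EnergyModel
from cernet.io_formats import TranscriptModel


# --- duplex -----------------------------------------------------------------


def duplex_mfe_bruteforce(seq_a: str, seq_b: str, model: EnergyModel) -> float:
    """Minimum energy over every antiparallel duplex structure: ordered pair
    chains advancing by (1,1) stacks or (2,1)/(1,2) single-nt bulges."""
    a, br = seq_a, seq_b[::-1]
    n, m = len(a), len(br)
    beta = model.bulge_penalty

    def pe(i: int, j: int) -> float | None:
        e = model.pair_energies.get((a[i], br[j]))
        return e

    best = 0.0

    def rec(i: int, j: int, acc: float) -> None:
        nonlocal best
        if acc < best:
            best = acc
        for di, dj, pen in ((1, 1, 0.0), (2, 1, beta), (1, 2, beta)):
            ni, nj = i + di, j + dj
            if ni < n and nj < m:
                e = pe(ni, nj)
                if e is not None:
                    rec(ni, nj, acc + pen + e)

    for i in range(n):
        for j in range(m):
            e = pe(i, j)
            if e is not None:
                rec(i, j, e)
    return best


# --- BH ---------------------------------------------------------------------


def bh_quadratic(p: list[float]) -> list[float]:
    """O(m^2) Benjamini-Hochberg: q_i = min over p_j >= p_i of p_j * m / k_j
    with k_j the count of p-values <= p_j."""
    m = len(p)
    out = []
    for pi in p:
        candidates = []
        for pj in p:
            if pj >= pi:
                k = sum(1 for x in p if x <= pj)
                candidates.append(pj * m / k)
        out.append(min(1.0, min(candidates)))
    return out


# --- hypergeometric ---------------------------------------------------------


def hypergeom_tail(k: int, M: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(M, K, n) by direct pmf summation."""
    total = 0.0
    denom = math.comb(M, n)
    for x in range(max(k, 0), min(K, n) + 1):
        total += math.comb(K, x) * math.comb(M - K, n - x) / denom
    return min(1.0, total)


# --- rank correlation -------------------------------------------------------


def average_ranks(values: list[float]) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def spearman_bruteforce(x: list[float], y: list[float]) -> float:
    rx, ry = average_ranks(list(x)), average_ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    dx = math.sqrt(sum((a - mx) ** 2 for a in rx))
    dy = math.sqrt(sum((b - my) ** 2 for b in ry))
    return num / (dx * dy)


# --- interval relations via explicit base sets ------------------------------


def _bases(tx: TranscriptModel) -> set[int]:
    out: set[int] = set()
    for ex in tx.exons:
        out.update(range(ex.start, ex.end))
    return out


def _span(tx: TranscriptModel) -> set[int]:
    return set(range(tx.interval.start, tx.interval.end))


def class_code_oracle(query: TranscriptModel, refs: list[TranscriptModel]) -> str:
    """Class-code assignment re-derived from base-position sets."""
    q_bases, q_span = _bases(query), _span(query)
    qint = query.introns

    def same(r):
        return r.interval.chrom == query.interval.chrom and r.interval.strand == query.interval.strand

    def anti(r):
        return r.interval.chrom == query.interval.chrom and r.interval.strand != query.interval.strand

    def span_overlap(r):
        return r.interval.chrom == query.interval.chrom and bool(q_span & _span(r))

    def exonic(r):
        return bool(q_bases & _bases(r))

    for r in refs:
        if same(r) and span_overlap(r) and qint == r.introns:
            return "="
    for r in refs:
        if not same(r):
            continue
        contained = q_span <= _span(r) and q_bases <= _bases(r)
        sub = any(
            r.introns[i : i + len(qint)] == qint for i in range(len(r.introns) - len(qint) + 1)
        ) or not qint
        if contained and sub:
            return "c"
    for r in refs:
        if same(r) and set(qint) & set(r.introns):
            return "j"
    if len(query.exons) == 1:
        for r in refs:
            if not same(r):
                continue
            for k, ex in enumerate(r.exons):
                ex_b = set(range(ex.start, ex.end))
                if q_span & ex_b:
                    into_left = k > 0 and query.interval.start < ex.start
                    into_right = k < len(r.exons) - 1 and query.interval.end > ex.end
                    if into_left or into_right:
                        return "e"
    for r in refs:
        if same(r) and exonic(r):
            return "o"
    for r in refs:
        if anti(r) and exonic(r):
            return "x"
    for r in refs:
        if same(r):
            for s, e in r.introns:
                if q_span <= set(range(s, e)):
                    return "i"
    if not any(span_overlap(r) for r in refs):
        return "u"
    return "other"


def classify_position_oracle(
    lnc: TranscriptModel, pcgs: list[TranscriptModel], window: int = 1000
) -> str:
    l_span, l_bases = _span(lnc), _bases(lnc)
    here = [p for p in pcgs if p.interval.chrom == lnc.interval.chrom]
    same = [p for p in here if p.interval.strand == lnc.interval.strand]
    anti = [p for p in here if p.interval.strand != lnc.interval.strand]
    for p in same:
        if any(l_span <= set(range(s, e)) for s, e in p.introns):
            return "intronic"
    for p in same:
        if l_span & _span(p):
            return "sense"
    l_tss = lnc.interval.start if lnc.interval.strand == "+" else lnc.interval.end
    for p in anti:
        p_tss = p.interval.start if p.interval.strand == "+" else p.interval.end
        prom = (
            set(range(p_tss - window, p_tss + 1))
            if p.interval.strand == "+"
            else set(range(p_tss, p_tss + window + 1))
        )
        if l_tss in prom and not (l_bases & _bases(p)):
            return "bidirectional"
    for p in anti:
        if l_bases & _bases(p):
            return "antisense"
    if not any(l_span & _span(p) for p in here):
        left = any(p.interval.end <= lnc.interval.start for p in here)
        right = any(p.interval.start >= lnc.interval.end for p in here)
        if left and right:
            return "intergenic"
    return "unclassified"


# --- random mini-genomes ----------------------------------------------------


def random_transcript(rng, tid: str, chrom: str, biotype: str = "unknown") -> TranscriptModel:
    from cernet.io_formats import GenomicInterval

    strand = "+" if rng.random() < 0.5 else "-"
    n_ex = int(rng.integers(1, 4))
    pos = int(rng.integers(0, 1500))
    exons = []
    for _ in range(n_ex):
        length = int(rng.integers(20, 150))
        exons.append(GenomicInterval(chrom, pos, pos + length, strand))
        pos += length + int(rng.integers(10, 120))
    span = GenomicInterval(chrom, exons[0].start, exons[-1].end, strand)
    return TranscriptModel(tid, f"g_{tid}", span, tuple(exons), biotype)
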