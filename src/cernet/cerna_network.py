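"""miRNA response element (MRE) prediction, the sign-constrained correlation
rules for competing-endogenous-RNA (ceRNA) triads, metabolite attachment,
and generic set enrichment.

A ceRNA triad (lncRNA, miRNA, mRNA) is emitted when

1. the miRNA has at least one MRE on the lncRNA AND on the mRNA (the sponge
   geometry: both transcripts carry the same seed-complementary site);
2. the miRNA is negatively Spearman-correlated with both the lncRNA and the
   mRNA (rho <= -scc_min, p <= p_max);
3. the lncRNA and the mRNA are positively correlated (rho >= +scc_min,
   p <= p_max);
4. the overlap between the miRNA sets bound by the lncRNA and targeting the
   mRNA is larger than chance: a hypergeometric upper tail over the universe
   of expressed miRNAs, BH-corrected across all tested (lncRNA, mRNA) pairs
   (q <= q_max).

The MRE definition is a perfect Watson-Crick reverse complement of the
miRNA seed (positions 2-8 from the 5' end), with G:U wobbles disallowed in
the seed; N never matches.  Correlation defaults (|rho| >= 0.7, p <= 0.05)
are stringent for n = 9 samples and are configuration-exposed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .differential import benjamini_hochberg
from .io_formats import AbundanceMatrix

logger = logging.getLogger(__name__)

_RC = {"A": "U", "U": "A", "G": "C", "C": "G"}

SEED_START, SEED_END = 1, 8  # python slice of miRNA positions 2..8 (1-based)


@dataclass(frozen=True)
class MREHit:
    mirna_id: str
    host_id: str
    host_layer: str  # {lncRNA, mRNA}
    site_start: int  # 0-based on the host
    match_type: str = "seed7"
    duplex_mfe: float | None = None


@dataclass(frozen=True)
class CeRNATriad:
    lncrna_id: str
    mirna_id: str
    mrna_id: str
    scc_mi_lnc: float
    scc_mi_mrna: float
    scc_lnc_mrna: float
    enrichment_p: float
    enrichment_q: float

    def __post_init__(self) -> None:
        if not (self.scc_mi_lnc < 0 and self.scc_mi_mrna < 0 and self.scc_lnc_mrna > 0):
            raise ValueError("triad violates the ceRNA sign constraints")


@dataclass(frozen=True)
class MetaboliteEdge:
    rna_id: str
    rna_layer: str
    metabolite_id: str
    scc: float
    p: float
    significance_tier: str  # {***, **, *, ns}


def significance_tier(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# MRE prediction
# ---------------------------------------------------------------------------


def reverse_complement(seq: str) -> str:
    return "".join(_RC.get(c, "N") for c in reversed(seq))


def predict_mre(
    mirna_seq: str,
    host_seq: str,
    mirna_id: str = "",
    host_id: str = "",
    host_layer: str = "mRNA",
    refine_energy: bool = False,
    energy_model=None,
) -> list[MREHit]:
    """All perfect seed-complementary sites of a miRNA on a host transcript.

    The site motif is the reverse complement of miRNA positions 2-8;
    overlapping occurrences each count.  A seed containing N never matches.
    Optionally each site is refined with the duplex MFE of the full miRNA
    against a 30-nt window centered on the site.
    """
    if len(mirna_seq) < 8:
        raise ValueError(f"miRNA {mirna_id!r} shorter than 8 nt")
    seed = mirna_seq[SEED_START:SEED_END]
    if "N" in seed:
        return []
    motif = reverse_complement(seed)
    hits = []
    pos = host_seq.find(motif)
    while pos != -1:
        mfe = None
        if refine_energy:
            from .interaction_models import DEFAULT_ENERGY, duplex_mfe

            lo = max(0, pos + 3 - 15)
            window = host_seq[lo : lo + 30]
            mfe = duplex_mfe(mirna_seq, window, energy_model or DEFAULT_ENERGY).mfe
        hits.append(MREHit(mirna_id, host_id, host_layer, pos, "seed7", mfe))
        pos = host_seq.find(motif, pos + 1)
    return hits


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def spearman_cc(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Average-rank Spearman rho with the t approximation on n-2 df.

    Ties get average ranks.  Zero rank variance in either vector yields
    (nan, 1.0) with a warning.  |rho| = 1 yields p = 0.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("spearman_cc needs two equal-length vectors, n >= 3")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        logger.warning("spearman_cc: zero rank variance, correlation undefined")
        return float("nan"), 1.0
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if abs(rho) >= 1.0:
        return float(np.sign(rho)), 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(min(p, 1.0))


def shared_mre_enrichment(
    lnc_mirnas: set[str], mrna_mirnas: set[str], universe_size: int
) -> float:
    """Hypergeometric upper tail P(X >= k) for the shared-miRNA count.

    Drawing |lnc_mirnas| from a universe of ``universe_size`` expressed
    miRNAs of which |mrna_mirnas| are successes.
    """
    if len(lnc_mirnas | mrna_mirnas) > universe_size:
        raise ValueError("miRNA sets exceed the declared universe")
    k = len(lnc_mirnas & mrna_mirnas)
    return float(stats.hypergeom.sf(k - 1, universe_size, len(mrna_mirnas), len(lnc_mirnas)))


# ---------------------------------------------------------------------------
# triad assembly
# ---------------------------------------------------------------------------


def build_cerna_triads(
    mre_hits: Iterable[MREHit],
    expr: Mapping[str, AbundanceMatrix],
    de_sets: Mapping[str, set[str]] | None = None,
    scc_min: float = 0.7,
    p_max: float = 0.05,
    q_max: float = 0.05,
    universe_size: int | None = None,
) -> list[CeRNATriad]:
    """Assemble ceRNA triads from MRE hits and per-layer expression.

    ``expr`` maps layer -> AbundanceMatrix; the three RNA layers must share
    the same sample columns.  When ``de_sets`` is given, candidate members
    are restricted to the differentially expressed features of their layer
    (the union over comparisons).  The enrichment universe defaults to the
    number of miRNAs in the miRNA expression matrix.
    """
    lnc_m, mi_m, mrna_m = expr["lncRNA"], expr["miRNA"], expr["mRNA"]
    samples = list(lnc_m.sample_ids)
    if list(mi_m.sample_ids) != samples or list(mrna_m.sample_ids) != samples:
        raise ValueError("expression layers must share sample columns")
    if universe_size is None:
        universe_size = len(mi_m.feature_ids)

    def in_scope(layer: str, fid: str) -> bool:
        return de_sets is None or fid in de_sets.get(layer, set())

    lnc_sites: dict[str, set[str]] = {}
    mrna_sites: dict[str, set[str]] = {}
    dropped: set[str] = set()
    for hit in mre_hits:
        table = lnc_sites if hit.host_layer == "lncRNA" else mrna_sites
        host_expr = lnc_m if hit.host_layer == "lncRNA" else mrna_m
        if not (in_scope(hit.host_layer, hit.host_id) and in_scope("miRNA", hit.mirna_id)):
            continue
        if hit.host_id not in host_expr.data.index or hit.mirna_id not in mi_m.data.index:
            dropped.add(hit.host_id if hit.host_id not in host_expr.data.index else hit.mirna_id)
            continue
        table.setdefault(hit.host_id, set()).add(hit.mirna_id)
    if dropped:
        logger.info("build_cerna_triads: dropped candidates without expression: %s",
                    sorted(dropped)[:10])

    # enrichment over all tested (lnc, mrna) pairs = pairs sharing >= 1 miRNA
    pairs = []
    pvals = []
    for lnc_id, lset in sorted(lnc_sites.items()):
        for mrna_id, rset in sorted(mrna_sites.items()):
            shared = lset & rset
            if not shared:
                continue
            pairs.append((lnc_id, mrna_id, tuple(sorted(shared))))
            pvals.append(shared_mre_enrichment(lset, rset, universe_size))
    if not pairs:
        return []
    qvals = benjamini_hochberg(pvals)

    scc_cache: dict[tuple[str, str, str, str], tuple[float, float]] = {}

    def scc(layer_a: str, fa: str, layer_b: str, fb: str) -> tuple[float, float]:
        key = (layer_a, fa, layer_b, fb)
        if key not in scc_cache:
            va = expr[layer_a].data.loc[fa, samples].to_numpy(float)
            vb = expr[layer_b].data.loc[fb, samples].to_numpy(float)
            scc_cache[key] = spearman_cc(va, vb)
        return scc_cache[key]

    triads = []
    for (lnc_id, mrna_id, shared), p_enr, q_enr in zip(pairs, pvals, qvals):
        if q_enr > q_max:
            continue
        r_lm, p_lm = scc("lncRNA", lnc_id, "mRNA", mrna_id)
        if not (r_lm >= scc_min and p_lm <= p_max):
            continue
        for mi in shared:
            r_ml, p_ml = scc("miRNA", mi, "lncRNA", lnc_id)
            r_mr, p_mr = scc("miRNA", mi, "mRNA", mrna_id)
            if (
                r_ml <= -scc_min
                and p_ml <= p_max
                and r_mr <= -scc_min
                and p_mr <= p_max
            ):
                triads.append(
                    CeRNATriad(lnc_id, mi, mrna_id, r_ml, r_mr, r_lm, p_enr, float(q_enr))
                )
    return triads


def attach_metabolites(
    triads: Sequence[CeRNATriad],
    rna_expr: Mapping[str, AbundanceMatrix],
    metab: AbundanceMatrix,
) -> list[MetaboliteEdge]:
    """Spearman edges between every RNA appearing in a triad and every
    metabolite.  No sign constraint is imposed; each edge carries a
    significance tier (*** p<=0.001, ** p<=0.01, * p<=0.05, else ns)."""
    samples = list(metab.sample_ids)
    members: list[tuple[str, str]] = []
    seen = set()
    for t in triads:
        for fid, layer in ((t.lncrna_id, "lncRNA"), (t.mirna_id, "miRNA"), (t.mrna_id, "mRNA")):
            if (fid, layer) not in seen:
                seen.add((fid, layer))
                members.append((fid, layer))
    edges = []
    for fid, layer in members:
        v = rna_expr[layer].data.loc[fid, samples].to_numpy(float)
        for met in metab.feature_ids:
            w = metab.data.loc[met, samples].to_numpy(float)
            rho, p = spearman_cc(v, w)
            tier = "ns" if np.isnan(rho) else significance_tier(p)
            edges.append(MetaboliteEdge(fid, layer, met, float(rho), float(p), tier))
    return edges


# ---------------------------------------------------------------------------
# enrichment + export
# ---------------------------------------------------------------------------


def enrich_terms(
    feature_set: set[str],
    annotation: Mapping[str, set[str]],
    universe: set[str],
) -> list[tuple[str, int, int, float, float]]:
    """Generic hypergeometric set enrichment with BH correction.

    Returns (term, k, K, p, q) rows for terms with k >= 1, sorted by p then
    term name.  Term annotations are user-supplied; no database ships here.
    """
    if not universe:
        raise ValueError("empty universe")
    if not feature_set <= universe:
        raise ValueError("feature set must be a subset of the universe")
    n_u, n_s = len(universe), len(feature_set)
    rows = []
    for term in sorted(annotation):
        members = annotation[term] & universe
        k = len(feature_set & members)
        if k == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, n_u, len(members), n_s))
        rows.append([term, k, len(members), p])
    if not rows:
        return []
    q = benjamini_hochberg([r[3] for r in rows])
    out = [(r[0], r[1], r[2], r[3], float(qi)) for r, qi in zip(rows, q)]
    out.sort(key=lambda r: (r[3], r[0]))
    return out


def export_sankey(
    triads: Sequence[CeRNATriad],
    metabolite_edges: Sequence[MetaboliteEdge],
    path: str | Path,
) -> None:
    """Four-column flow TSV (lncRNA -> miRNA -> mRNA -> metabolite).

    One row per complete chain; a triad whose mRNA has no significant
    metabolite edge gets a row with an empty metabolite field.  Rows are
    sorted, so shuffled input yields byte-identical output.
    """
    by_mrna: dict[str, list[str]] = {}
    for e in metabolite_edges:
        if e.rna_layer == "mRNA" and e.significance_tier != "ns":
            by_mrna.setdefault(e.rna_id, []).append(e.metabolite_id)
    rows = []
    for t in triads:
        mets = sorted(set(by_mrna.get(t.mrna_id, [])))
        if mets:
            rows.extend((t.lncrna_id, t.mirna_id, t.mrna_id, m) for m in mets)
        else:
            rows.append((t.lncrna_id, t.mirna_id, t.mrna_id, ""))
    rows = sorted(set(rows))
    with open(path, "w") as fh:
        fh.write("lncRNA\tmiRNA\tmRNA\tmetabolite\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")
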