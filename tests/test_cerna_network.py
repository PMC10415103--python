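import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cernet.cerna_network import (
    CeRNATriad,
    attach_metabolites,
    build_cerna_triads,
    enrich_terms,
    export_sankey,
    predict_mre,
    reverse_complement,
    shared_mre_enrichment,
    significance_tier,
    spearman_cc,
)
from cernet.differential import AbundanceMatrix

from .oracles import hypergeom_tail, spearman_bruteforce

LET7 = "UGAGGUAGUAGGUUGUAUAGUU"  # seed (pos 2-8) GAGGUAG -> site CUACCUC


class TestPredictMre:
    def test_known_seed_site(self):
        host = "AAAA" + "CUACCUC" + "GGGG"
        (hit,) = predict_mre(LET7, host, "let7", "h")
        assert hit.site_start == 4 and hit.match_type == "seed7"

    def test_no_match_empty(self):
        assert predict_mre(LET7, "A" * 50) == []

    def test_tandem_repeats_counted_individually(self):
        unit = "CUACCUC" + "AAA"
        host = unit * 3
        hits = predict_mre(LET7, host, "let7", "h")
        assert [h.site_start for h in hits] == [0, 10, 20]

    def test_bruteforce_scan_agreement(self, rng):
        alpha = np.array(list("ACGU"))
        site = reverse_complement(LET7[1:8])
        for _ in range(20):
            host = "".join(alpha[rng.integers(0, 4, 300)])
            want = [i for i in range(294) if host[i : i + 7] == site]
            got = [h.site_start for h in predict_mre(LET7, host)]
            assert got == want

    def test_short_mirna_rejected_and_n_never_matches(self):
        with pytest.raises(ValueError):
            predict_mre("ACGUACG", "ACGU" * 10)
        assert predict_mre("UNAGGUAGUAGGUU", "AUCGAUCG" * 5) == []


class TestSpearman:
    def test_monotone(self):
        assert spearman_cc([1, 2, 3], [10, 20, 30])[0] == pytest.approx(1.0)
        assert spearman_cc([1, 2, 3], [30, 20, 10])[0] == pytest.approx(-1.0)

    def test_ties_match_reference(self, rng):
        for _ in range(50):
            x = rng.integers(0, 4, 6).astype(float)
            y = rng.integers(0, 4, 6).astype(float)
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            rho, p = spearman_cc(x, y)
            assert rho == pytest.approx(spearman_bruteforce(list(x), list(y)), abs=1e-12)
            ref_rho, ref_p = stats.spearmanr(x, y)
            assert rho == pytest.approx(ref_rho, abs=1e-12)
            if abs(rho) < 1:
                assert p == pytest.approx(ref_p, abs=1e-9)

    def test_degenerate_constant_vector(self):
        rho, p = spearman_cc([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(rho) and p == 1.0


class TestSharedMreEnrichment:
    def test_disjoint_sets_p_one(self):
        assert shared_mre_enrichment({"a"}, {"b"}, 20) == pytest.approx(1.0)

    def test_full_universe_certain_overlap(self):
        u = {f"m{i}" for i in range(20)}
        assert shared_mre_enrichment(u, u, 20) == pytest.approx(1.0)

    def test_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            shared_mre_enrichment({"a", "b"}, {"c"}, 2)

    def test_matches_pmf_summation(self, rng):
        for _ in range(100):
            M = int(rng.integers(5, 51))
            nA, nB = int(rng.integers(1, M + 1)), int(rng.integers(1, M + 1))
            universe = [f"m{i}" for i in range(M)]
            A = set(rng.choice(universe, nA, replace=False))
            B = set(rng.choice(universe, nB, replace=False))
            got = shared_mre_enrichment(A, B, M)
            want = hypergeom_tail(len(A & B), M, len(B), len(A))
            assert got == pytest.approx(want, abs=1e-12)


def _mat(rows, ids, layer, samples=None):
    samples = samples or [f"s{i}" for i in range(len(rows[0]))]
    df = pd.DataFrame(np.asarray(rows, float), index=ids, columns=samples)
    return AbundanceMatrix(layer, "FPKM", df, {s: "G" for s in samples})


class TestBuildCernaTriads:
    def sponge_exprs(self, flip_mrna=False):
        trend = np.array([1, 2, 3, 10, 11, 12, 30, 31, 32], float)
        anti = trend.max() + trend.min() - trend
        mrna = anti if flip_mrna else trend * 1.1
        return {
            "lncRNA": _mat([trend], ["L"], "lncRNA"),
            "miRNA": _mat([anti] + [np.ones(9) * (i + 2) for i in range(29)],
                          ["M"] + [f"m{i}" for i in range(29)], "miRNA"),
            "mRNA": _mat([mrna], ["R"], "mRNA"),
        }

    def hits(self):
        from cernet.cerna_network import MREHit

        return [
            MREHit("M", "L", "lncRNA", 5),
            MREHit("M", "R", "mRNA", 9),
        ]

    def test_planted_sponge_recovered(self):
        triads = build_cerna_triads(self.hits(), self.sponge_exprs())
        assert [(t.lncrna_id, t.mirna_id, t.mrna_id) for t in triads] == [("L", "M", "R")]
        t = triads[0]
        assert t.scc_mi_lnc < 0 and t.scc_mi_mrna < 0 and t.scc_lnc_mrna > 0

    def test_negative_lnc_mrna_correlation_blocks_triad(self):
        triads = build_cerna_triads(self.hits(), self.sponge_exprs(flip_mrna=True))
        assert triads == []

    def test_scc_min_monotone(self, gen_mre_hits, gen_norm, gen_de_sets):
        t_loose = build_cerna_triads(gen_mre_hits, gen_norm, gen_de_sets, scc_min=0.7)
        t_tight = build_cerna_triads(gen_mre_hits, gen_norm, gen_de_sets, scc_min=0.9)
        ids = lambda ts: {(t.lncrna_id, t.mirna_id, t.mrna_id) for t in ts}
        assert ids(t_tight) <= ids(t_loose)

    def test_sign_constraints_hold_on_all_output(self, gen_mre_hits, gen_norm, gen_de_sets):
        for t in build_cerna_triads(gen_mre_hits, gen_norm, gen_de_sets):
            assert t.scc_mi_lnc < 0 and t.scc_mi_mrna < 0 and t.scc_lnc_mrna > 0

    def test_triad_type_rejects_bad_signs(self):
        with pytest.raises(ValueError):
            CeRNATriad("l", "m", "r", 0.5, -0.9, 0.9, 0.01, 0.01)


class TestAttachMetabolites:
    def triad(self):
        return CeRNATriad("L", "M", "R", -0.9, -0.9, 0.9, 0.01, 0.01)

    def test_tightly_coupled_metabolite_significant(self, rng):
        r = np.array([1, 2, 3, 10, 11, 12, 30, 31, 32], float)
        expr = {
            "lncRNA": _mat([r], ["L"], "lncRNA"),
            "miRNA": _mat([r[::-1]], ["M"], "miRNA"),
            "mRNA": _mat([r], ["R"], "mRNA"),
        }
        metab = _mat([2 * r + rng.normal(0, 1e-9, 9)], ["met1"], "metabolite")
        edges = attach_metabolites([self.triad()], expr, metab)
        e = next(e for e in edges if e.rna_id == "R")
        assert e.scc == pytest.approx(1.0) and e.significance_tier == "***"

    def test_independent_metabolite_mostly_ns(self):
        rng = np.random.default_rng(3)
        r = np.arange(9.0)
        expr = {
            "lncRNA": _mat([r], ["L"], "lncRNA"),
            "miRNA": _mat([r[::-1]], ["M"], "miRNA"),
            "mRNA": _mat([r], ["R"], "mRNA"),
        }
        ns = 0
        n_rep = 300
        for _ in range(n_rep):
            metab = _mat([rng.lognormal(size=9)], ["met"], "metabolite")
            edges = attach_metabolites([self.triad()], expr, metab)
            e = next(e for e in edges if e.rna_id == "R")
            ns += e.significance_tier == "ns"
        assert ns / n_rep >= 0.90  # ~5% of null correlations reach p<=0.05

    def test_constant_metabolite_ns(self):
        r = np.arange(9.0)
        expr = {
            "lncRNA": _mat([r], ["L"], "lncRNA"),
            "miRNA": _mat([r[::-1]], ["M"], "miRNA"),
            "mRNA": _mat([r], ["R"], "mRNA"),
        }
        metab = _mat([np.ones(9)], ["met"], "metabolite")
        edges = attach_metabolites([self.triad()], expr, metab)
        assert all(e.significance_tier == "ns" for e in edges)

    def test_tier_mapping(self):
        assert [significance_tier(p) for p in (0.0005, 0.005, 0.04, 0.2)] == [
            "***", "**", "*", "ns"
        ]


class TestEnrichTerms:
    def test_term_equals_universe_p_one(self):
        u = {f"f{i}" for i in range(10)}
        rows = enrich_terms(u, {"t": set(u)}, u)
        assert rows[0][3] == pytest.approx(1.0)

    def test_rare_term_exact_tail(self):
        u = {f"f{i}" for i in range(20)}
        s = {"f0", "f1", "f2"}
        rows = enrich_terms(s, {"t": set(s)}, u)
        want = hypergeom_tail(3, 20, 3, 3)
        assert rows[0][3] == pytest.approx(want, abs=1e-12)

    def test_q_dominates_p_and_zero_hit_terms_omitted(self, rng):
        u = {f"f{i}" for i in range(50)}
        s = set(list(u)[:10])
        ann = {f"t{k}": set(rng.choice(sorted(u), 8, replace=False)) for k in range(12)}
        ann["empty"] = set(sorted(u - s))  # may have k=0 against s
        rows = enrich_terms(s, ann, u)
        for term, k, K, p, q in rows:
            assert q >= p - 1e-15 and k >= 1

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            enrich_terms(set(), {}, set())


class TestExportSankey:
    def edges(self):
        from cernet.cerna_network import MetaboliteEdge

        return [MetaboliteEdge("R", "mRNA", "met1", 0.9, 0.001, "***")]

    def test_one_complete_chain(self, tmp_path):
        t = CeRNATriad("L", "M", "R", -0.9, -0.9, 0.9, 0.01, 0.01)
        p = tmp_path / "s.tsv"
        export_sankey([t], self.edges(), p)
        lines = p.read_text().splitlines()
        assert lines[1] == "L\tM\tR\tmet1"

    def test_triad_without_metabolite_keeps_row(self, tmp_path):
        t = CeRNATriad("L", "M", "R2", -0.9, -0.9, 0.9, 0.01, 0.01)
        p = tmp_path / "s.tsv"
        export_sankey([t], self.edges(), p)
        assert p.read_text().splitlines()[1] == "L\tM\tR2\t"

    def test_shuffled_input_byte_identical(self, tmp_path):
        ts = [
            CeRNATriad("L2", "M", "R", -0.9, -0.9, 0.9, 0.01, 0.01),
            CeRNATriad("L1", "M", "R", -0.8, -0.8, 0.8, 0.01, 0.01),
        ]
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        export_sankey(ts, self.edges(), p1)
        export_sankey(ts[::-1], self.edges()[::-1], p2)
        assert p1.read_bytes() == p2.read_bytes()
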