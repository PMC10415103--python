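import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cernet.differential import (
    DEFAULT_THRESHOLDS,
    AbundanceMatrix,
    ComparisonGroup,
    ThresholdConfig,
    benjamini_hochberg,
    compute_fpkm,
    compute_tpm,
    de_test,
    filter_de,
    venn,
)

from .oracles import bh_quadratic

GROUPS = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B", "b3": "B"}
COMP = ComparisonGroup("B_vs_A", "B", "A")


def counts_matrix(rows, ids=None, layer="lncRNA"):
    df = pd.DataFrame(
        np.asarray(rows, float), index=ids or [f"f{i}" for i in range(len(rows))],
        columns=list(GROUPS),
    )
    return AbundanceMatrix(layer, "raw_count", df, GROUPS, df.sum(axis=0))


class TestNormalization:
    def test_fpkm_formula(self):
        m = counts_matrix([[10, 10, 10, 10, 10, 10]])
        m.library_sizes = pd.Series(1e6, index=m.sample_ids)
        out = compute_fpkm(m, {"f0": 1000})
        assert np.allclose(out.data.to_numpy(), 10.0)

    def test_fpkm_formula_other_scale(self):
        m = counts_matrix([[5, 5, 5, 5, 5, 5]])
        m.library_sizes = pd.Series(2e6, index=m.sample_ids)
        out = compute_fpkm(m, {"f0": 500})
        assert np.allclose(out.data.to_numpy(), 5.0)

    def test_fpkm_zero_count_and_zero_length(self):
        m = counts_matrix([[0, 0, 0, 0, 0, 1], [5, 5, 5, 5, 5, 5]])
        assert compute_fpkm(m, {"f0": 100, "f1": 100}).data.iloc[0, 0] == 0.0
        with pytest.raises(ValueError, match="length"):
            compute_fpkm(m, {"f0": 0, "f1": 100})

    def test_fpkm_linear_in_counts(self, rng):
        rows = rng.integers(1, 1000, (20, 6))
        m1 = counts_matrix(rows)
        m2 = counts_matrix(rows * 3)
        m2.library_sizes = m1.library_sizes  # same depth, tripled counts
        lengths = {f"f{i}": 500 for i in range(20)}
        assert np.allclose(
            compute_fpkm(m2, lengths).data.to_numpy(),
            3 * compute_fpkm(m1, lengths).data.to_numpy(),
        )

    def test_tpm_equal_rates(self):
        m = counts_matrix([[10] * 6, [20] * 6])
        out = compute_tpm(m, {"f0": 1000, "f1": 2000})
        assert np.allclose(out.data.to_numpy(), 5e5)

    def test_tpm_columns_sum_to_1e6(self, rng):
        m = counts_matrix(rng.integers(1, 500, (30, 6)))
        out = compute_tpm(m, {f"f{i}": int(v) for i, v in enumerate(rng.integers(100, 5000, 30))})
        assert np.allclose(out.data.sum(axis=0), 1e6, atol=1e-6)

    def test_tpm_all_zero_column_error(self):
        df = pd.DataFrame([[0.0, 1, 1, 1, 1, 1]], index=["f0"], columns=list(GROUPS))
        m = AbundanceMatrix("lncRNA", "raw_count", df, GROUPS,
                            pd.Series(1.0, index=df.columns))
        with pytest.raises(ValueError, match="all-zero"):
            compute_tpm(m, {"f0": 100})


class TestDeTest:
    def test_log2fc_formula(self):
        m = counts_matrix([[1, 1, 1, 8, 8, 8]], layer="mRNA")
        t = de_test(m, COMP)
        assert t["log2fc"].iloc[0] == pytest.approx(np.log2(9 / 2))

    def test_degenerate_equal_groups(self):
        m = counts_matrix([[5, 5, 5, 5, 5, 5]])
        t = de_test(m, COMP)
        assert t["log2fc"].iloc[0] == 0.0 and t["p"].iloc[0] == 1.0

    def test_degenerate_zero_variance_unequal_means(self):
        m = counts_matrix([[1, 1, 1, 9, 9, 9]])
        assert de_test(m, COMP)["p"].iloc[0] == 0.0

    def test_single_replicate_rejected(self):
        df = pd.DataFrame([[1.0, 2.0]], index=["f"], columns=["a1", "b1"])
        m = AbundanceMatrix("mRNA", "raw_count", df, {"a1": "A", "b1": "B"}, df.sum(axis=0))
        with pytest.raises(ValueError, match="replicates"):
            de_test(m, COMP)

    def test_passthrough_keeps_pvalues(self):
        m = counts_matrix([[1, 1, 1, 8, 8, 8]])
        t = de_test(m, COMP, method="passthrough", pvalues={"f0": 0.123})
        assert t["p"].iloc[0] == 0.123

    def test_planted_effect_detected_in_nearly_all_features(self):
        # planted 8x fold change, lognormal noise sigma=0.1, 1000 features
        rng = np.random.default_rng(1)
        base = rng.lognormal(5, 1, 1000)
        ctrl = base[:, None] * rng.lognormal(0, 0.1, (1000, 3))
        case = 8 * base[:, None] * rng.lognormal(0, 0.1, (1000, 3))
        df = pd.DataFrame(np.hstack([ctrl, case]), columns=list(GROUPS),
                          index=[f"f{i}" for i in range(1000)])
        m = AbundanceMatrix("mRNA", "FPKM", df, GROUPS)
        t = de_test(m, COMP)
        assert (t["p"] < 0.01).mean() >= 0.99


class TestBenjaminiHochberg:
    def test_known_example(self):
        assert np.allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.3])[0] == pytest.approx(0.3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_quadratic_reference(self, ps):
        assert np.allclose(benjamini_hochberg(ps), bh_quadratic(ps), atol=1e-12)

    def test_dominates_raw_p_and_permutation_invariant(self, rng):
        p = rng.uniform(size=200)
        q = benjamini_hochberg(p)
        assert (q >= p - 1e-15).all() and (q <= 1).all()
        perm = rng.permutation(200)
        assert np.allclose(benjamini_hochberg(p[perm]), q[perm])


class TestFilterDe:
    def table(self, **cols):
        n = len(next(iter(cols.values())))
        return pd.DataFrame(cols, index=[f"f{i}" for i in range(n)])

    def test_lncrna_boundary_inclusive(self):
        t = self.table(log2fc=[1.0, 0.99], p=[0.01, 0.01], fdr=[0.05, 0.05])
        res = filter_de(t, DEFAULT_THRESHOLDS["lncRNA"])
        assert [r.direction for r in res] == ["up", "ns"]

    def test_mirna_boundary(self):
        t = self.table(log2fc=[0.58, 0.585], p=[0.01, 0.01], fdr=[0.5, 0.5])
        res = filter_de(t, DEFAULT_THRESHOLDS["miRNA"])
        assert [r.direction for r in res] == ["ns", "up"]

    def test_metabolite_vip_rule(self):
        t = self.table(log2fc=[0.6, 0.6], p=[0.01, 0.01], vip=[1.5, 0.5])
        res = filter_de(t, DEFAULT_THRESHOLDS["metabolite"])
        assert [r.direction for r in res] == ["up", "ns"]

    def test_literal_vip_direction_available(self):
        t = self.table(log2fc=[0.6], p=[0.01], vip=[0.5])
        literal = ThresholdConfig("metabolite", 0.585, "p", 1.0, vip_min=1.0,
                                  vip_direction="le")
        assert filter_de(t, literal)[0].direction == "up"

    def test_down_direction_symmetric(self):
        t = self.table(log2fc=[-1.2], p=[0.01], fdr=[0.01])
        assert filter_de(t, DEFAULT_THRESHOLDS["lncRNA"])[0].direction == "down"

    def test_monotone_in_thresholds(self, rng):
        t = self.table(
            log2fc=list(rng.normal(0, 2, 300)),
            p=list(rng.uniform(size=300)),
            fdr=list(rng.uniform(size=300)),
        )
        def called(fc_min, sig_max):
            cfg = ThresholdConfig("lncRNA", fc_min, "fdr", sig_max)
            return {r.feature_id for r in filter_de(t, cfg) if r.direction != "ns"}
        assert called(2.0, 0.05) <= called(1.0, 0.05) <= called(0.5, 0.05)
        assert called(1.0, 0.01) <= called(1.0, 0.05) <= called(1.0, 0.2)


class TestVenn:
    def test_pair(self):
        v = venn({"A": {"1", "2"}, "B": {"2", "3"}})
        assert v.intersection == {"2"} and v.union == {"1", "2", "3"}
        assert v.regions[("A",)] == 1 and v.regions[("A", "B")] == 1

    def test_three_disjoint(self):
        v = venn({"A": {"1"}, "B": {"2"}, "C": {"3", "4"}})
        assert v.intersection == frozenset() and len(v.union) == 4

    def test_requires_two_groups(self):
        with pytest.raises(ValueError):
            venn({"A": {"1"}})

    @given(
        st.lists(st.sets(st.integers(0, 30).map(str), max_size=20), min_size=2, max_size=4)
    )
    def test_inclusion_exclusion_identity(self, sets):
        groups = {f"G{i}": s for i, s in enumerate(sets)}
        v = venn(groups)
        # exclusive regions partition the union
        assert sum(v.regions.values()) == len(v.union)
        # inclusion-exclusion for each group: sum of regions containing it
        for name, s in groups.items():
            total = sum(n for r, n in v.regions.items() if name in r)
            assert total == len(s)
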