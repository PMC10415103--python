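"""Normalization, per-comparison differential tests, per-layer threshold
filters, and Venn arithmetic over comparison groups.

The pipeline's built-in significance test is Welch's two-sample t on
log2(normalized value + pseudocount).  It deliberately stands in for the
negative-binomial engines used on real count data; the quantities this
package is about are the downstream thresholds and set arithmetic, which are
agnostic to the p-value engine, and a passthrough mode accepts externally
computed p-values.  Fold change is always log2 of (mean case + pc) /
(mean control + pc) on the normalized scale.

Per-layer default thresholds (boundary-inclusive, as conventionally printed):

=========== ============== ================== =========================
layer       |log2FC| >=     significance       extra
=========== ============== ================== =========================
lncRNA      1 (FC 2)        FDR <= 0.05
miRNA       0.585           p <= 0.05
mRNA        1               p <= 0.05
metabolite  0.585           (none)             VIP >= 1 (direction
                                               configurable; see note)
=========== ============== ================== =========================

The metabolite VIP rule defaults to the conventional (O)PLS reading
(VIP >= 1).  The opposite direction is selectable via ``vip_direction='le'``;
selecting it logs a warning because it contradicts the usual use of VIP to
rank discriminating metabolites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import AbundanceMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ComparisonGroup:
    """A case-vs-control contrast, e.g. McII_vs_McI."""

    name: str
    case_group: str
    control_group: str

    def __post_init__(self) -> None:
        if self.case_group == self.control_group:
            raise ValueError("case and control groups must differ")


@dataclass(frozen=True)
class ThresholdConfig:
    layer: str
    log2fc_min: float
    significance_field: str  # "p" | "fdr"
    significance_max: float
    vip_min: float | None = None
    vip_direction: str = "ge"  # "ge" | "le"

    def __post_init__(self) -> None:
        if self.significance_field not in ("p", "fdr"):
            raise ValueError("significance_field must be 'p' or 'fdr'")
        if not 0 < self.significance_max <= 1:
            raise ValueError("significance_max must be in (0, 1]")
        if self.log2fc_min < 0:
            raise ValueError("log2fc_min must be non-negative")
        if self.vip_direction not in ("ge", "le"):
            raise ValueError("vip_direction must be 'ge' or 'le'")


DEFAULT_THRESHOLDS: dict[str, ThresholdConfig] = {
    "lncRNA": ThresholdConfig("lncRNA", 1.0, "fdr", 0.05),
    "miRNA": ThresholdConfig("miRNA", 0.585, "p", 0.05),
    "mRNA": ThresholdConfig("mRNA", 1.0, "p", 0.05),
    "metabolite": ThresholdConfig("metabolite", 0.585, "p", 1.0, vip_min=1.0),
}


@dataclass(frozen=True)
class DEResult:
    feature_id: str
    comparison: str
    log2fc: float
    p: float
    fdr: float
    vip: float | None = None
    direction: str = "ns"  # {up, down, ns}


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def compute_fpkm(counts: AbundanceMatrix, lengths: Mapping[str, float]) -> AbundanceMatrix:
    """Fragments per kilobase of transcript per million mapped fragments.

    fpkm[i, s] = counts[i, s] / (length_i / 1e3) / (library_size_s / 1e6)
    """
    if counts.unit != "raw_count":
        raise ValueError("compute_fpkm expects raw counts")
    lens = pd.Series({f: float(lengths[f]) for f in counts.feature_ids})
    if (lens <= 0).any():
        bad = lens.index[lens <= 0].tolist()
        raise ValueError(f"non-positive transcript length for {bad[:5]}")
    fpkm = counts.data.div(lens / 1e3, axis=0).div(counts.library_sizes / 1e6, axis=1)
    return counts.with_values(fpkm, "FPKM")


def compute_tpm(counts: AbundanceMatrix, lengths: Mapping[str, float]) -> AbundanceMatrix:
    """Transcripts per million: length-normalized rates rescaled so every
    sample column sums to 1e6."""
    if counts.unit != "raw_count":
        raise ValueError("compute_tpm expects raw counts")
    lens = pd.Series({f: float(lengths[f]) for f in counts.feature_ids})
    if (lens <= 0).any():
        raise ValueError("non-positive transcript length")
    rate = counts.data.div(lens, axis=0)
    colsum = rate.sum(axis=0)
    if (colsum == 0).any():
        bad = colsum.index[colsum == 0].tolist()
        raise ValueError(f"all-zero sample column(s) {bad}: TPM undefined")
    return counts.with_values(rate.div(colsum, axis=1) * 1e6, "TPM")


# ---------------------------------------------------------------------------
# testing
# ---------------------------------------------------------------------------


def de_test(
    matrix: AbundanceMatrix,
    comparison: ComparisonGroup,
    method: str = "welch_log",
    pseudocount: float = 1.0,
    pvalues: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-feature log2 fold change and p-value for one comparison.

    ``welch_log`` runs Welch's t on log2(value + pseudocount); degenerate
    features (zero variance in both groups) get p = 1.0 when the group means
    are equal and p = 0.0 otherwise.  ``passthrough`` keeps user-supplied
    p-values and computes only the fold change.

    Returns a DataFrame indexed by feature with columns ``log2fc`` and ``p``.
    """
    case_cols = matrix.samples_of(comparison.case_group)
    ctrl_cols = matrix.samples_of(comparison.control_group)
    if not case_cols or not ctrl_cols:
        raise ValueError(f"comparison {comparison.name}: empty group")
    case = matrix.data[case_cols].to_numpy(float)
    ctrl = matrix.data[ctrl_cols].to_numpy(float)
    log2fc = np.log2(case.mean(axis=1) + pseudocount) - np.log2(
        ctrl.mean(axis=1) + pseudocount
    )
    if method == "passthrough":
        if pvalues is None:
            raise ValueError("passthrough requires pvalues")
        p = np.array([float(pvalues[f]) for f in matrix.feature_ids])
    elif method == "welch_log":
        if case.shape[1] < 2 or ctrl.shape[1] < 2:
            raise ValueError("welch_log needs >= 2 replicates per group")
        la = np.log2(case + pseudocount)
        lb = np.log2(ctrl + pseudocount)
        with np.errstate(divide="ignore", invalid="ignore"):
            _, p = stats.ttest_ind(la, lb, axis=1, equal_var=False)
        degenerate = (la.var(axis=1) == 0) & (lb.var(axis=1) == 0)
        equal_means = np.isclose(la.mean(axis=1), lb.mean(axis=1))
        p = np.where(degenerate, np.where(equal_means, 1.0, 0.0), p)
        p = np.nan_to_num(p, nan=1.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame({"log2fc": log2fc, "p": p}, index=matrix.feature_ids)


def benjamini_hochberg(p_values: Iterable[float]) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjustment, aligned to input order.

    q_(i) = min_{j >= i} p_(j) * m / j, clipped to 1; ties are handled by a
    stable sort.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def filter_de(
    results: pd.DataFrame,
    thresholds: ThresholdConfig,
    comparison: str = "",
) -> list[DEResult]:
    """Apply per-layer thresholds and return directed DE records.

    ``results`` must carry ``log2fc`` plus the configured significance field
    (``p`` and/or ``fdr``) and, for metabolites, a ``vip`` column.  A feature
    is up iff log2fc >= log2fc_min, the significance is <= significance_max,
    and the VIP rule (when configured) holds; down mirrors with
    log2fc <= -log2fc_min; everything else is ns.
    """
    if thresholds.significance_field not in results.columns:
        raise ValueError(f"results lack column {thresholds.significance_field!r}")
    sig = results[thresholds.significance_field].to_numpy(float)
    fc = results["log2fc"].to_numpy(float)
    ok = sig <= thresholds.significance_max
    if thresholds.vip_min is not None:
        if "vip" not in results.columns:
            raise ValueError("metabolite thresholds need a 'vip' column")
        vip = results["vip"].to_numpy(float)
        if thresholds.vip_direction == "ge":
            ok &= vip >= thresholds.vip_min
        else:
            logger.warning(
                "vip_direction='le' selected: this keeps LOW-importance "
                "metabolites and contradicts conventional VIP ranking"
            )
            ok &= vip <= thresholds.vip_min
    up = ok & (fc >= thresholds.log2fc_min)
    down = ok & (fc <= -thresholds.log2fc_min)
    out = []
    p_col = results["p"] if "p" in results.columns else results[thresholds.significance_field]
    fdr_col = results["fdr"] if "fdr" in results.columns else p_col
    vip_col = results["vip"] if "vip" in results.columns else None
    for i, feat in enumerate(results.index):
        direction = "up" if up[i] else "down" if down[i] else "ns"
        out.append(
            DEResult(
                str(feat),
                comparison,
                float(fc[i]),
                float(p_col.iloc[i]),
                float(fdr_col.iloc[i]),
                None if vip_col is None else float(vip_col.iloc[i]),
                direction,
            )
        )
    return out


def de_analysis(
    matrix: AbundanceMatrix,
    comparison: ComparisonGroup,
    thresholds: ThresholdConfig,
    method: str = "welch_log",
    pseudocount: float = 1.0,
    pvalues: Mapping[str, float] | None = None,
    vip: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, list[DEResult]]:
    """Convenience wrapper: test, BH-adjust, filter.  Returns the full table
    (log2fc, p, fdr[, vip]) and the directed records."""
    table = de_test(matrix, comparison, method=method, pseudocount=pseudocount, pvalues=pvalues)
    table["fdr"] = benjamini_hochberg(table["p"])
    if vip is not None:
        table["vip"] = [float(vip[f]) for f in table.index]
    return table, filter_de(table, thresholds, comparison.name)


# ---------------------------------------------------------------------------
# Venn arithmetic
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VennSummary:
    """Exclusive-region cardinalities plus the k-way intersection and union."""

    group_names: tuple[str, ...]
    regions: Mapping[tuple[str, ...], int]
    intersection: frozenset[str]
    union: frozenset[str]


def venn(groups: Mapping[str, set[str]]) -> VennSummary:
    """All exclusive-region cardinalities over >= 2 named sets."""
    if len(groups) < 2:
        raise ValueError("venn needs >= 2 groups")
    names = tuple(groups)
    union: set[str] = set().union(*groups.values())
    inter = set(groups[names[0]])
    for n in names[1:]:
        inter &= groups[n]
    regions: dict[tuple[str, ...], int] = {}
    for item_membership in _memberships(groups, names, union):
        regions[item_membership] = regions.get(item_membership, 0) + 1
    return VennSummary(names, regions, frozenset(inter), frozenset(union))


def _memberships(groups, names, union):
    for item in union:
        yield tuple(n for n in names if item in groups[n])
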