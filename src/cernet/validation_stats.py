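"""Quantitative qPCR validation: relative expression by the 2^-ddCt method
and the qPCR-vs-sequencing concordance fit.

ddCt: dCt = Ct_target - Ct_reference per (feature, sample); replicate Ct
pairs are averaged first.  Relative expression is 2^-(dCt_sample -
dCt_calibrator), so the calibrator sample is 1.0 by construction and the
result is invariant under any Ct offset applied equally to target and
reference.

Concordance: ordinary least squares of the qPCR log2 fold changes on the
sequencing log2 fold changes, reported as (slope, intercept, Pearson r, n).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CtRecord:
    feature_id: str
    sample_id: str
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for v in (self.ct_target, self.ct_reference):
            if not math.isfinite(v):
                raise ValueError(f"{self.feature_id}/{self.sample_id}: non-finite Ct")
            if not 10 <= v <= 40:
                logger.warning(
                    "Ct %.2f for %s/%s outside the usual 10-40 range",
                    v, self.feature_id, self.sample_id,
                )


@dataclass(frozen=True)
class ConcordanceFit:
    slope: float
    intercept: float
    r: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| must be <= 1")


def ddct(
    records: Iterable[CtRecord], calibrator_sample: str
) -> dict[tuple[str, str], float]:
    """Relative expression 2^-ddCt per (feature, sample).

    The calibrator sample must be present for every feature; replicate
    records of the same (feature, sample) are averaged before dCt.
    """
    dct_sum: dict[tuple[str, str], list[float]] = {}
    for r in records:
        dct_sum.setdefault((r.feature_id, r.sample_id), []).append(
            r.ct_target - r.ct_reference
        )
    dct = {k: sum(v) / len(v) for k, v in dct_sum.items()}
    features = {f for f, _ in dct}
    missing = sorted(f for f in features if (f, calibrator_sample) not in dct)
    if missing:
        raise ValueError(
            f"calibrator sample {calibrator_sample!r} missing for features {missing}"
        )
    return {
        (f, s): 2.0 ** -(d - dct[(f, calibrator_sample)]) for (f, s), d in dct.items()
    }


def concordance_fit(
    log2fc_qpcr: Sequence[float], log2fc_seq: Sequence[float]
) -> ConcordanceFit:
    """OLS of qPCR log2FC on sequencing log2FC with Pearson r."""
    y = np.asarray(log2fc_qpcr, float)
    x = np.asarray(log2fc_seq, float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("concordance_fit needs paired vectors, n >= 3")
    if x.std() == 0:
        raise ValueError("zero variance in the sequencing fold changes")
    fit = stats.linregress(x, y)
    return ConcordanceFit(float(fit.slope), float(fit.intercept), float(fit.rvalue), x.size)
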