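"""ROI statistics and method-agreement analysis.

Provides ROI mean +- SD, Bland-Altman limits of agreement, and the
intra-class correlation coefficient ICC(A,1) (two-way random effects,
absolute agreement, single measurement) used to compare absolute
quantitative values between methods or repeated scans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AgreementResult", "roi_stats", "bland_altman", "icc_agreement"]


@dataclass
class AgreementResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    icc: float | None = None
    icc_defined: bool = True


def roi_stats(map_values: np.ndarray, roi: np.ndarray):
    """Mean and sample SD (n-1 denominator) over a boolean ROI mask.

    A single-voxel ROI has SD 0 by convention.
    """
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != np.shape(map_values):
        raise ValueError("ROI mask shape does not match map shape")
    vals = np.asarray(map_values)[roi]
    if vals.size == 0:
        raise ValueError("ROI mask is empty")
    mean = float(np.mean(vals.real)) if np.isrealobj(vals) else complex(np.mean(vals))
    sd = 0.0 if vals.size == 1 else float(np.std(vals, ddof=1))
    return mean, sd


def bland_altman(x, y) -> AgreementResult:
    """Bland-Altman agreement of paired values: differences d = x - y,
    mean difference, sample SD, and 95 % limits mean -+ 1.96*SD."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired value arrays must have equal length")
    if x.size < 2:
        raise ValueError("need at least two pairs")
    d = x - y
    mean_diff = float(np.mean(d))
    sd_diff = float(np.std(d, ddof=1))
    return AgreementResult(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - 1.96 * sd_diff,
        loa_high=mean_diff + 1.96 * sd_diff,
    )


def icc_agreement(x, y) -> AgreementResult:
    """ICC(A,1): two-way random effects, absolute agreement, single rater.

    Computed with pingouin (its ICC2 row).  Degenerate input with zero
    total variance returns ``icc_defined=False``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired value arrays must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least three pairs for the ICC")

    ba = bland_altman(x, y)
    if np.var(np.concatenate([x, y])) < 1e-30:
        ba.icc = None
        ba.icc_defined = False
        return ba

    import warnings

    import pandas as pd
    import pingouin as pg

    df = pd.DataFrame(
        {
            "target": np.tile(np.arange(n), 2),
            "rater": np.repeat(["a", "b"], n),
            "value": np.concatenate([x, y]),
        }
    )
    with warnings.catch_warnings():
        # perfect agreement has a zero error mean square; the point
        # estimate is still well defined
        warnings.simplefilter("ignore", RuntimeWarning)
        res = pg.intraclass_corr(
            data=df, targets="target", raters="rater", ratings="value"
        )
    row = res["Type"].isin(["ICC(A,1)", "ICC2"])  # label differs by version
    icc = float(res.loc[row, "ICC"].iloc[0])
    ba.icc = icc
    ba.icc_defined = np.isfinite(icc)
    return ba
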