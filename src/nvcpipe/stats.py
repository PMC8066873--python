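"""Univariate group statistics for coupling and unimodal power metrics.

One-sample t-tests ask whether a group's mean coupling differs from
zero; pooled-variance two-sample t-tests compare the patient and control
groups (df = n1 + n2 - 2).  All p-values are two-tailed.  No multiple
comparison correction is applied across the six metrics: the multivariate
analysis in :mod:`nvcpipe.classify` is the guard against false positives
from considering several couplings at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _st

from .errors import DataError, ParameterError

__all__ = ["TTestResult", "one_sample_t", "two_sample_t", "group_comparison_table"]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    mean_diff: float
    n: tuple[int, ...]


def one_sample_t(values, null_value: float = 0.0) -> TTestResult:
    """One-sample t-test of the mean against ``null_value`` (two-tailed)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ParameterError(f"need a 1-D sample with n >= 2, got shape {x.shape}")
    if x.std(ddof=1) == 0:
        raise DataError("sample has zero variance; t statistic undefined")
    res = _st.ttest_1samp(x, popmean=null_value)
    return TTestResult(
        t=float(res.statistic),
        df=len(x) - 1,
        p=float(res.pvalue),
        mean_diff=float(x.mean() - null_value),
        n=(len(x),),
    )


def two_sample_t(a, b) -> TTestResult:
    """Pooled-variance two-sample t-test (df = n1 + n2 - 2, two-tailed)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or len(a) < 2 or len(b) < 2:
        raise ParameterError("need two 1-D samples with n >= 2 each")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise DataError("both samples have zero variance; t statistic undefined")
    res = _st.ttest_ind(a, b, equal_var=True)
    return TTestResult(
        t=float(res.statistic),
        df=len(a) + len(b) - 2,
        p=float(res.pvalue),
        mean_diff=float(a.mean() - b.mean()),
        n=(len(a), len(b)),
    )


def group_comparison_table(features: pd.DataFrame, labels) -> pd.DataFrame:
    """Tidy per-metric statistics: one-sample per group and AD-vs-HC contrast.

    ``features`` is subjects x metrics; ``labels`` is 1 for the patient
    group and 0 for controls.  The two-sample contrast is patient minus
    control, so negative t means lower values in patients.
    """
    labels = np.asarray(labels)
    rows = []
    for name in features.columns:
        x = features[name].to_numpy(dtype=float)
        ad, hc = x[labels == 1], x[labels == 0]
        r_ad = one_sample_t(ad)
        r_hc = one_sample_t(hc)
        r2 = two_sample_t(ad, hc)
        rows.append(
            {
                "metric": name,
                "t_ad_vs_zero": r_ad.t, "p_ad_vs_zero": r_ad.p, "df_ad": r_ad.df,
                "t_hc_vs_zero": r_hc.t, "p_hc_vs_zero": r_hc.p, "df_hc": r_hc.df,
                "t_ad_vs_hc": r2.t, "p_ad_vs_hc": r2.p, "df_groups": r2.df,
                "mean_ad": float(ad.mean()), "mean_hc": float(hc.mean()),
            }
        )
    return pd.DataFrame(rows)
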