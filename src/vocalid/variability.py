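"""Acoustic variability statistics: CV, PIC, and Friedman comparisons.

For each call type and acoustic parameter we compute

* ``cv_inter`` — 100 * SD / mean over the pooled calls of all callers,
* ``cv_intra`` — the unweighted mean of the per-caller CVs,
* ``pic`` — the potential for identity coding, cv_inter / cv_intra; values
  above 1 indicate that between-caller variation exceeds within-caller
  variation, i.e. the parameter could support caller recognition.

Per call type the parameter-wise CVs are averaged into ``cv_inter_mean`` and
``cv_intra_mean``, whose ratio is the overall PIC of the call type.

Sample standard deviations (n-1 denominator) are used throughout. Friedman
tests (mid-rank tie correction, chi-square approximation) compare CV or PIC
profiles across call types with parameters as blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import FEATURE_NAMES

__all__ = ["VariabilitySummary", "cv", "variability_summary", "friedman_test"]


def cv(values) -> float:
    """Coefficient of variation, 100 * sample SD / mean, in percent.

    Requires at least two values; a zero mean leaves the CV undefined and
    returns NaN (flagged missing downstream).
    """
    x = np.asarray(values, dtype=np.float64)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("cv requires a flat list of at least 2 values")
    m = x.mean()
    if m == 0:
        return float("nan")
    return float(100.0 * x.std(ddof=1) / m)


@dataclass
class VariabilitySummary:
    """Variability statistics of one call type.

    ``per_parameter`` has one row per acoustic parameter with columns
    mean_inter, sd_inter, cv_inter, cv_intra, pic.
    """

    call_type: str
    callers: tuple[str, ...]
    per_parameter: pd.DataFrame
    cv_inter_mean: float
    cv_intra_mean: float
    overall_pic: float


def variability_summary(
    table: pd.DataFrame,
    call_type: str,
    parameters: tuple[str, ...] = FEATURE_NAMES,
) -> VariabilitySummary:
    """CV / PIC summary of one call type from a per-segment feature table.

    ``table`` needs columns ``caller_id``, ``call_type`` and the parameter
    columns. Callers with fewer than two calls of the type are excluded with
    a warning; at least two callers must remain.
    """
    sub = table[table["call_type"] == call_type]
    if sub.empty:
        raise ValueError(f"no rows for call type {call_type!r}")
    counts = sub.groupby("caller_id").size()
    small = counts[counts < 2].index.tolist()
    if small:
        warnings.warn(
            f"{call_type}: excluding callers with <2 calls: {sorted(small)}",
            stacklevel=2,
        )
        sub = sub[~sub["caller_id"].isin(small)]
    callers = tuple(sorted(sub["caller_id"].unique()))
    if len(callers) < 2:
        raise ValueError(f"{call_type}: need >=2 callers with >=2 calls each")

    rows = []
    for p in parameters:
        pooled = sub[p].to_numpy(dtype=np.float64)
        pooled = pooled[~np.isnan(pooled)]
        if len(pooled) < 2:
            rows.append((p, np.nan, np.nan, np.nan, np.nan, np.nan))
            continue
        mean_inter = pooled.mean()
        sd_inter = pooled.std(ddof=1)
        cv_inter = 100.0 * sd_inter / mean_inter if mean_inter != 0 else np.nan
        caller_cvs = []
        for c in callers:
            vals = sub.loc[sub["caller_id"] == c, p].to_numpy(dtype=np.float64)
            vals = vals[~np.isnan(vals)]
            if len(vals) >= 2:
                caller_cvs.append(cv(vals))
        cv_intra = float(np.nanmean(caller_cvs)) if caller_cvs else np.nan
        pic = cv_inter / cv_intra if (cv_intra and cv_intra > 0) else np.nan
        rows.append((p, mean_inter, sd_inter, cv_inter, cv_intra, pic))

    per_param = pd.DataFrame(
        rows, columns=["parameter", "mean_inter", "sd_inter", "cv_inter", "cv_intra", "pic"]
    ).set_index("parameter")
    cv_inter_mean = float(per_param["cv_inter"].mean())
    cv_intra_mean = float(per_param["cv_intra"].mean())
    overall = cv_inter_mean / cv_intra_mean if cv_intra_mean > 0 else float("nan")
    return VariabilitySummary(
        call_type=call_type,
        callers=callers,
        per_parameter=per_param,
        cv_inter_mean=cv_inter_mean,
        cv_intra_mean=cv_intra_mean,
        overall_pic=overall,
    )


def friedman_test(matrix) -> tuple[float, int, float]:
    """Friedman rank test over a blocks x treatments matrix.

    Rows are blocks (here: the 20 acoustic parameters), columns treatments
    (here: call types). Returns (chi2, df, p) with df = treatments - 1 and p
    from the chi-square approximation (mid-rank tie correction applied).
    """
    m = np.asarray(matrix, dtype=np.float64)
    if m.ndim != 2:
        raise ValueError("friedman_test expects a 2-D blocks x treatments matrix")
    n_blocks, k = m.shape
    if n_blocks < 2 or k < 2:
        raise ValueError("need at least 2 blocks and 2 treatments")
    if np.isnan(m).any():
        raise ValueError("missing cells are not allowed in the Friedman test")
    ranks = np.apply_along_axis(stats.rankdata, 1, m)  # mid-ranks within blocks
    rank_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n_blocks * k * (k + 1)) * np.sum(rank_sums**2) - 3.0 * n_blocks * (
        k + 1
    )
    # mid-rank tie correction
    ties = 0.0
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    correction = 1.0 - ties / (n_blocks * (k**3 - k))
    if correction <= 0:
        # every block fully tied: no rank information
        return 0.0, k - 1, 1.0
    chi2 = float(chi2 / correction)
    p = float(stats.chi2.sf(chi2, k - 1))
    return chi2, k - 1, p
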