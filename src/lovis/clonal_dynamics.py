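"""Longitudinal and cross-tissue clone analytics.

Frequency-band classification (quartiles of per-clone maximum frequency),
persistence (detection at every tracked timepoint), top-k clones,
sharing matrices between timepoints or tissues, and the two replicate
concordance statistics used for clonal profiles: Pearson's r and the
single-rater, absolute-agreement intraclass correlation coefficient
computed from a two-way ANOVA decomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "ConcordanceResult",
    "classify_frequency_bands",
    "find_persistent",
    "top_clones",
    "sharing_matrix",
    "pearson_r",
    "icc_a1",
    "classify_clones",
]


@dataclass(frozen=True)
class ConcordanceResult:
    pearson_r: float
    icc: float
    n: int
    k: int


def classify_frequency_bands(max_freqs) -> pd.Series:
    """Band clones by quartiles of their maximum frequency.

    A clone is ``low`` if its maximum frequency is strictly below the first
    quartile, ``high`` if strictly above the third quartile, ``medium``
    otherwise (boundary values inclusive).  Quartiles are computed by
    linear interpolation between order statistics.  With fewer than four
    clones quartiles are not meaningful: all clones are ``medium`` and a
    warning is emitted.
    """
    x = pd.Series(max_freqs, dtype=float)
    if len(x) < 4:
        warnings.warn("fewer than 4 clones: all bands set to medium")
        return pd.Series("medium", index=x.index)
    q1, q3 = np.quantile(x.to_numpy(), [0.25, 0.75])
    bands = pd.Series("medium", index=x.index)
    bands[x < q1] = "low"
    bands[x > q3] = "high"
    return bands


def find_persistent(freqs: pd.DataFrame) -> pd.Series:
    """True iff a clone has frequency > 0 at every tracked timepoint.

    ``freqs`` is clone x timepoint.
    """
    if freqs.shape[1] < 2:
        raise ValueError("persistence needs at least 2 timepoints")
    return (freqs > 0).all(axis=1)


def top_clones(freqs: pd.Series, k: int = 10) -> list:
    """The k highest-frequency clones, ties broken by site-key order."""
    df = freqs.to_frame("f")
    df["_key"] = list(df.index)
    df = df.sort_values(["f", "_key"], ascending=[False, True])
    return list(df.index[:k])


def top_clone_set(freqs: pd.DataFrame, k: int = 10) -> set:
    """Union over timepoints of the per-timepoint top-k clone lists."""
    out: set = set()
    for col in freqs.columns:
        out.update(top_clones(freqs[col], k))
    return out


def sharing_matrix(site_sets: Mapping[str, set]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise shared-site counts and row-relative percentages.

    ``shared[i, j] = |V_i & V_j|``; the diagonal reports |V_i|.
    ``percent[i, j] = 100 * |V_i & V_j| / |V_i|`` (relative to the row
    unit's set size; 100 on the diagonal).
    """
    units = list(site_sets)
    shared = pd.DataFrame(0, index=units, columns=units, dtype=int)
    percent = pd.DataFrame(np.nan, index=units, columns=units, dtype=float)
    for i in units:
        for j in units:
            n = len(site_sets[i] & site_sets[j])
            shared.loc[i, j] = n
            if len(site_sets[i]) > 0:
                percent.loc[i, j] = 100.0 * n / len(site_sets[i])
    return shared, percent


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation between two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance")
    return float(scipy.stats.pearsonr(x, y).statistic)


def icc_a1(
    data,
    form: Literal["absolute", "consistency"] = "absolute",
) -> float:
    """Single-rater intraclass correlation from a two-way ANOVA.

    ``data`` is n targets (clones) x k raters (replicates/samples) with no
    missing cells.  The default ``absolute`` agreement form is

        ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

    which penalizes systematic column shifts; ``consistency`` drops the
    column-variance term: (MS_R - MS_E) / (MS_R + (k-1) MS_E).
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need an n x k matrix with n >= 2, k >= 2")
    if np.isnan(x).any():
        raise ValueError("missing cells are not supported")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = ((x - grand) ** 2).sum()
    if ss_total == 0:
        raise ValueError("degenerate data")
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    if form == "absolute":
        denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    elif form == "consistency":
        denom = ms_r + (k - 1) * ms_e
    else:
        raise ValueError(f"unknown form: {form}")
    if denom == 0:
        raise ValueError("degenerate data")
    return float((ms_r - ms_e) / denom)


def concordance(data, form: Literal["absolute", "consistency"] = "absolute") -> ConcordanceResult:
    """Pearson r (first two columns) and ICC over all columns of ``data``."""
    x = np.asarray(data, dtype=float)
    return ConcordanceResult(
        pearson_r=pearson_r(x[:, 0], x[:, 1]),
        icc=icc_a1(x, form=form),
        n=x.shape[0],
        k=x.shape[1],
    )


def classify_clones(freqs: pd.DataFrame, k_top: int = 10) -> pd.DataFrame:
    """Per-clone summary over timepoints: max frequency, band, persistence,
    and the timepoints at which the clone ranks in the top k."""
    max_f = freqs.max(axis=1)
    bands = classify_frequency_bands(max_f)
    persistent = find_persistent(freqs)
    top_weeks: dict = {key: [] for key in freqs.index}
    for col in freqs.columns:
        for key in top_clones(freqs[col], k_top):
            top_weeks[key].append(col)
    return pd.DataFrame(
        {
            "max_frequency": max_f,
            "band": bands,
            "persistent": persistent,
            "top10_weeks": [",".join(map(str, top_weeks[key])) for key in freqs.index],
        },
        index=freqs.index,
    )
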