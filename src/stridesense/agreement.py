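"""Agreement between IMU-derived and reference stride lengths.

The headline statistics are Bland–Altman bias and limits of agreement (LOA)
on the per-stride percentage difference 100·(SL_imu − SL_ref)/SL_ref,
accounting for the repeated measures within participants: many strides per
athlete are not independent, so the SD entering the LOA is built from a
one-way random-effects decomposition of the differences over participants
(the Bland & Altman multiple-observations-per-individual method),

    MSB, MSW  from one-way ANOVA over participants,
    σ²_b = (MSB − MSW) / n₀       with n₀ the effective cluster size
           n₀ = (N² − Σnᵢ²) / ((m − 1)·N),
    SD_total = √(σ²_b + σ²_w),    LOA = 1.96·SD_total.

With one observation per participant this reduces to the classic
Bland–Altman SD of the differences, which is also the fallback when fewer
than two participants (or no within-participant replication) are available.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .types import AgreementReport

__all__ = ["percent_errors", "bland_altman_repeated"]

_Z = 1.96  # normal quantile for 95% limits of agreement


def percent_errors(pairs: pd.DataFrame) -> np.ndarray:
    """Per-stride percentage differences 100·(sl_imu − sl_ref)/sl_ref.

    ``pairs`` needs columns ``sl_imu`` and ``sl_ref`` (m); references must
    be positive.
    """
    ref = pairs["sl_ref"].to_numpy(dtype=float)
    imu = pairs["sl_imu"].to_numpy(dtype=float)
    if np.any(ref <= 0):
        raise ValueError("reference stride lengths must be positive")
    return 100.0 * (imu - ref) / ref


def _anova_components(d: np.ndarray, groups: np.ndarray):
    """One-way random-effects variance components of differences d grouped
    by participant.  Returns (sd_within, sd_between)."""
    labels, counts = np.unique(groups, return_counts=True)
    m, N = len(labels), len(d)
    grand = d.mean()
    means = np.array([d[groups == lab].mean() for lab in labels])
    ssb = float(np.sum(counts * (means - grand) ** 2))
    ssw = float(sum(np.sum((d[groups == lab] - means[i]) ** 2)
                    for i, lab in enumerate(labels)))
    msb = ssb / (m - 1)
    msw = ssw / (N - m) if N > m else 0.0
    n0 = (N**2 - np.sum(counts**2)) / ((m - 1) * N)
    var_b = max(0.0, (msb - msw) / n0)
    return np.sqrt(msw), np.sqrt(var_b)


def bland_altman_repeated(
    pairs: pd.DataFrame,
    scale: str = "percent",
    by: str | None = None,
) -> AgreementReport:
    """Bland–Altman bias ± LOA with the repeated-measures variance partition.

    Parameters
    ----------
    pairs
        One row per stride with columns ``participant``, ``sl_imu``,
        ``sl_ref`` (and optionally a grouping column such as ``effort``).
    scale
        ``"percent"`` analyses 100·(imu − ref)/ref (how sprint validity is
        usually reported); ``"absolute"`` analyses imu − ref in metres.
    by
        Optional column name; per-group sub-reports are attached to
        ``subgroups``.

    Falls back to the classic (independent-differences) LOA with a warning
    when the variance partition is not identifiable (single participant, or
    no participant with ≥ 2 strides).
    """
    if scale == "percent":
        d = percent_errors(pairs)
    elif scale == "absolute":
        d = pairs["sl_imu"].to_numpy(float) - pairs["sl_ref"].to_numpy(float)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    groups = pairs["participant"].to_numpy()
    labels, counts = np.unique(groups, return_counts=True)

    bias = float(d.mean())
    if len(labels) < 2 or counts.max() < 2:
        if len(d) > 1:
            sd_total = float(np.std(d, ddof=1))
        else:
            sd_total = 0.0
        if len(labels) < 2:
            warnings.warn(
                "fewer than 2 participants: falling back to classic "
                "Bland–Altman limits",
                stacklevel=2,
            )
        method = "classic"
        sd_w, sd_b = sd_total, 0.0
    else:
        sd_w, sd_b = _anova_components(d, groups)
        sd_total = float(np.hypot(sd_w, sd_b))
        method = "repeated"

    report = AgreementReport(
        bias=bias,
        loa=_Z * sd_total,
        sd_total=sd_total,
        sd_within=float(sd_w),
        sd_between=float(sd_b),
        n_strides=len(d),
        n_participants=len(labels),
        scale=scale,
        method=method,
    )
    if by is not None:
        for key, sub in pairs.groupby(by):
            report.subgroups[str(key)] = bland_altman_repeated(sub, scale=scale)
    return report
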