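"""Touch-down-artefact-corrected stride-length estimation.

A stride runs from touch-down (TD) of one foot to the next TD of the same
foot.  Horizontal global-frame acceleration is integrated once to velocity
and again to displacement; stride length is the norm of the horizontal
displacement vector.  The landing impact produces large acceleration peaks
in the first ~20 ms of ground contact that do not reflect horizontal foot
motion; upon integration they leave a spurious constant velocity offset.
The correction (a zero-velocity update, ZVU) exploits the amortisation
phase of early stance, where the foot is momentarily at rest:

1. integrate the unfiltered acceleration over the stride, axis by axis,
   mirroring an axis whose mean velocity is negative;
2. build a *temporary* velocity copy whose first 20 ms are clamped to the
   20 ms value plus a +1 m·s⁻¹ guard (so the trace always declines after
   20 ms) and low-pass filter it at 40 Hz;
3. take the minimum of the temporary trace 20–100 ms after touch-down
   (20–160 ms for stride 2, whose ground contact is the longest, usually
   >150 ms) as the velocity offset;
4. subtract the offset from the *original* velocity and zero all samples
   before the offset index;
5. integrate the corrected velocity to displacement.

The first stride of each foot has no preceding touch-down (standing start):
integration starts 280 ms before the first toe-off with zero initial
velocity and no offset correction.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.signal import bilinear, butter, filtfilt

from .config import RunConfig
from .types import (
    GaitEvents,
    GlobalSprint,
    StrideResult,
    StrideSegment,
    VelocityCorrection,
)

__all__ = [
    "segment_strides",
    "integrate_and_mirror",
    "temporary_velocity",
    "find_offset",
    "zero_velocity_update",
    "stride_length",
    "process_sprint",
    "max_stride_speed",
    "STRIDE_TABLE_COLUMNS",
]

#: Column order of the stride-table CSV produced by :func:`process_sprint`.
STRIDE_TABLE_COLUMNS = [
    "participant",
    "sprint",
    "effort",
    "foot",
    "stride_index",
    "td_time_s",
    "to_time_s",
    "duration_s",
    "length_m",
    "speed_m_s",
    "offset_vx_m_s",
    "offset_vz_m_s",
    "offset_index",
    "mirrored_x",
    "mirrored_z",
]


def segment_strides(
    ev: GaitEvents,
    fs: float,
    n_samples: int,
    pre_toeoff_s: float = 0.280,
) -> list[StrideSegment]:
    """Cut the signal of one foot into per-stride half-open index ranges.

    Stride 1 spans ``[first_to − round(pre_toeoff_s·fs), td[0])``; stride
    k ≥ 2 spans ``[td[k−2], td[k−1])``.  Strides truncated by the end of the
    signal are dropped with a warning.
    """
    ev.validate_alternation()
    if len(ev.to) == 0 or len(ev.td) == 0:
        return []
    pre = int(round(pre_toeoff_s * fs))
    start0 = int(ev.to[0]) - pre
    if start0 < 0:
        raise ValueError(
            f"first toe-off at sample {ev.to[0]} leaves fewer than "
            f"{pre} pre-start samples ({pre_toeoff_s * 1e3:.0f} ms at {fs} Hz)"
        )
    segments: list[StrideSegment] = []
    dropped = 0
    if ev.td[0] <= n_samples:
        segments.append(
            StrideSegment(
                foot=ev.foot,
                stride_index=1,
                start_idx=start0,
                end_idx=int(ev.td[0]),
                td_idx=None,
                contact_end_idx=None,
            )
        )
    else:
        dropped += 1
    for k in range(1, len(ev.td)):
        end = int(ev.td[k])
        if end > n_samples:
            dropped += 1
            continue
        start = int(ev.td[k - 1])
        # the toe-off terminating the stance that begins this stride
        later_tos = ev.to[ev.to > start]
        contact_end = int(later_tos[0]) if len(later_tos) else None
        segments.append(
            StrideSegment(
                foot=ev.foot,
                stride_index=k + 1,
                start_idx=start,
                end_idx=end,
                td_idx=start,
                contact_end_idx=contact_end,
            )
        )
    if dropped:
        warnings.warn(
            f"{dropped} stride(s) truncated by the end of the signal were dropped",
            stacklevel=2,
        )
    return segments


def integrate_and_mirror(
    seg: StrideSegment, sprint: GlobalSprint
) -> tuple[np.ndarray, np.ndarray, bool, bool]:
    """First integration: unfiltered acceleration → 'original' velocities.

    Cumulative trapezoid with zero initial velocity, per axis.  An axis whose
    mean velocity over the stride is negative is mirrored (negated) so that
    the downstream minimum search and offset subtraction always operate on a
    forward-running trace; the mirror flag is reported.

    Returns ``(vx, vz, mirrored_x, mirrored_z)``.
    """
    if seg.start_idx < 0 or seg.end_idx > len(sprint):
        raise ValueError(
            f"stride {seg.stride_index} range [{seg.start_idx}, {seg.end_idx}) "
            f"outside signal of {len(sprint)} samples"
        )
    dt = 1.0 / sprint.fs
    out = []
    flags = []
    for a in (sprint.acc_x, sprint.acc_z):
        v = cumulative_trapezoid(a[seg.start_idx : seg.end_idx], dx=dt, initial=0.0)
        mirrored = bool(np.mean(v) < 0)
        if mirrored:
            v = -v
        out.append(v)
        flags.append(mirrored)
    return out[0], out[1], flags[0], flags[1]


def _zero_phase_lowpass(
    v: np.ndarray, fs: float, cutoff_hz: float, kind: str = "critical"
) -> np.ndarray:
    """Zero-phase (forward–backward) 2nd-order low-pass.

    ``kind="critical"`` uses a critically damped section (double real pole
    at ``cutoff_hz``): its step response is monotone, so the +1 m·s⁻¹ guard
    step cannot ring an artificial minimum into the offset-search window,
    and its stop-band suppression of filtered white noise above 40 Hz is
    stronger than the Butterworth's.  ``kind="butter"`` is the conventional
    maximally flat alternative (slight step undershoot).
    """
    if kind == "critical":
        w0 = 2.0 * np.pi * cutoff_hz
        b, a = bilinear([w0**2], [1.0, 2.0 * w0, w0**2], fs)
    elif kind == "butter":
        b, a = butter(2, cutoff_hz / (fs / 2.0), btype="low")
    else:
        raise ValueError(f"unknown filter kind {kind!r}")
    return filtfilt(b, a, v)


def temporary_velocity(
    v_orig: np.ndarray,
    fs: float,
    guard_m_s: float = 1.0,
    lowpass_hz: float = 40.0,
    filter_kind: str = "critical",
) -> np.ndarray:
    """Build the filtered guard ('temporary') velocity used for offset search.

    The first ``round(0.020·fs)`` samples are replaced by the value at the
    20 ms sample plus ``guard_m_s`` (default +1 m·s⁻¹), guaranteeing the
    trace declines after 20 ms; the result is low-pass filtered at
    ``lowpass_hz`` with a zero-phase 2nd-order filter (see
    :func:`_zero_phase_lowpass`; the critically damped default cannot
    undershoot the guard step).  ``v_orig`` is left untouched.
    """
    clamp = int(round(0.020 * fs))
    if len(v_orig) <= clamp:
        raise ValueError(
            f"stride of {len(v_orig)} samples is shorter than the "
            f"{clamp}-sample clamp window"
        )
    v = np.array(v_orig, dtype=float)
    v[:clamp] = v[clamp] + guard_m_s
    return _zero_phase_lowpass(v, fs, lowpass_hz, kind=filter_kind)


def find_offset(
    v_tmp: np.ndarray,
    td_rel_idx: int,
    window: tuple[float, float],
    fs: float,
) -> tuple[float, int]:
    """Minimum of the temporary velocity within a window after touch-down.

    The window endpoints (seconds after TD) are converted with
    ``round(·fs)`` and are inclusive on both ends; ties take the earliest
    sample.  Returns ``(offset_value, offset_idx)`` with the index relative
    to the stride start.
    """
    lo = td_rel_idx + int(round(window[0] * fs))
    hi = td_rel_idx + int(round(window[1] * fs))
    if hi >= len(v_tmp):
        raise ValueError(
            f"offset window [{lo}, {hi}] exceeds stride of {len(v_tmp)} samples"
        )
    sl = v_tmp[lo : hi + 1]
    k = int(np.argmin(sl))  # argmin returns the first minimum on ties
    return float(sl[k]), lo + k


def zero_velocity_update(
    v_orig: np.ndarray, offset_value: float, offset_idx: int
) -> np.ndarray:
    """Apply the zero-velocity update.

    Samples strictly before ``offset_idx`` are set to zero; from
    ``offset_idx`` on, ``offset_value`` is subtracted.
    """
    if not 0 <= offset_idx < len(v_orig):
        raise IndexError(
            f"offset index {offset_idx} out of range for {len(v_orig)} samples"
        )
    out = np.asarray(v_orig, dtype=float) - offset_value
    out[:offset_idx] = 0.0
    return out


def linear_dedrift(v: np.ndarray) -> np.ndarray:
    """Remove a linear velocity ramp so the stride ends at zero velocity.

    Classic drift correction for constant-speed running; offered for
    comparison (default off) — with the first 20 ms of contact dominated by
    impact artefacts it does not remove the touch-down velocity offset.
    """
    n = len(v)
    if n < 2:
        return np.array(v, dtype=float)
    ramp = np.linspace(0.0, v[-1], n)
    return np.asarray(v, dtype=float) - ramp


def stride_length(
    v_final_x: np.ndarray, v_final_z: np.ndarray, fs: float
) -> tuple[float, float, float]:
    """Second integration: corrected velocities → (length, dx, dz).

    dx and dz are trapezoid time-integrals of the final velocities; stride
    length is √(dx² + dz²).
    """
    if len(v_final_x) != len(v_final_z):
        raise ValueError("velocity components must have equal length")
    dt = 1.0 / fs
    dx = float(np.trapezoid(v_final_x, dx=dt))
    dz = float(np.trapezoid(v_final_z, dx=dt))
    return float(np.hypot(dx, dz)), dx, dz


def _process_segment(
    seg: StrideSegment, sprint: GlobalSprint, cfg: RunConfig
) -> StrideResult:
    fs = sprint.fs
    vx, vz, mx, mz = integrate_and_mirror(seg, sprint)
    qc: set = set()
    correction: Optional[VelocityCorrection] = None

    use_zvu = bool(cfg["zvu.enabled"]) and seg.stride_index >= 2
    if use_zvu:
        hi = (
            cfg["zvu.window_hi_stride2_s"]
            if seg.stride_index == 2
            else cfg["zvu.window_hi_s"]
        )
        window = (cfg["zvu.window_lo_s"], hi)
        if seg.contact_end_idx is not None:
            contact_s = (seg.contact_end_idx - seg.start_idx) / fs
            if contact_s < window[0]:
                qc.add("contact_shorter_than_window")
                raise _SkippedStride(seg, "ground contact shorter than the offset window")
        offsets = []
        for v in (vx, vz):
            v_tmp = temporary_velocity(
                v,
                fs,
                guard_m_s=cfg["zvu.guard_m_s"],
                lowpass_hz=cfg["zvu.lowpass_hz"],
                filter_kind=cfg["zvu.filter"],
            )
            offsets.append(find_offset(v_tmp, 0, window, fs))
        (ox, ix), (oz, iz) = offsets
        vx = zero_velocity_update(vx, ox, ix)
        vz = zero_velocity_update(vz, oz, iz)
        correction = VelocityCorrection(
            offset_vx=ox,
            offset_vz=oz,
            offset_idx_x=ix,
            offset_idx_z=iz,
            window=window,
            mirrored_x=mx,
            mirrored_z=mz,
        )
    elif seg.stride_index >= 2:
        qc.add("zvu_bypassed")

    if cfg["dedrift.linear"]:
        vx = linear_dedrift(vx)
        vz = linear_dedrift(vz)
        qc.add("linear_dedrift")

    length, dx, dz = stride_length(vx, vz, fs)
    duration = seg.n_samples / fs
    return StrideResult(
        foot=seg.foot,
        stride_index=seg.stride_index,
        length=length,
        duration=duration,
        speed=length / duration,
        displacement=(dx, dz),
        td_time=None if seg.td_idx is None else sprint.t[seg.td_idx],
        to_time=(
            None
            if seg.contact_end_idx is None or seg.contact_end_idx >= len(sprint)
            else sprint.t[seg.contact_end_idx]
        ),
        correction=correction,
        qc_flags=qc,
    )


class _SkippedStride(Exception):
    def __init__(self, seg: StrideSegment, reason: str):
        self.seg = seg
        self.reason = reason
        super().__init__(f"stride {seg.stride_index} ({seg.foot}): {reason}")


def process_sprint(
    sprint: GlobalSprint,
    ev: Optional[GaitEvents] = None,
    cfg: Optional[RunConfig] = None,
    participant: str = "unknown",
    sprint_id: str = "sprint",
    effort: str = "unknown",
) -> pd.DataFrame:
    """Run the full stride pipeline on one sprint of one foot.

    Returns a stride table (one row per complete stride, numbered from 1)
    with the columns of :data:`STRIDE_TABLE_COLUMNS`.  Strides whose stance
    is shorter than the offset-search window are skipped with a warning.
    """
    cfg = cfg or RunConfig()
    if ev is None:
        ev = sprint.events
    if ev is None:
        raise ValueError("no gait events supplied and none attached to the sprint")
    segments = segment_strides(
        ev, sprint.fs, len(sprint), pre_toeoff_s=cfg["start.pre_toeoff_s"]
    )
    rows = []
    for seg in segments:
        try:
            res = _process_segment(seg, sprint, cfg)
        except _SkippedStride as exc:
            warnings.warn(str(exc), stacklevel=2)
            continue
        except Exception as exc:
            raise RuntimeError(
                f"stride {seg.stride_index} ({seg.foot}) failed: {exc}"
            ) from exc
        corr = res.correction
        rows.append(
            {
                "participant": participant,
                "sprint": sprint_id,
                "effort": effort,
                "foot": res.foot,
                "stride_index": res.stride_index,
                "td_time_s": np.nan if res.td_time is None else res.td_time,
                "to_time_s": np.nan if res.to_time is None else res.to_time,
                "duration_s": res.duration,
                "length_m": res.length,
                "speed_m_s": res.speed,
                "offset_vx_m_s": np.nan if corr is None else corr.offset_vx,
                "offset_vz_m_s": np.nan if corr is None else corr.offset_vz,
                "offset_index": -1 if corr is None else corr.offset_idx_x,
                "mirrored_x": False if corr is None else corr.mirrored_x,
                "mirrored_z": False if corr is None else corr.mirrored_z,
            }
        )
    return pd.DataFrame(rows, columns=STRIDE_TABLE_COLUMNS)


def max_stride_speed(table: pd.DataFrame) -> float:
    """The highest stride speed reached in a sprint (m·s⁻¹), over both feet."""
    if len(table) == 0:
        raise ValueError("empty stride table")
    return float(table["speed_m_s"].max())
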