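"""Gait-event detection and dual-sensor time synchronization.

Touch-down (TD) and toe-off (TO) are detected from the medial–lateral
(sensor x) gyroscope axis.  During the swing phase the foot rotates rapidly
forward, producing a large angular-rate peak at mid-swing; the instants of
ground contact show up as sharp opposite-sign extrema immediately around
the stance phase.  The rule implemented here:

1. low-pass the angular rate at 10 Hz (zero phase) and locate mid-swing
   peaks by prominence;
2. between consecutive swing peaks, find opposite-sign local extrema of the
   *raw* signal: the first one after a swing peak is that swing's
   touch-down, the last one before the next swing peak is the next toe-off;
3. before the first swing peak only a toe-off exists (standing start), so
   the event sequence of each foot is TO, TD, TO, TD, ...

Two sensors logged independently are aligned via the shared transient
produced by tapping them together on a hard surface before mounting: the
integer lag maximizing the cross-correlation of the acceleration norms over
a search window.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.signal import butter, correlate, correlation_lags, filtfilt, find_peaks

from .types import GaitEvents, ImuRecording, G_DEFAULT

__all__ = ["detect_events", "detect_sync_tap", "ground_contact_times"]


def detect_events(
    gyr_x: np.ndarray,
    fs: float,
    foot: str = "unknown",
    lowpass_hz: float = 10.0,
    swing_prominence: float = 3.0,
    dip_prominence: float = 1.0,
) -> GaitEvents:
    """Detect touch-downs and toe-offs from the medial–lateral angular rate.

    Parameters
    ----------
    gyr_x
        Angular rate about the medial–lateral axis, rad·s⁻¹ (sign such that
        mid-swing rotation is positive; the detector flips the sign itself
        if the median swing polarity is negative).
    fs
        Sampling frequency, Hz.
    swing_prominence
        Minimum prominence (rad·s⁻¹) of a low-passed mid-swing peak.
    dip_prominence
        Minimum prominence of the raw-signal opposite-sign extrema marking
        TD and TO.

    Returns an alternating event sequence; with no detectable swing peaks an
    empty :class:`GaitEvents` is returned with a warning.
    """
    gyr_x = np.asarray(gyr_x, dtype=float)
    if len(gyr_x) < fs:
        raise ValueError("need at least 1 s of signal")
    b, a = butter(2, lowpass_hz / (fs / 2.0), btype="low")
    smooth = filtfilt(b, a, gyr_x)

    peaks, _ = find_peaks(smooth, prominence=swing_prominence)
    npeaks, _ = find_peaks(-smooth, prominence=swing_prominence)
    if len(npeaks) > len(peaks):
        # mounting polarity inverted: mid-swing rotation shows up negative
        gyr_x = -gyr_x
        smooth = -smooth
        peaks = npeaks
    if len(peaks) == 0:
        warnings.warn("no swing peaks found; returning empty events", stacklevel=2)
        return GaitEvents(td=np.array([], int), to=np.array([], int), foot=foot)

    def dips(lo: int, hi: int) -> np.ndarray:
        """Opposite-sign (negative) raw extrema in the half-open range."""
        seg = gyr_x[lo:hi]
        idx, _ = find_peaks(-seg, prominence=dip_prominence)
        return idx + lo

    td, to = [], []
    # toe-off preceding the first swing peak (standing start)
    first = dips(0, peaks[0])
    if len(first):
        to.append(int(first[-1]))
    for k, p in enumerate(peaks):
        hi = peaks[k + 1] if k + 1 < len(peaks) else len(gyr_x)
        d = dips(p, hi)
        if len(d) == 0:
            continue
        td.append(int(d[0]))           # touch-down ending this swing
        if k + 1 < len(peaks) and len(d) >= 2:
            to.append(int(d[-1]))      # toe-off starting the next swing

    td_arr, to_arr = np.array(sorted(td), int), np.array(sorted(to), int)
    ev = GaitEvents(td=td_arr, to=to_arr, foot=foot)
    ev.validate_alternation()
    return ev


def detect_sync_tap(
    rec_a: ImuRecording,
    rec_b: ImuRecording,
    window_s: float = 5.0,
    threshold_g: float = 3.0,
) -> int:
    """Integer lag (samples) aligning two sensors via the shared tap transient.

    Positive lag means ``rec_b`` is delayed relative to ``rec_a`` by that
    many samples (advance b by the lag to align).  The transient must exceed
    ``threshold_g`` above 1 g in the acceleration norm within the first
    ``window_s`` seconds of both logs.
    """
    fs = rec_a.fs
    n = int(round(window_s * fs))
    norms = []
    for name, rec in (("rec_a", rec_a), ("rec_b", rec_b)):
        nm = np.linalg.norm(rec.acc[:n], axis=1)
        if np.max(np.abs(nm - G_DEFAULT)) < threshold_g * G_DEFAULT:
            raise ValueError(
                f"no tap transient above {threshold_g} g found in {name} "
                f"within the first {window_s} s"
            )
        norms.append(nm - np.mean(nm))
    xc = correlate(norms[0], norms[1], mode="full")
    lags = correlation_lags(len(norms[0]), len(norms[1]), mode="full")
    return -int(lags[np.argmax(xc)])


def ground_contact_times(ev: GaitEvents, fs: float) -> np.ndarray:
    """Per-stance durations (s): each touch-down to the following toe-off."""
    if len(ev.td) == 0:
        return np.array([], dtype=float)
    ev.validate_alternation()
    out = []
    for td in ev.td:
        later = ev.to[ev.to > td]
        if len(later):
            out.append((later[0] - td) / fs)
    return np.array(out, dtype=float)
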