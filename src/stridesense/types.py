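"""Core data containers for the stride-length pipeline.

Conventions used throughout the package:

* Sensor frame: x = medial–lateral foot axis, y and z per mounting.
* Global frame: y points upward (against gravity), x along the initial
  horizontal heading (or the horizontal geomagnetic component when a
  magnetometer is available), z transverse.  Stride length is the norm of
  the horizontal (x, z) displacement, so the choice of horizontal heading
  does not affect it.
* All quantities are SI: seconds, m·s⁻², rad·s⁻¹, μT for the magnetic field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Default gravitational acceleration, m·s⁻².
G_DEFAULT = 9.81

#: Accelerometer full-scale range of the reference sensor (MPU-9150), in g.
ACC_RANGE_G = 16.0

#: Gyroscope full-scale range of the reference sensor, in °/s.
GYR_RANGE_DPS = 2000.0


@dataclass
class ImuRecording:
    """Time-synchronized raw streams of one foot-mounted 9-DOF sensor."""

    t: np.ndarray                      # seconds, monotonically increasing
    acc: np.ndarray                    # (n, 3) specific force, m·s⁻²
    gyr: np.ndarray                    # (n, 3) angular rate, rad·s⁻¹
    fs: float                          # Hz
    foot: str = "unknown"              # "left" | "right" | "unknown"
    mag: Optional[np.ndarray] = None   # (n, 3) magnetic field, μT
    acc_saturated: Optional[np.ndarray] = None  # (n, 3) bool flags
    gyr_saturated: Optional[np.ndarray] = None  # (n, 3) bool flags

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.atleast_2d(np.asarray(self.acc, dtype=float))
        self.gyr = np.atleast_2d(np.asarray(self.gyr, dtype=float))
        n = len(self.t)
        if self.acc.shape != (n, 3) or self.gyr.shape != (n, 3):
            raise ValueError(
                f"stream length mismatch: t has {n} samples, "
                f"acc {self.acc.shape}, gyr {self.gyr.shape}"
            )
        if self.fs <= 0:
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")
        if n > 1 and np.any(np.diff(self.t) <= 0):
            bad = int(np.argmax(np.diff(self.t) <= 0))
            raise ValueError(f"timestamps not strictly increasing at sample {bad + 1}")
        if self.mag is not None:
            self.mag = np.atleast_2d(np.asarray(self.mag, dtype=float))
            if self.mag.shape != (n, 3):
                raise ValueError(f"mag shape {self.mag.shape} != ({n}, 3)")
        if self.acc_saturated is None:
            self.acc_saturated = np.zeros((n, 3), dtype=bool)
        if self.gyr_saturated is None:
            self.gyr_saturated = np.zeros((n, 3), dtype=bool)

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class GaitEvents:
    """Ordered touch-down (td) and toe-off (to) sample indices of one foot.

    From a standing start the first event of each foot is a toe-off, so the
    sequence alternates TO, TD, TO, TD, ...; every touch-down is terminated
    by the following toe-off of the same foot.
    """

    td: np.ndarray
    to: np.ndarray
    foot: str = "unknown"

    def __post_init__(self) -> None:
        self.td = np.asarray(self.td, dtype=int)
        self.to = np.asarray(self.to, dtype=int)
        for name, arr in (("td", self.td), ("to", self.to)):
            if arr.size > 1 and np.any(np.diff(arr) <= 0):
                raise ValueError(f"{name} indices must be strictly increasing")

    def validate_alternation(self) -> None:
        """Raise if the merged event sequence does not alternate TO, TD, TO, ..."""
        merged = sorted(
            [(i, 0) for i in self.to] + [(i, 1) for i in self.td]
        )
        bad = [
            merged[k][0]
            for k in range(len(merged))
            if merged[k][1] != k % 2  # even slots are TOs, odd slots TDs
        ]
        if bad:
            raise ValueError(
                f"events do not alternate TO, TD, TO, ... (offending indices {bad})"
            )

    @property
    def n_strides(self) -> int:
        """Complete strides available: the 280 ms pre-start stride plus one
        per consecutive touch-down pair."""
        return len(self.td) if len(self.to) else 0

    def __len__(self) -> int:
        return len(self.td) + len(self.to)


@dataclass
class GlobalSprint:
    """Global-frame foot acceleration of one sprint for one foot.

    Only the horizontal components ``acc_x`` and ``acc_z`` feed the
    double-integration core; the vertical component is carried through for
    completeness.
    """

    t: np.ndarray
    acc_x: np.ndarray
    acc_z: np.ndarray
    fs: float
    acc_y: Optional[np.ndarray] = None
    foot: str = "unknown"
    events: Optional[GaitEvents] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc_x = np.asarray(self.acc_x, dtype=float)
        self.acc_z = np.asarray(self.acc_z, dtype=float)
        n = len(self.t)
        if len(self.acc_x) != n or len(self.acc_z) != n:
            raise ValueError("acceleration streams must match timestamp length")
        if self.acc_y is not None:
            self.acc_y = np.asarray(self.acc_y, dtype=float)
            if len(self.acc_y) != n:
                raise ValueError("acc_y length mismatch")
        if self.fs <= 0:
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")
        if self.events is not None:
            hi = max(
                [self.events.td.max(initial=-1), self.events.to.max(initial=-1)]
            )
            if hi >= n:
                raise ValueError(
                    f"event index {hi} out of range for signal of {n} samples"
                )

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class OrientationSeries:
    """Per-sample unit quaternions (w, x, y, z) mapping sensor → global frame."""

    q: np.ndarray       # (n, 4)
    beta: float
    fs: float

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim != 2 or self.q.shape[1] != 4:
            raise ValueError("quaternion array must have shape (n, 4)")

    def __len__(self) -> int:
        return len(self.q)


@dataclass
class StrideSegment:
    """Half-open sample range [start_idx, end_idx) of one stride.

    A stride runs from a touch-down to the next touch-down of the same foot.
    Stride 1 has no preceding touch-down: it starts a fixed interval
    (default 280 ms) before the first toe-off.
    """

    foot: str
    stride_index: int                  # 1-based
    start_idx: int
    end_idx: int
    td_idx: Optional[int] = None       # absent for stride 1
    contact_end_idx: Optional[int] = None  # toe-off ending the stance at stride start

    def __post_init__(self) -> None:
        if self.start_idx >= self.end_idx:
            raise ValueError(
                f"stride {self.stride_index}: start {self.start_idx} "
                f">= end {self.end_idx}"
            )
        if self.stride_index >= 2 and self.td_idx != self.start_idx:
            raise ValueError("strides ≥ 2 must start at their touch-down index")

    @property
    def n_samples(self) -> int:
        return self.end_idx - self.start_idx


@dataclass
class VelocityCorrection:
    """Diagnostics of the per-axis touch-down velocity-offset correction."""

    offset_vx: float
    offset_vz: float
    offset_idx_x: int          # sample index of the detected minimum, stride-relative
    offset_idx_z: int
    window: tuple              # (lo, hi) seconds after touch-down
    mirrored_x: bool = False
    mirrored_z: bool = False


@dataclass
class StrideResult:
    """One stride's estimated geometry plus correction diagnostics."""

    foot: str
    stride_index: int
    length: float              # m
    duration: float            # s
    speed: float               # m·s⁻¹
    displacement: tuple        # (dx, dz) m
    td_time: Optional[float] = None   # s, absent for stride 1
    to_time: Optional[float] = None
    correction: Optional[VelocityCorrection] = None
    qc_flags: set = field(default_factory=set)


@dataclass
class SprintProfile:
    """Mono-exponential sprint-speed profile v(t) = v_max·(1 − e^(−t/τ))."""

    v_max: float               # m·s⁻¹
    tau: float                 # s
    distance: float = 35.0     # m
    effort_label: str = "100"

    def __post_init__(self) -> None:
        if self.v_max <= 0 or self.tau <= 0:
            raise ValueError("v_max and tau must be positive")

    def speed(self, t):
        """Body speed at time t (s) since the start of the push-off."""
        t = np.asarray(t, dtype=float)
        return self.v_max * (1.0 - np.exp(-np.maximum(t, 0.0) / self.tau))

    def position(self, t):
        """Body displacement ∫₀ᵗ v dτ = v_max·(t + τ·e^(−t/τ) − τ)."""
        t = np.maximum(np.asarray(t, dtype=float), 0.0)
        return self.v_max * (t + self.tau * np.exp(-t / self.tau) - self.tau)

    def time_to_distance(self, d: float) -> float:
        """Closed-form-free inverse of :meth:`position` (monotone bisection)."""
        from scipy.optimize import brentq

        hi = d / self.v_max + 10.0 * self.tau
        return float(brentq(lambda t: self.position(t) - d, 0.0, hi, xtol=1e-10))


@dataclass
class SyntheticSprint:
    """Simulator output: per-foot signals, ground-truth events and lengths."""

    sprints: dict              # foot -> GlobalSprint
    true_events: dict          # foot -> GaitEvents
    true_stride_lengths: dict  # foot -> np.ndarray (m), stride 1 first
    true_foot_positions: dict  # foot -> (m, 2) footfall (x, z) incl. start position
    gyr_x: dict                # foot -> medial–lateral angular rate, rad·s⁻¹
    profile: SprintProfile
    fs: float
    seed: int
    params: dict = field(default_factory=dict)


@dataclass
class AgreementReport:
    """Bland–Altman agreement between IMU and reference stride lengths."""

    bias: float                # mean difference (% or m)
    loa: float                 # half-width of the limits of agreement (1.96·SD)
    sd_total: float
    sd_within: float
    sd_between: float
    n_strides: int
    n_participants: int
    scale: str = "percent"     # "percent" | "absolute"
    method: str = "repeated"   # "repeated" | "classic"
    subgroups: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "bias": self.bias,
            "loa": self.loa,
            "sd_total": self.sd_total,
            "sd_within": self.sd_within,
            "sd_between": self.sd_between,
            "n_strides": self.n_strides,
            "n_participants": self.n_participants,
            "scale": self.scale,
            "method": self.method,
        }
        if self.subgroups:
            d["subgroups"] = {k: v.to_dict() for k, v in self.subgroups.items()}
        return d
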