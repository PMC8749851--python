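"""Synthetic sprint generator with exact ground truth.

The simulator produces global-frame foot acceleration of maximal linear
sprint acceleration with known touch-down/toe-off instants and known stride
lengths, so every stage of the pipeline can be validated without measured
data.

Model
-----
Body speed follows the canonical mono-exponential sprint profile
``v(t) = v_max·(1 − e^(−t/τ))``.  Footfalls alternate: each foot is planted
during stance (true foot velocity ≡ 0 in contact — the premise of the
zero-velocity update) and advances to its next footfall position during
swing along a minimum-jerk trajectory, which starts and ends with zero
velocity and acceleration.  Stride frequency rises and ground contact time
falls linearly with running speed, so strides lengthen as the sprint
progresses.  Footfall positions track the body position, making each true
stride length the product of stride duration and mean body speed over the
stride.

On top of the exact kinematic acceleration the generator can add

* a touch-down impact artefact: an exponentially damped ~120 Hz burst
  confined to the first ~15 ms of contact, peaking at 10–40 g, optionally
  carrying a nonzero net velocity integral (default 0.4 m·s⁻¹ nominal) —
  the spurious velocity offset that the zero-velocity update corrects;
* white sensor noise on acceleration and angular rate;
* saturation clipping at the ±16 g accelerometer range.

A synthetic medial–lateral angular-rate channel is generated alongside:
a broad positive mid-swing lobe plus sharp negative extrema exactly at each
touch-down and toe-off, which is the signature the event detector keys on.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .types import (
    GaitEvents,
    GlobalSprint,
    ImuRecording,
    SprintProfile,
    SyntheticSprint,
    G_DEFAULT,
)

__all__ = [
    "make_profile",
    "simulate",
    "emit_fixtures",
    "ArtefactConfig",
    "NoiseConfig",
    "inject_tap",
    "prescribed_rotation_imu",
    "EFFORT_VMAX",
]

#: Default maximal speed (m·s⁻¹) per subjective-effort level, matching the
#: maximal stride speeds typically reached by recreational sprinters at
#: 60 / 80 / 100 % effort.
EFFORT_VMAX = {"60": 7.0, "80": 7.65, "100": 8.4}


@dataclass
class ArtefactConfig:
    """Touch-down impact transient parameters."""

    enabled: bool = True
    duration_s: float = 0.015        # confined to the first ~15 ms of contact
    peak_g: tuple = (10.0, 40.0)     # oscillatory peak range, g
    center_freq_hz: float = 120.0
    decay_s: float = 0.004
    net_dv_m_s: float = 0.4          # nominal spurious velocity offset magnitude
    zero_net: bool = False           # force zero net velocity integral


@dataclass
class NoiseConfig:
    acc_sigma: float = 0.3           # white acceleration noise, m·s⁻²
    gyr_sigma: float = 0.05          # white angular-rate noise, rad·s⁻¹


def make_profile(
    effort_label: str | int,
    v_max: float | None = None,
    tau: float = 1.3,
    distance: float = 35.0,
) -> SprintProfile:
    """Mono-exponential speed profile for a 35 m sprint at a given effort.

    Defaults: v_max = 7.0 / 7.65 / 8.4 m·s⁻¹ at 60 / 80 / 100 % effort,
    τ = 1.3 s; all overridable.
    """
    label = str(effort_label)
    if label not in EFFORT_VMAX:
        raise ValueError(f"effort must be one of {sorted(EFFORT_VMAX)}, got {label!r}")
    return SprintProfile(
        v_max=EFFORT_VMAX[label] if v_max is None else v_max,
        tau=tau,
        distance=distance,
        effort_label=label,
    )


def _stride_frequency(v: float) -> float:
    """Stride (full-cycle) frequency vs running speed, Hz."""
    return 1.55 + 0.08 * v


def _contact_time(v: float) -> float:
    """Ground contact time vs running speed, s (>150 ms at jogging speeds,
    ~120 ms near maximal sprinting)."""
    return max(0.105, 0.240 - 0.014 * v)


def _minimum_jerk(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalized minimum-jerk position s(u) and acceleration s''(u)."""
    s = 10 * u**3 - 15 * u**4 + 6 * u**5
    s2 = 60 * u - 180 * u**2 + 120 * u**3
    return s, s2


def _schedule_foot(
    profile: SprintProfile,
    first_to_s: float,
    p0: float,
    t_launch: float,
    fs: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Footfall schedule of one foot: toe-off times, touch-down times and
    landing x-positions, all event times snapped to the sample grid."""
    snap = lambda t: round(t * fs) / fs
    to_times, td_times, positions = [], [], []
    t_to = snap(first_to_s)
    while True:
        v_ref = float(profile.speed(t_to - t_launch))
        t_sw = 1.0 / _stride_frequency(v_ref) - _contact_time(v_ref)
        if t_sw <= 0:
            raise ValueError("infeasible cadence/contact parameters: negative swing time")
        t_td = snap(t_to + t_sw)
        x_land = float(profile.position(t_td - t_launch))
        if x_land > profile.distance:
            break
        to_times.append(t_to)
        td_times.append(t_td)
        positions.append(x_land)
        t_to = snap(t_td + _contact_time(float(profile.speed(t_td - t_launch))))
    if not td_times:
        raise ValueError("sprint distance too short: no complete stride generated")
    return np.array(to_times), np.array(td_times), np.array(positions)


def _foot_signals(
    t: np.ndarray,
    to_times: np.ndarray,
    td_times: np.ndarray,
    x_positions: np.ndarray,
    z_positions: np.ndarray,
    p0: tuple[float, float],
    hop_height: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic second derivative of the piecewise stance/swing foot path."""
    ax = np.zeros_like(t)
    ay = np.zeros_like(t)
    az = np.zeros_like(t)
    prev = np.array([p0[0], p0[1]])
    for k in range(len(td_times)):
        t0, t1 = to_times[k], td_times[k]
        tsw = t1 - t0
        mask = (t >= t0) & (t < t1)
        u = (t[mask] - t0) / tsw
        _, s2 = _minimum_jerk(u)
        target = np.array([x_positions[k], z_positions[k]])
        delta = target - prev
        ax[mask] = delta[0] * s2 / tsw**2
        az[mask] = delta[1] * s2 / tsw**2
        # vertical hop: y(u) = h·sin²(πu); y'' = 2h·π²·cos(2πu)/tsw²
        ay[mask] = 2 * hop_height * np.pi**2 * np.cos(2 * np.pi * u) / tsw**2
        prev = target
    return ax, ay, az


def _gyro_signature(
    t: np.ndarray,
    to_times: np.ndarray,
    td_times: np.ndarray,
    swing_peak: float = 12.0,
    dip: float = 8.0,
    dip_sigma_s: float = 0.005,
) -> np.ndarray:
    """Synthetic medial–lateral angular rate: broad positive mid-swing lobes,
    sharp negative extrema centred exactly on each toe-off and touch-down."""
    g = np.zeros_like(t)
    for k in range(len(td_times)):
        t0, t1 = to_times[k], td_times[k]
        mid, sig = 0.5 * (t0 + t1), (t1 - t0) / 6.0
        g += swing_peak * np.exp(-0.5 * ((t - mid) / sig) ** 2)
        g -= dip * np.exp(-0.5 * ((t - t0) / dip_sigma_s) ** 2)
        g -= dip * np.exp(-0.5 * ((t - t1) / dip_sigma_s) ** 2)
    return g


def _impact_bursts(
    t: np.ndarray,
    td_times: np.ndarray,
    cfg: ArtefactConfig,
    rng: np.random.Generator,
    g: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Damped high-frequency bursts at each touch-down (x and z channels)."""
    ax = np.zeros_like(t)
    az = np.zeros_like(t)
    for td in td_times:
        rel = t - td
        mask = (rel >= 0) & (rel < cfg.duration_s)
        tr = rel[mask]
        peak = rng.uniform(*cfg.peak_g) * g
        osc = np.exp(-tr / cfg.decay_s) * np.sin(2 * np.pi * cfg.center_freq_hz * tr)
        if len(osc):
            osc = osc - osc.mean()  # burst alone carries no net velocity change
        ax[mask] += rng.choice([-1.0, 1.0]) * peak * osc
        az[mask] += rng.choice([-1.0, 1.0]) * 0.5 * peak * osc
        if not cfg.zero_net:
            # half-sine pulse with net time-integral dv (the spurious
            # velocity offset the ZVU must remove)
            dv_x = cfg.net_dv_m_s * rng.uniform(0.8, 1.2) * rng.choice([-1.0, 1.0])
            dv_z = cfg.net_dv_m_s * rng.uniform(0.2, 0.5) * rng.choice([-1.0, 1.0])
            pulse = (np.pi / (2 * cfg.duration_s)) * np.sin(np.pi * tr / cfg.duration_s)
            ax[mask] += dv_x * pulse
            az[mask] += dv_z * pulse
    return ax, az


def simulate(
    profile: SprintProfile,
    fs: float = 500.0,
    seed: int = 1,
    artefact: ArtefactConfig | None = None,
    noise: NoiseConfig | None = None,
    clip_range: bool = False,
    z_scatter_m: float = 0.02,
    hop_height_m: float = 0.12,
    g: float = G_DEFAULT,
) -> SyntheticSprint:
    """Generate one synthetic sprint (both feet) with exact ground truth.

    Parameters
    ----------
    profile
        Body-speed profile (see :func:`make_profile`).
    fs
        Sampling frequency, Hz (≥ 200).
    artefact, noise
        Touch-down transient and sensor-noise settings; ``None`` uses the
        defaults, pass ``ArtefactConfig(enabled=False)`` / a zero-σ
        ``NoiseConfig`` for clean signals.
    clip_range
        Clip acceleration at the ±16 g sensor range (flags are not modelled
        on the global-frame output; clipping simply saturates).
    z_scatter_m
        SD of the lateral footfall scatter around each foot's line, m.
    """
    if fs < 200:
        raise ValueError("fs must be at least 200 Hz")
    artefact = artefact if artefact is not None else ArtefactConfig()
    noise = noise if noise is not None else NoiseConfig()
    rng = np.random.default_rng(seed)

    t_launch = 0.35                      # quiet standing before the push-off
    feet = {
        "left": {"first_to": t_launch + 0.20, "p0x": 0.0, "z_line": 0.06},
        "right": {"first_to": t_launch + 0.05, "p0x": -0.35, "z_line": -0.06},
    }

    sprints, true_events, true_lengths, true_positions, gyrs = {}, {}, {}, {}, {}
    t_end = 0.0
    schedules = {}
    for foot, spec in feet.items():
        to_t, td_t, x_pos = _schedule_foot(
            profile, spec["first_to"], spec["p0x"], t_launch, fs
        )
        z_pos = spec["z_line"] + rng.normal(0.0, z_scatter_m, size=len(x_pos))
        schedules[foot] = (to_t, td_t, x_pos, z_pos)
        t_end = max(t_end, td_t[-1] + 0.6)

    n = int(round(t_end * fs))
    t = np.arange(n) / fs

    for foot, spec in feet.items():
        to_t, td_t, x_pos, z_pos = schedules[foot]
        p0 = (spec["p0x"], spec["z_line"])
        ax, ay, az = _foot_signals(t, to_t, td_t, x_pos, z_pos, p0, hop_height_m)
        if artefact.enabled:
            bx, bz = _impact_bursts(t, td_t, artefact, rng, g)
            ax, az = ax + bx, az + bz
        if noise.acc_sigma > 0:
            ax = ax + rng.normal(0.0, noise.acc_sigma, size=n)
            az = az + rng.normal(0.0, noise.acc_sigma, size=n)
            ay = ay + rng.normal(0.0, noise.acc_sigma, size=n)
        if clip_range:
            lim = 16.0 * g
            ax, ay, az = (np.clip(s, -lim, lim) for s in (ax, ay, az))

        gyr = _gyro_signature(t, to_t, td_t)
        if noise.gyr_sigma > 0:
            gyr = gyr + rng.normal(0.0, noise.gyr_sigma, size=n)

        td_idx = np.round(td_t * fs).astype(int)
        to_idx = np.round(to_t * fs).astype(int)
        ev = GaitEvents(td=td_idx, to=to_idx, foot=foot)
        xy = np.column_stack(
            [np.concatenate([[p0[0]], x_pos]), np.concatenate([[p0[1]], z_pos])]
        )
        true_lengths[foot] = np.hypot(np.diff(xy[:, 0]), np.diff(xy[:, 1]))
        true_positions[foot] = xy
        true_events[foot] = ev
        gyrs[foot] = gyr
        sprints[foot] = GlobalSprint(
            t=t, acc_x=ax, acc_z=az, acc_y=ay, fs=fs, foot=foot, events=ev
        )

    return SyntheticSprint(
        sprints=sprints,
        true_events=true_events,
        true_stride_lengths=true_lengths,
        true_foot_positions=true_positions,
        gyr_x=gyrs,
        profile=profile,
        fs=fs,
        seed=seed,
        params={
            "artefact": asdict(artefact),
            "noise": asdict(noise),
            "clip_range": clip_range,
            "z_scatter_m": z_scatter_m,
            "hop_height_m": hop_height_m,
            "g": g,
        },
    )


def emit_fixtures(sprint: SyntheticSprint, out_dir) -> dict:
    """Write deposit-style global-frame files plus a ground-truth sidecar.

    One CSV per foot (named ``sprint_<foot>.csv``) and one
    ``truth.json`` with events, stride lengths and generator parameters.
    Returns the mapping of written paths.
    """
    from .io import write_global_sprint

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for foot, gs in sprint.sprints.items():
        p = out / f"sprint_{foot}.csv"
        write_global_sprint(gs, p)
        paths[foot] = str(p)
    truth = {
        "seed": sprint.seed,
        "fs": sprint.fs,
        "effort": sprint.profile.effort_label,
        "v_max": sprint.profile.v_max,
        "tau": sprint.profile.tau,
        "params": sprint.params,
        "feet": {
            foot: {
                "td": sprint.true_events[foot].td.tolist(),
                "to": sprint.true_events[foot].to.tolist(),
                "stride_lengths_m": sprint.true_stride_lengths[foot].tolist(),
                "foot_positions_m": sprint.true_foot_positions[foot].tolist(),
            }
            for foot in sprint.sprints
        },
    }
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=1))
    paths["truth"] = str(truth_path)
    return paths


def inject_tap(
    rec: ImuRecording,
    at_s: float,
    peak_g: float = 8.0,
    duration_s: float = 0.02,
    g: float = G_DEFAULT,
) -> ImuRecording:
    """Add a short high-magnitude tap transient to a recording's y-axis
    acceleration (used to emulate the pre-session synchronization tap)."""
    t = rec.t
    rel = t - at_s
    mask = (rel >= 0) & (rel < duration_s)
    acc = rec.acc.copy()
    acc[mask, 1] += peak_g * g * np.exp(-rel[mask] / (duration_s / 4)) * np.sin(
        2 * np.pi * 150.0 * rel[mask]
    )
    return ImuRecording(t=t, acc=acc, gyr=rec.gyr.copy(), fs=rec.fs, foot=rec.foot,
                        mag=None if rec.mag is None else rec.mag.copy())


def prescribed_rotation_imu(
    theta: np.ndarray,
    fs: float,
    g: float = G_DEFAULT,
    foot: str = "unknown",
) -> tuple[ImuRecording, np.ndarray]:
    """Body-frame IMU streams for a prescribed rotation about the sensor
    x-axis under gravity only (no linear acceleration).

    ``theta`` is the pitch-angle profile (rad) about the medial–lateral
    axis, sampled at ``fs``.  Returns the recording and the true
    sensor→global quaternion series — the oracle for orientation tests.
    """
    theta = np.asarray(theta, dtype=float)
    n = len(theta)
    t = np.arange(n) / fs
    omega = np.gradient(theta, 1.0 / fs)
    q = np.column_stack(
        [np.cos(theta / 2), np.sin(theta / 2), np.zeros(n), np.zeros(n)]
    )
    # accelerometer measures specific force: +g along global y, expressed in
    # the sensor frame (rotate by the inverse orientation)
    cy, sy = np.cos(theta), np.sin(theta)
    acc = np.column_stack([np.zeros(n), g * cy, -g * sy])
    gyr = np.column_stack([omega, np.zeros(n), np.zeros(n)])
    return ImuRecording(t=t, acc=acc, gyr=gyr, fs=fs, foot=foot), q
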