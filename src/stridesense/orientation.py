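"""Sensor-orientation estimation and rotation into the global frame.

The orientation of the foot-mounted sensor is tracked with the
gradient-descent (Madgwick) complementary filter: gyroscope strap-down
integration corrected by a gradient step toward agreement with the
accelerometer's gravity observation (and, when magnetometer data is
available, the geomagnetic field).  The single gain β trades gyroscope
trust against the vector observations; the default is 0.043.

The global frame has the y-axis pointing upward, the x-axis along the
horizontal component of the geomagnetic field when a magnetometer is used
— otherwise along the initial horizontal heading — and a transverse z-axis.
Stride length is the norm of horizontal displacement, so it is invariant to
the horizontal heading choice.

The gradient is formulated for an arbitrary global reference direction, so
the y-up frame is handled natively rather than through an axis permutation
of the usual z-up derivation.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .types import GlobalSprint, ImuRecording, OrientationSeries, G_DEFAULT

__all__ = [
    "estimate_orientation",
    "to_global",
    "pitch_about_x",
    "quat_multiply",
    "quat_conjugate",
    "quat_rotate",
]

_UP = np.array([0.0, 1.0, 0.0])  # gravity reference direction, global frame


def quat_multiply(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Hamilton product p ⊗ q for (…, 4) arrays ordered (w, x, y, z)."""
    pw, px, py, pz = np.moveaxis(np.asarray(p, float), -1, 0)
    qw, qx, qy, qz = np.moveaxis(np.asarray(q, float), -1, 0)
    return np.stack(
        [
            pw * qw - px * qx - py * qy - pz * qz,
            pw * qx + px * qw + py * qz - pz * qy,
            pw * qy - px * qz + py * qw + pz * qx,
            pw * qz + px * qy - py * qx + pz * qw,
        ],
        axis=-1,
    )


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, float)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def quat_rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vectors v (sensor frame) into the global frame: q ⊗ v ⊗ q*.

    Broadcasts over leading axes; ``q`` may be (4,) or (n, 4) and ``v``
    (3,) or (n, 3).
    """
    squeeze = np.asarray(q).ndim == 1 and np.asarray(v).ndim == 1
    q = np.atleast_2d(np.asarray(q, float))
    v = np.atleast_2d(np.asarray(v, float))
    vq = np.zeros(np.broadcast_shapes(q.shape[:-1] + (4,), v.shape[:-1] + (4,)))
    vq[..., 1:] = v
    out = quat_multiply(quat_multiply(q, vq), quat_conjugate(q))[..., 1:]
    return out[0] if squeeze else out


def _objective(q: np.ndarray, d: np.ndarray, s: np.ndarray):
    """Error f = R(q)ᵀ·d − s and its Jacobian ∂f/∂q for a unit reference
    direction d (global) versus a unit measurement s (sensor frame)."""
    w, x, y, z = q
    d1, d2, d3 = d
    f = np.array(
        [
            d1 * (1 - 2 * y * y - 2 * z * z) + 2 * d2 * (x * y + w * z) + 2 * d3 * (x * z - w * y),
            2 * d1 * (x * y - w * z) + d2 * (1 - 2 * x * x - 2 * z * z) + 2 * d3 * (y * z + w * x),
            2 * d1 * (x * z + w * y) + 2 * d2 * (y * z - w * x) + d3 * (1 - 2 * x * x - 2 * y * y),
        ]
    ) - s
    J = np.array(
        [
            [2 * (d2 * z - d3 * y), 2 * (d2 * y + d3 * z),
             -4 * d1 * y + 2 * d2 * x - 2 * d3 * w, -4 * d1 * z + 2 * d2 * w + 2 * d3 * x],
            [2 * (d3 * x - d1 * z), 2 * d1 * y - 4 * d2 * x + 2 * d3 * w,
             2 * (d1 * x + d3 * z), -2 * d1 * w - 4 * d2 * z + 2 * d3 * y],
            [2 * (d1 * y - d2 * x), 2 * d1 * z - 2 * d2 * w - 4 * d3 * x,
             2 * d1 * w + 2 * d2 * z - 4 * d3 * y, 2 * (d1 * x + d2 * y)],
        ]
    )
    return f, J


def _align_quaternion(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Shortest-arc unit quaternion rotating unit vector u onto unit vector v."""
    dot = float(np.dot(u, v))
    if dot < -1.0 + 1e-12:
        # antiparallel: rotate 180° about any axis orthogonal to u
        axis = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-9:
            axis = np.cross(u, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return np.array([0.0, *axis])
    q = np.array([1.0 + dot, *np.cross(u, v)])
    return q / np.linalg.norm(q)


def _initial_quaternion(rec: ImuRecording, window_s: float) -> np.ndarray:
    """Align the mean specific force of an initial quiet window with global up."""
    n = max(1, min(len(rec), int(round(window_s * rec.fs))))
    a = rec.acc[:n].mean(axis=0)
    norm = np.linalg.norm(a)
    if norm == 0:
        raise ValueError(
            "cannot initialize orientation: zero mean specific force in the "
            f"first {n} samples"
        )
    return _align_quaternion(a / norm, _UP)


def estimate_orientation(
    rec: ImuRecording,
    beta: float = 0.043,
    q0: Optional[np.ndarray] = None,
    use_magnetometer: str = "auto",
    init_window_s: float = 0.5,
) -> OrientationSeries:
    """Track sensor orientation through a recording.

    Parameters
    ----------
    rec
        Raw recording in SI units (gyroscope in rad·s⁻¹).
    beta
        Filter gain; 0 gives pure gyroscope strap-down integration.
    q0
        Initial sensor→global quaternion.  When omitted it is derived from
        the mean accelerometer direction over the first ``init_window_s``
        seconds of (assumed quiet) standing.
    use_magnetometer
        ``"auto"`` uses the magnetometer when present, ``"always"`` requires
        it, ``"never"`` ignores it (gravity-only correction; yaw then drifts
        at the gyroscope bias rate, which stride length tolerates).
    """
    if rec.fs <= 0:
        raise ValueError("sampling frequency must be positive")
    use_mag = {
        "auto": rec.mag is not None,
        "always": True,
        "never": False,
    }[use_magnetometer]
    if use_mag and rec.mag is None:
        raise ValueError("magnetometer requested but recording has none")

    dt = 1.0 / rec.fs
    n = len(rec)
    q = np.empty((n, 4))
    if q0 is None:
        cur = _initial_quaternion(rec, init_window_s)
    else:
        cur = np.asarray(q0, float)
        cur = cur / np.linalg.norm(cur)

    for i in range(n):
        a = rec.acc[i]
        anorm = np.linalg.norm(a)
        if anorm == 0.0:
            raise ValueError(
                f"accelerometer sample {i} has zero norm; cannot normalize "
                "the gravity observation"
            )
        omega = rec.gyr[i]
        qdot = 0.5 * quat_multiply(cur, np.array([0.0, *omega]))
        if beta > 0.0:
            f, J = _objective(cur, _UP, a / anorm)
            grad = J.T @ f
            if use_mag:
                m = rec.mag[i]
                mnorm = np.linalg.norm(m)
                if mnorm > 0:
                    h = quat_rotate(cur, m / mnorm)  # field in global frame
                    b = np.array([np.hypot(h[0], h[2]), h[1], 0.0])
                    fm, Jm = _objective(cur, b, m / mnorm)
                    grad = grad + Jm.T @ fm
            gnorm = np.linalg.norm(grad)
            if gnorm > 0:
                qdot = qdot - beta * grad / gnorm
        cur = cur + qdot * dt
        cur = cur / np.linalg.norm(cur)
        q[i] = cur

    return OrientationSeries(q=q, beta=beta, fs=rec.fs)


def to_global(
    rec: ImuRecording, ori: OrientationSeries, g: float = G_DEFAULT
) -> GlobalSprint:
    """Rotate body-frame specific force into the global frame and remove gravity.

    The result's horizontal components (acc_x, acc_z) are the integrands of
    the stride-length double integration; the vertical residual acc_y is
    carried for diagnostics only.
    """
    if len(rec) != len(ori):
        raise ValueError(
            f"recording has {len(rec)} samples but orientation has {len(ori)}"
        )
    acc_global = quat_rotate(ori.q, rec.acc)
    acc_global = np.atleast_2d(acc_global) - np.array([0.0, g, 0.0])
    return GlobalSprint(
        t=rec.t,
        acc_x=acc_global[:, 0],
        acc_z=acc_global[:, 2],
        acc_y=acc_global[:, 1],
        fs=rec.fs,
        foot=rec.foot,
    )


def pitch_about_x(q: np.ndarray) -> np.ndarray:
    """Foot (sagittal-plane) angle: signed rotation of the sensor y-axis about
    the medial–lateral x-axis, in radians.  Zero when the sensor y-axis points
    straight up."""
    y_rot = quat_rotate(np.atleast_2d(np.asarray(q, float)), np.array([0.0, 1.0, 0.0]))
    y_rot = np.atleast_2d(y_rot)
    return np.arctan2(y_rot[:, 2], y_rot[:, 1])
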