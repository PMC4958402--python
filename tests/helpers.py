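"""Independent oracles shared across the test suite.

These deliberately avoid the library's own code paths: matrix products are
triple loops, the rigid fit is a derivative-free optimization over six pose
parameters, and rotations are parametrized through scipy's Rotation.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def naive_matmul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Triple-loop matrix product."""
    n, m = a.shape[0], b.shape[1]
    out = np.zeros((n, m))
    for i in range(n):
        for j in range(m):
            s = 0.0
            for k in range(a.shape[1]):
                s += a[i, k] * b[k, j]
            out[i, j] = s
    return out


def naive_apply(matrix: np.ndarray, point: np.ndarray) -> np.ndarray:
    """Homogeneous 4-vector product."""
    h = np.append(np.asarray(point, dtype=float), 1.0)
    out = naive_matmul(matrix, h.reshape(4, 1)).ravel()
    return out[:3]


def params_to_matrix(params: np.ndarray) -> np.ndarray:
    """Six pose parameters (rotation vector + translation) to a 4x4 matrix."""
    m = np.eye(4)
    m[:3, :3] = Rotation.from_rotvec(params[:3]).as_matrix()
    m[:3, 3] = params[3:]
    return m


def rms_after(params: np.ndarray, src: np.ndarray, dst: np.ndarray) -> float:
    m = params_to_matrix(params)
    mapped = src @ m[:3, :3].T + m[:3, 3]
    return float(np.sqrt(np.mean(np.sum((mapped - dst) ** 2, axis=1))))


def brute_force_rigid_fit(
    src: np.ndarray, dst: np.ndarray, n_starts: int = 4, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Derivative-free least-squares rigid fit over 6 pose parameters.

    Multi-start Powell polished by Nelder-Mead at tight tolerances; returns
    (4x4 matrix, RMS residual).  Independent of the SVD solver under test.
    """
    rng = np.random.default_rng(seed)
    # an informed but solver-independent start: translate centroids together
    t0 = dst.mean(axis=0) - src.mean(axis=0)
    starts = [np.concatenate([np.zeros(3), t0])]
    for _ in range(n_starts - 1):
        rotvec = rng.uniform(-np.pi, np.pi, size=3)
        r = Rotation.from_rotvec(rotvec).as_matrix()
        t = dst.mean(axis=0) - r @ src.mean(axis=0)
        starts.append(np.concatenate([rotvec, t]))
    best = None
    for x0 in starts:
        res = minimize(
            rms_after, x0, args=(src, dst), method="Powell",
            options={"xtol": 1e-12, "ftol": 1e-14, "maxiter": 20000},
        )
        res = minimize(
            rms_after, res.x, args=(src, dst), method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-15, "maxiter": 20000},
        )
        if best is None or res.fun < best.fun:
            best = res
    return params_to_matrix(best.x), float(best.fun)


def rotation_angle_deg(r1: np.ndarray, r2: np.ndarray) -> float:
    """Geodesic angle between two rotations, in degrees."""
    cos = (np.trace(r1.T @ r2) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))
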