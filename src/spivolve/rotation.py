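"""Rotation utilities: quaternions and deterministic SO(3) sampling."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# super-Fibonacci spiral constants: sqrt(2) and the real root of x^4 = x + 4
_PHI = np.sqrt(2.0)
_PSI = 1.533751168755204288118041


@dataclass
class RotationSet:
    """A set of unit quaternions with probability weights."""

    quaternions: np.ndarray  # (R, 4), unit norm, scalar-first (w, x, y, z)
    weights: np.ndarray      # (R,), sums to 1

    def __post_init__(self):
        self.quaternions = np.asarray(self.quaternions, dtype=np.float64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        norms = np.linalg.norm(self.quaternions, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("quaternions must have unit norm")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")

    def __len__(self):
        return self.quaternions.shape[0]

    def matrices(self) -> np.ndarray:
        return quat_to_matrix(self.quaternions)


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Unit quaternion(s) (w, x, y, z) to rotation matrix/matrices."""
    q = np.asarray(q, dtype=np.float64)
    single = q.ndim == 1
    q = np.atleast_2d(q)
    w, x, y, z = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    m = np.empty((q.shape[0], 3, 3))
    m[:, 0, 0] = 1 - 2 * (y * y + z * z)
    m[:, 0, 1] = 2 * (x * y - w * z)
    m[:, 0, 2] = 2 * (x * z + w * y)
    m[:, 1, 0] = 2 * (x * y + w * z)
    m[:, 1, 1] = 1 - 2 * (x * x + z * z)
    m[:, 1, 2] = 2 * (y * z - w * x)
    m[:, 2, 0] = 2 * (x * z - w * y)
    m[:, 2, 1] = 2 * (y * z + w * x)
    m[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return m[0] if single else m


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product a * b (scalar-first), broadcasting over leading dims."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    aw, ax, ay, az = np.moveaxis(a, -1, 0)
    bw, bx, by, bz = np.moveaxis(b, -1, 0)
    return np.stack([
        aw * bw - ax * bx - ay * by - az * bz,
        aw * bx + ax * bw + ay * bz - az * by,
        aw * by - ax * bz + ay * bw + az * bx,
        aw * bz + ax * by - ay * bx + az * bw,
    ], axis=-1)


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=np.float64)
    out = q.copy()
    out[..., 1:] *= -1
    return out


def random_quaternions(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniformly random unit quaternions (Haar measure on SO(3))."""
    q = rng.normal(size=(n, 4))
    return q / np.linalg.norm(q, axis=1, keepdims=True)


def make_rotation_samples(n_target: int) -> RotationSet:
    """Deterministic quasi-uniform cover of rotation space.

    Uses the super-Fibonacci spiral: a closed-form low-discrepancy sequence
    of unit quaternions.  ``n_target = 1`` returns the identity rotation.
    Weights are uniform.
    """
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    if n_target == 1:
        return RotationSet(np.array([[1.0, 0.0, 0.0, 0.0]]), np.array([1.0]))
    i = np.arange(n_target, dtype=np.float64)
    s = i + 0.5
    t = s / n_target
    d = 2.0 * np.pi * s
    r = np.sqrt(t)
    big_r = np.sqrt(1.0 - t)
    alpha = d / _PHI
    beta = d / _PSI
    q = np.stack([r * np.sin(alpha), r * np.cos(alpha),
                  big_r * np.sin(beta), big_r * np.cos(beta)], axis=1)
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    return RotationSet(q, np.full(n_target, 1.0 / n_target))


def geodesic_distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation angle (radians) between quaternions a and b (sign-blind)."""
    dot = np.abs(np.sum(np.asarray(a) * np.asarray(b), axis=-1))
    return 2.0 * np.arccos(np.clip(dot, -1.0, 1.0))


def max_nn_geodesic(rotset: RotationSet) -> float:
    """Maximum nearest-neighbour geodesic distance over the set (coverage)."""
    q = rotset.quaternions
    # |dot| accounts for the q ~ -q double cover
    dots = np.abs(q @ q.T)
    np.fill_diagonal(dots, -np.inf)
    nn = dots.max(axis=1)
    return float(2.0 * np.arccos(np.clip(nn, -1.0, 1.0)).max())


def average_quaternion(quats: np.ndarray, weights=None) -> np.ndarray:
    """Chordal-mean quaternion (largest eigenvector of the moment matrix).

    Handles the q ~ -q sign ambiguity; returns a unit quaternion.
    """
    q = np.asarray(quats, dtype=np.float64)
    if weights is None:
        weights = np.ones(q.shape[0])
    m = (q * weights[:, None]).T @ q
    vals, vecs = np.linalg.eigh(m)
    mean = vecs[:, -1]
    return mean / np.linalg.norm(mean)
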