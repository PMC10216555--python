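"""Deterministic unit-direction sets on the sphere.

Directional kurtosis metrics (MK, RK, the K_max search behind AWF) are
defined here as averages/extrema over *fixed* direction sets so that every
map is reproducible bit-for-bit.  The sets are generated on the fly from
closed-form spiral constructions — no data files are shipped.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.stats import qmc

#: number of directions used for spherical averaging (MK) and K_max search
N_SPHERE_DEFAULT = 250
#: number of in-plane directions used for the radial (perpendicular) average
N_CIRCLE_DEFAULT = 64


def fibonacci_sphere(n: int) -> np.ndarray:
    """Return ``n`` approximately uniform unit vectors (Fibonacci spiral).

    Deterministic: the same ``n`` always yields the same array.
    """
    if n < 1:
        raise ValueError("need at least one direction")
    i = np.arange(n, dtype=float)
    # golden-angle longitude, equal-area latitude bands
    phi = i * (np.pi * (3.0 - np.sqrt(5.0)))
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    dirs = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


def sphere_directions(n: int = N_SPHERE_DEFAULT) -> np.ndarray:
    """Fixed direction set for spherical averages (cached for the default)."""
    return _sphere_cache(n)


_CACHE: dict[int, np.ndarray] = {}


def _sphere_cache(n: int) -> np.ndarray:
    if n not in _CACHE:
        _CACHE[n] = fibonacci_sphere(n)
    return _CACHE[n]


def circle_directions(axis: np.ndarray, n: int = N_CIRCLE_DEFAULT) -> np.ndarray:
    """``n`` equispaced unit vectors perpendicular to ``axis``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    # deterministic orthonormal frame: pick the world axis least aligned
    helper = np.zeros(3)
    helper[int(np.argmin(np.abs(axis)))] = 1.0
    u = np.cross(axis, helper)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    theta = 2.0 * np.pi * np.arange(n) / n
    return np.outer(np.cos(theta), u) + np.outer(np.sin(theta), v)


def circle_frames(axes: np.ndarray, n: int = N_CIRCLE_DEFAULT) -> np.ndarray:
    """Vectorised :func:`circle_directions` for a batch of axes.

    Parameters
    ----------
    axes : (..., 3) array of unit vectors.

    Returns
    -------
    (..., n, 3) array of perpendicular directions.
    """
    axes = np.asarray(axes, dtype=float)
    norm = np.linalg.norm(axes, axis=-1, keepdims=True)
    axes = axes / norm
    helper = np.zeros(axes.shape)
    idx = np.argmin(np.abs(axes), axis=-1)
    np.put_along_axis(helper, idx[..., None], 1.0, axis=-1)
    u = np.cross(axes, helper)
    u /= np.linalg.norm(u, axis=-1, keepdims=True)
    v = np.cross(axes, u)
    theta = 2.0 * np.pi * np.arange(n) / n
    cos_t = np.cos(theta)
    sin_t = np.sin(theta)
    return cos_t[:, None] * u[..., None, :] + sin_t[:, None] * v[..., None, :]


def electrostatic_repulsion(points: np.ndarray, n_iter: int = 80,
                            step: float = 0.05) -> np.ndarray:
    """Relax unit vectors by antipodally symmetric Coulomb repulsion.

    Deterministic given the starting configuration.  Antipodal symmetry
    (forces from both p_j and −p_j) matches diffusion-gradient tables,
    where n and −n are equivalent, and breaks the algebraic degeneracies
    of regular spiral sets.
    """
    p = points / np.linalg.norm(points, axis=1, keepdims=True)
    for _ in range(n_iter):
        diff_p = p[:, None, :] - p[None, :, :]
        diff_m = p[:, None, :] + p[None, :, :]
        d2_p = (diff_p ** 2).sum(-1)
        d2_m = (diff_m ** 2).sum(-1)
        np.fill_diagonal(d2_p, np.inf)
        force = (diff_p / np.maximum(d2_p, 1e-12)[..., None] ** 1.5).sum(1) \
            + (diff_m / np.maximum(d2_m, 1e-12)[..., None] ** 1.5).sum(1)
        # project onto the tangent plane and take a bounded step
        force -= (force * p).sum(-1, keepdims=True) * p
        norm = np.linalg.norm(force, axis=1, keepdims=True)
        p = p + step * force / np.maximum(norm.max(), 1e-12)
        p /= np.linalg.norm(p, axis=1, keepdims=True)
    return p


def scheme_directions(n: int, seed: int = 0) -> np.ndarray:
    """Gradient directions for one shell: electrostatic repulsion from a
    seed-rotated Fibonacci start.

    The repulsion stage is essential for well-posedness: regular spiral
    sets can be exactly degenerate for the quartic (kurtosis) design.
    """
    base = electrostatic_repulsion(fibonacci_sphere(n))
    rot = Rotation.random(random_state=np.random.default_rng(seed)).as_matrix()
    return base @ rot.T


def qmc_sphere(n: int, seed: int) -> np.ndarray:
    """Randomised low-discrepancy points on the sphere (scrambled Sobol).

    A Monte-Carlo estimator of spherical averages with O(N^-3/2) error —
    used as the independent oracle for the fixed-set averages.
    """
    eng = qmc.Sobol(d=2, scramble=True, seed=seed)
    u = eng.random(n)
    z = 2.0 * u[:, 0] - 1.0
    phi = 2.0 * np.pi * u[:, 1]
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def qmc_circle(axis: np.ndarray, n: int, seed: int) -> np.ndarray:
    """Randomised low-discrepancy angles on the circle perpendicular to axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    helper = np.zeros(3)
    helper[int(np.argmin(np.abs(axis)))] = 1.0
    u = np.cross(axis, helper)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    eng = qmc.Sobol(d=1, scramble=True, seed=seed)
    theta = 2.0 * np.pi * eng.random(n)[:, 0]
    return np.outer(np.cos(theta), u) + np.outer(np.sin(theta), v)
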