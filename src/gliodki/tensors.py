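"""Compact tensor storage, projections and the DKI design matrix.

Conventions (documented at the I/O boundary as well):

* diffusivities in µm²/ms; b internally in ms/µm² (b[s/mm²] / 1000);
* the diffusion tensor ``d`` is stored as 6 unique components in the order
  ``Dxx, Dyy, Dzz, Dxy, Dxz, Dyz``;
* the kurtosis tensor ``w`` is stored as 15 unique components of the fully
  symmetric order-4 tensor W, ordered lexicographically by sorted index:
  ``W1111, W1112, W1113, W1122, W1123, W1133, W1222, W1223, W1233, W1333,
  W2222, W2223, W2233, W2333, W3333``;
* W follows the standard MD²-normalised DKI convention:
  K(n) = (MD² / D(n)²) · Σ nᵢnⱼnₖnₗ Wᵢⱼₖₗ.

The log-linear model fitted by :mod:`gliodki.model` is

  ln S = ln S0 − b·D(n) + (b²/6)·Σ nᵢnⱼnₖnₗ Vᵢⱼₖₗ,   V = MD²·W,

so the 22 design columns are [ln S0, 6 diffusion terms, 15 quartic terms]
with the multiplicities of each unique component folded in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scheme import AcquisitionScheme, SchemeError

# unique-index tables -------------------------------------------------------

#: (i, j) pairs of the 6 unique diffusion-tensor components
IDX2 = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
#: multiplicity of each unique pair in Σ nᵢnⱼ Dᵢⱼ
MULT2 = np.array([1, 1, 1, 2, 2, 2], dtype=float)

#: sorted (i, j, k, l) quadruples of the 15 unique kurtosis-tensor components
IDX4 = [
    (0, 0, 0, 0), (0, 0, 0, 1), (0, 0, 0, 2), (0, 0, 1, 1), (0, 0, 1, 2),
    (0, 0, 2, 2), (0, 1, 1, 1), (0, 1, 1, 2), (0, 1, 2, 2), (0, 2, 2, 2),
    (1, 1, 1, 1), (1, 1, 1, 2), (1, 1, 2, 2), (1, 2, 2, 2), (2, 2, 2, 2),
]
#: multiplicity 4!/∏(count!) of each quadruple in Σ nᵢnⱼnₖnₗ Wᵢⱼₖₗ
MULT4 = np.array([1, 4, 4, 6, 12, 6, 4, 12, 12, 4, 1, 4, 6, 4, 1], dtype=float)

B_INTERNAL = 1e-3  # s/mm² → ms/µm²


def quad_monomials(n: np.ndarray) -> np.ndarray:
    """nᵢnⱼ monomials (multiplicity-weighted) for directions ``n`` (..., 3)."""
    n = np.asarray(n, dtype=float)
    out = np.empty(n.shape[:-1] + (6,))
    for c, (i, j) in enumerate(IDX2):
        np.multiply(n[..., i], n[..., j], out=out[..., c])
        if MULT2[c] != 1:
            out[..., c] *= MULT2[c]
    return out


def quartic_monomials(n: np.ndarray) -> np.ndarray:
    """nᵢnⱼnₖnₗ monomials (multiplicity-weighted) for directions (..., 3)."""
    n = np.asarray(n, dtype=float)
    sq = n * n
    out = np.empty(n.shape[:-1] + (15,))
    for c, (i, j, k, l) in enumerate(IDX4):
        if i == j and k == l:
            np.multiply(sq[..., i], sq[..., k], out=out[..., c])
        elif i == j:
            np.multiply(sq[..., i], n[..., k] * n[..., l], out=out[..., c])
        elif j == k and k == l:
            np.multiply(n[..., i], sq[..., j] * n[..., l], out=out[..., c])
        else:
            np.multiply(n[..., i] * n[..., j], n[..., k] * n[..., l],
                        out=out[..., c])
        if MULT4[c] != 1:
            out[..., c] *= MULT4[c]
    return out


def d6_to_matrix(d6: np.ndarray) -> np.ndarray:
    """Expand (..., 6) compact diffusion tensors to (..., 3, 3) matrices."""
    d6 = np.asarray(d6, dtype=float)
    m = np.empty(d6.shape[:-1] + (3, 3))
    m[..., 0, 0] = d6[..., 0]
    m[..., 1, 1] = d6[..., 1]
    m[..., 2, 2] = d6[..., 2]
    m[..., 0, 1] = m[..., 1, 0] = d6[..., 3]
    m[..., 0, 2] = m[..., 2, 0] = d6[..., 4]
    m[..., 1, 2] = m[..., 2, 1] = d6[..., 5]
    return m


def matrix_to_d6(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    return np.stack(
        [m[..., 0, 0], m[..., 1, 1], m[..., 2, 2],
         m[..., 0, 1], m[..., 0, 2], m[..., 1, 2]], axis=-1
    )


def sym_outer_w15(delta6: np.ndarray) -> np.ndarray:
    """Unique components of the symmetrised outer product Δ⊗Δ.

    For compact symmetric Δ (..., 6) returns (..., 15) with
    S_ijkl = (Δᵢⱼ Δₖₗ + Δᵢₖ Δⱼₗ + Δᵢₗ Δⱼₖ)/3, whose quartic projection is
    exactly (Σ nᵢnⱼ Δᵢⱼ)².  Used for closed-form two-compartment kurtosis.
    """
    dm = d6_to_matrix(delta6)
    out = np.empty(dm.shape[:-2] + (15,))
    for c, (i, j, k, l) in enumerate(IDX4):
        out[..., c] = (
            dm[..., i, j] * dm[..., k, l]
            + dm[..., i, k] * dm[..., j, l]
            + dm[..., i, l] * dm[..., j, k]
        ) / 3.0
    return out


def project_d(d6: np.ndarray, dirs: np.ndarray) -> np.ndarray:
    """D(n) = Σ nᵢnⱼ Dᵢⱼ for tensors (..., 6) and directions (M, 3) → (..., M)."""
    return np.asarray(d6) @ quad_monomials(dirs).T


def project_w(w15: np.ndarray, dirs: np.ndarray) -> np.ndarray:
    """W(n) = Σ nᵢnⱼnₖnₗ Wᵢⱼₖₗ for tensors (..., 15), directions (M, 3)."""
    return np.asarray(w15) @ quartic_monomials(dirs).T


@dataclass
class TensorPair:
    """Per-voxel diffusion tensor (6) + kurtosis tensor (15) + baseline."""

    d: np.ndarray   # (6,) µm²/ms
    w: np.ndarray   # (15,) dimensionless (MD²-normalised)
    s0: float = 1.0

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float).reshape(6)
        self.w = np.asarray(self.w, dtype=float).reshape(15)

    @property
    def md(self) -> float:
        return float(self.d[:3].mean())

    def apparent(self, dirs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(D(n), K(n)) along unit directions ``dirs`` (M, 3)."""
        dn = project_d(self.d, dirs)
        wn = project_w(self.w, dirs)
        md = self.md
        with np.errstate(divide="ignore", invalid="ignore"):
            kn = md * md * wn / (dn * dn)
        return dn, kn


@dataclass
class TensorField:
    """Voxel grid of tensor pairs (flattened storage + validity mask)."""

    d: np.ndarray        # (..., 6)
    w: np.ndarray        # (..., 15)
    s0: np.ndarray       # (...)
    valid: np.ndarray    # (...) bool

    @property
    def shape(self) -> tuple[int, ...]:
        return self.s0.shape

    @property
    def md(self) -> np.ndarray:
        return self.d[..., :3].mean(axis=-1)

    def voxel(self, index) -> TensorPair:
        return TensorPair(self.d[index], self.w[index], float(self.s0[index]))


def build_design(scheme: AcquisitionScheme) -> np.ndarray:
    """Assemble the (V, 22) DKI design matrix for a scheme.

    Column order: [ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz, then the 15 quartic
    V-columns in IDX4 order].  Raises ``SchemeError`` when the matrix is
    rank-deficient (degenerate direction set).
    """
    b = np.asarray(scheme.bvalues, dtype=float) * B_INTERNAL  # ms/µm²
    n = np.asarray(scheme.bvectors, dtype=float)
    X = np.empty((len(scheme), 22))
    X[:, 0] = 1.0
    X[:, 1:7] = -b[:, None] * quad_monomials(n)
    X[:, 7:] = (b[:, None] ** 2 / 6.0) * quartic_monomials(n)
    if np.linalg.matrix_rank(X) < 22:
        raise SchemeError("degenerate design")
    return X


def predict_log_signal(X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """ln S for design X (V, 22) and coefficients beta (..., 22)."""
    return np.asarray(beta) @ X.T


def beta_to_tensors(beta: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split solved coefficients into (s0, d6, w15); W = V / MD²."""
    beta = np.asarray(beta, dtype=float)
    s0 = np.exp(beta[..., 0])
    d6 = beta[..., 1:7]
    v15 = beta[..., 7:]
    md = d6[..., :3].mean(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        w15 = v15 / (md * md)[..., None]
    return s0, d6, w15


def tensors_to_beta(d6: np.ndarray, w15: np.ndarray, s0) -> np.ndarray:
    """Inverse of :func:`beta_to_tensors` — used by the signal generator."""
    d6 = np.asarray(d6, dtype=float)
    w15 = np.asarray(w15, dtype=float)
    md = d6[..., :3].mean(axis=-1)
    v15 = w15 * (md * md)[..., None]
    ln_s0 = np.log(np.broadcast_to(np.asarray(s0, dtype=float), md.shape))
    return np.concatenate([ln_s0[..., None], d6, v15], axis=-1)
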