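"""Scalar DKI maps (MD, FA, MK, AK, RK, KA) and the MK deletion rule.

All directional quantities derive from the apparent projections

    D(n) = Σ nᵢnⱼ Dᵢⱼ,      K(n) = (MD²/D(n)²) Σ nᵢnⱼnₖnₗ Wᵢⱼₖₗ.

MK is the average of K(n) over a fixed deterministic 250-direction spiral
set; AK is K along the principal diffusion eigenvector; RK averages K over
64 equispaced directions perpendicular to it; KA is an FA-analogue over the
three eigenvector-projected kurtoses.  Voxels whose fitted MK falls outside
(0, 3) — strictly — are deleted from every kurtosis-family map; MD and FA
keep their own validity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .directions import (N_CIRCLE_DEFAULT, N_SPHERE_DEFAULT, circle_frames,
                         sphere_directions)
from .tensors import (TensorField, TensorPair, d6_to_matrix, quad_monomials,
                      quartic_monomials)

logger = logging.getLogger(__name__)

#: the MK deletion thresholds: voxels with MK < low or MK > high are removed
QC_MK_BOUNDS = (0.0, 3.0)


@dataclass
class ScalarMapSet:
    """The six scalar maps on a shared grid plus validity masks.

    ``valid`` gates the kurtosis-family maps (mk/ak/rk/ka and downstream
    WMTI); ``valid_diffusion`` gates md/fa and is not touched by the MK rule.
    """

    md: np.ndarray
    fa: np.ndarray
    mk: np.ndarray
    ak: np.ndarray
    rk: np.ndarray
    ka: np.ndarray
    valid: np.ndarray
    valid_diffusion: np.ndarray
    evals: np.ndarray = None    # (..., 3) descending, for downstream use
    evecs: np.ndarray = None    # (..., 3, 3) rows = eigenvectors
    n_qc_deleted: int = 0

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"MD": self.md, "FA": self.fa, "MK": self.mk,
                "AK": self.ak, "RK": self.rk, "KA": self.ka}

    def mask_for(self, name: str) -> np.ndarray:
        return self.valid_diffusion if name in ("MD", "FA") else self.valid


def apparent_values(t: TensorPair, n) -> tuple[float, float]:
    """(D(n), K(n)) of one tensor pair along a unit direction ``n``."""
    n = np.asarray(n, dtype=float).reshape(1, 3)
    dn, kn = t.apparent(n)
    return float(dn[0]), float(kn[0])


def _sorted_eigh(d6: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Descending eigenvalues + deterministically oriented eigenvectors.

    Rows of the returned ``evecs`` are eigenvectors.  Orientation is fixed
    by making the first component of largest magnitude positive, so
    repeated runs (and near-degenerate voxels) produce identical AK/RK.
    """
    vals, vecs = np.linalg.eigh(d6_to_matrix(d6))   # ascending
    vals = vals[..., ::-1]
    vecs = np.swapaxes(vecs, -1, -2)[..., ::-1, :]  # rows = eigenvectors
    lead = np.argmax(np.abs(vecs), axis=-1)
    sign = np.sign(np.take_along_axis(vecs, lead[..., None], axis=-1))
    sign[sign == 0] = 1.0
    return vals, vecs * sign


def _k_along(field_d, field_w, md, dirs) -> np.ndarray:
    """K(n) for per-voxel directions ``dirs`` (..., M, 3) → (..., M)."""
    dn = np.einsum("...c,...mc->...m", field_d, quad_monomials(dirs))
    wn = np.einsum("...c,...mc->...m", field_w, quartic_monomials(dirs))
    with np.errstate(divide="ignore", invalid="ignore"):
        return (md * md)[..., None] * wn / (dn * dn)


def scalar_maps(field: TensorField, n_sphere: int = N_SPHERE_DEFAULT,
                n_circle: int = N_CIRCLE_DEFAULT,
                ka_variant: str = "eigen") -> ScalarMapSet:
    """Compute the six scalar maps from a fitted tensor field.

    ka_variant : ``"eigen"`` (default; FA-analogue over K(e₁..e₃)) or
        ``"sphere"`` (normalised std of K(n) over the spherical set).
    """
    d, w = field.d, field.w
    md = field.md
    finite = np.isfinite(d).all(axis=-1) & np.isfinite(w).all(axis=-1)
    base_valid = np.asarray(field.valid, dtype=bool) & finite

    evals, evecs = _sorted_eigh(d)
    lam_bar = evals.mean(axis=-1)
    num = ((evals - lam_bar[..., None]) ** 2).sum(axis=-1)
    den = (evals ** 2).sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fa = np.sqrt(1.5 * num / den)
    fa = np.where(den > 0, fa, 0.0)

    sphere = sphere_directions(n_sphere)
    dn_sph = np.einsum("...c,mc->...m", d, quad_monomials(sphere))
    wn_sph = np.einsum("...c,mc->...m", w, quartic_monomials(sphere))
    with np.errstate(divide="ignore", invalid="ignore"):
        k_sph = (md * md)[..., None] * wn_sph / (dn_sph * dn_sph)
    # non-positive apparent diffusivity in any direction → directional
    # metrics undefined for that voxel
    dir_ok = (dn_sph > 0).all(axis=-1)
    mk = k_sph.mean(axis=-1)

    k_eig = _k_along(d, w, md, evecs)           # K along e1, e2, e3
    ak = k_eig[..., 0]
    perp = circle_frames(np.where(base_valid[..., None],
                                  evecs[..., 0, :], [1.0, 0.0, 0.0]),
                         n=n_circle)
    rk = _k_along(d, w, md, perp).mean(axis=-1)

    if ka_variant == "eigen":
        k_bar = k_eig.mean(axis=-1)
        num_k = ((k_eig - k_bar[..., None]) ** 2).sum(axis=-1)
        den_k = (k_eig ** 2).sum(axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ka = np.sqrt(1.5 * num_k / den_k)
        ka = np.where(den_k > 0, ka, 0.0)
    elif ka_variant == "sphere":
        ka = k_sph.std(axis=-1)
    else:
        raise ValueError(f"unknown ka_variant {ka_variant!r}")

    valid_diff = base_valid & np.isfinite(fa) & (md > 0)
    valid_k = valid_diff & dir_ok & np.isfinite(mk) & np.isfinite(ak) \
        & np.isfinite(rk) & np.isfinite(ka)

    def clean(x, ok):
        return np.where(ok, x, 0.0)

    return ScalarMapSet(
        md=clean(md, valid_diff), fa=np.clip(clean(fa, valid_diff), 0.0, 1.0),
        mk=clean(mk, valid_k), ak=clean(ak, valid_k),
        rk=clean(rk, valid_k), ka=clean(ka, valid_k),
        valid=valid_k, valid_diffusion=valid_diff,
        evals=evals, evecs=evecs,
    )


def qc_filter(maps: ScalarMapSet,
              bounds: tuple[float, float] = QC_MK_BOUNDS) -> ScalarMapSet:
    """Delete voxels with MK < low or MK > high (strict) from all
    kurtosis-family maps; MD/FA validity is untouched."""
    low, high = bounds
    if not low < high:
        raise ValueError("QC thresholds must satisfy lower < upper")
    keep = ~((maps.mk < low) | (maps.mk > high)) & maps.valid
    n_del = int(maps.valid.sum() - keep.sum())
    if n_del:
        logger.info("qc_filter: deleted %d voxels with MK outside (%g, %g)",
                    n_del, low, high)
    return replace(maps, valid=keep, n_qc_deleted=maps.n_qc_deleted + n_del)
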