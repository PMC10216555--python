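"""White-matter tract-integrity (WMTI) maps from fitted DKI tensors.

Two-compartment interpretation of the diffusion/kurtosis pair: water sits
either inside axons (restricted, radially impermeable) or outside them.
The axonal water fraction is obtained from the largest apparent kurtosis,

    f = K_max / (K_max + 3),

and, per direction n, the compartment diffusivities follow as

    De(n) = D(n) · [1 + √(K(n)·f / (3(1−f)))]   (extra-axonal, larger)
    Da(n) = D(n) · [1 − √(K(n)·(1−f) / (3f))]   (intra-axonal)

— the conventional branch assigning the larger diffusivity to the
extra-axonal space.  Each compartment tensor is then recovered by linear
least squares of its directional values against the quadratic design, and
axial/radial diffusivities are read off the eigenvalues (axial = largest,
radial = mean of the two smaller).  TORT = AxEAD / RadEAD.

K_max is located by discrete search over the fixed spherical direction set
augmented with the three diffusion-tensor eigenvectors (deterministic; the
eigenvectors capture the axially symmetric optimum exactly).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .directions import N_SPHERE_DEFAULT, sphere_directions
from .metrics import _k_along, _sorted_eigh
from .tensors import TensorField, quad_monomials, quartic_monomials

logger = logging.getLogger(__name__)

#: below this axonal fraction the restricted compartment is undetectable
F_MIN = 1e-3


@dataclass
class WMTIMapSet:
    """AWF, compartment diffusivities (µm²/ms) and tortuosity maps."""

    awf: np.ndarray
    ax_ead: np.ndarray
    rad_ead: np.ndarray
    ax_iad: np.ndarray
    rad_iad: np.ndarray
    tort: np.ndarray
    valid: np.ndarray        # awf + extra-axonal maps
    valid_intra: np.ndarray  # intra-axonal maps + tort (needs f ≥ F_MIN)

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"AWF": self.awf, "AxEAD": self.ax_ead, "RadEAD": self.rad_ead,
                "AxIAD": self.ax_iad, "RadIAD": self.rad_iad, "TORT": self.tort}

    def mask_for(self, name: str) -> np.ndarray:
        return self.valid if name in ("AWF", "AxEAD", "RadEAD") else self.valid_intra


def wmti_maps(field: TensorField, kurtosis_valid=None,
              n_sphere: int = N_SPHERE_DEFAULT) -> WMTIMapSet:
    """Derive the six WMTI maps from a tensor field.

    kurtosis_valid : optional mask (e.g. after the MK deletion rule);
        defaults to the field's own validity.
    """
    if n_sphere < 30:
        raise ValueError("direction set must have >= 30 directions")
    valid_in = np.asarray(field.valid if kurtosis_valid is None
                          else kurtosis_valid, dtype=bool)
    d, w = field.d, field.w
    md = field.md

    sphere = sphere_directions(n_sphere)
    q_sph = quad_monomials(sphere)                    # (M, 6)
    dn = np.einsum("...c,mc->...m", d, q_sph)
    wn = np.einsum("...c,mc->...m", w, quartic_monomials(sphere))
    with np.errstate(divide="ignore", invalid="ignore"):
        k_sph = (md * md)[..., None] * wn / (dn * dn)
    k_sph = np.where(dn > 0, k_sph, np.nan)

    evals, evecs = _sorted_eigh(d)
    k_eig = _k_along(d, w, md, evecs)
    k_all = np.concatenate([k_sph, k_eig], axis=-1)
    k_all = np.clip(k_all, 0.0, None)                 # clamp before sqrt
    with np.errstate(invalid="ignore"):
        k_max = np.nanmax(np.where(np.isfinite(k_all), k_all, 0.0), axis=-1)

    f = k_max / (k_max + 3.0)
    has_axons = f >= F_MIN

    one_m_f = 1.0 - f
    with np.errstate(divide="ignore", invalid="ignore"):
        root_e = np.sqrt(k_sph * (f / (3.0 * one_m_f))[..., None])
        root_a = np.sqrt(k_sph * (one_m_f / (3.0 * np.maximum(f, F_MIN)))[..., None])
    de_dir = dn * (1.0 + np.nan_to_num(root_e))
    da_dir = dn * (1.0 - np.nan_to_num(root_a))

    # 6-unknown LLS against the quadratic design, shared across voxels
    pinv_q = np.linalg.pinv(q_sph)                    # (6, M)
    de6 = np.einsum("cm,...m->...c", pinv_q, np.nan_to_num(de_dir))
    da6 = np.einsum("cm,...m->...c", pinv_q, np.nan_to_num(da_dir))
    # Gaussian voxels: the extra-axonal space IS the full tensor
    de6 = np.where(has_axons[..., None], de6, d)
    da6 = np.where(has_axons[..., None], da6, 0.0)

    ev_e, _ = _sorted_eigh(de6)
    ev_a, _ = _sorted_eigh(da6)
    ax_ead = np.clip(ev_e[..., 0], 0.0, None)
    rad_ead = np.clip(ev_e[..., 1:].mean(axis=-1), 0.0, None)
    ax_iad = np.clip(ev_a[..., 0], 0.0, None)
    rad_iad = np.clip(ev_a[..., 1:].mean(axis=-1), 0.0, None)

    with np.errstate(divide="ignore", invalid="ignore"):
        tort = ax_ead / rad_ead

    finite = np.isfinite(k_max) & np.isfinite(ax_ead) & np.isfinite(rad_ead)
    valid = valid_in & finite
    valid_intra = valid & has_axons & np.isfinite(tort) & (rad_ead > 0)

    n_gauss = int((valid & ~has_axons).sum())
    if n_gauss:
        logger.info("wmti_maps: %d voxels with f < %g "
                    "(intra-axonal maps invalidated)", n_gauss, F_MIN)

    def clean(x, ok):
        return np.where(ok, x, 0.0)

    return WMTIMapSet(
        awf=clean(f, valid),
        ax_ead=clean(ax_ead, valid), rad_ead=clean(rad_ead, valid),
        ax_iad=clean(ax_iad, valid_intra), rad_iad=clean(rad_iad, valid_intra),
        tort=clean(np.nan_to_num(tort), valid_intra),
        valid=valid, valid_intra=valid_intra,
    )
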