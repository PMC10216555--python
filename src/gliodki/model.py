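"""Voxel-wise least-squares diffusion-kurtosis model.

The central object is :class:`DiffusionKurtosisModel`, built from a 4-D
multi-shell DWI array and an :class:`~gliodki.scheme.AcquisitionScheme`;
``fit()`` returns a :class:`DiffusionKurtosisResults` carrying the tensor
field, per-voxel validity, derived scalar/WMTI maps and a ``summary()``.

Fitting is linear least squares on log-signals (22 unknowns).  The default
is a two-pass signal-weighted fit: an unweighted pass predicts the signals,
whose squares become the weights of the second pass — the standard variance
stabilisation for log-linearised diffusion models.  Both modes are exact on
noise-free cumulant-model signals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .scheme import AcquisitionScheme
from .tensors import TensorField, TensorPair, beta_to_tensors, build_design

logger = logging.getLogger(__name__)

#: default clamp for the log transform, relative to the volume maximum
MIN_SIGNAL_REL = 1e-6


@dataclass
class FitOptions:
    """Options of the linear solve.

    weighting : ``"wls"`` (two-pass signal-weighted, default) or ``"ols"``.
    min_signal : absolute clamp for the log transform; default
        ``1e-6 × max(signal)`` resolved at fit time.
    """

    weighting: str = "wls"
    min_signal: float | None = None

    def __post_init__(self):
        if self.weighting not in ("wls", "ols"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        if self.min_signal is not None and self.min_signal <= 0:
            raise ValueError("min_signal must be > 0")


class DiffusionKurtosisModel:
    """DKI model for a 4-D DWI volume (or a (voxels, V) signal matrix).

    Parameters
    ----------
    data : ndarray, shape (..., V)
        Signal intensities; the last axis indexes acquisition volumes.
    scheme : AcquisitionScheme
        Must match the last axis of ``data``.
    mask : ndarray or None
        Boolean array over the spatial axes; voxels outside are not fitted.
    """

    def __init__(self, data, scheme: AcquisitionScheme, mask=None,
                 options: FitOptions | None = None):
        data = np.asarray(data, dtype=float)
        if data.shape[-1] != len(scheme):
            raise ValueError("scheme/volume mismatch")
        self.data = data
        self.scheme = scheme
        self.options = options or FitOptions()
        spatial = data.shape[:-1]
        if mask is None:
            mask = np.ones(spatial, dtype=bool)
        else:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != spatial:
                raise ValueError("mask/volume mismatch")
        self.mask = mask
        self.design = build_design(scheme)

    def fit(self, weighting: str | None = None) -> "DiffusionKurtosisResults":
        opts = self.options if weighting is None else FitOptions(
            weighting=weighting, min_signal=self.options.min_signal)
        spatial = self.data.shape[:-1]
        flat = self.data.reshape(-1, self.data.shape[-1])
        sel = self.mask.reshape(-1)
        sig = flat[sel]

        min_signal = opts.min_signal
        if min_signal is None:
            vmax = float(self.data.max()) if self.data.size else 1.0
            min_signal = MIN_SIGNAL_REL * max(vmax, np.finfo(float).tiny)

        # a voxel with no signal above the clamp is unfit-table, not an error
        fit_ok = (sig > min_signal).any(axis=-1)
        clamped = np.maximum(sig, min_signal)
        y = np.log(clamped)

        X = self.design
        beta = np.zeros((sig.shape[0], X.shape[1]))
        if fit_ok.any():
            pinv = np.linalg.pinv(X)
            beta[fit_ok] = y[fit_ok] @ pinv.T
            if opts.weighting == "wls":
                pred = np.exp(beta[fit_ok] @ X.T)
                wts = pred * pred  # squared predicted signals
                xt_w = X.T[None, :, :] * wts[:, None, :]     # (n, 22, V)
                A = xt_w @ X
                rhs = xt_w @ y[fit_ok][:, :, None]
                beta[fit_ok] = np.linalg.solve(A, rhs)[..., 0]

        s0, d6, w15 = beta_to_tensors(beta)
        md = d6[..., :3].mean(axis=-1)
        valid = fit_ok & np.isfinite(md) & (md > 0) & np.isfinite(w15).all(axis=-1)

        n_invalid = int(np.sum(sel) - np.sum(valid))
        if n_invalid:
            logger.info("fit_volume: %d invalid voxels (of %d in mask)",
                        n_invalid, int(np.sum(sel)))

        def unflatten(arr, fill=0.0):
            shape = spatial + arr.shape[1:]
            out = np.full(shape, fill, dtype=arr.dtype).reshape(
                (-1,) + arr.shape[1:])
            out[sel] = arr
            return out.reshape(shape)

        full_valid = np.zeros(np.prod(spatial, dtype=int), dtype=bool)
        full_valid[sel] = valid
        tensors = TensorField(
            d=unflatten(d6), w=unflatten(w15), s0=unflatten(s0),
            valid=full_valid.reshape(spatial),
        )
        return DiffusionKurtosisResults(self, tensors, opts, min_signal)


@dataclass
class DiffusionKurtosisResults:
    """Fitted tensors plus lazily computed derived maps."""

    model: DiffusionKurtosisModel
    tensors: TensorField
    options: FitOptions
    min_signal: float
    _scalar: object = field(default=None, repr=False)
    _wmti: object = field(default=None, repr=False)

    @property
    def n_fitted(self) -> int:
        return int(self.tensors.valid.sum())

    def scalar_maps(self, qc: bool = True, **kw):
        """MD/FA/MK/AK/RK/KA maps; ``qc`` applies the MK∈[0,3] deletion rule."""
        from .metrics import qc_filter, scalar_maps
        if self._scalar is None:
            maps = scalar_maps(self.tensors, **kw)
            self._scalar = qc_filter(maps) if qc else maps
        return self._scalar

    def wmti_maps(self, **kw):
        """Two-compartment WMTI maps (AWF, compartment diffusivities, TORT)."""
        from .wmti import wmti_maps
        if self._wmti is None:
            scal = self.scalar_maps()
            self._wmti = wmti_maps(self.tensors, kurtosis_valid=scal.valid, **kw)
        return self._wmti

    def predicted(self) -> np.ndarray:
        """Model-predicted signals on the acquisition scheme (masked voxels)."""
        from .tensors import predict_log_signal, tensors_to_beta
        beta = tensors_to_beta(self.tensors.d, self.tensors.w,
                               np.maximum(self.tensors.s0, np.finfo(float).tiny))
        return np.exp(predict_log_signal(self.model.design, beta))

    def summary(self) -> str:
        maps = self.scalar_maps()
        lines = [
            "Diffusion kurtosis model fit",
            "============================",
            f"volumes:          {len(self.model.scheme)}",
            f"shells (s/mm2):   {', '.join(f'{s:g}' for s in self.model.scheme.shells)}",
            f"weighting:        {self.options.weighting}",
            f"voxels in mask:   {int(self.model.mask.sum())}",
            f"voxels fitted:    {self.n_fitted}",
            f"QC-deleted (MK):  {int(self.tensors.valid.sum() - maps.valid.sum())}",
        ]
        v = maps.valid
        if v.any():
            lines += [
                f"median MD:        {np.median(maps.md[v]):.4f} um2/ms",
                f"median FA:        {np.median(maps.fa[v]):.4f}",
                f"median MK:        {np.median(maps.mk[v]):.4f}",
            ]
        return "\n".join(lines)


def fit_voxel(signals, scheme: AcquisitionScheme,
              options: FitOptions | None = None) -> TensorPair:
    """Fit one voxel; thin wrapper over :class:`DiffusionKurtosisModel`."""
    signals = np.asarray(signals, dtype=float)[None, :]
    res = DiffusionKurtosisModel(signals, scheme, options=options).fit()
    if not res.tensors.valid[0]:
        raise ValueError("voxel could not be fitted (all signals at clamp?)")
    return res.tensors.voxel(0)


def fit_volume(dwi, scheme: AcquisitionScheme, mask=None,
               options: FitOptions | None = None) -> DiffusionKurtosisResults:
    """Fit a 4-D volume; thin wrapper over :class:`DiffusionKurtosisModel`."""
    return DiffusionKurtosisModel(dwi, scheme, mask=mask, options=options).fit()
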