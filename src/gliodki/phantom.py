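"""Synthetic multi-shell DWI phantom with four tumour-related tissue zones.

The phantom emulates the statistical structure the invasion-border analysis
assumes: four zones (1 enhancing core, 2 infiltrative edema, 3 ipsilateral
normal-appearing white matter, 4 contralateral white matter) on a voxel
grid, each generated from a two-compartment (intra-/extra-axonal) tissue
model with closed-form diffusion and kurtosis tensors, plus a co-registered
CBF perfusion map and square ROI patches of configurable area inside each
zone.  Magnitude (Rician) noise is applied at a configurable SNR.

Zone presets are calibration choices: they reproduce the qualitative
orderings the analysis relies on (FA/MK/AWF rising from core to
contralateral WM, MD falling, CBF far higher in the core than anywhere
else, zone CBF means straddling ~50 mL/100g/min) — not any patient values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .scheme import AcquisitionScheme, make_scheme
from .tensors import (TensorPair, matrix_to_d6, project_d, sym_outer_w15)

#: default in-plane/through-plane voxel size of the DKI grid, mm
VOXEL_MM_DEFAULT = 2.5
#: default ROI patch area, mm²
ROI_AREA_MM2_DEFAULT = 44.0

ZONE_NAMES = {1: "enhancing core", 2: "infiltrative edema",
              3: "ipsilateral NAWM", 4: "contralateral WM"}


@dataclass(frozen=True)
class TissueParams:
    """Two-compartment tissue parameters of one zone.

    f : axonal water fraction, [0, 1).
    da_ax, da_rad : intra-axonal axial/radial diffusivity (µm²/ms);
        the canonical model has da_rad = 0 (impermeable cylinders).
    de_ax, de_rad : extra-axonal axial/radial diffusivity (µm²/ms).
    orientation : principal fiber axis (unit 3-vector).
    """

    f: float
    da_ax: float
    de_ax: float
    de_rad: float
    da_rad: float = 0.0
    orientation: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self):
        if not 0.0 <= self.f < 1.0:
            raise ValueError("invalid fraction")
        for name in ("da_ax", "da_rad", "de_ax", "de_rad"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        n = np.asarray(self.orientation, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-6:
            raise ValueError("orientation must be unit-norm")

    def compartment_tensors(self) -> tuple[np.ndarray, np.ndarray]:
        """(Da6, De6) axially symmetric compact tensors."""
        e = np.asarray(self.orientation, dtype=float)
        outer = np.outer(e, e)
        eye = np.eye(3)
        da = self.da_rad * eye + (self.da_ax - self.da_rad) * outer
        de = self.de_rad * eye + (self.de_ax - self.de_rad) * outer
        return matrix_to_d6(da), matrix_to_d6(de)


def wmti_forward(params: TissueParams, s0: float = 1.0) -> TensorPair:
    """Exact diffusion + kurtosis tensors of the two-compartment mixture.

    D = f·Da + (1−f)·De and, from the mixture-of-Gaussians cumulants,
    W = 3 f (1−f) (Da − De)⊗(Da − De) (symmetrised) / MD², so that for any
    unit n:  K(n) = 3 f (1−f) (Da(n) − De(n))² / D(n)².
    """
    f = params.f
    da6, de6 = params.compartment_tensors()
    d6 = f * da6 + (1.0 - f) * de6
    md = d6[:3].mean()
    delta6 = da6 - de6
    if md <= 0:
        raise ValueError("degenerate tissue: non-positive mean diffusivity")
    w15 = 3.0 * f * (1.0 - f) * sym_outer_w15(delta6) / (md * md)
    return TensorPair(d=d6, w=w15, s0=s0)


def forward_signal(tensors: TensorPair, scheme: AcquisitionScheme,
                   s0: float | None = None) -> np.ndarray:
    """Noise-free signals of the truncated-cumulant (DKI) model.

    S(b, n) = s0 · exp(−b·D(n) + (b²/6)·MD²·W(n)); exactly the model the
    fitter inverts, so noise-free round trips are exact.
    """
    b = np.asarray(scheme.bvalues, dtype=float) * 1e-3  # ms/µm²
    if np.any(b < 0):
        raise ValueError("invalid b-factor")
    n = np.asarray(scheme.bvectors, dtype=float)
    dn, kn = tensors.apparent(n)
    md = tensors.md
    base = tensors.s0 if s0 is None else float(s0)
    # b=0 rows have arbitrary directions; their exponent is identically 0
    expo = -b * np.where(b > 0, dn, 0.0) \
        + (b * b / 6.0) * np.where(b > 0, dn * dn * np.nan_to_num(kn), 0.0)
    return base * np.exp(expo)


def biexp_signal(params: TissueParams, scheme: AcquisitionScheme,
                 s0: float = 1.0) -> np.ndarray:
    """Bi-exponential (full two-compartment) signals.

    More realistic than the cumulant truncation but *not* the model the
    fitter inverts: DKI fits of these signals are biased at b = 2500 s/mm².
    """
    b = np.asarray(scheme.bvalues, dtype=float) * 1e-3
    n = np.asarray(scheme.bvectors, dtype=float)
    da6, de6 = params.compartment_tensors()
    da_n = project_d(da6, n)
    de_n = project_d(de6, n)
    return s0 * (params.f * np.exp(-b * da_n)
                 + (1.0 - params.f) * np.exp(-b * de_n))


def rician(signal: np.ndarray, sigma: float, rng: np.random.Generator,
           mode: str = "rician") -> np.ndarray:
    """Apply magnitude-MRI noise (two independent Gaussian channels)."""
    if sigma == 0 or not np.isfinite(sigma):
        return np.asarray(signal, dtype=float).copy()
    g1 = rng.standard_normal(signal.shape)
    g2 = rng.standard_normal(signal.shape)
    if mode == "rician":
        return np.sqrt((signal + sigma * g1) ** 2 + (sigma * g2) ** 2)
    if mode == "gaussian":
        return signal + sigma * g1
    raise ValueError(f"unknown noise mode {mode!r}")


# calibrated zone presets -----------------------------------------------------

def default_zone_params() -> dict[int, TissueParams]:
    """Per-zone tissue presets (see module docstring for the calibration)."""
    return {
        1: TissueParams(f=0.16, da_ax=0.6, de_ax=2.2, de_rad=1.8),
        2: TissueParams(f=0.20, da_ax=0.7, de_ax=2.1, de_rad=1.5),
        3: TissueParams(f=0.33, da_ax=0.9, de_ax=2.2, de_rad=0.9),
        4: TissueParams(f=0.48, da_ax=1.0, de_ax=2.3, de_rad=0.8),
    }


def default_zone_cbf() -> dict[int, tuple[float, float]]:
    """(mean, voxel SD) of CBF per zone, mL/100 g/min.

    The core mean (60) and edema mean (25) straddle ~50 mL/100g/min; the
    remaining zones sit at normal-WM perfusion.
    """
    return {1: (60.0, 8.0), 2: (25.0, 4.0), 3: (20.0, 3.0), 4: (18.0, 3.0)}


@dataclass(frozen=True)
class PhantomSpec:
    """Full specification of one synthetic case."""

    shape: tuple[int, int, int] = (40, 40, 10)
    voxel_mm: float = VOXEL_MM_DEFAULT
    zone_params: dict[int, TissueParams] = field(default_factory=default_zone_params)
    zone_cbf: dict[int, tuple[float, float]] = field(default_factory=default_zone_cbf)
    s0: float = 1000.0
    snr: float = 30.0
    noise: str = "rician"
    roi_area_mm2: float = ROI_AREA_MM2_DEFAULT
    n_dirs: int = 60
    shells: tuple[float, ...] = (0.0, 1000.0, 2500.0)
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(self.shape))
        object.__setattr__(self, "shells", tuple(self.shells))
        if self.snr <= 0:
            raise ValueError("snr must be > 0")
        bad = set(self.zone_params) - {1, 2, 3, 4}
        if bad:
            raise ValueError(f"unknown zone labels {sorted(bad)}")

    def scheme(self) -> AcquisitionScheme:
        return make_scheme(self.n_dirs, self.shells)


def zone_layout(shape: tuple[int, int, int]) -> np.ndarray:
    """Integer label map: nested boxes 1⊂2⊂3 in one hemisphere, 4 in the other.

    Zone 4 is spatially disjoint from zones 1–3 by construction.
    """
    nx, ny, nz = shape
    # nested rings of >=3-voxel thickness around a >=3-voxel core need
    # this much room for interior 3x3 ROI patches in every zone
    if nx < 36 or ny < 30 or nz < 3:
        raise ValueError("grid too small for the default zone layout")
    lab = np.zeros(shape, dtype=np.int16)
    z0, z1 = 1, nz - 1
    half = nx // 2
    # ipsilateral nested boxes (fractions of the left half)
    b3 = (1, half - 1, 2, ny - 2)
    b2 = (b3[0] + 3, b3[1] - 3, b3[2] + 4, b3[3] - 4)
    b1 = (b2[0] + 3, b2[1] - 3, b2[2] + 4, b2[3] - 4)
    lab[b3[0]:b3[1], b3[2]:b3[3], z0:z1] = 3
    lab[b2[0]:b2[1], b2[2]:b2[3], z0:z1] = 2
    lab[b1[0]:b1[1], b1[2]:b1[3], z0:z1] = 1
    # contralateral block
    cx0 = half + 2
    lab[cx0:nx - 1, ny // 4:ny - ny // 4, z0:z1] = 4
    return lab


def roi_patches(labels: np.ndarray, voxel_mm: float,
                area_mm2: float = ROI_AREA_MM2_DEFAULT) -> np.ndarray:
    """Square in-plane ROI patches of ≈``area_mm2``, interior to each zone.

    The patch side is the nearest voxel count to √area/voxel; patches are
    centred on each zone's in-plane centroid at the mid-slice.
    """
    from numpy.lib.stride_tricks import sliding_window_view

    side = max(1, round(np.sqrt(area_mm2) / voxel_mm))
    rois = np.zeros_like(labels)
    kz = labels.shape[2] // 2
    plane = labels[:, :, kz]
    if min(plane.shape) < side:
        raise ValueError("grid too small for the configured ROI area")
    windows = sliding_window_view(plane, (side, side))
    for lab in (1, 2, 3, 4):
        where = np.argwhere(plane == lab)
        if where.size == 0:
            continue
        fits = np.argwhere((windows == lab).all(axis=(2, 3)))
        if fits.size == 0:
            raise ValueError(
                f"zone {lab} cannot hold an interior {side}x{side} ROI")
        # deterministic: the fitting window whose centre is nearest the
        # zone centroid (ties resolved by scan order)
        centers = fits + (side - 1) / 2.0
        dist = ((centers - where.mean(axis=0)) ** 2).sum(axis=1)
        ci, cj = fits[np.argmin(dist)]
        rois[ci:ci + side, cj:cj + side, kz] = lab
    return rois


def zone_truth(params: TissueParams) -> dict[str, float]:
    """Ground-truth derived parameters of one zone (exact forward tensors
    pushed through the package's own metric definitions)."""
    from .metrics import scalar_maps
    from .tensors import TensorField
    from .wmti import wmti_maps

    t = wmti_forward(params)
    fld = TensorField(d=t.d[None, :], w=t.w[None, :],
                      s0=np.array([t.s0]), valid=np.array([True]))
    sm = scalar_maps(fld)
    wm = wmti_maps(fld)
    out = {k: float(v[0]) for k, v in sm.as_dict().items()}
    out.update({k: float(v[0]) for k, v in wm.as_dict().items()})
    return out


@dataclass
class PhantomCase:
    """Everything :func:`build_phantom` produces for one case."""

    dwi: np.ndarray            # (nx, ny, nz, V)
    cbf: np.ndarray            # (nx, ny, nz)
    labels: np.ndarray         # zone labels 0–4
    rois: np.ndarray           # ROI patch labels 0–4
    truth: dict[str, np.ndarray]   # per-parameter ground-truth maps
    scheme: AcquisitionScheme
    spec: PhantomSpec


def build_phantom(spec: PhantomSpec) -> PhantomCase:
    """Generate one synthetic case: DWI + CBF + labels + ROIs + ground truth.

    Identical spec (including seed) ⇒ bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    scheme = spec.scheme()
    labels = zone_layout(spec.shape)
    present = set(np.unique(labels)) - {0}
    missing = present - set(spec.zone_params)
    if missing:
        raise ValueError(f"unparameterized zone {sorted(missing)}")

    nvol = len(scheme)
    dwi = np.zeros(spec.shape + (nvol,))
    cbf = np.zeros(spec.shape)
    truth_maps: dict[str, np.ndarray] = {}

    for lab in sorted(present):
        mask = labels == lab
        tensors = wmti_forward(spec.zone_params[lab], s0=spec.s0)
        sig = forward_signal(tensors, scheme)
        dwi[mask] = sig
        mean, sd = spec.zone_cbf.get(lab, (0.0, 0.0))
        cbf[mask] = np.clip(mean + sd * rng.standard_normal(int(mask.sum())),
                            0.0, None)
        for name, val in zone_truth(spec.zone_params[lab]).items():
            truth_maps.setdefault(name, np.zeros(spec.shape))[mask] = val
        truth_maps.setdefault("CBF", np.zeros(spec.shape))[mask] = mean

    sigma = spec.s0 / spec.snr if np.isfinite(spec.snr) else 0.0
    noisy = rician(dwi, sigma, rng, mode=spec.noise)

    rois = roi_patches(labels, spec.voxel_mm, spec.roi_area_mm2)
    return PhantomCase(dwi=noisy, cbf=cbf, labels=labels, rois=rois,
                       truth=truth_maps, scheme=scheme, spec=spec)


def jittered_spec(spec: PhantomSpec, rng: np.random.Generator,
                  f_rel: float = 0.10, diff_rel: float = 0.25,
                  cbf_rel: float = 0.18) -> PhantomSpec:
    """Between-case biological variability: multiplicative log-normal jitter
    of each zone's tissue parameters and CBF mean.

    The axonal fraction varies less (10%) than the diffusivities (25%),
    reflecting that kurtosis-family parameters discriminate zones more
    reliably than pure diffusivities — the structure the ROC ranking of the
    calibrated phantom is meant to exhibit.
    """
    def lognorm(rel):
        return float(np.exp(rng.normal(0.0, rel)))

    new_params = {}
    for lab, p in spec.zone_params.items():
        new_params[lab] = replace(
            p,
            f=min(0.95, p.f * lognorm(f_rel)),
            da_ax=p.da_ax * lognorm(diff_rel),
            de_ax=p.de_ax * lognorm(diff_rel),
            de_rad=p.de_rad * lognorm(diff_rel),
        )
    new_cbf = {lab: (m * lognorm(cbf_rel), sd)
               for lab, (m, sd) in spec.zone_cbf.items()}
    return replace(spec, zone_params=new_params, zone_cbf=new_cbf)


def simulate_image_cohort(spec: PhantomSpec, n_cases: int,
                          seed: int) -> list[PhantomCase]:
    """Generate ``n_cases`` jittered phantom cases (seeded, deterministic)."""
    master = np.random.default_rng(seed)
    cases = []
    for _ in range(n_cases):
        case_seed = int(master.integers(2**31 - 1))
        case_spec = replace(jittered_spec(spec, master), seed=case_seed)
        cases.append(build_phantom(case_spec))
    return cases
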