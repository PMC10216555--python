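# Methods

`gliodki` implements a quantitative-MRI analysis of the glioma invasion
border: it estimates diffusion-kurtosis (DKI) and white-matter
tract-integrity (WMTI) parameter maps from multi-shell diffusion MRI,
extracts per-ROI means jointly with a cerebral-blood-flow (CBF) perfusion
map across four tissue zones (enhancing tumour core, perifocal infiltrative
edema, ipsilateral normal-appearing white matter, contralateral white
matter), and runs a group-comparison / ROC / correlation battery that ranks
the resulting biomarkers.  A synthetic phantom generator stands in for
patient data throughout.

## Signal model and tensor fit

The fitted model is the truncated cumulant expansion of the diffusion
signal,

    ln S(b, n) = ln S0 − b·D(n) + (b²/6)·D(n)²·K(n),

with apparent diffusivity `D(n) = Σ nᵢnⱼ Dᵢⱼ` and apparent kurtosis
`K(n) = (MD²/D(n)²)·Σ nᵢnⱼnₖnₗ Wᵢⱼₖₗ` in the standard MD²-normalised
convention.  Substituting `V = MD²·W` makes the model linear in 22
unknowns (ln S0, 6 diffusion components, 15 kurtosis components), which are
solved per voxel by linear least squares on log-signals.  The default is a
two-pass signal-weighted solve: an unweighted pass predicts the signals and
their squares become the weights of the second pass — the usual variance
stabilisation for log-linearised diffusion models.  Both modes recover
noise-free cumulant-model signals exactly (tested to ~1e-9), so estimator
correctness is separated from model mismatch.

Units: diffusivities in µm²/ms; b-values are read/written in s/mm²
(FSL dialect) and converted to ms/µm² internally.

No positivity or kurtosis-range constraints are imposed in the solve.
Implausible voxels are handled downstream by the MK deletion rule: voxels
with fitted MK strictly below 0 or strictly above 3 are removed from all
kurtosis-family maps (MK, AK, RK, KA and the WMTI maps); MD and FA keep
their own validity, since the rule targets kurtosis maps specifically.
Signals at or below the clamp (default 1e-6 × volume maximum) are clamped
before the log; a voxel with no signal above the clamp is marked invalid
rather than raising.

## Scalar metrics

* MD, FA from the diffusion-tensor eigenvalues
  (FA = √(3/2)·√(Σ(λᵢ−λ̄)²/Σλᵢ²)); eigenvalues sorted descending, with a
  deterministic eigenvector sign convention so near-degenerate voxels
  reproduce exactly.
* MK: mean of K(n) over a fixed 250-direction Fibonacci-spiral set.
* AK: K along the principal eigenvector; RK: mean of K over 64 equispaced
  directions perpendicular to it (trapezoidal rule on the circle —
  spectrally accurate).
* KA: an FA-analogue over the eigenvector-projected kurtoses
  K(e₁), K(e₂), K(e₃).  The KA definition in the literature is ambiguous;
  this choice is deterministic and reduces to 0 for isotropic kurtosis.
  A spherical-standard-deviation variant is available via
  `ka_variant="sphere"`.

Numerical accuracy of the fixed-set averages is test-enforced against
randomised quasi-Monte-Carlo spherical averages (2^14 Owen-scrambled Sobol
points mapped to the sphere; power-of-two counts preserve the Sobol balance
and give ~1e-5 integration error, so the check isolates the fixed set's own
~1e-4 error).  One consequence worth knowing: MK computed from a fixed
discrete set is rotation-invariant only up to the set's discretisation
anisotropy (~1e-4 in practice, test bound 1e-3); MD, FA, AK, RK and KA are
invariant to solver precision.

## WMTI inversion

The two-compartment interpretation assumes impermeable, infinitely long
axons (intra-axonal radial diffusivity 0) inside a Gaussian extra-axonal
space.  The axonal water fraction comes from the largest apparent
kurtosis, `f = K_max/(K_max+3)`, located by discrete search over the
250-direction set augmented with the three diffusion eigenvectors; because
the compartment tensors are axially symmetric the radial eigenvectors
attain the optimum exactly, making the inversion exact on forward-model
voxels (round trip tested to 1e-3 over f ∈ [0.1, 0.7]).  Per direction,

    De(n) = D(n)·[1 + √(K(n)·f/(3(1−f)))],
    Da(n) = D(n)·[1 − √(K(n)·(1−f)/(3f))],

adopting the conventional branch (extra-axonal = larger diffusivity);
K(n) is clamped at 0 before the square roots.  Each compartment tensor is
recovered from its directional values by the same linear least-squares
machinery as the main fit (6 unknowns against the quadratic design).
Axial = largest eigenvalue, radial = mean of the two smaller;
TORT = AxEAD/RadEAD.  RadIAD is reported from the intra-axonal minor
eigenvalues even though the canonical model predicts ≈0, because the ROC
battery tabulates it.  Voxels with f < 1e-3 have no detectable restricted
compartment: intra-axonal maps and TORT are invalidated and the
extra-axonal tensor falls back to the full diffusion tensor.

## Phantom generator

The phantom defines the study conditions the statistics are calibrated
under; it emulates structure, not anatomy.

* Acquisition: b = 0, 1000, 2500 s/mm², 60 directions per nonzero shell
  (121 volumes), matching the DKI protocol the analysis targets.  Shell
  directions are Fibonacci-initialised and relaxed by antipodally symmetric
  electrostatic repulsion; the relaxation is required for well-posedness
  (regular spiral sets can be exactly degenerate for the quartic design —
  the 15-direction spiral is).
* Geometry: nested boxes (core ⊂ edema ⊂ ipsilateral NAWM) in one
  hemisphere and a disjoint contralateral block, default 40×40×10 voxels at
  2.5 mm isotropic.  Square in-plane ROI patches of ≈44 mm² (3×3 voxels at
  2.5 mm) are placed fully interior to each zone at the mid-slice.
* Tissue presets per zone (f, Da_ax, De_ax, De_rad in µm²/ms):
  core (0.16, 0.6, 2.2, 1.8), edema (0.20, 0.7, 2.1, 1.5),
  ipsilateral NAWM (0.33, 0.9, 2.2, 0.9), contralateral WM
  (0.48, 1.0, 2.3, 0.8).  These are calibration choices, not measured
  values: they reproduce the qualitative orderings the analysis relies on
  (FA/MK/RK/KA/AWF rising core → contralateral, MD falling) and keep the
  kurtosis-family core-vs-edema gap small relative to the CBF gap, so the
  calibrated discriminability structure mirrors the clinical one (CBF
  dominates core-vs-edema; MK/RK/AWF dominate the outer-border contrasts).
  Derived zone values bracket round-number decision points (AWF 0.2/0.33
  around 0.31; MK 0.88/1.41 around 1.21).
* CBF: per-zone Gaussian voxel values, means 60/25/20/18 mL/100 g/min
  (core mean above, edema mean below, ~50 mL/100 g/min).
* Ground-truth tensors come from the exact mixture-of-Gaussians cumulants
  (W = 3f(1−f)·sym((Da−De)⊗(Da−De))/MD²), so every derived metric has a
  closed-form truth.  Signals are generated from the truncated cumulant
  model by default so the fit is exactly specified; a bi-exponential mode
  (`biexp_signal`) exists for realism studies and is biased at
  b = 2500 s/mm² by construction.
* Noise: Rician (magnitude of two independent Gaussian channels,
  σ = S0/SNR, default SNR 30); a Gaussian mode exists for analytic checks.
  All generators are seeded and bit-reproducible.
* Between-case variability (`jittered_spec`): multiplicative log-normal
  jitter, 10 % on the axonal fraction, 25 % on diffusivities, 18 % on zone
  CBF means.  Fractions vary less than diffusivities, which encodes the
  assumption that kurtosis-family parameters separate zones more reliably
  than raw diffusivities — this asymmetry is what produces the calibrated
  biomarker ranking and should be revisited by anyone re-using the phantom
  for other questions.

What the phantom does *not* model: anatomy, partial volume, susceptibility
or eddy artifacts, motion, fibre dispersion or crossing, compartment
exchange, perfusion physics.  Passing tests therefore demonstrate estimator
and pipeline correctness under the stated generative model, not performance
on patient data.

## Cohort simulation and marker link

Table-level cohorts draw each (case, ROI, parameter) value from a Gaussian
with the zone's derived-metric mean and a 15 % relative SD (CBF uses
absolute between-case SDs 10/6/4/3).  Immunohistochemistry columns are
attached by a Gaussian copula: the marker's latent normal is a linear blend
of the latents of its anchor columns with weights 2·sin(π·ρ/6), so the
population Spearman correlation equals the target exactly; a log-normal
marginal then sets the scale without touching ranks.  Defaults anchor
Ki-67 LI to core CBF (ρ_s = 0.363) and Bcl-2 EA to edema MK
(ρ_s = −0.444).  Markers are drawn once per case and repeated across ROI
rows — adequate because each correlation is evaluated within one ROI.
Infeasible link sets (implied latent correlation matrix not PSD) raise.

## Statistics battery

* Comparisons: two-sided Mann-Whitney per parameter for ROI pairs 1–2,
  2–3, 3–4, treated as independent samples (mirroring the clinical
  analysis; statistically debatable for within-patient ROIs, and noted as
  such).  Exact enumeration for tie-free groups of ≤8; normal approximation
  with tie correction otherwise.  Significance at α = 0.001; no
  multiple-testing correction by default, matching the fixed-alpha design.
* ROC: AUC from the rank statistic (= concordant-pair fraction, ties ½),
  oriented so AUC ≥ 0.5 with the direction recorded; cutoff by Youden's J
  over midpoint thresholds, ties broken toward higher specificity;
  percentile bootstrap CIs (default 2000 replicates) resampling cases
  within group, seeded.  Parameters are ranked by AUC per pair.
* Correlations: Spearman with tie-corrected p at α = 0.05, percentile
  bootstrap 95 % CIs, pairwise deletion, ≥5 pairs required.

Calibration facts the test suite enforces: the null configuration
(identical zones) keeps the α = 0.001 flag rate at ~7e-4 over 500
replicates; bootstrap CI coverage for ρ at n = 50 sits inside [0.90, 0.98];
the copula recovers its Spearman targets at n = 500.

## Problem sizes and numerical choices

The shipped checks run at deliberately modest sizes chosen to exercise the
full machinery: 100 random tissues for noise-free round trips, 1000 voxels
at SNR 30 for noise bias (|MK bias| ≈ 0.02, AWF RMSE ≈ 0.03), 500 null
cohorts of n = 50 for type-I calibration, and a 50-case image cohort on a
36×30×6 grid for the end-to-end ranking — 50 matching the cohort size the
analysis design assumes.  Degenerate inputs (constant groups, constant
marker columns, emptied ROIs, all-clamped voxels, unparameterized zones)
are flagged or raise with specific messages rather than propagating NaNs.

## Known limitations

* The WMTI inversion assumes a single coherent fibre population; crossing
  fibres bias f and the compartment diffusivities.
* The AWF formula is exact only when the kurtosis maximum lies where the
  intra-axonal projection vanishes; with nonzero intra-axonal radial
  diffusivity it becomes an approximation.
* The MK deletion rule is applied per voxel with no spatial context.
* CBF maps are consumed, not computed: ASL quantification, registration
  and anatomical realism are out of scope.
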