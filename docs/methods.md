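# Methods

`icaperf` quantifies cerebral blood flow (CBF) from dynamic susceptibility
contrast (DSC) MRI with an arterial input function (AIF) determined
automatically by spatial independent component analysis (ICA) of the
dynamic series. This note records the models implemented, the parameters
that matter, and the design choices made where the design was genuinely
open.

## The perfusion model

During the first pass of a paramagnetic bolus, the tissue concentration
curve obeys the dilution (indicator) relation

    C_t(t) = F · (C_a ⊛ R)(t),

where `C_a` is the AIF, `R(t)` the residue function (fraction of tracer
still inside the voxel at delay `t`), and `F` the flow. The flow-scaled
residue `F·R(t)` is recovered by inverting the lower-triangular Toeplitz
discretization `A[i,j] = dt·C_a[i−j]` by truncated SVD; CBF is the peak of
that solution scaled by `6000·k_H/ρ` with the literature-standard
large/small-vessel hematocrit correction `k_H = (1−0.45)/(1−0.25)` and
brain density `ρ = 1.04 g/mL`. Concentration is obtained from the spin
signal via the log ratio `C = −(K/TE)·ln(S/S0)` with `S0` the mean
pre-contrast baseline. `K` and `TE` are applied literally in whatever
consistent unit the caller supplies; any global scale on `C` cancels in the
AIF/tissue ratio that yields CBF, so only documentation — not correctness —
depends on the unit convention.

### Adaptive truncation

Truncated SVD trades oscillation of the residue against flow
underestimation. The adaptive threshold walks a fixed grid of truncation
fractions (1%…60% of the largest singular value in 1% steps) and keeps
the smallest fraction whose residue is acceptably smooth, measured by the
oscillation index

    OI = Σ_i |r[i+1] − 2r[i] + r[i−1]| / (n · max|r|),

the normalized total second difference (zero for affine residues). The
smoothness bound `oscillation_limit` defaults to 0.034. It was calibrated
once, on the ideal-AIF study only, so that the mean adaptive threshold
lands at ≈13.6% — the truncation level the reference flow-sensitivity
analysis reports for the ideal AIF — and is configurable. With that
setting, deconvolving the ideal gamma-variate AIF (α = 3, β = 1.5 s,
sampled at 1.5 s) from a dilution-theory tissue curve at true flow
80 mL/100 g/min with Gaussian noise at SNR 27.7 recovers ≈72–74
mL/100 g/min: the familiar truncation-plus-discretization underestimate of
sSVD at coarse sampling.

## AIF determination by spatial ICA

The series is arranged as a time-by-voxel matrix X (p×v). After PCA
reduction — either a fixed component count q (10 for the phantom) or the
smallest q covering a target eigenvalue fraction (0.99 for clinical-scale
data) — FastICA maximizes the non-Gaussianity of the voxel-domain maps,
giving q spatial maps with paired time courses. Choices that matter:

* **Contrast function and convergence.** `fun="exp"`, `tol = 1e−5`,
  `max_iter = 2000`. The data are decomposed raw (no voxel-wise temporal
  centering): the static baseline pattern differs between blood and tissue
  and carries genuine compartment information; removing it measurably
  degrades separation on phantoms.
* **Bipolar maps.** An estimated IC map is a spatial *contrast*: after the
  spatial mean is removed, compartments with a weaker-than-average bolus
  load one pole and stronger-than-average the other. Both poles of every
  map are therefore treated as candidate regions. Each pole is
  characterized by the mean raw signal of its top-50 z voxels, expressed
  as the positive-going drop (baseline minus signal) and fitted with a
  gamma-variate; its rank score is `peak / (FWHM · TTP)`, so early,
  narrow, high-peaked responses — arteries — rank first.
* **Restart pooling.** FastICA solves a non-convex problem; single runs
  occasionally split or smear a source. The selection step pools the
  ranked poles of `n_restarts = 8` runs (restart r seeded with
  `seed·1009 + r`) and never averages maps across runs, so every candidate
  remains a genuine ICA solution.
* **Region selection.** The artery is the globally top-scoring pole.
  Surrounding-tissue candidates are the pooled poles whose top-50 voxel
  sets share at most 13 voxels with the artery set — about half the
  partial-volume strip, which legitimately belongs to both regions, so
  strictly disjoint sets rarely exist — and are face-adjacent to it.
  Among those the winner maximizes restart stability (mean Jaccard
  overlap with the other eligible candidates) times spatial compactness
  (count of face-adjacent pairs inside the set). Stability rewards
  regions the restarts agree on; compactness separates genuine contiguous
  regions from noise-scattered voxel sets. Selection is semi-automatic:
  the full ranking is always returned (and printed by the CLI) so a
  reader can confirm or override the picks.
* **z-maps and weighting.** A selected map is standardized by its own
  moments (population, divide-by-n convention), the 50 voxels of largest z
  form the region (ties broken by ascending voxel index), and the AIF is
  the z-weighted average of their curves with weights normalized to mean
  one — under a uniform map this reduces exactly to the plain region
  average, keeping the weighted AIF commensurate with a manual-ROI
  average. Selection operates on the signal curves; the weighted curve is
  then converted to concentration (the reverse order is available via
  `aif_on="concentration"` for sensitivity checks).

## The synthetic phantom

The generator emulates a single-slice DSC acquisition of three 9×9 blocks
in a row — artery (I), artery-surrounding tissue (II), parenchyma (III) —
with adjacent blocks sharing 3 columns whose signal is a 0.5/0.5 mixture of
the two pure compartments (the partial-volume strips). 80 time points at
1.5 s; injection at time point 7; Gaussian noise with
σ = (peak arterial drop)/CNR, the CNR of the arterial curve.

Signal physics: the arterial bolus is
`C_a(t) = C_max·(t/t_0)·exp(1 − t/t_0)` with `C_max = 3 mM`; `t_0`
defaults to 7 s on the series time axis (the millisecond-scale printed
convention, `t_0 = 0.007 s`, is degenerate at 1.5 s sampling and available
by passing it literally). The blood concentration in tissue follows
dilution theory with a monoexponential residue at MTT 2.6 s, discretized
with the exact bin-integrated exponential kernel so a constant input
converges to ζ·c (the left-endpoint Riemann kernel, which carries an
O(dt/MTT) scale bias, is kept as an option). Relaxation uses the two
asymptotic susceptibility regimes behind a pluggable interface:

* static dephasing (SDR), large vessels: `ΔR2* = (2π/3)·ζ·δω`, linear in
  the frequency shift `δω = γ·B0·χ_mM·C`;
* diffusional narrowing (DNR), capillaries:
  `ΔR2 = k_DNR·ζ·δω²·ρ_c²/D_w`, quadratic.

The artery block is relaxed by SDR with ζ = 1 (pure blood, baseline
R2 = 6.21 s⁻¹); the surrounding block by SDR only, driven by the delayed
dilution curve with an effective perivascular large-vessel fraction
ζ_peri = 0.3; the parenchyma block by SDR (ζ_v = 0.01) plus DNR
(ζ_c = 0.02, ρ_c = 3.5 µm); both tissue blocks use the venous baseline
13.43 s⁻¹. Two constants are calibrations rather than printed physics:
`χ_mM = 0.027 ppm/mM` (the cgs molar susceptibility of Gd-DTPA) and
`k_DNR = 40`, which absorbs the cgs→SI susceptibility convention
((4π)² ≈ 158) times an O(0.25) asymptotic prefactor. They were chosen so
the compartments show realistic 1.5 T first-pass responses — ≈95% peak
signal drop in the artery, ≈50% perivascular, ≈26% parenchymal — and give
the perivascular curve the lower-and-later profile relative to the artery
that clinical feature tables show. ζ_peri is a modelling choice, not a
printed value: perivascular voxels see the field of the adjacent large
vessel, and the stated arteriole fraction (ζ_a = 0.005) would render the
compartment invisible at any simulated CNR.

What the phantom does *not* emulate: recirculation (the gamma fit window,
time points 7–25, excludes it by design), vessel-orientation-dependent
field maps, Rician noise statistics (additive Gaussian is justified in the
high-SNR magnitude regime), motion, and multi-slice clinical geometry.
Passing phantom tests therefore demonstrates the segmentation and
deconvolution machinery under controlled partial-volume mixing — not
robustness to clinical confounds.

## Gamma-variate characterization

Candidate AIFs are summarized by fitting
`y(t) = A·(t−t₀)^α·e^{−(t−t₀)/β}` over time points 7–25 (1-based,
matching the injection at time point 7) by bounded least squares from a
deterministic 6-start grid (arrival at the last pre-peak sample minus
{0,1,2} sampling intervals × α ∈ {2,3}); the best residual wins, ties by
start order, and a fit whose TTP leaves the window is rejected. Reported
features: TTP = t₀ + αβ; peak height = A·(αβ)^α·e^{−α} (the analytic
mode); FWHM by root bisection of the fitted curve on both sides of the
peak; onset = the first raw sample strictly above the whole-curve mean.

## Numerical conventions and degenerate inputs

Time-point indices are 1-based at every user-facing interface and 0-based
internally. All randomness flows from a single seed per run; derived seeds
stay below 2³¹. Non-positive signal samples become NaN concentrations
(logged) rather than errors; voxel-level deconvolution failures yield NaN
map entries; constant maps, flat curves, empty masks and mismatched grids
raise immediately. The phantom's effective tissue "flow" is deliberately
not a controlled quantity (its parenchymal response is nonlinear in
concentration through the DNR term), so quantitative flow recovery is
validated on the linear dilution forward model instead.

## Problem sizes of the shipped studies

The segmentation study runs 24 phantom seeds at CNR 30 (10-component ICA,
8 restarts each, ≈7 s per seed); the flow-sensitivity study runs 60 noise
realizations (seconds). These sizes put the seed-averaged estimates'
standard errors well under the decision margins used in the tests.

## Known limitations

* Standard (non-circulant) sSVD is delay-sensitive; AIFs selected by this
  package minimize delay by construction, but a delayed AIF would bias CBF
  low. Block-circulant oSVD is out of scope.
* The surround/parenchyma time courses of the phantom are strongly
  correlated (r ≈ 0.96), so their ICA separation is intrinsically noisy at
  low CNR; restart pooling and compactness-based selection recover the
  perivascular region at >90% on average at CNR 30, but individual seeds
  can fall below that.
* CBV/MTT maps, recirculation modelling, DICOM ingestion and motion
  correction are not implemented.
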