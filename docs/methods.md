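# Methods

## Scope and data flow

The package analyses four measurement streams of a preclinical
brain-tumor MRI study — DCE pharmacokinetics, VFA T1 mapping, ADC
mapping and T2-weighted volumetry — and the group statistics built on
them. All inputs are either NIfTI-1 volumes with JSON timing sidecars
or long-format cohort CSVs. Because the intended studies rarely deposit
image data, a digital phantom and a cohort simulator generate inputs
with the statistical structure the analysis assumes; they are
first-class, tested modules, not fixtures.

## Kinetic model

The extended Tofts model describes tissue concentration as
`Ct(t) = vp·Cp(t) + Ktrans·∫ Cp(τ)·exp[−kep(t−τ)]dτ` with
`kep = Ktrans/ve`. For a sum-of-exponentials arterial input function
(AIF) the convolution is evaluated in closed form,

    ∫₀ᵘ a·e^{−mτ'}·e^{−kep(u−τ')}dτ' = a·(e^{−mu} − e^{−kep·u})/(kep − m),

with the `u·e^{−kep·u}` limit when `kep → m`; tabulated AIFs fall back
to an O(n²) trapezoidal convolution. The trapezoid path doubles as an
independent numeric oracle: its composite error scales as
`(kep·Δt)²`, so the 1e-5 relative agreement check is run at
Δt = 0.01 min in the `kep ≲ 1/min` regime where that bound sits below
the tolerance; at larger kep the expected discrepancy grows
quadratically and the comparison would measure quadrature error, not a
defect.

Voxelwise fitting is bounded trust-region least squares
(`scipy.optimize.least_squares`, TRF) on (Ktrans, ve, vp) with bounds
[0, 5] 1/min × (0, 1] × [0, 1), start (0.1, 0.3, 0.05) and a single
fallback multi-start at (1.0, 0.5, 0.1) on non-convergence. Fitting is
done in concentration space, after T1-based signal normalization.
`kep` is always derived as `Ktrans/ve`, never fitted independently, so
the kinetic identity holds exactly on every output voxel. Voxels whose
fit lands outside the physiological window (Ktrans < 0.01 1/min,
Ktrans > 5 1/min, ve > 1) are excluded from ROI summaries rather than
clipped or zeroed. No per-voxel bolus-delay fitting is attempted; the
AIF arrival time is taken as known from the injection protocol.

A note on monotonicity: `Ct` is provably nondecreasing in Ktrans (at
fixed ve) only for a non-decaying `Cp`; with a decaying AIF,
faster-filling voxels also wash out faster, so late-time `Ct` can
decrease as Ktrans grows. The property suite therefore asserts
monotonicity for a constant `Cp` and over the uptake window for the
default AIF.

## Arterial input function

The population AIF is a dose-scaled biexponential,
`Cp(t) = D·(a₁e^{−m₁(t−t₀)} + a₂e^{−m₂(t−t₀)})`, zero before the bolus
arrival `t₀`. The default amplitudes (3.99, 4.78 kg/L) and rates
(0.144, 0.0111 1/min) are Weinmann-type surrogate values for a
0.1 mmol/kg gadoterate bolus — placeholders for a measured population
curve, not species-specific measurements — and every field is
configurable. The bolus is modelled as instantaneous at `t₀`
(default 60 s); the ~2 s injection duration is not smoothed.

## Relaxometry

SPGR signal: `S = M0·sinα·(1−E1)/(1−E1·cosα)`, `E1 = exp(−TR/T1)`.
VFA T1/M0 mapping uses the classical linearization (`S/sinα` against
`S/tanα`); voxels with slope outside (0, 1), nonpositive M0, or a
perfectly angle-independent signal (no SPGR solution) are flagged
invalid rather than raising. Signal→concentration conversion fixes M0
from the pre-bolus baseline mean (default 50 frames = 30 s,
configurable), inverts the SPGR equation per frame for T1(t), and
applies `C = (1/T1(t) − 1/T10)/r1` with rates in 1/s. Frames at or
above the attainable maximum `M0·sinα` are clamped just below it and
flagged; the flags are returned alongside the curve. Defaults:
r1 = 3.5 /mM/s (a 7 T literature value for gadoterate — the agent's
relaxivity is protocol-dependent and configurable), T2*/TE effects
neglected (TE = 2 ms), fast water exchange assumed (linear 1/T1 vs C).
Unit convention: concentrations in mM, kinetic rate constants in
1/min, with the single s↔min conversion at the pharmacokinetics
boundary.

## Diffusion

ADC is estimated by weighted linear regression of ln S on b with
weights S², which counteracts the log-transform noise amplification at
high b; it is deterministic and closed-form, adequate at the SNR the
protocol provides, and deliberately swappable for a nonlinear fit.
All five b-values are used by default; a `min_b` option excludes the
perfusion-contaminated b = 0 image. The ×10⁴ report-unit conversion is
applied exactly once, at the summary stage. No IVIM or kurtosis terms
are modelled.

## Volumetry

Masks are binary with the center-in rule (a voxel belongs to an ROI
iff its center is inside the surface), matching manual-ROI practice;
volume is voxel count × voxel volume (0.007 mm³ at the default
geometry). Mask transfer between sequence grids assumes a shared world
FOV and uses nearest-neighbor lookup of voxel centers; full image
registration is out of scope, and phantoms are generated pre-aligned.
On the default grid the rasterization error of a compact ~5 mm³ ROI is
dominated by the coarse 0.7 mm slice axis and stays within one
surface-voxel layer (≲5%); elongating the ROI across more slices
reduces it.

## Phantom and noise

The phantom is a homogeneous ellipsoidal tumor (no necrotic core) in
uniform background on the acquisition grid; per-compartment Ktrans,
ve, vp, T1, M0 and ADC are configurable, with tumor defaults equal to
the day-0 treated-arm cohort medians (Ktrans 0.41 1/min, ve 0.32,
vp 0.06, ADC 7.62e-4 mm²/s). Forward simulation composes the kinetic
model with the SPGR signal model so that the noise-free simulate→fit
roundtrip is exact; pre-bolus frames equal the baseline signal
bit-for-bit. Noise is rician by default (magnitude MRI),
`sqrt((S+ε₁)²+ε₂²)`, at baseline SNR 20 unless σ is given explicitly;
every stochastic operation is a pure function of (inputs, seed).

What the phantom deliberately omits: anatomy, motion, B1
inhomogeneity, eddy currents, k-space effects, partial-volume mixing
and intra-tumor heterogeneity. Passing recovery tests therefore
demonstrates correctness of the estimation chain under the model's own
assumptions, not robustness to real-data artifacts.

The acquisition default follows the stated 0.6 s × 300-frame protocol
(180 s); where a protocol's printed total scan time disagrees with
resolution × repetitions, the resolution × repetitions reading is
used, and both are configurable.

## Cohort simulator

Each subject's value is its group × day median multiplied by
`exp(b + e)` with a persistent per-subject effect `b ~ N(0, σ_b²)` and
day-level fluctuation `e ~ N(0, σ_w²)` — multiplicative lognormal
dispersion that preserves the median trajectory. Defaults
σ_b = 0.25, σ_w = 0.10 were calibrated once to the spread of the
published IQRs (log-IQR of the baseline Ktrans cells ≈ 0.4). `Kep`
rows are derived per subject via `Ktrans/Ve`. The default median
trajectories are the published four-arm × three-day cohort medians,
with one adjustment: the treated-arm day-14 Ktrans is set to
0.41 × (1 − 0.591) ≈ 0.168 so the default trajectory carries the
reported 59.1% decline, which the printed day-14 median (0.21,
a 48.8% decline) does not reproduce exactly; the two published numbers
are mutually inconsistent and the percent-change statement was chosen
as the calibration anchor. At 8 subjects per arm the day-14
treated-vs-sham Ktrans contrast is detected by the rank tests in well
over 80% of seeded replicates.

## Statistics

Values are reported as median (Q1, Q3) with linear-interpolation
quantiles (the convention of the originating software being unknown,
this choice is documented rather than inferred). Within-group change
across days uses one-way repeated-measures ANOVA (statsmodels AnovaRM;
sphericity assumed; subjects missing a day are excluded and counted).
Between-group comparisons use a normality gate (Shapiro–Wilk at
α = 0.05 per group, overridable to force either branch): the
parametric branch runs one-way ANOVA with t-test post hocs, the
nonparametric branch Kruskal–Wallis (tie-corrected, χ² approximation)
with Mann–Whitney post hocs — exact enumeration when n ≤ 12 without
ties, tie-corrected normal approximation otherwise. Post hoc p-values
are Bonferroni-corrected within each metric × day family of six group
pairs and capped at 1; post hocs run only when the omnibus is
significant unless configured to run always. Reports state which
branch ran for every cell. Kep is tabulated in 1/min throughout
(≈1.3 1/min at the default tumor parameters); published tables
sometimes print Kep under a 10⁻³ scale that is inconsistent with
Ktrans/Ve at the printed values, and the 1/min convention is used
deliberately.

## Problem sizes and numerical choices

The validation studies use deliberately small grids chosen as the
smallest instances that exercise every stage: tissue-curve recovery at
the full 300-frame protocol; image-space studies on 16×16×1 grids with
a ~16-voxel tumor; the stochastic-recovery study runs 100 seeded
phantoms through the complete noisy chain (VFA fit, conversion, Tofts
fit) at SNR 20. Optimizer tolerances are xtol = ftol = gtol = 1e-12;
determinism of every fit and simulation for fixed inputs and seed is
asserted in the suite. Degenerate inputs (all-zero curves, zero
semi-axes, empty ROIs, ve = 0 voxels, all-tied samples) return flagged
or empty results rather than NaN surprises, and error messages name
the offending axis, key or bound.

## Known limitations

No B1 correction in VFA; no bolus dispersion or per-voxel delay; no
model selection (Patlak/2CXM); monoexponential diffusion only; no
image registration; rank-test power claims are specific to the default
dispersion calibration. The AIF defaults are surrogates — analyses of
real data should substitute a measured population curve.
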