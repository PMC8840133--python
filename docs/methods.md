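# Methods

This note documents the models, numerical choices and limitations behind the
`deepmaldi` processing chain, and what the synthetic-data generator does and
does not emulate.

## Peak-shape model

Isolated MALDI-TOF peaks are modeled as asymmetric Gaussians with independent
left and right half-widths at half maximum (HWHM): the right side is wider
because the isotope envelope and the instrument response both broaden the
high-mass flank. Width trends vs m/z are piecewise — linear below a crossover
mass `m_int`, quadratic above — with `FWHM(m) = σ_L(m) + σ_R(m)`. Calibration
(`calibrate_peak_shape`) fits each of ≥ 8 isolated seed peaks (19 is typical)
using only points above 0.25 × the window maximum, so the local background
under the tails does not bias the widths; linear branches are fitted on
3–17 kDa and quadratic branches on 13–30 kDa (deliberately overlapping), and a
single `m_int` is taken from the intersection of the FWHM branches inside
13–17 kDa so all three trends switch at the same mass and `σ_L + σ_R` stays
consistent with the FWHM trend. If the branches do not intersect there,
`m_int` falls back to 15 kDa with a warning. Trend fits are unweighted
ordinary least squares; replicate preparations are fitted independently and
their coefficients averaged arithmetically. Nonlinear peak fits initialize
from the apex (position, height) and the empirical half-max width; they are
deterministic.

The package ships `default_shape_model()`, a *synthetic* width model (linear
σ_L = 0.45 + 1.8e-4·m, σ_R = 0.75 + 2.6e-4·m below 15 kDa; transversally
crossing quadratics above, so that branch intersection is well defined). It
parameterizes the generator and the test fixtures; it is not an instrument
calibration, and real analyses should calibrate from reference spectra.

## Background estimation and decomposition

The background estimator is an asymmetric penalized least-squares (Whittaker)
smoother with two penalties:

    minimize  Σ wᵢ (yᵢ − zᵢ)² + λ₁ Σ (Δ²z)² + λ₂ Σ (Δz)²

with wᵢ = p where yᵢ > zᵢ and 1 − p otherwise. Differences are taken on index
spacing (the assignment λ₁ ↔ second differences, λ₂ ↔ first differences is the
standard two-penalty form; the alternative assignment is not supported).
Weights start at 0.5 and iterate until the above/below assignment is stable;
a small fraction of boundary points (`tol`, default 1e-4 of the points) may
chatter indefinitely and is tolerated as converged, otherwise the last
iterate is returned with a warning after `max_iter` = 50 rounds. The linear
system is pentadiagonal and solved by a banded Cholesky factorization in a
mean-shifted frame (the penalties annihilate constants; shifting removes the
constant mode, which the large penalties otherwise resolve poorly and which
would break exactness on constant inputs and scale equivariance).

Two regimes produce the decomposition: stiff (λ₁ = 1e11, λ₂ = 1e4, p = 0.001)
for the instrument background `bg1`, relaxed (λ₁ = 1e6, λ₂ = 1e2, p = 0.001)
for background plus bumps `bg2`; then `bumps = bg2 − bg1`, `fine = y − bg2`,
and `y = bg1 + bumps + fine` holds to machine precision by construction.
Bumps may dip locally negative where the two backgrounds cross; the
decomposition preserves the identity and clipping happens only at
feature-value time.

Numerical notes, measured on synthetic data:

- *Effective stiffness.* With p = 0.001 nearly all points sit above the fit,
  so the effective data weight is ~p and the smoothing length is roughly
  (λ₁/p)^¼ samples (≈ 3,200 samples for the stiff regime). Structure narrower
  than this stays out of `bg1`; structure broader is followed. Because the
  length is measured in samples, the corresponding Da scale depends on the
  sampling density of the spectrum.
- *Boundary layers.* The penalties impose natural boundary conditions
  (effectively z′ ≈ 0, z″ ≈ 0 at the ends). A baseline with a steep slope at
  the acquisition edge produces an undershoot that relaxes over
  ~√(λ₁/λ₂) samples. The synthetic generator therefore models the matrix
  background as a Gaussian-shaped hump peaking at the 3 kDa cutoff (zero edge
  slope, as real TOF backgrounds roll over near the detection cutoff); on
  data with a steep-edged background, the first ~1,000 samples of `bg1`
  should be treated with caution.
- *Solver comparisons.* The normal matrix has condition number
  ~16 λ₁/p, so above λ₁ ≈ 1e5 two correct double-precision solvers can
  legitimately differ by more than 1e-8; oracle-equivalence checks therefore
  run both implementations with an identical fixed two-iteration weight
  schedule at λ₁ ∈ [1e3, 1e5], where the comparison is well posed.

## Peak detection

Detection operates on the fine structure. It is matched-filtered first: the
sliding inner product with the unit-amplitude asymmetric Gaussian at the
local widths, normalized so a model-matching unit peak gives response 1 at
its center. The m/z-varying kernel is handled by processing ~1,500-sample
segments (widths vary slowly) with overlap margins. Candidates are strict
local minima of the second derivative of the convolved signal (convolution
before differentiation — the filtering is what makes differentiation usable),
with negative curvature and positive response, refined to sub-grid precision
by a three-point parabola. The second derivative uses central differences on
the possibly non-uniform grid. Candidates closer than FWHM/4 are
de-duplicated keeping the higher-SNR one.

SNR is the fine-structure intensity over a local noise level. The noise
deviation signal is the first difference of the signal scaled by 1/√2 (for
white noise this equals the noise standard deviation, the same quantity a
peak-width smoothing window measures on pure noise). The shortest-support
high-pass is used because with peak amplitudes spanning 3.5 decades an
FWHM-wide smoothing kernel smears strong peaks across many peak widths and
leaves no clean residual anywhere in busy regions (measured 2.5–10× noise
inflation), whereas the first difference confines each peak's contamination
to its own footprint. The absolute deviation is aggregated into a smooth
local scale by a low quantile (default 0.2, calibrated against the
half-normal distribution) over blocks ~12 local FWHM wide, with two
refinement passes that mask deviations above 3.5× the running estimate
(peak slopes otherwise shift the quantile upward by ~50%). Constant signals
get a floored noise so SNR saturates instead of dividing by zero. Detection
thresholds: SNR > 10 for analysis spectra, SNR > 3 for single rasters.

Influence clustering: two candidates are linked when their centers are within
0.5 × FWHM at the pair midpoint, or when either model peak evaluated at the
other's center exceeds 10% of that other peak's amplitude (both constants
configurable; candidate amplitudes for the test come from the convolved
response). Clusters are connected components; multiplicity is uncapped with a
warning above 25 members. Isolated peaks are fitted singly, clusters jointly:
in detection mode amplitudes and centers are free (widths from the shape
model, evaluated at the current center; trust-region least squares, centers
bounded within ± FWHM/2 of the candidate); in extraction mode only
amplitudes are free and the fit is non-negative linear least squares on fixed
unit-shape columns — fast, convex, and exactly the detection-mode model with
centers pinned. Non-convergent fits fall back to the convolved-response
amplitude with a warning flag.

## Raster alignment and averaging

Each 800-shot raster is decomposed, peaks are detected at SNR > 3, and
detected positions are matched to the nearest alignment point within
1500 ppm. With ≥ 20 detected peaks and ≥ 13 matches, a quadratic
m′ = b₀ + b₁m + b₂m² is fitted (unweighted) and applied to the axis; the
fitted shift at the lowest alignment point must stay within 15 Da, otherwise
(or on any shortfall) the raster fails QC and is returned unchanged. The
default alignment-point set is the seven external calibration masses
(3320 … 28093.951 Da) and is config-overridable; note that the 13-match
requirement presumes a richer instrument-specific point list, so deployments
must supply one (the synthetic tests do). Averaging selects
`n_select` rasters uniformly without replacement (seeded), interpolates
linearly onto the first QC-passed raster's grid, and averages pointwise.

## Spectrum alignment and master peak list

Per-spectrum alignment uses only fitted peaks with SNR > 10, keeps those at
or above the 80th SNR percentile, and calls a peak alignable when it lies
within 0.5 × FWHM of its nearest alignment point. Four contiguous sub-ranges
(defaults 3–7.5, 7.5–12, 12–18, 18–30 kDa, config-overridable; the defaults
are synthetic, chosen as roughly equal log-spacing) must each contribute at
least five alignable peaks; the quadratic is fitted with weights 1/m (peaks
weighted inversely to their m/z location) and applied as an axis rewrite
without resampling (optional resampling is a config flag). Failing spectra
are excluded from all further analysis.

Master-list merging is iterative: an incoming peak further than 0.5 × FWHM
(at the incoming mass) from every master entry is appended, otherwise the
nearest entry's position is updated by a running mean weighted by its
contributor count — order-robust; a final pass enforces the
minimum-separation invariant on the result. Exact order-invariance is not
claimed; permuting input lists moves positions by far less than 0.25 × FWHM
in practice.

## Feature values and reproducibility

Extraction groups master positions with the same influence rule, fits all
amplitudes non-negatively (isolated singly, clusters jointly) with centers
and widths fixed, and reads the bump intensity at each master m/z by linear
interpolation, clipped at zero. Standard value = fitted amplitude A0 (areas
are a trivial transform and intentionally not the default); enhanced value =
A0 + max(bumps, 0), so enhanced ≥ standard always. Master positions outside a
spectrum's range are flagged missing (NaN), not zero. Feature tables are
normalized per sample by the total feature-value intensity; replicate
statistics use the sample (n − 1) standard deviation, CV = sd/mean (NaN for
zero-mean features), and the cumulative curve N_CV(x) = fraction of features
with CV ≤ x. Standard and enhanced tables are normalized independently before
CV comparison.

## Protein set enrichment

Feature–protein association uses Spearman correlation (mid-ranked ties) over
the shared samples; constant series give undefined correlations and are
excluded. The enrichment score of a feature against a process's protein set
is a weighted Kolmogorov–Smirnov running sum — proteins ranked by decreasing
correlation, members advance the sum by |ρ|^w (w = 1) normalized over
members, non-members retreat it by 1/(N − N_members), score = signed maximum
deviation — averaged over 25 random half-splits of the samples with
correlations recomputed per split. The split-averaged form trades the single
full-sample ranking for lower variance across sample composition; split
count and fraction are configurable, and the exact weighting of the original
split-based score it approximates is not published, so this form is a
documented choice. Significance: the whole score is recomputed for
permutations of the feature's values across samples (default 1000;
p = (1 + #{|null| ≥ |observed|}) / (1 + n_perm), two-sided, never zero), and
a (feature, process) pair is reported associated when p < 0.01 and its
Benjamini–Hochberg adjusted FDR across the processes tested for that feature
is ≤ 5%. Sample-collection-sensitive features (hemoglobin- or
fibrinogen-related masses) are handled by an exclusion-list input rather than
hard-coded masses. The implementation is vectorized across permutations
(ranks of a permuted vector are the permuted ranks), which is what makes
1000-permutation runs over hundreds of features practical.

## Synthetic data

The generator emulates: a TOF-like m/z grid with spacing ∝ √m (uniform
flight-time sampling) over 3–30 kDa; several hundred asymmetric-Gaussian
peaks with widths from the shape model, positions uniform with a
minimum-separation constraint (default 3 FWHM), and amplitudes log-uniform
over 3.5 decades (default floor 30 a.u. with noise σ = 10, so ~85% of peaks
sit above the SNR-10 detection threshold); broad Gaussian bumps
(700–1400 Da FWHM, heights 300–1200 a.u.) tiling the range; the
Gaussian-shaped matrix background described above; and i.i.d. Gaussian noise.
Replicates share the truth and draw lognormal amplitude jitter (default
CV 0.10 per peak), a common lognormal bump-height jitter (default CV 0.02 —
bumps pool many unresolved proteins and are more stable than individual weak
peaks, the regime in which enhanced values help), fresh noise, and small
random quadratic m/z warps. The enrichment-panel generator draws lognormal
protein abundances, disjoint process sets, and planted features as the mean
of a process's member proteins plus relative noise. Everything is
reproducible from (parameters, seed).

Not emulated: detector saturation and dead-time, chemical (non-Gaussian,
heteroscedastic) noise, isotope fine structure, correlated batch effects, and
matrix-cluster interference below ~3 kDa. Passing tests therefore demonstrate
the algorithmic properties of the chain (conservation, recovery, calibration,
power) under a faithful structural model of the data, not instrument-level
performance.

## Problem sizes and defaults used in validation

The validation suite and `scripts/acceptance.py` use: 100 random 3,000-point
spectra for conservation; 50 random 1,000-point problems for the solver
oracle; 19 seed peaks / 60,000-point spectra for calibration; one
500-peak, 60,000-point spectrum for detection; 60 random doublets at
0.5–1.0 FWHM separation; 220 jittered 70% subset lists of 300 true positions
for merging; 8 replicates of a 300-peak, 40,000-point truth for the
reproducibility comparison; and 100 samples × 150 proteins × 5 processes with
1000 permutations (200 null features; 30 planted) for enrichment
calibration. These sizes were chosen as the smallest at which each property
is measured with comfortable statistical margin.

## Known limitations

- Feature values are semi-quantitative: amplitudes in arbitrary units after
  total-intensity normalization, suited to relative comparisons across
  samples, not absolute quantification.
- The stiff/relaxed λ values are tied to sampling density (penalties act on
  index differences); spectra sampled very differently from ~0.4–1.4 Da per
  point over 3–30 kDa may need rescaled penalties.
- Heavily overlapped peaks closer than ~FWHM/4 are detected as one candidate
  by design (the minimum-separation rule); they can still be fitted
  separately at extraction time if the master list resolves them.
- Raster-level QC defaults (≥ 13 usable alignment matches) require an
  instrument-specific alignment-point list richer than the seven calibration
  masses shipped as the default.
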