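# Methods

## The ECI statistic

Differential pulse voltammetry of an agave distillate in phosphate buffer
(pH 4) shows oxidation peaks near 0.34 V and 0.50 V vs Ag/AgCl(sat),
assigned to hydroxyl oxidation on the A and B rings of the flavonoid
skeleton (total polyphenols and flavonoids). Each peak contributes the
ratio of peak current to peak potential, jointly reflecting concentration
and ease of oxidation, and the Electrochemical Color Index is their sum:
`ECI = i1/E1 + i2/E2` in μA/V.

Peak detection reports the grid point of maximum current within
`target ± window` for each nominal peak. Defaults: targets (0.34, 0.50) V
and window 0.06 V — wide enough to tolerate drift, narrow enough that the
two windows (0.16 V apart) never overlap. No sub-grid interpolation is
performed; at the 5 mV scan step the index is insensitive to it. By
default raw currents are used; `baseline="linear"` fits a straight line by
least squares over all scan points at distance ≥ 3×window from every
target centre and subtracts it. At that distance a Gaussian peak with
sigma ≤ window/2 contributes ≤ e⁻¹⁸ of its height, so a truly linear drift
is removed essentially exactly; window-edge interpolation was rejected
because peak tails at ±2 sigma would bias the heights by ~13%. A window
whose maximum does not rise above the (corrected) baseline is flagged
"peak absent" and its height reported as 0 rather than negative.

## Kinetic model and sign convention

`ECI(t) = ECI_eq + A1·e^(−k1·t) + A2·e^(−k2·t)` is a two-compartment
description: fast extraction from accessible surface sites, slower
re-adsorption/release associated with less accessible sites, converging to
the equilibrium value ECI_eq. Published parameter tables print positive
magnitudes, but with both amplitudes positive the function is monotone
decreasing and cannot reproduce the observed first-week rise. The package
therefore fixes a canonical *extraction-negative* convention: `a1 = −|A1|`
(extraction), `a2 = +|A2|` (adsorption-limited relaxation). With the
light-toast magnitudes this gives ECI(0) = 0.168 − 20.848 + 20.651 ≈ −0.03
(≈ 0, the unaged spirit), a positive initial slope, a peak within the
first week and relaxation toward ECI_eq — the observed phase structure.
Fits report signed amplitudes plus magnitudes for table comparison; terms
are labelled so the negative-amplitude term is `a1` (larger rate breaks
ties when both signs match).

### Fitting

The model is linear in (ECI_eq, a1, a2) and nonlinear only in (k1, k2), so
the fitter uses variable projection: over a 40×40 log-spaced grid of rate
pairs on [0.01, 2] day⁻¹ the three linear parameters are solved exactly
from the 3×3 normal equations; the five best grid solutions seed a
Levenberg–Marquardt refinement of all five parameters (rates
log-parameterized to stay positive), and the lowest-SSE refinement wins.
The default fitting window is days 0–90. R² = 1 − SSres/SStot on the
fitted window; a constant series returns zero amplitudes, rates pinned at
the grid lower bound, a degenerate flag and R² = 1 by the 0/0 convention.
Fewer than 6 distinct days (5 parameters) is an error.

### Identifiability near k1 ≈ k2

The reference parameter sets have k1 within 5–15% of k2 with large
near-cancelling amplitudes. In that regime the likelihood surface has a
ridge: as k1 → k2 the two exponentials become collinear and solutions with
arbitrarily large opposite amplitudes fit (almost) equally well. Noiseless
series still refit exactly — the tests and the acceptance computation
verify recovery to ≤ 1e-3 relative — but under measurement noise of
0.02 μA/V (≈5% of the curve maximum) the Fisher-information standard error
of |A1| exceeds the parameter by nearly two orders of magnitude, and the
global least-squares optimum genuinely drifts along the ridge. Amplitude
magnitudes recovered from noisy series should therefore be read as
curve-level descriptors, not as precisely estimable quantities; only
ECI_eq (relative SE ≈ 1.5% under the same conditions) is sharply
identified. The package does not regularize or bound the amplitudes, since
any such constraint would substitute a prior for information the data do
not contain.

## Phase segmentation

The four phases are recovered by a continuous piecewise-linear fit with
three breakpoints chosen by exhaustive search on the integer-day grid,
minimizing SSE; given breakpoints the fit is linear least squares on the
basis {1, t, (t−b1)₊, (t−b2)₊, (t−b3)₊}. The default search windows —
b1 ∈ [3, 15], b2 ∈ [b1+2, 25], b3 ∈ [40, 80] — bracket where the rise,
re-adsorption decrease and late increase are expected; they are
overridable. The (+, −, ≈0, +) pattern flag uses `flat_tol` = 1e-3
μA/V/day as the "≈0" threshold for the pseudo-steady segment (an order of
magnitude below the first-week slopes, and below the default late-ramp
slope of 2e-3 so the fourth phase still registers as positive). A series
that a single straight line explains to machine precision leaves interior
breakpoints arbitrary and is flagged `no_phase_structure` instead of
reporting spurious phases.

## GLCM texture

Images are quantized to 256 gray levels (8-bit input untouched;
higher-depth input mapped linearly with round-half-even). Co-occurrence
counts use a 1-pixel offset at 0°, 45°, 90°, 135° under the (row, col)
convention 0° → (0,+1), 45° → (−1,+1), 90° → (−1,0), 135° → (−1,−1),
symmetrized by adding the transpose and normalized to probabilities.
Counting is delegated to scikit-image's co-occurrence routine (with the
angle relabelling needed to match this displacement convention); the
metric scalars are computed in-package because the homogeneity weight here
is 1/(1+|i−j|), not scikit-image's 1/(1+(i−j)²). Entropy uses log₂ with
0·log 0 ≡ 0; contrast is the standard Σ(i−j)²P (no published equation
names a variant). Correlation is undefined for a constant image (zero
marginal variance) and reported as NaN with a warning — propagating
through the four-direction average rather than silently biasing it —
because substituting 0 or 1 would be an arbitrary value, not a measurement.
Reported metrics are arithmetic means over the four directions. The
heterogeneity map is the per-pixel standard deviation over an odd square
window (default 15 px) with reflect padding.

## Multivariate stage

The 3 toast levels × 11 descriptors matrix (FTIR O–H, FTIR C=O, Raman G,
contrast, entropy, homogeneity, |A1|, |A2|, k1, k2, ECI_eq) is standardized
column-wise with the sample (n−1) standard deviation — with n = 3 the
denominator choice materially changes scores, and n−1 is the common
default of standardization routines. PCA is the SVD of the standardized
matrix; explained percentages come from squared singular values, and the
min(n−1, p) retainable components are kept (rank ≤ 2 here, so two
components carry 100%). Loading signs are fixed so each component's
largest-magnitude loading is positive — PCA signs are arbitrary and the
published signs cannot be matched without the unpublished FTIR values.
Spearman ρ uses average ranks for ties; no p-values are attached (n = 3
makes them meaningless) and no multiple-testing correction is applied, in
keeping with the descriptive framing. One-way ANOVA is the classical
between/within decomposition with the upper-tail F p-value; zero
within-group variance yields an infinite F flagged degenerate.

## Synthetic data

The generators emulate the study conditions so that every stage is
testable without the (undeposited) raw data:

- **Voltammograms** — Gaussian peaks on a linear baseline plus i.i.d.
  Gaussian noise on the standard grid (−0.3 to 1.0 V, 5 mV, 261 points).
  Gaussians are the simplest shape consistent with DPV peak profiles; no
  electrochemical mechanism (diffusion, electrode kinetics) is simulated.
- **ECI series** — the canonical signed model per toast level (reference
  parameter sets in `ecikin.reference`), plus an additive linear ramp
  after `late_onset` (default day 60, slope 0.002 μA/V/day) standing in
  for the late release from deeper pores that the closed-form model cannot
  produce, plus Gaussian noise (default 0.02 μA/V, ≈5% of the light-toast
  curve maximum; published plots show error bars but no magnitudes).
  Replicates per day are exposed as a parameter (default 1; the original
  per-day replication is not stated).
- **Stave images** — sinusoidal grain + random dark char blotches (radius
  1–3 px, depth scaled by `speckle_contrast`) + pixel noise, clipped to
  8-bit. `speckle_density` is a per-pixel blotch seeding rate; with ≈16 px
  per blotch the presets (0.002 / 0.004 / 0.008) char roughly 3–13% of the
  area, with depths chosen so blotches do not saturate to black. Presets
  darken the base level and increase speckle and noise with toast level,
  reproducing the published *ordering* of contrast and homogeneity across
  toast levels — not the printed values, which depend on the actual
  photographs (resolution, optics, lighting) that are not available.
- **Feature matrix** — reference kinetic and texture descriptor values.
  The two FTIR descriptors have no published scalars; defaults are clearly
  documented synthetic placeholder triples (O–H decreasing, C=O increasing
  with toast, the qualitative published trend) and are injectable.

What passing tests on these data show: the estimators invert the assumed
generative models and reproduce published-table self-consistency. What
they do not show: robustness to real-data features absent from the
generators — non-Gaussian and drifting DPV baselines, day-to-day electrode
variability, correlated measurement error, real wood anatomy.

## Problem sizes and determinism

Default analyses run on daily grids of 91 days, 128×128 images and 16×16
oracle fixtures; fits take well under a second each and the full synthetic
pipeline a few seconds. All stochastic generators take explicit integer
seeds (numpy `default_rng`), and pipeline runs derive per-stage seeds
deterministically from the single configured seed, so equal configurations
give byte-identical outputs.
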