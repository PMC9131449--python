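# Methods

## Endpoint (ensemble MMPBSA) aggregation

The endpoint binding free energy is the difference
ΔG = G_com − G_pro − G_lig of component free energies averaged over MD
ensembles. Each per-frame G is, when decomposed, the sum of the
gas-phase molecular-mechanics energy, the polar solvation free energy
(from a Poisson–Boltzmann solve) and the nonpolar solvation free
energy (from solvent-accessible surface area); those solvers live
upstream — this package consumes their per-frame outputs. No
configurational-entropy term is added: an entropy hook exists in the
estimate structure but ships disabled, since entropic corrections
rarely change rankings and the protocols modeled here omit them.

Averaging order is per-frame ΔG → per-replica mean → ensemble mean.
For the 1-trajectory protocol (all components extracted from the
complex trajectory, frames matched one-to-one) this equals the
difference of component means, but it defines the per-replica values
the bootstrap needs. A 3-trajectory mode combines independent
component ensembles as a difference of means with SEs added in
quadrature.

The adaptation free energy — mean bound-state protein energy minus
mean free-state protein energy — measures binding-induced strain and
can be added to the endpoint estimate; the two ensembles are
independent so SEs combine in quadrature.

**Bootstrap.** The resampling unit is the replica, never the frame:
frames are autocorrelated while replicas differ only in initial
velocities and are exchangeable. The SE is the standard deviation of
1000 resampled means by default (seeded; stable to a couple of percent
on the tested cases). A single replica carries no spread information;
its SE is reported as 0 with a warning flag. Note the plug-in
bootstrap SE of a mean has expectation ≈ s·√(n−1)/n, so the expected
SE ratio between 10- and 25-replica ensembles of the same population
is (√9/10)/(√24/25) ≈ 1.53 rather than the naive √2.5 ≈ 1.58; the
200-seed simulation in `scripts/acceptance.py` measures ≈ 1.5.

## Thermodynamic integration

Each leg's free-energy change is ∫₀¹ ⟨∂V/∂λ⟩ dλ on a fixed 13-window
schedule dense near the endpoints (0.0, 0.05, 0.1, 0.2, …, 0.9, 0.95,
1.0). Quadrature is the trapezoidal rule on exactly those nodes — the
standard TI choice, exact for constant and linear integrands; no
attempt is made to interpolate between windows, so the quadrature bias
of a curved integrand is part of the estimator and is tested as such
(against an independent panel-sum oracle, and against numpy's
trapezoid). Integration is per replica with the bootstrap over
per-replica integrals; for a linear quadrature this gives the same
point estimate as integrating pooled window means, but yields the
replica-level distribution the bootstrap needs. Replicas missing from
some windows are dropped everywhere with a warning (error in strict
mode). ΔΔG = ΔG_complex − ΔG_aqueous with leg SEs combined in
quadrature (legs are separate simulations). Transformations between
compounds of different net charge are refused rather than corrected:
charge-changing alchemy needs finite-size/electrostatic corrections
that are out of scope.

## Experiment comparison

pIC50 → ΔG uses ΔG = −RT ln10 · pIC50 with R = 1.9872×10⁻³
kcal mol⁻¹ K⁻¹ and T = 300 K by default; pIC50 is −log₁₀ of a molar
IC50. Correlation CIs are percentile bootstrap over paired resampling
(default 10⁴ resamples, seeded); a Fisher-z interval is available
behind a flag but the bootstrap is the default precisely because the
surrounding analysis argues against normality assumptions. Degenerate
bootstrap resamples (a constant vector) carry no correlation
information and are skipped. The OLS slope of calc on exp is reported
descriptively only — with non-normal errors, regression-dilution
corrections do not apply. "Within k error bars" in the cross-platform
comparison means |diff| ≤ k·√(seA² + seB²), i.e. error bars are
combined, not per-platform. The per-compound outlier offset orients
every pairwise discrepancy so the named compound sits on the "to"
side, making the statistic invariant to how pairs were written down.
Censored records (potency only bounded by the highest tested
concentration) are excluded from fitted statistics by default and
listed in the report, since their true affinity is likely less
negative than the bound suggests.

## Distribution characterization

Skewness is the adjusted Fisher–Pearson standardized third moment and
excess kurtosis the bias-corrected fourth standardized moment minus 3
— the common defaults for replicate counts around 100–300; the choice
is isolated in one function should an uncorrected variant be wanted.
σ bins use the best-fit normal, i.e. sample mean and sd (denominator
n−1), with half-open bins [a, b) about the mean; the analytic normal
reference is (2.275, 13.591, 34.134, 34.134, 13.591, 2.275)%. The
histogram uses a fixed 0.05-pIC50-unit bin width aligned to integer
multiples of the width; the KDE is Gaussian with Silverman's
bandwidth. The drift test regresses value on measurement index and
computes a two-sided permutation p-value (10⁴ seeded shuffles) —
chosen over a t-test because the replicate distributions themselves
are the evidence against normality. When the optional dates are
absent, the measurement index is the time axis; drift is modeled as
linear because nothing stronger than "a small amount of time
dependency" is being emulated.

## Synthetic data

The generators define the study conditions for every test.

*Replica traces* are AR(1) series: frame t is
μ_r + φ(x_{t−1} − μ_r) + ε with stationary sd equal to `frame_sd`, and
the replica mean μ_r drawn as N(mean_g, replica_sd²). AR(1) is the
simplest stationary process reproducing the frame autocorrelation that
makes per-frame SEs optimistic — which is exactly the property the
replica-level bootstrap is designed around. Defaults (25 replicas,
200 frames, frame_sd 2 kcal/mol, replica_sd 0.5 kcal/mol, φ = 0.5)
emulate a production ensemble protocol of 25 (or 5 for TI) replicas of
a few ns each at the scale a test suite can afford. The model is a
stand-in: real MMPBSA frame energies are neither Gaussian nor exactly
AR(1), so passing tests show estimator correctness on exchangeable
replica data, not robustness to every pathology of real trajectories.

*∂V/∂λ curves* are polynomials with i.i.d. Gaussian window noise; the
analytic integral Σ cₖ/(k+1) is recorded as truth. Real TI gradients
have λ-dependent variance and within-window autocorrelation; tests
using these data check integration and error propagation, not sampling
adequacy.

*Assay replicates* are drawn by pushing a standard normal through a
monotone transform matched numerically to the requested skewness and
excess kurtosis (moments by 301-node Gauss–Hermite quadrature, shape
parameters by least squares), then rescaled to the requested mean and
sd. The sinh–arcsinh family is tried first; combinations it cannot
reach — it cannot, for instance, pair skewness 2.11 with excess
kurtosis as low as 5.30, a combination observed in real replicate
sets — fall back to the bounded Johnson SB family, so together the
two families cover the feasible moment plane down to the universal
bound excess kurtosis ≥ skewness² − 2, which is checked first and
reported when violated. Optional drift is linear in measurement index
and centered so the requested mean is preserved. Sample kurtosis is a
noisy statistic even at n = 10⁵ (sd up to ≈ 0.3 for the heavy-tailed
parameter sets), so recovery tests average sample moments over 20
seeds rather than asserting on a single draw.

*Compound sets* place true ΔG values on an even grid over a range
(default −12 to −6 kcal/mol, the span of a typical lead series) and
add independent Gaussian "experimental" (0.3 kcal/mol, the commonly
claimed assay uncertainty) and "calculated" (1 kcal/mol) noise, with
optional systematic offsets for an outlier compound or a charged
stratum.

## Problem sizes and numerical choices

Tests run ensembles of 25 replicas × 200 frames, TI legs of 5
replicas × 50 samples per window, assay sets of 10⁵ draws for moment
recovery and ~100–200 for table-style summaries, and 100-seed coverage
runs with 400–1000 bootstrap resamples — sizes chosen so the whole
suite completes in about a minute while keeping Monte-Carlo assertions
comfortably inside their tolerances. Oracle-equivalence checks use
1e-9 or tighter; exact identities (conversion round trips, trapezoid
on constant/linear integrands, noiseless cycle closure) use 1e-12.
Coverage-style assertions (CI covers truth in ≥ 90/100 seeds, ≥ 18/20
recoveries within 3 SE) are the deterministic-seed analogue of the
nominal rates, leaving room for the expected few misses.

## Known limitations

- The estimators assume exchangeable replicas; systematic inter-replica
  drift (e.g. incomplete equilibration) is not modeled or detected.
- No BAR/MBAR alternative to trapezoidal TI, and no charge corrections
  for net-charge-changing transformations (such pairs are refused).
- The I/O layer reads only the package's own TSV/CSV dialects; engine
  converters (NAMD, Amber) are a plausible extension, not core.
- The distribution stage is descriptive by design: it characterizes
  non-normality (moments, bins, tails) rather than running a battery
  of formal normality tests.
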