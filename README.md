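# ensemblefe

Ensemble binding free-energy analysis for structure-based drug design:
endpoint (MMPBSA-style) aggregation over replica MD ensembles,
relative free energies by thermodynamic integration, statistics for
comparing calculations with assay data, and characterization of the
non-normal distributions that repeated potency measurements exhibit.

## Who this is for

Computational chemists running ensemble free-energy protocols — many
independent replicas of the same system, differing only in initial
velocities — who need the *analysis* half of the workflow: turning
per-frame energies and per-λ gradients into binding free energies with
honest, bootstrap-based error bars, and confronting the results with
experimental potencies without assuming everything is Gaussian.

## The statistics at the core

**Endpoint estimate.** The binding free energy is
ΔG = G_com − G_pro − G_lig, each component averaged over frames of an
ensemble of replicas. In the 1-trajectory protocol all three component
energies come from the complex trajectory, so ΔG is formed per frame,
averaged per replica, then over replicas. Each G may decompose into a
gas-phase molecular-mechanics term plus polar (Poisson–Boltzmann) and
nonpolar (surface-area) solvation terms; configurational entropy is
not included. Uncertainty is the bootstrap standard error over
*replicas* — the independent unit of the protocol, since frames within
a replica are autocorrelated.

**Thermodynamic integration.** An alchemical transformation is run in
water and in the complex; each leg's free-energy change is
ΔG_alch = ∫₀¹ ⟨∂V/∂λ⟩_λ dλ, integrated by the trapezoidal rule over a
fixed 13-window schedule (0.0, 0.05, 0.1, 0.2, …, 0.9, 0.95, 1.0),
per replica, with a replica bootstrap SE. The relative binding free
energy is ΔΔG = ΔG_complex − ΔG_aqueous. Pairs whose endpoints differ
in net charge are refused (no charge corrections are applied).

**Experiment comparison.** pIC50 converts to ΔG_exp = −RT ln10 · pIC50
(R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹, T = 300 K, so one pIC50 unit is
1.373 kcal/mol). Agreement is summarized by Pearson/Spearman
coefficients with percentile-bootstrap 95% CIs, mean unsigned/signed
errors, cross-platform within-k-error-bars counts, and per-compound
systematic offsets recovered from pairwise ΔΔG discrepancies.
Censored measurements ("no activity at the highest concentration")
are excluded from fitted statistics and reported separately.

**Distribution characterization.** Repeated pIC50 measurements are
summarized by bias-corrected skewness and excess kurtosis, occupancy
of the six σ bins about the mean against the analytic normal
reference (2.3, 13.6, 34.1, 34.1, 13.6, 2.3 %), tail probabilities
beyond k·σ, a 0.05-unit histogram with Gaussian KDE, and a
permutation test for drift over measurement order.

Because real MD trajectories and raw assay replicates cannot ship with
a package, `ensemblefe.synthetic` generates every input with known
ground truth: AR(1) replica energy traces, polynomial ∂V/∂λ curves
with analytic integrals, and moment-matched skewed/heavy-tailed assay
replicates (sinh–arcsinh or Johnson SB transform of a normal).

## Worked example

```python
from ensemblefe import TraceSpec, gen_replica_traces, esmacs_estimate

spec = TraceSpec(
    mean_g={"complex": -100.0, "protein": -60.0, "ligand": -30.0},
    n_replicas=25, n_frames=200, frame_sd=2.0, replica_sd=0.5, seed=7,
)
data = gen_replica_traces(spec)
est = esmacs_estimate(data.ensembles["complex"], data.ensembles["protein"],
                      data.ensembles["ligand"], seed=7)
print(f"estimated dG : {est.value:+.3f} +/- {est.se:.3f} kcal/mol")
```

prints

```
estimated dG : -10.053 +/- 0.154 kcal/mol
```

i.e. the 25-replica ensemble recovers the constructed truth of
−10 kcal/mol well within one bootstrap standard error. The scripts in
`examples/` walk through each capability the same way (TI legs and ΔΔG
assembly, correlation/error reports with an injected 3.21 kcal/mol
outlier, σ-bin tables for heavy-tailed assay data); each prints the
numbers it computes and what they mean.

A thin CLI wraps the same functions:

```sh
ensemble-fe simulate --kind traces --out traces.tsv --seed 7
ensemble-fe esmacs --traces traces.tsv --n-boot 1000 --seed 42
ensemble-fe diststats --assay replicates.csv --bin-size 0.05
ensemble-fe run --config pipeline.yaml --out-dir reports
```

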