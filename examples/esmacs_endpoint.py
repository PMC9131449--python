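"""Ensemble endpoint (MMPBSA-style) binding free energy with bootstrap errors.

Generates a 25-replica synthetic ensemble whose true binding free
energy is known by construction (-10 kcal/mol), runs the 1-trajectory
endpoint estimator, and adds the protein adaptation term from a second
(free-state) protein ensemble.
"""

import numpy as np

from ensemblefe import (
    TraceSpec,
    adaptation_free_energy,
    esmacs_estimate,
    gen_replica_traces,
)

spec = TraceSpec(
    mean_g={"complex": -100.0, "protein": -60.0, "ligand": -30.0},
    n_replicas=25,
    n_frames=200,
    frame_sd=2.0,      # within-replica frame noise, kcal/mol
    replica_sd=0.5,    # spread of replica means, kcal/mol
    autocorr=0.5,      # AR(1) frame autocorrelation
    seed=7,
)
data = gen_replica_traces(spec)

est = esmacs_estimate(
    data.ensembles["complex"],
    data.ensembles["protein"],
    data.ensembles["ligand"],
    mode="one_trajectory",
    n_boot=1000,
    seed=7,
)
print(f"true dG        : {data.true_dg:+.3f} kcal/mol")
print(f"estimated dG   : {est.value:+.3f} +/- {est.se:.3f} kcal/mol "
      f"({est.n_replicas} replicas x {est.n_frames_per_replica} frames)")
print(f"|error| / SE   : {abs(est.value - data.true_dg) / est.se:.2f}")

# adaptation free energy: strain of the protein on binding, here built as
# a free-state ensemble shifted 1.5 kcal/mol below the bound state
free_spec = TraceSpec(mean_g={"protein": -61.5}, n_replicas=25, n_frames=200,
                      frame_sd=2.0, replica_sd=0.5, seed=8)
free = gen_replica_traces(free_spec, roles=["protein"])
adapt = adaptation_free_energy(data.ensembles["protein"], free.ensembles["protein"],
                               seed=7)
print(f"adaptation dG  : {adapt.value:+.3f} +/- {adapt.se:.3f} kcal/mol "
      "(bound minus free protein; positive = strain)")

# The estimate should recover the constructed truth within a few bootstrap
# standard errors; the adaptation term should sit near +1.5 kcal/mol.
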