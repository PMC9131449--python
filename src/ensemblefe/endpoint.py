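"""Ensemble endpoint (MMPBSA-style) binding free-energy aggregation.

The endpoint estimate of a binding free energy is

    ΔG = G_complex − G_protein − G_ligand,

where each component free energy is averaged over the frames of an
ensemble of replica MD simulations.  In the 1-trajectory protocol all
three component energies are extracted from the complex trajectory, so
frames match one-to-one across components and the difference can be
formed per frame.  Each component G may itself be the sum of a gas-phase
molecular-mechanics term, a polar (Poisson–Boltzmann) solvation term and
a nonpolar (surface-area) solvation term; configurational entropy is not
included.

Uncertainty is estimated by bootstrap resampling at the replica level:
replicas are independent draws of the ensemble protocol, whereas frames
within a replica are autocorrelated, so the replica is the exchangeable
unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "EnergyTrace",
    "FreeEnergyEstimate",
    "mmpbsa_frame_energy",
    "esmacs_estimate",
    "adaptation_free_energy",
    "bootstrap_se",
]

_ROLES = ("complex", "protein", "ligand")
_DECOMP_TOL = 1e-6


@dataclass
class EnergyTrace:
    """Per-frame free-energy series for one replica of one component.

    Parameters
    ----------
    replica_id : str
        Label of the replica the frames come from.
    role : {"complex", "protein", "ligand"}
        Which thermodynamic component the energies belong to.
    frames : array of float
        Per-frame total free energy G in kcal/mol.
    e_mm, g_polar, g_nonpolar : array of float, optional
        Decomposition of ``frames`` into gas-phase molecular mechanics,
        polar solvation and nonpolar solvation terms.  When given, the
        three must sum to ``frames`` within 1e-6 kcal/mol.
    """

    replica_id: str
    role: str
    frames: np.ndarray
    e_mm: np.ndarray | None = None
    g_polar: np.ndarray | None = None
    g_nonpolar: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 1 or self.frames.size == 0:
            raise ValueError("frames must be a non-empty 1-d series")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError(f"non-finite frame energy in replica {self.replica_id!r}")
        if self.role not in _ROLES:
            raise ValueError(f"role must be one of {_ROLES}, got {self.role!r}")
        parts = [self.e_mm, self.g_polar, self.g_nonpolar]
        present = [p is not None for p in parts]
        if any(present):
            if not all(present):
                raise ValueError("decomposition requires all of e_mm, g_polar, g_nonpolar")
            self.e_mm = np.asarray(self.e_mm, dtype=float)
            self.g_polar = np.asarray(self.g_polar, dtype=float)
            self.g_nonpolar = np.asarray(self.g_nonpolar, dtype=float)
            total = self.e_mm + self.g_polar + self.g_nonpolar
            if np.max(np.abs(total - self.frames)) > _DECOMP_TOL:
                raise ValueError(
                    "decomposed terms do not sum to the frame total within "
                    f"{_DECOMP_TOL} kcal/mol (replica {self.replica_id!r})"
                )

    @property
    def n_frames(self) -> int:
        return int(self.frames.size)


@dataclass
class FreeEnergyEstimate:
    """Point estimate of a (relative or absolute) free energy.

    ``value`` is always the mean of ``per_replica``; ``se`` comes from a
    replica bootstrap.  ``se_warning`` is set when the ensemble had a
    single replica and the SE is reported as 0 by convention.
    """

    value: float
    se: float
    per_replica: np.ndarray
    n_replicas: int
    n_frames_per_replica: int
    mode: str = "one_trajectory"
    adaptation_included: bool = False
    se_warning: bool = False

    def __post_init__(self) -> None:
        self.per_replica = np.asarray(self.per_replica, dtype=float)
        if self.se < 0:
            raise ValueError("se must be non-negative")
        if abs(self.value - float(np.mean(self.per_replica))) > 1e-9:
            raise ValueError("value must equal the mean of per_replica")


def mmpbsa_frame_energy(mm: float, polar_solv: float, nonpolar_solv: float) -> float:
    """Total endpoint free energy of one frame.

    The sum of the gas-phase molecular mechanics energy, the polar
    (Poisson–Boltzmann) solvation free energy and the nonpolar
    (surface-area) solvation free energy, all in kcal/mol.  No entropic
    term is added.
    """
    terms = np.asarray([mm, polar_solv, nonpolar_solv], dtype=float)
    if not np.all(np.isfinite(terms)):
        raise ValueError("all energy terms must be finite")
    return float(terms.sum())


def bootstrap_se(
    per_replica: Sequence[float],
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Bootstrap standard error of the mean of per-replica values.

    Resamples the replica values with replacement ``n_boot`` times and
    returns the standard deviation of the resampled means.  A single
    replica carries no spread information: the SE is reported as 0 and a
    warning is emitted.
    """
    values = np.asarray(per_replica, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise ValueError("per_replica must be a non-empty 1-d sequence")
    if values.size == 1:
        warnings.warn("single replica: bootstrap SE reported as 0", stacklevel=2)
        return 0.0
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    rng = np.random.default_rng(seed)
    n = values.size
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_means = values[idx].mean(axis=1)
    return float(np.std(boot_means, ddof=1))


def _replica_means(ens: Sequence[EnergyTrace]) -> tuple[list[str], np.ndarray]:
    if len(ens) == 0:
        raise ValueError("empty ensemble")
    ids = [t.replica_id for t in ens]
    means = np.array([t.frames.mean() for t in ens])
    return ids, means


def esmacs_estimate(
    complex_ens: Sequence[EnergyTrace],
    protein_ens: Sequence[EnergyTrace],
    ligand_ens: Sequence[EnergyTrace],
    mode: str = "one_trajectory",
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> FreeEnergyEstimate:
    """Ensemble endpoint binding free energy ΔG = G_com − G_pro − G_lig.

    In ``one_trajectory`` mode the three ensembles must share replica ids
    and frame counts (all components extracted from the complex
    trajectory); ΔG is formed per frame, averaged per replica, and the
    estimate is the replica mean with a replica-bootstrap SE.

    In ``three_trajectory`` mode the three component ensembles are
    independent; their means are combined and the SE adds the three
    replica-bootstrap SEs in quadrature.
    """
    if mode not in ("one_trajectory", "three_trajectory"):
        raise ValueError(f"unknown mode {mode!r}")
    for ens in (complex_ens, protein_ens, ligand_ens):
        if len(ens) == 0:
            raise ValueError("empty ensemble")

    if mode == "one_trajectory":
        com = {t.replica_id: t for t in complex_ens}
        pro = {t.replica_id: t for t in protein_ens}
        lig = {t.replica_id: t for t in ligand_ens}
        if set(com) != set(pro) or set(com) != set(lig):
            raise ValueError("one_trajectory mode requires matching replica ids")
        per_replica = []
        n_frames = None
        for rid in sorted(com):
            c, p, l = com[rid], pro[rid], lig[rid]
            if not (c.n_frames == p.n_frames == l.n_frames):
                raise ValueError(
                    f"one_trajectory mode requires matching frame counts (replica {rid!r})"
                )
            n_frames = c.n_frames
            dg_frames = c.frames - p.frames - l.frames
            per_replica.append(dg_frames.mean())
        per_replica = np.asarray(per_replica)
        if per_replica.size == 1:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                se = 0.0
            se_warn = True
        else:
            se = bootstrap_se(per_replica, n_boot=n_boot, seed=seed)
            se_warn = False
        return FreeEnergyEstimate(
            value=float(per_replica.mean()),
            se=se,
            per_replica=per_replica,
            n_replicas=per_replica.size,
            n_frames_per_replica=int(n_frames),
            mode=mode,
            se_warning=se_warn,
        )

    # three_trajectory: independent component means
    _, com_means = _replica_means(complex_ens)
    _, pro_means = _replica_means(protein_ens)
    _, lig_means = _replica_means(ligand_ens)
    rng = np.random.default_rng(seed)
    ses = []
    for means in (com_means, pro_means, lig_means):
        if means.size > 1:
            ses.append(bootstrap_se(means, n_boot=n_boot, seed=rng))
        else:
            ses.append(0.0)
    per_replica = com_means - pro_means.mean() - lig_means.mean()
    return FreeEnergyEstimate(
        value=float(per_replica.mean()),
        se=float(np.sqrt(sum(s**2 for s in ses))),
        per_replica=per_replica,
        n_replicas=com_means.size,
        n_frames_per_replica=complex_ens[0].n_frames,
        mode=mode,
        se_warning=any(m.size == 1 for m in (com_means, pro_means, lig_means)),
    )


def adaptation_free_energy(
    protein_bound_ens: Sequence[EnergyTrace],
    protein_free_ens: Sequence[EnergyTrace],
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> FreeEnergyEstimate:
    """Adaptation free energy: bound-state minus free-state protein energy.

    Measures the conformational strain the protein takes on upon
    binding.  The two ensembles are independent simulations, so the SE
    combines the two replica-bootstrap SEs in quadrature.
    """
    _, bound = _replica_means(protein_bound_ens)
    _, free = _replica_means(protein_free_ens)
    rng = np.random.default_rng(seed)
    se_b = bootstrap_se(bound, n_boot=n_boot, seed=rng) if bound.size > 1 else 0.0
    se_f = bootstrap_se(free, n_boot=n_boot, seed=rng) if free.size > 1 else 0.0
    per_replica = bound - free.mean()
    return FreeEnergyEstimate(
        value=float(per_replica.mean()),
        se=float(np.hypot(se_b, se_f)),
        per_replica=per_replica,
        n_replicas=bound.size,
        n_frames_per_replica=protein_bound_ens[0].n_frames,
        mode="adaptation",
        adaptation_included=True,
        se_warning=(bound.size == 1 or free.size == 1),
    )
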