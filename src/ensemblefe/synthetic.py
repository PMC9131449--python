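"""Synthetic data generators for every stage of the analysis.

Real inputs to this package are (i) per-frame endpoint energies from
replica MD simulations, (ii) per-λ ∂V/∂λ samples from alchemical legs,
and (iii) repeated assay pIC50 measurements.  None of these can ship
with the package, so each generator here produces data with the
statistical structure the downstream estimators assume, together with a
ground-truth record, making every stage testable end to end.

Replica energy traces are stationary AR(1) series around replica-level
means; frames within a replica are autocorrelated (which is why naive
per-frame standard errors are optimistic) while replicas are
independent.  ∂V/∂λ curves are polynomials in λ with known analytic
integrals plus i.i.d. noise.  Assay replicates are drawn from a
moment-matched transformed-normal family so that skewed, heavy-tailed
distributions with prescribed first four moments can be produced.

Every generator takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy.optimize import least_squares

from .alchemical import LambdaLeg, LambdaWindow
from .compare import CompoundRecord, dg_to_pic50
from .diststats import AssayReplicateSet
from .endpoint import EnergyTrace

__all__ = [
    "TraceSpec",
    "DvdlCurveSpec",
    "AssaySpec",
    "ReplicaTraceData",
    "TiLegData",
    "CompoundSetData",
    "gen_replica_traces",
    "gen_ti_samples",
    "gen_assay_replicates",
    "gen_compound_set",
]

DEFAULT_SEED = 2024

_ROLES = ("complex", "protein", "ligand")


# ---------------------------------------------------------------------------
# replica energy traces


@dataclass
class TraceSpec:
    """Parameters of a synthetic replica-ensemble energy trace.

    ``mean_g`` maps each component role to its true mean free energy
    (kcal/mol).  ``frame_sd`` is the stationary within-replica spread,
    ``replica_sd`` the spread of replica-level means about ``mean_g``,
    and ``autocorr`` the lag-1 autocorrelation of the AR(1) frame
    series.
    """

    mean_g: Mapping[str, float]
    n_replicas: int = 25
    n_frames: int = 200
    frame_sd: float = 2.0
    replica_sd: float = 0.5
    autocorr: float = 0.5
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_replicas < 1 or self.n_frames < 1:
            raise ValueError("n_replicas and n_frames must be at least 1")
        if self.frame_sd < 0 or self.replica_sd < 0:
            raise ValueError("frame_sd and replica_sd must be non-negative")
        if not (0.0 <= self.autocorr < 1.0):
            raise ValueError("autocorr must lie in [0, 1)")
        for role in self.mean_g:
            if role not in _ROLES:
                raise ValueError(f"unknown component role {role!r}")


@dataclass
class ReplicaTraceData:
    """Generated ensembles per role, with the truth that produced them."""

    ensembles: dict[str, list[EnergyTrace]]
    true_dg: float | None
    spec: TraceSpec


def _ar1_series(rng: np.random.Generator, n: int, mean: float, sd: float, phi: float) -> np.ndarray:
    if sd == 0:
        return np.full(n, mean)
    innov_sd = sd * math.sqrt(1.0 - phi**2)
    x = np.empty(n)
    x[0] = mean + sd * rng.standard_normal()  # stationary start
    shocks = innov_sd * rng.standard_normal(n - 1) if n > 1 else np.empty(0)
    for t in range(1, n):
        x[t] = mean + phi * (x[t - 1] - mean) + shocks[t - 1]
    return x


def gen_replica_traces(
    spec: TraceSpec,
    roles: Sequence[str] = _ROLES,
) -> ReplicaTraceData:
    """Generate replica-ensemble energy traces for the given roles.

    Each replica's frame series is a stationary AR(1) process around a
    replica-level mean drawn with spread ``replica_sd`` about the role's
    ``mean_g``.  Replica ids match across roles, so the output feeds the
    1-trajectory endpoint estimator directly.  When all three roles are
    generated, the implied true binding free energy
    mean_com − mean_pro − mean_lig is recorded as ``true_dg``.
    """
    for role in roles:
        if role not in spec.mean_g:
            raise ValueError(f"spec.mean_g has no entry for role {role!r}")
    rng = np.random.default_rng(spec.seed)
    ensembles: dict[str, list[EnergyTrace]] = {}
    for role in roles:
        traces = []
        for r in range(spec.n_replicas):
            mu_r = spec.mean_g[role] + spec.replica_sd * rng.standard_normal()
            frames = _ar1_series(rng, spec.n_frames, mu_r, spec.frame_sd, spec.autocorr)
            traces.append(EnergyTrace(replica_id=f"rep{r:02d}", role=role, frames=frames))
        ensembles[role] = traces
    true_dg = None
    if all(r in spec.mean_g for r in _ROLES):
        true_dg = spec.mean_g["complex"] - spec.mean_g["protein"] - spec.mean_g["ligand"]
    return ReplicaTraceData(ensembles=ensembles, true_dg=true_dg, spec=spec)


# ---------------------------------------------------------------------------
# thermodynamic-integration samples


@dataclass
class DvdlCurveSpec:
    """A polynomial true ⟨∂V/∂λ⟩(λ) with additive Gaussian noise.

    ``coefficients`` are in increasing powers of λ, so ``[0, 2]`` is the
    curve 2λ.  The analytic integral over [0, 1] is Σ cₖ/(k+1) and is
    recorded with the generated data as ground truth.
    """

    coefficients: Sequence[float]
    noise_sd: float = 0.5
    n_samples_per_window: int = 50
    n_replicas: int = 5
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        self.coefficients = [float(c) for c in self.coefficients]
        if not self.coefficients:
            raise ValueError("coefficients must be non-empty")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_samples_per_window < 1 or self.n_replicas < 1:
            raise ValueError("counts must be at least 1")

    @property
    def analytic_integral(self) -> float:
        return float(sum(c / (k + 1) for k, c in enumerate(self.coefficients)))

    def true_curve(self, lam: np.ndarray | float) -> np.ndarray | float:
        return npoly.polyval(lam, self.coefficients)


@dataclass
class TiLegData:
    """A generated alchemical leg and the truth behind it."""

    leg: LambdaLeg
    true_integral: float
    spec: DvdlCurveSpec


def gen_ti_samples(
    spec: DvdlCurveSpec,
    schedule: Sequence[float],
    leg: str = "complex",
    pair: tuple[str, str] | None = None,
) -> TiLegData:
    """Generate per-window ∂V/∂λ samples for one alchemical leg.

    Every sample at window λ is the true polynomial value there plus
    independent N(0, noise_sd²) noise.  The schedule must be strictly
    increasing within [0, 1] and contain both endpoints, otherwise the
    integral over [0, 1] is undefined.
    """
    sched = [float(s) for s in schedule]
    if sched != sorted(set(sched)):
        raise ValueError("schedule must be strictly increasing")
    if not sched or sched[0] != 0.0 or sched[-1] != 1.0:
        raise ValueError("schedule must include both endpoints 0 and 1")
    if any(not (0.0 <= s <= 1.0) for s in sched):
        raise ValueError("schedule values must lie in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    windows = []
    for lam in sched:
        truth = float(spec.true_curve(lam))
        samples = {
            f"rep{r:02d}": truth
            + spec.noise_sd * rng.standard_normal(spec.n_samples_per_window)
            for r in range(spec.n_replicas)
        }
        windows.append(LambdaWindow(lam=lam, samples=samples))
    return TiLegData(
        leg=LambdaLeg(leg=leg, windows=windows, pair=pair),
        true_integral=spec.analytic_integral,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# assay replicates: moment-matched transformed-normal family

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(301)
_GH_Z = math.sqrt(2.0) * _GH_NODES
_GH_W = _GH_WEIGHTS / math.sqrt(math.pi)


def _standardized_moments(x: np.ndarray) -> tuple[float, float, float, float]:
    """(mean, sd, skewness, excess kurtosis) of a transform of Z ~ N(0,1),
    evaluated by Gauss–Hermite quadrature on the transform values ``x``."""
    m1 = float(np.sum(_GH_W * x))
    m2 = float(np.sum(_GH_W * x**2))
    m3 = float(np.sum(_GH_W * x**3))
    m4 = float(np.sum(_GH_W * x**4))
    var = m2 - m1**2
    mu3 = m3 - 3 * m1 * m2 + 2 * m1**3
    mu4 = m4 - 4 * m1 * m3 + 6 * m1**2 * m2 - 3 * m1**4
    return m1, math.sqrt(var), mu3 / var**1.5, mu4 / var**2 - 3


def _sinh_arcsinh(z: np.ndarray, eps: float, delta: float) -> np.ndarray:
    return np.sinh((np.arcsinh(z) + eps) / delta)


def _johnson_sb(z: np.ndarray, gamma: float, delta: float) -> np.ndarray:
    from scipy.special import expit

    return expit((z - gamma) / delta)


def _solve_shape(skewness: float, excess_kurtosis: float):
    """Find a transform of a standard normal with the requested shape.

    Tries the sinh-arcsinh family first (unbounded, covers the
    heavy-tailed side of the moment plane) and falls back to the
    Johnson SB family (bounded, covers the remainder down to the
    universal feasibility boundary).  Returns ``(transform, params)``.
    """
    target = np.array([skewness, excess_kurtosis])

    def fit(transform, starts):
        def resid(p):
            a, logd = p
            _, _, s, k = _standardized_moments(transform(_GH_Z, a, math.exp(logd)))
            return [s - target[0], k - target[1]]

        best = None
        for a0, ld0 in starts:
            try:
                r = least_squares(resid, [a0, ld0], xtol=1e-14, ftol=1e-14, gtol=1e-14)
            except Exception:
                continue
            if best is None or r.cost < best.cost:
                best = r
        return best

    sas_starts = [(s, d) for s in (0.0, 0.3, -0.3, 0.8, -0.8) for d in (0.0, -0.4, 0.4)]
    r = fit(_sinh_arcsinh, sas_starts)
    if r is not None and np.max(np.abs(r.fun)) < 1e-8:
        return _sinh_arcsinh, (r.x[0], math.exp(r.x[1]))
    sb_starts = [(g, d) for g in (-2.0, -1.0, 0.0, 1.0, 2.0) for d in (-1.5, -0.8, -0.3, 0.2)]
    r = fit(_johnson_sb, sb_starts)
    if r is not None and np.max(np.abs(r.fun)) < 1e-8:
        return _johnson_sb, (r.x[0], math.exp(r.x[1]))
    raise ValueError(
        f"moment combination (skewness={skewness}, excess_kurtosis={excess_kurtosis}) "
        "is not attainable; any distribution requires "
        f"excess_kurtosis >= skewness^2 - 2 = {skewness**2 - 2:.4f}, and the "
        "transformed-normal families used here cover a slightly smaller region"
    )


@dataclass
class AssaySpec:
    """Target moments of a synthetic assay-replicate distribution.

    ``drift_per_index`` adds a linear trend over the measurement index,
    centered on the midpoint so the requested mean is preserved; the
    least-squares slope of value on index recovers it.
    """

    n: int
    mean: float
    sd: float
    skewness: float = 0.0
    excess_kurtosis: float = 0.0
    drift_per_index: float = 0.0
    seed: int = DEFAULT_SEED
    compound_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.excess_kurtosis < self.skewness**2 - 2:
            raise ValueError(
                f"infeasible moments: excess_kurtosis={self.excess_kurtosis} "
                f"< skewness^2 - 2 = {self.skewness**2 - 2:.4f}"
            )


def gen_assay_replicates(spec: AssaySpec) -> AssayReplicateSet:
    """Draw assay replicates with prescribed first four moments.

    A standard normal is pushed through a moment-matched monotone
    transform (sinh-arcsinh or Johnson SB), then rescaled to the
    requested mean and sd; the population skewness and excess kurtosis
    equal the requested values by construction.  Optional linear drift
    is then added over the measurement index.
    """
    if spec.skewness == 0.0 and spec.excess_kurtosis == 0.0:
        transform, params = (lambda z, *_: z), ()
        m1, s0 = 0.0, 1.0
    else:
        transform, params = _solve_shape(spec.skewness, spec.excess_kurtosis)
        m1, s0, _, _ = _standardized_moments(transform(_GH_Z, *params))
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal(spec.n)
    x = (np.asarray(transform(z, *params), dtype=float) - m1) / s0
    values = spec.mean + spec.sd * x
    if spec.drift_per_index != 0.0:
        idx = np.arange(spec.n, dtype=float)
        values = values + spec.drift_per_index * (idx - idx.mean())
    return AssayReplicateSet(compound_id=spec.compound_id, values=values)


# ---------------------------------------------------------------------------
# paired experimental / calculated compound sets


@dataclass
class CompoundSetData:
    """Paired per-compound truth, experimental and calculated values."""

    records: list[CompoundRecord]
    true_dg: dict[str, float]
    dg_exp: dict[str, float]
    dg_calc: dict[str, float]
    outlier_id: str | None = None
    outlier_offset: float = 0.0


def gen_compound_set(
    n_compounds: int,
    dg_range: tuple[float, float] = (-12.0, -6.0),
    exp_noise_sd: float = 0.3,
    calc_noise_sd: float = 1.0,
    outlier: tuple[int, float] | None = None,
    charged_fraction: float = 0.0,
    charged_offset: float = 0.0,
    seed: int = DEFAULT_SEED,
) -> CompoundSetData:
    """Generate paired experimental/calculated binding free energies.

    True ΔG values are spread evenly over ``dg_range``; the
    "experimental" and "calculated" values add independent Gaussian
    noise to the truth.  ``outlier=(index, offset)`` adds a systematic
    offset to one compound's calculated value, emulating a compound
    whose calculations disagree with the assay by a fixed amount.  A
    fraction of compounds can be flagged as net-charge +1 with an extra
    (favorable) contribution ``charged_offset`` added to their true ΔG.
    """
    if n_compounds < 3:
        raise ValueError("need at least 3 compounds")
    rng = np.random.default_rng(seed)
    ids = [f"S{i + 1:02d}" for i in range(n_compounds)]
    truths = np.linspace(dg_range[0], dg_range[1], n_compounds)
    rng.shuffle(truths)
    n_charged = int(round(charged_fraction * n_compounds))
    charged = np.zeros(n_compounds, dtype=bool)
    charged[rng.choice(n_compounds, size=n_charged, replace=False)] = True
    truths = truths + np.where(charged, charged_offset, 0.0)
    exp_vals = truths + exp_noise_sd * rng.standard_normal(n_compounds)
    calc_vals = truths + calc_noise_sd * rng.standard_normal(n_compounds)
    outlier_id, offset = None, 0.0
    if outlier is not None:
        oi, offset = outlier
        if not (0 <= oi < n_compounds):
            raise ValueError("outlier index out of range")
        calc_vals[oi] += offset
        outlier_id = ids[oi]
    records = [
        CompoundRecord(
            compound_id=cid,
            pIC50=dg_to_pic50(dg),
            net_charge=1 if ch else 0,
        )
        for cid, dg, ch in zip(ids, exp_vals, charged)
    ]
    return CompoundSetData(
        records=records,
        true_dg=dict(zip(ids, truths)),
        dg_exp=dict(zip(ids, exp_vals)),
        dg_calc=dict(zip(ids, calc_vals)),
        outlier_id=outlier_id,
        outlier_offset=float(offset),
    )
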