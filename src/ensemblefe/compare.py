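"""Calculation-versus-experiment comparison statistics.

Experimental potencies arrive as pIC50 = −log₁₀(IC50 in mol/L) and are
converted to free energies through ΔG = RT·ln(IC50) = −RT·ln10·pIC50.
Agreement between calculated and experimental free energies is
quantified with rank and linear correlations (bootstrap 95% CIs), mean
unsigned/signed errors, cross-platform reproducibility counts, and
per-compound systematic offsets inferred from relative estimates.

Censored measurements ("no activity at the highest tested
concentration") bound rather than measure the potency; they are
excluded from fitted statistics by default and listed in the report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GAS_CONSTANT_KCAL",
    "CompoundRecord",
    "ComparisonReport",
    "pic50_to_dg",
    "dg_to_pic50",
    "correlation_with_ci",
    "error_metrics",
    "outlier_offset",
    "cross_platform_agreement",
    "stratify_by_charge",
    "compare_to_experiment",
]

#: Gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 1.9872e-3

#: Assay temperature used for pIC50 -> free energy conversion.
DEFAULT_TEMPERATURE_K = 300.0


@dataclass
class CompoundRecord:
    """One compound: identity, potency, net charge, censoring status."""

    compound_id: str
    pIC50: float
    net_charge: int = 0
    censored: bool = False
    dg_exp: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.pIC50):
            raise ValueError(f"non-finite pIC50 for {self.compound_id!r}")
        derived = pic50_to_dg(self.pIC50)
        if self.dg_exp is None:
            self.dg_exp = derived
        elif abs(self.dg_exp - derived) > 1e-6:
            raise ValueError(
                f"dg_exp inconsistent with pIC50 for {self.compound_id!r}: "
                f"{self.dg_exp} vs {derived}"
            )


def pic50_to_dg(pic50: float, temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
    """Convert pIC50 to a binding free energy in kcal/mol.

    ΔG = −R·T·ln(10)·pIC50 with R = 1.9872e-3 kcal/(mol·K).  At the
    default 300 K one pIC50 unit corresponds to 1.3727 kcal/mol.
    """
    if temperature_k <= 0:
        raise ValueError("temperature must be positive")
    if not np.all(np.isfinite(np.asarray(pic50, dtype=float))):
        raise ValueError("pIC50 must be finite")
    return -GAS_CONSTANT_KCAL * temperature_k * math.log(10) * pic50


def dg_to_pic50(dg: float, temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
    """Inverse of :func:`pic50_to_dg`."""
    if temperature_k <= 0:
        raise ValueError("temperature must be positive")
    return -dg / (GAS_CONSTANT_KCAL * temperature_k * math.log(10))


class CorrelationResult(NamedTuple):
    coefficient: float
    ci_low: float
    ci_high: float
    method: str


def correlation_with_ci(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "pearson",
    n_boot: int = 10_000,
    seed: int | np.random.Generator = 0,
    ci_level: float = 0.95,
    use_fisher_z: bool = False,
) -> CorrelationResult:
    """Correlation coefficient with a 95% confidence interval.

    The point estimate is Pearson's r or Spearman's ρ; the CI is a
    percentile bootstrap over paired resampling, which avoids the
    normality assumption.  ``use_fisher_z`` switches to the parametric
    Fisher-z interval instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d sequences")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 pairs for a correlation with CI")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    if method == "pearson":
        stat = lambda a, b: stats.pearsonr(a, b).statistic
    elif method == "spearman":
        stat = lambda a, b: stats.spearmanr(a, b).statistic
    else:
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    r = float(stat(x, y))

    if use_fisher_z:
        z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
        half = stats.norm.ppf(0.5 + ci_level / 2) / math.sqrt(n - 3)
        lo, hi = np.tanh(z - half), np.tanh(z + half)
        return CorrelationResult(r, float(lo), float(hi), method)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    count = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        xb, yb = x[idx], y[idx]
        if np.ptp(xb) == 0 or np.ptp(yb) == 0:
            continue  # degenerate resample carries no correlation information
        boots[count] = stat(xb, yb)
        count += 1
    boots = boots[:count]
    alpha = 1 - ci_level
    lo, hi = np.nanpercentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return CorrelationResult(r, float(lo), float(hi), method)


def error_metrics(exp: Sequence[float], calc: Sequence[float]) -> tuple[float, float]:
    """Mean unsigned and mean signed error of calc relative to exp.

    Returns ``(mue, mse)`` where mue = mean|calc − exp| and
    mse = mean(calc − exp), both in the input units (kcal/mol here).
    """
    exp = np.asarray(exp, dtype=float)
    calc = np.asarray(calc, dtype=float)
    if exp.shape != calc.shape or exp.ndim != 1 or exp.size == 0:
        raise ValueError("exp and calc must be equal-length non-empty sequences")
    diff = calc - exp
    return float(np.mean(np.abs(diff))), float(np.mean(diff))


def outlier_offset(
    compound_id: str,
    pair_results: Iterable[tuple[tuple[str, str], float, float]],
) -> float:
    """Average oriented calculation-minus-experiment discrepancy for one compound.

    Each entry is ``((from_id, to_id), ddg_calc, ddg_exp)``.  The
    discrepancy ddg_calc − ddg_exp is oriented so the named compound sits
    on the "to" side of its pairs (a pair where it is the "from" compound
    contributes with flipped sign); the mean over all involving pairs is
    the systematic offset a consistent outlier would show.
    """
    oriented = []
    for (frm, to), ddg_calc, ddg_exp in pair_results:
        d = ddg_calc - ddg_exp
        if to == compound_id:
            oriented.append(d)
        elif frm == compound_id:
            oriented.append(-d)
    if not oriented:
        raise ValueError(f"compound {compound_id!r} appears in no pair")
    return float(np.mean(oriented))


class PlatformAgreement(NamedTuple):
    mean_signed_diff: float
    mean_unsigned_diff: float
    frac_within_1se: float
    frac_within_2se: float
    n: int


def cross_platform_agreement(
    set_a: Mapping[str, tuple[float, float]],
    set_b: Mapping[str, tuple[float, float]],
) -> PlatformAgreement:
    """Agreement between two independent sets of estimates.

    Both arguments map compound id to ``(value, se)``.  Differences are
    B − A; "within k error bars" means |diff| ≤ k·√(seA²+seB²).
    """
    if set(set_a) != set(set_b):
        raise ValueError("the two sets must cover the same compound ids")
    ids = sorted(set_a)
    diffs = np.array([set_b[i][0] - set_a[i][0] for i in ids])
    comb = np.array([math.hypot(set_a[i][1], set_b[i][1]) for i in ids])
    within1 = np.abs(diffs) <= comb
    within2 = np.abs(diffs) <= 2 * comb
    return PlatformAgreement(
        mean_signed_diff=float(diffs.mean()),
        mean_unsigned_diff=float(np.abs(diffs).mean()),
        frac_within_1se=float(within1.mean()),
        frac_within_2se=float(within2.mean()),
        n=len(ids),
    )


@dataclass
class ChargeStratumSummary:
    net_charges: tuple[int, ...]
    n: int
    mean_calc: float
    mean_exp: float
    sd_calc: float


def stratify_by_charge(
    records: Sequence[CompoundRecord],
    estimates: Mapping[str, float],
) -> tuple[dict[str, ChargeStratumSummary], bool | None]:
    """Group compounds into charged vs neutral and compare group means.

    Returns per-stratum summaries and a flag that is True when the
    charged group's mean calculated ΔG is lower (more favorable) than
    the neutral group's — the sanity check that calculations reproduce
    the extra electrostatic stabilization of charged binders.  The flag
    is None when either stratum is empty.
    """
    strata: dict[str, list[CompoundRecord]] = {"charged": [], "neutral": []}
    for rec in records:
        strata["charged" if rec.net_charge != 0 else "neutral"].append(rec)
    summaries: dict[str, ChargeStratumSummary] = {}
    for name, recs in strata.items():
        recs = [r for r in recs if r.compound_id in estimates]
        if not recs:
            continue
        calc = np.array([estimates[r.compound_id] for r in recs])
        summaries[name] = ChargeStratumSummary(
            net_charges=tuple(sorted({r.net_charge for r in recs})),
            n=len(recs),
            mean_calc=float(calc.mean()),
            mean_exp=float(np.mean([r.dg_exp for r in recs])),
            sd_calc=float(calc.std(ddof=1)) if len(recs) > 1 else 0.0,
        )
    if "charged" in summaries and "neutral" in summaries:
        flag = summaries["charged"].mean_calc < summaries["neutral"].mean_calc
    else:
        flag = None
    return summaries, flag


@dataclass
class ComparisonReport:
    """Full agreement report between calculated and experimental ΔG."""

    pearson: CorrelationResult
    spearman: CorrelationResult
    mue: float
    mse: float
    n_pairs: int
    slope: float
    intercept: float
    excluded_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for res in (self.pearson, self.spearman):
            if not (-1 - 1e-12 <= res.coefficient <= 1 + 1e-12):
                raise ValueError("correlation coefficient outside [-1, 1]")
            if not (res.ci_low - 1e-9 <= res.coefficient <= res.ci_high + 1e-9):
                raise ValueError("CI bounds must bracket the point estimate")


def compare_to_experiment(
    records: Sequence[CompoundRecord],
    estimates: Mapping[str, float],
    n_boot: int = 10_000,
    seed: int | np.random.Generator = 0,
    include_censored: bool = False,
) -> ComparisonReport:
    """Build the full calculated-vs-experimental comparison report.

    Censored compounds are excluded from all fitted statistics unless
    ``include_censored`` is set; their ids appear in ``excluded_ids``.
    The regression line is ordinary least squares of calc on exp.  Note
    that with non-normal errors regression-dilution corrections do not
    apply, so the slope is descriptive only.
    """
    used, excluded = [], []
    for rec in records:
        if rec.compound_id not in estimates:
            continue
        if rec.censored and not include_censored:
            excluded.append(rec.compound_id)
        else:
            used.append(rec)
    if len(used) < 4:
        raise ValueError("need at least 4 uncensored matched compounds")
    exp = np.array([r.dg_exp for r in used])
    calc = np.array([estimates[r.compound_id] for r in used])
    rng = np.random.default_rng(seed)
    pearson = correlation_with_ci(exp, calc, "pearson", n_boot=n_boot, seed=rng)
    spearman = correlation_with_ci(exp, calc, "spearman", n_boot=n_boot, seed=rng)
    mue, mse = error_metrics(exp, calc)
    slope, intercept = np.polyfit(exp, calc, 1)
    return ComparisonReport(
        pearson=pearson,
        spearman=spearman,
        mue=mue,
        mse=mse,
        n_pairs=len(used),
        slope=float(slope),
        intercept=float(intercept),
        excluded_ids=excluded,
    )
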