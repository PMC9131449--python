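"""Readers and writers for the package's tabular dialects.

Three plain-text formats carry all inputs, keeping the analysis
engine-agnostic (any MD engine's output can be converted to them):

* energy traces (TSV): system_id, replica_id, frame, role, e_mm,
  g_polar, g_nonpolar, g_total — per-frame endpoint energy components
  in kcal/mol; the components must sum to g_total.
* ∂V/∂λ samples (TSV): pair_id, leg, replica_id, lambda, sample_index,
  dvdl — alchemical-leg samples in kcal/mol.
* assay replicates (CSV): compound_id, pIC50[, date] — repeated
  measurements; and compound tables (CSV): compound_id, pIC50_mean,
  net_charge, censored.

Headers are required; lines starting with '#' are comments.  Malformed
content is reported with the offending line number.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .alchemical import LambdaLeg, LambdaWindow
from .compare import CompoundRecord
from .diststats import AssayReplicateSet
from .endpoint import EnergyTrace

__all__ = [
    "read_energy_traces",
    "write_energy_traces",
    "read_dvdl",
    "write_dvdl",
    "read_assay_replicates",
    "write_assay_replicates",
    "read_compound_table",
    "write_compound_table",
]

_TRACE_COLS = ["system_id", "replica_id", "frame", "role", "e_mm", "g_polar", "g_nonpolar", "g_total"]
_DVDL_COLS = ["pair_id", "leg", "replica_id", "lambda", "sample_index", "dvdl"]
_DECOMP_TOL = 1e-6


def _read_table(path: str | Path, sep: str, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def _line_numbers(path: Path, sep: str) -> pd.Series:
    """Map dataframe row position to 1-based file line number."""
    lines = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.strip() and not line.lstrip().startswith("#"):
                lines.append(i)
    return pd.Series(lines[1:])  # drop the header line


# ---------------------------------------------------------------------------
# energy traces


def read_energy_traces(
    path: str | Path, strict: bool = True
) -> dict[str, dict[str, list[EnergyTrace]]]:
    """Read an energy-trace TSV, grouped by system id and role.

    Validates the component-sum invariant (g_total = e_mm + g_polar +
    g_nonpolar within 1e-6 kcal/mol) and the uniqueness of
    (replica_id, frame, role) per system, naming the offending line on
    failure.  In strict mode, unequal frame counts across replicas of
    one system/role are an error.
    """
    path = Path(path)
    df = _read_table(path, "\t", _TRACE_COLS)
    lineno = _line_numbers(path, "\t")
    for col in ("e_mm", "g_polar", "g_nonpolar", "g_total"):
        bad = ~np.isfinite(pd.to_numeric(df[col], errors="coerce"))
        if bad.any():
            raise ValueError(
                f"{path}: non-numeric {col} at line {int(lineno.iloc[bad.idxmax()])}"
            )
    resid = (df["e_mm"] + df["g_polar"] + df["g_nonpolar"] - df["g_total"]).abs()
    if (resid > _DECOMP_TOL).any():
        i = int(resid.idxmax())
        raise ValueError(
            f"{path}: g_total does not equal e_mm+g_polar+g_nonpolar at line "
            f"{int(lineno.iloc[i])} (residual {resid.iloc[i]:.3g} kcal/mol)"
        )
    dup = df.duplicated(subset=["system_id", "replica_id", "frame", "role"])
    if dup.any():
        raise ValueError(
            f"{path}: duplicate (replica_id, frame, role) at line "
            f"{int(lineno.iloc[int(dup.idxmax())])}"
        )
    out: dict[str, dict[str, list[EnergyTrace]]] = {}
    for (system, role), grp in df.groupby(["system_id", "role"], sort=True):
        counts = set()
        traces = []
        for rid, rep in grp.sort_values("frame").groupby("replica_id", sort=True):
            counts.add(len(rep))
            traces.append(
                EnergyTrace(
                    replica_id=str(rid),
                    role=str(role),
                    frames=rep["g_total"].to_numpy(float),
                    e_mm=rep["e_mm"].to_numpy(float),
                    g_polar=rep["g_polar"].to_numpy(float),
                    g_nonpolar=rep["g_nonpolar"].to_numpy(float),
                )
            )
        if strict and len(counts) > 1:
            raise ValueError(
                f"{path}: inconsistent frame counts {sorted(counts)} for "
                f"system {system!r} role {role!r}"
            )
        out.setdefault(str(system), {})[str(role)] = traces
    return out


def write_energy_traces(
    path: str | Path,
    ensembles: dict[str, list[EnergyTrace]],
    system_id: str = "system",
    component_fractions: tuple[float, float, float] = (0.7, 0.2, 0.1),
) -> None:
    """Write role-keyed ensembles to the energy-trace TSV dialect.

    Traces without an explicit decomposition are split into components
    by the fixed ``component_fractions`` (which sum to the total by
    construction).
    """
    rows = []
    for role, traces in ensembles.items():
        for t in traces:
            if t.e_mm is not None:
                e_mm, g_pol, g_np = t.e_mm, t.g_polar, t.g_nonpolar
            else:
                f1, f2, f3 = component_fractions
                e_mm, g_pol = f1 * t.frames, f2 * t.frames
                g_np = t.frames - e_mm - g_pol
            for i, (g, a, b, c) in enumerate(zip(t.frames, e_mm, g_pol, g_np)):
                rows.append((system_id, t.replica_id, i, role, a, b, c, g))
    df = pd.DataFrame(rows, columns=_TRACE_COLS)
    with open(path, "w") as fh:
        fh.write("# ensemblefe energy-trace table; energies in kcal/mol\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# dV/dlambda tables


def read_dvdl(path: str | Path, strict: bool = True) -> dict[str, dict[str, LambdaLeg]]:
    """Read a ∂V/∂λ TSV into legs grouped by pair id and leg name.

    λ values outside [0, 1] are rejected.  In strict mode the λ schedule
    must be identical across replicas of a leg.
    """
    path = Path(path)
    df = _read_table(path, "\t", _DVDL_COLS)
    lineno = _line_numbers(path, "\t")
    lam = pd.to_numeric(df["lambda"], errors="coerce")
    bad = ~((lam >= 0) & (lam <= 1))
    if bad.any():
        raise ValueError(
            f"{path}: lambda outside [0, 1] at line {int(lineno.iloc[int(bad.idxmax())])}"
        )
    out: dict[str, dict[str, LambdaLeg]] = {}
    for (pair_id, leg_name), grp in df.groupby(["pair_id", "leg"], sort=True):
        if strict:
            schedules = {
                rid: tuple(sorted(rep["lambda"].unique()))
                for rid, rep in grp.groupby("replica_id")
            }
            if len(set(schedules.values())) > 1:
                raise ValueError(
                    f"{path}: lambda schedule differs across replicas of "
                    f"pair {pair_id!r} leg {leg_name!r}"
                )
        windows = []
        for lam_val, wgrp in grp.groupby("lambda", sort=True):
            samples = {
                str(rid): rep.sort_values("sample_index")["dvdl"].to_numpy(float)
                for rid, rep in wgrp.groupby("replica_id", sort=True)
            }
            windows.append(LambdaWindow(lam=float(lam_val), samples=samples))
        pair = tuple(str(pair_id).split("->")) if "->" in str(pair_id) else None
        out.setdefault(str(pair_id), {})[str(leg_name)] = LambdaLeg(
            leg=str(leg_name), windows=windows, pair=pair if pair and len(pair) == 2 else None
        )
    return out


def write_dvdl(path: str | Path, legs: dict[str, LambdaLeg] | Sequence[LambdaLeg],
               pair_id: str | None = None) -> None:
    """Write legs to the ∂V/∂λ TSV dialect.

    ``legs`` is either a mapping of leg name to :class:`LambdaLeg` or a
    sequence of legs; the pair id defaults to "from->to" built from the
    leg's own pair label.
    """
    if isinstance(legs, dict):
        leg_list = list(legs.values())
    else:
        leg_list = list(legs)
    rows = []
    for leg in leg_list:
        pid = pair_id or ("->".join(leg.pair) if leg.pair else "pair")
        for w in leg.windows:
            for rid in sorted(w.samples):
                for i, v in enumerate(w.samples[rid]):
                    rows.append((pid, leg.leg, rid, w.lam, i, v))
    df = pd.DataFrame(rows, columns=_DVDL_COLS)
    with open(path, "w") as fh:
        fh.write("# ensemblefe dV/dlambda table; energies in kcal/mol\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# assay and compound tables


def read_assay_replicates(path: str | Path) -> dict[str, AssayReplicateSet]:
    """Read an assay-replicate CSV into per-compound replicate sets."""
    df = _read_table(path, ",", ["compound_id", "pIC50"])
    out = {}
    for cid, grp in df.groupby("compound_id", sort=True):
        ts = grp["date"].astype(str).tolist() if "date" in df.columns else None
        out[str(cid)] = AssayReplicateSet(
            compound_id=str(cid), values=grp["pIC50"].to_numpy(float), timestamps=ts
        )
    return out


def write_assay_replicates(path: str | Path, sets: Sequence[AssayReplicateSet]) -> None:
    rows = []
    for s in sets:
        for i, v in enumerate(s.values):
            date = s.timestamps[i] if s.timestamps else None
            rows.append((s.compound_id, v, date) if date else (s.compound_id, v))
    has_date = any(len(r) == 3 for r in rows)
    cols = ["compound_id", "pIC50"] + (["date"] if has_date else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format="%.17g")


def read_compound_table(path: str | Path) -> list[CompoundRecord]:
    """Read a compound CSV into :class:`CompoundRecord` objects."""
    df = _read_table(path, ",", ["compound_id", "pIC50_mean"])
    records = []
    for _, row in df.iterrows():
        records.append(
            CompoundRecord(
                compound_id=str(row["compound_id"]),
                pIC50=float(row["pIC50_mean"]),
                net_charge=int(row.get("net_charge", 0) or 0),
                censored=bool(int(row.get("censored", 0) or 0)),
            )
        )
    return records


def write_compound_table(path: str | Path, records: Sequence[CompoundRecord]) -> None:
    df = pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in records],
            "pIC50_mean": [r.pIC50 for r in records],
            "net_charge": [r.net_charge for r in records],
            "censored": [int(r.censored) for r in records],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")
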