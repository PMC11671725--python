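"""CSV/TOML/JSON input-output and schema validation.

Canonical machine output is JSON; CSVs mirror the same tables for
spreadsheets. Internal units are always fractions and permil; SPC and
R_N2O may be given as percentages in input files via a ``unit`` column
("percent"/"%"), and reports print percentages with one decimal.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
import warnings
from dataclasses import asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import SchemaError
from .gas_flux import FluxSummary, HeadspaceSample, IncubationSetup
from .iso_core import PROCESS_ORDER, Process, ProcessSignature, SourceLibrary
from .partition_ls import EmittedMeasurement, MonteCarloRun
from .partition_bayes import PosteriorRun

logger = logging.getLogger(__name__)

_SOURCE_COLUMNS = ["process", "sp_mean", "sp_sd", "o18_mean", "o18_sd"]
_MEASUREMENT_COLUMNS = [
    "sp_mean", "sp_sd", "o18_mean", "o18_sd",
    "spc_mean", "spc_sd", "r_mean", "r_sd",
]
_HEADSPACE_COLUMNS = ["replicate", "time_h", "n2o_ppm", "r29", "r30", "r45", "r46"]

DEFAULT_EPS = dict(eps_sp_mean=-5.0, eps_sp_sd=1.35, eps_o_mean=-15.0, eps_o_sd=5.0)


def default_sources_path():
    """Path-like handle to the shipped source-signature table."""
    return resources.files("n2opart").joinpath("data/sources_default.csv")


def read_sources(path: str | Path | None = None, **eps) -> SourceLibrary:
    """Load a source library from CSV (shipped literature table if None).

    Required columns: process, sp_mean, sp_sd, o18_mean, o18_sd. Unknown
    extra columns are ignored with a warning. Reduction isotope effects are
    taken from keyword overrides (eps_sp_mean, ...) falling back to the
    shipped values.
    """
    if path is None:
        with resources.as_file(default_sources_path()) as p:
            df = pd.read_csv(p, float_precision="round_trip")
    else:
        df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _SOURCE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"sources table missing columns {missing}")
    extra = [c for c in df.columns if c not in _SOURCE_COLUMNS]
    if extra:
        warnings.warn(f"ignoring unknown sources columns {extra}", UserWarning)
    if df["process"].duplicated().any():
        raise SchemaError("duplicate process rows in sources table")
    params = {**DEFAULT_EPS, **{k: v for k, v in eps.items() if v is not None}}
    try:
        signatures = tuple(
            ProcessSignature(
                Process(row.process),
                float(row.sp_mean), float(row.sp_sd),
                float(row.o18_mean), float(row.o18_sd),
            )
            for row in df.itertuples()
        )
        return SourceLibrary(signatures=signatures, **params)
    except ValueError as err:  # covers bad process names, SDs, missing rows
        raise SchemaError(f"bad sources table: {err}") from err


def write_sources(library: SourceLibrary, path: str | Path) -> None:
    pd.DataFrame(
        [
            dict(process=s.process.value, sp_mean=s.sp_mean, sp_sd=s.sp_sd,
                 o18_mean=s.o18_mean, o18_sd=s.o18_sd)
            for s in library.signatures
        ]
    ).to_csv(path, index=False, float_format="%.17g")


def _ratio_scale(unit: str) -> float:
    if unit in ("fraction", ""):
        return 1.0
    if unit in ("percent", "%"):
        return 0.01
    raise SchemaError(f"unknown ratio unit {unit!r}; use 'fraction' or 'percent'")


def read_measurement(path: str | Path) -> EmittedMeasurement:
    """Load the one-row emitted-N2O measurement table.

    SPC and R_N2O are fractions by default; add a ``unit`` column with
    ``percent`` (or ``%``) to give them as percentages.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"measurement table missing columns {missing}")
    if len(df) != 1:
        raise SchemaError(f"measurement table must have exactly 1 row, got {len(df)}")
    row = df.iloc[0]
    scale = _ratio_scale(str(row.get("unit", "fraction")).strip())
    try:
        return EmittedMeasurement(
            sp_mean=float(row.sp_mean), sp_sd=float(row.sp_sd),
            o18_mean=float(row.o18_mean), o18_sd=float(row.o18_sd),
            spc_mean=float(row.spc_mean) * scale, spc_sd=float(row.spc_sd) * scale,
            r_mean=float(row.r_mean) * scale, r_sd=float(row.r_sd) * scale,
        )
    except ValueError as err:
        raise SchemaError(f"bad measurement table: {err}") from err


def write_measurement(m: EmittedMeasurement, path: str | Path) -> None:
    pd.DataFrame([asdict(m)]).to_csv(path, index=False, float_format="%.17g")


def read_headspace(path: str | Path) -> list[HeadspaceSample]:
    """Load a raw headspace time series (one row per replicate x time)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _HEADSPACE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"headspace table missing columns {missing}")
    has_dilution = "cumulative_dilution" in df.columns
    try:
        return [
            HeadspaceSample(
                replicate=str(row.replicate),
                time=float(row.time_h),
                n2o_conc=float(row.n2o_ppm),
                r29=float(row.r29), r30=float(row.r30),
                r45=float(row.r45), r46=float(row.r46),
                cumulative_dilution=(
                    float(row.cumulative_dilution) if has_dilution else 1.0
                ),
            )
            for row in df.itertuples()
        ]
    except ValueError as err:
        raise SchemaError(f"bad headspace table: {err}") from err


def write_headspace(samples: list[HeadspaceSample], path: str | Path) -> None:
    pd.DataFrame(
        [
            dict(replicate=s.replicate, time_h=s.time, n2o_ppm=s.n2o_conc,
                 r29=s.r29, r30=s.r30, r45=s.r45, r46=s.r46,
                 cumulative_dilution=s.cumulative_dilution)
            for s in samples
        ]
    ).to_csv(path, index=False, float_format="%.17g")


def read_setup(path: str | Path) -> IncubationSetup:
    """Incubation setup from the ``[setup]`` table of a TOML config."""
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    return IncubationSetup(**cfg.get("setup", {}))


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serializable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _provenance(seed, extra=None) -> dict:
    prov = {"package": "n2opart", "version": __version__, "seed": seed}
    if extra:
        prov["config_hash"] = config_hash(extra)
    return prov


def flux_summary_to_dict(fs: FluxSummary) -> dict:
    return asdict(fs)


def run_to_dict(run: MonteCarloRun) -> dict:
    """JSON payload for a constrained Monte Carlo run (percent scale)."""
    return {
        **_provenance(run.seed),
        "method": "monte_carlo_ls",
        "scenario": run.scenario.value,
        "n_draws": run.n_draws,
        "acceptance_count": run.acceptance_count,
        "acceptance_rate": run.acceptance_rate,
        "fractions_percent": {
            col: {"mean": 100 * run.summary.loc["mean", col],
                  "sd": 100 * run.summary.loc["sd", col]}
            for col in run.summary.columns
        },
        "mean_spc_accepted": float(np.mean(run.accepted_spc)),
        "r_check": run.r_check,
        "rejection_diagnostics": run.rejection_diagnostics,
    }


def posterior_to_dict(run: PosteriorRun) -> dict:
    """JSON payload for an MCMC run (percent scale for fractions and r)."""
    seed = run.config.seed if run.config else None
    return {
        **_provenance(seed),
        "method": "bayes_mcmc",
        "scenario": run.config.scenario if run.config else None,
        "n_iter": run.config.n_iter if run.config else None,
        "acceptance_rate": run.acceptance_rate,
        "percent": {
            col: {"mean": 100 * run.summary.loc["mean", col],
                  "sd": 100 * run.summary.loc["sd", col]}
            for col in run.summary.columns
        },
        "correlations": {
            row: {col: (None if not np.isfinite(v) else float(v))
                  for col, v in run.correlations.loc[row].items()}
            for row in run.correlations.index
        },
        "diagnostics": run.diagnostics,
    }


def write_report(payload: dict, path: str | Path, ensemble=None) -> None:
    """Write a JSON report; optionally a sibling CSV with the ensemble."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=float)
    if ensemble is not None:
        ensemble_path = path.with_suffix(".ensemble.csv")
        pd.DataFrame(
            ensemble, columns=[f"f_{p.value}" for p in PROCESS_ORDER][: ensemble.shape[1]]
            if ensemble.shape[1] == 4
            else [f"f_{p.value}" for p in PROCESS_ORDER] + ["r_n2o"],
        ).to_csv(ensemble_path, index=False)
    logger.info("wrote report to %s", path)


def format_fraction_table(percent_dict: dict) -> str:
    """Human-readable table of fractions as percentages with one decimal."""
    lines = [f"{'variable':<8} {'mean %':>8} {'sd %':>8}"]
    for name, ms in percent_dict.items():
        lines.append(f"{name:<8} {ms['mean']:>8.1f} {ms['sd']:>8.1f}")
    return "\n".join(lines)
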