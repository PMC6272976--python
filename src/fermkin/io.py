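"""Readers, writers, packaged fixtures and run configuration.

Design tables travel as CSV (factor columns then response columns, with
optional ``<response>_sd`` uncertainty columns); a structured YAML config
declares factor centers/halfwidths (or two-level low/high pairs), dummy
columns and response units.  Analysis results serialize to JSON or TSV with
full float precision.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .doe import (
    AnovaTable,
    DesignTable,
    FactorSpec,
    OptimumPoint,
    PBResult,
    QuadraticFit,
)
from .kinetics import KineticFitResult, LogisticParams, LPParams, TimeSeries

__all__ = [
    "RunConfig",
    "ParseError",
    "load_factor_config",
    "read_design_csv",
    "read_timeseries_csv",
    "load_fixture_path",
    "load_pb_fixture",
    "load_bbd_fixture",
    "load_kinetic_params_fixture",
    "write_report",
    "report_to_dict",
]

logger = logging.getLogger("fermkin")


class ParseError(ValueError):
    """An input file does not match the declared schema."""


@dataclass
class RunConfig:
    """Declares how to interpret a design CSV: factor specs, dummy columns,
    response names/units."""

    factors: dict[str, FactorSpec] = field(default_factory=dict)
    dummy_columns: tuple[str, ...] = ()
    responses: dict[str, str] = field(default_factory=dict)  # name -> unit
    #: when True, factor columns in the CSV already hold coded levels and
    #: the specs are used only for decoding results back to real units
    columns_coded: bool = False


def load_factor_config(source: str | Path | dict, section: str | None = None) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file or an equivalent mapping.

    Each factor entry gives either ``center``/``halfwidth`` (three-level
    response-surface factor) or ``low``/``high`` (two-level screening
    factor); ``column`` names the CSV column it occupies.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = source
    if section is not None:
        raw = raw[section]
    factors: dict[str, FactorSpec] = {}
    for entry in raw.get("factors", []):
        column = entry.get("column", entry["name"])
        if "center" in entry:
            spec = FactorSpec(
                name=entry["name"],
                center=float(entry["center"]),
                halfwidth=float(entry["halfwidth"]),
                unit=entry.get("unit", ""),
            )
        else:
            spec = FactorSpec.from_two_levels(
                entry["name"],
                float(entry["low"]),
                float(entry["high"]),
                unit=entry.get("unit", ""),
            )
        factors[column] = spec
    responses = {r["name"]: r.get("unit", "") for r in raw.get("responses", [])}
    return RunConfig(
        factors=factors,
        dummy_columns=tuple(raw.get("dummy_columns", ())),
        responses=responses,
        columns_coded=bool(raw.get("columns_coded", False)),
    )


def _packaged(name: str):
    return resources.files("fermkin.data").joinpath(name)


def load_fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture file."""
    return Path(str(_packaged(name)))


def read_design_csv(
    path: str | Path,
    config: RunConfig,
    run_column: str = "run",
) -> DesignTable:
    """Read a design CSV into a typed, coded :class:`DesignTable`.

    Factor columns listed in ``config.factors`` may hold real-unit values
    (encoded via the factor spec) or already-coded levels when no spec is
    given for the column.  Dummy columns must already be coded +/-1.
    Columns named ``<response>_sd`` are stored as uncertainties.
    """
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    if raw.empty:
        raise ParseError(f"{path}: no data rows")

    if run_column in raw.columns:
        runs = raw[run_column]
        if runs.duplicated().any():
            dupes = runs[runs.duplicated()].tolist()
            raise ParseError(f"{path}: duplicate run ids {dupes}")
        raw = raw.drop(columns=[run_column])

    needed = list(config.factors) + list(config.dummy_columns) + list(config.responses)
    missing = [c for c in needed if c not in raw.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")

    for col in needed:
        bad = raw[pd.to_numeric(raw[col], errors="coerce").isna()]
        if len(bad):
            raise ParseError(
                f"{path}: non-numeric value in column {col!r}, "
                f"row(s) {bad.index.tolist()}"
            )

    coded = pd.DataFrame(index=raw.index)
    for col, spec in config.factors.items():
        values = raw[col].to_numpy(dtype=float)
        coded[col] = values if config.columns_coded else spec.encode(values)
    for col in config.dummy_columns:
        coded[col] = raw[col].astype(float)

    responses = raw[list(config.responses)].astype(float)
    sd_cols = {f"{r}_sd": r for r in config.responses if f"{r}_sd" in raw.columns}
    uncertainties = (
        raw[list(sd_cols)].rename(columns=sd_cols).astype(float)
        if sd_cols
        else None
    )
    table = DesignTable(
        coded=coded,
        responses=responses,
        dummy_columns=config.dummy_columns,
        factor_specs=dict(config.factors),
        response_units=dict(config.responses),
        uncertainties=uncertainties,
    )
    logger.info(
        "read design %s: %d runs, factors=%s, dummies=%s, responses=%s",
        path, table.n_runs, table.factor_columns,
        list(config.dummy_columns), list(config.responses),
    )
    return table


def read_timeseries_csv(
    path: str | Path,
    time_column: str = "t_h",
    value_column: str = "biomass_od600",
    label: str | None = None,
) -> TimeSeries:
    """Read one fermentation time series (hours + one response column)."""
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    for col in (time_column, value_column):
        if col not in raw.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    return TimeSeries(
        t=raw[time_column].to_numpy(dtype=float),
        y=raw[value_column].to_numpy(dtype=float),
        label=label or value_column,
    )


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

def _fixture_config(section: str) -> RunConfig:
    with resources.as_file(_packaged("factors.yaml")) as p:
        return load_factor_config(p, section=section)


def load_pb_fixture() -> DesignTable:
    """The packaged 12-run Plackett-Burman screening table (8 medium
    factors, 3 dummy columns, EA and BM responses)."""
    with resources.as_file(_packaged("pb_table2.csv")) as p:
        return read_design_csv(p, _fixture_config("pb"))


def load_bbd_fixture() -> DesignTable:
    """The packaged 29-run Box-Behnken response-surface table (4 medium
    factors at 3 coded levels, 5 center replicates, EA and BM responses)."""
    with resources.as_file(_packaged("bbd_table4.csv")) as p:
        return read_design_csv(p, _fixture_config("rsm"))


def load_kinetic_params_fixture() -> pd.DataFrame:
    """Fitted kinetic parameters across the nine operating conditions:
    stirring speed, temperature and inoculum size one at a time, with
    logistic (mu_m, X0, Xm) and Luedeking-Piret (alpha, beta) estimates and
    their R^2 values."""
    with resources.as_file(_packaged("table6_params.csv")) as p:
        return pd.read_csv(p)


# ---------------------------------------------------------------------------
# report serialization
# ---------------------------------------------------------------------------

def report_to_dict(obj) -> dict:
    """Lossless dict form of any analysis result object."""
    if isinstance(obj, PBResult):
        return {
            "kind": "pb_result",
            "response": obj.response,
            "factors": obj.factors.reset_index().to_dict(orient="records"),
            "dummy_effects": obj.dummy_effects.to_dict(),
            "error_estimate": obj.error_estimate,
            "error_df": obj.error_df,
            "t_limit": obj.t_limit,
        }
    if isinstance(obj, QuadraticFit):
        return {
            "kind": "quadratic_fit",
            "response": obj.response,
            "factor_names": obj.factor_names,
            "coefficients": obj.coefficients.to_dict(),
            "r_squared": obj.r_squared,
            "n_runs": obj.n_runs,
            "n_params": obj.n_params,
        }
    if isinstance(obj, AnovaTable):
        return {
            "kind": "anova_table",
            "response": obj.response,
            "rows": obj.table.reset_index().to_dict(orient="records"),
        }
    if isinstance(obj, OptimumPoint):
        return {
            "kind": "optimum_point",
            "coded_location": obj.coded_location,
            "real_location": obj.real_location,
            "predicted_response": obj.predicted_response,
            "on_boundary": obj.on_boundary,
            "sense": obj.sense,
        }
    if isinstance(obj, KineticFitResult):
        p = obj.params
        if isinstance(p, LogisticParams):
            params = {"X0": p.x0, "Xm": p.xm, "mu_m": p.mu_m}
        elif isinstance(p, LPParams):
            params = {
                "alpha": p.alpha,
                "beta": p.beta,
                "p0": p.p0,
                "gaden_type": p.gaden_type,
            }
        else:  # pragma: no cover
            params = dict(p)
        return {
            "kind": "kinetic_fit",
            "params": params,
            "r_squared": obj.r_squared,
            "residual_sse": obj.residual_sse,
            "converged": obj.converged,
        }
    raise TypeError(f"cannot serialize {type(obj).__name__}")


def _to_tsv(d: dict) -> str:
    """Tabular TSV rendering of a report dict."""
    kind = d["kind"]
    if kind == "pb_result":
        frame = pd.DataFrame(d["factors"])
    elif kind == "anova_table":
        frame = pd.DataFrame(d["rows"])
    elif kind == "quadratic_fit":
        frame = pd.DataFrame(
            {"term": list(d["coefficients"]), "coefficient": list(d["coefficients"].values())}
        )
    elif kind == "optimum_point":
        rows = [
            {
                "factor": name,
                "coded": d["coded_location"][name],
                "real": d["real_location"][name],
            }
            for name in d["coded_location"]
        ]
        frame = pd.DataFrame(rows)
    elif kind == "kinetic_fit":
        frame = pd.DataFrame([{**d["params"], "r_squared": d["r_squared"]}])
    else:
        raise ValueError(f"unknown report kind {kind!r}")
    return frame.to_csv(sep="\t", index=False)


def write_report(obj, format: str = "json", path: str | Path | None = None) -> str:
    """Serialize an analysis result to JSON or TSV; returns the text and
    optionally writes it to ``path``.  Floats keep full precision."""
    d = report_to_dict(obj) if not isinstance(obj, dict) else obj
    if format == "json":
        text = json.dumps(d, indent=2, default=_json_default)
    elif format == "tsv":
        text = _to_tsv(d)
    else:
        raise ValueError(f"unknown format {format!r}: use 'json' or 'tsv'")
    if path is not None:
        Path(path).write_text(text)
    return text


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.bool_):
        return bool(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o).__name__}")
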