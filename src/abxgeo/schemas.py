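"""Schema validation for pipeline outputs.

Each output table has a declared column set with optional per-column value
ranges; :func:`validate_outputs` checks every emitted CSV against its
schema and raises with an itemised report on the first failing table.
The replicate-experiment report has a corresponding nested-key schema.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    pass


#: name -> {column: (lo, hi) | None}; None means no range constraint
TABLE_SCHEMAS: dict[str, dict] = {
    "surveys.csv": {"survey_id": None, "year": (1900, 2100), "location_type": None,
                    "location": None, "N": (0, None), "k": (0, None),
                    "weight": (0, None)},
    "resampled_surveys.csv": {"survey_id": None, "year": (1900, 2100),
                              "location_type": None, "location": None,
                              "N": (0, None), "k": (0, None), "weight": (0, None)},
    "sales.csv": {"country": None, "year": (1900, 2100), "atc": None, "route": None,
                  "sector": None, "unit": None, "quantity": (0, None),
                  "mg_per_su": None},
    "stack_oos.csv": {"row": (0, None), "additive-smoother": (0, 1),
                      "boosted-trees": (0, 1), "elastic-net": (0, 1),
                      "fold": (0, None)},
    "usage_cells.csv": {"cell_id": None, "year": (1900, 2100), "mean": (0, 1),
                        "lower": (0, 1), "upper": (0, 1)},
    "estimates_district.csv": {"unit_id": None, "year": (1900, 2100),
                               "mean": (0, 1), "lower": None, "upper": None,
                               "level": None, "imputed": None},
    "estimates_state.csv": {"unit_id": None, "year": (1900, 2100), "mean": (0, 1),
                            "lower": None, "upper": None, "level": None,
                            "imputed": None},
    "estimates_country.csv": {"unit_id": None, "year": (1900, 2100), "mean": (0, 1),
                              "lower": None, "upper": None, "level": None,
                              "imputed": None},
    "deviation_report.csv": {"country": None, "year": (1900, 2100),
                             "deviation_range": (0, None), "max_deviation": None,
                             "min_deviation": None},
    "consumption_obs.csv": {"country": None, "year": (1900, 2100),
                            "ddd_total": (0, None), "ddd_hospital": (0, None),
                            "ddd_retail": (0, None), "population": (0, None),
                            "ddd_per_1000_per_day": (0, None),
                            "imputed_hospital": None},
    "consumption_country.csv": {"country": None, "year": (1900, 2100),
                                "track": None, "mean": (0, None), "lower": None,
                                "upper": None, "population": (0, None),
                                "volume_ddd": (0, None), "n_draws": (0, None)},
    "consumption_summary.csv": {"scope": None, "year": (1900, 2100),
                                "volume_ddd": (0, None), "volume_lower": (0, None),
                                "volume_upper": (0, None), "rate": (0, None),
                                "rate_lower": (0, None), "rate_upper": (0, None),
                                "population": (0, None),
                                "pct_of_global": (0, 100 + 1e-9)},
    "class_consumption.csv": {"country": None, "year": (1900, 2100), "class": None,
                              "rate": (0, None), "basis": None},
    "aware_consumption.csv": {"country": None, "year": (1900, 2100), "aware": None,
                              "rate": (0, None)},
}


def validate_table(name: str, df: pd.DataFrame) -> list[str]:
    """Return a list of schema violations for one table (empty if valid)."""
    schema = TABLE_SCHEMAS.get(name)
    if schema is None:
        return [f"{name}: no schema declared"]
    problems = []
    missing = set(schema) - set(df.columns)
    if missing:
        problems.append(f"{name}: missing columns {sorted(missing)}")
    for col, bounds in schema.items():
        if col not in df.columns or bounds is None:
            continue
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy(float)
        vals = vals[np.isfinite(vals)]
        lo, hi = bounds
        if lo is not None and len(vals) and vals.min() < lo - 1e-12:
            problems.append(f"{name}.{col}: value {vals.min()} below {lo}")
        if hi is not None and len(vals) and vals.max() > hi + 1e-12:
            problems.append(f"{name}.{col}: value {vals.max()} above {hi}")
    return problems


def validate_outputs(directory) -> None:
    """Validate every known output CSV in a pipeline run directory."""
    problems = []
    for name in TABLE_SCHEMAS:
        path = Path(directory) / name
        if not path.exists():
            continue
        problems.extend(validate_table(name, pd.read_csv(path)))
    if problems:
        raise SchemaError("output schema violations:\n  " + "\n  ".join(problems))


#: nested key -> type of the replicate-experiment report
REPORT_SCHEMA = {
    "n_replicates": int,
    "usage": {"beta_max_abs_z": float, "beta_share_within_3sd": float,
              "range_rel_err": float, "sd_rel_err": float, "rho_err": float,
              "district_coverage": float},
    "consumption": {"rmse_pipeline_mean": float, "rmse_stage1_mean": float,
                    "share_pipeline_beats_stage1": float, "cv_coverage": float},
    "per_replicate": dict,
}


def validate_report(report: dict, schema: dict | None = None, prefix: str = "") -> None:
    schema = REPORT_SCHEMA if schema is None else schema
    for key, expect in schema.items():
        if key not in report:
            raise SchemaError(f"report missing key {prefix}{key}")
        if expect is dict:
            if not isinstance(report[key], dict):
                raise SchemaError(f"report key {prefix}{key} is not a mapping")
        elif isinstance(expect, dict):
            validate_report(report[key], expect, prefix=f"{prefix}{key}.")
        elif not isinstance(report[key], expect):
            raise SchemaError(
                f"report key {prefix}{key} has type {type(report[key]).__name__}, "
                f"expected {expect.__name__}")
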