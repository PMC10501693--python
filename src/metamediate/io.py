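"""Reading and writing study tables and analysis reports.

Two comma-separated input layouts are accepted (UTF-8, header row):

* **long** — one row per effect entry, columns ``study_id, n, design,
  region, flag_nightmare_overlap, flag_under5, pair, effect_type, value``
  (plus optional ``path_a, path_b, path_cprime`` for ``path_model``
  rows);
* **wide** — one row per study with ``r_xm, r_xy, r_my`` columns (blank
  where the study did not report that element).

Missing values may be empty fields or the literal strings ``NA``/``nan``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .effects import CorrelationSet, EffectEntry, StudyRecord
from .moderation import SensitivityResult, SubgroupResult
from .stage1 import PooledCorrelations
from .stage2 import PATH_NAMES, MediationFit

__all__ = [
    "read_study_table",
    "write_study_table",
    "stage1_report",
    "stage2_report",
    "format_stage2_table",
    "residual_table",
    "SchemaError",
]

LONG_COLUMNS = ("study_id", "n", "pair", "effect_type", "value")
WIDE_COLUMNS = ("study_id", "n", "r_xm", "r_xy", "r_my")
_FLAG_DEFAULTS = {
    "design": "cross_sectional",
    "region": "western",
    "flag_nightmare_overlap": False,
    "flag_under5": False,
}


class SchemaError(ValueError):
    """Input table does not match the documented schema."""


def _read_csv(path):
    return pd.read_csv(
        path, na_values=["NA", "nan", "NaN", ""], keep_default_na=True,
        skipinitialspace=True, float_precision="round_trip",
    )


def _to_bool(x) -> bool:
    if isinstance(x, str):
        return x.strip().lower() in ("1", "true", "yes")
    return bool(x) and not pd.isna(x)


def _study_fields(group: pd.DataFrame, sid: str) -> dict:
    out = {}
    for col, default in _FLAG_DEFAULTS.items():
        if col in group.columns and not group[col].isna().all():
            val = group[col].dropna().iloc[0]
            out[col] = _to_bool(val) if col.startswith("flag_") else str(val)
        else:
            out[col] = default
    n_vals = group["n"].dropna().unique()
    if len(n_vals) != 1:
        raise SchemaError(f"study {sid}: sample size must be a single value")
    out["n"] = int(n_vals[0])
    return out


def read_study_table(path) -> list[StudyRecord]:
    """Parse a long- or wide-format study table into StudyRecords."""
    df = _read_csv(path)
    cols = set(df.columns)
    if {"pair", "effect_type"} <= cols:
        required = set(LONG_COLUMNS) - {"value"}
        layout = "long"
    elif {"r_xm", "r_xy", "r_my"} & cols:
        required = {"study_id", "n"}
        layout = "wide"
    else:
        raise SchemaError(
            "unrecognized table: need either long columns "
            f"{LONG_COLUMNS} or wide columns {WIDE_COLUMNS}"
        )
    missing = required - cols
    if missing:
        raise SchemaError(f"missing required column(s): {sorted(missing)}")

    records = []
    for sid, group in df.groupby("study_id", sort=False):
        fields = _study_fields(group, sid)
        entries = []
        if layout == "long":
            for line_no, row in group.iterrows():
                etype = str(row["effect_type"])
                if etype == "path_model":
                    payload_cols = ("path_a", "path_b", "path_cprime")
                    if not set(payload_cols) <= cols:
                        raise SchemaError(
                            f"row {line_no + 2}: path_model rows require "
                            f"columns {payload_cols}"
                        )
                    payload = {
                        "a": float(row["path_a"]),
                        "b": float(row["path_b"]),
                        "c_prime": float(row["path_cprime"]),
                    }
                    entries.append(EffectEntry(str(sid), "XM", etype,
                                               path_payload=payload))
                else:
                    if pd.isna(row["value"]):
                        raise SchemaError(
                            f"row {line_no + 2}: missing value for "
                            f"{etype} entry of study {sid}"
                        )
                    entries.append(
                        EffectEntry(str(sid), str(row["pair"]), etype,
                                    value=float(row["value"]))
                    )
        else:
            row = group.iloc[0]
            for col, pair in (("r_xm", "XM"), ("r_xy", "XY"), ("r_my", "MY")):
                if col in cols and not pd.isna(row.get(col)):
                    entries.append(
                        EffectEntry(str(sid), pair, "correlation",
                                    value=float(row[col]))
                    )
        try:
            records.append(StudyRecord(study_id=str(sid), entries=entries, **fields))
        except ValueError as exc:
            raise SchemaError(str(exc)) from exc
    return records


def write_study_table(records: list[StudyRecord], path) -> None:
    """Write records in the long input layout."""
    rows = []
    for rec in records:
        base = dict(
            study_id=rec.study_id, n=rec.n, design=rec.design, region=rec.region,
            flag_nightmare_overlap=rec.flag_nightmare_overlap,
            flag_under5=rec.flag_under5,
        )
        for e in rec.entries:
            row = dict(base, pair=e.pair, effect_type=e.effect_type,
                       value=e.value)
            if e.effect_type == "path_model":
                payload = e.path_payload
                row.update(path_a=payload["a"], path_b=payload["b"],
                           path_cprime=payload["c_prime"])
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def write_correlation_sets(sets: list[CorrelationSet], path,
                           labels: dict | None = None) -> None:
    rows = []
    for s in sets:
        row = dict(study_id=s.study_id, n=s.n,
                   r_xm=s.r[0] if s.mask[0] else None,
                   r_xy=s.r[1] if s.mask[1] else None,
                   r_my=s.r[2] if s.mask[2] else None)
        if labels and s.study_id in labels:
            row.update(labels[s.study_id])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def stage1_report(pooled: PooledCorrelations) -> dict:
    """JSON-compatible Stage-1 summary."""
    return {
        "rho": pooled.rho.tolist(),
        "acov": pooled.acov.tolist(),
        "tau2": pooled.tau2.tolist(),
        "i2": None if pooled.i2 is None else pooled.i2.tolist(),
        "i2_mean": pooled.i2_mean,
        "Q": pooled.Q,
        "df": pooled.df,
        "p_Q": pooled.p_Q,
        "n_studies": pooled.n_studies,
        "n_total": pooled.n_total,
        "n_observed": pooled.n_observed,
        "projected": pooled.projected,
    }


def pooled_from_report(report: dict) -> PooledCorrelations:
    """Inverse of :func:`stage1_report` (round-trips estimates exactly)."""
    return PooledCorrelations(
        rho=np.asarray(report["rho"]),
        acov=np.asarray(report["acov"]),
        tau2=np.asarray(report["tau2"]),
        fe_rho=np.asarray(report.get("fe_rho", report["rho"])),
        n_studies=report.get("n_studies", 0),
        n_total=report.get("n_total", 0),
        n_observed=report.get("n_observed", 0),
        Q=report.get("Q"),
        df=report.get("df"),
        p_Q=report.get("p_Q"),
        i2=None if report.get("i2") is None else np.asarray(report["i2"]),
        i2_mean=report.get("i2_mean"),
        projected=report.get("projected", False),
    )


def stage2_report(fit: MediationFit) -> dict:
    rows = {}
    for k, name in enumerate(PATH_NAMES):
        rows[name] = {
            "estimate": float(fit.paths[k]),
            "se": float(fit.se[k]),
            "lower": float(fit.ci[k, 0]),
            "upper": float(fit.ci[k, 1]),
        }
    rows["indirect"] = {
        "estimate": fit.indirect,
        "se": fit.indirect_se,
        "lower": fit.indirect_ci[0],
        "upper": fit.indirect_ci[1],
    }
    return {
        "parameters": rows,
        "discrepancy": fit.discrepancy,
        "df": fit.df,
        "converged": fit.converged,
    }


_ROW_LABELS = {
    "a": "Exposure -> Mediator (a)",
    "b": "Mediator -> Outcome (b)",
    "c_prime": "Exposure -> Outcome direct (c')",
    "indirect": "Indirect effect (a*b)",
}


def format_stage2_table(fit: MediationFit) -> str:
    """Human-readable path table (2-dp display rounding)."""
    lines = [f"{'Parameter':36s} {'Estimate':>8s} {'Lower':>7s} {'Upper':>7s}"]
    rep = stage2_report(fit)["parameters"]
    for key, label in _ROW_LABELS.items():
        row = rep[key]
        lines.append(
            f"{label:36s} {row['estimate']:8.2f} {row['lower']:7.2f} "
            f"{row['upper']:7.2f}"
        )
    return "\n".join(lines)


def subgroup_report(result: SubgroupResult) -> dict:
    return {
        "grouping": result.grouping,
        "delta_chi2": result.delta_chi2,
        "df": result.df,
        "p": result.p,
        "per_path": {
            k: {"delta_chi2": v[0], "df": v[1], "p": v[2]}
            for k, v in result.per_path.items()
        },
        "groups": {
            label: {
                "n_studies": g.n_studies,
                "n_total": g.n_total,
                "stage1": stage1_report(g.pooled),
                "stage2": stage2_report(g.fit),
            }
            for label, g in result.groups.items()
        },
    }


def sensitivity_report(result: SensitivityResult) -> dict:
    return {
        "exclusions": list(result.exclusions),
        "n_excluded": result.n_excluded,
        "excluded_ids": result.excluded_ids,
        "stage2": stage2_report(result.sensitivity),
        "comparison": result.comparison.to_dict(orient="records"),
    }


def residual_table(sets, pooled: PooledCorrelations) -> pd.DataFrame:
    """Per-study elements with normal-approximation 95% CIs (forest-plot data)."""
    from .stage1 import sampling_covariance

    rows = []
    for s in sets:
        sv = sampling_covariance(s, pooled.fe_rho)
        for pos, k in enumerate(sv.indices):
            se = float(np.sqrt(sv.V[pos, pos] + pooled.tau2[k]))
            rows.append(
                dict(study_id=s.study_id, element=("XM", "XY", "MY")[k],
                     r=float(s.r[k]), lower=s.r[k] - 1.959963984540054 * se,
                     upper=s.r[k] + 1.959963984540054 * se, n=s.n)
            )
    return pd.DataFrame(rows)


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")
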