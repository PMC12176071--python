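"""Serialisation and table rendering of a :class:`~ehrdiv.stats.ComparisonReport`.

``report.json`` keeps unrounded values; the rendered CSV tables round the way
epidemiological registry reports are printed (rates to 1 decimal, SDs to 2
decimals, percentages to 1 decimal).
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import pandas as pd

from .stats import ComparisonReport, GroupIndicators, PairedTestResult


def _clean(obj):
    """Recursively convert NaN to None for JSON round-tripping."""
    if isinstance(obj, float) and math.isnan(obj):
        return None
    if isinstance(obj, dict):
        return {k: _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    return obj


def _restore(obj):
    if obj is None:
        return math.nan
    if isinstance(obj, dict):
        return {k: _restore(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_restore(v) for v in obj]
    return obj


def report_to_dict(report: ComparisonReport) -> dict:
    return _clean(
        {
            "name_a": report.name_a,
            "name_b": report.name_b,
            "analysis_year": report.analysis_year,
            "conf_level": report.conf_level,
            "link": report.link,
            "demographics_a": report.demographics_a.to_dict(orient="list"),
            "demographics_b": report.demographics_b.to_dict(orient="list"),
            "paired": {k: v.to_dict() for k, v in report.paired.items()},
            "step2_skipped": report.step2_skipped,
            "groups": [
                {"a": g["a"].to_dict(), "b": g["b"].to_dict(), "sd": g["sd"]} for g in report.groups
            ],
            "notes": report.notes,
        }
    )


def report_to_json(report: ComparisonReport, path=None) -> str:
    text = json.dumps(report_to_dict(report), indent=2, sort_keys=True) + "\n"
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def report_from_json(path) -> ComparisonReport:
    data = _restore(json.loads(Path(path).read_text(encoding="utf-8")))
    paired = {k: PairedTestResult(**v) for k, v in data["paired"].items()}
    groups = [
        {"a": GroupIndicators(**g["a"]), "b": GroupIndicators(**g["b"]), "sd": g["sd"]}
        for g in data["groups"]
    ]
    demo_cols = ["characteristic", "statistic", "value", "value2"]
    return ComparisonReport(
        name_a=data["name_a"],
        name_b=data["name_b"],
        analysis_year=int(data["analysis_year"]),
        conf_level=float(data["conf_level"]),
        link=data["link"],
        demographics_a=pd.DataFrame(data["demographics_a"], columns=demo_cols),
        demographics_b=pd.DataFrame(data["demographics_b"], columns=demo_cols),
        paired=paired,
        step2_skipped=data["step2_skipped"] if not isinstance(data["step2_skipped"], float) else None,
        groups=groups,
        notes=list(data["notes"]),
    )


def _fmt(v: float, nd: int) -> str:
    return "" if (isinstance(v, float) and math.isnan(v)) else f"{v:.{nd}f}"


def table1(report: ComparisonReport) -> pd.DataFrame:
    """Demographics of the two full datasets, side by side."""
    a = report.demographics_a.set_index("characteristic")
    b = report.demographics_b.set_index("characteristic")
    rows = []
    for char in a.index:
        ra, rb = a.loc[char], b.loc[char]
        if ra["statistic"] == "n (%)":
            va = f"{int(ra['value'])} ({_fmt(ra['value2'], 1)})"
            vb = f"{int(rb['value'])} ({_fmt(rb['value2'], 1)})"
        elif ra["statistic"] == "mean (sd)":
            va = f"{_fmt(ra['value'], 1)} ({_fmt(ra['value2'], 1)})"
            vb = f"{_fmt(rb['value'], 1)} ({_fmt(rb['value2'], 1)})"
        elif char == "patient_years_per_patient":
            va, vb = _fmt(ra["value"], 3), _fmt(rb["value"], 3)
        else:
            va, vb = _fmt(ra["value"], 2), _fmt(rb["value"], 2)
        rows.append({"characteristic": char, report.name_a: va, report.name_b: vb})
    return pd.DataFrame(rows)


def table2(report: ComparisonReport) -> pd.DataFrame:
    """Paired per-patient indicators of the concordant patients."""
    rows = []
    for ind, r in report.paired.items():
        rows.append(
            {
                "indicator": ind,
                f"{report.name_a} mean (SD)": f"{r.mean_a:.2f} ({r.sd_a:.2f})",
                f"{report.name_b} mean (SD)": f"{r.mean_b:.2f} ({r.sd_b:.2f})",
                "mean difference": f"{r.mean_diff:.2f}",
                "p value": "<.001" if r.p_value < 0.001 else f"{r.p_value:.2f}",
                f"{int(report.conf_level * 100)}% CI": f"{r.ci_low:.2f} to {r.ci_high:.2f}",
            }
        )
    return pd.DataFrame(rows)


def table3(report: ComparisonReport) -> pd.DataFrame:
    """Diagnosis-group indicators with standardized differences."""
    rows = []
    for g in report.groups:
        a: GroupIndicators = g["a"]
        b: GroupIndicators = g["b"]
        sds = g["sd"]

        def _sd(key: str) -> str:
            v = sds.get(key)
            return "" if v is None else f"{v['sd_value']:.2f}"

        label = f"{a.label} ({a.icpc_code})"
        rows += [
            {"group": label, "indicator": "n cases", report.name_a: str(a.n_cases), report.name_b: str(b.n_cases), "SD": ""},
            {"group": label, "indicator": "patient years", report.name_a: _fmt(a.group_patient_years, 2), report.name_b: _fmt(b.group_patient_years, 2), "SD": ""},
            {"group": label, "indicator": "patient years per case", report.name_a: _fmt(a.patient_years_per_case, 3), report.name_b: _fmt(b.patient_years_per_case, 3), "SD": ""},
            {"group": label, "indicator": "prevalence per 1000 py", report.name_a: _fmt(a.prevalence_per_1000py, 1), report.name_b: _fmt(b.prevalence_per_1000py, 1), "SD": _sd("prevalence")},
            {"group": label, "indicator": "prescriptions per 1000 py", report.name_a: _fmt(a.prescriptions_per_1000py, 1), report.name_b: _fmt(b.prescriptions_per_1000py, 1), "SD": _sd("prescriptions")},
            {"group": label, "indicator": "consults per 1000 py", report.name_a: _fmt(a.consults_per_1000py, 1), report.name_b: _fmt(b.consults_per_1000py, 1), "SD": _sd("consults")},
        ]
    return pd.DataFrame(rows)


def write_tables(report: ComparisonReport, directory) -> list[Path]:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in (("table1", table1(report)), ("table2", table2(report)), ("table3", table3(report))):
        p = d / f"{name}.csv"
        df.to_csv(p, index=False)
        paths.append(p)
    return paths
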