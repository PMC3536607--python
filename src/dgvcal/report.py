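"""Reference tables, in-table algebra verification and run reports.

The published variance-component, correlation and efficiency tables for the
two breeds ship with the package as TSV fixtures.  ``verify_table_algebra``
replays the arithmetic that links them: every genetic correlation must be
recoverable from its (co)variance row and every selection efficiency from
its correlation and parent-average reliability.  Rows that do not reproduce
at the printed precision are re-checked under interval arithmetic that
widens every printed input by half its last printed digit; rows explainable
that way are flagged ``rounding_sensitive`` rather than failed.
"""

from __future__ import annotations

import importlib.resources
import json
from itertools import product

import numpy as np
import pandas as pd

__all__ = [
    "load_table",
    "verify_table_algebra",
    "build_report",
]

_TABLES = {
    "traits": "table2_traits.tsv",
    "covariances": "table4_covariances.tsv",
    "correlations": "table5_correlations.tsv",
    "efficiency": "table6_efficiency.tsv",
}


def _data_path(name: str):
    if name not in _TABLES:
        raise KeyError(f"unknown reference table {name!r}; options: {sorted(_TABLES)}")
    return importlib.resources.files("dgvcal.data") / _TABLES[name]


def load_table(name: str, as_str: bool = False) -> pd.DataFrame:
    """Load a bundled reference table ('traits', 'covariances',
    'correlations', 'efficiency').  ``as_str`` preserves printed precision."""
    kwargs = {"dtype": str} if as_str else {}
    with importlib.resources.as_file(_data_path(name)) as path:
        return pd.read_csv(path, sep="\t", **kwargs)


def _half_ulp(printed: str) -> float:
    """Half of the last printed decimal place, e.g. '0.93' -> 0.005."""
    s = printed.strip()
    if "." not in s:
        return 0.5
    return 0.5 * 10 ** (-(len(s) - s.index(".") - 1))


def _decimals(printed: str) -> int:
    s = printed.strip()
    return len(s) - s.index(".") - 1 if "." in s else 0


def _interval(value: str):
    v = float(value)
    h = _half_ulp(value)
    return (v - h, v + h)


def _corner_range(fn, intervals):
    vals = [fn(*corner) for corner in product(*intervals)]
    return min(vals), max(vals)


def _classify(recomputed: float, printed: str, lo: float, hi: float) -> str:
    target = float(printed)
    nd = _decimals(printed)
    if round(recomputed, nd) == round(target, nd):
        return "consistent"
    # does any pre-rounding input combination round to the printed value?
    tol = _half_ulp(printed)
    if lo <= target + tol and hi >= target - tol:
        return "rounding_sensitive"
    return "fail"


def verify_table_algebra(
    table4: pd.DataFrame | None = None,
    table5: pd.DataFrame | None = None,
    table6: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Recompute r_g from the (co)variance table and efficiency from the
    correlation + parent-average tables; one verdict row per check.

    Arguments default to the bundled fixtures; user-supplied frames must use
    string cells so printed precision is known.
    """
    t4 = table4 if table4 is not None else load_table("covariances", as_str=True)
    t5 = table5 if table5 is not None else load_table("correlations", as_str=True)
    t6 = table6 if table6 is not None else load_table("efficiency", as_str=True)
    rows = []
    t5_idx = t5.set_index(["trait", "breed"]) if len(t5) else t5
    for _, rec in t4.iterrows():
        v1, v2, c = rec["var_trait"], rec["var_dgv"], rec["cov_trait_dgv"]
        r = float(c) / np.sqrt(float(v1) * float(v2))
        lo, hi = _corner_range(
            lambda a, b, cc: cc / np.sqrt(a * b),
            [_interval(v1), _interval(v2), _interval(c)],
        )
        printed = t5_idx.loc[(rec["trait"], rec["breed"]), "r_g"]
        rows.append(
            {
                "check": "r_g",
                "trait": rec["trait"],
                "breed": rec["breed"],
                "cohort": "",
                "recomputed": r,
                "printed": float(printed),
                "status": _classify(r, printed, lo, hi),
            }
        )
    for _, rec in t6.iterrows():
        key = (rec["trait"], rec["breed"])
        if key not in t5_idx.index:
            continue
        r_g = t5_idx.loc[key, "r_g"]
        eff = float(r_g) / np.sqrt(float(rec["r2_pa"]))
        lo, hi = _corner_range(
            lambda r, p: r / np.sqrt(p),
            [_interval(r_g), _interval(rec["r2_pa"])],
        )
        rows.append(
            {
                "check": "efficiency",
                "trait": rec["trait"],
                "breed": rec["breed"],
                "cohort": rec["cohort"],
                "recomputed": eff,
                "printed": float(rec["efficiency"]),
                "status": _classify(eff, rec["efficiency"], lo, hi),
            }
        )
    return pd.DataFrame(rows)


def _frame_block(title: str, frame: pd.DataFrame) -> str:
    return f"## {title}\n\n```\n{frame.to_string(index=False)}\n```\n"


def build_report(manifest: dict, results: dict) -> str:
    """Assemble a Markdown run report from stage outputs.

    ``results`` may contain any of the keys ``qc_report``, ``amax``,
    ``estimates``, ``efficiency``, ``verification`` (DataFrames or dicts);
    missing stages are listed in a gaps section and the report is still
    produced.  Two runs with the same seed produce byte-identical reports.
    """
    lines = ["# dgvcal run report", ""]
    lines.append("## Run manifest")
    lines.append("")
    lines.append("```json")
    lines.append(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    lines.append("```")
    lines.append("")
    known = ["qc_report", "amax", "estimates", "efficiency", "verification"]
    titles = {
        "qc_report": "Marker QC",
        "amax": "Clustering quality (a_max within / between groups)",
        "estimates": "Bivariate variance components",
        "efficiency": "Selection efficiency (DGV vs parent average)",
        "verification": "Reference-table algebra verification",
    }
    gaps = []
    for key in known:
        if key not in results or results[key] is None:
            gaps.append(key)
            continue
        value = results[key]
        if isinstance(value, pd.DataFrame):
            lines.append(_frame_block(titles[key], value))
        else:
            lines.append(f"## {titles[key]}\n\n```json\n{json.dumps(value, indent=2, sort_keys=True, default=str)}\n```\n")
    if gaps:
        lines.append("## Missing stages\n")
        for g in gaps:
            lines.append(f"- {g}: no output available")
        lines.append("")
    return "\n".join(lines)
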