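"""Selection efficiency of DGV relative to parent average.

For a newborn candidate the default information is the parent average (PA)
of its sire's and dam's EBV, with reliability R2_PA = (r2_sire + r2_dam)/4.
Selecting instead on the animal's DGV changes the expected response by the
ratio of accuracies

    Efficiency = accuracy(DGV) / accuracy(PA) = r_g(T, DGV) / sqrt(R2_PA),

with selection intensity and generation interval assumed equal for the two
strategies.  Trait-level efficiency uses the cohort mean of per-animal
R2_PA; per-animal distributions are retained because PA reliabilities are
strongly bimodal (AI sires with many progeny versus natural-mating sires),
so individual efficiencies can exceed 1 even when the trait-level value
does not.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .deregression import bif_to_reliability, parent_average_reliability
from .pedigree import Pedigree

__all__ = [
    "selection_efficiency",
    "cohort_pa_reliability",
    "efficiency_report",
]


def selection_efficiency(r_g: float, r2_pa: float) -> float:
    """r_g / sqrt(r2_pa); NaN (with a warning) when r2_pa is 0."""
    if r_g < 0:
        raise ValueError("selection efficiency expects a non-negative genetic correlation")
    if not 0 <= r2_pa <= 1:
        raise ValueError("parent-average reliability must lie in [0, 1]")
    if r2_pa == 0:
        warnings.warn("parent-average reliability is zero: efficiency undefined", stacklevel=2)
        return float("nan")
    return float(r_g / np.sqrt(r2_pa))


def cohort_pa_reliability(
    evaluations: pd.DataFrame,
    pedigree: Pedigree,
    cohort: Iterable,
    trait: str,
) -> pd.DataFrame:
    """Per-animal parent-average reliability for a cohort and trait.

    Parents missing from the pedigree or from the evaluation table
    contribute reliability 0.  Returns one row per cohort animal with its
    R2_PA; the cohort mean is ``frame["r2_pa"].mean()``.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("empty cohort")
    rows = evaluations[evaluations["trait"] == trait].set_index("animal")
    out = []
    for animal in cohort:
        r2s = []
        if animal in pedigree:
            parents = pedigree.parents_of(animal)
        else:
            parents = (None, None)
        for p in parents:
            if p is None or p not in rows.index:
                r2s.append(0.0)
            else:
                r2s.append(bif_to_reliability(rows.loc[p, "bif_acc"]))
        out.append({"animal": animal, "trait": trait, "r2_pa": parent_average_reliability(*r2s)})
    return pd.DataFrame(out)


def efficiency_report(
    estimates: Mapping[str, object],
    pa: Mapping[str, pd.DataFrame],
    cohort_label: str = "genotyped",
) -> pd.DataFrame:
    """Per-trait table of r_g, cohort-mean R2_PA and selection efficiency.

    ``estimates`` maps trait -> BivariateEstimates (or an object/float with
    an ``r_g``); ``pa`` maps trait -> the frame from
    :func:`cohort_pa_reliability`.  Traits without an estimate are skipped
    with a warning.
    """
    rows = []
    for trait, pa_frame in pa.items():
        if trait not in estimates:
            warnings.warn(f"no bivariate estimate for trait {trait!r}; row skipped", stacklevel=2)
            continue
        est = estimates[trait]
        r_g = float(getattr(est, "r_g", est))
        r2_pa = float(pa_frame["r2_pa"].mean())
        eff = selection_efficiency(max(r_g, 0.0), r2_pa) if r2_pa > 0 else float("nan")
        rows.append(
            {
                "trait": trait,
                "cohort": cohort_label,
                "r_g": r_g,
                "r2_pa": r2_pa,
                "efficiency": eff,
            }
        )
    return pd.DataFrame(rows, columns=["trait", "cohort", "r_g", "r2_pa", "efficiency"])
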