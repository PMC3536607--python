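"""Deregression of estimated breeding values and information weights.

National beef evaluations publish expected progeny differences (EPD = EBV/2)
with BIF accuracies.  For use as a genomic-training response the EBV must be
deregressed: shrinkage undone and the parent-average contribution removed,
leaving a pseudo-phenotype whose information content reflects only the
animal's own and descendant records.

The parent-average-removing deregression solves a 2x2 mixed-model system in
the parent-average effect g_PA and the animal effect g_i, with additive
inverse-covariance lambda * [[4, -2], [-2, 2]] (from Var[g_PA, g_i] =
sigma_g^2 [[1/2, 1/2], [1/2, 1]]) and unknown effective information
contents Z'Z_PA and Z'Z_i chosen to reproduce the published reliabilities of
the parent average and of the animal's EBV:

    lambda  = (1 - h^2) / h^2
    alpha   = 1 / (0.5 - r2_PA)
    delta   = (0.5 - r2_PA) / (1 - r2)
    Z'Z_PA  = lambda (0.5 alpha - 4) + 0.5 lambda sqrt(alpha^2 + 16 / delta)
    Z'Z_i   = delta Z'Z_PA + 2 lambda (2 delta - 1)

The right-hand side recovered from the solved system, y_i = -2 lambda
EBV_PA + (Z'Z_i + 2 lambda) EBV_i, is the animal's own information;
DEBV = y_i / Z'Z_i with reliability r2_DEBV = 1 - lambda / (Z'Z_i + lambda).
The training weight for a record with reliability r2 is

    w = (1 - h^2) / [(c + (1 - r2) / r2) h^2]

with c the proportion of genetic variance not captured by markers
(default 0.40 throughout this package).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import Pedigree

__all__ = [
    "DeregressionError",
    "DeregressedRecord",
    "bif_to_reliability",
    "reliability_to_bif",
    "epd_to_ebv",
    "parent_average_reliability",
    "deregress",
    "debv_weight",
    "deregress_table",
    "DEFAULT_C",
    "TRAIT_HERITABILITY",
]

#: proportion of genetic variance not explained by markers
DEFAULT_C = 0.40

#: built-in per-trait heritabilities for nationally evaluated beef traits
TRAIT_HERITABILITY: dict[str, float] = {
    "birth_weight": 0.42,
    "calving_ease_direct": 0.12,
    "calving_ease_maternal": 0.13,
    "carcass_weight": 0.40,
    "docility": 0.35,
    "fat_thickness": 0.35,
    "marbling": 0.54,
    "rib_eye_muscle_area": 0.46,
    "scrotal_circumference": 0.43,
    "shear_force": 0.40,
    "stayability": 0.21,
    "weaning_weight_direct": 0.30,
    "weaning_weight_maternal": 0.14,
    "yield_grade": 0.40,
    "yearling_weight": 0.29,
}


class DeregressionError(ValueError):
    """Domain errors in deregression inputs."""


@dataclass(frozen=True)
class DeregressedRecord:
    """One training record: deregressed EBV with reliability and weight."""

    animal_id: object
    trait: str
    debv: float
    reliability_debv: float
    weight: float
    heritability: float


def bif_to_reliability(bif_accuracy: float) -> float:
    """Reliability R^2 = 1 - (1 - BIF)^2 from a BIF accuracy in [0, 1]."""
    b = np.asarray(bif_accuracy, dtype=float)
    if np.any((b < 0) | (b > 1)):
        raise DeregressionError("BIF accuracy must lie in [0, 1]")
    out = 1.0 - (1.0 - b) ** 2
    return float(out) if np.isscalar(bif_accuracy) or out.ndim == 0 else out


def reliability_to_bif(r2: float) -> float:
    """Inverse map: BIF = 1 - sqrt(1 - R^2)."""
    r = np.asarray(r2, dtype=float)
    if np.any((r < 0) | (r > 1)):
        raise DeregressionError("reliability must lie in [0, 1]")
    out = 1.0 - np.sqrt(1.0 - r)
    return float(out) if np.isscalar(r2) or out.ndim == 0 else out


def epd_to_ebv(epd: float) -> float:
    """EBV = 2 * EPD."""
    return 2.0 * epd


def parent_average_reliability(r2_sire: float, r2_dam: float) -> float:
    """R^2_PA = (r2_sire + r2_dam) / 4; missing parent contributes 0."""
    for v in (r2_sire, r2_dam):
        if not 0 <= v <= 1:
            raise DeregressionError("parental reliabilities must lie in [0, 1]")
    return (r2_sire + r2_dam) / 4.0


def _information_contents(r2: float, r2_pa: float, lam: float) -> tuple[float, float]:
    alpha = 1.0 / (0.5 - r2_pa)
    delta = (0.5 - r2_pa) / (1.0 - r2)
    zz_pa = lam * (0.5 * alpha - 4.0) + 0.5 * lam * math.sqrt(alpha**2 + 16.0 / delta)
    zz_i = delta * zz_pa + 2.0 * lam * (2.0 * delta - 1.0)
    return zz_pa, zz_i


def deregress(
    ebv: float,
    r2: float,
    ebv_pa: float,
    r2_pa: float,
    h2: float,
) -> tuple[float, float]:
    """Parent-average-free deregressed EBV and its reliability.

    Parameters are the animal's EBV and reliability, the parent-average EBV
    (mean of parental EBV) and its reliability, and the trait heritability.
    Returns (debv, r2_debv).  Animals whose EBV reliability does not exceed
    the parent-average reliability carry no own/descendant information and
    raise :class:`DeregressionError`; callers building training tables catch
    this and drop the record.

    With both parents unknown (r2_pa == 0) the parent-average effect is
    vacuous and simple deregression applies: debv = ebv / r2 with
    r2_debv = r2.
    """
    if not 0 < h2 < 1:
        raise DeregressionError("h2 must be in (0, 1)")
    if not 0 < r2 < 1:
        raise DeregressionError("EBV reliability must be in (0, 1)")
    if not 0 <= r2_pa < 0.5:
        raise DeregressionError("parent-average reliability must be in [0, 0.5)")
    if r2 <= r2_pa:
        raise DeregressionError(
            "record is uninformative: EBV reliability does not exceed parent-average reliability"
        )
    if r2_pa == 0.0:
        return ebv / r2, r2
    lam = (1.0 - h2) / h2
    zz_pa, zz_i = _information_contents(r2, r2_pa, lam)
    if zz_i <= 0:
        raise DeregressionError("record is uninformative: nonpositive own information content")
    y_i = -2.0 * lam * ebv_pa + (zz_i + 2.0 * lam) * ebv
    debv = y_i / zz_i
    r2_debv = 1.0 - lam / (zz_i + lam)
    return debv, r2_debv


def debv_weight(r2_debv: float, c: float = DEFAULT_C, h2: float | None = None) -> float:
    """Information weight w = (1 - h2) / [(c + (1 - r2)/r2) h2].

    Strictly increasing in r2_debv.  At r2_debv = 1 with c = 0 the weight is
    unbounded and returns inf.
    """
    if h2 is None or not 0 < h2 < 1:
        raise DeregressionError("h2 must be supplied in (0, 1)")
    if not 0 < r2_debv <= 1:
        raise DeregressionError("r2_debv must be in (0, 1]")
    if not 0 <= c < 1:
        raise DeregressionError("c must be in [0, 1)")
    denom = (c + (1.0 - r2_debv) / r2_debv) * h2
    if denom == 0.0:
        return math.inf
    return (1.0 - h2) / denom


def deregress_table(
    evaluation: pd.DataFrame,
    pedigree: Pedigree,
    trait: str,
    h2: float | None = None,
    c: float = DEFAULT_C,
) -> pd.DataFrame:
    """Build the per-trait training table (animal, debv, r2_debv, weight).

    ``evaluation`` holds columns animal/trait/epd/bif_acc for the genotyped
    animals *and their parents* (parents missing from the table, like
    unknown parents, contribute reliability 0).  Records failing the
    informativeness precondition are dropped, mirroring the varying per-trait
    counts in national data.
    """
    if h2 is None:
        if trait not in TRAIT_HERITABILITY:
            raise DeregressionError(f"no built-in heritability for trait {trait!r}; pass h2=")
        h2 = TRAIT_HERITABILITY[trait]
    rows = evaluation[evaluation["trait"] == trait]
    by_animal = rows.set_index("animal")
    out = []
    n_dropped = 0
    for animal, rec in by_animal.iterrows():
        r2 = bif_to_reliability(rec["bif_acc"])
        if r2 <= 0 or r2 >= 1:
            n_dropped += 1
            continue
        sire, dam = pedigree.parents_of(animal) if animal in pedigree else (None, None)

        def parent_info(p):
            if p is None or p not in by_animal.index:
                return 0.0, 0.0
            prec = by_animal.loc[p]
            return epd_to_ebv(prec["epd"]), bif_to_reliability(prec["bif_acc"])

        ebv_s, r2_s = parent_info(sire)
        ebv_d, r2_d = parent_info(dam)
        r2_pa = min(parent_average_reliability(r2_s, r2_d), 0.499)
        ebv_pa = (ebv_s + ebv_d) / 2.0
        try:
            debv, r2_debv = deregress(epd_to_ebv(rec["epd"]), r2, ebv_pa, r2_pa, h2)
        except DeregressionError:
            n_dropped += 1
            continue
        out.append(
            {
                "animal": animal,
                "trait": trait,
                "debv": debv,
                "r2_debv": r2_debv,
                "weight": debv_weight(r2_debv, c=c, h2=h2),
                "h2": h2,
            }
        )
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} uninformative records for trait {trait!r}", stacklevel=2
        )
    return pd.DataFrame(out, columns=["animal", "trait", "debv", "r2_debv", "weight", "h2"])
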