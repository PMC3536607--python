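"""Marker quality control, panel harmonization and mean imputation.

Genotypes are B-allele dosages on a 0-2 scale with NaN marking a missing
call.  QC keeps markers with call rate >= 0.95, minor allele frequency
>= 0.005 and Hardy-Weinberg chi-square p-value > 1e-30 (all thresholds
configurable); missing calls on retained markers are replaced by the
marker's mean dosage over non-missing animals, so imputed dosages may be
fractional.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "QCThresholds",
    "harmonize_panels",
    "compute_marker_stats",
    "filter_markers",
    "impute_missing",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_plink",
    "write_plink",
]

MARKER_COLUMNS = ["name", "chromosome", "position", "panel"]


@dataclass
class GenotypeMatrix:
    """Animals x markers dosage matrix with marker metadata.

    ``dosages`` is float64 with entries in {0, 1, 2, NaN} before imputation
    (fractional after mean imputation).  ``markers`` is a frame with columns
    name/chromosome/position/panel aligned to the dosage columns.
    """

    animal_ids: np.ndarray
    markers: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.animal_ids = np.asarray(self.animal_ids)
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.shape != (len(self.animal_ids), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.animal_ids)} animals x {len(self.markers)} markers"
            )
        if len(set(self.animal_ids)) != len(self.animal_ids):
            raise ValueError("duplicate animal ids in genotype matrix")
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and (obs.min() < 0 or obs.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_names(self) -> np.ndarray:
        return self.markers["name"].to_numpy()

    def has_missing(self) -> bool:
        return bool(np.isnan(self.dosages).any())

    def select_markers(self, mask_or_names) -> "GenotypeMatrix":
        if isinstance(mask_or_names, (list, tuple, pd.Index)) or (
            isinstance(mask_or_names, np.ndarray) and mask_or_names.dtype.kind in "UOS"
        ):
            pos = {n: i for i, n in enumerate(self.markers["name"])}
            idx = np.asarray([pos[n] for n in mask_or_names], dtype=np.int64)
        else:
            idx = np.flatnonzero(np.asarray(mask_or_names))
        return GenotypeMatrix(
            animal_ids=self.animal_ids,
            markers=self.markers.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[:, idx],
        )

    def select_animals(self, ids: Sequence) -> "GenotypeMatrix":
        pos = {a: i for i, a in enumerate(self.animal_ids)}
        idx = np.asarray([pos[a] for a in ids], dtype=np.int64)
        return GenotypeMatrix(
            animal_ids=np.asarray(ids), markers=self.markers, dosages=self.dosages[idx]
        )


@dataclass(frozen=True)
class QCThresholds:
    min_call_rate: float = 0.95
    min_maf: float = 0.005
    min_hwe_p: float = 1e-30

    def validate(self) -> None:
        for name in ("min_call_rate", "min_maf", "min_hwe_p"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def harmonize_panels(panels: Sequence[GenotypeMatrix]) -> GenotypeMatrix:
    """Merge genotype panels on the intersection of marker names.

    Marker order follows the first panel; animals are concatenated across
    panels.  Allele orientation is assumed consistent across panels (the
    writers in this package always emit B-allele dosages on a common
    orientation); duplicate animal ids across panels are an error.
    """
    if not panels:
        raise ValueError("harmonize_panels requires at least one panel")
    common = set(panels[0].markers["name"])
    for p in panels[1:]:
        common &= set(p.markers["name"])
    if not common:
        raise ValueError("no markers shared across all panels")
    order = [n for n in panels[0].markers["name"] if n in common]
    seen: set = set()
    for p in panels:
        dup = seen & set(p.animal_ids)
        if dup:
            raise ValueError(f"animal ids present in more than one panel: {sorted(dup)[:5]}")
        seen |= set(p.animal_ids)
    parts = [p.select_markers(order) for p in panels]
    return GenotypeMatrix(
        animal_ids=np.concatenate([p.animal_ids for p in parts]),
        markers=parts[0].markers.copy(),
        dosages=np.vstack([p.dosages for p in parts]),
    )


def _hwe_pvalue(n0: int, n1: int, n2: int) -> float:
    """Pearson 1-df chi-square HWE test at the observed allele frequency.

    Monomorphic markers (p in {0, 1}) get p-value 1; they are removed by the
    MAF criterion instead.
    """
    n = n0 + n1 + n2
    if n == 0:
        return np.nan
    p = (n1 + 2 * n2) / (2 * n)
    if p == 0.0 or p == 1.0:
        return 1.0
    q = 1.0 - p
    expected = np.array([q * q, 2 * p * q, p * p]) * n
    observed = np.array([n0, n1, n2], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def compute_marker_stats(G: GenotypeMatrix, thresholds: QCThresholds | None = None) -> pd.DataFrame:
    """Per-marker call rate, MAF and HWE p-value, with pass flags.

    Computed on pre-imputation dosages.  All-missing markers get call_rate 0
    and missing maf / hwe_p, and fail overall.
    """
    thresholds = thresholds or QCThresholds()
    thresholds.validate()
    X = G.dosages
    n = G.n_animals
    observed = ~np.isnan(X)
    n_obs = observed.sum(axis=0)
    call_rate = n_obs / n
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        p = np.nanmean(X, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    maf[n_obs == 0] = np.nan
    hwe = np.empty(G.n_markers)
    for j in range(G.n_markers):
        col = X[observed[:, j], j]
        n1 = int((col == 1).sum())
        n2 = int((col == 2).sum())
        n0 = len(col) - n1 - n2
        hwe[j] = _hwe_pvalue(n0, n1, n2)
    report = pd.DataFrame(
        {
            "name": G.marker_names,
            "call_rate": call_rate,
            "maf": maf,
            "hwe_p": hwe,
        }
    )
    report["pass_call_rate"] = report["call_rate"] >= thresholds.min_call_rate
    report["pass_maf"] = report["maf"] >= thresholds.min_maf
    report["pass_hwe"] = report["hwe_p"] > thresholds.min_hwe_p
    # NaN comparisons are False, so all-missing markers fail all criteria
    report["pass"] = report["pass_call_rate"] & report["pass_maf"] & report["pass_hwe"]
    return report


def filter_markers(
    G: GenotypeMatrix,
    report: pd.DataFrame | None = None,
    thresholds: QCThresholds | None = None,
) -> GenotypeMatrix:
    """Keep markers passing all three QC criteria, preserving order."""
    thresholds = thresholds or QCThresholds()
    thresholds.validate()
    if report is None:
        report = compute_marker_stats(G, thresholds)
    if len(report) != G.n_markers or not (report["name"].to_numpy() == G.marker_names).all():
        raise ValueError("QC report is not aligned to the genotype matrix")
    keep = (
        (report["call_rate"] >= thresholds.min_call_rate)
        & (report["maf"] >= thresholds.min_maf)
        & (report["hwe_p"] > thresholds.min_hwe_p)
    ).to_numpy()
    return G.select_markers(keep)


def impute_missing(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing call with its marker's mean observed dosage."""
    X = G.dosages.copy()
    missing = np.isnan(X)
    if not missing.any():
        return GenotypeMatrix(animal_ids=G.animal_ids, markers=G.markers.copy(), dosages=X)
    all_missing = missing.all(axis=0)
    if all_missing.any():
        bad = G.marker_names[all_missing]
        raise ValueError(f"markers with no observed calls cannot be imputed: {list(bad[:5])}")
    means = np.nanmean(X, axis=0)
    rows, cols = np.nonzero(missing)
    X[rows, cols] = means[cols]
    return GenotypeMatrix(animal_ids=G.animal_ids, markers=G.markers.copy(), dosages=X)


# ---------------------------------------------------------------------------
# file formats


def write_matrix_tsv(G: GenotypeMatrix, path) -> None:
    frame = pd.DataFrame(G.dosages, index=G.animal_ids, columns=G.marker_names)
    frame.index.name = "animal"
    frame.to_csv(path, sep="\t", na_rep="NA")


def read_matrix_tsv(path, markers: pd.DataFrame | None = None, panel: str = "tsv") -> GenotypeMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if markers is None:
        markers = pd.DataFrame(
            {
                "name": frame.columns,
                "chromosome": "0",
                "position": np.arange(1, frame.shape[1] + 1),
                "panel": panel,
            }
        )
    return GenotypeMatrix(
        animal_ids=frame.index.to_numpy(), markers=markers, dosages=frame.to_numpy(dtype=float)
    )


def write_plink(G: GenotypeMatrix, prefix) -> None:
    """PLINK-style .ped/.map with A/B allele letters; missing written 0 0.

    Fractional (imputed) dosages cannot be represented and are an error.
    """
    frac = ~np.isnan(G.dosages) & (G.dosages != np.round(G.dosages))
    if frac.any():
        raise ValueError("cannot write fractional (imputed) dosages to .ped")
    geno_strings = {0: "A A", 1: "A B", 2: "B B"}
    with open(f"{prefix}.map", "w") as out:
        for _, m in G.markers.iterrows():
            out.write(f"{m['chromosome']}\t{m['name']}\t0\t{m['position']}\n")
    with open(f"{prefix}.ped", "w") as out:
        for i, animal in enumerate(G.animal_ids):
            fields = ["FAM", str(animal), "0", "0", "0", "-9"]
            for dose in G.dosages[i]:
                fields.append("0 0" if np.isnan(dose) else geno_strings[int(dose)])
            out.write("\t".join(fields) + "\n")


def read_plink(prefix, panel: str = "plink") -> GenotypeMatrix:
    mp = pd.read_csv(
        f"{prefix}.map", sep="\t", header=None, names=["chromosome", "name", "cm", "position"]
    )
    markers = pd.DataFrame(
        {"name": mp["name"], "chromosome": mp["chromosome"].astype(str), "position": mp["position"], "panel": panel}
    )
    animals = []
    rows = []
    with open(f"{prefix}.ped") as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            animals.append(fields[1])
            row = np.empty(len(markers))
            for j, cell in enumerate(fields[6:]):
                a, b = cell.split()
                if a == "0" or b == "0":
                    row[j] = np.nan
                else:
                    row[j] = (a == "B") + (b == "B")
            rows.append(row)
    ids: list = []
    for a in animals:  # restore integer ids where possible
        try:
            ids.append(int(a))
        except ValueError:
            ids.append(a)
    return GenotypeMatrix(animal_ids=np.asarray(ids), markers=markers, dosages=np.vstack(rows))
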