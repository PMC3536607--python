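"""Synthetic herds with known truth.

Everything downstream of this module (deregression, marker-effect training,
cross-validation, bivariate REML) is exercised on herds generated here:

* a multi-generation pedigree in which a small number of sires per
  generation are mated to many dams, producing the large half-sib families
  that give relatedness-based clustering something to find;
* unlinked biallelic SNP genotypes gene-dropped through that pedigree from
  Hardy-Weinberg founders;
* a trait controlled by a sparse subset of loci with a target heritability;
* an emulated national-evaluation output (EPD and BIF accuracy per animal)
  constructed so that each animal's EBV has an assigned reliability, with a
  bimodal reliability mixture mimicking heavily-used AI sires versus
  natural-mating sires.

The generator is fully deterministic under its seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotype_qc import GenotypeMatrix
from .pedigree import Pedigree

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "ConfigurationError",
    "simulate_pedigree",
    "gene_drop",
    "simulate_trait",
    "emulate_evaluation",
    "simulate_herd",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic herd.

    Defaults target a mid-size seed-stock population: moderate founder
    number, heavy sire reuse (8 sires per generation), ~2 offspring per
    mating, a trait of heritability 0.4 controlled by 50 of 1000 markers,
    and EBV reliabilities averaging ~0.55 (the middle of the range reported
    for US beef national-evaluation traits) with a high/low mixture
    emulating AI versus natural-mating sires.
    """

    n_founders: int = 60
    n_generations: int = 4
    n_sires: int = 8
    n_lineages: int = 5
    migration_rate: float = 0.05
    offspring_per_mating: float = 2.0
    n_markers: int = 1000
    n_qtl: int = 50
    founder_allele_freq_range: tuple[float, float] = (0.05, 0.95)
    trait_heritability: float = 0.4
    trait_name: str = "trait"
    target_reliability_mean: float = 0.55
    # reliability mixture: AI-sire-like high component vs natural-mating low
    reliability_high: float = 0.85
    reliability_low: float = 0.40
    high_reliability_fraction: float = 0.25
    first_birth_year: int = 2000
    seed: int = 0

    def validate(self) -> None:
        if self.n_founders < 2:
            raise ConfigurationError("n_founders must be >= 2")
        if self.n_generations < 1:
            raise ConfigurationError("n_generations must be >= 1")
        if self.n_sires < 1:
            raise ConfigurationError("n_sires must be >= 1")
        if self.n_lineages < 1:
            raise ConfigurationError("n_lineages must be >= 1")
        if not 0 <= self.migration_rate <= 1:
            raise ConfigurationError("migration_rate must be in [0, 1]")
        if self.offspring_per_mating <= 0:
            raise ConfigurationError("offspring_per_mating must be positive")
        if self.n_markers < 1:
            raise ConfigurationError("n_markers must be >= 1")
        if not 0 <= self.n_qtl <= self.n_markers:
            raise ConfigurationError("n_qtl must satisfy 0 <= n_qtl <= n_markers")
        lo, hi = self.founder_allele_freq_range
        if not (0 <= lo <= hi <= 1):
            raise ConfigurationError("founder_allele_freq_range must be an ordered pair in [0, 1]")
        if not 0 < self.trait_heritability < 1:
            raise ConfigurationError("trait_heritability must be in (0, 1)")
        for name in ("target_reliability_mean", "reliability_high", "reliability_low"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ConfigurationError(f"{name} must be in [0, 1)")
        if not 0 <= self.high_reliability_fraction <= 1:
            raise ConfigurationError("high_reliability_fraction must be in [0, 1]")

@dataclass
class TruthSet:
    """Simulated truth: per-animal TBV, per-marker QTL effects, variances."""

    animal_ids: np.ndarray
    true_breeding_value: np.ndarray
    qtl_effects: np.ndarray  # length = n_markers, zero off-QTL
    true_genetic_variance: float
    true_residual_variance: float

    def tbv_series(self) -> pd.Series:
        return pd.Series(self.true_breeding_value, index=self.animal_ids, name="tbv")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"animal": self.animal_ids, "tbv": self.true_breeding_value}
        ).to_csv(path, index=False)


def _hash_stream(seed: int, stream: str) -> np.random.Generator:
    # stable across processes: do not rely on PYTHONHASHSEED
    h = np.int64(0)
    for ch in stream:
        h = np.int64((int(h) * 131 + ord(ch)) % (2**31 - 1))
    ss = np.random.SeedSequence([int(seed) % (2**31), int(h)])
    return np.random.Generator(np.random.PCG64(ss))


def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Multi-generation pedigree with lineage and half-sib structure.

    Founders (generation 0, unknown parents) are split evenly by sex and
    round-robin into ``n_lineages`` sub-populations (herd lines).  In each
    later generation and lineage, up to ``n_sires`` males of the previous
    generation are drawn as service sires and every previous-generation
    female of the lineage is mated to one of them — to a sire from a random
    other lineage with probability ``migration_rate`` — leaving 1 +
    Poisson(offspring_per_mating - 1) offspring that stay in the dam's
    lineage.  Sire reuse creates large paternal half-sib families; the
    lineages keep between-family relatedness low, the structure
    relatedness-based clustering relies on.  Birth years advance one per
    generation.
    """
    config.validate()
    rng = _hash_stream(config.seed, "pedigree")
    records: list[tuple] = []
    next_id = 1
    L = config.n_lineages
    males: list[list[int]] = [[] for _ in range(L)]
    females: list[list[int]] = [[] for _ in range(L)]
    for i in range(config.n_founders):
        sex = "M" if rng.random() < 0.5 else "F"
        lin = i % L
        records.append((next_id, 0, 0, config.first_birth_year, sex))
        (males[lin] if sex == "M" else females[lin]).append(next_id)
        next_id += 1
    for lin in range(L):  # guarantee each lineage can breed
        if not males[lin]:
            donor = max(range(L), key=lambda j: len(males[j]))
            if males[donor]:
                males[lin].append(males[donor][-1])
        if not females[lin]:
            donor = max(range(L), key=lambda j: len(females[j]))
            if females[donor]:
                females[lin].append(females[donor][-1])
    for gen in range(1, config.n_generations):
        sires_by_lineage = []
        for lin in range(L):
            pool = np.asarray(males[lin] if males[lin] else sum(males, []))
            k = min(config.n_sires, len(pool))
            sires_by_lineage.append(rng.choice(pool, size=k, replace=False))
        new_m: list[list[int]] = [[] for _ in range(L)]
        new_f: list[list[int]] = [[] for _ in range(L)]
        for lin in range(L):
            for dam in females[lin]:
                source = lin
                if L > 1 and rng.random() < config.migration_rate:
                    source = int(rng.choice([j for j in range(L) if j != lin]))
                sires = sires_by_lineage[source]
                sire = int(sires[rng.integers(len(sires))])
                n_off = 1 + rng.poisson(max(config.offspring_per_mating - 1.0, 0.0))
                for _ in range(n_off):
                    sex = "M" if rng.random() < 0.5 else "F"
                    records.append((next_id, sire, dam, config.first_birth_year + gen, sex))
                    (new_m[lin] if sex == "M" else new_f[lin]).append(next_id)
                    next_id += 1
        for lin in range(L):
            if new_m[lin]:
                males[lin] = new_m[lin]
            if new_f[lin]:
                females[lin] = new_f[lin]
    frame = pd.DataFrame(records, columns=["animal", "sire", "dam", "birth_year", "sex"])
    return Pedigree(frame)


def gene_drop(pedigree: Pedigree, config: SimulationConfig) -> GenotypeMatrix:
    """Drop unlinked biallelic SNPs through the pedigree.

    Founders are Hardy-Weinberg draws at per-marker B-allele frequencies
    sampled uniformly from ``founder_allele_freq_range``; each offspring
    receives, independently per marker, one allele sampled uniformly from
    each parent's two alleles.  Dosages are counts of the B allele (0/1/2).
    """
    config.validate()
    rng = _hash_stream(config.seed, "genedrop")
    k = config.n_markers
    lo, hi = config.founder_allele_freq_range
    freqs = rng.uniform(lo, hi, size=k)
    order, sire, dam = pedigree.parent_indices()
    n = len(pedigree)
    # two allele slots per animal per marker
    alleles = np.zeros((n, 2, k), dtype=np.int8)
    for rank in range(n):
        s, d = sire[rank], dam[rank]
        if s < 0:
            alleles[rank, 0] = rng.random(k) < freqs
        else:
            pick = rng.integers(0, 2, size=k)
            alleles[rank, 0] = alleles[s, pick, np.arange(k)]
        if d < 0:
            alleles[rank, 1] = rng.random(k) < freqs
        else:
            pick = rng.integers(0, 2, size=k)
            alleles[rank, 1] = alleles[d, pick, np.arange(k)]
    dosages = alleles.sum(axis=1).astype(np.float64)
    topo_ids = pedigree.frame["animal"].to_numpy()[order]
    # return in pedigree order
    pos = {a: i for i, a in enumerate(topo_ids)}
    ped_ids = pedigree.animals
    dosages = dosages[[pos[a] for a in ped_ids]]
    markers = pd.DataFrame(
        {
            "name": [f"snp{j + 1}" for j in range(k)],
            "chromosome": ["1"] * k,
            "position": np.arange(1, k + 1) * 1000,
            "panel": ["sim"] * k,
        }
    )
    return GenotypeMatrix(animal_ids=np.asarray(ped_ids), markers=markers, dosages=dosages)


def simulate_trait(genotypes: GenotypeMatrix, config: SimulationConfig) -> TruthSet:
    """Sparse additive trait: n_qtl markers with normal effects.

    TBV_i = sum_j z_ij * effect_j, centered.  The residual variance is set
    from the realized TBV variance so that Var(TBV) / (Var(TBV) +
    Var(residual)) equals the configured heritability.
    """
    config.validate()
    rng = _hash_stream(config.seed, "trait")
    k = genotypes.n_markers
    effects = np.zeros(k)
    if config.n_qtl > 0:
        poly = genotypes.dosages.std(axis=0) > 0
        candidates = np.flatnonzero(poly)
        if len(candidates) < config.n_qtl:
            warnings.warn(
                "monomorphic markers reduced the QTL candidate pool; "
                "sampling QTL from polymorphic markers only",
                stacklevel=2,
            )
            if len(candidates) == 0:
                candidates = np.arange(k)
        qtl = rng.choice(candidates, size=min(config.n_qtl, len(candidates)), replace=False)
        effects[qtl] = rng.standard_normal(len(qtl))
    g = genotypes.dosages @ effects
    tbv = g - g.mean()
    var_g = float(np.var(tbv))
    h2 = config.trait_heritability
    var_e = var_g * (1.0 - h2) / h2 if var_g > 0 else 1.0
    return TruthSet(
        animal_ids=np.asarray(genotypes.animal_ids),
        true_breeding_value=tbv,
        qtl_effects=effects,
        true_genetic_variance=var_g if var_g > 0 else 0.0,
        true_residual_variance=var_e,
    )


def _assign_reliabilities(pedigree: Pedigree, config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Heterogeneous target reliabilities r^2 per animal.

    Sires with many recorded offspring (AI-like) draw from the high
    component; everyone else from a low/high mixture whose mean is nudged to
    the configured target.  Values are clipped inside (0.02, 0.98).
    """
    ids = pedigree.animals
    n_offspring = pd.Series(0, index=ids, dtype=int)
    sire_counts = pedigree.frame["sire"].value_counts()
    for a, cnt in sire_counts.items():
        if a in n_offspring.index:
            n_offspring[a] = int(cnt)
    heavy = (n_offspring >= 10).to_numpy()
    base_high = rng.random(len(ids)) < config.high_reliability_fraction
    use_high = heavy | base_high
    r2 = np.where(
        use_high,
        rng.normal(config.reliability_high, 0.05, size=len(ids)),
        rng.normal(config.reliability_low, 0.08, size=len(ids)),
    )
    # nudge the overall mean toward the configured target
    shift = config.target_reliability_mean - float(np.mean(r2))
    r2 = r2 + np.clip(shift, -0.15, 0.15)
    return np.clip(r2, 0.02, 0.98)


def emulate_evaluation(
    truth: TruthSet,
    pedigree: Pedigree,
    config: SimulationConfig,
    reliabilities: np.ndarray | None = None,
) -> pd.DataFrame:
    """Emulated national-evaluation table (animal, trait, epd, bif_acc).

    EBV are built recursively in pedigree order so that each animal's EBV
    *contains* its parents' EBV, as a real evaluation's does:

        EBV_i = PA_EBV_i + beta_i (m_i + delta_i),

    where PA_EBV is the mean of the parents' emulated EBV (zero if both
    unknown), m_i = TBV_i - PA_TBV_i is the Mendelian-sampling deviation,
    delta_i is noise, and beta_i is the shrinkage that makes the achieved
    reliability equal the assigned target r2_i (clamped to the attainable
    range [r2_PA, r2_PA + Var(m)/Var(TBV)]).  Founders reduce to
    EBV = r2 * TBV + noise with Var(noise) = r2 (1 - r2) Var(TBV); in both
    cases corr(EBV, TBV)^2 = r2 in expectation.  EPD = EBV / 2 and the BIF
    accuracy is back-derived from the achieved reliability as
    1 - sqrt(1 - r2).  An assigned reliability of exactly 0 yields a pure
    noise EBV.
    """
    config.validate()
    rng = _hash_stream(config.seed, "evaluation")
    if reliabilities is None:
        reliabilities = _assign_reliabilities(pedigree, config, rng)
    r2_target = pd.Series(np.asarray(reliabilities, dtype=float), index=pedigree.animals)
    if ((r2_target < 0) | (r2_target >= 1)).any():
        raise ConfigurationError("reliabilities must lie in [0, 1)")
    tbv = truth.tbv_series().reindex(pedigree.animals)
    var_t = truth.true_genetic_variance if truth.true_genetic_variance > 0 else 1.0
    order, _, _ = pedigree.parent_indices()
    topo_ids = pedigree.animals[order]
    ebv = pd.Series(0.0, index=pedigree.animals)
    r2_achieved = pd.Series(0.0, index=pedigree.animals)
    for a in topo_ids:
        target = float(r2_target[a])
        if target == 0.0:
            ebv[a] = rng.standard_normal() * np.sqrt(var_t)
            r2_achieved[a] = 0.0
            continue
        sire, dam = pedigree.parents_of(a)
        known = [p for p in (sire, dam) if p is not None]
        pa_ebv = sum(ebv[p] for p in known) / 2.0
        pa_tbv = sum(tbv[p] for p in known) / 2.0
        r2_pa = sum(r2_achieved[p] for p in known) / 4.0
        var_m = var_t * (1.0 - 0.25 * len(known))  # Mendelian-sampling variance
        m = float(tbv[a]) - pa_tbv
        # beta * var_m / var_t is the reliability added by own information
        beta = np.clip((target - r2_pa) * var_t / var_m, 1e-4, 1.0)
        delta = rng.standard_normal() * np.sqrt(var_m * (1.0 - beta) / beta)
        ebv[a] = pa_ebv + beta * (m + delta)
        r2_achieved[a] = r2_pa + beta * var_m / var_t
    bif = 1.0 - np.sqrt(1.0 - r2_achieved.to_numpy())
    return pd.DataFrame(
        {
            "animal": pedigree.animals,
            "trait": config.trait_name,
            "epd": ebv.to_numpy() / 2.0,
            "bif_acc": bif,
        }
    )


@dataclass
class SyntheticHerd:
    """Bundle of all simulated artifacts for one herd."""

    config: SimulationConfig
    pedigree: Pedigree
    genotypes: GenotypeMatrix
    truth: TruthSet
    evaluation: pd.DataFrame


def simulate_herd(config: SimulationConfig) -> SyntheticHerd:
    """Pedigree -> gene drop -> trait -> evaluation, one call."""
    ped = simulate_pedigree(config)
    geno = gene_drop(ped, config)
    truth = simulate_trait(geno, config)
    evaluation = emulate_evaluation(truth, ped, config)
    return SyntheticHerd(config=config, pedigree=ped, genotypes=geno, truth=truth, evaluation=evaluation)
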