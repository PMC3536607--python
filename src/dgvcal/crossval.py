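"""K-fold cross-validation over relatedness-clustered groups, and the
end-to-end pipeline.

Each fold trains the marker-effect model on the deregressed EBV of every
animal *outside* one cluster group and predicts DGV for the animals inside
it, so every genotyped animal receives a DGV computed without its own
record.  Fold seeds are derived deterministically from the master seed, so
folds are reproducible in isolation and independent of execution order.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import bayesc, bivariate, clustering, deregression, efficiency, genotype_qc, pedigree, simdata

logger = logging.getLogger("dgvcal")

__all__ = ["CrossValResult", "run_crossval", "fold_seed", "run_pipeline", "PipelineResult"]


def fold_seed(master_seed: int, fold: int) -> int:
    """Deterministic per-fold seed derived from (master seed, fold id)."""
    return int(
        np.random.SeedSequence([int(master_seed) % (2**31), int(fold)]).generate_state(1)[0]
        % (2**31 - 1)
    )


@dataclass
class FoldFit:
    group: int
    n_train: int
    n_validate: int
    training_ids: np.ndarray
    effects: bayesc.MarkerEffectEstimates


@dataclass
class CrossValResult:
    """DGV for every genotyped animal, tagged with its validation group."""

    trait: str
    dgv: pd.DataFrame  # animal, dgv, group
    folds: list

    def training_checksums(self) -> dict:
        """Sorted-training-id checksums per fold, for leakage audits."""
        import hashlib

        out = {}
        for f in self.folds:
            h = hashlib.sha256()
            for a in sorted(map(str, f.training_ids)):
                h.update(a.encode())
                h.update(b"|")
            out[f.group] = h.hexdigest()
        return out


def run_crossval(
    debv: pd.DataFrame,
    genotypes: genotype_qc.GenotypeMatrix,
    assignment: clustering.ClusterAssignment,
    config: bayesc.BayesCConfig,
) -> CrossValResult:
    """Train on k-1 groups, predict the held-out group, for every group.

    All genotyped animals in the held-out group are predicted (a DGV needs
    only genotypes), including those lacking a DEBV; the latter are excluded
    from downstream bivariate fitting by the animal-matching there.
    """
    config.validate()
    if assignment.k < 2:
        raise ValueError("cross-validation needs at least 2 groups")
    not_covered = set(genotypes.animal_ids) - set(assignment.ids)
    if not_covered:
        raise ValueError(f"genotyped animals without a group: {sorted(map(str, not_covered))[:5]}")
    trait = debv["trait"].iloc[0] if "trait" in debv.columns and len(debv) else "trait"
    group_of = assignment.as_mapping()
    debv = debv[debv["animal"].isin(set(genotypes.animal_ids))]
    folds = []
    predictions = []
    for g in range(1, assignment.k + 1):
        val_ids = [a for a in genotypes.animal_ids if group_of[a] == g]
        train = debv[[group_of[a] != g for a in debv["animal"]]]
        if len(train) == 0:
            warnings.warn(f"fold {g}: no training records; fold skipped", stacklevel=2)
            continue
        cfg_g = replace(config, seed=fold_seed(config.seed, g))
        logger.info("fold %d: training n=%d, validating n=%d", g, len(train), len(val_ids))
        effects = bayesc.train_bayesc(train, genotypes, cfg_g)
        pred = bayesc.predict_dgv(genotypes.select_animals(val_ids), effects, group=g)
        predictions.append(pred)
        folds.append(
            FoldFit(
                group=g,
                n_train=len(train),
                n_validate=len(val_ids),
                training_ids=train["animal"].to_numpy(),
                effects=effects,
            )
        )
    dgv = pd.concat(predictions, ignore_index=True)
    return CrossValResult(trait=trait, dgv=dgv, folds=folds)


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclass
class PipelineResult:
    herd: simdata.SyntheticHerd
    genotypes: genotype_qc.GenotypeMatrix  # post-QC, imputed
    qc_report: pd.DataFrame
    debv: pd.DataFrame
    relationships: pedigree.RelationshipMatrix
    assignment: clustering.ClusterAssignment
    quality: pedigree.AmaxReport
    crossval: CrossValResult
    estimates: bivariate.BivariateEstimates
    efficiency_table: pd.DataFrame
    manifest: dict


def run_pipeline(
    sim_config: simdata.SimulationConfig,
    bayes_config: bayesc.BayesCConfig | None = None,
    k_groups: int = 5,
    restarts: int = 10,
    c: float = deregression.DEFAULT_C,
    weight_side: str = "debv",
    out_dir=None,
) -> PipelineResult:
    """simulate -> qc -> deregress -> cluster -> crossval -> bivariate ->
    efficiency, on one synthetic herd.

    The master seed is ``sim_config.seed``; every stage derives its own
    stream from it.  When ``out_dir`` is given, per-stage artifacts and a
    run manifest are written there.
    """
    seed = sim_config.seed
    herd = simdata.simulate_herd(sim_config)
    trait = sim_config.trait_name
    h2 = sim_config.trait_heritability

    qc_report = genotype_qc.compute_marker_stats(herd.genotypes)
    filtered = genotype_qc.filter_markers(herd.genotypes, qc_report)
    imputed = genotype_qc.impute_missing(filtered)

    debv = deregression.deregress_table(herd.evaluation, herd.pedigree, trait, h2=h2, c=c)

    A = pedigree.build_nrm(herd.pedigree, ids=list(imputed.animal_ids))
    D = clustering.difference_matrix(A)
    assignment = clustering.kmeans_groups(
        D, k=k_groups, restarts=restarts, seed=fold_seed(seed, 10_001), ids=imputed.animal_ids
    )
    quality = clustering.clustering_quality(assignment, A)

    bayes_config = bayes_config or bayesc.BayesCConfig(chain_length=4000, burn_in=500)
    bayes_config = replace(bayes_config, seed=fold_seed(seed, 20_002))
    bayes_config = bayesc.initialize_priors(debv, imputed, bayes_config)
    cv = run_crossval(debv, imputed, assignment, bayes_config)

    G = bivariate.build_block_relationship(A, assignment)
    estimates = bivariate.fit_bivariate_reml(debv, cv.dgv, G, weight_side=weight_side)

    pa = efficiency.cohort_pa_reliability(
        herd.evaluation, herd.pedigree, list(imputed.animal_ids), trait
    )
    eff = efficiency.efficiency_report({trait: estimates}, {trait: pa})

    manifest = {
        "seed": seed,
        "trait": trait,
        "n_animals": int(imputed.n_animals),
        "n_markers_pre_qc": int(herd.genotypes.n_markers),
        "n_markers_post_qc": int(imputed.n_markers),
        "n_debv": int(len(debv)),
        "k_groups": int(k_groups),
        "group_sizes": assignment.group_sizes.to_dict(),
        "fold_training_checksums": cv.training_checksums(),
        "bayesc": {
            "pi": bayes_config.pi,
            "chain_length": bayes_config.chain_length,
            "burn_in": bayes_config.burn_in,
        },
        "estimates": {
            k: (v if not isinstance(v, dict) else v)
            for k, v in estimates.to_dict().items()
            if k != "se"
        },
    }
    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        herd.pedigree.to_csv(out / "pedigree.csv")
        genotype_qc.write_matrix_tsv(imputed, out / "genotypes_imputed.tsv")
        qc_report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
        debv.to_csv(out / "debv.tsv", sep="\t", index=False)
        assignment.to_tsv(out / "assignment.tsv")
        quality.to_tsv(out / "amax_quality.tsv")
        cv.dgv.to_csv(out / "dgv.tsv", sep="\t", index=False)
        eff.to_csv(out / "efficiency.tsv", sep="\t", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return PipelineResult(
        herd=herd,
        genotypes=imputed,
        qc_report=qc_report,
        debv=debv,
        relationships=A,
        assignment=assignment,
        quality=quality,
        crossval=cv,
        estimates=estimates,
        efficiency_table=eff,
        manifest=manifest,
    )
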