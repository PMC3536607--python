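"""Weighted BayesC: Gibbs sampling of SNP effects and genomic prediction.

The training model for a deregressed-EBV response y is

    y_i = mu + sum_j z_ij u_j + e_i,

with z_ij the B-allele dosage, u_j = 0 with probability pi and
u_j ~ N(0, sigma_u^2) otherwise, and heterogeneous residuals
Var(e_i) = sigma_e^2 / w_i where w_i is the record's information weight.
Both variances carry scaled-inverse-chi-square priors.  A single-site Gibbs
sampler draws, per sweep: each marker's inclusion indicator from its
marginalized conditional odds and its effect from the Gaussian full
conditional; the intercept; and the two variances from their
scaled-inverse-chi-square full conditionals.

The direct genomic value of an animal is the dosage-weighted sum of
posterior-mean marker effects, DGV_i = sum_j z_ij uhat_j (no intercept: a
constant shift is irrelevant to the correlations and variance components
estimated downstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit

from .genotype_qc import GenotypeMatrix

__all__ = [
    "BayesCConfig",
    "MarkerEffectEstimates",
    "train_bayesc",
    "initialize_priors",
    "predict_dgv",
]


@dataclass(frozen=True)
class BayesCConfig:
    """Sampler settings; chain defaults follow routine national-scale runs.

    Tests and the bundled pipeline use much shorter chains; posterior-mean
    checks are Monte-Carlo-error aware.
    """

    pi: float = 0.95
    chain_length: int = 41_000
    burn_in: int = 1_000
    prior_df_genetic: float = 4.0
    prior_df_residual: float = 4.0
    prior_scale_genetic: float | None = None  # per-marker effect variance scale
    prior_scale_residual: float | None = None
    estimate_variances: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.pi < 1:
            raise ValueError("pi must be in [0, 1)")
        if self.burn_in >= self.chain_length:
            raise ValueError("burn_in must be smaller than chain_length")
        if self.chain_length < 2:
            raise ValueError("chain_length must be >= 2")


@dataclass
class MarkerEffectEstimates:
    """Posterior summaries from one training run."""

    marker_names: np.ndarray
    intercept: float
    effects: np.ndarray
    inclusion_freq: np.ndarray
    sigma2_u: float
    sigma2_e: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": self.marker_names,
                "posterior_mean": self.effects,
                "inclusion_freq": self.inclusion_freq,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@njit(cache=True)
def _gibbs(Z, y, w, pi, nu_u, scale_u, nu_e, scale_e, n_iter, burn_in, seed, estimate_variances, s2u0, s2e0):
    n, k = Z.shape
    np.random.seed(seed)
    u = np.zeros(k)
    delta = np.zeros(k, dtype=np.int64)
    mu = 0.0
    for i in range(n):
        mu += w[i] * y[i]
    sw = w.sum()
    mu /= sw
    e = y - mu  # residual vector maintained incrementally
    s2u = s2u0
    s2e = s2e0
    zwz = np.zeros(k)
    for j in range(k):
        acc = 0.0
        for i in range(n):
            acc += w[i] * Z[i, j] * Z[i, j]
        zwz[j] = acc
    log_prior_odds = np.log(pi / (1.0 - pi)) if pi > 0.0 else -np.inf
    u_mean = np.zeros(k)
    incl = np.zeros(k)
    mu_mean = 0.0
    s2u_mean = 0.0
    s2e_mean = 0.0
    kept = 0
    for it in range(n_iter):
        for j in range(k):
            if zwz[j] == 0.0:
                continue
            rhs = zwz[j] * u[j]
            for i in range(n):
                rhs += w[i] * Z[i, j] * e[i]
            lam_j = s2e / s2u
            C = zwz[j] + lam_j
            if pi > 0.0:
                log_bf = 0.5 * (np.log(lam_j) - np.log(C)) + 0.5 * rhs * rhs / (s2e * C)
                p_incl = 1.0 / (1.0 + np.exp(log_prior_odds - log_bf))
                include = np.random.random() < p_incl
            else:
                include = True
            old = u[j]
            if include:
                new = rhs / C + np.random.standard_normal() * np.sqrt(s2e / C)
                delta[j] = 1
            else:
                new = 0.0
                delta[j] = 0
            if new != old:
                diff = new - old
                for i in range(n):
                    e[i] -= Z[i, j] * diff
                u[j] = new
        # intercept
        rhs = 0.0
        for i in range(n):
            rhs += w[i] * (e[i] + mu)
        mu_new = rhs / sw + np.random.standard_normal() * np.sqrt(s2e / sw)
        dmu = mu_new - mu
        for i in range(n):
            e[i] -= dmu
        mu = mu_new
        if estimate_variances:
            m = 0
            ssu = 0.0
            for j in range(k):
                if delta[j] == 1:
                    ssu += u[j] * u[j]
                    m += 1
            s2u = (ssu + nu_u * scale_u) / np.random.chisquare(nu_u + m)
            sse = 0.0
            for i in range(n):
                sse += w[i] * e[i] * e[i]
            s2e = (sse + nu_e * scale_e) / np.random.chisquare(nu_e + n)
        if it >= burn_in:
            kept += 1
            mu_mean += mu
            s2u_mean += s2u
            s2e_mean += s2e
            for j in range(k):
                u_mean[j] += u[j]
                incl[j] += delta[j]
    inv = 1.0 / kept
    for j in range(k):
        u_mean[j] *= inv
        incl[j] *= inv
    return u_mean, incl, mu_mean * inv, s2u_mean * inv, s2e_mean * inv


def _seed32(seed: int) -> int:
    return int(np.random.SeedSequence([int(seed) % (2**31), 0xBC]).generate_state(1)[0] % (2**31 - 1))


def _default_scales(y, w, Z, pi):
    """Generic starting scales from the weighted phenotypic variance."""
    vy = float(np.var(y))
    if vy <= 0:
        raise ValueError("zero phenotypic variance: cannot construct priors")
    p = Z.mean(axis=0) / 2.0
    het = float(np.sum(2.0 * p * (1.0 - p)))
    het = max(het, 1e-12)
    frac = max(1.0 - pi, 1e-6)
    scale_u = 0.5 * vy / (frac * het)
    scale_e = 0.5 * vy
    return scale_u, scale_e


def train_bayesc(
    debv: pd.DataFrame,
    genotypes: GenotypeMatrix,
    config: BayesCConfig,
) -> MarkerEffectEstimates:
    """Run the weighted BayesC Gibbs sampler on a training table.

    ``debv`` has columns animal/debv/weight; every animal must be genotyped
    and the genotype matrix must be fully imputed.  Deterministic under
    ``config.seed``.
    """
    config.validate()
    if genotypes.has_missing():
        raise ValueError("genotypes must be imputed before training")
    missing = set(debv["animal"]) - set(genotypes.animal_ids)
    if missing:
        raise ValueError(f"training animals without genotypes: {sorted(missing)[:5]}")
    w = debv["weight"].to_numpy(dtype=float)
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be positive and finite")
    G = genotypes.select_animals(debv["animal"].to_numpy())
    y = debv["debv"].to_numpy(dtype=float)
    Z = np.ascontiguousarray(G.dosages)
    scale_u, scale_e = config.prior_scale_genetic, config.prior_scale_residual
    if scale_u is None or scale_e is None:
        d_u, d_e = _default_scales(y, w, Z, config.pi)
        scale_u = d_u if scale_u is None else scale_u
        scale_e = d_e if scale_e is None else scale_e
    u_mean, incl, mu, s2u, s2e = _gibbs(
        Z,
        y,
        w,
        float(config.pi),
        float(config.prior_df_genetic),
        float(scale_u),
        float(config.prior_df_residual),
        float(scale_e),
        int(config.chain_length),
        int(config.burn_in),
        _seed32(config.seed),
        config.estimate_variances,
        float(scale_u),
        float(scale_e),
    )
    return MarkerEffectEstimates(
        marker_names=G.marker_names.copy(),
        intercept=float(mu),
        effects=u_mean,
        inclusion_freq=incl,
        sigma2_u=float(s2u),
        sigma2_e=float(s2e),
    )


def initialize_priors(
    debv: pd.DataFrame,
    genotypes: GenotypeMatrix,
    config: BayesCConfig,
    preliminary_chain: int = 2_000,
    preliminary_burn_in: int = 500,
) -> BayesCConfig:
    """Set prior scales from a preliminary full-data fit.

    Runs a short whole-training-set chain starting from generic scales and
    returns a config whose prior scales are that run's posterior means of
    the marker-effect and residual variances.  The per-marker genetic scale
    divides the implied genetic variance by (1 - pi) * sum_j 2 p_j (1 - p_j)
    with the (1 - pi) factor floored at 1e-6.
    """
    pre = replace(
        config,
        chain_length=preliminary_chain,
        burn_in=preliminary_burn_in,
        prior_scale_genetic=None,
        prior_scale_residual=None,
    )
    fit = train_bayesc(debv, genotypes, pre)
    return replace(config, prior_scale_genetic=fit.sigma2_u, prior_scale_residual=fit.sigma2_e)


def predict_dgv(
    genotypes: GenotypeMatrix,
    effects: MarkerEffectEstimates,
    group: int | None = None,
) -> pd.DataFrame:
    """DGV_i = sum_j z_ij * uhat_j for every genotyped animal.

    Marker sets must match exactly and in order; the intercept is excluded.
    """
    if genotypes.n_markers != len(effects.marker_names) or not (
        genotypes.marker_names == effects.marker_names
    ).all():
        ours = set(genotypes.marker_names)
        theirs = set(effects.marker_names)
        diff = sorted((ours ^ theirs)) or ["<order mismatch>"]
        raise ValueError(f"marker sets of genotypes and effects differ: {diff[:5]}")
    if genotypes.has_missing():
        raise ValueError("genotypes must be imputed before prediction")
    dgv = genotypes.dosages @ effects.effects
    out = pd.DataFrame({"animal": genotypes.animal_ids, "dgv": dgv})
    if group is not None:
        out["group"] = group
    return out
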