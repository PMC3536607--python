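"""Bivariate REML: block relationships, estimation, oracle equality."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from dgvcal import simdata
from dgvcal.bivariate import (
    BivariateEstimates,
    build_block_relationship,
    fit_bivariate_reml,
    genetic_correlation,
)
from dgvcal.clustering import ClusterAssignment, difference_matrix, kmeans_groups
from dgvcal.pedigree import build_nrm
from conftest import make_pedigree


# ---------------------------------------------------------------------------
# helpers


def family_structure(n_groups=5, seed=21, n_founders=80, n_generations=5, offspring=2.0):
    cfg = simdata.SimulationConfig(
        n_founders=n_founders, n_generations=n_generations,
        offspring_per_mating=offspring, seed=seed,
    )
    ped = simdata.simulate_pedigree(cfg)
    A = build_nrm(ped)
    ass = kmeans_groups(
        difference_matrix(A), k=n_groups, restarts=8, seed=3, ids=A.ids
    )
    return A, ass, build_block_relationship(A, ass)


def simulate_bivariate(G, rng, sa1=4.0, sa2=1.0, r_g=0.6, se1=6.0, se2=0.25, mu2=10.0):
    """Draw (DEBV, DGV) directly from the fitted model's distribution."""
    n = len(G.ids)
    sa12 = r_g * np.sqrt(sa1 * sa2)
    Sig_chol = np.linalg.cholesky(np.array([[sa1, sa12], [sa12, sa2]]))
    w = rng.uniform(0.5, 2.5, size=n)
    y1 = np.empty(n)
    y2 = np.empty(n)
    start = 0
    for B in G.blocks:
        m = B.shape[0]
        L = np.linalg.cholesky(B + 1e-10 * np.eye(m))
        a = L @ (rng.standard_normal((m, 2)) @ Sig_chol.T)
        y1[start : start + m] = a[:, 0] + rng.standard_normal(m) * np.sqrt(se1 / w[start : start + m])
        y2[start : start + m] = mu2 + a[:, 1] + rng.standard_normal(m) * np.sqrt(se2)
        start += m
    debv = pd.DataFrame({"animal": G.ids, "debv": y1, "weight": w})
    dgv = pd.DataFrame({"animal": G.ids, "dgv": y2})
    return debv, dgv


def dense_reml_negloglik(theta, y, w, Gd, X):
    """Independent restricted log-likelihood: explicit Kronecker V, direct
    slogdet/inverse; shares no code with the fitted implementation."""
    sa1, sa12, sa2, se1, se2 = theta
    m = Gd.shape[0]
    if min(sa1, sa2, se1, se2) <= 0 or sa12**2 >= sa1 * sa2:
        return 1e10
    V = np.kron(np.array([[sa1, sa12], [sa12, sa2]]), Gd)
    V[:m, :m] += np.diag(se1 / w)
    V[m:, m:] += se2 * np.eye(m)
    _, ld = np.linalg.slogdet(V)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    _, ld2 = np.linalg.slogdet(XtViX)
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    return 0.5 * (ld + ld2 + y @ P @ y)


# ---------------------------------------------------------------------------


class TestBlockRelationship:
    def test_k1_equals_A(self, sib_pedigree):
        A = build_nrm(sib_pedigree)
        ass = ClusterAssignment(ids=A.ids, labels=np.ones(len(A.ids), dtype=int), k=1)
        G = build_block_relationship(A, ass)
        np.testing.assert_array_equal(G.dense(), A.values)

    def test_singletons_give_diagonal(self, sib_pedigree):
        A = build_nrm(sib_pedigree)
        ass = ClusterAssignment(ids=A.ids, labels=np.arange(1, len(A.ids) + 1), k=len(A.ids))
        G = build_block_relationship(A, ass)
        np.testing.assert_array_equal(G.dense(), np.diag(np.diag(A.values)))

    def test_matches_double_loop(self):
        cfg = simdata.SimulationConfig(n_founders=8, n_generations=3, seed=13)
        ped = simdata.simulate_pedigree(cfg)
        sub = ped.subset(list(ped.animals[:20]))
        A = build_nrm(sub)
        rng = np.random.default_rng(0)
        labels = rng.integers(1, 4, size=20)
        labels[:3] = [1, 2, 3]
        ass = ClusterAssignment(ids=A.ids, labels=labels, k=3)
        G = build_block_relationship(A, ass)
        dense = G.dense()
        pos = {a: i for i, a in enumerate(G.ids)}
        lab = dict(zip(ass.ids, ass.labels))
        for x in A.ids:
            for y in A.ids:
                expect = A.loc(x, y) if lab[x] == lab[y] else 0.0
                assert dense[pos[x], pos[y]] == pytest.approx(expect)

    def test_mismatch_raises(self, sib_pedigree):
        A = build_nrm(sib_pedigree)
        ass = ClusterAssignment(ids=np.array([1, 2, 99]), labels=np.array([1, 1, 2]), k=2)
        with pytest.raises(ValueError, match="absent"):
            build_block_relationship(A, ass)


class TestGeneticCorrelation:
    def test_printed_variance_rows(self):
        # birth weight and yearling weight variance components reproduce the
        # published correlations at 2 decimals
        assert genetic_correlation((2.80, 0.93, 0.93)) == pytest.approx(0.58, abs=0.005)
        assert genetic_correlation((111.76, 22.82, 38.44)) == pytest.approx(0.76, abs=0.005)

    def test_zero_covariance(self):
        assert genetic_correlation((1.0, 2.0, 0.0)) == 0.0

    def test_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert genetic_correlation((1.0, 1.0, 1.5)) == 1.0

    def test_zero_variance_undefined(self):
        with pytest.raises(ValueError):
            genetic_correlation((0.0, 1.0, 0.5))


class TestFit:
    def test_perfect_correlation_limit(self):
        """DGV duplicated from a noiseless heritable signal: r_g -> 1 and
        h2_dgv -> 1."""
        A, ass, G = family_structure(seed=41)
        rng = np.random.default_rng(8)
        n = len(G.ids)
        start = 0
        gvec = np.empty(n)
        for B in G.blocks:
            m = B.shape[0]
            L = np.linalg.cholesky(B + 1e-10 * np.eye(m))
            gvec[start : start + m] = L @ rng.standard_normal(m) * 2.0
            start += m
        w = np.ones(n)
        debv = pd.DataFrame(
            {"animal": G.ids, "debv": gvec + rng.standard_normal(n) * 1.0, "weight": w}
        )
        dgv = pd.DataFrame({"animal": G.ids, "dgv": gvec})
        est = fit_bivariate_reml(debv, dgv, G)
        assert est.r_g == pytest.approx(1.0, abs=0.02)
        assert est.h2_dgv == pytest.approx(1.0, abs=0.02)

    @pytest.mark.parametrize("data_seed", [12, 7, 31])
    def test_matches_dense_likelihood_oracle_small_n(self, data_seed):
        """n <= 40 fit agrees with direct maximization of an independently
        coded dense restricted likelihood (K = 1, deep family structure)."""
        cfg = simdata.SimulationConfig(
            n_founders=10, n_generations=4, offspring_per_mating=2.2, n_lineages=1, seed=6
        )
        ped = simdata.simulate_pedigree(cfg)
        ids = list(ped.animals)[-38:]
        A = build_nrm(ped, ids=ids)
        ass = ClusterAssignment(ids=A.ids, labels=np.ones(len(ids), dtype=int), k=1)
        G = build_block_relationship(A, ass)
        rng = np.random.default_rng(data_seed)
        debv, dgv = simulate_bivariate(G, rng, sa1=4.0, sa2=2.0, r_g=0.5, se1=2.0, se2=1.5)
        est = fit_bivariate_reml(debv, dgv, G, tol=1e-10, max_iter=400, n_starts=4)
        d1 = debv.set_index("animal").loc[list(G.ids)]
        d2 = dgv.set_index("animal").loc[list(G.ids)]
        m = len(G.ids)
        X = np.zeros((2 * m, 2))
        X[:m, 0] = 1
        X[m:, 1] = 1
        y = np.concatenate([d1["debv"], d2["dgv"]])
        w = d1["weight"].to_numpy()
        best = None
        for x0 in ([2.0, 0.5, 2.0, 2.0, 1.0], [4, 1, 1, 3, 2], [1, 0, 3, 1, 1]):
            res = minimize(
                dense_reml_negloglik,
                np.array(x0, dtype=float),
                args=(y, w, G.dense(), X),
                method="Nelder-Mead",
                options=dict(maxiter=20000, maxfev=20000, xatol=1e-10, fatol=1e-12),
            )
            if best is None or res.fun < best.fun:
                best = res
        assert -best.fun == pytest.approx(est.loglik, abs=1e-4)
        np.testing.assert_allclose(est.params(), best.x, rtol=2e-3, atol=1e-3)

    def test_parameter_recovery_r_g(self):
        """Mean r_g over a few replicates near the simulated 0.6 (the full
        20-replicate check at n ~ 600 lives in the acceptance suite)."""
        _, _, G = family_structure(seed=77, n_founders=140, offspring=1.9)
        rgs = []
        for rep in range(6):
            rng = np.random.default_rng(1000 + rep)
            debv, dgv = simulate_bivariate(G, rng, r_g=0.6)
            est = fit_bivariate_reml(debv, dgv, G)
            rgs.append(est.r_g)
        assert abs(np.mean(rgs) - 0.6) < 0.08  # ~4 Monte-Carlo SE

    def test_likelihood_separable_across_groups(self):
        """With between-group covariances zeroed, the restricted likelihood
        pools per-group likelihoods: dropping the shared intercept coupling
        (fitting each group alone at the same parameter values) sums to the
        full fit's likelihood when the fixed-effect design is per-group."""
        _, _, G = family_structure(seed=33, n_founders=40, n_generations=4)
        rng = np.random.default_rng(3)
        debv, dgv = simulate_bivariate(G, rng, mu2=0.0)
        est = fit_bivariate_reml(debv, dgv, G)
        theta = est.params()
        # evaluate the full restricted likelihood and the per-group sum at
        # the same theta using the independent dense code, with a per-group
        # DEBV intercept so the fixed-effect profile also separates
        total = 0.0
        d1 = debv.set_index("animal")
        d2 = dgv.set_index("animal")
        start = 0
        full_y = []
        full_w = []
        for B in G.blocks:
            m = B.shape[0]
            ids_g = list(G.ids[start : start + m])
            start += m
            y = np.concatenate([d1.loc[ids_g, "debv"], d2.loc[ids_g, "dgv"]])
            w = d1.loc[ids_g, "weight"].to_numpy()
            X = np.zeros((2 * m, 2))
            X[:m, 0] = 1
            X[m:, 1] = 1
            total += -dense_reml_negloglik(theta, y, w, B, X)
            full_y.append((y, w, B, X))
        # full model with block-diagonal everything and per-group intercepts
        mtot = sum(B.shape[0] for B in G.blocks)
        Gd = np.zeros((mtot, mtot))
        ytot = np.concatenate([np.concatenate([fy[0][: fy[2].shape[0]] for fy in full_y]),
                               np.concatenate([fy[0][fy[2].shape[0] :] for fy in full_y])])
        wtot = np.concatenate([fy[1] for fy in full_y])
        pos = 0
        Xtot = np.zeros((2 * mtot, 2 * len(full_y)))
        for gi, (y, w, B, X) in enumerate(full_y):
            m = B.shape[0]
            Gd[pos : pos + m, pos : pos + m] = B
            Xtot[pos : pos + m, 2 * gi] = 1
            Xtot[mtot + pos : mtot + pos + m, 2 * gi + 1] = 1
            pos += m
        full_ll = -dense_reml_negloglik(theta, ytot, wtot, Gd, Xtot)
        assert full_ll == pytest.approx(total, abs=1e-6)

    def test_weight_side_switch_runs(self):
        _, _, G = family_structure(seed=21, n_founders=40, n_generations=4)
        rng = np.random.default_rng(5)
        debv, dgv = simulate_bivariate(G, rng)
        est = fit_bivariate_reml(debv, dgv, G, weight_side="dgv")
        assert est.converged
        with pytest.raises(ValueError):
            fit_bivariate_reml(debv, dgv, G, weight_side="nope")

    def test_standard_errors_finite_and_reasonable(self):
        _, _, G = family_structure(seed=21)
        rng = np.random.default_rng(77)
        debv, dgv = simulate_bivariate(G, rng)
        est = fit_bivariate_reml(debv, dgv, G)
        assert 0 < est.r_g_se < 0.5
        assert np.isfinite(est.h2_dgv_se)
        assert all(np.isfinite(v) for v in est.se.values())
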