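import numpy as np
import pandas as pd
import pytest
from scipy import stats

from helpers import anova_estimates, dense_reml_loglik
from metqtl import (
    GLSSolver, ModelSpec, VarParams, build_design, fa_percent_variance,
    reml_fit, reml_loglik, wald_test,
    simulate_dh_genotypes, simulate_map, simulate_met_phenotypes,
)
from metqtl.dh_simulator import MapSpec, SimConfig, SpatialSpec
from metqtl.mixed_model import FitResult


def _balanced_env(m, r, sg2, se2, seed, mean=10.0):
    rng = np.random.default_rng(seed)
    g = rng.normal(0.0, np.sqrt(sg2), m)
    y = mean + g[:, None] + rng.normal(0.0, np.sqrt(se2), (m, r))
    rows = []
    col = 1
    for i in range(m):
        for k in range(r):
            rows.append({"env": "E1", "line": f"L{i}", "rep": k + 1,
                         "row": 1, "col": col, "value": y[i, k]})
            col += 1
    return pd.DataFrame(rows), [f"L{i}" for i in range(m)], y


def _sim_design(n_lines=25, n_envs=3, seed=0, structure="DIAG", residual="IID",
                rep_effect=False, **cfg_kwargs):
    gmap = simulate_map(MapSpec(1, 50.0, 4), seed=1)
    geno = simulate_dh_genotypes(gmap, n_lines, seed=seed + 1)
    cfg = SimConfig(n_lines=n_lines, n_envs=n_envs, n_reps=2, seed=seed + 2,
                    **cfg_kwargs)
    ph, _ = simulate_met_phenotypes(geno, gmap, cfg)
    spec = ModelSpec(response="yield", genetic_structure=structure,
                     residual=residual, rep_effect=rep_effect)
    return build_design(ph, geno.lines, spec), ph, geno


class TestBuildDesign:
    def test_counts_and_blocks(self):
        d, ph, geno = _sim_design(n_lines=10, n_envs=2)
        assert d.n_obs == 2 * 10 * 2
        assert d.n_envs == 2 and d.n_lines == 10
        for s in d.env_slices:
            assert s.stop - s.start == 20

    def test_control_line_gets_fixed_column(self):
        d, ph, geno = _sim_design(n_lines=8, n_envs=2, n_controls=1)
        assert any(n.startswith("control:") for n in d.fixed_names)
        assert (d.line_idx < 0).sum() == 2 * 2  # control plots, 2 envs x 2 reps

    def test_duplicate_plot_errors(self, balanced_toy):
        ph, lines = balanced_toy
        bad = pd.concat([ph, ph.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            build_design(bad, lines, ModelSpec(response="value"))

    def test_singular_fixed_matrix_names_columns(self, balanced_toy):
        ph, lines = balanced_toy
        ph = ph.copy()
        ph["dup"] = 1.0  # collinear with the environment intercept
        spec = ModelSpec(response="value", covariates=("dup",))
        with pytest.raises(ValueError, match="collinear"):
            build_design(ph, lines, spec)


class TestREMLOracles:
    def test_balanced_toy_anova_equivalence(self, balanced_toy):
        ph, lines = balanced_toy
        fit = reml_fit(build_design(ph, lines, ModelSpec(response="value")))
        assert fit.var_params.sigma2_e[0] == pytest.approx(2.0, abs=1e-6)
        assert fit.var_params.sigma2_g[0] == pytest.approx(15.0, abs=1e-6)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_balanced_interior_matches_anova(self, seed):
        ph, lines, y = _balanced_env(10, 3, sg2=4.0, se2=1.0, seed=seed)
        mse, vg = anova_estimates(y)
        fit = reml_fit(build_design(ph, lines, ModelSpec(response="value")))
        assert fit.var_params.sigma2_e[0] == pytest.approx(mse, rel=1e-6)
        assert fit.var_params.sigma2_g[0] == pytest.approx(vg, rel=1e-6)

    def test_zero_genetic_signal_hits_boundary(self):
        rng = np.random.default_rng(0)
        rows = [{"env": "E1", "line": f"L{i}", "rep": r + 1, "row": 1,
                 "col": i * 2 + r + 1, "value": float(rng.standard_normal())}
                for i in range(12) for r in range(2)]
        ph = pd.DataFrame(rows)
        # every line re-drawn each plot: no line-to-line signal beyond noise
        ph["value"] = rng.permutation(ph["value"].to_numpy())
        fit = reml_fit(build_design(ph, [f"L{i}" for i in range(12)],
                                    ModelSpec(response="value")))
        assert fit.var_params.sigma2_g[0] < 0.05 * fit.var_params.sigma2_e[0]

    @pytest.mark.parametrize("structure,residual,rep", [
        ("DIAG", "IID", False),
        ("DIAG", "AR1", True),
        ("FA", "IID", False),
        ("FA", "AR1", True),
    ])
    def test_loglik_matches_dense_evaluation(self, structure, residual, rep):
        d, _, _ = _sim_design(n_lines=8, n_envs=3, seed=4, structure=structure,
                              residual=residual, rep_effect=rep,
                              spatial=SpatialSpec(4, 4, 0.3, 0.2, 0.8),
                              rep_sigma2=0.2)
        assert d.n_obs <= 50
        kw = dict(rho_row=np.array([0.3, 0.1, 0.2]) if residual == "AR1" else None,
                  rho_col=np.array([0.2, 0.4, 0.1]) if residual == "AR1" else None,
                  sigma2_u=0.3 if rep else None)
        if structure == "DIAG":
            vp = VarParams(np.array([0.5, 0.8, 1.2]),
                           sigma2_g=np.array([0.7, 1.1, 0.4]), **kw)
        else:
            vp = VarParams(np.array([0.5, 0.8, 1.2]),
                           loadings=np.array([[0.6], [0.9], [0.3]]),
                           psi=np.array([0.2, 0.5, 0.3]), **kw)
        assert reml_loglik(d, vp) == pytest.approx(dense_reml_loglik(d, vp), abs=1e-8)

    def test_loglik_trace_non_decreasing(self):
        d, _, _ = _sim_design(n_lines=15, n_envs=2, seed=7)
        fit = reml_fit(d, compute_blups=False)
        assert np.all(np.diff(fit.loglik_trace) >= 0)

    def test_fa_nests_diag(self):
        d, ph, geno = _sim_design(n_lines=30, n_envs=3, seed=9, sigma2_g=1.0)
        diag = reml_fit(d, ModelSpec(response="yield"), compute_blups=False)
        fa = reml_fit(d, ModelSpec(response="yield", genetic_structure="FA"),
                      compute_blups=False)
        assert fa.reml_loglik >= diag.reml_loglik - 1e-4


class TestBLUPsAndPEV:
    def test_pev_diagonal_nonnegative(self, balanced_toy):
        ph, lines = balanced_toy
        fit = reml_fit(build_design(ph, lines, ModelSpec(response="value")))
        assert np.all(np.diag(fit.pev) >= -1e-10)
        assert fit.blups.shape == (1, 3)

    def test_pev_shrinks_with_replication(self):
        out = {}
        for reps in (2, 4):
            rng = np.random.default_rng(11)
            m = 20
            g = rng.normal(0, 1.0, m)
            rows = []
            col = 1
            for i in range(m):
                for r in range(reps):
                    rows.append({"env": "E1", "line": f"L{i}", "rep": r + 1,
                                 "row": 1, "col": col,
                                 "value": g[i] + rng.normal(0, 1.0)})
                    col += 1
            ph = pd.DataFrame(rows)
            fit = reml_fit(build_design(ph, [f"L{i}" for i in range(m)],
                                        ModelSpec(response="value")))
            out[reps] = float(np.mean(np.diag(fit.pev)))
        assert out[4] < out[2]


class TestWald:
    def _fake_fit(self, beta, cov, terms):
        return FitResult(var_params=None, reml_loglik=0.0, beta=np.asarray(beta),
                         cov_beta=np.asarray(cov), fixed_names=[], fixed_terms=terms,
                         blups=None, pev=None, converged=True, n_iter=0,
                         loglik_trace=[], boundary=[], design=None)

    def test_zero_coefficient(self):
        fit = self._fake_fit([0.0], [[4.0]], {"x": [0]})
        W, df, p = wald_test(fit, "x")
        assert W == 0.0 and df == 1 and p == 1.0

    def test_z_of_1_96(self):
        fit = self._fake_fit([1.96], [[1.0]], {"x": [0]})
        W, df, p = wald_test(fit, "x")
        assert W == pytest.approx(3.8416)
        assert p == pytest.approx(0.05, abs=2e-4)

    def test_unknown_term(self):
        fit = self._fake_fit([1.0], [[1.0]], {"x": [0]})
        with pytest.raises(KeyError):
            wald_test(fit, "y")

    def test_null_p_uniform_under_known_variance(self):
        # GLS Wald p-values on a null genetic covariate are Uniform(0, 1)
        # when both the response and the predictor are redrawn per replicate
        d, ph, geno = _sim_design(n_lines=30, n_envs=2, seed=13, sigma2_g=1.0)
        lam, psi = np.full((2, 1), np.sqrt(0.6)), np.full(2, 0.4)
        vp = VarParams(np.ones(2), loadings=lam, psi=psi)
        solver = GLSSolver(d, vp)
        sigma = vp.genetic_cov()
        L = np.linalg.cholesky(sigma)
        rng = np.random.default_rng(5)
        mask = d.line_idx >= 0
        env_of = np.zeros(d.n_obs, dtype=int)
        for j, s in enumerate(d.env_slices):
            env_of[s] = j
        ps = []
        for _ in range(500):
            g = rng.standard_normal((d.n_lines, 2)) @ L.T
            y = rng.standard_normal(d.n_obs)
            y[mask] += g[d.line_idx[mask], env_of[mask]]
            x = rng.choice([-1.0, 1.0], size=d.n_lines)
            xp = np.zeros(d.n_obs)
            xp[mask] = x[d.line_idx[mask]]
            X = np.column_stack([d.X, xp])
            beta, cov = solver.fit_fixed(X, y=y)
            W = beta[-1] ** 2 / cov[-1, -1]
            ps.append(stats.chi2.sf(W, 1))
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestFAPercentVariance:
    def test_examples(self):
        vp = VarParams(np.ones(2), loadings=np.array([[1.0], [1.0]]),
                       psi=np.array([0.25, 0.25]))
        per_env, overall = fa_percent_variance(vp)
        assert overall == pytest.approx(80.0)
        assert per_env == pytest.approx([80.0, 80.0])

        vp = VarParams(np.ones(2), loadings=np.array([[1.0], [2.0]]),
                       psi=np.zeros(2))
        assert fa_percent_variance(vp)[1] == pytest.approx(100.0)

        vp = VarParams(np.ones(2), loadings=np.zeros((2, 1)),
                       psi=np.array([1.0, 1.0]))
        assert fa_percent_variance(vp)[1] == pytest.approx(0.0)

    def test_requires_fa(self):
        with pytest.raises(ValueError):
            fa_percent_variance(VarParams(np.ones(2), sigma2_g=np.ones(2)))
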