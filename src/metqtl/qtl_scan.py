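"""Genome-wide QTL scanning over a fitted MET mixed model.

Pipeline: fit the diagonal genotype-by-environment model, drop trials whose
genetic variance is below 1% of their residual variance, grow the
factor-analytic order until the common factors explain more than 80% of the
between-environment genetic variance, then scan marker-interval genetic
predictors one at a time as fixed effects — a main effect plus a
predictor-by-environment (Q x E) interaction in sum-to-zero environment
coding — testing each with Wald chi-squares at p = 0.01.  Significant
contiguous intervals merge into QTL records; generalised (Cullis)
heritability per environment comes from the prediction error variance of
the genetic BLUPs: h^2 = 1 - mean pairwise PEV / (2 sigma_g^2).

Variance parameters are held at the base-model estimates during the scan
(optionally re-estimated per interval), the standard fast approximation for
one-at-a-time interval testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genmap import GeneticMap, GenotypeMatrix
from .mixed_model import (
    Design, FitResult, GLSSolver, ModelSpec, VarParams,
    build_design, fa_percent_variance, reml_fit,
)
from .predictors import PredictorMatrix, predictor_matrix

__all__ = [
    "ScanConfig", "QTLRecord", "filter_trials", "select_fa_order",
    "genome_scan", "merge_to_qtl", "heritability", "run_pipeline",
    "PipelineResult",
]


@dataclass
class ScanConfig:
    """Thresholds and options of the QTL pipeline."""

    p_threshold: float = 0.01          # Wald significance for main and QxE terms
    fa_target: float = 80.0            # % common variance at which FA order stops
    trial_filter_ratio: float = 0.01   # drop trials with sigma_g^2 < ratio * sigma_e^2
    covariate_markers: tuple = ()
    ci_multiplier: float = 1.96
    refit_variance: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.p_threshold < 1.0) or not (0.0 < self.trial_filter_ratio < 1.0):
            raise ValueError("thresholds must lie in (0, 1)")
        if not (0.0 < self.fa_target <= 100.0):
            raise ValueError("fa_target must lie in (0, 100]")


@dataclass
class QTLRecord:
    """One detected locus, in the style of a MET QTL summary table."""

    name: str
    group: str
    peak_interval: tuple[float, float]
    flanking_markers: tuple[str, str]
    term: str                          # "main" or "QxE"
    p: float
    main_effect: float
    main_se: float
    per_env_effects: list[tuple[str, float, float, bool]]  # env, est, se, significant
    phenology_colocated: bool = False  # overlaps a phenology-trait QTL

    def significant_range(self) -> tuple[float, float] | None:
        sig = [est for _, est, _, s in self.per_env_effects if s]
        if not sig:
            return None
        return (min(sig), max(sig))


def filter_trials(fit: FitResult, trial_filter_ratio: float = 0.01):
    """Apply the low-genetic-variance trial filter to a DIAG fit.

    Environment j is dropped iff sigma_g,j^2 < ratio * sigma_e,j^2.
    Returns (kept envs, list of (env, reason) for dropped ones).
    """
    vp = fit.var_params
    if vp.structure != "DIAG":
        raise ValueError("trial filtering uses the diagonal genetic model")
    kept, dropped = [], []
    for j, env in enumerate(fit.design.envs):
        sg2, se2 = vp.sigma2_g[j], vp.sigma2_e[j]
        if sg2 < trial_filter_ratio * se2:
            dropped.append((env, f"genetic variance {sg2:.4g} < "
                                 f"{trial_filter_ratio:.0%} of residual {se2:.4g}"))
        else:
            kept.append(env)
    if not kept:
        raise ValueError("all trials dropped by the genetic-variance filter")
    return kept, dropped


def select_fa_order(
    design: Design,
    spec: ModelSpec,
    fa_target: float = 80.0,
    diag_fit: FitResult | None = None,
    compute_blups: bool = True,
) -> tuple[int, FitResult]:
    """Grow the FA order until the common-factor variance exceeds the target.

    Fits FA(1), FA(2), ... each initialised from the previous model (FA(1)
    from the diagonal fit), stopping at the first order whose overall
    percent common variance exceeds ``fa_target``, or at J - 1.
    """
    J = design.n_envs
    if J < 2:
        raise ValueError("FA selection needs at least 2 environments")
    if diag_fit is None:
        diag_spec = ModelSpec(**{**spec.__dict__, "genetic_structure": "DIAG"})
        diag_fit = reml_fit(design, diag_spec, compute_blups=False)

    prev = diag_fit.var_params
    fit = None
    for k in range(1, J):
        fa_spec = ModelSpec(**{**spec.__dict__, "genetic_structure": "FA", "fa_order": k})
        init = _fa_init_from(prev, k)
        new_fit = reml_fit(design, fa_spec, init=init, compute_blups=compute_blups)
        if not new_fit.converged and fit is not None:
            warnings.warn(f"FA({k}) did not converge; keeping FA({k - 1})")
            return k - 1, fit
        fit = new_fit
        prev = fit.var_params
        _, overall = fa_percent_variance(fit.var_params)
        if overall > fa_target or k == J - 1:
            return k, fit
    return J - 1, fit


def _fa_init_from(vp: VarParams, k: int) -> VarParams:
    """FA(k) starting values from a DIAG or FA(k-1) fit."""
    J = vp.n_envs
    if vp.structure == "DIAG":
        lam = np.zeros((J, k))
        lam[:, 0] = np.sqrt(0.5 * np.maximum(vp.sigma2_g, 1e-12))
        psi = 0.5 * np.maximum(vp.sigma2_g, 1e-12)
    else:
        k_old = vp.loadings.shape[1]
        lam = np.zeros((J, k))
        lam[:, :min(k, k_old)] = vp.loadings[:, :min(k, k_old)]
        for f in range(k_old, k):
            lam[f:, f] = 0.1 * np.sqrt(np.maximum(vp.psi[f:], 1e-12))
        psi = 0.9 * np.maximum(vp.psi, 1e-12)
    for f in range(1, k):
        lam[:f, f] = 0.0
    return VarParams(vp.sigma2_e.copy(), loadings=lam, psi=psi,
                     rho_row=None if vp.rho_row is None else vp.rho_row.copy(),
                     rho_col=None if vp.rho_col is None else vp.rho_col.copy(),
                     sigma2_u=vp.sigma2_u)


def _sum_to_zero_contrast(J: int) -> np.ndarray:
    """J x (J-1) effects coding: main effect = across-environment mean."""
    H = np.zeros((J, J - 1))
    H[:J - 1, :] = np.eye(J - 1)
    H[J - 1, :] = -1.0
    return H


def _expand_to_plots(design: Design, line_values: np.ndarray) -> np.ndarray:
    """Line-level values to plot-level column (controls score 0)."""
    out = np.zeros(design.n_obs)
    mask = design.line_idx >= 0
    out[mask] = line_values[design.line_idx[mask]]
    return out


def _env_indicators(design: Design) -> np.ndarray:
    ind = np.zeros((design.n_obs, design.n_envs))
    for j, s in enumerate(design.env_slices):
        ind[s, j] = 1.0
    return ind


def genome_scan(
    base_fit: FitResult,
    predictors: PredictorMatrix,
    config: ScanConfig = None,
    covariate_positions: dict | None = None,
) -> pd.DataFrame:
    """One-at-a-time Wald scan of marker-interval genetic predictors.

    For each query position, the base fixed effects are extended with the
    predictor main effect and its environment interaction (sum-to-zero
    coding), plus any covariate predictors not on the scanned group, and
    both terms are tested against chi-square (1 df main, J-1 df Q x E) with
    variance parameters held at the base-fit estimates (re-estimated per
    interval if ``refit_variance``).  Returns the per-interval table.

    ``covariate_positions`` maps covariate label -> (group, line values).
    """
    config = config or ScanConfig()
    design = base_fit.design
    J = design.n_envs
    if predictors.lines != design.lines:
        idx = {l: i for i, l in enumerate(predictors.lines)}
        try:
            sel = [idx[l] for l in design.lines]
        except KeyError as e:
            raise ValueError(f"predictor matrix lacks fitted line {e}") from None
        pred_values = predictors.values[sel]
    else:
        pred_values = predictors.values
    covariate_positions = covariate_positions or {}

    solver = GLSSolver(design, base_fit.var_params)
    H = _sum_to_zero_contrast(J)
    env_ind = _env_indicators(design)
    p0 = design.X.shape[1]

    cov_cols = {lbl: (grp, _expand_to_plots(design, vals))
                for lbl, (grp, vals) in covariate_positions.items()}

    rows = []
    for qi, q in enumerate(predictors.queries):
        x_line = pred_values[:, qi]
        if np.ptp(x_line) < 1e-12:
            warnings.warn(f"monomorphic predictor at {q.label}; skipped")
            continue
        x_plot = _expand_to_plots(design, x_line)
        qxe = env_ind[:, :J] @ H * x_plot[:, None]   # (n, J-1) interaction block
        use_covs = [c for lbl, (grp, c) in cov_cols.items() if grp != q.group]
        X_ext = np.column_stack([design.X] + use_covs + [x_plot, qxe])

        if config.refit_variance:
            spec = design.spec
            d2 = Design(**{**design.__dict__, "X": X_ext,
                           "fixed_names": design.fixed_names
                           + [f"cov{i}" for i in range(len(use_covs))]
                           + ["qtl_main"] + [f"qtl_qxe{f}" for f in range(J - 1)],
                           "fixed_terms": design.fixed_terms})
            refit = reml_fit(d2, spec, init=base_fit.var_params, compute_blups=False)
            beta, cov = refit.beta, refit.cov_beta
        else:
            beta, cov = solver.fit_fixed(X_ext)

        i_main = p0 + len(use_covs)
        i_qxe = list(range(i_main + 1, i_main + J))
        b_main = beta[i_main]
        se_main = float(np.sqrt(max(cov[i_main, i_main], 0.0)))
        W_main = float(b_main**2 / cov[i_main, i_main])
        p_main = float(stats.chi2.sf(W_main, 1))
        bq = beta[i_qxe]
        Cq = cov[np.ix_(i_qxe, i_qxe)]
        W_qxe = float(bq @ np.linalg.solve(Cq, bq))
        p_qxe = float(stats.chi2.sf(W_qxe, J - 1))

        # per-environment effect = main + H_j . gamma
        per_env = []
        sel_idx = [i_main] + i_qxe
        Csub = cov[np.ix_(sel_idx, sel_idx)]
        bsub = beta[sel_idx]
        for j, env in enumerate(design.envs):
            a = np.concatenate([[1.0], H[j]])
            est = float(a @ bsub)
            se = float(np.sqrt(max(a @ Csub @ a, 0.0)))
            per_env.append((env, est, se))

        rows.append({
            "group": q.group, "label": q.label, "pos_cM": q.pos_cM,
            "left_marker": q.left_marker, "right_marker": q.right_marker,
            "W_main": W_main, "p_main": p_main,
            "W_qxe": W_qxe, "p_qxe": p_qxe,
            "effect_main": float(b_main), "se_main": se_main,
            "per_env": per_env,
        })
    return pd.DataFrame.from_records(rows)


def merge_to_qtl(
    scan: pd.DataFrame,
    config: ScanConfig,
    gmap: GeneticMap,
    trait: str = "trait",
    prefix: str = "sim",
) -> list[QTLRecord]:
    """Merge contiguous significant intervals into QTL records.

    An interval is significant when either its main-effect or its Q x E
    Wald p-value is below the threshold; runs of adjacent significant
    intervals on a group form one QTL whose peak is the interval with the
    largest Wald statistic.  The term is "main" when only the main effect
    is significant at the peak, otherwise "QxE"; per-environment effects
    carry a flag for |estimate| > ci_multiplier * SE.
    """
    if scan.empty:
        return []
    records: list[QTLRecord] = []
    thr = config.p_threshold
    for group, sub in scan.groupby("group", sort=False):
        sub = sub.sort_values("pos_cM").reset_index(drop=True)
        sig = (sub["p_main"] < thr) | (sub["p_qxe"] < thr)
        runs = []
        start = None
        for i, s in enumerate(sig):
            if s and start is None:
                start = i
            elif not s and start is not None:
                runs.append((start, i - 1)); start = None
        if start is not None:
            runs.append((start, len(sig) - 1))
        for run_i, (a, b) in enumerate(runs):
            block = sub.iloc[a:b + 1]
            stat = np.maximum(block["W_main"].to_numpy(), block["W_qxe"].to_numpy())
            peak = block.iloc[int(np.argmax(stat))]
            main_sig = peak["p_main"] < thr
            qxe_sig = peak["p_qxe"] < thr
            term = "main" if (main_sig and not qxe_sig) else "QxE"
            p = float(peak["p_main"] if term == "main" else peak["p_qxe"])
            _, left_pos = gmap.position(peak["left_marker"])
            _, right_pos = gmap.position(peak["right_marker"])
            per_env = [(env, est, se, bool(abs(est) > config.ci_multiplier * se))
                       for env, est, se in peak["per_env"]]
            suffix = f".{run_i + 1}" if len(runs) > 1 else ""
            records.append(QTLRecord(
                name=f"Q{trait}.{prefix}-{group}{suffix}",
                group=str(group),
                peak_interval=(left_pos, right_pos),
                flanking_markers=(peak["left_marker"], peak["right_marker"]),
                term=term, p=p,
                main_effect=float(peak["effect_main"]),
                main_se=float(peak["se_main"]),
                per_env_effects=per_env,
            ))
    return records


def qtl_table(records: list[QTLRecord]) -> pd.DataFrame:
    """Summary table: QTL, flanking markers, peak range, term, p, effect."""
    rows = []
    for r in records:
        if r.term == "main":
            effect = f"{r.main_effect:.3g}"
        else:
            rng = r.significant_range()
            effect = f"{rng[0]:.3g} to {rng[1]:.3g}" if rng else "ns per env"
        rows.append({
            "QTL": r.name, "group": r.group,
            "flanking_markers": f"{r.flanking_markers[0]}-{r.flanking_markers[1]}",
            "peak_cM": f"{r.peak_interval[0]:.1f}-{r.peak_interval[1]:.1f}",
            "term": r.term, "p": r.p, "effect": effect,
        })
    return pd.DataFrame.from_records(rows)


def heritability(fit: FitResult) -> pd.DataFrame:
    """Generalised (Cullis) heritability per environment.

    h^2_j = 1 - mean_{i<i'}(PEV_ii + PEV_i'i' - 2 PEV_ii') / (2 Sigma_jj),
    clamped to [0, 1]; environments with boundary genetic variance report 0
    with a flag.
    """
    if fit.pev is None:
        raise ValueError("fit has no PEV; refit with compute_blups=True")
    d = fit.design
    m = d.n_lines
    sigma = fit.var_params.genetic_cov()
    floor = 2.0 * 1e-8 * max(float(np.var(d.y)), 1e-12)
    rows = []
    for j, env in enumerate(d.envs):
        blk = fit.pev[j * m:(j + 1) * m, j * m:(j + 1) * m]
        tr = float(np.trace(blk))
        tot = float(blk.sum())
        mean_pairwise = 2.0 * (m * tr - tot) / (m * (m - 1))
        sg2 = float(sigma[j, j])
        at_floor = sg2 <= floor
        h2 = 0.0 if at_floor else float(np.clip(1.0 - mean_pairwise / (2.0 * sg2), 0.0, 1.0))
        rows.append({"env": env, "h2": h2, "sigma2_g": sg2,
                     "mean_pairwise_pev": mean_pairwise, "boundary": at_floor})
    return pd.DataFrame.from_records(rows)


@dataclass
class PipelineResult:
    qtl: dict                       # trait -> list[QTLRecord]
    qtl_tables: dict                # trait -> DataFrame
    heritability: dict              # trait -> DataFrame
    fits: dict                      # trait -> FitResult (base model)
    scans: dict                     # trait -> scan DataFrame
    logs: list[str]


def run_pipeline(
    phenotypes: pd.DataFrame,
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    traits: list[str],
    config: ScanConfig | None = None,
    phenology_trait: str | None = None,
    residual: str = "IID",
    rep_effect: bool = False,
    genetic_structure: str = "FA",
    prefix: str = "sim",
) -> PipelineResult:
    """The full MET QTL workflow on one phenotype table.

    Per trait: diagonal fit, low-genetic-variance trial filter, FA-order
    selection (when requested and >= 2 trials survive), then the
    one-at-a-time genome scan.  When ``phenology_trait`` is given it is
    scanned first and the peak flanking markers of its QTL become fixed
    covariates for the remaining traits (skipped on the chromosome being
    scanned, to avoid collinearity with the tested predictor).
    """
    config = config or ScanConfig()
    logs: list[str] = []
    preds = predictor_matrix(genotypes, gmap, scheme="interval_midpoints")

    covariate_positions: dict = {}
    for mk in config.covariate_markers:
        grp, _ = gmap.position(mk)
        col = _marker_predictor_values(genotypes, gmap, mk)
        covariate_positions[mk] = (grp, col)

    order = ([phenology_trait] if phenology_trait else []) + \
        [t for t in traits if t != phenology_trait]

    results = PipelineResult({}, {}, {}, {}, {}, logs)
    for trait in order:
        spec = ModelSpec(response=trait, genetic_structure="DIAG",
                         residual=residual, rep_effect=rep_effect)
        design = build_design(phenotypes, genotypes.lines, spec)
        diag_fit = reml_fit(design, compute_blups=False)
        kept, dropped = filter_trials(diag_fit, config.trial_filter_ratio)
        for env, reason in dropped:
            logs.append(f"[{trait}] dropped trial {env}: {reason}")
        if dropped:
            sub = phenotypes[phenotypes["env"].isin(kept)]
            design = build_design(sub, genotypes.lines, spec)
            diag_fit = reml_fit(design, compute_blups=False)

        if genetic_structure == "FA" and design.n_envs >= 2:
            k, base_fit = select_fa_order(design, spec, config.fa_target,
                                          diag_fit=diag_fit)
            logs.append(f"[{trait}] selected FA order k={k}")
        else:
            base_fit = reml_fit(design, compute_blups=True)
            logs.append(f"[{trait}] diagonal genetic model")

        use_covs = {} if trait == phenology_trait else covariate_positions
        if use_covs:
            logs.append(f"[{trait}] covariate markers: {sorted(use_covs)}")
        scan = genome_scan(base_fit, preds, config, covariate_positions=use_covs)
        records = merge_to_qtl(scan, config, gmap, trait=trait, prefix=prefix)
        logs.append(f"[{trait}] {len(records)} QTL detected")

        if trait == phenology_trait and not config.covariate_markers:
            for r in records:
                mk = r.flanking_markers[0]
                grp, _ = gmap.position(mk)
                covariate_positions[mk] = (grp, _marker_predictor_values(genotypes, gmap, mk))
            if covariate_positions:
                logs.append(f"[{trait}] derived covariates: {sorted(covariate_positions)}")

        if phenology_trait and trait != phenology_trait:
            # phenology covariates cannot adjust their own chromosome (they
            # are excluded there to avoid collinearity with the tested
            # predictor), so co-locating QTL are flagged instead
            for r in records:
                for pr in results.qtl.get(phenology_trait, []):
                    if r.group == pr.group and _peaks_close(r, pr):
                        r.phenology_colocated = True
                        logs.append(f"[{trait}] {r.name} co-locates with "
                                    f"phenology QTL {pr.name}")

        results.qtl[trait] = records
        results.qtl_tables[trait] = qtl_table(records)
        results.heritability[trait] = heritability(base_fit)
        results.fits[trait] = base_fit
        results.scans[trait] = scan
    return results


def _peaks_close(a: QTLRecord, b: QTLRecord, window_cM: float = 10.0) -> bool:
    mid_a = 0.5 * (a.peak_interval[0] + a.peak_interval[1])
    mid_b = 0.5 * (b.peak_interval[0] + b.peak_interval[1])
    return abs(mid_a - mid_b) <= window_cM


def _marker_predictor_values(genotypes: GenotypeMatrix, gmap: GeneticMap,
                             marker: str) -> np.ndarray:
    """Expected ±1 genotype of every line at one marker position."""
    from .predictors import line_predictor
    grp, pos = gmap.position(marker)
    order = [genotypes._marker_idx[m] for m in gmap.markers]
    calls_map_order = genotypes.calls[:, order]
    return np.array([line_predictor(calls_map_order[i], gmap, grp, pos)
                     for i in range(len(genotypes.lines))])
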