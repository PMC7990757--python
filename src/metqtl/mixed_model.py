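"""REML engine for stacked multi-environment linear mixed models.

The model is the plot-level multi-environment trial (MET) model

    y = X tau + Z_u u + Z_g g + e

with fixed effects ``tau`` (environment intercepts, control-variety
contrasts, optional linear row/column trends and covariates), an optional
replicate-within-environment random term ``u`` with scalar variance, a
genetic term ``g`` for the test lines distributed N(0, Sigma (x) I_m) where
``Sigma`` is a J x J between-environment genetic covariance (diagonal or
factor-analytic Sigma = Lambda Lambda' + Psi), and residuals that are
independent between environments with either iid or separable AR1 x AR1
correlation over the field row/column grid and an environment-specific
variance.

Variance parameters are estimated by maximising the residual log-likelihood

    l_R = -1/2 [ log|V| + log|X' V^-1 X| + y' P y + (n - p) log 2 pi ]

over an unconstrained parameterisation (log variances, arctanh
autocorrelations, free factor loadings).  The likelihood is evaluated
through the Woodbury identity on the genetic term, so the expensive pieces
are per-environment residual factorisations plus one capacitance solve; for
iid residuals without a replicate term the evaluation reduces to cached
per-environment Gram matrices and is essentially free, which is what makes
replicated genome-scan simulations tractable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

__all__ = [
    "ModelSpec",
    "Design",
    "VarParams",
    "FitResult",
    "build_design",
    "reml_fit",
    "reml_loglik",
    "wald_test",
    "fa_percent_variance",
    "GLSSolver",
]

LOG2PI = float(np.log(2.0 * np.pi))

# variances are floored at this multiple of var(y); estimates landing on the
# floor are reported as boundary values
VAR_FLOOR_FRACTION = 1e-8


# ---------------------------------------------------------------------------
# model specification and design assembly
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """What goes into the MET mixed model."""

    response: str = "value"
    genetic_structure: str = "DIAG"  # "DIAG" or "FA"
    fa_order: int = 1
    residual: str = "IID"  # "IID" or "AR1"
    rep_effect: bool = False
    row_col_trends: bool = False
    covariates: tuple = ()

    def __post_init__(self) -> None:
        if self.genetic_structure not in ("DIAG", "FA"):
            raise ValueError("genetic_structure must be 'DIAG' or 'FA'")
        if self.residual not in ("IID", "AR1"):
            raise ValueError("residual must be 'IID' or 'AR1'")
        if self.genetic_structure == "FA" and self.fa_order < 1:
            raise ValueError("FA order must be >= 1")


@dataclass
class Design:
    """Assembled design: response, fixed matrix and random-term indices.

    Rows are ordered by (environment, row, column) so residual blocks are
    separable by environment.  ``line_idx`` maps each plot to its test-line
    index (-1 for control plots, which carry their own fixed columns and do
    not enter the genetic term).
    """

    y: np.ndarray
    X: np.ndarray
    fixed_names: list[str]
    fixed_terms: dict[str, list[int]]
    envs: list[str]
    lines: list[str]
    env_slices: list[slice]
    line_idx: np.ndarray
    rep_idx: np.ndarray | None
    n_rep_levels: int
    rows: np.ndarray
    cols: np.ndarray
    spec: ModelSpec

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def n_envs(self) -> int:
        return len(self.envs)

    @property
    def n_lines(self) -> int:
        return len(self.lines)


def build_design(
    phenotypes: pd.DataFrame,
    genotype_lines: Sequence[str],
    spec: ModelSpec,
    control_lines: Sequence[str] | None = None,
) -> Design:
    """Assemble the design bundle from a plot-level phenotype table.

    ``phenotypes`` needs columns ``env, line, row, col`` (plus ``rep`` when
    the replicate term is requested) and the response column named by the
    spec.  Lines present in ``genotype_lines`` enter the genetic term; other
    lines are controls and receive one fixed-effect column each.
    """
    required = {"env", "line", "row", "col", spec.response}
    if spec.rep_effect:
        required.add("rep")
    missing = required - set(phenotypes.columns)
    if missing:
        raise ValueError(f"phenotype table lacks columns: {sorted(missing)}")
    df = phenotypes.dropna(subset=[spec.response]).copy()
    if df["line"].isna().any():
        raise ValueError("phenotype rows with missing line id")

    dup = df.duplicated(subset=["env", "row", "col"])
    if dup.any():
        first = df.loc[dup, ["env", "row", "col"]].iloc[0].tolist()
        raise ValueError(f"duplicate (environment, row, column) plot: {first}")

    geno_set = set(genotype_lines)
    present = set(df["line"])
    if control_lines is not None:
        unknown = present - geno_set - set(control_lines)
        if unknown:
            raise ValueError(f"phenotype lines absent from genotypes and controls: {sorted(unknown)[:5]}")
        controls = [c for c in control_lines if c in present]
    else:
        controls = sorted(present - geno_set)

    envs = sorted(df["env"].unique().tolist())
    df["__env_order"] = df["env"].map({e: i for i, e in enumerate(envs)})
    df = df.sort_values(["__env_order", "row", "col"], kind="mergesort").reset_index(drop=True)

    lines = [l for l in genotype_lines if l in present]
    if not lines:
        raise ValueError("no genotyped line is phenotyped")
    line_map = {l: i for i, l in enumerate(lines)}
    line_idx = np.array([line_map.get(l, -1) for l in df["line"]], dtype=np.int64)

    n = len(df)
    y = df[spec.response].to_numpy(dtype=float)
    rows = df["row"].to_numpy(dtype=np.int64)
    cols = df["col"].to_numpy(dtype=np.int64)

    env_slices = []
    env_order = df["__env_order"].to_numpy()
    for j in range(len(envs)):
        idx = np.flatnonzero(env_order == j)
        if idx.size < 2:
            raise ValueError(f"environment {envs[j]!r} has fewer than 2 observations")
        env_slices.append(slice(int(idx[0]), int(idx[-1]) + 1))

    cols_X: list[np.ndarray] = []
    names: list[str] = []
    terms: dict[str, list[int]] = {}

    def add(name: str, term: str, col: np.ndarray) -> None:
        terms.setdefault(term, []).append(len(names))
        names.append(name)
        cols_X.append(col.astype(float))

    for j, e in enumerate(envs):
        add(f"env:{e}", "env", (env_order == j).astype(float))
    for c in controls:
        add(f"control:{c}", f"control:{c}", (df["line"] == c).to_numpy().astype(float))
    if spec.row_col_trends:
        for j, e in enumerate(envs):
            in_env = env_order == j
            for ax, vals in (("row", rows), ("col", cols)):
                centred = np.where(in_env, vals - vals[in_env].mean(), 0.0)
                add(f"trend_{ax}:{e}", "trend", centred)
    for cov in spec.covariates:
        if cov not in df.columns:
            raise ValueError(f"covariate column missing: {cov!r}")
        add(f"cov:{cov}", f"cov:{cov}", df[cov].to_numpy(dtype=float))

    X = np.column_stack(cols_X)
    _check_full_rank(X, names)

    rep_idx = None
    n_rep_levels = 0
    if spec.rep_effect:
        levels = sorted({(e, r) for e, r in zip(df["env"], df["rep"])})
        lv = {k: i for i, k in enumerate(levels)}
        rep_idx = np.array([lv[(e, r)] for e, r in zip(df["env"], df["rep"])], dtype=np.int64)
        n_rep_levels = len(levels)

    return Design(
        y=y, X=X, fixed_names=names, fixed_terms=terms, envs=envs, lines=lines,
        env_slices=env_slices, line_idx=line_idx, rep_idx=rep_idx,
        n_rep_levels=n_rep_levels, rows=rows, cols=cols, spec=spec,
    )


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # name the columns whose removal restores full column rank
        bad = []
        q, rr = np.linalg.qr(X)
        diag = np.abs(np.diag(rr))
        tol = diag.max() * 1e-10 if diag.size else 0.0
        for i in np.flatnonzero(diag < tol):
            bad.append(names[i])
        raise ValueError(f"fixed-effect matrix is singular; collinear columns: {bad or names}")


# ---------------------------------------------------------------------------
# variance parameters
# ---------------------------------------------------------------------------

@dataclass
class VarParams:
    """Variance parameters of the MET model.

    Exactly one of (``sigma2_g``) or (``loadings``, ``psi``) is set,
    selecting the DIAG or FA genetic structure.  ``rho_row``/``rho_col``
    are None for iid residuals; ``sigma2_u`` is None without a replicate
    term.
    """

    sigma2_e: np.ndarray
    sigma2_g: np.ndarray | None = None
    loadings: np.ndarray | None = None
    psi: np.ndarray | None = None
    rho_row: np.ndarray | None = None
    rho_col: np.ndarray | None = None
    sigma2_u: float | None = None

    def __post_init__(self) -> None:
        self.sigma2_e = np.asarray(self.sigma2_e, dtype=float)
        if (self.sigma2_g is None) == (self.loadings is None):
            raise ValueError("set either sigma2_g (DIAG) or loadings+psi (FA)")
        if self.loadings is not None:
            self.loadings = np.atleast_2d(np.asarray(self.loadings, dtype=float))
            if self.loadings.shape[0] != self.sigma2_e.size:
                raise ValueError("loadings must have one row per environment")
            if self.psi is None:
                raise ValueError("FA structure requires psi")
            self.psi = np.asarray(self.psi, dtype=float)
        if self.sigma2_g is not None:
            self.sigma2_g = np.asarray(self.sigma2_g, dtype=float)

    @property
    def structure(self) -> str:
        return "FA" if self.loadings is not None else "DIAG"

    @property
    def n_envs(self) -> int:
        return self.sigma2_e.size

    def genetic_cov(self) -> np.ndarray:
        """The implied J x J between-environment genetic covariance Sigma."""
        if self.structure == "DIAG":
            return np.diag(self.sigma2_g)
        return self.loadings @ self.loadings.T + np.diag(self.psi)


def fa_percent_variance(vp: VarParams) -> tuple[np.ndarray, float]:
    """Percent of genetic variance explained by the common factors.

    Per environment: 100 * (Lambda Lambda')_jj / Sigma_jj; overall is the
    ratio of sums.  Environments with zero total genetic variance are
    undefined (NaN) and excluded from the overall figure.
    """
    if vp.structure != "FA":
        raise ValueError("fa_percent_variance requires an FA structure")
    common = np.sum(vp.loadings**2, axis=1)
    total = common + vp.psi
    per_env = np.where(total > 0, 100.0 * common / np.where(total > 0, total, 1.0), np.nan)
    ok = total > 0
    overall = 100.0 * common[ok].sum() / total[ok].sum()
    return per_env, float(overall)


# ---------------------------------------------------------------------------
# unconstrained parameterisation
# ---------------------------------------------------------------------------

class _ParamMap:
    """Maps VarParams <-> unconstrained optimisation vector."""

    def __init__(self, spec: ModelSpec, n_envs: int, var_floor: float):
        self.spec = spec
        self.J = n_envs
        self.floor = var_floor
        k = spec.fa_order
        self.n_load = sum(min(k, j + 1) for j in range(n_envs)) if spec.genetic_structure == "FA" else 0

    def _exp(self, t):
        return self.floor + np.exp(np.clip(t, -700.0, 50.0))

    def _log(self, v):
        return np.log(np.maximum(np.asarray(v, dtype=float) - self.floor, 1e-300))

    def to_theta(self, vp: VarParams) -> np.ndarray:
        parts = [self._log(vp.sigma2_e)]
        if self.spec.residual == "AR1":
            parts.append(np.arctanh(np.clip(vp.rho_row, -0.999, 0.999)))
            parts.append(np.arctanh(np.clip(vp.rho_col, -0.999, 0.999)))
        if self.spec.rep_effect:
            parts.append(self._log([vp.sigma2_u]))
        if self.spec.genetic_structure == "DIAG":
            parts.append(self._log(vp.sigma2_g))
        else:
            k = self.spec.fa_order
            lam = [vp.loadings[j, f] for j in range(self.J) for f in range(min(k, j + 1))]
            parts.append(np.asarray(lam, dtype=float))
            parts.append(self._log(vp.psi))
        return np.concatenate(parts)

    def to_params(self, theta: np.ndarray) -> VarParams:
        J = self.J
        i = 0
        sigma2_e = self._exp(theta[i:i + J]); i += J
        rho_row = rho_col = None
        if self.spec.residual == "AR1":
            rho_row = np.tanh(theta[i:i + J]); i += J
            rho_col = np.tanh(theta[i:i + J]); i += J
        sigma2_u = None
        if self.spec.rep_effect:
            sigma2_u = float(self._exp(theta[i:i + 1])[0]); i += 1
        if self.spec.genetic_structure == "DIAG":
            sigma2_g = self._exp(theta[i:i + J]); i += J
            return VarParams(sigma2_e, sigma2_g=sigma2_g, rho_row=rho_row,
                             rho_col=rho_col, sigma2_u=sigma2_u)
        k = self.spec.fa_order
        lam = np.zeros((J, k))
        for j in range(J):
            for f in range(min(k, j + 1)):
                lam[j, f] = theta[i]; i += 1
        psi = self._exp(theta[i:i + J]); i += J
        return VarParams(sigma2_e, loadings=lam, psi=psi, rho_row=rho_row,
                         rho_col=rho_col, sigma2_u=sigma2_u)


# ---------------------------------------------------------------------------
# likelihood workspace
# ---------------------------------------------------------------------------

class _Workspace:
    """Per-design caches for repeated likelihood evaluations.

    The fast path (iid residual, no replicate term) works entirely from
    per-environment Gram matrices; otherwise per-environment data blocks are
    kept for dense residual factorisations.
    """

    def __init__(self, design: Design):
        d = design
        self.design = d
        self.fast = d.spec.residual == "IID" and not d.spec.rep_effect
        self.J = d.n_envs
        self.m = d.n_lines
        self.p = d.X.shape[1]
        self.n = d.n_obs
        self.env_data = []
        M = np.column_stack([d.X, d.y])
        for j, s in enumerate(d.env_slices):
            Mj = M[s]
            li = d.line_idx[s]
            mask = li >= 0
            ent = {"M": Mj, "line_idx": li, "mask": mask, "n": Mj.shape[0],
                   "rows": d.rows[s], "cols": d.cols[s],
                   "rep_idx": d.rep_idx[s] if d.rep_idx is not None else None}
            if self.fast:
                ent["G"] = Mj.T @ Mj
                A = np.zeros((self.m, self.p + 1))
                np.add.at(A, li[mask], Mj[mask])
                ent["A"] = A
                counts = np.zeros(self.m)
                np.add.at(counts, li[mask], 1.0)
                ent["counts"] = counts
            self.env_data.append(ent)

    def _agg(self, ent, M):
        out = np.zeros((self.m, M.shape[1]))
        np.add.at(out, ent["line_idx"][ent["mask"]], M[ent["mask"]])
        return out

    def resid_solve(self, j: int, vp: VarParams, M: np.ndarray):
        """(R_j^-1 M, logdet R_j) for environment j."""
        ent = self.env_data[j]
        if self.fast:
            s2 = vp.sigma2_e[j]
            return M / s2, ent["n"] * np.log(s2)
        R = self._resid_matrix(j, vp)
        cf = linalg.cho_factor(R, lower=True, check_finite=False)
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        return linalg.cho_solve(cf, M, check_finite=False), logdet

    def _resid_matrix(self, j: int, vp: VarParams) -> np.ndarray:
        ent = self.env_data[j]
        n = ent["n"]
        if self.design.spec.residual == "AR1":
            dr = np.abs(ent["rows"][:, None] - ent["rows"][None, :])
            dc = np.abs(ent["cols"][:, None] - ent["cols"][None, :])
            K = vp.rho_row[j] ** dr * vp.rho_col[j] ** dc
        else:
            K = np.eye(n)
        R = vp.sigma2_e[j] * K
        if self.design.spec.rep_effect:
            ri = ent["rep_idx"]
            same = ri[:, None] == ri[None, :]
            R = R + vp.sigma2_u * same
        return R


def _genetic_solve(ws: _Workspace, vp: VarParams, D_list, U):
    """Capacitance solve: returns (C^-1 U, logdet C, logdet Sigma * m).

    ``D_list`` holds the per-environment Z_g' R^-1 Z_g blocks, either as a
    diagonal vector (fast path) or a dense m x m matrix.  ``U`` is the
    (J, m, q) stack of Z_g' R^-1 M blocks.
    """
    J, m = ws.J, ws.m
    diag_D = all(d.ndim == 1 for d in D_list)
    if vp.structure == "DIAG":
        logdet_sigma = float(np.sum(np.log(vp.sigma2_g))) * m
        W = np.empty_like(U)
        logdet_C = 0.0
        for j in range(J):
            if D_list[j].ndim == 1:
                c = D_list[j] + 1.0 / vp.sigma2_g[j]
                logdet_C += float(np.sum(np.log(c)))
                W[j] = U[j] / c[:, None]
            else:
                C = D_list[j] + np.eye(m) / vp.sigma2_g[j]
                cf = linalg.cho_factor(C, lower=True, check_finite=False)
                logdet_C += 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
                W[j] = linalg.cho_solve(cf, U[j], check_finite=False)
        return W, logdet_C, logdet_sigma

    sigma = vp.genetic_cov()
    sign, ld = np.linalg.slogdet(sigma)
    if sign <= 0:
        raise np.linalg.LinAlgError("genetic covariance not positive definite")
    logdet_sigma = float(ld) * m
    sigma_inv = np.linalg.inv(sigma)
    if diag_D:
        # capacitance decouples by line: one J x J system per line
        Dmat = np.stack(D_list, axis=0)            # (J, m)
        A = np.broadcast_to(sigma_inv, (m, J, J)).copy()
        A[:, np.arange(J), np.arange(J)] += Dmat.T
        ch = np.linalg.cholesky(A)                 # (m, J, J)
        logdet_C = float(2.0 * np.sum(np.log(np.diagonal(ch, axis1=1, axis2=2))))
        Ul = np.swapaxes(U, 0, 1)                  # (m, J, q)
        z = np.linalg.solve(ch, Ul)
        Wl = np.linalg.solve(np.swapaxes(ch, 1, 2), z)
        return np.swapaxes(Wl, 0, 1), logdet_C, logdet_sigma
    # dense capacitance in env-major layout
    C = np.kron(sigma_inv, np.eye(m))
    for j in range(J):
        blk = slice(j * m, (j + 1) * m)
        C[blk, blk] += D_list[j] if D_list[j].ndim == 2 else np.diag(D_list[j])
    cf = linalg.cho_factor(C, lower=True, check_finite=False)
    logdet_C = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    Uf = U.reshape(J * m, -1)
    Wf = linalg.cho_solve(cf, Uf, check_finite=False)
    return Wf.reshape(J, m, -1), logdet_C, logdet_sigma


def _reml_pieces(ws: _Workspace, vp: VarParams):
    """Everything the REML log-likelihood and GLS summaries need."""
    J, m, p = ws.J, ws.m, ws.p
    F = np.zeros((p + 1, p + 1))
    U = np.zeros((J, m, p + 1))
    D_list = []
    logdet_R = 0.0
    for j in range(J):
        ent = ws.env_data[j]
        if ws.fast:
            s2 = vp.sigma2_e[j]
            F += ent["G"] / s2
            U[j] = ent["A"] / s2
            D_list.append(ent["counts"] / s2)
            logdet_R += ent["n"] * np.log(s2)
        else:
            RiM, ld = ws.resid_solve(j, vp, ent["M"])
            logdet_R += ld
            F += ent["M"].T @ RiM
            U[j] = ws._agg(ent, RiM)
            Z = np.zeros((ent["n"], m))
            Z[ent["mask"], ent["line_idx"][ent["mask"]]] = 1.0
            RiZ, _ = ws.resid_solve(j, vp, Z)
            D_list.append(Z.T @ RiZ)
    W, logdet_C, logdet_sigma = _genetic_solve(ws, vp, D_list, U)
    F_adj = F - np.einsum("jmq,jmr->qr", U, W)
    return F_adj, U, W, D_list, logdet_R, logdet_C, logdet_sigma


def _reml_from_pieces(ws: _Workspace, pieces):
    F_adj, _, _, _, logdet_R, logdet_C, logdet_sigma = pieces
    p = ws.p
    XtVX = F_adj[:p, :p]
    XtVy = F_adj[:p, p]
    ytVy = F_adj[p, p]
    cf = linalg.cho_factor(XtVX, lower=True, check_finite=False)
    logdet_XtVX = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    beta = linalg.cho_solve(cf, XtVy, check_finite=False)
    yPy = float(ytVy - XtVy @ beta)
    ll = -0.5 * (logdet_R + logdet_sigma + logdet_C + logdet_XtVX + yPy
                 + (ws.n - p) * LOG2PI)
    return float(ll), beta, cf


def reml_loglik(design: Design, vp: VarParams) -> float:
    """Residual log-likelihood of the MET model at fixed variance parameters."""
    ws = _Workspace(design)
    ll, _, _ = _reml_from_pieces(ws, _reml_pieces(ws, vp))
    return ll


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """REML fit: variance parameters, fixed effects, BLUPs and their PEV."""

    var_params: VarParams
    reml_loglik: float
    beta: np.ndarray
    cov_beta: np.ndarray
    fixed_names: list[str]
    fixed_terms: dict[str, list[int]]
    blups: np.ndarray | None        # (J, m) genetic predictions, env-major
    pev: np.ndarray | None          # (J*m, J*m) prediction-error covariance
    converged: bool
    n_iter: int
    loglik_trace: list[float]
    boundary: list[str]
    design: Design

    @property
    def fixed_estimates(self) -> pd.DataFrame:
        se = np.sqrt(np.maximum(np.diag(self.cov_beta), 0.0))
        return pd.DataFrame({"term": self.fixed_names, "estimate": self.beta, "se": se})


def _moment_start(design: Design, spec: ModelSpec) -> VarParams:
    """Moment-based starting values: per-environment line-mean ANOVA split."""
    d = design
    sigma2_e = np.empty(d.n_envs)
    sigma2_g = np.empty(d.n_envs)
    for j, s in enumerate(d.env_slices):
        yj = d.y[s]
        li = d.line_idx[s]
        vy = max(float(np.var(yj)), 1e-12)
        mask = li >= 0
        if mask.sum() >= 4:
            df_j = pd.DataFrame({"g": li[mask], "y": yj[mask]})
            grp = df_j.groupby("g")["y"]
            counts = grp.count()
            if (counts >= 2).any():
                wv = grp.var(ddof=1)[counts >= 2]
                mse = float(np.nanmean(wv)) if np.isfinite(np.nanmean(wv)) else 0.5 * vy
                mse = max(mse, 1e-3 * vy)
                r_bar = float(counts.mean())
                vg = max(float(grp.mean().var(ddof=1)) - mse / r_bar, 0.05 * vy)
            else:
                mse, vg = 0.5 * vy, 0.5 * vy
        else:
            mse, vg = 0.5 * vy, 0.5 * vy
        sigma2_e[j] = mse
        sigma2_g[j] = vg
    rho_row = rho_col = None
    if spec.residual == "AR1":
        rho_row = np.full(d.n_envs, 0.1)
        rho_col = np.full(d.n_envs, 0.1)
    sigma2_u = 0.05 * float(np.var(d.y)) if spec.rep_effect else None
    if spec.genetic_structure == "DIAG":
        return VarParams(sigma2_e, sigma2_g=sigma2_g, rho_row=rho_row,
                         rho_col=rho_col, sigma2_u=sigma2_u)
    k = spec.fa_order
    lam = np.zeros((d.n_envs, k))
    lam[:, 0] = np.sqrt(0.5 * sigma2_g)
    for f in range(1, k):
        lam[f:, f] = 0.1 * np.sqrt(sigma2_g[f:])
    psi = 0.5 * sigma2_g
    return VarParams(sigma2_e, loadings=lam, psi=psi, rho_row=rho_row,
                     rho_col=rho_col, sigma2_u=sigma2_u)


def _canonicalise_fa(vp: VarParams) -> VarParams:
    """Fix FA sign indeterminacy: first nonzero loading per factor positive."""
    if vp.structure != "FA":
        return vp
    lam = vp.loadings.copy()
    for f in range(lam.shape[1]):
        col = lam[:, f]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            lam[:, f] = -col
    vp.loadings = lam
    return vp


def reml_fit(
    design: Design,
    spec: ModelSpec | None = None,
    init: VarParams | None = None,
    tol: float = 1e-10,
    max_iter: int = 500,
    n_starts: int | None = None,
    compute_blups: bool = True,
) -> FitResult:
    """Maximise the REML log-likelihood over the variance parameters.

    Quasi-Newton (L-BFGS-B) on the unconstrained parameterisation, with a
    Nelder-Mead polish for low-dimensional problems and multiple perturbed
    starts for FA structures (which can have local optima).  Non-convergence
    returns the last iterate flagged rather than raising.
    """
    spec = spec or design.spec
    ws = _Workspace(design)
    floor = VAR_FLOOR_FRACTION * max(float(np.var(design.y)), 1e-12)
    pmap = _ParamMap(spec, design.n_envs, floor)
    if spec.genetic_structure == "FA" and spec.fa_order >= design.n_envs:
        raise ValueError("FA order must be smaller than the number of environments")

    start_vp = init if init is not None else _moment_start(design, spec)
    theta0 = pmap.to_theta(start_vp)
    if n_starts is None:
        n_starts = 3 if spec.genetic_structure == "FA" else 1
    rng = np.random.default_rng(1234)  # internal, deterministic perturbations
    starts = [theta0] + [theta0 + rng.normal(0.0, 0.3, size=theta0.size)
                         for _ in range(n_starts - 1)]

    trace: list[float] = []
    best_ll = [-np.inf]

    def negll(theta: np.ndarray) -> float:
        try:
            vp = pmap.to_params(theta)
            ll, _, _ = _reml_from_pieces(ws, _reml_pieces(ws, vp))
        except (np.linalg.LinAlgError, FloatingPointError, ValueError):
            return 1e12
        if not np.isfinite(ll):
            return 1e12
        if ll > best_ll[0]:
            best_ll[0] = ll
            trace.append(ll)
        return -ll

    best = None
    total_nit = 0
    converged = False
    for th0 in starts:
        res = optimize.minimize(
            negll, th0, method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-9},
        )
        total_nit += int(res.nit)
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success) or converged

    if best.x.size <= 10:
        res = optimize.minimize(
            negll, best.x, method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 4000},
        )
        if res.fun <= best.fun:
            best = res
            converged = converged or bool(res.success)
    if not converged:
        warnings.warn("REML did not converge; returning last iterate")

    vp = _canonicalise_fa(pmap.to_params(best.x))
    pieces = _reml_pieces(ws, vp)
    ll, beta, cf_x = _reml_from_pieces(ws, pieces)
    cov_beta = linalg.cho_solve(cf_x, np.eye(ws.p), check_finite=False)

    boundary = []
    for name, vals in (("sigma2_e", vp.sigma2_e),
                       ("sigma2_g", vp.sigma2_g if vp.structure == "DIAG" else vp.psi)):
        if vals is not None and np.any(vals < 2.0 * floor):
            boundary.append(name)

    blups = pev = None
    if compute_blups:
        blups, pev = _blup_pev(ws, vp, pieces, beta, cov_beta)

    return FitResult(
        var_params=vp, reml_loglik=ll, beta=beta, cov_beta=cov_beta,
        fixed_names=design.fixed_names, fixed_terms=design.fixed_terms,
        blups=blups, pev=pev, converged=converged, n_iter=total_nit,
        loglik_trace=trace, boundary=boundary, design=design,
    )


def _blup_pev(ws: _Workspace, vp: VarParams, pieces, beta, cov_beta):
    """BLUPs g~ = G Z' P y and PEV = G - G Z' P Z G (env-major layout)."""
    F_adj, U, W, D_list, *_ = pieces
    J, m, p = ws.J, ws.m, ws.p
    sigma = vp.genetic_cov()
    G = np.kron(sigma, np.eye(m))

    # Z' V^-1 [X, y] = U - D C^-1 U, flattened env-major
    Uf = U.reshape(J * m, p + 1)
    Wf = W.reshape(J * m, p + 1)
    D = _blockdiag(D_list, m)
    ZVM = Uf - D @ Wf
    ZVX, ZVy = ZVM[:, :p], ZVM[:, p]

    t = ZVy - ZVX @ beta
    g_flat = G @ t
    blups = g_flat.reshape(J, m)

    # Z' V^-1 Z = D - D C^-1 D
    CiD = _capacitance_solve(ws, vp, D_list, D)
    S0 = D - D @ CiD
    ZPZ = S0 - ZVX @ cov_beta @ ZVX.T
    pev = G - G @ ZPZ @ G
    return blups, pev


def _blockdiag(D_list, m):
    J = len(D_list)
    D = np.zeros((J * m, J * m))
    for j, Dj in enumerate(D_list):
        blk = slice(j * m, (j + 1) * m)
        D[blk, blk] = np.diag(Dj) if Dj.ndim == 1 else Dj
    return D


def _capacitance_solve(ws: _Workspace, vp: VarParams, D_list, Mat):
    """C^-1 Mat for the dense env-major capacitance C = Sigma^-1 (x) I + D."""
    J, m = ws.J, ws.m
    sigma_inv = np.linalg.inv(vp.genetic_cov())
    C = np.kron(sigma_inv, np.eye(m)) + _blockdiag(D_list, m)
    cf = linalg.cho_factor(C, lower=True, check_finite=False)
    return linalg.cho_solve(cf, Mat, check_finite=False)


def wald_test(fit: FitResult, term: str) -> tuple[float, int, float]:
    """Wald chi-square for one fixed-effect term being zero.

    Returns (W, df, p) with W = beta' C^-1 beta over the term's coefficient
    block and p the upper chi-square tail on df = block size.
    """
    if term not in fit.fixed_terms:
        raise KeyError(f"no fixed term {term!r}; have {sorted(fit.fixed_terms)}")
    idx = fit.fixed_terms[term]
    b = fit.beta[idx]
    C = fit.cov_beta[np.ix_(idx, idx)]
    try:
        W = float(b @ np.linalg.solve(C, b))
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(f"singular coefficient covariance for term {term!r}") from e
    df = len(idx)
    return W, df, float(stats.chi2.sf(W, df))


# ---------------------------------------------------------------------------
# fixed-theta generalised least squares (used by the genome scan)
# ---------------------------------------------------------------------------

class GLSSolver:
    """GLS with variance parameters frozen at fitted values.

    Prepares the per-environment residual factorisations and the genetic
    capacitance once, then fits arbitrary fixed-effect matrices against the
    same V.  This is what makes one-interval-at-a-time genome scans cheap.
    """

    def __init__(self, design: Design, vp: VarParams):
        self.design = design
        self.vp = vp
        self.ws = _Workspace(design)
        ws, J, m = self.ws, self.ws.J, self.ws.m
        self._resid = []
        D_list = []
        for j in range(J):
            ent = ws.env_data[j]
            if ws.fast:
                self._resid.append(None)
                D_list.append(ent["counts"] / vp.sigma2_e[j])
            else:
                R = ws._resid_matrix(j, vp)
                cf = linalg.cho_factor(R, lower=True, check_finite=False)
                self._resid.append(cf)
                Z = np.zeros((ent["n"], m))
                msk = ent["mask"]
                Z[msk, ent["line_idx"][msk]] = 1.0
                RiZ = linalg.cho_solve(cf, Z, check_finite=False)
                D_list.append(Z.T @ RiZ)
        self.D_list = D_list
        self._prep_capacitance()

    def _prep_capacitance(self) -> None:
        ws, vp = self.ws, self.vp
        J, m = ws.J, ws.m
        diag_D = all(d.ndim == 1 for d in self.D_list)
        if vp.structure == "DIAG" and diag_D:
            self._cap = ("diag", np.stack([self.D_list[j] + 1.0 / vp.sigma2_g[j]
                                           for j in range(J)]))
        elif vp.structure == "FA" and diag_D:
            sigma_inv = np.linalg.inv(vp.genetic_cov())
            A = np.broadcast_to(sigma_inv, (m, J, J)).copy()
            A[:, np.arange(J), np.arange(J)] += np.stack(self.D_list).T
            self._cap = ("batched", np.linalg.cholesky(A))
        else:
            sigma_inv = np.linalg.inv(vp.genetic_cov())
            C = np.kron(sigma_inv, np.eye(m)) + _blockdiag(self.D_list, m)
            self._cap = ("dense", linalg.cho_factor(C, lower=True, check_finite=False))

    def _cap_solve(self, U: np.ndarray) -> np.ndarray:
        """C^-1 U for U of shape (J, m, q)."""
        kind, obj = self._cap
        if kind == "diag":
            return U / obj[:, :, None]
        if kind == "batched":
            Ul = np.swapaxes(U, 0, 1)
            z = np.linalg.solve(obj, Ul)
            Wl = np.linalg.solve(np.swapaxes(obj, 1, 2), z)
            return np.swapaxes(Wl, 0, 1)
        J, m, q = U.shape
        Wf = linalg.cho_solve(obj, U.reshape(J * m, q), check_finite=False)
        return Wf.reshape(J, m, q)

    def normal_equations(self, X: np.ndarray, y: np.ndarray):
        """(X'V^-1X, X'V^-1y) under the frozen variance parameters."""
        ws, vp = self.ws, self.vp
        M = np.column_stack([X, y])
        F = np.zeros((M.shape[1], M.shape[1]))
        U = np.zeros((ws.J, ws.m, M.shape[1]))
        for j in range(ws.J):
            ent = ws.env_data[j]
            Mj = M[self.design.env_slices[j]]
            if ws.fast:
                RiM = Mj / vp.sigma2_e[j]
            else:
                RiM = linalg.cho_solve(self._resid[j], Mj, check_finite=False)
            F += Mj.T @ RiM
            U[j] = ws._agg(ent, RiM)
        W = self._cap_solve(U)
        F_adj = F - np.einsum("jmq,jmr->qr", U, W)
        q = X.shape[1]
        return F_adj[:q, :q], F_adj[:q, q]

    def fit_fixed(self, X: np.ndarray, y: np.ndarray | None = None):
        """GLS estimates and covariance for a fixed-effect matrix X."""
        y = self.design.y if y is None else y
        XtVX, XtVy = self.normal_equations(X, y)
        cf = linalg.cho_factor(XtVX, lower=True, check_finite=False)
        beta = linalg.cho_solve(cf, XtVy, check_finite=False)
        cov = linalg.cho_solve(cf, np.eye(X.shape[1]), check_finite=False)
        return beta, cov
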