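"""Independent oracles shared by the test suite.

These deliberately avoid the package's own computational paths: the dense
REML evaluator builds V explicitly and uses generic inverses/determinants,
and the interval-probability oracle enumerates the doubled-haploid
three-locus joint frequencies instead of using closed-form conditionals.
"""

import numpy as np


def dense_reml_loglik(design, vp):
    """Brute-force REML log-likelihood from an explicitly assembled V."""
    n, J, m = design.n_obs, design.n_envs, design.n_lines
    X, y = design.X, design.y
    V = np.zeros((n, n))
    for j, s in enumerate(design.env_slices):
        idx = np.arange(s.start, s.stop)
        if design.spec.residual == "AR1":
            dr = np.abs(np.subtract.outer(design.rows[idx], design.rows[idx]))
            dc = np.abs(np.subtract.outer(design.cols[idx], design.cols[idx]))
            K = vp.rho_row[j] ** dr * vp.rho_col[j] ** dc
        else:
            K = np.eye(idx.size)
        V[np.ix_(idx, idx)] += vp.sigma2_e[j] * K
        if design.spec.rep_effect:
            ri = design.rep_idx[idx]
            V[np.ix_(idx, idx)] += vp.sigma2_u * (ri[:, None] == ri[None, :])
    Zg = np.zeros((n, J * m))
    for j, s in enumerate(design.env_slices):
        for i in range(s.start, s.stop):
            li = design.line_idx[i]
            if li >= 0:
                Zg[i, j * m + li] = 1.0
    V += Zg @ np.kron(vp.genetic_cov(), np.eye(m)) @ Zg.T
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    yPy = (y - X @ beta) @ Vi @ y
    p = X.shape[1]
    return float(-0.5 * (np.linalg.slogdet(V)[1] + np.linalg.slogdet(XtViX)[1]
                         + yPy + (n - p) * np.log(2.0 * np.pi)))


def enumerate_dh_prob_A(left_state, right_state, r_left, r_right):
    """P(query = A | flanks) by summing DH three-locus joint frequencies."""
    states = ("A", "B")
    joint = {}
    for l in states:
        for q in states:
            for r in states:
                p = 0.5
                p *= (1.0 - r_left) if q == l else r_left
                p *= (1.0 - r_right) if r == q else r_right
                joint[(l, q, r)] = p
    num = joint[(left_state, "A", right_state)]
    den = num + joint[(left_state, "B", right_state)]
    return num / den


def anova_estimates(y_by_line):
    """Balanced one-way ANOVA method-of-moments variance estimates."""
    y = np.asarray(y_by_line, dtype=float)  # (m, r)
    m, r = y.shape
    line_means = y.mean(axis=1)
    mse = float(((y - line_means[:, None]) ** 2).sum() / (m * (r - 1)))
    msg = float(r * line_means.var(ddof=1))
    return mse, (msg - mse) / r
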