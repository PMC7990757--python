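"""Synthetic doubled-haploid MET data with recorded truth.

Generates the statistical structure the MET mixed model assumes: a DH
population recombining along a linkage map (marker-to-marker Markov chain,
no interference, Kosambi map<->r conversion), planted QTL with main and
environment-specific effects, a factor-analytic polygenic
genotype-by-environment term, replicate effects and separable AR1 x AR1
spatial plot noise.  Every draw is seeded, and a :class:`TruthRecord`
carries enough of the realised state (true QTL genotypes and effects,
genetic covariance, per-line genetic values) to score recovery without
re-simulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .genmap import CALL_A, CALL_B, CALL_NA, GeneticMap, GenotypeMatrix, r_from_kosambi_cm
from .predictors import interval_probability

__all__ = [
    "MapSpec", "QTLSpec", "SpatialSpec", "PhenologyLocus", "SimConfig", "TruthRecord",
    "simulate_map", "simulate_dh_genotypes", "simulate_met_phenotypes",
    "inject_missing", "simulate_nil_experiment",
]


@dataclass
class MapSpec:
    n_groups: int = 21
    length_cM: float = 130.0
    markers_per_group: int = 40
    even: bool = True


@dataclass
class QTLSpec:
    group: str
    pos_cM: float
    main_effect: float
    env_effects: Sequence[float] | None = None  # per-environment deviations


@dataclass
class SpatialSpec:
    n_rows: int
    n_cols: int
    rho_row: float = 0.0
    rho_col: float = 0.0
    sigma2: float = 1.0


@dataclass
class PhenologyLocus:
    group: str
    pos_cM: float
    effect_covariate: float  # effect on the phenology trait (e.g. DTH)
    effect_target: float     # pleiotropic effect on the target trait


@dataclass
class SimConfig:
    """Study conditions for one synthetic MET.

    Defaults loosely mirror a wheat DH study: ~200 lines, two replicates,
    eight environments with heterogeneous genetic variance, FA(1) G x E.
    """

    n_lines: int = 200
    map_spec: MapSpec = field(default_factory=MapSpec)
    qtl: Sequence[QTLSpec] = ()
    n_envs: int = 8
    loadings: np.ndarray | None = None   # (J, k); default sqrt(0.6*sg2)
    psi: np.ndarray | None = None        # (J,); default 0.4*sg2
    sigma2_g: float = 1.0                # scale used for the FA defaults
    env_means: Sequence[float] | None = None
    spatial: SpatialSpec | Sequence[SpatialSpec] | None = None
    noise_sigma2: float = 0.0            # extra iid plot noise (nugget)
    n_reps: int = 2
    rep_sigma2: float = 0.0
    missing_rate: float = 0.0
    n_controls: int = 0
    phenology: PhenologyLocus | None = None
    trait: str = "yield"
    covariate_trait: str = "dth"
    seed: int = 0

    def genetic_cov(self) -> np.ndarray:
        J = self.n_envs
        if self.loadings is not None:
            lam = np.atleast_2d(np.asarray(self.loadings, dtype=float))
            psi = np.asarray(self.psi if self.psi is not None else np.zeros(J), dtype=float)
            return lam @ lam.T + np.diag(psi)
        lam = np.full((J, 1), np.sqrt(0.6 * self.sigma2_g))
        psi = np.full(J, 0.4 * self.sigma2_g)
        return lam @ lam.T + np.diag(psi)

    def spatial_specs(self) -> list[SpatialSpec]:
        if self.spatial is None:
            # square-ish grid whose replicate row-bands each hold all entries
            n_entries = self.n_lines + self.n_controls
            n_cols = int(np.ceil(np.sqrt(n_entries * self.n_reps)))
            band = int(np.ceil(n_entries / n_cols))
            return [SpatialSpec(band * self.n_reps, n_cols, 0.0, 0.0, 1.0)] * self.n_envs
        if isinstance(self.spatial, SpatialSpec):
            return [self.spatial] * self.n_envs
        return list(self.spatial)


@dataclass
class TruthRecord:
    """Realised simulation state, sufficient to score recovery tests."""

    qtl: list[dict]                 # group, pos_cM, main_effect, env_effects
    qtl_genotypes: np.ndarray       # (n_lines, n_qtl) in ±1
    sigma: np.ndarray               # (J, J) polygenic covariance
    env_means: np.ndarray
    spatial: list[dict]
    genetic_values: np.ndarray      # (n_lines, J) total genetic value
    lines: list[str]
    envs: list[str]
    phenology: dict | None = None
    phenology_genotypes: np.ndarray | None = None

    def to_json(self, path) -> None:
        def conv(v):
            return v.tolist() if isinstance(v, np.ndarray) else v
        with open(path, "w") as fh:
            json.dump({k: conv(v) for k, v in asdict(self).items()}, fh, indent=1)


def simulate_map(map_spec: MapSpec, seed: int = 0) -> GeneticMap:
    """Linkage map with markers placed evenly or uniformly at random."""
    if map_spec.length_cM <= 0:
        raise ValueError("group length must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(map_spec.n_groups):
        group = f"G{g + 1:02d}"
        if map_spec.even:
            pos = np.linspace(0.0, map_spec.length_cM, map_spec.markers_per_group)
        else:
            pos = np.sort(rng.uniform(0.0, map_spec.length_cM, map_spec.markers_per_group))
        for k, p in enumerate(pos):
            rows.append((f"{group}M{k + 1:03d}", group, float(p)))
    return GeneticMap(pd.DataFrame(rows, columns=["marker", "group", "pos_cM"]))


def simulate_dh_genotypes(gmap: GeneticMap, n_lines: int, seed: int = 0) -> GenotypeMatrix:
    """DH genotypes from a marker-to-marker Markov recombination model.

    The first marker of each group is A or B with probability 1/2; each
    subsequent marker switches parent with the recombination fraction
    implied by the Kosambi distance to its neighbour.  No interference, no
    heterozygotes.
    """
    rng = np.random.default_rng(seed)
    n_markers = len(gmap.markers)
    calls = np.empty((n_lines, n_markers), dtype=np.int8)
    for group in gmap.groups:
        sub = gmap.group_table(group)
        idx = sub.index.to_numpy()
        pos = sub["pos_cM"].to_numpy()
        r = r_from_kosambi_cm(np.diff(pos))
        state = rng.random(n_lines) < 0.5  # True = A
        calls[:, idx[0]] = np.where(state, CALL_A, CALL_B)
        for k in range(1, idx.size):
            flip = rng.random(n_lines) < r[k - 1]
            state = state ^ flip
            calls[:, idx[k]] = np.where(state, CALL_A, CALL_B)
    return GenotypeMatrix([f"L{i + 1:04d}" for i in range(n_lines)],
                          gmap.markers, calls, is_dh=True)


def inject_missing(genotypes: GenotypeMatrix, rate: float, seed: int = 0) -> GenotypeMatrix:
    """Set each call to missing independently with probability ``rate``."""
    if not (0.0 <= rate < 1.0):
        raise ValueError("missing rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    calls = genotypes.calls.copy()
    calls[rng.random(calls.shape) < rate] = CALL_NA
    return GenotypeMatrix(genotypes.lines, genotypes.markers, calls, genotypes.is_dh)


def _true_locus_genotype(genotypes: GenotypeMatrix, gmap: GeneticMap,
                         group: str, pos: float, rng) -> np.ndarray:
    """±1 genotype at (group, pos): the marker itself, or a conditional draw.

    For a position between markers the true DH genotype is sampled from its
    conditional distribution given the flanking markers, which is exact
    under the no-interference Markov model used for the chromosomes.
    """
    sub = gmap.group_table(group)
    pos_arr = sub["pos_cM"].to_numpy()
    markers = sub["marker"].tolist()
    hit = np.flatnonzero(np.isclose(pos_arr, pos))
    if hit.size:
        col = genotypes.column(markers[hit[0]])
        return np.where(col == CALL_A, 1.0, -1.0)
    left = np.flatnonzero(pos_arr < pos)
    right = np.flatnonzero(pos_arr > pos)
    n = len(genotypes.lines)
    x = np.empty(n)
    for i in range(n):
        ls = dl = rs = dr = None
        if left.size:
            k = left[-1]
            c = genotypes.column(markers[k])[i]
            if c != CALL_NA:
                ls = "A" if c == CALL_A else "B"
                dl = pos - pos_arr[k]
        if right.size:
            k = right[0]
            c = genotypes.column(markers[k])[i]
            if c != CALL_NA:
                rs = "A" if c == CALL_A else "B"
                dr = pos_arr[k] - pos
        p_a = interval_probability(
            ls, rs,
            r_from_kosambi_cm(dl) if ls is not None else None,
            r_from_kosambi_cm(dr) if rs is not None else None,
        )
        x[i] = 1.0 if rng.random() < p_a else -1.0
    return x


def _ar1_field(sp: SpatialSpec, rng) -> np.ndarray:
    """One draw of a separable AR1 x AR1 Gaussian field on the grid."""
    def chol_ar1(n, rho):
        if n == 1 or rho == 0.0:
            return np.eye(n)
        K = rho ** np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        return np.linalg.cholesky(K)
    Lr = chol_ar1(sp.n_rows, sp.rho_row)
    Lc = chol_ar1(sp.n_cols, sp.rho_col)
    z = rng.standard_normal((sp.n_rows, sp.n_cols))
    return np.sqrt(sp.sigma2) * (Lr @ z @ Lc.T)


def simulate_met_phenotypes(
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    config: SimConfig,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Plot-level multi-environment phenotypes with planted QTL.

    The genetic value of line i in environment j is
    sum_q x_iq (beta_q + beta_qj) + (Lambda f_i + delta_ij); a plot adds the
    environment mean, a replicate effect, the AR1 x AR1 field and optional
    iid noise.  Lines (and optional control entries) are assigned to plots
    by a seeded randomised layout, one replicate per row band.
    """
    rng = np.random.default_rng(config.seed)
    J = config.n_envs
    m = len(genotypes.lines)
    sigma = config.genetic_cov()
    env_means = np.asarray(config.env_means if config.env_means is not None
                           else np.zeros(J), dtype=float)
    envs = [f"E{j + 1:02d}" for j in range(J)]
    spatials = config.spatial_specs()
    if len(spatials) != J:
        raise ValueError("need one spatial spec per environment")

    # planted QTL: true ±1 genotypes and per-env effect sizes
    qtl_truth, x_cols = [], []
    for q in config.qtl:
        x = _true_locus_genotype(genotypes, gmap, q.group, q.pos_cM, rng)
        dev = np.asarray(q.env_effects if q.env_effects is not None else np.zeros(J), dtype=float)
        qtl_truth.append({"group": q.group, "pos_cM": q.pos_cM,
                          "main_effect": q.main_effect, "env_effects": dev.tolist()})
        x_cols.append(x)
    x_qtl = np.column_stack(x_cols) if x_cols else np.zeros((m, 0))

    # polygenic G x E term: line values across environments ~ N(0, Sigma)
    if np.allclose(sigma, 0.0):
        poly = np.zeros((m, J))
    else:
        L = np.linalg.cholesky(sigma + 1e-12 * np.eye(J))
        poly = rng.standard_normal((m, J)) @ L.T
    gvals = poly.copy()
    for qi, q in enumerate(qtl_truth):
        eff = q["main_effect"] + np.asarray(q["env_effects"])
        gvals += np.outer(x_qtl[:, qi], eff)

    pheno_truth = None
    x_phen = None
    phen_gval = None
    if config.phenology is not None:
        ph = config.phenology
        x_phen = _true_locus_genotype(genotypes, gmap, ph.group, ph.pos_cM, rng)
        pheno_truth = {"group": ph.group, "pos_cM": ph.pos_cM,
                       "effect_covariate": ph.effect_covariate,
                       "effect_target": ph.effect_target}
        gvals += np.outer(x_phen, np.full(J, ph.effect_target))
        phen_gval = x_phen * ph.effect_covariate

    controls = [f"CTRL{c + 1:02d}" for c in range(config.n_controls)]
    entries = list(genotypes.lines) + controls
    control_shift = rng.normal(0.0, 1.0, size=config.n_controls)

    records = []
    for j in range(J):
        sp = spatials[j]
        capacity = sp.n_rows * sp.n_cols
        if capacity < len(entries) * config.n_reps:
            raise ValueError(
                f"grid {sp.n_rows}x{sp.n_cols} cannot hold "
                f"{len(entries)} entries x {config.n_reps} reps in {envs[j]}")
        field = _ar1_field(sp, rng)
        rep_eff = rng.normal(0.0, np.sqrt(config.rep_sigma2), size=config.n_reps) \
            if config.rep_sigma2 > 0 else np.zeros(config.n_reps)
        # replicates occupy consecutive row-major blocks of the grid
        all_cells = [(row, col) for row in range(sp.n_rows)
                     for col in range(sp.n_cols)]
        for r in range(config.n_reps):
            order = rng.permutation(len(entries))
            cells = all_cells[r * len(entries):(r + 1) * len(entries)]
            for slot, ei in enumerate(order):
                row, col = cells[slot]
                name = entries[ei]
                if ei < m:
                    g = gvals[ei, j]
                else:
                    g = control_shift[ei - m]
                value = env_means[j] + g + rep_eff[r] + field[row, col]
                if config.noise_sigma2 > 0:
                    value += rng.normal(0.0, np.sqrt(config.noise_sigma2))
                rec = {"env": envs[j], "line": name, "rep": r + 1,
                       "row": row + 1, "col": col + 1, config.trait: value}
                if pheno_truth is not None:
                    base = 100.0 + 2.0 * j  # arbitrary phenology level per env
                    pv = base + (phen_gval[ei] if ei < m else 0.0) \
                        + rng.normal(0.0, 1.0)
                    rec[config.covariate_trait] = pv
                records.append(rec)

    table = pd.DataFrame.from_records(records)
    truth = TruthRecord(
        qtl=qtl_truth, qtl_genotypes=x_qtl, sigma=sigma, env_means=env_means,
        spatial=[asdict(s) for s in spatials], genetic_values=gvals,
        lines=list(genotypes.lines), envs=envs,
        phenology=pheno_truth, phenology_genotypes=x_phen,
    )
    return table, truth


def simulate_nil_experiment(
    pair_effects: dict,
    baselines: dict,
    n_plants: int = 48,
    n_blocks: int = 2,
    block_sigma2: float = 0.0,
    noise_sigma2: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Trait table for a NIL validation trial (randomised complete blocks).

    ``pair_effects`` maps pair_id -> {trait: AA-minus-BB effect};
    ``baselines`` maps trait -> baseline level.  Each pair member gets
    ``n_plants`` plant-level values per block: baseline + allele effect
    (+effect for the AA member) + block effect + iid noise.
    """
    if n_plants < 2:
        raise ValueError("need at least 2 plants per plot")
    rng = np.random.default_rng(seed)
    traits = sorted(baselines)
    rows = []
    for pair_id in sorted(pair_effects):
        effects = pair_effects[pair_id]
        for b in range(n_blocks):
            blk = {t: rng.normal(0.0, np.sqrt(block_sigma2)) if block_sigma2 > 0 else 0.0
                   for t in traits}
            for member in ("AA", "BB"):
                for plant in range(n_plants):
                    rec = {"pair": pair_id, "member": member,
                           "block": b + 1, "plant": plant + 1}
                    for t in traits:
                        eff = effects.get(t, 0.0) if member == "AA" else 0.0
                        rec[t] = baselines[t] + eff + blk[t] \
                            + rng.normal(0.0, np.sqrt(noise_sigma2))
                    rows.append(rec)
    return pd.DataFrame.from_records(rows)
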