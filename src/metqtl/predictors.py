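"""Marker-interval genetic predictors for whole-genome scanning.

A genetic predictor at an arbitrary map position is the conditional
expectation of the ±1-coded genotype given the nearest non-missing flanking
markers, with flanking-marker distances converted to recombination fractions
through the Kosambi map function and the three-point conditional
probabilities combined under no interference.  At an observed homozygous
marker the predictor is exactly +1 (parent-1 / Excalibur-role allele) or -1
(parent-2 / Kukri-role allele); between markers, or where calls are missing,
it shrinks towards 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genmap import CALL_A, CALL_B, CALL_NA, GeneticMap, GenotypeMatrix, r_from_kosambi_cm

__all__ = ["QueryPosition", "PredictorMatrix", "interval_probability", "line_predictor", "predictor_matrix"]


@dataclass(frozen=True)
class QueryPosition:
    group: str
    pos_cM: float
    label: str
    left_marker: str | None
    right_marker: str | None


@dataclass
class PredictorMatrix:
    """Lines x query-positions matrix of expected ±1 genotype codes."""

    lines: list[str]
    queries: list[QueryPosition]
    values: np.ndarray  # (n_lines, n_queries), entries in [-1, 1]

    def column(self, label: str) -> np.ndarray:
        labels = [q.label for q in self.queries]
        return self.values[:, labels.index(label)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[q.label for q in self.queries])
        df.insert(0, "line", self.lines)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def interval_probability(left_state, right_state, r_left: float, r_right: float) -> float:
    """P(query locus carries the A allele | flanking DH calls).

    ``left_state``/``right_state`` are 'A', 'B' or None (no informative
    flank on that side).  Under no interference the flank-to-flank fraction
    is r_LR = r_l + r_r - 2 r_l r_r and the conditional probabilities follow
    from the joint DH three-locus frequencies.
    """
    for r in (r_left, r_right):
        if r is not None and not (0 <= r < 0.5):
            raise ValueError("recombination fractions must lie in [0, 0.5)")
    ls, rs = left_state, right_state
    if ls is None and rs is None:
        return 0.5
    if rs is None:
        p_same = 1.0 - r_left
        return p_same if ls == "A" else 1.0 - p_same
    if ls is None:
        p_same = 1.0 - r_right
        return p_same if rs == "A" else 1.0 - p_same

    r_lr = r_left + r_right - 2.0 * r_left * r_right
    if ls == rs:
        denom = 1.0 - r_lr
        num = (1.0 - r_left) * (1.0 - r_right) if ls == "A" else r_left * r_right
        return num / denom
    if r_lr == 0.0:
        raise ValueError("discordant flanks at zero recombination distance")
    if ls == "A":  # (A, B)
        return (1.0 - r_left) * r_right / r_lr
    return r_left * (1.0 - r_right) / r_lr  # (B, A)


def _flank_states(codes: np.ndarray, positions: np.ndarray, pos: float):
    """Nearest non-missing flanking calls around ``pos`` (outward search)."""
    obs = codes != CALL_NA
    left = right = None
    d_left = d_right = None
    left_idx = right_idx = None
    # markers at the query position count as a left flank at distance zero
    for i in range(len(positions) - 1, -1, -1):
        if positions[i] <= pos and obs[i]:
            left = "A" if codes[i] == CALL_A else "B"
            d_left = pos - positions[i]
            left_idx = i
            break
    for i in range(len(positions)):
        if positions[i] > pos and obs[i]:
            right = "A" if codes[i] == CALL_A else "B"
            d_right = positions[i] - pos
            right_idx = i
            break
    return left, d_left, left_idx, right, d_right, right_idx


def line_predictor(line_calls, gmap: GeneticMap, group: str, pos_cM: float) -> float:
    """Expected ±1 genotype of one line at (group, pos_cM).

    ``line_calls`` is the line's call codes in map marker order (full map).
    A line with no informative marker on the group scores 0 (no information).
    """
    sub = gmap.group_table(group)
    idx = sub.index.to_numpy()
    positions = sub["pos_cM"].to_numpy()
    codes = np.asarray(line_calls, dtype=np.int8)[idx]
    ls, dl, _, rs, dr, _ = _flank_states(codes, positions, pos_cM)
    if ls is None and rs is None:
        warnings.warn(f"line has no informative marker on group {group!r}; predictor set to 0")
        return 0.0
    r_l = r_from_kosambi_cm(dl) if ls is not None else None
    r_r = r_from_kosambi_cm(dr) if rs is not None else None
    p_a = interval_probability(ls, rs, r_l, r_r)
    return 2.0 * p_a - 1.0


def _group_predictors(codes_block, positions, queries):
    """Predictor values for all lines of one group at the given positions."""
    n_lines = codes_block.shape[0]
    out = np.zeros((n_lines, len(queries)))
    for i in range(n_lines):
        codes = codes_block[i]
        for q, pos in enumerate(queries):
            ls, dl, _, rs, dr, _ = _flank_states(codes, positions, pos)
            if ls is None and rs is None:
                continue
            r_l = r_from_kosambi_cm(dl) if ls is not None else None
            r_r = r_from_kosambi_cm(dr) if rs is not None else None
            out[i, q] = 2.0 * interval_probability(ls, rs, r_l, r_r) - 1.0
    return out


def predictor_matrix(
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    scheme: str = "interval_midpoints",
) -> PredictorMatrix:
    """Build the lines x query-positions predictor matrix.

    ``interval_midpoints`` places one predictor at the midpoint of each
    adjacent-marker interval per group, labelled by its flanking markers
    (groups with fewer than two markers are skipped with a warning);
    ``markers`` evaluates at the marker positions themselves; ``both``
    concatenates the two schemes in map order.
    """
    if scheme not in ("interval_midpoints", "markers", "both"):
        raise ValueError(f"unknown scheme: {scheme!r}")
    shared = [m for m in gmap.markers if m in genotypes._marker_idx]
    gmap = gmap.subset(shared)
    genotypes = genotypes.subset_markers(shared)

    queries: list[QueryPosition] = []
    blocks: list[np.ndarray] = []
    for group in gmap.groups:
        sub = gmap.group_table(group)
        markers = sub["marker"].tolist()
        positions = sub["pos_cM"].to_numpy()
        codes_block = np.stack([genotypes.column(m) for m in markers], axis=1)

        group_queries: list[QueryPosition] = []
        if scheme in ("interval_midpoints", "both"):
            if len(markers) < 2:
                warnings.warn(f"group {group!r} has < 2 markers; skipped for interval scheme")
            else:
                for k in range(len(markers) - 1):
                    mid = 0.5 * (positions[k] + positions[k + 1])
                    group_queries.append(
                        QueryPosition(
                            group, mid, f"{group}:{markers[k]}-{markers[k + 1]}",
                            markers[k], markers[k + 1],
                        )
                    )
        if scheme in ("markers", "both"):
            for k, m in enumerate(markers):
                group_queries.append(
                    QueryPosition(group, positions[k], f"{group}:{m}", m, m)
                )
        if scheme == "both":
            group_queries.sort(key=lambda q: q.pos_cM)
        if not group_queries:
            continue
        queries.extend(group_queries)
        blocks.append(
            _group_predictors(codes_block, positions, [q.pos_cM for q in group_queries])
        )
    values = np.concatenate(blocks, axis=1) if blocks else np.zeros((len(genotypes.lines), 0))
    return PredictorMatrix(list(genotypes.lines), queries, values)
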