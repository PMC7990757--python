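"""Near-isogenic line (NIL) development bookkeeping and fine mapping.

NILs are sib lines fixed for opposite parental alleles across a target
marker segment but (ideally) identical elsewhere.  This module selects
heterozygous progenitors, derives homozygous sib pairs and their differing
segments, checks background homogeneity, compares traits between pair
members with t-tests, and delimits the QTL interval from the concordance of
segments with phenotype differences: the region shared by all phenotypically
significant pairs minus anything covered by a non-significant pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genmap import CALL_A, CALL_B, CALL_H, CALL_NA, GeneticMap, GenotypeMatrix

__all__ = [
    "NILPair", "PairComparison", "select_heterozygous", "derive_pairs",
    "background_homogeneity", "compare_traits", "delimit_interval",
    "derived_traits", "pair_report",
]


@dataclass
class NILPair:
    pair_id: str
    line_AA: str
    line_BB: str
    segment_markers: tuple[str, ...]   # contiguous block, map order
    group: str
    background_identity: float | None = None


@dataclass
class PairComparison:
    trait: str
    mean_AA: float
    mean_BB: float
    t: float
    df: int
    p: float
    stars: str       # "ns", "*", "**", "***"
    pct_diff: float  # 100 * (mean_AA - mean_BB) / mean_BB
    degenerate: bool = False


def _stars(p: float) -> str:
    # strict inequalities: p exactly at a cutoff stays in the weaker tier
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def select_heterozygous(genotypes: GenotypeMatrix, target_markers: Sequence[str]) -> list[str]:
    """Lines heterozygous at every target marker (NIL progenitor candidates)."""
    if genotypes.is_dh:
        raise ValueError("doubled haploids carry no heterozygotes; use RIL genotypes")
    mask = np.ones(len(genotypes.lines), dtype=bool)
    for m in target_markers:
        mask &= genotypes.column(m) == CALL_H
    out = [l for l, keep in zip(genotypes.lines, mask) if keep]
    if not out:
        warnings.warn("no line heterozygous at all target markers")
    return out


def derive_pairs(
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    interval_markers: Sequence[str],
    families: Mapping[str, Sequence[str]],
) -> list[NILPair]:
    """Pair homozygous sibs within each family over the interval markers.

    Within a family, the member carrying parent-1 (A) alleles in the
    interval is paired with an all-B member; the pair's segment is the
    maximal contiguous block of interval markers where the members carry
    opposite homozygous calls.  Families lacking one homozygous class are
    skipped with a warning.
    """
    groups = {gmap.position(m)[0] for m in interval_markers}
    if len(groups) != 1:
        raise ValueError("interval markers must lie on one linkage group")
    group = groups.pop()
    ordered = [m for m in gmap.group_table(group)["marker"] if m in set(interval_markers)]

    pairs = []
    for fam, members in families.items():
        calls = {l: np.array([genotypes.column(m)[genotypes.lines.index(l)]
                              for m in ordered]) for l in members}
        homoz = {l: c for l, c in calls.items()
                 if not np.any((c == CALL_H) | (c == CALL_NA))}
        a_cands = [l for l, c in homoz.items() if np.any(c == CALL_A)]
        b_cands = [l for l, c in homoz.items() if np.all(c == CALL_B)]
        # an all-A line is the cleanest A member; fall back to recombinants
        a_cands.sort(key=lambda l: -int(np.sum(homoz[l] == CALL_A)))
        b_only = [l for l in b_cands if l not in a_cands]
        if not a_cands or not b_only:
            warnings.warn(f"family {fam!r} lacks a homozygous class; skipped")
            continue
        la, lb = a_cands[0], b_only[0]
        diff = (homoz[la] == CALL_A) & (homoz[lb] == CALL_B)
        seg = _longest_run(diff)
        if not seg:
            warnings.warn(f"family {fam!r} members do not differ in the interval; skipped")
            continue
        pairs.append(NILPair(
            pair_id=fam, line_AA=la, line_BB=lb,
            segment_markers=tuple(ordered[i] for i in seg), group=group,
        ))
    return pairs


def _longest_run(mask: np.ndarray) -> list[int]:
    best: list[int] = []
    cur: list[int] = []
    for i, v in enumerate(mask):
        if v:
            cur.append(i)
            if len(cur) > len(best):
                best = list(cur)
        else:
            cur = []
    return best


def background_homogeneity(
    pair: NILPair,
    genotypes: GenotypeMatrix,
    background_markers: Sequence[str],
) -> float | None:
    """Fraction of background markers with identical non-missing calls.

    Background markers overlapping the pair's segment are rejected; returns
    None (undefined) when no marker is jointly observed in both members.
    """
    overlap = set(background_markers) & set(pair.segment_markers)
    if overlap:
        raise ValueError(f"background markers overlap the segment: {sorted(overlap)}")
    ca = genotypes.line_row(pair.line_AA)
    cb = genotypes.line_row(pair.line_BB)
    idx = [genotypes._marker_idx[m] for m in background_markers]
    a, b = ca[idx], cb[idx]
    both = (a != CALL_NA) & (b != CALL_NA)
    if not both.any():
        warnings.warn(f"pair {pair.pair_id!r}: no jointly observed background marker")
        return None
    return float(np.mean(a[both] == b[both]))


def compare_traits(values_AA, values_BB, trait: str = "trait",
                   welch: bool = False) -> PairComparison:
    """Two-sided two-sample t-test between NIL pair members.

    Pooled-variance Student test by default (``welch=True`` for unequal
    variances).  Star tiers follow p < 0.05 / 0.01 / 0.001 with strict
    inequalities; pct_diff is the AA mean relative to the BB mean.
    """
    a = np.asarray(values_AA, dtype=float)
    b = np.asarray(values_BB, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 replicate values per member")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    va, vb = float(a.var(ddof=1)), float(b.var(ddof=1))
    degenerate = False
    if va == 0.0 and vb == 0.0:
        if mean_a == mean_b:
            t, df, p = 0.0, a.size + b.size - 2, 1.0
        else:
            t, df, p = np.inf if mean_a > mean_b else -np.inf, a.size + b.size - 2, 0.0
            degenerate = True
    else:
        res = stats.ttest_ind(a, b, equal_var=not welch)
        t, p = float(res.statistic), float(res.pvalue)
        df = int(round(res.df))
    pct = 100.0 * (mean_a - mean_b) / mean_b if mean_b != 0 else np.nan
    return PairComparison(trait=trait, mean_AA=mean_a, mean_BB=mean_b,
                          t=t, df=df, p=p, stars=_stars(p), pct_diff=pct,
                          degenerate=degenerate)


def delimit_interval(
    pairs: Sequence[NILPair],
    comparisons: Mapping[str, PairComparison],
    gmap: GeneticMap,
    alpha: float = 0.05,
) -> tuple[str | None, str | None, float]:
    """Delimit the QTL region from segment/phenotype concordance.

    Candidate region = intersection of the segments of phenotypically
    significant pairs (p < alpha) minus the union of the segments of
    non-significant pairs.  Returns the markers immediately flanking the
    surviving block (None at a map end) and its cM span.  Discordant
    configurations (empty intersection, or a non-significant segment
    covering it entirely) raise rather than resolve silently.
    """
    sig = [p for p in pairs if comparisons[p.pair_id].p < alpha]
    nonsig = [p for p in pairs if comparisons[p.pair_id].p >= alpha]
    if not sig:
        raise ValueError("no pair is significant for the focal trait")
    groups = {p.group for p in pairs}
    if len(groups) != 1:
        raise ValueError("pairs span multiple linkage groups")
    group = groups.pop()

    region = set(sig[0].segment_markers)
    for p in sig[1:]:
        region &= set(p.segment_markers)
    if not region:
        raise ValueError("discordant pairs: significant segments do not intersect")
    for p in nonsig:
        region -= set(p.segment_markers)
    if not region:
        raise ValueError("discordant pairs: non-significant segments cover the "
                         "entire shared significant region")

    sub = gmap.group_table(group).reset_index(drop=True)
    order = sub["marker"].tolist()
    idx = sorted(order.index(m) for m in region)
    left = order[idx[0] - 1] if idx[0] > 0 else None
    right = order[idx[-1] + 1] if idx[-1] < len(order) - 1 else None
    span = float(sub["pos_cM"].iloc[idx[-1]] - sub["pos_cM"].iloc[idx[0]])
    return left, right, span


def derived_traits(records: pd.DataFrame) -> pd.DataFrame:
    """Add derived trait columns where their components are present.

    Scr = 100 * screened_weight / total_weight (percent small grains),
    HI = Yld / BM (harvest index), GFD = DTM - DTA (grain-filling days).
    """
    out = records.copy()
    if {"screened_weight", "total_weight"} <= set(out.columns):
        out["Scr"] = 100.0 * out["screened_weight"] / out["total_weight"]
    if {"Yld", "BM"} <= set(out.columns):
        out["HI"] = out["Yld"] / out["BM"]
    if {"DTA", "DTM"} <= set(out.columns):
        out["GFD"] = out["DTM"] - out["DTA"]
    return out


def pair_report(
    pairs: Sequence[NILPair],
    comparisons: Mapping[str, Mapping[str, PairComparison]],
) -> pd.DataFrame:
    """Per-pair, per-trait summary table (segment bounds, t, p, stars)."""
    rows = []
    for p in pairs:
        for trait, c in comparisons.get(p.pair_id, {}).items():
            rows.append({
                "pair": p.pair_id, "group": p.group,
                "segment_start": p.segment_markers[0],
                "segment_end": p.segment_markers[-1],
                "background_identity": p.background_identity,
                "trait": trait, "t": c.t, "df": c.df, "p": c.p,
                "stars": c.stars, "pct_diff": c.pct_diff,
            })
    return pd.DataFrame.from_records(rows)
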