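"""Genetic maps and biparental genotype matrices.

The containers here carry the two genetic inputs of the pipeline: an ordered
linkage map (marker, linkage group, position in centimorgans) and a lines x
markers matrix of categorical calls for a biparental population.  Calls are
coded relative to the two parents: ``A`` for the parent-1 allele, ``B`` for
the parent-2 allele, ``H`` for heterozygotes (absent in doubled-haploid
material) and ``NA`` for missing.  Map distances are interconverted with
recombination fractions through the Kosambi map function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneticMap",
    "GenotypeMatrix",
    "RecombEstimate",
    "kosambi_cm_from_r",
    "r_from_kosambi_cm",
    "estimate_recomb_fraction",
    "segregation_distortion_test",
    "filter_markers",
]

# integer codes for genotype calls; NA deliberately 0 so bool(call) tests presence
CALL_NA = 0
CALL_A = 1
CALL_B = 2
CALL_H = 3

_STR_TO_CODE = {"A": CALL_A, "B": CALL_B, "H": CALL_H, "NA": CALL_NA, "": CALL_NA}
_CODE_TO_STR = {CALL_A: "A", CALL_B: "B", CALL_H: "H", CALL_NA: "NA"}

# recombination fractions are capped just below 1/2 before map conversion:
# unlinked markers carry no interval information and would map to infinity
R_CAP = 0.4999


def kosambi_cm_from_r(r):
    """Map distance in cM for recombination fraction ``r`` (Kosambi).

    d = 100 * (1/4) * ln((1+2r)/(1-2r)); defined for 0 <= r < 0.5.
    """
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(d) if d.ndim == 0 else d


def r_from_kosambi_cm(d):
    """Recombination fraction for a Kosambi map distance ``d`` in cM.

    Inverse of :func:`kosambi_cm_from_r`: r = tanh(2d/100) / 2.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * np.tanh(2.0 * d / 100.0)
    return float(r) if r.ndim == 0 else r


@dataclass
class GeneticMap:
    """Ordered linkage map: one row per marker with group and cM position."""

    table: pd.DataFrame  # columns: marker, group, pos_cM

    def __post_init__(self) -> None:
        t = self.table
        required = {"marker", "group", "pos_cM"}
        if not required.issubset(t.columns):
            raise ValueError(f"map table needs columns {sorted(required)}")
        if t["marker"].duplicated().any():
            dups = t.loc[t["marker"].duplicated(), "marker"].tolist()
            raise ValueError(f"duplicate marker names in map: {dups[:5]}")
        if (t["pos_cM"] < 0).any():
            raise ValueError("map positions must be >= 0")
        for g, sub in t.groupby("group", sort=False):
            if not np.all(np.diff(sub["pos_cM"].to_numpy()) >= 0):
                raise ValueError(f"positions not non-decreasing within group {g!r}")
        self.table = t.reset_index(drop=True)

    @property
    def markers(self) -> list[str]:
        return self.table["marker"].tolist()

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.table["group"]))

    def group_table(self, group: str) -> pd.DataFrame:
        sub = self.table[self.table["group"] == group]
        if sub.empty:
            raise KeyError(f"no such linkage group: {group!r}")
        return sub

    def position(self, marker: str) -> tuple[str, float]:
        row = self.table[self.table["marker"] == marker]
        if row.empty:
            raise KeyError(f"marker not on map: {marker!r}")
        return row["group"].iloc[0], float(row["pos_cM"].iloc[0])

    def subset(self, markers) -> "GeneticMap":
        keep = self.table["marker"].isin(set(markers))
        return GeneticMap(self.table[keep].reset_index(drop=True))

    @classmethod
    def read_csv(cls, path) -> "GeneticMap":
        t = pd.read_csv(path, dtype={"marker": str, "group": str})
        return cls(t[["marker", "group", "pos_cM"]])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class GenotypeMatrix:
    """Lines x markers categorical calls for a biparental population.

    ``calls`` is an int8 array with the CALL_* codes above.  ``is_dh`` marks
    doubled-haploid material, for which heterozygous calls are invalid.
    """

    lines: list[str]
    markers: list[str]
    calls: np.ndarray
    is_dh: bool = True
    _marker_idx: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.lines), len(self.markers)):
            raise ValueError("calls shape must be (n_lines, n_markers)")
        if self.is_dh and np.any(self.calls == CALL_H):
            raise ValueError("doubled-haploid matrix contains heterozygous calls")
        self._marker_idx = {m: j for j, m in enumerate(self.markers)}

    def column(self, marker: str) -> np.ndarray:
        return self.calls[:, self._marker_idx[marker]]

    def line_row(self, line: str) -> np.ndarray:
        return self.calls[self.lines.index(line)]

    def missing_rate(self) -> np.ndarray:
        """Per-marker fraction of missing calls."""
        return (self.calls == CALL_NA).mean(axis=0)

    def to_numeric(self) -> np.ndarray:
        """+1 for A, -1 for B, 0 for H, NaN for missing."""
        out = np.full(self.calls.shape, np.nan)
        out[self.calls == CALL_A] = 1.0
        out[self.calls == CALL_B] = -1.0
        out[self.calls == CALL_H] = 0.0
        return out

    def subset_markers(self, markers) -> "GenotypeMatrix":
        idx = [self._marker_idx[m] for m in markers]
        return GenotypeMatrix(self.lines, list(markers), self.calls[:, idx], self.is_dh)

    @classmethod
    def from_strings(cls, lines, markers, rows, is_dh: bool = True) -> "GenotypeMatrix":
        arr = np.array(
            [[_STR_TO_CODE[str(c).strip()] for c in row] for row in rows], dtype=np.int8
        )
        return cls(list(lines), list(markers), arr, is_dh)

    @classmethod
    def read_csv(cls, path, is_dh: bool = True) -> "GenotypeMatrix":
        t = pd.read_csv(path, dtype=str).fillna("NA")
        lines = t.iloc[:, 0].tolist()
        markers = list(t.columns[1:])
        return cls.from_strings(lines, markers, t.iloc[:, 1:].to_numpy(), is_dh)

    def to_csv(self, path, numeric: bool = False) -> None:
        if numeric:
            num = self.to_numeric()
            df = pd.DataFrame(num, columns=self.markers)
            df = df.map(lambda v: "" if np.isnan(v) else f"{v:+.0f}")
        else:
            df = pd.DataFrame(
                [[_CODE_TO_STR[c] for c in row] for row in self.calls],
                columns=self.markers,
            )
        df.insert(0, "line", self.lines)
        df.to_csv(path, index=False)


@dataclass
class RecombEstimate:
    r_hat: float | None
    n_informative: int

    @property
    def informative(self) -> bool:
        return self.n_informative > 0


def estimate_recomb_fraction(calls_a, calls_b, population_type: str = "DH") -> RecombEstimate:
    """Estimate the recombination fraction between two DH marker columns.

    r_hat is the discordance rate among lines with both calls present,
    capped at :data:`R_CAP` so the Kosambi conversion stays finite.  A
    column pair with no jointly observed lines yields a flagged
    no-information result rather than a number.
    """
    if population_type != "DH":
        raise NotImplementedError("only DH populations are supported")
    a = np.asarray(calls_a, dtype=np.int8)
    b = np.asarray(calls_b, dtype=np.int8)
    if a.shape != b.shape:
        raise ValueError("marker columns must have equal length")
    for col in (a, b):
        if np.any(col == CALL_H):
            raise ValueError("DH columns must not contain H calls")
    both = (a != CALL_NA) & (b != CALL_NA)
    n = int(both.sum())
    if n == 0:
        return RecombEstimate(r_hat=None, n_informative=0)
    r = float(np.mean(a[both] != b[both]))
    return RecombEstimate(r_hat=min(r, R_CAP), n_informative=n)


def segregation_distortion_test(calls) -> tuple[float, float]:
    """Chi-square goodness-of-fit of a DH marker column against 1:1.

    Returns (chi2, upper-tail p) with 1 degree of freedom; missing calls
    are ignored.
    """
    a = np.asarray(calls, dtype=np.int8)
    n_a = int(np.sum(a == CALL_A))
    n_b = int(np.sum(a == CALL_B))
    n = n_a + n_b
    if n == 0:
        raise ValueError("no non-missing calls to test")
    expected = n / 2.0
    chi2 = (n_a - expected) ** 2 / expected + (n_b - expected) ** 2 / expected
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def filter_markers(
    gmap: GeneticMap,
    genotypes: GenotypeMatrix,
    max_missing: float = 0.20,
    distortion_alpha: float = 1e-3,
    n_tests: int | None = None,
) -> tuple[GeneticMap, GenotypeMatrix, pd.DataFrame]:
    """Drop markers with too many missing calls or strong segregation distortion.

    A marker is removed when its missing rate exceeds ``max_missing`` or its
    1:1 distortion p-value falls below ``distortion_alpha`` (divided by
    ``n_tests`` when a family-wise adjustment over a fixed number of tests
    is wanted).  Returns the filtered map and matrix (input order preserved)
    plus a report of removals with reasons.
    """
    if not (0 < max_missing < 1) or not (0 < distortion_alpha < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    cutoff = distortion_alpha / n_tests if n_tests else distortion_alpha

    removals = []
    keep = []
    shared = [m for m in gmap.markers if m in genotypes._marker_idx]
    for m in shared:
        col = genotypes.column(m)
        miss = float(np.mean(col == CALL_NA))
        if miss > max_missing:
            removals.append((m, "missing", miss))
            continue
        if np.any(col != CALL_NA):
            chi2, p = segregation_distortion_test(col)
            if p < cutoff:
                removals.append((m, "distortion", p))
                continue
        keep.append(m)
    if not keep:
        raise ValueError(
            f"all markers removed (max_missing={max_missing}, "
            f"distortion cutoff={cutoff})"
        )
    report = pd.DataFrame(removals, columns=["marker", "reason", "value"])
    return gmap.subset(keep), genotypes.subset_markers(keep), report
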