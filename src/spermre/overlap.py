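"""Gene-list overlap statistics and exposure-response movement patterns.

The significance of an overlap x between two gene lists of sizes n1 and n2
drawn from a universe of N genes follows the hypergeometric distribution.
Reported alongside the one-sided tail probabilities is the representation
factor x / (n1*n2/N): >1 means more overlap than expected by chance.  The
``normal_approx`` method uses the hypergeometric mean and variance with a
+/-0.5 continuity correction, matching the classic online calculator style of
over/under-representation testing; one-sided tails are reported separately,
never doubled.

Movement patterns describe how an RE's abundance moves across the two
segments of a crossover-crossback arm ("Down—same", "Up—up", ...).  A segment
is called Up/Down only when that segment's comparison flagged the RE as
significant; otherwise it is Same.  Significance comes from membership in the
segment's responsive list, not from re-testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import normalize_symbol, SEGMENTS

__all__ = [
    "OverlapResult",
    "MovementPattern",
    "DBPComparison",
    "ADDITION_SEGMENTS",
    "WITHDRAWAL_SEGMENTS",
    "SEGMENT_ARM",
    "hypergeometric_overlap",
    "intersect_lists",
    "classify_movement",
    "movement_table",
    "consistent_responders",
    "shared_between_arms",
    "welch_t",
]

# segments where high-DBP is added vs withdrawn
ADDITION_SEGMENTS = frozenset({"B1H", "BH2"})
WITHDRAWAL_SEGMENTS = frozenset({"H1B", "HB2"})
SEGMENT_ARM = {"B1H": "B1HB2", "HB2": "B1HB2", "H1B": "H1BH2", "BH2": "H1BH2"}


@dataclass(frozen=True)
class OverlapResult:
    x: int
    n1: int
    n2: int
    N: int
    expected: float
    representation_factor: float
    p_over: float
    p_under: float
    method: str

    def as_dict(self) -> dict:
        return {
            "x": self.x, "n1": self.n1, "n2": self.n2, "N": self.N,
            "expected": self.expected,
            "representation_factor": self.representation_factor,
            "p_over": self.p_over, "p_under": self.p_under,
            "method": self.method,
        }


@dataclass
class DBPComparison:
    """One crossover-crossback segment's responsive RE list."""

    arm: str
    segment: str
    entries: pd.DataFrame  # re_id, gene, direction in {up, down}, empirical_p

    def __post_init__(self) -> None:
        if self.segment not in SEGMENTS:
            raise ValueError(f"unknown segment {self.segment!r}")
        if SEGMENT_ARM[self.segment] != self.arm:
            raise ValueError(f"segment {self.segment} inconsistent with arm {self.arm}")
        p = self.entries["empirical_p"].to_numpy(dtype=float)
        if len(p) and ((p <= 0).any() or (p > 0.05).any()):
            raise ValueError(f"{self.segment}: empirical_p outside (0, 0.05]")

    @property
    def genes(self) -> list[str]:
        return sorted({normalize_symbol(g) for g in self.entries["gene"]})


def hypergeometric_overlap(
    x: int, n1: int, n2: int, N: int,
    method: str = "exact",
    continuity_correction: bool = True,
) -> OverlapResult:
    """Tail probabilities and representation factor for an overlap of x genes.

    ``p_over`` = P[X >= x] (includes the observed x); ``p_under`` = P[X <= x].
    """
    if N <= 0:
        raise ValueError("universe size N must be positive")
    if not (0 <= n1 <= N and 0 <= n2 <= N):
        raise ValueError(f"list sizes must lie in [0, N]: n1={n1}, n2={n2}, N={N}")
    lo, hi = max(0, n1 + n2 - N), min(n1, n2)
    if not (lo <= x <= hi):
        raise ValueError(f"infeasible overlap x={x}; feasible range [{lo}, {hi}]")
    expected = n1 * n2 / N
    rf = x / expected if expected > 0 else (math.inf if x > 0 else 1.0)
    if method == "exact":
        dist = stats.hypergeom(N, n1, n2)
        p_over = float(dist.sf(x - 1))
        p_under = float(dist.cdf(x))
    elif method == "normal_approx":
        var = n1 * n2 * (N - n1) * (N - n2) / (N**2 * (N - 1)) if N > 1 else 0.0
        if var == 0.0:
            p_over = 1.0 if x <= expected else 0.0
            p_under = 1.0 if x >= expected else 0.0
        else:
            sd = math.sqrt(var)
            cc = 0.5 if continuity_correction else 0.0
            p_over = float(stats.norm.sf((x - cc - expected) / sd))
            p_under = float(stats.norm.cdf((x + cc - expected) / sd))
    else:
        raise ValueError(f"unknown method {method!r}")
    p_over = min(max(p_over, 0.0), 1.0)
    p_under = min(max(p_under, 0.0), 1.0)
    return OverlapResult(x=x, n1=n1, n2=n2, N=N, expected=expected,
                         representation_factor=rf, p_over=p_over,
                         p_under=p_under, method=method)


def intersect_lists(a: Iterable[str], b: Iterable[str]) -> list[str]:
    """Sorted intersection of two gene lists after symbol normalization."""
    sa = {normalize_symbol(g) for g in a}
    sb = {normalize_symbol(g) for g in b}
    return sorted(sa & sb)


@dataclass(frozen=True)
class MovementPattern:
    re_id: str
    first: str   # Up / Down / Same
    second: str

    def __post_init__(self) -> None:
        for v in (self.first, self.second):
            if v not in ("Up", "Down", "Same"):
                raise ValueError(f"bad movement direction {v!r}")

    @property
    def label(self) -> str:
        """Rendered as printed: capitalized first segment, em dash, lowercase second."""
        return f"{self.first}—{self.second.lower()}"


def classify_movement(
    mean_baseline: float,
    mean_crossover: float,
    mean_crossback: float,
    sig_first: bool,
    sig_second: bool,
    re_id: str = "",
) -> MovementPattern:
    """Direction of abundance movement over the two segments of one arm."""
    def direction(before: float, after: float, sig: bool) -> str:
        if not sig:
            return "Same"
        if after > before:
            return "Up"
        if after < before:
            return "Down"
        raise ValueError(f"{re_id or 'RE'}: significant segment with equal means")

    return MovementPattern(
        re_id=re_id,
        first=direction(mean_baseline, mean_crossover, sig_first),
        second=direction(mean_crossover, mean_crossback, sig_second),
    )


def movement_table(
    visit_means: pd.DataFrame,
    sig_first: set[str],
    sig_second: set[str],
) -> pd.DataFrame:
    """Movement patterns for every RE with baseline/crossover/crossback means.

    ``visit_means`` is indexed by re_id with columns baseline, crossover,
    crossback; ``sig_first``/``sig_second`` are the RE ids flagged significant
    in the arm's first and second segment comparisons.
    """
    for col in ("baseline", "crossover", "crossback"):
        if col not in visit_means.columns:
            raise ValueError(f"visit_means missing column {col!r}")
    rows = []
    for rid, r in visit_means.iterrows():
        mp = classify_movement(r["baseline"], r["crossover"], r["crossback"],
                               rid in sig_first, rid in sig_second, re_id=str(rid))
        rows.append((rid, mp.first, mp.second, mp.label))
    return pd.DataFrame(rows, columns=["re_id", "first", "second", "pattern"]) \
        .set_index("re_id")


def consistent_responders(
    moves: pd.DataFrame,
) -> list[str]:
    """Genes moving coherently under DBP addition vs withdrawal.

    ``moves`` needs columns gene, segment, direction ('up'/'down'), one row
    per significant gene-segment call.  A gene qualifies iff it has at least
    one significant addition-segment move and one withdrawal-segment move,
    each side is internally unanimous, and the two sides point in opposite
    directions (abundance tracking exposure either way round).
    """
    for col in ("gene", "segment", "direction"):
        if col not in moves.columns:
            raise ValueError(f"moves missing column {col!r}")
    bad = set(moves["segment"]) - set(SEGMENTS)
    if bad:
        raise ValueError(f"unknown segment(s) {sorted(bad)}")
    out = []
    df = moves.assign(gene=moves["gene"].map(normalize_symbol))
    for gene, grp in df.groupby("gene"):
        add = set(grp.loc[grp["segment"].isin(ADDITION_SEGMENTS), "direction"])
        wd = set(grp.loc[grp["segment"].isin(WITHDRAWAL_SEGMENTS), "direction"])
        if len(add) == 1 and len(wd) == 1 and add != wd:
            out.append(gene)
    return sorted(out)


def shared_between_arms(
    genes_a: Iterable[str], genes_b: Iterable[str]
) -> tuple[list[str], list[str], list[str]]:
    """(specific to A, specific to B, shared) after normalization."""
    sa = {normalize_symbol(g) for g in genes_a}
    sb = {normalize_symbol(g) for g in genes_b}
    return sorted(sa - sb), sorted(sb - sa), sorted(sa & sb)


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-tailed t test for two samples of unequal variance (Welch)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs >= 2 values")
    if np.var(x, ddof=1) == 0.0 and np.var(y, ddof=1) == 0.0:
        raise ValueError("degenerate variance: both samples are constant")
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)
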