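"""P-value partitioning and local gene-set over-representation analysis (ORA).

Large responsive-RE lists are split into six groups by empirical p value
(boundaries 0.013, 0.023, 0.032, 0.041, 0.045, 0.05) so that no single query
exceeds the 500-recognized-gene analysis cap.  Group 1 is (0, 0.013); later
groups are closed intervals [b_{k-1}, b_k] assigned first-match, so the
partition exhausts (0, 0.05] with no gaps (a boundary p lands in the earlier
eligible group).

ORA replaces the web-service workflow with a local hypergeometric test per
gene set: p = P[X >= k] for k = |query ∩ set| within a stated universe,
Benjamini–Hochberg FDR within each collection separately, reporting at most
the top 100 sets with q < 0.05 and a minimum two-gene overlap.

Enriched set names are mapped to five biological-process categories
(cellular stress, cell cycle, apoptosis, DNA damage response, gene
regulation) via an ordered, editable keyword map.  The shipped default is a
reconstruction of a manual curation, not an authoritative ontology.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import normalize_symbol
from .overlap import OverlapResult, hypergeometric_overlap

__all__ = [
    "DEFAULT_BOUNDARIES",
    "DEFAULT_CATEGORY_MAP",
    "CATEGORIES",
    "PValueGroups",
    "GroupCapacityError",
    "partition_by_pvalue",
    "ora",
    "categorize",
    "proportion_test",
]

DEFAULT_BOUNDARIES = (0.013, 0.023, 0.032, 0.041, 0.045, 0.05)

CATEGORIES = (
    "cellular stress",
    "cell cycle",
    "apoptosis",
    "DNA damage response",
    "gene regulation",
    "uncategorized",
)

# Ordered (pattern, category) pairs; first match wins.  DNA damage precedes
# cellular stress so UV/radiation signatures are not swallowed by "RESPONSE".
DEFAULT_CATEGORY_MAP: tuple[tuple[str, str], ...] = (
    (r"APOPTOSIS|CELL_DEATH|PROGRAMMED_CELL", "apoptosis"),
    (r"CELL_CYCLE|G2M|MITOTIC|CHECKPOINT|DREAM_TARGETS|E2F", "cell cycle"),
    (r"DNA_DAMAGE|DNA_REPAIR|UV_RESPONSE|RADIATION|POSTRADIATION", "DNA damage response"),
    (r"STRESS|RESPONSES?_TO_STIMUL|RESPONSE_VIA|TRETINOIN_RESPONSE", "cellular stress"),
    (r"TRANSCRIPTION|CHROMATIN|HISTONE|HDAC|RNA_POLYMERASE|RNA_METABOL"
     r"|GENE_EXPRESSION|SMARCA|FOXP3|MYC_TARGETS|REGULATION_OF", "gene regulation"),
)


class GroupCapacityError(ValueError):
    """A p-value group exceeds the recognized-gene analysis cap."""


@dataclass
class PValueGroups:
    boundaries: tuple[float, ...]
    groups: list[pd.DataFrame]          # six frames: re_id, gene, empirical_p
    recognized_counts: list[int]        # per group, genes found in the universe

    @property
    def sizes(self) -> list[int]:
        return [len(g) for g in self.groups]


def assign_group(p: float, boundaries: Sequence[float] = DEFAULT_BOUNDARIES) -> int:
    """1-based group index for an empirical p value in (0, boundaries[-1]]."""
    if not 0 < p <= boundaries[-1]:
        raise ValueError(f"empirical p {p} outside (0, {boundaries[-1]}]")
    if p < boundaries[0]:
        return 1
    for k in range(1, len(boundaries)):
        if p <= boundaries[k]:
            return k + 1
    raise AssertionError("unreachable")


def partition_by_pvalue(
    entries: pd.DataFrame,
    boundaries: Sequence[float] = DEFAULT_BOUNDARIES,
    symbol_universe: Iterable[str] | None = None,
    cap: int = 500,
) -> PValueGroups:
    """Partition (re_id, gene, empirical_p) entries into the six p groups.

    Raises :class:`GroupCapacityError` naming any group whose recognized gene
    count exceeds ``cap``.
    """
    boundaries = tuple(boundaries)
    if any(b2 <= b1 for b1, b2 in zip(boundaries, boundaries[1:])):
        raise ValueError("boundaries must be strictly increasing")
    for col in ("re_id", "gene", "empirical_p"):
        if col not in entries.columns:
            raise ValueError(f"entries missing column {col!r}")
    uni = {normalize_symbol(g) for g in symbol_universe} if symbol_universe is not None else None
    idx = entries["empirical_p"].map(lambda p: assign_group(float(p), boundaries))
    groups = [entries[idx == k].reset_index(drop=True) for k in range(1, len(boundaries) + 1)]
    recognized = []
    for k, g in enumerate(groups, 1):
        genes = {normalize_symbol(x) for x in g["gene"]}
        n_rec = len(genes & uni) if uni is not None else len(genes)
        if n_rec > cap:
            raise GroupCapacityError(
                f"group {k}: {n_rec} recognized genes exceeds the {cap}-gene cap"
            )
        recognized.append(n_rec)
    return PValueGroups(boundaries=boundaries, groups=groups, recognized_counts=recognized)


def ora(
    query: Iterable[str],
    collection: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    q_max: float = 0.05,
    min_overlap: int = 2,
    top: int = 100,
    keyword_map: Sequence[tuple[str, str]] = DEFAULT_CATEGORY_MAP,
) -> pd.DataFrame:
    """Over-representation of ``query`` against one gene-set collection.

    Query genes outside the universe are dropped (they cannot be scored under
    the hypergeometric null).  Every non-empty set is tested and enters the
    BH correction; only rows with k >= ``min_overlap`` and q < ``q_max`` are
    reported, sorted by p ascending, truncated to ``top``.

    Returns a DataFrame: set_name, k, K, n, N, p, q, category.
    """
    if not collection:
        raise ValueError("empty gene-set collection")
    uni = {normalize_symbol(g) for g in universe}
    if not uni:
        raise ValueError("empty universe")
    qset = {normalize_symbol(g) for g in query} & uni
    N, n = len(uni), len(qset)
    rows = []
    for name, genes in collection.items():
        members = {normalize_symbol(g) for g in genes} & uni
        K = len(members)
        if K == 0:
            continue
        k = len(qset & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, p))
    if not rows:
        raise ValueError("no gene set overlaps the universe")
    df = pd.DataFrame(rows, columns=["set_name", "k", "K", "p"])
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    df["n"] = n
    df["N"] = N
    keep = (df["k"] >= min_overlap) & (df["q"] < q_max)
    out = df[keep].sort_values(["p", "set_name"], kind="mergesort").head(top)
    out = out[["set_name", "k", "K", "n", "N", "p", "q"]].reset_index(drop=True)
    out["category"] = [categorize(s, keyword_map) for s in out["set_name"]]
    return out


def categorize(
    set_name: str,
    keyword_map: Sequence[tuple[str, str]] = DEFAULT_CATEGORY_MAP,
) -> str:
    """First matching biological-process category, else 'uncategorized'."""
    upper = set_name.upper().replace(" ", "_")
    for pattern, category in keyword_map:
        if re.search(pattern, upper):
            return category
    return "uncategorized"


def proportion_test(
    genes: Iterable[str],
    annotation: Iterable[str],
    background: Iterable[str],
    method: str = "exact",
) -> OverlapResult:
    """Is an annotation class (e.g. CRREW) over-represented in a gene list?

    Delegates to the hypergeometric overlap test with x = |list ∩ annotation|
    inside the supplied background universe.
    """
    bg = {normalize_symbol(g) for g in background}
    gs = {normalize_symbol(g) for g in genes} & bg
    ann = {normalize_symbol(g) for g in annotation} & bg
    if not gs:
        raise ValueError("empty gene list after background intersection")
    return hypergeometric_overlap(len(gs & ann), len(gs), len(ann), len(bg), method=method)
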