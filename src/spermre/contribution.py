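"""Paternal/maternal decomposition of zygote RE abundance and RE classification.

Before embryonic genome activation, a zygotic transcript pool is the union of
what sperm and oocyte delivered.  For an RE with zygote RPKM Z, sperm RPKM s
and oocyte RPKM o (medians across biological replicates), the paternal
contribution is

    Pc = Z - Z / (1 + s/o)        (equivalently  Z * s / (s + o))

with the maternal complement Mc = Z - Pc.  When Z exceeds s + o the
decomposition is capped at the gamete abundances: Pc = s, Mc = o.  The o = 0
limit gives Pc = Z (when uncapped, i.e. Z <= s); Z > 0 with s = o = 0 has no
defined decomposition and is an error.

Classification (all inequalities strict, exactly as published):

* fivefold paternally enriched: sperm median > 25 RPKM, oocyte < 5 RPKM,
  zygote > 10 RPKM.
* twofold paternally enriched (excluding REs already in the fivefold or
  prior maternal sets, zygote > 10 RPKM):  Pc > 2 * Mc,  OR  oocyte < 2 RPKM
  with 2 < sperm < 25 RPKM.  The second clause captures sperm-specific REs
  whose oocyte abundance is below the 2 RPKM floor at which presence can be
  confirmed.
* sperm-specific flag: oocyte median < 2 RPKM on a classified paternal RE.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import AbundanceMatrix, normalize_symbol

__all__ = [
    "Thresholds",
    "PaternalContribution",
    "REClassification",
    "ContributionError",
    "compute_contribution",
    "classify_fivefold",
    "classify_twofold",
    "classify_res",
    "aggregate_to_rernas",
    "zygote_excess",
    "FIVEFOLD",
    "TWOFOLD",
    "NONE",
]

FIVEFOLD = "FIVEFOLD_PATERNAL"
TWOFOLD = "TWOFOLD_PATERNAL"
NONE = "NONE"


class ContributionError(ValueError):
    """Z > 0 with s = o = 0: the decomposition is undefined."""


@dataclass(frozen=True)
class Thresholds:
    """Published RPKM thresholds, each configurable with the printed default."""

    sperm_min_5x: float = 25.0      # sperm median must exceed this for the 5x class
    oocyte_max_5x: float = 5.0      # oocyte median must be below this for the 5x class
    zygote_min: float = 10.0        # presence gate in the zygote for any paternal class
    fold_2x: float = 2.0            # Pc must exceed fold_2x * Mc for the 2x class
    oocyte_absent: float = 2.0      # oocyte RPKM below which presence is unconfirmed
    sperm_specific_2x_lower: float = 2.0   # sperm-specific OR-clause: sperm > this
    sperm_specific_2x_upper: float = 25.0  # sperm-specific OR-clause: sperm < this
    rerna_present: float = 5.0      # gene-level presence gate

    def __post_init__(self) -> None:
        vals = (
            self.sperm_min_5x, self.oocyte_max_5x, self.zygote_min, self.fold_2x,
            self.oocyte_absent, self.sperm_specific_2x_lower,
            self.sperm_specific_2x_upper, self.rerna_present,
        )
        if any(v <= 0 for v in vals):
            raise ValueError("all thresholds must be positive")
        if self.fold_2x <= 1:
            raise ValueError("fold_2x must exceed 1")


@dataclass(frozen=True)
class PaternalContribution:
    re_id: str
    Z: float
    s: float
    o: float
    Pc: float
    Mc: float
    capped: bool


@dataclass(frozen=True)
class REClassification:
    re_id: str
    label: str
    sperm_specific: bool = False
    excluded_reason: str | None = None


def compute_contribution(Z: float, s: float, o: float, re_id: str = "") -> PaternalContribution:
    """Decompose zygote abundance Z into paternal Pc and maternal Mc."""
    if Z < 0 or s < 0 or o < 0:
        raise ValueError(f"{re_id or 'RE'}: negative RPKM input")
    if s == 0.0 and o == 0.0:
        if Z > 0:
            raise ContributionError(f"{re_id or 'RE'}: Z > 0 with s = o = 0")
        return PaternalContribution(re_id=re_id, Z=0.0, s=0.0, o=0.0, Pc=0.0, Mc=0.0, capped=False)
    if Z > s + o:
        return PaternalContribution(re_id=re_id, Z=Z, s=s, o=o, Pc=s, Mc=o, capped=True)
    if o == 0.0:
        # limit of Z - Z/(1 + s/o) as o -> 0 is Z (all paternal)
        return PaternalContribution(re_id=re_id, Z=Z, s=s, o=o, Pc=Z, Mc=0.0, capped=False)
    Pc = Z - Z / (1.0 + s / o)
    Mc = Z - Pc
    return PaternalContribution(re_id=re_id, Z=Z, s=s, o=o, Pc=Pc, Mc=Mc, capped=False)


def classify_fivefold(s_med: float, o_med: float, z_med: float,
                      t: Thresholds = Thresholds()) -> bool:
    """Fivefold paternal enrichment: strict thresholds on the three medians."""
    return s_med > t.sperm_min_5x and o_med < t.oocyte_max_5x and z_med > t.zygote_min


def classify_twofold(
    pc: PaternalContribution,
    prior_5x: set[str] = frozenset(),
    prior_maternal: set[str] = frozenset(),
    t: Thresholds = Thresholds(),
) -> REClassification:
    """Twofold paternal enrichment for one RE, excluding prior sets."""
    sperm_specific = pc.o < t.oocyte_absent
    if pc.re_id in prior_5x:
        return REClassification(pc.re_id, NONE, sperm_specific, "prior_fivefold")
    if pc.re_id in prior_maternal:
        return REClassification(pc.re_id, NONE, sperm_specific, "prior_maternal")
    if not pc.Z > t.zygote_min:
        return REClassification(pc.re_id, NONE, sperm_specific, "zygote_gate")
    ratio_clause = pc.Pc > t.fold_2x * pc.Mc
    absent_clause = (
        pc.o < t.oocyte_absent
        and t.sperm_specific_2x_lower < pc.s < t.sperm_specific_2x_upper
    )
    if ratio_clause or absent_clause:
        return REClassification(pc.re_id, TWOFOLD, sperm_specific, None)
    return REClassification(pc.re_id, NONE, sperm_specific, None)


def _medians(am: AbundanceMatrix | pd.DataFrame, aggregate: str) -> pd.Series:
    df = am.data if isinstance(am, AbundanceMatrix) else am
    return df.median(axis=1) if aggregate == "median" else df.mean(axis=1)


def classify_res(
    sperm: AbundanceMatrix | pd.DataFrame,
    oocyte: AbundanceMatrix | pd.DataFrame,
    zygote: AbundanceMatrix | pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
    prior_5x: set[str] | None = None,
    prior_maternal: set[str] | None = None,
    gene_map: pd.Series | dict[str, str] | None = None,
    aggregate: str = "median",
) -> pd.DataFrame:
    """Full per-RE classification over the zygote RE universe.

    Per-tissue abundances are aggregated across biological replicates
    (median by default) before any threshold is applied.  REs absent from the
    sperm or oocyte matrix are treated as undetected (0 RPKM) in that tissue.
    When ``prior_5x`` is None, the fivefold set is computed here first and
    excluded from the twofold candidates, mirroring the two-stage definition.

    Returns a DataFrame indexed by re_id with columns gene, s, o, Z, Pc, Mc,
    capped, label, sperm_specific, excluded_reason.
    """
    if aggregate not in ("median", "mean"):
        raise ValueError("aggregate must be 'median' or 'mean'")
    z = _medians(zygote, aggregate)
    s = _medians(sperm, aggregate).reindex(z.index, fill_value=0.0)
    o = _medians(oocyte, aggregate).reindex(z.index, fill_value=0.0)

    t = thresholds
    rows = []
    fivefold_here: set[str] = set()
    if prior_5x is None:
        computed_5x = {
            rid for rid in z.index if classify_fivefold(s[rid], o[rid], z[rid], t)
        }
        excl_5x = computed_5x
        fivefold_here = computed_5x
    else:
        # a supplied prior list is authoritative: its REs keep the fivefold
        # label and are excluded from the twofold candidates
        excl_5x = set(prior_5x)
        fivefold_here = {rid for rid in z.index if rid in excl_5x}
    excl_mat = set(prior_maternal) if prior_maternal else set()

    for rid in z.index:
        zi, si, oi = float(z[rid]), float(s[rid]), float(o[rid])
        if rid in fivefold_here:
            pc = compute_contribution(zi, si, oi, rid) if (si or oi or not zi) else None
            rows.append((rid, si, oi, zi,
                         pc.Pc if pc else np.nan, pc.Mc if pc else np.nan,
                         pc.capped if pc else False,
                         FIVEFOLD, oi < t.oocyte_absent, None))
            continue
        if not zi > t.zygote_min:
            rows.append((rid, si, oi, zi, np.nan, np.nan, False, NONE,
                         False, "zygote_gate"))
            continue
        if si == 0.0 and oi == 0.0:
            rows.append((rid, si, oi, zi, np.nan, np.nan, False, NONE,
                         False, "undefined_contribution"))
            continue
        pc = compute_contribution(zi, si, oi, rid)
        cls = classify_twofold(pc, excl_5x, excl_mat, t)
        rows.append((rid, si, oi, zi, pc.Pc, pc.Mc, pc.capped, cls.label,
                     cls.sperm_specific if cls.label == TWOFOLD else False,
                     cls.excluded_reason))

    out = pd.DataFrame(
        rows,
        columns=["re_id", "s", "o", "Z", "Pc", "Mc", "capped", "label",
                 "sperm_specific", "excluded_reason"],
    ).set_index("re_id")
    # fivefold REs with oocyte below the presence floor are sperm-specific too
    ff = out["label"] == FIVEFOLD
    out.loc[ff, "sperm_specific"] = out.loc[ff, "o"] < t.oocyte_absent
    if gene_map is not None:
        gm = pd.Series(gene_map) if isinstance(gene_map, dict) else gene_map
        out.insert(0, "gene", gm.reindex(out.index))
    return out


def aggregate_to_rernas(classified: pd.DataFrame) -> dict[str, list[str]]:
    """Roll RE labels up to gene (RE-RNA) level.

    A gene carries a class iff at least one of its REs does; a gene may appear
    in several class lists.  REs without a gene are dropped (count reported
    under key ``_dropped_no_gene`` is left to the caller via attrs).
    """
    if "gene" not in classified.columns:
        raise ValueError("classified frame has no 'gene' column; pass gene_map to classify_res")
    has_gene = classified["gene"].notna()
    df = classified[has_gene]
    out: dict[str, list[str]] = {}
    for label in (FIVEFOLD, TWOFOLD):
        genes = sorted({normalize_symbol(g) for g in df.loc[df["label"] == label, "gene"]})
        out[label] = genes
    out["SPERM_SPECIFIC"] = sorted(
        {normalize_symbol(g)
         for g in df.loc[(df["label"] != NONE) & df["sperm_specific"], "gene"]}
    )
    out["_n_dropped_no_gene"] = int((~has_gene).sum())  # type: ignore[assignment]
    return out


def zygote_excess(
    gene_abundance: pd.DataFrame,
    t: Thresholds = Thresholds(),
) -> list[str]:
    """Genes more abundant in the zygote than in sperm, above the presence gate.

    ``gene_abundance`` needs columns ``sperm`` and ``zygote`` (gene-level
    RPKM).  The > 5 RPKM presence gate is applied to both tissues.
    """
    for col in ("sperm", "zygote"):
        if col not in gene_abundance.columns:
            raise ValueError(f"gene_abundance missing column {col!r}")
    g = gene_abundance
    mask = (g["sperm"] > t.rerna_present) & (g["zygote"] > t.rerna_present) \
        & (g["zygote"] > g["sperm"])
    return sorted(normalize_symbol(x) for x in g.index[mask])
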