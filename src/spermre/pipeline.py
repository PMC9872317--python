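"""End-to-end orchestration: QC -> classify -> overlap -> movement ->
enrichment -> integrity -> CRREW annotation -> network export.

A single declarative :class:`RunConfig` names every input file and every
threshold; :func:`run_pipeline` executes the stages in order, persists each
intermediate as TSV/JSON under the output directory, and returns a
machine-readable :class:`RunReport` whose counts are all recomputable from
those intermediates.  Reruns with identical config and inputs are
bit-identical.  Dropped records are logged with a reason code so count
discrepancies stay auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .contribution import (
    FIVEFOLD,
    TWOFOLD,
    Thresholds,
    aggregate_to_rernas,
    classify_res,
)
from .enrichment import DEFAULT_CATEGORY_MAP, ora, proportion_test
from .io import (
    normalize_symbol,
    read_abundance,
    read_crrew,
    read_bedgraph,
    read_dbp_list,
    read_exon_bed,
    read_gmt,
    write_network,
)
from .overlap import (
    SEGMENT_ARM,
    consistent_responders,
    hypergeometric_overlap,
    intersect_lists,
    movement_table,
    shared_between_arms,
)
from .tii import compute_tii, filter_q4

__all__ = ["RunConfig", "RunReport", "run_pipeline", "export_network"]

ARM_SEGMENTS = {"B1HB2": ("B1H", "HB2"), "H1BH2": ("H1B", "BH2")}


@dataclass
class RunConfig:
    """Declarative pipeline configuration; every path is required to exist."""

    sperm: str
    sperm_meta: str
    oocyte: str
    oocyte_meta: str
    zygote: str
    zygote_meta: str
    outdir: str
    dbp_lists: dict[str, str] = field(default_factory=dict)   # segment -> path
    visit_means: dict[str, str] = field(default_factory=dict)  # arm -> path
    gmt: str | None = None
    universe: str | None = None
    crrew: str | None = None
    coverage_dir: str | None = None
    panel_bed: str | None = None
    prior_5x: str | None = None
    prior_maternal: str | None = None
    gene_map: str | None = None   # TSV re_id<TAB>gene; default: simulation truth table
    thresholds: Thresholds = field(default_factory=Thresholds)
    rpm_threshold: float = 5.0
    coverage_fraction: float = 0.5
    rpkm_min: float = 5.0
    q_max: float = 0.05
    min_overlap: int = 2
    top: int = 100
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "thresholds" in raw and isinstance(raw["thresholds"], dict):
            raw["thresholds"] = Thresholds(**raw["thresholds"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        raw["thresholds"] = dataclasses.asdict(self.thresholds)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)

    def content_hash(self) -> str:
        raw = dataclasses.asdict(self)
        raw["thresholds"] = dataclasses.asdict(self.thresholds)
        return hashlib.sha256(json.dumps(raw, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunReport:
    counts: dict
    version: str
    config_hash: str

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"counts": self.counts, "version": self.version,
                 "config_hash": self.config_hash},
                fh, indent=2, sort_keys=True,
            )
            fh.write("\n")


def _load_gene_map(cfg: RunConfig) -> pd.Series | None:
    if cfg.gene_map is None:
        return None
    df = pd.read_csv(cfg.gene_map, sep="\t")
    re_col = "re_id" if "re_id" in df.columns else df.columns[0]
    gene_col = "gene" if "gene" in df.columns else df.columns[1]
    return df.set_index(re_col)[gene_col]


def run_pipeline(cfg: RunConfig) -> RunReport:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict = {}

    # --- stage 1: sample QC by transcript integrity --------------------------
    dropped_samples: list[str] = []
    if cfg.coverage_dir and cfg.panel_bed:
        models = read_exon_bed(cfg.panel_bed)
        panel = sorted(models)
        results = []
        for bg in sorted(Path(cfg.coverage_dir).glob("*.bedGraph")):
            sample = bg.stem
            tracks = {
                tid: read_bedgraph(bg, exons, chrom, tid, sample)
                for tid, (chrom, exons) in models.items()
            }
            results.append(compute_tii(tracks, panel, cfg.rpm_threshold,
                                       cfg.coverage_fraction))
        kept, removed = filter_q4(results)
        dropped_samples = sorted(r.sample_id for r in removed)
        pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in results],
                "tii_score": [r.tii_score for r in results],
                "quartile": [r.quartile for r in results],
                "pass": [r.passed for r in results],
            }
        ).to_csv(out / "tii.tsv", sep="\t", index=False)
        counts["tii"] = {"n_samples": len(results), "n_dropped_q4": len(removed),
                         "dropped": dropped_samples}

    # --- stage 2: paternal classification ------------------------------------
    sperm = read_abundance(cfg.sperm, cfg.sperm_meta)
    oocyte = read_abundance(cfg.oocyte, cfg.oocyte_meta)
    zygote = read_abundance(cfg.zygote, cfg.zygote_meta)
    prior_5x = set(pd.read_csv(cfg.prior_5x, sep="\t", header=None)[0]) \
        if cfg.prior_5x else None
    prior_mat = set(pd.read_csv(cfg.prior_maternal, sep="\t", header=None)[0]) \
        if cfg.prior_maternal else None
    classified = classify_res(
        sperm, oocyte, zygote, thresholds=cfg.thresholds,
        prior_5x=prior_5x, prior_maternal=prior_mat,
        gene_map=_load_gene_map(cfg),
    )
    classified.to_csv(out / "classes.tsv", sep="\t")
    counts["classification"] = {
        "n_res": int(len(classified)),
        "n_fivefold": int((classified["label"] == FIVEFOLD).sum()),
        "n_twofold": int((classified["label"] == TWOFOLD).sum()),
        "n_sperm_specific": int(classified["sperm_specific"].sum()),
        "n_capped": int(classified["capped"].fillna(False).sum()),
        "dropped_reasons": classified["excluded_reason"].value_counts(dropna=True)
        .to_dict(),
    }

    paternal_genes: list[str] = []
    if "gene" in classified.columns:
        rollup = aggregate_to_rernas(classified)
        paternal_genes = sorted(set(rollup[FIVEFOLD]) | set(rollup[TWOFOLD]))
        counts["rernas"] = {
            "n_fivefold_genes": len(rollup[FIVEFOLD]),
            "n_twofold_genes": len(rollup[TWOFOLD]),
            "n_sperm_specific_genes": len(rollup["SPERM_SPECIFIC"]),
            "n_paternal_genes": len(paternal_genes),
        }

    # default universe: all genes with >= 1 detected RE in the zygote input
    if cfg.universe:
        with open(cfg.universe) as fh:
            universe = sorted({normalize_symbol(l) for l in fh if l.strip()})
    elif "gene" in classified.columns:
        universe = sorted({normalize_symbol(g)
                           for g in classified["gene"].dropna()})
    else:
        universe = []

    # --- stage 3: DBP overlap -------------------------------------------------
    dbp = {seg: read_dbp_list(path) for seg, path in sorted(cfg.dbp_lists.items())}
    overlaps = {}
    all_moves = []
    if dbp and paternal_genes and universe:
        dbp_genes_all = sorted({g for df in dbp.values() for g in df["gene"]})
        shared = intersect_lists(paternal_genes, dbp_genes_all)
        uni = set(universe)
        n1 = len(set(paternal_genes) & uni)
        n2 = len(set(dbp_genes_all) & uni)
        x = len(set(shared) & uni)
        res = hypergeometric_overlap(x, n1, n2, len(universe), method="exact")
        overlaps["paternal_vs_dbp"] = res.as_dict()
        counts["overlap"] = {
            "n_paternal_genes": n1, "n_dbp_genes": n2, "n_shared": x,
            "universe": len(universe),
            "representation_factor": res.representation_factor,
            "p_over": res.p_over,
        }
        for seg, df in dbp.items():
            all_moves.append(df.assign(segment=seg)[["gene", "segment", "direction"]])
    with open(out / "overlap.json", "w") as fh:
        json.dump(overlaps, fh, indent=2, sort_keys=True)

    # --- stage 4: movement patterns -------------------------------------------
    movement_frames = []
    for arm, path in sorted(cfg.visit_means.items()):
        vm = pd.read_csv(path, sep="\t", index_col="re_id")
        seg1, seg2 = ARM_SEGMENTS[arm]
        sig1 = set(dbp[seg1]["re_id"]) if seg1 in dbp else set()
        sig2 = set(dbp[seg2]["re_id"]) if seg2 in dbp else set()
        mt = movement_table(vm[["baseline", "crossover", "crossback"]], sig1, sig2)
        mt.insert(0, "arm", arm)
        movement_frames.append(mt)
    if movement_frames:
        movement = pd.concat(movement_frames)
        movement.to_csv(out / "movement.tsv", sep="\t")
        counts["movement"] = movement["pattern"].value_counts().to_dict()

    consistent: list[str] = []
    if all_moves:
        moves = pd.concat(all_moves, ignore_index=True)
        consistent = consistent_responders(moves)
        pd.Series(consistent, name="gene").to_csv(out / "consistent_responders.tsv",
                                                  sep="\t", index=False)
        counts["consistent_responders"] = len(consistent)

    # --- stage 5: enrichment ---------------------------------------------------
    enrich_df = None
    if cfg.gmt and universe:
        collection = read_gmt(cfg.gmt)
        query = intersect_lists(paternal_genes, {g for df in dbp.values()
                                                 for g in df["gene"]}) \
            if dbp and paternal_genes else paternal_genes
        if query:
            enrich_df = ora(query, collection, universe, q_max=cfg.q_max,
                            min_overlap=cfg.min_overlap, top=cfg.top)
            enrich_df.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            counts["enrichment"] = {
                "n_enriched_sets": int(len(enrich_df)),
                "per_category": enrich_df["category"].value_counts().to_dict(),
            }

    # --- stage 6: CRREW annotation ---------------------------------------------
    if cfg.crrew and universe:
        records = read_crrew(cfg.crrew)
        crrew_genes = sorted({r.gene for r in records})
        arm_genes = {}
        for arm, segs in ARM_SEGMENTS.items():
            genes = {g for seg in segs if seg in dbp for g in dbp[seg]["gene"]}
            arm_genes[arm] = sorted(set(intersect_lists(genes, crrew_genes))
                                    & set(paternal_genes))
        only_a, only_b, both = shared_between_arms(arm_genes.get("B1HB2", []),
                                                   arm_genes.get("H1BH2", []))
        counts["crrew"] = {
            "n_crrew_universe": len(set(crrew_genes) & set(universe)),
            "B1HB2_specific": len(only_a), "H1BH2_specific": len(only_b),
            "shared": len(both),
            "distinct_union": len(set(only_a) | set(only_b) | set(both)),
        }
        if paternal_genes:
            pt = proportion_test(paternal_genes, crrew_genes, universe)
            counts["crrew"]["proportion_p_over"] = pt.p_over
            counts["crrew"]["proportion_representation_factor"] = \
                pt.representation_factor

    # --- stage 7: network export -------------------------------------------------
    if enrich_df is not None and dbp:
        nodes, edges = export_network(enrich_df, collection, dbp, paternal_genes)
        write_network(nodes, edges, out / "network")
        counts["network"] = {"n_nodes": int(len(nodes)), "n_edges": int(len(edges))}

    report = RunReport(counts=counts, version=__version__,
                       config_hash=cfg.content_hash())
    report.to_json(out / "report.json")
    return report


def export_network(
    enrich_df: pd.DataFrame,
    collection: dict[str, set[str]],
    dbp: dict[str, pd.DataFrame],
    paternal_genes: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node/edge tables linking biological processes to direction classes.

    Nodes are the enriched biological-process categories plus the four
    direction classes (abundance up/down on DBP exposure/withdrawal).  An
    edge counts the paternally provided responsive REs connecting a process
    to a direction class within one segment: the count drives edge-color
    scaling in a graph tool, the segment the line type.
    """
    from .overlap import ADDITION_SEGMENTS

    categories = sorted(set(enrich_df["category"]) - {"uncategorized"})
    # genes credited to a category: union of its enriched sets' members
    cat_genes = {
        c: {g
            for name in enrich_df.loc[enrich_df["category"] == c, "set_name"]
            for g in collection.get(name, ())}
        for c in categories
    }
    direction_nodes = {
        ("up", True): "up_on_exposure",
        ("down", True): "down_on_exposure",
        ("up", False): "up_on_withdrawal",
        ("down", False): "down_on_withdrawal",
    }
    nodes = pd.DataFrame(
        [(c, "process", c) for c in categories]
        + [(n, "direction", n) for n in sorted(set(direction_nodes.values()))],
        columns=["id", "type", "class"],
    )
    pat = set(paternal_genes)
    rows = []
    for seg, df in sorted(dbp.items()):
        adding = seg in ADDITION_SEGMENTS
        resp = df[df["gene"].isin(pat)]
        for direction, grp in resp.groupby("direction"):
            dnode = direction_nodes[(str(direction), adding)]
            for c in categories:
                n_res = int(grp["gene"].isin(cat_genes[c]).sum())
                if n_res:
                    rows.append((c, dnode, n_res, seg))
    edges = pd.DataFrame(rows, columns=["source", "target", "n_res", "segment"])
    return nodes, edges
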