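"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the statistical structure the analysis assumes rather
than raw sequencing: per-tissue RPKM abundances are log-normal around a
class-specific target median (strictly positive, heavy right tail), with the
realized per-RE median rescaled to equal its target so planted margins from
every classification threshold are exact.  Classes are planted at a relative
margin ``delta`` from the published thresholds:

* ``fivefold``       sperm > 25(1+d), oocyte in (2(1+d), 5(1-d)), zygote > 10(1+d)
* ``twofold``        oocyte > 5(1+d) (so never fivefold), sperm > 2(1+d)*oocyte
* ``sperm_specific`` oocyte < 2(1-d), sperm in (2(1+d), 25(1-d)), zygote > 10(1+d)
* ``maternal``       oocyte-dominated, sperm below the presence floor
* ``null``           zygote below the 10 RPKM gate

A configurable fraction of paternal REs draw zygote abundance above sperm +
oocyte so the capping branch of the contribution model is exercised in every
run.  Responsive-RE lists for the four crossover-crossback segments are
planted with a fixed overlap fraction against the paternal gene list,
Uniform(0, 0.05] empirical p values, and an exactly recoverable set of
consistent responders (non-consistent responsive genes appear in a single
segment only, so the consistency rule cannot fire on them).  Coverage tracks
are either full-length (every exon base above threshold) or degraded with a
5'->3' tail below threshold over a configurable fraction of bases.

Everything is a pure function of (config, seed); identical configs produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .contribution import Thresholds
from .io import (
    AbundanceMatrix,
    CoverageTrack,
    CRREWRecord,
    write_abundance,
    write_bedgraph,
    write_crrew,
    write_dbp_list,
    write_gene_list,
    write_gmt,
)
from .overlap import ADDITION_SEGMENTS, DBPComparison, SEGMENT_ARM

__all__ = [
    "SimulationConfig",
    "simulate_abundances",
    "simulate_dbp_lists",
    "simulate_visit_means",
    "simulate_panel_coverage",
    "simulate_transcript_tracks",
    "simulate_gmt",
    "simulate_crrew",
    "write_simulation",
]

SEGMENTS_ORDER = ("B1H", "HB2", "H1B", "BH2")


@dataclass
class SimulationConfig:
    seed: int = 0
    # abundance matrices
    n_res: int = 2000
    res_per_gene: int = 3
    n_sperm: int = 7           # biological sperm replicates in the reference design
    n_oocyte: int = 3
    n_zygote: int = 3
    frac_fivefold: float = 0.10
    frac_twofold: float = 0.10
    frac_sperm_specific: float = 0.05
    frac_maternal: float = 0.15
    margin: float = 0.2        # relative distance of planted medians from thresholds
    sigma: float = 0.35        # log-normal spread of per-sample values around the median
    capped_fraction: float = 0.05  # paternal REs with Z > s + o (capping branch)
    thresholds: Thresholds = field(default_factory=Thresholds)
    # DBP-responsive lists
    dbp_n_per_segment: int = 150
    dbp_overlap_fraction: float = 0.3   # fraction of each segment list that is paternal
    dbp_n_consistent: int = 12          # genes responding coherently in all 4 segments
    # coverage / TII
    n_panel_transcripts: int = 22
    n_exons: int = 4
    exon_length: int = 250
    full_depth_range: tuple[float, float] = (6.0, 15.0)
    degraded_tail_fraction: float = 0.6  # fraction of 3' bases below threshold
    n_tii_samples: int = 12
    n_tii_bad: int = 3                   # planted poor-quality samples
    # GMT
    gmt_n_sets: int = 25
    gmt_set_size: tuple[int, int] = (10, 50)
    gmt_planted_size: int = 30
    # CRREW annotation
    crrew_fraction: float = 0.15

    def __post_init__(self) -> None:
        fr = (self.frac_fivefold + self.frac_twofold + self.frac_sperm_specific
              + self.frac_maternal)
        if fr > 1.0:
            raise ValueError(f"class fractions sum to {fr} > 1")
        if not 0 < self.margin < 1:
            raise ValueError("margin must lie in (0, 1)")
        d = self.margin
        if not 2 * (1 + d) < 25 * (1 - d):
            raise ValueError("margin too wide for the sperm-specific window (2, 25)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _lognormal_around_median(rng: np.random.Generator, median: float,
                             sigma: float, n: int) -> np.ndarray:
    """n strictly positive draws whose realized median equals ``median``."""
    if median <= 0:
        raise ValueError("target median must be positive")
    vals = median * np.exp(sigma * rng.standard_normal(n))
    return vals * (median / np.median(vals))


def _class_counts(cfg: SimulationConfig) -> dict[str, int]:
    n = cfg.n_res
    counts = {
        "fivefold": int(round(cfg.frac_fivefold * n)),
        "twofold": int(round(cfg.frac_twofold * n)),
        "sperm_specific": int(round(cfg.frac_sperm_specific * n)),
        "maternal": int(round(cfg.frac_maternal * n)),
    }
    counts["null"] = n - sum(counts.values())
    if counts["null"] < 0:
        raise ValueError("class fractions leave no room at this n_res")
    return counts


def _target_medians(cls: str, cfg: SimulationConfig,
                    rng: np.random.Generator) -> tuple[float, float, float, bool]:
    """(sperm, oocyte, zygote) target medians and capped flag for one RE."""
    t, d = cfg.thresholds, cfg.margin
    capped = False
    if cls == "fivefold":
        s = rng.uniform(t.sperm_min_5x * (1 + d), t.sperm_min_5x * 4)
        o = rng.uniform(t.oocyte_absent * (1 + d), t.oocyte_max_5x * (1 - d))
        capped = rng.random() < cfg.capped_fraction
        if capped:
            z = (s + o) * rng.uniform(1.05, 1.4)
        else:
            z = rng.uniform(t.zygote_min * (1 + d), s + o)
    elif cls == "twofold":
        o = rng.uniform(t.oocyte_max_5x * (1 + d), 2 * t.oocyte_max_5x)
        s = o * t.fold_2x * (1 + d) * rng.uniform(1.05, 1.6)
        capped = rng.random() < cfg.capped_fraction
        if capped:
            z = (s + o) * rng.uniform(1.05, 1.4)
        else:
            z = rng.uniform(t.zygote_min * (1 + d), s + o)
    elif cls == "sperm_specific":
        o = rng.uniform(0.2, t.oocyte_absent * (1 - d))
        s = rng.uniform(t.sperm_specific_2x_lower * (1 + d),
                        t.sperm_specific_2x_upper * (1 - d))
        z = rng.uniform(t.zygote_min * (1 + d), max(s + o, 2 * t.zygote_min))
        capped = z > s + o
    elif cls == "maternal":
        o = rng.uniform(25.0, 100.0)
        s = rng.uniform(0.05, t.oocyte_absent * (1 - d))
        z = rng.uniform(t.zygote_min * (1 + d), 0.9 * (s + o))
        capped = False
    elif cls == "null":
        s = rng.uniform(0.5, 30.0)
        o = rng.uniform(0.5, 30.0)
        z = rng.uniform(0.5, cfg.thresholds.zygote_min * (1 - d))
    else:
        raise ValueError(f"unknown class {cls!r}")
    return float(s), float(o), float(z), capped


def simulate_abundances(
    cfg: SimulationConfig,
) -> tuple[AbundanceMatrix, AbundanceMatrix, AbundanceMatrix, pd.DataFrame]:
    """Sperm/oocyte/zygote matrices plus the planted truth table.

    Truth columns: gene, cls, sperm_specific, s_med, o_med, z_med, capped.
    Genes are class-pure (all REs of one gene share the planted class) so
    gene-level rollups have unambiguous expected labels.
    """
    rng = cfg.rng()
    counts = _class_counts(cfg)
    labels = [c for c, k in counts.items() for _ in range(k)]

    rows = []
    gene_idx = 0
    within = 0
    prev_cls = None
    for i, cls in enumerate(labels):
        if cls != prev_cls or within >= cfg.res_per_gene:
            gene_idx += 1
            within = 0
            prev_cls = cls
        within += 1
        gene = f"GENE{gene_idx:05d}"
        chrom = f"chr{1 + i % 22}"
        start = 100_000 + (i // 22) * 1_000
        re_id = f"{chrom}_{start}_{start + 99}"
        s, o, z, capped = _target_medians(cls, cfg, rng)
        rows.append((re_id, gene, cls, s, o, z, capped))
    truth = pd.DataFrame(
        rows, columns=["re_id", "gene", "cls", "s_med", "o_med", "z_med", "capped"]
    ).set_index("re_id")
    truth["sperm_specific"] = (truth["o_med"] < cfg.thresholds.oocyte_absent) & \
        truth["cls"].isin(["fivefold", "twofold", "sperm_specific"])

    def matrix(tissue: str, n_samples: int, med_col: str) -> AbundanceMatrix:
        data = np.empty((len(truth), n_samples))
        for j, med in enumerate(truth[med_col].to_numpy()):
            data[j] = _lognormal_around_median(rng, med, cfg.sigma, n_samples)
        samples = [f"{tissue}_{k + 1:02d}" for k in range(n_samples)]
        df = pd.DataFrame(data, index=truth.index, columns=samples)
        meta = pd.DataFrame(
            {"tissue": tissue, "study_arm": "none", "visit": "none"},
            index=pd.Index(samples, name="sample_id"),
        )
        return AbundanceMatrix(data=df, meta=meta)

    sperm = matrix("sperm", cfg.n_sperm, "s_med")
    oocyte = matrix("oocyte", cfg.n_oocyte, "o_med")
    zygote = matrix("zygote", cfg.n_zygote, "z_med")
    return sperm, oocyte, zygote, truth


def simulate_dbp_lists(
    cfg: SimulationConfig,
    truth: pd.DataFrame,
) -> tuple[list[DBPComparison], dict]:
    """Responsive-RE lists for the four segments with planted overlap.

    Returns the comparisons and a truth dict with keys ``overlap_genes`` (per
    segment), ``consistent_genes``, and ``directions`` {(gene, segment):
    'up'/'down'}.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    paternal = truth[truth["cls"].isin(["fivefold", "twofold", "sperm_specific"])]
    other = truth[~truth["cls"].isin(["fivefold", "twofold", "sperm_specific"])]
    pat_genes = paternal["gene"].unique()
    oth_genes = other["gene"].unique()

    n_olap = int(round(cfg.dbp_overlap_fraction * cfg.dbp_n_per_segment))
    n_cons = min(cfg.dbp_n_consistent, n_olap)
    need_pat = n_cons + 4 * (n_olap - n_cons)
    need_oth = 4 * (cfg.dbp_n_per_segment - n_olap)
    if need_pat > len(pat_genes):
        raise ValueError(f"not enough paternal genes ({len(pat_genes)}) for {need_pat} slots")
    if need_oth > len(oth_genes):
        raise ValueError(f"not enough non-paternal genes ({len(oth_genes)}) for {need_oth} slots")

    pat_pool = list(rng.permutation(pat_genes))
    oth_pool = list(rng.permutation(oth_genes))
    consistent = sorted(pat_pool[:n_cons])
    pat_pool = pat_pool[n_cons:]

    gene_to_re = truth.reset_index().groupby("gene")["re_id"].first()
    directions: dict[tuple[str, str], str] = {}
    per_segment: dict[str, list[tuple[str, str, str]]] = {s: [] for s in SEGMENTS_ORDER}

    # consistent responders: coherent sign across every segment
    for g in consistent:
        exposure_up = bool(rng.random() < 0.5)
        for seg in SEGMENTS_ORDER:
            adding = seg in ADDITION_SEGMENTS
            d = "up" if (adding == exposure_up) else "down"
            directions[(g, seg)] = d
            per_segment[seg].append((gene_to_re[g], g, d))

    # segment-exclusive paternal overlap and non-paternal filler
    for seg in SEGMENTS_ORDER:
        for _ in range(n_olap - n_cons):
            g = pat_pool.pop()
            d = "up" if rng.random() < 0.5 else "down"
            directions[(g, seg)] = d
            per_segment[seg].append((gene_to_re[g], g, d))
        for _ in range(cfg.dbp_n_per_segment - n_olap):
            g = oth_pool.pop()
            d = "up" if rng.random() < 0.5 else "down"
            directions[(g, seg)] = d
            per_segment[seg].append((gene_to_re[g], g, d))

    comparisons = []
    overlap_genes = {}
    pat_gene_set = set(pat_genes)
    for seg in SEGMENTS_ORDER:
        recs = per_segment[seg]
        p = 0.05 * (1.0 - rng.random(len(recs)))  # Uniform(0, 0.05]
        entries = pd.DataFrame(
            {
                "re_id": [r[0] for r in recs],
                "gene": [r[1] for r in recs],
                "direction": [r[2] for r in recs],
                "empirical_p": p,
            }
        )
        comparisons.append(DBPComparison(arm=SEGMENT_ARM[seg], segment=seg, entries=entries))
        overlap_genes[seg] = sorted(g for _, g, _ in recs if g in pat_gene_set)

    return comparisons, {
        "overlap_genes": overlap_genes,
        "consistent_genes": consistent,
        "directions": directions,
    }


def simulate_visit_means(
    cfg: SimulationConfig,
    comparisons: list[DBPComparison],
) -> dict[str, pd.DataFrame]:
    """Baseline/crossover/crossback mean abundances per arm.

    Significant segments move the mean by +/-40%; non-significant segments
    wiggle by < 3% so every planted movement direction is recovered exactly.
    Returns per-arm frames indexed by re_id with the three visit columns and
    the expected pattern columns ``first``/``second``.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    by_seg = {c.segment: c for c in comparisons}
    out = {}
    for arm, (seg1, seg2) in (("B1HB2", ("B1H", "HB2")), ("H1BH2", ("H1B", "BH2"))):
        first = by_seg[seg1].entries.set_index("re_id")["direction"] if seg1 in by_seg \
            else pd.Series(dtype=object)
        second = by_seg[seg2].entries.set_index("re_id")["direction"] if seg2 in by_seg \
            else pd.Series(dtype=object)
        re_ids = sorted(set(first.index) | set(second.index))
        rows = []
        for rid in re_ids:
            base = rng.uniform(10.0, 50.0)
            if rid in first.index:
                d1 = str(first[rid])
                cross = base * (1.4 if d1 == "up" else 0.6)
                exp1 = "Up" if d1 == "up" else "Down"
            else:
                cross = base * (1.0 + rng.uniform(0.005, 0.02) * rng.choice([-1, 1]))
                exp1 = "Same"
            if rid in second.index:
                d2 = str(second[rid])
                back = cross * (1.4 if d2 == "up" else 0.6)
                exp2 = "Up" if d2 == "up" else "Down"
            else:
                back = cross * (1.0 + rng.uniform(0.005, 0.02) * rng.choice([-1, 1]))
                exp2 = "Same"
            rows.append((rid, base, cross, back, exp1, exp2))
        out[arm] = pd.DataFrame(
            rows, columns=["re_id", "baseline", "crossover", "crossback", "first", "second"]
        ).set_index("re_id")
    return out


def _panel_models(cfg: SimulationConfig) -> dict[str, tuple[str, list[tuple[int, int]]]]:
    """Exon models for the stable-transcript panel on a synthetic chromosome."""
    models = {}
    gap, intron = 10_000, 100
    pos = 1_000
    for i in range(cfg.n_panel_transcripts):
        tid = f"STABLE{i + 1:02d}"
        exons = []
        p = pos
        for _ in range(cfg.n_exons):
            exons.append((p, p + cfg.exon_length - 1))
            p += cfg.exon_length + intron
        models[tid] = ("chrT", exons)
        pos = p + gap
    return models


def _make_track(tid: str, sample: str, chrom: str, exons: list[tuple[int, int]],
                degraded: bool, cfg: SimulationConfig,
                rng: np.random.Generator, units: str = "RPM") -> CoverageTrack:
    n = sum(e - s + 1 for s, e in exons)
    lo, hi = cfg.full_depth_range
    depth = rng.uniform(lo, hi, size=n)
    if degraded:
        # 5'->3' decay: the 3' tail drops below the 5 RPM/RPKM threshold
        n_tail = int(round(cfg.degraded_tail_fraction * n))
        if n_tail > 0:
            depth[n - n_tail:] = rng.uniform(0.0, 4.5, size=n_tail)
    return CoverageTrack(transcript_id=tid, sample_id=sample, chrom=chrom,
                         exons=list(exons), depth=depth, units=units)


def simulate_panel_coverage(
    cfg: SimulationConfig,
) -> tuple[list[CoverageTrack], list[str], pd.DataFrame]:
    """Coverage of the stable panel for a TII study with planted bad samples.

    Good samples have 0-3 degraded panel transcripts; planted poor-quality
    samples have all but 0-2 degraded, so their TII scores separate cleanly.
    Returns (tracks, panel ids, truth with per-sample degraded counts and the
    ``bad`` flag).
    """
    rng = np.random.default_rng(cfg.seed + 3)
    models = _panel_models(cfg)
    panel = list(models)
    samples = [f"S{k + 1:02d}" for k in range(cfg.n_tii_samples)]
    bad = set(rng.choice(samples, size=cfg.n_tii_bad, replace=False))
    tracks, rows = [], []
    for sample in samples:
        n_deg = int(rng.integers(cfg.n_panel_transcripts - 3, cfg.n_panel_transcripts)) \
            if sample in bad else int(rng.integers(0, 4))
        degraded = set(rng.choice(panel, size=n_deg, replace=False))
        for tid in panel:
            chrom, exons = models[tid]
            tracks.append(_make_track(tid, sample, chrom, exons, tid in degraded, cfg, rng))
        rows.append((sample, n_deg, sample in bad))
    truth = pd.DataFrame(rows, columns=["sample_id", "n_degraded", "bad"]) \
        .set_index("sample_id")
    return tracks, panel, truth


def simulate_transcript_tracks(
    cfg: SimulationConfig,
    n_samples: int = 7,
    statuses: dict[str, int] | None = None,
) -> tuple[dict[str, list[CoverageTrack]], pd.DataFrame]:
    """Per-sample tracks for transcripts with planted integrity outcomes.

    ``statuses`` maps transcript id -> number of samples passing the
    full-coverage rule (default: one fully covered, one partial, one failed).
    Returns ({tid: tracks}, truth with expected n_pass).
    """
    rng = np.random.default_rng(cfg.seed + 4)
    if statuses is None:
        statuses = {"TXFULL": n_samples, "TXPART": max(1, n_samples // 2), "TXFAIL": 0}
    gap, intron = 10_000, 100
    pos = 1_000
    out: dict[str, list[CoverageTrack]] = {}
    rows = []
    for tid, n_pass in statuses.items():
        exons = []
        p = pos
        for _ in range(cfg.n_exons):
            exons.append((p, p + cfg.exon_length - 1))
            p += cfg.exon_length + intron
        pos = p + gap
        tracks = []
        for k in range(n_samples):
            degraded = k >= n_pass
            tracks.append(_make_track(tid, f"P{k + 1:02d}", "chrI", exons,
                                      degraded, cfg, rng, units="RPKM"))
        out[tid] = tracks
        rows.append((tid, n_pass, n_samples))
    truth = pd.DataFrame(rows, columns=["transcript_id", "n_pass", "n_total"]) \
        .set_index("transcript_id")
    return out, truth


def simulate_gmt(
    cfg: SimulationConfig,
    genes: list[str],
    planted_pool: list[str] | None = None,
) -> tuple[dict[str, set[str]], str, list[str]]:
    """A gene-set collection with one planted enriched set and a query.

    The planted set is drawn from ``planted_pool`` (default: the whole
    universe); the query holds half the planted set plus background genes, so
    a correct over-representation analysis ranks the planted set first.
    Returns (collection, planted set name, query genes).
    """
    rng = np.random.default_rng(cfg.seed + 5)
    genes = sorted(set(genes))
    if len(genes) < cfg.gmt_planted_size * 2:
        raise ValueError("gene universe too small for the planted set")
    pool = sorted(set(planted_pool)) if planted_pool is not None else genes
    if len(pool) < cfg.gmt_planted_size:
        raise ValueError("planted pool smaller than the planted set size")
    # named so the default keyword map files it under "cellular stress"
    planted_name = "PLANTED_CELLULAR_STRESS_RESPONSE"
    planted = sorted(rng.choice(pool, size=cfg.gmt_planted_size, replace=False))
    collection: dict[str, set[str]] = {planted_name: set(planted)}
    lo, hi = cfg.gmt_set_size
    for i in range(cfg.gmt_n_sets - 1):
        size = int(rng.integers(lo, hi + 1))
        members = set(rng.choice(genes, size=size, replace=False))
        collection[f"RANDOM_SET_{i + 1:03d}"] = members
    n_hit = cfg.gmt_planted_size // 2
    hits = list(rng.choice(planted, size=n_hit, replace=False))
    background = [g for g in genes if g not in set(planted)]
    fillers = list(rng.choice(background, size=n_hit, replace=False))
    return collection, planted_name, sorted(hits + fillers)


def simulate_crrew(cfg: SimulationConfig, genes: list[str]) -> list[CRREWRecord]:
    """Synthetic curated CRREW annotation over a fraction of the gene universe."""
    rng = np.random.default_rng(cfg.seed + 6)
    genes = sorted(set(genes))
    n = int(round(cfg.crrew_fraction * len(genes)))
    chosen = sorted(rng.choice(genes, size=n, replace=False))
    classes = ("chromatin remodeler cofactor", "RNA interactor", "reader",
               "eraser", "writer")
    return [
        CRREWRecord(gene=g, crrew_class=classes[i % len(classes)],
                    in_sperm_proteome=bool(rng.random() < 0.3))
        for i, g in enumerate(chosen)
    ]


def write_simulation(cfg: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Emit every input file the pipeline consumes, plus truth tables.

    Returns a dict of logical name -> path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    sperm, oocyte, zygote, truth = simulate_abundances(cfg)
    for name, am in (("sperm", sperm), ("oocyte", oocyte), ("zygote", zygote)):
        p, m = outdir / f"{name}.tsv", outdir / f"{name}_meta.tsv"
        write_abundance(am, p, m)
        paths[name] = p
        paths[f"{name}_meta"] = m
    truth.to_csv(outdir / "truth_res.tsv", sep="\t")
    paths["truth_res"] = outdir / "truth_res.tsv"

    comparisons, dbp_truth = simulate_dbp_lists(cfg, truth)
    for c in comparisons:
        p = outdir / f"dbp_{c.segment}.tsv"
        write_dbp_list(c.entries, p)
        paths[f"dbp_{c.segment}"] = p
    pd.Series(dbp_truth["consistent_genes"]).to_csv(
        outdir / "truth_consistent_genes.tsv", sep="\t", index=False, header=["gene"])
    paths["truth_consistent"] = outdir / "truth_consistent_genes.tsv"

    for arm, vm in simulate_visit_means(cfg, comparisons).items():
        p = outdir / f"visit_means_{arm}.tsv"
        vm.to_csv(p, sep="\t")
        paths[f"visit_means_{arm}"] = p

    tracks, panel, tii_truth = simulate_panel_coverage(cfg)
    covdir = outdir / "coverage"
    covdir.mkdir(exist_ok=True)
    by_sample: dict[str, list[CoverageTrack]] = {}
    for t in tracks:
        by_sample.setdefault(t.sample_id, []).append(t)
    for sample, ts in by_sample.items():
        p = covdir / f"{sample}.bedGraph"
        for i, t in enumerate(ts):
            write_bedgraph(t, p, append=i > 0)
    paths["coverage_dir"] = covdir
    models = _panel_models(cfg)
    with open(outdir / "panel.bed", "w") as fh:
        for tid, (chrom, exons) in models.items():
            for s, e in exons:
                fh.write(f"{chrom}\t{s - 1}\t{e}\t{tid}\n")
    paths["panel_bed"] = outdir / "panel.bed"
    tii_truth.to_csv(outdir / "truth_tii.tsv", sep="\t")
    paths["truth_tii"] = outdir / "truth_tii.tsv"

    genes = sorted(truth["gene"].unique())
    # plant the enriched set among the paternal/responsive overlap genes so the
    # pipeline's enrichment stage has signal to find
    overlap_pool = sorted({g for gs in dbp_truth["overlap_genes"].values() for g in gs})
    collection, planted_name, query = simulate_gmt(
        cfg, genes, planted_pool=overlap_pool or None)
    write_gmt(collection, outdir / "sets.gmt")
    paths["gmt"] = outdir / "sets.gmt"
    write_gene_list(genes, outdir / "universe.txt")
    paths["universe"] = outdir / "universe.txt"
    write_gene_list(query, outdir / "query.txt")
    paths["query"] = outdir / "query.txt"
    (outdir / "truth_gmt.txt").write_text(planted_name + "\n")

    write_crrew(simulate_crrew(cfg, genes), outdir / "crrew.tsv")
    paths["crrew"] = outdir / "crrew.tsv"

    cfg_dict = dataclasses.asdict(cfg)
    cfg_dict["thresholds"] = dataclasses.asdict(cfg.thresholds)
    with open(outdir / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(cfg_dict, fh, sort_keys=True)
    paths["config"] = outdir / "sim_config.yaml"
    return paths
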