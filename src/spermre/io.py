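"""Readers and writers for the external formats the pipeline touches.

RNA elements (REs) are exon-sized genomic intervals named ``chrom_start_end``
with coordinates treated as 1-based inclusive (UCSC browser display
convention).  BED export converts to 0-based half-open.  Chromosome names may
themselves contain underscores (e.g. ``chrUn_KI270742v1``); parsing therefore
splits on the *final two* underscore-delimited integer tokens only.

Abundance matrices are TSV files with a ``re_id`` index column and one column
per sample, paired with a sample-metadata TSV (``sample_id``, ``tissue``,
``study_arm``, ``visit``).  Missing cells are errors, never zeros: silent
zero-filling would corrupt downstream threshold classification.
"""

from __future__ import annotations

import re as _re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RE",
    "AbundanceMatrix",
    "CoverageTrack",
    "CRREWRecord",
    "ParseError",
    "FormatError",
    "parse_re_id",
    "format_re_id",
    "normalize_symbol",
    "read_abundance",
    "write_abundance",
    "read_gmt",
    "write_gmt",
    "read_crrew",
    "write_crrew",
    "read_bedgraph",
    "write_bedgraph",
    "read_exon_bed",
    "write_bed",
    "write_network",
    "read_network",
    "read_gene_list",
    "write_gene_list",
    "read_dbp_list",
    "write_dbp_list",
]

TISSUES = ("sperm", "oocyte", "zygote")
STUDY_ARMS = ("B1HB2", "H1BH2", "none")
VISITS = ("baseline", "crossover", "crossback", "none")
SEGMENTS = ("B1H", "H1B", "HB2", "BH2")
CRREW_CLASSES = (
    "chromatin remodeler cofactor",
    "RNA interactor",
    "reader",
    "eraser",
    "writer",
)


class ParseError(ValueError):
    """Raised for malformed identifiers or records, naming the offender."""


class FormatError(ValueError):
    """Raised when a file violates its format contract."""


@dataclass(frozen=True)
class RE:
    """A genomic RNA element: 1-based inclusive interval, optional gene."""

    chrom: str
    start: int
    end: int
    gene: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ParseError("RE chromosome name is empty")
        if self.start < 0 or self.end < 0:
            raise ParseError(f"negative coordinate in {self.chrom}_{self.start}_{self.end}")
        if self.start > self.end:
            raise ParseError(f"start > end in {self.chrom}_{self.start}_{self.end}")

    @property
    def id(self) -> str:
        return f"{self.chrom}_{self.start}_{self.end}"


def parse_re_id(re_id: str) -> RE:
    """Parse ``chrom_start_end`` into an :class:`RE`.

    Splits on the final two underscore tokens, so chromosome names containing
    underscores survive:  ``chrUn_KI270742v1_100_200`` has chrom
    ``chrUn_KI270742v1``.
    """
    parts = re_id.split("_")
    if len(parts) < 3:
        raise ParseError(f"malformed RE id {re_id!r}: need chrom_start_end")
    chrom = "_".join(parts[:-2])
    try:
        start, end = int(parts[-2]), int(parts[-1])
    except ValueError:
        raise ParseError(f"malformed RE id {re_id!r}: non-integer coordinates") from None
    if start < 0 or end < 0:
        raise ParseError(f"malformed RE id {re_id!r}: negative coordinate")
    if start > end:
        raise ParseError(f"malformed RE id {re_id!r}: start > end")
    return RE(chrom=chrom, start=start, end=end)


def format_re_id(re: RE) -> str:
    return re.id


def normalize_symbol(gene: str) -> str:
    """Gene symbols are matched case-insensitively by uppercasing both sides."""
    return gene.strip().upper()


@dataclass
class AbundanceMatrix:
    """RPKM per (RE, sample) plus per-sample metadata.

    ``data``: DataFrame indexed by re_id with one float column per sample.
    ``meta``: DataFrame indexed by sample_id with columns tissue, study_arm,
    visit.
    """

    data: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise FormatError(f"duplicate re_id {dup!r} in abundance matrix")
        if self.data.isna().any().any():
            raise FormatError("missing abundance cells are errors, not zeros")
        if (self.data.to_numpy() < 0).any():
            raise FormatError("negative RPKM value in abundance matrix")
        missing = [s for s in self.data.columns if s not in self.meta.index]
        if missing:
            raise FormatError(f"samples absent from metadata: {missing}")
        if self.meta.index.has_duplicates:
            raise FormatError("duplicate sample_id in metadata")
        bad = set(self.meta["tissue"]) - set(TISSUES)
        if bad:
            raise FormatError(f"unknown tissue(s) {sorted(bad)}")

    @property
    def re_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def median_per_re(self) -> pd.Series:
        """Median RPKM across biological replicates, per RE."""
        return self.data.median(axis=1)

    def mean_per_re(self) -> pd.Series:
        return self.data.mean(axis=1)


@dataclass
class CoverageTrack:
    """Per-base normalized coverage over the exon union of one transcript.

    ``exons`` are 1-based inclusive, sorted, non-overlapping; ``depth`` has one
    value per exon base, concatenated in exon order.  ``units`` declares the
    normalization (RPM or RPKM).
    """

    transcript_id: str
    sample_id: str
    chrom: str
    exons: list[tuple[int, int]]
    depth: np.ndarray
    units: str = "RPM"

    def __post_init__(self) -> None:
        if not self.exons:
            raise FormatError(f"{self.transcript_id}: empty exon set")
        prev_end = -1
        for s, e in self.exons:
            if s > e:
                raise FormatError(f"{self.transcript_id}: exon start > end ({s} > {e})")
            if s <= prev_end:
                raise FormatError(f"{self.transcript_id}: exons overlap or unsorted")
            prev_end = e
        n = sum(e - s + 1 for s, e in self.exons)
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.shape != (n,):
            raise FormatError(
                f"{self.transcript_id}: depth length {self.depth.shape} != exon bases {n}"
            )

    @property
    def n_bases(self) -> int:
        return int(self.depth.shape[0])


@dataclass(frozen=True)
class CRREWRecord:
    """Curated epigenetic-mediator annotation for one gene."""

    gene: str
    crrew_class: str
    in_sperm_proteome: bool

    def __post_init__(self) -> None:
        if self.crrew_class not in CRREW_CLASSES:
            raise FormatError(
                f"{self.gene}: crrew_class {self.crrew_class!r} not one of {CRREW_CLASSES}"
            )


# ---------------------------------------------------------------------------
# abundance matrices


def read_abundance(path: str | Path, meta_path: str | Path) -> AbundanceMatrix:
    data = pd.read_csv(path, sep="\t", index_col="re_id")
    data = data.astype(float)
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
    for col in ("tissue", "study_arm", "visit"):
        if col not in meta.columns:
            raise FormatError(f"{meta_path}: metadata missing column {col!r}")
    return AbundanceMatrix(data=data, meta=meta)


def write_abundance(am: AbundanceMatrix, path: str | Path, meta_path: str | Path) -> None:
    am.data.to_csv(path, sep="\t", index_label="re_id")
    am.meta.to_csv(meta_path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# GMT gene-set collections (MSigDB format: name, description, genes...)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    collection: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            name = fields[0]
            genes = {normalize_symbol(g) for g in fields[2:] if g.strip()}
            if not genes:
                raise FormatError(f"{path}:{lineno}: empty gene set {name!r}")
            if name in collection:
                raise FormatError(f"{path}:{lineno}: duplicated set name {name!r}")
            collection[name] = genes
    return collection


def write_gmt(collection: Mapping[str, Iterable[str]], path: str | Path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            genes = sorted({normalize_symbol(g) for g in genes})
            if not genes:
                raise FormatError(f"refusing to write empty gene set {name!r}")
            fh.write("\t".join([name, description, *genes]) + "\n")


# ---------------------------------------------------------------------------
# CRREW annotation tables


def read_crrew(path: str | Path) -> list[CRREWRecord]:
    df = pd.read_csv(path, sep="\t")
    for col in ("gene", "crrew_class", "in_sperm_proteome"):
        if col not in df.columns:
            raise FormatError(f"{path}: CRREW table missing column {col!r}")
    return [
        CRREWRecord(
            gene=normalize_symbol(r.gene),
            crrew_class=str(r.crrew_class),
            in_sperm_proteome=bool(r.in_sperm_proteome),
        )
        for r in df.itertuples()
    ]


def write_crrew(records: Sequence[CRREWRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "crrew_class": [r.crrew_class for r in records],
            "in_sperm_proteome": [r.in_sperm_proteome for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# coverage: bedGraph (0-based half-open) projected onto exon models


def read_bedgraph(
    path: str | Path,
    exons: Sequence[tuple[int, int]],
    chrom: str,
    transcript_id: str,
    sample_id: str,
    units: str = "RPM",
) -> CoverageTrack:
    """Project a bedGraph onto 1-based inclusive ``exons`` of ``chrom``.

    Bases without a bedGraph interval get depth 0.  bedGraph coordinates are
    0-based half-open, per the UCSC definition.
    """
    exons = sorted(tuple(e) for e in exons)
    n = sum(e - s + 1 for s, e in exons)
    depth = np.zeros(n, dtype=float)
    # offset of each exon's first base within the concatenated depth vector
    offsets = np.cumsum([0] + [e - s + 1 for s, e in exons[:-1]])
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: bedGraph line needs 4 fields")
            c, s0, e0, v = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if c != chrom:
                continue
            # convert 0-based half-open -> 1-based inclusive [s0+1, e0]
            lo, hi = s0 + 1, e0
            for (es, ee), off in zip(exons, offsets):
                a, b = max(lo, es), min(hi, ee)
                if a <= b:
                    depth[off + (a - es): off + (b - es) + 1] = v
    return CoverageTrack(
        transcript_id=transcript_id,
        sample_id=sample_id,
        chrom=chrom,
        exons=list(exons),
        depth=depth,
        units=units,
    )


def write_bedgraph(track: CoverageTrack, path: str | Path, append: bool = False) -> None:
    """Write a track as bedGraph, run-length collapsing constant stretches."""
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        pos = 0
        for es, ee in track.exons:
            n = ee - es + 1
            seg = track.depth[pos: pos + n]
            i = 0
            while i < n:
                j = i
                while j + 1 < n and seg[j + 1] == seg[i]:
                    j += 1
                if seg[i] != 0.0:
                    # 1-based inclusive [es+i, es+j] -> 0-based half-open
                    fh.write(f"{track.chrom}\t{es + i - 1}\t{es + j}\t{seg[i]:g}\n")
                i = j + 1
            pos += n


def read_exon_bed(path: str | Path) -> dict[str, tuple[str, list[tuple[int, int]]]]:
    """Read a BED of exons keyed by the name column.

    Returns ``{transcript_id: (chrom, [(start, end), ...])}`` with 1-based
    inclusive exon coordinates.
    """
    models: dict[str, tuple[str, list[tuple[int, int]]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: exon BED needs chrom,start,end,name")
            chrom, s0, e0, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if name in models and models[name][0] != chrom:
                raise FormatError(f"{path}:{lineno}: transcript {name!r} on two chromosomes")
            models.setdefault(name, (chrom, []))[1].append((s0 + 1, e0))
    return {k: (c, sorted(ex)) for k, (c, ex) in models.items()}


# ---------------------------------------------------------------------------
# BED6 export of REs (1-based inclusive -> 0-based half-open)


def write_bed(res: Iterable[RE], path: str | Path) -> None:
    with open(path, "w") as fh:
        for re in res:
            name = re.gene if re.gene else re.id
            fh.write(f"{re.chrom}\t{re.start - 1}\t{re.end}\t{name}\t0\t+\n")


# ---------------------------------------------------------------------------
# gene lists and DBP-responsive lists


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        genes = [normalize_symbol(l) for l in fh if l.strip()]
    return sorted(set(genes))


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted({normalize_symbol(g) for g in genes}):
            fh.write(g + "\n")


def read_dbp_list(path: str | Path) -> pd.DataFrame:
    """Read a DBP-responsive RE list: re_id, gene, direction, empirical_p."""
    df = pd.read_csv(path, sep="\t")
    for col in ("re_id", "gene", "direction", "empirical_p"):
        if col not in df.columns:
            raise FormatError(f"{path}: DBP list missing column {col!r}")
    bad = set(df["direction"]) - {"up", "down"}
    if bad:
        raise FormatError(f"{path}: direction must be up/down, got {sorted(bad)}")
    p = df["empirical_p"].to_numpy(dtype=float)
    if (p <= 0).any() or (p > 0.05).any():
        raise FormatError(f"{path}: empirical_p must lie in (0, 0.05]")
    df = df.copy()
    df["gene"] = df["gene"].map(normalize_symbol)
    return df


def write_dbp_list(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# network tables (node/edge TSVs loadable by standard graph tools)


def write_network(nodes: pd.DataFrame, edges: pd.DataFrame, prefix: str | Path) -> tuple[Path, Path]:
    """Write node and edge TSVs mirroring the exposure-response network.

    nodes: id, type, class; edges: source, target, n_res, segment.
    """
    prefix = Path(prefix)
    for col in ("id", "type", "class"):
        if col not in nodes.columns:
            raise FormatError(f"node table missing column {col!r}")
    for col in ("source", "target", "n_res", "segment"):
        if col not in edges.columns:
            raise FormatError(f"edge table missing column {col!r}")
    if len(edges):
        bad = set(edges["segment"]) - set(SEGMENTS)
        if bad:
            raise FormatError(f"edge segment(s) {sorted(bad)} not in {SEGMENTS}")
    node_path = prefix.with_name(prefix.name + "_nodes.tsv")
    edge_path = prefix.with_name(prefix.name + "_edges.tsv")
    nodes.to_csv(node_path, sep="\t", index=False)
    edges.to_csv(edge_path, sep="\t", index=False)
    return node_path, edge_path


def read_network(prefix: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    prefix = Path(prefix)
    nodes = pd.read_csv(prefix.with_name(prefix.name + "_nodes.tsv"), sep="\t")
    edges = pd.read_csv(prefix.with_name(prefix.name + "_edges.tsv"), sep="\t")
    return nodes, edges
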