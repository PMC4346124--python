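"""Readers and writers for every external format the pipeline touches.

Formats
-------
- probe table: tab-delimited with header
  ``sample_id  probe_id  chrom  start  end  log2_ratio``
- genes: BED4/BED6 (+ optional probe-count column 7)
- arms: TSV with ``chrom  centromere`` (+ optional length)
- metadata / IHC: TSV keyed by ``sample_id``
- Cluster 3.0 dialect ``.cdt`` / ``.gtr`` / ``.atr`` files for
  TreeView-compatible heat-map and dendrogram viewers

All coordinates are 0-based, half-open.  Floats are written with 10
significant digits, so write->read round-trips are identity to that
precision.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import Dendrogram
from .profile import GeneMatrix

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"
PROBE_COLUMNS = ["sample_id", "probe_id", "chrom", "start", "end", "log2_ratio"]


# ---------------------------------------------------------------------------
# Probe tables
# ---------------------------------------------------------------------------

def read_probe_table(path) -> pd.DataFrame:
    """Read a probe-level log2-ratio table.

    Non-numeric ratios are flagged missing (NaN) with a warning naming the
    offending line numbers — never silently dropped.  Malformed intervals
    raise with line numbers; a missing required column raises naming it.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=0, comment="#", dtype=str)
    for col in PROBE_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing column: {col}")
    for col in ("start", "end"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
    ratio = pd.to_numeric(df["log2_ratio"], errors="coerce")
    bad = ratio.isna() & df["log2_ratio"].notna() & (df["log2_ratio"].str.upper() != "NA")
    flagged = ratio.isna()
    if flagged.any():
        lines = [int(i) + 2 for i in df.index[flagged]]  # +2: header + 1-based
        warnings.warn(
            f"{int(flagged.sum())} non-numeric/missing log2_ratio values "
            f"flagged missing (lines {lines[:10]}{'...' if len(lines) > 10 else ''})",
            stacklevel=2,
        )
    del bad
    df["log2_ratio"] = ratio
    invalid = df["start"] >= df["end"]
    if invalid.any():
        line = int(df.index[invalid][0]) + 2
        raise ValueError(f"start >= end at line {line}")
    return df[PROBE_COLUMNS]


def write_probe_table(df: pd.DataFrame, path) -> None:
    df[PROBE_COLUMNS].to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# BED / arms / metadata
# ---------------------------------------------------------------------------

def read_gene_bed(path) -> pd.DataFrame:
    """Read gene annotation from BED4/BED6 (+ optional probe-count col 7).

    Intervals are kept 0-based half-open verbatim.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"line {lineno}: expected >= 4 BED fields")
            chrom, start, end, name = fields[:4]
            start, end = int(start), int(end)
            if start >= end:
                raise ValueError(f"line {lineno}: start >= end ({start} >= {end})")
            row = {
                "gene_id": name,
                "chrom": chrom,
                "start": start,
                "end": end,
                "strand": fields[5] if len(fields) >= 6 else "unknown",
            }
            if len(fields) >= 7:
                row["probe_count"] = int(fields[6])
            rows.append(row)
    df = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "probe_count"]
    )
    if df["gene_id"].duplicated().any():
        dup = df["gene_id"][df["gene_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate gene_id: {dup}")
    if df["probe_count"].isna().all():
        df = df.drop(columns=["probe_count"])
    return df


def write_gene_bed(genes: pd.DataFrame, path) -> None:
    cols = [genes["chrom"], genes["start"], genes["end"], genes["gene_id"],
            pd.Series(0, index=genes.index),
            genes.get("strand", pd.Series("+", index=genes.index))]
    names = ["chrom", "start", "end", "gene_id", "score", "strand"]
    if "probe_count" in genes.columns:
        cols.append(genes["probe_count"])
        names.append("probe_count")
    out = pd.concat(cols, axis=1)
    out.columns = names
    out.to_csv(path, sep="\t", index=False, header=False)


def read_arms_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("chrom", "centromere"):
        if col not in df.columns:
            raise ValueError(f"missing column: {col}")
    return df


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if "sample_id" not in df.columns:
        raise ValueError("missing column: sample_id")
    return df


read_ihc = read_metadata  # same contract: TSV keyed by sample_id


def write_tsv(df: pd.DataFrame, path, provenance: str | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Gene matrix TSV
# ---------------------------------------------------------------------------

def write_gene_matrix(matrix: GeneMatrix, path) -> None:
    """Gene matrix as TSV: genes in rows with annotation, samples in columns."""
    out = matrix.gene_info.copy()
    out.insert(0, "gene_id", out.index)
    out["probe_count"] = matrix.probe_counts
    for s in matrix.samples:
        out[s] = matrix.values.loc[s]
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_gene_matrix(path) -> GeneMatrix:
    df = pd.read_csv(path, sep="\t", comment="#")
    meta_cols = [c for c in ("gene_id", "chrom", "start", "end", "strand",
                             "probe_count") if c in df.columns]
    for col in ("gene_id", "probe_count"):
        if col not in meta_cols:
            raise ValueError(f"missing column: {col}")
    sample_cols = [c for c in df.columns if c not in meta_cols]
    df = df.set_index("gene_id")
    info_cols = [c for c in ("chrom", "start", "end", "strand") if c in df.columns]
    return GeneMatrix(
        values=df[sample_cols].T.astype(float),
        probe_counts=df["probe_count"].astype(int),
        gene_info=df[info_cols],
    )


# ---------------------------------------------------------------------------
# Cluster 3.0 CDT / GTR / ATR
# ---------------------------------------------------------------------------

def write_cdt_gtr(
    matrix: GeneMatrix,
    sample_tree: Dendrogram,
    gene_tree: Dendrogram | None,
    out_prefix,
) -> list[Path]:
    """Write Cluster 3.0 dialect viewer files.

    ``.cdt`` holds the matrix (genes in rows, arrays in columns) in tree
    leaf order; ``.atr``/``.gtr`` hold the array/gene merge histories with
    node IDs ``NODE<k>X``, leaf IDs ``ARRY<k>X``/``GENE<k>X`` and merge
    scores written as similarity (1 - distance).
    """
    out_prefix = Path(out_prefix)
    if set(sample_tree.leaves) != set(matrix.samples):
        raise ValueError("sample tree leaves do not match matrix samples")
    if gene_tree is not None and set(gene_tree.leaves) != set(matrix.genes):
        raise ValueError("gene tree leaves do not match matrix genes")

    files: list[Path] = []
    arry_id = {s: f"ARRY{i}X" for i, s in enumerate(matrix.samples)}
    gene_id = {g: f"GENE{i}X" for i, g in enumerate(matrix.genes)}

    atr_path = out_prefix.with_suffix(".atr")
    _write_tree_file(atr_path, sample_tree, arry_id)
    files.append(atr_path)
    if gene_tree is not None:
        gtr_path = out_prefix.with_suffix(".gtr")
        _write_tree_file(gtr_path, gene_tree, gene_id)
        files.append(gtr_path)

    sample_order = sample_tree.leaf_order()
    row_order = gene_tree.leaf_order() if gene_tree is not None else matrix.genes
    cdt_path = out_prefix.with_suffix(".cdt")
    with open(cdt_path, "w") as fh:
        header = ["GID", "UNIQID", "NAME", "GWEIGHT"] + sample_order
        fh.write("\t".join(header) + "\n")
        fh.write("\t".join(["AID", "", "", ""] + [arry_id[s] for s in sample_order]) + "\n")
        fh.write("\t".join(["EWEIGHT", "", "", ""] + ["1"] * len(sample_order)) + "\n")
        vals = matrix.values
        for g in row_order:
            row = [gene_id[g], g, g, "1"]
            for s in sample_order:
                v = vals.at[s, g]
                row.append("" if pd.isna(v) else FLOAT_FORMAT % v)
            fh.write("\t".join(row) + "\n")
    files.append(cdt_path)
    return files


def _write_tree_file(path: Path, tree: Dendrogram, leaf_ids: dict[str, str]) -> None:
    n = tree.n_leaves
    node_name: dict[int, str] = {
        i: leaf_ids[leaf] for i, leaf in enumerate(tree.leaves)
    }
    with open(path, "w") as fh:
        for t, (left, right, height) in enumerate(tree.merges):
            node = f"NODE{t + 1}X"
            node_name[n + t] = node
            similarity = 1.0 - height
            fh.write(
                "\t".join(
                    [node, node_name[left], node_name[right], FLOAT_FORMAT % similarity]
                )
                + "\n"
            )


def read_tree_file(path) -> list[tuple[str, str, str, float]]:
    """Parse a .gtr/.atr file -> (node, child1, child2, height) rows.

    Heights are recovered as 1 - similarity (the written convention).
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            node, c1, c2, sim = line.rstrip("\n").split("\t")
            rows.append((node, c1, c2, 1.0 - float(sim)))
    return rows


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------

def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_report(results: dict, out_dir, provenance: str) -> list[Path]:
    """Persist the pipeline result bundle as headed TSV/JSON files.

    ``results`` maps artifact names to DataFrames (written as TSV with a
    provenance comment) or JSON-serialisable objects.  Reruns with the
    same inputs produce byte-identical files.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ValueError(f"unwritable output directory {out_dir}: {exc}") from exc
    written: list[Path] = []
    for name, obj in sorted(results.items()):
        if isinstance(obj, pd.DataFrame):
            path = out_dir / f"{name}.tsv"
            write_tsv(obj, path, provenance)
        elif isinstance(obj, pd.Series):
            path = out_dir / f"{name}.tsv"
            write_tsv(obj.rename_axis("id").reset_index(), path, provenance)
        else:
            path = out_dir / f"{name}.json"
            with open(path, "w") as fh:
                json.dump(obj, fh, indent=2, sort_keys=True, default=str)
                fh.write("\n")
        written.append(path)
    return written


# ---------------------------------------------------------------------------
# GEO-style import
# ---------------------------------------------------------------------------

def import_geo(series_matrix_path, platform_path) -> pd.DataFrame:
    """Map a GEO-style series matrix + platform positions to a probe table.

    ``series_matrix_path``: TSV with a probe ``ID_REF`` column and one
    log2-ratio column per sample.  ``platform_path``: TSV with columns
    ``probe_id`` (or ``ID``), ``chrom``, ``start``, ``end``.  Full scanner
    feature-extraction files are deliberately not parsed; if an accession
    provides only raw two-channel data, log2 tumour/reference ratios must
    be computed upstream and exported in this two-table form.
    """
    series = pd.read_csv(series_matrix_path, sep="\t", comment="!")
    id_col = "ID_REF" if "ID_REF" in series.columns else series.columns[0]
    platform = pd.read_csv(platform_path, sep="\t", comment="#")
    pid_col = "probe_id" if "probe_id" in platform.columns else "ID"
    for col in (pid_col, "chrom", "start", "end"):
        if col not in platform.columns:
            raise ValueError(f"missing column: {col}")
    platform = platform.rename(columns={pid_col: "probe_id"})

    long = series.melt(
        id_vars=[id_col], var_name="sample_id", value_name="log2_ratio"
    ).rename(columns={id_col: "probe_id"})
    merged = long.merge(
        platform[["probe_id", "chrom", "start", "end"]], on="probe_id", how="inner"
    )
    n_lost = len(long) - len(merged)
    if n_lost:
        logger.warning(
            "%d measurements dropped: probes absent from platform table", n_lost
        )
    if merged.empty:
        raise ValueError("no probes shared between series matrix and platform")
    merged["log2_ratio"] = pd.to_numeric(merged["log2_ratio"], errors="coerce")
    return merged[PROBE_COLUMNS]
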