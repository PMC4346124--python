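"""Gene-level copy-number profiles from probe measurements.

Probe log2 tumour/reference ratios are averaged within each gene to improve
the signal-to-noise ratio, thresholded into gain/loss/neutral calls at
|log2| > 0.3219 (a 1.25-fold change), and summarised as per-sample CNA
burden, per-group frequencies and chromosome-arm penetrance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

#: log2(1.25) printed to 4 decimals: the CNA gain threshold.
GAIN_THRESHOLD = 0.3219
LOSS_THRESHOLD = -0.3219

GAIN, NEUTRAL, LOSS = 1.0, 0.0, -1.0  # call codes; missing = NaN


@dataclass
class GeneMatrix:
    """Samples x genes matrix of probe-averaged log2 ratios.

    ``values`` rows are samples, columns genes; ``probe_counts`` gives the
    number of array probes assigned to each retained gene; ``gene_info``
    (indexed by gene_id) carries chrom/start/end annotation.
    """

    values: pd.DataFrame
    probe_counts: pd.Series
    gene_info: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.probe_counts < 1).any():
            raise ValueError("probe_counts must be >= 1 for every retained gene")
        if list(self.values.columns) != list(self.probe_counts.index):
            raise ValueError("values columns and probe_counts index differ")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return len(self.values.index)

    @property
    def n_genes(self) -> int:
        return len(self.values.columns)

    def filter_min_probes(self, min_probes: int) -> "GeneMatrix":
        """Restrict to genes covered by at least *min_probes* probes."""
        keep = self.probe_counts.index[self.probe_counts >= min_probes]
        return GeneMatrix(
            self.values[keep],
            self.probe_counts.loc[keep],
            self.gene_info.loc[keep],
        )

    def subset_samples(self, sample_ids) -> "GeneMatrix":
        return replace(self, values=self.values.loc[list(sample_ids)])

    def subset_genes(self, gene_ids) -> "GeneMatrix":
        gene_ids = list(gene_ids)
        return GeneMatrix(
            self.values[gene_ids],
            self.probe_counts.loc[gene_ids],
            self.gene_info.loc[gene_ids],
        )


def average_probes_to_genes(
    probes: pd.DataFrame, annotation: pd.DataFrame
) -> GeneMatrix:
    """Average probe log2 ratios within genes.

    A probe belongs to a gene iff the probe's midpoint lies within the gene
    interval (0-based half-open); if gene intervals overlap, the
    lexicographically smallest gene_id wins.  The gene value is the
    arithmetic mean of the gene's non-missing probe ratios; a (sample,
    gene) value is missing only when every probe was missing.  Genes that
    acquire no probes are dropped; probes in no gene are dropped with a
    logged count.  The result is invariant to probe input order.
    """
    required = {"sample_id", "probe_id", "chrom", "start", "end", "log2_ratio"}
    missing_cols = required - set(probes.columns)
    if missing_cols:
        raise ValueError(f"missing column: {sorted(missing_cols)[0]}")

    trees: dict[str, IntervalTree] = {}
    for row in annotation.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(
            row.start, row.end, row.gene_id
        )

    # assign each distinct probe once, then broadcast across samples
    uniq = probes[["probe_id", "chrom", "start", "end"]].drop_duplicates("probe_id")
    gene_of: dict[str, str | None] = {}
    for row in uniq.itertuples(index=False):
        tree = trees.get(row.chrom)
        hits = tree[(row.start + row.end) / 2.0] if tree is not None else set()
        gene_of[row.probe_id] = min(h.data for h in hits) if hits else None
    assigned = probes["probe_id"].map(gene_of).to_numpy(dtype=object)

    in_gene = pd.notna(assigned)
    n_dropped = int((~in_gene).sum())
    if n_dropped:
        logger.info("dropped %d probes overlapping no gene", n_dropped)
    if not in_gene.any():
        raise ValueError("no probe overlaps any gene")

    assigned_df = probes.loc[in_gene, ["sample_id", "probe_id", "log2_ratio"]].copy()
    assigned_df["gene_id"] = assigned[in_gene]
    # stable sort before aggregating => probe-order invariance
    assigned_df = assigned_df.sort_values(
        ["gene_id", "sample_id", "probe_id"], kind="mergesort"
    )

    values = (
        assigned_df.groupby(["sample_id", "gene_id"], sort=True)["log2_ratio"]
        .mean()  # skips NaN; all-NaN group -> NaN
        .unstack("gene_id")
    )
    probe_counts = (
        assigned_df.groupby("gene_id", sort=True)["probe_id"].nunique()
    )

    ann = annotation.set_index("gene_id")
    gene_order = [g for g in ann.index if g in values.columns]
    sample_order = sorted(probes["sample_id"].unique())
    values = values.reindex(index=sample_order, columns=gene_order)
    info_cols = [c for c in ("chrom", "start", "end", "strand") if c in ann.columns]
    return GeneMatrix(
        values, probe_counts.reindex(gene_order), ann.loc[gene_order, info_cols]
    )


@dataclass(frozen=True)
class CnaCallParams:
    """Thresholds for gain/loss calling on the log2 scale.

    Comparisons are strict (exclusive) by default: a value exactly at the
    threshold is neutral.
    """

    gain_threshold: float = GAIN_THRESHOLD
    loss_threshold: float = LOSS_THRESHOLD
    strict: bool = True

    def __post_init__(self) -> None:
        if not self.loss_threshold < 0 < self.gain_threshold:
            raise ValueError("need loss_threshold < 0 < gain_threshold")


@dataclass
class CnaCallMatrix:
    """Per (sample, gene) call: +1 gain, -1 loss, 0 neutral, NaN missing."""

    codes: pd.DataFrame
    params: CnaCallParams = field(default_factory=CnaCallParams)

    def is_gain(self) -> pd.DataFrame:
        return self.codes == GAIN

    def is_loss(self) -> pd.DataFrame:
        return self.codes == LOSS

    def is_missing(self) -> pd.DataFrame:
        return self.codes.isna()


def call_cna(matrix: GeneMatrix, params: CnaCallParams | None = None) -> CnaCallMatrix:
    """Threshold gene-level log2 ratios into gain/loss/neutral calls."""
    params = params or CnaCallParams()
    v = matrix.values.to_numpy(dtype=float)
    if params.strict:
        gains = v > params.gain_threshold
        losses = v < params.loss_threshold
    else:
        gains = v >= params.gain_threshold
        losses = v <= params.loss_threshold
    codes = np.where(gains, GAIN, np.where(losses, LOSS, NEUTRAL))
    codes = np.where(np.isnan(v), np.nan, codes)
    return CnaCallMatrix(
        pd.DataFrame(codes, index=matrix.values.index, columns=matrix.values.columns),
        params,
    )


def cna_burden(calls: CnaCallMatrix) -> pd.DataFrame:
    """Per-sample CNA burden: counts and fraction of altered genes.

    fraction = (gains + losses) / non-missing genes; samples whose genes
    are all missing get NaN fraction and a warning.
    """
    if calls.codes.empty:
        raise ValueError("call matrix is empty")
    gains = calls.is_gain().sum(axis=1)
    losses = calls.is_loss().sum(axis=1)
    tested = calls.codes.notna().sum(axis=1)
    if (tested == 0).any():
        bad = list(calls.codes.index[tested == 0])
        logger.warning("samples with all-missing genes (fraction undefined): %s", bad)
    fraction = (gains + losses) / tested.where(tested > 0)
    return pd.DataFrame(
        {
            "gains": gains,
            "losses": losses,
            "altered": gains + losses,
            "tested": tested,
            "fraction": fraction,
        }
    )


def group_cna_frequency(
    burden: pd.DataFrame,
    metadata: pd.DataFrame,
    group_col: str = "vienna_group",
) -> tuple[pd.Series, pd.DataFrame]:
    """Mean CNA fraction per group plus pairwise Welch tests.

    Groups with fewer than two samples are excluded from testing with a
    warning.  Returns ``(per-group mean fraction, tests table)``.
    """
    from .differential import welch_t  # shared Welch implementation

    groups = metadata.set_index("sample_id")[group_col]
    unmapped = [s for s in burden.index if s not in groups.index]
    if unmapped:
        raise ValueError(f"samples missing from metadata: {unmapped}")
    by_group = burden["fraction"].groupby(groups.loc[burden.index])
    means = by_group.mean()

    rows = []
    names = sorted(by_group.groups)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            xa = by_group.get_group(a).dropna().to_numpy()
            xb = by_group.get_group(b).dropna().to_numpy()
            if len(xa) < 2 or len(xb) < 2:
                logger.warning(
                    "group %s vs %s: fewer than 2 samples, test skipped",
                    a, b,
                )
                continue
            t, df, p = welch_t(xa, xb)
            rows.append(
                {"group1": a, "group2": b, "t": t, "df": df, "p": p,
                 "n1": len(xa), "n2": len(xb)}
            )
    return means, pd.DataFrame(
        rows, columns=["group1", "group2", "t", "df", "p", "n1", "n2"]
    )


def arm_penetrance(
    calls: CnaCallMatrix,
    gene_info: pd.DataFrame,
    arms: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    group_col: str = "vienna_group",
    arm_fraction_threshold: float = 0.5,
) -> pd.DataFrame:
    """Percentage of samples per group carrying each arm-level gain/loss.

    A sample carries an arm gain (loss) iff the fraction of the arm's
    called (non-missing) genes in state gain (loss) is >= the threshold
    (default 0.5).  ``arms`` must provide a centromere for every chromosome
    present; arms with no genes are excluded with a warning.
    """
    centromere = arms.set_index("chrom")["centromere"]
    present = set(gene_info["chrom"])
    uncovered = present - set(centromere.index)
    if uncovered:
        raise ValueError(f"arms table missing chromosome: {sorted(uncovered)[0]}")

    mid = (gene_info["start"] + gene_info["end"]) / 2.0
    arm_of_gene = gene_info["chrom"] + np.where(
        mid < centromere.reindex(gene_info["chrom"]).to_numpy(), "p", "q"
    )
    all_arms = [f"{c}{a}" for c in centromere.index for a in ("p", "q")]
    empty = [a for a in all_arms if (arm_of_gene == a).sum() == 0]
    if empty:
        logger.warning("arms with zero genes excluded: %s", empty)

    if metadata is None:
        groups = pd.Series("all", index=calls.codes.index)
    else:
        groups = metadata.set_index("sample_id")[group_col].reindex(calls.codes.index)

    rows = []
    for arm in all_arms:
        gene_ids = gene_info.index[arm_of_gene == arm]
        if len(gene_ids) == 0:
            continue
        sub = calls.codes[gene_ids]
        tested = sub.notna().sum(axis=1)
        frac_gain = (sub == GAIN).sum(axis=1) / tested.where(tested > 0)
        frac_loss = (sub == LOSS).sum(axis=1) / tested.where(tested > 0)
        has_gain = frac_gain >= arm_fraction_threshold
        has_loss = frac_loss >= arm_fraction_threshold
        for gname, idx in groups.groupby(groups).groups.items():
            n = len(idx)
            rows.append(
                {
                    "group": gname,
                    "arm": arm,
                    "pct_gain": 100.0 * has_gain.loc[idx].sum() / n,
                    "pct_loss": 100.0 * has_loss.loc[idx].sum() / n,
                    "n_samples": n,
                    "n_genes": len(gene_ids),
                }
            )
    return pd.DataFrame(rows)
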