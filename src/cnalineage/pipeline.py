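"""End-to-end orchestration: simulate/load -> call -> cluster -> diff -> report.

A single validated :class:`RunConfig` drives every stage; all randomness
flows from one seed through named sub-streams, intermediate artifacts are
persisted after each stage, and a manifest records version, config hash
and seed so reruns are byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as aio
from .clustering import (
    SamplePair,
    label_lineages,
    lineage_recovery_score,
    sweep_gene_size,
)
from .differential import DEFAULT_CONTRASTS, find_differential_genes, supervised_2d_cluster
from .genome import build_genome
from .phenotype import classify_from_percentages, phenotype_by_group_report
from .profile import (
    CnaCallParams,
    arm_penetrance,
    average_probes_to_genes,
    call_cna,
    cna_burden,
    group_cna_frequency,
)
from .simulate import (
    CohortConfig,
    LineageCohortSpec,
    LineageSpec,
    NoiseModel,
    pairs_from_metadata,
    simulate_cohort,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    seed: int = 0
    simulate: dict | None = None  # cohort-simulation block
    inputs: dict | None = None  # or paths: probes, genes, arms, metadata, ihc
    gain_threshold: float = 0.3219
    loss_threshold: float = -0.3219
    strict: bool = True
    arm_fraction: float = 0.5
    sweep: tuple[int, ...] = (10, 6, 4, 3, 2)
    k: int = 3
    adjacency: str = "sibling"
    alpha: float = 0.05
    label_mode: str = "auto"
    manual_map: dict | None = None
    raw: dict = field(default_factory=dict)


_KNOWN_TOP = {"seed", "simulate", "inputs", "call", "cluster", "differential", "label"}
_KNOWN_SIM = {
    "lineages", "lineage_specs", "noise", "genome",
    "same_tumour_pairs", "concurrent_pairs",
}
_KNOWN_CALL = {"gain_threshold", "loss_threshold", "strict", "arm_fraction"}
_KNOWN_CLUSTER = {"sweep", "k", "adjacency"}
_KNOWN_DIFF = {"alpha"}
_KNOWN_LABEL = {"mode", "manual_map"}
_KNOWN_INPUTS = {"probes", "genes", "arms", "metadata", "ihc"}


def validate_config(source) -> RunConfig:
    """Normalise a config file/dict; report every error at once.

    Raises ``ValueError`` whose message lists all problems with their key
    paths; otherwise returns a :class:`RunConfig` with defaults filled
    (thresholds 0.3219/-0.3219, sweep 10,6,4,3,2, k=3, alpha=0.05).
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(source or {})
    errors: list[str] = []
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")

    for key in data:
        if key not in _KNOWN_TOP:
            errors.append(f"unknown key: {key}")

    def section(name: str, known: set[str]) -> dict:
        block = data.get(name) or {}
        if not isinstance(block, dict):
            errors.append(f"{name}: must be a mapping")
            return {}
        for key in block:
            if key not in known:
                errors.append(f"unknown key: {name}.{key}")
        return block

    sim = section("simulate", _KNOWN_SIM) if "simulate" in data else None
    inputs = section("inputs", _KNOWN_INPUTS) if "inputs" in data else None
    call = section("call", _KNOWN_CALL)
    cluster = section("cluster", _KNOWN_CLUSTER)
    diff = section("differential", _KNOWN_DIFF)
    label = section("label", _KNOWN_LABEL)

    if sim is None and inputs is None:
        errors.append("config needs a 'simulate' or 'inputs' section")
    if sim is not None and inputs is not None:
        errors.append("'simulate' and 'inputs' are mutually exclusive")
    if inputs is not None:
        for key in ("probes", "genes", "arms", "metadata"):
            if key not in inputs:
                errors.append(f"inputs.{key}: required path missing")

    seed = data.get("seed", 0)
    if not isinstance(seed, int):
        errors.append("seed: must be an integer")
        seed = 0

    cfg = RunConfig(seed=seed, simulate=sim, inputs=inputs, raw=data)
    cfg.gain_threshold = call.get("gain_threshold", 0.3219)
    cfg.loss_threshold = call.get("loss_threshold", -0.3219)
    cfg.strict = call.get("strict", True)
    cfg.arm_fraction = call.get("arm_fraction", 0.5)
    if not (isinstance(cfg.gain_threshold, (int, float)) and cfg.gain_threshold > 0):
        errors.append("call.gain_threshold: must be a positive number")
    if not (isinstance(cfg.loss_threshold, (int, float)) and cfg.loss_threshold < 0):
        errors.append("call.loss_threshold: must be a negative number")
    if not (isinstance(cfg.arm_fraction, (int, float)) and 0 < cfg.arm_fraction <= 1):
        errors.append("call.arm_fraction: must be in (0,1]")

    sweep = cluster.get("sweep", [10, 6, 4, 3, 2])
    if not (isinstance(sweep, (list, tuple)) and sweep
            and all(isinstance(t, int) and t >= 1 for t in sweep)):
        errors.append("cluster.sweep: must be a non-empty list of integers >= 1")
    else:
        cfg.sweep = tuple(sweep)
    k = cluster.get("k", 3)
    if not (isinstance(k, int) and k >= 1):
        errors.append("cluster.k: must be an integer >= 1")
    else:
        cfg.k = k
    cfg.adjacency = cluster.get("adjacency", "sibling")
    if cfg.adjacency not in ("sibling", "leaf-order"):
        errors.append("cluster.adjacency: must be 'sibling' or 'leaf-order'")

    alpha = diff.get("alpha", 0.05)
    if not (isinstance(alpha, (int, float)) and 0 < alpha <= 1):
        errors.append("differential.alpha: alpha must be in (0,1]")
    else:
        cfg.alpha = float(alpha)

    cfg.label_mode = label.get("mode", "auto")
    if cfg.label_mode not in ("auto", "manual"):
        errors.append("label.mode: must be 'auto' or 'manual'")
    cfg.manual_map = label.get("manual_map")

    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    return cfg


def _build_cohort_config(sim: dict, seed: int) -> CohortConfig:
    kwargs: dict = {"seed": seed}
    for key in ("same_tumour_pairs", "concurrent_pairs"):
        if key in sim:
            kwargs[key] = int(sim[key])
    if "lineages" in sim:
        kwargs["lineages"] = {
            lab: LineageCohortSpec(
                int(spec["n"]), tuple((g, int(c)) for g, c in spec["vienna"].items())
            )
            for lab, spec in sim["lineages"].items()
        }
    if "lineage_specs" in sim:
        kwargs["lineage_specs"] = {
            lab: LineageSpec(
                lab,
                float(spec["focal_cna_rate"]),
                tuple(
                    (a, k, float(p)) for a, k, p in spec.get("arm_events", [])
                ),
                int(spec.get("copy_gain", 3)),
                int(spec.get("copy_loss", 1)),
            )
            for lab, spec in sim["lineage_specs"].items()
        }
    if "noise" in sim:
        kwargs["noise"] = NoiseModel(**sim["noise"])
    if "genome" in sim:
        kwargs["genome"] = build_genome(**sim["genome"])
    return CohortConfig(**kwargs)


def run_pipeline(config: RunConfig | dict | str | Path, out_dir) -> dict:
    """Run all stages in order, persisting artifacts under *out_dir*.

    Returns the result bundle (also written to disk).  A failing stage
    raises :class:`PipelineError` naming the stage; artifacts from earlier
    stages remain on disk.
    """
    if not isinstance(config, RunConfig):
        config = validate_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = aio.config_hash(config.raw)
    provenance = f"cnalineage {__version__} config={chash} seed={config.seed}"
    timings: list[tuple[str, float]] = []
    results: dict = {}

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                out = fn()
            except Exception as exc:  # halt, keep last good artifacts
                raise PipelineError(name, exc) from exc
            dt = time.perf_counter() - t0
            timings.append((name, dt))
            logger.info("stage %-12s %6.2fs", name, dt)
            return out
        return wrap

    # -- acquire -------------------------------------------------------
    def _acquire():
        if config.simulate is not None:
            cohort = simulate_cohort(_build_cohort_config(config.simulate, config.seed))
            genes = cohort.genome.genes_df()
            arms = cohort.genome.arms_df()
            aio.write_probe_table(cohort.probes, out_dir / "probes.tsv")
            aio.write_gene_bed(genes, out_dir / "genes.bed")
            aio.write_tsv(arms, out_dir / "arms.tsv")
            aio.write_tsv(cohort.metadata, out_dir / "metadata.tsv")
            aio.write_tsv(cohort.ihc, out_dir / "ihc.tsv")
            return cohort.probes, genes, arms, cohort.metadata, cohort.ihc
        paths = config.inputs
        for key in ("probes", "genes", "arms", "metadata"):
            if not Path(paths[key]).exists():
                raise FileNotFoundError(f"input path does not exist: {paths[key]}")
        probes = aio.read_probe_table(paths["probes"])
        genes = aio.read_gene_bed(paths["genes"])
        arms = aio.read_arms_tsv(paths["arms"])
        metadata = aio.read_metadata(paths["metadata"])
        ihc = aio.read_ihc(paths["ihc"]) if paths.get("ihc") else None
        return probes, genes, arms, metadata, ihc

    probes, genes, arms, metadata, ihc = stage("acquire")(_acquire)

    # -- gene matrix ---------------------------------------------------
    matrix = stage("average")(lambda: average_probes_to_genes(probes, genes))
    aio.write_gene_matrix(matrix, out_dir / "gene_matrix.tsv")

    # -- calls, burden, penetrance ------------------------------------
    params = CnaCallParams(config.gain_threshold, config.loss_threshold, config.strict)
    calls = stage("call")(lambda: call_cna(matrix, params))
    burden = stage("burden")(lambda: cna_burden(calls))
    freq_means, freq_tests = stage("group_freq")(
        lambda: group_cna_frequency(burden, metadata)
    )
    penetrance = stage("penetrance")(
        lambda: arm_penetrance(
            calls, matrix.gene_info, arms, metadata,
            arm_fraction_threshold=config.arm_fraction,
        )
    )

    # -- sweep on the combined set, lineage call on mucosal samples ----
    pairs = [SamplePair(*p) for p in pairs_from_metadata(metadata)]
    sweep = stage("sweep")(
        lambda: sweep_gene_size(
            matrix, config.sweep, pairs, config.k, config.adjacency
        )
    )
    selected_threshold = (
        sweep.selected if sweep.selected is not None
        else int(sweep.table["min_probes"].iloc[-1])
    )

    def _lineages():
        mucosal = metadata.loc[metadata["part"] == "mucosal", "sample_id"] \
            if "part" in metadata.columns else pd.Series(matrix.samples)
        sub = matrix.subset_samples(mucosal).filter_min_probes(selected_threshold)
        from .clustering import complete_linkage
        tree = complete_linkage(sub)
        partition = tree.cut(config.k)
        return tree, label_lineages(
            partition, burden["fraction"], config.label_mode, config.manual_map
        )

    mucosal_tree, assignment = stage("label")(_lineages)

    # -- differential screen + supervised 2-D clustering ---------------
    def _diff():
        mucosal_matrix = matrix.subset_samples(list(assignment.labels.index))
        return find_differential_genes(
            mucosal_matrix, assignment.labels, DEFAULT_CONTRASTS, config.alpha
        ), mucosal_matrix

    diff, mucosal_matrix = stage("differential")(_diff)

    def _supervised():
        if len(diff.selected) < 2:
            logger.warning(
                "fewer than 2 selected genes; supervised clustering skipped"
            )
            return None
        stree, gtree, sub = supervised_2d_cluster(mucosal_matrix, diff.selected)
        aio.write_cdt_gtr(sub, stree, gtree, out_dir / "supervised")
        return stree, gtree

    stage("supervised")(_supervised)

    # -- phenotype -----------------------------------------------------
    def _phenotype():
        if ihc is None:
            return None
        phen = pd.Series(
            {
                row["sample_id"]: classify_from_percentages(row).label
                for row in ihc.to_dict("records")
            }
        )
        return phen, phenotype_by_group_report(phen, metadata)

    phen_out = stage("phenotype")(_phenotype)

    # -- report --------------------------------------------------------
    results = {
        "lineage_assignment": assignment.labels.rename("lineage")
        .rename_axis("sample_id").reset_index(),
        "cna_burden": burden.rename_axis("sample_id").reset_index(),
        "group_cna_frequency": freq_means.rename("mean_fraction")
        .rename_axis("group").reset_index(),
        "group_cna_tests": freq_tests,
        "penetrance": penetrance,
        "sweep": sweep.table,
        "differential_genes": diff.table,
        "selected_genes": pd.DataFrame({"gene_id": diff.selected}),
    }
    if phen_out is not None:
        phen, report = phen_out
        results["phenotypes"] = phen.rename("phenotype") \
            .rename_axis("sample_id").reset_index()
        results["phenotype_by_group"] = report.table.reset_index()
        results["phenotype_trend_tests"] = report.trend_tests
        results["phenotype_fisher_tests"] = report.fisher_tests
    stage("report")(lambda: aio.write_report(results, out_dir, provenance))

    manifest = {
        "version": __version__,
        "config_hash": chash,
        "seed": config.seed,
        "selected_min_probes": int(selected_threshold),
        "n_samples": int(len(matrix.samples)),
        "n_genes": int(matrix.n_genes),
        "stages": [name for name, _ in timings],
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    for name, dt in timings:
        logger.debug("timing %s: %.3fs", name, dt)

    results["assignment"] = assignment
    results["sweep_result"] = sweep
    results["matrix"] = matrix
    results["calls"] = calls
    results["manifest"] = manifest
    if config.simulate is not None and "truth_lineage" in metadata.columns:
        truth = metadata.set_index("sample_id")["truth_lineage"]
        results["recovery_ari"] = lineage_recovery_score(truth, assignment.labels)
    return results
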