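"""Synthetic aCGH cohort generation with known lineage structure.

The generator emulates the data structure of an FFPE tumour/reference
two-colour CGH study: three lineage archetypes of increasing copy-number
instability (``stable``, ``intermediate``, ``unstable``), recurrent
chromosome-arm events (8q and 20q gains, 5q and 21q losses in the unstable
lineage), paired mucosal/deep samples of one tumour, concurrent separate
lesions in one patient, probe-level log2 noise, and a gene-specific
amplification bias that enters both channels identically and therefore
cancels exactly in the emitted tumour/reference log ratio.

Every source of randomness is split into a named sub-stream of one cohort
seed, so adding samples to a configuration never perturbs earlier ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import GenomeModel, build_genome

logger = logging.getLogger(__name__)

LINEAGE_LABELS = ("stable", "intermediate", "unstable")

# Named sub-stream identifiers (spawn-key prefixes).
_STREAM_PROFILE = 1
_STREAM_DIVERGE = 2
_STREAM_SAMPLE = 3
_STREAM_META = 4
_STREAM_IHC = 5

# Gene-bias stream is a property of the assay, not of a cohort seed: the
# bias must be reproducible across samples and cohorts.
_BIAS_ENTROPY = 46_501


def substream(seed: int, *key: int) -> np.random.Generator:
    """Deterministic named child stream of a cohort seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in key))
    )


@dataclass(frozen=True)
class LineageSpec:
    """Event rates defining one lineage archetype.

    ``arm_events`` are ``(arm, "gain"|"loss", probability)`` triples applied
    whole-arm; ``focal_cna_rate`` is the per-gene probability of a private
    random gain/loss applied afterwards (focal events override arm events).
    """

    label: str
    focal_cna_rate: float
    arm_events: tuple[tuple[str, str, float], ...] = ()
    copy_gain: int = 3
    copy_loss: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.focal_cna_rate <= 1.0:
            raise ValueError("focal_cna_rate must be in [0,1]")
        for arm, kind, prob in self.arm_events:
            if kind not in ("gain", "loss"):
                raise ValueError(f"arm event kind must be gain|loss, got {kind!r}")
            if not 0.0 <= prob <= 1.0:
                raise ValueError(f"arm event probability out of [0,1]: {prob}")


#: Default archetypes.  Each lineage carries one defining core arm event at
#: probability 1.0 plus secondary recurrent arms; focal rates give the
#: stable < intermediate <= unstable burden ordering.
DEFAULT_LINEAGE_SPECS: dict[str, LineageSpec] = {
    "stable": LineageSpec("stable", 0.02, (("chr7q", "gain", 1.0),)),
    "intermediate": LineageSpec(
        "intermediate",
        0.10,
        (("chr17p", "loss", 1.0), ("chr18q", "loss", 0.7), ("chr13q", "loss", 0.4)),
    ),
    "unstable": LineageSpec(
        "unstable",
        0.18,
        (
            ("chr8q", "gain", 1.0),
            ("chr20q", "gain", 0.8),
            ("chr5q", "loss", 0.5),
            ("chr21q", "loss", 0.4),
        ),
    ),
}


def validate_lineage_specs(specs: dict[str, LineageSpec]) -> None:
    """Enforce the burden ordering stable < intermediate <= unstable."""
    s, i, u = (specs[k].focal_cna_rate for k in LINEAGE_LABELS)
    if not (s < i <= u):
        raise ValueError(
            "focal rates must satisfy stable < intermediate <= unstable, "
            f"got {s}, {i}, {u}"
        )


@dataclass
class TrueProfile:
    """Ground-truth per-gene integer copy numbers (diploid reference = 2)."""

    copies: np.ndarray
    lineage: str
    lesion_id: str = ""
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.copies = np.asarray(self.copies, dtype=int)
        if (self.copies < 0).any():
            raise ValueError("copy numbers must be >= 0")

    def altered_mask(self) -> np.ndarray:
        return self.copies != 2


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise parameters on the log2 scale.

    probe_sd
        SD of additive probe-level noise (FFPE + WGA data are noisy; 0.25
        is the default calibration choice, see the methods note).
    gene_bias_sd
        SD of the per-gene amplification bias.  The bias is drawn once per
        assay design, applied to tumour and reference channels identically
        and cancels exactly in the emitted ratio.
    part_divergence / concurrent_divergence
        Per-gene probability of a private copy-number edit in, respectively,
        a second part of the same tumour and a separate concurrent lesion.
    purity
        Neoplastic cell fraction of the tumour sample (1.0 = pure).
    """

    probe_sd: float = 0.25
    gene_bias_sd: float = 0.5
    part_divergence: float = 0.005
    concurrent_divergence: float = 0.05
    purity: float = 1.0

    def __post_init__(self) -> None:
        if self.probe_sd < 0:
            raise ValueError("probe_sd must be >= 0")
        if self.gene_bias_sd < 0:
            raise ValueError("gene_bias_sd must be >= 0")
        if not 0.0 <= self.part_divergence < self.concurrent_divergence <= 1.0:
            raise ValueError(
                "need 0 <= part_divergence < concurrent_divergence <= 1"
            )
        if not 0.0 < self.purity <= 1.0:
            raise ValueError("purity must be in (0,1]")


def simulate_profile(
    genome: GenomeModel,
    spec: LineageSpec,
    seed: int | np.random.Generator,
    patient_id: str = "",
    lesion_id: str = "",
) -> TrueProfile:
    """Draw a ground-truth copy-number profile for one lesion.

    Arm events fire first (whole arm set to the event copy number), then
    focal events override individual genes.
    """
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed)
    n = genome.n_genes
    copies = np.full(n, 2, dtype=int)
    for arm, kind, prob in spec.arm_events:
        idx = genome.genes_on_arm(arm)  # raises KeyError for unknown arm
        if rng.random() < prob:
            copies[idx] = spec.copy_gain if kind == "gain" else spec.copy_loss
    focal = rng.random(n) < spec.focal_cna_rate
    gain_side = rng.random(n) < 0.5
    copies[focal & gain_side] = spec.copy_gain
    copies[focal & ~gain_side] = spec.copy_loss
    return TrueProfile(copies, spec.label, lesion_id, patient_id)


def diverge_profile(
    profile: TrueProfile,
    rate: float,
    rng: np.random.Generator,
    copy_gain: int = 3,
    copy_loss: int = 1,
    lesion_id: str | None = None,
) -> TrueProfile:
    """Copy of *profile* with per-gene probability *rate* of a private edit.

    A hit toggles the gene: an altered gene reverts to diploid, a diploid
    gene acquires a random gain or loss.
    """
    copies = profile.copies.copy()
    hit = rng.random(copies.size) < rate
    gain_side = rng.random(copies.size) < 0.5
    was_altered = copies != 2
    copies[hit & was_altered] = 2
    copies[hit & ~was_altered & gain_side] = copy_gain
    copies[hit & ~was_altered & ~gain_side] = copy_loss
    return replace(profile, copies=copies,
                   lesion_id=profile.lesion_id if lesion_id is None else lesion_id)


def gene_bias(genome: GenomeModel, sd: float) -> np.ndarray:
    """Per-gene amplification bias, reproducible for a given genome size."""
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=_BIAS_ENTROPY, spawn_key=(genome.n_genes,))
    )
    return rng.normal(0.0, sd, genome.n_genes)


def simulate_sample(
    profile: TrueProfile,
    genome: GenomeModel,
    noise: NoiseModel,
    seed: int | np.random.Generator,
    sample_id: str = "S1",
) -> pd.DataFrame:
    """Emit probe-level log2 tumour/reference measurements for one sample.

    Both channels are computed explicitly: the tumour channel carries
    ``log2(copy/2) + bias_g`` and the reference channel ``bias_g``; the
    emitted ratio is their difference, so the gene bias cancels by
    construction, plus additive probe noise.
    """
    if profile.copies.size != genome.n_genes:
        raise ValueError(
            f"profile has {profile.copies.size} genes but genome has "
            f"{genome.n_genes}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed)
    bias = gene_bias(genome, noise.gene_bias_sd)

    pdf = genome.probes_df()
    gidx = np.array(
        [genome.gene_index(g) if g is not None else -1 for g in pdf["gene_id"]]
    )
    copy = np.where(gidx >= 0, profile.copies[np.clip(gidx, 0, None)], 2)
    # purity mixes neoplastic with diploid stromal cells
    eff = noise.purity * copy + (1.0 - noise.purity) * 2.0
    probe_bias = np.where(gidx >= 0, bias[np.clip(gidx, 0, None)], 0.0)
    tumour = np.log2(eff / 2.0) + probe_bias
    reference = probe_bias
    ratio = tumour - reference
    if noise.probe_sd > 0:
        ratio = ratio + rng.normal(0.0, noise.probe_sd, ratio.size)
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "probe_id": pdf["probe_id"],
            "chrom": pdf["chrom"],
            "start": pdf["start"],
            "end": pdf["end"],
            "log2_ratio": ratio,
        }
    )


# ---------------------------------------------------------------------------
# Cohort-level simulation
# ---------------------------------------------------------------------------

#: Tumour-size distributions (mm, mean/sd and minimum) per histological group.
_SIZE_PARAMS = {
    "A": (5.7, 3.1, 2.0),
    "B": (9.4, 7.9, 3.0),
    "Cm": (27.1, 7.8, 15.0),
    "Cd": (51.1, 27.1, 15.0),
}

#: Mucin-phenotype composition per histological group (low-grade lesions
#: intestinal; invasive groups mixed, with occasional null phenotype).
_PHENOTYPE_PROBS = {
    "A": {"I": 1.0},
    "B": {"G": 0.33, "GI": 0.33, "I": 0.34},
    "Cm": {"G": 0.29, "GI": 0.29, "I": 0.34, "N": 0.08},
    "Cd": {"G": 0.29, "GI": 0.29, "I": 0.34, "N": 0.08},
}

_LINEAGE_PREFIX = {"stable": "ST", "intermediate": "IM", "unstable": "UN"}


@dataclass(frozen=True)
class LineageCohortSpec:
    """Sample count and Vienna-group composition for one lineage."""

    n: int
    vienna: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        total = sum(c for _, c in self.vienna)
        if total != self.n:
            raise ValueError(f"vienna counts sum to {total}, expected n={self.n}")
        for g, _ in self.vienna:
            if g not in _SIZE_PARAMS:
                raise ValueError(f"unknown Vienna group: {g}")


DEFAULT_COHORT_LINEAGES: dict[str, LineageCohortSpec] = {
    "stable": LineageCohortSpec(11, (("A", 5), ("B", 6))),
    "intermediate": LineageCohortSpec(10, (("A", 4), ("B", 6))),
    "unstable": LineageCohortSpec(12, (("A", 1), ("B", 3), ("Cm", 3), ("Cd", 5))),
}


@dataclass
class CohortConfig:
    lineages: dict[str, LineageCohortSpec] = field(
        default_factory=lambda: dict(DEFAULT_COHORT_LINEAGES)
    )
    lineage_specs: dict[str, LineageSpec] = field(
        default_factory=lambda: dict(DEFAULT_LINEAGE_SPECS)
    )
    noise: NoiseModel = field(default_factory=NoiseModel)
    genome: GenomeModel | None = None
    same_tumour_pairs: int = 3
    concurrent_pairs: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for label in self.lineages:
            if label not in LINEAGE_LABELS:
                raise ValueError(f"unknown lineage label: {label}")
        if set(self.lineage_specs) >= set(LINEAGE_LABELS):
            validate_lineage_specs(self.lineage_specs)
        if self.same_tumour_pairs < 0 or self.concurrent_pairs < 0:
            raise ValueError("pair counts must be >= 0")
        n_cd = sum(
            c
            for spec in self.lineages.values()
            for g, c in spec.vienna
            if g == "Cd"
        )
        if self.same_tumour_pairs > n_cd:
            raise ValueError(
                f"same_tumour_pairs={self.same_tumour_pairs} exceeds the "
                f"{n_cd} deep-capable (Cd) samples"
            )
        total = sum(spec.n for spec in self.lineages.values())
        if 2 * self.concurrent_pairs > total:
            raise ValueError("concurrent pairs exceed available samples")


@dataclass
class CohortResult:
    """Probe table, metadata, IHC table and per-sample ground truth."""

    probes: pd.DataFrame
    metadata: pd.DataFrame
    ihc: pd.DataFrame
    genome: GenomeModel
    profiles: dict[str, TrueProfile]

    def truth_labels(self, mucosal_only: bool = False) -> pd.Series:
        md = self.metadata
        if mucosal_only:
            md = md[md["part"] == "mucosal"]
        return md.set_index("sample_id")["truth_lineage"]


def simulate_cohort(config: CohortConfig | None = None) -> CohortResult:
    """Generate a full cohort: probe table, metadata, IHC and ground truth.

    Concurrent-lesion pairs are drawn from one patient-level base profile,
    each lesion diverging at ``concurrent_divergence``; mucosal/deep pairs
    share one lesion profile, the deep part diverging at
    ``part_divergence``.  Deep-part samples attach to Vienna group Cd
    lesions (deeply invasive tumours), mirroring how mucosal and deep parts
    of the same tumour are sampled.
    """
    config = config or CohortConfig()
    genome = config.genome if config.genome is not None else build_genome()
    seed = config.seed

    # --- enumerate lesions -------------------------------------------
    lesions: list[dict] = []  # lineage, vienna, lesion_id
    for label in LINEAGE_LABELS:
        if label not in config.lineages:
            continue
        spec = config.lineages[label]
        i = 0
        for group, count in spec.vienna:
            for _ in range(count):
                lesions.append(
                    {
                        "lineage": label,
                        "vienna_group": group,
                        "lesion_id": f"{_LINEAGE_PREFIX[label]}{i:02d}",
                    }
                )
                i += 1

    # --- concurrent pairs: two lesions share one patient + base profile
    pair_lineages = [LINEAGE_LABELS[j % 3] for j in range(config.concurrent_pairs)]
    concurrent_groups: list[list[int]] = []
    used: set[int] = set()
    for label in pair_lineages:
        members = [
            k
            for k, les in enumerate(lesions)
            if les["lineage"] == label and k not in used
        ]
        if len(members) < 2:
            raise ValueError(
                f"concurrent pairs exceed available {label} samples"
            )
        concurrent_groups.append(members[:2])
        used.update(members[:2])

    # --- patients -----------------------------------------------------
    patient_of: dict[int, str] = {}
    pid = 0
    for grp in concurrent_groups:
        pid += 1
        for k in grp:
            patient_of[k] = f"P{pid:02d}"
    for k in range(len(lesions)):
        if k not in patient_of:
            pid += 1
            patient_of[k] = f"P{pid:02d}"

    # --- deep parts attach to the first same_tumour_pairs Cd lesions --
    cd_idx = [k for k, les in enumerate(lesions) if les["vienna_group"] == "Cd"]
    deep_of = set(cd_idx[: config.same_tumour_pairs])

    # --- draw profiles ------------------------------------------------
    lineage_specs = config.lineage_specs
    profiles: dict[int, TrueProfile] = {}
    for grp in concurrent_groups:
        base_rng = substream(seed, _STREAM_PROFILE, grp[0])
        label = lesions[grp[0]]["lineage"]
        base = simulate_profile(genome, lineage_specs[label], base_rng)
        for k in grp:
            div_rng = substream(seed, _STREAM_DIVERGE, k)
            profiles[k] = diverge_profile(
                base,
                config.noise.concurrent_divergence,
                div_rng,
                lineage_specs[label].copy_gain,
                lineage_specs[label].copy_loss,
                lesion_id=lesions[k]["lesion_id"],
            )
            profiles[k].patient_id = patient_of[k]
    for k, les in enumerate(lesions):
        if k in profiles:
            continue
        rng = substream(seed, _STREAM_PROFILE, k)
        profiles[k] = simulate_profile(
            genome,
            lineage_specs[les["lineage"]],
            rng,
            patient_id=patient_of[k],
            lesion_id=les["lesion_id"],
        )

    # --- emit samples -------------------------------------------------
    probe_frames: list[pd.DataFrame] = []
    meta_rows: list[dict] = []
    ihc_rows: list[dict] = []
    sample_profiles: dict[str, TrueProfile] = {}
    sample_counter = 0
    for k, les in enumerate(lesions):
        meta_rng = substream(seed, _STREAM_META, k)
        size_mm = _draw_size(les["vienna_group"], meta_rng)
        parts = [("mucosal", profiles[k])]
        if k in deep_of:
            div_rng = substream(seed, _STREAM_DIVERGE, 10_000 + k)
            deep = diverge_profile(
                profiles[k],
                config.noise.part_divergence,
                div_rng,
                lineage_specs[les["lineage"]].copy_gain,
                lineage_specs[les["lineage"]].copy_loss,
            )
            parts.append(("deep", deep))
        for part, prof in parts:
            sample_id = f"{les['lesion_id']}{'m' if part == 'mucosal' else 'd'}"
            srng = substream(seed, _STREAM_SAMPLE, sample_counter)
            probe_frames.append(
                simulate_sample(prof, genome, config.noise, srng, sample_id)
            )
            meta_rows.append(
                {
                    "sample_id": sample_id,
                    "patient_id": patient_of[k],
                    "lesion_id": les["lesion_id"],
                    "part": part,
                    "vienna_group": les["vienna_group"],
                    "size_mm": size_mm,
                    "truth_lineage": les["lineage"],
                }
            )
            sample_profiles[sample_id] = prof
            sample_counter += 1
        ihc_rng = substream(seed, _STREAM_IHC, k)
        ihc_rows.append(
            _draw_ihc(f"{les['lesion_id']}m", les["vienna_group"], ihc_rng)
        )

    probes = pd.concat(probe_frames, ignore_index=True)
    metadata = pd.DataFrame(meta_rows)
    ihc = pd.DataFrame(ihc_rows)
    logger.info(
        "simulated cohort: %d samples (%d lesions), %d probe measurements",
        len(metadata),
        len(lesions),
        len(probes),
    )
    return CohortResult(probes, metadata, ihc, genome, sample_profiles)


def _draw_size(group: str, rng: np.random.Generator) -> float:
    mean, sd, lo = _SIZE_PARAMS[group]
    return round(float(max(lo, rng.normal(mean, sd))), 1)


def _draw_ihc(sample_id: str, group: str, rng: np.random.Generator) -> dict:
    probs = _PHENOTYPE_PROBS[group]
    labels = list(probs)
    phenotype = labels[
        int(rng.choice(len(labels), p=np.array([probs[l] for l in labels])))
    ]
    gastric = phenotype in ("G", "GI")
    intestinal = phenotype in ("I", "GI")

    def neg() -> float:
        return round(float(rng.uniform(0.0, 4.9)), 1)

    row = {"sample_id": sample_id}
    if gastric:
        row["MUC5AC"] = round(float(rng.uniform(10.0, 90.0)), 1)
        row["MUC6"] = (
            round(float(rng.uniform(5.0, 70.0)), 1) if rng.random() < 0.6 else neg()
        )
    else:
        row["MUC5AC"], row["MUC6"] = neg(), neg()
    if intestinal:
        row["MUC2"] = round(float(rng.uniform(10.0, 90.0)), 1)
        row["CD10"] = (
            round(float(rng.uniform(5.0, 80.0)), 1) if rng.random() < 0.6 else neg()
        )
    else:
        row["MUC2"], row["CD10"] = neg(), neg()
    return row


def pairs_from_metadata(metadata: pd.DataFrame) -> list[tuple[str, str, str]]:
    """Derive (sample_a, sample_b, kind) pairs from cohort metadata.

    ``same_tumour``: two parts of one lesion; ``concurrent``: mucosal
    samples of two different lesions in one patient.
    """
    pairs: list[tuple[str, str, str]] = []
    for _, grp in metadata.groupby("lesion_id", sort=True):
        if len(grp) == 2:
            a, b = sorted(grp["sample_id"])
            pairs.append((a, b, "same_tumour"))
    mucosal = metadata[metadata["part"] == "mucosal"]
    for _, grp in mucosal.groupby("patient_id", sort=True):
        if grp["lesion_id"].nunique() == 2:
            a, b = sorted(grp["sample_id"])
            pairs.append((a, b, "concurrent"))
    return pairs
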