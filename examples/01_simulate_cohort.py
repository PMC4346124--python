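"""Generate a synthetic aCGH cohort with known lineage structure.

Builds the default miniature genome (8 chromosomes, ~100 genes each,
2-12 probes per gene), simulates 33 mucosal lesions across the three
lineage archetypes plus 3 deep-part samples and 2 concurrent-lesion
pairs, and prints what the cohort contains.
"""

from cnalineage import CohortConfig, simulate_cohort

cohort = simulate_cohort(CohortConfig(seed=5))

print(f"genome: {len(cohort.genome.chromosomes)} chromosomes, "
      f"{cohort.genome.n_genes} genes, {len(cohort.genome.probes)} probes")
print(f"samples: {len(cohort.metadata)} "
      f"({(cohort.metadata['part'] == 'deep').sum()} deep parts)")
print(f"probe measurements: {len(cohort.probes)}")
print("\nsamples per lineage and Vienna group:")
print(cohort.metadata.groupby(["truth_lineage", "vienna_group"]).size()
      .unstack(fill_value=0))

# Each sample's ground-truth copy numbers are recorded, so downstream
# stages can be scored against the simulated truth.
sample = cohort.metadata["sample_id"].iloc[0]
altered = cohort.profiles[sample].altered_mask().mean()
print(f"\nexample truth: sample {sample} has {altered:.1%} of genes altered")
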