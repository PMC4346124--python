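"""Probe averaging, CNA calling, burden and penetrance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cnalineage.genome import build_genome
from cnalineage.profile import (
    CnaCallParams,
    GAIN,
    LOSS,
    NEUTRAL,
    arm_penetrance,
    average_probes_to_genes,
    call_cna,
    cna_burden,
    group_cna_frequency,
    GeneMatrix,
)
from cnalineage.simulate import LineageSpec, NoiseModel, simulate_profile, simulate_sample


def _probe_row(sample, probe, chrom, start, end, ratio):
    return {"sample_id": sample, "probe_id": probe, "chrom": chrom,
            "start": start, "end": end, "log2_ratio": ratio}


def _genes(*rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


class TestAverageProbesToGenes:
    def test_mean_of_probe_ratios(self):
        probes = pd.DataFrame([
            _probe_row("s1", "p1", "chr1", 100, 160, 0.2),
            _probe_row("s1", "p2", "chr1", 200, 260, 0.4),
        ])
        genes = _genes(("G1", "chr1", 50, 300))
        m = average_probes_to_genes(probes, genes)
        assert m.values.at["s1", "G1"] == pytest.approx(0.3)
        assert m.probe_counts["G1"] == 2

    def test_probe_outside_all_genes_is_dropped(self):
        probes = pd.DataFrame([
            _probe_row("s1", "p1", "chr1", 100, 160, 0.2),
            _probe_row("s1", "p2", "chr1", 900, 960, 5.0),
        ])
        m = average_probes_to_genes(probes, _genes(("G1", "chr1", 50, 300)))
        assert m.genes == ["G1"]
        assert m.values.at["s1", "G1"] == pytest.approx(0.2)

    def test_assignment_by_midpoint_containment(self):
        # probe straddles the gene edge; midpoint 95 is outside [100, 300)
        probes = pd.DataFrame([_probe_row("s1", "p1", "chr1", 80, 110, 1.0)])
        with pytest.raises(ValueError, match="no probe overlaps any gene"):
            average_probes_to_genes(probes, _genes(("G1", "chr1", 100, 300)))

    def test_matches_bruteforce_mean_on_random_fixture(self, rng):
        genes = _genes(*[(f"G{i}", "chr1", i * 1000, i * 1000 + 800)
                         for i in range(50)])
        rows = []
        for s in ("s1", "s2", "s3"):
            for i in range(50):
                for j in range(rng.integers(1, 5)):
                    pos = i * 1000 + 100 + j * 150
                    rows.append(_probe_row(s, f"p{i}_{j}", "chr1", pos, pos + 60,
                                           float(rng.normal())))
        probes = pd.DataFrame(rows)
        m = average_probes_to_genes(probes, genes)
        # independent per-gene mean
        for s in ("s1", "s2"):
            for i in (0, 7, 31, 49):
                vals = [r["log2_ratio"] for r in rows
                        if r["sample_id"] == s and r["probe_id"].startswith(f"p{i}_")]
                assert m.values.at[s, f"G{i}"] == pytest.approx(np.mean(vals))

    def test_invariant_to_probe_input_order(self, rng):
        genes = _genes(("G1", "chr1", 0, 1000), ("G2", "chr1", 2000, 3000))
        rows = [_probe_row("s1", f"p{j}", "chr1", 100 * j, 100 * j + 60,
                           float(rng.normal())) for j in range(8)] + \
               [_probe_row("s1", f"q{j}", "chr1", 2000 + 100 * j, 2060 + 100 * j,
                           float(rng.normal())) for j in range(5)]
        probes = pd.DataFrame(rows)
        shuffled = probes.sample(frac=1.0, random_state=1)
        a = average_probes_to_genes(probes, genes)
        b = average_probes_to_genes(shuffled, genes)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_missing_ratios_excluded_not_imputed(self):
        probes = pd.DataFrame([
            _probe_row("s1", "p1", "chr1", 100, 160, 0.4),
            _probe_row("s1", "p2", "chr1", 200, 260, np.nan),
        ])
        m = average_probes_to_genes(probes, _genes(("G1", "chr1", 50, 300)))
        assert m.values.at["s1", "G1"] == pytest.approx(0.4)


def _matrix_from_values(values: dict, probe_counts=None):
    df = pd.DataFrame(values).T  # samples x genes
    pc = pd.Series(probe_counts or {g: 2 for g in df.columns})
    info = pd.DataFrame(
        {"chrom": "chr1", "start": 0, "end": 100}, index=df.columns
    )
    return GeneMatrix(df, pc.loc[df.columns], info)


class TestCallCna:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.40, GAIN), (0.3219, NEUTRAL), (0.0, NEUTRAL), (-1.0, LOSS),
         (-0.3219, NEUTRAL), (0.322, GAIN)],
    )
    def test_threshold_is_exclusive(self, value, expected):
        m = _matrix_from_values({"s1": {"G1": value}})
        calls = call_cna(m)
        assert calls.codes.at["s1", "G1"] == expected

    def test_inclusive_mode(self):
        m = _matrix_from_values({"s1": {"G1": 0.3219}})
        calls = call_cna(m, CnaCallParams(strict=False))
        assert calls.codes.at["s1", "G1"] == GAIN

    def test_missing_stays_missing(self):
        m = _matrix_from_values({"s1": {"G1": np.nan}})
        assert np.isnan(call_cna(m).codes.at["s1", "G1"])

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(-2, 2, allow_nan=False), st.floats(0, 0.5))
    def test_monotone_in_value(self, value, bump):
        lo = call_cna(_matrix_from_values({"s": {"G": value}})).codes.iat[0, 0]
        hi = call_cna(_matrix_from_values({"s": {"G": value + bump}})).codes.iat[0, 0]
        assert hi >= lo

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            CnaCallParams(gain_threshold=-0.1)


class TestBurden:
    def test_counts_and_fraction(self):
        vals = {f"G{i}": 0.0 for i in range(10)}
        vals.update({"G0": 1.0, "G1": -1.0, "G2": 0.9})
        calls = call_cna(_matrix_from_values({"s1": vals}))
        b = cna_burden(calls)
        assert b.at["s1", "altered"] == 3
        assert b.at["s1", "fraction"] == pytest.approx(0.30)

    def test_all_neutral_counts_zero(self):
        calls = call_cna(_matrix_from_values({"s1": {"G1": 0.0, "G2": 0.1}}))
        assert cna_burden(calls).at["s1", "altered"] == 0

    def test_state_counts_partition_the_gene_set(self, default_matrix):
        calls = call_cna(default_matrix)
        total = (calls.is_gain().sum(axis=1) + calls.is_loss().sum(axis=1)
                 + (calls.codes == NEUTRAL).sum(axis=1)
                 + calls.is_missing().sum(axis=1))
        assert (total == default_matrix.n_genes).all()

    def test_matches_bruteforce_recount(self, rng):
        vals = {f"s{k}": {f"G{i}": float(rng.normal(0, 0.5)) for i in range(40)}
                for k in range(6)}
        calls = call_cna(_matrix_from_values(vals))
        b = cna_burden(calls)
        for k in range(6):
            manual = sum(
                1 for v in vals[f"s{k}"].values()
                if v > 0.3219 or v < -0.3219
            )
            assert b.at[f"s{k}", "altered"] == manual


class TestGroupFrequency:
    def _meta(self, mapping):
        return pd.DataFrame(
            {"sample_id": list(mapping), "vienna_group": list(mapping.values())}
        )

    def test_identical_groups_give_zero_t(self):
        burden = pd.DataFrame({"fraction": [0.1, 0.2, 0.3, 0.1, 0.2, 0.3]},
                              index=[f"s{i}" for i in range(6)])
        meta = self._meta({f"s{i}": ("A" if i < 3 else "B") for i in range(6)})
        means, tests = group_cna_frequency(burden, meta)
        assert means["A"] == pytest.approx(means["B"])
        assert tests.iloc[0]["t"] == pytest.approx(0.0)
        assert tests.iloc[0]["p"] == pytest.approx(1.0)

    def test_single_sample_group_skipped_with_warning(self, caplog):
        burden = pd.DataFrame({"fraction": [0.1, 0.2, 0.3]},
                              index=["s0", "s1", "s2"])
        meta = self._meta({"s0": "A", "s1": "A", "s2": "B"})
        with caplog.at_level("WARNING"):
            _, tests = group_cna_frequency(burden, meta)
        assert tests.empty
        assert "skipped" in caplog.text

    def test_unstable_mean_fraction_exceeds_stable(self, default_cohort, default_matrix):
        calls = call_cna(default_matrix)
        burden = cna_burden(calls)
        meta = default_cohort.metadata.rename(
            columns={"truth_lineage": "lineage"}
        )
        means, _ = group_cna_frequency(burden, meta, group_col="lineage")
        assert means["unstable"] > means["stable"]


class TestArmPenetrance:
    def _arms(self, genome):
        return genome.arms_df()

    def test_universal_arm_gain_is_100_percent(self):
        genome = build_genome(2, 10, probe_count_distribution=3, seed=1,
                              chrom_names=["chr8", "chr5"])
        spec = LineageSpec("unstable", 0.0, (("chr8q", "gain", 1.0),))
        frames = []
        for i in range(4):
            prof = simulate_profile(genome, spec, seed=i)
            frames.append(simulate_sample(prof, genome, NoiseModel(probe_sd=0.0),
                                          seed=i, sample_id=f"s{i}"))
        m = average_probes_to_genes(pd.concat(frames), genome.genes_df())
        pen = arm_penetrance(call_cna(m), m.gene_info, self._arms(genome))
        row = pen[(pen["arm"] == "chr8q") & (pen["group"] == "all")].iloc[0]
        assert row["pct_gain"] == 100.0
        assert row["pct_loss"] == 0.0

    def test_no_calls_gives_zero_everywhere(self):
        genome = build_genome(1, 8, probe_count_distribution=2, seed=1)
        prof = simulate_profile(genome, LineageSpec("stable", 0.0), seed=1)
        s = simulate_sample(prof, genome, NoiseModel(probe_sd=0.0), seed=1)
        m = average_probes_to_genes(s, genome.genes_df())
        pen = arm_penetrance(call_cna(m), m.gene_info, self._arms(genome))
        assert (pen["pct_gain"] == 0.0).all() and (pen["pct_loss"] == 0.0).all()

    def test_probabilistic_arm_event_within_binomial_interval(self):
        from scipy.stats import binom

        genome = build_genome(2, 30, probe_count_distribution=3, seed=1,
                              chrom_names=["chr8", "chr5"])
        spec = LineageSpec("unstable", 0.0, (("chr8q", "gain", 0.4),))
        frames = []
        n = 40
        for i in range(n):
            prof = simulate_profile(genome, spec, seed=100 + i)
            frames.append(simulate_sample(prof, genome, NoiseModel(probe_sd=0.0),
                                          seed=i, sample_id=f"s{i:02d}"))
        m = average_probes_to_genes(pd.concat(frames), genome.genes_df())
        pen = arm_penetrance(call_cna(m), m.gene_info, self._arms(genome))
        row = pen[(pen["arm"] == "chr8q") & (pen["group"] == "all")].iloc[0]
        observed = row["pct_gain"] / 100.0 * n
        lo, hi = binom.ppf([0.005, 0.995], n, 0.4)
        assert lo <= observed <= hi

    def test_missing_chromosome_in_arms_table_rejected(self):
        genome = build_genome(2, 5, probe_count_distribution=2, seed=1)
        prof = simulate_profile(genome, LineageSpec("stable", 0.0), seed=1)
        s = simulate_sample(prof, genome, NoiseModel(probe_sd=0.0), seed=1)
        m = average_probes_to_genes(s, genome.genes_df())
        arms = genome.arms_df().iloc[:1]
        with pytest.raises(ValueError, match="missing chromosome"):
            arm_penetrance(call_cna(m), m.gene_info, arms)


def test_zero_noise_calls_reproduce_true_profile(zero_noise_cohort, zero_noise_matrix):
    """At probe_sd=0, thresholding recovers every simulated gain/loss."""
    c = zero_noise_cohort
    calls = call_cna(zero_noise_matrix)
    gene_ids = [g.gene_id for g in c.genome.genes]
    for sample_id in c.metadata["sample_id"]:
        copies = c.profiles[sample_id].copies
        expected = np.where(copies > 2, GAIN, np.where(copies < 2, LOSS, NEUTRAL))
        got = calls.codes.loc[sample_id, gene_ids].to_numpy()
        assert (got == expected).all()
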