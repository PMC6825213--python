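"""Synthetic-data generator: determinism, conservation, selection logic."""

import numpy as np
import pandas as pd
import pytest

from bctrace import (
    RegimenSpec,
    SimConfig,
    SimulationError,
    analyze_counts,
    generate_library,
    make_benchmark_dataset,
    simulate_population,
    simulate_sequencing,
    simulate_treatment_course,
    simulate_xenograft_lda,
    standard_regimens,
)


class TestPopulation:
    def test_same_seed_is_identical(self):
        cfg = SimConfig(seed=9)
        a = simulate_population(cfg)
        b = simulate_population(cfg)
        pd.testing.assert_frame_equal(a.clones, b.clones)

    def test_frequencies_sum_to_one_for_any_seed(self):
        for seed in range(10):
            pop = simulate_population(SimConfig(seed=seed))
            assert pop.frequencies.sum() == pytest.approx(1.0, abs=1e-9)
            assert (pop.frequencies >= 0).all()

    def test_default_clone_count_in_reported_range(self):
        counts = {
            len(simulate_population(SimConfig(seed=s)).clones) for s in range(5)
        }
        assert all(210 <= n <= 330 for n in counts)
        assert len(counts) > 1  # the count is drawn, not fixed

    def test_planted_labels_and_attributes(self):
        cfg = SimConfig(seed=2, n_clones=250)
        pop = simulate_population(cfg)
        assert pop.clones["resistant"].sum() == cfg.n_resistant
        assert pop.clones["hilic"].sum() == cfg.n_hilic
        res, sens = pop.clones["resistant"], ~pop.clones["resistant"]
        # stem-like phenotype: slower growth, higher L-IC content
        assert (
            pop.clones.loc[res, "growth_rate"].mean()
            < pop.clones.loc[sens, "growth_rate"].mean()
        )
        overlap = (pop.clones["resistant"] & pop.clones["hilic"]).sum()
        assert overlap == cfg.hilic_from_resistant

    def test_too_few_clones_errors(self):
        with pytest.raises(SimulationError):
            simulate_population(SimConfig(seed=0, n_clones=1))


class TestTreatmentCourse:
    def test_bulk_kill_matches_binomial_expectation(self):
        cfg = SimConfig(seed=3, n_clones=250, n0_cells=1e7)
        pop = simulate_population(cfg)
        regimen = RegimenSpec("kill-only", kill_fraction=0.999, duration=0.0)
        n, p = 1e7, 0.001
        se = np.sqrt(n * p * (1 - p))
        post = simulate_treatment_course(pop, regimen, seed=4)
        assert abs(post.total_cells - n * p) <= 3.0 * se

    def test_nt_course_preserves_frequencies_exactly(self):
        cfg = SimConfig(seed=5, n_clones=100)
        pop = simulate_population(cfg)
        pop.clones["growth_rate"] = 0.2  # equal rates
        nt = RegimenSpec("NT", kill_fraction=0.0, duration=30.0)
        post = simulate_treatment_course(pop, nt, seed=1)
        assert np.allclose(
            post.frequencies.to_numpy(), pop.frequencies.to_numpy(), atol=0
        )

    def test_nt_architecture_correlation_survives_sequencing(self):
        from bctrace import architecture_correlation, normalize_profile

        cfg = SimConfig(seed=6, n_clones=250)
        pop = simulate_population(cfg)
        post = simulate_treatment_course(
            pop, standard_regimens(cfg)["NT"], seed=2
        )
        reads = simulate_sequencing(post, depth=100_000, seed=3)
        observed = normalize_profile(reads["A"])
        assert architecture_correlation(pop.frequencies, observed) > 0.7

    def test_extinction_flagged_not_raised(self):
        cfg = SimConfig(seed=7, n_clones=10, n0_cells=1e3)
        pop = simulate_population(cfg)
        lethal = RegimenSpec("lethal", kill_fraction=0.9999)
        out = simulate_treatment_course(pop, lethal, seed=0)
        if out.total_cells == 0:
            assert not out.relapsed

    def test_higher_survival_never_lowers_expected_outcome(self):
        """Raising one clone's kill survival (all else fixed) increases its
        mean post-course frequency."""
        cfg = SimConfig(seed=8, n_clones=50, n0_cells=1e6)
        pop = simulate_population(cfg)
        clone = pop.clones.index[10]
        means = []
        for boost in (1.0, 20.0):
            pop2 = simulate_population(cfg)
            pop2.clones.loc[clone, "survival_weight"] = boost
            regimen = RegimenSpec("chemo", kill_fraction=0.99)
            freqs = [
                simulate_treatment_course(pop2, regimen, seed=s)
                .frequencies[clone]
                for s in range(30)
            ]
            means.append(np.mean(freqs))
        assert means[1] > means[0]


class TestSequencing:
    def test_column_sums_equal_depth(self):
        pop = simulate_population(SimConfig(seed=10, n_clones=80))
        reads = simulate_sequencing(pop, depth=12_345, n_tech_reps=2, seed=1)
        assert (reads.sum(axis=0) == 12_345).all()

    def test_zero_frequency_clone_gets_no_reads(self):
        pop = simulate_population(SimConfig(seed=11, n_clones=40))
        pop.clones.iloc[0, pop.clones.columns.get_loc("frequency")] = 0.0
        reads = simulate_sequencing(pop, depth=50_000, seed=2)
        assert (reads.iloc[0] == 0).all()

    def test_technical_replicates_pass_concordance_gate(self):
        from bctrace import concordance_filter, normalize_profile

        passes = 0
        for seed in range(20):
            pop = simulate_population(SimConfig(seed=seed, n_clones=250))
            reads = simulate_sequencing(pop, depth=100_000, seed=seed)
            ok, _ = concordance_filter(
                normalize_profile(reads["A"]), normalize_profile(reads["B"])
            )
            passes += ok
        assert passes == 20

    def test_invalid_depth_errors(self):
        pop = simulate_population(SimConfig(seed=0, n_clones=10))
        with pytest.raises(SimulationError):
            simulate_sequencing(pop, depth=0)


class TestXenograft:
    def test_dose_zero_gives_all_negative(self):
        pop = simulate_population(SimConfig(seed=12, n_clones=50))
        design, engraft = simulate_xenograft_lda(pop, [0], 6, seed=1)
        assert design["positive"].iloc[0] == 0
        assert engraft.drop(columns="dose").to_numpy().sum() == 0

    def test_no_lic_clone_never_engrafts(self):
        pop = simulate_population(SimConfig(seed=13, n_clones=50))
        clone = pop.clones.index[0]
        pop.clones.loc[clone, "lic_fraction"] = 0.0
        _, engraft = simulate_xenograft_lda(pop, [10_000, 1000], 8, seed=2)
        assert engraft[clone].sum() == 0

    def test_empty_ladder_errors(self):
        pop = simulate_population(SimConfig(seed=0, n_clones=10))
        with pytest.raises(SimulationError):
            simulate_xenograft_lda(pop, [], 6)


class TestLibraryAndBenchmark:
    def test_library_prefixes_unique(self):
        lib = generate_library(500, seed=3)
        prefixes = {s[:15] for s in lib.sequences}
        assert len(prefixes) == 500

    def test_benchmark_files_byte_identical_across_runs(self, tmp_path):
        cfg = SimConfig(seed=4, n_clones=220)
        make_benchmark_dataset(cfg, out_dir=tmp_path / "a", conditions=("NT",))
        make_benchmark_dataset(cfg, out_dir=tmp_path / "b", conditions=("NT",))
        for name in (
            "library.tsv",
            "counts.tsv",
            "sample_sheet.tsv",
            "lda_design.tsv",
            "engraftment.tsv",
            "manifest.yaml",
        ):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes(), name

    def test_dac_mode_core_is_empty(self, benchmark_full):
        result = analyze_counts(benchmark_full.counts, benchmark_full.sheet)
        assert result.cores["Doxo+Cyta+DAC"].barcodes == frozenset()
        # while standard chemotherapy arms recover the planted set
        planted = frozenset(benchmark_full.manifest["planted_resistant"])
        assert result.cores["Doxo"].barcodes >= planted

    def test_dac_relapses_lose_diversity(self, benchmark_full):
        result = analyze_counts(benchmark_full.counts, benchmark_full.sheet)
        joined = result.diversity.join(result.profile_meta)
        trelapse = joined[joined["timepoint"] == "Trelapse"]
        by_cond = trelapse.groupby("condition")["shannon_h"].mean()
        assert by_cond["Doxo+Cyta+DAC"] < by_cond["Doxo"] < by_cond["NT"]

    def test_nt_self_competitive_index_near_one(self, benchmark):
        result = analyze_counts(benchmark.counts, benchmark.sheet)
        from bctrace import competitive_index

        nt_folds = result.folds["NT"]["E1"]
        ci = competitive_index(nt_folds, nt_folds.copy())
        assert np.allclose(ci.dropna(), 1.0)
        # across distinct NT replicates the deviation is only sampling noise
        half_a = nt_folds.iloc[:, :2]
        ci2 = competitive_index(half_a, nt_folds)
        assert float((ci2.dropna() - 1.0).abs().mean()) < 0.1
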