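"""Synthetic-data generator: determinism, design contracts, ground truth."""

import numpy as np
import pandas as pd
import pytest

from tnscreen.simulate import (
    ConfigurationError,
    CorrelatedBlock,
    PlantedEffect,
    SimulationConfig,
    gen_annotation,
    gen_growth,
    gen_insertions,
    gen_peak_data,
    make_fixture,
)


class TestConfig:
    def test_defaults_mirror_the_study_design(self):
        cfg = SimulationConfig()
        assert cfg.wt_samples_total == 45
        assert cfg.qc_per_experiment == 6
        assert cfg.mutant_replicates == 3
        assert cfg.coding_density == 0.87

    def test_growth_probabilities_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(growth_group_probabilities=(0.5, 0.5, 0.5, 0.5))

    def test_infeasible_annotation_rejected(self):
        cfg = SimulationConfig(genome_length=1000, n_genes=100, coding_density=0.9)
        with pytest.raises(ConfigurationError, match="infeasible"):
            gen_annotation(cfg)


class TestAnnotationGenerator:
    def test_realized_coding_fraction_near_target(self):
        cfg = SimulationConfig(coding_density=0.87, seed=1)
        annotation = gen_annotation(cfg)
        assert 0.85 <= annotation.coding_fraction <= 0.89

    def test_no_genes_gives_empty_annotation(self):
        cfg = SimulationConfig(n_genes=0)
        annotation = gen_annotation(cfg)
        assert len(annotation) == 0
        assert annotation.coding_fraction == 0.0

    def test_same_seed_identical_output(self, small_config):
        a = gen_annotation(small_config)
        b = gen_annotation(small_config)
        assert a.to_frame().equals(b.to_frame())

    def test_flag_fractions_near_configured(self):
        cfg = SimulationConfig(seed=2)
        annotation = gen_annotation(cfg)
        frame = annotation.to_frame()
        n = len(frame)
        # binomial 3-SD bounds around the configured fractions
        for col, p in (("hypothetical", 0.36), ("investigated", 0.11)):
            k = frame[col].sum()
            assert abs(k - n * p) < 3 * np.sqrt(n * p * (1 - p)) + 1


class TestInsertionGenerator:
    def test_positions_within_genome(self):
        cfg = SimulationConfig(genome_length=100, n_genes=0, n_mutants=50, seed=3)
        ann = gen_annotation(cfg)
        mutants = gen_insertions(ann, cfg)
        assert mutants["position"].between(1, 100).all()
        assert mutants["mutant_id"].is_unique

    def test_zero_mutants_empty(self):
        cfg = SimulationConfig(n_mutants=0, n_genes=0)
        mutants = gen_insertions(gen_annotation(cfg), cfg)
        assert len(mutants) == 0

    def test_gene_hit_rate_matches_coding_fraction(self):
        from tnscreen.mapping import map_library

        cfg = SimulationConfig(n_mutants=10_000, seed=4)
        ann = gen_annotation(cfg)
        mutants = gen_insertions(ann, cfg)
        calls = map_library(mutants, ann)
        hit_rate = (calls["category"] == "gene_hit").mean()
        p = ann.coding_fraction
        assert abs(hit_rate - p) < 3 * np.sqrt(p * (1 - p) / len(calls))


class TestGrowthGenerator:
    def test_degenerate_probabilities(self):
        cfg = SimulationConfig(
            n_mutants=50, growth_group_probabilities=(0, 0, 1, 0), seed=5,
            n_genes=0, genome_length=1000,
        )
        mutants = gen_insertions(gen_annotation(cfg), cfg)
        growth = gen_growth(mutants, cfg)
        assert growth.between(80, 120).all()

    def test_group_counts_within_multinomial_bounds(self):
        probs = (0.1, 0.1, 0.75, 0.05)
        cfg = SimulationConfig(
            n_mutants=1000, growth_group_probabilities=probs, seed=6,
            n_genes=0, genome_length=1000,
        )
        from tnscreen.screen import growth_group

        mutants = gen_insertions(gen_annotation(cfg), cfg)
        growth = gen_growth(mutants, cfg)
        counts = growth.map(growth_group).value_counts()
        for group, p in zip(("minimal", "reduced", "similar", "enhanced"), probs):
            k = counts.get(group, 0)
            assert abs(k - 1000 * p) < 3 * np.sqrt(1000 * p * (1 - p))

    def test_empty_mutants(self):
        cfg = SimulationConfig(n_mutants=0, n_genes=0)
        growth = gen_growth(pd.DataFrame({"mutant_id": []}), cfg)
        assert growth.empty


class TestPeakGenerator:
    def test_unknown_effect_targets_rejected_with_offenders(self, small_study):
        cfg = small_study["config"]
        with pytest.raises(ConfigurationError, match="nosuchmutant"):
            gen_peak_data(
                small_study["annotation"],
                small_study["mutants"],
                [PlantedEffect("nosuchmutant", "glutamine", 2.0)],
                cfg,
            )

    def test_sample_design_counts(self, small_study):
        meta = small_study["bundle"].sample_meta
        cfg = small_study["config"]
        counts = meta["sample_type"].value_counts()
        assert counts["wildtype"] == cfg.wt_samples_total
        assert counts["quality_standard"] == cfg.qc_per_experiment * cfg.n_experiments
        assert counts["mutant"] == cfg.n_mutants * cfg.mutant_replicates
        assert counts["blank"] == cfg.blanks_per_experiment * cfg.n_experiments

    def test_every_sample_has_internal_standard(self, small_study):
        bundle = small_study["bundle"]
        with_is = set(
            bundle.peaks.loc[bundle.peaks["label"] == "ribitol", "sample_id"]
        )
        assert with_is == set(bundle.sample_meta.index)

    def test_nonblank_samples_have_od(self, small_study):
        meta = small_study["bundle"].sample_meta
        nonblank = meta[meta["sample_type"] != "blank"]
        assert nonblank["od"].notna().all()
        assert (nonblank["od"] > 0).all()
        assert meta.loc[meta["sample_type"] == "blank", "od"].isna().all()

    def test_no_noise_no_effects_gives_unit_ratios(self):
        """With noise off the whole chain returns mutant/WT ratios of one."""
        from tnscreen.peaks import process_peak_tables
        from tnscreen.qc import wildtype_reference
        from tnscreen.screen import mutant_ratios

        cfg = SimulationConfig(
            genome_length=100_000, n_genes=50, n_mutants=4, n_experiments=1,
            qc_per_experiment=2, n_metabolites=8, noise_cv=1e-12, batch_sd=0.0,
            injection_sd=0.0, missing_rate=0.0, blocks=(), seed=8,
        )
        ann = gen_annotation(cfg)
        mutants = gen_insertions(ann, cfg)
        bundle = gen_peak_data(ann, mutants, [], cfg)
        res = process_peak_tables(bundle.peaks, bundle.sample_meta, bundle.derivative_map)
        ratios = mutant_ratios(res.matrix, wildtype_reference(res.matrix))
        np.testing.assert_allclose(ratios["ratio"], 1.0, rtol=1e-6)
        np.testing.assert_allclose(ratios["log2_ratio_median"], 0.0, atol=1e-6)

    def test_truth_table_records_planted_folds(self, small_study):
        truth = small_study["bundle"].truth
        effect = small_study["effects"][0]
        row = truth[
            (truth["mutant_id"] == effect.mutant_id)
            & (truth["metabolite"] == effect.metabolite)
        ]
        assert row["planted_fold_change"].iloc[0] == pytest.approx(effect.fold_change)

    def test_planted_three_fold_recovered_within_noise_bounds(self):
        """Estimated ratio for a planted 3.0-fold effect lands in [2.4, 3.75]."""
        from tnscreen.peaks import process_peak_tables
        from tnscreen.qc import wildtype_reference
        from tnscreen.screen import mutant_ratios

        cfg = SimulationConfig(
            genome_length=100_000, n_genes=50, n_mutants=6, n_experiments=2,
            qc_per_experiment=2, n_metabolites=20, noise_cv=0.1, blocks=(), seed=9,
        )
        ann = gen_annotation(cfg)
        mutants = gen_insertions(ann, cfg)
        target = mutants["mutant_id"].iloc[0]
        bundle = gen_peak_data(
            ann, mutants, [PlantedEffect(target, "glutamine", 3.0)], cfg
        )
        res = process_peak_tables(bundle.peaks, bundle.sample_meta, bundle.derivative_map)
        ratios = mutant_ratios(res.matrix, wildtype_reference(res.matrix))
        est = ratios.loc[
            (ratios["mutant_id"] == target) & (ratios["metabolite"] == "glutamine"),
            "ratio",
        ].iloc[0]
        assert 2.4 <= est <= 3.75


class TestFixtureIO:
    def test_fixture_bundle_deterministic_on_disk(self, tmp_path):
        cfg = SimulationConfig(
            genome_length=50_000, n_genes=40, n_mutants=4, n_experiments=1,
            qc_per_experiment=2, n_metabolites=6, seed=10,
        )
        p1 = make_fixture(tmp_path / "a", config=cfg, effects=[])
        p2 = make_fixture(tmp_path / "b", config=cfg, effects=[])
        for key in ("annotation", "insertions", "growth", "sample_meta",
                    "derivative_map", "truth", "config"):
            assert p1[key].read_bytes() == p2[key].read_bytes(), key
        peaks1 = sorted((tmp_path / "a" / "peaks").iterdir())
        peaks2 = sorted((tmp_path / "b" / "peaks").iterdir())
        assert [p.name for p in peaks1] == [p.name for p in peaks2]
        for f1, f2 in zip(peaks1, peaks2):
            assert f1.read_bytes() == f2.read_bytes()

    def test_fixture_lists_all_wildtype_samples(self, tmp_path):
        cfg = SimulationConfig(
            genome_length=50_000, n_genes=40, n_mutants=2, n_experiments=2,
            qc_per_experiment=2, n_metabolites=5, seed=12,
        )
        paths = make_fixture(tmp_path / "fx", config=cfg, effects=[])
        meta = pd.read_csv(paths["sample_meta"], sep="\t")
        assert (meta["sample_type"] == "wildtype").sum() == cfg.wt_samples_total
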