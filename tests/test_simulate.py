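"""Generator contracts: determinism, moments, truth separation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methylhet import io
from methylhet.simulate import (
    ConfigError,
    SimulationConfig,
    simulate_amplicon_reads,
    simulate_chip_windows,
    simulate_feature_table,
    simulate_rrbs_pair,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"coverage_mean": -1},
            {"coverage_mean": float("nan")},
            {"dmr_fraction": 1.5},
            {"dmr_effect": -0.1},
            {"baseline_beta_params": (0.0, 1.0)},
            {"site_susceptibility": (0.5, 1.2)},
            {"amplicon_model": "telepathic"},
            {"chip_enrichment_factor": 1.0},
            {"processive_run_mean": 0.5},
        ],
    )
    def test_bad_parameters_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SimulationConfig(**kwargs)


class TestRrbsPair:
    def test_fixed_seed_is_byte_identical(self, small_config, tmp_path):
        import methylhet.methylation as mc

        files = []
        for run in ("x", "y"):
            a, b, _ = simulate_rrbs_pair(small_config)
            pa, pb = tmp_path / f"a{run}.tsv", tmp_path / f"b{run}.tsv"
            mc.write_cpg_table(a, pa)
            mc.write_cpg_table(b, pb)
            files.append((pa.read_bytes(), pb.read_bytes()))
        assert files[0] == files[1]

    def test_truth_not_leaked_into_tables(self, small_config):
        a, b, truth = simulate_rrbs_pair(small_config)
        for table in (a, b):
            assert "is_dmr" not in table.columns
            assert "m_baseline" not in table.columns
        assert "is_dmr" in truth.region_truth.columns

    def test_null_pvalues_approximately_uniform(self):
        from methylhet import dmr

        cfg = SimulationConfig(seed=42, n_regions=2000, dmr_fraction=0.0)
        a, b, truth = simulate_rrbs_pair(cfg)
        res = dmr.call_dmrs(a, b, truth.region_truth)
        p = res.loc[res["status"] == "ok", "p_value"].to_numpy()
        # CDF comparison at a grid rather than a full KS test: with 10
        # CpGs per region the t reference is itself an approximation
        for cut in (0.1, 0.25, 0.5, 0.75):
            assert abs((p < cut).mean() - cut) < 0.04

    def test_zero_effect_labels_exist_but_data_is_null(self):
        cfg = SimulationConfig(seed=3, n_regions=600, dmr_fraction=0.5,
                               dmr_effect=0.0)
        a, b, truth = simulate_rrbs_pair(cfg)
        planted = truth.region_truth["is_dmr"]
        assert 0 < planted.sum() < len(planted)
        from methylhet import dmr

        res = dmr.call_dmrs(a, b, truth.region_truth)
        p = res["p_value"].to_numpy()
        rate_in = (p[planted] < 0.05).mean()
        rate_out = (p[~planted] < 0.05).mean()
        assert abs(rate_in - rate_out) < 0.05

    def test_coverage_mean_matches_request(self):
        cfg = SimulationConfig(seed=8, n_regions=1000)
        a, _, _ = simulate_rrbs_pair(cfg)
        cov = a["total_count"].to_numpy()
        se = cov.std() / np.sqrt(cov.size)
        # NB truncation at 1 nudges the mean upward by < 0.1 at mu=30
        assert abs(cov.mean() - 30.0) < 3 * se + 0.1


class TestAmpliconReads:
    def test_all_zero_susceptibility(self):
        cfg = SimulationConfig(seed=1, site_susceptibility=(0.0,) * 10)
        reads, _ = simulate_amplicon_reads(cfg, 100)
        assert (reads["pattern"] == "U" * 10).all()

    def test_all_one_susceptibility(self):
        cfg = SimulationConfig(seed=1, site_susceptibility=(1.0,) * 10)
        reads, _ = simulate_amplicon_reads(cfg, 100)
        assert (reads["pattern"] == "M" * 10).all()

    def test_distributive_per_site_frequencies(self):
        cfg = SimulationConfig(seed=2)
        reads, truth = simulate_amplicon_reads(cfg, 50_000)
        from methylhet.epiallele import count_epialleles

        summary = count_epialleles(reads)
        assert np.all(np.abs(summary.per_site_meth
                             - truth.per_site_probability) < 0.01)

    def test_rejects_nonpositive_reads(self, small_config):
        with pytest.raises(ConfigError):
            simulate_amplicon_reads(small_config, 0)

    def test_deterministic(self, small_config):
        r1, _ = simulate_amplicon_reads(small_config, 500)
        r2, _ = simulate_amplicon_reads(small_config, 500)
        pd.testing.assert_frame_equal(r1, r2)

    def test_processive_mean_methylation_tracks_susceptibility(self):
        cfg = SimulationConfig(seed=4, amplicon_model="processive")
        reads, truth = simulate_amplicon_reads(cfg, 20_000)
        mean_meth = reads["pattern"].str.count("M").mean() / 50
        assert abs(mean_meth - truth.per_site_probability.mean()) < 0.08


class TestChipWindows:
    def test_mixture_mean(self):
        cfg = SimulationConfig(seed=6)  # lambda 10, factor 6, fraction 0.05
        table, _ = simulate_chip_windows(cfg, 10_000)
        counts = table["count"].to_numpy()
        se = counts.std() / np.sqrt(counts.size)
        assert abs(counts.mean() - 12.5) < 3 * se

    def test_empty_output(self, small_config):
        table, truth = simulate_chip_windows(small_config, 0)
        assert table.empty
        assert truth.window_is_enriched.size == 0

    def test_no_enrichment_gives_nominal_false_positive_rate(self):
        cfg = SimulationConfig(seed=9, chip_enriched_fraction=0.0,
                               chip_lambda_background=200.0)
        table, _ = simulate_chip_windows(cfg, 10_000)
        from methylhet.chromatin import poisson_enrichment

        enr = poisson_enrichment(table["count"].to_numpy())
        # discrete survival p-values are conservative, hence <= alpha + MC
        assert (enr.p_values < 0.05).mean() <= 0.065

    def test_truth_labels_match_table_length(self, small_config):
        table, truth = simulate_chip_windows(small_config, 123)
        assert truth.window_is_enriched.size == len(table)
        assert "enriched" not in table.columns


class TestFeatureTable:
    def test_deterministic(self, small_config):
        t1 = simulate_feature_table(small_config, 500)
        t2 = simulate_feature_table(small_config, 500)
        pd.testing.assert_frame_equal(t1, t2)

    def test_correlation_structure(self):
        cfg = SimulationConfig(seed=12)
        t = simulate_feature_table(cfg, 20_000)
        assert t["h3k4me3"].corr(t["dnase"]) > 0.3
        assert t["h3k4me3"].corr(t["h3k27me3"]) < -0.2
        assert t["h3k4me3"].corr(t["control_methylation"]) < -0.2

    def test_control_methylation_below_cutoff(self):
        t = simulate_feature_table(SimulationConfig(seed=1), 5000)
        assert (t["control_methylation"] < 0.2).all()

    def test_zero_weights_decouple_labels(self):
        cfg = SimulationConfig(seed=2)
        t = simulate_feature_table(cfg, 20_000, label_weights={},
                                   intercept=-1.0)
        # labels independent of every feature
        for col in ("h3k4me3", "dnase", "control_methylation"):
            r = np.corrcoef(t[col], t["label"])[0, 1]
            assert abs(r) < 0.03

    def test_unknown_weight_name_rejected(self, small_config):
        with pytest.raises(ConfigError):
            simulate_feature_table(small_config, 10,
                                   label_weights={"nope": 1.0})


class TestTruthSidecar:
    def test_round_trip(self, small_config, tmp_path):
        _, _, truth = simulate_rrbs_pair(small_config)
        path = tmp_path / "truth.json"
        io.write_truth(truth, path)
        back = io.read_truth(path)
        assert back["config"]["seed"] == small_config.seed
        assert back["region_truth"]["is_dmr"] == \
            truth.region_truth["is_dmr"].tolist()
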