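"""The synthetic-experiment generator and its ground-truth contract."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spikefill.kinetics import logistic_weight
from spikefill.novel import evaluate_all
from spikefill.simulate import (
    SimulationConfig,
    simulate_counts,
    simulate_length_histograms,
    simulate_novel_candidates,
    simulate_targets,
    simulate_weights,
)
from spikefill.normalization import apply_floor, length_distribution, tpm_normalize


class TestConfig:
    def test_invalid_fields_named(self):
        with pytest.raises(ValueError, match="de_fraction"):
            SimulationConfig(seed=1, de_fraction=1.5).validate()
        with pytest.raises(ValueError, match="library_size_range"):
            SimulationConfig(seed=1, library_size_range=(10, 5)).validate()
        with pytest.raises(ValueError, match="dispersion"):
            SimulationConfig(seed=1, dispersion=-0.1).validate()
        with pytest.raises(ValueError, match="kinetics_superior"):
            SimulationConfig(seed=1, kinetics_superior=(0, 1, 1)).validate()


class TestCounts:
    def test_same_seed_identical_output(self):
        cfg = SimulationConfig(seed=42, n_mirnas=50)
        c1, m1, t1 = simulate_counts(cfg)
        c2, m2, t2 = simulate_counts(cfg)
        pd.testing.assert_frame_equal(c1, c2)
        assert m1 == m2 and t1.de_log2fc == t2.de_log2fc

    def test_design_shape_and_metadata(self):
        cfg = SimulationConfig(seed=5, n_mirnas=30)
        counts, meta, _ = simulate_counts(cfg)
        assert counts.shape == (30, 10)
        assert sum(m.condition == "superior" for m in meta) == 5
        assert sorted({m.stage_daf for m in meta}) == [10, 15, 21, 27, 35]
        for m in meta:
            assert counts[m.library_id].sum() <= m.total_clean_reads

    def test_null_config_has_empty_truth(self):
        cfg = SimulationConfig(seed=7, n_mirnas=40, de_fraction=0.0)
        _, _, truth = simulate_counts(cfg)
        assert truth.de_log2fc == {}
        assert truth.de_label("mir0001", 10) == 0.0

    def test_spiked_fold_change_recovered_empirically(self):
        # fc = +2 at high baseline: empirical log2 TPM ratio within +-0.3
        cfg = SimulationConfig(
            seed=9, n_mirnas=500, de_fraction=1.0, de_log2fc_range=(2.0, 2.0),
            dispersion=0.0, baseline_log_tpm_mean=6.0, baseline_log_tpm_sd=0.3,
        )
        counts, meta, truth = simulate_counts(cfg)
        expr = apply_floor(tpm_normalize(counts, meta))
        positive = [e for e, fc in truth.de_log2fc.items() if fc > 0]
        sup_cols = [m.library_id for m in meta if m.condition == "superior"]
        inf_cols = [m.library_id for m in meta if m.condition == "inferior"]
        ratios = np.log2(expr.loc[positive, inf_cols].mean(axis=1)
                         / expr.loc[positive, sup_cols].mean(axis=1))
        assert abs(ratios.mean() - 2.0) < 0.3


class TestWeights:
    def test_zero_noise_is_exact_logistic(self):
        cfg = SimulationConfig(seed=3, weight_noise_sd=0.0)
        sup, inf = simulate_weights(cfg)
        K, a, b = cfg.kinetics_superior
        np.testing.assert_allclose(
            sup.weights, logistic_weight(np.array(sup.times), K, a, b)
        )

    def test_superior_peak_rate_exceeds_inferior(self):
        cfg = SimulationConfig(seed=3)
        Ks, _, bs = cfg.kinetics_superior
        Ki, _, bi = cfg.kinetics_inferior
        assert Ks * bs / 4 > Ki * bi / 4

    def test_weights_non_negative_across_seeds(self):
        for seed in range(30):
            sup, inf = simulate_weights(SimulationConfig(seed=seed))
            assert min(sup.weights) >= 0 and min(inf.weights) >= 0


class TestTargets:
    def test_zero_noise_slope_minus_one_gives_spearman_minus_one(self):
        cfg = SimulationConfig(seed=2, n_mirnas=10, target_noise_sd=0.0)
        counts, meta, truth = simulate_counts(cfg)
        expr = apply_floor(tpm_normalize(counts, meta))
        targets, coupling = simulate_targets(cfg, expr, truth=truth)
        assert truth.coupling == coupling
        for mirna, target in list(coupling.items())[:5]:
            rho = stats.spearmanr(expr.loc[mirna], targets.loc[target]).statistic
            assert rho == pytest.approx(-1.0)

    def test_zero_slope_decouples(self):
        cfg = SimulationConfig(seed=2, n_mirnas=40, target_coupling_slope=0.0,
                               target_noise_sd=0.5)
        counts, meta, _ = simulate_counts(cfg)
        expr = apply_floor(tpm_normalize(counts, meta))
        targets, coupling = simulate_targets(cfg, expr)
        rs = [
            stats.pearsonr(np.log2(expr.loc[m]), np.log2(targets.loc[t])).statistic
            for m, t in coupling.items()
        ]
        assert abs(np.mean(rs)) < 0.25


class TestLengthsAndNovel:
    def test_pooled_length_mix_matches_configured_weights(self):
        cfg = SimulationConfig(seed=8)
        hists = simulate_length_histograms(cfg, reads_per_library=50_000)
        _, pooled = length_distribution(hists)
        assert pooled.proportions[24] == pytest.approx(0.5828, abs=0.01)
        assert pooled.proportions[21] == pytest.approx(0.1830, abs=0.01)
        assert pooled.proportions[24] > pooled.proportions[21]

    def test_candidate_truth_agrees_with_evaluator(self):
        cfg = SimulationConfig(seed=13)
        candidates, flags = simulate_novel_candidates(cfg, n_candidates=40)
        decisions = evaluate_all(candidates, n_libraries=10)
        for d in decisions:
            assert d.evidence_codes == flags[d.candidate_id]
            assert d.accepted == bool(flags[d.candidate_id])
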