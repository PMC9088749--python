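"""Synthetic-data generator: determinism, area conservation, recovery."""

import numpy as np
import pytest

from saffronms.fragments import match_msms, rank_candidates
from saffronms.compounds import find
from saffronms.peaks import integrate_cluster, snr_filter
from saffronms.quantify import (
    estimate_adulteration,
    fit_calibration,
    molar_ratio,
    QuantInput,
)
from saffronms.simulate import (
    DEFAULT_LEVELS,
    SimulationConfig,
    molar_ratios_from_series,
    simulate_adulteration_series,
    simulate_ms1,
    simulate_msms,
)


class TestSimulateMs1:
    def test_seed_determinism(self):
        cfg = SimulationConfig.for_composition({"C-2": 1.0, "curcumin": 0.5},
                                               seed=9)
        a = simulate_ms1(cfg).to_dataframe()
        b = simulate_ms1(cfg).to_dataframe()
        assert a.equals(b)

    def test_different_seeds_differ(self):
        base = {"C-2": 1.0}
        a = simulate_ms1(SimulationConfig.for_composition(base, seed=1))
        b = simulate_ms1(SimulationConfig.for_composition(base, seed=2))
        assert a.mzs != b.mzs

    def test_zero_jitter_hits_theoretical_mz(self, registry):
        cfg = SimulationConfig.for_composition(
            {"C-3": 1.0}, seed=0, ppm_jitter=0.0, n_noise_peaks=0,
            adduct_weights=(("M+Na", 1.0),))
        spectrum = simulate_ms1(cfg)
        c3 = find(registry, "C-3")[0]
        assert min(abs(m - c3.mz("M+Na")) for m in spectrum.mzs) < 1e-6

    def test_area_conservation_per_envelope(self):
        cfg = SimulationConfig.for_composition(
            {"C-2": 2.0, "C-3": 1.0}, seed=0, ppm_jitter=0.0,
            n_noise_peaks=0, adduct_weights=(("M+Na", 1.0),))
        spectrum = simulate_ms1(cfg)
        total = sum(p.effective_area for p in spectrum)
        assert total == pytest.approx(3.0 * cfg.base_area, abs=1e-6)

    def test_turmeric_triplet_present(self):
        cfg = SimulationConfig.for_composition(
            {"C-2": 1.0, "curcumin": 0.02, "demethoxycurcumin": 0.02,
             "bisdemethoxycurcumin": 0.02}, seed=4, n_noise_peaks=0)
        mzs = simulate_ms1(cfg).mzs
        for target in (369.13, 339.12, 309.11):
            assert any(abs(m - target) < 0.05 for m in mzs)

    def test_unknown_compound_rejected(self):
        cfg = SimulationConfig.for_composition({"unobtainium": 1.0})
        with pytest.raises(ValueError):
            simulate_ms1(cfg)


class TestSimulateMsms:
    def test_picrocrocin_diagnostics_present(self):
        cfg = SimulationConfig(seed=0, ppm_jitter=0.0)
        mzs = simulate_msms("picrocrocin", "M+K", cfg).mzs
        for target in (351.1, 337.1, 309.1, 225.1, 207.1):
            assert any(abs(m - target) <= 0.3 for m in mzs)

    def test_full_dropout_gives_empty_list(self):
        cfg = SimulationConfig(seed=0, msms_dropout=1.0)
        assert len(simulate_msms("picrocrocin", "M+K", cfg)) == 0

    def test_c7_topology_classified_in_all_seeds(self, registry):
        from saffronms.fragments import GlycoStructure
        from saffronms.compounds import CROCETIN

        # the (4,3) ion masses are a strict subset of (6,1)'s, so the true
        # topology must never score worse, and must win outright whenever
        # any chain-length-discriminating ion (B5/C5/B6/C6) survives dropout
        good = GlycoStructure(CROCETIN, 6, 1, "crocetin")
        bad = GlycoStructure(CROCETIN, 4, 3, "crocetin")
        wins = ties = 0
        for seed in range(100):
            cfg = SimulationConfig(seed=seed, msms_dropout=0.3, ppm_jitter=2.0)
            spectrum = simulate_msms("C-7", "M+Na", cfg)
            a = match_msms(spectrum.mzs, good, "M+Na")
            b = match_msms(spectrum.mzs, bad, "M+Na")
            assert a.n_matched >= b.n_matched
            wins += a.n_matched > b.n_matched
            ties += a.n_matched == b.n_matched
        assert wins >= 95 and wins + ties == 100


class TestAdulterationSeries:
    def test_design_shape(self):
        df, truth = simulate_adulteration_series()
        assert len(df) == len(DEFAULT_LEVELS) * 3
        assert set(df.columns) == {"level_percent", "replicate", "ICA_C2",
                                   "ICA_C3", "ICA_C4", "ICA_curcumin"}

    def test_zero_noise_recovers_effective_line_exactly(self):
        df, truth = simulate_adulteration_series(area_sigma=0.0)
        mr = molar_ratios_from_series(df)
        model = fit_calibration(mr["level_percent"], mr["MR_S"])
        assert model.slope == pytest.approx(truth["effective_slope"], abs=1e-12)
        assert model.intercept == pytest.approx(truth["effective_intercept"],
                                                abs=1e-12)

    def test_mr_decreases_with_adulteration(self):
        df, _ = simulate_adulteration_series(area_sigma=0.0)
        mr = molar_ratios_from_series(df).groupby("level_percent")["MR_S"].mean()
        assert mr.is_monotonic_decreasing

    def test_linearity_at_study_noise(self):
        """R^2 >= 0.99 in >= 90/100 seeded series at the default noise."""
        good = 0
        for seed in range(100):
            df, _ = simulate_adulteration_series(
                cfg=SimulationConfig(seed=seed))
            mr = molar_ratios_from_series(df)
            model = fit_calibration(mr["level_percent"], mr["MR_S"])
            good += model.r2 >= 0.99
        assert good >= 90

    def test_invalid_levels_rejected(self):
        with pytest.raises(ValueError):
            simulate_adulteration_series(levels=[0.0, 120.0])


class TestEndToEndRecovery:
    def test_true_level_inside_ci_in_most_runs(self):
        """Calibrate, then quantify a 12.6% sample: CI covers truth >= 90%."""
        true_level = 12.60
        covered = 0
        n_runs = 50
        for seed in range(n_runs):
            df, _ = simulate_adulteration_series(
                cfg=SimulationConfig(seed=1000 + seed))
            mr = molar_ratios_from_series(df)
            model = fit_calibration(mr["level_percent"], mr["MR_S"])
            # three replicate measurements of the unknown sample
            sample_df, _ = simulate_adulteration_series(
                levels=[true_level], replicates=3,
                cfg=SimulationConfig(seed=5000 + seed))
            sample_mr = molar_ratios_from_series(sample_df)["MR_S"].mean()
            est = estimate_adulteration(sample_mr, model, n_sample=3)
            covered += est.ci95[0] <= true_level <= est.ci95[1]
        assert covered >= 0.9 * n_runs

    def test_spectrum_level_pipeline_recovers_level(self):
        """Full route: spectra -> ICA -> MR -> calibration -> estimate."""
        def mr_from_spectrum(level, seed):
            scale = 1.0 - level / 100.0
            comp = {"C-2": 5.0 * scale, "C-3": 3.0 * scale, "C-4": 2.0 * scale,
                    "picrocrocin": 0.5 * scale, "curcumin": 0.105 * level}
            comp = {k: v for k, v in comp.items() if v > 0}
            cfg = SimulationConfig.for_composition(
                comp, seed=seed, ppm_jitter=1.0, n_noise_peaks=20)
            spectrum = snr_filter(simulate_ms1(cfg), 200)
            icas = []
            for name, mz in (("C-2", 675.2623), ("C-3", 837.3151),
                             ("C-4", 999.3680)):
                icas.append(integrate_cluster(spectrum, mz, tol=0.05).ica)
            # the 369.13 cluster is the unresolved curcumin/picrocrocin-K
            # isobar pair: integrate both envelopes into the standard area
            ica_t = integrate_cluster(spectrum, 369.1310, tol=0.0015).ica
            if level > 0:
                ica_t += integrate_cluster(spectrum, 369.1333, tol=0.0015).ica
            return molar_ratio(QuantInput(tuple(icas), ica_t, level_percent=level))

        levels, responses = [], []
        for i, level in enumerate([0.0, 5.0, 10.0, 20.0, 30.0]):
            for rep in range(2):
                levels.append(level)
                responses.append(mr_from_spectrum(level, seed=10 * i + rep))
        model = fit_calibration(levels, responses)
        assert model.r2 > 0.98
        sample_mr = mr_from_spectrum(12.6, seed=777)
        est = estimate_adulteration(sample_mr, model)
        assert est.level_percent == pytest.approx(12.6, abs=2.5)
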