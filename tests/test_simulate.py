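"""Simulator unit and property tests against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from sphase import (
    SimConfig, simulate_time_course, closed_form_rm, ConfigurationError,
)

from conftest import ideal_config


def numeric_rm_oracle(u: float, n_grid: int = 200_001) -> float:
    """Mean cohort position by brute-force integration of min(f + u, 1)
    over initial replicated fractions f uniform on (0, 1)."""
    f = np.linspace(0.0, 1.0, n_grid)
    return float(np.trapezoid(np.minimum(f + u, 1.0), f))


class TestClosedFormRM:
    @pytest.mark.parametrize("u, expected", [(0.0, 0.5), (1.0, 1.0), (0.5, 0.875)])
    def test_stated_values(self, u, expected):
        assert closed_form_rm(u) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("u", [0.0, 0.1, 0.25, 0.5, 0.8, 1.0])
    def test_matches_numeric_integration(self, u):
        assert closed_form_rm(u) == pytest.approx(numeric_rm_oracle(u), abs=1e-9)

    @pytest.mark.parametrize("u", [-0.01, 1.01, np.nan])
    def test_domain_error(self, u):
        with pytest.raises(ValueError):
            closed_form_rm(u)


class TestConfigValidation:
    @pytest.mark.parametrize("bad", [
        {"t_s": 0.0}, {"t_g1": -1.0}, {"t_g2m": float("nan")},
        {"pulse_len": -0.5}, {"slow_fraction": 1.5}, {"debris_fraction": -0.1},
        {"dapi_cv": -0.01}, {"slow_factor": 0.5}, {"n_cells": 0},
        {"chase_times": (1.0, 2.0)}, {"chase_times": (0.0, 2.0, 1.0)},
        {"age_distribution": "bimodal"},
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            SimConfig(**bad)


class TestCohortKinetics:
    def test_t0_cohort_uniform_between_2c_and_4c(self):
        cfg = ideal_config()
        table = simulate_time_course(cfg).entries[0]
        lab = table.data[table.data.truth_labeled]
        dapi = lab.dapi.to_numpy()
        lo, hi = 2 * cfg.dapi_gain, 4 * cfg.dapi_gain
        assert dapi.min() > lo and dapi.max() < hi
        # uniformity: mean at midpoint, variance of U(lo, hi)
        n = len(dapi)
        assert dapi.mean() == pytest.approx((lo + hi) / 2,
                                            abs=3 * (hi - lo) / np.sqrt(12 * n))
        assert dapi.std() == pytest.approx((hi - lo) / np.sqrt(12), rel=0.05)

    def test_cohort_all_4c_after_ts(self):
        cfg = ideal_config(chase_times=(0.0, 2.7, 4.0))
        for table in simulate_time_course(cfg).entries[1:]:
            lab = table.data[table.data.truth_labeled & ~table.data.truth_divided]
            assert (lab.dapi == 4 * cfg.dapi_gain).all()

    @pytest.mark.parametrize("t", [0.5, 1.35, 2.0])
    def test_cohort_mean_matches_closed_form(self, t):
        cfg = ideal_config(chase_times=(0.0, t), n_cells=100_000)
        table = simulate_time_course(cfg).entries[1]
        lab = table.data[table.data.truth_labeled]
        rm = (lab.dapi.mean() - 2 * cfg.dapi_gain) / (2 * cfg.dapi_gain)
        n = len(lab)
        mc_se = lab.dapi.std() / (2 * cfg.dapi_gain) / np.sqrt(n)
        assert rm == pytest.approx(closed_form_rm(t / cfg.t_s), abs=3 * mc_se)


class TestPopulationBookkeeping:
    def test_event_count_conservation_without_division(self):
        cfg = SimConfig(divide_labeled=False, n_cells=10_000, seed=3,
                        chase_times=(0.0, 2.0, 5.0))
        d = cfg.debris_fraction
        expected = 10_000 + round(10_000 * d / (1 - d))
        for table in simulate_time_course(cfg):
            assert abs(len(table) - expected) <= 1

    def test_nondecreasing_counts_with_division(self):
        cfg = SimConfig(n_cells=10_000, seed=3)
        counts = [int((~t.data.truth_debris).sum())
                  for t in simulate_time_course(cfg)]
        assert counts == sorted(counts)
        assert counts[-1] > counts[0]  # divisions occurred

    def test_noise_free_dna_in_2c_4c_range(self):
        cfg = SimConfig(dapi_cv=0.0, n_cells=10_000, seed=5,
                        chase_times=(0.0, 3.0))
        for table in simulate_time_course(cfg):
            live = table.data[~table.data.truth_debris]
            assert live.dapi.min() >= 2 * cfg.dapi_gain
            assert live.dapi.max() <= 4 * cfg.dapi_gain

    def test_bitwise_determinism(self):
        cfg = SimConfig(n_cells=5_000, seed=42, residual_rate=0.05,
                        slow_fraction=0.1, slow_factor=2.0)
        a = simulate_time_course(cfg)
        b = simulate_time_course(cfg)
        for ta, tb in zip(a, b):
            pd.testing.assert_frame_equal(ta.data, tb.data)

    def test_division_halves_label_and_returns_to_2c(self):
        cfg = ideal_config(divide_labeled=True, chase_times=(0.0, 6.5),
                           t_g1=5.0, n_cells=20_000)
        table = simulate_time_course(cfg).entries[1]
        d = table.data
        div = d[d.truth_divided & d.truth_labeled]
        assert len(div) > 0
        assert (div.dapi == 2 * cfg.dapi_gain).all()
        # unit saturating label at pulse_len=0, halved once at division
        assert np.allclose(div.label, cfg.label_background + cfg.label_gain * 0.5)


class TestResidualArm:
    @pytest.mark.parametrize("rate", [0.01, 0.1])
    def test_arm_10_to_100_fold_dimmer(self, rate):
        cfg = SimConfig(residual_rate=rate, seed=5, n_cells=30_000)
        for table in simulate_time_course(cfg):
            if not 1 <= table.time_h <= 4:
                continue
            d = table.data
            arm = d[~d.truth_labeled & d.truth_s_fraction.notna()]
            cohort = d[d.truth_labeled & ~d.truth_divided]
            ratio = np.median(cohort.label) / np.median(arm.label)
            assert 10 <= ratio <= 100


class TestSlowAndArrested:
    def test_arrested_cells_freeze_mid_s(self):
        cfg = ideal_config(slow_fraction=0.5, slow_factor=float("inf"),
                           chase_times=(0.0, 2.0, 5.0), n_cells=20_000)
        tables = simulate_time_course(cfg).entries

        def labeled_in_s(table):
            d = table.data
            return d[d.truth_labeled & d.truth_s_fraction.notna()].truth_s_fraction
        # at 5 h (> t_s) the only labeled cells still in S are the arrested
        # ones, frozen at the replicated fraction they held at 2 h
        stuck = labeled_in_s(tables[2])
        assert len(stuck) > 0
        assert (stuck < 1.0).all()
        assert set(np.round(stuck, 12)) <= set(np.round(labeled_in_s(tables[1]), 12))

    def test_exponential_growth_age_option(self):
        cfg = ideal_config(age_distribution="exponential_growth")
        table = simulate_time_course(cfg).entries[0]
        lab = table.data[table.data.truth_labeled]
        # younger cells over-represented: cohort mean sits below midpoint
        assert 2.8 * cfg.dapi_gain < lab.dapi.mean() < 3.0 * cfg.dapi_gain
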