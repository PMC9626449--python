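"""Monte Carlo engine: determinism, ordering, linearity, dominance."""

import copy

import numpy as np
import pandas as pd
import pytest

from rorqualrisk.exposure import total_exposure
from rorqualrisk.morphometrics import AllometryCoefficients
from rorqualrisk.pipeline import build_scenario_config
from rorqualrisk.scenarios import (
    PreyConfig,
    ScenarioConfig,
    SpeciesPools,
    _replicate_rng,
    compare_scenarios,
    draw_whale,
    run_scenario,
    scenario_table,
)
from rorqualrisk.synthetic import PlasticProfile
from rorqualrisk.tagproc import DEPTH_BINS, DielLungeRates


def degenerate_config(n_replicates=5) -> ScenarioConfig:
    """All pools collapse to point masses: no randomness left."""
    pool = SpeciesPools(
        rate_pool=[DielLungeRates("d0", 10.0, 5.0, 2.0, 12.0, 2.0, 10.0)],
        depth_mixture={b: (1.0 if b == "deep" else 0.0) for b in DEPTH_BINS},
        lengths=np.array([22.0]),
        profiles=[PlasticProfile({b: 3.0 for b in DEPTH_BINS})],
    )
    coeffs = {
        ("blue", "engulfment_volume_m3"): AllometryCoefficients(
            "blue", "engulfment_volume_m3", np.log10(80.0), 0.0
        ),
        ("blue", "body_mass_kg"): AllometryCoefficients(
            "blue", "body_mass_kg", 5.0, 0.0
        ),
    }
    return ScenarioConfig(
        pools={"blue": pool},
        prey={"krill": PreyConfig(0.15, 0.0, 1e-4)},
        coeff_table=coeffs,
        n_replicates=n_replicates,
        seed=42,
    )


class TestDrawWhale:
    def test_degenerate_pools_identical_draws(self):
        cfg = degenerate_config()
        draws = [draw_whale(cfg, "blue", "krill", _replicate_rng(1, "blue", "krill", i))
                 for i in range(5)]
        assert all(d == draws[0] for d in draws)

    def test_seeded_determinism(self):
        cfg = degenerate_config()
        a = draw_whale(cfg, "blue", "krill", _replicate_rng(7, "blue", "krill", 0))
        b = draw_whale(cfg, "blue", "krill", _replicate_rng(7, "blue", "krill", 0))
        assert a == b

    def test_bootstrapped_daily_count_mean(self, tiny_scenario_config):
        """The mean of 10,000 bootstrapped daily lunge counts lands within
        3 standard errors of the pool's analytic mean."""
        cfg = tiny_scenario_config
        pool = cfg.pools["blue:krill"]
        analytic = []
        for rec in pool.rate_pool:
            h = np.array([rec.hours_day, rec.hours_twilight, rec.hours_night])
            r = np.array([rec.rate_day, rec.rate_twilight, rec.rate_night])
            analytic.append(float(np.dot(r, 24.0 * h / h.sum())))
        draws = np.array(
            [draw_whale(cfg, "blue", "krill", _replicate_rng(3, "blue", "krill", i)).f
             for i in range(10_000)]
        )
        se = np.std(analytic) / np.sqrt(10_000)
        # the multinomial rounding of f adds at most 0.5 lunges of bias
        assert abs(draws.mean() - np.mean(analytic)) < 3 * se + 0.5

    def test_missing_pool_is_error(self):
        with pytest.raises(KeyError, match="fin"):
            draw_whale(degenerate_config(), "fin", "krill", np.random.default_rng(0))


class TestRunScenario:
    def test_degenerate_collapses_to_deterministic_value(self):
        """With point-mass pools the summary's median, Q1 and Q3 all equal
        the deterministic exposure-equation evaluation."""
        cfg = degenerate_config()
        cell = run_scenario(cfg, "blue", "krill", "medium")
        inputs = draw_whale(cfg, "blue", "krill", _replicate_rng(cfg.seed, "blue", "krill", 0))
        expected = total_exposure(inputs).pieces_total
        s = cell.summary()
        row = s[s["statistic"] == "pieces_total"].iloc[0]
        assert row["median"] == row["q1"] == row["q3"] == pytest.approx(expected)

    def test_quantile_ordering_and_additivity(self, tiny_scenario_config):
        cell = run_scenario(tiny_scenario_config, "blue", "krill", "medium")
        s = cell.summary()
        assert (s["q1"] <= s["median"]).all() and (s["median"] <= s["q3"]).all()
        rep = cell.replicates
        np.testing.assert_allclose(
            rep["pieces_total"], rep["pieces_from_water"] + rep["pieces_from_prey"], rtol=0
        )
        assert (rep[["pieces_from_water", "pieces_from_prey"]] >= 0).all().all()

    def test_stochastic_dominance_across_levels(self, tiny_scenario_config):
        """Matched replicate substreams make risk ordered replicate-by-
        replicate: low <= medium <= high."""
        cells = {lv: run_scenario(tiny_scenario_config, "blue", "krill", lv)
                 for lv in ("low", "medium", "high")}
        low = cells["low"].replicates["pieces_total"].values
        med = cells["medium"].replicates["pieces_total"].values
        high = cells["high"].replicates["pieces_total"].values
        assert (low <= med).all() and (med <= high).all()
        assert np.median(med) >= np.median(low)

    def test_replicate_invariant_to_count(self, tiny_scenario_config):
        cfg_small = copy.copy(tiny_scenario_config)
        cfg_small.n_replicates = 10
        small = run_scenario(cfg_small, "blue", "krill", "medium").replicates
        big = run_scenario(tiny_scenario_config, "blue", "krill", "medium").replicates
        pd.testing.assert_frame_equal(small, big.iloc[:10].reset_index(drop=True))

    def test_krill_trophic_fraction_dominates(self, tiny_scenario_config):
        """Under medium krill parameters, most replicates take >90% of
        their plastic via prey."""
        rep = run_scenario(tiny_scenario_config, "blue", "krill", "medium").replicates
        frac = rep["pieces_from_prey"] / rep["pieces_total"]
        assert np.median(frac) > 0.9

    def test_water_term_linear_in_concentration(self, tiny_scenario_config):
        """Scaling every concentration by k scales the water term by k
        exactly, replicate by replicate (matched seeds)."""
        base = run_scenario(tiny_scenario_config, "blue", "krill", "medium").replicates
        scaled_cfg = copy.deepcopy(tiny_scenario_config)
        for prof in scaled_cfg.pools["blue:krill"].profiles:
            for b in prof.concentrations:
                prof.concentrations[b] *= 3.0
        scaled = run_scenario(scaled_cfg, "blue", "krill", "medium").replicates
        np.testing.assert_allclose(
            scaled["pieces_from_water"], 3.0 * base["pieces_from_water"], rtol=1e-12
        )

    def test_prey_term_linear_in_fo(self, tiny_scenario_config):
        """Scaling FO by k scales the prey term by k exactly under matched
        seeds; the high/medium krill FO ratio is 0.50/0.06."""
        base = run_scenario(tiny_scenario_config, "blue", "krill", "medium").replicates
        fo_cfg = copy.deepcopy(tiny_scenario_config)
        fo_cfg.retention["high"] = fo_cfg.retention["medium"]  # isolate FO
        high = run_scenario(fo_cfg, "blue", "krill", "high").replicates
        ratio = 0.50 / 0.06
        np.testing.assert_allclose(
            high["pieces_from_prey"], ratio * base["pieces_from_prey"], rtol=1e-12
        )


class TestScenarioTable:
    def test_row_set_and_determinism(self, tiny_scenario_config):
        s1 = scenario_table(tiny_scenario_config, levels=("medium",))
        s2 = scenario_table(tiny_scenario_config, levels=("medium",))
        pd.testing.assert_frame_equal(s1.table, s2.table)
        per_cell = s1.table.groupby(["species", "prey_type", "level"]).size()
        assert (per_cell == 7).all()  # the seven statistic rows

    def test_missing_combination_warns_not_raises(self, tiny_scenario_config, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="rorqualrisk.scenarios"):
            s = scenario_table(
                tiny_scenario_config, combinations=[("fin", "krill"), ("blue", "krill")]
            )
        assert "fin" in caplog.text
        assert set(s.table["species"]) == {"blue"}

    def test_compare_scenarios_ordering(self, tiny_scenario_config):
        summary = scenario_table(tiny_scenario_config)
        comp = compare_scenarios(summary)
        blue = comp[(comp["species"] == "blue") & (comp["prey_type"] == "krill")]
        assert list(blue["level"]) == ["low", "medium", "high"]
        assert (blue["median"].diff().dropna() > 0).all()
        assert (blue["ratio_to_previous_level"].dropna() > 1).all()

    def test_identical_levels_unit_ratio(self):
        cfg = degenerate_config()
        cfg.retention = {lv: 0.5 for lv in cfg.retention}
        cfg.fo_table = {"krill": {lv: 0.06 for lv in cfg.fo_table["krill"]}}
        comp = compare_scenarios(scenario_table(cfg))
        assert comp["ratio_to_previous_level"].dropna().tolist() == pytest.approx([1.0, 1.0])
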