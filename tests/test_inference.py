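"""Inference layer: preference tests, clustered binomial choice model,
mixed models, Tukey contrasts and fixed-effect models."""

import numpy as np
import pandas as pd
import pytest

from shoalresp.inference import (
    fixed_effect_model,
    initial_choice_test,
    metabolic_mixed_model,
    preference_deviation_test,
    tukey_contrasts,
)
from shoalresp.simulate import SimConfig, config_with, simulate_choice_events


def simulate_preferences(p, n_shoals=9, fish_per_shoal=2, shoal_sd=0.25,
                         seed=0, cfg=None):
    """Event-level preference draws for one treatment."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(seed)
    prefs, shoals = [], []
    for s in range(n_shoals):
        if 0 < p < 1:
            logit = np.log(p / (1 - p)) + rng.normal(0.0, shoal_sd)
            p_shoal = 1.0 / (1.0 + np.exp(-logit))
        else:
            p_shoal = p
        for _ in range(fish_per_shoal):
            ev = simulate_choice_events(
                p_shoal, cfg, rng.integers(2**31), force_informed=True
            )
            prefs.append(ev.familiar_preference)
            shoals.append(f"s{s}")
    return prefs, shoals


def null_summaries(seed, n_per_treatment=10, effect=1.0):
    """Summary-level cohort with a known group/alone MR_min ratio."""
    rng = np.random.default_rng(seed)
    rows = []
    for co2 in (450, 750, 1000):
        for i in range(n_per_treatment):
            mass = max(rng.normal(1.29, 0.22), 0.4)
            smr = 0.49 * mass ** 0.8 * rng.lognormal(0.0, 0.15)
            for testing, mult in (("alone", 1.0), ("group", effect)):
                rows.append(
                    {
                        "fish_id": f"{co2}_{i}", "co2_uatm": co2,
                        "testing": testing, "mass_g": mass,
                        "mr_min": smr * mult * (1.0 + rng.normal(0.0, 0.02)),
                    }
                )
    return pd.DataFrame(rows)


class TestPreferenceDeviation:
    def test_exact_null_gives_p_one(self):
        prefs = [0.5] * 18
        shoals = [f"s{i // 2}" for i in range(18)]
        res = preference_deviation_test(prefs, shoals)
        row = res.term("deviation_from_0.5")
        assert row["estimate"] == pytest.approx(0.0)
        assert row["stat"] == pytest.approx(0.0)
        assert row["p"] == pytest.approx(1.0)

    def test_singular_grouping_falls_back(self):
        prefs = [0.6, 0.7, 0.55, 0.65, 0.72, 0.58]
        shoals = [f"s{i}" for i in range(6)]
        res = preference_deviation_test(prefs, shoals)
        assert "one-sample t" in res.method
        assert res.term("deviation_from_0.5")["p"] < 0.05

    def test_power_under_strong_preference(self):
        """p_familiar = 0.75, n = 18: significant in >= 90% of 200
        replicates."""
        hits = 0
        for rep in range(200):
            prefs, shoals = simulate_preferences(0.75, seed=rep)
            res = preference_deviation_test(prefs, shoals)
            hits += res.term("deviation_from_0.5")["p"] < 0.05
        assert hits / 200 >= 0.90

    def test_reported_df_matches_design(self):
        prefs, shoals = simulate_preferences(0.6, seed=3)
        res = preference_deviation_test(prefs, shoals)
        assert res.term("deviation_from_0.5")["df_den"] == 8  # 9 shoals - 1


class TestInitialChoice:
    def _df(self, counts):
        rows = []
        for co2, (fam, unfam) in counts.items():
            for i in range(fam):
                rows.append({"chose_familiar": 1.0, "co2_uatm": co2,
                             "shoal_id": f"s{co2}_{i % 9}"})
            for i in range(unfam):
                rows.append({"chose_familiar": 0.0, "co2_uatm": co2,
                             "shoal_id": f"s{co2}_{i % 9}"})
        return pd.DataFrame(rows)

    def test_even_split_everywhere_is_null(self):
        res = initial_choice_test(self._df({450: (9, 9), 750: (9, 9),
                                            1000: (9, 9)}))
        row = res.term("co2_treatment")
        assert row["stat"] == pytest.approx(0.0, abs=1e-6)
        assert row["p"] == pytest.approx(1.0, abs=1e-6)

    def test_separation_triggers_penalized_fallback(self):
        with pytest.warns(UserWarning, match="separation"):
            res = initial_choice_test(
                self._df({450: (18, 0), 750: (9, 9), 1000: (9, 9)})
            )
        assert "Haldane" in res.method
        assert np.isfinite(res.term("co2_treatment")["stat"])

    def test_detects_strong_treatment_difference(self):
        res = initial_choice_test(self._df({450: (17, 1), 750: (9, 9),
                                            1000: (9, 9)}))
        assert res.term("co2_treatment")["p"] < 0.05


class TestMetabolicMixedModel:
    def test_no_within_fish_change_gives_null_testing_effect(self):
        df = null_summaries(seed=5, effect=1.0)
        wide = df.pivot_table(index=["fish_id", "co2_uatm", "mass_g"],
                              columns="testing", values="mr_min").reset_index()
        rows = []
        for _, r in wide.iterrows():
            for testing in ("alone", "group"):
                rows.append({"fish_id": r["fish_id"], "co2_uatm": r["co2_uatm"],
                             "mass_g": r["mass_g"], "testing": testing,
                             "mr_min": r["alone"]})
        res = metabolic_mixed_model(pd.DataFrame(rows), "mr_min")
        assert res.term("testing_treatment")["stat"] == pytest.approx(0.0, abs=1e-8)

    def test_power_for_programmed_calming(self):
        """A 22.8% within-fish reduction at n = 30 is detected at p < 0.05
        in >= 80% of replicates."""
        hits = 0
        for rep in range(50):
            res = metabolic_mixed_model(
                null_summaries(seed=100 + rep, effect=0.772), "mr_min"
            )
            hits += res.term("testing_treatment")["p"] < 0.05
        assert hits / 50 >= 0.80

    def test_unpaired_fish_dropped(self):
        df = null_summaries(seed=6)
        df = df.drop(df[(df.fish_id == "450_0") & (df.testing == "group")].index)
        res = metabolic_mixed_model(df, "mr_min")
        assert any("450_0" in n for n in res.notes)

    def test_containment_df_match_design_arithmetic(self):
        """30 paired fish: between terms (CO2, mass) get df 26; within terms
        (testing, interaction) get df 27."""
        res = metabolic_mixed_model(null_summaries(seed=7), "mr_min")
        assert res.term("co2_treatment")["df_den"] == 26
        assert res.term("mass")["df_den"] == 26
        assert res.term("testing_treatment")["df_den"] == 27
        assert res.term("co2_x_testing")["df_den"] == 27

    def test_permutation_null_calibrated(self):
        """Testing-effect rejection rate at alpha = 0.05 stays in
        [0.03, 0.07] over 1000 null cohorts."""
        rej = 0
        n = 1000
        for rep in range(n):
            res = metabolic_mixed_model(null_summaries(seed=2000 + rep), "mr_min")
            rej += res.term("testing_treatment")["p"] < 0.05
        assert 0.03 <= rej / n <= 0.07


class TestTukey:
    def test_identical_means_all_nonsignificant(self):
        res = metabolic_mixed_model(null_summaries(seed=8), "mr_min")
        table = tukey_contrasts(res)
        assert len(table) == 3
        assert (table["adj_p"] > 0.2).all()

    def test_adjusted_p_never_below_raw(self):
        res = metabolic_mixed_model(null_summaries(seed=9, effect=0.772),
                                    "mr_min")
        table = tukey_contrasts(res)
        assert (table["adj_p"] >= table["p"] - 1e-12).all()

    def test_shifted_level_detected(self):
        df = null_summaries(seed=10)
        df.loc[df["co2_uatm"] == 1000, "mr_min"] *= 1.6
        table = tukey_contrasts(metabolic_mixed_model(df, "mr_min"))
        sig = table[table["adj_p"] < 0.05]["contrast"].tolist()
        assert any("1000" in c for c in sig)
        assert not any(("450" in c) and ("750" in c) for c in sig)

    def test_two_level_factor_rejected(self):
        res = metabolic_mixed_model(
            null_summaries(seed=11).query("co2_uatm != 1000"), "mr_min"
        )
        with pytest.raises(ValueError, match="3-level"):
            tukey_contrasts(res)


class TestFixedEffectModel:
    def _mass_only(self, seed, slope=0.9):
        rng = np.random.default_rng(seed)
        rows = []
        for co2 in (450, 750, 1000):
            for i in range(10):
                mass = max(rng.normal(1.29, 0.22), 0.4)
                rows.append({"fish_id": f"{co2}_{i}", "co2_uatm": co2,
                             "mass_g": mass, "testing": "alone",
                             "mmr": 0.3 + slope * mass + rng.normal(0.0, 0.03)})
        return pd.DataFrame(rows)

    def test_recovers_mass_slope_without_treatment_effect(self):
        res = fixed_effect_model(self._mass_only(seed=12), "mmr")
        assert res.term("mass_slope")["estimate"] == pytest.approx(0.9, abs=0.1)
        assert res.term("co2_treatment")["p"] > 0.05

    def test_zero_variance_guard(self):
        df = self._mass_only(seed=13)
        df["mmr"] = 1.0
        res = fixed_effect_model(df, "mmr")
        assert "degenerate" in res.method

    def test_constant_shift_changes_intercept_only(self):
        df = self._mass_only(seed=14)
        base = fixed_effect_model(df, "mmr")
        shifted = df.copy()
        shifted["mmr"] = shifted["mmr"] + 5.0
        after = fixed_effect_model(shifted, "mmr")
        assert after.term("co2_treatment")["stat"] == pytest.approx(
            base.term("co2_treatment")["stat"], rel=1e-9
        )
        np.testing.assert_allclose(
            after.level_means.to_numpy(), base.level_means.to_numpy() + 5.0,
            rtol=1e-9,
        )

    def test_response_rescaling_equivariance(self):
        df = self._mass_only(seed=15)
        base = fixed_effect_model(df, "mmr")
        scaled = df.copy()
        scaled["mmr"] = scaled["mmr"] * 1000.0  # mg -> ug
        after = fixed_effect_model(scaled, "mmr")
        assert after.term("co2_treatment")["stat"] == pytest.approx(
            base.term("co2_treatment")["stat"], rel=1e-9
        )
        assert after.term("mass_slope")["estimate"] == pytest.approx(
            base.term("mass_slope")["estimate"] * 1000.0, rel=1e-9
        )
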