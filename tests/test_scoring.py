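"""Screen calling: bands, criteria, control normalization, exclusions, recovery."""

import numpy as np
import pandas as pd
import pytest

from lightscreen.scoring import (
    ScreenThresholds,
    aggregate_calls,
    call_resistant,
    call_strains,
    control_band_median,
    control_band_medians,
    criterium1,
    density_band,
    estimate_false_positive_rate,
    lgnorm,
    slow_growth_excluded,
)

THR = ScreenThresholds()


class TestDensityBand:
    @pytest.mark.parametrize(
        "day0,band",
        [
            (121, "high"),
            (120, "moderate"),
            (61, "moderate"),
            (60, "discarded"),
            (0, "discarded"),
            (-5, "discarded"),
            (1e6, "high"),
        ],
    )
    def test_inclusive_boundaries(self, day0, band):
        assert density_band(day0, THR) == band

    def test_haploid_variant_has_no_moderate_band(self):
        thr = ScreenThresholds.variant("confirm_haploid")
        assert density_band(13, thr) == "high"
        assert density_band(12.9, thr) == "discarded"

    def test_diploid_variant_bands(self):
        thr = ScreenThresholds.variant("confirm_diploid")
        assert density_band(105, thr) == "high"
        assert density_band(104, thr) == "moderate"
        assert density_band(45, thr) == "moderate"
        assert density_band(44, thr) == "discarded"


class TestCriterium1:
    @pytest.mark.parametrize(
        "day0,day6,expected",
        [
            (150, 899, True),
            (150, 900, False),
            (100, 399, True),
            (100, 400, False),
        ],
    )
    def test_strict_band_cutoffs(self, day0, day6, expected):
        assert criterium1(day0, day6, THR) is expected

    def test_discarded_band_is_an_error(self):
        with pytest.raises(ValueError, match="discarded"):
            criterium1(10, 100, THR)

    def test_diploid_moderate_cutoff_500(self):
        thr = ScreenThresholds.variant("confirm_diploid")
        assert criterium1(50, 499, thr) is True
        assert criterium1(50, 500, thr) is False


class TestLgnorm:
    def test_self_normalization(self):
        assert lgnorm(600.0, 200.0, 3.0) == pytest.approx(1.0)

    def test_arithmetic(self):
        assert lgnorm(100.0, 200.0, 2.0) == pytest.approx(0.25)

    def test_non_positive_denominators_rejected(self):
        with pytest.raises(ValueError):
            lgnorm(100.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            lgnorm(100.0, 10.0, 0.0)


class TestSlowGrowth:
    @pytest.mark.parametrize(
        "d0,d1,excluded", [(100, 149, True), (100, 150, False), (100, 300, False)]
    )
    def test_fold_boundary(self, d0, d1, excluded):
        assert slow_growth_excluded(d0, d1, THR) is excluded

    def test_non_positive_day0_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            slow_growth_excluded(0, 100, THR)


def _tables(rows):
    """rows: (plate, row, col, strain, ctrl, ld0, ld6, dd0, dd1) -> light/dark frames."""
    recs = []
    for plate, r, c, strain, ctrl, ld0, ld6, dd0, dd1 in rows:
        for cond, day, v in (
            ("light", 0, ld0), ("light", 6, ld6), ("dark", 0, dd0), ("dark", 1, dd1)
        ):
            if v is None:
                continue
            recs.append(
                {"plate": plate, "row": r, "col": c, "strain": strain,
                 "control_flag": ctrl, "dubious_flag": False,
                 "condition": cond, "day": day, "cde": float(v)}
            )
    df = pd.DataFrame.from_records(recs)
    return df[df["condition"] == "light"], df[df["condition"] == "dark"]


class TestControlMedians:
    def test_identical_ratios_give_that_ratio(self):
        rows = [("p1", 0, c, "his3", True, 150, 600, 150, 200) for c in range(5)]
        light, dark = _tables(rows)
        assert control_band_median(light, dark, THR, "p1", "high") == pytest.approx(3.0)

    def test_odd_count_median(self):
        rows = [
            ("p1", 0, 0, "his3", True, 150, 100, 150, 100),  # ratio 1
            ("p1", 0, 1, "his3", True, 150, 200, 150, 100),  # ratio 2
            ("p1", 0, 2, "his3", True, 150, 400, 150, 100),  # ratio 4
        ]
        light, dark = _tables(rows)
        assert control_band_median(light, dark, THR, "p1", "high") == pytest.approx(2.0)

    def test_neighbor_plate_fallback_prefers_nearest_then_lower(self):
        rows = [
            # plate p1: high-band control only; p2: none in moderate either
            ("p1", 0, 0, "his3", True, 150, 300, 150, 100),  # high ratio 3
            ("p1", 0, 1, "his3", True, 90, 180, 90, 90),     # moderate ratio 2
            ("p2", 0, 0, "his3", True, 150, 500, 150, 100),  # high ratio 5
            ("p3", 0, 0, "his3", True, 90, 360, 90, 90),     # moderate ratio 4
            ("p3", 0, 1, "his3", True, 150, 100, 150, 100),  # high ratio 1
        ]
        light, dark = _tables(rows)
        med = control_band_medians(light, dark, THR)
        assert med[("p2", "moderate")] == pytest.approx(2.0)  # tie p1/p3 -> lower index
        assert med[("p2", "high")] == pytest.approx(5.0)      # own value kept

    def test_no_control_anywhere_is_fatal(self):
        rows = [("p1", 0, 0, "mut1", False, 150, 600, 150, 200)]
        light, dark = _tables(rows)
        with pytest.raises(ValueError, match="no control"):
            control_band_medians(light, dark, THR)


class TestCallStrains:
    def test_null_screen_calls_nothing(self, small_screen):
        from lightscreen.synthetic import SyntheticScreenSpec, simulate_screen_tables

        spec = SyntheticScreenSpec(n_plates=1, noise_sd=0.0, seed=2)
        light, dark, layout, truth = simulate_screen_tables(spec)
        calls = call_strains(light, dark)
        assert not calls["verdict"].str.startswith("sensitive").any()

    def test_noise_free_planted_recovery_exact(self, small_screen):
        spec, (light, dark, layout, truth) = small_screen
        calls = call_strains(light, dark)
        sens = set(calls.loc[calls["verdict"].str.startswith("sensitive"), "strain"])
        slow = set(calls.loc[calls["verdict"] == "excluded_slow_growth", "strain"])
        assert sens == set(spec.planted_sensitive)
        assert slow == set(spec.planted_slow)
        assert call_resistant(light) == set(spec.planted_resistant)

    def test_every_position_gets_exactly_one_verdict(self, small_screen):
        spec, (light, dark, layout, truth) = small_screen
        calls = call_strains(light, dark)
        assert len(calls) == len(layout)
        assert calls["verdict"].isin(
            ["sensitive_high", "sensitive_moderate", "resistant", "not_called",
             "excluded_low_density", "excluded_slow_growth", "excluded_missing_data"]
        ).all()
        merged = calls.merge(layout, on=["plate", "row", "col"])
        assert (merged["strain_x"] == merged["strain_y"]).all()

    def test_missing_day_excludes_with_reason(self):
        rows = [
            ("p1", 0, 0, "his3", True, 150, 600, 150, 200),
            ("p1", 0, 1, "mutA", False, 150, None, 150, 200),
        ]
        light, dark = _tables(rows)
        calls = call_strains(light, dark).set_index("strain")
        assert calls.loc["mutA", "verdict"] == "excluded_missing_data"
        assert "light_day6" in calls.loc["mutA", "reasons"]

    def test_sensitive_requires_both_criteria(self):
        # mutB passes criterium I but its LGnorm (1.0 vs controls) fails II;
        # mutC fails I (day6 above cutoff) despite a tiny LGnorm
        rows = [
            ("p1", 0, c, "his3", True, 150, 600, 150, 200) for c in range(3)
        ] + [
            ("p1", 1, 0, "mutB", False, 150, 800, 150, 267),   # ratio ~3 -> lgnorm ~1
            ("p1", 1, 1, "mutC", False, 150, 950, 150, 2000),  # lgnorm ~0.16, crit I fails
            ("p1", 1, 2, "mutD", False, 150, 500, 150, 500),   # both criteria hold
        ]
        light, dark = _tables(rows)
        calls = call_strains(light, dark).set_index("strain")
        assert calls.loc["mutB", "verdict"] == "not_called"
        assert calls.loc["mutC", "verdict"] == "not_called"
        assert calls.loc["mutD", "verdict"] == "sensitive_high"

    def test_low_density_verdict(self):
        rows = [
            ("p1", 0, 0, "his3", True, 150, 600, 150, 200),
            ("p1", 0, 1, "mutE", False, 40, 10, 40, 120),
        ]
        light, dark = _tables(rows)
        calls = call_strains(light, dark).set_index("strain")
        assert calls.loc["mutE", "verdict"] == "excluded_low_density"

    def test_lgnorm_scale_equivariance(self, small_screen):
        # a plate-wide gain change in the day-6 light exposure cancels out
        # of LGnorm because the control median scales identically; day-0
        # values stay put so band membership is unchanged
        spec, (light, dark, layout, truth) = small_screen
        base = call_strains(light, dark)
        scaled_light = light.copy()
        plate = scaled_light["plate"].iloc[0]
        mask = (scaled_light["plate"] == plate) & (scaled_light["day"] == 6)
        scaled_light.loc[mask, "cde"] *= 3.7
        scaled = call_strains(scaled_light, dark)
        sel = base["plate"] == plate
        np.testing.assert_allclose(
            base.loc[sel, "lgnorm"].to_numpy(dtype=float),
            scaled.loc[sel, "lgnorm"].to_numpy(dtype=float),
            rtol=1e-12,
        )

    def test_control_lgnorm_median_is_one(self, small_screen):
        spec, (light, dark, layout, truth) = small_screen
        calls = call_strains(light, dark)
        ctrl = calls[calls["control_flag"] & calls["lgnorm"].notna()]
        for (_, _), grp in ctrl.groupby(["plate", "band"]):
            assert grp["lgnorm"].median() == pytest.approx(1.0, abs=1e-9)


class TestResistant:
    @pytest.mark.parametrize(
        "ld0,ld6,expected",
        [(150, 1642, False), (150, 1643, True), (50, 5000, False), (61, 1700, True)],
    )
    def test_strict_boundaries_and_density_gate(self, ld0, ld6, expected):
        light, _ = _tables([("p1", 0, 0, "mutR", False, ld0, ld6, ld0, 300)])
        assert (("mutR" in call_resistant(light)) is expected)


class TestFalsePositiveRate:
    def test_counting(self):
        rows = [("p1", 0, c, "his3", True, 90, 500, 90, 90) for c in range(19)]
        rows.append(("p1", 1, 0, "his3", True, 90, 350, 90, 90))  # passes the 400 cutoff
        light, _ = _tables(rows)
        ctrl = light[light["control_flag"]]
        rate = estimate_false_positive_rate(ctrl, THR, "moderate")
        assert rate == pytest.approx(1 / 20)

    def test_all_above_cutoff_gives_zero(self):
        rows = [("p1", 0, c, "his3", True, 150, 1200, 150, 400) for c in range(10)]
        light, _ = _tables(rows)
        assert estimate_false_positive_rate(light, THR, "high") == 0.0

    def test_empty_band_is_an_error(self):
        rows = [("p1", 0, 0, "his3", True, 150, 1200, 150, 400)]
        light, _ = _tables(rows)
        with pytest.raises(ValueError, match="moderate"):
            estimate_false_positive_rate(light, THR, "moderate")


class TestAggregation:
    def _calls(self, verdicts):
        return pd.DataFrame(
            [{"strain": "s1", "verdict": v} for v in verdicts]
        )

    def test_any_vs_majority(self):
        calls = self._calls(
            ["sensitive_high", "not_called", "not_called", "excluded_low_density"]
        )
        assert aggregate_calls(calls, "any").loc[0, "verdict"] == "sensitive_high"
        assert aggregate_calls(calls, "majority").loc[0, "verdict"] == "not_called"

    def test_no_voting_replicates(self):
        calls = self._calls(["excluded_low_density", "excluded_missing_data"])
        assert aggregate_calls(calls).loc[0, "verdict"] == "excluded_missing_data"
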