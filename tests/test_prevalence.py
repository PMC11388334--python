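"""Prevalence flags, tallies and monetary arithmetic — exact checks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gwyield.prevalence import flag_conditions, monetary_impact, tally
from gwyield.zones import ZoneReport

ZONES = ZoneReport(
    baseline_found=True,
    subsidy_detected=True,
    subsidy_low=1.1,
    subsidy_high=2.5,
    penalty_threshold=1.1,
)


def _table(rows):
    df = pd.DataFrame(rows, columns=["cell_id", "year", "wt_depth_jul", "deficit_july"])
    df["production_t"] = 1000.0
    df["price_usd_t"] = 150.0
    return df


class TestFlagConditions:
    @pytest.mark.parametrize(
        "depth, deficit, expect",
        [
            (1.8, -80.0, dict(access=True, dry=True, subsidy=True, strong_subsidy=False, penalty=False)),
            (0.9, -200.0, dict(penalty=True, access=False, subsidy=False)),
            (2.5, -160.0, dict(access=True, strong_subsidy=True)),  # closed upper bound
            (1.1, -40.0, dict(access=True, dry=False, subsidy=False, penalty=False)),
            (3.0, -300.0, dict(access=False, very_dry=True, subsidy=False)),
        ],
    )
    def test_threshold_logic(self, depth, deficit, expect):
        flagged = flag_conditions(_table([(0, 0, depth, deficit)]), zones=ZONES)
        for key, val in expect.items():
            assert bool(flagged[key].iloc[0]) is val, key

    def test_penalty_and_access_disjoint(self, default_world):
        flagged = flag_conditions(default_world, zones=ZONES)
        assert not (flagged["penalty"] & flagged["access"]).any()

    def test_missing_rows_rejected_with_count(self):
        df = _table([(0, 0, 1.8, -80.0), (1, 0, np.nan, -80.0)])
        flagged = flag_conditions(df, zones=ZONES)
        assert len(flagged) == 1

    def test_undetected_zone_needs_explicit_thresholds(self):
        with pytest.raises(ValueError):
            flag_conditions(_table([(0, 0, 1.8, -80.0)]), zones=ZoneReport())
        flagged = flag_conditions(
            _table([(0, 0, 1.8, -80.0)]),
            penalty_threshold=1.05, subsidy_low=1.1, subsidy_high=2.5,
        )
        assert flagged["subsidy"].iloc[0]


class TestTally:
    def _toy(self):
        # 3 cells x 2 years with hand-set conditions
        rows = [
            (0, 0, 1.8, -80.0),   # subsidy
            (0, 1, 0.9, -80.0),   # penalty, dry
            (1, 0, 2.0, -160.0),  # strong subsidy
            (1, 1, 3.0, -20.0),   # nothing
            (2, 0, 1.2, 30.0),    # access, wet
            (2, 1, 0.5, -155.0),  # penalty, very dry
        ]
        return flag_conditions(_table(rows), zones=ZONES)

    def test_hand_tally(self):
        t = tally(self._toy())
        pc = t.per_cell
        assert pc.loc[0, "subsidy_years"] == 1
        assert pc.loc[0, "penalty_years"] == 1
        assert pc.loc[1, "strong_subsidy_years"] == 1
        assert pc.loc[2, "access_years"] == 1
        assert pc.loc[2, "penalty_years"] == 1
        assert t.fractions["dry"] == pytest.approx(4 / 6)
        assert t.fractions["subsidy"] == pytest.approx(2 / 6)
        assert t.mean_subsidy_frequency == pytest.approx((0.5 + 0.5 + 0) / 3)
        assert t.annual_extent.loc[0] == pytest.approx(2 / 3)

    def test_all_false_gives_zeros(self):
        flagged = flag_conditions(_table([(0, 0, 4.0, 20.0), (1, 0, 5.0, 10.0)]), zones=ZONES)
        t = tally(flagged)
        counts = t.per_cell[[f"{c}_years" for c in
                             ("penalty", "access", "dry", "very_dry", "subsidy", "strong_subsidy")]]
        assert (counts.to_numpy() == 0).all()

    def test_intersection_bounds(self, default_world):
        t = tally(flag_conditions(default_world, zones=ZONES))
        pc = t.per_cell
        assert (pc["subsidy_years"] <= np.minimum(pc["access_years"], pc["dry_years"])).all()
        assert (pc["strong_subsidy_years"] <= pc["subsidy_years"]).all()
        assert t.fractions["subsidy"] <= min(t.fractions["access"], t.fractions["dry"])

    @given(st.randoms(use_true_random=False))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_permutation_invariance(self, rnd):
        flagged = self._toy()
        perm = list(range(len(flagged)))
        rnd.shuffle(perm)
        t1 = tally(flagged)
        t2 = tally(flagged.iloc[perm].reset_index(drop=True))
        pd.testing.assert_frame_equal(t1.per_cell, t2.per_cell)


class TestMonetary:
    def test_single_cell_year_subsidy_value(self):
        flagged = flag_conditions(_table([(0, 0, 1.8, -80.0)]), zones=ZONES)
        rep = monetary_impact(flagged, effect_pcts=(-0.01, 0.034, 0.078))
        assert rep.total_subsidy_usd == pytest.approx(1000 * 150 * 0.034)  # $5,100
        assert rep.total_penalty_usd == 0.0

    def test_strong_rate_replaces_not_stacks(self):
        flagged = flag_conditions(_table([(0, 0, 2.0, -160.0)]), zones=ZONES)
        rep = monetary_impact(flagged)
        assert rep.total_subsidy_usd == pytest.approx(1000 * 150 * 0.078)

    def test_penalty_reported_positive(self):
        flagged = flag_conditions(_table([(0, 0, 0.5, -80.0)]), zones=ZONES)
        rep = monetary_impact(flagged)
        assert rep.total_penalty_usd == pytest.approx(1000 * 150 * 0.01)
        assert rep.net_usd == -rep.total_penalty_usd

    def test_zero_production_zero_dollars(self):
        df = _table([(0, 0, 1.8, -80.0)])
        df["production_t"] = 0.0
        rep = monetary_impact(flag_conditions(df, zones=ZONES))
        assert rep.total_subsidy_usd == 0.0

    def test_price_linearity(self, default_world):
        flagged = flag_conditions(default_world, zones=ZONES)
        rep1 = monetary_impact(flagged)
        doubled = flagged.assign(price_usd_t=flagged["price_usd_t"] * 2)
        rep2 = monetary_impact(doubled)
        assert rep2.total_subsidy_usd == pytest.approx(2 * rep1.total_subsidy_usd)
        assert rep2.total_penalty_usd == pytest.approx(2 * rep1.total_penalty_usd)

    def test_zero_effect_pcts_zero_totals(self, default_world):
        flagged = flag_conditions(default_world, zones=ZONES)
        rep = monetary_impact(flagged, effect_pcts=(0.0, 0.0, 0.0))
        assert rep.total_subsidy_usd == 0.0 and rep.total_penalty_usd == 0.0

    def test_negative_price_rejected(self):
        df = _table([(0, 0, 1.8, -80.0)])
        df["price_usd_t"] = -1.0
        with pytest.raises(ValueError):
            monetary_impact(flag_conditions(df, zones=ZONES))

    def test_annual_additivity(self, default_world):
        flagged = flag_conditions(default_world, zones=ZONES)
        rep = monetary_impact(flagged)
        assert rep.annual["subsidy_usd"].sum() == pytest.approx(rep.total_subsidy_usd)
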