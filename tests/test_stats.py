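import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from miniscrewsim.anatomy import GROUPS, make_segment
from miniscrewsim.measure import MeasurementRecord, Outcome, measure
from miniscrewsim.screw import initial_placement
from miniscrewsim.stats import (
    GeeSpec,
    bilateral_average,
    categorize,
    fit_ordinal_gee,
    nonmeasurable_rates,
    paired_side_test,
    rate_gt2,
    round_half_up,
    summarize_measurable,
)

HYPER, NORMO, HYPO = GROUPS


def _rec(outcome, distance=None, side="left", **kwargs):
    ids = dict(subject_id="S1", jaw="Mx", site="5-6", side=side, angle=0.0)
    ids.update(kwargs)
    return MeasurementRecord(outcome=outcome, distance=distance, **ids)


class TestCategorize:
    @pytest.mark.parametrize(
        "outcome,distance,expected",
        [
            (Outcome.CONTACT, None, 0),
            (Outcome.MEASURABLE, 0.3, 1),
            (Outcome.MEASURABLE, 0.5, 1),   # inclusive upper edge
            (Outcome.MEASURABLE, 0.8, 2),
            (Outcome.MEASURABLE, 1.0, 2),
            (Outcome.MEASURABLE, 1.2, 3),
            (Outcome.MEASURABLE, 1.5, 3),
            (Outcome.MEASURABLE, 1.7, 4),
            (Outcome.MEASURABLE, 2.0, 4),
            (Outcome.MEASURABLE, 2.0001, 5),
            (Outcome.MEASURABLE, 9.0, 5),
            (Outcome.NONCONTACT, None, 6),
        ],
    )
    def test_bins(self, outcome, distance, expected):
        assert categorize((outcome, distance)) == expected

    def test_accepts_record(self):
        assert categorize(_rec(Outcome.MEASURABLE, 1.2)) == 3

    @given(
        a=st.floats(0.001, 10, allow_nan=False),
        b=st.floats(0.001, 10, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_distance(self, a, b):
        ca = categorize((Outcome.MEASURABLE, a))
        cb = categorize((Outcome.MEASURABLE, b))
        if a <= b:
            assert ca <= cb
        assert 1 <= ca <= 5


class TestBilateralAverage:
    def test_both_measurable(self):
        rec, flag = bilateral_average(
            _rec(Outcome.MEASURABLE, 1.0, "left"), _rec(Outcome.MEASURABLE, 1.4, "right")
        )
        assert rec.distance == pytest.approx(1.2)
        assert not flag

    def test_both_contact(self):
        rec, flag = bilateral_average(
            _rec(Outcome.CONTACT, side="left"), _rec(Outcome.CONTACT, side="right")
        )
        assert rec.outcome is Outcome.CONTACT and not flag

    def test_discordant_measurability(self):
        rec, flag = bilateral_average(
            _rec(Outcome.MEASURABLE, 2.0, "left"), _rec(Outcome.NONCONTACT, side="right")
        )
        assert rec.outcome is Outcome.MEASURABLE
        assert rec.distance == pytest.approx(2.0)
        assert flag

    def test_contact_vs_noncontact_resolves_to_contact(self):
        rec, flag = bilateral_average(
            _rec(Outcome.NONCONTACT, side="left"), _rec(Outcome.CONTACT, side="right")
        )
        assert rec.outcome is Outcome.CONTACT and flag

    def test_identifier_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            bilateral_average(
                _rec(Outcome.CONTACT, side="left"),
                _rec(Outcome.CONTACT, side="right", jaw="Mn"),
            )


def _side_frame(rows):
    return pd.DataFrame(
        [
            dict(
                subject_id=f"S{i}",
                jaw="Mx",
                site="5-6",
                angle=0,
                side=side,
                outcome="measurable",
                distance_mm=v,
            )
            for i, pair in enumerate(rows)
            for side, v in zip(("left", "right"), pair)
        ]
    )


class TestPairedSideTest:
    def test_identical_sides(self):
        res = paired_side_test(_side_frame([(1.0, 1.0), (1.4, 1.4), (2.0, 2.0)]))
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_constant_offset_degenerate(self):
        res = paired_side_test(_side_frame([(1.2, 1.0), (1.6, 1.4), (2.2, 2.0)]))
        assert res.degenerate
        assert res.pvalue == 0.0

    def test_insufficient_pairs(self):
        with pytest.raises(ValueError):
            paired_side_test(_side_frame([(1.0, 1.1)]))

    def test_type_one_error_rate(self, rng):
        # symmetric jitter: rejection rate ~ alpha (within 2 Monte-Carlo SE)
        n_rep, n_pairs, alpha = 1000, 24, 0.05
        rejections = 0
        for _ in range(n_rep):
            base = rng.uniform(1.0, 2.0, n_pairs)
            left = base + rng.normal(0, 0.08, n_pairs)
            right = base + rng.normal(0, 0.08, n_pairs)
            res = paired_side_test(_side_frame(list(zip(left, right))))
            rejections += res.pvalue < alpha
        rate = rejections / n_rep
        se = np.sqrt(alpha * (1 - alpha) / n_rep)
        assert abs(rate - alpha) <= 2 * se + 1e-9


def _cohort_frame(cells):
    """cells: list of (facial_type, jaw, site, angle, outcome, distance)."""
    rows = []
    for i, (ft, jaw, site, angle, outcome, dist) in enumerate(cells):
        rows.append(
            dict(
                subject_id=f"S{i}",
                facial_type=ft,
                sex="F",
                mp_angle=33.0,
                fhi=66.0,
                jaw=jaw,
                site=site,
                angle=angle,
                outcome=outcome,
                distance_mm=dist,
                category=categorize((outcome, dist)),
            )
        )
    return pd.DataFrame(rows)


class TestSummaries:
    def test_constant_measurable(self):
        df = _cohort_frame([(NORMO, "Mx", "5-6", 0, "measurable", 1.0)] * 4)
        out = summarize_measurable(df)
        total = out[(out.group == "Total")].iloc[0]
        assert total.mean_mm == 1.0 and total.sd_mm == 0.0 and total.n == 4

    def test_nonmeasurable_excluded_from_mean(self):
        df = _cohort_frame(
            [
                (NORMO, "Mx", "5-6", 0, "measurable", 1.0),
                (NORMO, "Mx", "5-6", 0, "measurable", 2.0),
                (NORMO, "Mx", "5-6", 0, "contact", None),
                (NORMO, "Mx", "5-6", 0, "noncontact", None),
            ]
        )
        total = summarize_measurable(df)
        row = total[total.group == "Total"].iloc[0]
        assert row.mean_mm == pytest.approx(1.5) and row.n == 2

    def test_empty_cells_flagged(self):
        df = _cohort_frame(
            [
                (NORMO, "Mx", "5-6", 0, "contact", None),
                (HYPO, "Mx", "5-6", 0, "measurable", 1.0),
            ]
        )
        out = summarize_measurable(df)
        flagged = out[(out.group == NORMO)].iloc[0]
        assert flagged.empty_cell and flagged.n == 0 and np.isnan(flagged.mean_mm)

    def test_row_order_invariance(self):
        cells = [
            (HYPER, "Mn", "5-6", 0, "measurable", 1.1),
            (NORMO, "Mn", "5-6", 0, "measurable", 1.3),
            (HYPO, "Mn", "5-6", 0, "measurable", 1.5),
            (HYPO, "Mn", "5-6", 30, "noncontact", None),
        ]
        a = summarize_measurable(_cohort_frame(cells))
        b = summarize_measurable(_cohort_frame(cells[::-1]))
        pd.testing.assert_frame_equal(
            a.reset_index(drop=True), b.reset_index(drop=True)
        )

    def test_rate_gt2_arithmetic(self):
        cells = [(NORMO, "Mx", "5-6", 60, "measurable", 2.5)] * 3 + [
            (NORMO, "Mx", "5-6", 60, "measurable", 1.0)
        ] * 17
        out = rate_gt2(_cohort_frame(cells))
        assert out.loc[0, "60"] == 15.0  # 3 of 20

    def test_rate_gt2_extremes(self):
        all5 = _cohort_frame([(NORMO, "Mn", "6-7", 45, "measurable", 2.3)] * 5)
        none = _cohort_frame([(NORMO, "Mn", "6-7", 45, "measurable", 1.3)] * 5)
        assert rate_gt2(all5).loc[0, "45"] == 100.0
        assert rate_gt2(none).loc[0, "45"] == 0.0

    def test_nonmeasurable_rates_arithmetic(self):
        cells = [(NORMO, "Mn", "5-6", 60, "noncontact", None)] * 11 + [
            (NORMO, "Mn", "5-6", 60, "measurable", 1.5)
        ] * 9
        out = nonmeasurable_rates(_cohort_frame(cells))
        row = out[(out.facial_type == NORMO)].iloc[0]
        assert row.noncontact_pct == 55.0  # 11 of 20
        assert row.contact_pct == 0.0

    def test_category_conservation(self):
        cells = (
            [(HYPER, "Mx", "6-7", 0, "contact", None)] * 3
            + [(NORMO, "Mx", "5-6", 30, "measurable", 1.2)] * 5
            + [(HYPO, "Mn", "5-6", 60, "noncontact", None)] * 2
        )
        df = _cohort_frame(cells)
        counts = df["category"].value_counts()
        assert counts.sum() == len(df)
        assert counts.get(0) == 3 and counts.get(3) == 5 and counts.get(6) == 2

    def test_round_half_up(self):
        assert round_half_up(71.65) == 71.7
        assert round_half_up(71.64) == 71.6
        assert round_half_up(0.05) == 0.1

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            summarize_measurable(pd.DataFrame())


class TestContactOnlyAtThinSite:
    def test_constructed_thin_corridor(self):
        # narrow the Mx 6-7 corridor only; contact must appear there and
        # nowhere else
        zero = dict(taper=0.0, tilt=0.0, tilt_bl=0.0, bow=0.0)
        outcomes = {}
        for jaw in ("Mx", "Mn"):
            for site in ("5-6", "6-7"):
                ov = {"anterior": dict(zero), "posterior": dict(zero)}
                ov["cej_gap"] = 0.7 if (jaw, site) == ("Mx", "6-7") else 3.0
                seg = make_segment(jaw, site, overrides=ov)
                pl = initial_placement(seg)
                outcomes[(jaw, site)] = measure(seg, pl).outcome
        assert outcomes[("Mx", "6-7")] is Outcome.CONTACT
        for key, out in outcomes.items():
            if key != ("Mx", "6-7"):
                assert out is Outcome.MEASURABLE


def _synthetic_gee_cohort(
    rng,
    n_per_group=12,
    angle_slope=0.0,
    mn_facial_shift=0.0,
    subject_sd=0.45,
    noise_sd=0.4,
):
    """Fast synthetic cohort table with configurable built-in effects."""
    shift = {HYPER: -mn_facial_shift, NORMO: 0.0, HYPO: mn_facial_shift}
    mp = {HYPER: 42.5, NORMO: 33.6, HYPO: 23.9}
    fhi = {HYPER: 58.7, NORMO: 66.8, HYPO: 75.3}
    rows = []
    sid = 0
    for g in GROUPS:
        for _ in range(n_per_group):
            sid += 1
            u = rng.normal(0, subject_sd)
            sex = "M" if rng.random() < 0.4 else "F"
            for jaw in ("Mx", "Mn"):
                for site in ("5-6", "6-7"):
                    for angle in (0, 30, 45, 60):
                        lat = 1.2 + angle_slope * angle + u + rng.normal(0, noise_sd)
                        if jaw == "Mn":
                            lat += shift[g]
                        cat = 1 + int(
                            np.searchsorted([0.5, 1, 1.5, 2], lat, side="left")
                        )
                        rows.append(
                            dict(
                                subject_id=f"S{sid}",
                                facial_type=g,
                                sex=sex,
                                mp_angle=mp[g] + rng.normal(0, 2),
                                fhi=fhi[g] + rng.normal(0, 2),
                                jaw=jaw,
                                site=site,
                                angle=angle,
                                category=min(cat, 5),
                            )
                        )
    return pd.DataFrame(rows)


class TestOrdinalGee:
    def test_angle_effect_recovered(self, rng):
        df = _synthetic_gee_cohort(rng, angle_slope=0.02)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_ordinal_gee(df, GeeSpec(covariates=("sex",)))
        assert res.term_pvalues["angle"] < 0.01
        assert res.orderings["angle"] == [60, 45, 30, 0]

    def test_mandible_only_facial_effect(self, rng):
        df = _synthetic_gee_cohort(rng, mn_facial_shift=0.5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_ordinal_gee(df, GeeSpec(covariates=("sex",)))
        assert res.term_pvalues["facial_type*jaw"] < 0.01
        assert res.orderings["facial_type|Mn"] == [HYPO, NORMO, HYPER]

    def test_too_few_subjects_rejected(self, rng):
        df = _synthetic_gee_cohort(rng, n_per_group=1)
        with pytest.raises(ValueError):
            fit_ordinal_gee(df)

    def test_constant_outcome_rejected(self, rng):
        df = _synthetic_gee_cohort(rng)
        df["category"] = 3
        with pytest.raises(ValueError, match="constant"):
            fit_ordinal_gee(df)

    def test_unknown_cov_struct_rejected(self, rng):
        df = _synthetic_gee_cohort(rng)
        with pytest.raises(ValueError):
            fit_ordinal_gee(df, GeeSpec(cov_struct="exchangeable-ar1"))

    def test_global_odds_ratio_struct_runs(self, rng):
        df = _synthetic_gee_cohort(rng, angle_slope=0.02, n_per_group=8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_ordinal_gee(
                df, GeeSpec(covariates=("sex",), cov_struct="global_odds_ratio")
            )
        assert res.cov_struct == "global_odds_ratio"
        assert res.term_pvalues["angle"] < 0.05

    def test_ordinal_angle_coding(self, rng):
        df = _synthetic_gee_cohort(rng, angle_slope=0.02)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_ordinal_gee(
                df, GeeSpec(covariates=("sex",), ordinal_factors=("angle",))
            )
        assert res.term_pvalues["angle"] < 0.01
        assert res.coefficients["angle_linear"] > 0
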