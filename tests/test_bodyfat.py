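"""The twelve-method %BF battery: published coefficients, branch logic,
derivation identities, and agreement with the independent oracle."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from adipoquant import (
    DomainError,
    Maturation,
    MissingCovariateError,
    MissingMeasurementError,
    Race,
    Sex,
    SubjectRecord,
    UnsupportedAgeError,
    arm_muscle_circumference,
    bia1_percent_fat,
    classify_excess_fat,
    evaluate_battery,
    eq1_durnin,
    eq2_boileau,
    eq3_slaughter_tc,
    eq4_slaughter_ts,
    eq5_weststrate,
    eq6_guo,
    eq7_deurenberg90,
    eq8_deurenberg91,
    eq9_houtkooper,
    eq10_ellis,
    siri_percent_fat,
)
from adipoquant.bodyfat import METHODS, density_from_siri
from adipoquant.experiments import random_subject
from oracles import oracle_percent_fat


def make_subject(**overrides):
    base = dict(
        subject_id="s", sex="male", age=16.0, weight=60.0, height=170.0,
        race="white", maturation="postpubescent",
        skinfolds={"biceps": 8.0, "triceps": 10.0, "suprailiac": 9.0,
                   "subscapular": 9.0, "midaxillary": 8.0, "calf": 11.0},
        brachial_perimeter=27.0, resistance=520.0, bia2_percent_fat=18.0,
    )
    base.update(overrides)
    return SubjectRecord(**base)


# ---------------------------------------------------------------------------
# Siri conversion
# ---------------------------------------------------------------------------

class TestSiri:
    def test_reference_points(self):
        assert siri_percent_fat(1.1) == pytest.approx(0.0, abs=1e-12)
        assert siri_percent_fat(0.99) == pytest.approx(50.0, abs=1e-9)
        assert siri_percent_fat(1.05) == pytest.approx((4.95 / 1.05 - 4.50) * 100, rel=1e-12)

    @pytest.mark.parametrize("bad", [0.0, -1.0, 0.89, 1.25, 2.0])
    def test_nonphysiological_density_rejected(self, bad):
        with pytest.raises(DomainError):
            siri_percent_fat(bad)

    @given(st.floats(min_value=0.991, max_value=1.199))
    @settings(max_examples=200, deadline=None)
    def test_round_trip(self, density):
        assert density_from_siri(siri_percent_fat(density)) == pytest.approx(
            density, abs=1e-9
        )


# ---------------------------------------------------------------------------
# Worked examples for each equation (direct evaluation of the published forms)
# ---------------------------------------------------------------------------

class TestWorkedExamples:
    def test_eq1_male_adolescent_band(self, male_subject):
        est = eq1_durnin(male_subject)  # folds sum to 20 mm
        d = 1.1533 - 0.0643 * math.log10(20.0)
        assert est.density == pytest.approx(d, rel=1e-12)
        assert est.percent_fat == pytest.approx((4.95 / d - 4.50) * 100, rel=1e-12)

    def test_eq1_female_adult_band(self):
        s = make_subject(sex="female", age=17.2,
                         skinfolds={"biceps": 5, "triceps": 5, "suprailiac": 5,
                                    "subscapular": 5})
        est = eq1_durnin(s)
        d = 1.1549 - 0.0678 * math.log10(20.0)
        assert est.density == pytest.approx(d, rel=1e-12)

    def test_eq1_unit_density_inversion(self):
        # fold sum solving D = 1.0 exactly gives the Siri value at D=1
        target_sum = 10 ** ((1.1533 - 1.0) / 0.0643)
        s = make_subject(age=15.0, skinfolds={k: target_sum / 4 for k in
                                              ("biceps", "triceps", "suprailiac", "subscapular")})
        est = eq1_durnin(s)
        assert est.density == pytest.approx(1.0, rel=1e-12)
        assert est.percent_fat == pytest.approx(45.0, rel=1e-9)

    def test_eq2_both_sexes_and_offset(self):
        m = eq2_boileau(make_subject(skinfolds={"triceps": 10, "subscapular": 10}))
        f = eq2_boileau(make_subject(sex="female",
                                     skinfolds={"triceps": 10, "subscapular": 10}))
        assert m.percent_fat == pytest.approx(1.35 * 20 - 0.012 * 400 - 4.4, rel=1e-12)
        assert f.percent_fat == pytest.approx(19.8, rel=1e-12)
        assert f.percent_fat - m.percent_fat == pytest.approx(2.0, abs=1e-12)

    def test_eq3_both_sexes(self):
        m = eq3_slaughter_tc(make_subject(skinfolds={"triceps": 10, "calf": 10}))
        f = eq3_slaughter_tc(make_subject(sex="female",
                                          skinfolds={"triceps": 10, "calf": 10}))
        assert m.percent_fat == pytest.approx(15.7, rel=1e-12)
        assert f.percent_fat == pytest.approx(17.3, rel=1e-12)

    def test_eq4_low_branch_intercepts(self):
        folds = {"triceps": 10, "subscapular": 10}
        white = eq4_slaughter_ts(make_subject(skinfolds=folds))
        black = eq4_slaughter_ts(make_subject(race="nonwhite", skinfolds=folds))
        assert white.percent_fat == pytest.approx(1.21 * 20 - 0.008 * 400 - 5.5, rel=1e-12)
        assert black.percent_fat - white.percent_fat == pytest.approx(-1.3, abs=1e-12)

    def test_eq4_high_branch_female(self):
        est = eq4_slaughter_ts(make_subject(sex="female",
                                            skinfolds={"triceps": 20, "subscapular": 20}))
        assert est.percent_fat == pytest.approx(0.546 * 40 + 9.7, rel=1e-12)

    def test_eq4_boundary_sum_takes_quadratic_branch(self):
        # the published footnotes say "<35" and ">35"; 35 resolves quadratic
        folds = {"triceps": 17.5, "subscapular": 17.5}
        est = eq4_slaughter_ts(make_subject(sex="female", skinfolds=folds))
        assert est.percent_fat == pytest.approx(1.33 * 35 - 0.013 * 35**2 - 2.5, rel=1e-12)

    def test_eq4_switch_is_discontinuous(self):
        # the 35 mm switch is a documented jump, not a continuous splice
        lo = eq4_slaughter_ts(make_subject(skinfolds={"triceps": 17.45, "subscapular": 17.45}))
        hi = eq4_slaughter_ts(make_subject(skinfolds={"triceps": 17.55, "subscapular": 17.55}))
        assert abs(hi.percent_fat - lo.percent_fat) > 1.0

    def test_eq5_age_terms_vanish_at_male_reference_age(self):
        s = make_subject(age=2.0, skinfolds={"biceps": 5, "triceps": 5,
                                             "suprailiac": 5, "subscapular": 5})
        with pytest.warns(UserWarning):  # age below the adolescent soft bound
            s = dataclasses.replace(s)
        est = eq5_weststrate(s)
        d = 1.1315 - 0.0719 * math.log10(20.0)
        assert est.density == pytest.approx(d, rel=1e-12)
        assert est.percent_fat == pytest.approx(562.0 / d - 525.0, rel=1e-12)

    def test_eq5_male_adolescent(self):
        s = make_subject(age=17.0, skinfolds={"biceps": 5, "triceps": 5,
                                              "suprailiac": 5, "subscapular": 5})
        est = eq5_weststrate(s)
        d = (1.1315 + 0.0018 * 15) - (0.0719 - 0.0006 * 15) * math.log10(20.0)
        assert est.density == pytest.approx(d, rel=1e-12)
        assert est.percent_fat == pytest.approx((562 - 4.2 * 15) / d - (525 - 4.7 * 15),
                                                rel=1e-12)

    def test_eq5_female_age_term_variant(self):
        folds = {"biceps": 6, "triceps": 8, "suprailiac": 7, "subscapular": 7}
        s = make_subject(sex="female", age=16.0, skinfolds=folds)
        printed = eq5_weststrate(s)
        variant = eq5_weststrate(s, female_consistent_age_term=True)
        d_printed = (1.1350 + 0.0031 * 6.0) - (0.0719 - 0.0003 * 14.0) * math.log10(28.0)
        d_variant = (1.1350 + 0.0031 * 6.0) - (0.0719 - 0.0003 * 6.0) * math.log10(28.0)
        assert printed.density == pytest.approx(d_printed, rel=1e-12)
        assert variant.density == pytest.approx(d_variant, rel=1e-12)

    def test_eq5_monotone_in_fold_sum(self):
        prev = -np.inf
        for total in np.linspace(20, 180, 30):
            s = make_subject(age=16.5, skinfolds={k: total / 4 for k in
                                                  ("biceps", "triceps", "suprailiac", "subscapular")})
            pbf = eq5_weststrate(s).percent_fat
            assert pbf > prev
            prev = pbf

    def test_eq6_male(self):
        # brachial perimeter chosen so arm muscle circumference is exactly 25
        s = make_subject(weight=60.0, height=170.0, resistance=500.0,
                         brachial_perimeter=25.0 + math.pi,
                         skinfolds={"calf": 10, "midaxillary": 8, "triceps": 10})
        est = eq6_guo(s)
        ffm = 0.646 * 60 - 0.116 * 10 - 0.375 * 8 + 0.475 * 25 + 0.156 * (170**2 / 500) - 2.932
        assert est.ffm == pytest.approx(ffm, rel=1e-12)
        assert est.percent_fat == pytest.approx(100 * (60 - ffm) / 60, rel=1e-12)

    def test_eq6_female(self):
        s = make_subject(sex="female", weight=55.0, height=160.0, resistance=600.0,
                         skinfolds={"calf": 12, "midaxillary": 10,
                                    "triceps": 14, "subscapular": 12})
        est = eq6_guo(s)
        ffm = (0.682 * 55 - 0.185 * 12 - 0.244 * 14 - 0.202 * 12
               + 0.182 * (160**2 / 600) + 4.338)
        assert est.ffm == pytest.approx(ffm, rel=1e-12)

    def test_eq7_both_sexes(self):
        m = eq7_deurenberg90(make_subject(skinfolds={k: 25.0 for k in
                                                     ("biceps", "triceps", "suprailiac", "subscapular")}))
        assert m.percent_fat == pytest.approx(18.88 * 2 - 15.58, rel=1e-12)
        root = 10 ** (15.58 / 18.88)
        z = eq7_deurenberg90(make_subject(skinfolds={k: root / 4 for k in
                                                     ("biceps", "triceps", "suprailiac", "subscapular")}))
        assert z.percent_fat == pytest.approx(0.0, abs=1e-9)

    def test_eq7_negative_result_flagged_not_clamped(self):
        f = eq7_deurenberg90(make_subject(sex="female",
                                          skinfolds={k: 2.5 for k in
                                                     ("biceps", "triceps", "suprailiac", "subscapular")}))
        assert f.percent_fat == pytest.approx(39.02 * 1 - 43.49, rel=1e-9)
        assert f.percent_fat < 0
        assert f.out_of_range

    def test_eq8_adult_branch_and_sex_coefficient(self):
        m = eq8_deurenberg91(make_subject(age=17.0, weight=61.25, height=170.0))
        bmi = 61.25 / 1.70**2
        assert m.percent_fat == pytest.approx(1.2 * bmi + 0.23 * 17 - 10.8 - 5.4, rel=1e-12)
        f = eq8_deurenberg91(make_subject(sex="female", age=17.0, weight=61.25, height=170.0))
        assert m.percent_fat - f.percent_fat == pytest.approx(-10.8, abs=1e-12)

    def test_eq8_child_branch(self):
        m = eq8_deurenberg91(make_subject(age=15.4, weight=55.0, height=165.0))
        bmi = 55.0 / 1.65**2
        assert m.percent_fat == pytest.approx(1.51 * bmi - 0.70 * 15.4 - 3.6 + 1.4, rel=1e-12)

    def test_eq9(self):
        est = eq9_houtkooper(make_subject(weight=60.0, height=170.0, resistance=500.0))
        assert est.ffm == pytest.approx(0.61 * 57.8 + 15 + 1.31, rel=1e-12)
        assert est.percent_fat == pytest.approx(100 * (60 - 51.568) / 60, rel=1e-12)

    def test_eq10_all_four_forms(self):
        w_m = eq10_ellis(make_subject(weight=60.0, age=17.0))
        assert w_m.fat_mass == pytest.approx(0.534 * 60 - 1.59 * 17 + 3.03, rel=1e-12)
        assert w_m.percent_fat == pytest.approx(100 * 8.04 / 60, rel=1e-9)
        b_m = eq10_ellis(make_subject(race="nonwhite", weight=60.0, height=170.0))
        assert b_m.fat_mass == pytest.approx(0.594 * 60 - 0.381 * 170 + 36.0, rel=1e-12)
        w_f = eq10_ellis(make_subject(sex="female", weight=55.0, height=160.0, age=17.0))
        assert w_f.fat_mass == pytest.approx(0.642 * 55 - 0.120 * 160 - 0.606 * 17 + 8.98,
                                             rel=1e-12)
        b_f = eq10_ellis(make_subject(sex="female", race="nonwhite",
                                      weight=55.0, height=160.0, age=17.0))
        assert b_f.fat_mass == pytest.approx(0.653 * 55 - 0.163 * 160 - 0.298 * 17 + 10.7,
                                             rel=1e-12)


# ---------------------------------------------------------------------------
# Preconditions and error surfaces
# ---------------------------------------------------------------------------

class TestErrors:
    def test_eq1_age_outside_bands(self):
        with pytest.raises(UnsupportedAgeError):
            eq1_durnin(make_subject(age=14.6))
        with pytest.raises(UnsupportedAgeError):
            eq1_durnin(make_subject(age=19.0))

    def test_missing_skinfold_named(self):
        s = make_subject(skinfolds={"triceps": 10.0})
        with pytest.raises(MissingMeasurementError, match="subscapular"):
            eq2_boileau(s)

    def test_eq4_male_low_branch_needs_covariates(self):
        s = make_subject(race=None, skinfolds={"triceps": 10, "subscapular": 10})
        with pytest.raises(MissingCovariateError):
            eq4_slaughter_ts(s)

    def test_eq10_needs_race(self):
        with pytest.raises(MissingCovariateError):
            eq10_ellis(make_subject(race=None))

    def test_resistance_required(self):
        s = make_subject(resistance=None)
        with pytest.raises(MissingMeasurementError):
            eq9_houtkooper(s)

    def test_invalid_record_rejected(self):
        with pytest.raises(DomainError):
            make_subject(weight=-1.0)
        with pytest.raises(DomainError):
            make_subject(skinfolds={"triceps": 0.0})


# ---------------------------------------------------------------------------
# Battery orchestration, BIA bindings, classification
# ---------------------------------------------------------------------------

class TestBattery:
    def test_complete_record_yields_all_twelve(self, male_subject):
        result = evaluate_battery(male_subject)
        assert [e.method for e in result] == list(METHODS)
        assert not result.skipped

    def test_missing_resistance_skips_impedance_methods(self, male_subject):
        s = dataclasses.replace(male_subject, resistance=None)
        result = evaluate_battery(s)
        assert {sk.method for sk in result.skipped} == {"EQ6", "EQ9", "BIA1"}
        assert all(sk.reason for sk in result.skipped)

    def test_strict_mode_raises_instead_of_skipping(self, male_subject):
        s = dataclasses.replace(male_subject, resistance=None)
        with pytest.raises(MissingMeasurementError):
            evaluate_battery(s, strict=True)

    def test_empty_method_set_is_usage_error(self, male_subject):
        with pytest.raises(DomainError):
            evaluate_battery(male_subject, [])

    def test_deterministic(self, female_subject):
        a = evaluate_battery(female_subject)
        b = evaluate_battery(female_subject)
        assert [(e.method, e.percent_fat) for e in a] == [
            (e.method, e.percent_fat) for e in b
        ]

    def test_bia1_default_binding_matches_eq9(self, male_subject):
        assert bia1_percent_fat(male_subject).percent_fat == pytest.approx(
            eq9_houtkooper(male_subject).percent_fat, rel=1e-12
        )

    def test_bia1_guo_binding_matches_eq6(self, male_subject):
        assert bia1_percent_fat(male_subject, equation="guo").percent_fat == pytest.approx(
            eq6_guo(male_subject).percent_fat, rel=1e-12
        )

    def test_amc_helper(self):
        assert arm_muscle_circumference(28.0, 10.0) == pytest.approx(
            28.0 - math.pi, rel=1e-12
        )

    @pytest.mark.parametrize("pbf,sex,expected", [
        (0.0, Sex.MALE, False),
        (99.0, Sex.MALE, True),
        (20.0, Sex.MALE, True),      # boundary inclusive
        (19.999, Sex.MALE, False),
        (25.0, Sex.FEMALE, True),
        (24.999, Sex.FEMALE, False),
    ])
    def test_excess_fat_classification(self, pbf, sex, expected):
        assert classify_excess_fat(pbf, sex) is expected


# ---------------------------------------------------------------------------
# Invariants: conservation, monotonicity, oracle equivalence
# ---------------------------------------------------------------------------

class TestInvariants:
    def test_ffm_fat_mass_conservation(self, rng):
        for i in range(200):
            s = random_subject(rng, i)
            for est in evaluate_battery(s, ["EQ6", "EQ9", "BIA1"], strict=True):
                assert est.ffm + est.fat_mass == pytest.approx(s.weight, abs=1e-9)

    def test_skinfold_methods_monotone_in_each_fold(self):
        # grid scan over the physiological range, one fold at a time
        base = {"biceps": 10.0, "triceps": 10.0, "suprailiac": 10.0,
                "subscapular": 10.0, "midaxillary": 10.0, "calf": 10.0}
        fns = {"EQ1": eq1_durnin, "EQ2": eq2_boileau, "EQ3": eq3_slaughter_tc,
               "EQ5": eq5_weststrate, "EQ7": eq7_deurenberg90}
        uses = {"EQ1": ("biceps", "triceps", "suprailiac", "subscapular"),
                "EQ2": ("triceps", "subscapular"),
                "EQ3": ("triceps", "calf"),
                "EQ5": ("biceps", "triceps", "suprailiac", "subscapular"),
                "EQ7": ("biceps", "triceps", "suprailiac", "subscapular")}
        for method, fn in fns.items():
            for site in uses[method]:
                prev = -np.inf
                for value in np.linspace(5.0, 45.0, 9):
                    folds = dict(base, **{site: value})
                    pbf = fn(make_subject(age=16.0, skinfolds=folds)).percent_fat
                    assert pbf >= prev, f"{method} not monotone in {site}"
                    prev = pbf

    def test_battery_matches_independent_oracle(self, rng):
        from adipoquant.experiments import battery_oracle_max_diff

        result = battery_oracle_max_diff(oracle_percent_fat, 1000, seed=20230516)
        assert result["max_abs_diff"] < 1e-9

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=60, deadline=None)
    def test_eq10_percent_fat_inverts_to_fat_mass(self, i):
        s = random_subject(np.random.default_rng(i), i)
        est = eq10_ellis(s)
        assert est.percent_fat * s.weight / 100.0 == pytest.approx(est.fat_mass, abs=1e-9)
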