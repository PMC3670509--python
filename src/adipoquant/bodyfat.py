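"""Anthropometric and bioimpedance body-fat estimation for adolescents.

Twelve estimators of percent body fat (%BF) are provided: ten published
anthropometric prediction equations (``EQ1``–``EQ10``) and two bioimpedance
routes (``BIA1``: resistance fed through a fat-free-mass equation; ``BIA2``:
a direct %BF reading from a vertical eight-electrode device).

Three families of equations appear:

* densitometric — a linear model in log10 of a four-skinfold sum predicts
  whole-body density D (g/mL), converted to %BF by the Siri two-compartment
  formula ``%BF = (4.95/D − 4.50) × 100`` (EQ1) or by an age-adjusted
  Siri-like expression (EQ5);
* direct %BF — quadratic or linear forms in skinfold sums, BMI or weight
  (EQ2, EQ3, EQ4, EQ7, EQ8, EQ10);
* fat-free mass — FFM (kg) predicted from anthropometry and the impedance
  index Ht²/R; fat mass is then ``weight − FFM`` and
  ``%BF = 100 · fat mass / weight`` (EQ6, EQ9, BIA1).

Every ``log`` in the published equations is base 10 (the densitometry
convention); this is centralised in :func:`_log10`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

from .errors import (
    DomainError,
    MissingCovariateError,
    MissingMeasurementError,
    UnsupportedAgeError,
)

__all__ = [
    "Sex",
    "Race",
    "Maturation",
    "SubjectRecord",
    "BodyFatEstimate",
    "BatteryResult",
    "SkippedMethod",
    "METHODS",
    "FOUR_SKINFOLDS",
    "SKINFOLD_SITES",
    "siri_percent_fat",
    "density_from_siri",
    "arm_muscle_circumference",
    "eq1_durnin",
    "eq2_boileau",
    "eq3_slaughter_tc",
    "eq4_slaughter_ts",
    "eq5_weststrate",
    "eq6_guo",
    "eq7_deurenberg90",
    "eq8_deurenberg91",
    "eq9_houtkooper",
    "eq10_ellis",
    "bia1_percent_fat",
    "bia2_percent_fat",
    "evaluate_battery",
    "battery_frame",
    "classify_excess_fat",
    "DEFAULT_EXCESS_FAT_THRESHOLDS",
]


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class Race(str, Enum):
    WHITE = "white"
    NONWHITE = "nonwhite"


class Maturation(str, Enum):
    PREPUBESCENT = "prepubescent"
    PUBESCENT = "pubescent"
    POSTPUBESCENT = "postpubescent"


#: Canonical method order used everywhere (tables, grids, tie-breaks).
METHODS: tuple[str, ...] = (
    "EQ1", "EQ2", "EQ3", "EQ4", "EQ5", "EQ6", "EQ7", "EQ8", "EQ9", "EQ10",
    "BIA1", "BIA2",
)

SKINFOLD_SITES: tuple[str, ...] = (
    "biceps", "triceps", "subscapular", "suprailiac", "midaxillary", "calf",
)

#: The four-fold sum used by the densitometric and log-sum equations.
FOUR_SKINFOLDS: tuple[str, ...] = ("biceps", "triceps", "suprailiac", "subscapular")

#: Lohman "risk of overweight or above" %BF thresholds (male, female),
#: boundary inclusive.  Not printed in the source tables; configurable.
DEFAULT_EXCESS_FAT_THRESHOLDS: tuple[float, float] = (20.0, 25.0)


def _log10(x: float) -> float:
    """log base 10 — the convention for every 'log' in the published equations."""
    return math.log10(x)


def _coerce(enum_cls, value):
    if value is None:
        return None
    if isinstance(value, enum_cls):
        return value
    return enum_cls(str(value).lower())


@dataclass
class SubjectRecord:
    """One adolescent's demographics, anthropometry and maturation.

    Heights are centimetres throughout; skinfolds millimetres; weight kg;
    resistance ohms.  ``group`` is a study label (eutrophic / overweight)
    carried as an input — it is never recomputed here.
    """

    subject_id: str
    sex: Sex
    age: float
    weight: float
    height: float
    race: Optional[Race] = None
    maturation: Optional[Maturation] = Maturation.POSTPUBESCENT
    skinfolds: dict = field(default_factory=dict)
    brachial_perimeter: Optional[float] = None
    resistance: Optional[float] = None
    bia2_percent_fat: Optional[float] = None
    group: Optional[str] = None

    def __post_init__(self) -> None:
        self.sex = _coerce(Sex, self.sex)
        self.race = _coerce(Race, self.race)
        self.maturation = _coerce(Maturation, self.maturation)
        if self.weight is None or self.weight <= 0:
            raise DomainError(f"subject {self.subject_id}: weight must be > 0, got {self.weight}")
        if self.height is None or self.height <= 0:
            raise DomainError(f"subject {self.subject_id}: height must be > 0, got {self.height}")
        for site, value in self.skinfolds.items():
            if value is not None and value <= 0:
                raise DomainError(
                    f"subject {self.subject_id}: skinfold '{site}' must be > 0, got {value}"
                )
        if self.resistance is not None and self.resistance <= 0:
            raise DomainError(
                f"subject {self.subject_id}: resistance must be > 0, got {self.resistance}"
            )
        if not 10.0 <= self.age <= 25.0:
            warnings.warn(
                f"subject {self.subject_id}: age {self.age} outside [10, 25]; the "
                "prediction equations were developed for adolescents",
                stacklevel=2,
            )

    # -- convenience accessors -------------------------------------------------

    def skinfold(self, site: str, method: str) -> float:
        value = self.skinfolds.get(site)
        if value is None:
            raise MissingMeasurementError(
                f"{method}: subject {self.subject_id} lacks skinfold '{site}'"
            )
        return float(value)

    def skinfold_sum(self, sites: Sequence[str], method: str) -> float:
        return sum(self.skinfold(s, method) for s in sites)

    @property
    def bmi(self) -> float:
        """Body mass index, kg/m² (height converted cm → m here only)."""
        return self.weight / (self.height / 100.0) ** 2

    @property
    def height_sq_over_r(self) -> float:
        if self.resistance is None:
            raise MissingMeasurementError(
                f"subject {self.subject_id} lacks BIA resistance"
            )
        return self.height**2 / self.resistance

    @property
    def completed_years(self) -> int:
        """Decimal age truncated to completed years, used for branch selection."""
        return int(self.age)


@dataclass
class BodyFatEstimate:
    """One method's %BF for one subject, with intermediates.

    ``density`` is populated only by the densitometric methods (EQ1, EQ5);
    ``ffm`` only by the FFM-based ones (EQ6, EQ9, BIA1).  ``out_of_range``
    marks raw results outside [0, 100)%, which are retained, never clamped.
    """

    method: str
    subject_id: str
    percent_fat: float
    fat_mass: float
    density: Optional[float] = None
    ffm: Optional[float] = None
    excess_fat_flag: Optional[bool] = None
    out_of_range: bool = False


@dataclass
class SkippedMethod:
    method: str
    reason: str


@dataclass
class BatteryResult:
    """Estimates in canonical method order plus structured skips."""

    estimates: list
    skipped: list

    def __iter__(self):
        return iter(self.estimates)

    def __len__(self):
        return len(self.estimates)

    def by_method(self) -> dict:
        return {e.method: e for e in self.estimates}


# ---------------------------------------------------------------------------
# Densitometric conversion
# ---------------------------------------------------------------------------

def siri_percent_fat(density: float) -> float:
    """Convert whole-body density (g/mL) to %BF: ``(4.95/D − 4.50) × 100``.

    Density must be physiological, in (0.9, 1.2) g/mL.
    """
    if density is None or not 0.9 < density < 1.2:
        raise DomainError(
            f"density {density!r} g/mL outside the physiological bound (0.9, 1.2)"
        )
    return (4.95 / density - 4.50) * 100.0


def density_from_siri(percent_fat: float) -> float:
    """Inverse of :func:`siri_percent_fat` (used for round-trip checks)."""
    return 4.95 / (percent_fat / 100.0 + 4.50)


def arm_muscle_circumference(brachial_perimeter: float, triceps: float) -> float:
    """Arm muscle circumference (cm) = brachial perimeter − π·triceps/10.

    The standard derivation from a measured brachial perimeter (cm) and a
    triceps skinfold (mm; hence the /10).
    """
    return brachial_perimeter - math.pi * triceps / 10.0


def _finish_percent_fat(
    method: str, subject: SubjectRecord, percent_fat: float,
    density: Optional[float] = None,
) -> BodyFatEstimate:
    fat_mass = percent_fat * subject.weight / 100.0
    return BodyFatEstimate(
        method=method,
        subject_id=subject.subject_id,
        percent_fat=percent_fat,
        fat_mass=fat_mass,
        density=density,
        out_of_range=not (0.0 <= percent_fat < 100.0),
    )


def _finish_ffm(method: str, subject: SubjectRecord, ffm: float) -> BodyFatEstimate:
    # Fat mass is weight minus FFM, exactly; %BF follows as 100·fat/weight.
    fat_mass = subject.weight - ffm
    percent_fat = 100.0 * fat_mass / subject.weight
    return BodyFatEstimate(
        method=method,
        subject_id=subject.subject_id,
        percent_fat=percent_fat,
        fat_mass=fat_mass,
        ffm=ffm,
        out_of_range=not (0.0 <= percent_fat < 100.0),
    )


# ---------------------------------------------------------------------------
# The ten anthropometric equations
# ---------------------------------------------------------------------------

# EQ1 — Durnin-family densitometry.  Age 15–16 uses the adolescent
# (Durnin & Rahaman) coefficients, 17–18 the adult (Durnin & Womersley) ones.
_EQ1_COEFFS = {
    # (age band, sex): (intercept, slope on log10 of the 4-fold sum)
    ("15-16", Sex.MALE): (1.1533, 0.0643),
    ("15-16", Sex.FEMALE): (1.1369, 0.0598),
    ("17-18", Sex.MALE): (1.1620, 0.0630),
    ("17-18", Sex.FEMALE): (1.1549, 0.0678),
}


def eq1_durnin(subject: SubjectRecord) -> BodyFatEstimate:
    """Skinfold densitometry: D linear in log10(4-fold sum), then Siri."""
    years = subject.completed_years
    if years in (15, 16):
        band = "15-16"
    elif years in (17, 18):
        band = "17-18"
    else:
        raise UnsupportedAgeError(
            f"EQ1: age {subject.age} outside the 15-18 y coefficient bands"
        )
    c0, c1 = _EQ1_COEFFS[(band, subject.sex)]
    total = subject.skinfold_sum(FOUR_SKINFOLDS, "EQ1")
    density = c0 - c1 * _log10(total)
    est = _finish_percent_fat("EQ1", subject, siri_percent_fat(density), density=density)
    return est


def eq2_boileau(subject: SubjectRecord) -> BodyFatEstimate:
    """Quadratic in triceps+subscapular; sex enters through the constant."""
    s = subject.skinfold("triceps", "EQ2") + subject.skinfold("subscapular", "EQ2")
    const = -4.4 if subject.sex is Sex.MALE else -2.4
    pbf = 1.35 * s - 0.012 * s**2 + const
    return _finish_percent_fat("EQ2", subject, pbf)


def eq3_slaughter_tc(subject: SubjectRecord) -> BodyFatEstimate:
    """Linear in triceps+calf."""
    s = subject.skinfold("triceps", "EQ3") + subject.skinfold("calf", "EQ3")
    if subject.sex is Sex.MALE:
        pbf = 0.735 * s + 1.0
    else:
        pbf = 0.610 * s + 5.1
    return _finish_percent_fat("EQ3", subject, pbf)


# Male intercept of the low-sum branch of EQ4, by race and maturation.
_EQ4_INTERCEPTS = {
    (Race.NONWHITE, Maturation.PREPUBESCENT): -3.5,
    (Race.NONWHITE, Maturation.PUBESCENT): -5.2,
    (Race.NONWHITE, Maturation.POSTPUBESCENT): -6.8,
    (Race.WHITE, Maturation.PREPUBESCENT): -1.7,
    (Race.WHITE, Maturation.PUBESCENT): -3.4,
    (Race.WHITE, Maturation.POSTPUBESCENT): -5.5,
}


def eq4_slaughter_ts(subject: SubjectRecord) -> BodyFatEstimate:
    """Triceps+subscapular with a 35 mm branch switch.

    Sums of exactly 35 mm take the quadratic branch (the published footnotes
    say "<35" and ">35", orphaning 35; we resolve it to the quadratic form).
    The male quadratic intercept varies with race and maturation.
    """
    s = subject.skinfold("triceps", "EQ4") + subject.skinfold("subscapular", "EQ4")
    if s <= 35.0:
        if subject.sex is Sex.MALE:
            if subject.race is None or subject.maturation is None:
                raise MissingCovariateError(
                    "EQ4: male low-sum branch needs race and maturation for the intercept"
                )
            intercept = _EQ4_INTERCEPTS[(subject.race, subject.maturation)]
            pbf = 1.21 * s - 0.008 * s**2 + intercept
        else:
            pbf = 1.33 * s - 0.013 * s**2 - 2.5
    else:
        if subject.sex is Sex.MALE:
            pbf = 0.783 * s + 1.6
        else:
            pbf = 0.546 * s + 9.7
    return _finish_percent_fat("EQ4", subject, pbf)


def eq5_weststrate(
    subject: SubjectRecord, *, female_consistent_age_term: bool = False
) -> BodyFatEstimate:
    """Age-adjusted skinfold densitometry.

    Density comes from a sex-specific, age-modulated linear model in log10 of
    the four-fold sum; %BF from an age-adjusted Siri-like form:

    * male (age ≥ 2):   ``%BF = (562 − 4.2(A−2))/D − (525 − 4.7(A−2))``
      with ``D = (1.1315 + 0.0018(A−2)) − (0.0719 − 0.0006(A−2))·log10(Σ4)``
    * female (age ≥ 10): ``%BF = (553 − 7.3(A−10))/D − (514 − 8.0(A−10))``
      with ``D = (1.1350 + 0.0031(A−10)) − (0.0719 − 0.0003(A−2))·log10(Σ4)``

    The published female density multiplier mixes (A−2) with the (A−10) of
    its additive term; we implement it as printed.  Passing
    ``female_consistent_age_term=True`` switches the multiplier to (A−10).
    """
    total = subject.skinfold_sum(FOUR_SKINFOLDS, "EQ5")
    a = subject.age
    if subject.sex is Sex.MALE:
        if a < 2.0:
            raise UnsupportedAgeError(f"EQ5: male form defined for ages ≥ 2, got {a}")
        density = (1.1315 + 0.0018 * (a - 2.0)) - (
            (0.0719 - 0.0006 * (a - 2.0)) * _log10(total)
        )
        pbf = (562.0 - 4.2 * (a - 2.0)) / density - (525.0 - 4.7 * (a - 2.0))
    else:
        if a < 10.0:
            raise UnsupportedAgeError(f"EQ5: female form defined for ages ≥ 10, got {a}")
        mult_age = (a - 10.0) if female_consistent_age_term else (a - 2.0)
        density = (1.1350 + 0.0031 * (a - 10.0)) - (
            (0.0719 - 0.0003 * mult_age) * _log10(total)
        )
        pbf = (553.0 - 7.3 * (a - 10.0)) / density - (514.0 - 8.0 * (a - 10.0))
    est = _finish_percent_fat("EQ5", subject, pbf, density=density)
    return est


def eq6_guo(subject: SubjectRecord) -> BodyFatEstimate:
    """FFM from weight, skinfolds, arm muscle circumference and Ht²/R."""
    ht2_r = subject.height_sq_over_r  # raises on missing resistance
    calf = subject.skinfold("calf", "EQ6")
    midax = subject.skinfold("midaxillary", "EQ6")
    if subject.sex is Sex.MALE:
        if subject.brachial_perimeter is None:
            raise MissingMeasurementError(
                f"EQ6: subject {subject.subject_id} lacks brachial perimeter "
                "(needed for arm muscle circumference)"
            )
        amc = arm_muscle_circumference(
            subject.brachial_perimeter, subject.skinfold("triceps", "EQ6")
        )
        ffm = (
            0.646 * subject.weight
            - 0.116 * calf
            - 0.375 * midax
            + 0.475 * amc
            + 0.156 * ht2_r
            - 2.932
        )
    else:
        triceps = subject.skinfold("triceps", "EQ6")
        subscap = subject.skinfold("subscapular", "EQ6")
        ffm = (
            0.682 * subject.weight
            - 0.185 * calf
            - 0.244 * triceps
            - 0.202 * subscap
            + 0.182 * ht2_r
            + 4.338
        )
    return _finish_ffm("EQ6", subject, ffm)


def eq7_deurenberg90(subject: SubjectRecord) -> BodyFatEstimate:
    """%BF linear in log10 of the four-fold sum, sex-specific coefficients."""
    total = subject.skinfold_sum(FOUR_SKINFOLDS, "EQ7")
    if subject.sex is Sex.MALE:
        pbf = 18.88 * _log10(total) - 15.58
    else:
        pbf = 39.02 * _log10(total) - 43.49
    return _finish_percent_fat("EQ7", subject, pbf)


def eq8_deurenberg91(subject: SubjectRecord) -> BodyFatEstimate:
    """%BF from BMI, age and sex; child (≤15 y) vs adult (≥16 y) coefficients.

    Sex is coded masculine = 1, feminine = 0.  BMI is computed internally
    from weight (kg) and height (cm).
    """
    s = 1.0 if subject.sex is Sex.MALE else 0.0
    bmi = subject.bmi
    if subject.completed_years <= 15:
        pbf = 1.51 * bmi - 0.70 * subject.age - 3.6 * s + 1.4
    else:
        pbf = 1.2 * bmi + 0.23 * subject.age - 10.8 * s - 5.4
    return _finish_percent_fat("EQ8", subject, pbf)


def eq9_houtkooper(subject: SubjectRecord) -> BodyFatEstimate:
    """FFM = 0.61·Ht²/R + 0.25·Wt + 1.31 (sex-common, adolescent-specific)."""
    ffm = 0.61 * subject.height_sq_over_r + 0.25 * subject.weight + 1.31
    return _finish_ffm("EQ9", subject, ffm)


def eq10_ellis(subject: SubjectRecord) -> BodyFatEstimate:
    """Fat mass (kg) directly from weight, height, age; sex × race forms.

    Study "non-whites" are mapped onto the black-coefficient forms.
    """
    if subject.race is None:
        raise MissingCovariateError(
            f"EQ10: subject {subject.subject_id} lacks race (selects coefficients)"
        )
    wt, ht, a = subject.weight, subject.height, subject.age
    if subject.sex is Sex.MALE:
        if subject.race is Race.WHITE:
            fat = 0.534 * wt - 1.59 * a + 3.03
        else:
            fat = 0.594 * wt - 0.381 * ht + 36.0
    else:
        if subject.race is Race.WHITE:
            fat = 0.642 * wt - 0.120 * ht - 0.606 * a + 8.98
        else:
            fat = 0.653 * wt - 0.163 * ht - 0.298 * a + 10.7
    pbf = 100.0 * fat / wt
    est = _finish_percent_fat("EQ10", subject, pbf)
    est.fat_mass = fat  # identical up to rounding; keep the direct value
    return est


# ---------------------------------------------------------------------------
# Bioimpedance routes
# ---------------------------------------------------------------------------

_BIA1_EQUATIONS = {"houtkooper": eq9_houtkooper, "guo": eq6_guo}


def bia1_percent_fat(subject: SubjectRecord, *, equation: str = "houtkooper") -> BodyFatEstimate:
    """Horizontal tetra-polar BIA: resistance fed through an FFM equation.

    The device-internal prediction equation is proprietary; the FFM binding
    is configurable and defaults to the Houtkooper equation (EQ9), the only
    published resistance-based FFM form covering both sexes here.
    """
    try:
        fn = _BIA1_EQUATIONS[equation]
    except KeyError:
        raise DomainError(
            f"BIA1: unknown FFM equation '{equation}' (choose from {sorted(_BIA1_EQUATIONS)})"
        ) from None
    est = fn(subject)
    return replace(est, method="BIA1")


def bia2_percent_fat(subject: SubjectRecord) -> BodyFatEstimate:
    """Vertical eight-electrode BIA: %BF taken as a direct device reading."""
    if subject.bia2_percent_fat is None:
        raise MissingMeasurementError(
            f"BIA2: subject {subject.subject_id} lacks a direct BIA %BF reading"
        )
    return _finish_percent_fat("BIA2", subject, float(subject.bia2_percent_fat))


# ---------------------------------------------------------------------------
# Battery orchestration and classification
# ---------------------------------------------------------------------------

def classify_excess_fat(
    percent_fat: float,
    sex: Sex,
    thresholds: tuple[float, float] = DEFAULT_EXCESS_FAT_THRESHOLDS,
) -> bool:
    """Lohman-style excess-fat flag: %BF at or above the sex threshold.

    "Risk of overweight" and above are pooled as excess fat; the boundary is
    inclusive.
    """
    sex = _coerce(Sex, sex)
    cutoff = thresholds[0] if sex is Sex.MALE else thresholds[1]
    return percent_fat >= cutoff


_DISPATCH = {
    "EQ1": eq1_durnin,
    "EQ2": eq2_boileau,
    "EQ3": eq3_slaughter_tc,
    "EQ4": eq4_slaughter_ts,
    "EQ5": eq5_weststrate,
    "EQ6": eq6_guo,
    "EQ7": eq7_deurenberg90,
    "EQ8": eq8_deurenberg91,
    "EQ9": eq9_houtkooper,
    "EQ10": eq10_ellis,
}


def evaluate_battery(
    subject: SubjectRecord,
    methods: Iterable[str] | str = "all",
    *,
    bia1_equation: str = "houtkooper",
    excess_thresholds: tuple[float, float] = DEFAULT_EXCESS_FAT_THRESHOLDS,
    eq5_female_consistent: bool = False,
    strict: bool = False,
) -> BatteryResult:
    """Evaluate the requested methods on one subject, in canonical order.

    Methods whose required measurements are absent become structured
    :class:`SkippedMethod` entries (or errors when ``strict``).  Each
    estimate carries the Lohman excess-fat flag.
    """
    if methods == "all":
        selected = list(METHODS)
    else:
        selected = [m.upper() for m in methods]
        unknown = [m for m in selected if m not in METHODS]
        if unknown:
            raise DomainError(f"unknown method id(s): {unknown}")
    if not selected:
        raise DomainError("empty method set: nothing to evaluate")
    selected = [m for m in METHODS if m in selected]

    estimates: list[BodyFatEstimate] = []
    skipped: list[SkippedMethod] = []
    for method in selected:
        try:
            if method == "BIA1":
                est = bia1_percent_fat(subject, equation=bia1_equation)
            elif method == "BIA2":
                est = bia2_percent_fat(subject)
            elif method == "EQ5":
                est = eq5_weststrate(
                    subject, female_consistent_age_term=eq5_female_consistent
                )
            else:
                est = _DISPATCH[method](subject)
        except (MissingMeasurementError, MissingCovariateError, UnsupportedAgeError) as exc:
            if strict:
                raise
            skipped.append(SkippedMethod(method=method, reason=str(exc)))
            continue
        est.excess_fat_flag = classify_excess_fat(
            est.percent_fat, subject.sex, excess_thresholds
        )
        estimates.append(est)
    return BatteryResult(estimates=estimates, skipped=skipped)


def battery_frame(subjects: Sequence[SubjectRecord], methods="all", **kwargs):
    """Tidy per-(subject, method) table of battery output.

    Returns a pandas DataFrame with one row per successful estimate plus a
    list of per-subject skips.
    """
    import pandas as pd

    rows = []
    skips = []
    for subject in subjects:
        result = evaluate_battery(subject, methods, **kwargs)
        for est in result.estimates:
            rows.append(
                {
                    "subject_id": est.subject_id,
                    "method": est.method,
                    "percent_fat": est.percent_fat,
                    "fat_mass": est.fat_mass,
                    "ffm": est.ffm,
                    "density": est.density,
                    "excess_fat_flag": est.excess_fat_flag,
                    "out_of_range": est.out_of_range,
                }
            )
        for sk in result.skipped:
            skips.append(
                {"subject_id": subject.subject_id, "method": sk.method, "reason": sk.reason}
            )
    frame = pd.DataFrame(
        rows,
        columns=[
            "subject_id", "method", "percent_fat", "fat_mass", "ffm", "density",
            "excess_fat_flag", "out_of_range",
        ],
    )
    return frame, skips


def percent_fat_wide(frame) -> "object":
    """Pivot the tidy battery frame to subjects × methods of %BF."""
    wide = frame.pivot(index="subject_id", columns="method", values="percent_fat")
    order = [m for m in METHODS if m in wide.columns]
    return wide[order]
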