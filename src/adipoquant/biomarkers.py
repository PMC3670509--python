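"""Derived cardiometabolic biomarkers and clinical risk flags.

Derivations (all pure functions of the fasting measurements):

* Friedewald LDL: ``LDL = TC − HDL − TG/5`` (mg/dL), valid for TG < 400 mg/dL;
* HOMA-IR: ``insulin (µU/mL) × glucose (mg/dL) / 405`` — the mass-unit
  HOMA1-IR convention (the molar form divides by 22.5);
* lipid ratios TC/HDL and LDL/HDL;
* BMI: ``weight / (height in m)²``.

Risk flags follow fixed clinical cutoffs with the comparator conventions of
the guidelines they come from (≥, ≤, >; see :class:`RiskCutoffs`).  The
module also provides the finite-population-corrected sample-size formula for
cross-sectional prevalence studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

from scipy.stats import norm

from .bodyfat import Sex, _coerce
from .errors import DomainError

__all__ = [
    "BiomarkerPanel",
    "RiskCutoffs",
    "RiskFlags",
    "DEFAULT_CUTOFFS",
    "friedewald_ldl",
    "homa_ir",
    "bmi",
    "risk_flags",
    "cross_sectional_sample_size",
    "round_half_up",
]


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals (report convention)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def friedewald_ldl(tc: float, hdl: float, tg: float) -> float:
    """Estimate LDL cholesterol (mg/dL) as ``TC − HDL − TG/5``.

    The TG/5 term approximates VLDL; the formula is invalid at
    TG ≥ 400 mg/dL, where LDL must be measured directly.
    """
    if tc <= 0 or hdl <= 0 or tg < 0:
        raise DomainError(f"Friedewald inputs must be positive: TC={tc}, HDL={hdl}, TG={tg}")
    if tg >= 400:
        raise DomainError(
            f"Friedewald formula invalid at TG={tg} mg/dL (≥ 400); supply a direct LDL"
        )
    return tc - hdl - tg / 5.0


def homa_ir(glucose: float, insulin: float) -> float:
    """HOMA-IR = insulin (µU/mL) × fasting glucose (mg/dL) / 405."""
    if glucose <= 0 or insulin <= 0:
        raise DomainError(f"HOMA-IR inputs must be positive: glucose={glucose}, insulin={insulin}")
    return insulin * glucose / 405.0


def bmi(weight: float, height: float) -> float:
    """Body mass index (kg/m²) from weight (kg) and height (cm)."""
    if weight <= 0 or height <= 0:
        raise DomainError(f"BMI inputs must be positive: weight={weight}, height={height}")
    return weight / (height / 100.0) ** 2


@dataclass
class BiomarkerPanel:
    """Fasting biochemistry and blood pressure with derived indices.

    Construct via :meth:`from_measurements` so the derived fields (LDL,
    ratios, HOMA-IR) are consistent by construction; :meth:`rederive`
    recomputes them (idempotent).
    """

    subject_id: str
    glucose: float
    insulin: float
    total_cholesterol: float
    hdl: float
    triglycerides: float
    uric_acid: float
    sbp: float
    dbp: float
    ldl: Optional[float] = None
    tc_hdl_ratio: Optional[float] = None
    ldl_hdl_ratio: Optional[float] = None
    homa_ir: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("glucose", "insulin", "total_cholesterol", "hdl",
                     "triglycerides", "uric_acid", "sbp", "dbp"):
            v = getattr(self, name)
            if v is None or v <= 0:
                raise DomainError(
                    f"subject {self.subject_id}: biomarker '{name}' must be > 0, got {v}"
                )

    @classmethod
    def from_measurements(cls, subject_id, glucose, insulin, total_cholesterol,
                          hdl, triglycerides, uric_acid, sbp, dbp) -> "BiomarkerPanel":
        panel = cls(subject_id, glucose, insulin, total_cholesterol, hdl,
                    triglycerides, uric_acid, sbp, dbp)
        panel.rederive()
        return panel

    def rederive(self) -> "BiomarkerPanel":
        self.ldl = friedewald_ldl(self.total_cholesterol, self.hdl, self.triglycerides)
        self.tc_hdl_ratio = self.total_cholesterol / self.hdl
        self.ldl_hdl_ratio = self.ldl / self.hdl
        self.homa_ir = homa_ir(self.glucose, self.insulin)
        return self


@dataclass(frozen=True)
class RiskCutoffs:
    """Clinical cutoffs with their printed comparator conventions.

    tc/ldl/tg/glucose/insulin/homa flags are inclusive lower bounds (≥);
    hdl is an inclusive upper bound (≤); uric acid is a strict upper bound
    (>), sex-specific by default with a pooled >7 mg/dL option; blood
    pressure flags at SBP ≥ 120 or DBP ≥ 80 mmHg.  The fasting-glucose and
    hyperinsulinemia cutoffs are guideline defaults, configurable.
    """

    tc: float = 150.0
    ldl: float = 100.0
    hdl: float = 45.0
    tg: float = 100.0
    glucose: float = 100.0
    insulin: float = 15.0
    homa: float = 3.16
    uric_acid_male: float = 7.0
    uric_acid_female: float = 6.0
    uric_acid_pooled: bool = False
    sbp: float = 120.0
    dbp: float = 80.0


DEFAULT_CUTOFFS = RiskCutoffs()

_COMPONENT_FLAGS = (
    "tc_high", "ldl_high", "hdl_low", "tg_high", "glucose_high",
    "hyperinsulinemia", "insulin_resistant", "uric_acid_high", "bp_high",
)


@dataclass
class RiskFlags:
    subject_id: str
    tc_high: bool
    ldl_high: bool
    hdl_low: bool
    tg_high: bool
    glucose_high: bool
    hyperinsulinemia: bool
    insulin_resistant: bool
    uric_acid_high: bool
    bp_high: bool
    risk_count: int = field(init=False)
    any_risk: bool = field(init=False)

    def __post_init__(self) -> None:
        components = [getattr(self, name) for name in _COMPONENT_FLAGS]
        self.risk_count = int(sum(components))
        self.any_risk = any(components)


def risk_flags(panel: BiomarkerPanel, sex: Sex,
               cutoffs: RiskCutoffs = DEFAULT_CUTOFFS) -> RiskFlags:
    """Evaluate every clinical risk flag on a derived panel."""
    sex = _coerce(Sex, sex)
    if panel.ldl is None or panel.homa_ir is None:
        panel = panel.rederive()
    if cutoffs.uric_acid_pooled:
        ua_cut = cutoffs.uric_acid_male
    else:
        ua_cut = cutoffs.uric_acid_male if sex is Sex.MALE else cutoffs.uric_acid_female
    return RiskFlags(
        subject_id=panel.subject_id,
        tc_high=panel.total_cholesterol >= cutoffs.tc,
        ldl_high=panel.ldl >= cutoffs.ldl,
        hdl_low=panel.hdl <= cutoffs.hdl,
        tg_high=panel.triglycerides >= cutoffs.tg,
        glucose_high=panel.glucose >= cutoffs.glucose,
        hyperinsulinemia=panel.insulin >= cutoffs.insulin,
        insulin_resistant=panel.homa_ir >= cutoffs.homa,
        uric_acid_high=panel.uric_acid > ua_cut,
        bp_high=panel.sbp >= cutoffs.sbp or panel.dbp >= cutoffs.dbp,
    )


def cross_sectional_sample_size(population: int, prevalence: float,
                                margin: float, confidence: float = 0.95) -> int:
    """Minimum n for a cross-sectional prevalence study.

    ``n0 = z²·p·(1−p)/d²`` with z the two-sided normal quantile for the
    confidence level, then the finite-population correction
    ``n = n0 / (1 + (n0 − 1)/N)``, rounded up.
    """
    if not 0 < prevalence < 1:
        raise DomainError(f"prevalence must be in (0,1), got {prevalence}")
    if not 0 < margin < 1:
        raise DomainError(f"margin must be in (0,1), got {margin}")
    if not 0 < confidence < 1:
        raise DomainError(f"confidence must be in (0,1), got {confidence}")
    if population < 1:
        raise DomainError(f"population must be ≥ 1, got {population}")
    z = norm.ppf((1.0 + confidence) / 2.0)
    n0 = z**2 * prevalence * (1.0 - prevalence) / margin**2
    n = n0 / (1.0 + (n0 - 1.0) / population)
    return math.ceil(n)
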