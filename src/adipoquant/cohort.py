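"""Synthetic two-group adolescent cohorts for exercising the pipeline.

The generator emulates the statistical structure the analysis assumes:

* two groups — eutrophic (n=140) and overweight (n=70) — whose age, weight,
  height, and fasting biomarkers match published group means, SDs and
  min–max ranges; skewed variables (triglycerides, insulin) are lognormal,
  the rest Gaussian, all truncated to the printed ranges;
* sex (52.4% female) and race (61.4% non-white) composition;
* a latent adiposity factor driving all six skinfolds (with site-specific
  loadings and noise), the brachial perimeter, weight and BIA resistance, so
  the twelve %BF estimates correlate strongly but imperfectly;
* the Friedewald/HOMA identities hold by construction: LDL is drawn from
  its own published lognormal moments, total cholesterol is assembled as
  LDL + HDL + TG/5 (the generative direction of the same identity, and the
  physiological one — TC is the sum of its fractions), and HOMA-IR and the
  lipid ratios are always computed, never drawn;
* optional planted effects: a chosen method's %BF can drive chosen measured
  outcomes as ``outcome = target_mean + slope · (%BF − mean %BF) + noise``.

Moment fidelity: the parent (mu, sigma) of each truncated marginal is
calibrated by root finding so the *truncated* mean and SD equal the targets;
sampling goes through a Gaussian copula and inverse-CDF transforms, which
also carries the biomarker correlation matrix and keeps every draw a pure
function of the seeded generator stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.optimize import least_squares
from scipy.special import ndtr
from scipy.stats import truncnorm

from .biomarkers import BiomarkerPanel
from .bodyfat import (
    Maturation,
    Race,
    Sex,
    SubjectRecord,
    eq9_houtkooper,
    evaluate_battery,
)
from .errors import CohortSpecError

__all__ = [
    "MomentTarget",
    "PlantedEffect",
    "CohortSpec",
    "Cohort",
    "DEFAULT_MOMENTS",
    "DRAWN_BIOMARKERS",
    "generate_cohort",
    "plant_null",
    "eq5_signal_effects",
]


@dataclass(frozen=True)
class MomentTarget:
    """Target mean/SD and truncation range for one generated variable."""

    mean: float
    sd: float
    min: float
    max: float
    dist: str = "normal"  # or "lognormal"

    def __post_init__(self):
        if self.sd < 0:
            raise CohortSpecError(f"SD must be ≥ 0, got {self.sd}")
        if not self.min < self.mean < self.max:
            raise CohortSpecError(
                f"mean {self.mean} must lie inside the truncation range "
                f"({self.min}, {self.max})"
            )
        if self.dist not in ("normal", "lognormal"):
            raise CohortSpecError(f"unknown distribution '{self.dist}'")
        if self.dist == "lognormal" and self.min <= 0:
            raise CohortSpecError("lognormal variables need a positive lower bound")


@dataclass(frozen=True)
class PlantedEffect:
    """A %BF → outcome signal to inject into the generator.

    ``scale='linear'``: outcome = mean + slope·(%BF − mean %BF) + N(0, noise_sd),
    slope in outcome units per %BF point.  ``scale='log10'``: the same linear
    model on log10(outcome) — slope in log10 units per %BF point, matching
    how the skewed outcomes are analysed and reported, and keeping positive
    quantities positive by construction.
    """

    slope: float
    noise_sd: float = 0.0
    scale: str = "linear"

    def __post_init__(self):
        if self.noise_sd < 0:
            raise CohortSpecError(f"noise SD must be ≥ 0, got {self.noise_sd}")
        if self.scale not in ("linear", "log10"):
            raise CohortSpecError(f"unknown effect scale '{self.scale}'")


#: Biomarkers drawn directly.  Total cholesterol is *derived* as
#: LDL + HDL + TG/5 — the generative direction of the Friedewald identity —
#: so that LDL is lognormal as the analysis expects and the identity holds
#: exactly; HOMA-IR and the lipid ratios are likewise always derived.
DRAWN_BIOMARKERS: tuple[str, ...] = (
    "glucose", "ldl", "hdl", "tg", "uric_acid", "insulin", "sbp", "dbp",
)

# Group moment targets: mean, SD, and min–max truncation ranges per group.
# Skewed variables (TG, insulin, LDL) are lognormal, the rest Gaussian;
# TC is assembled from LDL + HDL + TG/5, not drawn.
DEFAULT_MOMENTS: Dict[str, Dict[str, MomentTarget]] = {
    "G1": {
        "age": MomentTarget(16.9, 1.0, 15.1, 19.0),
        "weight": MomentTarget(60.2, 6.1, 44.7, 75.9),
        "height": MomentTarget(168.4, 8.2, 149.5, 185.7),
        "glucose": MomentTarget(84.0, 6.0, 69.0, 99.0),
        "ldl": MomentTarget(85.1, 22.9, 44.8, 202.8, dist="lognormal"),
        "hdl": MomentTarget(48.9, 11.0, 21.0, 74.0),
        "tg": MomentTarget(63.2, 26.9, 24.0, 189.0, dist="lognormal"),
        "uric_acid": MomentTarget(3.7, 1.1, 1.5, 7.4),
        "insulin": MomentTarget(9.1, 3.6, 2.0, 23.4, dist="lognormal"),
        "sbp": MomentTarget(102.9, 8.2, 82.0, 125.0),
        "dbp": MomentTarget(60.5, 7.9, 40.0, 84.0),
    },
    "G2": {
        "age": MomentTarget(16.7, 1.0, 15.0, 18.7),
        "weight": MomentTarget(75.7, 13.7, 57.5, 128.7),
        "height": MomentTarget(166.4, 10.3, 149.2, 191.3),
        "glucose": MomentTarget(84.7, 7.0, 71.0, 98.0),
        "ldl": MomentTarget(90.0, 22.4, 40.2, 148.6, dist="lognormal"),
        "hdl": MomentTarget(44.8, 10.7, 27.0, 72.0),
        "tg": MomentTarget(85.2, 53.3, 31.0, 320.0, dist="lognormal"),
        "uric_acid": MomentTarget(3.8, 1.2, 1.6, 7.5),
        "insulin": MomentTarget(12.8, 5.6, 3.9, 27.1, dist="lognormal"),
        "sbp": MomentTarget(104.7, 9.3, 83.0, 125.0),
        "dbp": MomentTarget(61.1, 8.7, 43.0, 82.0),
    },
}

# Modest positive dependence among drawn biomarkers (Gaussian-copula scale):
# lipid fractions move together, insulin with TG and glucose, SBP with DBP.
_DEFAULT_CORR_PAIRS = {
    ("ldl", "hdl"): 0.10,
    ("ldl", "tg"): 0.15,
    ("hdl", "tg"): -0.20,
    ("insulin", "tg"): 0.30,
    ("insulin", "glucose"): 0.20,
    ("insulin", "uric_acid"): 0.15,
    ("sbp", "dbp"): 0.55,
    ("uric_acid", "tg"): 0.15,
}


def default_correlation() -> np.ndarray:
    k = len(DRAWN_BIOMARKERS)
    corr = np.eye(k)
    idx = {name: i for i, name in enumerate(DRAWN_BIOMARKERS)}
    for (a, b), rho in _DEFAULT_CORR_PAIRS.items():
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = rho
    return corr


# Latent-adiposity skinfold model: site base levels (mm) for a eutrophic
# male, site loadings on the shared factor, and site-specific log noise.
_FOLD_BASE = {
    "biceps": 5.5, "triceps": 9.0, "subscapular": 8.5,
    "suprailiac": 9.0, "midaxillary": 7.0, "calf": 10.0,
}
_FOLD_LOADING = {
    "biceps": 0.40, "triceps": 0.36, "subscapular": 0.40,
    "suprailiac": 0.42, "midaxillary": 0.38, "calf": 0.34,
}
_FOLD_NOISE_SD = 0.28          # site-specific lognormal noise, log scale
_FEMALE_FOLD_FACTOR = 1.35     # girls carry more subcutaneous fat
_OVERWEIGHT_FOLD_FACTOR = 1.8  # overweight group shift
_WEIGHT_ADIPOSITY_RHO = 0.55   # copula correlation of weight with the factor


@dataclass
class CohortSpec:
    """Design of a synthetic cohort (defaults mirror the study)."""

    n_eutrophic: int = 140
    n_overweight: int = 70
    female_fraction: float = 0.524
    nonwhite_fraction: float = 0.614
    moments: Dict[str, Dict[str, MomentTarget]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_MOMENTS.items()}
    )
    effects: Dict[Tuple[str, str], PlantedEffect] = field(default_factory=dict)
    correlation: Optional[np.ndarray] = None
    biomarker_sd_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_eutrophic <= 0 or self.n_overweight <= 0:
            raise CohortSpecError("group sizes must be positive")
        for frac, name in ((self.female_fraction, "female_fraction"),
                           (self.nonwhite_fraction, "nonwhite_fraction")):
            if not 0.0 <= frac <= 1.0:
                raise CohortSpecError(f"{name} must be in [0,1], got {frac}")
        if self.correlation is None:
            self.correlation = default_correlation()
        corr = np.asarray(self.correlation, dtype=float)
        if corr.shape != (len(DRAWN_BIOMARKERS),) * 2:
            raise CohortSpecError(
                f"correlation matrix must be {len(DRAWN_BIOMARKERS)}×{len(DRAWN_BIOMARKERS)}"
            )
        if not np.allclose(corr, corr.T):
            raise CohortSpecError("correlation matrix must be symmetric")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise CohortSpecError("correlation matrix must be positive semi-definite")
        self.correlation = corr
        for (method, outcome) in self.effects:
            if outcome not in DRAWN_BIOMARKERS:
                raise CohortSpecError(
                    f"planted effects apply to measured biomarkers only, got '{outcome}' "
                    f"(derived indices inherit the signal through their inputs)"
                )


def plant_null(spec: CohortSpec) -> CohortSpec:
    """Return a copy of the spec with every planted slope set to zero."""
    nulled = {k: PlantedEffect(0.0, e.noise_sd, e.scale) for k, e in spec.effects.items()}
    return replace(spec, effects=nulled)


def eq5_signal_effects() -> Dict[Tuple[str, str], PlantedEffect]:
    """Canonical planted-signal design: the age-adjusted densitometric
    method's %BF drives triglycerides, insulin and diastolic pressure.

    Effect sizes give per-outcome R² around 0.4 at the study group size —
    the upper end of the coefficients of determination the motivating
    analysis reports (insulin reached 0.51 in the eutrophic group).  The
    skewed outcomes carry their signal on the log10 scale, where their
    regression slopes are reported.
    """
    return {
        ("EQ5", "tg"): PlantedEffect(0.018, 0.14, scale="log10"),
        ("EQ5", "insulin"): PlantedEffect(0.016, 0.11, scale="log10"),
        ("EQ5", "dbp"): PlantedEffect(0.75, 6.5, scale="linear"),
    }


# ---------------------------------------------------------------------------
# Truncated-marginal calibration
# ---------------------------------------------------------------------------

def _trunc_norm_mean_sd(mu, sigma, lo, hi):
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    m, v = truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
    return float(m), float(np.sqrt(v))


def _trunc_lognorm_mean_sd(mu, sigma, lo, hi):
    # X = exp(Y), Y ~ N(mu, sigma²) truncated to [ln lo, ln hi];
    # E[e^{kY}] has a closed form in normal CDFs.
    a, b = (math.log(lo) - mu) / sigma, (math.log(hi) - mu) / sigma
    z = ndtr(b) - ndtr(a)
    if z <= 0:
        return math.nan, math.nan
    e1 = math.exp(mu + sigma**2 / 2) * (ndtr(b - sigma) - ndtr(a - sigma)) / z
    e2 = math.exp(2 * mu + 2 * sigma**2) * (ndtr(b - 2 * sigma) - ndtr(a - 2 * sigma)) / z
    var = max(e2 - e1**2, 0.0)
    return e1, math.sqrt(var)


@lru_cache(maxsize=None)
def _calibrate(dist: str, mean: float, sd: float, lo: float, hi: float):
    """Solve for parent (mu, sigma) so the truncated mean/SD hit the targets."""
    if sd == 0.0:
        raise CohortSpecError("degenerate SD = 0 moment target")
    if dist == "normal":
        x0 = np.array([mean, math.log(sd)])

        def resid(x):
            with np.errstate(invalid="ignore"):
                m, s = _trunc_norm_mean_sd(x[0], math.exp(x[1]), lo, hi)
            if not (math.isfinite(m) and math.isfinite(s)):
                return [1e6, 1e6]
            return [(m - mean) / sd, (s - sd) / sd]
    else:
        s2 = math.log1p((sd / mean) ** 2)
        x0 = np.array([math.log(mean) - s2 / 2, math.log(math.sqrt(s2))])

        def resid(x):
            m, s = _trunc_lognorm_mean_sd(x[0], math.exp(x[1]), lo, hi)
            if not (math.isfinite(m) and math.isfinite(s)):
                return [1e6, 1e6]
            return [(m - mean) / sd, (s - sd) / sd]

    sol = least_squares(resid, x0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success or np.abs(sol.fun).max() > 1e-6:
        raise CohortSpecError(
            f"infeasible moment target: {dist} mean={mean} sd={sd} on ({lo}, {hi})"
        )
    return float(sol.x[0]), float(math.exp(sol.x[1]))


def _marginal_ppf(target: MomentTarget, u: np.ndarray) -> np.ndarray:
    """Inverse CDF of the calibrated truncated marginal at uniforms ``u``."""
    if target.dist == "normal":
        mu, sigma = _calibrate("normal", target.mean, target.sd, target.min, target.max)
        a, b = (target.min - mu) / sigma, (target.max - mu) / sigma
        return truncnorm.ppf(u, a, b, loc=mu, scale=sigma)
    mu, sigma = _calibrate("lognormal", target.mean, target.sd, target.min, target.max)
    a = (math.log(target.min) - mu) / sigma
    b = (math.log(target.max) - mu) / sigma
    return np.exp(truncnorm.ppf(u, a, b, loc=mu, scale=sigma))


def _scaled(target: MomentTarget, sd_scale: float) -> MomentTarget:
    if sd_scale == 1.0:
        return target
    return replace(target, sd=target.sd * sd_scale)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    subjects: list
    panels: list
    spec: CohortSpec

    def frame(self):
        """Merged per-subject DataFrame of demographics and panel values."""
        import pandas as pd

        rows = []
        by_id = {p.subject_id: p for p in self.panels}
        for s in self.subjects:
            p = by_id[s.subject_id]
            rows.append({
                "subject_id": s.subject_id, "group": s.group,
                "sex": s.sex.value, "age": s.age, "race": s.race.value,
                "weight": s.weight, "height": s.height,
                "glucose": p.glucose, "tc": p.total_cholesterol, "hdl": p.hdl,
                "tg": p.triglycerides, "uric_acid": p.uric_acid,
                "insulin": p.insulin, "sbp": p.sbp, "dbp": p.dbp,
                "ldl": p.ldl, "tc_hdl_ratio": p.tc_hdl_ratio,
                "ldl_hdl_ratio": p.ldl_hdl_ratio, "homa_ir": p.homa_ir,
            })
        return pd.DataFrame(rows)


_PANEL_KEYS = {"tc": "total_cholesterol", "tg": "triglycerides"}


def _generate_group(spec: CohortSpec, group: str, n: int, rng: np.random.Generator,
                    id_offset: int):
    moments = spec.moments[group]
    female = rng.random(n) < spec.female_fraction
    nonwhite = rng.random(n) < spec.nonwhite_fraction
    z_adip = rng.standard_normal(n)  # latent adiposity factor

    age = _marginal_ppf(moments["age"], rng.random(n))
    # weight shares the adiposity factor through the copula; height independent
    w_norm = (_WEIGHT_ADIPOSITY_RHO * z_adip
              + math.sqrt(1 - _WEIGHT_ADIPOSITY_RHO**2) * rng.standard_normal(n))
    weight = _marginal_ppf(moments["weight"], ndtr(w_norm))
    height = _marginal_ppf(moments["height"], rng.random(n))

    group_factor = _OVERWEIGHT_FOLD_FACTOR if group == "G2" else 1.0
    folds = {}
    for site in _FOLD_BASE:
        base = _FOLD_BASE[site] * group_factor * np.where(female, _FEMALE_FOLD_FACTOR, 1.0)
        folds[site] = np.clip(
            base * np.exp(_FOLD_LOADING[site] * z_adip
                          + _FOLD_NOISE_SD * rng.standard_normal(n)),
            2.0, 60.0,
        )

    brachial = np.clip(
        np.where(group == "G2", 29.5, 26.5) + 1.2 * z_adip + 1.2 * rng.standard_normal(n),
        18.0, 45.0,
    )
    # Resistance follows the physics of a tetra-polar measurement:
    # R ≈ k·Ht²/FFM for a conductor of length Ht and conductive (lean) mass
    # FFM, plus multiplicative device noise.  A latent %BF consistent with
    # the skinfold model (shared adiposity factor, higher in girls and in
    # the overweight group) sets the lean mass.
    pbf_latent = np.clip(
        (25.0 if group == "G2" else 15.0)
        + 6.0 * z_adip + 7.0 * female + 2.0 * rng.standard_normal(n),
        4.0, 55.0,
    )
    ffm_latent = weight * (1.0 - pbf_latent / 100.0)
    resistance = np.clip(
        0.61 * height**2 / (ffm_latent - 0.25 * weight - 1.31)
        * np.exp(0.06 * rng.standard_normal(n)),
        300.0, 900.0,
    )

    # correlated biomarker block through the Gaussian copula
    chol = np.linalg.cholesky(
        spec.correlation + 1e-12 * np.eye(len(DRAWN_BIOMARKERS))
    )
    z_bio = rng.standard_normal((n, len(DRAWN_BIOMARKERS))) @ chol.T
    u_bio = ndtr(z_bio)
    bio = {
        name: _marginal_ppf(_scaled(moments[name], spec.biomarker_sd_scale), u_bio[:, j])
        for j, name in enumerate(DRAWN_BIOMARKERS)
    }

    subjects = []
    for i in range(n):
        subjects.append(SubjectRecord(
            subject_id=f"{group}-{id_offset + i:04d}",
            sex=Sex.FEMALE if female[i] else Sex.MALE,
            age=float(age[i]),
            weight=float(weight[i]),
            height=float(height[i]),
            race=Race.NONWHITE if nonwhite[i] else Race.WHITE,
            maturation=Maturation.POSTPUBESCENT,
            skinfolds={site: float(folds[site][i]) for site in _FOLD_BASE},
            brachial_perimeter=float(brachial[i]),
            resistance=float(resistance[i]),
            group="eutrophic" if group == "G1" else "overweight",
        ))
    # direct vertical-BIA reading: impedance-based %BF plus device noise
    for i, s in enumerate(subjects):
        pbf9 = eq9_houtkooper(s).percent_fat
        s.bia2_percent_fat = float(np.clip(pbf9 + 2.0 * rng.standard_normal(), 3.0, 60.0))

    # planted %BF → outcome effects (centred, replacing the baseline draw)
    for (method, outcome), effect in spec.effects.items():
        pbf = np.array([
            evaluate_battery(s, [method], strict=True).estimates[0].percent_fat
            for s in subjects
        ])
        target = moments[outcome]
        if effect.scale == "log10":
            values = target.mean * 10.0 ** (
                effect.slope * (pbf - pbf.mean())
                + effect.noise_sd * rng.standard_normal(n)
            )
        else:
            values = (target.mean + effect.slope * (pbf - pbf.mean())
                      + effect.noise_sd * rng.standard_normal(n))
        # planted outcomes honour the printed observed range like every draw
        bio[outcome] = np.clip(values, target.min, target.max)

    # total cholesterol assembled from its fractions (Friedewald direction)
    tc = bio["ldl"] + bio["hdl"] + bio["tg"] / 5.0

    panels = [
        BiomarkerPanel.from_measurements(
            subjects[i].subject_id,
            glucose=float(bio["glucose"][i]),
            insulin=float(bio["insulin"][i]),
            total_cholesterol=float(tc[i]),
            hdl=float(bio["hdl"][i]),
            triglycerides=float(bio["tg"][i]),
            uric_acid=float(bio["uric_acid"][i]),
            sbp=float(bio["sbp"][i]),
            dbp=float(bio["dbp"][i]),
        )
        for i in range(n)
    ]
    return subjects, panels


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a reproducible two-group cohort from the spec.

    The same spec (including seed) always yields an identical cohort.
    """
    rng = np.random.default_rng(spec.seed)
    subjects, panels = [], []
    for group, n in (("G1", spec.n_eutrophic), ("G2", spec.n_overweight)):
        s, p = _generate_group(spec, group, n, rng, id_offset=0)
        subjects.extend(s)
        panels.extend(p)
    return Cohort(subjects=subjects, panels=panels, spec=spec)
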