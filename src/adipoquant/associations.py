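"""Group comparisons, bivariate screening, adjusted regression and ranking.

The statistical procedure mirrors a common epidemiological screen:

1. distribution check per variable (Lilliefors-corrected Kolmogorov–Smirnov,
   parameters estimated from the data) selecting Student's t vs Mann–Whitney
   for group comparisons;
2. log10 transform of the right-skewed outcomes (TG, insulin, HOMA-IR, LDL,
   TC, and the LDL/HDL and TC/HDL ratios);
3. a liberal bivariate screen: each outcome (on its analysis scale) is
   regressed on each method's %BF; cells with P < 0.20 are admitted;
4. multiple regression of admitted cells adjusted for sex (and, in the
   eutrophic group, for a "eutrophic with excess body fat" indicator);
   Shapiro–Wilk on the residuals gates reporting (P > 0.05 required), the
   White test probes heteroskedasticity, and when it rejects at 5% the
   standard errors and P-values are recomputed with a small-sample robust
   covariance (HC3 by default); the variance inflation factor monitors
   multicollinearity;
5. methods are ranked by the number of outcomes with an assumption-clean
   adjusted association at P < 0.05.

No multiplicity correction is applied in the default pipeline (a
Benjamini–Hochberg helper is available but off by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import het_white, lilliefors
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.outliers_influence import variance_inflation_factor
import statsmodels.api as sm

from .bodyfat import METHODS
from .errors import DomainError, RankDeficientError

__all__ = [
    "OUTCOMES",
    "LOG_OUTCOMES",
    "RegressionResult",
    "Cell",
    "AssociationMatrix",
    "normality_check",
    "compare_groups",
    "log_transform_outcomes",
    "bivariate_screen",
    "adjusted_regression",
    "build_association_matrix",
    "rank_methods",
]

#: Outcomes examined against every %BF method, in table order.
OUTCOMES: tuple[str, ...] = (
    "glucose", "tc", "hdl", "ldl", "tg", "tc_hdl_ratio", "ldl_hdl_ratio",
    "uric_acid", "insulin", "homa_ir", "sbp", "dbp",
)

#: Right-skewed outcomes analysed on the log10 scale.
LOG_OUTCOMES: tuple[str, ...] = (
    "tg", "insulin", "homa_ir", "ldl", "tc", "ldl_hdl_ratio", "tc_hdl_ratio",
)


@dataclass
class RegressionResult:
    """One (method, outcome) fit: slope, diagnostics and assumption flags."""

    method: str
    outcome: str
    beta: float
    r_squared: float
    p_value: float
    n: int
    log_scale: bool
    adjusted_for: list = field(default_factory=list)
    robust_se: bool = False
    residual_normality_p: Optional[float] = None
    white_test_p: Optional[float] = None
    vif_max: float = 1.0
    assumptions_met: bool = True
    admitted: Optional[bool] = None


@dataclass
class Cell:
    """One grid cell: a result, or a machine-readable reason for a dash."""

    status: str  # "significant" | "not_significant" | "not_admitted" |
    #              "assumptions_failed" | "error"
    result: Optional[RegressionResult] = None
    reason: Optional[str] = None


# ---------------------------------------------------------------------------
# Distribution utilities
# ---------------------------------------------------------------------------

def normality_check(values) -> dict:
    """Lilliefors-corrected KS test against a normal with estimated moments.

    Returns ``{"statistic", "p_value", "normal"}`` with ``normal`` meaning
    P > 0.05.  The correction matters: the plain KS test with estimated
    parameters is badly anti-conservative.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 8:
        raise DomainError(f"normality check needs n ≥ 8, got {x.size}")
    if np.ptp(x) == 0:
        raise DomainError("normality check undefined for a constant vector")
    stat, p = lilliefors(x, dist="norm", pvalmethod="table")
    return {"statistic": float(stat), "p_value": float(p), "normal": bool(p > 0.05)}


def compare_groups(values, groups, normal: bool) -> dict:
    """Two-group comparison: equal-variance t when normal, Mann–Whitney U else."""
    x = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    labels = np.unique(g)
    if labels.size != 2:
        raise DomainError(f"expected exactly 2 group labels, got {labels.tolist()}")
    a, b = x[g == labels[0]], x[g == labels[1]]
    if min(a.size, b.size) < 2:
        raise DomainError("each group needs n ≥ 2")
    if normal:
        stat, p = stats.ttest_ind(a, b, equal_var=True)
        name = "t-test"
    else:
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        name = "mann-whitney"
    return {"test_name": name, "statistic": float(stat), "p_value": float(p)}


def log_transform_outcomes(frame: pd.DataFrame,
                           columns: Sequence[str] = LOG_OUTCOMES) -> pd.DataFrame:
    """Replace the listed columns by their log10; others untouched.

    The returned frame carries the transformed column list in
    ``frame.attrs["log10_columns"]``.  Non-positive values are an error
    naming the offending subject and column.
    """
    out = frame.copy()
    applied = []
    for col in columns:
        if col not in out.columns:
            continue
        vals = out[col].astype(float)
        bad = vals <= 0
        if bad.any():
            where = out.loc[bad, "subject_id"].iloc[0] if "subject_id" in out else out.index[bad][0]
            raise DomainError(
                f"log transform of '{col}' undefined at non-positive value "
                f"(subject {where})"
            )
        out[col] = np.log10(vals)
        applied.append(col)
    out.attrs["log10_columns"] = applied
    return out


# ---------------------------------------------------------------------------
# Regression
# ---------------------------------------------------------------------------

def bivariate_screen(percent_fat, outcome, *, method: str = "", outcome_name: str = "",
                     log_scale: bool = False, screen_threshold: float = 0.20,
                     ) -> RegressionResult:
    """OLS of the outcome (analysis scale) on one method's %BF.

    ``admitted`` is True when the slope P-value is strictly below the screen
    threshold (default 0.20).
    """
    x = np.asarray(percent_fat, dtype=float)
    y = np.asarray(outcome, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 10:
        raise DomainError(f"bivariate screen needs n ≥ 10 complete pairs, got {x.size}")
    if np.ptp(x) == 0:
        raise DomainError("%BF vector has zero variance")
    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    sw_p = float(stats.shapiro(resid).pvalue) if np.ptp(resid) > 0 else 1.0
    return RegressionResult(
        method=method,
        outcome=outcome_name,
        beta=float(fit.slope),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=int(x.size),
        log_scale=log_scale,
        residual_normality_p=sw_p,
        assumptions_met=sw_p > 0.05,
        admitted=bool(fit.pvalue < screen_threshold),
    )


def _check_rank(exog: pd.DataFrame) -> None:
    mat = exog.to_numpy(dtype=float)
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        # name the offending columns via auxiliary regressions
        collinear = []
        for j, col in enumerate(exog.columns):
            others = np.delete(mat, j, axis=1)
            beta, *_ = np.linalg.lstsq(others, mat[:, j], rcond=None)
            if np.allclose(others @ beta, mat[:, j], atol=1e-8):
                collinear.append(str(col))
        raise RankDeficientError(f"design matrix is rank deficient; collinear columns: {collinear}")


def adjusted_regression(outcome, percent_fat, covariates: Optional[pd.DataFrame] = None,
                        *, method: str = "", outcome_name: str = "",
                        log_scale: bool = False, robust_flavour: str = "HC3",
                        compute_vif: bool = True,
                        ) -> RegressionResult:
    """Covariate-adjusted OLS of the outcome on %BF with assumption gates.

    Shapiro–Wilk on the residuals sets ``assumptions_met`` (P > 0.05
    required); the White test probes heteroskedasticity and, when it rejects
    at 5%, the %BF standard error and P-value are recomputed under a
    small-sample robust covariance (``robust_flavour``: HC1/HC2/HC3).
    ``vif_max`` is the largest variance inflation factor among non-intercept
    regressors.
    """
    if robust_flavour not in ("HC1", "HC2", "HC3"):
        raise DomainError(f"unknown robust covariance flavour '{robust_flavour}'")
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(percent_fat, dtype=float)
    data = {"percent_fat": x}
    if covariates is not None and len(covariates.columns):
        for col in covariates.columns:
            data[str(col)] = np.asarray(covariates[col], dtype=float)
    exog = pd.DataFrame(data)
    exog.insert(0, "const", 1.0)
    _check_rank(exog)

    ols = sm.OLS(y, exog).fit()
    resid = ols.resid
    sw_p = float(stats.shapiro(resid).pvalue) if np.ptp(resid) > 0 else 1.0
    _, white_p, _, _ = het_white(resid, exog.to_numpy(dtype=float))
    robust = bool(white_p < 0.05)
    use = ols.get_robustcov_results(cov_type=robust_flavour) if robust else ols
    names = list(exog.columns)
    i_pbf = names.index("percent_fat")
    beta = float(np.asarray(use.params)[i_pbf])
    p = float(np.asarray(use.pvalues)[i_pbf])
    mat = exog.to_numpy(dtype=float)
    if compute_vif and mat.shape[1] > 2:
        vif_max = max(
            float(variance_inflation_factor(mat, j)) for j in range(1, mat.shape[1])
        )
    else:
        vif_max = 1.0
    return RegressionResult(
        method=method,
        outcome=outcome_name,
        beta=beta,
        r_squared=float(ols.rsquared),
        p_value=p,
        n=int(y.size),
        log_scale=log_scale,
        adjusted_for=[c for c in names if c not in ("const", "percent_fat")],
        robust_se=robust,
        residual_normality_p=sw_p,
        white_test_p=float(white_p),
        vif_max=vif_max,
        assumptions_met=sw_p > 0.05,
    )


# ---------------------------------------------------------------------------
# The grid and the ranking
# ---------------------------------------------------------------------------

@dataclass
class AssociationMatrix:
    """Method × outcome grid of screen→adjust results."""

    cells: Dict[Tuple[str, str], Cell]
    methods: tuple
    outcomes: tuple
    screen_threshold: float = 0.20
    alpha: float = 0.05

    def significant_cells(self, method: str) -> list:
        return [
            c for (m, _), c in self.cells.items()
            if m == method and c.status == "significant"
        ]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (m, o), cell in self.cells.items():
            r = cell.result
            rows.append({
                "method": m, "outcome": o, "status": cell.status,
                "reason": cell.reason,
                "beta": r.beta if r else None,
                "r_squared": r.r_squared if r else None,
                "p_value": r.p_value if r else None,
                "n": r.n if r else None,
                "log_scale": r.log_scale if r else None,
                "robust_se": r.robust_se if r else None,
                "residual_normality_p": r.residual_normality_p if r else None,
                "white_test_p": r.white_test_p if r else None,
                "vif_max": r.vif_max if r else None,
            })
        return pd.DataFrame(rows)


def build_association_matrix(
    percent_fat_wide: pd.DataFrame,
    panel: pd.DataFrame,
    *,
    methods: Iterable[str] | None = None,
    outcomes: Iterable[str] | None = None,
    sex: Optional[pd.Series] = None,
    false_negative: Optional[pd.Series] = None,
    screen_threshold: float = 0.20,
    alpha: float = 0.05,
    robust_flavour: str = "HC3",
    log_columns: Sequence[str] = LOG_OUTCOMES,
    bh_correction: bool = False,
) -> AssociationMatrix:
    """Run the full screen→adjust pipeline over every (method, outcome) cell.

    ``percent_fat_wide`` is subjects × methods; ``panel`` holds outcome
    columns on the measurement scale (the listed skewed ones are log10-
    transformed here).  ``sex`` (masculine = 1, feminine = 0) and, for the
    eutrophic group, ``false_negative`` enter the adjusted model.  Per-cell
    failures become flagged cells; the grid never aborts.
    ``bh_correction`` optionally applies Benjamini–Hochberg across the
    admitted cells' adjusted P-values (off by default).
    """
    if not 0 < alpha < screen_threshold < 1:
        raise DomainError(
            f"need 0 < alpha < screen threshold < 1, got {alpha}, {screen_threshold}"
        )
    methods = tuple(methods) if methods is not None else tuple(
        m for m in METHODS if m in percent_fat_wide.columns
    )
    outcomes = tuple(outcomes) if outcomes is not None else tuple(
        o for o in OUTCOMES if o in panel.columns
    )
    panel_t = log_transform_outcomes(panel, [c for c in log_columns if c in outcomes])
    logged = set(panel_t.attrs.get("log10_columns", []))

    cov_frame = pd.DataFrame(index=panel.index)
    if sex is not None:
        cov_frame["sex"] = np.asarray(sex, dtype=float)
    if false_negative is not None:
        cov_frame["excess_fat_fn"] = np.asarray(false_negative, dtype=float)

    cells: Dict[Tuple[str, str], Cell] = {}
    for m in methods:
        pbf = percent_fat_wide[m].to_numpy(dtype=float)
        for o in outcomes:
            y = panel_t[o].to_numpy(dtype=float)
            try:
                screen = bivariate_screen(
                    pbf, y, method=m, outcome_name=o, log_scale=o in logged,
                    screen_threshold=screen_threshold,
                )
                if not screen.admitted:
                    cells[(m, o)] = Cell(
                        status="not_admitted", result=screen,
                        reason=f"failed bivariate screen (P={screen.p_value:.3g} ≥ {screen_threshold})",
                    )
                    continue
                adj = adjusted_regression(
                    y, pbf,
                    cov_frame if len(cov_frame.columns) else None,
                    method=m, outcome_name=o, log_scale=o in logged,
                    robust_flavour=robust_flavour,
                )
                adj.admitted = True
                if not adj.assumptions_met:
                    cells[(m, o)] = Cell(
                        status="assumptions_failed", result=adj,
                        reason=f"residuals non-normal (Shapiro-Wilk P={adj.residual_normality_p:.3g} ≤ 0.05)",
                    )
                elif adj.p_value < alpha:
                    cells[(m, o)] = Cell(status="significant", result=adj)
                else:
                    cells[(m, o)] = Cell(status="not_significant", result=adj)
            except Exception as exc:  # propagate as a flagged cell, never abort
                cells[(m, o)] = Cell(status="error", reason=f"{type(exc).__name__}: {exc}")

    if bh_correction:
        keyed = [(k, c) for k, c in cells.items()
                 if c.status in ("significant", "not_significant")]
        if keyed:
            pvals = [c.result.p_value for _, c in keyed]
            reject, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")
            for (k, c), rj in zip(keyed, reject):
                c.status = "significant" if rj else "not_significant"

    return AssociationMatrix(
        cells=cells, methods=methods, outcomes=outcomes,
        screen_threshold=screen_threshold, alpha=alpha,
    )


def rank_methods(matrix: AssociationMatrix) -> list:
    """Rank methods by how many outcomes they predict in the adjusted model.

    A cell counts when it was admitted by the screen, met the residual-
    normality assumption, and has adjusted P < alpha.  Ties break by mean
    adjusted R² over the significant cells (descending), then by canonical
    method order — purely for determinism.
    """
    rows = []
    for idx, m in enumerate(matrix.methods):
        sig = matrix.significant_cells(m)
        mean_r2 = float(np.mean([c.result.r_squared for c in sig])) if sig else 0.0
        rows.append({
            "method": m,
            "n_significant": len(sig),
            "mean_r_squared": mean_r2,
            "significant_outcomes": sorted(c.result.outcome for c in sig),
            "_order": idx,
        })
    rows.sort(key=lambda r: (-r["n_significant"], -r["mean_r_squared"], r["_order"]))
    for r in rows:
        del r["_order"]
    return rows
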