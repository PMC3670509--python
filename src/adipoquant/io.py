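"""CSV input/output, run configuration and the end-to-end pipeline.

The subject CSV is UTF-8, comma-separated, "." decimals (a
``decimal_comma`` switch accepts "," decimals), one row per subject with
columns named after the record fields; empty cells are missing values.  A
YAML column-mapping lets differently-named headers be used unchanged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .biomarkers import BiomarkerPanel, RiskCutoffs, risk_flags
from .bodyfat import (
    DEFAULT_EXCESS_FAT_THRESHOLDS,
    METHODS,
    Sex,
    SubjectRecord,
    battery_frame,
    classify_excess_fat,
    percent_fat_wide,
)
from .associations import (
    LOG_OUTCOMES,
    OUTCOMES,
    build_association_matrix,
    rank_methods,
)
from .cohort import CohortSpec, generate_cohort
from .errors import ConfigError, SchemaError

__all__ = [
    "SUBJECT_COLUMNS",
    "PANEL_COLUMNS",
    "RunConfig",
    "read_subjects",
    "read_panels",
    "subjects_to_frame",
    "write_cohort_csv",
    "run_all",
]

log = logging.getLogger("adipoquant")

SKINFOLD_COLUMNS = ("biceps", "triceps", "subscapular", "suprailiac", "midaxillary", "calf")

#: Required identity/anthropometry columns (skinfolds etc. may be empty).
SUBJECT_COLUMNS = ("subject_id", "sex", "age", "weight", "height")

OPTIONAL_SUBJECT_COLUMNS = SKINFOLD_COLUMNS + (
    "race", "maturation", "brachial_perimeter", "resistance",
    "bia2_percent_fat", "group",
)

PANEL_COLUMNS = ("glucose", "insulin", "tc", "hdl", "tg", "uric_acid", "sbp", "dbp")


def _read_csv(path, mapping: Optional[Mapping[str, str]] = None,
              decimal: str = ".") -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    frame = pd.read_csv(path, decimal=decimal)
    if mapping:
        frame = frame.rename(columns=dict(mapping))
    missing = [c for c in SUBJECT_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return frame


def _cell(row, col):
    v = row.get(col)
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return v


def read_subjects(path, mapping: Optional[Mapping[str, str]] = None,
                  decimal: str = ".") -> tuple[list, list]:
    """Read and validate subject records from CSV.

    Returns ``(records, violations)`` where each violation is a dict naming
    the 1-based data row and the offending field; invalid rows are excluded
    from the records.
    """
    frame = _read_csv(path, mapping, decimal)
    records, violations = [], []
    for i, row in frame.iterrows():
        row = row.to_dict()
        try:
            records.append(SubjectRecord(
                subject_id=str(row["subject_id"]),
                sex=row["sex"],
                age=float(row["age"]),
                weight=float(row["weight"]),
                height=float(row["height"]),
                race=_cell(row, "race"),
                maturation=_cell(row, "maturation") or "postpubescent",
                skinfolds={s: _cell(row, s) for s in SKINFOLD_COLUMNS
                           if _cell(row, s) is not None},
                brachial_perimeter=_cell(row, "brachial_perimeter"),
                resistance=_cell(row, "resistance"),
                bia2_percent_fat=_cell(row, "bia2_percent_fat"),
                group=_cell(row, "group"),
            ))
        except Exception as exc:
            violations.append({"row": int(i) + 1, "error": str(exc)})
    return records, violations


def read_panels(path, mapping: Optional[Mapping[str, str]] = None,
                decimal: str = ".") -> tuple[list, list]:
    """Read biomarker panels (derived fields recomputed) from the subject CSV."""
    frame = _read_csv(path, mapping, decimal)
    missing = [c for c in PANEL_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing biomarker column(s) {missing}")
    panels, violations = [], []
    for i, row in frame.iterrows():
        row = row.to_dict()
        try:
            panels.append(BiomarkerPanel.from_measurements(
                str(row["subject_id"]),
                glucose=float(row["glucose"]), insulin=float(row["insulin"]),
                total_cholesterol=float(row["tc"]), hdl=float(row["hdl"]),
                triglycerides=float(row["tg"]), uric_acid=float(row["uric_acid"]),
                sbp=float(row["sbp"]), dbp=float(row["dbp"]),
            ))
        except Exception as exc:
            violations.append({"row": int(i) + 1, "error": str(exc)})
    return panels, violations


def subjects_to_frame(subjects: Sequence[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        row = {
            "subject_id": s.subject_id, "sex": s.sex.value, "age": s.age,
            "race": s.race.value if s.race else None,
            "maturation": s.maturation.value if s.maturation else None,
            "weight": s.weight, "height": s.height,
            "brachial_perimeter": s.brachial_perimeter,
            "resistance": s.resistance,
            "bia2_percent_fat": s.bia2_percent_fat,
            "group": s.group,
        }
        for site in SKINFOLD_COLUMNS:
            row[site] = s.skinfolds.get(site)
        rows.append(row)
    return pd.DataFrame(rows)


def panels_to_frame(panels: Sequence[BiomarkerPanel]) -> pd.DataFrame:
    return pd.DataFrame([{
        "subject_id": p.subject_id, "glucose": p.glucose, "insulin": p.insulin,
        "tc": p.total_cholesterol, "hdl": p.hdl, "tg": p.triglycerides,
        "uric_acid": p.uric_acid, "sbp": p.sbp, "dbp": p.dbp,
        "ldl": p.ldl, "tc_hdl_ratio": p.tc_hdl_ratio,
        "ldl_hdl_ratio": p.ldl_hdl_ratio, "homa_ir": p.homa_ir,
    } for p in panels])


def write_cohort_csv(cohort, path) -> None:
    """Write a generated cohort as the subject+panel CSV dialect."""
    subj = subjects_to_frame(cohort.subjects)
    pan = panels_to_frame(cohort.panels)
    merged = subj.merge(pan, on="subject_id")
    merged.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Run configuration and the end-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything the end-to-end run needs; validated before any compute."""

    input: Optional[str] = None      # subject CSV; None → simulate
    outdir: str = "adipoquant-out"
    seed: int = 0
    methods: Sequence[str] = METHODS
    screen_threshold: float = 0.20
    alpha: float = 0.05
    robust_flavour: str = "HC3"
    excess_fat_thresholds: tuple = DEFAULT_EXCESS_FAT_THRESHOLDS
    reference_method: str = "EQ5"    # defines "eutrophic with excess fat"
    bia1_equation: str = "houtkooper"
    glucose_cutoff: float = 100.0
    uric_acid_pooled: bool = False
    decimal_comma: bool = False
    column_mapping: Optional[dict] = None

    def __post_init__(self):
        if not 0 < self.alpha < 1 or not 0 < self.screen_threshold < 1:
            raise ConfigError("thresholds must lie in (0, 1)")
        if self.screen_threshold <= self.alpha:
            raise ConfigError(
                f"screen threshold ({self.screen_threshold}) must exceed the "
                f"final alpha ({self.alpha})"
            )
        if self.reference_method not in METHODS:
            raise ConfigError(f"unknown reference method '{self.reference_method}'")
        bad = [m for m in self.methods if m not in METHODS]
        if bad:
            raise ConfigError(f"unknown method id(s) in selection: {bad}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def sha256(self) -> str:
        # output location is not part of the analysis provenance
        payload = {k: v for k, v in dataclasses.asdict(self).items() if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def cutoffs(self) -> RiskCutoffs:
        return RiskCutoffs(glucose=self.glucose_cutoff,
                           uric_acid_pooled=self.uric_acid_pooled)


def _grid_for_group(config, subjects, panels, group_label):
    subj = [s for s in subjects if s.group == group_label]
    if not subj:
        return None, None
    ids = [s.subject_id for s in subj]
    pan_by_id = {p.subject_id: p for p in panels}
    pan = panels_to_frame([pan_by_id[i] for i in ids])
    est, skips = battery_frame(
        subj, list(config.methods),
        bia1_equation=config.bia1_equation,
        excess_thresholds=config.excess_fat_thresholds,
    )
    if skips:
        log.warning("associate[%s]: %d method evaluations skipped", group_label, len(skips))
    wide = percent_fat_wide(est).reindex(ids)
    sex = pd.Series([1.0 if s.sex is Sex.MALE else 0.0 for s in subj], index=ids)
    false_negative = None
    if group_label == "eutrophic" and config.reference_method in wide.columns:
        ref = wide[config.reference_method]
        false_negative = pd.Series(
            [float(classify_excess_fat(v, s.sex, config.excess_fat_thresholds))
             for v, s in zip(ref, subj)],
            index=ids,
        )
    pan = pan.set_index("subject_id").reindex(ids).reset_index()
    matrix = build_association_matrix(
        wide.reset_index(drop=True),
        pan,
        sex=sex.reset_index(drop=True),
        false_negative=false_negative.reset_index(drop=True) if false_negative is not None else None,
        screen_threshold=config.screen_threshold,
        alpha=config.alpha,
        robust_flavour=config.robust_flavour,
    )
    return matrix, est


def _report(config, rankings, outdir: Path) -> str:
    lines = [
        "# adipoquant run report",
        "",
        "## Provenance",
        "",
        f"- package version: {_pkg_version}",
        f"- seed: {config.seed}",
        f"- config sha256: {config.sha256()}",
        f"- screen threshold: {config.screen_threshold}; final alpha: {config.alpha}",
        f"- robust covariance: {config.robust_flavour}",
        "",
    ]
    for group, (matrix, ranking) in rankings.items():
        lines += [f"## Group: {group}", ""]
        lines += ["| rank | method | significant outcomes | n |", "|---|---|---|---|"]
        for i, row in enumerate(ranking, 1):
            outs = ", ".join(row["significant_outcomes"]) or "—"
            lines.append(f"| {i} | {row['method']} | {outs} | {row['n_significant']} |")
        lines += ["", "### Grid (— = not admitted / assumptions failed)", ""]
        header = "| outcome | " + " | ".join(matrix.methods) + " |"
        lines += [header, "|" + "---|" * (len(matrix.methods) + 1)]
        for o in matrix.outcomes:
            cells = []
            for m in matrix.methods:
                c = matrix.cells[(m, o)]
                if c.status == "significant":
                    cells.append(f"{c.result.beta:.3g}*")
                elif c.status == "not_significant":
                    cells.append(f"{c.result.beta:.3g}")
                else:
                    cells.append("—")
            lines.append(f"| {o} | " + " | ".join(cells) + " |")
        lines.append("")
    return "\n".join(lines)


def run_all(config: RunConfig) -> int:
    """simulate/read → battery → biomarkers → associate per group → rank.

    Writes subjects, estimates, panel, per-group grids, ranking and a
    Markdown report with a provenance block into ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    decimal = "," if config.decimal_comma else "."

    if config.input:
        log.info("stage=read input=%s", config.input)
        subjects, viol = read_subjects(config.input, config.column_mapping, decimal)
        panels, pviol = read_panels(config.input, config.column_mapping, decimal)
        for v in viol + pviol:
            log.warning("stage=read row=%s error=%s", v["row"], v["error"])
        if not subjects:
            log.error("stage=read no valid subjects")
            return 1
    else:
        log.info("stage=simulate seed=%d", config.seed)
        cohort = generate_cohort(CohortSpec(seed=config.seed))
        subjects, panels = cohort.subjects, cohort.panels
        write_cohort_csv(cohort, outdir / "subjects.csv")

    log.info("stage=battery n=%d methods=%d", len(subjects), len(config.methods))
    est, skips = battery_frame(
        subjects, list(config.methods),
        bia1_equation=config.bia1_equation,
        excess_thresholds=config.excess_fat_thresholds,
    )
    est.to_csv(outdir / "estimates.csv", index=False)

    log.info("stage=biomarkers n=%d", len(panels))
    sex_by_id = {s.subject_id: s.sex for s in subjects}
    pan = panels_to_frame(panels)
    flags = pd.DataFrame([
        dataclasses.asdict(risk_flags(p, sex_by_id[p.subject_id], config.cutoffs()))
        for p in panels if p.subject_id in sex_by_id
    ])
    pan.merge(flags, on="subject_id").to_csv(outdir / "panel.csv", index=False)

    rankings = {}
    for group in ("eutrophic", "overweight"):
        matrix, _ = _grid_for_group(config, subjects, panels, group)
        if matrix is None:
            log.info("stage=associate group=%s skipped (no subjects)", group)
            continue
        log.info("stage=associate group=%s cells=%d", group, len(matrix.cells))
        matrix.to_frame().to_csv(outdir / f"grid_{group}.csv", index=False)
        rankings[group] = (matrix, rank_methods(matrix))

    rank_rows = []
    for group, (_, ranking) in rankings.items():
        for i, row in enumerate(ranking, 1):
            rank_rows.append({"group": group, "rank": i, "method": row["method"],
                              "n_significant": row["n_significant"],
                              "mean_r_squared": row["mean_r_squared"]})
    pd.DataFrame(rank_rows).to_csv(outdir / "ranking.csv", index=False)

    (outdir / "report.md").write_text(_report(config, rankings, outdir))
    log.info("stage=done outdir=%s", outdir)
    return 0
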