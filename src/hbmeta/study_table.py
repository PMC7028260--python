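"""Study-level categorical dose-response data.

A meta-analysis of HbA1c (glycated hemoglobin, %) and atrial fibrillation
works from a long-format table: one row per exposure category per study,
plus study-level fields (population, outcome, a reported per-1% relative
risk where the source publication gives one).  This module defines the
in-memory model, CSV reading/writing with validation, and the bundled
fixture encoding the published study-level data the pipeline reproduces.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .errors import EmptyInputError, SchemaError, ValidationError

POPULATIONS = ("diabetes_or_IGT", "no_known_diabetes", "mixed")
OUTCOMES = ("AF", "POAF_CABG")

#: required columns of the input CSV, in canonical order
CSV_COLUMNS = [
    "study_id", "label", "population", "outcome", "adjusted", "stratum",
    "cat_lower", "cat_upper", "cat_point", "cases", "total",
    "rr", "ci_lower", "ci_upper", "is_reference",
    "per_unit_rr", "per_unit_lo", "per_unit_hi",
]
#: optional columns (flags, study margins used by re-referencing, category labels)
CSV_OPTIONAL = ["ami_cohort", "auxiliary", "study_cases", "study_total", "cat_label"]


@dataclass
class ExposureCategory:
    """One exposure category of one study.

    ``lower``/``upper`` are HbA1c % bounds; either may be absent for an
    open-ended interval.  ``point_value`` covers single-value categories
    such as a bare "5%".  ``assigned_dose`` is filled by the dose
    assignment step.  ``rr`` is the category's risk ratio against the
    study's own reference category.
    """

    lower: Optional[float] = None
    upper: Optional[float] = None
    point_value: Optional[float] = None
    assigned_dose: Optional[float] = None
    cases: Optional[int] = None
    total: Optional[int] = None
    rr: Optional[float] = None
    ci_lower: Optional[float] = None
    ci_upper: Optional[float] = None
    is_reference: bool = False
    label: str = ""

    def validate(self, study_id: str = "?") -> None:
        if self.lower is not None and self.upper is not None and not self.lower < self.upper:
            raise ValidationError(f"{study_id}: category lower {self.lower} must be < upper {self.upper}")
        if self.rr is not None and self.rr <= 0:
            raise ValidationError(f"{study_id}: rr must be positive, got {self.rr}")
        if self.rr is not None and self.ci_lower is not None and self.ci_upper is not None:
            if not self.ci_lower <= self.rr <= self.ci_upper:
                raise ValidationError(
                    f"{study_id}: CI ({self.ci_lower}, {self.ci_upper}) does not bracket rr {self.rr}"
                )
        if self.is_reference and self.rr is not None and self.rr != 1.0:
            raise ValidationError(f"{study_id}: reference category must have rr = 1, got {self.rr}")
        if self.cases is not None and self.total is not None and not 0 <= self.cases <= self.total:
            raise ValidationError(f"{study_id}: need 0 <= cases <= total, got {self.cases}/{self.total}")


@dataclass
class StudyRecord:
    """One analyzable unit: a study or a study stratum.

    Strata of one publication (e.g. a diabetic and a non-diabetic cohort
    reported separately) carry distinct ``study_id`` values and enter the
    pooled analysis as independent units.  ``auxiliary`` marks category
    sets kept for the nonlinear model only (they never enter the per-1%
    linear pool, whose effect lives on the parent record).
    """

    study_id: str
    label: str
    population: str
    outcome: str
    adjusted: bool = True
    stratum: str = ""
    per_unit_rr: Optional[float] = None
    per_unit_ci_lower: Optional[float] = None
    per_unit_ci_upper: Optional[float] = None
    categories: list[ExposureCategory] = field(default_factory=list)
    ami_cohort: bool = False
    auxiliary: bool = False
    study_cases: Optional[int] = None
    study_total: Optional[int] = None

    def validate(self) -> None:
        if self.population not in POPULATIONS:
            raise ValidationError(f"{self.study_id}: unknown population {self.population!r}")
        if self.outcome not in OUTCOMES:
            raise ValidationError(f"{self.study_id}: unknown outcome {self.outcome!r}")
        n_rr = sum(1 for c in self.categories if c.rr is not None)
        if self.per_unit_rr is None and n_rr < 2:
            raise ValidationError(
                f"{self.study_id}: record needs a per-unit RR or >=2 categories with RRs"
            )
        if self.categories:
            n_ref = sum(1 for c in self.categories if c.is_reference)
            if n_ref != 1:
                raise ValidationError(f"{self.study_id}: exactly one reference category required, found {n_ref}")
        for c in self.categories:
            c.validate(self.study_id)

    @property
    def n_dosed_categories(self) -> int:
        return sum(1 for c in self.categories if c.assigned_dose is not None and c.rr is not None)


@dataclass
class StudyTable:
    records: list[StudyRecord]
    provenance: str = ""

    def validate(self) -> None:
        ids = [r.study_id for r in self.records]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise ValidationError(f"duplicate study_id values: {sorted(dup)}")
        for r in self.records:
            r.validate()

    def subset(self, predicate) -> "StudyTable":
        return StudyTable([r for r in self.records if predicate(r)], self.provenance)

    def get(self, study_id: str) -> StudyRecord:
        for r in self.records:
            if r.study_id == study_id:
                return r
        raise KeyError(study_id)


_INTERVAL_RE = re.compile(r"^\s*([0-9.]+)\s*[-–—]\s*([0-9.]+)\s*%?\s*$")


def parse_interval(text: str) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """Parse interval text like ``"7–8%"``, ``">9%"``, ``"<6.5%"`` or ``"5%"``.

    Returns ``(lower, upper, point_value)``.  En-dash and hyphen are both
    accepted; ``>=``/``<=``/unicode variants are treated like strict
    inequalities (the bound is the open endpoint either way).
    """
    t = text.strip().rstrip("%").strip()
    m = _INTERVAL_RE.match(text)
    if m:
        return float(m.group(1)), float(m.group(2)), None
    if t.startswith((">", "≥")):
        return float(t.lstrip(">≥= ")), None, None
    if t.startswith(("<", "≤")):
        return None, float(t.lstrip("<≤= ")), None
    return None, None, float(t)


def _opt(v):
    if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
        return None
    return v


def _opt_float(v):
    v = _opt(v)
    return None if v is None else float(v)


def _opt_int(v):
    v = _opt(v)
    return None if v is None else int(float(v))


def _as_bool(v, default=False):
    v = _opt(v)
    if v is None:
        return default
    if isinstance(v, bool):
        return v
    return str(v).strip().lower() in ("true", "1", "yes")


def read_study_table(path, schema: Optional[dict] = None) -> StudyTable:
    """Read and validate a long-format study table CSV.

    Parameters
    ----------
    path : str or Path
        CSV with one exposure category per row (study-level-only rows have
        empty category fields).  Required columns: :data:`CSV_COLUMNS`.
    schema : dict, optional
        Mapping from the file's column names to the canonical names, for
        files using a different header vocabulary.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if schema:
        df = df.rename(columns=schema)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if df.empty:
        raise EmptyInputError(f"{path} contains no data rows")

    records = []
    for sid, grp in df.groupby("study_id", sort=False):
        first = grp.iloc[0]
        rec = StudyRecord(
            study_id=str(sid),
            label=str(first["label"]),
            population=str(first["population"]),
            outcome=str(first["outcome"]),
            adjusted=_as_bool(first["adjusted"], default=True),
            stratum=str(_opt(first["stratum"]) or ""),
            per_unit_rr=_opt_float(first["per_unit_rr"]),
            per_unit_ci_lower=_opt_float(first["per_unit_lo"]),
            per_unit_ci_upper=_opt_float(first["per_unit_hi"]),
            ami_cohort=_as_bool(first.get("ami_cohort"), default=False),
            auxiliary=_as_bool(first.get("auxiliary"), default=False),
            study_cases=_opt_int(first.get("study_cases")),
            study_total=_opt_int(first.get("study_total")),
        )
        for _, row in grp.iterrows():
            has_cat = any(
                _opt(row[c]) is not None
                for c in ("cat_lower", "cat_upper", "cat_point", "rr")
            ) or _as_bool(row["is_reference"])
            if not has_cat:
                continue
            rec.categories.append(ExposureCategory(
                lower=_opt_float(row["cat_lower"]),
                upper=_opt_float(row["cat_upper"]),
                point_value=_opt_float(row["cat_point"]),
                cases=_opt_int(row["cases"]),
                total=_opt_int(row["total"]),
                rr=_opt_float(row["rr"]),
                ci_lower=_opt_float(row["ci_lower"]),
                ci_upper=_opt_float(row["ci_upper"]),
                is_reference=_as_bool(row["is_reference"]),
                label=str(_opt(row.get("cat_label")) or ""),
            ))
        records.append(rec)

    table = StudyTable(records, provenance=str(path))
    table.validate()
    return table


def write_study_table(table: StudyTable, path) -> None:
    """Write a StudyTable to CSV in the canonical long-format schema."""
    rows = []
    for rec in table.records:
        base = {
            "study_id": rec.study_id, "label": rec.label,
            "population": rec.population, "outcome": rec.outcome,
            "adjusted": str(rec.adjusted).lower(), "stratum": rec.stratum,
            "per_unit_rr": rec.per_unit_rr, "per_unit_lo": rec.per_unit_ci_lower,
            "per_unit_hi": rec.per_unit_ci_upper,
            "ami_cohort": str(rec.ami_cohort).lower(),
            "auxiliary": str(rec.auxiliary).lower(),
            "study_cases": rec.study_cases, "study_total": rec.study_total,
        }
        cats = rec.categories or [None]
        for i, cat in enumerate(cats):
            row = dict(base) if i == 0 else {
                k: base[k] for k in ("study_id", "label", "population", "outcome",
                                     "adjusted", "stratum", "ami_cohort", "auxiliary")
            }
            if cat is not None:
                row.update({
                    "cat_lower": cat.lower, "cat_upper": cat.upper,
                    "cat_point": cat.point_value, "cases": cat.cases,
                    "total": cat.total, "rr": cat.rr,
                    "ci_lower": cat.ci_lower, "ci_upper": cat.ci_upper,
                    "is_reference": str(cat.is_reference).lower(),
                    "cat_label": cat.label,
                })
            rows.append(row)
    df = pd.DataFrame(rows, columns=CSV_COLUMNS + CSV_OPTIONAL)
    df.to_csv(path, index=False)


def _cats(rows: Iterable[tuple]) -> list[ExposureCategory]:
    out = []
    for interval, rr, lo, hi, *flags in rows:
        lower, upper, point = parse_interval(interval) if interval else (None, None, None)
        out.append(ExposureCategory(
            lower=lower, upper=upper, point_value=point,
            rr=rr, ci_lower=lo, ci_upper=hi,
            is_reference=bool(flags and flags[0]),
        ))
    return out


def table1_fixture() -> StudyTable:
    """The published study-level data, hand-encoded verbatim.

    Fourteen publications: eight on incident atrial fibrillation (one with
    diabetic and non-diabetic strata, one with paroxysmal/nonparoxysmal
    auxiliary category sets) and six on postoperative AF after coronary
    artery bypass grafting.  Per-1% relative risks, category-level RRs with
    95% CIs, and per-study case/participant margins are stored exactly as
    printed in the source table.
    """
    R = StudyRecord
    records = [
        # --- POAF after CABG ---------------------------------------------
        R("halkos", "Halkos", "mixed", "POAF_CABG", adjusted=True,
          per_unit_rr=0.89, per_unit_ci_lower=0.80, per_unit_ci_upper=0.98,
          study_cases=549, study_total=3089),
        R("matsuura", "Matsuura", "mixed", "POAF_CABG", adjusted=False,
          per_unit_rr=0.87, per_unit_ci_lower=0.64, per_unit_ci_upper=1.19,
          study_cases=26, study_total=101),
        R("tsuruta", "Tsuruta", "mixed", "POAF_CABG", adjusted=False,
          per_unit_rr=1.12, per_unit_ci_lower=0.76, per_unit_ci_upper=1.65,
          study_cases=36, study_total=305,
          categories=_cats([
              ("<6.5%", 1.0, None, None, True),
              ("6.5–7.5%", 0.89, 0.36, 2.21),
              (">=7.5%", 1.25, 0.58, 2.71),
          ])),
        R("kinoshita", "Kinoshita", "mixed", "POAF_CABG", adjusted=True,
          per_unit_rr=0.78, per_unit_ci_lower=0.63, per_unit_ci_upper=0.95,
          study_cases=159, study_total=805,
          categories=_cats([
              ("3.8–5.6%", 1.0, None, None, True),
              ("6.8–11.4%", 0.55, 0.35, 0.88),
          ])),
        R("surer", "Surer", "mixed", "POAF_CABG", adjusted=False,
          per_unit_rr=3.92, per_unit_ci_lower=1.92, per_unit_ci_upper=7.99,
          study_cases=12, study_total=72),
        R("abbaszadeh", "Abbaszadeh", "mixed", "POAF_CABG", adjusted=True,
          per_unit_rr=1.06, per_unit_ci_lower=0.93, per_unit_ci_upper=1.2,
          study_cases=109, study_total=708),
        # --- incident AF --------------------------------------------------
        R("dublin", "Dublin", "no_known_diabetes", "AF", adjusted=True,
          per_unit_rr=1.14, per_unit_ci_lower=0.96, per_unit_ci_upper=1.35,
          study_cases=1410, study_total=3613,
          categories=_cats([
              ("5%", 1.0, None, None, True),
              ("<=7%", 1.06, 0.74, 1.51),
              ("7–8%", 1.48, 1.09, 2.01),
              ("8–9%", 1.46, 1.02, 2.08),
              (">9%", 1.96, 1.22, 3.14),
          ])),
        R("huxley_nondm", "Huxley", "no_known_diabetes", "AF", adjusted=True,
          stratum="non-DM",
          per_unit_rr=1.05, per_unit_ci_lower=0.96, per_unit_ci_upper=1.15,
          study_cases=1311, study_total=13025),
        R("huxley_dm", "Huxley", "diabetes_or_IGT", "AF", adjusted=True,
          stratum="DM",
          per_unit_rr=1.13, per_unit_ci_lower=1.07, per_unit_ci_upper=1.20,
          study_cases=1311, study_total=13025),
        R("iguchi", "Iguchi", "no_known_diabetes", "AF", adjusted=True,
          per_unit_rr=1.18, per_unit_ci_lower=1.09, per_unit_ci_upper=1.28,
          study_cases=1161, study_total=52448),
        R("turgut", "Turgut", "diabetes_or_IGT", "AF", adjusted=True,
          per_unit_rr=1.87, per_unit_ci_lower=0.747, per_unit_ci_upper=3.014,
          study_cases=81, study_total=162),
        R("latini", "Latini", "diabetes_or_IGT", "AF", adjusted=True,
          per_unit_rr=1.11, per_unit_ci_lower=0.91, per_unit_ci_upper=1.32,
          study_cases=613, study_total=8943),
        R("sandhu", "Sandhu", "no_known_diabetes", "AF", adjusted=True,
          per_unit_rr=1.08, per_unit_ci_lower=0.95, per_unit_ci_upper=1.22,
          study_cases=1039, study_total=34720),
        R("sandhu_parox", "Sandhu", "no_known_diabetes", "AF", adjusted=True,
          stratum="paroxysmal", auxiliary=True,
          study_cases=1039, study_total=34720,
          categories=_cats([
              ("<=4.84%", 1.0, None, None, True),
              ("4.84–5.00%", 0.90, 0.69, 1.17),
              ("5.00–5.19%", 0.99, 0.77, 1.27),
              (">5.19%", 0.76, 0.58, 1.00),
          ])),
        R("sandhu_nonparox", "Sandhu", "no_known_diabetes", "AF", adjusted=True,
          stratum="nonparoxysmal", auxiliary=True,
          study_cases=1039, study_total=34720,
          categories=_cats([
              ("<=4.84%", 1.0, None, None, True),
              ("4.84–5.00%", 1.30, 0.85, 1.97),
              ("5.00–5.19%", 1.43, 0.96, 2.15),
              (">5.19%", 1.48, 0.98, 2.22),
          ])),
        R("blasco", "Blasco", "no_known_diabetes", "AF", adjusted=True,
          ami_cohort=True,
          per_unit_rr=3.24, per_unit_ci_lower=2.41, per_unit_ci_upper=4.35,
          study_cases=12, study_total=601,
          categories=_cats([
              ("<5.5%", 1.0, None, None, True),
              ("5.5–6.4%", 1.68, 0.64, 4.39),
              (">6.4%", 29.74, 10.79, 81.94),
          ])),
        R("dahlqvist", "Dahlqvist", "diabetes_or_IGT", "AF", adjusted=True,
          per_unit_rr=1.14, per_unit_ci_lower=1.06, per_unit_ci_upper=1.24,
          study_cases=1283, study_total=216852,
          categories=[ExposureCategory(rr=1.0, is_reference=True, label="Control")] + _cats([
              ("<6.9%", 1.03, 0.84, 1.27),
              ("7.0–7.8%", 1.11, 0.97, 1.28),
              ("7.8–8.7%", 1.28, 1.12, 1.47),
              ("8.8–9.6%", 1.4, 1.15, 1.69),
              (">9.7%", 2.32, 1.8, 2.99),
          ])),
    ]
    table = StudyTable(records, provenance="bundled published study-level data")
    table.validate()
    return table


def packaged_fixture_path() -> Path:
    """Path to the packaged CSV copy of :func:`table1_fixture`."""
    return Path(resources.files("hbmeta").joinpath("data/study_table.csv"))
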