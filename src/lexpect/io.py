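"""Reading and writing the tabular artifacts of the analysis.

Subject records arrive as a CSV of baseline lifestyle measurements and
follow-up intervals; the national reference life table as a CSV of
per-band fractions of the last age interval and national mortality rates.
Rows failing validation are collected into a rejection report with the row
number and reason, never silently dropped.  All internal arithmetic is at
full precision; rounding to one decimal happens only at serialization.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .bands import OPEN, AgeBandGrid, DEFAULT_GRID
from .scoring import BehaviorProfile, LifestyleAssessment
from .sentinels import UNDEFINED, UNDEFINED_DISPLAY, is_undefined


class ConfigurationError(ValueError):
    """Input file cannot support the analysis (missing columns/rows)."""


# ---------------------------------------------------------------------------
# subject records
# ---------------------------------------------------------------------------

MIN_ENTRY_AGE = 40.0
MAX_ENTRY_AGE = 79.0  # entries above this are accepted with a warning

_RAW_LIFESTYLE_COLUMNS = (
    "smoking_status", "drinker_status", "alcohol_g_per_occasion",
    "walking_h_per_day", "sleep_h_per_day", "greens_daily", "bmi",
)
_DICHOTOMIZED_COLUMNS = (
    "b_smoke", "b_alcohol", "b_walk", "b_sleep", "b_greens", "b_bmi",
)


@dataclass(frozen=True)
class SubjectRecord:
    """One participant's follow-up interval, vital status and lifestyle.

    ``lifestyle`` holds the raw assessment when available; ``profile`` the
    pre-dichotomized flags.  At least one of the two is always present.
    """

    subject_id: str
    sex: str  # "male" | "female"
    age_entry: float
    age_exit: float
    died: bool  # True = death at age_exit, False = censored at age_exit
    lifestyle: LifestyleAssessment | None = None
    profile: BehaviorProfile | None = None

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise ValueError(f"bad sex {self.sex!r}")
        if not self.age_exit > self.age_entry:
            raise ValueError("age_exit must exceed age_entry")
        if self.age_entry < MIN_ENTRY_AGE:
            raise ValueError(f"age_entry below {MIN_ENTRY_AGE}")
        if self.lifestyle is None and self.profile is None:
            raise ValueError("record needs lifestyle or profile")


@dataclass(frozen=True)
class RowRejection:
    row_number: int  # 1-based data-row index (header excluded)
    reason: str


@dataclass
class ReadResult:
    records: list[SubjectRecord]
    rejections: list[RowRejection] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class SubjectSchema:
    """Column mapping for the subjects CSV.

    ``dichotomized`` selects the pre-dichotomized six-flag layout instead
    of raw lifestyle measurements.  ``columns`` renames CSV headers to the
    canonical field names (canonical name -> CSV header).
    """

    dichotomized: bool = False
    columns: dict = field(default_factory=dict)

    def col(self, name: str) -> str:
        return self.columns.get(name, name)


_SEX_CODES = {"male": "male", "m": "male", "1": "male",
              "female": "female", "f": "female", "2": "female"}
_BOOL_CODES = {"1": True, "true": True, "yes": True, "t": True,
               "0": False, "false": False, "no": False, "f": False}


def _parse_bool(text: str):
    return _BOOL_CODES.get(str(text).strip().lower())


def read_subjects(path, schema: SubjectSchema | None = None) -> ReadResult:
    """Read and validate subject records from a CSV file.

    Rows violating the record invariants (non-positive follow-up, entry
    below 40, unparseable codes) or missing any of the six lifestyle
    fields are rejected with a reason; valid rows become
    :class:`SubjectRecord` instances.  Entries above age 79 are accepted
    with a warning (the cohort enrolled ages 40-79).
    """
    schema = schema or SubjectSchema()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)

    mandatory = ["subject_id", "sex", "age_entry", "age_exit", "died"]
    mandatory += list(_DICHOTOMIZED_COLUMNS if schema.dichotomized
                      else _RAW_LIFESTYLE_COLUMNS)
    missing = [schema.col(c) for c in mandatory
               if schema.col(c) not in df.columns]
    # blank alcohol grams are allowed when drinker status says non-drinker
    missing = [c for c in missing
               if c != schema.col("alcohol_g_per_occasion")]
    if missing:
        raise ConfigurationError(f"subjects CSV missing columns: {missing}")

    result = ReadResult(records=[])
    n_over = 0
    for i, row in enumerate(df.to_dict(orient="records"), start=1):
        def get(name, row=row):
            return str(row.get(schema.col(name), "")).strip()

        sex = _SEX_CODES.get(get("sex").lower())
        if sex is None:
            result.rejections.append(RowRejection(i, "unparseable sex"))
            continue
        died = _parse_bool(get("died"))
        if died is None:
            result.rejections.append(
                RowRejection(i, "unparseable vital status"))
            continue
        try:
            age_entry = float(get("age_entry"))
            age_exit = float(get("age_exit"))
        except ValueError:
            result.rejections.append(RowRejection(i, "unparseable age"))
            continue
        if not age_exit > age_entry:
            result.rejections.append(
                RowRejection(i, "age_exit not after age_entry"))
            continue
        if age_entry < MIN_ENTRY_AGE:
            result.rejections.append(
                RowRejection(i, f"age_entry below {MIN_ENTRY_AGE:g}"))
            continue
        if age_entry > MAX_ENTRY_AGE:
            n_over += 1

        lifestyle = profile = None
        if schema.dichotomized:
            flags = [_parse_bool(get(c)) for c in _DICHOTOMIZED_COLUMNS]
            if any(f is None for f in flags):
                result.rejections.append(
                    RowRejection(i, "incomplete lifestyle"))
                continue
            profile = BehaviorProfile(*flags)
        else:
            raw = {c: get(c) for c in _RAW_LIFESTYLE_COLUMNS}
            drinker = raw["drinker_status"].lower()
            if raw["alcohol_g_per_occasion"] == "" and drinker in (
                    "never", "former"):
                raw["alcohol_g_per_occasion"] = "0"
            if any(v == "" for v in raw.values()):
                result.rejections.append(
                    RowRejection(i, "incomplete lifestyle"))
                continue
            greens = _parse_bool(raw["greens_daily"])
            if greens is None:
                result.rejections.append(
                    RowRejection(i, "incomplete lifestyle"))
                continue
            try:
                lifestyle = LifestyleAssessment(
                    smoking_status=raw["smoking_status"].lower(),
                    drinker_status=drinker,
                    alcohol_g_per_occasion=float(
                        raw["alcohol_g_per_occasion"]),
                    walking_h_per_day=float(raw["walking_h_per_day"]),
                    sleep_h_per_day=float(raw["sleep_h_per_day"]),
                    greens_daily=greens,
                    bmi=float(raw["bmi"]),
                )
            except ValueError:
                result.rejections.append(
                    RowRejection(i, "incomplete lifestyle"))
                continue

        result.records.append(SubjectRecord(
            subject_id=get("subject_id"), sex=sex,
            age_entry=age_entry, age_exit=age_exit, died=died,
            lifestyle=lifestyle, profile=profile,
        ))

    if n_over:
        msg = f"{n_over} subjects entered above age {MAX_ENTRY_AGE:g}"
        result.warnings.append(msg)
        warnings.warn(msg, stacklevel=2)
    return result


def write_subjects(records: Iterable[SubjectRecord], path) -> None:
    """Write subject records as the raw-schema CSV (round-trips through
    :func:`read_subjects` when raw lifestyle fields are present)."""
    rows = []
    for r in records:
        a = r.lifestyle
        row = {
            "subject_id": r.subject_id, "sex": r.sex,
            "age_entry": repr(r.age_entry), "age_exit": repr(r.age_exit),
            "died": int(r.died),
        }
        if a is not None:
            row.update({
                "smoking_status": a.smoking_status,
                "drinker_status": a.drinker_status,
                "alcohol_g_per_occasion": repr(a.alcohol_g_per_occasion),
                "walking_h_per_day": repr(a.walking_h_per_day),
                "sleep_h_per_day": repr(a.sleep_h_per_day),
                "greens_daily": int(a.greens_daily),
                "bmi": repr(a.bmi),
            })
        else:
            p = r.profile
            row.update(dict(zip(_DICHOTOMIZED_COLUMNS,
                                (int(f) for f in p.flags))))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# national reference life table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceLifeTable:
    """National reference values on the analysis grid.

    ``a_fraction`` maps closed-band starts to the average fraction of the
    band lived by those dying in it; ``national_rate`` maps band labels
    (closed starts, the 85-89 tracking band, and "85+") to national
    mortality rates per person-year.  The 85-89 and 85+ rates drive the
    open-interval correction.
    """

    a_fraction: dict
    national_rate: dict
    grid: AgeBandGrid = DEFAULT_GRID

    def __post_init__(self):
        t = self.grid.tracking_start
        for band in (t, OPEN):
            if self.national_rate.get(band, 0.0) <= 0.0:
                raise ConfigurationError(
                    f"reference life table needs a positive rate for "
                    f"{'85+' if band == OPEN else '85-89'}")
        for b, a in self.a_fraction.items():
            if not 0.0 < a < 1.0:
                raise ConfigurationError(
                    f"a_fraction {a} out of (0,1) at band {b}")

    def a(self, band, default: float = 0.5) -> float:
        """Fraction of last age interval for a band (0.5 when absent)."""
        return self.a_fraction.get(band, default)

    @property
    def open_rate_ratio(self) -> float:
        """National 85+ rate over national 85-89 rate."""
        return (self.national_rate[OPEN]
                / self.national_rate[self.grid.tracking_start])


def read_reference_lifetable(path, grid: AgeBandGrid = DEFAULT_GRID
                             ) -> ReferenceLifeTable:
    """Read the national reference CSV (columns: age_start, a_fraction,
    national_rate).  ``age_start`` is a band start; ``85`` means the
    85-89 band and ``85+`` the open interval."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    needed = {"age_start", "a_fraction", "national_rate"}
    if not needed.issubset(df.columns):
        raise ConfigurationError(
            f"reference CSV missing columns: {sorted(needed - set(df.columns))}")
    a_fraction: dict = {}
    national_rate: dict = {}
    for row in df.to_dict(orient="records"):
        key = str(row["age_start"]).strip()
        band = OPEN if key == "85+" else float(key)
        rate = str(row["national_rate"]).strip()
        if rate != "":
            national_rate[band] = float(rate)
        frac = str(row["a_fraction"]).strip()
        if frac != "" and band != OPEN:
            a_fraction[band] = float(frac)
    if grid.tracking_start not in national_rate:
        raise ConfigurationError("reference life table lacks the 85-89 row")
    if OPEN not in national_rate:
        raise ConfigurationError("reference life table lacks the 85+ row")
    return ReferenceLifeTable(a_fraction=a_fraction,
                              national_rate=national_rate, grid=grid)


def write_reference_lifetable(ref: ReferenceLifeTable, path) -> None:
    rows = []
    for band in ref.grid.table_bands:
        rows.append({
            "age_start": "85+" if band == OPEN else f"{band:g}",
            "a_fraction": (repr(float(ref.a_fraction[band]))
                           if band in ref.a_fraction else ""),
            "national_rate": (repr(float(ref.national_rate[band]))
                              if band in ref.national_rate else ""),
        })
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# report writing
# ---------------------------------------------------------------------------

def _render_value(v, decimals: int):
    if is_undefined(v) or v is None:
        return UNDEFINED_DISPLAY
    if isinstance(v, float):
        return f"{v:.{decimals}f}"
    return v


def write_report(table: pd.DataFrame, path, format: str = "csv",
                 decimals: int = 1,
                 rounded_columns: tuple[str, ...] | None = None) -> None:
    """Serialize a report table with deterministic column order.

    Float cells in *rounded_columns* (all float cells when None) are
    rounded to *decimals* places at serialization only; undefined
    estimates render as an em dash in CSV and as null in JSON.
    """
    path = Path(path)
    cols = list(table.columns)

    def rounded(col):
        return rounded_columns is None or col in rounded_columns

    if format == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(cols)
            for _, row in table.iterrows():
                w.writerow([
                    _render_value(row[c], decimals) if rounded(c)
                    else ("" if row[c] is None else row[c])
                    for c in cols])
    elif format == "json":
        out = []
        for _, row in table.iterrows():
            rec = {}
            for c in cols:
                v = row[c]
                if is_undefined(v):
                    rec[c] = None
                elif isinstance(v, float) and rounded(c):
                    rec[c] = round(v, decimals)
                else:
                    rec[c] = v
            out.append(rec)
        path.write_text(json.dumps(out, indent=2, ensure_ascii=False),
                        encoding="utf-8")
    else:
        raise ValueError(f"unknown report format {format!r}")
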