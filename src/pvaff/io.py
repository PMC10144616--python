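"""Reading, deduplication, recoding and merging of JADER-shaped report tables.

A spontaneous-report extract arrives as four linked CSV tables keyed by a
case identifier:

* ``DRUG`` — one row per reported drug: name, involvement role (suspect /
  concomitant / interaction) and administration start date;
* ``REAC`` — one row per adverse event: preferred term and onset date;
* ``DEMO`` — one row per case submission: report version, sex and coded
  age / height / weight;
* ``HIST`` — one row per primary-disease preferred term.

This module turns those four tables into a single per-case analysis table:
duplicate submissions are resolved (highest report version wins), decade
codes are converted to band midpoints, BMI is computed and implausible
values (< 10 or > 100 kg/m²) are excluded, only suspect-role drugs are
kept, and history terms are collapsed into the five SMQ groups. Per
(drug, event) pairs with both dates present, the time to onset in days is
computed as ``event date − start date + 1`` (same-day onset counts as
day 1).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .smq import HISTORY_GROUPS, SmqMap, assign_history_groups

logger = logging.getLogger(__name__)

ROLE_SUSPECT = "suspect"
ROLES = frozenset({"suspect", "concomitant", "interaction"})

#: canonical column sets per table
TABLE_COLUMNS: dict[str, tuple[str, ...]] = {
    "drug": ("case_id", "drug_name", "role", "start_date"),
    "reac": ("case_id", "event_term", "event_date"),
    "demo": ("case_id", "report_version", "sex", "age_code", "height_code", "weight_code"),
    "hist": ("case_id", "disease_term"),
}


def default_dialect() -> dict:
    """Identity column mapping with UTF-8 encoding.

    A dialect maps each table's canonical column names to the names used in
    the files, plus an ``encoding`` entry; real JADER extracts (Shift-JIS,
    Japanese headers) are handled by supplying a different mapping.
    """
    return {
        "encoding": "utf-8",
        **{t: {c: c for c in cols} for t, cols in TABLE_COLUMNS.items()},
    }


@dataclass
class RawTables:
    """The four report tables with canonical column names."""

    drug: pd.DataFrame
    reac: pd.DataFrame
    demo: pd.DataFrame
    hist: pd.DataFrame

    def validate(self) -> None:
        known = set(self.demo["case_id"])
        for name in ("drug", "reac", "hist"):
            orphans = set(getattr(self, name)["case_id"]) - known
            if orphans:
                logger.warning(
                    "%d case id(s) in %s absent from DEMO (e.g. %s)",
                    len(orphans), name.upper(), sorted(orphans)[:3],
                )
        if (self.demo["report_version"] < 1).any():
            raise ValueError("DEMO report_version must be >= 1")

    def copy(self) -> "RawTables":
        return RawTables(
            self.drug.copy(), self.reac.copy(), self.demo.copy(), self.hist.copy()
        )


@dataclass
class FilterReport:
    """Record-flow accounting across deduplication and BMI filtering.

    Counts are case submissions. ``n_input`` is the number of DEMO rows;
    every removal is attributed to exactly one category, so
    ``n_output = n_input − n_removed_dedup − n_removed_no_suspect
    − n_removed_bmi_low − n_removed_bmi_high`` holds on every run.
    """

    n_input: int = 0
    n_removed_dedup: int = 0
    n_removed_no_suspect: int = 0
    n_removed_bmi_low: int = 0
    n_removed_bmi_high: int = 0
    n_output: int = 0

    def is_conserved(self) -> bool:
        return self.n_output == (
            self.n_input
            - self.n_removed_dedup
            - self.n_removed_no_suspect
            - self.n_removed_bmi_low
            - self.n_removed_bmi_high
        ) and min(
            self.n_input,
            self.n_removed_dedup,
            self.n_removed_no_suspect,
            self.n_removed_bmi_low,
            self.n_removed_bmi_high,
            self.n_output,
        ) >= 0

    def to_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


@dataclass
class AnalysisTable:
    """Merged per-case analysis table plus per-(drug, event) onset durations.

    ``records`` has one row per retained case: demographics, BMI, the five
    ``hist_*`` flags, and frozensets ``suspect_drugs`` / ``events``.
    ``onsets`` is long-format: case_id, drug, event_term, onset_days.
    """

    records: pd.DataFrame
    onsets: pd.DataFrame
    report: FilterReport = field(default_factory=FilterReport)


# ---------------------------------------------------------------------------
# reading


def _parse_dates(raw: pd.Series, table: str, column: str) -> tuple[pd.Series, pd.Series]:
    """Parse ISO dates; year-month values resolve to day 1 and are flagged."""
    s = raw.fillna("").astype(str).str.strip()
    imprecise = s.str.fullmatch(r"\d{4}-\d{2}")
    s = s.where(~imprecise, s + "-01")
    parsed = pd.to_datetime(s, format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & (s != "")
    if bad.any():
        logger.warning(
            "%d unparseable %s value(s) in %s set to missing (e.g. %r)",
            int(bad.sum()), column, table.upper(), s[bad].iloc[0],
        )
    if imprecise.any():
        logger.warning(
            "%d year-month %s value(s) in %s resolved to day 1",
            int(imprecise.sum()), column, table.upper(),
        )
    return parsed, imprecise.fillna(False)


def read_tables(paths: Mapping[str, str | Path], dialect: dict | None = None) -> RawTables:
    """Read the four CSV tables into canonical form.

    ``paths`` maps table names (``drug``/``reac``/``demo``/``hist``) to file
    paths. Missing files and missing mandatory columns are fatal; dates that
    do not parse become missing with a warning.
    """
    dialect = dialect or default_dialect()
    encoding = dialect.get("encoding", "utf-8")
    frames: dict[str, pd.DataFrame] = {}
    for table, columns in TABLE_COLUMNS.items():
        if table not in paths:
            raise FileNotFoundError(f"no path given for table {table.upper()}")
        path = Path(paths[table])
        if not path.exists():
            raise FileNotFoundError(f"{table.upper()} table file not found: {path}")
        colmap = dialect.get(table, {})
        df = pd.read_csv(path, dtype=str, encoding=encoding, keep_default_na=False)
        rename = {colmap.get(c, c): c for c in columns}
        missing = [src for src in rename if src not in df.columns]
        if missing:
            canon = [rename[m] for m in missing]
            raise ValueError(
                f"{canon[0]} column absent from {table.upper()} table ({path})"
            )
        df = df.rename(columns=rename)[list(columns)]
        df = df.replace({"": pd.NA})
        frames[table] = df

    drug, reac, demo, hist = (frames[t] for t in ("drug", "reac", "demo", "hist"))
    drug["role"] = drug["role"].fillna("").str.strip().str.casefold()
    unknown = ~drug["role"].isin(ROLES) & (drug["role"] != "")
    if unknown.any():
        logger.warning("%d DRUG row(s) with unrecognized role kept as non-suspect",
                       int(unknown.sum()))
    drug["start_date"], drug["start_date_imprecise"] = _parse_dates(
        drug["start_date"], "drug", "start_date")
    reac["event_date"], reac["event_date_imprecise"] = _parse_dates(
        reac["event_date"], "reac", "event_date")
    demo["report_version"] = pd.to_numeric(demo["report_version"], errors="coerce")
    if demo["report_version"].isna().any():
        logger.warning("missing/unparseable report_version treated as 1")
        demo["report_version"] = demo["report_version"].fillna(1)
    demo["report_version"] = demo["report_version"].astype(int)

    tables = RawTables(drug, reac, demo, hist)
    tables.validate()
    return tables


def write_tables(tables: RawTables, out_dir: str | Path) -> dict[str, Path]:
    """Write the four tables as CSV in the canonical dialect; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, cols in TABLE_COLUMNS.items():
        df = getattr(tables, name)[list(cols)].copy()
        for c in df.columns:
            if pd.api.types.is_datetime64_any_dtype(df[c]):
                df[c] = df[c].dt.strftime("%Y-%m-%d")
        paths[name] = out / f"{name}.csv"
        df.to_csv(paths[name], index=False)
    return paths


# ---------------------------------------------------------------------------
# deduplication


def deduplicate(tables: RawTables) -> tuple[RawTables, int]:
    """Resolve duplicate case submissions; latest report version wins.

    Returns the deduplicated tables and the number of DEMO submission rows
    removed. Within a kept case, exact duplicate (drug_name, role) and
    event rows collapse to one. Idempotent.
    """
    demo = tables.demo.sort_values(
        ["case_id", "report_version"], kind="mergesort"
    ).drop_duplicates("case_id", keep="last")
    removed = len(tables.demo) - len(demo)
    drug = tables.drug.drop_duplicates(subset=["case_id", "drug_name", "role"])
    reac = tables.reac.drop_duplicates(subset=["case_id", "event_term"])
    hist = tables.hist.drop_duplicates(subset=["case_id", "disease_term"])
    return RawTables(drug, reac, demo.reset_index(drop=True), hist), removed


# ---------------------------------------------------------------------------
# demographic recoding

_DECADE = re.compile(r"^(\d+)s$")
_UNDER_10 = {"under 10", "under10", "<10", "under 10 years", "0s"}


def recode_value(code: object) -> float:
    """Convert one coded demographic value to a number.

    Decade-band codes (``"60s"``) map to the band midpoint (65); codes
    denoting an age below ten years map to 5; numeric literals pass
    through; anything else becomes missing with a warning.
    """
    if code is None or (isinstance(code, float) and np.isnan(code)) or code is pd.NA:
        return np.nan
    s = str(code).strip().casefold()
    if not s:
        return np.nan
    m = _DECADE.match(s)
    if m:
        if int(m.group(1)) == 0:
            return 5.0
        return float(m.group(1)) + 5.0
    if s in _UNDER_10:
        return 5.0
    try:
        return float(s)
    except ValueError:
        logger.warning("unrecognized demographic code %r set to missing", code)
        return np.nan


def recode_demographics(demo: pd.DataFrame) -> pd.DataFrame:
    """Add numeric ``age_years``, ``height_cm``, ``weight_kg`` and clean sex."""
    out = demo.copy()
    out["age_years"] = out["age_code"].map(recode_value)
    out["height_cm"] = out["height_code"].map(recode_value)
    out["weight_kg"] = out["weight_code"].map(recode_value)
    sex = out["sex"].fillna("").astype(str).str.strip().str.casefold()
    out["sex"] = sex.where(sex.isin(("male", "female")), pd.NA).replace("", pd.NA)
    return out


# ---------------------------------------------------------------------------
# BMI


def compute_and_filter_bmi(
    records: pd.DataFrame,
) -> tuple[pd.DataFrame, int, int]:
    """Compute BMI and drop implausible records (BMI < 10 or > 100).

    BMI = weight / (height/100)²; non-positive height or weight yields a
    missing BMI and the record is retained; the bounds are strict, so BMI
    exactly 10 or 100 is kept. Returns (records, n_low, n_high).
    """
    out = records.copy()
    h = out["height_cm"].to_numpy(float)
    w = out["weight_kg"].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        bmi = np.where((h > 0) & (w > 0), w / (h / 100.0) ** 2, np.nan)
    out["bmi"] = bmi
    low = bmi < 10.0
    high = bmi > 100.0
    keep = ~(low | high) | np.isnan(bmi)
    return out.loc[keep].reset_index(drop=True), int(np.nansum(low)), int(np.nansum(high))


# ---------------------------------------------------------------------------
# merging


def build_analysis_table(tables: RawTables, smq: SmqMap) -> AnalysisTable:
    """Merge the (deduplicated) four tables into the per-case analysis table.

    Only suspect-role drug rows contribute; cases with no suspect drug are
    excluded; cases in DRUG/REAC/HIST missing from DEMO are skipped with a
    warning. Applies demographic recoding and BMI filtering, and returns a
    :class:`FilterReport` whose dedup field the caller may fill in.
    """
    demo = recode_demographics(tables.demo)
    n_input = len(demo)

    suspect = tables.drug[tables.drug["role"] == ROLE_SUSPECT]
    known = set(demo["case_id"])
    orphan = ~suspect["case_id"].isin(known)
    if orphan.any():
        logger.warning("%d suspect DRUG row(s) for cases absent from DEMO skipped",
                       int(orphan.sum()))
    suspect = suspect.loc[~orphan]

    drugs_by_case = suspect.groupby("case_id")["drug_name"].agg(frozenset)
    events_by_case = tables.reac[tables.reac["case_id"].isin(known)].groupby(
        "case_id")["event_term"].agg(frozenset)
    hist_by_case = tables.hist[tables.hist["case_id"].isin(known)].groupby(
        "case_id")["disease_term"].agg(set)

    records = demo.set_index("case_id")
    records["suspect_drugs"] = drugs_by_case
    records["events"] = events_by_case
    no_suspect = records["suspect_drugs"].isna()
    n_no_suspect = int(no_suspect.sum())
    if n_no_suspect:
        logger.info("%d case(s) without a suspect drug excluded", n_no_suspect)
    records = records.loc[~no_suspect]
    records["events"] = records["events"].apply(
        lambda v: v if isinstance(v, frozenset) else frozenset())

    flags = pd.DataFrame(
        [
            assign_history_groups(hist_by_case.get(cid, set()), smq)
            for cid in records.index
        ],
        index=records.index,
    ).rename(columns={g: f"hist_{g}" for g in HISTORY_GROUPS})
    records = pd.concat([records, flags], axis=1).reset_index()

    records, n_low, n_high = compute_and_filter_bmi(records)

    onsets = _onset_durations(suspect, tables.reac, set(records["case_id"]))

    report = FilterReport(
        n_input=n_input,
        n_removed_no_suspect=n_no_suspect,
        n_removed_bmi_low=n_low,
        n_removed_bmi_high=n_high,
        n_output=len(records),
    )
    cols = (
        ["case_id", "report_version", "sex", "age_years", "height_cm",
         "weight_kg", "bmi"]
        + [f"hist_{g}" for g in HISTORY_GROUPS]
        + ["suspect_drugs", "events"]
    )
    return AnalysisTable(records[cols], onsets, report)


def _onset_durations(
    suspect: pd.DataFrame, reac: pd.DataFrame, case_ids: set
) -> pd.DataFrame:
    """Per (case, drug, event) time to onset: event − start + 1 days."""
    d = suspect.dropna(subset=["start_date"])
    r = reac.dropna(subset=["event_date"])
    merged = d.merge(r, on="case_id")
    merged = merged[merged["case_id"].isin(case_ids)]
    days = (merged["event_date"] - merged["start_date"]).dt.days + 1
    neg = days < 1
    if neg.any():
        logger.warning(
            "%d (drug, event) pair(s) with event before administration excluded",
            int(neg.sum()),
        )
    out = merged.loc[~neg, ["case_id", "drug_name", "event_term"]].copy()
    out["onset_days"] = days[~neg].astype(int)
    return out.reset_index(drop=True)


def onset_days(start_date, event_date) -> int:
    """Days from administration start to event, counting the start day.

    Same-day onset is day 1. Raises ``ValueError`` if the event precedes
    the start or either date is missing.
    """
    start = pd.Timestamp(start_date)
    event = pd.Timestamp(event_date)
    if pd.isna(start) or pd.isna(event):
        raise ValueError("both dates must be present")
    days = (event - start).days + 1
    if days < 1:
        raise ValueError("event date precedes administration start")
    return int(days)


def preprocess(tables: RawTables, smq: SmqMap) -> AnalysisTable:
    """Deduplicate, merge and filter: the full preparation stage in one call."""
    n_demo = len(tables.demo)
    deduped, removed = deduplicate(tables)
    table = build_analysis_table(deduped, smq)
    table.report.n_input = n_demo
    table.report.n_removed_dedup = removed
    return table
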