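"""Report deduplication, cohort selection, subgroup filters and descriptives.

A FAERS case (CASEID) accumulates follow-up reports over time, each with
its own PRIMARYID and FDA receipt date.  Deduplication keeps, per case,
the report with the highest FDA_DT, breaking ties by the highest
PRIMARYID (compared numerically) — the FDA-recommended practice.

The cohort is then the set of deduplicated reports in which the drug of
interest appears with the requested role code (primary suspect by
default), carrying along its reaction and therapy rows.  The event
counting unit throughout the package is one distinct (report, PT) pair.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (
    DatePrecision,
    PartialDate,
    RawTable,
    parse_partial_date,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Sex",
    "Reporter",
    "AgeBand",
    "ReportRecord",
    "CaseSet",
    "SubgroupSpec",
    "deduplicate",
    "select_cohort",
    "monotherapy_filter",
    "subgroup_filter",
    "descriptive_summary",
    "normalize_drugname",
    "convert_age_to_years",
]


class Sex(str, enum.Enum):
    M = "M"
    F = "F"
    UNKNOWN = "UNKNOWN"


class Reporter(str, enum.Enum):
    HEALTHCARE = "HEALTHCARE"
    NON_HEALTHCARE = "NON_HEALTHCARE"
    UNKNOWN = "UNKNOWN"


class AgeBand(str, enum.Enum):
    """Half-open age bands partitioning [0, 125): <18, [18,65), [65,85), >=85.

    The bands are printed ambiguously in most FAERS reports ("18-65 /
    65-85 / >85"); half-open intervals are used so that the bands
    partition the age axis with no double counting at 65 and 85.
    """

    UNDER_18 = "UNDER_18"
    FROM_18_TO_65 = "FROM_18_TO_65"
    FROM_65_TO_85 = "FROM_65_TO_85"
    OVER_85 = "OVER_85"

    @staticmethod
    def of(age_years: float) -> "AgeBand":
        if age_years < 18:
            return AgeBand.UNDER_18
        if age_years < 65:
            return AgeBand.FROM_18_TO_65
        if age_years < 85:
            return AgeBand.FROM_65_TO_85
        return AgeBand.OVER_85


#: AGE_COD unit -> factor converting AGE to years. DEC is decades.
_AGE_UNIT_TO_YEARS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.18,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

#: OCCP_COD -> reporter class. MD/PH/HP are healthcare professions;
#: CN (consumer), LW (lawyer) and OT (other) are not.
_OCCP_TO_REPORTER = {
    "MD": Reporter.HEALTHCARE,
    "PH": Reporter.HEALTHCARE,
    "HP": Reporter.HEALTHCARE,
    "CN": Reporter.NON_HEALTHCARE,
    "LW": Reporter.NON_HEALTHCARE,
    "OT": Reporter.NON_HEALTHCARE,
}


def convert_age_to_years(age: str, age_cod: str) -> float | None:
    """Convert a FAERS AGE/AGE_COD pair to years.

    A blank unit with a numeric AGE is taken as years (the common FAERS
    convention).  Values outside [0, 125] or unparseable values return
    ``None`` and are logged.
    """
    age = age.strip()
    if not age:
        return None
    try:
        value = float(age)
    except ValueError:
        logger.debug("non-numeric AGE %r -> null", age)
        return None
    unit = age_cod.strip().upper() or "YR"
    factor = _AGE_UNIT_TO_YEARS.get(unit)
    if factor is None:
        logger.debug("unknown AGE_COD %r -> null", age_cod)
        return None
    years = value * factor
    if not 0.0 <= years <= 125.0:
        logger.debug("implausible age %.1f years -> null", years)
        return None
    return years


@dataclass(frozen=True)
class ReportRecord:
    """One deduplicated safety report (a DEMO row, normalized)."""

    primaryid: str
    caseid: str
    fda_dt: PartialDate
    event_dt: PartialDate
    sex: Sex
    age_years: float | None
    country: str
    reporter: Reporter
    report_year: int | None


def _record_from_demo_row(row: dict[str, str]) -> ReportRecord:
    fda_dt = parse_partial_date(row.get("FDA_DT", ""))
    sex_raw = row.get("SEX", "").strip().upper()
    sex = Sex(sex_raw) if sex_raw in ("M", "F") else Sex.UNKNOWN
    occp = row.get("OCCP_COD", "").strip().upper()
    reporter = _OCCP_TO_REPORTER.get(occp, Reporter.UNKNOWN)
    return ReportRecord(
        primaryid=row["PRIMARYID"].strip(),
        caseid=row["CASEID"].strip(),
        fda_dt=fda_dt,
        event_dt=parse_partial_date(row.get("EVENT_DT", "")),
        sex=sex,
        age_years=convert_age_to_years(row.get("AGE", ""), row.get("AGE_COD", "")),
        country=row.get("REPORTER_COUNTRY", "").strip(),
        reporter=reporter,
        report_year=fda_dt.year,
    )


def _dedup_sort_key(row: dict[str, str]) -> tuple[int, int]:
    fda = row.get("FDA_DT", "").strip()
    fda_val = int(fda) if fda.isdigit() else -1
    pid = row.get("PRIMARYID", "").strip()
    pid_val = int(pid) if pid.isdigit() else -1
    return (fda_val, pid_val)


def deduplicate(demo: RawTable) -> list[ReportRecord]:
    """Keep one report per CASEID: highest FDA_DT, then highest PRIMARYID.

    PRIMARYID is compared numerically.  Output is sorted by CASEID so
    the result is deterministic.  Idempotent by construction.
    """
    best: dict[str, dict[str, str]] = {}
    for row in demo.rows:
        caseid = row.get("CASEID", "").strip()
        prev = best.get(caseid)
        if prev is None or _dedup_sort_key(row) > _dedup_sort_key(prev):
            best[caseid] = row
    n_removed = len(demo.rows) - len(best)
    if n_removed:
        logger.info("deduplicate: removed %d duplicate report(s)", n_removed)
    return [_record_from_demo_row(best[cid]) for cid in sorted(best)]


@dataclass
class CaseSet:
    """A cohort of reports with their drug, reaction and therapy rows."""

    reports: list[ReportRecord]
    #: (primaryid, drug_seq, role_cod, drugname)
    drug_rows: list[tuple[str, str, str, str]] = field(default_factory=list)
    #: (primaryid, pt_term), distinct after upper-case normalization
    reaction_rows: list[tuple[str, str]] = field(default_factory=list)
    #: (primaryid, drug_seq, start date)
    therapy_rows: list[tuple[str, str, PartialDate]] = field(default_factory=list)
    #: normalized target-drug names the cohort was selected on
    drug_names: tuple[str, ...] = ()

    @property
    def primaryids(self) -> set[str]:
        return {r.primaryid for r in self.reports}

    @property
    def events(self) -> set[tuple[str, str]]:
        """Distinct (report, PT) pairs — the event counting unit."""
        return set(self.reaction_rows)

    def restrict(self, keep_ids: set[str]) -> "CaseSet":
        """New CaseSet containing only reports whose primaryid is kept."""
        return CaseSet(
            reports=[r for r in self.reports if r.primaryid in keep_ids],
            drug_rows=[t for t in self.drug_rows if t[0] in keep_ids],
            reaction_rows=[t for t in self.reaction_rows if t[0] in keep_ids],
            therapy_rows=[t for t in self.therapy_rows if t[0] in keep_ids],
            drug_names=self.drug_names,
        )


def normalize_drugname(name: str) -> str:
    """Upper-case, trim, and strip trailing punctuation from a DRUGNAME."""
    return name.strip().upper().rstrip(".,;:/\\-")


def _drugname_matches(
    normalized: str, names: tuple[str, ...], exact: bool
) -> bool:
    if exact:
        return normalized in names
    return any(n in normalized for n in names)


def select_cohort(
    reports: list[ReportRecord],
    drug_table: RawTable,
    reac_table: RawTable,
    ther_table: RawTable,
    drug_names: list[str],
    role: str = "PS",
    exact_match: bool = False,
) -> CaseSet:
    """Select reports where the target drug carries the requested role.

    A report qualifies if at least one of its DRUG rows has a normalized
    DRUGNAME containing any of ``drug_names`` (substring match by
    default; ``exact_match=True`` requires equality) and ROLE_COD equal
    to ``role``.  All of the qualifying reports' drug, reaction and
    therapy rows are attached; reaction rows are deduplicated per
    (report, PT).
    """
    if not drug_names:
        raise ValueError("drug_names must be non-empty")
    names = tuple(normalize_drugname(n) for n in drug_names)
    report_ids = {r.primaryid for r in reports}

    qualifying: set[str] = set()
    for row in drug_table.rows:
        pid = row["PRIMARYID"].strip()
        if pid not in report_ids:
            continue
        if row.get("ROLE_COD", "").strip().upper() != role.upper():
            continue
        if _drugname_matches(normalize_drugname(row.get("DRUGNAME", "")), names, exact_match):
            qualifying.add(pid)

    if not qualifying:
        logger.warning("select_cohort: no reports matched %s with role %s", names, role)

    drug_rows = [
        (
            row["PRIMARYID"].strip(),
            row.get("DRUG_SEQ", "").strip(),
            row.get("ROLE_COD", "").strip().upper(),
            row.get("DRUGNAME", "").strip(),
        )
        for row in drug_table.rows
        if row["PRIMARYID"].strip() in qualifying
    ]
    seen: set[tuple[str, str]] = set()
    reaction_rows: list[tuple[str, str]] = []
    for row in reac_table.rows:
        pid = row["PRIMARYID"].strip()
        if pid not in qualifying:
            continue
        pair = (pid, row.get("PT", "").strip().upper())
        if pair[1] and pair not in seen:
            seen.add(pair)
            reaction_rows.append(pair)
    therapy_rows = [
        (
            row["PRIMARYID"].strip(),
            row.get("DSG_DRUG_SEQ", "").strip(),
            parse_partial_date(row.get("START_DT", "")),
        )
        for row in ther_table.rows
        if row["PRIMARYID"].strip() in qualifying
    ]
    return CaseSet(
        reports=[r for r in reports if r.primaryid in qualifying],
        drug_rows=drug_rows,
        reaction_rows=reaction_rows,
        therapy_rows=therapy_rows,
        drug_names=names,
    )


def monotherapy_filter(cs: CaseSet, exact_match: bool = False) -> CaseSet:
    """Keep only reports whose every DRUG row matches the target drug.

    Removes reports listing any concomitant or co-suspect other drug
    (the sensitivity analysis of the cohort); duplicate rows naming the
    target drug again do not disqualify a report.
    """
    offending: set[str] = set()
    for pid, _seq, _role, drugname in cs.drug_rows:
        if not _drugname_matches(normalize_drugname(drugname), cs.drug_names, exact_match):
            offending.add(pid)
    keep = cs.primaryids - offending
    if offending:
        logger.info("monotherapy_filter: removed %d polypharmacy report(s)", len(offending))
    return cs.restrict(keep)


@dataclass(frozen=True)
class SubgroupSpec:
    """A demographic stratum: optional sex, optional age band, monotherapy."""

    sex: Sex | None = None
    age_band: AgeBand | None = None
    monotherapy_only: bool = False


def subgroup_filter(cs: CaseSet, spec: SubgroupSpec) -> CaseSet:
    """Intersection of the requested strata.

    Reports with missing sex (age) are excluded whenever the spec
    conditions on sex (age).  An all-null spec is the identity.
    """
    keep = set(cs.primaryids)
    if spec.sex is not None:
        keep &= {r.primaryid for r in cs.reports if r.sex == spec.sex}
    if spec.age_band is not None:
        keep &= {
            r.primaryid
            for r in cs.reports
            if r.age_years is not None and AgeBand.of(r.age_years) == spec.age_band
        }
    out = cs.restrict(keep)
    if spec.monotherapy_only:
        out = monotherapy_filter(out)
    return out


_AGE_BAND_LABELS = {
    AgeBand.UNDER_18: "<18",
    AgeBand.FROM_18_TO_65: "18-65",
    AgeBand.FROM_65_TO_85: "65-85",
    AgeBand.OVER_85: ">85",
}


def descriptive_summary(cs: CaseSet, top_countries: int = 5) -> pd.DataFrame:
    """Descriptive table: sex, age bands, median age (IQR), countries,
    reporter type, reporting year.

    Returns a long-format DataFrame with columns ``section``,
    ``category``, ``count``, ``percent`` (percent of total reports,
    one decimal; blank for the median row).  The IQR uses linear
    interpolation between order statistics.
    """
    if not cs.reports:
        raise ValueError("descriptive_summary requires a non-empty CaseSet")
    n = len(cs.reports)
    rows: list[dict] = []

    def add(section: str, category: str, count) -> None:
        rows.append(
            {
                "section": section,
                "category": category,
                "count": count,
                "percent": round(100.0 * count / n, 1),
            }
        )

    rows.append(
        {"section": "total", "category": "reports", "count": n, "percent": 100.0}
    )
    rows.append(
        {
            "section": "total",
            "category": "events",
            "count": len(cs.events),
            "percent": float("nan"),
        }
    )

    sex_counts = {s: 0 for s in (Sex.M, Sex.F, Sex.UNKNOWN)}
    for r in cs.reports:
        sex_counts[r.sex] += 1
    add("sex", "M", sex_counts[Sex.M])
    add("sex", "F", sex_counts[Sex.F])
    add("sex", "missing", sex_counts[Sex.UNKNOWN])

    ages = np.array([r.age_years for r in cs.reports if r.age_years is not None])
    if ages.size:
        q1, med, q3 = np.quantile(ages, [0.25, 0.5, 0.75])
        rows.append(
            {
                "section": "age",
                "category": f"median (IQR) = {med:g} ({q1:g}, {q3:g})",
                "count": ages.size,
                "percent": float("nan"),
            }
        )
    band_counts = {b: 0 for b in AgeBand}
    n_age_missing = 0
    for r in cs.reports:
        if r.age_years is None:
            n_age_missing += 1
        else:
            band_counts[AgeBand.of(r.age_years)] += 1
    for band in AgeBand:
        add("age", _AGE_BAND_LABELS[band], band_counts[band])
    add("age", "missing", n_age_missing)

    country_counts: dict[str, int] = {}
    for r in cs.reports:
        key = r.country or "missing"
        country_counts[key] = country_counts.get(key, 0) + 1
    top = sorted(country_counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_countries]
    for country, count in top:
        add("country", country, count)

    rep_counts = {x: 0 for x in Reporter}
    for r in cs.reports:
        rep_counts[r.reporter] += 1
    add("reporter", "healthcare professional", rep_counts[Reporter.HEALTHCARE])
    add("reporter", "non-healthcare professional", rep_counts[Reporter.NON_HEALTHCARE])
    add("reporter", "missing", rep_counts[Reporter.UNKNOWN])

    year_counts: dict[str, int] = {}
    for r in cs.reports:
        key = str(r.report_year) if r.report_year else "missing"
        year_counts[key] = year_counts.get(key, 0) + 1
    for year in sorted(year_counts):
        add("report_year", year, year_counts[year])

    return pd.DataFrame(rows, columns=["section", "category", "count", "percent"])
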