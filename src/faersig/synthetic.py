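"""Synthetic FAERS corpora with known ground truth.

Emulates the statistical structure of a quarterly FAERS extract around
one focal drug: a background of other drugs, a MedDRA-like synthetic
vocabulary (``PT_0001``... mapped onto 20 ``SOC_``* groups), duplicate
reports sharing a CASEID with later FDA receipt dates, partial dates,
polypharmacy, and onset intervals drawn from a Weibull distribution.
Selected PTs of the focal drug get an elevated relative reporting rate
(the injected signal), so every pipeline stage can be checked against
ground truth without downloading FDA data.

Default demographic mixes mirror a recent monoclonal-antibody safety
cohort: 60.5% female reports, 44% missing age, US-dominant reporting
countries, two-thirds healthcare-professional reporters, and onset
times from Weibull(shape 0.74, scale 59.94 days) over a 2021Q4–2023Q4
reporting window.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from .io import RawTable, TableKind

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_corpus",
    "write_corpus",
    "generate_pt_soc_map",
    "end_to_end_recovery",
]

FOCAL_DRUG = "TRALOKINUMAB"
WINDOW_START = datetime.date(2021, 10, 1)
WINDOW_END = datetime.date(2023, 12, 31)

_DEMO_COLUMNS = [
    "PRIMARYID",
    "CASEID",
    "FDA_DT",
    "EVENT_DT",
    "SEX",
    "AGE",
    "AGE_COD",
    "OCCP_COD",
    "REPORTER_COUNTRY",
]


@dataclass
class SimConfig:
    """Knobs of the generator; defaults are the study-like conditions."""

    seed: int = 0
    n_background_drugs: int = 20
    n_terms: int = 60
    n_reports: int = 4000
    baseline_term_probs: np.ndarray | None = None  # default: Zipf-like
    focal_drug_share: float = 0.15
    signal_spec: dict[str, float] = dc_field(
        default_factory=lambda: {"PT_0005": 5.0, "PT_0010": 3.0}
    )
    duplicate_rate: float = 0.10
    partial_date_rate: float = 0.15
    polypharmacy_rate: float = 0.05
    tto_shape: float = 0.74
    tto_scale: float = 59.94
    # demographic mixes (probabilities)
    sex_probs: tuple[float, float, float] = (0.385, 0.605, 0.010)  # M, F, missing
    age_missing_rate: float = 0.444
    age_mean: float = 53.0
    age_sd: float = 16.0
    country_probs: dict[str, float] = dc_field(
        default_factory=lambda: {
            "US": 0.923,
            "DE": 0.019,
            "CA": 0.016,
            "FR": 0.014,
            "ES": 0.006,
            "GB": 0.022,
        }
    )
    occp_probs: dict[str, float] = dc_field(
        default_factory=lambda: {
            "MD": 0.30,
            "HP": 0.25,
            "PH": 0.10,
            "CN": 0.283,
            "": 0.067,
        }
    )

    def validate(self) -> None:
        for name in ("duplicate_rate", "partial_date_rate", "polypharmacy_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if not 0.0 < self.focal_drug_share <= 1.0:
            raise ValueError("focal_drug_share must be in (0, 1]")
        if self.tto_shape <= 0 or self.tto_scale <= 0:
            raise ValueError("Weibull parameters must be positive")
        probs = self.term_probs()
        if abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
            raise ValueError("baseline_term_probs must be a probability vector")
        for rho in self.signal_spec.values():
            if rho < 1.0:
                raise ValueError("signal relative reporting rates must be >= 1")
        for spec_probs in (self.sex_probs, tuple(self.country_probs.values()), tuple(self.occp_probs.values())):
            if abs(sum(spec_probs) - 1.0) > 1e-6:
                raise ValueError("demographic probabilities must sum to 1")

    def term_names(self) -> list[str]:
        return [f"PT_{i + 1:04d}" for i in range(self.n_terms)]

    def term_probs(self) -> np.ndarray:
        if self.baseline_term_probs is not None:
            return np.asarray(self.baseline_term_probs, dtype=float)
        ranks = np.arange(1, self.n_terms + 1, dtype=float)
        p = 1.0 / ranks  # Zipf-like frequency profile, as in real PT counts
        return p / p.sum()


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery checks."""

    rho: dict[str, float]
    tto_shape: float
    tto_scale: float
    #: (caseid, original primaryid, duplicate primaryid)
    duplicate_pairs: list[tuple[str, str, str]]
    #: surviving primaryid -> report is focal-drug monotherapy
    monotherapy: dict[str, bool]
    focal_primaryids: list[str]
    n_cases: int
    n_focal_cases: int
    n_focal_events: int
    pt_to_soc: dict[str, str]

    def to_json(self) -> str:
        payload = {
            "rho": self.rho,
            "tto_shape": self.tto_shape,
            "tto_scale": self.tto_scale,
            "duplicate_pairs": self.duplicate_pairs,
            "monotherapy": self.monotherapy,
            "focal_primaryids": self.focal_primaryids,
            "n_cases": self.n_cases,
            "n_focal_cases": self.n_focal_cases,
            "n_focal_events": self.n_focal_events,
            "pt_to_soc": self.pt_to_soc,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def generate_pt_soc_map(n_terms: int, n_socs: int = 20) -> dict[str, str]:
    """Deterministic synthetic PT -> SOC mapping (round-robin grouping)."""
    return {
        f"PT_{i + 1:04d}": f"SOC_{(i % n_socs) + 1:02d}" for i in range(n_terms)
    }


def _fmt(d: datetime.date) -> str:
    return d.strftime("%Y%m%d")


def simulate_corpus(
    cfg: SimConfig,
) -> tuple[RawTable, RawTable, RawTable, RawTable, GroundTruth]:
    """Generate DEMO/DRUG/REAC/THER tables plus ground truth.

    Fully deterministic given ``cfg.seed``.  Duplicates re-emit a case
    under a new (higher) PRIMARYID with a later FDA_DT, copying its
    drug/reaction/therapy rows, so deduplication has a well-defined
    survivor whose rows remain resolvable.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    terms = np.array(cfg.term_names())
    base_probs = cfg.term_probs()
    focal_probs = base_probs.copy()
    rho_map = {t: 1.0 for t in terms}
    for t, rho in cfg.signal_spec.items():
        idx = np.where(terms == t)[0]
        if idx.size == 0:
            raise ValueError(f"signal term {t!r} not in the vocabulary")
        focal_probs[idx[0]] *= rho
        rho_map[t] = float(rho)
    focal_probs = focal_probs / focal_probs.sum()

    background_drugs = [
        f"DRUG_{i + 1:04d}" for i in range(cfg.n_background_drugs)
    ]
    window_days = (WINDOW_END - WINDOW_START).days

    demo_rows: list[dict[str, str]] = []
    drug_rows: list[dict[str, str]] = []
    reac_rows: list[dict[str, str]] = []
    ther_rows: list[dict[str, str]] = []

    sexes = np.array(["M", "F", ""])
    countries = list(cfg.country_probs)
    country_p = np.array(list(cfg.country_probs.values()))
    occps = list(cfg.occp_probs)
    occp_p = np.array(list(cfg.occp_probs.values()))

    monotherapy: dict[str, bool] = {}
    focal_primaryids: list[str] = []
    n_focal_events = 0
    case_rows: list[dict] = []  # per-case bookkeeping for duplicate emission

    for i in range(cfg.n_reports):
        caseid = str(9_000_000 + i)
        primaryid = caseid + "1"  # FAERS-style caseid + version suffix
        is_focal = bool(rng.random() < cfg.focal_drug_share)
        drugname = FOCAL_DRUG if is_focal else background_drugs[int(rng.integers(cfg.n_background_drugs))]
        probs = focal_probs if is_focal else base_probs
        n_pts = int(rng.integers(1, 6))
        pts = rng.choice(terms, size=n_pts, replace=False, p=probs)

        fda_date = WINDOW_START + datetime.timedelta(days=int(rng.integers(0, window_days + 1)))
        event_date = WINDOW_START + datetime.timedelta(days=int(rng.integers(0, window_days + 1)))
        onset = int(round(float(rng.weibull(cfg.tto_shape)) * cfg.tto_scale))
        start_date = event_date - datetime.timedelta(days=onset)
        event_str = _fmt(event_date)
        start_str = _fmt(start_date)
        if rng.random() < cfg.partial_date_rate:
            # truncate the event date to month precision: report unusable for TTO
            event_str = event_str[:6]

        sex = str(sexes[int(rng.choice(3, p=np.array(cfg.sex_probs)))])
        if rng.random() < cfg.age_missing_rate:
            age, age_cod = "", ""
        else:
            age_val = float(np.clip(rng.normal(cfg.age_mean, cfg.age_sd), 12, 95))
            age, age_cod = str(int(round(age_val))), "YR"
        country = str(rng.choice(countries, p=country_p))
        occp = str(rng.choice(occps, p=occp_p))

        demo = {
            "PRIMARYID": primaryid,
            "CASEID": caseid,
            "FDA_DT": _fmt(fda_date),
            "EVENT_DT": event_str,
            "SEX": sex,
            "AGE": age,
            "AGE_COD": age_cod,
            "OCCP_COD": occp,
            "REPORTER_COUNTRY": country,
        }
        d_rows = [
            {"PRIMARYID": primaryid, "DRUG_SEQ": "1", "ROLE_COD": "PS", "DRUGNAME": drugname}
        ]
        poly = False
        if is_focal and rng.random() < cfg.polypharmacy_rate:
            poly = True
            conc = background_drugs[int(rng.integers(cfg.n_background_drugs))]
            d_rows.append(
                {"PRIMARYID": primaryid, "DRUG_SEQ": "2", "ROLE_COD": "C", "DRUGNAME": conc}
            )
        r_rows = [{"PRIMARYID": primaryid, "PT": str(pt)} for pt in pts]
        t_rows = [
            {"PRIMARYID": primaryid, "DSG_DRUG_SEQ": "1", "START_DT": start_str}
        ]

        demo_rows.append(demo)
        drug_rows.extend(d_rows)
        reac_rows.extend(r_rows)
        ther_rows.extend(t_rows)
        case_rows.append(
            {
                "caseid": caseid,
                "primaryid": primaryid,
                "fda_date": fda_date,
                "demo": demo,
                "drug": d_rows,
                "reac": r_rows,
                "ther": t_rows,
                "is_focal": is_focal,
                "poly": poly,
                "n_pts": n_pts,
            }
        )

    # Re-emit a fraction of cases as follow-up duplicates: same CASEID,
    # higher PRIMARYID (version 2), later-or-equal FDA_DT.
    n_dupes = int(round(cfg.duplicate_rate * cfg.n_reports))
    dup_idx = rng.choice(cfg.n_reports, size=n_dupes, replace=False)
    duplicate_pairs: list[tuple[str, str, str]] = []
    for i in sorted(int(j) for j in dup_idx):
        case = case_rows[i]
        new_pid = case["caseid"] + "2"
        new_fda = min(
            case["fda_date"] + datetime.timedelta(days=int(rng.integers(1, 91))),
            WINDOW_END,
        )
        demo = dict(case["demo"], PRIMARYID=new_pid, FDA_DT=_fmt(new_fda))
        demo_rows.append(demo)
        drug_rows.extend(dict(r, PRIMARYID=new_pid) for r in case["drug"])
        reac_rows.extend(dict(r, PRIMARYID=new_pid) for r in case["reac"])
        ther_rows.extend(dict(r, PRIMARYID=new_pid) for r in case["ther"])
        duplicate_pairs.append((case["caseid"], case["primaryid"], new_pid))
        case["survivor"] = new_pid

    for case in case_rows:
        survivor = case.get("survivor", case["primaryid"])
        monotherapy[survivor] = not case["poly"]
        if case["is_focal"]:
            focal_primaryids.append(survivor)
            n_focal_events += case["n_pts"]

    quarter = "SYNTH"
    demo = RawTable(TableKind.DEMO, quarter, demo_rows)
    drug = RawTable(TableKind.DRUG, quarter, drug_rows)
    reac = RawTable(TableKind.REAC, quarter, reac_rows)
    ther = RawTable(TableKind.THER, quarter, ther_rows)
    truth = GroundTruth(
        rho=rho_map,
        tto_shape=cfg.tto_shape,
        tto_scale=cfg.tto_scale,
        duplicate_pairs=duplicate_pairs,
        monotherapy=monotherapy,
        focal_primaryids=sorted(focal_primaryids),
        n_cases=cfg.n_reports,
        n_focal_cases=len(focal_primaryids),
        n_focal_events=n_focal_events,
        pt_to_soc=generate_pt_soc_map(cfg.n_terms),
    )
    return demo, drug, reac, ther, truth


def write_corpus(cfg: SimConfig, out_dir: str | Path) -> GroundTruth:
    """Simulate and write DEMO/DRUG/REAC/THER .txt plus ground_truth.json."""
    from .io import write_faers_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    demo, drug, reac, ther, truth = simulate_corpus(cfg)
    for table, name in ((demo, "DEMO"), (drug, "DRUG"), (reac, "REAC"), (ther, "THER")):
        write_faers_table(table, out / f"{name}.txt")
    (out / "ground_truth.json").write_text(truth.to_json(), encoding="utf-8")
    lines = ["pt_term,soc_term"] + [
        f"{pt},{soc}" for pt, soc in sorted(truth.pt_to_soc.items())
    ]
    (out / "pt_soc_map.csv").write_text("\n".join(lines) + "\n", encoding="utf-8")
    return truth


def background_events(
    reports, reac_table: RawTable, cohort_ids: set[str]
) -> set[tuple[str, str]]:
    """Distinct (report, PT) events of deduplicated non-cohort reports."""
    keep = {r.primaryid for r in reports} - cohort_ids
    return {
        (row["PRIMARYID"].strip(), row["PT"].strip().upper())
        for row in reac_table.rows
        if row["PRIMARYID"].strip() in keep and row["PT"].strip()
    }


def end_to_end_recovery(cfg: SimConfig, fit_prior: bool = True) -> dict:
    """Run the full pipeline on a simulated corpus; compare to truth.

    Returns a dict with deduplication exactness, the four estimators and
    flags for every injected signal term (plus the null-term flag
    rates), and the Weibull fit against the generating parameters.
    """
    from . import dispro
    from .cohort import deduplicate, select_cohort
    from .tto import compute_onsets, weibull_mle

    demo, drug, reac, ther, truth = simulate_corpus(cfg)
    reports = deduplicate(demo)
    n_removed = len(demo.rows) - len(reports)

    cs = select_cohort(reports, drug, reac, ther, [FOCAL_DRUG], role="PS")
    bg = background_events(reports, reac, cs.primaryids)

    prior = None
    if fit_prior:
        drug_of = {}
        for row in drug.rows:
            if row["ROLE_COD"].strip() == "PS":
                drug_of[row["PRIMARYID"].strip()] = row["DRUGNAME"].strip()
        kept = {r.primaryid for r in reports}
        pair_counts: dict[tuple[str, str], int] = {}
        drug_tot: dict[str, int] = {}
        term_tot: dict[str, int] = {}
        total = 0
        all_events = {
            (row["PRIMARYID"].strip(), row["PT"].strip().upper())
            for row in reac.rows
            if row["PRIMARYID"].strip() in kept
        }
        for pid, term in all_events:
            dname = drug_of.get(pid)
            if dname is None:
                continue
            pair_counts[(dname, term)] = pair_counts.get((dname, term), 0) + 1
            drug_tot[dname] = drug_tot.get(dname, 0) + 1
            term_tot[term] = term_tot.get(term, 0) + 1
            total += 1
        pairs = sorted(pair_counts)
        counts = np.array([pair_counts[p] for p in pairs], dtype=float)
        expected = np.array(
            [drug_tot[d] * term_tot[t] / total for d, t in pairs], dtype=float
        )
        prior = dispro.fit_gps_prior(counts, expected)

    results = dispro.evaluate_terms(cs.events, bg, prior=prior)
    by_term = {r.term: r for r in results}

    signal_report = {}
    for term, rho in truth.rho.items():
        if rho <= 1.0:
            continue
        r = by_term.get(term)
        signal_report[term] = None if r is None else {
            "true_rho": rho,
            "a": r.a,
            "ror": r.ror,
            "prr": r.prr,
            "ebgm": r.ebgm,
            "ic": r.ic,
            "flag_any": r.flag_any,
        }
    null_terms = [r for r in results if truth.rho.get(r.term, 1.0) == 1.0]
    null_flag_rates = {
        "ror": float(np.mean([r.flag_ror for r in null_terms])) if null_terms else 0.0,
        "mgps": float(np.mean([r.flag_mgps for r in null_terms])) if null_terms else 0.0,
        "any": float(np.mean([r.flag_any for r in null_terms])) if null_terms else 0.0,
        "n_null_terms": len(null_terms),
    }

    onsets, excl = compute_onsets(cs)
    weibull_report = None
    if len(onsets) >= 10:
        fit = weibull_mle(onsets)
        weibull_report = {
            "n": fit.n,
            "shape": fit.shape_beta,
            "shape_ci": fit.shape_ci,
            "scale": fit.scale_alpha,
            "scale_ci": fit.scale_ci,
            "failure_type": fit.failure_type.value,
            "true_shape": truth.tto_shape,
            "true_scale": truth.tto_scale,
        }

    return {
        "n_raw_reports": len(demo.rows),
        "n_deduplicated": len(reports),
        "n_duplicates_removed": n_removed,
        "n_duplicates_planted": len(truth.duplicate_pairs),
        "n_cohort_reports": len(cs.reports),
        "n_focal_cases_truth": truth.n_focal_cases,
        "n_cohort_events": len(cs.events),
        "signals": signal_report,
        "null_flag_rates": null_flag_rates,
        "weibull": weibull_report,
        "tto_exclusions": {
            "no_event_date": excl.no_event_date,
            "no_start_date": excl.no_start_date,
            "event_before_start": excl.event_before_start,
        },
    }
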