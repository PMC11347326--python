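"""End-to-end run orchestration and paper-style output tables.

``run_pipeline`` wires the stages together — ingest (or simulate) →
deduplicate → cohort selection → descriptives → SOC- and PT-level
signal tables → subgroup/sensitivity reruns → time-to-onset — and
writes one CSV per output table plus a JSON manifest recording the row
count at every stage (the audit trail of the analysis flowchart).

Outputs are deterministic: identical config and inputs produce
byte-identical files, and all randomness flows through the config seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import (
    CaseSet,
    SubgroupSpec,
    deduplicate,
    descriptive_summary,
    monotherapy_filter,
    select_cohort,
    subgroup_filter,
)
from .dispro import (
    SignalResult,
    SignalThresholds,
    TermLevel,
    evaluate_terms,
    events_to_soc,
)
from .io import RawTable, TableKind, read_faers_table
from .synthetic import SimConfig, background_events, simulate_corpus
from .tto import compute_onsets, cumulative_incidence, weibull_mle

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "render_signal_table", "read_pt_soc_map"]


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    output_dir: str
    input_dir: str | None = None  # directory with DEMO/DRUG/REAC/THER.txt
    simulate: bool = False  # generate the corpus instead of reading files
    seed: int = 0
    drug_names: list[str] = field(default_factory=lambda: ["TRALOKINUMAB"])
    role: str = "PS"
    pt_soc_map: str | None = None  # two-column CSV (pt_term, soc_term)
    thresholds: SignalThresholds = field(default_factory=SignalThresholds)
    subgroups: list[SubgroupSpec] = field(default_factory=list)
    monotherapy_sensitivity: bool = True
    top_k: int = 50
    tto_min_n: int = 10

    def config_hash(self) -> str:
        payload = json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=str
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunManifest:
    """Row counts at every stage plus provenance of the run."""

    config_hash: str
    version: str
    counts: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def read_pt_soc_map(path: str | Path) -> dict[str, str]:
    """Load a two-column (pt_term, soc_term) CSV into a dict."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("PT->SOC map needs two columns: pt_term, soc_term")
    pt_col, soc_col = df.columns[:2]
    return {
        str(pt).strip().upper(): str(soc).strip()
        for pt, soc in zip(df[pt_col], df[soc_col])
    }


def _fmt_pair(x: float, y: float) -> str:
    if math.isnan(x):
        return "NA"
    return f"{x:.2f} ({y:.2f})"


def _fmt_ci(x: float, lo: float, hi: float) -> str:
    if math.isnan(x):
        return "NA"
    return f"{x:.2f} ({lo:.2f}–{hi:.2f})"


def render_signal_table(
    results: list[SignalResult], top_k: int | None = 50
) -> pd.DataFrame:
    """Format signal results the way pharmacovigilance tables print them.

    Rows sorted by descending case count (ties alphabetical), truncated
    to the ``top_k`` most frequent terms; flagged terms get a trailing
    asterisk; estimators render as ``x.xx (x.xx–x.xx)`` pairs.
    """
    if not results:
        raise ValueError("render_signal_table requires non-empty results")
    rows = sorted(results, key=lambda r: (-r.a, r.term))
    if top_k is not None:
        rows = rows[:top_k]
    out = []
    for r in rows:
        out.append(
            {
                "term": r.term + ("*" if r.flag_any else ""),
                "cases": r.a,
                "ROR (95% CI)": _fmt_ci(r.ror, r.ror_lo, r.ror_hi),
                "PRR (chi2)": _fmt_pair(r.prr, r.chi2),
                "EBGM (EBGM05)": _fmt_pair(r.ebgm, r.ebgm05),
                "IC (IC025)": _fmt_pair(r.ic, r.ic025),
                "flag_ror": r.flag_ror,
                "flag_prr": r.flag_prr,
                "flag_bcpnn": r.flag_bcpnn,
                "flag_mgps": r.flag_mgps,
                "flag_any": r.flag_any,
            }
        )
    return pd.DataFrame(out)


def _load_tables(cfg: RunConfig) -> tuple[RawTable, RawTable, RawTable, RawTable, dict[str, str] | None]:
    if cfg.simulate:
        demo, drug, reac, ther, truth = simulate_corpus(SimConfig(seed=cfg.seed))
        return demo, drug, reac, ther, truth.pt_to_soc
    if cfg.input_dir is None:
        raise ValueError("RunConfig needs input_dir unless simulate=True")
    d = Path(cfg.input_dir)
    demo = read_faers_table(d / "DEMO.txt", TableKind.DEMO)
    drug = read_faers_table(d / "DRUG.txt", TableKind.DRUG)
    reac = read_faers_table(d / "REAC.txt", TableKind.REAC)
    ther = read_faers_table(d / "THER.txt", TableKind.THER)
    return demo, drug, reac, ther, None


def run_pipeline(cfg: RunConfig) -> RunManifest:
    """Execute the full analysis; write CSV/JSON outputs; return manifest.

    Writes ``table1_descriptive.csv``, ``table2_soc_signals.csv``,
    ``table3_pt_signals.csv``, ``table4_tto.csv``, ``cdf.csv``,
    ``manifest.json`` and ``run.log`` into ``cfg.output_dir``.  Any
    stage failure aborts with the stage name; the manifest so far is
    still written.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=cfg.config_hash(), version=__version__)
    log_lines: list[str] = []
    stage = "init"
    try:
        stage = "ingest"
        demo, drug, reac, ther, sim_map = _load_tables(cfg)
        manifest.counts["raw_reports"] = len(demo.rows)
        log_lines.append(f"ingest: {len(demo.rows)} DEMO rows")

        stage = "deduplicate"
        reports = deduplicate(demo)
        manifest.counts["deduplicated_reports"] = len(reports)
        log_lines.append(
            f"deduplicate: {len(reports)} reports "
            f"({len(demo.rows) - len(reports)} duplicates removed)"
        )

        stage = "cohort"
        cs = select_cohort(reports, drug, reac, ther, cfg.drug_names, role=cfg.role)
        manifest.counts["cohort_reports"] = len(cs.reports)
        manifest.counts["cohort_events"] = len(cs.events)
        log_lines.append(
            f"cohort: {len(cs.reports)} reports, {len(cs.events)} events"
        )
        if not cs.reports:
            raise ValueError("cohort is empty; nothing to analyse")

        stage = "descriptive"
        descriptive_summary(cs).to_csv(out / "table1_descriptive.csv", index=False)

        stage = "signals"
        bg = background_events(reports, reac, cs.primaryids)
        pt_results = evaluate_terms(
            cs.events, bg, level=TermLevel.PT, thresholds=cfg.thresholds
        )
        render_signal_table(pt_results, cfg.top_k).to_csv(
            out / "table3_pt_signals.csv", index=False
        )
        manifest.counts["pt_terms"] = len(pt_results)

        pt_to_soc = sim_map
        if cfg.pt_soc_map is not None:
            pt_to_soc = read_pt_soc_map(cfg.pt_soc_map)
        if pt_to_soc:
            soc_results = evaluate_terms(
                events_to_soc(cs.events, pt_to_soc),
                events_to_soc(bg, pt_to_soc),
                level=TermLevel.SOC,
                thresholds=cfg.thresholds,
            )
            render_signal_table(soc_results, top_k=None).to_csv(
                out / "table2_soc_signals.csv", index=False
            )
            manifest.counts["soc_terms"] = len(soc_results)
        else:
            manifest.warnings.append("no PT->SOC map supplied; SOC table skipped")
            pd.DataFrame().to_csv(out / "table2_soc_signals.csv", index=False)

        stage = "subgroups"
        for i, spec in enumerate(cfg.subgroups):
            sub = subgroup_filter(cs, spec)
            manifest.counts[f"subgroup_{i}_reports"] = len(sub.reports)
            if sub.reports and sub.events:
                sub_results = evaluate_terms(
                    sub.events, bg, level=TermLevel.PT, thresholds=cfg.thresholds
                )
                render_signal_table(sub_results, cfg.top_k).to_csv(
                    out / f"subgroup_{i}_pt_signals.csv", index=False
                )

        stage = "sensitivity"
        if cfg.monotherapy_sensitivity:
            mono = monotherapy_filter(cs)
            manifest.counts["monotherapy_reports"] = len(mono.reports)
            manifest.counts["monotherapy_events"] = len(mono.events)
            if mono.reports and mono.events:
                mono_results = evaluate_terms(
                    mono.events, bg, level=TermLevel.PT, thresholds=cfg.thresholds
                )
                render_signal_table(mono_results, cfg.top_k).to_csv(
                    out / "sensitivity_monotherapy_pt_signals.csv", index=False
                )

        stage = "tto"
        onsets, excl = compute_onsets(cs)
        manifest.counts["tto_eligible"] = len(onsets)
        log_lines.append(
            f"tto: {len(onsets)} eligible; excluded "
            f"{excl.no_event_date} without day-precision event date, "
            f"{excl.no_start_date} without day-precision therapy start, "
            f"{excl.event_before_start} with event before start"
        )
        if len(onsets) >= cfg.tto_min_n:
            fit = weibull_mle(onsets, min_n=cfg.tto_min_n)
            pd.DataFrame(
                [
                    {
                        "n": fit.n,
                        "median_days": fit.median_days,
                        "iqr_lo": fit.iqr[0],
                        "iqr_hi": fit.iqr[1],
                        "scale_alpha": round(fit.scale_alpha, 2),
                        "scale_ci_lo": round(fit.scale_ci[0], 2),
                        "scale_ci_hi": round(fit.scale_ci[1], 2),
                        "shape_beta": round(fit.shape_beta, 2),
                        "shape_ci_lo": round(fit.shape_ci[0], 2),
                        "shape_ci_hi": round(fit.shape_ci[1], 2),
                        "failure_type": fit.failure_type.value,
                        "model_median_days": round(fit.model_median_days, 2),
                        "n_zero_shifted": fit.n_zero_shifted,
                    }
                ]
            ).to_csv(out / "table4_tto.csv", index=False)
            cdf, bins = cumulative_incidence(onsets)
            cdf.to_csv(out / "cdf.csv", index=False)
            bins.to_csv(out / "tto_bins.csv", index=False)
        else:
            manifest.warnings.append(
                f"only {len(onsets)} day-precision onsets (< {cfg.tto_min_n}); "
                "time-to-onset analysis skipped"
            )
            pd.DataFrame().to_csv(out / "table4_tto.csv", index=False)
            pd.DataFrame().to_csv(out / "cdf.csv", index=False)
    except Exception as exc:
        manifest.warnings.append(f"aborted at stage {stage}: {exc}")
        (out / "manifest.json").write_text(manifest.to_json(), encoding="utf-8")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "manifest.json").write_text(manifest.to_json(), encoding="utf-8")
    (out / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return manifest
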