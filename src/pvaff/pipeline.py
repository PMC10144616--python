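"""Config-driven orchestration of the full analysis.

One run takes four report tables (read from disk or drawn from the
synthetic generator) through preparation, the per-drug disproportionality
screen, the univariate patient-background comparisons, the multivariable
logistic model and the Weibull time-to-onset analysis, writing each result
surface as a sorted TSV plus a JSON filter report, a JSON-lines stage log
and a manifest of artifacts with row counts. Outputs are deterministic for
a fixed config and seed and independent of input row order.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import covariates, io, smq, weibull
from . import synthetic as synth
from .disproportionality import DisproportionalityScreen
from .smq import HISTORY_GROUPS

logger = logging.getLogger(__name__)

TTA_STRATA = ("osteoporosis", "cancer")


@dataclass
class RunConfig:
    """Settings for one pipeline run."""

    input_paths: dict[str, str] | None = None
    synthetic: synth.SyntheticConfig | None = None
    event_term: str = synth.TARGET_EVENT
    ror_min: float = 1.0
    p_max: float = 0.05
    level: float = 0.95
    logistic_binary: list[str] | None = None  # None -> auto-select
    logistic_continuous: list[str] = field(
        default_factory=lambda: ["age_years", "bmi"])
    max_logistic_drugs: int = 15
    min_drug_events: int = 5
    tta_drugs: list[str] | None = None  # None -> signal drugs
    tta_min_n: int = 10
    smq_path: str | None = None
    out_dir: str = "pvaff_out"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.ror_min < 0 or self.p_max < 0:
            raise ValueError("thresholds must be non-negative")
        if not self.event_term:
            raise ValueError("event term must be non-empty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        syn = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if syn is not None:
            drugs = [synth.DrugSpec(**d) for d in syn.pop("drugs", [])]
            if not drugs:
                drugs = synth.default_drugs()
            cfg.synthetic = synth.SyntheticConfig(drugs=drugs, **syn)
        return cfg


class _StageLog:
    """JSON-lines structured log with per-stage record counts."""

    def __init__(self, path: Path):
        self.path = path
        self.path.write_text("", encoding="utf-8")

    def emit(self, stage: str, **fields: Any) -> None:
        rec = {"stage": stage, **fields}
        with open(self.path, "a", encoding="utf-8") as fh:
            fh.write(json.dumps(rec, default=str) + "\n")
        logger.info("stage %s: %s", stage, fields)


def _write_tsv(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return len(df)


def _records_frame(records: pd.DataFrame) -> pd.DataFrame:
    out = records.copy()
    for col in ("suspect_drugs", "events"):
        out[col] = out[col].apply(lambda s: ";".join(sorted(s)))
    return out.sort_values("case_id", kind="mergesort").reset_index(drop=True)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run every stage; returns the manifest (also written as JSON)."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _StageLog(out / "log.jsonl")
    artifacts: dict[str, dict[str, Any]] = {}

    smq_map = (smq.load_smq_config(config.smq_path) if config.smq_path
               else smq.load_default_smq())

    # --- acquire tables ---------------------------------------------------
    if config.synthetic is not None:
        syn = config.synthetic
        if config.seed is not None:
            syn = synth.with_seed(syn, config.seed)
        tables, truth = synth.generate(syn)
        syn_dir = out / "synthetic"
        io.write_tables(tables, syn_dir)
        n = _write_tsv(synth.truth_report(truth), syn_dir / "truth.tsv")
        log.emit("simulate", n_cases=syn.n_cases, n_truth_rows=n, seed=syn.seed)
    elif config.input_paths is not None:
        tables = io.read_tables(config.input_paths)
        log.emit("read", **{t: len(getattr(tables, t))
                            for t in ("drug", "reac", "demo", "hist")})
    else:
        raise ValueError("config needs either input_paths or a synthetic block")

    # --- preprocess -------------------------------------------------------
    table = io.preprocess(tables, smq_map)
    records = table.records
    (out / "filter_report.json").write_text(
        json.dumps(table.report.to_dict(), indent=2), encoding="utf-8")
    n = _write_tsv(_records_frame(records), out / "analysis_table.tsv")
    artifacts["analysis_table"] = {"path": "analysis_table.tsv", "rows": n}
    log.emit("preprocess", **table.report.to_dict())

    feats = covariates.features_from_records(records, event=config.event_term)

    # --- univariate (Table-1 style) --------------------------------------
    uni = covariates.univariate_table(
        feats,
        continuous=("age_years", "height_cm", "weight_kg", "bmi"),
        binary_two_sided=("female",),
        binary_right_tailed=tuple(f"hist_{g}" for g in HISTORY_GROUPS),
    )
    n = _write_tsv(uni, out / "univariate.tsv")
    artifacts["univariate"] = {"path": "univariate.tsv", "rows": n}
    log.emit("univariate", rows=n)

    # --- disproportionality screen ---------------------------------------
    screen = DisproportionalityScreen(
        records, config.event_term, level=config.level,
        ror_min=config.ror_min, p_max=config.p_max).fit()
    sig_frame = screen.frame()
    n = _write_tsv(sig_frame, out / "signals.tsv")
    artifacts["signals"] = {"path": "signals.tsv", "rows": n,
                            "n_signals": int(sig_frame["is_signal"].sum())}
    volcano = pd.DataFrame(
        screen.volcano_coordinates(),
        columns=["neg_log10_p", "ln_ror", "log10_n_reports"])
    volcano.insert(0, "drug", [r.drug for r in screen.results])
    volcano = volcano.sort_values("drug", kind="mergesort").reset_index(drop=True)
    n = _write_tsv(volcano, out / "volcano.tsv")
    artifacts["volcano"] = {"path": "volcano.tsv", "rows": n}
    log.emit("signals", drugs=len(sig_frame),
             n_signals=artifacts["signals"]["n_signals"])
    signal_drugs = [r.drug for r in screen.signals]

    # --- logistic model ---------------------------------------------------
    logi = _logistic_stage(records, feats, sig_frame, config)
    n = _write_tsv(logi, out / "logistic.tsv")
    artifacts["logistic"] = {"path": "logistic.tsv", "rows": n}
    log.emit("logistic", rows=n)

    # --- time to onset ----------------------------------------------------
    tta = _tta_stage(table, config, signal_drugs)
    n = _write_tsv(tta, out / "tta.tsv")
    artifacts["tta"] = {"path": "tta.tsv", "rows": n}
    log.emit("tta", rows=n)

    manifest = {
        "out_dir": str(out),
        "event_term": config.event_term,
        "artifacts": artifacts,
        "filter_report": table.report.to_dict(),
        "elapsed_s": round(time.time() - t0, 3),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2), encoding="utf-8")
    return manifest


def _auto_binary_predictors(
    feats: pd.DataFrame, sig_frame: pd.DataFrame, config: RunConfig
) -> list[str]:
    """Univariate-significant patient factors plus the screened drugs."""
    chosen: list[str] = []
    _, p = covariates.univariate_tests(feats, "female", "binary_two_sided")
    if p <= 0.05:
        chosen.append("female")
    for g in HISTORY_GROUPS:
        _, p = covariates.univariate_tests(feats, f"hist_{g}",
                                           "binary_right_tailed")
        if p <= 0.05:
            chosen.append(f"hist_{g}")
    sigs = sig_frame[(sig_frame["is_signal"])
                     & (sig_frame["a"] >= config.min_drug_events)]
    sigs = sigs.sort_values(["ror", "drug"], ascending=[False, True])
    chosen += [f"drug_{d}" for d in sigs["drug"].head(config.max_logistic_drugs)]
    return chosen


def _logistic_stage(
    records: pd.DataFrame,
    feats: pd.DataFrame,
    sig_frame: pd.DataFrame,
    config: RunConfig,
) -> pd.DataFrame:
    if config.logistic_binary is not None:
        binary = list(config.logistic_binary)
    else:
        binary = _auto_binary_predictors(feats, sig_frame, config)
    drugs = [b.removeprefix("drug_") for b in binary if b.startswith("drug_")]
    full = covariates.features_from_records(records, drugs=drugs,
                                            event=config.event_term)
    continuous = [c for c in config.logistic_continuous if c in full.columns]
    while True:
        spec = covariates.DesignSpec(binary_predictors=binary,
                                     continuous_predictors=continuous)
        X, y, ranges = covariates.encode_design(full, spec)
        try:
            res = covariates.LogisticRiskModel(X, y, spec, ranges).fit(
                level=config.level)
            break
        except ValueError as exc:
            msg = str(exc)
            dropped = next((b for b in binary if f"{b!r}" in msg), None)
            if dropped is None:
                raise
            logger.warning("excluding separated predictor %s and refitting",
                           dropped)
            binary = [b for b in binary if b != dropped]
            if not binary and not continuous:
                raise
    frame = res.odds_ratio_frame()
    frame.insert(1, "n_used", res.n_used)
    return frame


def _tta_stage(
    table: io.AnalysisTable, config: RunConfig, signal_drugs: list[str]
) -> pd.DataFrame:
    records = table.records
    onsets = table.onsets[table.onsets["event_term"] == config.event_term]
    drugs = config.tta_drugs if config.tta_drugs is not None else signal_drugs
    flags = records.set_index("case_id")
    rows = []
    for stratum in TTA_STRATA:
        in_stratum = set(flags.index[flags[f"hist_{stratum}"]])
        for drug in sorted(set(drugs)):
            sub = onsets[(onsets["drug_name"] == drug)
                         & onsets["case_id"].isin(in_stratum)]
            durations = tuple(int(v) for v in sub["onset_days"])
            if len(durations) < max(config.tta_min_n, 1):
                continue
            sample = weibull.DurationSample(drug, stratum, durations)
            try:
                fit = weibull.fit_weibull_mle(sample, level=config.level)
            except ValueError:
                continue
            rows.append({
                "drug": drug, "stratum": stratum, "n": fit.n,
                "median": fit.median, "q25": fit.q25, "q75": fit.q75,
                "alpha": fit.alpha,
                "alpha_ci_low": fit.alpha_ci[0], "alpha_ci_high": fit.alpha_ci[1],
                "beta": fit.beta,
                "beta_ci_low": fit.beta_ci[0], "beta_ci_high": fit.beta_ci[1],
                "pattern": fit.pattern, "ci_supported": fit.ci_supported,
            })
    return pd.DataFrame(rows, columns=[
        "drug", "stratum", "n", "median", "q25", "q75", "alpha",
        "alpha_ci_low", "alpha_ci_high", "beta", "beta_ci_low",
        "beta_ci_high", "pattern", "ci_supported"])
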