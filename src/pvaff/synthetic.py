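"""Synthetic JADER-shaped spontaneous-report generator with planted truth.

Emits the four linked tables (DRUG, REAC, DEMO, HIST) for ``n_cases``
independent cases whose target-event indicator follows a logistic model:

    logit P(event) = baseline + Σ_d effect_d·exposed_d
                     + γ_female·female + γ_bmi·(BMI − 22) + Σ_g γ_g·history_g

so each configured drug carries an exact planted odds ratio exp(effect_d).
Defaults emulate the rare-event regime of a large pharmacovigilance
extract: a target event around 0.1% of reports, decade-coded age, height
and weight (so BMI is reconstructed from band midpoints), heavy
missingness in the height/weight fields, a configurable fraction of
duplicated case submissions (re-emitted under the same case id with report
version 2), and — for event cases — per-drug onset times drawn from that
drug's Weibull(α, β) and rounded up, so the pipeline's "event − start + 1"
convention recovers the drawn day exactly (the administration start date
is back-dated from the event date).

Cases drawing no configured exposure receive one filler suspect drug
(rotating over a small pool of effect-free names) so every case has at
least one suspect drug, as real reports do. Everything is driven by one
seeded generator: a fixed seed reproduces the tables byte for byte.
``SyntheticTruth`` carries the per-drug planted odds ratios and onset
parameters, per-case exposure/event indicators, planted duplicate and
missing counts, so every pipeline stage can be checked against the truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import RawTables
from .smq import HISTORY_GROUPS

TARGET_EVENT = "atypical femoral fracture"

#: toy history preferred terms per group, drawn from the shipped SMQ lists
_HISTORY_TERMS = {
    "osteoporosis": "osteoporosis",
    "cancer": "breast cancer",
    "arthritis": "rheumatoid arthritis",
    "sle": "systemic lupus erythematosus",
    "renal_disorder": "chronic kidney disease",
}
_NEUTRAL_TERMS = ("hypertension", "diabetes mellitus", "asthma")
_GENERIC_EVENTS = ("nausea", "headache", "rash", "dizziness", "pyrexia")
_CONCOMITANT = ("ascorbic acid", "loxoprofen")


@dataclass(frozen=True)
class DrugSpec:
    """One configured drug: exposure rate, planted effect and onset law."""

    name: str
    exposure_prob: float
    log_odds_effect: float = 0.0
    onset_alpha: float = 1000.0
    onset_beta: float = 1.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.exposure_prob <= 1.0:
            raise ValueError("exposure_prob must be a probability")
        if self.onset_beta <= 0 or self.onset_alpha <= 0:
            raise ValueError("onset parameters must be positive")


def default_drugs() -> list[DrugSpec]:
    """Bisphosphonate-like exposure panel with planted signals and nulls."""
    return [
        DrugSpec("alendronic acid", 0.002, math.log(20.0), 2400.0, 1.5),
        DrugSpec("risedronic acid", 0.001, math.log(12.0), 1900.0, 1.8),
        DrugSpec("zoledronic acid", 0.002, math.log(8.0), 2700.0, 3.1),
        DrugSpec("denosumab", 0.002, math.log(10.0), 1050.0, 1.5),
        DrugSpec("prednisolone", 0.02, math.log(2.0), 900.0, 1.0),
        DrugSpec("teriparatide", 0.001, 0.0, 800.0, 1.2),
        DrugSpec("lansoprazole", 0.004, 0.0, 700.0, 1.0),
    ]


def default_covariate_effects() -> dict[str, float]:
    """Planted patient-background log-odds (female, BMI/unit, history)."""
    return {
        "female": math.log(4.02),
        "bmi_unit": math.log(1.11),
        "hist_osteoporosis": math.log(2.53),
        "hist_sle": math.log(1.91),
        "hist_arthritis": math.log(1.36),
        "hist_cancer": 0.0,
        "hist_renal_disorder": 0.0,
    }


@dataclass
class SyntheticConfig:
    """Generator settings; defaults reflect a rare-event report database."""

    n_cases: int = 10_000
    baseline_event_logit: float = -8.0
    drugs: list[DrugSpec] = field(default_factory=default_drugs)
    covariate_effects: dict[str, float] = field(
        default_factory=default_covariate_effects)
    history_prevalence: dict[str, float] = field(default_factory=lambda: {
        "osteoporosis": 0.04, "cancer": 0.30, "arthritis": 0.08,
        "sle": 0.06, "renal_disorder": 0.10,
    })
    missing_rates: dict[str, float] = field(default_factory=lambda: {
        "sex": 0.03, "age": 0.07, "height": 0.55, "weight": 0.55,
    })
    duplicate_rate: float = 0.0
    p_female: float = 0.5
    n_filler_drugs: int = 5
    event_term: str = TARGET_EVENT
    seed: int = 0

    def validate(self) -> None:
        probs = [self.duplicate_rate, self.p_female,
                 *self.missing_rates.values(), *self.history_prevalence.values()]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all rates must be probabilities in [0, 1]")
        names = [d.name for d in self.drugs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate drug name in config")


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery testing.

    ``per_drug`` has one row per configured drug (true odds ratio, onset
    parameters, realized exposure / exposed-event counts); ``cases`` one
    row per case (event indicator, event probability, exposures and
    covariates before missingness was applied).
    """

    per_drug: pd.DataFrame
    cases: pd.DataFrame
    n_duplicates: int
    missing_counts: dict[str, int]


def generate(config: SyntheticConfig) -> tuple[RawTables, SyntheticTruth]:
    """Draw one dataset; a fixed config (incl. seed) is fully reproducible."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    case_ids = np.array([f"C{i:08d}" for i in range(n)])

    # demographics (true values; coded + blanked later)
    female = rng.random(n) < config.p_female
    age_decade = rng.choice(np.arange(10, 100, 10), size=n,
                            p=_age_weights())
    under10 = rng.random(n) < 0.02
    age_years = np.where(under10, 5.0, age_decade + 5.0)
    height_decade = rng.choice(np.arange(130, 190, 10), size=n,
                               p=[0.05, 0.25, 0.35, 0.25, 0.08, 0.02])
    weight_decade = rng.choice(np.arange(30, 100, 10), size=n,
                               p=[0.08, 0.22, 0.35, 0.20, 0.10, 0.04, 0.01])
    height_cm = height_decade + 5.0
    weight_kg = weight_decade + 5.0
    bmi = weight_kg / (height_cm / 100.0) ** 2

    hist_flags = {
        g: rng.random(n) < config.history_prevalence.get(g, 0.0)
        for g in HISTORY_GROUPS
    }

    exposures = {
        d.name: rng.random(n) < d.exposure_prob for d in config.drugs
    }

    eff = config.covariate_effects
    eta = np.full(n, config.baseline_event_logit)
    eta += eff.get("female", 0.0) * female
    eta += eff.get("bmi_unit", 0.0) * (bmi - 22.0)
    for g in HISTORY_GROUPS:
        eta += eff.get(f"hist_{g}", 0.0) * hist_flags[g]
    for d in config.drugs:
        eta += d.log_odds_effect * exposures[d.name]
    p_event = 1.0 / (1.0 + np.exp(-eta))
    event = rng.random(n) < p_event

    # one REAC event per case (target term for event cases)
    base = pd.Timestamp("2018-01-01")
    event_offset = rng.integers(0, 1000, size=n)
    event_dates = base + pd.to_timedelta(event_offset, unit="D")
    event_terms = np.where(
        event, config.event_term, rng.choice(_GENERIC_EVENTS, size=n))

    # DRUG rows: configured exposures (+ filler for unexposed cases)
    drug_rows: list[tuple[str, str, str, object]] = []
    onset_draws: dict[str, list[int]] = {d.name: [] for d in config.drugs}
    any_exposed = np.zeros(n, dtype=bool)
    for d in config.drugs:
        idx = np.flatnonzero(exposures[d.name])
        any_exposed[idx] = True
        durations = np.ones(len(idx), dtype=int)
        is_event = event[idx]
        k = int(is_event.sum())
        if k:
            draws = np.ceil(d.onset_alpha * rng.weibull(d.onset_beta, size=k))
            durations[is_event] = np.maximum(1, draws).astype(int)
            onset_draws[d.name].extend(durations[is_event].tolist())
        lead = rng.integers(0, 365, size=len(idx))
        for j, ci in enumerate(idx):
            if event[ci]:
                start = event_dates[ci] - pd.Timedelta(int(durations[j]) - 1, "D")
            else:
                start = event_dates[ci] - pd.Timedelta(int(lead[j]), "D")
            drug_rows.append((case_ids[ci], d.name, "suspect",
                              start.strftime("%Y-%m-%d")))
    filler_names = [f"filler drug {i:02d}" for i in range(config.n_filler_drugs)]
    unexposed = np.flatnonzero(~any_exposed)
    filler_pick = rng.integers(0, config.n_filler_drugs, size=len(unexposed))
    filler_lead = rng.integers(0, 365, size=len(unexposed))
    for j, ci in enumerate(unexposed):
        start = event_dates[ci] - pd.Timedelta(int(filler_lead[j]), "D")
        drug_rows.append((case_ids[ci], filler_names[filler_pick[j]],
                          "suspect", start.strftime("%Y-%m-%d")))
    conc = np.flatnonzero(rng.random(n) < 0.2)
    for ci in conc:
        drug_rows.append((case_ids[ci],
                          _CONCOMITANT[ci % len(_CONCOMITANT)],
                          "concomitant", ""))

    drug_df = pd.DataFrame(
        drug_rows, columns=["case_id", "drug_name", "role", "start_date"])

    reac_df = pd.DataFrame({
        "case_id": case_ids,
        "event_term": event_terms,
        "event_date": pd.Series(event_dates).dt.strftime("%Y-%m-%d"),
    })

    # coded demographics with missingness
    mr = config.missing_rates
    miss = {f: rng.random(n) < mr.get(f, 0.0)
            for f in ("sex", "age", "height", "weight")}
    sex_code = np.where(miss["sex"], "",
                        np.where(female, "female", "male"))
    age_code = np.where(miss["age"], "",
                        np.where(under10, "under 10",
                                 np.char.add(age_decade.astype(str), "s")))
    height_code = np.where(miss["height"], "",
                           np.char.add(height_decade.astype(str), "s"))
    weight_code = np.where(miss["weight"], "",
                           np.char.add(weight_decade.astype(str), "s"))
    demo_df = pd.DataFrame({
        "case_id": case_ids,
        "report_version": 1,
        "sex": sex_code,
        "age_code": age_code,
        "height_code": height_code,
        "weight_code": weight_code,
    })

    # HIST rows from the set flags (+ occasional neutral term)
    hist_rows = []
    for g in HISTORY_GROUPS:
        for ci in np.flatnonzero(hist_flags[g]):
            hist_rows.append((case_ids[ci], _HISTORY_TERMS[g]))
    neutral = np.flatnonzero(rng.random(n) < 0.3)
    for ci in neutral:
        hist_rows.append((case_ids[ci], _NEUTRAL_TERMS[ci % len(_NEUTRAL_TERMS)]))
    hist_df = pd.DataFrame(hist_rows, columns=["case_id", "disease_term"])

    # duplicated submissions: same case id, version 2, identical rows
    n_dup = int(round(config.duplicate_rate * n))
    if n_dup:
        dup_idx = rng.choice(n, size=n_dup, replace=False)
        dup_ids = set(case_ids[dup_idx])
        demo_dup = demo_df[demo_df["case_id"].isin(dup_ids)].copy()
        demo_dup["report_version"] = 2
        demo_df = pd.concat([demo_df, demo_dup], ignore_index=True)
        drug_df = pd.concat(
            [drug_df, drug_df[drug_df["case_id"].isin(dup_ids)]],
            ignore_index=True)
        reac_df = pd.concat(
            [reac_df, reac_df[reac_df["case_id"].isin(dup_ids)]],
            ignore_index=True)
        hist_df = pd.concat(
            [hist_df, hist_df[hist_df["case_id"].isin(dup_ids)]],
            ignore_index=True)

    # deterministic row order
    drug_df = drug_df.sort_values(
        ["case_id", "drug_name", "role"], kind="mergesort").reset_index(drop=True)
    reac_df = reac_df.sort_values(
        ["case_id", "event_term"], kind="mergesort").reset_index(drop=True)
    demo_df = demo_df.sort_values(
        ["case_id", "report_version"], kind="mergesort").reset_index(drop=True)
    hist_df = hist_df.sort_values(
        ["case_id", "disease_term"], kind="mergesort").reset_index(drop=True)

    per_drug = pd.DataFrame([
        {
            "drug": d.name,
            "true_or": math.exp(d.log_odds_effect),
            "exposure_prob": d.exposure_prob,
            "onset_alpha": d.onset_alpha,
            "onset_beta": d.onset_beta,
            "n_exposed": int(exposures[d.name].sum()),
            "n_exposed_event": int((exposures[d.name] & event).sum()),
        }
        for d in config.drugs
    ])
    cases = pd.DataFrame({
        "case_id": case_ids,
        "event": event,
        "event_prob": p_event,
        "female": female,
        "age_years": age_years,
        "bmi": bmi,
        **{f"hist_{g}": hist_flags[g] for g in HISTORY_GROUPS},
        **{f"exposed_{d.name}": exposures[d.name] for d in config.drugs},
    })
    truth = SyntheticTruth(
        per_drug=per_drug,
        cases=cases,
        n_duplicates=n_dup,
        missing_counts={f: int(m.sum()) for f, m in miss.items()},
    )

    # canonical dtypes matching read_tables output (parsed dates, NA blanks)
    drug_df["start_date"] = pd.to_datetime(
        drug_df["start_date"].replace("", pd.NA), format="%Y-%m-%d")
    drug_df["start_date_imprecise"] = False
    reac_df["event_date"] = pd.to_datetime(reac_df["event_date"], format="%Y-%m-%d")
    reac_df["event_date_imprecise"] = False
    for col in ("sex", "age_code", "height_code", "weight_code"):
        demo_df[col] = demo_df[col].replace("", pd.NA)

    tables = RawTables(drug=drug_df, reac=reac_df, demo=demo_df, hist=hist_df)
    return tables, truth


def _age_weights() -> np.ndarray:
    w = np.array([2, 3, 5, 8, 12, 18, 22, 19, 11], dtype=float)
    return w / w.sum()


def truth_report(truth: SyntheticTruth) -> pd.DataFrame:
    """Machine-readable per-drug truth table for test-harness joins."""
    out = truth.per_drug.copy()
    out["n_duplicates"] = truth.n_duplicates
    return out


def with_seed(config: SyntheticConfig, seed: int) -> SyntheticConfig:
    """Copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
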