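"""Patient-background comparisons and effect-coded multiple logistic regression.

Univariate comparisons between case and non-case reports use the Wilcoxon
rank-sum test for continuous variables (age, height, weight, BMI), Fisher's
exact two-sided test for sex, and Fisher's exact right-sided test for the
history flags, each on the complete cases for that variable.

The multivariable model is an ordinary maximum-likelihood logistic
regression of the event indicator on effect-coded binary predictors
(exposed +1 / unexposed −1) plus untransformed continuous predictors,
complete cases only. Under ±1 coding the odds ratio for the unexposed →
exposed contrast is exp(2·coefficient); for continuous predictors both a
per-unit odds ratio exp(b) and an observed-range odds ratio
exp(b·(max − min)) are reported, with Wald confidence intervals throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# univariate comparisons (Table-1 style)


def univariate_tests(
    records: pd.DataFrame,
    variable: str,
    kind: str,
    outcome: str = "is_case",
) -> tuple[float, float]:
    """Compare one variable between case and non-case reports.

    ``kind`` is ``continuous`` (Wilcoxon rank-sum), ``binary_two_sided`` or
    ``binary_right_tailed`` (Fisher's exact on the 2×2 table). Missing
    values are dropped for the variable under test. Returns
    (statistic, p); both are NaN with a warning if either outcome group is
    empty after missing-value removal.
    """
    from .disproportionality import ContingencyTable, fisher_p

    sub = records[[variable, outcome]].dropna(subset=[variable])
    case = sub.loc[sub[outcome].astype(bool), variable]
    ctrl = sub.loc[~sub[outcome].astype(bool), variable]
    if len(case) == 0 or len(ctrl) == 0:
        logger.warning("variable %r: a group is empty after missing-value "
                       "removal; p set missing", variable)
        return math_nan, math_nan
    if kind == "continuous":
        res = stats.mannwhitneyu(case.to_numpy(float), ctrl.to_numpy(float),
                                 alternative="two-sided", method="auto")
        return float(res.statistic), float(res.pvalue)
    if kind in ("binary_two_sided", "binary_right_tailed"):
        a = int(pd.Series(case).astype(bool).sum())
        b = int(pd.Series(ctrl).astype(bool).sum())
        tab = ContingencyTable(a, b, len(case) - a, len(ctrl) - b)
        side = "two_sided" if kind == "binary_two_sided" else "right_tailed"
        return float(a), fisher_p(tab, side)
    raise ValueError(f"unknown test kind {kind!r}")


math_nan = float("nan")


def univariate_table(
    records: pd.DataFrame,
    continuous: Sequence[str] = ("age_years", "height_cm", "weight_kg", "bmi"),
    binary_two_sided: Sequence[str] = ("female",),
    binary_right_tailed: Sequence[str] = (),
    outcome: str = "is_case",
) -> pd.DataFrame:
    """Table-1-style per-variable comparison of case vs non-case reports."""
    rows = []
    for var in continuous:
        stat, p = univariate_tests(records, var, "continuous", outcome)
        rows.append({"variable": var, "kind": "continuous", "statistic": stat, "p": p})
    for var in binary_two_sided:
        stat, p = univariate_tests(records, var, "binary_two_sided", outcome)
        rows.append({"variable": var, "kind": "binary_two_sided", "statistic": stat, "p": p})
    for var in binary_right_tailed:
        stat, p = univariate_tests(records, var, "binary_right_tailed", outcome)
        rows.append({"variable": var, "kind": "binary_right_tailed", "statistic": stat, "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# design encoding


@dataclass
class DesignSpec:
    """Predictor lists for the multivariable model.

    ``binary_predictors`` name boolean columns of the feature frame (drug
    exposures, ``female``, history flags) that are effect-coded ±1;
    ``continuous_predictors`` (age, BMI) enter untransformed and their
    observed post-filter range is recorded for the range odds ratio.
    ``binary_coding`` maps (unexposed, exposed) numeric levels and exists
    so the coding-equivalence identity (±1 vs 0/1) is testable.
    """

    binary_predictors: list[str] = field(default_factory=list)
    continuous_predictors: list[str] = field(default_factory=list)
    binary_coding: tuple[float, float] = (-1.0, 1.0)

    def __post_init__(self) -> None:
        names = list(self.binary_predictors) + list(self.continuous_predictors)
        if len(set(names)) != len(names):
            raise ValueError("duplicated predictor name in DesignSpec")


def features_from_records(
    records: pd.DataFrame,
    drugs: Sequence[str] = (),
    event: str | None = None,
) -> pd.DataFrame:
    """Flatten the analysis table into a numeric feature frame.

    Adds ``female``, per-drug ``drug_<name>`` exposure indicators, keeps
    the ``hist_*`` flags and continuous demographics, and (if ``event``)
    an ``is_case`` outcome column.
    """
    out = pd.DataFrame(index=records.index)
    out["case_id"] = records["case_id"]
    sex = records["sex"]
    out["female"] = np.where(sex.isna(), np.nan, (sex == "female").astype(float))
    for col in ("age_years", "height_cm", "weight_kg", "bmi"):
        out[col] = records[col].astype(float)
    for col in records.columns:
        if col.startswith("hist_"):
            out[col] = records[col].astype(float)
    for drug in drugs:
        out[f"drug_{drug}"] = records["suspect_drugs"].apply(
            lambda s: float(drug in s))
    if event is not None:
        out["is_case"] = records["events"].apply(
            lambda s: float(event in s))
    return out


def encode_design(
    features: pd.DataFrame,
    spec: DesignSpec,
    outcome: str = "is_case",
) -> tuple[pd.DataFrame, pd.Series, dict[str, tuple[float, float]]]:
    """Complete-case design matrix, outcome vector, and observed ranges.

    Binary predictors are mapped 0 → coding[0], 1 → coding[1]; continuous
    predictors pass through. Columns constant after filtering are dropped
    with a warning. Returns (X with constant, y, ranges) where ``ranges``
    records each continuous predictor's observed (min, max).
    """
    cols = list(spec.binary_predictors) + list(spec.continuous_predictors)
    sub = features[cols + [outcome]].dropna()
    lo, hi = spec.binary_coding
    X = pd.DataFrame(index=sub.index)
    ranges: dict[str, tuple[float, float]] = {}
    for name in spec.binary_predictors:
        X[name] = np.where(sub[name].astype(float) > 0, hi, lo)
    for name in spec.continuous_predictors:
        X[name] = sub[name].astype(float)
        ranges[name] = (float(sub[name].min()), float(sub[name].max()))
    constant = [c for c in X.columns if X[c].nunique() < 2]
    if constant:
        logger.warning("dropping constant predictor column(s): %s", constant)
        X = X.drop(columns=constant)
        ranges = {k: v for k, v in ranges.items() if k not in constant}
    y = sub[outcome].astype(float)
    X = sm.add_constant(X, has_constant="add")
    return X, y, ranges


# ---------------------------------------------------------------------------
# model / results


class LogisticRiskModel:
    """Multiple logistic regression for the combined risk-factor analysis.

    Thin modelling surface over a maximum-likelihood logit fit; built
    either from a prepared design (``__init__``) or straight from the
    analysis table (:meth:`from_records`). ``fit()`` returns a
    :class:`LogisticRiskResults`.
    """

    def __init__(
        self,
        X: pd.DataFrame,
        y: pd.Series,
        spec: DesignSpec,
        ranges: dict[str, tuple[float, float]] | None = None,
    ) -> None:
        if y.sum() < 1 or (1 - y).sum() < 1:
            raise ValueError("need at least one event and one non-event")
        self.X = X
        self.y = y
        self.spec = spec
        self.ranges = ranges or {}

    @classmethod
    def from_records(
        cls,
        records: pd.DataFrame,
        spec: DesignSpec,
        event: str,
        drugs: Sequence[str] = (),
    ) -> "LogisticRiskModel":
        feats = features_from_records(records, drugs=drugs, event=event)
        X, y, ranges = encode_design(feats, spec)
        return cls(X, y, spec, ranges)

    def fit(self, maxiter: int = 100, level: float = 0.95) -> "LogisticRiskResults":
        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        model = sm.Logit(self.y.to_numpy(), self.X.to_numpy())
        with warnings.catch_warnings():
            warnings.filterwarnings("error", category=PerfectSeparationWarning)
            try:
                res = model.fit(disp=0, maxiter=maxiter, method="newton")
            except Exception as exc:  # separation manifests several ways
                raise _diagnose_separation(self.X, self.y, exc) from exc
        if not res.mle_retvals.get("converged", True):
            exc = RuntimeError(
                f"logistic fit did not converge after {maxiter} iterations "
                f"(last log-likelihood {res.llf:.4f})")
            raise _diagnose_separation(self.X, self.y, exc)
        return LogisticRiskResults(self, res, level)


def _diagnose_separation(X: pd.DataFrame, y: pd.Series, exc: Exception) -> Exception:
    yv = y.to_numpy() > 0
    for col in X.columns:
        if col == "const":
            continue
        v = X[col].to_numpy()
        if len(np.unique(v)) == 2:
            hi = v == v.max()
            if yv[hi].all() or (~yv[hi]).all() or yv[~hi].all() or (~yv[~hi]).all():
                return ValueError(
                    f"complete separation on predictor {col!r}: {exc}")
    return RuntimeError(f"logistic fit failed: {exc}")


class LogisticRiskResults:
    """Estimates, odds ratios and Wald intervals from the logistic fit."""

    def __init__(self, model: LogisticRiskModel, res, level: float = 0.95):
        self.model = model
        self._res = res
        self.level = level
        names = list(model.X.columns)
        self.params = pd.Series(res.params, index=names)
        self.bse = pd.Series(res.bse, index=names)
        self.pvalues = pd.Series(res.pvalues, index=names)
        ci = res.conf_int(alpha=1 - level)
        self.conf_int = pd.DataFrame(ci, index=names, columns=["low", "high"])
        self.llf = float(res.llf)
        self.llnull = float(res.llnull)
        self.n_used = int(len(model.y))

    @property
    def intercept(self) -> float:
        return float(self.params["const"])

    def predict(self, X: pd.DataFrame | None = None) -> np.ndarray:
        Xv = self.model.X if X is None else X
        return self._res.predict(np.asarray(Xv, dtype=float))

    # --- odds ratios -------------------------------------------------------
    def _contrast(self, name: str) -> float:
        lo, hi = self.model.spec.binary_coding
        return hi - lo

    @property
    def level_or(self) -> pd.Series:
        """Unexposed → exposed odds ratio per binary predictor.

        Equals exp(coefficient × coding span): exp(2b) under ±1 coding,
        exp(b) under 0/1 — invariant to the coding choice.
        """
        out = {}
        for name in self.model.spec.binary_predictors:
            if name in self.params.index:
                out[name] = float(np.exp(self.params[name] * self._contrast(name)))
        return pd.Series(out, dtype=float)

    @property
    def unit_or(self) -> pd.Series:
        out = {
            name: float(np.exp(self.params[name]))
            for name in self.model.spec.continuous_predictors
            if name in self.params.index
        }
        return pd.Series(out, dtype=float)

    @property
    def range_or(self) -> pd.Series:
        out = {}
        for name, (lo, hi) in self.model.ranges.items():
            if name in self.params.index:
                out[name] = float(np.exp(self.params[name] * (hi - lo)))
        return pd.Series(out, dtype=float)

    def odds_ratio_frame(self) -> pd.DataFrame:
        """Table-3-shaped frame: predictor, OR, CI bounds, p-value."""
        rows = []
        span = self._contrast("")
        for name in self.model.spec.binary_predictors:
            if name not in self.params.index:
                continue
            rows.append({
                "predictor": name,
                "or": float(np.exp(self.params[name] * span)),
                "ci_low": float(np.exp(self.conf_int.loc[name, "low"] * span)),
                "ci_high": float(np.exp(self.conf_int.loc[name, "high"] * span)),
                "p": float(self.pvalues[name]),
            })
        for name in self.model.spec.continuous_predictors:
            if name not in self.params.index:
                continue
            rows.append({
                "predictor": f"{name} (unit)",
                "or": float(np.exp(self.params[name])),
                "ci_low": float(np.exp(self.conf_int.loc[name, "low"])),
                "ci_high": float(np.exp(self.conf_int.loc[name, "high"])),
                "p": float(self.pvalues[name]),
            })
            if name in self.model.ranges:
                lo, hi = self.model.ranges[name]
                rows.append({
                    "predictor": f"{name} (range)",
                    "or": float(np.exp(self.params[name] * (hi - lo))),
                    "ci_low": float(np.exp(self.conf_int.loc[name, "low"] * (hi - lo))),
                    "ci_high": float(np.exp(self.conf_int.loc[name, "high"] * (hi - lo))),
                    "p": float(self.pvalues[name]),
                })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        head = (
            f"Logistic risk model (n = {self.n_used}), "
            f"log-likelihood {self.llf:.2f} (null {self.llnull:.2f})\n"
        )
        return head + self.odds_ratio_frame().to_string(
            index=False, float_format=lambda v: f"{v:.4g}")
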