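"""Disproportionality signal screening for a target adverse event.

For each drug a 2×2 contingency table is formed over the analysis table:

====================  ===========  =============
exposure               event        no event
====================  ===========  =============
drug suspected         a            b
drug not suspected     c            d
====================  ===========  =============

The reporting odds ratio (ROR) is (a/b)/(c/d) computed on cells to which
0.5 has been added unconditionally (Haldane–Anscombe correction), which
keeps the estimate finite for zero cells; its confidence interval is the
Woolf log-normal interval ``exp(ln ROR ± z·sqrt(Σ 1/cell))`` on the same
corrected cells. Statistical support comes from Fisher's exact test on the
raw counts, evaluated in log space so that margins in the millions are
handled exactly. A drug is screened as a signal when ROR ≥ 1 and the
two-sided exact p ≤ 0.05 (both bounds inclusive); results feed a volcano
plot of −log10 p against ln ROR, coloured by log10 of the drug's report
count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import norm

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    """Raw 2×2 counts; ``corrected()`` yields the +0.5 view."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def corrected(self) -> tuple[float, float, float, float]:
        return self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5


def build_contingency(
    records: pd.DataFrame, drug: str, event: str
) -> ContingencyTable:
    """Count each case once into the drug × event 2×2 table."""
    exposed = records["suspect_drugs"].apply(lambda s: drug in s).to_numpy()
    has_event = records["events"].apply(lambda s: event in s).to_numpy()
    a = int(np.sum(exposed & has_event))
    b = int(np.sum(exposed & ~has_event))
    c = int(np.sum(~exposed & has_event))
    d = int(np.sum(~exposed & ~has_event))
    return ContingencyTable(a, b, c, d)


def ror_with_ci(
    table: ContingencyTable, level: float = 0.95
) -> tuple[float, float, float]:
    """Corrected ROR with Woolf CI: ``((a+½)/(b+½)) / ((c+½)/(d+½))``.

    The 0.5 correction is applied to every cell regardless of zeros, so the
    estimate and interval are always finite.
    """
    a, b, c, d = table.corrected()
    ror = (a / b) / (c / d)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = norm.ppf(0.5 + level / 2)
    return ror, ror * math.exp(-z * se), ror * math.exp(z * se)


def _log_hypergeom_pmf(k: np.ndarray, N: int, K: int, n: int) -> np.ndarray:
    # log P(X = k) for X ~ Hypergeom(N, K, n), via log-gamma
    k = np.asarray(k, dtype=float)
    return (
        gammaln(K + 1) - gammaln(k + 1) - gammaln(K - k + 1)
        + gammaln(N - K + 1) - gammaln(n - k + 1) - gammaln(N - K - n + k + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )


def fisher_p(table: ContingencyTable, sidedness: str = "two_sided") -> float:
    """Exact hypergeometric p-value on the raw counts, in log space.

    ``two_sided`` sums the probabilities of all tables (at fixed margins)
    no more probable than the observed one; ``right_tailed`` is
    P(A ≥ a), the enrichment direction. Any zero margin gives p = 1.
    """
    if sidedness not in ("two_sided", "right_tailed"):
        raise ValueError(f"unknown sidedness {sidedness!r}")
    a, b, c, d = table.a, table.b, table.c, table.d
    N = a + b + c + d
    row, col = a + b, a + c
    if min(row, col, N - row, N - col) == 0:
        return 1.0
    lo = max(0, row + col - N)
    hi = min(row, col)
    support = np.arange(lo, hi + 1)
    logp = _log_hypergeom_pmf(support, N, col, row)
    if sidedness == "right_tailed":
        return float(min(1.0, math.exp(logsumexp(logp[support >= a]))))
    log_obs = logp[a - lo]
    mask = logp <= log_obs + 1e-7  # relative tolerance guards fp ties
    return float(min(1.0, math.exp(logsumexp(logp[mask]))))


def reporting_ratio(table: ContingencyTable) -> float:
    """Fraction of the drug's reports that are the target event: a/(a+b)."""
    if table.a + table.b == 0:
        return math.nan
    return table.a / (table.a + table.b)


@dataclass(frozen=True)
class SignalResult:
    """Per-drug screening result with volcano-plot coordinates."""

    drug: str
    table: ContingencyTable
    ror: float
    ci_low: float
    ci_high: float
    p_two_sided: float
    reporting_ratio: float
    ln_ror: float
    neg_log10_p: float
    log10_n_reports: float
    is_signal: bool


class DisproportionalityScreen:
    """Exhaustive per-drug disproportionality screen against one event.

    Parameters
    ----------
    records
        Analysis table (one row per case with ``suspect_drugs`` and
        ``events`` frozenset columns).
    event
        Target adverse-event preferred term.
    drugs
        Drugs to screen; defaults to every drug appearing as a suspect.
    level, ror_min, p_max
        CI level and the signal rule thresholds (ROR ≥ ror_min and
        p ≤ p_max, both inclusive).
    """

    def __init__(
        self,
        records: pd.DataFrame,
        event: str,
        drugs: Sequence[str] | None = None,
        level: float = 0.95,
        ror_min: float = 1.0,
        p_max: float = 0.05,
    ) -> None:
        self.records = records
        self.event = event
        self.level = level
        self.ror_min = ror_min
        self.p_max = p_max
        if drugs is None:
            drugs = sorted({d for s in records["suspect_drugs"] for d in s})
        self.drugs = list(drugs)

    def fit(self) -> "ScreenResults":
        records = self.records
        has_event = records["events"].apply(lambda s: self.event in s).to_numpy()
        n_total = len(records)
        n_event = int(has_event.sum())
        # exploded exposure bookkeeping: one pass over all suspect sets
        exploded = records.loc[:, ["suspect_drugs"]].copy()
        exploded["has_event"] = has_event
        long = exploded.explode("suspect_drugs")
        grp = long.groupby("suspect_drugs")["has_event"]
        a_counts = grp.sum().astype(int)
        n_counts = grp.size()
        results = []
        for drug in self.drugs:
            a = int(a_counts.get(drug, 0))
            nd = int(n_counts.get(drug, 0))
            tab = ContingencyTable(a, nd - a, n_event - a, n_total - nd - n_event + a)
            results.append(evaluate_drug(drug, tab, self.level, self.ror_min, self.p_max))
        return ScreenResults(self, results)


def evaluate_drug(
    drug: str,
    table: ContingencyTable,
    level: float = 0.95,
    ror_min: float = 1.0,
    p_max: float = 0.05,
) -> SignalResult:
    """ROR, CI, exact p and volcano coordinates for one contingency table."""
    ror, lo, hi = ror_with_ci(table, level)
    p = fisher_p(table, "two_sided")
    if p <= 0.0:
        p = float(np.nextafter(0, 1))
        logger.warning("p-value for %s underflowed; clamped to %.3g", drug, p)
    n_reports = table.a + table.b
    return SignalResult(
        drug=drug,
        table=table,
        ror=ror,
        ci_low=lo,
        ci_high=hi,
        p_two_sided=p,
        reporting_ratio=reporting_ratio(table),
        ln_ror=math.log(ror),
        neg_log10_p=-math.log10(p),
        log10_n_reports=math.log10(n_reports) if n_reports > 0 else math.nan,
        is_signal=bool(ror >= ror_min and p <= p_max),
    )


def screen_signals(
    results: Iterable[SignalResult],
    ror_min: float = 1.0,
    p_max: float = 0.05,
) -> list[SignalResult]:
    """Re-apply the signal rule and return signals sorted by descending ROR."""
    flagged = []
    for r in results:
        is_signal = bool(r.ror >= ror_min and r.p_two_sided <= p_max)
        flagged.append(
            SignalResult(**{**r.__dict__, "is_signal": is_signal})
        )
    signals = [r for r in flagged if r.is_signal]
    signals.sort(key=lambda r: (-r.ror, r.drug))
    return signals


def volcano_coordinates(
    results: Iterable[SignalResult], p_axis: str = "x"
) -> list[tuple[float, float, float]]:
    """Volcano-plot points (x, y, colour) per drug.

    With ``p_axis="x"`` (default) x = −log10 p and y = ln ROR; ``p_axis="y"``
    swaps the axes. Colour is log10 of the drug's total report count.
    """
    if p_axis not in ("x", "y"):
        raise ValueError("p_axis must be 'x' or 'y'")
    pts = []
    for r in results:
        x, y = r.neg_log10_p, r.ln_ror
        if p_axis == "y":
            x, y = y, x
        pts.append((x, y, r.log10_n_reports))
    return pts


class ScreenResults:
    """Results container for :class:`DisproportionalityScreen`."""

    def __init__(self, model: DisproportionalityScreen, results: list[SignalResult]):
        self.model = model
        self.results = results

    @property
    def signals(self) -> list[SignalResult]:
        return screen_signals(self.results, self.model.ror_min, self.model.p_max)

    def volcano_coordinates(self, p_axis: str = "x") -> list[tuple[float, float, float]]:
        return volcano_coordinates(self.results, p_axis)

    def frame(self) -> pd.DataFrame:
        """One row per screened drug, Table-2 style, sorted by descending ROR."""
        rows = [
            {
                "drug": r.drug,
                "a": r.table.a,
                "b": r.table.b,
                "c": r.table.c,
                "d": r.table.d,
                "reporting_ratio": r.reporting_ratio,
                "ror": r.ror,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p_two_sided": r.p_two_sided,
                "ln_ror": r.ln_ror,
                "neg_log10_p": r.neg_log10_p,
                "log10_n_reports": r.log10_n_reports,
                "is_signal": r.is_signal,
            }
            for r in self.results
        ]
        df = pd.DataFrame(rows)
        if len(df):
            df = df.sort_values(["ror", "drug"], ascending=[False, True])
        return df.reset_index(drop=True)

    def summary(self) -> str:
        df = self.frame()
        n_sig = int(df["is_signal"].sum()) if len(df) else 0
        head = (
            f"Disproportionality screen: event={self.model.event!r}, "
            f"{len(df)} drugs, {n_sig} signals "
            f"(ROR >= {self.model.ror_min}, p <= {self.model.p_max})\n"
        )
        show = df[["drug", "a", "b", "reporting_ratio", "ror", "ci_low",
                   "ci_high", "p_two_sided", "is_signal"]]
        return head + show.to_string(
            index=False,
            float_format=lambda v: f"{v:.4g}",
        )
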