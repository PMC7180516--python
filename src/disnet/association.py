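"""Pairwise temporal relative risks and the filtered edge set.

For an ordered disease pair D1 -> D2 the at-risk group is every cohort member
with no observation-window diagnosis of D2. Within that group the 2x2
contingency table is

    a  exposed to D1 (observation) and acquiring D2 (outcome)
    b  exposed to D1, not acquiring D2
    c  not exposed to D1, acquiring D2
    d  neither

and the relative risk is RR = (a / (a + b)) / (c / (c + d)). Independence is
tested per pair (two-sided Fisher exact by default), P values are corrected
for the number of pairs tested (Bonferroni by default, Benjamini-Hochberg
optional), and edges are kept when RR strictly exceeds an integer cutoff
derived from the top percentile of the empirical RR distribution and the
corrected P falls below the threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import ExposureMatrix

log = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "EdgeFilter",
    "DegenerateMarginError",
    "at_risk_size",
    "at_risk_group",
    "contingency",
    "relative_risk",
    "independence_p",
    "adjust_p",
    "pair_universe",
    "percentile_cutoff",
    "pair_stats",
    "filter_edges",
]


class DegenerateMarginError(ValueError):
    """A contingency margin needed for the relative risk is zero."""


@dataclass(frozen=True)
class ContingencyTable:
    """Ordered-pair 2x2 patient counts over the target's at-risk group."""

    a: int
    b: int
    c: int
    d: int
    source_code: str = ""
    target_code: str = ""

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class EdgeFilter:
    """Edge retention rule: RR strictly above ``rr_cutoff`` and corrected P
    strictly below ``p_threshold``."""

    rr_cutoff: int
    p_threshold: float = 0.001
    method: str = "bonferroni"

    def __post_init__(self) -> None:
        if self.rr_cutoff < 0:
            raise ValueError("rr_cutoff must be >= 0")


def at_risk_size(cohort_size: int, exposed_count: int) -> int:
    """Size of the at-risk group for an outcome disease: cohort members minus
    those already diagnosed with it during the observation window."""
    if not 0 <= exposed_count <= cohort_size:
        raise ValueError("exposed_count must lie in [0, cohort_size]")
    return cohort_size - exposed_count


def at_risk_group(outcome_code: str, observation: ExposureMatrix) -> np.ndarray:
    """Boolean mask over the cohort: True for patients with no
    observation-window diagnosis of ``outcome_code``."""
    return ~observation.column(outcome_code)


def contingency(source_code: str, target_code: str,
                observation: ExposureMatrix, outcome: ExposureMatrix
                ) -> ContingencyTable:
    """The 2x2 table for one ordered pair, computed over the target's at-risk
    group. Self-pairs are rejected (self-interaction is out of scope)."""
    if source_code == target_code:
        raise ValueError(f"self-interaction {source_code}->{target_code} "
                         "is not a valid pair")
    if not np.array_equal(observation.patients, outcome.patients):
        raise ValueError("observation and outcome matrices must share the "
                         "same patient axis")
    risk = at_risk_group(target_code, observation)
    src = observation.column(source_code)[risk]
    tgt = outcome.column(target_code)[risk]
    a = int(np.sum(src & tgt))
    b = int(np.sum(src & ~tgt))
    c = int(np.sum(~src & tgt))
    d = int(np.sum(~src & ~tgt))
    return ContingencyTable(a, b, c, d, source_code, target_code)


def relative_risk(t: ContingencyTable) -> float:
    """RR = (a/(a+b)) / (c/(c+d)).

    Returns ``inf`` when c=0 and a>0, ``0.0`` when a=0 and c>0, and ``nan``
    when a=c=0 (no outcome events at all); raises when a margin is empty.
    """
    if t.a + t.b == 0 or t.c + t.d == 0:
        raise DegenerateMarginError(
            f"{t.source_code}->{t.target_code}: empty exposure margin"
        )
    if t.c == 0:
        if t.a == 0:
            return float("nan")
        return float("inf")
    return (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))


def independence_p(t: ContingencyTable, method: str = "fisher") -> float:
    """P value against independence of exposure and outcome.

    ``fisher`` (default) is the two-sided Fisher exact test (hypergeometric
    tail summation); ``chi2`` is the continuity-corrected chi-square, useful
    for speed on very large cohorts. Degenerate margins give P=1.
    """
    table = [[t.a, t.b], [t.c, t.d]]
    if t.a + t.b == 0 or t.c + t.d == 0 or t.a + t.c == 0 or t.b + t.d == 0:
        log.warning("%s->%s: degenerate margins, P set to 1",
                    t.source_code, t.target_code)
        return 1.0
    if method == "fisher":
        return float(stats.fisher_exact(table, alternative="two-sided").pvalue)
    if method == "chi2":
        return float(stats.chi2_contingency(table, correction=True).pvalue)
    raise ValueError(f"unknown test method {method!r}")


def adjust_p(p_values, method: str = "bonferroni", m: int | None = None):
    """Multiplicity-corrected P values, order preserved.

    Bonferroni multiplies by ``m`` (default: the number of values given, i.e.
    the number of pairs actually tested) and caps at 1; ``bh`` applies the
    Benjamini-Hochberg step-up procedure.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p values must lie in [0, 1]")
    if method == "bonferroni":
        m = len(p) if m is None else m
        return np.minimum(1.0, m * p)
    if method == "bh":
        if p.size == 0:
            return p
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown adjustment method {method!r}")


def pair_universe(n_codes: int) -> int:
    """Number of ordered code pairs excluding self-pairs: n(n-1)."""
    if n_codes < 2:
        raise ValueError("need at least 2 codes for a pair universe")
    return n_codes * (n_codes - 1)


def percentile_cutoff(rrs, tail: float = 0.01) -> int:
    """Integer RR cutoff: the nearest integer (halves round up) to the
    empirical (1 - tail) quantile of the finite RR values."""
    rr = np.asarray(list(rrs), dtype=float)
    rr = rr[np.isfinite(rr)]
    if rr.size == 0:
        raise ValueError("no finite RR values to take a percentile of")
    if not 0.0 < tail < 1.0:
        raise ValueError("tail must lie in (0, 1)")
    q = float(np.percentile(rr, 100.0 * (1.0 - tail)))
    return int(math.floor(q + 0.5))


def pair_stats(observation: ExposureMatrix, outcome: ExposureMatrix,
               test: str = "fisher") -> pd.DataFrame:
    """Contingency counts, RR and raw P for every ordered pair of codes.

    Both matrices must share patient and code axes. The a/b/c/d counts for
    all pairs are obtained with four boolean matrix products (the at-risk
    restriction folds into the outcome indicator as "acquired in outcome and
    not present in observation"), then RR and the independence P value are
    evaluated per pair. Returns a DataFrame with columns
    ``source target a b c d rr p_raw``.
    """
    if observation.codes != outcome.codes:
        raise ValueError("observation and outcome must cover the same codes")
    if not np.array_equal(observation.patients, outcome.patients):
        raise ValueError("observation and outcome matrices must share the "
                         "same patient axis")
    O = observation.presence.astype(np.float64)
    notO = 1.0 - O
    V = outcome.presence & ~observation.presence  # newly acquired, at risk
    V = V.astype(np.float64)
    a = (O.T @ V).round().astype(np.int64)
    ab = (O.T @ notO).round().astype(np.int64)   # exposed among at-risk(j)
    c = (notO.T @ V).round().astype(np.int64)
    cd = (notO.T @ notO).round().astype(np.int64)
    b = ab - a
    d = cd - c

    codes = observation.codes
    n = len(codes)
    rows = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            t = ContingencyTable(int(a[i, j]), int(b[i, j]),
                                 int(c[i, j]), int(d[i, j]),
                                 codes[i], codes[j])
            try:
                rr = relative_risk(t)
            except DegenerateMarginError:
                rr = float("nan")
            p = independence_p(t, method=test)
            rows.append((codes[i], codes[j], t.a, t.b, t.c, t.d, rr, p))
    return pd.DataFrame(
        rows, columns=["source", "target", "a", "b", "c", "d", "rr", "p_raw"]
    )


def filter_edges(stats_table: pd.DataFrame, f: EdgeFilter) -> pd.DataFrame:
    """Apply the retention rule to the full statistics table.

    Keeps rows with finite RR strictly greater than the cutoff and adjusted P
    strictly below the threshold; infinite RRs (unstable estimates) are
    excluded with their count logged. Adds/keeps a ``p_adj`` column.
    """
    out = stats_table.copy()
    if "p_adj" not in out.columns:
        out["p_adj"] = adjust_p(out["p_raw"].values, method=f.method)
    n_inf = int(np.isinf(out["rr"]).sum())
    if n_inf:
        log.info("excluding %d infinite-RR pairs from the edge set", n_inf)
    keep = (np.isfinite(out["rr"])
            & (out["rr"] > f.rr_cutoff)
            & (out["p_adj"] < f.p_threshold))
    return out.loc[keep].reset_index(drop=True)
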