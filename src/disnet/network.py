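"""Directed weighted disease network and node-level topology metrics.

Nodes are the diagnosis codes incident to at least one retained edge, each
annotated with a demographic summary (sex counts and age-band mix of the
patients diagnosed with it in the observation window). Edges carry the
relative risk as weight. Node metrics are the in/out degree and the in/out
strength, the strength of a node being the sum of the RR weights on its
incoming or outgoing edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ExposureMatrix

log = logging.getLogger(__name__)

__all__ = [
    "DemographicSummary",
    "demographic_summary",
    "build_network",
    "node_metrics",
    "metric_correlation",
    "degree_distribution",
    "top_nodes",
]

AGE_BAND_EDGES = (30, 60)  # <30, 30-59, >=60


@dataclass(frozen=True)
class DemographicSummary:
    """Sex counts and age composition of one disease's patient pool."""

    code: str
    n_female: int
    n_male: int
    age_band_fractions: tuple  # (<30, 30-59, >=60), sums to 1
    mean_age: float
    sd_age: float
    reference_date: date

    def __post_init__(self) -> None:
        if self.n_female < 0 or self.n_male < 0:
            raise ValueError("sex counts must be non-negative")
        total = self.n_female + self.n_male
        if total and abs(sum(self.age_band_fractions) - 1.0) > 1e-9:
            raise ValueError("age band fractions must sum to 1")


def _ages_at(birth_years: np.ndarray, reference_date: date) -> np.ndarray:
    # claims data carry birth year only, so age is whole years at the
    # reference date's year
    return reference_date.year - birth_years


def age_band_fractions(ages: np.ndarray) -> tuple:
    """Fractions of patients aged <30, 30-59 and >=60."""
    n = len(ages)
    if n == 0:
        return (0.0, 0.0, 0.0)
    lo, hi = AGE_BAND_EDGES
    return (float(np.mean(ages < lo)),
            float(np.mean((ages >= lo) & (ages < hi))),
            float(np.mean(ages >= hi)))


def demographic_summary(code: str, observation: ExposureMatrix,
                        demographics: pd.DataFrame,
                        reference_date: date) -> DemographicSummary:
    """Summary of the patients diagnosed with ``code`` in the observation
    window, with ages taken at ``reference_date``."""
    mask = observation.column(code)
    pats = observation.patients[mask]
    demo = demographics.set_index("patient_id").loc[pats]
    ages = _ages_at(demo["birth_year"].to_numpy(), reference_date)
    n_f = int((demo["sex"] == "F").sum())
    n_m = int((demo["sex"] == "M").sum())
    return DemographicSummary(
        code=code,
        n_female=n_f,
        n_male=n_m,
        age_band_fractions=age_band_fractions(ages),
        mean_age=float(ages.mean()) if len(ages) else float("nan"),
        sd_age=float(ages.std(ddof=1)) if len(ages) > 1 else 0.0,
        reference_date=reference_date,
    )


def build_network(edges: pd.DataFrame, observation: ExposureMatrix,
                  demographics: pd.DataFrame,
                  reference_date: date | None = None) -> nx.DiGraph:
    """Assemble the directed disease network from the filtered edge table.

    ``edges`` needs columns ``source target rr p_adj``. Only codes incident
    to at least one edge become nodes (isolated codes are dropped). Each node
    carries its demographic summary; ``reference_date`` defaults to nothing
    more specific than the summary caller provides — the pipeline uses the
    start of the outcome period.
    """
    if len(edges) == 0:
        raise ValueError("edge list is empty; no network to build")
    if reference_date is None:
        raise ValueError("reference_date is required for node demographics")
    G = nx.DiGraph()
    codes = sorted(set(edges["source"]) | set(edges["target"]))
    for code in codes:
        s = demographic_summary(code, observation, demographics, reference_date)
        f = s.age_band_fractions
        G.add_node(code, n_female=s.n_female, n_male=s.n_male,
                   frac_under30=f[0], frac_30_59=f[1], frac_60plus=f[2],
                   mean_age=s.mean_age, sd_age=s.sd_age)
    for row in edges.itertuples(index=False):
        if row.source == row.target:
            raise ValueError(f"self-loop {row.source} in edge table")
        G.add_edge(row.source, row.target, rr=float(row.rr),
                   p_adj=float(row.p_adj))
    return G


def node_metrics(G: nx.DiGraph) -> pd.DataFrame:
    """Degree and strength per node.

    out_strength(i) = sum of RR over edges i->j; in_strength(i) = sum over
    edges j->i; degrees are the corresponding edge counts.
    """
    rows = []
    for v in sorted(G.nodes):
        rows.append((
            v,
            G.out_degree(v),
            G.in_degree(v),
            float(sum(d["rr"] for _, _, d in G.out_edges(v, data=True))),
            float(sum(d["rr"] for _, _, d in G.in_edges(v, data=True))),
        ))
    return pd.DataFrame(
        rows,
        columns=["code", "out_degree", "in_degree", "out_strength",
                 "in_strength"],
    )


def metric_correlation(metrics: pd.DataFrame, x_field: str,
                       y_field: str) -> float:
    """Pearson correlation between two metric columns; NaN (not an error)
    when either column has zero variance."""
    x = metrics[x_field].to_numpy(dtype=float)
    y = metrics[y_field].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 nodes for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def degree_distribution(metrics: pd.DataFrame, field: str) -> pd.DataFrame:
    """Empirical complementary CDF of a metric: rows ``(value, ccdf)`` with
    ccdf = P[X >= value], non-increasing and starting at 1."""
    x = np.sort(metrics[field].to_numpy(dtype=float))
    if len(x) == 0:
        raise ValueError("empty metrics table")
    values = np.unique(x)
    ccdf = [float(np.mean(x >= v)) for v in values]
    return pd.DataFrame({"value": values, "ccdf": ccdf})


def top_nodes(metrics: pd.DataFrame, field: str, k: int) -> pd.DataFrame:
    """The k nodes with the highest ``field``, ties broken by code order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(metrics):
        log.warning("k=%d exceeds node count %d; returning all", k,
                    len(metrics))
        k = len(metrics)
    ordered = metrics.sort_values(["code"]).sort_values(
        field, ascending=False, kind="stable")
    return ordered.head(k).reset_index(drop=True)
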