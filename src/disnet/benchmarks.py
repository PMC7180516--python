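"""Calibration and recovery experiments on cohorts with known ground truth.

These are the package's standard self-checks: plant a risk ratio and see the
association stage recover it; simulate fully independent diseases and verify
the independence tests are calibrated; plant a block structure and verify the
community detection finds it. They are used both by the test suite and by the
reproduction script.
"""

from __future__ import annotations

from math import comb

import networkx as nx
import numpy as np
import pandas as pd

from .association import contingency, pair_stats, relative_risk
from .cohort import WindowConfig, build_exposure
from .community import walktrap
from .simulate import DiseaseSpec, PopulationSpec, ProgressionSpec, \
    generate_cohort

__all__ = [
    "rr_recovery_estimates",
    "null_pair_stats",
    "planted_partition_ari",
    "adjusted_rand_index",
]

# planted pairs use common sources (prevalence 0.2, in line with the common
# diagnoses the design targets) and rarer targets (0.02)
_RECOVERY_PAIRS = {2.0: ("A01", "A02"), 5.0: ("B01", "B02"),
                   10.0: ("C01", "C02")}


def _exposures(cohort, windows):
    # benchmark cohorts simulate only the study diseases, so the whole
    # population stands in for "patients with at least one medical visit"
    patients = cohort.demographics.patient_id.values
    obs = build_exposure(cohort.claims, windows.observation, "observation",
                         patients=patients)
    out = build_exposure(cohort.claims, windows.outcome, "outcome",
                         patients=patients, codes=obs.codes)
    return obs, out


def rr_recovery_estimates(seed: int, n_patients: int = 100_000,
                          planted=(2.0, 5.0, 10.0),
                          source_prevalence: float = 0.2,
                          target_prevalence: float = 0.02) -> dict:
    """Estimate the relative risk of each planted progression from one
    simulated cohort; returns {planted_rr: estimated_rr}.

    Diseases carry no age/sex effects so the planted value is the exact
    truth (no demographic confounding).
    """
    windows = WindowConfig()
    pop = PopulationSpec(n_patients=n_patients)
    diseases, progressions = [], []
    for rr in planted:
        src, tgt = _RECOVERY_PAIRS[float(rr)]
        diseases += [DiseaseSpec(src, source_prevalence),
                     DiseaseSpec(tgt, target_prevalence)]
        progressions.append(ProgressionSpec(src, tgt, float(rr)))
    cohort = generate_cohort(pop, diseases, progressions, windows, seed=seed)
    obs, out = _exposures(cohort, windows)
    est = {}
    for pr in progressions:
        t = contingency(pr.source_code, pr.target_code, obs, out)
        est[pr.planted_rr] = relative_risk(t)
    return est


def null_pair_stats(seed: int, n_patients: int = 20_000,
                    n_diseases: int = 20) -> pd.DataFrame:
    """Full ordered-pair statistics for a cohort of mutually independent
    diseases (no planted progressions, no shared demographic effects)."""
    windows = WindowConfig()
    pop = PopulationSpec(n_patients=n_patients)
    prevalences = np.linspace(0.02, 0.3, n_diseases)
    diseases = [DiseaseSpec(f"A{i:02d}", float(p))
                for i, p in enumerate(prevalences)]
    cohort = generate_cohort(pop, diseases, [], windows, seed=seed)
    obs, out = _exposures(cohort, windows)
    return pair_stats(obs, out)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Adjusted Rand index between two labelings of the same items."""
    a = pd.factorize(np.asarray(labels_a))[0]
    b = pd.factorize(np.asarray(labels_b))[0]
    if len(a) != len(b):
        raise ValueError("labelings must have equal length")
    n = len(a)
    ct = pd.crosstab(a, b).to_numpy()
    sum_cells = sum(comb(int(x), 2) for x in ct.ravel())
    sum_rows = sum(comb(int(x), 2) for x in ct.sum(axis=1))
    sum_cols = sum(comb(int(x), 2) for x in ct.sum(axis=0))
    total = comb(n, 2)
    expected = sum_rows * sum_cols / total if total else 0.0
    max_index = (sum_rows + sum_cols) / 2.0
    if max_index == expected:
        return 1.0
    return (sum_cells - expected) / (max_index - expected)


def planted_partition_ari(seed: int, n_blocks: int = 4, block_size: int = 25,
                          p_in: float = 0.3, p_out: float = 0.01,
                          t: int = 4) -> float:
    """Walktrap recovery of a planted-partition random graph, as adjusted
    Rand index against the planted blocks."""
    G = nx.planted_partition_graph(n_blocks, block_size, p_in, p_out,
                                   seed=seed)
    n = n_blocks * block_size
    truth = [v // block_size for v in range(n)]
    result = walktrap(nx.Graph(G), t=t)
    found = [result.partition[v] for v in range(n)]
    return adjusted_rand_index(truth, found)
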