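"""Random-walk community detection, modularity and cluster characterisation.

Communities are found with the walktrap algorithm of Pons & Latapy: short
random walks of length t from each vertex give a probability profile over the
graph; vertices (and, as merging proceeds, communities) whose profiles are
close in a degree-normalised Euclidean metric are agglomerated greedily,
always taking the merge with the smallest increase in mean squared
profile-to-centroid distance. The dendrogram is cut at the partition with
maximum Newman-Girvan modularity. The directed disease network is symmetrised
(edge present if either direction is) and walks are unweighted by default,
so clustering reflects pure connectivity.

Clusters are then characterised two ways: demographically, by pooling every
patient diagnosed with at least one member disease (pools overlap across
clusters by construction), and nosologically, by Fisher-exact enrichment of
the ICD-10/KCD chapter labels among member codes.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass
from datetime import date

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .association import adjust_p
from .cohort import ExposureMatrix
from .icd import icd10_chapter

log = logging.getLogger(__name__)

__all__ = [
    "ClusterResult",
    "ClusterProfile",
    "walktrap",
    "modularity",
    "category_partition",
    "profile_cluster",
    "enrich",
]


@dataclass
class ClusterResult:
    """Outcome of walktrap clustering."""

    partition: dict           # node -> cluster id (0-based, ordered by size)
    merges: list              # sequence of (community_i, community_j) merges
    modularity: float         # Newman Q of the chosen cut
    walk_length: int

    def clusters(self) -> dict:
        """cluster id -> sorted list of member nodes."""
        out: dict = {}
        for node, cid in self.partition.items():
            out.setdefault(cid, []).append(node)
        return {cid: sorted(m) for cid, m in out.items()}


@dataclass
class ClusterProfile:
    """Demographics of the pooled patients of one cluster."""

    cluster_id: int
    codes: list
    pooled_patient_count: int
    n_female: int
    n_male: int
    mean_age: float
    sd_age: float
    male_to_female: float     # the x in a 1:x male:female ratio; inf if no males
    age_histogram: tuple      # counts per (<30, 30-59, >=60)


def _symmetrize(G: nx.Graph | nx.DiGraph, use_weights: bool) -> nx.Graph:
    H = nx.Graph()
    H.add_nodes_from(G.nodes)
    for u, v, data in G.edges(data=True):
        if u == v:
            continue
        w = float(data.get("rr", 1.0)) if use_weights else 1.0
        if H.has_edge(u, v):
            if use_weights:
                H[u][v]["weight"] += w
        else:
            H.add_edge(u, v, weight=w)
    return H


def modularity(G: nx.Graph | nx.DiGraph, partition: dict) -> float:
    """Newman-Girvan modularity of a partition on the symmetrised, unweighted
    graph: Q = sum_c (e_c/m - (d_c/2m)^2)."""
    H = _symmetrize(G, use_weights=False)
    if set(partition) != set(H.nodes):
        raise ValueError("partition must cover every node exactly once")
    m = H.number_of_edges()
    if m == 0:
        raise ValueError("graph has no edges")
    within: dict = {}
    degsum: dict = {}
    for v in H.nodes:
        degsum[partition[v]] = degsum.get(partition[v], 0) + H.degree(v)
    for u, v in H.edges:
        if partition[u] == partition[v]:
            within[partition[u]] = within.get(partition[u], 0) + 1
    q = 0.0
    for c in degsum:
        q += within.get(c, 0) / m - (degsum[c] / (2.0 * m)) ** 2
    return q


def walktrap(G: nx.Graph | nx.DiGraph, t: int = 4,
             use_weights: bool = False) -> ClusterResult:
    """Pons-Latapy walktrap clustering.

    Directed input is symmetrised first. Walk length ``t`` defaults to the
    algorithm's canonical 4. Only adjacent communities are merged, so
    disconnected components are clustered independently; the returned
    partition is the dendrogram cut with maximum modularity (which is also
    evaluated for the initial all-singleton state). Ties in the merge
    criterion are broken on the lowest community index pair, making the
    result deterministic.
    """
    if t < 1:
        raise ValueError("walk length t must be >= 1")
    H = _symmetrize(G, use_weights)
    n = H.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    nodes = sorted(H.nodes)
    index = {v: i for i, v in enumerate(nodes)}

    A = nx.to_numpy_array(H, nodelist=nodes,
                          weight="weight" if use_weights else None)
    deg = A.sum(axis=1)
    # isolated vertices walk in place; they stay singletons regardless
    safe_deg = np.where(deg > 0, deg, 1.0)
    P = A / safe_deg[:, None]
    P[deg == 0] = 0.0
    P[deg == 0, deg == 0] = 1.0
    Pt = np.linalg.matrix_power(P, t)
    inv_sqrt_deg = 1.0 / np.sqrt(safe_deg)

    # community state: profile (mean walk profile of members), size, members
    profiles = {i: Pt[i].copy() for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    members = {i: [i] for i in range(n)}
    neighbors = {i: set() for i in range(n)}
    for u, v in H.edges:
        neighbors[index[u]].add(index[v])
        neighbors[index[v]].add(index[u])

    def delta_sigma(c1: int, c2: int) -> float:
        diff = (profiles[c1] - profiles[c2]) * inv_sqrt_deg
        r2 = float(diff @ diff)
        s1, s2 = sizes[c1], sizes[c2]
        return (s1 * s2) / (s1 + s2) / n * r2

    heap: list = []
    for u in range(n):
        for v in neighbors[u]:
            if u < v:
                heapq.heappush(heap, (delta_sigma(u, v), u, v))

    # record the best-modularity cut along the merge sequence
    current = {i: i for i in range(n)}  # node index -> community id
    best_partition = dict(current)
    best_q = modularity(H, {nodes[i]: c for i, c in current.items()})
    merges = []
    alive = set(range(n))
    next_id = n

    while heap:
        ds, c1, c2 = heapq.heappop(heap)
        if c1 not in alive or c2 not in alive:
            continue
        if abs(ds - delta_sigma(c1, c2)) > 1e-12:
            heapq.heappush(heap, (delta_sigma(c1, c2), c1, c2))
            continue
        cid = next_id
        next_id += 1
        s1, s2 = sizes[c1], sizes[c2]
        profiles[cid] = (s1 * profiles[c1] + s2 * profiles[c2]) / (s1 + s2)
        sizes[cid] = s1 + s2
        members[cid] = members[c1] + members[c2]
        neighbors[cid] = (neighbors[c1] | neighbors[c2]) - {c1, c2}
        for nb in neighbors[cid]:
            neighbors[nb] -= {c1, c2}
            neighbors[nb].add(cid)
            lo, hi = (nb, cid) if nb < cid else (cid, nb)
            heapq.heappush(heap, (delta_sigma(lo, hi), lo, hi))
        alive -= {c1, c2}
        alive.add(cid)
        for prof in (c1, c2):
            del profiles[prof], neighbors[prof]
        merges.append((c1, c2))

        for i in members[cid]:
            current[i] = cid
        q = modularity(H, {nodes[i]: c for i, c in current.items()})
        if q > best_q + 1e-12:
            best_q = q
            best_partition = dict(current)

    # relabel clusters 0..k-1 by decreasing size, ties by smallest member
    groups: dict = {}
    for i, c in best_partition.items():
        groups.setdefault(c, []).append(i)
    ordered = sorted(groups.values(), key=lambda g: (-len(g), min(g)))
    partition = {}
    for cid, group in enumerate(ordered):
        for i in group:
            partition[nodes[i]] = cid
    return ClusterResult(partition=partition, merges=merges,
                         modularity=best_q, walk_length=t)


def category_partition(codes) -> dict:
    """Partition codes by their ICD-10/KCD chapter (see
    :func:`disnet.icd.icd10_chapter`)."""
    out = {}
    for code in codes:
        ch = icd10_chapter(code)
        if ch == "unknown":
            log.warning("code %r maps to no ICD-10 chapter", code)
        out[code] = ch
    return out


def profile_cluster(cluster_id: int, codes, observation: ExposureMatrix,
                    demographics: pd.DataFrame,
                    reference_date: date) -> ClusterProfile:
    """Demographics of the union of patients diagnosed with at least one
    member code in the observation window (ages at ``reference_date``,
    conventionally the start of the observation period)."""
    codes = sorted(codes)
    if not codes:
        raise ValueError("cluster is empty")
    mask = np.zeros(observation.n_patients, dtype=bool)
    for c in codes:
        mask |= observation.column(c)
    pats = observation.patients[mask]
    if len(pats) == 0:
        log.warning("cluster %s has an empty patient pool", cluster_id)
        return ClusterProfile(cluster_id, codes, 0, 0, 0, float("nan"),
                              float("nan"), float("nan"), (0, 0, 0))
    demo = demographics.set_index("patient_id").loc[pats]
    ages = reference_date.year - demo["birth_year"].to_numpy()
    n_f = int((demo["sex"] == "F").sum())
    n_m = int((demo["sex"] == "M").sum())
    ratio = float("inf") if n_m == 0 else n_f / n_m
    hist = (int(np.sum(ages < 30)),
            int(np.sum((ages >= 30) & (ages < 60))),
            int(np.sum(ages >= 60)))
    return ClusterProfile(
        cluster_id=cluster_id,
        codes=codes,
        pooled_patient_count=int(len(pats)),
        n_female=n_f,
        n_male=n_m,
        mean_age=float(ages.mean()),
        sd_age=float(ages.std(ddof=1)) if len(ages) > 1 else 0.0,
        male_to_female=ratio,
        age_histogram=hist,
    )


def enrich(partition: dict, chapters: dict) -> pd.DataFrame:
    """Chapter enrichment per cluster.

    For every (cluster, chapter) pair, a one-sided (over-representation)
    Fisher exact test on the 2x2 membership table of codes, with
    Benjamini-Hochberg adjustment across all tests performed. Returns a
    DataFrame ``cluster chapter a b c d odds_ratio p_raw p_adj``.
    """
    nodes = sorted(partition)
    if set(chapters) < set(nodes):
        raise ValueError("every node needs a chapter label")
    total = len(nodes)
    clusters = sorted(set(partition.values()))
    chaps = sorted({chapters[v] for v in nodes})
    rows = []
    for cl in clusters:
        in_cl = {v for v in nodes if partition[v] == cl}
        for ch in chaps:
            in_ch = {v for v in nodes if chapters[v] == ch}
            a = len(in_cl & in_ch)
            b = len(in_cl - in_ch)
            c = len(in_ch - in_cl)
            d = total - a - b - c
            orx, p = stats.fisher_exact([[a, b], [c, d]],
                                        alternative="greater")
            rows.append((cl, ch, a, b, c, d, float(orx), float(p)))
    out = pd.DataFrame(rows, columns=["cluster", "chapter", "a", "b", "c",
                                      "d", "odds_ratio", "p_raw"])
    out["p_adj"] = adjust_p(out["p_raw"].values, method="bh")
    return out
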