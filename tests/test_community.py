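"""Walktrap clustering, modularity, chapter mapping, profiles, enrichment."""

import itertools
from datetime import date

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from disnet.benchmarks import adjusted_rand_index, planted_partition_ari
from disnet.community import (category_partition, enrich, modularity,
                              profile_cluster, walktrap)
from disnet.icd import icd10_chapter
from tests.conftest import make_exposure


def two_triangles():
    return nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5),
                     (2, 3)])


class TestModularity:
    def test_single_community_is_zero(self):
        G = nx.gnp_random_graph(12, 0.4, seed=0)
        assert modularity(G, {v: 0 for v in G}) == pytest.approx(0.0)

    def test_two_disconnected_triangles_half(self):
        G = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        part = {v: (0 if v < 3 else 1) for v in G}
        assert modularity(G, part) == pytest.approx(0.5)

    def test_singleton_partition_formula(self):
        G = nx.gnp_random_graph(10, 0.5, seed=2)
        m = G.number_of_edges()
        expected = -sum((G.degree(v) / (2 * m)) ** 2 for v in G)
        assert modularity(G, {v: v for v in G}) == pytest.approx(expected)
        assert expected < 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_networkx(self, seed):
        """Cross-check against the independent networkx implementation on
        random graphs and random partitions."""
        rng = np.random.default_rng(seed)
        G = nx.gnp_random_graph(20, 0.2, seed=seed)
        if G.number_of_edges() == 0:
            pytest.skip("empty draw")
        labels = rng.integers(0, 4, 20)
        part = {v: int(labels[v]) for v in G}
        groups = [{v for v in G if part[v] == c} for c in set(labels)]
        expected = nx.community.modularity(G, [g for g in groups if g])
        assert modularity(G, part) == pytest.approx(expected)

    def test_partial_partition_rejected(self):
        G = nx.path_graph(4)
        with pytest.raises(ValueError, match="cover"):
            modularity(G, {0: 0, 1: 0})


class TestWalktrap:
    def test_two_triangles_split(self):
        r = walktrap(two_triangles(), t=4)
        assert sorted(map(sorted, r.clusters().values())) \
            == [[0, 1, 2], [3, 4, 5]]
        assert r.modularity == pytest.approx(modularity(
            two_triangles(), r.partition))

    def test_complete_graph_single_community(self):
        r = walktrap(nx.complete_graph(5))
        assert len(r.clusters()) == 1
        assert r.modularity == pytest.approx(0.0)

    def test_deterministic(self):
        G = nx.gnp_random_graph(30, 0.15, seed=7)
        r1, r2 = walktrap(G), walktrap(G)
        assert r1.partition == r2.partition
        assert r1.merges == r2.merges

    def test_directed_input_symmetrized(self):
        D = nx.DiGraph()
        for u, v in two_triangles().edges:
            D.add_edge(u, v, rr=5.0)
        r = walktrap(D, t=4)
        assert sorted(map(sorted, r.clusters().values())) \
            == [[0, 1, 2], [3, 4, 5]]

    def test_disconnected_components_handled(self):
        G = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        r = walktrap(G)
        assert len(r.clusters()) == 2

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            walktrap(nx.Graph())

    @staticmethod
    def set_partitions(n):
        """All set partitions of range(n) as restricted-growth label
        strings."""
        def rec(prefix, k):
            i = len(prefix)
            if i == n:
                yield tuple(prefix)
                return
            for lab in range(k + 1):
                yield from rec(prefix + [lab], max(k, lab + 1))
        yield from rec([], 0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_q_bounded_by_exhaustive_partition_search(self, seed):
        """On small graphs, walktrap's chosen Q never exceeds the best Q
        over every possible partition."""
        G = nx.gnp_random_graph(6, 0.5, seed=seed)
        if G.number_of_edges() < 2 or not nx.is_connected(G):
            pytest.skip("degenerate draw")
        r = walktrap(G)
        nodes = sorted(G.nodes)
        best = max(
            modularity(G, dict(zip(nodes, labels)))
            for labels in self.set_partitions(6)
        )
        assert r.modularity <= best + 1e-12

    def test_planted_partition_recovery(self):
        aris = [planted_partition_ari(seed) for seed in range(10)]
        assert np.mean(aris) >= 0.9

    def test_agrees_with_igraph(self):
        """Independent cross-check: igraph's walktrap finds a partition with
        the same modularity on the planted benchmark."""
        igraph = pytest.importorskip("igraph")
        G = nx.planted_partition_graph(4, 25, 0.3, 0.01, seed=5)
        G = nx.Graph(G)
        r = walktrap(G, t=4)
        g = igraph.Graph.from_networkx(G)
        theirs = g.community_walktrap(steps=4).as_clustering()
        mine = [r.partition[v] for v in range(100)]
        assert adjusted_rand_index(mine, theirs.membership) \
            == pytest.approx(1.0)
        assert r.modularity == pytest.approx(theirs.modularity, abs=1e-9)


class TestCategoryPartition:
    @pytest.mark.parametrize("code,chapter", [
        ("J20", "X"), ("H25", "VII"), ("H60", "VIII"), ("A09", "I"),
        ("B99", "I"), ("C50", "II"), ("D48", "II"), ("D50", "III"),
        ("E11", "IV"), ("F31", "V"), ("G20", "VI"), ("I10", "IX"),
        ("K29", "XI"), ("L22", "XII"), ("M48", "XIII"), ("N18", "XIV"),
        ("O24", "XV"), ("P59", "XVI"), ("Q90", "XVII"), ("R80", "XVIII"),
        ("S32", "XIX"), ("T10", "XIX"), ("V01", "XX"), ("Y99", "XX"),
        ("Z00", "XXI"), ("U22", "KR"),
    ])
    def test_chapter_blocks(self, code, chapter):
        assert icd10_chapter(code) == chapter

    def test_unmappable_warns(self, caplog):
        with caplog.at_level("WARNING"):
            part = category_partition(["J20", "??9"])
        assert part["J20"] == "X" and part["??9"] == "unknown"


class TestProfileCluster:
    def make_pool(self):
        patients = [1, 2, 3]
        codes = ["A00", "B00"]
        # A00 and B00 share exactly the same patients {1, 2}
        obs = make_exposure("observation", patients, codes,
                            [[1, 1], [1, 1], [0, 0]])
        demo = pd.DataFrame({"patient_id": patients,
                             "sex": ["F", "F", "M"],
                             "birth_year": [1980, 1960, 1990]})
        return obs, demo

    def test_pool_is_union_not_sum(self):
        obs, demo = self.make_pool()
        p = profile_cluster(0, ["A00", "B00"], obs, demo, date(2002, 1, 1))
        assert p.pooled_patient_count == 2

    def test_all_female_ratio_infinite(self):
        obs, demo = self.make_pool()
        p = profile_cluster(0, ["A00"], obs, demo, date(2002, 1, 1))
        assert p.n_male == 0 and p.male_to_female == float("inf")

    def test_recovers_planted_cluster_age(self, windows):
        """A simulated women's cluster yields pooled mean age within 1 year
        of the generator's stratum expectation at n=10,000."""
        from disnet.cohort import build_exposure
        from disnet.simulate import (DiseaseSpec, PopulationSpec,
                                     generate_cohort)
        pop = PopulationSpec(n_patients=10_000)
        repro = (0.0, 1.0, 0.0)  # only the 30-59 band is affected
        diseases = [DiseaseSpec("N91", 0.3, repro, 5.0),
                    DiseaseSpec("N76", 0.3, repro, 5.0)]
        cohort = generate_cohort(pop, diseases, [], windows, seed=2)
        obs = build_exposure(cohort.claims, windows.observation,
                             "observation")
        p = profile_cluster(0, ["N91", "N76"], obs, cohort.demographics,
                            windows.observation_start)
        assert abs(p.mean_age - 44.5) < 1.0   # uniform over 30..59
        assert p.male_to_female > 1.5

    def test_empty_cluster_rejected(self):
        obs, demo = self.make_pool()
        with pytest.raises(ValueError):
            profile_cluster(0, [], obs, demo, date(2002, 1, 1))


class TestEnrich:
    def test_pure_chapter_cluster_minimal_p(self):
        codes = [f"J{i:02d}" for i in range(6)] + \
            [f"K{i:02d}" for i in range(6)]
        partition = {c: (0 if c.startswith("J") else 1) for c in codes}
        chapters = category_partition(codes)
        res = enrich(partition, chapters)
        c0 = res[res.cluster == 0].set_index("chapter")
        assert c0.p_raw.idxmin() == "X"
        assert c0.loc["X", "p_raw"] == pytest.approx(1 / 924)  # C(12,6)^-1
        assert (res.p_adj >= res.p_raw - 1e-12).all()

    def test_singleton_cluster_powerless(self):
        codes = ["J20", "K29", "K30", "K31"]
        partition = {"J20": 0, "K29": 1, "K30": 1, "K31": 1}
        res = enrich(partition, category_partition(codes))
        assert (res[res.cluster == 0].p_adj >= 0.05).all()

    def test_uniform_assignment_calibrated(self):
        """With random chapter labels, ~5% of tests are raw-significant."""
        rng = np.random.default_rng(0)
        codes = [f"A{i:02d}" for i in range(40)]
        sig = 0
        n_tests = 0
        for rep in range(30):
            partition = {c: int(rng.integers(0, 4)) for c in codes}
            chapters = {c: f"ch{rng.integers(0, 5)}" for c in codes}
            res = enrich(partition, chapters)
            sig += int((res.p_raw < 0.05).sum())
            n_tests += len(res)
        assert sig / n_tests < 0.10  # one-sided discrete test is conservative
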