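"""Hit classification against a sort-and-filter oracle; module detection
against a flood-fill component oracle."""

import numpy as np
import pytest

from ecomics.eclass import (
    ModuleSet,
    assign_queries,
    best_hits,
    build_similarity_graph,
    modularize,
    summarize_composition,
)
from ecomics.fixtures import gen_hit_table, gen_similarity_graph
from ecomics.io_formats import HitRecord, HitTable, TaxonomyTable

import networkx as nx


def oracle_best_hits(hits, e_threshold):
    """Brute force: per query, sort passing hits by the tie rules."""
    by_query = {}
    for rec in hits:
        by_query.setdefault(rec.query_id, []).append(rec)
    out = {}
    for qid, recs in by_query.items():
        passing = [r for r in recs if r.e_value <= e_threshold]
        if passing:
            out[qid] = sorted(passing, key=lambda r: (r.e_value, -r.bit_score, r.subject_id))[0]
    return out


def oracle_components(graph):
    """Flood-fill connected components."""
    seen, comps = set(), []
    for start in graph.nodes:
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            v = stack.pop()
            if v in comp:
                continue
            comp.add(v)
            stack.extend(graph.neighbors(v))
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)


def _lineage(phylum, **kw):
    base = dict(domain="Bacteria", phylum=phylum, **{
        r: kw.get(r, "unclassified") for r in ("class", "order", "family")
    })
    return {k: base[k] for k in ("domain", "phylum", "class", "order", "family")}


class TestAssignQueries:
    def test_six_query_phylum_toy(self):
        """Six DGGE-band queries classify 3:1:1:1 to Proteobacteria,
        Cyanobacteria, Planctomycetes and Bacteroidetes."""
        hits, taxa = gen_hit_table(
            {"Proteobacteria": 3, "Cyanobacteria": 1, "Planctomycetes": 1, "Bacteroidetes": 1},
            seed=0,
        )
        assigned = assign_queries(hits, taxa, 1e-50, "phylum")
        summary = summarize_composition(assigned)
        assert summary.counts == {
            "Proteobacteria": 3,
            "Cyanobacteria": 1,
            "Planctomycetes": 1,
            "Bacteroidetes": 1,
        }

    def test_threshold_boundary(self):
        hits = HitTable([HitRecord("q1", "s1", 99.0, 100, 1e-40, 300.0)])
        taxa = TaxonomyTable(lineages={"s1": _lineage("Proteobacteria")})
        (q,) = assign_queries(hits, taxa, 1e-50, "phylum")
        assert not q.assigned and q.labels == ("unassigned",)
        (q,) = assign_queries(hits, taxa, 1e-40, "phylum")  # <= passes
        assert q.assigned and q.label == "Proteobacteria"

    def test_tie_rules_evalue_bitscore_subject(self):
        hits = HitTable(
            [
                HitRecord("q", "z_low_bits", 99.0, 100, 1e-60, 100.0),
                HitRecord("q", "a_high_bits", 99.0, 100, 1e-60, 200.0),
                HitRecord("q", "better_e", 99.0, 100, 1e-70, 50.0),
            ]
        )
        best = best_hits(hits, 1.0)
        assert best["q"].subject_id == "better_e"  # lowest E wins outright
        hits2 = HitTable(hits.records[:2])
        assert best_hits(hits2, 1.0)["q"].subject_id == "a_high_bits"

    def test_missing_metadata_warns_unclassified(self):
        hits = HitTable([HitRecord("q1", "mystery", 99.0, 100, 1e-80, 300.0)])
        with pytest.warns(UserWarning, match="mystery"):
            (q,) = assign_queries(hits, TaxonomyTable(), 1e-50, "phylum")
        assert q.label == "unclassified"

    def test_rank_truncation_and_missing_rank(self):
        taxa = TaxonomyTable(lineages={"s": _lineage("Proteobacteria", **{"class": "Gamma"})})
        hits = HitTable([HitRecord("q", "s", 99.0, 100, 1e-80, 300.0)])
        assert assign_queries(hits, taxa, 1e-50, "class")[0].label == "Gamma"
        assert assign_queries(hits, taxa, 1e-50, "family")[0].label == "unclassified"

    def test_cbm_rank_multi_domain(self):
        taxa = TaxonomyTable(cbm_families={"s": ("CBM2", "CBM6")})
        hits = HitTable([HitRecord("q", "s", 99.0, 100, 1e-80, 300.0)])
        (q,) = assign_queries(hits, taxa, 1e-50, "CBM")
        assert q.labels == ("CBM2", "CBM6")
        summary = summarize_composition([q], rank="CBM")
        assert summary.counts == {"CBM2": 1, "CBM6": 1}  # once per distinct family

    def test_unknown_rank_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            assign_queries(HitTable([]), TaxonomyTable(), 1e-50, "genus")

    def test_fasta_query_roster_adds_unassigned(self):
        hits = HitTable([HitRecord("q1", "s", 99.0, 100, 1e-80, 300.0)])
        taxa = TaxonomyTable(lineages={"s": _lineage("Proteobacteria")})
        assigned = assign_queries(hits, taxa, 1e-50, "phylum", query_ids=["q1", "q2"])
        assert [q.assigned for q in assigned] == [True, False]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sort_and_filter_oracle(self, seed):
        rng = np.random.default_rng(seed)
        records = [
            HitRecord(
                f"q{rng.integers(0, 8)}",
                f"s{rng.integers(0, 10)}",
                90.0,
                100,
                float(10.0 ** rng.uniform(-80, 0)),
                float(rng.uniform(50, 500)),
            )
            for _ in range(60)
        ]
        hits = HitTable(records)
        thr = float(10.0 ** rng.uniform(-60, -5))
        expect = oracle_best_hits(hits, thr)
        got = best_hits(hits, thr)
        assert {q: (r.subject_id, r.e_value) for q, r in got.items()} == {
            q: (r.subject_id, r.e_value) for q, r in expect.items()
        }

    @pytest.mark.parametrize("seed", range(3))
    def test_threshold_monotonicity(self, seed):
        hits, taxa = gen_hit_table({"Proteobacteria": 5, "Bacteroidetes": 5}, seed=seed)
        counts = []
        for thr in (1e-120, 1e-80, 1e-40, 1.0):
            assigned = assign_queries(hits, taxa, thr, "phylum")
            counts.append(sum(q.assigned for q in assigned))
        assert counts == sorted(counts)  # weaker filter never assigns fewer


class TestSummarize:
    def test_six_query_fractions(self):
        hits, taxa = gen_hit_table(
            {"Proteobacteria": 3, "Cyanobacteria": 1, "Planctomycetes": 1, "Bacteroidetes": 1},
            seed=1,
        )
        summary = summarize_composition(assign_queries(hits, taxa, 1e-50, "phylum"))
        fr = summary.fractions()
        assert fr["Proteobacteria"] == pytest.approx(0.5)
        for other in ("Cyanobacteria", "Planctomycetes", "Bacteroidetes"):
            assert fr[other] == pytest.approx(1 / 6)
        assert sum(fr.values()) == pytest.approx(1.0, abs=1e-12)

    def test_all_unassigned_single_slice(self):
        hits = HitTable([HitRecord("q1", "s", 99.0, 100, 1e-10, 300.0)])
        assigned = assign_queries(hits, TaxonomyTable(), 1e-50, "phylum", query_ids=["q1", "q2"])
        summary = summarize_composition(assigned)
        assert summary.counts == {"unassigned": 2}
        assert summary.fractions()["unassigned"] == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_composition([])

    @pytest.mark.parametrize("seed", range(5))
    def test_counts_sum_to_total(self, seed):
        rng = np.random.default_rng(seed)
        comp = {f"Phylum{i}": int(rng.integers(0, 6)) for i in range(5)}
        hits, taxa = gen_hit_table(comp, seed=seed)
        assigned = assign_queries(hits, taxa, 1e-50, "phylum")
        if not assigned:
            return
        summary = summarize_composition(assigned)
        assert sum(summary.counts.values()) == summary.total_queries

    def test_ordering_count_desc_then_alpha(self):
        summary = summarize_composition(
            [
                *([_cq("Beta")] * 2),
                *([_cq("Alpha")] * 2),
                _cq("Gamma"),
            ]
        )
        assert summary.ordered_labels() == ["Alpha", "Beta", "Gamma"]


def _cq(label):
    from ecomics.eclass import ClassifiedQuery

    _cq.counter = getattr(_cq, "counter", 0) + 1
    return ClassifiedQuery(f"q{_cq.counter}", "s", 1e-80, (label,))


class TestSimilarityGraph:
    def test_dedupe_and_self_loop_removal(self):
        hits = HitTable(
            [
                HitRecord("a", "b", 99.0, 100, 1e-80, 300.0),
                HitRecord("b", "a", 99.0, 100, 1e-70, 280.0),
                HitRecord("a", "a", 100.0, 100, 0.0, 400.0),
            ]
        )
        g = build_similarity_graph(hits, 1e-50)
        assert set(g.edges) == {("a", "b")} or set(g.edges) == {("b", "a")}
        assert not any(u == v for u, v in g.edges)

    def test_threshold_below_all_gives_singletons(self):
        hits = HitTable(
            [
                HitRecord("a", "b", 99.0, 100, 1e-20, 300.0),
                HitRecord("b", "c", 99.0, 100, 1e-25, 300.0),
            ]
        )
        g = build_similarity_graph(hits, 1e-50)
        mods = modularize(g)
        assert mods.n_modules == 3
        assert all(len(m) == 1 for m in mods.modules)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        names = [f"n{i}" for i in range(12)]
        records = [
            HitRecord(
                str(rng.choice(names)), str(rng.choice(names)), 90.0, 100,
                float(10.0 ** rng.uniform(-60, 0)), 100.0,
            )
            for _ in range(50)
        ]
        thr = 1e-30
        g = build_similarity_graph(HitTable(records), thr)
        expect = set()
        for r in records:
            if r.e_value <= thr and r.query_id != r.subject_id:
                expect.add(frozenset((r.query_id, r.subject_id)))
        assert {frozenset(e) for e in g.edges} == expect


class TestModularize:
    def test_path_representative_is_middle(self):
        g = nx.Graph([("A", "B"), ("B", "C")])
        mods = modularize(g)
        assert mods.n_modules == 1
        assert mods.representatives == ["B"]

    def test_triangle_tie_break_plus_singleton(self):
        g = nx.Graph([("A", "B"), ("B", "C"), ("A", "C")])
        g.add_node("D")
        mods = modularize(g)
        assert mods.n_modules == 2
        assert set(mods.representatives) == {"A", "D"}  # 3-way degree tie -> lexicographic

    def test_reduction_ratio(self):
        g, _ = gen_similarity_graph([4, 3, 2, 1], seed=0)
        mods = modularize(g)
        assert mods.n_modules == 4
        assert mods.reduction_ratio == pytest.approx(4 / 10)

    def test_order_invariance(self):
        g, _ = gen_similarity_graph([5, 4, 3], extra_edge_prob=0.3, seed=3)
        h = nx.Graph()
        h.add_nodes_from(sorted(g.nodes, reverse=True))
        h.add_edges_from(sorted(g.edges, reverse=True))
        assert modularize(g).canonical() == modularize(h).canonical()

    @pytest.mark.parametrize("seed", range(10))
    def test_components_match_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(20, 0.08, seed=int(rng.integers(0, 2**31)))
        g = nx.relabel_nodes(g, {i: f"v{i:02d}" for i in g.nodes})
        mods = modularize(g)
        assert set(mods.modules) == oracle_components(g)
        # partition: disjoint cover of all nodes
        assert mods.n_nodes == g.number_of_nodes()

    def test_planted_module_recovery(self):
        g, truth = gen_similarity_graph([5, 3, 1], hub_per_module=True, seed=7)
        mods = modularize(g)
        assert mods.canonical() == truth.canonical()

    def test_representative_must_be_member(self):
        with pytest.raises(ValueError, match="member"):
            ModuleSet([frozenset({"a", "b"})], ["c"])
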