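"""Ontology handling, annotation propagation and the three GO flavours."""

import math

import networkx as nx
import numpy as np
import pytest

from prionnet.datasets import ProteinSet
from prionnet.enrichment import hypergeom_upper
from prionnet.go import (
    GODag,
    TermResult,
    cross_reference,
    high_membership_report,
    interaction_go_enrichment,
    membership_enrichment,
    propagate,
    protein_term_pairs,
    read_annotations,
    read_ontology,
)
from prionnet.network import InteractionNetwork
from prionnet.synthetic import SynthConfig, gen_ontology


def make_dag(edges, namespace="biological_process"):
    g = nx.MultiDiGraph()
    terms = {t for e in edges for t in e}
    for t in terms:
        g.add_node(t, name=t, namespace=namespace)
    for child, parent in edges:
        g.add_edge(child, parent, key="is_a")
    return GODag(g)


CHAIN = [("GO:C", "GO:M"), ("GO:M", "GO:R")]


def write_gaf_rows(path, rows):
    lines = ["!gaf-version: 2.1"]
    for acc, term, qualifier, aspect in rows:
        cols = [
            "UniProtKB", acc, acc, qualifier, term, "PMID:1", "IDA", "",
            aspect, "", "", "protein", "taxon:4932", "20140101", "SYN", "", "",
        ]
        lines.append("\t".join(cols))
    path.write_text("\n".join(lines) + "\n")


class TestOntologyAndAnnotations:
    def test_chain_propagation(self):
        dag = make_dag(CHAIN)
        annot = propagate({"P1": {"GO:C"}}, dag)
        assert annot.terms_of("P1") == {"GO:C", "GO:M", "GO:R"}

    def test_propagation_idempotent(self):
        dag = make_dag(CHAIN)
        once = propagate({"P1": {"GO:C"}}, dag)
        twice = propagate(once.propagated, dag)
        assert once.propagated == twice.propagated

    def test_not_qualifier_dropped(self, tmp_path):
        dag = make_dag(CHAIN)
        gaf = tmp_path / "t.gaf"
        write_gaf_rows(gaf, [("P1", "GO:C", "NOT", "P"), ("P2", "GO:C", "", "P")])
        annot = read_annotations(gaf, dag)
        assert "P1" not in annot.direct and annot.terms_of("P2") == {"GO:C", "GO:M", "GO:R"}

    def test_non_bp_aspect_dropped(self, tmp_path):
        dag = make_dag(CHAIN)
        gaf = tmp_path / "t.gaf"
        write_gaf_rows(gaf, [("P1", "GO:C", "", "F")])
        assert read_annotations(gaf, dag).direct == {}

    def test_unknown_term_skipped_with_warning(self, tmp_path, caplog):
        dag = make_dag(CHAIN)
        gaf = tmp_path / "t.gaf"
        write_gaf_rows(gaf, [("P1", "GO:UNKNOWN", "", "P"), ("P1", "GO:M", "", "P")])
        annot = read_annotations(gaf, dag)
        assert annot.terms_of("P1") == {"GO:M", "GO:R"}

    def test_cyclic_ontology_rejected(self):
        with pytest.raises(ValueError, match="cyclic"):
            make_dag([("GO:A", "GO:B"), ("GO:B", "GO:A")])

    def test_ancestor_closure_matches_reachability_oracle(self):
        cfg = SynthConfig(n_go_terms=50, dag_depth=5, seed=11)
        onto = gen_ontology(cfg)
        dag = make_dag(
            [(t, p) for t, p in onto.parents.items() if p is not None]
        )
        # independent oracle: boolean matrix closure by repeated squaring
        terms = sorted(dag.terms)
        idx = {t: i for i, t in enumerate(terms)}
        A = np.zeros((len(terms), len(terms)), dtype=bool)
        for t, p in onto.parents.items():
            if p is not None:
                A[idx[t], idx[p]] = True
        reach = A.copy()
        for _ in range(int(math.ceil(math.log2(len(terms))))):
            reach = reach | (reach @ reach)
        for t in terms:
            assert dag.ancestors(t) == {u for u in terms if reach[idx[t], idx[u]]}

    def test_obo_round_trip(self, tmp_path):
        onto = gen_ontology(SynthConfig(n_go_terms=25, seed=3))
        path = tmp_path / "mini.obo"
        onto.to_obo(path)
        dag = read_ontology(path)
        assert dag.terms == set(onto.terms)
        child = onto.terms[-1]
        expected = set()
        cursor = onto.parents[child]
        while cursor is not None:
            expected.add(cursor)
            cursor = onto.parents[cursor]
        assert dag.ancestors(child) == expected


class TestMembershipEnrichment:
    def test_fully_captured_term(self):
        dag = make_dag(CHAIN)
        universe = [f"P{i}" for i in range(100)]
        annotated = universe[:10]
        annot = propagate({p: {"GO:C"} for p in annotated}, dag)
        sample = ProteinSet("S", set(annotated))
        results = membership_enrichment(sample, annot, universe, dag)
        by_term = {r.term: r for r in results}
        c = by_term["GO:C"].counts
        assert (c.N, c.K, c.n, c.k) == (100, 10, 10, 10)
        expected = hypergeom_upper(c)
        assert by_term["GO:C"].p_raw == pytest.approx(expected)
        assert expected == pytest.approx(1 / math.comb(100, 10), rel=1e-9)
        assert by_term["GO:C"].significant

    def test_term_absent_from_sample_has_p_one(self):
        dag = make_dag(CHAIN)
        universe = [f"P{i}" for i in range(20)]
        annot = propagate({"P0": {"GO:C"}, "P1": {"GO:C"}}, dag)
        results = membership_enrichment(ProteinSet("S", {"P5", "P6"}), annot, universe, dag)
        assert all(r.p_raw == 1.0 for r in results)

    def test_saturating_sample(self):
        dag = make_dag(CHAIN)
        universe = [f"P{i}" for i in range(10)]
        annot = propagate({p: {"GO:C"} for p in universe[:4]}, dag)
        results = membership_enrichment(ProteinSet("S", set(universe)), annot, universe, dag)
        assert all(r.counts.k == r.counts.K and r.p_raw == 1.0 for r in results)

    def test_empty_sample(self):
        dag = make_dag(CHAIN)
        annot = propagate({"P0": {"GO:C"}}, dag)
        results = membership_enrichment(ProteinSet("S", set()), annot, ["P0", "P1"], dag)
        assert all(r.counts.k == 0 for r in results)

    def test_singleton_terms_skipped(self):
        dag = make_dag(CHAIN)
        annot = propagate({"P0": {"GO:C"}}, dag)
        results = membership_enrichment(
            ProteinSet("S", {"P0"}), annot, ["P0", "P1", "P2"], dag
        )
        assert results == []


class TestHighMembership:
    def _results(self, sample, annot, universe, dag):
        return membership_enrichment(sample, annot, universe, dag)

    def test_fraction_filter(self):
        dag = make_dag(CHAIN)
        universe = [f"P{i}" for i in range(40)]
        # GO:C annotates 4 proteins, 3 in the sample -> fraction 0.75
        annot = propagate({p: {"GO:C"} for p in ("P0", "P1", "P2", "P3")}, dag)
        sample = ProteinSet("S", {"P0", "P1", "P2"})
        results = self._results(sample, annot, universe, dag)
        records = high_membership_report(results, sample, annot, dag, universe, max_p=None)
        rec = next(r for r in records if r.term == "GO:C")
        assert rec.fraction == pytest.approx(0.75) and rec.set_count == 3

    def _nested_setup(self, child_extra_protein=False):
        dag = make_dag([("GO:child", "GO:parent")])
        universe = [f"P{i}" for i in range(50)]
        members = {"P0", "P1", "P2"}
        direct = {p: {"GO:child"} for p in members}
        if child_extra_protein:
            # parent annotates one extra universe protein, so the child's
            # annotated-member list equals the parent's but its K is
            # smaller -> child P strictly lower
            direct["P40"] = {"GO:parent"}
        annot = propagate(direct, dag)
        sample = ProteinSet("S", members)
        results = self._results(sample, annot, universe, dag)
        return dag, annot, sample, universe, results

    def test_collapse_keeps_more_specific_lower_p(self):
        dag, annot, sample, universe, results = self._nested_setup(True)
        records = high_membership_report(results, sample, annot, dag, universe, max_p=None)
        terms = {r.term for r in records}
        assert terms == {"GO:child"}

    def test_identical_p_keeps_both(self):
        # without the extra parent annotation both terms have identical
        # protein lists AND identical P-values: the collapse rule's
        # "lower P" condition fails, so both are retained
        dag, annot, sample, universe, results = self._nested_setup(False)
        records = high_membership_report(results, sample, annot, dag, universe, max_p=None)
        assert {r.term for r in records} == {"GO:child", "GO:parent"}


class TestInteractionGO:
    def test_shared_term_partners_deduplicate(self):
        dag = make_dag(CHAIN)
        net = InteractionNetwork([("A", "B"), ("A", "C")])
        annot = propagate({"B": {"GO:C"}, "C": {"GO:C"}}, dag)
        pairs = protein_term_pairs(net, annot)
        assert pairs["A"] == {"GO:C", "GO:M", "GO:R"}

    def test_empty_network(self):
        dag = make_dag(CHAIN)
        annot = propagate({"B": {"GO:C"}}, dag)
        assert interaction_go_enrichment(InteractionNetwork(), ProteinSet("S", {"A"}), annot) == []

    def test_counts_match_brute_force(self):
        dag = make_dag([("GO:T1", "GO:R"), ("GO:T2", "GO:R"), ("GO:T3", "GO:R")])
        net = InteractionNetwork(
            [("A", "B"), ("A", "C"), ("B", "C"), ("C", "D"), ("D", "E"), ("E", "F")]
        )
        direct = {
            "A": {"GO:T1"}, "B": {"GO:T1", "GO:T2"}, "C": {"GO:T3"},
            "D": {"GO:T2"}, "F": {"GO:T1"},
        }
        annot = propagate(direct, dag)
        sample = ProteinSet("S", {"A", "D"})
        results = interaction_go_enrichment(net, sample, annot, dag)
        # brute force pair construction
        pairs = []
        for prot in net.proteins:
            terms = set()
            for partner in net.interactors(prot):
                terms |= annot.terms_of(partner)
            pairs.extend((prot, t) for t in terms)
        N = len(pairs)
        n = sum(1 for p, _ in pairs if p in sample)
        for r in results:
            K = sum(1 for _, t in pairs if t == r.term)
            k = sum(1 for p, t in pairs if t == r.term and p in sample)
            assert (r.counts.N, r.counts.K, r.counts.n, r.counts.k) == (N, K, n, k)
            assert r.counts.k <= r.counts.n and r.counts.k <= r.counts.K

    def test_duplicate_evidence_invariance(self, tmp_path):
        from prionnet.network import read_mitab

        def mitab_line(a, b):
            return "\t".join(
                [f"uniprotkb:{a}", f"uniprotkb:{b}"] + ["-"] * 13
            )

        dag = make_dag(CHAIN)
        annot = propagate({"B": {"GO:C"}}, dag)
        p1 = tmp_path / "once.mitab"
        p1.write_text(mitab_line("A", "B") + "\n")
        p2 = tmp_path / "dup.mitab"
        p2.write_text((mitab_line("A", "B") + "\n") * 3 + mitab_line("B", "A") + "\n")
        r1 = interaction_go_enrichment(read_mitab(p1), ProteinSet("S", {"A"}), annot)
        r2 = interaction_go_enrichment(read_mitab(p2), ProteinSet("S", {"A"}), annot)
        assert [(r.term, r.counts) for r in r1] == [(r.term, r.counts) for r in r2]


class TestCrossReference:
    def _res(self, term, sig):
        from prionnet.enrichment import ContingencyCounts

        return TermResult(
            term, term, ContingencyCounts(10, 2, 2, 1), 0.5, -0.3, significant=sig
        )

    def test_disjoint_significant_sets(self):
        a = [self._res("GO:1", True)]
        b = [self._res("GO:2", True)]
        c = [self._res("GO:3", True)]
        assert cross_reference(a, b, c) == set()

    def test_shared_term_found(self):
        a = [self._res("GO:1", True), self._res("GO:2", True)]
        b = [self._res("GO:1", True), self._res("GO:3", False)]
        c = [self._res("GO:1", True)]
        assert cross_reference(a, b, c) == {"GO:1"}

    def test_matches_triple_loop(self, rng):
        terms = [f"GO:{i}" for i in range(30)]
        lists = []
        for _ in range(3):
            lists.append(
                [self._res(t, bool(rng.random() < 0.4)) for t in rng.choice(terms, 15, replace=False)]
            )
        expected = set()
        for ra in lists[0]:
            for rb in lists[1]:
                for rc in lists[2]:
                    if (
                        ra.term == rb.term == rc.term
                        and ra.significant and rb.significant and rc.significant
                    ):
                        expected.add(ra.term)
        assert cross_reference(*lists) == expected
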