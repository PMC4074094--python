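"""Gene Ontology biological-process enrichment in three flavours.

1. Set membership: per-term hypergeometric test of a protein set against
   the proteome universe.
2. High membership: significant terms ranked by how many of their
   annotated yeast proteins fall in the examined set (fraction >= 0.5),
   collapsed to the most specific term when nested terms are driven by
   the identical protein list and the specific term's P is lower.
3. Interaction-based: interactions are deduplicated to protein<->term
   pairs (a protein interacting with two partners annotated to the same
   term yields one pair), then tested with pair-level counts.

The ontology graph is parsed with ``obonet``; annotations (GAF 2.x) with
Biopython.  Annotations are propagated to all ancestors before counting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet
from Bio.UniProt import GOA

from .datasets import ProteinSet, strip_isoform
from .enrichment import ContingencyCounts, holm_bonferroni, hypergeom_log_upper
from .network import InteractionNetwork

logger = logging.getLogger(__name__)

BIOLOGICAL_PROCESS = "biological_process"


class GODag:
    """Biological-process slice of the GO graph with ancestor closure."""

    def __init__(self, graph: nx.MultiDiGraph, part_of: bool = True):
        keys = {"is_a", "part_of"} if part_of else {"is_a"}
        g = nx.DiGraph()
        for term, data in graph.nodes(data=True):
            if data.get("namespace", BIOLOGICAL_PROCESS) == BIOLOGICAL_PROCESS:
                g.add_node(term, name=data.get("name", term))
        for child, parent, key in graph.edges(keys=True):
            if key in keys and child in g and parent in g:
                g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ontology graph is cyclic")
        self.graph = g
        self._ancestors: dict[str, frozenset[str]] = {}

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def name(self, term: str) -> str:
        return self.graph.nodes[term].get("name", term)

    def ancestors(self, term: str) -> frozenset[str]:
        """All (strict) ancestors reachable via is_a / part_of."""
        if term not in self._ancestors:
            self._ancestors[term] = frozenset(nx.descendants(self.graph, term))
        return self._ancestors[term]

    def is_ancestor(self, ancestor: str, descendant: str) -> bool:
        return ancestor in self.ancestors(descendant)


def read_ontology(path: str | Path, part_of: bool = True) -> GODag:
    return GODag(obonet.read_obo(str(path)), part_of=part_of)


@dataclass
class GOAnnotations:
    """Direct and ancestor-propagated biological-process annotations."""

    direct: dict[str, frozenset[str]]
    propagated: dict[str, frozenset[str]]

    def terms_of(self, accession: str) -> frozenset[str]:
        return self.propagated.get(accession, frozenset())

    @property
    def annotated_terms(self) -> set[str]:
        out: set[str] = set()
        for terms in self.propagated.values():
            out |= terms
        return out


def propagate(direct: Mapping[str, Iterable[str]], dag: GODag) -> GOAnnotations:
    """Close annotations over ancestry; idempotent by construction."""
    d = {acc: frozenset(terms) for acc, terms in direct.items() if terms}
    prop = {
        acc: frozenset(set(terms).union(*(dag.ancestors(t) for t in terms)))
        for acc, terms in d.items()
    }
    return GOAnnotations(direct=d, propagated=prop)


def read_annotations(path: str | Path, dag: GODag) -> GOAnnotations:
    """Read a GAF 2.x file, keep biological-process rows, drop NOT rows."""
    direct: dict[str, set[str]] = {}
    skipped_unknown = 0
    with open(path) as fh:
        for rec in GOA.gafiterator(fh):
            if "NOT" in rec.get("Qualifier", []):
                continue
            if rec.get("Aspect") != "P":
                continue
            term = rec["GO_ID"]
            if term not in dag:
                skipped_unknown += 1
                continue
            acc = strip_isoform(rec["DB_Object_ID"])
            direct.setdefault(acc, set()).add(term)
    if skipped_unknown:
        logger.warning("skipped %d annotations to unknown terms", skipped_unknown)
    return propagate(direct, dag)


# ---------------------------------------------------------------------------
# enrichment flavours


@dataclass
class TermResult:
    term: str
    name: str
    counts: ContingencyCounts
    p_raw: float
    log10_p: float
    significant: bool | None = None


def _finish(results: list[TermResult], alpha: float, correct: bool) -> list[TermResult]:
    if correct and results:
        flags = holm_bonferroni([r.p_raw for r in results], alpha)
        for r, f in zip(results, flags):
            r.significant = f
    results.sort(key=lambda r: (r.log10_p, r.term))
    return results


def membership_enrichment(
    sample: ProteinSet,
    annot: GOAnnotations,
    universe: Iterable[str],
    dag: GODag | None = None,
    alpha: float = 0.05,
    min_annotated: int = 2,
    correct: bool = True,
) -> list[TermResult]:
    """Per-term membership enrichment of a protein set in the universe.

    N = universe size, K = proteins annotated with the term, n = sample
    size, k = annotated sample members; upper-tail hypergeometric with a
    Holm-Bonferroni family over all tested terms.  Terms annotating
    fewer than ``min_annotated`` universe proteins are skipped.
    """
    universe = set(universe)
    members = sample.members & universe
    by_term: dict[str, set[str]] = {}
    for acc in universe:
        for t in annot.terms_of(acc):
            by_term.setdefault(t, set()).add(acc)
    results = []
    for term in sorted(by_term):
        annotated = by_term[term]
        if len(annotated) < min_annotated:
            continue
        c = ContingencyCounts(
            len(universe), len(annotated), len(members), len(annotated & members)
        )
        logp = hypergeom_log_upper(c)
        results.append(
            TermResult(
                term=term,
                name=dag.name(term) if dag else term,
                counts=c,
                p_raw=math.exp(logp) or 5e-324,
                log10_p=logp / math.log(10),
            )
        )
    return _finish(results, alpha, correct)


@dataclass
class HighMembershipRecord:
    term: str
    name: str
    yeast_count: int
    set_count: int
    fraction: float
    p_raw: float
    passes_correction: bool


def high_membership_report(
    results: Sequence[TermResult],
    sample: ProteinSet,
    annot: GOAnnotations,
    dag: GODag,
    universe: Iterable[str],
    min_fraction: float = 0.5,
    max_p: float | None = 1e-4,
) -> list[HighMembershipRecord]:
    """Terms most of whose annotated yeast proteins lie in the sample.

    Keeps terms with set fraction >= ``min_fraction`` (and raw P <=
    ``max_p`` when given), ranks by set membership count descending, and
    collapses nested terms enriched by the identical protein list to the
    most specific one -- but only when the specific term's P-value is
    lower; otherwise both are retained.
    """
    universe = set(universe)
    members = sample.members & universe
    kept: list[tuple[TermResult, frozenset[str]]] = []
    for r in results:
        annotated_members = frozenset(
            acc for acc in members if r.term in annot.terms_of(acc)
        )
        if r.counts.K == 0:
            continue
        fraction = r.counts.k / r.counts.K
        if fraction < min_fraction:
            continue
        if max_p is not None and r.p_raw > max_p:
            continue
        kept.append((r, annotated_members))

    drop: set[str] = set()
    for r1, prot1 in kept:
        for r2, prot2 in kept:
            if r1.term == r2.term or prot1 != prot2:
                continue
            # r1 is an ancestor (less specific) of r2: drop it only if
            # the more specific term has the lower P-value
            if dag.is_ancestor(r1.term, r2.term) and r2.log10_p < r1.log10_p:
                drop.add(r1.term)

    records = [
        HighMembershipRecord(
            term=r.term,
            name=r.name,
            yeast_count=r.counts.K,
            set_count=r.counts.k,
            fraction=r.counts.k / r.counts.K,
            p_raw=r.p_raw,
            passes_correction=bool(r.significant),
        )
        for r, _ in kept
        if r.term not in drop
    ]
    records.sort(key=lambda rec: (-rec.set_count, rec.p_raw, rec.term))
    return records


def protein_term_pairs(
    network: InteractionNetwork, annot: GOAnnotations
) -> dict[str, frozenset[str]]:
    """Deduplicated protein -> interacted-term map.

    If a protein interacts with two partners both annotated to term X,
    that is a single protein-X pair.
    """
    pairs: dict[str, frozenset[str]] = {}
    for protein in network.proteins:
        terms: set[str] = set()
        for partner in network.interactors(protein):
            terms |= annot.terms_of(partner)
        if terms:
            pairs[protein] = frozenset(terms)
    return pairs


def interaction_go_enrichment(
    network: InteractionNetwork,
    sample: ProteinSet,
    annot: GOAnnotations,
    dag: GODag | None = None,
    alpha: float = 0.05,
    correct: bool = True,
) -> list[TermResult]:
    """Enrichment of terms among the sample's interaction partners.

    Counts are over deduplicated protein<->term pairs: N = all pairs
    proteome-wide, K = pairs with the term, n = pairs whose protein is a
    sample member, k = sample pairs with the term.
    """
    pairs = protein_term_pairs(network, annot)
    N = sum(len(t) for t in pairs.values())
    if N == 0:
        return []
    term_total: dict[str, int] = {}
    term_sample: dict[str, int] = {}
    n = 0
    for protein, terms in pairs.items():
        in_sample = protein in sample
        if in_sample:
            n += len(terms)
        for t in terms:
            term_total[t] = term_total.get(t, 0) + 1
            if in_sample:
                term_sample[t] = term_sample.get(t, 0) + 1
    results = []
    for term in sorted(term_total):
        c = ContingencyCounts(N, term_total[term], n, term_sample.get(term, 0))
        logp = hypergeom_log_upper(c)
        results.append(
            TermResult(
                term=term,
                name=dag.name(term) if dag and term in dag else term,
                counts=c,
                p_raw=math.exp(logp) or 5e-324,
                log10_p=logp / math.log(10),
            )
        )
    return _finish(results, alpha, correct)


def cross_reference(*result_lists: Sequence[TermResult]) -> set[str]:
    """Terms flagged significant in every supplied result list."""
    sig_sets = [
        {r.term for r in results if r.significant} for results in result_lists
    ]
    if not sig_sets:
        return set()
    out = sig_sets[0]
    for s in sig_sets[1:]:
        out = out & s
    return out


def term_results_frame(results: Sequence[TermResult]) -> "pandas.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        {
            "term": r.term,
            "name": r.name,
            "N": r.counts.N,
            "K": r.counts.K,
            "n": r.counts.n,
            "k": r.counts.k,
            "p_raw": r.p_raw,
            "log10_p": r.log10_p,
            "significant": r.significant,
        }
        for r in results
    )
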