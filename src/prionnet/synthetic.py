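"""Synthetic proteomes, interactomes, annotations and disorder tracks.

Every generator plants parameterized structure -- N/Q-biased domains,
category-pair interaction preference odds, GO-term/set coupling, and
disorder elevation -- and writes the exact text formats the pipeline
readers consume (FASTA, MITAB, OBO, GAF, disorder TSV), together with a
truth table.  All output is deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bias import AMINO_ACIDS, BackgroundComposition
from .datasets import DisorderTrack, DisorderTracks, ProteinRecord, ProteinSet
from .network import InteractionNetwork

#: aggregate amino-acid frequencies of the budding-yeast proteome
YEAST_COMPOSITION = BackgroundComposition.from_frequencies(
    {
        "A": 0.0550, "C": 0.0131, "D": 0.0585, "E": 0.0656, "F": 0.0441,
        "G": 0.0498, "H": 0.0217, "I": 0.0655, "K": 0.0728, "L": 0.0958,
        "M": 0.0207, "N": 0.0613, "P": 0.0438, "Q": 0.0394, "R": 0.0445,
        "S": 0.0899, "T": 0.0592, "V": 0.0556, "W": 0.0104, "Y": 0.0337,
    }
)


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the planted-structure generators.

    Defaults emulate a small budding-yeast-like study: 500 proteins with
    log-normally distributed lengths (median 350 aa), 8% of proteins
    carrying a planted 60-residue domain whose positions are forced to
    N/Q with probability 0.55 (so the domain's realized N/Q content is
    ~60%, matching genuine prion-like domains), 2000 unique binary
    interactions, a 60-term biological-process tree of depth 3, and a
    baseline disorder fraction of 0.2 elevated by 0.5 for planted
    prion-like proteins.
    """

    n_proteins: int = 500
    length_median: float = 350.0
    length_sigma: float = 0.45
    min_length: int = 60
    background: BackgroundComposition = YEAST_COMPOSITION
    planted_nqp_fraction: float = 0.08
    bias_nq_fraction: float = 0.55
    bias_domain_length: int = 60
    n_interactions: int = 2000
    preference_odds: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    n_go_terms: int = 60
    dag_depth: int = 3
    coupling_odds: Mapping[str, float] = field(default_factory=dict)
    annotations_per_protein: float = 3.0
    disorder_base: float = 0.2
    disorder_nqp_boost: float = 0.5
    disorder_concentration: float = 20.0
    seed: int = 0

    def __post_init__(self):
        for frac in (self.planted_nqp_fraction, self.bias_nq_fraction, self.disorder_base):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.n_proteins <= 0 or self.n_go_terms <= 0:
            raise ValueError("sizes must be positive")
        for row in self.preference_odds.values():
            if any(v < 0 for v in row.values()):
                raise ValueError("preference odds must be non-negative")

    def with_seed(self, seed: int) -> "SynthConfig":
        return replace(self, seed=seed)


def _rng(cfg: SynthConfig) -> np.random.Generator:
    return np.random.default_rng(cfg.seed)


def _accession(i: int) -> str:
    return f"S{i:05d}"


def gen_proteome(
    cfg: SynthConfig, rng: np.random.Generator | None = None
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """I.i.d. background sequences with planted N/Q-biased domains.

    Returns the records and a truth table (accession, domain start/end
    1-based, realized N/Q count; one row per planted domain).
    """
    rng = rng if rng is not None else _rng(cfg)
    letters = np.array(list(AMINO_ACIDS))
    probs = np.array(cfg.background.freqs)
    n_planted = int(round(cfg.planted_nqp_fraction * cfg.n_proteins))
    planted_idx = set(
        rng.choice(cfg.n_proteins, size=n_planted, replace=False).tolist()
    )
    records: list[ProteinRecord] = []
    truth_rows = []
    for i in range(cfg.n_proteins):
        length = max(
            cfg.min_length,
            int(round(np.exp(rng.normal(np.log(cfg.length_median), cfg.length_sigma)))),
        )
        seq = rng.choice(letters, size=length, p=probs)
        acc = _accession(i)
        if i in planted_idx:
            dlen = min(cfg.bias_domain_length, length)
            start = int(rng.integers(0, length - dlen + 1))
            biased = rng.random(dlen) < cfg.bias_nq_fraction
            nq = rng.choice(np.array(["N", "Q"]), size=dlen)
            domain = np.where(biased, nq, rng.choice(letters, size=dlen, p=probs))
            seq[start : start + dlen] = domain
            truth_rows.append(
                {
                    "accession": acc,
                    "start": start + 1,
                    "end": start + dlen,
                    "nq_count": int(np.isin(domain, ["N", "Q"]).sum()),
                }
            )
        records.append(ProteinRecord(acc, "".join(seq)))
    truth = pd.DataFrame(truth_rows, columns=["accession", "start", "end", "nq_count"])
    return records, truth


def gen_network(
    cfg: SynthConfig,
    categories: Mapping[str, str],
    rng: np.random.Generator | None = None,
) -> InteractionNetwork:
    """Unique random pairs accepted with category-pair preference odds.

    With an all-ones odds matrix this is a uniform random graph on the
    categorized proteins.  Rejection sampling keeps the acceptance-odds
    semantics exact.
    """
    rng = rng if rng is not None else _rng(cfg)
    accessions = sorted(categories)
    n = len(accessions)
    max_pairs = n * (n - 1) // 2
    if cfg.n_interactions > max_pairs:
        raise ValueError(
            f"requested {cfg.n_interactions} interactions but only {max_pairs} pairs exist"
        )

    def odds(a: str, b: str) -> float:
        ca, cb = categories[a], categories[b]
        row = cfg.preference_odds.get(ca, {})
        fwd = row.get(cb)
        rev = cfg.preference_odds.get(cb, {}).get(ca)
        if fwd is None and rev is None:
            return 1.0
        return fwd if fwd is not None else rev

    max_odds = max(
        [1.0] + [v for row in cfg.preference_odds.values() for v in row.values()]
    )
    net = InteractionNetwork()
    seen: set[tuple[str, str]] = set()
    while len(net) < cfg.n_interactions:
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        a, b = accessions[int(i)], accessions[int(j)]
        pair = InteractionNetwork.canonical(a, b)
        if pair in seen:
            continue
        if rng.random() < odds(a, b) / max_odds:
            seen.add(pair)
            net.add(a, b)
    return net


@dataclass
class SyntheticOntology:
    terms: list[str]
    parents: dict[str, str | None]
    names: dict[str, str]
    leaves: list[str]

    def to_obo(self, path: str | Path) -> None:
        lines = ["format-version: 1.2", "ontology: synthetic-go", ""]
        for term in self.terms:
            lines += [
                "[Term]",
                f"id: {term}",
                f"name: {self.names[term]}",
                "namespace: biological_process",
            ]
            parent = self.parents[term]
            if parent is not None:
                lines.append(f"is_a: {parent} ! {self.names[parent]}")
            lines.append("")
        Path(path).write_text("\n".join(lines))


def gen_ontology(cfg: SynthConfig, rng: np.random.Generator | None = None) -> SyntheticOntology:
    """Random tree-shaped biological-process ontology (one parent each)."""
    rng = rng if rng is not None else _rng(cfg)
    terms = [f"GO:{7000000 + i:07d}" for i in range(cfg.n_go_terms)]
    parents: dict[str, str | None] = {terms[0]: None}
    depth = {terms[0]: 0}
    for i in range(1, cfg.n_go_terms):
        eligible = [t for t in terms[:i] if depth[t] < cfg.dag_depth]
        parent = eligible[int(rng.integers(0, len(eligible)))]
        parents[terms[i]] = parent
        depth[terms[i]] = depth[parent] + 1
    children = {t: 0 for t in terms}
    for t, p in parents.items():
        if p is not None:
            children[p] += 1
    leaves = [t for t in terms if children[t] == 0]
    names = {t: f"synthetic process {i}" for i, t in enumerate(terms)}
    return SyntheticOntology(terms=terms, parents=parents, names=names, leaves=leaves)


def gen_annotations(
    cfg: SynthConfig,
    records: Sequence[ProteinRecord],
    sets: Mapping[str, ProteinSet],
    rng: np.random.Generator | None = None,
) -> tuple[SyntheticOntology, dict[str, set[str]], DisorderTracks]:
    """Leaf annotations with term/set coupling, plus disorder tracks.

    A protein's chance of carrying a leaf term is multiplied by the
    coupling odds of any set (``coupling_odds[set_name]``) it belongs to,
    for terms coupled to that set (the first ``len(coupling_odds)``
    leaves are assigned round-robin to the coupled sets).  Disorder
    fractions are Beta-distributed around the base rate, with the mean
    shifted up by ``disorder_nqp_boost`` for members of the ``NQP`` set.
    """
    rng = rng if rng is not None else _rng(cfg)
    onto = gen_ontology(cfg, rng)
    leaves = onto.leaves
    base_p = min(1.0, cfg.annotations_per_protein / len(leaves))
    coupled_terms: dict[str, str] = {}  # term -> set name
    for leaf, set_name in zip(leaves, cfg.coupling_odds):
        coupled_terms[leaf] = set_name

    annotations: dict[str, set[str]] = {}
    for rec in records:
        mine: set[str] = set()
        for leaf in leaves:
            p = base_p
            set_name = coupled_terms.get(leaf)
            if set_name is not None and rec.accession in sets[set_name]:
                p = min(1.0, p * cfg.coupling_odds[set_name])
            if rng.random() < p:
                mine.add(leaf)
        if mine:
            annotations[rec.accession] = mine

    nqp_members = sets["NQP"].members if "NQP" in sets else set()
    conc = cfg.disorder_concentration
    tracks: DisorderTracks = {}
    for rec in records:
        mean = cfg.disorder_base
        if rec.accession in nqp_members:
            mean = min(0.95, mean + cfg.disorder_nqp_boost)
        frac = rng.beta(mean * conc, (1 - mean) * conc)
        count = int(round(frac * len(rec)))
        tracks[rec.accession] = DisorderTrack(rec.accession, len(rec), float(count))
    return onto, annotations, tracks


def write_gaf(annotations: Mapping[str, set[str]], path: str | Path) -> None:
    """Write direct annotations as a GAF 2.1 file."""
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.1\n")
        for acc in sorted(annotations):
            for term in sorted(annotations[acc]):
                cols = [
                    "UniProtKB", acc, acc, "", term, "PMID:0000001", "IDA", "",
                    "P", "", "", "protein", "taxon:4932", "20140101", "SYN", "", "",
                ]
                fh.write("\t".join(cols) + "\n")


def bundle_to_dir(
    cfg: SynthConfig,
    out_dir: str | Path,
    preference_sets: Mapping[str, ProteinSet] | None = None,
) -> dict[str, Path]:
    """Generate one complete input bundle on disk (all formats + truth).

    Planted-domain proteins form the true ``NQP`` set; remaining proteins
    are split round-robin into ``EPD``-like / ``EPN``-like / ``other``
    categories for interaction-preference purposes unless explicit sets
    are supplied.
    """
    from .datasets import write_disorder, write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = _rng(cfg)
    records, truth = gen_proteome(cfg, rng)
    nqp = ProteinSet("NQP", set(truth["accession"]))
    if preference_sets is None:
        others = [r.accession for r in records if r.accession not in nqp]
        preference_sets = {
            "NQP": nqp,
            "EPD": ProteinSet("EPD", set(others[0::10])),
            "EPN": ProteinSet("EPN", set(others[1::10])),
        }
    categories = {}
    for rec in records:
        categories[rec.accession] = "other"
        for name, pset in preference_sets.items():
            if rec.accession in pset:
                categories[rec.accession] = name
                break
    net = gen_network(cfg, categories, rng)
    onto, annotations, tracks = gen_annotations(cfg, records, preference_sets, rng)

    from .network import write_mitab

    paths = {
        "fasta": out / "proteome.fasta",
        "truth": out / "planted_domains.tsv",
        "mitab": out / "interactions.mitab",
        "obo": out / "ontology.obo",
        "gaf": out / "annotations.gaf",
        "disorder": out / "disorder.tsv",
        "nqp": out / "nqp_members.txt",
    }
    write_fasta(records, paths["fasta"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    write_mitab(net, paths["mitab"])
    onto.to_obo(paths["obo"])
    write_gaf(annotations, paths["gaf"])
    write_disorder(tracks, paths["disorder"])
    paths["nqp"].write_text(
        f"# seed={cfg.seed}\n" + "".join(f"{a}\n" for a in sorted(nqp.members))
    )
    return paths
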