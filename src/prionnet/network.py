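"""Binary protein-interaction networks from PSI-MI TAB (MITAB) files.

Interactions are undirected, deduplicated pairs of UniProt accessions;
A-B and B-A rows and duplicate evidence lines collapse to a single
interaction.  Self-interactions are retained by default and count once.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Callable, Iterable

from .datasets import ProteinSet, strip_isoform

logger = logging.getLogger(__name__)

#: default taxon filter: S. cerevisiae (strain-level and species-level ids)
YEAST_TAXA = frozenset({"559292", "4932"})

#: node colours for network-viewer export, by category precedence
CATEGORY_COLORS = {
    "KP": "black",
    "EPD": "grey",
    "EPN": "yellow",
    "NQP": "darkblue",
    "other": "brown",
}

_UNIPROT_RE = re.compile(r"uniprotkb:([A-Za-z0-9\-]+)")
_TAXID_RE = re.compile(r"taxid:(-?\d+)")


class InteractionNetwork:
    """A set of unique undirected interactions with an interactor index."""

    def __init__(self, pairs: Iterable[tuple[str, str]] = (), keep_self: bool = True):
        self._pairs: set[tuple[str, str]] = set()
        self._adjacency: dict[str, set[str]] = {}
        self.keep_self = keep_self
        for a, b in pairs:
            self.add(a, b)

    @staticmethod
    def canonical(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str) -> None:
        if a == b and not self.keep_self:
            return
        pair = self.canonical(a, b)
        if pair in self._pairs:
            return
        self._pairs.add(pair)
        self._adjacency.setdefault(a, set()).add(b)
        self._adjacency.setdefault(b, set()).add(a)

    @property
    def interactions(self) -> frozenset[tuple[str, str]]:
        return frozenset(self._pairs)

    def __len__(self) -> int:
        return len(self._pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return self.canonical(*pair) in self._pairs

    @property
    def proteins(self) -> set[str]:
        return set(self._adjacency)

    def interactors(self, accession: str) -> set[str]:
        """All partners of a protein; contains itself iff a self-loop exists."""
        return set(self._adjacency.get(accession, set()))

    def subset(self, predicate: Callable[[tuple[str, str]], bool]) -> "InteractionNetwork":
        return InteractionNetwork(
            (p for p in self._pairs if predicate(p)), keep_self=self.keep_self
        )

    def restricted_to(self, pset: ProteinSet) -> "InteractionNetwork":
        """Sub-network of interactions with at least one endpoint in the set."""
        return self.subset(lambda p: p[0] in pset or p[1] in pset)


def read_mitab(
    path: str | Path,
    taxa: frozenset[str] | None = YEAST_TAXA,
    keep_self: bool = True,
) -> InteractionNetwork:
    """Parse a MITAB 2.5/2.6/2.7 file into a deduplicated network.

    UniProt accessions are extracted from the ID columns (1-2), falling
    back to the alternative-ID columns (3-4); isoform suffixes are
    stripped.  Rows without a UniProt identifier on either side are
    skipped and counted.  When ``taxa`` is given, rows whose taxon
    columns (10-11) are present and not in the allowed set are dropped;
    rows without taxon columns pass through.
    """
    net = InteractionNetwork(keep_self=keep_self)
    skipped = 0
    parsed = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                continue
            accs = []
            for side in (0, 1):
                m = _UNIPROT_RE.search(cols[side])
                if not m and len(cols) > side + 2:
                    m = _UNIPROT_RE.search(cols[side + 2])  # alt-ID columns
                accs.append(strip_isoform(m.group(1)) if m else None)
            if accs[0] is None or accs[1] is None:
                skipped += 1
                continue
            if taxa is not None and len(cols) >= 11:
                ok = True
                for col in (cols[9], cols[10]):
                    m = _TAXID_RE.search(col)
                    if m and m.group(1) not in taxa:
                        ok = False
                if not ok:
                    skipped += 1
                    continue
            net.add(accs[0], accs[1])
            parsed += 1
    if parsed == 0:
        logger.warning("no parseable MITAB rows in %s", path)
    if skipped:
        logger.info("skipped %d MITAB rows (non-UniProt or foreign taxon)", skipped)
    return net


def write_mitab(net: InteractionNetwork, path: str | Path, taxid: str = "4932") -> None:
    """Write a minimal 15-column MITAB 2.5 file readable by :func:`read_mitab`."""
    tax = f"taxid:{taxid}(Saccharomyces cerevisiae)"
    with open(path, "w") as fh:
        for a, b in sorted(net.interactions):
            cols = [
                f"uniprotkb:{a}",
                f"uniprotkb:{b}",
                "-",
                "-",
                "-",
                "-",
                'psi-mi:"MI:0018"(two hybrid)',
                "-",
                "-",
                tax,
                tax,
                'psi-mi:"MI:0915"(physical association)',
                "-",
                "-",
                "-",
            ]
            fh.write("\t".join(cols) + "\n")


def set_interactions(
    net: InteractionNetwork, pset: ProteinSet
) -> tuple[int, list[tuple[str, str]]]:
    """Unique interactions with at least one endpoint in the set.

    Each interaction counts exactly once even when both endpoints are
    members; this is the ``n`` of the interaction-level contingency
    counts.
    """
    pairs = sorted(p for p in net.interactions if p[0] in pset or p[1] in pset)
    return len(pairs), pairs


def categorize(
    accession: str, sets: dict[str, ProteinSet], precedence: tuple[str, ...] = ("KP", "EPD", "EPN", "NQP")
) -> str:
    for name in precedence:
        if name in sets and accession in sets[name]:
            return name
    return "other"


def write_edge_list(
    net: InteractionNetwork,
    path: str | Path,
    sets: dict[str, ProteinSet] | None = None,
) -> None:
    """Export an annotated edge list for external network viewers.

    Columns: the two accessions, each endpoint's category and its display
    colour (known prions black, other prionogenic grey, prion negatives
    yellow, N/Q-rich prion-like dark blue, everything else brown).
    """
    sets = sets or {}
    with open(path, "w") as fh:
        fh.write("a\tb\tcategory_a\tcategory_b\tcolor_a\tcolor_b\n")
        for a, b in sorted(net.interactions):
            ca, cb = categorize(a, sets), categorize(b, sets)
            fh.write(
                f"{a}\t{b}\t{ca}\t{cb}\t{CATEGORY_COLORS[ca]}\t{CATEGORY_COLORS[cb]}\n"
            )
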