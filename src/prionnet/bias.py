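"""Compositional-bias detection and N/Q-rich prion-like classification.

The detector is a lowest-probability-subsequence (LPS) scan: for a chosen
set of "success" residues it finds the contiguous region of a protein
that minimizes the binomial upper-tail probability of its success count,
given the background composition of the proteome.  A protein is classed
as an N/Q-rich prion-like protein (NQP) when its best N/Q(-plus-optional-
subsidiary) region reaches the main P-value threshold and carries no
contributing bias from charged or major hydrophobic residues.

The search is exact: for a fixed region length the binomial tail is
monotone decreasing in the success count, so only the maximal-count
window at each length can be the global minimizer.  Scanning the best
window per length with prefix-sum counts therefore equals the exhaustive
all-substrings scan at O(L^2) window-count work and O(L) tail
evaluations per residue set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import bdtrc, gammaln, logsumexp

from .datasets import ProteinRecord, ProteinSet

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class BackgroundComposition:
    """Per-residue background frequencies for the 20 amino acids."""

    freqs: tuple[float, ...]  # ordered as AMINO_ACIDS

    def __post_init__(self):
        if len(self.freqs) != 20:
            raise ValueError("need 20 amino-acid frequencies")
        if any(f < 0 for f in self.freqs):
            raise ValueError("negative frequency")
        if abs(sum(self.freqs) - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")

    @classmethod
    def uniform(cls) -> "BackgroundComposition":
        return cls((1 / 20,) * 20)

    @classmethod
    def from_frequencies(cls, table: dict[str, float]) -> "BackgroundComposition":
        total = sum(table.values())
        return cls(tuple(table.get(aa, 0.0) / total for aa in AMINO_ACIDS))

    @classmethod
    def from_proteome(cls, records: Iterable[ProteinRecord]) -> "BackgroundComposition":
        counts = {aa: 0 for aa in AMINO_ACIDS}
        for rec in records:
            for aa in rec.sequence:
                if aa in counts:
                    counts[aa] += 1
        total = sum(counts.values())
        if total == 0:
            return cls.uniform()
        return cls(tuple(counts[aa] / total for aa in AMINO_ACIDS))

    def prob(self, residue_set: Iterable[str]) -> float:
        """Aggregate success probability of a residue set."""
        idx = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
        return sum(self.freqs[idx[aa]] for aa in set(residue_set))


@dataclass(frozen=True)
class BiasThresholds:
    """Threshold rules for the N/Q-rich prion-like classification.

    ``main_p`` bounds the binomial tail of the best N/Q(-subsidiary)
    region; subsidiary Y/S/G biases are admissible only below
    ``subsidiary_p`` within the region; any charged (D,E,R,K) or major
    hydrophobic (V,I,L,M) bias below ``exclusion_p`` within the region
    disqualifies the protein.
    """

    main_p: float = 1e-10
    subsidiary_p: float = 1e-4
    exclusion_p: float = 1e-4
    subsidiary_residues: frozenset[str] = frozenset("YSG")
    excluded_residues: frozenset[str] = frozenset("DERKVILM")
    min_region_length: int = 20

    def __post_init__(self):
        for p in (self.main_p, self.subsidiary_p, self.exclusion_p):
            if not 0 < p <= 1:
                raise ValueError("thresholds must lie in (0, 1]")


@dataclass(frozen=True)
class BiasedRegion:
    """A contiguous biased region; coordinates are 1-based inclusive."""

    accession: str
    start: int
    end: int
    residue_set: frozenset[str]
    count: int
    pvalue: float
    log10_pvalue: float

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise ValueError("bad region coordinates")
        if self.count > self.end - self.start + 1:
            raise ValueError("count exceeds region length")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class NQPDecision:
    accession: str
    is_nqp: bool
    region: BiasedRegion | None
    reason: str  # "accepted" | "main threshold" | "excluded-residue bias" | ...


# ---------------------------------------------------------------------------
# binomial tails


def binomial_tail(k: int, n: int, p: float) -> float:
    """Exact upper-tail binomial probability P(X >= k).

    Computed by log-space summation of the individual terms, so it stays
    meaningful far below double underflow of the naive sum's partial
    terms; monotone non-increasing in ``k``.
    """
    return math.exp(min(0.0, log_binomial_tail(k, n, p)))


def log_binomial_tail(k: int, n: int, p: float) -> float:
    """Natural log of P(X >= k) for X ~ Binomial(n, p)."""
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    if k == 0:
        return 0.0
    i = np.arange(k, n + 1)
    log_terms = (
        gammaln(n + 1)
        - gammaln(i + 1)
        - gammaln(n - i + 1)
        + i * math.log(p)
        + (n - i) * math.log1p(-p)
    )
    return float(min(0.0, logsumexp(log_terms)))


# ---------------------------------------------------------------------------
# LPS region search


def _prefix_counts(sequence: str, residue_set: frozenset[str]) -> np.ndarray:
    flags = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    member = np.zeros(128, dtype=np.int64)
    for aa in residue_set:
        member[ord(aa)] = 1
    hits = member[flags]
    prefix = np.zeros(len(sequence) + 1, dtype=np.int64)
    np.cumsum(hits, out=prefix[1:])
    return prefix


def find_min_p_region(
    record: ProteinRecord,
    residue_set: Iterable[str],
    bg: BackgroundComposition,
    thresholds: BiasThresholds = BiasThresholds(),
) -> BiasedRegion | None:
    """Minimal binomial-tail region of length >= ``min_region_length``.

    Ties are broken by lower P, then greater length, then smaller start,
    which makes the result deterministic.  Returns ``None`` only when the
    sequence is shorter than the minimum region length.
    """
    residue_set = frozenset(residue_set)
    if not residue_set:
        raise ValueError("empty residue set")
    seq = record.sequence.upper().rstrip("*")
    L = len(seq)
    min_len = thresholds.min_region_length
    if L < min_len:
        logger.debug("%s shorter than min region length", record.accession)
        return None
    p_set = bg.prob(residue_set)
    if not 0 < p_set < 1:
        raise ValueError(f"background probability of {set(residue_set)} is {p_set}")

    prefix = _prefix_counts(seq, residue_set)
    lengths = np.arange(min_len, L + 1)
    best_counts = np.empty(len(lengths), dtype=np.int64)
    best_starts = np.empty(len(lengths), dtype=np.int64)
    for j, n in enumerate(lengths):
        window = prefix[n:] - prefix[:-n]  # counts of all windows of length n
        s = int(np.argmax(window))  # first (= smallest start) maximum
        best_starts[j] = s
        best_counts[j] = window[s]

    # For fixed length the tail is monotone decreasing in count, so the
    # per-length maxima contain the global minimizer.
    tails = bdtrc(best_counts - 1, lengths, p_set)
    order = np.argsort(tails, kind="stable")
    min_p = tails[order[0]]
    tied = np.flatnonzero(tails == min_p)
    if len(tied) > 1 or min_p < 1e-290:
        # refine underflowed/tied candidates in log space
        logs = np.array(
            [log_binomial_tail(int(best_counts[j]), int(lengths[j]), p_set) for j in tied]
        )
        # lower log-P first, then greater length, then smaller start
        keys = sorted(
            range(len(tied)),
            key=lambda i: (logs[i], -lengths[tied[i]], best_starts[tied[i]]),
        )
        j = int(tied[keys[0]])
        logp = float(logs[keys[0]])
    else:
        j = int(order[0])
        logp = log_binomial_tail(int(best_counts[j]), int(lengths[j]), p_set)
    start = int(best_starts[j])
    n = int(lengths[j])
    return BiasedRegion(
        accession=record.accession,
        start=start + 1,
        end=start + n,
        residue_set=residue_set,
        count=int(best_counts[j]),
        pvalue=math.exp(min(0.0, logp)) or 5e-324,
        log10_pvalue=logp / math.log(10),
    )


# ---------------------------------------------------------------------------
# NQP classification


def _candidate_sets(thresholds: BiasThresholds) -> list[frozenset[str]]:
    bases = [frozenset("N"), frozenset("Q"), frozenset("NQ")]
    candidates = list(bases)
    for base in bases:
        for sub in sorted(thresholds.subsidiary_residues):
            candidates.append(base | {sub})
    return candidates


def _region_residue_tail(
    seq: str, start: int, end: int, residue: str, bg: BackgroundComposition
) -> float:
    """Log10 within-region binomial tail for a single residue's bias."""
    segment = seq[start - 1 : end]
    count = segment.count(residue)
    p = bg.prob({residue})
    if not 0 < p < 1:
        return 0.0
    return log_binomial_tail(count, len(segment), p) / math.log(10)


def classify_nqp(
    record: ProteinRecord,
    bg: BackgroundComposition,
    thresholds: BiasThresholds = BiasThresholds(),
) -> NQPDecision:
    """Decide whether a protein carries an N/Q-rich prion-like domain.

    Candidate success sets are {N}, {Q}, {N,Q} and each of their unions
    with a single subsidiary residue (Y, S or G).  A subsidiary-bearing
    candidate is admissible only if the subsidiary residue's own bias
    within the winning region reaches ``subsidiary_p``.  The best
    admissible region must reach ``main_p``, and no excluded residue may
    show a within-region bias below ``exclusion_p``.
    """
    seq = record.sequence.upper().rstrip("*")
    norm = ProteinRecord(record.accession, seq)
    if len(seq) < thresholds.min_region_length:
        return NQPDecision(record.accession, False, None, "sequence too short")

    best: BiasedRegion | None = None
    for cand in _candidate_sets(thresholds):
        if not 0 < bg.prob(cand) < 1:
            continue  # degenerate background (residue absent from proteome)
        region = find_min_p_region(norm, cand, bg, thresholds)
        if region is None:
            continue
        subsidiaries = cand & thresholds.subsidiary_residues
        if subsidiaries:
            (sub,) = subsidiaries
            sub_log10 = _region_residue_tail(seq, region.start, region.end, sub, bg)
            if sub_log10 >= math.log10(thresholds.subsidiary_p):
                continue  # subsidiary bias not individually supported
        if (
            best is None
            or region.log10_pvalue < best.log10_pvalue
            or (
                region.log10_pvalue == best.log10_pvalue
                and (-region.length, region.start) < (-best.length, best.start)
            )
        ):
            best = region

    if best is None:
        return NQPDecision(record.accession, False, None, "no candidate region")
    if best.log10_pvalue > math.log10(thresholds.main_p):
        return NQPDecision(record.accession, False, best, "main threshold")
    for residue in sorted(thresholds.excluded_residues):
        log10 = _region_residue_tail(seq, best.start, best.end, residue, bg)
        if log10 < math.log10(thresholds.exclusion_p):
            return NQPDecision(record.accession, False, best, "excluded-residue bias")
    return NQPDecision(record.accession, True, best, "accepted")


def scan_proteome(
    records: Sequence[ProteinRecord],
    bg: BackgroundComposition | None = None,
    thresholds: BiasThresholds = BiasThresholds(),
) -> tuple[ProteinSet, "pandas.DataFrame"]:
    """Classify every protein; returns the NQP set and a per-protein table.

    The background composition defaults to the aggregate residue
    frequencies of the supplied proteome.
    """
    import pandas as pd

    if bg is None:
        bg = BackgroundComposition.from_proteome(records)
    rows = []
    members: set[str] = set()
    for rec in records:
        decision = classify_nqp(rec, bg, thresholds)
        if decision.is_nqp:
            members.add(rec.accession)
        region = decision.region
        rows.append(
            {
                "accession": rec.accession,
                "start": region.start if region else 0,
                "end": region.end if region else 0,
                "residue_set": "".join(sorted(region.residue_set)) if region else "",
                "count": region.count if region else 0,
                "pvalue": region.pvalue if region else 1.0,
                "log10_pvalue": region.log10_pvalue if region else 0.0,
                "decision": decision.is_nqp,
                "reason": decision.reason,
            }
        )
    return ProteinSet("NQP", members), pd.DataFrame(rows)
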