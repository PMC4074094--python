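"""Hypergeometric enrichment/depletion with interaction-level counting.

The counting convention is interaction-level: the population is the set
of unique binary interactions, a "success" is an interaction involving
at least one member of the target set, the sample is the interactions
involving at least one member of the sample set, and ``k`` counts sample
interactions that also involve a target member.  An interaction internal
to both sets counts once in each of K, n and k.

Tails are computed exactly in log space so magnitudes far below 1e-30
remain meaningful.  Family-wise error is controlled with the
Holm-Bonferroni step-down procedure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .datasets import ProteinSet
from .network import InteractionNetwork


@dataclass(frozen=True)
class ContingencyCounts:
    """The (N, K, n, k) quadruple of a hypergeometric test."""

    N: int
    K: int
    n: int
    k: int

    def __post_init__(self):
        if not (0 <= self.K <= self.N and 0 <= self.n <= self.N):
            raise ValueError(f"invalid counts {self}")
        if not 0 <= self.k <= min(self.n, self.K):
            raise ValueError(f"invalid k in {self}")

    @property
    def expected(self) -> float:
        return self.n * self.K / self.N if self.N else 0.0


def _log_hypergeom_pmf(c: ContingencyCounts, ks: np.ndarray) -> np.ndarray:
    N, K, n = c.N, c.K, c.n
    return (
        gammaln(K + 1)
        - gammaln(ks + 1)
        - gammaln(K - ks + 1)
        + gammaln(N - K + 1)
        - gammaln(n - ks + 1)
        - gammaln(N - K - n + ks + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )


def hypergeom_log_upper(c: ContingencyCounts) -> float:
    """log P(X >= k)."""
    if c.N == 0 or c.k == 0:
        return 0.0
    hi = min(c.n, c.K)
    ks = np.arange(c.k, hi + 1)
    return float(min(0.0, logsumexp(_log_hypergeom_pmf(c, ks))))


def hypergeom_log_lower(c: ContingencyCounts) -> float:
    """log P(X <= k)."""
    if c.N == 0:
        return 0.0
    lo = max(0, c.n + c.K - c.N)
    ks = np.arange(lo, c.k + 1)
    return float(min(0.0, logsumexp(_log_hypergeom_pmf(c, ks))))


def hypergeom_upper(c: ContingencyCounts) -> float:
    """Exact upper-tail probability P(X >= k) of the hypergeometric."""
    return math.exp(hypergeom_log_upper(c)) or 5e-324


def hypergeom_lower(c: ContingencyCounts) -> float:
    """Exact lower-tail probability P(X <= k) of the hypergeometric."""
    return math.exp(hypergeom_log_lower(c)) or 5e-324


@dataclass
class EnrichmentResult:
    """One enrichment/depletion test over interaction-level counts."""

    label: str
    counts: ContingencyCounts
    direction: str  # "enrichment" | "depletion"
    p_raw: float
    p_upper: float
    p_lower: float
    log10_p: float
    significant: bool | None = None  # set after family-wise correction

    @property
    def cell(self) -> str:
        """Table-style cell text ``k/n (p, direction)``."""
        sig = "" if self.significant is None else (", sig" if self.significant else ", ns")
        return (
            f"{self.counts.k}/{self.counts.n} "
            f"({self.p_raw:.2g}, {self.direction}{sig})"
        )


def _involves(pair: tuple[str, str], members: set[str]) -> bool:
    return pair[0] in members or pair[1] in members


def _cross(pair: tuple[str, str], s: set[str], t: set[str]) -> bool:
    """Sample interaction whose partner endpoint is a target member."""
    a, b = pair
    return (a in s and b in t) or (b in s and a in t)


def count_interactions(
    pairs: Iterable[tuple[str, str]],
    sample: set[str],
    target: set[str],
    convention: str = "interaction",
) -> ContingencyCounts:
    """The (N, K, n, k) quadruple over a collection of unique interactions.

    ``convention='interaction'`` (the published convention): each unique
    interaction counts once; K and n count interactions involving at
    least one target / sample member, and k counts sample interactions
    whose *partner* endpoint is a target member (so an interaction
    internal to both sets counts once in each of K, n and k, and the
    sample-equals-target diagonal counts internal interactions).

    ``convention='endpoint'``: oriented counting over 2N endpoint slots
    (n = sample endpoints, k = sample endpoints with a target partner).
    Unlike the published convention this variant is calibrated against
    an edge-random null; see the methods notes.
    """
    s, t = sample, target
    N = K = n = k = 0
    if convention == "interaction":
        for pair in pairs:
            N += 1
            K += _involves(pair, t)
            n += _involves(pair, s)
            k += _cross(pair, s, t)
    elif convention == "endpoint":
        for a, b in pairs:
            for tail, head in ((a, b), (b, a)):
                N += 1
                K += head in t
                n += tail in s
                k += tail in s and head in t
    else:
        raise ValueError(f"unknown counting convention {convention!r}")
    return ContingencyCounts(N, K, n, k)


def interactor_set_enrichment(
    network: InteractionNetwork,
    sample: ProteinSet,
    target: ProteinSet,
    background: InteractionNetwork | None = None,
    label: str | None = None,
    convention: str = "interaction",
) -> EnrichmentResult:
    """Test whether the sample set's interactions are enriched (or
    depleted) in interactions with the target set.

    ``background`` restricts the population (e.g. to the NQP-involving
    interactions); it defaults to the whole network.  The reported
    direction is chosen by comparing ``k`` with its expectation
    ``n*K/N``; both one-tailed probabilities are retained.
    """
    bg = background if background is not None else network
    counts = count_interactions(
        bg.interactions, sample.members, target.members, convention
    )
    log_up = hypergeom_log_upper(counts)
    log_lo = hypergeom_log_lower(counts)
    if counts.N == 0 or counts.K == 0 or counts.n == 0:
        direction, logp = "enrichment", 0.0
    elif counts.k >= counts.expected:
        direction, logp = "enrichment", log_up
    else:
        direction, logp = "depletion", log_lo
    return EnrichmentResult(
        label=label or f"{sample.name}x{target.name}",
        counts=counts,
        direction=direction,
        p_raw=math.exp(logp) or 5e-324,
        p_upper=math.exp(log_up) or 5e-324,
        p_lower=math.exp(log_lo) or 5e-324,
        log10_p=logp / math.log(10),
    )


def holm_bonferroni(p_values: Sequence[float], alpha: float = 0.05) -> list[bool]:
    """Holm-Bonferroni step-down rejections, returned in input order.

    Sort ascending; reject p_(i) while p_(i) <= alpha/(m - i + 1)
    (1-based i); stop at the first failure.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    m = len(p_values)
    flags = [False] * m
    order = sorted(range(m), key=lambda i: p_values[i])
    for rank, idx in enumerate(order):
        if p_values[idx] <= alpha / (m - rank):
            flags[idx] = True
        else:
            break
    return flags


def apply_holm(results: Sequence[EnrichmentResult], alpha: float = 0.05) -> None:
    """Set ``significant`` flags across one correction family in place."""
    flags = holm_bonferroni([r.p_raw for r in results], alpha)
    for r, f in zip(results, flags):
        r.significant = f


def enrichment_grid(
    network: InteractionNetwork,
    samples: Sequence[ProteinSet],
    targets: Sequence[ProteinSet],
    background: InteractionNetwork | None = None,
    alpha: float = 0.05,
    correct: bool = True,
) -> list[EnrichmentResult]:
    """All sample x target tests; one Holm family over the whole grid."""
    results = [
        interactor_set_enrichment(network, s, t, background) for s in samples for t in targets
    ]
    if correct and results:
        apply_holm(results, alpha)
    return results


def grid_tables(results: Sequence[EnrichmentResult]) -> tuple["pandas.DataFrame", "pandas.DataFrame"]:
    """Wide (table-layout) and long (full-count) report frames."""
    import pandas as pd

    long = pd.DataFrame(
        {
            "label": r.label,
            "sample": r.label.split("x")[0],
            "target": r.label.split("x")[-1],
            "N": r.counts.N,
            "K": r.counts.K,
            "n": r.counts.n,
            "k": r.counts.k,
            "expected": r.counts.expected,
            "direction": r.direction,
            "p_raw": r.p_raw,
            "log10_p": r.log10_p,
            "significant": r.significant,
        }
        for r in results
    )
    wide = long.assign(
        cell=[r.cell for r in results]
    ).pivot(index="sample", columns="target", values="cell")
    return wide, long
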