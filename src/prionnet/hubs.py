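"""Hub extraction and hub/non-hub partitioned enrichment.

A hub is a sample-set protein with at least ``min_partners`` distinct
interactors in a partner set (>= 10 N/Q-rich prion-like partners in the
reference analysis).  The sample's interactions can then be split into
hub-involving and non-hub interactions and each partition re-tested for
target-set enrichment against an unchanged background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .datasets import ProteinSet
from .enrichment import (
    ContingencyCounts,
    EnrichmentResult,
    hypergeom_log_lower,
    hypergeom_log_upper,
)
from .network import InteractionNetwork


@dataclass
class HubRecord:
    accession: str
    interactor_count: int
    partner_count: int
    p_raw: float

    def __post_init__(self):
        if self.partner_count > self.interactor_count:
            raise ValueError("partner count exceeds interactor count")


def hub_enrichment(
    network: InteractionNetwork,
    hub: str,
    partner_set: ProteinSet,
    background: InteractionNetwork | None = None,
) -> EnrichmentResult:
    """Per-hub enrichment of partner-set proteins among its interactors.

    n = distinct interactors of the hub, k = those in the partner set;
    the population is interaction-level: N = background interactions,
    K = interactions involving a partner-set member.
    """
    bg = background if background is not None else network
    interactors = network.interactors(hub)
    if not interactors and hub not in network.proteins:
        raise KeyError(f"{hub} absent from network")
    members = partner_set.members
    N = len(bg.interactions)
    K = sum(1 for a, b in bg.interactions if a in members or b in members)
    n = len(interactors)
    k = len(interactors & members)
    counts = ContingencyCounts(N, K, n, k)
    log_up = hypergeom_log_upper(counts)
    log_lo = hypergeom_log_lower(counts)
    enriched = N == 0 or k >= counts.expected
    logp = log_up if enriched else log_lo
    return EnrichmentResult(
        label=f"hub:{hub}",
        counts=counts,
        direction="enrichment" if enriched else "depletion",
        p_raw=math.exp(logp) or 5e-324,
        p_upper=math.exp(log_up) or 5e-324,
        p_lower=math.exp(log_lo) or 5e-324,
        log10_p=logp / math.log(10),
    )


def find_hubs(
    network: InteractionNetwork,
    sample: ProteinSet,
    partner_set: ProteinSet,
    min_partners: int = 10,
) -> list[HubRecord]:
    """Sample members with >= ``min_partners`` distinct partner-set interactors.

    Sorted by partner count descending (ties by accession).
    """
    records = []
    for acc in sorted(sample.members):
        interactors = network.interactors(acc)
        partners = interactors & partner_set.members
        if len(partners) >= min_partners:
            result = hub_enrichment(network, acc, partner_set)
            records.append(
                HubRecord(
                    accession=acc,
                    interactor_count=len(interactors),
                    partner_count=len(partners),
                    p_raw=result.p_raw,
                )
            )
    records.sort(key=lambda r: (-r.partner_count, r.accession))
    return records


def partition_sample_interactions(
    network: InteractionNetwork, sample: ProteinSet, hubs: Sequence[str]
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Split the sample's interactions into hub-involving and the rest."""
    hub_set = set(hubs)
    hub_pairs, nonhub_pairs = [], []
    for pair in sorted(network.interactions):
        if pair[0] in sample or pair[1] in sample:
            if pair[0] in hub_set or pair[1] in hub_set:
                hub_pairs.append(pair)
            else:
                nonhub_pairs.append(pair)
    return hub_pairs, nonhub_pairs


def partition_and_enrich(
    network: InteractionNetwork,
    sample: ProteinSet,
    hubs: Sequence[str],
    target_sets: Sequence[ProteinSet],
    background: InteractionNetwork | None = None,
) -> dict[str, list[EnrichmentResult]]:
    """Re-run set enrichment separately on hub and non-hub interactions.

    Partition sizes always sum to the sample's total interaction count;
    the background population (N, K) is unchanged.
    """
    from .enrichment import _cross

    bg = background if background is not None else network
    hub_pairs, nonhub_pairs = partition_sample_interactions(network, sample, hubs)
    N = len(bg.interactions)
    out: dict[str, list[EnrichmentResult]] = {"hub": [], "nonhub": []}
    for part_name, pairs in (("hub", hub_pairs), ("nonhub", nonhub_pairs)):
        for target in target_sets:
            members = target.members
            K = sum(1 for a, b in bg.interactions if a in members or b in members)
            n = len(pairs)
            k = sum(1 for pair in pairs if _cross(pair, sample.members, members))
            counts = ContingencyCounts(N, K, n, k)
            log_up = hypergeom_log_upper(counts)
            log_lo = hypergeom_log_lower(counts)
            enriched = N == 0 or K == 0 or n == 0 or k >= counts.expected
            logp = log_up if enriched else log_lo
            out[part_name].append(
                EnrichmentResult(
                    label=f"{sample.name}_{part_name}x{target.name}",
                    counts=counts,
                    direction="enrichment" if enriched else "depletion",
                    p_raw=math.exp(logp) or 5e-324,
                    p_upper=math.exp(log_up) or 5e-324,
                    p_lower=math.exp(log_lo) or 5e-324,
                    log10_p=logp / math.log(10),
                )
            )
    return out
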