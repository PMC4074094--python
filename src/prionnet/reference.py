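"""Published contingency counts for the yeast prion interactome survey.

The published tables report, for every sample-set x target-set cell, the
interaction-level counts (N, K, n, k) alongside a 1-2 significant-figure
hypergeometric P-value.  Because the counts themselves are printed, every
P-value can be recomputed from scratch; :func:`verify_printed_values`
does so and applies a factor-of-two agreement rule (and a strict bound
for the one bounded claim).

Universe: 5796 yeast proteins, 36467 unique binary interactions.
Set sizes (proteins / interactions): KP 10/152, EPD 27/314, EPN 18/259,
NQP 354/4405, highly-disordered-not-NQP 251/2432, PBD-not-NQP -/19481,
NQP-not-PBD -/2877, NQP-and-PBD -/1631.  The three EPD hubs (LSM4, PUB1,
NUP100) account for 78 of the 314 EPD interactions.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .enrichment import ContingencyCounts, hypergeom_lower, hypergeom_upper

#: total unique binary interactions in the published interactome snapshot
TOTAL_INTERACTIONS = 36467
#: total proteins in the published proteome universe
TOTAL_PROTEINS = 5796


@dataclass(frozen=True)
class ReferenceCell:
    """One published contingency cell and its printed P-value."""

    label: str
    N: int
    K: int
    n: int
    k: int
    direction: str  # "enrichment" | "depletion"
    printed_p: float | None  # None for cells printed as non-significant
    bound: bool = False  # printed as an upper bound ("< printed_p")

    @property
    def counts(self) -> ContingencyCounts:
        return ContingencyCounts(self.N, self.K, self.n, self.k)

    def recompute(self) -> float:
        if self.direction == "enrichment":
            return hypergeom_upper(self.counts)
        return hypergeom_lower(self.counts)


_N = TOTAL_INTERACTIONS

REFERENCE_CELLS: tuple[ReferenceCell, ...] = (
    # main grid: sample-set interactor lists x target sets
    ReferenceCell("EPD_x_NQP", _N, 4405, 314, 63, "enrichment", 3.4e-5),
    ReferenceCell("NQP_x_EPD", _N, 314, 4405, 63, "enrichment", 3.4e-5),
    ReferenceCell("KP_x_EPD", _N, 314, 152, 5, "enrichment", 0.010),
    ReferenceCell("EPD_x_KP", _N, 152, 314, 5, "enrichment", 0.010),
    ReferenceCell("EPD_x_EPD", _N, 314, 314, 7, "enrichment", 0.019),
    ReferenceCell("EPD_x_EPN", _N, 259, 314, 7, "enrichment", 0.0074),
    ReferenceCell("EPN_x_EPD", _N, 314, 259, 7, "enrichment", 0.0074),
    ReferenceCell("EPN_x_NQP", _N, 4405, 259, 46, "enrichment", 0.0050),
    ReferenceCell("NQP_x_EPN", _N, 259, 4405, 46, "enrichment", 0.0047),
    ReferenceCell("NQP_x_NQP", _N, 4405, 4405, 251, "depletion", 1e-30, bound=True),
    ReferenceCell("EPD_x_disordered_not_NQP", _N, 2432, 314, 9, "depletion", 0.00083),
    ReferenceCell("EPN_x_disordered_not_NQP", _N, 2432, 259, 7, "depletion", 0.0013),
    ReferenceCell("NQP_x_disordered_not_NQP", _N, 2432, 4405, 162, "depletion", 1e-20),
    # protein-binding-domain composites for the EPD rows
    ReferenceCell("EPD_x_PBD_not_NQP", _N, 19481, 314, 89, "depletion", 9e-20),
    ReferenceCell("EPD_x_NQP_not_PBD", _N, 2877, 314, 48, "enrichment", 7.9e-6),
    ReferenceCell("EPD_x_NQP_and_PBD", _N, 1631, 314, 15, "enrichment", None),
    # hub / non-hub partition of the EPD interactions (78 + 236 = 314)
    ReferenceCell("EPD_hubs_x_NQP", _N, 4405, 78, 36, "enrichment", 8e-14),
    ReferenceCell("EPD_hubs_x_PBD_not_NQP", _N, 19481, 78, 8, "depletion", 9e-16),
    ReferenceCell("EPD_hubs_x_NQP_not_PBD", _N, 2877, 78, 27, "enrichment", 2e-11),
    ReferenceCell("EPD_hubs_x_NQP_and_PBD", _N, 1631, 78, 9, "enrichment", 0.006),
    ReferenceCell("EPD_hubs_x_disordered_not_NQP", _N, 2432, 78, 0, "depletion", 0.005),
    ReferenceCell("EPD_nonhubs_x_NQP", _N, 4405, 236, 27, "depletion", None),
    ReferenceCell("EPD_nonhubs_x_PBD_not_NQP", _N, 19481, 236, 81, "depletion", 1e-9),
    ReferenceCell("EPD_nonhubs_x_NQP_not_PBD", _N, 2877, 236, 21, "enrichment", None),
    ReferenceCell("EPD_nonhubs_x_NQP_and_PBD", _N, 1631, 236, 6, "depletion", 0.048),
    ReferenceCell("EPD_nonhubs_x_disordered_not_NQP", _N, 2432, 236, 9, "depletion", 0.022),
    # the three per-hub enrichments (n = distinct interactors, k = NQP partners)
    ReferenceCell("hub_LSM4_x_NQP", _N, 4405, 31, 14, "enrichment", 4e-6),
    ReferenceCell("hub_PUB1_x_NQP", _N, 4405, 20, 13, "enrichment", 4e-8),
    ReferenceCell("hub_NUP100_x_NQP", _N, 4405, 28, 10, "enrichment", 8.5e-4),
)

#: labels whose published depletion value does not recompute within a
#: factor of two under the inclusive lower tail P(X <= k) -- the printed
#: values for these cells are consistent only with mixed tail
#: conventions and 1-significant-figure rounding (see docs/methods.md)
KNOWN_DISCREPANT = frozenset(
    {
        "EPD_x_disordered_not_NQP",
        "EPN_x_disordered_not_NQP",
        "NQP_x_disordered_not_NQP",
        "EPD_nonhubs_x_PBD_not_NQP",
    }
)


def verify_printed_values(factor: float = 2.0) -> pd.DataFrame:
    """Recompute every reference P-value and compare with the print.

    Pass rule: recomputed within ``factor`` of the printed value; for
    bounded claims, strictly below the bound.  Cells printed only as
    non-significant pass when the recomputed value exceeds 0.05.
    """
    rows = []
    for cell in REFERENCE_CELLS:
        recomputed = cell.recompute()
        if cell.printed_p is None:
            ok = recomputed > 0.05
            ratio = float("nan")
        elif cell.bound:
            ok = recomputed < cell.printed_p
            ratio = recomputed / cell.printed_p
        else:
            ratio = recomputed / cell.printed_p
            ok = 1 / factor <= ratio <= factor
        rows.append(
            {
                "label": cell.label,
                "N": cell.N,
                "K": cell.K,
                "n": cell.n,
                "k": cell.k,
                "direction": cell.direction,
                "printed_p": cell.printed_p,
                "recomputed_p": recomputed,
                "ratio": ratio,
                "passes": ok,
            }
        )
    return pd.DataFrame(rows)
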