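"""Combine Boolean and linear-model call sets into final gene lists.

Only genes called hormone-responsive by BOTH methods survive.  Agreement on
G-protein independence keeps the independent label; disagreement on the
existence of G-protein regulation resolves to independent; only genes called
dependent by both methods are reported dependent.  Direction conflicts
between the two methods are dropped (with a logged count) rather than
resolved by either method alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .boolean_classifier import BooleanCallSet
from .io_core import GeneSet
from .moderated_de import LimmaCallSet

logger = logging.getLogger("abatrans")

#: provenance labels for the two-method cross subsectors.
PROVENANCE = (
    "both_independent",
    "boolean_dependent_limma_independent",
    "boolean_independent_limma_dependent",
    "both_dependent",
)

_IND = "gprotein_independent_aba"
_DEP = "gprotein_dependent_aba"


@dataclass
class FinalCall:
    category: str       # gprotein_independent_aba | gprotein_dependent_aba
    direction: str      # induced | repressed | conflict
    provenance: str


@dataclass
class FinalCallSet:
    calls: dict[str, FinalCall]
    n_direction_conflicts: int = 0

    def genes(self, category: str | None = None) -> set[str]:
        if category is None:
            return set(self.calls)
        return {g for g, c in self.calls.items() if c.category == category}

    def directed(self) -> dict[str, str]:
        """gene -> direction, excluding direction conflicts."""
        return {
            g: c.direction for g, c in self.calls.items() if c.direction != "conflict"
        }


def finalize_calls(boolean: BooleanCallSet, limma: LimmaCallSet) -> FinalCallSet:
    """Intersect the two methods' hormone calls per the cross-table rules."""
    calls: dict[str, FinalCall] = {}
    n_conflicts = 0
    for gene in boolean.aba_called & limma.aba_called:
        b, l = boolean.calls[gene], limma.calls[gene]
        if b.category == _IND and l.category == _IND:
            category, provenance = _IND, "both_independent"
        elif b.category == _DEP and l.category == _DEP:
            category, provenance = _DEP, "both_dependent"
        elif b.category == _DEP:
            category, provenance = _IND, "boolean_dependent_limma_independent"
        else:
            category, provenance = _IND, "boolean_independent_limma_dependent"
        if b.direction == l.direction:
            direction = b.direction
        else:
            direction = "conflict"
            n_conflicts += 1
        calls[gene] = FinalCall(category, direction, provenance)
    if n_conflicts:
        logger.warning("%d gene(s) with conflicting direction between methods", n_conflicts)
    return FinalCallSet(calls, n_conflicts)


def split_direction(final: FinalCallSet, name: str = "final") -> tuple[GeneSet, GeneSet]:
    """Disjoint induced/repressed sets; direction conflicts dropped with warning."""
    induced, repressed = set(), set()
    n_dropped = 0
    for gene, call in final.calls.items():
        if call.direction == "induced":
            induced.add(gene)
        elif call.direction == "repressed":
            repressed.add(gene)
        else:
            n_dropped += 1
    if n_dropped:
        logger.warning("%d gene(s) dropped from direction split (conflicts)", n_dropped)
    return (
        GeneSet(f"{name}_induced", induced, "induced"),
        GeneSet(f"{name}_repressed", repressed, "repressed"),
    )


@dataclass
class TissueComparison:
    common_induced: GeneSet
    common_repressed: GeneSet
    opposite: GeneSet
    only_a: GeneSet
    only_b: GeneSet


def cross_tissue_compare(gc: FinalCallSet, lf: FinalCallSet) -> TissueComparison:
    """Partition the union of two tissues' directed calls by direction match."""
    a, b = gc.directed(), lf.directed()
    common = set(a) & set(b)
    common_induced = {g for g in common if a[g] == b[g] == "induced"}
    common_repressed = {g for g in common if a[g] == b[g] == "repressed"}
    opposite = {g for g in common if a[g] != b[g]}
    return TissueComparison(
        GeneSet("common_induced", common_induced, "induced"),
        GeneSet("common_repressed", common_repressed, "repressed"),
        GeneSet("opposite", opposite),
        GeneSet("tissue_a_only", set(a) - set(b)),
        GeneSet("tissue_b_only", set(b) - set(a)),
    )


def concordance_rate(calls_a: dict, calls_b: dict) -> float:
    """Percent agreement between two label maps over identical keys.

    Reported to one decimal, e.g. 32 matches out of 34 comparisons -> 94.1.
    """
    if not calls_a:
        raise ValueError("cannot compute concordance of empty call maps")
    if set(calls_a) != set(calls_b):
        raise ValueError("call maps must cover the same (gene, tissue) keys")
    matches = sum(1 for k in calls_a if calls_a[k] == calls_b[k])
    return round(100.0 * matches / len(calls_a), 1)
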