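"""Gene-set overlap statistics.

Representation factor RF = |A ∩ B| / (|A||B|/N) — observed overlap over the
overlap expected for independent sets of the same sizes drawn from an
N-gene universe — with an upper-tail hypergeometric P, pairwise matrices
across many experiments, and core-set (present in >= k experiments)
analysis with the full cumulative curve.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from scipy import stats

from .io_core import GeneSet


@dataclass
class OverlapResult:
    name_a: str
    name_b: str
    size_a: int
    size_b: int
    overlap: int
    universe_size: int
    rf: float
    p_value: float
    pct_of_a: float
    pct_of_b: float
    pct_of_min: float
    is_self: bool = False


def _validate(a: GeneSet, b: GeneSet, n_universe: int) -> None:
    if n_universe < len(a.genes | b.genes):
        raise ValueError(
            f"universe size {n_universe} smaller than |A ∪ B| = {len(a.genes | b.genes)}"
        )


def _overlap(a: GeneSet, b: GeneSet, n_universe: int, is_self: bool = False) -> OverlapResult:
    _validate(a, b, n_universe)
    k = len(a.genes & b.genes)
    expected = len(a) * len(b) / n_universe
    rf = k / expected if expected > 0 else 0.0
    if k == 0:
        rf, p = 0.0, 1.0
    else:
        p = float(stats.hypergeom.sf(k - 1, n_universe, len(a), len(b)))
    small = min(len(a), len(b))
    return OverlapResult(
        a.name, b.name, len(a), len(b), k, n_universe, rf, p,
        100.0 * k / len(a) if len(a) else 0.0,
        100.0 * k / len(b) if len(b) else 0.0,
        100.0 * k / small if small else 0.0,
        is_self,
    )


def representation_factor(a: GeneSet, b: GeneSet, n_universe: int) -> OverlapResult:
    """Observed-over-expected overlap of two sets from an N-gene universe."""
    return _overlap(a, b, n_universe)


def overlap_pvalue(a: GeneSet, b: GeneSet, n_universe: int) -> OverlapResult:
    """Upper-tail hypergeometric P for the observed overlap (log-space via scipy)."""
    return _overlap(a, b, n_universe)


def pairwise_matrix(sets: list[GeneSet], n_universe: int) -> list[list[OverlapResult]]:
    """Symmetric matrix of overlap results; diagonal flagged not-a-comparison."""
    if len(sets) < 2:
        raise ValueError("pairwise matrix needs at least two sets")
    m = len(sets)
    matrix: list[list[OverlapResult]] = [[None] * m for _ in range(m)]  # type: ignore
    for i in range(m):
        for j in range(i, m):
            res = _overlap(sets[i], sets[j], n_universe, is_self=(i == j))
            matrix[i][j] = res
            matrix[j][i] = res
    return matrix


@dataclass
class CoreSetResult:
    membership: dict[str, int]       # gene -> number of experiments containing it
    cumulative: dict[int, int]       # k -> number of genes in >= k experiments


def core_sets(sets: list[GeneSet], k: int) -> tuple[GeneSet, CoreSetResult]:
    """Genes present in at least k of the given sets, plus the cumulative curve."""
    if not 1 <= k <= len(sets):
        raise ValueError(f"k must lie in 1..{len(sets)}")
    membership = Counter()
    for s in sets:
        membership.update(s.genes)
    cumulative = {
        j: sum(1 for c in membership.values() if c >= j)
        for j in range(1, len(sets) + 1)
    }
    core = {g for g, c in membership.items() if c >= k}
    return GeneSet(f"core_ge_{k}", core), CoreSetResult(dict(membership), cumulative)
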