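"""Degenerate motif scanning, enrichment, positional stats and k-mer discovery.

Patterns are written either as parenthesized alternations, e.g.
``(A/G)CCGAC``, or as plain/IUPAC letters.  Scanning is exact match on the
forward strand of the supplied upstream sequences (no inserts, no
mismatches; ``N`` never matches), with overlapping occurrences all reported.
Match coordinates are negative offsets from the transcription start site:
a start index ``i`` in a sequence of length ``L`` maps to position ``i - L``,
so the final base of the sequence sits at position -1.

Enrichment is gene-level (a gene either contains the motif or not) with an
upper-tail hypergeometric P against a universe of genes with available
promoter sequence; genes without a promoter are excluded from both margins.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_core import GeneSet, PromoterSet

logger = logging.getLogger("abatrans")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class MotifParseError(ValueError):
    pass


@dataclass(frozen=True)
class MotifPattern:
    source: str
    positions: tuple[frozenset[str], ...]

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def word_count(self) -> int:
        n = 1
        for s in self.positions:
            n *= len(s)
        return n

    def to_regex(self) -> str:
        parts = []
        for s in self.positions:
            letters = "".join(sorted(s))
            parts.append(letters if len(s) == 1 else f"[{letters}]")
        return "".join(parts)


_TOKEN = re.compile(r"\(([A-Za-z/]*)\)|([A-Za-z])|(.)")


def parse_motif(s: str) -> MotifPattern:
    """Parse ``(A/G)CCGAC``-style or IUPAC motif notation."""
    if not s:
        raise MotifParseError("empty motif string")
    if s.count("(") != s.count(")"):
        raise MotifParseError(f"unbalanced parentheses in motif {s!r}")
    positions: list[frozenset[str]] = []
    for group, letter, bad in _TOKEN.findall(s):
        if bad:
            raise MotifParseError(f"invalid character {bad!r} in motif {s!r}")
        if letter:
            letter = letter.upper()
            if letter not in IUPAC:
                raise MotifParseError(f"invalid letter {letter!r} in motif {s!r}")
            positions.append(frozenset(IUPAC[letter]))
        else:
            bases = [b.upper() for b in group.split("/") if b]
            if not bases:
                raise MotifParseError(f"empty group in motif {s!r}")
            if any(b not in "ACGT" for b in bases):
                raise MotifParseError(f"invalid base in group ({group}) of motif {s!r}")
            positions.append(frozenset(bases))
    return MotifPattern(s, tuple(positions))


@dataclass
class HitTable:
    """gene -> sorted match start positions in promoter coordinates.

    Covers every scanned gene, including zero-hit genes (empty lists), so the
    key set defines the scannable universe for enrichment.
    """

    hits: dict[str, list[int]]

    def genes_with_hit(self) -> set[str]:
        return {g for g, h in self.hits.items() if h}

    def total_hits(self) -> int:
        return sum(len(h) for h in self.hits.values())


def scan(promoters: PromoterSet, motif: MotifPattern | str) -> HitTable:
    """All exact-match start positions of the motif in each promoter."""
    if isinstance(motif, str):
        motif = parse_motif(motif)
    pattern = re.compile(f"(?=({motif.to_regex()}))")  # lookahead: overlaps allowed
    hits: dict[str, list[int]] = {}
    for gene, seq in promoters.records.items():
        length = len(seq)
        hits[gene] = [m.start() - length for m in pattern.finditer(seq)]
    return HitTable(hits)


@dataclass
class EnrichmentResult:
    motif: str
    n_foreground: int
    k_foreground: int
    n_universe: int
    k_universe: int
    p_value: float

    @property
    def foreground_fraction(self) -> float:
        return self.k_foreground / self.n_foreground if self.n_foreground else 0.0


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n); computed in log space by scipy."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrichment(fg: GeneSet, universe: GeneSet, hits: HitTable, motif: str = "") -> EnrichmentResult:
    """Gene-level hypergeometric enrichment of a motif in fg against universe."""
    if not fg.genes <= universe.genes:
        raise ValueError("foreground must be a subset of the universe")
    scannable = set(hits.hits)
    uni = universe.genes & scannable
    fgs = fg.genes & scannable
    n_excluded = len(universe.genes - scannable) + len(fg.genes - scannable)
    if n_excluded:
        logger.info("%d gene(s) without promoter excluded from enrichment margins", n_excluded)
    with_hit = hits.genes_with_hit()
    K = len(uni & with_hit)
    k = len(fgs & with_hit)
    p = hypergeom_upper_tail(k, len(uni), K, len(fgs))
    return EnrichmentResult(motif, len(fgs), k, len(uni), K, p)


@dataclass
class PositionalDistribution:
    bin_edges: np.ndarray    # e.g. -1000, -950, ..., 0
    counts: np.ndarray
    fractions: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def positional_distribution(
    hits: HitTable, genes: GeneSet, bin_size: int = 50, span: int = 1000
) -> PositionalDistribution:
    """Histogram of match start positions over [-span, 0) for a gene set."""
    if len(genes) == 0:
        raise ValueError("positional distribution requires a non-empty gene set")
    if span % bin_size != 0:
        raise ValueError("bin size must divide the promoter span")
    positions = [
        p for g in genes.genes for p in hits.hits.get(g, ()) if -span <= p < 0
    ]
    edges = np.arange(-span, 1, bin_size)
    counts, _ = np.histogram(positions, bins=edges)
    total = counts.sum()
    fractions = counts / total if total > 0 else np.zeros_like(counts, dtype=float)
    return PositionalDistribution(edges, counts, fractions)


# ---------------------------------------------------------------------------
# exhaustive k-mer discovery
# ---------------------------------------------------------------------------

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _gene_kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Distinct k-mer integer codes present in one encoded sequence."""
    if len(codes) < k:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win >= 0).all(axis=1)
    if not valid.any():
        return np.empty(0, dtype=np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return np.unique(win[valid] @ powers)


def _decode(code: int, k: int) -> str:
    bases = []
    for _ in range(k):
        bases.append("ACGT"[code % 4])
        code //= 4
    return "".join(reversed(bases))


def discover_kmers(
    fg: GeneSet,
    universe: GeneSet,
    promoters: PromoterSet,
    k_min: int = 5,
    k_max: int = 10,
    threshold_induced: float = 1.0e-10,
    threshold_repressed: float = 1.0e-4,
    direction: str = "induced",
) -> list[EnrichmentResult]:
    """Exhaustively test every k-mer, k_min <= k <= k_max, for enrichment.

    Streams one k at a time (the 4^k candidate space is never materialized as
    strings); returns results below the direction's raw P threshold sorted by
    P.  Gene-level counting throughout.
    """
    if k_min < 1 or k_max < k_min:
        raise ValueError("need 1 <= k_min <= k_max")
    if direction not in ("induced", "repressed"):
        raise ValueError("direction must be 'induced' or 'repressed'")
    if not fg.genes <= universe.genes:
        raise ValueError("foreground must be a subset of the universe")
    threshold = threshold_induced if direction == "induced" else threshold_repressed

    uni_genes = sorted(universe.genes & set(promoters.records))
    fg_genes = set(fg.genes) & set(promoters.records)
    n_excluded = len(universe.genes) - len(uni_genes)
    if n_excluded:
        logger.info("%d universe gene(s) without promoter excluded from discovery", n_excluded)
    N, n = len(uni_genes), len(fg_genes)
    if N == 0 or n == 0:
        raise ValueError("no scannable genes in universe or foreground")

    encoded = {g: _encode(promoters.records[g]) for g in uni_genes}
    results: list[EnrichmentResult] = []
    for k in range(k_min, k_max + 1):
        space = 4**k
        count_uni = np.zeros(space, dtype=np.int32)
        count_fg = np.zeros(space, dtype=np.int32)
        for g in uni_genes:
            present = _gene_kmer_codes(encoded[g], k)
            count_uni[present] += 1
            if g in fg_genes:
                count_fg[present] += 1
        candidates = np.nonzero(count_fg)[0]
        if len(candidates) == 0:
            continue
        kf = count_fg[candidates].astype(float)
        Ku = count_uni[candidates].astype(float)
        p = stats.hypergeom.sf(kf - 1, N, Ku, n)
        keep = p < threshold
        for code, kfi, Kui, pi in zip(
            candidates[keep], kf[keep], Ku[keep], p[keep]
        ):
            results.append(
                EnrichmentResult(_decode(int(code), k), n, int(kfi), N, int(Kui), float(pi))
            )
    results.sort(key=lambda r: (r.p_value, r.motif))
    return results


def specificity_call(
    motif: MotifPattern | str,
    own_set: GeneSet,
    merged_set: GeneSet,
    universe: GeneSet,
    promoters: PromoterSet,
    alpha: float = 1.0e-3,
) -> str:
    """Two-background tissue-specificity rule.

    ``specific``: enriched in own_set vs the genome universe, NOT enriched in
    the merged set vs the universe, and still enriched in own_set when the
    merged set itself is the background.  ``shared``: enriched in both own
    and merged sets vs the universe.  ``not_enriched`` otherwise.
    """
    if isinstance(motif, str):
        motif = parse_motif(motif)
    if not own_set.genes <= universe.genes or not merged_set.genes <= universe.genes:
        raise ValueError("own and merged sets must be subsets of the universe")
    hits = scan(promoters, motif)
    p_own = enrichment(own_set, universe, hits, motif.source).p_value
    p_merged = enrichment(merged_set, universe, hits, motif.source).p_value
    if p_own >= alpha:
        return "not_enriched"
    if p_merged < alpha:
        return "shared"
    outside = own_set.genes - merged_set.genes
    if outside:
        # the merged background rarely contains the own set; augment it so
        # the foreground stays a subset of the universe of the third test
        logger.info(
            "%d own-set gene(s) outside the merged background; third test "
            "runs against merged + own",
            len(outside),
        )
    background = GeneSet("merged_bg", merged_set.genes | own_set.genes)
    p_third = enrichment(own_set, background, hits, motif.source).p_value
    return "specific" if p_third < alpha else "not_enriched"
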