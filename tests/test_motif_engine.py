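import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abatrans import motif_engine as me
from abatrans import synthetic_data as sd
from abatrans.io_core import GeneSet, PromoterSet


class TestParseMotif:
    def test_alternation_groups(self):
        p = me.parse_motif("(A/G)CCGAC")
        assert [set(s) for s in p.positions] == [
            {"A", "G"}, {"C"}, {"C"}, {"G"}, {"A"}, {"C"},
        ]
        assert p.word_count == 2

    def test_word_count_product(self):
        assert me.parse_motif("(C/G/T)ACGTG(G/T)(A/C)").word_count == 12

    def test_plain_word_singletons(self):
        p = me.parse_motif("CCGAC")
        assert all(len(s) == 1 for s in p.positions)
        assert p.word_count == 1

    def test_iupac_letters(self):
        assert me.parse_motif("RCCGAC").positions[0] == frozenset("AG")
        assert me.parse_motif("NAC").positions[0] == frozenset("ACGT")

    @pytest.mark.parametrize("bad", ["", "(A/G", "()CC", "(A/X)C", "AC%G"])
    def test_parse_errors(self, bad):
        with pytest.raises(me.MotifParseError):
            me.parse_motif(bad)


def naive_scan(seq, pattern):
    """Position-by-position oracle, independent of the regex implementation."""
    L, m = len(seq), len(pattern.positions)
    out = []
    for start in range(L - m + 1):
        if all(seq[start + j] in pattern.positions[j] for j in range(m)):
            out.append(start - L)
    return out


class TestScan:
    def test_single_match_coordinates(self):
        hits = me.scan(PromoterSet({"X": "TTCCGACGT"}), "CCGAC")
        assert hits.hits["X"] == [-7]

    def test_degenerate_mismatch(self):
        hits = me.scan(PromoterSet({"X": "TTCCGACGT"}), "(A/G)CCGAC")
        assert hits.hits["X"] == []

    def test_tandem_and_overlapping_matches(self):
        assert me.scan(PromoterSet({"X": "CCGACCGAC"}), "CCGAC").hits["X"] == [-9, -5]
        assert me.scan(PromoterSet({"X": "CCCGACCGAC"}), "CGACC").hits["X"] == [-8]
        # self-overlapping pattern: both occurrences reported
        assert me.scan(PromoterSet({"X": "AAAA"}), "AAA").hits["X"] == [-4, -3]

    def test_n_never_matches(self):
        assert me.scan(PromoterSet({"X": "CCNAC"}), "CCNAC").hits["X"] == []
        assert me.scan(PromoterSet({"X": "CCGAC"}), "CCNAC").hits["X"] == [-5]

    def test_motif_longer_than_sequence(self):
        assert me.scan(PromoterSet({"X": "ACG"}), "ACGTACGT").hits["X"] == []

    def test_zero_hit_genes_still_present(self):
        hits = me.scan(PromoterSet({"X": "AAAA", "Y": "CCGAC"}), "CCGAC")
        assert set(hits.hits) == {"X", "Y"}
        assert hits.genes_with_hit() == {"Y"}

    @settings(max_examples=40, deadline=None)
    @given(
        st.text(alphabet="ACGTN", min_size=0, max_size=60),
        st.sampled_from(["CCGAC", "(A/G)CCGAC", "RYSW", "AA", "CACATG"]),
    )
    def test_matches_naive_oracle(self, seq, motif):
        pattern = me.parse_motif(motif)
        assert me.scan(PromoterSet({"X": seq}), pattern).hits["X"] == naive_scan(seq, pattern)


def oracle_upper_tail(k, N, K, n):
    """Exact upper tail by subset enumeration (N <= 10) or rational comb sum."""
    if N <= 10:
        hit_mask = (1 << K) - 1  # first K universe genes carry the motif
        total = hits_ge = 0
        for subset in itertools.combinations(range(N), n):
            total += 1
            count = sum(1 for g in subset if (1 << g) & hit_mask)
            hits_ge += count >= k
        return Fraction(hits_ge, total)
    num = sum(
        Fraction(math.comb(K, i) * math.comb(N - K, n - i))
        for i in range(k, min(n, K) + 1)
    )
    return num / math.comb(N, n)


class TestEnrichment:
    def _fixture(self, N, K, n, k):
        universe = GeneSet("u", {f"G{i}" for i in range(N)})
        hits = me.HitTable(
            {f"G{i}": ([-5] if i < K else []) for i in range(N)}
        )
        fg_genes = {f"G{i}" for i in range(k)} | {
            f"G{i}" for i in range(K, K + (n - k))
        }
        return GeneSet("fg", fg_genes), universe, hits

    def test_enumeration_example(self):
        # N=10, K=4, n=3, k=3 -> 4/120
        fg, universe, hits = self._fixture(10, 4, 3, 3)
        res = me.enrichment(fg, universe, hits, "m")
        assert res.p_value == pytest.approx(4 / 120)
        assert res.p_value == pytest.approx(float(oracle_upper_tail(3, 10, 4, 3)))

    def test_k_zero_gives_one(self):
        fg, universe, hits = self._fixture(10, 4, 3, 0)
        assert me.enrichment(fg, universe, hits).p_value == 1.0

    def test_fg_equals_universe(self):
        universe = GeneSet("u", {f"G{i}" for i in range(6)})
        hits = me.HitTable({f"G{i}": ([-3] if i < 2 else []) for i in range(6)})
        res = me.enrichment(universe, universe, hits)
        assert res.k_foreground == res.k_universe
        assert res.p_value == pytest.approx(1.0)

    def test_fg_not_subset_rejected(self):
        universe = GeneSet("u", {"A"})
        with pytest.raises(ValueError, match="subset"):
            me.enrichment(GeneSet("fg", {"B"}), universe, me.HitTable({"A": []}))

    def test_promoterless_genes_excluded_from_both_margins(self):
        universe = GeneSet("u", {"A", "B", "C", "D"})
        fg = GeneSet("fg", {"A", "D"})
        hits = me.HitTable({"A": [-3], "B": [], "C": [-2]})  # D unscanned
        res = me.enrichment(fg, universe, hits)
        assert res.n_universe == 3 and res.n_foreground == 1
        assert res.k_universe == 2 and res.k_foreground == 1


class TestPositionalDistribution:
    def test_single_bin(self):
        hits = me.HitTable({f"G{i}": [-75] for i in range(5)})
        genes = GeneSet("g", {f"G{i}" for i in range(5)})
        dist = me.positional_distribution(hits, genes)
        bin_idx = int(np.where(dist.bin_edges[:-1] == -100)[0][0])
        assert dist.counts[bin_idx] == 5
        assert dist.fractions[bin_idx] == 1.0

    def test_counts_conserved(self):
        rng = np.random.default_rng(20)
        hits = me.HitTable(
            {f"G{i}": sorted(rng.integers(-1000, 0, rng.integers(0, 5)).tolist()) for i in range(50)}
        )
        genes = GeneSet("g", {f"G{i}" for i in range(50)})
        dist = me.positional_distribution(hits, genes)
        assert dist.total == hits.total_hits()
        assert dist.fractions.sum() == pytest.approx(1.0)

    def test_uniform_positions_flat(self):
        rng = np.random.default_rng(21)
        positions = rng.integers(-1000, 0, 10_000)
        hits = me.HitTable({"G0": positions.tolist()})
        dist = me.positional_distribution(hits, GeneSet("g", {"G0"}))
        from scipy import stats as ss

        chi2, p = ss.chisquare(dist.counts)
        assert p > 0.01

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError):
            me.positional_distribution(me.HitTable({}), GeneSet("g", set()))

    def test_bad_bin_rejected(self):
        with pytest.raises(ValueError, match="divide"):
            me.positional_distribution(
                me.HitTable({"G0": [-1]}), GeneSet("g", {"G0"}), bin_size=33
            )


class TestDiscoverKmers:
    def test_planted_word_recovered(self):
        cfg = sd.PromoterSimConfig(
            n_genes=400,
            n_foreground=60,
            length=200,
            plant_spec=[sd.PlantSpec("GTCGG", 0.6, 0.05)],
            seed=22,
        )
        promoters, _ = sd.simulate_promoters(cfg)
        universe = GeneSet("u", set(promoters.records))
        fg = GeneSet("fg", set(sd.foreground_ids(cfg)))
        results = me.discover_kmers(fg, universe, promoters, k_min=5, k_max=5)
        assert results, "no motifs found"
        assert "GTCGG" in {r.motif for r in results}

    def test_kmer_counting_matches_scan(self):
        cfg = sd.PromoterSimConfig(n_genes=50, n_foreground=0, length=120, seed=23)
        promoters, _ = sd.simulate_promoters(cfg)
        universe = GeneSet("u", set(promoters.records))
        fg = GeneSet("fg", set(list(promoters.records)[:10]))
        results = me.discover_kmers(
            fg, universe, promoters, k_min=5, k_max=5, threshold_induced=1.1, direction="induced"
        )
        by_motif = {r.motif: r for r in results}
        for word in ("GTCGG", "ACGTA", "CCGAC"):
            hits = me.scan(promoters, word)
            with_hit = hits.genes_with_hit()
            k_fg = len(with_hit & fg.genes)
            if k_fg == 0:
                assert word not in by_motif or by_motif[word].k_foreground == 0
                continue
            assert by_motif[word].k_universe == len(with_hit)
            assert by_motif[word].k_foreground == k_fg
            expected = me.hypergeom_upper_tail(k_fg, 50, len(with_hit), 10)
            assert by_motif[word].p_value == pytest.approx(expected)

    def test_no_planting_rarely_significant(self):
        n_sig = 0
        for seed in range(5):
            cfg = sd.PromoterSimConfig(n_genes=200, n_foreground=20, seed=seed)
            promoters, _ = sd.simulate_promoters(cfg)
            universe = GeneSet("u", set(promoters.records))
            fg = GeneSet("fg", set(sd.foreground_ids(cfg)))
            results = me.discover_kmers(fg, universe, promoters, k_min=5, k_max=5)
            n_sig += bool(results)
        assert n_sig == 0

    def test_decode_encode_round_trip(self):
        for word in ("AAAAA", "GTCGG", "TTTTT", "ACGTACGTAC"):
            codes = me._gene_kmer_codes(me._encode(word), len(word))
            assert me._decode(int(codes[0]), len(word)) == word

    def test_bad_k_rejected(self):
        promoters = PromoterSet({"A": "ACGT"})
        gs = GeneSet("g", {"A"})
        with pytest.raises(ValueError):
            me.discover_kmers(gs, gs, promoters, k_min=0, k_max=5)
        with pytest.raises(ValueError):
            me.discover_kmers(gs, gs, promoters, k_min=6, k_max=5)


class TestSpecificityCall:
    def _setup(self, plant_in, seed):
        """800 genes; own set = first 40, merged = next 200 (disjoint from own)."""
        cfg = sd.PromoterSimConfig(n_genes=800, n_foreground=0, length=200, seed=seed)
        promoters, _ = sd.simulate_promoters(cfg)
        ids = sorted(promoters.records)
        own = GeneSet("own", set(ids[:40]))
        merged = GeneSet("merged", set(ids[40:240]))
        universe = GeneSet("u", set(ids))
        rng = np.random.default_rng(seed)
        records = dict(promoters.records)
        for g in plant_in:
            seq = records[g]
            pos = int(rng.integers(0, len(seq) - 5))
            records[g] = seq[:pos] + "GTCGG" + seq[pos + 5 :]
        return own, merged, universe, PromoterSet(records)

    def test_own_only_planting_is_specific(self):
        own, merged, universe, promoters = self._setup(
            plant_in=[f"PRM{i + 1:05d}" for i in range(40)], seed=24
        )
        assert (
            me.specificity_call("GTCGG", own, merged, universe, promoters) == "specific"
        )

    def test_merged_wide_planting_is_shared(self):
        own, merged, universe, promoters = self._setup(
            plant_in=[f"PRM{i + 1:05d}" for i in range(240)], seed=25
        )
        assert me.specificity_call("GTCGG", own, merged, universe, promoters) == "shared"

    def test_unplanted_not_enriched(self):
        for seed in range(5):
            own, merged, universe, promoters = self._setup(plant_in=[], seed=seed)
            assert (
                me.specificity_call("GTCGG", own, merged, universe, promoters)
                == "not_enriched"
            )


class TestWordSetMonotonicity:
    def test_specializing_a_pattern_never_gains_genes(self):
        cfg = sd.PromoterSimConfig(
            n_genes=300, n_foreground=300, plant_spec=[sd.PlantSpec("GCCGAC", 0.3)], seed=26
        )
        promoters, _ = sd.simulate_promoters(cfg)
        broad = me.scan(promoters, "CCGAC").genes_with_hit()
        narrow = me.scan(promoters, "(A/G)CCGAC").genes_with_hit()
        narrower = me.scan(promoters, "GCCGAC").genes_with_hit()
        assert narrow <= broad
        assert narrower <= narrow
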