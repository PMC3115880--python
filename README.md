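# abatrans

Analysis pipeline for factorial hormone-treatment microarray designs
(2 tissues x 4 genotypes x 2 treatments x replicates):

- **boolean_classifier** — classifies genes against idealized 0/1 expression
  templates of the composed form `B(ABA, A(GPA1, AGB1))` over the 8
  genotype x treatment conditions, scoring each gene by Pearson correlation
  times log2 amplitude, with a permutation-based FDR estimate.  The scoring
  function is a reconstruction (`r * |delta|`); the original method's exact
  measure is not published alongside it.
- **moderated_de** — per-gene cell-means OLS for the 2 x 4 factorial,
  empirical-Bayes variance moderation (moments on log s²), moderated-t
  contrasts (treated-vs-control wild type; mutants vs wild type under each
  treatment) and Benjamini-Hochberg adjustment.
- **integration** — intersects the two call sets (disagreement on the
  existence of G-protein regulation resolves to "independent"; "dependent"
  requires both methods), splits by direction, compares tissues, and
  computes concordance rates against external direction calls.
- **motif_engine** — degenerate-pattern parsing (`(A/G)CCGAC`, IUPAC),
  exact-match forward-strand scanning of upstream regions with TSS-relative
  coordinates, gene-level hypergeometric enrichment, 50-bp positional
  distributions, exhaustive 5–10-mer discovery with direction-specific raw-P
  thresholds, and a two-background tissue-specificity rule.
- **overlap_stats** — representation factor (observed/expected overlap),
  hypergeometric overlap P, pairwise matrices, and core-set (≥ k
  experiments) analysis with cumulative curves.
- **synthetic_data** — expression matrices with planted Boolean regulatory
  modes, promoter sets with planted motif words, and study-set collections
  with a planted shared core, so the whole pipeline is testable offline.
- **io_core** — data model plus readers/writers for TSV matrices/designs,
  upstream FASTA (splice suffixes stripped), and gene lists.

## CLI

```sh
abatrans simulate --config cfg.yaml --seed 1 --out sim/
abatrans classify-boolean --matrix sim/matrix.tsv --design sim/design.tsv \
    --threshold 1.5 --n-perm 100 --seed 1 --out bool.json
abatrans de --matrix sim/matrix.tsv --design sim/design.tsv --out limma.json
abatrans integrate --boolean bool.json --limma limma.json --out final.json
abatrans scan-motifs --fasta up.fa --motif "(A/G)CCGAC" \
    --fg fg.txt --universe all.txt --out enr.json
abatrans discover-motifs --fasta up.fa --fg fg.txt --universe all.txt \
    --kmin 5 --kmax 10 --direction induced --out motifs.tsv
abatrans position-dist --fasta up.fa --motif CCGAC --genes fg.txt --bin 50 --out pos.tsv
abatrans overlap --sets a.txt --sets b.txt --universe-size 22000 --out ov.json
abatrans core-sets --sets a.txt --sets b.txt --sets c.txt --min-count 2 --out core.tsv
```

The `simulate` YAML config has two optional blocks, `experiment:` (keyword
arguments of `synthetic_data.SimConfig`) and `promoters:`
(`PromoterSimConfig`, with `plant_spec` as a list of
`{word, foreground_fraction, background_fraction, window}` entries).

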