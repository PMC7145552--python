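# tecisreg

Transposable elements (TEs) are a major source of new *cis*-regulatory
sequence: when a retrotransposon family carries a transcription-factor
binding motif in its consensus, every copy it pastes into the genome is a
potential binding site.  `tecisreg` is a pipeline for quantifying this
process from ChIP-seq peak summits and a RepeatMasker annotation, built
around the biology of estrogen receptor α (ERα) and its pioneer factors
(FoxA1, GATA3, AP2γ) in mammary cells, but applicable to any factor set.

It answers, stage by stage:

1. **Which TE families are enriched for binding?**  For each family with
   genomic fraction *p* and a factor with *n* summits of which *k* fall
   inside the family's copies, a two-tailed binomial test (minimum-
   likelihood convention, as in R's `binom.test`) with Bonferroni
   correction over all family × factor pairs.
2. **Where on the consensus do the sites sit?**  Each in-TE summit is
   projected through the copy's RepeatMasker `.align` alignment onto the
   subfamily consensus, binned into 100 bins, and normalized by the number
   of copies covering each consensus site — correcting for 5′ truncation
   of LINEs, which otherwise inflates 3′ counts.  Positional uniformity is
   tested over 10 segments (exact Monte-Carlo multinomial for 30–100
   events, χ² above 100), and binding-peak regions are scanned for JASPAR
   motifs with exact lattice-DP p-values (FIMO-style).
3. **Are the bound copies functional?**  Conservation and DNase
   accessibility meta-profiles (±400 bp, 10-bp smoothing) against matched
   random in-TE sites (Welch *t*-test), TSS distances, read-coverage
   matrices normalized to a fixed subsampled read count, and chromatin-
   state proportions from a segmentation.
4. **When did each site arise?**  A 10-bp window around every summit is
   lifted through per-species chain files; the most distantly related
   species with a surviving ortholog fixes the clade of origin, capped by
   the known phylogenetic range of the host TE subfamily.
   Divergence-from-consensus histograms give the complementary age axis.
5. **Do factors co-occupy the same copies, and where do bound TEs
   cluster?**  Conditional χ² colocalization per TE category, and a
   100-kb/50-kb sliding-window density scan that locates the densest locus
   of factor-bound TEs.

A fully self-consistent synthetic-genome generator (`tecisreg simulate`)
emits genome FASTA, `.out`/`.align` annotation, narrowPeak summits, signal
tracks, per-species chains, tree and taxonomy — with a ground-truth
manifest — so the entire pipeline is testable end to end without any
download.

## Worked example

Generate a toy genome (two chromosomes, five TE subfamilies, four factors,
an ERα-like motif planted in three subfamily consensi) and test which
subfamilies are enriched for ERα summits:

```sh
$ tecisreg simulate --seed 4 --preset small --out demo
bundle written to demo (audit passed)

$ tecisreg enrich --summits demo/summits_ERa.narrowPeak --factor ERa \
    --rmsk demo/rmsk.out --genome demo/sizes.tsv --taxonomy demo/taxonomy.tsv
group     factor  k   n    fraction  fold    p_raw      p_bonf
L2_toy    ERa     26  100  0.059468  4.372   1.223e-10  6.117e-10
ERV1_toy  ERa     16  100  0.04      4       2.35e-06   1.175e-05
MIR_toy   ERa     14  100  0.039     3.59    3.522e-05  0.0001761
AluY_toy  ERa     2   100  0.0522    0.3831  0.1789     0.8947
L1_toy    ERa     6   100  0.101558  0.5908  0.2431     1
```

The three motif-bearing subfamilies (L2_toy, ERV1_toy, MIR_toy) are
recovered as significantly enriched: e.g. 26 of 100 ERα summits fall in
L2_toy copies although the subfamily covers only 5.9% of the genome — a
4.4-fold enrichment, Bonferroni-corrected p ≈ 6×10⁻¹⁰.  The two families
without a planted motif (AluY_toy, L1_toy) attract summits only at the
background rate.  `tecisreg run --config run.yaml` executes all remaining
stages (consensus profiles, motif scans, conservation, origin dating,
colocalization, density) and writes one TSV per stage plus a run record.

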