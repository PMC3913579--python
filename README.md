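# tnscreen

High-throughput screening of a transposon mutant library on the genomic and
metabolic level, as a tested, reusable pipeline. The package targets
microbial functional-genomics groups who combine two assays over the same
mutant collection of *Corynebacterium glutamicum*-style organisms:

1. **Insertion-site mapping** — each mutant's transposon insertion
   coordinate (or an exactly locatable flank sequence) is placed on the
   genome annotation and classified as a gene hit or intergenic, with
   library-level summaries (gene-hit rate vs coding density, operon /
   hypothetical / investigated fractions) and a chi-square test of
   genome-wide insertion uniformity.
2. **GC/MS metabolic profiling** — per-sample peak tables are turned into a
   cross-experiment comparable metabolite × sample matrix and screened for
   mutants with pathway-level metabolic changes.

Because raw data for such studies are rarely deposited, the package ships a
first-class synthetic-data generator that emulates the full study design
(45 wild-type samples, six pooled-extract quality standards per experiment,
mutant triplicates over seven experiments, ribitol internal standard, 1–3
derivative peaks per metabolite, log-normal noise with batch effects,
planted fold-changes and correlated metabolite blocks) so every stage is
testable against known ground truth.

## The processing and screening model

Peak areas go through the chain

1. unlabeled peaks are matched across samples by retention index
   (RI = 100·(n + (rt − t_n)/(t_{n+1} − t_n)) from an n-alkane ladder) and
   named `NA_<RI>`;
2. derivative areas are summed per metabolite;
3. non-biological peaks are eliminated with blanks (mean biological area
   < 3 × mean blank area);
4. areas are normalized by culture OD and the ribitol internal standard:
   a → a / (OD · a_ribitol);
5. metabolites quantified in under 80% of an experiment's samples are
   discarded there;
6. per experiment, each metabolite row is divided by its median, then each
   sample column by its median (after which every sample's median is 1).

Per mutant *g* and metabolite *m*, the screen computes the mean-based fold
change R = x̄_g / x̄_WT and a log2 median-based ratio, tests
log-transformed areas with a two-sample Student's t-test (mutant n = 3 vs
the 45-sample wild-type reference), and flags significance at the
Bonferroni level p ≤ α/m with α = 0.01 and m the number of metabolites
tested for that mutant. Mutant profiles are summarized by the Pearson
correlation of log mean peak areas against the wild type and a growth group
(%OD bins: [0,40) minimal, [40,80) reduced, [80,120] similar, >120
enhanced). Across mutants, metabolite–metabolite Pearson correlations of
the log2 median ratios (metabolites at >95% reproducibility over all
samples) give a correlation matrix and an average-linkage dendrogram on
Euclidean distances between correlation rows; the pathway pattern screen
selects mutants with ≥2 Bonferroni-significant metabolites in a predefined
set (TCA cycle, glutamate-associated).

## Worked example

```sh
python analysis/01_simulate_study.py   # synthetic study -> scratch/fixture
python analysis/02_map_insertions.py
python analysis/03_process_peaks.py
python analysis/04_qc_reference.py
python analysis/05_screen_mutants.py
```

prints, among other lines:

```
     sample_type  count
          mutant    774
        wildtype     45
quality_standard     42
coding density 0.870; gene-hit rate 83% — uniform-insertion chi2 p = 0.827
overall relative error over 42 quality-standard samples: 11.5%
pathway screen: 25 mutants selected (TCA 18, GLU 14, both 7)
correlation matrix: 37 metabolites (pairwise r range -0.59..0.63)
median profile correlation to wild type: 0.995
```

Reading: 258 mutants in triplicate plus reference and quality samples give
861 profiled injections. The 83% gene-hit rate sits within binomial noise
of the 87% coding density, the signature of unbiased transposition. The
11.5% mean relative error across pooled-extract quality standards is the
technical precision of the whole chain (it equals the generator's
configured technical CV, i.e. the processing adds no artificial variance).
The pathway screen recovers the 15 planted affected mutants plus a handful
drawn in by the correlated-block biological variability; per-mutant tables
are written to `results/screen_report.tsv`, the correlation matrix and
Newick dendrogram alongside it.

The same pipeline runs from the command line (`tnscreen simulate`,
`tnscreen run-all --fixture ... --out ...`) or on real data arranged in the
same plain-text formats (GFF3 annotation, one peak TSV per sample, sample
metadata TSV).

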