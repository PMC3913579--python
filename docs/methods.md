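# Methods

## Study design being modelled

The pipeline models a two-layer screen of a random transposon mutant
library in a *C. glutamicum*-type organism. Layer one locates each mutant's
insertion on the circular chromosome; layer two measures GC/MS metabolic
profiles of randomly chosen mutants (three biological replicates each)
against a wild-type reference of 45 samples, with six pooled-extract
quality standards and two blanks per experiment. The default synthetic
study uses 258 mutants spread over seven experiments — seven because six
quality standards per experiment and 42 quality-standard samples in total
imply seven batches — for 861 biological injections plus 14 blanks.

## Insertion mapping

Gene intervals are 1-based and inclusive on both ends (GFF3 convention);
boundary positions count as hits. The annotation loader rejects overlapping
genes so the hit/intergenic partition is total and unambiguous. Intergenic
insertions report the nearest gene whose translational start lies
downstream along that gene's own reading direction — the start coordinate
for + strand genes, the end coordinate for − strand genes — searching both
strands circularly and taking the smaller distance (ties favour the +
strand). This is the promoter-damage interpretation: an insertion a few
dozen bases upstream of a start codon can silence the gene without hitting
it. Flank sequences are located by unique exact match of the flank or its
reverse complement; multiple matches are ambiguous and leave the mutant
unidentified rather than guessing. Library percentages follow two
denominators: the gene-hit rate is relative to located insertions, while
operon/hypothetical/investigated rates are relative to gene hits;
percentages are reported rounded to integers. `investigated` is an input
flag carried through from the annotation, not computed.

Uniformity of insertion density uses a chi-square goodness-of-fit over
equal-width circular bins (default 50). With expected counts below 5 per
bin a warning is raised but the statistic is still returned.

## Peak processing chain

The order of operations is: unknown matching → derivative aggregation →
blank elimination → OD/internal-standard normalization → reproducibility
filter → two-step median normalization. Blank elimination operates on the
aggregated metabolite matrix (blanks carry no OD, so the comparison uses
raw areas): a metabolite is non-biological when its mean area over
biological samples is below `blank_ratio` (default 3) times its mean over
blanks, with missing values counted as zero (absence of detection). The
threshold is a parameter because "eliminated by the aid of blanks" admits
several rules; 3× is a common field choice. The ribitol internal standard
is spiked into blanks as well and is exempt from the filter; it is removed
from the matrix at the normalization step after its area is recorded per
sample.

Retention indices interpolate linearly between bracketing alkanes and are
exact at the nodes; no extrapolation by default (a flag enables linear
extension of the terminal segments). Unknown peaks are matched across
samples by single-linkage grouping of retention indices with a gap
tolerance of ±2 RI units (the matching window of automated GC/MS software
is typically 1–5 units; 2 separates the default catalog's unknowns by two
orders of magnitude relative to their RI jitter). Each group is named
`NA_<mean RI>` with one decimal.

Reproducibility of a metabolite in a sample group is the fraction of
samples where it is quantified (present and positive). The 80% filter is
strictly below-threshold ("under 80%" keeps exactly 80%) and applies per
experiment — a metabolite can be discarded in one experiment and kept in
another; the stricter 95% variant applies globally and gates the
correlation analysis. Median normalization runs per experiment (its purpose
is cross-experiment compatibility): rows are divided by their
within-experiment median, then columns by their within-metabolite median;
missing values are ignored by the medians and preserved. A metabolite row
with no quantified value inside an experiment — the legitimate product of
the per-experiment filter — is left missing there; a sample column with no
quantified metabolite is an error, since the sample median would be
undefined. After the two steps every sample's median is exactly 1, and the
whole chain is invariant to rescaling all peaks of one sample (the factor
cancels through the internal standard and the sample median). Missing
values are never imputed; all downstream statistics are available-case.

## Statistics

**Technical precision.** Per metabolite, the relative error is the
coefficient of variation (sample SD / mean) — the standard metabolomics
reading of "relative standard error"; a flag switches to SEM/mean. The
overall figure is the unweighted mean CV of identified (non-`NA_`)
metabolites over the pooled quality standards of all experiments.

**Mutant tests.** Fold changes are mean-based for reporting and
median-based (log2) for the correlation stage; the median of three
log-normal replicates is exactly median-unbiased on the log scale, which
keeps the log2 ratios unbiased. Significance uses a two-sample t-test on
log-transformed areas — the log scale matches the multiplicative error
structure of GC/MS areas — with pooled variance by default (the classical
Student form; both groups share the technical-noise variance by design).
The Welch unequal-variance form is available via `equal_var=False`, but
note that with n = 3 replicates its degrees of freedom collapse to ≈2 and
the attainable p-values cannot pass a Bonferroni threshold of 0.01/37; the
pooled form with df = n₁+n₂−2 is both the classical reading and the one
with usable power at triplicate scale. The Bonferroni family is per mutant
(m = metabolites tested for that mutant) by default; a global-m variant is
a flag. Degenerate inputs (both groups constant) give p = 1 when means
agree and p = 0 otherwise; metabolites with fewer than two quantified
values in either group are untested and never significant.

**Profile correlation.** The per-mutant Pearson correlation against the
wild type uses log mean peak areas from the matrix *before* median
normalization: that matrix still carries the metabolite abundance
hierarchy spanning ~3 orders of magnitude, which is what makes wild-type-
like profiles correlate at 0.92–0.99. After median normalization every
metabolite sits near 1 and the statistic would degenerate to noise
correlation. The log base is irrelevant (Pearson is scale-invariant).

**Metabolite correlation and clustering.** Pairwise Pearson correlations of
log2 median ratios across mutants use pairwise-complete observations with
at least 3 shared mutants; sparser pairs are missing, and the dendrogram
refuses missing entries (raise the reproducibility threshold instead of
silently imputing). Clustering is agglomerative with average linkage
(unspecified in the emulated protocol; average linkage is the common
default for correlation heatmaps and is selectable) on Euclidean distances
between rows of the correlation matrix, i.e. each metabolite is represented
by its correlation vector to all metabolites. Trees serialize as Newick
with branch lengths.

**Growth groups.** %OD bins are [0,40) minimal, [40,80) reduced, [80,120]
similar, >120 enhanced. The published bin edges are ambiguous at 80 and
120 ("40–80" and "80–120" both printed); 80 is assigned to "similar"'s
neighbour consistently: [40,80) reduced, [80,120] similar, so each boundary
belongs to exactly one group.

**Pathway screen.** A mutant is selected for a pathway when at least
`min_hits` (default 2) of the pathway's metabolites are Bonferroni-
significant. The default sets are TCA = {citrate, 2-oxoglutarate,
succinate, fumarate, malate} and GLU = {glutamate, glutamine, proline,
N-acetyl-glutamate, 2-oxoglutarate}; 2-oxoglutarate legitimately sits in
both as the carbon acceptor of ammonium assimilation and a cycle
intermediate. Pathway metabolites absent from the data are warned about and
treated as non-significant.

## Synthetic-data generator

The generator is the package's ground-truth engine, not a fixture dump.

*Genome.* Default length 3,282,708 bp (typical *C. glutamicum* scale),
3000 genes, coding density 0.87 realized exactly up to integer rounding:
gamma-distributed gene lengths (shape 6) are rescaled to the target coding
total and interleaved with randomly partitioned gaps; no gene wraps the
origin by default. Hypothetical (36%), investigated (11%) and operon
membership (55%, in runs of 2–4 consecutive genes) are assigned at
configured rates. Insertions are uniform over [1, genome length]; growth
groups follow the configured probabilities (defaults proportional to the
published group sizes 22/29/204/5) with %OD uniform within each bin.

*Abundances.* Each metabolite has a base mean drawn log-uniformly over
10³–10⁶ area units. A sample's raw area is
`base · fold(g,m) · exp(b_em) · OD_s · f_s · exp(σz − σ²/2)` where
`fold(g,m)` combines planted effects and correlated-block draws,
`b_em ~ N(0, batch_sd²)` is a per-(metabolite, experiment) batch effect
(removed by per-experiment median normalization), `OD_s` is the culture
density (mutants scaled by their growth; quality standards are pooled
extract with OD ≡ 1), `f_s` is a per-sample injection/derivatization factor
shared by the ribitol spike (so it cancels on normalization — this is what
makes the chain's scale-invariance property physically meaningful), and
σ = √ln(1+cv²) with technical CV 0.115. The expectation is exactly
`base · fold · OD · f` (the −σ²/2 term), so mean-based ratios are unbiased.
Metabolite abundance is split over 1–3 derivative peaks with fixed
per-metabolite Dirichlet weights summing to one — derivative areas conserve
the metabolite total by construction. Blanks carry only ribitol and
contaminant peaks; contaminants appear in all samples at OD-independent
background level and are the blank filter's targets. Missingness is
missing-at-random per (metabolite, sample) at rate 0.02.

*Correlated blocks.* Each block draws one latent factor per mutant:
member m of a block with parameters (ρ, s) receives the mutant-level log
effect `s·(√ρ·z_g + √(1−ρ)·ε_gm)`, so the true log-effect correlation
between members is exactly ρ and the observed log2-ratio correlation
attenuates to ρs²/(s² + τ²), with τ² the sampling variance of the
estimated log ratio (≈ σ²(c₃ + c₄₅) for median-of-3 vs median-of-45) —
the closed form used as the test oracle. Defaults plant a TCA-like block,
a glutamine/proline block and a fatty-acid block at modest scale
(s ≈ 0.10–0.12), producing correlation ranges like the screened study's
without overwhelming the significance screen.

*What the generator does not emulate:* chromatographic peak shape and
deconvolution errors, retention-time drift, censoring of low-abundance
metabolites below a detection limit (missingness is random, not
intensity-dependent), mutant-level biological variability outside planted
effects and blocks, and growth–metabolome coupling beyond OD scaling.
Passing tests therefore demonstrate the correctness of the processing and
inference chain under the stated noise model, not robustness to every
failure mode of real GC/MS data.

## Problem sizes and defaults used in checks

The recovery and error-rate checks run at reduced but statistically
meaningful sizes chosen as the smallest designs that leave the target
quantities well-estimated: the power/accuracy sweep uses 50 independent
studies of 9 mutants × 37 metabolites with nine planted 3-fold effects each
(450 planted effects); the family-wise error check uses one null study of
200 mutants × 37 metabolites (the per-mutant false-flag probability is
estimated over 200 families); correlated-block recovery uses 200 mutants
with a three-metabolite block at ρ = 0.9, scale 0.5, where the attenuated
expectation is ≈0.88. The acceptance script mirrors these sizes and
derives all random streams from its `--seed`.

## Known limitations

- Flank location is exact-match only; real flanks with sequencing errors
  need an external aligner upstream.
- The per-experiment reproducibility filter can leave a metabolite present
  in some experiments only; downstream ratios then rest on fewer samples
  (the `n_mutant` column records this).
- The dendrogram requires a complete correlation matrix; with few mutants
  the 95% filter may need tightening.
- Ratio denominators use the wild-type reference pooled over all
  experiments; a strong wild-type batch imbalance would bias ratios, which
  the median normalization mitigates but does not eliminate.
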