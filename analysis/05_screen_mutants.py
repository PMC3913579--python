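"""Screen all mutants: ratios, significance, correlations, pathway patterns.

Per mutant, computes metabolite fold changes against the 45-sample
wild-type reference with Bonferroni-corrected t-tests, the profile
correlation to the wild type and the growth group. Across mutants, builds
the pairwise metabolite correlation matrix (log2 median ratios, metabolites
at >95% reproducibility), its average-linkage dendrogram, and selects
mutants with significant changes in at least two TCA-cycle or
glutamate-associated metabolites.
"""

from pathlib import Path

import pandas as pd

from tnscreen.peaks import load_matrix_tsv, load_sample_meta, reproducibility_filter
from tnscreen.screen import (
    correlation_dendrogram,
    dual_pathway_count,
    log2_ratio_matrix,
    mutant_ratios,
    mutant_summaries,
    pairwise_metabolite_correlation,
    pathway_pattern_screen,
    screen_report,
)
from tnscreen.qc import wildtype_reference

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    meta = load_sample_meta(ROOT / "scratch" / "fixture" / "sample_meta.tsv")
    matrix = load_matrix_tsv(ROOT / "scratch" / "metabolite_matrix.tsv", meta)
    prenorm = load_matrix_tsv(ROOT / "scratch" / "metabolite_matrix_prenorm.tsv", meta)
    growth = pd.read_csv(
        ROOT / "scratch" / "fixture" / "growth.tsv", sep="\t", index_col="mutant_id"
    )["pct_od"]
    calls = pd.read_csv(ROOT / "scratch" / "insertion_calls.tsv", sep="\t")

    wt = wildtype_reference(matrix)
    ratios = mutant_ratios(matrix, wt)
    summaries = mutant_summaries(matrix, ratios, growth=growth, prenorm=prenorm)
    pathway = pathway_pattern_screen(ratios)
    report = screen_report(summaries, pathway.selections, calls=calls)

    strict = reproducibility_filter(matrix, threshold=0.95, scope="global")
    log2 = log2_ratio_matrix(ratios[ratios["metabolite"].isin(strict.values.index)])
    corr = pairwise_metabolite_correlation(log2.dropna(axis=1, how="any"))
    tree = correlation_dendrogram(corr)

    ratios.to_csv(ROOT / "scratch" / "mutant_profiles.tsv", sep="\t", index=False,
                  na_rep="NA", float_format="%.6g")
    report.to_csv(RESULTS / "screen_report.tsv", sep="\t", index=False,
                  na_rep="NA", float_format="%.6g")
    pathway.heatmap.to_csv(RESULTS / "pathway_heatmap.tsv", sep="\t",
                           na_rep="NA", float_format="%.4f")
    corr.to_csv(RESULTS / "correlation_matrix.tsv", sep="\t", float_format="%.4f")
    tree.write(str(RESULTS / "dendrogram.nwk"))

    import numpy as np

    selected = pathway.selections.any(axis=1)
    off_diag = corr.values[~np.eye(len(corr), dtype=bool)]
    print(f"profiled mutants: {summaries.shape[0]}")
    print(f"pathway screen: {int(selected.sum())} mutants selected "
          f"(TCA {int(pathway.selections['TCA'].sum())}, "
          f"GLU {int(pathway.selections['GLU'].sum())}, "
          f"both {dual_pathway_count(pathway.selections)})")
    print(f"correlation matrix: {corr.shape[0]} metabolites "
          f"(pairwise r range {off_diag.min():.2f}..{off_diag.max():.2f})")
    print(f"median profile correlation to wild type: "
          f"{summaries['profile_pearson'].median():.3f}")


if __name__ == "__main__":
    main()
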