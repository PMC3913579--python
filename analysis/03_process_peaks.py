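"""Process per-sample GC/MS peak tables into the normalized metabolite matrix.

Runs the chain: unknown matching by retention index, derivative summation,
blank elimination, OD/ribitol normalization, the 80% per-experiment
reproducibility filter, and the two-step per-experiment median
normalization. Writes the matrix (and its pre-median-normalization stage,
needed for profile correlations) to scratch/ and the filtering funnel to
results/.
"""

from pathlib import Path

import pandas as pd

from tnscreen.peaks import load_derivative_map, load_peak_tables, load_sample_meta, process_peak_tables

ROOT = Path(__file__).resolve().parents[1]
FIXTURE = ROOT / "scratch" / "fixture"
RESULTS = ROOT / "results"


def main() -> None:
    peaks = load_peak_tables(FIXTURE / "peaks")
    meta = load_sample_meta(FIXTURE / "sample_meta.tsv")
    derivative_map = load_derivative_map(FIXTURE / "derivative_map.tsv")
    result = process_peak_tables(peaks, meta, derivative_map)

    result.matrix.to_tsv(ROOT / "scratch" / "metabolite_matrix.tsv")
    result.prenorm.to_tsv(ROOT / "scratch" / "metabolite_matrix_prenorm.tsv")
    funnel = pd.DataFrame(result.funnel, columns=["stage", "metabolites_in", "metabolites_out"])
    funnel.to_csv(RESULTS / "processing_funnel.tsv", sep="\t", index=False)

    print(funnel.to_string(index=False))
    m, s = result.matrix.values.shape
    print(f"final matrix: {m} metabolites x {s} samples "
          f"({result.matrix.values.notna().to_numpy().mean():.1%} quantified)")


if __name__ == "__main__":
    main()
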