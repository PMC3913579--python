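"""Quality-standard error statistics and the wild-type reference table.

Quality standards are aliquots of one pooled wild-type extract measured in
every experiment; the spread of each metabolite across them estimates the
technical error of the whole measurement chain. The wild-type reference
aggregates all wild-type samples into per-metabolite means/medians used as
the denominator of every mutant ratio.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .peaks import MetaboliteMatrix


class QCError(ValueError):
    pass


def metabolite_stats(values, error_kind: str = "cv") -> tuple[float, float, float, int]:
    """(mean, median, relative error, n) over the quantified values.

    Relative error is the coefficient of variation, sample SD / mean
    (``error_kind="cv"``, the standard metabolomics usage) or the relative
    standard error of the mean, SD/√n / mean (``error_kind="sem"``); it is
    ``NaN`` when fewer than two values are quantified. Missing entries are
    dropped (available-case).
    """
    if error_kind not in ("cv", "sem"):
        raise QCError(f"unknown error_kind {error_kind!r}")
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    n = arr.size
    if n == 0:
        return float("nan"), float("nan"), float("nan"), 0
    mean = float(arr.mean())
    median = float(np.median(arr))
    if n < 2 or mean == 0:
        return mean, median, float("nan"), n
    rel = float(arr.std(ddof=1) / mean)
    if error_kind == "sem":
        rel /= np.sqrt(n)
    return mean, median, rel, n


def _stats_frame(values: pd.DataFrame, error_kind: str = "cv") -> pd.DataFrame:
    rows = {m: metabolite_stats(values.loc[m], error_kind=error_kind) for m in values.index}
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["mean", "median", "relative_error", "n_quantified"]
    )
    out.index.name = "metabolite"
    out["n_quantified"] = out["n_quantified"].astype(int)
    return out


def qc_overall_error(matrix: MetaboliteMatrix, error_kind: str = "cv") -> float:
    """Mean relative error of all identified metabolites in the quality standards.

    Pools the quality-standard samples of all experiments, computes each
    identified (non-``NA_``) metabolite's coefficient of variation, and
    averages them unweighted. This is the study's single-number technical
    precision figure.
    """
    qc_cols = matrix.samples_of_type("quality_standard")
    if not qc_cols:
        raise QCError("no quality-standard samples in matrix")
    identified = [m for m in matrix.values.index if not str(m).startswith("NA_")]
    stats = _stats_frame(matrix.values.loc[identified, qc_cols], error_kind=error_kind)
    rel = stats["relative_error"].dropna()
    if rel.empty:
        raise QCError("no identified metabolite with >= 2 quality-standard values")
    return float(rel.mean())


def qc_report(matrix: MetaboliteMatrix) -> pd.DataFrame:
    """Per-metabolite quality-standard statistics (all metabolites)."""
    qc_cols = matrix.samples_of_type("quality_standard")
    if not qc_cols:
        raise QCError("no quality-standard samples in matrix")
    return _stats_frame(matrix.values[qc_cols])


def wildtype_reference(matrix: MetaboliteMatrix) -> pd.DataFrame:
    """Reference statistics per metabolite over all wild-type samples.

    Returns a frame with mean, median, relative error and the number of
    wild-type samples in which the metabolite was quantified.
    """
    wt_cols = matrix.samples_of_type("wildtype")
    if len(wt_cols) < 2:
        raise QCError("need >= 2 wild-type samples for a reference")
    return _stats_frame(matrix.values[wt_cols])
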