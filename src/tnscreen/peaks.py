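"""Peak-table processing: retention indices, aggregation and normalization.

Implements the chain that turns per-sample GC/MS peak tables into one
cross-experiment comparable metabolite × sample matrix:

1. unlabeled peaks are matched across samples by retention index and named
   ``NA_<RI>``;
2. derivative peaks are summed per metabolite;
3. non-biological peaks are eliminated with blank samples;
4. areas are normalized by culture optical density and the ribitol internal
   standard;
5. poorly reproducible metabolites are discarded;
6. a two-step median normalization (metabolite-specific, then
   sample-specific, per experiment) makes peak areas comparable between
   experiments.

Missing values are never imputed; all statistics downstream are
available-case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SAMPLE_TYPES = ("wildtype", "mutant", "quality_standard", "blank")
INTERNAL_STANDARD = "ribitol"

PEAK_COLUMNS = ["sample_id", "label", "retention_index", "area"]
META_COLUMNS = ["sample_type", "mutant_id", "experiment_id", "od"]


class ProcessingError(ValueError):
    """Raised for invalid inputs in the peak-processing chain."""


# --------------------------------------------------------------- retention index


@dataclass(frozen=True)
class AlkaneCalibration:
    """n-alkane ladder (carbon number, retention time in minutes).

    Retention times must increase strictly with carbon number; at least two
    alkanes are needed to interpolate.
    """

    carbons: tuple[int, ...]
    retention_times: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.carbons) != len(self.retention_times) or len(self.carbons) < 2:
            raise ProcessingError("calibration needs >= 2 (carbon, rt) pairs")
        c = np.asarray(self.carbons)
        t = np.asarray(self.retention_times)
        if np.any(np.diff(c) <= 0) or np.any(np.diff(t) <= 0):
            raise ProcessingError("carbons and retention times must be strictly increasing")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AlkaneCalibration":
        df = pd.read_csv(path, sep="\t")
        return cls(tuple(df["carbon_number"].astype(int)), tuple(df["retention_time"].astype(float)))


def retention_index(
    rt: float | np.ndarray, cal: AlkaneCalibration, extrapolate: bool = False
) -> float | np.ndarray:
    """Convert retention time to a retention index.

    Linear interpolation between the bracketing alkanes:
    ``RI = 100 * (n + (rt - t_n) / (t_{n+1} - t_n))`` where ``n`` is the
    carbon number of the preceding alkane. Outside the calibration range an
    error is raised unless ``extrapolate`` allows linear extension of the
    terminal segments.
    """
    t = np.asarray(cal.retention_times, dtype=float)
    ri_nodes = 100.0 * np.asarray(cal.carbons, dtype=float)
    rt_arr = np.asarray(rt, dtype=float)
    if not extrapolate and (np.any(rt_arr < t[0]) or np.any(rt_arr > t[-1])):
        raise ProcessingError(
            f"retention time outside calibration range [{t[0]}, {t[-1]}]"
        )
    slope_lo = (ri_nodes[1] - ri_nodes[0]) / (t[1] - t[0])
    slope_hi = (ri_nodes[-1] - ri_nodes[-2]) / (t[-1] - t[-2])
    out = np.interp(rt_arr, t, ri_nodes)
    out = np.where(rt_arr < t[0], ri_nodes[0] + (rt_arr - t[0]) * slope_lo, out)
    out = np.where(rt_arr > t[-1], ri_nodes[-1] + (rt_arr - t[-1]) * slope_hi, out)
    return float(out) if np.isscalar(rt) else out


def label_unknown(ri: float) -> str:
    """Name an unidentified substance from its retention index (``NA_1705.4``)."""
    if ri <= 0:
        raise ProcessingError("retention index must be positive")
    return f"NA_{ri:.1f}"


def match_unknowns(peaks: pd.DataFrame, ri_tolerance: float = 2.0) -> pd.DataFrame:
    """Assign ``NA_<RI>`` labels to unlabeled peaks, matched across samples.

    Unlabeled peaks are grouped by single-linkage on retention index: sorted
    RIs are split wherever the gap between neighbours exceeds
    ``ri_tolerance``; each group is named from its mean RI. Returns a copy of
    the table with the ``label`` column completed.
    """
    peaks = peaks.copy()
    unlabeled = peaks["label"].isna() | (peaks["label"] == "")
    if not unlabeled.any():
        return peaks
    ris = peaks.loc[unlabeled, "retention_index"].to_numpy(dtype=float)
    if np.any(~np.isfinite(ris)):
        raise ProcessingError("unlabeled peak without retention index")
    order = np.argsort(ris)
    sorted_ri = ris[order]
    breaks = np.flatnonzero(np.diff(sorted_ri) > ri_tolerance)
    group_of_sorted = np.zeros(len(sorted_ri), dtype=int)
    group_of_sorted[breaks + 1] = 1
    group_of_sorted = np.cumsum(group_of_sorted)
    groups = np.empty_like(group_of_sorted)
    groups[order] = group_of_sorted
    names = {}
    for g in np.unique(groups):
        names[g] = label_unknown(float(np.mean(ris[groups == g])))
    peaks.loc[unlabeled, "label"] = [names[g] for g in groups]
    return peaks


# ----------------------------------------------------------------- containers


@dataclass
class MetaboliteMatrix:
    """Metabolite × sample abundance matrix with sample metadata.

    ``values`` has metabolites as the index and sample ids as columns, with
    ``NaN`` marking unquantified entries. ``meta`` is indexed by sample id
    and carries ``sample_type``, ``mutant_id``, ``experiment_id``, ``od`` and
    (after extraction) ``internal_standard_area``.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.meta.index):
            self.meta = self.meta.loc[self.values.columns]
        bad = set(self.meta["sample_type"]) - set(SAMPLE_TYPES)
        if bad:
            raise ProcessingError(f"unknown sample types: {sorted(bad)}")

    @property
    def metabolites(self) -> list[str]:
        return list(self.values.index)

    def samples_of_type(self, *types: str) -> list[str]:
        mask = self.meta["sample_type"].isin(types)
        return list(self.meta.index[mask])

    def copy(self) -> "MetaboliteMatrix":
        return MetaboliteMatrix(self.values.copy(), self.meta.copy())

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")


# ----------------------------------------------------------------- operations


def aggregate_derivatives(
    peaks: pd.DataFrame,
    derivative_map: Mapping[str, str],
    ri_tolerance: float = 2.0,
) -> pd.DataFrame:
    """Sum derivative peak areas to metabolite level, per sample.

    ``derivative_map`` maps derivative labels (e.g. ``glutamate_2TMS``) to
    metabolite names; a labeled peak absent from the map is treated as a
    single-derivative metabolite under its own label. Unlabeled peaks are
    first named via :func:`match_unknowns`. Returns a wide metabolite ×
    sample frame; a metabolite is missing in a sample iff none of its
    derivatives were detected there.
    """
    peaks = match_unknowns(peaks, ri_tolerance=ri_tolerance)
    metabolite = peaks["label"].map(lambda l: derivative_map.get(l, l))
    wide = (
        peaks.assign(metabolite=metabolite)
        .pivot_table(
            index="metabolite",
            columns="sample_id",
            values="area",
            aggfunc="sum",
            dropna=True,
        )
        .sort_index()
    )
    wide.columns.name = None
    wide.index.name = "metabolite"
    return wide


def load_derivative_map(path: str | Path) -> dict[str, str]:
    """Load a two-column TSV (derivative, metabolite); duplicates must agree."""
    df = pd.read_csv(path, sep="\t")
    mapping: dict[str, str] = {}
    for row in df.itertuples(index=False):
        d, m = str(row.derivative), str(row.metabolite)
        if d in mapping and mapping[d] != m:
            raise ProcessingError(
                f"derivative {d!r} mapped to both {mapping[d]!r} and {m!r}"
            )
        mapping[d] = m
    return mapping


def blank_filter(
    matrix: MetaboliteMatrix,
    min_sample_to_blank_ratio: float = 3.0,
    exempt: Sequence[str] = (INTERNAL_STANDARD,),
) -> MetaboliteMatrix:
    """Eliminate non-biological peaks using blank samples.

    A metabolite is dropped when its mean area over biological samples
    (wildtype, mutant, quality standard; missing counted as zero) is below
    ``min_sample_to_blank_ratio`` times its mean area over blanks. Blank
    columns are removed from the output. The internal standard is spiked
    into blanks as well and is therefore exempt. Without blanks the matrix
    passes through unchanged with a warning.
    """
    blanks = matrix.samples_of_type("blank")
    if not blanks:
        import warnings

        warnings.warn("no blank samples present; blank filter skipped", stacklevel=2)
        return matrix.copy()
    bio = matrix.samples_of_type("wildtype", "mutant", "quality_standard")
    bio_mean = matrix.values[bio].fillna(0.0).mean(axis=1)
    blank_mean = matrix.values[blanks].fillna(0.0).mean(axis=1)
    keep = bio_mean >= min_sample_to_blank_ratio * blank_mean
    keep |= matrix.values.index.isin(exempt)
    values = matrix.values.loc[keep, bio]
    return MetaboliteMatrix(values, matrix.meta.loc[bio])


def normalize_by_od_is(area: float, od: float, internal_standard_area: float) -> float:
    """Normalize one raw area by optical density and internal-standard area."""
    if od <= 0 or internal_standard_area <= 0:
        raise ProcessingError("optical density and internal-standard area must be positive")
    return area / (od * internal_standard_area)


def normalize_matrix(
    matrix: MetaboliteMatrix, internal_standard: str = INTERNAL_STANDARD
) -> MetaboliteMatrix:
    """Divide every sample column by od × internal-standard area.

    The internal-standard area is taken from the matrix's own
    ``internal_standard`` row, recorded in the metadata, and the row is
    excluded from the output.
    """
    if internal_standard not in matrix.values.index:
        raise ProcessingError(f"internal standard {internal_standard!r} not found in matrix")
    is_area = matrix.values.loc[internal_standard]
    meta = matrix.meta.copy()
    meta["internal_standard_area"] = is_area
    for sample in matrix.values.columns:
        od = meta.at[sample, "od"]
        if pd.isna(od) or od <= 0:
            raise ProcessingError(f"sample {sample!r}: missing or non-positive optical density")
        if pd.isna(is_area[sample]) or is_area[sample] <= 0:
            raise ProcessingError(f"sample {sample!r}: missing or non-positive internal-standard area")
    divisor = meta["od"].astype(float) * is_area.astype(float)
    values = matrix.values.drop(index=internal_standard).div(divisor, axis=1)
    return MetaboliteMatrix(values, meta)


def reproducibility_fraction(values: Sequence[float] | pd.Series | np.ndarray) -> float:
    """Fraction of samples in which a metabolite is quantified (present and > 0)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ProcessingError("empty sample group")
    return float(np.sum(np.isfinite(arr) & (arr > 0)) / arr.size)


def reproducibility_filter(
    matrix: MetaboliteMatrix, threshold: float = 0.8, scope: str = "per_experiment"
) -> MetaboliteMatrix:
    """Discard poorly reproducible metabolites.

    ``per_experiment``: a metabolite whose quantified fraction within one
    experiment is strictly below ``threshold`` is discarded (set missing) in
    that experiment only. ``global``: a metabolite is dropped everywhere when
    its fraction over all samples is strictly below ``threshold`` (the
    stricter 0.95 global variant feeds the pairwise-correlation stage).
    A fraction exactly at the threshold is kept.
    """
    if not (0 < threshold <= 1):
        raise ProcessingError("threshold must be in (0, 1]")
    out = matrix.copy()
    if scope == "global":
        frac = out.values.apply(lambda row: reproducibility_fraction(row), axis=1)
        return MetaboliteMatrix(out.values.loc[frac >= threshold], out.meta)
    if scope != "per_experiment":
        raise ProcessingError(f"unknown scope {scope!r}")
    for exp, cols in out.meta.groupby("experiment_id").groups.items():
        block = out.values[list(cols)]
        frac = block.apply(lambda row: reproducibility_fraction(row), axis=1)
        out.values.loc[frac < threshold, list(cols)] = np.nan
    dropped = out.values.index[out.values.isna().all(axis=1)]
    out.values = out.values.drop(index=dropped)
    return out


def two_step_median_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Metabolite-median then sample-median normalization of one frame.

    Step 1 divides each metabolite row by its median across samples; step 2
    divides each sample column by that sample's median across metabolites.
    Medians ignore missing values; missing entries stay missing. After both
    steps every sample's median equals one.
    """
    row_med = values.median(axis=1, skipna=True)
    out = values.div(row_med.replace(0, np.nan), axis=0)
    col_med = out.median(axis=0, skipna=True)
    if (col_med.isna() | (col_med <= 0)).any():
        bad = list(col_med.index[col_med.isna() | (col_med <= 0)])
        raise ProcessingError(f"samples without quantified metabolites: {bad}")
    return out.div(col_med, axis=1)


def median_normalize(matrix: MetaboliteMatrix, scope: str = "per_experiment") -> MetaboliteMatrix:
    """Two-step median normalization, per experiment by default.

    Per-experiment operation makes peak areas from separate experiments
    compatible. Metabolite rows with no quantified value inside an
    experiment (e.g. removed there by the reproducibility filter) are left
    missing in that experiment; a sample with no quantified metabolite is an
    error.
    """
    out = matrix.copy()
    if scope == "global":
        out.values = two_step_median_normalize(out.values)
        return out
    if scope != "per_experiment":
        raise ProcessingError(f"unknown scope {scope!r}")
    for exp, cols in out.meta.groupby("experiment_id").groups.items():
        cols = list(cols)
        block = out.values[cols]
        present = ~block.isna().all(axis=1)
        normalized = two_step_median_normalize(block.loc[present])
        out.values.loc[present, cols] = normalized
    return out


# ------------------------------------------------------------------ pipeline


@dataclass
class ProcessingResult:
    #: final cross-experiment comparable matrix (median normalized)
    matrix: MetaboliteMatrix
    #: OD/IS-normalized matrix before median normalization; retains the
    #: abundance hierarchy needed for profile correlations
    prenorm: MetaboliteMatrix | None = None
    funnel: list[tuple[str, int, int]] = field(default_factory=list)


def process_peak_tables(
    peaks: pd.DataFrame,
    sample_meta: pd.DataFrame,
    derivative_map: Mapping[str, str],
    *,
    blank_ratio: float = 3.0,
    repro_threshold: float = 0.8,
    repro_scope: str = "per_experiment",
    ri_tolerance: float = 2.0,
    internal_standard: str = INTERNAL_STANDARD,
) -> ProcessingResult:
    """Run the full chain from long-format peak tables to a normalized matrix.

    ``peaks`` columns: sample_id, label (empty for unknowns),
    retention_index, area. ``sample_meta`` is indexed by sample id with
    columns sample_type, mutant_id, experiment_id, od. Records the
    metabolite count before/after every filtering stage.
    """
    funnel: list[tuple[str, int, int]] = []
    wide = aggregate_derivatives(peaks, derivative_map, ri_tolerance=ri_tolerance)
    meta = sample_meta.loc[wide.columns].copy()
    matrix = MetaboliteMatrix(wide, meta)
    n0 = len(matrix.values)
    matrix = blank_filter(matrix, min_sample_to_blank_ratio=blank_ratio)
    funnel.append(("blank_filter", n0, len(matrix.values)))
    n0 = len(matrix.values)
    matrix = normalize_matrix(matrix, internal_standard=internal_standard)
    funnel.append(("od_is_normalization", n0, len(matrix.values)))
    n0 = len(matrix.values)
    matrix = reproducibility_filter(matrix, threshold=repro_threshold, scope=repro_scope)
    funnel.append(("reproducibility_filter", n0, len(matrix.values)))
    prenorm = matrix.copy()
    matrix = median_normalize(matrix, scope="per_experiment")
    funnel.append(("median_normalization", len(matrix.values), len(matrix.values)))
    return ProcessingResult(matrix=matrix, prenorm=prenorm, funnel=funnel)


def load_peak_tables(peaks_dir: str | Path) -> pd.DataFrame:
    """Read one TSV per sample (named ``<sample_id>.tsv``) into long format."""
    frames = []
    for path in sorted(Path(peaks_dir).glob("*.tsv")):
        df = pd.read_csv(path, sep="\t")
        df["sample_id"] = path.stem
        frames.append(df[["sample_id", "label", "retention_index", "area"]])
    if not frames:
        raise ProcessingError(f"no peak tables found in {peaks_dir}")
    out = pd.concat(frames, ignore_index=True)
    out["label"] = out["label"].fillna("")
    return out


def load_matrix_tsv(path: str | Path, sample_meta: pd.DataFrame) -> MetaboliteMatrix:
    """Read a metabolite × sample TSV (``NA`` missing) back into a matrix."""
    values = pd.read_csv(path, sep="\t", index_col="metabolite", na_values=["NA"])
    return MetaboliteMatrix(values, sample_meta.loc[values.columns].copy())


def load_sample_meta(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col="sample_id")
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ProcessingError(f"sample metadata lacks columns: {missing}")
    return meta
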