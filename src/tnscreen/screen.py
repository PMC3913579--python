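"""Mutant-level screening statistics and metabolite correlation analysis.

Per mutant: metabolite ratios against the wild-type reference, t-tests with
Bonferroni control, the Pearson correlation of the whole log profile to the
wild type, and the growth group. Across mutants: the pairwise Pearson
correlation of metabolites over all genotypes (on log2-transformed
mutant/wild-type median ratios), its dendrogram, and a pathway pattern
screen selecting mutants with significant changes in at least ``min_hits``
metabolites of a predefined metabolite set (e.g. TCA cycle).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from skbio import TreeNode

from .peaks import MetaboliteMatrix

GROWTH_GROUPS = ("minimal", "reduced", "similar", "enhanced")

#: Metabolite sets used by the pathway pattern screen. The TCA set covers
#: the cycle intermediates quantified by GC/MS profiling; the GLU set covers
#: glutamate-associated metabolites (2-oxoglutarate sits in both, being the
#: carbon acceptor of ammonium assimilation and a cycle intermediate).
DEFAULT_PATHWAYS: dict[str, tuple[str, ...]] = {
    "TCA": ("citrate", "2-oxoglutarate", "succinate", "fumarate", "malate"),
    "GLU": ("glutamate", "glutamine", "proline", "N-acetyl-glutamate", "2-oxoglutarate"),
}


class ScreenError(ValueError):
    pass


# ------------------------------------------------------------------- growth


def growth_group(pct_od: float) -> str:
    """Bin relative growth (%OD vs wild type) into four groups.

    [0, 40) minimal, [40, 80) reduced, [80, 120] similar, (120, ∞) enhanced.
    """
    if pct_od < 0 or not np.isfinite(pct_od):
        raise ScreenError(f"invalid %OD value {pct_od}")
    if pct_od < 40:
        return "minimal"
    if pct_od < 80:
        return "reduced"
    if pct_od <= 120:
        return "similar"
    return "enhanced"


def growth_histogram(pct_od_values, bin_width: float = 10.0) -> pd.DataFrame:
    """Histogram table of relative growth values (for the growth overview plot)."""
    arr = np.asarray(list(pct_od_values), dtype=float)
    arr = arr[np.isfinite(arr)]
    top = max(160.0, float(arr.max()) if arr.size else 160.0)
    edges = np.arange(0.0, top + bin_width, bin_width)
    counts, _ = np.histogram(arr, bins=edges)
    return pd.DataFrame({"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts})


# ----------------------------------------------------------------- statistics


def significance_test(
    mutant_values,
    wt_values,
    alpha: float = 0.01,
    m: int = 1,
    *,
    log_scale: bool = True,
    equal_var: bool = True,
) -> tuple[float, bool]:
    """Two-sample t-test of a mutant against the wild-type reference.

    Performed on log-transformed areas by default, matching the
    multiplicative error structure of GC/MS peak areas; ``equal_var=False``
    switches to the Welch unequal-variance form. Significance uses the
    Bonferroni-adjusted threshold ``alpha / m``. Returns ``(p, significant)``;
    with fewer than two quantified values per group the metabolite is
    untested (``p = NaN``, never significant).
    """
    a = np.asarray(mutant_values, dtype=float)
    b = np.asarray(wt_values, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if log_scale:
        a = a[a > 0]
        b = b[b > 0]
        a = np.log(a)
        b = np.log(b)
    if a.size < 2 or b.size < 2:
        return float("nan"), False
    if np.allclose(a.var(), 0) and np.allclose(b.var(), 0):
        p = 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
        return p, bool(p <= alpha / m)
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    p = float(res.pvalue)
    return p, bool(p <= alpha / m)


def profile_pearson(mutant_means, wt_means) -> float:
    """Pearson correlation of log mean peak areas, mutant vs wild type.

    Computed over metabolites quantified (positive) in both profiles; with
    fewer than three shared metabolites, or zero variance in either log
    vector, the correlation is undefined (``NaN``).
    """
    a = np.asarray(mutant_means, dtype=float)
    b = np.asarray(wt_means, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b) & (a > 0) & (b > 0)
    if ok.sum() < 3:
        return float("nan")
    la, lb = np.log(a[ok]), np.log(b[ok])
    if la.std() == 0 or lb.std() == 0:
        return float("nan")
    return float(stats.pearsonr(la, lb).statistic)


def mutant_ratios(
    matrix: MetaboliteMatrix,
    wt_stats: pd.DataFrame,
    *,
    alpha: float = 0.01,
    bonferroni_scope: str = "per_mutant",
    log_scale: bool = True,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-(mutant, metabolite) ratios, log2 median ratios and significance.

    The reported ratio divides the mutant's mean by the wild-type mean;
    the correlation stage uses the log2 of the median-based ratio.
    ``bonferroni_scope`` chooses the multiple-testing family: the number of
    metabolites tested for that mutant (``per_mutant``) or across the whole
    screen (``global``).
    """
    wt_cols = matrix.samples_of_type("wildtype")
    mutants = sorted(
        set(matrix.meta.loc[matrix.meta["sample_type"] == "mutant", "mutant_id"].dropna())
    )
    mets = np.array(matrix.values.index)
    wt = matrix.values[wt_cols].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        lwt = np.where(wt > 0, np.log(wt), np.nan)
    n_wt = np.isfinite(wt).sum(axis=1)
    wt_mean = wt_stats["mean"].reindex(mets).to_numpy(dtype=float)
    wt_median = wt_stats["median"].reindex(mets).to_numpy(dtype=float)

    frames: list[pd.DataFrame] = []
    for mutant in mutants:
        cols = list(
            matrix.meta.index[
                (matrix.meta["sample_type"] == "mutant")
                & (matrix.meta["mutant_id"] == mutant)
            ]
        )
        sub = matrix.values[cols].to_numpy(dtype=float)  # (M, replicates)
        n_mut = np.isfinite(sub).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mut_mean = np.nanmean(sub, axis=1)
            mut_median = np.nanmedian(sub, axis=1)
            if log_scale:
                a = np.where(sub > 0, np.log(sub), np.nan)
                b = lwt
            else:
                a, b = sub, wt
            res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var, nan_policy="omit")
            p = np.asarray(res.pvalue, dtype=float)
            # degenerate rows: both groups constant -> p = 1 iff means agree
            var_a = np.nanvar(a, axis=1)
            var_b = np.nanvar(b, axis=1)
            degen = (var_a == 0) & (var_b == 0) & (n_mut >= 2) & (n_wt >= 2)
            if degen.any():
                same = np.isclose(np.nanmean(a, axis=1), np.nanmean(b, axis=1))
                p = np.where(degen, np.where(same, 1.0, 0.0), p)
            p = np.where((n_mut < 2) | (n_wt < 2), np.nan, p)
            ratio = np.where(wt_mean > 0, mut_mean / wt_mean, np.nan)
            log2_med = np.where(
                (mut_median > 0) & (wt_median > 0), np.log2(mut_median / wt_median), np.nan
            )
        if np.any((wt_mean <= 0) & (n_mut > 0)):
            warnings.warn("zero wild-type mean; ratio undefined for some metabolites", stacklevel=2)
        keep = (n_mut > 0) & (n_wt > 0)
        frames.append(
            pd.DataFrame(
                {
                    "mutant_id": mutant,
                    "metabolite": mets[keep],
                    "mutant_mean": mut_mean[keep],
                    "mutant_median": mut_median[keep],
                    "wt_mean": wt_mean[keep],
                    "wt_median": wt_median[keep],
                    "ratio": ratio[keep],
                    "log2_ratio_median": log2_med[keep],
                    "n_mutant": n_mut[keep].astype(int),
                    "p_value": p[keep],
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=[
                "mutant_id", "metabolite", "mutant_mean", "mutant_median", "wt_mean",
                "wt_median", "ratio", "log2_ratio_median", "n_mutant", "p_value",
            ]
        )
    out = pd.concat(frames, ignore_index=True)
    if bonferroni_scope == "per_mutant":
        m_tests = out.groupby("mutant_id")["p_value"].transform(lambda s: s.notna().sum())
    elif bonferroni_scope == "global":
        m_tests = float(out["p_value"].notna().sum())
    else:
        raise ScreenError(f"unknown bonferroni_scope {bonferroni_scope!r}")
    out["m_tests"] = m_tests
    out["significant"] = out["p_value"].notna() & (out["p_value"] <= alpha / out["m_tests"])
    return out


def mutant_summaries(
    matrix: MetaboliteMatrix,
    ratios: pd.DataFrame,
    growth: Mapping[str, float] | pd.Series | None = None,
    prenorm: MetaboliteMatrix | None = None,
) -> pd.DataFrame:
    """Per-mutant profile correlation to the wild type, growth and test counts.

    The profile correlation compares log mean peak areas mutant vs wild
    type; pass ``prenorm`` (the matrix before median normalization) so the
    correlation is taken on areas that still carry the metabolite abundance
    hierarchy — after median normalization every metabolite sits near one
    and the correlation degenerates.
    """
    src = prenorm if prenorm is not None else matrix
    wt_cols = src.samples_of_type("wildtype")
    wt_means = src.values[wt_cols].mean(axis=1, skipna=True)
    rows = []
    for mutant, sub in ratios.groupby("mutant_id"):
        cols = list(
            src.meta.index[
                (src.meta["sample_type"] == "mutant") & (src.meta["mutant_id"] == mutant)
            ]
        )
        if cols:
            mut_means = src.values[cols].mean(axis=1, skipna=True)
            pearson = profile_pearson(mut_means, wt_means)
        else:
            pearson = profile_pearson(sub["mutant_mean"], sub["wt_mean"])
        pct = np.nan
        if growth is not None:
            pct = float(pd.Series(growth).get(mutant, np.nan))
        rows.append(
            {
                "mutant_id": mutant,
                "profile_pearson": pearson,
                "growth_pct_od": pct,
                "growth_group": growth_group(pct) if np.isfinite(pct) else "",
                "n_metabolites": int(sub["p_value"].notna().sum()),
                "n_significant": int(sub["significant"].sum()),
            }
        )
    return pd.DataFrame(rows).set_index("mutant_id")


# ------------------------------------------------------ metabolite correlation


def log2_ratio_matrix(ratios: pd.DataFrame) -> pd.DataFrame:
    """Mutant × metabolite matrix of log2 median ratios."""
    return ratios.pivot(index="mutant_id", columns="metabolite", values="log2_ratio_median")


def pairwise_metabolite_correlation(
    log2_ratios: pd.DataFrame, min_shared: int = 3
) -> pd.DataFrame:
    """Pearson correlation of every metabolite pair across mutants.

    Each pair uses the mutants where both metabolites have a log2 ratio;
    pairs sharing fewer than ``min_shared`` mutants get a missing entry.
    """
    if len(log2_ratios) < min_shared:
        raise ScreenError(f"need >= {min_shared} mutants for pairwise correlation")
    corr = log2_ratios.corr(method="pearson", min_periods=min_shared)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def correlation_dendrogram(corr: pd.DataFrame, method: str = "average") -> TreeNode:
    """Agglomerative clustering of metabolites from their correlation vectors.

    Each metabolite is represented by its row of correlations to all
    metabolites; distances between rows are Euclidean. Returns a tree with
    branch lengths, one leaf per metabolite (serializable as Newick).
    """
    if corr.isna().any().any():
        raise ScreenError(
            "correlation matrix has missing entries; raise the reproducibility "
            "threshold so that all metabolite pairs share enough mutants"
        )
    if not np.allclose(corr.values, corr.values.T):
        raise ScreenError("correlation matrix is not symmetric")
    Z = linkage(corr.values, method=method, metric="euclidean")
    tree = TreeNode.from_linkage_matrix(Z, list(corr.index))
    return tree


# ----------------------------------------------------------- pathway screening


def load_pathways(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Load pathway metabolite sets from JSON ({name: [metabolites]}) or TSV."""
    path = Path(path)
    if path.suffix == ".json":
        data = json.loads(path.read_text())
        out = {str(k): tuple(v) for k, v in data.items()}
    else:
        df = pd.read_csv(path, sep="\t")
        out = {
            str(name): tuple(sub["metabolite"])
            for name, sub in df.groupby("pathway", sort=True)
        }
    for name, mets in out.items():
        if len(mets) < 2:
            raise ScreenError(f"pathway {name!r} needs >= 2 metabolites")
    return out


@dataclass
class PathwayScreenResult:
    #: mutant × pathway boolean selection table
    selections: pd.DataFrame
    #: log2 median-ratio table (selected mutants × pathway metabolites)
    heatmap: pd.DataFrame
    #: per-pathway significant-hit counts per mutant
    hit_counts: pd.DataFrame


def pathway_pattern_screen(
    ratios: pd.DataFrame,
    pathways: Mapping[str, Sequence[str]] | None = None,
    min_hits: int = 2,
) -> PathwayScreenResult:
    """Select mutants with significant changes in >= ``min_hits`` pathway metabolites.

    ``ratios`` is the output of :func:`mutant_ratios` (must carry the
    ``significant`` flags). Pathway metabolites absent from the data are
    treated as non-significant with a warning.
    """
    if pathways is None:
        pathways = DEFAULT_PATHWAYS
    if "significant" not in ratios.columns:
        raise ScreenError("ratios table lacks significance flags; run mutant_ratios first")
    sig = ratios.pivot(index="mutant_id", columns="metabolite", values="significant").fillna(False)
    log2 = log2_ratio_matrix(ratios)
    hit_counts = {}
    for name, mets in pathways.items():
        present = [m for m in mets if m in sig.columns]
        absent = sorted(set(mets) - set(present))
        if absent:
            warnings.warn(
                f"pathway {name!r}: metabolites {absent} not in matrix; treated as non-significant",
                stacklevel=2,
            )
        hit_counts[name] = sig[present].sum(axis=1).astype(int) if present else 0
    hit_counts = pd.DataFrame(hit_counts, index=sig.index)
    selections = hit_counts >= min_hits
    selected_mutants = selections.index[selections.any(axis=1)]
    pathway_mets = [m for mets in pathways.values() for m in mets]
    pathway_mets = list(dict.fromkeys(m for m in pathway_mets if m in log2.columns))
    heatmap = log2.loc[selected_mutants, pathway_mets]
    return PathwayScreenResult(selections=selections, heatmap=heatmap, hit_counts=hit_counts)


def dual_pathway_count(flags: pd.DataFrame, pathways: Sequence[str] = ("TCA", "GLU")) -> int:
    """Count mutants flagged in every one of the given pathways.

    ``flags`` is a mutant-indexed boolean table with one column per pathway
    (the Table-2-style report's flag columns).
    """
    return int(flags[list(pathways)].all(axis=1).sum())


def screen_report(
    summaries: pd.DataFrame,
    selections: pd.DataFrame,
    calls: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Table-style report: mutant, locus, description, operon, Pearson, %OD, flags."""
    report = summaries.copy()
    for pathway in selections.columns:
        report[pathway] = selections[pathway].reindex(report.index).fillna(False)
    if calls is not None:
        anno = calls.set_index("mutant_id")[
            ["category", "locus", "in_operon"]
        ].reindex(report.index)
        report = anno.join(report)
    return report.reset_index(names="mutant_id")
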