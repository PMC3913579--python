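"""End-to-end orchestration: fixture on disk -> full report bundle.

Wires the stages together — insertion mapping, peak processing, quality
control, mutant screening — reads every input from a fixture directory (as
written by :func:`tnscreen.simulate.make_fixture` or assembled from real
data in the same formats) and writes all reports as TSV/Newick.  Every
filtering stage logs before/after counts so the screening funnel is
reconstructible; outputs are byte-identical for identical inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import peaks as pk
from . import qc as qcmod
from . import screen as sc
from .annotation import GeneAnnotation
from .mapping import insertion_density, map_library, summarize_library

FLOAT_FMT = "%.6g"


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Paths and stage parameters for one pipeline run."""

    fixture_dir: Path
    out_dir: Path
    blank_ratio: float = 3.0
    repro_threshold: float = 0.8
    repro_scope: str = "per_experiment"
    corr_repro_threshold: float = 0.95
    ri_tolerance: float = 2.0
    alpha: float = 0.01
    bonferroni_scope: str = "per_mutant"
    equal_var: bool = True
    min_hits: int = 2
    linkage: str = "average"
    density_bins: int = 50
    pathways_file: Path | None = None

    def __post_init__(self) -> None:
        self.fixture_dir = Path(self.fixture_dir)
        self.out_dir = Path(self.out_dir)


@dataclass
class PipelineResult:
    matrix: pk.MetaboliteMatrix
    ratios: pd.DataFrame
    summaries: pd.DataFrame
    pathway: sc.PathwayScreenResult
    correlation: pd.DataFrame | None
    library_summary: object
    qc_error: float
    log_lines: list[str] = field(default_factory=list)


def _write(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", na_rep="NA", float_format=FLOAT_FMT, **kw)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages on a fixture directory and write the report bundle."""
    fx = config.fixture_dir
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def stage(name: str):
        def fail(exc: Exception):
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return fail

    # ---------------- insertion mapping ----------------
    try:
        annotation = GeneAnnotation.from_gff3(fx / "annotation.gff3")
        mutants = pd.read_csv(fx / "insertions.tsv", sep="\t")
        calls = map_library(mutants, annotation)
        summary = summarize_library(calls)
        positions = mutants["position"].dropna().to_numpy()
        density, chi2, chi2_p = insertion_density(
            positions, annotation.genome_length, n_bins=config.density_bins
        )
    except Exception as exc:  # noqa: BLE001
        stage("insertion_mapping")(exc)
    n_total = len(mutants)
    n_located = int(mutants["position"].notna().sum())
    log.append(f"insertion_mapping: screened={n_total} located={n_located} "
               f"discarded={n_total - n_located}")
    log.append(f"insertion_density: chi2={chi2:.4g} p={chi2_p:.4g} bins={config.density_bins}")
    _write(calls, out / "insertion_calls.tsv", index=False)
    _write(summary.to_frame(), out / "library_summary.tsv", index=False)
    _write(density, out / "insertion_density.tsv", index=False)

    # ---------------- growth groups ----------------
    try:
        growth = pd.read_csv(fx / "growth.tsv", sep="\t", index_col="mutant_id")["pct_od"]
        groups = growth.map(sc.growth_group)
        group_table = (
            groups.value_counts().reindex(sc.GROWTH_GROUPS, fill_value=0).rename_axis("growth_group").reset_index(name="count")
        )
        hist = sc.growth_histogram(growth)
    except Exception as exc:  # noqa: BLE001
        stage("growth_groups")(exc)
    _write(group_table, out / "growth_groups.tsv", index=False)
    _write(hist, out / "growth_histogram.tsv", index=False)

    # ---------------- peak processing ----------------
    try:
        peaks_long = pk.load_peak_tables(fx / "peaks")
        meta = pk.load_sample_meta(fx / "sample_meta.tsv")
        derivative_map = pk.load_derivative_map(fx / "derivative_map.tsv")
        processed = pk.process_peak_tables(
            peaks_long,
            meta,
            derivative_map,
            blank_ratio=config.blank_ratio,
            repro_threshold=config.repro_threshold,
            repro_scope=config.repro_scope,
            ri_tolerance=config.ri_tolerance,
        )
    except Exception as exc:  # noqa: BLE001
        stage("peak_processing")(exc)
    matrix = processed.matrix
    for name, before, after in processed.funnel:
        log.append(f"peak_processing/{name}: in={before} out={after} discarded={before - after}")
    matrix.to_tsv(out / "metabolite_matrix.tsv")

    # ---------------- quality control ----------------
    try:
        qc_error = qcmod.qc_overall_error(matrix)
        qc_table = qcmod.qc_report(matrix)
        wt_stats = qcmod.wildtype_reference(matrix)
    except Exception as exc:  # noqa: BLE001
        stage("quality_control")(exc)
    log.append(f"quality_control: overall_relative_error={qc_error:.4f}")
    _write(qc_table, out / "qc_report.tsv")
    _write(wt_stats, out / "wildtype_reference.tsv")

    # ---------------- mutant screening ----------------
    try:
        ratios = sc.mutant_ratios(
            matrix,
            wt_stats,
            alpha=config.alpha,
            bonferroni_scope=config.bonferroni_scope,
            equal_var=config.equal_var,
        )
        summaries = sc.mutant_summaries(matrix, ratios, growth=growth, prenorm=processed.prenorm)
        pathways = (
            sc.load_pathways(config.pathways_file)
            if config.pathways_file is not None
            else sc.DEFAULT_PATHWAYS
        )
        pathway = sc.pathway_pattern_screen(ratios, pathways, min_hits=config.min_hits)
        report = sc.screen_report(summaries, pathway.selections, calls=calls)
    except Exception as exc:  # noqa: BLE001
        stage("mutant_screening")(exc)
    n_mut = summaries.shape[0]
    n_sel = int(pathway.selections.any(axis=1).sum())
    log.append(f"mutant_screening: profiled={n_mut} pathway_selected={n_sel} "
               f"dual={sc.dual_pathway_count(pathway.selections) if set(('TCA', 'GLU')) <= set(pathway.selections.columns) else 'NA'}")
    _write(ratios, out / "mutant_profiles.tsv", index=False)
    _write(report, out / "screen_report.tsv", index=False)
    _write(pathway.heatmap, out / "pathway_heatmap.tsv")
    _write(pathway.hit_counts, out / "pathway_hits.tsv")

    # ---------------- metabolite correlation ----------------
    correlation = None
    try:
        strict = pk.reproducibility_filter(
            matrix, threshold=config.corr_repro_threshold, scope="global"
        )
        log2 = sc.log2_ratio_matrix(ratios[ratios["metabolite"].isin(strict.values.index)])
        if len(log2) >= 3:
            correlation = sc.pairwise_metabolite_correlation(log2)
            tree = sc.correlation_dendrogram(correlation, method=config.linkage)
            _write(correlation, out / "correlation_matrix.tsv")
            tree.write(str(out / "dendrogram.nwk"))
            log.append(
                f"correlation: metabolites={correlation.shape[0]} "
                f"(repro>{config.corr_repro_threshold:g} of {len(matrix.values)})"
            )
        else:
            log.append("correlation: skipped (fewer than 3 mutants)")
    except Exception as exc:  # noqa: BLE001
        stage("correlation")(exc)

    (out / "pipeline_log.txt").write_text("\n".join(log) + "\n")
    return PipelineResult(
        matrix=matrix,
        ratios=ratios,
        summaries=summaries,
        pathway=pathway,
        correlation=correlation,
        library_summary=summary,
        qc_error=qc_error,
        log_lines=log,
    )
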