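"""Insertion-site mapping onto a gene annotation and library-level summaries.

Maps transposon insertion coordinates (or located flank sequences) onto a
:class:`~tnscreen.annotation.GeneAnnotation`, classifies each insertion as a
gene hit or intergenic, and aggregates library statistics: the fraction of
insertions hitting a gene (which, for an unbiased transposon, approaches the
genome's coding density), and — among hit genes — the fractions in operons,
with unknown/hypothetical function, or previously investigated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement
from scipy import stats

from .annotation import GeneAnnotation


@dataclass(frozen=True)
class FlankHit:
    """Result of locating a flank sequence on the genome.

    ``status`` is one of ``unique`` (position set), ``not_found`` or
    ``ambiguous`` (multiple exact matches; the mutant stays unidentified).
    """

    status: str
    position: int | None = None
    reverse: bool = False


@dataclass(frozen=True)
class InsertionCall:
    mutant_id: str
    category: str  # "gene_hit" | "intergenic"
    locus: str | None = None
    in_operon: bool = False
    hypothetical: bool = False
    investigated: bool = False
    nearest_downstream_gene: str | None = None
    upstream_distance: int | None = None


@dataclass(frozen=True)
class LibrarySummary:
    """Counts and integer percentages of an insertion library.

    ``pct_gene_hits`` is relative to located insertions; the operon,
    hypothetical and investigated percentages are relative to insertions
    that hit a gene. Percentages are ``None`` when the denominator is zero.
    """

    n_located: int
    n_gene_hits: int
    n_in_operon: int
    n_hypothetical: int
    n_investigated: int
    pct_gene_hits: int | None
    pct_in_operon: int | None
    pct_hypothetical: int | None
    pct_investigated: int | None

    @classmethod
    def from_counts(
        cls,
        n_located: int,
        n_gene_hits: int,
        n_in_operon: int,
        n_hypothetical: int,
        n_investigated: int,
    ) -> "LibrarySummary":
        return cls(
            n_located=n_located,
            n_gene_hits=n_gene_hits,
            n_in_operon=n_in_operon,
            n_hypothetical=n_hypothetical,
            n_investigated=n_investigated,
            pct_gene_hits=_pct(n_gene_hits, n_located),
            pct_in_operon=_pct(n_in_operon, n_gene_hits),
            pct_hypothetical=_pct(n_hypothetical, n_gene_hits),
            pct_investigated=_pct(n_investigated, n_gene_hits),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "statistic": [
                    "located_insertion_points",
                    "insertion_hits_gene",
                    "hit_gene_in_operon",
                    "hit_gene_hypothetical",
                    "hit_gene_investigated",
                ],
                "count": [
                    self.n_located,
                    self.n_gene_hits,
                    self.n_in_operon,
                    self.n_hypothetical,
                    self.n_investigated,
                ],
                "percent": [
                    "",
                    _fmt(self.pct_gene_hits),
                    _fmt(self.pct_in_operon),
                    _fmt(self.pct_hypothetical),
                    _fmt(self.pct_investigated),
                ],
            }
        )


def _pct(num: int, den: int) -> int | None:
    if den == 0:
        return None
    return int(math.floor(100.0 * num / den + 0.5))


def _fmt(value: int | None) -> str:
    return "" if value is None else str(value)


def locate_flank(flank: str, genome: str) -> FlankHit:
    """Locate the unique exact match of ``flank`` (or its reverse complement).

    Stands in for a BLAST search when the flank is error-free: the returned
    position is the 1-based start of the matching genomic window. Multiple
    matches are ambiguous and leave the mutant unidentified.
    """
    flank = flank.upper()
    genome = genome.upper()
    if len(flank) < 20:
        raise ValueError("flank sequence must be at least 20 bp")
    fwd = _find_all(genome, flank)
    rc = reverse_complement(flank)
    rev = [] if rc == flank else _find_all(genome, rc)
    hits = [(p, False) for p in fwd] + [(p, True) for p in rev]
    if not hits:
        return FlankHit(status="not_found")
    if len(hits) > 1:
        return FlankHit(status="ambiguous")
    pos, is_rev = hits[0]
    return FlankHit(status="unique", position=pos + 1, reverse=is_rev)


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def map_insertion(
    position: int, annotation: GeneAnnotation, mutant_id: str = ""
) -> InsertionCall:
    """Classify one insertion position as a gene hit or intergenic.

    Gene intervals are inclusive at both boundaries. Intergenic insertions
    report the nearest gene whose translational start lies downstream of the
    insertion along that gene's own reading direction (the gene whose
    promoter region the insertion may damage), together with the distance in
    base pairs; the search wraps around the circular genome and considers
    both strands, taking the smaller distance (ties favour the + strand).
    """
    position = int(position)
    if not (1 <= position <= annotation.genome_length):
        raise ValueError(
            f"position {position} outside genome [1, {annotation.genome_length}]"
        )
    starts = annotation.starts
    idx = int(np.searchsorted(starts, position, side="right")) - 1
    if idx >= 0:
        gene = annotation.genes[idx]
        if gene.start <= position <= gene.end:
            return InsertionCall(
                mutant_id=mutant_id,
                category="gene_hit",
                locus=gene.locus,
                in_operon=gene.in_operon,
                hypothetical=gene.hypothetical,
                investigated=gene.investigated,
            )
    if not annotation.genes:
        return InsertionCall(mutant_id=mutant_id, category="intergenic")

    L = annotation.genome_length
    plus_starts, plus_loci, minus_ends, minus_loci = _strand_index(annotation)
    best: tuple[int, str] | None = None
    # + strand: translational start = gene.start, downstream means start >= pos
    if plus_starts.size:
        j = int(np.searchsorted(plus_starts, position, side="left"))
        if j < plus_starts.size:
            best = (int(plus_starts[j]) - position, plus_loci[j])
        else:  # wrap around the origin
            best = (int(plus_starts[0]) + L - position, plus_loci[0])
    # - strand: translational start = gene.end, downstream (on the minus
    # strand's reading direction) means end <= pos
    if minus_ends.size:
        j = int(np.searchsorted(minus_ends, position, side="right")) - 1
        if j >= 0:
            cand = (position - int(minus_ends[j]), minus_loci[j])
        else:  # wrap around the origin
            cand = (position + L - int(minus_ends[-1]), minus_loci[-1])
        if best is None or cand[0] < best[0]:
            best = cand
    assert best is not None
    return InsertionCall(
        mutant_id=mutant_id,
        category="intergenic",
        nearest_downstream_gene=best[1],
        upstream_distance=best[0],
    )


_STRAND_INDEX_CACHE: dict[int, tuple] = {}


def _strand_index(annotation: GeneAnnotation) -> tuple:
    """Per-strand sorted translational-start arrays, cached per annotation."""
    key = id(annotation)
    cached = _STRAND_INDEX_CACHE.get(key)
    if cached is not None:
        return cached
    plus = [(g.start, g.locus) for g in annotation.genes if g.strand == "+"]
    minus = [(g.end, g.locus) for g in annotation.genes if g.strand == "-"]
    plus.sort()
    minus.sort()
    out = (
        np.array([p for p, _ in plus], dtype=np.int64),
        [l for _, l in plus],
        np.array([e for e, _ in minus], dtype=np.int64),
        [l for _, l in minus],
    )
    _STRAND_INDEX_CACHE.clear()  # keep at most one annotation cached
    _STRAND_INDEX_CACHE[key] = out
    return out


def locate_flanks(flanks: dict[str, str], genome: str) -> pd.DataFrame:
    """Locate many mutants' flank sequences; unresolved ones stay unidentified.

    Returns a mutants table (``mutant_id``, ``position``, ``status``) ready
    for :func:`map_library`; ambiguous or unmatched flanks get a missing
    position.
    """
    rows = []
    for mutant_id, flank in flanks.items():
        hit = locate_flank(flank, genome)
        rows.append(
            {
                "mutant_id": mutant_id,
                "position": hit.position if hit.status == "unique" else np.nan,
                "status": hit.status,
            }
        )
    return pd.DataFrame(rows)


def map_library(mutants: pd.DataFrame, annotation: GeneAnnotation) -> pd.DataFrame:
    """Map a table of mutants (columns ``mutant_id``, ``position``).

    Mutants with a missing position stay unidentified (``category`` =
    ``not_identified``) and are excluded from summary denominators.
    """
    rows = []
    for row in mutants.itertuples(index=False):
        if pd.isna(row.position):
            rows.append(
                {
                    "mutant_id": row.mutant_id,
                    "category": "not_identified",
                    "locus": "",
                    "in_operon": False,
                    "hypothetical": False,
                    "investigated": False,
                    "nearest_downstream_gene": "",
                    "upstream_distance": np.nan,
                }
            )
            continue
        call = map_insertion(int(row.position), annotation, mutant_id=str(row.mutant_id))
        rows.append(
            {
                "mutant_id": call.mutant_id,
                "category": call.category,
                "locus": call.locus or "",
                "in_operon": call.in_operon,
                "hypothetical": call.hypothetical,
                "investigated": call.investigated,
                "nearest_downstream_gene": call.nearest_downstream_gene or "",
                "upstream_distance": call.upstream_distance
                if call.upstream_distance is not None
                else np.nan,
            }
        )
    return pd.DataFrame(rows)


def summarize_library(calls: pd.DataFrame | list[InsertionCall]) -> LibrarySummary:
    """Tabulate located / gene-hit / operon / hypothetical / investigated counts."""
    if isinstance(calls, list):
        calls = pd.DataFrame(
            {
                "category": [c.category for c in calls],
                "in_operon": [c.in_operon for c in calls],
                "hypothetical": [c.hypothetical for c in calls],
                "investigated": [c.investigated for c in calls],
            }
        )
    located = calls[calls["category"] != "not_identified"]
    hits = located[located["category"] == "gene_hit"]
    return LibrarySummary.from_counts(
        n_located=len(located),
        n_gene_hits=len(hits),
        n_in_operon=int(hits["in_operon"].sum()),
        n_hypothetical=int(hits["hypothetical"].sum()),
        n_investigated=int(hits["investigated"].sum()),
    )


def insertion_density(
    positions, genome_length: int, n_bins: int = 50
) -> tuple[pd.DataFrame, float, float]:
    """Bin insertion positions into equal-width windows and test uniformity.

    Returns (per-bin table, chi-square statistic, p-value). A high p-value is
    consistent with site-unbiased transposition across the genome.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.size == 0:
        raise ValueError("no insertion positions given")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if positions.min() < 1 or positions.max() > genome_length:
        raise ValueError("positions outside [1, genome_length]")
    edges = np.linspace(0.5, genome_length + 0.5, n_bins + 1)
    counts, _ = np.histogram(positions, bins=edges)
    expected = positions.size / n_bins
    if expected < 5:
        warnings.warn(
            f"expected count per bin ({expected:.2f}) below 5; "
            "chi-square approximation is unreliable",
            stacklevel=2,
        )
    stat, pvalue = stats.chisquare(counts)
    table = pd.DataFrame(
        {
            "bin_start": edges[:-1] + 0.5,
            "bin_end": edges[1:] - 0.5,
            "count": counts,
        }
    )
    return table, float(stat), float(pvalue)
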