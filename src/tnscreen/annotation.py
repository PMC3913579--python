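"""Gene annotation for a circular bacterial genome, with GFF3 and TSV I/O.

Gene coordinates are 1-based and inclusive at both ends (GFF3 convention).
Overlapping genes are rejected at load time so that the gene-hit /
intergenic partition used by the insertion mapper stays well defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

_GFF_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent gene annotations."""


@dataclass(frozen=True)
class GeneRecord:
    """One protein-coding gene on the chromosome.

    ``hypothetical`` marks genes without an assigned function;
    ``investigated`` marks genes with prior experimental characterisation in
    this organism (an input flag, not computed); ``operon_id`` groups genes
    transcribed as one unit.
    """

    locus: str
    start: int
    end: int
    strand: str
    description: str = ""
    hypothetical: bool = False
    operon_id: str | None = None
    investigated: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise AnnotationError(
                f"gene {self.locus!r}: invalid interval [{self.start}, {self.end}]"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"gene {self.locus!r}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def in_operon(self) -> bool:
        return self.operon_id is not None

    @property
    def translational_start(self) -> int:
        """Genomic coordinate of the start codon (strand aware)."""
        return self.start if self.strand == "+" else self.end


class GeneAnnotation:
    """Ordered, non-overlapping gene records on a circular genome."""

    def __init__(self, genome_length: int, genes: Iterable[GeneRecord]):
        genome_length = int(genome_length)
        if genome_length <= 0:
            raise AnnotationError("genome_length must be positive")
        genes = sorted(genes, key=lambda g: g.start)
        seen: set[str] = set()
        for g in genes:
            if g.end > genome_length:
                raise AnnotationError(
                    f"gene {g.locus!r} ends at {g.end} beyond genome length {genome_length}"
                )
            if g.locus in seen:
                raise AnnotationError(f"duplicate locus {g.locus!r}")
            seen.add(g.locus)
        for a, b in zip(genes, genes[1:]):
            if b.start <= a.end:
                raise AnnotationError(
                    f"overlapping genes {a.locus!r} [{a.start},{a.end}] and "
                    f"{b.locus!r} [{b.start},{b.end}]"
                )
        self.genome_length = genome_length
        self.genes: list[GeneRecord] = genes
        self._starts = np.array([g.start for g in genes], dtype=np.int64)
        self._ends = np.array([g.end for g in genes], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.genes)

    @property
    def starts(self) -> np.ndarray:
        return self._starts

    @property
    def ends(self) -> np.ndarray:
        return self._ends

    @property
    def coding_fraction(self) -> float:
        """Fraction of the genome covered by annotated genes."""
        if not self.genes:
            return 0.0
        return float((self._ends - self._starts + 1).sum() / self.genome_length)

    # ------------------------------------------------------------------ I/O

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus": [g.locus for g in self.genes],
                "start": self._starts,
                "end": self._ends,
                "strand": [g.strand for g in self.genes],
                "description": [g.description for g in self.genes],
                "hypothetical": [g.hypothetical for g in self.genes],
                "operon_id": [g.operon_id if g.operon_id is not None else "" for g in self.genes],
                "investigated": [g.investigated for g in self.genes],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, genome_length: int) -> "GeneAnnotation":
        genes = []
        for row in frame.itertuples(index=False):
            operon = getattr(row, "operon_id", "") or None
            if isinstance(operon, float) and np.isnan(operon):
                operon = None
            genes.append(
                GeneRecord(
                    locus=str(row.locus),
                    start=int(row.start),
                    end=int(row.end),
                    strand=str(row.strand),
                    description=str(getattr(row, "description", "")),
                    hypothetical=_as_bool(getattr(row, "hypothetical", False)),
                    operon_id=str(operon) if operon is not None else None,
                    investigated=_as_bool(getattr(row, "investigated", False)),
                )
            )
        return cls(genome_length, genes)

    def to_gff3(self, path: str | Path, seqid: str = "chromosome") -> None:
        lines = ["##gff-version 3", f"##sequence-region {seqid} 1 {self.genome_length}"]
        for g in self.genes:
            attrs = [f"locus_tag={g.locus}", f"product={g.description}"]
            if g.hypothetical:
                attrs.append("hypothetical=true")
            if g.operon_id is not None:
                attrs.append(f"operon_id={g.operon_id}")
            if g.investigated:
                attrs.append("investigated=true")
            lines.append(
                "\t".join(
                    [seqid, "tnscreen", "gene", str(g.start), str(g.end), ".",
                     g.strand, ".", ";".join(attrs)]
                )
            )
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_gff3(cls, path: str | Path, genome_length: int | None = None) -> "GeneAnnotation":
        genes = []
        for line in Path(path).read_text().splitlines():
            if line.startswith("##sequence-region"):
                parts = line.split()
                if genome_length is None and len(parts) >= 4:
                    genome_length = int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(f"malformed GFF3 line: {line!r}")
            if fields[2] != "gene":
                continue
            attrs = dict(
                item.split("=", 1) for item in fields[8].split(";") if "=" in item
            )
            genes.append(
                GeneRecord(
                    locus=attrs.get("locus_tag", ""),
                    start=int(fields[3]),
                    end=int(fields[4]),
                    strand=fields[6],
                    description=attrs.get("product", ""),
                    hypothetical=attrs.get("hypothetical", "false") == "true",
                    operon_id=attrs.get("operon_id"),
                    investigated=attrs.get("investigated", "false") == "true",
                )
            )
        if genome_length is None:
            raise AnnotationError("genome length not given and no ##sequence-region header")
        return cls(genome_length, genes)


def _as_bool(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in ("true", "1", "yes")
    return bool(value)
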