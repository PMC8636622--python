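"""Shared domain types: genome layout and gene annotations.

Coordinates are 0-based, half-open (BED convention) throughout the package.
For a minus-strand gene the ``tss`` coordinate is numerically larger than
``tts``; ``plus1_dyad`` always lies downstream of the TSS in the gene's
reading direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = ["GenomeLayout", "GeneAnnotation", "write_chrom_sizes",
           "read_chrom_sizes", "write_annotation", "read_annotation"]


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names and lengths of a (toy or real) genome."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene with its +1-nucleosome dyad anchor.

    ``tss``/``tts`` are stated in reading direction: on the minus strand
    ``tss > tts``.  ``plus1_dyad`` is the dyad coordinate of the first
    nucleosome downstream of the TSS.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tts: int
    plus1_dyad: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.strand == "+":
            if not (self.tss < self.tts and self.plus1_dyad >= self.tss):
                raise ValueError(f"{self.gene_id}: invalid + strand coordinates")
        else:
            if not (self.tss > self.tts and self.plus1_dyad <= self.tss):
                raise ValueError(f"{self.gene_id}: invalid - strand coordinates")

    @property
    def start(self) -> int:
        """Leftmost genomic coordinate (BED start)."""
        return min(self.tss, self.tts)

    @property
    def end(self) -> int:
        """Rightmost genomic coordinate, exclusive (BED end)."""
        return max(self.tss, self.tts)

    @property
    def length(self) -> int:
        return self.end - self.start


def write_chrom_sizes(layout: GenomeLayout, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in zip(layout.chrom_names, layout.chrom_lengths):
            fh.write(f"{name}\t{length}\n")


def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return GenomeLayout(tuple(df["chrom"].astype(str)), tuple(df["length"].astype(int)))


_ANNOT_COLS = ["chrom", "start", "end", "gene_id", "score", "strand", "plus1_dyad"]


def write_annotation(genes: list[GeneAnnotation], path: str | Path) -> None:
    """Write genes as BED6-like TSV with an extra plus1_dyad column."""
    rows = [(g.chrom, g.start, g.end, g.gene_id, 0, g.strand, g.plus1_dyad)
            for g in genes]
    pd.DataFrame(rows, columns=_ANNOT_COLS).to_csv(path, sep="\t", index=False, header=False)


def read_annotation(path: str | Path) -> list[GeneAnnotation]:
    df = pd.read_csv(path, sep="\t", header=None, names=_ANNOT_COLS)
    genes = []
    for r in df.itertuples(index=False):
        if r.strand == "+":
            tss, tts = int(r.start), int(r.end)
        else:
            tss, tts = int(r.end), int(r.start)
        genes.append(GeneAnnotation(str(r.gene_id), str(r.chrom), str(r.strand),
                                    tss, tts, int(r.plus1_dyad)))
    return genes
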