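"""+1-anchored matrices, composite (metagene) profiles, and heatmap ordering.

The central object is an ``AlignedMatrix``: genes x relative-position signal
extracted from a dyad track around each gene's +1 dyad, strand-flipped for
minus-strand genes so that positive positions always point into the gene
body.  Composites average the matrix per position and normalise to the mean
over a chosen window.  Gene bodies of unequal length can also be rescaled
onto a fixed number of bins for TSS-TTS metagenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GeneAnnotation
from .fragments import DyadTrack

__all__ = ["AlignedMatrix", "CompositeProfile", "align_matrix", "composite",
           "heatmap_matrix", "rescaled_metagene"]


@dataclass
class AlignedMatrix:
    """Genes x relative-position matrix; NaN marks positions outside the
    source chromosome."""

    gene_ids: list[str]
    positions: np.ndarray          # relative bp (or bin labels), ascending
    values: np.ndarray             # shape (n_genes, n_positions), NaN = missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.positions = np.asarray(self.positions)
        if self.values.shape != (len(self.gene_ids), len(self.positions)):
            raise ValueError("values shape does not match gene_ids x positions")

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids,
                            columns=self.positions)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class CompositeProfile:
    """Per-position mean across genes, optionally window-normalised."""

    positions: np.ndarray
    values: np.ndarray
    n_genes: int = 0
    norm_window: tuple[int, int] | None = None

    def value_at(self, pos: int) -> float:
        idx = int(np.searchsorted(self.positions, pos))
        if idx >= len(self.positions) or self.positions[idx] != pos:
            raise KeyError(f"position {pos} not in profile")
        return float(self.values[idx])

    def slice(self, start: int, stop: int) -> tuple[np.ndarray, np.ndarray]:
        sel = (self.positions >= start) & (self.positions < stop)
        return self.positions[sel], self.values[sel]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"position": self.positions, "value": self.values}
                     ).to_csv(path, sep="\t", index=False)


def align_matrix(track: DyadTrack, genes: list[GeneAnnotation],
                 upstream: int = 500, downstream: int = 1500) -> AlignedMatrix:
    """Extract track signal around each gene's +1 dyad, strand-aware.

    Column x holds the track value at ``plus1_dyad + x`` for plus-strand
    genes and ``plus1_dyad - x`` for minus-strand genes; out-of-chromosome
    positions are NaN.
    """
    positions = np.arange(-upstream, downstream)
    values = np.full((len(genes), len(positions)), np.nan)
    for i, g in enumerate(genes):
        if g.chrom not in track.data:
            raise ValueError(f"gene {g.gene_id} on chromosome {g.chrom!r} "
                             "absent from track")
        arr = track.data[g.chrom]
        if g.strand == "+":
            lo, hi = g.plus1_dyad - upstream, g.plus1_dyad + downstream
            src_lo, src_hi = max(lo, 0), min(hi, len(arr))
            if src_lo < src_hi:
                values[i, src_lo - lo: src_hi - lo] = arr[src_lo:src_hi]
        else:
            # column x maps to genomic plus1_dyad - x
            lo, hi = g.plus1_dyad - downstream + 1, g.plus1_dyad + upstream + 1
            src_lo, src_hi = max(lo, 0), min(hi, len(arr))
            if src_lo < src_hi:
                seg = arr[src_lo:src_hi][::-1]
                # genomic src_hi-1 -> column plus1_dyad - (src_hi-1)
                col0 = g.plus1_dyad - (src_hi - 1) + upstream
                values[i, col0: col0 + len(seg)] = seg
    return AlignedMatrix([g.gene_id for g in genes], positions, values)


def composite(matrix: AlignedMatrix,
              norm_window: tuple[int, int] | None = None) -> CompositeProfile:
    """Column means over non-missing rows, normalised so the mean over
    ``norm_window`` (a half-open position interval; default the full range)
    equals 1.  Fully-masked columns stay NaN and are excluded from the
    normalising mean."""
    if matrix.values.size == 0:
        raise ValueError("empty matrix")
    with np.errstate(invalid="ignore"):
        means = np.nanmean(matrix.values, axis=0)
    if norm_window is None:
        norm_window = (int(matrix.positions[0]), int(matrix.positions[-1]) + 1)
    sel = (matrix.positions >= norm_window[0]) & (matrix.positions < norm_window[1])
    if not sel.any():
        raise ValueError("norm_window outside matrix positions")
    norm = np.nanmean(means[sel])
    if not np.isfinite(norm) or norm == 0:
        raise ValueError("cannot normalize: window mean is zero or undefined")
    return CompositeProfile(matrix.positions.copy(), means / norm,
                            n_genes=len(matrix.gene_ids),
                            norm_window=norm_window)


def heatmap_matrix(matrix: AlignedMatrix, sort_key: dict[str, float]
                   ) -> AlignedMatrix:
    """Reorder rows by ascending key (e.g. per-gene NRL), ties broken by
    gene_id for determinism."""
    missing = [g for g in matrix.gene_ids if g not in sort_key]
    if missing:
        raise ValueError(f"sort_key missing for genes: {', '.join(missing)}")
    order = sorted(range(len(matrix.gene_ids)),
                   key=lambda i: (sort_key[matrix.gene_ids[i]],
                                  matrix.gene_ids[i]))
    return AlignedMatrix([matrix.gene_ids[i] for i in order],
                         matrix.positions.copy(), matrix.values[order])


def _mean_bins(signal: np.ndarray, n_bins: int) -> np.ndarray:
    """Rescale a 1-D signal to ``n_bins`` intensity-preserving bins.

    For signals at least as long as ``n_bins``, bin i is the mean of the
    piecewise-constant signal over [i*L/n, (i+1)*L/n) with exact fractional
    edge weights; shorter signals are linearly interpolated at bin centres.
    """
    L = len(signal)
    if L == n_bins:
        return signal.astype(np.float64).copy()
    if L < n_bins:
        centers = (np.arange(n_bins) + 0.5) * L / n_bins
        return np.interp(centers, np.arange(L) + 0.5, signal)
    cum = np.concatenate([[0.0], np.cumsum(signal, dtype=np.float64)])
    edges = np.arange(n_bins + 1) * (L / n_bins)

    def integral(x: np.ndarray) -> np.ndarray:
        i = np.clip(np.floor(x).astype(int), 0, L - 1)
        return cum[i] + (x - i) * signal[i]

    ints = integral(edges)
    ints[-1] = cum[-1]
    return np.diff(ints) / (L / n_bins)


def rescaled_metagene(track: DyadTrack, genes: list[GeneAnnotation],
                      body_bins: int = 1000, flank: int = 500) -> AlignedMatrix:
    """Length-rescaled gene-body metagene matrix (TSS..TTS onto
    ``body_bins`` bins, 1 bp flanks), strand-aware.

    Columns are labelled -flank..-1 (upstream), 0..body_bins-1 (body bins)
    and body_bins..body_bins+flank-1 (downstream).
    """
    n_cols = flank + body_bins + flank
    positions = np.arange(-flank, body_bins + flank)
    values = np.full((len(genes), n_cols), np.nan)
    for i, g in enumerate(genes):
        arr = track.data[g.chrom]
        if g.length < 1:
            raise ValueError(f"gene {g.gene_id} has empty body")
        body = arr[g.start:g.end]
        if g.strand == "+":
            up = arr[max(g.start - flank, 0):g.start]
            down = arr[g.end:min(g.end + flank, len(arr))]
        else:
            body = body[::-1]
            up = arr[g.end:min(g.end + flank, len(arr))][::-1]
            down = arr[max(g.start - flank, 0):g.start][::-1]
        values[i, flank - len(up):flank] = up
        values[i, flank:flank + body_bins] = _mean_bins(body, body_bins)
        values[i, flank + body_bins:flank + body_bins + len(down)] = down
    return AlignedMatrix([g.gene_id for g in genes], positions, values)
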