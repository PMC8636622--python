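"""Paired-end fragment handling and dyad-coverage tracks.

Fragments are genomic intervals (0-based, half-open) produced upstream by
paired-end alignment.  Mononucleosomal fragments are selected by length
(140-160 bp by default), optionally depleted of blacklist regions (e.g.
chrM, the rDNA locus), subsampled to a fixed count, and collapsed to their
centre — the dyad estimate — which is extended to a 50 bp window to build a
base-resolution coverage track, raw or normalised to reads per million.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .core import GenomeLayout

__all__ = ["Fragment", "FragmentSet", "DyadTrack", "load_fragments",
           "write_fragments", "filter_fragments", "subsample_fragments",
           "dyad_track", "write_bedgraph", "read_bedgraph",
           "RDNA_EXCLUDE", "MNASE_MIN_LEN", "MNASE_MAX_LEN"]

MNASE_MIN_LEN = 140
MNASE_MAX_LEN = 160
ATAC_MIN_LEN = 50
ATAC_MAX_LEN = 500

# Standard exclusion for S. cerevisiae sacCer3: the rDNA repeat locus.
# Mitochondrial reads are excluded by listing "chrM" with a whole-chromosome
# interval when working with real annotations.
RDNA_EXCLUDE = [("chrXII", 451_000, 469_000)]


class Fragment(NamedTuple):
    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        # floor of the midpoint: a fixed convention for even-length fragments
        return (self.start + self.end) // 2


@dataclass
class FragmentSet:
    """An ordered collection of fragments plus free-form provenance."""

    fragments: list[Fragment]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self):
        return iter(self.fragments)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.fragments, columns=["chrom", "start", "end"])


@dataclass
class DyadTrack:
    """Per-chromosome 1 bp resolution dyad coverage.

    Raw mode: each used fragment adds +1 over a ``2*half_width`` bp window
    centred on its midpoint (edge-truncated), so the raw track sum equals
    the summed window lengths.  RPM mode scales by 1e6 / n_fragments_used.
    """

    data: dict[str, np.ndarray]
    normalization: str = "raw"
    half_width: int = 25
    n_fragments_used: int = 0

    def total(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))


def load_fragments(path: str | Path) -> FragmentSet:
    """Read a BED3-compatible table (extra columns ignored), preserving order."""
    path = Path(path)
    frags: list[Fragment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 columns")
            chrom, s, e = parts[0], parts[1], parts[2]
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise ValueError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})")
            frags.append(Fragment(chrom, start, end))
    return FragmentSet(frags, provenance={"source": str(path)})


def write_fragments(frags: FragmentSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in frags:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\n")


def filter_fragments(frags: FragmentSet,
                     min_len: int = MNASE_MIN_LEN,
                     max_len: int = MNASE_MAX_LEN,
                     exclude: Iterable[tuple[str, int, int]] = (),
                     ) -> FragmentSet:
    """Keep fragments with min_len <= length <= max_len (inclusive bounds)
    that do not overlap any excluded region."""
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    excl: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in exclude:
        excl.setdefault(chrom, []).append((s, e))

    def keep(f: Fragment) -> bool:
        if not (min_len <= f.length <= max_len):
            return False
        for s, e in excl.get(f.chrom, ()):
            if f.start < e and f.end > s:  # any overlap
                return False
        return True

    kept = [f for f in frags if keep(f)]
    prov = dict(frags.provenance)
    prov["length_filter"] = (min_len, max_len)
    if excl:
        prov["excluded_regions"] = sorted((c, s, e) for c, v in excl.items()
                                          for s, e in v)
    return FragmentSet(kept, provenance=prov)


def subsample_fragments(frags: FragmentSet, n: int = 10_000_000,
                        seed: int = 0) -> FragmentSet:
    """Uniform sample of exactly ``n`` fragments without replacement.

    If ``n`` is at least the input size the input is returned unchanged
    (with a provenance note).  Input order is preserved in the sample.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    prov = dict(frags.provenance)
    if n >= len(frags):
        prov["subsample"] = f"requested {n} >= available {len(frags)}; kept all"
        warnings.warn(prov["subsample"])
        return FragmentSet(list(frags.fragments), provenance=prov)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(frags), size=n, replace=False))
    prov["subsample"] = {"n": n, "seed": seed}
    return FragmentSet([frags.fragments[i] for i in idx], provenance=prov)


def dyad_track(frags: FragmentSet, layout: GenomeLayout,
               half_width: int = 25, normalization: str = "raw") -> DyadTrack:
    """Build the dyad-coverage track: +1 over [c-half_width, c+half_width)
    per fragment centre c, truncated at chromosome edges.

    ``normalization="rpm"`` multiplies the track by 1e6 / n_fragments_used,
    with the denominator being the fragments used to build this track.
    """
    if normalization not in ("raw", "rpm"):
        raise ValueError("normalization must be 'raw' or 'rpm'")
    lengths = layout.lengths
    data = {c: np.zeros(l, dtype=np.float64) for c, l in lengths.items()}

    by_chrom: dict[str, list[int]] = {}
    for f in frags:
        if f.chrom not in lengths:
            raise ValueError(f"fragment on unknown chromosome {f.chrom!r}")
        by_chrom.setdefault(f.chrom, []).append(f.center)

    for chrom, centers in by_chrom.items():
        arr = data[chrom]
        c = np.asarray(centers, dtype=np.int64)
        starts = np.clip(c - half_width, 0, len(arr))
        ends = np.clip(c + half_width, 0, len(arr))
        # difference-array trick: O(n + L) window accumulation
        np.add.at(arr, starts, 1.0)
        delta_end = ends[ends < len(arr)]
        np.add.at(arr, delta_end, -1.0)
        np.cumsum(arr, out=arr)

    n_used = len(frags)
    if normalization == "rpm" and n_used > 0:
        scale = 1e6 / n_used
        for arr in data.values():
            arr *= scale
    return DyadTrack(data, normalization=normalization,
                     half_width=half_width, n_fragments_used=n_used)


def write_bedgraph(track: DyadTrack, path: str | Path) -> None:
    """Write the track as 4-column bedGraph (0-based, half-open), run-length
    compressed, zero runs omitted."""
    with open(path, "w") as fh:
        for chrom, arr in track.data.items():
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(arr)]])
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_bedgraph(path: str | Path, layout: GenomeLayout,
                  normalization: str = "raw") -> DyadTrack:
    """Read a 4-column bedGraph into a dense per-base track."""
    data = {c: np.zeros(l, dtype=np.float64) for c, l in layout.lengths.items()}
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"])
    for r in df.itertuples(index=False):
        if r.chrom not in data:
            raise ValueError(f"bedGraph chromosome {r.chrom!r} not in layout")
        data[r.chrom][int(r.start):int(r.end)] = float(r.value)
    return DyadTrack(data, normalization=normalization, half_width=0,
                     n_fragments_used=0)
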