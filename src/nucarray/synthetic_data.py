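"""Synthetic genomes, annotations, and MNase/ATAC-like fragment sets.

Generates phased nucleosome arrays downstream of a +1 anchor with known
ground truth (repeat length, phasing jitter, background rate), so the
downstream track/metagene/array-statistics machinery can be tested without
any external sequencing data.  No sequence is generated — only fragment
intervals over a toy genome.

Randomness is organised as one master seed split into independent named
streams (one per gene, one for background), so adding genes to a layout
does not perturb fragments generated for existing genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import GenomeLayout, GeneAnnotation
from .fragments import Fragment, FragmentSet

__all__ = ["GroundTruth", "make_annotation", "simulate_mnase", "simulate_atac",
           "MNASE_LENGTH_MODEL", "ATAC_LENGTH_MODEL"]

# (min, max, mode) in bp. MNase mononucleosomal fragments are selected at
# 140-160 bp; a triangular shape with mode 150 stands in for the size
# selection. ATAC libraries span a broad 50-500 bp range, modelled uniform.
MNASE_LENGTH_MODEL = (140, 160, 150)
ATAC_LENGTH_MODEL = (50, 500, None)

PLUS1_TSS_OFFSET = 60  # bp from TSS to the +1 dyad in generated annotations


@dataclass(frozen=True)
class GroundTruth:
    """True parameters of a synthetic phased-array fragment set.

    depth is the expected number of array-derived fragments per gene; the
    realised count is Poisson.  background_rate is expected background
    fragments per bp of genome.  jitter_growth optionally widens the phasing
    jitter with nucleosome index k: sd_k = jitter_sd * (1 + jitter_growth*k).
    """

    true_nrl: int = 165
    jitter_sd: float = 10.0
    n_nucleosomes: int = 10
    background_rate: float = 0.0
    fragment_length_model: tuple = MNASE_LENGTH_MODEL
    depth: float = 5000.0
    seed: int = 0
    center_jitter: float = 5.0
    jitter_growth: float = 0.0

    def __post_init__(self) -> None:
        if self.true_nrl < 147:
            raise ValueError("true_nrl must be >= 147 bp (nucleosome footprint)")
        if self.jitter_sd < 0 or self.depth <= 0:
            raise ValueError("jitter_sd must be >= 0 and depth > 0")


def _draw_lengths(rng: np.random.Generator, n: int, model: tuple) -> np.ndarray:
    lo, hi, mode = model
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    if mode is None:
        return rng.integers(lo, hi + 1, size=n)
    # discrete triangular on [lo, hi] with the given mode
    x = rng.triangular(lo, mode, hi + 1, size=n)
    return np.clip(np.floor(x).astype(np.int64), lo, hi)


def make_annotation(n_genes: int,
                    chrom_length: int = 200_000,
                    gene_length_range: tuple[int, int] = (1500, 3000),
                    intergenic_gap: int = 500,
                    seed: int = 0,
                    chrom_name: str = "chrS",
                    alternate_strands: bool = True,
                    plus1_offset: int = PLUS1_TSS_OFFSET,
                    ) -> tuple[GenomeLayout, list[GeneAnnotation]]:
    """Lay out ``n_genes`` non-overlapping genes on a single toy chromosome.

    Genes are placed left to right separated by ``intergenic_gap`` bp, with
    lengths drawn uniformly from ``gene_length_range``.  Strands alternate
    (+,-,+,...) unless ``alternate_strands`` is False, in which case they are
    randomised.  The +1 dyad sits ``plus1_offset`` bp downstream of the TSS.

    Raises ``ValueError`` if the layout cannot fit within ``chrom_length``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = gene_length_range
    if lo > hi or lo < 2 * plus1_offset + 1:
        raise ValueError("invalid gene_length_range")
    max_needed = intergenic_gap + n_genes * (hi + intergenic_gap)
    if max_needed > chrom_length:
        raise ValueError(
            f"cannot fit {n_genes} genes of <= {hi} bp with {intergenic_gap} bp "
            f"gaps on a {chrom_length} bp chromosome (needs up to {max_needed} bp)")

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    lengths = rng.integers(lo, hi + 1, size=n_genes)
    if alternate_strands:
        strands = ["+" if i % 2 == 0 else "-" for i in range(n_genes)]
    else:
        strands = ["+" if s else "-" for s in rng.integers(0, 2, size=n_genes)]

    genes: list[GeneAnnotation] = []
    pos = intergenic_gap
    for i, (length, strand) in enumerate(zip(lengths, strands)):
        start, end = pos, pos + int(length)
        if strand == "+":
            tss, tts, dyad = start, end, start + plus1_offset
        else:
            tss, tts, dyad = end, start, end - plus1_offset
        genes.append(GeneAnnotation(f"gene{i + 1:04d}", chrom_name, strand,
                                    tss, tts, dyad))
        pos = end + intergenic_gap
    layout = GenomeLayout((chrom_name,), (chrom_length,))
    return layout, genes


def _gene_fragments(gene: GeneAnnotation, layout: GenomeLayout,
                    truth: GroundTruth, rng: np.random.Generator) -> np.ndarray:
    """Sample (start, end) pairs for one gene's phased array."""
    n = rng.poisson(truth.depth)
    if n == 0:
        return np.zeros((0, 2), dtype=np.int64)
    direction = 1 if gene.strand == "+" else -1
    k = rng.integers(0, truth.n_nucleosomes, size=n)
    sd = truth.jitter_sd * (1.0 + truth.jitter_growth * k)
    dyads = gene.plus1_dyad + direction * k * truth.true_nrl
    dyads = dyads + rng.normal(0.0, 1.0, size=n) * sd
    centers = dyads + (rng.normal(0.0, truth.center_jitter, size=n)
                       if truth.center_jitter > 0 else 0.0)
    centers = np.rint(centers).astype(np.int64)
    lens = _draw_lengths(rng, n, truth.fragment_length_model)
    starts = centers - lens // 2
    ends = starts + lens
    chrom_len = layout.lengths[gene.chrom]
    ok = (starts >= 0) & (ends <= chrom_len)
    return np.stack([starts[ok], ends[ok]], axis=1)


def simulate_mnase(genes: list[GeneAnnotation], layout: GenomeLayout,
                   truth: GroundTruth) -> FragmentSet:
    """Generate an MNase-like fragment set over phased arrays plus background.

    Per gene, nucleosome dyads are drawn at ``plus1_dyad + k*true_nrl`` (in
    reading direction) with Gaussian phasing jitter; each dyad emits one
    fragment whose centre adds Gaussian centre jitter and whose length comes
    from ``fragment_length_model``.  Background fragments fall uniformly over
    each chromosome at ``background_rate`` fragments/bp.  Fully reproducible
    from ``truth.seed``.
    """
    frags: list[np.ndarray] = []
    chroms: list[np.ndarray] = []
    for i, gene in enumerate(genes):
        rng = np.random.default_rng(
            np.random.SeedSequence(truth.seed, spawn_key=(1, i)))
        arr = _gene_fragments(gene, layout, truth, rng)
        frags.append(arr)
        chroms.append(np.full(len(arr), gene.chrom, dtype=object))

    if truth.background_rate > 0:
        for j, (chrom, chrom_len) in enumerate(
                zip(layout.chrom_names, layout.chrom_lengths)):
            rng = np.random.default_rng(
                np.random.SeedSequence(truth.seed, spawn_key=(2, j)))
            n_bg = rng.poisson(truth.background_rate * chrom_len)
            lens = _draw_lengths(rng, n_bg, truth.fragment_length_model)
            starts = rng.integers(0, np.maximum(chrom_len - lens, 1))
            arr = np.stack([starts, starts + lens], axis=1)
            ok = arr[:, 1] <= chrom_len
            frags.append(arr[ok])
            chroms.append(np.full(ok.sum(), chrom, dtype=object))

    all_frags = [Fragment(str(c), int(s), int(e))
                 for chrom_arr, arr in zip(chroms, frags)
                 for c, (s, e) in zip(chrom_arr, arr)]
    prov = {"source": "synthetic_mnase", "seed": truth.seed,
            "true_nrl": truth.true_nrl, "jitter_sd": truth.jitter_sd,
            "n_genes": len(genes)}
    return FragmentSet(all_frags, provenance=prov)


def simulate_atac(genes: list[GeneAnnotation], layout: GenomeLayout,
                  truth: GroundTruth) -> FragmentSet:
    """ATAC-style variant: broad uniform 50-500 bp fragment lengths."""
    from dataclasses import replace
    atac_truth = replace(truth, fragment_length_model=ATAC_LENGTH_MODEL)
    fs = simulate_mnase(genes, layout, atac_truth)
    fs.provenance["source"] = "synthetic_atac"
    return fs
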