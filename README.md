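# nucarray

Analysis of phased nucleosome arrays from MNase-seq-style dyad data, and a
stochastic hard-sphere simulator of statistical nucleosome positioning.

## The problem

In budding yeast, most genes carry a well-positioned **+1 nucleosome** just
downstream of the transcription start site, followed by an evenly spaced,
phased array of nucleosomes through the gene body. Two population-level
quantities summarise this organisation per gene:

- the **nucleosome repeat length (NRL)** — the centre-to-centre spacing of
  adjacent nucleosomes in the array (bp);
- the **array regularity** — how evenly spaced and well phased the genic
  nucleosomes are.

A long-standing null model for array formation is **statistical
positioning**: nucleosomes packed as hard spheres against the +1 barrier
produce apparent ordering with no active spacing at all. Distinguishing
remodeler-generated arrays from this excluded-volume effect — especially
under histone depletion, where occupancy drops — requires both careful
measurement (dyad tracks, +1-anchored composites, per-gene NRL scores) and
an explicit simulation of the null.

`nucarray` provides both halves for anyone analysing MNase-seq/ATAC-seq
fragment data or modelling nucleosome deposition:

- **`synthetic_data`** — toy genomes and phased-array fragment sets with
  known ground truth (NRL, phasing jitter, background, depth);
- **`fragments`** — BED fragment IO, mononucleosomal length selection
  (140–160 bp), blacklist exclusion, subsampling, and 50 bp dyad-centred
  coverage tracks (raw or reads-per-million);
- **`metagene`** — +1-anchored gene × position matrices, window-normalised
  composite profiles, NRL-sorted heatmap ordering, and TSS–TTS metagenes
  with gene bodies rescaled to a fixed bin count;
- **`arraystats`** — per-gene NRL and regularity by phase-maximised Pearson
  correlation against periodic Gaussian-comb templates, plus the standard
  gene filters (regularity > 0.5, NRL 150–200 bp) and quartile grouping;
- **`statpos_sim`** — the hard-sphere simulator: random sequential
  adsorption of 146 bp footprints on an ensemble of DNA fragments behind a
  Gaussian-positioned +1, with dissociation/re-placement churn cycles;
- **`genestats`** — trimmed gene-body signal densities, occupancy-band gene
  filters, and peak-to-peak distances between composite profiles.

## The core statistics

**NRL / regularity.** For gene *g* with dyad signal *y(x)* over the first
kilobase downstream of its +1 dyad, smoothed with a 75 bp moving average,
and a comb template

&nbsp;&nbsp;&nbsp;&nbsp;*t<sub>L,φ</sub>(x) = Σ<sub>k</sub>
exp(−(x − φ − kL)² / 2σ²)*,

the score of repeat length *L* is *s(L) = max<sub>φ</sub> r(y, t<sub>L,φ</sub>)*
(Pearson correlation, phase-maximised). Then
NRL(*g*) = argmax<sub>L</sub> *s(L)* over a 120–220 bp grid and
regularity(*g*) = max<sub>L</sub> *s(L)* ∈ [−1, 1].

**Statistical positioning.** Each of 10,000 fragments (2,000–2,500 bp)
receives one +1 nucleosome with dyad ~ round(N(73, 25)); further 146 bp
hard-sphere footprints are placed at uniformly random (fragment, position)
draws, rejected on overlap, until footprints cover the target fraction of
the DNA (51% emulating histone depletion). Then, nine times, 20% of the
nucleosomes (never the +1) dissociate and are re-deposited by the same
rule. The dyad composite over the ensemble shows decaying oscillations
behind the +1 — arrays without any spacing machinery.

## Worked example

```python
import numpy as np
from nucarray.synthetic_data import make_annotation, simulate_mnase, GroundTruth
from nucarray.fragments import dyad_track
from nucarray.metagene import align_matrix
from nucarray.arraystats import matrix_array_stats

layout, genes = make_annotation(n_genes=20, chrom_length=250_000,
                                gene_length_range=(2200, 2800), seed=165)
truth = GroundTruth(true_nrl=165, jitter_sd=10.0, depth=10_000,
                    n_nucleosomes=12, seed=165)
frags = simulate_mnase(genes, layout, truth)
track = dyad_track(frags, layout)
mat = align_matrix(track, genes, upstream=500, downstream=1500)
stats = matrix_array_stats(mat)
nrls = np.array([s.nrl for s in stats])
print(f"median NRL {np.median(nrls):.0f} bp, "
      f"median regularity {np.median([s.regularity for s in stats]):.2f}, "
      f"within 2 bp of truth: {np.mean(np.abs(nrls - 165) <= 2):.0%}")
```

prints

```
median NRL 164 bp, median regularity 0.88, within 2 bp of truth: 100%
```

i.e. on arrays generated with a 165 bp repeat and 10 bp phasing jitter the
estimator recovers the repeat length within ±2 bp for every gene (the 75 bp
smoothing biases the argmax down by about one base pair), and the
regularity score sits well above the 0.5 cut used to select genes with
discernible arrays.

The simulator has a command-line front end:

```
simulate-statpos --occupancy 0.51 --fragments 10000 --seed 1 --out run1
```

which writes per-fragment dyad positions, a JSON run manifest with the
per-cycle occupancy, and the dyad composite.

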