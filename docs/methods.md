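# Methods

This note documents the models, parameter choices and numerical conventions
behind `nucarray`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Coordinates and fragment processing

All coordinates are 0-based, half-open (BED convention). A paired-end
fragment's dyad estimate is the floor of its midpoint — for even-length
fragments the midpoint is ambiguous by half a base and a fixed convention
keeps tracks reproducible. Dyad tracks extend each dyad to a
`2 * half_width` window (default 50 bp, the canonical dyad-centred resize),
truncated at chromosome ends, so for interior fragments the raw track mass
is exactly 50 per fragment.

Mononucleosomal selection keeps fragment lengths in the closed interval
[140, 160] bp (ATAC-style selection uses [50, 500]); the bounds are read as
inclusive. Blacklist exclusion (e.g. chrM, the rDNA locus chrXII
451,000–469,000) removes a fragment on *any* overlap, not only containment.
Subsampling (default 10 million) is uniform without replacement, counts
fragments (read pairs, not single reads), preserves input order, and
records its seed in the provenance dict; requesting more fragments than
available returns the input with a warning. Reads-per-million
normalisation divides by the number of fragments actually used to build
the track — post-filter, post-subsample — not the raw library size.

BAM decoding is out of scope: the package starts from fragment intervals
(BED3), which any aligner pipeline can produce; MAPQ and concordance
filtering belong upstream.

## +1-anchored matrices and composites

`align_matrix` places column *x* at `plus1_dyad + x` for plus-strand genes
and `plus1_dyad − x` for minus-strand genes, so positive positions always
point into the gene body. Positions outside the chromosome are NaN and are
excluded from composite means rather than zero-filled (zero-filling creates
spurious edge decay). Composites are per-column means over genes weighted
equally — not coverage-weighted — then divided by the mean over a
normalisation window; the default analysis window is −500..+1500 bp around
the +1 dyad with the full window as the normalisation range. Gene-body
rescaling (TSS–TTS mapped to 1000 bins) averages the piecewise-constant
per-base signal over exact fractional bin edges when the body is longer
than the bin count, and linearly interpolates at bin centres when shorter;
using means rather than sums makes rescaling intensity-preserving.

One consequence of the half-open window convention: reading a row in the
reverse direction shifts window supports by exactly 1 bp. The strand
"mirror" identities in the tests hold up to that fixed shift.

## NRL and regularity

Per gene, the dyad signal over the scoring region (default the first
1000 bp downstream of the +1 dyad; configurable) is smoothed with a 75 bp
centred moving average (boxcar; the window shrinks symmetrically at the
edges so a linear trend passes through unchanged). For each candidate
repeat length L on a 120–220 bp grid (1 bp step) the smoothed profile is
correlated with periodic Gaussian combs at every integer phase 0..L−1; the
score of L is the maximum Pearson correlation over phases, the NRL is the
argmax over L (ties to the smaller L), and the regularity is the maximum
score. Pearson normalisation makes the score scale- and offset-invariant
and bounded by 1, which is what makes a fixed 0.5 selection threshold
meaningful. A zero-variance profile gets regularity 0 and a NaN-flagged
NRL.

**Template width.** The comb's Gaussian σ defaults to 15 bp, the width of
an ideally phased dyad-track peak: a 50 bp dyad window contributes
50/√12 ≈ 14.4 bp, fragment-centre scatter a further ~5 bp. This choice is
a calibration requirement, not a free dial: because the 75 bp smoothing is
applied to the profile but not to the template, a wider template (e.g.
σ = 25 bp) is best matched by a profile that has *already* been blurred by
~20 bp of phasing jitter — the noise-free regularity-versus-jitter curve
then peaks at non-zero jitter, inverting the meaning of the score. With
σ = 15 bp a perfectly phased array scores highest and regularity decreases
strictly with phasing jitter, which is the defining property of a
regularity measure. σ remains configurable via `TemplateSpec`.

**Implementation.** Scoring all (L, phase) pairs naively is O(grid ×
phases × length) Gaussian evaluations per gene. Since every comb with an
integer phase is a sum of single Gaussians at integer centres, the scorer
precomputes, per (profile length, σ), the per-centre dot products with the
profile, the per-centre sums, and the centre × centre Gram matrix; each
comb's correlation then reduces to small gather-sums. This is an exact
reformulation — the unit and acceptance suites verify agreement with an
exhaustive brute-force (L, phase) Pearson loop to within floating-point
round-off (rtol 1e-9), with identical argmax.

Gene selection keeps regularity strictly greater than 0.5 and NRL in the
closed interval [150, 200] bp. Quartile grouping sorts ascending (stable on
gene id), splits into four contiguous groups with sizes differing by at
most one, larger remainders going to the lower quartiles; Q1 holds the
smallest values.

## The hard-sphere simulator

Nucleosomes are 146 bp hard footprints on an ensemble of 10,000 DNA
fragments with lengths uniform on [2000, 2500] bp. Each fragment first
receives one +1 nucleosome with dyad ~ round(Normal(73, 25)) — mean 73 bp
puts the footprint flush against the fragment start, approximating the
promoter-proximal barrier; draws whose footprint does not fit are redrawn
rather than clamped (clamping would pile mass at the boundary). Deposition
then repeats: pick a fragment uniformly (not length-weighted — the literal
random-fragment/random-position rule), pick a dyad uniformly among the
positions where the footprint fits, accept iff no overlap with any resident
footprint; stop once `(placed footprints × 146) / (summed fragment
lengths) ≥ target`. The default target of 51% emulates histone-depletion
occupancy; targets must stay below the 1-D random-sequential-adsorption
jamming limit (~74.8%), and a consecutive-rejection guard (default 10⁷)
raises a saturation error rather than spinning when a target is
practically unreachable.

Churn cycles model histone exchange: in each of 9 cycles (the first plus
eight repeats), ⌊0.2 × N⌋ nucleosomes — N counting all nucleosomes, the
picks drawn uniformly among non-+1 particles only — dissociate and are
re-deposited by the same rule. Counts, and therefore occupancy, are
conserved exactly across cycles; +1 particles survive all cycles by
construction. Randomness is split from the master seed into four named
streams (lengths, +1 draws, deposition, churn picks) so each stage is
independently reproducible; placement draws are consumed in fixed-size
batches, which is deterministic for a given seed.

The dyad composite divides the 1 bp dyad histogram (position 0 = fragment
start) by the number of fragments long enough to contain each position.
Peak calling boxcar-smooths the composite (31 bp default) and applies a
minimum-separation rule (100 bp default, keeping the higher of two close
maxima, via `scipy.signal.find_peaks`). The +2 robustness statistic runs
each occupancy condition several times and reports the absolute difference
of the mean +2 peak positions; per-replicate +2 scatter at the default
ensemble size is a few bp.

Open protocol details resolved here: dissociated nucleosomes may re-land on
any fragment (not only their original one), and the control occupancies
(43%, 60%) use the identical churn protocol as the 51% run.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes:
per gene, nucleosome dyads at `plus1_dyad + k·NRL` in reading direction
with Gaussian phasing jitter (optionally growing with k via
`jitter_growth`, whose in-vivo value the generator makes no claim about),
fragment centres scattered ~5 bp around dyads, fragment lengths from a
triangular distribution on [140, 160] bp with mode 150 (windows are known;
the shape is a modelling choice) or uniform [50, 500] bp for ATAC-style
sets, uniform background fragments at a configurable per-bp rate, and
Poisson total counts. The +1 dyad sits 60 bp downstream of the TSS in
generated annotations — a typical promoter geometry. One master seed is
split into per-gene and per-background streams, so extending a gene set
never perturbs fragments already generated.

What it does *not* emulate: DNA sequence (no FASTA, no sequence-dependent
MNase bias), digestion-degree effects, nucleosome eviction dynamics,
coverage heterogeneity between genes, or replication/transcription
artefacts. Tests passing on this generator therefore demonstrate that the
estimators are correct and well-calibrated for phased Gaussian-jittered
arrays over clean backgrounds — not that real MNase-seq idiosyncrasies are
handled; on real data the regularity score's absolute scale shifts with
digestion degree and background level, which is why downstream analyses
use within-dataset comparisons (filters, quartiles) rather than absolute
scores.

## Gene-body statistics

Densities sum a track over [TSS+100, TTS−100) and divide by the analysed
length; genes with bodies ≤ 200 bp are skipped and reported. The occupancy
filter (0.78–0.88, inclusive bounds) consumes externally measured absolute
occupancies from a two-column TSV — the package never derives absolute
occupancy from MNase coverage, which is not calibrated for that. Composite
peak distances take the argmax of each profile within a search window
(default 0–150 bp around the +1 anchor, configurable; ties toward the
window start) and subtract; affinity composites supplied as bedGraph are
smoothed with the same boxcar as everything else.

## Problem sizes

Default test and script workloads use 10,000-fragment simulation ensembles
(seconds per run) and 12–24 synthetic genes at 5,000–10,000 fragments per
gene for estimator calibration — sizes at which the stochastic acceptance
checks are stable across seeds while the whole suite runs in well under a
minute of compute for the analysis half and a few seconds per simulator
run.
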