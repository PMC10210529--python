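# Methods

This note documents the models, conventions and numerical choices behind
`dafca`, in the order the pipeline runs them.

## Coordinates and missingness

Internally every coordinate is 0-based and half-open (BED/bedGraph
convention). The Bionano text formats are 1-based: CMAP/XMAP positions are
converted at the IO boundary, with fractional base pairs rounded
half-to-even. Genome tracks store one value per fixed-size bin; a bin no
molecule covers is *missing* (NaN), which is distinct from a measured zero
and is propagated — never imputed — through binning, smoothing (by weight
renormalization), metaplots and the allelic analysis.

## Generative model of the simulator

The simulator emulates the two-channel single-molecule assay on an i.i.d.
random genome of configurable GC content (default 0.41, human-like).

**Accessibility ground truth.** A two-state piecewise-constant function per
chromosome: alternating open/closed segments with exponential lengths
(default mean 20 kb each, so segments are much wider than the optical
blur), openness = the probability that a GATC site is enzymatically
labeled (defaults 0.9 open / 0.1 closed). A deproteinized naked control is
the same generator with openness fixed at 1. Openness-as-labeling-
probability is a modeling assumption, not a measured quantity; it makes
the naked control a special case rather than a separate code path.

**Molecules.** Reads are drawn uniformly over the genome with log-normal
lengths (median 200 kb, log-sd 0.35); reads under 150 kb are discarded, as
the instrument does not report them. Each read carries:

- *genetic labels*: CTTAAG sites retained with efficiency 0.85, plus
  spurious labels at 1 per 100 kb, with multiplicative Gaussian sizing
  noise (sd 2% of each inter-label distance) mimicking stretch variation —
  applied to distances, not absolute positions, so errors accumulate the
  way stretch errors do;
- *an accessibility profile*: each GATC site is labeled with probability
  openness x efficiency (efficiency 0.8); a labeled site emits a total
  intensity drawn from N(73.66, 15) arbitrary units, spread as a Gaussian
  point-spread function of sd 350 bp (FWHM ~820 bp, inside the 500-1000 bp
  resolution of nanochannel imaging) and sampled at 500 bp pixel centers;
  per-pixel background noise N(216.18, 25) is added and the profile is
  truncated at zero.

The per-label intensity and background defaults put the simulated
calibration on the same scale as a typical instrument run, whose naked fit
is ~59 units per site over a ~216-unit background; with labeling
efficiency 0.8 the expected fitted slope is 73.66 x 0.8 = 58.9.

**Diploids.** Allele 2 is derived from allele 1 by non-overlapping
deletions, insertions and inversions (the default layout: ten events of
4-6 kb for indels and 40-50 kb for inversions, spread along a 2 Mb
genome). Differential accessibility is planted as 20 kb regions starting
5 kb past an SV — where allele-specific differences are observed in
practice, and where phase-informative (SV-spanning) molecule coverage is
densest — with openness 0.4 on allele 1 vs min(1, 0.4 x fold) on allele 2.
Ground truths are edited per-bp alongside the sequence, so inversions
carry reversed openness and inserted sequence inherits the local state.

**What the simulator does not model** — and hence what passing tests do
not establish about real data: nucleosome-scale positioning, sequence- or
GC-dependent labeling bias, optical chimeras and knots, fragile-site
breakage, reference gaps/blacklist regions, and instrument-specific image
processing artifacts. The genome is i.i.d., so repeat-induced alignment
ambiguity is far rarer than in a real genome.

## Label alignment

Molecules are placed on the reference CTTAAG site map by dynamic
programming over label pairs. A chain scores a match bonus (4.0) per
paired label minus the squared normalized discrepancy between consecutive
inter-label gaps, the normalization being `0.03 x gap + 150 bp` (expected
fractional sizing error plus a label localization floor); skipped
reference sites (unlabeled, ~15% expected) cost 1.0 each and skipped
molecule labels (spurious) 3.0 each, with at most 4 consecutive skips on
either side. Alignment is *local*: unaligned molecule ends are free, which
keeps the null score distribution independent of label count; fragmentary
placements are instead caught by the aligned-fraction filter, as in the
instrument's own pipeline. Both orientations are scored; a tie, or an
equal-scoring placement at a locus more than 2 kb away, yields *no* call
rather than an arbitrary one. Molecules with fewer than 5 labels are not
aligned.

**Confidence.** Reported as a -log10 p-value proxy calibrated per
reference: null molecules are synthesized by sampling inter-label gaps
i.i.d. from the reference's own gap distribution (destroying colinearity
while preserving spacing statistics), their best scores are collected for
several label counts, and a Gumbel right tail is fitted to each; a
molecule's confidence is its score's upper-tail -log10 p under the
interpolated null. On simulated data good 150 kb+ molecules score
confidence 30-75 and gap-shuffled molecules below ~5, so the standard
filter — confidence >= 17, >= 60% of length aligned, length >= 150 kb, all
inclusive — retains the same kind of molecule it does on instrument data.
Exact numerical equivalence with the commercial aligner's confidence is
not attainable; this scale is a calibrated stand-in.

## Track building

Each aligned molecule's profile is projected through its label pairs:
pixel centers are mapped to reference coordinates by piecewise-linear
interpolation between paired labels (extrapolating the flanking pair's
scale beyond the outermost pairs; minus-orientation reverses the profile).
The raw track value of a bin is the *mean* of all pixel intensities mapped
into it across molecules — a mean rather than a sum so molecule count does
not masquerade as signal — and a separate coverage track counts
contributing molecules. Bins with no mapped pixel are missing; a minimum
molecule count per reported bin is configurable (default 1).

Gaussian smoothing operates on the track's own grid: kernel sd `std/step`
bins, truncated to `window/step` bins total and renormalized over
non-missing neighbors (a constant track is reproduced exactly, including
at edges). The shipped defaults (window 4000 bp, sd 2000 bp, step 500 bp)
are the field-standard values for matching a theoretical site track to
Saphyr-resolution data.

## Normalization

`sites(b)` is the GATC count per 500 bp bin of the reference (zero is a
real value). The naked control's binned signal is regressed (OLS) on the
*smoothed* predicted track; the fitted slope/intercept invert to an
effective labeled-site count, and division by the smoothed predicted count
gives the accessible-site fraction. Values can exceed 1 where noise puts
the effective count above prediction; they are reported unclipped (the
floor at 0 reflects that negative site counts are unphysical, the absence
of a ceiling that the prediction is itself an estimate). Bins with zero
predicted sites are missing. The raw effective-site track is also exposed
for users who prefer not to divide.

**Smoothing calibration.** The width used to smooth the theoretical track
must match the data's effective resolution — PSF plus sizing and alignment
jitter — or the regression slope is biased: smoothing the regressor much
more heavily than the optics smooth the response inflates the slope (a
spectral argument gives ~+40% for a 2000 bp sd against a 350 bp PSF, which
we confirmed numerically). `calibrate_predicted_smoothing` therefore scans
candidate widths (250-2000 bp sd, window = 2 x sd) and keeps the one
maximizing the Pearson correlation between smoothed prediction and naked
signal — the same fit-quality criterion by which the standard parameters
were originally chosen on instrument data. The end-to-end pipelines use
this calibration; on simulator data it selects ~500-750 bp and the fitted
slope lands within ~5% of the generative value.

## Metaplots

Gene groups: the expressed set is drawn from the top TPM quantile (default
top 25%, highest first, capped at 5000 genes — both conventions in use are
reachable by the two parameters), the unexpressed set from genes with TPM
exactly 0; ordering is deterministic (TPM descending, ties by gene id).
Scale-regions mode rescales each gene body to 15 kb in 300 bp bins by
per-bp averaging (no unscaled flanks); reference-point mode tiles
[-flank, +flank) around interval midpoints. Minus-strand rows are flipped
so column 0 is always the 5' side. Error bars use the sample (n-1)
standard deviation; per-column n is reported alongside.

## Allele-specific analysis

Molecules are phased by aligning against both allele site maps and
assigning to the allele whose *score* exceeds the other's by a margin
(default 20, roughly the evidence gained by spanning an SV breakpoint on
the correct allele); ambiguous molecules are excluded. Raw scores are
compared rather than confidences: the two references carry independently
estimated null calibrations whose sampling error would otherwise shift the
two confidence scales relative to each other and bias every assignment the
same way.

Each allele's track is normalized with the model fitted once on the naked
control (slope and intercept are instrument constants, not allele
properties) against its own allele's predicted site track. The allele-2
track is lifted to allele-1 coordinates by piecewise-linear mapping
through the SV breakpoints: indels shift downstream coordinates by their
length, inversions reflect positions within the interval, and positions
inside deletions have no image (missing). Windows of 100 kb are centered
on each heterozygous SV midpoint (clipped at chromosome ends, overlapping
windows merged so each bin counts once); within them the normalized signal
is summed in 1 kb bins, bins missing in either allele are dropped and
counted, and a bin is *highly differential* when

    (max + pc) / (min + pc) > 1.5   (strictly)

**Pseudocount.** `pc` defaults to 3 x the robust per-allele noise sd,
estimated as MAD(sum1 - sum2) x 1.4826 / sqrt(2) over all analyzed bins —
for the non-differential majority the between-allele difference is pure
measurement noise, so its MAD estimates the noise floor without being
dragged by genuine differences. A three-sigma prior count keeps
near-background bins (condensed chromatin, where the assay is noisiest)
from being called differential on noise alone, while remaining far below
typical open-chromatin sums so genuine fold changes survive. A
signal-scale pseudocount (e.g. a quantile of the positive sums) is *not*
suitable: it varies with how open the analyzed windows happen to be and
can damp true fold-2 ratios to the threshold.

Feature overlap counts a flagged bin in a class if it intersects >= 1 bp of
any interval (a bin may count in several classes); enrichment is the
fraction of flagged bins overlapping divided by the fraction of all
analyzed bins overlapping.

## Problem sizes and expected numbers

The test suite and the acceptance script use a 2 Mb single-chromosome
genome: chromatin at 100x and naked at 50x coverage for the haploid study
(~850 and ~430 molecules), and 50x per allele for the diploid study —
sizes at which every stage remains statistically meaningful while a full
study runs in about a minute on one core. Under these conditions the
pipeline typically measures: fitted slope within ~5% of the generative
value, naked self-normalization mean 1.00 +- 0.01, ground-truth openness
correlation r ~ 0.97, aligner recovery ~99% within 2 kb, allelic recall
~0.88-0.95 with false-positive rate ~0.02-0.05 at the 1.5-fold threshold.

## Known limitations

- The aligner is a single-hit, single-locus DP; it does not produce split
  alignments, call SVs, or assemble. SV lists and allele maps are inputs.
- Confidence is a calibrated proxy; absolute values are comparable within
  one reference, not across software.
- Normalization assumes a globally affine fluorescence-site relation; no
  GC, stretch-factor or per-run covariate correction is attempted.
- The accessible-site fraction is resolution-limited: sub-bin (sub-500 bp)
  structure is not deconvolved from the diffraction-limited signal.
- The allelic ratio test is a fixed-threshold classifier, not a
  significance test; per-bin uncertainty is not propagated.
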