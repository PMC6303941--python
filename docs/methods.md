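# Methods

## The inference model

MeDIP-seq enrichment of a fixed-width genomic bin is taken to be
multiplicative in the bin's methylation signal and its CpG-density effect,

    y = M · f(n),        f(n) = expit(β₀ + β₁·n),

where `y` is the (extended-fragment) read count of the bin on one DNA
strand, `n` its CpG count, and `M` the methylation-induced signal. The
sigmoid shape encodes antibody-binding saturation: beyond some density,
additional CpGs no longer increase the pull-down efficiency of a fully
methylated fragment. The density effect is estimated from the sample
itself, using the empirical regularity that sparse-CpG regions of somatic
mammalian genomes are nearly fully methylated, so the mean read count of
low-density bins is a fully-methylated calibration series for `f`.

### Fitting

Bins are grouped by exact CpG count; group means ȳ(n) are computed over
all bins of a group, zeros included. With `y_max` the maximum group mean
(the empirical asymptote), ordinary least squares is applied to

    logit(ȳ(n) / y_max) = β₀ + β₁·n

over the usable groups. Exclusion rules for the fit:

- groups smaller than `min_bins_per_group` (default 10) are never fitted
  (their bins are still corrected by the fitted curve);
- groups at and beyond the first argmax of ȳ are excluded — past the
  peak, declining methylation of dense regions (CpG islands) dominates the
  group mean and the calibration assumption fails;
- groups with ȳ ≤ 0 or ȳ ≥ y_max are excluded (logit undefined);
- **saturation guard**: groups with ȳ/y_max above 0.95 (configurable)
  are excluded even below the argmax. The logit derivative `1/(p(1−p))`
  diverges as p → 1, so groups just under the empirical asymptote carry
  unbounded leverage; since the observed maximum generally *under*-states
  the true asymptote, those points systematically inflate β̂₁. Under the
  default simulation conditions the guard reduces the slope bias from
  roughly +12% to +4%.

The regression is unweighted, matching the plain least-squares reading of
the calibration equation; when the true asymptote is known (simulation
studies) it can be supplied in place of the observed maximum, in which
case noise-free group means invert exactly. At least three groups must
survive the exclusions or the fit aborts with an "insufficient dynamic
range" error. A non-positive fitted slope is logged as a warning — on
genuine MeDIP data enrichment must increase with CpG density.

The linear baseline fits a straight line through the same rising-regime
group means and extrapolates it to all densities, floored at a tiny
positive constant (machine epsilon scaled by the largest group mean) so
division stays defined. Its unbounded growth is exactly the classical
over-correction of dense regions that the sigmoid's asymptote avoids.

### Correction, transform, scaling, merge

Corrected signal: `y′ = y / f(n)`. Bins with `y = 0` are assigned
methylation 0 directly — zero enrichment is the model's strongest evidence
of absent methylation, and the log transform is undefined there. For the
rest, `y″ = log y′`, then min–max scaling `(y″ − y″_min)/(y″_max −
y″_min)` over the non-zero bins of the analysis set (genome-wide over the
selected chromosomes, per strand), clamped to [0, 1]. Scaling is invariant
to a global rescaling of counts (the log of a constant cancels), so
sequencing depth does not shift the track.

The full group→fit→correct→scale procedure runs independently on the
plus-strand and minus-strand counts, and the final track is the per-bin
mean of the two per-strand tracks (where exactly one strand is missing,
the other's value is reported). With `strand_split=False` the strands are
summed first and processed once — the strand-blind classical pipeline.
An exact consequence of the design, kept as a regression property: evenly
re-assigning each bin's combined reads to the two strands ("halve and
mirror") makes strand-split inference bin-for-bin identical to combined
inference, because every stage is equivariant under a constant scaling of
the counts. Strand-specific processing can therefore only help when the
strands genuinely differ.

## Counting conventions

Coordinates are 0-based half-open everywhere inside the package;
conversion to 1-based dialects (Bismark coverage) happens only at I/O. A
CpG is indexed by its C position on the forward strand and belongs to the
bin containing that C, even when the G falls in the next bin; dinucleotides
containing N never match. Reads are extended from their 5′ end in the 3′
direction to the fragment-extension length (default 200 bp, a typical
MeDIP sonication fragment; setting it to the read length reproduces
raw-read counting), and an extended fragment increments **every** bin it
overlaps. Duplicate filtering (by 5′ position and strand) and a MAPQ
floor are available but off by default.

## Evaluation harness

Bisulfite truth: per-CpG methylation fractions with read depth, filtered
at ≥ 10 reads per CpG, averaged per bin, with bins reported only when at
least 4 covered CpGs fall in them (missing otherwise, never zero).
Agreement is Pearson and Spearman correlation over pairwise-complete bins,
overall and within four CpG-count strata bounded by nearest-rank quartiles
of the evaluated bins (ties to the lower stratum). The strand-concordance
report builds plus-only and minus-only truth tracks per chromosome at a
series of bin sizes and correlates them — the computation behind the
observation that between-strand bin methylation concordance decays as bins
grow.

## The synthetic-data generator

The generator realizes the inference model's own generative law so that
every stage is testable end-to-end without external data:

- **Genome**: one chromosome, `n_bins` bins of `bin_size` bp (defaults
  20 000 × 100 bp). Per-bin CpG counts are drawn uniformly on 1..20
  (or as a deterministic density gradient). The emitted sequence is built
  CG-free and the requested CpGs are planted at non-adjacent in-bin
  offsets, so realized per-bin counts equal the configuration exactly.
- **Methylation field**: mean bin methylation `0.85 · expit(−1.5·(n −
  17))` — a plateau of 0.85 at low density (typical genome-wide somatic
  methylation; a *constant* plateau cancels exactly in the y_max
  normalization and does not bias the fit) declining to ~0 for the densest
  bins, emulating hypomethylated CpG islands. Per-bin levels are
  Beta-distributed about that mean (concentration 2, giving the wide
  bin-to-bin variation real genomes show at every density), per-CpG values
  jitter about the bin level (Beta, concentration 8), and the two strands
  are coupled per CpG through a Gaussian copula with correlation
  `strand_rho` (default 0.9, in the range observed for real RRBS
  strand concordance), giving correlated but asymmetric strands.
- **Reads**: expected count per strand `(depth/2) · M_s · f*(n)` with
  `f* = expit(−2 + 0.5·n)` and Poisson noise; default total depth 30
  expected reads for a fully methylated bin at bias saturation. In
  read-level mode each counted fragment (50 bp, equal to the read length)
  is placed uniformly *inside* its bin, so recounting the emitted SAM/BED
  with extension 50 reproduces the realized counts read-for-read; per-CpG
  bisulfite-like call tables (binomial sampling at Poisson(30) depth per
  CpG and strand) accompany the reads.

What the generator does **not** emulate: mappability and repeat structure,
sequencing error, copy-number variation, paired-end fragments, non-CpG
(CHG/CHH) methylation, and spatial autocorrelation of methylation beyond
the bin scale. Passing tests therefore demonstrate correctness of the
algorithmic machinery under the model's own assumptions, not performance
on real libraries. One visible consequence: on synthetic data the densest
quartile scores *best* (it has the most signal and no island-specific
artifacts), whereas on real data dense regions are the hardest.

## Problem sizes and numerical choices

The standard synthetic study uses 2×10⁴ bins × 10 seeds; at that size
group means rest on ~1000 bins each, the fitted slope recovers the
generative slope within a few percent, and the whole ten-seed study runs
in seconds. Tie-breaks: the argmax cut uses the smallest-n group attaining
the maximum; quartile boundary ties go to the lower stratum. Degenerate
inputs: an all-zero count vector yields an all-zero track with a warning;
a single distinct transformed value maps all non-zero bins to 1 with a
warning; correlations over fewer than two pairwise-complete bins, or over
constant vectors, are reported as missing (NaN), not as errors.

## Known limitations

- The empirical asymptote `y_max` is a biased (low) estimate of the true
  saturation level; the saturation guard mitigates but does not remove the
  resulting small positive bias in β̂₁.
- Min–max scaling ties the output scale to the extreme bins of the run;
  results are comparable across runs only under the same binning and
  chromosome selection. Per-chromosome scaling is available but changes
  the interpretation.
- Copy-number variation violates the multiplicative model and is not
  corrected.
- The zero-count rule maps unsequenced-but-methylated bins to 0; at low
  depth this depresses accuracy in sparse-CpG regions, an intrinsic limit
  of enrichment assays.
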