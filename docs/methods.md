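# Methods

This note documents the models and numerical choices behind `replistress`:
what each analysis computes, what the matched synthetic-data generators
emulate, and where the design was genuinely open.

## Replication-timing (RT) profiling

**Signal model.** Each probe carries two channel intensities from
early-S and late-S sorted fractions; the RT signal is the log-ratio
M = log2(early/late) (positive = early replicating) with mean log-intensity
A = (log2 early + log2 late)/2. Probes sit on a regular 13 kb grid.

**Normalization.** Within each array, the intensity-dependent dye bias is
estimated by a degree-1 tricube local regression of M on A (nearest-
neighbour span, default 0.3 of probes) and subtracted. Between arrays,
M-values are quantile-normalized: every array is mapped rank-for-rank onto
the mean of the order statistics, so all arrays share an identical marginal
distribution while preserving within-array ranks; ties receive the mean of
the quantiles they span, making the map permutation-stable. Quantile
normalization acts on M-values (not single channels) — a stated assumption,
since the upstream protocol is ambiguous.

**Smoothing.** Per chromosome, normalized M is smoothed by a local-linear
tricube regression over a fixed genomic window. "Bandwidth 3 Mb" is
interpreted as the full window width, i.e. probes within ±1.5 Mb
contribute. The fitted value at a probe is an explicit linear functional
l(x)'y of the data, so its standard error is σ·‖l(x)‖ with σ estimated
globally from the fit residuals (df = n − trace of the smoother). Windows
holding fewer than 3 probes yield missing values. Smoothing never crosses a
chromosome boundary.

**Confidence bands and differential calling.** Replicate profiles are
smoothed separately and averaged probe-wise to form the reported average RT
profile. The confidence band used for differential calling is obtained by
fitting the loess once to the per-probe *mean of the normalized replicate
M-values* and taking fit ± z(level)·SE (z(0.95) = 1.959964, Normal
quantile — per-window probe counts are large). Fitting the band to an
already-smoothed curve instead would leave near-zero residuals and collapse
the band, so the CI-carrying fit always sees probe-level noise; a coverage
simulation (flat truth, σ = 0.3) confirms 92–98% pointwise coverage at
interior probes for the 95% band.

A probe is differentially timed when the two conditions' confidence
intervals are disjoint. Maximal same-direction runs of at least
`min_probes` (default 8, ≈100 kb at 13 kb spacing, suppressing single-probe
calls) become regions spanning first-probe start to last-probe end (0-based
half-open). Direction is *earlier* when the condition of interest sits
above the reference. Genome fractions are reported relative to the
probe-covered span.

**Known limitation — boundary blur.** Band disjointness effectively
thresholds the smoothed between-condition difference at τ = sum of the two
band half-widths. Region edges are unbiased only when τ equals half the
shift amplitude; with ΔRT = 1.5 and the residual spread of Mb-scale domain
structure under a 3 Mb window, τ ≈ 0.25, so each called region extends
~0.5–0.6 Mb beyond the true shift boundary. Under the default synthetic
conditions (3% of the genome shifted in ~3 Mb intervals) the called earlier
fraction therefore overshoots the injected fraction by ≈1 percentage
point. The false-positive rate with matched conditions is essentially zero
(noise in the smoothed difference is ~12 SD below τ). Shrinking the window
would sharpen boundaries at the cost of noisier profiles; the 3 Mb default
is kept as the method's standard operating point.

## Synthetic RT data

RT truth is piecewise constant over domains with exponential lengths
(mean 1 Mb, truncated to [100 kb, 5 Mb]) and values alternating in sign
with magnitude |N(1, 0.2)| log2 units — the Mb-scale early/late domain
structure the smoother assumes. Differential shifts (+ΔRT earlier, −ΔRT
later; default ΔRT = 1.5) are injected into a second condition as
contiguous runs of domains grown toward a 3 Mb interval target — matching
the multi-Mb scale of the reported shifted regions (≈1.6% of a ~250 Mb
chromosome in one region) — until the configured genome fraction is
covered; the realized fraction lands within one domain of the target.
Arrays add per-probe Gaussian noise (default σ = 0.3 log2 units) and a
polynomial dye-bias in A − 10 (default 0.15·x + 0.08·x², with
A ~ N(10, 1)), exercising the MA-normalization nontrivially. With noise and
bias at zero, quantile normalization plus smoothing returns the truth
exactly at probes further than the window from any domain boundary (the
within-array MA step is skipped in that identity because it always removes
the genome-mean trend estimate, a constant offset).

## SMARD fiber statistics

Fibers are run-length encodings of U / EdU / IdU / telomere-FISH segments
in kb (µm inputs convert by the 2 kb/µm combing stretch factor). Scoring
conventions, fixed by the labeling scheme (EdU = first 20-min pulse,
IdU = second):

- replication track length = maximal IdU segment; fork rate = track / 20 min;
- stalled fork = maximal EdU segment with no adjacent IdU;
- origin = EdU segment flanked by IdU on both sides (two diverging forks
  that fired during the first pulse); origin position = EdU midpoint. The
  flanked-EdU rule is an implementation convention, documented rather than
  prescribed by the protocol;
- telomere is replicating when its terminal FISH tract is adjacent to EdU
  or IdU; FISH tract length approximates telomere length. Internal FISH
  tracts are flagged invalid.

The generator emulates the 3 h chase between labeling cycles: most visible
forks are caught *in transit* (EdU tract then IdU tract, per-fork speed
N(2.0, 0.3) kb/min), while origins firing within the first pulse produce
the flanked pattern. Stalls arrest an in-transit fork at a uniform time
within pulse 1 (origin-attached forks are assumed to progress — a
generator simplification). Segments under the 1 kb optical floor are
dropped, and events are placed wholly inside the fiber, since partial
tracks running off a fiber end would not be scored. Telomere-FISH tracts
are lognormal (default mean 9 kb, SD 1.2 kb) and, when replicating, abut an
IdU tract moving at the telomeric fork speed (default 1.0 kb/min).

What this does *not* emulate: track merging/splitting from microscopy
artifacts beyond simple event overlap, fiber breakage, variable stretch
factor, or inter-cycle correlation of fork speeds. Inter-origin-distance
estimates from finite fibers are right-censored (long gaps fall off the
fiber); the Poisson-spacing recovery test therefore uses long (20 Mb)
fibers where the censoring bias is ≈5%, inside its 10% tolerance.

## QIBC cell-cycle gating

Per-nucleus DAPI (integrated, proportional to DNA content, linear scale)
and EdU (mean, log scale) intensities are gated in a flow-cytometry-like
fashion: EdU-positive ⇒ S; EdU-negative nuclei split at a DAPI threshold
into G1 (2N) and G2/M (4N). Automatic thresholds: the EdU cut is the
kernel-density valley between the two largest modes of log10 intensity;
the DAPI cut is the midpoint of the two largest DAPI modes among
EdU-negative nuclei (an explicit split is required if that distribution is
unimodal). Nuclei with DAPI above 2× the 4N mode are treated as doublets,
left unassigned, and excluded from marker summaries. The exact thresholds
used upstream are not published; auto-thresholding is a stated convention.

The generator draws G1/G2M DAPI as lognormals around the 2N/4N means
(CV 5%), S-phase DNA content uniform between 2N and 4N, EdU lognormal with
10× separation between S and non-S, γH2AX lognormal with phase-wise means
(S elevated 2× by default) and 53BP1 focus counts Poisson. Real QIBC data
additionally carry segmentation errors, illumination gradients and
S-phase-entry edge cases that the mixture model does not represent; the
≥95% phase-assignment recovery demonstrates correctness of the gating
logic, not expected accuracy on microscopy data.

## Telomere and growth assays

- Population doublings: PD = log2(harvested/seeded); cumulative PD is the
  running sum over passages.
- Ladder calibration: monotone cubic (PCHIP) interpolation of log(kb)
  against migration distance, exact at the knots, with a monotone inverse.
- TRF mean length = ΣOD / Σ(OD/L) over lane bins — the OD-weighted
  harmonic correction for longer fragments binding proportionally more
  probe. The upstream quantification formula is unpublished ("ImageJ");
  this standard correction is a documented convention.
- Shortening rate = −OLS slope of mean length (bp) on PD.
- qPCR fold enrichment = efficiency^(Ct_ref − Ct_sample), efficiency
  default 2.0 (amplification close to 100% per the assay's own control).
- MadID: per replicate r = m6A/telomere-qPCR; condition means of r are
  scaled to the reference condition (reference ≡ 1.0; gain-invariant).
- ChIP: IP/input (input scaled by its sampled fraction), optionally
  divided by the H3 ratio; lane profiles are background-subtracted
  (minimum) and peak-normalized.

The TRF lane generator evaluates the lognormal length density analytically
on the gel-distance grid — intensity ∝ density × length × |dL/дdistance| —
rather than sampling fragments, so a zero-noise, zero-rate series is
exactly reproducible; multiplicative lognormal bin noise (CV 5%) is added
on top. Lengths shorten linearly with PD (default 9 kb initial,
150 bp/PD, the upper end of the normal-fibroblast range).

## Problem sizes and tolerances

Recovery tests use the sizes at which their standard errors make the
stated tolerances meaningful: 10 × 20 Mb chromosomes (15,380 probes, 2
replicates) for RT shift recovery over 10 seeds; ~5,000 scored forks for
the stall fraction (±2 points); 300 fibers per arm for the 1 kb telomere
difference (±0.3 kb ≈ 3 SE); 5,000 nuclei for gating (≥95% accuracy, EdU
fraction ±1.5 points); 200 simulations for CI coverage (band [0.92,
0.98]). Oracle tests (per-probe WLS, run-grouping scans) are exact to
1e-9. Degenerate inputs (empty layouts, windows with <3 probes, flat
lanes, unimodal DAPI) raise or mark missing rather than guessing.

## Randomness

Every generator is a pure function of (config, seed). Independent
generators derive independent streams from the seed via fixed
`SeedSequence` spawn keys, so, e.g., the fiber set for a seed does not
change when the RT section of a configuration changes.
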