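# Methods

This note documents the model, the numerical choices, and what the
synthetic validation does and does not establish. Notation: C_b is the
per-base coverage of one chromosome of length G; RM_W(b) the centered
running median with odd window W; C̃_b = C_b/RM_W(b) the normalized
coverage; z(b) = (C̃_b − μ̃₀)/σ̃₀.

## Detrending

The running median is the trend estimator because it is insensitive to
atypical regions occupying less than half of the window: a deletion or
duplication of length L shifts the window median only once L/W exceeds
about 1/2, whereas a moving average is shifted proportionally to L/W at
any L. The practical rule is therefore W ≥ 2L for the longest event one
expects to normalize *across*; the default W = 20,001 bases (chromosomes
above 100 kb; otherwise one fifth of the length, forced odd) balances
this against the opposite failure mode, where a very large W stops
following genuine low-frequency trends. z-scores are insensitive to W
over a wide range (checked by a test: μ̃₀ moves < 0.5% and σ̃₀ < 10%
between W = 5,001 and 100,001 on a trend-free 1 Mb track), so W mainly
decides which event lengths are *detectable* rather than how they are
scored.

Both statistics are computed with pandas' centered rolling windows
(an incremental sorted-window structure, O(N log W) total); the tests
pin the output to a naive per-window sort oracle, bit-identically, on
200 random series — linear and circular — at three sampled odd windows
each (a full sweep over all windows would be ~10^9 median evaluations
for no extra coverage of the contract). Circular chromosomes are
handled by wrapping the series; linear chromosomes use truncated
windows at the first/last V positions (median/mean of the available
points, even counts averaging the two central order statistics) so that
detection covers the whole chromosome; users who prefer the strict
"undefined edges" reading can mask the first/last V bases. Where
RM_W(b) = 0 (long fully deleted stretches) the ratio is undefined: such
bases are flagged, excluded from model fitting, and force-classified as
low-side candidates (z sentinel −inf).

## The mixture model of normalized coverage

For depth δ ≫ 1 the central mass of C̃_b is well approximated by a
Gaussian centred on 1 whose width scales like 1/√δ; deleted, depleted
and duplicated regions form a second, minor population. A k=2 Gaussian
mixture is fitted by EM to the unmasked, nonzero C̃ values (exact zeros
are deleted bases and would otherwise drag the outlier component to 0).
k is fixed at 2; no model selection is attempted.

Numerical choices:

- Initialization is robust: μ₀ ← median, σ₀ ← 1.4826·MAD,
  μ₁ ← mean of values outside μ₀ ± 3σ₀ (0.5 if empty), σ₁ ← 2σ₀,
  π₀ = 0.95.
- Convergence: change in mean (per-base) log-likelihood < 1e-6, at most
  200 iterations. The likelihood path is recorded and asserted
  non-decreasing in the tests.
- A variance floor of 1e-6 on both σ prevents component collapse.
- Whole-chromosome inputs (> 500k values) run the E/M passes in float32
  (the cost is memory-bound; parameter error vs float64 is ~1e-4,
  far below the statistical uncertainty); smaller inputs stay float64.
- Fewer than 100 usable values is an error, as is an all-identical
  input.

**Labeling.** The central component is the one with the dominant weight.
This encodes the model's premise (the central population predominates,
π̃₀ ≫ π̃₁) and is deliberately *not* "mean nearest 1": when a track
carries symmetric outliers (e.g., a mix of CN 1.5 and CN 0.5 events),
the outlier component is broad and centred near 1, and a nearest-1 rule
can pick it as central, which collapses detection.

**Single-population guard.** Maximum likelihood for k=2 on an
outlier-free track lets the second component model the slight right
skew of the Poisson ratio — it carves out the central distribution's
shoulder, biasing μ̃₀ low and σ̃₀ low and inflating the false-positive
rate roughly threefold. The outlier component is therefore accepted
only if it is a separated outlier class; if its weight is below 0.1
*and* more than half of its mass lies inside μ̃₀ ± 3σ̃₀, the track is
treated as a single population and (μ̃₀, σ̃₀) revert to the plain
mean/SD of the usable values (the ML fit for k=1). Both conditions
matter: the weight condition keeps genuine broad outlier classes (a
mixed-CN track has π̃₁ ≈ 0.3 centred near 1), the mass condition keeps
small but well-separated ones. The summary output marks this case.

**Thresholds.** Defaults n = ±4 with α = 1/2 (inner threshold m = ±2).
At n = 4 a 1 Mb genome yields ≈ 63 chance-level outlier *bases*
(G·erfc(n/√2), printed loosely as "about 70" in coarse rounding); the
hysteresis clustering merges neighbouring crossings, and the CNV filter
(|mean z| ≥ 5, size ≥ 100 bases) removes what remains of pure noise.
For very low depth (< ~10X) the Gaussian approximation degrades and
thresholds should be raised.

## Detection

The double-threshold scan opens a cluster at the first base with
z ≥ m (ties at exactly m belong to the cluster), extends it while
z ≥ m, and reports it iff max z ≥ n; the low side is symmetric, and
masked bases always satisfy the low-side test. High- and low-side scans
are independent; since m⁺ > 0 > m⁻ a base belongs to at most one side.
On circular chromosomes the scan starts from a rotation whose origin is
quiet on both sides (if none exists the whole chromosome is one
candidate cluster), making clustering rotation-invariant and reporting
an origin-spanning event as a single ROI (its start coordinate is then
larger than its end).

Each ROI records mean/max coverage, mean RM, mean z and the signed
extreme z on its side, and the copy-number ratio
cn = mean(C)/mean(RM) with its log2 (NA at zero coverage). No
length-adjusted significance is computed for long events — consecutive
bases are strongly dependent — only the mean and extreme z.

## The simulator and what the validation shows

`SimulationSpec` defaults describe the validation conditions: 3 Mb
circular chromosome, depth 100X. Noise models:

- `poisson` (default): independent per-base Poisson counts, the
  Lander–Waterman idealization. Used for the injected-event recovery
  experiments.
- `read_placement`: uniform random placement of fixed-length reads
  (100 bp), paired into fragments of N(200, 10) bases (the standard
  short-read-simulator default for 2×100 libraries; mates abut or
  slightly overlap, and overlaps double-count as per-read coverage
  counters do). This reproduces the ~read-length autocorrelation of
  real coverage and is used for the false-positive (null) experiments,
  where excursion *lengths* matter.
- `none`: the noise-free limit, for testing trend shapes.

The optional bow trend multiplies expected depth by
f + (1−f)·sin(πb/G): factor f at both ends, 1 mid-genome.

Injections: cn = 0 zeroes a region exactly; cn < 1 thins counts
binomially; cn > 1 adds Poisson counts at (cn−1) times the region's
mean. Event positions for the recovery experiments are drawn uniformly
with rejection, non-overlapping, and spaced at least W/2 apart so that
no running-median window is majority-atypical — the regime the W ≥ 2L
rule defines as valid for the method. The copy-number experiments run
at W = 40,001, the window of the published copy-number protocol; the
residual negative bias of cn-estimates (≈ −1% at that window, ≈ −3.5%
at W = 20,001) is running-median contamination: a window fraction q
covered by an elevated event shifts the median to the q-adjusted
quantile of the baseline. An event whose per-base mean z is near the
acceptance threshold (CN 1.5 at 100X) may be reported as several
pieces; the recovery experiments therefore estimate an event's CN over
the union span of its matching ROIs, which is unbiased, rather than
averaging per-piece ratios, which are conditioned on exceeding the
inner threshold.

The null experiment (100 event-free read-placement replicates, default
parameters) yields ≈ 20–24 ROIs per 3 Mb replicate (SD ≈ 5), none with
|mean z| ≥ 5 — this is what motivates the CNV filter's z-cut. The
largest null ROI, however, measures 300–500 bases here: with 100 bp
reads in ~200 bp fragments, the length of a level-m excursion around a
level-n peak is of the order of the fragment length. A length cut at
100 bases is therefore *not* reproduced as sufficient by this
generator; users applying the CNV filter to data with longer effective
autocorrelation should scale the size cut with fragment length.

What passing tests do not show: the simulator places reads uniformly —
no GC bias, no repeats/mappability structure, no duplicate-read or
quality-trimming artifacts. Real tracks will show systematic (not just
stochastic) outliers, which is precisely what the z-score machinery is
for; the simulation validates calibration under the null and
sensitivity under clean injections, not robustness to mapping
artifacts.

## Known limitations

- Depth below ~10X: the central distribution is discrete and
  overdispersed; a count-model mixture would be needed.
- Binning trades breakpoint resolution for speed on large genomes; ROI
  coordinates are mapped back to base space at bin granularity.
- The first/last V bases of linear chromosomes use truncated windows,
  so their RM is noisier than the interior's.
- Events longer than ~W/2 corrupt their own baseline estimate; detect
  them with a larger W (two-pass strategy: one run at the default W for
  short events, one at large W for long ones).
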