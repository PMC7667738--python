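# Methods

## The measurement: cell-density estimates from plate photographs

A 384-format pinned array (16 rows x 24 columns) is photographed as a
grayscale raster in which each colony row occupies a 30-pixel horizontal
band and colony centers sit 60 pixels apart.  The `imaging` module turns
such a photograph into one *cell-density estimate* (CDE) per position:

1. **Band profile.** Each 30-px band is reduced to a per-column sum of
   its 25 brightest pixels.  Summing only the top of each column keeps
   the signal-to-background ratio usable for the faint colonies present
   right after pinning, when a full-column sum would be dominated by
   agar background.
2. **Colony windows.** The profile is cut into 60-value windows, one per
   colony, with the colony centered at position 30 (1-based).
3. **Colony intensity** is the median of the 10 largest values among the
   central 20 positions (21-40); the median of an even count is the mean
   of the two central order statistics.
4. **Background** is the mean of the two flank minima, taken over
   positions 5-20 and 40-55.
5. **CDE = colony intensity - background**, deliberately unclipped:
   empty positions can score slightly negative and the calling
   thresholds operate on raw values.

Order statistics use multiset semantics (tied values each count), which
makes every step exactly invariant under a uniform additive illumination
offset: the top-25 sum shifts by 25c, and both the colony median and the
flank minima shift by the same amount, so their difference is unchanged
— exactly so in integer arithmetic, which the test suite checks bit-for-bit.

RGB photographs are collapsed with an unweighted channel mean; the
camera pipeline behind a given dataset is unknown and downstream
thresholds are recalibrated per dataset anyway.  Registration is a fixed
(row, col) pixel offset supplied in the layout; automatic grid detection
is out of scope.  Colony *area* is intentionally not measured — dense
colonies saturate in area long before they saturate in intensity.

## Scoring: density bands, two criteria, control calibration

Light toxicity depends sharply on initial cell density, so raw day-6
growth alone cannot separate a light-sensitive genotype from a thinly
pinned colony.  Scoring therefore proceeds in four steps, all cutoffs
configurable via `ScreenThresholds` with these defaults:

| parameter | default | meaning |
|---|---|---|
| band bounds | moderate 61-120, high >= 121 CDE | day-0 light CDE bands; < 61 discarded |
| `day6_cutoff_high` | 900 CDE | criterium I cutoff, high band (strict `<`) |
| `day6_cutoff_moderate` | 400 CDE | criterium I cutoff, moderate band |
| `lgnorm_cutoff` | 0.75 | criterium II cutoff (strict `<`) |
| `slow_growth_fold` | 1.5 | minimum day-1 dark fold-change |
| `resistant_day6_cutoff` | 1642 CDE | light-resistance cutoff (strict `>`) |
| `resistant_day0_min` | 61 CDE | density gate for resistance calls |

**Criterium I** asks whether the day-6 light CDE stays below the
band-specific cutoff.  **Criterium II** computes the double-normalized
light growth

    LGnorm_j = (LG_j / DG_j) / median_ctr(LGctr / DGctr)

where LG is the day-6 light CDE, DG the day-1 dark CDE, and the
denominator is the median of the same ratio over the neutral his3-delta
control colonies of the *same plate and the same density band* (band
medians differ slightly, so they are kept separate).  LG and DG are raw
CDEs, not day-0-normalized: the day-0 dependence is handled entirely by
the banding.  A plate/band with no usable control takes the median from
the nearest plate by index, preferring the lower index on ties.  By
construction the median control LGnorm on every plate/band is exactly 1.

A strain is called **sensitive** (at its band's confidence level) only
when both criteria hold.  Strains growing less than 1.5-fold in the dark
over day 1 are excluded as generic slow growers before criterium II —
without this filter a slow grower's depressed light growth reads as
sensitivity.  **Resistant** strains are those with day-0 CDE >= 61 and
day-6 light CDE > 1642; the slow-growth filter does not apply to the
standalone resistance call, which uses only the two stated gates (a
slow-excluded colony keeps its exclusion verdict in the main call table
but still appears in `call_resistant`'s output).

Verdict precedence per colony: missing data > low density > slow growth
> sensitive > resistant > not called.  Every exclusion carries a
machine-readable reason string, and every layout position receives
exactly one verdict.  Named variants `confirm_haploid` (single high band
from day-0 CDE 13) and `confirm_diploid` (high >= 105; moderate 45-104
with cutoff 500) reproduce the recalibrated confirmation-assay
thresholds; replicate-colony confirmation data can be collapsed to
strain level with `aggregate_calls` using an *any* (default) or
*majority* vote — the aggregation rule for replicate pinnings is not
uniquely determined, so both are exposed.

The control colonies double as a false-positive meter:
`estimate_false_positive_rate` reports the fraction of in-band controls
that pass their band's criterium-I cutoff, since a genetically neutral
control passing it is a false positive by definition.

## Drop tests

The serial-dilution spot assay quantifies growth as background-subtracted
intensity per unit area (INT/mm^2): spot pixels are summed over a
supplied circular region, and the local background level is the median
of an annulus around the spot (annulus width configurable; the choice of
median makes the estimate robust to neighboring spots clipping the
annulus).  Because growth under illumination is slower, the scored
light/dark ratio compares the *first* light dilution (OD610 ~ 1) to the
*second* dark dilution (OD610 ~ 0.1) at day 3; a per-strain flag reads
the light value at day 5 instead for slow growers (the flag is an input,
not auto-detected — no operational trigger for "slow" exists in the
assay definition).  Strain ratios are compared to the same batch's
wild-type ratios with a pooled-variance two-sided Student t-test
(df = n1 + n2 - 2), significant at p < 0.05.  Two identical zero-spread
groups return t = 0, p = 1; zero-spread groups with unequal means return
p = 0, the one measure-zero input on which p leaves the (0, 1] interval.
Zero-spread is detected from the group ranges rather than the computed
variance so that mean round-off cannot manufacture a spurious t.

## Enrichment

Term over-representation among called strains is tested with the
hypergeometric upper tail P(X >= k) against the *screenable* reference
set (every strain with a comparable day-0 density), followed by
Benjamini-Hochberg FDR control with an enrichment flag at q < 0.06.
Dubious ORFs are removed from hits and reference alike; term sizes are
counted within the reference, not the genome, and terms with fewer than
25 reference genes are skipped.  GO slim is a flattened term set, so no
ontology-graph propagation is performed.  Depletion (lower tail) is
available but off by default: the screen's claims are about
over-representation, and a two-sided reading would double-count.

## The synthetic-data generator

The generator reproduces the statistical structure the pipeline
consumes, with known ground truth; it does not model photochemistry,
ROS kinetics or signaling.

* **Initial density** is lognormal (median 100 CDE, log-sd 0.6), a
  right-skewed law placing roughly a fifth of colonies below the 61-CDE
  discard line — about the fraction unscoreable in a real screen.
* **Light response** is logistic in initial density (maximum 1500 CDE,
  midpoint 60, scale 15), multiplied by a strain effect.  This
  reproduces the near-binary control behavior that motivates the bands:
  controls pinned above ~120 CDE grow out under light, controls below
  60 fail, the region between is variable.  The maximum sits below the
  1642 resistance cutoff because resistance is rare among neutral
  strains; resistant mutants exceed it through their effect multiplier.
* **Planted effects**: sensitive strains scale light growth by 0.1,
  resistant by 2.5.  Slow growers get a 1.1-fold first-day dark growth
  (vs 3.0 for everyone else) *and* a 0.25x light factor, so that only
  the dark-growth filter keeps them from being miscalled sensitive —
  the filter is load-bearing in the simulation, as in the screen.
* **Planted strains draw day-0 density from the same lognormal truncated
  at >= 100 CDE.**  This guarantees every planted strain lands in a
  scoreable band; recovery metrics therefore measure the calling logic,
  not the (density-driven) censoring of the discard band.
* **Noise** is additive Gaussian per measurement, sd 15 CDE — about 1%
  of the dynamic range, a flatbed-scan-scale error.  Emitted CDEs are
  rounded to whole units, as real CDEs derived from integer pixel sums
  are; this also keeps the integer-complete density bands gapless.
* **Drop tests** use multiplicative lognormal spot noise (log-sd 0.15)
  on a tenfold dilution ladder, with the strain effect applied to the
  light/dark ratio.

What the generator does *not* emulate: spatial plate gradients and edge
effects, day-to-day illumination drift, pinning carry-over, correlated
replicate structure, or density-dependent *variance* (real faint
colonies are noisier).  Passing recovery tests therefore demonstrate the
correctness of the scoring logic under the stated statistical
conditions, not robustness to every artifact of real plates.

## Problem sizes and determinism

The test suite and the acceptance script run the screen at 2000 strains
(7 plates, 76 controls each) with 200 planted sensitive, 50 resistant
and 50 slow growers, 100 random plates for the densitometry-vs-oracle
comparison, and 34-strain drop tests with two experiments — sizes at
which every check completes in seconds while keeping per-class counts
large enough for stable precision/recall.  All randomness flows through
explicit integer seeds (`numpy.random.default_rng`); there is no hidden
global state, and identical (spec, seed) pairs give byte-identical
outputs.

## Known limitations

* Registration beyond a fixed pixel offset (rotation, scale, lens
  distortion) is unsupported; images must be pre-cropped to the grid.
* The annulus background of the spot assay assumes spots are far enough
  apart that the annulus is mostly agar.
* With the default geometry, 1-based window position 40 belongs to both
  the colony core (21-40) and the right flank (40-55); raising that
  single profile value can raise the background estimate, which is why
  the monotonicity guarantee is stated for positions 21-39.
* Negative or zero dark-growth denominators exclude a strain rather than
  aborting the run; the exclusion reasons make such records auditable.
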