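# Methods

## Track metrics

A track is an ordered sequence of 2D centroid positions with strictly
increasing timestamps; recordings are treated as single confocal
sections, so no 3D geometry is attempted. Velocity is total path length
over elapsed time; persistence is net displacement over path length;
deviation angles are the signed turns between consecutive displacement
vectors, positive counter-clockwise, in (−180°, 180°] (a perfect reversal
is +180°). Triples containing a zero-length displacement have no defined
turn; they are skipped and counted per track (`n_skipped_triples`), and a
fully stationary track has undefined (NaN) persistence, which group
summaries exclude with a logged count. These conventions matter only in
degenerate data — simulated steps are almost surely nonzero — but real
manual annotations do contain repeated centroids.

The complete-track filter retains a track only if its samples span the
whole analysis window (a point at or before the start *and* at or after
the end) with no internal gap exceeding 1.5× the nominal sampling
interval, then crops it to the window. The analysis window defaults to
360 min (6 h at 10-min sampling); a 7-h window is a one-argument
override. Where the recording literature quotes both 6-h and 7-h windows
for the same kind of experiment, we default to the shorter one that the
filtering rule names and expose the other.

Angle histograms use equal-width bins partitioning (−180°, 180°] with the
half-open `(lo, hi]` convention (an angle on an edge closes its bin), and
default to 8 bins (45°), a conventional rose-plot resolution that divides
360. Deviation angles are pooled across all cells of a group; the
group-level chi-square therefore treats steps, not cells, as counts.
Pooling is only strictly calibrated when steps are exchangeable (no
persistence); see "What the generator does not emulate" below.

## Statistics

* **Welch t-test** (scipy, unequal variances, Welch–Satterthwaite df).
  The tail must be stated by the caller; the pipeline default for
  persistence is `one_tailed_less` (mutant below wild type), velocity
  two-tailed. The degenerate all-constant case returns p = 0.5
  (one-tailed) flagged rather than NaN.
* **Chi-square independence** (Pearson, margins-based expectations, no
  continuity correction). Zero margins are input errors naming the
  offending row/column. For angle-histogram comparisons, bins empty in
  both groups are dropped first so no expected count is zero.
* **Fisher's exact test** is computed with exact integer arithmetic:
  hypergeometric weights are binomial coefficients, the two-tailed p sums
  all tables (same margins) whose weight does not exceed the observed
  weight, with ties decided by integer comparison rather than floating
  tolerance. This makes the test reproducible to the last bit and exactly
  matched to enumeration; p-values per margin family are cached, so
  scanning all tables with a common margin set costs one enumeration.
* **Tukey–Kramer**: pooled within-group MSE on N−k df;
  q = |Δmean| / √(MSE/2·(1/nₐ+1/n_b)); adjusted p from the
  studentized-range distribution (scipy's `studentized_range`, accurate
  well beyond the 1e-6 target). The Kramer form is the standard, mildly
  conservative extension to unequal group sizes; with k = 2 it reduces
  exactly to the pooled two-sided t-test, which the tests verify.

## Synthetic generators

**Tracks.** A biased persistent random walk: the first heading is
uniform; each subsequent heading is drawn from the circular density
∝ exp(κ_p·cos(θ−θ_prev) + κ_b·cos(θ−θ_goal)), sampled exactly as a von
Mises draw around the resultant of the two pulls (the resultant length is
the effective concentration, so aligned pulls reinforce and opposed pulls
cancel). Step length is max(0, N(speed_mean, speed_sd))·dt — a
truncated-normal speed, the simplest non-negative choice. Defaults: dt
10 min, duration 360 min, speed 0.3 ± 0.1 μm/min. The speed scale is a
free parameter, not a calibrated claim: it puts 6-h net displacements in
the tens of microns, the size scale of a forming pouch, but no canonical
pouch-cell speed exists to anchor it. κ_b is the "guidance" knob (0 =
no directional cue, 5 ≈ strongly guided); κ_p controls step-to-step
smoothness. Dropout truncates a cell's track at a uniformly random
interior sample, emulating cells that cannot be followed reliably, so the
complete-track filter has real work to do.

**Phenotypes.** Pouch and CB states are independent categorical draws
per position; fused pairs then replace adjacent normal CB pairs with
probability `fusion_prob` (greedy anterior-to-posterior scan). Shipped
classes and their closed-form mean pouch scores: wild_type 5, tbx1 1
(only p1), single_mutant 1+4·0.75 = 4, double_mutant 1+4·0.25 = 2; CB
means 5.0, 0.0, 4.0, 2.5 analogously. `fusion_prob` defaults to 0 in all
shipped classes so these means are exact in expectation; a class with
fusions enabled has its CB mean reduced by 0.5 per expected fusion.

**Timelines.** Wild type: p1 = 16, p2 = 20, …, p6 = 36 hpf. Only "p1–p2
in place by 20 hpf" is externally constrained; the 16-hpf p1 time extends
the 4-h spacing backward for consistency and is config-overridable. The
tbx1-like class forms only p1, so any observation window from 26 hpf on
is empty — the arrested-outpocketing phenotype. Optional Gaussian jitter
(off by default) keeps the schedule deterministic unless asked.

**Contribution tables.** Two independent binomial draws (marker-positive
and -negative cells) on fixed row totals.

All four generators are bit-reproducible under a fixed config + seed; the
pipeline derives per-generator child seeds (< 2³¹) from one master seed
via `numpy.random.SeedSequence`.

## What the generator does and does not emulate

It reproduces the *statistical shape* the analysis assumes: group
differences in directional bias at matched speed, heavy-tailed
persistence contrast, truncated tracks, class-dependent score
distributions, and the deterministic developmental schedule. It does
**not** emulate spatial interactions between cells (collective cohesion,
contact inhibition), temporal autocorrelation of speed, measurement noise
on centroids, left/right asymmetries, or correlations between pouch and
cartilage defects within an embryo (states are drawn independently,
whereas real CB loss is downstream of pouch loss). Passing tests
therefore validate the *pipeline's arithmetic and calibration*, not any
biological claim about real recordings; with real data the chi-square on
pooled steps additionally assumes within-track turns are roughly
exchangeable, which persistent cells violate (the test is then
anti-conservative — compare per-cell circular-mean angles instead via
`pooled_group_angles(..., per_cell_mean=True)`).

## Numerical choices

- Persistence is clipped to ≤ 1 against last-ulp rounding; the triangle
  inequality guarantees the mathematical bound.
- Deviation angles map the atan2 branch value −180° to +180° so the
  interval is exactly (−180°, 180°].
- Binning uses `ceil((a+180)/width)−1` with an index clip at the
  extremes, realizing `(lo, hi]` without floating-edge ambiguity.
- CSV reads use pandas' round-trip float parser so write→read is the
  identity on coordinates.
- Degenerate statistical inputs (zero variance, zero MSE, empty-in-both
  bins) return flagged results or named errors rather than NaN.

## Test-suite problem sizes

Monte-Carlo checks run at sizes chosen to make their tolerance bands
meaningful on a single CPU in seconds: 2,000 replicates for Welch type-I
calibration (±0.02 band ≈ 4×binomial s.e.), 200 for chi-square null
rejection, 100 for power checks, 100,000 draws for the studentized-range
null oracle, 1,000 random tracks for the metric oracles, n = 200 embryos
for generator round trips (3 s.e. ≈ 0.18 score units), and exhaustive
enumeration of all ~136,000 2×2 tables with total ≤ 40 for Fisher.

## Known limitations

- 2D only; tracks from z-projections inherit projection bias.
- The complete-track filter assumes a single nominal sampling interval
  per dataset (median-estimated when not given).
- Tukey–Kramer p-values are the standard conservative approximation for
  unbalanced designs, not exact.
- Score summaries treat sides of one embryo as exchangeable when
  averaging; no side-effect modeling.
- The track generator's speed process is iid across steps; real cells
  have autocorrelated speeds, so simulated velocity s.e.m.s are smaller
  than real ones at matched n.
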