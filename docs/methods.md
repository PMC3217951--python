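# Methods

## The measurement problem

Newly emerged *Anopheles gambiae* are released (as pupae) at the centre of a
cubic enclosure with eight exit traps: four on the corners and four on the
side centres.  Each night every enclosure is oriented with either a corner
trap or a side trap pointing magnetic North, so the four corner traps sit
either on the cardinal points or on the intermediate points of the compass.
The premise of the design is that an adult trying to move in some direction
is most likely to be caught in the exit trap pointing that way.  Captures
are counted per trap and per collection check, split by sex; in practice
almost all adults are recovered in corner traps, so the analysis uses corner
counts only (side-trap rows are retained in the data model and counted as
exclusions).

Per season, only some collection checks carry signal: dry-season adults are
all dead by the day after emergence, so only the first morning check is
analysed; wet-season adults survive longer and the first two morning checks
are analysed.  Check indexes number the mornings consecutively (0, 1, 2)
and give the discarded afternoon collection a later index (3), so the
default retained-check sets are `{dry: {0}, wet: {0, 1}}`.

## Dispersal vectors

All internal angles are radians, mathematical convention: 0 = magnetic
East, increasing counterclockwise, reduced to [0, 2π).  Compass points and
meteorological wind bearings are converted at the I/O boundary via
θ = ((90° − bearing) mod 360°)·π/180.

Each mosquito caught in a corner trap contributes one unit vector pointing
in that trap's direction; component addition over the four corner traps of
one enclosure-night gives the dispersal vector (x, y), reported in polar
form (θ, r).  For cardinal corners x = N_E − N_W, y = N_N − N_S; for
intermediate corners x = (N_NE + N_SE − N_NW − N_SW)·cos π/4 and
y = (N_NE + N_NW − N_SE − N_SW)·sin π/4.  The magnitude r is kept in raw
mosquito-unit-lengths (0 ≤ r ≤ n) because the significance filter compares
it against a null at matched n; r/n is exported as a convenience column
only.  A zero vector has no direction: θ is NaN, never 0.0, and every
downstream consumer skips undefined directions explicitly.

## Monte-Carlo magnitude filter

Circular tests analyse angles, not magnitudes, so enclosure-nights with no
real directional signal must be screened out first.  Null model: each of
the n captured mosquitoes chooses one of the 4 corner traps independently
and uniformly.  For each observed n, 1000 simulated assignments give an
empirical null distribution of r; a vector is retained iff its magnitude
strictly exceeds the empirical 95% quantile ("exceeds", so the strict
inequality is the conservative, literal reading).  The quantile is the
order statistic at rank ⌈q·n_sims⌉ (lower tie value) — with 1000 draws any
standard interpolation rule differs negligibly, and a fixed rule keeps the
pipeline bit-reproducible.

Thresholds are cached per distinct n by default; `per_night_sims` runs a
fresh simulation per enclosure-night instead (statistically identical).
Child seeds derive deterministically from the master seed — per n in cached
mode, per (night, enclosure) hash in per-night mode — so reruns are
byte-identical.  Because the 4 corner directions are orthogonal zero-mean
unit vectors, E[r²] = n under the null; the test suite uses this closed
form, and exhaustive enumeration at small n, as independent oracles.

## Wind summaries and re-projection

A night's weather is a 10-minute time series from 18:00 to 06:00.  Readings
with speed below the calm cutoff (default 0.1 m/s, configurable) carry no
usable direction; the night's upwind direction is the *unweighted* circular
mean of the upwind (pointing into the wind) direction over non-calm
readings.  Unweighted is the plainest reading of a "circular mean wind
direction", and weighting is a one-line change if wanted.  Speeds and gusts
are summarised by arithmetic means over all readings.  Re-projection
subtracts the nightly upwind mean from a dispersal direction, so 0 rad
means upwind movement and π rad downwind; nights with every reading calm
have an undefined wind frame and their vectors keep θ_rel_wind = NaN.

Wind roses bin non-calm readings by the bearing the wind comes from
(16 bins by default) with per-bin frequencies (summing to 1 over non-calm
readings), per-bin mean speed, and the percent of calm readings.

## Circular inference

Implemented from the primary literature with small-sample oracles; no
installed package provides these tests.

* **Descriptives** — mean direction arg Σe^{iθ}, mean resultant length
  R̄, circular variance 1 − R̄.  R̄ = 0 yields an undefined (NaN) mean.
* **Hodges–Ajne** uniformity test: m = minimum count over all closed
  half-planes bounded by a diameter, computed by a sweep over data angles
  (the count only changes when a boundary crosses a data angle);
  p = min(1, 2^{1−n}(n − 2m)·C(n, m)), Hodges' exact formula.  When
  n = 2m the formula degenerates to 0 while the data are maximally
  dispersed, so p is reported as 1 with a method note.  Requires n ≥ 4
  (below that no useful level is attainable).
* **Watson–Williams** F test for equality of mean directions, k groups:
  F = (N−k)(ΣR_j − R) / ((k−1)(N − ΣR_j)) times the 1 + 3/(8κ̂)
  correction, referred to F(k−1, N−k).  κ̂ comes from the within-group
  weighted mean resultant length by the piecewise inverse-A approximation
  (2r + r³ + 5r⁵/6 below r = 0.53; −0.4 + 1.39r + 0.43/(1−r) to 0.85;
  1/(r³ − 4r² + 3r) above).  A warning is raised when κ̂ < 1.
* **Harrison–Kanji** two-factor ANOVA analogue: squared resultant lengths
  decomposed by cell, row and column.  Above the published branch point
  (κ̂ ≥ 2, estimated from the total resultant) effects are F ratios against
  the residual mean square, main effects corrected by
  1/(1 − 1/(5κ̂) − 1/(10κ̂²)).  Below it the scaled decomposition
  2/(1 − A₁(κ̂)²)·(effect sum) is referred to chi-square with **twice** the
  ANOVA df per effect: the between-group resultant term carries a cosine
  and a sine component, each asymptotically chi-square with (levels − 1)
  df, and the doubled-df reference is exact in the κ → 0 limit where both
  component variances equal 1/2.  (With single df the branch is markedly
  anti-conservative — empirical type-I ≈ 0.13 at κ = 2 with 18 angles per
  cell — and with doubled df it calibrates to ≈ 0.04–0.06.)  The branch
  taken, κ̂ and the residual df are recorded in `method_note`.
* **Wilcoxon signed-rank** on per-trap (male − female) counts, paired per
  corner trap × enclosure-night: zero differences dropped; up to 25
  non-zero pairs the two-sided p is exact, by convolving the sign-assignment
  distribution of the doubled midranks (valid under ties, where scipy's
  exact method is not); beyond 25 pairs the normal approximation with tie
  and continuity corrections (scipy) is used.

All tests are rotation invariant and return (statistic, df, p,
method_note); degenerate inputs (zero resultants, empty cells, one-level
factors) raise rather than silently substituting values.

## Synthetic campaigns

The generator emulates the field design so the whole pipeline can be tested
against known truth:

* **Design**: 13 dry + 16 wet nights split across two years (6+7 and 8+8),
  3 enclosures per night placed on 3 of 4 village sites (two per village
  side), nightly random orientation (can be pinned for controlled
  experiments).
* **Load and capture**: pupae per enclosure ~ truncated normal, mean 345,
  SD 83 on [200, 470]; captures binomial at the capture rate (default 0.2,
  which reproduces the observed ≈ 70 adults per enclosure-morning).
* **Behaviour**: each adult draws a heading ~ von Mises(μ, κ) and enters
  the corner trap nearest its heading (Voronoi assignment over trap
  directions, ties broken counterclockwise); with probability
  p_side = 0.036 it leaks into the nearest side trap instead, reproducing
  the observed ≈ 96.4% corner share.  The default rule is anemotactic with
  a seasonal switch: μ = nightly upwind mean + π in the dry season
  (downwind) and + 0 in the wet (upwind).  κ is a free parameter (the field
  data cannot constrain individual heading concentration); the reference
  campaign uses κ = 2 and every test states the value it uses.
* **Checks**: wet-season captures split multinomially over the collection
  checks in the observed proportions (43, 9, 119, 10)/181 for first
  morning, afternoon, second morning, third morning; dry-season captures
  all occur at the first morning check (mortality itself is not modelled).
  Zero counts are emitted as explicit rows.
* **Weather**: 73 ten-minute readings per night; from-directions von Mises
  around the seasonal mean (dry: 315°, κ = 4 — the consistent nocturnal NW
  trade wind; wet: 225°, κ = 1 — weaker, more variable monsoon flow);
  speeds gamma (shape 2) scaled so the grand mean including calm intervals
  matches the seasonal mean (dry 0.225, wet 0.12 m/s — per-season averages
  of the observed nightly means); calm probabilities 0.05/0.15; humidity
  and temperature seasonal constants (31%/94%, 30.8/23.7 °C); gust =
  speed × seasonal multiplier.
* **Reproducibility**: every night draws from a child generator seeded by
  (master seed, year, season, night index), so campaigns are byte-identical
  across reruns and invariant to generation order.  A truth table records
  each enclosure-night's intended μ, κ and the upwind direction realised by
  its simulated weather.

What the generator does *not* emulate: within-enclosure micro-climate,
heading-dependent side-trap leakage, survival/energetics, attractant
plumes, site geography, or any dependence of behaviour on temperature and
humidity beyond the seasonal μ rule.  Passing recovery tests therefore
shows the *pipeline* recovers a known directional signal under the stated
design — not that real mosquitoes behave like the generator.

## Pipeline order and reporting

aggregate → dispersal vectors → wind summaries → re-projection → magnitude
filter → descriptives on significant vectors only → Hodges–Ajne per
season-year block → Watson–Williams between years within season and
between site pairs within village side → Harrison–Kanji side × season →
Wilcoxon sex check → wind roses.  Groupings are data-driven from the CSV
factor columns.  Every exclusion (side-trap rows, out-of-window checks,
non-significant vectors, nights without a defined wind frame) is counted in
`report.json`, because the headline sample sizes are products of those
filters.  Tests whose preconditions fail (too few angles, degenerate
groups) are skipped with a recorded reason, never silently.

## Problem sizes

The reference campaign is the full design (29 nights, 87 enclosure-nights,
≈ 6000 captures).  Calibration suites use 500–1000 replicates (filter
false-positive rate on 1000 uniform-null enclosure-nights; test type-I
rates over 500 null replicates at κ = 2 with 18 angles per cell; parameter
recovery over 200 replicate 16-night campaigns), sizes at which the
binomial standard error of an ≈ 5% rate is ≈ 0.7–1%.

## Known limitations

* The Hodges–Ajne exact p is anti-conservative for m near n/3 and
  degenerate at m = n/2; it is exact in the small-m regime where decisions
  are made.
* The Watson–Williams and Harrison–Kanji F branches assume a common von
  Mises concentration across groups; violations are flagged only via the
  κ̂ warning, not tested.
* The doubled-df chi-square reference for the low-concentration
  Harrison–Kanji branch is exact only as κ → 0; at the κ ≈ 2 branch point
  it is mildly conservative (measured type-I ≈ 0.05 mixed over branches).
* The significance filter screens on magnitude only; enclosure-nights with
  two opposed movement modes are excluded along with the truly
  directionless, and no multimodality diagnostics are provided.
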