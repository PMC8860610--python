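# Methods

## Measurement model

A confocal ALEX experiment interrogates single molecules diffusing through a
femtoliter excitation volume at ~50 pM, so transits ("bursts") are sparse and
non-overlapping.  Two lasers alternate — donor excitation during phase
[0, 50) µs, acceptor excitation during [50, 100) µs of a 100 µs period, at a
1 MHz timestamp clock (1 tick = 1 µs) — and two detectors (green/red) record
photon timestamps.  The phase of a timestamp within the alternation period
decides which laser produced the photon, giving the three classic streams:

| phase        | detector | label   |
|--------------|----------|---------|
| donor on     | green    | DD      |
| donor on     | red      | DA      |
| acceptor on  | red      | AA      |
| acceptor on  | green    | discard |

Per burst, `E* = DA/(DA+DD)` and `S = (DA+DD)/(DA+DD+AA)` are *apparent*
quantities: no leakage, direct-excitation or gamma correction is applied.
This matches how destabilization assays report them — free DNA shows
E* ≈ 0.2 purely from donor leakage into the red channel, and the statistic of
interest ("loss of FRET", the percentage of bursts with E* below a universal
0.4 cutoff) is defined on the apparent scale.  A burst exactly at the cutoff
counts as high-FRET; the choice is arbitrary but fixed.

## Dual-color burst search

Photon *i* is "hot" when the half-open centered window
[t_i − w/2, t_i + w/2) contains at least `m_dex` donor-excitation photons
(DD + DA) **and** at least `m_aex` acceptor-excitation photons (AA).  A burst
is a maximal run of consecutive hot photons, with the additional rule that a
run breaks between consecutive hot photons farther apart than the window —
two photons whose windows share nothing cannot belong to one transit.  Bursts
with fewer than `min_size` total photons are dropped.  Defaults
(w = 500 µs, m_dex = m_aex = 10, min_size = 30) follow established ALEX
practice; they are not uniquely dictated by any one published dataset, so
they are fixed, documented and config-exposed.  The production search is
O(n log n) via sorted-array counting and is property-tested against an
independent O(n²) re-derivation on random streams.

Requiring simultaneous DEX and AA rates enriches doubly labeled molecules,
so stoichiometry filtering defaults off (it is available in
`select_bursts`).

## Synthetic photon streams

The generator emulates exactly the statistical structure the analysis
assumes, nothing more:

* burst starts at exponential inter-start times (default 20 bursts/s), burst
  durations exponential (default mean 1 ms); a collision with the previous
  burst is redrawn, and exceeding the retry budget is an error — the sparse
  model is then inapplicable;
* within a burst, photon counts per excitation window are Poisson with the
  species' on-rates (default 100 photons/ms while the respective laser is
  on, i.e. ~50 detected photons/ms of transit — a typical mid-brightness
  confocal regime); each donor-excitation photon is red with probability
  `p_da`, the per-species parameter that folds true FRET and donor leakage
  together (free DNA 0.2, intact nucleosome 0.7);
* background photons are Poisson throughout at per-window, per-detector
  rates (defaults 1000/600/300/900 s⁻¹ for donor-green/donor-red/
  acceptor-green/acceptor-red — sub-kilohertz values typical of a clean
  confocal setup, and far below any burst-search threshold);
* randomness derives from one top-level seed via `numpy` `SeedSequence`
  spawning: child 0 drives placement, species assignment and background,
  child i+1 the i-th burst.  Identical config ⇒ byte-identical stream.

What it deliberately does **not** model: diffusion paths and the resulting
intra-burst intensity envelope, point-spread functions, triplet blinking,
photobleaching, dynamic interconversion within a burst, and acceptor direct
excitation during donor windows (default 0).  Passing recovery tests
therefore show that the *analysis chain* is unbiased for mixtures of static
species under Poisson statistics — not that any of those photophysical
effects are handled.

`simulate_burst_table` is a fast path drawing per-burst counts directly
(Poisson DEX count, binomial DA split, Poisson AA) without timestamps.
Because it skips the search, its tables should be filtered with the same
`min_size` before threshold statistics; sub-threshold bursts otherwise
inflate shot-noise misclassification around the cutoff.  The pipeline does
this automatically.

A note on accuracy of the threshold statistic: with ~15–50 donor-excitation
photons per retained burst, a `p_da = 0.2` burst crosses E* = 0.4 with
probability up to a few percent, which biases the loss-of-FRET of a
0.70-weight mixture downward by roughly half a percentage point.  This is a
property of the statistic at realistic photon counts, not of the simulator;
recovery tests at ≥ 10,000 retained bursts budget 1 percentage point for the
combined bias and sampling noise.

## Group statistics

Conditions are summarized as mean ± sample s.d. (n − 1 denominator) over
n = 3 replicates and compared by one-way ANOVA followed by Tukey HSD.

*Replicate reconstruction.*  A balanced one-way ANOVA depends on the data
only through group means and the pooled within-group variance, so any
triplet with a given (mean, s.d.) yields identical F and Tukey p-values.
`reconstruct_replicates` returns the symmetric triplet {m − s, m, m + s},
whose sample mean and s.d. equal m and s exactly.  This is what makes
published p-values recomputable from figure captions; only n = 3 is
supported, deliberately.

*Studentized range.*  The Tukey adjusted p-value is
P(Q_{k,df} ≥ q) with q = |Δmean|/√(MSE/n).  The tail is computed by direct
double numerical integration: the inner integral
k ∫ φ(u) [Φ(u + r) − Φ(u)]^{k−1} du is the CDF of the range of k standard
normals, and the outer integral averages it over the distribution of the
pooled scale estimate (chi_df/√df).  Both axes use 256-node Gauss–Legendre
quadrature (u over [−9, 9], s over the 10⁻¹⁴–(1−10⁻¹⁴) chi quantile range),
giving absolute accuracy near machine precision — far inside the 10⁻⁶
target — verified against an independent Monte-Carlo oracle and against
`scipy.stats.studentized_range`.

Caveat for comparisons with the literature: many analysis stacks compute
Tukey p-values by interpolating tabulated studentized-range quantiles, which
can be off by ~0.02 in the mid-range (q ≈ 2, k = 7).  Exact integration here
reproduces published values computed the same way to ≤ 0.001, but values
printed from table-interpolating software can differ by up to that
interpolation error.

Degenerate designs are reported, not hidden: zero pooled variance with
unequal means gives F = ∞, p = 0 with a warning; unbalanced groups are
rejected (`UnsupportedDesignError`) rather than silently Tukey–Kramer'd.

## Förster geometry

`bp_separation → contour_distance_nm → forster_efficiency` chains the design
arithmetic for the labeled construct: positions 35/112 → 77 bp; B-DNA rise
0.34 nm/bp → 26.18 nm (no transfer at R₀ = 5 nm since E = 1/(1+(r/R₀)⁶));
the ~4.5 nm dyad-axis inter-dye distance — taken as a direct input from the
nucleosome crystal structure, not computed from coordinates — gives
E ≈ 0.65.  `apparent_e(E, leakage) = E + leakage·(1 − E)` maps a true
efficiency to the apparent scale under a pure-leakage model.  No
accessible-volume dye modeling and no orientation-factor treatment.

## Gel densitometry

Coordinates run from the gel top (wells, position 0) downward; on alkaline
gels longer products migrate less, so longer = smaller position.  A lane
profile is the raw per-row column sum over the lane's band (no background
rolling-ball or other ImageJ-style preprocessing).  The dominant band is fit
by least squares to `baseline + A·exp(−(x−c)²/2σ²)` (scipy `curve_fit`),
initialized from the maximum, half-max width and minimum.  Flat profiles and
non-convergent fits return `converged = False` with diagnostics — the center
is never fabricated — and the residual sum of squares is reported so
multi-band contamination is detectable.  Only the leading-strand band is
modeled; lagging-strand/Okazaki material is out of scope.

Enhancement `100·(test − neg)/(pos − neg)` is affine-invariant, exact at the
controls by construction, and permitted outside [0, 100] (test reactions can
exceed the positive control).  It can be computed on ladder-calibrated
lengths (log₁₀ length linear in migration; slope necessarily negative) or
directly on fitted centers; centers are the default since a ladder is not
always available, with `metric_kind` recording which was used.

Simulated gel images spread each lane's 1-D profile evenly over a
power-of-two-wide column band, so extraction by column sum returns the
profile exactly (including its noise draw) — the image round trip adds no
unrelated noise model.  Pixel values beyond the 16-bit range are an error at
simulation and TIFF-write time.

## Problem sizes in the test suite

The suite favors the smallest sizes at which each claim is sharp: oracle
equivalence on 200 random streams of ≤ 300 photons; population recovery on
14,000 simulated bursts per condition (≥ 10,000 surviving the size filter),
where the binomial error budget is well under a percentage point; the
Monte-Carlo studentized-range check at 10⁶ draws (standard error ≤ 0.0005);
gel recovery over 100 noise seeds at 2 % relative noise.  The full suite
runs in well under a minute on one core.

## Known limitations

* `p_da` is a single static number per species: dynamic FRET within bursts,
  gamma, and acceptor direct excitation are not modeled or corrected.
* Burst-search parameters are field-standard defaults, not fitted to any
  instrument; absolute burst counts are therefore not comparable across
  setups, only the per-burst statistics.
* Replicate reconstruction and Tukey HSD assume the balanced n = 3 design;
  nothing here handles unbalanced or multi-factor layouts.
* The gel model is a single Gaussian band; strongly skewed or overlapping
  bands show up only as elevated `rss`.
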