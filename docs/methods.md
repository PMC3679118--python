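# Methods

## The problem

Sediment-core proxy counts are snapshots of unequal effort: a sample's
taxon list grows with the time span it accumulated over, the sediment
volume analyzed, and the number of particles counted — the
species–time–area problem in paleoecological form. Macroremain records add
a harder constraint: influx sums are typically far below one particle
cm⁻²·yr⁻¹ and many samples are empty, so individual-based rarefaction,
which needs a positive minimum count, cannot be applied to the raw series.
`paleodiv` implements the standardization chain that makes richness and
evenness estimates comparable along a core and between cores.

## Resampling model

Sample ages come from piecewise-linear interpolation of the age–depth
control points (construction of the age–depth model itself — calibration,
smoothing — is out of scope; control points are consumed as given, and the
package refuses to extrapolate beyond them). Counts and volume of each
sample are distributed over half-open bins [t, t+w) of constant width *w*
in proportion to the temporal overlap of the sample's age span with each
bin (the proportion matrix). Binned counts over binned volume give
concentration; multiplying by the bin's sedimentation rate — the depth
deposited across the bin's age span under the inverse age–depth map,
divided by *w* — gives influx.

Choices where the procedure is genuinely open:

- **Grid anchor.** Bins are anchored at the youngest sample's top age and
  run back in time. Deterministic and reproducible; an arbitrary anchor
  would change bin contents slightly but not the method.
- **Partial bins are dropped, not renormalized.** Edge bins and bins over
  unsampled gaps have coverage < 1; renormalizing would extrapolate influx
  from partial data. Coverage is reported per bin so callers can relax
  this.
- **Contribution weights are temporal.** The weight of sample *s* in bin
  *b* is overlap time / sample span; volume-proportional weighting is
  equivalent here because volume enters both numerator and denominator of
  the concentration.
- **Numerical guard.** Overlaps below 10⁻⁹·w yr are zeroed: the depth→age
  round trip can carry ~10⁻¹⁵-yr float noise at sample boundaries, which
  would otherwise leak phantom counts into genuinely empty bins and
  corrupt the minimal-window search.

**Minimal window.** `find_min_window` scans integer *w* (1-yr steps) for
the smallest width at which every retained bin has a positive influx sum;
it reports the longest empty-sample gap when no width up to `w_max`
(default: the record span) works. The median-resolution policy
(`median_resolution`, rounded to integer years) is the pollen default,
where minimum influx sums are always comfortably positive.

## Rarefaction

Expected richness at subsample size n is the Heck et al. form,
E(T_n) = Σᵢ [1 − C(N−Nᵢ, n)/C(N, n)]. Influxes are real-valued, so the
coefficients are evaluated through log-Γ:
C(a, n)/C(N, n) = exp[lnΓ(a+1) − lnΓ(a−n+1) − lnΓ(N+1) + lnΓ(N−n+1)].
A taxon with N − Nᵢ < n cannot be missed and contributes exactly 1 (the
generalized coefficient is 0 or undefined there). An `integer_counts`
option rounds abundances first, to mimic factorial-on-integers
implementations.

**n′ replication.** The whole influx matrix is multiplied by n′/n (n = the
record's minimum bin sum), which leaves all within-bin proportions
untouched, and every bin is rarefied at n′, for n′ = 1…R (default R = 500).
The subsample size is capped at the bin's scaled total — binding only for
the minimum bin itself, where the cap equals n′ up to rounding. Because
both the scaling and the cap depend on the influxes only through ratios,
the E(T_n′) surface is invariant to multiplying all influxes by any
positive constant; this is tested to 10⁻⁹. Summary series are the per-bin
median and the 5/25/75/95 percentiles over n′ (configurable), plus the
minimax transform (x − min)/range of the median series; a constant series
maps to zeros with a warning.

The per-bin/per-n′ surface is computed by a vectorized log-Γ evaluation
(one (R × S) array per bin), so R = 500 on ~60 bins costs tens of
milliseconds.

## Evenness

Hurlbert's PIE, Δ₁ = N/(N−1)·(1 − Σpᵢ²), evaluated on each bin's influx
vector with real-valued N. When N ≤ 1 — routine for macroremain influx —
the finite-sample factor is undefined or negative, and the uncorrected
1 − Σpᵢ² is returned with a logged note. Δ₁ is exactly 0 for single-taxon
bins. Functional-group percentages (tree / shrub / herb / other) summarize
composition; zero-total rows are reported as missing, never 0/0.

## Window statistics

Per-bin median E(T_n′) values (not the full replicate pool — the summary
series is the quantity of interest, and pooling the 500 strongly dependent
replicates would fabricate sample size) are grouped into adjacent
half-open 1000-yr windows tiling from floor(min age/width)·width. The
Kruskal–Wallis test uses the tie-corrected H with a χ²(k−1) p-value; an
all-identical pool returns H = 0, p = 1. When significant at α (default
0.05), pairwise comparisons use Conover's rank-based procedure: t
statistics from pooled-rank means with tie-corrected rank variance scaled
by (N−1−H)/(N−k), df = N−k, two-sided and unadjusted by default (a Holm
option exists). Letters come from an insert-and-absorb compact-letter
display, which guarantees by construction that two windows share a letter
iff their pairwise p ≥ α.

## Synthetic records

The generator emulates the two study regimes rather than any single site:

| parameter | macro-like | pollen-like |
|---|---|---|
| samples | 84 | 62 |
| resolution (yr/sample) | U(24, 351) | U(50, 379) |
| volume (cm³) | U(8, 12) | 1 |
| intensity (particles·cm⁻³·yr⁻¹) | 8×10⁻⁴ | 3.0 |

Counts are Poisson–multinomial: sample total ~ Poisson(intensity × volume
× duration), allocated to a 20-taxon pool (6 trees, 5 shrubs, 8 herbs, 1
other) with geometric rank-abundance weights (ratio 0.75). The macro
intensity makes the expected count ≈ 1.5 particles per sample, giving
~25–35% empty samples and influx sums well below 1 cm⁻²·yr⁻¹ — the regime
the minimal-window search exists for. The pollen intensity gives hundreds
of grains per sample; totals under 100 are redrawn so the regime keeps the
no-sparse-samples character of real pollen counts. The age–depth model has
equally spaced depth control points with multiplicatively jittered segment
rates (monotone by construction; jitter 0 is exactly linear). Everything
is bit-reproducible per seed.

`gen_richness_step` truncates the pool to S_early taxa before a change age
and S_late after (equal weights within each epoch), giving records with a
known richness trajectory. The recovery check uses S 5→15 on 60
pollen-like samples and asks that (a) the late-epoch median of the per-bin
median E(T_n′) exceeds the early-epoch median and (b) the 1000-yr window
holding the late-epoch age quartile shares no letter with the window
holding the early-epoch quartile; both hold in ≥ 90% of 100 seeds.

What the generator does **not** emulate: taphonomic loss, pollen
dispersal/source area, autocorrelated deposition, taxonomic miscounting.
Passing tests therefore demonstrate the statistical machinery — binning,
rarefaction, testing — not robustness to those field realities.

## Verification strategy

- Heck's formula is checked against exhaustive subset enumeration for
  every integer abundance partition with N ≤ 12 and against 100,000-draw
  multivariate-hypergeometric subsampling (within 3 SE, with a
  rule-of-three floor for cases whose sample variance collapses to zero)
  for N ≤ 200.
- The binning conserves per-taxon totals to 10⁻⁹ on fully covered records
  and agrees with an independent interval-overlap scan.
- `find_min_window` matches a brute-force scan over all w.
- The KW type-I error at α = 0.05 is estimated over 20,000 null
  simulations of 4 windows × 10 values (SE ≈ 0.15%); the χ² approximation
  is mildly conservative at these sizes (≈ 4.5%), within the 4–6% band.

## Limitations

- Piecewise-linear age interpolation ignores age-model uncertainty; no
  error propagation into E(T_n′).
- Dropping partial bins shortens the usable record by up to one bin at
  each end and around gaps.
- The minimal-window rule couples bin width to the sparsest part of the
  record; a single long barren interval coarsens the whole series.
- Conover pairwise p-values are unadjusted by default; with many windows
  the letter display inherits the multiplicity of ~k²/2 comparisons
  (use `adjust="holm"` to be conservative).
- Rarefaction conditions on the observed taxon list; it estimates expected
  richness of the archived assemblage, not of the living community.
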