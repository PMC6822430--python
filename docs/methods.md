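# Methods

## Scope

`kinfiber` implements the two quantitative procedures that sit downstream of
a kinome peptide-array screen and a single-fiber physiology rig:

1. **Upstream kinase-activity inference.** A flow-through peptide microarray
   reads phosphorylation of immobilized substrate peptides by the kinases in
   a lysate, as spot intensity over repeated pump cycles. The pipeline turns
   each kinetic series into an initial velocity, filters replicates, scores
   peptides between two conditions, aggregates peptide scores into kinase
   scores through a peptide→kinase mapping, attaches a permutation
   significance, selects the top-K kinases and tests annotation sets for
   overrepresentation.
2. **Fiber physiology.** Intact fast-twitch fibers loaded with the
   ratiometric calcium dye indo-1 are stimulated with 350-ms tetani; the
   module converts the 405/495 emission ratio to myoplasmic free calcium,
   normalizes peak force to fiber cross-sectional area, and summarizes
   force/calcium–frequency relations, fatigue runs and caffeine probes.

Group statistics on experimental cohorts (t tests, two-way ANOVA) are out of
scope; the modules emit tidy tables any statistics tool can consume.

## Initial velocity (V_ini)

Each (peptide, well) series is fit by least squares to the
exponential-association model

    S(t) = c + A · (1 − exp(−k t)),

and `V_ini` is the analytic derivative at the first kinetic read,
`A·k·exp(−k·t₁)`. The baseline `c` makes the estimate invariant to additive
intensity offsets. The fit profiles the linear parameters `(c, A)` in closed
form and scans `k` over a log-spaced grid (80 points from `1e-4/t_max` to
`20/t₁`) followed by bounded scalar refinement to a relative `xatol` of
1e-10; on noiseless exponential data this recovers `V_ini` to better than
1e-6 relative. When the exponential fit yields a non-finite result the
ordinary least-squares slope is used instead (`model="linear"` selects it
directly). The vendor's proprietary curve-fit algorithm is not documented
anywhere; this profile fit is this package's own, fully specified
replacement with the same "initial velocity at the first read" semantics.

## Replicate quality control

Wells flagged as visually damaged are dropped unconditionally. Every
remaining well's peptide-wise `V_ini` vector is Pearson-correlated against
the mean vector of the *other* non-damaged replicates of its condition;
wells below `min_corr` (default 0.95, the conventional cut for array
replicates) are dropped. The filter runs in a single pass against the
pre-filter reference means — no iterative re-computation — which is simple
and order-independent but means a grossly corrupted well also perturbs its
mates' references. With three replicates a half-randomized well depresses
its neighbours' correlations to ≈0.87; QC validation scenarios therefore
use eight replicates per condition, where the dilution is representative.
A condition left with fewer than two kept wells is an error, not a silent
degradation.

## Peptide and kinase scores

The peptide score is a standardized mean difference,
`(mean_exp − mean_ctrl) / s_pooled`, with `s_pooled` the two-group pooled
standard deviation (a Welch-style denominator is a one-line change in
`peptide_scores`). A zero pooled SD with a nonzero difference marks a
degenerate peptide: it is flagged, carries a signed infinite sentinel and is
excluded from set averaging.

The kinase score is the unweighted arithmetic mean of the signed scores of
the peptides mapped to that kinase (mapping: the top eight candidate
upstream kinases per peptide, inverted into per-kinase sets). Kinases whose
sets end up empty are reported with a null score.

## Permutation significance Q

Each permutation iteration applies **one global relabeling** of the peptide
score values, shared by all kinases, preserving the inter-kinase
correlation induced by overlapping peptide sets. `m` counts iterations in
which the permuted kinase score strictly exceeds the observed one — by
absolute value by default (activation and inhibition both count); a signed
one-sided mode is available. Then

    Q = −10·log₁₀( max(m/M, 1/M) ),

a Phred/decibel-style score capped at `10·log₁₀(M)`. No further
multiple-testing adjustment is applied. An enumerated mode replaces sampling
with all orderings of the score vector (feasible for ≤ 8 peptides) and is
checked against a brute-force oracle in the tests. Top-K selection (default
K = 35) orders by descending |score|, ties broken by higher Q then lexical
kinase id.

## Overrepresentation

For each annotation term the one-sided hypergeometric upper-tail p-value of
the overlap between the top-K set and the term, within a fixed kinase
universe, is reported as −log₁₀(p). The universe defaults to every kinase in
the mapping — the population that could have been selected. The
hypergeometric tail is the canonical test behind such plots; raw p-values
are reported by default with an optional Benjamini–Hochberg column.

## Indo-1 calibration and fiber summaries

The emission ratio converts to calcium via

    [Ca²⁺]ᵢ = K_D · β · (R − R_min) / (R_max − R),

strictly increasing on (R_min, R_max), with the exact algebraic inverse
`R = (R_min + x·R_max)/(1 + x)`, `x = ca/(K_D·β)`, used by the simulator and
round-trip tests (identity to better than 1e-9 relative). **K_D, β, R_min
and R_max are rig-calibration inputs; no defaults are baked into the
analysis module.** Out-of-range ratios raise by default — silent clipping
would hide a calibration breach — with an explicit `clip=True` escape hatch.

Per tetanus: peak force is the maximum inside the annotated window; tetanic
calcium is the **mean over the final third of the window**, a plateau
estimate chosen because the calcium transient reaches steady state within a
few rise time-constants and the tail mean is robust to onset kinetics (a
peak estimate would be noise-biased). Specific force is peak force divided
by cross-sectional area, reported in kN·m⁻² (1 mN/µm² = 10⁶ kN·m⁻²).
Fatigue runs report `pᵢ = 100·peakᵢ/peak₁`, making the series invariant to
any positive rescaling of the force channel; a missing contraction window
is an error. The caffeine probe is a descriptive paired pre/post comparison
of tetanic calcium at 150 Hz.

## Synthetic data: what it emulates, and what it does not

The generators define the test conditions for every stage.

**Array experiments** (`ArrayScenario`, defaults: 60 peptides, 20 kinases,
8 kinases per peptide, 3+3 replicate wells, reads at 2–30 min,
`noise_cv = 0.05`): amplitudes are log-normal around 1000 a.u. (σ = 0.8) and
rates log-normal around 0.08 min⁻¹ (σ = 0.5), so the peptide-wise velocity
profile of a well is strongly structured, as on a real array where substrate
affinities span orders of magnitude. `noise_cv` is the between-replicate
amplitude CV; within-series point noise carries a 0.2 share of it because
initial-slope estimation amplifies point noise several-fold, keeping the
total well-level velocity error of the same order as `noise_cv`. The planted
effect multiplies the experimental-condition amplitude of every peptide
whose kinase set intersects the planted kinases by
`1 + effect_size·noise_cv`, i.e. an `effect_size`-standard-deviation shift
of `V_ini` in replicate-noise units, exact in the truth record. Damaged
wells have half their time points replaced by uniform noise, which reliably
destroys inter-replicate correlation. One scenario seed drives a splittable
per-component stream (`numpy.random.SeedSequence.spawn`), so outputs are
bitwise reproducible.

The null-calibration scenario (60 peptides, 12 kinases, 3+3 wells, M = 500)
uses a **disjoint peptide panel** (one kinase per peptide): with a dense
top-8 mapping over a 12-kinase universe the per-kinase permutation p-values
are strongly correlated and a binomial envelope is the wrong yardstick for
their tail fraction; the disjoint panel makes the per-kinase statistics
independent, which is what the envelope assumes.

**Fiber recordings** (`FiberScenario`): calcium waveforms are square pulses
with 15-ms rise and 40-ms decay time-constants over a 0.05 µM resting level;
default tetanic amplitudes follow a saturating function of stimulation
frequency (max 1.8 µM, half-saturation 45 Hz) and default force amplitudes
follow a Hill force–calcium relation (F_max 0.45 mN, Ca₅₀ 0.6 µM, n 3),
so force–frequency and calcium–frequency curves are mutually consistent and
the half-activation point is recoverable. The ratio trace is the exact
algebraic inverse of the calibration equation applied to the (noisy) calcium
waveform, so it always lies strictly inside (R_min, R_max). Force noise is
band-limited (25-ms smoothing) and scaled to the local tetanic amplitude
with the same 0.2 measurement-noise share as the array generator, so window
maxima are not dominated by single extreme samples. Fatigue mode applies a
geometric per-contraction decline to both amplitudes; the 50th-contraction
relative force is exactly `(1 − d)⁴⁹`. Default calibration constants for
*simulation* are indo-1-like (K_D 0.25 µM, β 3, R_min 0.2, R_max 1.0);
default CSA is 1500 µm², typical of mouse flexor digitorum brevis fibers.

Not modeled: spot morphology or image quantification, dye loading and
bleaching, stimulus artifacts, motion, cross-bridge mechanics beyond the
phenomenological Hill relation, and any between-fiber biological
variability beyond what the scenario amplitudes encode. Passing tests
therefore demonstrate correctness of the computations under a clean
generative model, not robustness to every artifact of real recordings.

## Numerical choices and problem sizes

- Rate-grid bounds `1e-4/t_max` to `20/t₁`; best grid point refined by
  bounded minimization between its neighbours. Perfectly linear series land
  on the lower rate bound and return the OLS slope to ~1e-4 relative.
- Permutations are vectorized (`rng.permuted` of the tiled score vector);
  M = 500–1000 is ample for Q resolution up to 27–30.
- p-values are clamped to `[tiny, 1]` before taking logs.
- Validation runs use: 10 seeds × (60 peptides, 12 kinases) for null
  calibration; 20 seeds of the default planted scenario for recovery; 100
  seeds of an 8-replicate design for QC; 1000 peptides for velocity
  recovery; a 7-frequency sweep and a 50-contraction fatigue run for the
  fiber arm. These sizes give stable rates while keeping the whole suite
  fast on a laptop-class single core.

## Known limitations

- The study's correlation QC pairing is not documented; the leave-one-out
  condition-mean choice here is one defensible reading (see the replicate
  dilution caveat above).
- The kinase mapping is taken as given; no motif scoring or database
  querying is performed, and the original screen's kinase list cannot be
  reproduced without the original lysates and database snapshot.
- `Q` is an exceedance rate on the sampled null, not a calibrated p-value
  under dependence; interpret ranked lists, not absolute thresholds.
- The fiber arm assumes annotated stimulation windows; it does not detect
  tetani from raw traces.
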