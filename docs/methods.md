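# Methods

`hubcycle` analyses the temporal behaviour of "singlish" hub proteins —
yeast interactome hubs with only one or two structurally distinct
interaction interfaces — across the cell cycle. Because such a hub can
physically engage at most one or two partners at a time, the timing of
partner expression decides whether partners compete for the interface or
are kept apart by regulation. The pipeline overlays smoothed
synchronized-culture expression time courses on hub-seeded interaction
networks, calls each gene periodic or aperiodic, classifies hubs as
Dynamic/Static, assigns competitive/non-competitive regulatory classes,
and quantifies interface competition over time.

## Data model

Expression data are log2 sample/reference ratios, one gene × timepoint
matrix per synchronization experiment (e.g. α-factor, cdc15-2 or Cdc28
arrest–release), each with its own minutes axis. Missing cells are carried
as an explicit mask and never imputed; downstream stages decide how to
treat them (smoothing excludes them from local fits; thresholding treats
them as inactive; scoring marks genes with too few points unusable).
Interaction networks are undirected simple graphs over uppercase gene
symbols; self-loops are dropped at parse time because interface analysis
concerns hetero-interactions, and reciprocal duplicate edges collapse.

## Smoothing

Each gene's series is smoothed with loess: tricube-weighted local
polynomial regression over the `ceil(span * n)` nearest non-missing
neighbours of each observed timepoint (distance ties broken toward the
earlier time), evaluated at the observed timepoints only. Defaults are
span 0.5, local quadratic (degree 2), no robustness iterations — the
defaults of the classical loess smoother; our implementation agrees with
R's `loess(span = 0.5, degree = 2, surface = "direct")` to ~1e-10 on
reference series and with a brute-force weighted-least-squares oracle to
1e-8 on random series.

Degree matters more than is obvious. With span 0.5 a local *linear* fit
nearly annihilates a 66-minute cosine on sparse long grids: measured
amplitude attenuation factors for a noiseless 66-min cosine are
0.62 / 0.03 / 0.31 on the 18-point/119-min, 24-point/290-min and
17-point/160-min grids, versus 0.95 / 0.12 / 0.79 for local quadratic.
Since the downstream amplitude floor (0.2 log2 units) is applied to the
smoothed series, degree 1 would reject genuinely periodic genes wholesale
on the coarser grids; degree 2 is therefore the default (degree 1 remains
available via `smoothing.degree`). Note that even at degree 2 a ~66-min
oscillation does not survive smoothing on the 290-minute grid — the window
spans more than a full period — so on that grid periodic genes are
expected to be called aperiodic and the cross-experiment majority rule
(below) carries the call.

Genes with fewer than 4 usable points (or a span window below 2 points)
are flagged unsmoothable, propagate as all-missing, and end up
unclassifiable rather than raising.

## Periodicity

The published analysis judged periodicity by visual inspection of rendered
networks. We substitute an explicit statistic:

* **Shared period.** Synchronized cultures oscillate together, so one
  period per experiment is estimated by maximizing the mean cosinor R²
  over all usable genes (≥ 8 points, non-constant) on a candidate grid
  (default 40–100 min, step 2; ties toward the shorter period).
* **Cosinor score.** Per gene, least squares for
  `x(t) = m + A·cos(2π(t − φ)/T)` at the fixed T, giving amplitude `A`
  (half the peak-to-trough swing), peak time `φ`, and R².
* **Permutation test.** Timepoint labels are shuffled `n_perm` times
  (default 1000, seeded, seed recorded in every score);
  `p = (1 + #{R²_perm ≥ R²_obs}) / (1 + n_perm)`. The observed and
  permuted R² share one projection, so p-values are exactly reproducible
  by a brute-force per-permutation refit with the same seed.
* **Call.** Periodic iff `p ≤ α` (default 0.05) *and* `A ≥ 0.2` log2
  units. The amplitude floor matters twice: it mirrors the documented
  low-amplitude exception in the original rendering (a periodic hub whose
  peak amplitude was below 0.2 needed a raised display threshold), and it
  protects specificity, because smoothing makes noise look smooth and the
  permutation test alone would be anticonservative on smoothed flat genes.
* **Combination.** Across experiments: strict majority among usable
  experiments; ties or fewer than two usable experiments give
  *unclassifiable* — the analogue of hubs whose expression was
  inconsistent between synchronization conditions.

A series must have ≥ 6 usable points spanning at least one full period to
be scored; constant series get amplitude 0 (hence aperiodic). No
multiple-testing correction is applied across genes, matching the original
analysis; α is config-exposed.

## Thresholded network frames

A gene is *active* at a sampled time when its smoothed value is at or
above the display threshold (default −0.2 log2 units; the original
rendering hides proteins *below* the threshold, so equality displays).
Per-gene overrides reproduce the documented −0.1 exception. A frame at
time t contains the active nodes and exactly those edges with both
endpoints active; frames exist only at sampled timepoints (the GUI's
continuous interpolation is out of scope) and export deterministically as
JSON-lines or a GraphML file per timepoint, with node colours on a
green/black/red gradient anchored at (−max|v|, 0, +max|v|). Missing values
render inactive (conservative).

## Hub classification

Partners are the hub's 1-step neighbours (2-step ego networks are used for
frame context only; the published partner criterion concerns direct
interactions). Rules:

* periodic hub → **Dynamic**; with ≥ 1 aperiodic partner → *competitive*
  (constitutive partners compete for the interface whenever the hub is
  present). A Dynamic hub whose whole neighbourhood co-oscillates is not
  competitive — that is the co-ordinate-regulation pattern seen for
  rRNA-processing hubs — and gets regulatory class *none*.
* aperiodic hub with ≥ 1 periodic partner → **Static**, regulatory class
  *non_competitive* (partner expression is staggered by regulation).
* aperiodic hub with no periodic partner → **unassigned**. The published
  Static definition is conditional on a periodic partner and silent
  otherwise; we report these hubs but exclude them from the
  competitive/non-competitive tallies.
* unclassifiable hub → **not_classified**, matching the published
  treatment of hubs with missing or low-quality expression.

The packaged annotation table of the 36 singlish hubs is transcribed
verbatim from the published survey (one row per hub: interface count, Pfam
domain strings, functional group, Dynamic/Static/unclassified). Its
tallies are 10 Dynamic + 11 Static + 15 unclassified. The source reports
"20" hubs in the two groups in one place, 10 + 11 = 21 in another, and a
total of 35 vs 36 elsewhere; the table is carried verbatim and the
discrepancy left as-is.

## Competition metrics

For a hub with `k ∈ {1,2}` interfaces, the competition profile counts
simultaneously active direct partners at each sampled time; the *excess*
is `max(0, count − k)`. Counts are reported both unconditionally and
restricted to hub-active times (partners can only compete for an interface
that is present). Pairwise partner overlap is the Jaccard index of
active-time index sets; the *staggered score* is the mean off-diagonal
Jaccard, and partners are flagged staggered below a cutoff of 0.5 (no
published value exists; the cutoff is config-exposed). Pairs never active
get Jaccard 0 with an explicit flag. Because interface-to-partner
assignments are generally unknown, all partners are treated as competing
for all interfaces — a documented simplification; likewise the metrics
cannot distinguish competition from cooperation (e.g. kinase priming).

## Synthetic cohorts

The generator produces networks and expression with ground truth so every
stage is testable without external downloads. Periodic genes follow
`m + A·cos(2π(t − φ)/T) + ε`, static genes `m + ε`, with `ε ~ N(0, σ²)`;
stochastic genes are stationary AR(1) series (ρ = 0.6, innovation sd σ)
drawn independently per experiment, so their behaviour is inconsistent
between conditions — chosen over a pure random walk because a unit-root
walk drifts to implausible log2 ratios over a 24-sample course. Defaults:
period 66 min; amplitudes uniform on [0.4, 1.0]; σ = 0.15; baselines
uniform on [−0.05, 0.05] so the −0.2 threshold is meaningful; three
experiments on the classical grids (18 pts/119 min, 24/290, 17/160); 10
hubs (3 dynamic-competitive, 3 static-non-competitive, 2 co-ordinate, 2
stochastic) with 46 dedicated partners plus 44 background genes (40%
periodic / 40% static / 20% stochastic) — 100 genes total. Background
genes attach only to non-hub nodes so each hub's 1-step neighbourhood is
exactly its dedicated partners and recorded hub truth stays consistent
with the classification rules. Everything is driven by one integer seed
through `numpy.random.default_rng`; reruns are bit-identical.

What the generator does *not* emulate: array-specific noise structure,
loss of synchrony over time, per-experiment period differences, missing
values, and false positive/negative interactions. Passing recovery tests
therefore demonstrates internal consistency of the method under its own
assumptions, not performance on real arrays.

## Numerical choices and degenerate inputs

Constant series are detected exactly (zero peak-to-trough) rather than via
a floating-point variance test. Local fits with too few distinct
timepoints fall back to a lower degree, then to the weighted mean. Phase
is reported in `[0, T)`. Permutation p-values use strict `≥` with no
tolerance: observed and permuted statistics come from the same data, so
machine-precision ties arise only for the identity permutation. Frame
times must match sampled times exactly (tolerance 1e-9 minutes); there is
no interpolation.

## Reported sizes

The test suite and the acceptance script use the default 100-gene cohort,
1000 (tests: down to 200–300) permutations per gene, 50-series smoothing
oracles and 100-replicate mask sweeps; the full suite runs in seconds on
one CPU.

## Known limitations

The periodicity statistic is a surrogate for the original visual
judgement and cannot be validated against it except through the packaged
annotation table, which is used as a fixture, never as a fitting target.
The majority combination rule is one of several defensible choices (the
original text does not state whether periodicity was required in all
conditions). Expression is an imperfect proxy for protein abundance, and
no protein half-life, localization, modification state or affinity
information enters the analysis.
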