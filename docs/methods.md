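# Methods

## The problem

Continuous microvascular perfusion recordings (e.g. laser speckle contrast
imaging of brain blood flow in rodents) are interrupted by experimental
interventions — here thermal stimuli — that inject large instrumentation
artifacts exactly at the moments of greatest scientific interest.  The
experimenter annotates each recording with state markers (basal, post-cold,
post-warm), but these markers are approximate and the samples around each
intervention are contaminated.  The package's job is to recover, per
subject, artifact-free "times of interest" (TOIs), normalize each subject's
response against its own baseline, and compare responses across subjects
and groups with rank statistics.

## Segmentation model

A recording `y(1..n)` is modelled as piecewise linear with additive noise.
Segmentation minimizes the penalized objective

    sum_j RSS(y[a_j..b_j])  +  beta * m

where `RSS` is the residual sum of squares of the ordinary-least-squares
line on the segment, `m` the number of interior changepoints, and
`beta >= 0` a per-changepoint penalty.  `pelt_segment` solves this exactly
with the PELT dynamic program; pruning is safe because line-fit RSS is
subadditive under splitting.  One subtlety: with a minimum segment length
`L > 1`, a candidate whose prune condition first holds at time `t` may still
be needed for ends in `(t, t+L)` where `t` itself cannot yet be a last
changepoint; pruning therefore takes effect only `L` steps after the
condition holds.  Ties are broken toward fewer changepoints, then the
leftmost last changepoint, so results are deterministic.  An
`exhaustive_segment` enumerator (guarded to n <= 25) provides the
independent optimum in tests.

The line-fit cost (rather than a constant-mean cost) matches the
piecewise-linear approximation used downstream; a constant-mean cost is
available via `PenaltyConfig(cost="constant")`.  `min_len` defaults to 3
because 2-point segments have zero residual and would be degenerately
favoured.

### Default penalty

The study data's penalty is not published, so the default is the package's
own choice and every piece of it is overridable.  It is BIC-flavoured:
`beta = 2 * sigma_hat^2 * log(n)`, with the noise scale estimated robustly
from first differences (`1.4826 * MAD(diff)/sqrt(2)` for white noise).
Perfusion noise is strongly autocorrelated, and a white-noise penalty is far
too permissive there (slow noise wander mimics mean shifts; on the default
synthetic design it produced ~35 spurious changepoints per 900-sample
subject).  The default therefore estimates an AR(1) coefficient from the
lag-1 autocorrelation of the differences (`rho_d = -(1-phi)/2` under AR(1))
and inflates `sigma_hat` to the long-run scale
`s * sqrt((1+phi)/(1-phi))`; at `phi = 0` this reduces exactly to the
white-noise value.  The autocorrelation is computed on spike-trimmed
differences (|d - median| <= 5 robust SDs, pairwise-complete), because
artifact bursts otherwise inflate the variance denominator and drag `phi`
toward 1, exploding the penalty.  A degenerate noise estimate (noise-free
input) triggers a warning and a small penalty floor.

## TOIs and transition windows

Interior changepoints are split into per-TOI subsets by the marker of the
sample at each changepoint position.  The intervention time of TOI `j >= 2`
is the earliest changepoint in its subset; if a TOI produced no changepoint
(a non-responder with weak artifacts), the first sample of its marker block
is used, with a logged warning — the marker is the only information left.
The transition half-width `k` is the total number of interior changepoints
outside the basal subset, and each transition window is the symmetric range
`[IT - k, IT + k]`; the optimal TOIs fill the complementary ranges, so the
result partitions `[1, ni]` exactly.  All arithmetic is in 1-based
sample-index space, which requires uniform sampling; this is the only
reading under which the +-k/+-1 algebra is well defined for non-unit
sampling intervals.

Two deliberate behaviours:

* `k` is computed from *detected* changepoints, so it does vary with the
  data (it is surfaced in every result and run log rather than hidden);
* windows that would swallow a neighbouring TOI raise an
  `InadmissibleWindowError` naming the offending window and suggesting a
  penalty change.  This arises legitimately when a non-responding TOI has no
  changepoint of its own and inherits the next boundary's artifact as its
  "intervention time".  An optional `clamp=True` mode truncates windows at
  the midpoints between adjacent intervention times instead, trading window
  symmetry for an always-admissible cover.

## Piecewise-linear approximation and normalization

Each changepoint segment carries its own independently fitted OLS line (no
continuity constraint — the approximation is intentionally step-like at
changepoints, which is what makes between-state level changes visible).
The total residual equals the unpenalized part of the segmentation
objective at the same changepoints.

Signals and their PLAs are z-normalized against the subject's own
*optimal* reference TOI (default basal): `z = (y - mean_ref)/sd_ref`, with
sample (n-1) standard deviations, each series using its own reference
statistics.  Transition samples never enter the reference statistics
(excluding them is the point of the windowing), but the normalization is
applied to all samples so full traces can be plotted.  Between-state
difference series are aligned by within-TOI sample order and truncated to
the shorter TOI; padding was rejected because invented values would enter
statistics.  The identity `z_k - z_l = (y_k - y_l)/sd_ref` holds to
rounding error and is asserted in tests.

A caveat worth knowing: the PLA is smoother than the signal *per segment*
(an exact projection property), but on the z scale the PLA is divided by
its own, usually much smaller, reference SD, so its normalized within-TOI
variance can occasionally exceed the signal's.  The tests assert the exact
per-segment property and the z-scale comparison only as a sampled majority.

## Group statistics

Each subject contributes one sample — its aligned difference series (e.g.
cold-to-basal) or its normalized basal segment.  The Kruskal-Wallis test
(tie-corrected, chi-square reference) is the omnibus; Dunn's pairwise rank
test with Holm correction at alpha = 0.05 localizes differences.  The
published analysis names only a "pairwise multi-comparison test", so the
post-hoc is configurable (`dunn-holm`, `dunn-bonferroni`, `conover-holm`)
and every report records which was used.  Per-subject counts of significant
differences are formatted in the publication-table style
("32: 15 WT and 17 LNAME").  Box summaries use type-6 (Weibull) quantiles
— Q1 of 1..7 is 2 — with Tukey 1.5*IQR whiskers.

Group-level comparisons default to pooling all aligned samples per interest
group (WT/L-NAME x sex).  Pooled samples from the same subject are
autocorrelated, so under a true null the pooled test is anti-conservative;
a `pooling="subject-median"` mode, where each subject contributes a single
summary value, restores exchangeability and is the mode under which null
calibration is tested.  The pooled default mirrors the published per-group
panels and is fine for the large, consistent effects it is used on.

## Synthetic cohorts

The generator emulates the study conditions: 33 subjects (16 control: 8
female + 8 male; 17 experimental: 9 female + 8 male), three marker blocks
of 300 samples each, baseline 250 perfusion units with a between-subject SD
of 15, AR(1) noise (stationary SD 10, coefficient 0.6), and a square
artifact burst of amplitude 80 and half-width 5 centred on each marker
boundary (triangular and exponential-decay shapes available).  Controls
respond to cold with a -40 shift and nearly recover under warm (-5);
the experimental group is flat apart from a slight +5 cold shift.  The
recordings' true sampling rate and length are not published; 300 samples
per state is the package's choice and is configurable.  Per-subject seeds
are derived deterministically from the design seed.

What the generator does *not* model: physiological hemodynamics, slow
drifts within states, heteroscedasticity between states, or marker
misplacement.  Passing tests therefore demonstrate the pipeline's
statistical machinery, not biological validity on real recordings.

Because artifacts straddle each boundary while the transition window is
centred on the detected intervention time, a few artifact edge samples can
leak into adjacent TOIs when `k` is smaller than the artifact half-width.
This slightly inflates reference SDs (a faithful property of the windowing,
visible in the default design) without changing any qualitative outcome.

## Numerical choices and problem sizes

Segment costs are computed from prefix sums in O(1) with a clamp at zero
against cancellation; exact float equality is used for tie-breaking in the
dynamic program.  Tests and the acceptance script run on scaled problem
sizes chosen for quick iteration: oracle sweeps use signals of length <= 20
(the enumeration guard is 25), the partition invariant uses 1,000 subjects
at the full 900-sample design, and the replicate study uses 50 cohorts of
33 subjects.

## Known limitations

* The transition half-width `k` is global per subject; a subject with many
  changepoints in one post-intervention state widens *all* its windows.
* Non-responding subjects may need the marker-boundary fallback, which
  reintroduces trust in the experimenter's annotation.
* The pooled group-level test ignores within-subject autocorrelation (see
  above for the calibrated alternative).
* No multiscale or online changepoint variants; no continuity-constrained
  PLA.
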