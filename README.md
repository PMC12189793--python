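# toiseg

Optimal segmentation and comparison of intervention-perturbed perfusion
signals.

Continuous microvascular perfusion recordings — such as laser speckle
contrast imaging of brain blood flow — are punctuated by experimental
interventions (here, thermal stimuli) that inject large instrumentation
artifacts precisely at the transitions between experimental states.
`toiseg` recovers artifact-free *times of interest* (TOIs) per subject,
normalizes each subject's response against its own baseline, and compares
responses across subjects and interest groups with rank statistics.  It is
aimed at researchers analyzing perfusion (or similar physiological) time
series from designed intervention experiments, and ships a synthetic-cohort
generator so the entire pipeline is testable without animal data.

## Method

For a recording `y(1..n)` with experimenter marker blocks for `nT` states
(basal first):

1. **Changepoint detection.** Exact penalized segmentation
   `min Σ_j RSS(y[a_j..b_j]) + β·m` by the PELT dynamic program, where each
   segment's cost is the residual of its ordinary-least-squares line and
   `m` is the number of interior changepoints τ.  The default β is
   BIC-flavoured with a robust, autocorrelation-aware noise scale.
2. **TOIs and transition windows.** τ is split into per-state subsets
   τ₁..τ_nT by the marker at each changepoint; the intervention time of
   state `j` is `IT_j = min τ_j`, and `k = |τ \ τ₁|`.  Each transition
   window `[IT_j − k, IT_j + k]` absorbs the intervention artifacts; the
   optimal TOIs are the complementary ranges, partitioning `[1, n]`
   exactly.
3. **Normalization.** Signals and their piecewise-linear approximations are
   z-scored against the subject's own optimal basal TOI:
   `z(t) = (y(t) − ȳ_ref)/s_ref`.  Between-state responses are the aligned
   differences `z_k − z_l = (y_k − y_l)/s_ref`.
4. **Comparison.** Kruskal–Wallis omnibus tests across subjects or interest
   groups, Dunn's pairwise rank test with Holm (or Bonferroni) correction,
   publication-style per-subject difference counts, and Tukey box
   summaries.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

`examples/04_full_pipeline.py` simulates the default 33-subject cohort
(16 control responders, 17 experimental non-responders) and runs the whole
pipeline:

```text
basal_groups             KW H=    0.38  p=0.9434
cold_to_basal_groups     KW H= 6360.04  p=0
warm_to_cold_groups      KW H= 6188.03  p=0
most distinctive cold responder: subject 12 (20: 3 WT and 17 LNAME)
report bundle written to results_example/
```

Reading: the four interest groups (control/experimental × female/male) are
indistinguishable at baseline (p ≈ 0.94) but separate decisively in their
cold-induced response (p below floating-point resolution), because only the
control group's perfusion drops under the cold stimulus.  The last line is
the publication-table format: subject 12 — a control responder — differs
significantly from 20 of the 32 other subjects, including all 17
unresponsive experimental animals.  Other examples cover simulation (`01`), single-subject
segmentation (`02`) and normalization/differences (`03`).

The same pipeline is scriptable from the shell:

```sh
toiseg simulate --seed 1 --out cohort.tsv
toiseg segment --input cohort.tsv --subject 1
toiseg analyze --input cohort.tsv --out results/
toiseg all --config cfg.yaml          # YAML-configured end-to-end run
```

Real data enter as an XLSX workbook with four columns per subject (row
index, time, marker, perfusion value; blocks side by side) or as the
long-format TSV shown above; see `toiseg.LayoutConfig` to adapt other
arrangements.

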