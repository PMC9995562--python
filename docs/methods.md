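# Methods

`eventrsa` implements a representational similarity analysis (RSA) of
memory for naturalistic events whose content is systematically recombined:
a small set of central persons crossed with a set of contexts, where the
contexts come in types (e.g., two distinct cafes, two distinct grocery
stores). The default design is 8 events = 2 persons x 4 contexts (2 types
x 2 exemplars), encoded over 3 runs and recalled once. The package computes
event-by-event multivoxel pattern similarity, fits binary hypothesis
matrices, runs the factorial event-type and temporal-epoch analyses, and
relates encoding-recall reinstatement to recall behavior — all driven
either by user-supplied beta patterns or by the built-in synthetic
generator.

## Similarity computation

Patterns are compared with Pearson correlation over voxels. Correlations
pass through the Fisher r-to-z transform z = atanh(r) before any averaging;
this is the variance-stabilizing convention standard in RSA. A switch
(`z_before_averaging=False`) averages raw r first and transforms once —
provided because the two orders differ slightly (atanh is convex away from
zero) and the right choice is a matter of convention. Correlations of
exactly +-1, which arise only in noise-free synthetic data, are clamped to
+-(1 - 1e-7) so atanh stays finite.

Encoding-encoding similarity with R runs averages, per cell:

- same-event cell (i, i): the C(R,2) unordered cross-run correlations
  (3 terms with R = 3);
- different-event cell (i, j): all 2 C(R,2) ordered cross-run pairings
  (6 terms with R = 3), which makes the matrix symmetric by construction
  rather than by post-hoc symmetrization.

Encoding-recall similarity correlates each encoding run's event patterns
with the single recall run's patterns and averages over encoding runs; the
resulting matrix (row = encoding event, column = recall event) is not
required to be symmetric. Voxels that are non-finite in any run are
excluded listwise per ROI before any correlation.

## Model matrices and fits

Four binary event-by-event hypothesis matrices: person (1 where the two
events share their central person), context (same context), schema (same
context type), and episodic (identity only). The diagonal is 1 in all four
— cross-run same-event cells are meaningful data, and an event trivially
shares its own attributes — with a flag to drop that convention. The schema
matrix defaults to the full context-type block (same-context cells
included), since a schema generalizes across exemplars *including* the
exemplar itself; an exclusive variant that isolates
similar-but-not-identical contexts is exposed because the inclusive/
exclusive choice is not dictated by the hypothesis itself.

Fit is the point-biserial correlation (Pearson r against the 0/1 model
vector) over the lower half of the matrix including the diagonal, 36 cells
for 8 events, vectorized row-major over i >= j (any consistent ordering
gives the same r; a fixed order aids testing). Group-level fits correlate
the element-wise mean similarity matrix across subjects with each model;
the associated p treats cells as observations and is labelled descriptive,
since cells within a subject are not strictly independent. Subject-level
fits are atanh-transformed and compared with a one-way repeated-measures
ANOVA over models (error term = subject x model interaction, df =
(m-1)(n-1) = (3, 57) at n = 20) followed by Tukey HSD using that error term
and scipy's studentized-range distribution. The four model matrices share
mutual information (episodic is nested in all three others); fits are
interpreted as relative, and no partial-correlation adjustment is applied.

## Factorial event-type analysis

Each lower-half cell is classified by person (same/different) and context
(same / similar = different contexts of one type / different types). The
36 cells partition as 8/4/8 (same person) + 4/4/8 (different person); the
(same, same) condition consists solely of cross-run same-event diagonal
cells, which is worth keeping in mind when comparing it against off-
diagonal conditions. Cell values are averaged per subject and condition,
and the 6 subject-condition means per subject enter a balanced two-way
fixed-effects ANOVA (each mean one observation; error df = 6n - 6 = 114 at
n = 20) with Tukey HSD on the three context levels. A mixed-effects model
would be defensible, but the fixed-effects analysis is the one whose df
structure matches the condition-collapsed design, and its type-I error on
structureless data is calibrated (see below).

## Temporal epochs

The beta series models one pattern per TR of each ~40-s event: 33 TRs at
TR = 1.22 s, the first 4 covering the title screen. Each TR's pattern is
correlated with the same TR of the same event in the other runs (Fisher-z,
averaged over run pairs), giving a per-TR trace; after discarding title
TRs, epochs are onset = TRs 5-11, mid = 12-26, offset = 27-33 (1-based,
inclusive — the convention used throughout). Epoch means are tested per
subject against the subject's grand mean — the TR-matched cross-run
similarity pooled over *all* event pairs, matched and mismatched, and all
runs; a `matched_only` option restricts the pool, since the pooling
convention is ambiguous in principle. Because the grand mean varies by
subject, the one-sample t-tests are computed on paired differences
(epoch mean minus subject grand mean, df = n - 1), followed by a
repeated-measures ANOVA over the three epochs (df = (2, 2(n-1)) = (2, 38)
at n = 20) with Tukey HSD.

## Reinstatement and behavior

Per subject, matched reinstatement is the mean of the E diagonal cells of
the encoding-recall matrix, mismatched the mean of the E(E-1) off-diagonal
cells. Each is correlated (Pearson, two-tailed t-based p) with the
subject's total verifiable detail count. The matched and mismatched
correlations are compared with the independent-samples Fisher r-to-z test,
z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)); the two summaries
come from the same subjects, so a dependent-correlations variant
(Steiger's test, requiring the correlation between the two predictors) is
provided but non-default — the independent formula is the conventional
report for this contrast. Recognition is summarized as
d' = Phi^-1(hit rate) - Phi^-1(false-alarm rate), with extreme rates
replaced by 1/(2N) and 1 - 1/(2N).

## Synthetic generator

Per subject and ROI, independent unit-variance Gaussian voxel vectors are
drawn for each person, context, context type, event identity, and one
subject-global component; the noise-free event signal is their weighted sum
with non-negative ROI-specific weights, and each encoding run adds i.i.d.
N(0, noise_sd^2) voxel noise. Component vectors are subject-specific — all
analyses are within-subject, so no cross-subject alignment is simulated —
and noise has no spatial autocorrelation, appropriate for unsmoothed
correlation-based analyses. The seed stream is forked per subject, so
growing `n_subjects` leaves existing subjects' data bit-identical.

Default ROI profiles plant the four hypothesized signatures: PM (posterior-
medial network) context-dominant (w_context = 1, w_schema = w_episodic =
0.4), AT (anterior-temporal) person-dominant (w_person = 1, w_episodic =
0.4), mPFC schema-dominant (w_schema = 1, w_context = w_episodic = 0.3),
HPC episodic-dominant (w_episodic = 1, w_context = 0.4); all include
w_global = 0.2. The secondary weights mirror the qualitative pattern of
secondary fits expected for each network. Effect sizes for real data are
unknown; these values are chosen once so the planted structure is
comfortably recoverable with 20 subjects and 500 voxels at noise_sd = 1,
and recovery rates are *measured*, not assumed.

Recall patterns are the noise-free signal attenuated by
`recall_attenuation` (default 0.7) plus noise with SD
recall_noise_sd / f_s, where the subject fidelity latent
f_s ~ LogNormal(0, 0.25) is the single mechanism coupling reinstatement to
behavior: detail totals are round(base + coupling * f_s + N(0,1)) floored
at 0 (base = 90, coupling = 20, giving totals near 110, i.e. ~14 details
per event), and recognition hits/false alarms are binomial draws with
d' = 1.5 f_s. The beta series multiplies the event signal by a per-TR gain
profile: flat for cortical ROIs, boundary-weighted for HPC (full gain on
TRs 5-11 and 27-33, 0.2 elsewhere) to emulate boundary-sensitive
hippocampal encoding.

What the generator does *not* emulate: hemodynamics and GLM estimation
(patterns are generated directly at the beta level), event-order
randomization (irrelevant to beta-level analyses), variable-length recall
epochs, spatial noise structure, and between-subject anatomical
variability. Passing recovery tests therefore demonstrates that the
analysis pipeline is correct and well-calibrated under the planted model,
not that real fMRI data would show these effects.

## Numerical choices and degenerate inputs

- Correlation clamp 1 - 1e-7 before atanh (above).
- A constant similarity vector has zero covariance with any model; its fit
  is returned as r = 0, p = 1 rather than NaN.
- Exactly-degenerate ANOVA tables (all condition means identical to
  round-off) return F = 0, p = 1, guarded by a floor of 1e-12 relative to
  the total sum of squares; a zero error term with non-zero effect returns
  F = inf, p = 0.
- Zero-variance voxel patterns raise, since they signal a degenerate ROI
  extraction rather than valid data.
- Fisher comparison requires n > 3 per correlation; d' requires at least
  one target and one lure.

## Problem sizes in tests and the acceptance script

Closed-form checks are exact and instant. Simulation-based checks use:
winner recovery, 100 replicate datasets at full default size (20 subjects,
4 ROIs, 500 voxels); factorial type-I calibration, 1000 structureless
datasets at 60 voxels (voxel count affects only the scale of the null
similarity values, not the calibration of the F tests); boundary-epoch
recovery, 50 replicates at 10 subjects x 60 voxels; behavior coupling, 200
replicates per coupling grid point at 20 subjects x 150 voxels. These sizes
give binomial standard errors small enough for the stated bounds while
keeping a full run inexpensive on one CPU.

## Known limitations

- Group-fit p-values are descriptive (cell-independence caveat above).
- The factorial conditions have mildly heterogeneous variances (different
  cell counts and 3- vs 6-term averaging); the balanced ANOVA is robust to
  this, and calibration is verified empirically rather than assumed.
- The generator's lognormal fidelity latent is a deliberately minimal
  coupling mechanism; real reinstatement-behavior coupling is surely less
  collinear.
- No noise-ceiling estimation, crossvalidated RSA distances, searchlight
  mapping, or mixed-effects alternatives to the printed-df ANOVAs.
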