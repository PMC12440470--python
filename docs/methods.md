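# Methods

`phenorisk` implements a complete EHR dementia-phenotyping pipeline —
stable-topic features from clinical notes, era-spanning diagnosis-code
groups, a cross-validated linear max-margin risk score, and design-based
validation under stratified verification sampling — together with a
synthetic cohort generator that provides planted ground truth for every
stage.  This note documents the models, the defaults and why they are set
where they are, and what the synthetic experiments do and do not show.

## Study design being emulated

The pipeline targets the following study shape.  A case/control cohort is
drawn from a large health system: cases are patients with a first dementia
diagnosis code after age 65 and at least two other note-bearing visits in
each of the three years before it; controls have no dementia code ever, no
fills of the dementia medications (donepezil, galantamine, rivastigmine,
memantine), and three consecutive qualifying years of visits after age 62,
with the index visit chosen at random among qualifying dates.  Features are
computed over the half-open 3-year window `[index − 3y, index)`; the index
date itself (which for cases carries the diagnosis) is excluded.  A model
trained on balanced cases/controls scores a separate validation sample of
controls; a stratified subsample of the validation sample is verified by
chart review, and screening characteristics of the score are estimated with
inverse-probability weighting.

Sampling, feature selection, scaling and model fitting are all run
independently per race stratum; nothing estimated on one stratum is reused
in another.

## Unstructured features: stable topics, PWC, presence

Topics are learned with latent Dirichlet allocation three times under
independent seeds.  A topic is *stable* when the three runs agree on it:
one topic per run, every pair mutually best-matching by cosine similarity
between topic–word distributions, and all three pairwise similarities at or
above a threshold (default 0.8).  The stable topic's word distribution is
the renormalized average of its three members.

For each note, the inferred proportion of a topic times the note's word
count gives the *pseudo word count* (PWC) — the number of words in the note
attributable to the topic, generally non-integer.  A stable topic's PWC is
the median of its three members' PWCs (invariant to run order).  Presence
of a topic in a note is the piecewise map

    presence(PWC) = 0            if PWC < 2.0
                    PWC / 10.0   if 2.0 ≤ PWC ≤ 10.0
                    1.0          if PWC > 10.0

i.e. a topic carrying fewer than two words of a note is treated as absent,
and more than ten words as fully present; both boundary points belong to
the linear middle piece.  A patient's topic feature is the maximum presence
over all their notes in the window.

Implementation choices:

* LDA is scikit-learn's variational-EM `LatentDirichletAllocation`
  (batch mode, `max_iter` 10), with symmetric document prior
  `alpha = min(1, 5/K)` and word prior `beta = 0.01`.  The solver caps the
  document prior at 1, so the cap binds only for K < 5.
* Topic learning may run on a random fraction of the corpus
  (`learn_fraction`) with inference applied to all notes — the two-step
  learn-on-a-subsample / infer-on-everything procedure used at
  multi-million-note scale.  The pipeline default is 0.25.
* Tokenization: lowercase, split on non-alphanumerics, drop tokens shorter
  than two characters and English stopwords; vocabulary keeps tokens with
  document frequency ≥ 2.  Notes that become entirely out-of-vocabulary
  receive uniform topic proportions (logged); notes with zero tokens are an
  upstream eligibility violation and raise.
* K defaults to 30 at desk scale (the reference design uses 1000 at
  hospital-system scale); the similarity threshold and presence thresholds
  are exposed in `PipelineConfig` / `PresenceParams`.

## Structured features: GEM groups and binary indicators

The ICD-9↔ICD-10 general equivalence mapping is read as a bipartite graph
(ICD-9 vertices, ICD-10 vertices, an edge per listed conversion) and
decomposed into connected components — the minimal disjoint bipartite
subgraphs that cannot be split without breaking an edge.  Each component
becomes one era-spanning group code: diagnosis events look up their group
by the ICD-9 side before the transition date and the ICD-10 side on or
after it (half-open convention, consistent with the generator).  Codes
absent from the crosswalk become deterministic singleton groups
(`ICD9:<code>` / `ICD10:<code>`) rather than being dropped.  Codes are
normalized (dots stripped, uppercased) before matching, since GEM files
omit dots while event tables usually include them.  Group ids are the
lexicographically smallest namespaced member code, so repeated
decompositions name groups identically.  Edge direction is ignored; any
mix of forward and backward mapping rows yields the same partition.

Structured candidates (ICD groups, CPT codes, medications, note types) are
binary: 1 iff at least one qualifying event in the patient's window.  A
candidate enters the model only if present in at least `min_support = 10`
training patients of the stratum.  Demographics are age in years at index
(z-scored with the training stratum's mean/SD) and sex as {0, 1}; age and
sex and all topic features bypass the support filter.  Age stays
continuous; binning would discard information the margin model can use, and
z-scoring one continuous column keeps the otherwise-{0,1} design matrix
well conditioned.

## Risk model

A linear SVM (hinge loss, L2 penalty — `LinearSVC`) is trained on the
balanced training stratum.  The cost parameter C is selected from the grid
{1e-4 … 1e2} by stratified 5-fold cross-validation maximizing the AUC of
the fold decision scores; AUC ties break toward the smaller C (more
regularization).  CV folds use decision scores, not hard predictions —
AUC on predictions is degenerate.  No class weighting is applied: the
training design is balanced by construction.  The final model refits on the
whole training stratum at the chosen C; the risk score is the signed
distance to the hyperplane, `w·x + b`, unbounded, higher = more
dementia-like.  Percentiles of a score are mean-rank percentiles within the
full validation stratum.

Solver settings: tolerance 1e-4, `max_iter` 50,000, fixed `random_state`;
non-convergence is logged, not raised.

## Validation design and estimation

The verification sample unions two phases: a simple random sample (default
n = 200) from the full validation frame, then stratified draws from the
remaining frame — 100 from the (75, 90] score-percentile stratum and 30
from each 1-percentile band partitioning (90, 100] (600 total by default).
Inclusion probabilities use the two-phase union convention
`π = 1 − (1 − n_srs/N)(1 − n_h/N_h)`, with `N_h` counted on the full frame;
patients below the 75th percentile have `π = n_srs/N`.  How the reference
design handled SRS/stratified overlap is not stated; drawing the SRS first
and removing it from the stratified frame is this package's choice, and the
union π above is the matching (slightly approximate) marginal — its bias is
second-order in `n_srs/N` and empirically ≪ the ±0.005 recovery tolerance.

Estimates weight each reviewed patient by `1/π`.  At a cutoff percentile,
the cutoff value is the linear-interpolation quantile of the full
validation stratum's scores and a patient is flagged iff strictly above it
("above the Xth percentile").  Prevalence, sensitivity, specificity, PPV,
NPV and accuracy come from the weighted 2×2 table, so the Bayes identity
among them holds to machine precision; weighted AUC is the area under the
weighted empirical ROC, equal to the weighted concordance probability with
ties counting half.  Rates with a zero weighted margin are reported as
missing, not zero.

Confidence intervals are percentile bootstrap (default B = 1000),
resampling within sampling strata at each stratum's own n so the design
stays fixed.  Cohen's kappa for dual review uses
`κ = (p_o − p_e)/(1 − p_e)` with the standard large-sample standard error
`sqrt(p_o(1 − p_o)/(n(1 − p_e)²))`; which variance estimator produced the
reference kappa SE is unstated, so agreement there is not expected.  Two
constant, identical raters return κ = 1 by convention.

The chart review itself is simulated: latent truth is reported with
configurable reviewer sensitivity/specificity (defaults 1.0/1.0);
uncertain-case adjudication is not modelled.

## Synthetic cohort generator

The generator is the package's study bed, not a fixture.  Defaults are the
study conditions the rest of the package is exercised under:

* 1,000 cases + 1,000 training controls + 2,000 validation controls in a
  single stratum (multi-stratum generation is supported; counts are per
  stratum).  Desk-scale stand-in for the reference 5K/5K/10K per race.
* Notes: 20 planted topics over a 500-word vocabulary; each topic puts 80%
  of its mass uniformly on its own 25-word block plus a uniform background.
  Per note, a Dirichlet topic mixture is drawn and tokens are drawn i.i.d.
  from the mixture distribution (the standard LDA generative process;
  marginally identical to per-token topic-then-word draws).  Note lengths
  are uniform on [50, 200]; visit/note rate is Poisson with mean 8 per
  patient-year, floored at 2 so eligibility holds by construction.
* Signal: topics 0 and 1 are the dementia signal.  Background patients
  carry Dirichlet prior 0.25 on ordinary topics and 0.02 on signal topics
  (signal content is rare in unaffected patients); cases and
  latent-positive controls add +1.5 to each signal topic's prior, and also
  carry designated risk codes (3 ICD groups, 2 CPTs, 2 medications) at
  probability 0.6 per window vs 0.08 for background patients.
* Latent truth: each control (training and validation alike) is an
  undiagnosed positive with probability `latent_prevalence` (default 0.04,
  the prevalence scale reported for this population).  Latent positives
  draw their age from the case distribution — undiagnosed disease skews
  older.  Training controls therefore contain ~4% mislabelled positives,
  exactly the label noise the real design lives with.
* Demographics: ~97% male; case ages N(72.4, 4.8²) truncated to [66, 84],
  control ages N(69.1, 3.7²) truncated to [65.2, 84] — so control windows
  start at age ≥ 62.2.  Whether a control's 3-year window may start before
  65 is ambiguous in the source design; the generator allows it and flags
  such patients (`window_starts_before_65`).
* Calendar: index dates uniform on [2013-01-01, 2018-09-12]; the ICD-10
  transition is 2015-10-01, so windows straddle it.  Lookback years are
  365-day blocks.  ICD-9 events are strictly before the transition, ICD-10
  events on/after it.
* Crosswalk: a fabricated GEM with 40 planted components cycling through
  1:1, 2:1, 1:2, 2:2 and 3:2 shapes, plus a dementia component built from
  real dementia codes (331.0, 290.40 ↔ G30.9, F03.90) used only to stamp
  case index events.
* Determinism: one `numpy` generator seeded from the config; identical
  config ⇒ byte-identical cohort.

What the generator does *not* emulate: realistic clinical language (tokens
are abstract vocabulary symbols), code hierarchies, temporal disease
progression within the window, correlated comorbidity structure, reviewer
disagreement dynamics, or site effects.  Passing tests therefore
demonstrate that the pipeline's machinery recovers structure it is designed
to recover under its own assumptions — not that it would achieve any
particular performance on real notes.

## Problem sizes and numerical choices

The default end-to-end experiment (4,000 patients, ~96K notes, 3 LDA runs
at K = 30 learning on a 25% note subsample) and the repeated-sampling
study (500 review draws from a 10,000-score frame with B = 500 bootstrap
resamples each) are sized to run comfortably on a single CPU; all sizes
are config parameters.  Scores, percentiles and weighted tables are exact
affine/order computations; the only iterative numerics are the LDA
variational EM and the SVM dual solver, both seeded and deterministic.

Known limitations:

* Percentile-bootstrap coverage for the IPW prevalence degrades when
  verified positives with large weights are rare — e.g. under very strong
  top-decile score enrichment, the low-score SRS stratum may contain ~1
  positive per draw and intervals undercover (~87% observed in such a
  regime).  Under the prevalence profile matching the reference setting
  (~4% overall, ~3% below the 90th percentile), coverage is ~94%.
* Stable-topic matching is greedy mutual-best; with K well above the number
  of planted topics some runs split a topic, and the split parts are
  correctly dropped as unstable rather than merged.
* The kappa SE is the standard large-sample formula; reported reference
  values computed under a different variance estimator will differ.
* The two-phase union π is a first-order approximation to the exact
  marginal inclusion probability (see above); the IPW estimator inherits a
  bias ≪ 0.001 at the default design.
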