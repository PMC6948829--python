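# Methods

`painnet` implements a longitudinal biopsychosocial analysis of pain around
total joint replacement (TJR) in knee (KOA) and hip (HOA) osteoarthritis:
residual-pain quantification, factor reduction of a questionnaire battery,
stepwise outcome modelling, and correlation-network analysis with
permutation inference. Because no patient-level dataset accompanies the
analysis, a first-class synthetic-cohort generator supplies data with the
structure the pipeline assumes; every stage is validated against oracles and
planted ground truth on those cohorts.

## Data model

The canonical input is a long-format table — one row per (subject, visit,
measure) — with visits `baseline`, `m3`, `m6` and two arms (`KOA`, `HOA`).
A measure registry carries, for each of the 21 behavioural/clinical measures
(19 questionnaire subscales of HADS, PCS, MPQ, DN4, KOOS and SF-36, plus the
timed-up-and-go and six-minute-walk tests) and the 4 pain-intensity outcomes
(NRS, BPI severity, KOOS/HOOS pain, SF-36 bodily pain): instrument, native
score range, orientation (whether a higher score is worse), and the
behavioural community it belongs to (Affect, Pain Catastrophizing, Pain
Quality, Health, Physical Performance). Native ranges follow the standard
scoring of each instrument; where versions differ (e.g. DN4 variants) the
registry default is documented and overridable. The two community
assignments not uniquely pinned down by the five-domain description (MPQ
affective score, KOOS activities of daily living) default to Pain Quality.

## Preprocessing

All measures are mapped affinely to a common 0–10 scale with 10 = worst;
"higher is better" instruments are reversed. The map is a bijection per
measure, so native values are recoverable exactly.

Missing data follow a two-branch rule applied within one instrument's
entries for a subject-visit: if 30% or more are missing (inclusive — 3 of 10
already excludes) the instrument is excluded for that subject-visit;
otherwise missing entries are replaced by the mean of the observed entries
of the same instrument. Inputs carry subscale scores rather than raw items,
so the rule operates at subscale granularity — the documented fallback of
the item-level rule. Subjects still incomplete after the rule are dropped
from that visit's matrix and recorded in the exclusion report. No
model-based imputation is attempted.

**Residual pain** for a scale is `100 · post / pre` (percent): 100 means
surgery changed nothing, 0 complete relief, above 100 worsening. It is
undefined — not 0 or infinite — at a pain-free baseline (`pre = 0`), since
relative change from zero has no meaning; such cases are excluded from
aggregates and logged. **Aggregate pain** is the arithmetic mean of the four
outcome scales, defined only when all four are present.

## Synthetic cohorts

The generator draws, per arm, standard-normal factor scores on the five
communities and builds the 21 measures as `loadings · scores + unique
noise`, with |loading| 0.75 on the own factor (six-minute walk negative) and
uniqueness completing unit variance. Standardized values are placed on the
0–10 scale at mean 5, SD 1.5, clipped to range, and mapped back to native
units. Pain outcomes couple to the Pain Quality factor (loading 0.6 at
baseline, 0.45 post-surgery — the weaker post-surgical coupling reproduces
the published ordering in which baseline models explain more variance than
post-surgical ones, which explain more than residual-pain models) with
group × visit means and SDs defaulting to the published cohort table;
post-surgical means are `baseline × retention`, the retention fractions
being the ratios implied by that table. Because clipping to [0, 10] would
bias low post-surgical means upward (~+0.2 at a mean of 0.55, SD 1.06), the
pre-clip location is solved from the truncated-normal mean so the clipped
mean hits its target exactly; the clipping fraction is recorded.

The surgery effect on the inter-measure structure has two dials per arm:

* **rewire_strength** `s` — factor scores at 3 months are a convex mix of
  the baseline scores and fresh draws (renormalized to unit variance), and
  each loading row is rotated toward a random direction by the same `s`
  (row norms preserved). Score mixing alone cannot alter the population
  correlation matrix, so the rotation is what gives the dial its defined
  effect on mean Δr.
* **structure_attenuation** — shrinks post-surgical loading row norms,
  moving shared variance into uniqueness. This emulates the fracturing of
  the shared behavioural structure with strong pain relief, the mechanism
  behind a genuine clustering/modularity drop.

Month-6 factor scores are 0.9-correlated with month-3 scores and reuse the
month-3 loadings, so the post-surgical state is stable — the 3→6-month
contrasts are null by construction. Defaults — KOA `s = 0.2`, no
attenuation; HOA `s = 0.5`, attenuation 0.7 — were calibrated once to the
qualitative published ordering (hip arm reorganizes more: mean Δr ≈ 0.11 vs
≈ 0.31; topology change detectable only in the hip arm) and not revisited.
Missingness is injected completely at random at 0.5% of cells; at subscale
granularity the inclusive 30% rule amplifies cell missingness into
subject-visit attrition (singleton instruments are excluded by one missing
cell), and 0.5% keeps per-visit attrition near 5% so the arms stay close to
the n = 84 / n = 22 design. Everything is deterministic given `rng_seed`.

What the generator does *not* emulate: item-level questionnaire structure,
informative dropout, medication effects, radiographic progression, floor and
ceiling clustering of real questionnaire scores, or any dependence of the
surgery effect on baseline covariates. Passing tests therefore demonstrate
that the pipeline recovers what it assumes — linear factor structure and
MCAR missingness — not that real cohorts satisfy those assumptions.

## Factor reduction

PCA is run on the correlation matrix (measures are on heterogeneous scales)
of the knee arm at baseline, pain-intensity outcomes excluded. Sampling
adequacy is the Kaiser–Meyer–Olkin statistic (overall and per measure),
computed from anti-image partial correlations via the inverse correlation
matrix; an overall value below 0.5 warns but does not abort. Components are
retained by the strict eigenvalue > 1 rule; the scree elbow is reported for
inspection, never auto-applied. Retained components are varimax-rotated
(Kaiser row normalization; SVD iteration run to a 1e-14 rotation-change
tolerance) and then Promax-transformed with the conventional power κ = 4
(configurable). Columns are sign-fixed so each component's dominant loading
is positive and ordered by explained variance. Measures join the component
on which their pattern loading passes |0.5|; a measure passing on two
components is assigned to the larger |loading| (ties broken by component
order) and flagged.

Scoring uses regression-method weights `R⁻¹ (pattern · Φ)` with the fitting
sample's means and SDs, so hip-arm subjects can be projected through the
knee-arm solution exactly as fitted.

## Outcome models

Candidate predictors are the five component scores plus age, gender
(0 = male, 1 = female), education (ordinal 0/1/2), BMI, pain duration and
Kellgren–Lawrence grade. Selection alternates forward entry (smallest
partial-t p-value < 0.05) and backward elimination (largest p > 0.10) until
stable, with a cycle guard; ties are broken by candidate order, making the
procedure deterministic. Factor scores enter unstandardized; standardized
coefficients β = b·sd(x)/sd(y) are reported alongside. After the final
selection, cases with |studentized deleted residual| > 3 are pruned — at
most three, most extreme first, refitting after each — followed by one
re-selection pass (pruning before selection is available as an option; the
original ordering is not documented anywhere authoritative). Note that at
n = 84 a ±3 SD cut falsely flags about 0.3 clean cases per dataset — an
arithmetic property of the rule. Hip-arm re-tests fit the knee-selected
predictor set as a plain multiple regression, no selection.

## Network analysis

Pearson correlation matrices of the 21 measures are computed per arm and
visit and binarized by keeping the top `round(0.25 · C(21,2)) = 53` pairs
ranked by |r| (absolute ranking is the default because the six-minute-walk
test correlates negatively with everything "worse" yet participates in the
networks; positive-only ranking is available). Rounding is half-up; ties
break deterministically (higher |r|, then lexicographic pair). Node
communities come from the factor model.

Topology is summarized by the mean local clustering coefficient
(`2·triangles/(k(k−1))`, degree < 2 contributing 0 — the convention of the
standard brain-connectivity toolbox) and by Newman–Girvan modularity of
Louvain partitions averaged over 100 repetitions with independent random
node orders. A single greedy Louvain pass is not a consistent estimator of
attainable Q on small rugged graphs — it can stick in local optima that no
single-node move escapes — so each repetition reports the best of 5
independent runs; with that choice the repetition mean stays within 0.02 of
the exhaustive-search optimum across dense random, clique and
planted-community test graphs up to 10 nodes.

Network change from visit a to b is **mean Δr**: the mean over all 210
measure pairs of |r_b − r_a|. The absolute value is the default (group-level
reorganization can both strengthen and weaken individual pairs; a signed
mean would cancel); the signed mean is reported alongside. Fisher z tests
compare individual correlations between visits in the independent-samples
form as published; this ignores the within-subject dependence of
correlations measured on the same people, a documented limitation.

Inference is by resampling, the schemes being the analysis's main
under-specified detail and chosen to respect exchangeability:

* change statistics (mean Δr, Δ clustering, Δ modularity) use a
  **within-subject visit swap** — each subject's pre and post vectors are
  exchanged with probability ½ and the entire statistic pipeline recomputed
  per draw;
* between-arm contrasts reshuffle **group labels** over subjects,
  preserving arm sizes.

Probabilities are one-sided on the magnitude statistic with the +1
correction, `(1 + #{null ≥ observed}) / (1 + reps)`, never exactly zero;
draws on which a statistic is undefined (zero variance) are redrawn and
counted. Defaults: 10,000 draws, Louvain over 100 repetitions for reported
metrics; statistics evaluated inside permutation loops use cheap
fixed-procedure internals (2–3 single-start Louvain runs), which is valid
because a permutation test only requires the same procedure on observed and
null draws.

## Pipeline and reproducibility

One YAML config and one root seed drive the full run; the root seed spawns
per-stage sub-seeds deterministically, so identical config + seed reproduce
byte-identical JSON reports. Networks are exported as GraphML (community
attribute attached) and plain edge lists; models and permutation results as
JSON with full-precision floats; per-pair Δr matrices as CSV. A run log
records the config hash and seed.

## Test-suite problem sizes

Monte-Carlo checks use the study's design sizes (n = 84 knee, n = 22 hip)
with replicate counts chosen for stable rates: 500 cohorts for permutation
type-I calibration (500 draws each), 150 for power, 100 seeds for factor
recovery, 500 seeds for stepwise power and entry-rate calibration. The
qualitative reorganization pattern is evaluated as a majority vote over 9
replicate cohorts, because single draws at n = 22 carry substantial
sampling noise in graph metrics (per-draw detection power ≈ 0.8 at the
default effect sizes); the vote tests the same pattern with controlled
error. Exhaustive modularity search is limited to graphs of ≤ 10 nodes
(115,975 partitions), where enumeration is exact and fast.

## Known limitations

* The published headline numbers (69.9% explained variance, the exact model
  coefficient tables, mean Δr 0.14–0.28) depend on the undeposited cohort
  and are not reproduction targets; the pipeline reproduces the definitional
  identities and the qualitative structure.
* Promax scoring weights follow the regression method; other scoring
  conventions (Bartlett, Anderson–Rubin) would give different cross-group
  projections.
* The independent-samples Fisher z comparison across visits is
  anti-conservative for within-subject correlation changes.
* MCAR is the only missingness mechanism; the imputation rule is mean-based
  by design.
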