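# Methods

## Data model and the difference transform

The unit of analysis is a patient with exactly two visits.  The loader
accepts one CSV row per patient; when a patient appears in several rows
(more than two visits) the optional `visits="first_last"` mode keeps the
earliest first visit and the latest second visit, because the model uses a
single difference per patient and a two-point difference cannot represent
more than a linear trend anyway.  Differences are ΔY = Y(T2) − Y(T1) per
feature and ΔT = T2 − T1 (> 0 enforced).  Treatment and Growth are coded
0/1; Growth may be missing, and only for treated patients.

The "adjusted" variant subtracts a normative (feature, age) reference value
from each visit measurement before differencing, turning the variables into
deviations from normal growth.  Reference evaluation interpolates linearly
between tabulated ages; requests outside the tabulated range are an error
rather than a clamp, because atlas tables are sparse and extrapolating a
growth curve is not defensible.  Subtraction commutes with differencing, so
the adjusted difference equals the raw difference minus the interpolated
reference difference; a test asserts this to 1e-9.

## Correlation network

Pairwise Pearson correlation over all nine columns (binary columns on their
0/1 codes, where Pearson equals the point-biserial coefficient); an
undirected edge joins pairs with |r| strictly above the threshold, default
0.4.  Pairs are evaluated on their pairwise-complete rows; pairs constant on
those rows (e.g. Treatment against a Growth recorded only for untreated
patients) get no edge and a warning.  This model is descriptive only — it
cannot distinguish direct from mediated association — and is kept as the
baseline the directed analysis improves on.

## Network score

Every node, including the binary Treatment and Growth, carries a Gaussian
local model over its parents; the all-Gaussian treatment keeps the forced
arc ΔT→Growth expressible and the likelihood unified (a hybrid
discrete/continuous scheme would forbid a continuous parent of a discrete
node).  Classification on Growth is recovered afterwards by thresholding at
0.5.  The local score is the maximised Gaussian log-likelihood of the
node-on-parents regression, penalised per BIC: ℓ̂ − (k/2)·log n with
k = parents + 2 (intercept, slopes, variance) and the ML variance
convention (denominator n).  The network score is the sum of local scores.

Scores are computed from cached cross-product (Gram) matrices of [1, X], so
a local regression costs O(p³) independent of the row count; this is what
makes 200-replicate bootstraps and cross-validated re-learning cheap.
Families whose Gram submatrix is numerically singular (duplicated or
constant parents) raise a scoring error; residual variances are floored at
`SD_FLOOR² = 1e-12` so degenerate (noiseless) fits cannot produce infinite
likelihoods or zero-variance samplers.

**Missing Growth.**  Local models whose scope includes Growth are scored and
fitted on the listwise-complete rows.  The log-likelihood is rescaled to the
full sample size (ℓ̂ · n_total / n_complete, penalty on log n_total):
log-likelihood magnitude grows with the row count, so without the rescaling
any parent set that shrinks the complete-row set would receive a large
spurious gain, and the partially observed node would attract arcs from
everything.

## Structure search

Hill-climbing from the whitelist-only graph over single-arc additions,
deletions and reversals, applying the best strictly-improving move
(improvement > 1e-10) until none exists.  Moves are evaluated in
lexicographic (parent, child, move-type) order with ties going to the
earlier candidate, so the search is deterministic across platforms.
Whitelisted arcs are never deleted or reversed; blacklisted arcs
(direction-specific) are never added; acyclicity is maintained by a
reachability check.

Gaussian networks score identically across score-equivalent orientations,
so plain greedy search stalls on plateaus — the classic case is a star
oriented the wrong way around a collider, where the needed reversal has
exactly zero gain and the profitable deletion only becomes available after
several such reversals.  At a local maximum the search therefore runs a
bounded, deterministic best-first walk over arc-reversal sequences
(cumulative score change ≥ −10, at most 256 visited states) and commits the
first state from which a strictly improving single move makes the total
gain positive.  The committed score strictly increases on every escape, so
termination is preserved.  This is not a restart or tabu scheme — the walk
is exhaustive within its bounds and has no randomness.  On 4-node problems
the search then attains the exhaustive-enumeration optimum in 19 of 20
random instances (never exceeding it).

The constraint tiers mirror the clinical reading of the variables: ΔT and
Treatment are exogenous (patients are treated or not for the whole window,
and time passes regardless), features do not determine the prognosis
variable, and the dental-compensation collider ΔANB→ΔIMPA←ΔPPPM plus
ΔT→Growth are forced.

## Bootstrap averaging and the consensus DAG

R = 200 nonparametric bootstrap resamples (n rows with replacement), one
hill-climb each; replicates that fail to learn are logged and removed from
the denominator.  A pair's strength is the fraction of replicates containing
it in either direction; its direction frequency is the majority share among
those.  The estimated significance threshold minimises the L1 distance
between the empirical strength CDF and the nearest "noiseless" step CDF (a
fraction of arcs at strength 0, the rest at 1), evaluated at midpoints
between consecutive distinct strengths with ties resolved toward the
smaller threshold; perfectly separated strengths therefore give 0.5, and an
all-identical table returns 0.5 with a warning.  Consensus inclusion is
inclusive (strength ≥ threshold).  Majority directions from different
replicates can conflict and form cycles; arcs are then dropped
weakest-first (strength, then direction frequency, then lexicographic)
until acyclic, each drop logged.  Fixed 0.5 and 0.85 views are reported
alongside the estimated threshold.

## Inference

Forward sampling visits nodes in topological order and draws from
N(μ + β·parents, σ²).  Conditional probability queries use rejection:
estimate n_{E,q}/n_E with binomial standard error √(p̂(1−p̂)/n_E); an
evidence set matched by no draw returns an explicit no-match result rather
than a number.  Evidence on continuous nodes is interval-valued (point
evidence has probability zero under forward sampling); a scalar constraint
is widened to ± 0.1 units by default.  Binary nodes are sampled as Gaussian
and thresholded at 0.5 before constraints are applied.  The default
n = 10⁴ draws per query sits at the bottom of the 10⁴–10⁶ range that keeps
Monte-Carlo error below the effects of interest here.

Because the network is all-Gaussian it implies a joint multivariate normal,
computed by topological recursion over the local models; exact conditioning
on point evidence is the deterministic oracle for the sampler and the
predictor in cross-validation.  The conditioning solve uses a pseudo-inverse
(relative cutoff 1e-12) so near-deterministic networks — residual sds at the
floor — stay well-defined.

Interventions follow graph mutilation: do(X = x) removes every arc into X
and replaces its local model by a point mass (sd at the floor).  Fixing a
node and conditioning on it are deliberately distinct operations, and both
are exposed, because "hold this feature at zero" queries can be read either
way; the hypothesis suite uses the intervention reading.

## Cross-validation

Seeded uniform fold assignment (optional stratification by Treatment, off
by default), sizes differing by at most one.  Per fold, structure
(single-sample or bootstrap-averaged) and parameters are learned on the
training rows; each variable of each test row is predicted from all its
other variables via the exact conditional mean — equivalent in expectation
to sampling-based prediction but deterministic and faster.  Pooled
(observed, predicted) pairs give the predictive correlation per continuous
variable, computed by the same Pearson routine as the correlation module
(one implementation, one contract).  Growth predictions are thresholded at
0.5; rows with missing Growth are excluded from Growth's metric but retained
for the feature metrics (their prediction conditions on one variable fewer).
An isolated node yields constant predictions; its correlation is reported
as NaN rather than a number.

## Synthetic cohorts: what they emulate, and what not

The generator draws, per patient: Treatment ~ Bernoulli(66/143); first-visit
age from N(8, 1) truncated to [6, 19]; ΔT ~ U(4, 9) years; Growth from a
logistic link in (ΔT, Treatment) with coefficients (−0.5, 0.077, 0.5) —
about 0.50 / 0.62 good-grower probability for untreated / treated patients —
or, for clean recovery studies, from the truth's Gaussian local model
thresholded at 0.5; then the six delta variables by forward sampling of the
ground-truth network given (ΔT, Treatment, Growth); first-visit baselines
from per-feature normal distributions (means/sds are order-of-magnitude
plausible and otherwise arbitrary: ANB −1 ± 2°, IMPA 85 ± 5°, PPPM 27 ± 4°,
CoA 85 ± 4 mm, GoPg 70 ± 5 mm, CoGo 52 ± 4 mm); visit-2 values are
baseline + delta, exactly.

Two ground-truth constructions are provided.  `study_truth()` is the fixed,
hand-specified, clinically plausible network behind the fixture cohort
(growth of 1–1.5 mm/year in the skeletal lengths, sub-degree angular drift,
treatment entering through ΔCoA and ΔANB, compensation arcs positive,
residual sds 1–2.5 units).  `make_truth(seed, ...)` samples random
tier-respecting truths for simulation studies: ΔT is a parent of every
feature, optional parents (earlier features, Growth) appear with
probability `density`, coefficients have |β| ∈ [1, 5] with random sign, and
residual sds are noise_scale · U(0.5, 1.5).  `regime_effects` adds
Treatment→feature coefficients so treated and untreated laws can differ; at
the default 0 they are identical.

Density matters.  The default 0.4 produces networks about as dense as
published craniofacial consensus DAGs (15–20 arcs over 9 nodes), but
near-complete graphs of strongly dependent variables are not reliably
orientable by any greedy search, and with |β| up to 5 the shared-ΔT
cascades make parent sets heavily collinear.  Structure-recovery and
parameter-recovery experiments therefore use the sparse regime
(density 0.15, arcs ≈ nodes; noise_scale 0.2 for |β|/σ ≥ 3), which is the
standard design for scoring skeleton recovery; results there say nothing
about recovering near-complete graphs at clinical sample sizes, and the
fixture-cohort analysis should be read as descriptive, not as a recovery
claim.  Other simplifications relative to real data: no measurement error
distinct from residual noise, no missingness except the optional blanked
Growth for treated patients, no inter-feature heteroscedasticity, exactly
two visits, and Gaussian baselines independent of the deltas.

## Numerical choices

- `SD_FLOOR = 1e-6` on every residual sd (fits, interventions, truths).
- Strict improvement threshold 1e-10 in the search; score-equivalence
  plateaus are walked, not jumped randomly.
- Consensus threshold candidates are midpoints of consecutive distinct
  strengths; L1 objective integrated exactly between CDF breakpoints.
- Gram-matrix scoring uses Cholesky with a relative pivot floor of 1e-7 to
  declare singularity; parameter fits use `lstsq` with a rank check.
- Exact conditioning and CV prediction use `pinv` (hermitian, rcond 1e-12)
  and clamp negative conditional variances at 0.

## Known limitations

- Greedy search with bounded lookahead still misses the global BIC optimum
  on dense, strongly coupled truths; bootstrap strengths inherit that bias
  systematically rather than averaging it away.
- BIC at n ≈ 10³ admits chance |r| ≈ 0.1 associations whose likelihood gain
  exceeds the log(n)/2 penalty, so occasional spurious consensus arcs are
  expected and observed.
- The all-Gaussian treatment of binary nodes is a modelling convenience;
  probabilities for Growth are obtained by thresholding, not from a
  calibrated link.
- Arc directions between features are only identified up to score
  equivalence plus the constraint tiers; skeleton-level conclusions are the
  robust ones.
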