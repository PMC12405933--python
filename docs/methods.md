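# Methods

This note documents the models, algorithms and design decisions behind
`exacbn`, in the spirit of a package vignette: what is computed, under which
assumptions, which defaults matter, and what the synthetic testbed does and
does not establish.

## 1. The synthetic cohort generator

### Structure

The generator (`exacbn.synthetic`) produces registry-like cohorts of adult
severe-asthma patients from a ground-truth pathway network.  The `core9`
preset has ten nodes: nine pathway predictors — age, sex, chronic
rhinosinusitis (None / without polyps / with polyps), macrolide use, blood
eosinophil count (BEC), Feno, % predicted FEV₁, IgE, prior severe
exacerbations — plus the 12-month outcome (0 / 1 / ≥2 severe
exacerbations).  Its 16 arcs encode the pathway this package exists to
recover: age and sex drive CRS; age drives macrolide use; CRS drives BEC,
Feno and lung function; BEC and lung function feed Feno; the three
biomarkers drive prior exacerbations; and prior exacerbations, the three
biomarkers and macrolide use drive the future outcome.  IgE is present but
unconnected — a deliberate negative control reflecting its position off the
essential pathway.  The `extended15` preset appends five consequence nodes
(ER visits, invasive ventilation, LAMA use, anxiety, eczema) as children of
pathway nodes.

### Band-mediated dependencies

Every dependency flows through *clinical bands*: each node carries a
discrete band layer (e.g. BEC < 150 / 150–300 / ≥ 300 cells/μL) with a
conditional probability table over its parents' bands, and continuous
measurements are drawn *within* the sampled band from a band-truncated
marginal (log-normal for BEC, Feno, IgE; truncated normal for age and
FEV₁).  Consequently, discretizing a cohort at the same cut points yields
data exactly Markov — and, by the monotone parameterisation, faithful — to
the generating DAG.  This is the property that makes structure-recovery
experiments meaningful: without it, coarse discretization of a continuous
model breaks conditional independences by an amount confounded with the
learner's own errors.  The price is that within-band variation carries no
information; the generator is a testbed for the discrete pipeline, not a
biophysical model.

### Calibration

Marginals are calibrated to the published baseline profile of a large
international severe-asthma registry: 61.2% female, 31.1% CRS with polyps
(48.9% none), 11.9% macrolide use, age 55.2 ± 15.1 y, FEV₁ 73.6 ± 20.0 %,
Feno 41.8 ± 32.7 ppb, BEC 426.4 ± 326.2 cells/μL, IgE 406.7 ± 884.9 kU/L,
and 0.5 prior / 0.2 future severe exacerbations per year.  Discrete-layer
intercepts (ordered-logit thresholds, logistic intercepts, the latent
outcome base rate) are solved by deterministic bisection at build time, so
the female, CRS-with-polyps and macrolide marginals hold to ~1e-10 and the
count means exactly.

Exacerbation counts arise from a latent negative-binomial rate per parent
configuration, λ(config) = λ₀·exp(Σ effects), thresholded at {0, 1, ≥2}.
Defaults: NB size 6.0 (mildly overdispersed), and the outcome rate is capped
at 2 events/year before calibration.  The cap matters: without it the fixed
mean of 0.2 is spent on a few extreme configurations' high counts, leaving
so few distinct exacerbators that calibration statistics on 30% test splits
become noise-dominated.  With it, P(≥1) ≈ 0.10 and P(≥2) ≈ 0.05.  The
registry's reported count SD (0.8) is *not* matched — dispersion was traded
for identifiability (next paragraph) — and the per-country outcome-rate
multipliers (log-SD 0.2 over 10 countries, deterministic quantile spacing)
add the between-country heterogeneity that leave-one-country-out validation
exercises.

### Effect sizes are strong by design

The package's recovery experiments run at n = 20,000 with full-table CPTs.
A BIC-penalised search must pay (ln n / 2)·Δparameters to keep an arc; for
the outcome's fifth parent that is ≈ 1,070 nats, i.e. a conditional mutual
information of ≥ 0.054 nats against an outcome whose entire marginal entropy
is ≈ 0.4 nats.  Registry-typical effect sizes (rate ratios of 1.5–3 across
bands) are an order of magnitude below this; no generator with such effects
can be recovered under these conditions by any of the implemented learners.
The defaults therefore use strong band effects (rate ratios up to e²·⁶ ≈ 13
between extreme bands along single arcs), fixed once by an identifiability
analysis on the exact band joint: every arc must clear the G² critical value
at its worst realistic conditioning set, the arcs the consensus is expected
to find must clear the BIC add/delete margin of the family the greedy search
actually builds, and two arcs — BEC→outcome and Feno→outcome — are placed
deliberately in the window where constraint-based tests see them but
BIC-penalised searches cannot afford them.  The bootstrap consensus at the
0.75 threshold then lands a known, stable two edits from the truth, which is
what the recovery tests assert.  Passing them demonstrates correctness of
the machinery under identifiable conditions; it does not imply real
registry effects are this strong, nor that the published network could be
re-derived from data this size without expert constraints.

Missingness defaults are mild MCAR rates on the biomarkers (BEC 6%, Feno
10%, IgE 12%, FEV₁ 4%, reversibility 10%); MAR with a configurable driver
and odds is available for imputation experiments.  Real registry
missingness is higher and less benign; the defaults keep preprocessing in
the loop without dominating recovery error.

## 2. Preprocessing

* **Recoding** — zero readings in BEC, Feno and IgE become missing (a zero
  reading on these assays is an artefact, not a value), as do values outside
  per-column plausibility bounds.
* **Imputation** — iterative nonparametric imputation in the missForest
  mould: columns visited in order of increasing missingness (ties
  lexicographic), random-forest regressors/classifiers as pluggable base
  learners (default: 20 trees, depth ≤ 12), stopping at the first rise of
  the between-iteration difference statistic (computed separately for
  continuous and categorical columns; both must rise) and returning the
  previous iteration, or at `max_iter` = 10.  Columns more than 50% missing
  are refused.  Observed cells are never altered.
* **Discretization** — two mechanisms, as configuration: fixed clinical cut
  points (defaults: BEC 150/300 cells·μL⁻¹, Feno 25/50 ppb, FEV₁ 60/80 %,
  age 40/60 y, IgE 150/600 kU/L; half-open bins, boundary assigned upward)
  and Hartemink's information-preserving merge (initial quantile bins,
  greedy adjacent-pair merging that minimises the loss of total pairwise
  mutual information, round-robin over columns).  The pipeline default is
  the clinical cuts; maps serialize to JSON so test folds and new patients
  are banded identically.
* **Rebalancing** — ADASYN oversampling of minority outcome classes with
  exact largest-remainder allocation (class ratios land on the target
  exactly), SMOTE-NC-style handling of categoricals (copied from the seed
  row), interpolation for continuous features.  Rebalancing is applied to
  *training folds only* and is off by default for structure learning:
  class-biased resampling makes data non-Markov to the generating DAG
  (selection on the outcome induces dependence among its parents), which
  would corrupt constraint-free recovery.

## 3. Structure learning

The G² likelihood-ratio test (Pearson χ² optional) uses the
(|X|−1)(|Y|−1)·Π|Z| dof convention with empty strata skipped and
zero-margin levels removed; results with average cell counts below 5 are
flagged unreliable but returned.  BIC counts parameters over all parent
configurations; BDeu uses the Dirichlet-multinomial marginal likelihood
with equivalent sample size `ess`.

Hill climbing uses add/delete/reverse moves with exact delta evaluation via
family-score caching, whitelists/blacklists, optional tabu search
(move-exclusion list, aspiration-free best-of-visited) and optional random
restarts.  Ties keep the first candidate in scan order, so the default
lexicographic node order makes results reproducible; a custom `tie_order`
can be supplied.  Plain greedy search provably sticks in
coordinated-reversal local optima on a few percent of small instances; the
optimality tests therefore run with `restarts=4`, which is the operation's
intended escape mechanism.  PC-stable freezes neighbour sets per depth
(order-independence), records separating sets, orients v-structures and
closes under the Meek rules.  The local-discovery strategies (grow–shrink
Markov blankets, MMPC with an incremental max-min heuristic, semi-
interleaved HITON-PC) all apply AND-rule symmetry; `rsmax2` restricts a
final hill climb to the symmetric neighbourhood skeleton.

**Consensus.**  Each bootstrap replicate (resample size `m_fraction`·n,
default full size) is learned by every algorithm in the ensemble; DAG
outputs are reduced to their CPDAG before counting, so direction
frequencies reflect compelled orientations rather than arbitrary
equivalence-class representatives (undirected edges contribute ½ per
direction).  Pooling is equal-weight across all replicate × algorithm
graphs; per-algorithm tables are retained for diagnostics.  The averaged
network keeps adjacencies at the published 0.75 threshold and orients by
simple majority (`direction_margin` = 0; exact ties stay undirected and are
resolved by `pdag_to_dag` or the whitelist).  Expert constraints remove
blacklisted arcs (a blacklisted direction on an undirected edge orients it
the other way), force whitelisted arcs, and re-check acyclicity.  Learner
failures are tolerated up to 5% of runs.

Structure comparisons in the tests are made between Markov-equivalence
patterns: the consensus PDAG is extended to a DAG (Dor–Tarsi) and reduced
to its CPDAG before the structural Hamming distance to the true CPDAG is
taken.  This is the fair comparison — the truly reversible Age–Macrolide
edge, for instance, may be oriented either way by vote noise without being
an error.

## 4. Inference, counterfactuals, decisions

CPTs are fitted by (count + α)/(total + α·levels); the default α = 1
(Laplace) avoids zero cells in prediction, α = 0 gives maximum likelihood
with uniform fallback (and a warning) for unobserved parent
configurations.  Queries run exact variable elimination over the CPT
factors with a min-degree elimination order (name tie-break; exact answers
are order-invariant).  Counterfactuals are do-interventions by graph
mutilation — the operation of setting CRS and propagating downstream is
intervention semantics, not twin-network counterfactual identification.
Risk prediction marginalizes absent evidence, which is why test patients
with missing biomarkers need no imputation.  Influence diagrams attach
finite-action decision nodes (optionally observing chance parents) and
real-valued utility sinks; evaluation enumerates the chance joint and, for
"optimal", all deterministic policies — adequate for the one-decision
diagrams in scope, and itself the oracle the tests compare against.
Utility and cost values are user inputs; the analysis script's defaults
(exacerbation burden −1, treatment cost −0.2, benefit +0.6 for would-be
exacerbators) are illustrative only.

## 5. Validation

Stratified k-fold (fold sizes within one patient, class mix preserved to
rounding) and leave-one-country-out plans; the full preprocessing and
learning pipeline runs inside each training fold (discretization maps,
imputation models and any rebalancing never see test patients — asserted by
checksumming test folds).  Discrimination: rank AUC (ties ½) at the ≥1 and
≥2 cuts plus their macro-average as the headline; confusion metrics use
maximum-probability class assignment collapsed at the cut.  Calibration:
slope from Newton-fitted logistic recalibration of outcomes on predicted
log-odds, intercept from the offset model with slope fixed at 1
(calibration-in-the-large); probabilities at 0/1 are clipped to
[1e-6, 1−1e-6] with a warning; constant predictions leave the slope
undefined (flagged).  Test folds are always evaluated at natural
prevalence.

## 6. Problem sizes and numerical choices

Recovery and calibration experiments run at the design scale n = 20,000
with B = 200 bootstrap replicates and 5 algorithms (the package default
B = 1,000 matches the published operating point; B = 200 gives strength
standard errors below 0.035 and identical consensus decisions in repeated
runs).  Cross-validation experiments use n = 5,000–10,000.  Contingency
tables are computed by radix-encoding rows once and marginalising a cached
joint table, so a full five-algorithm replicate costs ~0.2 s at this scale.
CPT rows are validated to sum to 1 within 1e-12; scores compare with
1e-9/1e-10 slack; bisection calibrations run to 1e-12.

## 7. Known limitations

* The generator's effect sizes, dispersion and missingness are an
  identifiable testbed, not an epidemiological reconstruction; discrimination
  on synthetic cohorts (AUC ≈ 0.95) is far above what registry data yield.
* Continuous/hybrid networks are out of scope; data must be discretized.
* The influence-diagram evaluator assumes decisions affect utilities only
  (policies may condition on observed chance parents); decision-dependent
  chance dynamics would require per-action CPTs.
* The calibration-intercept experiment inherits real Monte-Carlo noise
  (SE ≈ 0.05–0.06 at the stated protocol); its tolerance is met with margin
  but not by orders of magnitude.
* ADASYN on fully-discrete feature sets degenerates to weighted duplication
  of minority rows (interpolation has nothing to interpolate), which is the
  correct SMOTE-NC-style behaviour but worth knowing when reading class
  counts.
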