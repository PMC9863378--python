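# Methods

## Data model

The outcome is the clearance index CI > 0, observed in replicate (one value
per compound per placenta); replicates share their compound's descriptor
row, so every statistical step that moves observations between sets moves
whole compounds.  Descriptors are either molecular (50 canonical slots:
16 physicochemical, 14 topological — including the Connolly surface/volume
slots, which are shape-derived — and 20 thermo-electronic) or
chromatographic (104 slots coded `<column><solvent><parameter>`, e.g.
`T3A2` = width at 5 % height on HSS T3 with acetonitrile; parameter digits:
2 width, 5 relative retention, 7 asymmetry, 8 tailing factor).  CSV is the
canonical dialect (UTF-8, comma, `.` decimal, `compound_id` first column,
empty cell = missing); an Excel import shim converts supplementary sheets.
Matrices with missing cells load but are rejected by every modelling
operation — no imputation is attempted.

## Peak measurement

A trace is a strictly increasing time grid with one dominant baseline-
corrected peak.  The apex is the global maximum refined by a parabola
through the three surrounding samples (crossing interpolation is linear, so
apex precision should exceed the sampling grid).  Threshold crossings at a
fraction of apex height are located by linear interpolation on each flank;
asymmetry uses the 4.4 % level, tailing factor and width the 5 % level
(both fractions are arguments and are echoed in the metric metadata).
Asymmetry is the trailing/leading ratio b/a, > 1 for tailed peaks.  A peak
whose flanks never cross a required level raises a truncation error; more
than one disjoint region above half height raises a multi-peak error.  A
linear-baseline helper (fitted to the first/last 5 % of samples) exists but
is off by default — nothing in the measurement conventions describes
baseline handling, so traces are assumed corrected upstream.

## Descriptor selection

Descriptors are autoscaled with sample SD (denominator n − 1); zero-
variance columns are dropped and recorded.  The importance network is a
single sigmoid output unit wired directly to the inputs — the architecture
is described only as an input layer connected to each descriptor and an
output linked to CI, and the no-hidden-layer reading makes "the weight of
each descriptor" unambiguous (an optional hidden layer is available for
sensitivity analysis, scored by connection-weight products).  The outcome
is min-max rescaled into [0.05, 0.95] rather than [0, 1]: sigmoid targets
of exactly 0/1 are reached only at infinite weights, and the margin keeps
the optimum finite.  Training is full-batch gradient backpropagation on the
squared-error loss with a per-restart backtracking step size (halve on loss
increase, grow 10 % on success), stopping when the largest absolute
gradient component falls below 0.005 or after 100 000 steps.  Two numerical
choices matter and are deliberate:

* **Gradient-proportional updates.**  Sign-based update rules (RPROP
  family) move uninformative weights as fast as informative ones in the
  d > n regime and erase the contrast that the selection rule needs;
  plain gradient descent from small initialisation stays close to the
  minimum-norm interpolator, in which informative descriptors dominate.
* **Small, identity-keyed initialisation.**  Weights are initialised at
  SD 0.05/√d from a stream seeded by (seed, restart, hash(descriptor
  code)).  Gradient descent only adds row-space components, so the initial
  noise survives additively in the trained weights; keeping it an order of
  magnitude below typical trained weights protects the median-based
  threshold, and keying by code (not column position) makes training
  exactly equivariant under column permutation.

The per-descriptor weight is the mean absolute input weight over restarts
(default 5) that converged; a descriptor is selected when its weight is
strictly greater than twice the median of all weights.  With 15 compounds
this rule is intrinsically coarse: chance |correlation| of a noise
descriptor with the outcome has half-normal scale 1/√14 ≈ 0.27, while six
mutually uncorrelated true descriptors can reach at most 1/√6 ≈ 0.41 each
(Σr² ≤ 1), so the selected set always contains chance descriptors and may
miss weak true ones.  Passing tests on synthetic data therefore certify the
machinery, not reliable descriptor identification at n = 15.

Uncorrelated-combination enumeration branches on every pair with pairwise
Pearson R² strictly above 0.5 (computed on per-compound rows), dropping one
endpoint per branch; after deduplication and removal of nested sets the
result equals the maximal independent sets of the correlation graph, which
are enumerated directly by Bron–Kerbosch with pivoting (naive branching
revisits exponentially many intermediate subsets).  Ties at exactly
R² = 0.5 do not branch.

## Regression and model choice

Weighted least squares with observation weights 1, 1/Y or 1/Y²
(Y = observed CI; CI > 0 keeps the weights finite) is solved by the
weighted normal equations in plain linear algebra; statsmodels' WLS is the
independent oracle in the test suite (agreement ~1e−14).  Reported R² is
computed from unweighted residuals — the validation formulas carry no
weights — while the weighted R² is stored alongside.  AIC/BIC use the
Gaussian weighted log-likelihood with variance RSS_w/I and parameter count
A + 1, matching the standard convention so model comparisons are valid;
absolute BIC values are not comparable across likelihood conventions and
are not treated as reference values.  Leverage is the diagonal of the
weighted hat matrix (sums to A + 1).

Pruning removes the least significant descriptor (largest two-sided t-test
p-value at α = 0.05) one at a time, refitting after each removal; when more
than 3 descriptors are simultaneously non-significant (the trigger is
configurable — the switch point is described only qualitatively) a
bidirectional stepwise search minimising AIC runs once over the model's
descriptor pool, after which one-at-a-time removal resumes.  A model pruned
to the intercept is returned flagged degenerate.  Ranking keeps fully
significant models with R² > 0.7 and sorts by BIC, ties broken by fewer
descriptors then lexicographic codes.

**High-leverage rule.**  The conventional warning leverage 3(A+1)/I applied
to observation-level hat values is provably unreachable in replicated
designs: r identical replicate rows each have hat value at most 1/r (0.2
with five replicates), below the 0.28 cutoff this data shape produces.
Per-compound leverage is therefore defined as the compound's **hat share**
— the sum over its replicate rows, bounded by 1 and invariant to replicate
count — and compared to min(3(A+1)/N, (1 + (A+1)/N)/2) over N compounds:
the classic rule when attainable, otherwise the midpoint between the mean
share (A+1)/N and the maximum 1.  Flagged compounds are pinned to training
sets; a test-set compound that is nevertheless high-leverage in its
training fit has its prediction kept but flagged unreliable.

## Validation battery

Splits allocate whole compounds: three data sets, each with 4 test
compounds (20 observations) against 11 training compounds (55
observations); test sets are disjoint and pinned compounds never leave
training.  The published allocation is available as a fixture (test set 1
differs between the molecular model, which pins BPAF, and the
chromatography-based models, which pin BP44; BPS and BPFL are always
pinned).

Cross-validation is leave-one-compound-out — replicates share identical
descriptor rows, so observation-level folds would leak the held-out
compound into training.  Metrics follow the standard battery: calibration
R² and RMSEC (denominator I − A − 1); cross-validated Q² and RMSECV
(denominator I); external QLMO² = 1 − (PRESS/n_EXT)/(SS_tr/n_TR), RMSEP,
CCC and squared Pearson/Spearman correlations.  n_EXT and n_TR are read as
numbers of observations (the standard external-Q² form); the variable list
accompanying the printed formulas calls them numbers of descriptors, which
is treated as a typo.  R², Q², QLMO², RMSEC and RMSECV aggregate as means
over the three data sets; CCC, Pearson² and Spearman² are computed on
predictions pooled across the three test sets against per-compound mean
observed CI; the aggregate RMSEP is pooled over all test observations (the
per-set values and their mean are also reported).  Verdicts compare the
aggregates to R² > 0.65, Q² > 0.5, QLMO² > 0.65, CCC > 0.85.

## Synthetic studies

The generator emulates the study's shape, not its chemistry: 15 compounds
(two of them deliberate descriptor-space outliers), 13 × 2 conditions,
5 replicates.  Peaks are exponentially modified Gaussians — tailing and
asymmetry are natural monotone functions of τ/σ — with per-condition base
retention, width and tailing, and per-compound propensities shared across
conditions (retention affinity, band broadening, tailing; the tailing
propensity correlates 0.5 with affinity, as H-bonding plausibly drives
both).  These shared propensities give the realistic feature that
same-parameter slots correlate across columns, most strongly the relative-
retention family.  Traces are sampled at 400 points/min on a window
covering ±5σ plus 12τ; detector noise is off by default.  The molecular-
like matrix is Gaussian with exact in-sample correlation blocks
(anchor-plus-residual construction, so requested block correlations hold
exactly at n = 15).

Replicate CI values come from a planted linear model in scaled descriptor
space — default: six peak-shape slots with coefficients between |0.06| and
|0.14| and intercept 0.44, chosen so compound means span roughly the
observed 0.06–0.85 range — plus Gaussian replicate noise (default SD
0.08).  Values at or below 0.01 are resampled and, failing that, clamped
just above 0.01: a generator property keeping 1/Y weights finite, not a
modelling assumption.  The outliers are displaced on three planted slots
each (τ × 8 or σ × 3), with coefficient signs arranged so their CI stays
mid-range; they reliably exceed the leverage cutoff and exercise pinning.

What the generator does **not** emulate: real retention physics, detector
artefacts, inter-placenta structure beyond iid replicate noise, and any
genuine relationship between molecular structure and peak shape.  Passing
recovery tests therefore demonstrate correctness of the pipeline's
mechanics under a known truth, not field performance.

## Pipeline guards and determinism

`run_pipeline` is a pure function of (inputs, config); all randomness flows
from the config seed.  Guards, all configurable: the combination list is
capped at 500 sets (ranked by summed selection weight) because redundant
descriptor families can produce tens of thousands of maximal sets; fits
are skipped for sets larger than n_compounds − 2 (replicate rows add no
rank); ranked models are limited to 8 descriptors (larger models saturate
the 11-compound training sets and their CV folds); when no combination
survives, candidates are built by forward stepwise-AIC over the selected
codes, and when no model passes the R² filter the best-BIC fully
significant model is reported instead of aborting.  Stage progress is
logged as `key=value` lines; any stage error aborts with the stage name and
a JSON partial-state dump.

## Known limitations

* Descriptor selection at n = 15 compounds is dominated by chance
  correlation (see above); the end-to-end recovery experiment documents
  this rather than hiding it — leave-one-compound-out Q² of final models
  containing chance descriptors is frequently negative.
* Observation-level t-tests treat replicates as independent; with
  descriptors constant within compound this overstates significance
  (pseudo-replication).  The pruning simulations in the tests therefore use
  independent observations where nominal error rates are asserted.
* The Empower conventions behind the asymmetry ratio at 4.4 % are not
  fully specified; b/a is assumed and recorded in the metric metadata.
* Whether the original cross-validation was grouped or row-level is
  unstated; both are implemented and grouped is the default.
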