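# Methods

`omegrow` implements a desk-scale version of a multi-omics growth-modeling
workflow for a bacterium: a normalized gene-expression compendium, a
regression-based transcription-factor network, a metabolism-and-expression
(ME) model, a machine-learning growth-prediction harness, two-view
ensembles, and a loop that feeds ML predictions back into the ME model.
Everything runs against synthetic organisms whose ground truth is recorded
at generation time, so each analysis can be scored against what was planted.

## Expression compendium

Heterogeneous gene×array tables are merged and normalized in five fixed
stages: identifier harmonization (source ids → canonical BSU-style ids,
unmapped rows dropped and counted, same-array collisions marked conflicting
and set missing), per-gene min–max rescaling, magnitude-outlier flagging,
random-forest imputation, and a final min–max rescale.

Numerical choices worth knowing:

* **Scaling axis.** Min–max scaling is per gene across arrays, so each
  gene's profile becomes comparable across conditions. Constant rows map to
  0 and are logged as degenerate.
* **Outlier rule.** A cell is an outlier when its log10 intensity is more
  than `k_orders` (default 2) away from the gene's median log10 intensity.
  The criterion is evaluated on the raw, strictly positive intensities —
  a log rule cannot be applied after rescaling to [0,1] — but the flags are
  applied at the stage's position in the pipeline order.
* **Imputation.** One pass of per-gene random-forest regression (default
  100 trees) of each incomplete gene on all others over its observed
  arrays; not iterated chained imputation. Deterministic per seed.
* **Differential expression.** Welch two-sample t-test per gene with
  Benjamini–Hochberg correction; `up` requires mean log2 fold change ≥
  `lfc_min` (default 1) and q < alpha (default 0.05). A pseudocount of 1e-3
  guards the log of the [0,1]-scaled means.

## TF–gene regression network

For every target gene, ordinary least squares (with intercept) of its
expression on all annotated regulator TFs across arrays. "Confidence" of an
edge is 1 − p of the coefficient's two-sided t-test; edges with confidence
above 0.95 are classed activation (β > 0) or repression (β < 0). No
multiple-testing correction is applied to the headline classification; a
BH-adjusted variant is available. Near-collinear regressor sets are
reported as unstable/unclassified rather than fitted.

Because the compendium is min–max scaled per gene, a β planted on the raw
scale appears rescaled by span(tf)/span(target); the generators record both
the raw and the effective (normalized-scale) coefficients, and recovery is
scored against the latter.

## ME model

The model is a stoichiometric network whose coefficients depend on the
growth rate μ (1/h). Coupling follows the COBRAme convention with k_eff =
k_cat·3600:

* catalyzed reaction: enzyme consumed at μ/k_eff (default k_cat 65 s⁻¹);
* translation: ribosome consumed at μ·L_aa/(k_ribo·3600), k_ribo 12 aa/s;
* transcription: RNA polymerase consumed at μ·L_nt/(k_rnap·3600), k_rnap
  55 nt/s;
* mRNA consumed by translation at (μ + k_deg)·L_aa/(k_ribo·3600), k_deg
  8 h⁻¹ — the ribosome coupling with decay added to dilution;
* polymerization costs counted exactly from sequence composition: NTPs by
  base counts (T→U), one PPi per nucleotide, one charged tRNA per codon,
  and 2 GTP-equivalents per amino acid (per-bond cost plus
  initiation/termination, aggregated);
* every macromolecule has a free dilution reaction; biomass demands (growth
  associated precursor, ATP, the unmodeled-protein stand-in) close the
  remaining balances.

Coefficients are stored as `(const, lin, rat)` triples meaning
(const + lin·μ)/(1 + rat·μ); the builder emits only affine terms, but the
rational slot is part of the JSON schema so saturating forms round-trip.
tRNA charging is aggregated per amino acid (per-codon records are supported
structurally but collapsed at toy scale).

**Solving.** At fixed μ the model is an LP: maximize the biomass-dilution
flux subject to S(μ)v = 0 and bounds, solved with HiGHS (double precision,
primal feasibility tightened to 1e-10; reported solutions satisfy
‖S(μ)v‖∞ < 1e-9). μ is feasible iff max v_bio ≥ μ; since every coupling
coefficient grows with μ, the feasible set is an interval and bisection
(tolerance 1e-6 h⁻¹, validated against a dense feasibility sweep) recovers
the maximal self-consistent growth rate. This replaces the quad-precision
nonlinear solving used at genome scale, which is out of scope at desk
scale.

**Shadow prices and growth regions.** The substrate shadow price is the
dual (bound marginal) of the substrate-uptake upper bound in the
max-biomass LP at μ*, sign-flipped so positive means growth-limiting.
Curve points are labeled strictly-nutrient-limited (SNL: dual > 1e-6 and
local slope within 5% of the initial slope), batch (dual < 1e-6), and
Janusian (between); labels are forced into three contiguous blocks.

**RNA-to-protein ratio.** Macromolecule amounts follow from the dilution
balance: total protein is Σ v_transl·L_aa/μ; mRNA turns over at μ + k_deg;
rRNA (in ribosomes) dilutes at μ; aggregate tRNA uses a turnover proxy
(charging flux · 76 nt / (k_trna·3600), k_trna 50 s⁻¹). Masses use 330
g/mol per nucleotide and 110 g/mol per amino acid. On the toy model the
ratio rises linearly with μ, the expected growth-law direction, with a
degradation-dominated floor at μ→0 that the tests derive by hand from the
coupling algebra.

## Toy organism

The generator builds a self-consistent minimal cell: an efficient
glucose-assimilation route (spontaneous, capacity-capped), an inefficient
enzyme-catalyzed route, respiration, enzyme-catalyzed tRNA charging and NTP
synthesis, RNA polymerase and ribosome complexes (the ribosome includes an
rRNA subunit and an ATP-consuming assembly subreaction), a translocated
membrane protein, an unmodeled-proteome stand-in (5 mmol amino acid
polymerized per unit growth), and optional dead-weight enzyme genes.

The SNL growth yield has a closed form recorded with the organism: with P
and A the μ-linear precursor and ATP demands summed from the biomass
composition (including the mRNA-decay NTP floor), the glucose requirement
per unit growth solves 2g − r = P, 2g + 3r = A with r the respiration flux,
so Y = 1/g. Machinery terms are O(μ²) and excluded; observed SNL slopes
agree with the oracle to ≈0.2%. A cap on ribosome formation (derived from a
target ceiling growth rate, default 1.2 h⁻¹) produces the batch plateau;
the efficient-route cap produces the intermediate mixed-limitation regime.

What the toy does *not* emulate: genome-scale stoichiometry, realistic
codon usage or sequence composition, rRNA/tRNA modification chemistry
beyond stoichiometric placeholders, and condition-specific regulation of
metabolism. Passing the toy-scale tests demonstrates the algebra, the
solver contracts and the analysis logic — not genome-scale numerical
behavior.

## ML harness

Datasets are arrays × gene-expression features with a growth-rate target,
split 80/20 per repeat. Metrics are computed from their definitions (R²,
RMSE, explained variance, MAE) and cross-checked against scikit-learn in
tests.

**HDMPPK feature engineering**, six stages in acronym order: gradient-
boosted-tree importance ranking (shallow trees, max_depth 2, max_iter 300;
permutation importance with 5 repeats; keep top m = min(200, p)); DBSCAN
outlier-array removal on the standardized feature space (eps scaled by
√dims, factor 2.5); min–max scaling; PCA keeping 95% variance; binary
particle-swarm search over component inclusion (30 particles, 50
iterations, inertia 0.72, cognitive/social 1.49) with 5-fold k-NN CV R² as
fitness; and a final k-NN fitness. Because principal components mix
features, the report's selected-feature list is attributed from the
supervised importance stage (features above the mean importance). On the
standard benchmark (500 features, 20 informative, 400 arrays, σ = 0.1) the
recall of planted features is ≥80%, deterministic per seed.

**Model families.** KNN and SVR wrap scikit-learn. The CNN (1-D valid
convolution → ReLU → global average pooling → linear head) and LSTM
(chunked subsequences → final hidden state → linear head) are compact numpy
implementations trained full-batch with Adam on standardized targets, with
seeded initialization; both include a position-wise linear skip path into
the head so position-specific signals survive the pooling/recurrent
summary. Gene vectors feed the sequence models in genome-coordinate order.
LSTM gradients are verified against finite differences in the tests.

**Optimizers.** Grid (exhaustive over a lattice, truncated at the budget),
random, ant colony (16 pheromone levels per dimension, evaporation 0.1,
10 ants per iteration), Harris Hawks (soft/hard besiege over the unit-box
encoding), and Gaussian-process expected improvement (Matern 5/2, 5 random
initial points, 256-candidate acquisition pools). Fitness defaults to
5-fold CV R² on the training split; all evaluations are traced.

**Scenario matrix.** Per view, KNN pairs only with grid and random search
while SVR/CNN/LSTM run under all five optimizers: 17 scenarios per view, 34
total. The repeated evaluation re-draws the split with consecutive seeds
(default 100 repeats; reduced sizes in the demo); individual repeat
failures are tolerated up to 5% and logged. Hyperparameters are held fixed
across repeats; only splits are re-drawn.

**Sparse group lasso** (the feature-selection baseline) is solved by
proximal gradient descent with elementwise and blockwise soft-thresholding;
the mixing parameter interpolates lasso and pure group lasso.

## Ensembles

Two members — one per data view — are stacked with an ordinary-least-
squares combiner (two weights + intercept) fitted strictly on out-of-fold
member predictions (5 folds), so no member's training targets leak into the
stacking fit; the members are then refitted on the full training split.
The named ensembles follow the optimizer-prefix convention (AB = ACOCNN on
translation + BOLSTM on transcription, BB, AA); the baseline is one SVR on
the concatenated views. Compendium profiles are mapped onto each view's
training features for growth prediction, mean-imputing unmappable features
(an error above 50%).

## ME↔ML integration

GE-MF simulation solves the ME model per condition and exports the
normalized per-gene transcription fluxes plus μ*. Simulated arrays extend
the experimental dataset (feature intersection, origin flags; default
placement keeps them out of training splits). The EM update rescales each
targeted gene's translation-side mRNA requirement by a bounded multiplier
(bounds [0.2, 5]), chosen on a log-spaced grid (17 points plus 1.0) to
minimize the deviation from the expression target at growth fixed to the
ML-predicted μ; updates that break feasibility are reverted and logged.
Targets equal to the model's own predictions are a fixed point (all
multipliers exactly 1). Accuracy scoring declares a gene correct when
|pred − ref| ≤ 0.2 on the normalized scale ("band" rule; a tertile rule is
selectable), since no standard correctness rule exists for normalized
expression heatmaps.

The update takes one growth rate and one target vector per call;
multi-condition updates are an outer loop over calls. Whether ML growth
predictions should act as hard constraints or as targets is genuinely open;
the μ is imposed exactly (a constraint) while expression enters the
objective (a target).

## Problem sizes and determinism

Everything is sized for a single CPU: the toy ME model has ~56 metabolites
and ~83 reactions; growth curves use 15-point uptake grids; regression
recovery uses 500 arrays; the feature-selection benchmark is 400×500; the
ensemble benchmark 300 arrays × 60 features per view; demo scenario runs
use 10 repeats. Every random step takes an explicit seed (default 0), and
identical configuration + seed reproduces byte-identical primary outputs
(fixed-precision text).

## Known limitations

* The LP duals at a degenerate optimum are not unique; region
  classification is robust to this because it thresholds rather than
  compares dual magnitudes.
* The numpy CNN/LSTM are deliberately small; they demonstrate the training
  and evaluation contracts, not deep-learning-scale capacity.
* The EM update searches one multiplier per gene independently; joint
  optimization across genes (which interact through the shared machinery)
  is out of scope.
* The aggregate tRNA mass proxy is a convention, not a mechanistic balance.
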