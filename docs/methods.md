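# Methods

`metacross` models two layers of cell state from one gene-expression matrix —
the production activity of metabolites and the signal output of receptor→
effector circuits — and then asks whether metabolite production *predicts*
circuit activity, controlling for the trivial explanation that the two layers
share genes. This note records the models, the parameter choices, and the
limits of what the synthetic studies can demonstrate.

## Metabolite production on sub-pathways

A metabolic pathway is a bipartite directed graph of metabolite and reaction
nodes; edges alternate metabolite→reaction (substrate use) and
reaction→metabolite (product formation). Reversible reactions are expanded at
load time into two antiparallel reaction instances sharing one gene rule, so
traversal and propagation never need a special case for reversibility. Gene
rules combine enzyme genes with AND (complexes, evaluated as the minimum of
the member expression values) and OR (isozymes, maximum). A reaction with no
rule is treated as non-enzymatic with activity 1 (logged).

The production of a metabolite *p* is modeled on its **sub-pathway**: the
subgraph of all nodes from which *p* is reachable, found by breadth-first
search against the edge direction. The product's own outgoing edges are
deleted — the producing pathway cannot consume its product — while feedback
loops elsewhere are retained. **Starting nodes** are chosen in two steps:
(1) metabolites with indegree zero within the sub-pathway, plus those at
maximal backward BFS distance from the product; (2) a topology-only dry run
(unit activities) is executed, and while any node remains unvisited, the
farthest uncovered metabolite (lexicographic tie-break) is added and the dry
run repeated. Step 2 guarantees coverage of feedback cycles that contain no
indegree-zero metabolite. Because the graph alternates metabolite/reaction
levels, "distance counted over all nodes" and "distance counted over
metabolites only" give the same ordering; both are exposed.

Propagation applies three rules per sweep, visiting nodes in BFS order from
the starting nodes (lexicographic tie-break):

1. **distribution** — a metabolite with amount `m_s` sends
   `w(m_s, r_i) = m_s · a(r_i) / Σ_j a(r_j)` to each consuming reaction
   (zero if all consumers are inactive), so outgoing flows conserve the
   amount;
2. **reaction rate** — `w(r_i, m_p) = a(r_i) · min_s w(m_s, r_i)`: the rate
   is set by the scarcest substrate and scaled by enzyme capacity. A
   saturating variant `a·s/(s+K)` (default `K = 0.5`) is available behind
   `rate_rule="mm"` but is not the tested default: the multiplicative-min
   rule keeps closure in [0, 1] and monotonicity provable;
3. **product update** — `m_p ← (m_p + Σ_i w(r_i, m_p)) / n` with
   `n = indegree + 1`. Its fixed point under stationary inflows is the
   arithmetic mean of the inflows, so the update is non-saturating and
   stable on loops.

Starting metabolites are replenished to `init_value` (default 1.0, full
substrate availability: production then reflects enzyme expression only)
every sweep; amounts are activities, not masses. Sweeps repeat until the
largest change in any amount or flow falls below `tol = 1e-6` (at most
`max_iter = 1000` sweeps; non-convergence raises, carrying the last state).
With inputs in [0, 1] every amount, flow and output stays in [0, 1]. On
acyclic sub-pathways the converged values equal a one-pass topological
evaluation, which the tests use as an independent oracle.

**Monotonicity caveat.** Production is monotone non-decreasing in every
expression coordinate only on *competition-free* sub-pathways (each
metabolite has at most one consuming reaction). With competing consumers the
proportional split re-routes flow, and raising the activity of a consumer on
a lossier branch can lower the product value (a diamond with unequal branch
activities is a counterexample). The test suite therefore asserts
monotonicity on competition-free topologies.

## Circuit activity

A signaling circuit is a signed directed graph from one receptor (indegree 0)
to one effector (outdegree 0); each node's value `v_n` comes from its gene
rule (same min/max convention). The receptor's signal is its own value; any
other node transmits

    S_n = v_n · (1 − Π_{a∈activators}(1 − S_a)) · Π_{i∈inhibitors}(1 − S_i),

i.e. parallel activating inputs combine as a probabilistic OR and a fully
active inhibitor silences the node. On a chain this reduces exactly to the
product of node values. Cyclic circuits iterate to tolerance 1e-6. This
propagation stage stands in for the published receptor–effector signal
transduction model it emulates, and it is isolated behind one function so an
alternative rule can be swapped in.

## Preprocessing

The pipeline consumes matrices that are already library-size normalized and
batch corrected (those corrections are established external methods and out
of scope). The owned steps: `log2(x+1)`, per-gene clipping at the gene-wise
0.99 quantile (upper tail only), per-gene min–max rescale to [0, 1]
(constant genes map to 0); rank-mean quantile normalization with averaged
ties for metabolomics-style tables; and loss-of-function masking — a
(sample, gene) cell whose variant is called damaging by at least 3 of 5
predictors is multiplied by 0.001, emulating a non-expressed enzyme.
Truncation is per-gene because the subsequent rescale is per-gene; the log
base and pseudo-count are the conventional choice for expression data.

## Differential production

Per metabolite, a two-sided paired Student t-test compares tumor against
matched normal production (`t = mean(d)/(sd(d)/√n)`, `df = n−1`); two-sided
because no direction is assumed. Degenerate zero-variance differences give
p = 0 (non-zero mean shift) or p = 1 (no change). Benjamini–Hochberg step-up
q-values are computed across all metabolites in the run; the significance
flag is `q < α` with `α = 0.05`. The overlap report against an external
differential-abundance list returns raw counts and the fraction under either
denominator, leaving the denominator choice to the caller.

## GP relevance and Shapley attribution

Tumor-sample metabolite production (inputs, `n_m` dimensions) is regressed
onto circuit activities (outputs, `n_s` tasks) with a sparse variational GP:
one latent GP per output mixed by the identity matrix, a kernel that is the
sum of a squared-exponential and a linear component with one hyperparameter
set shared across all input dimensions and tasks, a Gaussian likelihood with
a learned homoscedastic noise per task, and one shared set of inducing
points (default 50; reduced to `n` with a warning when `n < 50`). Because
the likelihood is Gaussian, the optimal variational posterior over inducing
values is analytic, so the bound is optimized in collapsed form over the
kernel hyperparameters and per-task noises with L-BFGS-B in log-space
(bounds ±8, iteration cap 200, relative-change stopping handled by the
optimizer). Inducing locations are placed by seeded k-means on the training
inputs and held fixed: with numerical gradients, optimizing `n_i × n_m`
coordinates is not worthwhile, and at `n_i = n` the placement is immaterial
(the model is then an exact GP, which the tests confirm against an
independent backend to 1e-2 RMSE). Initialization is deterministic: median-
heuristic lengthscale, output-variance-scaled amplitudes, noise at 10% of
the output variance. Predictive means used for scoring are projected onto
the output codomain ([0, 1] for circuit activities) — the outputs are
bounded by construction and unprojected extrapolation at leverage points
(e.g. a tumor whose enzyme was knocked out by a variant) produces
out-of-range predictions that say nothing about fit quality.

Model quality is scored by repeated k-fold cross-validation (defaults
k = 5, 100 repetitions; each repetition reshuffles the partition and every
fold refits from scratch with a seed derived from (seed, rep, fold)).
Scores are the coefficient of determination `R² = 1 − SSres/SStot` (0 is
the mean predictor; constant observations give NaN) and MSE, per task.

Attribution uses Shapley values with background-mean imputation: the
explained prediction minus the base value is exactly the sum of the
per-metabolite attributions (local accuracy). The data are split 80/20; the
model is fitted on the 80% training split, which also serves as the SHAP
background, and attributions are computed on the held-out 20% to avoid
explaining the model on its own support. With at most 12 features the exact
enumeration over all 2^p coalitions is used; otherwise kernel SHAP solves
the Shapley-kernel-weighted least squares over `2p + 2048` sampled
coalitions (all singleton and all-but-one coalitions always included), with
the local-accuracy constraint eliminated into the solve. Metabolites are
ranked per circuit by the mean absolute attribution over explained samples
(ties broken by metabolite id), and a circuit contributes annotated
(metabolite, circuit) pairs only if its mean test R² exceeds 0.5 — a score
exactly at the threshold is non-relevant. The attributions are predictive
importances; no causal claim is attached.

## Shared-gene control and annotation

For each circuit's top-k predictive metabolites (k = 1 by default, k = 20 as
a sensitivity check), predictions are cross-tabulated as {relevant,
non-relevant} × {≥1 shared gene between the circuit and the metabolite's
sub-pathway, none}. A one-sided (greater) Fisher exact test — assembled from
hypergeometric tail probabilities via log-gamma, verified against exhaustive
enumeration — asks whether relevant predictions are enriched for shared
genes; the two-sided alternative is also exposed. An empty margin returns
the degenerate p = 1. Relevant circuits propagate their effector function
terms and hallmark labels (user-supplied TSV maps; external text-mining
services are deliberately not a dependency) to the metabolites that regulate
them, with aggregate percentages over all (metabolite, term) incidences.

## Synthetic studies

The generator emulates a paired tumor/normal cohort on the post-
normalization [0, 1] scale. Pathway graphs are chain backbones with optional
parallel conversions, feedback-closing reactions (`loop_frac`), reversible
reactions (`reversible_frac`) and AND-joined multi-gene rules; circuits are
receptor→effector DAGs (chain plus forward skip edges, OR-joined node
genes, optional inhibitory edges). Expression is per-gene baseline
U(0.35, 0.65) plus independent Gaussian noise (`noise_sd`, default 0.05),
clipped to [0, 1].

Planted structure: (1) *differential production* — enzyme genes of one deep
product per pathway are shifted ±`dpm_effect`/2 between tumor and normal
(default 0.3); (2) *metabolite→circuit links* — the variant table is drawn
first, the planted metabolite's production is computed on the LoF-masked
tumor enzyme expression, and the linked circuit's genes in tumors follow
`0.5 + link_effect · z` (z the standardized production) plus a per-circuit
latent (`circuit_latent_sd`, default = `noise_sd`, representing circuit-
level variation not attributable to metabolites) and gene noise — so an
enzyme knockout propagates to the circuit through the metabolite, as it
would causally, and the link is only recoverable through the full
production → GP → attribution chain; (3) *gene sharing* — a chosen fraction
of circuit genes is renamed into enzyme-gene slots to exercise the Fisher
control. Damaging-variant rows are drawn per (tumor sample, gene) at 0.5%
(somatic damaging rates per gene per tumor are well below 1%), with a
configurable damaging-vote distribution.

What the generator does *not* emulate: RNA-seq count distributions,
library-size or batch effects, correlated co-expression programs, germline
variation, or pathway crosstalk at the graph level. Passing tests therefore
demonstrate that the pipeline recovers the planted causal structure under
realistic noise — not that it would recover biology from a real cohort.

## Test and verification scale

Deterministic seeds throughout (`numpy.random.default_rng`; identical seeds
give byte-identical studies and pipeline artifacts, which the manifest's
SHA-256 hashes verify). Verification sizes are chosen for a single CPU:
propagation properties on ~100 random sub-pathways per property; BH-FDR
against the literal step-up definition on 1000 random vectors; Fisher
against enumeration on every 2×2 table with grand total ≤ 30; paired-t null
uniformity on 2000 simulated nulls; CV at 5 repetitions in tests (the
pipeline default remains 100×5-fold); end-to-end recovery on 100 seeds of a
compact study (3 pathways × 4 metabolites, 4 circuits, 100 tumor/normal
pairs, link effect 5× noise) with 1×5-fold CV for the relevance gate. The
acceptance script re-runs the same computations at 25 recovery seeds by
default (`--recovery-seeds` raises it).

## Known limitations

- The signal-propagation rule for circuits follows the cited mechanistic
  model family but is not a re-implementation of any specific released
  package; absolute activity values are not comparable across rules.
- The propagation model is non-stoichiometric: no mass balance, no
  compartments, no consumption accounting beyond removing the product's
  out-edges.
- Kernel hyperparameters are shared across input dimensions (no ARD), so
  with many irrelevant inputs and few samples the GP's per-task R² is
  conservative.
- Shapley attributions under collinear inputs split credit among correlated
  metabolites; sibling metabolites on one chain can dilute each other's
  rank.
- The Michaelis–Menten rate variant is exposed but untested against any
  kinetic ground truth; it exists as a sensitivity knob.
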