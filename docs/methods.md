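# Methods

## Multiplex model and the classic random walk

A set of undirected PPI networks is combined into a multiplex network: one
layer per network, a state node for every (gene, layer) pair — including
genes absent from a given layer's input — intralayer edges copied verbatim
with the layer's emphasis weight w (default 1), and interlayer edges of
weight 1 joining all state nodes of the same gene. The interlayer weight is
a free modelling choice; it only exists to let the walk change layers, and
it is exposed as a configuration knob (`interlayer_weight`). Setting a
layer's weight above 1 biases the walk — and therefore conductance and the
local graphs — toward that layer's topology (e.g. weight 5 to emphasise a
context-specific network).

The walk is the classic random walk on the weighted union graph:
T = D⁻¹A. Because the graph is undirected, its stationary distribution is
degree-proportional, p(iα) = deg(iα)/Σdeg, and is computed in closed form;
the test suite checks it against 10,000-step power iteration to 1e-10.
Generalized conductance, defined as stationary outflow over internal mass,
reduces for this walk to cut-weight/volume — the normalizers cancel — so
Φ(S) is evaluated exactly in sparse arithmetic, with no tolerance beyond
float rounding. In a single-layer multiplex with unit weights it coincides
with standard graph conductance.

Isolated genes are still walkable in a multi-layer multiplex (their
interlayer edges carry the walk); with a single layer they have no edges at
all, are flagged unwalkable, and are excluded from seeding and local
graphs.

## Local FDR estimation

The two-groups model follows standard empirical-Bayes practice. p-values
are clipped to [1e-15, 1−1e-15] and mapped one-sided to z = Φ⁻¹(1−p), so
large z means significant — appropriate for MutSig-style significance
p-values. The marginal density f(z) is estimated by Lindsey's method: 120
histogram bins spanning [min z − 0.1, max z + 0.1], Poisson regression of
the counts on a degree-7 polynomial basis (rescaled to [−1, 1] for
conditioning), fit with statsmodels. The null proportion π₀ is the largest
constant with π₀·f₀ ≤ f over the central half of the z range, capped at 1.
The null f₀ is the standard normal by default; with `null="empirical"` the
null centre and scale are estimated by central matching — a quadratic fit
to log f on the central window — which recovers (0, 1) under a true
uniform-p null. (A truncated-sample MLE restricted to the interquartile
window was tried first and rejected: the truncated likelihood is nearly
flat in the scale parameter, so the estimate is unstable.)

lfdr = min(1, π₀f₀/f) is additionally made non-increasing in z beyond the
null mode by a cumulative minimum. This removes edge wiggle of the
polynomial fit in the sparse right tail, where the raw ratio can be
non-monotone; it never lowers a null gene's lfdr below the fitted value at
smaller z. If the Poisson regression fails to converge the estimator falls
back to a unimodal isotonic fit of the log-counts and warns. Below ~200
genes the density fit is unreliable and a warning is emitted.

Calibration under the null (checked by the suite over 20 replicates of
n = 10,000): on average well under 2% of null genes fall below lfdr 0.1.
When lfdr tables from several data types are available (mutation, copy
number amplification/deletion), `combine_min_lfdr` takes the per-gene
minimum — local FDRs, unlike p-values, are comparable across data types.

## Local graph extraction

The per-seed search region is computed by approximate personalized
PageRank with continuation probability c = 0.998 (restart 0.002). The
residual starts at 1/|L| on each of the seed's state nodes. A push at u
moves (1−c)·r(u) to the score and spreads c·r(u) along T's row; nodes are
pushed while r(u) > ε·deg(u). Because the chain is reversible, this
terminates with |exact(u) − score(u)| ≤ ε·deg(u) for every state node
(verified against a dense linear solve of (I − cTᵀ)π = (1−c)r₀ on small
graphs).

Pushes are performed in deterministic batched sweeps — every eligible node
per sweep, ascending state index — rather than one node at a time from a
priority queue. A batch is a fixed ordering of individual pushes, so
correctness and the termination guarantee are unchanged, while the sparse
row operations are an order of magnitude faster at c close to 1, where
pushes number in the millions. All state is held in dictionaries keyed by
state index; no dense vector over the state space is allocated.

The ε schedule starts at 1/(50K), divides by 10 per round (resuming the
previous residuals), and floors at 1e-10; it stops as soon as the score
vector has K nonzero entries. The K top-scoring state nodes are kept
(ties broken by gene identifier, then layer index), the seed's state nodes
are always retained, and the set is augmented to layer-completeness.
Ranking uses raw PPR scores. Note that at c = 0.998 the PPR vector is
close to the stationary distribution, so the top-K set is a
degree-inflected neighbourhood, not a strictly nearest-first ball; this
matches the local-clustering usage the parameter comes from. Per-gene
boundary weights (intralayer edge weight leaving the local gene set) are
recorded for the search step.

## The search MILP

The cover constraint (a chosen gene is included in every layer) collapses
state-node indicators to per-gene binaries x_i, under which

- cut weight N(x) = Σ_{i<j} c_ij·|x_i − x_j| + Σ_i b_i·x_i, with c_ij the
  summed layer weight of intralayer edges (i, j) inside the local graph
  and b_i the boundary weight;
- volume D(x) = Σ_i d_i·x_i, with d_i the gene's total state-node degree
  in the full multiplex (interlayer edges included).

Interlayer edges never appear in the cut (both endpoints share x_i), and
N/D equals the generalized conductance of S = P×L exactly.

The fractional objective is minimized by Dinkelbach iteration: solve the
MILP min N(x) − λD(x), update λ ← N(x*)/D(x*), stop when the subproblem
value exceeds −1e-7 (λ is then optimal and non-increasing across
iterations; iteration counts of 2–5 are typical, 50 is a hard cap). λ is
initialized at the singleton seed's conductance. |x_i − x_j| is linearized
with a continuous y_ij and four standard inequalities. Connectivity of the
selected gene set is enforced by single-commodity flow on the physical
local-graph adjacency: the seed supplies Σ_{u≠s} x_u units, every other
selected gene consumes one, and arc capacities (n−1)·x bound flow to
selected genes. Under the cover constraint, physical connectivity is
equivalent to random-walk (T_adj) connectivity of the state-node set,
because interlayer edges always link a gene's copies; running the flow on
genes rather than state nodes shrinks the model |L|-fold.

Subproblems are solved with HiGHS through `scipy.optimize.milp` at a
relative MIP gap of 1e-6 and a per-seed time limit (default 600 s; the
benchmark uses 120 s). On timeout the best incumbent is returned with
status `incumbent`; with no incumbent, the seed singleton (always feasible,
since seeds satisfy lfdr < B) is returned as `singleton-fallback`. The
FDR constraint Σ(lfdr_i − B)x_i ≤ 0 guarantees every returned subnetwork
has mean lfdr ≤ B by construction. The test suite checks the whole solver
against exhaustive enumeration of all connected, seed-containing,
FDR-feasible subsets on instances of up to 12 genes.

Seeds are ordered by the number of other seeds among their neighbours in
the aggregated (union) network, ties lexicographic; a seed contained in
any earlier subnetwork is skipped.

## Synthetic benchmark

The generator plants disjoint dense modules (Erdős–Rényi blocks with
intra-module edge probability 0.6) over a sparse G(n, p) background with
mean degree 4 — dense enough for modules to be conductance-detectable,
sparse enough that they do not merge by chance. Each layer is an
independent degree-preserving rewiring of this shared scaffold (double-edge
swaps; a fraction r of edges rewired means r·|E|/2 attempted swaps, since
each swap moves two edges). Module genes draw p-values from Beta(a, 1) —
mean a/(a+1), so a = 0.01 is strong signal — and background genes from
U(0, 1). Everything is reproducible from a single integer seed.

Metrics: gene-level F (harmonic mean of precision and recall over pooled
gene sets); symmetric Fsub (size-weighted best-match F between the two
subnetwork collections, averaged over both directions); exact FDR of a
subnetwork (proportion of its genes outside the planted truth) alongside
the estimated FDR (mean lfdr).

### Problem sizes and the choice of K

The default exploration size K = 400 state nodes is calibrated to
genome-scale multiplexes (tens of thousands of genes across several
layers), where a local graph of ~100 genes comfortably brackets protein
complexes of 10–50 members while remaining a tiny fraction of the network.
The benchmark runs at desk scale — 500 genes, 3 layers, 1,500 state nodes —
for speed and testability. At that scale K = 400 covers over a quarter of
all state nodes, so "local" graphs span several planted modules, and the
conductance optimum legitimately merges them into larger, still
FDR-controlled subnetworks: FDR control is unaffected, module-resolution
(Fsub) degrades. The benchmark therefore uses two settings:

- **FDR-control experiment**: K = 400 (20 replicates, a = 0.01, B = 0.1) —
  the quantity under test (mean estimated FDR of detected subnetworks) is
  invariant to K, and the full-size setting exercises the solver hardest.
- **Recovery, signal-trend and robustness experiments**: K = 100 (~33
  genes per local graph, 1.6–3× the planted module size — the same ratio
  the default K gives at genome scale), 10 replicates per condition at
  a ∈ {0.01, 0.05, 0.11}.

Observed behaviour (recomputed by the suite): mean estimated FDR ≈ 0.09
≤ 0.1 at K = 400; mean Fsub ≈ 0.97 at a = 0.01 falling monotonically with
a; replacing one of three layers by its degree-preserving randomization
costs < 0.02 Fsub.

### What the synthetic benchmark does and does not show

The generator reproduces the *statistical* structure of the planted-module
benchmark (module sizes, the Beta/uniform p-value mixture, layer
derivation by rewiring) but not real PPI topology: true networks are
scale-free with hubs, layers differ far more than a 10% rewiring, and real
"modules" (complexes, pathways) overlap. Passing tests demonstrate correct
mechanics and FDR control under the model's assumptions, not absolute
performance figures on real cancer data. The CLI accepts real-data-shaped
inputs (multiple genome-scale edge lists, MutSig-style p-value tables,
precomputed lfdr tables, per-layer weights) unchanged.

## Numerical choices and degenerate inputs

- p-value clipping at 1e-15; transition rows sum to 1 within 1e-12.
- Gene identifiers are whitespace-trimmed, case-sensitive; no alias
  resolution (that is data curation, not method).
- Self-loops dropped with a warning; duplicate edges stored once.
- Degenerate score tables (all p identical) abort with a diagnostic.
- Solver ties in top-K selection and seed ordering broken
  lexicographically, making runs bit-reproducible given a seed (except
  `incumbent`-status results, which are flagged).
- A seed whose neighbours all carry lfdr 1 returns its singleton whenever
  the singleton is the conductance optimum among feasible sets.

## Known limitations

- The MILP scales to local graphs of a few hundred genes; K much beyond
  that (or very dense local graphs) makes the flow model large. The
  per-seed time limit keeps runs bounded at the cost of optimality
  certificates (status `incumbent`).
- Edge-level confidence weights within a layer are not supported (layers
  are weighted as wholes); directed/signed interactions are out of scope.
- The lfdr estimator assumes a unimodal, mostly-null z distribution;
  heavy signal contamination (> ~30% non-null) inflates π₀ estimates and
  makes lfdrs conservative.
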