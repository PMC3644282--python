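# Methods

This note records the model, the defaults, the numerical conventions and the
design decisions behind `ctxnet`, in the package's own words. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Data model

All analysis operates on three-state (trinary) matrices: rows are genes or
gene sets, columns are samples, entries are UP / DOWN / NOCHANGE, coded
internally as +1 / −1 / 0. Two quantization rules produce this
representation from continuous data:

* **Fold change** (tumor/baseline ratios): ratio ≥ 2 → UP, ≤ 1/2 → DOWN,
  else NOCHANGE. The boundary is *inclusive* (a ratio of exactly 2 is UP).
* **z-score** (against designated reference samples, per gene): z > 1 → UP,
  z < −1 → DOWN, else NOCHANGE. The boundary is *exclusive*; a gene whose
  reference standard deviation is zero is set to NOCHANGE everywhere with a
  warning (its z-score is undefined).

The two boundary conventions are fixed so results are deterministic; the
quantization sources only state the thresholds, not the boundary side.
State tokens in files are case-insensitive on read, upper-case on write.

## Gene-set summarization

A gene set G with m members is summarized per sample to UP when both

1. strictly more than r·m members are UP (strict majority, r = 0.5), and
2. the count k of UP members is hypergeometrically surprising:
   P(X ≥ k) < 0.05 for X ~ Hypergeom(N, K, m), with N the number of genes
   in the quantized matrix and K the number of those UP in that sample,

symmetrically for DOWN, and NOCHANGE otherwise. The two clauses are
conjunctive: a majority without significance summarizes to NOCHANGE. For
r ≥ 0.5 the directional majorities are mutually exclusive, so the result is
unique. The background universe is all genes of the input matrix — the only
universe available to the program. Sets that are NOCHANGE everywhere can be
dropped before network learning (`drop_flat`), off by default.

## Consensus network

Dependencies between gene sets are learned with a discrete Bayesian-network
model on the summarized matrix. Every variable is treated as three-state
categorical whether or not all states are observed; variables constant
across samples are excluded from search and reported with d = 0.

**Score.** The BDeu (Bayesian-Dirichlet equivalent uniform) log marginal
likelihood with equivalent sample size ess = 1: for child with parent
configuration space of size q, the Dirichlet mass ess is spread uniformly
over the q·3 cells. It is the single score of this package (no BIC option);
ess = 1 is in the default family of the common structure-learning tools,
and the score is likelihood-equivalent, so both orientations of a single
edge score identically — consistent with ignoring edge direction.

**Search.** Greedy hill climbing over add / delete / reverse moves from a
seeded random start, respecting a parent limit (default 5). Candidate moves
are scanned in a fixed lexicographic order over (parent, child) pairs; the
first strictly-best move wins and a move is only taken if it strictly
improves the score, so an exact tie between adding an edge and not adding
it keeps the sparser structure. The random start draws a uniform
topological order and includes each forward edge with probability
min(2/(n−1), 0.5), truncated at the parent limit — sparse starts for large
node counts. The start is the *only* stochastic element; this run-to-run
variability is what makes the consensus frequency informative. The inner
loops (scoring, cycle checks, the climb itself) are compiled with numba;
one search on 20 variables × 200 samples takes ~2 ms, which is what makes
the permutation experiments tractable on one CPU.

**Consensus.** d_ij is the fraction of R = 1024 independent runs whose DAG
contains i→j or j→i. Per-run seeds derive from a base seed and the run
index by SHA-256 folding (to 31 bits, safe for every consumer), so runs are
order-insensitive and consensus estimates on different sample subsets never
share streams. Edges are called when d_ij strictly exceeds d_θ = 0.5. On
two-variable data every run lands on the better of the two structures, so
d ∈ {0, 1} and equals the score-comparison indicator exactly — the test
suite uses this as an exact oracle.

## Condition specificity

For a condition with samples S_Tk, the leave-out likelihood d_ij^Tk is a
consensus on S_U − S_Tk with R_perm runs (default: same as R; exposed
separately because M × R_perm consensus learning dominates runtime), and

γ = d_ij / max(d_ij^Tk, 1/(R_perm+1)).

The floor — one pseudo-count at the frequency resolution — keeps γ finite
when the leave-out consensus never finds the edge; the ratio definition is
otherwise silent about a zero denominator.

**Permutation test.** M = 100 subsets of size |S_Tk| are drawn uniformly
without replacement from S_U; γ_m is recomputed for each; H counts
γ_m ≥ γ (ties count toward H) and P = H/M exactly — zero P values are
possible, no add-one smoothing. An edge is specific when γ > γ_θ = 2 and
P < p_θ = 0.05. No multiple-testing correction is applied across
(edge, condition) pairs by default (raw P at 0.05); Benjamini–Hochberg is
available as an opt-in.

One permutation consensus yields the d matrix for *all* edges at once, so
`test_all` shares each permutation's consensus across the tested edges, and
across conditions of equal size (the null draw depends only on |S_Tk|).
This changes nothing statistically — subsets remain i.i.d. uniform draws —
and divides the dominant cost by the number of tested edges. Overlapping
conditions are tested independently; results are deterministic given the
seed regardless of edge or condition order.

**Centricity.** A gene set with at least one called edge is labelled
generic (no incident edge specific to any condition), T_k-centric (every
incident edge specific, all to the same single condition), or mixed.

**Declaration rule.** Specificity is a property of interactions present in
the network: an edge is *declared* specific only if it is also called
(d > d_θ). γ and P can still be evaluated for arbitrary pairs (the statins
experiment evaluates every pathway regulation and reports both sets); this
matters because the γ floor can push near-zero edges (d_all ≪ d_θ) over the
γ threshold even though no dependency was ever established.

## Boolean-network simulation

The simulator is synchronous: all unclamped nodes update simultaneously
from AND/OR/NOT rules; clamped nodes hold their value (modelling a
perturbation such as statins administration). Per sample, a uniformly
random initial state is drawn, clamps applied, and the trajectory followed
until a fixed point or cycle; fixed points emit themselves, cycles emit one
uniformly chosen cycle state. A step cap (default 4096) guards pathological
cases with a warning.

**Cholesterol fixture.** The packaged model (18 nodes,
`models/cholesterol.bnet`) reduces a published boolean model of the
cholesterol regulatory pathway: the synthesis chain from acetyl-CoA through
HMG-CoA, mevalonate, the isoprenoid intermediates and the two final sterol
branches to cholesterol; cholesterol repressing SREBP-SCAP, whose
transcriptional program drives the synthesis enzymes (HMG-CoA synthase,
HMG-CoA reductase, mevalonate kinase, FPP synthase, squalene synthase); and
statins inhibiting HMG-CoA reductase. All multi-input nodes are AND except
cholesterol, which ORs its two branches. The enzyme tier is retained
deliberately: without it, consecutive chain metabolites are *exact copies*
of one another in any synchronous sample, the consensus dilutes d across
the resulting clique of equivalent explanations, and the reductase →
mevalonate dependency is invisible at any sample size. With statins clamped
on, every attractor has the reductase, mevalonate and all downstream
products off — the perturbation signature the simulation experiment
recovers.

**What the simulation does and does not emulate.** Samples are attractor
states of a small deterministic logic model: they capture steady-state
co-variation induced by shared regulators and perturbations, and the
two-arm design mimics a treated/untreated cohort. They do not model
measurement noise, continuous dose response, asynchronous or stochastic
updating, or the scale and redundancy of genome-wide data — passing the
simulation experiment shows the specificity machinery isolates a known
perturbation path in clean data, not that it would do so at biobank scale.
The exact sampling protocol behind the original experiment is not public;
attractor emission from uniform random initial states is this package's
documented choice.

**Planted-dependency generator.** Background variables i.i.d. over the
three states (uniform by default); for each planted ((i, j), T_k, s),
variable j copies variable i with probability s inside T_k's block and is
background otherwise; finally every cell flips to one of the other two
states with probability `noise`. Ground truth is returned for scoring.
Marginals, blocks and strengths are checked by the test suite (exact copy
at s = 1, chi-square independence at s = 0, marginal frequencies within
3 SE).

## Validation experiments and their problem sizes

The packaged experiments (shared by `tests/test_acceptance.py` and
`scripts/acceptance.py`) run at sizes chosen for a single CPU:

* **Statins simulation** — 100 samples per arm, R = 1024 for the observed
  network, R_perm = 128, M = 100 permutations (the original simulation used
  1000 permutations; 100 keeps the resolution of P at 0.01, sufficient for
  a 0.05 threshold).
* **Two-variable oracle** — 50 datasets, 40–500 samples, alternating
  dependent/independent regimes.
* **Planted recovery** — 20 replicates of the 20-set / 200-sample /
  4-block / strength-0.9 / noise-0.05 design, R = 256, R_perm = 64.
* **Rank property** — γ versus the edge frequency estimated from the
  condition's samples alone, 8 strengths spanning the score's detection
  transition (0.28–0.58), two equal 100-sample blocks, each design point
  averaged over 40 generated datasets: edge frequencies of borderline
  dependencies are the noisiest consensus estimates, so single datasets
  would rank noise. The block design uses half the samples because a
  50-sample block leaves every γ at the floor regardless of strength.
* **Summarizer oracle** — 1000 random backgrounds, set sizes ≤ 12, against
  explicit summation of hypergeometric masses.

## Known limitations

* **Detection threshold of weak, localized dependencies.** A dependency
  confined to a fraction of samples must carry more pooled log-likelihood
  than the BDeu complexity penalty (~10.6 nats for adding one three-state
  parent at ess = 1) to be called at all. A strength-0.9 copy inside 50 of
  200 samples carries only ~7 nats and is effectively undetectable; the
  planted-recovery experiment documents this honestly (its recovery count
  is reported, not asserted away). Raising ess buys detection but destroys
  specificity control: at ess ≥ 32 the weakened penalty makes the best
  noise edges stable across all restarts (d = 1 on independent data), which
  corrupts the leave-out estimates. At intermediate ess the permutation
  subsets themselves fall below the detection threshold, γ_m ties with the
  observed γ at the floor, and P → 1. Condition-specific effects need to be
  strong relative to the block size (roughly: block-restricted mutual
  information × block size well above the parent penalty) to be both called
  and certified.
* Consensus frequencies are Monte-Carlo estimates; their binomial
  fluctuation at R runs bounds the reproducibility of d between seed
  blocks (tested).
* The hill climb finds local optima; the consensus aggregates over random
  starts but inherits any systematic bias of greedy search, and score ties
  between exactly equivalent explanations are resolved by scan order, which
  can concentrate d on the lexicographically first of two identical
  variables.
* Permutation P values have resolution 1/M; with M = 100 the smallest
  nonzero P is 0.01.
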