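# Methods

## Model and objective

GSEM treats link prediction in the drug × side-effect incidence matrix
`X ∈ {0,1}^{n×m}` as two independent self-expressive regressions. The
side-effect factor `W (m × m)` minimizes

    f(W) = ½‖X − XW‖²_F + a/2‖W‖²_F + b‖W‖₁
         + Σ_g μ_g/2 · Tr(W L_g Wᵀ) + γ Tr(W),    W ≥ 0,

and the drug factor `H (n × n)` the analogous objective with
`½‖X − HX‖²_F`, smoothness `Tr(Hᵀ L H)` (rows of `H` are the
self-representations, so rows are smoothed, columns for `W`), and
elastic-net weights `c, d`. The smoothness penalty is defined as
`Tr(S L Sᵀ)` exactly; the pairwise form `Σ_ij A_ij‖s_i − s_j‖²` equals
twice that trace, and the factor is absorbed into the graph weights.
Dimension dictates the graph assignment: drug graphs (n × n) regularize
`H`, side-effect graphs (m × m) regularize `W`. On the real-data scale the
published operating point is `a=60, b=0` for `W`, `c=40, d=0.5` for `H`,
`γ=10⁴`, and graph weights `μ_chem=0.1, μ_ind=0.5, μ_target=0.01, μ_atc=5`
(drug side) and `α_meddra=0.5` (side-effect side).

All terms are convex (quadratic + linear on the non-negative orthant), so
the program has a global optimum; with `a > 0` (resp. `c > 0`) it is
strictly convex and the optimum is unique, which is what makes refits with
different random initializations agree.

## Multiplicative learning algorithm

The gradient splits into a positive part `P(S)` (everything that grows with
`S`: `XᵀX S`, `Σ μ S D_g`, `a S`, `b`, `γI`) and a negative part `N`
(`XᵀX`, `Σ μ S A_g`). The update

    S ← S ⊙ N / (P(S) + ε),     ε = 1e-12,

is the diagonally rescaled descent rule familiar from non-negative matrix
factorization: iterates stay non-negative, the objective never increases,
zeros are absorbing, and fixed points satisfy the KKT complementarity
conditions `min(S, ∇f(S)) = 0`. The `H`-side denominator uses the
gradient-consistent `H·XXᵀ` ordering. The stabilizer ε only matters when a
denominator entry is exactly zero (an entity with no associations, which is
also logged as a warning, since its coefficients can only decay).

Initialization is `Uniform(0, 0.01)` from a caller-provided seed; each fit
uses one generator, and the `H`/`W` fits take independent seeds. The
stopping rule is `max_ij |ΔS_ij| / (|S_ij| + 1e-12) < tol` with default
`tol = 1e-2` and `max_iter = 500` (tighter tolerances need more headroom;
entries decaying geometrically toward zero change by a constant relative
factor per step and only satisfy a tight tolerance once they underflow the
`1e-12` floor — hitting `max_iter` returns a warning and `converged=False`,
never an exception). The per-iteration objective trace is recorded and the
descent property is asserted in the tests at `1e-9` relative slack.

Diagonal handling: during the fit the diagonal is suppressed only through
the linear `γ Tr(S)` penalty (with `γ = 10⁴` a converged diagonal entry is
below `1e-3`, typically underflowed to 0). `fit_gsem` hard-zeroes both
diagonals once after convergence so that predictions `HX + XW` contain no
self-loop term; single fits returned by `fit_selfrep` are left untouched so
that optimality diagnostics (KKT residual, objective comparisons) see the
exact fixed point.

## Similarity constructions

Feature-set similarity is the Jaccard index `|U∩V|/|U∪V|` (for binary
structural fingerprints this is the 2D Tanimoto chemical similarity); two
empty sets give 0 by convention, with a warning. Taxonomy similarity over a
code hierarchy (ATC-like for drugs, multi-axial MedDRA-like for side
effects) is `1 − SP(u,v)/max_pairs SP`, where `SP` is the undirected
shortest-path edge count between the two entities' annotation sets,
aggregated over cross pairs by the minimum (the conservative choice that
reproduces the 2-to-8 path range of a 4-level hierarchy), and the
normalizer is the empirical maximum over all annotated pairs. Consequences
worth knowing: with only two entities the off-diagonal similarity is forced
to 0; entities sharing a code get similarity 1; and the min-aggregated set
distance is not a metric for multi-code entities (two sets can each be at
distance 0 from a common superset while being far apart), so the
pseudometric properties are only guaranteed for single-code annotations.

## Evaluation protocol

Splits draw `floor(test_frac·P)` positives for testing, then
`floor(val_frac·(P−|test|))` for validation (floor rounding reproduces the
2,761/2,484/22,365 partition of 27,610 positives at 10 %/10 %). Negatives
— two per positive by default — are sampled uniformly without replacement
from the zero entries, so they can never contradict a labeled positive;
validation and test negatives are disjoint. AUROC uses the mid-rank
statistic (ties count ½, constant scores give 0.5); AUPR is the step-wise
precision-recall integral with tied thresholds grouped
(`sklearn.average_precision_score`; the test oracle is an independent
hand-rolled loop). Per-drug evaluation scores each drug's training-zero
entries with its test positives as the positive class, reported only for
drugs with at least `min_test = 10` test positives.

The ratio of reporting frequency of side effect `j` is
`RRF(j) = Σ_i x_ij / Z` with `Z` the maximum column count. Group shift
tests compare a group's RRF values against the pooled remainder with a
one-tailed Wilcoxon rank-sum test — both tails evaluated, the more
significant reported with its direction — Benjamini-Hochberg adjusted
across groups, with effect size group-median minus overall median; groups
with fewer than 3 members are skipped. The exact null distribution is used
when both sides have n < 10 and no ties, the normal approximation with tie
correction otherwise.

The data-integration comparison trains the target drug on its
clinical-trial associations only while the remaining drugs contribute
either clinical-only (strategy 1) or clinical ∪ postmarket (strategy 2)
associations; other drugs with chemical similarity ≥ 0.6 to the target are
removed first to prevent leakage through close analogs. Performance is the
AUROC over the target's training-zero entries with its postmarket
associations as positives.

## Synthetic fixtures

The generator plants the union-of-subspaces structure self-expressive
models assume: drugs and side effects are assigned uniformly to clusters
(defaults 60 × 50 entities, 4 × 4 clusters), a random permutation maps each
drug cluster to its compatible side-effect cluster, and cells are Bernoulli
`density_in = 0.6` inside compatible blocks and `density_out = 0.02`
outside. Rows are redrawn until every drug has ≥ 5 positives, mirroring the
usual clinical-trial inclusion rule. Companion fixtures are
cluster-consistent unit-weight graphs (`p_in = 0.8`, `p_out = 0.05`), a
balanced toy hierarchy (branching 3, depth 4, so leaf distances span 2–8),
and a holdout planter that hides a fraction of positives without emptying
any row. Everything is bit-reproducible from a seed.

What the fixture does *not* emulate: the long-tailed (near power-law)
column distribution of real reporting data, correlated noise between
similar drugs, and the scale of real matrices. Passing the recovery
benchmark therefore shows that the algorithm recovers planted
self-expressive structure, not that it attains the published real-data
accuracy. Note also an intrinsic ceiling of the block design: an in-block
zero is statistically exchangeable with a held-out in-block positive, so
the achievable holdout AUROC depends on the instance (fraction of in-block
zeros among sampled negatives); the documented benchmark instance
(generator seed 7) has ample headroom, but unlucky instances top out lower
for any model.

## Benchmark operating points

The synthetic-scale benchmarks (`gsem.experiments`) fit with `l2 = 10`,
`l1 = 0.1`, `γ = 10⁴`, graph weight 1.0, `tol = 1e-2`, `max_iter = 3000`
— moderate elastic-net strength for a 60 × 50 matrix (the published values
target a 505 × 904 matrix) with enough iteration headroom for the slowly
decaying near-zero entries. The holdout-recovery benchmark hides 10 % of
positives, samples two negatives per hidden positive, and compares against
the degree-product baseline `rowsum_i × colsum_j`. The integration
benchmark uses 20 repetitions of 40 × 30 instances whose postmarket
associations occupy each drug cluster's "next" side-effect cluster
(density 0.5), a chemical graph at 0.3 within / 0.05 across clusters, and
two planted 0.9-similarity analogs that exercise the 0.6 leakage filter.

Problem sizes in the test suite and acceptance script (8 × 6 instances for
the projected-gradient and KKT oracles, 10⁵ oracle steps, 60 × 50 recovery,
20 integration repetitions) were chosen so the whole suite completes in
well under a minute of numerical work while still exercising every
guarantee at full tolerance.

## Numerical choices and limitations

* Convergence metric: max relative per-element change, applied to `W` and
  `H` separately.
* Tie-breaks: explanation terms sort by descending contribution, then
  identifier order; metric ties use mid-ranks.
* Degenerate inputs: all-zero matrices (RRF), normalizer-zero hierarchies,
  and leak filters that remove every neighbour raise typed degenerate-input
  errors rather than returning NaN.
* Graph files list each undirected edge once; a file carrying both
  directions with different weights is rejected, while the in-memory
  builder symmetrizes duplicate directions by maximum.
* Long-format association files cannot encode identifier order by
  themselves; writers therefore emit `#drugs=`/`#side_effects=`
  (`#entities=` for graphs) header directives that the readers honor,
  making write→read round trips exact.
* No incremental update path exists for adding a single new compound row;
  refitting is required. GPU execution and the competitor models from the
  side-effect prediction literature (MF, PPN, IMC, FGRMF) are out of scope.
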