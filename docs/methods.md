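# Methods

## Model

`epiforest` fits a classification random forest to an `nS × nV` matrix of
ordinal genotypes (0/1/2 = alternate-allele count of a bi-allelic variant)
and a categorical phenotype (binary case/control by default; multi-class is
supported).  Trees are binary.  A candidate split on variant *v* is a
threshold over the ordinal domain — `g ≤ 0` or `g ≤ 1` for three levels —
and is scored by the Gini gain

    gain = imp(parent) − (nL/n)·imp(L) − (nR/n)·imp(R),   imp = 1 − Σ_c p_c²

Splits must leave both children non-empty and have strictly positive gain.
Each tree is grown on a bootstrap sample of size `nS` drawn with
replacement; at each node `mTry` candidate variants are drawn globally
without replacement.  A node becomes a leaf when it is pure, when it holds
fewer than `minNS` samples, when it sits at depth `maxD` (root = depth 0),
or when no candidate yields positive gain; the leaf class is the majority
(ties to the lowest class index).

**Importance.**  The score of variant *v* is the node-size-weighted Gini
gain accumulated wherever *v* is the best split, divided by the number of
trees: `(1/nTree) Σ (n_node/nS)·gain`.  Because the gain at a node is
conditional on every split above it, the score absorbs interaction signal
that marginal tests cannot see.  An unweighted variant (plain `Σ gain /
nTree`) is available via `importance(mode="unweighted")`; the weighted form
is the default because it discounts the deep, small nodes where variants
gain information by chance.  Variants never selected score exactly 0.

**OOB error.**  Each sample is predicted by majority vote over the trees
whose bootstrap excluded it (ties to the lowest class index); the error is
the misclassification rate over samples with at least one out-of-bag vote.

**Cost model.**  Evaluating one candidate at one node is a single pass over
the node's samples, so training cost is `nTree × nNode × mTry × nS` with
`nNode` the average number of split nodes per tree (`op_count`), and
projected wall time for a forest is `β + nTree·θ` with `β` the data-load
time and `θ` the per-tree training time (`expected_runtime`).

## Vertical partitioning and determinism

The variant axis is tiled into contiguous, near-equal column blocks
(`partition`); genotypes are stored Fortran-ordered so a variant's column is
a contiguous, allocation-free view.  At each node the sampled candidates are
routed to their owning blocks; each block computes one local best split from
its own columns only (`best_split`), and the master takes the global argmax
(`aggregate_local_bests`).  This mirrors a distributed layout in which
workers hold disjoint column sets and communicate only one candidate per
node, rather than per-sample summaries.

Determinism is enforced by two rules:

* **Total-order tie-break.**  Candidates are ordered by (gain descending,
  variant index ascending, threshold ascending).  Gains are computed from a
  candidate's own column and the node labels only, so their floating-point
  values are bit-identical no matter which block computed them, and exact
  float comparison is safe.
* **Counter-based RNG streams.**  The bootstrap stream of tree *i* is seeded
  by `SeedSequence(seed, spawn_key=(0, i))`; the candidate stream of node
  *j* of tree *i* by `SeedSequence(seed, spawn_key=(1, i, j))`, with node
  ids assigned in pre-order.  No stream depends on blocking, batching, or
  scheduling.

Consequently the fitted model (trees, importance, OOB) is bit-identical for
any `n_blocks`, any batch size `rbs`, and any worker count; this is asserted
by test, and `ForestResults.to_json` excludes execution provenance so
exports compare equal across run configurations.

## Parameters

| name | meaning | default | rationale |
|---|---|---|---|
| `n_tree` | trees in the forest | 1000 | standard benchmarking forest size for this workload |
| `m_try` | candidates per node | `round(√nV)` | classic rule of thumb; pass a fraction (e.g. `0.1`) of `nV` for genome-scale association, which markedly improves accuracy |
| `max_depth` | depth limit (root 0) | unlimited | limits are dataset tuning, not a universal default |
| `min_node_size` | smallest node processed | unlimited | same |
| `batch_size` (`rbs`) | trees per parallel batch | 100 | throughput only; result-invariant |
| `seed` | master RNG seed | 0 | all streams derive from it |

## Simulators

`gen_features(nS, nV, maf_range, seed)` draws a per-variant allele frequency
uniformly from `maf_range` (default 0.05–0.5, a realistic common-variant
spectrum) and genotypes Binomial(2, f) independently across variants and
samples — Hardy-Weinberg, no linkage disequilibrium, no relatedness, no
population structure.

`gen_label` (additive design): `k_causal` causal variants (default 5, all
weights 1.0) and `round(gvf·nV)` noise variants (default `gvf = 100/nV`,
i.e. 100 noise variants) are drawn without replacement; each noise variant
gets one weight from N(`gm`, `gs`) (defaults 0.5, 0.5) — drawn once per
variant, not per sample, so noise variants are genuine weak confounders.
The liability is the weighted genotype sum; only causal variants enter the
truth set.

`gen_epistatic_label` (polygenic-epistatic design): disjoint member sets are
sampled for the requested number of *n*-way truth-variables (n = 1..5 in the
standard designs); the value of a variable is the parity (XOR) of its
members' dominance indicators `[g ≥ 1]`, and the liability is the weighted
variable sum plus N(0, `noise_sd`) (default 0.5, chosen to keep the
liability continuous without drowning unit-weight variables).  With carrier
probability ½ (allele frequency `1 − √½ ≈ 0.293`), the parity of an n ≥ 2
set is marginally independent of every member — the defining property that
makes these phenotypes invisible to single-variant tests.  The parity
functional form is this package's reconstruction of an interaction
penetrance model; it is the simplest mechanism that guarantees exact
marginal nullity.

**Dichotomization.**  Labels are 1 iff liability ≥ median.  When the
liability is discrete the inclusive rule can be degenerate, so the strict
rule (`>` median) is used whenever it is strictly closer to a 50/50 split
(ties prefer `≥`).  Continuous liabilities are therefore exactly balanced;
discrete ones keep the natural indicator semantics.

What passing tests on these simulators do **not** show: behaviour under
linkage disequilibrium (where γ-style proxy detection matters most),
population stratification, genotyping error/missingness patterns, rare
variants, or quantitative phenotypes.

## Baseline

The marginal baseline fits, per variant, a logistic regression of the label
on `[1, covariates, genotype]` by Newton-Raphson (≤ 25 iterations,
convergence when the max coefficient change < 1e-8) and reports the Wald
p-value of the genotype coefficient.  Covariates default to the top-2
principal components of the column-standardised genotype matrix (constant
columns dropped; component signs fixed by making the largest-magnitude
loading positive).  Fits that diverge (complete or quasi-complete
separation, singular information) yield a missing p-value and rank last.
Agreement with an independent maximum-likelihood implementation is verified
in the tests.

## Evaluation metrics

With `t` truth-variants, recovery at `r = m·t` (m ∈ {1, 2, 5, 10}) is the
fraction of truth-variants among the top `r` ranked variants, order ignored.
γ of a truth-variant is the maximum |Pearson correlation| between its
genotype column and any of the top `10t` ranked variants (the column is
taken from the full matrix even if the variant was excluded from the
analysis; constant columns give 0).  A truth-variant is *exclusively
detected* by method A when `γ_A > 0.75` and `γ_B < 0.5`.

## Numerical and design choices

* Ordinal splits are binary thresholds (not one-vs-rest subsets): standard
  for ordered features and required for binary trees.
* Missing VCF genotypes encode as 0 (reference) by default; per-variant
  modal imputation is available (`missing_policy="mode"`).  Multi-allelic
  records are rejected rather than auto-split — decompose upstream.
* `m_try` accepts an absolute count or a fraction of `nV`; unset resolves to
  `round(√nV)`.
* The per-node genotype-by-class counting kernel is compiled with numba;
  all gains are derived from integer contingency counts, which is what makes
  bitwise reproducibility across blockings possible.
* Degenerate inputs: single-class labels are accepted at load and rejected
  at training; an all-in-bag forest (bootstrap disabled) has undefined OOB
  and raises.

## Problem sizes used in the checks

The behavioural test suite runs at desk scale: split-search exactness on
≤ 12-sample matrices against exhaustive enumeration; invariance at nS = 500,
nV = 2000, 50 trees; planted-signal recovery at nS = nV = 2000 with 500
trees, `mTry = 0.1·nV`, `maxD = 15`, `minNS = 50` (additive: five 1-way
variables; epistatic: five 2-way parity pairs, 10 replicate seeds against
the Wald baseline with 2 PCs); OOB calibration under label permutation at
nS = 1000 and a 100 → 1600-tree comparison at nS = 400.

## Known limitations

* Detection of pure 2-way parity interactions at these scales is thin: a
  pair member is only elevated when its partner is chosen (by chance) as a
  split and the member is then drawn among the `mTry` candidates below —
  roughly `(1/mTry)·(mTry/nV)·nNode·nTree` opportunities per forest, only a
  handful at nS = nV = 2000 with 500 trees.  Recovery of such pairs is
  therefore highly seed-dependent, for this engine and for reference
  implementations alike; larger forests raise the event count linearly.
* The engine holds the full matrix in one process; the vertical-partitioning
  contract is honoured semantically (block-local evaluation, one candidate
  communicated per node) but no multi-host networking is implemented.
* No regression forests, permutation importance, probability calibration,
  or dosage genotypes.
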