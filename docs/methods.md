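# Methods

## Problem setting

Drug–drug interaction (DDI) prediction is treated as binary link prediction
on a symmetric graph: drugs are nodes, a recorded interaction is an edge,
and every unrecorded pair is treated as a negative. The retrospective
setting splits drugs by "era": a training network over known drugs, and test
pairs involving new drugs that have no training edges at all. Test pairs are
partitioned into *known-new* (one endpoint trained on), *new-new* (neither)
and *known-known* (both), with "all" the union — the cold-start subsets are
the ones the method exists for.

## Factorization model

The adjacency matrix is modelled as
`ŷ(i,j) = σ(μ + bᵢ + bⱼ + pᵢ·pⱼ)` with a **single** factor matrix: the row
and column embeddings are identified, which makes the raw score symmetric by
construction (the alternative, two factor matrices tied only by the loss, is
implementable behind the same interface but is not what a symmetric relation
calls for). μ is fixed to the adjacency density — the natural base rate for
a near-empty matrix — and is not trained; biases and factors are.

Training minimizes the mean binary cross-entropy over all off-diagonal
pairs (optionally a seeded negative sample at a configurable
positive:negative ratio) plus an L2 penalty, using full-batch Adam on the
closed-form gradient. At the few-hundred-drug scale this package targets,
the full n×n gradient is a handful of dense matrix products per epoch and
runs in milliseconds, so no minibatching or autodiff framework is involved;
the optimization is deterministic given the config seed (one named
generator, no global state). Initialization: factors ~ Normal(0, 0.1/√k),
biases 0.

Defaults: k = 64, α = 0.3, learning rate 0.01, 100 epochs, L2 = 1e-5, all
exposed in `TrainConfig`. The studies in this repository use k = 32,
learning rate 0.05 and 300 epochs (set in `benchmark.py`): the synthetic
graphs are small enough that a larger step and longer schedule converge
fully in about a second.

### Latent-factor propagation

One Jacobi-style pass, `pᵢ ← (1−α)·pᵢ + α·mean_{j∈N(i)} pⱼ`, computed
simultaneously from a frozen copy of the factors. Design points:

* α = 0 returns the factors bit-for-bit (no arithmetic is applied), so the
  propagated and plain models are exactly equivalent there — asserted
  exactly, not to a tolerance.
* Degree-0 drugs keep their factor: the mean over an empty neighbourhood is
  undefined and identity is the only non-arbitrary completion.
* The step is applied once, not iterated to a diffusion fixed point — the
  model calls for one sharing step between a drug and its direct partners.
* Float grouping in the scorer is symmetric (`μ + (bᵢ + bⱼ) + pᵢ·pⱼ`) so
  `score(i,j) == score(j,i)` holds exactly, not just to round-off.

## Similarity measures

* **Tanimoto** on 2048-bit Morgan fingerprints. The radius is 2
  (ECFP4-equivalent, the community default), exposed as a module constant.
  Fingerprinting is the only operation that parses SMILES; the string
  measures act on the raw text, so non-canonical SMILES are accepted
  everywhere and an unparseable SMILES fails loudly only when the
  fingerprint path is actually used. Two all-zero fingerprints score 0
  rather than NaN (no substructure evidence either way).
* **Edit similarity** `1 − lev(s,t)/max(|s|,|t|)`; the Levenshtein distance
  is computed by `edlib` and checked against a full-table DP oracle in the
  tests.
* **NLCS** `LCS(s,t)² / (|s|·|t|)` — the squared-LCS normalization is
  implemented as stated, not the more common `LCS/max(|s|,|t|)` variant.
  The two-row LCS DP is hand-rolled (no installed library provides it).
* **TF-cosine** on character-frequency vectors; clamped at 1.0 against
  float round-off; invariant to character order by construction.

Neighbour retrieval sorts all known drugs by similarity, descending, with
ascending drug id as the tie-break — determinism where the ordering would
otherwise be platform-dependent. The query's own id is excluded; if the
known set is smaller than m, everything available is returned and the
downstream averages run over what was returned.

## Lookup mechanism

Routing is by training-set membership. One-unseen pairs are normalized so
the unseen drug plays the lookup role (interactions are unordered, so the
swap is semantics-preserving). The one-new score is the similarity-weighted
mean of the neighbours' factorization scores against the known partner; the
two-new score pairs the two neighbour lists **rank-aligned** (index i with
index i, not all m×m combinations — the m×m variant exists behind
`pair_all_combinations` for experimentation, off by default) with
harmonic-mean weights `w = 2/(1/s_a + 1/s_b)`.

Degenerate cases, all of which surface in the tests:

* a zero-similarity neighbour is skipped — the harmonic mean's limit at
  zero is zero and such a neighbour carries no information;
* a neighbour pair that would require a drug's score against itself
  (identical entries at the same rank, or a one-new neighbour equal to the
  known partner) is skipped — the model defines no self-interaction;
* if every contribution is skipped the pair raises a `NoSupportError`
  rather than returning an arbitrary constant. Batch prediction collects
  these per pair instead of aborting.

The ensemble averages the final per-measure *predictions*, not the
similarities; a measure that reports no-support is dropped from the average
and the error propagates only if all measures fail. Because every lookup
score is a convex combination of factorization probabilities, all outputs
are guaranteed to lie in [0, 1].

## Evaluation harness

AUC is the normalized Mann–Whitney statistic (ties ½); AUPR is computed as
average precision (step interpolation), avoiding the optimism of
trapezoidal interpolation on PR curves. MRR and MAP@k rank, for each drug,
its candidate partners within the subset by score; each pair contributes to
both endpoints' lists. Drugs with no positive candidate are excluded from
the MRR/MAP means (their reciprocal rank is undefined; the report's notes
field records the convention and the counts make the denominator visible).
Confusion metrics use a 0.5 threshold by default, exposed as a flag. The
default MAP@k grid is {1, 5, 10, 50, 100, 500}. AUC/AUPR are delegated to
scikit-learn; the test suite checks both against exhaustive pair-counting /
enumeration oracles on hundreds of random instances.

## Synthetic data generator

The generator emulates the *shape* of a curated DDI resource, not its
content: a few hundred drugs, a sparse symmetric network (realized positive
density in the few-percent range under the defaults), and — the premise the
lookup rests on — a statistical coupling between chemical similarity and
shared interaction partners.

Mechanism: each of `n_families` families has a prototype molecule, a linear
heteroatom-chain SMILES over C/N/O (lengths 12–30), guaranteed parseable;
members are seeded point mutations of the prototype (per-character
substitution/insertion/deletion at `smiles_mutation_rate`, bounded retries
against unparseable output). Interactions are drawn from a symmetric
family-pair propensity matrix: `within_family_edge_prob` (default 0.6) on
the diagonal, off-diagonal propensities exponential with mean
`between_family_edge_mean` (default 0.03), clipped to [0, 1]. The
retrospective split marks a seeded `fraction_new` (default 0.2) of drugs as
new, moves *all* their incident pairs (positive and negative) to the test
set, and drops them from the training graph entirely.

The mutation dial doubles as the control condition: at rate 0.9 a member's
SMILES is essentially independent of its family. Per-character edits alone
would preserve the prototype's *length*, which by itself keeps family
members recognizable to the string measures, so mutation also redraws the
chain length from the global prototype-length distribution with probability
equal to the rate — at rate → 1 the molecule is fully decoupled from its
family, which is the dial's contract. With decoupling, nearest-neighbour
family-hit rates sit at chance and the lookup's advantage over the
chemistry-free baselines disappears.

What the generator does **not** emulate: real pharmacophores or ring/charge
chemistry (molecules are linear chains), DrugBank's heavy-tailed degree
distribution, biologics, interaction types or severities, and the
correlation structure of real similarity measures (on real drugs the four
measures are highly correlated; on synthetic chains they are too, but for
different reasons). Passing the mechanism tests therefore shows that the
pipeline exploits similarity-coupled interaction structure when it exists —
not that any particular AUC will be attained on a real database.

## Baselines

* **Random-embedding factorization**: the trained model extended with
  Normal(0, 0.1/√k) factors and zero biases for unseen drugs — what a
  factorization model does when forced to answer cold.
* **Popularity**: `deg(a) + deg(b)` in the training graph (0 for unseen
  drugs), normalized to [0, 1]. AUC only depends on the ranking, so the
  normalization is cosmetic.

## Study configuration

The standard cold-start study uses the generator defaults (200 drugs, 10
families, mutation 0.1, within 0.6, between-mean 0.03, 20% new — about
7,200 test pairs) with k = 32 / 300 epochs / lr 0.05 and the ensemble
lookup at m = 3; the decoupled condition differs only in mutation rate 0.9.
These sizes keep the full study under a few seconds while leaving the AUC
estimates stable to well under the 0.05–0.10 margins the mechanism checks
use. The acceptance script runs both conditions plus a rank-8,
100-drug parameter-recovery check and reports every number it computes.

## Known limitations

* Interaction types/severities and biologics are out of scope; the model is
  binary and small-molecule only.
* m×m neighbour pairing in the two-new case is implemented but unstudied.
* The MRR averaging convention (exclude drugs with no positive) is one of
  two defensible readings; the report carries enough counts to recompute
  under the other.
* α is a config value, not tuned; no hyperparameter search is provided.
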