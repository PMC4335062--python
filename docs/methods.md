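# Methods

## Scope and coordinate conventions

A `RegisteredCoil` is a sequence plus a per-residue heptad register that must
cycle `…f,g,a,b,c,d,e,f…` without gaps.  Two frames coexist:

* **a-frame** — heptad *i* spans `a_i…g_i`; all feature categories are
  indexed here (e.g. `g_i–e'_{i+1}`).  Heptad 1 starts at the first residue
  and the counter increments at every subsequent `a`.
* **f-frame (blocks)** — non-overlapping 7-residue windows in
  `(f,g,a,b,c,d,e)` order, anchored at the first `f`.  Blocks are the design
  building unit; block *k* holds `f_k, g_k` of a-frame heptad *k* and
  `a…e` of heptad *k+1*.

Residue indices are 0-based internally, heptad/block indices 1-based.  Two
coils in a dimer are aligned by a-frame heptad coordinates (heptad *i* faces
heptad *i*): registers are explicit inputs (FASTA + a sidecar TSV of phases),
not inferred, because register inference requires a family alignment that is
out of scope here.

## Feature encoding

Eight pair and ten triplet categories over the interface positions a, d, e,
g define the feature space (4·210 + 4·400 + 10·8000 = 82,440 combinations;
the symmetric pairs a·a′, d·d′, g·e′₊₁, e·g′ store residues in lexicographic
order, triplets are never symmetrized).  The encoder counts **physical
contacts**: each distinct set of residue sites instantiating a category is
counted once.  Consequences:

* a·a′ and d·d′ yield one contact per heptad (the two chain-role assignments
  name the same residue pair);
* g·e′₊₁ and e·g′ yield two per heptad in a heterodimer (A.g–B.e′ and
  B.g–A.e′ are distinct contacts under one unordered key);
* all asymmetric categories yield two per heptad (both chain roles), which
  coincide in residue content for homodimers — hence even counts there.

This is the unique convention that is simultaneously symmetric under chain
swap (`encode(A,B) == encode(B,A)` exactly) and consistent with one count
for an a·a′ contact.  A `single_role` switch restricts counting to the
(A unprimed, B primed) role for sensitivity analyses.  Cross-heptad contacts
are emitted only when every heptad index they touch exists in both chains,
so terminal heptads carry fewer categories (a single f-anchored block
instantiates 6 of 8 pair and 5 of 10 triplet categories).

## Curation

Three filters remove unreliable records before training:

1. **Asn mismatches** — records where an `a`-position Asn faces Val/Leu/Ile
   in any non-terminal aligned block are dropped (such pairs may not adopt
   the canonical register).  Terminal blocks are exempt.
2. **PSSM outliers** — positional scores
   `s_pos(aa) = −log(p_pos(aa)/p(aa))` are estimated from all a/d/e/g
   residues with add-one smoothing; each protein is scored by the
   length-normalized mean over its core residues (a raw-sum mode exists),
   and the top 10 % of proteins (ceil, ties broken by id) are removed with
   all their records.  Being a quantile rule, this filter is deliberately
   applied once; the rule-based filters are idempotent.
3. **Variant conflicts** — records whose two coiled-coil regions are
   sequence-identical but whose K_d values disagree are contradictory and
   all removed; agreeing duplicates collapse to one.

Class labels: binders are K_d < 5,000 nM (the censoring ceiling); the ROC
contrast is strong (< 250 nM) vs weak/non (≥ 5,000 nM) with intermediates
excluded; fold stratification uses < 50 / 50–5,000 / ≥ 5,000 nM bins.

## SemiSVR

Training minimizes `|w|² + C₁Σξ¹ + C₂Σξ²` under `|E_k − y_k| ≤ ε + ξ¹_k`
(binders) and `E_k ≥ E_cutoff − ξ²_k` (censored records), ξ ≥ 0.  The
non-binder constraint is stated with a *relaxing* slack (−ξ²); the
alternative sign would make the slack tighten the constraint, contradicting
its role.  `E_cutoff` defaults to log₁₀(5000) ≈ 3.699, the ceiling on the
working scale.  There is no intercept by default (the score is a pure
feature sum).

The solver maximizes the dual — one multiplier per record,
θ ∈ [−C₁, C₁] for binders and [0, C₂] for non-binders, with
`w = Xᵀθ/2` — by exact coordinate updates (soft-threshold for binder
coordinates, clipped Newton step for censored ones) in seeded random order.
Iteration stops when the primal–dual gap certifies the objective to `tol`
(default 1e-9 relative); a residual gap above 5 % raises an error rather
than returning silently bad weights.  Typical problems (10³ records, 10³–10⁴
sparse features) converge in well under 10³ epochs; small dense problems at
large C can need 10⁴–10⁵ cheap epochs, hence the generous default
`max_iter=50_000`.  Tests verify the objective against an independent
generic QP solve (trust-constr on the explicit slack formulation with exact
Hessian) to 1e-6 relative.

Hyperparameters (C₁, C₂, ε) are chosen by exhaustive grid search under
cross-validation; the selection key is pooled Pearson R on binders, ties
broken by AUC, then by smaller C₁+C₂.  Default grids bracket the
interpolation and strong-regularization regimes (C ∈ 10⁻²…10³, ε ∈
{0, 0.1, 0.2, 0.4}).  Recursive feature elimination ranks features by |w|,
drops the lowest ceil(5 %) per round, refits, and returns the subset with
the best validation R on binders.

## Validation protocol

Records are partitioned into K balanced, minimally-inter-similar folds:
a record-similarity graph (edge weight = 1 − Jaccard distance between
feature supports, sparsified to 20 nearest neighbours, computed by sparse
matrix products) is first cut by placing whole connected components into
folds under per-stratum capacities (fold sizes within one record per
stratum), then polished by same-stratum swaps that reduce cut weight.  No
external graph partitioner is required; all steps are deterministic given
the seed.

Nested cross-validation holds out each fold, re-partitions the remainder for
the inner grid search, trains with the selected hyperparameters, and pools
held-out predictions; a record never influences the model that scores it.
Pearson R is computed on binders with 1 < K_d < 5,000 nM, AUC by the
Mann–Whitney statistic with tie correction (lower score = strong class).
Supporting procedures: percentile bootstrap CI over prediction–truth pairs,
a permutation control (K_d values reshuffled jointly before the full nested
CV — a sound protocol must return R ≈ 0, AUC ≈ 0.5), stratified learning
curves, and an identity-constrained train/test split (single-linkage
clustering of proteins at a core-identity threshold over a/d/e/g positions;
whole clusters assigned to one side; bridging records dropped).

## Design

The heptad library contains unique f-anchored 7-mers from registered source
coils; first blocks are flagged N-terminal and restricted to the design's
first position.  An optional prefilter keeps heptads whose **a** residue is
in {L,N,V,I,K,A,R,T} and **d** in {L,H,V,M,I} (the sets covering 85 % of
native occurrences; with e/g ∈ {E,K,R,Q,L} these define a
8×5×5×5 = 1,000-combination core basis).

Because the score is linear, the dimer score of an assembled design against
a fixed partner splits exactly into per-block terms `s_i^j` (contacts whose
*design-chain* residues all fall in block i when heptad j occupies it) and
junction corrections `c_{i,i+1}^{j,k}` (contacts whose design residues span
blocks i and i+1).  Only the design chain's residues decide the split — a
cross-heptad pair such as d_i–a′_{i+1} contributes a single design residue
and therefore stays in `s`; junction terms arise from triplets that place
two same-chain residues in adjacent blocks.  Exactness
(Σs + Σc = full re-encoded score to 1e-9) is enforced by test and by the
post-hoc verifier.

The ILP minimizes the target score over binary placement variables `x_i^j`
(Σ_j x_i^j = 1) with adjacency indicators `z_{i,i+1}^{j,k}` linked by
Σ_j z = x_{i+1}^k and Σ_k z = x_i^j; z variables are created only for
junctions admissible by the rule that the three intra-chain cross-junction
residue pairs (e–f, d–g, e–a) each occur in at least one native coil, and
they relax to continuous because their transportation structure is integral
whenever x is.  Off-target constraints come in a relative mode
(S_off ≥ S_target + Δ, default Δ = 2.0 log units ≈ 100-fold K_d margin) and
an absolute-cutoff mode.  Composition rules are linear rows or variable
fixings: His at **d** only in the last block, Glu at **a** only in the
first, ≤ 1 Met at **d**, ≤ 4 polar residues (N,K,R,E,T,A) at **a**, Asn at
**a** only in non-terminal blocks, N-terminal-flagged heptads only at block
1, and per-block vetoes of heptads whose a/d residue forms a core pair with
the target that is either destabilizing by a user-supplied coupling-energy
table (> 1 kcal/mol; that table is external literature data and not
bundled) or seen fewer than twice among strong binders in the training
data.  The branch-and-bound backend is HiGHS via `scipy.optimize.milp`; the
solver returns the proven optimum or the best incumbent with its gap, and
`verify_solution` re-encodes the assembled sequence from scratch and
re-checks scores, margins and composition.

Off-targets longer than the design are scored over the M-block window
anchored at their first full block; a family filter drops off-targets whose
a/d/e/g identity to the target exceeds 60 % (paralogs are near-impossible to
avoid and are excluded from the constraint set).

Design scores are predicted log₁₀(K_d/nM), lower = tighter, throughout.
Published per-design score anecdotes in this problem area sometimes print
higher-score-=-tighter values; this package fixes the log₁₀ K_d convention
and reports margins as S_off − S_target > 0.

## Synthetic data generator

The generator provides everything needed to exercise the pipeline offline.
It emulates: iid registered sequences over the position alphabets above
(with a configurable 5 % default chance of an off-alphabet residue at
a/d/e/g, approximating curated survey data; 15 % reproduces the raw native
occupancy), an all-vs-all measurement design (every homodimer plus a
configurable fraction of heterodimers — all, by default), a sparse planted
weight vector, Gaussian noise (SD 0.2) on log₁₀ K_d applied before
censoring, right-censoring at 5,000 nM, and a 20 % binder fraction achieved
by shifting the score offset (the shift is recorded on the returned model's
intercept).

The planted model always contains the family's hallmark specificity element
(favorable Asn–Asn and destabilizing Asn–{L,V,I} a·a′ pairs) plus 16 further
keys, 90 % drawn from pair categories over the frequent alphabets and 10 %
from triplets, with weight SD 0.5.  The pair-heavy support reflects the
established structure of coiled-coil specificity — classic coupling-energy
models with a few dozen pairwise terms already rank these interactions well,
and triplets are a modest correction — and it is also what makes the
planted signal identifiable: with iid sequences, triplet keys are
near-singletons across records, and weight placed on them is unlearnable in
principle.

What the generator does *not* emulate: phylogenetic relatedness between
proteins (real surveys contain families of similar sequences, which both
concentrates feature usage and makes the similarity-aware partition
markedly harder), length variation and register uncertainty, and
measurement artifacts beyond homoscedastic log-scale noise.  Passing tests
on synthetic data therefore demonstrate that the machinery is correct and
that the censored-training pipeline recovers plantable signal — not that
any particular accuracy level transfers to real measurements.

Under the default conditions (60 proteins, noise SD 0.2, ~80 % censored),
the full pipeline (simulate → curate → encode → nested CV) reaches held-out
R ≈ 0.75 and AUC ≈ 0.99 at the best settings, against a true-model ceiling
of R ≈ 0.98 on the same splits; the residual gap is estimation error from
record-private features.  The end-to-end regression test asserts R ≥ 0.55
and AUC ≥ 0.93 at its fixed seed and scaled protocol (5 outer folds,
3-point C₁ grid), leaving headroom for the measured seed-to-seed spread.
The permutation control on the same machinery returns R ≈ 0, AUC ≈ 0.5, and
training with censored records included yields strictly better strong-vs-
weak AUC than binders-only training in ≥ 4 of 5 seeds.

## Reference dataset layout

Full-data checks expect, under `data/`:

* `bzip_curated_interactions.csv` — columns `idA,idB,kd_nM`, one row per
  unordered pair (reciprocal duplicates collapse to the lower K_d at load);
* `bzip_curated_sequences.fasta` — the registered coiled-coil sequences;
* `bzip_curated_registers.tsv` — columns `id`, `phase` (heptad label of the
  first residue), optional `species`, `parent`.

With those files present, the loader should yield 4,549 records (948
binders, 699 strong binders), 1,930 observed pair features and 17,239
observed triplet features (513 under the aa′/dd′/ge′ restriction); these
counts pin the encoding conventions.  The exclusion counts of the original
curation (120 Asn-mismatch records, 22 PSSM outliers with 555 records, 56
variant conflicts) depend on the pre-curation release and are logged, not
asserted.

## Numerical choices and degenerate inputs

* Duplicate unordered pairs collapse to the minimum K_d (reciprocal
  fluorescence measurements label donor/acceptor arbitrarily).
* K_d values above the ceiling clamp to it and become censored; non-positive
  K_d is a hard error; the generator floors K_d at 10⁻³ nM.
* Jaccard distance of two empty supports is 0.
* PSSM probabilities use add-one smoothing, so no log(0) on small sets.
* Ties in the PSSM cut, RFE ranking (stable sort) and grid search
  (AUC, then smaller C₁+C₂) are broken deterministically.
* Every stochastic step (partitioning, nested CV, bootstrap, permutation,
  generator) takes an explicit integer seed and is reproducible from it.

## Known limitations

Only parallel dimers are scored; anti-parallel alignments, higher-order
oligomers, b/c/f-position energetics, DNA-binding context, and solubility or
aggregation constraints are out of scope.  The additive model assigns one
weight per residue combination independent of structural context, so
contributions of rarely observed combinations are poorly determined — the
motivation for restricting designs to native heptads and frequent core
residues.
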