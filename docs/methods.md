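# Methods

## The undated DTL model

`dtlrec` models the evolution of a gene family along a rooted binary
species tree by a birth–death process with four events: speciation (S),
duplication (D), lateral transfer (T) and loss (L).  The species tree is
*undated*: its internal nodes carry no time order, so nothing constrains
which lineages may exchange genes.  Time therefore drops out of the model
entirely; the speciation rate is normalized to 1 and the duplication,
transfer and loss rates (δ, τ, λ) are relative rates, entering only
through per-branch event probabilities

```
p_S = 1/(1+δ+τ+λ),  p_D = δ/(1+δ+τ+λ),  p_T = τ/(1+δ+τ+λ),  p_L = λ/(1+δ+τ+λ).
```

Only relative rates are identifiable, which is also all the downstream
statistics use (T/(T+D), L/(T+D+L)).

Every node of the species tree owns one *branch* — the edge above it —
including the root, whose branch is the "root stem".  A tree with n leaves
has N = 2n−1 branches.  Originations are uniform over branches with prior
1/N, and a transfer lands on a branch drawn uniformly among all N,
including the donor itself (a self-transfer is indistinguishable from a
duplication and contributes O(1/N); keeping it makes the normalizers
trivially uniform, and the forward simulator uses the identical
convention, so likelihood and simulation agree exactly rather than
approximately).

A lineage entering branch e draws one event: S sends one copy into each
child branch (at a species-tree leaf, S is the sampling/observation
event); D puts two copies back onto e; T puts one copy back onto e and one
onto the drawn recipient branch; L terminates the lineage.

## Extinction

E(e), the probability that a lineage entering e leaves no sampled
descendant, solves

```
E(e) = p_L + p_D E(e)² + p_T E(e) Ē + p_S E(f) E(g)
```

with the speciation term dropped on leaf branches and Ē the mean of E over
branches.  It is found by fixed-point iteration from E ≡ 0 (tolerance
1e−12 on the sup-norm residual, cap 10 000 iterations; convergence is
monotone).  Closed-form anchors used in tests: on a single-leaf tree,
δ=τ=0, λ=1 gives E = 1/2 exactly, and δ=λ=1, τ=0 gives E = (3−√5)/2.

## Amalgamation: conditional clade probabilities

A posterior-like sample of topologies for one family is condensed into
clade counts n(γ) and conditional split probabilities q(γ₁,γ₂|γ).  Clades
are bitsets over the family's genes ordered by name, making clade
identities reproducible.  In the default *unrooted* mode each directed
edge of each (unrooted) topology contributes one observation of the clade
on its far side together with its induced split, and each undirected edge
contributes one candidate root split of the full gene set Γ; the DP then
effectively sums over all 2k−3 root positions.  A *rooted* mode (one
observation per node) serves simulator output and single-tree reductions.
No pseudo-counts are added: only observed clades and splits can appear in
reconciliations, which is exactly what makes the dynamic program
tractable while still covering a super-exponential set of amalgamated
trees.

## The likelihood dynamic program

π(γ,e) is the probability that a single lineage entering branch e gives
rise to exactly the observed genes of clade γ.  For each clade, in
ascending size, and each branch e (children f, g):

```
π(γ,e) = Σ_splits q(γ₁,γ₂|γ) [ p_S (π(γ₁,f)π(γ₂,g) + π(γ₁,g)π(γ₂,f))
                             + 2 p_D π(γ₁,e) π(γ₂,e)
                             + p_T (π̄(γ₁) π(γ₂,e) + π̄(γ₂) π(γ₁,e)) ]
       + [γ singleton of species s, e = leaf(s)] p_S
       + p_S (π(γ,f) E(g) + π(γ,g) E(f))          (speciation–loss)
       + 2 p_D π(γ,e) E(e)                         (duplication, one copy extinct)
       + p_T (π̄(γ) E(e) + Ē π(γ,e))               (transfer, one copy extinct)
```

where π̄ is the mean over branches.  All pair terms follow the *ordered*
convention — the two daughter copies of any birth event are
distinguishable, because their fates are independent draws in the
generative process.  This includes the visible duplication term (factor
2).  Under this convention the likelihood is exactly generatively
consistent: for a class c of observable outcomes (a pruned
species-labelled tree shape),

```
P(c) = (Π_s n_s!)⁻¹ · Σ_{labeled trees t ∈ c} exp(loglik(t)),
```

an identity the test suite verifies against 10⁶ forward draws per
configuration on 1–3-leaf trees.  An unordered visible-duplication term
(no factor 2) breaks this identity in both directions (multi-copy
same-species outcomes overshoot through the transfer term, class-distinct
duplication outcomes undershoot), so the ordered form is used throughout —
likelihood, fixed-tree route, and sampler.

The last three (feedback) terms couple π(γ,·) across branches.  They are
*linear* in π(γ,·) and their operator M does not depend on γ, so instead
of iterating, (I−M) is LU-factorized once per rate vector and each clade
is solved exactly with one back-substitution.  The independent fixed-tree
route `gene_tree_loglik` deliberately retains the naive per-node
fixed-point iteration (tolerance 1e−10, cap 100 by default) so the two
routes share no numerical machinery; they agree to machine precision on
random fixtures.

Underflow is handled by per-clade rescaling: each π(γ,·) is stored with
its largest entry O(1) plus an accumulated log scale; split terms combine
child scales explicitly.  The family likelihood is (1/N) Σ_e π(Γ,e) with
Γ's "splits" given by the root-split distribution in unrooted mode.

Conditioning: by default none.  With `conditioning="survival"` the
likelihood is divided by 1−Ē, the probability that a family originating
uniformly survives to be observed.  The parameter-recovery experiments
keep single-gene families in the data and condition on survival, making
the sampling scheme and the likelihood consistent; without conditioning,
fitting only surviving families biases λ̂ downward by roughly a third at
the simulated rates.

## Rate estimation

Nelder–Mead on (log δ, log τ, log λ) with box bounds [1e−6, 10] per rate,
default start (0.1, 0.1, 0.1); DL mode fixes τ=0 and optimizes the
remaining two.  The likelihood surface is smooth and unimodal in the
regimes exercised here; optimization is deterministic given the start
point.  Both global (one rate vector for all families, the default) and
per-family scopes are exposed.

## Reconciliation sampling and event accounting

Reconciliations are drawn by stochastic backtracking: the origination
branch ∝ π(Γ,e), then at each DP cell one term — split × event type ×
transfer recipient — is drawn proportional to its contribution to π(γ,e).
Transfer recipients are drawn ∝ π(clade, ·) over all branches.  DP terms
in which a freshly born copy goes immediately extinct are traversed
silently: they leave no observable trace and the event vocabulary
deliberately excludes them.

Event kinds: O (origination), S, SL (speciation with one extinct
daughter), D, T, TL (transfer with donor-copy loss), C (leaf sampling).
Losses are charged to the branch where the lineage died: the lost child
for SL, the donor for TL.  Per-branch copy numbers count lineages alive
when the end of the branch is reached — one per S, SL or C event on the
branch — which anchors leaf-branch totals exactly at the observed numbers
of genes per species.  "Gains" on a branch are incoming transfers plus
originations.  The default is 100 sampled reconciliations per family;
per-branch and per-branch-pair counts are means over samples and sums over
families.

A replacement transfer is an incoming transfer whose family also records a
loss on the same recipient branch *within the same sampled
reconciliation* (the within-sample pairing is a documented choice; the
alternative — pairing across sample means — is not implemented).  The
statistic reported is the median over branches with any incoming transfer.

## Forward simulator

`simulate_family` implements the generative process exactly as the
likelihood assumes it (same normalization, same uniform recipient set
including the donor) and is the package's oracle: DP values are compared
with simulated outcome frequencies, survival frequencies with 1−Ē, and
sampled root-branch frequencies with π(Γ,·).  Posterior-like tree-sample
noise is emulated by independent NNI rearrangements of the true topology
(`perturb_tree_sample`, probability per unrooted-internal edge); this is a
desk-scale stand-in for MCMC samples — it produces topology uncertainty
concentrated around the truth but not the correlated, alignment-driven
error structure of real posterior samples, so tests passing on it say
nothing about alignment artefacts in real data.

`simulate_genomes` additionally evolves ordered circular single-chromosome
genomes (one gene per family at the root stem, random initial order):
duplications insert in tandem, losses delete, transferred blocks insert at
a uniform random position of the recipient genome, and with probability
`block_prob` a transfer co-transfers the donor gene's current right
neighbour (block size capped at 2 — sufficient to create an adjacency
signal without inventing an unmeasured block-size distribution).  Because
ordered genomes must be constructed top-down along the tree, transfer
recipients in *this* simulator are drawn uniformly among branches not yet
visited in a fixed pre-order sweep (plus the donor); this processing-order
restriction resembles a time-consistency constraint and is irrelevant to
the adjacency and synteny statistics the genome simulator feeds.  The
per-family oracle above keeps the exact unrestricted semantics.

## Downstream statistics

* **Event ratios** T/(T+D) and L/(T+D+L) from summed branch totals.
* **Rarefaction**: for each (subsample size, replicate), species are drawn
  uniformly without replacement, the species tree and families are pruned,
  CCPs rebuilt, rates re-optimized per subsample, reconciliations
  resampled; all seeds derive deterministically from the master seed.
* **Saturation extrapolation**: y(n) = a − (a−y0)·exp(−n/s) fit by
  Levenberg–Marquardt least squares (initialization a = max y, y0 = min y,
  s = median n; standard errors from the Jacobian).  The parameterization
  is the simplest curve that "starts at a zero-species value and saturates
  exponentially"; constant data degenerate to a = y0 exactly.
* **Highways**: branch pairs ranked by mean transfer count, ties broken by
  branch ids; ordered (donor→recipient) by default with an unordered
  pooling flag, since transfer direction between a branch pair can be
  ambiguous when the donor is near the root.
* **Tandem enrichment**: a gene is called transferred on its terminal
  branch when the majority (threshold 0.5, configurable) of
  reconciliation samples show its lineage arriving there by transfer.  Per
  genome, the fraction of transferred genes with a transferred circular
  neighbour is compared with a seeded permutation null (uniform
  replacement of the same number of labels, default 1000 permutations); an
  analytic hypergeometric null is computed alongside as a cross-check.
  The null model behind published enrichment folds is not uniquely
  determined by their description, so folds are treated as qualitative.
* **Synteny comparison**: for a species pair, families with exactly one
  gene in each species enter; a pair of orthologues is transferred when a
  majority of reconciliation samples place at least one transfer hop on
  the gene-tree path between them; synteny is conserved when a neighbour's
  family has its own orthologue adjacent to the partner gene.
* **Ancestral vs extant genome sizes**: rank-sum (Mann–Whitney) test,
  two-sided for the transfer-aware model (sizes should be exchangeable) and
  one-sided "greater" for the duplication–loss-only pathology.

## Problem sizes and numerical choices

The built-in experiments run at desk scale: 16-leaf trees with 100–500
families for rate recovery and coverage analyses, 8-leaf trees with
50–100 families for the model-comparison, highway and tandem experiments,
10⁶ forward draws per configuration for the generative-consistency grid,
and 10–25 sampled reconciliations per family inside replicated
experiments (100 where a single analysis is run).  Extinction tolerance
1e−12; optimizer tolerances xatol 1e−3 (log-rate units), fatol 1e−4
(log-likelihood), loosened to 1e−2 with an 80-iteration cap inside
replicated model-comparison loops where only the rate ballpark matters.
Ties in CCP serialization and highway ranking are broken by integer ids;
all stochastic steps take explicit seeds and identical seeds give
byte-identical outputs.

## Known limitations

* The undated model ignores chronology, so it can propose transfers
  between non-contemporaneous branches; this is intrinsic to the model
  class, not an implementation artefact.
* NNI-based tree-sample noise underrepresents the heavy-tailed error of
  real posterior samples.
* The genome simulator's pre-order recipient restriction means its
  per-family histories are not exchangeable with the unrestricted model;
  only adjacency/synteny statistics should be computed from it.
* Rate estimates are consistent only when the observation filter matches
  the conditioning (see above); fitting heavily filtered family sets
  without conditioning underestimates loss.
* Block transfers are capped at two genes; real co-transfer tracts can be
  longer.
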