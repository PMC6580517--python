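# Methods

## Ontology handling

GO namespaces (BP, CC, MF) are treated as disjoint rooted DAGs over `is_a`
edges only; other relations are ignored. Term **depth** is the length of the
shortest is-a path from the namespace root (`depth_mode="longest"` is
available), with roots at depth 0. Depth matters because the
interaction–function rule is instantiated per depth level, so the choice of
convention changes which terms fall in each `Domain_l`. Annotation tables are
kept closed under the true-path rule: positives propagate to all ancestors;
a negative term implies negative descendants. The missing-equals-negative
policy is applied when a table is constructed, not inside propagation, so
unknown atoms stay representable for transductive runs. Dataset assembly
supports a per-namespace depth cutoff and a minimum-support filter (terms
with fewer positives than a threshold are dropped); filtering never orphans
an annotation because ancestors of retained positives always survive both
filters, and this is asserted at run time.

## Kernels

Five sources, one Gram matrix each over the protein index:

| kernel | form | parameter |
|---|---|---|
| co-localization | `exp(−γ·distance)` within a chromosome, 0 across | `γ = 1` (1/bases) |
| complex diffusion | `exp(−β·L)`, `L = D − A` combinatorial Laplacian | `β = 1` |
| co-expression | raw inner product of expression vectors | — |
| domains | count of shared domain indicators | — |
| sequence spectrum | inner product of k-mer count vectors | `k = 3` |

The diffusion kernel follows the standard heat-kernel construction on the
combinatorial Laplacian; the normalized Laplacian is available as an option.
Expression vectors are used raw (no centering or scaling), matching the bare
inner-product form; a standardization flag exists but defaults off. The
sequence kernel is a plain k-mer spectrum kernel — a composition-level
similarity; profile/PSSM-based kernels require external alignment databases
and are instead supported through ingestion of any precomputed kernel matrix
from file.

Every kernel is cosine-normalized (`K̂ = K/√(K_ii K_jj)`) and preconditioned
by adding `1e-6` to the diagonal; sources are combined by unweighted
averaging. An entity with zero self-similarity (e.g. a protein with no
annotated domains) cannot be cosine-normalized; the library treats that as an
error by default, while the pipeline isolates such entities (unit
self-similarity, zero elsewhere). The pairwise kernel for interaction
prediction is the symmetrized two-product form, then normalized and
preconditioned the same way.

## Rules and their fuzzy relaxation

Rules are prenex universally-quantified implications over `Fun` and `Bound`
atoms, compiled to constraints: a propositional body plus an explicit list of
groundings. The degree of satisfaction `Φ` is the mean T-norm truth of the
body over groundings (vacuously 1 with no groundings), so crisp inputs
reproduce Boolean logic exactly. Łukasiewicz is the default T-norm: its
connectives are piecewise linear and 1-Lipschitz, which keeps the constraint
terms well-scaled subgradient-friendly penalties; the minimum (Gödel) T-norm
is selectable. Negation is the standard involution `1 − a` for both;
disjunction comes from De Morgan and implication from the residuum
(`min(1, 1−a+b)` for Łukasiewicz; `1 if a ≤ b else b` for Gödel). At
piecewise-linear kinks the subgradient averages the active branches, ties
included.

The converse readings of the hierarchy rules (a missing parent forbids the
child; a term with no positive child is suspect) are consequences of the
residuum semantics — the contrapositive needs no separate formula — but an
`explicit_converse` flag compiles them separately for study. The
interaction–function rule is grounded only over the supplied pair list
(observed plus sampled pairs), not all O(n²) pairs, and only for BP and CC at
the top levels (all three levels of the synthetic ontologies; top 5 by
default on deeper ontologies): molecular function is less driven by physical
binding, and the rule's cost grows with `|Domain_l| × |pairs|`.

Constraint weights `λ_h` default to 1 per family and are configurable per
family (`lambda_go`, `lambda_ppi`).

## Objective, losses and optimization

Stage 1 minimizes `Σ_k wᵀG w + λ_l Σ_labeled L(y, squash(Gw))` by
deterministic full-batch gradient descent with backtracking (Armijo) line
search from `w = 0`; the objective is non-increasing by construction and
training is bit-reproducible. The supervised loss is a plain sum over
labeled atoms; with the quadratic-on-margin loss the problem is exactly
kernel ridge regression and the fit is checked against the closed form.
Default loss is squared error on the squashed output; hinge-on-margin is
selectable. The squash mapping margins to [0,1] truth values is logistic by
default (a clipped-linear map is available). `λ_l` defaults to 10, chosen so
that the machines fit desk-scale training sets closely (training F1 ≈ 0.97 on
the reference genomes) without interpolating noise.

Full constrained training (`fit_full`) refines all weights by subgradient
descent on the complete objective, warm-started from stage 1; with all
constraint weights at zero it reproduces the stage-1 trajectory exactly, and
its analytic gradient is verified against central finite differences.

**Collective inference** optimizes the truth values directly: minimize

    C_coll(x) = (1/|free|) Σ_free (x_i − prior_i)² + Σ_h λ_h (1 − Φ_h(x))

by projected gradient descent in [0,1], starting at — and anchored to — the
stage-1 predictions, with labeled atoms clamped. The prior term is the *mean*
squared deviation over free atoms. This normalization is deliberate: `Φ_h`
averages over its groundings, so a per-grounding violation carries weight
`λ_h/|groundings|`; anchoring with an unnormalized sum would let a handful of
priors overpower any constraint at realistic sizes, while the per-atom mean
keeps the two terms on comparable scales for any problem size and makes `λ_h`
meaningful across genomes. With no active constraints the output equals the
prior exactly.

Interaction atoms are clamped to their stage-1 values during collective
inference by default (`clamp_bound=True`): interaction prediction is the
easier task and should inform function prediction, not be perturbed by it.
A flag unfreezes them.

## Evaluation

CAFA protein-centric measures: precision averages over proteins with at
least one prediction at threshold τ; recall averages over proteins with a
nonempty truth set (proteins with no true annotations in a namespace are
excluded from that namespace's averages). Fmax maximizes F1 over a grid of
101 evenly spaced thresholds plus all distinct scores when there are at most
1000. Smin is `min_τ sqrt(ru² + mi²)` with information-content weights; a
`printed_minus` flag computes the `ru² − mi²` variant (clipped at zero under
the radical) for comparison. Information content is conditional
(information-accretion style): `ic(f) = −log₂(n_f / n_parents(f))`, where the
denominator counts proteins positive for all parents; roots get 0; a marginal
`−log₂` frequency variant is selectable. Term-centric AUC is the rank-based
Mann–Whitney statistic with half credit for ties. All metrics can be
restricted per namespace and per depth; terms absent from the filtered
ontology or the score matrix contribute to no metric.

## Synthetic genomes

The generator emulates the statistical structure the model assumes, at desk
scale. Each protein has a latent vector `z ~ N(0, I_d)` (`d = 8`).
Ontologies are per-namespace trees of configurable depth (default 3 levels,
branching 2, all three namespaces) with a 0.2 chance of an extra same-level
parent, making them proper DAGs. Term membership is drawn top-down: a child
term keeps the highest-scoring fraction (`sparsity`, default 0.6/0.5/0.4 per
level) of the proteins positive for all its parents, ranked by a noisy latent
projection — so closure holds by construction and deep terms are rarer, as in
real annotation tables. All kernel ingredients are noisy functions of the
same latents (linear maps for expression and gene coordinates, thresholded
projections for domains and chromosome assignment, a top-3% latent-similarity
graph for complexes, composition-biased random sequences), so kernels
correlate with annotations without determining them.

Interaction edges are drawn by ranking pairs under
`σ(b + coupling·(6·(shared_frac − ½) + ½·tanh(z·z'/d)))`, where `shared_frac`
is the fraction of (namespace, level) slots at which the pair shares a term;
the `n` highest-probability pairs (default `1.5·n_proteins`) become
positives. Gating the latent-similarity term by the coupling knob keeps
`coupling = 0` genomes exactly annotation-independent (latent similarity
itself predicts shared terms, so an ungated term would leak coupling); at
`coupling = 0.8` interacting pairs share terms at most levels, which is the
structural assumption behind the interaction–function rule. Negative pairs
are sampled uniformly from the complement (equal count by default), and
cross-validation folds are built greedily: proteins in decreasing annotation
count, each placed in the fold minimizing the sum of squared per-term count
deviations, fold size breaking ties; pairs are split the same way over their
labels. Everything is deterministic per seed.

What the generator does *not* emulate: sequence evolution and homology
structure (redundancy is controlled through latent similarity, not sequence
identity), realistic GO topology beyond shape parameters, evidence codes, or
the marginal statistics of any real genome. Results on these genomes
demonstrate that the machinery behaves as designed — constraints are
enforced, information flows from interactions into deep terms, metrics and
gradients are correct — not that any particular real-genome accuracy would be
attained.

## Reference experiments

`sbrgo.experiments.rule_variant_study` (the basis of the reproduction
script) uses ten genomes of 200 proteins at coupling 0.8, an 80/20
protein split, interaction labels hidden for any pair touching a test
protein, and default model settings. Typical outcome: held-out F1@0.5 at the
deepest level ≈ 0.12 with no rules, ≈ 0.15 with hierarchy rules, ≈ 0.26 with
the full rule set, with the full-vs-none gap growing monotonically with
depth, while held-out interaction F1 (≈ 0.60) is identical across variants
by construction (interaction atoms are clamped). The violation study (120
proteins, `lambda_go = 10`) shows a small positive fraction of
child-positive/parent-negative predictions at τ = 0.5 for the unconstrained
model and exactly zero after collective inference. Problem sizes were chosen
so the full reproduction run completes in minutes on a single CPU.

## Numerical choices and degenerate inputs

* Optimizer stopping: relative objective change below `tol` (default 1e-6;
  1e-8 in collective inference) or a vanishing backtracked step; iteration
  caps of 500 (weights) and 1000 (collective inference).
* Kernels are validated symmetric within 1e-9; training kernels must have
  eigenvalues above −1e-6.
* Constraints with no groundings evaluate to 1 and are logged; empty
  `Domain_l` levels are skipped with a warning.
* Sequences shorter than k contribute zero spectrum rows (warned); proteins
  with undefined information content are excluded from Smin (warned).
* Ties in fold assignment break toward the lower fold id after the seeded
  shuffle, so splits are reproducible.

## Known limitations

Collective inference is a local method on a non-convex landscape; the
two-stage warm start is a heuristic with no global guarantee. Łukasiewicz
consensus can trade a confident child against an unconfident parent
(lowering both toward their midpoint), which slightly depresses shallow-level
F1 when rules are active — visible in the reference study. Grounding the
interaction rule only over supplied pairs means unobserved pairs exert no
constraint. The collective stage scales linearly in groundings per iteration
but the constraint set grows with terms × proteins + levels × pairs, so
genome-scale runs need batching or sparsification that this implementation
does not attempt.
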