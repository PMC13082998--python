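# Methods

## Problem setting

The package addresses transductive binary node classification on patient
graphs. A cohort of Z patients is encoded as a binary matrix
X ∈ {0,1}^{Z×F} of diagnosis-history indicators over F disease codes;
the label marks whether the patient's outcome was the target comorbidity.
Patients are connected when their histories share at least `min_shared`
codes (default 1; co-diagnosis graphs are dense, so the threshold is the
practical sparsification knob). Self-loops are excluded — self-information
enters through the learnable μ-weighted self terms of the update rules
instead. Edges are stored once per unordered pair and expanded to both
directions for message passing.

## The layer stack

Each of the `n_layers` (default 2) layers first applies the layer
transforms H ← H W_h and P ← P W_p to node features and position
embeddings, then computes, per directed edge (i receiver, j sender):

1. feature attention e^base = a_srcᵀ LeakyReLU(W h_i) + a_dstᵀ LeakyReLU(W h_j),
   with a_src, a_dst two shared learnable vectors (per-patient attention
   vectors would not generalise across nodes); negative slope 0.2;
2. structural attention e^pos = (s_i ⊙ a_s)ᵀ(s_j ⊙ a_s);
3. the fused score e^fusion = e^base + e^pos;
4. a composite Bregman divergence d = ω·d_f + (1−ω)·d_s with the
   squared-Euclidean generator in both the feature and position space.
   The generator is the canonical choice — symmetric, nonnegative, cheap —
   and the divergence function is pluggable in principle (a generalised-KL
   variant would apply to strictly positive features);
5. the adjusted score e^adjust = e^fusion − δ·d;
6. the potential mask m_ij (below) and the masked softmax
   α_ij = exp(e^adjust_ij)·m_ij / Σ_k exp(e^adjust_ik). The mask
   multiplies the numerator only, exactly as the rule is stated, so a row
   with suppressed edges deliberately sums to less than one; a
   `renormalize_masked_attention` switch restores unit rows and is off by
   default. The softmax is shifted by the per-receiver maximum, which is
   a no-op mathematically and prevents overflow;
7. aggregation h_i' = μ Σ_j α_ij W h_j; isolated nodes pass μ W h_i.

A parallel similarity–difference branch (on by default, flag
`use_sim_diff_branch`) forms the relation R_ij = exp((C_ij − β·O_ij)/τ)
on graph edges, with C_ij the inner product of `sim_proj`-projected
features, O_ij = d_ij (the one difference measure the model defines), and
τ the temperature (default 1). Messages are the R-normalised convex
combination of neighbour features, and the branch output
μ·h_i/|N(i)| + M_i is added to the attention output before the ELU
nonlinearity. The two aggregation rules are composed this way — masked
attention as the layer's trunk, the relation branch as an additive
correction — because the model defines both without stating their
composition; the flag makes the choice auditable and reversible.

Heads (default 4) are concatenated on hidden layers with per-head width
hid/heads, so the concatenated width equals `hid` and matches the branch
output; on the last layer each head produces a full `hid`-wide output and
heads are averaged. A linear classifier with softmax over the two classes
produces the prediction. Dropout (default 0.3) applies to layer inputs
and to attention weights during training only.

### Disease potential and mask

The potential p_i = σ(Σ_{q∈D} X_iq) is computed once from the raw binary
matrix (the defining sum acts on X, not on hidden features, so it is
layer-independent). D defaults to all features; in a study it should be
the designated disease-feature set for the target comorbidity
(`potential_features`). The sum is unweighted as defined; a learnable-
weight variant was considered and left out of the default path. The mask
compares integer raw sums rather than their sigmoids: the comparison is
equivalent by monotonicity and immune to floating-point saturation ties.
m_ij = 1 requires the *strict* inequality, so ties give ε on both
directions and (m_ij, m_ji) = (1,1) is impossible; ε defaults to 0.1,
suppressing rather than severing reverse-gradient flow.

### Parameters and constraints

μ ("a learnable positive scalar") is stored unconstrained and mapped
through softplus; ω through a sigmoid onto [0,1]. β and δ are free
scalars (init 1.0 and 0.1). Position embeddings P⁰ are free per-node
vectors initialised from the eigenvectors of the `hid` smallest
eigenvalues of the combinatorial Laplacian L = D − A — a reproducible,
topology-aware start — and trained under the smoothness penalty
L_p = Σ_{(i,j)∈E} w_ij ‖p_i − p_j‖² (edge weights default 1, summed once
per unordered edge; this equals tr(PᵀLP)).

## Training protocol

L_total = L_c + λ·L_p with λ = 1 by default; L_c is binary cross-entropy
over training nodes computed via log-softmax; the full graph participates
in message passing every epoch. The optimiser is adaptive-moment descent
(lr 5e-4 by default, 1e-3 recommended for larger cohorts; weight decay
5e-4) — the training rule itself is not specified beyond the loss, so
standard attention-network practice is followed and everything is
configurable. Model selection keeps the parameters of the epoch with the
best validation accuracy. `evaluate_runs` repeats split → train → test
with fresh seeds (re-splitting, not merely re-initialising, matches the
nontrivial across-run variance such protocols report) and returns mean ±
sample standard deviation of test accuracy and macro-F1. Metrics come
from confusion counts; F1 is macro-averaged with 0/0 defined as 0.
Dropout is inactive at evaluation. Divergent (non-finite) losses abort
with a diagnostic rather than continuing silently.

## Autodiff engine

No deep-learning framework is used: `dpga.autodiff` is a reverse-mode
engine over float64 numpy arrays with exactly the operations the layers
need. Edge-level operations (pairwise squared distances, bilinear edge
scores, weighted neighbour sums) are fused primitives whose forward and
backward passes run through cached `scipy.sparse` incidence/adjacency
templates — per-edge scatter-adds via `np.add.at` are orders of magnitude
slower at realistic edge counts. Gradient correctness is established by
finite-difference comparison (relative tolerance 1e-4) over every
parameter group of the full training loss.

## Comorbidity networks

For diseases u, v with prevalence counts Y_u, Y_v and co-occurrence N_uv
in Z patients, φ_uv = (N_uv Z − Y_u Y_v)/√(Y_u Y_v (Z−Y_u)(Z−Y_v)) — the
Pearson correlation of the two indicator columns, which the tests verify
as an identity. Degenerate margins (Y ∈ {0, Z}) yield a flagged NaN, not
0, to avoid silently manufacturing independence. Edge significance is the
correlation t statistic t = φ√((Z−2)/(1−φ²)) with Z−2 degrees of freedom
(the standard choice; the network tables report t without defining it).
Networks keep pairs with N_uv ≥ `min_pair_count` (default 5) and
t ≥ `min_t` (default 1.96); φ = ±1 edges carry infinite t and survive any
threshold but stay flagged. Endpoint degrees are computed on the surviving
network and reported separately from prevalence — recomputation shows the
published-style tables' "degree" columns cannot be prevalences. No
multiple-testing correction is applied across pairs (deliberately out of
scope); at min_t = 1.96 the per-pair one-sided type-I rate is ≈ 2.5%,
which the acceptance suite verifies stays under 10% end to end.

## Synthetic cohorts

The generator emulates the *shape* of case/control EMR cohorts: balanced
binary labels; per-feature baseline Bernoulli prevalence (default 0.08,
a typical secondary-diagnosis rate); co-occurrence modules driven by a
shared latent Bernoulli switch per module (a mixture construction —
simpler than pairwise copulas and sufficient to plant network structure);
and a severity gradient: a designated potential-feature set whose
prevalence is raised by `effect_size` in cases. Presets reproduce the
three study shapes (630×355, 1,024×435, 1,668×500). One seed governs all
randomness and regeneration is bit-identical.

What the generator does **not** emulate: ICD code semantics and
hierarchy, visit-level longitudinal structure, age/sex confounding, and
informative missingness. Passing tests therefore demonstrate that the
implementation recovers the structure it assumes — planted gradients and
co-occurrence modules — not that the model transfers to real EMR data.

## Problem sizes used in tests and the acceptance script

The planted-recovery experiment uses a 400-patient cohort (200/200) with
80 features, two 5-feature co-occurrence modules, and 25 potential
features at effect size 0.3 — chosen so the cohort is genuinely strongly
separable (a logistic-regression oracle on the raw features reaches
≈ 0.95, comfortably above the 0.90 recovery bar; with too few potential
features the Bayes accuracy itself falls below 0.9 and no model could
pass). The graph is built at min_shared=3 because at these prevalences
the min_shared=1 graph is ~80% dense and nearly uninformative; training
runs 150 epochs (validation accuracy plateaus by ~80) over 3 runs. The
type-I experiment uses 20 independent-feature cohorts of n=5,000.

## Known limitations

* Transductive only: the fitted model scores nodes of the graph it was
  trained on; inductive inference on unseen patients is out of scope.
* The non-normalised masked attention makes representation magnitude
  carry potential information; with `renormalize_masked_attention` the
  model reverts to distribution-valued attention rows.
* Dense Z×Z adjacency and dense eigendecomposition bound practical graph
  size to a few thousand nodes — ample for the cohort sizes in scope.
* The |E| convention: unordered pairs are the stored representation;
  directed-pair counts are exactly twice that.
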