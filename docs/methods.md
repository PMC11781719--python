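# Methods

## Model

`dtiwalk` treats drug–target interaction (DTI) prediction as link
prediction on a heterogeneous network of four node classes (drug,
protein, disease, side-effect) and six binary relations. The working
assumption is the standard network pharmacology premise: similar drugs
act on similar targets. Similarity is assembled per class from several
complementary views, each view is summarized by the stationary behavior
of a restart random walk, and the resulting diffusion states are
compressed into features whose bilinear projection scores pairs.

### Similarity views

Profile-based views compare rows of a relation table with the Jaccard
coefficient J = M₁₁/(M₁₁+M₀₁+M₁₀), where M_xy counts positions with value
x in the first profile and y in the second. Two conventions the
coefficient itself does not fix:

- *Empty versus empty profiles score 0*, not 1: two nodes with no
  recorded associations share no evidence of similarity. Diagonals follow
  the same rule (1 for non-empty profiles, 0 for empty ones).
- The drug–drug and protein–protein interaction views are computed by
  Jaccard over the within-class adjacency rows, i.e. interaction
  *profiles*, not the raw adjacency.

The Hamming alternative (M₁₁+M₀₀)/L replaces Jaccard in all
profile-derived views when the ISLHRWR variant is selected; the
structure and genome views are not profile-derived and are left
untouched.

Structural similarity is Tanimoto over fingerprint bit-vectors (on binary
vectors, identical to Jaccard). Genomic similarity is normalized
Smith–Waterman: SW(a,b)/√(SW(a,a)·SW(b,b)), computed with BLOSUM62,
gap open 10, gap extension 0.5 (all configurable; a length-n gap costs
open + (n−1)·extend). The geometric-mean normalization is the standard
choice; it guarantees a score of exactly 1 for identical sequences and
symmetry in the arguments.

### Diffusion

Each view defines a graph whose edge set is the support of its
similarity matrix and whose degrees K(i) are unweighted neighbor counts;
weights enter only through the edge set and through the ISLRWR rule.
Transition constructions:

| variant | off-diagonal rule | diagonal |
|---|---|---|
| RWR | 1/K(i) on edges | 0 |
| MHRW | min(1/K(i), 1/K(j)) on edges | 1 − row sum |
| IMRWR | MHRW + K(j)/Σ_{l∈Γ(i)} K(l) · MHRW self-loop | 0 |
| ISLRWR | J(i,j)/(Σ_{j∈Γ(i)} J(i,j) + n_iso) | policy-dependent |

Numerical and interpretive choices:

- **Dangling rows.** The RWR/MHRW/IMRWR rules produce an all-zero row for
  an isolated node; it is replaced by a unit self-loop (the standard
  dangling correction) so every transition matrix is row-stochastic,
  which the stationary solve requires.
- **IMRWR denominator.** The redistribution denominator Σ_l K(l) sums
  over the *neighbors* of i. This is the only reading that conserves
  probability row by row, and it is enforced by test.
- **ISLRWR residual mass.** The ISLRWR row sums to
  Σ J/(Σ J + n_iso) < 1 whenever isolated nodes exist. The missing mass
  n_iso/(Σ J + n_iso) is placed, by default, uniformly on the isolated
  nodes themselves ("teleport": each receives 1/(Σ J + n_iso)), which
  realizes the design goal that walkers perceive isolated nodes rather
  than ignore them. A "selfloop" policy (mass on the diagonal) is offered
  as an alternative; both keep rows stochastic.
- **J in ISLRWR.** Each view is diffused with its own similarity matrix
  as J; within-class relation views therefore use their profile-Jaccard
  (or Hamming) similarity, not raw adjacency.
- **Continuation probability c = 0.85** (restart 0.15), the conventional
  restart-walk setting; configurable, recorded in all output metadata.
- **Solvers.** The closed form πᵢ = (1−c)(I−cPᵀ)⁻¹eᵢ (one dense solve for
  all seeds) is the default. Power iteration is provided as an
  independent route; it stops when the contraction bound
  c/(1−c)·‖Δ‖_∞ falls below the tolerance (default 1e-8, max 1000
  iterations), so the tolerance bounds the true distance to the fixed
  point rather than the last step size.

### Features and projection

Node i's diffusion states across all V views of its class are
concatenated into a row of an N×(N·V) matrix, transformed by
x ↦ log(x + s) with smoothing s = 1/N by default (stationary
probabilities span orders of magnitude; the log makes small visiting
probabilities informative), column-centered, and factored by truncated
SVD of rank f (default f_d = f_p = 100). Features are U√Σ, so feature
inner products approximate the log-state Gram matrix. The randomized SVD
is seeded, making embeddings deterministic. Concatenation (rather than
averaging) of views preserves per-view signal; this was a genuinely open
design choice. A multinomial-logistic formulation of diffusion-state
compression exists in the literature; the log+SVD surrogate used here is
the established practical realization and keeps the solver convex and
deterministic.

The projection Z = (XᵀX+λI)⁻¹ Xᵀ A_train Y (YᵀY+λI)⁻¹ (λ = 0.1 default)
is the closed-form minimizer of the two-sided ridge objective. During
cross-validation, held-out test positives are zeroed in A_train — an
unobserved pair is treated as a non-interaction at training time,
matching the protocol where only 90% of positives are visible per fold.
Z is full f_d×f_p; no further factorization.

### Cross-validation protocol

- Positives are shuffled once per seed and partitioned into ten
  near-equal folds; negatives are drawn uniformly from non-positive
  pairs, rejecting collisions, with |negatives| = |positives| in both
  training and test sets; per fold, test and train negatives are
  disjoint.
- **Similarity, diffusion and embeddings are computed once on the full
  network; only Z is refit per fold.** The similarity views never encode
  drug–protein edges, so the held-out interactions cannot leak through
  them; refitting diffusion per fold would change nothing but cost.
  This choice is recorded in the output metadata
  (`embeddings_refit_per_fold: false`).
- The classification threshold for precision/recall/F1/MCC is the
  F1-maximizing threshold on the *training* fold's scores, applied
  unchanged to the test fold (a fixed midpoint policy is selectable).
  AUROC (tie-aware trapezoidal) and AUPRC (step-interpolated) are
  threshold-free.
- The homolog filter compares each evaluation pair against the training
  pairs of its own fold: it removes pairs whose protein similarity to any
  training protein is ≥ 0.4 (inclusive) or whose drug similarity to any
  training drug is ≥ 0.6. Protein "sequence identity" is realized by the
  normalized Smith–Waterman matrix when sequences are available,
  otherwise by the supplied protein similarity view; drugs use the
  structure view. Filtering relative to training (rather than pruning
  the dataset once) is the reading that directly prevents inflated test
  metrics; a dataset-level policy can be emulated by pre-filtering
  inputs.

## Synthetic data

The generator emulates the input universe's structure while planting a
recoverable signal. Drugs and proteins receive latent factors
U ∈ R^{N_d×r}, V ∈ R^{N_p×r} with standard normal entries; the
interaction matrix is exactly the top ρ·N_d·N_p entries of UVᵀ. Disease
and side-effect entities get random unit latent directions; a node is
linked to an entity when its factor projection exceeds the entity's 80th
percentile, and each profile bit then flips independently with
probability ε. Within-class edges link pairs above the 95th percentile
of latent cosine similarity; a designated fraction of nodes is then
fully disconnected (and every stranded non-designated node reconnected
to its nearest eligible neighbor), so the isolated-node count is exact —
these nodes exercise the ISLRWR mechanism specifically. Structure and
genome similarity matrices are (cos+1)/2 of latent factors plus
symmetric Gaussian jitter of scale ε, clipped to [0,1].

Defaults: N_d = 300, N_p = 400, N_dis = 500, N_se = 400, r = 10,
ρ = 0.03, ε = 0.05, isolated fraction 0.05. These sizes are a few-fold
smaller than typical curated DTI benchmarks and keep a full five-variant
cross-validated run under a minute while leaving ~3,600 positives — 
enough for stable ten-fold metrics.

What the generator does *not* emulate: the heavy-tailed degree
distributions of curated databases, correlated ascertainment bias
(popular drugs have more recorded associations of every kind), within-
class edge noise, and real sequence/fingerprint inputs (similarities are
generated directly). Passing the planted-signal tests therefore shows
the pipeline recovers latent structure that all views share; it does not
certify performance on any particular curated dataset.

## Degenerate inputs and tie-breaks

- A non-isolated ISLRWR row with zero similarity to all its neighbors
  and no isolated nodes falls back to a unit self-loop with a warning.
- Jaccard of two empty profiles is 0; Hamming of zero-length profiles is
  an error.
- Metrics with a zero denominator (e.g. no positive predictions) are
  reported as 0 with a `zero_division` flag rather than NaN.
- `argpartition` resolves ties at the interaction-density cutoff
  arbitrarily but deterministically for a fixed seed.
- Negative sampling requires the requested count to be feasible and
  otherwise raises.

## Known limitations

- Dense linear algebra throughout: node classes beyond ~5,000 nodes will
  want sparse transition storage and iterative solvers.
- Only direct (one-hop) relational evidence enters the similarity views;
  multi-hop metapath information is not modeled.
- The homolog filter can empty a test fold when thresholds are very low;
  metrics then fail loudly rather than silently degrade.
- Diffusion and embeddings are deliberately not refit per fold (see
  above); experiments that add or remove *similarity* edges per fold
  would need that extension.
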