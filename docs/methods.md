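# Methods

## Model and estimation problem

The package assumes a collection of orthologous genes G₁…G_m whose trees
are topologically compatible with a known reference topology 𝒯 and differ
mainly by rate: under the *proportional model*, the tree of gene k equals
the species tree scaled by a gene rate r_k (after removing taxa not
sampled for that gene). Branch lengths of the species tree are defined as
substitutions per site pooled over genes, b_e = (1/N) Σ_k N_k b_e^(k) with
N = Σ N_k, which fixes the rate scale: (1/N) Σ_k N_k r_k = 1.

Estimation works on the inverse rates. With scale factors α_k ≈ 1/r_k and
branch lengths b, the criterion

    Q(α, b) = Σ_k Σ_{i<j ∈ L_k} w_ij^(k) (α_k δ_ij^(k) − d_ij(b))²

is minimized subject to Σ Z_k α_k = rhs_scale · Σ Z_k. The constraint only
removes the trivial all-zero solution; its right-hand side sets an
arbitrary intermediate scale that cancels in the final rescaling (this is
asserted by a test that multiplies `rhs_scale` by 10³).

Weight and constraint choices, all configurable via `SolverConfig`:

| parameter | default | meaning |
|---|---|---|
| `weight_mode` | `seqlen` (w_ij^(k) = N_k) | confidence in δ_ij^(k); `flat` = 1, `custom` = user matrix |
| `z_mode` | `seqlen_distsum` (Z_k = N_k Σ_{i<j} δ_ij^(k)) | constraint coefficients; `unit`, `seqlen` also available |
| `rhs_scale` | 1 | arbitrary constraint scale (result-invariant) |
| `singular_tol` | 1e-10 | relative rank tolerance for multiplicity detection |
| `clamp_negative_lengths` | off | zero out negative output lengths after rescaling |

The `seqlen_distsum` default couples the constraint strength to both gene
length and overall divergence, which prevents the systematic
over-estimation of scale factors for genes observed only in a few closely
related taxa that the simpler choices (Z_k = 1 or N_k) incur. The distance
sum runs over unordered defined pairs; any fixed convention differs only
by a gene-uniform factor and is applied uniformly.

## Solving: gene elimination on an augmented system

Writing x^{ij} for the 0/1 path-incidence vector of pair (i,j) on 𝒯
(B edges), the assembly accumulates per gene S_k = Σ w δ², u_k = Σ w δ x,
and globally H = Σ w x xᵀ, over *defined* pairs only — pairs whose
distance is undefined (saturation, no comparable sites) carry weight zero,
and a gene left without a defined positive pair is rejected by name rather
than silently imputed. Lagrange stationarity gives α_k = (u_kᵀb + μZ_k)/S_k
(μ = −λ/2), and eliminating the α_k leaves the Schur complement
M = H − Σ u_k u_kᵀ/S_k in the system

    [ M   −v ] [ b ]   [ 0 ]        v = Σ (Z_k/S_k) u_k,
    [ vᵀ   z ] [ μ ] = [ R ],       z = Σ Z_k²/S_k,  R = rhs_scale Σ Z_k.

One B×B-sized solve, so runtime is linear in m and cubic only in the
number of taxa. The augmented form — rather than solving M b₀ = v and
scaling — is deliberate: **M is singular on every exactly proportional
input** (if α*, b* fit all distances perfectly, M b* = 0), yet the
constrained optimum there is unique, with μ = 0. Because the full quadratic
form is positive semidefinite, the augmented matrix is rank-deficient
*precisely when* the optimizer has multiple solutions, which makes its
rank (at relative tolerance `singular_tol`, via SVD) the authoritative
multiplicity test. When it is rank-deficient, the minimum-norm solution is
returned, flagged, and the null-space support identifies the unconstrained
edges; taxon pairs that co-occur in no gene are reported separately as the
classical necessary-but-not-sufficient symptom. Q is evaluated through the
assembled quadratic form Q = Σ S_k α_k² − 2 Σ α_k u_kᵀb + bᵀHb and clipped
at zero against floating-point cancellation.

Rescaling applies c = (1/N) Σ N_k/α̂_k; the returned rates 1/(c·α̂_k) then
have N-weighted mean exactly one and the returned lengths are c·b̂_e.
Negative branch lengths (a standard possibility in unconstrained
least-squares fitting) are kept by default and only clamped on request,
after rescaling, with a warning; negative α̂_k (possible under extreme
noise) produce a warning and a negative reported rate rather than a
failure. A zero α̂_k aborts with an error, as Eq.-style rescaling is then
undefined.

With m = 1 the constraint forces α̂₁ = 1 and the solver reduces exactly to
classical WLS branch-length fitting; this reduction is tested against an
independent design-matrix least-squares oracle, and the gene-elimination
path is tested against a dense solve of the full (B+m+1) stationarity
system on random noisy instances.

## Distance estimation

`pair_counts` uses pairwise deletion: each pair of rows is compared only at
sites where both carry a determinate base (A/C/G/T), since distances are
estimated per pair anyway. Closed forms:

* JC69: d = −(3/4) ln(1 − 4p/3);
* K2P: d = −(1/2) ln(1 − 2P − Q) − (1/4) ln(1 − 2Q);
* TN93: the three-term formula splitting purine (P1) and pyrimidine (P2)
  transitions, with empirical base frequencies averaged over the two
  sequences of the pair; a term whose frequency class is absent is dropped
  when no such substitutions were observed, and the distance is undefined
  otherwise.

The continuous-gamma correction replaces every −ln(x) term by
a(x^(−1/a) − 1) termwise. Distances decrease monotonically in the shape
parameter a and converge to the log formulas as a → ∞ (both asserted).
The shape cannot be estimated from pairwise comparisons alone, so it is a
user parameter (default 1.0, matching the simulator's default). Saturated
pairs (any log/power argument ≤ 0) become *undefined*, never an exception,
and are excluded downstream. An optional `max_distance` ceiling can
additionally mark effectively saturated estimates as undefined; it is off
by default (see Limitations).

## Simulator

`generate_replicate` emulates a multilocus study: a random binary base
tree on n taxa (default 40) normalized to total length 1; m gene trees
(default 500) scaled by t_k ~ U[0.4, 9]; per-gene alignment lengths
N_k ~ U{200..600}; sequences evolved natively under K2P with κ = 4
(transition/transversion *event* ratio R = κ/2 = 2 under equal base
frequencies — `kappa_from_event_ratio` converts) and one Gamma(shape 1,
mean 1) rate drawn per site; and per-gene dropout where p ~ U[0,1] and each
taxon is suppressed independently with probability p, with a floor of 4
surviving taxa drawn uniformly when fewer remain. The ground truth is the
model tree (N_k-weighted average of gene-tree lengths, restricted to the
union of sampled taxa) and model rates r_k = t_k/F, F = (1/N) Σ N_k t_k.

Design choices: base-tree topologies come from random sequential leaf
addition with i.i.d. exponential(mean 0.1) lengths before normalization —
a simple, documented convention; real estimated trees have a different
(typically less heavy-tailed) branch-length profile, and
`random_base_tree` is isolated so users can substitute their own trees.
Sequence evolution is implemented from the closed-form K2P transition
probabilities (testable against them directly) and rooted at an arbitrary
internal node, which is immaterial since K2P is reversible. One seed
drives independent child streams for topology, rates, lengths, sequences
and missingness, so generating a replicate without sequences leaves every
other draw unchanged.

What passing simulation-based tests shows — and what it does not: the data
satisfy the proportional model exactly (no heterotachy), share one
topology (no incomplete lineage sorting, duplication or transfer), and are
alignment-error free. Accuracy on such data bounds what the method can do
when its assumptions hold; it does not certify behaviour under violations.

## Evaluation conventions

Fraction of variance unexplained, FVU = Σ(b̂_e − b_e)² / Σ(b_e − b̄)², and
mean absolute log-ratio, MALR = (1/m) Σ |ln(r̂_k/r_k)| (natural log), are
this package's explicit conventions. Edges are matched across trees by
leaf-set bipartition. Genes with non-positive estimated rates are excluded
from MALR with a warning.

## Numerical choices and degenerate inputs

* Rank and multiplicity: SVD of the augmented matrix at relative tolerance
  1e-10; minimum-norm representative under deficiency.
* Constraint residual is verified post-solve at 1e-8 relative; failure
  raises a degenerate-system error (exit code 2 in the CLI).
* Multi-matrix input is symmetrized by averaging (asymmetry beyond 1e-9 is
  an error); the diagonal must be zero; `NA` marks undefined entries.
* Restriction sums suppressed degree-2 node lengths exactly, so patristic
  distances among retained taxa are preserved to machine precision.
* Output precision: 10 significant digits in TSV/matrix files; Newick
  lengths use fixed notation with a configurable number of decimals.

## Problem sizes used in the test suite

Unit and property tests run on trees of 4–40 taxa and up to 20 genes; the
end-to-end recovery tests use a replicate with n = 20 taxa and m = 100
genes, and the dropout-floor check uses 10,000 draws. These sizes keep the
full suite in the seconds-to-a-minute range while exercising every code
path at the same per-gene dimensions as larger studies (runtime is linear
in m).

## Known limitations

* Gamma-corrected pairwise distances have rapidly exploding variance near
  saturation: a(x^(−1/a) − 1) grows without bound as the corrected
  argument x → 0, so short alignments of fast genes occasionally yield
  enormous distance estimates that enter the fit with full weight N_k and
  can dominate branch-length error on deep trees. Across simulated
  replicates this makes FVU heavy-tailed (typically a few percent, rarely
  large). Remedies: longer sequences, the `max_distance` ceiling, or
  custom per-pair weights via the `custom` weighting hook.
* A single gamma shape shared by all genes biases rate estimates for genes
  whose true shape differs; per-gene shapes require multi-sequence
  comparison and are out of scope for pairwise estimation.
* No variance-based (e.g. Bulmer) weighting is built in; the custom-weight
  hook accepts any externally computed weights.
* The solver estimates lengths and rates for a *given* topology; topology
  inference, rooting and dating are out of scope.
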