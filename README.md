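# erable

Distance-based estimation of **phylogenomic branch lengths** and **relative
gene evolutionary rates**, for a fixed reference tree topology.

## The problem

Supertree methods recover the *shape* of a species tree from many genes but
usually discard branch lengths, while maximum-likelihood analysis of a
concatenated alignment recovers lengths at a heavy computational cost. This
package takes the middle ("medium-level") road: it consumes a collection of
per-gene distance matrices Δ₁…Δ_m — estimated directly from alignments, or
read off inferred gene trees — over partially overlapping taxon sets
L₁…L_m, plus a reference topology 𝒯 on the union of the taxa, and jointly
estimates

* the branch lengths b_e of 𝒯, interpreted as substitutions per site
  averaged over genes and weighted by alignment lengths
  (b_e = (1/N) Σ_k N_k b_e^(k), N = Σ N_k), and
* the relative rate r_k of each gene under the **proportional model**
  (every gene tree equals the species tree up to a multiplicative rate),
  normalized so that the sequence-length-weighted mean rate is one:
  (1/N) Σ_k N_k r_k = 1.

It solves the constrained weighted least-squares problem

```
minimize    Q(α, b) = Σ_k Σ_{i<j ∈ L_k} w_ij^(k) (α_k δ_ij^(k) − d_ij(b))²
subject to  Σ_k Z_k α_k = Σ_k Z_k
```

where α_k is the *scale factor* (inverse rate) of gene k, d_ij(b) the path
sum between leaves i and j on 𝒯, w_ij^(k) = N_k by default, and
Z_k = N_k Σ_ij δ_ij^(k) by default (this constraint choice avoids
over-estimating the scale factors of genes observed only in small sets of
close taxa). Lagrange elimination of the α_k leaves one (B+1)-dimensional
linear system, so the cost grows linearly in the number of genes. Raw
estimates are then rescaled by c = (1/N) Σ_k N_k/α̂_k, and the method
returns r̂_k = 1/(c·α̂_k) and branch lengths c·b̂_e. With a single input
matrix it reduces exactly to classical WLS branch-length fitting.

The package also provides JC69/K2P/TN93 pairwise distance estimation with a
continuous-gamma rate-heterogeneity correction, a sequence/replicate
simulator with known ground truth, and evaluation metrics (fraction of
variance unexplained for branch lengths; mean absolute log-ratio for
rates). See `docs/methods.md` for the modelling details and conventions.

## Worked example

The quartet `((A:1,B:2):3,(C:4,D:5));` with two proportional genes — gene 2
three times faster than gene 1, both with 100 sites:

```python
import numpy as np
from erable import DistanceMatrix, GeneMatrix, parse_newick, run

topology = parse_newick("((A:1,B:2):3,(C:4,D:5));")
d1 = topology.patristic_matrix()
genes = [
    GeneMatrix("g1", n_sites=100, delta=d1),
    GeneMatrix("g2", n_sites=100, delta=DistanceMatrix(d1.taxa, 3 * d1.values)),
]
result = run(genes, topology)
print(np.round(result.rates, 6), round(result.c, 6))
print(sorted(np.round(result.tree.edge_lengths, 6).tolist()))
```

prints

```
[0.5 1.5] 1.0
[2.0, 4.0, 6.0, 8.0, 10.0]
```

i.e. the two genes evolve at 0.5× and 1.5× the phylogenomic rate (their
sites-weighted mean is 1), and the branch lengths are the rate-weighted
average of the two gene trees — twice the input quartet, as the definition
b_e = (1/N) Σ N_k b_e^(k) = ((100·1 + 100·3)/200)·b_e^(1) requires.

The same analysis from the shell:

```sh
erable simulate --taxa 20 --genes 100 --seed 1 --out rep/
erable distances --alignments 'rep/alignments/*.fasta' --model tn93 \
       --gamma-shape 1.0 --out genes.mat
erable solve --matrices genes.mat --topology rep/model_tree.nwk \
       --out-tree est.nwk --out-rates rates.tsv --out-summary summary.json
erable evaluate --truth rep/ --tree est.nwk --rates rates.tsv --out cmp.tsv
```

The multi-matrix file format is plain text: first line the number of gene
blocks; each block is a header line `name N_k`, a taxon count `p`, and `p`
rows `taxon d_1 … d_p` (full square matrix, `NA` for undefined entries).

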