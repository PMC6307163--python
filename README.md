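# nvbarcode

Alignment-free DNA barcode analysis with covariance-augmented natural
vectors.

DNA barcoding identifies species from a short standardized marker sequence
(for fungi, the ribosomal ITS region, typically 500–800 bp). Alignment-based
identification is slow at collection scale and fragile for markers, like ITS,
with frequent indels. `nvbarcode` instead maps every barcode to a fixed
18-dimensional feature vector built from the positional distribution of its
nucleotides, and runs the downstream analyses a barcoding study needs on
those vectors: species-level classification, separability checks, barcode-gap
analysis, and distance-based phylogenies.

## The 18-dimensional natural vector

For a sequence S = (s₁, …, s_N) over {A, C, G, T}, each nucleotide k
contributes three moments of its position set:

- **count** n_k,
- **mean position** μ_k = Σ i·w_k(i) / n_k,
- **normalized variation** D₂ᵏ = Σ (i − μ_k)² w_k(i) / (n_k N),

and each of the six nucleotide pairs (k₁, k₂) contributes a **subset-averaged
positional covariance**. With position sets A (size n) and B (size m ≥ n),
Cov(A, B) is the average over all C(m, n) ascending size-n subsets B' ⊆ B of
Σᵢ (aᵢ − μ_A)(b'ᵢ − μ_B')/n, and the vector entry is Cov(k₁, k₂) =
Cov(A, B)/N. For k₁ = k₂ this reduces exactly to D₂ᵏ. Worked example for
S = ACGTAC: A occurs at {1, 5}, C at {2, 6}, μ_A = 3, μ_C = 4, and
Cov(A, C) = [(1−3)(2−4)/2 + (5−3)(6−4)/2]/6 = 2/3.

The combinatorial average is never enumerated in the library path: a
hypergeometric rank-weight identity gives an exact O(nm) closed form
(see `docs/methods.md`), so full-length barcodes featurize in milliseconds.

On top of the vectors the package provides:

- **Convex-hull separability** (`hulls_disjoint`, `pairwise_hull_scan`) — an
  LP feasibility test for whether two species' point clouds have intersecting
  convex hulls, with a verified convex-combination certificate when they do;
  no explicit hull is ever constructed.
- **LDA projection** (`DiscriminantProjector`, `lda_project`) — Fisher
  discriminant projection to 2-D for visualizing separability.
- **Classification** (`BarcodeForest`, `evaluate_ranks`, `oob_curve`,
  `roc_tree_sweep`) — a bagged ensemble of unit-vote decision trees with
  out-of-bag error curves, per-rank accuracy, and a tree-count-sweep ROC/AUC.
- **Barcode gap** (`barcode_gap`) — intra- vs inter-group Euclidean distance
  distributions and means at any taxonomic rank.
- **Phylogeny** (`distance_matrix`, `single_linkage`, `to_newick`) —
  single-linkage dendrograms over vector distances with Newick export.
- **Synthetic data** (`generate_dataset`, `spike_outliers`) — seeded,
  hierarchically structured barcode families for end-to-end testing without
  any external download.

Feature variants for method comparison: the classic 12-dim vector
(`nv12`), four ablations (`ablated:<block>`), and k-mer count vectors
(`kmer:<k>`).

## Worked example

```python
from nvbarcode import (benchmark_spec, generate_dataset, featurize,
                       evaluate_ranks, barcode_gap, pairwise_hull_scan)

records, truth = generate_dataset(benchmark_spec(seed=1))   # 363 barcodes, 30 species
features = featurize(records)                                # 363 x 18 natural vectors

print(evaluate_ranks(records, features, n_trees=20, seed=1))
species = [r.taxonomy.species for r in records]
gap = barcode_gap(features, species)
print(f"mean intra {gap.mean_intra:.2f}  mean inter {gap.mean_inter:.2f}")
scan = pairwise_hull_scan(features, species)
print(f"intersecting hull pairs: {(~scan['disjoint']).sum()} of {len(scan)}")
```

prints

```
      rank  n_labels  oob_error  accuracy
0    class         3   0.000000  1.000000
1    order         6   0.000000  1.000000
2   family         6   0.000000  1.000000
3    genus        12   0.022039  0.977961
4  species        30   0.008264  0.991736
mean intra 5.36  mean inter 137.39
intersecting hull pairs: 0 of 435
```

i.e. out-of-bag accuracy at 20 trees is ≥ 97.8% at every rank, the mean
between-species distance exceeds the mean within-species distance ~25-fold
(a clear barcode gap), and no two species' convex hulls intersect in R¹⁸ —
the geometric property that makes nearest-hull species assignment sound.

The same workflows are available from the shell:

```bash
nvbarcode simulate --seed 1 --out-dir data/
nvbarcode featurize --fasta data/sequences.fasta --out-dir out/
nvbarcode classify --fasta data/sequences.fasta --taxonomy data/taxonomy.tsv --out-dir out/
nvbarcode gap --fasta data/sequences.fasta --taxonomy data/taxonomy.tsv --out-dir out/
nvbarcode hulls --fasta data/sequences.fasta --taxonomy data/taxonomy.tsv --out-dir out/
nvbarcode tree --fasta data/sequences.fasta --out-newick out/tree.nwk
```

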