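# Methods

## The feature map

A barcode sequence S = (s₁, …, s_N) over {A, C, G, T} is represented by 18
real features in fixed order:

    (n_A, n_C, n_G, n_T,
     μ_A, μ_C, μ_G, μ_T,
     D₂^A, D₂^C, D₂^G, D₂^T,
     cov_AC, cov_AG, cov_AT, cov_CG, cov_CT, cov_GT)

with n_k the count of nucleotide k, μ_k its mean 1-based position, and
D₂ᵏ = Σᵢ (i − μ_k)² w_k(i) / (n_k N) its normalized positional variation.
The map is effectively one-to-one on barcodes of practical length, so no
sequence information relevant to identification is lost, and it requires no
alignment and no model of the substitution process.

### Subset-averaged covariance

The pair features measure whether two nucleotides are positionally
correlated. Position sets A = {a₁ < … < a_n} and B = {b₁ < … < b_m} generally
have different sizes, so the usual paired covariance is undefined. The
definition used here: when m = n, Cov(A, B) = Σᵢ (aᵢ − μ_A)(bᵢ − μ_B)/n;
when m > n, Cov(A, B) is the average of the equal-size formula over all
C(m, n) ascending size-n subsets of B (each subset centered on its own
mean). The vector entry is Cov(k₁, k₂) = Cov(A, B)/N; with k₁ = k₂ this
equals D₂ᵏ identically, which the test suite asserts exactly.

Enumeration is intractable for real barcodes (n, m ≈ 150 gives astronomically
many subsets), but the average has an exact closed form. Because
Σᵢ (aᵢ − μ_A) = 0, each subset's own mean contributes nothing, so

    Cov(A, B) = (1/n) Σⱼ bⱼ Σᵢ (aᵢ − μ_A) · P(rank of bⱼ in the subset = i),
    P = C(j−1, i−1) · C(m−j, n−i) / C(m, n),

an O(nm) computation. The binomials are evaluated in log space (gammaln), so
the weights stay finite for any barcode length; agreement with the literal
enumeration is asserted to 1e-9 relative tolerance on randomized small
instances, and the cancellation identity itself (subset-mean vs full-mean
centering) is tested as a separate oracle variant.

Conventions for degenerate inputs: if a nucleotide is absent, its μ, D₂ and
every covariance involving it are 0, keeping vectors finite and comparable;
singleton position sets give zero covariance (a size-1 subset has no
deviation). Positions are 1-based. Sequences are uppercased, U is mapped to
T, and IUPAC ambiguity codes are dropped by default (with strict rejection
available) since the feature map is defined only on the canonical alphabet.

### Variants

`nv12` is the prefix without the covariance block; `ablated:<block>` removes
any one of the four feature blocks (14- or 12-dim), used to assess each
block's contribution; `kmer:<k>` gives overlapping k-mer counts in
lexicographic order (default k = 5 as a baseline), summing to N − k + 1.

## Convex-hull separability

Two species are linearly separable iff the convex hulls of their vector
clouds are disjoint. Rather than constructing hulls in R¹⁸ (exponential in
dimension), disjointness is decided by the LP

    min ‖s‖₁  s.t.  Σλᵢaᵢ − Σμⱼbⱼ = s,  λ, μ ≥ 0,  Σλ = 1,  Σμ = 1,

solved with HiGHS. A zero optimum (≤ `tol`, default 1e-7) means a common
point exists; the (λ, μ) certificate is then re-verified by substitution
before being returned, and solver failure raises rather than returning a
silent verdict. The slack formulation is always feasible, avoiding the
numerical fragility of a pure phase-1 feasibility test. Degenerate
(collinear/coplanar) clouds need no special casing. In 2-D the verdicts are
cross-checked in the tests against an exact polygon-intersection oracle.

## LDA visualization

For plotting, vectors are projected to 2-D by Fisher discriminant analysis:
the generalized eigenproblem S_b v = λ S_w v with within-class scatter
S_w = Σ_c Σ_{x∈c} (x − m_c)(x − m_c)ᵀ and between-class scatter
S_b = Σ_c n_c (m − m_c)(m − m_c)ᵀ, taking the top eigenvectors. A ridge of
`reg`·tr(S_w)/d (default reg = 1e-8) regularizes singular S_w. With k
classes only k − 1 directions are informative; for a two-class plot the
second axis is the leading within-class principal direction orthogonal to
the discriminant, recorded in `axis_meaning_`. The implementation is
cross-checked against scikit-learn's eigen-solver LDA in the tests.

## Classification and evaluation

`BarcodeForest` is a bagging ensemble: each tree is a CART classifier grown
on a bootstrap resample (per-split feature subsampling √d, trees fully
grown), and each tree casts a unit vote. Evaluation is out-of-bag: a sample
is scored only by trees whose bootstrap omitted it, giving an unbiased error
estimate without a held-out split; per-rank accuracy is 1 − OOB error. The
ensemble has the nested prefix property — the k-tree model is literally the
first k trees of a larger model with the same seed — so the OOB-error curve
over tree counts is read off a single fit. Samples that appear in every
bootstrap of a small ensemble receive no OOB vote and are excluded from that
count's error; vote ties resolve to the lowest class index
(deterministic). Fixed seeds make all outputs bit-reproducible.

The ROC construction sweeps the tree count k over a grid (default
{1, 2, 3, 5, 10, 15, 20, 30, 50}): at each k, OOB-vote predictions yield
one-vs-rest confusion counts per class, and TPR = TP/(TP+FN),
FPR = FP/(FP+TN) are macro-averaged over classes. The curve is these points
sorted by FPR with (0, 0) and (1, 1) anchors; AUC is its trapezoidal area.
OOB predictions (not resubstitution) are used because resubstitution is
near-perfect for any ensemble of a few trees and collapses the curve into a
single corner point. Note a structural consequence: when every point sits at
near-zero FPR, the AUC is ≈ (1 + min_k TPR)/2, i.e. it is governed by the
*worst* tree count in the grid — on a few hundred samples the 2–3-tree
points carry few OOB votes and depress the AUC relative to what the same
construction yields on collection-scale data.

## Distances, gap, and trees

Distances are Euclidean on the raw vectors; the count and mean-position
blocks are of order 10², so they dominate, which is intended — an optional
z-scaling flag exists but defaults off. The barcode gap at a rank partitions
all C(n, 2) pairwise distances into intra- and inter-group lists (all cross
pairs, not centroid distances; it is flagged that averaging over pairs, not
over group-pair means, is the convention) and reports their means — absent
means (no intra pairs) are reported as missing, never 0 — and shared-bin
histograms. Dendrograms are single-linkage (scipy), whose merge heights are
checked in the tests against a naive O(n³) agglomeration oracle and are
monotone by theorem. Newick export uses the half-height convention (branch
length = (parent height − child height)/2, so sibling leaves merged at
height h each get h/2); a cladogram mode omits lengths; labels with
metacharacters are quoted and duplicate labels are index-suffixed.

## Synthetic data generator

The generator emulates a hierarchical barcode collection: one independent
random root per class (length uniform in 500–800 bp, uniform base
composition), then ancestors derived down the ranks by uniform random
substitution to a different base at per-rank rates (order 0.12, family 0.09,
genus 0.07, species 0.05), and specimens drawn from their species ancestor
at the within-species rate 0.005. The 0.5% within / 5% between divergence
contrast is the regime in which a barcode marker is considered diagnostic.
Specimen counts per species are uniform in 5–20, giving the uneven species
sizes real collections show. The default taxonomy is 3 classes × 2 orders ×
1 family × 2 genera, with species counts cycling (2, 3) over the 12 genera —
exactly 30 species, ~360 specimens (the family partition coincides with the
order partition, which is harmless for the properties tested). Optional
indels (off by default) probe the length-sensitivity of the count features,
and `spike_outliers` lengthens and GC-enriches chosen specimens to emulate
divergent conspecific barcodes that attach basally in their species clade.

What the generator does **not** emulate: ITS secondary structure, PCR and
sequencing artifacts, rate heterogeneity across sites, and real taxonomic
label noise. Passing benchmarks therefore demonstrate the geometry and the
machinery — that well-separated species are separable, gapped, and
classifiable from natural vectors — not field-accuracy on any particular
real collection.

## Benchmark scale and expectations

All stochastic benchmarks run on the 30-species generator output (~360
sequences) over ≥ 5 seeds: 20-tree per-rank OOB accuracy is ≥ 0.95 at every
rank, the mean inter/intra distance ratio ≥ 5, and all 435 species hull
pairs are disjoint. The tree-count-sweep AUC at species rank measures
0.92–0.96 at this sample size for the structural reason given above; the
class-rank AUC is ≥ 0.99. Permutation nulls (shuffled labels) give AUC
0.5 ± 0.05 and chance-level OOB accuracy, confirming the evaluation carries
no optimistic bias.

## Known limitations

- The count/mean blocks dominate Euclidean distance; sequences of very
  different lengths are far apart even when homologous (the ablation and
  z-scaling options exist to probe this).
- The subset-averaged covariance assumes both nucleotides occur at least
  twice to be informative; short or extremely biased sequences yield zero
  covariance blocks.
- OOB-based evaluation reuses the training set; it is unbiased for bagging
  but small ensembles leave some samples unscored.
- The hull test is exact only up to LP tolerance; clouds separated by less
  than `tol` in scaled coordinates may be called intersecting.
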