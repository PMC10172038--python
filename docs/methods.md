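# Methods

## The model

`funcmap` analyses an undirected gene–gene interaction network from a
*function-centric* perspective. The pipeline has four stages.

**1. Network representation (PPMI).** A network with adjacency matrix
`A`, degree matrix `D`, transition matrix `P = D⁻¹A` and volume
`vol = Σᵢ dᵢ` is represented by the closed-form random-walk co-occurrence
matrix

    M    = vol / (b·T) · (Σ_{r=1..T} Pʳ) D⁻¹
    PPMI = max(log M, 0)

with context window `T = 10` and negative-sampling constant `b = 1` by
default. Entry `M[i,j]` is proportional to the probability that a length-
≤T random walk starting at gene *i* visits gene *j*, normalised so that
`log M` is a pointwise mutual information. Clamping at zero keeps
positively associated pairs only. `PPMI` captures higher-order proximity
that the bare adjacency matrix misses. The natural logarithm is used, and
entries with `M = 0` are set to 0 directly rather than clamped from −∞ to
avoid spurious floating-point warnings. Every node must have degree ≥ 1
(`D` must be invertible); matrices are dense (the package targets
desk-scale networks of 10²–10⁴ nodes).

**2. Gene embedding (orthonormal NMTF).** The PPMI matrix `X` is
decomposed as

    X ≈ P S Gᵀ,   P, S, G ≥ 0,   GᵀG = I

by minimising the Frobenius objective `‖X − P S Gᵀ‖²`. Rows of `P·S` are
the gene embedding vectors; columns of `G` are the basis of the space.
The orthonormality constraint on `G` minimises colinearity between basis
vectors, which is what makes the basis usable for projecting other
entities (annotations) into the same space.

The solver is a fixed-point iteration of multiplicative updates from a
deterministic SVD initialisation (`P₀ = |U_k|`, `S₀ = Σ_k`, `G₀ = |V_k|`
from the truncated SVD), so the whole fit is reproducible bit-for-bit
with no random state. The updates are

    P ← P ∘ (X G Sᵀ) ⊘ (P S GᵀG Sᵀ)
    S ← S ∘ (PᵀX G) ⊘ (PᵀP S GᵀG)
    G ← G ∘ sqrt( (XᵀP S) ⊘ (G GᵀXᵀP S) )

with denominators stabilised by ε = 1e−12. The square root on the `G`
update is the standard damping for an orthonormally constrained factor:
the undamped quotient overshoots and makes the error oscillate (we
observed divergence on PPMI inputs), while the damped form descends
monotonically. `GᵀG` is kept explicitly in the `S` denominator rather
than assumed to be `I`, which is safer while orthonormality is only
approximate; the residual `‖GᵀG − I‖_F` is reported as a diagnostic, not
enforced as a hard constraint.

Fit quality is the relative square error
`RSE = ‖X − P S Gᵀ‖²_F / ‖X‖²_F`. Iteration stops when the relative RSE
improvement falls below `tol = 1e−6`, when the RSE would increase (the
previous factors are kept, so the recorded trace is non-increasing), or
after `max_iter = 500` rounds.

**3. Annotation embedding and the FMM.** Given the binary annotation ×
gene incidence matrix `A` (aligned to the network's node order),
annotations are embedded by solving `A ≈ U Gᵀ`:

    U = A · pinv(Gᵀ)

which reduces to `U = A G` when `G` is exactly orthonormal (the
pseudoinverse form is used because orthonormality is approximate). The
**Functional Mapping Matrix** of a space is the symmetric matrix of
pairwise cosine distances between annotation vectors,
`FMM[i,j] = 1 − cos(uᵢ, uⱼ) ∈ [0, 2]`, with zero diagonal. Cosine
distance is normalised, so FMMs from different spaces are directly
comparable with no further normalisation. A zero annotation vector (an
annotation with no genes in the network, possible only with
`min_genes = 0`) is assigned distance 1 to everything and flagged.

*Dimensionality.* The embedding dimensionality `k` is chosen by tracking
the RSE between FMMs at consecutive points of a `k` grid: the chosen `k`
is the smallest grid point after which every later consecutive RSE
changes by less than `rel_tol = 5%` (the plateau start). If the RSE is
still changing at the end of the grid the largest `k` is returned with a
warning flag. The comparison is between *consecutive* dimensions; an
alternative (each dimension against the largest) exists but is not
implemented.

**4. Movement between two spaces.** For a control and a case space
restricted to their common annotations,

    D = FMM_control − FMM_case.

`D[i,j] > 0` means the pair moved **closer** in the case space, `< 0`
means it moved apart. Over the distribution of unordered off-diagonal
pair values, pairs at or above the 95th percentile are "moving
significantly closer" and at or below the 5th percentile "moving
significantly apart" (linear-interpolation percentiles, inclusive
comparisons — so each set is ~5% of pairs for continuous values). The
**total movement** of annotation *i* is `‖D[i]‖₂` (diagonal excluded).
Annotations at or above `mean + 2·sd` of the total-movement distribution
are **shifted**, at or below `mean − 2·sd` **stable**. The standard
deviation is the population formula (`ddof = 0`; the totals are treated
as the full distribution, not a sample), configurable.

*Gene scoring.* For gene `g` (embedding row of `P·S`) and shifted
annotation `a`, the movement is
`m(g,a) = |cosdist_control(g,a) − cosdist_case(g,a)|`; a gene's score is
`max_a m(g,a)`, and genes at or above the 95th percentile of the score
distribution are predicted as condition-related. Genes are restricted to
the intersection of the two node orders.

**Supporting statistics.** Condition-related annotations are defined by
hypergeometric enrichment of a seed gene set (e.g. known oncogenes)
against an explicit background, with Benjamini–Hochberg correction at
α = 0.05; depletion uses the lower tail of the same distribution. The
background is a required argument (corpus vs network universes differ and
the caller must choose). Functional organization of a space is assessed
by (i) clustering annotations on the FMM with PAM k-medoids
(deterministic BUILD initialisation + best-improvement swaps;
`k = round(sqrt(n/2))` by default) and comparing mean within- vs
between-cluster Lin semantic similarity (the *fold*, with a one-sided
Mann–Whitney U test), and (ii) the Pearson correlation between cosine
distance and Lin similarity over all annotation pairs (negative when
organized). Lin similarity uses corpus-derived information content with
ancestor propagation over `is_a` links only, per-namespace roots, natural
log, and lexicographic tie-breaks for the maximally informative common
ancestor; the IC corpus is the same annotation table used for embedding.
Mann–Whitney tests use the exact distribution for small samples and the
tie-corrected normal approximation otherwise (scipy's automatic rule).

## Synthetic data: what it emulates and what it does not

Because the real inputs (a proteome-scale interaction network, tissue
expression lists, a GO release, a curated oncogene list) are large
external snapshots, the package ships a generator that reproduces the
features the method actually relies on, at desk scale:

* **Control network** — planted-partition graph: 5 modules × 30 genes,
  within-module edge probability 0.3, between-module 0.01, plus a
  spanning cycle over modules (connectivity) and an attachment edge for
  any isolated gene. Modules play the role of functional units
  (pathways/complexes).
* **Annotations + toy ontology** — each term annotates genes of one
  module plus a small fraction of outside genes ("leak"), under a
  two-level ontology (root → one parent per module → terms), so
  same-module terms have an informative common ancestor and cross-module
  terms meet only at the root. Two regimes are used:
  - *dense* (default; 4 terms/module, coverage 0.75, leak 0.05):
    coherent, heavily annotated processes — the regime of the
    perturbation-recovery experiment;
  - *corpus-like* (`CORPUS_ANNOTATIONS`: 10 terms/module, coverage 0.10
    — an exact disjoint partition of each module — leak 0.02): a
    genome-wide annotation corpus of many small, non-redundant terms —
    the regime of the functional-organization baselines. The distinction
    matters: if related terms share most of their genes, their embedding
    vectors nearly coincide in *any* space and clusters remain
    semantically coherent even on a randomized network; only
    low-redundancy terms make "fold ≈ 1 after rewiring" the correct
    expectation.
* **Randomized twin** — degree-preserving double-edge-swap rewiring
  (10×|E| swaps), the no-organization null.
* **Perturbed (case) twin** — a fraction (intensity 0.75) of the edges
  incident to one target module are re-routed by degree-preserving swaps
  against inter-module edges, so the module's internal structure
  genuinely dissolves into random positions while (a) the degree
  sequence is exactly preserved and (b) the internal edge sets of all
  untouched modules are bit-identical between control and case. The
  target module's annotations and genes are the planted ground truth.

All stages derive their randomness from a single seed
(`stage_seed = seed + stage offset`); scenarios are bit-reproducible, and
collection iteration never feeds seeded samplers (a hash-order leak would
silently break reproducibility).

What the generator does **not** emulate: scale-free degree
distributions, the depth and multiple inheritance of the real GO DAG,
evidence-code heterogeneity, annotation incompleteness bias, or
proteome-scale `n`. Passing tests therefore demonstrate correctness of
the machinery and qualitative recoverability of planted signal, not
effect sizes on real tissues.

## Reference experiments

* **Percentile construction** — two synthetic 200-annotation FMMs with
  i.i.d. uniform entries; the closer-pair rule must select 5% of the
  19 900 pairs (it does, by construction, for continuous values).
* **Randomized-network fold** — corpus-regime annotations on a rewired
  network; the intra/inter Lin fold is averaged over 30 seeds (per-seed
  sd ≈ 0.16, so 30 seeds put the standard error near 0.03). Expected
  value ≈ 1 (no organization).
* **Perturbation recovery** — 20 scenario seeds (dense regime, k = 20).
  Per-seed shifted sets are small (0–2 of 20 terms pass the 2-sd rule),
  so evidence is pooled across seeds: one rank test on all total
  movements (perturbed-module terms vs others), one hypergeometric test
  on summed shifted-set counts, and the mean over seeds of the fraction
  of predicted genes falling in the perturbed module.

Embedding dimensionality for the experiments is k = 20 with a
{10, 20, 30, 40} grid for the plateau search — a deliberate desk-scale
reduction of the method's usual 50–300 grid, matched to 150-gene
networks.

## Numerical choices and degenerate inputs

* Cosine distance to a zero vector: defined as 1 and flagged.
* All pairwise movements identical: percentile thresholds coincide, both
  significant-pair sets degenerate to all pairs, flagged.
* Zero variance of total movements (identical spaces): no shifted/stable
  calls, flagged, and gene prediction returns an empty set rather than
  predicting everything.
* All pairwise Lin similarities identical: fold reported as 1 with a
  degeneracy flag; Pearson r reported as 0 with the same flag.
* Between-cluster Lin similarity exactly 0 with non-zero within: fold is
  undefined (infinite organization) and raises — encountered only with
  leak-free toy ontologies.
* PAM k-medoids is deterministic; the seed recorded in reports is
  provenance only.
* MICA ties are broken lexicographically (the Lin value is unaffected).
* `k = n` clustering puts every annotation in its own cluster; the
  organization report then raises (no within-cluster pairs).

## Known limitations

* Dense linear algebra only; networks beyond ~10⁴ nodes need a sparse
  backend that is out of scope.
* NMTF converges to a local optimum; the SVD initialisation makes the
  solution deterministic but not globally optimal, and two spaces are
  fitted independently — residual fit noise enters the movement matrix
  and is the main driver of false shifted calls at desk scale.
* Only `is_a` ontology relations are traversed; `part_of`/`regulates`
  would change IC and Lin values on real GO data.
* The 2-sd shifted rule is fragile for small annotation sets (< ~50
  terms) and with strongly bimodal movement distributions, where
  `mean + 2·sd` can exceed the maximum.
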