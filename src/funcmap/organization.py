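"""Is an embedding space functionally organized?

A space is called functionally organized when annotations that are close
in it (low cosine distance in the FMM) are also semantically similar (high
Lin similarity). Two complementary checks are implemented:

* cluster the annotations on the FMM with k-medoids (PAM on the
  precomputed distance matrix, k = round(sqrt(n/2)) by default) and
  compare the mean within-cluster to the mean between-cluster Lin
  similarity (the intra/inter "fold", with a one-sided Mann-Whitney U
  test of within > between);
* correlate, over all annotation pairs, the cosine distance with the Lin
  similarity (functional organization shows as a negative Pearson r).

A third check works at the gene level: annotation vectors should sit
closer to the embedding vectors of the genes they annotate than to other
genes' vectors (one-sided Mann-Whitney U on pooled cosine distances).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .fmm import FMM, AnnotationEmbedding, cosine_distance_matrix
from .graph_io import AnnotationMatrix, DataError
from .nmtf import TriFactorization
from .semantic import ICTable, Ontology, lin_similarity

__all__ = [
    "kmedoids_pam",
    "cluster_annotations",
    "OrganizationReport",
    "organization_report",
    "gene_function_proximity_test",
]


def kmedoids_pam(
    dist: np.ndarray, k: int, max_iter: int = 200
) -> tuple[np.ndarray, np.ndarray]:
    """PAM k-medoids on a precomputed distance matrix.

    Deterministic: BUILD initialisation (greedy cost reduction, index-order
    tie-break) followed by best-improvement SWAP passes until no swap
    lowers the total cost. Returns (labels, medoid indices).
    """
    n = dist.shape[0]
    if dist.shape != (n, n):
        raise DataError("distance matrix must be square")
    if not 1 <= k <= n:
        raise DataError(f"k must be in [1, {n}], got {k}")
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        cur = dist[:, medoids].min(axis=1)
        best_gain, best_j = -np.inf, None
        for j in range(n):
            if j in medoids:
                continue
            gain = np.maximum(cur - dist[:, j], 0.0).sum()
            if gain > best_gain:
                best_gain, best_j = gain, j
        medoids.append(best_j)
    medoids = sorted(medoids)

    def cost(meds: list[int]) -> float:
        return float(dist[:, meds].min(axis=1).sum())

    best = cost(medoids)
    for _ in range(max_iter):
        improved = False
        for mi, m in enumerate(list(medoids)):
            for j in range(n):
                if j in medoids:
                    continue
                cand = sorted(medoids[:mi] + [j] + medoids[mi + 1 :])
                c = cost(cand)
                if c < best - 1e-12:
                    medoids, best, improved = cand, c, True
                    break
            if improved:
                break
        if not improved:
            break
    med_arr = np.array(medoids)
    labels = np.argmin(dist[:, med_arr], axis=1)
    labels[med_arr] = np.arange(len(med_arr))  # medoids belong to their own cluster
    return labels, med_arr


def _auto_k(n: int) -> int:
    """Rule-of-thumb cluster count k = round(sqrt(n/2))."""
    return max(2, round(math.sqrt(n / 2)))


def cluster_annotations(fmm: FMM, k: int | str = "auto", seed: int = 0) -> dict:
    """k-medoids clustering of annotations on their FMM distances.

    ``k="auto"`` uses the rule of thumb round(sqrt(n/2)). The ``seed`` is
    recorded for provenance; PAM with BUILD initialisation is deterministic
    and does not consume it.
    """
    n = len(fmm.annotation_order)
    if k == "auto":
        k = _auto_k(n)
    if not isinstance(k, int) or k < 1:
        raise DataError(f"invalid cluster count {k!r}")
    if k > n:
        raise DataError(f"k={k} exceeds the number of annotations {n}")
    labels, _ = kmedoids_pam(fmm.values, k)
    return {a: int(c) for a, c in zip(fmm.annotation_order, labels)}


@dataclass(frozen=True)
class OrganizationReport:
    """Functional-organization diagnostics of one embedding space."""

    k_clusters: int
    clusters: dict  # annotation -> cluster index
    intra: float  # mean Lin similarity over within-cluster pairs
    inter: float  # mean Lin similarity over between-cluster pairs
    fold: float  # intra / inter
    mw_p: float  # one-sided Mann-Whitney U p (within > between)
    pearson_r: float  # cosine distance vs Lin similarity over all pairs
    pearson_p: float
    seed: int
    degenerate: bool = False


def organization_report(
    fmm: FMM,
    ic: ICTable,
    ont: Ontology,
    seed: int = 0,
    k: int | str = "auto",
) -> OrganizationReport:
    """Cluster-level and correlation-level functional-organization report."""
    anns = fmm.annotation_order
    clusters = cluster_annotations(fmm, k=k, seed=seed)
    labels = np.array([clusters[a] for a in anns])
    n = len(anns)
    lin_vals, cos_vals, within = [], [], []
    for i in range(n):
        for j in range(i + 1, n):
            lin_vals.append(lin_similarity(anns[i], anns[j], ic, ont))
            cos_vals.append(fmm.values[i, j])
            within.append(labels[i] == labels[j])
    lin_arr = np.array(lin_vals)
    cos_arr = np.array(cos_vals)
    within_arr = np.array(within)
    if not within_arr.any():
        raise DataError("no within-cluster pairs; cannot measure intra similarity")
    if not (~within_arr).any():
        raise DataError("no between-cluster pairs")
    intra = float(lin_arr[within_arr].mean())
    inter = float(lin_arr[~within_arr].mean())
    degenerate = False
    if np.ptp(lin_arr) == 0:
        # every pair equally similar: organization is unmeasurable
        fold, degenerate = 1.0, True
    elif inter == 0:
        raise DataError("zero between-cluster similarity; fold undefined")
    else:
        fold = intra / inter
    if np.ptp(lin_arr) == 0 or np.ptp(cos_arr) == 0:
        pearson_r, pearson_p, degenerate = 0.0, 1.0, True
    else:
        pearson_r, pearson_p = stats.pearsonr(cos_arr, lin_arr)
    if np.ptp(lin_arr) == 0:
        mw_p = 1.0
    else:
        mw_p = float(
            stats.mannwhitneyu(
                lin_arr[within_arr], lin_arr[~within_arr], alternative="greater"
            ).pvalue
        )
    return OrganizationReport(
        k_clusters=int(labels.max()) + 1,
        clusters=clusters,
        intra=intra,
        inter=inter,
        fold=float(fold),
        mw_p=mw_p,
        pearson_r=float(pearson_r),
        pearson_p=float(pearson_p),
        seed=seed,
        degenerate=degenerate,
    )


def gene_function_proximity_test(
    f: TriFactorization, emb: AnnotationEmbedding, A: AnnotationMatrix
) -> float:
    """Are annotation vectors closer to their own genes than to other genes?

    For every annotation, the cosine distances from its embedding vector to
    the embedding vectors (rows of P S) of its annotated genes go into one
    sample and the distances to all other genes into the other; the pooled
    samples are compared with a one-sided Mann-Whitney U test (alternative:
    annotated genes are closer). Returns the p-value.
    """
    if A.gene_order != f.node_order:
        raise DataError("annotation matrix gene order is not aligned to the factorization")
    if A.annotation_order != emb.annotation_order:
        raise DataError("annotation matrix and embedding annotation orders differ")
    gene_vecs = f.gene_embeddings
    dists = cosine_distance_matrix(emb.U, gene_vecs)
    annotated_d, other_d = [], []
    used = 0
    for i in range(A.values.shape[0]):
        mask = A.values[i] > 0
        if not mask.any() or mask.all():
            continue
        used += 1
        annotated_d.extend(dists[i, mask])
        other_d.extend(dists[i, ~mask])
    if used == 0:
        raise DataError("no annotation with both annotated and non-annotated genes")
    return float(
        stats.mannwhitneyu(annotated_d, other_d, alternative="less").pvalue
    )
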