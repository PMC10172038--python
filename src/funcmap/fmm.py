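"""Annotation embedding and the Functional Mapping Matrix (FMM).

Given a fitted gene embedding space with basis G (columns of the NMTF
factor G) and the binary annotation x gene incidence matrix A, each
annotation is embedded into the same space by solving A ~= U G^T for U:

    U = A pinv(G^T)

(the Moore-Penrose pseudoinverse; when G is exactly column-orthonormal
this reduces to U = A G). Row u_i of U is the embedding vector of
annotation a_i.

The FMM of a space is the symmetric matrix of pairwise cosine distances
between all annotation embedding vectors, FMM[i, j] = cosdist(u_i, u_j).
Because cosine distance is normalised to [0, 2], FMMs of different spaces
(e.g. cancer vs control, or the same network at different dimensionalities)
are directly comparable without further normalisation.

Comparing the FMMs of the same network embedded at increasing
dimensionality gives a data-driven choice of dimensionality: the smallest
k after which the between-consecutive-dimension RSE stops decreasing
(plateaus).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .graph_io import AnnotationMatrix, DataError
from .nmtf import TriFactorization

__all__ = [
    "AnnotationEmbedding",
    "FMM",
    "embed_annotations",
    "compute_fmm",
    "fmm_rse",
    "align_fmms",
    "DimensionalityReport",
    "optimal_dimensionality",
    "cosine_distance_matrix",
]


@dataclass(frozen=True)
class AnnotationEmbedding:
    """Annotation embedding vectors (rows of U; may contain negatives)."""

    U: np.ndarray
    annotation_order: tuple[str, ...]
    k: int

    def __post_init__(self) -> None:
        if self.U.shape != (len(self.annotation_order), self.k):
            raise DataError("embedding shape does not match annotation order / k")


@dataclass(frozen=True)
class FMM:
    """Symmetric annotation x annotation cosine-distance matrix, zero diagonal."""

    values: np.ndarray
    annotation_order: tuple[str, ...]

    def __post_init__(self) -> None:
        m = len(self.annotation_order)
        v = self.values
        if v.shape != (m, m):
            raise DataError("FMM shape does not match annotation order")
        if not np.allclose(v, v.T, atol=1e-8):
            raise DataError("FMM must be symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise DataError("FMM diagonal must be zero")
        if np.any(v < -1e-12) or np.any(v > 2 + 1e-12):
            raise DataError("FMM entries must lie in [0, 2]")

    def restrict(self, annotations: tuple[str, ...]) -> "FMM":
        """Reorder/subset to the given annotation ids (all must be present)."""
        idx = {a: i for i, a in enumerate(self.annotation_order)}
        missing = [a for a in annotations if a not in idx]
        if missing:
            raise DataError(f"annotations not in FMM: {missing[:5]}")
        sel = np.array([idx[a] for a in annotations])
        return FMM(values=self.values[np.ix_(sel, sel)], annotation_order=tuple(annotations))


def embed_annotations(f: TriFactorization, A: AnnotationMatrix) -> AnnotationEmbedding:
    """Embed annotations into a fitted gene space: U = A pinv(G^T)."""
    if A.gene_order != f.node_order:
        raise DataError("annotation matrix gene order is not aligned to the factorization")
    u = A.values @ np.linalg.pinv(f.G.T)
    return AnnotationEmbedding(U=u, annotation_order=A.annotation_order, k=f.k)


def cosine_distance_matrix(rows_a: np.ndarray, rows_b: np.ndarray) -> np.ndarray:
    """Pairwise cosine distances 1 - cos(u, v) between two row sets.

    Zero rows are maximally uninformative: their distance to anything is
    defined as 1.
    """
    na = np.linalg.norm(rows_a, axis=1)
    nb = np.linalg.norm(rows_b, axis=1)
    za, zb = na == 0, nb == 0
    sim = (rows_a @ rows_b.T) / np.outer(np.where(za, 1.0, na), np.where(zb, 1.0, nb))
    dist = 1.0 - sim
    dist[za, :] = 1.0
    dist[:, zb] = 1.0
    return np.clip(dist, 0.0, 2.0)


def compute_fmm(emb: AnnotationEmbedding, max_zero_fraction: float = 0.5) -> FMM:
    """Pairwise cosine-distance matrix over annotation embedding vectors.

    Zero embedding vectors get distance 1 to every other vector (flagged by
    a warning); more than ``max_zero_fraction`` zero rows is an error, and
    an all-zero embedding is always an error.
    """
    norms = np.linalg.norm(emb.U, axis=1)
    zero = norms == 0
    if zero.all():
        raise DataError("all annotation embedding vectors are zero")
    if zero.mean() > max_zero_fraction:
        raise DataError(
            f"{zero.sum()} of {zero.size} annotation vectors are zero "
            f"(> max_zero_fraction={max_zero_fraction})"
        )
    if zero.any():
        warnings.warn(f"{zero.sum()} zero annotation vectors; their distances set to 1")
    d = cosine_distance_matrix(emb.U, emb.U)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return FMM(values=d, annotation_order=emb.annotation_order)


def align_fmms(f1: FMM, f2: FMM) -> tuple[FMM, FMM]:
    """Restrict two FMMs to their common annotations, in sorted order."""
    common = sorted(set(f1.annotation_order) & set(f2.annotation_order))
    if not common:
        raise DataError("FMMs share no annotations")
    common_t = tuple(common)
    return f1.restrict(common_t), f2.restrict(common_t)


def fmm_rse(f1: FMM, f2: FMM) -> float:
    """RSE between two FMMs over the same annotation order: ||F1-F2||^2/||F1||^2."""
    if f1.annotation_order != f2.annotation_order:
        raise DataError("FMMs are not aligned; use align_fmms first")
    denom = np.linalg.norm(f1.values) ** 2
    if denom == 0:
        raise DataError("first FMM is the zero matrix; RSE undefined")
    return float(np.linalg.norm(f1.values - f2.values) ** 2 / denom)


@dataclass(frozen=True)
class DimensionalityReport:
    """Outcome of the RSE-plateau dimensionality search."""

    chosen_k: int
    dims: tuple[int, ...]
    step_rse: tuple[float, ...]  # step_rse[i] = RSE(FMM at dims[i], FMM at dims[i+1])
    rel_tol: float
    plateau_found: bool


def optimal_dimensionality(
    fmms_by_dim: dict[int, FMM], rel_tol: float = 0.05
) -> DimensionalityReport:
    """Choose the embedding dimensionality where the FMM stops changing.

    The FMMs at consecutive grid dimensions are compared by RSE (after
    restriction to the common annotation set); the chosen dimensionality is
    the smallest one from which every later consecutive RSE changes by a
    relative amount below ``rel_tol``. If the RSE keeps changing through
    the whole grid, the largest dimension is returned with
    ``plateau_found=False``.
    """
    dims = tuple(sorted(fmms_by_dim))
    if len(dims) < 3:
        raise DataError("need at least 3 dimension points")
    common = set(fmms_by_dim[dims[0]].annotation_order)
    for d in dims[1:]:
        common &= set(fmms_by_dim[d].annotation_order)
    if not common:
        raise DataError("no annotation shared across all dimensionalities")
    order = tuple(sorted(common))
    restricted = {d: fmms_by_dim[d].restrict(order) for d in dims}
    steps = tuple(
        fmm_rse(restricted[dims[i]], restricted[dims[i + 1]]) for i in range(len(dims) - 1)
    )

    def rel_change(a: float, b: float) -> float:
        if a == 0:
            return 0.0 if b == 0 else np.inf
        return abs(b - a) / a

    chosen = None
    for i in range(len(steps)):
        if all(rel_change(steps[j], steps[j + 1]) < rel_tol for j in range(i, len(steps) - 1)):
            chosen = dims[i]
            break
    if chosen is None:  # unreachable (i = len(steps)-1 always qualifies) but kept safe
        chosen = dims[-1]
    # a plateau that only "starts" at the final comparison is no plateau
    plateau_found = chosen != dims[len(steps) - 1] or len(steps) == 1
    if not plateau_found:
        warnings.warn("FMM RSE still decreasing at the largest dimension; no plateau")
        chosen = dims[-1]
    return DimensionalityReport(
        chosen_k=chosen, dims=dims, step_rse=steps, rel_tol=rel_tol,
        plateau_found=plateau_found,
    )
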