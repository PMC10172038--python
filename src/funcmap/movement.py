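"""Movement of annotation vectors between two embedding spaces.

Given the FMMs of a control and a case (e.g. cancer) space over the same
annotations, the movement matrix is

    D = FMM_control - FMM_case

so D[i, j] > 0 means annotations i and j are *closer* in the case space
than in control, D[i, j] < 0 means they moved apart. Significance of a
pair's movement is defined by the 5th/95th percentiles of the off-diagonal
pair distribution (inclusive thresholds). The "total movement" of an
annotation is the Euclidean norm of its row of D; annotations more than
two standard deviations above (below) the mean of the total-movement
distribution are called shifted (stable).

Genes are scored against the shifted annotations: for gene g and shifted
annotation a, movement is the absolute change of their cosine distance
between the two spaces; a gene's score is its maximum movement over the
shifted annotations, and genes at or above the 95th percentile of the
score distribution are predicted as condition-related.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fmm import FMM, AnnotationEmbedding, cosine_distance_matrix
from .graph_io import DataError
from .nmtf import TriFactorization

__all__ = [
    "MovementReport",
    "pairwise_movement",
    "SignificantPairs",
    "significant_pairs",
    "total_movement",
    "Classification",
    "classify_shifted_stable",
    "GeneMovementReport",
    "gene_movement_scores",
]


@dataclass(frozen=True)
class MovementReport:
    """Movement matrix D = FMM_control - FMM_case over a shared annotation order."""

    D: np.ndarray
    annotation_order: tuple[str, ...]

    def __post_init__(self) -> None:
        m = len(self.annotation_order)
        if self.D.shape != (m, m):
            raise DataError("movement matrix shape does not match annotation order")


def pairwise_movement(fmm_control: FMM, fmm_case: FMM) -> MovementReport:
    """Elementwise FMM difference; inputs must already share an annotation order.

    Use :func:`funcmap.fmm.align_fmms` to reduce two FMMs to their common
    annotations first. Positive entries mean a pair moved closer in the
    case space.
    """
    if fmm_control.annotation_order != fmm_case.annotation_order:
        raise DataError("FMMs are not aligned; use align_fmms first")
    if not fmm_control.annotation_order:
        raise DataError("empty annotation set")
    return MovementReport(
        D=fmm_control.values - fmm_case.values,
        annotation_order=fmm_control.annotation_order,
    )


@dataclass(frozen=True)
class SignificantPairs:
    """Pairs moving significantly closer / apart, with the percentile thresholds."""

    closer: frozenset  # pairs with D >= hi threshold (closer in case space)
    apart: frozenset  # pairs with D <= lo threshold
    lo_threshold: float
    hi_threshold: float
    n_pairs: int
    degenerate: bool = False


def _offdiag_pairs(report: MovementReport) -> tuple[list, np.ndarray]:
    anns = report.annotation_order
    m = len(anns)
    iu = np.triu_indices(m, k=1)
    pairs = [(anns[i], anns[j]) for i, j in zip(*iu)]
    return pairs, report.D[iu]


def significant_pairs(
    report: MovementReport, lo: float = 5.0, hi: float = 95.0
) -> SignificantPairs:
    """Percentile rule over the unordered off-diagonal pair distribution.

    Thresholds are linear-interpolation percentiles and comparisons are
    inclusive, so for continuous movement values each set holds ~5% of all
    pairs. If every movement is identical the thresholds coincide and both
    sets degenerate to all pairs (flagged).
    """
    pairs, vals = _offdiag_pairs(report)
    if len(vals) < 20:
        raise DataError(f"only {len(vals)} pairs; percentile thresholds are meaningless")
    lo_t = float(np.percentile(vals, lo))
    hi_t = float(np.percentile(vals, hi))
    closer = frozenset(p for p, v in zip(pairs, vals) if v >= hi_t)
    apart = frozenset(p for p, v in zip(pairs, vals) if v <= lo_t)
    degenerate = bool(np.ptp(vals) == 0)
    return SignificantPairs(
        closer=closer, apart=apart, lo_threshold=lo_t, hi_threshold=hi_t,
        n_pairs=len(pairs), degenerate=degenerate,
    )


def total_movement(report: MovementReport) -> dict:
    """Euclidean norm of each annotation's movement vector (its row of D)."""
    d = report.D.copy()
    np.fill_diagonal(d, 0.0)  # diagonal excluded from the movement vector
    norms = np.linalg.norm(d, axis=1)
    return {a: float(v) for a, v in zip(report.annotation_order, norms)}


@dataclass(frozen=True)
class Classification:
    """Shifted/stable annotation calls from the total-movement distribution."""

    shifted: frozenset
    stable: frozenset
    mean: float
    sd: float
    n_sd: float
    degenerate: bool = False


def classify_shifted_stable(totals: dict, n_sd: float = 2.0, ddof: int = 0) -> Classification:
    """Call annotations shifted (>= mean + n_sd*sd) or stable (<= mean - n_sd*sd).

    The standard deviation is the population formula by default (the totals
    are the full distribution, not a sample); ``ddof=1`` switches to the
    sample formula.
    """
    if len(totals) < 3:
        raise DataError("need at least 3 annotations to classify")
    vals = np.array(list(totals.values()), dtype=float)
    mean = float(vals.mean())
    sd = float(vals.std(ddof=ddof))
    if sd == 0:
        return Classification(
            shifted=frozenset(), stable=frozenset(), mean=mean, sd=sd,
            n_sd=n_sd, degenerate=True,
        )
    hi = mean + n_sd * sd
    lo = mean - n_sd * sd
    shifted = frozenset(a for a, v in totals.items() if v >= hi)
    stable = frozenset(a for a, v in totals.items() if v <= lo)
    return Classification(shifted=shifted, stable=stable, mean=mean, sd=sd, n_sd=n_sd)


@dataclass(frozen=True)
class GeneMovementReport:
    """Per-gene movement scores against the shifted annotations."""

    scores: dict  # gene -> max |movement| over shifted annotations
    threshold: float  # 95th percentile of the score distribution
    predicted: frozenset  # genes with score >= threshold
    percentile: float
    degenerate: bool = False


def gene_movement_scores(
    f_control: TriFactorization,
    f_case: TriFactorization,
    emb_control: AnnotationEmbedding,
    emb_case: AnnotationEmbedding,
    shifted: set | frozenset,
    percentile: float = 95.0,
) -> GeneMovementReport:
    """Score genes by their maximal movement relative to shifted annotations.

    Genes are restricted to the intersection of the two node orders. For
    each gene and each shifted annotation the movement is the absolute
    difference of their cosine distances in the two spaces; a gene's score
    is the maximum over the shifted annotations, and genes at or above the
    ``percentile``-th percentile of the score distribution are predicted.
    An all-equal score distribution (e.g. identical spaces) yields an empty
    prediction with ``degenerate=True``.
    """
    shifted = sorted(shifted)
    if not shifted:
        raise DataError("shifted annotation set is empty")
    for name, order in (
        ("control", emb_control.annotation_order),
        ("case", emb_case.annotation_order),
    ):
        missing = set(shifted) - set(order)
        if missing:
            raise DataError(f"shifted annotations missing from the {name} embedding: "
                            f"{sorted(missing)[:5]}")
    genes = sorted(set(f_control.node_order) & set(f_case.node_order))
    if not genes:
        raise DataError("the two spaces share no genes")

    def space_dists(f: TriFactorization, emb: AnnotationEmbedding) -> np.ndarray:
        gidx = {g: i for i, g in enumerate(f.node_order)}
        aidx = {a: i for i, a in enumerate(emb.annotation_order)}
        gv = f.gene_embeddings[[gidx[g] for g in genes]]
        av = emb.U[[aidx[a] for a in shifted]]
        return cosine_distance_matrix(gv, av)  # genes x shifted

    move = np.abs(space_dists(f_control, emb_control) - space_dists(f_case, emb_case))
    scores = move.max(axis=1)
    threshold = float(np.percentile(scores, percentile))
    degenerate = bool(np.ptp(scores) == 0)
    if degenerate:
        predicted: frozenset = frozenset()
    else:
        predicted = frozenset(g for g, sc in zip(genes, scores) if sc >= threshold)
    return GeneMovementReport(
        scores={g: float(sc) for g, sc in zip(genes, scores)},
        threshold=threshold,
        predicted=predicted,
        percentile=percentile,
        degenerate=degenerate,
    )
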