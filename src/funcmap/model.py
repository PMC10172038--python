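"""High-level model: compare the functional organization of two networks.

:class:`FunctionalMapping` bundles the whole pipeline behind the familiar
model/results pattern: construct it from a control network, a case
network and an annotation table, call :meth:`~FunctionalMapping.fit`, and
read the comparison off the returned :class:`FunctionalMappingResults`
(FMMs, the movement matrix, shifted/stable annotation calls, per-gene
movement scores and a text ``summary()``).

Every stage is also available separately in the corresponding module
(:mod:`~funcmap.ppmi`, :mod:`~funcmap.nmtf`, :mod:`~funcmap.fmm`,
:mod:`~funcmap.movement`, ...) for custom workflows.
"""

from __future__ import annotations

from dataclasses import dataclass

from .fmm import FMM, AnnotationEmbedding, align_fmms, compute_fmm, embed_annotations
from .graph_io import AnnotationMatrix, AnnotationTable, Network, annotation_matrix
from .movement import (
    Classification,
    GeneMovementReport,
    MovementReport,
    SignificantPairs,
    classify_shifted_stable,
    gene_movement_scores,
    pairwise_movement,
    significant_pairs,
    total_movement,
)
from .nmtf import NMTF, TriFactorization
from .ppmi import ppmi_matrix

__all__ = ["FunctionalMapping", "FunctionalMappingResults", "SpaceFit"]


@dataclass(frozen=True)
class SpaceFit:
    """One embedded space: factorization, annotation embedding and FMM."""

    factorization: TriFactorization
    annotation_matrix: AnnotationMatrix
    embedding: AnnotationEmbedding
    fmm: FMM


@dataclass(frozen=True)
class FunctionalMappingResults:
    """Everything the control-vs-case comparison produced."""

    control: SpaceFit
    case: SpaceFit
    fmm_control: FMM  # aligned to the common annotation set
    fmm_case: FMM
    movement: MovementReport
    pairs: SignificantPairs
    totals: dict  # annotation -> total movement
    classification: Classification
    gene_report: GeneMovementReport | None  # None when no annotation shifted

    @property
    def shifted(self) -> frozenset:
        return self.classification.shifted

    @property
    def stable(self) -> frozenset:
        return self.classification.stable

    def top_moved(self, n: int = 10) -> list[tuple[str, float]]:
        """Annotations ranked by total movement, largest first."""
        return sorted(self.totals.items(), key=lambda kv: -kv[1])[:n]

    def top_genes(self, n: int = 10) -> list[tuple[str, float]]:
        """Genes ranked by movement score, largest first."""
        if self.gene_report is None:
            return []
        return sorted(self.gene_report.scores.items(), key=lambda kv: -kv[1])[:n]

    def summary(self) -> str:
        cls = self.classification
        lines = [
            "Functional mapping comparison (control vs case)",
            "=" * 55,
            f"genes: control {len(self.control.factorization.node_order):>5d}"
            f"   case {len(self.case.factorization.node_order):>5d}",
            f"embedding dimensions (k)        {self.control.factorization.k:>8d}",
            f"final RSE control / case        "
            f"{self.control.factorization.final_rse:8.4f} / "
            f"{self.case.factorization.final_rse:8.4f}",
            f"annotations compared            {len(self.movement.annotation_order):>8d}",
            f"pairs closer / apart (5%/95%)   {len(self.pairs.closer):>8d} / "
            f"{len(self.pairs.apart):>8d}",
            f"total movement mean (sd)        {cls.mean:8.4f} ({cls.sd:.4f})",
            f"shifted / stable annotations    {len(cls.shifted):>8d} / {len(cls.stable):>8d}",
        ]
        if cls.shifted:
            lines.append("top shifted annotations:")
            for a, v in self.top_moved(5):
                mark = "*" if a in cls.shifted else " "
                lines.append(f"  {mark} {a:<20s} total movement {v:.4f}")
        if self.gene_report is not None:
            lines.append(
                f"predicted genes (>= {self.gene_report.percentile:.0f}th pct) "
                f"{len(self.gene_report.predicted):>8d}"
            )
            for g, v in self.top_genes(5):
                lines.append(f"    {g:<20s} movement score {v:.4f}")
        return "\n".join(lines)


class FunctionalMapping:
    """Control-vs-case functional comparison of two annotated networks.

    Parameters
    ----------
    control, case
        The two condition-specific networks (e.g. healthy tissue and
        cancer). Node sets may differ; annotations are compared on the
        common annotation universe and genes on the common gene set.
    annotations
        (annotation id, gene id) table covering both networks.
    n_dims
        Embedding dimensionality k of both spaces (default 20; desk-scale.
        Use :func:`funcmap.fmm.optimal_dimensionality` over a k grid to
        pick it in a data-driven way).
    window, negatives
        PPMI random-walk window T (default 10) and negative-sampling
        constant b (default 1).
    min_genes
        Drop annotations with fewer network genes than this (default 1).
    """

    def __init__(
        self,
        control: Network,
        case: Network,
        annotations: AnnotationTable,
        n_dims: int = 20,
        window: int = 10,
        negatives: int = 1,
        min_genes: int = 1,
    ):
        self.control = control
        self.case = case
        self.annotations = annotations
        self.n_dims = n_dims
        self.window = window
        self.negatives = negatives
        self.min_genes = min_genes

    @classmethod
    def from_files(
        cls,
        control_path: str,
        case_path: str,
        annotations_path: str,
        annotation_dialect: str = "two-column-tsv",
        **kwargs,
    ) -> "FunctionalMapping":
        from .graph_io import read_annotations, read_edge_list

        return cls(
            control=read_edge_list(control_path),
            case=read_edge_list(case_path),
            annotations=read_annotations(annotations_path, dialect=annotation_dialect),
            **kwargs,
        )

    def _fit_space(self, network: Network, max_iter: int, tol: float) -> SpaceFit:
        x = ppmi_matrix(network, window=self.window, negatives=self.negatives)
        fact = NMTF(x, self.n_dims).fit(max_iter=max_iter, tol=tol)
        amat = annotation_matrix(self.annotations, network.nodes, min_genes=self.min_genes)
        emb = embed_annotations(fact, amat)
        return SpaceFit(
            factorization=fact, annotation_matrix=amat, embedding=emb, fmm=compute_fmm(emb)
        )

    def fit(self, max_iter: int = 500, tol: float = 1e-6) -> FunctionalMappingResults:
        """Embed both networks, compare their FMMs and score the movement."""
        ctrl = self._fit_space(self.control, max_iter, tol)
        case = self._fit_space(self.case, max_iter, tol)
        fmm_c, fmm_x = align_fmms(ctrl.fmm, case.fmm)
        report = pairwise_movement(fmm_c, fmm_x)
        pairs = significant_pairs(report)
        totals = total_movement(report)
        classification = classify_shifted_stable(totals)
        gene_report = None
        if classification.shifted:
            gene_report = gene_movement_scores(
                ctrl.factorization,
                case.factorization,
                ctrl.embedding,
                case.embedding,
                classification.shifted,
            )
        return FunctionalMappingResults(
            control=ctrl,
            case=case,
            fmm_control=fmm_c,
            fmm_case=fmm_x,
            movement=report,
            pairs=pairs,
            totals=totals,
            classification=classification,
            gene_report=gene_report,
        )
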