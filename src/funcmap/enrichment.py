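"""Hypergeometric enrichment with Benjamini-Hochberg correction.

Used in two places: to define condition-related annotations from a seed
gene set (e.g. known oncogenes: every annotation is tested for
over-representation of seed genes against a background gene universe),
and to test whether the shifted/stable annotation sets are enriched or
depleted in a category of annotations (e.g. condition-related ones).

The upper-tail probability P(X >= k) of the hypergeometric distribution
with population N, K successes and draw size n is the enrichment p-value;
depletion uses the lower tail P(X <= k) of the same distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .graph_io import AnnotationTable, DataError

__all__ = [
    "hypergeom_upper_tail",
    "hypergeom_lower_tail",
    "bh_adjust",
    "EnrichmentResult",
    "enriched_annotations",
    "category_enrichment",
]


def _check_counts(k: int, K: int, n: int, N: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N):
        raise DataError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise DataError(f"k={k} outside [0, min(K={K}, n={n})]")


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    _check_counts(k, K, n, N)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeom_lower_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X <= k) for X ~ Hypergeometric(N, K, n) (depletion tail)."""
    _check_counts(k, K, n, N)
    return float(stats.hypergeom.cdf(k, N, K, n))


def bh_adjust(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, order-preserving."""
    if not pvals:
        return []
    for p in pvals:
        if not (0 < p <= 1):
            raise DataError(f"p-value outside (0, 1]: {p}")
    _, adj, _, _ = multipletests(pvals, method="fdr_bh")
    return [float(p) for p in adj]


@dataclass(frozen=True)
class EnrichmentResult:
    """One enrichment test: k of n drawn vs K of N background successes."""

    term: str
    k: int
    K: int
    n: int
    N: int
    p: float
    p_adj: float
    significant: bool


def enriched_annotations(
    selection: set,
    background: set,
    table: AnnotationTable,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Test every annotation for enrichment of ``selection`` genes.

    ``selection`` must be a subset of ``background``. For each annotation
    with at least one background gene: K = background genes it annotates,
    k = selection genes it annotates, n = |selection|, N = |background|.
    BH correction is applied across annotations; results are sorted by
    adjusted then raw p-value.
    """
    selection = set(selection)
    background = set(background)
    if not selection:
        raise DataError("selection is empty")
    if not selection <= background:
        raise DataError("selection is not a subset of the background")
    rows = []
    for ann in table.annotation_ids:
        genes = table.genes_of(ann) & background
        if not genes:
            continue
        k = len(genes & selection)
        rows.append((ann, k, len(genes)))
    if not rows:
        raise DataError("no annotation overlaps the background")
    n, N = len(selection), len(background)
    pvals = [hypergeom_upper_tail(k, K, n, N) for _, k, K in rows]
    adj = bh_adjust(pvals)
    results = [
        EnrichmentResult(
            term=ann, k=k, K=K, n=n, N=N, p=p, p_adj=pa, significant=pa <= alpha
        )
        for (ann, k, K), p, pa in zip(rows, pvals, adj)
    ]
    return sorted(results, key=lambda r: (r.p_adj, r.p, r.term))


def category_enrichment(
    selection: set,
    universe: set,
    category: set,
    alpha: float = 0.05,
    tail: str = "upper",
) -> EnrichmentResult:
    """Single hypergeometric test of a category within a selected item set.

    Items can be anything (here typically annotations: is the shifted set
    enriched in condition-related annotations?). ``tail="lower"`` tests
    depletion instead of enrichment.
    """
    selection = set(selection)
    universe = set(universe)
    if not selection <= universe:
        raise DataError("selection is not a subset of the universe")
    category = set(category) & universe
    k = len(selection & category)
    K, n, N = len(category), len(selection), len(universe)
    if tail == "upper":
        p = hypergeom_upper_tail(k, K, n, N)
    elif tail == "lower":
        p = hypergeom_lower_tail(k, K, n, N)
    else:
        raise DataError(f"unknown tail {tail!r}")
    return EnrichmentResult(
        term="category", k=k, K=K, n=n, N=N, p=p, p_adj=p, significant=p <= alpha
    )
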