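"""Orthonormality-constrained non-negative matrix tri-factorization.

The gene embedding space is obtained by decomposing the PPMI matrix X as

    X ~= P S G^T,   P, S, G >= 0,   G^T G = I,

minimising ||X - P S G^T||_F^2. The rows of P S are the gene embedding
vectors; the columns of G are the basis of the space. The orthonormality
constraint on G minimises colinearities between basis vectors, which is
what later allows annotations to be projected onto the same basis.

The problem is NP-hard and is solved heuristically with the canonical
KKT-derived multiplicative update rules for this objective:

    P <- P * (X G S^T)   / (P S G^T G S^T)
    S <- S * (P^T X G)   / (P^T P S G^T G)
    G <- G * sqrt( (X^T P S) / (G G^T X^T P S) )

(the square root on the orthonormally constrained factor is the standard
damping for orthogonal NMTF updates; the undamped quotient oscillates),

starting from a deterministic truncated-SVD initialisation (absolute
values of the leading singular vectors), which makes the whole solver
deterministic and shortens convergence. Fit quality is tracked by the
relative square error RSE = ||X - P S G^T||_F^2 / ||X||_F^2; iteration
stops when the RSE stops decreasing or after ``max_iter`` rounds.

Usage follows the model/results pattern::

    model = NMTF(ppmi, k=50)
    fit = model.fit()          # -> TriFactorization
    fit.gene_embeddings        # rows of P S
    print(fit.summary())
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_io import DataError
from .ppmi import PPMIMatrix

__all__ = ["NMTF", "TriFactorization", "svd_initialize", "nmtf_decompose", "rse"]

_EPS = 1e-12  # denominator stabiliser; does not move fixed points materially


@dataclass(frozen=True)
class TriFactorization:
    """Result of an NMTF fit: factors, convergence trace and diagnostics."""

    P: np.ndarray
    S: np.ndarray
    G: np.ndarray
    k: int
    rse_trace: tuple[float, ...]
    node_order: tuple[str, ...]
    n_iter: int = 0
    converged: str = "initialized"

    def __post_init__(self) -> None:
        for name, m in (("P", self.P), ("S", self.S), ("G", self.G)):
            if np.any(m < 0):
                raise DataError(f"factor {name} has negative entries")
        n = len(self.node_order)
        if self.P.shape != (n, self.k) or self.G.shape != (n, self.k):
            raise DataError("factor shapes do not match node order / k")
        if self.S.shape != (self.k, self.k):
            raise DataError("S must be k x k")

    @property
    def gene_embeddings(self) -> np.ndarray:
        """Gene embedding vectors: the rows of P S, aligned to node_order."""
        return self.P @ self.S

    @property
    def basis(self) -> np.ndarray:
        """Basis of the embedding space: the columns of G."""
        return self.G

    def reconstruction(self) -> np.ndarray:
        return self.P @ self.S @ self.G.T

    @property
    def orthonormality_residual(self) -> float:
        """||G^T G - I||_F, a diagnostic of how orthonormal G ended up."""
        k = self.k
        return float(np.linalg.norm(self.G.T @ self.G - np.eye(k)))

    @property
    def final_rse(self) -> float:
        return self.rse_trace[-1]

    def summary(self) -> str:
        lines = [
            "Orthonormal NMTF fit",
            "=" * 40,
            f"genes (n)                 {len(self.node_order):>10d}",
            f"dimensions (k)            {self.k:>10d}",
            f"iterations                {self.n_iter:>10d}",
            f"stop reason               {self.converged:>10s}",
            f"final RSE                 {self.final_rse:>10.4g}",
            f"||G'G - I||_F             {self.orthonormality_residual:>10.4g}",
        ]
        return "\n".join(lines)


def _as_array(X: PPMIMatrix | np.ndarray) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(X, PPMIMatrix):
        return X.values, X.node_order
    X = np.asarray(X, dtype=float)
    return X, tuple(str(i) for i in range(X.shape[0]))


def rse(X: PPMIMatrix | np.ndarray, f: TriFactorization) -> float:
    """Relative square error ||X - P S G^T||_F^2 / ||X||_F^2."""
    x, _ = _as_array(X)
    denom = np.linalg.norm(x) ** 2
    if denom == 0:
        raise DataError("||X||_F is zero; RSE undefined")
    return float(np.linalg.norm(x - f.reconstruction()) ** 2 / denom)


def _rse_arrays(x: np.ndarray, p: np.ndarray, s: np.ndarray, g: np.ndarray, denom: float) -> float:
    return float(np.linalg.norm(x - p @ s @ g.T) ** 2 / denom)


class NMTF:
    """Orthonormal non-negative tri-factorization model of a symmetric matrix.

    Parameters
    ----------
    X
        Symmetric non-negative matrix (a :class:`~funcmap.ppmi.PPMIMatrix`
        or a plain array).
    k
        Embedding dimensionality, 1 <= k <= n.
    """

    def __init__(self, X: PPMIMatrix | np.ndarray, k: int):
        self.X, self.node_order = _as_array(X)
        n = self.X.shape[0]
        if self.X.shape != (n, n):
            raise DataError("X must be square")
        if np.any(self.X < 0):
            raise DataError("X must be non-negative")
        if not (1 <= k <= n):
            raise DataError(f"k must be in [1, {n}], got {k}")
        self.k = int(k)
        self._xnorm2 = float(np.linalg.norm(self.X) ** 2)
        if self._xnorm2 == 0:
            raise DataError("X is the zero matrix")

    def initialize(self) -> TriFactorization:
        """Deterministic SVD-based initial factors.

        X ~= U_k Sigma_k V_k^T truncated at rank k; the initial factors are
        the elementwise absolute values P0 = |U_k|, G0 = |V_k| and
        S0 = Sigma_k. No randomness is involved, so repeated calls are
        bit-identical.
        """
        u, sing, vt = np.linalg.svd(self.X, full_matrices=False)
        p0 = np.abs(u[:, : self.k])
        g0 = np.abs(vt[: self.k, :].T)
        s0 = np.diag(sing[: self.k])
        trace = (_rse_arrays(self.X, p0, s0, g0, self._xnorm2),)
        return TriFactorization(
            P=p0, S=s0, G=g0, k=self.k, rse_trace=trace,
            node_order=self.node_order, n_iter=0, converged="initialized",
        )

    def fit(self, max_iter: int = 500, tol: float = 1e-6) -> TriFactorization:
        """Run multiplicative updates from the SVD initialisation.

        Stops when the relative RSE improvement drops below ``tol``, when
        the RSE would increase (the previous factors are kept, so the
        recorded trace is non-increasing), or after ``max_iter`` rounds.
        """
        init = self.initialize()
        x = self.X
        p, s, g = init.P.copy(), init.S.copy(), init.G.copy()
        trace = [init.rse_trace[0]]
        converged = "max_iter"
        it = 0
        for it in range(1, max_iter + 1):
            p_prev, s_prev, g_prev = p.copy(), s.copy(), g.copy()
            gtg = g.T @ g
            p *= (x @ g @ s.T) / (p @ s @ gtg @ s.T + _EPS)
            s *= (p.T @ x @ g) / (p.T @ p @ s @ (g.T @ g) + _EPS)
            xtps = x.T @ p @ s
            # square-root damping is the canonical form for an orthonormally
            # constrained factor; the undamped quotient oscillates
            g *= np.sqrt(xtps / (g @ (g.T @ xtps) + _EPS))
            if not (np.all(np.isfinite(p)) and np.all(np.isfinite(s)) and np.all(np.isfinite(g))):
                raise DataError(f"non-finite factor entries at iteration {it}")
            cur = _rse_arrays(x, p, s, g, self._xnorm2)
            prev = trace[-1]
            if cur > prev:
                # keep the last non-increasing state
                p, s, g = p_prev, s_prev, g_prev
                it -= 1
                converged = "rse_increase"
                break
            trace.append(cur)
            if prev > 0 and (prev - cur) / prev < tol:
                converged = "rse_plateau"
                break
            if prev == 0:
                converged = "rse_plateau"
                break
        return TriFactorization(
            P=p, S=s, G=g, k=self.k, rse_trace=tuple(trace),
            node_order=self.node_order, n_iter=it, converged=converged,
        )


def svd_initialize(X: PPMIMatrix | np.ndarray, k: int) -> TriFactorization:
    """Functional wrapper: deterministic SVD initial factors for X at rank k."""
    return NMTF(X, k).initialize()


def nmtf_decompose(
    X: PPMIMatrix | np.ndarray, k: int, max_iter: int = 500, tol: float = 1e-6
) -> TriFactorization:
    """Functional wrapper: fit the orthonormal NMTF of X at rank k."""
    return NMTF(X, k).fit(max_iter=max_iter, tol=tol)
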