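"""Gaussian Markov random fields on SNP positions.

Each mixture component j carries an independent field x_j = (x_1j..x_nj)
over the n ordered SNPs of a chromosome, with joint density

    p(x | h) = c(h) * exp{ -1/2 ( h * sum_{i~i'} (x_i - x_{i'})^2 + sum_i x_i^2 ) }

where i~i' ranges over unordered pairs of window neighbors (|i - i'| <= nb)
and h >= 0 controls the smoothing.  Expanding the exponent shows the
precision matrix is I + hQ with Q the graph Laplacian of the window graph,
so c(h) = (2*pi)^(-n/2) * prod_i (1 + h*g_i)^(1/2) with g_i the Laplacian
eigenvalues.  Mixture weights are a tempered softmax of the field values:
w_ij = exp(x_ij/phi) / sum_l exp(x_il/phi).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cholesky_banded, eigvals_banded, solve_banded
from scipy.special import softmax

__all__ = [
    "NeighborGraph",
    "FieldState",
    "build_neighbor_graph",
    "log_gmrf_density",
    "conditional_params",
    "weights_from_field",
    "sample_field",
]


@dataclass(frozen=True)
class NeighborGraph:
    """Window neighbor graph over ``n`` ordered SNPs.

    SNPs i and i' are neighbors iff 0 < |i - i'| <= nb; SNPs near the
    chromosome ends simply have fewer neighbors.  Laplacian eigenvalues are
    precomputed once (banded solver) and cached with the graph.
    """

    n: int
    nb: int
    degrees: np.ndarray = field(repr=False)
    laplacian_eigenvalues: np.ndarray = field(repr=False)

    def neighbor_range(self, i: int) -> tuple[int, int]:
        """Inclusive index range [lo, hi] of the window around SNP i."""
        return max(0, i - self.nb), min(self.n - 1, i + self.nb)

    def neighbors(self, i: int) -> np.ndarray:
        lo, hi = self.neighbor_range(i)
        idx = np.arange(lo, hi + 1)
        return idx[idx != i]

    def laplacian(self) -> np.ndarray:
        """Dense Laplacian Q = D - A; intended for small-n oracles and export."""
        q = np.zeros((self.n, self.n))
        for d in range(1, self.nb + 1):
            idx = np.arange(self.n - d)
            q[idx, idx + d] = -1.0
            q[idx + d, idx] = -1.0
        q[np.diag_indices(self.n)] = self.degrees
        return q


def build_neighbor_graph(n: int, nb: int) -> NeighborGraph:
    """Construct the window graph and its Laplacian spectrum.

    The eigenvalues g_1..g_n are those of Q = D - A, so the quadratic form
    in the field density equals x^T (I + hQ) x and the normalizing constant
    uses 1 + h*g_i.
    """
    if n < 2:
        raise ValueError("a chromosome needs at least 2 SNPs")
    if nb <= 0:
        raise ValueError("neighbor window nb must be positive")
    if nb >= n:
        raise ValueError("neighbor window nb must be smaller than n")
    idx = np.arange(n)
    degrees = np.minimum(idx + nb, n - 1) - np.maximum(idx - nb, 0)
    # Banded (upper) storage of Q: row nb holds the diagonal, row nb-d the
    # d-th superdiagonal (all -1 within the window).
    ab = np.zeros((nb + 1, n))
    ab[nb] = degrees
    for d in range(1, nb + 1):
        ab[nb - d, d:] = -1.0
    eigs = eigvals_banded(ab, lower=False)
    eigs = np.where(np.abs(eigs) < 1e-9, 0.0, eigs)
    if np.any(eigs < 0):  # pragma: no cover - Laplacians are PSD
        raise AssertionError("negative Laplacian eigenvalue")
    return NeighborGraph(n=n, nb=nb, degrees=degrees.astype(np.int64),
                         laplacian_eigenvalues=eigs)


def _pair_sq_sum(x_col: np.ndarray, nb: int) -> float:
    """sum over unordered neighbor pairs of (x_i - x_i')^2."""
    s = 0.0
    for d in range(1, nb + 1):
        if d < len(x_col):
            diff = x_col[d:] - x_col[:-d]
            s += float(diff @ diff)
    return s


def log_gmrf_density(x_col: np.ndarray, h: float, graph: NeighborGraph) -> float:
    """Log joint density of one field column under smoothing parameter h."""
    if h < 0:
        raise ValueError("smoothing parameter h must be non-negative")
    x_col = np.asarray(x_col, dtype=float)
    if x_col.shape != (graph.n,):
        raise ValueError(f"expected a length-{graph.n} field column")
    log_c = -0.5 * graph.n * np.log(2.0 * np.pi) \
        + 0.5 * float(np.sum(np.log1p(h * graph.laplacian_eigenvalues)))
    quad = h * _pair_sq_sum(x_col, graph.nb) + float(x_col @ x_col)
    return log_c - 0.5 * quad


def conditional_params(x_col: np.ndarray, h: float, i: int,
                       graph: NeighborGraph) -> tuple[float, float]:
    """Full-conditional mean and variance of x_i given the rest of its field.

    mean = h * sum_{i'~i} x_{i'} / (1 + h n_i),  variance = 1 / (1 + h n_i).
    """
    if h < 0:
        raise ValueError("smoothing parameter h must be non-negative")
    lo, hi = graph.neighbor_range(i)
    n_i = graph.degrees[i]
    s = float(np.sum(x_col[lo:hi + 1])) - float(x_col[i])
    denom = 1.0 + h * n_i
    return h * s / denom, 1.0 / denom


def weights_from_field(x: np.ndarray, phi: float) -> np.ndarray:
    """Tempered softmax turning field values into mixture weights.

    Rows index SNPs, columns components; each output row sums to 1.  The
    scaling factor phi acts as a temperature: small phi pushes each row
    toward an indicator of its largest field value.
    """
    if phi <= 0:
        raise ValueError("scaling factor phi must be positive")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    return softmax(x / phi, axis=1)


def sample_field(h: float, graph: NeighborGraph, rng: np.random.Generator,
                 size: int | None = None) -> np.ndarray:
    """Draw field column(s) from N(0, (I + hQ)^-1) via banded Cholesky."""
    if h < 0:
        raise ValueError("smoothing parameter h must be non-negative")
    n, nb = graph.n, graph.nb
    ab = np.zeros((nb + 1, n))
    ab[nb] = 1.0 + h * graph.degrees
    for d in range(1, nb + 1):
        ab[nb - d, d:] = -h
    u = cholesky_banded(ab, lower=False)  # I + hQ = U^T U
    z = rng.standard_normal(n if size is None else (n, size))
    x = solve_banded((0, nb), u, z)  # cov = U^-1 U^-T = (I + hQ)^-1
    return x if size is None else x.T


@dataclass
class FieldState:
    """Field matrix x (n SNPs x k components) with its smoothing parameter
    h and weight temperature phi."""

    x: np.ndarray
    h: float
    phi: float

    def __post_init__(self) -> None:
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        if not np.all(np.isfinite(self.x)):
            raise ValueError("field values must be finite")
        if self.h < 0:
            raise ValueError("smoothing parameter h must be non-negative")
        if self.phi <= 0:
            raise ValueError("scaling factor phi must be positive")

    def weights(self) -> np.ndarray:
        return weights_from_field(self.x, self.phi)
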