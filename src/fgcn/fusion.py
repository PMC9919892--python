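"""Normalization, sparsification and fusion of channel graphs.

The three connectivity matrices live on different scales (RBF weights in
(0, 1], Pearson in [-1, 1], Granger log ratios in [0, inf)), so each is
first mapped row-wise onto a common scale: every off-diagonal row is
min-max rescaled into [0, 1/2] and the diagonal is fixed at 1/2. A hard
threshold then sparsifies each matrix, and the surviving graphs are fused
entrywise into a single adjacency H_fuse. Point-by-point addition is the
default strategy — strong connections present in any view are enhanced,
weak ones vanish — with four alternatives (entrywise product, Kronecker
product/addition with block-mean pooling, and SNF-style cross-diffusion)
available for ablation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .connectivity import ConnectivityMatrix
from .exceptions import ParameterError

logger = logging.getLogger(__name__)

FUSION_STRATEGIES = (
    "add",
    "product",
    "kronecker_product",
    "kronecker_addition",
    "cross_diffusion",
)


@dataclass(frozen=True)
class NormalizedGraph:
    """A row-normalized channel graph: off-diagonal in [0, 1/2], diagonal 1/2."""

    weights: np.ndarray
    source_kind: str
    threshold_spec: dict | None = None

    @property
    def n_channels(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class FusedGraph:
    """The fused adjacency H_fuse with provenance of how it was built."""

    weights: np.ndarray
    strategy: str
    components: tuple[str, ...]
    threshold_spec: dict | None = None
    channel_names: tuple[str, ...] | None = field(default=None)

    @property
    def n_channels(self) -> int:
        return self.weights.shape[0]


def normalize_rows(graph: ConnectivityMatrix | np.ndarray) -> NormalizedGraph:
    """Row-wise min-max normalization onto [0, 1/2] with diagonal 1/2.

    For each row i, the off-diagonal entries are affinely mapped so the row
    minimum becomes 0 and the row maximum 1/2; the diagonal (self-
    similarity) is pinned at 1/2. A row whose off-diagonal entries are all
    equal has no scale: its off-diagonal is set to 0 and a warning logged.
    """
    if isinstance(graph, ConnectivityMatrix):
        a = graph.weights
        kind = graph.kind
    else:
        a = np.asarray(graph, dtype=float)
        kind = "unknown"
    n = a.shape[0]
    if n < 2:
        raise ParameterError("normalization needs at least 2 channels")
    mask = ~np.eye(n, dtype=bool)
    h = np.zeros_like(a, dtype=float)
    for i in range(n):
        row = a[i, mask[i]]
        lo, hi = row.min(), row.max()
        if hi == lo:
            logger.warning(
                "row %d of %s graph has constant off-diagonal; set to 0", i, kind
            )
            continue
        h[i, mask[i]] = 0.5 * (row - lo) / (hi - lo)
    np.fill_diagonal(h, 0.5)
    return NormalizedGraph(weights=h, source_kind=kind)


def sparsify(
    graph: NormalizedGraph, rule: str = "percentile", value: float = 50.0
) -> NormalizedGraph:
    """Hard-threshold the off-diagonal entries of a normalized graph.

    ``rule="percentile"`` zeroes entries strictly below the given
    percentile of all off-diagonal entries; ``rule="absolute"`` uses the
    value itself as the threshold. The diagonal is never touched and
    surviving entries are unchanged.
    """
    h = graph.weights.copy()
    n = h.shape[0]
    mask = ~np.eye(n, dtype=bool)
    if rule == "percentile":
        if not 0.0 <= value < 100.0:
            raise ParameterError("percentile must lie in [0, 100)")
        thr = float(np.percentile(h[mask], value))
    elif rule == "absolute":
        if value < 0.0:
            raise ParameterError("absolute threshold must be >= 0")
        thr = float(value)
    else:
        raise ParameterError(f"unknown sparsification rule {rule!r}")
    off = h[mask]
    off[off < thr] = 0.0
    h[mask] = off
    return NormalizedGraph(
        weights=h,
        source_kind=graph.source_kind,
        threshold_spec={"rule": rule, "value": float(value), "threshold": thr},
    )


def _as_weight_list(graphs: Sequence[NormalizedGraph | np.ndarray]) -> list[np.ndarray]:
    ws = [
        g.weights if isinstance(g, NormalizedGraph) else np.asarray(g, dtype=float)
        for g in graphs
    ]
    if len(ws) < 2:
        raise ParameterError("fusion needs at least 2 graphs")
    shape = ws[0].shape
    if any(w.shape != shape for w in ws):
        raise ParameterError("all graphs must share the same shape")
    return ws


def _kron_pool_product(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # Block (i, j) of kron(a, b) is a[i, j] * b, so its mean is a[i, j]*mean(b).
    return a * b.mean()


def _kron_pool_sum(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # kron(a, I) + kron(I, b): block (i, j) is a[i, j]*I + delta_ij*b.
    n = a.shape[0]
    return a / n + np.eye(n) * b.mean()


def _knn_kernel(w: np.ndarray, k: int) -> np.ndarray:
    """Row-stochastic kernel keeping each row's diagonal and k largest
    off-diagonal entries."""
    n = w.shape[0]
    k = min(k, n - 1)
    s = np.zeros_like(w)
    for i in range(n):
        row = w[i].copy()
        row[i] = -np.inf
        keep = np.argsort(row)[::-1][:k]
        s[i, keep] = w[i, keep]
        s[i, i] = w[i, i]
        total = s[i].sum()
        if total > 0:
            s[i] /= total
        else:
            s[i, i] = 1.0
    return s


def _row_stochastic(w: np.ndarray) -> np.ndarray:
    sums = w.sum(axis=1, keepdims=True)
    out = np.where(sums > 0, w / np.where(sums == 0, 1.0, sums), 0.0)
    zero = sums.ravel() == 0
    if zero.any():
        out[zero, zero] = 1.0
    return out


def _cross_diffusion(
    ws: list[np.ndarray], k: int = 10, iterations: int = 20
) -> np.ndarray:
    """Similarity-network-fusion cross-diffusion.

    Each graph contributes a dense row-stochastic status kernel P_m and a
    sparse kNN kernel S_m; the statuses diffuse through each other's local
    neighborhoods, P_m <- S_m · mean_{m' != m}(P_m') · S_m^T, for a fixed
    number of iterations, and the fused graph is the mean of the final
    statuses.
    """
    ps = [_row_stochastic(w) for w in ws]
    ss = [_knn_kernel(w, k) for w in ws]
    m = len(ws)
    for _ in range(iterations):
        new = []
        for idx in range(m):
            others = np.mean([ps[j] for j in range(m) if j != idx], axis=0)
            new.append(ss[idx] @ others @ ss[idx].T)
        ps = new
    return np.mean(ps, axis=0)


def fuse(
    graphs: Sequence[NormalizedGraph | np.ndarray],
    strategy: str = "add",
    *,
    knn: int = 10,
    iterations: int = 20,
    channel_names: Sequence[str] | None = None,
) -> FusedGraph:
    """Combine >= 2 normalized graphs into one fused adjacency.

    Strategies
    ----------
    add
        Entrywise sum (default; the local fusion strategy).
    product
        Entrywise (Hadamard) product.
    kronecker_product / kronecker_addition
        Sequential pairwise Kronecker product / Kronecker sum, with each
        N x N block mean-pooled back to N x N before folding in the next
        graph (the Kronecker result itself is N^2 x N^2 and unusable as an
        N-node adjacency).
    cross_diffusion
        SNF-style iterative cross-diffusion; ``knn`` and ``iterations``
        control the local kernel and diffusion length.
    """
    ws = _as_weight_list(graphs)
    if strategy == "add":
        out = np.sum(ws, axis=0)
    elif strategy == "product":
        out = ws[0].copy()
        for w in ws[1:]:
            out = out * w
    elif strategy == "kronecker_product":
        out = ws[0]
        for w in ws[1:]:
            out = _kron_pool_product(out, w)
    elif strategy == "kronecker_addition":
        out = ws[0]
        for w in ws[1:]:
            out = _kron_pool_sum(out, w)
    elif strategy == "cross_diffusion":
        out = _cross_diffusion(ws, k=knn, iterations=iterations)
    else:
        raise ParameterError(f"unknown fusion strategy {strategy!r}")
    if out.min() < 0:
        raise ParameterError(
            "fusion produced negative weights; normalize inputs first"
        )
    kinds = tuple(
        g.source_kind if isinstance(g, NormalizedGraph) else "unknown"
        for g in graphs
    )
    specs = [
        g.threshold_spec
        for g in graphs
        if isinstance(g, NormalizedGraph) and g.threshold_spec is not None
    ]
    return FusedGraph(
        weights=out,
        strategy=strategy,
        components=kinds,
        threshold_spec=specs[0] if specs else None,
        channel_names=tuple(channel_names) if channel_names is not None else None,
    )


def prepare_component(
    graph: ConnectivityMatrix,
    rule: str = "percentile",
    value: float = 50.0,
) -> NormalizedGraph:
    """Normalize then sparsify one connectivity matrix (the standard
    per-component pipeline before fusion)."""
    return sparsify(normalize_rows(graph), rule=rule, value=value)
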