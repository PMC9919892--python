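"""Channel-graph construction from montage geometry and multichannel signals.

Three complementary views of inter-channel structure are estimated, each as
an N x N weighted adjacency matrix over the same electrode set:

topological
    Physical proximity of electrodes. Connection strength between brain
    sites decays with distance, so the graph is a Gaussian RBF kernel of
    the pairwise electrode distances,
    ``A[i, j] = exp(-dist(i, j)^2 / (2 theta^2))``.

functional
    Undirected statistical dependence: the Pearson correlation of the two
    channels' time series over a trial (or window).

causal (effective)
    Directed influence via the Granger-causality test: for each ordered
    pair, the log ratio of the prediction-error variance of a channel's own
    autoregression to that of the autoregression augmented with the other
    channel's lags, ``GC[i<-j] = ln(var_restricted(i) / var_full(i|j))``.
    In-sample this is always >= 0 and generally asymmetric.

Random and identity matrices are provided as ablation baselines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import DegenerateSignalError, EstimationError, ParameterError
from .montage import Montage

GRAPH_KINDS = ("topological", "functional", "causal", "random", "identity")


@dataclass(frozen=True)
class SignalEpochs:
    """Epoched multichannel signals: ``data`` is trials x channels x time."""

    data: np.ndarray
    fs: float
    labels: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "labels", labels)
        if data.ndim != 3:
            raise ParameterError(
                f"data must be trials x channels x time, got shape {data.shape}"
            )
        if self.fs <= 0:
            raise ParameterError("sampling rate fs must be positive")
        if labels.shape != (data.shape[0],):
            raise ParameterError("labels must have one entry per trial")
        if labels.size and labels.min() < 0:
            raise ParameterError("labels must be non-negative class indices")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """An N x N weighted channel graph with a kind tag.

    ``directed`` is True only for the causal graph; the others are
    symmetric by construction.
    """

    weights: np.ndarray
    kind: str
    directed: bool = False
    params: dict = field(default_factory=dict)
    channel_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if self.kind not in GRAPH_KINDS:
            raise ParameterError(f"unknown graph kind {self.kind!r}")
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ParameterError("weights must be a square matrix")
        if not np.all(np.isfinite(w)):
            raise EstimationError(f"{self.kind} graph contains non-finite weights")

    @property
    def n_channels(self) -> int:
        return self.weights.shape[0]


def build_topological_graph(
    montage: Montage, theta: float | None = None
) -> ConnectivityMatrix:
    """RBF kernel of pairwise electrode distances.

    Parameters
    ----------
    montage
        Electrode positions; supplies ``dist(i, j)``.
    theta
        RBF width controlling the radial range of action. Defaults to the
        montage's median pairwise distance, which makes the graph invariant
        to the montage's length unit.
    """
    if theta is None:
        theta = montage.median_distance()
    if not theta > 0:
        raise ParameterError(f"theta must be positive, got {theta}")
    d = montage.distances()
    n = montage.n_channels
    off = d[~np.eye(n, dtype=bool)]
    if off.size and np.any(off == 0.0):
        warnings.warn(
            "distinct channels at distance 0 receive topological weight 1",
            stacklevel=2,
        )
    w = np.exp(-(d**2) / (2.0 * theta**2))
    np.fill_diagonal(w, 1.0)
    return ConnectivityMatrix(
        weights=w,
        kind="topological",
        directed=False,
        params={"theta": float(theta)},
        channel_names=montage.channel_names,
    )


def _trial_window(
    signals: SignalEpochs, trial: int, window: tuple[int, int] | None
) -> np.ndarray:
    if not 0 <= trial < signals.n_trials:
        raise ParameterError(f"trial index {trial} out of range")
    x = signals.data[trial]
    if window is not None:
        start, stop = window
        x = x[:, start:stop]
    if x.shape[1] < 2:
        raise ParameterError("selected window must contain at least 2 samples")
    return x


def build_functional_graph(
    signals: SignalEpochs,
    trial: int = 0,
    window: tuple[int, int] | None = None,
    channel_names: Sequence[str] | None = None,
) -> ConnectivityMatrix:
    """Pearson-correlation graph of one trial (optionally one window)."""
    x = _trial_window(signals, trial, window)
    sd = x.std(axis=1)
    if np.any(sd == 0.0):
        bad = int(np.flatnonzero(sd == 0.0)[0])
        name = channel_names[bad] if channel_names is not None else f"#{bad}"
        raise DegenerateSignalError(
            f"channel {name} is constant over the window (zero standard deviation)"
        )
    w = np.corrcoef(x)
    w = np.clip((w + w.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(w, 1.0)
    return ConnectivityMatrix(
        weights=w,
        kind="functional",
        directed=False,
        params={"trial": int(trial), "window": window},
        channel_names=tuple(channel_names) if channel_names is not None else None,
    )


def _lag_matrix(series: np.ndarray, order: int) -> np.ndarray:
    """Columns are lags 1..order of ``series``; rows t = order..T-1."""
    return np.column_stack([series[order - k : -k] for k in range(1, order + 1)])


def fit_var_residual_variance(
    target: np.ndarray,
    predictors: Sequence[np.ndarray] = (),
    order: int = 1,
) -> float:
    """Prediction-error variance of an autoregression with optional
    exogenous lag blocks.

    Regresses ``target[t]`` on an intercept, lags 1..order of ``target``
    and lags 1..order of every predictor, by ordinary least squares, and
    returns the mean squared residual. This is the sigma^2 entering the
    Granger-causality log variance ratio.
    """
    if order < 1:
        raise ParameterError("VAR order must be >= 1")
    target = np.asarray(target, dtype=float).ravel()
    preds = [np.asarray(p, dtype=float).ravel() for p in predictors]
    n_coef = order * (1 + len(preds)) + 1
    if target.size <= 2 * order + len(preds) * order:
        raise ParameterError(
            f"series of length {target.size} too short for order {order} "
            f"with {len(preds)} predictor(s)"
        )
    y = target[order:]
    blocks = [_lag_matrix(target, order)]
    blocks += [_lag_matrix(p, order) for p in preds]
    blocks.append(np.ones((y.size, 1)))
    X = np.column_stack(blocks)
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < n_coef:
        raise EstimationError(
            "singular lag design matrix; try a lower VAR order"
        )
    resid = y - X @ coef
    return float(resid @ resid / y.size)


def _gc_matrix(x: np.ndarray, order: int) -> np.ndarray:
    """All-pairs Granger-causality log variance ratios for one trial.

    Uses a shared Gram matrix of the lagged design so each ordered pair
    reduces to a small normal-equations solve; numerically equivalent to
    calling :func:`fit_var_residual_variance` per pair (tested), but
    O(N^2 p^3) instead of O(N^2 T p^2) after the single O(T (Np)^2) pass.
    """
    n, t = x.shape
    p = order
    if t <= 2 * p + p:
        raise ParameterError(
            f"trial length {t} too short for causal estimation at order {p}"
        )
    # Z columns: for channel c, lags 1..p (block c*p..c*p+p-1); final column 1.
    lags = np.concatenate([_lag_matrix(x[c], p) for c in range(n)], axis=1)
    Z = np.column_stack([lags, np.ones(t - p)])
    Y = x[:, p:].T  # (t-p, n) targets
    G = Z.T @ Z
    C = Z.T @ Y
    yy = np.einsum("ti,ti->i", Y, Y)
    const = n * p  # index of the intercept column

    def rss(target: int, cols: np.ndarray) -> float:
        Gs = G[np.ix_(cols, cols)]
        cs = C[cols, target]
        try:
            beta = np.linalg.solve(Gs, cs)
        except np.linalg.LinAlgError:
            beta, *_ = np.linalg.lstsq(Gs, cs, rcond=None)
        return float(yy[target] - cs @ beta)

    gc = np.zeros((n, n))
    for i in range(n):
        own = np.arange(i * p, i * p + p)
        cols_r = np.concatenate([own, [const]])
        rss_r = rss(i, cols_r)
        for j in range(n):
            if j == i:
                continue
            cols_f = np.concatenate([own, np.arange(j * p, j * p + p), [const]])
            rss_f = rss(i, cols_f)
            if rss_f <= 0.0:
                raise DegenerateSignalError(
                    f"zero full-model residual variance for channel pair "
                    f"({i}, {j}); signals are degenerate"
                )
            # in-sample nesting guarantees rss_r >= rss_f up to rounding
            gc[i, j] = max(np.log(rss_r / rss_f), 0.0)
    np.fill_diagonal(gc, 1.0)
    return gc


def build_causal_graph(
    signals: SignalEpochs,
    trial: int = 0,
    order: int = 1,
    window: tuple[int, int] | None = None,
    channel_names: Sequence[str] | None = None,
) -> ConnectivityMatrix:
    """Granger-causality graph of one trial.

    ``weights[i, j]`` is the influence of channel j on channel i
    (``GC[i<-j]``), the log ratio of restricted to full prediction-error
    variance from nested OLS autoregressions of order ``order``. The
    diagonal is set to 1 (full self-connection), matching the convention
    used for the other graph kinds.
    """
    if order < 1:
        raise ParameterError("VAR order must be >= 1")
    x = _trial_window(signals, trial, window)
    w = _gc_matrix(x, order)
    return ConnectivityMatrix(
        weights=w,
        kind="causal",
        directed=True,
        params={"order": int(order), "trial": int(trial), "window": window},
        channel_names=tuple(channel_names) if channel_names is not None else None,
    )


def build_baseline_graph(
    kind: str, n: int, seed: int | None = 0
) -> ConnectivityMatrix:
    """Ablation baselines: exact identity, or i.i.d. uniform [0, 1) entries."""
    if n < 2:
        raise ParameterError("baseline graphs need n >= 2 channels")
    if kind == "identity":
        w = np.eye(n)
        return ConnectivityMatrix(weights=w, kind="identity", directed=False)
    if kind == "random":
        rng = np.random.default_rng(seed)
        w = rng.random((n, n))
        return ConnectivityMatrix(
            weights=w, kind="random", directed=False, params={"seed": seed}
        )
    raise ParameterError(f"unknown baseline kind {kind!r}")


def average_graphs(graphs: Sequence[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Entrywise mean of same-kind graphs (e.g. across training trials)."""
    if not graphs:
        raise ParameterError("need at least one graph to average")
    kinds = {g.kind for g in graphs}
    if len(kinds) != 1:
        raise ParameterError(f"cannot average graphs of mixed kinds {kinds}")
    w = np.mean([g.weights for g in graphs], axis=0)
    g0 = graphs[0]
    return ConnectivityMatrix(
        weights=w,
        kind=g0.kind,
        directed=g0.directed,
        params={"averaged_over": len(graphs), **g0.params},
        channel_names=g0.channel_names,
    )
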