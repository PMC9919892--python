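"""Chebyshev spectral graph convolutional classifier.

Spectral graph convolution filters node signals in the eigenbasis of the
graph Laplacian. With the fused adjacency H_fuse (symmetrized, degrees D),
the normalized Laplacian is

    R_fuse = I_N - D^{-1/2} H_fuse D^{-1/2},

whose spectrum lies in [0, 2]. Rescaling R'_fuse = R_fuse / lambda_max - I_N
maps the spectrum into [-1, 1], the domain of the Chebyshev polynomials
T_0 = I, T_1 = R', T_i = 2 R' T_{i-1} - T_{i-2}. A degree-k filter is then

    X * G_fuse  ~=  sum_{i=0..k} theta_i T_i(R'_fuse) X,

which avoids an explicit eigendecomposition and is exactly equal to
spectral filtering with the polynomial applied to the eigenvalues (a
property the tests verify against a dense eigensolver).

:class:`ChebGCNClassifier` stacks one such graph-convolution layer (ReLU),
a depthwise-separable convolution over the node x feature-map array
(depthwise filter per map, then 1x1 pointwise mixing), and a dense softmax
layer, trained by Adam on the cross-entropy. It follows the scikit-learn
estimator protocol and is implemented in NumPy with explicit
backpropagation, so training is deterministic given ``random_state``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import confusion_matrix
from sklearn.utils.validation import check_is_fitted

from .connectivity import ConnectivityMatrix
from .exceptions import EstimationError, IsolatedNodeError, ParameterError
from .fusion import FusedGraph

logger = logging.getLogger(__name__)

BAND_NAMES = ("delta", "theta", "alpha", "beta", "gamma")

_LAMBDA_FALLBACK = 2.0
_LAMBDA_EPS = 1e-6


@dataclass(frozen=True)
class FeatureBatch:
    """Per-segment node features: ``x`` is samples x channels x bands."""

    x: np.ndarray
    y: np.ndarray
    band_selector: str = "total"
    trial_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=int)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.ndim != 3:
            raise ParameterError(
                f"features must be samples x channels x bands, got {x.shape}"
            )
        if y.shape != (x.shape[0],):
            raise ParameterError("labels must have one entry per sample")

    @property
    def n_samples(self) -> int:
        return self.x.shape[0]

    @property
    def n_channels(self) -> int:
        return self.x.shape[1]

    @property
    def n_bands(self) -> int:
        return self.x.shape[2]


def select_band(batch: FeatureBatch, band: str) -> FeatureBatch:
    """Restrict a 5-band feature batch to one named band (or 'total')."""
    if band == "total":
        return batch
    if band not in BAND_NAMES:
        raise ParameterError(f"unknown band {band!r}; use {BAND_NAMES} or 'total'")
    if batch.n_bands != len(BAND_NAMES):
        raise ParameterError("band selection requires a 5-band feature batch")
    idx = BAND_NAMES.index(band)
    return FeatureBatch(
        x=batch.x[:, :, idx : idx + 1],
        y=batch.y,
        band_selector=band,
        trial_index=batch.trial_index,
    )


@dataclass(frozen=True)
class SpectralOperator:
    """The fused graph's spectral machinery: Laplacian and its rescaling."""

    h_fuse: np.ndarray
    degree: np.ndarray
    r_fuse: np.ndarray
    r_scaled: np.ndarray
    lambda_max: float
    channel_names: tuple[str, ...] | None = None

    @property
    def n_channels(self) -> int:
        return self.h_fuse.shape[0]


def _largest_eigenvalue(r: np.ndarray, tol: float = 1e-8) -> float:
    n = r.shape[0]
    if n <= 128:
        return float(np.linalg.eigvalsh(r)[-1])
    # power iteration on the PSD matrix R; deterministic start
    v = np.ones(n) / np.sqrt(n)
    lam = 0.0
    for _ in range(10_000):
        w = r @ v
        norm = np.linalg.norm(w)
        if norm == 0.0:
            return 0.0
        v_new = w / norm
        lam_new = float(v_new @ r @ v_new)
        if abs(lam_new - lam) <= tol * max(1.0, abs(lam_new)):
            return lam_new
        v, lam = v_new, lam_new
    return lam


def build_spectral_operator(
    fused: FusedGraph | ConnectivityMatrix | np.ndarray,
) -> SpectralOperator:
    """Symmetrize H_fuse, form the normalized Laplacian and its rescaling.

    A directed (causal-carrying) fused matrix is symmetrized as
    (H + H^T)/2, which preserves total edge weight; the Laplacian requires
    a symmetric non-negative adjacency. When the Laplacian is (near-)zero
    — e.g. a pure identity adjacency — lambda_max falls back to 2, the
    upper end of the normalized-Laplacian spectrum.
    """
    names: tuple[str, ...] | None = None
    if isinstance(fused, FusedGraph):
        h = fused.weights
        names = fused.channel_names
    elif isinstance(fused, ConnectivityMatrix):
        h = fused.weights
        names = fused.channel_names
    else:
        h = np.asarray(fused, dtype=float)
    if h.ndim != 2 or h.shape[0] != h.shape[1]:
        raise ParameterError("fused adjacency must be square")
    if h.min() < 0:
        raise ParameterError("fused adjacency must be non-negative")
    h = (h + h.T) / 2.0
    n = h.shape[0]
    deg = h.sum(axis=1)
    if np.any(deg <= 0):
        bad = int(np.flatnonzero(deg <= 0)[0])
        name = names[bad] if names is not None else f"#{bad}"
        raise IsolatedNodeError(
            f"channel {name} has zero degree in the fused graph"
        )
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    r = np.eye(n) - (d_inv_sqrt[:, None] * h * d_inv_sqrt[None, :])
    r = (r + r.T) / 2.0
    lam = _largest_eigenvalue(r)
    if lam < _LAMBDA_EPS:
        lam = _LAMBDA_FALLBACK
    r_scaled = r / lam - np.eye(n)
    return SpectralOperator(
        h_fuse=h,
        degree=deg,
        r_fuse=r,
        r_scaled=r_scaled,
        lambda_max=float(lam),
        channel_names=names,
    )


def cheb_polynomials(
    operator: SpectralOperator | np.ndarray, k: int
) -> list[np.ndarray]:
    """T_0..T_k of the scaled Laplacian via the three-term recurrence."""
    if k < 0:
        raise ParameterError("Chebyshev order k must be >= 0")
    r = operator.r_scaled if isinstance(operator, SpectralOperator) else np.asarray(
        operator, dtype=float
    )
    n = r.shape[0]
    terms = [np.eye(n)]
    if k >= 1:
        terms.append(r.copy())
    for _ in range(2, k + 1):
        terms.append(2.0 * r @ terms[-1] - terms[-2])
    return terms


def spectral_graph_conv(
    x: np.ndarray,
    terms: Sequence[np.ndarray],
    coeffs: np.ndarray,
) -> np.ndarray:
    """Apply the Chebyshev filter sum_i theta_i T_i X.

    ``x`` may be (channels, bands) or (samples, channels, bands). ``coeffs``
    is either a vector of k+1 scalars (one shared filter) or an array of
    shape (k+1, bands, maps) mapping input bands to output feature maps.
    The operation is linear in both ``x`` and ``coeffs``.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 2
    if single:
        x = x[None]
    t = np.stack([np.asarray(m, dtype=float) for m in terms])
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape[0] != t.shape[0]:
        raise ParameterError(
            f"need {t.shape[0]} coefficient blocks, got {coeffs.shape[0]}"
        )
    if t.shape[1] != x.shape[1]:
        raise ParameterError(
            f"graph has {t.shape[1]} nodes but features have {x.shape[1]} channels"
        )
    if coeffs.ndim == 1:
        out = np.einsum("k,knm,bmf->bnf", coeffs, t, x)
    elif coeffs.ndim == 3:
        out = np.einsum("knm,bmf,kfc->bnc", t, x, coeffs)
    else:
        raise ParameterError("coeffs must be 1-D (scalars) or 3-D (k+1, bands, maps)")
    return out[0] if single else out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_loss(
    probs: np.ndarray, labels: np.ndarray, reduction: str = "mean"
) -> float:
    """Multiclass cross-entropy of predicted distributions vs true labels.

    ``L = -sum_s sum_k y_sk log p_sk`` with one-hot y; ``reduction`` is
    ``"mean"`` (default, per-sample average) or ``"sum"``. Zero predicted
    probability at a true label is clamped at 1e-12 and logged.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if probs.ndim != 2 or labels.shape != (probs.shape[0],):
        raise ParameterError("probs must be (samples, classes) with matching labels")
    if labels.size and (labels.min() < 0 or labels.max() >= probs.shape[1]):
        raise ParameterError("labels out of range for the probability matrix")
    p_true = probs[np.arange(labels.size), labels]
    if np.any(p_true <= 0.0):
        logger.warning(
            "clamping %d zero probabilities at the true label", int((p_true <= 0).sum())
        )
        p_true = np.clip(p_true, 1e-12, None)
    losses = -np.log(p_true)
    if reduction == "mean":
        return float(losses.mean())
    if reduction == "sum":
        return float(losses.sum())
    raise ParameterError(f"unknown reduction {reduction!r}")


class _Adam:
    """Adam optimizer over a dict of NumPy parameter arrays."""

    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps
            )


class ChebGCNClassifier(BaseEstimator, ClassifierMixin):
    """Graph-convolutional classifier over a fixed channel graph.

    Architecture: one Chebyshev graph-convolution layer (order
    ``cheb_order``, ``n_maps`` output feature maps, ReLU), a
    depthwise-separable block (depthwise filter of length
    ``depthwise_kernel`` along the node axis per map — or a 3x3 filter on
    the 8x9 electrode grid when ``depthwise_layout="grid"`` — followed by
    1x1 pointwise mixing to ``pointwise_maps`` maps, ReLU), then a dense
    softmax layer. Trained with Adam on the mean cross-entropy.

    Parameters
    ----------
    adjacency
        The (fused) adjacency: a :class:`~fgcn.fusion.FusedGraph`, a
        :class:`SpectralOperator`, a raw non-negative matrix, or None for
        the identity graph (no message passing).
    cheb_order
        Chebyshev polynomial order k; the layer uses k+1 terms.
    depthwise_layout
        ``"nodes"`` (default) filters along the channel axis;
        ``"grid"`` scatters channels onto the 8x9 electrode grid (requires
        ``grid_index``) and applies a 3x3 depthwise filter there.
    standardize
        Standardize each (channel, band) feature using training statistics.
    """

    def __init__(
        self,
        adjacency=None,
        cheb_order: int = 3,
        n_maps: int = 16,
        depthwise_kernel: int = 3,
        pointwise_maps: int = 16,
        depthwise_layout: str = "nodes",
        grid_index=None,
        learning_rate: float = 1e-3,
        n_epochs: int = 100,
        batch_size: int = 32,
        standardize: bool = True,
        random_state: int = 0,
    ):
        self.adjacency = adjacency
        self.cheb_order = cheb_order
        self.n_maps = n_maps
        self.depthwise_kernel = depthwise_kernel
        self.pointwise_maps = pointwise_maps
        self.depthwise_layout = depthwise_layout
        self.grid_index = grid_index
        self.learning_rate = learning_rate
        self.n_epochs = n_epochs
        self.batch_size = batch_size
        self.standardize = standardize
        self.random_state = random_state

    # ------------------------------------------------------------------ #

    def _validate_x(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, :, None]
        if X.ndim != 3:
            raise ParameterError(
                "X must be (samples, channels, bands) or (samples, channels)"
            )
        if not np.all(np.isfinite(X)):
            raise ParameterError("X contains non-finite values")
        return X

    def _resolve_operator(self, n_channels: int) -> SpectralOperator:
        adj = self.adjacency
        if adj is None:
            adj = np.eye(n_channels)
        if isinstance(adj, SpectralOperator):
            op = adj
        else:
            op = build_spectral_operator(adj)
        if op.n_channels != n_channels:
            raise ParameterError(
                f"graph has {op.n_channels} nodes but features have "
                f"{n_channels} channels"
            )
        return op

    def fit(self, X, y):
        X = self._validate_x(X)
        y = np.asarray(y)
        if y.shape != (X.shape[0],):
            raise ParameterError("y must have one label per sample")
        if self.cheb_order < 0:
            raise ParameterError("cheb_order must be >= 0")
        if self.depthwise_kernel < 1 or self.depthwise_kernel % 2 == 0:
            raise ParameterError("depthwise_kernel must be a positive odd integer")
        if self.depthwise_layout not in ("nodes", "grid"):
            raise ParameterError("depthwise_layout must be 'nodes' or 'grid'")
        if self.depthwise_layout == "grid" and self.grid_index is None:
            raise ParameterError("grid layout requires grid_index")

        self.classes_, y_enc = np.unique(y, return_inverse=True)
        n, n_nodes, n_bands = X.shape
        m = len(self.classes_)
        self.n_features_in_ = n_nodes * n_bands

        self.operator_ = self._resolve_operator(n_nodes)
        self.cheb_terms_ = np.stack(
            cheb_polynomials(self.operator_, self.cheb_order)
        )

        if self.standardize:
            self.feature_mean_ = X.mean(axis=0)
            scale = X.std(axis=0)
            scale[scale == 0.0] = 1.0
            self.feature_scale_ = scale
        else:
            self.feature_mean_ = np.zeros((n_nodes, n_bands))
            self.feature_scale_ = np.ones((n_nodes, n_bands))
        Xs = (X - self.feature_mean_) / self.feature_scale_

        rng = np.random.default_rng(self.random_state)
        k1 = self.cheb_order + 1
        c1, c2 = self.n_maps, self.pointwise_maps

        def glorot(*shape, fan_in, fan_out):
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, size=shape)

        params = {
            "W1": glorot(k1, n_bands, c1, fan_in=k1 * n_bands, fan_out=c1),
            "b1": np.zeros(c1),
            "Wp": glorot(c1, c2, fan_in=c1, fan_out=c2),
            "bp": np.zeros(c2),
            "Wd": glorot(n_nodes * c2, m, fan_in=n_nodes * c2, fan_out=m),
            "bd": np.zeros(m),
        }
        if self.depthwise_layout == "nodes":
            kd = self.depthwise_kernel
            params["Kd"] = glorot(kd, c1, fan_in=kd, fan_out=1)
        else:
            params["Kd"] = glorot(3, 3, c1, fan_in=9, fan_out=1)
            gi = np.asarray(self.grid_index, dtype=int)
            if gi.shape != (n_nodes, 2):
                raise ParameterError("grid_index must be (n_channels, 2)")
            self._grid_rc_ = gi

        opt = _Adam(params, lr=self.learning_rate)
        self.loss_curve_: list[float] = []
        n_batches = max(1, int(np.ceil(n / self.batch_size)))
        for _epoch in range(self.n_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for b in range(n_batches):
                idx = order[b * self.batch_size : (b + 1) * self.batch_size]
                if idx.size == 0:
                    continue
                loss, grads = self._loss_and_grads(Xs[idx], y_enc[idx], params)
                if not np.isfinite(loss):
                    raise EstimationError(
                        f"training diverged (non-finite loss at epoch {_epoch})"
                    )
                opt.step(params, grads)
                epoch_loss += loss * idx.size
            self.loss_curve_.append(epoch_loss / n)
        self.params_ = params
        self.n_iter_ = self.n_epochs
        return self

    # ------------------------------------------------------------------ #

    def _depthwise_forward(self, a1: np.ndarray, params: dict):
        if self.depthwise_layout == "nodes":
            kd = params["Kd"]  # (K, c1)
            K = kd.shape[0]
            pad = K // 2
            a1p = np.pad(a1, ((0, 0), (pad, pad), (0, 0)))
            nn = a1.shape[1]
            dw = np.zeros_like(a1)
            for t in range(K):
                dw += kd[t] * a1p[:, t : t + nn, :]
            return dw, a1p
        # grid layout: scatter nodes onto the 8x9 image, 3x3 depthwise, gather
        b, nn, c1 = a1.shape
        rc = self._grid_rc_
        img = np.zeros((b, 8 + 2, 9 + 2, c1))
        img[:, rc[:, 0] + 1, rc[:, 1] + 1, :] = a1
        kd = params["Kd"]  # (3, 3, c1)
        out_img = np.zeros((b, 8, 9, c1))
        for dr in range(3):
            for dc in range(3):
                out_img += kd[dr, dc] * img[:, dr : dr + 8, dc : dc + 9, :]
        dw = out_img[:, rc[:, 0], rc[:, 1], :]
        return dw, img

    def _depthwise_backward(self, d_dw: np.ndarray, cache, params: dict):
        if self.depthwise_layout == "nodes":
            a1p = cache
            kd = params["Kd"]
            K = kd.shape[0]
            pad = K // 2
            nn = d_dw.shape[1]
            d_kd = np.zeros_like(kd)
            d_a1p = np.zeros_like(a1p)
            for t in range(K):
                d_kd[t] = np.einsum("bnc,bnc->c", d_dw, a1p[:, t : t + nn, :])
                d_a1p[:, t : t + nn, :] += kd[t] * d_dw
            d_a1 = d_a1p[:, pad : pad + nn, :] if pad else d_a1p
            return d_a1, d_kd
        img = cache
        rc = self._grid_rc_
        b, nn, c1 = d_dw.shape
        d_out_img = np.zeros((b, 8, 9, c1))
        d_out_img[:, rc[:, 0], rc[:, 1], :] = d_dw
        kd = params["Kd"]
        d_kd = np.zeros_like(kd)
        d_img = np.zeros_like(img)
        for dr in range(3):
            for dc in range(3):
                patch = img[:, dr : dr + 8, dc : dc + 9, :]
                d_kd[dr, dc] = np.einsum("brcx,brcx->x", d_out_img, patch)
                d_img[:, dr : dr + 8, dc : dc + 9, :] += kd[dr, dc] * d_out_img
        d_a1 = d_img[:, rc[:, 0] + 1, rc[:, 1] + 1, :]
        return d_a1, d_kd

    def _forward(self, Xs: np.ndarray, params: dict):
        tx = np.einsum("knm,bmf->kbnf", self.cheb_terms_, Xs)
        z1 = np.einsum("kbnf,kfc->bnc", tx, params["W1"]) + params["b1"]
        a1 = np.maximum(z1, 0.0)
        dw, dw_cache = self._depthwise_forward(a1, params)
        z2 = dw @ params["Wp"] + params["bp"]
        a2 = np.maximum(z2, 0.0)
        flat = a2.reshape(a2.shape[0], -1)
        logits = flat @ params["Wd"] + params["bd"]
        probs = _softmax(logits)
        cache = (tx, z1, a1, dw, dw_cache, z2, a2, flat)
        return probs, cache

    def _loss_and_grads(self, Xs, y_enc, params):
        b = Xs.shape[0]
        probs, cache = self._forward(Xs, params)
        tx, z1, a1, dw, dw_cache, z2, a2, flat = cache
        loss = cross_entropy_loss(probs, y_enc, reduction="mean")

        d_logits = probs.copy()
        d_logits[np.arange(b), y_enc] -= 1.0
        d_logits /= b
        grads = {
            "Wd": flat.T @ d_logits,
            "bd": d_logits.sum(axis=0),
        }
        d_flat = d_logits @ params["Wd"].T
        d_a2 = d_flat.reshape(a2.shape)
        d_z2 = d_a2 * (z2 > 0)
        grads["Wp"] = np.einsum("bnc,bnd->cd", dw, d_z2)
        grads["bp"] = d_z2.sum(axis=(0, 1))
        d_dw = d_z2 @ params["Wp"].T
        d_a1, d_kd = self._depthwise_backward(d_dw, dw_cache, params)
        grads["Kd"] = d_kd
        d_z1 = d_a1 * (z1 > 0)
        grads["W1"] = np.einsum("kbnf,bnc->kfc", tx, d_z1)
        grads["b1"] = d_z1.sum(axis=(0, 1))
        return loss, grads

    # ------------------------------------------------------------------ #

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        X = self._validate_x(X)
        if X.shape[1:] != self.feature_mean_.shape:
            raise ParameterError(
                f"X has shape {X.shape[1:]}, model was fit on "
                f"{self.feature_mean_.shape}"
            )
        Xs = (X - self.feature_mean_) / self.feature_scale_
        probs, _ = self._forward(Xs, self.params_)
        return probs

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


# Thin functional wrappers matching the train / forward / evaluate surface.

def train(model: ChebGCNClassifier, X, y) -> tuple[ChebGCNClassifier, list[float]]:
    """Fit the classifier; returns the model and its per-epoch loss history."""
    model.fit(X, y)
    return model, model.loss_curve_


def forward(model: ChebGCNClassifier, X) -> np.ndarray:
    """Per-sample class probabilities of a fitted model."""
    return model.predict_proba(X)


def evaluate(model: ChebGCNClassifier, X, y) -> dict:
    """Accuracy and per-class confusion counts on a test set."""
    y = np.asarray(y)
    if y.size == 0:
        raise ParameterError("empty test set")
    pred = model.predict(X)
    acc = float(np.mean(pred == y))
    conf = confusion_matrix(y, pred, labels=model.classes_)
    return {"accuracy": acc, "confusion": conf}
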