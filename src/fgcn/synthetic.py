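"""Seeded synthetic multichannel EEG-like data with class-dependent structure.

The generator emulates the layout of SEED-style emotion datasets: per
subject, a sequence of labelled trials of multichannel signals, from which
per-second, per-channel, per-band differential-entropy (DE) features are
computed. Class structure enters twice:

* each class has its own sparse set of directed lag-1 couplings in a
  stationary vector autoregression, so functional (correlation) and causal
  (Granger) channel graphs genuinely differ by class and graph-recovery
  metrics have a ground truth;
* a class-dependent mean shift is added to the DE features of the coupled
  (driven) channels in the high-frequency bands, giving a tunable
  classification difficulty knob.

Every dataset is bit-reproducible from (spec, seed): all randomness flows
through ``numpy.random.SeedSequence`` chains of small integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.signal import periodogram

from .connectivity import SignalEpochs
from .exceptions import ParameterError
from .gcn import BAND_NAMES, FeatureBatch

DEFAULT_BANDS: tuple[tuple[str, float, float], ...] = (
    ("delta", 1.0, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 14.0),
    ("beta", 14.0, 31.0),
    ("gamma", 31.0, 50.0),
)


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the synthetic EEG generator.

    Defaults mirror the SEED recording layout: 62 channels at 200 Hz,
    15 subjects, 3 emotion classes with 5 trials each (first 9 of the 15
    interleaved trials train, last 6 test), five standard frequency bands,
    and 1-second DE feature windows.
    """

    n_channels: int = 62
    n_subjects: int = 15
    n_classes: int = 3
    trials_per_class: int = 5
    fs: float = 200.0
    duration: float = 10.0
    var_order: int = 1
    coupling_strength: float | tuple[float, ...] = 0.7
    n_edges_per_class: int = 15
    ar_coeff: float = 0.5
    noise_sd: float = 1.0
    class_effect: float = 1.0
    effect_bands: tuple[str, ...] = ("beta", "gamma")
    feature_noise_sd: float = 0.0
    split_fraction: float = 0.6
    band_definitions: tuple[tuple[str, float, float], ...] = DEFAULT_BANDS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 2 or self.n_classes < 2:
            raise ParameterError("need >= 2 channels and >= 2 classes")
        if self.var_order < 1:
            raise ParameterError("var_order must be >= 1")
        if not 0.0 < self.split_fraction < 1.0:
            raise ParameterError("split_fraction must lie in (0, 1)")
        prev_hi = 0.0
        for name, lo, hi in self.band_definitions:
            if not (0.0 < lo < hi):
                raise ParameterError(f"band {name} has invalid range ({lo}, {hi})")
            if hi > self.fs / 2:
                raise ParameterError(f"band {name} exceeds the Nyquist frequency")
            if lo < prev_hi:
                raise ParameterError("bands must be disjoint and ordered")
            prev_hi = hi
        for b in self.effect_bands:
            if b not in {n for n, _, _ in self.band_definitions}:
                raise ParameterError(f"unknown effect band {b!r}")

    def coupling_for_class(self, class_idx: int) -> float:
        if np.isscalar(self.coupling_strength):
            return float(self.coupling_strength)
        strengths = tuple(self.coupling_strength)
        if len(strengths) != self.n_classes:
            raise ParameterError(
                "coupling_strength must be scalar or one value per class"
            )
        return float(strengths[class_idx])

    @property
    def n_trials(self) -> int:
        return self.n_classes * self.trials_per_class

    @property
    def samples_per_trial(self) -> int:
        return int(round(self.fs * self.duration))


def class_coupling(spec: SynthSpec, class_idx: int) -> tuple[np.ndarray, list]:
    """Lag-1 coefficient matrix and ground-truth edge list for one class.

    Edges are drawn acyclically (upper-triangular under a class-specific
    node ordering), so the VAR eigenvalues equal the self-regression
    coefficient and the process is stationary by construction. Edge
    ``(i, j)`` means channel j drives channel i.
    """
    if not 0 <= class_idx < spec.n_classes:
        raise ParameterError(f"class index {class_idx} out of range")
    n = spec.n_channels
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 97, class_idx]))
    order = rng.permutation(n)
    max_edges = n * (n - 1) // 2
    n_edges = min(spec.n_edges_per_class, max_edges)
    pairs = [(a, b) for a in range(n) for b in range(a + 1, n)]
    chosen = rng.choice(len(pairs), size=n_edges, replace=False)
    strength = spec.coupling_for_class(class_idx)
    a = np.eye(n) * spec.ar_coeff
    edges = []
    for c in chosen:
        lo_pos, hi_pos = pairs[c]
        driver, driven = int(order[lo_pos]), int(order[hi_pos])
        a[driven, driver] = strength
        edges.append((driven, driver))
    radius = float(np.max(np.abs(np.linalg.eigvals(a))))
    if radius >= 1.0:
        raise ParameterError(
            f"class {class_idx} coupling is non-stationary (spectral radius "
            f"{radius:.3f} >= 1)"
        )
    return a, edges


def generate_var_signals(
    spec: SynthSpec,
    class_idx: int,
    seed: int | None = None,
    n_trials: int | None = None,
) -> SignalEpochs:
    """Stationary VAR realizations of one class's coupling graph.

    Gaussian innovations with ``spec.noise_sd``; a 200-sample burn-in is
    discarded so trials start near the stationary distribution. All trials
    of the class are simulated in one vectorized sweep.
    """
    if seed is None:
        seed = spec.seed
    if n_trials is None:
        n_trials = spec.trials_per_class
    a, _ = class_coupling(spec, class_idx)
    n = spec.n_channels
    t_len = spec.samples_per_trial
    burn = 200
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11, class_idx]))
    x = np.zeros((n_trials, n))
    out = np.empty((n_trials, n, t_len))
    for t in range(burn + t_len):
        eps = rng.normal(0.0, spec.noise_sd, size=(n_trials, n))
        x = x @ a.T + eps
        if t >= burn:
            out[:, :, t - burn] = x
    labels = np.full(n_trials, class_idx, dtype=int)
    return SignalEpochs(data=out, fs=spec.fs, labels=labels)


def compute_de_features(
    signals: SignalEpochs,
    bands: Sequence[tuple[str, float, float]] = DEFAULT_BANDS,
    window_s: float = 1.0,
) -> FeatureBatch:
    """Band-wise differential entropy per window, channel and band.

    Each trial is cut into non-overlapping windows of ``window_s`` seconds;
    per window and channel the band variance sigma^2_band is the
    periodogram power integrated over the band, and the DE feature is the
    Gaussian closed form ``0.5 * ln(2 pi e sigma^2_band)``. Samples are
    windows; labels are inherited from the window's trial.
    """
    fs = signals.fs
    win = int(round(fs * window_s))
    if win < 2:
        raise ParameterError("window too short for a periodogram")
    n_win = signals.n_times // win
    if n_win < 1:
        raise ParameterError("trial shorter than one feature window")
    for name, lo, hi in bands:
        if hi > fs / 2:
            raise ParameterError(f"band {name} exceeds the Nyquist frequency")
    n_trials, n_ch = signals.n_trials, signals.n_channels
    segs = signals.data[:, :, : n_win * win].reshape(n_trials, n_ch, n_win, win)
    freqs, pxx = periodogram(segs, fs=fs, axis=-1, detrend="constant")
    df = freqs[1] - freqs[0]
    feats = np.empty((n_trials, n_win, n_ch, len(bands)))
    for b, (_, lo, hi) in enumerate(bands):
        mask = (freqs >= lo) & (freqs < hi)
        var_band = pxx[..., mask].sum(axis=-1) * df
        feats[..., b] = 0.5 * np.log(
            2.0 * np.pi * np.e * np.maximum(var_band, 1e-30)
        ).transpose(0, 2, 1)
    x = feats.reshape(n_trials * n_win, n_ch, len(bands))
    y = np.repeat(signals.labels, n_win)
    trial_index = np.repeat(np.arange(n_trials), n_win)
    selector = "total" if len(bands) == len(BAND_NAMES) else bands[0][0]
    return FeatureBatch(x=x, y=y, band_selector=selector, trial_index=trial_index)


@dataclass(frozen=True)
class SubjectDataset:
    """One synthetic subject: ordered trials, split, features, ground truth."""

    subject: int
    signals: SignalEpochs
    train_trials: np.ndarray
    test_trials: np.ndarray
    train: FeatureBatch
    test: FeatureBatch
    true_edges: dict = field(default_factory=dict)


def _split_trials(n_trials: int, fraction: float) -> tuple[np.ndarray, np.ndarray]:
    n_train = int(round(n_trials * fraction))
    if n_train < 1 or n_train >= n_trials:
        raise ParameterError("too few trials to split into train and test")
    return np.arange(n_train), np.arange(n_train, n_trials)


def make_subject(spec: SynthSpec, subject: int, seed: int | None = None) -> SubjectDataset:
    """Generate one subject: interleaved class trials, DE features, split.

    Trials are ordered class-interleaved (c0, c1, c2, c0, ...) so the
    first-fraction/last-fraction split — first 9 / last 6 for the 3-class
    default — contains every class on both sides. Class mean shifts of
    ``spec.class_effect`` are added to the DE features of each class's
    driven channels in ``spec.effect_bands``.
    """
    if seed is None:
        seed = spec.seed
    m = spec.n_classes
    subject_seed = int(
        np.random.SeedSequence([seed, 5, subject]).generate_state(1)[0] % (2**31)
    )
    per_class = [
        generate_var_signals(spec, c, seed=subject_seed) for c in range(m)
    ]
    edges = {c: class_coupling(spec, c)[1] for c in range(m)}
    order = [
        (c, t) for t in range(spec.trials_per_class) for c in range(m)
    ]
    data = np.stack([per_class[c].data[t] for c, t in order])
    labels = np.array([c for c, _ in order], dtype=int)
    signals = SignalEpochs(data=data, fs=spec.fs, labels=labels)

    feats = compute_de_features(signals, bands=spec.band_definitions)
    x = feats.x.copy()
    band_names = [n for n, _, _ in spec.band_definitions]
    effect_cols = [band_names.index(b) for b in spec.effect_bands]
    for c in range(m):
        driven = sorted({i for i, _ in edges[c]})
        if not driven:
            continue
        rows = feats.y == c
        for col in effect_cols:
            x[np.ix_(rows, driven, [col])] += spec.class_effect
    if spec.feature_noise_sd > 0:
        noise_rng = np.random.default_rng(
            np.random.SeedSequence([seed, 7, subject])
        )
        x = x + noise_rng.normal(0.0, spec.feature_noise_sd, size=x.shape)

    train_tr, test_tr = _split_trials(signals.n_trials, spec.split_fraction)
    for side, trials in (("train", train_tr), ("test", test_tr)):
        present = set(labels[trials])
        if present != set(range(m)):
            raise ParameterError(
                f"{side} split is missing classes {set(range(m)) - present}"
            )
    in_train = np.isin(feats.trial_index, train_tr)
    train = FeatureBatch(
        x=x[in_train],
        y=feats.y[in_train],
        band_selector=feats.band_selector,
        trial_index=feats.trial_index[in_train],
    )
    test = FeatureBatch(
        x=x[~in_train],
        y=feats.y[~in_train],
        band_selector=feats.band_selector,
        trial_index=feats.trial_index[~in_train],
    )
    return SubjectDataset(
        subject=subject,
        signals=signals,
        train_trials=train_tr,
        test_trials=test_tr,
        train=train,
        test=test,
        true_edges=edges,
    )


def make_classification_dataset(
    spec: SynthSpec, seed: int | None = None
) -> list[SubjectDataset]:
    """All subjects of a synthetic study, each with its train/test split."""
    return [make_subject(spec, s, seed=seed) for s in range(spec.n_subjects)]


def chance_level_spec(spec: SynthSpec | None = None) -> SynthSpec:
    """A null variant: no coupling differences and no class effect, so a
    trained model's test accuracy is at chance (1 / n_classes)."""
    base = spec if spec is not None else SynthSpec()
    return replace(base, coupling_strength=0.0, class_effect=0.0)


def hemispheric_pairs(channel_names: Sequence[str]) -> list[tuple[int, int]]:
    """Left/right electrode pairs by 10-20 naming (odd left, even right).

    Used for DASM-style asymmetry features: DE(left) - DE(right).
    """
    index = {n.upper(): i for i, n in enumerate(channel_names)}
    pairs = []
    for name, i in index.items():
        if name[-1].isdigit():
            digit = int(name[-1])
            if digit % 2 == 1:
                partner = f"{name[:-1]}{digit + 1}"
                if partner in index:
                    pairs.append((i, index[partner]))
    return sorted(pairs)


def compute_dasm(batch: FeatureBatch, channel_names: Sequence[str]) -> FeatureBatch:
    """Differential-asymmetry features: DE differences over hemispheric pairs."""
    pairs = hemispheric_pairs(channel_names)
    if not pairs:
        raise ParameterError("no hemispheric pairs found in channel names")
    left = np.array([p[0] for p in pairs])
    right = np.array([p[1] for p in pairs])
    return FeatureBatch(
        x=batch.x[:, left, :] - batch.x[:, right, :],
        y=batch.y,
        band_selector=batch.band_selector,
        trial_index=batch.trial_index,
    )
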