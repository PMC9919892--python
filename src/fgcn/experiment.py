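"""Experiment harness: subject-wise runs, aggregation, ablations, figures.

The evaluation protocol mirrors subject-dependent emotion-recognition
studies: for each subject, channel graphs are estimated from the training
trials only (no test leakage), the per-kind graphs are normalized,
sparsified and fused per the configuration, a Chebyshev GCN is trained on
the training split's DE features, and accuracy is measured on the held-out
trials. Reported numbers are the mean and standard deviation over
subjects. Ablations sweep the adjacency mode (random / identity /
correlation / causality / fusion) or the fusion strategy under shared
seeds and shared data, so rows differ only in the quantity ablated.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from matplotlib.figure import Figure
from matplotlib import colormaps
from matplotlib.image import imsave

from . import io as fio
from .connectivity import (
    average_graphs,
    build_baseline_graph,
    build_causal_graph,
    build_functional_graph,
    build_topological_graph,
)
from .exceptions import ParameterError
from .fusion import FUSION_STRATEGIES, fuse, prepare_component
from .gcn import ChebGCNClassifier, evaluate, select_band
from .montage import Montage, default_montage
from .synthetic import SubjectDataset, SynthSpec, make_classification_dataset

ADJACENCY_MODES = ("random", "identity", "correlation", "causality", "fusion")


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one experiment run."""

    spec: SynthSpec = field(default_factory=SynthSpec)
    montage_path: str | None = None
    band: str = "total"
    adjacency_mode: str = "fusion"
    fusion_strategy: str = "add"
    sparsify_rule: str = "percentile"
    sparsify_value: float = 50.0
    theta: float | None = None
    knn: int = 10
    diffusion_iterations: int = 20
    model_params: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.adjacency_mode not in ADJACENCY_MODES:
            raise ParameterError(
                f"adjacency_mode must be one of {ADJACENCY_MODES}"
            )
        if self.fusion_strategy not in FUSION_STRATEGIES:
            raise ParameterError(
                f"fusion_strategy must be one of {FUSION_STRATEGIES}"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        spec = SynthSpec(**_tuplify(raw.pop("spec", {})))
        return cls(spec=spec, **raw)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _tuplify(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, list):
            out[k] = tuple(tuple(e) if isinstance(e, list) else e for e in v)
        else:
            out[k] = v
    return out


@dataclass(frozen=True)
class EvalReport:
    """Aggregated results of one experiment run.

    ``created_at`` is provenance only and excluded from equality, so two
    runs of the same config+seed compare equal field-by-field.
    """

    adjacency_mode: str
    fusion_strategy: str
    band: str
    seed: int
    config_hash: str
    subject_accuracies: tuple[float, ...]
    mean_accuracy: float
    std_accuracy: float
    confusions: tuple[tuple[tuple[int, ...], ...], ...]
    train_trials: tuple[int, ...]
    test_trials: tuple[int, ...]
    graph_trials: tuple[int, ...]
    partition_hash: str
    created_at: str = field(default="", compare=False)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_accuracies)

    def to_dict(self, with_timestamp: bool = False) -> dict:
        d = asdict(self)
        if not with_timestamp:
            d.pop("created_at")
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _derived_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


def _partition_hash(train: np.ndarray, test: np.ndarray) -> str:
    payload = json.dumps([train.tolist(), test.tolist()])
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _resolve_montage(config: ExperimentConfig) -> Montage:
    if config.montage_path is not None:
        return Montage.from_csv(config.montage_path)
    return default_montage(config.spec.n_channels)


def _component_graph(
    kind: str,
    subject: SubjectDataset,
    montage: Montage,
    config: ExperimentConfig,
    cache: dict,
):
    """Estimate one connectivity kind from the subject's TRAINING trials."""
    if kind in cache:
        return cache[kind]
    if kind == "topological":
        g = build_topological_graph(montage, theta=config.theta)
    elif kind == "functional":
        g = average_graphs(
            [
                build_functional_graph(
                    subject.signals, trial=int(t),
                    channel_names=montage.channel_names,
                )
                for t in subject.train_trials
            ]
        )
    elif kind == "causal":
        g = average_graphs(
            [
                build_causal_graph(
                    subject.signals, trial=int(t), order=config.spec.var_order,
                    channel_names=montage.channel_names,
                )
                for t in subject.train_trials
            ]
        )
    else:  # pragma: no cover - internal misuse
        raise ParameterError(f"unknown component kind {kind!r}")
    cache[kind] = g
    return g


def subject_adjacency(
    mode: str,
    subject: SubjectDataset,
    montage: Montage,
    config: ExperimentConfig,
    cache: dict,
    strategy: str | None = None,
):
    """The adjacency a given mode feeds to the spectral operator.

    Baselines are used raw; single-graph modes (correlation, causality)
    pass through the same row normalization + sparsification as fusion
    components, so the operator always sees non-negative weights; fusion
    combines topological, causal and functional components (in that order)
    under the configured strategy.
    """
    n = subject.signals.n_channels
    if mode == "identity":
        return build_baseline_graph("identity", n)
    if mode == "random":
        return build_baseline_graph(
            "random", n, seed=_derived_seed(config.seed, 23, subject.subject)
        )
    prep = lambda g: prepare_component(  # noqa: E731
        g, rule=config.sparsify_rule, value=config.sparsify_value
    )
    if mode == "correlation":
        comp = _component_graph("functional", subject, montage, config, cache)
        return prep(comp).weights
    if mode == "causality":
        comp = _component_graph("causal", subject, montage, config, cache)
        return prep(comp).weights
    if mode == "fusion":
        parts = [
            prep(_component_graph(k, subject, montage, config, cache))
            for k in ("topological", "causal", "functional")
        ]
        return fuse(
            parts,
            strategy=strategy or config.fusion_strategy,
            knn=config.knn,
            iterations=config.diffusion_iterations,
            channel_names=montage.channel_names,
        )
    raise ParameterError(f"unknown adjacency mode {mode!r}")


def _evaluate_mode(
    config: ExperimentConfig,
    mode: str,
    strategy: str,
    subjects: Sequence[SubjectDataset],
    montage: Montage,
    graph_caches: Sequence[dict],
) -> EvalReport:
    accs, confs = [], []
    for subject, cache in zip(subjects, graph_caches):
        adjacency = subject_adjacency(
            mode, subject, montage, config, cache, strategy=strategy
        )
        model_params = dict(config.model_params)
        model = ChebGCNClassifier(
            adjacency=adjacency,
            random_state=_derived_seed(config.seed, 41, subject.subject),
            **model_params,
        )
        train_batch = select_band(subject.train, config.band)
        test_batch = select_band(subject.test, config.band)
        model.fit(train_batch.x, train_batch.y)
        res = evaluate(model, test_batch.x, test_batch.y)
        accs.append(res["accuracy"])
        confs.append(tuple(tuple(int(v) for v in row) for row in res["confusion"]))
    first = subjects[0]
    return EvalReport(
        adjacency_mode=mode,
        fusion_strategy=strategy,
        band=config.band,
        seed=config.seed,
        config_hash=config.config_hash(),
        subject_accuracies=tuple(float(a) for a in accs),
        mean_accuracy=float(np.mean(accs)),
        std_accuracy=float(np.std(accs)),
        confusions=tuple(confs),
        train_trials=tuple(int(t) for t in first.train_trials),
        test_trials=tuple(int(t) for t in first.test_trials),
        graph_trials=tuple(int(t) for t in first.train_trials),
        partition_hash=_partition_hash(first.train_trials, first.test_trials),
        created_at=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )


def run_experiment(config: ExperimentConfig) -> EvalReport:
    """Run the full subject-wise protocol for one configuration."""
    montage = _resolve_montage(config)
    subjects = make_classification_dataset(config.spec, seed=config.seed)
    caches = [dict() for _ in subjects]
    report = _evaluate_mode(
        config, config.adjacency_mode, config.fusion_strategy, subjects,
        montage, caches,
    )
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_json(out / f"report_{config.adjacency_mode}.json")
    return report


def ablate_adjacency(
    config: ExperimentConfig, modes: Sequence[str] = ADJACENCY_MODES
) -> pd.DataFrame:
    """Mean/std accuracy per adjacency mode, on shared data and seeds."""
    montage = _resolve_montage(config)
    subjects = make_classification_dataset(config.spec, seed=config.seed)
    caches = [dict() for _ in subjects]
    rows = {}
    for mode in modes:
        rep = _evaluate_mode(
            config, mode, config.fusion_strategy, subjects, montage, caches
        )
        rows[mode] = {
            "mean_accuracy": rep.mean_accuracy,
            "std_accuracy": rep.std_accuracy,
            "partition_hash": rep.partition_hash,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "adjacency_mode"
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "ablate_adjacency.csv")
    return df


def ablate_fusion_strategy(
    config: ExperimentConfig, strategies: Sequence[str] = FUSION_STRATEGIES
) -> pd.DataFrame:
    """Mean/std accuracy per fusion strategy (adjacency mode 'fusion')."""
    montage = _resolve_montage(config)
    subjects = make_classification_dataset(config.spec, seed=config.seed)
    caches = [dict() for _ in subjects]
    rows = {}
    for strategy in strategies:
        rep = _evaluate_mode(config, "fusion", strategy, subjects, montage, caches)
        rows[strategy] = {
            "mean_accuracy": rep.mean_accuracy,
            "std_accuracy": rep.std_accuracy,
            "partition_hash": rep.partition_hash,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "fusion_strategy"
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "ablate_fusion.csv")
    return df


def ablate_bands(
    config: ExperimentConfig,
    bands: Sequence[str] = ("delta", "theta", "alpha", "beta", "gamma", "total"),
) -> pd.DataFrame:
    """Mean/std accuracy per frequency band for the configured adjacency."""
    rows = {}
    for band in bands:
        rep = run_experiment(replace(config, band=band, out_dir=None))
        rows[band] = {
            "mean_accuracy": rep.mean_accuracy,
            "std_accuracy": rep.std_accuracy,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "band"
    return df


def export_heatmaps(
    graphs: dict[str, np.ndarray],
    out_dir: str | Path,
    cmap: str = "viridis",
    raw: bool = False,
) -> list[Path]:
    """One heatmap PNG per graph, channel-ordered axes, shared color scale.

    ``raw=True`` writes one image pixel per matrix entry (no axes), which
    is exactly invertible through the color map.
    """
    if not graphs:
        raise ParameterError("no graphs to export")
    shapes = {np.asarray(g).shape for g in graphs.values()}
    if len(shapes) != 1:
        raise ParameterError(f"graphs disagree in shape: {shapes}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mats = {k: np.asarray(v, dtype=float) for k, v in graphs.items()}
    vmin = min(m.min() for m in mats.values())
    vmax = max(m.max() for m in mats.values())
    paths = []
    for name, mat in mats.items():
        path = out_dir / f"{name}.png"
        if raw:
            imsave(path, mat, cmap=cmap, vmin=vmin, vmax=vmax, origin="upper")
        else:
            fig = Figure(figsize=(4.5, 4.0))
            ax = fig.add_subplot(111)
            im = ax.imshow(mat, cmap=colormaps[cmap], vmin=vmin, vmax=vmax)
            ax.set_title(name)
            ax.set_xlabel("channel")
            ax.set_ylabel("channel")
            fig.colorbar(im, ax=ax, shrink=0.85)
            fig.savefig(path, dpi=120)
        paths.append(path)
    return paths


def export_component_heatmaps(
    config: ExperimentConfig, subject_idx: int = 0, out_dir: str | Path = "."
) -> list[Path]:
    """Export per-component graphs plus the fused graph for one subject,
    as CSVs and heatmaps on a shared color scale."""
    montage = _resolve_montage(config)
    subjects = make_classification_dataset(config.spec, seed=config.seed)
    subject = subjects[subject_idx]
    cache: dict = {}
    prep = lambda g: prepare_component(  # noqa: E731
        g, rule=config.sparsify_rule, value=config.sparsify_value
    )
    comps = {
        k: prep(_component_graph(k, subject, montage, config, cache)).weights
        for k in ("topological", "causal", "functional")
    }
    fused = subject_adjacency("fusion", subject, montage, config, cache)
    comps["fused"] = fused.weights
    for name, mat in comps.items():
        fio.save_matrix_csv(
            mat, Path(out_dir) / f"{name}.csv", montage.channel_names
        )
    return export_heatmaps(comps, out_dir)
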