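"""Repeated-learning protocol: N passes over a corpus, per-trial metrics.

Trial k is one full pass of the learner over every song of the corpus (fixed
song order), followed by one round of chunk detection. The per-trial metrics
are the total chunk count, the hierarchy depth and the total Bayesian
surprise of the pass, plus their z-scores across trials — the three readouts
tracked over fifteen trials of learning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corpus import SymbolSequence
from .model import HBSLModel, ModelConfig


@dataclass
class ExperimentConfig:
    n_trials: int = 15
    n_generated_per_model: int = 20
    model: ModelConfig = field(default_factory=ModelConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass
class TrialMetrics:
    trial: int
    n_chunks: int
    hierarchy: int
    total_surprise: float
    z_chunks: float = float("nan")
    z_hierarchy: float = float("nan")
    z_surprise: float = float("nan")


def zscore(values) -> np.ndarray:
    """Standardize with the population SD; constant input maps to zeros."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("zscore needs at least two values")
    sd = arr.std()
    if sd == 0.0:
        warnings.warn("constant input to zscore; returning zeros", stacklevel=2)
        return np.zeros_like(arr)
    return (arr - arr.mean()) / sd


def run_learning(
    corpus: list[SymbolSequence], config: ExperimentConfig | None = None
) -> tuple[list[HBSLModel], list[TrialMetrics]]:
    """Train one model on a corpus over repeated trials.

    Returns one model snapshot per trial (the state after that trial's pass
    and chunk detection) and the per-trial metrics with z-scored columns.
    Deterministic: learning itself involves no randomness; the seed is only
    recorded on the model for downstream generation.
    """
    if not corpus:
        raise ValueError("corpus must be non-empty")
    config = config or ExperimentConfig()
    model = HBSLModel(config=config.model, seed=config.seed)
    snapshots: list[HBSLModel] = []
    metrics: list[TrialMetrics] = []
    for trial in range(1, config.n_trials + 1):
        total = 0.0
        for song in corpus:
            total += sum(model.observe_sequence(song))
        model.detect_and_create_chunks()
        snapshots.append(model.snapshot())
        metrics.append(
            TrialMetrics(
                trial=trial,
                n_chunks=model.chunk_count(),
                hierarchy=model.hierarchy_depth(),
                total_surprise=total,
            )
        )
    if config.n_trials >= 2:
        for name, attr in (
            ("z_chunks", "n_chunks"),
            ("z_hierarchy", "hierarchy"),
            ("z_surprise", "total_surprise"),
        ):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                zs = zscore([getattr(m, attr) for m in metrics])
            for m, z in zip(metrics, zs):
                setattr(m, name, float(z))
    return snapshots, metrics


def run_learning_per_song(
    corpus: list[SymbolSequence], config: ExperimentConfig | None = None
) -> dict[str, tuple[list[HBSLModel], list[TrialMetrics]]]:
    """Alternative protocol: one independent model per song.

    Returns ``{song_id: (snapshots, metrics)}``; each song is learned in
    isolation over the same number of trials.
    """
    if not corpus:
        raise ValueError("corpus must be non-empty")
    config = config or ExperimentConfig()
    return {
        song.source_id or f"song-{i}": run_learning([song], config)
        for i, song in enumerate(corpus)
    }


def metrics_table(metrics: list[TrialMetrics]) -> pd.DataFrame:
    """Per-trial metrics as a tidy table (raw and z-scored columns)."""
    return pd.DataFrame(
        {
            "trial": [m.trial for m in metrics],
            "n_chunks": [m.n_chunks for m in metrics],
            "hierarchy": [m.hierarchy for m in metrics],
            "total_surprise": [m.total_surprise for m in metrics],
            "z_chunks": [m.z_chunks for m in metrics],
            "z_hierarchy": [m.z_hierarchy for m in metrics],
            "z_surprise": [m.z_surprise for m in metrics],
        }
    )
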