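"""Distributional comparisons: Bayesian surprise (KL), bigram distributions,
Jensen-Shannon drift trajectories, and t-SNE embeddings of generated songs
against their training corpus.

All comparisons live at the base-token bigram level: chunk-level output is
expanded to base tokens first, so generated and original songs share a
support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.manifold import TSNE

from .corpus import SymbolSequence

Bigram = tuple[str, str]


@dataclass
class DistributionVector:
    """A probability distribution over an ordered bigram support."""

    support: tuple[Bigram, ...]
    probs: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if len(self.probs) != len(self.support):
            raise ValueError("support and probs length mismatch")
        if np.any(self.probs < 0) or abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("probs must be a distribution (>=0, sum 1)")


def align_supports(vectors: Sequence[DistributionVector]) -> list[DistributionVector]:
    """Re-express distributions on the sorted union of their supports."""
    union = sorted({bg for v in vectors for bg in v.support})
    index = {bg: i for i, bg in enumerate(union)}
    out = []
    for v in vectors:
        probs = np.zeros(len(union))
        for bg, p in zip(v.support, v.probs):
            probs[index[bg]] = p
        out.append(DistributionVector(tuple(union), probs, v.label))
    return out


def kl_divergence(
    p: DistributionVector | np.ndarray,
    q: DistributionVector | np.ndarray,
    smoothing: float = 1e-9,
) -> float:
    """D_KL(P || Q) = sum_i P(i) log(P(i)/Q(i)), natural log.

    Terms with P(i)=0 contribute zero. Where Q has sampling zeros on P's
    support, Q receives additive smoothing so the divergence stays finite.
    """
    pv = p.probs if isinstance(p, DistributionVector) else np.asarray(p, float)
    qv = q.probs if isinstance(q, DistributionVector) else np.asarray(q, float)
    if isinstance(p, DistributionVector) and isinstance(q, DistributionVector):
        if p.support != q.support:
            raise ValueError("distributions must share a support (align_supports)")
    if pv.shape != qv.shape:
        raise ValueError("distributions must share a support")
    if np.any((pv > 0) & (qv == 0)):
        qv = qv + smoothing
        qv = qv / qv.sum()
    mask = pv > 0
    return float(np.sum(pv[mask] * np.log(pv[mask] / qv[mask])))


def js_distance(
    p: DistributionVector | np.ndarray, q: DistributionVector | np.ndarray
) -> float:
    """Jensen-Shannon distance (sqrt of the base-e JS divergence).

    Symmetric, bounded in [0, sqrt(ln 2)]; no smoothing needed because the
    mixture is positive wherever either input is.
    """
    pv = p.probs if isinstance(p, DistributionVector) else np.asarray(p, float)
    qv = q.probs if isinstance(q, DistributionVector) else np.asarray(q, float)
    m = 0.5 * (pv + qv)
    div = 0.5 * kl_divergence(pv, m) + 0.5 * kl_divergence(qv, m)
    return float(np.sqrt(max(div, 0.0)))


def bigram_distribution(seq: SymbolSequence, label: str = "") -> DistributionVector:
    """Empirical base-token bigram distribution of one song."""
    tokens = seq.tokens
    if len(tokens) < 2:
        raise ValueError("need at least two tokens for a bigram distribution")
    counts: dict[Bigram, int] = {}
    for a, b in zip(tokens[:-1], tokens[1:]):
        counts[(a, b)] = counts.get((a, b), 0) + 1
    support = tuple(sorted(counts))
    probs = np.array([counts[bg] for bg in support], dtype=float)
    return DistributionVector(support, probs / probs.sum(), label or seq.source_id)


def average_generated_distribution(
    songs: Sequence[SymbolSequence], label: str = ""
) -> DistributionVector:
    """Arithmetic mean of per-song bigram distributions, renormalized.

    Songs with fewer than two tokens are skipped with a warning.
    """
    dists = []
    for song in songs:
        if len(song.tokens) < 2:
            warnings.warn(f"skipping short song {song.source_id!r}", stacklevel=2)
            continue
        dists.append(bigram_distribution(song))
    if not dists:
        raise ValueError("no song long enough for a bigram distribution")
    aligned = align_supports(dists)
    mean = np.mean([v.probs for v in aligned], axis=0)
    return DistributionVector(aligned[0].support, mean / mean.sum(), label)


def distance_trajectory(
    trial_vectors: Sequence[DistributionVector], original: DistributionVector
) -> list[float]:
    """Jensen-Shannon distance of each trial's distribution from the original."""
    aligned = align_supports([original, *trial_vectors])
    ref = aligned[0]
    return [js_distance(v, ref) for v in aligned[1:]]


def tsne_embed(
    vectors: Sequence[DistributionVector],
    perplexity: float = 5.0,
    seed: int = 0,
) -> np.ndarray:
    """2-D t-SNE embedding of distributions under Jensen-Shannon distance.

    Pairwise JS distances are precomputed; with the small point counts used
    here (about 16: the original corpus plus one per trial) a perplexity of
    5 is appropriate. Deterministic under a fixed seed.
    """
    n = len(vectors)
    if n < 3:
        raise ValueError("t-SNE needs at least three distributions")
    if perplexity >= n - 1:  # sklearn requires perplexity < n_samples - 1
        raise ValueError(f"perplexity {perplexity} too high for {n} points")
    aligned = align_supports(vectors)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = js_distance(aligned[i], aligned[j])
    emb = TSNE(
        n_components=2,
        metric="precomputed",
        init="random",
        perplexity=perplexity,
        random_state=seed,
    ).fit_transform(dist)
    return np.asarray(emb)
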