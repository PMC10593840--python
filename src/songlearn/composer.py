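"""Probabilistic song generation from a trained model.

Production walks the learned transition structure at the highest populated
hierarchy level: a start unit is drawn from the marginal of observed
contexts, successors from the Dirichlet posterior mean restricted to
successors that were actually observed, and every sampled unit is expanded
recursively to base tokens. With an empty chunk inventory this reduces
exactly to a first-order Markov sampler on base tokens.
"""

from __future__ import annotations

import numpy as np

from .corpus import SymbolSequence, write_midi  # re-exported for convenience
from .model import HBSLModel, UntrainedModelError

__all__ = [
    "generate_song",
    "generate_set",
    "expand_to_tokens",
    "level0_transition_matrix",
    "write_midi",
]


def expand_to_tokens(symbol_id: str, model: HBSLModel) -> list[str]:
    """Flatten a unit to base tokens: a chunk expands to its children's
    concatenated expansions; a base token to itself."""
    return list(model.expand(symbol_id))


def _top_level(model: HBSLModel) -> int:
    levels = [lvl for (lvl, _ctx), row in model.rows.items() if row.counts]
    if not levels:
        raise UntrainedModelError("model has no observed transitions")
    return max(levels)


def _observed_distribution(row) -> tuple[list[str], np.ndarray]:
    succ = sorted(row.counts)
    weights = np.array([row.alpha[s] for s in succ], dtype=float)
    return succ, weights / weights.sum()


def generate_song(
    model: HBSLModel,
    target_len: int,
    seed: int,
    source_id: str = "generated",
    tempo: float = 120.0,
) -> SymbolSequence:
    """Sample one song of ``target_len`` base tokens from the model.

    Units are sampled at the highest level with observed transitions,
    falling back level-by-level (ultimately to the level-0 row of the last
    expanded token) when the current context has no observed successor at
    the preferred level. The expansion is truncated to exactly
    ``target_len`` tokens. Deterministic under a fixed seed.
    """
    top = _top_level(model)
    rng = np.random.default_rng(seed)

    def sample_start() -> str:
        ctxs = sorted(
            ctx for (lvl, ctx), row in model.rows.items() if lvl == top and row.counts
        )
        weights = np.array(
            [sum(model.rows[(top, c)].counts.values()) for c in ctxs], dtype=float
        )
        return ctxs[rng.choice(len(ctxs), p=weights / weights.sum())]

    def sample_next(unit: str) -> str | None:
        for level in range(top, -1, -1):
            ctx = unit
            if level == 0 and model.symbols[unit].level > 0:
                ctx = model.expand(unit)[-1]
            row = model.rows.get((level, ctx))
            if row is not None and row.counts:
                succ, probs = _observed_distribution(row)
                return succ[rng.choice(len(succ), p=probs)]
        return None

    tokens: list[str] = []
    unit = sample_start()
    tokens.extend(model.expand(unit))
    while len(tokens) < target_len:
        nxt = sample_next(unit)
        if nxt is None:
            nxt = sample_start()
        tokens.extend(model.expand(nxt))
        unit = nxt
    return SymbolSequence(tokens=tokens[:target_len], source_id=source_id, tempo=tempo)


def generate_set(
    model: HBSLModel,
    n_songs: int,
    target_len: int,
    seed: int,
    tempo: float = 120.0,
) -> list[SymbolSequence]:
    """Generate ``n_songs`` independent songs (seed offsets per song)."""
    return [
        generate_song(
            model,
            target_len,
            seed=int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % 2**31),
            source_id=f"gen-{i:03d}",
            tempo=tempo,
        )
        for i in range(n_songs)
    ]


def level0_transition_matrix(model: HBSLModel) -> tuple[list[str], np.ndarray]:
    """The level-0 production matrix: posterior-mean rows renormalized over
    observed successors (the distribution generation actually samples)."""
    vocab = sorted(model.pools.get(0, {}))
    index = {t: i for i, t in enumerate(vocab)}
    mat = np.zeros((len(vocab), len(vocab)))
    for tok in vocab:
        row = model.rows.get((0, tok))
        if row is None or not row.counts:
            continue
        succ, probs = _observed_distribution(row)
        for s, p in zip(succ, probs):
            mat[index[tok], index[s]] = p
    return vocab, mat
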