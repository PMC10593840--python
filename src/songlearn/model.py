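"""Dirichlet-Markov sequence learner with reliability-gated chunking.

The learner maintains, for every context unit, a Dirichlet posterior over its
successors (symmetric prior, pseudo-count ``alpha_prior`` per known
successor). From a row it derives

* the transition probability — the Dirichlet posterior mean ``alpha_i/alpha_0``;
* the reliability — the inverse of the marginal (Beta) variance
  ``alpha_i (alpha_0 - alpha_i) / (alpha_0^2 (alpha_0 + 1))``.

Reliability grows with the amount of evidence even when the mean stays fixed:
nine B's after ten A's and ninety B's after a hundred A's both give a 90 %
transition probability, but the latter is far more reliable. Transitions whose
normalized probability-reliability product exceeds a constant ``c`` are merged
into chunk units; chunks of chunks cascade into a hierarchy. Each observation
pass parses a song with the current chunk inventory, updates the rows at every
representation level, and reports the Bayesian surprise
``KL(row before || row after)`` of each update.
"""

from __future__ import annotations

import copy
import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

from .corpus import SymbolSequence

RELIABILITY_CAP = 1e12


class UntrainedModelError(RuntimeError):
    """Raised when an operation requires at least one observed transition."""


@dataclass(frozen=True)
class Symbol:
    """A unit of the vocabulary: a base token (level 0) or a chunk.

    A chunk's ``children`` are the two unit ids it merges; its level is one
    above the deeper child, so expansion to base tokens is finite and acyclic.
    """

    id: str
    level: int
    children: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if (self.level == 0) != (len(self.children) == 0):
            raise ValueError("level 0 iff children empty")


@dataclass
class DirichletRow:
    """Per-context pseudo-count vector (prior floor included in ``alpha``)."""

    context: str
    alpha: dict[str, float] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def alpha0(self) -> float:
        return sum(self.alpha.values())


def transition_probability(
    row: DirichletRow, successor: str, alpha_prior: float = 1.0
) -> float:
    """Dirichlet posterior mean of the transition ``context -> successor``.

    A successor absent from the row is treated at the prior floor, as if it
    had just entered the vocabulary.
    """
    if not row.alpha:
        raise UntrainedModelError("row has an empty successor vocabulary")
    if successor in row.alpha:
        return row.alpha[successor] / row.alpha0
    return alpha_prior / (row.alpha0 + alpha_prior)


def beta_variance(alpha_i: float, alpha_0: float) -> float:
    """Marginal variance of one Dirichlet component: Beta(a_i, a_0 - a_i)."""
    return alpha_i * (alpha_0 - alpha_i) / (alpha_0**2 * (alpha_0 + 1.0))


def reliability(row: DirichletRow, successor: str, alpha_prior: float = 1.0) -> float:
    """Inverse marginal variance of the transition probability.

    Capped at ``RELIABILITY_CAP`` when the variance is exactly zero (a row
    whose whole mass sits on one successor).
    """
    if not row.alpha:
        raise UntrainedModelError("row has an empty successor vocabulary")
    if successor in row.alpha:
        a_i, a_0 = row.alpha[successor], row.alpha0
    else:
        a_i, a_0 = alpha_prior, row.alpha0 + alpha_prior
    var = beta_variance(a_i, a_0)
    if var <= 0.0:
        warnings.warn("zero-variance transition; reliability capped", stacklevel=2)
        return RELIABILITY_CAP
    return min(1.0 / var, RELIABILITY_CAP)


@dataclass(frozen=True)
class TransitionStats:
    """Probability, variance and reliability of one observed transition."""

    context: str
    successor: str
    probability: float
    variance: float
    reliability: float


def transition_stats(row: DirichletRow, successor: str) -> TransitionStats:
    p = transition_probability(row, successor)
    a_i = row.alpha.get(successor, 1.0)
    a_0 = row.alpha0 if successor in row.alpha else row.alpha0 + 1.0
    var = beta_variance(a_i, a_0)
    return TransitionStats(row.context, successor, p, var, reliability(row, successor))


@dataclass
class ModelConfig:
    """Hyperparameters of the learner.

    c is the chunking threshold on the normalized probability-reliability
    product; 5 means "jointly five times the typical same-level transition".
    """

    alpha_prior: float = 1.0
    c: float = 5.0
    max_level: int = 5
    #: prior_baseline (default) | row_loo_product | level_loo_product | mean_separate
    normalization: str = "prior_baseline"


class HBSLModel:
    """Hierarchical Bayesian statistical learner over symbol sequences.

    State: the base vocabulary, the chunk inventory (chunks are never
    deleted), and one Dirichlet row per (representation level, context unit).
    Level 0 is the raw token stream; level ``l`` is the stream re-parsed with
    all chunks of level <= l by greedy longest match.
    """

    def __init__(self, config: ModelConfig | None = None, seed: int = 0) -> None:
        self.config = config or ModelConfig()
        self.seed = seed
        self.symbols: dict[str, Symbol] = {}
        self.chunk_order: list[str] = []  # creation order of chunks
        self.rows: dict[tuple[int, str], DirichletRow] = {}
        self.pools: dict[int, dict[str, None]] = {}  # level -> ordered symbol set
        self._expansion_cache: dict[str, tuple[str, ...]] = {}
        self._charmap: dict[str, str] = {}
        self._pattern_cache: dict[str, str] = {}
        self.n_observed_transitions = 0

    # -- vocabulary ---------------------------------------------------------

    def _register(self, symbol_id: str, level: int) -> None:
        if symbol_id not in self.symbols:
            self.symbols[symbol_id] = Symbol(id=symbol_id, level=0)
        self.pools.setdefault(level, {}).setdefault(symbol_id, None)

    def add_chunk(self, children: tuple[str, str]) -> Symbol:
        """Create (or return) the chunk merging two existing units."""
        for ch in children:
            if ch not in self.symbols:
                raise KeyError(f"chunk child {ch!r} not in vocabulary")
        cid = f"({children[0]}+{children[1]})"
        if cid in self.symbols:
            return self.symbols[cid]
        level = 1 + max(self.symbols[ch].level for ch in children)
        sym = Symbol(id=cid, level=level, children=children)
        self.symbols[cid] = sym
        self.chunk_order.append(cid)
        return sym

    @property
    def inventory(self) -> list[Symbol]:
        return [self.symbols[cid] for cid in self.chunk_order]

    def chunk_count(self) -> int:
        """Total number of chunks ever created (never decreases)."""
        return len(self.chunk_order)

    def hierarchy_depth(self) -> int:
        """Maximum unit level in the vocabulary; 0 with no chunks."""
        if not self.chunk_order:
            return 0
        return max(self.symbols[cid].level for cid in self.chunk_order)

    def expand(self, symbol_id: str) -> tuple[str, ...]:
        """Flatten a unit to its base-token expansion (identity at level 0)."""
        cached = self._expansion_cache.get(symbol_id)
        if cached is not None:
            return cached
        sym = self.symbols.get(symbol_id)
        if sym is None:
            raise KeyError(f"unknown symbol {symbol_id!r}")
        if sym.level == 0:
            out: tuple[str, ...] = (symbol_id,)
        else:
            out = tuple(t for ch in sym.children for t in self.expand(ch))
        self._expansion_cache[symbol_id] = out
        return out

    # -- parsing ------------------------------------------------------------

    def _char(self, token: str) -> str:
        ch = self._charmap.get(token)
        if ch is None:
            ch = chr(0xE000 + len(self._charmap))  # private-use area
            self._charmap[token] = ch
        return ch

    def _chunk_pattern(self, cid: str) -> str:
        pat = self._pattern_cache.get(cid)
        if pat is None:
            pat = "".join(self._char(t) for t in self.expand(cid))
            self._pattern_cache[cid] = pat
        return pat

    def parse(self, tokens: Sequence[str], max_level: int | None = None) -> list[str]:
        """Segment a base-token stream into chunk units by priority matching.

        Chunks claim non-overlapping occurrences in priority order — longest
        expansion first, then earliest created (chunk detection creates the
        strongest-scoring chunks first, so early creation means a stronger
        unit). Within one chunk, occurrences are claimed left to right.
        Unclaimed positions remain base tokens. Deterministic and
        independent of reading direction for the strong units, so a weak
        chunk can never fragment a stronger overlapping one.
        """
        if max_level is None:
            max_level = self.config.max_level
        order = sorted(
            (
                (-len(self.expand(cid)), idx, cid)
                for idx, cid in enumerate(self.chunk_order)
                if self.symbols[cid].level <= max_level
            ),
        )
        stream = "".join(self._char(t) for t in tokens)
        n = len(stream)
        claimed = bytearray(n)  # 0 free; else unit index + 1
        claims: dict[int, tuple[str, int]] = {}  # start -> (chunk id, length)
        for _neglen, _idx, cid in order:
            pat = self._chunk_pattern(cid)
            ln = len(pat)
            pos = stream.find(pat)
            while pos != -1:
                if not any(claimed[pos : pos + ln]):
                    for j in range(pos, pos + ln):
                        claimed[j] = 1
                    claims[pos] = (cid, ln)
                    pos = stream.find(pat, pos + ln)
                else:
                    pos = stream.find(pat, pos + 1)
        units: list[str] = []
        i = 0
        while i < n:
            if i in claims:
                cid, ln = claims[i]
                units.append(cid)
                i += ln
            else:
                units.append(tokens[i])
                i += 1
        return units

    # -- observation --------------------------------------------------------

    def _get_row(self, level: int, context: str) -> DirichletRow:
        key = (level, context)
        row = self.rows.get(key)
        if row is None:
            floor = self.config.alpha_prior
            row = DirichletRow(
                context=context,
                alpha={s: floor for s in self.pools.get(level, {})},
            )
            self.rows[key] = row
        return row

    def _update(self, row: DirichletRow, successor: str) -> float:
        """Add one observation to a row; return KL(pre || post) in nats.

        Closed form of the Dirichlet-mean update: with pre-counts ``a`` and
        total ``a0``, KL = log((a0+1)/a0) + (a_j/a0) log(a_j/(a_j+1)).
        """
        floor = self.config.alpha_prior
        if successor not in row.alpha:
            row.alpha[successor] = floor  # lazy vocabulary entry
        a_j = row.alpha[successor]
        a_0 = row.alpha0
        kl = math.log((a_0 + 1.0) / a_0) + (a_j / a_0) * math.log(a_j / (a_j + 1.0))
        row.alpha[successor] = a_j + 1.0
        row.counts[successor] = row.counts.get(successor, 0) + 1
        self.n_observed_transitions += 1
        return kl

    def representations(self, tokens: Sequence[str]) -> list[tuple[int, list[str]]]:
        """Distinct parses of a token stream at each hierarchy level.

        Level 0 is always the raw stream; higher levels are included only
        when adding that level's chunks changes the parse.
        """
        reps: list[tuple[int, list[str]]] = [(0, list(tokens))]
        depth = self.hierarchy_depth()
        prev = list(tokens)
        for level in range(1, depth + 1):
            units = self.parse(tokens, max_level=level)
            if units != prev:
                reps.append((level, units))
                prev = units
        return reps

    def observe_sequence(self, seq: SymbolSequence) -> list[float]:
        """Learn one song; return the per-event Bayesian-surprise trace.

        The song is represented at level 0 (raw tokens) and at every level
        whose chunks change the parse; every adjacent unit pair in every
        representation increments its row by one pseudo-count.
        """
        if not seq.tokens:
            return []
        for tok in seq.tokens:
            self._register(tok, level=0)
        trace: list[float] = []
        for level, units in self.representations(seq.tokens):
            for u in units:
                self._register(u, level=level)
            for ctx, succ in zip(units[:-1], units[1:]):
                row = self._get_row(level, ctx)
                trace.append(self._update(row, succ))
        return trace

    # -- chunking -----------------------------------------------------------

    def _prior_baseline_product(self, row: DirichletRow) -> float:
        """p*r of a fresh symmetric prior with this row's support size."""
        k = max(len(row.alpha), 2)
        var = beta_variance(1.0, float(k))
        return (1.0 / k) / var

    def candidate_transitions(
        self,
    ) -> list[tuple[int, tuple[int, str], str, str, float, float]]:
        """All observed transitions as (chunk level, row key, ctx, succ, p, r)."""
        out = []
        for key, row in sorted(self.rows.items()):
            ctx = key[1]
            for succ in sorted(row.counts):
                lvl = 1 + max(self.symbols[ctx].level, self.symbols[succ].level)
                p = transition_probability(row, succ, self.config.alpha_prior)
                r = reliability(row, succ, self.config.alpha_prior)
                out.append((lvl, key, ctx, succ, p, r))
        return out

    def chunk_scores(self) -> list[tuple[int, str, str, float]]:
        """Normalized probability-reliability score of each observed transition.

        Scores are comparable to the threshold ``c``. The default
        (``row_loo_product``) divides each transition's p*r by the mean p*r
        of the context's *other* continuations (plus the row's fresh-prior
        baseline), so a transition scores high only when it is jointly more
        probable and more reliable than the typical alternative from the
        same context. This cancels the row-total dependence of the raw
        product (p*r = a0(a0+1)/(a0-a_i)), which would otherwise favour any
        successor of a frequent context. ``level_loo_product`` normalizes
        against all observed transitions whose merge would sit at the same
        hierarchy level; ``mean_separate`` normalizes probability and
        reliability separately by their level means; ``prior_baseline``
        compares against a fresh symmetric prior.
        """
        cands = self.candidate_transitions()
        mode = self.config.normalization
        scores: list[tuple[int, str, str, float]] = []
        if mode == "row_loo_product":
            for lvl, row_key, ctx, succ, p, r in cands:
                row = self.rows[row_key]
                a_0 = row.alpha0
                products = {
                    s: transition_probability(row, s, self.config.alpha_prior)
                    / beta_variance(a, a_0)
                    for s, a in row.alpha.items()
                    if a < a_0  # zero-variance entries excluded from the pool
                }
                base = self._prior_baseline_product(row)
                others = [v for s, v in products.items() if s != succ]
                denom = (sum(others) + base) / (len(others) + 1)
                scores.append((lvl, ctx, succ, (p * r) / denom))
            return scores

        by_level: dict[int, list[int]] = {}
        for i, (lvl, *_rest) in enumerate(cands):
            by_level.setdefault(lvl, []).append(i)
        for lvl, idxs in by_level.items():
            ps = [cands[i][4] for i in idxs]
            rs = [cands[i][5] for i in idxs]
            products = [p * r for p, r in zip(ps, rs)]
            for j, i in enumerate(idxs):
                lvl_i, row_key, ctx, succ, p, r = cands[i]
                base = self._prior_baseline_product(self.rows[row_key])
                if mode == "level_loo_product":
                    others = [products[k] for k in range(len(idxs)) if k != j]
                    denom = (sum(others) + base) / (len(others) + 1)
                    score = products[j] / denom
                elif mode == "mean_separate":
                    score = (p / (sum(ps) / len(ps))) * (r / (sum(rs) / len(rs)))
                elif mode == "prior_baseline":
                    score = products[j] / base
                else:
                    raise ValueError(f"unknown normalization {mode!r}")
                scores.append((lvl_i, ctx, succ, score))
        return scores

    def detect_and_create_chunks(self) -> list[Symbol]:
        """Create chunk units for transitions whose score exceeds ``c``.

        Evaluated on a snapshot of the current statistics; existing chunks
        are never duplicated or removed. Returns the newly created symbols.
        """
        created: list[Symbol] = []
        existing = {self.symbols[cid].children for cid in self.chunk_order}
        ranked = sorted(
            self.chunk_scores(), key=lambda t: (-t[3], t[0], t[1], t[2])
        )  # strongest first: creation order doubles as parse priority
        for lvl, ctx, succ, score in ranked:
            if score <= self.config.c:
                continue
            if lvl > self.config.max_level:
                continue
            if (ctx, succ) in existing:
                continue
            created.append(self.add_chunk((ctx, succ)))
            existing.add((ctx, succ))
        return created

    # -- serialization ------------------------------------------------------

    def snapshot(self) -> "HBSLModel":
        return copy.deepcopy(self)

    def to_json(self, path: str | Path | None = None) -> str:
        """Serialize the full model state to a JSON document."""
        doc = {
            "config": asdict(self.config),
            "seed": self.seed,
            "symbols": [
                {"id": s.id, "level": s.level, "children": list(s.children)}
                for s in self.symbols.values()
            ],
            "chunk_order": self.chunk_order,
            "pools": {str(k): list(v) for k, v in self.pools.items()},
            "rows": [
                {
                    "level": level,
                    "context": ctx,
                    "alpha": row.alpha,
                    "counts": row.counts,
                }
                for (level, ctx), row in self.rows.items()
            ],
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "HBSLModel":
        text = str(text_or_path)
        if isinstance(text_or_path, Path):
            text = text_or_path.read_text()
        else:
            try:
                if Path(text).exists():
                    text = Path(text).read_text()
            except (OSError, ValueError):
                pass  # not a path: treat as a JSON document
        doc = json.loads(text)
        model = cls(config=ModelConfig(**doc["config"]), seed=doc["seed"])
        for s in doc["symbols"]:
            model.symbols[s["id"]] = Symbol(
                id=s["id"], level=s["level"], children=tuple(s["children"])
            )
        model.chunk_order = list(doc["chunk_order"])
        model.pools = {int(k): dict.fromkeys(v) for k, v in doc["pools"].items()}
        for r in doc["rows"]:
            model.rows[(r["level"], r["context"])] = DirichletRow(
                context=r["context"],
                alpha=dict(r["alpha"]),
                counts={k: int(v) for k, v in r["counts"].items()},
            )
        model.n_observed_transitions = sum(
            sum(row.counts.values()) for row in model.rows.values()
        )
        return model

    # -- convenience --------------------------------------------------------

    def recovered_motifs(
        self, motifs: Iterable[tuple[str, ...]], max_level: int = 2
    ) -> list[bool]:
        """Whether each planted motif exists as a single unit of level <= max_level."""
        expansions = {
            self.expand(cid)
            for cid in self.chunk_order
            if self.symbols[cid].level <= max_level
        }
        return [tuple(m) in expansions for m in motifs]
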