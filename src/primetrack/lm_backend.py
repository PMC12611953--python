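"""Autoregressive token-probability backends behind one contract.

A backend takes (context text, continuation text) and returns one natural-log
probability per continuation token under an autoregressive model; only
continuation tokens are scored, the context merely conditions them.  Two toy
backends (uniform and add-one-smoothed bigram) make every downstream analysis
testable with no model download, and a recorded-reply backend exercises the
adapter contract that external pretrained models plug into.

Toy tokenization is deliberately simple: lowercase, strip punctuation from
token edges, split on whitespace.  External adapters own their tokenization
and report their own token counts, which is why absolute surprisal values are
only comparable within a backend.
"""

from __future__ import annotations

import math
import string
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Mapping, Protocol, Sequence, runtime_checkable

BOS = "<s>"
UNK = "<unk>"

_STRIP_CHARS = string.punctuation + "…"


class ScoringError(ValueError):
    """Raised when a continuation cannot be scored (e.g. empty after tokenizing)."""


def tokenize(text: str) -> list[str]:
    """Lowercase whitespace tokenization with edge punctuation stripped."""
    tokens = []
    for raw in text.lower().split():
        tok = raw.strip(_STRIP_CHARS)
        if tok:
            tokens.append(tok)
    return tokens


@dataclass(frozen=True)
class TokenScore:
    token: str
    logprob: float  # natural log; <= 0 for any proper probability model

    def __post_init__(self) -> None:
        if self.logprob > 1e-12:
            raise ValueError(f"logprob must be <= 0, got {self.logprob}")


@dataclass(frozen=True)
class BackendDescriptor:
    name: str
    vocabulary_size: int | None
    tokenizer_policy: str


@runtime_checkable
class Backend(Protocol):
    """Adapter contract: ordered continuation-token scores given a context."""

    descriptor: BackendDescriptor

    def score(self, context: str, continuation: str) -> list[TokenScore]: ...


class UniformBackend:
    """Every token of a ``vocab_size`` vocabulary is equally likely.

    Context-free by construction; each continuation token scores −ln(V).
    """

    def __init__(self, vocab_size: int = 10):
        if vocab_size < 1:
            raise ValueError("vocab_size must be >= 1")
        self.vocab_size = vocab_size
        self.descriptor = BackendDescriptor(
            name=f"uniform{vocab_size}",
            vocabulary_size=vocab_size,
            tokenizer_policy="lowercase, strip edge punctuation, whitespace split",
        )

    def score(self, context: str, continuation: str) -> list[TokenScore]:
        tokens = tokenize(continuation)
        if not tokens:
            raise ScoringError("empty continuation")
        lp = -math.log(self.vocab_size)
        return [TokenScore(t, lp) for t in tokens]


class BigramBackend:
    """Add-one-smoothed bigram model over a training corpus.

    P(w | v) = (c(v, w) + 1) / (c(v) + V) where c are corpus bigram/left-token
    counts, and V is the vocabulary size including an unknown symbol.  Each
    training sentence is prefixed with a begin-of-sentence symbol; unknown
    tokens (in context or continuation) map to the unknown symbol.  The first
    continuation token conditions on the last context token, or on
    begin-of-sentence when the context is empty.
    """

    def __init__(self, corpus: Sequence[str], name: str = "bigram"):
        if not corpus:
            raise ValueError("corpus must be nonempty")
        self.bigram_counts: Counter[tuple[str, str]] = Counter()
        self.left_counts: Counter[str] = Counter()
        vocab: set[str] = set()
        for sentence in corpus:
            tokens = tokenize(sentence)
            vocab.update(tokens)
            for left, right in zip([BOS] + tokens, tokens):
                self.bigram_counts[(left, right)] += 1
                self.left_counts[left] += 1
        self.vocab = vocab | {UNK}
        self.V = len(self.vocab)
        self.descriptor = BackendDescriptor(
            name=name,
            vocabulary_size=self.V,
            tokenizer_policy="lowercase, strip edge punctuation, whitespace split",
        )

    def _map(self, token: str) -> str:
        return token if token in self.vocab else UNK

    def logprob(self, left: str, right: str) -> float:
        """ln P(right | left) with both tokens mapped into the vocabulary."""
        left = left if left == BOS else self._map(left)
        right = self._map(right)
        num = self.bigram_counts[(left, right)] + 1
        den = self.left_counts[left] + self.V
        return math.log(num / den)

    def score(self, context: str, continuation: str) -> list[TokenScore]:
        cont = tokenize(continuation)
        if not cont:
            raise ScoringError("empty continuation")
        ctx = tokenize(context)
        left = ctx[-1] if ctx else BOS
        scores = []
        for tok in cont:
            scores.append(TokenScore(tok, self.logprob(left, tok)))
            left = tok
        return scores


class RecordedBackend:
    """Replays pre-recorded per-token log probabilities.

    Stands in for an external adapter in tests: proves the scoring layer only
    depends on the (context, continuation) -> ordered log-probabilities
    contract, not on any particular model.
    """

    def __init__(self, replies: Mapping[tuple[str, str], Sequence[float]],
                 name: str = "recorded"):
        self.replies = dict(replies)
        self.descriptor = BackendDescriptor(
            name=name, vocabulary_size=None,
            tokenizer_policy="as recorded by the originating model",
        )

    def score(self, context: str, continuation: str) -> list[TokenScore]:
        key = (context, continuation)
        if key not in self.replies:
            raise ScoringError(f"no recorded scores for {key!r}")
        tokens = tokenize(continuation)
        logprobs = self.replies[key]
        if len(tokens) != len(logprobs):
            # the recording owns tokenization; fall back to positional names
            tokens = [f"tok{i}" for i in range(len(logprobs))]
        return [TokenScore(t, lp) for t, lp in zip(tokens, logprobs)]


# --- registry ----------------------------------------------------------------

_REGISTRY: dict[str, Callable[..., Backend]] = {}


def register_backend(name: str, factory: Callable[..., Backend]) -> None:
    if name in _REGISTRY:
        raise ValueError(f"backend name already registered: {name!r}")
    _REGISTRY[name] = factory


def available_backends() -> list[str]:
    return sorted(_REGISTRY)


def get_backend(name: str, **kwargs) -> Backend:
    """Build a registered backend by name (e.g. ``uniform``, ``bigram``)."""
    if name not in _REGISTRY:
        raise KeyError(
            f"unknown backend {name!r}; available: {available_backends()}"
        )
    return _REGISTRY[name](**kwargs)


register_backend("uniform", UniformBackend)
register_backend("bigram", BigramBackend)

__all__ = [
    "BOS",
    "UNK",
    "ScoringError",
    "tokenize",
    "TokenScore",
    "BackendDescriptor",
    "Backend",
    "UniformBackend",
    "BigramBackend",
    "RecordedBackend",
    "register_backend",
    "available_backends",
    "get_backend",
]
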