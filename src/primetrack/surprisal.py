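"""Conditional surprisal of a production given its target sentence.

The statistic at the centre of the pipeline:

    Surp(P | C) = - sum_{i=1..n} ln P(w_i | C, w_1 .. w_{i-1})

where C is the expected target sentence (here a DO dative), P the cleaned
participant production with tokens w_1..w_n, and the probabilities come from
any registered autoregressive backend.  A higher value means the production is
less predictable given the target — more diverged from the expected output.

Two reductions are carried on every score: the raw sum, and the per-token mean
(sum / n), which smooths out length differences and is the default for group
comparisons.  Individual-trajectory analyses use the raw sum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .corpus import ProductionRecord, records_to_frame
from .lm_backend import Backend, ScoringError, TokenScore

logger = logging.getLogger(__name__)

REDUCTIONS = ("sum", "mean")


@dataclass(frozen=True)
class SurprisalScore:
    """Per-token scores plus both reductions for one (target, production) pair."""

    token_scores: tuple[TokenScore, ...]
    n_tokens: int
    surprisal_sum: float
    surprisal_mean: float
    context: str
    production: str
    backend: str
    reduction: str = "mean"

    @property
    def value(self) -> float:
        """The score under the requested default reduction."""
        return self.surprisal_mean if self.reduction == "mean" else self.surprisal_sum


def conditional_surprisal(
    backend: Backend, target: str, production: str, reduction: str = "mean"
) -> SurprisalScore:
    """Score ``production`` conditioned on ``target`` under ``backend``.

    Only production tokens contribute; the target conditions the chain.  Both
    reductions are always populated; ``reduction`` just selects ``.value``.
    Raises :class:`ScoringError` on an empty production so batch layers can
    skip-and-log.
    """
    if reduction not in REDUCTIONS:
        raise ValueError(f"reduction must be one of {REDUCTIONS}")
    if not production.strip():
        raise ScoringError("empty production")
    token_scores = tuple(backend.score(target, production))
    if not token_scores:
        raise ScoringError("backend returned no token scores")
    total = -sum(ts.logprob for ts in token_scores)
    n = len(token_scores)
    return SurprisalScore(
        token_scores=token_scores,
        n_tokens=n,
        surprisal_sum=total,
        surprisal_mean=total / n,
        context=target,
        production=production,
        backend=backend.descriptor.name,
        reduction=reduction,
    )


def score_corpus(
    backend: Backend,
    records: Sequence[ProductionRecord],
    reduction: str = "mean",
) -> pd.DataFrame:
    """Score every record with a nonempty cleaned production.

    Returns the trials table extended with ``surprisal_sum``,
    ``surprisal_mean``, ``n_tokens`` and ``backend`` columns, in input order.
    Records whose production is empty after cleaning are skipped; the skip
    count is logged and exposed as ``df.attrs["n_skipped"]``.  Zero scorable
    records is an error.
    """
    kept: list[ProductionRecord] = []
    scores: list[SurprisalScore] = []
    n_skipped = 0
    for record in records:
        try:
            score = conditional_surprisal(
                backend, record.target, record.production_clean, reduction
            )
        except ScoringError:
            n_skipped += 1
            continue
        kept.append(record)
        scores.append(score)
    if not scores:
        raise ScoringError("no scorable records (all productions empty)")
    if n_skipped:
        logger.info("score_corpus: skipped %d empty production(s)", n_skipped)
    df = records_to_frame(kept)
    df["surprisal_sum"] = [s.surprisal_sum for s in scores]
    df["surprisal_mean"] = [s.surprisal_mean for s in scores]
    df["n_tokens"] = [s.n_tokens for s in scores]
    df["backend"] = backend.descriptor.name
    df.attrs["n_skipped"] = n_skipped
    df.attrs["reduction"] = reduction
    return df


__all__ = ["REDUCTIONS", "SurprisalScore", "conditional_surprisal", "score_corpus"]
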