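"""Error-taxonomy analyses: encodings, surprisal associations, similarity.

The taxonomy distinguishes grammatical non-target responses (NT_po: the
prepositional-dative re-framing of the DO target; NT_other: other grammatical
structures) from genuinely errorful ones (GE: argument-structure violations,
NS: non-sentential noun strings, LE: lexical substitutions, OTHER:
multi-error responses).  Codes are mutually exclusive.

Associations between per-trial surprisal and one-hot error indicators are
rank-based (Spearman); raw p-values are reported by default, with an optional
Holm correction across the six codes.  The semantic-similarity control uses a
bag-of-words sentence embedder by default (an L2-normalized token-count
vector), which makes the NT_po mechanism inspectable offline: PO re-framings
share almost all content with their DO targets, so their similarity — and
their conditional surprisal under a backend trained on dative sentences —
stays high and low respectively, while noun strings share little.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .corpus import ERROR_CODES, ValidationError
from .lm_backend import tokenize
from .trajectory import TIMEPOINT_PAIRS, two_stage_contrast

logger = logging.getLogger(__name__)

ERROR_PRODUCTION_CODES = frozenset({"GE", "NS", "LE"})


@dataclass(frozen=True)
class SpearmanResult:
    code: str
    rho: float | None
    p_value: float | None
    defined: bool
    n: int


@dataclass(frozen=True)
class SimilarityResult:
    record_ref: str
    cosine: float | None
    defined: bool = True


@dataclass(frozen=True)
class ErrorTimeContrast:
    """Within-group surprisal contrast of error productions, earlier minus later."""

    group: str
    pair: tuple[str, str]
    estimate: float
    std_error: float
    p_value: float
    n_earlier: int
    n_later: int


def one_hot_errors(scored: pd.DataFrame) -> pd.DataFrame:
    """One-hot indicator per error code, indexed like the scored table.

    Correct records encode all-zero; incorrect records encode exactly their
    code.  An incorrect record without a code is a validation error.
    """
    bad = scored[(scored["correct"] == 0) & (scored["error_code"].isna())]
    if len(bad):
        raise ValidationError(
            f"{len(bad)} incorrect record(s) without an error code"
        )
    out = pd.DataFrame(index=scored.index)
    for code in ERROR_CODES:
        out[code] = (scored["error_code"] == code).astype(int)
    return out


def error_spearman(
    scored: pd.DataFrame,
    value: str = "surprisal_mean",
    holm: bool = False,
) -> dict[str, SpearmanResult]:
    """Spearman rank correlation of surprisal with each one-hot error column.

    Constant columns (a code never or always present) and constant surprisal
    yield an undefined result with a flag, never a silent zero.  With
    ``holm=True`` the p-values are Holm-adjusted across the defined codes.
    """
    if len(scored) < 3:
        raise ValueError("need at least 3 records")
    encodings = one_hot_errors(scored)
    surp = scored[value].to_numpy(dtype=float)
    results: dict[str, SpearmanResult] = {}
    defined_codes = []
    for code in ERROR_CODES:
        col = encodings[code].to_numpy()
        if np.ptp(col) == 0 or np.ptp(surp) == 0:
            results[code] = SpearmanResult(code, None, None, False, len(scored))
            continue
        rho, p = stats.spearmanr(surp, col)
        results[code] = SpearmanResult(code, float(rho), float(p), True, len(scored))
        defined_codes.append(code)
    if holm and defined_codes:
        raw = [results[c].p_value for c in defined_codes]
        adjusted = multipletests(raw, method="holm")[1]
        for code, p_adj in zip(defined_codes, adjusted):
            r = results[code]
            results[code] = SpearmanResult(code, r.rho, float(p_adj), True, r.n)
    return results


def error_time_contrasts(
    scored: pd.DataFrame,
    group: str,
    codes: frozenset[str] | set[str] = ERROR_PRODUCTION_CODES,
    value: str = "surprisal_mean",
) -> list[ErrorTimeContrast]:
    """Pairwise time contrasts of error-production surprisal within one group.

    Restricted to genuinely errorful codes (GE/NS/LE by default); the same
    two-stage contrast machinery as the group comparisons, applied across time
    points.  Positive estimates for pre-minus-post pairs mean error
    productions became more target-like.  A group whose such errors occur at
    fewer than two time points yields an empty list (the analysis is skipped,
    mirroring control groups that rarely make these errors).
    """
    sub = scored[(scored["group"] == group) & (scored["error_code"].isin(codes))]
    by_tp = {
        tp: sub[sub["timepoint"] == tp][value].to_numpy(dtype=float)
        for tp in ("pre", "post1", "post2")
    }
    populated = [tp for tp, v in by_tp.items() if len(v) >= 2]
    if len(populated) < 2:
        logger.warning(
            "error_time_contrasts skipped for %s: %s errors at <2 time points",
            group, "/".join(sorted(codes)),
        )
        return []
    results = []
    for a, b in TIMEPOINT_PAIRS:
        if a not in populated or b not in populated:
            continue
        est, se, p = two_stage_contrast(by_tp[a], by_tp[b])
        results.append(
            ErrorTimeContrast(group, (a, b), est, se, p, len(by_tp[a]), len(by_tp[b]))
        )
    return results


# --- semantic similarity -----------------------------------------------------

class BagOfWordsEmbedder:
    """L2-normalized token-count sentence embedding (toy, download-free)."""

    name = "bag_of_words"

    def embed(self, text: str) -> Counter[str]:
        return Counter(tokenize(text))


def _cosine(a, b) -> float | None:
    """Cosine over sparse Counter embeddings or dense vectors alike."""
    if isinstance(a, Counter) and isinstance(b, Counter):
        norm_a = math.sqrt(sum(v * v for v in a.values()))
        norm_b = math.sqrt(sum(v * v for v in b.values()))
        if norm_a == 0.0 or norm_b == 0.0:
            return None
        dot = sum(v * b[k] for k, v in a.items())
        return dot / (norm_a * norm_b)
    va, vb = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    norm_a, norm_b = np.linalg.norm(va), np.linalg.norm(vb)
    if norm_a == 0.0 or norm_b == 0.0:
        return None
    return float(np.dot(va, vb) / (norm_a * norm_b))


def semantic_similarity(
    target: str,
    production: str,
    embedder: BagOfWordsEmbedder | None = None,
    record_ref: str = "",
) -> SimilarityResult:
    """Cosine similarity between the target and production embeddings.

    A zero-norm embedding (e.g. an empty production) gives an undefined,
    flagged result.
    """
    if not target.strip() or not production.strip():
        return SimilarityResult(record_ref, None, defined=False)
    embedder = embedder or BagOfWordsEmbedder()
    cos = _cosine(embedder.embed(target), embedder.embed(production))
    return SimilarityResult(record_ref, cos, defined=cos is not None)


def similarity_by_error_code(
    scored: pd.DataFrame, embedder: BagOfWordsEmbedder | None = None
) -> tuple[pd.Series, Mapping[str, float]]:
    """Per-record cosine column plus the mean cosine per error code."""
    embedder = embedder or BagOfWordsEmbedder()
    cosines = []
    for target, production in zip(scored["target"], scored["production_clean"]):
        result = semantic_similarity(target, production, embedder)
        cosines.append(result.cosine if result.defined else np.nan)
    series = pd.Series(cosines, index=scored.index, name="cosine")
    means = {
        code: float(series[scored["error_code"] == code].mean())
        for code in ERROR_CODES
        if (scored["error_code"] == code).any()
    }
    return series, means


__all__ = [
    "ERROR_PRODUCTION_CODES",
    "SpearmanResult",
    "SimilarityResult",
    "ErrorTimeContrast",
    "one_hot_errors",
    "error_spearman",
    "error_time_contrasts",
    "BagOfWordsEmbedder",
    "semantic_similarity",
    "similarity_by_error_code",
]
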