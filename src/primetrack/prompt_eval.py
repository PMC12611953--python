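"""Few-shot prompt assembly, reply parsing, a rule-based judge, and scoring.

The protocol is "one trial per run": each prompt carries one instruction, six
in-context exemplars (three positive and three negative in correctness mode),
and exactly one query pair, so no state leaks across trials.  Group membership
is never disclosed in prompts.

Live hosted models are out of the default build; the contract accepts any
callable that maps a rendered prompt to a reply string.  The shipped
:class:`RuleJudgeModel` is a deterministic offline classifier built on a frame
parser for DO datives — it doubles as the mock for the reply pipeline and as a
transparent baseline judge.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import re

from sklearn.metrics import f1_score

from .corpus import ERROR_CODES, ProductionRecord
from .lm_backend import tokenize

INVALID = "<invalid>"

MODES = ("correctness", "error_type")

#: Opening excerpt of the correctness instruction; stepwise guidance follows.
INSTRUCTION_CORRECTNESS = (
    "Evaluate the Participant Production against the Target Sentence by "
    "following the step-by-step instructions. Return 1 if the candidate uses "
    "a correct Double Object (DO) structure that matches the target’s "
    "meaning; otherwise return 0."
)

_STEPWISE_CORRECTNESS = (
    "Step 1: Check that the production contains the dative verb.\n"
    "Step 2: Check that the verb is followed by a recipient noun phrase and "
    "then a theme noun phrase, with no preposition introducing the theme or "
    "recipient.\n"
    "Step 3: Check that the nouns preserve the target's meaning.\n"
    "Step 4: Return 1 if all checks pass, otherwise return 0."
)

#: Six-way taxonomy definitions appended as stepwise guidance in error_type mode.
ERROR_TYPE_DEFINITIONS = (
    "Assign exactly one error category to the Participant Production:\n"
    "NT_po: a grammatical prepositional-object dative (the theme is "
    "introduced by 'to', e.g. 'the man is giving the cake to the woman').\n"
    "NT_other: any other grammatical sentence that is not the target "
    "structure.\n"
    "GE: a grammatical error such as omitting obligatory arguments or an "
    "incorrect argument order.\n"
    "NS: a non-sentential response, e.g. a string of nouns with no lexical "
    "verb.\n"
    "LE: a lexical error — an incorrect verb or noun substitution that "
    "deviates from the target.\n"
    "OTHER: multiple error types, or none of the above applies.\n"
    "Return only the category code."
)

#: Stopword inventory for content-overlap checks inside the judge.
_FUNCTION_WORDS = frozenset({"the", "a", "an", "to", "and", "with", "for", "is", "are"})

_PREPOSITIONS = frozenset({"to", "with", "for"})


@dataclass(frozen=True)
class Exemplar:
    target: str
    production: str
    label: str  # "1"/"0" in correctness mode, an error code otherwise


@dataclass(frozen=True)
class PromptBundle:
    """One instruction, a fixed exemplar list, and exactly one query pair."""

    instruction: str
    exemplars: tuple[Exemplar, ...]
    query_target: str
    query_production: str
    mode: str

    def render(self) -> str:
        parts = [self.instruction, ""]
        for i, ex in enumerate(self.exemplars, start=1):
            parts.append(
                f"Example {i}:\nTarget Sentence: {ex.target}\n"
                f"Participant Production: {ex.production}\nLabel: {ex.label}\n"
            )
        parts.append(
            f"Now evaluate:\nTarget Sentence: {self.query_target}\n"
            f"Participant Production: {self.query_production}\nLabel:"
        )
        return "\n".join(parts)


def build_prompt(
    target: str,
    production: str,
    mode: str,
    exemplar_pool: Sequence[Exemplar],
) -> PromptBundle:
    """Assemble a deterministic one-trial prompt.

    Correctness mode requires an exemplar pool of exactly three positive and
    three negative items; error_type mode requires six exemplars and appends
    the six category definitions as stepwise guidance.  Identical inputs
    produce byte-identical prompts.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    exemplars = tuple(exemplar_pool)
    if len(exemplars) != 6:
        raise ValueError("exemplar pool must hold exactly 6 items")
    if mode == "correctness":
        n_pos = sum(1 for e in exemplars if e.label == "1")
        n_neg = sum(1 for e in exemplars if e.label == "0")
        if (n_pos, n_neg) != (3, 3):
            raise ValueError(
                f"correctness pool needs 3 positive and 3 negative exemplars, "
                f"got {n_pos}/{n_neg}"
            )
        instruction = INSTRUCTION_CORRECTNESS + "\n" + _STEPWISE_CORRECTNESS
    else:
        for e in exemplars:
            if e.label not in ERROR_CODES:
                raise ValueError(f"error_type exemplar with non-code label {e.label!r}")
        instruction = (
            INSTRUCTION_CORRECTNESS + "\n" + _STEPWISE_CORRECTNESS + "\n\n"
            + ERROR_TYPE_DEFINITIONS
        )
    return PromptBundle(
        instruction=instruction,
        exemplars=exemplars,
        query_target=target,
        query_production=production,
        mode=mode,
    )


# standalone 0/1: not inside a word or a multi-digit/decimal number
# ("The answer is 0." parses; the "0" of "0.95" does not)
_BINARY_TOKEN_RE = re.compile(r"(?<![\w.])([01])(?!\.?\d)(?!\w)")


def parse_label(reply: str, mode: str) -> str:
    """Extract a label from an arbitrary model reply.

    Correctness mode: the first standalone "0" or "1" token wins.  Error-type
    mode: the earliest occurrence of a canonical code string wins (longest
    match at a tie position).  Anything else is the invalid marker — a value,
    not an exception.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if mode == "correctness":
        m = _BINARY_TOKEN_RE.search(reply)
        return m.group(1) if m else INVALID
    hits = []
    for code in ERROR_CODES:
        m = re.search(rf"\b{re.escape(code)}\b", reply, flags=re.IGNORECASE)
        if m:
            hits.append((m.start(), -len(code), code))
    return min(hits)[2] if hits else INVALID


# --- rule-based judge --------------------------------------------------------

def _inflections(verb: str) -> set[str]:
    forms = {verb, verb + "s"}
    if verb.endswith(("s", "sh", "ch", "x", "z")):
        forms.add(verb + "es")
    return forms


def _content(tokens: Sequence[str]) -> set[str]:
    return {t for t in tokens if t not in _FUNCTION_WORDS}


def _args_after_verb(tokens: Sequence[str], verb_idx: int) -> list[str]:
    return [
        t
        for t in tokens[verb_idx + 1:]
        if t not in _FUNCTION_WORDS and t not in _PREPOSITIONS
    ]


def rule_based_do_judge(
    target: str,
    production: str,
    verb_lexicon: Sequence[str],
    overlap_threshold: float = 0.9,
) -> tuple[str, str | None]:
    """Deterministic DO-structure judge; returns (label, error code or None).

    Returns "1" iff a lexicon verb is present, followed by two noun-phrase
    slots with no preposition introducing them, in the target's argument
    order, and content-word overlap with the target meets the threshold.
    On "0" the code is assigned by the same cues: a "to"-dative frame is
    NT_po; no lexicon verb is NS; a correct frame failing the overlap check is
    LE; anything else (dropped/swapped arguments, spurious prepositions) is
    GE.  An empty production is the invalid marker.
    """
    prod_tokens = tokenize(production)
    if not prod_tokens:
        return INVALID, None
    verb_forms: set[str] = set()
    for v in verb_lexicon:
        verb_forms |= _inflections(v)
    verb_idx = next((i for i, t in enumerate(prod_tokens) if t in verb_forms), None)
    if verb_idx is None:
        return "0", "NS"
    if "to" in prod_tokens[verb_idx + 1:]:
        return "0", "NT_po"
    after = prod_tokens[verb_idx + 1:]
    args = _args_after_verb(prod_tokens, verb_idx)
    frame_ok = len(args) >= 2 and not (_PREPOSITIONS & set(after))
    if not frame_ok:
        return "0", "GE"
    target_tokens = tokenize(target)
    t_verb_idx = next(
        (i for i, t in enumerate(target_tokens) if t in verb_forms), None
    )
    if t_verb_idx is not None:
        t_args = _args_after_verb(target_tokens, t_verb_idx)
        if set(args) == set(t_args) and args != t_args:
            return "0", "GE"  # right arguments, wrong order
    t_content = _content(target_tokens)
    overlap = len(_content(prod_tokens) & t_content) / len(t_content) if t_content else 0.0
    if overlap >= overlap_threshold:
        return "1", None
    return "0", "LE"


class RuleJudgeModel:
    """Reply-producing callable over rendered prompts, backed by the rule judge.

    Serves as the deterministic mock for the live-model adapter contract:
    given a :class:`PromptBundle` it answers with the bare label text, so
    every reply round-trips through :func:`parse_label`.
    """

    def __init__(self, verb_lexicon: Sequence[str], overlap_threshold: float = 0.9):
        self.verb_lexicon = tuple(verb_lexicon)
        self.overlap_threshold = overlap_threshold

    def __call__(self, bundle: PromptBundle) -> str:
        label, code = rule_based_do_judge(
            bundle.query_target,
            bundle.query_production,
            self.verb_lexicon,
            self.overlap_threshold,
        )
        if bundle.mode == "correctness":
            return label if label != INVALID else ""
        if label == "1":
            return "OTHER"  # error-type queries are only posed for incorrect trials
        return code or ""


# --- evaluation --------------------------------------------------------------

@dataclass(frozen=True)
class EvalReport:
    mode: str
    group: str
    f1_positive: float | None  # binary mode only (positive class = "1")
    f1_macro: float
    accuracy: float
    confusion: Mapping[tuple[str, str], int]
    n: int
    n_invalid: int
    per_class_f1: Mapping[str, float] = field(default_factory=dict)


def _evaluate_one(
    predictions: Sequence[str], truths: Sequence[str], mode: str, group: str
) -> EvalReport:
    labels = ["0", "1"] if mode == "correctness" else list(ERROR_CODES)
    confusion = Counter(zip(truths, predictions))
    n = len(truths)
    n_invalid = sum(1 for p in predictions if p == INVALID)
    accuracy = sum(1 for p, t in zip(predictions, truths) if p == t) / n
    per_class = f1_score(
        truths, predictions, labels=labels, average=None, zero_division=0.0
    )
    per_class_f1 = {lab: float(v) for lab, v in zip(labels, per_class)}
    present = [lab for lab in labels if lab in set(truths) | set(predictions)]
    macro = f1_score(
        truths, predictions, labels=present or labels, average="macro",
        zero_division=0.0,
    )
    return EvalReport(
        mode=mode,
        group=group,
        f1_positive=per_class_f1["1"] if mode == "correctness" else None,
        f1_macro=float(macro),
        accuracy=accuracy,
        confusion=dict(confusion),
        n=n,
        n_invalid=n_invalid,
        per_class_f1=per_class_f1,
    )


def evaluate(
    predictions: Sequence[str],
    truths: Sequence[str],
    groups: Sequence[str] | None = None,
    mode: str = "correctness",
) -> dict[str, EvalReport]:
    """Score predictions against ground truth, per group and overall.

    Invalid predictions are kept and always count as wrong (dropping them
    would inflate scores under class imbalance); they are tallied in
    ``n_invalid``.  Binary mode reports positive-class F1 (positive = "1")
    and macro-F1; error-type mode reports matching accuracy and per-class F1.
    Reports are produced for each group present plus "ALL".
    """
    if len(predictions) != len(truths):
        raise ValueError("predictions and truths differ in length")
    if groups is not None and len(groups) != len(truths):
        raise ValueError("groups and truths differ in length")
    out = {"ALL": _evaluate_one(list(predictions), list(truths), mode, "ALL")}
    if groups is not None:
        for g in sorted(set(groups)):
            idx = [i for i, gi in enumerate(groups) if gi == g]
            out[g] = _evaluate_one(
                [predictions[i] for i in idx], [truths[i] for i in idx], mode, g
            )
    return out


def run_prompt_evaluation(
    records: Sequence[ProductionRecord],
    exemplar_pool: Sequence[Exemplar],
    model: Callable[[PromptBundle], str],
    mode: str = "correctness",
) -> dict[str, EvalReport]:
    """End-to-end protocol: build one prompt per labeled record, query, score.

    Correctness mode evaluates every labeled record; error-type mode follows
    the protocol of classifying only records ground-truthed as incorrect.
    """
    predictions, truths, groups = [], [], []
    for r in records:
        if r.correct is None:
            continue
        if mode == "error_type":
            if r.correct != 0 or r.error_code is None:
                continue
            truth = r.error_code
        else:
            truth = str(r.correct)
        bundle = build_prompt(r.target, r.production_clean, mode, exemplar_pool)
        reply = model(bundle)
        predictions.append(parse_label(reply, mode))
        truths.append(truth)
        groups.append(r.group)
    if not truths:
        raise ValueError("no evaluable records for this mode")
    return evaluate(predictions, truths, groups, mode)


def default_exemplar_pool(mode: str = "correctness") -> tuple[Exemplar, ...]:
    """A fixed held-out exemplar pool rendered from the frame grammar."""
    if mode == "correctness":
        return (
            Exemplar("The king gives the queen the rose",
                     "The king gives the queen the rose", "1"),
            Exemplar("The farmer hands the doctor the letter",
                     "The farmer hands the doctor the letter", "1"),
            Exemplar("The singer shows the sailor the coin",
                     "The singer shows the sailor the coin", "1"),
            Exemplar("The nurse serves the clown the burger",
                     "The nurse serves the burger to the clown", "0"),
            Exemplar("The teacher lends the artist the book",
                     "teacher, artist, book", "0"),
            Exemplar("The pirate sends the waiter the cake",
                     "The pirate sends", "0"),
        )
    return (
        Exemplar("The nurse serves the clown the burger",
                 "The nurse serves the burger to the clown", "NT_po"),
        Exemplar("The teacher lends the artist the book",
                 "teacher, artist, book", "NS"),
        Exemplar("The pirate sends the waiter the cake",
                 "The pirate sends", "GE"),
        Exemplar("The king gives the queen the rose",
                 "The king gives the queen the ticket", "LE"),
        Exemplar("The farmer hands the doctor the letter",
                 "The farmer and the doctor like the letter", "NT_other"),
        Exemplar("The singer shows the sailor the coin",
                 "The singer shows the ring to the dancer", "OTHER"),
    )


__all__ = [
    "INVALID",
    "MODES",
    "INSTRUCTION_CORRECTNESS",
    "ERROR_TYPE_DEFINITIONS",
    "Exemplar",
    "PromptBundle",
    "build_prompt",
    "parse_label",
    "rule_based_do_judge",
    "RuleJudgeModel",
    "EvalReport",
    "evaluate",
    "run_prompt_evaluation",
    "default_exemplar_pool",
]
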