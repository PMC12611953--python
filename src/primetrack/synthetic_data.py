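"""Synthetic cohorts of target/production trials with known ground truth.

The generator emulates the statistical structure of a structural-priming
treatment study of the dative alternation: a PWA group with a latent severity
scalar and an AEM control group, three sessions (pre-test, one-day and
one-week post-tests) of DO-dative sentence-production trials, training-induced
accuracy gains concentrated in the pre->post1 window (the post1->post2
increment defaults to 0, i.e. gains are maintained), an inverse-preference
coupling that scales the gain with severity, and a six-way error mixture in
which AEM errors are almost exclusively grammatical prepositional-dative
(NT_po) responses.

Default rates approximate the published class imbalance of the study this
package is designed around (pooled correctness ~36% for PWA and ~50% for AEM,
error mixtures proportional to the published per-code counts); exact counts
remain configurable, not hard-coded.  Productions are generated by the same
frame grammar the rule-based judge parses, so cohorts are noise-free by
construction: every label is internally consistent with its production.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import ERROR_CODES, GROUPS, TIMEPOINTS, ProductionRecord

#: One-syllable dative verbs (base forms) of the kind used as study stimuli.
DEFAULT_VERB_LEXICON = (
    "give", "show", "lend", "serve", "send", "hand", "toss", "sell",
    "mail", "pass", "feed", "bring", "teach", "throw", "read",
)

DEFAULT_NOUN_LEXICON = (
    "nurse", "clown", "burger", "king", "queen", "doctor", "farmer", "singer",
    "teacher", "sailor", "pirate", "waiter", "artist", "dancer", "cake",
    "book", "ball", "kite", "rose", "coin", "ring", "drum", "scarf", "apple",
    "letter", "ticket", "puppy", "robot", "wizard", "cookie",
)

#: Error mixtures proportional to the published per-code counts.
DEFAULT_ERROR_MIXTURE: Mapping[str, Mapping[str, float]] = {
    "PWA": {"NT_po": 745 / 976, "GE": 152 / 976, "OTHER": 28 / 976,
            "LE": 25 / 976, "NS": 19 / 976, "NT_other": 7 / 976},
    "AEM": {"NT_po": 561 / 564, "LE": 1 / 564, "NT_other": 1 / 564,
            "OTHER": 1 / 564},
}

#: Mixture over GE realizations: argument swap, spurious preposition,
#: argument drop.  Weighted so bag-of-words similarity to the target orders
#: the taxonomy as NT_po > GE > LE > NS in expectation.
_GE_VARIANTS = ("swap", "with", "drop")
_GE_WEIGHTS = (0.6, 0.2, 0.2)

_FRAME_RE = re.compile(r"^The (\w+) (\w+) the (\w+) the (\w+)$")


def inflect(verb: str) -> str:
    """Third-person-singular present form ("serve" -> "serves")."""
    if verb.endswith(("s", "sh", "ch", "x", "z")):
        return verb + "es"
    return verb + "s"


@dataclass(frozen=True)
class CohortParams:
    """Generative parameters of a synthetic PWA/AEM cohort.

    ``baseline_accuracy`` is the pre-test correctness probability before the
    severity penalty; a participant with severity s has pre-test accuracy
    baseline - severity_penalty * s.  The pre->post1 gain is
    improvement[(group, "pre_post1")] + inverse_preference_coupling * s, so a
    positive coupling makes more impaired participants improve more (the
    inverse preference effect); the post1->post2 increment defaults to 0
    (maintenance of gains).  All probabilities are clipped to [0, 1].
    """

    n_pwa: int = 24
    n_aem: int = 16
    trials_per_session: int = 15
    pwa_severity: tuple[float, float] = (0.15, 0.95)  # uniform range
    aem_severity: tuple[float, float] = (0.0, 0.1)
    baseline_accuracy: Mapping[str, float] = field(
        default_factory=lambda: {"PWA": 0.45, "AEM": 0.42}
    )
    improvement: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("PWA", "pre_post1"): 0.0, ("PWA", "post1_post2"): 0.0,
            ("AEM", "pre_post1"): 0.135, ("AEM", "post1_post2"): 0.0,
        }
    )
    severity_penalty: float = 0.4
    inverse_preference_coupling: float = 0.4
    error_mixture: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            g: dict(m) for g, m in DEFAULT_ERROR_MIXTURE.items()
        }
    )
    verb_lexicon: tuple[str, ...] = DEFAULT_VERB_LEXICON
    noun_lexicon: tuple[str, ...] = DEFAULT_NOUN_LEXICON
    seed: int = 0

    def validate(self) -> None:
        if len(self.noun_lexicon) < 4:
            raise ValueError(
                "noun lexicon too small for distinct agent/recipient/theme "
                "plus a lexical-error distractor"
            )
        if len(self.verb_lexicon) < 1:
            raise ValueError("verb lexicon is empty")
        for g in GROUPS:
            mixture = self.error_mixture[g]
            if abs(sum(mixture.values()) - 1.0) > 1e-9:
                raise ValueError(f"error mixture for {g} does not sum to 1")
            for code, p in mixture.items():
                if code not in ERROR_CODES:
                    raise ValueError(f"unknown error code in mixture: {code!r}")
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"mixture probability out of range: {p}")
            if not 0.0 <= self.baseline_accuracy[g] <= 1.0:
                raise ValueError("baseline accuracy out of [0, 1]")
        if self.inverse_preference_coupling < 0:
            raise ValueError("inverse_preference_coupling must be >= 0")


@dataclass
class Cohort:
    """Generated records plus the latent ground truth used to generate them."""

    records: list[ProductionRecord]
    participants: pd.DataFrame  # participant_id, group, severity, accuracies
    params: CohortParams
    seed: int

    def ground_truth(self) -> dict:
        """JSON-serializable generative parameters, for recovery tests."""
        return {
            "seed": self.seed,
            "n_pwa": self.params.n_pwa,
            "n_aem": self.params.n_aem,
            "trials_per_session": self.params.trials_per_session,
            "severity_penalty": self.params.severity_penalty,
            "inverse_preference_coupling": self.params.inverse_preference_coupling,
            "baseline_accuracy": dict(self.params.baseline_accuracy),
            "improvement": {
                f"{g}:{w}": v for (g, w), v in self.params.improvement.items()
            },
            "participants": self.participants.to_dict(orient="records"),
        }


def _parse_frame(target: str) -> tuple[str, str, str, str]:
    m = _FRAME_RE.match(target)
    if m is None:
        raise ValueError(f"target does not parse under the DO frame grammar: {target!r}")
    return m.group(1), m.group(2), m.group(3), m.group(4)


def apply_error_transform(
    target: str,
    code: str,
    rng: np.random.Generator,
    noun_lexicon: Sequence[str] = DEFAULT_NOUN_LEXICON,
) -> str:
    """Realize an error code as a structural transform of a DO target.

    The transforms are structural stand-ins for attested error patterns:
    NT_po re-frames the target as a prepositional dative; NT_other is a
    templated grammatical paraphrase outside the dative frame; GE violates
    argument structure (swapped arguments, a spurious preposition, or dropped
    obligatory arguments); NS reduces the response to a noun string with no
    verb; LE substitutes one noun with a seeded distractor; OTHER composes a
    lexical substitution with the PO re-framing (a multi-error response).
    """
    agent, verb, recipient, theme = _parse_frame(target)
    if code == "NT_po":
        return f"The {agent} {verb} the {theme} to the {recipient}"
    if code == "NT_other":
        return f"The {agent} and the {recipient} like the {theme}"
    if code == "GE":
        variant = rng.choice(_GE_VARIANTS, p=_GE_WEIGHTS)
        if variant == "swap":
            return f"The {agent} {verb} the {theme} the {recipient}"
        if variant == "with":
            return f"The {agent} {verb} with the {recipient} the {theme}"
        return f"The {agent} {verb}"
    if code == "NS":
        return f"{agent}, {recipient}, {theme}"
    if code == "LE":
        slot = int(rng.integers(3))
        nouns = [agent, recipient, theme]
        candidates = [n for n in noun_lexicon if n not in nouns]
        nouns[slot] = candidates[int(rng.integers(len(candidates)))]
        return f"The {nouns[0]} {verb} the {nouns[1]} the {nouns[2]}"
    if code == "OTHER":
        substituted = apply_error_transform(target, "LE", rng, noun_lexicon)
        return apply_error_transform(substituted, "NT_po", rng, noun_lexicon)
    raise ValueError(f"unknown error code {code!r}")


def _session_accuracy(params: CohortParams, group: str, severity: float) -> dict[str, float]:
    base = params.baseline_accuracy[group] - params.severity_penalty * severity
    gain1 = (
        params.improvement[(group, "pre_post1")]
        + params.inverse_preference_coupling * severity
    )
    gain2 = gain1 + params.improvement[(group, "post1_post2")]
    return {
        "pre": float(np.clip(base, 0.0, 1.0)),
        "post1": float(np.clip(base + gain1, 0.0, 1.0)),
        "post2": float(np.clip(base + gain2, 0.0, 1.0)),
    }


def generate_cohort(params: CohortParams | None = None, seed: int | None = None) -> Cohort:
    """Generate a full cohort; a pure function of (params, seed).

    Per participant and session, targets are DO datives built from the
    lexicons ("The <agent> <verb>s the <recipient> the <theme>", distinct
    nouns per trial); a correct trial copies its target, an incorrect trial
    draws a code from the group's error mixture and realizes it via
    :func:`apply_error_transform`.
    """
    params = params or CohortParams()
    params.validate()
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)

    roster: list[tuple[str, str, float]] = []
    lo, hi = params.pwa_severity
    for i in range(params.n_pwa):
        roster.append((f"P{i + 1:02d}", "PWA", float(rng.uniform(lo, hi))))
    lo, hi = params.aem_severity
    for i in range(params.n_aem):
        roster.append((f"A{i + 1:02d}", "AEM", float(rng.uniform(lo, hi))))

    records: list[ProductionRecord] = []
    truth_rows = []
    for pid, group, severity in roster:
        acc = _session_accuracy(params, group, severity)
        truth_rows.append(
            {"participant_id": pid, "group": group, "severity": severity,
             "acc_pre": acc["pre"], "acc_post1": acc["post1"],
             "acc_post2": acc["post2"]}
        )
        mixture = params.error_mixture[group]
        codes = list(mixture)
        weights = np.array([mixture[c] for c in codes])
        weights = weights / weights.sum()
        for tp in TIMEPOINTS:
            for k in range(params.trials_per_session):
                verb = params.verb_lexicon[int(rng.integers(len(params.verb_lexicon)))]
                nouns = rng.choice(len(params.noun_lexicon), size=3, replace=False)
                agent, recipient, theme = (params.noun_lexicon[int(j)] for j in nouns)
                target = f"The {agent} {inflect(verb)} the {recipient} the {theme}"
                if rng.random() < acc[tp]:
                    correct, code, production = 1, None, target
                else:
                    correct = 0
                    code = codes[int(rng.choice(len(codes), p=weights))]
                    production = apply_error_transform(
                        target, code, rng, params.noun_lexicon
                    )
                records.append(
                    ProductionRecord(
                        participant_id=pid, group=group, timepoint=tp,
                        trial_id=f"{pid}-{tp}-{k + 1:02d}", target=target,
                        production_raw=production, correct=correct,
                        error_code=code,
                    )
                )
    return Cohort(
        records=records,
        participants=pd.DataFrame(truth_rows),
        params=params,
        seed=seed,
    )


__all__ = [
    "DEFAULT_VERB_LEXICON",
    "DEFAULT_NOUN_LEXICON",
    "DEFAULT_ERROR_MIXTURE",
    "CohortParams",
    "Cohort",
    "inflect",
    "apply_error_transform",
    "generate_cohort",
]
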