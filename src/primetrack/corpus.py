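"""Trial records, transcript cleaning, label tallies, and clinical-score tables.

The unit of analysis is one sentence-production trial: a participant (either a
person with aphasia, PWA, or an age- and education-matched control, AEM) was
shown a verb and three nouns and asked to produce a sentence; the expected
target is a double-object (DO) dative ("The nurse serves the clown the
burger").  Trials are recorded at three time points around a structural
priming training: a pre-test and two post-tests (one day and one week after
training).  Trained annotators labelled each production as correct or not and,
when incorrect, assigned one code from a six-way error taxonomy.
"""

from __future__ import annotations

import csv
import importlib.resources
import math
import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

GROUPS = ("PWA", "AEM")
TIMEPOINTS = ("pre", "post1", "post2")

#: Error taxonomy for incorrect productions.  NT_po: grammatical non-target
#: prepositional-object dative; NT_other: any other grammatical non-target
#: structure; GE: grammatical/argument-structure error; NS: non-sentential
#: response (e.g. a noun string with no verb); LE: lexical substitution error;
#: OTHER: multiple error types or unclassifiable.  Codes are mutually
#: exclusive; OTHER absorbs multi-error responses.
ERROR_CODES = ("NT_po", "NT_other", "GE", "NS", "LE", "OTHER")

TRIALS_COLUMNS = (
    "participant_id",
    "group",
    "timepoint",
    "trial_id",
    "target",
    "production",
    "correct",
    "error_code",
)

#: Canonical column names for the clinical-score table (percent-scaled columns
#: end in ``_pct``; WAB-R AQ is on a 0-100 scale).
CLINICAL_COLUMNS = (
    "wab_aq",
    "wab_fluency",
    "wab_ac",
    "wab_naming",
    "wab_repetition",
    "palpa_swp_pct",
    "navs_vct",
    "navs_vnt",
    "navs_aspt",
    "navs_sppt",
    "navs_sct",
    "cat_written_words_pct",
    "pcb_total_pct",
)

_PERCENT_COLUMNS = frozenset(
    c for c in CLINICAL_COLUMNS if c.endswith("_pct") or c in ("wab_aq",)
)

#: Published per-group correct/incorrect pair counts and per-code error counts
#: for the clinical study this package's analyses were designed around.  The
#: per-code PWA counts as published sum to 969 against 976 incorrect pairs;
#: the 7 remaining records are carried as NT_other, consistent with the
#: published remainder of 231 incorrect PWA pairs once NT_po is excluded.
REPORTED_PAIR_COUNTS: Mapping[str, Mapping[str, int]] = {
    "PWA": {"correct": 555, "incorrect": 976},
    "AEM": {"correct": 574, "incorrect": 564},
}
REPORTED_ERROR_COUNTS: Mapping[str, Mapping[str, int]] = {
    "PWA": {"NT_po": 745, "GE": 152, "OTHER": 28, "LE": 25, "NS": 19, "NT_other": 7},
    "AEM": {"NT_po": 561, "LE": 1, "NT_other": 1, "OTHER": 1},
}


class SchemaError(ValueError):
    """A required column is missing from an input file."""


class ValidationError(ValueError):
    """A field value falls outside its closed vocabulary."""


@dataclass
class ProductionRecord:
    """One target/production trial with optional human labels."""

    participant_id: str
    group: str
    timepoint: str
    trial_id: str
    target: str
    production_raw: str
    production_clean: str = ""
    correct: int | None = None
    error_code: str | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}")
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(f"unknown timepoint {self.timepoint!r}")
        if self.correct not in (None, 0, 1):
            raise ValidationError(f"correct must be 0/1/absent, got {self.correct!r}")
        if self.error_code is not None:
            if self.error_code not in ERROR_CODES:
                raise ValidationError(f"unknown error_code {self.error_code!r}")
            if self.correct != 0:
                raise ValidationError("error_code is only valid when correct = 0")
        if not self.production_clean:
            self.production_clean = clean_production(self.production_raw)


@dataclass(frozen=True)
class LabelTally:
    group: str
    n_pairs: int
    n_correct: int
    n_incorrect: int
    per_error_code: Mapping[str, int]
    n_unlabeled: int = 0
    #: incorrect count after removing excluded codes; None when no exclusion.
    n_incorrect_after_exclusion: int | None = None


@dataclass(frozen=True)
class ColumnSummary:
    mean: float
    sd: float | None  # None: undefined (fewer than 2 rows)
    n: int

    @property
    def mean_rounded(self) -> float:
        return _round_half_up(self.mean, 1)

    @property
    def sd_rounded(self) -> float | None:
        return None if self.sd is None else _round_half_up(self.sd, 1)


def _round_half_up(x: float, ndigits: int) -> float:
    """Round half away from zero, matching printed clinical summaries."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# --- transcript cleaning -----------------------------------------------------

_BRACKETS_RE = re.compile(r"[()\[\]{}]")
_ELLIPSIS_RE = re.compile(r"…|\.{3,}")
_PP_TOKEN_RE = re.compile(r"(?<!\S)pp(?!\S)")
_WS_RE = re.compile(r"\s+")
_PARENTHETICAL_RE = re.compile(r"\([^()]*\)")


def clean_production(raw: str, drop_parenthetical_content: bool = False) -> str:
    """Strip transcription annotation symbols from a verbatim production.

    Removes the documented symbol inventory: parenthesis and bracket
    characters, ellipsis marks ("..." and the one-character ellipsis), and the
    standalone paraphasia annotation token "pp".  Whitespace is collapsed and
    trimmed; lexical content is otherwise preserved.  With
    ``drop_parenthetical_content`` the words inside parentheses are dropped
    along with the symbols (by default only the symbols go).

    Idempotent: cleaning a cleaned string is a no-op.  An empty result is
    legal; downstream scoring skips and logs it.
    """
    text = raw
    for _ in range(10):  # iterate to a fixed point so removal never re-exposes symbols
        prev = text
        if drop_parenthetical_content:
            text = _PARENTHETICAL_RE.sub(" ", text)
        text = _BRACKETS_RE.sub(" ", text)
        text = _ELLIPSIS_RE.sub(" ", text)
        text = _PP_TOKEN_RE.sub(" ", text)
        text = _WS_RE.sub(" ", text).strip()
        if text == prev:
            break
    return text


# --- trials file I/O ---------------------------------------------------------

def _normalize_group(value: str, row: int) -> str:
    v = value.strip().upper()
    if v not in GROUPS:
        raise ValidationError(f"row {row}: unknown group {value!r}")
    return v


def _normalize_timepoint(value: str, row: int) -> str:
    v = value.strip().lower().replace("-", "").replace("_", "").replace(" ", "")
    aliases = {
        "pre": "pre", "pretest": "pre",
        "post1": "post1", "posttest1": "post1",
        "post2": "post2", "posttest2": "post2",
    }
    if v not in aliases:
        raise ValidationError(f"row {row}: unknown timepoint {value!r}")
    return aliases[v]


def _normalize_error_code(value: str, row: int) -> str:
    by_lower = {c.lower(): c for c in ERROR_CODES}
    v = value.strip().lower()
    if v not in by_lower:
        raise ValidationError(f"row {row}: unknown error_code {value!r}")
    return by_lower[v]


def read_trials(path: str | Path, delimiter: str = ",") -> list[ProductionRecord]:
    """Read a delimited trials file into validated :class:`ProductionRecord`s.

    The header must contain every column of ``TRIALS_COLUMNS``; empty strings
    in ``correct``/``error_code`` denote absent labels (never coerced to 0).
    Group/timepoint/error-code values are normalized case-insensitively to
    their canonical forms.
    """
    path = Path(path)
    records: list[ProductionRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        missing = [c for c in TRIALS_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"{path.name}: missing required column(s) {missing}")
        for i, row in enumerate(reader, start=2):  # 1-based, after header
            correct_raw = (row["correct"] or "").strip()
            if correct_raw == "":
                correct: int | None = None
            elif correct_raw in ("0", "1"):
                correct = int(correct_raw)
            else:
                raise ValidationError(f"row {i}: correct must be '', '0' or '1'")
            code_raw = (row["error_code"] or "").strip()
            code = _normalize_error_code(code_raw, i) if code_raw else None
            try:
                records.append(
                    ProductionRecord(
                        participant_id=row["participant_id"].strip(),
                        group=_normalize_group(row["group"], i),
                        timepoint=_normalize_timepoint(row["timepoint"], i),
                        trial_id=row["trial_id"].strip(),
                        target=row["target"],
                        production_raw=row["production"],
                        correct=correct,
                        error_code=code,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"row {i}: {exc}") from None
    return records


def write_trials(records: Iterable[ProductionRecord], path: str | Path) -> None:
    """Write records in the standard trials-file schema (lossless round-trip)."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(TRIALS_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.participant_id,
                    r.group,
                    r.timepoint,
                    r.trial_id,
                    r.target,
                    r.production_raw,
                    "" if r.correct is None else str(r.correct),
                    r.error_code or "",
                ]
            )


def records_to_frame(records: Sequence[ProductionRecord]) -> pd.DataFrame:
    """Tabular view of records (one row per trial, absent labels as NA)."""
    return pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in records],
            "group": [r.group for r in records],
            "timepoint": [r.timepoint for r in records],
            "trial_id": [r.trial_id for r in records],
            "target": [r.target for r in records],
            "production": [r.production_raw for r in records],
            "production_clean": [r.production_clean for r in records],
            "correct": pd.array([r.correct for r in records], dtype="Int64"),
            "error_code": [r.error_code for r in records],
        }
    )


# --- label tallies -----------------------------------------------------------

def tally_labels(
    records: Sequence[ProductionRecord],
    exclude_codes: frozenset[str] | set[str] = frozenset(),
) -> dict[str, LabelTally]:
    """Per-group (plus ``ALL``) counts of correct/incorrect pairs and codes.

    With a nonempty ``exclude_codes`` the tally additionally reports the
    incorrect count after removing records whose code is excluded — e.g.
    excluding NT_po isolates genuinely errorful productions from grammatical
    prepositional-dative responses.
    """
    for c in exclude_codes:
        if c not in ERROR_CODES:
            raise ValidationError(f"unknown error_code in exclude set: {c!r}")
    out: dict[str, LabelTally] = {}
    for grp in (*GROUPS, "ALL"):
        subset = [r for r in records if grp == "ALL" or r.group == grp]
        n_correct = sum(1 for r in subset if r.correct == 1)
        n_incorrect = sum(1 for r in subset if r.correct == 0)
        n_unlabeled = sum(1 for r in subset if r.correct is None)
        per_code = {
            c: sum(1 for r in subset if r.error_code == c) for c in ERROR_CODES
        }
        after = None
        if exclude_codes:
            after = sum(
                1
                for r in subset
                if r.correct == 0 and r.error_code not in exclude_codes
            )
        out[grp] = LabelTally(
            group=grp,
            n_pairs=len(subset),
            n_correct=n_correct,
            n_incorrect=n_incorrect,
            per_error_code=per_code,
            n_unlabeled=n_unlabeled,
            n_incorrect_after_exclusion=after,
        )
    return out


def expand_reported_tallies() -> list[ProductionRecord]:
    """Materialize the published per-group label counts as placeholder records.

    Productions and targets are schematic; only the label structure (group,
    correct/incorrect, error code) matters, so tally arithmetic on the real
    study's printed counts can be recomputed rather than restated.
    """
    target = "The man gives the woman the cake"
    records: list[ProductionRecord] = []
    serial = 0
    for grp in GROUPS:
        for _ in range(REPORTED_PAIR_COUNTS[grp]["correct"]):
            serial += 1
            records.append(
                ProductionRecord(
                    participant_id=f"{grp}-pooled", group=grp, timepoint="pre",
                    trial_id=f"t{serial}", target=target, production_raw=target,
                    correct=1,
                )
            )
        counts = REPORTED_ERROR_COUNTS[grp]
        assert sum(counts.values()) == REPORTED_PAIR_COUNTS[grp]["incorrect"]
        for code, n in counts.items():
            for _ in range(n):
                serial += 1
                records.append(
                    ProductionRecord(
                        participant_id=f"{grp}-pooled", group=grp, timepoint="pre",
                        trial_id=f"t{serial}", target=target,
                        production_raw="the man gives the cake to the woman",
                        correct=0, error_code=code,
                    )
                )
    return records


# --- clinical-score tables ---------------------------------------------------

def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical-score table with the canonical column spelling."""
    df = pd.read_csv(path)
    missing = [c for c in ("participant_id", *CLINICAL_COLUMNS) if c not in df.columns]
    if missing:
        raise SchemaError(f"clinical table missing column(s) {missing}")
    for col in _PERCENT_COLUMNS:
        bad = df[(df[col] < 0) | (df[col] > 100)]
        if not bad.empty:
            raise ValidationError(f"{col}: values outside [0, 100]")
    return df


def load_reference_clinical() -> pd.DataFrame:
    """Bundled language-testing scores for the 24-participant PWA cohort."""
    ref = importlib.resources.files("primetrack.data") / "pwa_clinical_scores.csv"
    with importlib.resources.as_file(ref) as path:
        return read_clinical(path)


def summarize_clinical_columns(
    table: pd.DataFrame, columns: Sequence[str] = CLINICAL_COLUMNS
) -> dict[str, ColumnSummary]:
    """Mean and n−1 standard deviation per clinical column.

    Single-row tables get a defined mean and an undefined (None) sd; an empty
    table is an error.
    """
    if len(table) == 0:
        raise ValidationError("empty clinical table")
    out: dict[str, ColumnSummary] = {}
    for col in columns:
        values = pd.to_numeric(table[col], errors="raise").astype(float)
        mean = float(values.mean())
        sd = float(values.std(ddof=1)) if len(values) >= 2 else None
        if sd is not None and math.isnan(sd):
            sd = None
        out[col] = ColumnSummary(mean=mean, sd=sd, n=len(values))
    return out


__all__ = [
    "GROUPS",
    "TIMEPOINTS",
    "ERROR_CODES",
    "TRIALS_COLUMNS",
    "CLINICAL_COLUMNS",
    "REPORTED_PAIR_COUNTS",
    "REPORTED_ERROR_COUNTS",
    "SchemaError",
    "ValidationError",
    "ProductionRecord",
    "LabelTally",
    "ColumnSummary",
    "clean_production",
    "read_trials",
    "write_trials",
    "records_to_frame",
    "tally_labels",
    "expand_reported_tallies",
    "read_clinical",
    "load_reference_clinical",
    "summarize_clinical_columns",
]
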