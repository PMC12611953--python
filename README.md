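# primetrack

Tracking priming-induced language recovery in aphasia with conditional
surprisal from autoregressive language models.

## The problem

Structural priming — the unconscious tendency to reuse recently encountered
syntactic structures — is used as a treatment to improve sentence production
in people with aphasia (PWA). A typical protocol trains double-object (DO)
dative productions ("The nurse serves the clown the burger") over several
sessions and measures production at a pre-test and two post-tests against
age- and education-matched controls (AEM). Binary correctness scores miss
graded change; `primetrack` quantifies recovery with a continuous measure:
the **conditional surprisal** of a participant's production `P = w_1..w_n`
given the expected target sentence `C` under an autoregressive language
model,

```
Surp(P | C) = - Σ_{i=1..n} log P(w_i | C, w_1, ..., w_{i-1})
```

Higher surprisal means the production is less predictable given the target —
more diverged from the expected output. Both the raw sum and the per-token
mean (`Surp / n`) are carried on every score.

On top of the scorer, the package provides:

- **corpus** — trial-record I/O, transcript cleaning (annotation symbols,
  ellipses, paraphasia markers), label tallies with code exclusion, and
  clinical-score summaries (a reference PWA language-testing table is
  bundled).
- **lm_backend** — pluggable autoregressive backends: a uniform toy backend,
  an add-one-smoothed bigram backend, a recorded-reply stub, and optional
  adapters for locally cached pretrained models (`primetrack.external`,
  requires the `external` extra).
- **trajectory** — Wilcoxon signed-rank time-point comparisons with
  Bonferroni correction, per-participant slopes, the inverse-preference
  regression (pre-test surprisal predicting the training-induced drop),
  AEM−PWA contrasts per time point, and change-score correlations of
  surprisal reduction with accuracy gain.
- **error_analysis** — the six-way error taxonomy (NT_po, NT_other, GE, NS,
  LE, OTHER), one-hot encodings, Spearman associations between surprisal and
  error codes, error-production time contrasts, and a bag-of-words
  cosine-similarity control.
- **prompt_eval** — a few-shot prompt harness ("one trial per run", six
  exemplars, one query pair), reply parsing, a deterministic rule-based DO
  judge usable as an offline classifier or mock for live-model adapters, and
  F1/accuracy evaluation per group and overall.
- **synthetic_data** — a cohort simulator with latent severity, an
  inverse-preference coupling, maintenance of gains, and structural error
  transforms, so every analysis is testable with known ground truth.

## Worked example

```bash
primetrack simulate --seed 0 --out trials.csv
primetrack score --backend bigram --trials trials.csv --out scored.csv
primetrack analyze --scored scored.csv --seed 0 --out report.json
```

This simulates a 24-PWA / 16-AEM cohort (15 trials per session at pre-test
and two post-tests), scores each production against its target under a
bigram backend fitted to the cohort's correct target sentences, and writes a
JSON report. At seed 0 the report contains, among other blocks:

- Wilcoxon (Bonferroni-adjusted) for PWA: pre→post1 p = 0.0001, pre→post2
  p = 0.0033, post1→post2 p = 0.48 — surprisal drops with training and the
  gains are maintained.
- Inverse-preference regression (PWA, pre→post1): β = 1.14, SE = 0.23,
  p = 4.9e-05, adjusted R² = 0.51 — participants starting with higher
  surprisal improve more.
- Change-score correlations (PWA): r = 0.81 (pre→post1) — surprisal
  reduction tracks clinician-scored accuracy gain.
- Mean target/production cosine by error code: NT_po 0.964 > GE 0.957 >
  LE 0.923 > NS 0.480 — grammatical PO re-framings stay semantically close
  to their DO targets, noun strings do not.

The few-shot evaluation harness and the clinical summary run the same way:

```bash
primetrack prompt-eval --trials trials.csv --out eval.json
primetrack summarize-clinical
```

`summarize-clinical` prints the bundled reference table's columns, e.g.
`wab_aq  79.2  9.2  24` (mean, n−1 SD, n).

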