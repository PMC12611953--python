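# Methods

## Conditional surprisal

The central statistic is the conditional surprisal of a cleaned participant
production `P = w_1..w_n` given the expected target sentence `C` under an
autoregressive model:

    Surp(P | C) = - Σ_i ln P(w_i | C, w_1..w_{i-1})

Natural logarithms are used throughout (the scale is nats). Only production
tokens are scored; the target conditions the chain. Two reductions are
always carried: the raw sum, and the per-token mean `Surp / n`, which
removes the length confound and is the default for group-level analyses
(longer productions would otherwise accumulate surprisal mechanically).
Individual-trajectory work can opt into the raw sum; every scored table
carries both columns plus the token count and backend name, and scores are
never re-normalized across a session.

Context–continuation joining is a convention, not a fact of the world:
a begin-of-sequence marker precedes the target, the production follows,
and only production tokens contribute. Absolute surprisal values therefore
depend on the backend's tokenizer and this joining rule, which is why the
package only ever compares surprisals *within* a backend, and why the
optional pretrained-model check in `primetrack.external` is tolerance-based.

## Backends

Two toy backends make everything testable offline:

- **uniform(V)** — every token scores −ln V regardless of context. Used as
  an exact oracle (the per-token mean must equal ln V).
- **bigram** — add-one (Laplace) smoothing over a training corpus:
  `P(w|v) = (c(v,w)+1) / (c(v)+V)`, with a begin-of-sentence symbol
  prefixed to each training sentence and an unknown symbol included in the
  vocabulary of size V; out-of-vocabulary tokens map to unknown. Each
  conditional distribution sums to one by construction, which the tests
  check exhaustively.

Toy tokenization is lowercase whitespace splitting with edge punctuation
stripped. External adapters (HuggingFace causal LMs, sentence-transformer
embedders) own their tokenization, are loaded lazily, and are exercised in
the default build only through a recorded-reply stub that proves the scoring
layer is backend-agnostic.

The default pipeline fits the bigram backend to the distinct *correct target
sentences* of the input corpus: the expected DO productions define the
probability model, so correct productions are maximally in-distribution and
divergence from the target raises surprisal. The error-mechanism analyses
additionally use a backend fitted to DO *and* PO realizations to show why
grammatical PO re-framings score low despite being "incorrect".

## Trajectory statistics

The exchangeable unit is the participant, so paired tests and contrasts run
on participant-session means:

- **Time-point comparisons** — Wilcoxon signed-rank on participant means for
  the three session pairs, Bonferroni-corrected with the family size fixed
  at 3 (`p_adj = min(1, 3p)`). All-zero difference vectors are reported as a
  degenerate case with p = 1 and a flag rather than raised as errors.
- **Per-participant slopes** — OLS of per-trial surprisal on session coded
  0/1; with a binary predictor this equals the mean difference, which is the
  closed-form oracle the tests use.
- **Inverse-preference regression** — the surprisal *drop* over a window
  (mean at the earlier session minus the later one; positive = improvement)
  regressed on the pre-test mean, separately per group and window (six
  regressions). A positive slope is the inverse-preference signature:
  participants who start with less target-like production improve more.
  The pre-test mean appears in both predictor and response, so the estimate
  contains a regression-to-the-mean component. This is left in deliberately
  — it is how slope-difference analyses of this design behave — and is
  quantified rather than corrected: the null simulation in the tests (and
  the acceptance script) draws predictor and response independently and
  confirms the nominal 5% rejection rate of the test itself.
- **Group contrasts** — AEM − PWA difference of group means of participant
  means at each time point, with a Welch-style large-sample normal SE. With
  balanced data this equals the least-squares adjusted-mean contrast of a
  group × time linear model; exact small-sample df approximations are out of
  contract.
- **Change-score correlations** — Pearson r across participants between the
  surprisal reduction and the accuracy gain for pre→post1 and post1→post2.
  Constant change vectors leave r undefined and are reported as such.

## Error taxonomy and similarity control

Incorrect productions carry exactly one of six codes: NT_po (grammatical
prepositional-dative re-framing), NT_other (other grammatical non-target),
GE (argument-structure violation), NS (non-sentential noun string), LE
(lexical substitution), OTHER (multi-error/unclassifiable). OTHER absorbs
multi-error responses; there is no multi-label mode. Surprisal–code
associations are Spearman rank correlations against one-hot encodings;
constant columns are flagged undefined, never coerced to zero. Raw p-values
are the default (a Holm option exists) because six simultaneous rank tests
are reported descriptively, not as a confirmatory family.

The similarity control embeds target and production as L2-normalized
bag-of-words count vectors and takes the cosine. This deliberately measures
*content overlap only*: it shows that PO re-framings share nearly all
content with their DO targets (cosine ≈ 0.96) while noun strings do not
(≈ 0.48), which is the mechanism behind NT_po's low conditional surprisal.
A dense sentence-embedding adapter can be substituted where available.

## The synthetic cohort generator

The generator emulates the statistical structure the analyses assume, with
known ground truth; it is the package's test bed, not a model of speech.

Defaults (the study conditions):

| parameter | default | rationale |
|---|---|---|
| roster | 24 PWA, 16 AEM | clinical-study group sizes |
| trials/session | 15 | production-test length |
| sessions | pre, post1 (one day), post2 (one week) | design |
| PWA severity | Uniform(0.15, 0.95), latent scalar | moderate-to-mild range; not an aphasia-type taxonomy |
| AEM severity | Uniform(0.0, 0.1) | controls near ceiling |
| baseline accuracy | 0.45 (PWA), 0.42 (AEM), minus 0.4·severity | yields pre-test DO rates ≈ 0.23 / 0.40 |
| gain pre→post1 | 0.0 + 0.4·severity (PWA); 0.135 + 0.4·severity (AEM) | see calibration below |
| gain post1→post2 | 0 | maintenance of training gains |
| error mixture | proportional to published per-code counts; AEM ≈ 99.5% NT_po | class imbalance of real annotation tallies |

Pooled correctness lands near 36% (PWA) and 50% (AEM), the published class
imbalance. The severity→gain coupling of 0.4 was calibrated so that the
PWA pre→post1 inverse-preference regression has adjusted R² ≈ 0.53, the
published effect size for that analysis; with the severity penalty of 0.4
the population slope of drop on pre-test mean is coupling/penalty = 1.

Targets are built from a frame grammar ("The ⟨agent⟩ ⟨verb⟩s the
⟨recipient⟩ the ⟨theme⟩") over 15 one-syllable dative verbs and 30 nouns.
Correct trials copy the target; incorrect trials realize their code as a
structural transform: PO re-framing (NT_po), a templated non-dative
paraphrase (NT_other), argument swap / spurious preposition / argument drop
in a 0.6/0.2/0.2 seeded mixture (GE), a comma-joined noun string (NS), one
seeded distractor-noun substitution (LE), or a composed substitution +
re-framing (OTHER). Generation is a pure function of (params, seed).

What the generator does **not** emulate: disfluency phonetics, real
paraphasia strings, synonym acceptance in correctness scoring, annotator
noise, or aphasia subtypes. Productions come from the same frame grammar
the rule-based judge parses, so the judge's perfect binary accuracy on
synthetic cohorts demonstrates pipeline correctness, not clinical
performance; on real transcripts every component downstream of
`clean_production` would face inputs outside the frame grammar.

## Few-shot evaluation harness

Prompts follow a one-trial-per-run protocol: one instruction (the binary DO
judgment, extended with the six category definitions in error-type mode),
six exemplars (exactly three positive and three negative for correctness),
and a single query pair. Group membership is never disclosed in prompts.
Reply parsing takes the first standalone 0/1 token (correctness) or the
earliest canonical code string (error type); anything else is an invalid
marker that always scores as wrong — dropping invalid replies would inflate
F1 under class imbalance. The positive class for binary F1 is "correct = 1",
and macro-F1 is co-reported; error-type mode reports matching accuracy and
per-class F1. The deterministic rule judge (frame parser + content-overlap
threshold 0.9) stands in for live models offline and doubles as the mock
proving the prompt→reply→parse→score loop is total.

## Numerical choices and problem sizes

- Clinical summaries round half away from zero to one decimal, matching the
  printed precision of clinical score tables; full precision is retained
  alongside.
- Surprisal identities (sum = −Σ log p, mean = sum/n) are asserted to 1e−10
  against a brute-force chain-rule enumerator on random fixtures.
- Wilcoxon p-values come from scipy's exact/approximate machinery; contrast
  p-values use the large-sample normal approximation.
- Simulation sizes: parameter recovery uses 100 cohorts at the study roster;
  the null calibration uses 1,000 direct regression replicates (n = 24);
  qualitative-pattern checks (maintenance, contrast signs, cosine ordering)
  run on 4×-roster or 200-PWA cohorts because at n = 24/16 the AEM Wilcoxon
  legs have only ~68% power per window under the calibrated effect sizes —
  the larger rosters test the pattern rather than sampling luck, while all
  rates and effects stay at the study conditions.
- Degenerate inputs (empty productions, constant columns, missing sessions,
  all-zero difference vectors) are skipped-and-logged or flagged, never
  silently dropped; the analysis report carries the counts.

## Known limitations

- Toy backends capture order statistics only at bigram range; long-range
  syntactic dependencies need the external pretrained adapters.
- The two-stage contrast is exactly mixed-model-equivalent only for
  balanced designs; badly unbalanced real data would warrant REML fits.
- The inverse-preference estimate is not causally identified; the built-in
  regression-to-the-mean coupling is documented and quantified, not removed.
- Absolute surprisal values are backend-specific; cross-backend comparisons
  are meaningless and deliberately unsupported.
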