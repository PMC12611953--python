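"""Error-taxonomy encodings, rank associations, similarity control."""

import math

import numpy as np
import pandas as pd
import pytest

from primetrack.corpus import ERROR_CODES, ValidationError
from primetrack.error_analysis import (
    BagOfWordsEmbedder,
    error_spearman,
    error_time_contrasts,
    one_hot_errors,
    semantic_similarity,
    similarity_by_error_code,
)
from primetrack.lm_backend import BigramBackend
from primetrack.surprisal import conditional_surprisal


def make_scored(rows):
    """rows: (trial, group, timepoint, surprisal, correct, code)."""
    return pd.DataFrame(
        rows,
        columns=["trial_id", "group", "timepoint", "surprisal_mean", "correct",
                 "error_code"],
    )


class TestOneHotErrors:
    def test_single_code_encodes_exactly_one_indicator(self):
        df = make_scored([("t1", "PWA", "pre", 3.0, 0, "GE")])
        enc = one_hot_errors(df)
        assert enc.loc[0, "GE"] == 1
        assert enc.loc[0].sum() == 1

    def test_correct_record_encodes_all_zero(self):
        enc = one_hot_errors(make_scored([("t1", "PWA", "pre", 2.0, 1, None)]))
        assert enc.loc[0].sum() == 0

    def test_column_sums_match_hand_tally(self):
        codes = ["GE", "GE", "NS", None, None, "LE", "NT_po", None, "GE", "OTHER"]
        rows = [
            (f"t{i}", "PWA", "pre", 2.0 + i, 0 if c else 1, c)
            for i, c in enumerate(codes)
        ]
        sums = one_hot_errors(make_scored(rows)).sum()
        assert sums["GE"] == 3 and sums["NS"] == 1 and sums["LE"] == 1
        assert sums["NT_po"] == 1 and sums["OTHER"] == 1 and sums["NT_other"] == 0

    def test_incorrect_without_code_is_validation_error(self):
        with pytest.raises(ValidationError):
            one_hot_errors(make_scored([("t1", "PWA", "pre", 2.0, 0, None)]))


def manual_spearman(x, y):
    """Rank both vectors by hand (average ranks for ties), Pearson on ranks."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den


class TestErrorSpearman:
    def test_separated_code_reaches_binary_maximum(self):
        # every GE surprisal above every non-GE: rho equals the rank
        # correlation of a perfectly separated binary column
        rows = [(f"g{i}", "PWA", "pre", 9.0 + i, 0, "GE") for i in range(5)]
        rows += [(f"c{i}", "PWA", "pre", 1.0 + i, 1, None) for i in range(5)]
        df = make_scored(rows)
        res = error_spearman(df)["GE"]
        assert res.defined
        assert res.rho == pytest.approx(
            manual_spearman(df["surprisal_mean"], (df["error_code"] == "GE").astype(int))
        )
        assert res.rho > 0.8

    def test_constant_column_flagged_undefined_not_zero(self):
        rows = [(f"t{i}", "PWA", "pre", float(i), 1, None) for i in range(5)]
        res = error_spearman(make_scored(rows))
        assert all(not r.defined and r.rho is None for r in res.values())

    def test_constant_surprisal_flagged(self):
        rows = [("t0", "PWA", "pre", 2.0, 0, "GE"),
                ("t1", "PWA", "pre", 2.0, 1, None),
                ("t2", "PWA", "pre", 2.0, 1, None)]
        assert not error_spearman(make_scored(rows))["GE"].defined

    def test_matches_manual_rank_computation_on_twenty_records(self, rng):
        surp = rng.normal(3, 1, 20)
        codes = [
            "GE" if i % 4 == 0 else ("NS" if i % 7 == 0 else None) for i in range(20)
        ]
        rows = [
            (f"t{i}", "PWA", "pre", float(surp[i]), 0 if codes[i] else 1, codes[i])
            for i in range(20)
        ]
        df = make_scored(rows)
        res = error_spearman(df)
        for code in ("GE", "NS"):
            expected = manual_spearman(surp, [1 if c == code else 0 for c in codes])
            assert res[code].rho == pytest.approx(expected, abs=1e-12)

    def test_label_shuffle_centres_rho_on_zero(self, scored_default):
        pwa = scored_default[scored_default["group"] == "PWA"]
        rng = np.random.default_rng(7)
        rhos = []
        for _ in range(30):
            shuffled = pwa.copy()
            perm = rng.permutation(len(pwa))
            shuffled["error_code"] = pwa["error_code"].to_numpy()[perm]
            shuffled["correct"] = pwa["correct"].to_numpy()[perm]
            res = error_spearman(shuffled)["NT_po"]
            rhos.append(res.rho)
        assert abs(np.mean(rhos)) < 0.02

    def test_holm_adjustment_is_monotone(self, scored_default):
        pwa = scored_default[scored_default["group"] == "PWA"]
        raw = error_spearman(pwa, holm=False)
        adj = error_spearman(pwa, holm=True)
        for code in ERROR_CODES:
            if raw[code].defined:
                assert adj[code].p_value >= raw[code].p_value - 1e-15


class TestErrorTimeContrasts:
    def test_identical_distributions_give_zero_estimates(self):
        rows = []
        for tp in ("pre", "post1", "post2"):
            rows += [(f"{tp}{i}", "PWA", tp, 3.0, 0, "GE") for i in range(4)]
        for c in error_time_contrasts(make_scored(rows), "PWA"):
            assert c.estimate == pytest.approx(0.0)

    def test_drop_then_flat_pattern(self):
        # error surprisal falls pre -> post and stays flat post1 -> post2
        rng = np.random.default_rng(3)
        rows = []
        for tp, mu in (("pre", 4.0), ("post1", 3.0), ("post2", 3.0)):
            rows += [
                (f"{tp}{i}", "PWA", tp, float(rng.normal(mu, 0.1)), 0, "GE")
                for i in range(30)
            ]
        contrasts = {c.pair: c for c in error_time_contrasts(make_scored(rows), "PWA")}
        assert contrasts[("pre", "post1")].estimate > 0.5
        assert contrasts[("pre", "post2")].estimate > 0.5
        assert abs(contrasts[("post1", "post2")].estimate) < 0.2

    def test_restricted_to_genuine_error_codes(self):
        rows = [(f"a{i}", "PWA", "pre", 5.0, 0, "NT_po") for i in range(5)]
        rows += [(f"b{i}", "PWA", "post1", 1.0, 0, "NT_po") for i in range(5)]
        assert error_time_contrasts(make_scored(rows), "PWA") == []

    def test_group_with_too_few_error_sessions_is_skipped(self, scored_default):
        # AEM errors are nearly all NT_po; GE/NS/LE rarely span two sessions
        rows = [("t0", "AEM", "pre", 3.0, 0, "GE"), ("t1", "AEM", "pre", 3.1, 0, "GE")]
        assert error_time_contrasts(make_scored(rows), "AEM") == []

    def test_label_swap_equivariance(self, scored_default):
        swapped = scored_default.copy()
        swapped["group"] = swapped["group"].map({"PWA": "AEM", "AEM": "PWA"})
        original = error_time_contrasts(scored_default, "PWA")
        relabeled = error_time_contrasts(swapped, "AEM")
        assert [c.estimate for c in original] == [c.estimate for c in relabeled]


class TestSemanticSimilarity:
    def test_identical_sentences_give_one(self):
        res = semantic_similarity("the king gives the queen the rose",
                                  "the king gives the queen the rose")
        assert res.cosine == pytest.approx(1.0)

    def test_disjoint_vocabulary_gives_zero(self):
        res = semantic_similarity("a b c", "x y z")
        assert res.cosine == pytest.approx(0.0)

    def test_hand_computed_bag_of_words_cosine(self):
        # target counts {the:3, nurse, serves, clown, burger}, production adds
        # "to": dot = 9+1+1+1+1 = 13, norms sqrt(13) and sqrt(14)
        res = semantic_similarity(
            "the nurse serves the clown the burger",
            "the nurse serves the burger to the clown",
        )
        assert res.cosine == pytest.approx(13 / math.sqrt(13 * 14), abs=1e-12)

    def test_empty_production_flagged_undefined(self):
        res = semantic_similarity("a b", "   ")
        assert not res.defined and res.cosine is None

    def test_cosine_ordering_over_error_taxonomy(self):
        """PO re-framings stay closest to their DO targets, then argument
        errors, then lexical substitutions, then bare noun strings."""
        from primetrack.synthetic_data import CohortParams, generate_cohort
        from primetrack.corpus import records_to_frame

        cohort = generate_cohort(CohortParams(n_pwa=200, n_aem=8), seed=0)
        df = records_to_frame(cohort.records)
        _, means = similarity_by_error_code(df)
        assert means["NT_po"] > means["GE"] > means["LE"] > means["NS"]


class TestNtPoMechanism:
    def test_po_reframings_score_below_argument_errors(self):
        """Under a bigram backend trained on both DO and PO realizations,
        grammatical PO responses are in-distribution and score lower than
        argument-structure or non-sentential errors for matched targets."""
        do = "the nurse serves the clown the burger"
        corpus = [do, "the nurse serves the burger to the clown",
                  "the king gives the queen the rose",
                  "the king gives the rose to the queen"]
        backend = BigramBackend(corpus)

        def mean_surp(production):
            return conditional_surprisal(backend, do, production).surprisal_mean

        nt_po = mean_surp("the nurse serves the burger to the clown")
        ge = mean_surp("the nurse serves with the clown the burger")
        ns = mean_surp("nurse, clown, burger")
        assert nt_po < ge
        assert nt_po < ns
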