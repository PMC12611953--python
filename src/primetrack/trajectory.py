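"""Treatment-trajectory statistics over scored trial tables.

All operations consume the scored-trials table produced by
``surprisal.score_corpus`` (one row per trial with ``surprisal_mean`` /
``surprisal_sum`` columns).  The analysis unit for paired tests and contrasts
is the participant-session mean, which keeps participants — not trials — as
the exchangeable unit.

The inverse preference effect is operationalized as: the surprisal *drop*
over a window (mean at the earlier session minus mean at the later one,
positive = improvement) regressed on the pre-test mean.  A positive slope
means participants who started with less target-like productions improved
more.  Because the pre-test mean appears in both predictor and response, the
estimate carries a built-in regression-to-the-mean component; this is
deliberate (it mirrors the clinical analysis being modelled), documented, and
quantified by the null simulation in the test suite rather than "corrected".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .corpus import GROUPS, TIMEPOINTS

logger = logging.getLogger(__name__)

#: The three pairwise session comparisons; Bonferroni family size is fixed at 3.
TIMEPOINT_PAIRS = (("pre", "post1"), ("pre", "post2"), ("post1", "post2"))


@dataclass(frozen=True)
class RegressionSummary:
    coefficient: float
    std_error: float
    p_value: float
    adj_r2: float
    n: int
    intercept: float = float("nan")
    label: str = ""


@dataclass(frozen=True)
class PairComparison:
    pair: tuple[str, str]
    statistic: float
    p_raw: float
    p_adjusted: float
    n: int
    degenerate: bool = False


@dataclass(frozen=True)
class ContrastResult:
    """Group contrast at one time point; sign convention is AEM minus PWA."""

    timepoint: str
    estimate: float
    std_error: float
    p_value: float
    n_aem: int
    n_pwa: int


def participant_session_means(
    scored: pd.DataFrame, value: str = "surprisal_mean"
) -> pd.DataFrame:
    """Per participant-session trajectory points.

    Returns one row per (participant, timepoint) with the arithmetic mean of
    the per-trial scores, the trial count, and the session accuracy (mean of
    the binary correctness labels, NaN when unlabeled).
    """
    grouped = scored.groupby(["participant_id", "group", "timepoint"], sort=False)
    out = grouped.agg(
        mean_surprisal=(value, "mean"),
        n_trials=(value, "size"),
        accuracy=("correct", "mean"),
    ).reset_index()
    return out


def _paired_session_means(
    points: pd.DataFrame, a: str, b: str
) -> tuple[np.ndarray, np.ndarray]:
    wide = points.pivot_table(
        index="participant_id", columns="timepoint", values="mean_surprisal"
    )
    wide = wide.dropna(subset=[a, b]) if {a, b} <= set(wide.columns) else wide.iloc[0:0]
    if len(wide) == 0:
        return np.array([]), np.array([])
    return wide[a].to_numpy(), wide[b].to_numpy()


def timepoint_comparisons(
    scored: pd.DataFrame, group: str, value: str = "surprisal_mean"
) -> list[PairComparison]:
    """Wilcoxon signed-rank tests across the three session pairs, one group.

    Participant-session means are the paired samples.  Raw p-values are
    Bonferroni-adjusted for the family of three comparisons
    (p_adj = min(1, 3p)).  All-zero differences are a degenerate case reported
    with p = 1 and a flag rather than an error.
    """
    points = participant_session_means(scored[scored["group"] == group], value)
    results = []
    for a, b in TIMEPOINT_PAIRS:
        xs, ys = _paired_session_means(points, a, b)
        if len(xs) < 2:
            raise ValueError(
                f"fewer than 2 participants paired across {a}/{b} for {group}"
            )
        diffs = xs - ys
        if np.allclose(diffs, 0.0):
            results.append(
                PairComparison((a, b), 0.0, 1.0, 1.0, len(xs), degenerate=True)
            )
            continue
        res = stats.wilcoxon(xs, ys)
        results.append(
            PairComparison(
                (a, b),
                float(res.statistic),
                float(res.pvalue),
                min(1.0, 3.0 * float(res.pvalue)),
                len(xs),
            )
        )
    return results


def participant_slopes(
    scored: pd.DataFrame,
    pair: tuple[str, str] = ("pre", "post1"),
    value: str = "surprisal_mean",
) -> dict[str, float]:
    """OLS slope of per-trial surprisal on session coded A=0, B=1, per participant.

    With a binary predictor the least-squares slope equals mean(B) - mean(A);
    the fit is still done on the trial-level data.  Participants missing
    either session are excluded with a log entry.
    """
    a, b = pair
    slopes: dict[str, float] = {}
    for pid, sub in scored.groupby("participant_id", sort=False):
        ya = sub.loc[sub["timepoint"] == a, value].to_numpy(dtype=float)
        yb = sub.loc[sub["timepoint"] == b, value].to_numpy(dtype=float)
        if len(ya) == 0 or len(yb) == 0:
            logger.info("participant_slopes: %s missing a session in %s", pid, pair)
            continue
        x = np.concatenate([np.zeros(len(ya)), np.ones(len(yb))])
        y = np.concatenate([ya, yb])
        xc = x - x.mean()
        slopes[pid] = float(np.dot(xc, y - y.mean()) / np.dot(xc, xc))
    return slopes


def surprisal_drops(
    scored: pd.DataFrame,
    pair: tuple[str, str] = ("pre", "post1"),
    value: str = "surprisal_mean",
) -> dict[str, float]:
    """Per-participant surprisal drop mean(A) - mean(B); positive = improvement."""
    return {pid: -s for pid, s in participant_slopes(scored, pair, value).items()}


def inverse_preference_regression(
    pretest_mean: dict[str, float], drop: dict[str, float], label: str = ""
) -> RegressionSummary:
    """Simple linear regression of the surprisal drop on the pre-test mean.

    A positive, significant coefficient is the inverse preference signature:
    higher initial surprisal (more impaired production) predicts a larger
    training-induced drop.
    """
    ids = sorted(set(pretest_mean) & set(drop))
    if len(ids) < 3:
        raise ValueError("need at least 3 participants with both quantities")
    x = np.array([pretest_mean[i] for i in ids])
    y = np.array([drop[i] for i in ids])
    if np.ptp(x) == 0:
        raise ValueError("zero variance in the pre-test predictor")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionSummary(
        coefficient=float(model.params[1]),
        std_error=float(model.bse[1]),
        p_value=float(model.pvalues[1]),
        adj_r2=float(model.rsquared_adj),
        n=len(ids),
        intercept=float(model.params[0]),
        label=label,
    )


def inverse_preference_by_group(
    scored: pd.DataFrame, value: str = "surprisal_mean"
) -> list[RegressionSummary]:
    """The six regressions (two groups x three windows), pre-test as predictor."""
    out = []
    for group in GROUPS:
        sub = scored[scored["group"] == group]
        points = participant_session_means(sub, value)
        pre = dict(
            points[points["timepoint"] == "pre"][
                ["participant_id", "mean_surprisal"]
            ].itertuples(index=False, name=None)
        )
        for pair in TIMEPOINT_PAIRS:
            drops = surprisal_drops(sub, pair, value)
            out.append(
                inverse_preference_regression(
                    pre, drops, label=f"{group}:{pair[0]}-{pair[1]}"
                )
            )
    return out


def two_stage_contrast(
    means_a: np.ndarray, means_b: np.ndarray
) -> tuple[float, float, float]:
    """Difference of means of participant-level means, A minus B.

    Large-sample normal approximation for the p-value (Welch-style standard
    error); with balanced data this equals the least-squares adjusted-mean
    contrast from a group x time linear model.
    """
    est = float(np.mean(means_a) - np.mean(means_b))
    se = float(
        math.sqrt(
            np.var(means_a, ddof=1) / len(means_a)
            + np.var(means_b, ddof=1) / len(means_b)
        )
    )
    if se == 0.0:
        p = 1.0 if est == 0.0 else 0.0
    else:
        p = float(2.0 * stats.norm.sf(abs(est) / se))
    return est, se, p


def group_timepoint_contrasts(
    scored: pd.DataFrame, value: str = "surprisal_mean"
) -> list[ContrastResult]:
    """AEM - PWA contrast of adjusted mean surprisal at each time point.

    Negative estimates indicate higher surprisal (less target-like
    production) in the PWA group.  A time point missing a group is omitted
    with a warning.
    """
    points = participant_session_means(scored, value)
    results = []
    for tp in TIMEPOINTS:
        at_tp = points[points["timepoint"] == tp]
        aem = at_tp[at_tp["group"] == "AEM"]["mean_surprisal"].to_numpy()
        pwa = at_tp[at_tp["group"] == "PWA"]["mean_surprisal"].to_numpy()
        if len(aem) < 2 or len(pwa) < 2:
            logger.warning("contrast at %s omitted: a group is absent/singleton", tp)
            continue
        est, se, p = two_stage_contrast(aem, pwa)
        results.append(ContrastResult(tp, est, se, p, len(aem), len(pwa)))
    return results


def change_score_correlation(
    scored: pd.DataFrame,
    group: str | None = "PWA",
    value: str = "surprisal_mean",
) -> dict[str, dict[str, float]]:
    """Pearson correlation of surprisal reduction with accuracy gain.

    Per participant and change window (pre->post1, post1->post2), the
    reduction is mean surprisal at the earlier session minus the later one and
    the gain is accuracy at the later session minus the earlier one; the
    correlation is computed across participants.  Positive r links surprisal
    reduction to clinician-scored improvement.
    """
    sub = scored if group is None else scored[scored["group"] == group]
    points = participant_session_means(sub, value)
    out: dict[str, dict[str, float]] = {}
    for earlier, later in (("pre", "post1"), ("post1", "post2")):
        surp = points.pivot_table(
            index="participant_id", columns="timepoint", values="mean_surprisal"
        )
        acc = points.pivot_table(
            index="participant_id", columns="timepoint", values="accuracy"
        )
        both = surp[[earlier, later]].dropna().join(
            acc[[earlier, later]].dropna(), lsuffix="_surp", rsuffix="_acc",
            how="inner",
        )
        if len(both) < 3:
            raise ValueError("need at least 3 participants per change window")
        reduction = both[f"{earlier}_surp"] - both[f"{later}_surp"]
        gain = both[f"{later}_acc"] - both[f"{earlier}_acc"]
        if np.ptp(reduction) == 0 or np.ptp(gain) == 0:
            # a constant change vector leaves r undefined; report, don't guess
            out[f"{earlier}->{later}"] = {
                "r": float("nan"), "p": float("nan"), "n": len(both)
            }
            continue
        r, p = stats.pearsonr(reduction, gain)
        out[f"{earlier}->{later}"] = {"r": float(r), "p": float(p), "n": len(both)}
    return out


__all__ = [
    "TIMEPOINT_PAIRS",
    "RegressionSummary",
    "PairComparison",
    "ContrastResult",
    "participant_session_means",
    "timepoint_comparisons",
    "participant_slopes",
    "surprisal_drops",
    "inverse_preference_regression",
    "inverse_preference_by_group",
    "two_stage_contrast",
    "group_timepoint_contrasts",
    "change_score_correlation",
]
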