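"""Strategy evaluation: mixed models, best-cue selection and
top-decile counting.

The experiment compares strategies in three stages.  First, each
similarity measure is modelled against the model label with a linear
mixed model carrying a random intercept per animal (repeated measures).
Second, within each strategy the cue variant with the most favourable
adjusted estimate is retained, so every strategy contributes an equal
number of simulations.  Third, the retained simulations are pooled,
ranked by a similarity measure, and the best 10% tallied by strategy —
the resulting proportions (against a 1/5 = 20% equal-share baseline)
are the evidence for which navigational strategy best reproduces the
observed tracks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .strategies import STRATEGIES

log = logging.getLogger(__name__)

#: measures where smaller = more similar
ASCENDING = {"mean_distance": True, "dtw": True, "di": False}


@dataclass(frozen=True)
class LmmFit:
    """Per-label adjusted estimates of one similarity measure.

    ``estimates``/``std_errors`` map model label -> fixed-effect cell
    mean (and SE); ``random_intercept_sd`` is the fitted between-animal
    SD; ``fallback`` flags a singular fit resolved by cell means with
    animal-clustered standard errors.
    """

    measure: str
    estimates: dict = field(default_factory=dict)
    std_errors: dict = field(default_factory=dict)
    random_intercept_sd: float = 0.0
    n_obs: int = 0
    fallback: bool = False


@dataclass(frozen=True)
class StrategyCounts:
    """Tally of strategies among the retained top fraction."""

    measure: str
    counts: dict
    proportions: dict
    n_retained: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_retained:
            raise ValueError("counts do not sum to the retained total")
        if abs(sum(self.proportions.values()) - 1.0) > 1e-9:
            raise ValueError("proportions do not sum to 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "strategy": list(self.counts),
                "count": list(self.counts.values()),
                "proportion": [self.proportions[s] for s in self.counts],
            }
        )


def fit_strategy_lmm(scores: pd.DataFrame, measure: str) -> LmmFit:
    """Mixed model measure ~ 0 + label with a per-animal random
    intercept, fitted by REML.

    Cell-means coding makes each fixed-effect coefficient directly the
    adjusted mean of one model label.  Singular/non-converged fits fall
    back to per-label means with animal-clustered standard errors
    (``fallback=True``).
    """
    if measure not in scores.columns:
        raise ValueError(f"measure {measure!r} not in scores table")
    df = scores[["animal_id", "label", measure]].rename(columns={measure: "y"})
    labels = sorted(df["label"].unique())
    n_animals = df["animal_id"].nunique()
    if n_animals >= 2 and df["y"].var() > 0:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm("y ~ 0 + C(label)", df,
                                    groups=df["animal_id"])
                fit = model.fit(reml=True)
            if np.all(np.isfinite(fit.bse.iloc[: len(labels)])):
                est = {
                    lab: float(fit.params[f"C(label)[{lab}]"]) for lab in labels
                }
                se = {
                    lab: float(fit.bse[f"C(label)[{lab}]"]) for lab in labels
                }
                return LmmFit(
                    measure=measure,
                    estimates=est,
                    std_errors=se,
                    random_intercept_sd=float(
                        np.sqrt(max(fit.cov_re.iloc[0, 0], 0.0))
                    ),
                    n_obs=len(df),
                )
        except (np.linalg.LinAlgError, ValueError) as exc:
            log.warning("mixed model failed (%s); falling back to cell means",
                        exc)
    # fallback: OLS cell means, animal-clustered SEs where possible
    X = pd.get_dummies(df["label"], dtype=float)[labels]
    ols = sm.OLS(df["y"], X)
    if n_animals >= 2:
        res = ols.fit(cov_type="cluster",
                      cov_kwds={"groups": df["animal_id"]})
    else:
        res = ols.fit()
    return LmmFit(
        measure=measure,
        estimates={lab: float(res.params[lab]) for lab in labels},
        std_errors={lab: float(res.bse[lab]) for lab in labels},
        random_intercept_sd=0.0,
        n_obs=len(df),
        fallback=True,
    )


def lmm_to_frame(fit: LmmFit) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "label": list(fit.estimates),
            "estimate": list(fit.estimates.values()),
            "std_error": [fit.std_errors[k] for k in fit.estimates],
            "measure": fit.measure,
            "fallback": fit.fallback,
        }
    )


def select_best_variant(fits: dict, strategy_of: dict,
                        reference_measure: str = "mean_distance") -> dict:
    """Per strategy, the label whose adjusted estimate on the reference
    measure is most favourable (lowest for mean_distance/dtw, highest
    for di).  Exact ties go to the lexicographically smallest label
    (logged).  The no-bias control maps to itself.
    """
    if reference_measure not in fits:
        raise ValueError(f"no fit supplied for {reference_measure!r}")
    fit = fits[reference_measure]
    ascending = ASCENDING[reference_measure]
    best: dict[str, str] = {}
    by_strategy: dict[str, list[str]] = {}
    for label in fit.estimates:
        by_strategy.setdefault(strategy_of[label], []).append(label)
    for strategy, labels in by_strategy.items():
        vals = {lab: fit.estimates[lab] for lab in labels}
        opt = min(vals.values()) if ascending else max(vals.values())
        winners = sorted(lab for lab, v in vals.items() if v == opt)
        if len(winners) > 1:
            log.info("tie among %s; keeping %s", winners, winners[0])
        best[strategy] = winners[0]
    return best


def top_decile_counts(scores: pd.DataFrame, measure: str,
                      fraction: float = 0.10,
                      strategy_col: str = "strategy") -> StrategyCounts:
    """Rank the pooled (one-variant-per-strategy) table by ``measure``
    and tally strategies among the best ``fraction``.

    Requires equal replicate counts per strategy (the pooling step
    equalises them by construction).  Ranking is a stable sort on
    (score, animal_id, replicate) for determinism; the retained count
    is floor(fraction * N).
    """
    if measure not in scores.columns:
        raise ValueError(f"measure {measure!r} not in scores table")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    per = scores[strategy_col].value_counts()
    if per.nunique() != 1:
        raise ValueError(
            "unequal per-strategy counts "
            f"({per.to_dict()}); pool exactly one variant per strategy"
        )
    ascending = ASCENDING[measure]
    tie_cols = [c for c in ("animal_id", "replicate") if c in scores.columns]
    ranked = scores.sort_values(
        [measure, *tie_cols],
        ascending=[ascending] + [True] * len(tie_cols),
        kind="stable",
    )
    n_keep = int(np.floor(fraction * len(ranked)))
    top = ranked.head(n_keep)
    strategies = [s for s in STRATEGIES if s in set(scores[strategy_col])]
    strategies += sorted(set(scores[strategy_col]) - set(strategies))
    counts = {s: int((top[strategy_col] == s).sum()) for s in strategies}
    props = {s: counts[s] / n_keep for s in strategies}
    return StrategyCounts(measure=measure, counts=counts,
                          proportions=props, n_retained=n_keep)


def evaluate_scores(scores: pd.DataFrame, strategy_of: dict,
                    reference_measure: str = "mean_distance",
                    fraction: float = 0.10):
    """Full evaluation: per-measure LMM fits, best-variant selection,
    pooling, and top-fraction counts per measure.

    Returns (fits, best, pooled, counts) where counts maps measure ->
    :class:`StrategyCounts` computed on the pooled one-variant-per-
    strategy table.
    """
    measures = [m for m in ASCENDING if m in scores.columns]
    fits = {m: fit_strategy_lmm(scores, m) for m in measures}
    best = select_best_variant(fits, strategy_of, reference_measure)
    pooled = scores[scores["label"].isin(best.values())].copy()
    if "strategy" not in pooled.columns:
        pooled["strategy"] = pooled["label"].map(strategy_of)
    counts = {m: top_decile_counts(pooled, m, fraction) for m in measures}
    return fits, best, pooled, counts
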