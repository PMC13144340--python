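"""Emotion composites and framing-effect linear models for survey tables.

A light behavioral stage: average configurable item sets into affect
composites (negative/positive affect, fear, anger), then estimate framing
effects with linear models — plain OLS for between-subject tables,
participant fixed effects (equivalent to demeaning) for within-subject
tables — with the neutral frame as the reference level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from framesync.simulate import ANGER_ITEMS, FEAR_ITEMS, NEG_ITEMS, POS_ITEMS

DEFAULT_ITEM_SETS: dict[str, list[str]] = {
    "negative_affect": list(NEG_ITEMS),
    "positive_affect": list(POS_ITEMS),
    "fear": list(FEAR_ITEMS),
    "anger": list(ANGER_ITEMS),
}


@dataclass
class ModelResult:
    """Tidy fit summary: one row per term with estimate, SE, p and 95% CI."""

    outcome: str
    params: pd.DataFrame
    n: int
    formula: str

    def coef(self, term: str) -> pd.Series:
        hits = self.params[self.params["term"] == term]
        if hits.empty:
            raise KeyError(f"term {term!r} not in model: {list(self.params['term'])}")
        return hits.iloc[0]


def composite_scores(
    table: pd.DataFrame, item_sets: Mapping[str, Sequence[str]] | None = None
) -> pd.DataFrame:
    """Append composite columns (means of their item sets) to a survey table.

    The item -> composite mapping is configuration, not code: pass your own
    ``item_sets`` to change which items feed fear and anger.
    """
    item_sets = dict(item_sets) if item_sets is not None else DEFAULT_ITEM_SETS
    out = table.copy()
    for name, items in item_sets.items():
        missing = [i for i in items if i not in table.columns]
        if missing:
            raise ValueError(f"composite {name!r} missing items: {missing}")
        out[name] = table[list(items)].mean(axis=1)
    return out


def _frame_term(frame_col: str = "frame") -> str:
    return f"C({frame_col}, Treatment('neutral'))"


def _tidy(fit, outcome: str, formula: str) -> ModelResult:
    ci = fit.conf_int()
    params = pd.DataFrame(
        dict(
            term=[_clean_term(t) for t in fit.params.index],
            estimate=fit.params.to_numpy(),
            se=fit.bse.to_numpy(),
            p=fit.pvalues.to_numpy(),
            ci_low=ci[0].to_numpy(),
            ci_high=ci[1].to_numpy(),
        )
    )
    return ModelResult(outcome=outcome, params=params, n=int(fit.nobs), formula=formula)


def _clean_term(term: str) -> str:
    """Compact patsy term names: frame dummies become frame[threat] etc."""
    return (
        term.replace("C(frame, Treatment('neutral'))", "frame")
        .replace("C(participant_id)", "participant")
        .replace("T.", "")
    )


def fit_framing_model(
    table: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str] = (),
    within_subject: bool = False,
) -> ModelResult:
    """OLS of an outcome on frame dummies (neutral reference) + covariates.

    ``within_subject=True`` adds participant fixed effects, the
    dummy-variable form of participant demeaning, absorbing the random
    participant level with the correct residual degrees of freedom.
    Rows with missing values in the used columns are dropped.
    """
    needed = [outcome, "frame", *covariates] + (
        ["participant_id"] if within_subject else []
    )
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise ValueError(f"table missing columns: {missing}")
    df = table[needed].dropna()
    if df["frame"].nunique() < 2:
        raise ValueError("frame has fewer than 2 levels after dropping missing rows")
    terms = [_frame_term()]
    terms += list(covariates)
    if within_subject:
        terms.append("C(participant_id)")
    formula = f"{outcome} ~ " + " + ".join(terms)
    fit = smf.ols(formula, data=df).fit()
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise ValueError("design matrix is collinear")
    result = _tidy(fit, outcome, formula)
    if within_subject:
        result.params = result.params[
            ~result.params["term"].str.startswith("participant[")
        ].reset_index(drop=True)
    return result


def interaction_model(
    table: pd.DataFrame,
    outcome: str,
    factors: Sequence[str],
    covariates: Sequence[str] = (),
    terms: Sequence[str] | None = None,
) -> ModelResult:
    """Hierarchical interaction model, e.g. importance x frame x affect.

    ``factors`` are crossed fully (patsy ``*``), so every lower-order margin
    of the highest interaction is included automatically. If an explicit
    ``terms`` list is given instead, it must contain all marginal terms of
    any interaction it requests; a bare three-way term without its margins
    is refused.
    """
    if terms is not None:
        import itertools

        term_set = {tuple(sorted(t.split(":"))) for t in terms}
        for t in terms:
            parts = t.split(":")
            for k in range(1, len(parts)):
                for sub in itertools.combinations(parts, k):
                    if tuple(sorted(sub)) not in term_set:
                        raise ValueError(
                            f"interaction {t!r} requires marginal term {':'.join(sub)!r}"
                        )
        rhs = " + ".join(terms)
    else:
        if len(factors) < 2:
            raise ValueError("need at least two factors to interact")
        rhs = " * ".join(factors)
    if covariates:
        rhs += " + " + " + ".join(covariates)
    formula = f"{outcome} ~ {rhs}"
    df = table.dropna(subset=[c for c in table.columns if c in formula])
    fit = smf.ols(formula, data=df).fit()
    return _tidy(fit, outcome, formula)
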