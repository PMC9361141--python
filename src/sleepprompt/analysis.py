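"""Longitudinal and pre-post analysis of trial outcomes.

The primary analysis is a linear mixed-effects model on weekly ISI
totals over the five time points (baseline and weeks 1-4): a random
intercept per participant and fixed effects for time, arm, and the
time x arm interaction, fitted by REML with Wald tests.  Missing weeks
are simply absent rows — no imputation.  Time is coded as continuous
weeks 0-4 by default; a categorical-time variant is available for
sensitivity analysis.  Secondary outcomes are compared as pre-post
change scores with the independent-samples t test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .trial import ARMS, TrialOpsError, two_sample_t_change

__all__ = [
    "TrialRecord",
    "ModelFit",
    "records_to_frame",
    "fit_longitudinal_model",
    "weekly_means",
    "change_score_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrialRecord:
    """One participant-week ISI observation with its arm label."""

    participant_id: str
    arm: str
    week: int
    isi: int

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise TrialOpsError(f"unknown arm {self.arm!r}")
        if not 0 <= self.week <= 4:
            raise TrialOpsError(f"week must be 0..4, got {self.week}")
        if not 0 <= self.isi <= 28:
            raise TrialOpsError(f"ISI must be 0..28, got {self.isi}")


@dataclass(frozen=True)
class ModelFit:
    """Fixed effects and variance components of the fitted mixed model."""

    params: Mapping[str, float]
    bse: Mapping[str, float]
    pvalues: Mapping[str, float]
    var_participant: float
    var_residual: float
    n_obs: int
    n_participants: int
    time_coding: str

    @property
    def interaction(self) -> float:
        """The week x arm trend contrast (the primary effect estimate)."""
        return self.params["week:arm"]

    @property
    def interaction_p(self) -> float:
        return self.pvalues["week:arm"]


def records_to_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {"participant_id": r.participant_id, "arm": r.arm, "week": r.week, "isi": r.isi}
            for r in records
        ]
    )
    if df.duplicated(["participant_id", "week"]).any():
        raise TrialOpsError("at most one record per participant-week")
    return df


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        need = {"participant_id", "arm", "week", "isi"}
        if not need.issubset(df.columns):
            raise TrialOpsError(f"records frame must have columns {sorted(need)}")
        return df
    return records_to_frame(records)


def fit_longitudinal_model(records, *, time_coding: str = "linear") -> ModelFit:
    """Fit the random-intercept model ISI ~ week * arm, grouped by participant.

    ``time_coding="linear"`` treats week as a continuous 0-4 trend (the
    primary specification; the interaction is the between-arm difference
    in weekly slope).  ``"categorical"`` fits separate week effects as a
    sensitivity check; its reported interaction is the week-4 contrast.
    Estimated by REML; p-values are two-sided Wald tests.
    """
    df = _as_frame(records)
    for arm in ARMS:
        sub = df[df["arm"] == arm]
        if sub["participant_id"].nunique() < 2 or sub["week"].nunique() < 2:
            raise TrialOpsError(f"arm {arm!r} needs >=2 participants and >=2 time points")
    df = df.assign(arm_i=(df["arm"] == "SPA").astype(float), week=df["week"].astype(float))
    if time_coding == "linear":
        formula = "isi ~ week * arm_i"
        inter_key = "week:arm_i"
    elif time_coding == "categorical":
        formula = "isi ~ C(week) * arm_i"
        inter_key = "C(week)[T.4.0]:arm_i"
    else:
        raise TrialOpsError(f"unknown time_coding {time_coding!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM.from_formula(formula, groups="participant_id", data=df)
        fit = model.fit(reml=True)
    rename = lambda k: k.replace("arm_i", "arm").replace("week", "week")
    params = {rename(k): float(v) for k, v in fit.fe_params.items()}
    bse = {rename(k): float(fit.bse[k]) for k in fit.fe_params.index}
    pvalues = {rename(k): float(fit.pvalues[k]) for k in fit.fe_params.index}
    # expose the primary contrast under the canonical name
    canon = rename(inter_key)
    params["week:arm"] = params.get("week:arm", params[canon])
    bse["week:arm"] = bse.get("week:arm", bse[canon])
    pvalues["week:arm"] = pvalues.get("week:arm", pvalues[canon])
    return ModelFit(
        params=params,
        bse=bse,
        pvalues=pvalues,
        var_participant=float(np.asarray(fit.cov_re)[0, 0]),
        var_residual=float(fit.scale),
        n_obs=len(df),
        n_participants=df["participant_id"].nunique(),
        time_coding=time_coding,
    )


def weekly_means(records) -> pd.DataFrame:
    """Per-arm mean ISI by week (full precision; round at presentation)."""
    df = _as_frame(records)
    out = (
        df.groupby(["arm", "week"], sort=True)["isi"]
        .agg(mean="mean", n="count")
        .reset_index()
    )
    return out


def change_score_table(
    scores: pd.DataFrame,
    *,
    measures: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Pre-post summary per measure and arm, plus the between-arm test.

    ``scores`` is tidy: participant_id, arm, measure, baseline, posttest.
    Participants missing either assessment for a measure are dropped from
    that measure (logged).  Output rows carry per-arm baseline/posttest/
    change means and SDs; the intervention-arm rows carry the between-arm
    mean difference in change with its 95% CI and p value.
    """
    need = {"participant_id", "arm", "measure", "baseline", "posttest"}
    if not need.issubset(scores.columns):
        raise TrialOpsError(f"scores frame must have columns {sorted(need)}")
    rows = []
    for measure in measures or sorted(scores["measure"].unique()):
        sub = scores[scores["measure"] == measure]
        unpaired = sub["baseline"].isna() | sub["posttest"].isna()
        if unpaired.any():
            logger.info(
                "measure %s: excluding %d unpaired participant(s)", measure, unpaired.sum()
            )
            sub = sub[~unpaired]
        changes = {}
        for arm in ARMS:
            s = sub[sub["arm"] == arm]
            change = (s["posttest"] - s["baseline"]).to_numpy()
            changes[arm] = change
            rows.append(
                {
                    "measure": measure,
                    "arm": arm,
                    "n": len(s),
                    "baseline_mean": s["baseline"].mean(),
                    "baseline_sd": s["baseline"].std(ddof=1),
                    "posttest_mean": s["posttest"].mean(),
                    "posttest_sd": s["posttest"].std(ddof=1),
                    "change_mean": change.mean() if len(s) else np.nan,
                    "change_sd": change.std(ddof=1) if len(s) > 1 else np.nan,
                }
            )
        if all(len(changes[a]) >= 2 for a in ARMS):
            t = two_sample_t_change(changes[ARMS[0]], changes[ARMS[1]])
            rows[-2].update(
                {
                    "diff_change": t.mean_difference,
                    "ci_low": t.ci_low,
                    "ci_high": t.ci_high,
                    "p_value": t.p_value,
                }
            )
    return pd.DataFrame(rows)
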