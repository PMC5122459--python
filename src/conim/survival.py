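"""Kaplan-Meier quartile comparison of CNA burden.

Patients of each cancer type are split into quartiles of the stratifier (CNA
number or mean CNA length) after removing hypermutator and aneuploid samples;
the bottom and top quartiles are compared with the log-rank test (chi-square
distributed with 1 df).  Ties at a quartile cut point are assigned to the
lower group.  A literal chi-square on end-of-follow-up event counts is
available behind ``test="chi2_events"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .stats import chi2_2x2

__all__ = ["km_estimate", "SurvivalResult", "quartile_compare", "QuartileSurvival"]


def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit survival curve with right censoring.

    Returns a table (time, survival, at_risk) at the observed event/censor
    times.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty input")
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    surv = kmf.survival_function_["KM_estimate"]
    at_risk = kmf.event_table["at_risk"].reindex(surv.index)
    return pd.DataFrame({"time": surv.index.to_numpy(float),
                         "survival": surv.to_numpy(float),
                         "at_risk": at_risk.to_numpy(float)})


@dataclass
class SurvivalResult:
    cancer_type: str
    stratifier: str
    n_bottom: int
    n_top: int
    curve_bottom: pd.DataFrame
    curve_top: pd.DataFrame
    statistic: float
    p: float
    direction: str  # "bottom_better" / "top_better"

    def summary(self) -> str:
        return (
            f"Quartile survival comparison ({self.cancer_type}, {self.stratifier})\n"
            f"  bottom quartile: n = {self.n_bottom}; top quartile: n = {self.n_top}\n"
            f"  log-rank chi2 = {self.statistic:.3f}, p = {self.p:.4g}\n"
            f"  better survival in: {self.direction.replace('_better', '')} quartile"
        )


def quartile_compare(burdens: pd.DataFrame, clinical: pd.DataFrame,
                     stratifier: str = "cna_number", cancer_type: str | None = None,
                     test: str = "logrank") -> SurvivalResult:
    """Bottom vs top burden-quartile survival within one cancer type.

    ``burdens`` must carry hypermutator/aneuploid flags (exclusions are
    applied before the quartile cuts); ``clinical`` supplies time/event.
    """
    col = {"cna_number": "n_cna", "mean_cna_length": "mean_cna_length"}[stratifier]
    df = burdens.merge(clinical[["sample", "time", "event"]], on="sample")
    if cancer_type is not None:
        df = df[df["cancer_type"] == cancer_type]
    else:
        types = df["cancer_type"].unique()
        if len(types) != 1:
            raise ValueError("specify cancer_type for a multi-type table")
        cancer_type = types[0]
    df = df[~(df["hypermutator_flag"] | df["aneuploid_flag"])]
    df = df.dropna(subset=[col, "time"])
    if len(df) < 8:
        raise ValueError(f"only {len(df)} eligible samples; quartiles meaningless")

    vals = df[col].to_numpy(float)
    q1, q3 = np.quantile(vals, [0.25, 0.75])
    bottom = df[vals <= q1]
    top = df[df[col] > q3]
    if len(bottom) == 0 or len(top) == 0:
        raise ValueError("empty quartile group")

    if test == "logrank":
        res = logrank_test(bottom["time"], top["time"],
                           event_observed_A=bottom["event"],
                           event_observed_B=top["event"])
        stat, p = float(res.test_statistic), float(res.p_value)
    elif test == "chi2_events":
        table = [[int(bottom["event"].sum()), int((1 - bottom["event"]).sum())],
                 [int(top["event"].sum()), int((1 - top["event"]).sum())]]
        stat, p = chi2_2x2(table)
    else:
        raise ValueError(f"unknown test {test!r}")

    mean_b = float(km_estimate(bottom["time"], bottom["event"])["survival"].mean())
    mean_t = float(km_estimate(top["time"], top["event"])["survival"].mean())
    return SurvivalResult(
        cancer_type=cancer_type, stratifier=stratifier,
        n_bottom=len(bottom), n_top=len(top),
        curve_bottom=km_estimate(bottom["time"], bottom["event"]),
        curve_top=km_estimate(top["time"], top["event"]),
        statistic=stat, p=p,
        direction="bottom_better" if mean_b > mean_t else "top_better")


class QuartileSurvival:
    """Model facade: bind burdens + clinical, ``fit()`` per cancer type."""

    def __init__(self, burdens: pd.DataFrame, clinical: pd.DataFrame):
        self.burdens = burdens
        self.clinical = clinical

    def fit(self, stratifier: str = "cna_number",
            cancer_type: str | None = None, test: str = "logrank") -> SurvivalResult:
        return quartile_compare(self.burdens, self.clinical, stratifier,
                                cancer_type, test)

    def fit_all(self, stratifier: str = "cna_number") -> list[SurvivalResult]:
        out = []
        for ct in sorted(self.clinical["cancer_type"].unique()):
            try:
                out.append(self.fit(stratifier, cancer_type=ct))
            except ValueError:
                continue
        return out
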