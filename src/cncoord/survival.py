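"""Survival analysis of CN-specific frequencies.

Single-covariate Cox proportional-hazards models on log(pseudocount +
frequency), Kaplan-Meier curves at the optimal covariate split (log-rank p
minimized over admissible cutpoints — reported uncorrected for the split
selection, so optimistic by construction), and a proportional-hazards
diagnostic from scaled Schoenfeld residuals against (rank) time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, proportional_hazard_test

log = logging.getLogger(__name__)


@dataclass
class CoxResult:
    covariate: str
    log_hr: float
    se: float
    p_lrt: float          # likelihood-ratio-test p
    p_wald: float
    n: int
    n_events: int
    ph_p: float | None    # Schoenfeld diagnostic, filled by ph_diagnostic
    fitter: CoxPHFitter
    data: pd.DataFrame    # the modeling frame (time, event, covariate)


@dataclass
class SplitResult:
    split_value: float
    logrank_p: float
    km_low: pd.DataFrame     # timeline + survival estimate, low-covariate arm
    km_high: pd.DataFrame
    n_low: int
    n_high: int


def cox_cn_frequency(clinical: pd.DataFrame, frequency: pd.Series,
                     pseudocount: float = 1e-3,
                     covariate_name: str = "log_freq") -> CoxResult:
    """Cox PH fit of survival on log(pseudocount + frequency).

    ``frequency`` is indexed by patient_id; missing patients are dropped.
    Requires >= 2 observed events and a non-constant covariate.
    """
    df = clinical.set_index("patient_id")[["survival_time", "event"]].copy()
    df[covariate_name] = np.log(pseudocount + frequency.reindex(df.index))
    df = df.dropna()
    if int(df["event"].sum()) < 2:
        raise ValueError("fewer than 2 observed events")
    if df[covariate_name].std(ddof=0) == 0:
        raise ValueError(f"covariate {covariate_name!r} has no variation")
    cph = CoxPHFitter()
    cph.fit(df, duration_col="survival_time", event_col="event")
    lrt = cph.log_likelihood_ratio_test()
    return CoxResult(
        covariate=covariate_name,
        log_hr=float(cph.params_[covariate_name]),
        se=float(cph.standard_errors_[covariate_name]),
        p_lrt=float(lrt.p_value),
        p_wald=float(cph.summary.loc[covariate_name, "p"]),
        n=len(df), n_events=int(df["event"].sum()),
        ph_p=None, fitter=cph, data=df)


def km_optimal_split(clinical: pd.DataFrame, covariate: pd.Series,
                     min_group_size: int = 3) -> SplitResult:
    """Kaplan-Meier curves at the covariate split minimizing the log-rank p.

    Scans midpoints between consecutive sorted covariate values leaving at
    least ``min_group_size`` patients on each side. The selected p is not
    corrected for the scan (optimism caveat, logged).
    """
    df = clinical.set_index("patient_id")[["survival_time", "event"]].copy()
    df["cov"] = covariate.reindex(df.index)
    df = df.dropna()
    if df["event"].sum() == 0:
        raise ValueError("no observed events")
    v = np.sort(df["cov"].unique())
    cand = [(a + b) / 2 for a, b in zip(v[:-1], v[1:])]
    cand = [c for c in cand if min((df["cov"] <= c).sum(), (df["cov"] > c).sum())
            >= min_group_size]
    if not cand:
        raise ValueError("no admissible split")
    best = None
    for c in cand:
        lo, hi = df[df["cov"] <= c], df[df["cov"] > c]
        res = logrank_test(lo["survival_time"], hi["survival_time"],
                           lo["event"], hi["event"])
        if best is None or res.p_value < best[1]:
            best = (c, float(res.p_value))
    split, p = best
    log.info("optimal split %.4g (log-rank p = %.3g); p is optimistic — "
             "uncorrected for split selection", split, p)
    lo, hi = df[df["cov"] <= split], df[df["cov"] > split]

    def km(frame: pd.DataFrame) -> pd.DataFrame:
        f = KaplanMeierFitter().fit(frame["survival_time"], frame["event"])
        sf = f.survival_function_
        return sf.rename(columns={sf.columns[0]: "survival"}).reset_index(
            names="time")

    return SplitResult(float(split), p, km(lo), km(hi), len(lo), len(hi))


def ph_diagnostic(result: CoxResult, time_transform: str = "rank") -> float:
    """Proportional-hazards p from scaled Schoenfeld residuals vs time.

    Small p indicates violation of proportional hazards. Returns NaN with a
    warning when fewer than 3 events are available.
    """
    if result.n_events < 3:
        log.warning("fewer than 3 events; PH diagnostic not computed")
        return float("nan")
    res = proportional_hazard_test(result.fitter, result.data,
                                   time_transform=time_transform)
    p = float(np.atleast_1d(res.p_value)[0])
    result.ph_p = p
    return p


def km_curve(durations: pd.Series, events: pd.Series) -> pd.DataFrame:
    """Product-limit survival curve as a (time, survival) table."""
    f = KaplanMeierFitter().fit(durations, events)
    sf = f.survival_function_
    return sf.rename(columns={sf.columns[0]: "survival"}).reset_index(names="time")
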