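"""Kaplan-Meier estimation, log-rank testing, and data-driven biomarker
cut-off optimization.

The product-limit estimator and the two-group log-rank statistic are
implemented in-repo (the test suite cross-checks them against lifelines
where available). Cut-off optimization performs the exhaustive in-range
scan that minimizes the log-rank p - the standard "minimum p-value"
dichotomization - with an optional permutation correction for the
selection effect inherent in scanning (off by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .simulate import substream


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    p: float
    O1: float
    E1: float
    O2: float
    E2: float
    hazard_ratio: float
    n1: int
    n2: int
    cutoff: float


def _check_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    for col in ("time", "event"):
        if col not in cohort:
            raise ValueError(f"cohort lacks a {col!r} column")
    if (cohort["time"] <= 0).any():
        raise ValueError("follow-up times must be positive")
    if not cohort["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0/1")
    return cohort


def km_estimate(cohort: pd.DataFrame) -> pd.DataFrame:
    """Product-limit survival curve for one (sub)cohort.

    Rows at each distinct observed time with the at-risk count, event
    count, censored count, and S(t) = prod_{t_i <= t} (1 - d_i / n_i).
    Censored-only times reduce the risk set but leave S unchanged.
    """
    _check_cohort(cohort)
    times = cohort["time"].to_numpy(dtype=float)
    events = cohort["event"].to_numpy(dtype=int)
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    distinct = np.unique(times)
    n_at_risk = len(times)
    s = 1.0
    rows = []
    for t in distinct:
        here = times == t
        d = int(events[here].sum())
        c = int(here.sum()) - d
        if d > 0:
            s *= 1.0 - d / n_at_risk
        rows.append({"time": t, "at_risk": n_at_risk, "events": d,
                     "censored": c, "survival": s})
        n_at_risk -= d + c
    return pd.DataFrame(rows)


def logrank(cohort: pd.DataFrame, cutoff: float,
            marker_col: str = "marker") -> LogRankResult:
    """Two-group log-rank test splitting at ``marker > cutoff``.

    Group 1 is the high-marker group. chi2 = (O1 - E1)^2 / V with the
    expectation and hypergeometric variance accumulated over distinct
    event times; p from chi-square with 1 df. The hazard ratio is the
    ratio of O/E rates, (O1/E1)/(O2/E2).
    """
    _check_cohort(cohort)
    high = (cohort[marker_col].to_numpy() > cutoff)
    if high.all() or not high.any():
        raise ValueError("degenerate split: a group has zero members")
    return _logrank_arrays(cohort["time"].to_numpy(dtype=float),
                           cohort["event"].to_numpy(dtype=int),
                           high, cutoff)


def _logrank_arrays(times: np.ndarray, events: np.ndarray,
                    high: np.ndarray, cutoff: float) -> LogRankResult:
    order = np.argsort(times, kind="stable")
    times, events, high = times[order], events[order], high[order]
    n = len(times)
    event_times = np.unique(times[events == 1])

    # at-risk counts just before each event time (times sorted ascending)
    left = np.searchsorted(times, event_times, side="left")
    n_at = n - left
    high_cum = np.concatenate([[0], np.cumsum(high)])
    n1_at = (high.sum() - high_cum[left]).astype(float)

    # events at each event time, split by group
    d_tot = np.zeros(len(event_times))
    d1 = np.zeros(len(event_times))
    idx = np.searchsorted(event_times, times)
    ev = events == 1
    np.add.at(d_tot, idx[ev], 1)
    np.add.at(d1, idx[ev], high[ev].astype(float))

    with np.errstate(invalid="ignore", divide="ignore"):
        e1 = d_tot * n1_at / n_at
        v = np.where(
            n_at > 1,
            d_tot * (n1_at / n_at) * (1 - n1_at / n_at)
            * (n_at - d_tot) / (n_at - 1),
            0.0,
        )
    O1, E1, V = float(d1.sum()), float(e1.sum()), float(v.sum())
    O_tot = float(d_tot.sum())
    O2, E2 = O_tot - O1, O_tot - E1
    chi = (O1 - E1) ** 2 / V if V > 0 else 0.0
    p = float(chi2.sf(chi, df=1)) if V > 0 else 1.0
    if E1 > 0 and E2 > 0 and O2 > 0:
        hr = (O1 / E1) / (O2 / E2)
    else:
        hr = np.nan
    return LogRankResult(
        chi_square=float(chi), p=p, O1=O1, E1=E1, O2=O2, E2=E2,
        hazard_ratio=float(hr), n1=int(high.sum()),
        n2=int(n - high.sum()), cutoff=float(cutoff))


def optimize_cutoff(cohort: pd.DataFrame,
                    quantile_range: tuple[float, float] = (0.10, 0.90),
                    correction: str = "none", n_perm: int = 500,
                    seed: int = 0, marker_col: str = "marker") -> dict:
    """Data-driven marker dichotomization by minimum log-rank p.

    Every distinct marker value whose split keeps both group fractions
    inside ``quantile_range`` is evaluated; the cutoff minimizing p wins,
    ties breaking toward the cutoff nearest the marker median. With
    ``correction="permutation"`` the scan is re-run on marker-shuffled
    cohorts and the empirical p of the observed minimum is reported,
    quantifying the optimism of the scan itself.
    """
    _check_cohort(cohort)
    marker = cohort[marker_col].to_numpy(dtype=float)
    times = cohort["time"].to_numpy(dtype=float)
    events = cohort["event"].to_numpy(dtype=int)
    best = _scan(times, events, marker, quantile_range)
    if best is None:
        raise ValueError("no admissible split inside the quantile range")
    out = {"cutoff": best.cutoff, "result": best, "corrected_p": None}
    if correction == "permutation":
        rng = substream(seed, "cutoff-permutation")
        null_min_p = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(marker)
            r = _scan(times, events, perm, quantile_range)
            null_min_p[i] = r.p if r is not None else 1.0
        out["corrected_p"] = float(
            (1 + np.sum(null_min_p <= best.p)) / (n_perm + 1))
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")
    return out


def _scan(times: np.ndarray, events: np.ndarray, marker: np.ndarray,
          quantile_range: tuple[float, float]) -> LogRankResult | None:
    lo_q, hi_q = quantile_range
    n = len(marker)
    candidates = np.unique(marker)
    median = float(np.median(marker))
    best: LogRankResult | None = None
    for cut in candidates:
        n_high = int(np.sum(marker > cut))
        frac_high = n_high / n
        if not (1 - hi_q <= frac_high <= 1 - lo_q) or n_high in (0, n):
            continue
        res = _logrank_arrays(times, events, marker > cut, float(cut))
        if best is None or res.p < best.p or (
                res.p == best.p
                and abs(cut - median) < abs(best.cutoff - median)):
            best = res
    return best
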