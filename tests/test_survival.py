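import numpy as np
import pandas as pd
import pytest

from breakscape.simulate import SimConfig, simulate_survival_cohort
from breakscape.survival import km_estimate, logrank, optimize_cutoff


def cohort_from(times, events, marker=None):
    n = len(times)
    return pd.DataFrame({
        "time": times, "event": events,
        "marker": marker if marker is not None else np.zeros(n),
    })


# -- Kaplan-Meier -----------------------------------------------------

def test_km_no_events_survival_one():
    km = km_estimate(cohort_from([1, 2, 3], [0, 0, 0]))
    assert (km["survival"] == 1.0).all()


def test_km_single_subject():
    km = km_estimate(cohort_from([5.0], [1]))
    assert km.loc[0, "survival"] == 0.0
    assert km.loc[0, "at_risk"] == 1


def test_km_six_patient_worked_set():
    """times 1,2,3+,4,5+,6 (+ censored): hand product-limit ledger."""
    km = km_estimate(cohort_from([1, 2, 3, 4, 5, 6], [1, 1, 0, 1, 0, 1]))
    km = km.set_index("time")
    assert km.loc[1, "survival"] == pytest.approx(5 / 6)
    assert km.loc[2, "survival"] == pytest.approx(5 / 6 * 4 / 5)     # 2/3
    assert km.loc[3, "survival"] == pytest.approx(2 / 3)             # censor
    assert km.loc[4, "survival"] == pytest.approx(2 / 3 * 2 / 3)     # 4/9
    assert km.loc[5, "survival"] == pytest.approx(4 / 9)
    assert km.loc[6, "survival"] == pytest.approx(0.0)
    assert km["at_risk"].tolist() == [6, 5, 4, 3, 2, 1]


def test_km_monotone_right_continuous():
    rng = np.random.default_rng(32)
    km = km_estimate(cohort_from(rng.exponential(5, 100),
                                 rng.integers(0, 2, 100)))
    s = km["survival"].to_numpy()
    assert (np.diff(s) <= 1e-12).all()
    assert s[0] <= 1.0 and (s >= 0).all()


def test_km_matches_lifelines():
    from lifelines import KaplanMeierFitter
    rng = np.random.default_rng(33)
    t = rng.exponential(5, 200)
    e = rng.integers(0, 2, 200)
    km = km_estimate(cohort_from(t, e))
    kmf = KaplanMeierFitter().fit(t, e)
    for _, row in km.iterrows():
        assert row["survival"] == pytest.approx(
            float(kmf.survival_function_at_times(row["time"]).iloc[0]),
            abs=1e-10)


# -- log-rank ---------------------------------------------------------

def test_logrank_symmetric_cohort_chi_zero():
    # every patient duplicated into both groups: identical survival
    # experience, so O1 = E1 and the statistic vanishes
    times = [1, 2, 3, 4, 5] * 2
    events = [1, 1, 0, 1, 0] * 2
    marker = [0] * 5 + [1] * 5
    res = logrank(cohort_from(times, events, marker), cutoff=0.5)
    assert res.chi_square == pytest.approx(0.0, abs=1e-12)
    assert res.O1 + res.O2 == sum(events)


def test_logrank_eight_patient_hand_ledger():
    """O, E, V accumulated by hand over the 5 distinct event times."""
    times = [1, 3, 5, 7, 2, 4, 6, 8]
    events = [1, 1, 0, 1, 1, 0, 1, 0]
    marker = [1, 1, 1, 1, 0, 0, 0, 0]   # group 1 = marker > 0.5
    res = logrank(cohort_from(times, events, marker), cutoff=0.5)
    E1 = 0.5 + 3 / 7 + 0.5 + 1 / 3 + 0.5
    V = 0.25 + 12 / 49 + 0.25 + 2 / 9 + 0.25
    assert res.O1 == 3 and res.O2 == 2
    assert res.E1 == pytest.approx(E1, abs=1e-12)
    assert res.chi_square == pytest.approx((3 - E1) ** 2 / V, abs=1e-12)
    assert res.E1 + res.E2 == pytest.approx(5.0)
    assert res.hazard_ratio == pytest.approx((3 / E1) / (2 / (5 - E1)))


def test_logrank_matches_lifelines():
    from lifelines.statistics import logrank_test
    rng = np.random.default_rng(34)
    n = 300
    marker = rng.normal(size=n)
    t = rng.exponential(np.where(marker > 0, 2.0, 5.0))
    e = (rng.uniform(size=n) < 0.8).astype(int)
    cohort = cohort_from(t, e, marker)
    res = logrank(cohort, 0.0)
    ll = logrank_test(t[marker > 0], t[marker <= 0],
                      e[marker > 0], e[marker <= 0])
    assert res.chi_square == pytest.approx(ll.test_statistic, rel=1e-9)
    assert res.p == pytest.approx(ll.p_value, rel=1e-9)


def test_logrank_label_swap_invariance():
    rng = np.random.default_rng(35)
    n = 120
    marker = rng.normal(size=n)
    cohort = cohort_from(rng.exponential(3, n),
                         rng.integers(0, 2, n), marker)
    res = logrank(cohort, 0.0)
    flipped = cohort.copy()
    flipped["marker"] = -flipped["marker"]
    res_f = logrank(flipped, -1e-12)
    assert res.chi_square == pytest.approx(res_f.chi_square, rel=1e-9)
    assert res.hazard_ratio == pytest.approx(1 / res_f.hazard_ratio, rel=1e-9)


def test_logrank_degenerate_split_rejected():
    cohort = cohort_from([1, 2, 3], [1, 1, 1], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError, match="degenerate"):
        logrank(cohort, 10.0)


def test_hazard_ratio_recovery():
    """Simulated HR=2.5 cohort recovers the hazard ratio within 25%."""
    cfg = SimConfig(seed=11, cohort_size=800)
    cohort = simulate_survival_cohort(cfg, (1.0, 2.5))
    res = logrank(cohort, 1.0)
    assert res.hazard_ratio == pytest.approx(2.5, rel=0.25)


# -- cut-off optimization --------------------------------------------

def test_optimizer_constant_marker_degenerate():
    cohort = cohort_from([1, 2, 3, 4], [1, 1, 1, 1], [5.0] * 4)
    with pytest.raises(ValueError, match="admissible"):
        optimize_cutoff(cohort)


def test_optimizer_min_p_property():
    """The optimized p never exceeds the p at any fixed in-range cutoff."""
    cfg = SimConfig(seed=36, cohort_size=300)
    cohort = simulate_survival_cohort(cfg, (1.0, 2.0))
    opt = optimize_cutoff(cohort)
    marker = cohort["marker"]
    for q in (0.2, 0.4, 0.5, 0.6, 0.8):
        res = logrank(cohort, float(marker.quantile(q)))
        assert opt["result"].p <= res.p + 1e-15


def test_optimizer_recovers_planted_threshold():
    """Planted 60th-percentile threshold recovered within 5 percentile
    points (single-seed check; the multi-seed rate lives in acceptance)."""
    cfg = SimConfig(seed=29, cohort_size=800)
    cutoff, hr = np.exp(0.2533), 2.5    # 60th pct of lognormal(0,1)
    cohort = simulate_survival_cohort(cfg, (cutoff, hr))
    opt = optimize_cutoff(cohort)
    pct = (cohort["marker"] <= opt["cutoff"]).mean() * 100
    assert abs(pct - 60) <= 5


def test_permutation_correction_reports_selection_effect():
    """On a null cohort the uncorrected minimum p is optimistic; the
    permutation-corrected p is not small."""
    cfg = SimConfig(seed=38, cohort_size=150)
    cohort = simulate_survival_cohort(cfg, (1.0, 1.0))
    opt = optimize_cutoff(cohort, correction="permutation", n_perm=99,
                          seed=5)
    assert opt["corrected_p"] > opt["result"].p
    assert 0 < opt["corrected_p"] <= 1
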