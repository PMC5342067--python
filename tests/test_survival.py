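import math

import numpy as np
import pandas as pd
import pytest

from metdiv import survival as sv
from metdiv.exceptions import DegenerateDataError, MetdivError, ValidationError


def logrank_oracle(times, events, in_group):
    """Hand log-rank tableau: observed minus expected over event times."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    g = np.asarray(in_group, bool)
    o1 = e1 = var = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n, n1 = at_risk.sum(), (at_risk & g).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & g).sum()
        o1 += d1
        e1 += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return (o1 - e1) ** 2 / var


def test_km_hand_values():
    km = sv.km_estimate([2, 4, 6], [1, 1, 0])
    assert km.survival_at(2) == pytest.approx(2 / 3)
    assert km.survival_at(4) == pytest.approx(1 / 3)
    assert km.survival_at(5) == pytest.approx(1 / 3)


def test_km_censored_then_event():
    km = sv.km_estimate([5, 10], [0, 1])
    assert km.survival_at(9.9) == 1.0
    assert km.survival_at(10) == 0.0


def test_km_all_censored():
    km = sv.km_estimate([3, 7, 9], [0, 0, 0])
    assert km.survival_at(9) == 1.0


def test_km_no_censoring_equals_empirical_survival():
    rng = np.random.default_rng(1)
    t = rng.exponential(10, 200)
    km = sv.km_estimate(t, np.ones(200, int))
    for q in (2.0, 5.0, 15.0):
        assert km.survival_at(q) == pytest.approx((t > q).mean(), abs=1e-12)


def test_km_empty_errors():
    with pytest.raises(ValidationError):
        sv.km_estimate([], [])


def test_landmark_survival():
    km = sv.km_estimate([2, 4, 6], [1, 1, 0])
    assert sv.landmark_survival(km, 3) == pytest.approx(2 / 3)
    assert sv.landmark_survival(km, 0) == 1.0
    assert np.isnan(sv.landmark_survival(km, 100.0))


def test_logrank_hand_tableau():
    t = [1, 2, 3, 4]
    e = [1, 1, 1, 1]
    g = [True, True, False, False]
    expected = logrank_oracle(t, e, g)
    assert expected == pytest.approx(2.8824, abs=1e-3)
    assert sv.logrank_2group(t, e, g).statistic == pytest.approx(expected, abs=1e-10)
    res = sv.logrank_test(t, e, ["a", "a", "b", "b"])
    assert res.statistic == pytest.approx(expected, abs=1e-8)


def test_logrank_identical_groups():
    t = [1, 2, 3, 1, 2, 3]
    e = [1, 1, 0, 1, 1, 0]
    res = sv.logrank_test(t, e, ["a"] * 3 + ["b"] * 3)
    assert res.statistic == pytest.approx(0.0, abs=1e-10)
    assert res.p == pytest.approx(1.0, abs=1e-10)


def test_fast_logrank_matches_lifelines_randomized():
    rng = np.random.default_rng(6)
    for _ in range(40):
        n = rng.integers(10, 60)
        t = np.round(rng.exponential(10, n), 1) + 0.1  # induce ties
        e = rng.integers(0, 2, n)
        g = rng.integers(0, 2, n).astype(bool)
        if e.sum() == 0 or g.all() or not g.any():
            continue
        fast = sv.logrank_2group(t, e, g)
        ref = sv.logrank_test(t, e, g.astype(int))
        assert fast.statistic == pytest.approx(ref.statistic, abs=1e-8)
        assert fast.p == pytest.approx(ref.p, abs=1e-10)
        assert fast.statistic == pytest.approx(logrank_oracle(t, e, g), abs=1e-8)


def test_logrank_invariant_to_time_rescaling():
    rng = np.random.default_rng(14)
    t = rng.exponential(10, 50)
    e = rng.integers(0, 2, 50)
    g = rng.integers(0, 2, 50).astype(bool)
    a = sv.logrank_2group(t, e, g)
    b = sv.logrank_2group(t * 12.0, e, g)
    assert a.statistic == pytest.approx(b.statistic, abs=1e-10)


def test_logrank_type_i_error():
    rng = np.random.default_rng(15)
    rej = 0
    n_sim = 500
    for _ in range(n_sim):
        t = rng.exponential(1.0, 100)
        g = np.zeros(100, bool)
        g[:50] = True
        rej += sv.logrank_2group(t, np.ones(100, int), g).p < 0.05
    assert rej / n_sim == pytest.approx(0.05, abs=0.02)


def test_cox_sign_agrees_with_km_ordering():
    rng = np.random.default_rng(16)
    n = 300
    hi = np.zeros(n, bool)
    hi[:100] = True
    t = rng.exponential(np.where(hi, 5.0, 20.0))
    fit = sv.grouped_univariate_fit(t, np.ones(n, int), np.where(hi, "high", "low"))
    km_hi = sv.km_estimate(t[hi], np.ones(hi.sum(), int))
    km_lo = sv.km_estimate(t[~hi], np.ones((~hi).sum(), int))
    assert fit.hr["group"] > 1  # high group dies faster
    assert km_hi.survival_at(10) < km_lo.survival_at(10)
    assert fit.ci_low["group"] <= fit.hr["group"] <= fit.ci_high["group"]


def test_cox_recovery_moderate():
    rng = np.random.default_rng(18)
    hrs = []
    for _ in range(20):
        n = 300
        hi = rng.random(n) < 0.4
        lam = 0.05 * np.exp(math.log(2.5) * hi)
        t = rng.exponential(1 / lam)
        df = pd.DataFrame({"g": hi.astype(int), "t": t, "e": 1})
        hrs.append(sv.cox_fit(df, "t", "e", ["g"]).hr["g"])
    assert np.mean(hrs) == pytest.approx(2.5, rel=0.1)


def test_cox_null_covariate():
    rng = np.random.default_rng(19)
    ps = []
    for _ in range(30):
        n = 200
        df = pd.DataFrame({"g": rng.integers(0, 2, n), "t": rng.exponential(10, n), "e": 1})
        fit = sv.cox_fit(df, "t", "e", ["g"])
        ps.append(fit.p["g"])
    assert 0.8 < np.mean(np.array(ps) > 0.05) <= 1.0  # mostly non-significant
    assert np.exp(np.mean(np.log([sv.cox_fit(
        pd.DataFrame({"g": rng.integers(0, 2, 200), "t": rng.exponential(10, 200), "e": 1}),
        "t", "e", ["g"]).hr["g"] for _ in range(20)]))) == pytest.approx(1.0, abs=0.15)


def test_cox_single_subject_errors():
    df = pd.DataFrame({"g": [1], "t": [5.0], "e": [1]})
    with pytest.raises((ValidationError, MetdivError)):
        sv.cox_fit(df, "t", "e", ["g"])


def test_cox_no_covariate_errors():
    with pytest.raises(ValidationError):
        sv.cox_fit(pd.DataFrame({"t": [1.0, 2.0], "e": [1, 1]}), "t", "e", [])


def test_select_multivariate_factors():
    fits = [("metdiv", 0.002), ("age", 0.03), ("stromal", 0.12), ("lym", 0.30)]
    assert sv.select_multivariate_factors(fits) == ["metdiv", "age"]
    assert sv.select_multivariate_factors([("a", 0.5), ("b", 0.8)]) == []
    assert sv.select_multivariate_factors([("a", 0.05)]) == []  # strict <


def test_concordance_extremes():
    t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    e = np.ones(5, int)
    risk = np.array([5.0, 4.0, 3.0, 2.0, 1.0])  # highest risk dies first
    assert sv.concordance(risk, t, e) == 1.0
    assert sv.concordance(-risk, t, e) == 0.0
    with pytest.raises(DegenerateDataError):
        sv.concordance(risk, t, np.zeros(5, int))


def test_concordance_random_score_near_half():
    rng = np.random.default_rng(20)
    cs = [sv.concordance(rng.normal(size=100), rng.exponential(10, 100),
                         np.ones(100, int)) for _ in range(20)]
    assert np.mean(cs) == pytest.approx(0.5, abs=0.03)
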