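"""Recurrence-free survival: Kaplan-Meier product-limit estimate and the
two-group log-rank test.

RFS time zero is the first vaccine injection for vaccinated patients; for the
historical control arm, time zero is reset to 4 months after surgery to
account for vaccine design and manufacture time, so the two arms are
comparable.  Ties between events and censorings at the same time follow the
standard convention (events first: censored subjects remain at risk at that
time).  Confidence bands use Greenwood's variance on the log(-log) scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

VACCINATED, CONTROL = "vaccinated", "control"


def _validate(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("need at least one record")
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    if (t <= 0).any():
        raise ValueError("survival times must be positive")
    return t, e


def km_estimate(times, events, conf_level: float = 0.95) -> pd.DataFrame:
    """Kaplan-Meier product-limit table.

    One row per distinct event time: n_risk, n_event, n_censored (censorings
    in (previous event time, this one]), S(t) = prod(1 - d_i/n_i), and a
    Greenwood log-log confidence band.  S(0) = 1 and S is constant between
    event times."""
    t, e = _validate(times, events)
    event_times = np.unique(t[e])
    z = stats.norm.ppf(0.5 + conf_level / 2)
    rows, surv, var_sum, prev = [], 1.0, 0.0, -np.inf
    for ti in event_times:
        n_risk = int((t >= ti).sum())
        d = int((e & (t == ti)).sum())
        c = int((~e & (t > prev) & (t <= ti)).sum())
        surv *= 1.0 - d / n_risk
        lo = hi = math.nan
        if 0.0 < surv < 1.0:
            var_sum += d / (n_risk * (n_risk - d)) if n_risk > d else math.inf
            se_loglog = math.sqrt(var_sum) / abs(math.log(surv))
            theta = math.log(-math.log(surv))
            lo = math.exp(-math.exp(theta + z * se_loglog))
            hi = math.exp(-math.exp(theta - z * se_loglog))
        elif surv == 0.0:
            lo = hi = 0.0
        rows.append({"time": ti, "n_risk": n_risk, "n_event": d, "n_censored": c,
                     "survival": surv, "ci_lower": lo, "ci_upper": hi})
        prev = ti
    return pd.DataFrame(rows, columns=["time", "n_risk", "n_event", "n_censored",
                                       "survival", "ci_lower", "ci_upper"])


def km_survival_at(km: pd.DataFrame, time: float) -> float:
    """Step-function value S(time) from a km_estimate table (1.0 before the
    first event)."""
    past = km[km["time"] <= time]
    return 1.0 if past.empty else float(past["survival"].iloc[-1])


def km_interval_at(km: pd.DataFrame, time: float) -> tuple[float, float, float]:
    """(S, ci_lower, ci_upper) at ``time``."""
    past = km[km["time"] <= time]
    if past.empty:
        return 1.0, math.nan, math.nan
    row = past.iloc[-1]
    return float(row["survival"]), float(row["ci_lower"]), float(row["ci_upper"])


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Standard two-group log-rank test; returns (chi-square statistic, p)
    with p from the chi-square distribution with 1 df.  Symmetric in arm
    labels and invariant to record order."""
    ta, ea = _validate(times_a, events_a)
    tb, eb = _validate(times_b, events_b)
    event_times = np.unique(np.concatenate([ta[ea], tb[eb]]))
    o_minus_e, var = 0.0, 0.0
    for ti in event_times:
        na = int((ta >= ti).sum())
        nb = int((tb >= ti).sum())
        da = int((ea & (ta == ti)).sum())
        db = int((eb & (tb == ti)).sum())
        n, d = na + nb, da + db
        if n < 2 or d == 0:
            continue
        o_minus_e += da - d * na / n
        var += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    if var == 0.0:
        return 0.0, 1.0
    chi2 = o_minus_e ** 2 / var
    return float(chi2), float(stats.chi2.sf(chi2, 1))


@dataclass(frozen=True)
class SurvivalComparison:
    horizon_months: float
    rfs_vaccinated: float
    rfs_vaccinated_ci: tuple[float, float]
    rfs_control: float
    rfs_control_ci: tuple[float, float]
    logrank_chi2: float
    logrank_p: float
    n_vaccinated: int
    n_control: int
    events_vaccinated: int
    events_control: int


def compare_arms(followup: pd.DataFrame, horizon_months: float = 36.0,
                 ) -> SurvivalComparison:
    """KM estimate per arm at a horizon plus the log-rank comparison, from a
    tidy follow-up table (subject, arm, time_months, event)."""
    arms = {}
    for arm in (VACCINATED, CONTROL):
        sub = followup[followup["arm"] == arm]
        if sub.empty:
            raise ValueError(f"no records for arm {arm!r}")
        arms[arm] = (sub["time_months"].to_numpy(), sub["event"].to_numpy(bool))
    km_v = km_estimate(*arms[VACCINATED])
    km_c = km_estimate(*arms[CONTROL])
    sv, lov, hiv = km_interval_at(km_v, horizon_months)
    sc, loc, hic = km_interval_at(km_c, horizon_months)
    chi2, p = logrank_test(*arms[VACCINATED], *arms[CONTROL])
    return SurvivalComparison(
        horizon_months, sv, (lov, hiv), sc, (loc, hic), chi2, p,
        len(arms[VACCINATED][0]), len(arms[CONTROL][0]),
        int(arms[VACCINATED][1].sum()), int(arms[CONTROL][1].sum()))
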