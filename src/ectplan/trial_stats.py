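"""Self-contained trial statistics: exact Fisher, Mann-Whitney, Kaplan-Meier,
log-rank, Welch t and one-way ANOVA, plus response-rate summaries.

The test statistics are implemented here from their definitions (the exact
tests with integer arithmetic, the survival machinery from the product-limit
construction); only textbook reference distributions (chi-square, normal,
t, F) come from :mod:`scipy.stats`.  Third-party implementations serve as
independent cross-checks in the test suite, never as the computation.

Conventions, fixed to match the trial's reporting:

* Fisher's exact test is two-sided by the point-probability rule: the
  p-value sums the hypergeometric probabilities of every table (at fixed
  margins) no more probable than the observed one.
* The Mann-Whitney test is exact (full enumeration of the U null
  distribution) when the smaller sample has at most 8 observations and
  there are no ties; otherwise a normal approximation with tie and
  continuity corrections is used.
* The Kaplan-Meier median is the first time at which S(t) <= 0.5.
* Percentages are reported to one decimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _sps

from .clinical_scoring import Group, PatientRecord, Response

__all__ = [
    "ContingencyTable2x2",
    "SurvivalSample",
    "KMCurve",
    "fisher_exact_two_sided",
    "response_rate_summary",
    "mann_whitney",
    "kaplan_meier",
    "log_rank",
    "welch_t_test",
    "one_way_anova",
    "TrialSummary",
    "summarize_trial",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows = groups, columns = responder / non-responder."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("empty table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def has_empty_margin(self) -> bool:
        return (
            self.a + self.b == 0
            or self.c + self.d == 0
            or self.a + self.c == 0
            or self.b + self.d == 0
        )


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value (point-probability rule), exact arithmetic.

    With fixed margins the table is determined by its first cell; the
    p-value is the sum of hypergeometric point probabilities not exceeding
    the observed table's.  All weights are Python integers, so the result is
    exact up to the final division (totals up to ~10^4 are fine).

    A table with an empty margin carries no information; by convention
    p = 1.
    """
    if table.has_empty_margin:
        return 1.0
    r1 = table.a + table.b
    c1 = table.a + table.c
    n = table.total
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    weights = {k: math.comb(r1, k) * math.comb(n - r1, c1 - k) for k in range(lo, hi + 1)}
    w_obs = weights[table.a]
    numer = sum(w for w in weights.values() if w <= w_obs)
    denom = math.comb(n, c1)
    return float(Fraction(numer, denom))


def response_rate_summary(
    counts: dict[str, int] | Sequence[int], n: Optional[int] = None
) -> dict[str, float]:
    """Category percentages and the objective-response rate, to one decimal.

    ``counts`` maps CR/PR/SD/PD/NE to counts (or gives them in that order).
    OR% combines CR and PR; NE counts as a non-responder.
    """
    order = ["CR", "PR", "SD", "PD", "NE"]
    if not isinstance(counts, dict):
        counts = dict(zip(order, counts))
    counts = {k: int(counts.get(k, 0)) for k in order}
    if any(v < 0 for v in counts.values()):
        raise ValueError("counts must be non-negative")
    total = sum(counts.values())
    if n is None:
        n = total
    if total > n or n <= 0:
        raise ValueError(f"counts sum to {total} but group n = {n}")
    out = {k: round(100.0 * v / n, 1) for k, v in counts.items()}
    out["OR"] = round(100.0 * (counts["CR"] + counts["PR"]) / n, 1)
    return out


# ---------------------------------------------------------------------------
# Mann-Whitney


@lru_cache(maxsize=None)
def _u_count(n1: int, n2: int, u: int) -> int:
    """Number of rank arrangements of n1 + n2 untied values giving U = u."""
    if u < 0 or u > n1 * n2:
        return 0
    if n1 == 0 or n2 == 0:
        return 1 if u == 0 else 0
    return _u_count(n1 - 1, n2, u - n2) + _u_count(n1, n2 - 1, u)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> dict[str, float]:
    """Two-sided Mann-Whitney test; returns ``{"U": ..., "p": ...}``.

    U is the statistic of the first sample (number of (x, y) pairs with
    x > y, ties counting one half).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    u1 = float(gt) + 0.5 * float(eq)
    has_ties = len(np.unique(np.concatenate([x, y]))) < n1 + n2
    if min(n1, n2) <= 8 and not has_ties:
        total = math.comb(n1 + n2, n1)
        u_small = min(u1, n1 * n2 - u1)
        tail = sum(_u_count(n1, n2, u) for u in range(0, int(u_small) + 1))
        p = min(1.0, 2.0 * tail / total)
        return {"U": u1, "p": p}
    # normal approximation with tie and continuity corrections
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return {"U": u1, "p": 1.0}
    z = max(0.0, abs(u1 - mu) - 0.5) / math.sqrt(var)
    p = 2.0 * _sps.norm.sf(z)
    return {"U": u1, "p": min(1.0, p)}


# ---------------------------------------------------------------------------
# survival


@dataclass(frozen=True)
class SurvivalSample:
    """Right-censored survival times in days; event=True marks observed deaths."""

    times: tuple[float, ...]
    events: tuple[bool, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        object.__setattr__(self, "events", tuple(bool(e) for e in self.events))
        if len(self.times) != len(self.events):
            raise ValueError("times and events must have equal length")
        if any(t <= 0 for t in self.times):
            raise ValueError("survival times must be positive")

    @classmethod
    def from_records(cls, records: Sequence[PatientRecord]) -> "SurvivalSample":
        return cls(
            tuple(r.survival_days for r in records),
            tuple(r.event_observed for r in records),
        )

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class KMCurve:
    """Product-limit survival curve."""

    event_times: np.ndarray
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # number at risk just before each event time
    median: Optional[float]  # first t with S(t) <= 0.5, None if never reached

    def survival_at(self, t: float) -> float:
        """Step-function evaluation of S(t)."""
        s = 1.0
        for et, sv in zip(self.event_times, self.survival):
            if et <= t:
                s = sv
            else:
                break
        return s


def kaplan_meier(sample: SurvivalSample) -> KMCurve:
    """Product-limit estimator; censored times shrink the risk set silently."""
    if len(sample) == 0:
        raise ValueError("empty survival sample")
    times = np.asarray(sample.times)
    events = np.asarray(sample.events)
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    uniq = np.unique(times[events])
    ev_times, surv, risk = [], [], []
    s = 1.0
    for t in uniq:
        n_at_risk = int((times >= t).sum())
        d = int(((times == t) & events).sum())
        s *= 1.0 - d / n_at_risk
        ev_times.append(float(t))
        surv.append(s)
        risk.append(n_at_risk)
    surv_arr = np.array(surv)
    median = None
    for t, s in zip(ev_times, surv):
        if s <= 0.5:
            median = t
            break
    return KMCurve(
        event_times=np.array(ev_times),
        survival=surv_arr,
        at_risk=np.array(risk),
        median=median,
    )


def log_rank(g1: SurvivalSample, g2: SurvivalSample) -> dict[str, float]:
    """Two-group log-rank test (1 df); returns ``{"chi2": ..., "p": ...}``."""
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("both samples must be non-empty")
    t1, e1 = np.asarray(g1.times), np.asarray(g1.events)
    t2, e2 = np.asarray(g2.times), np.asarray(g2.events)
    all_event_times = np.unique(np.concatenate([t1[e1], t2[e2]]))
    if all_event_times.size == 0:
        raise ValueError("no observed events in either group")
    o_minus_e = 0.0
    var = 0.0
    for t in all_event_times:
        n1 = int((t1 >= t).sum())
        n2 = int((t2 >= t).sum())
        d1 = int(((t1 == t) & e1).sum())
        d2 = int(((t2 == t) & e2).sum())
        n = n1 + n2
        d = d1 + d2
        if n < 2 or n1 == 0 or n2 == 0:
            continue
        e1_t = n1 * d / n
        o_minus_e += d1 - e1_t
        if n > 1:
            var += n1 * n2 * d * (n - d) / (n**2 * (n - 1))
    if var <= 0:
        return {"chi2": 0.0, "p": 1.0}
    chi2 = o_minus_e**2 / var
    return {"chi2": float(chi2), "p": float(_sps.chi2.sf(chi2, df=1))}


# ---------------------------------------------------------------------------
# balance checks


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> dict[str, float]:
    """Welch's unequal-variance t-test, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per group")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if v1 == 0 and v2 == 0:
        raise ValueError("degenerate variance: both samples are constant")
    se2 = v1 / len(x) + v2 / len(y)
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / (
        (v1 / len(x)) ** 2 / (len(x) - 1) + (v2 / len(y)) ** 2 / (len(y) - 1)
    )
    p = 2.0 * _sps.t.sf(abs(t), df)
    return {"t": float(t), "df": float(df), "p": float(min(1.0, p))}


def one_way_anova(groups: Sequence[Sequence[float]]) -> dict[str, float]:
    """Fixed-effects one-way ANOVA F test."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(g) < 2 for g in arrays):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    all_vals = np.concatenate(arrays)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in arrays)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    df_b = len(arrays) - 1
    df_w = len(all_vals) - len(arrays)
    if ss_within == 0:
        raise ValueError("degenerate variance: no within-group variation")
    f = (ss_between / df_b) / (ss_within / df_w)
    return {"F": float(f), "df": (df_b, df_w), "p": float(_sps.f.sf(f, df_b, df_w))}


# ---------------------------------------------------------------------------
# cohort-level summary


@dataclass
class TrialSummary:
    """Headline statistics of one cohort."""

    n_standard: int
    n_thin: int
    response_rates: dict[str, dict[str, float]]
    responder_table: ContingencyTable2x2
    fisher_p: float
    anorexia_mann_whitney: dict[str, float]
    km_standard: KMCurve
    km_thin: KMCurve
    log_rank_groups: dict[str, float]
    log_rank_early_late: Optional[dict[str, float]]
    balance: dict[str, float]

    def to_dict(self) -> dict:
        def km(curve: KMCurve) -> dict:
            return {
                "event_times": curve.event_times.tolist(),
                "survival": curve.survival.tolist(),
                "at_risk": curve.at_risk.tolist(),
                "median_days": curve.median,
            }

        return {
            "n": {"standard": self.n_standard, "thin": self.n_thin},
            "response_rates_pct": self.response_rates,
            "responder_table": [
                [self.responder_table.a, self.responder_table.b],
                [self.responder_table.c, self.responder_table.d],
            ],
            "fisher_p": round(self.fisher_p, 3),
            "anorexia_mann_whitney": self.anorexia_mann_whitney,
            "km": {"standard": km(self.km_standard), "thin": km(self.km_thin)},
            "log_rank_groups": self.log_rank_groups,
            "log_rank_early_vs_late": self.log_rank_early_late,
            "balance": self.balance,
        }


def summarize_trial(records: Sequence[PatientRecord]) -> TrialSummary:
    """Full analysis of a cohort: rates, exact tests, survival curves."""
    std = [r for r in records if r.group is Group.STANDARD]
    thin = [r for r in records if r.group is Group.THIN]
    if not std or not thin:
        raise ValueError("cohort must contain both groups")

    def counts(rs):
        return {c.value: sum(1 for r in rs if r.response is c) for c in Response}

    rates = {
        "standard": response_rate_summary(counts(std), n=len(std)),
        "thin": response_rate_summary(counts(thin), n=len(thin)),
    }
    responders = {
        g: sum(1 for r in rs if r.response in (Response.CR, Response.PR))
        for g, rs in (("thin", thin), ("standard", std))
    }
    table = ContingencyTable2x2(
        a=responders["thin"],
        b=len(thin) - responders["thin"],
        c=responders["standard"],
        d=len(std) - responders["standard"],
    )
    mw = mann_whitney(
        [r.anorexia_grade for r in std], [r.anorexia_grade for r in thin]
    )
    km_std = kaplan_meier(SurvivalSample.from_records(std))
    km_thin = kaplan_meier(SurvivalSample.from_records(thin))
    lr = log_rank(
        SurvivalSample.from_records(std), SurvivalSample.from_records(thin)
    )
    early = [r for r in records if r.stage <= 2]
    late = [r for r in records if r.stage >= 3]
    lr_stage = None
    if early and late:
        try:
            lr_stage = log_rank(
                SurvivalSample.from_records(early), SurvivalSample.from_records(late)
            )
        except ValueError:
            lr_stage = None
    balance = {}
    try:
        balance["age_anova_p"] = one_way_anova(
            [[r.age_years for r in std], [r.age_years for r in thin]]
        )["p"]
        balance["weight_anova_p"] = one_way_anova(
            [[r.weight_kg for r in std], [r.weight_kg for r in thin]]
        )["p"]
        balance["sex_t_p"] = welch_t_test(
            [1.0 if r.sex == "M" else 0.0 for r in std],
            [1.0 if r.sex == "M" else 0.0 for r in thin],
        )["p"]
    except ValueError:
        pass  # degenerate synthetic cohorts may lack variation
    return TrialSummary(
        n_standard=len(std),
        n_thin=len(thin),
        response_rates=rates,
        responder_table=table,
        fisher_p=fisher_exact_two_sided(table),
        anorexia_mann_whitney=mw,
        km_standard=km_std,
        km_thin=km_thin,
        log_rank_groups=lr,
        log_rank_early_late=lr_stage,
        balance=balance,
    )


def fisher_p_round(table: ContingencyTable2x2, decimals: int = 3) -> float:
    """Fisher p rounded the way the trial reports it (3 decimals)."""
    return round(fisher_exact_two_sided(table), decimals)
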