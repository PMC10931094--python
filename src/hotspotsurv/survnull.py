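"""Survival statistics for heavily unbalanced two-group comparisons.

The classical log-rank test refers ``L^2/V`` to a chi-square(1)
distribution, which presumes large and comparably sized groups.  When one
group holds only a handful of patients — the typical situation for a
mutational hotspot — that approximation can be badly wrong in either
direction.  This module therefore tabulates the *conditional permutation
null* of the signed log-rank statistic ``L``: holding the observed times
and censoring pattern fixed, ``L`` is recomputed over reassignments of the
minority-group labels, either by full enumeration of all ``C(n, n1)``
assignments or, when that is infeasible, by stratifying on ``k`` — the
number of events that land in the minority group — with closed-form
hypergeometric stratum weights.  Small strata are enumerated exactly;
large ones are sampled.  The resulting null may be asymmetric and
multimodal; a two-sided p-value is twice the smaller tail area.

The key computational fact is that ``L`` is *linear* in the group labels:
``L = sum_{i in minority} w_i`` where ``w_i = delta_i - H(t_i)`` is the
log-rank score residual of patient ``i`` (``delta_i`` the event indicator,
``H`` the Nelson-Aalen cumulative hazard of the pooled sample).  This
reduces every permutation to a subset sum and makes exact enumeration of
hundreds of thousands of assignments cheap.

Also provided: the chi-square p-value, a binary-covariate Cox model
(Breslow ties, Newton iteration) with explicit degenerate-case flags, and
the Kaplan-Meier estimator (via lifelines) with median survival.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalSample",
    "NullStratum",
    "NullDistribution",
    "LogRankResult",
    "CoxResult",
    "KMCurve",
    "logrank_statistic",
    "logrank_scores",
    "asymptotic_p",
    "exact_null",
    "empirical_p",
    "cox_fit",
    "km_estimate",
]


@dataclass
class SurvivalSample:
    """Two survival groups in parallel arrays.

    ``group`` is True for the minority/hotspot group.  ``times`` are days;
    ``events`` mark observed deaths.
    """

    times: np.ndarray
    events: np.ndarray
    group: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=bool)
        self.group = np.asarray(self.group, dtype=bool)
        if not (len(self.times) == len(self.events) == len(self.group)):
            raise ValueError("times, events and group must have equal length")
        if np.any(self.times < 0):
            raise ValueError("negative survival time")

    @property
    def n(self) -> int:
        return len(self.times)

    @property
    def n1(self) -> int:
        return int(self.group.sum())

    @property
    def d(self) -> int:
        return int(self.events.sum())

    def validate_comparison(self) -> None:
        if not 0 < self.n1 < self.n:
            raise ValueError(f"invalid comparison: n1={self.n1} of n={self.n}")

    def swapped(self) -> "SurvivalSample":
        """The same data with group labels inverted."""
        return SurvivalSample(self.times, self.events, ~self.group)

    @classmethod
    def from_groups(
        cls,
        times_minority: Sequence[float],
        events_minority: Sequence[bool],
        times_comparison: Sequence[float],
        events_comparison: Sequence[bool],
    ) -> "SurvivalSample":
        t = np.concatenate([np.asarray(times_minority, float), np.asarray(times_comparison, float)])
        e = np.concatenate([np.asarray(events_minority, bool), np.asarray(events_comparison, bool)])
        g = np.zeros(len(t), dtype=bool)
        g[: len(times_minority)] = True
        return cls(t, e, g)


def _event_table(times: np.ndarray, events: np.ndarray, group: np.ndarray | None = None):
    """Distinct-time risk table: (unique times, d_j, r_j[, d1_j, r1_j])."""
    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order].astype(float)
    uniq, first = np.unique(t, return_index=True)
    d = np.add.reduceat(e, first)
    r = (len(t) - first).astype(float)
    if group is None:
        return uniq, d, r, None, None
    g = group[order].astype(float)
    suffix = np.cumsum(g[::-1])[::-1]
    r1 = suffix[first]
    d1 = np.add.reduceat(e * g, first)
    return uniq, d, r, d1, r1


def logrank_statistic(sample: SurvivalSample) -> tuple[float, float]:
    """Signed log-rank statistic ``L`` and its hypergeometric variance ``V``.

    ``L`` sums, over distinct event times, the observed minus expected
    events in the minority group with the standard multiplicity-aware tie
    terms.  Returns ``(0.0, 0.0)`` when there are no events.
    """
    sample.validate_comparison()
    if sample.d == 0:
        return 0.0, 0.0
    _, d, r, d1, r1 = _event_table(sample.times, sample.events, sample.group)
    mask = d > 0
    d, r, d1, r1 = d[mask], r[mask], d1[mask], r1[mask]
    frac = r1 / r
    L = float(np.sum(d1 - d * frac))
    with np.errstate(divide="ignore", invalid="ignore"):
        v_terms = d * frac * (1.0 - frac) * (r - d) / (r - 1.0)
    v_terms = np.where(r > 1.0, v_terms, 0.0)
    V = float(np.sum(v_terms))
    return L, V


def logrank_scores(times: np.ndarray, events: np.ndarray) -> np.ndarray:
    """Per-patient log-rank score residuals ``w_i = delta_i - H(t_i)``.

    ``H`` is the pooled Nelson-Aalen cumulative hazard, evaluated at the
    patient's own (event or censoring) time.  The minority-group sum of
    these scores equals the log-rank statistic ``L`` for any label
    assignment, and the scores always sum to zero over the whole cohort.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order].astype(float)
    uniq, first = np.unique(t, return_index=True)
    d = np.add.reduceat(e, first)
    r = (len(t) - first).astype(float)
    cumhaz = np.cumsum(d / r)
    pos = np.searchsorted(uniq, t)
    w = np.empty(len(t))
    w[order] = e - cumhaz[pos]
    return w


def asymptotic_p(L: float, V: float) -> float:
    """Classical chi-square(1) p-value of ``L^2/V`` (1.0 when ``V`` is 0)."""
    if V <= 0:
        return 1.0
    return float(stats.chi2.sf(L * L / V, df=1))


@dataclass
class LogRankResult:
    """Observed log-rank statistic with both p-values."""

    L: float
    V: float
    p_asymptotic: float
    p_empirical: float | None = None


# ---------------------------------------------------------------------------
# conditional permutation null
# ---------------------------------------------------------------------------


@dataclass
class NullStratum:
    """Conditional distribution of ``L`` given ``k`` minority-group events.

    ``values`` are equally probable support points: the full within-stratum
    enumeration when ``exact`` is True, otherwise uniform draws.
    """

    k: int
    weight: float
    values: np.ndarray
    exact: bool


@dataclass
class NullDistribution:
    """Discrete (possibly asymmetric, multimodal) null of the log-rank L.

    A mixture over strata indexed by ``k`` (minority-group event count)
    with hypergeometric weights ``w_k = C(d,k) C(n-d, n1-k) / C(n, n1)``.
    ``mode`` is ``"exact-enumeration"`` (all assignments listed) or
    ``"stratified-sampling"`` (per-stratum enumeration where small,
    sampling where large).
    """

    strata: list[NullStratum]
    mode: str
    n_samples_per_stratum: int | None = None
    _values: np.ndarray = field(default=None, repr=False, compare=False)
    _cumw: np.ndarray = field(default=None, repr=False, compare=False)

    def _aggregate(self) -> tuple[np.ndarray, np.ndarray]:
        if self._values is None:
            vals = np.concatenate([s.values for s in self.strata])
            wts = np.concatenate(
                [np.full(len(s.values), s.weight / len(s.values)) for s in self.strata]
            )
            order = np.argsort(vals, kind="stable")
            self._values = vals[order]
            self._cumw = np.cumsum(wts[order])
        return self._values, self._cumw

    @property
    def support(self) -> np.ndarray:
        """Sorted support points (duplicates merged)."""
        vals, _ = self._aggregate()
        return np.unique(vals)

    @property
    def weights(self) -> np.ndarray:
        """Probabilities parallel to :attr:`support`."""
        vals, cumw = self._aggregate()
        uniq, inverse = np.unique(vals, return_inverse=True)
        w = np.diff(np.concatenate([[0.0], cumw]))
        return np.bincount(inverse, weights=w, minlength=len(uniq))

    def prob_leq(self, x: float) -> float:
        vals, cumw = self._aggregate()
        i = np.searchsorted(vals, x, side="right")
        return float(cumw[i - 1]) if i > 0 else 0.0

    def prob_geq(self, x: float) -> float:
        vals, cumw = self._aggregate()
        i = np.searchsorted(vals, x, side="left")
        total = float(cumw[-1])
        return total - (float(cumw[i - 1]) if i > 0 else 0.0)

    def to_frame(self) -> pd.DataFrame:
        """Serialize the mixture (stratum k, L value, probability) for
        plotting or TSV export."""
        rows = []
        for s in sorted(self.strata, key=lambda s: s.k):
            p = s.weight / len(s.values)
            for v in np.sort(s.values):
                rows.append({"stratum_k": s.k, "L": v, "weight": p, "exact": s.exact})
        return pd.DataFrame(rows)


def _tie_tol(x: float) -> float:
    return 1e-9 * (1.0 + abs(x))


def empirical_p(null: NullDistribution, L_obs: float) -> float:
    """Two-sided empirical p-value: twice the smaller tail area, capped at 1.

    Support points equal to ``L_obs`` (within floating tolerance) count
    fully in both tails, which keeps the test valid on discrete nulls.
    """
    tol = _tie_tol(L_obs)
    lower = null.prob_leq(L_obs + tol)
    upper = null.prob_geq(L_obs - tol)
    return min(1.0, 2.0 * min(lower, upper))


def _enumerate_subset_sums(pool: np.ndarray, k: int) -> np.ndarray:
    """Sums of every k-subset of ``pool`` (C(len(pool), k) values)."""
    m = len(pool)
    if k == 0:
        return np.zeros(1)
    if k == m:
        return np.array([pool.sum()])
    combos = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(m), k)),
        dtype=np.intp,
        count=math.comb(m, k) * k,
    ).reshape(-1, k)
    return pool[combos].sum(axis=1)


def _sample_subset_sums(rng: np.random.Generator, pool: np.ndarray, k: int, n_draws: int) -> np.ndarray:
    """Sums of ``n_draws`` uniformly random k-subsets of ``pool``."""
    m = len(pool)
    if k == 0:
        return np.zeros(n_draws)
    if k == m:
        return np.full(n_draws, pool.sum())
    if k == 1:
        return pool[rng.integers(0, m, n_draws)]
    keys = rng.random((n_draws, m))
    part = np.argpartition(keys, k - 1, axis=1)[:, :k]
    return pool[part].sum(axis=1)


def exact_null(
    sample: SurvivalSample,
    *,
    seed: int,
    enum_limit: int = 100_000,
    n_perm_per_stratum: int = 10_000,
    stratum_enum_limit: int | None = None,
) -> NullDistribution:
    """Conditional permutation null of the log-rank statistic.

    With ``C(n, n1) <= enum_limit`` every minority-label assignment is
    enumerated, giving the exact null with uniform weights.  Otherwise the
    null is built stratum by stratum over ``k`` (minority-group event
    count): strata whose subset count is at most ``stratum_enum_limit``
    (default: ``n_perm_per_stratum``) are still enumerated exactly; larger
    strata are estimated from ``n_perm_per_stratum`` uniform draws.
    Stratum weights are the closed-form hypergeometric probabilities, so
    rare-``k`` tails are weighted correctly no matter how they were
    estimated.  Fully reproducible given ``seed``.  Setting
    ``stratum_enum_limit=0`` forces pure sampling in every stratum.
    """
    sample.validate_comparison()
    n, n1, d = sample.n, sample.n1, sample.d
    w = logrank_scores(sample.times, sample.events)
    ev = sample.events

    if math.comb(n, n1) <= enum_limit:
        combos = np.fromiter(
            itertools.chain.from_iterable(itertools.combinations(range(n), n1)),
            dtype=np.intp,
            count=math.comb(n, n1) * n1,
        ).reshape(-1, n1)
        L = w[combos].sum(axis=1)
        k_all = ev[combos].sum(axis=1)
        total = len(combos)
        strata = [
            NullStratum(
                k=int(k),
                weight=float(np.count_nonzero(k_all == k)) / total,
                values=np.sort(L[k_all == k]),
                exact=True,
            )
            for k in np.unique(k_all)
        ]
        return NullDistribution(strata=strata, mode="exact-enumeration")

    rng = np.random.default_rng(seed)
    if stratum_enum_limit is None:
        stratum_enum_limit = n_perm_per_stratum
    ev_scores = w[ev]
    cen_scores = w[~ev]
    n_cen = n - d
    strata = []
    for k in range(max(0, n1 - n_cen), min(d, n1) + 1):
        wk = float(stats.hypergeom.pmf(k, n, d, n1))
        if wk <= 0.0:
            continue
        stratum_size = math.comb(d, k) * math.comb(n_cen, n1 - k)
        if stratum_size <= stratum_enum_limit:
            se = _enumerate_subset_sums(ev_scores, k)
            sc = _enumerate_subset_sums(cen_scores, n1 - k)
            values = np.add.outer(se, sc).ravel()
            exact = True
        else:
            se = _sample_subset_sums(rng, ev_scores, k, n_perm_per_stratum)
            sc = _sample_subset_sums(rng, cen_scores, n1 - k, n_perm_per_stratum)
            values = se + sc
            exact = False
        strata.append(NullStratum(k=k, weight=wk, values=np.sort(values), exact=exact))
    total_w = sum(s.weight for s in strata)
    for s in strata:
        s.weight /= total_w
    return NullDistribution(
        strata=strata, mode="stratified-sampling", n_samples_per_stratum=n_perm_per_stratum
    )


def logrank_test(
    sample: SurvivalSample,
    null: NullDistribution | None = None,
) -> LogRankResult:
    """Convenience wrapper: statistic, chi-square p, and (when a null is
    supplied) the two-sided empirical p."""
    L, V = logrank_statistic(sample)
    p_emp = empirical_p(null, L) if null is not None else None
    return LogRankResult(L=L, V=V, p_asymptotic=asymptotic_p(L, V), p_empirical=p_emp)


# ---------------------------------------------------------------------------
# Cox proportional hazards, binary covariate
# ---------------------------------------------------------------------------


@dataclass
class CoxResult:
    """Binary-covariate Cox fit (minority group vs comparison).

    When one side has no events the partial likelihood is monotone and the
    hazard ratio diverges; the fit then reports a qualitative direction in
    ``hr_label`` (``"<1"`` when the minority group has no events, ``">1"``
    when the comparison group has none) with ``degenerate`` set.
    """

    log_hr: float | None
    hr: float | None
    se: float | None
    p_cox: float | None
    degenerate: str = "none"  # none | no_events | no_events_in_group | nonconvergence
    hr_label: str | None = None
    events_minority: int = 0
    events_comparison: int = 0


def cox_fit(sample: SurvivalSample, max_iter: int = 100, tol: float = 1e-9) -> CoxResult:
    """Maximize the Cox partial likelihood (Breslow ties) by Newton iteration.

    For a single binary covariate the score and information have closed
    forms over the distinct event times, so each iteration is one pass over
    the risk table.  Degenerate configurations never raise: they return a
    flagged result.
    """
    sample.validate_comparison()
    _, d, r, d1, r1 = _event_table(sample.times, sample.events, sample.group)
    mask = d > 0
    d, r, d1, r1 = d[mask], r[mask], d1[mask], r1[mask]
    k1 = int(d1.sum())
    k0 = int(d.sum()) - k1
    if k1 + k0 == 0:
        return CoxResult(None, None, None, None, degenerate="no_events")
    if k1 == 0:
        return CoxResult(
            None, None, None, None,
            degenerate="no_events_in_group", hr_label="<1",
            events_minority=0, events_comparison=k0,
        )
    if k0 == 0:
        return CoxResult(
            None, None, None, None,
            degenerate="no_events_in_group", hr_label=">1",
            events_minority=k1, events_comparison=0,
        )
    r0 = r - r1
    beta = 0.0
    info = np.nan
    converged = False
    for _ in range(max_iter):
        eb = math.exp(beta)
        denom = r1 * eb + r0
        p = r1 * eb / denom
        score = k1 - float(np.sum(d * p))
        info = float(np.sum(d * p * (1.0 - p)))
        if info <= 0:
            break
        step = score / info
        # cap the step so early iterations cannot overshoot into overflow
        step = max(-5.0, min(5.0, step))
        beta += step
        if abs(step) < tol:
            converged = True
            break
    if not converged or not math.isfinite(beta) or info <= 0 or abs(beta) > 15.0:
        # a drifting |beta| means a monotone partial likelihood (e.g. every
        # minority event precedes every comparison event): the MLE is at
        # infinity and only the direction of the effect is identified
        label = None
        if math.isfinite(beta) and abs(beta) > 15.0:
            label = ">1" if beta > 0 else "<1"
            logger.info("monotone Cox partial likelihood; reporting direction %s", label)
        else:
            logger.warning("Cox fit did not converge (beta=%.3g)", beta)
        return CoxResult(
            None, None, None, None,
            degenerate="nonconvergence", hr_label=label,
            events_minority=k1, events_comparison=k0,
        )
    se = 1.0 / math.sqrt(info)
    p_wald = 2.0 * float(stats.norm.sf(abs(beta) / se))
    return CoxResult(
        log_hr=beta, hr=math.exp(beta), se=se, p_cox=p_wald,
        degenerate="none", events_minority=k1, events_comparison=k0,
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


@dataclass
class KMCurve:
    """Product-limit survival curve with numbers at risk.

    ``median_survival`` is the smallest time with S(t) <= 0.5, ``None``
    when the curve never drops that far.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median_survival: float | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> KMCurve:
    """Kaplan-Meier estimate (delegates to lifelines' product-limit fitter)."""
    from lifelines import KaplanMeierFitter

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(times) == 0:
        raise ValueError("empty sample")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    step_times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    table = kmf.event_table
    at_risk = table["at_risk"].reindex(sf.index).ffill().to_numpy(dtype=float)
    median = float(kmf.median_survival_time_)
    return KMCurve(
        times=step_times,
        survival=surv,
        at_risk=at_risk,
        median_survival=None if math.isinf(median) else median,
    )
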