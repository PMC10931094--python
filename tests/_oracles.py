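"""Independent brute-force oracles for the permutation-null machinery.

These deliberately avoid the score-linearization shortcut used by the
implementation: every subset's log-rank statistic is recomputed from the
risk table, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import itertools

import numpy as np

from hotspotsurv.survnull import NullDistribution, SurvivalSample, logrank_statistic


def brute_force_null_values(sample: SurvivalSample) -> np.ndarray:
    """L for every C(n, n1) minority assignment, one value per subset."""
    n, n1 = sample.n, sample.n1
    values = []
    for combo in itertools.combinations(range(n), n1):
        g = np.zeros(n, dtype=bool)
        g[list(combo)] = True
        L, _ = logrank_statistic(SurvivalSample(sample.times, sample.events, g))
        values.append(L)
    return np.sort(np.asarray(values))


def brute_force_p(values: np.ndarray, L_obs: float) -> float:
    """Two-sided permutation p over an enumerated null (ties in both tails)."""
    tol = 1e-9 * (1.0 + abs(L_obs))
    lower = np.mean(values <= L_obs + tol)
    upper = np.mean(values >= L_obs - tol)
    return min(1.0, 2.0 * min(lower, upper))


def null_atoms(null: NullDistribution) -> tuple[np.ndarray, np.ndarray]:
    """Flatten a NullDistribution into (values, probabilities)."""
    vals = np.concatenate([s.values for s in null.strata])
    wts = np.concatenate(
        [np.full(len(s.values), s.weight / len(s.values)) for s in null.strata]
    )
    return vals, wts


def tv_distance(
    vals_a: np.ndarray,
    wts_a: np.ndarray,
    vals_b: np.ndarray,
    wts_b: np.ndarray,
    tol: float = 1e-9,
) -> float:
    """Total-variation distance between two discrete distributions whose
    atoms are matched up to floating tolerance ``tol``."""
    allv = np.concatenate([vals_a, vals_b])
    signed = np.concatenate([wts_a, -np.asarray(wts_b)])
    order = np.argsort(allv, kind="stable")
    v, w = allv[order], signed[order]
    groups = np.concatenate([[0], np.cumsum(np.diff(v) > tol)])
    return 0.5 * float(np.abs(np.bincount(groups, weights=w)).sum())
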