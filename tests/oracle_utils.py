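"""Independent oracles used across the test suite.

These deliberately take the slow, transparent route (exhaustive dynamic
programming, brute-force enumeration, Monte-Carlo sampling) so that the
package's fast implementations can be checked against them.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.special import logsumexp

from smstoich.steps import _MarginalScorer


def exhaustive_changepoints(y: np.ndarray, prior_odds: float = 1.0,
                            min_segment: int = 3, max_cp: int = 4) -> tuple[int, ...]:
    """Global Bayesian changepoint search by dynamic programming.

    For each changepoint count m the evidence is the log-mean (uniform
    prior over placements) of the product of segment marginal likelihoods
    over all admissible placements, times prior_odds^m; the best m wins
    and its maximum-scoring placement is returned.  Same per-segment score
    as the recursive implementation, entirely different search.
    """
    y = np.asarray(y, float)
    n = y.size
    sc = _MarginalScorer(y)
    lpo = np.log(prior_odds)

    # lse[m][j]: logsumexp over placements of m changepoints in y[:j]
    # (last segment ending at j); cnt analogous placement counts;
    # mx/arg: max-score placement tracking.
    j_all = np.arange(0, n + 1)
    lm0 = np.full(n + 1, -np.inf)
    valid = j_all >= min_segment
    lm0[valid] = np.atleast_1d(sc.log_marginal(0, j_all[valid]))
    lse = [lm0]
    cnt = [np.where(valid, 1.0, 0.0)]
    mx = [lm0.copy()]
    arg: list[list[tuple[int, ...] | None]] = [[() if valid[j] else None
                                               for j in range(n + 1)]]
    best_m, best_ev, best_cps = 0, float(lse[0][n]), ()
    for m in range(1, max_cp + 1):
        lse_m = np.full(n + 1, -np.inf)
        cnt_m = np.zeros(n + 1)
        mx_m = np.full(n + 1, -np.inf)
        arg_m: list[tuple[int, ...] | None] = [None] * (n + 1)
        for j in range(min_segment * (m + 1), n + 1):
            ts = np.arange(min_segment * m, j - min_segment + 1)
            ts = ts[np.isfinite(lse[m - 1][ts])]
            if ts.size == 0:
                continue
            seg = sc.log_marginal(ts, j)
            terms = lse[m - 1][ts] + seg
            lse_m[j] = logsumexp(terms)
            cnt_m[j] = cnt[m - 1][ts].sum()
            cand = mx[m - 1][ts] + seg
            k = int(np.argmax(cand))
            mx_m[j] = cand[k]
            prev = arg[m - 1][int(ts[k])]
            arg_m[j] = prev + (int(ts[k]),) if prev is not None else None
        lse.append(lse_m)
        cnt.append(cnt_m)
        mx.append(mx_m)
        arg.append(arg_m)
        if cnt_m[n] > 0:
            ev = float(lse_m[n]) - np.log(cnt_m[n]) + m * lpo
            if ev > best_ev:
                best_ev, best_m, best_cps = ev, m, arg_m[n]
    return tuple(best_cps)


def enumerate_step_distribution(k: int, p_label: float, d: float) -> np.ndarray:
    """Observed-step pmf for k binding events by explicit enumeration.

    Every event is expanded into (monomer | dimer) x per-protomer label
    flags and all outcome combinations are summed — no convolution.
    """
    event_outcomes = []  # (n_labeled, probability)
    outcomes = []
    for flags in itertools.product([0, 1], repeat=1):  # monomer
        p = (1 - d)
        for f in flags:
            p *= p_label if f else (1 - p_label)
        outcomes.append((sum(flags), p))
    for flags in itertools.product([0, 1], repeat=2):  # dimer
        p = d
        for f in flags:
            p *= p_label if f else (1 - p_label)
        outcomes.append((sum(flags), p))
    event_outcomes = outcomes

    pmf = np.zeros(2 * k + 1)
    for combo in itertools.product(event_outcomes, repeat=k):
        total = sum(c[0] for c in combo)
        prob = np.prod([c[1] for c in combo]) if combo else 1.0
        pmf[total] += prob
    if k == 0:
        pmf = np.array([1.0])
    return pmf


def monte_carlo_two_step_fraction(d: float, p_label: float, n: int,
                                  rng: np.random.Generator) -> float:
    """Observed two-step fraction of visible protein-only spots, simulated."""
    dimer = rng.random(n) < d
    protomers = np.where(dimer, 2, 1)
    labels = rng.binomial(protomers, p_label)
    visible = labels >= 1
    return float(np.mean(labels[visible] == 2))


def grid_search_geometric(counts: np.ndarray, support: tuple[int, ...],
                          n_grid: int = 200001) -> float:
    """Truncated-geometric MLE by brute-force grid search over p."""
    n = np.asarray(support, float) - min(support)
    ps = np.linspace(1e-6, 1 - 1e-6, n_grid)
    ll = np.empty_like(ps)
    for i, p in enumerate(ps):
        w = p * (1 - p) ** n
        w /= w.sum()
        ll[i] = np.sum(counts * np.log(w))
    return float(ps[int(np.argmax(ll))])


def ols_by_hand(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Textbook least-squares formulas."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xbar, ybar = x.mean(), y.mean()
    slope = np.sum((x - xbar) * (y - ybar)) / np.sum((x - xbar) ** 2)
    intercept = ybar - slope * xbar
    yhat = intercept + slope * x
    ss_res = np.sum((y - yhat) ** 2)
    ss_tot = np.sum((y - ybar) ** 2)
    return float(slope), float(intercept), float(1 - ss_res / ss_tot)
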