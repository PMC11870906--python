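"""Survival estimation, group comparison and optimal-cutpoint selection.

Implements the statistical toolkit used to relate tumor shape to outcome:

* Kaplan–Meier product-limit estimation with log-log (Brookmeyer–Crowley
  style) confidence intervals for the median;
* the two-group log-rank test with the hypergeometric variance under ties;
* **maximally selected rank statistics**: scan every admissible cutpoint of
  a continuous index (e.g. 6-month solidity), take the maximum standardized
  log-rank statistic, and correct the inference for the selection.  The
  primary p-value is a seeded permutation p (index values permuted against
  the survival records); the Miller–Siegmund asymptotic approximation is
  reported alongside as a cross-check;
* Kendall's tau-b, the Friedman test and Cohen's kappa for the association
  and agreement analyses.

All estimators are written against plain numpy arrays; records are
``(time, event)`` pairs with ``time > 0`` days and ``event`` true when the
death/progression was observed (false = right-censored).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps

__all__ = [
    "SurvivalDataError",
    "KMCurve",
    "LogrankResult",
    "MaxstatResult",
    "kaplan_meier",
    "logrank_test",
    "maxstat_cutpoint",
    "kendall_tau_b",
    "friedman_test",
    "cohen_kappa",
]


class SurvivalDataError(ValueError):
    """Invalid or insufficient survival data."""


def _check_records(time, event, min_n: int = 1):
    t = np.asarray(time, dtype=float).ravel()
    e = np.asarray(event).ravel().astype(bool)
    if t.shape != e.shape:
        raise SurvivalDataError("time and event must have equal length")
    if len(t) < min_n:
        raise SurvivalDataError(f"need at least {min_n} records, got {len(t)}")
    if not np.all(np.isfinite(t)) or np.any(t <= 0):
        raise SurvivalDataError("survival times must be finite and positive")
    return t, e


# ---------------------------------------------------------------------------
# Kaplan–Meier


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve.

    ``times`` are the distinct observed times (events and censorings), so
    ``at_risk`` strictly decreases along the curve; ``survival`` drops only
    at event times.  ``median`` is the smallest time with S(t) <= 0.5 and is
    NaN when the curve never reaches 0.5; the same convention applies to the
    confidence limits of the median (NaN = open-ended).
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    n_censored: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    median: float
    median_ci: tuple[float, float]
    n: int

    def survival_at(self, t) -> np.ndarray:
        """Step-function evaluation S(t) (right-continuous)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])
        return out


def _qth_time(times: np.ndarray, surv: np.ndarray, q: float = 0.5) -> float:
    hit = np.nonzero(surv <= q + 1e-12)[0]
    return float(times[hit[0]]) if len(hit) else float("nan")


def kaplan_meier(time, event, alpha: float = 0.05) -> KMCurve:
    """Kaplan–Meier estimate with Greenwood/log-log confidence intervals.

    Censorings tied with events at the same time are counted as still at
    risk for those events (standard convention).  The median CI is read off
    the confidence band (log-log transform), open ends reported as NaN.
    """
    t, e = _check_records(time, event, min_n=1)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    n = len(t)

    utimes, start = np.unique(t, return_index=True)
    d = np.add.reduceat(e.astype(int), start)              # events per time
    c = np.add.reduceat((~e).astype(int), start)           # censorings per time
    at_risk = n - start

    with np.errstate(divide="ignore", invalid="ignore"):
        frac = 1.0 - d / at_risk
        surv = np.cumprod(frac)
        # Greenwood variance of log S
        gw = np.cumsum(np.where(at_risk > d, d / (at_risk * (at_risk - d)), np.inf))
        se_loglog = np.sqrt(gw) / np.abs(np.log(np.where(surv > 0, surv, np.nan)))
        z = _sps.norm.ppf(1 - alpha / 2)
        loglog = np.log(-np.log(np.where((surv > 0) & (surv < 1), surv, np.nan)))
        lo = np.exp(-np.exp(loglog + z * se_loglog))
        hi = np.exp(-np.exp(loglog - z * se_loglog))
    lo = np.where(surv >= 1.0, 1.0, np.where(surv <= 0.0, 0.0, lo))
    hi = np.where(surv >= 1.0, 1.0, np.where(surv <= 0.0, np.nan, hi))

    median = _qth_time(utimes, surv)
    median_ci = (_qth_time(utimes, lo), _qth_time(utimes, hi))
    return KMCurve(
        times=utimes, survival=surv, at_risk=at_risk, n_events=d, n_censored=c,
        ci_lower=lo, ci_upper=hi, median=median, median_ci=median_ci, n=n,
    )


# ---------------------------------------------------------------------------
# Log-rank


@dataclass(frozen=True)
class LogrankResult:
    statistic: float          # chi-square, 1 df
    p_value: float
    observed: tuple[float, float]
    expected: tuple[float, float]


def logrank_test(time_a, event_a, time_b, event_b) -> LogrankResult:
    """Two-group log-rank test (hypergeometric variance under ties)."""
    ta, ea = _check_records(time_a, event_a)
    tb, eb = _check_records(time_b, event_b)
    if ea.sum() + eb.sum() == 0:
        raise SurvivalDataError("log-rank test needs at least one event")
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    grp = np.concatenate([np.zeros(len(ta), bool), np.ones(len(tb), bool)])
    o_e, var, o1, e1 = _logrank_terms(t, e, grp)
    chi2 = o_e**2 / var if var > 0 else 0.0
    p = float(_sps.chi2.sf(chi2, df=1)) if var > 0 else 1.0
    d = float(e.sum())
    return LogrankResult(
        statistic=float(chi2), p_value=p,
        observed=(d - o1, o1), expected=(d - e1, e1),
    )


def _logrank_terms(t, e, grp_b):
    """(O-E, Var, O_b, E_b) for group ``grp_b`` of a two-group log-rank."""
    order = np.argsort(t, kind="stable")
    t, e, g = t[order], e[order], grp_b[order]
    utimes, start = np.unique(t, return_index=True)
    n_at = len(t) - start
    d = np.add.reduceat(e.astype(float), start)
    n1 = np.add.reduceat(g.astype(float), start)
    n1 = n1[::-1].cumsum()[::-1]          # at-risk in group b at each time
    d1 = np.add.reduceat((e & g).astype(float), start)
    ev = d > 0
    n_at, d, n1, d1 = n_at[ev], d[ev], n1[ev], d1[ev]
    exp1 = d * n1 / n_at
    with np.errstate(divide="ignore", invalid="ignore"):
        v = d * (n1 / n_at) * (1 - n1 / n_at) * (n_at - d) / np.maximum(n_at - 1, 1)
    return float((d1 - exp1).sum()), float(v.sum()), float(d1.sum()), float(exp1.sum())


# ---------------------------------------------------------------------------
# Maximally selected rank statistics


@dataclass(frozen=True)
class MaxstatResult:
    """Outcome of a maximally-selected-log-rank cutpoint search.

    ``p_value`` is the seeded permutation p-value of the maximal statistic
    (selection-corrected by construction).  ``p_value_naive`` is the
    chi-square p of the plain log-rank at the selected cutpoint — it ignores
    the selection and is reported only for comparison.  ``p_value_asymptotic``
    is the Miller–Siegmund approximation for the supremum of a standardized
    Brownian bridge over the admissible quantile band.
    """

    cutpoint: float
    statistic: float                     # max standardized |log-rank|
    p_value: float
    n_candidates: int
    p_value_naive: float
    p_value_asymptotic: float
    candidates: np.ndarray = field(repr=False)
    statistics: np.ndarray = field(repr=False)
    n_low: int = 0
    n_high: int = 0
    n_perm: int = 0
    seed: int | None = None


def _scan_stats(rank_rows: np.ndarray, block_id, n_at, d, e_sorted, cand_idx, n_ranks):
    """Standardized |log-rank| for each candidate split, batched over rows.

    ``rank_rows`` is (P, n): per row (the observed assignment or one
    permutation), the value-rank of each record in time-sorted order.
    Candidate j puts records with rank <= cand_idx[j] in the low group.
    Counting is done via a per-(block, rank) histogram followed by a suffix
    cumsum over time blocks (at-risk counts) and a cumsum over ranks
    (low-group membership), which keeps the work at O(P * m * n_ranks)
    numpy passes.  Returns (P, C).
    """
    P, n = rank_rows.shape
    m = len(n_at)
    ev = d > 0
    dd, nn = d[ev], n_at[ev]
    # per-block variance/expectation coefficients of the hypergeometric terms
    a_coef = dd / nn
    c_coef = dd * (nn - dd) / (np.maximum(nn - 1.0, 1.0) * nn * nn)

    flat = (np.arange(P)[:, None] * (m * n_ranks)
            + block_id[None, :] * n_ranks + rank_rows)
    cnt = np.bincount(flat.ravel(), minlength=P * m * n_ranks).astype(np.float64)
    cnt = cnt.reshape(P, m, n_ranks)
    at_risk_low = cnt[:, ::-1, :].cumsum(axis=1)[:, ::-1, :]
    n1 = at_risk_low.cumsum(axis=2)[:, ev, :][:, :, cand_idx]    # (P, me, C)

    ev_hist = np.zeros((P, n_ranks))
    rows = np.repeat(np.arange(P), int(e_sorted.sum()))
    np.add.at(ev_hist, (rows, rank_rows[:, e_sorted].ravel()), 1.0)
    o1 = ev_hist.cumsum(axis=1)[:, cand_idx]                     # (P, C)

    num = o1 - np.einsum("b,pbc->pc", a_coef, n1)
    var = np.einsum("b,pbc->pc", c_coef, n1 * (nn[None, :, None] - n1))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, np.abs(num) / np.sqrt(var), 0.0)
    return z


def _miller_siegmund_p(b: float, eps_lo: float, eps_hi: float) -> float:
    """Asymptotic p for max |standardized Brownian bridge| over a band."""
    if b <= 0:
        return 1.0
    phi = _sps.norm.pdf(b)
    p = 4.0 * phi / b + phi * (b - 1.0 / b) * np.log(
        (eps_hi * (1.0 - eps_lo)) / (eps_lo * (1.0 - eps_hi))
    )
    return float(min(1.0, max(0.0, p)))


def maxstat_cutpoint(
    values,
    time,
    event,
    *,
    min_prop: float = 0.1,
    n_perm: int = 2000,
    seed: int | np.random.Generator | None = None,
    perm_chunk: int = 256,
) -> MaxstatResult:
    """Optimal survival cutpoint by maximally selected rank statistics.

    Candidate cutpoints are midpoints between consecutive distinct sorted
    index values whose induced split leaves at least ``min_prop`` of the
    subjects on each side.  For each candidate the standardized log-rank
    statistic of the induced two-group comparison is computed; the cutpoint
    with the maximal |statistic| is selected (ties broken toward the smaller
    cutpoint).  The p-value permutes the index values against the survival
    records ``n_perm`` times with the given seed and uses the add-one
    estimator ``(1 + #{perm max >= observed max}) / (1 + n_perm)``.
    """
    x = np.asarray(values, dtype=float).ravel()
    t, e = _check_records(time, event, min_n=10)
    if len(x) != len(t):
        raise SurvivalDataError("index values and survival records must align")
    if not np.all(np.isfinite(x)):
        raise SurvivalDataError("index values must be finite")
    if not (0.0 < min_prop < 0.5):
        raise SurvivalDataError("min_prop must lie in (0, 0.5)")
    if e.sum() == 0:
        raise SurvivalDataError("cutpoint search needs at least one event")
    n = len(x)

    uvals, inv = np.unique(x, return_inverse=True)
    counts = np.bincount(inv)
    cum = np.cumsum(counts)                      # low-group size per distinct value
    m_min = int(np.ceil(min_prop * n))
    ok = (cum >= m_min) & (n - cum >= m_min)
    ok[-1] = False                               # splitting above the max is void
    cand_idx = np.nonzero(ok)[0]
    if len(cand_idx) == 0:
        raise SurvivalDataError(
            f"no admissible cutpoint: min_prop={min_prop} leaves no candidate "
            f"split among {len(uvals)} distinct values"
        )
    cuts = 0.5 * (uvals[cand_idx] + uvals[cand_idx + 1])

    order = np.argsort(t, kind="stable")
    ranks_sorted = inv[order]
    e_sorted = e[order]
    _, start = np.unique(t[order], return_index=True)
    n_at = (n - start).astype(float)
    d = np.add.reduceat(e_sorted.astype(float), start)
    m = len(start)
    block_id = np.repeat(np.arange(m), np.diff(np.append(start, n)))
    n_ranks = len(uvals)

    obs = _scan_stats(ranks_sorted[None, :], block_id, n_at, d, e_sorted,
                      cand_idx, n_ranks)[0]
    best = int(np.argmax(obs))                   # first max -> smaller cutpoint
    stat = float(obs[best])
    cutpoint = float(cuts[best])
    n_low = int(cum[cand_idx[best]])

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # cap the (perms x blocks x ranks) histogram at ~4e6 doubles per chunk
    perm_chunk = max(1, min(perm_chunk, int(4e6 / max(m * n_ranks, 1))))
    exceed = 0
    done = 0
    while done < n_perm:
        k = min(perm_chunk, n_perm - done)
        perms = rng.permuted(np.broadcast_to(ranks_sorted, (k, n)), axis=1)
        zmax = _scan_stats(perms, block_id, n_at, d, e_sorted,
                           cand_idx, n_ranks).max(axis=1)
        exceed += int(np.sum(zmax >= stat - 1e-12))
        done += k
    p_perm = (1.0 + exceed) / (1.0 + n_perm)

    p_naive = float(_sps.chi2.sf(stat**2, df=1))
    p_asym = _miller_siegmund_p(stat, min_prop, 1.0 - min_prop)
    seed_out = seed if isinstance(seed, (int, np.integer)) else None
    return MaxstatResult(
        cutpoint=cutpoint, statistic=stat, p_value=float(p_perm),
        n_candidates=len(cuts), p_value_naive=p_naive, p_value_asymptotic=p_asym,
        candidates=cuts, statistics=obs, n_low=n_low, n_high=n - n_low,
        n_perm=n_perm, seed=seed_out,
    )


# ---------------------------------------------------------------------------
# Association and agreement


def kendall_tau_b(x, y, *, exact_max_n: int = 8) -> tuple[float, float]:
    """Kendall's tau-b with tie correction.

    The p-value uses the normal approximation with the tie-corrected variance
    of ``C - D``; for n <= ``exact_max_n`` (and by default 8) an exact
    permutation enumeration is used instead.  Returns ``(nan, nan)`` with a
    warning when either variable is entirely tied.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("x and y must have equal length >= 3")
    n = len(x)
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        warnings.warn("Kendall tau undefined: a variable is entirely tied", stacklevel=2)
        return float("nan"), float("nan")

    def _s(v):
        return np.sign(v[:, None] - v[None, :])

    sx, sy = _s(x), _s(y)
    cd = float(np.sum(np.triu(sx * sy, k=1)))    # C - D
    n0 = n * (n - 1) / 2.0

    def _tie_sizes(v):
        return np.bincount(np.unique(v, return_inverse=True)[1]).astype(float)

    tx, ty = _tie_sizes(x), _tie_sizes(y)
    n1 = float(np.sum(tx * (tx - 1) / 2))
    n2 = float(np.sum(ty * (ty - 1) / 2))
    tau = cd / np.sqrt((n0 - n1) * (n0 - n2))

    if n <= exact_max_n:
        denom = np.sqrt((n0 - n1) * (n0 - n2))
        hits = total = 0
        for perm in itertools.permutations(range(n)):
            cd_p = float(np.sum(np.triu(sx * sy[np.ix_(perm, perm)], k=1)))
            hits += abs(cd_p / denom) >= abs(tau) - 1e-12
            total += 1
        return float(tau), hits / total

    # Kendall's tie-corrected asymptotic variance of C - D
    v0 = n * (n - 1) * (2 * n + 5)
    vt = float(np.sum(tx * (tx - 1) * (2 * tx + 5)))
    vu = float(np.sum(ty * (ty - 1) * (2 * ty + 5)))
    v1 = float(np.sum(tx * (tx - 1)) * np.sum(ty * (ty - 1))) / (2 * n * (n - 1))
    v2 = (
        float(np.sum(tx * (tx - 1) * (tx - 2)) * np.sum(ty * (ty - 1) * (ty - 2)))
        / (9 * n * (n - 1) * (n - 2))
    )
    var = (v0 - vt - vu) / 18.0 + v1 + v2
    z = cd / np.sqrt(var)
    return float(tau), float(2 * _sps.norm.sf(abs(z)))


def friedman_test(blocks) -> tuple[float, float]:
    """Friedman rank test across repeated measurements (rows = subjects).

    Rows containing NaN are dropped with a warning (complete blocks only);
    ties within a row receive average ranks and the statistic carries the
    standard tie correction.  Returns (chi2, p) with k-1 degrees of freedom.
    """
    b = np.asarray(blocks, dtype=float)
    if b.ndim != 2 or b.shape[1] < 3:
        raise ValueError("blocks must be 2D with at least 3 columns (timepoints)")
    complete = ~np.isnan(b).any(axis=1)
    if not complete.all():
        warnings.warn(
            f"dropping {int((~complete).sum())} incomplete rows from Friedman test",
            stacklevel=2,
        )
        b = b[complete]
    n, k = b.shape
    if n < 2:
        raise ValueError("Friedman test needs at least 2 complete rows")
    ranks = _sps.rankdata(b, axis=1)
    col_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(col_sums**2) - 3.0 * n * (k + 1)
    # tie correction
    ties = 0.0
    for row in b:
        sizes = np.bincount(np.unique(row, return_inverse=True)[1])
        ties += float(np.sum(sizes**3 - sizes))
    cf = 1.0 - ties / (n * k * (k**2 - 1))
    if cf <= 0:
        return 0.0, 1.0
    chi2 /= cf
    return float(chi2), float(_sps.chi2.sf(chi2, df=k - 1))


def cohen_kappa(ratings_a, ratings_b) -> float:
    """Cohen's kappa for two raters over a shared category set.

    kappa = (p_o - p_e) / (1 - p_e) with marginal-product expected agreement.
    Returns NaN with a warning when both raters are constant and identical
    (p_e = 1, chance-corrected agreement undefined).
    """
    a = np.asarray(ratings_a).ravel()
    bb = np.asarray(ratings_b).ravel()
    if a.shape != bb.shape or len(a) == 0:
        raise ValueError("ratings must be non-empty and of equal length")
    cats, a_i = np.unique(np.concatenate([a, bb]), return_inverse=True)
    ai, bi = a_i[: len(a)], a_i[len(a):]
    n = len(a)
    table = np.zeros((len(cats), len(cats)))
    np.add.at(table, (ai, bi), 1.0)
    p_o = np.trace(table) / n
    p_e = float(np.sum(table.sum(axis=1) * table.sum(axis=0))) / n**2
    if p_e >= 1.0 - 1e-15:
        warnings.warn("kappa undefined: both raters constant and identical", stacklevel=2)
        return float("nan")
    return float((p_o - p_e) / (1.0 - p_e))
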