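"""Cohort-level modelling: shape-index survival stratification.

:class:`ShapeSurvivalModel` dichotomises a continuous shape index (for
example 6-month solidity, or the baseline-minus-6-month solidity variation)
at the cutpoint selected by maximally selected rank statistics, and
summarises the resulting stratification: Kaplan–Meier curves and median
survival per group, the log-rank comparison at the selected cutpoint, and
both the selection-corrected (permutation) and naive p-values.

The model is built from the analysis-ready cohort table
(:func:`tumorshape.response.build_cohort_table`) and follows the familiar
model/results split: ``ShapeSurvivalModel(...).fit()`` returns a
:class:`ShapeSurvivalResults` carrying the estimates and a ``summary()``.

:func:`analyze_cohort` runs the full battery of the analysis — maxstat
stratification per index, Kendall's tau-b against RECIST status, the
Friedman test of shape over time — and returns a JSON-ready dictionary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import survival as ss
from .response import ResponseStatus

__all__ = ["ShapeSurvivalModel", "ShapeSurvivalResults", "analyze_cohort"]


class ShapeSurvivalModel:
    """Survival stratification of a cohort by a continuous shape index.

    Parameters
    ----------
    data : pandas.DataFrame
        One row per patient with the index column and survival columns.
        Rows with a missing index or missing survival data are dropped.
    index : str
        Column holding the stratifying shape index (default 6-month solidity).
    time, event : str
        Survival columns in days / event-observed flag.
    min_prop : float
        Minimum fraction of patients on each side of any candidate cutpoint.

    Examples
    --------
    >>> res = ShapeSurvivalModel(cohort, index="solidity_m6").fit(seed=7)
    >>> res.cutpoint, res.p_value            # doctest: +SKIP
    >>> print(res.summary())                 # doctest: +SKIP
    """

    def __init__(self, data: pd.DataFrame, index: str = "solidity_m6",
                 time: str = "os_days", event: str = "os_event",
                 min_prop: float = 0.1):
        for col in (index, time, event):
            if col not in data.columns:
                raise ValueError(f"cohort table has no column {col!r}")
        sub = data[[index, time, event]].dropna()
        self.index_name = index
        self.time_name = time
        self.event_name = event
        self.min_prop = float(min_prop)
        self.values = sub[index].to_numpy(dtype=float)
        self.time = sub[time].to_numpy(dtype=float)
        self.event = sub[event].to_numpy(dtype=bool)
        self.nobs = len(sub)
        self.n_dropped = len(data) - len(sub)

    @classmethod
    def from_cohort(cls, cohort: pd.DataFrame, **kwargs) -> "ShapeSurvivalModel":
        return cls(cohort, **kwargs)

    def fit(self, n_perm: int = 2000, seed: int | None = None) -> "ShapeSurvivalResults":
        """Select the optimal cutpoint and estimate the stratified curves."""
        ms = ss.maxstat_cutpoint(
            self.values, self.time, self.event,
            min_prop=self.min_prop, n_perm=n_perm, seed=seed,
        )
        low = self.values <= ms.cutpoint
        km_low = ss.kaplan_meier(self.time[low], self.event[low])
        km_high = ss.kaplan_meier(self.time[~low], self.event[~low])
        lr = ss.logrank_test(self.time[low], self.event[low],
                             self.time[~low], self.event[~low])
        return ShapeSurvivalResults(model=self, maxstat=ms, km_low=km_low,
                                    km_high=km_high, logrank=lr)


@dataclass
class ShapeSurvivalResults:
    """Fitted shape-based survival stratification."""

    model: ShapeSurvivalModel
    maxstat: ss.MaxstatResult
    km_low: ss.KMCurve
    km_high: ss.KMCurve
    logrank: ss.LogrankResult

    # -- convenience accessors ------------------------------------------------
    @property
    def cutpoint(self) -> float:
        return self.maxstat.cutpoint

    @property
    def statistic(self) -> float:
        return self.maxstat.statistic

    @property
    def p_value(self) -> float:
        """Selection-corrected permutation p-value of the maximal statistic."""
        return self.maxstat.p_value

    @property
    def p_value_naive(self) -> float:
        return self.maxstat.p_value_naive

    def km_frames(self) -> dict[str, pd.DataFrame]:
        from .io import km_curve_frame
        return {"low": km_curve_frame(self.km_low),
                "high": km_curve_frame(self.km_high)}

    def to_dict(self) -> dict:
        ms = self.maxstat

        def _median_block(km: ss.KMCurve) -> dict:
            return {"n": km.n, "median_days": km.median,
                    "median_ci_days": list(km.median_ci)}

        return {
            "index": self.model.index_name,
            "n": self.model.nobs,
            "n_dropped_missing": self.model.n_dropped,
            "maxstat": {
                "cutpoint": ms.cutpoint,
                "statistic": ms.statistic,
                "p_value_permutation": ms.p_value,
                "p_value_naive_logrank": ms.p_value_naive,
                "p_value_asymptotic": ms.p_value_asymptotic,
                "n_candidates": ms.n_candidates,
                "n_perm": ms.n_perm,
                "seed": ms.seed,
                "min_prop": self.model.min_prop,
            },
            "groups": {
                "low": _median_block(self.km_low),
                "high": _median_block(self.km_high),
            },
            "logrank_at_cutpoint": {
                "chi2": self.logrank.statistic,
                "p_value": self.logrank.p_value,
            },
        }

    def summary(self) -> str:
        """Human-readable fit summary."""
        ms = self.maxstat
        m = self.model

        def _fmt_median(km: ss.KMCurve) -> str:
            med = "NA" if np.isnan(km.median) else f"{km.median:.0f}"
            lo, hi = km.median_ci
            lo = "NA" if np.isnan(lo) else f"{lo:.0f}"
            hi = "NA" if np.isnan(hi) else f"{hi:.0f}"
            return f"{med} d (95% CI {lo}-{hi})"

        lines = [
            "Shape-index survival stratification (maximally selected rank statistics)",
            "=" * 74,
            f"index: {m.index_name:<28} n = {m.nobs}"
            + (f" ({m.n_dropped} rows dropped: missing data)" if m.n_dropped else ""),
            f"survival: {m.time_name} / {m.event_name}; "
            f"admissible band: min_prop = {m.min_prop}",
            "-" * 74,
            f"selected cutpoint        {ms.cutpoint:>10.4f}   "
            f"(of {ms.n_candidates} candidates)",
            f"max |standardized logrank| {ms.statistic:>8.3f}",
            f"p (permutation, B={ms.n_perm})  {ms.p_value:>8.4f}   <- selection-corrected",
            f"p (naive logrank at cut)   {ms.p_value_naive:>8.4f}   <- ignores selection",
            f"p (asymptotic band approx) {ms.p_value_asymptotic:>8.4f}",
            "-" * 74,
            f"low  group (index <= cut): n = {ms.n_low:<4} median OS "
            + _fmt_median(self.km_low),
            f"high group (index >  cut): n = {ms.n_high:<4} median OS "
            + _fmt_median(self.km_high),
            f"log-rank at cutpoint: chi2 = {self.logrank.statistic:.3f}, "
            f"p = {self.logrank.p_value:.4f}",
            "=" * 74,
        ]
        return "\n".join(lines)


_DEFAULT_INDICES = ("solidity_m6", "circularity_m6",
                    "solidity_variation", "circularity_variation")


def analyze_cohort(
    cohort: pd.DataFrame,
    indices=_DEFAULT_INDICES,
    *,
    time: str = "os_days",
    event: str = "os_event",
    min_prop: float = 0.1,
    n_perm: int = 2000,
    seed: int | None = None,
    holm: bool = True,
) -> dict:
    """Run the full shape-vs-outcome battery on a cohort table.

    Per index: maxstat stratification with KM per group.  Across indices:
    Kendall's tau-b against the ordinal RECIST status (CR < PR < SD < PD),
    the Friedman test of each shape descriptor across the three timepoints
    (complete cases), and optionally Holm-adjusted maxstat p-values (the
    unadjusted values are always reported).
    """
    results: dict = {
        "settings": {"time": time, "event": event, "min_prop": min_prop,
                     "n_perm": n_perm, "seed": seed, "indices": list(indices)},
        "n_patients": int(len(cohort)),
        "stratification": {},
        "kendall_vs_recist": {},
        "friedman_over_time": {},
    }
    rng = np.random.default_rng(seed)
    pvals = []
    for idx_name in indices:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        try:
            res = ShapeSurvivalModel(
                cohort, index=idx_name, time=time, event=event, min_prop=min_prop
            ).fit(n_perm=n_perm, seed=sub_seed)
        except (ss.SurvivalDataError, ValueError) as exc:
            results["stratification"][idx_name] = {"error": str(exc)}
            continue
        block = res.to_dict()
        block["maxstat"]["seed"] = sub_seed
        results["stratification"][idx_name] = block
        pvals.append((idx_name, res.p_value))

    if holm and pvals:
        order = sorted(pvals, key=lambda kv: kv[1])
        m = len(order)
        running = 0.0
        for rank, (name, p) in enumerate(order):
            running = max(running, min(1.0, (m - rank) * p))
            results["stratification"][name]["maxstat"]["p_value_holm"] = running

    if "recist_6m" in cohort.columns:
        recist = cohort["recist_6m"].map(
            lambda v: ResponseStatus(v).ordinal if isinstance(v, str) else np.nan
        )
        for idx_name in indices:
            if idx_name not in cohort.columns:
                continue
            pair = pd.DataFrame({"x": cohort[idx_name], "y": recist}).dropna()
            if len(pair) < 3 or pair["y"].nunique() < 2 or pair["x"].nunique() < 2:
                results["kendall_vs_recist"][idx_name] = {"error": "insufficient data"}
                continue
            tau, p = ss.kendall_tau_b(pair["x"], pair["y"])
            results["kendall_vs_recist"][idx_name] = {"tau_b": tau, "p_value": p,
                                                      "n": int(len(pair))}

    for feat in ("solidity", "circularity"):
        cols = [f"{feat}_baseline", f"{feat}_m3", f"{feat}_m6"]
        if all(c in cohort.columns for c in cols):
            blocks = cohort[cols].dropna().to_numpy()
            if len(blocks) >= 2:
                chi2, p = ss.friedman_test(blocks)
                results["friedman_over_time"][feat] = {
                    "chi2": chi2, "p_value": p, "n_complete": int(len(blocks))}
            else:
                results["friedman_over_time"][feat] = {"error": "fewer than 2 complete cases"}
    return results
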