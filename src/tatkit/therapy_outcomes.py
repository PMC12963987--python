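"""Tumor-growth and survival outcome analysis.

The primary endpoint is the time, in days, for a tumor to reach a
six-fold volume relative to day 1 (day-1 anchoring avoids the less
accurate day-0 caliper measurements).  Each mouse's normalized curve is
fit by an exponential model ``Y = 100 * exp(k (t - t1))`` or a one-phase
association model ``Y = Ymax - (Ymax - 100) exp(-k (t - t1))`` (both
constrained to ``Y(day 1) = 100``); the better model is selected by
small-sample-corrected AIC.  Fits with R^2 <= r2_min are excluded, as
are one-phase fits plateauing below the six-fold threshold — the latter
removes the best responders, a bias the report surfaces explicitly.
If a regression (nadir below the day-1 volume) precedes regrowth, only
the growth phase is fitted exponentially, re-anchored at the nadir.

The secondary endpoint is Kaplan-Meier survival with the humane
endpoint (tumor volume above a fixed threshold) as the event, compared
by pairwise Mantel-Cox log-rank tests with Bonferroni correction over a
configured comparison set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from scipy.optimize import curve_fit

from .core_io import StudyConfig

#: relative drop below the day-1 volume that counts as a real regression
#: (rather than measurement noise) and triggers growth-phase-only fitting
NADIR_TRIGGER = 0.95


@dataclass
class GrowthCurve:
    mouse: str
    group: str
    days: np.ndarray
    volumes_mm3: np.ndarray
    normalized_pct: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.volumes_mm3 = np.asarray(self.volumes_mm3, dtype=float)
        order = np.argsort(self.days)
        self.days = self.days[order]
        self.volumes_mm3 = self.volumes_mm3[order]
        if self.normalized_pct is not None:
            self.normalized_pct = np.asarray(self.normalized_pct, float)[order]


@dataclass
class GrowthFit:
    mouse: str
    group: str
    model: str                      # "exponential" | "one_phase_association"
    k_per_day: float
    ymax_pct: float | None          # one-phase plateau, % of day-1 volume
    r2: float
    included: bool
    exclusion_reason: str | None    # None | "r2_below_min" | "plateau_below_sixfold" | "non_convergent"
    time_to_sixfold_days: float | None   # elapsed days from the day-1 anchor
    growth_phase_start: float | None = None
    aicc_exponential: float | None = None
    aicc_one_phase: float | None = None


@dataclass
class SurvivalRecord:
    mouse: str
    group: str
    time_days: float
    event: bool    # True = humane endpoint reached; False = censored

    def __post_init__(self) -> None:
        if self.time_days <= 0:
            raise ValueError("survival time must be positive")


def survival_frame(records: Iterable[SurvivalRecord]) -> pd.DataFrame:
    """Tabulate :class:`SurvivalRecord` objects for the survival tests."""
    return pd.DataFrame(
        [{"mouse": r.mouse, "group": r.group, "time_days": r.time_days,
          "event": int(r.event)} for r in records]
    )


def normalize_growth(curve: GrowthCurve) -> GrowthCurve:
    """Express volumes as a percentage of the day-1 volume (= 100 %)."""
    at_day1 = np.isclose(curve.days, 1.0)
    if not at_day1.any():
        raise ValueError(f"mouse {curve.mouse}: no day-1 measurement; "
                         "cannot normalize")
    v1 = float(curve.volumes_mm3[at_day1][0])
    if v1 <= 0:
        raise ValueError(f"mouse {curve.mouse}: day-1 volume must be positive")
    return GrowthCurve(curve.mouse, curve.group, curve.days, curve.volumes_mm3,
                       normalized_pct=100.0 * curve.volumes_mm3 / v1)


def _aicc(ss_res: float, n: int, n_params: int) -> float:
    if ss_res <= 0:
        ss_res = 1e-300
    aic = n * np.log(ss_res / n) + 2 * n_params
    denom = n - n_params - 1
    return aic + (2 * n_params * (n_params + 1) / denom) if denom > 0 else np.inf


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        return 1.0 if np.allclose(y, yhat) else 0.0
    return 1.0 - float(np.sum((y - yhat) ** 2)) / sst


def fit_growth(curve: GrowthCurve, config: StudyConfig | None = None) -> GrowthFit:
    """Fit a normalized growth curve and derive the time to the six-fold
    volume endpoint, applying the inclusion/exclusion rules."""
    config = config or StudyConfig()
    if curve.normalized_pct is None:
        curve = normalize_growth(curve)
    t, y = curve.days, curve.normalized_pct
    use = t >= 1.0  # day 1 is the anchor; day 0 excluded from fitting
    t, y = t[use], y[use]
    s = config.sixfold_threshold
    target = 100.0 * s

    # regression followed by regrowth: fit only the growth phase
    i_min = int(np.argmin(y))
    if (y[i_min] < 100.0 * NADIR_TRIGGER and 0 < i_min < len(y) - 1
            and y[-1] > y[i_min]):
        t_n, y_n = t[i_min:], y[i_min:]
        y0 = float(y_n[0])

        def grow(tt, k):
            return y0 * np.exp(k * (tt - t_n[0]))

        try:
            (k,), _ = curve_fit(grow, t_n, y_n, p0=(0.2,), maxfev=10000)
        except RuntimeError:
            return GrowthFit(curve.mouse, curve.group, "exponential",
                             np.nan, None, np.nan, False, "non_convergent",
                             None, growth_phase_start=float(t_n[0]))
        r2 = _r2(y_n, grow(t_n, k))
        # elapsed days from the day-1 anchor, like the un-anchored fits
        t6 = (float(t_n[0] - 1.0 + np.log(target / y0) / k)
              if k > 0 and target > y0 else None)
        included = r2 > config.r2_min
        return GrowthFit(curve.mouse, curve.group, "exponential", float(k),
                         None, r2, included,
                         None if included else "r2_below_min",
                         t6 if included else None,
                         growth_phase_start=float(t_n[0]))

    if len(t) < 3:
        raise ValueError(f"mouse {curve.mouse}: need >= 3 points from day 1 on")

    def exponential(tt, k):
        return 100.0 * np.exp(k * (tt - 1.0))

    def one_phase(tt, ymax, k):
        return ymax - (ymax - 100.0) * np.exp(-k * (tt - 1.0))

    fits: dict[str, tuple] = {}
    k0 = max(float(np.polyfit(t, np.log(np.maximum(y, 1e-9) / 100.0), 1)[0]),
             1e-3)
    try:
        (k_exp,), _ = curve_fit(exponential, t, y, p0=(k0,), maxfev=10000)
        ss = float(np.sum((y - exponential(t, k_exp)) ** 2))
        fits["exponential"] = (ss, _aicc(ss, len(t), 1), (float(k_exp), None))
    except RuntimeError:
        pass
    try:
        p0 = (max(float(y.max()) * 1.2, 150.0), max(k0, 0.05))
        (ymax, k_op), _ = curve_fit(one_phase, t, y, p0=p0,
                                    bounds=([100.0, 1e-6], [np.inf, np.inf]),
                                    maxfev=10000)
        ss = float(np.sum((y - one_phase(t, ymax, k_op)) ** 2))
        fits["one_phase_association"] = (ss, _aicc(ss, len(t), 2),
                                         (float(k_op), float(ymax)))
    except RuntimeError:
        pass
    if not fits:
        return GrowthFit(curve.mouse, curve.group, "exponential", np.nan,
                         None, np.nan, False, "non_convergent", None)

    model = min(fits, key=lambda name: fits[name][1])
    _, _, (k, ymax) = fits[model]
    yhat = exponential(t, k) if model == "exponential" else one_phase(t, ymax, k)
    r2 = _r2(y, yhat)

    if model == "exponential":
        t6 = float(np.log(s) / k) if k > 0 else None
    else:
        t6 = (float(np.log((ymax - 100.0) / (ymax - target)) / k)
              if ymax > target and k > 0 else None)

    included, reason = True, None
    if not r2 > config.r2_min:
        included, reason = False, "r2_below_min"
    elif model == "one_phase_association" and ymax < target:
        included, reason = False, "plateau_below_sixfold"

    return GrowthFit(
        curve.mouse, curve.group, model, float(k),
        ymax if model == "one_phase_association" else None,
        r2, included, reason, t6 if included else None,
        aicc_exponential=fits.get("exponential", (None, None))[1]
        if "exponential" in fits else None,
        aicc_one_phase=fits.get("one_phase_association", (None, None))[1]
        if "one_phase_association" in fits else None,
    )


def growth_auc(curve: GrowthCurve) -> float:
    """Trapezoidal area under the normalized growth curve, %.days, from
    day 1 to the last observation."""
    if curve.normalized_pct is None:
        curve = normalize_growth(curve)
    use = curve.days >= 1.0
    t, y = curve.days[use], curve.normalized_pct[use]
    if len(t) < 2:
        raise ValueError("AUC needs at least two observations from day 1 on")
    return float(np.trapezoid(y, t))


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

def km_estimate(records: pd.DataFrame, group: str) -> dict:
    """Kaplan-Meier product-limit estimate for one group.

    ``records`` has columns ``group, time_days, event`` (event = 1 when
    the humane endpoint was reached, 0 when censored).  The median is
    the earliest time with S(t) <= 0.5, or ``None`` if never reached.
    """
    sub = records[records["group"] == group]
    if len(sub) == 0:
        raise ValueError(f"no records for group {group!r}")
    kmf = KaplanMeierFitter()
    kmf.fit(sub["time_days"], event_observed=sub["event"], label=group)
    median = float(kmf.median_survival_time_)
    surv = kmf.survival_function_
    return {
        "group": group,
        "n": int(len(sub)),
        "events": int(sub["event"].sum()),
        "times": surv.index.to_numpy(dtype=float),
        "survival": surv[group].to_numpy(dtype=float),
        "median_days": None if np.isinf(median) else median,
    }


def pairwise_logrank(records: pd.DataFrame,
                     comparisons: Sequence[tuple[str, str]],
                     alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise Mantel-Cox log-rank tests with Bonferroni correction.

    The Bonferroni divisor is the size of the configured comparison set
    (not all possible pairs).  Returns one row per comparison with the
    chi-square statistic, raw p, Bonferroni-adjusted p and the decision
    at the corrected level.
    """
    m = len(comparisons)
    if m == 0:
        raise ValueError("empty comparison set")
    rows = []
    for ga, gb in comparisons:
        a = records[records["group"] == ga]
        b = records[records["group"] == gb]
        if len(a) == 0 or len(b) == 0:
            raise ValueError(f"missing group in comparison {(ga, gb)}")
        res = logrank_test(a["time_days"], b["time_days"],
                           event_observed_A=a["event"],
                           event_observed_B=b["event"])
        p = float(res.p_value)
        rows.append({
            "group_a": ga, "group_b": gb,
            "chi2": float(res.test_statistic),
            "p_raw": p,
            "p_bonferroni": min(1.0, m * p),
            "alpha_corrected": alpha / m,
            "significant": p < alpha / m,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Rank-based group comparison
# ---------------------------------------------------------------------------

def kruskal_dunn(values_by_group: dict[str, Iterable[float]],
                 comparisons: Sequence[tuple[str, str]] | None = None) -> dict:
    """Kruskal-Wallis H test with Dunn's pairwise z-tests.

    The H statistic carries the standard tie correction.  Dunn z-tests
    run on the configured comparison set (default: all pairs), two-sided,
    Bonferroni-adjusted over that set.
    """
    groups = list(values_by_group)
    arrays = {g: np.asarray(list(values_by_group[g]), dtype=float)
              for g in groups}
    if len(groups) < 2 or any(len(v) < 2 for v in arrays.values()):
        raise ValueError("need >= 2 groups with >= 2 values each")
    pooled = np.concatenate([arrays[g] for g in groups])
    if np.ptp(pooled) == 0:
        h_stat, p_kw = 0.0, 1.0
    else:
        h_stat, p_kw = stats.kruskal(*[arrays[g] for g in groups])
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    mean_ranks, sizes, start = {}, {}, 0
    for g in groups:
        n = len(arrays[g])
        mean_ranks[g] = float(ranks[start:start + n].mean())
        sizes[g] = n
        start += n
    # tie-corrected variance term for Dunn's z
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts ** 3 - counts))
    var_term = (n_total * (n_total + 1) / 12.0
                - tie_sum / (12.0 * (n_total - 1)))
    if comparisons is None:
        comparisons = [(groups[i], groups[j])
                       for i in range(len(groups))
                       for j in range(i + 1, len(groups))]
    m = len(comparisons)
    pairwise = []
    for ga, gb in comparisons:
        se = np.sqrt(var_term * (1.0 / sizes[ga] + 1.0 / sizes[gb]))
        if se == 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[ga] - mean_ranks[gb]) / se
            p = 2.0 * stats.norm.sf(abs(z))
        pairwise.append({"pair": (ga, gb), "z": float(z),
                         "p_raw": float(p),
                         "p_adj": min(1.0, m * float(p))})
    return {"H": float(h_stat), "p": float(p_kw), "pairwise": pairwise}


__all__ = [
    "GrowthCurve",
    "GrowthFit",
    "SurvivalRecord",
    "survival_frame",
    "fit_growth",
    "growth_auc",
    "km_estimate",
    "kruskal_dunn",
    "normalize_growth",
    "pairwise_logrank",
]
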