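"""Surrogate-tracer dosimetry for alpha-emitter therapy per tumor sub-volume.

An imaging surrogate (e.g. In-111) on the same targeting vector provides
measured time-activity curves (TACs).  Assuming identical biological
retention, the surrogate curve is re-decayed with the therapeutic
nuclide's decay constant, time-integrated (linear rise, trapezoid over
observations, analytic physical-decay tail), and converted to an
absorbed-dose coefficient in Gy per kBq injected using the decay chain's
locally absorbed energy per parent decay at secular equilibrium.  A
relative autoradiography intensity map scaled to the VOI mean dose gives
a pixel-wise dose-distribution map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .biodistribution import DecayChain, Nuclide
from .core_io import GrayImage

MEV_TO_J = 1.602176634e-13
SECONDS_PER_DAY = 86400.0


@dataclass
class TimeActivityCurve:
    """Activity concentration (%IA/mL) in a named VOI vs. days p.i."""

    voi: str
    times_days: np.ndarray
    pct_ia_per_ml: np.ndarray
    nuclide: Nuclide

    def __post_init__(self) -> None:
        self.times_days = np.asarray(self.times_days, dtype=float)
        self.pct_ia_per_ml = np.asarray(self.pct_ia_per_ml, dtype=float)
        if self.times_days.ndim != 1 or len(self.times_days) == 0:
            raise ValueError("need at least one time point")
        if np.any(np.diff(self.times_days) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.times_days < 0):
            raise ValueError("times must be non-negative")
        if np.any(self.pct_ia_per_ml < 0):
            raise ValueError("activity concentrations must be non-negative")


@dataclass
class VoiSegmentation:
    """Partition of the tumor into target-positive and -negative volumes."""

    caix_pos_ml: float
    caix_neg_ml: float
    threshold_rule: str

    def __post_init__(self) -> None:
        if self.caix_pos_ml < 0 or self.caix_neg_ml < 0:
            raise ValueError("volumes must be non-negative")

    @property
    def total_ml(self) -> float:
        return self.caix_pos_ml + self.caix_neg_ml

    @property
    def pos_fraction_pct(self) -> float:
        return 100.0 * self.caix_pos_ml / self.total_ml


def segment_voi(activity_map: np.ndarray, voxel_volume_ml: float,
                threshold: float, mode: str = "fraction_of_max") -> VoiSegmentation:
    """Threshold an activity-concentration map into positive/negative VOIs.

    ``mode`` is ``"fraction_of_max"`` (threshold as a fraction of the map
    maximum) or ``"absolute"`` (threshold in the map's own units).
    """
    arr = np.asarray(activity_map, dtype=float)
    if mode == "fraction_of_max":
        cut = threshold * arr.max()
    elif mode == "absolute":
        cut = threshold
    else:
        raise ValueError(f"unknown segmentation mode {mode!r}")
    pos = int(np.count_nonzero(arr > cut))
    return VoiSegmentation(
        caix_pos_ml=pos * voxel_volume_ml,
        caix_neg_ml=(arr.size - pos) * voxel_volume_ml,
        threshold_rule=f"{mode}:{threshold}",
    )


@dataclass
class DoseEstimate:
    voi: str
    dose_coefficient_gy_per_kbq: float
    total_dose_gy: float
    administered_kbq: float
    tail_fraction: float

    def __post_init__(self) -> None:
        if not 0 <= self.tail_fraction <= 1:
            raise ValueError("tail_fraction must lie in [0, 1]")


@dataclass
class DoseMap:
    dose_gy: np.ndarray
    voi_mean_dose_gy: float
    intensity_sum: float


def translate_surrogate(tac: TimeActivityCurve, target: Nuclide) -> TimeActivityCurve:
    """Predict the therapeutic nuclide's TAC from the surrogate's.

    Biological retention is assumed identical: each point is
    decay-corrected with the surrogate's physical decay constant and
    re-decayed with the target's,

        A_target(t) = A_surrogate(t) * exp((lambda_s - lambda_t) * t).
    """
    lam_in = tac.nuclide.decay_constant
    lam_out = target.decay_constant
    values = tac.pct_ia_per_ml * np.exp((lam_in - lam_out) * tac.times_days)
    if np.any(values < 0):
        raise ValueError("negative activity in translated curve")
    return TimeActivityCurve(voi=tac.voi, times_days=tac.times_days.copy(),
                             pct_ia_per_ml=values, nuclide=target)


def integrate_tac(tac: TimeActivityCurve, rise_model: str = "linear",
                  tail_model: str = "phys",
                  washout_rate_per_day: float = 0.0) -> tuple[float, float]:
    """Time-integrated activity concentration, in %IA·day/mL per unit
    injected activity, with the fraction contributed by the tail.

    Segments:

    * rise from injection to the first observation — ``"linear"`` (from
      zero) or ``"flat"`` (first value held constant);
    * trapezoid across the observations;
    * analytic tail beyond the last observation — ``"phys"`` freezes
      biological retention and decays physically
      (``A_last / lambda_phys``), ``"washout"`` adds a biological
      clearance rate (``A_last / (lambda_phys + k_washout)``).

    Returns ``(integral, tail_fraction)``.
    """
    t = tac.times_days
    a = tac.pct_ia_per_ml
    if rise_model == "linear":
        rise = 0.5 * a[0] * t[0]
    elif rise_model == "flat":
        rise = a[0] * t[0]
    else:
        raise ValueError(f"unknown rise model {rise_model!r}")
    body = float(np.trapezoid(a, t)) if len(t) > 1 else 0.0
    lam_eff = tac.nuclide.decay_constant
    if tail_model == "washout":
        lam_eff = lam_eff + washout_rate_per_day
    elif tail_model != "phys":
        raise ValueError(f"unknown tail model {tail_model!r}")
    if lam_eff <= 0:
        raise ValueError("tail integral diverges: effective decay rate is zero")
    tail = a[-1] / lam_eff
    total = rise + body + tail
    tail_fraction = tail / total if total > 0 else 0.0
    return float(total), float(tail_fraction)


def dose_coefficient(integral_pct_ia_day_per_ml: float, chain: DecayChain,
                     density_g_per_ml: float = 1.0,
                     exclude_after: str | None = None) -> float:
    """Absorbed-dose coefficient in Gy per kBq injected.

    ``integral_pct_ia_day_per_ml`` is the time-integrated activity
    concentration per unit injected activity.  Per kBq injected it
    corresponds to ``integral/100`` kBq·day/mL of parent decays, which
    are multiplied by the chain's locally absorbed energy per parent
    decay (alpha + electron, branching-weighted, secular equilibrium)
    and divided by the voxel mass.
    """
    if integral_pct_ia_day_per_ml < 0:
        raise ValueError("time-integrated activity must be non-negative")
    energy_mev = chain.energy_per_parent_decay_mev(exclude_after=exclude_after)
    if energy_mev <= 0:
        raise ValueError("decay chain carries no absorbed-energy data")
    decays_per_ml = (integral_pct_ia_day_per_ml / 100.0) * 1000.0 * SECONDS_PER_DAY
    joules_per_ml = decays_per_ml * energy_mev * MEV_TO_J
    kg_per_ml = density_g_per_ml * 1e-3
    return float(joules_per_ml / kg_per_ml)


def total_dose(coefficient_gy_per_kbq: float, administered_kbq: float,
               voi: str = "", tail_fraction: float = 0.0) -> DoseEstimate:
    """Total absorbed dose for an administered activity (product identity)."""
    return DoseEstimate(
        voi=voi,
        dose_coefficient_gy_per_kbq=float(coefficient_gy_per_kbq),
        total_dose_gy=float(coefficient_gy_per_kbq * administered_kbq),
        administered_kbq=float(administered_kbq),
        tail_fraction=float(tail_fraction),
    )


def dose_map(autorad: GrayImage, voi_mean_dose_gy: float,
             mask: GrayImage | None = None) -> DoseMap:
    """Scale a relative autoradiography intensity map to absolute dose.

    Each pixel's dose is ``voi_mean_dose * intensity / mean(intensity
    inside mask)``, so the mask-mean of the map equals the VOI mean dose.
    """
    intensity = autorad.pixels
    if mask is not None:
        if mask.shape != autorad.shape:
            raise ValueError("mask shape must match the autoradiograph")
        inside = mask.pixels > 0
        if not inside.any():
            raise ValueError("mask selects no pixels")
    else:
        inside = np.ones_like(intensity, dtype=bool)
    mean_inside = float(intensity[inside].mean())
    if mean_inside <= 0:
        raise ValueError("mean intensity inside the VOI is zero")
    dose = voi_mean_dose_gy * intensity / mean_inside
    return DoseMap(dose_gy=dose, voi_mean_dose_gy=float(voi_mean_dose_gy),
                   intensity_sum=float(intensity[inside].sum()))


__all__ = [
    "DoseEstimate",
    "DoseMap",
    "TimeActivityCurve",
    "VoiSegmentation",
    "dose_coefficient",
    "dose_map",
    "integrate_tac",
    "segment_voi",
    "total_dose",
    "translate_surrogate",
]
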