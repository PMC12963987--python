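"""Synthetic-data generators with known ground truth for every pipeline input.

Each generator is a pure function of a truth object and a seed, so
every analysis stage can be exercised — and its estimators validated by
parameter recovery — without any measured data.  Noise models follow
the physics of the corresponding measurement: Poisson counting noise
for gamma-counter assays, multiplicative lognormal noise for SPECT
activity quantification and caliper volumes (both positive quantities
with errors proportional to the signal), and additive Gaussian gray
noise for the imaging pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .binding_assays import CompetitionAssay, SerialDilutionAssay
from .biodistribution import Nuclide
from .core_io import GrayImage
from .dosimetry import TimeActivityCurve
from .therapy_outcomes import GrowthCurve, SurvivalRecord

#: serial-dilution range used for the immunoreactivity assay, cells/mL
LINDMO_CELL_CONCS = np.geomspace(1.1e6, 1.7e7, 8)
#: competitor concentrations for the one-site competition assay, nM
COMPETITION_CONCS = np.geomspace(0.03, 10000.0, 12)


# ---------------------------------------------------------------------------
# Truth objects
# ---------------------------------------------------------------------------

@dataclass
class BindingTruth:
    """Generating parameters for the binding assays."""

    irf: float = 0.94                 # immunoreactive fraction, (0, 1]
    affinity_scale: float = 3.0e6     # cells/mL at half-maximal binding
    ic50: float = 3.6                 # nM
    top: float = 100.0                # % binding at zero competitor
    bottom: float = 0.0               # % binding at infinite competitor
    counting_noise: str = "none"      # "none" | "poisson"
    total_cpm: float = 46729.0        # tracer added per well

    def __post_init__(self) -> None:
        if not 0 < self.irf <= 1:
            raise ValueError("irf must lie in (0, 1]")
        if self.ic50 <= 0:
            raise ValueError("ic50 must be positive")
        if self.counting_noise not in ("none", "poisson"):
            raise ValueError("counting_noise must be 'none' or 'poisson'")


@dataclass
class VoiKinetics:
    label: str
    a_peak: float        # %IA/mL scale of the uptake-retention curve
    k_uptake: float      # 1/day
    k_bio: float         # 1/day biological clearance

    def __post_init__(self) -> None:
        if self.a_peak < 0 or self.k_uptake < 0 or self.k_bio < 0:
            raise ValueError("kinetic parameters must be non-negative")


@dataclass
class TacTruth:
    """Generating parameters for per-VOI time-activity curves.

    Defaults bracket the measured day-5 uptake contrast between
    antigen-positive and antigen-negative tumor sub-volumes under the
    four-scan schedule (days 1, 2, 3 and 5 post injection).
    """

    vois: list[VoiKinetics] = field(default_factory=lambda: [
        VoiKinetics("CAIX+", a_peak=95.0, k_uptake=0.9, k_bio=0.02),
        VoiKinetics("CAIX-", a_peak=18.0, k_uptake=0.9, k_bio=0.02),
    ])
    nuclide: Nuclide = field(default_factory=lambda: Nuclide("In-111", 2.8047))
    sample_days: list[float] = field(default_factory=lambda: [1.0, 2.0, 3.0, 5.0])
    noise_cv: float = 0.0    # lognormal coefficient of variation

    def __post_init__(self) -> None:
        if len(self.sample_days) == 0:
            raise ValueError("sample_days must be non-empty")
        if np.any(np.diff(self.sample_days) <= 0):
            raise ValueError("sample_days must be increasing")


@dataclass
class ImageTruth:
    """Planted-structure image-pair parameters.

    A shared smooth field (Gaussian blobs, mimicking co-localized
    antigen expression and tracer signal) appears in both channels with
    independent additive gray noise on top.
    """

    grid: int = 200
    n_blobs: int = 12
    blob_radius: float = 18.0       # pixels
    shared_weight: float = 1.0      # amplitude multiplier of the shared field
    fluor_gain: float = 0.8         # shared-field gain in the IF channel
    noise_sd: float = 0.1           # additive gray noise, both channels
    peak_gray: float = 50000.0      # shared-field peak before noise (16-bit)

    def __post_init__(self) -> None:
        if self.shared_weight < 0 or self.noise_sd < 0:
            raise ValueError("weights and noise sd must be non-negative")


@dataclass
class GroupTruth:
    name: str
    n: int = 10
    doubling_days: float = 3.0
    plateau_pct: float | None = None   # one-phase plateau, % of day-1 volume
    cv_noise: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.doubling_days <= 0:
            raise ValueError("doubling time must be positive")


@dataclass
class CohortTruth:
    """Cohort generating parameters for the efficacy study layout:
    10 mice/group starting near 67 mm^3, followed for six weeks, with
    the humane endpoint at a 2.0 cm^3 tumor volume."""

    groups: list[GroupTruth] = field(default_factory=lambda: [
        GroupTruth("PBS", doubling_days=2.2, cv_noise=0.15),
        GroupTruth("TAT+ICI", doubling_days=4.5, cv_noise=0.15),
    ])
    start_volume_mm3: float = 67.0
    hep_volume_mm3: float = 2000.0
    follow_up_days: float = 42.0
    measure_every_days: float = 2.0


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def gen_lindmo(truth: BindingTruth,
               cell_concs: np.ndarray | None = None,
               seed: int = 0) -> SerialDilutionAssay:
    """One-site serial-dilution binding data.

    Bound fraction ``B(c) = irf * c / (c + affinity_scale)``; with
    ``counting_noise="poisson"`` the bound counts are Poisson draws
    around the noise-free expectation.
    """
    c = np.asarray(LINDMO_CELL_CONCS if cell_concs is None else cell_concs,
                   dtype=float)
    if len(c) < 4 or np.any(c <= 0):
        raise ValueError("need >= 4 positive cell concentrations")
    bound_frac = truth.irf * c / (c + truth.affinity_scale)
    bound = truth.total_cpm * bound_frac
    if truth.counting_noise == "poisson":
        rng = np.random.default_rng(seed)
        bound = rng.poisson(bound).astype(float)
    return SerialDilutionAssay(cell_conc=c, bound_cpm=bound,
                               total_cpm=truth.total_cpm, background_cpm=0.0)


def competition_model(c: np.ndarray, truth: BindingTruth) -> np.ndarray:
    """Un-normalized one-site competition curve in percent binding."""
    return truth.bottom + (truth.top - truth.bottom) / (1.0 + c / truth.ic50)


def gen_competition(truth: BindingTruth,
                    concs: np.ndarray | None = None,
                    seed: int = 0,
                    cpm_per_percent: float = 500.0) -> CompetitionAssay:
    """One-site competition data over increasing competitor concentrations."""
    c = np.asarray(COMPETITION_CONCS if concs is None else concs, dtype=float)
    if np.any(c <= 0) or np.any(np.diff(c) <= 0):
        raise ValueError("concentrations must be positive and increasing")
    y = competition_model(c, truth)
    cpm = y * cpm_per_percent
    if truth.counting_noise == "poisson":
        rng = np.random.default_rng(seed)
        cpm = rng.poisson(cpm).astype(float)
    return CompetitionAssay(competitor_conc=c, cell_bound_cpm=cpm)


def tac_model(t: np.ndarray, voi: VoiKinetics, nuclide: Nuclide) -> np.ndarray:
    """Uptake-and-retention model with physical decay:
    ``A(t) = a_peak (1 - e^{-ku t}) e^{-kb t} e^{-lambda t}``."""
    t = np.asarray(t, dtype=float)
    lam = nuclide.decay_constant
    return (voi.a_peak * (1.0 - np.exp(-voi.k_uptake * t))
            * np.exp(-(voi.k_bio + lam) * t))


def tac_integral_analytic(voi: VoiKinetics, nuclide: Nuclide) -> float:
    """Closed-form 0..infinity integral of :func:`tac_model`, %IA.day/mL."""
    lam = nuclide.decay_constant
    return voi.a_peak * (1.0 / (voi.k_bio + lam)
                         - 1.0 / (voi.k_uptake + voi.k_bio + lam))


def gen_tac(truth: TacTruth, seed: int = 0) -> list[TimeActivityCurve]:
    """Per-VOI time-activity curves, optionally with lognormal noise."""
    rng = np.random.default_rng(seed)
    t = np.asarray(truth.sample_days, dtype=float)
    curves = []
    for voi in truth.vois:
        a = tac_model(t, voi, truth.nuclide)
        if truth.noise_cv > 0:
            sigma = np.sqrt(np.log(1.0 + truth.noise_cv ** 2))
            a = a * rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma,
                                  size=a.shape)
        curves.append(TimeActivityCurve(voi=voi.label, times_days=t,
                                        pct_ia_per_ml=a,
                                        nuclide=truth.nuclide))
    return curves


def gen_image_pair(truth: ImageTruth, seed: int = 0
                   ) -> tuple[GrayImage, GrayImage, np.ndarray]:
    """A correlated (autoradiograph, IF) pair with a planted shared field.

    Returns ``(autorad, fluor, shared_field)``.  The IF channel is
    ``fluor_gain * shared + noise``; the autoradiograph is stored
    photographically inverted (signal dark), as phosphor-imager exports
    are, so downstream registration re-inverts it.  The planted field is
    returned for oracle tests of the block-correlation statistic.
    """
    rng = np.random.default_rng(seed)
    g = truth.grid
    yy, xx = np.mgrid[0:g, 0:g]
    shared = np.zeros((g, g), dtype=float)
    centers = rng.uniform(0, g, size=(truth.n_blobs, 2))
    for cy, cx in centers:
        shared += np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2)
                         / (2.0 * truth.blob_radius ** 2))
    if shared.max() > 0:
        shared *= truth.peak_gray / shared.max()
    shared *= truth.shared_weight
    noise_a = rng.normal(0.0, truth.noise_sd * truth.peak_gray, size=(g, g))
    noise_f = rng.normal(0.0, truth.noise_sd * truth.peak_gray, size=(g, g))
    max_gray = float(2 ** 16 - 1)
    autorad_signal = np.clip(shared + noise_a, 0.0, max_gray)
    autorad = max_gray - autorad_signal  # inverted phosphor-imager export
    fluor = np.clip(truth.fluor_gain * shared + noise_f, 0.0, max_gray)
    return (GrayImage(autorad, bit_depth=16),
            GrayImage(fluor, bit_depth=16),
            shared)


def gen_cohort(truth: CohortTruth, seed: int = 0
               ) -> tuple[list[GrowthCurve], list[SurvivalRecord]]:
    """Longitudinal tumor volumes and humane-endpoint event times.

    Exponential growth ``V(t) = V0 * 2^{t/doubling}`` (or a one-phase
    saturating curve when a plateau is set), multiplicative lognormal
    noise at the given CV, measurements on days 0, 1, then every
    ``measure_every_days`` until follow-up.  The survival event is the
    first measured day with volume above the humane-endpoint threshold;
    mice never crossing it are censored at follow-up.
    """
    rng = np.random.default_rng(seed)
    days = np.unique(np.concatenate([
        [0.0, 1.0],
        np.arange(1.0, truth.follow_up_days + 1e-9, truth.measure_every_days),
        [truth.follow_up_days],
    ]))
    curves: list[GrowthCurve] = []
    records: list[SurvivalRecord] = []
    for gt in truth.groups:
        k = np.log(2.0) / gt.doubling_days
        for i in range(gt.n):
            v0 = truth.start_volume_mm3
            if gt.plateau_pct is None:
                v = v0 * np.exp(k * days)
            else:
                p = gt.plateau_pct
                # one-phase association matched to the initial growth rate
                k1 = k * 100.0 / (p - 100.0)
                v = v0 * (p - (p - 100.0) * np.exp(-k1 * days)) / 100.0
            if gt.cv_noise > 0:
                sigma = np.sqrt(np.log(1.0 + gt.cv_noise ** 2))
                v = v * rng.lognormal(-0.5 * sigma ** 2, sigma, size=v.shape)
            mouse = f"{gt.name}-{i + 1:02d}"
            curves.append(GrowthCurve(mouse=mouse, group=gt.name,
                                      days=days.copy(), volumes_mm3=v))
            crossed = np.where(v > truth.hep_volume_mm3)[0]
            crossed = crossed[days[crossed] > 0]
            if crossed.size:
                records.append(SurvivalRecord(mouse, gt.name,
                                              float(days[crossed[0]]), True))
            else:
                records.append(SurvivalRecord(mouse, gt.name,
                                              float(truth.follow_up_days),
                                              False))
    return curves, records


__all__ = [
    "BindingTruth",
    "COMPETITION_CONCS",
    "CohortTruth",
    "GroupTruth",
    "ImageTruth",
    "LINDMO_CELL_CONCS",
    "TacTruth",
    "VoiKinetics",
    "competition_model",
    "gen_cohort",
    "gen_competition",
    "gen_image_pair",
    "gen_lindmo",
    "gen_tac",
    "tac_integral_analytic",
    "tac_model",
]
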