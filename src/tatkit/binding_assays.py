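"""Radiotracer binding estimators from gamma-counter assay tables.

Three estimators are provided:

* :func:`fit_lindmo` — the immunoreactive fraction (IRF) by linear
  extrapolation to infinite antigen excess.  The inverse of the specific
  cell-bound fraction is regressed on the inverse of the cell
  concentration; the IRF is the reciprocal of the y-intercept.
* :func:`fit_ic50` — the half-maximal inhibitory concentration from a
  one-site competition curve (unit Hill slope), after normalizing the
  lowest-competitor condition to 100 %.
* :func:`partition_fractions` — membrane-bound vs. internalized
  partition of cell-associated activity, with an optional blocked/
  unblocked ratio as a specificity readout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .core_io import AssayTable


@dataclass
class SerialDilutionAssay:
    """Serial-dilution binding assay for the Lindmo IRF estimate."""

    cell_conc: np.ndarray          # cells/mL, strictly positive
    bound_cpm: np.ndarray          # cpm bound per condition
    total_cpm: float               # cpm added per well
    background_cpm: float = 0.0

    def __post_init__(self) -> None:
        self.cell_conc = np.asarray(self.cell_conc, dtype=float)
        self.bound_cpm = np.asarray(self.bound_cpm, dtype=float)
        if np.any(self.cell_conc <= 0):
            raise ValueError("cell concentrations must be strictly positive")
        if np.any(self.bound_cpm > self.total_cpm):
            raise ValueError("bound cpm exceeds total added cpm")

    @classmethod
    def from_table(cls, table: AssayTable) -> "SerialDilutionAssay":
        df = table.data
        return cls(
            cell_conc=df["cell_conc"].to_numpy(),
            bound_cpm=df["bound_cpm"].to_numpy(),
            total_cpm=float(df["total_cpm"].iloc[0]),
            background_cpm=float(df["background_cpm"].iloc[0]),
        )


@dataclass
class IrfEstimate:
    irf: float                     # fraction; 1/intercept
    intercept: float
    slope: float                   # mL/cells
    r2: float
    flagged: bool = False          # irf > 1 or non-positive intercept
    flag_reason: str | None = None


@dataclass
class CompetitionAssay:
    """Competition binding assay: unlabeled competitor vs. fixed tracer."""

    competitor_conc: np.ndarray    # nM, increasing
    cell_bound_cpm: np.ndarray

    def __post_init__(self) -> None:
        self.competitor_conc = np.asarray(self.competitor_conc, dtype=float)
        self.cell_bound_cpm = np.asarray(self.cell_bound_cpm, dtype=float)
        if len(self.competitor_conc) < 5:
            raise ValueError("need >= 5 concentration levels for an IC50 fit")
        if np.any(self.competitor_conc <= 0):
            raise ValueError("competitor concentrations must be positive")

    @classmethod
    def from_table(cls, table: AssayTable) -> "CompetitionAssay":
        df = table.data.sort_values("conc_nM")
        return cls(df["conc_nM"].to_numpy(), df["bound_cpm"].to_numpy())


@dataclass
class Ic50Estimate:
    ic50: float                    # nM
    top: float                     # % of normalized binding
    bottom: float                  # fixed at 0
    r2: float
    extrapolated: bool = False     # ic50 outside the tested range
    top_flagged: bool = False      # top deviates > 20% from 100
    unreliable: bool = False       # no descending limb in the data


@dataclass
class FractionPartition:
    membrane_cpm: float
    internalized_cpm: float
    membrane_fraction: float
    internalized_fraction: float
    blocked_ratio: float | None = None


def fit_lindmo(assay: SerialDilutionAssay) -> IrfEstimate:
    """Estimate the immunoreactive fraction by the Lindmo inverse plot.

    Ordinary (unweighted) least squares of ``total/(bound - background)``
    on ``1/cell_conc``; the IRF is ``1/intercept``.  Under the one-site
    model ``B(c) = IRF * c / (c + K)`` the plot is exactly linear with
    intercept ``1/IRF``, so noise-free data are recovered to numerical
    precision.

    Raises
    ------
    ValueError
        If any condition has non-positive specific binding after
        background subtraction (the inverse plot is undefined there);
        the offending row is named rather than silently clipped.
    """
    if len(assay.cell_conc) < 4:
        raise ValueError("Lindmo fit requires >= 4 dilution levels")
    specific = assay.bound_cpm - assay.background_cpm
    bad = np.where(specific <= 0)[0]
    if bad.size:
        raise ValueError(
            f"non-positive specific binding after background subtraction "
            f"in row(s) {bad.tolist()}"
        )
    x = 1.0 / assay.cell_conc
    y = assay.total_cpm / specific
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / sst if sst > 0 else 1.0
    flagged, reason = False, None
    if intercept <= 0:
        flagged, reason = True, "non-positive intercept"
        irf = np.inf
    else:
        irf = 1.0 / intercept
        if irf > 1:
            flagged, reason = True, "irf > 1"
    return IrfEstimate(irf=float(irf), intercept=float(intercept),
                       slope=float(slope), r2=r2,
                       flagged=flagged, flag_reason=reason)


def _one_site(c: np.ndarray, top: float, ic50: float) -> np.ndarray:
    # one-site competition with unit Hill slope and bottom fixed at 0
    return top / (1.0 + c / ic50)


def fit_ic50(assay: CompetitionAssay, normalize_at: float = 0.03) -> Ic50Estimate:
    """Fit a one-site competition curve and report the IC50 in nM.

    The curve is first normalized so that binding at ``normalize_at``
    (which must be one of the tested concentrations) equals 100 %.  The
    model is ``y = top / (1 + c/IC50)`` with the bottom fixed at zero and
    ``top`` free; a fitted top deviating more than 20 % from 100 is
    flagged.
    """
    conc = assay.competitor_conc
    match = np.isclose(conc, normalize_at, rtol=1e-9)
    if not match.any():
        raise ValueError(
            f"normalization concentration {normalize_at} nM not among the "
            "tested concentrations"
        )
    ref = float(assay.cell_bound_cpm[match][0])
    if ref <= 0:
        raise ValueError("binding at the normalization concentration is zero")
    y = 100.0 * assay.cell_bound_cpm / ref

    # descending-limb sanity: the highest tested concentration should bind
    # less than the normalization point
    unreliable = bool(y[np.argmax(conc)] >= y[match][0])

    p0 = (100.0, float(np.sqrt(conc.min() * conc.max())))
    popt, _ = curve_fit(_one_site, conc, y, p0=p0,
                        bounds=([0.0, 1e-12], [np.inf, np.inf]),
                        maxfev=20000)
    top, ic50 = float(popt[0]), float(popt[1])
    resid = y - _one_site(conc, *popt)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / sst if sst > 0 else 1.0
    return Ic50Estimate(
        ic50=ic50, top=top, bottom=0.0, r2=r2,
        extrapolated=not (conc.min() <= ic50 <= conc.max()),
        top_flagged=abs(top - 100.0) > 20.0,
        unreliable=unreliable,
    )


def partition_fractions(
    membrane_cpm: float,
    internalized_cpm: float,
    blocked_pair: tuple[float, float] | None = None,
) -> FractionPartition:
    """Partition cell-associated activity into membrane-bound and
    internalized fractions.

    ``blocked_pair`` is an optional (membrane, internalized) measurement
    acquired with excess unlabeled competitor under identical geometry;
    the blocked/unblocked total ratio below 1 indicates specific
    (blockable) binding.
    """
    if membrane_cpm < 0 or internalized_cpm < 0:
        raise ValueError("cpm must be non-negative")
    total = membrane_cpm + internalized_cpm
    if total == 0:
        raise ValueError("both compartments are zero; fractions undefined")
    blocked_ratio = None
    if blocked_pair is not None:
        blocked_total = float(sum(blocked_pair))
        if blocked_total < 0:
            raise ValueError("blocked cpm must be non-negative")
        blocked_ratio = blocked_total / total
    return FractionPartition(
        membrane_cpm=float(membrane_cpm),
        internalized_cpm=float(internalized_cpm),
        membrane_fraction=membrane_cpm / total,
        internalized_fraction=internalized_cpm / total,
        blocked_ratio=blocked_ratio,
    )


def bootstrap_ci(assay, fit, estimate_attr: str, n_boot: int = 1000,
                 level: float = 0.95, seed: int = 0) -> tuple[float, float]:
    """Seeded nonparametric bootstrap percentile CI for a binding estimate.

    Resamples assay conditions with replacement and refits; ``fit`` is
    the estimator (:func:`fit_lindmo` or :func:`fit_ic50` via a lambda
    carrying its normalization) and ``estimate_attr`` names the field of
    the returned estimate (e.g. ``"irf"`` or ``"ic50"``).  Resamples on
    which the fit fails are skipped.
    """
    rng = np.random.default_rng(seed)
    if isinstance(assay, SerialDilutionAssay):
        x, y = assay.cell_conc, assay.bound_cpm
        rebuild = lambda i: SerialDilutionAssay(  # noqa: E731
            x[i], y[i], assay.total_cpm, assay.background_cpm)
    elif isinstance(assay, CompetitionAssay):
        x, y = assay.competitor_conc, assay.cell_bound_cpm
        rebuild = lambda i: CompetitionAssay(  # noqa: E731
            np.sort(x[i]), y[i][np.argsort(x[i])])
    else:
        raise TypeError("unsupported assay type for bootstrap")
    n = len(x)
    draws = []
    attempts = 0
    while len(draws) < n_boot:
        attempts += 1
        if attempts > 50 * n_boot:
            raise RuntimeError("bootstrap failed to find refittable resamples")
        idx = rng.integers(0, n, size=n)
        if len(np.unique(x[idx])) < max(4, 5 if isinstance(
                assay, CompetitionAssay) else 4):
            continue
        try:
            draws.append(getattr(fit(rebuild(idx)), estimate_attr))
        except (ValueError, RuntimeError):
            continue
    lo, hi = np.quantile(draws, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


__all__ = [
    "CompetitionAssay",
    "bootstrap_ci",
    "FractionPartition",
    "Ic50Estimate",
    "IrfEstimate",
    "SerialDilutionAssay",
    "fit_ic50",
    "fit_lindmo",
    "partition_fractions",
]
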