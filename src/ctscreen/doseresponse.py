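"""Confirmation-stage dose-response analysis.

The response model is the four-parameter logistic (Hill) curve on dose,

    fold(d) = bottom + (top - bottom) / (1 + (ec50 / d)^hill),

fit by unweighted least squares over all replicate points (no
pre-averaging), with EC50 optimized on the log scale for stability.  Fits
are canonicalized to hill > 0, so an induction curve has top > bottom and
an inhibition curve top < bottom.  The minimal-effective-concentration
summary mirrors a per-dose-mean table: the lowest tested dose whose mean
fold reaches the threshold, or "IA [max observed fold]" for inactives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

# deterministic jitter source for the multi-start fit; not user-facing noise
_RESTART_SEED = 20150326
_N_RESTARTS = 5

HILL_BOUNDS = (0.1, 10.0)
EC50_RANGE_FACTOR = 100.0  # ec50 searched in [min_dose/100, max_dose*100]


class FitError(ValueError):
    """Invalid dose-response input or use of a failed fit."""


@dataclass
class DoseResponseData:
    """Replicate fold-change measurements of one gene over a dose series.

    ``points`` columns: ``dose_um`` (> 0), ``fold`` (> 0), ``replicate``.
    """

    compound_id: str
    gene: str
    points: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"dose_um", "fold", "replicate"}
        if not required.issubset(self.points.columns):
            raise FitError(f"points missing columns {sorted(required - set(self.points.columns))}")
        if (self.points["dose_um"] <= 0).any():
            raise FitError("doses must be strictly positive")
        if not np.isfinite(self.points["fold"]).all():
            raise FitError("fold values must be finite")

    @property
    def doses(self) -> np.ndarray:
        return np.sort(self.points["dose_um"].unique())

    def mean_fold_by_dose(self) -> pd.Series:
        return self.points.groupby("dose_um")["fold"].mean().sort_index()


@dataclass(frozen=True)
class FourPLFit:
    """4PL parameters with convergence/extrapolation diagnostics."""

    bottom: float
    top: float
    ec50: float
    hill: float
    rss: float
    converged: bool
    ec50_in_range: bool
    n_points: int = 0

    def predict(self, dose) -> np.ndarray:
        return four_pl(dose, self.bottom, self.top, self.ec50, self.hill)


@dataclass(frozen=True)
class MecResult:
    """Table-style minimal-effective-concentration summary for one series.

    ``mec`` is one of the tested doses, or None when the threshold is never
    reached; then ``max_fold`` carries the maximal per-dose mean fold (the
    bracketed value of the "IA [max]" convention).
    """

    compound_id: str
    gene: str
    threshold_fold: float
    mec: float | None
    max_fold: float | None = None

    @property
    def is_active(self) -> bool:
        return self.mec is not None

    def cell(self) -> str:
        """Render as a summary-table cell: dose, or ``IA [max fold]``."""
        if self.is_active:
            return format(self.mec, "g")
        return f"IA [{self.max_fold:.2g}]"


def four_pl(dose, bottom: float, top: float, ec50: float, hill: float) -> np.ndarray:
    """Four-parameter logistic response at the given dose(s)."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ec50 / dose) ** hill)


def _residuals(theta: np.ndarray, dose: np.ndarray, fold: np.ndarray) -> np.ndarray:
    bottom, top, log_ec50, hill = theta
    return four_pl(dose, bottom, top, np.exp(log_ec50), hill) - fold


def fit_4pl(data: DoseResponseData) -> FourPLFit:
    """Least-squares 4PL fit with multi-start initialization.

    Initialization: bottom = min fold, top = max fold, ec50 = geometric-mean
    dose, hill = 1, plus deterministic jittered restarts; the lowest-RSS
    solution wins.  EC50 is bounded to [min_dose/100, max_dose*100] and
    hill to [0.1, 10]; an EC50 outside the tested dose range is flagged via
    ``ec50_in_range`` rather than rejected.  Non-convergence (including
    response-free, flat data) yields ``converged=False``, never an
    exception.
    """
    dose = data.points["dose_um"].to_numpy(float)
    fold = data.points["fold"].to_numpy(float)
    distinct = np.unique(dose)
    if distinct.size < 4:
        raise FitError(f"need >= 4 distinct doses to fit a 4PL, got {distinct.size}")
    lo, hi = distinct.min(), distinct.max()
    span = fold.max() - fold.min()
    scale = max(1.0, np.abs(fold).max())

    log_ec50_bounds = (np.log(lo / EC50_RANGE_FACTOR), np.log(hi * EC50_RANGE_FACTOR))
    lower = np.array([-np.inf, -np.inf, log_ec50_bounds[0], HILL_BOUNDS[0]])
    upper = np.array([np.inf, np.inf, log_ec50_bounds[1], HILL_BOUNDS[1]])

    geo_mean_dose = float(np.exp(np.mean(np.log(distinct))))
    base = np.array([fold.min(), fold.max(), np.log(geo_mean_dose), 1.0])
    rng = np.random.default_rng(_RESTART_SEED)
    starts = [base]
    for _ in range(_N_RESTARTS):
        jitter = base.copy()
        jitter[0] += rng.normal(0.0, 0.1 * max(span, 1e-3))
        jitter[1] += rng.normal(0.0, 0.1 * max(span, 1e-3))
        jitter[2] += rng.uniform(-np.log(10), np.log(10))
        jitter[3] = rng.uniform(0.3, 3.0)
        starts.append(np.clip(jitter, lower, upper))

    best = None
    for theta0 in starts:
        try:
            sol = least_squares(
                _residuals, theta0, bounds=(lower, upper), args=(dose, fold), xtol=1e-12,
                ftol=1e-12, gtol=1e-12,
            )
        except Exception:  # pragma: no cover - optimizer pathologies
            continue
        if not sol.success or not np.isfinite(sol.cost):
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return FourPLFit(np.nan, np.nan, np.nan, np.nan, np.inf, False, False, fold.size)

    bottom, top, log_ec50, hill = best.x
    ec50 = float(np.exp(log_ec50))
    rss = float(2.0 * best.cost)
    # flat data or a fitted span of ~0 leave ec50/hill unidentifiable
    degenerate = span < 1e-10 * scale or abs(top - bottom) < 1e-8 * scale
    in_range = (lo <= ec50 <= hi) and not degenerate
    return FourPLFit(
        bottom=float(bottom),
        top=float(top),
        ec50=ec50,
        hill=float(hill),
        rss=rss,
        converged=not degenerate,
        ec50_in_range=bool(in_range),
        n_points=int(fold.size),
    )


def ec50(fit: FourPLFit) -> float:
    """The fitted half-maximal concentration (µM).

    Raises :class:`FitError` on a non-converged fit; warns when the value
    lies outside the tested dose range (extrapolated).
    """
    if not fit.converged:
        raise FitError("EC50 requested from a non-converged fit")
    if not fit.ec50_in_range:
        warnings.warn(
            f"EC50 {fit.ec50:.3g} uM lies outside the tested dose range (extrapolated)",
            stacklevel=2,
        )
    return fit.ec50


def minimal_effective_concentration(
    data: DoseResponseData, threshold_fold: float = 2.0
) -> MecResult:
    """Lowest tested dose whose per-dose mean fold reaches the threshold.

    Replicates are averaged per dose first (a per-dose summary-table
    convention, unlike the fit which uses every point).  When no dose
    reaches the threshold the series is inactive and the maximal per-dose
    mean fold is reported alongside.
    """
    means = data.mean_fold_by_dose()
    reached = means[means >= threshold_fold]
    if len(reached):
        return MecResult(data.compound_id, data.gene, threshold_fold, float(reached.index[0]))
    return MecResult(
        data.compound_id, data.gene, threshold_fold, None, max_fold=float(means.max())
    )
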