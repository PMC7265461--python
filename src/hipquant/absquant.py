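"""Absolute quantification from embedded hipMHC calibration curves.

A targeted run fragments one peptide of interest repeatedly across its
chromatographic elution; each MS2 scan yields per-channel reporter
intensities.  Channels carrying known spiked amounts of the heavy calibrant
trace out Gaussian elution profiles whose fitted amplitude ("apex
intensity") is proportional to amount loaded.  Normalization standards in
the same run supply correction factors; the adjusted apexes versus fmol
spiked form a within-run standard curve, and the endogenous (light) channel
signal is back-calculated to fmol and converted to copies per cell via
Avogadro's number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats as sps

AVOGADRO = 6.02214076e23

logger = logging.getLogger("hipquant")


@dataclass
class GaussianFit:
    amplitude: float
    center: float
    width: float
    apex: float
    residual_norm: float
    converged: bool


@dataclass
class CalibrationCurve:
    """Linear standard curve: adjusted apex intensity vs fmol spiked."""

    spec_id: str
    points: list[tuple[float, float]]
    slope: float
    intercept: float
    r_squared: float


@dataclass
class CopiesPerCellResult:
    peptide: str
    fmol_per_replicate: list[float]
    copies_per_replicate: list[float]
    mean_copies: float
    sd_copies: float
    n_cells: float
    flags: list[str] = field(default_factory=list)


def fit_gaussian_profile(
    points: list[tuple[float, float]],
) -> GaussianFit:
    """Fit I(t) = A exp(-(t - mu)^2 / (2 sigma^2)) to an elution profile.

    Initialised at the max-intensity scan (mu, A) with sigma from the
    half-max width.  On convergence failure the apex falls back to the
    tallest observed scan, flagged via ``converged=False``.
    """
    if len(points) < 4:
        raise ValueError("need >= 4 scan points to fit an elution profile")
    t = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if not np.any(y > 0):
        raise ValueError("all-zero intensities: nothing to fit")
    order = np.argsort(t)
    t, y = t[order], y[order]

    i_max = int(np.argmax(y))
    a0, mu0 = y[i_max], t[i_max]
    above = t[y >= a0 / 2.0]
    fwhm = float(above.max() - above.min()) if len(above) > 1 else \
        float(np.ptp(t)) / 4.0
    sigma0 = max(fwhm / 2.3548200450309493, 1e-6)  # FWHM = 2 sqrt(2 ln 2) sigma

    def gauss(tt, a, mu, sigma):
        return a * np.exp(-((tt - mu) ** 2) / (2.0 * sigma ** 2))

    try:
        popt, _ = optimize.curve_fit(
            gauss, t, y, p0=[a0, mu0, sigma0], maxfev=5000)
        a, mu, sigma = float(popt[0]), float(popt[1]), abs(float(popt[2]))
        if a < 0 or sigma <= 0 or not np.isfinite([a, mu, sigma]).all():
            raise RuntimeError("non-physical fit")
        resid = float(np.linalg.norm(y - gauss(t, a, mu, sigma)))
        return GaussianFit(a, mu, sigma, apex=a, residual_norm=resid,
                           converged=True)
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        logger.warning("Gaussian fit failed (%s); apex = max observed scan",
                       exc)
        return GaussianFit(a0, mu0, sigma0, apex=float(a0),
                           residual_norm=float("nan"), converged=False)


def build_calibration_curve(
    spec_id: str,
    fmol: list[float],
    adjusted_apex: list[float],
) -> CalibrationCurve:
    """OLS (with intercept) of adjusted apex intensity on fmol spiked."""
    if len(fmol) != len(adjusted_apex) or len(fmol) < 2:
        raise ValueError("need >= 2 (fmol, apex) pairs")
    if len(set(fmol)) < 2:
        raise ValueError("singular design: all fmol values equal")
    x = np.asarray(fmol, dtype=float)
    y = np.asarray(adjusted_apex, dtype=float)
    res = sps.linregress(x, y)
    return CalibrationCurve(
        spec_id=spec_id,
        points=sorted(zip(map(float, x), map(float, y))),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2))


def quantify_endogenous(
    curve: CalibrationCurve,
    apexes: list[float],
    tolerance: float = 1e-9,
) -> tuple[list[float], list[str]]:
    """Back-calculate fmol per replicate: (apex - intercept) / slope.

    Results below zero are clamped to 0 and flagged.
    """
    if curve.slope <= 0:
        raise ValueError("calibration slope must be > 0")
    fmols, flags = [], []
    for i, apex in enumerate(apexes):
        f = (apex - curve.intercept) / curve.slope
        if f < 0:
            if f < -tolerance:
                flags.append(f"replicate {i}: apex below intercept "
                             f"({f:.3g} fmol), clamped to 0")
            f = 0.0
        fmols.append(float(f))
    return fmols, flags


def copies_per_cell(fmol: float, n_cells: float) -> float:
    """Convert fmol of peptide over ``n_cells`` cells to copies per cell."""
    if n_cells <= 0:
        raise ValueError("n_cells must be > 0")
    if fmol < 0:
        raise ValueError("fmol must be >= 0")
    return fmol * 1e-15 * AVOGADRO / n_cells


def quantify_target(
    peptide: str,
    curve: CalibrationCurve,
    endogenous_apexes: list[float],
    n_cells: float,
) -> CopiesPerCellResult:
    """Full back-calculation for one target: fmol then copies per cell.

    Replicates are quantified independently; the report carries their mean
    and sample SD (ddof=1; NaN for a single replicate).
    """
    fmols, flags = quantify_endogenous(curve, endogenous_apexes)
    copies = [copies_per_cell(f, n_cells) for f in fmols]
    mean_c = float(np.mean(copies))
    sd_c = float(np.std(copies, ddof=1)) if len(copies) > 1 else float("nan")
    return CopiesPerCellResult(
        peptide=peptide, fmol_per_replicate=fmols,
        copies_per_replicate=copies, mean_copies=mean_c, sd_copies=sd_c,
        n_cells=n_cells, flags=flags)
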