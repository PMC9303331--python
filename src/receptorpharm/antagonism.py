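"""Schild analysis of competitive antagonism.

A competitive antagonist at concentration B multiplies the agonist's
apparent EC50 by the Gaddum factor (1 + B/KB). The dose ratio
DR = EC50(+antagonist)/EC50(control) from paired logistic fits therefore
satisfies log10(DR - 1) = log10(B) - log10(KB); ordinary least squares of
log10(DR - 1) on log10(B in M) gives the Schild slope (unity for simple
competition) and the x-intercept gives pA2 = -log10(A2 in M), the apparent
antagonist affinity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .doseresponse import LogisticResults

logger = logging.getLogger("receptorpharm")


@dataclass(frozen=True)
class SchildPoint:
    """One antagonist concentration (molar) with its measured dose ratio."""

    antagonist_conc_M: float
    dose_ratio: float

    def __post_init__(self) -> None:
        if self.antagonist_conc_M <= 0:
            raise ValueError("antagonist concentration must be positive")
        if self.dose_ratio <= 0:
            raise ValueError("dose ratio must be positive")

    @property
    def usable(self) -> bool:
        """Only points with DR > 1 carry Schild information (log(DR-1))."""
        return self.dose_ratio > 1.0


@dataclass(frozen=True)
class SchildResults:
    """Schild regression output.

    pa2 is -log10(A2 in M); a2_nM the same affinity in concentration units
    (both reported because the literature often prints "pA2" values in nM).
    With exactly two usable points the line is exact and SEs/R^2 are
    reported as NaN (undefined), not zero.
    """

    slope: float
    se_slope: float
    pa2: float
    r2: float
    n_points: int

    @property
    def a2_nM(self) -> float:
        return 10.0 ** (9.0 - self.pa2)

    def summary(self) -> str:
        return (
            f"Schild regression (n={self.n_points} dose ratios)\n"
            f"  slope: {self.slope:.3f} +/- {self.se_slope:.3f}   R2: {self.r2:.4f}\n"
            f"  pA2:   {self.pa2:.3f}   (A2 = {self.a2_nM:.3g} nM)"
        )

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "se_slope": self.se_slope,
            "pa2": self.pa2,
            "a2_nM": self.a2_nM,
            "r2": self.r2,
            "n_points": self.n_points,
        }


def dose_ratio(
    fit_with_antagonist: LogisticResults,
    fit_control: LogisticResults,
    antagonist_conc_M: float,
) -> SchildPoint:
    """Dose ratio EC50(+B)/EC50(control) from paired converged fits.

    Both fits must describe the same agonist/receptor pairing when that
    metadata is present.
    """
    for f in (fit_with_antagonist, fit_control):
        if not f.converged:
            raise ValueError("dose_ratio requires converged fits")
    for attr in ("ligand_id", "receptor_id"):
        a, b = getattr(fit_with_antagonist, attr), getattr(fit_control, attr)
        if a is not None and b is not None and a != b:
            raise ValueError(f"mismatched assay metadata: {attr} {a!r} != {b!r}")
    return SchildPoint(
        antagonist_conc_M=antagonist_conc_M,
        dose_ratio=fit_with_antagonist.ec50_nM / fit_control.ec50_nM,
    )


class SchildModel:
    """OLS of log10(DR - 1) on log10([antagonist] in M).

    Points with DR <= 1 carry no information about the shift and are
    excluded with a logged warning (reason code DR_LE_1).
    """

    def __init__(self, points: list[SchildPoint]):
        usable = [p for p in points if p.usable]
        for p in points:
            if not p.usable:
                logger.warning(
                    "DR_LE_1: excluding Schild point at %.3g M with DR=%.3g",
                    p.antagonist_conc_M, p.dose_ratio,
                )
        if len(usable) < 2:
            raise ValueError("no usable Schild points: need >=2 with dose_ratio > 1")
        self.points = usable

    def fit(self) -> SchildResults:
        x = np.log10([p.antagonist_conc_M for p in self.points])
        y = np.log10([p.dose_ratio - 1.0 for p in self.points])
        res = sm.OLS(y, sm.add_constant(x)).fit()
        intercept, slope = res.params
        pa2 = intercept / slope  # x-intercept is -intercept/slope; pA2 = -that
        if len(self.points) == 2:  # exact line: uncertainty undefined
            se_slope, r2 = np.nan, np.nan
        else:
            se_slope, r2 = float(res.bse[1]), float(res.rsquared)
        return SchildResults(
            slope=float(slope),
            se_slope=se_slope,
            pa2=float(pa2),
            r2=r2,
            n_points=len(self.points),
        )


def schild_regression(points: list[SchildPoint]) -> SchildResults:
    """Fit the Schild regression; see :class:`SchildModel`."""
    return SchildModel(points).fit()
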