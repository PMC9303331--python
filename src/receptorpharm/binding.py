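"""Equilibrium competition-binding analysis.

Homologous curves (unlabeled tracer displacing its own radiolabel) give the
receptor density and tracer affinity directly:

    Bmax = B0 * IC50 / [L]          KD = IC50 - [L]

with B0 the total specific binding (CPM) at zero competitor and [L] the
tracer concentration in nM. Heterologous curves give the competitor's
inhibition constant via the Cheng-Prusoff correction:

    Ki = IC50 / (1 + [L]/KD).

IC50 comes from a three-parameter logistic fit (Hill fixed at -1) of bound
CPM vs log10 competitor concentration; the fitted bottom absorbs the
nonspecific floor, so B0 = top - bottom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import CompetitionCurve, specific_binding  # noqa: F401  (re-export)
from .doseresponse import LogisticModel, LogisticResults

logger = logging.getLogger("receptorpharm")


def bmax_eq1(b0_cpm: float, ic50_nM: float, L_nM: float) -> float:
    """Total receptor density (CPM scale) from a homologous curve: B0*IC50/L."""
    if b0_cpm <= 0 or ic50_nM <= 0 or L_nM <= 0:
        raise ValueError("b0_cpm, ic50_nM and L_nM must all be positive")
    return b0_cpm * ic50_nM / L_nM


def kd_eq2(ic50_nM: float, L_nM: float) -> float:
    """Tracer equilibrium dissociation constant from a homologous curve: IC50 - L."""
    if ic50_nM < L_nM:
        raise ValueError(
            f"IC50 ({ic50_nM} nM) < tracer concentration ({L_nM} nM): "
            "inconsistent homologous assay"
        )
    return ic50_nM - L_nM


def ki_cheng_prusoff(ic50_nM: float, L_nM: float, kd_nM: float) -> float:
    """Cheng-Prusoff inhibition constant: IC50 / (1 + L/KD)."""
    if kd_nM <= 0:
        raise ValueError("kd_nM must be positive")
    if L_nM < 0:
        raise ValueError("L_nM must be >= 0")
    return ic50_nM / (1.0 + L_nM / kd_nM)


def cpm_to_fmol_per_1e5_cells(
    bmax_cpm: float, specific_activity_cpm_per_fmol: float, n_cells: float
) -> float:
    """Convert a CPM-scale Bmax to fmol per 1e5 cells."""
    if specific_activity_cpm_per_fmol <= 0 or n_cells <= 0:
        raise ValueError("specific activity and cell count must be positive")
    return bmax_cpm / specific_activity_cpm_per_fmol / (n_cells / 1e5)


@dataclass
class EquilibriumResult:
    """Derived quantities from one competition-binding fit.

    Exactly one of kd_nM (homologous) / ki_nM (heterologous) is set.
    ``nb`` flags a curve with no detectable displacement ("N.B."), in which
    case no numeric IC50 is reported.
    """

    mode: str
    pic50: float
    se_pic50: float
    ic50_nM: float
    b0_cpm: float
    bottom_cpm: float
    tracer_conc_L: float
    n_points: int
    bmax_cpm: float | None = None
    kd_nM: float | None = None
    ki_nM: float | None = None
    nb: bool = False
    bmax_fmol_per_1e5cells: float | None = None

    def summary(self) -> str:
        if self.nb:
            return f"Competition binding ({self.mode}): N.B. (no displacement detected)"
        lines = [
            f"Competition binding ({self.mode}, n={self.n_points}, "
            f"[L]={self.tracer_conc_L:.3g} nM)",
            f"  pIC50: {self.pic50:.3f} +/- {self.se_pic50:.3f}"
            f"   (IC50 = {self.ic50_nM:.3g} nM)",
            f"  B0: {self.b0_cpm:.0f} CPM   floor: {self.bottom_cpm:.0f} CPM",
        ]
        if self.mode == "homologous":
            lines.append(f"  KD: {self.kd_nM:.3g} nM   Bmax: {self.bmax_cpm:.3g} CPM")
        else:
            lines.append(f"  Ki: {self.ki_nM:.3g} nM")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "pic50": self.pic50,
            "se_pic50": self.se_pic50,
            "ic50_nM": self.ic50_nM,
            "b0_cpm": self.b0_cpm,
            "bottom_cpm": self.bottom_cpm,
            "tracer_conc_nM": self.tracer_conc_L,
            "n_points": self.n_points,
            "bmax_cpm": self.bmax_cpm,
            "kd_nM": self.kd_nM,
            "ki_nM": self.ki_nM,
            "nb": self.nb,
        }


class CompetitionModel:
    """Homologous or heterologous competition-binding model for one curve.

    The assay mode is declared by the caller, never inferred; a homologous
    declaration is sanity-checked only through the IC50 >= [L] precondition
    of KD = IC50 - L. Heterologous mode requires the tracer KD (from a
    homologous experiment) for the Cheng-Prusoff correction.
    """

    def __init__(self, curve: CompetitionCurve, mode: str = "homologous", kd_nM: float | None = None):
        if mode not in ("homologous", "heterologous"):
            raise ValueError("mode must be 'homologous' or 'heterologous'")
        if mode == "heterologous":
            if kd_nM is None or kd_nM <= 0:
                raise ValueError("heterologous mode requires the tracer kd_nM > 0")
        self.curve = curve
        self.mode = mode
        self.kd_nM = kd_nM

    def fit(self) -> EquilibriumResult:
        data = self.curve.data
        try:
            logistic = LogisticModel(
                data["competitor_conc_M"], data["bound_cpm"], mode="inhibition"
            ).fit()
        except ValueError as err:
            if "degenerate span" in str(err):  # perfectly flat curve
                logger.warning("NB: no displacement detected (flat curve)")
                return EquilibriumResult(
                    mode=self.mode, pic50=np.nan, se_pic50=np.nan, ic50_nM=np.nan,
                    b0_cpm=np.nan, bottom_cpm=np.nan,
                    tracer_conc_L=self.curve.tracer_conc_L,
                    n_points=len(data), nb=True,
                )
            raise
        return self._derive(logistic)

    def _derive(self, logistic: LogisticResults) -> EquilibriumResult:
        L = self.curve.tracer_conc_L
        if not logistic.converged or logistic.na:
            logger.warning("NB: no displacement detected (flat or non-saturating curve)")
            return EquilibriumResult(
                mode=self.mode, pic50=np.nan, se_pic50=np.nan, ic50_nM=np.nan,
                b0_cpm=np.nan, bottom_cpm=np.nan, tracer_conc_L=L,
                n_points=logistic.n_points, nb=True,
            )
        ic50 = logistic.ec50_nM
        b0 = logistic.emax  # fitted top minus floor = total specific binding
        kwargs: dict = {}
        if self.mode == "homologous":
            kwargs["kd_nM"] = kd_eq2(ic50, L)
            kwargs["bmax_cpm"] = bmax_eq1(b0, ic50, L)
        else:
            kwargs["ki_nM"] = ki_cheng_prusoff(ic50, L, self.kd_nM)
        return EquilibriumResult(
            mode=self.mode,
            pic50=logistic.pec50,
            se_pic50=logistic.se_pec50,
            ic50_nM=ic50,
            b0_cpm=b0,
            bottom_cpm=logistic.basal,
            tracer_conc_L=L,
            n_points=logistic.n_points,
            **kwargs,
        )


def fit_competition(curve: CompetitionCurve, mode: str = "homologous", kd_nM: float | None = None) -> EquilibriumResult:
    """Fit one competition curve; see :class:`CompetitionModel`."""
    return CompetitionModel(curve, mode=mode, kd_nM=kd_nM).fit()
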