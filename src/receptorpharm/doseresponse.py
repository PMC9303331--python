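"""Three-parameter logistic dose-response fitting with a fixed Hill sign.

Sigmoidal curves are fitted with a Hill slope fixed at +1 (activation) or
-1 (inhibition), estimating (bottom, span, pEC50) by least squares with the
midpoint parameterized in log space (pEC50 = -log10(EC50 in M)), which both
conditions the optimization and matches the convention of reporting
pEC50 +/- SEM. Multi-start initialization over a deterministic pEC50 grid
guards against local minima.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .containers import BretTable, DoseResponseCurve

logger = logging.getLogger("receptorpharm")

_EXP_CLIP = 30.0  # clip base-10 exponents; occupancy saturates far before this


def _occupancy(x: np.ndarray, pxc50: float, hill: int) -> np.ndarray:
    """Fractional occupancy at log10 molar concentration x, Hill +/-1."""
    expo = np.clip(hill * (-pxc50 - x), -_EXP_CLIP, _EXP_CLIP)
    return 1.0 / (1.0 + 10.0**expo)


def logistic_response(
    conc_M: np.ndarray, bottom: float, span: float, pxc50: float, hill: int
) -> np.ndarray:
    """Three-parameter logistic on the molar concentration axis.

    Zero-dose wells take the zero-concentration limit (bottom for
    activation, bottom + span for inhibition) and never enter a log.
    """
    conc_M = np.asarray(conc_M, dtype=float)
    out = np.empty_like(conc_M)
    zero = conc_M == 0
    out[zero] = bottom if hill > 0 else bottom + span
    if np.any(~zero):
        x = np.log10(conc_M[~zero])
        out[~zero] = bottom + span * _occupancy(x, pxc50, hill)
    return out


@dataclass
class LogisticResults:
    """Fit results for a three-parameter logistic with fixed Hill sign.

    basal is the fitted bottom plateau, emax the fitted span (top - bottom);
    pec50 doubles as pIC50 for inhibition fits. ``na`` marks a curve judged
    non-saturating ("N.A.": span below 3x the residual SD, or midpoint
    outside the tested concentration range).
    """

    pec50: float
    basal: float
    emax: float
    hill: int
    sse: float
    se_pec50: float
    converged: bool
    n_points: int
    na: bool = False
    ligand_id: str | None = None
    receptor_id: str | None = None

    def __post_init__(self) -> None:
        if self.hill not in (+1, -1):
            raise ValueError("hill must be +1 or -1")

    @property
    def ec50_nM(self) -> float:
        """EC50 (or IC50) in nM; consistent with pec50 by construction."""
        return 10.0 ** (9.0 - self.pec50)

    @property
    def top(self) -> float:
        return self.basal + self.emax

    def predict(self, conc_M) -> np.ndarray:
        return logistic_response(np.asarray(conc_M, float), self.basal, self.emax, self.pec50, self.hill)

    def to_dict(self) -> dict:
        return {
            "pec50": self.pec50,
            "ec50_nM": self.ec50_nM,
            "basal": self.basal,
            "emax": self.emax,
            "hill": self.hill,
            "sse": self.sse,
            "se_pec50": self.se_pec50,
            "converged": self.converged,
            "n_points": self.n_points,
            "na": self.na,
            "ligand_id": self.ligand_id,
            "receptor_id": self.receptor_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LogisticResults":
        d = {k: v for k, v in d.items() if k != "ec50_nM"}
        return cls(**d)

    def summary(self) -> str:
        label = "pEC50" if self.hill > 0 else "pIC50"
        lines = [
            "Three-parameter logistic fit "
            f"(Hill {self.hill:+d}, n={self.n_points})",
            f"  {label}:  {self.pec50:.3f} +/- {self.se_pec50:.3f}"
            f"   ({'EC50' if self.hill > 0 else 'IC50'} = {self.ec50_nM:.3g} nM)",
            f"  basal: {self.basal:.3g}   span: {self.emax:.3g}   SSE: {self.sse:.4g}",
            f"  converged: {self.converged}" + ("   [N.A.: no saturation]" if self.na else ""),
        ]
        return "\n".join(lines)


class LogisticModel:
    """Least-squares three-parameter logistic model for one curve.

    Parameters
    ----------
    conc_M, response : array-like
        Paired observations; zero-dose wells inform the basal plateau but
        are excluded from the log-concentration axis.
    mode : {"activation", "inhibition"}
        Fixes the Hill slope at +1 or -1.
    basal_min : float or None
        Lower bound on the fitted bottom plateau (default 0; pass None to
        leave it unbounded).
    """

    def __init__(self, conc_M, response, mode: str = "activation", basal_min: float | None = 0.0):
        if mode not in ("activation", "inhibition"):
            raise ValueError("mode must be 'activation' or 'inhibition'")
        self.conc = np.asarray(conc_M, dtype=float)
        self.response = np.asarray(response, dtype=float)
        if self.conc.shape != self.response.shape:
            raise ValueError("conc_M and response must have equal length")
        if not np.isfinite(self.response).all():
            raise ValueError("responses must be finite")
        self.mode = mode
        self.hill = +1 if mode == "activation" else -1
        self.basal_min = basal_min
        n_distinct = np.unique(self.conc[self.conc > 0]).size
        if n_distinct < 4:
            raise ValueError(
                f"need >=4 distinct positive concentrations, got {n_distinct}"
            )
        if np.ptp(self.response) == 0:
            raise ValueError("all responses equal: degenerate span")

    @classmethod
    def from_curve(cls, curve: DoseResponseCurve, mode: str = "activation", **kw) -> "LogisticModel":
        m = cls(curve.data["conc_M"], curve.data["response"], mode=mode, **kw)
        m._ligand_id = curve.ligand_id
        m._receptor_id = curve.receptor_id
        return m

    def _start_points(self):
        lo = self.basal_min if self.basal_min is not None else -np.inf
        bottom0 = max(float(self.response.min()), lo) if np.isfinite(lo) else float(self.response.min())
        span0 = max(float(np.ptp(self.response)), 1e-12)
        x = np.log10(self.conc[self.conc > 0])
        grid = np.arange(np.floor(-x.max()) - 1.0, np.ceil(-x.min()) + 1.01, 0.5)
        return bottom0, span0, grid

    def fit(self) -> LogisticResults:
        hill = self.hill
        lo_basal = self.basal_min if self.basal_min is not None else -np.inf

        def f(conc, bottom, span, pxc50):
            return logistic_response(conc, bottom, span, pxc50, hill)

        bottom0, span0, grid = self._start_points()
        bounds = ([lo_basal, 0.0, -5.0], [np.inf, np.inf, 20.0])
        best = None
        for p50 in grid:  # deterministic order; strict improvement wins ties
            try:
                popt, pcov = curve_fit(
                    f,
                    self.conc,
                    self.response,
                    p0=[bottom0, span0, float(p50)],
                    bounds=bounds,
                    maxfev=5000,
                )
            except (RuntimeError, ValueError):
                continue
            sse = float(np.sum((f(self.conc, *popt) - self.response) ** 2))
            if best is None or sse < best[2]:
                best = (popt, pcov, sse)
        if best is None:
            return LogisticResults(
                pec50=np.nan, basal=np.nan, emax=np.nan, hill=hill,
                sse=np.nan, se_pec50=np.nan, converged=False,
                n_points=self.response.size,
                ligand_id=getattr(self, "_ligand_id", None),
                receptor_id=getattr(self, "_receptor_id", None),
            )
        popt, pcov, sse = best
        bottom, span, pxc50 = popt
        dof = max(self.response.size - 3, 1)
        se_pec50 = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else np.nan
        resid_sd = np.sqrt(sse / dof)
        x = np.log10(self.conc[self.conc > 0])
        na = bool(span < 3.0 * resid_sd or not (-x.max() - 0.5 <= pxc50 <= -x.min() + 0.5))
        if na:
            logger.warning("NONSATURATING: span %.3g < 3x residual SD %.3g or midpoint outside tested range", span, resid_sd)
        return LogisticResults(
            pec50=float(pxc50),
            basal=float(bottom),
            emax=float(span),
            hill=hill,
            sse=sse,
            se_pec50=se_pec50,
            converged=True,
            n_points=self.response.size,
            na=na,
            ligand_id=getattr(self, "_ligand_id", None),
            receptor_id=getattr(self, "_receptor_id", None),
        )


def fit_logistic(curve: DoseResponseCurve, mode: str = "activation", **kw) -> LogisticResults:
    """Fit one dose-response curve; see :class:`LogisticModel`."""
    return LogisticModel.from_curve(curve, mode=mode, **kw).fit()


def normalize_to_reference(
    curve: DoseResponseCurve, reference_response: float, basal: float = 0.0
) -> DoseResponseCurve:
    """Rescale raw signals to percent of the reference-agonist response.

    output = 100*(raw - basal)/(reference_response - basal), so the
    reference well maps to 100 and the assay basal to 0. Invariant under a
    common scaling of all raw signals (with basal scaled alike).
    """
    if reference_response <= basal:
        raise ValueError("reference_response must exceed the assay basal")
    scaled = 100.0 * (curve.data["response"] - basal) / (reference_response - basal)
    return DoseResponseCurve(
        ligand_id=curve.ligand_id,
        receptor_id=curve.receptor_id,
        data=curve.data.assign(response=scaled),
    )


def bret_ratio(acceptor, donor):
    """BRET ratio = acceptor (YFP) / donor (RLUC); donor must be positive."""
    acceptor = np.asarray(acceptor, dtype=float)
    donor = np.asarray(donor, dtype=float)
    if np.any(donor <= 0):
        raise ValueError("donor channel must be positive")
    out = acceptor / donor
    return float(out) if out.ndim == 0 else out


def bret_to_curve(table: BretTable) -> DoseResponseCurve:
    """Collapse a two-channel BRET table to a ratio dose-response curve."""
    ratio = bret_ratio(table.data["acceptor"], table.data["donor"])
    return DoseResponseCurve(
        ligand_id=table.ligand_id,
        receptor_id=table.receptor_id,
        data=pd.DataFrame(
            {
                "conc_M": table.data["conc_M"].to_numpy(),
                "response": ratio,
                "replicate": table.data["replicate"].to_numpy(),
            }
        ),
    )


def potency_shift(fit_a: LogisticResults, fit_b: LogisticResults) -> float:
    """Fold change in potency: EC50(a) / EC50(b) (>1 means a is less potent)."""
    for f in (fit_a, fit_b):
        if not f.converged:
            raise ValueError("potency_shift requires converged fits")
    return fit_a.ec50_nM / fit_b.ec50_nM


def pooled_pec50(fits: list[LogisticResults]) -> tuple[float, float]:
    """Mean pEC50 and SEM across independent per-experiment fits."""
    vals = np.array([f.pec50 for f in fits if f.converged and not f.na])
    if vals.size == 0:
        raise ValueError("no usable fits")
    sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else np.nan
    return float(vals.mean()), sem
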