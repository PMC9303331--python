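"""One-phase binding kinetics: kobs, koff, kon and the kinetic KD.

Association traces are fitted with specific(t) = plateau*(1 - exp(-kobs*t))
(binding starts at zero: the reaction is initiated by tracer addition), and
dissociation traces with specific(t) = B0*exp(-koff*t), floor fixed at zero
by default since nonspecific binding is already subtracted (a free-floor
variant is available). Under pseudo-first-order conditions

    kon = (kobs - koff) / [L]        KD = koff / kon

and standard errors are carried through both identities by the first-order
delta method, treating the fitted kobs, koff and the pipetted [L] as
independent:

    SE(kon)^2 = (SE(kobs)^2 + SE(koff)^2)/L^2 + ((kobs-koff)*SE(L)/L^2)^2
    SE(KD)^2  = (SE(koff)/kon)^2 + (koff*SE(kon)/kon^2)^2

Replicates are fitted jointly (pooled) by default; per-replicate fitting is
available for SEM-style reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .containers import KineticTrace

_REL_TOL = 1e-9


@dataclass(frozen=True)
class KineticFitResult:
    """Primary one-phase fit output: rate (min^-1) and amplitude (CPM) with SEs."""

    rate: float
    se_rate: float
    amplitude: float
    se_amplitude: float
    sse: float
    converged: bool
    n_points: int


@dataclass(frozen=True)
class KineticConstants:
    """Derived rate constants with delta-method standard errors.

    kobs and koff in min^-1, kon in nM^-1 min^-1, kd_nM in nM. Internal
    consistency (kon = (kobs-koff)/L and KD = koff/kon) is enforced at
    construction.
    """

    kobs: float
    se_kobs: float
    koff: float
    se_koff: float
    kon: float
    se_kon: float
    kd_nM: float
    se_kd_nM: float
    tracer_conc_L: float
    plateau_cpm: float | None = None

    def __post_init__(self) -> None:
        for name in ("kobs", "koff", "kon", "kd_nM"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        kon_chk = (self.kobs - self.koff) / self.tracer_conc_L
        if abs(self.kon - kon_chk) > _REL_TOL * kon_chk:
            raise ValueError("kon inconsistent with (kobs - koff)/L")
        kd_chk = self.koff / self.kon
        if abs(self.kd_nM - kd_chk) > _REL_TOL * kd_chk:
            raise ValueError("kd_nM inconsistent with koff/kon")

    def summary(self) -> str:
        return (
            f"Binding kinetics at [L] = {self.tracer_conc_L:.3g} nM\n"
            f"  kobs: {self.kobs:.4f} +/- {self.se_kobs:.2g} min-1\n"
            f"  koff: {self.koff:.4f} +/- {self.se_koff:.2g} min-1\n"
            f"  kon:  {self.kon:.4f} +/- {self.se_kon:.2g} nM-1 min-1\n"
            f"  KD:   {self.kd_nM:.4f} +/- {self.se_kd_nM:.2g} nM"
        )

    def to_dict(self) -> dict:
        return {
            "kobs_per_min": self.kobs,
            "se_kobs_per_min": self.se_kobs,
            "koff_per_min": self.koff,
            "se_koff_per_min": self.se_koff,
            "kon_per_nM_per_min": self.kon,
            "se_kon_per_nM_per_min": self.se_kon,
            "kd_nM": self.kd_nM,
            "se_kd_nM": self.se_kd_nM,
            "tracer_conc_nM": self.tracer_conc_L,
            "plateau_cpm": self.plateau_cpm,
        }


def kon_eq4(kobs: float, koff: float, L: float) -> float:
    """Association rate constant (nM^-1 min^-1): (kobs - koff)/[L]."""
    if L <= 0:
        raise ValueError("tracer concentration L must be positive")
    if kobs <= koff:
        raise ValueError(
            f"kobs ({kobs}) must exceed koff ({koff}): zero association component"
        )
    return (kobs - koff) / L


def kd_eq5(koff: float, kon: float) -> float:
    """Kinetic equilibrium dissociation constant (nM): koff/kon."""
    if koff <= 0 or kon <= 0:
        raise ValueError("koff and kon must be positive")
    return koff / kon


def propagate_kinetic_errors(
    kobs: float,
    se_kobs: float,
    koff: float,
    se_koff: float,
    L: float,
    se_L: float = 0.0,
    plateau_cpm: float | None = None,
) -> KineticConstants:
    """Derive kon and kinetic KD with first-order (delta-method) SEs."""
    for name, se in (("se_kobs", se_kobs), ("se_koff", se_koff), ("se_L", se_L)):
        if se < 0:
            raise ValueError(f"{name} must be >= 0")
    kon = kon_eq4(kobs, koff, L)
    kd = kd_eq5(koff, kon)
    var_kon = (se_kobs**2 + se_koff**2) / L**2 + ((kobs - koff) * se_L / L**2) ** 2
    se_kon = float(np.sqrt(var_kon))
    var_kd = (se_koff / kon) ** 2 + (koff * se_kon / kon**2) ** 2
    se_kd = float(np.sqrt(var_kd))
    return KineticConstants(
        kobs=kobs, se_kobs=se_kobs, koff=koff, se_koff=se_koff,
        kon=kon, se_kon=se_kon, kd_nM=kd, se_kd_nM=se_kd,
        tracer_conc_L=L, plateau_cpm=plateau_cpm,
    )


def _pooled_arrays(trace: KineticTrace, per_replicate: bool):
    if per_replicate:
        for _, grp in trace.data.groupby("replicate"):
            yield grp["time_min"].to_numpy(), grp["specific_cpm"].to_numpy()
    else:
        yield trace.data["time_min"].to_numpy(), trace.data["specific_cpm"].to_numpy()


def _one_phase_fit(t, y, model, p0_grid, bounds) -> KineticFitResult:
    best = None
    for p0 in p0_grid:
        try:
            popt, pcov = curve_fit(model, t, y, p0=p0, bounds=bounds, maxfev=5000)
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((model(t, *popt) - y) ** 2))
        if best is None or sse < best[2]:
            best = (popt, pcov, sse)
    if best is None:
        return KineticFitResult(np.nan, np.nan, np.nan, np.nan, np.nan, False, y.size)
    popt, pcov, sse = best
    ses = np.sqrt(np.diag(pcov))
    return KineticFitResult(
        rate=float(popt[0]), se_rate=float(ses[0]),
        amplitude=float(popt[1]), se_amplitude=float(ses[1]),
        sse=sse, converged=True, n_points=y.size,
    )


class AssociationModel:
    """One-phase association fit for a pooled (or single-replicate) trace."""

    def __init__(self, trace: KineticTrace):
        if trace.phase != "association":
            raise ValueError("AssociationModel requires an association-phase trace")
        if trace.data.groupby("replicate")["time_min"].count().min() < 10:
            raise ValueError("need >=10 time points per replicate")
        self.trace = trace

    @staticmethod
    def _model(t, kobs, plateau):
        return plateau * (1.0 - np.exp(-kobs * t))

    def fit(self, per_replicate: bool = False):
        results = []
        for t, y in _pooled_arrays(self.trace, per_replicate):
            span = float(np.ptp(y))
            if span == 0 or float(np.max(y)) <= 0:
                raise ValueError("no association signal: flat trace")
            plateau0 = float(np.max(y))
            p0_grid = [(k0, plateau0) for k0 in np.logspace(-3, 0, 7)]
            res = _one_phase_fit(
                t, y, self._model, p0_grid,
                bounds=([1e-9, 1e-9], [np.inf, np.inf]),
            )
            results.append(res)
        return results if per_replicate else results[0]


class DissociationModel:
    """One-phase dissociation fit; floor fixed at zero unless free_floor."""

    def __init__(self, trace: KineticTrace, free_floor: bool = False):
        if trace.phase != "dissociation":
            raise ValueError("DissociationModel requires a dissociation-phase trace")
        if trace.data.groupby("replicate")["time_min"].count().min() < 10:
            raise ValueError("need >=10 time points per replicate")
        self.trace = trace
        self.free_floor = free_floor

    @staticmethod
    def _model(t, koff, b0):
        return b0 * np.exp(-koff * t)

    @staticmethod
    def _model_floor(t, koff, b0, floor):
        return floor + b0 * np.exp(-koff * t)

    def fit(self, per_replicate: bool = False):
        results = []
        for t, y in _pooled_arrays(self.trace, per_replicate):
            # compare early vs late time quartiles (replicates are pooled,
            # so positional slices would interleave whole decays)
            early = float(np.mean(y[t <= np.quantile(t, 0.25)]))
            late = float(np.mean(y[t >= np.quantile(t, 0.75)]))
            if late > early:
                raise ValueError("increasing trace: not a dissociation signal")
            b0_0 = max(early, 1e-9)
            if self.free_floor:
                p0_grid = [(k0, b0_0, 0.0) for k0 in np.logspace(-4, -0.5, 7)]
                res = _one_phase_fit(
                    t, y, self._model_floor, p0_grid,
                    bounds=([1e-9, 1e-9, 0.0], [np.inf, np.inf, np.inf]),
                )
            else:
                p0_grid = [(k0, b0_0) for k0 in np.logspace(-4, -0.5, 7)]
                res = _one_phase_fit(
                    t, y, self._model, p0_grid,
                    bounds=([1e-9, 1e-9], [np.inf, np.inf]),
                )
            results.append(res)
        return results if per_replicate else results[0]


def fit_association(trace: KineticTrace, per_replicate: bool = False):
    """Fit kobs and plateau; see :class:`AssociationModel`."""
    return AssociationModel(trace).fit(per_replicate=per_replicate)


def fit_dissociation(trace: KineticTrace, per_replicate: bool = False, free_floor: bool = False):
    """Fit koff and starting amplitude; see :class:`DissociationModel`."""
    return DissociationModel(trace, free_floor=free_floor).fit(per_replicate=per_replicate)


def kinetic_constants_from_traces(
    association: KineticTrace,
    dissociation: KineticTrace,
    se_L: float = 0.0,
) -> KineticConstants:
    """Full pipeline: pooled association + dissociation fits -> derived constants."""
    if association.tracer_conc_L != dissociation.tracer_conc_L:
        raise ValueError("association and dissociation traces must share [L]")
    assoc = fit_association(association)
    dissoc = fit_dissociation(dissociation)
    if not (assoc.converged and dissoc.converged):
        raise ValueError("kinetic fits did not converge")
    return propagate_kinetic_errors(
        kobs=assoc.rate, se_kobs=assoc.se_rate,
        koff=dissoc.rate, se_koff=dissoc.se_rate,
        L=association.tracer_conc_L, se_L=se_L,
        plateau_cpm=assoc.amplitude,
    )
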