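"""Ground-truth parameter sets that drive the synthetic-assay generators.

Units follow the conventions of radioligand pharmacology: concentrations and
equilibrium constants in nM, rate constants in min^-1 (dissociation) and
nM^-1 min^-1 (association), binding signal in counts per minute (CPM).
"""

from __future__ import annotations

from dataclasses import dataclass

_KD_RTOL = 1e-9


@dataclass(frozen=True)
class SystemParams:
    """Mass-action receptor/radioligand system for binding simulations.

    Parameters
    ----------
    bmax_cpm : float
        Maximal specific binding (total receptor density) expressed in CPM.
    kd_nM : float, optional
        Equilibrium dissociation constant in nM. Derived as koff/kon when the
        kinetic rates are given; if supplied alongside them it must agree to
        1e-9 relative.
    kon : float, optional
        Association rate constant, nM^-1 min^-1.
    koff : float, optional
        Dissociation rate constant, min^-1.
    ns_fraction : float
        Nonspecific binding as a fraction of total added counts per well,
        modeled as time- and competitor-independent (mock-transfected
        membrane channel). Must lie in [0, 1).
    noise_cv : float
        Coefficient of variation of the Gaussian measurement noise applied to
        each expected count (truncated at zero).
    seed : int
        RNG seed; identical seeds reproduce every emitted number.
    """

    bmax_cpm: float
    kd_nM: float | None = None
    kon: float | None = None
    koff: float | None = None
    ns_fraction: float = 0.02
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.bmax_cpm > 0:
            raise ValueError("bmax_cpm must be positive")
        if not 0 <= self.ns_fraction < 1:
            raise ValueError("ns_fraction must lie in [0, 1)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if (self.kon is None) != (self.koff is None):
            raise ValueError("kon and koff must be supplied together")
        if self.kon is not None:
            if self.kon <= 0 or self.koff <= 0:
                raise ValueError("kon and koff must be positive")
            kinetic_kd = self.koff / self.kon
            if self.kd_nM is None:
                object.__setattr__(self, "kd_nM", kinetic_kd)
            elif abs(self.kd_nM - kinetic_kd) > _KD_RTOL * kinetic_kd:
                raise ValueError(
                    f"kd_nM={self.kd_nM} inconsistent with koff/kon={kinetic_kd}"
                )
        if self.kd_nM is None:
            raise ValueError("either kd_nM or the kinetic rates are required")
        if self.kd_nM <= 0:
            raise ValueError("kd_nM must be positive")

    def require_rates(self) -> tuple[float, float]:
        """Return (kon, koff), raising if the kinetic rates were not set."""
        if self.kon is None or self.koff is None:
            raise ValueError("kinetic rates kon/koff are required for this operation")
        return self.kon, self.koff


@dataclass(frozen=True)
class FunctionalParams:
    """Ground truth for functional (cAMP / BRET) dose-response simulations.

    basal is in response units (percent of reference for cAMP-style assays,
    raw ratio for BRET); emax_frac is the maximal effect as a fraction of the
    reference full agonist (0 for no activation, ~0.11 for the weak partial
    agonist profile, 1 for a full agonist); ec50_nM is the half-maximal
    agonist concentration; kb_nM is the competitive antagonist equilibrium
    constant driving the Gaddum rightward shift (optional).
    """

    ec50_nM: float
    emax_frac: float = 1.0
    basal: float = 0.0
    kb_nM: float | None = None
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.ec50_nM > 0:
            raise ValueError("ec50_nM must be positive")
        if self.emax_frac < 0:
            raise ValueError("emax_frac must be >= 0")
        if self.kb_nM is not None and self.kb_nM <= 0:
            raise ValueError("kb_nM must be positive when given")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
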