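"""Synthetic assay generator under mass-action receptor binding.

Emulates the four assay families of a radioligand pharmacology study —
SPA membrane kinetics (~0.2 nM tracer, 1-min sampling, micromolar chase),
whole-cell competition binding (13-86 pM tracer), cAMP-style dose-response
with a Gaddum competitive shift, and two-channel BRET — with the statistical
structure the analysis pipeline assumes:

* binding follows the pseudo-first-order mass-action closed forms
  (kobs = kon*[L] + koff; Beq = Bmax*[L]/([L]+KD));
* nonspecific binding is a time- and competitor-independent fraction of the
  added counts, emitted as a separate mock-transfected channel;
* measurement noise is Gaussian per replicate with a user CV, truncated at
  zero (gamma/SPA counts are large, so Gaussian is adequate);
* identical seeds reproduce every number bit-for-bit.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import BretTable, CompetitionCurve, DoseResponseCurve, KineticTrace
from .params import FunctionalParams, SystemParams

#: default total added counts per well (CPM); competition assays in the
#: emulated study added 21,400-30,000 cpm/well.
DEFAULT_ADDED_CPM = 25_000.0

#: minimum chase/KD ratio for a valid dissociation design (rebinding negligible)
CHASE_RATIO_MIN = 100.0

#: bound/added fraction above which the pseudo-first-order assumption degrades
DEPLETION_FRACTION = 0.10


class TracerDepletionWarning(UserWarning):
    """Bound tracer exceeds 10% of added tracer; pseudo-first-order regime violated."""


def _rng(params, seed):
    return np.random.default_rng(params.seed if seed is None else seed)


def _noisy(rng: np.random.Generator, expected: np.ndarray, cv: float) -> np.ndarray:
    """Gaussian noise with the given CV on each expectation, truncated at 0."""
    expected = np.asarray(expected, dtype=float)
    if cv == 0:
        return expected.copy()
    return np.clip(rng.normal(expected, cv * np.abs(expected)), 0.0, None)


def _check_times(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if times[0] < 0:
        raise ValueError("times must start at >= 0")
    if not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    return times


def _depletion_guard(beq_cpm: float, added_cpm: float) -> None:
    if beq_cpm > DEPLETION_FRACTION * added_cpm:
        warnings.warn(
            f"bound tracer ({beq_cpm:.0f} CPM) exceeds "
            f"{DEPLETION_FRACTION:.0%} of added tracer ({added_cpm:.0f} CPM); "
            "pseudo-first-order assumption violated",
            TracerDepletionWarning,
            stacklevel=3,
        )


def association_expectation(sys: SystemParams, L: float, times) -> np.ndarray:
    """Noise-free expected specific binding Beq*(1 - exp(-kobs*t)) in CPM."""
    kon, koff = sys.require_rates()
    kobs = kon * L + koff
    beq = sys.bmax_cpm * L / (L + sys.kd_nM)
    return beq * (1.0 - np.exp(-kobs * np.asarray(times, dtype=float)))


def simulate_association(
    sys: SystemParams,
    L: float,
    times,
    n_rep: int = 1,
    added_cpm: float = DEFAULT_ADDED_CPM,
    seed: int | None = None,
) -> KineticTrace:
    """Simulate an SPA association time course at tracer concentration L (nM).

    Total and nonspecific (mock-transfected) channels are emitted per
    replicate; nonspecific = ns_fraction * added counts, constant in time.
    """
    if L <= 0:
        raise ValueError("tracer concentration L must be positive")
    times = _check_times(times)
    rng = _rng(sys, seed)
    expected = association_expectation(sys, L, times)
    beq = sys.bmax_cpm * L / (L + sys.kd_nM)
    _depletion_guard(beq, added_cpm)
    ns = sys.ns_fraction * added_cpm
    frames = []
    for rep in range(n_rep):
        nonspec = _noisy(rng, np.full_like(times, ns), sys.noise_cv)
        total = _noisy(rng, expected + ns, sys.noise_cv)
        frames.append(
            pd.DataFrame(
                {
                    "time_min": times,
                    "total_cpm": total,
                    "nonspecific_cpm": nonspec,
                    "replicate": rep,
                }
            )
        )
    return KineticTrace(
        phase="association", tracer_conc_L=L, data=pd.concat(frames, ignore_index=True)
    )


def simulate_dissociation(
    sys: SystemParams,
    L: float,
    preincubation_min: float,
    chase_nM: float,
    times,
    n_rep: int = 1,
    added_cpm: float = DEFAULT_ADDED_CPM,
    seed: int | None = None,
) -> KineticTrace:
    """Simulate a chase-initiated dissociation time course.

    The tracer is preincubated for ``preincubation_min`` minutes (specific
    binding builds up along the association curve), then an excess of
    unlabeled ligand at ``chase_nM`` blocks rebinding and binding decays as
    B(t0)*exp(-koff*t). The chase must exceed 100*KD or the design is
    rejected (rebinding would not be negligible).
    """
    if L <= 0:
        raise ValueError("tracer concentration L must be positive")
    if chase_nM < CHASE_RATIO_MIN * sys.kd_nM:
        raise ValueError(
            f"chase concentration {chase_nM} nM is below {CHASE_RATIO_MIN:.0f}*KD "
            f"({CHASE_RATIO_MIN * sys.kd_nM:.3g} nM); rebinding not negligible"
        )
    if preincubation_min < 0:
        raise ValueError("preincubation_min must be >= 0")
    times = _check_times(times)
    _kon, koff = sys.require_rates()
    rng = _rng(sys, seed)
    b0 = float(association_expectation(sys, L, [preincubation_min])[0])
    _depletion_guard(b0, added_cpm)
    expected = b0 * np.exp(-koff * times)
    ns = sys.ns_fraction * added_cpm
    frames = []
    for rep in range(n_rep):
        nonspec = _noisy(rng, np.full_like(times, ns), sys.noise_cv)
        total = _noisy(rng, expected + ns, sys.noise_cv)
        frames.append(
            pd.DataFrame(
                {
                    "time_min": times,
                    "total_cpm": total,
                    "nonspecific_cpm": nonspec,
                    "replicate": rep,
                }
            )
        )
    return KineticTrace(
        phase="dissociation", tracer_conc_L=L, data=pd.concat(frames, ignore_index=True)
    )


def competition_expectation(
    sys: SystemParams,
    L: float,
    competitor_conc_M,
    ki_nM: float | None = None,
    homologous: bool = True,
) -> np.ndarray:
    """Noise-free expected specific binding (CPM) vs competitor concentration.

    Homologous (competitor = unlabeled tracer):
        Bmax*L/(L + C + KD)  ->  IC50 = L + KD.
    Heterologous (competitor with constant ki_nM):
        Bmax*L/(L + KD*(1 + C/Ki))  ->  IC50 = Ki*(1 + L/KD) (Cheng-Prusoff).
    C is converted from molar to nM internally.
    """
    c_nM = np.asarray(competitor_conc_M, dtype=float) * 1e9
    if homologous:
        return sys.bmax_cpm * L / (L + c_nM + sys.kd_nM)
    if ki_nM is None or ki_nM <= 0:
        raise ValueError("heterologous mode requires ki_nM > 0")
    return sys.bmax_cpm * L / (L + sys.kd_nM * (1.0 + c_nM / ki_nM))


def simulate_competition(
    sys: SystemParams,
    L: float,
    competitor_concs_M,
    n_rep: int = 1,
    ki_nM: float | None = None,
    homologous: bool = True,
    added_cpm: float = DEFAULT_ADDED_CPM,
    seed: int | None = None,
    radioligand_id: str = "tracer",
    competitor_id: str = "competitor",
    receptor_id: str = "receptor",
) -> CompetitionCurve:
    """Simulate an equilibrium competition binding curve at tracer L (nM).

    competitor_concs_M are molar and ascending; zero wells (B0) are allowed
    and carried as exact zeros. bound_cpm includes the nonspecific floor.
    """
    if L <= 0:
        raise ValueError("tracer concentration L must be positive")
    concs = np.asarray(competitor_concs_M, dtype=float)
    if (concs < 0).any():
        raise ValueError("competitor concentrations must be >= 0")
    rng = _rng(sys, seed)
    expected = competition_expectation(sys, L, concs, ki_nM=ki_nM, homologous=homologous)
    _depletion_guard(float(np.max(expected)), added_cpm)
    ns = sys.ns_fraction * added_cpm
    frames = []
    for rep in range(n_rep):
        bound = _noisy(rng, expected + ns, sys.noise_cv)
        frames.append(
            pd.DataFrame(
                {"competitor_conc_M": concs, "bound_cpm": bound, "replicate": rep}
            )
        )
    return CompetitionCurve(
        radioligand_id=radioligand_id,
        competitor_id=competitor_id,
        receptor_id=receptor_id,
        tracer_conc_L=L,
        data=pd.concat(frames, ignore_index=True),
    )


def dose_response_expectation(
    fp: FunctionalParams, agonist_conc_M, antagonist_nM: float = 0.0
) -> np.ndarray:
    """Expected percent-of-reference response with a Gaddum competitive shift.

    response = basal + 100*emax_frac * A/(A + EC50*(1 + B/KB)), Hill slope 1.
    """
    if antagonist_nM < 0:
        raise ValueError("antagonist_nM must be >= 0")
    shift = 1.0
    if antagonist_nM > 0:
        if fp.kb_nM is None:
            raise ValueError("antagonist given but kb_nM not set in FunctionalParams")
        shift = 1.0 + antagonist_nM / fp.kb_nM
    a_nM = np.asarray(agonist_conc_M, dtype=float) * 1e9
    return fp.basal + 100.0 * fp.emax_frac * a_nM / (a_nM + fp.ec50_nM * shift)


def simulate_dose_response(
    fp: FunctionalParams,
    agonist_concs_M,
    antagonist_nM: float = 0.0,
    n_rep: int = 1,
    seed: int | None = None,
    ligand_id: str = "agonist",
    receptor_id: str = "receptor",
) -> DoseResponseCurve:
    """Simulate a functional dose-response curve (percent-of-reference units)."""
    concs = np.asarray(agonist_concs_M, dtype=float)
    if (concs < 0).any():
        raise ValueError("agonist concentrations must be >= 0 (zero-dose basal wells allowed)")
    rng = _rng(fp, seed)
    expected = dose_response_expectation(fp, concs, antagonist_nM)
    frames = []
    for rep in range(n_rep):
        resp = expected if fp.noise_cv == 0 else rng.normal(expected, fp.noise_cv * np.maximum(np.abs(expected), 1.0))
        frames.append(pd.DataFrame({"conc_M": concs, "response": resp, "replicate": rep}))
    return DoseResponseCurve(
        ligand_id=ligand_id,
        receptor_id=receptor_id,
        data=pd.concat(frames, ignore_index=True),
    )


def simulate_bret(
    fp: FunctionalParams,
    concs_M,
    donor_level: float,
    n_rep: int = 1,
    seed: int | None = None,
    ligand_id: str = "agonist",
    receptor_id: str = "receptor",
) -> BretTable:
    """Simulate paired acceptor/donor (YFP/RLUC) channel readings.

    The expected acceptor/donor ratio follows the logistic of ``fp`` on the
    raw ratio scale (basal + emax_frac * A/(A + EC50)); the two channels are
    noised independently around donor_level and donor_level*ratio.
    """
    if donor_level <= 0:
        raise ValueError("donor_level must be positive")
    concs = np.asarray(concs_M, dtype=float)
    if (concs < 0).any():
        raise ValueError("concentrations must be >= 0")
    rng = _rng(fp, seed)
    a_nM = concs * 1e9
    ratio = fp.basal + fp.emax_frac * a_nM / (a_nM + fp.ec50_nM)
    frames = []
    for rep in range(n_rep):
        donor = _noisy(rng, np.full_like(concs, donor_level), fp.noise_cv)
        donor = np.maximum(donor, 1e-9)  # donor channel must stay positive
        acceptor = _noisy(rng, donor_level * ratio, fp.noise_cv)
        frames.append(
            pd.DataFrame(
                {"conc_M": concs, "acceptor": acceptor, "donor": donor, "replicate": rep}
            )
        )
    return BretTable(
        ligand_id=ligand_id,
        receptor_id=receptor_id,
        data=pd.concat(frames, ignore_index=True),
    )
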