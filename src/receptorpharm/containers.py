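"""Tidy in-memory containers for the four assay families.

Each container wraps a long-format :class:`pandas.DataFrame` (one row per
well reading) plus the assay metadata the downstream fits need. They are
deliberately thin: analysis models take these as input the way statsmodels
models take endog/exog.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("receptorpharm")


def specific_binding(total, nonspecific):
    """Specific binding = total binding minus nonspecific binding.

    Elementwise difference of two CPM series; negative values (noise below
    background) are clamped to zero, with the number of clamped points logged
    under reason code NEG_SPECIFIC_CLAMPED.
    """
    total = np.asarray(total, dtype=float)
    nonspecific = np.asarray(nonspecific, dtype=float)
    if total.shape != nonspecific.shape:
        raise ValueError(
            f"length mismatch: total has shape {total.shape}, "
            f"nonspecific has shape {nonspecific.shape}"
        )
    diff = total - nonspecific
    n_clamped = int(np.sum(diff < 0))
    if n_clamped:
        logger.warning("NEG_SPECIFIC_CLAMPED: clamped %d negative specific-binding points", n_clamped)
    return np.clip(diff, 0.0, None)


@dataclass
class DoseResponseCurve:
    """Concentration-response points for one ligand-receptor pairing.

    data columns: conc_M (molar; zero-dose basal wells allowed),
    response (raw signal or percent-of-reference), replicate (int).
    """

    ligand_id: str
    receptor_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"conc_M", "response", "replicate"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"DoseResponseCurve missing columns: {sorted(missing)}")
        if (self.data["conc_M"] < 0).any():
            raise ValueError("concentrations must be >= 0")
        if not np.isfinite(self.data["response"]).all():
            raise ValueError("responses must be finite")

    @property
    def n_distinct_positive(self) -> int:
        return self.data.loc[self.data["conc_M"] > 0, "conc_M"].nunique()


@dataclass
class CompetitionCurve:
    """Bound CPM vs competitor concentration at fixed tracer concentration L.

    data columns: competitor_conc_M (zero-competitor wells define B0),
    bound_cpm, replicate. tracer_conc_L is the radioligand concentration
    in nM.
    """

    radioligand_id: str
    competitor_id: str
    receptor_id: str
    tracer_conc_L: float
    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"competitor_conc_M", "bound_cpm", "replicate"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"CompetitionCurve missing columns: {sorted(missing)}")
        if self.tracer_conc_L <= 0:
            raise ValueError("tracer_conc_L must be positive (nM)")
        if (self.data["bound_cpm"] < 0).any():
            raise ValueError("bound_cpm must be >= 0")


@dataclass
class KineticTrace:
    """Timed CPM readings for one association or dissociation experiment.

    data columns: time_min, total_cpm, nonspecific_cpm, specific_cpm
    (total - nonspecific after clamping), replicate. Times are strictly
    increasing within each replicate.
    """

    phase: str  # "association" | "dissociation"
    tracer_conc_L: float
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.phase not in ("association", "dissociation"):
            raise ValueError(f"unknown phase {self.phase!r}")
        required = {"time_min", "total_cpm", "nonspecific_cpm", "replicate"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"KineticTrace missing columns: {sorted(missing)}")
        if self.tracer_conc_L <= 0:
            raise ValueError("tracer_conc_L must be positive (nM)")
        for rep, grp in self.data.groupby("replicate"):
            t = grp["time_min"].to_numpy()
            if not np.all(np.diff(t) > 0):
                raise ValueError(f"times must be strictly increasing (replicate {rep})")
        if "specific_cpm" not in self.data.columns:
            self.data = self.data.assign(
                specific_cpm=specific_binding(
                    self.data["total_cpm"], self.data["nonspecific_cpm"]
                )
            )


@dataclass
class BretTable:
    """Paired two-channel BRET readings per concentration and replicate.

    data columns: conc_M, acceptor (YFP counts), donor (RLUC counts),
    replicate. The BRET ratio is acceptor/donor.
    """

    ligand_id: str
    receptor_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"conc_M", "acceptor", "donor", "replicate"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"BretTable missing columns: {sorted(missing)}")
        if (self.data["donor"] <= 0).any():
            raise ValueError("donor channel must be positive")
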