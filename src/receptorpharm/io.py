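"""Tidy CSV dialects, statistical comparison, and report tables.

No standard on-disk format exists for plate-style pharmacology data, so the
package fixes four exact CSV dialects (one per assay family) with bit-exact
headers. Reading validates the header, coerces types, rejects malformed
rows with their line numbers, and returns a typed table; writers emit the
same dialects so simulate -> write -> read -> fit round-trips exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.stats

from .containers import BretTable, CompetitionCurve, DoseResponseCurve, KineticTrace

logger = logging.getLogger("receptorpharm")

DIALECTS: dict[str, list[str]] = {
    "dose_response": ["ligand", "receptor", "conc_M", "response", "replicate"],
    "competition": [
        "radioligand", "competitor", "receptor",
        "tracer_conc_nM", "competitor_conc_M", "bound_cpm", "replicate",
    ],
    "kinetics": [
        "phase", "time_min", "total_cpm", "nonspecific_cpm",
        "tracer_conc_nM", "replicate",
    ],
    "bret": ["ligand", "receptor", "conc_M", "acceptor", "donor", "replicate"],
}

_NUMERIC: dict[str, list[str]] = {
    "dose_response": ["conc_M", "response", "replicate"],
    "competition": ["tracer_conc_nM", "competitor_conc_M", "bound_cpm", "replicate"],
    "kinetics": ["time_min", "total_cpm", "nonspecific_cpm", "tracer_conc_nM", "replicate"],
    "bret": ["conc_M", "acceptor", "donor", "replicate"],
}


class SchemaError(ValueError):
    """The file does not match the declared assay dialect."""


@dataclass
class TidyAssayTable:
    """A validated, unit-normalized assay table plus its metadata block."""

    assay_type: str
    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def read_assay_csv(path, assay_type: str) -> TidyAssayTable:
    """Read and validate one of the fixed assay CSV dialects.

    Malformed rows (unparseable numerics) are rejected and logged with
    their 1-based file line numbers; an empty result is an error.
    """
    if assay_type not in DIALECTS:
        raise ValueError(f"unknown assay_type {assay_type!r}; choose from {sorted(DIALECTS)}")
    df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    missing = [c for c in DIALECTS[assay_type] if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s) {missing} for {assay_type} dialect")
    df = df[DIALECTS[assay_type]]
    for col in _NUMERIC[assay_type]:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df[_NUMERIC[assay_type]].isna().any(axis=1)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +1 header, +1 one-based
        logger.warning("MALFORMED_ROW: rejected rows at file lines %s", lines)
        df = df[~bad]
    if df.empty:
        raise SchemaError("empty table after validation")
    df = df.reset_index(drop=True)
    df["replicate"] = df["replicate"].astype(int)
    meta_cols = [c for c in DIALECTS[assay_type] if c not in _NUMERIC[assay_type] or c == "tracer_conc_nM"]
    metadata = {
        c: (df[c].iloc[0] if df[c].nunique() == 1 else None) for c in meta_cols
    }
    return TidyAssayTable(assay_type=assay_type, data=df, metadata=metadata)


# ---------------------------------------------------------------------------
# container <-> dialect conversion

def curve_to_frame(curve: DoseResponseCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "ligand": curve.ligand_id,
            "receptor": curve.receptor_id,
            "conc_M": curve.data["conc_M"],
            "response": curve.data["response"],
            "replicate": curve.data["replicate"],
        }
    )


def competition_to_frame(curve: CompetitionCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "radioligand": curve.radioligand_id,
            "competitor": curve.competitor_id,
            "receptor": curve.receptor_id,
            "tracer_conc_nM": curve.tracer_conc_L,
            "competitor_conc_M": curve.data["competitor_conc_M"],
            "bound_cpm": curve.data["bound_cpm"],
            "replicate": curve.data["replicate"],
        }
    )


def trace_to_frame(trace: KineticTrace) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "phase": trace.phase,
            "time_min": trace.data["time_min"],
            "total_cpm": trace.data["total_cpm"],
            "nonspecific_cpm": trace.data["nonspecific_cpm"],
            "tracer_conc_nM": trace.tracer_conc_L,
            "replicate": trace.data["replicate"],
        }
    )


def bret_to_frame(table: BretTable) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "ligand": table.ligand_id,
            "receptor": table.receptor_id,
            "conc_M": table.data["conc_M"],
            "acceptor": table.data["acceptor"],
            "donor": table.data["donor"],
            "replicate": table.data["replicate"],
        }
    )


def table_to_curve(table: TidyAssayTable) -> DoseResponseCurve:
    if table.assay_type != "dose_response":
        raise ValueError("expected a dose_response table")
    return DoseResponseCurve(
        ligand_id=str(table.metadata.get("ligand")),
        receptor_id=str(table.metadata.get("receptor")),
        data=table.data[["conc_M", "response", "replicate"]].copy(),
    )


def table_to_competition(table: TidyAssayTable) -> CompetitionCurve:
    if table.assay_type != "competition":
        raise ValueError("expected a competition table")
    L = table.metadata.get("tracer_conc_nM")
    if L is None:
        raise SchemaError("tracer_conc_nM must be constant within one curve")
    return CompetitionCurve(
        radioligand_id=str(table.metadata.get("radioligand")),
        competitor_id=str(table.metadata.get("competitor")),
        receptor_id=str(table.metadata.get("receptor")),
        tracer_conc_L=float(L),
        data=table.data[["competitor_conc_M", "bound_cpm", "replicate"]].copy(),
    )


def table_to_trace(table: TidyAssayTable) -> KineticTrace:
    if table.assay_type != "kinetics":
        raise ValueError("expected a kinetics table")
    phase = table.metadata.get("phase")
    L = table.metadata.get("tracer_conc_nM")
    if phase is None or L is None:
        raise SchemaError("phase and tracer_conc_nM must be constant within one trace")
    return KineticTrace(
        phase=str(phase),
        tracer_conc_L=float(L),
        data=table.data[["time_min", "total_cpm", "nonspecific_cpm", "replicate"]].copy(),
    )


def table_to_bret(table: TidyAssayTable) -> BretTable:
    if table.assay_type != "bret":
        raise ValueError("expected a bret table")
    return BretTable(
        ligand_id=str(table.metadata.get("ligand")),
        receptor_id=str(table.metadata.get("receptor")),
        data=table.data[["conc_M", "acceptor", "donor", "replicate"]].copy(),
    )


# ---------------------------------------------------------------------------
# statistics

class TTestResult(NamedTuple):
    t: float
    df: int
    p: float


def paired_t_test(values_a, values_b) -> TTestResult:
    """Classical paired Student's t-test on matched per-experiment summaries.

    Two-sided p. Zero-variance nonzero differences are degenerate: t is
    signed infinity and p is reported as 0 with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("unmatched lengths")
    if a.size < 2:
        raise ValueError("need at least 2 matched pairs")
    d = a - b
    dof = a.size - 1
    if np.ptp(d) == 0:
        if d[0] == 0:
            return TTestResult(t=0.0, df=dof, p=1.0)
        warnings.warn("zero-variance nonzero differences: degenerate paired t-test")
        return TTestResult(t=float(np.sign(d[0]) * np.inf), df=dof, p=0.0)
    res = scipy.stats.ttest_rel(a, b)
    return TTestResult(t=float(res.statistic), df=dof, p=float(res.pvalue))


# ---------------------------------------------------------------------------
# report tables

def _sigfig(x: float, n: int = 2) -> str:
    if x == 0 or not np.isfinite(x):
        return str(x)
    from decimal import Decimal
    d = Decimal(f"{x:.{n}g}")
    return str(d.normalize()) if "E" not in f"{x:.{n}g}".upper() else f"{x:.{n}g}"


def functional_table(fits: dict) -> pd.DataFrame:
    """Table of functional fits: ligand -> LogisticResults (or None for N.A.).

    Deterministic row order (insertion order of the dict); N.A. propagated
    as labels, never numbers.
    """
    rows = []
    for label, fit in fits.items():
        if fit is None or (hasattr(fit, "na") and fit.na) or not fit.converged:
            rows.append(
                {"ligand": label, "pEC50": "N.A.", "SEM": "N.A.",
                 "EC50_nM": "N.A.", "efficacy": "N.A.", "n": fit.n_points if fit is not None else 0}
            )
        else:
            rows.append(
                {
                    "ligand": label,
                    "pEC50": f"{fit.pec50:.1f}",
                    "SEM": f"{fit.se_pec50:.2f}",
                    "EC50_nM": _sigfig(fit.ec50_nM, 2),
                    "efficacy": f"{fit.top:.1f}",
                    "n": fit.n_points,
                }
            )
    return pd.DataFrame(rows, columns=["ligand", "pEC50", "SEM", "EC50_nM", "efficacy", "n"])


def binding_table(results: dict, reference_b0: float | None = None) -> pd.DataFrame:
    """Table of competition-binding results: label -> EquilibriumResult.

    %max is the fitted total specific binding as a percent of
    ``reference_b0`` (the reference radioligand's specific binding); when no
    reference is given each curve is its own reference (100%).
    """
    rows = []
    for label, res in results.items():
        if res is None or res.nb:
            rows.append(
                {"ligand": label, "pIC50": "N.B.", "SEM": "N.B.",
                 "Ki_or_KD_nM": "N.B.", "pct_max": "N.B.",
                 "n": res.n_points if res is not None else 0}
            )
        else:
            const = res.kd_nM if res.mode == "homologous" else res.ki_nM
            rows.append(
                {
                    "ligand": label,
                    "pIC50": f"{res.pic50:.1f}",
                    "SEM": f"{res.se_pic50:.2f}",
                    "Ki_or_KD_nM": _sigfig(const, 2),
                    "pct_max": f"{100.0 * res.b0_cpm / (reference_b0 if reference_b0 else res.b0_cpm):.1f}",
                    "n": res.n_points,
                }
            )
    return pd.DataFrame(rows, columns=["ligand", "pIC50", "SEM", "Ki_or_KD_nM", "pct_max", "n"])


def kinetics_table(constants: dict) -> pd.DataFrame:
    """Table of derived kinetic constants: label -> KineticConstants."""
    rows = []
    for label, c in constants.items():
        rows.append(
            {
                "radioligand": label,
                "kobs_per_min": f"{c.kobs:.3f} ± {c.se_kobs:.3f}",
                "koff_per_min": f"{c.koff:.3f} ± {c.se_koff:.3f}",
                "kon_per_nM_per_min": f"{c.kon:.3f} ± {c.se_kon:.3f}",
                "KD_nM": f"{c.kd_nM:.3f} ± {c.se_kd_nM:.3f}",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["radioligand", "kobs_per_min", "koff_per_min", "kon_per_nM_per_min", "KD_nM"],
    )
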