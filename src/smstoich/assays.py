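"""Bulk (ensemble) assay computations.

Three quantities support the single-molecule work:

* percent protection — from light-scatter aggregation curves:
  ``%Protection = (Delta - Delta_sHsp) / Delta * 100`` where ``Delta`` is
  the maximum change in light scatter of the client alone and
  ``Delta_sHsp`` the same in the presence of chaperone;
* labelled-protein concentration and degree of labelling (DOL) — from
  A280 and dye-peak absorbances:
  ``[Protein] = (A280 - A_dye * C.F.) / eps_protein`` and
  ``DOL = A_dye / (eps_dye * [Protein]) * 100`` with the maleimide-dye
  constants C.F.(AF488) = 0.11, C.F.(AF647) = 0.03,
  eps(AF488) = 72,000 and eps(AF647) = 83,000 /M/cm;
* bis-ANS hydrophobicity kinetics — a one-phase association fit
  ``y = y0 + (plateau - y0) (1 - exp(-k t))``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import FitFailureError, InvalidInputError, InvalidParameterError

# Maleimide-dye constants (unitless correction factors; extinction
# coefficients in /M/cm).
CORRECTION_FACTOR = {"AF488": 0.11, "AF647": 0.03}
EPS_DYE = {"AF488": 72_000.0, "AF647": 83_000.0}


@dataclass
class AggregationCurve:
    """Light scatter at 360 nm vs time for one well/condition."""

    time_h: np.ndarray
    scatter: np.ndarray
    condition: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.scatter = np.asarray(self.scatter, dtype=float)
        if self.time_h.shape != self.scatter.shape:
            raise InvalidInputError("time and scatter must have equal length")
        if np.any(np.diff(self.time_h) <= 0):
            raise InvalidInputError("time must be strictly increasing")


@dataclass
class LabelledProteinReading:
    """Absorbance readings for a dye-labelled protein."""

    a280: float
    max_dye_abs: float
    eps_protein: float
    dye: str = "AF488"
    correction_factor: float | None = None
    eps_dye: float | None = None

    def __post_init__(self) -> None:
        if self.a280 < 0 or self.max_dye_abs < 0:
            raise InvalidParameterError("absorbances must be >= 0")
        if self.eps_protein <= 0:
            raise InvalidParameterError("eps_protein must be > 0")
        if self.correction_factor is None:
            self.correction_factor = CORRECTION_FACTOR[self.dye]
        if self.eps_dye is None:
            self.eps_dye = EPS_DYE[self.dye]
        if self.eps_dye <= 0:
            raise InvalidParameterError("eps_dye must be > 0")


@dataclass
class BisAnsFit:
    """One-phase association fit result."""

    k_per_h: float
    plateau: float
    y0: float
    rss: float
    converged: bool


# --------------------------------------------------------------------------
# aggregation / protection


def max_delta(curve: AggregationCurve, baseline: str = "first") -> float:
    """Maximum change in light scatter over the incubation.

    The baseline is the first reading (default) or the curve minimum;
    technical replicates should be averaged into ``curve`` beforehand.
    """
    if len(curve.time_h) < 2:
        raise InvalidInputError("need at least two readings")
    if baseline == "first":
        base = curve.scatter[0]
    elif baseline == "min":
        base = float(np.min(curve.scatter))
    else:
        raise InvalidParameterError(f"unknown baseline mode {baseline!r}")
    return float(np.max(curve.scatter - base))


def percent_protection(delta: float, delta_shsp: float) -> float:
    """``100 * (Delta - Delta_sHsp) / Delta``.

    May exceed 100 or be negative when the inputs are; values are reported
    as computed, not clamped.
    """
    if delta == 0:
        raise InvalidInputError("protection undefined: client Delta is zero")
    return 100.0 * (delta - delta_shsp) / delta


def average_technical_replicates(df: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicate wells within (condition, replicate,
    time) for long-format plate-reader data with columns
    (well, condition, replicate, time_h, value)."""
    required = {"condition", "replicate", "time_h", "value"}
    if not required.issubset(df.columns):
        raise InvalidInputError(f"plate-reader table needs columns {sorted(required)}")
    return (
        df.groupby(["condition", "replicate", "time_h"], as_index=False)["value"]
        .mean()
        .sort_values(["condition", "replicate", "time_h"])
        .reset_index(drop=True)
    )


def protection_table(df: pd.DataFrame, client_condition: str) -> pd.DataFrame:
    """Percent protection per (condition, replicate) relative to the
    client-alone condition, computed after technical-replicate averaging;
    summarise as mean +/- SD over independent replicates downstream."""
    avg = average_technical_replicates(df)
    rows = []
    for rep, g in avg.groupby("replicate"):
        client = g[g["condition"] == client_condition]
        if client.empty:
            raise InvalidInputError(
                f"replicate {rep!r} lacks the client condition {client_condition!r}"
            )
        delta_client = max_delta(
            AggregationCurve(client["time_h"].to_numpy(), client["value"].to_numpy())
        )
        for cond, gc in g.groupby("condition"):
            if cond == client_condition:
                continue
            delta = max_delta(
                AggregationCurve(gc["time_h"].to_numpy(), gc["value"].to_numpy())
            )
            rows.append(
                {
                    "condition": cond,
                    "replicate": rep,
                    "delta_client": delta_client,
                    "delta_condition": delta,
                    "percent_protection": percent_protection(delta_client, delta),
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# labelling


def protein_concentration(r: LabelledProteinReading) -> tuple[float, bool]:
    """Molar labelled-protein concentration from absorbances.

    Returns (concentration in M, negative-numerator warning flag); the value
    is reported even when the dye-corrected numerator is negative.
    """
    numerator = r.a280 - r.max_dye_abs * r.correction_factor
    return numerator / r.eps_protein, numerator < 0


def degree_of_labelling(r: LabelledProteinReading, protein_conc_m: float) -> float:
    """Degree of labelling in percent:
    ``100 * A_dye / (eps_dye * [Protein])``."""
    if protein_conc_m <= 0:
        raise InvalidParameterError("protein concentration must be > 0")
    return 100.0 * r.max_dye_abs / (r.eps_dye * protein_conc_m)


def synthesize_reading(
    conc_m: float, dol_percent: float, eps_protein: float, dye: str = "AF488"
) -> LabelledProteinReading:
    """Forward-construct absorbance readings for a given concentration and
    DOL — the inverse of the two equations above, used for round-trip
    verification."""
    eps_dye = EPS_DYE[dye]
    cf = CORRECTION_FACTOR[dye]
    max_dye_abs = dol_percent / 100.0 * eps_dye * conc_m
    a280 = conc_m * eps_protein + max_dye_abs * cf
    return LabelledProteinReading(
        a280=a280, max_dye_abs=max_dye_abs, eps_protein=eps_protein, dye=dye
    )


# --------------------------------------------------------------------------
# bis-ANS kinetics


def blank_correct_bisans(
    signal: np.ndarray, blank: np.ndarray | float
) -> np.ndarray:
    """Subtract the buffer/bis-ANS blank, then the first corrected reading,
    giving the change in bis-ANS fluorescence over time."""
    corrected = np.asarray(signal, dtype=float) - np.asarray(blank, dtype=float)
    return corrected - corrected[0]


def one_phase_association(t: np.ndarray, y0: float, plateau: float, k: float) -> np.ndarray:
    return y0 + (plateau - y0) * (1.0 - np.exp(-k * t))


def fit_one_phase_association(
    time_h: np.ndarray, signal: np.ndarray
) -> BisAnsFit:
    """Nonlinear least-squares fit of ``y = y0 + (plateau - y0)(1 - e^-kt)``.

    ``k`` is constrained non-negative; a decreasing signal is handled by the
    sign freedom of ``plateau - y0``.  Non-convergence raises
    :class:`FitFailureError` with diagnostics.
    """
    t = np.asarray(time_h, dtype=float)
    y = np.asarray(signal, dtype=float)
    if len(t) < 4:
        raise InvalidInputError("need at least four points")
    if np.any(np.diff(t) <= 0):
        raise InvalidInputError("time must be strictly increasing")

    y0_guess = float(y[0])
    plateau_guess = float(y[-1])
    span = max(t[-1] - t[0], 1e-9)
    k_guess = 1.0 / span
    try:
        popt, _ = curve_fit(
            one_phase_association,
            t,
            y,
            p0=[y0_guess, plateau_guess, k_guess],
            bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(
            "one-phase association fit did not converge",
            diagnostics={"error": str(exc), "n_points": len(t)},
        ) from exc
    resid = y - one_phase_association(t, *popt)
    return BisAnsFit(
        k_per_h=float(popt[2]),
        plateau=float(popt[1]),
        y0=float(popt[0]),
        rss=float(np.sum(resid**2)),
        converged=True,
    )
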