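"""Extraction of PK parameters from concentration-time point tables.

The workflow mirrors how absorption rate constants are recovered from
published plasma curves: the elimination rate constant ``ke`` comes from
an ordinary least-squares fit of log10(concentration) against time over
the post-absorption (terminal) phase, the half-life follows as
``ln 2 / ke``, and ``ka`` is obtained by inverting the peak-time relation
with the observed (or tabulated) Tmax.  When a study tabulates Tmax or
t1/2 directly, those values take precedence over curve-derived ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .errors import DomainError, FitError, SelectionError
from .pk_core import LN2, PKParameters, solve_ka

__all__ = [
    "ConcentrationCurve",
    "TerminalFit",
    "select_terminal_phase",
    "fit_terminal_slope",
    "auc_trapezoid_tail",
    "extract_pk",
    "read_curves",
    "write_curve",
]

LN10 = math.log(10.0)


@dataclass
class ConcentrationCurve:
    """Time-ordered plasma concentration samples for one administration arm."""

    times: np.ndarray           # h, strictly increasing
    concentrations: np.ndarray  # ug/mL, non-negative
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.shape != self.concentrations.shape or self.times.ndim != 1:
            raise DomainError("times and concentrations must be 1-D and equal length")
        if self.times.size < 4:
            raise DomainError(f"need at least 4 samples, got {self.times.size}")
        if np.any(np.diff(self.times) <= 0):
            raise DomainError("times must be strictly increasing")
        if np.any(self.concentrations < 0):
            raise DomainError("concentrations must be non-negative")

    @property
    def peak_index(self) -> int:
        """Index of the observed maximum (first occurrence on ties)."""
        return int(np.argmax(self.concentrations))


@dataclass
class TerminalFit:
    """Log-linear fit of the terminal elimination phase."""

    ke: float                    # 1/h
    log_intercept: float         # log10 concentration at t = 0
    r_squared: float
    indices_used: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.ke > 0:
            raise FitError(f"terminal ke must be positive, got {self.ke}")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise FitError(f"r_squared out of [0, 1]: {self.r_squared}")
        if len(self.indices_used) < 3:
            raise FitError("terminal fit needs at least 3 points")


def select_terminal_phase(curve: ConcentrationCurve, min_points: int = 3) -> tuple[int, ...]:
    """Indices of the post-absorption phase.

    Rule: every sample strictly later than the observed peak time with a
    positive concentration.  Raises :class:`SelectionError` naming the
    number of qualifying points when fewer than *min_points* remain.
    """
    if min_points < 3:
        raise DomainError("min_points must be >= 3")
    t_peak = curve.times[curve.peak_index]
    idx = tuple(
        int(i)
        for i in range(curve.times.size)
        if curve.times[i] > t_peak and curve.concentrations[i] > 0
    )
    if len(idx) < min_points:
        raise SelectionError(
            f"only {len(idx)} positive post-peak points (need {min_points}); "
            "no usable post-absorption phase"
        )
    return idx


def fit_terminal_slope(curve: ConcentrationCurve, indices: Sequence[int]) -> TerminalFit:
    """OLS of log10(concentration) on time over the selected points.

    On a log10 axis a monoexponential decay has slope ``-ke/ln 10``, so
    ``ke = -slope * ln 10``.
    """
    indices = tuple(int(i) for i in indices)
    if len(indices) < 3:
        raise FitError(f"need >= 3 indices for the terminal fit, got {len(indices)}")
    t = curve.times[list(indices)]
    c = curve.concentrations[list(indices)]
    if np.any(c <= 0):
        raise DomainError("terminal-phase concentrations must be positive for log fit")
    if np.allclose(t, t[0]):
        raise FitError("all selected times equal; slope undefined")
    res = linregress(t, np.log10(c))
    ke = -res.slope * LN10
    if not ke > 0:
        raise FitError(f"terminal phase is not decaying (fitted ke={ke})")
    return TerminalFit(
        ke=ke,
        log_intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        indices_used=indices,
    )


def auc_trapezoid_tail(curve: ConcentrationCurve, ke: float) -> float:
    """AUC(0-inf): linear trapezoid over the samples plus a log-linear tail.

    The tail beyond the last sample is extrapolated as ``C_last / ke``,
    the integral of a monoexponential continuing at the fitted rate.
    """
    if not ke > 0:
        raise DomainError("ke must be positive")
    auc_obs = float(np.trapezoid(curve.concentrations, curve.times))
    c_last = float(curve.concentrations[-1])
    return auc_obs + c_last / ke


def extract_pk(
    curve: ConcentrationCurve,
    tmax_source: Literal["observed_peak", "provided"] = "observed_peak",
    provided_tmax: Optional[float] = None,
    provided_t_half: Optional[float] = None,
    branch: str = "absorption_limited",
    min_points: int = 3,
    fq: str = "",
    coadmin_label: str = "control",
) -> PKParameters:
    """Full PK extraction from one concentration curve.

    ``ke`` comes from the terminal-slope fit unless a tabulated half-life
    is supplied (tabulated values take precedence); ``Tmax`` is the
    observed peak time unless ``tmax_source="provided"``; ``ka`` solves
    the peak-time relation on the requested branch; ``Cmax`` is the
    observed maximum and AUC the trapezoid-plus-tail estimate.
    """
    if tmax_source == "provided":
        if provided_tmax is None:
            raise DomainError("tmax_source='provided' requires provided_tmax")
        tmax = float(provided_tmax)
    elif tmax_source == "observed_peak":
        tmax = float(curve.times[curve.peak_index])
    else:
        raise DomainError(f"unknown tmax_source {tmax_source!r}")

    if provided_t_half is not None:
        if not provided_t_half > 0:
            raise DomainError("provided_t_half must be positive")
        ke = LN2 / provided_t_half
    else:
        indices = select_terminal_phase(curve, min_points=min_points)
        ke = fit_terminal_slope(curve, indices).ke

    ka = solve_ka(tmax, ke, branch=branch)
    return PKParameters(
        fq=fq or curve.label or "unknown",
        coadmin_label=coadmin_label,
        cmax=float(np.max(curve.concentrations)),
        tmax=tmax,
        t_half=LN2 / ke,
        auc=auc_trapezoid_tail(curve, ke),
        ke=ke,
        ka=ka,
        branch=branch,
    )


def write_curve(curve: ConcentrationCurve, path) -> None:
    """Write one curve as CSV with columns time_h, conc_ug_ml."""
    pd.DataFrame({"time_h": curve.times, "conc_ug_ml": curve.concentrations}).to_csv(
        path, index=False
    )


def read_curves(path) -> list[ConcentrationCurve]:
    """Read curves from CSV.

    Accepts either one curve per file (columns ``time_h, conc_ug_ml``) or
    a long format with an additional ``arm`` column grouping rows.
    """
    df = pd.read_csv(path)
    required = {"time_h", "conc_ug_ml"}
    if not required <= set(df.columns):
        raise DomainError(f"curve CSV must have columns {sorted(required)}")
    if "arm" in df.columns:
        return [
            ConcentrationCurve(
                sub["time_h"].to_numpy(), sub["conc_ug_ml"].to_numpy(), label=str(arm)
            )
            for arm, sub in df.groupby("arm", sort=True)
        ]
    return [ConcentrationCurve(df["time_h"].to_numpy(), df["conc_ug_ml"].to_numpy())]
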