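"""One-compartment oral-absorption kinetics.

Closed-form relations for the standard one-compartment model with
first-order absorption (rate constant ``ka``) and first-order elimination
(rate constant ``ke``):

* elimination half-life            t1/2 = ln(2) / ke
* time of peak concentration       Tmax = ln(ka/ke) / (ka - ke)
* plasma concentration (Bateman)   C(t) = F D ka / (Vd (ka - ke))
                                          * (exp(-ke t) - exp(-ka t))

``Tmax`` is a strictly decreasing function of ``ka`` for fixed ``ke`` (and
vice versa), continuous through the removable singularity at ``ka = ke``
where it equals ``1/ke``.  Inverting it for ``ka`` given an observed peak
time therefore has exactly one root; whether that root lies above
(absorption-limited) or below (flip-flop) ``ke`` is decided entirely by
whether ``Tmax`` falls below or above ``1/ke``.  Because a concentration
curve alone cannot distinguish the two regimes, every solved ``ka`` is
annotated with the branch it was found on.

Units follow the pharmacological convention used throughout the package:
time in hours, rate constants in 1/h, dose in mg, volume of distribution
in L, concentration in ug/mL (mg/L).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import DomainError, NoSolutionError

__all__ = [
    "PKParameters",
    "RelativeChange",
    "ke_from_half_life",
    "half_life_from_ke",
    "tmax_forward",
    "solve_ka",
    "bateman_concentration",
    "relative_change",
    "read_pk_arms",
    "write_pk_arms",
]

LN2 = math.log(2.0)

#: relative width of the ka ~ ke window treated as the removable singularity
_SINGULAR_RTOL = 1e-10

Branch = Literal["absorption_limited", "flip_flop"]


def _require_positive(**values: float) -> None:
    for name, value in values.items():
        if not (value > 0) or not math.isfinite(value):
            raise DomainError(f"{name} must be a positive finite number, got {value!r}")


def ke_from_half_life(t_half: float) -> float:
    """Elimination rate constant from the half-life, ke = ln(2)/t1/2."""
    _require_positive(t_half=t_half)
    return LN2 / t_half


def half_life_from_ke(ke: float) -> float:
    """Half-life from the elimination rate constant, t1/2 = ln(2)/ke."""
    _require_positive(ke=ke)
    return LN2 / ke


def tmax_forward(ka: float, ke: float) -> float:
    """Time of maximum plasma concentration for given rate constants.

    Returns ``ln(ka/ke)/(ka - ke)``; at the removable singularity
    ``ka = ke`` the continuous limit ``1/ke`` is used.  Symmetric under
    swapping ``ka`` and ``ke``.
    """
    _require_positive(ka=ka, ke=ke)
    if abs(ka - ke) / ke < _SINGULAR_RTOL:
        return 1.0 / ke
    return math.log(ka / ke) / (ka - ke)


def solve_ka(
    tmax: float,
    ke: float,
    branch: Branch = "absorption_limited",
) -> float:
    """Invert the peak-time relation for the absorption rate constant.

    The map ``ka -> Tmax`` is strictly decreasing, so the observed peak
    time pins down a unique ``ka``: above ``ke`` when ``tmax < 1/ke``
    (absorption-limited), below ``ke`` when ``tmax > 1/ke`` (flip-flop),
    equal to ``ke`` when ``tmax = 1/ke``.  The requested *branch* must be
    consistent with where the root actually lies; asking for the other
    branch raises :class:`~fqchelate.errors.NoSolutionError` naming the
    boundary value ``1/ke``.
    """
    _require_positive(tmax=tmax, ke=ke)
    if branch not in ("absorption_limited", "flip_flop"):
        raise DomainError(f"unknown branch {branch!r}")
    bound = 1.0 / ke
    if abs(tmax - bound) / bound < 1e-9:
        return ke

    def f(log_ka: float) -> float:
        return tmax_forward(math.exp(log_ka), ke) - tmax

    if branch == "absorption_limited":
        if tmax > bound:
            raise NoSolutionError(
                f"no ka > ke root: tmax={tmax} exceeds the branch bound 1/ke={bound}"
            )
        lo, hi = math.log(ke * (1.0 + 1e-9)), math.log(ke * 1e6)
        while f(hi) > 0:  # extremely small tmax: push the bracket out
            hi += math.log(1e3)
            if hi > math.log(ke) + 80:
                raise NoSolutionError(f"tmax={tmax} too small to bracket a root")
    else:
        if tmax < bound:
            raise NoSolutionError(
                f"no ka < ke root: tmax={tmax} is below the branch bound 1/ke={bound}"
            )
        lo, hi = math.log(ke * 1e-6), math.log(ke * (1.0 - 1e-9))
        while f(lo) < 0:
            lo -= math.log(1e3)
            if lo < math.log(ke) - 80:
                raise NoSolutionError(f"tmax={tmax} too large to bracket a root")

    log_ka = brentq(f, lo, hi, xtol=1e-300, rtol=1e-15, maxiter=200)
    return math.exp(log_ka)


def bateman_concentration(
    t,
    dose: float,
    f: float,
    vd: float,
    ka: float,
    ke: float,
):
    """Plasma concentration of the one-compartment oral model at time(s) t.

    ``C(t) = F*D*ka / (Vd*(ka-ke)) * (exp(-ke t) - exp(-ka t))`` with the
    continuous limit ``F*D*ke*t/Vd * exp(-ke t)`` at ``ka = ke``.  With
    dose in mg and Vd in L the result is mg/L, numerically equal to ug/mL.
    Accepts scalar or array time; negative times are a domain error.
    """
    _require_positive(dose=dose, vd=vd, ka=ka, ke=ke)
    if not (0 < f <= 1):
        raise DomainError(f"bioavailability f must be in (0, 1], got {f!r}")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError("time must be non-negative")
    if abs(ka - ke) / ke < _SINGULAR_RTOL:
        out = (f * dose * ke * t_arr / vd) * np.exp(-ke * t_arr)
    else:
        pref = f * dose * ka / (vd * (ka - ke))
        out = pref * (np.exp(-ke * t_arr) - np.exp(-ka * t_arr))
    out = np.maximum(out, 0.0)  # guard tiny negative round-off at t ~ 0
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def relative_change(control: float, treatment: float) -> float:
    """Percent change of *treatment* relative to *control*.

    ``100 * (treatment - control) / control``; an increase is positive
    (e.g. control 8.0 -> treatment 8.488 gives +6.1).
    """
    if control == 0:
        raise DomainError("control value must be nonzero")
    return 100.0 * (treatment - control) / control


@dataclass
class PKParameters:
    """Pharmacokinetic parameters of one administration arm.

    All numeric fields are optional; the identity of the arm (drug name
    and coadministration label) is mandatory.  Internal consistency of
    redundant fields is enforced at construction: ``ke * t_half = ln 2``
    and the peak-time relation linking ``ka``, ``ke`` and ``tmax``, both
    to 1e-6 relative.
    """

    fq: str
    coadmin_label: str = "control"
    dose: Optional[float] = None        # mg
    cmax: Optional[float] = None        # ug/mL
    tmax: Optional[float] = None        # h
    t_half: Optional[float] = None      # h
    auc: Optional[float] = None         # ug*h/mL
    ke: Optional[float] = None          # 1/h
    ka: Optional[float] = None          # 1/h
    vd: Optional[float] = None          # L
    cl: Optional[float] = None          # L/h
    f: Optional[float] = None           # bioavailability fraction
    branch: Optional[str] = None        # branch annotation for solved ka

    _NUMERIC = ("dose", "cmax", "tmax", "t_half", "auc", "ke", "ka", "vd", "cl")

    def __post_init__(self) -> None:
        for name in self._NUMERIC:
            value = getattr(self, name)
            if value is not None and not (value > 0):
                raise DomainError(f"PKParameters.{name} must be > 0, got {value!r}")
        if self.f is not None and not (0 < self.f <= 1):
            raise DomainError(f"PKParameters.f must be in (0, 1], got {self.f!r}")
        if self.ke is not None and self.t_half is not None:
            if abs(self.ke * self.t_half - LN2) / LN2 > 1e-6:
                raise DomainError(
                    f"inconsistent ke={self.ke} and t_half={self.t_half}: "
                    f"ke*t_half={self.ke * self.t_half} != ln 2"
                )
        if self.ka is not None and self.ke is not None and self.tmax is not None:
            implied = tmax_forward(self.ka, self.ke)
            if abs(implied - self.tmax) / self.tmax > 1e-6:
                raise DomainError(
                    f"inconsistent (ka, ke, tmax): peak-time relation gives "
                    f"{implied}, recorded tmax is {self.tmax}"
                )


@dataclass
class RelativeChange:
    """A control-vs-treatment percent change for one PK metric."""

    metric: Literal["cmax", "auc", "ka"]
    control_value: float
    treatment_value: float
    percent_change: float

    def __post_init__(self) -> None:
        if self.control_value == 0:
            raise DomainError("control_value must be nonzero")
        expected = relative_change(self.control_value, self.treatment_value)
        if abs(self.percent_change - expected) > 1e-9 * max(1.0, abs(expected)):
            raise DomainError(
                f"percent_change={self.percent_change} inconsistent with "
                f"control/treatment (expected {expected})"
            )

    @classmethod
    def from_values(cls, metric, control_value, treatment_value) -> "RelativeChange":
        return cls(
            metric=metric,
            control_value=control_value,
            treatment_value=treatment_value,
            percent_change=relative_change(control_value, treatment_value),
        )


# CSV schema for PK administration arms
_ARM_COLUMNS = {
    "fq": "fq",
    "coadmin_label": "coadmin_label",
    "dose_mg": "dose",
    "cmax_ug_ml": "cmax",
    "tmax_h": "tmax",
    "thalf_h": "t_half",
    "auc_ug_h_ml": "auc",
    "ke_per_h": "ke",
    "ka_per_h": "ka",
    "branch": "branch",
}


def write_pk_arms(arms: Iterable[PKParameters], path) -> None:
    """Write administration arms to CSV in the fixed arm schema."""
    rows = []
    for arm in arms:
        rows.append({col: getattr(arm, attr) for col, attr in _ARM_COLUMNS.items()})
    pd.DataFrame(rows, columns=list(_ARM_COLUMNS)).to_csv(path, index=False)


def read_pk_arms(path) -> list[PKParameters]:
    """Read administration arms from the fixed CSV schema."""
    df = pd.read_csv(path)
    missing = set(_ARM_COLUMNS) - set(df.columns)
    if missing:
        raise DomainError(f"PK arm CSV missing columns: {sorted(missing)}")
    arms = []
    for _, row in df.iterrows():
        kwargs = {}
        for col, attr in _ARM_COLUMNS.items():
            value = row[col]
            if isinstance(value, float) and math.isnan(value):
                value = None
            kwargs[attr] = value
        arms.append(PKParameters(**kwargs))
    return arms
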