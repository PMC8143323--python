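"""Structure-property regressions of bioavailability reduction.

The interaction dataset pairs each fluoroquinolone with the relative
change in AUC observed when it is coadministered with a multivalent-metal
product.  Because several drugs have arms for more than one metal source,
a source-priority rule selects one AUC change per drug (aluminum
hydroxide preferred, the mixed aluminum/magnesium antacid Maalox as the
fallback); the selected values are then regressed, one predictor at a
time, against molecular weight, TPSA, logP and, when available, the
computed aluminum binding energy.

Two documented assembly variants are shipped (see
:data:`ASSEMBLY_VARIANTS`): the default literal source-priority rule, and
a variant substituting the sucralfate arm for fleroxacin, whose point set
reproduces the published per-panel R-squared triple exactly.  The exact
point membership of the published panels is not recoverable from the
printed record, so both are kept side by side.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .descriptors import MoleculeRecord
from .errors import AmbiguityError, AssemblyError, DomainError

__all__ = [
    "StudyRecord",
    "RegressionResult",
    "load_table2",
    "assemble_auc_dataset",
    "linear_fit",
    "reproduce_fig3",
    "ASSEMBLY_VARIANTS",
    "DEFAULT_PREFERENCE",
]

logger = logging.getLogger(__name__)

#: source-priority list of the default assembly; within "Aluminum hydroxide"
#: ties, the crossover-study arm (reference tag 71) wins
DEFAULT_PREFERENCE: tuple[str, ...] = ("Aluminum hydroxide", "Maalox")

PREFERRED_TAGS = {"Aluminum hydroxide": "71"}

#: named assembly variants: preference list plus per-drug overrides
ASSEMBLY_VARIANTS: dict[str, dict] = {
    # literal reading of the stated rule: aluminum hydroxide first
    # (tag 71 on ties), Maalox fallback; drugs with neither are dropped
    "default": {"preference": DEFAULT_PREFERENCE, "overrides": {}},
    # same rule, but fleroxacin taken from its sucralfate arm; this is the
    # point set whose per-panel R-squared values round to the published
    # triple (0.25 MW, 0.00 TPSA, 0.23 logP)
    "printed-figure": {
        "preference": DEFAULT_PREFERENCE,
        "overrides": {"fleroxacin": ("Sucralfate", "24")},
    },
    # sensitivity variant: keep the earlier aluminum hydroxide arm for
    # ciprofloxacin instead of the tag-71 crossover arm
    "ciprofloxacin-72": {
        "preference": DEFAULT_PREFERENCE,
        "overrides": {"ciprofloxacin": ("Aluminum hydroxide", "72")},
    },
}


@dataclass
class StudyRecord:
    """One coadministration arm: drug, metal source, relative PK changes."""

    fq: str
    metal: str
    metal_source: str
    pct_cmax: Optional[float]
    pct_auc: Optional[float]
    pct_ka: Optional[float]
    reference_tag: str

    def __post_init__(self) -> None:
        for name in ("pct_cmax", "pct_auc", "pct_ka"):
            value = getattr(self, name)
            if value is not None and value <= -100:
                raise DomainError(
                    f"{self.fq}/{self.metal_source}: {name}={value} is below -100%"
                )


@dataclass
class RegressionResult:
    """Simple (univariate) OLS fit summary."""

    slope: float
    intercept: float
    r_squared: float
    n: int
    x_name: str
    y_name: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise DomainError(f"r_squared out of [0, 1]: {self.r_squared}")
        if self.n < 3:
            raise DomainError(f"regression needs n >= 3, got {self.n}")


def _table2_path():
    return resources.files("fqchelate.data").joinpath("table2_interactions.csv")


def load_table2() -> list[StudyRecord]:
    """The packaged interaction dataset (26 coadministration arms)."""
    with _table2_path().open("r") as fh:
        df = pd.read_csv(fh, dtype={"reference_tag": str})
    records = []
    for _, row in df.iterrows():
        records.append(
            StudyRecord(
                fq=row["fq"],
                metal=row["metal"],
                metal_source=row["metal_source"],
                pct_cmax=None if pd.isna(row["pct_cmax"]) else float(row["pct_cmax"]),
                pct_auc=None if pd.isna(row["pct_auc"]) else float(row["pct_auc"]),
                pct_ka=None if pd.isna(row["pct_ka"]) else float(row["pct_ka"]),
                reference_tag=str(row["reference_tag"]),
            )
        )
    return records


def table2_text() -> str:
    """Raw bytes of the packaged dataset (for round-trip guards)."""
    return _table2_path().read_text()


def assemble_auc_dataset(
    records: Iterable[StudyRecord],
    preference: Sequence[str] = DEFAULT_PREFERENCE,
    overrides: Optional[dict[str, tuple[str, str]]] = None,
) -> list[tuple[str, float]]:
    """Select one AUC change per drug by source priority.

    For each drug the AUC change is taken from the highest-priority
    available source in *preference*; within a source, ties are broken by
    the preferred reference tag (:data:`PREFERRED_TAGS`), and unresolved
    ties raise :class:`AmbiguityError`.  *overrides* maps a drug name to
    an explicit ``(metal_source, reference_tag)`` choice.  Drugs with no
    arm in any listed source are excluded (and logged).  The output is
    sorted by drug name, so it is independent of input record order.
    """
    overrides = overrides or {}
    by_fq: dict[str, list[StudyRecord]] = {}
    for rec in records:
        by_fq.setdefault(rec.fq, []).append(rec)

    pairs: list[tuple[str, float]] = []
    for fq in sorted(by_fq):
        rows = [r for r in by_fq[fq] if r.pct_auc is not None]
        if fq in overrides:
            source, tag = overrides[fq]
            chosen = [
                r for r in rows if r.metal_source == source and r.reference_tag == tag
            ]
            if not chosen:
                raise AssemblyError(
                    f"{fq}: override ({source!r}, tag {tag}) matches no arm with AUC"
                )
            pairs.append((fq, chosen[0].pct_auc))
            continue
        selected = None
        for source in preference:
            candidates = [r for r in rows if r.metal_source == source]
            if not candidates:
                continue
            if len(candidates) > 1:
                tag = PREFERRED_TAGS.get(source)
                tagged = [r for r in candidates if r.reference_tag == tag]
                if len(tagged) == 1:
                    candidates = tagged
                else:
                    raise AmbiguityError(
                        f"{fq}: {len(candidates)} {source} arms and no tie-break: "
                        + ", ".join(f"tag {r.reference_tag}" for r in candidates)
                    )
            selected = candidates[0]
            break
        if selected is None:
            logger.info(
                "%s excluded: no AUC arm from sources %s", fq, list(preference)
            )
            continue
        pairs.append((fq, selected.pct_auc))
    return pairs


def linear_fit(
    x: Sequence[float],
    y: Sequence[float],
    x_name: str = "x",
    y_name: str = "y",
) -> RegressionResult:
    """Ordinary least squares of y on x with R-squared.

    For simple OLS, ``R^2 = 1 - SS_res/SS_tot`` equals the squared
    Pearson correlation.  A constant predictor is degenerate; a constant
    response yields ``R^2 = 0`` with a warning.
    """
    x_arr = np.asarray(x, dtype=float)
    y_arr = np.asarray(y, dtype=float)
    if x_arr.shape != y_arr.shape or x_arr.ndim != 1:
        raise DomainError("x and y must be 1-D and equal length")
    if x_arr.size < 3:
        raise DomainError(f"need >= 3 points, got {x_arr.size}")
    if np.allclose(x_arr, x_arr[0]):
        raise DomainError("constant predictor: slope undefined")
    if np.allclose(y_arr, y_arr[0]):
        warnings.warn("constant response: r_squared defined as 0", stacklevel=2)
        return RegressionResult(0.0, float(y_arr[0]), 0.0, x_arr.size, x_name, y_name)
    res = linregress(x_arr, y_arr)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=int(x_arr.size),
        x_name=x_name,
        y_name=y_name,
    )


def reproduce_fig3(
    auc_pairs: Sequence[tuple[str, float]],
    descriptor_table: Sequence[MoleculeRecord],
    energy_table: Optional[Sequence[tuple[str, float]]] = None,
) -> list[RegressionResult]:
    """One univariate regression of AUC change per structural predictor.

    Predictors are molecular weight, TPSA and logP from the descriptor
    table, plus the aluminum binding energy when *energy_table* is
    supplied.  Every drug in *auc_pairs* must have a descriptor record;
    a missing one raises :class:`AssemblyError` naming the drug.
    """
    by_name = {rec.name: rec for rec in descriptor_table}
    missing = [fq for fq, _ in auc_pairs if fq not in by_name]
    if missing:
        raise AssemblyError(f"drugs missing descriptors: {missing}")
    y = [pct for _, pct in auc_pairs]
    results = [
        linear_fit([by_name[fq].mw for fq, _ in auc_pairs], y, "mw", "pct_auc"),
        linear_fit([by_name[fq].tpsa for fq, _ in auc_pairs], y, "tpsa", "pct_auc"),
        linear_fit([by_name[fq].logp for fq, _ in auc_pairs], y, "logp", "pct_auc"),
    ]
    if energy_table is not None:
        energies = dict(energy_table)
        subset = [(fq, pct) for fq, pct in auc_pairs if fq in energies]
        if len(subset) < 3:
            raise AssemblyError(
                f"only {len(subset)} drugs have binding energies; need >= 3"
            )
        results.append(
            linear_fit(
                [energies[fq] for fq, _ in subset],
                [pct for _, pct in subset],
                "delta_e_bind",
                "pct_auc",
            )
        )
    return results


def regression_frame(results: Sequence[RegressionResult]) -> pd.DataFrame:
    """Regression results as a DataFrame (full precision plus 2-dp R^2)."""
    return pd.DataFrame(
        {
            "x_name": [r.x_name for r in results],
            "y_name": [r.y_name for r in results],
            "slope": [r.slope for r in results],
            "intercept": [r.intercept for r in results],
            "r_squared": [r.r_squared for r in results],
            "r_squared_2dp": [round(r.r_squared, 2) for r in results],
            "n": [r.n for r in results],
        }
    )
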