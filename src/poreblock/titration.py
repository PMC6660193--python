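"""Langmuir titration of blocker rate constants by the external permeant ion.

The dissociation-enhancement site and the association-antagonism site are
each described by a single-site saturation (Langmuir) isotherm in the
external K+ concentration:

    value([K+]) = at_sat + (at_zero - at_sat) * half_sat / (half_sat + [K+])

which equals ``at_zero`` at [K+] = 0 and tends to ``at_sat`` at saturating
K+.  One canonical form serves k_off, k_on and K_D titrations alike (the
k_on variant is algebraically identical:
``at_zero + (at_sat - at_zero)*[K+]/(half_sat + [K+])``).

The ratio of the two half-saturation constants, K_K2/K_K1, is a lower bound
on the fractional time the outermost filter site is exposed to external K+
while the blocker is bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .relaxation import RateSet

__all__ = [
    "TitrationPoint",
    "LangmuirParams",
    "SelectivitySummary",
    "DEFAULT_K_GRID",
    "langmuir_eval",
    "fit_langmuir",
    "fold_changes",
    "s1_availability",
    "selectivity_table",
]

#: mM grid mirroring a 0-100 mM titration with log-spaced interior points.
DEFAULT_K_GRID: tuple[float, ...] = (0.0, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0)

KINDS = ("k_off", "k_on", "K_D")


@dataclass
class TitrationPoint:
    """One rate (or K_D) measurement at one external K+ concentration."""

    k_conc: float  # mM
    value: float  # native unit of `kind`
    kind: str = "k_off"
    cell_id: str = ""

    def __post_init__(self) -> None:
        if self.k_conc < 0:
            raise ValueError("K+ concentration must be >= 0")
        if self.value <= 0:
            raise ValueError("rate/K_D values must be positive")
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")


@dataclass
class LangmuirParams:
    """Zero-K+ and saturating-K+ limits with a half-saturation constant (mM)."""

    at_zero: float
    at_sat: float
    half_sat: float
    se_at_zero: float = float("nan")
    se_at_sat: float = float("nan")
    se_half_sat: float = float("nan")
    kind: str = "k_off"
    poorly_identified: bool = False

    def __post_init__(self) -> None:
        if self.at_zero <= 0 or self.at_sat <= 0 or self.half_sat <= 0:
            raise ValueError("Langmuir parameters must all be positive")


@dataclass
class SelectivitySummary:
    """Per-cation K_D and k_off ratios against the reference conditions."""

    cation: str
    kd_ratio_vs_k: float
    koff_ratio_vs_na: float

    def __post_init__(self) -> None:
        if self.kd_ratio_vs_k <= 0 or self.koff_ratio_vs_na <= 0:
            raise ValueError("selectivity ratios must be positive")


def langmuir_eval(params: LangmuirParams, k_conc: float) -> float:
    """Evaluate the isotherm at an external K+ concentration (mM)."""
    if np.any(np.asarray(k_conc) < 0):
        raise ValueError("K+ concentration must be >= 0")
    return params.at_sat + (params.at_zero - params.at_sat) * params.half_sat / (
        params.half_sat + k_conc
    )


def fit_langmuir(
    points: Sequence[TitrationPoint],
    kind: str | None = None,
    relative_weights: bool = False,
) -> LangmuirParams:
    """Least-squares Langmuir fit of a titration table.

    Requires >= 4 distinct concentrations spanning at least a decade.
    Starts: ``at_zero`` from the lowest concentration, ``at_sat`` from the
    highest, ``half_sat`` from the geometric mean of the span.  Unweighted by
    default; ``relative_weights`` switches to 1/value^2 weighting.  When the
    half-saturation constant is poorly constrained by the design
    (se/half_sat > 1) the result carries ``poorly_identified=True`` rather
    than failing — a titration that stops short of saturation genuinely has
    that property.
    """
    if kind is not None:
        points = [p for p in points if p.kind == kind]
    if not points:
        raise ValueError("no titration points of the requested kind")
    kinds = {p.kind for p in points}
    if len(kinds) > 1:
        raise ValueError("cannot mix titration kinds in one fit")
    x = np.array([p.k_conc for p in points])
    y = np.array([p.value for p in points])

    distinct = np.unique(x)
    if distinct.size < 4:
        raise ValueError("need at least 4 distinct concentrations")
    positive = distinct[distinct > 0]
    if positive.size < 2 or positive.max() / positive.min() < 10.0:
        raise ValueError("concentration design must span at least one decade")

    order = np.argsort(x)
    at_zero0 = float(np.mean(y[x == distinct[0]]))
    at_sat0 = float(np.mean(y[x == distinct[-1]]))
    half0 = float(math.sqrt(positive.min() * positive.max()))

    def model(k, at_zero, at_sat, half_sat):
        return at_sat + (at_zero - at_sat) * half_sat / (half_sat + k)

    sigma = y if relative_weights else None
    popt, pcov = curve_fit(
        model,
        x,
        y,
        p0=[at_zero0, at_sat0, half0],
        sigma=sigma,
        bounds=(1e-12, np.inf),
        maxfev=20000,
    )
    se = np.sqrt(np.diag(pcov))
    params = LangmuirParams(
        at_zero=float(popt[0]),
        at_sat=float(popt[1]),
        half_sat=float(popt[2]),
        se_at_zero=float(se[0]),
        se_at_sat=float(se[1]),
        se_half_sat=float(se[2]),
        kind=points[0].kind,
    )
    if not math.isnan(params.se_half_sat) and params.se_half_sat / params.half_sat > 1.0:
        params.poorly_identified = True
    return params


def fold_changes(params: LangmuirParams) -> tuple[float, float]:
    """(at_sat/at_zero, at_zero/at_sat) fold changes between the two limits."""
    return params.at_sat / params.at_zero, params.at_zero / params.at_sat


def s1_availability(half_sat_on: float, half_sat_off: float) -> float:
    """Lower bound K_K2/K_K1 on the fractional external availability of S1.

    ``half_sat_on`` is the half-saturation of the association-antagonism
    site (K_K2, toxin-free channel); ``half_sat_off`` that of the
    dissociation-enhancement site (K_K1, toxin-bound channel).
    """
    if half_sat_on <= 0 or half_sat_off <= 0:
        raise ValueError("half-saturation constants must be positive")
    return half_sat_on / half_sat_off


def selectivity_table(
    ratesets: Mapping[str, RateSet],
    reference_kd: str = "K+",
    reference_koff: str = "Na+",
) -> list[SelectivitySummary]:
    """K_D ratios vs the K+ reference and k_off ratios vs the Na+ reference."""
    if reference_kd not in ratesets:
        raise ValueError(f"missing K_D reference condition {reference_kd!r}")
    if reference_koff not in ratesets:
        raise ValueError(f"missing k_off reference condition {reference_koff!r}")
    kd_ref = ratesets[reference_kd].k_d
    koff_ref = ratesets[reference_koff].k_off
    return [
        SelectivitySummary(
            cation=cation,
            kd_ratio_vs_k=rs.k_d / kd_ref,
            koff_ratio_vs_na=rs.k_off / koff_ref,
        )
        for cation, rs in ratesets.items()
    ]
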