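"""Four-state closed/open inhibition model with Boltzmann gating.

The channel interconverts between closed and open states (equilibrium
``K_V1`` in toxin-free, ``K_V2`` in toxin-bound channels) and binds toxin
in either state (dissociation constants ``K_DC`` closed, ``K_DO`` open).
Only the open-state affinity is voltage dependent,
``K_DO(V) = K_DO(0) exp(z F V / RT)``, and gating follows a single
Boltzmann, ``Po = 1/(1 + exp(-Z F (V - Vo)/RT))``.

The steady-state fraction of toxin-free channels is

    U/Umax = 1 / (1 + [Tx]/K_DO(V) * Po + [Tx]/K_DC * (1 - Po)),

voltage independent in the resting limit (Po -> 0, set by K_DC alone) and
governed by K_DO(V) in the open limit.  Written in terms of K_V1 =
Po/(1 - Po) this is the same expression as
``(1 + K_V1)/(1 + K_V1 + [Tx](1/K_DC + K_V1/K_DO))``; both forms are kept
and property-tested for equivalence.  Microscopic reversibility around the
cycle fixes the fourth constant: ``K_V2 = K_V1 * K_DC / K_DO``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import lmfit
import numpy as np
from scipy.optimize import curve_fit

from .constants import DEFAULT_CONSTANTS, PhysicalConstants

__all__ = [
    "SchemeParams",
    "TonicPoint",
    "GVPoint",
    "TonicFitResult",
    "GVFit",
    "po_boltzmann",
    "kdo_at_voltage",
    "unblocked_fraction",
    "unblocked_fraction_kv1",
    "fit_tonic_inhibition",
    "kv2_from_cycle",
    "gating_shift",
    "fit_gv",
]


@dataclass
class SchemeParams:
    """Parameters of the closed/open inhibition cycle.

    ``kdc``/``kdo0`` in nM (``kdo0`` at V = 0), ``z_tox`` the toxin effective
    valence, ``z_gate``/``v_half`` the gating Boltzmann (valence Z, mV), and
    ``toxin_conc`` in nM.
    """

    kdc: float
    kdo0: float
    z_tox: float
    z_gate: float
    v_half: float
    toxin_conc: float

    def __post_init__(self) -> None:
        if self.kdc <= 0 or self.kdo0 <= 0:
            raise ValueError("dissociation constants must be positive")
        if self.toxin_conc < 0:
            raise ValueError("toxin concentration must be >= 0")
        if self.z_gate <= 0:
            raise ValueError("gating valence must be positive")


@dataclass
class TonicPoint:
    """Steady-state inhibition ratio I/Io at one voltage."""

    voltage: float
    inhibition_ratio: float
    regime: str = "resting"  # "resting" (holding) or "open" (asymptote)

    def __post_init__(self) -> None:
        if not 0.0 <= self.inhibition_ratio <= 1.0:
            raise ValueError("inhibition ratio must lie in [0, 1]")
        if self.regime not in ("resting", "open"):
            raise ValueError("regime must be 'resting' or 'open'")


@dataclass
class GVPoint:
    """Normalized conductance G/Gmax at one voltage."""

    voltage: float
    g_norm: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.g_norm <= 1.0:
            raise ValueError("g_norm must lie in [0, 1]")


@dataclass
class TonicFitResult:
    params: SchemeParams
    se: dict[str, float] = field(default_factory=dict)
    rss: float = float("nan")
    success: bool = True


@dataclass
class GVFit:
    z_gate: float
    v_half: float
    se_z_gate: float = float("nan")
    se_v_half: float = float("nan")
    poorly_constrained: bool = False


def po_boltzmann(
    v: float,
    z_gate: float,
    v_half: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
):
    """Apparent open probability 1/(1 + exp(-Z F (V - Vo)/RT))."""
    vt = constants.thermal_voltage_mv
    return 1.0 / (1.0 + np.exp(-z_gate * (np.asarray(v, dtype=float) - v_half) / vt))


def kdo_at_voltage(
    kdo0: float,
    z_tox: float,
    v: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
):
    """Open-state dissociation constant K_DO(0) exp(z F V/RT), in nM."""
    if kdo0 <= 0:
        raise ValueError("kdo0 must be positive")
    vt = constants.thermal_voltage_mv
    return kdo0 * np.exp(z_tox * np.asarray(v, dtype=float) / vt)


def unblocked_fraction(
    v,
    scheme: SchemeParams,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
):
    """Steady-state toxin-free fraction U/Umax at voltage(s) ``v`` (mV)."""
    po = po_boltzmann(v, scheme.z_gate, scheme.v_half, constants)
    kdo = kdo_at_voltage(scheme.kdo0, scheme.z_tox, v, constants)
    tx = scheme.toxin_conc
    return 1.0 / (1.0 + tx / kdo * po + tx / scheme.kdc * (1.0 - po))


def unblocked_fraction_kv1(kv1: float, toxin_conc: float, kdc: float, kdo: float) -> float:
    """Equivalent form written with the gating equilibrium K_V1 = Po/(1-Po)."""
    if kv1 < 0:
        raise ValueError("kv1 must be >= 0")
    return (1.0 + kv1) / (1.0 + kv1 + toxin_conc * (1.0 / kdc + kv1 / kdo))


def kv2_from_cycle(kv1: float, kdc: float, kdo: float) -> float:
    """Gating equilibrium of toxin-bound channels from cycle closure.

    Microscopic reversibility around the four-state cycle requires
    ``K_V2 = K_V1 * K_DC / K_DO`` so that the product of equilibrium
    constants around the loop is exactly one.
    """
    if kv1 <= 0 or kdc <= 0 or kdo <= 0:
        raise ValueError("all equilibrium constants must be positive")
    return kv1 * kdc / kdo


def gating_shift(
    kdc: float,
    kdo: float,
    z_gate: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Predicted displacement (mV) of the toxin-bound half-activation voltage.

    From cycle closure, toxin binding shifts the gating midpoint by
    ``dV = (RT/ZF) ln(K_DO/K_DC)`` — positive when the open state binds
    more weakly than the closed state.
    """
    if kdc <= 0 or kdo <= 0 or z_gate <= 0:
        raise ValueError("inputs must be positive")
    return constants.thermal_voltage_mv / z_gate * math.log(kdo / kdc)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

_FITTED = ("kdc", "kdo0", "z_tox", "z_gate", "v_half")


def fit_tonic_inhibition(
    points: Sequence[TonicPoint],
    toxin_conc: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    fixed: Mapping[str, float] | None = None,
) -> TonicFitResult:
    """Joint Levenberg-Marquardt fit of I/Io vs V to the state model.

    Resting-regime points (V <= -60 mV) and open-regime asymptotes
    (V >= -30 mV) enter one least-squares problem; the regime label is
    bookkeeping only.  Any parameter subset can be frozen through
    ``fixed``.  Bounds: dissociation constants in [1e-3, 1e3] nM, valences
    in [0, 8], Vo in [-150, +50] mV.  Starts are data driven (K_DC from the
    most negative points, K_DO from the most positive).
    """
    if toxin_conc <= 0:
        raise ValueError("toxin concentration must be positive")
    v = np.array([p.voltage for p in points])
    y = np.array([p.inhibition_ratio for p in points])
    if v.size < 5:
        raise ValueError("need at least 5 points to fit the five-parameter model")
    has_resting = bool(np.any(v <= -60.0))
    has_open = bool(np.any(v >= -30.0))
    if not (has_resting and has_open):
        raise ValueError(
            "cannot separate K_DC from K_DO: data must span both the resting "
            "(V <= -60 mV) and open (V >= -30 mV) regimes"
        )
    if np.ptp(y) < 1e-9:
        raise ValueError("inhibition ratio is flat across voltage: model is degenerate")

    fixed = dict(fixed or {})
    unknown = set(fixed) - set(_FITTED)
    if unknown:
        raise ValueError(f"unknown fixed parameters: {sorted(unknown)}")

    def clip_ratio(u: float) -> float:
        return min(max(u, 0.02), 0.98)

    u_rest = clip_ratio(float(np.mean(y[v <= -60.0])))
    kdc0 = toxin_conc * u_rest / (1.0 - u_rest)
    v_max = float(v.max())
    u_open = clip_ratio(float(np.mean(y[v == v_max])))
    z_tox0 = fixed.get("z_tox", 0.3)
    kdo_vmax = toxin_conc * u_open / (1.0 - u_open)
    kdo00 = kdo_vmax / constants.boltzmann_factor(z_tox0, v_max)

    def residual(pars: lmfit.Parameters) -> np.ndarray:
        scheme = SchemeParams(
            kdc=pars["kdc"].value,
            kdo0=pars["kdo0"].value,
            z_tox=pars["z_tox"].value,
            z_gate=max(pars["z_gate"].value, 1e-9),
            v_half=pars["v_half"].value,
            toxin_conc=toxin_conc,
        )
        return unblocked_fraction(v, scheme, constants) - y

    # deterministic multi-start over the gating parameters; the two affinity
    # limits and z_tox start data-driven, gating starts on a coarse grid
    result = None
    for z_gate0 in (2.0, 4.0, 6.0):
        for v_half0 in (-90.0, -70.0, -50.0):
            p = lmfit.Parameters()
            p.add("kdc", value=min(max(kdc0, 1e-3), 1e3), min=1e-3, max=1e3)
            p.add("kdo0", value=min(max(kdo00, 1e-3), 1e3), min=1e-3, max=1e3)
            p.add("z_tox", value=0.3, min=0.0, max=8.0)
            p.add("z_gate", value=z_gate0, min=0.05, max=8.0)
            p.add("v_half", value=v_half0, min=-150.0, max=50.0)
            for name, value in fixed.items():
                p[name].set(value=value, vary=False)
            trial = lmfit.minimize(residual, p, method="leastsq", xtol=1e-10, ftol=1e-10)
            if result is None or trial.chisqr < result.chisqr:
                result = trial
    pr = result.params
    scheme = SchemeParams(
        kdc=pr["kdc"].value,
        kdo0=pr["kdo0"].value,
        z_tox=pr["z_tox"].value,
        z_gate=pr["z_gate"].value,
        v_half=pr["v_half"].value,
        toxin_conc=toxin_conc,
    )
    se = {
        name: (float(pr[name].stderr) if pr[name].stderr is not None else float("nan"))
        for name in _FITTED
    }
    return TonicFitResult(
        params=scheme,
        se=se,
        rss=float(np.sum(np.asarray(result.residual) ** 2)),
        success=bool(result.success),
    )


def fit_gv(
    points: Sequence[GVPoint],
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> GVFit:
    """Boltzmann fit of a G-V curve, returning (Z, Vo).

    ``v_half`` is the voltage at which G/Gmax = 0.5.  Data that do not span
    the transition (no points below 0.2 or above 0.8) come back with an
    identifiability warning flag instead of an error.
    """
    if len(points) < 4:
        raise ValueError("need at least 4 points spanning the transition")
    v = np.array([p.voltage for p in points])
    g = np.array([p.g_norm for p in points])
    vt = constants.thermal_voltage_mv

    def model(vv, z, vh):
        return 1.0 / (1.0 + np.exp(-z * (vv - vh) / vt))

    vh0 = float(v[np.argmin(np.abs(g - 0.5))])
    popt, pcov = curve_fit(
        model, v, g, p0=[3.0, vh0], bounds=([0.01, -150.0], [20.0, 50.0]), maxfev=20000
    )
    se = np.sqrt(np.diag(pcov))
    return GVFit(
        z_gate=float(popt[0]),
        v_half=float(popt[1]),
        se_z_gate=float(se[0]),
        se_v_half=float(se[1]),
        poorly_constrained=bool(g.min() > 0.2 or g.max() < 0.8),
    )
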