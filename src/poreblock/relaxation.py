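"""Relaxation kinetics of 1:1 pore block.

Two experimental geometries are covered:

* **Wash-in / wash-out time courses.**  Normalized current amplitude sampled
  every few seconds while toxin is applied and removed.  Both phases are
  mono-exponential for a bimolecular blocker; the on and off time constants
  give the association and dissociation rate constants through

  .. math::

      \\tau_{off} = 1/k_{off}, \\qquad
      \\tau_{on} = 1/(k_{on}[Tx] + k_{off}).

* **Voltage-step trace ratios.**  The point-by-point quotient of a +toxin
  current trace over its control relaxes mono-exponentially as toxin binding
  re-equilibrates on the open channel.  The time constant and asymptote
  satisfy

  .. math::

      \\tau = 1/(k_{on}[Tx] + k_{off}), \\qquad
      (I_{Tx}/I_{Con})_\\infty = k_{off}/(k_{on}[Tx] + k_{off}),

  a two-unknown system solved in closed form at every test voltage.  The
  voltage dependence of either rate is summarized by an exponential law
  ``k(V) = k(0) * exp(z_delta * F * V / RT)`` fitted in log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize

from .constants import DEFAULT_CONSTANTS, PhysicalConstants

__all__ = [
    "BlockTimeCourse",
    "ExponentialFit",
    "RateSet",
    "TracePair",
    "RelaxationPoint",
    "VoltageDependence",
    "fit_monoexponential",
    "fit_block_phase",
    "rates_from_on_off",
    "trace_ratio",
    "relaxation_from_pair",
    "rates_from_relaxation",
    "fit_voltage_dependence",
    "average_then_solve",
    "solve_then_average",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class BlockTimeCourse:
    """Normalized current amplitude versus time during toxin application.

    ``times`` are seconds (strictly increasing), ``amplitudes`` are
    dimensionless currents relative to the pre-toxin steady state.
    ``application_window`` marks the [start, end] of toxin perfusion and must
    lie inside the recorded span.
    """

    times: np.ndarray
    amplitudes: np.ndarray
    toxin_conc: float  # uM
    application_window: tuple[float, float]
    condition_label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.times.shape != self.amplitudes.shape:
            raise ValueError("times and amplitudes must have equal length")
        if self.times.size < 2 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.amplitudes < 0):
            raise ValueError("normalized amplitudes must be >= 0")
        t0, t1 = self.application_window
        if not (self.times[0] <= t0 <= t1 <= self.times[-1]):
            raise ValueError("application_window must lie inside the recorded span")


@dataclass
class ExponentialFit:
    """Result of a single-exponential least-squares fit.

    ``y(t) = baseline + amplitude * exp(-(t - t0)/tau)`` with ``t0`` the
    start of the fit window.  When the amplitude is indistinguishable from
    zero (|amplitude| <= 3x the MAD-based noise estimate) ``no_relaxation``
    is set and ``tau`` is NaN rather than a fit artifact.
    """

    amplitude: float
    tau: float
    baseline: float
    se_tau: float
    rss: float
    t0: float = 0.0
    no_relaxation: bool = False

    def __post_init__(self) -> None:
        if not self.no_relaxation and not self.tau > 0:
            raise ValueError("tau must be positive for a resolved relaxation")
        if self.rss < 0:
            raise ValueError("rss must be >= 0")


@dataclass
class RateSet:
    """Association rate, dissociation rate and implied K_D for a 1:1 blocker.

    Units: k_on uM^-1 s^-1, k_off s^-1, k_d nM (= 1000*k_off/k_on).
    """

    k_on: float
    k_off: float
    k_d: float = field(default=float("nan"))
    se_k_on: float = float("nan")
    se_k_off: float = float("nan")
    se_k_d: float = float("nan")
    n_cells: int = 1

    def __post_init__(self) -> None:
        if self.k_on < 0 or self.k_off < 0:
            raise ValueError("rate constants must be >= 0")
        implied = 1e3 * self.k_off / self.k_on if self.k_on > 0 else float("nan")
        if math.isnan(self.k_d):
            self.k_d = implied
        elif self.k_on > 0 and not math.isclose(self.k_d, implied, rel_tol=1e-9):
            raise ValueError("k_d inconsistent with 1000*k_off/k_on")


@dataclass
class TracePair:
    """Control and +toxin current traces on a shared time grid (ms, uA)."""

    times: np.ndarray
    control_current: np.ndarray
    toxin_current: np.ndarray
    step_voltage: float  # mV
    holding_voltage: float  # mV
    toxin_conc: float  # uM

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.control_current = np.asarray(self.control_current, dtype=float)
        self.toxin_current = np.asarray(self.toxin_current, dtype=float)
        if not (self.times.shape == self.control_current.shape == self.toxin_current.shape):
            raise ValueError("trace pair requires equal-length sampling grids")
        if self.times.size < 2 or self.times[-1] <= self.times[0]:
            raise ValueError("step length must be positive")


@dataclass
class RelaxationPoint:
    """Per-voltage relaxation time constant and asymptotic inhibition.

    ``tau`` is in seconds; ``asymptote`` is the equilibrium I_Tx/I_Con in
    [0, 1]; ``fit_window`` records the unmasked [t0, t1] in ms.
    """

    voltage: float
    tau: float
    asymptote: float
    fit_window: tuple[float, float] = (float("nan"), float("nan"))
    se_tau: float = float("nan")
    se_asymptote: float = float("nan")

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("tau must be positive")
        if not 0.0 <= self.asymptote <= 1.0:
            raise ValueError("asymptote must lie in [0, 1]")


@dataclass
class VoltageDependence:
    """Exponential voltage dependence k(V) = k(0) exp(z_delta F V / RT)."""

    k_at_zero: float
    z_delta: float
    se_k_at_zero: float = float("nan")
    se_z_delta: float = float("nan")

    def __post_init__(self) -> None:
        if not self.k_at_zero > 0:
            raise ValueError("k_at_zero must be positive")

    def evaluate(self, v_mv: float, constants: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
        return self.k_at_zero * constants.boltzmann_factor(self.z_delta, v_mv)


# ---------------------------------------------------------------------------
# exponential fitting
# ---------------------------------------------------------------------------


def _mad_noise(y: np.ndarray) -> float:
    """Robust noise scale: 1.4826 x MAD of residuals about a constant fit."""
    r = y - np.median(y)
    return 1.4826 * float(np.median(np.abs(r - np.median(r))))


def fit_monoexponential(
    times: Sequence[float],
    values: Sequence[float],
    window: tuple[float, float] | None = None,
    weights: Sequence[float] | None = None,
) -> ExponentialFit:
    """Least-squares single-exponential fit on a (sub)window of a series.

    Initialization is deterministic: baseline from the last-decile mean,
    amplitude from a robust early-sample estimate, tau from the (1 - 1/e)
    crossing time; refinement by damped least squares with tau bounded in
    [dt, 100*span].  Optional ``weights`` scale the residuals (used for
    trace-ratio series, whose point noise grows as the inverse of the
    control current).  Raises ``ValueError`` for fewer than 5 samples in
    the window.  A series whose fitted amplitude is below 3x the noise MAD
    comes back flagged ``no_relaxation`` instead of crashing.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    w = None if weights is None else np.asarray(weights, dtype=float)
    if w is not None and w.shape != t.shape:
        raise ValueError("weights must match the series length")
    if window is not None:
        lo, hi = window
        if lo < t[0] - 1e-12 or hi > t[-1] + 1e-12:
            raise ValueError("fit window must lie inside the series span")
        sel = (t >= lo) & (t <= hi)
        t, y = t[sel], y[sel]
        if w is not None:
            w = w[sel]
    if t.size < 5:
        raise ValueError("need at least 5 samples in the fit window")
    if w is not None:
        if np.any(w < 0) or w.max() <= 0:
            raise ValueError("weights must be non-negative with a positive maximum")
        w = w / w.max()

    t0 = float(t[0])
    noise = _mad_noise(y)

    if np.ptp(y) == 0.0:
        return ExponentialFit(
            amplitude=0.0, tau=float("nan"), baseline=float(y[0]),
            se_tau=float("nan"), rss=0.0, t0=t0, no_relaxation=True,
        )

    n_tail = max(1, t.size // 10)
    baseline0 = float(np.mean(y[-n_tail:]))
    y_start = float(np.median(y[: min(5, t.size)]))
    amp0 = y_start - baseline0
    span = float(t[-1] - t0)
    dt = float(np.min(np.diff(t)))

    # time to reach (1 - 1/e) of the span toward baseline
    target = abs(amp0) * (1.0 - 1.0 / math.e)
    crossed = np.nonzero(np.abs(y - y_start) >= target)[0]
    tau0 = float(t[crossed[0]] - t0) if crossed.size and crossed[0] > 0 else span / 3.0
    tau0 = min(max(tau0, dt), 100.0 * span)
    if amp0 == 0.0:
        amp0 = float(y[0] - np.mean(y))

    def resid(p: np.ndarray) -> np.ndarray:
        a, tau, b = p
        r = b + a * np.exp(-(t - t0) / tau) - y
        return r if w is None else w * r

    res = optimize.least_squares(
        resid,
        x0=[amp0, tau0, baseline0],
        bounds=([-np.inf, dt, -np.inf], [np.inf, 100.0 * span, np.inf]),
        method="trf",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=2000,
    )
    amp, tau, baseline = (float(v) for v in res.x)
    rss = float(np.sum(res.fun**2))

    # observable relaxation span across the window: for tau >> span the
    # raw amplitude is a degenerate drift term, not a resolved relaxation
    observable = abs(amp) * (1.0 - math.exp(-span / tau))
    if observable <= 3.0 * noise:
        return ExponentialFit(
            amplitude=amp, tau=float("nan"), baseline=baseline,
            se_tau=float("nan"), rss=rss, t0=t0, no_relaxation=True,
        )

    dof = t.size - 3
    se_tau = float("nan")
    if dof > 0:
        jtj = res.jac.T @ res.jac
        try:
            cov = np.linalg.pinv(jtj) * (rss / dof)
            se_tau = float(math.sqrt(max(cov[1, 1], 0.0)))
        except np.linalg.LinAlgError:  # pragma: no cover - pinv rarely fails
            pass
    return ExponentialFit(
        amplitude=amp, tau=tau, baseline=baseline, se_tau=se_tau, rss=rss, t0=t0
    )


def fit_block_phase(course: BlockTimeCourse, phase: str = "on") -> ExponentialFit:
    """Fit the wash-in (``"on"``) or wash-out (``"off"``) phase of a time course."""
    start, end = course.application_window
    if phase == "on":
        window = (start, end)
    elif phase == "off":
        window = (end, float(course.times[-1]))
    else:
        raise ValueError("phase must be 'on' or 'off'")
    return fit_monoexponential(course.times, course.amplitudes, window=window)


# ---------------------------------------------------------------------------
# closed-form rate algebra
# ---------------------------------------------------------------------------


def rates_from_on_off(tau_on: float, tau_off: float, toxin_conc: float) -> RateSet:
    """Invert the on/off time constants of a wash experiment into rates.

    ``k_off = 1/tau_off`` and ``k_on = (1/tau_on - k_off)/[Tx]``; ``[Tx]`` in
    uM, ``k_d`` in nM.  The on relaxation must be faster than the off one,
    otherwise the implied association rate would be non-positive.
    """
    if tau_on <= 0 or tau_off <= 0:
        raise ValueError("time constants must be positive")
    if toxin_conc <= 0:
        raise ValueError("toxin concentration must be positive")
    k_off = 1.0 / tau_off
    excess = 1.0 / tau_on - k_off
    if excess <= 0:
        raise ValueError("on-relaxation slower than off: k_on would be <= 0")
    k_on = excess / toxin_conc
    return RateSet(k_on=k_on, k_off=k_off)


def trace_ratio(
    pair: TracePair, guard_fraction: float = 0.10
) -> tuple[np.ndarray, np.ndarray]:
    """Point-by-point I_Tx/I_Con ratio with an activation guard.

    Samples before the control current first reaches ``guard_fraction`` of
    its steady-state magnitude (last-decile mean of |control|) are masked:
    there the ratio is dominated by the capacitive/early-activation segment
    and is ill-defined.  Returns ``(times, ratio)`` on the unmasked window.
    """
    if not 0.0 < guard_fraction < 1.0:
        raise ValueError("guard_fraction must be in (0, 1)")
    abs_ctrl = np.abs(pair.control_current)
    n_tail = max(1, abs_ctrl.size // 10)
    steady = float(np.mean(abs_ctrl[-n_tail:]))
    threshold = guard_fraction * steady
    crossed = np.nonzero(abs_ctrl >= threshold)[0]
    if steady == 0.0 or crossed.size == 0:
        raise ValueError("no analyzable window: control never exceeds guard level")
    i0 = int(crossed[0])
    ctrl = pair.control_current[i0:]
    if np.any(ctrl == 0.0):
        raise ValueError("control trace passes through zero inside the ratio window")
    return pair.times[i0:], pair.toxin_current[i0:] / ctrl


def relaxation_from_pair(
    pair: TracePair, guard_fraction: float = 0.10
) -> RelaxationPoint | None:
    """Ratio a trace pair and fit the relaxation; ``None`` if no relaxation.

    The exponential fit starts at the first unmasked sample and weights
    each ratio sample by the control magnitude (relative to steady state),
    since the ratio noise scales inversely with the control current.  The
    fitted baseline is the asymptotic (equilibrium) inhibition.  Time
    constants are converted from ms to seconds for the rate algebra
    downstream.
    """
    t_ms, ratio = trace_ratio(pair, guard_fraction)
    n_keep = t_ms.size
    abs_ctrl = np.abs(pair.control_current[-n_keep:])
    n_tail = max(1, abs_ctrl.size // 10)
    steady = float(np.mean(abs_ctrl[-n_tail:]))
    weights = np.clip(abs_ctrl / steady, 0.0, 1.0)
    fit = fit_monoexponential(t_ms, ratio, weights=weights)
    if fit.no_relaxation:
        return None
    asym = min(max(fit.baseline, 0.0), 1.0)
    return RelaxationPoint(
        voltage=pair.step_voltage,
        tau=fit.tau / 1e3,
        asymptote=asym,
        fit_window=(float(t_ms[0]), float(t_ms[-1])),
        se_tau=fit.se_tau / 1e3,
    )


def average_trace_pairs(pairs: Sequence[TracePair]) -> TracePair:
    """Pointwise average of replicate sweeps recorded on one protocol.

    Control and +toxin traces are averaged sample-by-sample across cells
    (the usual way replicate sweeps are combined before ratio analysis,
    cutting the trace noise by sqrt(n)).  All pairs must share the time
    grid, step voltage and toxin concentration.
    """
    if not pairs:
        raise ValueError("need at least one trace pair")
    first = pairs[0]
    for p in pairs[1:]:
        if p.times.shape != first.times.shape or not np.allclose(p.times, first.times):
            raise ValueError("replicate sweeps must share the time grid")
        if p.step_voltage != first.step_voltage:
            raise ValueError("replicate sweeps must share the step voltage")
        if p.toxin_conc != first.toxin_conc:
            raise ValueError("replicate sweeps must share the toxin concentration")
    return TracePair(
        times=first.times.copy(),
        control_current=np.mean([p.control_current for p in pairs], axis=0),
        toxin_current=np.mean([p.toxin_current for p in pairs], axis=0),
        step_voltage=first.step_voltage,
        holding_voltage=first.holding_voltage,
        toxin_conc=first.toxin_conc,
    )


def rates_from_relaxation(
    point: RelaxationPoint, toxin_conc: float
) -> tuple[float, float]:
    """Solve the two-unknown relaxation system for (k_on, k_off).

    Exact algebraic inversion: ``k_off = asymptote/tau`` and
    ``k_on = (1 - asymptote)/(tau * [Tx])``; no iteration involved.
    """
    if point.asymptote <= 0.0:
        raise ValueError("asymptote must be > 0 (lower bound violated)")
    if point.asymptote >= 1.0:
        raise ValueError("asymptote must be < 1 (upper bound violated): no equilibrium block")
    if toxin_conc <= 0:
        raise ValueError("toxin concentration must be positive")
    k_off = point.asymptote / point.tau
    k_on = (1.0 - point.asymptote) / (point.tau * toxin_conc)
    return k_on, k_off


def fit_voltage_dependence(
    points: Iterable[tuple[float, float]],
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> VoltageDependence:
    """Fit k(V) = k(0) exp(z_delta F V/RT) by least squares in log-rate space.

    Linear regression of ln(k) on V; slope maps to the effective valence
    through the thermal voltage.  At exactly two distinct voltages the fit
    is the exact two-point solution and standard errors are undefined.
    """
    pts = [(float(v), float(k)) for v, k in points]
    if any(k <= 0 for _, k in pts):
        raise ValueError("all rates must be positive")
    voltages = np.array([v for v, _ in pts])
    if np.unique(voltages).size < 2:
        raise ValueError("need at least 2 distinct voltages")
    logk = np.log([k for _, k in pts])
    vt = constants.thermal_voltage_mv

    if len(pts) == 2:
        slope = (logk[1] - logk[0]) / (voltages[1] - voltages[0])
        intercept = logk[0] - slope * voltages[0]
        return VoltageDependence(k_at_zero=math.exp(intercept), z_delta=slope * vt)

    from scipy.stats import linregress

    fit = linregress(voltages, logk)
    k0 = math.exp(fit.intercept)
    return VoltageDependence(
        k_at_zero=k0,
        z_delta=fit.slope * vt,
        se_k_at_zero=k0 * fit.intercept_stderr,
        se_z_delta=fit.stderr * vt,
    )


# ---------------------------------------------------------------------------
# multi-cell aggregation
# ---------------------------------------------------------------------------


def _grouped(points: Sequence[RelaxationPoint]) -> dict[float, list[RelaxationPoint]]:
    groups: dict[float, list[RelaxationPoint]] = {}
    for p in points:
        groups.setdefault(p.voltage, []).append(p)
    return dict(sorted(groups.items()))


def average_then_solve(
    points: Sequence[RelaxationPoint],
    toxin_conc: float | Sequence[float],
) -> dict[float, RateSet]:
    """Average tau and asymptote across cells per voltage, then solve.

    This is the conventional order of operations for multi-cell data:
    mean +/- SEM of the relaxation parameters first, closed-form solve at
    the means second.  ``toxin_conc`` may be a scalar or one value per
    point; mixed concentrations inside a voltage group are an error.
    """
    if isinstance(toxin_conc, (int, float)):
        concs = [float(toxin_conc)] * len(points)
    else:
        concs = [float(c) for c in toxin_conc]
        if len(concs) != len(points):
            raise ValueError("one toxin concentration per point required")
    conc_by_point = dict(zip(map(id, points), concs))

    out: dict[float, RateSet] = {}
    for voltage, group in _grouped(points).items():
        group_concs = {conc_by_point[id(p)] for p in group}
        if len(group_concs) != 1:
            raise ValueError(f"mixed toxin concentrations within voltage group {voltage} mV")
        conc = group_concs.pop()
        taus = np.array([p.tau for p in group])
        asyms = np.array([p.asymptote for p in group])
        n = len(group)
        mean_point = RelaxationPoint(
            voltage=voltage,
            tau=float(np.mean(taus)),
            asymptote=float(np.mean(asyms)),
            se_tau=float(np.std(taus, ddof=1) / math.sqrt(n)) if n > 1 else float("nan"),
            se_asymptote=float(np.std(asyms, ddof=1) / math.sqrt(n)) if n > 1 else float("nan"),
        )
        k_on, k_off = rates_from_relaxation(mean_point, conc)
        out[voltage] = RateSet(k_on=k_on, k_off=k_off, n_cells=n)
    return out


def solve_then_average(
    points: Sequence[RelaxationPoint],
    toxin_conc: float,
) -> dict[float, RateSet]:
    """Per-cell solves first, then mean +/- SEM of the rates per voltage."""
    out: dict[float, RateSet] = {}
    for voltage, group in _grouped(points).items():
        solved = np.array([rates_from_relaxation(p, toxin_conc) for p in group])
        k_on, k_off = solved.mean(axis=0)
        n = len(group)
        se = solved.std(axis=0, ddof=1) / math.sqrt(n) if n > 1 else (float("nan"),) * 2
        out[voltage] = RateSet(
            k_on=float(k_on), k_off=float(k_off),
            se_k_on=float(se[0]), se_k_off=float(se[1]), n_cells=n,
        )
    return out
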