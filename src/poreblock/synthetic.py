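"""Synthetic voltage-clamp data with the statistical structure the fits assume.

Every input the analysis pipeline consumes can be generated here: block
wash-in/wash-out time courses (two-state binding ODE, sampled at the pulse
interval), families of activation traces multiplied by toxin-binding
relaxations with Boltzmann-gated resting block, Langmuir-shaped rate
titration tables, and biphasic tonic-inhibition curves.  Generators are
bit-reproducible under a fixed seed and exact (model-valued) when their
noise is zero, so every fitter has a round-trip identity test against its
own generator.

The noise model is additive Gaussian on normalized currents and ratios
(default sd 0.01) and multiplicative log-normal on rate tables (default
relative sd 0.10), keeping rate values positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .relaxation import BlockTimeCourse, TracePair
from .state_model import SchemeParams, kdo_at_voltage, unblocked_fraction
from .titration import DEFAULT_K_GRID, LangmuirParams, TitrationPoint, langmuir_eval
from .state_model import TonicPoint

__all__ = [
    "GeneratorConfig",
    "ScheduleSegment",
    "simple_wash_schedule",
    "gen_block_timecourse",
    "gen_trace_family",
    "gen_titration_table",
    "gen_tonic_table",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Sampling, noise and solution-exchange settings shared by all generators.

    ``noise_sd`` — additive Gaussian sd on normalized currents/ratios;
    ``table_noise_sd`` — log-normal relative sd on rate tables;
    ``pulse_interval_s`` — spacing of the monitoring pulses for time courses
    (3 s by default); ``dt_ms`` — trace sampling step;
    ``perfusion_tau`` — first-order solution-exchange lag in s (0 =
    instantaneous); ``inactivation_scale`` — optional amplitude factor for
    depolarized holding (e.g. 0.9 to emulate slow inactivation; it scales
    control and toxin traces alike and must leave the ratio analysis
    untouched); ``activation_power`` — exponent of the activation kinetics
    (4 for a Hodgkin-Huxley-like delay, 1 for plain exponential).
    """

    seed: int | None = None
    noise_sd: float = 0.01
    table_noise_sd: float = 0.10
    pulse_interval_s: float = 3.0
    dt_ms: float = 0.5
    perfusion_tau: float = 0.0
    inactivation_scale: float = 1.0
    activation_power: int = 4

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.table_noise_sd < 0:
            raise ValueError("noise levels must be >= 0")
        if self.pulse_interval_s <= 0 or self.dt_ms <= 0:
            raise ValueError("sampling intervals must be positive")
        if self.perfusion_tau < 0:
            raise ValueError("perfusion_tau must be >= 0")

    def rng(self, needs_noise: bool = True) -> np.random.Generator:
        if needs_noise and self.seed is None:
            raise ValueError("seed is mandatory for any stochastic output")
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class ScheduleSegment:
    """One perfusion interval: [t_start, t_end) s at a toxin concentration.

    Optional per-segment rate overrides express a change of recording
    solution (e.g. alternating high-K+/high-Na+ wash-out, where the
    dissociation rate follows the solution currently being perfused).
    """

    t_start: float
    t_end: float
    tx_conc: float  # uM
    k_on: float | None = None
    k_off: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("segment must have positive duration")
        if self.tx_conc < 0:
            raise ValueError("toxin concentration must be >= 0")


def simple_wash_schedule(
    duration: float, app_start: float, app_end: float, tx_conc: float
) -> list[ScheduleSegment]:
    """Pre-application / application / recovery schedule for one wash cycle."""
    if not 0.0 <= app_start < app_end <= duration:
        raise ValueError("application window must lie inside [0, duration]")
    segments = []
    if app_start > 0:
        segments.append(ScheduleSegment(0.0, app_start, 0.0, label="pre"))
    segments.append(ScheduleSegment(app_start, app_end, tx_conc, label="on"))
    if app_end < duration:
        segments.append(ScheduleSegment(app_end, duration, 0.0, label="off"))
    return segments


def _check_schedule(schedule: Sequence[ScheduleSegment]) -> list[ScheduleSegment]:
    segs = sorted(schedule, key=lambda s: s.t_start)
    for a, b in zip(segs, segs[1:]):
        if b.t_start < a.t_end - 1e-12:
            raise ValueError(
                f"overlapping schedule segments at t = {b.t_start:g} s"
            )
    return segs


def gen_block_timecourse(
    config: GeneratorConfig,
    k_on: float,
    k_off: float,
    tx_conc: float,
    schedule: Sequence[ScheduleSegment],
    condition_label: str = "",
) -> BlockTimeCourse:
    """Integrate the two-state binding ODE over a perfusion schedule.

    ``dB/dt = k_on [Tx] (1 - B) - k_off B`` piecewise over the schedule
    (exact piecewise-exponential solution when ``perfusion_tau`` is 0,
    numerical integration of the lagged [Tx] otherwise), sampled every
    ``pulse_interval_s`` as the unblocked amplitude ``1 - B``, with seeded
    additive Gaussian noise.
    """
    segs = _check_schedule(schedule)
    t_end = segs[-1].t_end
    times = np.arange(0.0, t_end + 1e-9, config.pulse_interval_s)

    if config.perfusion_tau == 0.0:
        blocked = np.empty_like(times)
        b = 0.0
        t_prev = 0.0
        idx = 0
        for seg in segs:
            kon = seg.k_on if seg.k_on is not None else k_on
            koff = seg.k_off if seg.k_off is not None else k_off
            occ = kon * seg.tx_conc
            rate = occ + koff
            b_inf = occ / rate if rate > 0 else 0.0
            # roll the state to the segment start (handles schedule gaps)
            if seg.t_start > t_prev:
                b = b * math.exp(-k_off * (seg.t_start - t_prev))
            while idx < times.size and times[idx] <= seg.t_end + 1e-9:
                dt = times[idx] - seg.t_start
                if dt < -1e-9:
                    blocked[idx] = b
                else:
                    blocked[idx] = b_inf + (b - b_inf) * math.exp(-rate * dt)
                idx += 1
            b = b_inf + (b - b_inf) * math.exp(-rate * (seg.t_end - seg.t_start))
            t_prev = seg.t_end
        while idx < times.size:  # pragma: no cover - guard for fp rounding
            blocked[idx] = b
            idx += 1
    else:
        def target_tx(t: float) -> float:
            for seg in segs:
                if seg.t_start <= t < seg.t_end:
                    return seg.tx_conc
            return 0.0

        def seg_rates(t: float) -> tuple[float, float]:
            for seg in segs:
                if seg.t_start <= t < seg.t_end:
                    return (
                        seg.k_on if seg.k_on is not None else k_on,
                        seg.k_off if seg.k_off is not None else k_off,
                    )
            return k_on, k_off

        def rhs(t: float, y: np.ndarray) -> list[float]:
            tx_eff, b = y
            kon, koff = seg_rates(t)
            dtx = (target_tx(t) - tx_eff) / config.perfusion_tau
            db = kon * tx_eff * (1.0 - b) - koff * b
            return [dtx, db]

        sol = solve_ivp(
            rhs, (0.0, t_end), [0.0, 0.0], t_eval=times, max_step=config.perfusion_tau / 2,
            rtol=1e-8, atol=1e-10,
        )
        blocked = sol.y[1]

    amplitudes = 1.0 - blocked
    if config.noise_sd > 0:
        rng = config.rng()
        amplitudes = amplitudes + rng.normal(0.0, config.noise_sd, size=amplitudes.shape)
        amplitudes = np.clip(amplitudes, 0.0, None)

    app = [s for s in segs if s.tx_conc > 0]
    window = (app[0].t_start, app[-1].t_end) if app else (times[0], times[0])
    return BlockTimeCourse(
        times=times,
        amplitudes=amplitudes,
        toxin_conc=tx_conc,
        application_window=window,
        condition_label=condition_label,
    )


def gen_trace_family(
    config: GeneratorConfig,
    scheme: SchemeParams,
    koff0: float,
    activation_tau: float | Mapping[float, float] | Callable[[float], float],
    v_list: Sequence[float],
    holding_voltage: float = -120.0,
    t_max_ms: float = 200.0,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> list[TracePair]:
    """Families of voltage-step trace pairs under the state model.

    The control trace is a delayed activation
    ``(1 - exp(-t/tau_act))**activation_power`` (unit steady-state
    amplitude); the toxin trace is the control multiplied by the binding
    relaxation ``U(t) = U_inf + (U_0 - U_inf) exp(-t/tau(V))`` whose start
    ``U_0`` is the resting unblocked fraction at the holding voltage and
    whose ``U_inf``/``tau`` follow the open-channel two-state solution at
    ``K_DO(V)``.  ``koff0`` (s^-1, at V = 0) sets the absolute kinetic
    scale; the association rate is voltage independent,
    ``k_on = 1000 koff0 / K_DO(0)`` uM^-1 s^-1.
    """
    if koff0 <= 0:
        raise ValueError("koff0 must be positive")

    if callable(activation_tau):
        tau_act_of = activation_tau
    elif isinstance(activation_tau, Mapping):
        tau_act_of = lambda v: activation_tau[v]  # noqa: E731
    else:
        tau_act_of = lambda v: float(activation_tau)  # noqa: E731

    tx_nm = scheme.toxin_conc
    tx_um = tx_nm / 1e3
    k_on = 1e3 * koff0 / scheme.kdo0  # uM^-1 s^-1
    u0 = float(unblocked_fraction(holding_voltage, scheme, constants))
    rng = config.rng() if config.noise_sd > 0 else None

    pairs: list[TracePair] = []
    for v in v_list:
        tau_a = float(tau_act_of(v))
        if tau_a <= 0:
            raise ValueError("activation_tau must be positive at every voltage")
        t = np.arange(0.0, t_max_ms + 1e-9, config.dt_ms)
        control = (1.0 - np.exp(-t / tau_a)) ** config.activation_power
        koff_v = koff0 * constants.boltzmann_factor(scheme.z_tox, v)
        kdo_v = float(kdo_at_voltage(scheme.kdo0, scheme.z_tox, v, constants))
        u_inf = 1.0 / (1.0 + tx_nm / kdo_v)
        tau_ms = 1e3 / (k_on * tx_um + koff_v)
        u = u_inf + (u0 - u_inf) * np.exp(-t / tau_ms)
        toxin = control * u
        scale = config.inactivation_scale if holding_voltage >= -60.0 else 1.0
        control = control * scale
        toxin = toxin * scale
        if rng is not None:
            control = control + rng.normal(0.0, config.noise_sd, size=t.shape)
            toxin = toxin + rng.normal(0.0, config.noise_sd, size=t.shape)
        pairs.append(
            TracePair(
                times=t,
                control_current=control,
                toxin_current=toxin,
                step_voltage=float(v),
                holding_voltage=float(holding_voltage),
                toxin_conc=tx_um,
            )
        )
    return pairs


def gen_titration_table(
    config: GeneratorConfig,
    true_params: LangmuirParams,
    k_grid: Sequence[float] = DEFAULT_K_GRID,
    replicates: int = 1,
    kind: str | None = None,
) -> list[TitrationPoint]:
    """Langmuir model values on a concentration grid with log-normal noise."""
    if len(k_grid) == 0:
        raise ValueError("concentration grid must be non-empty")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    kind = kind or true_params.kind
    rng = config.rng() if config.table_noise_sd > 0 else None
    points: list[TitrationPoint] = []
    for r in range(replicates):
        for k in k_grid:
            value = float(langmuir_eval(true_params, k))
            if rng is not None:
                value *= math.exp(rng.normal(0.0, config.table_noise_sd))
            points.append(
                TitrationPoint(k_conc=float(k), value=value, kind=kind, cell_id=f"cell{r}")
            )
    return points


def gen_tonic_table(
    config: GeneratorConfig,
    scheme: SchemeParams,
    vh_list: Sequence[float],
    v_open_list: Sequence[float],
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> list[TonicPoint]:
    """Biphasic tonic-inhibition curve: resting points plus open asymptotes.

    Both regimes are model evaluations of the unblocked fraction; the
    regime label records whether the voltage is a holding potential or the
    asymptote of an open-channel relaxation.  Additive Gaussian noise,
    clipped to [0, 1].
    """
    if len(vh_list) == 0 or len(v_open_list) == 0:
        raise ValueError("both voltage lists must be non-empty")
    rng = config.rng() if config.noise_sd > 0 else None

    def make(v: float, regime: str) -> TonicPoint:
        u = float(unblocked_fraction(v, scheme, constants))
        if rng is not None:
            u = float(np.clip(u + rng.normal(0.0, config.noise_sd), 0.0, 1.0))
        return TonicPoint(voltage=float(v), inhibition_ratio=u, regime=regime)

    return [make(v, "resting") for v in vh_list] + [make(v, "open") for v in v_open_list]
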