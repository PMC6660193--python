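"""Unbinding energetics: Eyring inversion and the wobbling contact network.

Macroscopic blocker dissociation is treated as a rare escape over an
activation barrier, ``k_off = A0 exp(-dG++/RT)``, with attempt frequency
``A0`` (default 6e12 s^-1, the transition-state-theory frequency factor at a
transmission coefficient of 1).  The bound complex is pictured as ``n``
independent contact points, each in a fast local bind/unbind equilibrium
``K_j = k_joff / k_jon``; the complex dissolves only when all contacts are
simultaneously unbound, so that

    k_off = A0 * K1 K2 ... Kn * exp(sum(z_j) F V / RT)

(additivity of per-contact barrier energies is the same statement as the
product of equilibrium constants).  Voltage acts through the re-binding rate
of the designated (selectivity-filter) contacts:
``K_j(V) = K_j exp(z_j F V/RT)`` with a voltage-independent local off rate.

A continuous-time Markov simulation over the 2^n contact configurations,
plus an absorbing exit taken at the escape frequency while all contacts are
unbound, provides a numerical oracle for this picture; the exact mean
lifetime is available from a dense mean-first-passage solve on the same
generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import DEFAULT_CONSTANTS, PhysicalConstants

__all__ = [
    "EnergeticsParams",
    "ContactEquilibrium",
    "ContactNetwork",
    "NetworkSimResult",
    "DEFAULT_ATTEMPT_FREQUENCY",
    "barrier_from_rate",
    "rate_from_barrier",
    "per_contact_energy",
    "contact_kj_voltage",
    "composite_koff",
    "equilibrium_koff",
    "mean_first_passage_lifetime",
    "simulate_contact_network",
]

#: s^-1; the "6 ps^-1" transition-state frequency factor.
DEFAULT_ATTEMPT_FREQUENCY = 6e12


@dataclass(frozen=True)
class EnergeticsParams:
    """Attempt frequency (s^-1), barrier (kJ/mol) and contact count."""

    attempt_frequency: float = DEFAULT_ATTEMPT_FREQUENCY
    barrier: float = 0.0
    n_contacts: int = 1
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if self.attempt_frequency <= 0:
            raise ValueError("attempt frequency must be positive")
        if self.n_contacts < 1:
            raise ValueError("need at least one contact")
        if self.barrier < 0:
            raise ValueError("barrier must be >= 0")


@dataclass(frozen=True)
class ContactEquilibrium:
    """One local bind/unbind equilibrium of the interaction surface.

    Either ``k_eq`` alone (for the analytic product formulas) or the local
    rate pair ``local_off``/``local_on`` (required by the simulator and the
    mean-first-passage oracle) may be given; when both are present they must
    agree, ``k_eq = local_off / local_on``.  ``valence`` is the effective
    charge of the contact's voltage dependence (zero for voltage-insensitive
    contacts).
    """

    k_eq: float | None = None
    local_off: float | None = None
    local_on: float | None = None
    valence: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.local_off is not None and self.local_on is not None:
            if self.local_off <= 0 or self.local_on <= 0:
                raise ValueError("local rates must be positive")
            implied = self.local_off / self.local_on
            if self.k_eq is None:
                object.__setattr__(self, "k_eq", implied)
            elif not math.isclose(self.k_eq, implied, rel_tol=1e-9):
                raise ValueError("k_eq inconsistent with local_off/local_on")
        elif (self.local_off is None) != (self.local_on is None):
            raise ValueError("give both local rates or neither")
        if self.k_eq is None:
            raise ValueError("either k_eq or a local rate pair is required")
        if self.k_eq <= 0:
            raise ValueError("k_eq must be positive")

    @property
    def has_rates(self) -> bool:
        return self.local_off is not None

    @classmethod
    def from_k_eq(
        cls, k_eq: float, local_off: float, valence: float = 0.0, label: str = ""
    ) -> "ContactEquilibrium":
        """Build a contact with explicit kinetics from (K, k_off_local)."""
        return cls(local_off=local_off, local_on=local_off / k_eq, valence=valence, label=label)


@dataclass(frozen=True)
class ContactNetwork:
    """n independent contact equilibria plus a final escape frequency.

    ``voltage_mode`` selects where the voltage dependence of a contact acts:
    on the local re-binding rate (``"rebinding"``, the default physical
    reading) or on the local dissociation rate (``"unbinding"``, for
    sensitivity analysis).  The analytic product formulas are identical in
    both modes.
    """

    contacts: tuple[ContactEquilibrium, ...]
    escape_frequency: float
    voltage: float = 0.0
    voltage_mode: str = "rebinding"

    def __init__(
        self,
        contacts: Sequence[ContactEquilibrium],
        escape_frequency: float,
        voltage: float = 0.0,
        voltage_mode: str = "rebinding",
    ) -> None:
        if len(contacts) < 1:
            raise ValueError("need at least one contact")
        if escape_frequency <= 0:
            raise ValueError("escape frequency must be positive")
        if voltage_mode not in ("rebinding", "unbinding"):
            raise ValueError("voltage_mode must be 'rebinding' or 'unbinding'")
        object.__setattr__(self, "contacts", tuple(contacts))
        object.__setattr__(self, "escape_frequency", float(escape_frequency))
        object.__setattr__(self, "voltage", float(voltage))
        object.__setattr__(self, "voltage_mode", voltage_mode)

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)

    def local_rates(
        self, constants: PhysicalConstants = DEFAULT_CONSTANTS
    ) -> tuple[np.ndarray, np.ndarray]:
        """(off, on) local rates per contact with the voltage applied."""
        if not all(c.has_rates for c in self.contacts):
            raise ValueError("simulation requires local rate pairs on every contact")
        off = np.array([c.local_off for c in self.contacts], dtype=float)
        on = np.array([c.local_on for c in self.contacts], dtype=float)
        bf = np.array(
            [constants.boltzmann_factor(c.valence, self.voltage) for c in self.contacts]
        )
        if self.voltage_mode == "rebinding":
            on = on / bf
        else:
            off = off * bf
        return off, on


@dataclass
class NetworkSimResult:
    """Outcome of a contact-network simulation."""

    mean_lifetime: float
    sem_lifetime: float
    lifetimes: np.ndarray
    exposure_fraction: np.ndarray  # per-contact fraction of time unbound
    n_events: int
    seed: int


def barrier_from_rate(
    k_off: float,
    a0: float = DEFAULT_ATTEMPT_FREQUENCY,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Activation barrier dG++ = RT ln(A0/k_off) in kJ/mol (Eyring inversion)."""
    if k_off <= 0 or a0 <= 0:
        raise ValueError("rates must be positive")
    if k_off > a0:
        raise ValueError("negative barrier: k_off exceeds the attempt frequency")
    return constants.rt_kj_per_mol * math.log(a0 / k_off)


def rate_from_barrier(
    barrier: float,
    a0: float = DEFAULT_ATTEMPT_FREQUENCY,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Forward Eyring evaluation k_off = A0 exp(-dG++/RT)."""
    if barrier < 0:
        raise ValueError("barrier must be >= 0")
    return a0 * math.exp(-barrier / constants.rt_kj_per_mol)


def per_contact_energy(
    barrier: float,
    n: int,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> tuple[float, float]:
    """Share a barrier over n identical contacts.

    Returns ``(energy_kT, p_unbound)``: the per-contact energy in kT units
    and the fraction of time an independent contact spends unbound,
    ``exp(-energy_kT)``.
    """
    if n < 1:
        raise ValueError("need at least one contact")
    energy_kt = barrier / n / constants.rt_kj_per_mol
    return energy_kt, math.exp(-energy_kt)


def contact_kj_voltage(
    contact: ContactEquilibrium,
    v: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Voltage-dependent local equilibrium K_j(V) = K_j exp(z_j F V/RT)."""
    return contact.k_eq * constants.boltzmann_factor(contact.valence, v)


def composite_koff(
    network: ContactNetwork,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Product-form macroscopic rate A0 * prod(K_i) * exp(sum z_j F V/RT).

    This is the small-K limit in which the all-unbound probability is the
    plain product of the local equilibrium constants.
    """
    k = network.escape_frequency
    for c in network.contacts:
        k *= contact_kj_voltage(c, network.voltage, constants)
    return k


def equilibrium_koff(
    network: ContactNetwork,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Escape frequency times the exact equilibrium all-unbound probability.

    Each independent contact is unbound a fraction K/(1+K) of the time, so
    the predicted rate is ``A * prod(K_i/(1+K_i))`` — the quantity the mean
    first-passage time approaches under separation of timescales.
    """
    k = network.escape_frequency
    for c in network.contacts:
        kj = contact_kj_voltage(c, network.voltage, constants)
        k *= kj / (1.0 + kj)
    return k


# ---------------------------------------------------------------------------
# exact oracle and stochastic simulation
# ---------------------------------------------------------------------------


def _transition_table(
    network: ContactNetwork, constants: PhysicalConstants
) -> tuple[list[list[tuple[float, int]]], int]:
    """Per-state transition lists over the 2^n configuration space.

    State bit j set means contact j is unbound; state ``2**n`` is the
    absorbing (dissociated) pseudo-state.
    """
    off, on = network.local_rates(constants)
    n = network.n_contacts
    n_states = 1 << n
    absorb = n_states
    table: list[list[tuple[float, int]]] = []
    for s in range(n_states):
        moves: list[tuple[float, int]] = []
        for j in range(n):
            bit = 1 << j
            if s & bit:
                moves.append((on[j], s & ~bit))
            else:
                moves.append((off[j], s | bit))
        if s == n_states - 1:
            moves.append((network.escape_frequency, absorb))
        table.append(moves)
    return table, absorb


def mean_first_passage_lifetime(
    network: ContactNetwork,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    start_state: int = 0,
) -> float:
    """Exact mean complex lifetime by a dense mean-first-passage solve.

    Builds the full generator over the 2^n transient configurations and
    solves ``(-Q) tau = 1``; feasible for n <= ~12 contacts.  The default
    start is the all-bound configuration.
    """
    table, absorb = _transition_table(network, constants)
    n_states = len(table)
    m = np.zeros((n_states, n_states))
    for s, moves in enumerate(table):
        for rate, dest in moves:
            m[s, s] += rate
            if dest != absorb:
                m[s, dest] -= rate
    tau = np.linalg.solve(m, np.ones(n_states))
    return float(tau[start_state])


def simulate_contact_network(
    network: ContactNetwork,
    n_events: int,
    seed: int,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    min_separation: float = 10.0,
) -> NetworkSimResult:
    """Gillespie simulation of the wobbling network until dissociation.

    Each event starts from the all-bound configuration and runs the
    continuous-time Markov chain over the 2^n contact states until the
    absorbing exit (taken at the escape frequency while every contact is
    simultaneously unbound) fires.  Returns the empirical mean complex
    lifetime, all lifetime samples, and the per-contact fraction of time
    spent unbound, reproducibly under a fixed seed.

    The analytic product description only holds when contact exchange is
    much faster than dissociation; the slowest local rate must exceed
    ``min_separation`` times the predicted composite rate or the call is
    rejected.
    """
    if n_events < 100:
        raise ValueError("need at least 100 events for meaningful statistics")
    off, on = network.local_rates(constants)
    predicted = equilibrium_koff(network, constants)
    slowest = float(min(off.min(), on.min()))
    if slowest < min_separation * predicted:
        raise ValueError(
            "timescale precondition violated: local rates are not "
            f">= {min_separation:g}x the predicted composite k_off "
            f"({slowest:.3g} vs {predicted:.3g} s^-1); the analytic product "
            "formula is not expected to hold"
        )

    table, absorb = _transition_table(network, constants)
    n_states = len(table)
    totals = [sum(r for r, _ in moves) for moves in table]
    inv_totals = [1.0 / t for t in totals]
    cum_probs = [
        list(np.cumsum([r for r, _ in moves]) / totals[s])
        for s, moves in enumerate(table)
    ]
    dests = [[d for _, d in moves] for moves in table]
    last = [len(d) - 1 for d in dests]

    from bisect import bisect_right

    rng = np.random.default_rng(seed)
    chunk = 1 << 16
    e_buf = rng.standard_exponential(chunk)
    u_buf = rng.random(chunk)
    ei = ui = 0
    lifetimes = np.empty(n_events)
    dwell = [0.0] * n_states
    for ev in range(n_events):
        s = 0
        t = 0.0
        while s != absorb:
            if ei == chunk:
                e_buf = rng.standard_exponential(chunk)
                ei = 0
            if ui == chunk:
                u_buf = rng.random(chunk)
                ui = 0
            step = e_buf[ei] * inv_totals[s]
            ei += 1
            dwell[s] += step
            t += step
            k = bisect_right(cum_probs[s], u_buf[ui])
            ui += 1
            s = dests[s][k if k <= last[s] else last[s]]
        lifetimes[ev] = t
    dwell = np.asarray(dwell)

    total_time = dwell.sum()
    n = network.n_contacts
    exposure = np.array(
        [dwell[[s for s in range(n_states) if s & (1 << j)]].sum() for j in range(n)]
    ) / total_time
    return NetworkSimResult(
        mean_lifetime=float(lifetimes.mean()),
        sem_lifetime=float(lifetimes.std(ddof=1) / math.sqrt(n_events)),
        lifetimes=lifetimes,
        exposure_fraction=exposure,
        n_events=n_events,
        seed=seed,
    )
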