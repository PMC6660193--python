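"""Configuration schema and the simulate -> fit -> energetics pipeline.

``RunConfig`` is schema-validated (unknown keys rejected) before any stage
runs.  ``run_pipeline`` exercises the whole analysis on synthetic data: it
generates a wash time course, a voltage-step trace family, rate titration
tables and a tonic-inhibition curve from the configured true parameters,
runs every fitter, and derives the downstream quantities (fold changes,
half-saturation ratio, activation barrier, per-contact energies, a small
contact-network simulation against its exact oracle).  The JSON report
carries the seed and all fitted parameters needed to reproduce it.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import energetics as en
from . import relaxation as rx
from . import state_model as sm
from . import synthetic as syn
from . import titration as ti
from .constants import PhysicalConstants

__all__ = ["RunConfig", "run_pipeline", "default_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ConstantsBlock(_Strict):
    temperature: float = 298.15


class TimecourseBlock(_Strict):
    """Wash-in/wash-out scenario (high-affinity block, nM-range toxin)."""

    k_on: float = 73.0  # uM^-1 s^-1
    k_off: float = 0.0062  # s^-1
    tx_conc_uM: float = 2.5e-4
    app_start_s: float = 60.0
    app_end_s: float = 300.0
    duration_s: float = 1000.0
    noise_sd: float = 0.01


class RelaxationBlock(_Strict):
    """Open-channel relaxation scenario (trace-ratio analysis)."""

    kdc: float = 1.84  # nM
    kdo0: float = 1.7  # nM
    z_tox: float = 0.29
    z_gate: float = 3.9
    v_half: float = -66.0
    toxin_nM: float = 5.0
    koff0: float = 5.6  # s^-1
    v_list: list[float] = Field(default_factory=lambda: [30.0, 40.0, 50.0, 60.0])
    replicates: int = 5
    activation_tau_ms: float = 2.0
    noise_sd: float = 0.02
    guard_fraction: float = 0.10
    t_max_ms: float = 250.0


class TitrationBlock(_Strict):
    koff_at_zero: float = 0.0061
    koff_at_sat: float = 0.022
    koff_half_sat: float = 135.0
    kon_at_zero: float = 120.0
    kon_at_sat: float = 56.0
    kon_half_sat: float = 0.56
    replicates: int = 3
    noise_sd: float = 0.10


class TonicBlock(_Strict):
    kdc: float = 1.84
    kdo0: float = 1.7
    z_tox: float = 0.29
    z_gate: float = 3.9
    v_half: float = -66.0
    toxin_nM: float = 5.0
    vh_list: list[float] = Field(
        default_factory=lambda: list(np.arange(-120.0, -50.0, 10.0))
    )
    v_open_list: list[float] = Field(
        default_factory=lambda: list(np.arange(-30.0, 70.0, 10.0))
    )
    noise_sd: float = 0.03


class EnergeticsBlock(_Strict):
    attempt_frequency: float = en.DEFAULT_ATTEMPT_FREQUENCY
    n_contacts: int = 10
    sim_n_contacts: int = 2
    sim_k_eq: float = 0.1
    sim_escape: float = 1e4  # scaled-down escape frequency
    sim_local_off: float = 1e3
    sim_events: int = 300


class RunConfig(_Strict):
    seed: int
    constants: ConstantsBlock = Field(default_factory=ConstantsBlock)
    timecourse: TimecourseBlock = Field(default_factory=TimecourseBlock)
    relaxation: RelaxationBlock = Field(default_factory=RelaxationBlock)
    titration: TitrationBlock = Field(default_factory=TitrationBlock)
    tonic: TonicBlock = Field(default_factory=TonicBlock)
    energetics: EnergeticsBlock = Field(default_factory=EnergeticsBlock)


def default_config(seed: int = 1) -> RunConfig:
    return RunConfig(seed=seed)


def _seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def _stage_timecourse(cfg: TimecourseBlock, seed: int) -> dict:
    gen = syn.GeneratorConfig(seed=seed, noise_sd=cfg.noise_sd)
    course = syn.gen_block_timecourse(
        gen,
        cfg.k_on,
        cfg.k_off,
        cfg.tx_conc_uM,
        syn.simple_wash_schedule(cfg.duration_s, cfg.app_start_s, cfg.app_end_s, cfg.tx_conc_uM),
    )
    fit_on = rx.fit_block_phase(course, "on")
    fit_off = rx.fit_block_phase(course, "off")
    rates = rx.rates_from_on_off(fit_on.tau, fit_off.tau, cfg.tx_conc_uM)
    return {
        "tau_on_s": fit_on.tau,
        "tau_off_s": fit_off.tau,
        "k_on_per_uM_s": rates.k_on,
        "k_off_per_s": rates.k_off,
        "k_d_nM": rates.k_d,
        "converged": not (fit_on.no_relaxation or fit_off.no_relaxation),
    }


def _stage_relaxation(
    cfg: RelaxationBlock, seed: int, constants: PhysicalConstants
) -> dict:
    scheme = sm.SchemeParams(
        kdc=cfg.kdc, kdo0=cfg.kdo0, z_tox=cfg.z_tox,
        z_gate=cfg.z_gate, v_half=cfg.v_half, toxin_conc=cfg.toxin_nM,
    )
    families = []
    for rep_seed in _seeds(seed, cfg.replicates):
        gen = syn.GeneratorConfig(seed=rep_seed, noise_sd=cfg.noise_sd)
        families.append(
            syn.gen_trace_family(
                gen, scheme, cfg.koff0, cfg.activation_tau_ms, cfg.v_list,
                t_max_ms=cfg.t_max_ms, constants=constants,
            )
        )
    points: list[rx.RelaxationPoint] = []
    for i in range(len(cfg.v_list)):
        averaged = rx.average_trace_pairs([fam[i] for fam in families])
        point = rx.relaxation_from_pair(averaged, cfg.guard_fraction)
        if point is not None:
            points.append(point)
    tx_um = cfg.toxin_nM / 1e3
    per_voltage = rx.average_then_solve(points, tx_um)
    koff_fit = rx.fit_voltage_dependence(
        [(v, rs.k_off) for v, rs in per_voltage.items()], constants
    )
    kon_fit = rx.fit_voltage_dependence(
        [(v, rs.k_on) for v, rs in per_voltage.items()], constants
    )
    return {
        "per_voltage": {
            str(v): {"k_on": rs.k_on, "k_off": rs.k_off, "n_cells": rs.n_cells}
            for v, rs in per_voltage.items()
        },
        "koff_at_zero_per_s": koff_fit.k_at_zero,
        "koff_z_delta": koff_fit.z_delta,
        "kon_at_zero_per_uM_s": kon_fit.k_at_zero,
        "kon_z_delta": kon_fit.z_delta,
        "converged": len(per_voltage) >= 2,
    }


def _stage_titration(cfg: TitrationBlock, seed: int) -> dict:
    s_off, s_on = _seeds(seed, 2)
    true_off = ti.LangmuirParams(cfg.koff_at_zero, cfg.koff_at_sat, cfg.koff_half_sat, kind="k_off")
    true_on = ti.LangmuirParams(cfg.kon_at_zero, cfg.kon_at_sat, cfg.kon_half_sat, kind="k_on")
    fit_off = ti.fit_langmuir(
        syn.gen_titration_table(
            syn.GeneratorConfig(seed=s_off, table_noise_sd=cfg.noise_sd),
            true_off, replicates=cfg.replicates,
        )
    )
    fit_on = ti.fit_langmuir(
        syn.gen_titration_table(
            syn.GeneratorConfig(seed=s_on, table_noise_sd=cfg.noise_sd),
            true_on, replicates=cfg.replicates,
        )
    )
    up, down = ti.fold_changes(fit_off)
    return {
        "koff_fit": {"at_zero": fit_off.at_zero, "at_sat": fit_off.at_sat,
                     "half_sat_mM": fit_off.half_sat,
                     "poorly_identified": fit_off.poorly_identified},
        "kon_fit": {"at_zero": fit_on.at_zero, "at_sat": fit_on.at_sat,
                    "half_sat_mM": fit_on.half_sat,
                    "poorly_identified": fit_on.poorly_identified},
        "koff_fold_increase": up,
        "kd_fold_increase": (fit_off.at_sat / fit_off.at_zero)
        * (fit_on.at_zero / fit_on.at_sat),
        "s1_availability_lower_bound": ti.s1_availability(fit_on.half_sat, fit_off.half_sat),
        "converged": True,
    }


def _stage_tonic(cfg: TonicBlock, seed: int, constants: PhysicalConstants) -> dict:
    scheme = sm.SchemeParams(
        kdc=cfg.kdc, kdo0=cfg.kdo0, z_tox=cfg.z_tox,
        z_gate=cfg.z_gate, v_half=cfg.v_half, toxin_conc=cfg.toxin_nM,
    )
    gen = syn.GeneratorConfig(seed=seed, noise_sd=cfg.noise_sd)
    points = syn.gen_tonic_table(gen, scheme, cfg.vh_list, cfg.v_open_list, constants)
    fit = sm.fit_tonic_inhibition(points, cfg.toxin_nM, constants)
    p = fit.params
    return {
        "kdc_nM": p.kdc,
        "kdo0_nM": p.kdo0,
        "z_tox": p.z_tox,
        "z_gate": p.z_gate,
        "v_half_mV": p.v_half,
        "kv2_over_kv1": sm.kv2_from_cycle(1.0, p.kdc, p.kdo0),
        "gating_shift_mV": sm.gating_shift(p.kdc, p.kdo0, p.z_gate, constants),
        "converged": fit.success,
    }


def _stage_energetics(
    cfg: EnergeticsBlock, seed: int, koff_slow: float, koff_fast: float,
    constants: PhysicalConstants,
) -> dict:
    barrier_slow = en.barrier_from_rate(koff_slow, cfg.attempt_frequency, constants)
    barrier_fast = en.barrier_from_rate(koff_fast, cfg.attempt_frequency, constants)
    e_kt, p_unbound = en.per_contact_energy(barrier_slow, cfg.n_contacts, constants)
    network = en.ContactNetwork(
        [
            en.ContactEquilibrium.from_k_eq(cfg.sim_k_eq, cfg.sim_local_off)
            for _ in range(cfg.sim_n_contacts)
        ],
        escape_frequency=cfg.sim_escape,
    )
    sim = en.simulate_contact_network(network, cfg.sim_events, seed, constants)
    oracle = en.mean_first_passage_lifetime(network, constants)
    return {
        "barrier_slow_kJ_mol": barrier_slow,
        "barrier_fast_kJ_mol": barrier_fast,
        "per_contact_energy_kT": e_kt,
        "per_contact_p_unbound": p_unbound,
        "sim_mean_lifetime_s": sim.mean_lifetime,
        "sim_sem_lifetime_s": sim.sem_lifetime,
        "oracle_mean_lifetime_s": oracle,
        "product_formula_koff_per_s": en.composite_koff(network, constants),
        "exposure_fraction": list(sim.exposure_fraction),
        "converged": abs(sim.mean_lifetime - oracle) < 5 * sim.sem_lifetime,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on synthetic data and return the JSON-able report."""
    constants = PhysicalConstants(temperature=config.constants.temperature)
    seeds = _seeds(config.seed, 5)
    report: dict = {
        "schema_version": 1,
        "seed": config.seed,
        "temperature_K": constants.temperature,
    }
    report["timecourse"] = _stage_timecourse(config.timecourse, seeds[0])
    report["relaxation"] = _stage_relaxation(config.relaxation, seeds[1], constants)
    report["titration"] = _stage_titration(config.titration, seeds[2])
    report["tonic"] = _stage_tonic(config.tonic, seeds[3], constants)
    report["energetics"] = _stage_energetics(
        config.energetics,
        seeds[4],
        koff_slow=report["timecourse"]["k_off_per_s"],
        koff_fast=report["relaxation"]["koff_at_zero_per_s"],
        constants=constants,
    )
    report["converged"] = all(
        report[stage]["converged"]
        for stage in ("timecourse", "relaxation", "titration", "tonic", "energetics")
    )
    return report
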