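"""Implicit integration of the membrane equation on the compartment tree.

Each compartment obeys

    Cm dVm/dt = −g_pas(Vm − Vrest) − Isyn + Iaxial + Iext

with GABA_A synapses modelled as a persistent fluctuating conductance
("gclamp": a mean-reverting Ornstein–Uhlenbeck process clipped at zero) and
the synaptic current split into Cl⁻ and HCO₃⁻ components.  Time stepping is
backward Euler with conductances implicit and, in dynamic-chloride mode,
the ion state advanced in lockstep one operator-split step behind the
voltage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import _solver
from .chloride import IonState, transport_coefficients
from .constants import thermal_voltage
from .morphology import CompartmentGraph, locate

__all__ = [
    "SynapseSpec",
    "StimulusSpec",
    "SimConfig",
    "Recording",
    "run",
    "gclamp_trace",
    "gaba_current_split",
]

# GABA_A two-state kinetic constants (housed for completeness; the persistent
# gclamp conductance used throughout does not gate on transmitter binding).
ALPHA_GABA = 5.0  # mM⁻¹·ms⁻¹
BETA_GABA = 0.18  # ms⁻¹
G_GABA_MAX = 0.001  # μS


@dataclass(frozen=True)
class SynapseSpec:
    """A GABAergic conductance source.

    ``reversal_mode`` is ``"static"`` (fixed Esyn = Vrest + delta_egaba) or
    ``"dynamic"`` (Esyn follows the compartment's EGABA from the ion state;
    in a static-chloride run this reduces to the initial EGABA).
    """

    branch: int = 0
    x: float = 0.2  # electrotonic location
    g_mean: float = G_GABA_MAX  # μS, gclamp mean ⟨g⟩
    noise_sd_fraction: float = 0.1  # stationary sd as fraction of ⟨g⟩
    noise_tau: float = 10.0  # ms, gclamp correlation time
    reversal_mode: str = "static"
    delta_egaba: float = 0.0  # mV, ∇EGABA = Esyn − Vrest (static mode)
    p_cl: float = 0.8  # Cl⁻ permeability fraction (4:1 Cl:HCO3)
    alpha_gaba: float = ALPHA_GABA
    beta_gaba: float = BETA_GABA

    def __post_init__(self) -> None:
        if self.g_mean < 0:
            raise ValueError("mean conductance must be >= 0")
        if self.noise_sd_fraction < 0:
            raise ValueError("noise_sd_fraction must be >= 0")
        if self.noise_tau <= 0:
            raise ValueError("noise_tau must be positive")
        if self.reversal_mode not in ("static", "dynamic"):
            raise ValueError("reversal_mode must be 'static' or 'dynamic'")
        if not 0 <= self.p_cl <= 1:
            raise ValueError("p_cl must lie in [0, 1]")


@dataclass(frozen=True)
class StimulusSpec:
    """Constant current injection (the excitatory probe)."""

    branch: int = 0
    x: float = 0.0
    amplitude: float = 0.001  # nA
    onset: float = 0.0  # ms
    offset: float = math.inf  # ms

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("offset must exceed onset")


@dataclass(frozen=True)
class SimConfig:
    dt: float = 0.025  # ms
    duration: float = 150.0  # ms
    record_dt: float = 0.5  # ms
    seed: int | None = None
    chloride_mode: str = "static"  # or "dynamic"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration < self.record_dt:
            raise ValueError("duration must be at least one record interval")
        if self.chloride_mode not in ("static", "dynamic"):
            raise ValueError("chloride_mode must be 'static' or 'dynamic'")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def record_every(self) -> int:
        return max(1, int(round(self.record_dt / self.dt)))


@dataclass
class Recording:
    """Time series produced by :func:`run`.

    ``vm`` is (n_times, n_comp); ``cl`` and ``egaba_profile`` are present
    only for dynamic-chloride runs.  ``v0`` snapshots the initial state used
    as the baseline of all voltage-deflection integrals.
    """

    times: np.ndarray
    vm: np.ndarray
    v0: np.ndarray
    g_syn: np.ndarray  # (n_times, n_syn)
    syn_comp: np.ndarray  # (n_syn,)
    graph: CompartmentGraph = field(repr=False)
    config: SimConfig = field(repr=False)
    cl: np.ndarray | None = None
    egaba_profile: np.ndarray | None = None

    def vm_at(self, comp: int) -> np.ndarray:
        return self.vm[:, comp]

    def egaba_at(self, comp: int, t: float) -> float:
        if self.egaba_profile is None:
            raise ValueError("no chloride state recorded (static run)")
        idx = int(np.argmin(np.abs(self.times - t)))
        return float(self.egaba_profile[idx, comp])

    def to_frame(self, compartments: Sequence[int] | None = None) -> pd.DataFrame:
        """Tidy time × variable table (voltage, and ion state if recorded)."""
        comps = (
            np.arange(self.vm.shape[1])
            if compartments is None
            else np.asarray(list(compartments))
        )
        data = {"t": self.times}
        for c in comps:
            data[f"vm_{c}"] = self.vm[:, c]
            if self.cl is not None:
                data[f"cl_{c}"] = self.cl[:, c]
                data[f"egaba_{c}"] = self.egaba_profile[:, c]
        return pd.DataFrame(data)


def gclamp_trace(
    spec: SynapseSpec,
    duration: float,
    dt: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-step conductance trace of the persistent fluctuating synapse.

    Exact discretisation of a mean-reverting (OU) process with mean ⟨g⟩,
    stationary standard deviation ``noise_sd_fraction·⟨g⟩`` and correlation
    time ``noise_tau``, started from a stationary draw and clipped at zero.
    ``noise_sd_fraction = 0`` yields a constant trace (deterministic mode).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n_steps = int(round(duration / dt))
    sigma = spec.noise_sd_fraction * spec.g_mean
    if sigma == 0.0:
        return np.full(n_steps, spec.g_mean)
    if rng is None:
        rng = np.random.default_rng()
    rho = math.exp(-dt / spec.noise_tau)
    innov_sd = sigma * math.sqrt(1.0 - rho * rho)
    g = np.empty(n_steps)
    dev = sigma * rng.standard_normal()
    noise = rng.standard_normal(n_steps)
    for k in range(n_steps):
        g[k] = spec.g_mean + dev
        dev = rho * dev + innov_sd * noise[k]
    np.clip(g, 0.0, None, out=g)
    return g


def gaba_current_split(g, vm, e_cl, e_hco3, e_gaba):
    """Split the GABA_A current into (ICl, IHCO3) with the chloride fraction
    χ = (EHCO3 − EGABA)/(EHCO3 − ECl); ICl + IHCO3 = g·(Vm − EGABA) exactly.
    """
    if np.any(np.isclose(e_hco3, e_cl)):
        raise ValueError("degenerate reversal potentials: EHCO3 == ECl")
    chi = (e_hco3 - e_gaba) / (e_hco3 - e_cl)
    i_cl = chi * g * (vm - e_cl)
    i_hco3 = (1.0 - chi) * g * (vm - e_hco3)
    return i_cl, i_hco3


def _synapse_seeds(seed: int | None, n: int) -> list[np.random.Generator]:
    seq = np.random.SeedSequence(seed if seed is not None else 0)
    return [np.random.default_rng(s) for s in seq.spawn(max(n, 1))]


def run(
    graph: CompartmentGraph,
    synapses: Sequence[SynapseSpec] = (),
    stimuli: Sequence[StimulusSpec] = (),
    config: SimConfig = SimConfig(),
    ion_state: IonState | None = None,
) -> Recording:
    """Simulate the tree and return a :class:`Recording`.

    Paired IL protocols call this twice — once without and once with the
    inhibitory synapses — sharing ``stimuli`` and ``config``.  With a given
    seed the result is bitwise reproducible.
    """
    n_steps = config.n_steps
    dt = config.dt
    n_syn = len(synapses)
    dynamic_cl = config.chloride_mode == "dynamic"

    if dynamic_cl or any(s.reversal_mode == "dynamic" for s in synapses):
        if ion_state is None:
            ion_state = IonState.for_graph(graph)
        if ion_state.cl_i.shape[0] != graph.n_comp:
            raise ValueError("ion state does not match the graph")

    syn_comp = np.array(
        [locate(graph, s.branch, s.x) for s in synapses], dtype=np.int64
    )
    syn_dynamic = np.array(
        [s.reversal_mode == "dynamic" for s in synapses], dtype=np.bool_
    )
    syn_erev = np.empty(max(n_syn, 1))
    for i, s in enumerate(synapses):
        if s.reversal_mode == "static":
            syn_erev[i] = graph.v_rest + s.delta_egaba
        else:
            # static chloride: a dynamic synapse keeps its initial EGABA
            syn_erev[i] = float(ion_state.e_gaba[syn_comp[i]])
    syn_erev = syn_erev[:n_syn]

    p_cls = {s.p_cl for s in synapses}
    if len(p_cls) > 1:
        raise ValueError("all synapses must share one Cl⁻ permeability fraction")
    p_cl = p_cls.pop() if p_cls else (ion_state.p_cl if ion_state else 0.8)

    rngs = _synapse_seeds(config.seed, n_syn)
    syn_g = np.empty((n_syn, n_steps))
    for i, s in enumerate(synapses):
        syn_g[i] = gclamp_trace(s, n_steps * dt, dt, rngs[i])

    stim_comp = np.array(
        [locate(graph, s.branch, s.x) for s in stimuli], dtype=np.int64
    )
    stim_amp = np.array([s.amplitude for s in stimuli])
    stim_on = np.array(
        [max(0, int(math.ceil(s.onset / dt - 1e-9))) for s in stimuli],
        dtype=np.int64,
    )
    stim_off = np.array(
        [n_steps if math.isinf(s.offset) else int(round(s.offset / dt)) for s in stimuli],
        dtype=np.int64,
    )

    cap_over_dt = graph.cap / dt
    base_diag = cap_over_dt + graph.g_leak + graph.g_axial_sum()

    if dynamic_cl:
        kcc2_coef, diff_g, diff_sum = transport_coefficients(graph, ion_state)
        cl_init = ion_state.cl_i
        ion_args = (
            ion_state.cl_o,
            ion_state.hco3_i,
            ion_state.hco3_o,
            ion_state.k_i,
            ion_state.k_o,
            p_cl,
            thermal_voltage(ion_state.temperature),
        )
    else:
        kcc2_coef = np.zeros(graph.n_comp)
        diff_g = np.zeros(graph.n_comp)
        diff_sum = np.zeros(graph.n_comp)
        cl_init = np.full(graph.n_comp, 7.25)
        ion_args = (135.0, 12.0, 23.0, 140.0, 140.0 * 7.25 / 135.0, p_cl, thermal_voltage())

    v_init = np.full(graph.n_comp, graph.v_rest)

    times, vm, g_rec, cl_rec, eg_rec = _solver.integrate(
        graph.parent,
        graph.g_axial,
        base_diag,
        cap_over_dt,
        graph.g_leak,
        graph.v_rest,
        v_init,
        syn_comp,
        syn_g,
        syn_erev,
        syn_dynamic,
        stim_comp,
        stim_amp,
        stim_on,
        stim_off,
        dynamic_cl,
        cl_init,
        *ion_args,
        kcc2_coef,
        diff_g,
        diff_sum,
        graph.volume / dt,
        dt,
        n_steps,
        config.record_every,
        dynamic_cl,
    )

    if not np.all(np.isfinite(vm)):
        bad = np.argwhere(~np.isfinite(vm))
        raise FloatingPointError(
            f"non-finite membrane potential at t={times[bad[0, 0]]:.3f} ms"
        )
    if dynamic_cl and np.any(cl_rec <= 0):
        bad = np.argwhere(cl_rec <= 0)
        raise FloatingPointError(
            f"non-positive [Cl⁻]i at t={times[bad[0, 0]]:.3f} ms; reduce dt"
        )

    return Recording(
        times=times,
        vm=vm,
        v0=v_init.copy(),
        g_syn=g_rec,
        syn_comp=syn_comp,
        graph=graph,
        config=config,
        cl=cl_rec if dynamic_cl else None,
        egaba_profile=eg_rec if dynamic_cl else None,
    )
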