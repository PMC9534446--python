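"""Closed-form and steady-state passive cable analysis on the tree.

These routines are the analytic counterpart of the simulator: input
resistance and attenuation come from the steady-state conductance system
(the t → ∞ limit of the backward-Euler step), and the single-synapse shunt
level

    IL(d) = [gR_i/(1 + gR_i)] · A_{i,d} · A_{d,i}

is evaluated from them.  The semi-analytic decomposition

    IL(d) = (R_d − R_d^i)/R_d − IPSP_d/V_d

extends this to hyperpolarising synapses without time stepping.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from . import _solver
from .morphology import CompartmentGraph, space_constant

__all__ = [
    "space_constant",
    "r_infinity",
    "input_resistance",
    "attenuation",
    "shunt_level_analytic",
    "semianalytic_il",
    "steady_state_voltage",
]

Shunts = Sequence[tuple[int, float]]


def r_infinity(radius: float, rm: float = 20.0, ra: float = 100.0) -> float:
    """Input resistance (MΩ) of a semi-infinite cable: Rm/(2πrλ)."""
    lam_cm = space_constant(radius, rm, ra) * 1e-4
    r_ohm = rm * 1e3 / (2.0 * math.pi * radius * 1e-4 * lam_cm)
    return r_ohm * 1e-6


def _steady_diag(graph: CompartmentGraph, shunts: Shunts) -> np.ndarray:
    diag = graph.g_leak + graph.g_axial_sum()
    for comp, g in shunts:
        if g < 0:
            raise ValueError("shunt conductance must be >= 0")
        diag[comp] += g
    return diag


def steady_state_voltage(
    graph: CompartmentGraph, currents: np.ndarray, shunts: Shunts = ()
) -> np.ndarray:
    """Steady-state voltage deviation ΔV (mV) for injected currents (nA)."""
    diag = _steady_diag(graph, shunts)
    return _solver.hines_solve(graph.parent, graph.g_axial, diag, np.asarray(currents, float))


def input_resistance(graph: CompartmentGraph, loc: int, shunts: Shunts = ()) -> float:
    """Input resistance (MΩ) at compartment ``loc``: ΔV/I for unit current.

    Extra shunt conductances (compartment, μS) model inhibitory synapses at
    their mean conductance; adding a shunt g at ``loc`` itself scales R by
    1/(1 + gR).
    """
    rhs = np.zeros(graph.n_comp)
    rhs[loc] = 1.0
    return float(steady_state_voltage(graph, rhs, shunts)[loc])


def attenuation(
    graph: CompartmentGraph, src: int, dst: int, shunts: Shunts = ()
) -> float:
    """Steady-state voltage attenuation A_{src,dst} = V(dst)/V(src) for
    current injected at ``src``.  Directional: A_{i,d} ≠ A_{d,i} in general;
    A_{i,i} = 1 and 0 < A ≤ 1 on a passive tree.
    """
    rhs = np.zeros(graph.n_comp)
    rhs[src] = 1.0
    v = steady_state_voltage(graph, rhs, shunts)
    return float(v[dst] / v[src])


def shunt_level_analytic(
    graph: CompartmentGraph,
    synapse_loc: int,
    g_gaba: float,
    d: int,
    delta_egaba: float = 0.0,
) -> float:
    """Analytic inhibitory level of a single *shunting* synapse.

    Only ∇EGABA = 0 is supported here (the conductance-only formula); for
    hyperpolarising synapses or several synapses use :func:`semianalytic_il`
    or the simulated IL.
    """
    if delta_egaba != 0.0:
        raise ValueError(
            "analytic shunt level is defined for shunting synapses only "
            "(∇EGABA = 0); use semianalytic_il or the numerical IL"
        )
    if g_gaba < 0:
        raise ValueError("conductance must be >= 0")
    r_i = input_resistance(graph, synapse_loc)
    a_id = attenuation(graph, synapse_loc, d)
    a_di = attenuation(graph, d, synapse_loc)
    return g_gaba * r_i / (1.0 + g_gaba * r_i) * a_id * a_di


def semianalytic_il(
    graph: CompartmentGraph,
    synapses: Sequence[tuple[int, float, float]],
    d: int,
    probe_amplitude: float = 0.001,
) -> float:
    """Steady-state IL at ``d`` from the input-resistance + IPSP route.

    ``synapses`` are (compartment, conductance μS, ∇EGABA mV) triples, the
    conductances taken at their means.  Computes R_d without inhibition,
    R_d^i with all synaptic conductances as shunts, and the steady IPSP at
    ``d`` driven by the synaptic batteries, then applies
    IL = (R_d − R_d^i)/R_d − IPSP/V_d with V_d = I·R_d.
    """
    shunts = [(c, g) for c, g, _ in synapses]
    r_d = input_resistance(graph, d)
    r_d_i = input_resistance(graph, d, shunts)
    battery = np.zeros(graph.n_comp)
    for c, g, dE in synapses:
        battery[c] += g * dE
    ipsp = float(steady_state_voltage(graph, battery, shunts)[d])
    v_d = probe_amplitude * r_d
    return (r_d - r_d_i) / r_d - ipsp / v_d
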