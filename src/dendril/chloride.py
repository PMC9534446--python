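"""Chloride state and transport: Nernst/GHK reversal potentials, KCC2
extrusion, GABA_A Cl⁻ influx, and axial diffusion on the compartment tree.

Only intracellular chloride is dynamic.  Extracellular chloride and both
bicarbonate pools are clamped, so EHCO3 is a constant and EGABA moves with
[Cl⁻]i alone.  Potassium enters only through the KCC2 equilibrium condition
[K⁺]i·[Cl⁻]i = [K⁺]o·[Cl⁻]o, which pins the pump's set point; by default
[K⁺]o is derived from that condition at the initial [Cl⁻]i so the resting
state is an exact fixed point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _solver
from .constants import BODY_TEMPERATURE, FARADAY, thermal_voltage
from .morphology import CompartmentGraph

__all__ = [
    "IonState",
    "nernst",
    "egaba",
    "cl_from_egaba",
    "kcc2_rate",
    "chloride_step",
    "transport_coefficients",
]

CL_OUT = 135.0  # mM
CL_IN_INIT = 7.25  # mM
HCO3_IN = 12.0  # mM
HCO3_OUT = 23.0  # mM
K_IN = 140.0  # mM
P_CL = 0.8  # Cl⁻ fraction of GABA_A permeability (4:1 Cl:HCO3)
P_KCC2 = 1.9297e-5  # mA·mM⁻²·cm⁻² pump strength
D_CL = 2.03  # μm²/ms chloride diffusion coefficient


def nernst(c_in: float, c_out: float, temperature: float = BODY_TEMPERATURE) -> float:
    """Nernst potential (mV) for a monovalent anion: (RT/F)·ln(c_in/c_out).

    With the initial chloride pools (7.25 / 135 mM) this gives −78.2 mV, and
    −17.4 mV for bicarbonate (12 / 23 mM).
    """
    if np.any(np.asarray(c_in) <= 0) or np.any(np.asarray(c_out) <= 0):
        raise ValueError("concentrations must be positive")
    return thermal_voltage(temperature) * np.log(np.asarray(c_in) / c_out)


def egaba(
    cl_i,
    cl_o: float = CL_OUT,
    hco3_i: float = HCO3_IN,
    hco3_o: float = HCO3_OUT,
    p_cl: float = P_CL,
    temperature: float = BODY_TEMPERATURE,
):
    """GABA_A reversal potential (mV) from the Goldman–Hodgkin–Katz equation
    for the two permeant anions with permeability fractions p_cl : 1−p_cl.

    The defaults reproduce the initial EGABA of −70 mV.
    """
    if not 0.0 <= p_cl <= 1.0:
        raise ValueError("p_cl must lie in [0, 1]")
    if (
        np.any(np.asarray(cl_i) <= 0)
        or cl_o <= 0
        or hco3_i <= 0
        or hco3_o <= 0
    ):
        raise ValueError("concentrations must be positive")
    num = p_cl * np.asarray(cl_i) + (1.0 - p_cl) * hco3_i
    den = p_cl * cl_o + (1.0 - p_cl) * hco3_o
    return thermal_voltage(temperature) * np.log(num / den)


def cl_from_egaba(
    target: float,
    cl_o: float = CL_OUT,
    hco3_i: float = HCO3_IN,
    hco3_o: float = HCO3_OUT,
    p_cl: float = P_CL,
    temperature: float = BODY_TEMPERATURE,
) -> float:
    """Invert the GHK relation: the [Cl⁻]i (mM) that yields EGABA = target."""
    den = p_cl * cl_o + (1.0 - p_cl) * hco3_o
    num = den * math.exp(target / thermal_voltage(temperature))
    cl_i = (num - (1.0 - p_cl) * hco3_i) / p_cl
    if cl_i <= 0:
        raise ValueError(f"EGABA={target} mV is not reachable with positive [Cl⁻]i")
    return cl_i


@dataclass
class IonState:
    """Per-compartment chloride state plus the clamped ion pools.

    Created from a graph with :meth:`for_graph`; ``cl_i`` is the only
    dynamic field.  ``k_o = k_i·cl_i(0)/cl_o`` by default so KCC2 is at
    equilibrium in the initial state.
    """

    cl_i: np.ndarray  # (N,) mM
    cl_o: float = CL_OUT
    hco3_i: float = HCO3_IN
    hco3_o: float = HCO3_OUT
    k_i: float = K_IN
    k_o: float = field(default=-1.0)  # -1 -> derive from equilibrium
    p_cl: float = P_CL
    p_kcc2: float = P_KCC2
    d_cl: float = D_CL
    temperature: float = BODY_TEMPERATURE

    def __post_init__(self) -> None:
        self.cl_i = np.atleast_1d(np.asarray(self.cl_i, dtype=float)).copy()
        if np.any(self.cl_i <= 0):
            raise ValueError("[Cl⁻]i must be positive everywhere")
        if self.k_o <= 0:
            self.k_o = self.k_i * float(self.cl_i[0]) / self.cl_o

    @classmethod
    def for_graph(
        cls,
        graph: CompartmentGraph,
        cl_init: float | None = None,
        egaba_init: float | None = None,
        **kwargs,
    ) -> "IonState":
        """Uniform initial state for every compartment of ``graph``.

        Exactly one of ``cl_init`` (mM) or ``egaba_init`` (mV) may be given;
        the default is [Cl⁻]i = 7.25 mM, i.e. EGABA = −70 mV, a −5 mV driving
        force below the −65 mV resting potential.
        """
        if cl_init is not None and egaba_init is not None:
            raise ValueError("give either cl_init or egaba_init, not both")
        if egaba_init is not None:
            p_cl = kwargs.get("p_cl", P_CL)
            cl_o = kwargs.get("cl_o", CL_OUT)
            hco3_i = kwargs.get("hco3_i", HCO3_IN)
            hco3_o = kwargs.get("hco3_o", HCO3_OUT)
            temperature = kwargs.get("temperature", BODY_TEMPERATURE)
            cl_init = cl_from_egaba(
                egaba_init, cl_o, hco3_i, hco3_o, p_cl, temperature
            )
        elif cl_init is None:
            cl_init = CL_IN_INIT
        return cls(cl_i=np.full(graph.n_comp, float(cl_init)), **kwargs)

    @property
    def e_cl(self) -> np.ndarray:
        return nernst(self.cl_i, self.cl_o, self.temperature)

    @property
    def e_hco3(self) -> float:
        return float(nernst(self.hco3_i, self.hco3_o, self.temperature))

    @property
    def e_gaba(self) -> np.ndarray:
        return egaba(
            self.cl_i, self.cl_o, self.hco3_i, self.hco3_o, self.p_cl, self.temperature
        )


def kcc2_rate(ion: IonState, graph: CompartmentGraph) -> np.ndarray:
    """KCC2 contribution to d[Cl⁻]i/dt (mM/ms) in every compartment.

    Extrusion: zero at the pump equilibrium [K⁺]i[Cl⁻]i = [K⁺]o[Cl⁻]o,
    strictly negative above it.  The surface current density
    P_KCC2·([K⁺]i[Cl⁻]i − [K⁺]o[Cl⁻]o) (mA/cm²) is converted to a
    concentration rate through membrane area, F, and compartment volume.
    """
    imbalance = ion.k_i * ion.cl_i - ion.k_o * ion.cl_o  # mM²
    amount_rate = 1e12 * ion.p_kcc2 * graph.area * imbalance / FARADAY  # mM·μm³/ms
    return -amount_rate / graph.volume


def transport_coefficients(
    graph: CompartmentGraph, ion: IonState
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(kcc2_coef, diff_g, diff_sum) arrays for the implicit chloride step.

    ``kcc2_coef[j]`` (μm³/ms per mM²) scales the pump imbalance to an amount
    rate; ``diff_g[j]`` is the conservative diffusion coupling between j and
    its parent, built — like the electrical axial conductance — from the
    series resistance of the two half-compartments.
    """
    kcc2_coef = 1e12 * ion.p_kcc2 * graph.area / FARADAY
    n = graph.n_comp
    diff_g = np.zeros(n)
    cross = math.pi * graph.radius**2  # μm²
    for j in range(1, n):
        p = graph.parent[j]
        res = 0.5 * graph.length[j] / (ion.d_cl * cross[j])
        res += 0.5 * graph.length[p] / (ion.d_cl * cross[p])
        diff_g[j] = 1.0 / res  # μm³/ms
    diff_sum = diff_g.copy()
    np.add.at(diff_sum, graph.parent[1:], diff_g[1:])
    return kcc2_coef, diff_g, diff_sum


def chloride_step(
    ion: IonState,
    i_cl: np.ndarray,
    graph: CompartmentGraph,
    dt: float,
    pump: bool = True,
    diffusion: bool = True,
) -> IonState:
    """Advance [Cl⁻]i by one backward-Euler step of
    d[Cl⁻]i/dt = ICl/(F·Vol) + KCC2 + axial diffusion, in place.

    ``i_cl`` is the per-compartment GABA_A chloride current (nA) from the
    concurrent voltage step, outward-positive, so a synapse with Vm > ECl
    loads the compartment with chloride.  Diffusion and the (linear-in-Cl)
    KCC2 term are implicit, which keeps the tiny junction compartment stable
    at the default dt; the synaptic source is explicit.  ``pump`` and
    ``diffusion`` exist to isolate terms in tests.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    i_cl = np.asarray(i_cl, dtype=float)
    kcc2_coef, diff_g, diff_sum = transport_coefficients(graph, ion)
    if not pump:
        kcc2_coef = np.zeros_like(kcc2_coef)
    if not diffusion:
        diff_g = np.zeros_like(diff_g)
        diff_sum = np.zeros_like(diff_sum)
    vol_over_dt = graph.volume / dt
    diag = vol_over_dt + diff_sum + kcc2_coef * ion.k_i
    rhs = (
        vol_over_dt * ion.cl_i
        + kcc2_coef * ion.k_o * ion.cl_o
        + i_cl * 1e6 / FARADAY
    )
    new_cl = _solver.hines_solve(graph.parent, diff_g, diag, rhs)
    if np.any(new_cl <= 0):
        raise FloatingPointError(
            "chloride concentration became non-positive; reduce dt"
        )
    ion.cl_i = new_cl
    return ion
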