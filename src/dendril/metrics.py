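"""Inhibitory Level and Accumulation Index from paired recordings.

The Inhibitory Level of a synapse at i, read out at d, is the fractional
reduction of the time-integrated voltage deflection caused by an excitatory
probe at d:

    IL_d^i = (V_d − V_d^i) / V_d,

where V_d integrates Vm − Vm(t=0) over a backward window (5 ms for
time-resolved traces, 50 ms otherwise) ending at the evaluation time
(150 ms by default, by which the passive membrane has settled).  The
Accumulation Index AccIdx = IL_0 / IL_{d=i} compares inhibition at the
branch junction with inhibition at the synapse itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulator import Recording

__all__ = [
    "ILProfile",
    "AccumulationResult",
    "voltage_integral",
    "inhibitory_level",
    "inhibitory_level_semianalytic",
    "accumulation_index",
    "il_timeseries",
]

DEFAULT_T = 150.0  # ms
DEFAULT_WINDOW = 5.0  # ms


def voltage_integral(rec: Recording, comp: int, t: float, window: float) -> float:
    """∫ (Vm − Vm(t=0)) dt over [t − window, t] at ``comp`` (mV·ms).

    Trapezoidal on the recorded grid, with linear interpolation at the
    window edges when they fall between samples.
    """
    t0 = t - window
    times = rec.times
    if t0 < times[0] - 1e-9 or t > times[-1] + 1e-9:
        raise ValueError(
            f"window [{t0}, {t}] outside recording [{times[0]}, {times[-1]}]"
        )
    deflect = rec.vm[:, comp] - rec.v0[comp]
    inside = (times > t0) & (times < t)
    ts = np.concatenate(([t0], times[inside], [t]))
    vs = np.concatenate(
        ([np.interp(t0, times, deflect)], deflect[inside], [np.interp(t, times, deflect)])
    )
    return float(np.trapezoid(vs, ts))


def inhibitory_level(
    rec_without: Recording,
    rec_with: Recording,
    d: int,
    t: float = DEFAULT_T,
    window: float = DEFAULT_WINDOW,
) -> float:
    """Numerical IL at compartment ``d``: (V_d − V_d^i)/V_d.

    The two recordings must share the stimulus, geometry and solver
    settings; ``rec_without`` must show a positive excitatory deflection.
    """
    v_d = voltage_integral(rec_without, d, t, window)
    if v_d <= 0:
        raise ValueError("V_d <= 0: no excitatory deflection at d, IL undefined")
    v_d_i = voltage_integral(rec_with, d, t, window)
    return (v_d - v_d_i) / v_d


def inhibitory_level_semianalytic(
    r_d: float, r_d_i: float, ipsp: float, v_d: float
) -> float:
    """IL decomposed into conductance and IPSP parts:
    (R_d − R_d^i)/R_d − IPSP/V_d.

    ``ipsp`` is the signed inhibition-only deflection integral at d
    (negative for hyperpolarising synapses, zero for shunting ones), in the
    same units as ``v_d``.
    """
    if r_d <= 0 or v_d <= 0:
        raise ValueError("R_d and V_d must be positive")
    return (r_d - r_d_i) / r_d - ipsp / v_d


def il_timeseries(
    rec_without: Recording,
    rec_with: Recording,
    d: int,
    window: float = DEFAULT_WINDOW,
    step: float | None = None,
) -> pd.DataFrame:
    """IL at ``d`` in successive backward windows (columns t, IL)."""
    step = window if step is None else step
    t_end = rec_without.times[-1]
    ts = np.arange(window, t_end + 1e-9, step)
    ils = [inhibitory_level(rec_without, rec_with, d, t, window) for t in ts]
    return pd.DataFrame({"t": ts, "IL": ils})


@dataclass
class ILProfile:
    """IL along the tree at one evaluation time.

    ``ds`` are (branch, X) readout locations, aligned with ``il``.  When the
    matching static- and dynamic-chloride profiles are both present,
    ``delta_il`` stores ΔIL = IL_stat − IL_dyn.
    """

    ds: list[tuple[int, float]]
    il: np.ndarray
    t: float = DEFAULT_T
    window: float = DEFAULT_WINDOW
    chloride_mode: str = "stat"
    egaba_at_i: float | None = None
    delta_il: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "branch_id": [b for b, _ in self.ds],
                "d": [x for _, x in self.ds],
                "t": self.t,
                "dt_window": self.window,
                "chloride_mode": self.chloride_mode,
                "IL": self.il,
            }
        )
        if self.delta_il is not None:
            frame["delta_IL"] = self.delta_il
        if self.egaba_at_i is not None:
            frame["EGABA_at_i"] = self.egaba_at_i
        return frame

    def at(self, branch: int, x: float, atol: float = 1e-9) -> float:
        for (b, xx), v in zip(self.ds, self.il):
            if b == branch and abs(xx - x) <= atol:
                return float(v)
        raise KeyError(f"no IL stored for (branch={branch}, X={x})")


@dataclass
class AccumulationResult:
    """AccIdx = IL_0 / IL_{d=i} for a synapse location i."""

    acc_idx: float
    i: tuple[int, float]
    il_junction: float
    il_at_synapse: float


def accumulation_index(
    il_junction: float, il_at_synapse: float, i: tuple[int, float] = (0, 0.2)
) -> AccumulationResult:
    """Accumulation Index from the junction and synapse-site ILs."""
    if il_at_synapse == 0:
        raise ZeroDivisionError("IL at the synapse is zero; AccIdx undefined")
    return AccumulationResult(
        acc_idx=il_junction / il_at_synapse,
        i=i,
        il_junction=il_junction,
        il_at_synapse=il_at_synapse,
    )
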