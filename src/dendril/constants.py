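"""Physical constants and the coherent unit system used throughout.

Units: length μm, time ms, voltage mV, current nA, conductance μS,
capacitance nF, resistance MΩ, concentration mM, intracellular volume μm³.
These are mutually consistent: I(nA) = g(μS)·V(mV), V(mV) = I(nA)·R(MΩ),
and C(nF)·dV/dt(mV/ms) = I(nA).
"""

FARADAY = 96485.0  # C mol^-1
GAS_CONSTANT = 8.3145  # J K^-1 mol^-1
BODY_TEMPERATURE = 310.15  # K (37 °C)

#: nA per (mM·μm³/ms) of ion flux, for a monovalent ion: I = F·(amount rate).
#: 1 mM·μm³ = 1e-18 mol, 1 nA = 1e-12 C/ms  =>  factor = F·1e-18/1e-12 = F·1e-6.
NA_PER_AMOUNT_RATE = FARADAY * 1e-6


def thermal_voltage(temperature: float = BODY_TEMPERATURE) -> float:
    """RT/F in mV at the given absolute temperature (K)."""
    return 1000.0 * GAS_CONSTANT * temperature / FARADAY
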