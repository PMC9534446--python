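"""Numba kernels: Hines tree solve and the coupled voltage/chloride stepper.

The compartment tree is stored in Hines order (``parent[k] < k``), so the
symmetric tree-structured linear systems arising from backward-Euler steps of
both the cable equation and the chloride diffusion equation are solved
exactly by one leaf-to-root elimination pass and one root-to-leaf
back-substitution — O(N) per step, no fill-in.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .constants import FARADAY

__all__ = ["hines_solve", "integrate"]


@njit(cache=True)
def hines_solve(parent, g_off, diag, rhs):
    """Solve (D - A) v = rhs on a tree, where D = diag(diag) and A couples
    compartment k to parent[k] with symmetric off-diagonal ``-g_off[k]``.

    ``diag`` and ``rhs`` are not modified.  Requires parent[k] < k and
    parent[0] == -1 (Hines ordering).
    """
    n = diag.shape[0]
    d = diag.copy()
    b = rhs.copy()
    for k in range(n - 1, 0, -1):
        p = parent[k]
        f = g_off[k] / d[k]
        d[p] -= g_off[k] * f
        b[p] += b[k] * f
    v = np.empty(n)
    v[0] = b[0] / d[0]
    for k in range(1, n):
        v[k] = (b[k] + g_off[k] * v[parent[k]]) / d[k]
    return v


@njit(cache=True)
def _solve_inplace(parent, g_off, d, b, out):
    n = d.shape[0]
    for k in range(n - 1, 0, -1):
        p = parent[k]
        f = g_off[k] / d[k]
        d[p] -= g_off[k] * f
        b[p] += b[k] * f
    out[0] = b[0] / d[0]
    for k in range(1, n):
        out[k] = (b[k] + g_off[k] * out[parent[k]]) / d[k]


@njit(cache=True)
def integrate(
    parent,  # (N,) int64 tree topology, Hines-ordered
    g_axial,  # (N,) μS coupling to parent
    base_diag,  # (N,) cap/dt + g_leak + Σ axial conductances
    cap_over_dt,  # (N,) nF/ms
    g_leak,  # (N,) μS
    v_rest,  # float mV
    v_init,  # (N,) mV
    syn_comp,  # (S,) int64 compartment per synapse
    syn_g,  # (S, n_steps) μS conductance trace per synapse
    syn_erev,  # (S,) mV static reversal (ignored when dynamic)
    syn_dynamic,  # (S,) bool: reversal & Cl flux follow the ion state
    stim_comp,  # (M,) int64
    stim_amp,  # (M,) nA
    stim_on,  # (M,) int64 first step index
    stim_off,  # (M,) int64 one-past-last step index
    dynamic_cl,  # bool
    cl_init,  # (N,) mM
    cl_o,  # float mM
    hco3_i,  # float mM
    hco3_o,  # float mM
    k_i,  # float mM
    k_o,  # float mM
    p_cl,  # float Cl⁻ permeability fraction of the GABA_A conductance
    rtf,  # float mV (RT/F)
    kcc2_coef,  # (N,) μm³/ms per mM² (surface pump scaled by area)
    diff_g,  # (N,) μm³/ms diffusion coupling to parent
    diff_sum,  # (N,) Σ diffusion couplings at each compartment
    vol_over_dt,  # (N,) μm³/ms
    dt,  # float ms
    n_steps,  # int
    rec_every,  # int: record every rec_every-th step (t=0 included)
    ecl_rec,  # bool: also record per-compartment ECl/EGABA/[Cl⁻]i
):
    """Backward-Euler integration of the passive cable equation with GABA_A
    synapses, coupled (operator splitting, voltage first) to implicit
    chloride diffusion + KCC2 extrusion with explicit synaptic Cl⁻ influx.

    Returns (times, vm, g_rec, cl, egaba); chloride outputs are zero-sized
    when ``ecl_rec`` is False.
    """
    n = parent.shape[0]
    n_syn = syn_comp.shape[0]
    n_rec = n_steps // rec_every + 1

    e_hco3 = rtf * np.log(hco3_i / hco3_o)
    ghk_den = p_cl * cl_o + (1.0 - p_cl) * hco3_o

    times = np.empty(n_rec)
    vm_rec = np.empty((n_rec, n))
    g_rec = np.empty((n_rec, n_syn))
    if ecl_rec:
        cl_rec = np.empty((n_rec, n))
        eg_rec = np.empty((n_rec, n))
    else:
        cl_rec = np.empty((0, n))
        eg_rec = np.empty((0, n))

    v = v_init.copy()
    cl = cl_init.copy()

    times[0] = 0.0
    vm_rec[0] = v
    for s in range(n_syn):
        g_rec[0, s] = syn_g[s, 0] if n_steps > 0 else 0.0
    if ecl_rec:
        cl_rec[0] = cl
        for j in range(n):
            eg_rec[0, j] = rtf * np.log(
                (p_cl * cl[j] + (1.0 - p_cl) * hco3_i) / ghk_den
            )

    d = np.empty(n)
    b = np.empty(n)
    flux = np.empty(n)
    r = 1
    for step in range(n_steps):
        # --- voltage: implicit step on the tree -------------------------
        for j in range(n):
            d[j] = base_diag[j]
            b[j] = cap_over_dt[j] * v[j] + g_leak[j] * v_rest
        for m in range(stim_comp.shape[0]):
            if stim_on[m] <= step < stim_off[m]:
                b[stim_comp[m]] += stim_amp[m]
        for s in range(n_syn):
            c = syn_comp[s]
            g = syn_g[s, step]
            if syn_dynamic[s]:
                erev = rtf * np.log((p_cl * cl[c] + (1.0 - p_cl) * hco3_i) / ghk_den)
            else:
                erev = syn_erev[s]
            d[c] += g
            b[c] += g * erev
        _solve_inplace(parent, g_axial, d, b, v)

        # --- chloride: synaptic influx, KCC2, axial diffusion ------------
        if dynamic_cl:
            for j in range(n):
                flux[j] = 0.0
            for s in range(n_syn):
                if not syn_dynamic[s]:
                    continue
                c = syn_comp[s]
                g = syn_g[s, step]
                e_cl = rtf * np.log(cl[c] / cl_o)
                e_gaba = rtf * np.log(
                    (p_cl * cl[c] + (1.0 - p_cl) * hco3_i) / ghk_den
                )
                chi = (e_hco3 - e_gaba) / (e_hco3 - e_cl)
                i_cl = chi * g * (v[c] - e_cl)  # nA, outward-positive
                # positive (outward) current = anion influx: raises [Cl⁻]i
                flux[c] += i_cl * 1e6 / FARADAY  # mM·μm³/ms
            for j in range(n):
                d[j] = vol_over_dt[j] + diff_sum[j] + kcc2_coef[j] * k_i
                b[j] = vol_over_dt[j] * cl[j] + kcc2_coef[j] * k_o * cl_o + flux[j]
            _solve_inplace(parent, diff_g, d, b, cl)

        # --- record ------------------------------------------------------
        if (step + 1) % rec_every == 0:
            times[r] = (step + 1) * dt
            vm_rec[r] = v
            for s in range(n_syn):
                g_rec[r, s] = syn_g[s, step]
            if ecl_rec:
                cl_rec[r] = cl
                for j in range(n):
                    eg_rec[r, j] = rtf * np.log(
                        (p_cl * cl[j] + (1.0 - p_cl) * hco3_i) / ghk_den
                    )
            r += 1

    return times, vm_rec, g_rec, cl_rec, eg_rec
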