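"""Scripted reproductions of the study protocols: branch-count sweeps,
occupancy sweeps, synapse-distribution comparisons, dynamic-chloride time
courses, placement scans, and chloride-sink sweeps.

All protocols follow the same paired-run template: an excitatory probe
(0.001 nA constant current) is placed at the readout location d, the tree is
simulated with and without the GABAergic synapses, and the Inhibitory Level
is evaluated over a backward integration window.  Stochastic protocols
average the IL over several seeds; with ``deterministic=True`` the gclamp
noise is switched off (sd = 0) and a single run per condition is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .chloride import IonState
from .metrics import accumulation_index, inhibitory_level, voltage_integral
from .morphology import BranchSpec, CompartmentGraph, build_star_tree, discretise, locate
from .simulator import Recording, SimConfig, StimulusSpec, SynapseSpec, run

__all__ = [
    "DistributionSpec",
    "ScanResult",
    "default_placement_grid",
    "synapse_locations",
    "branch_sweep",
    "occupancy_sweep",
    "location_distribution_sweep",
    "chloride_timecourse",
    "placement_scan",
    "sink_sweep",
]

DEFAULT_SEEDS = (1, 2, 3, 4, 5)
DYN_EGABA_INIT = -70.0  # mV: initial ∇EGABA = −5 mV for dynamic-Cl protocols


@dataclass(frozen=True)
class DistributionSpec:
    """How the synapses are laid out on the tree.

    ``tree``: one synapse per branch, all at X = i.
    ``focal``: all synapses at the single location (branch 0, X = i).
    ``branch``: evenly spaced along branch 0 at k/(n+1) X for k = 1..n,
    rigidly shifted by the anchor ``i`` (clipped to the branch).
    """

    kind: str = "tree"
    i: float = 0.2
    count: int | None = None  # default: one per branch

    def __post_init__(self) -> None:
        if self.kind not in ("tree", "branch", "focal"):
            raise ValueError("kind must be 'tree', 'branch' or 'focal'")


def synapse_locations(dist: DistributionSpec, n_branches: int) -> list[tuple[int, float]]:
    """Resolve a distribution to explicit (branch, X) synapse locations."""
    n = dist.count if dist.count is not None else n_branches
    if dist.kind == "tree":
        return [(s % n_branches, dist.i) for s in range(n)]
    if dist.kind == "focal":
        return [(0, dist.i)] * n
    spacing = [k / (n + 1) for k in range(1, n + 1)]
    return [(0, min(max(p + dist.i, 0.0), 1.0)) for p in spacing]


@dataclass
class ScanResult:
    """Per-point summaries of a parameter scan plus its argmax."""

    scanned: str
    frame: pd.DataFrame
    argmax: dict
    seeds: tuple[int, ...]
    config: dict = field(default_factory=dict)


def _argmax_first(values: np.ndarray, grid: Sequence, rel_tol: float = 0.0):
    """First grid point attaining the maximum (within ``rel_tol`` of it)."""
    values = np.asarray(values, dtype=float)
    vmax = np.nanmax(values)
    thresh = vmax - rel_tol * abs(vmax)
    idx = int(np.argmax(values >= thresh))
    return grid[idx], float(values[idx])


@dataclass
class _Engine:
    """Shared machinery for the paired-run IL protocols."""

    dx: float = 0.01
    dt: float = 0.025
    record_dt: float = 0.5
    probe_amp: float = 0.001  # nA
    g_mean: float = 0.001  # μS
    noise_sd: float = 0.1
    noise_tau: float = 10.0  # ms
    seeds: tuple[int, ...] = DEFAULT_SEEDS
    branch: BranchSpec = field(default_factory=BranchSpec)
    _graphs: dict = field(default_factory=dict, repr=False)
    _rec0: dict = field(default_factory=dict, repr=False)

    @classmethod
    def make(cls, deterministic: bool, seeds: Sequence[int], **kw) -> "_Engine":
        if deterministic:
            return cls(noise_sd=0.0, seeds=(0,), **kw)
        return cls(seeds=tuple(seeds), **kw)

    def graph(self, n_branches: int, sink: BranchSpec | None = None) -> CompartmentGraph:
        key = (n_branches, sink)
        if key not in self._graphs:
            morph = build_star_tree(n_branches, self.branch, sink=sink)
            self._graphs[key] = discretise(morph, self.dx)
        return self._graphs[key]

    def synapses(
        self, locations: Sequence[tuple[int, float]], delta_egaba: float | None
    ) -> list[SynapseSpec]:
        """``delta_egaba=None`` marks ion-tracking (dynamic-reversal) synapses."""
        common = dict(
            g_mean=self.g_mean,
            noise_sd_fraction=self.noise_sd,
            noise_tau=self.noise_tau,
        )
        if delta_egaba is None:
            return [
                SynapseSpec(branch=b, x=x, reversal_mode="dynamic", **common)
                for b, x in locations
            ]
        return [
            SynapseSpec(branch=b, x=x, delta_egaba=delta_egaba, **common)
            for b, x in locations
        ]

    def baseline(self, graph: CompartmentGraph, probe: tuple[int, float], duration: float) -> Recording:
        """Probe-only run (no inhibition, deterministic); cached."""
        key = (id(graph), locate(graph, probe[0], probe[1]), duration)
        if key not in self._rec0:
            cfg = SimConfig(dt=self.dt, duration=duration, record_dt=self.record_dt)
            stim = StimulusSpec(branch=probe[0], x=probe[1], amplitude=self.probe_amp)
            self._rec0[key] = run(graph, (), (stim,), cfg)
        return self._rec0[key]

    def il(
        self,
        graph: CompartmentGraph,
        locations: Sequence[tuple[int, float]],
        probe: tuple[int, float],
        d: tuple[int, float] | None = None,
        *,
        delta_egaba: float | None = 0.0,
        chloride_mode: str = "static",
        duration: float = 150.0,
        t: float = 150.0,
        window: float = 5.0,
        egaba_init: float = DYN_EGABA_INIT,
    ) -> dict:
        """Seed-averaged IL at d (default: the probe site) plus extras."""
        d = probe if d is None else d
        d_comp = locate(graph, *d)
        rec0 = self.baseline(graph, probe, duration)
        stim = StimulusSpec(branch=probe[0], x=probe[1], amplitude=self.probe_amp)
        syns = self.synapses(locations, delta_egaba)
        dynamic_reversal = delta_egaba is None
        ils, egabas = [], []
        for seed in self.seeds:
            cfg = SimConfig(
                dt=self.dt,
                duration=duration,
                record_dt=self.record_dt,
                seed=int(seed),
                chloride_mode=chloride_mode,
            )
            ion = (
                IonState.for_graph(graph, egaba_init=egaba_init)
                if dynamic_reversal
                else None
            )
            rec = run(graph, syns, (stim,), cfg, ion_state=ion)
            ils.append(inhibitory_level(rec0, rec, d_comp, t, window))
            if chloride_mode == "dynamic":
                egabas.append(rec.egaba_at(rec.syn_comp[0], t))
        return {
            "IL": float(np.mean(ils)),
            "IL_per_seed": ils,
            "EGABA_at_i": float(np.mean(egabas)) if egabas else None,
        }

    def il_junction_and_synapse(
        self,
        graph: CompartmentGraph,
        locations: Sequence[tuple[int, float]],
        i_readout: tuple[int, float],
        **kw,
    ) -> dict:
        """IL_0 (probe and readout at the junction) and IL_{d=i}."""
        res0 = self.il(graph, locations, probe=(0, 0.0), **kw)
        resi = self.il(graph, locations, probe=i_readout, **kw)
        return {
            "IL_0": res0["IL"],
            "IL_d_i": resi["IL"],
            "EGABA_at_i": resi["EGABA_at_i"],
        }


def branch_sweep(
    n_branches: Sequence[int] = (1, 2, 4, 8, 16),
    delta_egabas: Sequence[float] = (0.0, -1.0, -2.0, -3.0, -5.0),
    i: float = 0.2,
    deterministic: bool = False,
    seeds: Sequence[int] = DEFAULT_SEEDS,
    t: float = 150.0,
    window: float = 5.0,
    **engine_kw,
) -> ScanResult:
    """IL_0, IL_{d=i} and AccIdx versus branch count and ∇EGABA (static Cl⁻)
    for one synapse per branch at X = i."""
    eng = _Engine.make(deterministic, seeds, **engine_kw)
    rows = []
    for n in n_branches:
        graph = eng.graph(n)
        locs = synapse_locations(DistributionSpec("tree", i), n)
        for dE in delta_egabas:
            res = eng.il_junction_and_synapse(
                graph, locs, (0, i), delta_egaba=dE, duration=t, t=t, window=window
            )
            acc = accumulation_index(res["IL_0"], res["IL_d_i"], (0, i))
            rows.append(
                {
                    "n_branches": n,
                    "delta_egaba": dE,
                    "i": i,
                    "IL_0": res["IL_0"],
                    "IL_d_i": res["IL_d_i"],
                    "AccIdx": acc.acc_idx,
                }
            )
    frame = pd.DataFrame(rows)
    best = frame.loc[frame["AccIdx"].idxmax()]
    return ScanResult(
        scanned="n_branches",
        frame=frame,
        argmax={"n_branches": int(best["n_branches"]), "AccIdx": float(best["AccIdx"])},
        seeds=eng.seeds,
        config={"i": i, "t": t, "window": window, "deterministic": deterministic},
    )


def occupancy_sweep(
    n_branches: Sequence[int] = (4, 8),
    occupancies: Sequence[float] = tuple(range(25, 201, 25)),
    delta_egabas: Sequence[float] = (0.0, -2.0),
    i: float = 0.2,
    deterministic: bool = False,
    seeds: Sequence[int] = DEFAULT_SEEDS,
    t: float = 150.0,
    window: float = 5.0,
    tie_rel_tol: float = 1e-3,
    **engine_kw,
) -> ScanResult:
    """AccIdx versus effective number of synapses (% of branch count).

    Synapses are assigned one per branch in branch order, then a second per
    branch, all at X = i.  IL_{d=i} is read on branch 0 (a branch carrying
    the maximal synapse count).  The argmax over occupancy prefers the
    smallest occupancy within ``tie_rel_tol`` of the maximum, since complete
    occupancies tie exactly for hyperpolarising synapses.
    """
    eng = _Engine.make(deterministic, seeds, **engine_kw)
    rows = []
    argmax = {}
    for n in n_branches:
        graph = eng.graph(n)
        for dE in delta_egabas:
            accs = []
            for occ in occupancies:
                n_syn = int(round(occ / 100.0 * n))
                locs = [(s % n, i) for s in range(n_syn)]
                res = eng.il_junction_and_synapse(
                    graph, locs, (0, i), delta_egaba=dE, duration=t, t=t, window=window
                )
                acc = res["IL_0"] / res["IL_d_i"]
                accs.append(acc)
                rows.append(
                    {
                        "n_branches": n,
                        "delta_egaba": dE,
                        "occupancy": occ,
                        "n_synapses": n_syn,
                        "IL_0": res["IL_0"],
                        "IL_d_i": res["IL_d_i"],
                        "AccIdx": acc,
                    }
                )
            occ_star, acc_star = _argmax_first(accs, list(occupancies), tie_rel_tol)
            argmax[(n, dE)] = {"occupancy": occ_star, "AccIdx": acc_star}
    return ScanResult(
        scanned="occupancy",
        frame=pd.DataFrame(rows),
        argmax=argmax,
        seeds=eng.seeds,
        config={"i": i, "t": t, "window": window, "deterministic": deterministic},
    )


def location_distribution_sweep(
    n_branches: int = 4,
    i_grid: Sequence[float] = tuple(np.round(np.arange(0.0, 1.01, 0.1), 2)),
    distributions: Sequence[str] = ("tree",),
    delta_egabas: Sequence[float] = (0.0, -2.0),
    deterministic: bool = False,
    seeds: Sequence[int] = DEFAULT_SEEDS,
    t: float = 150.0,
    window: float = 5.0,
    **engine_kw,
) -> ScanResult:
    """IL_0, IL_{d=i} and AccIdx versus common synapse location i (static Cl⁻)."""
    eng = _Engine.make(deterministic, seeds, **engine_kw)
    graph = eng.graph(n_branches)
    rows = []
    argmax = {}
    for kind in distributions:
        for dE in delta_egabas:
            accs = []
            for i in i_grid:
                locs = synapse_locations(DistributionSpec(kind, float(i)), n_branches)
                readout = locs[0] if kind != "tree" else (0, float(i))
                res = eng.il_junction_and_synapse(
                    graph, locs, readout, delta_egaba=dE, duration=t, t=t, window=window
                )
                acc = res["IL_0"] / res["IL_d_i"] if res["IL_d_i"] != 0 else np.nan
                accs.append(acc)
                rows.append(
                    {
                        "n_branches": n_branches,
                        "distribution": kind,
                        "delta_egaba": dE,
                        "i": float(i),
                        "IL_0": res["IL_0"],
                        "IL_d_i": res["IL_d_i"],
                        "AccIdx": acc,
                    }
                )
            i_star, acc_star = _argmax_first(accs, list(i_grid))
            argmax[(kind, dE)] = {"i": float(i_star), "AccIdx": acc_star}
    return ScanResult(
        scanned="i",
        frame=pd.DataFrame(rows),
        argmax=argmax,
        seeds=eng.seeds,
        config={"t": t, "window": window, "deterministic": deterministic},
    )


def chloride_timecourse(
    n_branches: Sequence[int] = (1, 2, 4, 8),
    i: float = 0.2,
    egaba_init: float = DYN_EGABA_INIT,
    duration: float = 1000.0,
    window: float = 5.0,
    il_step: float = 5.0,
    deterministic: bool = False,
    seeds: Sequence[int] = DEFAULT_SEEDS,
    **engine_kw,
) -> ScanResult:
    """IL_stat vs IL_dyn over time with one synapse per branch at X = i.

    Synapses track the ion state; in the static arm the chloride pools are
    frozen so the reversal stays at its initial value (∇EGABA = −5 mV by
    default).  Produces per-time rows with IL at the junction and at the
    synapse for both arms, ΔIL = IL_stat − IL_dyn, AccIdx, and EGABA at the
    synapse and junction.
    """
    eng = _Engine.make(deterministic, seeds, **engine_kw)
    ts = np.arange(window, duration + 1e-9, il_step)
    rows = []
    for n in n_branches:
        graph = eng.graph(n)
        locs = synapse_locations(DistributionSpec("tree", i), n)
        syns = eng.synapses(locs, None)
        i_comp = locate(graph, 0, i)
        recs: dict[tuple[str, str], list[Recording]] = {}
        rec0 = {
            "junction": eng.baseline(graph, (0, 0.0), duration),
            "synapse": eng.baseline(graph, (0, i), duration),
        }
        for mode in ("static", "dynamic"):
            for probe_name, probe in (("junction", (0, 0.0)), ("synapse", (0, i))):
                runs = []
                for seed in eng.seeds:
                    cfg = SimConfig(
                        dt=eng.dt,
                        duration=duration,
                        record_dt=eng.record_dt,
                        seed=int(seed),
                        chloride_mode=mode,
                    )
                    ion = IonState.for_graph(graph, egaba_init=egaba_init)
                    stim = StimulusSpec(branch=probe[0], x=probe[1], amplitude=eng.probe_amp)
                    runs.append(run(graph, syns, (stim,), cfg, ion_state=ion))
                recs[(mode, probe_name)] = runs

        def mean_il(mode: str, probe_name: str, comp: int, t: float) -> float:
            base = rec0[probe_name]
            return float(
                np.mean(
                    [
                        inhibitory_level(base, r, comp, t, window)
                        for r in recs[(mode, probe_name)]
                    ]
                )
            )

        dyn_i = recs[("dynamic", "synapse")]
        for t in ts:
            il_stat_0 = mean_il("static", "junction", 0, t)
            il_stat_i = mean_il("static", "synapse", i_comp, t)
            il_dyn_0 = mean_il("dynamic", "junction", 0, t)
            il_dyn_i = mean_il("dynamic", "synapse", i_comp, t)
            rows.append(
                {
                    "n_branches": n,
                    "t": float(t),
                    "IL_stat_0": il_stat_0,
                    "IL_stat_i": il_stat_i,
                    "IL_dyn_0": il_dyn_0,
                    "IL_dyn_i": il_dyn_i,
                    "dIL_i": il_stat_i - il_dyn_i,
                    "AccIdx_stat": il_stat_0 / il_stat_i,
                    "AccIdx_dyn": il_dyn_0 / il_dyn_i,
                    "EGABA_at_i": float(
                        np.mean([r.egaba_at(i_comp, t) for r in dyn_i])
                    ),
                    "EGABA_at_0": float(np.mean([r.egaba_at(0, t) for r in dyn_i])),
                }
            )
    frame = pd.DataFrame(rows)
    return ScanResult(
        scanned="t",
        frame=frame,
        argmax={},
        seeds=eng.seeds,
        config={
            "i": i,
            "egaba_init": egaba_init,
            "duration": duration,
            "window": window,
            "deterministic": deterministic,
        },
    )


def default_placement_grid(
    fine_to: float = 0.2, fine_step: float = 0.01, coarse_step: float = 0.05
) -> np.ndarray:
    """0.01 X resolution near the junction, 0.05 X beyond (out to 1.0 X)."""
    fine = np.arange(0.0, fine_to + 1e-9, fine_step)
    coarse = np.arange(fine_to + coarse_step, 1.0 + 1e-9, coarse_step)
    return np.round(np.concatenate([fine, coarse]), 6)


def placement_scan(
    n_branches: int = 4,
    distribution: str = "tree",
    i_grid: Sequence[float] | None = None,
    duration: float = 500.0,
    window: float = 5.0,
    egaba_init: float = DYN_EGABA_INIT,
    chloride_modes: Sequence[str] = ("static", "dynamic"),
    readouts: Sequence[str] = ("junction", "synapse"),
    deterministic: bool = False,
    seeds: Sequence[int] = DEFAULT_SEEDS,
    sink: BranchSpec | None = None,
    **engine_kw,
) -> ScanResult:
    """Scan the common synapse location i for the placement optima.

    For every i the IL is read out at the junction (probe at the junction,
    IL_0) and/or at the synapses (probe at d = i), for static and/or dynamic
    chloride, at the end of the simulation.  ``argmax`` holds the optimal i
    per (mode, readout) and per mode overall (max over readouts).
    """
    eng = _Engine.make(deterministic, seeds, **engine_kw)
    graph = eng.graph(n_branches, sink=sink)
    grid = default_placement_grid() if i_grid is None else np.asarray(i_grid, float)
    rows = []
    for i in grid:
        locs = synapse_locations(DistributionSpec(distribution, float(i)), n_branches)
        row: dict = {"i": float(i), "n_branches": n_branches, "distribution": distribution}
        for mode in chloride_modes:
            for readout in readouts:
                probe = (0, 0.0) if readout == "junction" else (
                    locs[0] if distribution != "tree" else (0, float(i))
                )
                res = eng.il(
                    graph,
                    locs,
                    probe,
                    delta_egaba=None,
                    chloride_mode=mode,
                    duration=duration,
                    t=duration,
                    window=window,
                    egaba_init=egaba_init,
                )
                tag = "IL_0" if readout == "junction" else "IL_d_i"
                row[f"{tag}_{mode[:4]}"] = res["IL"]
                if mode == "dynamic" and readout != "junction":
                    row["EGABA_at_i"] = res["EGABA_at_i"]
        rows.append(row)
    frame = pd.DataFrame(rows)
    argmax: dict = {}
    for mode in chloride_modes:
        cols = []
        for readout in readouts:
            col = ("IL_0" if readout == "junction" else "IL_d_i") + f"_{mode[:4]}"
            cols.append(col)
            i_star, v = _argmax_first(frame[col].to_numpy(), list(frame["i"]))
            argmax[(mode, readout)] = {"i": float(i_star), "IL": v}
        overall = frame[cols].max(axis=1).to_numpy()
        i_star, v = _argmax_first(overall, list(frame["i"]))
        argmax[(mode, "overall")] = {"i": float(i_star), "IL": v}
    return ScanResult(
        scanned="i",
        frame=frame,
        argmax=argmax,
        seeds=eng.seeds,
        config={
            "n_branches": n_branches,
            "distribution": distribution,
            "duration": duration,
            "egaba_init": egaba_init,
            "deterministic": deterministic,
            "sink": sink is not None,
        },
    )


def sink_sweep(
    n_child: int = 4,
    sink_diameters: Sequence[float] = (0.5, 1.0, 1.5, 2.0),
    length_mode: str = "fixed",
    i_grid: Sequence[float] | None = None,
    duration: float = 500.0,
    deterministic: bool = False,
    seeds: Sequence[int] = DEFAULT_SEEDS,
    **engine_kw,
) -> ScanResult:
    """Optimal synapse placement versus the diameter of a synapse-free
    parent (sink) branch, with dynamic chloride.

    ``length_mode='fixed'`` keeps the sink at the child-branch length (its
    electrotonic length then deviates from 1 X); ``'scaled'`` stretches it
    to one of its own space constants.
    """
    if length_mode not in ("fixed", "scaled"):
        raise ValueError("length_mode must be 'fixed' or 'scaled'")
    child = engine_kw.pop("branch", BranchSpec())
    rows = []
    argmax = {}
    for diam in sink_diameters:
        sink_len = child.resolved_length if length_mode == "fixed" else None
        sink = replace(child, radius=diam / 2.0, length=sink_len)
        scan = placement_scan(
            n_branches=n_child,
            distribution="tree",
            i_grid=i_grid,
            duration=duration,
            chloride_modes=("dynamic",),
            readouts=("junction", "synapse"),
            deterministic=deterministic,
            seeds=seeds,
            sink=sink,
            branch=child,
            **engine_kw,
        )
        sub = scan.frame.assign(sink_diameter=diam, length_mode=length_mode)
        rows.append(sub)
        best = scan.argmax[("dynamic", "overall")]
        readout_at_best = (
            "junction"
            if scan.argmax[("dynamic", "junction")]["IL"]
            >= scan.argmax[("dynamic", "synapse")]["IL"]
            else "synapse"
        )
        argmax[diam] = {**best, "readout": readout_at_best}
    return ScanResult(
        scanned="i",
        frame=pd.concat(rows, ignore_index=True),
        argmax=argmax,
        seeds=tuple(seeds) if not deterministic else (0,),
        config={
            "n_child": n_child,
            "length_mode": length_mode,
            "duration": duration,
            "deterministic": deterministic,
        },
    )
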