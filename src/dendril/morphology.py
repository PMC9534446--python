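"""Star-tree dendrite morphologies and their spatial discretisation.

The model geometry is a set of identical cylindrical branches joined at a
tiny central junction compartment (0.01 μm long), optionally together with a
synapse-free parent branch (a chloride "sink") of different diameter.
Distances along a branch are expressed in electrotonic units X = distance/λ,
with X = 0 at the junction and X = L/λ at the sealed tip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "BranchSpec",
    "Morphology",
    "CompartmentGraph",
    "SWCError",
    "space_constant",
    "build_star_tree",
    "discretise",
    "locate",
    "to_swc",
    "from_swc",
]

JUNCTION_LENGTH = 0.01  # μm

DEFAULT_RADIUS = 0.5  # μm
DEFAULT_RM = 20.0  # kΩ·cm² membrane resistivity
DEFAULT_RA = 100.0  # Ω·cm axial resistivity
DEFAULT_CM = 1.0  # μF/cm²
DEFAULT_VREST = -65.0  # mV


def space_constant(radius: float, rm: float = DEFAULT_RM, ra: float = DEFAULT_RA) -> float:
    """Steady-state space constant λ = sqrt(r·Rm / (2·Ra)) in μm.

    Parameters use the package unit conventions: ``radius`` in μm, ``rm`` in
    kΩ·cm², ``ra`` in Ω·cm.  For the default passive parameters
    (r = 0.5 μm, Rm = 20 kΩ·cm², Ra = 100 Ω·cm) λ = 707.1 μm.
    """
    if radius <= 0 or rm <= 0 or ra <= 0:
        raise ValueError("radius, rm and ra must all be positive")
    r_cm = radius * 1e-4
    rm_ohm = rm * 1e3  # Ω·cm²
    lam_cm = math.sqrt(r_cm * rm_ohm / (2.0 * ra))
    return lam_cm * 1e4


@dataclass(frozen=True)
class BranchSpec:
    """Geometry and passive electrical properties of one cylindrical branch.

    ``length=None`` resolves to one space constant λ(radius, rm, ra), which is
    the model's default branch (electrotonic length exactly 1.0 X; 707 μm for
    the default electrical parameters).
    """

    radius: float = DEFAULT_RADIUS  # μm
    length: float | None = None  # μm; None -> one space constant
    rm: float = DEFAULT_RM  # kΩ·cm²
    ra: float = DEFAULT_RA  # Ω·cm
    cm: float = DEFAULT_CM  # μF/cm²
    v_rest: float = DEFAULT_VREST  # mV

    def __post_init__(self) -> None:
        for name in ("radius", "rm", "ra", "cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"BranchSpec.{name} must be positive")
        if self.length is not None and self.length <= 0:
            raise ValueError("BranchSpec.length must be positive")

    @property
    def lam(self) -> float:
        """Space constant λ in μm."""
        return space_constant(self.radius, self.rm, self.ra)

    @property
    def resolved_length(self) -> float:
        """Physical length in μm (default: one space constant)."""
        return self.lam if self.length is None else self.length

    @property
    def electrotonic_length(self) -> float:
        """Branch length in units of λ."""
        return self.resolved_length / self.lam

    @property
    def tau_m(self) -> float:
        """Membrane time constant Rm·Cm in ms."""
        return self.rm * self.cm  # kΩ·cm² · μF/cm² = ms


@dataclass(frozen=True)
class Morphology:
    """A star tree: child branches joined at a 0.01 μm central compartment.

    The optional ``sink`` is a parent branch attached to the same junction
    that never carries synapses; it only drains current and chloride.
    """

    branches: tuple[BranchSpec, ...]
    sink: BranchSpec | None = None
    junction_length: float = JUNCTION_LENGTH  # μm
    junction_radius: float | None = None  # μm; None -> child branch radius

    def __post_init__(self) -> None:
        if len(self.branches) < 1:
            raise ValueError("a morphology needs at least one branch")
        if self.junction_length <= 0:
            raise ValueError("junction length must be positive")
        if self.junction_radius is not None and self.junction_radius <= 0:
            raise ValueError("junction radius must be positive")

    @property
    def n_branches(self) -> int:
        """Number of child branches (the sink excluded)."""
        return len(self.branches)

    @property
    def all_branches(self) -> tuple[BranchSpec, ...]:
        return self.branches + ((self.sink,) if self.sink is not None else ())

    @property
    def resolved_junction_radius(self) -> float:
        return (
            self.branches[0].radius
            if self.junction_radius is None
            else self.junction_radius
        )


def build_star_tree(
    n_branches: int,
    branch: BranchSpec | None = None,
    sink: BranchSpec | None = None,
) -> Morphology:
    """Build a star tree of ``n_branches`` identical child branches.

    A ``sink`` branch, if given, is attached to the junction as an extra
    branch flagged so that experiment drivers never place synapses on it.
    """
    if n_branches < 1:
        raise ValueError("n_branches must be >= 1")
    branch = branch if branch is not None else BranchSpec()
    return Morphology(branches=(branch,) * n_branches, sink=sink)


@dataclass
class CompartmentGraph:
    """Discretised morphology: per-compartment geometry, passive electrical
    parameters, and tree connectivity in Hines order (parent index < child).

    Compartment 0 is always the junction.  ``branch_id`` is −1 for the
    junction and 0..n−1 (plus n for the sink, see ``sink_branch``) otherwise;
    ``x`` is the electrotonic coordinate of the compartment centre measured
    from the junction.  ``g_axial[k]`` couples compartment k to its parent.
    """

    parent: np.ndarray  # (N,) int64, -1 at root
    length: np.ndarray  # (N,) μm
    radius: np.ndarray  # (N,) μm
    area: np.ndarray  # (N,) cm², lateral membrane area
    volume: np.ndarray  # (N,) μm³
    g_leak: np.ndarray  # (N,) μS
    cap: np.ndarray  # (N,) nF
    g_axial: np.ndarray  # (N,) μS (0 at root)
    branch_id: np.ndarray  # (N,) int64
    x: np.ndarray  # (N,) electrotonic coordinate
    v_rest: float  # mV
    branch_first: np.ndarray  # (B,) first compartment index of each branch
    branch_nseg: np.ndarray  # (B,) compartments per branch
    branch_elec_len: np.ndarray  # (B,) electrotonic length per branch
    sink_branch: int = -1  # branch id of the sink, -1 if none
    morphology: Morphology | None = field(default=None, repr=False)

    @property
    def n_comp(self) -> int:
        return int(self.parent.shape[0])

    @property
    def n_branches(self) -> int:
        return int(self.branch_first.shape[0])

    def g_axial_sum(self) -> np.ndarray:
        """Total axial conductance attached to each compartment (μS)."""
        total = self.g_axial.copy()
        np.add.at(total, self.parent[1:], self.g_axial[1:])
        return total

    def total_area(self) -> float:
        return float(self.area.sum())

    def total_volume(self) -> float:
        return float(self.volume.sum())


def _half_axial_resistance(ra: float, length: float, radius: float) -> float:
    """Axial resistance of half a compartment in MΩ."""
    l_cm = 0.5 * length * 1e-4
    a_cm2 = math.pi * (radius * 1e-4) ** 2
    return ra * l_cm / a_cm2 * 1e-6


def discretise(morph: Morphology, max_dx: float = 0.01) -> CompartmentGraph:
    """Split every branch into uniform compartments of electrotonic length
    ≤ ``max_dx`` (fraction of that branch's λ).

    Leak conductance is area/Rm and axial coupling is the series resistance
    of the two half-compartments it joins, so grid refinement conserves total
    membrane area and intracellular volume exactly.
    """
    if not 0 < max_dx <= 1:
        raise ValueError("max_dx must be in (0, 1]")

    specs = morph.all_branches
    v_rests = {spec.v_rest for spec in specs}
    if len(v_rests) != 1:
        raise ValueError("all branches must share one resting potential")

    child0 = morph.branches[0]
    nseg = [
        max(1, int(math.ceil(spec.electrotonic_length / max_dx - 1e-9)))
        for spec in specs
    ]
    n_total = 1 + sum(nseg)

    parent = np.full(n_total, -1, dtype=np.int64)
    length = np.empty(n_total)
    radius = np.empty(n_total)
    rm = np.empty(n_total)
    ra = np.empty(n_total)
    cm = np.empty(n_total)
    branch_id = np.full(n_total, -1, dtype=np.int64)
    x = np.zeros(n_total)

    # junction: membrane properties of the child branches, tiny length
    length[0] = morph.junction_length
    radius[0] = morph.resolved_junction_radius
    rm[0], ra[0], cm[0] = child0.rm, child0.ra, child0.cm

    branch_first = np.empty(len(specs), dtype=np.int64)
    k = 1
    for b, spec in enumerate(specs):
        m = nseg[b]
        seg_len = spec.resolved_length / m
        lam = spec.lam
        branch_first[b] = k
        for j in range(m):
            parent[k] = 0 if j == 0 else k - 1
            length[k] = seg_len
            radius[k] = spec.radius
            rm[k], ra[k], cm[k] = spec.rm, spec.ra, spec.cm
            branch_id[k] = b
            x[k] = (j + 0.5) * seg_len / lam
            k += 1

    area = 2.0 * math.pi * (radius * 1e-4) * (length * 1e-4)  # cm²
    volume = math.pi * radius**2 * length  # μm³
    g_leak = area / rm * 1e3  # cm²/(kΩ·cm²) = mS -> μS
    cap = cm * area * 1e3  # μF/cm²·cm² = μF -> nF

    g_axial = np.zeros(n_total)
    for j in range(1, n_total):
        p = parent[j]
        r_half = _half_axial_resistance(ra[j], length[j], radius[j])
        r_half += _half_axial_resistance(ra[p], length[p], radius[p])
        g_axial[j] = 1.0 / r_half  # μS

    return CompartmentGraph(
        parent=parent,
        length=length,
        radius=radius,
        area=area,
        volume=volume,
        g_leak=g_leak,
        cap=cap,
        g_axial=g_axial,
        branch_id=branch_id,
        x=x,
        v_rest=v_rests.pop(),
        branch_first=branch_first,
        branch_nseg=np.asarray(nseg, dtype=np.int64),
        branch_elec_len=np.array([s.electrotonic_length for s in specs]),
        sink_branch=len(specs) - 1 if morph.sink is not None else -1,
        morphology=morph,
    )


def locate(graph: CompartmentGraph, branch: int, x: float) -> int:
    """Compartment index whose centre is nearest to electrotonic coordinate
    ``x`` on ``branch``.  ``x = 0`` maps to the junction compartment; exact
    grid-boundary coordinates resolve toward the junction.
    """
    if not 0 <= branch < graph.n_branches:
        raise ValueError(f"branch {branch} out of range")
    lx = graph.branch_elec_len[branch]
    if x < -1e-12 or x > lx + 1e-9:
        raise ValueError(f"X={x} outside [0, {lx:.6g}] on branch {branch}")
    if x <= 1e-12:
        return 0
    m = int(graph.branch_nseg[branch])
    dx = lx / m
    u = x / dx
    k = int(math.floor(u))
    if u - k < 1e-9 and k > 0:  # boundary coordinate: pick the inner segment
        k -= 1
    k = min(k, m - 1)
    return int(graph.branch_first[branch]) + k


class SWCError(ValueError):
    """Malformed SWC document."""


_SWC_CHILD_TYPE = 3  # basal dendrite
_SWC_SINK_TYPE = 4  # apical code reused to flag the sink branch


def to_swc(morph: Morphology, samples_per_branch: int = 10) -> str:
    """Serialise a star tree to a standard 7-column SWC document.

    Branches radiate from a root sample at the origin in the x-y plane; the
    sink branch, if present, is written with SWC type 4 so that a round trip
    preserves its identity.  The 0.01 μm junction compartment is folded into
    the first segment of every branch and subtracted again by ``from_swc``.
    """
    lines = ["# SWC star-tree morphology (dendril)"]
    lines.append(f"1 1 0.0 0.0 0.0 {morph.resolved_junction_radius:.6g} -1")
    idx = 2
    specs = morph.all_branches
    n_all = len(specs)
    for b, spec in enumerate(specs):
        is_sink = morph.sink is not None and b == n_all - 1
        swc_type = _SWC_SINK_TYPE if is_sink else _SWC_CHILD_TYPE
        theta = 2.0 * math.pi * b / n_all
        ux, uy = math.cos(theta), math.sin(theta)
        parent = 1
        for j in range(1, samples_per_branch + 1):
            dist = morph.junction_length + spec.resolved_length * j / samples_per_branch
            lines.append(
                f"{idx} {swc_type} {dist * ux:.6f} {dist * uy:.6f} 0.0 "
                f"{spec.radius:.6g} {parent}"
            )
            parent = idx
            idx += 1
    return "\n".join(lines) + "\n"


def from_swc(document: str, template: BranchSpec | None = None) -> Morphology:
    """Parse an SWC document into a star-tree :class:`Morphology`.

    Electrical parameters are not represented in SWC; they are taken from
    ``template`` (default :class:`BranchSpec` values).  The document must be
    a tree with a single root whose children start unbranched chains.
    """
    template = template if template is not None else BranchSpec()
    samples: dict[int, tuple[int, float, float, float, float, int]] = {}
    for lineno, raw in enumerate(document.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise SWCError(f"line {lineno}: expected 7 columns, got {len(parts)}")
        try:
            sid = int(parts[0])
            stype = int(parts[1])
            px, py, pz, rad = (float(v) for v in parts[2:6])
            par = int(parts[6])
        except ValueError as exc:
            raise SWCError(f"line {lineno}: {exc}") from None
        if sid in samples:
            raise SWCError(f"line {lineno}: duplicate sample id {sid}")
        samples[sid] = (stype, px, py, pz, rad, par)

    roots = [sid for sid, s in samples.items() if s[5] == -1]
    if len(roots) != 1:
        raise SWCError(f"expected exactly one root sample, found {len(roots)}")
    root = roots[0]

    children: dict[int, list[int]] = {sid: [] for sid in samples}
    for sid, s in samples.items():
        par = s[5]
        if par == -1:
            continue
        if par not in samples:
            raise SWCError(f"sample {sid} references missing parent {par}")
        children[par].append(sid)

    # cycle / reachability check
    seen: set[int] = set()
    stack = [root]
    while stack:
        sid = stack.pop()
        if sid in seen:
            raise SWCError("SWC graph contains a cycle")
        seen.add(sid)
        stack.extend(children[sid])
    if len(seen) != len(samples):
        raise SWCError("SWC graph contains a cycle or disconnected samples")

    def dist(a: int, b: int) -> float:
        _, ax, ay, az, _, _ = samples[a]
        _, bx, by, bz, _, _ = samples[b]
        return math.dist((ax, ay, az), (bx, by, bz))

    branches: list[BranchSpec] = []
    sink: BranchSpec | None = None
    for head in children[root]:
        total = dist(root, head)
        radii = [samples[head][4]]
        stype = samples[head][0]
        node = head
        while children[node]:
            if len(children[node]) > 1:
                raise SWCError("non-star morphology: branching away from the root")
            nxt = children[node][0]
            total += dist(node, nxt)
            radii.append(samples[nxt][4])
            node = nxt
        spec = replace(
            template,
            radius=float(np.median(radii)),
            length=max(total - JUNCTION_LENGTH, 1e-9),
        )
        if stype == _SWC_SINK_TYPE:
            if sink is not None:
                raise SWCError("more than one sink (type 4) branch")
            sink = spec
        else:
            branches.append(spec)

    if not branches:
        raise SWCError("no child branches found")
    return Morphology(
        branches=tuple(branches), sink=sink, junction_radius=samples[root][4]
    )
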