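"""Neuronal morphologies: SWC reading, d_lambda discretization, and
conductance distribution over somatodendritic compartments.

A morphology is a tree of unbranched sections (soma / axon / dendrite), each
an ordered polyline of 3D points with per-point diameters.  Discretization
follows the d_lambda rule: each section is split into an odd number of equal
arc-length compartments no longer than a fraction (default 0.1) of the AC
length constant lambda_f at f = 100 Hz.  Compartment membrane areas are sums
of frustum lateral areas; path distances are measured along the tree from the
midpoint of the soma section.

The ``H_dist`` parameter selects the centripetal extent of dendrite that
carries h-channels: all somatic compartments plus every dendritic compartment
whose path distance from the soma does not exceed ``H_dist`` times the cell's
maximal dendritic path distance.  Distributing a total conductance uniformly
over the selected membrane yields the per-area channel density.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Morphology",
    "Section",
    "CompartmentalModel",
    "DistributionSpec",
    "SWCError",
    "REGION_SOMA",
    "REGION_AXON",
    "REGION_DEND",
    "load_swc",
    "save_swc",
    "lambda_f",
    "discretize",
    "surface_area",
    "select_by_hdist",
    "distribute_conductance",
    "PS_PER_UM2_TO_S_PER_CM2",
]

# 1 um^2 = 1e-8 cm^2, so 1 pS/um^2 = 1e-12 S / 1e-8 cm^2 = 1e-4 S/cm^2.
PS_PER_UM2_TO_S_PER_CM2 = 1.0e-4

REGION_SOMA = 0
REGION_AXON = 1
REGION_DEND = 2

_REGION_NAMES = {REGION_SOMA: "soma", REGION_AXON: "axon", REGION_DEND: "dend"}
_SWC_TYPE_TO_REGION = {1: REGION_SOMA, 2: REGION_AXON, 3: REGION_DEND}


class SWCError(ValueError):
    """Malformed or structurally invalid SWC content."""


@dataclass
class Section:
    """Unbranched stretch of neurite (or the soma).

    ``points`` is an (n, 4) array of x, y, z, diameter in um.  ``parent`` is
    the index of the parent section in the owning :class:`Morphology`
    (-1 for the root).  A single-point soma is stored as a cylinder with
    length equal to its diameter (area-equivalent sphere convention used by
    common simulators).
    """

    region: int
    points: np.ndarray
    parent: int = -1

    @property
    def region_name(self) -> str:
        return _REGION_NAMES[self.region]

    @property
    def length(self) -> float:
        """Arc length in um."""
        p = self.points[:, :3]
        if len(p) == 1:  # single-point soma-as-cylinder
            return float(self.points[0, 3])
        return float(np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1)))

    def arc_diameters(self) -> tuple[np.ndarray, np.ndarray]:
        """Cumulative arc positions (um) and diameters at each point."""
        if len(self.points) == 1:
            d = self.points[0, 3]
            return np.array([0.0, d]), np.array([d, d])
        seg = np.linalg.norm(np.diff(self.points[:, :3], axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        return arc, self.points[:, 3].copy()

    def diameter_at(self, s: float) -> float:
        """Diameter (um) at normalized arc position ``s`` in [0, 1]."""
        arc, diam = self.arc_diameters()
        return float(np.interp(s * arc[-1], arc, diam))


@dataclass
class Morphology:
    sections: list[Section] = field(default_factory=list)

    @property
    def root(self) -> int:
        roots = [i for i, s in enumerate(self.sections) if s.parent < 0]
        if len(roots) != 1:
            raise SWCError(f"morphology must have exactly one root, found {len(roots)}")
        return roots[0]

    @property
    def soma(self) -> int:
        for i, s in enumerate(self.sections):
            if s.region == REGION_SOMA:
                return i
        raise SWCError("morphology has no soma section")

    def validate(self) -> None:
        root = self.root
        for i, s in enumerate(self.sections):
            if np.any(s.points[:, 3] <= 0):
                raise SWCError(f"section {i} has non-positive diameter")
            if s.parent >= len(self.sections):
                raise SWCError(f"section {i} parent {s.parent} out of range")
        # acyclic / connected: every section must reach the root
        for i in range(len(self.sections)):
            seen, j = set(), i
            while j != root:
                if j in seen:
                    raise SWCError(f"cycle detected at section {i}")
                seen.add(j)
                j = self.sections[j].parent


def load_swc(path) -> Morphology:
    """Read a standard 7-column SWC file into a :class:`Morphology`.

    Sections are maximal unbranched sample chains; chains break at branch
    points and at type-code changes.  Type codes 1/2/3 map to soma/axon/dend;
    unknown codes map to dend with a warning.  Contiguous soma samples form a
    single frustum-chain soma section.
    """
    samples: dict[int, tuple[int, float, float, float, float, int]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            cols = line.split()
            if len(cols) != 7:
                raise SWCError(f"line {lineno}: expected 7 columns, got {len(cols)}")
            try:
                sid = int(cols[0])
                stype = int(cols[1])
                x, y, z, r = (float(c) for c in cols[2:6])
                parent = int(cols[6])
            except ValueError as exc:
                raise SWCError(f"line {lineno}: {exc}") from None
            if sid in samples:
                raise SWCError(f"line {lineno}: duplicate sample id {sid}")
            samples[sid] = (stype, x, y, z, 2.0 * r, parent)
    if not samples:
        raise SWCError("empty SWC file")

    roots = [sid for sid, s in samples.items() if s[5] < 0]
    if len(roots) != 1:
        raise SWCError(f"expected exactly one root sample, found {len(roots)}")
    for sid, s in samples.items():
        if s[5] >= 0 and s[5] not in samples:
            raise SWCError(f"sample {sid} references missing parent {s[5]}")

    children: dict[int, list[int]] = {}
    for sid, s in sorted(samples.items()):
        if s[5] >= 0:
            children.setdefault(s[5], []).append(sid)

    def region_of(stype: int) -> int:
        if stype not in _SWC_TYPE_TO_REGION:
            warnings.warn(
                f"unknown SWC type code {stype}; treating as dendrite", stacklevel=2
            )
            return REGION_DEND
        return _SWC_TYPE_TO_REGION[stype]

    sections: list[Section] = []
    sec_of_sample: dict[int, int] = {}
    # depth-first over sample chains
    stack: list[tuple[int, int]] = [(roots[0], -1)]  # (sample id, parent section)
    while stack:
        sid, parent_sec = stack.pop()
        chain = [sid]
        region = region_of(samples[sid][0])
        while True:
            kids = children.get(chain[-1], [])
            if len(kids) == 1 and region_of(samples[kids[0]][0]) == region:
                chain.append(kids[0])
            else:
                break
        pts = np.array(
            [[samples[s][1], samples[s][2], samples[s][3], samples[s][4]] for s in chain]
        )
        sec_idx = len(sections)
        sections.append(Section(region=region, points=pts, parent=parent_sec))
        for s in chain:
            sec_of_sample[s] = sec_idx
        for kid in children.get(chain[-1], []):
            if kid not in sec_of_sample:
                stack.append((kid, sec_idx))

    m = Morphology(sections=sections)
    m.validate()
    return m


def save_swc(morph: Morphology, path) -> None:
    """Write a morphology back to 7-column SWC (fixture writer for toy cells)."""
    region_to_type = {REGION_SOMA: 1, REGION_AXON: 2, REGION_DEND: 3}
    lines = []
    next_id = 1
    last_id_of_sec: dict[int, int] = {}
    order = _topological_order(morph)
    for si in order:
        sec = morph.sections[si]
        parent_id = last_id_of_sec.get(sec.parent, -1)
        for p in sec.points:
            lines.append(
                f"{next_id} {region_to_type[sec.region]} "
                f"{p[0]:.4f} {p[1]:.4f} {p[2]:.4f} {p[3] / 2.0:.4f} {parent_id}"
            )
            parent_id = next_id
            next_id += 1
        last_id_of_sec[si] = next_id - 1
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _topological_order(morph: Morphology) -> list[int]:
    order, stack = [], [morph.root]
    kids: dict[int, list[int]] = {}
    for i, s in enumerate(morph.sections):
        if s.parent >= 0:
            kids.setdefault(s.parent, []).append(i)
    while stack:
        i = stack.pop()
        order.append(i)
        stack.extend(reversed(kids.get(i, [])))
    return order


def lambda_f(diam_um: float, f: float, Ra: float, Cm: float) -> float:
    """AC length constant in um.

    lambda_f = (1/2) sqrt(d / (pi f Ra Cm)) in consistent units; with d in um,
    Ra in Ohm*cm and Cm in uF/cm^2 the unit algebra yields the familiar
    1e5 * sqrt(d / (4 pi f Ra Cm)) um.
    """
    return 1e5 * math.sqrt(diam_um / (4.0 * math.pi * f * Ra * Cm))


@dataclass
class CompartmentalModel:
    """Flat compartment arrays over a discretized morphology.

    Arrays are indexed by compartment; ``parent`` gives the index of the
    parent compartment (-1 at the root, which is the middle soma compartment).
    ``r_axial_per_ra`` is the axial resistance between a compartment's center
    and its parent's center per unit Ra (MOhm per Ohm*cm), so the electrical
    system for any Ra is a pure rescaling.
    """

    morphology: Morphology
    section: np.ndarray  # section index per compartment
    position: np.ndarray  # normalized arc position of compartment center
    length: np.ndarray  # um
    area: np.ndarray  # um^2
    diameter: np.ndarray  # effective diameter (um), area / (pi L)
    path_distance: np.ndarray  # um, from soma section midpoint
    region: np.ndarray  # REGION_* codes
    parent: np.ndarray  # parent compartment index
    r_axial_per_ra: np.ndarray  # MOhm per (Ohm*cm) of Ra, center-to-parent-center
    fraction: float = 0.1
    f: float = 100.0

    @property
    def n(self) -> int:
        return len(self.area)

    @property
    def soma_index(self) -> int:
        """Index of the middle soma compartment (recording/injection site)."""
        soma = np.flatnonzero(self.region == REGION_SOMA)
        return int(soma[len(soma) // 2])

    def compartments_of(self, region: int) -> np.ndarray:
        return np.flatnonzero(self.region == region)

    @property
    def max_dendritic_path(self) -> float:
        dend = self.region == REGION_DEND
        return float(self.path_distance[dend].max()) if dend.any() else 0.0


def _frustum_area(d1: float, d2: float, L: float) -> float:
    """Lateral surface of a conical frustum (um^2)."""
    return math.pi * 0.5 * (d1 + d2) * math.hypot(L, 0.5 * (d1 - d2))


def _section_compartments(sec: Section, nseg: int):
    """Per-compartment (length, area, axial resistance factor, center arc).

    The axial factor is resistance per unit Ra in MOhm/(Ohm*cm): integral of
    4/(pi d^2) dl along the compartment, with l in um converted to cm and the
    result to MOhm.
    """
    arc, diam = sec.arc_diameters()
    L = arc[-1]
    edges = np.linspace(0.0, L, nseg + 1)
    # refine the arc sampling so tapering within a compartment is integrated
    sub = np.unique(np.concatenate([arc, edges, np.linspace(0, L, 8 * nseg + 1)]))
    dsub = np.interp(sub, arc, diam)
    areas = np.zeros(nseg)
    rax = np.zeros(nseg)
    for i, (a, b) in enumerate(zip(sub[:-1], sub[1:])):
        j = np.searchsorted(edges, 0.5 * (a + b), side="right") - 1
        j = min(max(j, 0), nseg - 1)
        d1, d2 = dsub[i], dsub[i + 1]
        areas[j] += _frustum_area(d1, d2, b - a)
        # frustum axial resistance: 4 Ra L / (pi d1 d2); um -> cm is 1e-4,
        # um^-1 from d1 d2 is 1e8, Ohm -> MOhm is 1e-6  => net 1e-2... careful:
        # R = Ra * 4 * (L um * 1e-4 cm/um) / (pi * d1 d2 um^2 * 1e-8 cm^2/um^2)
        #   = Ra * 4 L / (pi d1 d2) * 1e4 Ohm  -> * 1e-6 MOhm = * 1e-2
        rax[j] += 4.0 * (b - a) / (math.pi * d1 * d2) * 1e-2
    lengths = np.full(nseg, L / nseg)
    centers = (edges[:-1] + edges[1:]) / (2.0 * L) if L > 0 else np.zeros(nseg)
    return lengths, areas, rax, centers


def discretize(
    morph: Morphology,
    fraction: float = 0.1,
    f: float = 100.0,
    Ra: float = 150.0,
    Cm: float = 1.0,
) -> CompartmentalModel:
    """Split each section into an odd number of compartments by the d_lambda rule.

    Per section the compartment count is
    ``2 * floor((L / (fraction * lambda_f) + 0.9) / 2) + 1`` with lambda_f
    evaluated at the section's midpoint diameter.  Raises on zero-length or
    degenerate sections.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    if Ra <= 0 or Cm <= 0 or f <= 0:
        raise ValueError("Ra, Cm and f must be positive")
    morph.validate()

    order = _topological_order(morph)
    sec_arrays: dict[int, tuple] = {}
    nsegs: dict[int, int] = {}
    for si in order:
        sec = morph.sections[si]
        L = sec.length
        if L <= 0:
            raise ValueError(f"section {si} has zero length")
        lam = lambda_f(sec.diameter_at(0.5), f, Ra, Cm)
        nseg = 2 * int((L / (fraction * lam) + 0.9) / 2.0) + 1
        nsegs[si] = nseg
        sec_arrays[si] = _section_compartments(sec, nseg)

    # assemble flat arrays, parents, and path distances
    sec_idx, pos, lengths, areas, rax, regions = [], [], [], [], [], []
    parents, pathd = [], []
    first_comp: dict[int, int] = {}
    last_comp: dict[int, int] = {}
    # distance from soma-section midpoint to the *end* of each section
    end_dist: dict[int, float] = {}
    # per-compartment half axial factors toward each neighbor
    r_half_start: list[float] = []  # from compartment center to its start edge
    r_half_end: list[float] = []

    root = morph.root
    for si in order:
        sec = morph.sections[si]
        lens, ars, rx, centers = sec_arrays[si]
        n0 = len(areas)
        first_comp[si] = n0
        L = sec.length
        if si == root:
            start_dist = -0.5 * L  # signed arc from section midpoint
        else:
            start_dist = end_dist[sec.parent]
        for j in range(nsegs[si]):
            sec_idx.append(si)
            pos.append(centers[j])
            lengths.append(lens[j])
            areas.append(ars[j])
            rax.append(rx[j])
            regions.append(sec.region)
            r_half_start.append(rx[j] / 2.0)
            r_half_end.append(rx[j] / 2.0)
            if si == root:
                pathd.append(abs(start_dist + centers[j] * L))
            else:
                pathd.append(start_dist + centers[j] * L)
            if j == 0:
                if si == root:
                    parents.append(-1)
                else:
                    # attach to parent: soma children attach at the soma
                    # midpoint compartment, others at the parent's last
                    psec = sec.parent
                    if morph.sections[psec].region == REGION_SOMA:
                        soma_n = nsegs[psec]
                        parents.append(first_comp[psec] + soma_n // 2)
                    else:
                        parents.append(last_comp[psec])
            else:
                parents.append(n0 + j - 1)
        last_comp[si] = len(areas) - 1
        if si == root:
            end_dist[si] = 0.5 * L
        else:
            end_dist[si] = start_dist + L
        if sec.region == REGION_SOMA:
            # children measured from the soma midpoint
            end_dist[si] = 0.5 * L

    # center-to-parent-center axial factors
    r_axial = np.zeros(len(areas))
    for i, p in enumerate(parents):
        if p < 0:
            continue
        if sec_idx[i] == sec_idx[p]:
            r_axial[i] = r_half_start[i] + r_half_end[p]
        else:
            # section junction: child start half + parent end half
            r_axial[i] = r_half_start[i] + r_half_end[p]

    # the root must precede children in index order for the tree solve
    parents = np.asarray(parents, dtype=np.int64)
    if np.any(parents >= np.arange(len(parents))):
        raise RuntimeError("compartment ordering violates parent-before-child")

    areas = np.asarray(areas)
    lengths = np.asarray(lengths)
    model = CompartmentalModel(
        morphology=morph,
        section=np.asarray(sec_idx, dtype=np.int64),
        position=np.asarray(pos),
        length=lengths,
        area=areas,
        diameter=areas / (math.pi * lengths),
        path_distance=np.asarray(pathd),
        region=np.asarray(regions, dtype=np.int64),
        parent=parents,
        r_axial_per_ra=r_axial,
        fraction=fraction,
        f=f,
    )
    if np.any(model.area <= 0):
        raise ValueError("degenerate geometry: compartment with zero area")
    return model


def surface_area(model: CompartmentalModel, selection=None) -> float:
    """Total membrane area (um^2) over ``selection`` (indices or bool mask).

    ``selection=None`` sums the whole cell.  Raises on an empty selection.
    """
    if selection is None:
        return float(model.area.sum())
    sel = np.asarray(selection)
    if sel.dtype == bool:
        sel = np.flatnonzero(sel)
    if sel.size == 0:
        raise ValueError("empty compartment selection")
    return float(model.area[sel].sum())


def select_by_hdist(model: CompartmentalModel, h_dist: float) -> np.ndarray:
    """Compartment indices carrying h-channels for a given ``H_dist``.

    All somatic compartments, plus dendritic compartments whose path distance
    from the soma is at most ``h_dist`` times the cell's maximal dendritic
    path distance.  The axon never carries h-channels.  ``h_dist = 0`` is
    soma-only; ``h_dist = 1`` is the full somatodendritic membrane.
    """
    if not (0.0 <= h_dist <= 1.0):
        raise ValueError("H_dist must lie in [0, 1]")
    mask = model.region == REGION_SOMA
    if h_dist > 0:
        cutoff = h_dist * model.max_dendritic_path
        mask |= (model.region == REGION_DEND) & (model.path_distance <= cutoff)
    return np.flatnonzero(mask)


def distribute_conductance(
    model: CompartmentalModel, total_gh_nS: float, selection
) -> float:
    """Uniform density (pS/um^2) that spreads ``total_gh_nS`` over ``selection``.

    density * selected area reproduces the total conductance exactly
    (1 nS = 1000 pS).
    """
    if total_gh_nS < 0:
        raise ValueError("total conductance must be non-negative")
    area = surface_area(model, selection)
    if area <= 0:
        raise ZeroDivisionError("selected membrane area is zero")
    return total_gh_nS * 1e3 / area


@dataclass
class DistributionSpec:
    """An H_dist choice together with its implied uniform density."""

    h_dist: float
    total_gh_nS: float
    density_ps_um2: float = 0.0

    def resolve(self, model: CompartmentalModel) -> "DistributionSpec":
        sel = select_by_hdist(model, self.h_dist)
        self.density_ps_um2 = distribute_conductance(model, self.total_gh_nS, sel)
        return self
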