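"""Ground-truth synthetic cells and virtual recording sessions.

Stands in for the study's recordings: toy OLM-like morphologies (soma, a few
long thin bifurcating dendrites, one axon; somatodendritic area in the
20,000-36,000 um^2 envelope of reconstructed OLM cells) carrying known
passive and h-channel parameters, run through the full chronological protocol
suite (current-clamp step families with and without h-channel block,
voltage-clamp activation and tail-current families) with additive Gaussian
recording noise and an optional late-session degradation: protocols recorded
last get a noise-amplitude ramp and a slow baseline drift across sweeps,
emulating deteriorating seal quality toward the end of a session.

Presets ``cell1``/``cell2`` copy the published per-cell parameter sets onto
toy morphologies matched to the published surface areas; ``point`` is a
single-compartment cell used for extraction-recovery tests; ``random``
samples within OLM-plausible ranges.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .channels import IhParams, NaTParams
from .io import write_dataset
from .model import CellModel
from .morphology import (
    Morphology,
    REGION_DEND,
    REGION_SOMA,
    Section,
    save_swc,
    surface_area,
)
from .simulator import (
    PassiveParams,
    PharmacologyFlags,
    Protocol,
    Simulator,
    Sweep,
    Trace,
    apply_pharmacology,
    cc_step_protocol,
    vc_activation_protocol,
    vc_tail_protocol,
)

__all__ = [
    "NoiseModel",
    "GroundTruthCell",
    "make_cell",
    "toy_morphology",
    "add_noise",
    "run_suite",
    "holding_current_for",
    "PRESETS",
]


@dataclass
class NoiseModel:
    """Additive recording noise and late-session degradation.

    ``sigma_cc``/``sigma_vc`` are white-noise SDs (mV / pA).  Protocols in the
    degraded (late) part of the session get a noise multiplier ramping from 1
    to ``late_mult`` across sweeps plus a baseline drift ramp (mV/s or pA/s,
    scaled the same way), so the last sweeps recorded are the worst — the
    pattern that makes the -120 pA trace preferable for fitting.
    """

    sigma_cc: float = 0.2  # mV
    sigma_vc: float = 2.0  # pA
    late_mult: float = 3.0
    drift_cc: float = 0.5  # mV/s on late sweeps
    drift_vc: float = 0.0  # the slow baseline ramp is a current-clamp artifact

    def __post_init__(self) -> None:
        if self.sigma_cc < 0 or self.sigma_vc < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.late_mult < 1.0:
            raise ValueError("late-session multiplier must be >= 1")

    @classmethod
    def none(cls) -> "NoiseModel":
        return cls(sigma_cc=0.0, sigma_vc=0.0, late_mult=1.0, drift_cc=0.0, drift_vc=0.0)


def add_noise(
    trace: Trace, sigma: float, rng: np.random.Generator, drift_per_s: float = 0.0
) -> Trace:
    """Additive white noise plus an optional linear baseline ramp.

    Reproducible given the generator state; noise parameters are recorded in
    the trace metadata.
    """
    out = trace.copy()
    if sigma > 0:
        out.y = out.y + rng.normal(0.0, sigma, size=len(out.y))
    if drift_per_s != 0.0:
        out.y = out.y + drift_per_s * out.t / 1000.0
    out.meta["noise_sigma"] = sigma
    out.meta["noise_drift_per_s"] = drift_per_s
    return out


# published per-cell parameter sets (voltage-clamp-derived I_h, re-fitted
# passive backbone) mapped onto toy morphologies with matching areas
PRESETS: dict[str, dict] = {
    "cell1": {
        "passive": dict(Ra=125.2, Cm=0.27, Gpas=7.58e-6, Epas=-64.6),
        "ih": dict(
            e_h=-34.0, v_half=-103.4, k=8.63,
            t1=8.03, t2=0.025, t3=-4.40, t4=0.15, t5=7.32e-6,
            gh_total_nS=4.17, h_dist=1.0,
        ),
        "soma_area": 7651.0,
        "total_area": 29378.0,
        "n_dend": 5,
        "holding_spiking_pA": 4.0,
    },
    "cell2": {
        "passive": dict(Ra=348.1, Cm=0.38, Gpas=1.19e-5, Epas=-61.8),
        "ih": dict(
            e_h=-27.9, v_half=-100.1, k=11.16,
            t1=8.98, t2=0.035, t3=-8.49, t4=0.19, t5=3.57e-7,
            gh_total_nS=3.64, h_dist=1.0,
        ),
        "soma_area": 13035.0,
        "total_area": 35159.0,
        "n_dend": 5,
        "holding_spiking_pA": -5.0,
    },
}

# stylized spiking-channel densities (pS/um^2 per region) for the optimization
# target cell: OLM-like firing (silent at +30 pA, ~5-9 Hz at +60/+90 pA),
# no spontaneous or rebound spikes at the -72 mV holding, and near-silent
# spiking conductances over the hyperpolarized range so the full model's
# hyperpolarizing responses track the h-channel-only model
SPIKING_DENSITIES: dict[str, dict[str, float]] = {
    "kdrf": {"soma": 50.0, "dend": 25.0, "axon": 100.0},
    "kdrs": {"soma": 2.0, "dend": 1.0, "axon": 2.0},
    "ka": {"soma": 30.0, "dend": 18.0, "axon": 0.0},
    "m": {"soma": 2.0, "dend": 0.0, "axon": 2.0},
    "kca": {"soma": 4.0, "dend": 2.0, "axon": 0.0},
    "cat": {"soma": 0.0, "dend": 1.0, "axon": 0.0},
    "cal": {"soma": 0.0, "dend": 1.0, "axon": 0.0},
}
# somatic Na_T unshifted; dendritic/axonal Na_T shifted depolarized (as in
# the published top models) so the left-shifted dendritic rate equations do
# not destabilize the resting state
SPIKING_NAT = dict(
    g_soma=120.0,
    g_dend=32.0,
    g_axon=240.0,
    e_na=90.0,
    v_shift_soma=0.0,
    v_shift_dend=5.0,
    v_shift_axon=7.0,
)


@dataclass
class GroundTruthCell:
    """A fully known synthetic cell: every emitted trace is re-derivable."""

    name: str
    seed: int
    model: CellModel
    holding_spiking_pA: float = 0.0

    @property
    def ih(self) -> IhParams:
        return self.model.ih

    @property
    def passive(self) -> PassiveParams:
        return self.model.passive

    def parameter_dict(self) -> dict:
        d = {
            "name": self.name,
            "seed": self.seed,
            "passive": asdict(self.passive),
            "ih": asdict(self.ih) if self.ih else None,
            "nat": asdict(self.model.nat) if self.model.nat else None,
            "spiking": self.model.spiking,
            "holding_spiking_pA": self.holding_spiking_pA,
        }
        return d

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        save_swc(self.model.morphology, outdir / f"{self.name}.swc")
        (outdir / f"{self.name}_params.json").write_text(
            json.dumps(self.parameter_dict(), indent=1)
        )


def _unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


# toy dendrite template: (span fraction, start diameter um, end diameter um)
# per branch order — a thin trunk splitting twice, most membrane distal, as
# in reconstructed OLM trees
_DEND_ORDERS = ((0.25, 1.6, 1.3), (0.35, 1.1, 0.9), (0.40, 0.8, 0.6))


def toy_morphology(
    rng: np.random.Generator,
    soma_area: float = 8000.0,
    dend_area: float = 18000.0,
    n_dend: int = 5,
    with_axon: bool = True,
) -> Morphology:
    """Soma + ``n_dend`` thin bifurcating dendrites + one thin axon.

    The soma is an area-matched cylinder (L = d); each dendrite runs a
    trunk that bifurcates twice (1 trunk, 2 daughters, 4 granddaughters;
    diameters tapering 1.6 -> 0.6 um), placing most dendritic membrane
    behind substantial axial resistance — the electrotonic profile of
    reconstructed OLM trees.  Dendritic spans are solved so the total
    somatodendritic area matches ``soma_area + dend_area``.
    """
    d_soma = math.sqrt(soma_area / math.pi)
    sections = [
        Section(
            region=REGION_SOMA,
            points=np.array([[0, 0, -d_soma / 2, d_soma], [0, 0, d_soma / 2, d_soma]]),
        )
    ]
    per_len = math.pi * sum(
        (2.0**order) * frac * 0.5 * (d0 + d1)
        for order, (frac, d0, d1) in enumerate(_DEND_ORDERS)
    )
    span = dend_area / (n_dend * per_len)
    dirs = _unit_vectors(rng, n_dend)
    jitter = rng.uniform(0.85, 1.15, size=n_dend)
    jitter *= n_dend / jitter.sum()  # keep the total area on target

    def sidestep(u, sign, angle=0.4):
        side = _unit_vectors(rng, 1)[0]
        side = side - np.dot(side, u) * u
        nrm = np.linalg.norm(side)
        side = side / nrm if nrm > 1e-9 else np.array([u[1], -u[0], 0.0])
        w = u * math.cos(angle) + sign * side * math.sin(angle)
        return w / np.linalg.norm(w)

    for i in range(n_dend):
        L = span * jitter[i]
        u = dirs[i]
        # (parent section index, origin, direction) per growing tip
        tips = [(0, u * (d_soma / 2), u)]
        for frac, d0, d1 in _DEND_ORDERS:
            new_tips = []
            for parent_idx, origin, direction in tips:
                end = origin + direction * (frac * L)
                sec_idx = len(sections)
                sections.append(
                    Section(
                        region=REGION_DEND,
                        points=np.array([[*origin, d0], [*end, d1]]),
                        parent=parent_idx,
                    )
                )
                for sign in (+1.0, -1.0):
                    new_tips.append((sec_idx, end, sidestep(direction, sign)))
            tips = new_tips
    if with_axon:
        u = _unit_vectors(rng, 1)[0]
        sections.append(
            Section(
                region=1,  # axon
                points=np.array(
                    [[*(u * d_soma / 2), 1.0], [*(u * (d_soma / 2 + 400.0)), 1.0]]
                ),
                parent=0,
            )
        )
    return Morphology(sections=sections)


def _compact_morphology(rng: np.random.Generator) -> Morphology:
    """Small unbranched-dendrite cell for optimization runs: soma + three
    stout tapered dendrites + axon (~45 compartments), keeping evolutionary
    evaluations fast while preserving soma/dendrite/axon regions."""
    d_soma = math.sqrt(7000.0 / math.pi)
    sections = [
        Section(
            region=REGION_SOMA,
            points=np.array([[0, 0, -d_soma / 2, d_soma], [0, 0, d_soma / 2, d_soma]]),
        )
    ]
    for u, L in zip(_unit_vectors(rng, 3), (480.0, 520.0, 550.0)):
        o = u * d_soma / 2
        tip = o + u * L
        sections.append(
            Section(
                region=REGION_DEND,
                points=np.array([[*o, 2.2], [*tip, 1.4]]),
                parent=0,
            )
        )
    u = _unit_vectors(rng, 1)[0]
    sections.append(
        Section(
            region=1,
            points=np.array([[*(u * d_soma / 2), 1.0], [*(u * (d_soma / 2 + 350)), 1.0]]),
            parent=0,
        )
    )
    return Morphology(sections)


def _point_morphology(area_um2: float = 10000.0) -> Morphology:
    d = math.sqrt(area_um2 / math.pi)
    return Morphology(
        [
            Section(
                region=REGION_SOMA,
                points=np.array([[0, 0, -d / 2, d], [0, 0, d / 2, d]]),
            )
        ]
    )


def make_cell(
    preset: str = "cell1",
    seed: int = 0,
    h_dist: float | None = None,
    spiking: bool = False,
) -> GroundTruthCell:
    """Deterministically build a ground-truth cell.

    ``preset`` is 'cell1', 'cell2', 'random' (parameters sampled within
    OLM-plausible ranges) or 'point' (single-compartment, soma-only h-channels
    for clean extraction tests).  ``h_dist`` overrides the h-channel extent;
    ``spiking=True`` attaches the stylized spiking-channel complement.
    """
    rng = np.random.default_rng(seed)
    if preset == "point":
        morph = _point_morphology()
        passive = PassiveParams(Ra=150.0, Cm=0.9, Gpas=1.0e-5, Epas=-65.0)
        ih = IhParams(h_dist=0.0 if h_dist is None else h_dist)
        model = CellModel(morphology=morph, passive=passive, ih=ih)
        return GroundTruthCell(name=f"point_s{seed}", seed=seed, model=model)
    if preset == "spiker":
        # compact optimization testbed: cell1-like biophysics on a small tree
        p = PRESETS["cell1"]
        morph = _compact_morphology(rng)
        model = CellModel(
            morphology=morph,
            passive=PassiveParams(**p["passive"]),
            ih=IhParams(**p["ih"]) if h_dist is None else IhParams(
                **{**p["ih"], "h_dist": h_dist}
            ),
            nat=NaTParams(**SPIKING_NAT),
            spiking={k: dict(v) for k, v in SPIKING_DENSITIES.items()},
        )
        return GroundTruthCell(
            name=f"spiker_s{seed}", seed=seed, model=model, holding_spiking_pA=4.0
        )
    if preset in PRESETS:
        p = PRESETS[preset]
        morph = toy_morphology(
            rng,
            soma_area=p["soma_area"],
            dend_area=p["total_area"] - p["soma_area"],
            n_dend=p["n_dend"],
        )
        passive = PassiveParams(**p["passive"])
        ih_kw = dict(p["ih"])
        if h_dist is not None:
            ih_kw["h_dist"] = h_dist
        ih = IhParams(**ih_kw)
        nat = NaTParams(**SPIKING_NAT) if spiking else None
        model = CellModel(
            morphology=morph,
            passive=passive,
            ih=ih,
            nat=nat,
            spiking=dict(SPIKING_DENSITIES) if spiking else None,
        )
        return GroundTruthCell(
            name=f"{preset}_s{seed}",
            seed=seed,
            model=model,
            holding_spiking_pA=p["holding_spiking_pA"],
        )
    if preset == "random":
        soma_area = rng.uniform(7000.0, 13000.0)
        total = rng.uniform(21000.0, 36000.0)
        morph = toy_morphology(
            rng,
            soma_area=soma_area,
            dend_area=total - soma_area,
            n_dend=int(rng.integers(4, 7)),
        )
        passive = PassiveParams(
            Ra=rng.uniform(120.0, 360.0),
            Cm=rng.uniform(0.25, 0.6),
            Gpas=rng.uniform(7e-6, 1.3e-5),
            Epas=rng.uniform(-76.0, -61.0),
        )
        ih = IhParams(
            e_h=rng.uniform(-35.0, -25.0),
            v_half=rng.uniform(-112.0, -99.0),
            k=rng.uniform(7.0, 11.0),
            t1=rng.uniform(8.0, 12.0),
            t2=rng.uniform(0.02, 0.05),
            t3=rng.uniform(-9.0, -4.0),
            t4=rng.uniform(0.1, 0.2),
            t5=rng.uniform(0.0, 5.0),
            gh_total_nS=rng.uniform(2.0, 4.5),
            h_dist=1.0 if h_dist is None else h_dist,
        )
        model = CellModel(morphology=morph, passive=passive, ih=ih)
        return GroundTruthCell(name=f"random_s{seed}", seed=seed, model=model)
    raise ValueError(f"unknown preset {preset!r}")


def holding_current_for(
    sim: Simulator, v_target: float, bracket_pA: float = 200.0, tol_mV: float = 0.05
) -> float:
    """Holding current (pA) that settles the soma at ``v_target`` (bisection)."""

    def settled_v(i_pA: float) -> float:
        proto = Protocol(
            name="hold",
            mode="cc",
            holding=i_pA,
            sweeps=[Sweep(label="hold", levels=[(0.0, 500.0)])],
        )
        tr = sim.run_protocol(proto, dt=0.25, settle_ms=4000.0, settle_dt=0.5)[0]
        tail = tr.y[len(tr.y) // 2 :]
        if np.ptp(tail) > 20.0:  # spiking: the cell is above target, not settled
            return float(np.max(tail))
        return float(np.median(tail))

    lo, hi = -bracket_pA, bracket_pA
    v_lo, v_hi = settled_v(lo), settled_v(hi)
    if not (v_lo < v_target < v_hi):
        raise ValueError("holding-current bracket does not contain the target")
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        v = settled_v(mid)
        if abs(v - v_target) < tol_mV:
            return mid
        if v < v_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# chronological protocol plan: (key, order index, degraded?)
_SUITE_ORDER = [
    ("cc_ctrl", 2, False),
    ("vc_act_ttx", 3, False),
    ("cc_ttx", 4, False),
    ("vc_tail_ttx", 6, False),
    ("cc_zd", 7, True),
    ("vc_act_zd", 8, True),
    ("vc_tail_zd", 8, True),
]

_HYPERPOL_AMPS = (-120, -90, -60, -30)

# current-clamp baseline in the junction-corrected frame (nominal -60 mV
# amplifier setting minus the 11.88 mV junction potential)
CC_HOLDING_MV = -72.0


def run_suite(
    cell: GroundTruthCell,
    noise: NoiseModel | None = None,
    seed: int = 0,
    dt: float = 0.05,
    outdir=None,
    include_spiking: bool | None = None,
) -> dict[str, list[Trace]]:
    """Simulate the chronological protocol suite for one cell.

    Emits (as applicable): control current-clamp steps (``cc_ctrl``, only for
    spiking cells), I_h activation and tail voltage-clamp families in the TTX
    state, hyperpolarizing current-clamp steps in TTX, then the h-channel-
    blocked (ZD) repeats — the last-recorded protocols carrying the
    degradation ramp.  Returns {protocol key: [Trace, ...]}; optionally
    persists the dataset plus ground truth to ``outdir``.
    """
    noise = noise or NoiseModel.none()
    rng = np.random.default_rng(seed)
    if include_spiking is None:
        include_spiking = cell.model.spiking is not None

    ttx = PharmacologyFlags(ttx_tea_4ap=True)
    zd = PharmacologyFlags(ttx_tea_4ap=True, zd7288=True)

    dataset: dict[str, list[Trace]] = {}
    for key, order, degraded in _SUITE_ORDER:
        if key == "cc_ctrl":
            if not include_spiking:
                continue
            proto = cc_step_protocol(
                holding_pA=cell.holding_spiking_pA,
                pharmacology=PharmacologyFlags(),
                name=key,
            )
        elif key in ("cc_ttx", "cc_zd"):
            flags = ttx if key == "cc_ttx" else zd
            # the holding current is condition-specific: blocking I_h changes
            # the resting potential, as it does at the rig.  The nominal
            # -60 mV amplifier setting corresponds to about -72 mV after the
            # 11.88 mV junction-potential correction, which is the frame all
            # traces are emitted in.
            hold = holding_current_for(
                Simulator(
                    cell.model.geometry,
                    cell.model.passive,
                    apply_pharmacology(cell.model.channel_list(), flags),
                ),
                CC_HOLDING_MV,
            )
            proto = cc_step_protocol(
                amplitudes_pA=_HYPERPOL_AMPS,
                holding_pA=hold,
                pharmacology=flags,
                name=key,
            )
        elif key in ("vc_act_ttx", "vc_act_zd"):
            proto = vc_activation_protocol(
                pharmacology=ttx if key == "vc_act_ttx" else zd, name=key
            )
        else:  # tails
            proto = vc_tail_protocol(
                pharmacology=ttx if key == "vc_tail_ttx" else zd, name=key
            )
        sim = cell.model.simulator()
        traces = sim.run_protocol(proto, dt=dt)
        n_sw = len(traces)
        sigma0 = noise.sigma_cc if proto.mode == "cc" else noise.sigma_vc
        drift0 = noise.drift_cc if proto.mode == "cc" else noise.drift_vc
        noisy = []
        for i, tr in enumerate(traces):
            ramp = i / max(n_sw - 1, 1)
            mult = 1.0 + (noise.late_mult - 1.0) * ramp if degraded else 1.0
            drift = drift0 * ramp if degraded else 0.0
            tr.meta["protocol_order"] = order
            tr.meta["cell"] = cell.name
            noisy.append(add_noise(tr, sigma0 * mult, rng, drift))
        dataset[key] = noisy

    if outdir is not None:
        write_dataset(dataset, outdir, ground_truth=cell.parameter_dict())
        cell.save(Path(outdir))
    return dataset
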