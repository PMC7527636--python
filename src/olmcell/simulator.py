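"""Branched-cable simulation of compartmental models under virtual clamp.

The membrane equation per compartment i,

    C_i dV_i/dt = -g_leak,i (V_i - E_pas) - sum_c g_c,i prod_g x^p (V_i - E_c)
                  + sum_{j ~ i} g_ij (V_j - V_i) + I_inj,i

is integrated by backward Euler on the tree-structured system, solved exactly
each step in linear time by child-to-root elimination (Hines ordering).
Gating variables advance by the exact exponential update at the voltage of
the previous step (staggered scheme).  Gate kinetics are linear
interpolations of inf/tau tables on a shared voltage grid.

Voltage clamp is implemented as a large clamp conductance at the clamped
compartment (default 1 uS * 1e6, i.e. an effectively ideal clamp with
sub-nanovolt error); an optional series resistance turns the same mechanism
into a realistic non-ideal clamp.  Dendrites evolve freely, so space-clamp
escape is emergent.

Internal unit system: mV, ms, nA, uS, nF, MOhm (self-consistent:
nF*mV/ms = uS*mV = mV/MOhm = nA).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .channels import ChannelSpec, V_GRID
from .morphology import CompartmentalModel, REGION_AXON, REGION_DEND, REGION_SOMA

__all__ = [
    "PassiveParams",
    "PharmacologyFlags",
    "Sweep",
    "Protocol",
    "Trace",
    "Simulator",
    "IntegrationError",
    "apply_pharmacology",
    "run_current_clamp",
    "run_voltage_clamp",
    "current_shares",
    "cc_step_protocol",
    "vc_activation_protocol",
    "vc_tail_protocol",
    "density_by_region",
]

_CLAMP_G = 1.0e6  # uS; ideal-clamp conductance (1 S)


@dataclass
class PassiveParams:
    """Uniform passive membrane properties."""

    Ra: float = 300.0  # Ohm*cm
    Cm: float = 0.5  # uF/cm^2
    Gpas: float = 1.0e-5  # S/cm^2
    Epas: float = -65.0  # mV

    def __post_init__(self) -> None:
        if not (10.0 < self.Ra < 1000.0):
            raise ValueError("Ra out of plausible range (10, 1000) Ohm*cm")
        if not (0.05 < self.Cm < 3.0):
            raise ValueError("Cm out of plausible range (0.05, 3) uF/cm^2")
        if self.Gpas <= 0:
            raise ValueError("Gpas must be positive")

    @property
    def tau_m(self) -> float:
        """Isopotential membrane time constant Cm/Gpas in ms."""
        return self.Cm * 1e-6 / self.Gpas * 1e3

    def with_(self, **kw) -> "PassiveParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class PharmacologyFlags:
    """Bath-applied blocker state.

    ``ttx_tea_4ap`` silences all voltage-gated Na and K conductances (leak and
    calcium retained); ``zd7288`` additionally silences I_h.  Flags are
    idempotent and composable by construction (they zero densities).
    """

    synaptic_blockers: bool = True
    ttx_tea_4ap: bool = False
    zd7288: bool = False


@dataclass
class Sweep:
    """One stimulus epoch sequence: (level, duration ms) pairs.

    Levels are injected current in pA for current clamp (on top of the
    holding current) or command potential in mV for voltage clamp.
    """

    label: str
    levels: list[tuple[float, float]]
    meta: dict = field(default_factory=dict)


@dataclass
class Protocol:
    name: str
    mode: str  # 'cc' | 'vc'
    holding: float  # pA (cc: holding current) or mV (vc: holding potential)
    sweeps: list[Sweep]
    pharmacology: PharmacologyFlags = field(default_factory=PharmacologyFlags)

    def __post_init__(self) -> None:
        if self.mode not in ("cc", "vc"):
            raise ValueError("mode must be 'cc' or 'vc'")
        for sw in self.sweeps:
            for _, dur in sw.levels:
                if dur <= 0:
                    raise ValueError("epoch durations must be positive")


@dataclass
class Trace:
    """Uniformly sampled recording plus protocol metadata.

    ``y`` is somatic V_m in mV (cc) or clamp current in pA (vc).
    ``channel_currents`` maps mechanism name -> nA series at the recorded
    compartment when channel recording was enabled.
    """

    t: np.ndarray
    y: np.ndarray
    dt: float
    meta: dict = field(default_factory=dict)
    channel_currents: dict | None = None

    def __post_init__(self) -> None:
        if len(self.t) != len(self.y):
            raise ValueError("t and y lengths differ")

    def copy(self) -> "Trace":
        ch = None
        if self.channel_currents is not None:
            ch = {k: v.copy() for k, v in self.channel_currents.items()}
        return Trace(self.t.copy(), self.y.copy(), self.dt, dict(self.meta), ch)

    def window(self, t0: float, t1: float) -> tuple[np.ndarray, np.ndarray]:
        m = (self.t >= t0) & (self.t <= t1)
        return self.t[m], self.y[m]


class IntegrationError(RuntimeError):
    pass


_BLOCKED_BY_TTX = ("na", "k")


def apply_pharmacology(channels, flags: PharmacologyFlags):
    """Return the channel list with blocked families' densities zeroed.

    ``channels`` is a list of (ChannelSpec, density) pairs.  Leak is not a
    channel here and is always retained; calcium channels are not blocked by
    the TTX/TEA/4-AP cocktail.
    """
    out = []
    for spec, dens in channels:
        blocked = (flags.ttx_tea_4ap and spec.family in _BLOCKED_BY_TTX) or (
            flags.zd7288 and spec.family == "ih"
        )
        if not blocked:
            out.append((spec, dens))
    return out


def density_by_region(model: CompartmentalModel, soma=0.0, dend=0.0, axon=0.0):
    """Per-compartment density array (pS/um^2) from per-region values."""
    dens = np.zeros(model.n)
    dens[model.region == REGION_SOMA] = soma
    dens[model.region == REGION_DEND] = dend
    dens[model.region == REGION_AXON] = axon
    return dens


@njit(cache=True, fastmath=True)
def _integrate(
    dt,
    nt,
    parent,
    g_ax,
    c_over_dt,
    g_leak,
    e_leak,
    gbar,
    erev,
    gate_chan,
    gate_exp,
    inf_tab,
    edt_tab,  # exp(-dt / tau(V)) per gate, precomputed for this dt
    vmin,
    inv_dv,
    nv,
    V,
    gates,
    mode,
    drive,
    stim_comp,
    g_clamp,
    rec_comp,
    record_ch,
    out_v,
    out_i,
    out_ich,
):
    n = V.shape[0]
    nch = gbar.shape[0]
    ng = gates.shape[0]
    g_ch = np.empty((nch, n))
    diag = np.empty(n)
    rhs = np.empty(n)
    for step in range(nt):
        # exact-exponential gate update at the previous voltage
        for gi in range(ng):
            for i in range(n):
                u = (V[i] - vmin) * inv_dv
                j = int(u)
                if j < 0:
                    j = 0
                elif j > nv - 2:
                    j = nv - 2
                f = u - j
                if f < 0.0:
                    f = 0.0
                elif f > 1.0:
                    f = 1.0
                inf = inf_tab[gi, j] * (1.0 - f) + inf_tab[gi, j + 1] * f
                edt = edt_tab[gi, j] * (1.0 - f) + edt_tab[gi, j + 1] * f
                gates[gi, i] = inf + (gates[gi, i] - inf) * edt
        # channel conductances
        for ch in range(nch):
            for i in range(n):
                g_ch[ch, i] = gbar[ch, i]
        for gi in range(ng):
            ch = gate_chan[gi]
            p = gate_exp[gi]
            for i in range(n):
                x = gates[gi, i]
                xp = x
                for _ in range(p - 1):
                    xp *= x
                g_ch[ch, i] *= xp
        # assemble diagonal and rhs
        for i in range(n):
            gtot = g_leak[i]
            ge = g_leak[i] * e_leak
            for ch in range(nch):
                gtot += g_ch[ch, i]
                ge += g_ch[ch, i] * erev[ch]
            diag[i] = c_over_dt[i] + gtot
            rhs[i] = c_over_dt[i] * V[i] + ge
        for i in range(1, n):
            diag[i] += g_ax[i]
            diag[parent[i]] += g_ax[i]
        if mode == 0:
            rhs[stim_comp] += drive[step]
        else:
            diag[stim_comp] += g_clamp
            rhs[stim_comp] += g_clamp * drive[step]
        # Hines elimination (children have larger indices than parents)
        for i in range(n - 1, 0, -1):
            p = parent[i]
            ratio = g_ax[i] / diag[i]
            diag[p] -= ratio * g_ax[i]
            rhs[p] += ratio * rhs[i]
        V[0] = rhs[0] / diag[0]
        for i in range(1, n):
            V[i] = (rhs[i] + g_ax[i] * V[parent[i]]) / diag[i]
        out_v[step] = V[rec_comp]
        if mode == 1:
            out_i[step] = g_clamp * (drive[step] - V[stim_comp])
        else:
            out_i[step] = drive[step]
        if record_ch:
            for ch in range(nch):
                out_ich[ch, step] = g_ch[ch, rec_comp] * (V[rec_comp] - erev[ch])
            out_ich[nch, step] = g_leak[rec_comp] * (V[rec_comp] - e_leak)
    return 0


class Simulator:
    """Compiled machine for one (geometry, passive, channel set) triple.

    ``channels`` is a list of (ChannelSpec, density) pairs where density is a
    scalar or per-compartment array in pS/um^2.  Pharmacology is applied per
    protocol at run time.
    """

    def __init__(
        self,
        model: CompartmentalModel,
        passive: PassiveParams,
        channels=(),
        record_channels: bool = False,
        record_comp: int | None = None,
        series_resistance_MOhm: float = 0.0,
    ):
        self.model = model
        self.passive = passive
        self.channels = [
            (spec, np.broadcast_to(np.asarray(d, dtype=float), (model.n,)).copy())
            for spec, d in channels
        ]
        self.record_channels = record_channels
        self.record_comp = model.soma_index if record_comp is None else record_comp
        self.series_resistance = series_resistance_MOhm

        area = model.area  # um^2
        self._c = passive.Cm * area * 1e-5  # nF
        self._g_leak = passive.Gpas * area * 1e-2  # uS
        with np.errstate(divide="ignore"):
            g_ax = np.where(
                model.parent >= 0, 1.0 / (model.r_axial_per_ra * passive.Ra), 0.0
            )
        self._g_ax = g_ax  # uS

    def _build_tables(self, channels):
        gbar_rows, erev, gate_chan, gate_exp, inf_rows, tau_rows, names = (
            [],
            [],
            [],
            [],
            [],
            [],
            [],
        )
        for ci, (spec, dens) in enumerate(channels):
            gbar_rows.append(dens * self.model.area * 1e-6)  # pS/um^2 * um^2 -> uS
            erev.append(spec.erev)
            names.append(spec.name)
            for gate in spec.gates:
                gate_chan.append(ci)
                gate_exp.append(gate.exponent)
                inf_rows.append(gate.table.inf)
                tau_rows.append(gate.table.tau)
        nv = len(V_GRID)
        gbar = np.array(gbar_rows) if gbar_rows else np.zeros((0, self.model.n))
        inf_tab = np.array(inf_rows) if inf_rows else np.zeros((0, nv))
        tau_tab = np.array(tau_rows) if tau_rows else np.ones((0, nv))
        return (
            gbar,
            np.array(erev, dtype=float),
            np.array(gate_chan, dtype=np.int64),
            np.array(gate_exp, dtype=np.int64),
            inf_tab,
            tau_tab,
            names,
        )

    def _init_state(self, v0: float, inf_tab):
        V = np.full(self.model.n, float(v0), dtype=np.float64)
        ng = inf_tab.shape[0]
        gates = np.empty((ng, self.model.n))
        j = int((v0 - V_GRID[0]) / (V_GRID[1] - V_GRID[0]))
        j = min(max(j, 0), len(V_GRID) - 1)
        for gi in range(ng):
            gates[gi, :] = inf_tab[gi, j]
        return V, gates

    def _run_arrays(self, mode, drive, dt, V, gates, tabs, record_ch):
        gbar, erev, gate_chan, gate_exp, inf_tab, tau_tab, _ = tabs
        edt_tab = np.exp(-dt / tau_tab) if tau_tab.size else tau_tab
        nt = len(drive)
        out_v = np.empty(nt)
        out_i = np.empty(nt)
        nch = gbar.shape[0]
        out_ich = np.empty((nch + 1, nt)) if record_ch else np.empty((1, 1))
        g_clamp = (
            1.0 / self.series_resistance if self.series_resistance > 0 else _CLAMP_G
        )
        _integrate(
            dt,
            nt,
            self.model.parent,
            self._g_ax,
            self._c / dt,
            self._g_leak,
            self.passive.Epas,
            gbar,
            erev,
            gate_chan,
            gate_exp,
            inf_tab,
            edt_tab,
            V_GRID[0],
            1.0 / (V_GRID[1] - V_GRID[0]),
            len(V_GRID),
            V,
            gates,
            0 if mode == "cc" else 1,
            drive,
            self.model.soma_index,
            g_clamp,
            self.record_comp,
            record_ch,
            out_v,
            out_i,
            out_ich,
        )
        if not np.all(np.isfinite(V)):
            bad = int(np.flatnonzero(~np.isfinite(out_v))[0]) if not np.all(
                np.isfinite(out_v)
            ) else nt - 1
            raise IntegrationError(f"integration diverged at step {bad}")
        return out_v, out_i, out_ich

    def run_protocol(
        self,
        protocol: Protocol,
        dt: float = 0.025,
        settle_ms: float = 2000.0,
        settle_dt: float = 0.5,
    ) -> list[Trace]:
        """Run every sweep from a settled holding state; return one Trace each."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        channels = apply_pharmacology(self.channels, protocol.pharmacology)
        tabs = self._build_tables(channels)
        names = tabs[6]

        if protocol.mode == "cc":
            hold_drive = float(protocol.holding) * 1e-3  # pA -> nA
            v0 = self.passive.Epas
        else:
            hold_drive = float(protocol.holding)
            v0 = protocol.holding
        V0, gates0 = self._init_state(v0, tabs[4])
        n_settle = max(int(round(settle_ms / settle_dt)), 1)
        self._run_arrays(
            protocol.mode,
            np.full(n_settle, hold_drive, dtype=np.float64),
            settle_dt,
            V0,
            gates0,
            tabs,
            False,
        )

        traces = []
        for si, sweep in enumerate(protocol.sweeps):
            segs = []
            for value, dur in sweep.levels:
                nsteps = int(round(dur / dt))
                if protocol.mode == "cc":
                    segs.append(
                        np.full(
                            nsteps,
                            (float(protocol.holding) + float(value)) * 1e-3,
                            dtype=np.float64,
                        )
                    )
                else:
                    segs.append(np.full(nsteps, float(value), dtype=np.float64))
            drive = np.concatenate(segs)
            V = V0.copy()
            gates = gates0.copy()
            out_v, out_i, out_ich = self._run_arrays(
                protocol.mode, drive, dt, V, gates, tabs, self.record_channels
            )
            t = np.arange(1, len(drive) + 1) * dt
            y = out_v if protocol.mode == "cc" else out_i * 1e3  # nA -> pA
            meta = {
                "mode": protocol.mode,
                "units": "mV" if protocol.mode == "cc" else "pA",
                "protocol": protocol.name,
                "sweep": sweep.label,
                "sweep_index": si,
                "holding": protocol.holding,
                "dt_ms": dt,
                "pharmacology": {
                    "synaptic_blockers": protocol.pharmacology.synaptic_blockers,
                    "ttx_tea_4ap": protocol.pharmacology.ttx_tea_4ap,
                    "zd7288": protocol.pharmacology.zd7288,
                },
                "junction_potential_mV": 11.88,
            }
            meta.update(sweep.meta)
            ch_rec = None
            if self.record_channels:
                ch_rec = {name: out_ich[i] for i, name in enumerate(names)}
                ch_rec["leak"] = out_ich[len(names)]
            traces.append(Trace(t=t, y=y, dt=dt, meta=meta, channel_currents=ch_rec))
        return traces


def run_current_clamp(
    model: CompartmentalModel,
    passive: PassiveParams,
    channels,
    protocol: Protocol,
    dt: float = 0.025,
    **kw,
) -> list[Trace]:
    """Somatic V_m traces for a current-clamp protocol (injection at soma)."""
    if protocol.mode != "cc":
        raise ValueError("protocol is not current clamp")
    return Simulator(model, passive, channels, **kw).run_protocol(protocol, dt=dt)


def run_voltage_clamp(
    model: CompartmentalModel,
    passive: PassiveParams,
    channels,
    protocol: Protocol,
    dt: float = 0.025,
    **kw,
) -> list[Trace]:
    """Somatic clamp-current traces for a voltage-clamp protocol."""
    if protocol.mode != "vc":
        raise ValueError("protocol is not voltage clamp")
    return Simulator(model, passive, channels, **kw).run_protocol(protocol, dt=dt)


def current_shares(trace: Trace) -> dict[str, dict[str, np.ndarray]]:
    """Per-channel fractional contribution to total inward and outward current.

    At each time point each mechanism's current is split by sign; shares are
    |i| / sum(|i|) within the sign class (zero where the class total is zero).
    Shares sum to 1 within each class whenever the class total is nonzero.
    """
    if not trace.channel_currents:
        raise ValueError("trace has no channel-current record")
    names = list(trace.channel_currents)
    cur = np.array([trace.channel_currents[k] for k in names])
    inward = np.where(cur < 0, -cur, 0.0)
    outward = np.where(cur > 0, cur, 0.0)
    tot_in = inward.sum(axis=0)
    tot_out = outward.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sh_in = np.where(tot_in > 0, inward / np.where(tot_in > 0, tot_in, 1.0), 0.0)
        sh_out = np.where(
            tot_out > 0, outward / np.where(tot_out > 0, tot_out, 1.0), 0.0
        )
    return {
        "inward": {k: sh_in[i] for i, k in enumerate(names)},
        "outward": {k: sh_out[i] for i, k in enumerate(names)},
    }


# ---------------------------------------------------------------------------
# protocol builders (Table-1-style step families)
# ---------------------------------------------------------------------------

def cc_step_protocol(
    amplitudes_pA=tuple(range(-120, 91, 30)),
    holding_pA: float = 0.0,
    pre_ms: float = 1000.0,
    step_ms: float = 2000.0,
    post_ms: float = 2000.0,
    pharmacology: PharmacologyFlags | None = None,
    name: str = "cc_steps",
) -> Protocol:
    """2 s current steps (default -120..+90 pA in 30 pA increments)."""
    sweeps = [
        Sweep(
            label=f"{a:+.0f}pA",
            levels=[(0.0, pre_ms), (float(a), step_ms), (0.0, post_ms)],
            meta={"level": float(a), "onset_ms": pre_ms, "duration_ms": step_ms},
        )
        for a in amplitudes_pA
    ]
    return Protocol(
        name=name,
        mode="cc",
        holding=holding_pA,
        sweeps=sweeps,
        pharmacology=pharmacology or PharmacologyFlags(),
    )


def vc_activation_protocol(
    commands_mV=tuple(range(-50, -121, -10)),
    holding_mV: float = -40.0,
    pre_ms: float = 200.0,
    step_ms: float = 1200.0,
    post_ms: float = 500.0,
    pharmacology: PharmacologyFlags | None = None,
    name: str = "vc_activation",
) -> Protocol:
    """I_h activation: 1.2 s steps to progressively hyperpolarized commands."""
    sweeps = [
        Sweep(
            label=f"{v:+.0f}mV",
            levels=[(holding_mV, pre_ms), (float(v), step_ms), (holding_mV, post_ms)],
            meta={"level": float(v), "onset_ms": pre_ms, "duration_ms": step_ms},
        )
        for v in commands_mV
    ]
    return Protocol(
        name=name,
        mode="vc",
        holding=holding_mV,
        sweeps=sweeps,
        pharmacology=pharmacology or PharmacologyFlags(),
    )


def vc_tail_protocol(
    relax_commands_mV=tuple(range(-110, -39, 10)),
    holding_mV: float = -40.0,
    pre_ms: float = 200.0,
    prepulse_mV: float = -120.0,
    prepulse_ms: float = 1200.0,
    relax_ms: float = 1000.0,
    post_ms: float = 300.0,
    pharmacology: PharmacologyFlags | None = None,
    name: str = "vc_tails",
) -> Protocol:
    """Tail currents: -120 mV prepulse then a family of relaxation commands."""
    sweeps = [
        Sweep(
            label=f"tail{v:+.0f}mV",
            levels=[
                (holding_mV, pre_ms),
                (prepulse_mV, prepulse_ms),
                (float(v), relax_ms),
                (holding_mV, post_ms),
            ],
            meta={
                "level": float(v),
                "onset_ms": pre_ms,
                "duration_ms": prepulse_ms,
                "relax_onset_ms": pre_ms + prepulse_ms,
                "relax_duration_ms": relax_ms,
                "prepulse_mV": prepulse_mV,
            },
        )
        for v in relax_commands_mV
    ]
    return Protocol(
        name=name,
        mode="vc",
        holding=holding_mV,
        sweeps=sweeps,
        pharmacology=pharmacology or PharmacologyFlags(),
    )
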