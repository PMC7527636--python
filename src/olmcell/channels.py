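"""Voltage-gated channel mechanisms.

The h-current (I_h) model is a single activation gate r with first-order
kinetics:

    I_h   = G_h * r * (V - E_h)
    dr/dt = (r_inf - r) / tau_h
    r_inf = 1 / (1 + exp((V - V_half) / k))
    tau_h = 1 / (exp(-t1 - t2 V) + exp(-t3 + t4 V)) + t5

with V in mV, tau in ms.  k > 0 makes r_inf increase with hyperpolarization
(the channel is hyperpolarization-activated) and t5 is a strictly positive
floor on the kinetics.

The transient sodium current uses m^3 h Hodgkin-Huxley gating with
region-specific rate functions (soma vs dendrite/axon) and a rigid voltage
shift V_shift, bounded to +/- 7 mV, applied identically to all four rates so
the activation/inactivation window is preserved.

All remaining spiking channels (fast/slow delayed rectifier, A-type, M-type,
T-/L-type calcium and a calcium-dependent potassium surrogate) are expressed
through a declarative :class:`ChannelSpec` interface (gates with exponents and
closed-form rate expressions) loaded from a JSON config.  The bundled config
(``data/spiking_channels.json``) contains stylized HH-type kinetics authored
for this package; the KCa entry is a voltage-gated surrogate since no
intracellular calcium dynamics are modelled.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np

__all__ = [
    "IhParams",
    "NaTParams",
    "GateState",
    "ChannelSpec",
    "GateSpec",
    "RateTable",
    "ih_rinf",
    "ih_tau",
    "ih_current",
    "nat_rates",
    "gate_step",
    "ih_channel_spec",
    "nat_channel_spec",
    "load_channel_config",
    "builtin_spiking_config",
    "V_GRID",
]

# shared tabulation grid for gate kinetics (mV)
V_GRID = np.arange(-150.0, 70.0 + 1e-9, 0.05)


@dataclass
class IhParams:
    """H-channel parameter set for one cell.

    ``gh_total_nS`` is the whole-cell maximal conductance measured from the
    tail-current I-V slope; ``h_dist`` records the dendritic extent used when
    the conductance is distributed over the membrane.
    """

    e_h: float = -34.0  # mV
    v_half: float = -103.4  # mV
    k: float = 8.63  # mV, > 0
    t1: float = 8.03
    t2: float = 0.025
    t3: float = -4.40
    t4: float = 0.15
    t5: float = 7.32e-6  # ms, floor on tau_h
    gh_total_nS: float = 4.17
    h_dist: float = 1.0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("slope factor k must be positive")
        if self.t5 < 0:
            raise ValueError("tau floor t5 must be non-negative")
        if self.gh_total_nS < 0:
            raise ValueError("total conductance must be non-negative")

    @property
    def tau_params(self) -> tuple[float, float, float, float, float]:
        return (self.t1, self.t2, self.t3, self.t4, self.t5)

    def with_(self, **kw) -> "IhParams":
        return replace(self, **kw)


@dataclass
class NaTParams:
    """Transient-sodium densities and per-region voltage shifts."""

    g_soma: float = 0.0  # pS/um^2
    g_dend: float = 0.0
    g_axon: float = 0.0
    e_na: float = 90.0  # mV; sodium reversal (not printed per-cell, simulator default)
    v_shift_soma: float = 0.0
    v_shift_dend: float = 0.0
    v_shift_axon: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.v_shift_soma, self.v_shift_dend, self.v_shift_axon):
            if abs(v) > 7.0 + 1e-12:
                raise ValueError("|V_shift| must not exceed 7 mV")


@dataclass
class GateState:
    """Gating variables, each confined to [0, 1]."""

    r: float = 0.0
    m: float = 0.0
    h: float = 1.0


def ih_rinf(v, p: IhParams):
    """Steady-state activation of I_h (Boltzmann, decreasing in V for k > 0)."""
    return 1.0 / (1.0 + np.exp((np.asarray(v, dtype=float) - p.v_half) / p.k))


def ih_tau(v, p: IhParams):
    """Voltage-dependent time constant of I_h (ms), double-exponential form."""
    v = np.asarray(v, dtype=float)
    return 1.0 / (np.exp(-p.t1 - p.t2 * v) + np.exp(-p.t3 + p.t4 * v)) + p.t5


def ih_current(v, r, density_ps_um2, e_h):
    """I_h per unit membrane area.

    With density in pS/um^2 and voltages in mV the result is in
    1e-15 A/um^2 (fA/um^2); multiply by area in um^2 for fA.
    """
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r > 1)):
        raise ValueError("gate value outside [0, 1]")
    return density_ps_um2 * r * (np.asarray(v, dtype=float) - e_h)


def _linexp(x, q):
    """x / (exp(x/q) - 1) with the analytic limit q at x -> 0."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-6
    out[small] = q - x[small] / 2.0
    xs = x[~small]
    out[~small] = xs / np.expm1(xs / q)
    return out


def nat_rates(v, region: str, v_shift: float = 0.0):
    """(alpha_m, beta_m, alpha_h, beta_h) in ms^-1 for the Na_T channel.

    Somatic compartments use rate functions centred 7 mV depolarized relative
    to dendritic/axonal ones.  ``v_shift`` rigidly shifts all four rates.
    """
    v = np.asarray(v, dtype=float) - v_shift
    if region == "soma":
        am = -0.1 * _linexp(v + 38.0, -10.0)  # -0.1 x / (exp(-x/10) - 1)
        bm = 4.0 * np.exp(-(v + 63.0) / 18.0)
        ah = 0.07 * np.exp(-(v + 63.0) / 20.0)
        bh = 1.0 / (1.0 + np.exp(-(v + 33.0) / 10.0))
    elif region in ("dend", "axon"):
        am = -0.1 * _linexp(v + 45.0, -10.0)
        bm = 4.0 * np.exp(-(v + 70.0) / 18.0)
        ah = 0.07 * np.exp(-(v + 70.0) / 20.0)
        bh = 1.0 / (1.0 + np.exp(-(v + 40.0) / 10.0))
    else:
        raise ValueError(f"unknown region {region!r}")
    return am, bm, ah, bh


def gate_step(x, v, dt: float, inf, tau):
    """Exact exponential update of a gate at frozen voltage.

    ``inf``/``tau`` may be callables of V or precomputed values.  Preserves
    [0, 1] for any dt > 0 and satisfies the semigroup property (two dt/2
    steps equal one dt step).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    xinf = inf(v) if callable(inf) else inf
    xtau = tau(v) if callable(tau) else tau
    if np.any(np.asarray(xtau) <= 0):
        raise ValueError("gate time constant must be positive")
    return xinf + (np.asarray(x, dtype=float) - xinf) * np.exp(-dt / xtau)


# ---------------------------------------------------------------------------
# declarative channel specs and rate tables
# ---------------------------------------------------------------------------

def _eval_rate(expr: dict, v: np.ndarray) -> np.ndarray:
    """Evaluate a declarative rate/steady-state expression on a voltage array.

    Supported kinds:
      constant   : value
      exp        : a * exp((V - vhalf) / q)
      sigmoid    : a / (1 + exp((V - vhalf) / q))
      linexp     : a * (V - vhalf) / (exp((V - vhalf)/q) - 1), limit a*q
      boltzmann  : 1 / (1 + exp((V - vhalf) / q))
      bellexp    : 1 / (exp(-t1 - t2 V) + exp(-t3 + t4 V)) + t5
      sumsigmoid : base + amp / (1 + exp((V - vhalf) / q))
    """
    kind = expr["kind"]
    if kind == "constant":
        return np.full_like(v, float(expr["value"]))
    if kind == "exp":
        return expr["a"] * np.exp((v - expr["vhalf"]) / expr["q"])
    if kind == "sigmoid":
        return expr["a"] / (1.0 + np.exp((v - expr["vhalf"]) / expr["q"]))
    if kind == "linexp":
        return expr["a"] * _linexp(v - expr["vhalf"], expr["q"])
    if kind == "boltzmann":
        return 1.0 / (1.0 + np.exp((v - expr["vhalf"]) / expr["q"]))
    if kind == "bellexp":
        return (
            1.0
            / (np.exp(-expr["t1"] - expr["t2"] * v) + np.exp(-expr["t3"] + expr["t4"] * v))
            + expr["t5"]
        )
    if kind == "sumsigmoid":
        return expr["base"] + expr["amp"] / (1.0 + np.exp((v - expr["vhalf"]) / expr["q"]))
    raise ValueError(f"unknown rate kind {kind!r}")


@dataclass
class RateTable:
    """inf/tau lookup tables for one gate on the shared voltage grid."""

    inf: np.ndarray
    tau: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.tau <= 0):
            raise ValueError("tabulated tau must be positive everywhere")
        if np.any((self.inf < -1e-12) | (self.inf > 1 + 1e-12)):
            raise ValueError("tabulated inf must lie in [0, 1]")


@dataclass
class GateSpec:
    name: str
    exponent: int
    table: RateTable


@dataclass
class ChannelSpec:
    """A gated conductance: name, ion family, reversal and gate list.

    ``family`` classifies the carried ion for pharmacology ('na', 'k', 'ca',
    'ih'); densities are attached per model at build time.
    """

    name: str
    family: str
    erev: float  # mV
    gates: list[GateSpec] = field(default_factory=list)


def _gate_from_config(name: str, g: dict) -> GateSpec:
    v = V_GRID
    if "alpha" in g:
        a = _eval_rate(g["alpha"], v)
        b = _eval_rate(g["beta"], v)
        if np.any(a < 0) or np.any(b < 0):
            raise ValueError(f"gate {name}: negative rate on the simulated range")
        tau = 1.0 / (a + b)
        inf = a * tau
    else:
        inf = _eval_rate(g["inf"], v)
        tau = _eval_rate(g["tau"], v)
    return GateSpec(name=name, exponent=int(g.get("exponent", 1)), table=RateTable(inf, tau))


def load_channel_config(source) -> dict[str, ChannelSpec]:
    """Load channel specs from a JSON config (path, file object, or dict).

    Schema (version 1)::

        {"schema_version": 1,
         "channels": {"kdrf": {"family": "k", "erev": -85.0,
                               "gates": {"n": {"exponent": 4,
                                               "inf": {...}, "tau": {...}}}}}}
    """
    if isinstance(source, dict):
        cfg = source
    elif hasattr(source, "read"):
        cfg = json.load(source)
    else:
        with open(source) as fh:
            cfg = json.load(fh)
    if cfg.get("schema_version") != 1:
        raise ValueError("unsupported channel config schema version")
    specs: dict[str, ChannelSpec] = {}
    for name, ch in cfg["channels"].items():
        gates = [_gate_from_config(gn, g) for gn, g in ch["gates"].items()]
        specs[name] = ChannelSpec(
            name=name, family=ch["family"], erev=float(ch["erev"]), gates=gates
        )
    return specs


def builtin_spiking_config() -> dict[str, ChannelSpec]:
    """The bundled spiking-channel set (stylized kinetics, see module docs)."""
    with resources.files("olmcell.data").joinpath("spiking_channels.json").open() as fh:
        return load_channel_config(fh)


def ih_channel_spec(p: IhParams) -> ChannelSpec:
    """Tabulated I_h mechanism from an :class:`IhParams` set."""
    table = RateTable(inf=ih_rinf(V_GRID, p), tau=ih_tau(V_GRID, p))
    return ChannelSpec(
        name="ih", family="ih", erev=p.e_h, gates=[GateSpec("r", 1, table)]
    )


def nat_channel_spec(region: str, v_shift: float, e_na: float) -> ChannelSpec:
    """Region-specific Na_T mechanism (m^3 h) with a rigid voltage shift."""
    am, bm, ah, bh = nat_rates(V_GRID, "soma" if region == "soma" else "dend", v_shift)
    tm = 1.0 / (am + bm)
    th = 1.0 / (ah + bh)
    return ChannelSpec(
        name=f"nat_{region}",
        family="na",
        erev=e_na,
        gates=[
            GateSpec("m", 3, RateTable(am * tm, tm)),
            GateSpec("h", 1, RateTable(ah * th, th)),
        ],
    )
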