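"""Passive-property fitting against hyperpolarizing current-clamp traces.

The -120 pA trace recorded with all voltage-gated channels blocked (the "ZD
trace") constrains the passive backbone: axial resistivity R_a, specific
capacitance C_m, leak conductance G_pas and leak reversal E_pas, fitted by
weighted least squares on the somatic V_m trajectory.  Region weighting
follows the experimental fitting protocol: the first 500 ms are excluded
(model settling), the brief charging portions at step onset and release get a
10x weight, about one second after the step is included to capture the
release response, and when a residual slow depolarization contaminates the
step plateau only a short window after charging completes is used.

Also provides the derived measures used for model-experiment comparison:
input resistance from the step deflection, the membrane time constant from a
mono-exponential charging fit, and a quality ranking across a trace family
(the last-recorded sweeps of a session are noisier and drift-contaminated).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, least_squares, minimize

from .model import CellModel
from .simulator import PassiveParams, PharmacologyFlags, Protocol, Sweep, Trace

__all__ = [
    "FitRegionSpec",
    "FitResult",
    "fit_passive",
    "compute_rin",
    "fit_tau_m",
    "rank_trace_quality",
    "charging_end",
    "region_weights",
    "simulate_like",
    "weighted_rmse",
]


def charging_end(trace: Trace, frac: float = 0.02) -> float:
    """Time (ms) at which V_m first comes within ``frac`` of its step
    steady-state deflection, measured from the step onset."""
    onset = trace.meta["onset_ms"]
    dur = trace.meta["duration_ms"]
    base = float(np.mean(trace.y[(trace.t > onset - 100) & (trace.t < onset)]))
    ss = float(np.mean(trace.y[(trace.t > onset + 0.8 * dur) & (trace.t < onset + dur)]))
    if abs(ss - base) < 1e-9:
        return 1.0
    m = (trace.t >= onset) & (trace.t <= onset + dur)
    reached = np.abs(trace.y[m] - ss) <= frac * abs(ss - base)
    idx = np.flatnonzero(reached)
    if len(idx) == 0:
        return dur
    return float(trace.t[m][idx[0]] - onset)


@dataclass
class FitRegionSpec:
    """Weight layout over a step trace for fitting."""

    exclude_before_ms: float = 500.0
    charging_weight: float = 10.0
    post_step_ms: float = 1000.0  # included after step release
    # 'auto': use a short post-charging window when a residual slow
    # depolarization contaminates the plateau (passive ZD fitting);
    # None: keep the full step (h-channel fitting, where the sag is signal);
    # a number: fixed window (ms) after charging completes.
    steady_window_ms: float | str | None = "auto"
    mask_rebound: bool = False  # exclude the post-release rebound window
    rebound_window_ms: float = 500.0
    extra_excluded: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.charging_weight <= 0:
            raise ValueError("weight multipliers must be positive")


def region_weights(trace: Trace, spec: FitRegionSpec) -> np.ndarray:
    """Per-sample weights implementing the region policy (0 = excluded)."""
    t = trace.t
    onset = trace.meta["onset_ms"]
    dur = trace.meta["duration_ms"]
    offset = onset + dur
    w = np.ones_like(t)
    w[t < spec.exclude_before_ms] = 0.0
    w[t > offset + spec.post_step_ms] = 0.0
    t_charge = charging_end(trace)
    w[(t >= onset) & (t <= onset + t_charge)] = spec.charging_weight
    if spec.mask_rebound:
        w[(t > offset) & (t <= offset + spec.rebound_window_ms)] = 0.0
    else:
        w[(t > offset) & (t <= offset + t_charge)] = spec.charging_weight
    # steady-state contamination: compare the early plateau with the step end
    steady = spec.steady_window_ms
    if steady == "auto":
        steady = None
        early = (t >= onset + t_charge) & (t <= onset + t_charge + 60.0)
        late = (t >= offset - 200.0) & (t <= offset)
        if early.any() and late.any():
            drift = abs(float(np.mean(trace.y[late]) - np.mean(trace.y[early])))
            noise = float(np.std(np.diff(trace.y)) / math.sqrt(2.0)) + 1e-12
            if drift > max(3.0 * noise / math.sqrt(early.sum()), 0.5):
                steady = 60.0
    if steady is not None:
        w[(t > onset + t_charge + steady) & (t < offset)] = 0.0
    for t0, t1 in spec.extra_excluded:
        w[(t >= t0) & (t <= t1)] = 0.0
    return w


def weighted_rmse(model_y: np.ndarray, target: Trace, w: np.ndarray) -> float:
    num = np.sum(w * (model_y - target.y) ** 2)
    den = np.sum(w)
    if den <= 0:
        raise ValueError("region spec excludes the whole trace")
    return float(math.sqrt(num / den))


def weighted_residual(model_y: np.ndarray, target: Trace, w: np.ndarray) -> np.ndarray:
    """Residual vector whose root-mean-square equals ``weighted_rmse``."""
    den = np.sum(w)
    if den <= 0:
        raise ValueError("region spec excludes the whole trace")
    return np.sqrt(w * (len(w) / den)) * (model_y - target.y)


def simulate_like(
    model: CellModel, target: Trace, dt: float = 0.1, t_stop: float | None = None
) -> np.ndarray:
    """Simulate the protocol that produced ``target`` and sample the somatic
    response on the target's grid.

    ``t_stop`` truncates the simulation (samples beyond it hold the last
    value); fitting callers pass the end of the weighted region.
    """
    meta = target.meta
    onset, dur = meta["onset_ms"], meta["duration_ms"]
    total = float(target.t[-1])
    if t_stop is not None:
        total = min(total, max(t_stop, onset + dur + dt))
    sweep = Sweep(
        label=meta.get("sweep", "fit"),
        levels=[(0.0, onset), (meta["level"], dur), (0.0, max(total - onset - dur, 1.0))],
        meta={"level": meta["level"], "onset_ms": onset, "duration_ms": dur},
    )
    ph = meta.get("pharmacology", {})
    proto = Protocol(
        name="refit",
        mode="cc",
        holding=meta.get("holding", 0.0),
        sweeps=[sweep],
        pharmacology=PharmacologyFlags(
            synaptic_blockers=ph.get("synaptic_blockers", True),
            ttx_tea_4ap=ph.get("ttx_tea_4ap", True),
            zd7288=ph.get("zd7288", False),
        ),
    )
    tr = model.simulator().run_protocol(proto, dt=dt, settle_dt=1.0)[0]
    return np.interp(target.t, tr.t, tr.y)  # holds tr.y[-1] beyond t_stop


def simplex_minimize(
    f,
    x0: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    log_scale: np.ndarray | None = None,
    xatol: float = 3e-3,
    fatol: float = 1e-7,
    maxiter: int = 400,
):
    """Bounded Nelder-Mead on unit-normalized coordinates.

    Parameters spanning decades (``log_scale`` mask) are normalized in log
    space so the simplex sees comparable scales; out-of-bounds proposals are
    clipped with a quadratic penalty.  Returns (x_best, f_best, nfev).
    """
    x0 = np.asarray(x0, dtype=float)
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    if log_scale is None:
        log_scale = np.zeros(len(x0), dtype=bool)

    def to_unit(x):
        u = np.empty_like(x)
        for i in range(len(x)):
            if log_scale[i]:
                u[i] = (np.log(x[i]) - np.log(lo[i])) / (np.log(hi[i]) - np.log(lo[i]))
            else:
                u[i] = (x[i] - lo[i]) / (hi[i] - lo[i])
        return u

    def from_unit(u):
        x = np.empty_like(u)
        uc = np.clip(u, 0.0, 1.0)
        for i in range(len(u)):
            if log_scale[i]:
                x[i] = np.exp(np.log(lo[i]) + uc[i] * (np.log(hi[i]) - np.log(lo[i])))
            else:
                x[i] = lo[i] + uc[i] * (hi[i] - lo[i])
        return x

    nfev = 0

    def wrapped(u):
        nonlocal nfev
        nfev += 1
        penalty = np.sum(np.maximum(0.0, np.abs(u - 0.5) - 0.5) ** 2)
        return f(from_unit(u)) * (1.0 + 10.0 * penalty) + penalty

    res = minimize(
        wrapped,
        to_unit(np.clip(x0, lo, hi)),
        method="Nelder-Mead",
        options={"xatol": xatol, "fatol": fatol, "maxiter": maxiter, "adaptive": True},
    )
    return from_unit(res.x), float(res.fun), nfev


def trf_minimize(
    resid_fn,
    x0: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    log_scale: np.ndarray | None = None,
    max_nfev: int = 60,
    xtol: float = 1e-8,
):
    """Bounded trust-region least squares on unit-normalized coordinates.

    ``resid_fn(x)`` returns the weighted residual vector.  Parameters
    spanning decades (``log_scale``) are normalized in log space so the
    finite-difference Jacobian is well scaled.  Returns
    (x_best, rms_best, nfev).  Preferred over the simplex for these smooth
    trace-matching objectives: it converges in tens of evaluations and does
    not wander between compensating basins.
    """
    x0 = np.asarray(x0, dtype=float)
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    if log_scale is None:
        log_scale = np.zeros(len(x0), dtype=bool)
    ls = np.asarray(log_scale, dtype=bool)
    safe_lo = np.where(ls, np.maximum(lo, 1e-300), 1.0)
    safe_hi = np.where(ls, np.maximum(hi, 1e-300), 1.0)
    span = np.where(ls, np.log(safe_hi) - np.log(safe_lo), hi - lo)
    base = np.where(ls, np.log(safe_lo), lo)

    def from_unit(u):
        raw = base + np.clip(u, 0.0, 1.0) * span
        return np.where(ls, np.exp(raw), raw)

    def to_unit(x):
        xc = np.clip(x, lo, hi)
        raw = np.where(ls, np.log(np.where(ls, np.maximum(xc, 1e-300), 1.0)), xc)
        return (raw - base) / span

    nfev = 0

    def wrapped(u):
        nonlocal nfev
        nfev += 1
        return resid_fn(from_unit(u))

    res = least_squares(
        wrapped,
        to_unit(x0),
        bounds=(np.zeros(len(x0)), np.ones(len(x0))),
        method="trf",
        diff_step=1e-3,
        xtol=xtol,
        ftol=1e-10,
        gtol=1e-10,
        max_nfev=max_nfev * (len(x0) + 1),
    )
    rms = float(np.sqrt(np.mean(res.fun**2)))
    return from_unit(res.x), rms, nfev


@dataclass
class FitResult:
    params: dict
    rmse: float
    region: FitRegionSpec
    weights: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValueError("rmse must be non-negative")


_PASSIVE_BOUNDS = {
    "Ra": (10.5, 999.0),
    "Cm": (0.06, 2.9),
    "Gpas": (5e-7, 5e-4),
    "Epas": (-100.0, -40.0),
}


def _heuristic_passive_start(model: CellModel, trace: Trace) -> PassiveParams:
    """Closed-form initial guesses from the trace itself."""
    rin = compute_rin(trace, trace.meta["level"])  # MOhm
    area_cm2 = float(model.geometry.area.sum()) * 1e-8
    gpas = 1.0 / (rin * 1e6) / area_cm2  # S/cm^2, isopotential approximation
    try:
        tau = fit_tau_m(trace)
    except Exception:
        tau = 30.0
    cm = gpas * tau * 1e3  # uF/cm^2
    onset = trace.meta["onset_ms"]
    base = float(np.mean(trace.y[(trace.t > onset - 100) & (trace.t < onset)]))
    epas = base - trace.meta.get("holding", 0.0) * rin * 1e-3
    lo_hi = _PASSIVE_BOUNDS
    return PassiveParams(
        Ra=model.passive.Ra,
        Cm=float(np.clip(cm, *lo_hi["Cm"])),
        Gpas=float(np.clip(gpas, *lo_hi["Gpas"])),
        Epas=float(np.clip(epas, *lo_hi["Epas"])),
    )


def fit_passive(
    model: CellModel,
    target: Trace,
    regions: FitRegionSpec | None = None,
    I_step_pA: float | None = None,
    restarts: int = 8,
    seed: int = 0,
    dt: float = 0.1,
) -> tuple[CellModel, FitResult]:
    """Fit (Ra, Cm, Gpas, Epas) to a blocked-cell hyperpolarizing trace.

    Derivative-free simplex search with bounded parameters and ``restarts``
    randomized restarts; the best solution over all restarts is kept.
    Returns the fitted model and a :class:`FitResult`.
    """
    regions = regions or FitRegionSpec()
    if I_step_pA is not None and abs(I_step_pA - target.meta["level"]) > 1e-6:
        raise ValueError("I_step does not match the trace metadata")
    w = region_weights(target, regions)
    rng = np.random.default_rng(seed)
    leak_model = model.replace(ih=None, nat=None, spiking=None)
    names = ("Ra", "Cm", "Gpas", "Epas")
    lo = np.array([_PASSIVE_BOUNDS[k][0] for k in names])
    hi = np.array([_PASSIVE_BOUNDS[k][1] for k in names])
    log_mask = np.array([True, True, True, False])

    t_stop = float(target.t[np.flatnonzero(w > 0)[-1]]) + target.dt

    def residuals(x: np.ndarray) -> np.ndarray:
        pas = PassiveParams(Ra=x[0], Cm=x[1], Gpas=x[2], Epas=x[3])
        y = simulate_like(leak_model.replace(passive=pas), target, dt=dt, t_stop=t_stop)
        return weighted_residual(y, target, w)

    starts = [_heuristic_passive_start(leak_model, target), leak_model.passive]
    while len(starts) < restarts:
        base = starts[len(starts) % 2]
        jitter = {
            "Ra": base.Ra * rng.uniform(0.4, 2.5),
            "Cm": base.Cm * rng.uniform(0.6, 1.6),
            "Gpas": base.Gpas * rng.uniform(0.6, 1.6),
            "Epas": base.Epas + rng.uniform(-4.0, 4.0),
        }
        starts.append(
            PassiveParams(
                **{
                    k: float(np.clip(v, *_PASSIVE_BOUNDS[k]))
                    for k, v in jitter.items()
                }
            )
        )

    best, best_rmse, nfev = None, np.inf, 0
    results = []
    for start in starts[:restarts]:
        x0 = np.array([getattr(start, k) for k in names])
        x, fval, n = trf_minimize(residuals, x0, lo, hi, log_mask)
        nfev += n
        results.append(fval)
        if fval < best_rmse:
            best_rmse, best = fval, x
        # stop early once two independent starts agree on the optimum
        agreed = sum(1 for r in results if r <= best_rmse * 1.005)
        if len(results) >= 2 and agreed >= 2:
            break
    if best is None:
        raise RuntimeError("passive fit failed to converge from any start")
    pas = PassiveParams(Ra=best[0], Cm=best[1], Gpas=best[2], Epas=best[3])
    fitted = model.replace(passive=pas)
    result = FitResult(
        params={k: getattr(pas, k) for k in ("Ra", "Cm", "Gpas", "Epas")},
        rmse=best_rmse,
        region=regions,
        weights=w,
        diagnostics={"nfev": nfev, "restarts": restarts},
    )
    return fitted, result


def compute_rin(trace: Trace, I_step_pA: float | None = None) -> float:
    """Input resistance (MOhm) from the step deflection:
    (V at step onset - V at step end) / |I|, positive for hyperpolarizing
    steps."""
    if I_step_pA is None:
        if "level" not in trace.meta:
            raise KeyError("trace metadata lacks the step amplitude")
        I_step_pA = trace.meta["level"]
    if "onset_ms" not in trace.meta:
        raise KeyError("trace metadata lacks step timing")
    onset = trace.meta["onset_ms"]
    dur = trace.meta["duration_ms"]
    v_start = float(np.mean(trace.y[(trace.t > onset - 50) & (trace.t < onset)]))
    v_end = float(np.mean(trace.y[(trace.t > onset + dur - 50) & (trace.t < onset + dur)]))
    return (v_start - v_end) / abs(I_step_pA) * 1e3  # mV/pA -> MOhm


def fit_tau_m(trace: Trace, weighting: str = "uniform") -> float:
    """Membrane time constant (ms) from a mono-exponential fit to the
    charging portion (step onset to approximate steady state).

    ``weighting='step'`` weights samples by the local inter-sample spacing so
    densely sampled stretches do not dominate; identical to 'uniform' on a
    uniform grid.
    """
    onset = trace.meta["onset_ms"]
    t_charge = charging_end(trace, frac=0.01)
    m = (trace.t >= onset) & (trace.t <= onset + max(t_charge, 5 * trace.dt))
    t = trace.t[m] - onset
    y = trace.y[m]
    if weighting == "step":
        spacing = np.gradient(t)
        sigma = 1.0 / np.sqrt(spacing / spacing.mean())
    elif weighting == "uniform":
        sigma = None
    else:
        raise ValueError("weighting must be 'uniform' or 'step'")

    def f(tt, a, tau, c):
        return a * np.exp(-tt / tau) + c

    a0 = y[0] - y[-1]
    tau0 = max(t[-1] / 4.0, trace.dt)
    try:
        popt, _ = curve_fit(
            f,
            t,
            y,
            p0=[a0, tau0, y[-1]],
            sigma=sigma,
            bounds=([-np.inf, 1e-3, -np.inf], [np.inf, 10 * t[-1], np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"tau_m fit failed: {exc}") from None
    return float(popt[1])


def rank_trace_quality(traces: list[Trace]) -> list[dict]:
    """Rank a comparable trace family by recording quality.

    Per trace: tau_m from a normalized-amplitude charging fit and a
    drift-insensitive noise estimate.  The ordering (best first: lowest
    noise, ties by label) recommends the fitting trace; late-session sweeps
    with injected degradation rank worse.
    """
    if len(traces) < 2:
        raise ValueError("need at least two traces to rank")
    rows = []
    for tr in traces:
        d = np.diff(tr.y)
        noise = float(np.median(np.abs(d)) / 0.6745 / math.sqrt(2.0))
        try:
            tau = fit_tau_m(tr)
        except Exception:
            tau = math.nan
        rows.append(
            {
                "label": tr.meta.get("sweep", ""),
                "level": tr.meta.get("level"),
                "tau_m_ms": tau,
                "noise_mV": noise,
            }
        )
    rows.sort(key=lambda r: (round(r["noise_mV"], 9), str(r["label"])))
    for i, r in enumerate(rows):
        r["rank"] = i
    return rows
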