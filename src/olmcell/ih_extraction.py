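"""Extraction of h-channel biophysics from voltage-clamp trace families.

The pipeline mirrors the experimental analysis chain: blocker-subtraction
isolates I_h (control minus ZD7288 arm), a robust local-linear smoother
(25 ms window) suppresses recording noise, tail currents after a fully
activating -120 mV prepulse yield the I-V relation by two methods (current
read at a fixed post-transient time point, and mono-exponential fits
extrapolated back to the relaxation onset), a line through the linear portion
of the I-V gives the reversal potential E_h (zero-current intercept) and the
maximal conductance G_h (slope, pA/mV = nS), exponential fits to activation
and deactivation time courses build the tau_h(V) data which a five-parameter
double-exponential function is fitted to, and end-of-step currents from the
activation family give the Boltzmann steady-state activation curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, least_squares
from scipy.signal import oaconvolve

from .channels import IhParams
from .simulator import Trace

__all__ = [
    "IVPoint",
    "TauPoint",
    "ExponentialFit",
    "IhExtractionReport",
    "subtract_blocker",
    "smooth_local_linear",
    "choose_t_fixed",
    "tail_iv_fixed",
    "tail_iv_extrapolated",
    "fit_reversal_and_gh",
    "fit_exponential",
    "build_tau_curve",
    "fit_tau_function",
    "steady_state_activation",
    "extract_cell",
]


@dataclass
class IVPoint:
    v: float  # command mV
    i: float  # pA
    method: str  # 'fixed' | 'extrapolated'
    include: bool = True


@dataclass
class TauPoint:
    v: float  # mV
    tau: float  # ms, > 0
    kind: str  # 'activation' | 'deactivation'
    outlier: bool = False

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")


@dataclass
class ExponentialFit:
    """y(t) = a * exp(-t / tau) + c on a window with t relative to its start."""

    a: float
    tau: float
    c: float
    a_err: float = math.nan
    tau_err: float = math.nan
    ok: bool = True
    note: str = ""

    def __call__(self, t):
        return self.a * np.exp(-np.asarray(t) / self.tau) + self.c


def subtract_blocker(control: Trace, zd: Trace) -> Trace:
    """Pointwise control - ZD7288 arm; isolates I_h plus subtraction noise.

    Grids must match; a small mismatch is resampled onto the control grid.
    """
    if control.meta.get("mode") != zd.meta.get("mode") and control.meta and zd.meta:
        raise ValueError("cannot subtract traces from different clamp modes")
    if len(control.t) == len(zd.t) and np.allclose(control.t, zd.t, atol=1e-9):
        y = control.y - zd.y
    else:
        if (
            zd.t[0] > control.t[0] + control.dt
            or zd.t[-1] < control.t[-1] - control.dt
        ):
            raise ValueError("trace grids differ beyond resampling tolerance")
        y = control.y - np.interp(control.t, zd.t, zd.y)
    out = control.copy()
    out.y = y
    out.meta["subtracted"] = True
    return out


def _rloess(y: np.ndarray, dt: float, window_ms: float, it: int = 1) -> np.ndarray:
    """Local linear regression with tricube weights and ``it`` robustness
    iterations, on a uniform grid.

    All weighted sums are correlations with fixed kernels, so each pass is a
    handful of FFT convolutions: with robust weights rw,

        S0 = rw * k0,  S1 = rw * k1,  S2 = rw * k2,
        Sy = (rw y) * k0,  Sxy = (rw y) * k1,
        fit = (S2 Sy - S1 Sxy) / (S0 S2 - S1^2)   (value at the window centre)

    where k0/k1/k2 are the tricube kernel and its first/second moment.
    Window truncation at the ends falls out of the zero-padded convolution.
    """
    half = max(int(round(window_ms / (2.0 * dt))), 2)
    dx = np.arange(-half, half + 1) * dt
    u = np.abs(dx) / (half * dt + dt)
    k0 = (1.0 - u**3) ** 3
    # np.convolve flips the kernel; use pre-flipped moments for correlation
    k1 = (k0 * dx)[::-1]
    k2 = (k0 * dx**2)[::-1]
    k0r = k0[::-1]
    rw = np.ones_like(y)
    fit = y
    for _ in range(it + 1):
        wy = rw * y
        s0 = oaconvolve(rw, k0r, mode="same")
        s1 = oaconvolve(rw, k1, mode="same")
        s2 = oaconvolve(rw, k2, mode="same")
        sy = oaconvolve(wy, k0r, mode="same")
        sxy = oaconvolve(wy, k1, mode="same")
        det = s0 * s2 - s1**2
        det = np.where(np.abs(det) < 1e-300, 1.0, det)
        fit = (s2 * sy - s1 * sxy) / det
        resid = y - fit
        ar = np.abs(resid)
        # floor the robustness scale so that when the bulk of the data fits
        # exactly (zero median residual) only the outlier itself is rejected,
        # not its regression-contaminated neighbours
        scale = 6.0 * max(float(np.median(ar)), 0.05 * float(ar.max()), 1e-300)
        rw = np.clip(1.0 - (resid / scale) ** 2, 0.0, None) ** 2
    return fit


def smooth_local_linear(trace: Trace, window_ms: float = 25.0) -> Trace:
    """Robust locally weighted linear regression (tricube weights, one
    robustness iteration) over a ``window_ms`` window; reproduces straight
    lines exactly and suppresses isolated spikes."""
    duration = trace.t[-1] - trace.t[0]
    if window_ms >= duration:
        raise ValueError("smoothing window must be shorter than the trace")
    out = trace.copy()
    out.y = _rloess(trace.y, trace.dt, window_ms, it=1)
    out.meta["smoothed_window_ms"] = window_ms
    return out


def choose_t_fixed(
    traces: list[Trace],
    threshold: float = 0.05,
    max_delay_ms: float = 50.0,
    floor_ms: float = 0.0,
) -> float:
    """Delay after the relaxation onset at which the step transient has
    decayed: first sample where |dI/dt| falls below ``threshold`` times its
    post-onset peak (chosen by eye in the experimental analysis).

    Pass the arm whose transient matters: with a non-ideal clamp that is the
    capacitive transient of the ZD arm; with clean somatic commands the
    dominant transient is the dendritic re-equilibration in the subtracted
    (smoothed) tails.  Returns the maximum delay over sweeps, at least
    ``floor_ms``."""
    delays = [floor_ms]
    for tr in traces:
        onset = tr.meta["relax_onset_ms"]
        m = (tr.t >= onset) & (tr.t <= onset + max_delay_ms)
        t, y = tr.t[m], tr.y[m]
        if len(t) < 4:
            raise ValueError("relaxation window outside trace")
        # short boxcar tames sample noise without smearing the transient
        k = max(int(round(2.0 / tr.dt)), 1)
        y = np.convolve(y, np.ones(k) / k, mode="same")
        didt = np.abs(np.gradient(y, t))
        peak = didt.max()
        if peak <= 0:
            delays.append(0.0)
            continue
        below = np.flatnonzero(didt < threshold * peak)
        delays.append(float(t[below[0]] - onset) if len(below) else max_delay_ms)
    return max(delays)


def tail_iv_fixed(subtracted_tails: list[Trace], t_fixed_ms: float) -> list[IVPoint]:
    """Current read from each (smoothed) tail at ``t_fixed_ms`` after the
    relaxation onset, one I-V point per relaxation command."""
    points = []
    for tr in subtracted_tails:
        onset = tr.meta["relax_onset_ms"]
        t_read = onset + t_fixed_ms
        if t_read > tr.t[-1]:
            raise ValueError("fixed time point outside trace")
        i = float(np.interp(t_read, tr.t, tr.y))
        points.append(IVPoint(v=float(tr.meta["level"]), i=i, method="fixed"))
    return points


def fit_exponential(t, y) -> ExponentialFit:
    """Nonlinear least squares of y = a exp(-t/tau) + c (t from window start).

    Initial values come from the endpoint offset and a log-linear slope;
    near-constant data are flagged (a ~ 0, tau unidentifiable).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) <= 3:
        raise ValueError("window must contain more than 3 samples")
    t = t - t[0]
    span = y.max() - y.min()
    scale = max(abs(y).max(), 1.0)
    if span < 1e-12 * scale:
        return ExponentialFit(
            a=0.0, tau=math.nan, c=float(y.mean()), ok=False, note="constant data"
        )
    c0 = float(np.mean(y[-max(len(y) // 20, 2):]))
    a0 = float(y[0] - c0)
    # log-linear slope on the early half for tau
    z = y - c0
    sgn = np.sign(a0) if a0 != 0 else 1.0
    zz = sgn * z[: max(len(z) // 2, 4)]
    tt = t[: len(zz)]
    good = zz > 1e-12 * scale
    if good.sum() >= 3:
        slope = np.polyfit(tt[good], np.log(zz[good]), 1)[0]
        tau0 = -1.0 / slope if slope < 0 else t[-1] / 3.0
    else:
        tau0 = t[-1] / 3.0
    tau0 = min(max(tau0, t[1] if len(t) > 1 else 1e-3), 10 * t[-1])

    def f(tt, a, tau, c):
        return a * np.exp(-tt / tau) + c

    try:
        popt, pcov = curve_fit(
            f,
            t,
            y,
            p0=[a0, tau0, c0],
            bounds=([-np.inf, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        return ExponentialFit(a=a0, tau=tau0, c=c0, ok=False, note=str(exc))
    errs = np.sqrt(np.abs(np.diag(pcov)))
    fit = ExponentialFit(
        a=float(popt[0]),
        tau=float(popt[1]),
        c=float(popt[2]),
        a_err=float(errs[0]),
        tau_err=float(errs[1]),
    )
    if abs(fit.a) < 1e-9 * scale:
        fit.ok = False
        fit.note = "amplitude ~ 0; tau unidentifiable"
    return fit


def estimate_noise(trace: Trace) -> float:
    """White-noise SD estimate from first differences (drift-insensitive)."""
    d = np.diff(trace.y)
    return float(np.median(np.abs(d)) / 0.6745 / math.sqrt(2.0))


def tail_iv_extrapolated(
    subtracted_tails: list[Trace],
    t_fixed_ms: float,
    min_amp_snr: float = 0.0,
) -> tuple[list[IVPoint], list[TauPoint]]:
    """Per sweep, a mono-exponential fit on the raw subtracted tail over
    [onset + t_fixed, relaxation end], extrapolated back to the relaxation
    onset (a + c at t = onset).  Also returns the deactivation time constants
    from the same fits.  Non-convergent sweeps are dropped and reported via
    the missing point."""
    points: list[IVPoint] = []
    taus: list[TauPoint] = []
    for tr in subtracted_tails:
        onset = tr.meta["relax_onset_ms"]
        end = onset + tr.meta["relax_duration_ms"]
        m = (tr.t >= onset + t_fixed_ms) & (tr.t <= end)
        fit_t = tr.t[m] - onset  # reference time to the onset for extrapolation
        fit = fit_exponential(fit_t - fit_t[0], tr.y[m])
        if not fit.ok:
            continue
        # shift the fitted curve back to the onset
        value_at_onset = fit.a * math.exp(fit_t[0] / fit.tau) + fit.c
        points.append(
            IVPoint(v=float(tr.meta["level"]), i=float(value_at_onset), method="extrapolated")
        )
        # a time constant is only meaningful when the decay rises well above
        # the recording noise
        if abs(fit.a) >= min_amp_snr * estimate_noise(tr):
            taus.append(
                TauPoint(v=float(tr.meta["level"]), tau=fit.tau, kind="deactivation")
            )
    return points, taus


def iv_linearity(points: list[IVPoint]) -> float:
    """Normalized RMS residual of a line through the included points
    (dimensionless; lower = more linear)."""
    inc = [p for p in points if p.include]
    vv = np.array([p.v for p in inc])
    ii = np.array([p.i for p in inc])
    slope, icpt = np.polyfit(vv, ii, 1)
    resid = ii - (slope * vv + icpt)
    scale = max(np.ptp(ii), 1e-12)
    return float(np.sqrt(np.mean(resid**2)) / scale)


def fit_reversal_and_gh(
    points: list[IVPoint], noise_pA: float | None = None
) -> tuple[float, float]:
    """Least-squares line through the included I-V points.

    E_h is the zero-current intercept (mV) and G_h the slope (pA/mV = nS).
    When ``noise_pA`` is given, the linear portion is selected automatically:
    starting from the most depolarized command, points are added while the
    incremental line fit's residual stays within 2x the noise estimate;
    points beyond get ``include=False``.  User-set include flags are honored
    (only included points enter the selection).
    """
    cand = [p for p in points if p.include]
    if len(cand) < 2:
        raise ValueError("need at least 2 included I-V points")
    cand.sort(key=lambda p: -p.v)  # most depolarized first
    if noise_pA is not None and len(cand) > 3:
        kept = cand[:3]
        for j, p in enumerate(cand[3:], start=3):
            vv = np.array([q.v for q in kept])
            ii = np.array([q.i for q in kept])
            slope, icpt = np.polyfit(vv, ii, 1)
            if abs(slope * p.v + icpt - p.i) > max(2.0 * noise_pA, 1e-12):
                for q in cand[j:]:  # stop at the first departure from linearity
                    q.include = False
                break
            kept.append(p)
        cand = kept
    vv = np.array([p.v for p in cand])
    ii = np.array([p.i for p in cand])
    if np.ptp(vv) < 1e-9:
        raise ValueError("degenerate I-V: commands are collinear in V")
    slope, icpt = np.polyfit(vv, ii, 1)
    if abs(slope) < 1e-12:
        raise ValueError("degenerate I-V: zero slope, no reversal")
    e_h = -icpt / slope
    return float(e_h), float(slope)


def build_tau_curve(
    act: list[TauPoint],
    deact: list[TauPoint],
    outlier_ratio: float = 5.0,
) -> list[TauPoint]:
    """Merge activation and deactivation branches into one tau_h(V) curve.

    Deactivation points whose tau differs from the activation branch
    (interpolated at the same V) by more than ``outlier_ratio``-fold in either
    direction are flagged as outliers (retained in the output, excluded from
    function fits) — the leak-subtraction transients make some deactivation
    points unreliable.
    """
    if not act:
        raise ValueError("need at least one activation time constant")
    av = np.array([p.v for p in act])
    at = np.array([p.tau for p in act])
    order = np.argsort(av)
    av, at = av[order], at[order]
    merged = [TauPoint(p.v, p.tau, p.kind, p.outlier) for p in act]
    for p in deact:
        ref = float(np.interp(p.v, av, at))
        flag = p.tau > outlier_ratio * ref or p.tau < ref / outlier_ratio
        merged.append(TauPoint(p.v, p.tau, p.kind, flag or p.outlier))
    return merged


def _tau_model(params, v):
    t1, t2, t3, t4, t5 = params
    return 1.0 / (np.exp(-t1 - t2 * v) + np.exp(-t3 + t4 * v)) + t5


def fit_tau_function(
    points: list[TauPoint],
    n_starts: int = 32,
    seed: int = 12345,
) -> tuple[IhParams, float]:
    """Least-squares fit of the five-parameter tau_h(V) function.

    The parameters are mutually degenerate (five numbers describing a smooth
    unimodal curve), so acceptance is judged in curve space: the returned
    RMSE (ms) over the data points is the meaningful quantity.  Multi-start
    from randomized initializations (fixed seed) with the best result kept.
    Returns (IhParams carrying t1..t5, curve RMSE in ms).
    """
    use = [p for p in points if not p.outlier]
    if len(use) < 5:
        raise ValueError("need at least 5 unflagged tau points")
    vv = np.array([p.v for p in use])
    tt = np.array([p.tau for p in use])
    if np.ptp(vv) < 40.0:
        raise ValueError("tau points must span at least 40 mV")
    rng = np.random.default_rng(seed)
    lb = np.array([-50.0, 1e-4, -60.0, 1e-4, 0.0])
    ub = np.array([60.0, 0.6, 30.0, 0.6, max(200.0, 0.9 * tt.min())])

    def resid(x):
        return _tau_model(x, vv) - tt

    # the five parameters can place an arbitrarily tall, narrow peak between
    # measured voltages without hurting the data residuals; reject such
    # degenerate solutions by bounding the fitted curve on a dense grid
    v_dense = np.arange(vv.min() - 20.0, vv.max() + 10.0, 0.25)
    tau_cap = 5.0 * tt.max()

    best, best_cost = None, np.inf
    fallback, fallback_cost = None, np.inf
    starts = [np.array([8.0, 0.03, -6.0, 0.15, max(0.5 * tt.min(), 1e-6)])]
    for _ in range(n_starts - 1):
        starts.append(
            np.array(
                [
                    rng.uniform(2.0, 40.0),
                    rng.uniform(0.005, 0.3),
                    rng.uniform(-30.0, -1.0),
                    rng.uniform(0.02, 0.5),
                    rng.uniform(0.0, min(50.0, 0.9 * tt.min())),
                ]
            )
        )
    for x0 in starts:
        x0 = np.clip(x0, lb + 1e-9, ub - 1e-9)
        try:
            res = least_squares(resid, x0, bounds=(lb, ub), max_nfev=2000)
        except Exception:
            continue
        sane = float(_tau_model(res.x, v_dense).max()) <= tau_cap
        if sane and res.cost < best_cost:
            best, best_cost = res, res.cost
        if res.cost < fallback_cost:
            fallback, fallback_cost = res, res.cost
    if best is None:
        best = fallback
    if best is None:
        raise RuntimeError("all tau-function fit starts failed")
    t1, t2, t3, t4, t5 = best.x
    rmse = float(np.sqrt(np.mean(resid(best.x) ** 2)))
    params = IhParams(t1=t1, t2=t2, t3=t3, t4=t4, t5=t5)
    return params, rmse


def steady_state_activation(
    subtracted_act: list[Trace],
    e_rev: float | None = None,
    tail_window_ms: float = 50.0,
) -> tuple[float, float, list[tuple[float, float]]]:
    """Boltzmann fit to the steady-state activation curve.

    End-of-step currents are taken from each subtracted activation sweep
    (mean over the last ``tail_window_ms`` of the step) and normalized to the
    most hyperpolarized (maximal) value.  When ``e_rev`` is supplied the
    driving force is divided out first (chord conductance), removing the
    bias the raw-current normalization would introduce.  The Boltzmann is
    fitted with a free overall scale, since the normalizing command is not
    fully activating.  Returns (V_half, k, normalized points).
    """
    vals = []
    for tr in subtracted_act:
        onset, dur = tr.meta["onset_ms"], tr.meta["duration_ms"]
        m = (tr.t >= onset + dur - tail_window_ms) & (tr.t <= onset + dur)
        i_end = float(np.mean(tr.y[m]))
        v = float(tr.meta["level"])
        if e_rev is not None:
            if abs(v - e_rev) < 1e-6:
                continue
            vals.append((v, i_end / (v - e_rev)))
        else:
            vals.append((v, i_end))
    if len(vals) < 5:
        raise ValueError("activation family must span at least 5 commands")
    vals.sort(key=lambda p: p[0])
    v_arr = np.array([p[0] for p in vals])
    g_arr = np.array([p[1] for p in vals])
    ref = g_arr[0]  # most hyperpolarized = maximal
    if abs(ref) < 1e-15:
        raise ValueError("zero reference current at the most hyperpolarized step")
    norm = g_arr / ref
    if np.any(np.diff(norm) > 0.1):
        import warnings

        warnings.warn("normalized activation curve is non-monotonic beyond tolerance")

    def f(v, s, vh, k):
        return s / (1.0 + np.exp((v - vh) / k))

    popt, _ = curve_fit(
        f,
        v_arr,
        norm,
        p0=[1.2, -100.0, 9.0],
        bounds=([0.1, -140.0, 1.0], [10.0, -60.0, 30.0]),
        maxfev=10000,
    )
    return float(popt[1]), float(popt[2]), list(zip(v_arr, norm))


@dataclass
class IhExtractionReport:
    """Per-cell extraction result: fitted parameters plus point tables."""

    ih: IhParams
    t_fixed_ms: float
    iv_fixed: list[IVPoint] = field(default_factory=list)
    iv_extrapolated: list[IVPoint] = field(default_factory=list)
    tau_points: list[TauPoint] = field(default_factory=list)
    activation_points: list[tuple[float, float]] = field(default_factory=list)
    tau_rmse_ms: float = math.nan
    e_h_method: str = "extrapolated"

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return {
            "ih": asdict(self.ih),
            "t_fixed_ms": self.t_fixed_ms,
            "e_h_method": self.e_h_method,
            "tau_rmse_ms": self.tau_rmse_ms,
            "iv_fixed": [asdict(p) for p in self.iv_fixed],
            "iv_extrapolated": [asdict(p) for p in self.iv_extrapolated],
            "tau_points": [asdict(p) for p in self.tau_points],
            "activation_points": [list(p) for p in self.activation_points],
        }


def extract_cell(
    dataset: dict[str, list[Trace]],
    t_fixed_ms: float | None = None,
    iv_method: str = "auto",
    noise_pA: float | None = None,
    act_fit_delay_ms: float = 5.0,
    smoothing_window_ms: float = 25.0,
) -> IhExtractionReport:
    """Full I_h characterization from a protocol-suite dataset.

    Requires ``vc_tail_ttx``/``vc_tail_zd`` and ``vc_act_ttx``/``vc_act_zd``
    arms.  ``iv_method`` selects which I-V variant supplies E_h and G_h:
    'extrapolated', 'fixed', or 'auto' (whichever is more linear — on
    electrotonically extended cells the dendritic relaxation corrupts the
    mono-exponential tail decays and the fixed method is the safer choice,
    as it was for the study's third cell).
    """
    tails = [
        subtract_blocker(c, z)
        for c, z in zip(dataset["vc_tail_ttx"], dataset["vc_tail_zd"])
    ]
    smoothed = [smooth_local_linear(tr, smoothing_window_ms) for tr in tails]
    if t_fixed_ms is None:
        t_fixed_ms = choose_t_fixed(tails, floor_ms=5.0)
    iv_fixed = tail_iv_fixed(smoothed, t_fixed_ms)
    iv_extrap, deact_taus = tail_iv_extrapolated(tails, t_fixed_ms, min_amp_snr=5.0)
    if iv_method == "auto":
        iv_method = (
            "extrapolated"
            if len(iv_extrap) >= len(iv_fixed) - 1
            and iv_linearity(iv_extrap) <= iv_linearity(iv_fixed)
            else "fixed"
        )
    chosen = iv_extrap if iv_method == "extrapolated" else iv_fixed
    e_h, gh = fit_reversal_and_gh(chosen, noise_pA=noise_pA)

    acts = [
        subtract_blocker(c, z)
        for c, z in zip(dataset["vc_act_ttx"], dataset["vc_act_zd"])
    ]
    act_taus = []
    for tr in acts:
        onset, dur = tr.meta["onset_ms"], tr.meta["duration_ms"]
        m = (tr.t >= onset + act_fit_delay_ms) & (tr.t <= onset + dur)
        fit = fit_exponential(tr.t[m], tr.y[m])
        if fit.ok and abs(fit.a) >= 5.0 * estimate_noise(tr):
            act_taus.append(
                TauPoint(v=float(tr.meta["level"]), tau=fit.tau, kind="activation")
            )
    tau_points = build_tau_curve(act_taus, deact_taus)
    tau_fit, tau_rmse = fit_tau_function(tau_points)
    v_half, k, act_points = steady_state_activation(acts, e_rev=e_h)

    # the tail I-V slope is G_h * r(prepulse): the -120 mV prepulse activates
    # nearly, but not exactly, all channels.  Correct by the fitted Boltzmann
    # at the prepulse command.
    prepulse = float(dataset["vc_tail_ttx"][0].meta.get("prepulse_mV", -120.0))
    r_pre = 1.0 / (1.0 + math.exp((prepulse - v_half) / k))
    gh = gh / r_pre

    ih = IhParams(
        e_h=e_h,
        v_half=v_half,
        k=k,
        t1=tau_fit.t1,
        t2=tau_fit.t2,
        t3=tau_fit.t3,
        t4=tau_fit.t4,
        t5=tau_fit.t5,
        gh_total_nS=gh,
    )
    return IhExtractionReport(
        ih=ih,
        t_fixed_ms=t_fixed_ms,
        iv_fixed=iv_fixed,
        iv_extrapolated=iv_extrap,
        tau_points=tau_points,
        activation_points=act_points,
        tau_rmse_ms=tau_rmse,
        e_h_method=iv_method,
    )
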