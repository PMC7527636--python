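"""Spiking-model optimization against electrophysiological features.

Depolarizing current steps (+30/+60/+90 pA) are summarized by a feature
vector (spike count, mean frequency, latency, AP half-width and height, AHP
depth, spike-frequency adaptation); model fitness is the sum over features
of the absolute deviation from the target in units of a manually chosen
standard deviation sigma (so sigma acts as an inverse weight), plus a heavy
penalty for any spike fired during the baseline (holding) periods.

The optimizer is an indicator-based evolutionary algorithm (IBEA with the
additive-epsilon indicator): each candidate's multi-objective vector is the
per-feature deviation list; selection pressure comes from the pairwise
epsilon indicator, variation from simulated-binary crossover and polynomial
mutation.  Deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .channels import NaTParams
from .model import CellModel
from .simulator import PharmacologyFlags, Protocol, Sweep, Trace, cc_step_protocol

__all__ = [
    "SpikeTrain",
    "FeatureVector",
    "ObjectiveSpec",
    "OptimizationConfig",
    "ParamSpec",
    "detect_spikes",
    "extract_features",
    "fitness",
    "evolve",
    "targets_from_traces",
    "simulate_steps",
    "DEFAULT_SIGMAS",
    "DEFAULT_FREE_PARAMS",
]

ABSENT = None  # marker for features that require spikes that did not occur


@dataclass
class SpikeTrain:
    times: np.ndarray  # peak times, ms
    thresholds: np.ndarray  # mV, per spike
    peak_v: np.ndarray  # mV, per spike

    def __len__(self) -> int:
        return len(self.times)


def detect_spikes(
    trace: Trace,
    dvdt_threshold: float = 20.0,  # mV/ms
    peak_min_mV: float = -10.0,
    merge_ms: float = 2.0,
) -> SpikeTrain:
    """Spike detection by a dV/dt criterion.

    A spike is a local maximum above ``peak_min_mV`` whose upstroke reached
    ``dvdt_threshold``; its threshold is the voltage at the first sample of
    that upstroke.  Peaks closer than ``merge_ms`` are merged.
    """
    v = trace.y
    t = trace.t
    dvdt = np.gradient(v, t)
    above = v >= peak_min_mV
    fast = dvdt >= dvdt_threshold
    times, thresholds, peaks = [], [], []
    i = 0
    n = len(v)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            seg = slice(i, j)
            pk = i + int(np.argmax(v[seg]))
            # find the threshold: walk back to the start of the fast upstroke
            k = pk
            while k > 0 and dvdt[k] < dvdt_threshold:
                k -= 1
            while k > 0 and dvdt[k - 1] >= dvdt_threshold:
                k -= 1
            if np.any(fast[max(k - 1, 0) : pk + 1]):
                if times and t[pk] - times[-1] < merge_ms:
                    if v[pk] > peaks[-1]:
                        times[-1], peaks[-1] = t[pk], v[pk]
                        thresholds[-1] = v[k]
                else:
                    times.append(float(t[pk]))
                    thresholds.append(float(v[k]))
                    peaks.append(float(v[pk]))
            i = j
        else:
            i += 1
    return SpikeTrain(
        times=np.array(times), thresholds=np.array(thresholds), peak_v=np.array(peaks)
    )


@dataclass
class FeatureVector:
    """Electrophysiological features of one step response.

    Features that require spikes that did not occur are ``None`` (absent),
    never zero.
    """

    spike_count: int = 0
    mean_frequency_Hz: float = 0.0
    time_to_first_spike_ms: float | None = None
    ap_half_width_ms: float | None = None
    ap_height_mV: float | None = None
    ahp_depth_mV: float | None = None
    adaptation_coefficient: float | None = None
    baseline_spike_count: int = 0
    steady_state_V_mV: float | None = None
    sag_ratio: float | None = None

    def get(self, name: str):
        return getattr(self, name)


def extract_features(trace: Trace, spikes: SpikeTrain | None = None) -> FeatureVector:
    """Features of a current-clamp step response.

    Conventions: AP height = peak minus threshold; half-width measured at
    half height between threshold and peak; AHP depth = threshold minus the
    minimum between consecutive spikes; adaptation coefficient = first ISI /
    last ISI; sag ratio = steady-state deflection / peak deflection from
    baseline (hyperpolarizing steps); mean frequency = spike count / step
    duration.
    """
    onset = trace.meta["onset_ms"]
    dur = trace.meta["duration_ms"]
    level = trace.meta.get("level", 0.0)
    if spikes is None:
        spikes = detect_spikes(trace)
    fv = FeatureVector()
    in_step = (spikes.times >= onset) & (spikes.times <= onset + dur)
    step_idx = np.flatnonzero(in_step)
    fv.baseline_spike_count = int(len(spikes.times) - len(step_idx))
    fv.spike_count = int(len(step_idx))
    fv.mean_frequency_Hz = fv.spike_count / (dur / 1000.0)
    base_mask = (trace.t > onset - 200) & (trace.t < onset)
    baseline = float(np.mean(trace.y[base_mask])) if base_mask.any() else math.nan

    if fv.spike_count:
        first = step_idx[0]
        fv.time_to_first_spike_ms = float(spikes.times[first] - onset)
        thr = spikes.thresholds[first]
        pk = spikes.peak_v[first]
        fv.ap_height_mV = float(pk - thr)
        half = thr + 0.5 * (pk - thr)
        # half-width of the first AP
        ipk = int(np.searchsorted(trace.t, spikes.times[first]))
        i0 = ipk
        while i0 > 0 and trace.y[i0] > half:
            i0 -= 1
        i1 = ipk
        while i1 < len(trace.y) - 1 and trace.y[i1] > half:
            i1 += 1
        fv.ap_half_width_ms = float(trace.t[i1] - trace.t[i0])
    if fv.spike_count >= 2:
        tt = spikes.times[step_idx]
        mins = []
        for a, b in zip(tt[:-1], tt[1:]):
            m = (trace.t > a) & (trace.t < b)
            if m.any():
                mins.append(float(trace.y[m].min()))
        if mins:
            fv.ahp_depth_mV = float(spikes.thresholds[step_idx[0]] - min(mins))
    if fv.spike_count >= 3:
        isis = np.diff(spikes.times[step_idx])
        if isis[-1] > 0:
            fv.adaptation_coefficient = float(isis[0] / isis[-1])

    ss_mask = (trace.t > onset + 0.8 * dur) & (trace.t < onset + dur)
    if fv.spike_count == 0 and ss_mask.any():
        fv.steady_state_V_mV = float(np.mean(trace.y[ss_mask]))
    if level < 0 and ss_mask.any() and not math.isnan(baseline):
        m = (trace.t >= onset) & (trace.t <= onset + dur)
        peak_defl = float(trace.y[m].min() - baseline)
        ss_defl = float(np.mean(trace.y[ss_mask]) - baseline)
        if peak_defl < 0:
            fv.sag_ratio = ss_defl / peak_defl
    return fv


# default manual SDs: 1-2 orders of magnitude below each feature's leading
# digit, mirroring the hand-weighting strategy used for the optimizations
DEFAULT_SIGMAS: dict[str, float] = {
    "spike_count": 0.2,
    "mean_frequency_Hz": 0.1,
    "time_to_first_spike_ms": 2.0,
    "ap_half_width_ms": 0.01,
    "ap_height_mV": 0.5,
    "ahp_depth_mV": 0.5,
    "adaptation_coefficient": 0.02,
}

# features meaningful only when enough spikes occur; applied to the larger
# steps only, since +30 pA does not always produce enough spikes
_RESTRICTED_FEATURES = ("adaptation_coefficient", "ahp_depth_mV")


@dataclass
class ObjectiveSpec:
    """Per-step feature targets with manual SD weights.

    ``targets[amplitude][feature]`` holds the target value; features listed
    in ``restricted`` contribute only for amplitudes in ``restricted_amps``.
    ``miss_penalty`` is charged when a required feature is absent in the
    model; ``baseline_penalty`` per baseline spike.
    """

    targets: dict[float, dict[str, float]]
    sigmas: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SIGMAS))
    restricted: tuple[str, ...] = _RESTRICTED_FEATURES
    restricted_amps: tuple[float, ...] = (60.0, 90.0)
    baseline_penalty: float = 250.0
    # charged per absent-but-required feature; must exceed any plausible
    # sigma-normalized deviation so "not spiking at all" never beats a poor
    # spiking match
    miss_penalty: float = 250.0

    def __post_init__(self) -> None:
        for s in self.sigmas.values():
            if s <= 0:
                raise ValueError("sigma weights must be positive")

    def objective_names(self) -> list[str]:
        names = []
        for amp in sorted(self.targets):
            for feat in sorted(self.targets[amp]):
                if feat in self.restricted and amp not in self.restricted_amps:
                    continue
                names.append(f"{feat}@{amp:+.0f}pA")
        names.append("baseline_spikes")
        return names


def fitness(
    features: dict[float, FeatureVector], spec: ObjectiveSpec
) -> tuple[float, dict[str, float]]:
    """Scalar fitness plus the per-objective breakdown (exactly summing to
    the total).  Each feature contributes |model - target| / sigma; absent
    required features incur ``miss_penalty``; every baseline spike adds
    ``baseline_penalty``."""
    breakdown: dict[str, float] = {}
    baseline_spikes = 0
    for amp in sorted(spec.targets):
        fv = features.get(amp)
        if fv is None:
            raise KeyError(f"missing features for {amp} pA step")
        baseline_spikes += fv.baseline_spike_count
        for feat, target in sorted(spec.targets[amp].items()):
            if feat in spec.restricted and amp not in spec.restricted_amps:
                continue
            val = fv.get(feat)
            key = f"{feat}@{amp:+.0f}pA"
            if val is None:
                breakdown[key] = spec.miss_penalty
            else:
                breakdown[key] = abs(val - target) / spec.sigmas[feat]
    breakdown["baseline_spikes"] = spec.baseline_penalty * baseline_spikes
    return float(sum(breakdown.values())), breakdown


def targets_from_traces(
    traces: dict[float, Trace], sigmas: dict[str, float] | None = None
) -> ObjectiveSpec:
    """Build an objective spec from recorded step responses (one per
    amplitude); absent target features are simply not constrained."""
    targets: dict[float, dict[str, float]] = {}
    sig = dict(DEFAULT_SIGMAS)
    if sigmas:
        sig.update(sigmas)
    for amp, tr in traces.items():
        fv = extract_features(tr)
        row = {}
        for feat in sig:
            val = fv.get(feat)
            if val is not None:
                row[feat] = float(val)
        targets[float(amp)] = row
    return ObjectiveSpec(targets=targets, sigmas=sig)


# ---------------------------------------------------------------------------
# candidate parameterization and evaluation
# ---------------------------------------------------------------------------

@dataclass
class ParamSpec:
    """One free parameter: a (mechanism, region) density or a Na_T V_shift."""

    name: str  # e.g. 'nat.soma', 'kdrf.dend', 'vshift.soma'
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lo) and np.isfinite(self.hi) and self.lo < self.hi):
            raise ValueError(f"bad bounds for {self.name}")


DEFAULT_FREE_PARAMS: tuple[ParamSpec, ...] = (
    ParamSpec("nat.soma", 30.0, 300.0),
    ParamSpec("nat.dend", 10.0, 200.0),
    ParamSpec("nat.axon", 50.0, 500.0),
    ParamSpec("kdrf.soma", 15.0, 200.0),
    ParamSpec("kdrf.dend", 5.0, 100.0),
    ParamSpec("ka.soma", 5.0, 150.0),
    ParamSpec("vshift.soma", -7.0, 7.0),
)


def apply_free_params(base: CellModel, specs, values) -> CellModel:
    """Realize a candidate: densities in pS/um^2, shifts in mV."""
    nat = base.nat or NaTParams()
    nat_kw = {
        "g_soma": nat.g_soma,
        "g_dend": nat.g_dend,
        "g_axon": nat.g_axon,
        "e_na": nat.e_na,
        "v_shift_soma": nat.v_shift_soma,
        "v_shift_dend": nat.v_shift_dend,
        "v_shift_axon": nat.v_shift_axon,
    }
    spiking = {k: dict(v) for k, v in (base.spiking or {}).items()}
    for spec, val in zip(specs, values):
        mech, region = spec.name.split(".")
        if mech == "nat":
            nat_kw[f"g_{region}"] = float(val)
        elif mech == "vshift":
            nat_kw[f"v_shift_{region}"] = float(val)
        else:
            spiking.setdefault(mech, {})[region] = float(val)
    return base.replace(nat=NaTParams(**nat_kw), spiking=spiking)


def simulate_steps(
    model: CellModel,
    amplitudes=(30.0, 60.0, 90.0),
    holding_pA: float = 0.0,
    dt: float = 0.05,
    pre_ms: float = 500.0,
    step_ms: float = 2000.0,
    post_ms: float = 300.0,
) -> dict[float, Trace]:
    """Run the depolarizing step family and return traces keyed by amplitude."""
    proto = cc_step_protocol(
        amplitudes_pA=amplitudes,
        holding_pA=holding_pA,
        pre_ms=pre_ms,
        step_ms=step_ms,
        post_ms=post_ms,
        pharmacology=PharmacologyFlags(),
        name="opt_steps",
    )
    traces = model.simulator().run_protocol(proto, dt=dt, settle_ms=1000.0)
    return {float(tr.meta["level"]): tr for tr in traces}


@dataclass
class OptimizationConfig:
    free_params: tuple[ParamSpec, ...] = DEFAULT_FREE_PARAMS
    offspring: int = 100
    generations: int = 200
    mutation_rate: float = 0.15
    crossover_rate: float = 0.85
    eta: float = 0.5
    seed: int = 61
    holding_pA: float = 0.0
    top_k: int = 5
    dt: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.mutation_rate <= 1.0 and 0.0 <= self.crossover_rate <= 1.0):
            raise ValueError("rates must lie in [0, 1]")
        if self.offspring < 4 or self.generations < 1:
            raise ValueError("population too small")


def _sbx(rng, a, b, lo, hi, eta):
    """Simulated binary crossover (per gene)."""
    u = rng.random(len(a))
    beta = np.where(
        u <= 0.5,
        (2.0 * u) ** (1.0 / (eta + 1.0)),
        (1.0 / (2.0 * (1.0 - u))) ** (1.0 / (eta + 1.0)),
    )
    c1 = 0.5 * ((1 + beta) * a + (1 - beta) * b)
    c2 = 0.5 * ((1 - beta) * a + (1 + beta) * b)
    return np.clip(c1, lo, hi), np.clip(c2, lo, hi)


def _poly_mutate(rng, x, lo, hi, rate, eta):
    # at least one gene always mutates: with small populations, crossover of
    # near-identical parents plus a low per-gene rate would otherwise emit
    # clones and stall the search
    y = x.copy()
    forced = rng.integers(0, len(x))
    for i in range(len(x)):
        if i == forced or rng.random() < rate:
            u = rng.random()
            delta = (
                (2 * u) ** (1.0 / (eta + 1.0)) - 1.0
                if u < 0.5
                else 1.0 - (2 * (1 - u)) ** (1.0 / (eta + 1.0))
            )
            y[i] = x[i] + delta * (hi[i] - lo[i])
    return np.clip(y, lo, hi)


def _ibea_fitness(objs: np.ndarray, kappa: float = 0.05) -> np.ndarray:
    """Additive-epsilon IBEA fitness (higher is better)."""
    lo = objs.min(axis=0)
    span = np.maximum(objs.max(axis=0) - lo, 1e-12)
    z = (objs - lo) / span
    # eps[j, i] = I(i, j) = max_m (z_i - z_j): how much worse j is than i
    eps = np.max(z[None, :, :] - z[:, None, :], axis=2)
    c = max(np.abs(eps).max(), 1e-12)
    contrib = -np.exp(-eps / (kappa * c))
    np.fill_diagonal(contrib, 0.0)
    # F(j) = sum_i -exp(-I(i, j) / kappa c); a dominated j accumulates large
    # negative terms, so higher fitness = better
    return contrib.sum(axis=1)


def evolve(
    base_model: CellModel | None,
    objective: ObjectiveSpec | None,
    config: OptimizationConfig,
    amplitudes=(30.0, 60.0, 90.0),
    evaluator=None,
) -> list[dict]:
    """IBEA optimization of the free parameters against the feature targets.

    Returns the top-K parameter sets (dicts with 'params', 'fitness',
    'breakdown', 'objectives'), ranked by aggregate scalar fitness.
    Candidates whose simulation fails get the worst observed fitness.
    Deterministic for a fixed config seed.  ``evaluator(x) -> (total,
    breakdown dict)`` replaces the simulation-based evaluation when given
    (testing hook / custom objectives).
    """
    rng = np.random.default_rng(config.seed)
    specs = config.free_params
    lo = np.array([p.lo for p in specs])
    hi = np.array([p.hi for p in specs])
    npar = len(specs)

    cache: dict[tuple, tuple] = {}

    def evaluate(x: np.ndarray):
        key = tuple(np.round(x, 10))
        if key in cache:
            return cache[key]
        if evaluator is not None:
            total, breakdown = evaluator(x)
            vec = np.array([breakdown[k] for k in sorted(breakdown)] + [total])
            cache[key] = (total, breakdown, vec)
            return cache[key]
        try:
            model = apply_free_params(base_model, specs, x)
            traces = simulate_steps(
                model, amplitudes, holding_pA=config.holding_pA, dt=config.dt
            )
            feats = {amp: extract_features(tr) for amp, tr in traces.items()}
            total, breakdown = fitness(feats, objective)
            # the aggregate joins the objective vector so the indicator also
            # rewards all-round improvement (helps at small budgets)
            vec = np.array([breakdown[k] for k in sorted(breakdown)] + [total])
        except Exception:
            total, breakdown, vec = math.inf, {"failed": math.inf}, None
        cache[key] = (total, breakdown, vec)
        return cache[key]

    # Latin-hypercube start: every parameter's range is covered evenly even
    # by a small population
    u = (rng.permuted(np.tile(np.arange(config.offspring), (npar, 1)), axis=1).T
         + rng.random((config.offspring, npar))) / config.offspring
    pop = lo + u * (hi - lo)
    evals = [evaluate(x) for x in pop]
    n_obj = next(len(e[2]) for e in evals if e[2] is not None)
    worst_scalar = max((e[0] for e in evals if np.isfinite(e[0])), default=1e6)

    def obj_matrix(ev):
        rows = []
        for total, _, vec in ev:
            if vec is None:
                rows.append(np.full(n_obj, worst_scalar))
            else:
                rows.append(vec)
        return np.array(rows)

    for gen in range(config.generations):
        # mutation sharpens over the run: coarse jumps early, fine polishing
        # of the incumbent late
        mut_eta = 10.0 + 60.0 * gen / max(config.generations - 1, 1)
        fit = _ibea_fitness(obj_matrix(evals))
        # binary tournaments to pick parents
        children = []

        def pick_parent():
            idx = rng.integers(0, len(pop), 3)
            return pop[idx[np.argmax(fit[idx])]]

        while len(children) < config.offspring:
            pa = pick_parent()
            pb = pick_parent()
            if rng.random() < config.crossover_rate:
                c1, c2 = _sbx(rng, pa, pb, lo, hi, max(config.eta, 1e-3))
            else:
                c1, c2 = pa.copy(), pb.copy()
            children.append(
                _poly_mutate(rng, c1, lo, hi, config.mutation_rate, mut_eta)
            )
            if len(children) < config.offspring:
                children.append(
                    _poly_mutate(rng, c2, lo, hi, config.mutation_rate, mut_eta)
                )
        child_evals = [evaluate(x) for x in children]
        merged = np.vstack([pop, np.array(children)])
        merged_evals = evals + child_evals
        # environmental selection: iteratively drop the worst by IBEA
        # fitness, always protecting the scalar-best individual (elitism)
        best_idx = int(np.argmin([e[0] for e in merged_evals]))
        keep = list(range(len(merged)))
        objs = obj_matrix(merged_evals)
        while len(keep) > config.offspring:
            f = _ibea_fitness(objs[keep])
            order = np.argsort(f)
            drop = next(i for i in order if keep[i] != best_idx)
            keep.pop(int(drop))
        pop = merged[keep]
        evals = [merged_evals[i] for i in keep]

    order = np.argsort([e[0] for e in evals])
    out = []
    for rank, idx in enumerate(order[: config.top_k]):
        total, breakdown, _ = evals[idx]
        out.append(
            {
                "rank": rank + 1,
                "params": {p.name: float(v) for p, v in zip(specs, pop[idx])},
                "fitness": total,
                "breakdown": breakdown,
            }
        )
    return out
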