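"""Plain-text trace and dataset persistence.

A trace is a two-column delimited text file (t_ms, value) with a JSON sidecar
(same stem, ``.json``) carrying the protocol metadata: clamp mode, units,
holding level, sweep label, pharmacology flags, cell id and noise settings.
A dataset directory holds one subdirectory per protocol arm plus a
``ground_truth.json`` when the data are synthetic.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .simulator import Trace

__all__ = ["write_trace", "read_trace", "write_dataset", "read_dataset"]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_trace(trace: Trace, path) -> None:
    """Write (t_ms, value) columns plus a ``.json`` metadata sidecar."""
    path = Path(path)
    data = np.column_stack([trace.t, trace.y])
    np.savetxt(path, data, fmt="%.6g", delimiter="\t", header="t_ms\tvalue")
    sidecar = dict(trace.meta)
    sidecar["dt_ms"] = trace.dt
    path.with_suffix(".json").write_text(json.dumps(_jsonable(sidecar), indent=1))


def read_trace(path) -> Trace:
    """Read a trace file; the sidecar is optional (grid inferred from t)."""
    path = Path(path)
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (t_ms, value)")
    t, y = data[:, 0], data[:, 1]
    dts = np.diff(t)
    if len(dts) and not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
        raise ValueError(f"{path}: non-uniform time grid")
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    dt = float(meta.get("dt_ms", dts[0] if len(dts) else 1.0))
    return Trace(t=t, y=y, dt=dt, meta=meta)


def write_dataset(dataset: dict[str, list[Trace]], outdir, ground_truth=None) -> None:
    """Persist a {protocol name: [sweeps]} mapping as a dataset directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for proto_name, traces in dataset.items():
        sub = outdir / proto_name
        sub.mkdir(exist_ok=True)
        for i, tr in enumerate(traces):
            label = tr.meta.get("sweep", f"sweep{i}")
            write_trace(tr, sub / f"{i:02d}_{label}.txt")
    if ground_truth is not None:
        (outdir / "ground_truth.json").write_text(
            json.dumps(_jsonable(ground_truth), indent=1)
        )


def read_dataset(indir) -> dict[str, list[Trace]]:
    indir = Path(indir)
    dataset: dict[str, list[Trace]] = {}
    for sub in sorted(p for p in indir.iterdir() if p.is_dir()):
        traces = [read_trace(f) for f in sorted(sub.glob("*.txt"))]
        if traces:
            dataset[sub.name] = traces
    return dataset
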