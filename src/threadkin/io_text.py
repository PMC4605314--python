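"""Plain-text readers/writers and the run manifest.

The field has no standard trace format, so traces travel as delimited
text with a '#'-prefixed key=value metadata block, making each file
self-describing.  All numbers are written with 12 significant digits so
a write/read round trip is lossless to formatting precision.  A manifest
JSON records the config snapshot, seeds, and a sha256 checksum for every
output file.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .landscape import EnergyLandscape
from .trace_model import Trace

_FMT = "%.12g"


def _write_metadata(fh, meta: dict) -> None:
    for key, value in meta.items():
        fh.write(f"# {key} = {value}\n")


def _read_metadata(lines) -> tuple[dict, list[str]]:
    meta: dict = {}
    body: list[str] = []
    for line in lines:
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            content = stripped.lstrip("#").strip()
            if "=" in content:
                key, _, value = content.partition("=")
                meta[key.strip()] = value.strip()
            continue
        body.append(stripped)
    return meta, body


def _parse_scalar(s: str):
    for cast in (int, float):
        try:
            return cast(s)
        except (TypeError, ValueError):
            continue
    return None if s == "None" else s


def write_trace(path, trace: Trace) -> Path:
    path = Path(path)
    meta = {"force_pN": _FMT % trace.force, "conc_nM": _FMT % trace.concentration}
    for key, value in trace.metadata.items():
        meta[key] = _FMT % value if isinstance(value, float) else value
    with open(path, "w") as fh:
        _write_metadata(fh, meta)
        fh.write("# time_s\tdx_nm_per_bp\n")
        for t, x in zip(trace.times, trace.extensions):
            fh.write(f"{_FMT % t}\t{_FMT % x}\n")
    return path


def read_trace(path) -> Trace:
    with open(path) as fh:
        meta, body = _read_metadata(fh)
    data = np.array([[float(v) for v in line.split()] for line in body])
    force = float(meta.pop("force_pN"))
    conc = float(meta.pop("conc_nM"))
    metadata = {k: _parse_scalar(v) for k, v in meta.items()}
    return Trace(times=data[:, 0], extensions=data[:, 1], force=force,
                 concentration=conc, metadata=metadata)


def write_force_extension(path, forces, extensions, meta: dict | None = None) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        if meta:
            _write_metadata(fh, meta)
        fh.write("# force_pN\textension_nm_per_bp\n")
        for f, x in zip(forces, extensions):
            fh.write(f"{_FMT % f}\t{_FMT % x}\n")
    return path


def read_force_extension(path) -> tuple[np.ndarray, np.ndarray]:
    with open(path) as fh:
        _, body = _read_metadata(fh)
    data = np.array([[float(v) for v in line.split()] for line in body])
    return data[:, 0], data[:, 1]


def write_landscape(path, landscape: EnergyLandscape) -> Path:
    """Delimited landscape table plus a sibling JSON with full context."""
    path = Path(path)
    with open(path, "w") as fh:
        _write_metadata(fh, {
            "attempt_rate_per_s": _FMT % landscape.attempt_rate,
            "conc_nM": _FMT % landscape.concentration,
            "mono_convention": landscape.mono_convention,
        })
        fh.write("# label\telongation_nm\tenergy_kBT\n")
        for s in landscape.states:
            fh.write(f"{s.label}\t{_FMT % s.elongation}\t{_FMT % s.energy}\n")
    json_path = path.with_suffix(path.suffix + ".json")
    payload = {
        "attempt_rate_per_s": landscape.attempt_rate,
        "conc_nM": landscape.concentration,
        "mono_convention": landscape.mono_convention,
        "states": [
            {"label": s.label, "elongation_nm": s.elongation, "energy_kBT": s.energy}
            for s in landscape.states
        ],
    }
    json_path.write_text(json.dumps(payload, indent=2))
    return path


def interpolate_landscape(landscape: EnergyLandscape, n: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear rendering of the landscape (cosmetic only)."""
    x = np.array([s.elongation for s in landscape.states])
    g = np.array([s.energy for s in landscape.states])
    xs = np.linspace(x[0], x[-1], n)
    return xs, np.interp(xs, x, g)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def build_manifest(config: dict, files: list, seeds: dict | None = None,
                   stage_outcomes: dict | None = None) -> dict:
    from . import __version__

    return {
        "tool_version": __version__,
        "config": config,
        "seeds": seeds or {},
        "stage_outcomes": stage_outcomes or {},
        "files": [{"path": str(Path(p).name), "sha256": sha256_of(p)} for p in files],
    }


def write_manifest(path, manifest: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
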