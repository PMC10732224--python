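"""Extended-XYZ trajectory I/O and dataset containers.

The trajectory format is the plain extended-XYZ convention: a bead
count line, a comment line of ``key=value`` pairs (ring/open flag, knot
label, seeds), then one ``C x y z`` line per bead.  Multiple frames are
concatenated.  Feature tensors and labels are stored as ``.npz``
archives with a JSON sidecar carrying the generating configuration.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .conformation import RingConformation

__all__ = ["write_xyz", "read_xyz", "save_dataset", "load_dataset"]


def _format_comment(meta: dict) -> str:
    parts = []
    for k, v in meta.items():
        s = str(v)
        if " " in s:
            s = f'"{s}"'
        parts.append(f"{k}={s}")
    return " ".join(parts)


def _parse_comment(line: str) -> dict:
    meta = {}
    import shlex
    for tok in shlex.split(line):
        if "=" in tok:
            k, v = tok.split("=", 1)
            meta[k] = v
    return meta


def write_xyz(path, frames, metadata=None, mode: str = "w") -> None:
    """Write conformations (or one conformation) to an extended-XYZ file."""
    if isinstance(frames, RingConformation):
        frames = [frames]
    metadata = metadata or {}
    with open(path, mode) as fh:
        for idx, conf in enumerate(frames):
            meta = {
                "frame": idx,
                "closed": "T" if conf.closed else "F",
                "bead_spacing": f"{conf.bead_spacing_target:.6g}",
            }
            meta.update(metadata)
            fh.write(f"{conf.n_beads}\n")
            fh.write(_format_comment(meta) + "\n")
            for x, y, z in conf.positions:
                fh.write(f"C {x:.8f} {y:.8f} {z:.8f}\n")


def read_xyz(path, validate: bool = True):
    """Read all frames from an extended-XYZ file.

    Returns a list of ``(RingConformation, metadata)`` pairs.
    """
    frames = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            meta = _parse_comment(fh.readline())
            pos = np.empty((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                pos[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
            closed = meta.get("closed", "T") == "T"
            spacing = float(meta.get("bead_spacing", 1.0))
            conf = RingConformation(pos, closed=closed, bead_spacing_target=spacing,
                                    validate=validate)
            frames.append((conf, meta))
    return frames


def save_dataset(path, arrays: dict, config: dict | None = None) -> None:
    """Save named arrays (.npz) with a JSON sidecar of the generating config."""
    path = Path(path)
    np.savez_compressed(path, **arrays)
    if config is not None:
        sidecar = path.with_suffix(path.suffix + ".json") if path.suffix != ".npz" \
            else path.with_suffix(".json")
        sidecar.write_text(json.dumps(config, indent=2, default=str))


def load_dataset(path):
    path = Path(path)
    data = dict(np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")))
    sidecar = path.with_suffix(".json")
    config = json.loads(sidecar.read_text()) if sidecar.exists() else None
    return data, config
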