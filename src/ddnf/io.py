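"""CSV / JSON writers and readers for trajectories and stability reports.

Numbers are serialized with ``repr``, Python's shortest round-trip
representation of a double, so write-then-read reproduces every value
bit-exactly and repeated runs of a deterministic scenario produce
byte-identical files.
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path

import numpy as np

from .dynamics import Trajectory
from .exceptions import InputError
from .stability import StabilityReport

__all__ = [
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_report_json",
    "write_cobweb_csv",
    "write_manifest",
]


def _fmt(x: float) -> str:
    return repr(float(x))


def trajectory_header(sizes: tuple[int, ...]) -> list[str]:
    """Column labels ``n, 1:1, 1:2, ..., k:i`` (1-based layer:neuron)."""
    cols = ["n"]
    for k, m in enumerate(sizes, start=1):
        cols.extend(f"{k}:{i}" for i in range(1, m + 1))
    return cols


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> Path:
    """One row per time step; padded entries are not written."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(trajectory_header(traj.sizes))
        for n in range(len(traj)):
            row = [str(n)]
            for k, m in enumerate(traj.sizes):
                row.extend(_fmt(v) for v in traj.values[n, k, :m])
            writer.writerow(row)
    return path


def read_trajectory_csv(path: str | Path) -> Trajectory:
    """Inverse of :func:`write_trajectory_csv` (bit-exact round trip)."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header[0] != "n":
            raise InputError(f"{path}: malformed trajectory header")
        sizes: dict[int, int] = {}
        for label in header[1:]:
            k_s, i_s = label.split(":")
            k, i = int(k_s), int(i_s)
            sizes[k] = max(sizes.get(k, 0), i)
        layer_sizes = tuple(sizes[k] for k in sorted(sizes))
        rows = [[float(v) for v in row[1:]] for row in reader]
    L = len(layer_sizes)
    M = max(layer_sizes)
    values = np.zeros((len(rows), L, M))
    for n, row in enumerate(rows):
        pos = 0
        for k, m in enumerate(layer_sizes):
            values[n, k, :m] = row[pos : pos + m]
            pos += m
    return Trajectory(values=values, sizes=layer_sizes)


def report_to_dict(report: StabilityReport) -> dict:
    out = {
        "rho": report.rho,
        "classification": report.classification,
        "eigenvalues": [[float(z.real), float(z.imag)] for z in report.eigenvalues],
        "theorem_flags": dict(report.theorem_flags),
        "details": {k: float(v) for k, v in report.details.items()},
        "adjacency_shape": list(report.adjacency.shape),
    }
    if report.mu_single is not None:
        out["mu_single"] = [float(v) for v in report.mu_single]
    if report.mu_multi is not None:
        out["mu_multi"] = [float(v) for v in report.mu_multi]
    return out


def write_report_json(report: StabilityReport, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report_to_dict(report), indent=2, sort_keys=True) + "\n")
    return path


def write_cobweb_csv(pairs: list[tuple[float, float]], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["v_n", "v_next"])
        for a, b in pairs:
            writer.writerow([_fmt(a), _fmt(b)])
    return path


def write_manifest(out_dir: str | Path, files: list[Path]) -> Path:
    """JSON manifest with SHA-256 checksums of the written artifacts."""
    out_dir = Path(out_dir)
    entries = {}
    for f in files:
        data = Path(f).read_bytes()
        entries[Path(f).name] = {
            "sha256": hashlib.sha256(data).hexdigest(),
            "bytes": len(data),
        }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps({"files": entries}, indent=2, sort_keys=True) + "\n")
    return path
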