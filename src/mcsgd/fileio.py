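"""Plain-text serialization of profiles, traces and run manifests.

Depth profiles are whitespace-separated columns with ``#``-prefixed header
lines carrying provenance (modality, photon counts, seeds).  Traces are CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

__all__ = ["write_profile", "read_profile", "write_manifest", "read_manifest"]


def write_profile(path, z: np.ndarray, columns: dict, header: dict | None = None) -> None:
    """Write a depth profile: first column z_center_cm, then ``columns``.

    ``header`` key-value pairs are recorded as ``# key: value`` lines.
    """
    path = Path(path)
    names = ["z_center_cm"] + list(columns)
    data = np.column_stack([np.asarray(z, float)] + [np.asarray(c, float) for c in columns.values()])
    lines = []
    for k, v in (header or {}).items():
        lines.append(f"# {k}: {v}")
    lines.append("# columns: " + " ".join(names))
    for row in data:
        lines.append(" ".join(f"{v:.10g}" for v in row))
    path.write_text("\n".join(lines) + "\n")


def read_profile(path) -> tuple[np.ndarray, dict]:
    """Read a profile written by :func:`write_profile`.

    Returns (data array with z in column 0, header dict of strings).
    """
    header: dict = {}
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                header[k.strip()] = v.strip()
            continue
        rows.append([float(tok) for tok in line.split()])
    return np.asarray(rows), header


def write_manifest(path, manifest: dict) -> None:
    Path(path).write_text(yaml.safe_dump(manifest, sort_keys=True))


def read_manifest(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
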