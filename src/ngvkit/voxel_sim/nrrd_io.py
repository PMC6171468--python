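"""Minimal NRRD (NRRD0004) writer/reader for scalar volumes.

Supports exactly what the volumetric exporter needs: 3-D or 4-D double
arrays, raw little-endian or ascii-text encodings, space directions and
origin. Axis convention: the first array axis is x and is fastest in the
file (Fortran byte order), matching the sizes field fastest-to-slowest.
"""

from __future__ import annotations

import numpy as np

__all__ = ["write_nrrd", "read_nrrd"]


def write_nrrd(
    path,
    data: np.ndarray,
    spacing: float,
    origin=(0.0, 0.0, 0.0),
    encoding: str = "raw",
) -> None:
    data = np.asarray(data, dtype="<f8")
    if data.ndim not in (3, 4):
        raise ValueError("only 3-D or 4-D volumes are supported")
    if encoding not in ("raw", "text"):
        raise ValueError(f"unsupported encoding {encoding!r}")
    sizes = " ".join(str(s) for s in data.shape)
    if data.ndim == 3:
        dirs = (f"({spacing},0,0) (0,{spacing},0) (0,0,{spacing})")
        kinds = "domain domain domain"
        space = "space: 3D-right-handed\n"
    else:
        # 4th axis: time/list
        dirs = f"({spacing},0,0) (0,{spacing},0) (0,0,{spacing}) none"
        kinds = "domain domain domain list"
        space = "space: 3D-right-handed\n"
    header = (
        "NRRD0004\n"
        "type: double\n"
        f"dimension: {data.ndim}\n"
        f"{space}"
        f"sizes: {sizes}\n"
        f"space directions: {dirs}\n"
        f"kinds: {kinds}\n"
        f"endian: little\n"
        f"encoding: {encoding}\n"
        f"space origin: ({origin[0]},{origin[1]},{origin[2]})\n"
        "\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        flat = data.flatten(order="F")
        if encoding == "raw":
            fh.write(flat.tobytes())
        else:
            fh.write("\n".join(repr(float(v)) for v in flat).encode("ascii"))


def read_nrrd(path) -> tuple[np.ndarray, dict]:
    """Read a volume written by :func:`write_nrrd`. Returns (data, header)."""
    with open(path, "rb") as fh:
        blob = fh.read()
    head, _, body = blob.partition(b"\n\n")
    lines = head.decode("ascii").splitlines()
    if not lines or not lines[0].startswith("NRRD"):
        raise ValueError(f"{path}: not an NRRD file")
    fields: dict[str, str] = {}
    for line in lines[1:]:
        if ":" in line:
            key, _, val = line.partition(":")
            fields[key.strip()] = val.strip()
    if fields.get("type") != "double":
        raise ValueError(f"unsupported NRRD type {fields.get('type')!r}")
    sizes = tuple(int(s) for s in fields["sizes"].split())
    encoding = fields.get("encoding", "raw")
    if encoding == "raw":
        flat = np.frombuffer(body, dtype="<f8", count=int(np.prod(sizes)))
    elif encoding == "text":
        flat = np.array([float(v) for v in body.split()], dtype=float)
    else:
        raise ValueError(f"unsupported encoding {encoding!r}")
    data = flat.reshape(sizes, order="F")
    return data, fields
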