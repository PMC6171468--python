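"""Format readers/writers with strict validation.

Meshes: OBJ (ascii) and PLY (ascii or binary little-endian); the class
label and object id come from a sidecar manifest CSV with columns
``(path, mesh_class, object_id)``. Granules: CSV ``(x, y, z, r,
host_id)``. Events: CSV or JSONL ``(t, x, y, z, q)``. Configs: TOML or
YAML. Readers reject malformed input with row/element-numbered errors;
they never coerce silently.
"""

from __future__ import annotations

import json
import struct
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ..glam_morphometrics.mesh import MESH_CLASSES, GranuleSet, SurfaceMesh
from ..voxel_sim.grid import EventStream

__all__ = [
    "read_mesh", "write_mesh", "read_granules", "write_granules",
    "read_events", "write_events", "read_config", "read_scene",
    "write_scene",
]


# -- meshes -------------------------------------------------------------


def _read_obj(path: Path) -> tuple[np.ndarray, np.ndarray]:
    verts, faces = [], []
    for ln, line in enumerate(path.read_text().splitlines(), 1):
        parts = line.split()
        if not parts or parts[0].startswith("#"):
            continue
        if parts[0] == "v":
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: malformed vertex line")
            verts.append([float(x) for x in parts[1:4]])
        elif parts[0] == "f":
            idx = [int(tok.split("/")[0]) - 1 for tok in parts[1:]]
            if len(idx) != 3:
                raise ValueError(f"{path}:{ln}: only triangle faces supported")
            faces.append(idx)
    return np.asarray(verts, dtype=float), np.asarray(faces, dtype=int)


def _write_obj(path: Path, mesh: SurfaceMesh) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {mesh.name or 'mesh'} class={mesh.mesh_class} id={mesh.object_id}\n")
        for v in mesh.vertices:
            fh.write(f"v {float(v[0])!r} {float(v[1])!r} {float(v[2])!r}\n")
        for f in mesh.triangles:
            fh.write(f"f {f[0]+1} {f[1]+1} {f[2]+1}\n")


def _read_ply(path: Path) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Minimal PLY reader: vertex x/y/z (+ optional float ``quality``),
    triangular faces; ascii or binary_little_endian."""
    with open(path, "rb") as fh:
        blob = fh.read()
    end = blob.find(b"end_header\n")
    if not blob.startswith(b"ply") or end < 0:
        raise ValueError(f"{path}: not a PLY file")
    header = blob[:end].decode("ascii").splitlines()
    body = blob[end + len(b"end_header\n"):]
    fmt = None
    elements: list[tuple[str, int, list[tuple[str, str]]]] = []
    for line in header:
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "format":
            fmt = parts[1]
        elif parts[0] == "element":
            elements.append((parts[1], int(parts[2]), []))
        elif parts[0] == "property":
            if parts[1] == "list":
                elements[-1][2].append((parts[4], f"list:{parts[2]}:{parts[3]}"))
            else:
                elements[-1][2].append((parts[2], parts[1]))
    if fmt not in ("ascii", "binary_little_endian"):
        raise ValueError(f"{path}: unsupported PLY format {fmt!r}")

    sizes = {"float": 4, "float32": 4, "double": 8, "float64": 8,
             "int": 4, "int32": 4, "uint": 4, "uint32": 4,
             "uchar": 1, "uint8": 1, "char": 1, "int8": 1}
    codes = {"float": "f", "float32": "f", "double": "d", "float64": "d",
             "int": "i", "int32": "i", "uint": "I", "uint32": "I",
             "uchar": "B", "uint8": "B", "char": "b", "int8": "b"}
    verts = faces = quality = None
    if fmt == "ascii":
        tokens = body.decode("ascii").split()
        pos = 0
        for ename, count, props in elements:
            if ename == "vertex":
                cols = {p[0]: [] for p in props}
                for _ in range(count):
                    for pname, _t in props:
                        cols[pname].append(float(tokens[pos])); pos += 1
                verts = np.column_stack([cols["x"], cols["y"], cols["z"]])
                if "quality" in cols:
                    quality = np.asarray(cols["quality"])
            elif ename == "face":
                rows = []
                for _ in range(count):
                    k = int(tokens[pos]); pos += 1
                    rows.append([int(tokens[pos + i]) for i in range(k)])
                    pos += k
                    if k != 3:
                        raise ValueError(f"{path}: non-triangle face")
                faces = np.asarray(rows, dtype=int)
    else:
        off = 0
        for ename, count, props in elements:
            if ename == "vertex":
                fmt_str = "<" + "".join(codes[t] for _n, t in props)
                rec = struct.calcsize(fmt_str)
                data = [struct.unpack_from(fmt_str, body, off + i * rec)
                        for i in range(count)]
                off += rec * count
                names = [n for n, _t in props]
                arr = np.asarray(data, dtype=float)
                verts = arr[:, [names.index("x"), names.index("y"), names.index("z")]]
                if "quality" in names:
                    quality = arr[:, names.index("quality")]
            elif ename == "face":
                rows = []
                for _ in range(count):
                    (cname, ctype) = props[0]
                    _, cnt_t, idx_t = ctype.split(":")
                    k = struct.unpack_from("<" + codes[cnt_t], body, off)[0]
                    off += sizes[cnt_t]
                    if k != 3:
                        raise ValueError(f"{path}: non-triangle face")
                    rows.append(struct.unpack_from("<" + codes[idx_t] * 3, body, off))
                    off += sizes[idx_t] * 3
                faces = np.asarray(rows, dtype=int)
    if verts is None or faces is None:
        raise ValueError(f"{path}: PLY missing vertex or face element")
    return verts, faces, quality


def write_mesh(path, mesh: SurfaceMesh, vertex_scalar: np.ndarray | None = None,
               binary: bool = True) -> None:
    """Write OBJ (by extension) or PLY; ``vertex_scalar`` becomes the PLY
    ``quality`` property (binary little-endian is the canonical form)."""
    path = Path(path)
    if path.suffix.lower() == ".obj":
        if vertex_scalar is not None:
            raise ValueError("OBJ cannot carry a vertex scalar; use PLY")
        _write_obj(path, mesh)
        return
    n, m = len(mesh.vertices), len(mesh.triangles)
    has_q = vertex_scalar is not None
    header = ["ply",
              f"format {'binary_little_endian' if binary else 'ascii'} 1.0",
              f"comment class={mesh.mesh_class} id={mesh.object_id}",
              f"element vertex {n}",
              "property double x", "property double y", "property double z"]
    if has_q:
        header.append("property double quality")
    header += [f"element face {m}", "property list uchar int vertex_indices",
               "end_header"]
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            for i in range(n):
                vals = [*mesh.vertices[i]]
                if has_q:
                    vals.append(float(vertex_scalar[i]))
                fh.write(struct.pack("<" + "d" * len(vals), *vals))
            for f in mesh.triangles:
                fh.write(struct.pack("<Biii", 3, int(f[0]), int(f[1]), int(f[2])))
        else:
            lines = []
            for i in range(n):
                vals = [repr(float(c)) for c in mesh.vertices[i]]
                if has_q:
                    vals.append(repr(float(vertex_scalar[i])))
                lines.append(" ".join(vals))
            for f in mesh.triangles:
                lines.append(f"3 {f[0]} {f[1]} {f[2]}")
            fh.write(("\n".join(lines) + "\n").encode("ascii"))


def read_mesh(path, mesh_class: str = "axon", object_id: int = 0,
              name: str = "", validate: bool = True) -> SurfaceMesh:
    """Load and validate one mesh file (units asserted as um)."""
    path = Path(path)
    if path.suffix.lower() == ".obj":
        verts, faces = _read_obj(path)
    elif path.suffix.lower() == ".ply":
        verts, faces, _ = _read_ply(path)
    else:
        raise ValueError(f"{path}: unsupported mesh format {path.suffix!r}")
    mesh = SurfaceMesh(verts, faces, mesh_class=mesh_class,
                       object_id=object_id, name=name or path.stem)
    if validate:
        mesh.validate()
    return mesh


def read_scene(manifest_csv) -> list[SurfaceMesh]:
    """Load all meshes listed in a manifest CSV (path, mesh_class, object_id)."""
    manifest_csv = Path(manifest_csv)
    table = pd.read_csv(manifest_csv)
    required = {"path", "mesh_class", "object_id"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{manifest_csv}: missing column(s) {sorted(missing)}")
    meshes = []
    for i, row in table.iterrows():
        cls = str(row["mesh_class"])
        if cls not in MESH_CLASSES:
            raise ValueError(
                f"{manifest_csv}: row {i}: class {cls!r} not in {MESH_CLASSES}"
            )
        p = manifest_csv.parent / str(row["path"])
        meshes.append(read_mesh(p, cls, int(row["object_id"])))
    return meshes


def write_scene(out_dir, meshes: list[SurfaceMesh], fmt: str = "obj") -> Path:
    """Write meshes plus manifest.csv; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for m in meshes:
        fname = f"{m.name or ('mesh_' + str(m.object_id))}.{fmt}"
        write_mesh(out / fname, m)
        rows.append({"path": fname, "mesh_class": m.mesh_class,
                     "object_id": m.object_id})
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


# -- granules and events -----------------------------------------------


def read_granules(path) -> GranuleSet:
    table = pd.read_csv(path)
    required = {"x", "y", "z", "r"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    r = table["r"].to_numpy(dtype=float)
    bad = np.flatnonzero(~(r > 0))
    if bad.size:
        raise ValueError(f"{path}: row {int(bad[0])}: non-positive radius {r[bad[0]]}")
    hosts = (table["host_id"].to_numpy(dtype=int)
             if "host_id" in table.columns else None)
    return GranuleSet(table[["x", "y", "z"]].to_numpy(dtype=float), r, hosts)


def write_granules(path, granules: GranuleSet) -> None:
    pd.DataFrame({
        "x": granules.centers[:, 0], "y": granules.centers[:, 1],
        "z": granules.centers[:, 2], "r": granules.radii,
        "host_id": granules.host_ids,
    }).to_csv(path, index=False)


def read_events(path) -> EventStream:
    path = Path(path)
    if path.suffix.lower() == ".jsonl":
        rows = []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                try:
                    rows.append(json.loads(line))
                except json.JSONDecodeError as exc:
                    raise ValueError(f"{path}:{ln}: bad JSON: {exc}") from exc
        table = pd.DataFrame(rows)
    else:
        table = pd.read_csv(path)
    missing = set(EventStream.COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    q = table["q"].to_numpy(dtype=float)
    bad = np.flatnonzero(~(q > 0))
    if bad.size:
        raise ValueError(f"{path}: row {int(bad[0])}: non-positive quanta {q[bad[0]]}")
    t = table["t"].to_numpy(dtype=float)
    if t.size > 1 and np.any(np.diff(t) < 0):
        row = int(np.flatnonzero(np.diff(t) < 0)[0]) + 1
        raise ValueError(f"{path}: row {row}: event times not sorted")
    return EventStream(table[list(EventStream.COLUMNS)])


def write_events(path, events: EventStream) -> None:
    path = Path(path)
    if path.suffix.lower() == ".jsonl":
        with open(path, "w") as fh:
            for _, row in events.table.iterrows():
                fh.write(json.dumps({c: float(row[c]) for c in EventStream.COLUMNS}) + "\n")
    else:
        events.table.to_csv(path, index=False)


def read_config(path) -> dict:
    """TOML or YAML config as a plain dict."""
    path = Path(path)
    if path.suffix.lower() == ".toml":
        with open(path, "rb") as fh:
            return tomllib.load(fh)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    return doc
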