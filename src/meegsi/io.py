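"""Readers and writers for the formats the toolkit touches.

Surfaces: OFF, ASCII PLY, FreeSurfer ASCII.  Sensor layouts: SFP/ELC-style
whitespace text (one ``label x y z`` row per sensor, meters; millimeter files
are auto-detected and converted).  Lead fields: HDF5 array + JSON sidecar
carrying the sensor labels, source count, orientation mode and units.
"""

from __future__ import annotations

import json
import logging
import os

import numpy as np

from .forward import LeadField, SensorArray
from .mesh import MeshValidationError, TriMesh

logger = logging.getLogger("meegsi")


class ParseError(ValueError):
    """Malformed file content; the message names the offending line."""


# ---------------------------------------------------------------------------
# surfaces

SURFACE_FORMATS = ("off", "ply", "fs_ascii")


def load_surface(path: str, format: str | None = None) -> TriMesh:
    """Load a triangular surface mesh (OFF, ASCII PLY or FreeSurfer ASCII)."""
    fmt = _infer_format(path) if format is None else format
    if fmt not in SURFACE_FORMATS:
        raise ValueError(f"unknown surface format {fmt!r}")
    with open(path) as fh:
        text = fh.read()
    if fmt == "off":
        return _parse_off(text)
    if fmt == "ply":
        return _parse_ply(text)
    return _parse_fs_ascii(text)


def save_surface(mesh: TriMesh, path: str, format: str | None = None) -> None:
    """Write a mesh; inverse of :func:`load_surface` up to float formatting."""
    if mesh.n_triangles == 0:
        raise MeshValidationError("refusing to write a mesh with no triangles")
    fmt = _infer_format(path) if format is None else format
    if fmt not in SURFACE_FORMATS:
        raise ValueError(f"unknown surface format {fmt!r}")
    v, t = mesh.vertices, mesh.triangles
    lines = []
    if fmt == "off":
        lines.append("OFF")
        lines.append(f"{len(v)} {len(t)} 0")
        lines += [f"{a:.17g} {b:.17g} {c:.17g}" for a, b, c in v]
        lines += [f"3 {a} {b} {c}" for a, b, c in t]
    elif fmt == "ply":
        lines += [
            "ply", "format ascii 1.0", f"element vertex {len(v)}",
            "property double x", "property double y", "property double z",
            f"element face {len(t)}", "property list uchar int vertex_indices",
            "end_header",
        ]
        lines += [f"{a:.17g} {b:.17g} {c:.17g}" for a, b, c in v]
        lines += [f"3 {a} {b} {c}" for a, b, c in t]
    else:  # fs_ascii
        lines.append("#!ascii")
        lines.append(f"{len(v)} {len(t)}")
        lines += [f"{a:.17g} {b:.17g} {c:.17g} 0" for a, b, c in v]
        lines += [f"{a} {b} {c} 0" for a, b, c in t]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _infer_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    return {".off": "off", ".ply": "ply", ".asc": "fs_ascii", ".srf": "fs_ascii"}.get(
        ext, "off"
    )


def _noncomment_lines(text: str, comment: str = "#"):
    for ln, raw in enumerate(text.splitlines(), start=1):
        s = raw.split(comment)[0].strip() if comment else raw.strip()
        if s:
            yield ln, s


def _parse_counted(tokens_iter, n_vertices, n_faces, face_style="counted"):
    """``face_style``: 'counted' rows start with the vertex count (OFF/PLY);
    'fixed' rows are three indices plus a trailing flag (FreeSurfer)."""
    verts, faces = [], []
    for ln, s in tokens_iter:
        parts = s.split()
        if len(verts) < n_vertices:
            if len(parts) < 3:
                raise ParseError(f"line {ln}: expected vertex 'x y z', got {s!r}")
            try:
                verts.append([float(p) for p in parts[:3]])
            except ValueError as exc:
                raise ParseError(f"line {ln}: non-numeric vertex coordinate") from exc
        elif len(faces) < n_faces:
            try:
                vals = [int(float(p)) for p in parts]
            except ValueError as exc:
                raise ParseError(f"line {ln}: non-integer face index") from exc
            if face_style == "counted":
                if len(vals) < 4 or vals[0] != 3:
                    raise ParseError(f"line {ln}: expected triangular face '3 a b c'")
                vals = vals[1:4]
            else:
                if len(vals) < 3:
                    raise ParseError(f"line {ln}: face needs 3 vertex indices")
                vals = vals[:3]
            faces.append(vals)
    if len(verts) != n_vertices or len(faces) != n_faces:
        raise ParseError(
            f"expected {n_vertices} vertices / {n_faces} faces, "
            f"found {len(verts)} / {len(faces)}"
        )
    return TriMesh(np.asarray(verts), np.asarray(faces, dtype=np.int64))


def _parse_off(text: str) -> TriMesh:
    it = _noncomment_lines(text)
    try:
        ln, header = next(it)
    except StopIteration:
        raise ParseError("line 1: empty OFF file")
    if header.upper() != "OFF":
        raise ParseError(f"line {ln}: expected 'OFF' header, got {header!r}")
    try:
        ln, counts = next(it)
        nv, nf = (int(x) for x in counts.split()[:2])
    except (StopIteration, ValueError) as exc:
        raise ParseError("malformed OFF count line") from exc
    return _parse_counted(it, nv, nf)


def _parse_ply(text: str) -> TriMesh:
    lines = text.splitlines()
    if not lines or lines[0].strip() != "ply":
        raise ParseError("line 1: not a PLY file")
    nv = nf = None
    body_start = None
    for i, raw in enumerate(lines[1:], start=2):
        s = raw.strip()
        if s.startswith("format") and "ascii" not in s:
            raise ParseError(f"line {i}: only ascii PLY is supported")
        if s.startswith("element vertex"):
            nv = int(s.split()[-1])
        elif s.startswith("element face"):
            nf = int(s.split()[-1])
        elif s == "end_header":
            body_start = i
            break
    if nv is None or nf is None or body_start is None:
        raise ParseError("malformed PLY header (missing element counts or end_header)")
    it = ((ln, s.strip()) for ln, s in enumerate(lines[body_start:], start=body_start + 1) if s.strip())
    return _parse_counted(it, nv, nf)


def _parse_fs_ascii(text: str) -> TriMesh:
    it = _noncomment_lines(text)
    try:
        ln, counts = next(it)
        nv, nf = (int(x) for x in counts.split()[:2])
    except (StopIteration, ValueError) as exc:
        raise ParseError("malformed FreeSurfer ASCII count line") from exc
    return _parse_counted(it, nv, nf, face_style="fixed")


# ---------------------------------------------------------------------------
# sensor layouts


def load_sensor_layout(path: str, kind: str = "eeg") -> SensorArray:
    """Load an SFP/ELC-style layout: one ``label x y z`` row per sensor.

    Coordinates with any |value| > 1.5 are taken to be millimeters and
    converted to meters with a logged warning.
    """
    labels, pos = [], []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            s = raw.split("#")[0].strip()
            if not s or s.lower().startswith(("numberpositions", "positions", "labels", "units")):
                continue
            parts = s.replace(":", " ").split()
            if len(parts) < 4:
                raise ParseError(f"line {ln}: expected 'label x y z', got {s!r}")
            try:
                xyz = [float(p) for p in parts[1:4]]
            except ValueError as exc:
                raise ParseError(f"line {ln}: non-numeric coordinate in {s!r}") from exc
            labels.append(parts[0])
            pos.append(xyz)
    if not labels:
        raise ParseError("sensor layout file contains no sensor rows")
    if len(set(labels)) != len(labels):
        dup = next(l for l in labels if labels.count(l) > 1)
        raise ParseError(f"duplicate sensor label {dup!r}")
    pos = np.asarray(pos, dtype=np.float64)
    if np.abs(pos).max() > 1.5:
        logger.warning("layout coordinates look like millimeters; converting to meters")
        pos = pos / 1000.0
    return SensorArray(labels=labels, positions=pos, kind=kind)


def save_sensor_layout(sensors: SensorArray, path: str) -> None:
    with open(path, "w") as fh:
        for lab, (x, y, z) in zip(sensors.labels, sensors.positions):
            fh.write(f"{lab} {x:.17g} {y:.17g} {z:.17g}\n")


# ---------------------------------------------------------------------------
# lead fields


def save_leadfield(lf: LeadField, path: str) -> None:
    """Write the lead-field array to HDF5 with a JSON sidecar of metadata."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.create_dataset("leadfield", data=lf.matrix)
    meta = {
        "sensor_labels": list(lf.sensor_labels),
        "n_sources": lf.n_sources,
        "orientation_mode": lf.mode,
        "units": lf.units,
        "reference": lf.reference,
        "provenance": lf.provenance,
    }
    with open(path + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)


def load_leadfield(path: str) -> LeadField:
    """Load a lead field, validating the array against its sidecar."""
    import h5py

    with h5py.File(path, "r") as h5:
        M = np.asarray(h5["leadfield"])
    with open(path + ".json") as fh:
        meta = json.load(fh)
    mode = meta["orientation_mode"]
    cols = M.shape[1]
    if mode == "free":
        if cols % 3 != 0:
            raise ValueError("free orientation mode but columns not divisible by 3")
        n_src = cols // 3
    else:
        n_src = cols
    if n_src != meta["n_sources"]:
        raise ValueError(
            f"sidecar declares {meta['n_sources']} sources but array implies {n_src}"
        )
    if meta["sensor_labels"] and len(meta["sensor_labels"]) != M.shape[0]:
        raise ValueError("sidecar sensor label count does not match array rows")
    return LeadField(
        M, mode=mode, units=meta["units"], reference=meta["reference"],
        provenance=meta["provenance"], sensor_labels=meta["sensor_labels"],
    )


# ---------------------------------------------------------------------------
# cross-spectral tensors


def save_cross_spectrum(tensor, path: str) -> None:
    import h5py

    with h5py.File(path, "w") as h5:
        h5.create_dataset("S", data=tensor.S)
        h5.create_dataset("frequencies", data=tensor.frequencies)
        h5.attrs["m"] = tensor.m
        h5.attrs["labels"] = json.dumps(list(tensor.labels))
        if tensor.band_names:
            h5.attrs["band_names"] = json.dumps(list(tensor.band_names))


def load_cross_spectrum(path: str):
    import h5py

    from .spectral import CrossSpectralTensor

    with h5py.File(path, "r") as h5:
        t = CrossSpectralTensor(
            S=np.asarray(h5["S"]),
            frequencies=np.asarray(h5["frequencies"]),
            m=int(h5.attrs["m"]),
            labels=json.loads(h5.attrs["labels"]),
            band_names=json.loads(h5.attrs["band_names"]) if "band_names" in h5.attrs else None,
        )
    return t
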