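"""File interfaces: VTK XML PolyData (.vtp), CSV and JSON dialects.

Centerlines travel as .vtp polylines with the point-data arrays
"Abscissa" and "MaximumInscribedSphereRadius" (plus any computed
arrays such as "Curvature"/"Torsion"/"FrenetTangent"...), or as plain
CSV with columns x,y,z[,radius].  Velocity point clouds travel as .vtp
point sets with a "Velocity" vector array, or CSV x,y,z,vx,vy,vz.
Aneurysm annotations are JSON with the neck extent along the abscissa
and a direction vector.

The .vtp dialect written here is plain ASCII VTK XML, readable by
ParaView and friends.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd

from .centerline import Centerline

__all__ = [
    "write_centerline_vtp", "read_centerline_vtp",
    "write_centerline_csv", "read_centerline_csv",
    "write_field_vtp", "read_field_vtp",
    "write_field_csv", "read_field_csv",
    "write_annotation", "read_annotation",
]


def _data_array(name: str, data: np.ndarray, components: int = 1) -> ET.Element:
    el = ET.Element("DataArray", {
        "type": "Float64", "Name": name, "format": "ascii",
        "NumberOfComponents": str(components),
    })
    el.text = " ".join(f"{x:.17g}" for x in np.asarray(data, float).ravel())
    return el


def _write_vtp(path, points: np.ndarray, point_data: dict[str, np.ndarray],
               lines: np.ndarray | None) -> None:
    n = len(points)
    root = ET.Element("VTKFile", {"type": "PolyData", "version": "1.0",
                                  "byte_order": "LittleEndian"})
    pd_el = ET.SubElement(root, "PolyData")
    piece = ET.SubElement(pd_el, "Piece", {
        "NumberOfPoints": str(n),
        "NumberOfLines": "1" if lines is not None else "0",
        "NumberOfVerts": "0", "NumberOfStrips": "0", "NumberOfPolys": "0",
    })
    pdata = ET.SubElement(piece, "PointData")
    for name, arr in point_data.items():
        arr = np.asarray(arr, float)
        comp = 1 if arr.ndim == 1 else arr.shape[1]
        pdata.append(_data_array(name, arr, comp))
    pts_el = ET.SubElement(piece, "Points")
    pts_el.append(_data_array("Points", points, 3))
    if lines is not None:
        lines_el = ET.SubElement(piece, "Lines")
        conn = ET.Element("DataArray", {"type": "Int64", "Name": "connectivity",
                                        "format": "ascii"})
        conn.text = " ".join(str(i) for i in lines)
        off = ET.Element("DataArray", {"type": "Int64", "Name": "offsets",
                                       "format": "ascii"})
        off.text = str(len(lines))
        lines_el.append(conn)
        lines_el.append(off)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")


def _read_vtp(path) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    piece = ET.parse(path).getroot().find("./PolyData/Piece")
    if piece is None:
        raise ValueError(f"{path}: not a VTK PolyData file")
    n = int(piece.get("NumberOfPoints"))

    def parse(el: ET.Element) -> np.ndarray:
        comp = int(el.get("NumberOfComponents", "1"))
        arr = np.fromstring(el.text, sep=" ")
        return arr if comp == 1 else arr.reshape(-1, comp)

    pts_el = piece.find("./Points/DataArray")
    points = parse(pts_el).reshape(n, 3)
    data = {}
    for el in piece.findall("./PointData/DataArray"):
        data[el.get("Name")] = parse(el)
    return points, data


# --------------------------------------------------------------------------
# centerlines
# --------------------------------------------------------------------------

def write_centerline_vtp(c: Centerline, path, frames=None) -> None:
    """Write a centerline (and optionally its Frenet arrays) as a .vtp polyline."""
    data: dict[str, np.ndarray] = {"Abscissa": c.abscissa}
    if c.radius is not None:
        data["MaximumInscribedSphereRadius"] = c.radius
    if frames is not None:
        data["Curvature"] = frames.kappa
        data["Torsion"] = np.nan_to_num(frames.tau, nan=0.0)
        data["FrenetTangent"] = frames.t
        data["FrenetNormal"] = np.nan_to_num(frames.n, nan=0.0)
        data["FrenetBinormal"] = np.nan_to_num(frames.b, nan=0.0)
    _write_vtp(path, c.points, data, lines=np.arange(len(c)))


def read_centerline_vtp(path) -> Centerline:
    points, data = _read_vtp(path)
    radius = data.get("MaximumInscribedSphereRadius")
    return Centerline(points, radius=radius)


def write_centerline_csv(c: Centerline, path) -> None:
    df = pd.DataFrame(c.points, columns=["x", "y", "z"])
    if c.radius is not None:
        df["radius"] = c.radius
    df.to_csv(path, index=False)


def read_centerline_csv(path) -> Centerline:
    df = pd.read_csv(path)
    radius = df["radius"].to_numpy() if "radius" in df.columns else None
    return Centerline(df[["x", "y", "z"]].to_numpy(), radius=radius)


# --------------------------------------------------------------------------
# velocity fields
# --------------------------------------------------------------------------

def write_field_vtp(points: np.ndarray, velocities: np.ndarray, path) -> None:
    _write_vtp(path, np.asarray(points, float),
               {"Velocity": np.asarray(velocities, float)}, lines=None)


def read_field_vtp(path) -> tuple[np.ndarray, np.ndarray]:
    points, data = _read_vtp(path)
    if "Velocity" not in data:
        raise ValueError(f"{path}: no Velocity array")
    return points, data["Velocity"].reshape(len(points), 3)


def write_field_csv(points, velocities, path) -> None:
    df = pd.DataFrame(np.hstack([points, velocities]),
                      columns=["x", "y", "z", "vx", "vy", "vz"])
    df.to_csv(path, index=False)


def read_field_csv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df[["x", "y", "z"]].to_numpy(), df[["vx", "vy", "vz"]].to_numpy()


# --------------------------------------------------------------------------
# aneurysm annotations
# --------------------------------------------------------------------------

def write_annotation(neck_start: float, neck_end: float, direction, path) -> None:
    Path(path).write_text(json.dumps({
        "neck_start_abscissa": float(neck_start),
        "neck_end_abscissa": float(neck_end),
        "direction": [float(x) for x in direction],
    }, indent=2))


def read_annotation(path) -> dict:
    d = json.loads(Path(path).read_text())
    for key in ("neck_start_abscissa", "neck_end_abscissa", "direction"):
        if key not in d:
            raise ValueError(f"{path}: missing annotation key {key!r}")
    d["direction"] = np.asarray(d["direction"], float)
    if not d["neck_start_abscissa"] < d["neck_end_abscissa"]:
        raise ValueError("neck interval must have positive extent")
    return d
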