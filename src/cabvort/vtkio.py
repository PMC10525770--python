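"""Write-only exporters for standard visualization formats.

Minimal ASCII VTK XML writers (VTU point clouds, VTP surfaces/polylines)
plus STL via trimesh, so every artifact can be opened in ParaView or any
VTK-based viewer.  Only writing is implemented; pipeline stages exchange
in-memory objects (or ``.npz`` archives), never VTK files.
"""

from __future__ import annotations

import numpy as np

__all__ = ["write_vtu_points", "write_vtp_mesh", "write_vtp_polyline",
           "write_stl", "write_series_npz"]


def _ascii(a: np.ndarray) -> str:
    return " ".join(f"{x:.10g}" for x in np.asarray(a).ravel())


def _data_arrays(data: dict | None) -> str:
    if not data:
        return ""
    chunks = []
    for name, arr in data.items():
        arr = np.asarray(arr, dtype=float)
        ncomp = 1 if arr.ndim == 1 else arr.shape[1]
        chunks.append(
            f'    <DataArray type="Float64" Name="{name}" '
            f'NumberOfComponents="{ncomp}" format="ascii">\n'
            f"      {_ascii(arr)}\n    </DataArray>")
    return "\n".join(chunks)


def write_vtu_points(path, points: np.ndarray, point_data: dict | None = None) -> None:
    """Point cloud as a VTU of vertex cells with the given point arrays."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    conn = _ascii(np.arange(n))
    offs = _ascii(np.arange(1, n + 1))
    types = " ".join(["1"] * n)
    with open(path, "w") as fh:
        fh.write(
            '<VTKFile type="UnstructuredGrid" version="0.1" '
            'byte_order="LittleEndian">\n <UnstructuredGrid>\n'
            f'  <Piece NumberOfPoints="{n}" NumberOfCells="{n}">\n'
            '   <Points>\n    <DataArray type="Float64" NumberOfComponents="3" '
            f'format="ascii">\n      {_ascii(points)}\n    </DataArray>\n'
            '   </Points>\n   <PointData>\n'
            f"{_data_arrays(point_data)}\n"
            '   </PointData>\n   <Cells>\n'
            f'    <DataArray type="Int64" Name="connectivity" format="ascii">'
            f"{conn}</DataArray>\n"
            f'    <DataArray type="Int64" Name="offsets" format="ascii">'
            f"{offs}</DataArray>\n"
            f'    <DataArray type="UInt8" Name="types" format="ascii">'
            f"{types}</DataArray>\n"
            "   </Cells>\n  </Piece>\n </UnstructuredGrid>\n</VTKFile>\n")


def write_vtp_mesh(path, vertices: np.ndarray, faces: np.ndarray,
                   point_data: dict | None = None,
                   cell_data: dict | None = None) -> None:
    """Triangulated surface as VTP PolyData."""
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=int)
    n, m = len(vertices), len(faces)
    with open(path, "w") as fh:
        fh.write(
            '<VTKFile type="PolyData" version="0.1" byte_order="LittleEndian">\n'
            ' <PolyData>\n'
            f'  <Piece NumberOfPoints="{n}" NumberOfPolys="{m}">\n'
            '   <Points>\n    <DataArray type="Float64" NumberOfComponents="3" '
            f'format="ascii">\n      {_ascii(vertices)}\n    </DataArray>\n'
            '   </Points>\n   <PointData>\n'
            f"{_data_arrays(point_data)}\n   </PointData>\n   <CellData>\n"
            f"{_data_arrays(cell_data)}\n   </CellData>\n   <Polys>\n"
            f'    <DataArray type="Int64" Name="connectivity" format="ascii">'
            f"{_ascii(faces)}</DataArray>\n"
            f'    <DataArray type="Int64" Name="offsets" format="ascii">'
            f"{_ascii(3 * np.arange(1, m + 1))}</DataArray>\n"
            "   </Polys>\n  </Piece>\n </PolyData>\n</VTKFile>\n")


def write_vtp_polyline(path, points: np.ndarray,
                       point_data: dict | None = None) -> None:
    """Open polyline (e.g. a centerline) as VTP PolyData."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    with open(path, "w") as fh:
        fh.write(
            '<VTKFile type="PolyData" version="0.1" byte_order="LittleEndian">\n'
            ' <PolyData>\n'
            f'  <Piece NumberOfPoints="{n}" NumberOfLines="1">\n'
            '   <Points>\n    <DataArray type="Float64" NumberOfComponents="3" '
            f'format="ascii">\n      {_ascii(points)}\n    </DataArray>\n'
            '   </Points>\n   <PointData>\n'
            f"{_data_arrays(point_data)}\n   </PointData>\n   <Lines>\n"
            f'    <DataArray type="Int64" Name="connectivity" format="ascii">'
            f"{_ascii(np.arange(n))}</DataArray>\n"
            f'    <DataArray type="Int64" Name="offsets" format="ascii">'
            f"{n}</DataArray>\n"
            "   </Lines>\n  </Piece>\n </PolyData>\n</VTKFile>\n")


def write_stl(path, mesh) -> None:
    """ASCII STL export of a trimesh surface."""
    from trimesh.exchange.stl import export_stl_ascii

    with open(path, "w") as fh:
        fh.write(export_stl_ascii(mesh))


def write_series_npz(path, series) -> None:
    """Compact archive of a FlowSeries (points + per-snapshot fields)."""
    first = series[0]
    np.savez_compressed(
        path, points=first.points,
        velocity=np.stack([s.velocity for s in series]),
        pressure=np.stack([s.pressure for s in series]),
        times=np.array([s.t for s in series]), period=first.period)
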