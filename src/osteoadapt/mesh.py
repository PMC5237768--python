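"""2D quadrilateral domains for bone-adaptation simulations.

Generates labeled structured-quad meshes (proximal-femur-like domain, rat
metaphysis, rectangular test plates), manages region / boundary sets, and
reads and writes meshes and per-element field snapshots (CSV tables and
ASCII VTU for visualization).

Coordinates are stored in cm.  Element areas are in cm²; with the configured
unit out-of-plane thickness they double as element volumes.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon, box
from shapely.ops import unary_union

from .config import FemurGeometry, RatGeometry, RemodelConfig

__all__ = [
    "Mesh",
    "generate_plate_fixture",
    "generate_femur_domain",
    "generate_rat_domain",
    "write_mesh",
    "read_mesh",
    "write_fields",
    "read_fields",
    "write_vtu",
    "read_vtu",
]


@dataclass
class Mesh:
    """A 2D mesh of 4-node quadrilaterals with named node and element sets.

    ``nodes`` is (n_nodes, 2) in cm; ``elements`` is (n_elements, 4) integer
    connectivity, counter-clockwise.  ``element_sets`` label regions
    (cortical / cancellous / defect, …) and must partition the element list;
    ``node_sets`` name boundary groups used for supports and loads.
    """

    nodes: np.ndarray
    elements: np.ndarray
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    element_sets: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 2:
            raise ValueError("nodes must be (n, 2)")
        if self.elements.ndim != 2 or self.elements.shape[1] != 4:
            raise ValueError("elements must be (m, 4)")
        if self.elements.size and (
            self.elements.min() < 0 or self.elements.max() >= len(self.nodes)
        ):
            raise ValueError("element connectivity references missing nodes")
        for row in self.elements:
            if len(set(row.tolist())) != 4:
                raise ValueError(f"element with repeated nodes: {row.tolist()}")
        self.node_sets = {k: np.asarray(v, dtype=np.int64) for k, v in self.node_sets.items()}
        self.element_sets = {
            k: np.asarray(v, dtype=np.int64) for k, v in self.element_sets.items()
        }

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def element_coords(self) -> np.ndarray:
        """(m, 4, 2) corner coordinates per element, cm."""
        return self.nodes[self.elements]

    @property
    def element_area(self) -> np.ndarray:
        """Per-element area (cm²) by the shoelace formula; positive for CCW quads."""
        xy = self.element_coords
        x, y = xy[..., 0], xy[..., 1]
        xr, yr = np.roll(x, -1, axis=1), np.roll(y, -1, axis=1)
        return 0.5 * np.sum(x * yr - xr * y, axis=1)

    @property
    def element_centroid(self) -> np.ndarray:
        return self.element_coords.mean(axis=1)

    def element_region(self) -> np.ndarray:
        """Region label per element; raises if the sets do not partition the mesh."""
        labels = np.full(self.n_elements, "", dtype=object)
        for name, idx in self.element_sets.items():
            if np.any(labels[idx] != ""):
                clash = idx[labels[idx] != ""][0]
                raise ValueError(f"element {clash} labeled twice (set {name!r})")
            labels[idx] = name
        if np.any(labels == ""):
            raise ValueError(f"unlabeled elements: {np.flatnonzero(labels == '')[:5]}")
        return labels.astype(str)


# ---------------------------------------------------------------------------
# structured grid helpers

def _structured_quads(nx: int, ny: int, h: float, origin=(0.0, 0.0)):
    """Node array and CCW quad connectivity of an nx×ny grid of h×h cells."""
    x0, y0 = origin
    xs = x0 + h * np.arange(nx + 1)
    ys = y0 + h * np.arange(ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="xy")
    nodes = np.column_stack([X.ravel(), Y.ravel()])

    def nid(i, j):  # column i, row j
        return j * (nx + 1) + i

    elems = np.empty((nx * ny, 4), dtype=np.int64)
    k = 0
    for j in range(ny):
        for i in range(nx):
            elems[k] = (nid(i, j), nid(i + 1, j), nid(i + 1, j + 1), nid(i, j + 1))
            k += 1
    return nodes, elems


def _mask_grid(nodes, elems, keep: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Drop masked-out cells and orphan nodes; return (nodes, elems, old->new elem index)."""
    elems = elems[keep]
    used = np.unique(elems)
    remap = -np.ones(len(nodes), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return nodes[used], remap[elems], used


def generate_plate_fixture(nx: int, ny: int, h: float = 1.0) -> Mesh:
    """Rectangular nx×ny structured plate with fixed left edge and loaded right edge.

    The workhorse unit-test fixture: (nx, ny) cells of size ``h`` cm, node set
    ``fixed`` on the left edge and ``tip`` on the right edge, and a single
    element set ``cancellous`` covering the plate.
    """
    if nx < 1 or ny < 1:
        raise ValueError(f"grid counts must be >= 1, got ({nx}, {ny})")
    nodes, elems = _structured_quads(nx, ny, h)
    left = np.flatnonzero(np.isclose(nodes[:, 0], 0.0))
    right = np.flatnonzero(np.isclose(nodes[:, 0], nx * h))
    return Mesh(
        nodes,
        elems,
        node_sets={"fixed": left, "tip": right},
        element_sets={"cancellous": np.arange(nx * ny)},
    )


# ---------------------------------------------------------------------------
# femur-like domain

def _femur_outline(geo: FemurGeometry) -> Polygon:
    shaft = box(geo.shaft_x[0], 0.0, geo.shaft_x[1], geo.shaft_top)
    head = Point(*geo.head_center).buffer(geo.head_radius, quad_segs=64)
    from shapely.geometry import LineString

    neck = LineString([geo.head_center, geo.neck_base]).buffer(
        geo.neck_width / 2.0, quad_segs=32
    )
    troch = Point(*geo.trochanter_center).buffer(geo.trochanter_radius, quad_segs=64)
    troch_join = LineString(
        [geo.trochanter_center, (geo.trochanter_center[0] - 1.5, geo.shaft_top - 2.0)]
    ).buffer(geo.trochanter_radius * 0.8, quad_segs=32)
    return unary_union([shaft, head, neck, troch, troch_join])


def generate_femur_domain(config: RemodelConfig) -> Mesh:
    """Labeled proximal-femur-like mesh: cortical shell, cancellous interior,
    distal fixed edge, femoral-head and trochanter load node sets, and (when
    enabled) a square defect block rooted in the lateral shaft cortex.

    The defect is a ``defect_nx × defect_ny`` block of elements (36 by
    default) spanning both cortical and cancellous bone, emulating a drilled
    lateral defect.
    """
    geo = config.femur
    h = geo.element_size
    outline = _femur_outline(geo)
    minx, miny, maxx, maxy = outline.bounds
    # snap grid to the shaft so the lateral cortex is a clean element column
    x0 = geo.shaft_x[0] - h * np.ceil((geo.shaft_x[0] - minx) / h)
    y0 = 0.0
    nx = int(np.ceil((maxx - x0) / h))
    ny = int(np.ceil((maxy - y0) / h))
    nodes, elems = _structured_quads(nx, ny, h, origin=(x0, y0))
    cent = nodes[elems].mean(axis=1)
    inside = np.array([outline.contains(Point(p)) for p in cent])
    nodes, elems, _ = _mask_grid(nodes, elems, inside)
    mesh_cent = nodes[elems].mean(axis=1)

    # region labels: cortical shell = within cortical_thickness of the outline
    boundary = outline.exterior
    dist = np.array([boundary.distance(Point(p)) for p in mesh_cent])
    cortical = dist <= geo.cortical_thickness

    n_elem = len(elems)
    defect = np.zeros(n_elem, dtype=bool)
    if geo.defect_enabled and geo.defect_nx > 0 and geo.defect_ny > 0:
        # block flush with the lateral shaft cortex unless defect_x0 is given
        x_lo = geo.shaft_x[1] - geo.defect_nx * h if geo.defect_x0 is None else geo.defect_x0
        x_hi = x_lo + geo.defect_nx * h
        y_lo = geo.defect_y0
        y_hi = y_lo + geo.defect_ny * h
        if geo.defect_x0 is None and not (
            x_lo >= geo.shaft_x[0] and 0.0 <= y_lo and y_hi <= geo.shaft_top
        ):
            raise ValueError(
                "defect block "
                f"[{x_lo}, {x_hi}] x [{y_lo}, {y_hi}] cm falls outside the shaft "
                f"[{geo.shaft_x[0]}, {geo.shaft_x[1]}] x [0, {geo.shaft_top}] cm"
            )
        defect = (
            (mesh_cent[:, 0] > x_lo) & (mesh_cent[:, 0] < x_hi)
            & (mesh_cent[:, 1] > y_lo) & (mesh_cent[:, 1] < y_hi)
        )
        expect = geo.defect_nx * geo.defect_ny
        if defect.sum() != expect:
            raise ValueError(
                f"defect block covers {int(defect.sum())} elements, expected {expect}; "
                "the block must lie fully inside the meshed domain"
            )

    element_sets = {
        "cortical": np.flatnonzero(cortical & ~defect),
        "cancellous": np.flatnonzero(~cortical & ~defect),
        "defect": np.flatnonzero(defect),
    }

    # node sets: distal fixed edge, femoral-head crown, trochanter crown
    fixed = np.flatnonzero(np.isclose(nodes[:, 1], 0.0))
    hc = np.asarray(geo.head_center)
    r = np.linalg.norm(nodes - hc, axis=1)
    on_head = (np.abs(r - geo.head_radius) <= 0.75 * h) & (nodes[:, 1] > hc[1] + 0.5 * geo.head_radius)
    head = np.flatnonzero(on_head)
    tc = np.asarray(geo.trochanter_center)
    rt = np.linalg.norm(nodes - tc, axis=1)
    on_troch = (np.abs(rt - geo.trochanter_radius) <= 0.75 * h) & (
        nodes[:, 1] > tc[1] + 0.4 * geo.trochanter_radius
    )
    troch = np.flatnonzero(on_troch)
    if len(fixed) < 2 or len(head) == 0 or len(troch) == 0:
        raise ValueError("femur outline produced empty support or load node sets")

    return Mesh(
        nodes,
        elems,
        node_sets={"fixed": fixed, "head": head, "trochanter": troch},
        element_sets=element_sets,
    )


# ---------------------------------------------------------------------------
# rat metaphysis

def generate_rat_domain(config: RemodelConfig) -> Mesh:
    """Labeled rat distal-femur metaphysis cross-section.

    A ``width × height`` rectangle with medial and lateral cortical walls,
    split into a stiff diaphyseal (lower) and softer metaphyseal (upper)
    segment, a cancellous core, and a ``defect_size``-square defect drilled
    through the lateral cortex.  The top edge carries the ``joint`` load node
    set; the bottom edge is the ``fixed`` set.
    """
    geo = config.rat
    h = geo.element_size
    nx = int(round(geo.width / h))
    ny = int(round(geo.height / h))
    nodes, elems = _structured_quads(nx, ny, h)
    cent = nodes[elems].mean(axis=1)

    lateral_wall = cent[:, 0] > geo.width - geo.cortical_thickness
    medial_wall = cent[:, 0] < geo.cortical_thickness
    cortex = lateral_wall | medial_wall
    metaphyseal = cent[:, 1] > geo.height * (1.0 - geo.metaphyseal_fraction)

    defect = np.zeros(len(elems), dtype=bool)
    if geo.defect_enabled:
        x_hi, x_lo = geo.width, geo.width - geo.defect_size
        y_lo, y_hi = geo.defect_y0, geo.defect_y0 + geo.defect_size
        if x_lo < 0 or y_hi > geo.height:
            raise ValueError(
                f"defect [{x_lo}, {x_hi}] x [{y_lo}, {y_hi}] cm exceeds the "
                f"metaphysis {geo.width} x {geo.height} cm"
            )
        defect = (
            (cent[:, 0] > x_lo) & (cent[:, 0] < x_hi)
            & (cent[:, 1] > y_lo) & (cent[:, 1] < y_hi)
        )

    element_sets = {
        "cortical_diaphyseal": np.flatnonzero(cortex & ~metaphyseal & ~defect),
        "cortical_metaphyseal": np.flatnonzero(cortex & metaphyseal & ~defect),
        "cancellous": np.flatnonzero(~cortex & ~defect),
        "defect": np.flatnonzero(defect),
    }
    fixed = np.flatnonzero(np.isclose(nodes[:, 1], 0.0))
    joint = np.flatnonzero(np.isclose(nodes[:, 1], geo.height))
    return Mesh(
        nodes,
        elems,
        node_sets={"fixed": fixed, "joint": joint},
        element_sets=element_sets,
    )


# ---------------------------------------------------------------------------
# mesh IO: CSV node/element tables plus a JSON named-sets sidecar

def write_mesh(mesh: Mesh, path: str | Path) -> list[Path]:
    """Write a mesh as ``nodes.csv`` + ``elements.csv`` + ``sets.json``."""
    import json

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    nodes = pd.DataFrame(mesh.nodes, columns=["x_cm", "y_cm"])
    nodes.insert(0, "node_id", np.arange(mesh.n_nodes))
    elems = pd.DataFrame(mesh.elements, columns=["n0", "n1", "n2", "n3"])
    elems.insert(0, "element_id", np.arange(mesh.n_elements))
    files = [path / "nodes.csv", path / "elements.csv", path / "sets.json"]
    nodes.to_csv(files[0], index=False, float_format="%.17g")
    elems.to_csv(files[1], index=False)
    sets = {
        "node_sets": {k: v.tolist() for k, v in mesh.node_sets.items()},
        "element_sets": {k: v.tolist() for k, v in mesh.element_sets.items()},
    }
    files[2].write_text(json.dumps(sets, indent=1))
    return files


def read_mesh(path: str | Path) -> Mesh:
    """Read a mesh written by :func:`write_mesh`."""
    import json

    path = Path(path)
    nodes = pd.read_csv(path / "nodes.csv", float_precision="round_trip")
    elems = pd.read_csv(path / "elements.csv")
    sets = json.loads((path / "sets.json").read_text())
    return Mesh(
        nodes[["x_cm", "y_cm"]].to_numpy(),
        elems[["n0", "n1", "n2", "n3"]].to_numpy(),
        node_sets={k: np.asarray(v) for k, v in sets["node_sets"].items()},
        element_sets={k: np.asarray(v) for k, v in sets["element_sets"].items()},
    )


# ---------------------------------------------------------------------------
# field / snapshot IO

def write_fields(mesh: Mesh, trace, path: str | Path, fmt: str = "both") -> list[Path]:
    """Write a simulation trace as a tidy per-day per-element CSV and/or a VTU series.

    CSV columns: ``day, element_id, density, remaining_implant_modulus,
    osteo_score``.  The VTU series stores one file per day with the density
    and score fields as cell data.  Returns the list of written files.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    days = trace.days
    fields = trace.density_fields
    if len(days) != len(fields):
        raise ValueError(f"{len(days)} days but {len(fields)} density fields")
    for f in fields:
        if len(f) != mesh.n_elements:
            raise ValueError(
                f"density field of length {len(f)} does not match "
                f"{mesh.n_elements} mesh elements"
            )
    written: list[Path] = []
    if fmt in ("csv", "both"):
        rows = []
        for day, rho in zip(days, fields):
            m = trace.metrics.loc[trace.metrics["day"] == day].iloc[0]
            rows.append(
                pd.DataFrame(
                    {
                        "day": day,
                        "element_id": np.arange(mesh.n_elements),
                        "density": rho,
                        "remaining_implant_modulus": m["remaining_implant_modulus"],
                        "osteo_score": m["osteo_score"],
                    }
                )
            )
        out = path / "fields.csv"
        pd.concat(rows, ignore_index=True).to_csv(out, index=False, float_format="%.17g")
        written.append(out)
        mout = path / "metrics.csv"
        trace.metrics.to_csv(mout, index=False, float_format="%.17g")
        written.append(mout)
    if fmt in ("vtu", "both"):
        for day, rho in zip(days, fields):
            out = path / f"fields_day{day:04d}.vtu"
            write_vtu(mesh, {"density": np.asarray(rho, dtype=float)}, out)
            written.append(out)
    return written


def read_fields(path: str | Path) -> pd.DataFrame:
    """Read back a ``fields.csv`` written by :func:`write_fields`, bit-exactly."""
    return pd.read_csv(Path(path) / "fields.csv", float_precision="round_trip")


def write_vtu(mesh: Mesh, cell_data: dict[str, np.ndarray], path: str | Path) -> Path:
    """Write the mesh plus per-element scalar fields as an ASCII VTK unstructured grid.

    Emits the standard ``.vtu`` XML dialect (UnstructuredGrid, quad cell type 9)
    readable by ParaView / VTK.
    """
    path = Path(path)
    n, m = mesh.n_nodes, mesh.n_elements
    for name, arr in cell_data.items():
        if len(arr) != m:
            raise ValueError(f"cell array {name!r} has {len(arr)} values, mesh has {m} cells")
    pts = " ".join(f"{x:.17g} {y:.17g} 0" for x, y in mesh.nodes)
    conn = " ".join(" ".join(str(i) for i in el) for el in mesh.elements)
    offs = " ".join(str(4 * (k + 1)) for k in range(m))
    types = " ".join("9" for _ in range(m))
    arrays = "\n".join(
        f'        <DataArray type="Float64" Name="{name}" format="ascii">'
        + " ".join(f"{v:.17g}" for v in arr)
        + "</DataArray>"
        for name, arr in cell_data.items()
    )
    xml = f"""<?xml version="1.0"?>
<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">
  <UnstructuredGrid>
    <Piece NumberOfPoints="{n}" NumberOfCells="{m}">
      <Points>
        <DataArray type="Float64" NumberOfComponents="3" format="ascii">{pts}</DataArray>
      </Points>
      <Cells>
        <DataArray type="Int64" Name="connectivity" format="ascii">{conn}</DataArray>
        <DataArray type="Int64" Name="offsets" format="ascii">{offs}</DataArray>
        <DataArray type="UInt8" Name="types" format="ascii">{types}</DataArray>
      </Cells>
      <CellData>
{arrays}
      </CellData>
    </Piece>
  </UnstructuredGrid>
</VTKFile>
"""
    path.write_text(xml)
    return path


def read_vtu(path: str | Path) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Minimal VTU reader for files written by :func:`write_vtu` (round-trip checks)."""
    root = ET.parse(Path(path)).getroot()
    piece = root.find("./UnstructuredGrid/Piece")
    pts = np.fromstring(piece.find("./Points/DataArray").text, sep=" ").reshape(-1, 3)
    arrays = {da.get("Name"): da for da in piece.findall("./Cells/DataArray")}
    conn = np.fromstring(arrays["connectivity"].text, sep=" ", dtype=np.int64)
    cells = conn.reshape(-1, 4)
    cell_data = {
        da.get("Name"): np.fromstring(da.text, sep=" ")
        for da in piece.findall("./CellData/DataArray")
    }
    return pts[:, :2], cells, cell_data
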