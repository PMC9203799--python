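"""Labeled simplicial meshes of head tissue and their conductivity fields.

The idealized 2D geometry is a 60 mm x 40 mm slice stacked, from the top,
as scalp / skull / CSF / grey matter (each 4 mm) with white matter filling
the remainder.  A central square of grey matter is labeled unstable
(seizure-like cell model); the white matter is split at the vertical midline
into a left half with vertically oriented fibre anisotropy and a right half
with horizontal orientation.

Coordinates are stored internally in cm so that conductivities in mS/cm,
capacitance in uF/cm^2, potentials in mV and time in ms are mutually
consistent; lengths at the public interface are accepted in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import itertools

import numpy as np

__all__ = [
    "GM_STABLE", "GM_UNSTABLE", "WM", "WM_LEFT", "WM_RIGHT",
    "CSF", "SKULL", "SCALP",
    "ALL_LABELS", "GM_LABELS", "WM_LABELS", "PASSIVE_LABELS",
    "MM_PER_CM", "DEFAULT_CONDUCTIVITY_TABLE",
    "LabeledMesh", "AnisotropySpec", "ConductivityMap",
    "build_idealized_slice", "wm_anisotropy_tensor", "build_conductivity_map",
    "default_probe_points", "gm_probe_at",
    "read_labeled_mesh", "write_labeled_mesh", "locate_points",
    "cell_volumes",
]

GM_STABLE = "GM_STABLE"
GM_UNSTABLE = "GM_UNSTABLE"
WM = "WM"
WM_LEFT = "WM_LEFT"
WM_RIGHT = "WM_RIGHT"
CSF = "CSF"
SKULL = "SKULL"
SCALP = "SCALP"

ALL_LABELS = (GM_STABLE, GM_UNSTABLE, WM_LEFT, WM_RIGHT, WM, CSF, SKULL, SCALP)
GM_LABELS = frozenset({GM_STABLE, GM_UNSTABLE})
WM_LABELS = frozenset({WM, WM_LEFT, WM_RIGHT})
PASSIVE_LABELS = frozenset({CSF, SKULL, SCALP})

MM_PER_CM = 10.0

# Physical conductivities in mS/cm: {label: (intracellular, extracellular)}.
# Grey/white matter values follow the active-tissue literature; CSF, skull and
# scalp are passive volume-conductor values, with the intracellular
# conductivity four orders of magnitude below active tissue.
DEFAULT_CONDUCTIVITY_TABLE: dict[str, tuple[float, float]] = {
    GM_STABLE: (1.0, 2.78),
    GM_UNSTABLE: (1.0, 2.78),
    WM: (1.0, 1.26),
    WM_LEFT: (1.0, 1.26),
    WM_RIGHT: (1.0, 1.26),
    CSF: (1e-4, 17.0),
    SKULL: (1e-4, 0.1),
    SCALP: (1e-4, 4.3),
}


class MeshValidationError(ValueError):
    pass


class MeshFormatError(ValueError):
    pass


@dataclass
class LabeledMesh:
    """Conforming simplicial mesh with one tissue label per cell.

    vertices: (n_vertices, dim) coordinates in cm.
    cells: (n_cells, dim+1) vertex indices.
    cell_labels: (n_cells,) tissue label strings.
    probe_points: (n_probes, dim) coordinates in cm.
    metadata: layout information (layer spans etc.) for generated geometries.
    """

    vertices: np.ndarray
    cells: np.ndarray
    cell_labels: np.ndarray
    probe_points: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.cells = np.asarray(self.cells, dtype=np.int64)
        self.cell_labels = np.asarray(self.cell_labels, dtype="U12")
        if self.vertices.ndim != 2 or self.vertices.shape[1] not in (2, 3):
            raise MeshValidationError("vertices must be (n, 2) or (n, 3)")
        dim = self.vertices.shape[1]
        if self.cells.ndim != 2 or self.cells.shape[1] != dim + 1:
            raise MeshValidationError(f"cells must have {dim + 1} vertices each")
        if len(self.cell_labels) != len(self.cells):
            raise MeshValidationError("one label per cell required")
        unknown = set(np.unique(self.cell_labels)) - set(ALL_LABELS)
        if unknown:
            raise MeshValidationError(f"unknown tissue labels: {sorted(unknown)}")
        if self.cells.min(initial=0) < 0 or self.cells.max(initial=-1) >= len(self.vertices):
            raise MeshValidationError("cell vertex index out of range")
        if self.probe_points is not None:
            self.probe_points = np.atleast_2d(np.asarray(self.probe_points, float))

    @property
    def dimension(self) -> int:
        return self.vertices.shape[1]

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def cell_centroids(self) -> np.ndarray:
        return self.vertices[self.cells].mean(axis=1)

    def validate_conforming(self, tol: float = 1e-12) -> None:
        """Check vertex uniqueness and facet sharing (at most two cells/facet)."""
        rounded = np.round(self.vertices / max(tol, 1e-300))
        _, counts = np.unique(rounded, axis=0, return_counts=True)
        if np.any(counts > 1):
            raise MeshValidationError("coincident duplicate vertices (non-conforming)")
        facet_counts: dict[tuple, int] = {}
        k = self.cells.shape[1]
        for cell in self.cells:
            for f in itertools.combinations(sorted(cell), k - 1):
                facet_counts[f] = facet_counts.get(f, 0) + 1
        if any(c > 2 for c in facet_counts.values()):
            raise MeshValidationError("facet shared by more than two cells")


def cell_volumes(mesh: LabeledMesh) -> np.ndarray:
    """Areas (2D) or volumes (3D) of all cells, in cm^dim."""
    pts = mesh.vertices[mesh.cells]
    d = mesh.dimension
    edges = pts[:, 1:, :] - pts[:, :1, :]
    if d == 2:
        return 0.5 * np.abs(np.linalg.det(edges))
    return np.abs(np.linalg.det(edges)) / 6.0


@dataclass
class AnisotropySpec:
    """Transversely isotropic conductivity: sigma_l along `orientation`,
    sigma_t across it (both mS/cm)."""

    sigma_l: float = 1.0
    sigma_t: float = 0.1
    orientation: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0]))

    def __post_init__(self) -> None:
        if self.sigma_l <= 0 or self.sigma_t <= 0:
            raise MeshValidationError("conductivities must be positive")
        self.orientation = np.asarray(self.orientation, dtype=float)
        norm = np.linalg.norm(self.orientation)
        if norm == 0:
            raise MeshValidationError("orientation vector must be nonzero")
        self.orientation = self.orientation / norm


def wm_anisotropy_tensor(spec: AnisotropySpec) -> np.ndarray:
    """Symmetric conductivity tensor sigma_l u u^T + sigma_t (I - u u^T).

    For a vertical unit orientation in 2D this is diag(sigma_t, sigma_l);
    eigenvalues are always {sigma_l, sigma_t (multiplicity dim-1)}.
    """
    u = spec.orientation
    eye = np.eye(len(u))
    return spec.sigma_l * np.outer(u, u) + spec.sigma_t * (eye - np.outer(u, u))


@dataclass
class ConductivityMap:
    """Per-cell symmetric intracellular (Mi) and extracellular (Me)
    conductivity tensors, mS/cm; shape (n_cells, dim, dim)."""

    Mi: np.ndarray
    Me: np.ndarray

    def __post_init__(self) -> None:
        self.Mi = np.asarray(self.Mi, float)
        self.Me = np.asarray(self.Me, float)
        if self.Mi.shape != self.Me.shape or self.Mi.ndim != 3:
            raise MeshValidationError("Mi and Me must be (n_cells, dim, dim)")
        for name, M in (("Mi", self.Mi), ("Me", self.Me)):
            if not np.allclose(M, np.swapaxes(M, 1, 2), atol=1e-12):
                raise MeshValidationError(f"{name} tensors must be symmetric")
            eigs = np.linalg.eigvalsh(M)
            if np.any(eigs <= 0):
                bad = int(np.argmax(np.any(eigs <= 0, axis=1)))
                raise MeshValidationError(
                    f"{name} not positive definite at cell {bad}"
                )


def _row_heights(total_mm: float, target_mm: float) -> np.ndarray:
    n = max(1, round(total_mm / target_mm))
    return np.full(n, total_mm / n)


def build_idealized_slice(
    width_mm: float = 60.0,
    height_mm: float = 40.0,
    layer_mm: float = 4.0,
    cells_across_gm: int = 5,
    unstable_width_mm: float = 4.0,
    wm_resolution_matches_gm: bool = False,
    passive_coarsening: float = 2.5,
    horizontal_coarsening: float = 1.0,
) -> LabeledMesh:
    """Triangulated head-slice rectangle with horizontal tissue layers.

    From the top: SCALP, SKULL, CSF, GM (each `layer_mm` thick) and WM filling
    the rest.  The GM layer is resolved with `cells_across_gm` element rows;
    CSF/skull/scalp (and WM, unless `wm_resolution_matches_gm`) use a target
    edge length `passive_coarsening` times coarser.  A central GM band of
    width `unstable_width_mm` is labeled GM_UNSTABLE; WM is split at the
    vertical midline into WM_LEFT / WM_RIGHT.
    """
    if width_mm <= 0 or height_mm <= 0 or layer_mm <= 0:
        raise MeshValidationError("dimensions must be positive")
    if 4.0 * layer_mm > height_mm:
        raise MeshValidationError("layer thicknesses exceed the slice height")
    if cells_across_gm < 1:
        raise MeshValidationError("cells_across_gm must be >= 1")
    if not 0.0 <= unstable_width_mm <= width_mm:
        raise MeshValidationError("unstable_width_mm outside [0, width]")

    gm_dy = layer_mm / cells_across_gm
    wm_mm = height_mm - 4.0 * layer_mm
    wm_target = gm_dy if wm_resolution_matches_gm else passive_coarsening * gm_dy
    passive_target = passive_coarsening * gm_dy

    # rows from the bottom: WM (may be absent), GM, CSF, SKULL, SCALP
    layer_rows = [
        (_row_heights(wm_mm, wm_target) if wm_mm > 0 else np.empty(0), "WM"),
        (np.full(cells_across_gm, gm_dy), "GM"),
        (_row_heights(layer_mm, passive_target), CSF),
        (_row_heights(layer_mm, passive_target), SKULL),
        (_row_heights(layer_mm, passive_target), SCALP),
    ]
    y_edges = [0.0]
    row_layer: list[str] = []
    for heights, name in layer_rows:
        for h in heights:
            y_edges.append(y_edges[-1] + h)
            row_layer.append(name)
    y_edges = np.asarray(y_edges)
    y_edges[-1] = height_mm  # kill accumulation round-off

    nx = max(1, round(width_mm / (horizontal_coarsening * gm_dy)))
    x_edges = np.linspace(0.0, width_mm, nx + 1)
    ny = len(row_layer)

    xs, ys = np.meshgrid(x_edges, y_edges, indexing="ij")
    vertices = np.column_stack([xs.ravel(), ys.ravel()]) / MM_PER_CM

    def vid(i, j):
        return i * (ny + 1) + j

    cells = []
    labels = []
    half_w = width_mm / 2.0
    band = (half_w - unstable_width_mm / 2.0, half_w + unstable_width_mm / 2.0)
    for i in range(nx):
        xc = 0.5 * (x_edges[i] + x_edges[i + 1])
        for j in range(ny):
            v00, v10 = vid(i, j), vid(i + 1, j)
            v01, v11 = vid(i, j + 1), vid(i + 1, j + 1)
            layer = row_layer[j]
            if layer == "GM":
                label = GM_UNSTABLE if band[0] < xc < band[1] else GM_STABLE
            elif layer == "WM":
                label = WM_LEFT if xc < half_w else WM_RIGHT
            else:
                label = layer
            cells.append((v00, v10, v11))
            cells.append((v00, v11, v01))
            labels.extend((label, label))

    gm_lo = wm_mm
    meta = {
        "kind": "idealized_slice",
        "width_mm": width_mm,
        "height_mm": height_mm,
        "layer_mm": layer_mm,
        "unstable_width_mm": unstable_width_mm,
        "layer_spans_mm": {  # (bottom, top), measured from the bottom edge
            "WM": (0.0, gm_lo),
            "GM": (gm_lo, gm_lo + layer_mm),
            CSF: (gm_lo + layer_mm, gm_lo + 2 * layer_mm),
            SKULL: (gm_lo + 2 * layer_mm, gm_lo + 3 * layer_mm),
            SCALP: (gm_lo + 3 * layer_mm, height_mm),
        },
    }
    mesh = LabeledMesh(vertices, np.array(cells), np.array(labels), metadata=meta)
    mesh.probe_points = default_probe_points(mesh)
    return mesh


def default_probe_points(mesh: LabeledMesh) -> np.ndarray:
    """Probe coordinates (cm).

    For an idealized slice: the mid-thickness of each tissue layer on the
    vertical line through the centre of the unstable region, plus the
    centroid of the unstable region itself (when present).  For any other
    mesh: volume-weighted centroids of each labeled region.
    """
    if mesh.metadata.get("kind") == "idealized_slice":
        x = mesh.metadata["width_mm"] / 2.0
        pts = [
            (x, 0.5 * (lo + hi))
            for name, (lo, hi) in mesh.metadata["layer_spans_mm"].items()
            if hi > lo
        ]
        if np.any(mesh.cell_labels == GM_UNSTABLE):
            vols = cell_volumes(mesh)
            m = mesh.cell_labels == GM_UNSTABLE
            c = np.average(mesh.cell_centroids()[m], axis=0, weights=vols[m])
            pts.append(tuple(c * MM_PER_CM))
        return np.array(pts) / MM_PER_CM
    vols = cell_volumes(mesh)
    cents = mesh.cell_centroids()
    out = []
    for label in np.unique(mesh.cell_labels):
        m = mesh.cell_labels == label
        out.append(np.average(cents[m], axis=0, weights=vols[m]))
    return np.array(out)


def gm_probe_at(mesh: LabeledMesh, x_mm: float) -> np.ndarray:
    """A grey-matter probe at horizontal position x_mm (idealized slice), cm."""
    if mesh.metadata.get("kind") != "idealized_slice":
        raise MeshValidationError("gm_probe_at requires an idealized slice")
    lo, hi = mesh.metadata["layer_spans_mm"]["GM"]
    return np.array([x_mm, 0.5 * (lo + hi)]) / MM_PER_CM


def build_conductivity_map(
    mesh: LabeledMesh,
    table: dict[str, tuple[float, float]] | None = None,
    wm_spec: AnisotropySpec | None = None,
    anisotropy_applies: str = "both",
) -> ConductivityMap:
    """Per-cell conductivity tensors from a per-label scalar table.

    Isotropic value*I tensors everywhere except white matter when `wm_spec`
    is given: WM_LEFT gets the anisotropy tensor with vertical orientation,
    WM_RIGHT horizontal (generic WM uses `wm_spec.orientation`).
    `anisotropy_applies` selects whether the anisotropic tensor replaces the
    intracellular field, the extracellular one, or both.
    """
    if table is None:
        table = DEFAULT_CONDUCTIVITY_TABLE
    if anisotropy_applies not in ("both", "mi", "me"):
        raise MeshValidationError("anisotropy_applies must be both|mi|me")
    dim = mesh.dimension
    eye = np.eye(dim)
    labels = mesh.cell_labels
    missing = set(np.unique(labels)) - set(table)
    if missing:
        raise KeyError(f"conductivity table lacks entries for {sorted(missing)}")

    Mi = np.empty((mesh.n_cells, dim, dim))
    Me = np.empty_like(Mi)
    for label in np.unique(labels):
        m = labels == label
        mi_val, me_val = table[label]
        Mi[m] = mi_val * eye
        Me[m] = me_val * eye
    if wm_spec is not None:
        vertical = np.zeros(dim)
        vertical[-1] = 1.0
        horizontal = np.zeros(dim)
        horizontal[0] = 1.0
        for label, orient in (
            (WM_LEFT, vertical),
            (WM_RIGHT, horizontal),
            (WM, wm_spec.orientation),
        ):
            m = labels == label
            if not np.any(m):
                continue
            tensor = wm_anisotropy_tensor(
                AnisotropySpec(wm_spec.sigma_l, wm_spec.sigma_t, orient)
            )
            if anisotropy_applies in ("both", "mi"):
                Mi[m] = tensor
            if anisotropy_applies in ("both", "me"):
                Me[m] = tensor
    return ConductivityMap(Mi, Me)


def locate_points(mesh: LabeledMesh, points: np.ndarray, tol: float = 1e-10):
    """Containing cell and barycentric weights for each query point (cm).

    Returns (cell_indices, weights) with weights shaped (n_points, dim+1).
    Raises MeshValidationError for points outside the mesh.
    """
    points = np.atleast_2d(np.asarray(points, float))
    d = mesh.dimension
    pts = mesh.vertices[mesh.cells]  # (m, d+1, d)
    T = np.swapaxes(pts[:, 1:, :] - pts[:, :1, :], 1, 2)  # (m, d, d)
    Tinv = np.linalg.inv(T)
    origins = pts[:, 0, :]
    cell_idx = np.empty(len(points), dtype=np.int64)
    weights = np.empty((len(points), d + 1))
    for k, p in enumerate(points):
        lam = np.einsum("mij,mj->mi", Tinv, p - origins)  # (m, d)
        w0 = 1.0 - lam.sum(axis=1)
        full = np.column_stack([w0, lam])
        inside = np.all(full >= -tol, axis=1)
        if not np.any(inside):
            raise MeshValidationError(f"probe point {p} lies outside the mesh")
        c = int(np.argmax(inside))
        cell_idx[k] = c
        weights[k] = np.clip(full[c], 0.0, None)
        weights[k] /= weights[k].sum()
    return cell_idx, weights


def refine_uniform(mesh: LabeledMesh) -> LabeledMesh:
    """One red (edge-midpoint) refinement of a triangle mesh; every cell is
    split into four congruent children inheriting its label."""
    if mesh.dimension != 2:
        raise MeshValidationError("uniform refinement implemented for 2D only")
    edges = {}
    verts = [mesh.vertices]

    def midpoint(a: int, b: int) -> int:
        key = (a, b) if a < b else (b, a)
        if key not in edges:
            edges[key] = mesh.n_vertices + len(edges)
            verts.append(0.5 * (mesh.vertices[key[0]] + mesh.vertices[key[1]])[None])
        return edges[key]

    cells, labels = [], []
    for (a, b, c), lab in zip(mesh.cells, mesh.cell_labels):
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        cells += [(a, ab, ca), (ab, b, bc), (ca, bc, c), (ab, bc, ca)]
        labels += [lab] * 4
    out = LabeledMesh(
        np.vstack(verts), np.array(cells), np.array(labels),
        probe_points=mesh.probe_points, metadata=dict(mesh.metadata),
    )
    return out


# ---------------------------------------------------------------------------
# Gmsh MSH 2.2 ASCII input/output (cell labels carried as the physical tag)

_GMSH_TYPE = {2: 3, 4: 4}  # element type -> number of vertices (tri, tet)
_GMSH_TYPE_OF_DIM = {2: 2, 3: 4}


def write_labeled_mesh(path, mesh: LabeledMesh, label_to_int: dict[str, int]) -> None:
    """Write a LabeledMesh as Gmsh MSH 2.2 ASCII with labels as physical tags."""
    inv_ok = len(set(label_to_int.values())) == len(label_to_int)
    if not inv_ok:
        raise MeshFormatError("label_to_int mapping must be injective")
    missing = set(np.unique(mesh.cell_labels)) - set(label_to_int)
    if missing:
        raise MeshFormatError(f"mapping lacks labels {sorted(missing)}")
    d = mesh.dimension
    etype = _GMSH_TYPE_OF_DIM[d]
    with open(path, "w") as fh:
        fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        fh.write(f"$Nodes\n{mesh.n_vertices}\n")
        for i, v in enumerate(mesh.vertices, start=1):
            coords = list(v) + [0.0] * (3 - d)
            fh.write(f"{i} {coords[0]:.17g} {coords[1]:.17g} {coords[2]:.17g}\n")
        fh.write("$EndNodes\n")
        fh.write(f"$Elements\n{mesh.n_cells}\n")
        for i, (cell, label) in enumerate(zip(mesh.cells, mesh.cell_labels), start=1):
            tag = label_to_int[str(label)]
            verts = " ".join(str(v + 1) for v in cell)
            fh.write(f"{i} {etype} 2 {tag} {tag} {verts}\n")
        fh.write("$EndElements\n")


def read_labeled_mesh(path, int_to_label: dict[int, str]) -> LabeledMesh:
    """Read a Gmsh MSH 2.2 ASCII file; physical tags map to tissue labels via
    `int_to_label`."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    try:
        n0 = lines.index("$Nodes")
        e0 = lines.index("$Elements")
    except ValueError as exc:
        raise MeshFormatError("missing $Nodes or $Elements section") from exc
    n_nodes = int(lines[n0 + 1])
    coords = np.empty((n_nodes, 3))
    node_ids = {}
    for k in range(n_nodes):
        parts = lines[n0 + 2 + k].split()
        node_ids[int(parts[0])] = k
        coords[k] = [float(x) for x in parts[1:4]]
    n_elem = int(lines[e0 + 1])
    cells, labels, dims = [], [], set()
    for k in range(n_elem):
        parts = lines[e0 + 2 + k].split()
        etype = int(parts[1])
        if etype not in _GMSH_TYPE:
            continue  # skip lower-dimensional boundary elements
        n_tags = int(parts[2])
        if n_tags < 1:
            raise MeshFormatError("element carries no physical (label) tag")
        tag = int(parts[3])
        if tag not in int_to_label:
            raise MeshFormatError(f"physical tag {tag} missing from label mapping")
        verts = [node_ids[int(x)] for x in parts[3 + n_tags:]]
        cells.append(verts)
        labels.append(int_to_label[tag])
        dims.add(_GMSH_TYPE[etype] - 1)
    if not cells:
        raise MeshFormatError("no simplicial elements with labels found")
    if len(dims) != 1:
        raise MeshFormatError("mixed triangle/tetrahedron meshes not supported")
    dim = dims.pop()
    vertices = coords[:, :dim]
    mesh = LabeledMesh(vertices, np.array(cells), np.array(labels))
    mesh.validate_conforming()
    return mesh
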