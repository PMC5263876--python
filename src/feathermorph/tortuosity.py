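"""Tissue tortuosity and apparent diffusivity on polygonal cell lattices.

Tortuosity lambda is the length L of the shortest path between two points
through the tissue divided by the straight chord C between them; a
molecule diffusing through a medium of tortuosity lambda shows apparent
diffusivity D* = D / lambda^2.  Paths run through cell centres: cells
sharing a boundary edge are connected, so a path is a chain of
centroid-to-centroid hops plus the end segments from the query points to
their cells' centroids.  Elongated cells force longer detours for chords
perpendicular to the elongation axis, which is how epithelial cell shape
feeds back on activator spreading.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from shapely.geometry import Point, Polygon
from shapely.strtree import STRtree


class MeshGeometryError(RuntimeError):
    pass


@dataclass
class CellMesh:
    """Polygonal cell lattice with shared-edge adjacency."""

    cells: list[Polygon]
    adjacency: set[tuple[int, int]]     # (i, j) with i < j, shared edge
    bounds: tuple[float, float, float, float] = field(init=False)

    def __post_init__(self) -> None:
        for i, c in enumerate(self.cells):
            if not c.is_valid or c.area <= 0:
                raise MeshGeometryError(f"cell {i} is degenerate")
        xs = [c.bounds for c in self.cells]
        self.bounds = (
            min(b[0] for b in xs), min(b[1] for b in xs),
            max(b[2] for b in xs), max(b[3] for b in xs),
        )
        for i, j in self.adjacency:
            if not (0 <= i < j < len(self.cells)):
                raise MeshGeometryError(f"bad adjacency pair {(i, j)}")

    def __len__(self) -> int:
        return len(self.cells)

    @classmethod
    def from_polygons(cls, polys: list[Polygon],
                      tol: float = 1e-9) -> "CellMesh":
        """Build adjacency from shared boundary segments."""
        adjacency: set[tuple[int, int]] = set()
        tree = STRtree(polys)
        for i, poly in enumerate(polys):
            for j in tree.query(poly):
                j = int(j)
                if j <= i:
                    continue
                inter = poly.boundary.intersection(polys[j].boundary)
                if inter.length > tol:
                    adjacency.add((i, j))
        return cls(cells=list(polys), adjacency=adjacency)

    def locate(self, point) -> int:
        p = Point(point)
        for i, c in enumerate(self.cells):
            if c.covers(p):
                return i
        raise MeshGeometryError(f"point {tuple(p.coords)[0]} outside the mesh")


@dataclass
class TortuosityResult:
    """Sampled path/chord ratios along one direction."""

    records: list[tuple[float, float, float]]   # (L, C, lambda)
    direction: str
    lambda_mean: float = field(init=False)

    def __post_init__(self) -> None:
        if any(lam < 1 for _, _, lam in self.records):
            raise ValueError("tortuosity below 1")
        self.lambda_mean = float(np.mean([lam for _, _, lam in self.records]))

    @property
    def d_star_ratio(self) -> float:
        return 1.0 / self.lambda_mean**2


def build_cell_graph(mesh: CellMesh) -> nx.Graph:
    """Weighted centroid-adjacency graph; raises on disconnected meshes."""
    g = nx.Graph()
    cents = [c.centroid for c in mesh.cells]
    for i, c in enumerate(cents):
        g.add_node(i, pos=(c.x, c.y))
    for i, j in mesh.adjacency:
        w = cents[i].distance(cents[j])
        g.add_edge(i, j, weight=w)
    if len(mesh) > 1 and not nx.is_connected(g):
        comps = [sorted(c) for c in nx.connected_components(g)]
        raise MeshGeometryError(f"mesh is disconnected: components {comps}")
    return g


def tortuosity_between(
    mesh: CellMesh,
    source,
    target,
    graph: nx.Graph | None = None,
) -> tuple[float, float, float]:
    """(L, C, lambda) between two points inside the mesh.

    L is the graph-shortest centroid path plus the end segments from each
    query point to its cell centroid; C the straight chord.  lambda is
    floored at 1 (centroid detours can undercut the chord at short range,
    but a path through tissue cannot beat the straight line).
    """
    src = Point(source)
    tgt = Point(target)
    i, j = mesh.locate(src), mesh.locate(tgt)
    chord = src.distance(tgt)
    if chord == 0:
        return 0.0, 0.0, 1.0
    if i == j:
        return chord, chord, 1.0
    if graph is None:
        graph = build_cell_graph(mesh)
    hop = nx.shortest_path_length(graph, i, j, weight="weight")
    ci, cj = mesh.cells[i].centroid, mesh.cells[j].centroid
    L = src.distance(ci) + hop + cj.distance(tgt)
    return float(L), float(chord), float(max(L / chord, 1.0))


def apparent_diffusivity(D: float, lam: float) -> float:
    """D* = D / lambda^2."""
    if D <= 0:
        raise ValueError("free diffusivity must be positive")
    if lam < 1:
        raise ValueError("tortuosity must be >= 1")
    return D / lam**2


def cell_shape_metrics(mesh: CellMesh) -> dict:
    """Per-cell best-fit-ellipse aspect ratio and area, with summaries.

    Aspect ratio is major/minor axis of the ellipse matching the polygon's
    second area moments; area by the (shapely) shoelace rule.
    """
    aspects, areas = [], []
    for idx, poly in enumerate(mesh.cells):
        a = poly.area
        if a <= 0:
            raise MeshGeometryError(f"cell {idx} has zero area")
        xy = np.asarray(poly.exterior.coords)[:-1]
        x, y = xy[:, 0], xy[:, 1]
        x1, y1 = np.roll(x, -1), np.roll(y, -1)
        cross = x * y1 - x1 * y
        signed = cross.sum() / 2.0
        cx = ((x + x1) * cross).sum() / (6 * signed)
        cy = ((y + y1) * cross).sum() / (6 * signed)
        xs, ys = x - cx, y - cy
        xs1, ys1 = np.roll(xs, -1), np.roll(ys, -1)
        cr = xs * ys1 - xs1 * ys
        ixx = (cr * (ys**2 + ys * ys1 + ys1**2)).sum() / 12.0
        iyy = (cr * (xs**2 + xs * xs1 + xs1**2)).sum() / 12.0
        ixy = (cr * (xs * ys1 + 2 * xs * ys + 2 * xs1 * ys1 + xs1 * ys)).sum() / 24.0
        if signed < 0:
            ixx, iyy, ixy = -ixx, -iyy, -ixy
        cov = np.array([[iyy, ixy], [ixy, ixx]]) / abs(signed)
        ev = np.sort(np.linalg.eigvalsh(cov))
        aspects.append(float(np.sqrt(ev[1] / max(ev[0], 1e-300))))
        areas.append(float(a))
    aspects = np.array(aspects)
    areas = np.array(areas)
    return {
        "aspect_ratio": aspects,
        "area": areas,
        "aspect_mean": float(aspects.mean()),
        "aspect_sd": float(aspects.std(ddof=1)) if len(aspects) > 1 else 0.0,
        "area_mean": float(areas.mean()),
        "area_sd": float(areas.std(ddof=1)) if len(areas) > 1 else 0.0,
    }


def mean_tortuosity(
    mesh: CellMesh,
    direction: str = "x",
    n_pairs: int = 100,
    min_chord_diameters: float = 5.0,
    seed: int = 0,
) -> TortuosityResult:
    """Mean lambda over seeded random point pairs separated along one axis.

    Pairs are rejected unless their chord exceeds ``min_chord_diameters``
    mean cell diameters, so the estimate probes tissue-scale detours
    rather than intra-cell geometry.
    """
    rng = np.random.default_rng(seed)
    minx, miny, maxx, maxy = mesh.bounds
    mean_diam = 2.0 * np.sqrt(np.mean([c.area for c in mesh.cells]) / np.pi)
    min_chord = min_chord_diameters * mean_diam
    graph = build_cell_graph(mesh)
    records = []
    attempts = 0
    while len(records) < n_pairs and attempts < n_pairs * 200:
        attempts += 1
        if direction == "x":
            y = rng.uniform(miny, maxy)
            x1, x2 = np.sort(rng.uniform(minx, maxx, 2))
            p, q = (x1, y), (x2, y)
        else:
            x = rng.uniform(minx, maxx)
            y1, y2 = np.sort(rng.uniform(miny, maxy, 2))
            p, q = (x, y1), (x, y2)
        if Point(p).distance(Point(q)) < min_chord:
            continue
        try:
            records.append(tortuosity_between(mesh, p, q, graph=graph))
        except MeshGeometryError:
            continue
    if not records:
        raise MeshGeometryError("no valid point pairs found")
    return TortuosityResult(records=records, direction=direction)


def mesh_to_geojson(mesh: CellMesh) -> dict:
    """GeoJSON FeatureCollection of the cell polygons."""
    return {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": {"id": i},
             "geometry": cell.__geo_interface__}
            for i, cell in enumerate(mesh.cells)
        ],
    }


def mesh_from_geojson(doc: dict) -> CellMesh:
    polys = [Polygon(f["geometry"]["coordinates"][0])
             for f in doc["features"]]
    return CellMesh.from_polygons(polys)


def mesh_from_label_image(labels: np.ndarray,
                          background: int = 0) -> CellMesh:
    """Trace a labelled segmentation mask into a polygonal mesh.

    Each label's region is traced with a marching-squares contour at the
    half-level; labels touching fewer than 3 contour points are skipped.
    Intended for importing real epithelial segmentations; synthetic
    lattices come from :func:`feathermorph.synthetic.generate_cell_lattice`.
    """
    from skimage import measure

    polys = []
    ids = []
    for lab in np.unique(labels):
        if lab == background:
            continue
        # pad so regions touching the image edge still trace closed loops
        mask = np.pad((labels == lab).astype(float), 1)
        contours = measure.find_contours(mask, 0.5)
        if not contours:
            continue
        contour = max(contours, key=len)
        if len(contour) < 3:
            continue
        poly = Polygon(contour[:, ::-1] - 1.0).buffer(0)  # (row,col)->(x,y)
        if poly.is_empty or poly.geom_type != "Polygon":
            continue
        polys.append(poly)
        ids.append(lab)
    if not polys:
        raise MeshGeometryError("no traceable labels in the image")
    # adjacency from 4-connected pixel neighbourhoods (traced contours sit
    # half a pixel inside each region and never touch)
    index = {lab: k for k, lab in enumerate(ids)}
    adjacency: set[tuple[int, int]] = set()
    for a, b in ((labels[:, :-1], labels[:, 1:]),
                 (labels[:-1, :], labels[1:, :])):
        touch = a != b
        for la, lb in zip(a[touch].ravel(), b[touch].ravel()):
            if la in index and lb in index:
                i, j = sorted((index[la], index[lb]))
                adjacency.add((i, j))
    return CellMesh(cells=polys, adjacency=adjacency)


def fit_tortuosity_curve(stretches, lambdas):
    """Least-squares fit of lambda(rho) = 1 + kappa (rho - 1).

    Returns (kappa, callable); the identity lambda(1) = 1 is built in so
    apparent-diffusivity multipliers are exactly 1 for isotropic tissue.
    """
    s = np.asarray(stretches, dtype=float) - 1.0
    lam = np.asarray(lambdas, dtype=float) - 1.0
    denom = float(np.dot(s, s))
    kappa = float(np.dot(s, lam) / denom) if denom > 0 else 0.0
    return kappa, lambda rho: 1.0 + kappa * (np.asarray(rho) - 1.0)
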