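import heapq

import numpy as np
import networkx as nx
import pytest
from shapely.geometry import Polygon

from feathermorph.synthetic import generate_cell_lattice
from feathermorph.tortuosity import (
    CellMesh,
    MeshGeometryError,
    apparent_diffusivity,
    build_cell_graph,
    cell_shape_metrics,
    fit_tortuosity_curve,
    mean_tortuosity,
    tortuosity_between,
)


def square_grid_mesh(nx_, ny, size=1.0):
    polys = [
        Polygon([
            (i * size, j * size), ((i + 1) * size, j * size),
            ((i + 1) * size, (j + 1) * size), (i * size, (j + 1) * size),
        ])
        for j in range(ny) for i in range(nx_)
    ]
    return CellMesh.from_polygons(polys)


def dijkstra_oracle(mesh, src, dst):
    """Independent shortest-path implementation (binary heap, no networkx)."""
    cents = [(c.centroid.x, c.centroid.y) for c in mesh.cells]
    adj = {i: [] for i in range(len(mesh))}
    for i, j in mesh.adjacency:
        w = float(np.hypot(cents[i][0] - cents[j][0],
                           cents[i][1] - cents[j][1]))
        adj[i].append((j, w))
        adj[j].append((i, w))
    dist = {src: 0.0}
    heap = [(0.0, src)]
    seen = set()
    while heap:
        d, u = heapq.heappop(heap)
        if u in seen:
            continue
        seen.add(u)
        if u == dst:
            return d
        for v, w in adj[u]:
            nd = d + w
            if nd < dist.get(v, np.inf):
                dist[v] = nd
                heapq.heappush(heap, (nd, v))
    raise RuntimeError("no path")


class TestCellGraph:
    def test_two_by_two_grid_hand_counted(self):
        mesh = square_grid_mesh(2, 2)
        g = build_cell_graph(mesh)
        assert g.number_of_nodes() == 4
        assert g.number_of_edges() == 4
        assert all(d["weight"] == pytest.approx(1.0)
                   for _, _, d in g.edges(data=True))

    def test_single_cell(self):
        mesh = CellMesh.from_polygons(
            [Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])]
        )
        g = build_cell_graph(mesh)
        assert g.number_of_nodes() == 1
        assert g.number_of_edges() == 0

    def test_ten_by_ten_corner_to_corner_is_manhattan(self):
        mesh = square_grid_mesh(10, 10)
        g = build_cell_graph(mesh)
        d = nx.shortest_path_length(g, 0, 99, weight="weight")
        assert d == pytest.approx(18.0)
        assert d == pytest.approx(dijkstra_oracle(mesh, 0, 99))

    def test_matches_independent_dijkstra_on_small_meshes(self):
        for mesh in (square_grid_mesh(5, 5),
                     generate_cell_lattice(25, 1.5, seed=4)):
            g = build_cell_graph(mesh)
            n = len(mesh)
            for src in range(0, n, 7):
                for dst in range(n - 1, 0, -9):
                    got = nx.shortest_path_length(g, src, dst,
                                                  weight="weight")
                    assert got == pytest.approx(
                        dijkstra_oracle(mesh, src, dst)
                    )

    def test_disconnected_mesh_reports_components(self):
        far = Polygon([(10, 10), (11, 10), (11, 11), (10, 11)])
        near = Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])
        mesh = CellMesh.from_polygons([near, far])
        with pytest.raises(MeshGeometryError, match="disconnected"):
            build_cell_graph(mesh)


class TestTortuosityBetween:
    def test_same_cell_chord_is_path(self):
        mesh = square_grid_mesh(3, 3)
        L, C, lam = tortuosity_between(mesh, (0.2, 0.2), (0.8, 0.6))
        assert lam == 1.0
        assert L == pytest.approx(C)

    def test_collinear_row_approaches_unity(self):
        # 10 cells in a row: centroid detour vanishes, error < 2%
        mesh = square_grid_mesh(10, 1)
        L, C, lam = tortuosity_between(mesh, (0.5, 0.5), (9.5, 0.5))
        assert lam == pytest.approx(1.0, abs=0.02)

    def test_point_outside_mesh_rejected(self):
        mesh = square_grid_mesh(2, 2)
        with pytest.raises(MeshGeometryError, match="outside"):
            tortuosity_between(mesh, (0.5, 0.5), (5.0, 5.0))

    def test_elongated_lattice_is_more_tortuous_perpendicular(self):
        iso = generate_cell_lattice(400, 1.0, seed=0)
        elong = generate_cell_lattice(400, 3.0, seed=0)
        lam_iso = mean_tortuosity(iso, "x", n_pairs=60, seed=1).lambda_mean
        lam_el = mean_tortuosity(elong, "x", n_pairs=60, seed=1).lambda_mean
        assert lam_el > lam_iso

    def test_lambda_monotone_in_stretch(self):
        lams = [
            mean_tortuosity(
                generate_cell_lattice(400, s, seed=0), "x",
                n_pairs=60, seed=1,
            ).lambda_mean
            for s in (1.0, 1.5, 2.0, 3.0)
        ]
        assert all(a < b for a, b in zip(lams, lams[1:]))
        # the chain closes: apparent diffusivity falls as stretch rises
        dstars = [apparent_diffusivity(1.0, lam) for lam in lams]
        assert all(a > b for a, b in zip(dstars, dstars[1:]))


class TestApparentDiffusivity:
    def test_unit_tortuosity_identity(self):
        assert apparent_diffusivity(0.7, 1.0) == 0.7

    def test_inverse_square_law(self):
        assert apparent_diffusivity(1.0, 2.0) == 0.25

    def test_composes_with_measured_lambda(self):
        mesh = generate_cell_lattice(400, 3.0, seed=0)
        lam = mean_tortuosity(mesh, "x", n_pairs=40, seed=2).lambda_mean
        assert apparent_diffusivity(1.0, lam) == pytest.approx(1 / lam**2)

    def test_sub_unity_tortuosity_rejected(self):
        with pytest.raises(ValueError):
            apparent_diffusivity(1.0, 0.9)


class TestCellShapeMetrics:
    def test_unit_square(self):
        mesh = CellMesh.from_polygons(
            [Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])]
        )
        m = cell_shape_metrics(mesh)
        assert m["aspect_mean"] == pytest.approx(1.0)
        assert m["area_mean"] == pytest.approx(1.0)

    def test_three_by_one_rectangle(self):
        mesh = CellMesh.from_polygons(
            [Polygon([(0, 0), (3, 0), (3, 1), (0, 1)])]
        )
        m = cell_shape_metrics(mesh)
        assert m["aspect_mean"] == pytest.approx(3.0)
        assert m["area_mean"] == pytest.approx(3.0)

    def test_generator_stretch_recovered_from_moments(self):
        mesh = generate_cell_lattice(400, 2.0, seed=0)
        m = cell_shape_metrics(mesh)
        assert m["aspect_mean"] == pytest.approx(2.0, rel=0.15)


def test_fitted_tortuosity_curve_passes_through_identity():
    stretches = [1.0, 1.5, 2.0, 3.0]
    lams = [1.0, 1.1, 1.22, 1.4]
    kappa, curve = fit_tortuosity_curve(stretches, lams)
    assert curve(1.0) == pytest.approx(1.0)
    assert kappa > 0
    assert curve(3.0) == pytest.approx(1 + 2 * kappa)


class TestMeshIO:
    def test_geojson_round_trip_preserves_cells_and_adjacency(self):
        mesh = generate_cell_lattice(25, 1.5, seed=2)
        from feathermorph.tortuosity import mesh_from_geojson, mesh_to_geojson

        back = mesh_from_geojson(mesh_to_geojson(mesh))
        assert len(back) == len(mesh)
        assert back.adjacency == mesh.adjacency

    def test_label_image_tracer_recovers_block_layout(self):
        from feathermorph.tortuosity import mesh_from_label_image

        labels = np.zeros((20, 20), int)
        labels[:10, :10] = 1
        labels[:10, 10:] = 2
        labels[10:, :10] = 3
        labels[10:, 10:] = 4
        mesh = mesh_from_label_image(labels)
        assert len(mesh) == 4
        # rook adjacency only: diagonal blocks are not neighbours
        assert sorted(mesh.adjacency) == [(0, 1), (0, 2), (1, 3), (2, 3)]
        m = cell_shape_metrics(mesh)
        assert m["aspect_mean"] == pytest.approx(1.0, rel=0.1)

    def test_empty_label_image_rejected(self):
        from feathermorph.tortuosity import mesh_from_label_image
        from feathermorph.tortuosity import MeshGeometryError

        with pytest.raises(MeshGeometryError):
            mesh_from_label_image(np.zeros((10, 10), int))
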