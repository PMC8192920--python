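"""Template graphs, ring clustering, wireframe building, manual edits."""

import networkx as nx
import numpy as np
import pytest

from stentrec.core import FrameField
from stentrec.errors import EditError, InsufficientInputError, InvalidInputError
from stentrec.lumen import interpolate_rotations
from stentrec.unroll import package_and_rotate, unroll_to_plane
from stentrec.wireframe import (
    StentTemplate,
    apply_manual_edits,
    build_wireframe,
    cluster_rows,
    make_generic_template,
    template_graph,
)


@pytest.fixture(scope="module")
def clean_planar(clean_phantom):
    spec, truth, frames = clean_phantom
    stack = package_and_rotate(frames, interpolate_rotations(frames))
    return spec, truth, unroll_to_plane(stack)


class TestTemplate:
    def test_invariants_enforced(self):
        with pytest.raises(InvalidInputError):
            make_generic_template(crowns_per_ring=2)
        with pytest.raises(InvalidInputError):
            make_generic_template(links_per_ring_pair=9, crowns_per_ring=8)

    def test_json_round_trip(self, tmp_path):
        t = make_generic_template()
        t.to_json(tmp_path / "t.json")
        t2 = StentTemplate.from_json(tmp_path / "t.json")
        assert t2.to_json() == t.to_json()

    def test_template_graph_structure(self):
        t = make_generic_template(rings=9, crowns_per_ring=8, links_per_ring_pair=3)
        W = np.pi * 3.0
        g = template_graph(t, W)
        C, R, L = 8, 9, 3
        assert g.g.number_of_edges() == R * 2 * C
        assert g.g.number_of_nodes() == R * 2 * C - L * (R - 1)
        for n, d in g.g.nodes(data=True):
            deg = g.g.degree[n]
            assert deg == (4 if d["role"] == "link-junction" else 2)
        assert nx.is_connected(g.g)

    def test_template_graph_wrap_periodic(self):
        t = make_generic_template()
        g = template_graph(t, np.pi * 3.0)
        # translating every node by one wrap period maps the graph onto itself
        pos = {
            (round(d["x"], 6), round(np.mod(d["y"], g.wrap_period), 6))
            for _, d in g.g.nodes(data=True)
        }
        shifted = {
            (round(d["x"], 6), round(np.mod(d["y"] + g.wrap_period, g.wrap_period), 6))
            for _, d in g.g.nodes(data=True)
        }
        assert pos == shifted


class TestClusterRows:
    def test_phantom_rings_recovered(self, clean_planar):
        spec, truth, planar = clean_planar
        groups, df = cluster_rows(planar, spec.template)
        assert len(groups) == spec.template.rings
        pitch = spec.template.ring_pitch
        for i, grp in enumerate(groups):
            assert len(grp) > 0
            x = df.x_mm.to_numpy()[grp]
            center = i * pitch + spec.template.crown_height / 2
            assert np.abs(x - center).max() < pitch  # stays near its own ring

    def test_two_clean_rings(self):
        t = make_generic_template(rings=2, crowns_per_ring=8, nominal_length=3.6)
        x = np.concatenate([np.full(16, 0.7), np.full(16, 2.6)])
        y = np.tile(np.linspace(0, 9, 16, endpoint=False), 2)
        import pandas as pd

        from stentrec.unroll import PlanarPointSet

        df = pd.DataFrame(
            {"x_mm": x, "y_mm": y, "role": "strut", "frame_index": 0,
             "malapposition_mm": 0.0, "flagged": False, "wrap_copy": False}
        )
        planar = PlanarPointSet(points=df, wrap_period={0: 9.42})
        groups, _ = cluster_rows(planar, t)
        assert [len(g) for g in groups] == [16, 16]

    def test_empty_input_rejected(self):
        import pandas as pd

        from stentrec.unroll import PlanarPointSet

        planar = PlanarPointSet(
            points=pd.DataFrame(
                columns=["x_mm", "y_mm", "role", "frame_index", "malapposition_mm",
                         "flagged", "wrap_copy"]
            ),
            wrap_period={},
        )
        with pytest.raises(InsufficientInputError):
            cluster_rows(planar, make_generic_template())


class TestBuildWireframe:
    def test_noiseless_phantom_isomorphic(self, clean_planar):
        spec, truth, planar = clean_planar
        g = build_wireframe(planar, spec.template)
        assert nx.is_isomorphic(g.g, truth.planar_graph.g)
        # crown apex positions within sampling tolerance of the truth pattern
        W = g.wrap_period
        tn = np.array([[d["x"], d["y"]] for _, d in truth.planar_graph.g.nodes(data=True)
                       if d["role"] != "link-junction"])
        for n, d in g.g.nodes(data=True):
            if d["role"] == "link-junction":
                continue
            dy = np.abs(tn[:, 1] - d["y"])
            dy = np.minimum(dy, W - dy)
            dist = np.sqrt((tn[:, 0] - d["x"]) ** 2 + dy**2)
            assert dist.min() < 0.05

    def test_shadow_bridged_nodes_restore_graph(self, noisy_phantom):
        spec, truth, frames = noisy_phantom
        stack = package_and_rotate(frames, interpolate_rotations(frames))
        planar = unroll_to_plane(stack)
        g = build_wireframe(planar, spec.template)
        assert nx.is_isomorphic(g.g, truth.planar_graph.g)
        bridged = [n for n, d in g.g.nodes(data=True) if d["provenance"] == "bridged"]
        assert len(bridged) > 0  # the 30 deg shadow hides some crowns
        # bridged positions within half a crown pitch of a truth apex
        W = g.wrap_period
        dy_pitch = W / (2 * spec.template.crowns_per_ring)
        tn = np.array([[d["x"], np.mod(d["y"], W)]
                       for _, d in truth.planar_graph.g.nodes(data=True)])
        for n in bridged:
            d = g.g.nodes[n]
            dy = np.abs(tn[:, 1] - d["y"])
            dy = np.minimum(dy, W - dy)
            dist = np.sqrt((tn[:, 0] - d["x"]) ** 2 + dy**2)
            assert dist.min() < 1.0 * dy_pitch

    def test_every_strut_point_near_an_edge(self, clean_planar):
        spec, truth, planar = clean_planar
        g = build_wireframe(planar, spec.template)
        segs = []
        for a, b, dd in g.g.edges(data=True):
            p = np.asarray(dd["polyline"])
            segs.append(np.stack([p[:-1], p[1:]], axis=1))
        segs = np.concatenate(segs)
        df = planar.struts()
        W = g.wrap_period
        pts = df[["x_mm", "y_mm"]].to_numpy()
        worst = 0.0
        for p in pts[:: max(1, len(pts) // 400)]:
            best = np.inf
            for shift in (-W, 0.0, W):
                q = p + [0, shift]
                a, b = segs[:, 0], segs[:, 1]
                ab = b - a
                tt = np.clip(
                    np.einsum("ij,ij->i", q - a, ab)
                    / np.maximum(np.einsum("ij,ij->i", ab, ab), 1e-12),
                    0, 1,
                )
                d = np.linalg.norm(q - (a + tt[:, None] * ab), axis=1)
                best = min(best, d.min())
            worst = max(worst, best)
        assert worst < 0.15  # clustering radius

    def test_single_ring_closed_zigzag(self):
        # 2k alternating points -> 2k edges forming a closed zig-zag
        t = make_generic_template(rings=1, crowns_per_ring=8, links_per_ring_pair=1,
                                  nominal_length=1.5, ring_gap_mm=0.0)
        import pandas as pd

        from stentrec.unroll import PlanarPointSet

        W = np.pi * 3.0
        k = 8
        ys, xs = [], []
        for j in range(2 * k):
            for f in np.linspace(0.1, 0.9, 5):  # points along each leg
                y0, y1 = j * W / (2 * k), (j + 1) * W / (2 * k)
                x0 = 0.0 if j % 2 == 0 else 1.5
                x1 = 1.5 - x0
                xs.append(x0 + f * (x1 - x0))
                ys.append(np.mod(y0 + f * (y1 - y0), W))
        df = pd.DataFrame(
            {"x_mm": xs, "y_mm": ys, "role": "strut", "frame_index": 0,
             "malapposition_mm": 0.0, "flagged": False, "wrap_copy": False}
        )
        planar = PlanarPointSet(points=df, wrap_period={0: W})
        g = build_wireframe(planar, t)
        apex_nodes = [n for n, d in g.g.nodes(data=True) if d["role"] != "link-junction"]
        assert g.g.number_of_edges() == 2 * k
        assert nx.is_connected(g.g)


class TestManualEdits:
    def _graph(self):
        return template_graph(make_generic_template(), np.pi * 3.0)

    def test_empty_edit_list_is_identity(self):
        g = self._graph()
        g2 = apply_manual_edits(g, [])
        assert nx.utils.graphs_equal(g.g, g2.g) or (
            g2.g.number_of_nodes() == g.g.number_of_nodes()
            and g2.g.number_of_edges() == g.g.number_of_edges()
        )

    def test_delete_and_readd_conserves_counts(self):
        g = self._graph()
        nid = next(n for n, d in g.g.nodes(data=True)
                   if d["role"] == "peak" and g.g.degree[n] == 2)
        d = dict(g.g.nodes[nid])
        nbrs = list(g.g.neighbors(nid))
        edits = [
            {"op": "delete_node", "id": nid},
            {"op": "add_node", "id": "fixed", "x": d["x"], "y": d["y"] + 0.05,
             "role": d["role"], "ring": d["ring"]},
            {"op": "add_edge", "a": "fixed", "b": nbrs[0]},
            {"op": "add_edge", "a": "fixed", "b": nbrs[1]},
        ]
        g2 = apply_manual_edits(g, edits)
        assert g2.g.number_of_nodes() == g.g.number_of_nodes()
        assert g2.g.number_of_edges() == g.g.number_of_edges()

    def test_degree_violation_rejected(self):
        g = self._graph()
        nid = next(n for n, d in g.g.nodes(data=True) if d["role"] == "peak")
        with pytest.raises(EditError):
            apply_manual_edits(g, [{"op": "delete_node", "id": nid}])

    def test_unknown_op_rejected(self):
        with pytest.raises(EditError):
            apply_manual_edits(self._graph(), [{"op": "sprinkle"}])
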