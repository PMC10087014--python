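import numpy as np
import pytest

import cloneviz as cv
from cloneviz.layout import mirror_band_layout
from conftest import random_instance

TOL = 1e-6


def band_at(layout, clone, t_index):
    """(lo, hi) of a clone's band at a time point's x coordinate."""
    pts = layout.support[clone]
    x = layout.x[t_index]
    rows = pts[np.isclose(pts[:, 0], x)]
    if len(rows) == 0:
        return None
    return float(rows[0, 1]), float(rows[0, 2])


class TestDolphinLayout:
    def test_single_clone_full_height(self, single_clone):
        layout = cv.dolphin_layout(single_clone)
        for t in range(2):
            lo, hi = band_at(layout, "A", t)
            assert hi - lo == pytest.approx(100.0)

    def test_birth_offset_default(self):
        evo = cv.build_evolution(
            {"A": [70, 70], "B": [0, 30]}, {"A": "normal", "B": "A"}
        )
        layout = cv.dolphin_layout(evo)
        birth_x = layout.support["B"][0, 0]
        assert birth_x - evo.timepoints[0] == pytest.approx(0.1)
        # the birth vertex has zero thickness
        assert layout.support["B"][0, 1] == layout.support["B"][0, 2]

    def test_centered_equal_gaps(self):
        evo = cv.build_evolution(
            {"A": [80], "B": [20], "C": [20]},
            {"A": "normal", "B": "A", "C": "A"},
        )
        layout = cv.dolphin_layout(
            evo, config=cv.LayoutConfig(vertical_mode="centered")
        )
        a = band_at(layout, "A", 0)
        b = band_at(layout, "B", 0)
        c = band_at(layout, "C", 0)
        gap = (80 - 40) / 3
        assert b[0] - a[0] == pytest.approx(gap)
        assert c[0] - b[1] == pytest.approx(gap)
        assert a[1] - c[1] == pytest.approx(gap)

    def test_bottom_mode_deepest_branch_on_axis(self):
        evo = cv.build_evolution(
            {"A": [90], "B": [20], "C": [40], "D": [10]},
            {"A": "normal", "B": "A", "C": "A", "D": "C"},
        )
        layout = cv.dolphin_layout(
            evo, config=cv.LayoutConfig(vertical_mode="bottom")
        )
        a = band_at(layout, "A", 0)
        c = band_at(layout, "C", 0)  # deepest branch (C -> D)
        assert a[0] == pytest.approx(0.0)
        assert c[0] == pytest.approx(a[0])  # hugs the parent's lower edge

    @pytest.mark.parametrize("mode", ["centered", "bottom"])
    @pytest.mark.parametrize("shape", ["polygon", "spline"])
    @pytest.mark.parametrize("seed", range(8))
    def test_thickness_equals_ccf_at_timepoints(self, mode, shape, seed):
        evo = random_instance(seed)
        layout = cv.dolphin_layout(
            evo, config=cv.LayoutConfig(shape=shape, vertical_mode=mode)
        )
        for k, lab in enumerate(evo.clone_labels):
            first = evo.first_positive_index(lab)
            if first is None:
                continue
            for t in range(first, evo.n_timepoints):
                assert layout.thickness_at(lab, evo.timepoints[t]) == (
                    pytest.approx(evo.ccf[k, t], abs=TOL)
                )

    @pytest.mark.parametrize("mode", ["centered", "bottom"])
    @pytest.mark.parametrize("seed", range(8))
    def test_nesting_invariant(self, mode, seed):
        evo = random_instance(seed)
        layout = cv.dolphin_layout(
            evo, config=cv.LayoutConfig(vertical_mode=mode)
        )
        _assert_nested(evo, layout)

    def test_spline_interpolates_support_points(self):
        evo = cv.build_evolution(
            {"A": [70, 50, 80], "B": [0, 30, 20]}, {"A": "normal", "B": "A"}
        )
        layout = cv.dolphin_layout(evo, config=cv.LayoutConfig(shape="spline"))
        xs, lo, hi = layout.boundaries("B", num=501)
        for row in layout.support["B"]:
            i = int(np.argmin(np.abs(xs - row[0])))
            assert lo[i] == pytest.approx(row[1], abs=1e-3)

    def test_layout_json_serializable(self, branched):
        import json

        layout = cv.dolphin_layout(branched)
        payload = json.loads(layout.to_json())
        assert set(payload["clones"]) == set(branched.clone_labels)


def _assert_nested(evo, layout):
    for lab, parent in zip(evo.clone_labels, evo.parents):
        if parent == cv.NORMAL:
            continue
        for t in range(evo.n_timepoints):
            child = band_at(layout, lab, t)
            par = band_at(layout, parent, t)
            if child is None:
                continue
            assert par is not None
            assert child[0] >= par[0] - TOL
            assert child[1] <= par[1] + TOL
    # founders jointly fit the plot height
    for t in range(evo.n_timepoints):
        total = sum(
            evo.ccf[evo.index(f), t] for f in evo.founders
        )
        assert total <= 100 + TOL


class TestSharkLayout:
    def test_chain_collinear(self, linear_chain):
        layout = cv.shark_layout(linear_chain)
        ys = {lab: xy[1] for lab, xy in layout.nodes.items()}
        assert len(set(ys.values())) == 1
        assert len(layout.edges) == 2

    def test_x_is_nested_level(self, branched):
        layout = cv.shark_layout(branched)
        for lab in branched.clone_labels:
            assert layout.nodes[lab][0] == branched.nested_level(lab)
        for parent, child in layout.edges:
            assert layout.nodes[child][0] == layout.nodes[parent][0] + 1

    def test_two_founders_no_shared_root(self):
        evo = cv.build_evolution(
            {"A": [40], "B": [30]}, {"A": "normal", "B": "normal"}
        )
        layout = cv.shark_layout(evo)
        assert layout.edges == ()
        assert layout.nodes["A"][1] != layout.nodes["B"][1]

    def test_bubble_radius_zero_iff_zero_ccf(self):
        evo = cv.build_evolution(
            {"A": [50, 60], "B": [0, 20]}, {"A": "normal", "B": "A"}
        )
        layout = cv.shark_layout(evo)
        assert layout.radii[1, 0] == 0.0
        assert layout.radii[1, 1] > 0.0

    def test_bubble_radius_strictly_increasing(self):
        ccf = np.linspace(1, 100, 50).reshape(1, -1)
        evo = cv.build_evolution(
            ccf, ["normal"], np.arange(50, dtype=float), clone_labels=["A"]
        )
        layout = cv.shark_layout(evo)
        assert np.all(np.diff(layout.radii[0]) > 0)


class TestPlaiceLayout:
    def test_mirror_identity(self, branched):
        layout = cv.plaice_layout(branched)
        for lab in branched.clone_labels:
            up = layout.upper.support[lab]
            lo = layout.lower.support[lab]
            np.testing.assert_allclose(lo[:, 0], up[:, 0])
            np.testing.assert_allclose(lo[:, 1], -up[:, 2])
            np.testing.assert_allclose(lo[:, 2], -up[:, 1])

    def test_upper_is_bottom_mode(self, branched):
        layout = cv.plaice_layout(branched)
        lows = [
            layout.upper.support[f][:, 1].min() for f in branched.founders
        ]
        assert min(lows) == pytest.approx(0.0)

    def test_annotation_fills_with_source(self):
        evo = cv.build_evolution(
            {"A": [60, 70], "B": [0, 40]}, {"A": "normal", "B": "A"}
        )
        layout = cv.plaice_layout(evo, annotations={"B": "A"})
        assert layout.lower_fill["B"] == "A"
        assert layout.lower_fill["A"] is None

    def test_no_annotations_all_unfilled(self, branched):
        layout = cv.plaice_layout(branched)
        assert all(v is None for v in layout.lower_fill.values())

    def test_unknown_annotation_clone(self, branched):
        with pytest.raises(cv.CloneLookupError):
            cv.plaice_layout(branched, annotations={"Z": "A"})
        with pytest.raises(cv.CloneLookupError):
            cv.plaice_layout(branched, annotations={"A": "Z"})

    def test_mirror_band_layout_involution(self, branched):
        layout = cv.dolphin_layout(
            branched, config=cv.LayoutConfig(vertical_mode="bottom")
        )
        twice = mirror_band_layout(mirror_band_layout(layout))
        for lab in branched.clone_labels:
            np.testing.assert_allclose(
                twice.support[lab], layout.support[lab]
            )


class TestConfig:
    def test_birth_offset_positive(self):
        with pytest.raises(cv.UsageError):
            cv.LayoutConfig(birth_offset=0.0)

    def test_unknown_shape(self):
        with pytest.raises(cv.UsageError):
            cv.LayoutConfig(shape="bezier")

    def test_separate_independent_gap(self):
        evo = cv.build_evolution(
            {"A": [40], "B": [30]}, {"A": "normal", "B": "normal"}
        )
        layout = cv.dolphin_layout(
            evo,
            config=cv.LayoutConfig(
                vertical_mode="bottom", separate_independent=True,
                independent_gap=5.0,
            ),
        )
        a = band_at(layout, "A", 0)
        b = band_at(layout, "B", 0)
        lo_first = min(a[0], b[0])
        hi_first = min(a[1], b[1])
        assert abs(max(a[0], b[0]) - hi_first) == pytest.approx(5.0)
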