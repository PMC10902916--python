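"""Polyline simplification and refinement semantics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from morphoedit import (
    DouglasPeucker,
    DouglasPeuckerN,
    GenParams,
    Lang,
    Node,
    NthPoint,
    Opheim,
    PerpendicularDistance,
    RadialDistance,
    RefineParams,
    ReumannWitkam,
    generate,
    refine_section,
    resample_morphology,
    simplify_section,
)
from morphoedit.resample import ResampleError, simplify_indices
from morphoedit.swc_io import dumps


def chain_nodes(points, radii=None):
    pts = np.asarray(points, dtype=float)
    radii = radii if radii is not None else np.ones(len(pts))
    nodes, prev = [], -1
    for k, (p, r) in enumerate(zip(pts, radii)):
        nodes.append(Node(k + 1, 3, p, float(r), prev))
        prev = k + 1
    return nodes


ALL_METHODS = [
    NthPoint(4),
    RadialDistance(2.0),
    PerpendicularDistance(0.5),
    ReumannWitkam(0.5),
    Opheim(0.5, 5.0),
    Lang(0.5, 5),
    DouglasPeucker(0.5),
    DouglasPeuckerN(4),
]


class TestSimplifyExamples:
    def test_nth_point_keeps_stride_and_last(self):
        pts = [(i, 0, 0) for i in range(9)]
        assert simplify_indices(np.array(pts, float), NthPoint(4)) == [0, 4, 8]

    def test_nth_point_off_stride_last_kept(self):
        pts = [(i, 0, 0) for i in range(10)]
        assert simplify_indices(np.array(pts, float), NthPoint(4)) == [0, 4, 8, 9]

    def test_radial_distance_hand_trace(self):
        pts = [(i, 0, 0) for i in range(5)]
        assert simplify_indices(np.array(pts, float), RadialDistance(2.0)) == [0, 2, 4]

    def test_douglas_peucker_collinear_keeps_endpoints_only(self):
        pts = [(i, 0, 0) for i in range(10)]
        assert simplify_indices(np.array(pts, float), DouglasPeucker(0.01)) == [0, 9]

    def test_douglas_peucker_keeps_apex_above_tolerance(self):
        pts = np.array([(0, 0, 0), (1, 1, 0), (2, 0, 0)], float)
        assert simplify_indices(pts, DouglasPeucker(0.5)) == [0, 1, 2]
        assert simplify_indices(pts, DouglasPeucker(1.5)) == [0, 2]

    def test_douglas_peucker_n_keeps_exact_count(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(20, 3))
        kept = simplify_indices(pts, DouglasPeuckerN(7))
        assert len(kept) == 7 and kept[0] == 0 and kept[-1] == 19

    def test_kept_nodes_unmodified(self):
        nodes = chain_nodes([(i, np.sin(i), 0) for i in range(12)])
        out = simplify_section(nodes, DouglasPeucker(0.2))
        for n in out:
            assert n is nodes[n.id - 1]

    def test_short_section_returned_with_warning(self):
        nodes = chain_nodes([(0, 0, 0)])
        with pytest.warns(UserWarning):
            assert simplify_section(nodes, NthPoint(2)) == nodes

    def test_invalid_params_rejected(self):
        with pytest.raises(ResampleError):
            NthPoint(1)
        with pytest.raises(ResampleError):
            DouglasPeucker(-1)
        with pytest.raises(ResampleError):
            Opheim(2.0, 1.0)


@st.composite
def polylines(draw):
    n = draw(st.integers(min_value=2, max_value=30))
    coords = draw(
        st.lists(
            st.tuples(*[st.floats(-50, 50) for _ in range(3)]),
            min_size=n,
            max_size=n,
        )
    )
    return np.array(coords, dtype=float)


class TestSimplifyProperties:
    @pytest.mark.parametrize("params", ALL_METHODS, ids=lambda p: type(p).__name__)
    @given(pts=polylines())
    def test_subsequence_with_endpoints(self, params, pts):
        kept = simplify_indices(pts, params)
        assert kept == sorted(set(kept))
        assert kept[0] == 0 and kept[-1] == len(pts) - 1

    def test_douglas_peucker_matches_recursive_reference(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = rng.integers(2, 51)
            pts = rng.uniform(-20, 20, size=(n, 3))
            tol = rng.uniform(0.0, 5.0)
            assert simplify_indices(pts, DouglasPeucker(tol)) == _dp_reference(pts, tol)

    def test_douglas_peucker_monotone_in_tolerance(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(-20, 20, size=(40, 3))
        tols = sorted(rng.uniform(0, 6, size=6))
        kept = [set(simplify_indices(pts, DouglasPeucker(t))) for t in tols]
        for coarse, fine in zip(kept[1:], kept[:-1]):
            assert coarse <= fine


def _dp_reference(pts, tol):
    """Plain recursive Douglas-Peucker, written independently of the
    implementation under test."""

    def seg_dist(p, a, b):
        ab = b - a
        if np.dot(ab, ab) == 0:
            return float(np.linalg.norm(p - a))
        t = np.dot(p - a, ab) / np.dot(ab, ab)
        t = min(1.0, max(0.0, t))
        return float(np.linalg.norm(p - (a + t * ab)))

    def rec(a, b):
        if b - a < 2:
            return []
        ds = [seg_dist(pts[j], pts[a], pts[b]) for j in range(a + 1, b)]
        jmax = int(np.argmax(ds))
        if ds[jmax] <= tol:
            return []
        j = a + 1 + jmax
        return rec(a, j) + [j] + rec(j, b)

    return sorted({0, len(pts) - 1} | set(rec(0, len(pts) - 1)))


class TestRefine:
    def test_linear_density_example(self):
        nodes = chain_nodes([(0, 0, 0), (10, 0, 0)], radii=[1.0, 2.0])
        out = refine_section(nodes, RefineParams("linear", 0.5))
        assert [n.position[0] for n in out] == [0, 2, 4, 6, 8, 10]
        assert [n.radius for n in out] == pytest.approx([1.0, 1.2, 1.4, 1.6, 1.8, 2.0])
        assert len({n.id for n in out}) == len(out)

    def test_density_zero_is_identity(self):
        nodes = chain_nodes([(0, 0, 0), (10, 0, 0)])
        assert refine_section(nodes, RefineParams("linear", 0.0)) == nodes

    def test_cubic_degenerates_to_line_on_collinear_input(self):
        nodes = chain_nodes([(i * 3.0, 0, 0) for i in range(5)])
        out = refine_section(nodes, RefineParams("cubic_hermite", 2.0))
        pos = np.array([n.position for n in out])
        assert np.abs(pos[:, 1:]).max() < 1e-9
        assert np.all(np.diff(pos[:, 0]) > 0)

    def test_originals_present_and_unmodified(self):
        nodes = chain_nodes([(0, 0, 0), (5, 3, 1), (11, 2, -2), (16, 5, 0)])
        for method in ("linear", "cubic_hermite"):
            out = refine_section(nodes, RefineParams(method, 0.7))
            kept = [n for n in out if any(n is orig for orig in nodes)]
            assert kept == nodes  # same objects, same order

    def test_achieved_density_meets_request(self):
        nodes = chain_nodes([(0, 0, 0), (7, 2, 0), (9, 9, 3), (20, 9, 3)])
        density = 0.8
        out = refine_section(nodes, RefineParams("linear", density))
        pos = np.array([n.position for n in out])
        for a, b in zip(pos, pos[1:]):
            assert np.linalg.norm(b - a) <= 1.0 / density + 1e-9

    def test_linear_refinement_stays_on_polyline(self):
        nodes = chain_nodes([(0, 0, 0), (5, 3, 1), (11, 2, -2)])
        out = refine_section(nodes, RefineParams("linear", 1.3))
        pts = np.array([n.position for n in nodes])
        for n in out:
            d = min(
                _seg_dist(n.position, pts[i], pts[i + 1]) for i in range(len(pts) - 1)
            )
            assert d < 1e-9

    def test_cap_on_insertion_count(self):
        nodes = chain_nodes([(0, 0, 0), (10, 0, 0)])
        with pytest.raises(ResampleError):
            refine_section(nodes, RefineParams("linear", 2000.0))


def _seg_dist(p, a, b):
    ab = b - a
    t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0, 1)
    return float(np.linalg.norm(p - (a + t * ab)))


class TestResampleMorphology:
    def test_empty_selection_processes_all_sections(self, clean_morph):
        out = resample_morphology(clean_morph, NthPoint(4))
        for nr_in, nr_out in zip(clean_morph.neurites, out.neurites):
            for sec_in, sec_out in zip(nr_in.sections(), nr_out.sections()):
                k = len(sec_in.nodes)
                expected = len(set(range(0, k, 4)) | {k - 1})
                assert len(sec_out.nodes) == expected

    def test_selection_restricts_to_one_section(self, clean_morph):
        target = clean_morph.neurites[0].sections()[0]
        out = resample_morphology(clean_morph, NthPoint(4), selection={target.nodes[1].id})
        changed = 0
        for nr_in, nr_out in zip(clean_morph.neurites, out.neurites):
            for sec_in, sec_out in zip(nr_in.sections(), nr_out.sections()):
                if len(sec_in.nodes) != len(sec_out.nodes):
                    changed += 1
        assert changed == 1

    def test_soma_points_never_resampled(self, clean_morph):
        out = resample_morphology(clean_morph, NthPoint(4))
        assert len(out.soma.nodes) == len(clean_morph.soma.nodes)
        out2 = resample_morphology(clean_morph, RefineParams("linear", 2.0))
        assert len(out2.soma.nodes) == len(clean_morph.soma.nodes)

    def test_refine_then_simplify_never_grows(self, clean_morph):
        refined = resample_morphology(clean_morph, RefineParams("linear", 1.0))
        assert refined.n_nodes >= clean_morph.n_nodes
        simplified = resample_morphology(refined, RadialDistance(1.0))
        assert simplified.n_nodes <= refined.n_nodes

    def test_untouched_output_round_trips(self, clean_morph):
        out = resample_morphology(clean_morph, NthPoint(4))
        assert dumps(out)  # structurally valid, serializable
        refined = resample_morphology(clean_morph, RefineParams("cubic_hermite", 1.0))
        ids = [n.id for n in refined.nodes()]
        assert len(ids) == len(set(ids))
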