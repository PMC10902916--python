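"""Error-detection catalog: spec'd boundary behavior, brute-force oracle
agreement, purity and determinism."""

import itertools

import numpy as np
import pytest

from morphoedit import (
    CheckId,
    ErrorSpec,
    GenParams,
    ValidationConfig,
    generate,
    inject_errors,
    run_all,
)
from morphoedit.swc_io import dumps
from morphoedit.validate import (
    check_bifurcation_collision,
    check_constant_radius,
    check_nodes_inside_soma,
    check_oversampling,
    check_radius_order,
    check_repeated_nodes,
    check_root_distance,
    check_sharp_angles,
)
from conftest import mk


def soma_plus(chain):
    """Single-point soma (origin, R=5) plus a chain of (pos, radius) tuples."""
    recs = [(1, 1, (0, 0, 0), 5.0, -1)]
    prev = 1
    for k, (pos, radius) in enumerate(chain):
        recs.append((2 + k, 3, pos, radius, prev))
        prev = 2 + k
    return mk(recs)


class TestRepeatedNodes:
    def test_coincident_pair_is_one_group(self):
        m = soma_plus([((6, 0, 0), 1), ((9, 0, 0), 1), ((12, 0, 0), 1), ((12, 0, 0), 1)])
        found = check_repeated_nodes(m)
        assert [f.node_ids for f in found] == [(4, 5)]

    def test_distinct_nodes_clean(self, clean_morph):
        assert check_repeated_nodes(clean_morph) == []

    def test_tolerance_groups_triplet(self):
        m = soma_plus([((6, 0, 0), 1), ((9, 0, 0), 1), ((9, 0, 0), 1), ((9, 0, 0), 1)])
        found = check_repeated_nodes(m)
        assert [f.node_ids for f in found] == [(3, 4, 5)]


class TestOversampling:
    def test_segment_below_radius_sum_flagged(self):
        m = soma_plus([((6, 0, 0), 1), ((7.5, 0, 0), 1)])  # 1.5 < 2
        found = check_oversampling(m)
        assert [f.node_ids for f in found] == [(2, 3)]

    def test_segment_above_threshold_clean(self):
        m = soma_plus([((6, 0, 0), 1), ((8.5, 0, 0), 1)])  # 2.5 > 2
        assert check_oversampling(m) == []

    def test_exact_threshold_not_flagged(self):
        m = soma_plus([((6, 0, 0), 1), ((8, 0, 0), 1)])  # exactly 2.0
        assert check_oversampling(m) == []

    def test_fixed_threshold_mode(self):
        m = soma_plus([((6, 0, 0), 0.1), ((8.5, 0, 0), 0.1)])
        cfg = ValidationConfig(oversampling_threshold=3.0)
        assert len(check_oversampling(m, cfg)) == 1


class TestInsideSoma:
    def test_node_inside_sphere_flagged(self):
        m = soma_plus([((1, 0, 0), 0.5), ((7, 0, 0), 0.5)])
        found = check_nodes_inside_soma(m)
        assert [f.node_ids for f in found] == [(2,)]

    def test_node_outside_clean(self):
        m = soma_plus([((6, 0, 0), 0.5)])
        assert check_nodes_inside_soma(m) == []

    def test_node_exactly_on_surface_not_flagged(self):
        m = soma_plus([((5, 0, 0), 0.5), ((8, 0, 0), 0.5)])
        assert check_nodes_inside_soma(m) == []


class TestRootDistance:
    def test_distant_root_flagged(self):
        m = soma_plus([((25, 0, 0), 1)])  # 25 > 4 * 5
        found = check_root_distance(m)
        assert [f.node_ids for f in found] == [(2,)]

    def test_near_root_clean(self):
        m = soma_plus([((10, 0, 0), 1)])
        assert check_root_distance(m) == []

    def test_exact_limit_not_flagged(self):
        m = soma_plus([((20, 0, 0), 1)])
        assert check_root_distance(m) == []


class TestSharpAngles:
    def test_doubling_back_trajectory_flagged(self):
        m = soma_plus([((0, 0, 0), 0.01), ((1, 0, 0), 0.01), ((0.5, 0.1, 0), 0.01)])
        found = check_sharp_angles(m)
        assert [f.node_ids for f in found] == [(2, 3, 4)]
        assert found[0].details["angle_deg"] == pytest.approx(11.31, abs=0.01)

    def test_collinear_trajectory_clean(self):
        m = soma_plus([((6, 0, 0), 0.1), ((9, 0, 0), 0.1), ((12, 0, 0), 0.1)])
        assert check_sharp_angles(m) == []

    def test_right_angle_not_flagged(self):
        m = soma_plus([((0, 0, 0), 0.01), ((1, 0, 0), 0.01), ((1, 1, 0), 0.01)])
        assert check_sharp_angles(m) == []

    def test_zero_length_segment_skipped(self):
        m = soma_plus([((6, 0, 0), 0.1), ((6, 0, 0), 0.1), ((9, 0, 0), 0.1)])
        assert check_sharp_angles(m) == []


class TestRadiusOrder:
    def _fork(self, child_radius):
        return mk(
            [
                (1, 1, (0, 0, 0), 5.0, -1),
                (2, 3, (6, 0, 0), 0.5, 1),
                (3, 3, (12, 0, 0), 0.5, 2),
                (4, 3, (18, 4, 0), child_radius, 3),
                (5, 3, (18, -4, 0), 0.3, 3),
            ]
        )

    def test_thicker_child_flagged(self):
        found = check_radius_order(self._fork(0.8))
        assert [f.node_ids for f in found] == [(3, 4)]

    def test_equal_radius_passes(self):
        assert check_radius_order(self._fork(0.5)) == []

    def test_thinner_child_passes(self):
        assert check_radius_order(self._fork(0.4)) == []


class TestConstantRadius:
    def test_constant_neurite_flagged(self):
        m = soma_plus([((6, 0, 0), 1.0), ((9, 0, 0), 1.0), ((12, 0, 0), 1.0)])
        found = check_constant_radius(m)
        assert [f.node_ids for f in found] == [(2, 3, 4)]

    def test_varying_neurite_clean(self):
        m = soma_plus([((6, 0, 0), 1.0), ((9, 0, 0), 1.0), ((12, 0, 0), 1.1)])
        assert check_constant_radius(m) == []

    def test_single_node_neurite_vacuously_constant(self):
        m = soma_plus([((6, 0, 0), 1.0)])
        assert len(check_constant_radius(m)) == 1


class TestBifurcationCollision:
    def _tri(self, starts):
        recs = [
            (1, 1, (0, 0, 0), 5.0, -1),
            (2, 3, (6, 0, 0), 1.0, 1),
            (3, 3, (12, 0, 0), 1.0, 2),
        ]
        for k, pos in enumerate(starts):
            recs.append((4 + k, 3, pos, 1.0, 3))
        return mk(recs)

    def test_overlapping_children_flagged(self):
        m = self._tri([(13, 0, 0), (13.5, 0, 0)])  # 0.5 < 2
        found = check_bifurcation_collision(m)
        assert [f.node_ids for f in found] == [(4, 5)]

    def test_separated_children_clean(self):
        m = self._tri([(13, 5, 0), (13, -5, 0)])
        assert check_bifurcation_collision(m) == []

    def test_trifurcation_single_overlapping_pair(self):
        m = self._tri([(13, 0, 0), (13.5, 0, 0), (12, 8, 0)])
        assert len(check_bifurcation_collision(m)) == 1


# ---------------------------------------------------------------------------
# brute-force oracles (independent, deliberately naive implementations)


def oracle_repeated(m, tol=1e-6):
    nodes = list(m.nodes())
    n = len(nodes)
    adj = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(nodes[i].position - nodes[j].position) <= tol:
                adj[i].add(j)
                adj[j].add(i)
    groups, visited = [], set()
    for i in range(n):
        if i in visited or not adj[i]:
            continue
        comp, frontier = set(), {i}
        while frontier:
            k = frontier.pop()
            comp.add(k)
            visited.add(k)
            frontier |= adj[k] - comp
        groups.append(tuple(sorted(nodes[k].id for k in comp)))
    return sorted(groups)


def oracle_oversampling(m, tol=1e-6):
    out = []
    for neurite in m.neurites:
        for sec in neurite.sections():
            for a, b in zip(sec.nodes, sec.nodes[1:]):
                d = np.linalg.norm(a.position - b.position)
                if tol < d < a.radius + b.radius:
                    out.append((a.id, b.id))
    return sorted(out)


def oracle_sharp(m, threshold=90.0, tol=1e-6):
    out = []
    for neurite in m.neurites:
        for sec in neurite.sections():
            for i, j, k in zip(sec.nodes, sec.nodes[1:], sec.nodes[2:]):
                v1, v2 = i.position - j.position, k.position - j.position
                n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
                if n1 <= tol or n2 <= tol:
                    continue
                cosang = np.dot(v1, v2) / (n1 * n2)
                if np.degrees(np.arccos(np.clip(cosang, -1, 1))) < threshold:
                    out.append((i.id, j.id, k.id))
    return sorted(out)


def oracle_inside_soma(m):
    from morphoedit import soma_sphere

    c, r = soma_sphere(m.soma)
    return sorted(
        n.id for n in m.neurite_nodes() if np.linalg.norm(n.position - c) < r
    )


@pytest.mark.parametrize("seed", range(8))
def test_checks_match_brute_force_oracles(seed):
    """Detector output equals exhaustive per-node/pairwise scans on small
    morphologies with one injected instance of each error."""
    m = generate(GenParams(n_neurites=3, depth=2, nodes_per_section=(3, 5), seed=seed))
    assert m.n_nodes <= 120
    mutated, _ = inject_errors(m, ErrorSpec.one_of_each(seed=seed))

    rep = check_repeated_nodes(mutated)
    assert sorted(f.node_ids for f in rep) == oracle_repeated(mutated)
    over = check_oversampling(mutated)
    assert sorted(f.node_ids for f in over) == oracle_oversampling(mutated)
    sharp = check_sharp_angles(mutated)
    assert sorted(f.node_ids for f in sharp) == oracle_sharp(mutated)
    inside = check_nodes_inside_soma(mutated)
    assert sorted(f.node_ids[0] for f in inside) == oracle_inside_soma(mutated)


@pytest.mark.parametrize("seed", range(20))
def test_injected_errors_recovered_exactly(seed):
    """Precision = recall = 1 against injector ground truth."""
    m = generate(GenParams(seed=seed))
    mutated, truth = inject_errors(m, ErrorSpec.one_of_each(seed=seed))
    got = {(f.check_id, f.node_ids) for f in run_all(mutated)}
    want = {(f.check_id, f.node_ids) for f in truth}
    assert got == want
    assert len(want) == len(CheckId)


def test_checks_are_pure(clean_morph):
    mutated, _ = inject_errors(clean_morph, ErrorSpec.one_of_each(seed=1))
    before = dumps(mutated)
    run_all(mutated)
    assert dumps(mutated) == before


def test_run_all_deterministic_and_sorted(clean_morph):
    mutated, _ = inject_errors(clean_morph, ErrorSpec.one_of_each(seed=2))
    a = run_all(mutated)
    b = run_all(mutated)
    assert [(f.check_id, f.node_ids) for f in a] == [(f.check_id, f.node_ids) for f in b]
    order = list(CheckId)
    keys = [(order.index(f.check_id), min(f.node_ids)) for f in a]
    assert keys == sorted(keys)


def test_finding_json_shape(clean_morph):
    mutated, _ = inject_errors(clean_morph, ErrorSpec({CheckId.REPEATED_NODES: 1}, seed=3))
    payload = run_all(mutated)[0].to_json()
    assert list(payload) == ["check_id", "node_ids", "section", "details", "actions"]
    assert payload["check_id"] == "repeated_nodes"
    assert "remove" in payload["actions"]


def test_config_rejects_negative_thresholds():
    with pytest.raises(ValueError):
        ValidationConfig(position_tolerance=-1)
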