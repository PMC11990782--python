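"""Association costs, gating, Hungarian assignment, matching cascade."""

import itertools

import numpy as np
import pytest

from uavtrack.association import (
    DescriptorGallery,
    Detection,
    combined_cost,
    cosine_matrix,
    gate_cost,
    mahalanobis_matrix,
    matching_cascade,
    solve_assignment,
)
from uavtrack.kalman import Measurement


def unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


class TestMahalanobis:
    def test_examples(self):
        y = np.array([10.0, 10.0, 1.0, 20.0])
        S = np.eye(4)
        # zero residual, unit quadratic form, scaled quadratic form
        d = mahalanobis_matrix(
            [(y, S), (y, np.diag([4.0, 1, 1, 1]))],
            [Measurement(y), Measurement(y + [1, 0, 0, 0]), Measurement(y + [2, 0, 0, 0])],
        )
        assert d[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert d[0, 1] == pytest.approx(1.0)
        assert d[1, 2] == pytest.approx(1.0)

    def test_invariant_under_linear_reparameterization(self, rng):
        base = np.array([50.0, 60.0, 1.0, 25.0])
        for _ in range(10):
            A = np.eye(4) + 0.05 * rng.normal(size=(4, 4))
            S = np.eye(4) + 0.2 * random_psd4(rng)
            z = base + rng.normal(0, 2, 4) * [1, 1, 0.05, 1]
            d0 = mahalanobis_matrix([(base, S)], [Measurement(z)])[0, 0]
            Az = A @ z
            if np.all(Az[[2, 3]] > 0):  # transformed vector must stay valid
                d1 = mahalanobis_matrix([(A @ base, A @ S @ A.T)], [Measurement(Az)])[0, 0]
                assert d1 == pytest.approx(d0, rel=1e-9)

    def test_singular_covariance_names_track(self):
        y = np.array([1.0, 1, 1, 1])
        with pytest.raises(ValueError, match="track index 0"):
            mahalanobis_matrix([(y, np.zeros((4, 4)))], [Measurement(y)])


def random_psd4(rng):
    A = rng.normal(size=(4, 4))
    return A @ A.T + 1e-3 * np.eye(4)


class TestCosine:
    def test_min_rule_and_bounds(self, rng):
        r = unit(rng.normal(size=16))
        # gallery members with known dot products 0.9 and 0.4 against r
        perp = unit(rng.normal(size=16) - (rng.normal(size=16) @ r) * r)
        perp = unit(perp - (perp @ r) * r)
        u = unit(0.9 * r + np.sqrt(1 - 0.81) * perp)
        v = unit(0.4 * r + np.sqrt(1 - 0.16) * perp)
        gal = DescriptorGallery(budget=10)
        gal.add(u)
        gal.add(v)
        d = cosine_matrix([gal], [r])
        assert d[0, 0] == pytest.approx(0.1, abs=1e-9)

    def test_identical_and_orthogonal(self):
        e0, e1 = np.eye(8)[0], np.eye(8)[1]
        gal = DescriptorGallery()
        gal.add(e0)
        d = cosine_matrix([gal], [e0, e1])
        assert d[0, 0] == pytest.approx(0.0)
        assert d[0, 1] == pytest.approx(1.0)

    def test_empty_gallery_is_infeasible(self):
        d = cosine_matrix([DescriptorGallery()], [np.eye(4)[0]])
        assert np.isinf(d[0, 0])

    def test_ring_buffer_evicts_oldest(self):
        gal = DescriptorGallery(budget=2)
        for k in range(3):
            gal.add(np.eye(8)[k])
        d = cosine_matrix([gal], [np.eye(8)[0]])
        assert d[0, 0] == pytest.approx(1.0)  # e0 evicted

    def test_non_unit_descriptor_renormalized_with_warning(self):
        with pytest.warns(UserWarning, match="re-normalis"):
            det = Detection(box=[0, 0, 5, 5], confidence=0.9, descriptor=[2.0, 0, 0, 0])
        assert np.linalg.norm(det.descriptor) == pytest.approx(1.0)


class TestCombinedAndGate:
    def test_lambda_endpoints_and_blend(self):
        d1 = np.array([[0.2]])
        d2 = np.array([[0.4]])
        assert combined_cost(d1, d2, 1.0)[0, 0] == pytest.approx(0.2)
        assert combined_cost(d1, d2, 0.0)[0, 0] == pytest.approx(0.4)
        assert combined_cost(d1, d2, 0.5)[0, 0] == pytest.approx(0.3)

    def test_infeasible_propagates(self):
        c = combined_cost(np.array([[np.inf]]), np.array([[0.1]]), 0.5)
        assert np.isinf(c[0, 0])

    def test_lambda_out_of_range(self):
        with pytest.raises(ValueError):
            combined_cost(np.zeros((1, 1)), np.zeros((1, 1)), 1.5)

    def test_gate_elementwise_oracle(self, rng):
        cost = rng.uniform(0, 1, (4, 5))
        d1 = rng.uniform(0, 20, (4, 5))
        gated = gate_cost(cost, d1, motion_gate=9.4877, appearance_gate=0.5)
        for i in range(4):
            for j in range(5):
                if d1[i, j] > 9.4877 or cost[i, j] > 0.5:
                    assert np.isinf(gated[i, j])
                else:
                    assert gated[i, j] == cost[i, j]

    def test_gate_is_idempotent(self, rng):
        cost = rng.uniform(0, 1, (6, 6))
        d1 = rng.uniform(0, 20, (6, 6))
        g1 = gate_cost(cost, d1, 9.4877, 0.5)
        g2 = gate_cost(g1, d1, 9.4877, 0.5)
        np.testing.assert_array_equal(g1, g2)


def brute_force_min_cost(cost):
    n, m = cost.shape
    best = (0.0, [])
    best_total = None
    k = min(n, m)
    rows = range(n)
    for rsub in itertools.permutations(rows, k):
        for csub in itertools.permutations(range(m), k):
            pairs = [(r, c) for r, c in zip(rsub, csub) if np.isfinite(cost[r, c])]
            total = sum(cost[r, c] for r, c in pairs)
            # prefer larger cardinality, then smaller cost (one-to-one optimum
            # of the solver maximises matched finite pairs at min total cost)
            key = (-len(pairs), total)
            if best_total is None or key < best_total:
                best_total = key
                best = (total, pairs)
    return best


class TestAssignment:
    def test_single_cell(self):
        matches, ur, uc = solve_assignment(np.array([[0.3]]))
        assert matches == [(0, 0)] and ur == [] and uc == []

    def test_diagonal_optimum(self):
        matches, _, _ = solve_assignment(np.array([[1.0, 10.0], [10.0, 1.0]]))
        assert sorted(matches) == [(0, 0), (1, 1)]

    def test_infeasible_never_matched(self):
        matches, ur, uc = solve_assignment(np.full((2, 2), np.inf))
        assert matches == [] and ur == [0, 1] and uc == [0, 1]

    def test_empty_inputs(self):
        matches, ur, uc = solve_assignment(np.zeros((0, 3)))
        assert matches == [] and ur == [] and uc == [0, 1, 2]

    def test_matches_brute_force_on_random_matrices(self, rng):
        """Total assignment cost equals exhaustive permutation minimum for
        100 seeded random matrices up to 5x5."""
        for trial in range(100):
            n = int(rng.integers(1, 6))
            m = int(rng.integers(1, 6))
            cost = rng.uniform(0, 1, (n, m))
            # sprinkle infeasible entries
            mask = rng.random((n, m)) < 0.2
            cost[mask] = np.inf
            matches, _, _ = solve_assignment(cost)
            total = sum(cost[r, c] for r, c in matches)
            bf_total, bf_pairs = brute_force_min_cost(cost)
            assert len(matches) == len(bf_pairs)
            assert total == pytest.approx(bf_total, abs=1e-9)


class TestMatchingCascade:
    def test_single_age_group_equals_plain_assignment(self, rng):
        cost = rng.uniform(0, 1, (3, 3))
        matches, ut, ud = matching_cascade(
            [0, 0, 0], [0, 1, 2], lambda r, c: cost[np.ix_(r, c)]
        )
        plain, put, pud = solve_assignment(cost)
        assert sorted(matches) == sorted(plain)

    def test_fresh_track_outranks_stale(self):
        # both tracks want detection 0; the fresher (age 0) track wins
        base = np.array([[0.5], [0.1]])  # stale track is actually closer

        def builder(r, c):
            return base[np.ix_(r, c)]

        matches, ut, ud = matching_cascade([1, 0], [0], builder)
        assert matches == [(1, 0)]
        assert ut == [0]

    def test_three_group_hand_trace(self):
        # age 0: t0; age 1: t1; age 2: t2 — hand-traced cascade outcome
        base = np.array(
            [
                [0.2, 0.1, np.inf],
                [0.3, 0.01, np.inf],
                [np.inf, np.inf, 0.4],
            ]
        )

        def builder(r, c):
            return base[np.ix_(r, c)]

        matches, ut, ud = matching_cascade([0, 1, 2], [0, 1, 2], builder)
        # t0 (age 0) takes det 1 first even though t1 is a better global fit
        assert sorted(matches) == [(0, 1), (1, 0), (2, 2)]
        assert ut == [] and ud == []

    def test_each_detection_matched_at_most_once(self, rng):
        cost = rng.uniform(0, 1, (6, 4))
        ages = [0, 0, 1, 1, 2, 2]
        matches, ut, ud = matching_cascade(
            ages, list(range(4)), lambda r, c: cost[np.ix_(r, c)]
        )
        dets = [d for _, d in matches]
        assert len(dets) == len(set(dets))
        tracks = [t for t, _ in matches]
        assert len(tracks) == len(set(tracks))
        assert len(matches) + len(ud) == 4
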