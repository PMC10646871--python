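import numpy as np
import pytest

from ecprofiles import (
    EulerProfile,
    betti_curve,
    build_curve,
    distance_curves,
    distance_profiles,
    ec_at,
    random_diagram,
    wasserstein1,
)


def _random_curve(rng, n_jumps=6, span=3.0, balanced=True):
    jumps = rng.uniform(0, span, n_jumps)
    deltas = rng.integers(-2, 3, n_jumps)
    contribs = [((float(f),), int(d)) for f, d in zip(jumps, deltas)]
    if balanced:
        total = int(deltas.sum())
        contribs.append(((float(span),), 1 - total))  # force terminal value 1
    return build_curve(contribs)


class TestDistanceCurves:
    def test_identity(self, rng):
        c = _random_curve(rng)
        assert distance_curves(c, c) == 0.0

    def test_unit_rectangle(self):
        a = build_curve([((0.0,), 1), ((2.0,), -1)])
        b = build_curve([])
        assert distance_curves(a, b, upper=2.0) == pytest.approx(2.0)
        assert distance_curves(a, b) == pytest.approx(2.0)

    def test_absolute_value_not_signed_area(self):
        # curves +1 then -1 vs 0: the signed sum would telescope to 0
        a = build_curve([((0.0,), 1), ((1.0,), -2), ((2.0,), 1)])
        b = build_curve([])
        assert distance_curves(a, b, upper=2.0) == pytest.approx(2.0)

    def test_diverging_terminal_values_need_a_bound(self):
        a = build_curve([((0.0,), 2)])
        b = build_curve([((0.0,), 1)])
        with pytest.raises(ValueError, match="unbounded|upper"):
            distance_curves(a, b)
        assert distance_curves(a, b, upper=3.0) == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_riemann_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b = _random_curve(rng), _random_curve(rng)
        upper = 3.5
        ts = np.arange(0.0, upper, 1e-4)
        dense = float(
            np.sum([abs(ec_at(a, t) - ec_at(b, t)) for t in ts]) * 1e-4
        )
        assert distance_curves(a, b, upper=upper) == pytest.approx(dense, abs=1e-3)

    def test_symmetry_and_triangle_inequality(self, rng):
        curves = [_random_curve(rng) for _ in range(3)]
        d = lambda x, y: distance_curves(x, y, upper=4.0)
        a, b, c = curves
        assert d(a, b) == pytest.approx(d(b, a))
        assert d(a, c) <= d(a, b) + d(b, c) + 1e-12


def _random_profile(rng, n=12, arity=2, span=1.0):
    locs = rng.uniform(0, span, size=(n, arity))
    deltas = rng.choice([-1, 1], n)
    return EulerProfile.from_contributions(zip(map(tuple, locs), deltas))


class TestDistanceProfiles:
    def test_identity(self, rng):
        p = _random_profile(rng)
        assert distance_profiles(p, p, (1.0, 1.0)) == 0.0

    def test_unit_cone_volume(self):
        p = EulerProfile.from_contributions([((0.0, 0.0), 1)])
        empty = EulerProfile(np.empty((0, 2)), np.empty(0, dtype=np.int64))
        assert distance_profiles(p, empty, (1.0, 1.0)) == pytest.approx(1.0)

    def test_missing_truncation_rejected(self, rng):
        p = _random_profile(rng)
        with pytest.raises(ValueError, match="truncat"):
            distance_profiles(p, p, None)

    def test_perturbed_vertex_rectangle_area_and_linear_growth(self):
        # one vertex moved by eps along the first axis: the difference region
        # is a rectangle of width eps reaching up to the truncation
        g = (0.3, 0.4)
        eps = 0.05
        a = EulerProfile.from_contributions([(g, 1)])
        b = EulerProfile.from_contributions([((g[0] + eps, g[1]), 1)])
        for f_inf in (1.0, 2.0, 4.0):
            expected = eps * (f_inf - g[1])
            got = distance_profiles(a, b, (f_inf, f_inf))
            assert got == pytest.approx(expected)
            # Prop-style bound: |K| * n * eps^(n-1) * f_inf with |K| = 1, n = 2
            assert got <= 1 * 2 * eps * f_inf + 1e-12

    def test_metric_axioms_on_random_triples(self, rng):
        trunc = (1.0, 1.0)
        for _ in range(20):
            a, b, c = (_random_profile(rng, n=8) for _ in range(3))
            dab = distance_profiles(a, b, trunc)
            assert dab == pytest.approx(distance_profiles(b, a, trunc))
            assert dab >= 0
            assert dab <= (
                distance_profiles(a, c, trunc) + distance_profiles(c, b, trunc) + 1e-9
            )

    def test_one_parameter_profile_equals_curve_distance(self, rng):
        for _ in range(10):
            locs = rng.uniform(0, 2, size=(8, 1))
            deltas = rng.choice([-1, 1], 8)
            contribs = list(zip(map(tuple, locs), deltas))
            pa = EulerProfile.from_contributions(contribs[:4])
            pb = EulerProfile.from_contributions(contribs[4:])
            ca = build_curve(contribs[:4])
            cb = build_curve(contribs[4:])
            assert distance_profiles(pa, pb, (2.5,)) == pytest.approx(
                distance_curves(ca, cb, upper=2.5)
            )

    def test_three_parameter_profile_against_dense_grid(self, rng):
        a = _random_profile(rng, n=6, arity=3)
        b = _random_profile(rng, n=6, arity=3)
        trunc = (1.0, 1.0, 1.0)
        exact = distance_profiles(a, b, trunc)
        step = 0.02
        ts = np.arange(0, 1.0, step) + step / 2
        dense = 0.0
        from ecprofiles import ecp_at

        for x in ts:
            for y in ts:
                for z in ts:
                    dense += abs(ecp_at(a, (x, y, z)) - ecp_at(b, (x, y, z)))
        dense *= step**3
        assert exact == pytest.approx(dense, rel=0.15, abs=0.02)


class TestCurveStabilityViaDiagrams:
    def test_ecc_distance_bounded_by_summed_wasserstein(self):
        # Euler curves as alternating sums of Betti curves in dimensions 0, 1:
        # the L1 distance is bounded by the summed per-dimension 2*W1 bound.
        for seed in range(25):
            rng = np.random.default_rng(seed)
            dgms_x = [random_diagram(int(rng.integers(1, 5)), seed=seed * 4 + k)
                      for k in range(2)]
            dgms_y = [random_diagram(int(rng.integers(1, 5)), seed=seed * 4 + 2 + k)
                      for k in range(2)]

            def ecc(dgms):
                contribs = []
                for k, dgm in enumerate(dgms):
                    sign = (-1) ** k
                    for loc, d in betti_curve(dgm).contributions():
                        contribs.append((loc, sign * d))
                return build_curve(contribs)

            lhs = distance_curves(ecc(dgms_x), ecc(dgms_y), upper=20.0)
            rhs = sum(2.0 * wasserstein1(a, b) for a, b in zip(dgms_x, dgms_y))
            assert lhs <= rhs + 1e-9
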