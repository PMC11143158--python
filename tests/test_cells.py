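"""Grid-cell lattice geometry and firing-rate model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gridcog import frames
from gridcog.cells import (
    FiringParams,
    GridCell,
    basis_matrix,
    basis_vectors,
    field_centers,
    firing_rate,
    lattice_distance,
    nearest_center_distance_along_axis,
    place_to_grid,
    place_to_grid_matrix,
    round_half_away,
)

SIN60 = math.sin(math.pi / 3)


def cells_strategy():
    return st.builds(
        GridCell,
        st.floats(0.5, 2.0),
        st.floats(0.0, math.pi / 3 - 1e-6),
        st.tuples(st.floats(0.0, 0.999), st.floats(0.0, 0.999)),
    )


class TestGridCellType:
    def test_invalid_spacing_rejected(self):
        for s in (0.0, -1.0, float("nan")):
            with pytest.raises(ValueError):
                GridCell(s)

    def test_theta_wrapped_to_hexagonal_sector(self):
        assert GridCell(1.0, math.pi / 3 + 0.1).theta == pytest.approx(0.1)
        assert GridCell(1.0, -0.1).theta == pytest.approx(math.pi / 3 - 0.1)

    def test_phase_wrapped_to_unit_cell(self):
        np.testing.assert_allclose(GridCell(1.0, 0.0, (1.5, -0.25)).phase, (0.5, 0.75))


class TestBasis:
    @pytest.mark.parametrize(
        "s, theta, eps1, eps2",
        [
            (1.0, 0.0, (1, 0), (0.5, SIN60)),
            (2.0, 0.0, (2, 0), (1, 2 * SIN60)),
            (1.0, math.pi / 4, (0.70710678, 0.70710678), (-0.25881905, 0.96592583)),
        ],
    )
    def test_basis_vectors(self, s, theta, eps1, eps2):
        e1, e2 = basis_vectors(GridCell(s, theta))
        np.testing.assert_allclose(e1, eps1, atol=1e-8)
        np.testing.assert_allclose(e2, eps2, atol=1e-8)

    @settings(max_examples=50, deadline=None)
    @given(cells_strategy())
    def test_basis_vectors_subtend_sixty_degrees(self, cell):
        e1, e2 = basis_vectors(cell)
        cosang = e1 @ e2 / (np.linalg.norm(e1) * np.linalg.norm(e2))
        assert cosang == pytest.approx(0.5, abs=1e-12)

    def test_place_to_grid_matrix_maps_basis_to_units(self):
        cell = GridCell(1.0, 0.0)
        R = place_to_grid_matrix(cell)
        np.testing.assert_allclose(R @ (1, 0), (1, 0), atol=1e-12)
        np.testing.assert_allclose(R @ (0.5, SIN60), (0, 1), atol=1e-12)

    def test_place_to_grid_matrix_numeric(self):
        R = place_to_grid_matrix(GridCell(1.0, math.pi / 4))
        np.testing.assert_allclose(
            R, [[1.11535507, 0.29885849], [-0.81649658, 0.81649658]], atol=1e-7
        )

    @settings(max_examples=50, deadline=None)
    @given(cells_strategy())
    def test_determinant_identity(self, cell):
        det = np.linalg.det(place_to_grid_matrix(cell))
        assert det * cell.s**2 * SIN60 == pytest.approx(1.0, abs=1e-12)


class TestPlaceToGrid:
    def test_origin_maps_to_minus_phase(self):
        cell = GridCell(1.0, math.pi / 4, (0.5, 0.0))
        np.testing.assert_allclose(place_to_grid(cell, (0, 0)), (-0.5, 0.0), atol=1e-12)

    def test_basis_vector_maps_to_unit_coordinate(self):
        cell = GridCell(1.0, math.pi / 4)
        e1, _ = basis_vectors(cell)
        np.testing.assert_allclose(place_to_grid(cell, e1), (1, 0), atol=1e-12)

    def test_vectorised_matches_scalar(self, eq_cell, rng):
        pts = rng.uniform(-3, 3, (50, 2))
        batch = place_to_grid(eq_cell, pts)
        for p, g in zip(pts, batch):
            np.testing.assert_allclose(place_to_grid(eq_cell, p), g, atol=1e-12)


class TestLatticeDistance:
    @pytest.mark.parametrize(
        "g, expected",
        [((0, 0), 0.0), ((2.0, -3.0), 0.0), ((0.5, 0), 0.5), ((0.25, -0.25), math.hypot(0.25, 0.25))],
    )
    def test_known_values(self, g, expected):
        assert lattice_distance(g) == pytest.approx(expected, abs=1e-12)

    def test_ties_round_away_from_zero(self):
        np.testing.assert_allclose(round_half_away([0.5, -0.5, 1.5, -2.5]), [1, -1, 2, -3])

    def test_squared_form(self):
        assert lattice_distance((0.5, 0.5), squared=True) == pytest.approx(0.5)


class TestFiringRate:
    def test_midpoint_at_threshold(self):
        # at d/s == zeta the sigmoid crosses exactly 1/2
        cell = GridCell(1.0, 0.0)
        p = FiringParams(zeta=0.4, kappa=3.0)
        assert firing_rate(cell, p, (0.4, 0.0)) == pytest.approx(0.5, abs=1e-12)

    def test_maximum_value_at_center(self):
        rate = firing_rate(GridCell(1.0), FiringParams(0.4, 3.0), (0, 0))
        assert rate == pytest.approx(0.5 + math.atan(1.2) / math.pi, abs=1e-12)  # 0.77886

    def test_far_limit_approaches_zero(self):
        # largest possible lattice distance at kappa -> large is still bounded,
        # so probe the arctan limit directly with a huge kappa
        rate = firing_rate(GridCell(1.0), FiringParams(0.01, 1e9), (0.5, 0.5))
        assert 0.0 <= rate < 1e-6

    @settings(max_examples=30, deadline=None)
    @given(cells_strategy(), st.tuples(st.floats(-5, 5), st.floats(-5, 5)),
           st.integers(-3, 3), st.integers(-3, 3))
    def test_periodicity_under_lattice_translation(self, cell, p, a, b):
        params = FiringParams(0.4, 3.0)
        e1, e2 = basis_vectors(cell)
        p = np.asarray(p)
        r0 = firing_rate(cell, params, p)
        r1 = firing_rate(cell, params, p + a * e1 + b * e2)
        assert r1 == pytest.approx(r0, abs=1e-9)

    def test_rates_bounded_and_monotone_in_distance(self, eq_cell, fparams, rng):
        pts = rng.uniform(-5, 5, (2000, 2))
        rates = firing_rate(eq_cell, fparams, pts)
        assert np.all(rates >= 0) and np.all(rates <= 1)
        d = lattice_distance(place_to_grid(eq_cell, pts))
        order = np.argsort(d)
        assert np.all(np.diff(rates[order]) <= 1e-12)

    def test_greater_kappa_sharpens_the_bump(self):
        cell = GridCell(1.0)
        lo, hi = FiringParams(0.4, 1.0), FiringParams(0.4, 6.0)
        inside, outside = (0.1, 0.0), (0.48, 0.0)  # d/s below and above zeta
        assert firing_rate(cell, hi, inside) > firing_rate(cell, lo, inside)
        assert firing_rate(cell, hi, outside) < firing_rate(cell, lo, outside)

    def test_greater_zeta_widens_the_field(self):
        cell = GridCell(1.0)
        radius = {}
        for zeta in (0.2, 0.45):
            params = FiringParams(zeta, 3.0)
            xs = np.linspace(0, 0.5, 501)
            rates = firing_rate(cell, params, np.column_stack([xs, np.zeros_like(xs)]))
            radius[zeta] = xs[np.argmin(np.abs(rates - 0.5))]
        assert radius[0.45] > radius[0.2]


class TestFieldCenters:
    def test_unit_square_contains_expected_centers(self):
        centers = field_centers(GridCell(1.0, 0.0), None, (0, 0, 1, 1))
        want = [(0, 0), (1, 0), (0.5, SIN60)]
        for w in want:
            assert np.min(np.linalg.norm(centers - np.array(w), axis=1)) < 1e-9

    def test_center_count_matches_lattice_density(self, eq_cell):
        centers = field_centers(eq_cell, None, (0, 0, 5, 5))
        # area / unit-cell area = 25 / sin60 ~ 28.9, plus boundary effects
        assert 25 <= len(centers) <= 40

    def test_phase_translates_the_center_set(self):
        base = field_centers(GridCell(1.0, 0.3), None, (-3, -3, 3, 3))
        shifted = field_centers(GridCell(1.0, 0.3, (0.5, 0.0)), None, (-3, -3, 3, 3))
        e1, _ = basis_vectors(GridCell(1.0, 0.3))
        checked = 0
        for c in shifted:
            pre = c - 0.5 * e1  # counterpart on the unshifted lattice
            if np.all(np.abs(pre) <= 3 - 1e-6):
                assert np.min(np.linalg.norm(base - pre, axis=1)) < 1e-9
                checked += 1
        assert checked >= 10

    def test_every_center_is_an_integer_lattice_point(self, eq_cell):
        centers = field_centers(eq_cell, None, (0, 0, 5, 5))
        g = place_to_grid(eq_cell, centers)
        np.testing.assert_allclose(g, np.round(g), atol=1e-9)

    def test_centers_respect_world_frame(self):
        T = frames.from_angle_translation(0.4, (1.0, -2.0))  # world -> place
        cell = GridCell(1.0, 0.1, (0.2, 0.7))
        centers = field_centers(cell, T, (-4, -4, 4, 4))
        g = place_to_grid(cell, frames.apply(T, centers))
        np.testing.assert_allclose(g, np.round(g), atol=1e-9)

    def test_hexagonal_neighbourhood(self, eq_cell):
        """Every interior center has exactly 6 nearest neighbours at distance s,
        at angles theta + k*60 degrees (brute-force search)."""
        centers = field_centers(eq_cell, None, (0, 0, 5, 5))
        s = eq_cell.s
        interior = [
            c for c in centers
            if 1.1 * s < c[0] < 5 - 1.1 * s and 1.1 * s < c[1] < 5 - 1.1 * s
        ]
        assert len(interior) >= 5
        for c in interior:
            d = np.linalg.norm(centers - c, axis=1)
            ring = centers[(d > 1e-9) & (d < s * 1.5)]
            dist = np.linalg.norm(ring - c, axis=1)
            assert len(ring) == 6
            np.testing.assert_allclose(dist, s, atol=1e-6)
            ang = np.sort(np.arctan2(ring[:, 1] - c[1], ring[:, 0] - c[0]) % (2 * math.pi))
            expected = np.sort((eq_cell.theta + np.arange(6) * math.pi / 3) % (2 * math.pi))
            np.testing.assert_allclose(ang, expected, atol=1e-9)

    def test_doubling_spacing_scales_center_geometry(self):
        c1 = field_centers(GridCell(1.0, 0.2), None, (0, 0, 4, 4))
        c2 = field_centers(GridCell(2.0, 0.2), None, (0, 0, 8, 8))
        assert len(c1) == len(c2)
        doubled = np.array(sorted(map(tuple, 2 * c1)))
        target = np.array(sorted(map(tuple, c2)))
        np.testing.assert_allclose(doubled, target, atol=1e-9)


class TestNearestCenterAlongAxis:
    def test_worked_example(self, eq_cell):
        assert nearest_center_distance_along_axis(eq_cell, 1) == pytest.approx(0.5)
        assert nearest_center_distance_along_axis(eq_cell, 2) == pytest.approx(0.0)

    def test_zero_phase_puts_bump_at_origin(self):
        cell = GridCell(1.3, 0.5)
        assert nearest_center_distance_along_axis(cell, 1) == 0.0
        assert nearest_center_distance_along_axis(cell, 2) == 0.0

    def test_invalid_axis(self, eq_cell):
        with pytest.raises(ValueError):
            nearest_center_distance_along_axis(eq_cell, 3)
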