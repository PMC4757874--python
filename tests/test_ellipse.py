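"""Ellipse rasterisation, overlap objective, moment initialisation and fitting."""

import numpy as np
import pytest
from scipy.ndimage import rotate

from conftest import make_rod
from rodmap.components import find_components
from rodmap.ellipse import (
    EllipseParams,
    UnfittableComponentError,
    cell_angle,
    fit_ellipse,
    min_cover_ellipse,
    moment_init,
    objective,
    rasterize_ellipse,
)


def axial_diff(a: float, b: float) -> float:
    d = abs(a - b) % 180
    return min(d, 180 - d)


class TestRasterize:
    def test_small_circle_is_plus_shape(self):
        p = EllipseParams(a=1.4, b=1.4, xc=2, yc=2, phi_deg=0)
        mask = rasterize_ellipse(p, (5, 5))
        expected = np.zeros((5, 5), dtype=bool)
        expected[1:4, 2] = True
        expected[2, 1:4] = True
        assert np.array_equal(mask, expected)

    def test_axial_symmetry_phi_plus_180(self):
        p1 = EllipseParams(a=10, b=3, xc=15, yc=15, phi_deg=37.0)
        p2 = EllipseParams(a=10, b=3, xc=15, yc=15, phi_deg=(37.0 + 180.0) % 180)
        assert np.array_equal(rasterize_ellipse(p1, (30, 30)), rasterize_ellipse(p2, (30, 30)))

    def test_circle_invariant_under_quarter_turn(self):
        p = EllipseParams(a=5, b=5, xc=10, yc=10, phi_deg=0)
        mask = rasterize_ellipse(p, (21, 21))
        assert np.array_equal(mask, np.rot90(mask))

    def test_nonpositive_axes_rejected(self):
        with pytest.raises(ValueError):
            EllipseParams(a=-1, b=1, xc=0, yc=0, phi_deg=0)
        from rodmap.ellipse import _rasterize

        with pytest.raises(ValueError):
            _rasterize(0, 1, 0, 0, 0, (4, 4))


class TestObjective:
    def test_perfect_overlap_scores_cardinality(self, rng):
        cc = rng.uniform(size=(10, 10)) < 0.4
        assert objective(cc, cc) == int(cc.sum())

    def test_disjoint_equal_sets(self):
        e = np.zeros((4, 8), dtype=bool)
        c = np.zeros((4, 8), dtype=bool)
        e[:, :3] = True
        c[:, 5:] = True
        k = int(e.sum())
        assert objective(e, c) == -2 * k

    def test_superset_penalised_per_extra_pixel(self):
        c = np.zeros((6, 6), dtype=bool)
        c[2:4, 2:4] = True
        e = c.copy()
        e[0, 0] = e[5, 5] = e[0, 5] = True  # 3 extra pixels
        assert objective(e, c) == int(c.sum()) - 3

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            objective(np.zeros((2, 2), bool), np.zeros((3, 3), bool))


class TestMomentInit:
    def test_square_is_isotropic_with_zero_angle(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True
        p = moment_init(mask)
        assert p.a == pytest.approx(p.b, rel=0.01)
        assert p.phi_deg == 0.0

    def test_recovers_rasterized_ellipse_parameters(self):
        mask = make_rod(20, 5, 30)
        p = moment_init(mask)
        assert axial_diff(p.phi_deg, 30) < 2.0
        assert p.a == pytest.approx(20, rel=0.05)
        assert p.b == pytest.approx(5, rel=0.05)

    def test_horizontal_run_oriented_along_x(self):
        mask = np.zeros((5, 9), dtype=bool)
        mask[2, 1:8] = True
        assert moment_init(mask).phi_deg == 0.0

    def test_vertical_run_oriented_at_90(self):
        mask = np.zeros((9, 5), dtype=bool)
        mask[1:8, 2] = True
        assert moment_init(mask).phi_deg == pytest.approx(90.0)

    def test_too_few_pixels_unfittable(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        with pytest.raises(UnfittableComponentError):
            moment_init(mask)


class TestFitEllipse:
    def test_self_consistency_on_rasterized_ellipse(self):
        mask = make_rod(18, 4, 62)
        fr = fit_ellipse(mask)
        n = int(mask.sum())
        assert fr.score >= 0.98 * n
        assert axial_diff(fr.params.phi_deg, 62) < 2.0
        assert fr.params.a == pytest.approx(18, rel=0.05)
        assert fr.params.b == pytest.approx(4, rel=0.05)

    def test_disk_is_isotropic(self):
        mask = make_rod(10, 10, 0)
        fr = fit_ellipse(mask)
        assert fr.params.a / fr.params.b == pytest.approx(1.0, abs=0.05)

    def test_score_never_below_initializer(self, rng):
        for _ in range(10):
            a = rng.uniform(8, 25)
            b = a / rng.uniform(2, 6)
            phi = rng.uniform(0, 180)
            mask = make_rod(a, b, phi)
            cc = find_components(mask)[0]
            init = moment_init(cc)
            e0 = rasterize_ellipse(init, mask.shape)
            fr = fit_ellipse(cc)
            assert fr.score >= objective(e0, mask)

    def test_beats_random_perturbations_of_optimum(self, rng):
        mask = make_rod(15, 4, 25)
        fr = fit_ellipse(mask)
        p = fr.params
        beaten = 0
        for _ in range(100):
            factors = rng.uniform(0.9, 1.1, size=4)
            try:
                q = EllipseParams(
                    a=max(p.a * factors[0], p.b * factors[1]),
                    b=min(p.a * factors[0], p.b * factors[1]),
                    xc=p.xc * factors[2],
                    yc=p.yc * factors[3],
                    phi_deg=(p.phi_deg + rng.uniform(-10, 10)) % 180,
                )
            except ValueError:
                continue
            s = objective(rasterize_ellipse(q, mask.shape), mask)
            if s > fr.score:
                beaten += 1
        assert beaten == 0

    def test_works_on_component_record(self):
        mask = make_rod(12, 3, 100)
        cc = find_components(mask)[0]
        fr = fit_ellipse(cc)
        assert axial_diff(fr.params.phi_deg, 100) < 2.0

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            fit_ellipse(make_rod(10, 3, 0), mode="banana")


class TestCellAngle:
    def test_identity_in_range(self):
        assert cell_angle(EllipseParams(a=2, b=1, xc=0, yc=0, phi_deg=30)) == 30.0

    def test_axial_folding(self):
        p = EllipseParams(a=2, b=1, xc=0, yc=0, phi_deg=210.0)
        assert cell_angle(p) == pytest.approx(30.0)

    def test_circle_convention_zero(self):
        assert cell_angle(EllipseParams(a=3, b=3, xc=0, yc=0, phi_deg=77)) == 0.0


class TestAxialEquivalence:
    @pytest.mark.parametrize("delta", [15.0, 45.0, 77.0])
    def test_rotation_shifts_angle_mod_180(self, delta):
        base = 20.0
        m1 = make_rod(16, 4, base)
        m2 = make_rod(16, 4, (base + delta) % 180)
        a1 = cell_angle(fit_ellipse(m1).params)
        a2 = cell_angle(fit_ellipse(m2).params)
        assert axial_diff(a2 - a1, delta) < 2.0

    def test_half_turn_leaves_angle_unchanged(self):
        mask = make_rod(16, 4, 33)
        rotated = rotate(mask.astype(float), 180, order=0, reshape=False) > 0.5
        a1 = cell_angle(fit_ellipse(mask).params)
        a2 = cell_angle(fit_ellipse(rotated).params)
        assert axial_diff(a1, a2) < 2.0


class TestCoverMode:
    def test_cover_encloses_all_pixels(self):
        mask = make_rod(14, 4, 50)
        fr = fit_ellipse(mask, mode="cover")
        rows, cols = np.nonzero(mask)
        p = fr.params
        theta = np.deg2rad(p.phi_deg)
        dx = cols - p.xc
        dy = p.yc - rows
        u = (dx * np.cos(theta) + dy * np.sin(theta)) / p.a
        v = (-dx * np.sin(theta) + dy * np.cos(theta)) / p.b
        assert np.all(u**2 + v**2 <= 1.0 + 1e-9)

    def test_cover_orientation_matches_rod(self):
        fr = fit_ellipse(make_rod(16, 3, 120), mode="cover")
        assert axial_diff(fr.params.phi_deg, 120) < 3.0

    def test_cover_not_grossly_oversized(self):
        mask = make_rod(14, 4, 50)
        fr = fit_ellipse(mask, mode="cover")
        assert fr.params.a < 14 * 1.2 and fr.params.b < 4 * 1.6
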