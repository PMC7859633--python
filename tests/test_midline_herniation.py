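"""Planar geometry: midline shift, skull lines, protrusion extents, indices."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import minimize_scalar

from strokequant import (
    LandmarkSet,
    herniation_indices,
    line_length_mm,
    midline_shift_mm,
    protrusion_extent_mm,
)

angles = st.floats(min_value=-np.pi, max_value=np.pi)
coords = st.floats(min_value=-100.0, max_value=100.0)


def _rotate(p, theta, shift):
    c, s = np.cos(theta), np.sin(theta)
    R = np.array([[c, -s], [s, c]])
    return R @ np.asarray(p, dtype=float) + np.asarray(shift, dtype=float)


class TestMidlineShift:
    def test_point_on_line_is_zero(self):
        assert midline_shift_mm((0, 0), (0, 10), (0, 4)) == pytest.approx(0.0)

    def test_constructed_displacement(self):
        # septum placed 2.7 mm along the unit normal of the (0,0)-(60,80) line
        assert midline_shift_mm((0, 0), (60, 80), (32.16, 38.38)) == pytest.approx(2.70, abs=1e-9)

    @given(theta=angles, dx=coords, dy=coords)
    def test_rigid_invariance(self, theta, dx, dy):
        pts = [(0.0, 0.0), (60.0, 80.0), (32.16, 38.38)]
        moved = [_rotate(p, theta, (dx, dy)) for p in pts]
        assert midline_shift_mm(*moved) == pytest.approx(2.70, abs=1e-6)

    def test_degenerate_line_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            midline_shift_mm((1, 1), (1, 1), (0, 0))


class TestLineLength:
    @pytest.mark.parametrize(
        "p,q,expected",
        [((1, 2), (1, 2), 0.0), ((0, 0), (96, -28), 100.0), ((0, 0), (3, 4), 5.0)],
    )
    def test_lengths(self, p, q, expected):
        assert line_length_mm(p, q) == pytest.approx(expected)


def _ttl():
    a, b = np.array([55.0, -30.0]), np.array([75.0, 10.0])
    d = (b - a) / np.linalg.norm(b - a)
    n = np.array([-d[1], d[0]])
    if n[0] < 0:  # caudal side of the tentorium: away from the cerebrum
        n = -n
    return a, b, n


class TestProtrusion:
    def test_all_points_on_non_herniated_side_clamps_to_zero(self):
        a, b, n = _ttl()
        contour = [np.asarray((a + b) / 2) - 5.0 * n, np.asarray((a + b) / 2) - 1.0 * n]
        assert protrusion_extent_mm(a, b, contour, n) == 0.0

    def test_constructed_12mm_protrusion(self):
        a, b, n = _ttl()
        mid = (a + b) / 2
        contour = [mid - 2.0 * n, mid + 12.0 * n]
        assert protrusion_extent_mm(a, b, contour, n) == pytest.approx(12.0, abs=1e-9)
        # the printed construction point
        assert protrusion_extent_mm(a, b, [(75.733, -15.367)], n) == pytest.approx(12.0, abs=2e-3)

    def test_point_exactly_on_line_contributes_zero(self):
        a, b, n = _ttl()
        assert protrusion_extent_mm(a, b, [(a + b) / 2], n) == 0.0

    def test_non_perpendicular_normal_rejected(self):
        a, b, _ = _ttl()
        with pytest.raises(ValueError, match="perpendicular"):
            protrusion_extent_mm(a, b, [(70, 0)], (1.0, 0.0))

    @given(
        offset=st.floats(min_value=0.0, max_value=30.0),
        extra=st.floats(min_value=0.0, max_value=20.0),
    )
    def test_monotone_in_outward_displacement(self, offset, extra):
        a, b, n = _ttl()
        mid = (a + b) / 2
        base = protrusion_extent_mm(a, b, [mid + offset * n], n)
        moved = protrusion_extent_mm(a, b, [mid + (offset + extra) * n], n)
        assert moved >= base - 1e-12


def _oracle_distance(p, a, b):
    """Brute force: minimize distance to points along the (extended) line."""
    p, a, b = map(lambda q: np.asarray(q, dtype=float), (p, a, b))
    d = b - a

    ts = np.linspace(-50.0, 50.0, 100_001)
    pts = a[None, :] + ts[:, None] * d[None, :]
    i = int(np.argmin(np.linalg.norm(pts - p, axis=1)))
    res = minimize_scalar(
        lambda t: float(np.linalg.norm(a + t * d - p)),
        bracket=(ts[max(i - 1, 0)], ts[min(i + 1, len(ts) - 1)]),
        method="brent",
        options={"xtol": 1e-14},
    )
    return float(res.fun)


def test_perpendicular_distance_matches_brute_force_oracle():
    rng = np.random.default_rng(42)
    for _ in range(200):
        a, b = rng.uniform(-60, 60, 2), rng.uniform(-60, 60, 2)
        if np.linalg.norm(a - b) < 1.0:
            continue
        p = rng.uniform(-80, 80, 2)
        assert midline_shift_mm(a, b, p) == pytest.approx(_oracle_distance(p, a, b), abs=1e-6)


def _sagittal_set(scale=1.0, theta=0.0, shift=(0.0, 0.0)):
    pts = {
        "cribriform_dorsal": (0, 0),
        "sella_dorsal": (55, -30),
        "tentorium_rostral": (75, 10),
        "foramen_magnum_dorsal": (96, -28),
        "foramen_magnum_ventral": (100, -48),
    }
    contours = {
        "tentorial": [[75.733, -15.367]],
        "caudal": [[85.213, -30.157]],
    }
    tf = lambda p: _rotate(np.asarray(p, dtype=float) * scale, theta, shift)
    return LandmarkSet(
        plane="midsagittal",
        points={k: tf(v) for k, v in pts.items()},
        contours={k: np.array([tf(p) for p in arr]) for k, arr in contours.items()},
    )


class TestHerniationIndices:
    def test_printed_group_mean_fixture(self):
        # SLL = 100 mm, TTX = 12 mm, FMX = 11 mm
        geo = herniation_indices(_sagittal_set())
        assert geo.sll_mm == pytest.approx(100.0)
        assert geo.cth == pytest.approx(0.12, abs=1e-3)
        assert geo.fmh == pytest.approx(0.11, abs=1e-3)

    def test_contour_rostral_of_tentorium_gives_zero_cth(self):
        lm = _sagittal_set()
        lm.contours["tentorial"] = np.array([[50.0, -20.0]])  # cerebral side
        lm.normals["ttl"] = _ttl()[2]
        geo = herniation_indices(lm)
        assert geo.cth == 0.0

    @given(theta=angles, dx=coords, dy=coords)
    def test_rigid_invariance(self, theta, dx, dy):
        geo = herniation_indices(_sagittal_set(theta=theta, shift=(dx, dy)))
        assert geo.cth == pytest.approx(0.12, abs=1e-3)
        assert geo.fmh == pytest.approx(0.11, abs=1e-3)
        assert geo.ttx_mm == pytest.approx(12.0, abs=0.1)

    @given(scale=st.floats(min_value=0.2, max_value=5.0))
    def test_indices_scale_invariant_lengths_scale_linearly(self, scale):
        base = herniation_indices(_sagittal_set())
        scaled = herniation_indices(_sagittal_set(scale=scale))
        assert scaled.cth == pytest.approx(base.cth, rel=1e-9)
        assert scaled.fmh == pytest.approx(base.fmh, rel=1e-9)
        assert scaled.sll_mm == pytest.approx(scale * base.sll_mm, rel=1e-9)
        assert scaled.ttx_mm == pytest.approx(scale * base.ttx_mm, rel=1e-9)

    def test_missing_landmark_raises(self):
        lm = _sagittal_set()
        del lm.points["sella_dorsal"]
        with pytest.raises(Exception, match="sella_dorsal"):
            herniation_indices(lm)
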