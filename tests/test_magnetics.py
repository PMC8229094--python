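"""Analytic charge-model field: oracle equivalence and field laws."""

import numpy as np
import pytest
from scipy.constants import mu_0
from scipy.integrate import quad

from halbachsim import (
    Magnet2D,
    MagnetArray,
    build_alternating,
    build_halbach,
    field_at,
    grad_Bmag_at,
)
from halbachsim.magnetics import bmag_at


def quadrature_field(magnet: Magnet2D, px: float, pz: float) -> np.ndarray:
    """Independent oracle: adaptive quadrature over the charge sheets."""
    bx = bz = 0.0
    for axis, a, b, pos, s in magnet.sheets():
        if axis == "x":
            fx = lambda t: (px - t) / ((px - t) ** 2 + (pz - pos) ** 2)
            fz = lambda t: (pz - pos) / ((px - t) ** 2 + (pz - pos) ** 2)
        else:
            fz = lambda t: (pz - t) / ((pz - t) ** 2 + (px - pos) ** 2)
            fx = lambda t: (px - pos) / ((pz - t) ** 2 + (px - pos) ** 2)
        kw = dict(epsabs=1e-15, epsrel=1e-13, limit=200)
        bx += s / (2 * np.pi) * quad(fx, a, b, **kw)[0]
        bz += s / (2 * np.pi) * quad(fz, a, b, **kw)[0]
    return np.array([bx, bz])


def single_magnet(mag=(0.0, 1.45 / mu_0)) -> MagnetArray:
    m = Magnet2D(-0.5e-3, 0.5e-3, -1.5e-3, 0.0, mag)
    return MagnetArray((m,), "alternating", 1e-3, (1.5e-3, 1.5e-3), (-0.5e-3, 0.5e-3))


class TestClosedForm:
    def test_matches_quadrature_oracle(self):
        """Closed form vs adaptive charge-sheet quadrature, 1e-6 relative."""
        rng = np.random.default_rng(42)
        for mag in [(0.0, 1.45 / mu_0), (1.45 / mu_0, 0.0)]:
            arr = single_magnet(mag)
            for _ in range(50):
                px = rng.uniform(-4e-3, 4e-3)
                pz = rng.uniform(0.05e-3, 4e-3)
                closed = field_at(arr, (px, pz))
                oracle = quadrature_field(arr.elements[0], px, pz)
                assert np.allclose(closed, oracle, rtol=1e-6, atol=1e-12)

    def test_top_face_standoff_value(self):
        """1 x 1.5 mm magnet, Br = 1.45 T, 0.2 mm above the top-face center."""
        arr = single_magnet()
        oracle = quadrature_field(arr.elements[0], 0.0, 0.2e-3)
        got = field_at(arr, (0.0, 0.2e-3))
        assert np.allclose(got, oracle, rtol=1e-6)
        # on-axis symmetry: Bx vanishes above a vertically magnetized magnet
        assert abs(got[0]) < 1e-12

    def test_far_field_decay(self, optimized_halbach):
        assert bmag_at(optimized_halbach, (optimized_halbach.x_center, 1.0)) < 1e-4

    def test_superposition(self, stock_halbach):
        """Array field equals the sum of its elements' fields."""
        pts = np.array([[10e-3, 0.3e-3], [25e-3, 0.7e-3], [40e-3, 1.2e-3]])
        total = field_at(stock_halbach, pts)
        parts = np.zeros_like(total)
        for el in stock_halbach.elements:
            sub = MagnetArray(
                (el,), "alternating", el.x_max - el.x_min,
                (1.5e-3, 1.5e-3), (el.x_min, el.x_max),
            )
            parts += field_at(sub, pts)
        assert np.allclose(total, parts, atol=1e-12)

    def test_divergence_and_curl_free(self, optimized_halbach):
        """Maxwell: div B = 0 and curl B = 0 outside the magnets."""
        h = 1e-6
        rng = np.random.default_rng(7)
        pts = np.column_stack([
            rng.uniform(15e-3, 35e-3, 20), rng.uniform(0.3e-3, 1.0e-3, 20)
        ])
        for x, z in pts:
            bxp = field_at(optimized_halbach, (x + h, z))
            bxm = field_at(optimized_halbach, (x - h, z))
            bzp = field_at(optimized_halbach, (x, z + h))
            bzm = field_at(optimized_halbach, (x, z - h))
            div = (bxp[0] - bxm[0] + bzp[1] - bzm[1]) / (2 * h)
            curl = (bzp[0] - bzm[0] - (bxp[1] - bxm[1])) / (2 * h)
            scale = bmag_at(optimized_halbach, (x, z)) / 0.3e-3
            assert abs(div) < 1e-3 * scale
            assert abs(curl) < 1e-3 * scale

    def test_corner_evaluation_is_finite(self):
        m = single_magnet()
        b = field_at(m, (-0.5e-3, 0.0))  # exactly on a sheet corner
        assert np.all(np.isfinite(b))


class TestGradient:
    def test_refinement_convergence(self, stock_halbach):
        """1-um central differences agree with a 4x finer stencil."""
        pts = np.array([[20e-3, 0.4e-3], [22.3e-3, 0.25e-3]])
        g1 = grad_Bmag_at(stock_halbach, pts, step=1e-6)
        g2 = grad_Bmag_at(stock_halbach, pts, step=0.25e-6)
        assert np.allclose(g1, g2, rtol=1e-4)

    def test_symmetry_midpoint(self):
        """d|B|/dx vanishes on the symmetry line between mirror magnets."""
        M = 1.45 / mu_0
        arr = MagnetArray(
            (
                Magnet2D(-2e-3, -1e-3, -1.5e-3, 0.0, (0.0, M)),
                Magnet2D(1e-3, 2e-3, -1.5e-3, 0.0, (0.0, M)),
            ),
            "alternating", 1e-3, (1.5e-3, 1.5e-3), (-2e-3, 2e-3),
        )
        g = grad_Bmag_at(arr, (0.0, 0.5e-3))
        assert abs(g[0]) < 1e-6 * abs(g[1]) + 1e-9

    def test_smaller_elements_give_larger_near_gradient(self, span):
        """Halving element width raises the gradient close to the array."""
        small = build_halbach(2e-3, 1.5e-3, 1.5e-3, 1.45, span)
        large = build_halbach(4e-3, 1.5e-3, 1.5e-3, 1.45, span)
        # element junction nearest the array center, 0.3 mm standoff
        def junction(arr):
            edges = [e.x_max for e in arr.elements[:-1]]
            return min(edges, key=lambda x: abs(x - arr.x_center))
        gs = np.linalg.norm(grad_Bmag_at(small, (junction(small), 0.3e-3)))
        gl = np.linalg.norm(grad_Bmag_at(large, (junction(large), 0.3e-3)))
        assert gs > gl


class TestBuilders:
    def test_default_span_gives_70_elements(self, optimized_halbach):
        assert len(optimized_halbach.elements) == 70
        assert optimized_halbach.heights == (2.75e-3, 2e-3)
        # top faces flush at z = 0
        assert all(e.z_max == 0.0 for e in optimized_halbach.elements)

    def test_halbach_one_sidedness(self, span):
        """Strong-side mean |B| exceeds the weak side for every build."""
        for w, hv, hh, Br in [(1e-3, 2.75e-3, 2e-3, 1.45), (1e-3, 1.5e-3, 1.5e-3, 1.35),
                              (4e-3, 4e-3, 4e-3, 1.35)]:
            arr = build_halbach(w, hv, hh, Br, span)
            xs = arr.x_center + np.linspace(-0.5, 0.5, 32, endpoint=False) * arr.period
            zup = np.full_like(xs, 0.5e-3)
            zdn = np.full_like(xs, -(max(hv, hh) + 0.5e-3))
            above = bmag_at(arr, np.column_stack([xs, zup])).mean()
            below = bmag_at(arr, np.column_stack([xs, zdn])).mean()
            assert above > below
        # the optimized build is strongly one-sided
        arr = build_halbach(1e-3, 2.75e-3, 2e-3, 1.45, span)
        xs = arr.x_center + np.linspace(-0.5, 0.5, 32, endpoint=False) * arr.period
        ratio = (
            bmag_at(arr, np.column_stack([xs, np.full_like(xs, 0.5e-3)])).mean()
            / bmag_at(arr, np.column_stack([xs, np.full_like(xs, -3.25e-3)])).mean()
        )
        assert ratio > 2

    def test_alternating_symmetry_and_pattern(self, alternating_array):
        e0, e1 = alternating_array.elements[:2]
        assert e0.magnetization[1] == -e1.magnetization[1] != 0
        # |B| identical above and below (no one-sidedness)
        xs = alternating_array.x_center + np.linspace(-1, 1, 16) * 1e-3
        up = bmag_at(alternating_array, np.column_stack([xs, np.full_like(xs, 0.4e-3)]))
        dn = bmag_at(
            alternating_array,
            np.column_stack([xs, np.full_like(xs, -2.375e-3 - 0.4e-3)]),
        )
        assert np.allclose(up, dn, rtol=1e-9)

    def test_volume_matched_cross_section(self, alternating_array, optimized_halbach):
        """2 x 2.375 mm alternating elements carry the same magnet volume
        per unit array length as the optimized Halbach period."""
        area_alt = 2e-3 * 2.375e-3 * 2  # one 2-element period, 4 mm long
        area_hal = 1e-3 * (2 * 2.75e-3 + 2 * 2e-3)  # one 4-element period
        assert area_alt == pytest.approx(area_hal)

    def test_periodicity_at_midspan(self, optimized_halbach):
        arr = optimized_halbach
        x0 = arr.x_center
        p = arr.period
        for z in (0.3e-3, 0.8e-3):
            b0 = field_at(arr, (x0 - p / 2, z))
            b1 = field_at(arr, (x0 + p / 2, z))
            assert np.allclose(b0, b1, rtol=1e-3, atol=1e-6)

    def test_phase_translation(self, span):
        a0 = build_halbach(1e-3, 1.5e-3, 1.5e-3, 1.45, span, phase=0)
        a2 = build_halbach(1e-3, 1.5e-3, 1.5e-3, 1.45, span, phase=2)
        x = a0.x_center
        # translation by two element widths (sign set by the rotation
        # sense); finite-array end effects leave a ~1e-3 residual
        for z in (0.3e-3, 0.6e-3):
            b2 = field_at(a2, (x, z))
            mism = min(
                np.max(np.abs(b2 - field_at(a0, (x + 2e-3, z)))),
                np.max(np.abs(b2 - field_at(a0, (x - 2e-3, z)))),
            )
            assert mism < 2e-3 * np.linalg.norm(b2)

    def test_span_too_short_raises(self):
        with pytest.raises(ValueError):
            build_halbach(1e-3, 1.5e-3, 1.5e-3, 1.45, (0.0, 3e-3))
        with pytest.raises(ValueError):
            build_halbach(-1e-3, 1.5e-3, 1.5e-3, 1.45, (0.0, 70e-3))
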