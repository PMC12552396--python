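"""Sector-annulus volume/radius conversions and overlay-thickness routes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bandgrad as bg


def test_volume_between_matches_desk_arithmetic(geom):
    # theta*l*(r2^2 - r1^2)/2 evaluated independently on a desk calculator
    # for the 6.163-7.166 cm channel: 0.3499993 cm^3 (350 uL)
    V = bg.volume_between(6.163, 7.166, geom)
    assert V == pytest.approx(0.3499993, abs=1e-6)


def test_volume_between_trivia(geom):
    assert bg.volume_between(6.5, 6.5, geom) == 0.0
    a, b, c = 6.2, 6.7, 7.1
    assert bg.volume_between(a, b, geom) + bg.volume_between(b, c, geom) == pytest.approx(
        bg.volume_between(a, c, geom), rel=1e-14
    )
    with pytest.raises(ValueError):
        bg.volume_between(7.0, 6.5, geom)


def test_meniscus_from_volume_edges(geom):
    assert bg.meniscus_from_volume(0.0, geom) == geom.r_b
    with pytest.raises(ValueError):
        bg.meniscus_from_volume(-1e-6, geom)
    with pytest.raises(ValueError):
        bg.meniscus_from_volume(geom.full_volume * 1.001, geom)


@settings(deadline=None, max_examples=100, derandomize=True, database=None)
@given(
    r_b=st.floats(1.0, 10.0),
    theta=st.floats(0.005, 1.0),
    l=st.floats(0.1, 2.0),
    f=st.floats(0.05, 0.95),
)
def test_volume_meniscus_round_trip(r_b, theta, l, f):
    """volume_between and meniscus_from_volume are mutually inverse."""
    geom = bg.CellGeometry(r_b, theta, l)
    r = f * r_b
    V = bg.volume_between(r, r_b, geom)
    assert bg.meniscus_from_volume(V, geom) == pytest.approx(r, rel=1e-12)


def test_overlay_thickness_matches_quadratic_solve_oracle():
    """Meniscus-route thickness equals the root of the defining quadratic.

    The layer satisfies (r_m + h)^2 = r_m^2 + 2 V_O/(theta l); solving that
    quadratic for h with a polynomial root-finder is the independent check.
    """
    theta, l, r_m, V_O = math.radians(2.5), 1.2, 6.5, 0.010
    h = bg.overlay_thickness_from_meniscus(theta, V_O, r_m, l)
    roots = np.roots([1.0, 2.0 * r_m, -2.0 * V_O / (theta * l)])
    h_oracle = float(roots[roots > 0][0])
    assert h == pytest.approx(h_oracle, rel=1e-12)
    assert h == pytest.approx(0.029316, abs=1e-6)  # ~293 um layer


def test_overlay_thickness_defining_property(geom):
    h = bg.overlay_thickness_from_meniscus(geom.theta, 0.010, 6.5, geom.l)
    assert bg.volume_between(6.5, 6.5 + h, geom) == pytest.approx(0.010, abs=1e-12)
    assert bg.overlay_thickness_from_meniscus(geom.theta, 0.0, 6.5, geom.l) == 0.0
    with pytest.raises(ValueError):
        bg.overlay_thickness_from_meniscus(-0.1, 0.01, 6.5, geom.l)


@settings(deadline=None, max_examples=100, derandomize=True, database=None)
@given(
    r_b=st.floats(2.0, 10.0),
    theta=st.floats(0.005, 1.0),
    l=st.floats(0.1, 2.0),
    f_pre=st.floats(0.3, 0.9),
    f_ov=st.floats(0.001, 0.5),
)
def test_two_thickness_routes_agree(r_b, theta, l, f_pre, f_ov):
    """Meniscus-based and volume-based thickness agree on consistent inputs."""
    geom = bg.CellGeometry(r_b, theta, l)
    r_pre = f_pre * r_b
    V_C = bg.volume_between(r_pre, r_b, geom)
    V_O = f_ov * bg.volume_between(0.2 * r_b, r_pre, geom)
    r_m = bg.meniscus_from_volume(V_C + V_O, geom)
    h_men = bg.overlay_thickness_from_meniscus(theta, V_O, r_m, l)
    h_vol = bg.overlay_thickness_from_volumes(r_b, theta, V_C, V_O, l)
    assert abs(h_men - h_vol) < 1e-12


def test_volume_route_thickness_trivia(geom):
    V_C = bg.volume_between(6.55, geom.r_b, geom)
    assert bg.overlay_thickness_from_volumes(geom.r_b, geom.theta, V_C, 0.0, geom.l) == 0.0
    with pytest.raises(ValueError):
        bg.overlay_thickness_from_volumes(geom.r_b, geom.theta, V_C, geom.full_volume, geom.l)


def test_channel_angle_round_trip_and_linearity(geom):
    r_m = 6.163
    V = bg.volume_between(r_m, geom.r_b, geom)
    th = bg.channel_angle_from_fill(geom.r_b, r_m, V, geom.l)
    assert th == pytest.approx(geom.theta, rel=1e-14)
    assert bg.channel_angle_from_fill(geom.r_b, r_m, 2 * V, geom.l) == pytest.approx(
        2 * th, rel=1e-14
    )
    with pytest.raises(ValueError):
        bg.channel_angle_from_fill(geom.r_b, geom.r_b, V, geom.l)


def test_channel_angle_meniscus_sensitivity(geom):
    """A 50 um meniscus shift at fixed volume moves the angle by ~0.01 deg."""
    r_m = 6.163
    V = bg.volume_between(r_m, geom.r_b, geom)
    th0 = bg.channel_angle_from_fill(geom.r_b, r_m, V, geom.l)
    th1 = bg.channel_angle_from_fill(geom.r_b, r_m + 0.005, V, geom.l)
    delta_deg = math.degrees(th1 - th0)
    assert 0.005 < delta_deg < 0.015


def test_channel_angle_sensitivity_matches_finite_difference(geom):
    r_m = 6.163
    V = bg.volume_between(r_m, geom.r_b, geom)
    analytic = bg.channel_angle_sensitivity(geom.r_b, r_m, V, geom.l)
    eps = 1e-6
    fd = (
        bg.channel_angle_from_fill(geom.r_b, r_m + eps, V, geom.l)
        - bg.channel_angle_from_fill(geom.r_b, r_m - eps, V, geom.l)
    ) / (2 * eps)
    assert analytic == pytest.approx(fd, rel=1e-6)


def test_make_overlay_state_routes_consistent(geom):
    """Building the overlay from r_m or from V_C gives the same state."""
    s1 = bg.make_overlay_state(geom, 0.010, 55.56, r_m=6.5)
    s2 = bg.make_overlay_state(geom, 0.010, 55.56, V_C=s1.V_C)
    assert s2.r_m == pytest.approx(s1.r_m, rel=1e-12)
    assert s2.h == pytest.approx(s1.h, rel=1e-10)
    assert s2.c_eq == pytest.approx(s1.c_eq, rel=1e-12)
    assert s1.r_m < s1.r_d < geom.r_b
    with pytest.raises(ValueError):
        bg.make_overlay_state(geom, 0.01, 55.56)
    with pytest.raises(ValueError):
        bg.make_overlay_state(geom, 0.01, 55.56, r_m=6.5, V_C=0.2)


def test_cell_geometry_invariants():
    with pytest.raises(ValueError):
        bg.CellGeometry(-1.0, 0.04, 1.2)
    with pytest.raises(ValueError):
        bg.CellGeometry(7.0, 2.0, 1.2)
    with pytest.raises(ValueError):
        bg.CellGeometry(7.0, 0.04, 0.0)
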