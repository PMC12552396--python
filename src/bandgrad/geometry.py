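"""Sector-annulus cell geometry for band-forming AUC centerpieces.

An AUC centerpiece channel is a thin wedge of an annulus: sector angle
``theta`` (radians), height (optical path length) ``l``, bounded by the
bottom radius ``r_b`` (far from the rotation axis) and, once filled, by the
meniscus radius ``r_m``.  Liquid volume between two radii therefore grows
quadratically with radius,

    V(r1, r2) = theta * l * (r2**2 - r1**2) / 2 ,

which is the origin of radial dilution and of the overlay-layer thickness
formulae implemented here.

All lengths are in cm, volumes in cm^3 and angles in radians throughout the
library; user-facing unit conversions (uL, mm, degrees) happen once, at the
configuration boundary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "CellGeometry",
    "OverlayState",
    "volume_between",
    "meniscus_from_volume",
    "overlay_thickness_from_meniscus",
    "overlay_thickness_from_volumes",
    "channel_angle_from_fill",
    "channel_angle_sensitivity",
    "make_overlay_state",
]


@dataclass(frozen=True)
class CellGeometry:
    """Sector-annulus cell: bottom radius, sector angle, channel height.

    Parameters
    ----------
    r_b : float
        Bottom (outer) radius from the rotation axis, cm.
    theta : float
        Full sector (channel) angle, radians.  Must lie in (0, pi/2).
    l : float
        Channel height, equal to the optical path length, cm.
    """

    r_b: float
    theta: float
    l: float

    def __post_init__(self) -> None:
        if self.r_b <= 0:
            raise ValueError(f"bottom radius must be positive, got {self.r_b}")
        if not 0 < self.theta < math.pi / 2:
            raise ValueError(f"sector angle must be in (0, pi/2) rad, got {self.theta}")
        if self.l <= 0:
            raise ValueError(f"channel height must be positive, got {self.l}")

    @property
    def full_volume(self) -> float:
        """Volume of the whole sector from the axis to ``r_b``, cm^3."""
        return volume_between(0.0, self.r_b, self)


@dataclass(frozen=True)
class OverlayState:
    """Meniscus/overlay configuration after layering the light solvent.

    Attributes
    ----------
    r_m : float
        Post-overlay meniscus radius, cm.
    h : float
        Overlay-layer thickness, cm.
    r_d : float
        Lower (outer) edge of the overlay layer, ``r_m + h``, cm.
    V_O : float
        Overlay volume, cm^3.
    V_C : float
        Pre-overlay channel fill volume, cm^3.
    c_i : float
        Concentration of the light solvent in the overlay, mol/L.
    c_eq : float
        Equilibrium uniform concentration after complete mixing, mol/L.
    """

    r_m: float
    h: float
    r_d: float
    V_O: float
    V_C: float
    c_i: float
    c_eq: float


def volume_between(r1: float, r2: float, geom: CellGeometry) -> float:
    """Liquid volume (cm^3) between radii ``r1 <= r2`` in a sector cell."""
    if r1 > r2:
        raise ValueError(f"require r1 <= r2, got r1={r1}, r2={r2}")
    return geom.theta * geom.l * (r2 * r2 - r1 * r1) / 2.0


def meniscus_from_volume(V: float, geom: CellGeometry) -> float:
    """Meniscus radius (cm) when volume ``V`` fills the cell from the bottom.

    Inverse of :func:`volume_between` measured from ``r_b`` inward:
    ``r = sqrt(r_b**2 - 2 V / (theta l))``.
    """
    if V < 0:
        raise ValueError(f"volume must be non-negative, got {V}")
    arg = geom.r_b**2 - 2.0 * V / (geom.theta * geom.l)
    if arg < 0:
        raise ValueError(
            f"volume {V} cm^3 exceeds full-cell capacity {geom.full_volume:.6g} cm^3"
        )
    return math.sqrt(arg)


def overlay_thickness_from_meniscus(theta: float, V_O: float, r_m: float, l: float) -> float:
    """Overlay-layer thickness from the observed post-overlay meniscus.

    ``h = sqrt(r_m**2 + 2 V_O/(theta l)) - r_m``, evaluated in the
    cancellation-free rationalized form.  This route uses the experimentally
    measured meniscus position and avoids the uncertainty of the channel
    fill volume.
    """
    if theta <= 0 or l <= 0:
        raise ValueError("sector angle and channel height must be positive")
    if V_O < 0:
        raise ValueError(f"overlay volume must be non-negative, got {V_O}")
    if r_m <= 0:
        raise ValueError(f"meniscus radius must be positive, got {r_m}")
    x = 2.0 * V_O / (theta * l)
    # (sqrt(r_m^2+x) - r_m) rationalized: exact zero for V_O = 0, no cancellation
    h = x / (math.sqrt(r_m * r_m + x) + r_m)
    if V_O > 0 and h == 0.0:
        warnings.warn(
            "overlay volume below machine-representable layer thickness; returning h = 0",
            RuntimeWarning,
            stacklevel=2,
        )
    return h


def overlay_thickness_from_volumes(
    r_b: float, theta: float, V_C: float, V_O: float, l: float
) -> float:
    """Overlay-layer thickness from the planned channel and overlay volumes.

    ``h = sqrt(r_b**2 - 2 V_C/(theta l)) - sqrt(r_b**2 - 2 (V_C+V_O)/(theta l))``.
    Equivalent to :func:`overlay_thickness_from_meniscus` when ``V_C`` is
    consistent with the observed meniscus; prefer the meniscus route when a
    measured ``r_m`` is available, since planned volumes carry unquantified
    pipetting/transfer errors.
    """
    if theta <= 0 or l <= 0:
        raise ValueError("sector angle and channel height must be positive")
    if V_C <= 0:
        raise ValueError(f"channel fill volume must be positive, got {V_C}")
    if V_O < 0:
        raise ValueError(f"overlay volume must be non-negative, got {V_O}")
    a = r_b * r_b - 2.0 * V_C / (theta * l)
    b = r_b * r_b - 2.0 * (V_C + V_O) / (theta * l)
    if b < 0:
        raise ValueError("V_C + V_O exceeds the cell capacity")
    # difference of square roots, rationalized
    return (2.0 * V_O / (theta * l)) / (math.sqrt(a) + math.sqrt(b))


def channel_angle_from_fill(r_b: float, r_m: float, V: float, l: float) -> float:
    """Back-calculate the sector angle from bottom radius, meniscus and volume.

    ``theta = 2 V / (l (r_b**2 - r_m**2))``.  The sensitivity of this
    estimate to the meniscus position (about 0.01 degrees per 50 um for
    typical cells) is why a direct measurement of the channel angle is
    preferred in practice.
    """
    if l <= 0:
        raise ValueError(f"channel height must be positive, got {l}")
    if V <= 0:
        raise ValueError(f"fill volume must be positive, got {V}")
    if not 0 < r_m < r_b:
        raise ValueError(f"require 0 < r_m < r_b, got r_m={r_m}, r_b={r_b}")
    return 2.0 * V / (l * (r_b * r_b - r_m * r_m))


def channel_angle_sensitivity(r_b: float, r_m: float, V: float, l: float) -> float:
    """d(theta)/d(r_m) of :func:`channel_angle_from_fill` at fixed volume, rad/cm."""
    theta = channel_angle_from_fill(r_b, r_m, V, l)
    return theta * 2.0 * r_m / (r_b * r_b - r_m * r_m)


def make_overlay_state(
    geom: CellGeometry,
    V_O: float,
    c_i: float,
    *,
    V_C: float | None = None,
    r_m: float | None = None,
) -> OverlayState:
    """Assemble the full overlay state from either route.

    Exactly one of ``V_C`` (planned channel fill volume, cm^3) or ``r_m``
    (measured post-overlay meniscus radius, cm) must be given.  The
    equilibrium concentration is the volume-weighted dilution
    ``c_eq = c_i * V_O / (V_C + V_O)``.
    """
    if (V_C is None) == (r_m is None):
        raise ValueError("give exactly one of V_C or r_m")
    if c_i < 0:
        raise ValueError(f"overlay concentration must be non-negative, got {c_i}")
    if r_m is not None:
        if not 0 < r_m < geom.r_b:
            raise ValueError(f"meniscus must satisfy 0 < r_m < r_b, got {r_m}")
        h = overlay_thickness_from_meniscus(geom.theta, V_O, r_m, geom.l)
        V_C = volume_between(r_m + h, geom.r_b, geom)
    else:
        assert V_C is not None
        h = overlay_thickness_from_volumes(geom.r_b, geom.theta, V_C, V_O, geom.l)
        r_m = meniscus_from_volume(V_C + V_O, geom)
    r_d = r_m + h
    c_eq = c_i * V_O / (V_C + V_O) if (V_C + V_O) > 0 else 0.0
    return OverlayState(r_m=r_m, h=h, r_d=r_d, V_O=V_O, V_C=V_C, c_i=c_i, c_eq=c_eq)
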