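"""Neumann-Neumann radial diffusion eigenproblem on an annulus.

Axisymmetric diffusion on [r_m, r_b] with zero-flux (reflecting) boundaries
separates into radial modes R(beta, r) satisfying the zero-order Bessel
equation.  The boundary conditions select

    R(beta, r) = Y1(beta r_b) J0(beta r) - J1(beta r_b) Y0(beta r),

whose derivative -beta [Y1(beta r_b) J1(beta r) - J1(beta r_b) Y1(beta r)]
vanishes at r_b identically and at r_m exactly when beta is a root of the
Bessel cross-product characteristic equation

    J1(beta r_m) Y1(beta r_b) - J1(beta r_b) Y1(beta r_m) = 0.

The constant mode beta_0 = 0 completes the basis.  Roots are located by a
sign-change scan at a step well below the asymptotic spacing
pi / (r_b - r_m), then refined by bracketed root-finding; an unbracketed
secant iteration can skip or double-count closely spaced roots.

Closed forms for the inverse norm 1/N = 1/int(R^2 r dr) and for the
projection of a radial step onto each mode are provided; both follow from
int(J0(x) x dx) = x J1(x) and the cross-product identity
J0(x) Y1(x) - J1(x) Y0(x) = -2/(pi x), and are verified against quadrature
in the test suite (quadrature is authoritative on any discrepancy).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import optimize, special

__all__ = [
    "EigenMode",
    "EigenSystem",
    "characteristic",
    "find_eigenvalues",
    "eigen_system",
    "eigenfunction",
    "eigenfunction_matrix",
    "inverse_norm",
    "projection_integral",
]

#: default upper end of the eigenvalue search interval, 1/cm
DEFAULT_BETA_MAX = 5000.0
#: default lower end of the scan; the constant mode beta_0 = 0 is inserted
#: analytically and never searched for numerically
DEFAULT_BETA_MIN = 0.01


@dataclass(frozen=True)
class EigenMode:
    """One radial mode: eigenvalue, inverse norm, optional step projection."""

    beta: float  # eigenvalue, 1/cm
    inv_norm: float  # 1 / int(R^2 r dr)
    proj: float | None = None  # int(R F r dr), (mol/L) cm^2


@dataclass(frozen=True)
class EigenSystem:
    """All modes of one annulus, ascending, constant mode first."""

    r_m: float
    r_b: float
    betas: np.ndarray = field(repr=False)  # includes beta_0 = 0
    inv_norms: np.ndarray = field(repr=False)

    @property
    def n_modes(self) -> int:
        return int(self.betas.size)

    @property
    def beta_max(self) -> float:
        return float(self.betas[-1])

    @property
    def modes(self) -> list[EigenMode]:
        return [
            EigenMode(float(b), float(n)) for b, n in zip(self.betas, self.inv_norms)
        ]

    def projections(self, r_d: float, c_i: float) -> np.ndarray:
        """Step projections int(R F r dr) for every mode (constant mode first)."""
        proj = np.empty_like(self.betas)
        proj[0] = c_i * (r_d * r_d - self.r_m * self.r_m) / 2.0
        if self.betas.size > 1:
            proj[1:] = projection_integral(self.betas[1:], self.r_m, r_d, self.r_b, c_i)
        return proj


def characteristic(beta, r_m: float, r_b: float):
    """Residual of the Bessel cross-product characteristic equation.

    Vanishes exactly at the positive eigenvalues of the annulus.  Accepts a
    scalar or array of positive ``beta``.
    """
    b = np.asarray(beta, dtype=float)
    if np.any(b <= 0):
        raise ValueError("characteristic is defined for beta > 0 only")
    out = special.j1(b * r_m) * special.y1(b * r_b) - special.j1(b * r_b) * special.y1(
        b * r_m
    )
    return out if np.ndim(beta) else float(out)


def _validate_annulus(r_m: float, r_b: float) -> None:
    if not 0 < r_m < r_b:
        raise ValueError(f"require 0 < r_m < r_b, got r_m={r_m}, r_b={r_b}")


def find_eigenvalues(
    r_m: float,
    r_b: float,
    beta_max: float = DEFAULT_BETA_MAX,
    beta_min: float = DEFAULT_BETA_MIN,
) -> EigenSystem:
    """Locate every eigenvalue in (0, beta_max] plus the constant mode.

    A vectorized sign-change scan at step 0.4 pi/(r_b - r_m) (well under
    half the asymptotic root spacing) brackets each root of
    :func:`characteristic`; Brent refinement then drives the relative
    bracket width below 1e-14.
    """
    _validate_annulus(r_m, r_b)
    if beta_max <= 0:
        raise ValueError(f"beta_max must be positive, got {beta_max}")
    spacing = np.pi / (r_b - r_m)
    step = 0.4 * spacing
    grid = np.arange(beta_min, beta_max + step, step)
    grid[-1] = min(grid[-1], beta_max)
    vals = characteristic(grid, r_m, r_b)
    sign_flip = np.flatnonzero(np.signbit(vals[:-1]) != np.signbit(vals[1:]))
    roots = []
    for i in sign_flip:
        root = optimize.brentq(
            characteristic,
            grid[i],
            grid[i + 1],
            args=(r_m, r_b),
            xtol=1e-300,
            rtol=4.0 * np.finfo(float).eps,
        )
        if root <= beta_max:
            roots.append(root)
    betas_pos = np.array(roots)
    if betas_pos.size:
        # dedupe: a root landing on a grid point could bracket twice
        keep = np.concatenate(([True], np.diff(betas_pos) > 1e-9))
        betas_pos = betas_pos[keep]
    betas = np.concatenate(([0.0], betas_pos))
    inv_norms = np.empty_like(betas)
    inv_norms[0] = 2.0 / (r_b * r_b - r_m * r_m)
    if betas_pos.size:
        inv_norms[1:] = inverse_norm(betas_pos, r_m, r_b)
    return EigenSystem(r_m=r_m, r_b=r_b, betas=betas, inv_norms=inv_norms)


@lru_cache(maxsize=32)
def eigen_system(r_m: float, r_b: float, beta_max: float = DEFAULT_BETA_MAX) -> EigenSystem:
    """Cached :func:`find_eigenvalues`; profiles at many times reuse one system."""
    return find_eigenvalues(r_m, r_b, beta_max)


def eigenfunction(beta: float, r, r_b: float):
    """Radial mode amplitude R(beta, r); the constant mode (beta = 0) is 1."""
    if beta < 0:
        raise ValueError(f"beta must be non-negative, got {beta}")
    rr = np.asarray(r, dtype=float)
    if beta == 0.0:
        out = np.ones_like(rr)
    else:
        out = special.y1(beta * r_b) * special.j0(beta * rr) - special.j1(
            beta * r_b
        ) * special.y0(beta * rr)
    return out if np.ndim(r) else float(out)


def eigenfunction_matrix(betas: np.ndarray, radii: np.ndarray, r_b: float) -> np.ndarray:
    """R(beta_n, r_j) for positive betas, shape (n_modes, n_radii)."""
    b = np.asarray(betas, dtype=float)[:, None]
    r = np.asarray(radii, dtype=float)[None, :]
    return special.y1(b * r_b) * special.j0(b * r) - special.j1(b * r_b) * special.y0(
        b * r
    )


def inverse_norm(beta, r_m: float, r_b: float):
    """Closed-form 1/N(beta) = 1/int(R^2 r dr) for a positive eigenvalue.

    Using J0'(x) = -J1(x):

        1/N = (pi^2/2) beta^2 J1(beta r_m)^2
              / (J1(beta r_m)^2 - J1(beta r_b)^2).

    Valid only at roots of :func:`characteristic`; for the constant mode the
    norm is int(r dr) = (r_b^2 - r_m^2)/2.
    """
    b = np.asarray(beta, dtype=float)
    if np.any(b <= 0):
        raise ValueError("inverse_norm applies to positive eigenvalues; beta_0 = 0 "
                         "has norm (r_b^2 - r_m^2)/2")
    j1m = special.j1(b * r_m)
    j1b = special.j1(b * r_b)
    out = (np.pi**2 / 2.0) * b * b * j1m * j1m / (j1m * j1m - j1b * j1b)
    return out if np.ndim(beta) else float(out)


def projection_integral(beta, r_m: float, r_d: float, r_b: float, c_i: float):
    """Projection of the initial overlay step onto a positive mode.

    The initial condition is c_i on [r_m, r_d] and 0 on (r_d, r_b); its
    weighted projection is

        int_{r_m}^{r_d} R(beta, r) c_i r dr
          = { Y1(beta r_b) [r_d J1(beta r_d) - r_m J1(beta r_m)]
            + J1(beta r_b) [r_m Y1(beta r_m) - r_d Y1(beta r_d)] } c_i / beta.
    """
    if not r_m <= r_d <= r_b:
        raise ValueError(f"require r_m <= r_d <= r_b, got r_m={r_m}, r_d={r_d}, r_b={r_b}")
    b = np.asarray(beta, dtype=float)
    if np.any(b <= 0):
        raise ValueError("projection_integral applies to positive eigenvalues")
    y1b = special.y1(b * r_b)
    j1b = special.j1(b * r_b)
    out = (
        y1b * (r_d * special.j1(b * r_d) - r_m * special.j1(b * r_m))
        + j1b * (r_m * special.y1(b * r_m) - r_d * special.y1(b * r_d))
    ) * (c_i / b)
    return out if np.ndim(beta) else float(out)
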