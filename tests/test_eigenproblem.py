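"""Bessel cross-product eigenvalues, eigenfunctions, norms and projections."""

import math

import numpy as np
import pytest
from numpy.polynomial.legendre import leggauss

import bandgrad as bg

C_I = 55.56


def _gauss_r(r_lo, r_hi, n=3000):
    x, w = leggauss(n)
    r = 0.5 * (r_hi - r_lo) * x + 0.5 * (r_hi + r_lo)
    return r, 0.5 * (r_hi - r_lo) * w


def test_constant_mode_first_and_betas_increasing(eig):
    assert eig.betas[0] == 0.0
    assert np.all(np.diff(eig.betas) > 0)
    assert np.all(np.diff(eig.betas[1:]) > 1e-9)


def test_characteristic_residual_tiny_at_eigenvalues(eig):
    res = np.abs(bg.characteristic(eig.betas[1:51], eig.r_m, eig.r_b))
    assert res.max() < 1e-12


def test_characteristic_rejects_nonpositive(eig):
    with pytest.raises(ValueError):
        bg.characteristic(0.0, eig.r_m, eig.r_b)
    with pytest.raises(ValueError):
        bg.find_eigenvalues(7.0, 6.5)


def test_first_root_near_asymptotic_spacing(eig):
    spacing = math.pi / (eig.r_b - eig.r_m)
    assert eig.betas[1] == pytest.approx(spacing, rel=0.05)


def test_root_count_matches_brute_force_scan(eig):
    """Count in (0, 50] equals a 10x-finer dense sign-change scan."""
    spacing = math.pi / (eig.r_b - eig.r_m)
    grid = np.arange(1e-3, 50.0 + 0.04 * spacing, 0.04 * spacing)
    grid = grid[grid <= 50.0]
    vals = bg.characteristic(grid, eig.r_m, eig.r_b)
    brute = int(np.count_nonzero(np.signbit(vals[:-1]) != np.signbit(vals[1:])))
    mine = int(np.count_nonzero((eig.betas > 0) & (eig.betas <= 50.0)))
    assert mine == brute


def test_root_density_scales_with_annulus_width():
    """Halving the gap roughly doubles the first eigenvalue; the root count
    in (0, B] grows linearly with slope (r_b - r_m)/pi."""
    wide = bg.find_eigenvalues(6.5, 7.166, 300.0)
    narrow = bg.find_eigenvalues(6.833, 7.166, 300.0)
    assert narrow.betas[1] == pytest.approx(2 * wide.betas[1], rel=0.05)
    for sys in (wide, narrow):
        n_roots = sys.n_modes - 1
        expected = 300.0 * (sys.r_b - sys.r_m) / math.pi
        assert n_roots == pytest.approx(expected, rel=0.05)


def test_eigenvalues_scale_inversely_with_radius():
    """Joint rescaling r -> s r maps eigenvalues to beta/s."""
    base = bg.find_eigenvalues(6.5, 7.166, 200.0)
    scaled = bg.find_eigenvalues(13.0, 14.332, 400.0)
    n = min(base.n_modes, scaled.n_modes)
    np.testing.assert_allclose(scaled.betas[1:n] * 2.0, base.betas[1:n], rtol=1e-9)


def test_eigenfunction_constant_mode(eig):
    r = np.linspace(eig.r_m, eig.r_b, 7)
    np.testing.assert_array_equal(bg.eigenfunction(0.0, r, eig.r_b), np.ones(7))


@pytest.mark.parametrize("mode_index", [1, 2, 5, 20])
def test_eigenfunction_zero_flux_boundaries(eig, mode_index):
    """dR/dr vanishes at both walls (centered finite difference)."""
    beta = eig.betas[mode_index]
    eps = 1e-6
    scale = beta * np.abs(
        bg.eigenfunction(beta, np.linspace(eig.r_m, eig.r_b, 101), eig.r_b)
    ).max()
    for r0 in (eig.r_m, eig.r_b):
        d = (
            bg.eigenfunction(beta, r0 + eps, eig.r_b)
            - bg.eigenfunction(beta, r0 - eps, eig.r_b)
        ) / (2 * eps)
        assert abs(d) / scale < 1e-6


def test_eigenfunctions_orthogonal_under_r_weight(eig):
    r, w = _gauss_r(eig.r_m, eig.r_b)
    R = np.array([bg.eigenfunction(b, r, eig.r_b) for b in eig.betas[:20]])
    gram = (R * r * w) @ R.T
    diag = np.diag(gram)
    off = np.abs(gram - np.diag(diag)) / np.sqrt(np.outer(diag, diag))
    assert off.max() < 1e-8


def test_inverse_norm_closed_form_matches_quadrature(eig):
    """Quadrature of int(R^2 r dr) is the authoritative norm; the closed
    form must reproduce it for the first 50 eigenvalues."""
    r, w = _gauss_r(eig.r_m, eig.r_b)
    for beta, inv in zip(eig.betas[1:51], eig.inv_norms[1:51]):
        R = bg.eigenfunction(beta, r, eig.r_b)
        quad = float(np.sum(R * R * r * w))
        assert inv > 0
        assert inv * quad == pytest.approx(1.0, rel=1e-8)


def test_inverse_norm_constant_mode(eig):
    assert eig.inv_norms[0] == pytest.approx(
        2.0 / (eig.r_b**2 - eig.r_m**2), rel=1e-14
    )
    with pytest.raises(ValueError):
        bg.inverse_norm(0.0, eig.r_m, eig.r_b)


def test_projection_closed_form_matches_quadrature(eig, overlay):
    """Step projection equals adaptive quadrature of R*F*r over the band."""
    from scipy.integrate import quad

    for beta in eig.betas[1:21]:
        oracle, _ = quad(
            lambda r: bg.eigenfunction(beta, r, eig.r_b) * r * C_I,
            overlay.r_m,
            overlay.r_d,
            epsabs=1e-14,
            epsrel=1e-13,
        )
        ana = bg.projection_integral(beta, overlay.r_m, overlay.r_d, eig.r_b, C_I)
        assert ana == pytest.approx(oracle, rel=1e-10)


def test_projection_degenerate_band_edges(eig, overlay):
    beta = eig.betas[1]
    assert bg.projection_integral(beta, overlay.r_m, overlay.r_m, eig.r_b, C_I) == 0.0
    # uniform fill: the step becomes the constant mode, orthogonal to all others
    full = bg.projection_integral(beta, eig.r_m, eig.r_b, eig.r_b, C_I)
    band = bg.projection_integral(beta, overlay.r_m, overlay.r_d, eig.r_b, C_I)
    assert abs(full) < 1e-10 * abs(band)
    with pytest.raises(ValueError):
        bg.projection_integral(beta, overlay.r_m, eig.r_b + 0.1, eig.r_b, C_I)


def test_step_reconstruction_l2_error_decreases_with_beta_max(overlay, geom):
    """Completeness: truncated reconstruction of the initial step converges
    in the L2(r dr) sense as the eigenvalue cutoff grows."""
    r, w = _gauss_r(overlay.r_m, geom.r_b, 4000)
    F = np.where(r <= overlay.r_d, C_I, 0.0)
    errs = []
    for beta_max in (50.0, 200.0, 1000.0):
        sys = bg.find_eigenvalues(overlay.r_m, geom.r_b, beta_max)
        proj = sys.projections(overlay.r_d, C_I)
        recon = np.zeros_like(r)
        for beta, inv, p in zip(sys.betas, sys.inv_norms, proj):
            recon += inv * p * bg.eigenfunction(beta, r, geom.r_b)
        errs.append(float(np.sum((recon - F) ** 2 * r * w)))
    assert errs[0] > errs[1] > errs[2]
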