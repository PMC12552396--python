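"""Isotope-mixture density/viscosity rules and transport correction factors.

For isotopic mixtures of water the mixture density and viscosity reduce to
volume-fraction-weighted averages of the pure-component values.  Writing
the H2O volume fraction as c / c_self, with c the local molar H2O
concentration and c_self = rho_H2O / M_H2O its self-concentration in pure
H2O, both properties become linear in c:

    rho(c) = rho_D2O + (rho_H2O - rho_D2O) c / c_self
    eta(c) = eta_D2O + (eta_H2O - eta_D2O) c / c_self.

The library ships 55.56 mol/L as the default self-concentration (the
rounded-input value rho = 1.000 g/mL, M = 18.00 g/mol); a
temperature-consistent value (e.g. 55.41 mol/L at 20 C) can be derived
with :func:`self_concentration` and passed explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .gradient_model import RadialProfile

__all__ = [
    "SolventPair",
    "mixture_density",
    "mixture_viscosity",
    "self_concentration",
    "transport_correction_factors",
    "density_profile",
    "viscosity_profile",
]

#: rounded-input self-concentration of H2O, mol/L (1.000 g/mL / 18.00 g/mol)
C_SELF_H2O = 55.56


@dataclass(frozen=True)
class SolventPair:
    """Pure-component properties of the light and heavy solvent.

    Densities in g/mL, viscosities in mPa s, both at the experiment
    temperature; ``c_self`` is the molar self-concentration of the light
    solvent (mol/L) that normalizes the mixing rules, ``M_light`` its molar
    mass (g/mol).
    """

    rho_light: float
    rho_heavy: float
    eta_light: float
    eta_heavy: float
    c_self: float = C_SELF_H2O
    M_light: float = 18.015

    def __post_init__(self) -> None:
        for name in ("rho_light", "rho_heavy", "eta_light", "eta_heavy", "c_self", "M_light"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.rho_heavy <= self.rho_light:
            warnings.warn(
                "heavy solvent is not denser than the light one; a band-forming "
                "overlay of the light solvent would be gravitationally unstable",
                RuntimeWarning,
                stacklevel=2,
            )


def _clamped(c, c_self: float):
    cc = np.asarray(c, dtype=float)
    n_out = int(np.count_nonzero((cc < 0) | (cc > c_self)))
    if n_out:
        warnings.warn(
            f"{n_out} concentration value(s) outside [0, c_self] clamped before "
            "property evaluation (series truncation ringing)",
            RuntimeWarning,
            stacklevel=3,
        )
    return np.clip(cc, 0.0, c_self)


def mixture_density(c, pair: SolventPair):
    """Mixture density (g/mL) at light-solvent concentration ``c`` (mol/L).

    Linear volume-fraction mixing; out-of-range concentrations (truncation
    ringing) are clamped to [0, c_self] with a warning.
    """
    cc = _clamped(c, pair.c_self)
    out = pair.rho_heavy + (pair.rho_light - pair.rho_heavy) * cc / pair.c_self
    return out if np.ndim(c) else float(out)


def mixture_viscosity(c, pair: SolventPair):
    """Mixture viscosity (mPa s) at light-solvent concentration ``c`` (mol/L)."""
    cc = _clamped(c, pair.c_self)
    out = pair.eta_heavy + (pair.eta_light - pair.eta_heavy) * cc / pair.c_self
    return out if np.ndim(c) else float(out)


def self_concentration(rho_light: float, M_light: float) -> float:
    """Molar self-concentration 1000 rho / M in mol/L (rho g/mL, M g/mol)."""
    if rho_light <= 0 or M_light <= 0:
        raise ValueError("density and molar mass must be positive")
    return 1000.0 * rho_light / M_light


def transport_correction_factors(
    rho_local: float,
    eta_local: float,
    vbar: float,
    ref_rho: float,
    ref_eta: float,
) -> tuple[float, float]:
    """Local-to-reference scaling of apparent s and D for a downstream analyte.

    Svedberg-type scaling: s scales with buoyancy (1 - vbar rho) and
    inversely with viscosity, D inversely with viscosity only:

        s_factor = (ref_eta / eta_local) (1 - vbar rho_local) / (1 - vbar ref_rho)
        D_factor =  ref_eta / eta_local.

    Raises if the analyte is isopycnic with the reference solvent
    (1 - vbar ref_rho = 0), where the scaling is undefined.
    """
    denom = 1.0 - vbar * ref_rho
    if abs(denom) < 1e-12:
        raise ZeroDivisionError(
            "analyte is isopycnic with the reference solvent; sedimentation "
            "scaling is undefined"
        )
    d_factor = ref_eta / eta_local
    s_factor = d_factor * (1.0 - vbar * rho_local) / denom
    return s_factor, d_factor


def _property_profile(profile: RadialProfile, pair: SolventPair, which: str) -> RadialProfile:
    if profile.quantity != "concentration":
        raise ValueError("input must be a concentration profile")
    fn = mixture_density if which == "density" else mixture_viscosity
    return RadialProfile(
        t=profile.t,
        radii=profile.radii,
        values=fn(profile.values, pair),
        quantity=which,
        n_modes=profile.n_modes,
        truncation_bound=profile.truncation_bound,
        warnings=profile.warnings,
        meta=dict(profile.meta),
    )


def density_profile(profile: RadialProfile, pair: SolventPair) -> RadialProfile:
    """Map a concentration profile to the mixture density profile (g/mL)."""
    return _property_profile(profile, pair, "density")


def viscosity_profile(profile: RadialProfile, pair: SolventPair) -> RadialProfile:
    """Map a concentration profile to the mixture viscosity profile (mPa s)."""
    return _property_profile(profile, pair, "viscosity")
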