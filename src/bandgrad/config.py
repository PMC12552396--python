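"""Run configuration: schema, unit conversion, and experiment presets.

User-facing units are lab-friendly (degrees, mm, uL); they are converted
exactly once, here, into the library's internal cm/cm^3/radian system.
Exactly one of the channel fill volume or the post-overlay meniscus radius
must be given — the two routes to the overlay-layer thickness.
"""

from __future__ import annotations

import math
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .geometry import CellGeometry, OverlayState, make_overlay_state
from .gradient_model import DiffusionParams
from .solvent_properties import C_SELF_H2O, SolventPair

__all__ = ["RunConfig", "make_fixture", "load_config", "PRESETS"]


class GeometryConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    bottom_radius_cm: float = Field(gt=0)
    top_radius_cm: float | None = Field(default=None, gt=0)
    channel_angle_deg: float = Field(gt=0, lt=90)
    path_length_mm: float = Field(gt=0)

    def to_domain(self) -> CellGeometry:
        return CellGeometry(
            r_b=self.bottom_radius_cm,
            theta=math.radians(self.channel_angle_deg),
            l=self.path_length_mm / 10.0,
        )


class OverlayConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    overlay_volume_ul: float = Field(ge=0)
    channel_volume_ul: float | None = Field(default=None, gt=0)
    meniscus_radius_cm: float | None = Field(default=None, gt=0)
    overlay_concentration_mol_per_l: float = Field(default=C_SELF_H2O, gt=0)

    @model_validator(mode="after")
    def _exactly_one_fill_spec(self) -> "OverlayConfig":
        if (self.channel_volume_ul is None) == (self.meniscus_radius_cm is None):
            raise ValueError(
                "give exactly one of channel_volume_ul or meniscus_radius_cm"
            )
        return self


class DiffusionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    d_cm2_per_s: float = Field(gt=0)
    time_offset_s: float = Field(default=0.0, ge=0)
    """Optional overlay-timing offset added to output times when comparing to
    experiments where the overlay happened during rotor acceleration."""

    def to_domain(self) -> DiffusionParams:
        return DiffusionParams(D=self.d_cm2_per_s)


class SolventConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    rho_light_g_per_ml: float = Field(gt=0)
    rho_heavy_g_per_ml: float = Field(gt=0)
    eta_light_mpa_s: float = Field(gt=0)
    eta_heavy_mpa_s: float = Field(gt=0)
    c_self_mol_per_l: float = Field(default=C_SELF_H2O, gt=0)
    molar_mass_light_g_per_mol: float = Field(default=18.015, gt=0)
    source_note: str = ""

    def to_domain(self) -> SolventPair:
        return SolventPair(
            rho_light=self.rho_light_g_per_ml,
            rho_heavy=self.rho_heavy_g_per_ml,
            eta_light=self.eta_light_mpa_s,
            eta_heavy=self.eta_heavy_mpa_s,
            c_self=self.c_self_mol_per_l,
            M_light=self.molar_mass_light_g_per_mol,
        )


Quantity = Literal["concentration", "density", "viscosity"]


class OutputConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    times_s: list[float] = Field(default_factory=list)
    n_radii: int = Field(default=2001, ge=11)
    quantities: list[Quantity] = Field(default_factory=lambda: ["concentration"])
    engine: Literal["series", "fd"] = "series"
    beta_max_per_cm: float = Field(default=5000.0, gt=0)
    fd_n_cells: int = Field(default=2000, ge=2)
    out_dir: str = "bandgrad_out"

    @model_validator(mode="after")
    def _times_sorted(self) -> "OutputConfig":
        if any(t < 0 for t in self.times_s):
            raise ValueError("times_s must be non-negative")
        if sorted(self.times_s) != self.times_s:
            raise ValueError("times_s must be ascending")
        return self


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    geometry: GeometryConfig
    overlay: OverlayConfig
    diffusion: DiffusionConfig
    solvents: SolventConfig
    output: OutputConfig = Field(default_factory=OutputConfig)
    seed: int = 0  # reserved for future stochastic features

    def domain_objects(self) -> tuple[CellGeometry, OverlayState, DiffusionParams, SolventPair]:
        geom = self.geometry.to_domain()
        ov = self.overlay
        kwargs = {}
        if ov.meniscus_radius_cm is not None:
            kwargs["r_m"] = ov.meniscus_radius_cm
        else:
            kwargs["V_C"] = ov.channel_volume_ul / 1000.0
        overlay = make_overlay_state(
            geom,
            V_O=ov.overlay_volume_ul / 1000.0,
            c_i=ov.overlay_concentration_mol_per_l,
            **kwargs,
        )
        return geom, overlay, self.diffusion.to_domain(), self.solvents.to_domain()

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=False)


#: presets encoding published band-forming setups; every value carries its
#: provenance in the solvents source_note / preset docstring
PRESETS: dict[str, dict] = {
    # 12 mm charcoal-filled Epon band-forming centerpiece, H2O over D2O,
    # 20 C: measured channel angle 2.5 deg, bottom radius 7.166 cm, channel
    # top radius 6.163 cm, 10 uL overlay, mutual diffusion coefficient
    # 1.8e-5 cm^2/s.
    "epon_bfe_12mm": {
        "geometry": {
            "bottom_radius_cm": 7.166,
            "top_radius_cm": 6.163,
            "channel_angle_deg": 2.5,
            "path_length_mm": 12.0,
        },
        "overlay": {
            "overlay_volume_ul": 10.0,
            "meniscus_radius_cm": 6.163,
            "overlay_concentration_mol_per_l": C_SELF_H2O,
        },
        "diffusion": {"d_cm2_per_s": 1.8e-5},
        "solvents": {
            "rho_light_g_per_ml": 0.99821,
            "rho_heavy_g_per_ml": 1.10498,
            "eta_light_mpa_s": 1.0016,
            "eta_heavy_mpa_s": 1.2467,
            "c_self_mol_per_l": C_SELF_H2O,
            "source_note": (
                "pure H2O/D2O density and viscosity at 20 C, CRC Handbook "
                "literature values; c_self is the rounded-input convention "
                "1.000 g/mL / 18.00 g/mol"
            ),
        },
        "output": {
            "times_s": [300.0, 600.0, 1800.0, 3600.0, 10800.0, 21600.0],
            "quantities": ["concentration", "density", "viscosity"],
        },
    },
}


def make_fixture(name: str) -> RunConfig:
    """Return a preset run configuration by name."""
    if name not in PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; available presets: {sorted(PRESETS)}"
        )
    return RunConfig.model_validate(PRESETS[name])


def load_config(path) -> RunConfig:
    """Parse a YAML (or JSON, a YAML subset) run configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig.model_validate(data)
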