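"""Plain-text readers and writers: profile TSVs, mode diagnostics, scans."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .eigenproblem import EigenSystem, characteristic
from .gradient_model import RadialProfile

__all__ = [
    "QUANTITY_COLUMNS",
    "write_profile_tsv",
    "read_profile_tsv",
    "write_property_table",
    "write_modes_tsv",
    "read_scan_table",
]

QUANTITY_COLUMNS = {
    "concentration": "c_h2o_mol_per_l",
    "density": "density_g_per_ml",
    "viscosity": "viscosity_mpa_s",
}


def write_profile_tsv(path, profile: RadialProfile) -> None:
    """One radial profile as TSV with a commented provenance header."""
    path = Path(path)
    col = QUANTITY_COLUMNS[profile.quantity]
    with open(path, "w") as fh:
        fh.write(f"# time_s = {profile.t:.10g}\n")
        fh.write(f"# quantity = {profile.quantity}\n")
        if profile.n_modes is not None:
            fh.write(f"# n_modes = {profile.n_modes}\n")
        if profile.truncation_bound is not None:
            fh.write(f"# truncation_bound = {profile.truncation_bound:.6g}\n")
        for w in profile.warnings:
            fh.write(f"# warning = {w}\n")
        fh.write(f"radius_cm\t{col}\n")
        for r, v in zip(profile.radii, profile.values):
            fh.write(f"{r:.10g}\t{v:.10g}\n")


def read_profile_tsv(path) -> RadialProfile:
    """Inverse of :func:`write_profile_tsv` (for regression comparisons)."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line[1:].partition("=")
            meta[key.strip()] = val.strip()
        else:
            body_start = i
            break
    df = pd.read_csv(path, sep="\t", skiprows=body_start)
    col = df.columns[1]
    quantity = {v: k for k, v in QUANTITY_COLUMNS.items()}[col]
    n_modes = int(meta["n_modes"]) if "n_modes" in meta else None
    trunc = float(meta["truncation_bound"]) if "truncation_bound" in meta else None
    return RadialProfile(
        t=float(meta.get("time_s", "nan")),
        radii=df["radius_cm"].to_numpy(),
        values=df[col].to_numpy(),
        quantity=quantity,
        n_modes=n_modes,
        truncation_bound=trunc,
    )


def write_property_table(path, t: float, radii, c, rho, eta) -> None:
    """Combined concentration/density/viscosity table at one time point."""
    df = pd.DataFrame(
        {
            "radius_cm": np.asarray(radii),
            "c_h2o_mol_per_l": np.asarray(c),
            "density_g_per_ml": np.asarray(rho),
            "viscosity_mpa_s": np.asarray(eta),
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# time_s = {t:.10g}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def write_modes_tsv(path, eig: EigenSystem, proj: np.ndarray | None = None) -> None:
    """Eigen-mode diagnostic dump: eigenvalue, inverse norm, projection, residual."""
    res = np.zeros_like(eig.betas)
    if eig.betas.size > 1:
        res[1:] = characteristic(eig.betas[1:], eig.r_m, eig.r_b)
    cols = {
        "beta_per_cm": eig.betas,
        "inv_norm": eig.inv_norms,
        "characteristic_residual": res,
    }
    if proj is not None:
        cols["proj"] = proj
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_scan_table(path) -> tuple[np.ndarray, np.ndarray]:
    """Two-column radial scan (radius_cm, signal), whitespace- or tab-separated.

    For qualitative shape comparison only; no fringe-to-concentration
    conversion is attempted.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if df.shape[1] < 2:
        raise ValueError("scan table needs two columns: radius and signal")
    return df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)
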