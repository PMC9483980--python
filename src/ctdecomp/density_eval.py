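"""Electron-density evaluation and the rearrangement density.

The rearrangement density uses the depletion-positive sign convention

    Δρ(r) = ρ_GS(r) − ρ_EX(r),

so regions that lose electron density upon excitation (becoming positively
charged relative to the ground state) carry Δρ > 0 and regions that gain
density carry Δρ < 0.  Some other tools use the opposite convention; the
convention tag travels with the data to keep reports unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem_io import DensityField, WfnData

__all__ = [
    "CARTESIAN_POWERS",
    "DifferenceDensity",
    "SignSplitDensity",
    "GridMismatchError",
    "evaluate_wfn_density",
    "density_on_grid",
    "difference_density",
    "split_signs",
]

SIGN_CONVENTION = "GS-minus-EX"

# AIM .wfn Cartesian type codes -> (a, b, c) powers of x^a y^b z^c.
# 1 = s; 2-4 = px,py,pz; 5-10 = dxx,dyy,dzz,dxy,dxz,dyz;
# 11-20 = fxxx,fyyy,fzzz,fxxy,fxxz,fyyz,fxyy,fxzz,fyzz,fxyz.
CARTESIAN_POWERS: dict[int, tuple[int, int, int]] = {
    1: (0, 0, 0),
    2: (1, 0, 0), 3: (0, 1, 0), 4: (0, 0, 1),
    5: (2, 0, 0), 6: (0, 2, 0), 7: (0, 0, 2),
    8: (1, 1, 0), 9: (1, 0, 1), 10: (0, 1, 1),
    11: (3, 0, 0), 12: (0, 3, 0), 13: (0, 0, 3),
    14: (2, 1, 0), 15: (2, 0, 1), 16: (0, 2, 1),
    17: (1, 2, 0), 18: (1, 0, 2), 19: (0, 1, 2),
    20: (1, 1, 1),
}


class GridMismatchError(ValueError):
    """Raised when two density fields do not share a common grid."""


@dataclass
class DifferenceDensity:
    """Signed rearrangement density Δρ = ρ_GS − ρ_EX on a common support."""

    support: DensityField          # grid metadata + GS geometry
    values: np.ndarray             # same shape as support.values, signed
    convention: str = SIGN_CONVENTION


@dataclass
class SignSplitDensity:
    """Non-negative split ρ⁺ = max(Δρ, 0), ρ⁻ = max(−Δρ, 0).

    At every point at most one of the two parts is nonzero and
    ρ⁺ − ρ⁻ reconstructs Δρ exactly.
    """

    support: DensityField
    rho_plus: np.ndarray
    rho_minus: np.ndarray


def evaluate_wfn_density(wfn: WfnData, points: np.ndarray,
                         chunk: int = 200_000) -> np.ndarray:
    """Evaluate ρ(r) = Σ_i occ_i (Σ_p c_ip χ_p(r))² at the given points.

    Primitives are Cartesian GTOs whose coefficients already absorb the
    normalisation constants, per the .wfn convention.  Points are (N, 3)
    in bohr; evaluation is chunked to bound memory on large point sets.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if not np.all(np.isfinite(pts)):
        raise ValueError("evaluation points must be finite")
    powers = np.array([CARTESIAN_POWERS[int(t)] for t in wfn.type_codes])
    centers = wfn.geometry.positions[wfn.centers]      # (nprim, 3)
    occ = wfn.occupations
    out = np.empty(len(pts))
    for start in range(0, len(pts), chunk):
        p = pts[start:start + chunk]                   # (n, 3)
        d = p[:, None, :] - centers[None, :, :]        # (n, nprim, 3)
        r2 = np.einsum("npk,npk->np", d, d)
        chi = np.exp(-wfn.exponents[None, :] * r2)
        for axis in range(3):
            pw = powers[:, axis]
            if np.any(pw):
                chi = chi * d[:, :, axis] ** pw[None, :]
        mo = chi @ wfn.coefficients.T                  # (n, nmo)
        out[start:start + chunk] = (mo * mo) @ occ
    return out


def density_on_grid(wfn: WfnData, origin: np.ndarray, axes: np.ndarray,
                    shape: tuple[int, int, int]) -> DensityField:
    """Evaluate a wavefunction density on a regular grid (voxel centers)."""
    shape = tuple(int(n) for n in shape)
    if min(shape) < 1:
        raise ValueError(f"empty grid shape {shape}")
    field = DensityField(origin, axes, np.zeros(shape), wfn.geometry)
    values = evaluate_wfn_density(wfn, field.voxel_centers())
    field.values = values.reshape(shape)
    return field


def difference_density(gs: DensityField, ex: DensityField) -> DifferenceDensity:
    """Δρ = ρ_GS − ρ_EX on the shared grid (depletion positive)."""
    mismatch = gs.same_grid(ex)
    if mismatch is not None:
        raise GridMismatchError(
            f"GS and EX fields differ in grid attribute '{mismatch}'"
        )
    if not gs.geometry.close_to(ex.geometry):
        raise GridMismatchError("GS and EX geometries differ beyond 1e-6 bohr")
    return DifferenceDensity(support=gs, values=gs.values - ex.values)


def split_signs(diff: DifferenceDensity) -> SignSplitDensity:
    """Split Δρ into its positive (depletion) and negative (enrichment)
    parts.  The exact sign decides; no magnitude threshold is applied, so
    ρ⁺ − ρ⁻ = Δρ bit-exactly and ρ⁺·ρ⁻ = 0 pointwise."""
    v = diff.values
    return SignSplitDensity(
        support=diff.support,
        rho_plus=np.where(v > 0, v, 0.0),
        rho_minus=np.where(v < 0, -v, 0.0),
    )
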