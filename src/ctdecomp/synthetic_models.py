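"""Synthetic ground/excited density pairs with known CT truth.

Model densities are sums of isotropic normalised 3-D Gaussians ("blobs"),

    ρ(r) = Σ_b  N_b (2πσ_b²)^{-3/2} exp(−|r − c_b|² / 2σ_b²),

with equal total norm in the ground and excited state (electron
conservation).  When every pair of distinct blob centers is separated by
more than 8σ the CT indexes have closed forms (each blob feeds one pole
entirely); otherwise a brute-force fine-grid oracle provides the truth.
This lets the full pipeline be validated end-to-end with no
quantum-chemistry input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .chem_io import DensityField, MolecularGeometry, WfnData, write_wfn
from .constants import BOHR_TO_ANGSTROM, DEBYE_PER_E_BOHR

__all__ = [
    "Blob",
    "BlobSpec",
    "ClosedFormTruth",
    "eval_blob_density",
    "make_cube_pair",
    "truth_for",
    "make_toy_wfn_pair",
    "two_blob_spec",
    "random_spec",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 20220902
SEPARATION_FACTOR = 8.0     # closed form valid beyond 8 sigma separation


@dataclass
class Blob:
    center: np.ndarray      # (3,) bohr
    sigma: float            # bohr
    norm: float             # e

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if self.sigma <= 0:
            raise ValueError("blob width must be positive")
        if self.norm < 0:
            raise ValueError("blob norm must be non-negative")


@dataclass
class BlobSpec:
    """A GS/EX blob-model pair plus grid and pseudo-atom metadata."""

    gs_blobs: list[Blob]
    ex_blobs: list[Blob]
    shape: tuple[int, int, int] = (80, 80, 80)
    padding_sigma: float = 6.0
    atoms: np.ndarray | None = None      # pseudo-atom positions, bohr

    def __post_init__(self) -> None:
        gs_total = sum(b.norm for b in self.gs_blobs)
        ex_total = sum(b.norm for b in self.ex_blobs)
        if abs(gs_total - ex_total) > 1e-9 * max(gs_total, 1.0):
            raise ValueError(
                f"electron conservation violated: GS norm {gs_total} vs "
                f"EX norm {ex_total}"
            )
        if self.atoms is not None:
            self.atoms = np.asarray(self.atoms, dtype=float).reshape(-1, 3)

    def all_blobs(self) -> list[Blob]:
        return list(self.gs_blobs) + list(self.ex_blobs)

    def geometry(self) -> MolecularGeometry:
        """Pseudo-atom geometry: explicit atoms, else distinct GS centers."""
        if self.atoms is not None:
            pos = self.atoms
        else:
            pos = _unique_rows([b.center for b in self.gs_blobs])
        n = len(pos)
        return MolecularGeometry(["H"] * n, np.ones(n, dtype=int), pos)

    def grid(self) -> tuple[np.ndarray, np.ndarray, tuple[int, int, int]]:
        """Cubic grid covering all blobs with the requested σ padding."""
        centers = np.array([b.center for b in self.all_blobs()])
        sig = max(b.sigma for b in self.all_blobs())
        lo = centers.min(axis=0) - self.padding_sigma * sig
        hi = centers.max(axis=0) + self.padding_sigma * sig
        shape = tuple(int(n) for n in self.shape)
        axes = np.diag((hi - lo) / np.array(shape))
        origin = lo + 0.5 * np.diag(axes)    # voxel centers
        return origin, axes, shape

    def to_dict(self) -> dict:
        return {
            "gs_blobs": [[b.center.tolist(), b.sigma, b.norm]
                         for b in self.gs_blobs],
            "ex_blobs": [[b.center.tolist(), b.sigma, b.norm]
                         for b in self.ex_blobs],
            "shape": list(self.shape),
            "padding_sigma": self.padding_sigma,
            "atoms": None if self.atoms is None else self.atoms.tolist(),
        }


@dataclass
class ClosedFormTruth:
    """Reference CT indexes for a blob spec."""

    q_ct: float                  # e
    r_plus: np.ndarray           # (3,) bohr
    r_minus: np.ndarray          # (3,) bohr
    d_ct_bohr: float
    d_ct_ang: float
    mu_norm_d: float
    mode: str                    # "well-separated" | "numeric-oracle"
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "q_ct_e": self.q_ct,
            "r_plus_bohr": self.r_plus.tolist(),
            "r_minus_bohr": self.r_minus.tolist(),
            "d_ct_bohr": self.d_ct_bohr,
            "d_ct_ang": self.d_ct_ang,
            "mu_norm_d": self.mu_norm_d,
            "mode": self.mode,
        }


def _unique_rows(rows, tol: float = 1e-9) -> np.ndarray:
    out: list[np.ndarray] = []
    for r in rows:
        r = np.asarray(r, dtype=float).reshape(3)
        if not any(np.linalg.norm(r - o) < tol for o in out):
            out.append(r)
    return np.array(out)


def eval_blob_density(spec: BlobSpec, points: np.ndarray,
                      which: str = "gs") -> np.ndarray:
    """Evaluate the GS or EX blob density at (N, 3) points (bohr)."""
    blobs = spec.gs_blobs if which == "gs" else spec.ex_blobs
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    out = np.zeros(len(pts))
    for b in blobs:
        d2 = np.sum((pts - b.center) ** 2, axis=1)
        pref = b.norm * (2.0 * np.pi * b.sigma ** 2) ** -1.5
        out += pref * np.exp(-d2 / (2.0 * b.sigma ** 2))
    return out


def make_cube_pair(spec: BlobSpec) -> tuple[DensityField, DensityField]:
    """GS and EX density fields on one shared grid.

    Warns (with the estimated truncated charge) if the grid padding is
    below 5σ for any blob.
    """
    import warnings

    origin, axes, shape = spec.grid()
    geometry = spec.geometry()
    gs = DensityField(origin, axes, np.zeros(shape), geometry)
    pts = gs.voxel_centers()
    gs_vals = eval_blob_density(spec, pts, "gs").reshape(shape)
    ex_vals = eval_blob_density(spec, pts, "ex").reshape(shape)
    gs.values = gs_vals
    ex = DensityField(origin, axes, ex_vals, geometry)
    if spec.padding_sigma < 5.0:
        # Gaussian tail mass beyond kσ: erfc-based bound per blob
        from math import erfc, sqrt
        k = spec.padding_sigma
        lost = sum(b.norm for b in spec.all_blobs()) * erfc(k / sqrt(2.0))
        warnings.warn(
            f"grid padding {k:.1f}σ < 5σ: up to ~{lost:.2e} e truncated",
            stacklevel=2,
        )
    return gs, ex


def _net_point_charges(spec: BlobSpec) -> tuple[np.ndarray, np.ndarray]:
    """Collapse blobs to signed point charges at distinct centers.

    GS blobs count +norm (depletion pole in the GS-minus-EX convention),
    EX blobs −norm; coincident centers merge.
    """
    centers = _unique_rows([b.center for b in spec.all_blobs()])
    net = np.zeros(len(centers))
    for b in spec.gs_blobs:
        i = int(np.argmin(np.linalg.norm(centers - b.center, axis=1)))
        net[i] += b.norm
    for b in spec.ex_blobs:
        i = int(np.argmin(np.linalg.norm(centers - b.center, axis=1)))
        net[i] -= b.norm
    return centers, net


def _is_well_separated(spec: BlobSpec) -> bool:
    blobs = spec.all_blobs()
    for i, bi in enumerate(blobs):
        for bj in blobs[i + 1:]:
            sep = float(np.linalg.norm(bi.center - bj.center))
            if sep < 1e-9:
                continue      # same center: merges, no overlap issue
            if sep <= SEPARATION_FACTOR * max(bi.sigma, bj.sigma):
                return False
    return True


def truth_for(spec: BlobSpec, oracle_shape: tuple[int, int, int] | None = None
              ) -> ClosedFormTruth:
    """Reference indexes: closed form when well separated, else a
    brute-force fine-grid integration of the difference density."""
    if _is_well_separated(spec):
        centers, net = _net_point_charges(spec)
        pos = net > 1e-12
        neg = net < -1e-12
        q_plus = float(np.sum(net[pos]))
        q_minus = float(-np.sum(net[neg]))
        if q_plus <= 0 or q_minus <= 0:
            return ClosedFormTruth(
                q_ct=0.0, r_plus=np.zeros(3), r_minus=np.zeros(3),
                d_ct_bohr=0.0, d_ct_ang=0.0, mu_norm_d=0.0,
                mode="well-separated", extra={"no_ct": True},
            )
        r_plus = (net[pos] @ centers[pos]) / q_plus
        r_minus = (-net[neg] @ centers[neg]) / q_minus
        q_ct = 0.5 * (q_plus + q_minus)
        d_bohr = float(np.linalg.norm(r_plus - r_minus))
        return ClosedFormTruth(
            q_ct=q_ct, r_plus=r_plus, r_minus=r_minus,
            d_ct_bohr=d_bohr, d_ct_ang=d_bohr * BOHR_TO_ANGSTROM,
            mu_norm_d=q_ct * d_bohr * DEBYE_PER_E_BOHR,
            mode="well-separated",
        )

    # numeric oracle: direct integration on a fine reference grid
    shape = oracle_shape or (192, 192, 192)
    ref = BlobSpec(spec.gs_blobs, spec.ex_blobs, shape=shape,
                   padding_sigma=max(spec.padding_sigma, 7.0),
                   atoms=spec.atoms)
    gs, ex = make_cube_pair(ref)
    diff = gs.values - ex.values
    plus = np.where(diff > 0, diff, 0.0)
    minus = np.where(diff < 0, -diff, 0.0)
    q_plus = gs.integrate(plus)
    q_minus = gs.integrate(minus)
    if q_plus < 1e-12 or q_minus < 1e-12:
        return ClosedFormTruth(
            q_ct=0.0, r_plus=np.zeros(3), r_minus=np.zeros(3),
            d_ct_bohr=0.0, d_ct_ang=0.0, mu_norm_d=0.0,
            mode="numeric-oracle", extra={"no_ct": True},
        )
    r_plus = gs.moment(plus) / q_plus
    r_minus = gs.moment(minus) / q_minus
    q_ct = 0.5 * (q_plus + q_minus)
    d_bohr = float(np.linalg.norm(r_plus - r_minus))
    return ClosedFormTruth(
        q_ct=q_ct, r_plus=r_plus, r_minus=r_minus,
        d_ct_bohr=d_bohr, d_ct_ang=d_bohr * BOHR_TO_ANGSTROM,
        mu_norm_d=q_ct * d_bohr * DEBYE_PER_E_BOHR,
        mode="numeric-oracle",
        extra={"oracle_shape": list(shape)},
    )


def _blobs_to_wfn(blobs: list[Blob], geometry: MolecularGeometry) -> WfnData:
    """Express blobs as single-s-primitive MOs: one MO per blob,
    occupation = norm, coefficient = the Gaussian normalisation prefactor
    so that occ·(cχ)² reproduces the blob density exactly."""
    nprim = len(blobs)
    centers = []
    for b in blobs:
        d = np.linalg.norm(geometry.positions - b.center, axis=1)
        i = int(np.argmin(d))
        if d[i] > 1e-9:
            raise ValueError(
                "toy wfn requires every blob center to sit on a pseudo-atom"
            )
        centers.append(i)
    exponents = np.array([1.0 / (4.0 * b.sigma ** 2) for b in blobs])
    coeffs = np.zeros((nprim, nprim))
    for k, b in enumerate(blobs):
        coeffs[k, k] = (2.0 * np.pi * b.sigma ** 2) ** -0.75
    return WfnData(
        geometry=geometry,
        centers=np.array(centers),
        type_codes=np.ones(nprim, dtype=int),
        exponents=exponents,
        occupations=np.array([b.norm for b in blobs]),
        energies=np.zeros(nprim),
        coefficients=coeffs,
    )


def make_toy_wfn_pair(spec: BlobSpec, gs_path: str, ex_path: str
                      ) -> tuple[WfnData, WfnData]:
    """Write GS/EX .wfn files whose densities equal the blob densities.

    Every blob must sit on a pseudo-atom (so the excited-state file shares
    the ground-state geometry, as for a vertical excitation).
    """
    all_centers = _unique_rows([b.center for b in spec.all_blobs()])
    if spec.atoms is None:
        geometry = MolecularGeometry(["H"] * len(all_centers),
                                     np.ones(len(all_centers), dtype=int),
                                     all_centers)
    else:
        geometry = spec.geometry()
    gs_wfn = _blobs_to_wfn(list(spec.gs_blobs), geometry)
    ex_wfn = _blobs_to_wfn(list(spec.ex_blobs), geometry)
    write_wfn(gs_wfn, gs_path, title="toy blob model, ground state")
    write_wfn(ex_wfn, ex_path, title="toy blob model, excited state")
    return gs_wfn, ex_wfn


def write_manifest(spec: BlobSpec, truth: ClosedFormTruth, path: str,
                   files: list[str]) -> None:
    with open(path, "w") as fh:
        json.dump({"spec": spec.to_dict(), "truth": truth.to_dict(),
                   "files": files}, fh, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------------------
# stock specs
# ---------------------------------------------------------------------------

def two_blob_spec(separation: float = 4.0, sigma: float = 0.4,
                  norm: float = 1.0, shape: tuple[int, int, int] = (80, 80, 80),
                  padding_sigma: float = 6.0) -> BlobSpec:
    """Unit charge hopping along x: GS blob at origin, EX blob at +separation."""
    return BlobSpec(
        gs_blobs=[Blob(np.zeros(3), sigma, norm)],
        ex_blobs=[Blob(np.array([separation, 0.0, 0.0]), sigma, norm)],
        shape=shape,
        padding_sigma=padding_sigma,
        atoms=np.array([[0.0, 0.0, 0.0], [separation, 0.0, 0.0]]),
    )


def random_spec(rng: np.random.Generator | int = DEFAULT_SEED,
                n_centers: int = 3, box: float = 6.0,
                sigma_range: tuple[float, float] = (0.35, 0.7),
                shape: tuple[int, int, int] = (64, 64, 64)) -> BlobSpec:
    """Randomised conserving GS/EX pair over a few pseudo-atom sites."""
    rng = np.random.default_rng(rng)
    centers = rng.uniform(-box / 2, box / 2, size=(n_centers, 3))
    sigmas = rng.uniform(*sigma_range, size=n_centers)
    gs_norms = rng.uniform(0.2, 1.0, size=n_centers)
    ex_norms = rng.uniform(0.2, 1.0, size=n_centers)
    ex_norms *= gs_norms.sum() / ex_norms.sum()
    gs = [Blob(c, s, n) for c, s, n in zip(centers, sigmas, gs_norms)]
    ex = [Blob(c, s, n) for c, s, n in zip(centers, sigmas, ex_norms)]
    return BlobSpec(gs, ex, shape=shape, atoms=centers)
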