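"""Real-space atomic partitions and molecular quadrature grids.

Three partition schemes are provided:

* grid QTAIM basins (disjoint): every voxel is attached to a density
  attractor by steepest ascent on the grid, with a near-grid
  trajectory-correction refinement of basin-boundary voxels; each attractor
  is mapped to its nearest nucleus,
* Becke fuzzy cells (weights in [0, 1] summing to 1 at every point), with
  the conventional k = 3 polynomial smoothing and Bragg–Slater size
  adjustment,
* nearest-nucleus (Voronoi) cells as a purely geometric baseline.

Partitions are state functions: for excited-state analyses they are meant
to be computed once from the ground-state density/geometry and reused for
every excited state of the same molecule.

Quadrature grids are atom-centered Gauss–Chebyshev radial grids (Becke's
rational map) crossed with a product Gauss–Legendre(cos θ) × uniform(φ)
angular grid, fused into one global grid by Becke weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dataclass_field

import numpy as np

from .chem_io import DensityField, GroupSpec, MolecularGeometry
from .constants import (
    ANGSTROM_TO_BOHR,
    BRAGG_SLATER_RADII_ANGSTROM,
    DEFAULT_BS_RADIUS_ANGSTROM,
    VACUUM_DENSITY,
)

__all__ = [
    "AtomPartition",
    "GroupPartition",
    "QuadratureGrid",
    "bader_grid_partition",
    "becke_partition",
    "nearest_nucleus_partition",
    "collapse_to_groups",
    "make_quadrature",
    "labels_to_field",
]


@dataclass
class AtomPartition:
    """Per-point assignment of space to atoms.

    ``mode == "disjoint"``: ``labels`` holds an integer atom index per point
    (any array shape).  ``mode == "fuzzy"``: ``weights`` holds one weight
    array per atom, stacked on axis 0, summing to 1 at every point.
    """

    mode: str
    natoms: int
    labels: np.ndarray | None = None
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("disjoint", "fuzzy"):
            raise ValueError(f"unknown partition mode {self.mode!r}")
        if self.mode == "disjoint":
            if self.labels is None:
                raise ValueError("disjoint partition requires labels")
            if np.any(self.labels < 0) or np.any(self.labels >= self.natoms):
                raise ValueError("labels outside atom range")
        else:
            if self.weights is None:
                raise ValueError("fuzzy partition requires weights")
            sums = np.sum(self.weights, axis=0)
            if not np.allclose(sums, 1.0, atol=1e-10):
                raise ValueError("fuzzy weights must sum to 1 at every point")

    def atom_weight(self, a: int) -> np.ndarray:
        """Indicator (disjoint) or fuzzy weight field of atom ``a``."""
        if self.mode == "disjoint":
            return (self.labels == a).astype(float)
        return self.weights[a]


@dataclass
class GroupPartition:
    """Atom partition collapsed onto named atom groups."""

    mode: str
    nsub: int
    names: list[str]
    labels: np.ndarray | None = None
    weights: np.ndarray | None = None

    def group_weight(self, g: int) -> np.ndarray:
        if self.mode == "disjoint":
            return (self.labels == g).astype(float)
        return self.weights[g]


@dataclass
class QuadratureGrid:
    """Global molecular quadrature: points (bohr) and weights (bohr³)."""

    points: np.ndarray          # (N, 3)
    weights: np.ndarray         # (N,)
    provenance: dict = dataclass_field(default_factory=dict)

    def integrate(self, values: np.ndarray) -> float:
        return float(np.dot(self.weights, values))

    def moment(self, values: np.ndarray) -> np.ndarray:
        return (self.weights * values) @ self.points


# ---------------------------------------------------------------------------
# grid QTAIM basins
# ---------------------------------------------------------------------------

_NEIGHBOR_OFFSETS = np.array(
    [(i, j, k)
     for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
     if (i, j, k) != (0, 0, 0)],
    dtype=int,
)


def _steepest_neighbor_pointers(field: DensityField) -> np.ndarray:
    """Flat pointer array: each voxel -> its best ascent neighbor (or self).

    The best neighbor maximises (ρ_nbr − ρ)/|Δr|; lexicographic offset order
    breaks ties deterministically (np.argmax keeps the first maximum).
    """
    rho = field.values
    n1, n2, n3 = rho.shape
    pad = np.full((n1 + 2, n2 + 2, n3 + 2), -np.inf)
    pad[1:-1, 1:-1, 1:-1] = rho
    best_gain = np.zeros_like(rho)
    best_off = np.full(rho.shape, -1, dtype=int)
    for m, off in enumerate(_NEIGHBOR_OFFSETS):
        dist = float(np.linalg.norm(off @ field.axes))
        i, j, k = off
        nbr = pad[1 + i:n1 + 1 + i, 1 + j:n2 + 1 + j, 1 + k:n3 + 1 + k]
        gain = (nbr - rho) / dist
        better = gain > best_gain
        best_gain = np.where(better, gain, best_gain)
        best_off = np.where(better, m, best_off)

    flat_idx = np.arange(rho.size).reshape(rho.shape)
    pointers = flat_idx.copy()
    strides = np.array([n2 * n3, n3, 1])
    has_up = best_off >= 0
    shift = _NEIGHBOR_OFFSETS[np.where(has_up, best_off, 0)] @ strides
    pointers = np.where(has_up, flat_idx + shift.reshape(rho.shape), flat_idx)
    return pointers.ravel()


def _resolve_pointers(pointers: np.ndarray) -> np.ndarray:
    """Pointer-jump every voxel to its terminal (self-pointing) voxel."""
    roots = pointers.copy()
    while True:
        nxt = roots[roots]
        if np.array_equal(nxt, roots):
            return roots
        roots = nxt


def _near_grid_refine(field: DensityField, labels: np.ndarray,
                      pointers: np.ndarray, max_steps: int = 100_000
                      ) -> np.ndarray:
    """Re-trace basin-boundary voxels with gradient trajectory correction.

    Each boundary voxel's trajectory follows the near-grid ascent all the
    way to its attractor: lattice steps track the true density gradient by
    accumulating the off-lattice remainder and paying it back whenever a
    component exceeds half a cell.  Steps are only accepted if the density
    strictly increases; otherwise the plain steepest-neighbor step is taken
    and the correction is reset, which guarantees termination.
    """
    rho = field.values
    shape = rho.shape
    n1, n2, n3 = shape
    inv_axes = np.linalg.inv(field.axes)

    # boundary voxels: any face neighbor with a different label
    lab3 = labels.reshape(shape)
    boundary = np.zeros(shape, dtype=bool)
    for axis in range(3):
        d = np.diff(lab3, axis=axis) != 0
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(0, -1)
        sl_hi[axis] = slice(1, None)
        boundary[tuple(sl_lo)] |= d
        boundary[tuple(sl_hi)] |= d

    # cartesian gradient mapped back to an index-space direction
    grad_idx = np.gradient(rho, axis=(0, 1, 2))
    gmat = inv_axes @ inv_axes.T
    gx = (grad_idx[0] * gmat[0, 0] + grad_idx[1] * gmat[1, 0]
          + grad_idx[2] * gmat[2, 0])
    gy = (grad_idx[0] * gmat[0, 1] + grad_idx[1] * gmat[1, 1]
          + grad_idx[2] * gmat[2, 1])
    gz = (grad_idx[0] * gmat[0, 2] + grad_idx[1] * gmat[1, 2]
          + grad_idx[2] * gmat[2, 2])

    new_labels = lab3.copy()
    for flat in np.flatnonzero(boundary.ravel()):
        i0, j0, k0 = np.unravel_index(flat, shape)
        if rho[i0, j0, k0] < VACUUM_DENSITY:
            continue
        i, j, k = int(i0), int(j0), int(k0)
        dri = drj = drk = 0.0
        for _ in range(max_steps):
            gi, gj, gk = gx[i, j, k], gy[i, j, k], gz[i, j, k]
            gmax = max(abs(gi), abs(gj), abs(gk))
            moved = False
            if gmax > 0:
                ti, tj, tk = gi / gmax, gj / gmax, gk / gmax
                si, sj, sk = round(ti), round(tj), round(tk)
                ndri, ndrj, ndrk = dri + ti - si, drj + tj - sj, drk + tk - sk
                if ndri > 0.5:
                    si += 1; ndri -= 1.0
                elif ndri < -0.5:
                    si -= 1; ndri += 1.0
                if ndrj > 0.5:
                    sj += 1; ndrj -= 1.0
                elif ndrj < -0.5:
                    sj -= 1; ndrj += 1.0
                if ndrk > 0.5:
                    sk += 1; ndrk -= 1.0
                elif ndrk < -0.5:
                    sk -= 1; ndrk += 1.0
                ci, cj, ck = i + si, j + sj, k + sk
                if ((si or sj or sk) and 0 <= ci < n1 and 0 <= cj < n2
                        and 0 <= ck < n3
                        and rho[ci, cj, ck] > rho[i, j, k]):
                    i, j, k = ci, cj, ck
                    dri, drj, drk = ndri, ndrj, ndrk
                    moved = True
            if not moved:
                cur_flat = (i * n2 + j) * n3 + k
                nxt = int(pointers[cur_flat])
                if nxt == cur_flat:
                    break       # attractor reached
                i, j, k = np.unravel_index(nxt, shape)
                i, j, k = int(i), int(j), int(k)
                dri = drj = drk = 0.0
        new_labels[i0, j0, k0] = lab3[i, j, k]
    return new_labels


def bader_grid_partition(field: DensityField, refine: bool = True,
                         attractor_cutoff: float = 2.0
                         ) -> tuple[AtomPartition, list[dict]]:
    """Partition a density grid into nuclear basins (zero-flux analogue).

    Every voxel is assigned to a density attractor by strictly-increasing
    steepest ascent; attractor voxels are then merged onto their nearest
    nucleus.  Attractors farther than ``attractor_cutoff`` (bohr) from every
    nucleus are flagged as non-nuclear and merged with a warning.  Voxels
    below the vacuum floor are labelled by nearest nucleus (their density
    contribution is numerically nil).
    """
    rho = field.values
    if not np.any(rho > 0):
        raise ValueError("density field has no positive values to ascend")
    geometry = field.geometry
    shape = rho.shape

    pointers = _steepest_neighbor_pointers(field)
    roots = _resolve_pointers(pointers)

    root_ids = np.unique(roots)
    # attractor positions and their nuclei
    attractors: list[dict] = []
    root_to_atom = {}
    centers = field.voxel_centers()
    for r in root_ids:
        pos = centers[r]
        dists = np.linalg.norm(geometry.positions - pos, axis=1)
        atom = int(np.argmin(dists))
        if dists[atom] > attractor_cutoff:
            warnings.warn(
                f"non-nuclear attractor at {pos} ({dists[atom]:.2f} bohr "
                f"from the nearest nucleus); merged to atom {atom + 1}",
                stacklevel=2,
            )
        root_to_atom[int(r)] = atom
        attractors.append({
            "position": pos,
            "voxel": int(r),
            "atom": atom,
            "density": float(rho.ravel()[r]),
        })
    lut = np.zeros(rho.size, dtype=int)
    lut[root_ids] = [root_to_atom[int(r)] for r in root_ids]
    labels = lut[roots].reshape(shape)

    # vacuum fallback keeps the partition total without polluting basins
    vacuum = rho < VACUUM_DENSITY
    if np.any(vacuum):
        vor = nearest_nucleus_partition(geometry, centers)
        labels = np.where(vacuum, vor.labels.reshape(shape), labels)

    if refine and geometry.natoms > 1:
        labels = _near_grid_refine(field, labels.ravel(), pointers)
        labels = np.where(vacuum,
                          nearest_nucleus_partition(
                              geometry, centers).labels.reshape(shape),
                          labels) if np.any(vacuum) else labels

    return AtomPartition(mode="disjoint", natoms=geometry.natoms,
                         labels=labels), attractors


# ---------------------------------------------------------------------------
# Becke fuzzy cells
# ---------------------------------------------------------------------------

def _bs_radius_bohr(symbol: str) -> float:
    r = BRAGG_SLATER_RADII_ANGSTROM.get(symbol.capitalize(),
                                        DEFAULT_BS_RADIUS_ANGSTROM)
    return r * ANGSTROM_TO_BOHR


def becke_partition(geometry: MolecularGeometry, points: np.ndarray,
                    k: int = 3, radii: dict[str, float] | None = None
                    ) -> AtomPartition:
    """Becke fuzzy atomic weights at the given points.

    Iterated-polynomial cell functions with ``k`` smoothing passes
    (default 3) and Bragg–Slater size adjustment.  ``radii`` optionally
    overrides per-element radii (in bohr).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    nat = geometry.natoms
    if nat == 1:
        return AtomPartition(mode="fuzzy", natoms=1,
                             weights=np.ones((1, len(pts))))
    pos = geometry.positions
    rij = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    if np.any(rij[~np.eye(nat, dtype=bool)] < 1e-8):
        raise ValueError("coincident nuclei: fuzzy cells undefined")

    if radii is None:
        rad = np.array([_bs_radius_bohr(s) for s in geometry.symbols])
    else:
        rad = np.array([
            radii.get(s.capitalize(), _bs_radius_bohr(s))
            for s in geometry.symbols
        ])
    chi = rad[:, None] / rad[None, :]
    u = (chi - 1.0) / (chi + 1.0)
    a = np.clip(u / (u * u - 1.0), -0.5, 0.5)

    dist = np.linalg.norm(pts[None, :, :] - pos[:, None, :], axis=-1)
    cell = np.ones((nat, len(pts)))
    for i in range(nat):
        for j in range(nat):
            if i == j:
                continue
            mu = (dist[i] - dist[j]) / rij[i, j]
            nu = mu + a[i, j] * (1.0 - mu * mu)
            f = nu
            for _ in range(k):
                f = 1.5 * f - 0.5 * f ** 3
            cell[i] *= 0.5 * (1.0 - f)
    total = np.sum(cell, axis=0)
    total = np.where(total > 0, total, 1.0)
    return AtomPartition(mode="fuzzy", natoms=nat, weights=cell / total)


def nearest_nucleus_partition(geometry: MolecularGeometry,
                              points: np.ndarray) -> AtomPartition:
    """Geometric Voronoi cells; distance ties go to the lowest atom index."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    dist = np.linalg.norm(pts[:, None, :] - geometry.positions[None, :, :],
                          axis=-1)
    labels = np.argmin(dist, axis=1)   # argmin takes the first minimum
    return AtomPartition(mode="disjoint", natoms=geometry.natoms,
                         labels=labels)


def collapse_to_groups(part: AtomPartition, spec: GroupSpec
                       ) -> GroupPartition:
    """Gather per-atom assignments into the selected atom-group subdomains."""
    if spec.natoms != part.natoms:
        raise ValueError(
            f"group spec covers {spec.natoms} atoms but partition has "
            f"{part.natoms}"
        )
    a2g = spec.atom_to_group()
    if part.mode == "disjoint":
        return GroupPartition(mode="disjoint", nsub=spec.nsub,
                              names=list(spec.names),
                              labels=a2g[part.labels])
    gw = np.zeros((spec.nsub,) + part.weights.shape[1:])
    for atom, g in enumerate(a2g):
        gw[g] += part.weights[atom]
    return GroupPartition(mode="fuzzy", nsub=spec.nsub,
                          names=list(spec.names), weights=gw)


# ---------------------------------------------------------------------------
# quadrature
# ---------------------------------------------------------------------------

def _radial_grid(n_radial: int, r_m: float) -> tuple[np.ndarray, np.ndarray]:
    """Gauss–Chebyshev (2nd kind) nodes under Becke's map r = r_m(1+x)/(1−x).

    Returns radii and weights such that Σ w_i f(r_i) ≈ ∫₀^∞ r² f(r) dr.
    """
    i = np.arange(1, n_radial + 1)
    x = np.cos(i * np.pi / (n_radial + 1))
    w_cheb = np.pi / (n_radial + 1) * np.sin(i * np.pi / (n_radial + 1)) ** 2
    # ∫ f dx = Σ w_cheb f(x)/√(1−x²)
    r = r_m * (1.0 + x) / (1.0 - x)
    dr_dx = 2.0 * r_m / (1.0 - x) ** 2
    w = w_cheb / np.sqrt(1.0 - x * x) * dr_dx * r * r
    return r, w


def make_quadrature(geometry: MolecularGeometry, n_radial: int = 75,
                    n_theta: int = 24, n_phi: int = 48, k_becke: int = 3
                    ) -> QuadratureGrid:
    """Atom-centered molecular quadrature grid fused by Becke weights.

    Radial: ``n_radial`` Gauss–Chebyshev points mapped to (0, ∞) with the
    Bragg–Slater radius of each element as map scale.  Angular: product
    grid, ``n_theta`` Gauss–Legendre points in cos θ × ``n_phi`` uniform
    points in φ.
    """
    if n_radial < 1 or n_theta < 1 or n_phi < 1:
        raise ValueError("quadrature point counts must be positive")
    cos_t, w_t = np.polynomial.legendre.leggauss(n_theta)
    sin_t = np.sqrt(1.0 - cos_t ** 2)
    phi = 2.0 * np.pi * (np.arange(n_phi) + 0.5) / n_phi
    w_phi = 2.0 * np.pi / n_phi

    # unit sphere directions and solid-angle weights
    dirs = np.empty((n_theta * n_phi, 3))
    w_ang = np.empty(n_theta * n_phi)
    m = 0
    for it in range(n_theta):
        for ip in range(n_phi):
            dirs[m] = (sin_t[it] * np.cos(phi[ip]),
                       sin_t[it] * np.sin(phi[ip]),
                       cos_t[it])
            w_ang[m] = w_t[it] * w_phi
            m += 1

    all_pts, all_w = [], []
    for atom in range(geometry.natoms):
        r_m = _bs_radius_bohr(geometry.symbols[atom])
        r, w_r = _radial_grid(n_radial, r_m)
        pts = (geometry.positions[atom]
               + (r[:, None, None] * dirs[None, :, :]).reshape(-1, 3))
        w = (w_r[:, None] * w_ang[None, :]).reshape(-1)
        all_pts.append(pts)
        all_w.append(w)
    points = np.concatenate(all_pts)
    weights = np.concatenate(all_w)

    if geometry.natoms > 1:
        becke = becke_partition(geometry, points, k=k_becke)
        n_per = n_radial * n_theta * n_phi
        fuse = np.empty(len(points))
        for atom in range(geometry.natoms):
            sl = slice(atom * n_per, (atom + 1) * n_per)
            fuse[sl] = becke.weights[atom][sl]
        weights = weights * fuse

    return QuadratureGrid(
        points=points,
        weights=weights,
        provenance={
            "n_radial": n_radial,
            "angular": f"product GL(cos theta) {n_theta} x uniform(phi) "
                       f"{n_phi}",
            "becke_k": k_becke,
        },
    )


def labels_to_field(field: DensityField, part: AtomPartition) -> DensityField:
    """Voxel labels as a cube-exportable scalar field (for visualisation)."""
    if part.mode != "disjoint":
        raise ValueError("only disjoint partitions have voxel labels")
    return DensityField(field.origin, field.axes,
                        part.labels.reshape(field.shape).astype(float),
                        field.geometry)
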