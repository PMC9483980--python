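"""Atomic partitions: grid basins, fuzzy cells, Voronoi cells, quadrature."""

import numpy as np
import pytest

from ctdecomp.chem_io import GroupSpec, MolecularGeometry
from ctdecomp.space_partition import (
    bader_grid_partition,
    becke_partition,
    collapse_to_groups,
    labels_to_field,
    make_quadrature,
    nearest_nucleus_partition,
)
from ctdecomp.synthetic_models import (
    Blob,
    BlobSpec,
    eval_blob_density,
    make_cube_pair,
)


def offgrid_ascent_labels(blobs, points, step=0.04, iters=400):
    """Independent oracle: fixed-step normalised gradient ascent on the
    analytic blob density, then assignment to the nearest blob center."""
    pts = np.asarray(points, dtype=float).copy()
    centers = np.array([b.center for b in blobs])
    for _ in range(iters):
        g = np.zeros_like(pts)
        for b in blobs:
            d = pts - b.center
            r2 = np.sum(d * d, axis=1)
            rho = b.norm * (2 * np.pi * b.sigma ** 2) ** -1.5 * np.exp(
                -r2 / (2 * b.sigma ** 2))
            g += -d / b.sigma ** 2 * rho[:, None]
        norm = np.linalg.norm(g, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        pts = pts + step * g / norm
    d = np.linalg.norm(pts[:, None, :] - centers[None, :, :], axis=2)
    return np.argmin(d, axis=1)


def _two_blob_field(norms=(1.0, 1.0), sigma=0.5, sep=4.0, n=56):
    spec = BlobSpec(
        gs_blobs=[Blob([-sep / 2, 0, 0], sigma, norms[0]),
                  Blob([sep / 2, 0, 0], sigma, norms[1])],
        ex_blobs=[Blob([-sep / 2, 0, 0], sigma, norms[0]),
                  Blob([sep / 2, 0, 0], sigma, norms[1])],
        shape=(n, n, n),
        atoms=np.array([[-sep / 2, 0, 0], [sep / 2, 0, 0]]),
    )
    gs, _ = make_cube_pair(spec)
    return spec, gs


class TestBaderGridPartition:
    def test_single_blob_single_basin(self):
        spec = BlobSpec([Blob([0, 0, 0], 0.5, 1.0)],
                        [Blob([0, 0, 0], 0.5, 1.0)], shape=(40, 40, 40),
                        atoms=np.array([[0.0, 0.0, 0.0]]))
        gs, _ = make_cube_pair(spec)
        part, attractors = bader_grid_partition(gs)
        assert np.all(part.labels == 0)
        pop = gs.integrate(gs.values * part.atom_weight(0))
        assert pop == pytest.approx(gs.integrate(gs.values), rel=1e-12)
        assert all(a["atom"] == 0 for a in attractors)

    def test_symmetric_blobs_split_fifty_fifty(self):
        _, gs = _two_blob_field()
        part, _ = bader_grid_partition(gs)
        total = gs.integrate(gs.values)
        p0 = gs.integrate(gs.values * part.atom_weight(0))
        assert p0 / total == pytest.approx(0.5, abs=0.005)
        # dividing surface sits on the x = 0 plane
        x = gs.origin[0] + np.arange(gs.shape[0]) * gs.axes[0, 0]
        labels = part.labels
        assert np.all(labels[x < -0.3] == 0)
        assert np.all(labels[x > 0.3] == 1)

    def test_unequal_blobs_match_offgrid_oracle(self):
        spec, gs = _two_blob_field(norms=(2.0, 1.0))
        part, _ = bader_grid_partition(gs)
        oracle = offgrid_ascent_labels(spec.gs_blobs, gs.voxel_centers())
        rho = gs.values.ravel()
        vol = gs.voxel_volume
        for atom in (0, 1):
            grid_pop = np.sum(rho[part.labels.ravel() == atom]) * vol
            oracle_pop = np.sum(rho[oracle == atom]) * vol
            assert grid_pop == pytest.approx(oracle_pop, rel=0.01)
        # the surface shifts toward the smaller blob
        assert gs.integrate(gs.values * part.atom_weight(0)) > \
            gs.integrate(gs.values * part.atom_weight(1))

    def test_basin_additivity_is_exact(self):
        _, gs = _two_blob_field(norms=(1.4, 0.6))
        part, _ = bader_grid_partition(gs)
        total = sum(gs.integrate(gs.values * part.atom_weight(a))
                    for a in range(2))
        assert total == pytest.approx(gs.integrate(gs.values), rel=1e-14)

    def test_nonnuclear_attractor_warns_and_merges(self):
        # nuclei placed far from the density maxima
        spec = BlobSpec([Blob([0, 0, 0], 0.5, 1.0)],
                        [Blob([0, 0, 0], 0.5, 1.0)], shape=(32, 32, 32),
                        atoms=np.array([[4.0, 4.0, 4.0]]))
        gs, _ = make_cube_pair(spec)
        with pytest.warns(UserWarning, match="non-nuclear attractor"):
            part, _ = bader_grid_partition(gs, attractor_cutoff=1.0)
        assert np.all(part.labels == 0)

    def test_labels_exportable_as_field(self):
        _, gs = _two_blob_field(n=24)
        part, _ = bader_grid_partition(gs)
        field = labels_to_field(gs, part)
        assert field.values.shape == gs.shape
        assert set(np.unique(field.values)) <= {0.0, 1.0}


class TestBeckePartition:
    def test_single_atom_weight_one(self, rng):
        geom = MolecularGeometry(["O"], [8], [[0.0, 0.0, 0.0]])
        part = becke_partition(geom, rng.normal(size=(50, 3)))
        assert np.all(part.weights == 1.0)

    def test_homonuclear_midpoint_half_half(self):
        geom = MolecularGeometry(["H", "H"], [1, 1],
                                 [[-1.0, 0, 0], [1.0, 0, 0]])
        part = becke_partition(geom, [[0.0, 0.0, 0.0]])
        assert part.weights[0, 0] == pytest.approx(0.5, abs=1e-12)
        assert part.weights[1, 0] == pytest.approx(0.5, abs=1e-12)

    def test_partition_of_unity(self, rng):
        geom = MolecularGeometry(["C", "O", "H"], [6, 8, 1],
                                 [[0, 0, 0], [2.3, 0, 0], [-1.0, 1.7, 0]])
        pts = rng.uniform(-6, 6, size=(1000, 3))
        part = becke_partition(geom, pts)
        assert np.allclose(part.weights.sum(axis=0), 1.0, atol=1e-10)
        assert np.all(part.weights >= 0) and np.all(part.weights <= 1)

    def test_coincident_nuclei_rejected(self):
        geom = MolecularGeometry(["H", "H"], [1, 1],
                                 [[0, 0, 0], [0, 0, 0]])
        with pytest.raises(ValueError, match="coincident"):
            becke_partition(geom, [[1.0, 0, 0]])

    def test_heteronuclear_size_adjustment_shifts_boundary(self):
        # at the geometric midpoint the larger atom should win weight
        geom = MolecularGeometry(["C", "H"], [6, 1],
                                 [[0, 0, 0], [2.0, 0, 0]])
        part = becke_partition(geom, [[1.0, 0.0, 0.0]])
        assert part.weights[0, 0] > part.weights[1, 0]


class TestNearestNucleus:
    def test_tie_goes_to_lowest_index(self):
        geom = MolecularGeometry(["H", "H"], [1, 1],
                                 [[-1.0, 0, 0], [1.0, 0, 0]])
        part = nearest_nucleus_partition(geom, [[0.0, 0.0, 0.0]])
        assert part.labels[0] == 0

    def test_point_on_atom(self):
        geom = MolecularGeometry(["C", "O"], [6, 8],
                                 [[0, 0, 0], [2.0, 0, 0]])
        part = nearest_nucleus_partition(geom, [[2.0, 0.0, 0.0]])
        assert part.labels[0] == 1

    def test_agrees_with_becke_argmax_far_from_boundary(self, rng):
        geom = MolecularGeometry(["H", "H"], [1, 1],
                                 [[-2.0, 0, 0], [2.0, 0, 0]])
        pts = rng.uniform(-5, 5, size=(400, 3))
        far = np.abs(pts[:, 0]) > 1.0        # away from the midplane
        vor = nearest_nucleus_partition(geom, pts[far])
        becke = becke_partition(geom, pts[far])
        assert np.array_equal(vor.labels, np.argmax(becke.weights, axis=0))


class TestCollapseToGroups:
    def test_per_atom_spec_is_identity(self):
        _, gs = _two_blob_field(n=20)
        part, _ = bader_grid_partition(gs)
        spec = GroupSpec.per_atom(gs.geometry)
        groups = collapse_to_groups(part, spec)
        assert np.array_equal(groups.labels, part.labels)

    def test_single_group_owns_everything(self):
        _, gs = _two_blob_field(n=20)
        part, _ = bader_grid_partition(gs)
        spec = GroupSpec(["all"], [[1, 2]], 2)
        groups = collapse_to_groups(part, spec)
        assert np.all(groups.group_weight(0) == 1.0)

    def test_fuzzy_group_weights_still_sum_to_one(self, rng):
        geom = MolecularGeometry(["C", "O", "H"], [6, 8, 1],
                                 [[0, 0, 0], [2.3, 0, 0], [-1.0, 1.7, 0]])
        pts = rng.uniform(-5, 5, size=(200, 3))
        part = becke_partition(geom, pts)
        spec = GroupSpec(["CO", "H"], [[1, 2], [3]], 3)
        groups = collapse_to_groups(part, spec)
        total = groups.group_weight(0) + groups.group_weight(1)
        assert np.allclose(total, 1.0, atol=1e-10)

    def test_geometry_mismatch_rejected(self):
        _, gs = _two_blob_field(n=16)
        part, _ = bader_grid_partition(gs)
        with pytest.raises(ValueError, match="group spec"):
            collapse_to_groups(part, GroupSpec(["a"], [[1, 2, 3]], 3))


class TestQuadrature:
    def _blob_on_atom(self, geom, sigma=0.6):
        return [Blob(p, sigma, 1.0) for p in geom.positions]

    def test_single_gaussian_integrates_to_one(self):
        geom = MolecularGeometry(["H"], [1], [[0.3, -0.2, 0.1]])
        quad = make_quadrature(geom, n_radial=50, n_theta=16, n_phi=32)
        spec = BlobSpec([Blob(geom.positions[0], 0.6, 1.0)],
                        [Blob(geom.positions[0], 0.6, 1.0)])
        vals = eval_blob_density(spec, quad.points, "gs")
        assert quad.integrate(vals) == pytest.approx(1.0, abs=1e-8)

    def test_two_atom_sum_integrates_to_two(self):
        geom = MolecularGeometry(["H", "H"], [1, 1],
                                 [[-1.5, 0, 0], [1.5, 0, 0]])
        quad = make_quadrature(geom, n_radial=60, n_theta=20, n_phi=40)
        spec = BlobSpec(self._blob_on_atom(geom), self._blob_on_atom(geom))
        vals = eval_blob_density(spec, quad.points, "gs")
        assert quad.integrate(vals) == pytest.approx(2.0, abs=1e-6)

    def test_radial_refinement_converges(self):
        geom = MolecularGeometry(["H", "H"], [1, 1],
                                 [[-1.5, 0, 0], [1.5, 0, 0]])
        spec = BlobSpec(self._blob_on_atom(geom), self._blob_on_atom(geom))
        errors = []
        for n_radial in (10, 20, 40):
            quad = make_quadrature(geom, n_radial=n_radial, n_theta=20,
                                   n_phi=40)
            vals = eval_blob_density(spec, quad.points, "gs")
            errors.append(abs(quad.integrate(vals) - 2.0))
        assert errors[0] > errors[1] > errors[2]

    def test_positive_counts_required(self):
        geom = MolecularGeometry(["H"], [1], [[0, 0, 0]])
        with pytest.raises(ValueError, match="positive"):
            make_quadrature(geom, n_radial=0)

    def test_weights_positive(self):
        geom = MolecularGeometry(["H", "O"], [1, 8],
                                 [[0, 0, 0], [1.8, 0, 0]])
        quad = make_quadrature(geom, n_radial=20, n_theta=10, n_phi=20)
        assert np.all(quad.weights >= 0)
        assert quad.provenance["n_radial"] == 20
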