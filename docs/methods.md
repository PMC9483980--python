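# Methods

## Model and assumptions

The package analyses *vertical* electronic excitations: ground and excited
densities share one nuclear geometry, so the nuclear dipole terms cancel
and the electronic first moment of the rearrangement density equals the
molecular dipole change.  The rearrangement density uses the
depletion-positive convention Δρ = ρ_GS − ρ_EX; some other CT-analysis
tools use the opposite sign, so every report carries a convention tag.
The sign split is exact — ρ⁺ = max(Δρ, 0), ρ⁻ = max(−Δρ, 0), with no
magnitude threshold — which makes ρ⁺ − ρ⁻ = Δρ bit-exact and keeps
∫ρ⁺ = ∫ρ⁻ for any conserving Δρ.

Analytically q⁺ = q⁻; numerically they differ by the integration error.
The package uses the symmetric mean q_CT = (q⁺ + q⁻)/2 wherever a single
transferred charge enters a product, and always reports the gap q⁺ − q⁻
verbatim as an accuracy diagnostic, alongside Δ‖μ_CT‖ against either a
supplied ab initio dipole change or the directly integrated first moment
of Δρ.

The decomposition is defined for any fuzzy or disjoint exhaustive
partition.  Two design points are pinned by exactness requirements rather
than convention:

* the subdomain length vectors are normalised per pole by the *global*
  charges, `d^Ω = ∫_Ω r ρ⁺ dr / q⁺ − ∫_Ω r ρ⁻ dr / q⁻`, which is the
  unique choice making `Σ_Ω d^Ω = R⁺ − R⁻` an identity (and hence every
  dipole sum rule exact up to floating point);
* the inter-subdomain (pair) dipole terms `M^{j,±}_{ik}` (i ≠ k) are
  reported as pair terms and never redistributed to single subdomains —
  any symmetric half-and-half split would be arbitrary, so the package
  deliberately refuses to offer one.

Degenerate inputs: a transition with both pole charges below
q_floor = 1e-8 e is rejected as "no appreciable charge transfer" (this
guard exists for identical-state inputs; real transitions never approach
it).  When D_CT = 0 with q_CT > 0 the direction cosines and g weights are
undefined and reported as NaN rather than invented.

## Space partitions

**Grid basins (QTAIM analogue).**  Voxels are assigned to density
attractors by steepest ascent on the grid: a vectorised pass points every
voxel to the 26-neighbour maximising (ρ_nbr − ρ)/|Δr| (lexicographic
neighbour order breaks ties deterministically), pointer-jumping resolves
all paths at once, and attractors are merged onto their nearest nucleus.
Because pure on-grid ascent biases basin boundaries along lattice
directions, voxels on a basin boundary are then re-traced with a
near-grid trajectory correction: lattice steps follow the interpolated
density gradient, the off-lattice remainder accumulates and is paid back
whenever a component exceeds half a cell, and each trajectory runs to its
attractor.  Steps are accepted only if the density strictly increases
(with fallback to the plain steepest neighbour and a correction reset),
which guarantees termination.  Accuracy is controlled by grid spacing:
on two-Gaussian test fields the basin populations agree with an off-grid
gradient-ascent oracle to ≲0.1% when the voxel spacing resolves the
boundary region, degrading to ~1% when two blobs overlap so strongly
(separation ≲ 3σ) that the dividing surface crosses high density — such
cases need finer grids, and the tests use them there.

Policies: attractors farther than a cutoff (default 2 bohr) from every
nucleus are flagged as non-nuclear with a warning and merged to the
nearest nucleus; voxels below 1e-12 e·bohr⁻³ are labelled by nearest
nucleus (their population contribution is numerically nil, but the
partition stays total).  No beta-sphere treatment is applied; all voxels
are treated uniformly.

**Becke fuzzy cells.**  Standard iterated-polynomial cell functions with
k = 3 smoothing passes and Bragg–Slater size adjustment (Slater radii,
H = 0.35 Å, default 1.0 Å for unlisted elements; all overridable).

**Nearest-nucleus cells.**  Geometric Voronoi baseline; distance ties go
to the lowest atom index.

The partition is a state function, so for excited-state series it is
computed once from the ground-state density/geometry and reused — ground
and excited densities are then decomposed over identical subdomains.

## Integration

Grid route: midpoint rule over voxels; first moments are accumulated by
index sums, never by materialising a point cloud.  Wavefunction route:
atom-centered quadrature, n_radial Gauss–Chebyshev (second kind) nodes
under Becke's rational map r = R_m(1+x)/(1−x) with the element's
Bragg–Slater radius as scale, crossed with a product angular grid
(Gauss–Legendre in cos θ × uniform φ), fused into one molecular grid by
Becke weights.  Defaults (75 radial, 24×48 angular) integrate
two-Gaussian test densities to ~1e-6; 50 radial points already recover a
single normalised Gaussian to 1e-8.  The two routes agree on q_CT to
better than 1e-3 e on toy fixtures, which is the package's own path-
equivalence bar.

Cartesian GTO evaluation follows the AIM `.wfn` conventions: type codes
1–20 (s, p, d up to f; the d order is xx, yy, zz, xy, xz, yz and the f
order xxx, yyy, zzz, xxy, xxz, yyz, xyy, xzz, yzz, xyz), with MO
coefficients absorbing primitive normalisation.  Codes above 20
(g functions) are rejected loudly.

## Units

Internally everything is in atomic units; Å and Debye appear only at the
reporting boundary, with pinned constants 1 bohr = 0.529177210903 Å and
1 e·bohr = 2.541746473 D (hence 1 e·Å ≈ 4.8032047 D).  Reported centroid
coordinates stay in the input frame; no recentering or reorientation is
ever applied.

## Synthetic models and what the tests show

The test generator builds GS/EX pairs as sums of isotropic normalised
Gaussians with equal total norm.  When all distinct blob centers are
separated by more than 8σ each blob feeds one pole entirely and every
index has a closed form (the 8σ switch-over is itself tested from both
sides); otherwise a fine-grid (192³–256³) brute-force integration serves
as oracle.  Grids default to 6σ padding (a warning estimates the
truncated charge below 5σ).  Blob models exercise the full pipeline —
formats, sign split, partitions, integrators, decomposition algebra —
with known truth, and their smooth, nodally simple densities are exactly
the regime where the density-difference CT construction is
well-conditioned.  What they do
*not* emulate: nuclear cusps, basis-set ripple, diffuse tails of real
TD-DFT densities, or near-degenerate multi-pole rearrangements; agreement
on blobs therefore validates the machinery and the algebra, not the
physics of any particular quantum-chemistry input.

The published four-subdomain worked example (a merocyanine dye) is used
as printed-number algebra: subdomain charges and length components from
the source tables recombine through the package's matrix and
charge-weighted decompositions into the printed dipole terms within the
3-decimal rounding of the inputs (≤0.3% relative).  The full ab initio
densities behind those tables (CAM-B3LYP/cc-pVDZ with implicit solvent)
are outside this package's scope — it consumes densities, it does not
produce them.

## Problem sizes

Default test problem sizes: 48³–128³ voxel grids for pipeline checks,
one 256³ reference integration for the overlapping-pair oracle, 96³
grids for basin/oracle comparison on strongly overlapping blobs, ~50k
quadrature points for the wavefunction route.  These sizes put grid
discretisation error one to two orders below every tolerance being
tested.

## Known limitations

* Grid basins approximate zero-flux surfaces by voxel assignment; there
  is no analytic surface triangulation, `.sur` boundary import, or
  critical-point classification.
* Only total densities are consumed: no transition densities, natural
  transition orbitals, or distinction between relaxed and unrelaxed
  excited-state densities (the EX density is treated as opaque input).
* Other CT metrics (Λ overlap, exciton size, hole–electron Δr) and
  delocalisation indices (which need pair densities) are out of scope.
* `.wfn` is the only wavefunction format read (no .wfx/fchk/molden), and
  cube files with the negative-natoms orbital-ID dialect are rejected.
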