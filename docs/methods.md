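# Methods

## Model

A molecule is modeled as the union of atomic spheres: atom `i` at position
`A_i` with radius `R_i` drawn from an element-indexed table, optionally
augmented by a solvent-probe radius `r_p` (so `r_p = 0` gives the van der
Waals surface and `r_p ≈ 1.4 Å` the water-accessible surface). The vdW
surface stands in for an electron iso-density surface; because different
iso-density thresholds are appropriate for different molecular states
(0.001 a.u. for gas phase, 0.002 a.u. for condensed phases, 0.0016 a.u.
for thermodynamically effective surfaces), three radius calibrations are
exposed under those names. The base (0.001 a.u.) table is the Bondi
consensus set with common extensions; the alternative calibrations apply
uniform shrink factors of 0.97 and 0.95. Those factors are declared
defaults, not fitted values — no published per-threshold radius set is
bundled — and any table can be substituted from a plain-text
`ELEMENT radius` file.

## Grid construction

The axis-aligned bounding box of the atom centers gives
`V_rec = ∏(k_max − k_min)`, which selects the grid spacing `h`: either the
universal 0.43 Å or a size-dependent lookup table `V_rec → h` supplied at
run time. The lattice origin is anchored at `box_min − padding` with
`padding = max_i R_i + 2h`. Anchoring to the molecule makes all counts
translation-covariant (translating the molecule translates the lattice
with it), and the padding guarantees that every non-exterior voxel has a
complete 3×3×3 neighborhood, which the correction pass requires.

## Classification

For every lattice point `P` the exact signed distance to the nearest
atomic surface is computed: `s(P) = min_i (|P − A_i| − R_i)`, evaluated
over per-atom local windows of half-width `R_i + 2h` (an exact
decomposition, not an approximation: points outside every window are
necessarily exterior). Labels are

* internal: `s < −2·tol`
* surface: `−2·tol ≤ s ≤ 0`
* external: `s > 0`

with `tol = h/2` by default, i.e. a surface band one voxel thick lying
*inside* the surface and ending exactly on it. Two consequences drive
this choice. First, the internal+surface count `G_V` is then exactly the
number of lattice points on or inside the union surface — the idealized
(measure-zero-equality) classification — so the volume estimator
`V = G_V·h³` is asymptotically unbiased; a band centered on the surface
would inflate the volume by approximately `S·tol` (measured: +7.5% for a
2 Å sphere at `h = 0.1`). Second, the one-voxel-thick shell makes the raw
count `G_S·h²` a first-order estimate of the surface area, which is what
the empirical calibration below expects.

"Nearest atom" means nearest *surface* (arg-min of the signed distance),
not nearest center. For unequal radii the two differ, and the
nearest-center variant misclassifies points covered by a larger neighbor
(measured: a 1.5 Å³ deficit per C–H pair against the union volume, and a
degenerate result for fully contained atoms). The signed-distance rule
makes "inside the nearest atom" coincide exactly with "inside the union
of spheres", and attributes each surface voxel to the atom whose surface
it lies on — the standard attribution for per-atom surface
decompositions. Ties (equidistant surfaces) go to the lowest atom index;
this is deterministic and affects only PSA attribution on exact symmetry
planes.

## Isolated-point correction

After classification, interior lattice points are scanned against their
26 neighbors (6 face-, 12 edge-, 8 corner-sharing; 13 opposing pairs). A
point is a correction candidate only when it is *isolated* — none of the
26 neighbors shares its label. An isolated point whose opposing neighbors
along some direction agree with each other is relabeled to their shared
label (first qualifying direction in lexicographic order). Sweeps run in
lexicographic order with in-place updates, repeating until a sweep
changes nothing (cap: 100 sweeps, with a logged warning on hitting it).

The isolation precondition is essential. Without it the pair rule acts as
a morphological erosion/dilation filter on correctly classified curved
shells: measured on exactly classified lattices it shifted volume by
−4% (water) to +2.7% (a 20-atom molecule) and oscillated without
terminating. Restricted to isolated voxels it is a targeted repair of
single-point misassignments, terminates, and is a near-no-op on exact
classifications — which is the correct behavior, since the exact
signed-distance classifier produces no misassignments to repair. The pass
is retained in the default pipeline because it is part of the method's
contract and remains meaningful for approximate or user-supplied
classifications.

## Descriptors

With `G_V`, `G_S`, `G_P` the internal+surface, surface, and polar-surface
voxel counts:

* `V = G_V · h³` (Å³)
* `S = G_S · h² · 1.261 + 13.506` (Å²)
* `S_PSA = (G_P / G_S) · S` (Å²), defined as 0 when `G_S = 0`

The two surface constants are fixed published calibration values mapping
the raw one-voxel shell count to quantum-chemistry reference surface
areas; they are applied identically in all threshold modes (an
approximation — whether the original calibration was per-threshold is not
disclosed) and are overridable only through keyword arguments intended
for research use. Note the additive constant imposes `S ≥ 13.506 Å²`, and
the calibration targets molecule-scale surfaces; the raw shell count
`G_S·h²` is exposed alongside for geometric validation work.

Polar atoms are N and O, plus hydrogens whose nearest N/O lies within
1.2 Å (covering N–H ≈ 1.01 Å and O–H ≈ 0.96 Å bonds while excluding
nonbonded contacts ≥ 1.5 Å; the pipeline performs no bond perception
anywhere, so bonded hydrogens are recognized geometrically). Optionally S
counts as polar, with its hydrogen reach extended by 0.25 Å because S–H
bonds (~1.34 Å) exceed the base cutoff.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| spacing `h` | 0.43 (universal) | Å | mean of 57 per-molecule optima; size-dependent table recommended for surface-area accuracy |
| `surface_tol` | `h/2` | Å | half-width of the surface band; `h/2` makes the shell one voxel thick |
| `probe_radius` | 0 | Å | 0 = vdW surface, 1.4 = water-accessible |
| threshold mode | `iso_0001` | — | radius calibration (0.001/0.0016/0.002 a.u.) |
| `polar_h_cutoff` | 1.2 | Å | max H→N/O distance for a polar hydrogen |
| `include_sulfur` | off | — | whether S/SH counts toward PSA |
| `point_cap` | 10⁹ | voxels | guard against accidental huge grids |
| correction `max_iters` | 100 | sweeps | termination cap with logged warning |

## Oracles and what passing tests show

The independent oracles are: closed-form sphere volume/area, the
spherical-cap two-sphere union formula, and a seeded Monte-Carlo
union-of-spheres integrator (uniform samples in the padded box, binomial
standard error). The Monte-Carlo estimator is the arbiter when grid and
analytic answers disagree, since it uses no lattice and no band.

The synthetic-molecule generator produces random clouds (default: atoms
uniform in an 8 Å cube, elements drawn C/H/N/O/S with drug-like weights
0.35/0.42/0.08/0.12/0.03), collinear chains and regular rings, all
deterministic per seed. These exercise overlapping spheres of mixed radii
at roughly drug-like packing, but they are not chemically valid
geometries: no valence, no bond-length realism in clouds, no
conformational correlation. Consequently the passing oracle suite
demonstrates the *geometric* correctness of the voxel integration
(volume within Monte-Carlo error, shell counts near analytic areas, PSA
attribution identities) — it does not re-establish the empirical accuracy
of the surface calibration against quantum-chemistry references, which
would require the original reference data set.

Problem sizes used by the validation suite: spheres at spacings
0.1–0.2 Å (≲10⁶ voxels), 20 synthetic molecules of 5–30 atoms at 0.15 Å
against 10⁶-sample Monte-Carlo runs. These sizes give standard errors
well below the tolerances being checked.

One check fails by design: the universal 0.43 Å spacing is defined as the
arithmetic mean of 57 per-molecule optima, but only the mean is published
in the main text; the per-molecule table ships in supplementary material
not distributed here, so the mean cannot be independently recomputed.
The test runs against a user-supplied optima table and fails with an
explanatory message when none is present.

## Numerical choices

* Exact nearest-surface distances (no 26-direction search heuristics);
  per-atom windows make classification O(atoms · (R/h)³).
* Ties in nearest-atom attribution: lowest index.
* Correction sweeps: lexicographic order, in-place (Gauss–Seidel style),
  numba-compiled.
* All coordinates are taken verbatim from input files (Å assumed); no
  recentering or sanitization beyond finiteness checks. Unknown elements
  and missing radii are hard errors, never silent skips.
* Degenerate inputs: a single atom yields `V_rec = 0` and a padded cube
  grid; an empty frame is rejected at parse time; an empty surface shell
  yields `S = 13.506 Å²` and `S_PSA = 0`.
* Determinism: the pipeline contains no randomness; identical inputs give
  bit-identical outputs. Monte-Carlo and bootstrap routines take explicit
  seeds.

## Statistics module

For paired method/reference series: MSE, RMSE (`= √MSE`), MAE, per-pair
relative error `(method − reference)/reference`, APE (its absolute value,
%), MAPE (mean APE), Pearson's r, R² (OLS of method on reference with
intercept, equal to r² in simple regression — reported separately because
both conventions appear in comparison tables), and Bland–Altman mean
residual with ±1.96·SD limits of agreement (sample SD, ddof = 1).
Bootstrap uncertainty is the replicate standard deviation over pairs
resampled with replacement (percentile intervals available behind a
flag). Cochran sample-size selection `n = z²·p̂(1−p̂)/ε²` with the
finite-population correction `n′ = n/(1 + n/N)` is included for building
reference subsets. MAPE is intentionally asymmetric under role swap (its
denominator is the reference); RMSE and MAE are symmetric.

## Known limitations

* Accuracy against quantum-chemistry surfaces is inherited from the
  published calibration, not re-established here.
* The surface calibration constants are applied identically across
  threshold modes and probe radii.
* Large systems scale as the voxel count: ~(extent/h)³ memory and time;
  the point cap guards but does not parallelize.
* No cavity/void detection, no solvent-excluded (Connolly) surfaces, no
  triangulated meshes; SDF is V2000 only; no bond-order or charge
  interpretation.
* PSA attribution at exact symmetry planes depends on the deterministic
  lowest-index tie-break.
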