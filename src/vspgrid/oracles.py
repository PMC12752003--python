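"""Independent ground truths: analytic sphere formulas, the two-sphere
union closed form, Monte-Carlo volume integration and a deterministic
synthetic-molecule generator.

None of these touch the voxel lattice, so they validate the grid engine
from the outside. The Monte-Carlo estimator is the arbiter whenever grid
and analytic answers disagree: it uses no grid and no tolerance band, only
union-of-spheres membership.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .frames import MolecularFrame
from .radii import RadiiTable, default_radii

__all__ = [
    "Geometry",
    "SyntheticSpec",
    "analytic_sphere",
    "two_sphere_union_volume",
    "mc_volume",
    "generate_molecule",
]


def analytic_sphere(r: float) -> tuple[float, float]:
    """Exact volume (4/3)πr³ and area 4πr² of a sphere of radius ``r`` Å."""
    if r <= 0:
        raise ValueError("sphere radius must be > 0")
    return (4.0 / 3.0) * math.pi * r**3, 4.0 * math.pi * r**2


def two_sphere_union_volume(r1: float, r2: float, d: float) -> float:
    """Exact volume of the union of two spheres at center distance ``d``.

    Inclusion–exclusion with the spherical-cap lens formula: disjoint
    spheres sum, a contained sphere contributes nothing beyond the larger
    one, and partial overlaps subtract the lens volume.
    """
    if r1 <= 0 or r2 <= 0:
        raise ValueError("sphere radii must be > 0")
    if d < 0:
        raise ValueError("center distance must be >= 0")
    v1 = (4.0 / 3.0) * math.pi * r1**3
    v2 = (4.0 / 3.0) * math.pi * r2**3
    if d >= r1 + r2:
        return v1 + v2
    if d + min(r1, r2) <= max(r1, r2):
        return max(v1, v2)
    lens = (
        math.pi
        * (r1 + r2 - d) ** 2
        * (d**2 + 2.0 * d * (r1 + r2) - 3.0 * (r1 - r2) ** 2)
        / (12.0 * d)
    )
    return v1 + v2 - lens


def mc_volume(
    frame: MolecularFrame,
    radii: RadiiTable | None = None,
    n_samples: int = 10**6,
    seed: int = 0,
    chunk: int = 200_000,
) -> tuple[float, float]:
    """Monte-Carlo union-of-spheres volume: (estimate, standard error), Å³.

    Uniform samples in the bounding box padded by the largest augmented
    radius; a hit is a sample inside any atom's sphere. The standard error
    is the binomial one, ``box_volume · sqrt(p(1−p)/n)``. Fixed seed ⇒
    reproducible.
    """
    if n_samples < 10**4:
        raise ValueError("n_samples must be >= 1e4 for a meaningful estimate")
    if radii is None:
        radii = default_radii()
    aug = radii.radii_for(frame)
    coords = frame.coords
    pad = aug.max()
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    box_volume = float(np.prod(hi - lo))
    rng = np.random.default_rng(seed)
    hits = 0
    done = 0
    while done < n_samples:
        m = min(chunk, n_samples - done)
        pts = rng.uniform(lo, hi, size=(m, 3))
        inside = np.zeros(m, dtype=bool)
        for pos, r in zip(coords, aug):
            need = ~inside
            if not need.any():
                break
            delta = pts[need] - pos
            inside[need] = np.einsum("ij,ij->i", delta, delta) <= r * r
        hits += int(inside.sum())
        done += m
    p = hits / n_samples
    estimate = p * box_volume
    se = box_volume * math.sqrt(max(p * (1.0 - p), 0.0) / n_samples)
    return estimate, se


class Geometry(enum.Enum):
    random_cloud = "random_cloud"
    linear_chain = "linear_chain"
    ring = "ring"


#: Drug-like organic element weights, so polar (N/O/H) paths are exercised.
_DEFAULT_POOL: tuple[tuple[str, float], ...] = (
    ("C", 0.35),
    ("H", 0.42),
    ("N", 0.08),
    ("O", 0.12),
    ("S", 0.03),
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Deterministic recipe for a synthetic test molecule.

    ``box_scale`` (default 8 Å) sets the cube edge for the random cloud;
    at 10–30 atoms it produces overlapping vdW spheres at roughly drug-like
    packing density. ``bond_length`` (default 1.5 Å, a typical C–C bond)
    spaces chains and rings. Identical specs produce identical molecules.
    """

    n_atoms: int
    element_pool: tuple[tuple[str, float], ...] = _DEFAULT_POOL
    geometry: Geometry = Geometry.random_cloud
    bond_length: float = 1.5
    box_scale: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_atoms < 1:
            raise ValueError("n_atoms must be >= 1")
        if self.geometry is Geometry.ring and self.n_atoms < 3:
            raise ValueError("a ring needs at least 3 atoms")
        if self.bond_length <= 0 or self.box_scale <= 0:
            raise ValueError("bond_length and box_scale must be > 0")


def generate_molecule(spec: SyntheticSpec) -> MolecularFrame:
    """Build the molecule a :class:`SyntheticSpec` describes.

    Geometries are purely geometric (no valence or clash checks): a chain
    is collinear at ``bond_length`` steps, a ring is a regular polygon with
    ``bond_length`` edges, and a cloud is uniform in a cube of edge
    ``box_scale``. Elements are drawn from the weighted pool with the
    spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    symbols = [s for s, _ in spec.element_pool]
    weights = np.array([w for _, w in spec.element_pool], dtype=float)
    weights /= weights.sum()
    elements = rng.choice(symbols, size=spec.n_atoms, p=weights)

    n = spec.n_atoms
    if spec.geometry is Geometry.linear_chain:
        coords = np.zeros((n, 3))
        coords[:, 0] = spec.bond_length * np.arange(n)
    elif spec.geometry is Geometry.ring:
        # regular polygon with edge length == bond_length
        circumradius = spec.bond_length / (2.0 * math.sin(math.pi / n))
        theta = 2.0 * math.pi * np.arange(n) / n
        coords = np.column_stack(
            [circumradius * np.cos(theta), circumradius * np.sin(theta), np.zeros(n)]
        )
    else:
        coords = rng.uniform(0.0, spec.box_scale, size=(n, 3))

    return MolecularFrame.from_arrays(list(elements), coords)
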