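"""Theoretical collision cross sections from atomic coordinates.

Two hard-sphere estimators are implemented from scratch:

* **Projection approximation (PA)** — the orientation-averaged shadow
  area of the union of atom spheres inflated by the buffer-gas radius.
  Each random orientation contributes a Monte-Carlo estimate of the
  projected union-of-disks area; PA is a lower bound for concave bodies
  because it ignores multiple scattering.

* **Exact hard sphere scattering (EHSS)** — the orientation-averaged
  momentum-transfer cross section. Probe rays are traced through
  specular reflections off the inflated atom spheres (multiple
  collisions allowed), and each ray is weighted by 1 - cos(theta) of its
  total deflection. For convex bodies EHSS equals PA; concavities can
  only add momentum transfer, so EHSS >= PA in general.

Also provided: optimal rigid-body superposition RMSD (Kabsch) between
conformers, and the percent contraction of an experimental CCS relative
to a theoretical one — the standard way of quantifying gas-phase
structural collapse after desolvation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .units import A2_PER_NM2

__all__ = [
    "AtomicStructure",
    "TheoreticalCCS",
    "ELEMENT_RADII",
    "pa_ccs",
    "ehss_ccs",
    "superpose_rmsd",
    "contraction_percent",
]

#: Hard-sphere collision radii per element, in angstroms (Bondi van der
#: Waals radii for the common biomolecular elements). Override per atom
#: via ``AtomicStructure.collision_radii``; atoms of unlisted elements
#: fall back to ``DEFAULT_RADIUS``.
ELEMENT_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80, "S": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "NA": 2.27, "MG": 1.73,
    "K": 2.75, "CA": 2.31, "ZN": 1.39, "FE": 1.52, "SE": 1.90,
}
DEFAULT_RADIUS = 1.70


@dataclass
class AtomicStructure:
    """Element symbols, coordinates (angstrom) and collision radii."""

    elements: list[str]
    coordinates: np.ndarray  # (N, 3) angstrom
    collision_radii: np.ndarray | None = None  # (N,) angstrom
    label: str = ""

    def __post_init__(self):
        self.coordinates = np.atleast_2d(
            np.asarray(self.coordinates, dtype=float))
        n = self.coordinates.shape[0]
        if self.coordinates.shape != (n, 3):
            raise ValueError("coordinates must have shape (N, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        if len(self.elements) != n:
            raise ValueError("one element symbol per atom required")
        if self.collision_radii is None:
            self.collision_radii = np.array(
                [ELEMENT_RADII.get(e.upper(), DEFAULT_RADIUS)
                 for e in self.elements])
        else:
            self.collision_radii = np.asarray(self.collision_radii,
                                              dtype=float)
        if self.collision_radii.shape != (n,):
            raise ValueError("one collision radius per atom required")
        if np.any(self.collision_radii <= 0):
            raise ValueError("collision radii must be positive")

    def __len__(self) -> int:
        return self.coordinates.shape[0]

    @classmethod
    def from_pdb(cls, path, label: str | None = None) -> "AtomicStructure":
        """First model of a PDB/mmCIF file; altloc B and beyond dropped.

        Hydrogens are included when present in the file, never added.
        """
        import gemmi

        structure = gemmi.read_structure(str(path))
        structure.setup_entities()
        model = structure[0]
        elements, coords = [], []
        for chain in model:
            for residue in chain:
                for atom in residue:
                    if atom.altloc not in ("", "A", "\x00"):
                        continue
                    elements.append(atom.element.name)
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
        if not coords:
            raise ValueError(f"no atoms read from {path}")
        return cls(elements, np.array(coords),
                   label=label or structure.name or str(path))

    @classmethod
    def from_xyz(cls, path, label: str | None = None) -> "AtomicStructure":
        """Plain XYZ file: count line, comment line, then `El x y z` rows."""
        with open(path) as fh:
            lines = [ln for ln in fh.read().splitlines() if ln.strip()]
        n = int(lines[0].split()[0])
        elements, coords = [], []
        for ln in lines[2:2 + n]:
            parts = ln.split()
            elements.append(parts[0])
            coords.append([float(v) for v in parts[1:4]])
        if len(coords) != n:
            raise ValueError(f"expected {n} atoms in {path}, got {len(coords)}")
        return cls(elements, np.array(coords), label=label or str(path))


@dataclass
class TheoreticalCCS:
    """A Monte-Carlo CCS estimate with its statistical uncertainty."""

    method: str  # "PA" or "EHSS"
    value: float  # nm^2
    mc_standard_error: float  # nm^2
    n_samples: int
    gas_radius: float  # angstrom
    seed: int
    extras: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"method": self.method, "value_nm2": self.value,
                       "mc_standard_error_nm2": self.mc_standard_error,
                       "n_samples": self.n_samples,
                       "gas_radius_A": self.gas_radius, "seed": self.seed,
                       **self.extras}, fh, indent=2, sort_keys=True)


def _random_rotations(n: int, rng: np.random.Generator) -> Rotation:
    """Uniform random rotations from normalised Gaussian quaternions."""
    quat = rng.normal(size=(n, 4))
    quat /= np.linalg.norm(quat, axis=1, keepdims=True)
    return Rotation.from_quat(quat)


def pa_ccs(structure: AtomicStructure, gas_radius: float = 1.0,
           n_orientations: int = 64, n_hits_per_orientation: int = 4000,
           seed: int = 0) -> TheoreticalCCS:
    """Projection-approximation CCS by Monte-Carlo shadow-area sampling.

    For each uniformly random orientation the structure is projected
    onto a plane and the area of the union of disks (atom radius + gas
    radius) is estimated by rejection sampling inside the bounding
    rectangle. The CCS is the mean over orientations; the standard
    error comes from the orientation-to-orientation spread.
    """
    if n_orientations < 1 or n_hits_per_orientation < 1:
        raise ValueError("sampling budgets must be >= 1")
    rng = np.random.default_rng(seed)
    radii = structure.collision_radii + gas_radius
    r2 = radii ** 2
    areas = np.empty(n_orientations)
    for i, rot in enumerate(_random_rotations(n_orientations, rng)):
        xy = rot.apply(structure.coordinates)[:, :2]
        lo = (xy - radii[:, None]).min(axis=0)
        hi = (xy + radii[:, None]).max(axis=0)
        box = np.prod(hi - lo)
        pts = rng.uniform(lo, hi, size=(n_hits_per_orientation, 2))
        d2 = ((pts[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
        inside = (d2 <= r2[None, :]).any(axis=1)
        areas[i] = box * inside.mean()
    value = areas.mean() / A2_PER_NM2
    se = (areas.std(ddof=1) / np.sqrt(n_orientations) / A2_PER_NM2
          if n_orientations > 1 else float("nan"))
    return TheoreticalCCS("PA", float(value), float(se),
                          n_samples=n_orientations * n_hits_per_orientation,
                          gas_radius=gas_radius, seed=seed)


def _trace_orientation(xyz, radii, n_rays, rng, max_reflections):
    """Momentum-transfer cross section (A^2) for one fixed orientation.

    Rays travel along -z from above the structure; each specular
    reflection off an inflated atom sphere updates the direction until
    the ray escapes. The contribution of a ray is 1 - cos(theta_total);
    misses deflect nothing and contribute zero.
    """
    r2 = radii ** 2
    lo = (xyz[:, :2] - radii[:, None]).min(axis=0)
    hi = (xyz[:, :2] + radii[:, None]).max(axis=0)
    box = float(np.prod(hi - lo))
    z0 = (xyz[:, 2] + radii).max() + 1.0

    pts = rng.uniform(lo, hi, size=(n_rays, 2))
    pos = np.column_stack([pts, np.full(n_rays, z0)])
    dirs = np.tile([0.0, 0.0, -1.0], (n_rays, 1))
    active = np.ones(n_rays, dtype=bool)
    discarded = np.zeros(n_rays, dtype=bool)

    for _ in range(max_reflections):
        if not active.any():
            break
        p, d = pos[active], dirs[active]
        oc = xyz[None, :, :] - p[:, None, :]  # (n_active, n_atoms, 3)
        proj = np.einsum("ijk,ik->ij", oc, d)
        disc = r2[None, :] - ((oc ** 2).sum(axis=2) - proj ** 2)
        t = np.where(disc >= 0, proj - np.sqrt(np.clip(disc, 0, None)),
                     np.inf)
        t = np.where(t > 1e-9, t, np.inf)
        t_min = t.min(axis=1)
        hit = np.isfinite(t_min)
        if not hit.any():
            active[active] = False
            break
        atom = t.argmin(axis=1)
        p_new = p + t_min[:, None].clip(max=1e30) * d
        normal = (p_new - xyz[atom]) / radii[atom][:, None]
        d_new = d - 2.0 * np.einsum("ij,ij->i", d, normal)[:, None] * normal

        idx = np.flatnonzero(active)
        pos[idx[hit]] = p_new[hit]
        dirs[idx[hit]] = d_new[hit]
        active[idx[~hit]] = False
    else:
        # rays still bouncing at the cap are discarded but counted
        discarded[active] = True
        active[:] = False

    # deflection weight: initial direction is (0,0,-1)
    weights = 1.0 + dirs[:, 2]
    weights[discarded] = 0.0
    n_used = n_rays - int(discarded.sum())
    omega = box * weights[~discarded].mean() if n_used else 0.0
    return omega, int(discarded.sum())


def ehss_ccs(structure: AtomicStructure, gas_radius: float = 1.0,
             n_trajectories: int = 50_000, seed: int = 0,
             n_orientations: int = 50,
             max_reflections: int = 100) -> TheoreticalCCS:
    """Exact-hard-sphere-scattering CCS by Monte-Carlo ray tracing.

    ``n_trajectories`` probe rays are split evenly over
    ``n_orientations`` uniformly random orientations. Rays exceeding
    ``max_reflections`` bounces are discarded and counted in
    ``extras['n_discarded']``.
    """
    if n_trajectories < 1:
        raise ValueError("n_trajectories must be >= 1")
    n_orientations = min(n_orientations, n_trajectories)
    per = max(n_trajectories // n_orientations, 1)
    rng = np.random.default_rng(seed)
    radii = structure.collision_radii + gas_radius

    omegas = np.empty(n_orientations)
    n_discarded = 0
    for i, rot in enumerate(_random_rotations(n_orientations, rng)):
        xyz = rot.apply(structure.coordinates)
        omegas[i], disc = _trace_orientation(xyz, radii, per, rng,
                                             max_reflections)
        n_discarded += disc
    value = omegas.mean() / A2_PER_NM2
    se = (omegas.std(ddof=1) / np.sqrt(n_orientations) / A2_PER_NM2
          if n_orientations > 1 else float("nan"))
    return TheoreticalCCS("EHSS", float(value), float(se),
                          n_samples=n_orientations * per,
                          gas_radius=gas_radius, seed=seed,
                          extras={"n_discarded": n_discarded,
                                  "n_orientations": n_orientations})


def superpose_rmsd(a: AtomicStructure, b: AtomicStructure,
                   normalize: bool = False):
    """RMSD after optimal rigid-body superposition (Kabsch).

    Atoms must be equal in number and matched in order. With
    ``normalize=True`` a second value is returned: the RMSD as a percent
    of the reference structure's radius of gyration — a package
    convention for a dimensionless deformation measure, not a standard.
    """
    if len(a) != len(b):
        raise ValueError("structures must have matching atom counts")
    xa = a.coordinates - a.coordinates.mean(axis=0)
    xb = b.coordinates - b.coordinates.mean(axis=0)
    if len(a) == 1:
        rmsd = 0.0
    else:
        _, rssd = Rotation.align_vectors(xa, xb)
        rmsd = float(rssd / np.sqrt(len(a)))
    if not normalize:
        return rmsd
    rg = float(np.sqrt((xa ** 2).sum(axis=1).mean()))
    return rmsd, 100.0 * rmsd / rg


def contraction_percent(ccs_exp: float, ccs_theory: float) -> float:
    """Percent contraction of an experimental CCS below a theoretical one.

    100 * (theory - exp) / theory: positive when the measured ion is
    more compact than the model structure; swapping the arguments flips
    the sign of the comparison (the convention here divides by theory).
    """
    if ccs_exp <= 0 or ccs_theory <= 0:
        raise ValueError("CCS values must be positive")
    return 100.0 * (ccs_theory - ccs_exp) / ccs_theory
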