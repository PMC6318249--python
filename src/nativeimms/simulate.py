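"""Synthetic-data generators standing in for the instrument.

Every input class the analysis pipeline consumes can be generated here
with known ground-truth parameters: native mass spectra as sums of
charge-state Gaussian envelopes (with optional +79.966 Da
phospho-proteoform ladders), titration ratio curves from the 1:1
binding model, CCS distributions of one or several Gaussian conformer
families, collision-induced-unfolding fingerprints with logistic state
transitions and optional pre-unfolding compaction, and toy atomic
geometries for validating the hard-sphere CCS engines.

All generators are deterministic for a fixed seed, and exactly
noise-free when the noise parameter is zero, so every downstream stage
can be tested against known truth. The noise model throughout is
additive Gaussian on intensity with a floor at zero.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.special import expit

from .binding import TitrationSeries, evaluate_binding_ratio
from .calibration import CCSDistribution
from .ciu import CIUFingerprint
from .ccstheory import AtomicStructure
from .spectra import MassSpectrum
from .units import mz_for

__all__ = [
    "SpeciesSpec",
    "CIUGroundTruth",
    "generate_mass_spectrum",
    "generate_titration_series",
    "generate_ccs_distribution",
    "generate_ciu_fingerprint",
    "generate_toy_structure",
    "write_ground_truth",
]


@dataclass
class SpeciesSpec:
    """Ground truth for one species in a synthetic native spectrum.

    ``proteoform_shifts`` lists (mass shift in Da, fraction) pairs for
    modified proteoforms; the unmodified form carries the remaining
    fraction. ``charge_weights`` optionally skews the envelope across
    its charge states (uniform by default).
    """

    label: str
    neutral_mass: float  # Da
    charge_states: list[int]
    relative_abundance: float = 1.0
    proteoform_shifts: list[tuple[float, float]] = field(default_factory=list)
    charge_weights: list[float] | None = None

    def __post_init__(self):
        if self.neutral_mass <= 0:
            raise ValueError("neutral_mass must be positive")
        if not self.charge_states:
            raise ValueError("charge_states must be non-empty")
        if any(z < 1 for z in self.charge_states):
            raise ValueError("charge states must be positive integers")
        if self.relative_abundance < 0:
            raise ValueError("relative_abundance must be >= 0")
        fracs = [f for _, f in self.proteoform_shifts]
        if any(not 0 <= f <= 1 for f in fracs) or sum(fracs) > 1 + 1e-12:
            raise ValueError("proteoform fractions must lie in [0,1] "
                             "and sum to <= 1")
        if self.charge_weights is not None and (
                len(self.charge_weights) != len(self.charge_states)):
            raise ValueError("one charge weight per charge state required")

    def proteoforms(self) -> list[tuple[float, float]]:
        """(mass shift, fraction) pairs including the unmodified form."""
        rest = 1.0 - sum(f for _, f in self.proteoform_shifts)
        return [(0.0, rest)] + list(self.proteoform_shifts)


def generate_mass_spectrum(species: list[SpeciesSpec], mz_range,
                           peak_sigma: float, noise_level: float = 0.0,
                           seed: int = 0, grid_step: float = 0.25,
                           total_area: float = 1.0) -> MassSpectrum:
    """Synthesise a native mass spectrum from species ground truth.

    The spectrum is the sum over species x charge state x proteoform of
    Gaussians of width ``peak_sigma`` (Da/e) whose *areas* are
    proportional to relative_abundance x charge weight x proteoform
    fraction; the summed envelope area of each species is its abundance
    fraction of ``total_area``. Additive Gaussian noise of standard
    deviation ``noise_level`` x (max signal) is applied and floored at
    zero; ``noise_level=0`` gives a deterministic spectrum.
    """
    if not species:
        raise ValueError("species list must not be empty")
    if peak_sigma <= 0:
        raise ValueError("peak_sigma must be positive")
    lo, hi = float(mz_range[0]), float(mz_range[1])
    if hi <= lo:
        raise ValueError("mz_range must be a non-empty interval")

    mz = np.arange(lo, hi + grid_step / 2, grid_step)
    intensity = np.zeros_like(mz)
    total_ab = sum(s.relative_abundance for s in species)
    if total_ab <= 0:
        raise ValueError("at least one species must have positive abundance")

    truth_peaks = []
    norm = 1.0 / (peak_sigma * np.sqrt(2.0 * np.pi))
    for sp in species:
        weights = (np.asarray(sp.charge_weights, dtype=float)
                   if sp.charge_weights is not None
                   else np.ones(len(sp.charge_states)))
        weights = weights / weights.sum()
        sp_area = total_area * sp.relative_abundance / total_ab
        for z, wz in zip(sp.charge_states, weights):
            for shift, frac in sp.proteoforms():
                if frac == 0:
                    continue
                centre = mz_for(sp.neutral_mass + shift, z)
                if not lo <= centre <= hi:
                    raise ValueError(
                        f"peak of {sp.label!r} at m/z {centre:.2f} (z={z}) "
                        f"falls outside mz_range {mz_range}")
                area = sp_area * wz * frac
                intensity += area * norm * np.exp(
                    -0.5 * ((mz - centre) / peak_sigma) ** 2)
                truth_peaks.append({"species": sp.label, "charge": z,
                                    "shift": shift, "centre": centre,
                                    "area": area})

    if noise_level > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(
            0.0, noise_level * intensity.max(), size=intensity.size)
        intensity = np.clip(intensity, 0.0, None)

    truth = {
        "species": [
            {"label": s.label, "neutral_mass": s.neutral_mass,
             "charge_states": list(s.charge_states),
             "relative_abundance": s.relative_abundance,
             "abundance_fraction": s.relative_abundance / total_ab,
             "proteoform_shifts": [list(p) for p in s.proteoform_shifts]}
            for s in species],
        "peaks": truth_peaks,
        "peak_sigma": peak_sigma, "noise_level": noise_level, "seed": seed,
    }
    return MassSpectrum(mz, intensity, metadata={"ground_truth": truth})


def generate_titration_series(kd_nm: float, p0_um: float, l0_values_um,
                              noise_sd: float = 0.0, seed: int = 0,
                              label: str = "") -> TitrationSeries:
    """Titration ratio curve from the 1:1 binding model, optionally noisy.

    Ratios follow :func:`nativeimms.binding.evaluate_binding_ratio`
    exactly when ``noise_sd`` is zero; otherwise additive Gaussian noise
    of that standard deviation is applied and floored at zero.
    """
    l0 = np.asarray(l0_values_um, dtype=float)
    ratio = np.atleast_1d(evaluate_binding_ratio(p0_um, l0, kd_nm))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ratio = np.clip(ratio + rng.normal(0.0, noise_sd, ratio.size),
                        0.0, None)
    return TitrationSeries(p0_um=p0_um, l0_um=l0, ratio=ratio, label=label)


def generate_ccs_distribution(centroids, fwhms, weights=None,
                              ccs_axis=None, charge: int = 1,
                              noise_level: float = 0.0,
                              seed: int = 0) -> CCSDistribution:
    """Gaussian single- or multi-conformer CCS distribution.

    ``centroids`` and ``fwhms`` are per-conformer (nm^2); weights
    default to equal. The default axis spans the conformers with a
    0.05 nm^2 grid step.
    """
    centroids = np.atleast_1d(np.asarray(centroids, dtype=float))
    fwhms = np.atleast_1d(np.asarray(fwhms, dtype=float))
    if fwhms.size == 1:
        fwhms = np.full(centroids.size, fwhms[0])
    if np.any(fwhms <= 0):
        raise ValueError("FWHM values must be positive")
    w = (np.ones(centroids.size) if weights is None
         else np.asarray(weights, dtype=float))
    w = w / w.sum()
    sigmas = fwhms / 2.3548200450309493  # FWHM of a Gaussian = 2*sqrt(2 ln2)*sigma
    if ccs_axis is None:
        lo = (centroids - 5 * sigmas).min()
        hi = (centroids + 5 * sigmas).max()
        ccs_axis = np.arange(lo, hi, 0.05)
    ccs_axis = np.asarray(ccs_axis, dtype=float)
    intensity = np.zeros_like(ccs_axis)
    for c, s, wk in zip(centroids, sigmas, w):
        intensity += wk * np.exp(-0.5 * ((ccs_axis - c) / s) ** 2)
    if noise_level > 0:
        rng = np.random.default_rng(seed)
        intensity = np.clip(
            intensity + rng.normal(0.0, noise_level * intensity.max(),
                                   intensity.size), 0.0, None)
    return CCSDistribution(ccs_axis, intensity, charge=charge)


@dataclass
class CIUGroundTruth:
    """Ground truth for a synthetic unfolding fingerprint.

    ``conformer_centroids`` (nm^2) has one entry per conformational
    state; consecutive states are connected by logistic transitions at
    ``transition_midpoints`` (V) with width ``transition_widths`` (V,
    scalar or one per transition). ``initial_compaction`` (nm^2) lowers
    the native-state centroid, ramped in over the pre-transition voltage
    range, emulating gentle-activation structural contraction.
    """

    conformer_centroids: list[float]
    transition_midpoints: list[float] = field(default_factory=list)
    transition_widths: float | list[float] = 2.0
    initial_compaction: float = 0.0

    def __post_init__(self):
        c = np.asarray(self.conformer_centroids, dtype=float)
        v = np.asarray(self.transition_midpoints, dtype=float)
        if c.size != v.size + 1:
            raise ValueError("need exactly one more conformer centroid than "
                             "transition midpoints")
        if c.size > 1 and np.any(np.diff(c) <= 0):
            raise ValueError("conformer centroids must be strictly increasing")
        if v.size > 1 and np.any(np.diff(v) <= 0):
            raise ValueError("transition midpoints must be strictly increasing")
        w = np.atleast_1d(np.asarray(self.transition_widths, dtype=float))
        if np.any(w <= 0):
            raise ValueError("transition widths must be positive")
        if self.initial_compaction < 0:
            raise ValueError("initial_compaction must be >= 0")

    def widths(self) -> np.ndarray:
        w = np.atleast_1d(np.asarray(self.transition_widths, dtype=float))
        if w.size == 1:
            w = np.full(len(self.transition_midpoints), w[0])
        return w


def generate_ciu_fingerprint(truth: CIUGroundTruth, cv_axis, ccs_axis,
                             peak_sigma: float, seed: int = 0,
                             noise_level: float = 0.0) -> CIUFingerprint:
    """Synthetic CIU fingerprint with logistic state transitions.

    At each collision voltage the state occupancies follow nested
    logistic transitions at the ground-truth midpoints; the mobility
    profile is a single Gaussian of width ``peak_sigma`` centred on the
    occupancy-weighted conformer centroid (lowered by the ramped
    compaction term while the native state dominates). Every voltage
    column is normalised to integrate (sum) to 1, before and after the
    optional additive noise.
    """
    cv = np.asarray(cv_axis, dtype=float)
    ccs = np.asarray(ccs_axis, dtype=float)
    if np.any(np.diff(cv) <= 0) or np.any(np.diff(ccs) <= 0):
        raise ValueError("cv and ccs axes must be strictly increasing")
    if peak_sigma <= 0:
        raise ValueError("peak_sigma must be positive")
    mids = np.asarray(truth.transition_midpoints, dtype=float)
    if mids.size and (mids.min() < cv[0] or mids.max() > cv[-1]):
        raise ValueError("transition midpoints must lie within cv_axis")

    centroids = np.asarray(truth.conformer_centroids, dtype=float)
    widths = truth.widths()
    n_states = centroids.size

    # nested occupancies: p_k = prod(f_1..f_k) - prod(f_1..f_{k+1});
    # telescopes to 1 and reduces to sequential steps when separated
    f = (expit((cv[:, None] - mids[None, :]) / widths[None, :])
         if mids.size else np.empty((cv.size, 0)))
    cumf = np.hstack([np.ones((cv.size, 1)), np.cumprod(f, axis=1)])
    occ = np.hstack([cumf[:, :-1] - cumf[:, 1:], cumf[:, -1:]])
    assert occ.shape == (cv.size, n_states)

    centre = occ @ centroids
    if truth.initial_compaction > 0 and mids.size:
        ramp = np.clip((cv - cv[0]) / max(mids[0] - cv[0], 1e-12), 0.0, 1.0)
        centre = centre - occ[:, 0] * truth.initial_compaction * ramp

    intensity = np.exp(-0.5 * ((ccs[None, :] - centre[:, None])
                               / peak_sigma) ** 2)
    if noise_level > 0:
        rng = np.random.default_rng(seed)
        intensity = np.clip(
            intensity + rng.normal(0.0, noise_level, intensity.shape),
            0.0, None)
    sums = intensity.sum(axis=1)
    if np.any(sums <= 0):
        raise ValueError("a voltage column lost all intensity; widen ccs_axis")
    intensity /= sums[:, None]
    return CIUFingerprint(cv, ccs, intensity, normalization="column_sum",
                          metadata={"ground_truth": asdict(truth),
                                    "seed": seed,
                                    "noise_level": noise_level})


def generate_toy_structure(geometry: str, n_atoms: int, scale: float = 10.0,
                           seed: int = 0, atom_radius: float = 1.7,
                           separation: float | None = None,
                           rise: float = 3.4,
                           atoms_per_turn: float = 10.0) -> AtomicStructure:
    """Toy atomic geometries for validating the CCS engines.

    * ``sphere-shell`` — ``n_atoms`` points uniformly distributed on a
      sphere of radius ``scale``.
    * ``two-sphere-dimer`` — two such shells of radius ``scale`` with
      centres ``separation`` apart (default 4 x scale) along x; in the
      widely separated limit the PA cross section approaches twice a
      single shell's.
    * ``helix`` — a helix of radius ``scale`` with ``rise`` angstrom per
      atom and ``atoms_per_turn`` atoms per turn; with the B-form DNA
      rise of 3.4 angstrom this serves as a crude duplex stand-in.

    All atoms get the uniform collision radius ``atom_radius``.
    A single atom is placed at the origin for any geometry.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    rng = np.random.default_rng(seed)
    if n_atoms == 1:
        coords = np.zeros((1, 3))
    elif geometry == "sphere-shell":
        coords = _sphere_points(n_atoms, scale, rng)
    elif geometry == "two-sphere-dimer":
        sep = 4.0 * scale if separation is None else separation
        half = n_atoms // 2
        a = _sphere_points(half, scale, rng) - [sep / 2, 0, 0]
        b = _sphere_points(n_atoms - half, scale, rng) + [sep / 2, 0, 0]
        coords = np.vstack([a, b])
    elif geometry == "helix":
        i = np.arange(n_atoms)
        theta = 2.0 * np.pi * i / atoms_per_turn
        coords = np.column_stack([scale * np.cos(theta),
                                  scale * np.sin(theta), rise * i])
    else:
        raise ValueError(f"unknown geometry {geometry!r}; expected "
                         "'sphere-shell', 'two-sphere-dimer' or 'helix'")
    return AtomicStructure(elements=["X"] * n_atoms, coordinates=coords,
                           collision_radii=np.full(n_atoms, atom_radius),
                           label=geometry)


def _sphere_points(n: int, radius: float, rng: np.random.Generator):
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return radius * v


def write_ground_truth(obj, path) -> None:
    """Write a generator's ground-truth sidecar JSON next to its CSV."""
    if isinstance(obj, MassSpectrum):
        payload = obj.metadata.get("ground_truth", obj.metadata)
    elif isinstance(obj, CIUFingerprint):
        payload = obj.metadata
    elif isinstance(obj, TitrationSeries):
        payload = {"p0_uM": obj.p0_um, "l0_uM": obj.l0_um.tolist(),
                   "ratio": obj.ratio.tolist(), "label": obj.label}
    else:
        payload = asdict(obj)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=float)
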