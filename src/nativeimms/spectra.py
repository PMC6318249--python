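"""Native mass-spectrum deconvolution and species quantification.

A native spectrum of a protein/protein-complex mixture is a set of
charge-state envelopes: each species of neutral mass M produces peaks at
m/z = (M + z * m_proton) / z for consecutive charges z. This module
picks candidate peaks, fits the spectrum as a sum of Gaussians plus a
constant baseline, assigns each fitted peak to a (species, charge)
hypothesis, infers neutral masses (resolving phospho-proteoforms spaced
by +79.966 Da), and sums peak areas per species into abundance tables
(e.g. monomer:dimer ratios or DNA-bound fractions).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import find_peaks

from .units import PHOSPHO_SHIFT, PROTON_MASS, mz_for

__all__ = [
    "MassSpectrum",
    "PeakFit",
    "SpectrumFit",
    "AbundanceTable",
    "pick_peaks",
    "fit_multi_gaussian",
    "assign_charge_states",
    "deconvolute_neutral_mass",
    "classify_proteoforms",
    "quantify_species",
]


@dataclass
class MassSpectrum:
    """Paired m/z and intensity arrays with free-form metadata."""

    mz: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be equal-length 1-D arrays")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise ValueError("mz must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")

    def __len__(self) -> int:
        return self.mz.size

    def to_csv(self, path) -> None:
        pd.DataFrame({"mz": self.mz, "intensity": self.intensity}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, **metadata) -> "MassSpectrum":
        df = pd.read_csv(path, sep=None, engine="python")
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(),
                   metadata=metadata)


@dataclass
class PeakFit:
    """One fitted Gaussian peak; area = amplitude * sigma * sqrt(2*pi)."""

    centre: float
    sigma: float
    area: float
    centre_uncertainty: float = float("nan")
    assigned_species: str | None = None
    assigned_charge: int | None = None

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.area < 0:
            raise ValueError("area must be non-negative")


@dataclass
class SpectrumFit:
    """A converged multi-Gaussian fit of one spectrum window."""

    peaks: list[PeakFit]
    baseline: float
    residual_norm: float
    converged: bool
    n_restarts: int = 0

    def __iter__(self):
        return iter(self.peaks)

    def __len__(self):
        return len(self.peaks)


def pick_peaks(spectrum: MassSpectrum, min_relative_height: float = 0.05,
               min_separation: float = 5.0) -> list[float]:
    """Local maxima above a relative height threshold.

    Maxima closer than ``min_separation`` (Da/e) are reduced to the
    tallest. Returns peak centres sorted by m/z.
    """
    if len(spectrum) == 0:
        raise ValueError("empty spectrum")
    if not 0 < min_relative_height < 1:
        raise ValueError("min_relative_height must be in (0, 1)")
    top = spectrum.intensity.max()
    if top <= 0:
        return []
    step = float(np.median(np.diff(spectrum.mz)))
    distance = max(1, int(round(min_separation / step)))
    idx, _ = find_peaks(spectrum.intensity, height=min_relative_height * top,
                        distance=distance)
    return sorted(float(m) for m in spectrum.mz[idx])


def _gaussian_sum(x, params, baseline):
    y = np.full_like(x, baseline)
    for amp, c, s in params.reshape(-1, 3):
        y += amp * np.exp(-0.5 * ((x - c) / s) ** 2)
    return y


def _estimate_sigma(spectrum: MassSpectrum, centre: float) -> float:
    """Initial sigma from the full width at half maximum around a maximum."""
    i0 = int(np.argmin(np.abs(spectrum.mz - centre)))
    half = spectrum.intensity[i0] / 2.0
    lo = i0
    while lo > 0 and spectrum.intensity[lo] > half:
        lo -= 1
    hi = i0
    while hi < len(spectrum) - 1 and spectrum.intensity[hi] > half:
        hi += 1
    fwhm = spectrum.mz[hi] - spectrum.mz[lo]
    step = float(np.median(np.diff(spectrum.mz)))
    return max(fwhm / 2.3548, step)


def fit_multi_gaussian(spectrum: MassSpectrum, initial_centres,
                       fit_baseline: bool = True,
                       max_restarts: int = 5) -> SpectrumFit:
    """Nonlinear least squares of a sum of Gaussians plus constant baseline.

    Peak centres are seeded from ``initial_centres`` (typically from
    :func:`pick_peaks`), sigmas from local FWHM estimates and amplitudes
    from local heights. On non-convergence the fit restarts up to
    ``max_restarts`` times with jittered sigmas; a fit that never
    converges is returned flagged (``converged=False``), never silently.
    """
    centres = np.sort(np.asarray(initial_centres, dtype=float))
    if centres.size == 0:
        raise ValueError("need at least one initial centre")
    if centres.min() < spectrum.mz[0] or centres.max() > spectrum.mz[-1]:
        raise ValueError("initial centres must lie within the spectrum range")

    x, y = spectrum.mz, spectrum.intensity
    base0 = float(np.percentile(y, 5)) if fit_baseline else 0.0
    sig0 = np.array([_estimate_sigma(spectrum, c) for c in centres])
    amp0 = np.array(
        [max(y[np.argmin(np.abs(x - c))] - base0, 1e-12) for c in centres]
    )
    span = x[-1] - x[0]
    step = float(np.median(np.diff(x)))
    rng = np.random.default_rng(0)  # deterministic restart jitter

    def pack(amps, cs, sigs):
        return np.column_stack([amps, cs, sigs]).ravel()

    def residuals(theta):
        if fit_baseline:
            return _gaussian_sum(x, theta[1:], theta[0]) - y
        return _gaussian_sum(x, theta, 0.0) - y

    n = centres.size
    lower = [0.0] * fit_baseline + [0.0, x[0], step / 4] * n
    upper = [np.inf] * fit_baseline + [np.inf, x[-1], span] * n

    best = None
    for attempt in range(max_restarts + 1):
        sigs = sig0 if attempt == 0 else sig0 * rng.uniform(0.5, 2.0, n)
        theta0 = pack(amp0, centres, sigs)
        if fit_baseline:
            theta0 = np.concatenate([[base0], theta0])
        res = least_squares(residuals, theta0, bounds=(lower, upper),
                            method="trf")
        ok = res.status > 0 and np.isfinite(res.cost)
        if best is None or res.cost < best[0].cost:
            best = (res, attempt)
        if ok:
            best = (res, attempt)
            break

    res, attempt = best
    converged = bool(res.status > 0 and np.isfinite(res.cost))
    if not converged:
        warnings.warn("multi-Gaussian fit did not converge after restarts",
                      RuntimeWarning, stacklevel=2)
    theta = res.x
    baseline = float(theta[0]) if fit_baseline else 0.0
    params = theta[1:] if fit_baseline else theta

    # asymptotic centre uncertainties from the Jacobian
    dof = max(x.size - theta.size, 1)
    s2 = 2.0 * res.cost / dof
    try:
        cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
        sd = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        sd = np.full(theta.size, np.nan)
    centre_sd = sd[(1 if fit_baseline else 0) + 1::3]

    peaks = []
    for k, (amp, c, s) in enumerate(params.reshape(-1, 3)):
        peaks.append(PeakFit(centre=float(c), sigma=float(s),
                             area=float(amp * s * np.sqrt(2 * np.pi)),
                             centre_uncertainty=float(centre_sd[k])))
    peaks.sort(key=lambda p: p.centre)
    return SpectrumFit(peaks=peaks, baseline=baseline,
                       residual_norm=float(np.sqrt(2.0 * res.cost)),
                       converged=converged, n_restarts=attempt)


def assign_charge_states(peaks, candidate_masses, tolerance: float = 2.0,
                         allowed_charges: dict | None = None,
                         max_charge: int = 100) -> list[PeakFit]:
    """Assign each peak to the (species, charge) with the nearest m/z.

    ``candidate_masses`` is a list of (label, neutral mass in Da).
    ``allowed_charges`` optionally restricts the charge range per label,
    e.g. ``{"dimer": range(16, 20)}``; unrestricted labels try 1..
    ``max_charge``. A peak with no hypothesis within ``tolerance``
    (Da/e) stays unassigned, which is legitimate (contaminants, adducts).
    Ties break deterministically: smaller |m/z residual|, then lower
    charge, then candidate-list order.
    """
    for label, mass in candidate_masses:
        if mass <= 0:
            raise ValueError(f"candidate mass for {label!r} must be positive")
    out = []
    for peak in peaks:
        hypotheses = []
        for order, (label, mass) in enumerate(candidate_masses):
            charges = (allowed_charges or {}).get(label,
                                                  range(1, max_charge + 1))
            for z in charges:
                dm = abs(peak.centre - mz_for(mass, z))
                if dm <= tolerance:
                    hypotheses.append((dm, z, order, label))
        if hypotheses:
            dm, z, _, label = min(hypotheses)
            out.append(replace(peak, assigned_species=label,
                               assigned_charge=int(z)))
        else:
            out.append(replace(peak))
    return out


def deconvolute_neutral_mass(peaks) -> tuple[float, float]:
    """Neutral mass from a set of peaks assigned to one species.

    Each assigned peak yields mass = z * centre - z * m_proton; the mean
    and standard deviation over charge states are returned. With a
    single charge state the mass is still returned but the spread is NaN.
    """
    assigned = [p for p in peaks if p.assigned_charge is not None]
    if not assigned:
        raise ValueError("no charge-assigned peaks")
    masses = np.array(
        [p.assigned_charge * p.centre - p.assigned_charge * PROTON_MASS
         for p in assigned]
    )
    if masses.size == 1:
        return float(masses[0]), float("nan")
    return float(masses.mean()), float(masses.std(ddof=1))


def classify_proteoforms(masses, shift: float = PHOSPHO_SHIFT,
                         base_mass: float | None = None) -> list[int]:
    """Number of phospho groups per deconvoluted mass.

    Masses forming a ladder spaced by ``shift`` (default +79.966 Da, one
    HPO3) are indexed relative to ``base_mass`` (default: the smallest
    mass, taken as the unmodified proteoform).
    """
    masses = np.asarray(masses, dtype=float)
    if base_mass is None:
        base_mass = masses.min()
    return [int(round((m - base_mass) / shift)) for m in masses]


@dataclass
class AbundanceTable:
    """Summed peak areas and fractional abundances per species label."""

    areas: dict
    fractions: dict

    def fraction(self, label: str) -> float:
        return self.fractions[label]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"species": list(self.areas),
             "area": [self.areas[k] for k in self.areas],
             "fraction": [self.fractions[k] for k in self.areas]}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"areas": self.areas, "fractions": self.fractions},
                      fh, indent=2, sort_keys=True)


def quantify_species(fits, labels=None) -> AbundanceTable:
    """Sum fitted peak areas per species and normalise to fractions.

    ``labels`` restricts the denominator to a chosen comparison set
    (e.g. {monomer, dimer}, excluding DNA-bound species, or
    {dimer, dimer:DNA} for occupancy); by default every assigned label
    contributes. Areas are summed over all assigned charge states.
    """
    areas: dict = {}
    for p in fits:
        if p.assigned_species is None:
            continue
        areas[p.assigned_species] = areas.get(p.assigned_species, 0.0) + p.area
    if not areas:
        raise ValueError("no peak carries a species assignment")
    if labels is not None:
        areas = {k: areas.get(k, 0.0) for k in labels}
    total = sum(areas.values())
    if total <= 0:
        raise ValueError("total assigned area is zero")
    fractions = {k: v / total for k, v in areas.items()}
    return AbundanceTable(areas=areas, fractions=fractions)
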