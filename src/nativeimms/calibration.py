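"""Travelling-wave ion-mobility CCS calibration and CCS distributions.

TW-IMS drift times have no first-principles relation to collision cross
section, so CCS is obtained empirically: drift times of calibrant
proteins with known helium-reference CCS values are corrected for the
m/z-dependent time spent outside the mobility cell,

    t' = t_d - edc * sqrt(m/z),

the reference CCS is reduced by charge and reduced mass,
CCS_red = CCS_ref * sqrt(mu) / q with mu = M * m_gas / (M + m_gas),
and ln(CCS_red) against ln(t') is fit with a straight line of slope m
and intercept C. An unknown ion's CCS then follows the power law

    CCS = (q / sqrt(mu)) * t'^m * exp(C).

The module also converts arrival-time distributions to CCS
distributions, measures their full width at half maximum (the CCSD, a
conformational-spread metric) and decomposes multimodal distributions
into Gaussian conformer families.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import linregress

from .units import HELIUM_MASS, mz_for

__all__ = [
    "Calibrant",
    "Calibration",
    "CCSDistribution",
    "correct_drift_time",
    "fit_calibration",
    "apply_calibration",
    "drift_time_for_ccs",
    "ccs_distribution_from_atd",
    "ccsd",
    "decompose_conformers",
]

#: Documented placeholder for the instrument-specific EDC (enhanced duty
#: cycle) delay coefficient, in ms / sqrt(Da/e). Real analyses must
#: supply the value of their instrument; synthetic round trips only need
#: the same value on both sides.
DEFAULT_EDC_COEFFICIENT = 1.41


@dataclass
class Calibrant:
    """One calibrant ion: known mass, charge, reference CCS, drift time."""

    label: str
    neutral_mass: float  # Da
    charge: int
    reference_ccs: float  # nm^2, helium reference
    drift_time: float  # ms

    def __post_init__(self):
        for name in ("neutral_mass", "charge", "reference_ccs", "drift_time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive for {self.label!r}")


@dataclass
class Calibration:
    """A fitted power-law calibration: slope, intercept and provenance."""

    slope: float
    intercept: float
    edc_coefficient: float
    gas_mass: float = HELIUM_MASS
    r_squared: float = float("nan")
    n_calibrants: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "slope": self.slope, "intercept": self.intercept,
                "edc_coefficient": self.edc_coefficient,
                "gas_mass": self.gas_mass, "r_squared": self.r_squared,
                "n_calibrants": self.n_calibrants,
            }, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "Calibration":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class CCSDistribution:
    """Intensity over CCS for one charge state, tied to its calibration."""

    ccs: np.ndarray  # nm^2, increasing
    intensity: np.ndarray
    charge: int
    calibration: Calibration | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.ccs = np.asarray(self.ccs, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ccs.shape != self.intensity.shape:
            raise ValueError("ccs and intensity must have the same length")
        if np.any(np.diff(self.ccs) <= 0):
            raise ValueError("ccs axis must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    def to_csv(self, path) -> None:
        pd.DataFrame({"ccs_nm2": self.ccs, "intensity": self.intensity}
                     ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, charge: int,
                 calibration: Calibration | None = None) -> "CCSDistribution":
        df = pd.read_csv(path)
        return cls(df["ccs_nm2"].to_numpy(), df["intensity"].to_numpy(),
                   charge=charge, calibration=calibration)


def reduced_mass(neutral_mass: float, gas_mass: float = HELIUM_MASS) -> float:
    """Reduced mass of the ion-drift gas pair, in Da."""
    return neutral_mass * gas_mass / (neutral_mass + gas_mass)


def correct_drift_time(t_d, mz, edc_coefficient: float):
    """Remove the m/z-dependent post-mobility flight time.

    t' = t_d - edc * sqrt(m/z); a non-positive corrected time means the
    supplied coefficient cannot be right for that record and is an error.
    """
    t_d = np.asarray(t_d, dtype=float)
    mz = np.asarray(mz, dtype=float)
    if np.any(t_d <= 0):
        raise ValueError("drift times must be positive")
    t_prime = t_d - edc_coefficient * np.sqrt(mz)
    if np.any(t_prime <= 0):
        bad = np.argmax(t_prime <= 0)
        raise ValueError(
            f"corrected drift time non-positive for record {bad} "
            f"(t_d={np.atleast_1d(t_d)[bad]:.4g} ms, "
            f"mz={np.atleast_1d(mz)[bad]:.6g})"
        )
    return float(t_prime) if t_prime.ndim == 0 else t_prime


def fit_calibration(calibrants, edc_coefficient: float,
                    gas_mass: float = HELIUM_MASS) -> Calibration:
    """Least-squares log-log fit of reduced CCS against corrected drift time."""
    calibrants = list(calibrants)
    if len(calibrants) < 3:
        raise ValueError("calibration needs at least 3 calibrant points")
    ln_t, ln_ccs_red = [], []
    for cal in calibrants:
        mz = mz_for(cal.neutral_mass, cal.charge)
        t_prime = correct_drift_time(cal.drift_time, mz, edc_coefficient)
        mu = reduced_mass(cal.neutral_mass, gas_mass)
        ln_t.append(np.log(t_prime))
        ln_ccs_red.append(np.log(cal.reference_ccs * np.sqrt(mu) / cal.charge))
    ln_t = np.asarray(ln_t)
    if np.ptp(ln_t) == 0:
        raise ValueError("degenerate calibration: identical corrected times")
    fit = linregress(ln_t, np.asarray(ln_ccs_red))
    return Calibration(slope=float(fit.slope), intercept=float(fit.intercept),
                       edc_coefficient=edc_coefficient, gas_mass=gas_mass,
                       r_squared=float(fit.rvalue ** 2),
                       n_calibrants=len(calibrants))


def apply_calibration(t_prime, charge: int, neutral_mass: float,
                      cal: Calibration):
    """CCS (nm^2) from a corrected drift time via the power-law calibration."""
    t_prime = np.asarray(t_prime, dtype=float)
    if np.any(t_prime <= 0):
        raise ValueError("corrected drift times must be positive")
    mu = reduced_mass(neutral_mass, cal.gas_mass)
    ccs = (charge / np.sqrt(mu)) * t_prime ** cal.slope * np.exp(cal.intercept)
    return float(ccs) if ccs.ndim == 0 else ccs


def drift_time_for_ccs(ccs, charge: int, neutral_mass: float,
                       cal: Calibration):
    """Inverse of the calibration: the raw drift time producing a CCS.

    Used to synthesise arrival-time data with known ground truth and for
    round-trip validation of the calibration itself.
    """
    ccs = np.asarray(ccs, dtype=float)
    mu = reduced_mass(neutral_mass, cal.gas_mass)
    t_prime = (ccs * np.sqrt(mu) /
               (charge * np.exp(cal.intercept))) ** (1.0 / cal.slope)
    mz = mz_for(neutral_mass, charge)
    t_d = t_prime + cal.edc_coefficient * np.sqrt(mz)
    return float(t_d) if t_d.ndim == 0 else t_d


def ccs_distribution_from_atd(drift_time_ms, intensity, charge: int,
                              neutral_mass: float,
                              cal: Calibration) -> CCSDistribution:
    """Map an arrival-time distribution to a CCS distribution.

    Each drift-time sample is corrected and pushed through the
    calibration; intensities are carried over sample-for-sample with no
    Jacobian reweighting (the common TW-IMS convention). The output is
    sorted onto an increasing CCS axis.
    """
    drift_time_ms = np.asarray(drift_time_ms, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if drift_time_ms.size == 0:
        raise ValueError("empty arrival-time distribution")
    mz = mz_for(neutral_mass, charge)
    t_prime = correct_drift_time(drift_time_ms, mz, cal.edc_coefficient)
    ccs = apply_calibration(t_prime, charge, neutral_mass, cal)
    order = np.argsort(ccs)
    return CCSDistribution(ccs[order], intensity[order], charge=charge,
                           calibration=cal)


def ccsd(dist: CCSDistribution) -> float:
    """Full width at half maximum of a CCS distribution, in nm^2.

    For multimodal profiles the width is taken between the *outermost*
    crossings of half the global maximum, with linear interpolation
    between grid points — matching how the spread of an asymmetric,
    partially resolved conformer ensemble is quoted.
    """
    y = dist.intensity
    if y.max() <= 0:
        raise ValueError("distribution has no positive intensity")
    half = y.max() / 2.0
    above = y >= half
    if above[0] or above[-1]:
        raise ValueError("distribution does not fall below half maximum "
                         "inside the CCS range; widen the axis")
    idx = np.nonzero(above)[0]
    i_lo, i_hi = idx[0], idx[-1]
    x = dist.ccs

    def cross(i_out, i_in):
        # linear interpolation between the outside and inside samples
        return x[i_out] + (half - y[i_out]) * (x[i_in] - x[i_out]) / (
            y[i_in] - y[i_out])

    left = cross(i_lo - 1, i_lo)
    right = cross(i_hi + 1, i_hi)
    return float(right - left)


def _gauss_mix(x, theta):
    y = np.zeros_like(x)
    for amp, c, s in theta.reshape(-1, 3):
        y += amp * np.exp(-0.5 * ((x - c) / s) ** 2)
    return y


def decompose_conformers(dist: CCSDistribution, n_components: int,
                         max_restarts: int = 5):
    """Decompose a CCS distribution into Gaussian conformer families.

    Least-squares fit of a sum of ``n_components`` Gaussians; the
    components are returned sorted by mean as (mean nm^2, sigma nm^2,
    weight) with weights = fractional areas summing to 1. Initialisation
    places components at quantiles of the cumulative intensity; on
    non-convergence the fit restarts with jittered starts and the best
    attempt is returned.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    x, y = dist.ccs, dist.intensity
    total = np.trapezoid(y, x)
    if total <= 0:
        raise ValueError("distribution has no area")
    cdf = np.cumsum(y)
    cdf = cdf / cdf[-1]
    q = (np.arange(n_components) + 0.5) / n_components
    means0 = np.interp(q, cdf, x)
    spread = np.sqrt(np.trapezoid(y * (x - np.trapezoid(y * x, x) / total) ** 2,
                                  x) / total)
    sig0 = np.full(n_components, max(spread / n_components,
                                     np.median(np.diff(x))))
    amp0 = np.interp(means0, x, y).clip(min=1e-12)

    lower = [0.0, x[0], np.median(np.diff(x)) / 4] * n_components
    upper = [np.inf, x[-1], x[-1] - x[0]] * n_components
    rng = np.random.default_rng(0)
    best = None
    for attempt in range(max_restarts + 1):
        m0 = means0 if attempt == 0 else means0 + rng.normal(
            0, spread / 2, n_components)
        m0 = np.clip(m0, x[0], x[-1])
        theta0 = np.column_stack([amp0, m0, sig0]).ravel()
        res = least_squares(lambda t: _gauss_mix(x, t) - y, theta0,
                            bounds=(lower, upper), method="trf")
        if best is None or res.cost < best.cost:
            best = res
        if res.cost <= 1e-12 * float(y @ y):
            break

    comps = []
    for amp, c, s in best.x.reshape(-1, 3):
        comps.append((float(c), float(s), float(amp * s * np.sqrt(2 * np.pi))))
    total_area = sum(w for _, _, w in comps)
    comps = [(c, s, w / total_area) for c, s, w in comps]
    comps.sort(key=lambda t: t[0])
    return comps
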