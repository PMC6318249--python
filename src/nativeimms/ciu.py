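"""Collision-induced unfolding (CIU) fingerprints and transition analysis.

In a CIU experiment a single mass-selected charge state is activated at
stepwise-increasing collision voltages while ion mobility is recorded;
stacking the per-voltage mobility profiles column-wise gives an
unfolding fingerprint. Gas-phase unfolding appears as stepwise jumps of
the mobility centroid towards larger CCS. This module assembles
fingerprints, extracts centroid traces, fits them with sums of logistic
steps to locate transition midpoints (CV50), detects the small
structural *compaction* some complexes show before the first unfolding
step, and compares stabilities between complexes as the shift of the
first transition voltage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import find_peaks
from scipy.special import expit

__all__ = [
    "CIUFingerprint",
    "UnfoldingTransition",
    "build_fingerprint",
    "column_centroid_trace",
    "detect_transitions",
    "detect_compaction",
    "stability_shift",
]


@dataclass
class CIUFingerprint:
    """Intensity matrix over (collision voltage x mobility/CCS)."""

    cv: np.ndarray  # V, increasing
    mobility: np.ndarray  # nm^2 (or ms), increasing
    intensity: np.ndarray  # shape (len(cv), len(mobility)), >= 0
    normalization: str = "none"  # none | column_max | column_sum
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.cv = np.asarray(self.cv, dtype=float)
        self.mobility = np.asarray(self.mobility, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (self.cv.size, self.mobility.size):
            raise ValueError("intensity must have shape (n_cv, n_mobility)")
        if np.any(np.diff(self.cv) <= 0) or np.any(np.diff(self.mobility) <= 0):
            raise ValueError("cv and mobility axes must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    def normalized(self, mode: str = "column_max") -> "CIUFingerprint":
        """Per-voltage normalised copy; idempotent for a given mode."""
        if mode not in ("column_max", "column_sum"):
            raise ValueError(f"unknown normalization mode {mode!r}")
        denom = (self.intensity.max(axis=1) if mode == "column_max"
                 else self.intensity.sum(axis=1))
        if np.any(denom <= 0):
            raise ValueError("cannot normalise an all-zero voltage column")
        return replace(self, intensity=self.intensity / denom[:, None],
                       normalization=mode)

    def to_long_csv(self, path) -> None:
        cv_col = np.repeat(self.cv, self.mobility.size)
        mob_col = np.tile(self.mobility, self.cv.size)
        pd.DataFrame({"cv": cv_col, "ccs": mob_col,
                      "intensity": self.intensity.ravel()}
                     ).to_csv(path, index=False)

    @classmethod
    def from_long_csv(cls, path) -> "CIUFingerprint":
        df = pd.read_csv(path)
        cv = np.unique(df["cv"].to_numpy())
        mob = np.unique(df["ccs"].to_numpy())
        mat = (df.pivot_table(index="cv", columns="ccs", values="intensity")
               .to_numpy())
        return cls(cv, mob, mat)


@dataclass
class UnfoldingTransition:
    """One logistic unfolding step of the centroid trace."""

    cv50: float  # V
    pre_centroid: float  # nm^2
    post_centroid: float  # nm^2
    width: float  # V

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("transition width must be positive")
        if self.post_centroid <= self.pre_centroid:
            raise ValueError("unfolding must increase the centroid")


def build_fingerprint(profiles, normalize: str | None = "column_max"
                      ) -> CIUFingerprint:
    """Assemble per-voltage mobility profiles into a fingerprint.

    ``profiles`` is a list of (cv, mobility_axis, intensity) triples.
    Ragged mobility grids are interpolated onto the union grid (linear,
    zero outside). Columns are max-normalised by default; pass
    ``normalize=None`` to keep raw intensities.
    """
    if len(profiles) < 2:
        raise ValueError("need profiles at >= 2 collision voltages")
    cvs = np.array([p[0] for p in profiles], dtype=float)
    if np.unique(cvs).size != cvs.size:
        raise ValueError("duplicate collision-voltage values")
    grids = [np.asarray(p[1], dtype=float) for p in profiles]
    same_grid = all(g.shape == grids[0].shape and np.allclose(g, grids[0])
                    for g in grids)
    grid = grids[0] if same_grid else np.unique(np.concatenate(grids))
    rows = []
    for (cv, mob, inten), g in zip(profiles, grids):
        inten = np.asarray(inten, dtype=float)
        rows.append(inten if same_grid
                    else np.interp(grid, g, inten, left=0.0, right=0.0))
    order = np.argsort(cvs)
    fp = CIUFingerprint(cvs[order], grid, np.vstack(rows)[order])
    return fp.normalized(normalize) if normalize else fp


def column_centroid_trace(fp: CIUFingerprint) -> np.ndarray:
    """Intensity-weighted mean mobility per voltage; shape (n_cv, 2)."""
    sums = fp.intensity.sum(axis=1)
    if np.any(sums <= 0):
        raise ValueError("all-zero voltage column has no centroid")
    centroids = (fp.intensity @ fp.mobility) / sums
    return np.column_stack([fp.cv, centroids])


def _step_model(cv, theta):
    """Baseline + sum of rising logistic steps."""
    y = np.full_like(cv, theta[0])
    for a, v, w in theta[1:].reshape(-1, 3):
        y += a * expit((cv - v) / w)
    return y


def _fit_steps(cv, centroid, n_steps, step):
    """Least-squares fit of n logistic steps; returns the optimiser result."""
    grad = np.gradient(centroid, cv)
    peaks, props = find_peaks(np.maximum(grad, 0), height=0)
    if peaks.size:
        top = peaks[np.argsort(props["peak_heights"])[::-1][:n_steps]]
        v0 = np.sort(cv[top])
    else:
        v0 = np.array([])
    if v0.size < n_steps:  # spread extra starts over the range
        extra = np.linspace(cv[0] + 0.25 * np.ptp(cv),
                            cv[-1] - 0.25 * np.ptp(cv),
                            n_steps - v0.size)
        v0 = np.sort(np.concatenate([v0, extra]))
    rise = max(centroid[-1] - centroid[0], 1e-6)
    a0 = np.full(n_steps, rise / n_steps)
    w0 = np.full(n_steps, 2.0 * step)
    theta0 = np.concatenate([[centroid[0]],
                             np.column_stack([a0, v0, w0]).ravel()])
    lower = [-np.inf] + [0.0, cv[0], step / 4] * n_steps
    upper = [np.inf] + [np.inf, cv[-1], np.ptp(cv)] * n_steps
    return least_squares(lambda t: _step_model(cv, t) - centroid, theta0,
                         bounds=(lower, upper), method="trf")


def detect_transitions(fp: CIUFingerprint, n_states: int | None = None,
                       max_states: int = 5) -> list[UnfoldingTransition]:
    """Locate unfolding transitions by logistic-step fitting.

    The column-centroid trace is fitted with a constant plus a sum of
    rising logistic steps; each step contributes one transition whose
    CV50 is the logistic midpoint. ``n_states`` fixes the number of
    conformational states (steps + 1); when omitted the step count is
    chosen by BIC over 1..``max_states``-1 steps. A trace that does not
    plateau at both ends yields a warning, since midpoints near the
    edges are then extrapolations.
    """
    trace = column_centroid_trace(fp)
    cv, centroid = trace[:, 0], trace[:, 1]
    step = float(np.median(np.diff(cv)))

    # plateau check: end slopes should be tiny next to the steepest slope
    rise = np.ptp(centroid)
    slopes = np.abs(np.gradient(centroid, cv))
    if rise > 0 and slopes.max() > 0:
        for sl in (slopes[0], slopes[-1]):
            if sl > 0.05 * slopes.max():
                warnings.warn("centroid trace does not plateau at the "
                              "fingerprint edges; transitions may be "
                              "partially out of range", RuntimeWarning,
                              stacklevel=2)
                break

    if n_states is not None:
        if n_states < 2:
            return []
        best = _fit_steps(cv, centroid, n_states - 1, step)
    else:
        n_pts = cv.size
        floor = n_pts * (1e-6 * max(rise, 1e-12)) ** 2
        best, best_bic = None, np.inf
        for n_steps in range(1, max_states):
            res = _fit_steps(cv, centroid, n_steps, step)
            rss = max(2.0 * res.cost, floor)
            k = 1 + 3 * n_steps
            bic = n_pts * np.log(rss / n_pts) + k * np.log(n_pts)
            if bic < best_bic:
                best, best_bic = res, bic

    theta = best.x
    steps = sorted(theta[1:].reshape(-1, 3).tolist(), key=lambda s: s[1])
    transitions, level = [], theta[0]
    for a, v, w in steps:
        transitions.append(UnfoldingTransition(
            cv50=float(v), pre_centroid=float(level),
            post_centroid=float(level + a), width=float(w)))
        level += a
    return transitions


def detect_compaction(fp: CIUFingerprint,
                      transitions: list[UnfoldingTransition] | None = None
                      ) -> tuple[bool, float]:
    """Detect pre-unfolding structural compaction.

    Some complexes contract slightly (centroid CCS decreases) under
    gentle activation before the first unfolding step. The magnitude is
    the drop from the initial centroid to the minimum centroid in the
    pre-transition region (voltages below CV50_1 - 2 * width_1), floored
    at zero; it is called *present* when it exceeds twice the local
    centroid noise (std of the linearly detrended pre-region trace).
    """
    if transitions is None:
        transitions = detect_transitions(fp)
    trace = column_centroid_trace(fp)
    cv, centroid = trace[:, 0], trace[:, 1]
    if transitions:
        first = transitions[0]
        mask = cv < first.cv50 - 2.0 * first.width
    else:
        mask = np.ones_like(cv, dtype=bool)
    if mask.sum() < 3:
        raise ValueError("need >= 3 voltage points before the first transition")
    pre_cv, pre = cv[mask], centroid[mask]
    magnitude = max(float(pre[0] - pre.min()), 0.0)
    detrended = pre - np.polyval(np.polyfit(pre_cv, pre, 1), pre_cv)
    noise = float(np.std(detrended))
    return magnitude > 2.0 * noise, magnitude


def stability_shift(fp_a: CIUFingerprint, fp_b: CIUFingerprint,
                    **detect_kwargs) -> float:
    """CV50 difference of the first unfolding transitions, b minus a.

    A positive shift means complex b needs more collisional activation
    to start unfolding, i.e. it is the gas-phase-stabilised form.
    """
    trans_a = detect_transitions(fp_a, **detect_kwargs)
    trans_b = detect_transitions(fp_b, **detect_kwargs)
    if not trans_a or not trans_b:
        raise ValueError("both fingerprints must show >= 1 transition")
    return trans_b[0].cv50 - trans_a[0].cv50
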