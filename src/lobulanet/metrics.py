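"""Population-coding and tuning metrics for lobula responses.

Includes the Treves-Rolls sparseness index, cosine angular distance between
population response vectors, pairwise response correlation, and orientation /
velocity tuning of single lobula units probed with moving bars.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from . import optic_lobe
from .optic_lobe import GainConfig, LifParams, VisualLobeWeights
from .stimuli import make_moving_bar

__all__ = [
    "sparseness_index",
    "angular_distance",
    "response_correlation",
    "TuningCurve",
    "orientation_tuning",
    "population_osi",
    "velocity_tuning",
    "DEFAULT_ANGLES",
]

#: probe orientations, 30 deg steps over the full circle
DEFAULT_ANGLES = tuple(range(0, 360, 30))


def sparseness_index(rates: np.ndarray) -> float:
    """Treves-Rolls population sparseness index.

    SI = (sum(r)/N)^2 / (sum(r^2)/N), bounded in [1/N, 1]: 1 for a uniform
    population (fully distributed code), 1/N when a single neuron carries all
    activity (maximally sparse).  Lower values mean sparser coding.  Undefined
    for an all-zero vector (returns NaN).
    """
    r = np.asarray(rates, dtype=float)
    if r.ndim != 1 or r.size == 0:
        raise ValueError("rates must be a non-empty 1-D vector")
    peak = r.max()
    if peak <= 0:
        return float("nan")
    r = r / peak  # scale invariant; guards against underflow of r**2
    n = r.size
    return float((np.sum(r) / n) ** 2 / (np.sum(r ** 2) / n))


def angular_distance(r1: np.ndarray, r2: np.ndarray) -> float:
    """Angle in degrees between two population response vectors.

    theta = arccos(r1 . r2 / (|r1| |r2|)); 0 deg for identical directions,
    90 deg for orthogonal responses.
    """
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    n1 = np.linalg.norm(r1)
    n2 = np.linalg.norm(r2)
    if n1 == 0 or n2 == 0:
        raise ValueError("angular distance is undefined for a zero vector")
    cos = np.clip(np.dot(r1, r2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def response_correlation(responses: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """Pairwise Pearson correlation of neurons across stimuli.

    ``responses`` is a (n_stimuli, n_neurons) rate matrix.  Neurons with
    constant rates across stimuli are excluded (their correlation is
    undefined); the returned boolean mask marks the neurons kept.  Returns
    (correlation matrix over kept neurons, mean absolute off-diagonal value,
    kept mask).
    """
    X = np.asarray(responses, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a (n_stimuli >= 2, n_neurons) response matrix")
    kept = X.std(axis=0) > 0
    C = np.corrcoef(X[:, kept], rowvar=False)
    C = np.atleast_2d(C)
    off = ~np.eye(C.shape[0], dtype=bool)
    mean_abs_off = float(np.abs(C[off]).mean()) if C.shape[0] > 1 else 0.0
    return C, mean_abs_off, kept


@dataclass
class TuningCurve:
    """Mean rate (+/- SEM) of one unit versus a stimulus parameter."""

    abscissa: np.ndarray
    rates: np.ndarray
    sem: np.ndarray

    def __post_init__(self) -> None:
        self.abscissa = np.asarray(self.abscissa, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)
        if not (len(self.abscissa) == len(self.rates) == len(self.sem)):
            raise ValueError("tuning curve arrays must have equal length")
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")

    @property
    def preferred(self) -> float:
        return float(self.abscissa[int(np.argmax(self.rates))])


def _unit_rates(lobe: VisualLobeWeights, unit: int, scan, n_reps: int,
                rng: np.random.Generator, lif: LifParams, gains: GainConfig) -> np.ndarray:
    out = np.empty(n_reps)
    for rep in range(n_reps):
        resp = optic_lobe.lobula_response(scan, lobe, p=lif, gains=gains, rng=rng)
        out[rep] = resp.rates[unit]
    return out


def orientation_tuning(lobe: VisualLobeWeights, unit: int,
                       angles=DEFAULT_ANGLES, n_reps: int = 50,
                       shift_px: int = 15, contrast: float = 1.0,
                       seed: int | None = None,
                       lif: LifParams | None = None,
                       gains: GainConfig | None = None) -> tuple[TuningCurve, float]:
    """Orientation tuning of one lobula unit probed with moving bars.

    Each bar moves orthogonally to its own axis; ``n_reps`` noise seeds per
    angle.  Returns the tuning curve and the orientation selectivity index
    OSI = (r_pref - r_orth) / (r_pref + r_orth), where r_orth is the response
    at 90 deg from the preferred orientation.
    """
    if unit >= lobe.n_lobula:
        raise IndexError("unit index out of range")
    lif = lif or LifParams()
    gains = gains or GainConfig()
    rng = np.random.default_rng(seed)
    angles = np.asarray(angles, dtype=float)
    means = np.empty(len(angles))
    sems = np.empty(len(angles))
    for i, ang in enumerate(angles):
        scan = make_moving_bar(ang, shift_px=shift_px, contrast=contrast)
        r = _unit_rates(lobe, unit, scan, n_reps, rng, lif, gains)
        means[i] = r.mean()
        sems[i] = r.std(ddof=1) / np.sqrt(n_reps) if n_reps > 1 else 0.0
    curve = TuningCurve(abscissa=angles, rates=means, sem=sems)
    i_pref = int(np.argmax(means))
    ortho = (angles[i_pref] + 90.0) % 360.0
    i_orth = int(np.argmin(np.abs((angles - ortho + 180.0) % 360.0 - 180.0)))
    denom = means[i_pref] + means[i_orth]
    osi = float((means[i_pref] - means[i_orth]) / denom) if denom > 0 else 0.0
    return curve, osi


def population_osi(lobe: VisualLobeWeights, angles=DEFAULT_ANGLES,
                   n_reps: int = 5, shift_px: int = 15, seed: int | None = None,
                   lif: LifParams | None = None,
                   gains: GainConfig | None = None) -> np.ndarray:
    """OSI of every lobula unit, from one shared moving-bar battery.

    Computes the full population response per angle once (per repetition)
    rather than per unit, so screening all units costs the same as one.
    """
    lif = lif or LifParams()
    gains = gains or GainConfig()
    rng = np.random.default_rng(seed)
    angles = np.asarray(angles, dtype=float)
    rates = np.zeros((len(angles), lobe.n_lobula))
    for i, ang in enumerate(angles):
        scan = make_moving_bar(ang, shift_px=shift_px)
        for _ in range(n_reps):
            resp = optic_lobe.lobula_response(scan, lobe, p=lif, gains=gains, rng=rng)
            rates[i] += resp.rates
    rates /= n_reps
    osi = np.zeros(lobe.n_lobula)
    for u in range(lobe.n_lobula):
        i_pref = int(np.argmax(rates[:, u]))
        ortho = (angles[i_pref] + 90.0) % 360.0
        i_orth = int(np.argmin(np.abs((angles - ortho + 180.0) % 360.0 - 180.0)))
        denom = rates[i_pref, u] + rates[i_orth, u]
        osi[u] = (rates[i_pref, u] - rates[i_orth, u]) / denom if denom > 0 else 0.0
    return osi


def _gamma_shape(v, c, k, theta):
    return c * np.power(np.maximum(v, 1e-9), k - 1.0) * np.exp(-v / theta)


def velocity_tuning(lobe: VisualLobeWeights, unit: int, shifts=(0, 5, 15, 30, 45, 60),
                    n_reps: int = 20, angle: float | None = None,
                    seed: int | None = None, lif: LifParams | None = None,
                    gains: GainConfig | None = None):
    """Velocity sensitivity of one unit at its preferred orientation.

    Rates versus pixel shift per step (the speed proxy), with a least-squares
    fit of the gamma-shaped curve r(v) = c v^(k-1) exp(-v / theta), k > 1.
    Returns (TuningCurve, fit dict) where the fit holds (c, k, theta), the
    fitted peak velocity (k-1) theta, and a ``degenerate`` flag when the fit
    fails or adds nothing over a flat line.
    """
    lif = lif or LifParams()
    gains = gains or GainConfig()
    rng = np.random.default_rng(seed)
    if angle is None:
        curve, _ = orientation_tuning(lobe, unit, n_reps=max(3, n_reps // 4),
                                      seed=seed, lif=lif, gains=gains)
        angle = curve.preferred
    shifts = np.asarray(shifts, dtype=float)
    means = np.empty(len(shifts))
    sems = np.empty(len(shifts))
    for i, s in enumerate(shifts):
        scan = make_moving_bar(angle, shift_px=int(s))
        r = _unit_rates(lobe, unit, scan, n_reps, rng, lif, gains)
        means[i] = r.mean()
        sems[i] = r.std(ddof=1) / np.sqrt(n_reps) if n_reps > 1 else 0.0
    curve = TuningCurve(abscissa=shifts, rates=means, sem=sems)

    fit = {"degenerate": True, "c": np.nan, "k": np.nan, "theta": np.nan,
           "peak_velocity": np.nan, "sse": np.nan, "sse_flat": np.nan}
    try:
        p0 = (max(means.max(), 1e-3), 2.0, max(shifts.max() / 3.0, 1.0))
        popt, _ = curve_fit(_gamma_shape, shifts, means, p0=p0,
                            bounds=((0, 1.0 + 1e-6, 1e-3), (np.inf, 50, 1e3)),
                            maxfev=20000)
        resid = means - _gamma_shape(shifts, *popt)
        sse = float(np.sum(resid ** 2))
        sse_flat = float(np.sum((means - means.mean()) ** 2))
        fit.update(degenerate=not np.all(np.isfinite(popt)), c=popt[0], k=popt[1],
                   theta=popt[2], peak_velocity=(popt[1] - 1.0) * popt[2],
                   sse=sse, sse_flat=sse_flat)
    except (RuntimeError, ValueError):
        pass
    return curve, fit
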