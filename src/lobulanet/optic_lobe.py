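"""Forward model of the optic lobe: photoreceptors -> lamina -> medulla -> lobula.

Architecture (one eye): a 75x75 photoreceptor grid driven directly by patch
intensities; 625 (25x25) lamina neurons, each pooling a non-overlapping 3x3
photoreceptor block through a sigmoidal activation; a bank of five small-field
medulla neurons per lobula unit, one bank per temporal instance of the scan;
wide-field lobula neurons that integrate their five delay-aligned medulla
banks at a single instant and inhibit each other laterally through the
non-negative matrix Q.

Spiking neurons follow the leaky integrate-and-fire (LIF) model
``tau du/dt = -u + R I`` with reset to v0 on crossing the threshold VT.  For a
constant current the stationary firing rate has the closed form
``rate = 1 / (tau ln((R I - v0) / (R I - VT)))`` whenever ``R I > VT``; the
forward pass uses this exact rate, while the Euler simulator is retained for
spike-time generation and as a numerical cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stimuli import M_PATCHES, PATCH_SIZE, ScanSequence

__all__ = [
    "LifParams",
    "SigmoidParams",
    "GainConfig",
    "VisualLobeWeights",
    "LayerResponse",
    "sigmoid_activation",
    "lamina_response",
    "lif_rate",
    "lif_rate_closed",
    "medulla_response",
    "lobula_response",
    "init_visual_lobe",
]

POOL = 3
LAMINA_SIDE = PATCH_SIZE // POOL      # 25
N_LAMINA = LAMINA_SIDE * LAMINA_SIDE  # 625
N_DELAYS = M_PATCHES                  # 5
DEFAULT_N_LOBULA = 50


@dataclass
class LifParams:
    """Leaky integrate-and-fire constants.

    R is a dimensionless input gain, tau_m the membrane time constant (ms),
    v0 the reset potential (mV), VT the spike threshold (mV).  dt is the Euler
    step and duration the presentation time per patch, both in ms.
    """

    R: float = 10.0
    tau_m: float = 10.0
    v0: float = -80.0
    VT: float = 0.0
    dt: float = 0.1
    duration: float = 100.0

    def __post_init__(self) -> None:
        if not self.v0 < self.VT:
            raise ValueError("reset potential must lie below threshold")
        if not self.dt < self.tau_m / 10:
            raise ValueError("dt must be small relative to tau_m")


@dataclass
class SigmoidParams:
    """Lamina activation f(r) = A0 / (1 + exp(m r + b))."""

    A0: float = 1.0
    m: float = -1.0
    b: float = 0.5

    def __post_init__(self) -> None:
        if self.A0 <= 0:
            raise ValueError("A0 must be positive")


@dataclass
class GainConfig:
    """Input-current scaling between layers and the noise level.

    The lamina emits analog activities in (0, 1) while LIF currents are in
    arbitrary units; ``medulla_gain`` converts the weighted lamina sum into a
    medulla input current and ``lobula_gain`` converts the summed medulla
    rates (spikes/s, minus lateral inhibition) into a lobula input current.
    Both are documented calibration constants, fixed so that a full-contrast
    preferred moving bar drives a trained lobula unit at roughly 25-30
    spikes/s.  ``noise_scale`` sets the Poisson spike-count noise (0 disables
    it; 1 gives plain Poisson counts; larger values scale the count variance
    at fixed mean).  The default is calibrated so that a visual lobe with
    random, untrained connectivity cannot discriminate the two crosses -- the
    behavioural signature of an untrained system.
    """

    medulla_gain: float = 1.0
    lobula_gain: float = 2e-4
    noise_scale: float = 3.0


@dataclass
class VisualLobeWeights:
    """Plastic connectivity of the visual lobe.

    W has shape (n_lobula, 5, 625): one 625-weight lamina slice per delay bank
    of every lobula unit, bounded in [-1, +1].  Q (n_lobula, n_lobula) holds
    the non-negative lateral inhibitory weights with a zero diagonal.
    """

    W: np.ndarray
    Q: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        n = self.W.shape[0]
        if self.W.ndim != 3 or self.W.shape[1:] != (N_DELAYS, N_LAMINA):
            raise ValueError(f"W must have shape (n, {N_DELAYS}, {N_LAMINA})")
        if self.Q.shape != (n, n):
            raise ValueError("Q must be square n_lobula x n_lobula")
        if np.any(self.W < -1 - 1e-9) or np.any(self.W > 1 + 1e-9):
            raise ValueError("W entries must lie in [-1, +1]")
        if np.any(self.Q < -1e-9) or np.any(self.Q > 1 + 1e-9):
            raise ValueError("Q entries must lie in [0, +1]")
        if np.any(np.abs(np.diag(self.Q)) > 1e-12):
            raise ValueError("Q diagonal must be zero")

    @property
    def n_lobula(self) -> int:
        return self.W.shape[0]

    def save(self, path) -> None:
        np.savez(path, W=self.W, Q=self.Q)

    @classmethod
    def load(cls, path) -> "VisualLobeWeights":
        data = np.load(path)
        return cls(W=data["W"], Q=data["Q"])


@dataclass
class LayerResponse:
    """Mean firing rates (spikes/s) of one layer, with optional spike times."""

    rates: np.ndarray
    spikes: list | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")


# ---------------------------------------------------------------------------
# static nonlinearities
# ---------------------------------------------------------------------------

def sigmoid_activation(r, p: SigmoidParams | None = None):
    """Lamina activation A0 / (1 + exp(m r + b)); increasing in r for m < 0."""
    p = p or SigmoidParams()
    return p.A0 / (1.0 + np.exp(p.m * np.asarray(r, dtype=float) + p.b))


def lamina_response(photo: np.ndarray, p: SigmoidParams | None = None) -> np.ndarray:
    """625-vector of lamina activities from a 75x75 photoreceptor patch.

    Lamina neuron (i, j) pools the non-overlapping 3x3 photoreceptor block
    rows 3i..3i+2, cols 3j..3j+2 and passes the summed intensity through the
    sigmoid.
    """
    photo = np.asarray(photo, dtype=float)
    if photo.shape != (PATCH_SIZE, PATCH_SIZE):
        raise ValueError(f"patch must be {PATCH_SIZE}x{PATCH_SIZE}, got {photo.shape}")
    pooled = photo.reshape(LAMINA_SIDE, POOL, LAMINA_SIDE, POOL).sum(axis=(1, 3))
    return sigmoid_activation(pooled, p).ravel()


def lamina_contrast(lam: np.ndarray) -> np.ndarray:
    """Background-subtracted lamina activity (the contrast channel).

    Lamina monopolar cells encode the deviation of each neuron's activity
    from the mean over the field, not the absolute level.  The plasticity
    rules learn from this contrast signal; because self-organised W rows are
    then zero-mean, the inference current W . r_La computed from the raw
    lamina activity coincides with the contrast projection for trained units,
    while untrained random rows retain a luminance-driven component.
    """
    lam = np.asarray(lam, dtype=float)
    return lam - lam.mean()


# ---------------------------------------------------------------------------
# LIF dynamics
# ---------------------------------------------------------------------------

def lif_rate(I: float, p: LifParams | None = None) -> tuple[float, np.ndarray]:
    """Exponential-Euler-integrated LIF response to a constant current.

    The membrane update ``u <- drive + (u - drive) exp(-dt/tau)`` is exact
    for constant input between spikes, so the simulated interspike interval
    matches the closed form ``tau ln((R I - v0)/(R I - VT))`` to within one
    dt.  Returns the mean rate (spike count / duration, in spikes/s) and the
    spike times in ms.
    """
    p = p or LifParams()
    if not np.isfinite(I):
        raise ValueError("input current must be finite")
    n_steps = int(round(p.duration / p.dt))
    u = p.v0
    drive = p.R * I
    decay = np.exp(-p.dt / p.tau_m)
    spikes = []
    for step in range(n_steps):
        u = drive + (u - drive) * decay
        if u >= p.VT:
            spikes.append((step + 1) * p.dt)
            u = p.v0
    rate = len(spikes) / p.duration * 1000.0
    return rate, np.asarray(spikes)


def lif_rate_closed(I, p: LifParams | None = None):
    """Exact stationary LIF rate (spikes/s) for constant current(s).

    Zero below threshold (R I <= VT); vectorised over I.
    """
    p = p or LifParams()
    I = np.asarray(I, dtype=float)
    drive = p.R * I
    supra = drive > p.VT
    isi = np.full(I.shape, np.inf)
    d = np.where(supra, drive, p.VT + 1.0)  # placeholder below threshold
    isi = np.where(supra, p.tau_m * np.log((d - p.v0) / (d - p.VT)), np.inf)
    with np.errstate(divide="ignore"):
        rate = np.where(supra, 1000.0 / isi, 0.0)
    return rate if rate.ndim else float(rate)


def _apply_poisson_noise(rates: np.ndarray, p: LifParams, noise_scale: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Replace deterministic spike counts with scaled Poisson draws.

    The expected count over the presentation window is preserved
    (E[count] = rate * duration); ``noise_scale`` scales the count variance,
    with 0 returning the deterministic rates unchanged.
    """
    if noise_scale <= 0:
        return rates
    lam = np.asarray(rates) * p.duration / 1000.0 / noise_scale
    counts = rng.poisson(lam) * noise_scale
    return counts / p.duration * 1000.0


def medulla_response(lamina: np.ndarray, W_slice: np.ndarray,
                     p: LifParams | None = None, noise_seed: int | None = None,
                     gains: GainConfig | None = None) -> LayerResponse:
    """Medulla rate(s) for one lamina vector through weight slice(s).

    ``W_slice`` may be a single 625-vector or a (n, 625) bank.  The input
    current is ``medulla_gain * W_slice @ lamina``; the deterministic rate is
    the closed-form LIF rate, optionally replaced by a seeded Poisson count.
    """
    p = p or LifParams()
    gains = gains or GainConfig()
    lamina = np.asarray(lamina, dtype=float)
    W_slice = np.asarray(W_slice, dtype=float)
    if W_slice.shape[-1] != lamina.shape[0]:
        raise ValueError("weight slice does not match lamina length")
    current = gains.medulla_gain * (W_slice @ lamina)
    rates = np.atleast_1d(lif_rate_closed(current, p))
    if noise_seed is not None and gains.noise_scale > 0:
        rng = np.random.default_rng(noise_seed)
        rates = _apply_poisson_noise(rates, p, gains.noise_scale, rng)
    return LayerResponse(rates=rates, extras={"current": current})


def lobula_response(scan: ScanSequence, weights: VisualLobeWeights,
                    p: LifParams | None = None,
                    gains: GainConfig | None = None,
                    rng: np.random.Generator | int | None = None,
                    sigmoid: SigmoidParams | None = None) -> LayerResponse:
    """Full forward pass: 5-patch scan -> lobula population rates.

    Patch k drives medulla bank k of every lobula unit; bank responses are
    buffered (the delay-line abstraction) and summed at the final instant into
    the excitatory drive.  Lateral inhibition Q is resolved by a damped
    fixed-point iteration on rates,

        r <- (1 - d) r + d LIF(lobula_gain (drive - Q r)),

    until the update falls below 1e-3 spikes/s or 50 iterations (flagged in
    ``extras['converged']``; the last iterate is returned).  When ``rng`` is
    given and noise is enabled, Poisson count noise perturbs the medulla
    rates before integration.
    """
    p = p or LifParams()
    gains = gains or GainConfig()
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n = weights.n_lobula

    lam = np.stack([lamina_response(scan.patches[k], sigmoid) for k in range(M_PATCHES)])
    # currents[i, k] = medulla_gain * W[i, k, :] . lamina_k
    currents = gains.medulla_gain * np.einsum("ikl,kl->ik", weights.W, lam)
    med_rates = lif_rate_closed(currents, p)
    if rng is not None and gains.noise_scale > 0:
        med_rates = _apply_poisson_noise(med_rates, p, gains.noise_scale, rng)
    drive = med_rates.sum(axis=1)

    damp = 0.5
    r = np.zeros(n)
    converged = False
    n_iter = 0
    for n_iter in range(1, 51):
        target = lif_rate_closed(gains.lobula_gain * (drive - weights.Q @ r), p)
        r_new = (1 - damp) * r + damp * target
        delta = np.max(np.abs(r_new - r))
        r = r_new
        if delta < 1e-3:
            converged = True
            break
    r = np.maximum(r, 0.0)
    # every spiking neuron's output carries Poisson count noise; the lobula
    # population output is perturbed after the recurrent inhibition settles
    if rng is not None and gains.noise_scale > 0:
        r = _apply_poisson_noise(r, p, gains.noise_scale, rng)
    return LayerResponse(
        rates=r,
        extras={
            "medulla_rates": med_rates,
            "lamina": lam,
            "drive": drive,
            "converged": converged,
            "n_iter": n_iter,
        },
    )


def init_visual_lobe(n_lobula: int = DEFAULT_N_LOBULA, seed: int | None = None) -> VisualLobeWeights:
    """Untrained weights: W from Gaussian white noise N(0, 1) (clipped to the
    permitted [-1, 1] range), Q uniform on [0, 1) with a zero diagonal."""
    rng = np.random.default_rng(seed)
    W = np.clip(rng.standard_normal((n_lobula, N_DELAYS, N_LAMINA)), -1.0, 1.0)
    Q = rng.uniform(0.0, 1.0, size=(n_lobula, n_lobula))
    np.fill_diagonal(Q, 0.0)
    return VisualLobeWeights(W=W, Q=Q)
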