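"""Non-associative learning in the visual lobe.

Two local, unsupervised rules run simultaneously while the model scans
training scenes:

* Oja's rule on the feedforward weights W (one 625-weight lamina slice per
  delay bank of each lobula unit),

      dW = gamma * r_post * (r_lamina - r_post * W),

  whose multiplicative decay self-normalises the weight vector.  The
  presynaptic signal is the lamina contrast (activity minus field mean; see
  ``optic_lobe.lamina_contrast``), which is what permits signed ON/OFF
  receptive fields at equilibrium.  The postsynaptic factor is the bank's
  medulla rate gated by its lobula unit's lateral-inhibition factor, so that
  units suppressed by the population competition learn proportionally less.
  This coupling is what lets the inhibitory plasticity sculpt a *diverse*
  bank of receptive fields; with it removed, all units share one attractor.

* A symmetric rate-based inhibitory STDP on the lateral weights Q,

      dQ_ij = eta * (r_i * r_j - alpha),   i != j,

  which potentiates inhibition between co-active lobula units and relaxes it
  elsewhere; the depression factor alpha is the target co-activity (in
  (spikes/s)^2), and with one-to-one inhibitory partners r_In == r_Lo.

Weights are clipped to [-1, +1] (W) and [0, +1] (Q, zero diagonal) after
every update.  Training stops when the maximum weight change, averaged over a
sliding window of scans, falls below ``convergence_eps`` (default 0.001).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import sparseness_index
from .optic_lobe import (
    DEFAULT_N_LOBULA,
    GainConfig,
    LifParams,
    N_DELAYS,
    N_LAMINA,
    VisualLobeWeights,
    init_visual_lobe,
    lamina_response,
    lif_rate_closed,
)
from .stimuli import M_PATCHES, PATCH_SIZE, SceneImage, make_scan

__all__ = [
    "LearningConfig",
    "TrainingHistory",
    "oja_update",
    "istdp_update",
    "train_visual_lobe",
    "receptive_field",
]


#: firing rates are expressed in units of this scale (spikes/s) inside the
#: plasticity rules, so that learning rates refer to O(1) activities and the
#: Oja equilibrium weight norm stays inside the [-1, 1] clip
RATE_SCALE = 1800.0


@dataclass
class LearningConfig:
    """Learning rates and schedule for non-associative training.

    gamma and eta are the Oja and iSTDP learning rates applied to activities
    in units of RATE_SCALE spikes/s; alpha is the iSTDP target co-activity in
    absolute (spikes/s)^2 (alpha = 3 tolerates only a few spikes/s of mutual
    co-activation, driving the lateral inhibition into the competitive regime
    that decorrelates the population).  The defaults keep the Oja decay
    factor gamma * r^2 well below 1 at the activities the network actually
    visits, the stable regime of the rule.
    """

    gamma: float = 10.0
    eta: float = 0.05
    alpha: float = 3.0
    n_patches: int = 50_000
    convergence_eps: float = 1e-3
    window: int = 100
    shift_px: int = 15
    plastic_q: bool = True
    couple_inhibition: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma < 0 or self.eta < 0:
            raise ValueError("learning rates must be non-negative")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.convergence_eps <= 0:
            raise ValueError("convergence_eps must be positive")


@dataclass
class TrainingHistory:
    """Per-interval training diagnostics (recorded every ``every`` scans)."""

    steps: list = field(default_factory=list)
    max_dW: list = field(default_factory=list)
    max_dQ: list = field(default_factory=list)
    mean_rate: list = field(default_factory=list)
    sparseness: list = field(default_factory=list)
    converged: bool = False
    n_scans: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "step": self.steps,
            "max_dW": self.max_dW,
            "max_dQ": self.max_dQ,
            "mean_rate": self.mean_rate,
            "sparseness": self.sparseness,
        })


def oja_update(W_row: np.ndarray, r_la: np.ndarray, r_me: float, gamma: float) -> np.ndarray:
    """Oja weight change for one 625-weight slice: gamma r_me (r_la - r_me W)."""
    W_row = np.asarray(W_row, dtype=float)
    r_la = np.asarray(r_la, dtype=float)
    if W_row.shape != r_la.shape:
        raise ValueError("weight row and lamina vector must have equal shape")
    return gamma * r_me * (r_la - r_me * W_row)


def istdp_update(Q: np.ndarray, r_lo: np.ndarray, eta: float, alpha: float) -> np.ndarray:
    """Symmetric iSTDP change: eta (r_i r_j - alpha) off-diagonal, 0 on it."""
    Q = np.asarray(Q, dtype=float)
    r = np.asarray(r_lo, dtype=float)
    if Q.shape != (r.size, r.size):
        raise ValueError("Q must be square and match the rate vector")
    dQ = eta * (np.outer(r, r) - alpha)
    np.fill_diagonal(dQ, 0.0)
    return dQ


def _forward_learn(lam: np.ndarray, W: np.ndarray, Q: np.ndarray,
                   lif: LifParams, gains: GainConfig):
    """Noise-free forward pass used inside the training loop.

    Returns (medulla rates (n, 5), lobula rates (n,), per-bank postsynaptic
    activity (n, 5)).  The postsynaptic factor for the Oja rule is the
    bank's medulla rate scaled by the unit's inhibition gate (inhibited over
    uninhibited lobula rate), so units suppressed by the lateral competition
    learn proportionally less from that scan.
    """
    currents = gains.medulla_gain * np.einsum("ikl,kl->ik", W, lam)  # lam pre-centred
    med = lif_rate_closed(currents, lif)
    drive = med.sum(axis=1)
    free = lif_rate_closed(gains.lobula_gain * drive, lif)
    r = np.zeros(W.shape[0])
    for _ in range(50):
        target = lif_rate_closed(gains.lobula_gain * (drive - Q @ r), lif)
        r_new = 0.5 * r + 0.5 * target
        if np.max(np.abs(r_new - r)) < 1e-3:
            r = r_new
            break
        r = r_new
    gate = np.where(free > 0, r / np.maximum(free, 1e-12), 0.0)
    post = med * np.clip(gate, 0.0, 1.0)[:, None]
    return med, r, post


def train_visual_lobe(scenes: list[SceneImage], cfg: LearningConfig | None = None,
                      lif: LifParams | None = None, gains: GainConfig | None = None,
                      n_lobula: int = DEFAULT_N_LOBULA,
                      init: VisualLobeWeights | None = None,
                      record_every: int = 100) -> tuple[VisualLobeWeights, TrainingHistory]:
    """Self-organise W and Q by scanning training scenes.

    Each step draws a random scene and a random valid 75-row window, builds a
    5-patch scan (direction alternating left/right), runs the noise-free
    forward pass, and applies one Oja update per delay bank plus one iSTDP
    update from the final lobula rates.  Weights start from Gaussian white
    noise (W) and uniform [0, 1) (Q) and stay clipped to their permitted
    ranges.  Stops early once the sliding-window mean of max |dW| drops below
    ``convergence_eps``; non-convergence within ``n_patches`` scans is
    recorded in the history, not raised.
    """
    if not scenes:
        raise ValueError("need at least one training scene")
    cfg = cfg or LearningConfig()
    lif = lif or LifParams()
    gains = gains or GainConfig()
    rng = np.random.default_rng(cfg.seed)

    weights = init if init is not None else init_visual_lobe(n_lobula, seed=cfg.seed)
    W = weights.W.copy()
    Q = weights.Q.copy()
    hist = TrainingHistory()
    recent_dw = []

    span = PATCH_SIZE + (M_PATCHES - 1) * cfg.shift_px
    for step in range(cfg.n_patches):
        scene = scenes[rng.integers(len(scenes))]
        h, w = scene.pixels.shape
        row = int(rng.integers(0, h - PATCH_SIZE + 1))
        col = int(rng.integers(0, w - span + 1))
        direction = "left_to_right" if step % 2 == 0 else "right_to_left"
        scan = make_scan(scene, region="custom", shift_px=cfg.shift_px,
                         direction=direction, window_row=row, col_start=col)
        lam = np.stack([lamina_response(scan.patches[k]) for k in range(M_PATCHES)])
        # lamina contrast coding: the signal forwarded to the medulla (and
        # entering the learning rule) is the background-subtracted activity
        lam_c = lam - lam.mean(axis=1, keepdims=True)

        med, r_lo, post = _forward_learn(lam_c, W, Q, lif, gains)
        if not cfg.couple_inhibition:
            post = med
        post = post / RATE_SCALE

        # Oja on every (unit, bank) slice, vectorised
        dW = cfg.gamma * post[:, :, None] * (lam_c[None, :, :] - post[:, :, None] * W)
        W = np.clip(W + dW, -1.0, 1.0)

        if cfg.plastic_q:
            dQ = istdp_update(Q, r_lo / RATE_SCALE, cfg.eta, cfg.alpha / RATE_SCALE ** 2)
            Q = np.clip(Q + dQ, 0.0, 1.0)
            np.fill_diagonal(Q, 0.0)
            max_dq = float(np.max(np.abs(dQ)))
        else:
            max_dq = 0.0

        max_dw = float(np.max(np.abs(dW)))
        recent_dw.append(max_dw)
        if len(recent_dw) > cfg.window:
            recent_dw.pop(0)

        if step % record_every == 0 or step == cfg.n_patches - 1:
            hist.steps.append(step)
            hist.max_dW.append(max_dw)
            hist.max_dQ.append(max_dq)
            hist.mean_rate.append(float(r_lo.mean()))
            hist.sparseness.append(sparseness_index(r_lo) if r_lo.any() else np.nan)

        if (len(recent_dw) == cfg.window
                and float(np.mean(recent_dw)) < cfg.convergence_eps):
            hist.converged = True
            hist.n_scans = step + 1
            break
    else:
        hist.n_scans = cfg.n_patches

    return VisualLobeWeights(W=W, Q=Q), hist


def receptive_field(weights: VisualLobeWeights, i: int) -> np.ndarray:
    """The five delay slices of unit i's lamina weights as 25x25 images.

    Positive values are excitatory, negative inhibitory; the sign is
    preserved for export.  Reshaping then flattening is the identity.
    """
    if not 0 <= i < weights.n_lobula:
        raise IndexError(f"lobula index {i} out of range")
    side = int(np.sqrt(N_LAMINA))
    return weights.W[i].reshape(N_DELAYS, side, side).copy()


def export_receptive_field_grid(weights: VisualLobeWeights, path,
                                cmap: str = "RdBu_r") -> None:
    """Render the whole population's spatiotemporal receptive fields to PNG.

    One row block per lobula unit, five columns (the delay slices); red for
    excitatory and blue for inhibitory weights, normalised per unit.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = weights.n_lobula
    fig, axes = plt.subplots(n, N_DELAYS, figsize=(N_DELAYS * 1.1, n * 1.1),
                             squeeze=False)
    for i in range(n):
        rf = receptive_field(weights, i)
        v = np.abs(rf).max() or 1.0
        for k in range(N_DELAYS):
            ax = axes[i][k]
            ax.imshow(rf[k], cmap=cmap, vmin=-v, vmax=v)
            ax.set_xticks([])
            ax.set_yticks([])
    fig.tight_layout(pad=0.2)
    fig.savefig(path, dpi=80)
    plt.close(fig)
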