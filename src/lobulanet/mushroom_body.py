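"""Mushroom body: sparse Kenyon-cell expansion, MBON readout, and
reinforcement-modulated STDP.

Lobula rates project through a random non-negative matrix S onto a large
Kenyon-cell (KC) population; a per-stimulus threshold at the 95th percentile
of the KC drive keeps fewer than 5% of KCs active per stimulus.  All KCs
converge on a single mushroom body output neuron (MBON) through the plastic
weight vector D; a low MBON rate signals preference, a high rate rejection.

During differential conditioning a reinforcement signal selects the learning
kernel applied to KC->MBON synapses of spiking KCs:

* punishment (dopamine): classical STDP, potentiating when the KC spike
  precedes the MBON spike and depressing otherwise, which on balance
  strengthens the drive from pattern-coding KCs (MBON rate rises);
* reward (octopamine): a depression-only kernel (negative for every spike
  ordering), weakening the same synapses (MBON rate falls).

No plasticity is applied during choice tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import optic_lobe
from .optic_lobe import GainConfig, LayerResponse, LifParams, VisualLobeWeights
from .stimuli import ScanSequence

__all__ = [
    "MushroomBodyWeights",
    "StdpParams",
    "ConditioningProtocol",
    "ChoiceOutcome",
    "init_mushroom_body",
    "kc_response",
    "mbon_response",
    "stdp_kernel",
    "conditioning_trial",
    "choice_test",
    "run_protocol",
]

DEFAULT_N_KC = 2000
#: scale of the random lobula->KC weights
DEFAULT_W_MAX = 0.25
#: KC active fraction ceiling enforced by the percentile threshold
KC_ACTIVE_FRACTION = 0.05
#: spikes/s of KC output per unit of suprathreshold drive
KC_GAIN = 10.0
#: MBON input current per unit of D-weighted KC rate sum
MBON_GAIN = 5e-4
#: exponential synaptic time constant of KC->MBON transmission (ms)
SYN_TAU = 5.0


@dataclass
class StdpParams:
    """STDP kernel constants: peak magnitude A and time constant tau (ms)."""

    A: float = 0.01
    tau: float = 20.0

    def __post_init__(self) -> None:
        if self.A <= 0 or self.tau <= 0:
            raise ValueError("A and tau must be positive")


@dataclass
class MushroomBodyWeights:
    """Random expansion S (lobula x KC) and plastic readout D (KC,)."""

    S: np.ndarray
    D: np.ndarray
    w_max: float = DEFAULT_W_MAX
    seed: int | None = None

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        if self.S.ndim != 2 or self.D.shape != (self.S.shape[1],):
            raise ValueError("S must be (n_lobula, n_kc) and D (n_kc,)")
        if self.S.min() < 0 or self.S.max() > self.w_max + 1e-9:
            raise ValueError("S entries must lie in [0, w_max]")
        if self.D.min() < 0 or self.D.max() > 1 + 1e-9:
            raise ValueError("D entries must lie in [0, 1]")

    @property
    def n_kc(self) -> int:
        return self.S.shape[1]


@dataclass
class ConditioningProtocol:
    """Differential conditioning schedule (S+ rewarded, S- punished)."""

    n_exposures: int = 100
    n_bees: int = 20
    n_tests: int = 50
    n_kc: int = DEFAULT_N_KC
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_bees, self.n_tests, self.n_kc) <= 0 or self.n_exposures < 0:
            raise ValueError("protocol counts must be positive")


@dataclass
class ChoiceOutcome:
    """MBON rates for the two test patterns and the resulting choice."""

    rate_a: float
    rate_b: float
    choice: int  # 0 -> pattern A, 1 -> pattern B


def init_mushroom_body(n_lobula: int, n_kc: int = DEFAULT_N_KC,
                       w_max: float = DEFAULT_W_MAX,
                       seed: int | None = None) -> MushroomBodyWeights:
    """Random S ~ U[0, w_max]; D ~ U[0.4, 0.6] so the naive MBON responds
    equally to either pattern with headroom to move both ways."""
    rng = np.random.default_rng(seed)
    S = rng.uniform(0.0, w_max, size=(n_lobula, n_kc))
    D = rng.uniform(0.4, 0.6, size=n_kc)
    return MushroomBodyWeights(S=S, D=D, w_max=w_max, seed=seed)


def kc_response(lobula_rates: np.ndarray, mb: MushroomBodyWeights,
                rng: np.random.Generator | None = None,
                p: LifParams | None = None) -> LayerResponse:
    """Sparse KC activity for one lobula rate vector.

    KC drive is S^T r; the firing threshold is set per stimulus at the 95th
    percentile of the drive, and only strictly suprathreshold KCs are active
    (at most 5% of the population).  Active KCs fire at ``KC_GAIN`` spikes/s
    per unit of suprathreshold drive; when ``rng`` is given, Poisson spike
    trains over the presentation window are attached.
    """
    p = p or LifParams()
    r = np.asarray(lobula_rates, dtype=float)
    if r.shape != (mb.S.shape[0],):
        raise ValueError("lobula rate vector does not match S")
    drive = mb.S.T @ r
    if not drive.any():
        return LayerResponse(rates=np.zeros(mb.n_kc), spikes=None,
                             extras={"threshold": 0.0, "active": np.zeros(mb.n_kc, bool)})
    thr = float(np.percentile(drive, 100 * (1 - KC_ACTIVE_FRACTION)))
    activity = np.where(drive > thr, drive - thr, 0.0)
    rates = KC_GAIN * activity
    spikes = None
    if rng is not None:
        spikes = [None] * mb.n_kc
        active = np.flatnonzero(rates > 0)
        for k in active:
            n_sp = rng.poisson(rates[k] * p.duration / 1000.0)
            spikes[k] = np.sort(rng.uniform(0.0, p.duration, size=n_sp))
    return LayerResponse(rates=rates, spikes=spikes,
                         extras={"threshold": thr, "active": rates > 0})


def mbon_response(kc: LayerResponse, D: np.ndarray,
                  p: LifParams | None = None) -> LayerResponse:
    """MBON response to KC activity.

    The input current is ``MBON_GAIN * sum_k D_k r_k``.  With KC spike trains
    attached the MBON membrane is Euler-integrated against the exponentially
    filtered spike input (so MBON spikes tend to follow the KC spikes that
    caused them, giving STDP its causal structure); otherwise the closed-form
    stationary rate for the equivalent constant current is returned.
    """
    p = p or LifParams()
    D = np.asarray(D, dtype=float)
    if D.shape != kc.rates.shape:
        raise ValueError("D does not match the KC population")
    if kc.spikes is None:
        current = MBON_GAIN * float(D @ kc.rates)
        rate = optic_lobe.lif_rate_closed(current, p)
        return LayerResponse(rates=np.array([rate]), extras={"current": current})

    n_steps = int(round(p.duration / p.dt))
    # accumulate D-weighted synaptic charge per time bin
    charge = np.zeros(n_steps + 1)
    for k, times in enumerate(kc.spikes):
        if times is None or len(times) == 0:
            continue
        idx = np.minimum((np.asarray(times) / p.dt).astype(int), n_steps)
        np.add.at(charge, idx, D[k])
    syn_decay = np.exp(-p.dt / SYN_TAU)
    # scale so that the time-averaged current matches the rate-mode current
    pulse_gain = MBON_GAIN * 1000.0 / SYN_TAU

    u = p.v0
    s = 0.0
    decay = p.dt / p.tau_m
    spike_times = []
    for step in range(n_steps):
        s = s * syn_decay + charge[step]
        I = pulse_gain * s
        u = u + decay * (-u + p.R * I)
        if u >= p.VT:
            spike_times.append((step + 1) * p.dt)
            u = p.v0
    rate = len(spike_times) / p.duration * 1000.0
    return LayerResponse(rates=np.array([rate]), spikes=[np.asarray(spike_times)])


def stdp_kernel(dt, mode: str, p: StdpParams | None = None):
    """Weight change for a single spike pair with timing dt = t_post - t_pre.

    ``dopamine`` (punishment): +A exp(-dt/tau) for dt > 0, -A exp(dt/tau) for
    dt < 0 (classical, odd in dt).  ``octopamine`` (reward): -A exp(-|dt|/tau)
    for every ordering (depression-only, even in dt).  Pairs at exactly dt = 0
    contribute nothing.  Vectorised over dt (ms).
    """
    p = p or StdpParams()
    if mode not in ("dopamine", "octopamine"):
        raise ValueError(f"unknown STDP mode {mode!r}")
    dt = np.asarray(dt, dtype=float)
    mag = p.A * np.exp(-np.abs(dt) / p.tau)
    if mode == "dopamine":
        out = np.where(dt > 0, mag, np.where(dt < 0, -mag, 0.0))
    else:
        out = np.where(dt != 0, -mag, 0.0)
    return out if out.ndim else float(out)


def conditioning_trial(scan: ScanSequence, valence: str, lobe: VisualLobeWeights,
                       mb: MushroomBodyWeights, rng: np.random.Generator,
                       lif: LifParams | None = None, gains: GainConfig | None = None,
                       stdp: StdpParams | None = None) -> float:
    """One reinforced exposure; updates ``mb.D`` in place.

    Runs the noisy forward pass, draws KC and MBON spike trains, then applies
    the reward (octopamine) or punishment (dopamine) kernel to every
    (KC spike, MBON spike) pair within +/- 5 tau, summing the changes into
    D for each KC that spiked.  D is clipped to [0, 1].  Returns the MBON
    rate of the trial (for learning curves).
    """
    if valence not in ("reward", "punishment"):
        raise ValueError(f"unknown valence {valence!r}")
    lif = lif or LifParams()
    gains = gains or GainConfig()
    stdp = stdp or StdpParams()
    mode = "octopamine" if valence == "reward" else "dopamine"

    lob = optic_lobe.lobula_response(scan, lobe, p=lif, gains=gains, rng=rng)
    kc = kc_response(lob.rates, mb, rng=rng, p=lif)
    mbon = mbon_response(kc, mb.D, p=lif)
    rate = float(mbon.rates[0])
    t_post = mbon.spikes[0] if mbon.spikes else np.empty(0)
    if t_post.size == 0 or kc.spikes is None:
        return rate

    window = 5.0 * stdp.tau
    for k, t_pre in enumerate(kc.spikes):
        if t_pre is None or len(t_pre) == 0:
            continue
        dts = t_post[None, :] - np.asarray(t_pre)[:, None]
        dts = dts[np.abs(dts) <= window]
        if dts.size:
            mb.D[k] = np.clip(mb.D[k] + np.sum(stdp_kernel(dts, mode, stdp)), 0.0, 1.0)
    return rate


def choice_test(lobe: VisualLobeWeights, mb: MushroomBodyWeights,
                scan_a: ScanSequence, scan_b: ScanSequence,
                rng: np.random.Generator, lif: LifParams | None = None,
                gains: GainConfig | None = None) -> ChoiceOutcome:
    """Two-alternative unrewarded test: the lower MBON rate wins.

    Fresh noise for both presentations, through the same spiking KC -> MBON
    pathway used during conditioning; no synaptic update of any kind.  Ties
    are broken uniformly at random from ``rng``.
    """
    lif = lif or LifParams()
    gains = gains or GainConfig()
    rates = []
    for scan in (scan_a, scan_b):
        lob = optic_lobe.lobula_response(scan, lobe, p=lif, gains=gains, rng=rng)
        kc = kc_response(lob.rates, mb, rng=rng, p=lif)
        rates.append(float(mbon_response(kc, mb.D, p=lif).rates[0]))
    if rates[0] == rates[1]:
        choice = int(rng.integers(2))
    else:
        choice = int(np.argmin(rates))
    return ChoiceOutcome(rate_a=rates[0], rate_b=rates[1], choice=choice)


def run_protocol(protocol: ConditioningProtocol, lobe: VisualLobeWeights,
                 scan_plus: ScanSequence, scan_minus: ScanSequence,
                 lif: LifParams | None = None, gains: GainConfig | None = None,
                 stdp: StdpParams | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Differential conditioning of a cohort of simulated bees.

    For each bee a fresh mushroom body is drawn from the bee's seed, reward
    (S+) and punishment (S-) exposures are interleaved in random order, and
    ``n_tests`` plasticity-free choice tests follow.  Returns a per-bee
    accuracy table (bee_seed, n_correct, n_tests, accuracy) and MBON learning
    curves (bee, exposure_index, mbon_rate_splus, mbon_rate_sminus).
    """
    lif = lif or LifParams()
    gains = gains or GainConfig()
    stdp = stdp or StdpParams()
    root = np.random.SeedSequence(protocol.seed)
    bee_seeds = root.spawn(protocol.n_bees)

    rows = []
    curves = []
    for b, ss in enumerate(bee_seeds):
        rng = np.random.default_rng(ss)
        mb_seed = int(rng.integers(2 ** 31))
        mb = init_mushroom_body(lobe.n_lobula, n_kc=protocol.n_kc, seed=mb_seed)
        schedule = ["reward"] * protocol.n_exposures + ["punishment"] * protocol.n_exposures
        rng.shuffle(schedule)
        i_plus = i_minus = 0
        for valence in schedule:
            scan = scan_plus if valence == "reward" else scan_minus
            rate = conditioning_trial(scan, valence, lobe, mb, rng,
                                      lif=lif, gains=gains, stdp=stdp)
            if valence == "reward":
                curves.append({"bee": b, "exposure_index": i_plus,
                               "mbon_rate_splus": rate, "mbon_rate_sminus": np.nan})
                i_plus += 1
            else:
                curves.append({"bee": b, "exposure_index": i_minus,
                               "mbon_rate_splus": np.nan, "mbon_rate_sminus": rate})
                i_minus += 1
        n_correct = 0
        for _ in range(protocol.n_tests):
            out = choice_test(lobe, mb, scan_plus, scan_minus, rng,
                              lif=lif, gains=gains)
            n_correct += int(out.choice == 0)
        rows.append({"bee": b, "bee_seed": mb_seed,
                     "n_correct": n_correct, "n_tests": protocol.n_tests,
                     "accuracy": n_correct / protocol.n_tests})
    return pd.DataFrame(rows), pd.DataFrame(curves)
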