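# Methods

This note records the model as implemented: its assumptions, the parameters
that matter, what the synthetic data do and do not emulate, the numerical
choices, and the places where the design was genuinely open and a choice had
to be made.

## Signal flow and units

All images are green-channel intensities in [0, 1], row-major, origin
top-left; the scan axis is the column axis. A scan is exactly five 75×75
patches displaced by `shift_px` columns; `shift_px` is the flight-speed proxy
(15 px ↔ 0.1 m/s, linear through the origin). Firing rates are reported in
spikes/s throughout; membrane constants follow the leaky integrate-and-fire
(LIF) model `τ du/dt = −u + R·I` with `R = 10` (dimensionless input gain),
`τ = 10 ms`, reset `v0 = −80 mV`, threshold `VT = 0 mV`.

For a constant current the LIF rate has the closed form
`1000 / (τ ln((R I − v0)/(R I − VT)))` spikes/s (zero at or below threshold).
The forward pass uses this exact stationary rate rather than re-simulating
every neuron; the exponential-Euler simulator (`lif_rate`) is kept for
spike-time generation and as a numerical cross-check (its interspike interval
matches the closed form to within one `dt`). Two consequences of this
particular LIF parameterisation are worth keeping in mind when reading
results: the current-to-rate map is strongly logarithmic (any clearly
positive current yields ≥ 10–25 spikes/s), so tuning expresses itself mostly
through *which* units are silenced, and spike counts over a 100 ms window
quantise rates in steps of 10 spikes/s.

## Lamina and the contrast channel

Each of the 625 lamina neurons pools a non-overlapping 3×3 photoreceptor
block and applies `f(r) = A0/(1 + exp(m r + b))` with `A0 = 1, m = −1,
b = 0.5`. Because the pooled input ranges over [0, 9], the sigmoid saturates
for mid-to-bright regions; the informative structure of a natural patch lives
in its dark features and edges.

The signal the lamina transmits onward is treated as *contrast*: activity
minus the mean over the field (`lamina_contrast`). This mirrors the
well-known predictive/contrast coding of lamina monopolar cells and is what
makes signed ON/OFF receptive fields reachable: with a strictly positive
presynaptic signal and a non-negative rate as the postsynaptic factor, the
Oja equilibrium `W* = E[post·x]/E[post²]` cannot contain negative components.
The plasticity rules therefore learn from the centred activity. Trained
weight rows end up zero-mean, so the inference current `W·r_La` computed from
the raw lamina activity coincides with the contrast projection for trained
units; untrained random rows additionally carry a luminance (DC) component,
which is why the naive network responds broadly to everything — the
"broad before, selective after" signature of non-associative learning.

## Non-associative learning

Two local rules run simultaneously, once per 5-patch scan:

* **Oja** on each delay bank's 625-weight slice:
  `ΔW = γ·post·(x − post·W)`, `W` clipped to [−1, 1]. `x` is the centred
  lamina vector of that bank's patch. `post` is the bank's medulla rate
  multiplied by the unit's *inhibition gate* — the ratio of its inhibited to
  uninhibited lobula rate. The gate is the coupling through which the
  inhibitory plasticity shapes the feedforward weights: units suppressed by
  the population competition learn proportionally less, which drives the
  population to tile different features instead of collapsing onto one
  attractor (and is what lets a frozen-Q ablation degrade the outcome).
* **Inhibitory STDP** on the lateral weights:
  `ΔQ_ij = η·(r_i r_j − α)` off-diagonal, `Q` clipped to [0, 1], zero
  diagonal. One-to-one inhibitory partners are assumed, so the presynaptic
  inhibitory rate equals the lobula rate.

Inside the rules, rates are expressed in units of `RATE_SCALE = 1800`
spikes/s. This single normalisation sets the Oja equilibrium weight norm;
it was calibrated (together with γ) so that trained preferred-stimulus
medulla currents land in the graded LIF regime and weight rows stay clear of
the ±1 clip. Defaults: `γ = 10`, `η = 0.05`, `α = 3 (spikes/s)²` — a small
target co-activity that keeps the lateral inhibition in the competitive
regime. Layer gains are `medulla_gain = 1.0` and `lobula_gain = 2e-4`, the
latter fixed so a full-contrast preferred moving bar drives a trained unit at
roughly 25–30 spikes/s.

Training samples a random scene, a random valid 75-row window and column
start, alternates scan direction, and runs the noise-free forward pass.
Convergence is declared when the sliding 100-scan mean of max |ΔW| drops
below 0.001; otherwise training stops at `n_patches` (50,000 by default;
5,000 in the reduced settings used by the tests and the acceptance script —
enough for the receptive-field structure to form, though with a noticeable
±5 percentage-point run-to-run spread in downstream behavioural accuracy,
which is why summary runs average over reseeded instantiations).

## Poisson noise

Each spiking neuron's output carries Poisson count noise: the deterministic
count `λ = rate × duration` is replaced by `noise_scale × Poisson(λ /
noise_scale)` — mean-preserving, variance scaled by `noise_scale`, 0
disabling it. It is applied to medulla and lobula outputs in the forward
pass, and Kenyon cells emit Poisson spike trains. The default
`noise_scale = 3` was calibrated on one behavioural anchor: a visual lobe
with random, untrained connectivity should not be able to discriminate the
two crosses. (At `noise_scale = 1` the untrained model still scored ~72%
through residual luminance differences between the two patterns' scan
windows; at 3 it sits near chance without erasing the trained model's
local-scanning performance.)

## Mushroom body

Lobula rates project through `S ~ U[0, 0.25]` (per bee reseeded) onto 2,000
Kenyon cells. The KC threshold is set per stimulus at the 95th percentile of
the drive, so at most 5% of KCs are active; active KCs fire at 10 spikes/s
per unit of suprathreshold drive. All KCs converge on one MBON
(`I = 5e-4 · Σ D_k r_k`); during conditioning the MBON membrane is
Euler-integrated against the exponentially filtered KC spike input (5 ms
synaptic time constant), so MBON spikes tend to follow the KC spikes that
caused them — the causal structure classical STDP needs.

Conditioning applies, for every (KC spike, MBON spike) pair within ±5τ, the
dopamine kernel `+A e^{−Δt/τ} (Δt>0) / −A e^{Δt/τ} (Δt<0)` for punished
patterns or the depression-only octopamine kernel `−A e^{−|Δt|/τ}` for
rewarded ones (`A = 0.01`, `τ = 20 ms`; pairs at exactly Δt = 0 contribute
nothing). `D` starts at `U[0.4, 0.6]` — the naive MBON responds equally to
either pattern with headroom both ways — and is clipped to [0, 1]. Choice
tests run the identical spiking pathway with fresh noise and *no* synaptic
updates; the pattern with the lower MBON rate is chosen, ties broken
uniformly at random.

## Stimuli

Patterns are drawn analytically from signed-distance bars with a 1-px
anti-alias ramp on a 300×300 canvas (the smallest round size that admits a
whole-pattern scan at the fast speed, 255 px, and a quadrant-confined scan at
normal speed, 135 ≤ 150 px). The multiplication sign equals the plus rotated
45° about the canvas centre. Stroke width defaults to 12% of the canvas;
foreground intensity equals the contrast on a black background. The
"distal view" shrinks a pattern five-fold onto the same canvas (it subtends
one fifth of the visual angle at five times the distance).

Scan regions: `lower_half` places the 75-row window just below the midline;
`lower_left` additionally confines the traverse to the lower-left quadrant;
`whole_fit` first rescales the pattern so its full width fits inside the
traverse — a bee surveying a whole pattern necessarily views it at coarser
angular resolution than one inspecting a sub-region close up. A lower-left
scan at the fast speed does not fit inside the quadrant and raises an error
(reported as NaN in condition tables).

The synthetic scene generator stands in for natural flower/scene
photographs. It superposes a `1/(f + f0)^1.2`-filtered noise base, oriented
soft-edged bars at random angles, and a 0.8-px optical blur, then normalises
to [0, 1]. It reproduces the second-order statistics that matter for the
learning rules — lag-1 autocorrelation above 0.9 and a radially averaged
log–log power-spectrum slope near −2, against ~0 and flat for its
pixel-shuffled control — but not the higher-order structure of real
photographs (occlusions, textures, luminance distributions of vegetation).
Passing tests therefore demonstrate that the mechanisms behave as designed
on images with naturalistic first- and second-order statistics, not that the
model reproduces every number obtainable with real photographs.

## Numerical choices

* Lobula lateral inhibition is resolved by a damped fixed-point iteration on
  rates, `r ← ½ r + ½ LIF(g (drive − Q r))`, stopping below 1e-3 spikes/s or
  after 50 iterations (flagged, last iterate returned). Published rates carry
  that ~1e-3 tolerance.
* Stationary LIF rates are evaluated in closed form; spike trains are only
  generated where spike timing matters (KC→MBON STDP).
* The Treves–Rolls index is computed on the peak-normalised vector (scale
  invariant; avoids underflow) and returns NaN for an all-zero population.
* The velocity-tuning fit uses the gamma-density shape
  `c v^{k−1} e^{−v/θ}` with `k > 1` and a free amplitude via bounded
  least squares; a failed or non-finite fit is flagged degenerate rather than
  raised.
* The orientation-selectivity index is `(r_pref − r_orth)/(r_pref + r_orth)`
  on mean rates over noise repetitions, probed with moving bars at 30°
  steps. Under this LIF a unit silenced at the orthogonal angle scores
  OSI = 1 regardless of how structured its receptive field is, so
  population fractions of "OSI > 0.3" have a chance level near 50%;
  receptive-field spatial smoothness is the sharper discriminator between
  natural-trained and shuffled-trained populations (≈100% vs ≈0% smooth
  units) and is what the unit tests assert.

## Known limitations

* The behavioural orderings of the scanning conditions (local close-up
  scanning best, whole-pattern overview worse, no scanning worst, untrained
  connectivity worst of all) are reproduced, but the model degrades less than
  the original under whole-pattern viewing and fast scanning: the two crosses
  remain discriminable at coarse resolution and large patch separations.
* The untrained-connectivity control sits a few points above chance because
  the two patterns' scan windows differ slightly in mean luminance, which
  leaks through the DC component of random weight rows.
* Trained response correlations across scenes are low but not lower than the
  naive network's (random projections are already nearly uncorrelated);
  decorrelation expresses itself as sparseness and distinct tuning rather
  than as a drop in pairwise correlation.
* No colour, no hexagonal ommatidial sampling, no 3-D flight or optics; the
  delay alignment is a buffering abstraction, not a biophysical delay line.
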