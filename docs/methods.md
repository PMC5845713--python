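# Model and methods

`mso_itd` simulates the mammalian brainstem circuit that extracts
interaural time differences (ITDs): auditory-nerve fibers (ANF) of both
ears excite globular bushy cells (GBC) and the medial superior olive
(MSO) of both hemispheres; GBCs provide fast, phase-locked inhibition to
the MSO.  ITDs are read out either by the linear opponent-channel
decoder dR = R_R - R_L or by a small multilayer perceptron that
regresses ITD from the population rates.  This note records the model's
assumptions, the parameters that matter, and the choices made where the
design was open.

## Stimuli

All stimuli live at 100 kHz.  Tones, AM tones and chirps are gated with
20 ms raised-cosine ramps and padded with 20 ms of silence per side
(60 ms for the MLP training corpus); WAV input is resampled with a
Kaiser-windowed polyphase filter.  Levels are calibrated so the RMS of
the ungated core equals the target dB SPL re 20 uPa; the reference
segment is the plateau, a choice the calibration contract leaves open.

Sign convention: **positive ITD = right ear leading**, and the left MSO
prefers positive ITDs.  Static ITDs are imposed in the frequency domain
as symmetric linear phase (+itd/2 delay left, -itd/2 right), which keeps
the binaural midpoint fixed, preserves per-channel energy exactly, and
supports sub-sample delays.  Time-varying ITDs (chirp experiments) are
instead realized as an instantaneous-phase offset on the left channel,
phi_L = phi - 2*pi*f(t)*itd(t).

## Auditory-nerve surrogate

The periphery is a statistical surrogate of high-spontaneous-rate ANF
responses, not a mechanical cochlea.  Stages: fourth-order gammatone at
the characteristic frequency (cascade of complex one-pole sections —
the direct polynomial form is numerically unstable at low cf for
fs = 100 kHz); half-wave rectification; a 4-pole low-pass at 1.2 kHz
whose progressive flattening of the fine structure produces the
vector-strength roll-off with frequency; a sigmoidal-in-dB rate-level
function driven by a slow (50 Hz) envelope (midpoint 20 dB, spread
6 dB); a fine-structure gate riding 3 dB above the envelope, normalized
by its own slow mean so it concentrates spikes into the depolarizing
phase without changing the mean driven rate; two multiplicative
depletion stages (recovery 10 ms / strength 1.2 and 80 ms / 0.4) giving
rapid and short-term adaptation with an onset overshoot; and per-fiber
inhomogeneous Poisson sampling by time rescaling with a 0.75 ms
absolute dead time.  Driven activity displaces spontaneous firing
(60 spikes/s) rather than adding to it.

Defaults were calibrated once to the response statistics that drive the
circuit: at 50 dB SPL, sustained rates of ~150-210 spikes/s roughly flat
over 125-1400 Hz, onset rates of ~300 spikes/s, pooled vector strength
~0.80 at 125-500 Hz falling to ~0.65 at 1.4 kHz, and an interaural
pooled-phase difference of 2*pi*f*ITD.  What the surrogate does *not*
emulate: basilar-membrane compression and suppression, middle-ear
filtering (a gain absorbed by calibration), medium/low-spontaneous-rate
fibers, and cochlear traveling-wave delay beyond the gammatone group
delay.  Tests passing on the surrogate therefore validate the circuit
and decoders given realistic input statistics, not the periphery
itself.  Any external cochlear model exposing the same
`anf_spikes(stim, config, hemisphere) -> SpikeTrains` signature can be
plugged in.

## Neuron models

Both cell types are single-compartment Hodgkin-Huxley models integrated
with exponential Euler at dt = 10 us (one stimulus sample; gating
updates use voltage lookup tables with linear interpolation).  The
scheme was validated against an adaptive LSODA reference (< 0.5 mV RMS
subthreshold) and spike counts change by only a few percent between
dt = 20 us and dt = 1 us.

**MSO.** Cm = 70 pF; E_rest = -55.8 mV; E_Na = 56.2, E_K = -90,
E_h = -35, E_e = 0, E_i = -70 mV; g_Na = 3.9 uS, g_KLT = 650 nS,
g_h = 520 nS, g_leak = 13 nS.  Sodium kinetics follow the
Rothman-Manis ventral-cochlear-nucleus formulation with a Q10 = 3
correction to 37 degC (k = 3^1.5 ~ 5.2); the *activation* time constant
is divided by an additional factor of four on top of k — without that
speed-up the depolarized compartment cannot regenerate spikes.  The
low-threshold potassium channel uses the gerbil-MSO activation curve
(V1/2 = -57.3 mV, slope 11.7 mV, fourth power) with its inactivation
held constant at z = 0.4; the hyperpolarization-activated current is a
single slow sigmoidal gate.  Two kinetic constants are not pinned down
by published values at this temperature and were calibrated once, then
frozen: the KLT time-constant scale (0.60) and the Ih half-activation
(-75 mV), set so that the compartment rests at -55.8 mV and its
subthreshold impedance peaks near 260 Hz (measured 265 Hz, stable
within a few Hz across probe amplitudes).  The leak reversal is solved
at construction so the stated rest is an exact fixed point.  Spikes are
detected as upward crossings of -20 mV with a 1 ms lockout.  Because
sodium is ~80% inactivated at this depolarized rest, action potentials
are small (peaks between about -15 and 0 mV depending on drive) — the
well-known smallness of somatic MSO spikes — so the detection threshold,
not a 0 mV overshoot, defines a spike.

**GBC.** Rothman-Manis type II parameters (g_Na = 1 uS,
g_KHT = 150 nS, g_KLT = 200 nS, g_h = 20 nS, g_leak = 2 nS,
Cm = 12 pF at the 22 degC reference, all rates Q10-corrected to
37 degC), driven by 40 non-depressing ANF synapses (alpha function,
tau = 0.2 ms, 8 nS per input — calibrated so that the cell entrains to
phase-locked volleys and sharpens vector strength, e.g. 0.80 to ~0.99
at 250 Hz, while single inputs cannot fire it).  Above ~1 kHz the
per-cycle volleys no longer reach threshold and the GBC falls silent;
this makes MSO inhibition ineffective at high frequencies, which is
what pins the high-frequency best-ITD at the axonal delay.

## Circuit

500 neurons per population per hemisphere at full scale (experiments
scale this down; fan-in falls back to sampling with replacement if a
scaled pool is smaller than a fan-in).  Each MSO neuron receives 6
ipsilateral + 6 contralateral ANF excitatory inputs (alpha conductance,
tau_e = 0.17 ms) and 3 + 3 GBC inhibitory inputs (peak-normalized
bi-exponential, tau = 0.14/1.6 ms).  The printed synaptic equations mix
conductance and current conventions; both synapses are implemented as
peak-normalized conductance waveforms scaled by their strengths and
driving currents g*(Vm - E), which keeps the membrane equation
dimensionally consistent.  Contralateral pathways carry a fixed 100 us
axonal delay; contralateral inhibition is offset a further 0.6 ms
(read as additive on top of the axonal delay; `inh_delay_additive`
makes the alternative reading available), ipsilateral inhibition 0 ms.

The two per-input strengths are free parameters fixed by
`scripts/calibrate.py` and frozen as defaults: g_syn_e = 20 nS puts the
cell in the coincidence-detector regime (bilateral in-phase volleys
fire it, unilateral volleys mostly do not; best-ITD without inhibition
= the 100 us axonal delay), and g_syn_i = 30 nS places the fitted
125 Hz best-ITD near the target 470 us contralateral lead.  With these
defaults the best-ITD magnitude falls monotonically with frequency to
~90-110 us at 1.4 kHz, and the midline sensitivity of dR peaks near
300 Hz.  A side effect of strong phase-locked inhibition is a response
minimum around 500-600 Hz, where the IPSP duration matches the cycle
and inhibition becomes a tonic blanket; the sensitivity peak at 300 Hz
is partly shaped by it.

Firing rates are population means inside an analysis window running
from 25 ms after core onset to 25 ms after core offset (clipped to the
recording) to skip the front-end group delay.

## ITD-rate fits and sensitivity

ITD-rate functions are fitted with the modified Gaussian
R(tau) = R_max exp(-((tau - B)/W)^2) + R_offset by bounded least
squares from multiple starts (lowest residual wins).  The ITD grid
spans +-1 ms but is restricted to one tuning period (+-1/(2f)) at high
frequencies, where the cyclic tuning would otherwise alias into the
unimodal fit.  Midline sensitivity is the slope of a linear regression
of dR on ITD within +-100 us of zero (window configurable).

## JND procedure

Two-interval trials present the same tone at -dITD/2 and +dITD/2; a
trial is correct when dR of a random N-neuron subset is larger for the
negative (left-leading) interval.  Fractions correct over a log-spaced
dITD grid (2-800 us) are fitted with a Weibull (guess 0.5, lapse fixed
at 0) and the JND is the 75% point.  Protocol choices the procedure
leaves open: JND tones are 300 ms long (the typical duration of
lateralization stimuli; tuning-curve experiments use 100 ms); the
subset is redrawn every trial but shared between the two intervals of a
trial (one observer listens to both); and instead of re-simulating the
network for every trial, a bank of `n_realizations` independent
fresh-noise responses is simulated per grid point and interval, from
which trials sample — with 8 realizations the psychometric functions
are smooth and the cost stays linear in the grid size.  The trial logic
was validated against the closed-form Phi(d') observer on synthetic
Gaussian response banks.

Measured at the most sensitive frequency (~300 Hz) the 100-neuron
decoder reaches JNDs of a few microseconds, and the JND decreases
monotonically with N.  Because the dominant noise is independent across
neurons, the measured power law is close to 1/sqrt(N) (fitted exponent
about -0.4 to -0.55 depending on protocol details); a strict 1/N
dependence would require noise whose variance scales faster than 1/N
and does not emerge from this circuit (see the known-limitations note
below).  Two resolution limits of the scaled protocol are worth
knowing: with a bank of k realizations per interval, trial outcomes at
large N are driven by at most k^2 realization pairs, so JND estimates
floor once the subset-mean noise falls below the bank's resolution
(visible as JND(50) ~ JND(100) at a 150-neuron pool with k = 8); and
thresholds near the 2 us lower edge of the dITD grid are quantized by
the log spacing.  JND *shape* comparisons across frequency are
therefore made at subset sizes well below the pool (N <= ~pool/3) and
with 100 ms tones, which keep thresholds inside the well-resolved part
of the grid; under those conditions the normalized JND-vs-frequency
curves collapse across N (max deviation ~0.07) and the JND ranks track
the inverse midline sensitivity (Spearman rho ~0.9).

## MLP predictor

7-20-2 perceptron, tanh on hidden and output layers.  Inputs: current
and previous 30 ms bin rates of left MSO, right MSO and left ANF
(monaural side fixed to the left), plus cf.  Rates are z-scored with
training-set statistics; cf is log-mapped to [-1, 1] over 125-1000 Hz;
the ITD target is scaled to [-1, 1] over +-1 ms because the output is
tanh-bounded.  The corpus is 2,000 tones (300 ms + 60 ms quiet padding,
14 bins each) at full scale with level ~ U(30, 70) dB, frequency ~
U(125, 1000) Hz, ITD ~ U(-500, +500) us, simulated in the on-frequency
channel (cf = tone frequency) — the cf input generalizes across
channels and the reliability output learns silence from the padding
bins, which at inference gates off-band channels whose responses look
like silence.  The exists target is -1 for the two bins at each end of
a tone, +1 elsewhere; the reliability gate at inference is
signal_score > 0 (the midpoint of the +-1 targets; configurable).
Split 80/10/10 by tone; optimization is mini-batch Adam (batch 64,
lr 3e-3, seeded shuffling) with early stopping when the relative
improvement of the best validation MSE stays below 0.01% for 20
consecutive epochs (the patience length is a package choice); the
best-validation weights are kept.  Cross-frequency estimates average
the reliable channels per bin; bins with no reliable channel yield no
estimate.

At the reduced scale used by the test suite (280 tones, 200 neurons per
population) the held-out per-frame RMSE on reliable frames is
~85 us and chirp tracking MAE ~40 us; accuracy is limited by rate noise
in 30 ms bins and by the low-information 500-600 Hz region, so RMSE
improves with population size and corpus size.

## Numerical and degenerate-input choices

Bi-exponential synapses reject tau_i1 == tau_i2; impedance probes that
drive the cell within 5 mV of threshold are rejected; the Weibull fit
bounds beta to [0.2, 20]; ITD application requires |itd|/2 smaller than
the padding; ITD-rate fits need >= 5 points; tied dR comparisons in a
trial are resolved by a seeded coin flip.  All experiments derive every
stream (periphery noise, wiring, subsets, training shuffles) from one
master seed via seed sequences, so runs are bit-reproducible.

## Known limitations

- The periphery is a statistical surrogate; level effects enter only
  through its rate-level function, and binaural level cues are ignored
  by design.
- MSO neurons of one channel share a single best-ITD; heterogeneous
  best-ITD populations (and population decoders over them) are out of
  scope.
- The JND-vs-N exponent is ~ -0.5 (independent-noise scaling), not -1.
- The 500-600 Hz response minimum makes ITD information sparse there;
  the MLP's reliability gate does not flag such low-information (but
  signal-containing) frames, which dominates its residual error.
- No synaptic depression/facilitation, no spherical-bushy-cell stage,
  no azimuth mapping.
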