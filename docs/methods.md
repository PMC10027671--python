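# Methods

`porekinetics` models the single-channel electrical signature of a
monobody-based nanopore protein sensor: a membrane-embedded pore whose open
(analyte-released, `O_on`) current is interrupted by resistive pulses each
time a single protein analyte binds the tethered monobody (captured
substates `O_off`). The package covers the full analysis chain — forward
simulation of traces, idealization, dwell-time inference, concentration
series kinetics, quantification, and noise spectroscopy.

## Kinetic model

Gating is a continuous-time Markov chain on one released state and one or
two captured substates. Released → captured transitions are bimolecular:
their rate is `k_on * C` with `k_on` in M⁻¹s⁻¹ and `C` the analyte
concentration; captured → released transitions are unimolecular (`k_off`,
s⁻¹). Three topologies are built in:

- **bimolecular** — `O_on ⇌ O_off` (one capture mode; hSUMO1- and
  WDR5-class sensors, `k_on ~ 1e8 M⁻¹s⁻¹`, `k_off ~ 70 s⁻¹`);
- **two_mode** — two independent captured substates `O_off1`, `O_off2`
  (bimodal recognition; EGFR-class sensors, `k_off ~ 12` and `1 s⁻¹`);
- **interconversion** — `two_mode` plus direct transitions `k_12`, `k_21`
  between the captured substates.

Consequences used throughout: the released dwell is exponential with rate
`Σ k_on_i · C`, so the capture frequency `f = 1/τ_on` is proportional to
concentration (slope `k_on`); captured dwells of a class A follow the
phase-type (matrix-exponential) density
`f(t) = φ_A · exp(Q_AA t) · (−Q_AA) · 1`, with `Q_AA` the within-class
generator block and `φ_A` the stationary entry distribution, which reduces
to an entry-flux-weighted exponential mixture when `k_12 = k_21 = 0`.
`K_D = k_off / k_on` exactly; an unknown concentration follows from a
calibrated `k_on` via `C = 1/(τ_on · k_on)`.

## Synthetic traces

`simulate_path` is an exact Gillespie realization starting in the released
state (the sensor is reconstituted before analyte addition); the final dwell
is right-censored and excluded from statistics. `render_trace` emulates the
acquisition chain: per-state current levels (pA), additive white Gaussian
instrument noise, optional `1/f^α` flicker noise synthesized by inverse-FFT
spectral shaping with Gaussian spectral coefficients (amplitude = one-sided
PSD at 1 Hz, `α = 1` by default), and a digital 8-pole Bessel low-pass
(bilinear transform, −3 dB at the cutoff) at 3 kHz by default, sampled at
50 kHz. Defaults mirror the study conditions (open currents 18–40 pA at
+20/+40 mV, noise sd ~1 pA); the serum-like condition adds flicker noise at
0.1 pA²·Hz^(α−1), chosen so the 1/f term dominates the spectrum below a few
hundred Hz, as serum constituents do, while single-molecule events remain
resolvable.

What the generator does *not* emulate: baseline drift, brief nonspecific
spikes as a distinct event class (they can be approximated by a fast
low-amplitude capture mode and removed with the spike filter), open-pore
gating noise, and electrode artifacts. Passing closed-loop tests therefore
demonstrate estimator correctness under the stated noise model, not
robustness to every pathology of real recordings.

## Idealization

Events are found by half-amplitude threshold crossing: a capture opens when
the current falls below `I_0 − 0.5·(I_0 − deepest level)` and closes on
re-crossing. `I_0` and the baseline sd come from a Gaussian fit to the
dominant highest-current peak of the all-points histogram (histogram lightly
smoothed; peaks below 10% of the modal count are treated as tail
fluctuations). The default deadtime is the Bessel 10–90% rise time
`T_r = 0.3321/f_c` (≈111 µs at 3 kHz): shorter events are
amplitude-attenuated and unreliable, so they are merged into their
neighbours (shortest first, iteratively). Event mean currents exclude the
first `T_r` of samples to avoid filter-rise bias. Boundary events are
flagged censored and excluded from dwell statistics.

For bimodal sensors the captured-event blockade fractions `A/I_0` are fit
with a maximum-likelihood Gaussian mixture (10 EM restarts, fixed seed);
events get hard maximum-posterior mode labels (ties to the lower index),
and released events inherit the label of the following capture. Mode-
specific interevent durations `τ_on-i` are the released time summed between
successive mode-i captures — the waiting-time construction whose mean is
`1/(k_on-i · C)`, matching the per-mode association identity; a single
preceding released dwell would instead estimate the pooled rate.

## Dwell-time inference

Dwell samples are fit by maximum likelihood with the left-truncated
exponential mixture density

    f(t) = [Σ p_i/τ_i · e^(−t/τ_i)] / [Σ p_i · e^(−d/τ_i)],  t ≥ d,

where `d` is the deadtime. Truncation-only deadtime handling is adequate
here because all rates of interest (≤75 s⁻¹) are far below `1/d ≈ 9000 s⁻¹`
— the missed-event bias is <1%; a full missed-event correction is out of
scope. Optimization is multi-start quasi-Newton in unconstrained
coordinates (weight logits, log τ), initialized from a k-quantile split of
the log durations plus seeded random restarts; standard errors come from
the observed Fisher information (numerical Hessian) in the
`(p_1..p_{k−1}, τ)` parametrization. Components whose τ ratio falls below
1.5 trigger an over-specification warning but still return.

The number of components is selected by a log-likelihood-ratio ladder:
`k+1` replaces `k` iff `2·ΔlogL` strictly exceeds the χ² quantile at the
chosen confidence (0.95 default) with 2 degrees of freedom per added
component (one τ, one weight). The χ² reference is conservative at the
boundary (the true null is a mixture of χ² laws), which keeps the realized
false-acceptance rate below nominal — acceptable for a selection rule meant
to err toward parsimony. The `k+1` fit is warm-started from the `k`
solution with its widest component split, which enforces the nested
log-likelihood ordering in practice.

## Topology comparison (interconversion)

Whether the two captured substates interconvert directly is decided by an
LLR test between the nested `two_mode` (4 rates) and `interconversion`
(6 rates) fits, df = 2, strict inequality at the χ² 0.95 quantile.

A subtlety dictated the likelihood design: the *pooled* captured-duration
density of the interconversion scheme is a two-term phase-type law that, for
a wide range of rates (including symmetric `k_12 = k_21`), has positive
spectral coefficients and is then *exactly representable* by the independent
two-substate model with refitted rates; and because every interevent period
passes through the single released state, successive class dwells are
independent, so the class-duration sequence carries no additional
information. A comparison built on pooled durations alone therefore has
essentially zero power. The fit consequently uses the substate-resolved
sequence likelihood whenever the idealization resolves the two captured
levels: entry substate (weights `k_on_i/Σk_on`), per-substate dwell
hazards, observed substate hops, and exits. Under the independent topology
an apparent hop can still occur — a released sojourn shorter than the
deadtime is unresolvable and merges the flanking captures — so hops enter
the restricted model through a missed-gap channel with rate
`k_off_s · (1 − e^(−λ_rel·d)) · w_s'`, keeping its likelihood finite and the
LLR well behaved. With only pooled durations available (e.g. an event table
without substate resolution) the fitter falls back to the marginal
phase-type likelihood and says so in its docstring; its comparisons are then
valid but nearly powerless. Since the marginal density does not always
identify `k_12`, `k_21` uniquely, likelihood-equivalent optima are resolved
toward the most parsimonious point (smallest `k_12 + k_21`).

Rates are optimized as `log k_on`, `log k_off` and `√k_12`, `√k_21` (the
square allows the zero boundary); Nelder-Mead polishing into L-BFGS-B from
moment-based starts. Standard errors use the observed information on the
log scale, delta-method back; rates at the zero boundary report no SE.

## Concentration-series kinetics

`k_on` is the least-squares slope of `1/τ_on` versus `C` constrained
through the origin (the capture frequency is proportional to concentration
1:1 for a bimolecular association); an unconstrained fit is carried as a
lack-of-fit diagnostic, and its intercept should sit within ~3 SE of zero.
Fits are unweighted by default. `k_off` is the mean of `1/τ_off` across
concentrations with a slope-versus-C diagnostic for its assumed
concentration independence. `K_D = k_off/k_on` with first-order error
propagation, as is `C = 1/(τ_on·k_on)` for quantification. Unitary
conductance is `G = I/Δψ` (pA/mV = nS). Single-concentration series fall
back to `k_on = 1/(C·τ_on)` with a warning.

## Noise spectroscopy

`welch_psd` computes a one-sided Welch periodogram (Hann window, 50%
overlap, mean removed, density scaling so `∫S df` equals the variance).
The noise model `S(f) = S_w + A_f/f^α` is fit by least squares on log S
over log-spaced frequency bins (default band 5–1000 Hz, 12 bins/decade),
`α ∈ (0.05, 2]`. Classification is `flicker` when the `A_f/f^α` term
carries more than half the power at 10 Hz, else `white`; a fitted exponent
below 0.2 means the "flicker" term is spectrally flat — indistinguishable
from white noise — so it is folded into the white floor and the trace is
called white. A non-convergent fit returns `mixed` with a warning.

## Numerical choices and edge cases

- Internal units are SI (s, pA, mol/L); reporting converts to ms/nM where
  customary.
- Phase-type densities use the eigendecomposition of `Q_AA` (analytic
  spectral projectors for the 2×2 captured block; generic eigen route for
  degenerate spectra); a within-class block with condition number >1e12
  raises with diagnostics.
- Deterministic seeding throughout: the pipeline derives per-stage seeds
  from the experiment seed; identical configs reproduce reports bit-for-bit.
- Zero-concentration simulations yield a single censored released dwell,
  not an error; zero-rate interconversion schemes generate identically to
  `two_mode`.
- Histogram display uses log₁₀-spaced bins with a square-root ordinate so
  an exponential population appears as a single peak at `t = τ`.

## Problem sizes in the shipped tests

Closed-loop suites run at sizes chosen to keep Monte-Carlo error well below
the asserted tolerances while remaining quick on one core: the bimolecular
recovery uses three concentrations with ≥300 events each; LLR calibration
uses 200 replicates of 1000 dwells; topology comparison uses 100 replicates
per direction at ~20 nM with 250 s of simulated gating each; the dwell-PDF
cross-check uses 1e5 Gillespie dwells; the noise classifier is exercised on
100 rendered traces. Larger runs only tighten the same comparisons.

## Known limitations

- No missed-event rate correction beyond left truncation; biases appear
  once `k_off` approaches `1/deadtime`.
- Hidden-Markov idealization of raw samples (Baum-Welch) is out of scope;
  the half-amplitude detector needs peak separation of a few baseline sd.
- The event-table (amplitude-only) topology comparison is nearly powerless
  by construction, as discussed above.
- The amplitude-mixture mode labels are hard assignments; posterior
  uncertainty does not propagate into per-mode dwell fits.
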