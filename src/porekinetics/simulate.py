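"""Continuous-time Markov simulation and rendering of single-channel traces.

``simulate_path`` produces an exact Gillespie realization of a gating scheme;
``render_trace`` turns the state path into a sampled current trace with white
Gaussian instrument noise, optional 1/f^alpha flicker noise (spectral
shaping), and digital 8-pole Bessel low-pass filtering, mimicking a
patch-clamp acquisition chain (50 kHz sampling, 3 kHz filter by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal

from .exceptions import ConfigurationError, ValidationError
from .schemes import KineticScheme, RELEASED

#: 10-90% step-response rise time of a Bessel low-pass, as a fraction of
#: 1/f_c (f_c the -3 dB cutoff).  Events shorter than this are attenuated.
BESSEL_RISETIME_FACTOR = 0.3321


def bessel_rise_time(filter_cutoff: float) -> float:
    """10-90% rise time (s) of the Bessel filter at the given cutoff (Hz)."""
    if filter_cutoff <= 0:
        return 0.0
    return BESSEL_RISETIME_FACTOR / filter_cutoff


@dataclass
class StatePath:
    """A Gillespie realization: sequence of states and dwell durations.

    The last dwell is right-censored at ``total_duration`` and flagged via
    ``censored_last``; it is excluded from dwell statistics by default.
    """

    states: np.ndarray          # int state indices into the scheme
    dwells: np.ndarray          # dwell durations, s
    total_duration: float
    seed: int | None = None
    censored_last: bool = True

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=int)
        self.dwells = np.asarray(self.dwells, dtype=float)
        if np.any(self.dwells <= 0):
            raise ValidationError("dwell durations must be > 0")
        if len(self.states) != len(self.dwells):
            raise ValidationError("states and dwells must have equal length")

    def state_dwells(self, state_index: int, include_censored: bool = False) -> np.ndarray:
        """Dwell durations spent in one microscopic state."""
        d = self.dwells if include_censored else self.dwells[: len(self.dwells) - int(self.censored_last)]
        s = self.states[: len(d)]
        return d[s == state_index]

    def class_segments(self, scheme: KineticScheme) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Aggregate consecutive same-class dwells.

        Returns ``(cls_codes, durations, censored)`` where ``cls_codes`` is 0
        for released and 1 for captured and ``censored`` flags the final
        (right-censored) segment.
        """
        codes = np.array([0 if scheme.class_of(s) == RELEASED else 1 for s in self.states])
        change = np.flatnonzero(np.diff(codes)) + 1
        bounds = np.concatenate(([0], change, [len(codes)]))
        seg_codes = codes[bounds[:-1]]
        seg_dur = np.add.reduceat(self.dwells, bounds[:-1])
        censored = np.zeros(len(seg_codes), dtype=bool)
        if self.censored_last and len(censored):
            censored[-1] = True
        return seg_codes, seg_dur, censored

    def class_dwells(self, scheme: KineticScheme, cls: str) -> np.ndarray:
        """Completed (non-censored) dwell durations of one observable class."""
        codes, dur, cens = self.class_segments(scheme)
        want = 0 if cls == RELEASED else 1
        return dur[(codes == want) & ~cens]


def simulate_path(
    scheme: KineticScheme,
    concentration: float,
    duration: float,
    seed: int | np.random.Generator | None = None,
    start_state: int | None = None,
) -> StatePath:
    """Exact stochastic simulation of the gating chain.

    The chain starts in the released state (the sensor is reconstituted
    before analyte capture).  Each dwell is exponential with rate equal to
    the total outgoing rate of the current state; the successor is drawn with
    probability proportional to its rate.  The final dwell is truncated at
    ``duration`` and flagged censored.
    """
    if duration <= 0:
        raise ValidationError("duration must be > 0")
    q = scheme.generator(concentration)
    if not np.all(np.isfinite(q)):
        raise ValidationError("non-finite rate in generator")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_label = seed if isinstance(seed, (int, np.integer)) else None

    out_rates = q.copy()
    np.fill_diagonal(out_rates, 0.0)
    totals = out_rates.sum(axis=1)

    state = scheme.released_index if start_state is None else start_state
    t = 0.0
    states: list[int] = []
    dwells: list[float] = []
    while t < duration:
        lam = totals[state]
        if lam <= 0.0:
            # absorbing under these conditions (e.g. zero concentration)
            states.append(state)
            dwells.append(duration - t)
            t = duration
            break
        dt = rng.exponential(1.0 / lam)
        if t + dt >= duration:
            states.append(state)
            dwells.append(duration - t)
            t = duration
            break
        states.append(state)
        dwells.append(dt)
        t += dt
        state = rng.choice(len(totals), p=out_rates[state] / lam)
    return StatePath(
        states=np.array(states), dwells=np.array(dwells),
        total_duration=duration, seed=seed_label, censored_last=True,
    )


def sample_class_dwells(
    scheme: KineticScheme,
    concentration: float,
    cls: str,
    n: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw ``n`` independent observable-class dwell durations by simulation.

    Each dwell starts from the stationary entry distribution into the class
    and runs the embedded chain until the class is left.  Vectorized over
    dwells, so 1e5 draws are cheap; used as a brute-force Monte-Carlo oracle
    for the matrix-exponential dwell PDFs.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q = scheme.generator(concentration)
    inside = np.array(
        [i for i in range(len(scheme.states)) if scheme.class_of(i) == cls], dtype=int
    )
    phi = class_entry_distribution(scheme, concentration, cls)
    out_rates = q.copy()
    np.fill_diagonal(out_rates, 0.0)
    totals = out_rates.sum(axis=1)
    probs = np.where(totals[:, None] > 0, out_rates / np.maximum(totals, 1e-300)[:, None], 0.0)

    state = rng.choice(inside, size=n, p=phi)
    dur = np.zeros(n)
    active = np.ones(n, dtype=bool)
    while active.any():
        s = state[active]
        lam = totals[s]
        if np.any(lam <= 0):
            raise ValidationError("class is absorbing; dwell duration infinite")
        dur[active] += rng.exponential(1.0, size=s.size) / lam
        # draw successors via inverse-CDF on the per-state transition rows
        u = rng.random(s.size)
        cdf = np.cumsum(probs[s], axis=1)
        nxt = (u[:, None] < cdf).argmax(axis=1)
        state[active] = nxt
        still = np.isin(nxt, inside)
        idx = np.flatnonzero(active)
        active[idx[~still]] = False
    return dur


def class_entry_distribution(scheme: KineticScheme, concentration: float, cls: str) -> np.ndarray:
    """Stationary entry distribution into the states of one class.

    phi_j is proportional to the stationary probability flux from outside
    the class into state j (Colquhoun-Hawkes entry vector).
    """
    q = scheme.generator(concentration)
    n = q.shape[0]
    inside = [i for i in range(n) if scheme.class_of(i) == cls]
    outside = [i for i in range(n) if i not in inside]
    if not inside:
        raise ValidationError(f"scheme has no {cls!r} states")
    pi = stationary_distribution(q)
    flux = pi[outside] @ q[np.ix_(outside, inside)]
    total = flux.sum()
    if total <= 0:
        raise ValidationError(f"no stationary flux into class {cls!r}")
    return flux / total


def stationary_distribution(q: np.ndarray) -> np.ndarray:
    """Stationary distribution of a generator matrix (pi Q = 0, sum pi = 1)."""
    n = q.shape[0]
    a = np.vstack([q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


@dataclass
class TraceConfig:
    """Acquisition settings for rendering a trace.

    Defaults follow the recording chain used throughout: 50 kHz sampling and
    a digital 8-pole Bessel low-pass at 3 kHz.  ``flicker_amplitude`` is the
    one-sided flicker PSD at 1 Hz in pA^2 Hz^(alpha-1); 0 disables it.
    """

    duration: float = 10.0
    sampling_rate: float = 50_000.0
    filter_cutoff: float | None = 3_000.0
    filter_poles: int = 8
    noise_sigma: float = 1.0
    flicker_amplitude: float = 0.0
    flicker_alpha: float = 1.0
    delta_psi: float = 40.0
    concentration: float = 0.0
    seed: int | None = None

    def validate(self):
        if self.duration <= 0:
            raise ValidationError("duration must be > 0")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be > 0")
        if self.filter_cutoff is not None and self.filter_cutoff > 0:
            if self.sampling_rate <= 2 * self.filter_cutoff:
                raise ConfigurationError(
                    f"sampling_rate ({self.sampling_rate} Hz) must exceed twice "
                    f"the filter cutoff ({self.filter_cutoff} Hz)"
                )
        for name in ("noise_sigma", "flicker_amplitude", "flicker_alpha"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass
class Trace:
    """A uniformly sampled current trace in pA."""

    samples: np.ndarray
    dt: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("trace contains non-finite samples")

    @property
    def sampling_rate(self) -> float:
        return 1.0 / self.dt

    @property
    def duration(self) -> float:
        return len(self.samples) * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) * self.dt


def bessel_sos(filter_cutoff: float, sampling_rate: float, poles: int = 8) -> np.ndarray:
    """Digital 8-pole Bessel low-pass (bilinear transform, -3 dB at cutoff)."""
    return signal.bessel(
        poles, filter_cutoff, btype="low", fs=sampling_rate, norm="mag", output="sos"
    )


def synthesize_flicker(
    n: int, dt: float, amplitude: float, alpha: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian 1/f^alpha noise with one-sided PSD amplitude/f^alpha.

    Synthesized by inverse-FFT spectral shaping with independent Gaussian
    real/imaginary spectral components (random phases); the DC bin is zeroed.
    """
    if amplitude == 0 or n == 0:
        return np.zeros(n)
    fs = 1.0 / dt
    f = np.fft.rfftfreq(n, d=dt)
    target = np.zeros_like(f)
    target[1:] = amplitude / f[1:] ** alpha
    scale = np.sqrt(target * fs * n / 2.0)
    spec = scale * (rng.standard_normal(len(f)) + 1j * rng.standard_normal(len(f))) / math.sqrt(2)
    spec[0] = 0.0
    if n % 2 == 0:
        spec[-1] = spec[-1].real * math.sqrt(2)
    return np.fft.irfft(spec, n=n)


def render_trace(path: StatePath, scheme: KineticScheme, config: TraceConfig) -> Trace:
    """Render a state path into a sampled, noisy, filtered current trace.

    The piecewise-constant level signal (per-state current levels) gets white
    Gaussian noise of sd ``noise_sigma``, optional 1/f^alpha flicker noise,
    and an 8-pole digital Bessel low-pass at ``filter_cutoff``; sampling is
    deterministic under a fixed ``config.seed``.
    """
    config.validate()
    fs = config.sampling_rate
    if path.total_duration < 1.0 / fs:
        raise ValidationError("path shorter than one sampling interval")
    n = int(round(path.total_duration * fs))
    # sample index boundaries of each dwell
    edges = np.concatenate(([0.0], np.cumsum(path.dwells)))
    idx = np.minimum(np.round(edges * fs).astype(int), n)
    counts = np.diff(idx)
    levels = scheme.levels[path.states]
    x = np.repeat(levels, counts)
    if len(x) < n:  # rounding shortfall: hold the last level
        x = np.concatenate([x, np.full(n - len(x), levels[-1] if len(levels) else 0.0)])
    x = x[:n].astype(float)

    rng = np.random.default_rng(config.seed)
    if config.noise_sigma > 0:
        x = x + rng.normal(0.0, config.noise_sigma, n)
    if config.flicker_amplitude > 0:
        x = x + synthesize_flicker(n, 1.0 / fs, config.flicker_amplitude, config.flicker_alpha, rng)
    if config.filter_cutoff is not None and config.filter_cutoff > 0:
        sos = bessel_sos(config.filter_cutoff, fs, config.filter_poles)
        # prime the filter state with the initial level to avoid a start-up step
        zi = signal.sosfilt_zi(sos) * x[0]
        x, _ = signal.sosfilt(sos, x, zi=zi)

    meta = asdict(config)
    meta.update(path_seed=path.seed, scheme_states=scheme.names,
                scheme_levels=list(scheme.levels))
    return Trace(samples=x, dt=1.0 / fs, metadata=meta)
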