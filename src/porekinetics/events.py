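"""Trace idealization: baseline estimation, event search, blockade amplitudes.

A trace is idealized into alternating released/captured events by
half-amplitude threshold crossing (the standard single-channel event
search).  Captured events are characterized by their normalized blockade
A/I_0; for bimodal sensors a two-component Gaussian mixture over A/I_0
separates the shallow/short (mode 1) and deep/long (mode 2) capture
families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.mixture import GaussianMixture

from .exceptions import EstimationError, FittingError, UsageError, ValidationError
from .simulate import Trace, bessel_rise_time
from .dwell import DwellSample

RELEASED = "released"
CAPTURED = "captured"

EVENT_COLUMNS = [
    "start_s", "duration_s", "cls", "mean_current_pA",
    "blockade_fraction", "mode", "censored",
]


@dataclass
class BaselineModel:
    """Open-substate current I_0 and baseline noise sd, both in pA."""

    i0: float
    sigma: float

    def __post_init__(self):
        if self.i0 <= 0:
            raise ValidationError("baseline i0 must be > 0")
        if self.sigma <= 0:
            raise ValidationError("baseline sigma must be > 0")


@dataclass
class EventTable:
    """Ordered alternating released/captured events from one trace.

    ``df`` columns: start_s, duration_s, cls, mean_current_pA,
    blockade_fraction, mode (0 = unassigned), censored.  The first and last
    events touch the trace boundaries and are censored; dwell statistics
    exclude them.
    """

    df: pd.DataFrame
    deadtime: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        cls = self.df["cls"].to_numpy()
        if len(cls) > 1 and np.any(cls[1:] == cls[:-1]):
            raise ValidationError("event classes must alternate")

    def captured(self) -> pd.DataFrame:
        return self.df[self.df["cls"] == CAPTURED]

    def released(self) -> pd.DataFrame:
        return self.df[self.df["cls"] == RELEASED]

    def dwell_sample(self, cls: str, mode: int | None = None) -> DwellSample:
        """Completed dwell durations of one class (optionally one mode)."""
        sel = self.df[(self.df["cls"] == cls) & ~self.df["censored"]]
        if mode is not None:
            sel = sel[sel["mode"] == mode]
        return DwellSample(
            durations=sel["duration_s"].to_numpy(copy=True),
            deadtime=self.deadtime, cls=cls, mode=mode,
        )

    def drop_spikes(self, cutoff: float) -> "EventTable":
        """Remove brief nonspecific captured events (< ``cutoff`` s).

        Biofluid traces show millisecond-range current spikes from serum
        constituents on top of ~1 s specific captures; dropping them merges
        the flanking released events.
        """
        df = self.df
        spike = (df["cls"] == CAPTURED) & (df["duration_s"] < cutoff) & ~df["censored"]
        keep = _merge_after_removal(df, spike.to_numpy())
        return EventTable(df=keep, deadtime=self.deadtime,
                         metadata={**self.metadata, "spike_cutoff": cutoff})


def _merge_after_removal(df: pd.DataFrame, remove: np.ndarray) -> pd.DataFrame:
    """Drop flagged events, absorbing their time into the flanking events."""
    rows = df.to_dict("records")
    out: list[dict] = []
    for i, row in enumerate(rows):
        if remove[i]:
            if out:
                out[-1]["duration_s"] += row["duration_s"]
            elif i + 1 < len(rows):
                rows[i + 1]["start_s"] = row["start_s"]
                rows[i + 1]["duration_s"] += row["duration_s"]
            continue
        if out and out[-1]["cls"] == row["cls"]:
            out[-1]["duration_s"] += row["duration_s"]
            out[-1]["censored"] = out[-1]["censored"] or row["censored"]
        else:
            out.append(dict(row))
    return pd.DataFrame(out, columns=df.columns)


def estimate_baseline(trace: Trace, bins: int = 400) -> BaselineModel:
    """Estimate I_0 and baseline sd from the all-points histogram.

    I_0 is the mean of the dominant highest-current Gaussian peak (the open
    O_on substate); sigma is its fitted sd.
    """
    x = trace.samples
    if len(x) < 1000:
        raise EstimationError("need at least 1000 samples to estimate a baseline")
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo <= 0:
        # degenerate noiseless constant trace: exact level, sd at the bin floor
        if x[0] <= 0:
            raise EstimationError("flat trace at non-positive current")
        return BaselineModel(i0=float(x[0]), sigma=max(abs(x[0]) * 1e-9, 1e-12))
    counts, edges = np.histogram(x, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    binw = edges[1] - edges[0]
    # candidate peaks on a lightly smoothed histogram; the height floor keeps
    # Poisson bumps in the tails from masquerading as substate peaks
    from scipy.signal import find_peaks

    smooth = np.convolve(counts, np.ones(5) / 5.0, mode="same")
    pk, _ = find_peaks(smooth, height=0.1 * smooth.max(),
                       prominence=0.05 * smooth.max(), distance=5)
    if len(pk) == 0:
        pk = np.array([int(np.argmax(smooth))])
    peak = pk[np.argmax(centers[pk])]  # highest-current peak
    mu0 = centers[peak]
    # local Gaussian fit around the peak
    sig0 = max(np.std(x[np.abs(x - mu0) < 10 * binw]), binw)
    window = np.abs(centers - mu0) < 4 * sig0
    if window.sum() < 5:
        window = np.abs(centers - mu0) < 10 * binw
    try:
        popt, _ = optimize.curve_fit(
            lambda c, a, mu, s: a * np.exp(-0.5 * ((c - mu) / s) ** 2),
            centers[window], counts[window],
            p0=(counts[peak], mu0, sig0), maxfev=5000,
        )
        mu, sig = float(popt[1]), float(abs(popt[2]))
    except RuntimeError as err:
        raise EstimationError(f"baseline peak fit did not converge: {err}") from None
    if not np.isfinite(mu) or mu <= 0:
        raise EstimationError("no resolvable open-substate peak")
    # refine with a symmetric sample clip (histogram-bias free)
    sel = np.abs(x - mu) < 3.0 * sig
    if sel.sum() > 100:
        mu = float(np.mean(x[sel]))
    return BaselineModel(i0=mu, sigma=max(sig, 1e-12))


def detect_events(
    trace: Trace,
    baseline: BaselineModel,
    threshold_fraction: float = 0.5,
    deadtime: float | None = None,
    deepest_level: float = 0.0,
    spike_cutoff: float | None = None,
) -> EventTable:
    """Idealize a trace by half-amplitude threshold crossing.

    A captured event opens when the current falls below
    ``i0 - threshold_fraction * (i0 - deepest_level)`` (default: half of the
    open-to-deepest-blockade span, i.e. I_0/2) and closes on re-crossing.
    Events shorter than ``deadtime`` (default: the Bessel filter rise time)
    are discarded with their time merged into the flanking events.  Mean
    currents exclude the filter-rise samples at the event start.
    """
    if not 0 < threshold_fraction < 1:
        raise ValidationError("threshold_fraction must be in (0, 1)")
    dt = trace.dt
    cutoff = trace.metadata.get("filter_cutoff") or 0.0
    if deadtime is None:
        deadtime = bessel_rise_time(cutoff) if cutoff else 2 * dt
    if deadtime < dt:
        raise ValidationError("deadtime must be at least one sampling interval")

    thr = baseline.i0 - threshold_fraction * (baseline.i0 - deepest_level)
    if baseline.sigma >= baseline.i0 - thr:
        warnings.warn(
            "baseline noise comparable to the level separation; "
            "idealization is low-confidence", stacklevel=2,
        )
    below = trace.samples < thr
    change = np.flatnonzero(np.diff(below)) + 1
    bounds = np.concatenate(([0], change, [len(below)]))
    starts, ends = bounds[:-1], bounds[1:]
    classes = np.where(below[starts], CAPTURED, RELEASED)
    durations = (ends - starts) * dt

    # deadtime rule: iteratively merge the shortest interior short event
    segs = [
        {"i0": int(a), "i1": int(b), "cls": c}
        for a, b, c in zip(starts, ends, classes)
    ]
    def _dur(seg):
        return (seg["i1"] - seg["i0"]) * dt

    while True:
        interior = [k for k in range(1, len(segs) - 1) if _dur(segs[k]) < deadtime]
        if not interior:
            break
        k = min(interior, key=lambda j: _dur(segs[j]))
        # absorb into neighbours and merge them (they share a class)
        prev, nxt = segs[k - 1], segs[k + 1]
        prev["i1"] = nxt["i1"]
        del segs[k:k + 2]

    rise_skip = int(np.ceil(bessel_rise_time(cutoff) / dt)) if cutoff else 0
    rows = []
    x = trace.samples
    for k, seg in enumerate(segs):
        a, b = seg["i0"], seg["i1"]
        core = x[a + rise_skip:b] if (b - a) > 2 * rise_skip else x[(a + b) // 2:(a + b) // 2 + 1]
        mean_i = float(np.mean(core))
        cls = seg["cls"]
        if cls == CAPTURED:
            bf = normalized_blockade(baseline.i0, mean_i)
        else:
            bf = np.nan
        rows.append(dict(
            start_s=a * dt, duration_s=(b - a) * dt, cls=cls,
            mean_current_pA=mean_i, blockade_fraction=bf, mode=0,
            censored=(k == 0 or k == len(segs) - 1),
        ))
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    table = EventTable(df=df, deadtime=deadtime,
                      metadata={**trace.metadata, "threshold_pA": thr,
                                "i0_pA": baseline.i0, "baseline_sigma_pA": baseline.sigma})
    if spike_cutoff:
        table = table.drop_spikes(spike_cutoff)
    return table


def normalized_blockade(i0: float, i_off: float) -> float:
    """Normalized blockade amplitude A/I_0 = (I_0 - I_off)/I_0.

    Negative values (enhanced-current events) are allowed but flagged with a
    warning.
    """
    if i0 <= 0:
        raise ValidationError("i0 must be > 0")
    value = (i0 - i_off) / i0
    if value < 0:
        warnings.warn("enhanced-current event: i_off exceeds i0", stacklevel=2)
    return value


@dataclass
class AmplitudeMixture:
    """Gaussian mixture over blockade fractions A/I_0.

    ``peaks`` holds (mean, sd, weight) sorted by ascending mean; weights are
    the mode probabilities.
    """

    peaks: list[tuple[float, float, float]]
    logL: float
    N: int

    def __post_init__(self):
        w = np.array([p[2] for p in self.peaks])
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-6:
            raise ValidationError("mixture weights must be >= 0 and sum to 1")

    @property
    def k(self) -> int:
        return len(self.peaks)

    def posterior(self, blockade: np.ndarray) -> np.ndarray:
        """Component posteriors, shape (n, k)."""
        b = np.atleast_1d(np.asarray(blockade, dtype=float))[:, None]
        mu = np.array([p[0] for p in self.peaks])
        sd = np.array([p[1] for p in self.peaks])
        w = np.array([p[2] for p in self.peaks])
        logp = (
            np.log(w) - 0.5 * np.log(2 * np.pi) - np.log(sd)
            - 0.5 * ((b - mu) / sd) ** 2
        )
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p / p.sum(axis=1, keepdims=True)


def fit_amplitude_mixture(events: EventTable, k: int, seed: int = 0) -> AmplitudeMixture:
    """ML Gaussian mixture over captured-event blockade fractions."""
    bf = events.captured()["blockade_fraction"].to_numpy()
    bf = bf[np.isfinite(bf)]
    if len(bf) < 10 * k:
        raise UsageError(f"need >= {10 * k} captured events for a {k}-component mixture")
    gm = GaussianMixture(
        n_components=k, covariance_type="full", n_init=10,
        random_state=seed, reg_covar=1e-8,
    ).fit(bf[:, None])
    if not gm.converged_:
        raise FittingError(
            f"amplitude mixture EM did not converge "
            f"(lower bound {gm.lower_bound_:.4g}, {gm.n_iter_} iterations)"
        )
    order = np.argsort(gm.means_.ravel())
    peaks = [
        (float(gm.means_.ravel()[j]), float(np.sqrt(gm.covariances_.ravel()[j])),
         float(gm.weights_[j]))
        for j in order
    ]
    w = np.array([p[2] for p in peaks])
    peaks = [(m, s, float(wi / w.sum())) for (m, s, _), wi in zip(peaks, w)]
    return AmplitudeMixture(peaks=peaks, logL=float(gm.score(bf[:, None]) * len(bf)), N=len(bf))


def assign_modes(events: EventTable, mixture: AmplitudeMixture) -> EventTable:
    """Label captured events by maximum-posterior mixture component.

    Mode 1 is the shallow (lowest-amplitude) family.  Ties go to the lower
    index.  Released events inherit the mode of the *following* capture so
    that per-mode released-duration bookkeeping is well defined.
    """
    if mixture.k < 2:
        raise UsageError("mode assignment needs a mixture with >= 2 peaks")
    df = events.df.copy()
    cap = df["cls"] == CAPTURED
    bf = df.loc[cap, "blockade_fraction"].to_numpy()
    post = mixture.posterior(bf)
    df.loc[cap, "mode"] = np.argmax(post, axis=1) + 1
    # released events take the mode of the next capture (backward fill)
    mode = df["mode"].to_numpy(dtype=float)
    mode[~cap.to_numpy()] = np.nan
    filled = pd.Series(mode).bfill().fillna(0).to_numpy()
    df["mode"] = filled.astype(int)
    return EventTable(df=df, deadtime=events.deadtime, metadata=dict(events.metadata))
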