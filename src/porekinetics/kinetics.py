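"""Concentration-series kinetics: k_on, k_off, K_D, and quantification.

The capture frequency f = 1/tau_on is proportional to the analyte
concentration for a bimolecular association, so k_on is the through-origin
slope of 1/tau_on versus C (k_on = 1/(tau_on [C]) at a single
concentration).  The dissociation rate k_off = 1/tau_off is concentration
independent.  K_D = k_off / k_on.  Inverting the calibration,
C = 1/(tau_on k_on) quantifies an unknown analyte concentration from the
observed interevent duration — e.g. a serum biomarker level from the
long-lived capture mode of a bimodal sensor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import UsageError, ValidationError

CAPTURED = "captured"
RELEASED = "released"


@dataclass
class ConcentrationSeries:
    """Per-concentration dwell summaries for one capture mode (or pooled).

    Arrays are aligned: concentration (M), tau_on/tau_off (s) with standard
    errors, and the number of events behind each entry.
    """

    concentrations: np.ndarray
    tau_on: np.ndarray
    tau_off: np.ndarray
    tau_on_se: np.ndarray | None = None
    tau_off_se: np.ndarray | None = None
    n_events: np.ndarray | None = None
    mode: int | None = None

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.tau_on = np.asarray(self.tau_on, dtype=float)
        self.tau_off = np.asarray(self.tau_off, dtype=float)
        if np.any(self.concentrations <= 0):
            raise ValidationError("all concentrations must be > 0")
        if not len(self.concentrations) == len(self.tau_on) == len(self.tau_off):
            raise ValidationError("series arrays must be aligned")

    def __len__(self):
        return len(self.concentrations)


@dataclass
class RateEstimate:
    """A rate constant with its standard error and fit diagnostics."""

    value: float
    se: float
    diagnostics: dict = field(default_factory=dict)

    def __iter__(self):  # allow tuple unpacking (value, se)
        return iter((self.value, self.se))


def fit_kon(series: ConcentrationSeries) -> RateEstimate:
    """Association rate constant from the event-frequency slope.

    Least-squares slope of f = 1/tau_on versus C constrained through the
    origin (the capture frequency is proportional to concentration 1:1).
    An unconstrained linear fit is reported in ``diagnostics`` as a
    lack-of-fit check.  A single-concentration series falls back to
    k_on = 1/(C tau_on) with a warning.
    """
    c = series.concentrations
    y = 1.0 / series.tau_on
    if len(c) == 1:
        warnings.warn("single concentration: k_on from 1/(C tau_on), no slope fit",
                      stacklevel=2)
        k = float(y[0] / c[0])
        se = float(k * series.tau_on_se[0] / series.tau_on[0]) if series.tau_on_se is not None else np.nan
        return RateEstimate(value=k, se=se, diagnostics={"method": "single_point"})
    slope = float(np.sum(c * y) / np.sum(c * c))
    resid = y - slope * c
    se = float(np.sqrt(np.sum(resid ** 2) / (len(c) - 1) / np.sum(c * c)))
    lr = stats.linregress(c, y)
    return RateEstimate(
        value=slope, se=se,
        diagnostics={
            "method": "through_origin",
            "free_slope": float(lr.slope), "free_slope_se": float(lr.stderr),
            "free_intercept": float(lr.intercept),
            "free_intercept_se": float(lr.intercept_stderr),
        },
    )


def fit_koff(series: ConcentrationSeries) -> RateEstimate:
    """Dissociation rate constant as the mean of 1/tau_off across entries.

    The standard error comes from the scatter across concentrations; a
    linear slope versus C is reported as a concentration-independence
    diagnostic.
    """
    y = 1.0 / series.tau_off
    k = float(np.mean(y))
    if len(y) > 1:
        se = float(np.std(y, ddof=1) / np.sqrt(len(y)))
        lr = stats.linregress(series.concentrations, y)
        diag = {"slope_vs_C": float(lr.slope), "slope_vs_C_se": float(lr.stderr),
                "slope_vs_C_p": float(lr.pvalue)}
    else:
        se = 0.0
        if series.tau_off_se is not None:
            se = float(k * series.tau_off_se[0] / series.tau_off[0])
        diag = {}
    return RateEstimate(value=k, se=se, diagnostics=diag)


def compute_kd(k_on, k_off, k_on_se: float = 0.0, k_off_se: float = 0.0) -> RateEstimate:
    """Equilibrium dissociation constant K_D = k_off / k_on (M).

    Accepts plain numbers or (value, se) pairs / RateEstimates; the standard
    error is propagated to first order.
    """
    if isinstance(k_on, (tuple, RateEstimate)):
        k_on, k_on_se = tuple(k_on)
    if isinstance(k_off, (tuple, RateEstimate)):
        k_off, k_off_se = tuple(k_off)
    if k_on <= 0:
        raise ValidationError("k_on must be > 0")
    kd = k_off / k_on
    rel = 0.0
    if k_off > 0:
        rel = (k_off_se / k_off) ** 2
    rel += (k_on_se / k_on) ** 2 if k_on_se else 0.0
    return RateEstimate(value=float(kd), se=float(kd * np.sqrt(rel)))


def mode_probabilities(events) -> dict[int, RateEstimate]:
    """Fraction of captured events in each mode, with binomial SEs."""
    cap = events.captured()
    cap = cap[~cap["censored"]]
    modes = cap["mode"].to_numpy()
    if len(modes) == 0:
        raise UsageError("no captured events")
    if np.all(modes == 0):
        raise UsageError("mode labels not assigned; run assign_modes first")
    n = len(modes)
    out = {}
    for m in sorted(set(modes)):
        p = float(np.mean(modes == m))
        out[int(m)] = RateEstimate(value=p, se=float(np.sqrt(p * (1 - p) / n)))
    return out


def mode_interevent_durations(events, mode: int) -> np.ndarray:
    """Interevent (released) durations specific to one capture mode.

    The mode-specific tau_on is the released time accumulated between
    successive captures of that mode, i.e. the waiting time for the next
    mode-``mode`` capture; its mean is 1/(k_on_mode * C).  Released dwells
    spent while other-mode captures intervene are included in the sum.
    """
    df = events.df
    waits: list[float] = []
    acc = 0.0
    armed = False  # only count waits that started at an observed capture
    for _, row in df.iterrows():
        if row["cls"] == RELEASED:
            if not row["censored"]:
                acc += row["duration_s"]
            else:
                armed = False
                acc = 0.0
        else:
            if row["censored"]:
                armed = False
                acc = 0.0
                continue
            if int(row["mode"]) == mode:
                if armed and acc > 0:
                    waits.append(acc)
                acc = 0.0
                armed = True
    return np.asarray(waits, dtype=float)


@dataclass
class QuantificationResult:
    """An analyte concentration inferred from calibrated kinetics."""

    concentration: float       # M
    se: float                  # M
    tau_on: float              # observed interevent duration, s
    k_on: float                # calibration association rate, M^-1 s^-1

    @property
    def concentration_nM(self) -> float:
        return self.concentration * 1e9

    @property
    def se_nM(self) -> float:
        return self.se * 1e9


def estimate_concentration(tau_on: float, k_on: float, tau_on_se: float = 0.0,
                           k_on_se: float = 0.0) -> QuantificationResult:
    """Analyte concentration from C = 1/(tau_on * k_on).

    For bimodal sensors ``tau_on`` must be the mode-specific interevent
    duration and ``k_on`` the matching calibrated association rate.
    """
    if tau_on <= 0 or k_on <= 0:
        raise ValidationError("tau_on and k_on must be > 0")
    c = 1.0 / (tau_on * k_on)
    rel = (tau_on_se / tau_on) ** 2 + (k_on_se / k_on) ** 2
    return QuantificationResult(concentration=float(c), se=float(c * np.sqrt(rel)),
                                tau_on=float(tau_on), k_on=float(k_on))


def conductance(i_pa: float, delta_psi_mv: float) -> float:
    """Unitary conductance G = I / delta_psi in nS (pA / mV == nS)."""
    if delta_psi_mv == 0:
        raise ValidationError("applied potential must be nonzero")
    return i_pa / delta_psi_mv


@dataclass
class KineticsSummary:
    """Per-mode kinetic constants of one sensor/analyte pair.

    ``k_on`` in M^-1 s^-1, ``k_off`` in s^-1, ``K_D`` in M, keyed by mode
    index (0 = single-mode/pooled).  ``P`` holds mode probabilities and
    ``frequency`` the per-entry event frequencies f = 1/tau_on (s^-1).
    """

    k_on: dict[int, RateEstimate]
    k_off: dict[int, RateEstimate]
    K_D: dict[int, RateEstimate]
    P: dict[int, RateEstimate] = field(default_factory=dict)
    frequency: dict[int, np.ndarray] = field(default_factory=dict)
    series: dict[int, ConcentrationSeries] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def _re(est):
            return {"value": est.value, "se": est.se}
        return {
            "k_on_per_M_s": {m: _re(v) for m, v in self.k_on.items()},
            "k_off_per_s": {m: _re(v) for m, v in self.k_off.items()},
            "K_D_M": {m: _re(v) for m, v in self.K_D.items()},
            "mode_probability": {m: _re(v) for m, v in self.P.items()},
        }

    def summary(self) -> str:
        lines = ["Kinetic constants (per capture mode; 0 = pooled/single)"]
        for m in sorted(self.k_on):
            kd = self.K_D[m]
            lines.append(
                f"  mode {m}: k_on = {self.k_on[m].value:.3g} "
                f"+/- {self.k_on[m].se:.2g} M^-1 s^-1, "
                f"k_off = {self.k_off[m].value:.3g} +/- {self.k_off[m].se:.2g} s^-1, "
                f"K_D = {kd.value * 1e9:.3g} +/- {kd.se * 1e9:.2g} nM"
            )
        for m, p in self.P.items():
            lines.append(f"  P_{m} = {p.value:.3f} +/- {p.se:.3f}")
        return "\n".join(lines)


def summarize_kinetics(series_by_mode: dict[int, ConcentrationSeries],
                       mode_p: dict[int, RateEstimate] | None = None) -> KineticsSummary:
    """Fit k_on/k_off/K_D for each mode's concentration series."""
    k_on, k_off, kd, freq = {}, {}, {}, {}
    for m, s in series_by_mode.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            k_on[m] = fit_kon(s)
        k_off[m] = fit_koff(s)
        kd[m] = compute_kd(k_on[m], k_off[m])
        freq[m] = 1.0 / s.tau_on
    return KineticsSummary(k_on=k_on, k_off=k_off, K_D=kd,
                           P=mode_p or {}, frequency=freq,
                           series=dict(series_by_mode))
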