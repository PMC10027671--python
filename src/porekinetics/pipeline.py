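"""End-to-end workflow: simulate -> idealize -> dwell fits -> kinetics -> report.

``run_pipeline`` drives the whole chain for a concentration series under one
:class:`ExperimentConfig`, producing a :class:`RunReport` whose numbers are
all traceable to a stage output.  Each stage is also usable on its own via
the underlying modules.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from . import __version__
from .dwell import fit_exp_mixture, llr_select
from .events import (EventTable, assign_modes, detect_events,
                     estimate_baseline, fit_amplitude_mixture)
from .exceptions import ConfigurationError
from .io import write_events, write_report
from .kinetics import (ConcentrationSeries, RateEstimate, mode_interevent_durations,
                       mode_probabilities, summarize_kinetics)
from .psd import classify_noise
from .ratematrix import compare_schemes, fit_scheme
from .schemes import (CAPTURED, RELEASED, SENSOR_PRESETS, KineticScheme,
                      build_scheme, sensor_scheme)
from .simulate import Trace, TraceConfig, render_trace, simulate_path

log = logging.getLogger("porekinetics")


@dataclass
class ExperimentConfig:
    """Everything needed to simulate and analyse one concentration series.

    Either ``sensor`` (a named preset: hsumo1, wdr5, egfr) or the triple
    ``preset``/``rates``/``levels`` defines the gating scheme.  ``trace``
    holds :class:`TraceConfig` overrides.  ``target_events`` sizes each
    trace so that roughly that many capture events are expected; an explicit
    ``trace['duration']`` wins.
    """

    sensor: str | None = None
    preset: str | None = None
    rates: dict | None = None
    levels: dict | None = None
    concentrations: list[float] = field(default_factory=list)
    trace: dict = field(default_factory=dict)
    target_events: int | None = None
    threshold_fraction: float = 0.5
    deadtime: float | None = None
    spike_cutoff: float | None = None
    k_max: int = 2
    confidence: float = 0.95
    compare_interconversion: bool = False
    psd_on: bool = True
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**d)

    def scheme(self) -> KineticScheme:
        if self.sensor:
            return sensor_scheme(self.sensor)
        if not (self.preset and self.rates and self.levels):
            raise ConfigurationError(
                "config needs either 'sensor' or preset/rates/levels")
        return build_scheme(self.preset, self.rates, self.levels)

    def trace_config(self, concentration: float, seed: int) -> TraceConfig:
        kwargs = dict(self.trace)
        if self.sensor and "delta_psi" not in kwargs:
            kwargs["delta_psi"] = SENSOR_PRESETS[self.sensor]["delta_psi"]
        if "duration" not in kwargs and self.target_events:
            kwargs["duration"] = self._duration_for(concentration)
        cfg = TraceConfig(concentration=concentration, seed=seed, **kwargs)
        cfg.validate()
        return cfg

    def _duration_for(self, concentration: float) -> float:
        scheme = self.scheme()
        q = scheme.generator(concentration)
        rel = scheme.released_index
        kon_tot = -q[rel, rel]
        if kon_tot <= 0:
            return float(self.trace.get("duration", 10.0))
        tau_on = 1.0 / kon_tot
        caps = scheme.captured_indices
        # expected capture duration weighted by entry flux
        entry = q[rel, caps] / kon_tot
        tau_off = float(np.sum(entry * (1.0 / -np.diag(q)[caps])))
        return 1.15 * self.target_events * (tau_on + tau_off)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Serializable record of a pipeline run."""

    config: dict
    config_hash: str
    version: str
    stages: dict = field(default_factory=dict)
    kinetics: dict = field(default_factory=dict)
    decisions: dict = field(default_factory=dict)
    notices: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def analyze_trace(trace: Trace, config: ExperimentConfig,
                  scheme: KineticScheme | None = None) -> EventTable:
    """Idealize one trace under the experiment's detection settings."""
    baseline = estimate_baseline(trace)
    deepest = float(min(scheme.levels[scheme.captured_indices])) if scheme else 0.0
    return detect_events(
        trace, baseline, threshold_fraction=config.threshold_fraction,
        deadtime=config.deadtime, deepest_level=deepest,
        spike_cutoff=config.spike_cutoff,
    )


def run_pipeline(config: ExperimentConfig, outdir=None) -> RunReport:
    """Execute simulate -> detect -> dwell fits -> kinetics -> report.

    Idempotent under fixed seeds; any stage failure propagates with the
    stage named in the log.
    """
    scheme = config.scheme()
    n_modes = len(scheme.captured_indices)
    report = RunReport(config=asdict(config), config_hash=config.hash(),
                       version=__version__)

    if not config.concentrations:
        log.info("stage simulate: no concentrations; simulation-only run")
        cfg = config.trace_config(0.0, seed=config.seed)
        path = simulate_path(scheme, 0.0, cfg.duration, seed=config.seed)
        trace = render_trace(path, scheme, cfg)
        report.stages["simulate"] = {"concentrations": [], "n_samples": len(trace.samples)}
        report.notices.append("no concentrations given; kinetics skipped")
        if config.psd_on:
            fit = classify_noise(trace)
            report.stages["psd"] = {"classification": fit.classification,
                                    "S_white": fit.S_white,
                                    "A_flicker": fit.A_flicker, "alpha": fit.alpha}
        return report

    per_c: list[dict] = []
    series_rows: dict[int, list[dict]] = {}
    mode_p_agg: dict[int, RateEstimate] = {}
    first_trace: Trace | None = None

    for i, conc in enumerate(config.concentrations):
        seed_i = config.seed + 1000 * (i + 1)
        log.info("stage simulate: C = %.3g nM", conc * 1e9)
        cfg = config.trace_config(conc, seed=seed_i)
        path = simulate_path(scheme, conc, cfg.duration, seed=seed_i)
        trace = render_trace(path, scheme, cfg)
        if first_trace is None:
            first_trace = trace

        log.info("stage detect: C = %.3g nM", conc * 1e9)
        events = analyze_trace(trace, config, scheme)
        if outdir is not None:
            write_events(events, f"{outdir}/events_{conc * 1e9:.4g}nM.tsv")

        entry: dict = {"concentration_M": conc, "duration_s": cfg.duration,
                       "n_events": int(len(events.captured()))}

        log.info("stage fitdwell: C = %.3g nM", conc * 1e9)
        if n_modes >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mixture = fit_amplitude_mixture(events, k=n_modes, seed=seed_i)
                events = assign_modes(events, mixture)
            entry["amplitude_peaks"] = mixture.peaks
            p_modes = mode_probabilities(events)
            entry["mode_probability"] = {m: (p.value, p.se) for m, p in p_modes.items()}
            if i == len(config.concentrations) - 1:
                mode_p_agg = p_modes
            for m in range(1, n_modes + 1):
                cap = events.dwell_sample(CAPTURED, mode=m)
                if len(cap) < 10:
                    continue
                off = fit_exp_mixture(cap, k=1, seed=seed_i)
                waits = mode_interevent_durations(events, m)
                if len(waits) < 5:
                    continue
                series_rows.setdefault(m, []).append(dict(
                    concentration=conc,
                    tau_on=float(np.mean(waits)),
                    tau_on_se=float(np.std(waits, ddof=1) / np.sqrt(len(waits))),
                    tau_off=float(off.taus[0]),
                    tau_off_se=float(off.bse_taus[0]),
                    n=len(cap),
                ))
            if config.compare_interconversion:
                m_ind = fit_scheme(events, "two_mode", conc, seed=seed_i)
                m_int = fit_scheme(events, "interconversion", conc, seed=seed_i)
                cmp = compare_schemes(m_ind, m_int, confidence=config.confidence)
                entry["interconversion_llr"] = {
                    "stat": cmp.stat, "threshold": cmp.threshold,
                    "superior": cmp.superior,
                }
        else:
            rel = events.dwell_sample(RELEASED)
            cap = events.dwell_sample(CAPTURED)
            sel_on = llr_select(rel, k_max=config.k_max,
                                confidence=config.confidence, seed=seed_i)
            sel_off = llr_select(cap, k_max=config.k_max,
                                 confidence=config.confidence, seed=seed_i)
            entry["k_released"] = sel_on.chosen_k
            entry["k_captured"] = sel_off.chosen_k
            on, off = sel_on.best, sel_off.best
            series_rows.setdefault(0, []).append(dict(
                concentration=conc,
                tau_on=float(on.taus[-1]), tau_on_se=float(on.bse_taus[-1]),
                tau_off=float(off.taus[-1]), tau_off_se=float(off.bse_taus[-1]),
                n=len(cap),
            ))
        per_c.append(entry)

    report.stages["per_concentration"] = per_c

    if config.psd_on and first_trace is not None:
        fit = classify_noise(first_trace)
        report.stages["psd"] = {"classification": fit.classification,
                                "S_white": fit.S_white,
                                "A_flicker": fit.A_flicker, "alpha": fit.alpha}

    log.info("stage kinetics")
    series = {
        m: ConcentrationSeries(
            concentrations=[r["concentration"] for r in rows],
            tau_on=[r["tau_on"] for r in rows],
            tau_off=[r["tau_off"] for r in rows],
            tau_on_se=np.array([r["tau_on_se"] for r in rows]),
            tau_off_se=np.array([r["tau_off_se"] for r in rows]),
            n_events=np.array([r["n"] for r in rows]),
            mode=m if m else None,
        )
        for m, rows in series_rows.items() if rows
    }
    if series:
        summary = summarize_kinetics(series, mode_p=mode_p_agg)
        report.kinetics = summary.to_dict()
        report.decisions["llr_confidence"] = config.confidence
    else:
        report.notices.append("too few events for kinetics")

    if outdir is not None:
        write_report(report.to_dict(), f"{outdir}/report.json")
    return report
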