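# porekinetics

Single-molecule kinetic analysis for monobody-based nanopore protein
sensors.

A nanopore sensor of this class is a monomeric β-barrel pore (tFhuA) with an
antibody-mimetic monobody tethered outside its opening. Each capture of a
protein analyte by the monobody produces a resistive pulse: the open-state
current `I_0` (substate `O_on`) drops to a blocked level (substate `O_off`)
for the duration of the binding event. The dwell times carry the chemistry:
released durations `τ_on` shorten with analyte concentration
(`k_on = 1/(τ_on·[C])`), captured durations `τ_off` do not
(`k_off = 1/τ_off`), and `K_D = k_off/k_on`. Some sensors show *bimodal*
recognition — two capture families distinguished jointly by blockade depth
`A/I_0` and duration — and a calibrated sensor quantifies its analyte in a
noisy biofluid background from `C = 1/(τ_on·k_on)` alone.

The package provides, for people analysing (or simulating) such recordings:

- **simulation** — Gillespie realizations of capture/release gating schemes
  (one or two captured substates, optional substate interconversion) and
  rendering to realistic traces: white instrument noise, serum-like `1/f^α`
  flicker noise, 8-pole Bessel low-pass filtering, 50 kHz sampling;
- **idealization** — baseline/`I_0` estimation, half-amplitude event
  search with deadtime handling, blockade-amplitude Gaussian mixtures and
  mode assignment;
- **dwell inference** — left-truncated exponential-mixture maximum
  likelihood (statsmodels-style model/results objects with standard errors
  and `summary()`), log-likelihood-ratio selection of the number of
  components, aggregated-Markov (phase-type) dwell densities, and LLR
  comparison of interconversion vs independent-substate topologies;
- **kinetics** — concentration-series `k_on` (through-origin frequency
  slope), `k_off`, `K_D`, mode probabilities, analyte quantification, and
  unitary conductance;
- **noise** — Welch power spectral densities and white-vs-flicker
  classification.

## Worked example

Simulate an hSUMO1-class sensor (deep ~91% blockades, `k_on = 1.12e8
M⁻¹s⁻¹`, `k_off = 74.5 s⁻¹`) at three concentrations, idealize, fit, and
recover the kinetic constants:

```python
import porekinetics as pk

cfg = pk.ExperimentConfig(
    sensor="hsumo1",
    concentrations=[65e-9, 130e-9, 260e-9],
    target_events=300,
    trace={"noise_sigma": 1.0},
    seed=101,
)
report = pk.run_pipeline(cfg)
k = report.kinetics
print(f"k_on  = {k['k_on_per_M_s'][0]['value']:.3g} M^-1 s^-1")
print(f"k_off = {k['k_off_per_s'][0]['value']:.3g} s^-1")
print(f"K_D   = {k['K_D_M'][0]['value'] * 1e9:.3g} nM")
```

prints (seed 101):

```
k_on  = 1.11e+08 M^-1 s^-1
k_off = 73.5 s^-1
K_D   = 662 nM
```

i.e. the full simulate → detect → fit → kinetics loop returns the generator
truth (1.12e8, 74.5, 665 nM) within a few percent at ~300 events per
concentration. The same objects work piecemeal — e.g. quantifying a serum
sample from the published long-mode calibration:

```python
from porekinetics.kinetics import estimate_concentration
q = estimate_concentration(tau_on=1.7, k_on=2.9e7)   # s, M^-1 s^-1
print(f"[EGFR] = {q.concentration_nM:.1f} nM")        # -> [EGFR] = 20.3 nM
```

A `porekin` CLI wraps the stages (`simulate`, `detect`, `fitdwell`,
`kinetics`, `psd`, `quantify`, `run`, `reproduce-paper`); traces round-trip
through CSV/HDF5, event tables through TSV, reports through JSON, and
configs through TOML/YAML.

## Layout

```
src/porekinetics/
  schemes.py      gating schemes, presets, generator matrices
  simulate.py     Gillespie paths, trace rendering, filters, flicker noise
  events.py       baseline, event search, amplitude mixtures, mode labels
  dwell.py        truncated exponential-mixture ML, LLR selection, histograms
  ratematrix.py   phase-type dwell densities, topology fits and comparison
  kinetics.py     k_on/k_off/K_D, quantification, conductance
  psd.py          Welch spectra, white-vs-flicker classification
  pipeline.py     end-to-end orchestration and reports
  io.py, cli.py   formats and the porekin command line
docs/methods.md   model, estimators, numerical choices, limitations
```
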