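"""Kinetic schemes for nanopore capture/release gating.

A scheme is a continuous-time Markov chain on a small set of current
substates.  One state is the analyte-released (open) substate ``O_on``; the
remaining states are analyte-captured substates with reduced current.
Released -> captured transitions are bimolecular and scale with the analyte
concentration (rate constants in M^-1 s^-1); captured -> released and
captured <-> captured transitions are unimolecular (s^-1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, ValidationError

RELEASED = "released"
CAPTURED = "captured"


@dataclass(frozen=True)
class StateSpec:
    """One current substate of the sensor.

    Parameters
    ----------
    name : str
        Label, e.g. ``"O_on"`` or ``"O_off1"``.
    cls : {"released", "captured"}
        Observable class of the state.
    current_level : float
        Single-channel current of the state in pA at the applied potential.
    """

    name: str
    cls: str
    current_level: float

    def __post_init__(self):
        if self.cls not in (RELEASED, CAPTURED):
            raise ValidationError(f"unknown state class {self.cls!r}")
        if not math.isfinite(self.current_level):
            raise ValidationError(f"non-finite current level for state {self.name!r}")


@dataclass(frozen=True)
class Rate:
    """A single transition rate constant.

    ``concentration_scaled`` rates are bimolecular association constants in
    M^-1 s^-1 and are multiplied by the analyte concentration when building
    the generator; all others are first-order rates in s^-1.
    """

    value: float
    concentration_scaled: bool = False

    def __post_init__(self):
        if not math.isfinite(self.value):
            raise ValidationError("rate constant must be finite")
        if self.value < 0:
            raise ValidationError(f"rate constant must be >= 0, got {self.value}")


@dataclass(frozen=True)
class KineticScheme:
    """A capture/release gating scheme.

    Attributes
    ----------
    states : tuple of StateSpec
        States of the chain; exactly one has class ``released``.
    rates : dict
        Mapping ``(from_name, to_name) -> Rate``.
    """

    states: tuple[StateSpec, ...]
    rates: dict[tuple[str, str], Rate] = field(default_factory=dict)

    def __post_init__(self):
        names = [s.name for s in self.states]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate state names")
        released = [s for s in self.states if s.cls == RELEASED]
        if len(released) != 1:
            raise ValidationError("scheme must have exactly one released state")
        open_level = released[0].current_level
        for s in self.states:
            if s.cls == CAPTURED and s.current_level >= open_level:
                raise ValidationError(
                    f"captured state {s.name!r} must sit below the open level "
                    f"({s.current_level} >= {open_level} pA)"
                )
        cls_of = {s.name: s.cls for s in self.states}
        for (a, b), r in self.rates.items():
            if a not in cls_of or b not in cls_of:
                raise ValidationError(f"rate {a}->{b} references unknown state")
            if a == b:
                raise ValidationError(f"self-transition {a}->{b} not allowed")
            bimolecular = cls_of[a] == RELEASED and cls_of[b] == CAPTURED
            if bimolecular != r.concentration_scaled:
                raise ValidationError(
                    f"rate {a}->{b}: concentration scaling must apply to "
                    "released->captured transitions and only to those"
                )

    # -- indexing helpers -------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [s.name for s in self.states]

    @property
    def released_index(self) -> int:
        return next(i for i, s in enumerate(self.states) if s.cls == RELEASED)

    @property
    def captured_indices(self) -> list[int]:
        return [i for i, s in enumerate(self.states) if s.cls == CAPTURED]

    @property
    def levels(self) -> np.ndarray:
        return np.array([s.current_level for s in self.states], dtype=float)

    def class_of(self, index: int) -> str:
        return self.states[index].cls

    def generator(self, concentration: float) -> np.ndarray:
        """Infinitesimal generator Q (s^-1) at the given concentration (M).

        Rows sum to zero; off-diagonal entry (i, j) is the i->j rate with
        concentration-scaled rates multiplied by ``concentration``.
        """
        if concentration < 0 or not math.isfinite(concentration):
            raise ValidationError("concentration must be finite and >= 0")
        n = len(self.states)
        idx = {s.name: i for i, s in enumerate(self.states)}
        q = np.zeros((n, n))
        for (a, b), r in self.rates.items():
            v = r.value * concentration if r.concentration_scaled else r.value
            q[idx[a], idx[b]] = v
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        return q


#: Rate names required by each preset topology.
PRESET_RATES = {
    "bimolecular": ("k_on", "k_off"),
    "two_mode": ("k_on_1", "k_on_2", "k_off_1", "k_off_2"),
    "interconversion": ("k_on_1", "k_on_2", "k_off_1", "k_off_2", "k_12", "k_21"),
}


def build_scheme(preset: str, rates: dict[str, float], levels: dict[str, float]) -> KineticScheme:
    """Build one of the canonical gating schemes.

    Presets
    -------
    ``bimolecular``
        Two states O_on <-> O_off with rates ``k_on`` (M^-1 s^-1) and
        ``k_off`` (s^-1); the single-site capture/release model.
    ``two_mode``
        O_on plus two independent captured substates O_off1, O_off2 with
        ``k_on_1``, ``k_on_2``, ``k_off_1``, ``k_off_2``; no direct
        transitions between captured substates.
    ``interconversion``
        ``two_mode`` extended with first-order interconversion rates
        ``k_12`` (O_off1 -> O_off2) and ``k_21`` (O_off2 -> O_off1).

    Parameters
    ----------
    rates : dict
        Named rate constants for the preset (see above).
    levels : dict
        Current level in pA for every state name of the preset
        (``O_on``/``O_off`` or ``O_on``/``O_off1``/``O_off2``).
    """
    if preset not in PRESET_RATES:
        raise ConfigurationError(
            f"unknown preset {preset!r}; choose from {sorted(PRESET_RATES)}"
        )
    missing = [r for r in PRESET_RATES[preset] if r not in rates]
    if missing:
        raise ConfigurationError(f"preset {preset!r} is missing rate(s): {', '.join(missing)}")

    def _level(name):
        if name not in levels:
            raise ConfigurationError(f"missing current level for state {name!r}")
        return float(levels[name])

    if preset == "bimolecular":
        states = (
            StateSpec("O_on", RELEASED, _level("O_on")),
            StateSpec("O_off", CAPTURED, _level("O_off")),
        )
        rmap = {
            ("O_on", "O_off"): Rate(float(rates["k_on"]), concentration_scaled=True),
            ("O_off", "O_on"): Rate(float(rates["k_off"])),
        }
    else:
        states = (
            StateSpec("O_on", RELEASED, _level("O_on")),
            StateSpec("O_off1", CAPTURED, _level("O_off1")),
            StateSpec("O_off2", CAPTURED, _level("O_off2")),
        )
        rmap = {
            ("O_on", "O_off1"): Rate(float(rates["k_on_1"]), concentration_scaled=True),
            ("O_on", "O_off2"): Rate(float(rates["k_on_2"]), concentration_scaled=True),
            ("O_off1", "O_on"): Rate(float(rates["k_off_1"])),
            ("O_off2", "O_on"): Rate(float(rates["k_off_2"])),
        }
        if preset == "interconversion":
            rmap[("O_off1", "O_off2")] = Rate(float(rates["k_12"]))
            rmap[("O_off2", "O_off1")] = Rate(float(rates["k_21"]))
    return KineticScheme(states=states, rates=rmap)


#: Study conditions for the three sensors: rate constants (M^-1 s^-1, s^-1)
#: and per-state current levels (pA) at the potential each was recorded at.
SENSOR_PRESETS = {
    # FN3SUMO-tFhuA + hSUMO1, +40 mV: deep ~91% blockades, fast kinetics.
    "hsumo1": dict(
        preset="bimolecular",
        rates={"k_on": 1.12e8, "k_off": 74.5},
        levels={"O_on": 32.1, "O_off": 2.9},
        delta_psi=40.0,
    ),
    # Mb4-tFhuA + WDR5, +40 mV: shallow ~14% blockades.
    "wdr5": dict(
        preset="bimolecular",
        rates={"k_on": 0.83e8, "k_off": 72.4},
        levels={"O_on": 39.5, "O_off": 34.5},
        delta_psi=40.0,
    ),
    # Adnectin1-tFhuA + EGFR ectodomain, +20 mV: bimodal recognition with
    # shallow/short (mode 1) and deep/long (mode 2) capture families.
    "egfr": dict(
        preset="two_mode",
        rates={"k_on_1": 6.62e7, "k_on_2": 2.89e7, "k_off_1": 12.0, "k_off_2": 1.01},
        levels={"O_on": 18.2, "O_off1": 6.4, "O_off2": 2.3},
        delta_psi=20.0,
    ),
}


def sensor_scheme(name: str) -> KineticScheme:
    """Scheme for one of the named sensor/analyte systems in ``SENSOR_PRESETS``."""
    if name not in SENSOR_PRESETS:
        raise ConfigurationError(f"unknown sensor preset {name!r}; choose from {sorted(SENSOR_PRESETS)}")
    p = SENSOR_PRESETS[name]
    return build_scheme(p["preset"], p["rates"], p["levels"])
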