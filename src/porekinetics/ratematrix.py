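"""Aggregated-Markov dwell-time distributions and rate-matrix ML fits.

States are observed only through their class (released vs captured).  The
dwell-time density of a class A with within-class generator block Q_AA and
stationary entry distribution phi_A is the phase-type form

    f(t) = phi_A . exp(Q_AA t) . (-Q_AA) . 1 ,

which reduces to an exponential mixture when the captured substates do not
interconvert.  ``AggregatedMarkovModel`` fits the released and captured
dwell samples jointly by maximum likelihood under either the independent
two-substate topology (k_on_1, k_on_2, k_off_1, k_off_2) or the
interconversion topology (adding k_12, k_21 between the captured
substates); the two are compared by an LLR test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_hess

from .dwell import DwellSample, ExponentialMixture, llr_threshold
from .exceptions import FittingError, UsageError, ValidationError
from .schemes import KineticScheme, build_scheme, CAPTURED, RELEASED
from .simulate import StatePath, class_entry_distribution

N_PARAMS = {"two_mode": 4, "interconversion": 6}


@dataclass
class SubstateSequences:
    """Substate-resolved captured events: one (labels, durations) pair each.

    Labels are 0 (short-lived/shallow substate) and 1 (long-lived/deep
    substate).  Built from an idealization that resolves the two captured
    current levels, e.g. :func:`apparent_substate_events`.
    """

    sequences: list[tuple[np.ndarray, np.ndarray]]
    deadtime: float = 0.0

    def __len__(self):
        return len(self.sequences)

    @property
    def total_durations(self) -> np.ndarray:
        return np.array([np.sum(d) for _, d in self.sequences])

    def sufficient_stats(self) -> dict:
        """Entry counts B, dwell times T, hop counts N, exit counts E."""
        B = np.zeros(2)
        T = np.zeros(2)
        N = np.zeros((2, 2))
        E = np.zeros(2)
        for labels, dur in self.sequences:
            labels = np.asarray(labels, dtype=int)
            dur = np.asarray(dur, dtype=float)
            B[labels[0]] += 1
            np.add.at(T, labels, dur)
            for a, b in zip(labels[:-1], labels[1:]):
                N[a, b] += 1
            E[labels[-1]] += 1
        return {"B": B, "T": T, "N": N, "E": E}


def apparent_substate_events(path: StatePath, scheme: KineticScheme,
                             deadtime: float) -> tuple[DwellSample, SubstateSequences]:
    """Observation model for a simulated path at substate resolution.

    Mimics what a three-level idealization of the rendered trace resolves:
    dwells shorter than ``deadtime`` are unresolved — a short released gap
    merges the flanking captured events (creating an apparent substate hop
    if their substates differ), and a short captured dwell is absorbed into
    its predecessor.  Returns the completed released dwells and the captured
    events as substate sequences; boundary (censored) events are excluded.
    """
    rel = scheme.released_index
    caps = scheme.captured_indices
    sub = {s: i for i, s in enumerate(caps)}
    segs = [[int(s), float(d)] for s, d in zip(path.states, path.dwells)]

    while True:
        interior = [k for k in range(1, len(segs) - 1) if segs[k][1] < deadtime]
        if not interior:
            break
        k = min(interior, key=lambda j: segs[j][1])
        segs[k - 1][1] += segs[k][1]
        del segs[k]
        # merge equal neighbours created by the removal
        if k < len(segs) and segs[k - 1][0] == segs[k][0]:
            segs[k - 1][1] += segs[k][1]
            del segs[k]

    released: list[float] = []
    sequences: list[tuple[np.ndarray, np.ndarray]] = []
    current: list[tuple[int, float]] = []
    for i, (s, d) in enumerate(segs):
        boundary = i == 0 or i == len(segs) - 1
        if s == rel:
            if current and not boundary_flag:
                sequences.append((
                    np.array([a for a, _ in current]),
                    np.array([b for _, b in current]),
                ))
            current = []
            if not boundary:
                released.append(d)
        else:
            if not current:
                boundary_flag = boundary
            boundary_flag = boundary_flag or boundary
            current.append((sub[s], d))
    # trailing captured event is censored; drop it
    return (
        DwellSample(durations=np.array(released), deadtime=deadtime, cls=RELEASED),
        SubstateSequences(sequences=sequences, deadtime=deadtime),
    )


@dataclass
class PhaseTypeDensity:
    """Dwell density f(t) = sum_j c_j exp(lambda_j t) of one observed class."""

    lambdas: np.ndarray      # eigenvalues of Q_AA (negative real parts)
    pdf_coefs: np.ndarray    # c_j = (phi V)_j (V^-1 r)_j
    surv_coefs: np.ndarray   # b_j = (phi V)_j (V^-1 1)_j

    def pdf(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.real(np.exp(np.multiply.outer(t, self.lambdas)) @ self.pdf_coefs)
        return np.clip(out, 0.0, None)

    __call__ = pdf

    def survival(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.real(np.exp(np.multiply.outer(t, self.lambdas)) @ self.surv_coefs)
        return np.clip(out, 0.0, 1.0)

    def cdf(self, t) -> np.ndarray:
        return 1.0 - self.survival(t)

    @property
    def mean(self) -> float:
        # integral of survival
        return float(np.real(np.sum(-self.surv_coefs / self.lambdas)))


def dwell_pdf(scheme: KineticScheme, concentration: float, cls: str) -> PhaseTypeDensity:
    """Observable-class dwell density from the full rate matrix.

    Entry probabilities are the stationary flux into the class; a singular
    within-class block raises with condition diagnostics.
    """
    q = scheme.generator(concentration)
    n = q.shape[0]
    inside = [i for i in range(n) if scheme.class_of(i) == cls]
    if not inside:
        raise ValidationError(f"scheme has no {cls!r} states")
    q_aa = q[np.ix_(inside, inside)]
    cond = np.linalg.cond(q_aa)
    if not np.isfinite(cond) or cond > 1e12:
        raise FittingError(
            f"within-class generator block is numerically singular "
            f"(condition number {cond:.3g})"
        )
    phi = class_entry_distribution(scheme, concentration, cls)
    return _phase_type(q_aa, phi)


def _phase_type(q_aa: np.ndarray, phi: np.ndarray) -> PhaseTypeDensity:
    r = -q_aa @ np.ones(q_aa.shape[0])
    lam, v = np.linalg.eig(q_aa)
    vinv = np.linalg.inv(v)
    left = phi @ v
    return PhaseTypeDensity(
        lambdas=lam,
        pdf_coefs=left * (vinv @ r),
        surv_coefs=left * (vinv @ np.ones(len(lam))),
    )


# ---------------------------------------------------------------------------
# 2x2 captured-block likelihood kernels (fast path used by the fitter)


def _two_state_density(kon1, kon2, koff1, koff2, k12, k21):
    """PhaseTypeDensity of the captured class for the 3-state topologies."""
    q_aa = np.array([[-(koff1 + k12), k12], [k21, -(koff2 + k21)]])
    phi = np.array([kon1, kon2]) / (kon1 + kon2)
    # analytic 2x2 spectral decomposition (eigenvalues are real: the
    # off-diagonal product is non-negative)
    a, b = q_aa[0]
    c, d = q_aa[1]
    half = 0.5 * (a + d)
    disc = np.sqrt(max(0.25 * (a - d) ** 2 + b * c, 0.0))
    l1, l2 = half + disc, half - disc
    eye = np.eye(2)
    r = -q_aa @ np.ones(2)
    if disc < 1e-12 * max(abs(l1), 1.0):
        # defective/near-degenerate: fall back to the generic eigen route
        return _phase_type(q_aa, phi)
    p1 = (q_aa - l2 * eye) / (l1 - l2)
    p2 = eye - p1
    return PhaseTypeDensity(
        lambdas=np.array([l1, l2]),
        pdf_coefs=np.array([phi @ p1 @ r, phi @ p2 @ r]),
        surv_coefs=np.array([phi @ p1 @ np.ones(2), phi @ p2 @ np.ones(2)]),
    )


class AggregatedMarkovModel:
    """Joint ML model for released and captured dwell samples.

    Released dwells are exponential with rate (k_on_1 + k_on_2) * C;
    captured dwells follow the phase-type density of the captured class.
    Both likelihood terms are left-truncated at the detection deadtime.

    When ``captured`` is a :class:`SubstateSequences` (substate-resolved
    idealization), the captured term is the sequence likelihood over entry
    substates, substate dwell hazards, observed hops and exits; apparent
    hops under the two_mode topology go through a missed-released-gap
    channel with probability 1 - exp(-lambda_rel * deadtime).  When only
    pooled captured durations are available the captured term falls back to
    the marginal phase-type density, which carries no information about the
    interconversion rates beyond the shape of the duration mixture.

    Parameters
    ----------
    released : DwellSample or array-like
        Completed released dwell durations (s).
    captured : DwellSample, array-like, or SubstateSequences
        Completed captured dwells, pooled or substate resolved.
    topology : {"two_mode", "interconversion"}
        Whether direct transitions between captured substates are allowed.
    concentration : float
        Analyte concentration (M) the data were recorded at.
    deadtime : float
        Left-truncation point (s); taken from the samples when given.
    """

    def __init__(self, released, captured, topology: str, concentration: float,
                 deadtime: float = 0.0):
        if topology not in N_PARAMS:
            raise UsageError(f"unknown topology {topology!r}")
        if concentration <= 0:
            raise ValidationError("concentration must be > 0")
        def _unpack(sample):
            if isinstance(sample, DwellSample):
                return sample.durations, sample.deadtime
            return np.asarray(sample, dtype=float), deadtime
        self.t_rel, d1 = _unpack(released)
        self.sequences: SubstateSequences | None = None
        if isinstance(captured, SubstateSequences):
            self.sequences = captured
            self._stats = captured.sufficient_stats()
            self.t_cap = captured.total_durations
            d2 = captured.deadtime
        else:
            self.t_cap, d2 = _unpack(captured)
        self.deadtime = max(d1, d2)
        self.topology = topology
        self.concentration = float(concentration)
        if len(self.t_rel) < 10 or len(self.t_cap) < 20:
            raise UsageError("too few dwells for a rate-matrix fit")

    @property
    def nobs(self) -> int:
        return len(self.t_rel) + len(self.t_cap)

    # internal parametrization: log kon1, log kon2, log koff1, log koff2,
    # then sqrt(k12), sqrt(k21) for the interconversion topology (the square
    # keeps the rates non-negative while allowing the 0 boundary).
    def _rates(self, x: np.ndarray) -> tuple[float, ...]:
        kon1, kon2, koff1, koff2 = np.exp(x[:4])
        if self.topology == "interconversion":
            k12, k21 = x[4] ** 2, x[5] ** 2
        else:
            k12 = k21 = 0.0
        return kon1, kon2, koff1, koff2, k12, k21

    def loglike_rates(self, kon1, kon2, koff1, koff2, k12=0.0, k21=0.0) -> float:
        d = self.deadtime
        lam = (kon1 + kon2) * self.concentration
        if lam <= 0 or koff1 <= 0 or koff2 <= 0 or k12 < 0 or k21 < 0:
            return -np.inf
        ll = len(self.t_rel) * (np.log(lam) + lam * d) - lam * np.sum(self.t_rel)
        if self.sequences is not None:
            return float(ll + self._loglike_sequences(
                kon1, kon2, koff1, koff2, k12, k21, lam))
        dens = _two_state_density(kon1, kon2, koff1, koff2, k12, k21)
        f = dens.pdf(self.t_cap)
        if np.any(f <= 0):
            return -np.inf
        surv_d = float(dens.survival(d)) if d > 0 else 1.0
        ll += float(np.sum(np.log(f))) - len(self.t_cap) * np.log(max(surv_d, 1e-300))
        return float(ll)

    def _loglike_sequences(self, kon1, kon2, koff1, koff2, k12, k21, lam) -> float:
        """Captured-term sequence likelihood from sufficient statistics.

        Hops between the observed substates happen either directly (the
        interconversion rates) or through a released gap shorter than the
        deadtime, which an idealizer cannot resolve; the latter channel has
        rate k_off_s * p_miss * w_s' with p_miss = 1 - exp(-lam * deadtime).
        """
        st = self._stats
        w = np.array([kon1, kon2]) / (kon1 + kon2)
        koff = np.array([koff1, koff2])
        p_miss = -np.expm1(-lam * self.deadtime)
        hop = np.array([[0.0, k12], [k21, 0.0]])
        hop[0, 1] += koff[0] * p_miss * w[1]
        hop[1, 0] += koff[1] * p_miss * w[0]
        h_end = koff * (1.0 - p_miss)
        h_total = hop.sum(axis=1) + h_end

        def xlogy(x, y):
            return 0.0 if x == 0 else (x * np.log(y) if y > 0 else -np.inf)

        ll = float(np.sum(st["B"] * np.log(w)))
        ll -= float(np.sum(h_total * st["T"]))
        ll += xlogy(st["N"][0, 1], hop[0, 1]) + xlogy(st["N"][1, 0], hop[1, 0])
        ll += xlogy(st["E"][0], h_end[0]) + xlogy(st["E"][1], h_end[1])
        return ll

    def _nll(self, x: np.ndarray) -> float:
        ll = self.loglike_rates(*self._rates(x))
        return -ll if np.isfinite(ll) else 1e15

    def _initial_points(self, seed: int):
        d = self.deadtime
        lam0 = 1.0 / max(np.mean(self.t_rel) - d, 1e-9)
        if self.sequences is not None:
            st = self._stats
            koff = np.clip(st["E"] / np.maximum(st["T"], 1e-12), 1e-6, None)
            w1 = float(np.clip(st["B"][0] / st["B"].sum(), 0.05, 0.95))
            base = np.log([w1 * lam0 / self.concentration,
                           (1 - w1) * lam0 / self.concentration,
                           koff[0], koff[1]])
            if self.topology == "two_mode":
                return [base]
            k12 = st["N"][0, 1] / max(st["T"][0], 1e-12)
            k21 = st["N"][1, 0] / max(st["T"][1], 1e-12)
            return [
                np.concatenate([base, np.sqrt([max(k12, 1e-8), max(k21, 1e-8)])]),
                np.concatenate([base, np.sqrt([1e-6, 1e-6])]),
            ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                mix = ExponentialMixture(self.t_cap, k=2, deadtime=d).fit(
                    seed=seed, n_restarts=3)
                taus, w = mix.taus, mix.weights
            except (FittingError, UsageError):
                m = max(np.mean(self.t_cap) - d, 1e-9)
                taus, w = np.array([0.5 * m, 2.0 * m]), np.array([0.5, 0.5])
        koff1, koff2 = 1.0 / taus[0], 1.0 / taus[1]       # short-lived first
        w1 = float(np.clip(w[0], 0.05, 0.95))
        kon1 = w1 * lam0 / self.concentration
        kon2 = (1 - w1) * lam0 / self.concentration
        base = np.log([kon1, kon2, koff1, koff2])
        if self.topology == "two_mode":
            return [base]
        starts = []
        for frac in (1e-3, 0.3):
            s12 = np.sqrt(frac * koff1)
            s21 = np.sqrt(frac * koff2)
            starts.append(np.concatenate([base, [s12, s21]]))
        return starts

    def fit(self, seed: int = 0) -> "AggregatedMarkovResults":
        candidates = []
        for x0 in self._initial_points(seed):
            res = optimize.minimize(self._nll, x0, method="Nelder-Mead",
                                    options={"maxiter": 4000, "xatol": 1e-8,
                                             "fatol": 1e-10})
            res = optimize.minimize(self._nll, res.x, method="L-BFGS-B",
                                    options={"maxiter": 500})
            candidates.append(res)
        candidates = [r for r in candidates if np.isfinite(r.fun)]
        if not candidates:
            raise FittingError("rate-matrix fit failed to converge")
        fmin = min(r.fun for r in candidates)
        # the marginal captured-class dwell density does not always identify
        # the interconversion rates uniquely; among likelihood-equivalent
        # optima prefer the most parsimonious one (smallest k_12 + k_21)
        tol = 1e-4 * max(abs(fmin), 1.0)
        ties = [r for r in candidates if r.fun <= fmin + tol]
        best = min(ties, key=lambda r: sum(self._rates(r.x)[4:]))
        kon1, kon2, koff1, koff2, k12, k21 = self._rates(best.x)
        # canonical labeling: substate 1 is the short-lived family (pooled
        # durations only — substate-resolved labels are anchored to the data)
        if self.sequences is None and koff1 < koff2:
            kon1, kon2, koff1, koff2 = kon2, kon1, koff2, koff1
            k12, k21 = k21, k12
        rates = {"k_on_1": kon1, "k_on_2": kon2,
                 "k_off_1": koff1, "k_off_2": koff2}
        if self.topology == "interconversion":
            rates.update(k_12=k12, k_21=k21)
        llf = self.loglike_rates(kon1, kon2, koff1, koff2, k12, k21)
        bse = self._standard_errors(rates)
        return AggregatedMarkovResults(
            model=self, topology=self.topology, rates=rates, bse=bse,
            llf=llf, concentration=self.concentration,
            converged=bool(best.success),
        )

    def _standard_errors(self, rates: dict) -> dict:
        names = list(rates)
        vals = np.array([rates[n] for n in names])
        free = vals > 1e-12  # boundary rates have no two-sided curvature
        def nll(logv):
            full = vals.copy()
            full[free] = np.exp(logv)
            kw = dict(zip(names, full))
            return -self.loglike_rates(
                kw["k_on_1"], kw["k_on_2"], kw["k_off_1"], kw["k_off_2"],
                kw.get("k_12", 0.0), kw.get("k_21", 0.0),
            )
        se = {n: np.nan for n in names}
        try:
            hess = approx_hess(np.log(vals[free]), nll)
            cov = np.linalg.inv(hess)
            diag = np.sqrt(np.clip(np.diag(cov), 0, None))
            for n, v, s in zip(np.array(names)[free], vals[free], diag):
                se[str(n)] = float(v * s)  # delta method from log scale
        except (np.linalg.LinAlgError, ValueError):
            warnings.warn("observed information is singular; standard errors "
                          "unavailable (flat likelihood direction)", stacklevel=2)
        return se


@dataclass
class AggregatedMarkovResults:
    """ML estimates of a capture/release rate matrix from dwell samples."""

    model: AggregatedMarkovModel
    topology: str
    rates: dict
    bse: dict
    llf: float
    concentration: float
    converged: bool = True

    @property
    def n_params(self) -> int:
        return N_PARAMS[self.topology]

    @property
    def nobs(self) -> int:
        return self.model.nobs

    def scheme(self, levels: dict | None = None) -> KineticScheme:
        """Fitted scheme as a KineticScheme (nominal levels if none given)."""
        levels = levels or {"O_on": 1.0, "O_off1": 0.35, "O_off2": 0.15}
        rates = dict(self.rates)
        if self.topology == "interconversion":
            rates.setdefault("k_12", 0.0)
            rates.setdefault("k_21", 0.0)
        return build_scheme(self.topology, rates, levels)

    def captured_density(self) -> PhaseTypeDensity:
        r = self.rates
        return _two_state_density(r["k_on_1"], r["k_on_2"], r["k_off_1"],
                                  r["k_off_2"], r.get("k_12", 0.0),
                                  r.get("k_21", 0.0))

    def to_dict(self) -> dict:
        return {"topology": self.topology, "logL": self.llf,
                "n_released": len(self.model.t_rel),
                "n_captured": len(self.model.t_cap),
                "concentration_M": self.concentration,
                "rates": dict(self.rates), "rates_se": dict(self.bse)}

    def summary(self) -> str:
        lines = [
            f"Aggregated-Markov dwell fit ({self.topology})",
            f"  N released: {len(self.model.t_rel)}    "
            f"N captured: {len(self.model.t_cap)}    "
            f"C: {self.concentration * 1e9:.3g} nM",
            f"  log-likelihood: {self.llf:.3f}",
            "  rate        value          se",
        ]
        for n, v in self.rates.items():
            lines.append(f"  {n:<9} {v:12.5g}  {self.bse.get(n, float('nan')):10.3g}")
        return "\n".join(lines)


def fit_scheme(events, topology: str, concentration: float,
               seed: int = 0) -> AggregatedMarkovResults:
    """Fit a 3-state capture/release topology to an idealized event table.

    Uses pooled captured durations (the amplitude sequence within events is
    not resolved in an event table); substate-resolved fits go through
    :func:`fit_scheme_from_path` or a :class:`SubstateSequences` built from
    a three-level idealization.
    """
    released = events.dwell_sample(RELEASED)
    captured = events.dwell_sample(CAPTURED)
    model = AggregatedMarkovModel(released, captured, topology=topology,
                                  concentration=concentration)
    return model.fit(seed=seed)


def fit_scheme_from_path(path: StatePath, scheme: KineticScheme, topology: str,
                         concentration: float, deadtime: float,
                         seed: int = 0) -> AggregatedMarkovResults:
    """Substate-resolved topology fit from a simulated path.

    Applies the deadtime observation model (:func:`apparent_substate_events`)
    and fits the sequence likelihood.
    """
    released, sequences = apparent_substate_events(path, scheme, deadtime)
    model = AggregatedMarkovModel(released, sequences, topology=topology,
                                  concentration=concentration)
    return model.fit(seed=seed)


@dataclass
class SchemeComparison:
    """LLR comparison of two nested rate-matrix models."""

    stat: float              # 2 * (logL_general - logL_restricted)
    df: int
    threshold: float
    confidence: float
    superior: bool           # general model significantly better (strict)
    p_value: float


def compare_schemes(m1: AggregatedMarkovResults, m2: AggregatedMarkovResults,
                    confidence: float = 0.95) -> SchemeComparison:
    """LLR test of a restricted model m1 against a nesting model m2.

    m1 must be nested in m2 (two_mode within interconversion, or identical
    topologies for a degenerate comparison).  The general model is superior
    iff 2*(logL_2 - logL_1) strictly exceeds the chi-square quantile with
    df = parameter-count difference.
    """
    if m1.nobs != m2.nobs:
        raise UsageError("models were fitted to different data")
    order = {"two_mode": 0, "interconversion": 1}
    if order[m1.topology] > order[m2.topology]:
        raise UsageError("m1 must be nested in m2")
    df = m2.n_params - m1.n_params
    stat = 2.0 * (m2.llf - m1.llf)
    if df == 0:
        return SchemeComparison(stat=stat, df=0, threshold=0.0,
                                confidence=confidence, superior=False,
                                p_value=1.0)
    thr = llr_threshold(confidence, df=df)
    return SchemeComparison(
        stat=stat, df=df, threshold=thr, confidence=confidence,
        superior=bool(stat > thr),
        p_value=float(stats.chi2.sf(max(stat, 0.0), df)),
    )
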