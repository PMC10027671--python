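"""Maximum-likelihood dwell-time analysis.

Dwell durations of released/captured events are modelled as left-truncated
exponential mixtures,

    f(t) = [sum_i (p_i / tau_i) exp(-t / tau_i)]
           / [sum_i p_i exp(-d / tau_i)],        t >= d,

where d is the detection deadtime (events shorter than d are censored by the
idealization).  The number of components is chosen by a log-likelihood-ratio
(LLR) test against a chi-square reference with 2 degrees of freedom per
added component, at a configurable confidence level (0.95 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp
from statsmodels.tools.numdiff import approx_hess

from .exceptions import FittingError, UsageError, ValidationError


@dataclass
class DwellSample:
    """Completed dwell durations of one observable class.

    All durations are >= ``deadtime``; right-censored dwells are excluded
    upstream.  ``mode`` records an optional amplitude-family filter.
    """

    durations: np.ndarray
    deadtime: float = 0.0
    cls: str = "captured"
    mode: int | None = None

    def __post_init__(self):
        self.durations = np.asarray(self.durations, dtype=float)
        if self.deadtime < 0:
            raise ValidationError("deadtime must be >= 0")
        if len(self.durations) and np.min(self.durations) < self.deadtime:
            raise ValidationError("all durations must be >= deadtime")

    def __len__(self):
        return len(self.durations)


# ---------------------------------------------------------------------------
# exponential-mixture model


class ExponentialMixture:
    """Left-truncated exponential mixture model for dwell durations.

    Parameters
    ----------
    dwells : DwellSample or array-like
        Dwell durations (s); if an array is given ``deadtime`` applies.
    k : int
        Number of exponential components.
    deadtime : float
        Left-truncation point (ignored when ``dwells`` is a DwellSample).

    ``fit`` maximizes the truncated-mixture log-likelihood by multi-start
    quasi-Newton optimization (components initialized from a k-quantile
    split of the log-durations plus seeded random restarts) and returns an
    :class:`ExponentialMixtureResults`.
    """

    def __init__(self, dwells, k: int = 1, deadtime: float = 0.0):
        if isinstance(dwells, DwellSample):
            self.t = dwells.durations
            self.deadtime = dwells.deadtime
        else:
            self.t = np.asarray(dwells, dtype=float)
            self.deadtime = float(deadtime)
        if k < 1:
            raise ValidationError("k must be >= 1")
        if len(self.t) < 10 * k:
            raise UsageError(f"need >= {10 * k} dwells to fit {k} components")
        if len(self.t) and self.deadtime > np.min(self.t):
            raise ValidationError("deadtime exceeds the shortest dwell")
        self.k = int(k)
        self.nobs = len(self.t)

    # -- likelihood in unconstrained coordinates (w logits, log taus) -----
    def _loglike_z(self, z: np.ndarray) -> float:
        k = self.k
        logw = z[:k] - logsumexp(z[:k])
        logtau = z[k:]
        tau = np.exp(logtau)
        # log numerator per observation
        a = logw - logtau - self.t[:, None] / tau
        num = logsumexp(a, axis=1)
        denom = logsumexp(logw - self.deadtime / tau)
        return float(np.sum(num) - self.nobs * denom)

    def loglike(self, weights, taus) -> float:
        """Log-likelihood at the given mixture weights and time constants."""
        w = np.asarray(weights, dtype=float)
        tau = np.asarray(taus, dtype=float)
        z = np.concatenate([np.log(w), np.log(tau)])
        return self._loglike_z(z)

    def _initial_points(self, seed: int, n_restarts: int, warm=None):
        logt = np.log(np.sort(self.t))
        k = self.k
        groups = np.array_split(logt, k)
        tau0 = np.array([np.exp(g.mean()) for g in groups])
        tau0 = np.maximum(tau0, 1e-12)
        inits = [np.concatenate([np.zeros(k), np.log(tau0)])]
        if warm is not None:
            inits.append(np.asarray(warm, dtype=float))
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts):
            jitter = np.concatenate([
                rng.normal(0, 1.0, k), np.log(tau0) + rng.normal(0, 1.0, k)
            ])
            inits.append(jitter)
        return inits

    def fit(self, seed: int = 0, n_restarts: int = 10, warm_start=None) -> "ExponentialMixtureResults":
        best = None
        for z0 in self._initial_points(seed, n_restarts, warm=warm_start):
            res = optimize.minimize(
                lambda z: -self._loglike_z(z), z0, method="L-BFGS-B",
                options={"maxiter": 500},
            )
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise FittingError("exponential mixture fit failed to converge")
        z = best.x
        k = self.k
        w = np.exp(z[:k] - logsumexp(z[:k]))
        tau = np.exp(z[k:])
        order = np.argsort(tau)
        w, tau = w[order], tau[order]
        if k > 1 and np.min(tau[1:] / tau[:-1]) < 1.5:
            warnings.warn(
                "mixture components are collapsing (tau ratio < 1.5); "
                "the model is likely over-specified", stacklevel=2,
            )
        llf = self._loglike_z(np.concatenate([np.log(w), np.log(tau)]))
        bse_w, bse_tau = self._standard_errors(w, tau)
        return ExponentialMixtureResults(
            model=self, weights=w, taus=tau, llf=llf,
            bse_weights=bse_w, bse_taus=bse_tau,
            converged=bool(best.success), warm_z=z,
        )

    def _standard_errors(self, w, tau):
        """Observed-information standard errors in (p_1..p_{k-1}, tau) space."""
        k = self.k
        def nll(theta):
            if k == 1:
                wk = np.array([1.0])
                tk = np.abs(theta)
            else:
                p = theta[: k - 1]
                wk = np.concatenate([p, [1.0 - p.sum()]])
                tk = np.abs(theta[k - 1:])
            if np.any(wk <= 0) or np.any(tk <= 0):
                return 1e12
            return -self.loglike(wk, tk)

        theta = np.concatenate([w[:-1], tau]) if k > 1 else tau.copy()
        try:
            hess = approx_hess(theta, nll)
            cov = np.linalg.inv(hess)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(len(theta), np.nan)
        if k == 1:
            return np.array([0.0]), se
        se_p = se[: k - 1]
        # se of the last weight from the sum constraint
        try:
            cov_p = np.linalg.inv(approx_hess(theta, nll))[: k - 1, : k - 1]
            se_last = float(np.sqrt(max(np.ones(k - 1) @ cov_p @ np.ones(k - 1), 0.0)))
        except np.linalg.LinAlgError:
            se_last = np.nan
        return np.concatenate([se_p, [se_last]]), se[k - 1:]


@dataclass
class ExponentialMixtureResults:
    """MLE of a left-truncated exponential mixture.

    ``components`` lists (p_i, tau_i) sorted by ascending tau; standard
    errors come from the observed Fisher information (numerical Hessian).
    """

    model: ExponentialMixture
    weights: np.ndarray
    taus: np.ndarray
    llf: float
    bse_weights: np.ndarray
    bse_taus: np.ndarray
    converged: bool = True
    warm_z: np.ndarray | None = None

    @property
    def k(self) -> int:
        return len(self.taus)

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def components(self) -> list[tuple[float, float]]:
        return [(float(p), float(t)) for p, t in zip(self.weights, self.taus)]

    @property
    def aic(self) -> float:
        return 2 * (2 * self.k - 1) - 2 * self.llf

    def pdf(self, t) -> np.ndarray:
        """Fitted truncated mixture density evaluated at t."""
        t = np.asarray(t, dtype=float)
        d = self.model.deadtime
        num = np.sum(
            (self.weights / self.taus) * np.exp(-t[..., None] / self.taus), axis=-1
        )
        den = np.sum(self.weights * np.exp(-d / self.taus))
        out = num / den
        return np.where(t >= d, out, 0.0)

    def to_dict(self) -> dict:
        return {
            "k": self.k, "n": self.nobs, "logL": self.llf,
            "deadtime_s": self.model.deadtime,
            "components": [
                {"p": p, "p_se": float(sp), "tau_s": t, "tau_se_s": float(st)}
                for (p, t), sp, st in zip(self.components, self.bse_weights, self.bse_taus)
            ],
        }

    def summary(self) -> str:
        lines = [
            "Left-truncated exponential mixture (MLE)",
            f"  components: {self.k}    N: {self.nobs}    "
            f"deadtime: {self.model.deadtime * 1e3:.3g} ms",
            f"  log-likelihood: {self.llf:.3f}",
            "  comp      p        se(p)     tau [ms]   se(tau) [ms]",
        ]
        for i, ((p, t), sp, st) in enumerate(
            zip(self.components, self.bse_weights, self.bse_taus), start=1
        ):
            lines.append(
                f"  {i:>4}  {p:8.4f}  {sp:8.4f}  {t * 1e3:10.4g}  {st * 1e3:10.4g}"
            )
        return "\n".join(lines)


def fit_exp_mixture(dwells: DwellSample, k: int, seed: int = 0,
                    n_restarts: int = 10) -> ExponentialMixtureResults:
    """Fit a k-component left-truncated exponential mixture to dwell data."""
    return ExponentialMixture(dwells, k=k).fit(seed=seed, n_restarts=n_restarts)


# ---------------------------------------------------------------------------
# LLR model selection


@dataclass
class LLRDecision:
    """Outcome of a log-likelihood-ratio model-comparison sequence.

    ``chosen_k`` is the smallest k such that k+1 components are not a
    statistically significant improvement at confidence ``confidence``;
    ``llr`` maps (k, k+1) -> 2*(logL_{k+1} - logL_k).
    """

    chosen_k: int
    llr: dict
    confidence: float
    threshold: float
    df: int = 2
    fits: dict = field(default_factory=dict, repr=False)

    @property
    def best(self):
        return self.fits.get(self.chosen_k)


def llr_threshold(confidence: float, df: int = 2) -> float:
    """Chi-square quantile used as the LLR acceptance threshold."""
    return float(stats.chi2.ppf(confidence, df))


def llr_select(dwells: DwellSample, k_max: int, confidence: float = 0.95,
               seed: int = 0, n_restarts: int = 6) -> LLRDecision:
    """Choose the number of exponential components by sequential LLR tests.

    k+1 components are accepted over k iff 2*(logL_{k+1} - logL_k) strictly
    exceeds the chi-square quantile at ``confidence`` with df = 2 (one extra
    time constant plus one extra weight).  Returns the smallest
    non-rejectable k.
    """
    if k_max < 1:
        raise ValidationError("k_max must be >= 1")
    thr = llr_threshold(confidence, df=2)
    fits: dict[int, ExponentialMixtureResults] = {}
    llr: dict[tuple[int, int], float] = {}

    def _fit(k):
        if k not in fits:
            warm = None
            if (k - 1) in fits:
                # warm start: split the widest component of the k-1 solution
                prev = fits[k - 1]
                tau = np.concatenate([prev.taus, [prev.taus[-1] * 3.0]])
                w = np.concatenate([prev.weights * (1 - 1.0 / k), [1.0 / k]])
                warm = np.concatenate([np.log(w), np.log(tau)])
            fits[k] = ExponentialMixture(dwells, k=k).fit(
                seed=seed + k, n_restarts=n_restarts, warm_start=warm,
            )
        return fits[k]

    chosen = k_max
    for k in range(1, k_max):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r0, r1 = _fit(k), _fit(k + 1)
        stat = 2.0 * (r1.llf - r0.llf)
        llr[(k, k + 1)] = stat
        if not stat > thr:
            chosen = k
            break
    else:
        _fit(k_max)
    return LLRDecision(chosen_k=chosen, llr=llr, confidence=confidence,
                       threshold=thr, fits=fits)


# ---------------------------------------------------------------------------
# log-binned dwell histogram


def log_binned_histogram(dwells: DwellSample, bins_per_decade: int = 10) -> pd.DataFrame:
    """Log10-binned dwell histogram in the Sigworth-Sine convention.

    Counts per logarithmic bin (with a square-root ordinate column) make an
    exponential population appear as a single peak located at t = tau on a
    semilogarithmic plot.
    """
    t = dwells.durations
    cols = ["left_s", "right_s", "center_s", "count", "sqrt_count", "density"]
    if len(t) == 0:
        return pd.DataFrame(columns=cols)
    lo = np.floor(np.log10(np.min(t)) * bins_per_decade) / bins_per_decade
    hi = np.ceil(np.log10(np.max(t)) * bins_per_decade) / bins_per_decade
    nbins = max(int(round((hi - lo) * bins_per_decade)), 1)
    edges = np.logspace(lo, hi, nbins + 1)
    counts, _ = np.histogram(t, bins=edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    width_log = np.diff(np.log10(edges))
    return pd.DataFrame({
        "left_s": edges[:-1], "right_s": edges[1:], "center_s": centers,
        "count": counts, "sqrt_count": np.sqrt(counts),
        "density": counts / (len(t) * width_log),
    })
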