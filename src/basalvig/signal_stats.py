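"""Disproportionality statistics on fourfold report tables.

Four estimators are implemented, with the signal criteria standard in
spontaneous-report pharmacovigilance:

* **ROR** — reporting odds ratio ``ad/bc`` with a Woolf (log-normal) 95% CI;
  signal when the CI lower bound exceeds 1.
* **PRR** — proportional reporting ratio ``[a/(a+b)]/[c/(c+d)]`` with its
  log-normal CI and a Yates-corrected Pearson chi-square; signal when
  PRR >= 2 and chi-square >= 4.
* **BCPNN information component** — ``IC = log2((a+0.5)/(E+0.5))`` with
  ``E = (a+b)(a+c)/n``, the gamma-Poisson credibility formulation: the
  observed-to-expected ratio has posterior Gamma(a+0.5, E+0.5), and IC025 is
  the log2 of its 2.5% quantile; signal when IC025 > 0.
* **MGPS / EBGM** — empirical-Bayes geometric mean under a two-component
  gamma mixture prior on the ratio, hyperparameters fitted by maximizing
  the negative-binomial mixture marginal likelihood over the whole
  drug-event pair universe; signal when the posterior 5% quantile EB05
  exceeds 1.

Zero cells make ROR/PRR non-estimable by default; an optional Haldane +0.5
continuity correction on all cells is available.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, special, stats

from basalvig.cohort import ContingencyTable

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class SignalResult:
    """Estimates, interval bounds and signal flags for one drug-event pair."""

    a: int
    expected: float
    ror: float
    ror_ci: tuple[float, float]
    prr: float
    prr_ci: tuple[float, float]
    chi2: float
    ic: float
    ic025: float
    ebgm: float = float("nan")
    eb05: float = float("nan")

    @property
    def estimable(self) -> bool:
        return np.isfinite(self.ror)

    @property
    def flags(self) -> dict[str, bool]:
        return signal_flags(self)


def _apply_continuity(table: ContingencyTable, haldane: bool):
    cells = np.asarray(table.as_tuple(), dtype=float)
    if haldane:
        cells = cells + 0.5
    return cells


def ror(table: ContingencyTable, haldane: bool = False) -> tuple[float, tuple[float, float]]:
    """Reporting odds ratio with 95% CI.

    Non-estimable tables (a zero in any cell without the Haldane correction)
    return ``(nan, (nan, nan))``.
    """
    a, b, c, d = _apply_continuity(table, haldane)
    if min(a, b, c, d) <= 0:
        return float("nan"), (float("nan"), float("nan"))
    est = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(est) - Z95 * se), np.exp(np.log(est) + Z95 * se)
    return float(est), (float(lo), float(hi))


def prr_chi2(
    table: ContingencyTable, haldane: bool = False, yates: bool = True
) -> tuple[float, tuple[float, float], float]:
    """PRR with 95% CI and the (optionally Yates-corrected) Pearson chi-square.

    The chi-square is always computed on the raw cells; the continuity option
    affects only the PRR ratio.  With Yates' correction the statistic is
    floored at 0 when ``|ad - bc| <= n/2``.
    """
    a, b, c, d = _apply_continuity(table, haldane)
    n = table.n
    if (a + b) <= 0 or (c + d) <= 0 or a <= 0 or c <= 0:
        est, ci = float("nan"), (float("nan"), float("nan"))
    else:
        est = (a / (a + b)) / (c / (c + d))
        se = np.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
        ci = (float(np.exp(np.log(est) - Z95 * se)), float(np.exp(np.log(est) + Z95 * se)))
        est = float(est)

    ra, rb, rc, rd = (float(x) for x in table.as_tuple())
    denom = (ra + rb) * (rc + rd) * (ra + rc) * (rb + rd)
    if n == 0 or denom == 0:
        chi2 = float("nan")
    else:
        diff = abs(ra * rd - rb * rc)
        if yates:
            diff = max(diff - n / 2.0, 0.0)
        chi2 = float(n * diff**2 / denom)
    return est, ci, chi2


def bcpnn_ic(table: ContingencyTable) -> tuple[float, float]:
    """Information component and its 2.5% credibility bound (bits)."""
    if table.n <= 0:
        return float("nan"), float("nan")
    e = table.expected
    if e <= 0:
        return float("nan"), float("nan")
    a = table.a
    ic = float(np.log2((a + 0.5) / (e + 0.5)))
    lam_lo = stats.gamma.ppf(0.025, a + 0.5, scale=1.0 / (e + 0.5))
    return ic, float(np.log2(lam_lo))


# --- MGPS -------------------------------------------------------------------


@dataclass(frozen=True)
class GPSHyperparams:
    """Two-component gamma mixture prior on the observed/expected ratio."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    p_mix: float
    loglik: float = float("nan")

    def __post_init__(self):
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma shapes/rates must be positive")
        if not 0 <= self.p_mix <= 1:
            raise ValueError("mixture weight must lie in [0, 1]")

    @property
    def prior_mean(self) -> float:
        return self.p_mix * self.alpha1 / self.beta1 + (1 - self.p_mix) * self.alpha2 / self.beta2


#: classical starting point for the marginal-likelihood optimization
GPS_START = GPSHyperparams(0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


def _nb_logpmf(a, alpha, beta, e):
    """log marginal P(a | alpha, beta, E): negative binomial with r=alpha,
    success prob beta/(beta+E), induced by a Gamma(alpha, beta) prior on the
    ratio of a Poisson mean to E."""
    return stats.nbinom.logpmf(a, alpha, beta / (beta + e))

def _mixture_loglik(theta, a, e):
    la1, lb1, la2, lb2, logit_p = theta
    a1, b1, a2, b2 = np.exp([la1, lb1, la2, lb2])
    p = special.expit(logit_p)
    comp = np.stack(
        [
            np.log(p + 1e-300) + _nb_logpmf(a, a1, b1, e),
            np.log(1 - p + 1e-300) + _nb_logpmf(a, a2, b2, e),
        ]
    )
    return float(np.sum(special.logsumexp(comp, axis=0)))


def fit_gps(
    observed,
    expected,
    start: GPSHyperparams = GPS_START,
    n_starts: int = 8,
    seed: int = 0,
) -> GPSHyperparams:
    """Fit the mixture hyperparameters to a drug-event pair universe.

    Parameters
    ----------
    observed, expected
        Arrays over all pairs: observed report counts ``a`` and their
        independence expectations ``E``.
    start
        First optimization start (the classical point by default); the
        remaining ``n_starts - 1`` starts are seeded log-scale perturbations
        guarding against local optima.
    """
    a = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    if a.shape != e.shape or a.ndim != 1:
        raise ValueError("observed and expected must be 1-d arrays of equal length")
    if np.any(e <= 0):
        raise ValueError("every pair needs a positive expectation")
    if len(a) < 50:
        import warnings

        warnings.warn(f"only {len(a)} pairs; hyperparameter estimates may be unstable")

    theta0 = np.array(
        [
            np.log(start.alpha1),
            np.log(start.beta1),
            np.log(start.alpha2),
            np.log(start.beta2),
            special.logit(start.p_mix),
        ]
    )
    rng = np.random.default_rng(seed)
    starts = [theta0] + [theta0 + rng.normal(0, 0.75, size=5) for _ in range(n_starts - 1)]

    best = None
    trace = []
    for th in starts:
        res = optimize.minimize(
            lambda t: -_mixture_loglik(t, a, e),
            th,
            method="L-BFGS-B",
            bounds=[(-15.0, 15.0)] * 5,  # log/logit scale; keeps exp() finite
            options={"maxiter": 500},
        )
        trace.append(-res.fun)
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(f"GPS hyperparameter fit failed to converge; loglik trace {trace}")

    la1, lb1, la2, lb2, logit_p = best.x
    a1, b1, a2, b2 = np.exp([la1, lb1, la2, lb2])
    p = float(special.expit(logit_p))
    # order components by prior mean so reported hyperparameters are canonical
    if a1 / b1 > a2 / b2:
        a1, b1, a2, b2, p = a2, b2, a1, b1, 1 - p
    return GPSHyperparams(float(a1), float(b1), float(a2), float(b2), p, loglik=float(-best.fun))


def _posterior_weight(a, e, hyper: GPSHyperparams) -> float:
    """Posterior probability that the pair's ratio came from component 1."""
    l1 = np.log(hyper.p_mix + 1e-300) + _nb_logpmf(a, hyper.alpha1, hyper.beta1, e)
    l2 = np.log(1 - hyper.p_mix + 1e-300) + _nb_logpmf(a, hyper.alpha2, hyper.beta2, e)
    return float(np.exp(l1 - special.logsumexp([l1, l2])))


def ebgm(table: ContingencyTable, hyper: GPSHyperparams, quantile: float = 0.05) -> tuple[float, float]:
    """EBGM and its lower posterior quantile (EB05 by default).

    The posterior on the observed/expected ratio is the mixture of
    ``Gamma(alpha_k + a, beta_k + E)``; EBGM is the geometric mean
    ``exp(E[ln ratio])`` and EB05 the 5% quantile of the mixture, solved by
    root finding on its CDF.  Some published table legends describe the lower
    bound as a 95%-CI limit (2.5%); ``quantile`` makes the convention
    explicit.
    """
    e = table.expected
    if not e > 0:
        return float("nan"), float("nan")
    a = table.a
    q = _posterior_weight(a, e, hyper)
    s1, r1 = hyper.alpha1 + a, hyper.beta1 + e
    s2, r2 = hyper.alpha2 + a, hyper.beta2 + e
    mean_log = q * (special.digamma(s1) - np.log(r1)) + (1 - q) * (special.digamma(s2) - np.log(r2))
    ebgm_val = float(np.exp(mean_log))

    def cdf(x):
        return q * stats.gamma.cdf(x, s1, scale=1 / r1) + (1 - q) * stats.gamma.cdf(
            x, s2, scale=1 / r2
        )

    lo = min(stats.gamma.ppf(quantile, s1, scale=1 / r1), stats.gamma.ppf(quantile, s2, scale=1 / r2))
    hi = max(stats.gamma.ppf(quantile, s1, scale=1 / r1), stats.gamma.ppf(quantile, s2, scale=1 / r2))
    if hi <= lo:
        eb_lo = lo
    else:
        eb_lo = float(optimize.brentq(lambda x: cdf(x) - quantile, lo * (1 - 1e-9) + 1e-300, hi * (1 + 1e-9)))
    return ebgm_val, eb_lo


def signal_flags(result: SignalResult) -> dict[str, bool]:
    """The four standard signal criteria as booleans.

    ror_sig: CI lower bound > 1; prr_sig: PRR >= 2 and chi2 >= 4;
    bcpnn_sig: IC025 > 0; mgps_sig: EB05 > 1.  Non-estimable statistics
    never flag.
    """
    def ok(x):
        return np.isfinite(x)

    return {
        "ror_sig": bool(ok(result.ror_ci[0]) and result.ror_ci[0] > 1),
        "prr_sig": bool(ok(result.prr) and ok(result.chi2) and result.prr >= 2 and result.chi2 >= 4),
        "bcpnn_sig": bool(ok(result.ic025) and result.ic025 > 0),
        "mgps_sig": bool(ok(result.eb05) and result.eb05 > 1),
    }


def compute_signal(
    table: ContingencyTable,
    hyper: GPSHyperparams | None = None,
    haldane: bool = False,
    yates: bool = True,
    eb_quantile: float = 0.05,
) -> SignalResult:
    """All four estimators on one table (EBGM needs fitted hyperparameters)."""
    ror_est, ror_ci_ = ror(table, haldane=haldane)
    prr_est, prr_ci_, chi2 = prr_chi2(table, haldane=haldane, yates=yates)
    ic, ic025 = bcpnn_ic(table)
    res = SignalResult(
        a=table.a,
        expected=table.expected,
        ror=ror_est,
        ror_ci=ror_ci_,
        prr=prr_est,
        prr_ci=prr_ci_,
        chi2=chi2,
        ic=ic,
        ic025=ic025,
    )
    if hyper is not None:
        eb, eb05 = ebgm(table, hyper, quantile=eb_quantile)
        res = replace(res, ebgm=eb, eb05=eb05)
    return res
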