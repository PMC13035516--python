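"""Time-to-onset (TTO) extraction and Weibull failure modelling.

TTO is the interval in days between therapy initiation (earliest full
therapy start date linked to the primary-suspect drug) and adverse-event
onset.  A two-parameter Weibull is fitted by maximum likelihood; the shape
parameter classifies the temporal reporting pattern:

* shape < 1 — *early failure*: hazard highest immediately after initiation
  and declining (the pattern expected under early worsening of diabetic
  retinopathy after rapid glycemic correction);
* shape ≈ 1 — *random* (exponential, memoryless);
* shape > 1 — *wear-out*: hazard increasing with treatment duration.

Classification uses the 95% CI of the shape (entirely below / above 1),
which is more conservative than a point-estimate rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from statsmodels.tools.numdiff import approx_hess1

from basalvig.cohort import DrugLexicon, DEFAULT_LEXICONS, _match_drug_table
from basalvig.faers_io import CaseStore, is_full_date

Z95 = 1.959963984540054


def compute_tto(
    store: CaseStore,
    report_ids: set[str],
    label: str,
    lexicons: tuple[DrugLexicon, ...] = DEFAULT_LEXICONS,
) -> tuple[pd.DataFrame, dict]:
    """One TTO sample (days) per report, with an exclusion tally.

    For each report, days = event date minus the *earliest* full therapy
    start date among THER rows linked (via ``dsg_drug_seq``) to a DRUG row
    matching the target label.  Same-day and negative intervals are excluded
    (reported onsets start at day 1); partial dates never contribute.
    """
    demo = store.demo[store.demo["primaryid"].isin(report_ids)]
    drug = store.drug[store.drug["primaryid"].isin(report_ids)]
    ther = store.ther[store.ther["primaryid"].isin(report_ids)] if len(store.ther) else store.ther

    tally = {"no event date": 0, "no therapy start": 0, "negative TTO": 0, "same-day": 0}

    matched = _match_drug_table(drug, lexicons) if len(drug) else pd.Series(dtype=object)
    target_drug = drug[matched == label]
    target_pids = set(target_drug["primaryid"])

    # earliest full therapy start per report, restricted to THER rows linked
    # to a target-drug row (rows with a blank link match by report alone)
    if len(ther) and "start_dt" in ther.columns:
        th = ther[ther["primaryid"].isin(target_pids)].copy()
        if "dsg_drug_seq" in th.columns and "drug_seq" in target_drug.columns:
            link = th["dsg_drug_seq"].fillna("").astype(str).str.strip()
            keys = set(zip(target_drug["primaryid"], target_drug["drug_seq"].astype(str).str.strip()))
            linked = pd.Series(list(zip(th["primaryid"], link)), index=th.index).isin(keys)
            th = th[(link == "") | linked]
        th["_start"] = pd.to_datetime(
            th["start_dt"].where(th["start_dt"].map(is_full_date), None),
            format="%Y%m%d", errors="coerce",
        )
        starts = th.dropna(subset=["_start"]).groupby("primaryid")["_start"].min()
    else:
        starts = pd.Series(dtype="datetime64[ns]")

    ev_raw = demo.get("event_dt", pd.Series("", index=demo.index)).fillna("")
    ev = pd.to_datetime(
        ev_raw.where(ev_raw.map(is_full_date), None), format="%Y%m%d", errors="coerce"
    )
    tally["no event date"] = int(ev.isna().sum())
    frame = pd.DataFrame({"primaryid": demo["primaryid"], "event": ev}).dropna(subset=["event"])
    frame = frame.merge(starts.rename("start"), left_on="primaryid", right_index=True, how="left")
    tally["no therapy start"] = int(frame["start"].isna().sum())
    frame = frame.dropna(subset=["start"])
    days = (frame["event"] - frame["start"]).dt.days
    tally["negative TTO"] = int((days < 0).sum())
    tally["same-day"] = int((days == 0).sum())
    keep = days >= 1
    samples = pd.DataFrame(
        {"primaryid": frame.loc[keep, "primaryid"].to_numpy(), "days": days[keep].astype(float).to_numpy()}
    )
    return samples, tally


@dataclass(frozen=True)
class WeibullFit:
    """ML estimates of the two-parameter Weibull on TTO samples (days)."""

    n: int
    shape: float
    scale: float
    shape_ci: tuple[float, float]
    scale_ci: tuple[float, float]
    loglik: float
    median_empirical: float
    tto_range: tuple[float, float]

    @property
    def median_model(self) -> float:
        """Model median: scale * (ln 2)^(1/shape)."""
        return self.scale * np.log(2.0) ** (1.0 / self.shape)

    @property
    def failure_type(self) -> str:
        return classify_failure(self)


def _weibull_nll(theta, x, logx_sum):
    log_k, log_lam = theta
    k, lam = np.exp(log_k), np.exp(log_lam)
    z = (x / lam) ** k
    n = len(x)
    return -(n * np.log(k) - n * k * np.log(lam) + (k - 1) * logx_sum - np.sum(z))


def fit_weibull(samples, min_n: int = 10) -> WeibullFit:
    """Maximum-likelihood Weibull fit with Wald CIs on the log-parameter scale.

    ``samples`` is any 1-d collection of positive durations (days).  The
    optimizer works on (log shape, log scale); 95% CIs come from the observed
    information at the optimum, exponentiated back, so they are always
    positive.  Fewer than 30 samples triggers a warning; degenerate all-equal
    samples raise (the shape diverges).
    """
    if isinstance(samples, pd.DataFrame):
        x = samples["days"].to_numpy(dtype=float)
    else:
        x = np.asarray(samples, dtype=float)
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} samples, got {len(x)}")
    if np.any(x <= 0):
        raise ValueError("durations must be positive")
    if np.ptp(x) == 0:
        raise ValueError("all samples identical; Weibull shape is non-estimable")
    if len(x) < 30:
        import warnings

        warnings.warn(f"only {len(x)} TTO samples; Weibull CIs will be wide")

    logx_sum = float(np.sum(np.log(x)))
    theta0 = np.array([0.0, np.log(np.mean(x))])
    res = optimize.minimize(
        _weibull_nll, theta0, args=(x, logx_sum), method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
    )
    res = optimize.minimize(
        _weibull_nll, res.x, args=(x, logx_sum), method="BFGS",
        options={"gtol": 1e-10},
    )
    log_k, log_lam = res.x
    shape, scale = float(np.exp(log_k)), float(np.exp(log_lam))

    hess = approx_hess1(res.x, _weibull_nll, args=(x, logx_sum))
    cov = np.linalg.inv(hess)
    se_logk, se_loglam = np.sqrt(np.diag(cov))
    shape_ci = (float(np.exp(log_k - Z95 * se_logk)), float(np.exp(log_k + Z95 * se_logk)))
    scale_ci = (float(np.exp(log_lam - Z95 * se_loglam)), float(np.exp(log_lam + Z95 * se_loglam)))

    return WeibullFit(
        n=len(x),
        shape=shape,
        scale=scale,
        shape_ci=shape_ci,
        scale_ci=scale_ci,
        loglik=float(-res.fun),
        median_empirical=float(np.median(x)),
        tto_range=(float(np.min(x)), float(np.max(x))),
    )


def classify_failure(fit: WeibullFit) -> str:
    """'early' if the shape CI lies below 1, 'wear-out' if above, else 'random'."""
    lo, hi = fit.shape_ci
    if hi < 1:
        return "early"
    if lo > 1:
        return "wear-out"
    return "random"


def empirical_band(samples, lo: float = 2.5, hi: float = 97.5) -> tuple[float, float]:
    """Empirical percentile band of the TTO distribution (display companion to
    the median; 2.5–97.5 by default)."""
    if isinstance(samples, pd.DataFrame):
        samples = samples["days"]
    x = np.asarray(samples, dtype=float)
    return float(np.percentile(x, lo)), float(np.percentile(x, hi))
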