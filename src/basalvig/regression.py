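"""Multivariate logistic regression for visual-impairment reporting.

The model contrasts the three basal insulins (insulin degludec as the
reference level) on a binary per-report outcome — a VISUAL IMPAIRMENT
reaction present versus absent — adjusting for sex, age group and body
weight group.  Body weight is missing in the large majority of spontaneous
reports, so every categorical carries an explicit ``missing`` level rather
than dropping rows (complete-case analysis would collapse the sample).

Fitting is maximum likelihood through statsmodels' IRLS machinery with Wald
standard errors from the observed information; terms driven to extreme
magnitude by complete separation are flagged non-estimable instead of being
reported at face value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from basalvig.cohort import (
    DEFAULT_LEXICONS,
    PTSet,
    VISUAL_IMPAIRMENT,
    age_group,
    age_in_years,
    reports_with_event,
    weight_in_kg,
)
from basalvig.faers_io import CaseStore

Z95 = 1.959963984540054

#: |coefficient| beyond which a term is treated as separated / non-estimable
SEPARATION_BOUND = 15.0

REFERENCE_LEVELS = {
    "drug": "insulin_degludec",
    "sex": "Female",
    "age_group": "18-64",
    "wt_group": "wt_q1",
}


def _wt_group(kg: pd.Series, bins: list[float] | None) -> pd.Series:
    """Weight bucket labels; default bins are tertiles of the non-missing kg."""
    out = pd.Series("missing", index=kg.index, dtype=object)
    obs = kg.dropna()
    if len(obs) == 0:
        return out
    if bins is None:
        qs = np.unique(np.quantile(obs, [1 / 3, 2 / 3]))
        bins = list(qs)
    edges = [-np.inf] + list(bins) + [np.inf]
    labels = [f"wt_q{i + 1}" for i in range(len(edges) - 1)]
    out.loc[obs.index] = pd.cut(obs, bins=edges, labels=labels).astype(str)
    return out


def build_design(
    store: CaseStore,
    cohorts: dict[str, set[str]],
    pt_set: PTSet = VISUAL_IMPAIRMENT,
    wt_bins: list[float] | None = None,
) -> pd.DataFrame:
    """One row per primary-suspect report across the given drug cohorts.

    Columns: ``outcome`` (event PT present), ``drug`` (cohort label), ``sex``,
    ``age_group``, ``wt_group`` — all categoricals with explicit ``missing``
    levels.  A report PS for two target insulins contributes one row per
    cohort (consistent with per-drug cohort counting).
    """
    event_ids = reports_with_event(store, pt_set)
    frames = []
    for label, ids in cohorts.items():
        demo = store.demo[store.demo["primaryid"].isin(ids)].copy()
        demo["drug"] = label
        frames.append(demo)
    if not frames:
        raise ValueError("no cohorts supplied")
    demo = pd.concat(frames, ignore_index=True)

    sex = demo.get("sex", pd.Series("", index=demo.index)).fillna("").str.strip().str.upper()
    design = pd.DataFrame(
        {
            "primaryid": demo["primaryid"],
            "drug": demo["drug"],
            "outcome": demo["primaryid"].isin(event_ids).astype(int),
            "sex": sex.map({"F": "Female", "M": "Male"}).fillna("missing"),
        }
    )
    years = demo.apply(lambda r: age_in_years(r.get("age", ""), r.get("age_cod", "")), axis=1)
    design["age_group"] = years.map(age_group).replace({"NA": "missing"})
    kg = demo.apply(lambda r: weight_in_kg(r.get("wt", ""), r.get("wt_cod", "")), axis=1)
    design["wt_group"] = _wt_group(kg, wt_bins)
    return design


@dataclass(frozen=True)
class RegressionResult:
    """Per-term odds ratios with Wald CIs, plus model-level fit summaries."""

    table: pd.DataFrame  # term, coef, se, or_, or_lo, or_hi, p, estimable
    loglik: float
    n: int

    def term(self, name: str) -> pd.Series:
        return self.table.set_index("term").loc[name]


def _encode(
    design: pd.DataFrame, covariates: list[str], references: dict | None = None
) -> tuple[pd.DataFrame, list[str]]:
    cols = {}
    for cov in covariates:
        values = design[cov].astype(str)
        ref = (references or {}).get(cov, REFERENCE_LEVELS.get(cov))
        levels = list(pd.unique(values))
        if ref in levels:
            levels.remove(ref)
            levels = [ref] + sorted(levels)
        else:
            levels = sorted(levels)
        for level in levels[1:]:
            cols[f"{cov}[{level}]"] = (values == level).astype(float)
    X = pd.DataFrame(cols, index=design.index)
    X.insert(0, "const", 1.0)
    return X, list(X.columns)


def fit_logistic(
    design: pd.DataFrame,
    covariates: list[str] | None = None,
    references: dict | None = None,
) -> RegressionResult:
    """Fit the logistic model by maximum likelihood.

    ``covariates`` defaults to every categorical present among
    ``drug, sex, age_group, wt_group``; single-level covariates are dropped
    (nothing to contrast).  ``references`` overrides the default reference
    level per covariate.  Requires at least one event and one non-event.
    """
    if covariates is None:
        covariates = [c for c in ("drug", "sex", "age_group", "wt_group") if c in design.columns]
    covariates = [c for c in covariates if design[c].nunique() > 1]
    y = design["outcome"].to_numpy(dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one event and one non-event")
    X, names = _encode(design, covariates, references)

    model = sm.GLM(y, X.to_numpy(), family=sm.families.Binomial())
    fit = model.fit(maxiter=100, tol=1e-10)

    coefs = fit.params
    ses = fit.bse
    estimable = np.abs(coefs) < SEPARATION_BOUND
    rows = []
    for name, b, se, ok in zip(names, coefs, ses, estimable):
        z = b / se if se > 0 else np.nan
        p = float(2 * (1 - _norm_cdf(abs(z))))
        rows.append(
            {
                "term": name,
                "coef": float(b),
                "se": float(se),
                "or_": float(np.exp(b)) if ok else float("nan"),
                "or_lo": float(np.exp(b - Z95 * se)) if ok else float("nan"),
                "or_hi": float(np.exp(b + Z95 * se)) if ok else float("nan"),
                "p": p if ok else float("nan"),
                "estimable": bool(ok),
            }
        )
    table = pd.DataFrame(rows)
    return RegressionResult(table=table, loglik=float(fit.llf), n=len(y))


def _norm_cdf(x: float) -> float:
    from scipy.stats import norm

    return float(norm.cdf(x))
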