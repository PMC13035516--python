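"""Full-corpus FAERS reference summaries shipped with the package.

These small tables hold the headline summary statistics of the full-scale
FAERS visual-impairment analysis of the three basal insulins (2004 Q1 -
2025 Q2, ~10^5 primary-suspect reports): per-drug demographic counts,
disproportionality statistics for the overall ocular screen and for the
VISUAL IMPAIRMENT endpoint, and the per-drug Weibull time-to-onset rows.
They serve as worked-example inputs and as fixed points for the signal
criteria and the Weibull median identity; the desk-scale pipeline does not
regenerate them (the full corpus is a multi-gigabyte download).

Note on the Weibull table: it is stored under the conventional naming —
``shape`` is the dimensionless exponent (≈0.3–0.44 here, the early-failure
regime) and ``scale`` the characteristic time in days.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

DRUGS = ("insulin_degludec", "insulin_detemir", "insulin_glargine")


def _load(name: str) -> pd.DataFrame:
    with resources.files("basalvig.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_demographics() -> pd.DataFrame:
    """Per-drug demographic counts (sex, country, age group, report year)."""
    return _load("reference_demographics.csv")


def load_signals() -> pd.DataFrame:
    """Disproportionality statistics per drug for the overall ocular screen
    (``scope == 'overall_ocular'``) and the VISUAL IMPAIRMENT endpoint."""
    return _load("reference_signals.csv")


def load_weibull() -> pd.DataFrame:
    """Weibull time-to-onset rows per drug (conventional shape/scale naming)."""
    return _load("reference_weibull.csv")


def cohort_sizes() -> dict[str, int]:
    """Reference per-drug visual/ocular cohort sizes (156, 249, 5380)."""
    sig = load_signals()
    rows = sig[sig["scope"] == "overall_ocular"]
    return dict(zip(rows["drug"], rows["n"].astype(int)))
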