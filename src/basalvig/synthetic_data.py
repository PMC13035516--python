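"""Synthetic FAERS-schema quarters with planted ground truth.

The generator emits DEMO/DRUG/REAC/THER/INDI/OUTC tables in the public
``$``-delimited dialect plus a deleted-case list, so every pipeline stage —
parsing, version deduplication, deleted-case removal, lexicon matching,
fourfold counting, demographics, regression and time-to-onset — can be
exercised and validated against known truths without any download.

What it emulates
----------------
* three basal-insulin cohorts plus a background of unrelated drugs, with
  per-PT event probabilities solved from target reporting odds ratios
  against configurable background rates;
* the demographic mix of the published visual-impairment cohorts
  (≈65% female, ≈94% US, heavy age/weight missingness, mixed KG/LBS units);
* Weibull-distributed onset intervals per drug, rendered as full calendar
  dates (therapy start, event onset, FDA receive date);
* follow-up case versions (ascending ``primaryid``, later or identical
  ``fda_dt``), officially deleted cases, and partial-date corruption.

Report counts default to desk scale (a few 10^4 reports); association
strengths, demographic fractions and onset laws default to the published
full-corpus values, so recovery tests run against realistic conditions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from basalvig.faers_io import CaseStore


def solve_event_prob(target_ror: float, background_rate: float) -> float:
    """Per-report event probability giving the requested reporting odds ratio.

    Solves ``odds(p) / odds(q) = R`` for ``p`` with ``q`` the background
    rate: ``p = R q/(1-q) / (1 + R q/(1-q))``.
    """
    if target_ror <= 0:
        raise ValueError("target ROR must be positive")
    if not 0 < background_rate < 1:
        raise ValueError("background rate must lie in (0, 1)")
    odds = target_ror * background_rate / (1 - background_rate)
    return odds / (1 + odds)


@dataclass
class DrugSpec:
    """Generation parameters for one target-drug cohort."""

    label: str
    names: tuple[str, ...]  # free-text drugnames to emit
    prod_ai: str
    n_reports: int
    target_ror: dict[str, float]  # PT -> planted reporting odds ratio
    tto_shape: float
    tto_scale: float  # days
    wt_missing: float


@dataclass
class SyntheticConfig:
    """Full generator configuration; a fixed seed makes output byte-identical.

    The defaults are the package's reference study conditions: published
    per-PT association strengths for VISUAL IMPAIRMENT / CATARACT / DIABETIC
    RETINOPATHY, the published demographic mix and weight missingness, and
    the published per-drug Weibull onset laws, at desk-scale report counts.
    """

    seed: int = 0
    drugs: tuple[DrugSpec, ...] = (
        DrugSpec(
            "insulin_degludec",
            ("TRESIBA", "TRESIBA FLEXTOUCH", "INSULIN DEGLUDEC"),
            "INSULIN DEGLUDEC",
            2000,
            {"VISUAL IMPAIRMENT": 4.19, "CATARACT": 2.87, "DIABETIC RETINOPATHY": 23.92},
            0.40,
            58.47,
            0.884,
        ),
        DrugSpec(
            "insulin_detemir",
            ("LEVEMIR", "LEVEMIR FLEXPEN", "LEVEMIR PENFILL", "INSULIN DETEMIR"),
            "INSULIN DETEMIR",
            2500,
            {"VISUAL IMPAIRMENT": 4.83, "CATARACT": 5.80, "DIABETIC RETINOPATHY": 36.19},
            0.31,
            127.54,
            0.768,
        ),
        DrugSpec(
            "insulin_glargine",
            ("LANTUS", "LANTUS SOLOSTAR", "BASAGLAR", "INSULIN GLARGINE"),
            "INSULIN GLARGINE",
            8000,
            {"VISUAL IMPAIRMENT": 15.21, "CATARACT": 8.02, "DIABETIC RETINOPATHY": 26.44},
            0.44,
            401.13,
            0.915,
        ),
    )
    n_background: int = 40000
    background_rates: dict = field(
        default_factory=lambda: {
            "VISUAL IMPAIRMENT": 0.02,
            "CATARACT": 0.01,
            "DIABETIC RETINOPATHY": 0.002,
        }
    )
    female_fraction: float = 0.647
    sex_missing: float = 0.04
    country_weights: dict = field(
        default_factory=lambda: {
            "US": 0.945,
            "GB": 0.004,
            "CN": 0.002,
            "JP": 0.001,
            "CA": 0.016,
            "FR": 0.012,
            "DE": 0.010,
            "BR": 0.010,
        }
    )
    age_mean: float = 60.0
    age_sd: float = 15.0
    age_missing: float = 0.45
    wt_mean: float = 85.0
    wt_sd: float = 20.0
    lbs_fraction: float = 0.10
    background_wt_missing: float = 0.85
    #: odds multiplier on VISUAL IMPAIRMENT for the heaviest true weight tertile
    wt_effect_or: float = 0.6
    background_tto_shape: float = 1.0
    background_tto_scale: float = 120.0
    duplicate_rate: float = 0.10
    deleted_rate: float = 0.02
    partial_date_rate: float = 0.10


BACKGROUND_DRUGS = (
    ("METFORMIN", "METFORMIN HYDROCHLORIDE"),
    ("LIPITOR", "ATORVASTATIN CALCIUM"),
    ("LISINOPRIL", "LISINOPRIL"),
    ("HUMIRA", "ADALIMUMAB"),
    ("OZEMPIC", "SEMAGLUTIDE"),
    ("OMEPRAZOLE", "OMEPRAZOLE"),
)

FILLER_PTS = (
    "NAUSEA",
    "HEADACHE",
    "DIZZINESS",
    "FATIGUE",
    "HYPOGLYCAEMIA",
    "INJECTION SITE PAIN",
    "WEIGHT INCREASED",
)


@dataclass
class GroundTruth:
    """The planted truths recorded at generation time.

    ``contingency`` maps ``(drug_label, pt)`` to the exact fourfold cells a
    correct pipeline must recover over the deduplicated, non-deleted store
    (universe = all surviving reports).  ``tto_days`` holds, per drug, the
    exact integer onset intervals of the VISUAL IMPAIRMENT reports that
    survive the full-date filter, so pipeline TTO extraction can be checked
    for equality and the Weibull fit for sample identity.
    """

    n_cases: int
    case_counts: dict  # label -> unique non-deleted case count
    contingency: dict  # (label, pt) -> (a, b, c, d)
    tto_params: dict  # label -> (shape, scale)
    tto_days: dict  # label -> list of planted integer TTO days (full-date VI reports)
    vi_prob: dict  # label -> per-report VI probability (below-top-tertile weight)
    wt_effect_or: float
    duplicate_caseids: list
    deleted_caseids: list

    def to_json(self, path: Path | str) -> None:
        enc = {
            "n_cases": self.n_cases,
            "case_counts": self.case_counts,
            "contingency": {f"{k[0]}|{k[1]}": list(v) for k, v in self.contingency.items()},
            "tto_params": self.tto_params,
            "tto_days": self.tto_days,
            "vi_prob": self.vi_prob,
            "wt_effect_or": self.wt_effect_or,
            "duplicate_caseids": self.duplicate_caseids,
            "deleted_caseids": self.deleted_caseids,
        }
        Path(path).write_text(json.dumps(enc, indent=1))


@dataclass
class SyntheticQuarter:
    """Generated tables plus the deleted list and ground truth."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    indi: pd.DataFrame
    outc: pd.DataFrame
    deleted: list
    ground_truth: GroundTruth

    def to_store(self) -> CaseStore:
        """In-memory CaseStore equivalent to writing and re-reading the files."""
        return CaseStore(
            demo=self.demo.copy(),
            drug=self.drug.copy(),
            reac=self.reac.copy(),
            ther=self.ther.copy(),
            indi=self.indi.copy(),
            outc=self.outc.copy(),
            provenance={"synthetic"},
        )

    def write(self, outdir: Path | str) -> dict[str, Path]:
        """Write the ``$``-delimited quarter files and the deleted-case list."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("demo", "drug", "reac", "ther", "indi", "outc"):
            path = outdir / f"{name}.txt"
            frame = getattr(self, name)
            with open(path, "w", newline="\n") as fh:
                fh.write("$".join(frame.columns) + "\n")
                for row in frame.itertuples(index=False):
                    fh.write("$".join(str(v) for v in row) + "\n")
            paths[name] = path
        del_path = outdir / "deleted_cases.txt"
        del_path.write_text("".join(f"{c}\n" for c in self.deleted))
        paths["deleted"] = del_path
        self.ground_truth.to_json(outdir / "ground_truth.json")
        return paths


def _fmt_dates(ts: pd.Series) -> pd.Series:
    return ts.dt.strftime("%Y%m%d")


def generate(config: SyntheticConfig | None = None) -> SyntheticQuarter:
    """Generate one synthetic quarter (deterministic in ``config.seed``)."""
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)

    labels = np.concatenate(
        [np.repeat(d.label, d.n_reports) for d in cfg.drugs]
        + [np.repeat("background", cfg.n_background)]
    )
    n = len(labels)
    caseid_num = np.arange(10_000_001, 10_000_001 + n)

    # --- demographics --------------------------------------------------
    u_sex = rng.random(n)
    sex = np.where(u_sex < cfg.sex_missing, "", np.where(
        u_sex < cfg.sex_missing + (1 - cfg.sex_missing) * cfg.female_fraction, "F", "M"))

    countries = list(cfg.country_weights)
    cw = np.array([cfg.country_weights[c] for c in countries], dtype=float)
    country = rng.choice(countries, size=n, p=cw / cw.sum())

    age_years = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, n), 18.5, 95.0)
    age_cod = rng.choice(["YR", "DEC", "MON"], size=n, p=[0.90, 0.08, 0.02])
    age_val = np.where(
        age_cod == "YR", np.round(age_years, 0),
        np.where(age_cod == "DEC", np.round(age_years / 10.0, 1), np.round(age_years * 12.0, 0)),
    )
    age_missing_mask = rng.random(n) < cfg.age_missing
    age_str = np.where(age_missing_mask, "", age_val.astype(str))
    age_cod_str = np.where(age_missing_mask, "", age_cod)

    kg = np.clip(rng.normal(cfg.wt_mean, cfg.wt_sd, n), 35.0, 190.0)
    wt_cod = np.where(rng.random(n) < cfg.lbs_fraction, "LBS", "KG")
    wt_val = np.where(wt_cod == "LBS", np.round(kg / 0.453592, 1), np.round(kg, 1))
    wt_missing_frac = np.full(n, cfg.background_wt_missing)
    for d in cfg.drugs:
        wt_missing_frac[labels == d.label] = d.wt_missing
    wt_missing_mask = rng.random(n) < wt_missing_frac
    wt_str = np.where(wt_missing_mask, "", wt_val.astype(str))
    wt_cod_str = np.where(wt_missing_mask, "", wt_cod)

    # --- events ---------------------------------------------------------
    # per-PT probabilities; the VI probability additionally carries the
    # planted protective odds multiplier for the heaviest true-weight tertile
    top_tertile = kg > np.quantile(kg, 2 / 3)
    pts = list(cfg.background_rates)
    event = {}
    vi_prob_by_label: dict[str, float] = {}
    for pt in pts:
        q = cfg.background_rates[pt]
        p = np.full(n, q)
        for d in cfg.drugs:
            p_drug = solve_event_prob(d.target_ror.get(pt, 1.0), q)
            p[labels == d.label] = p_drug
            if pt == "VISUAL IMPAIRMENT":
                vi_prob_by_label[d.label] = p_drug
        if pt == "VISUAL IMPAIRMENT":
            vi_prob_by_label["background"] = q
            odds = p / (1 - p) * np.where(top_tertile, cfg.wt_effect_or, 1.0)
            p = odds / (1 + odds)
        event[pt] = rng.random(n) < p

    # --- dates ----------------------------------------------------------
    t0 = pd.Timestamp("2004-01-01")
    start_offset = rng.integers(0, int((pd.Timestamp("2024-06-30") - t0).days), n)
    start_dt = t0 + pd.to_timedelta(start_offset, unit="D")

    any_vi = event.get("VISUAL IMPAIRMENT", np.zeros(n, bool))
    delta = np.ceil(cfg.background_tto_scale * rng.weibull(cfg.background_tto_shape, n))
    # per-drug planted Weibull onset law for VI reports
    for d in cfg.drugs:
        mask = (labels == d.label) & any_vi
        raw = d.tto_scale * rng.weibull(d.tto_shape, int(mask.sum()))
        delta[mask] = np.ceil(raw)
    delta = np.maximum(delta, 1.0).astype(int)
    # a report only exists if the event fell inside the data window: onset
    # intervals are right-truncated at the cutoff, as in any quarterly corpus
    cap = pd.Timestamp("2025-06-30")
    window = (cap - start_dt).days.to_numpy()
    delta = np.minimum(delta, np.maximum(window - 90, 1))
    event_dt = start_dt + pd.to_timedelta(delta, unit="D")
    fda_dt = event_dt + pd.to_timedelta(rng.integers(2, 90, n), unit="D")
    fda_dt = fda_dt.where(fda_dt <= cap, cap)

    # --- deletions, duplicates, partial dates ---------------------------
    deleted_mask = rng.random(n) < cfg.deleted_rate
    dup_mask = rng.random(n) < cfg.duplicate_rate
    dup_same_fda = rng.random(n) < 0.5  # half the duplicates share fda_dt exactly

    partial_mask = rng.random(n) < cfg.partial_date_rate
    partial_on_start = rng.random(n) < 0.5

    start_str = _fmt_dates(pd.Series(start_dt))
    event_str = _fmt_dates(pd.Series(event_dt))
    start_str = start_str.where(~(partial_mask & partial_on_start), start_str.str.slice(0, 6))
    event_str = event_str.where(~(partial_mask & ~partial_on_start), event_str.str.slice(0, 6))
    fda_str = _fmt_dates(pd.Series(fda_dt))

    caseid = caseid_num.astype(str)
    primaryid_latest = (caseid_num * 100 + 2).astype(str)
    primaryid_old = (caseid_num * 100 + 1).astype(str)

    # --- assemble tables -------------------------------------------------
    base_demo = pd.DataFrame(
        {
            "primaryid": primaryid_latest,
            "caseid": caseid,
            "fda_dt": fda_str,
            "event_dt": event_str,
            "age": age_str,
            "age_cod": age_cod_str,
            "sex": sex,
            "wt": wt_str,
            "wt_cod": wt_cod_str,
            "occr_country": country,
        }
    )
    old_demo = base_demo[dup_mask].copy()
    old_demo["primaryid"] = primaryid_old[dup_mask]
    earlier = pd.Series(fda_dt[dup_mask] - pd.to_timedelta(30, unit="D")).dt.strftime("%Y%m%d")
    old_demo["fda_dt"] = np.where(dup_same_fda[dup_mask], old_demo["fda_dt"], earlier.to_numpy())
    demo = pd.concat([base_demo, old_demo], ignore_index=True)

    drugname = np.empty(n, dtype=object)
    prod_ai = np.empty(n, dtype=object)
    for d in cfg.drugs:
        mask = labels == d.label
        drugname[mask] = rng.choice(d.names, size=int(mask.sum()))
        prod_ai[mask] = d.prod_ai
    bg_mask = labels == "background"
    bg_idx = rng.integers(0, len(BACKGROUND_DRUGS), int(bg_mask.sum()))
    drugname[bg_mask] = [BACKGROUND_DRUGS[i][0] for i in bg_idx]
    prod_ai[bg_mask] = [BACKGROUND_DRUGS[i][1] for i in bg_idx]

    def _child(pid, case_mask=None):
        """DRUG/THER/REAC builder for one version's primaryid column."""
        idx = np.arange(n) if case_mask is None else np.flatnonzero(case_mask)
        dr = pd.DataFrame(
            {
                "primaryid": pid[idx],
                "caseid": caseid[idx],
                "drug_seq": "1",
                "role_cod": "PS",
                "drugname": drugname[idx],
                "prod_ai": prod_ai[idx],
            }
        )
        th = pd.DataFrame(
            {
                "primaryid": pid[idx],
                "caseid": caseid[idx],
                "dsg_drug_seq": "1",
                "start_dt": start_str.to_numpy()[idx],
            }
        )
        reac_frames = [
            pd.DataFrame(
                {
                    "primaryid": pid[idx],
                    "caseid": caseid[idx],
                    "pt": rng.choice(FILLER_PTS, size=len(idx)),
                }
            )
        ]
        for pt in pts:
            sel = idx[event[pt][idx]]
            if len(sel):
                reac_frames.append(
                    pd.DataFrame({"primaryid": pid[sel], "caseid": caseid[sel], "pt": pt})
                )
        return dr, th, pd.concat(reac_frames, ignore_index=True)

    dr1, th1, rc1 = _child(primaryid_latest)
    dr0, th0, rc0 = _child(primaryid_old, dup_mask)
    drug = pd.concat([dr1, dr0], ignore_index=True)
    ther = pd.concat([th1, th0], ignore_index=True)
    reac = pd.concat([rc1, rc0], ignore_index=True)

    indi = pd.DataFrame(
        {
            "primaryid": primaryid_latest[~bg_mask],
            "caseid": caseid[~bg_mask],
            "indi_drug_seq": "1",
            "indi_pt": "DIABETES MELLITUS",
        }
    )
    outc = pd.DataFrame(
        {
            "primaryid": primaryid_latest,
            "caseid": caseid,
            "outc_cod": rng.choice(["OT", "HO", "DS"], size=n, p=[0.7, 0.2, 0.1]),
        }
    )

    # stable emission order so byte-identity holds under the same seed
    for frame in (demo, drug, reac, ther):
        frame.sort_values(["caseid", "primaryid"], inplace=True, kind="mergesort")
        frame.reset_index(drop=True, inplace=True)

    # --- ground truth -----------------------------------------------------
    alive = ~deleted_mask
    truth_cont = {}
    for pt in pts:
        ev = event[pt] & alive
        for d in cfg.drugs:
            tmask = (labels == d.label) & alive
            a = int((ev & tmask).sum())
            b = int(tmask.sum()) - a
            c = int(ev.sum()) - a
            dd = int(alive.sum()) - a - b - c
            truth_cont[(d.label, pt)] = (a, b, c, dd)

    full_dates = ~partial_mask  # a corrupted report lost either its start or event date
    tto_days = {}
    for d in cfg.drugs:
        mask = (labels == d.label) & any_vi & alive & full_dates
        tto_days[d.label] = [int(v) for v in delta[mask]]

    truth = GroundTruth(
        n_cases=int(alive.sum()),
        case_counts={d.label: int(((labels == d.label) & alive).sum()) for d in cfg.drugs},
        contingency=truth_cont,
        tto_params={d.label: (d.tto_shape, d.tto_scale) for d in cfg.drugs},
        tto_days=tto_days,
        vi_prob=vi_prob_by_label,
        wt_effect_or=cfg.wt_effect_or,
        duplicate_caseids=[str(c) for c in caseid[dup_mask]],
        deleted_caseids=[str(c) for c in caseid[deleted_mask]],
    )

    return SyntheticQuarter(
        demo=demo, drug=drug, reac=reac, ther=ther, indi=indi, outc=outc,
        deleted=[str(c) for c in caseid[deleted_mask]], ground_truth=truth,
    )
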