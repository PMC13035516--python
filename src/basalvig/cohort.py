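"""Target-drug cohorting and fourfold-table construction.

Drug identification works on FAERS free-text ``drugname``/``prod_ai`` fields
through small name lexicons (active ingredient + trade names) with
case/punctuation-insensitive substring matching.  Event cohorting selects
reports carrying at least one MedDRA preferred term (PT) from a configured
set; the shipped defaults cover the ocular safety screen with VISUAL
IMPAIRMENT as the primary functional endpoint.

The counting unit throughout is the deduplicated report: a report falls in
exactly one cell of the fourfold table however many matching drug or
reaction rows it carries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from basalvig.faers_io import CaseStore

_PUNCT = re.compile(r"[^A-Z0-9 ]+")
_WS = re.compile(r"\s+")


def normalize_name(text) -> str:
    """Uppercase, strip punctuation to spaces, collapse whitespace."""
    if text is None or (isinstance(text, float) and np.isnan(text)):
        return ""
    up = str(text).upper()
    up = _PUNCT.sub(" ", up)
    return _WS.sub(" ", up).strip()


@dataclass(frozen=True)
class DrugLexicon:
    """Name patterns identifying one active ingredient.

    ``match_mode='substring'`` (default) matches a normalized pattern anywhere
    inside the normalized field — FAERS free text is noisy, with dose/strength
    suffixes and combination products; ``'exact'`` requires the whole field to
    equal a pattern and is intended for sensitivity analyses.
    """

    ingredient: str
    patterns: tuple[str, ...]
    match_mode: str = "substring"

    def __post_init__(self):
        if not self.patterns:
            raise ValueError("lexicon needs at least one pattern")
        norm = tuple(dict.fromkeys(normalize_name(p) for p in self.patterns))
        object.__setattr__(self, "patterns", norm)


def _expand_terms(terms: list[str]) -> list[str]:
    """Split '+'-joined trade-name pairs (e.g. 'Lantus+Basaglar') into tokens."""
    out: list[str] = []
    for t in terms:
        out.extend(part for part in t.split("+") if part.strip())
    return out


DEFAULT_LEXICONS: tuple[DrugLexicon, ...] = (
    DrugLexicon("insulin_degludec", tuple(_expand_terms(["Tresiba", "Insulin Degludec"]))),
    DrugLexicon(
        "insulin_detemir",
        tuple(_expand_terms(["Insulin Detemir", "Levemir", "Levemir FlexPen", "Levemir PenFill"])),
    ),
    DrugLexicon(
        "insulin_glargine",
        tuple(_expand_terms(["LANTUS SOLOSTAR", "Insulin Glargine", "Lantus+Basaglar"])),
    ),
)

DRUG_LABELS = tuple(lex.ingredient for lex in DEFAULT_LEXICONS)

#: tokens whose presence marks a combination product (e.g. glargine+lixisenatide)
_COMBINATION_MARKERS = (" AND ", " WITH ", " PLUS ")


@dataclass(frozen=True)
class PTSet:
    """A named set of MedDRA preferred terms, case-normalized."""

    name: str
    terms: tuple[str, ...]

    def __post_init__(self):
        norm = tuple(dict.fromkeys(normalize_name(t) for t in self.terms))
        object.__setattr__(self, "terms", norm)

    def __contains__(self, pt) -> bool:
        return normalize_name(pt) in self.terms


VISUAL_IMPAIRMENT = PTSet("visual_impairment", ("VISUAL IMPAIRMENT",))

# The ocular screen is config-supplied; the shipped default carries the eight
# named terms of the published screen, the remaining slots being user-supplied.
OCULAR_PTS = PTSet(
    "ocular",
    (
        "VISUAL IMPAIRMENT",
        "CATARACT",
        "BLINDNESS",
        "MACULAR DEGENERATION",
        "EYE HAEMORRHAGE",
        "DIABETIC RETINOPATHY",
        "RETINOPATHY",
        "DIABETIC GLAUCOMA",
    ),
)


def match_drug(
    drugname,
    prod_ai=None,
    lexicons: tuple[DrugLexicon, ...] = DEFAULT_LEXICONS,
) -> tuple[str | None, set[str]]:
    """Match one drug row against the lexicons.

    Returns ``(canonical_label | None, flags)`` where flags may contain
    ``"ambiguous"`` (patterns of two different ingredients matched — the row
    should be excluded and tallied) and ``"combination"`` (the field names a
    multi-ingredient product; such rows match but carry the flag).
    """
    fields = [normalize_name(drugname), normalize_name(prod_ai)]
    if not any(fields):
        return None, set()
    hits: list[str] = []
    flags: set[str] = set()
    for lex in lexicons:
        matched = False
        for fld in fields:
            if not fld:
                continue
            for pat in lex.patterns:
                if (lex.match_mode == "substring" and pat in fld) or (
                    lex.match_mode == "exact" and pat == fld
                ):
                    matched = True
                    break
            if matched:
                break
        if matched:
            hits.append(lex.ingredient)
    if not hits:
        return None, flags
    padded = [f" {f} " for f in fields if f]
    if any(marker in f for f in padded for marker in _COMBINATION_MARKERS):
        flags.add("combination")
    if len(hits) > 1:
        flags.add("ambiguous")
        return None, flags
    return hits[0], flags


def _match_drug_table(drug: pd.DataFrame, lexicons) -> pd.Series:
    """Vectorized-ish canonical label per DRUG row (None where no/ambiguous match)."""
    prod = drug["prod_ai"] if "prod_ai" in drug.columns else pd.Series("", index=drug.index)
    labels = []
    cache: dict[tuple, str | None] = {}
    for name, ai in zip(drug["drugname"].fillna(""), prod.fillna("")):
        key = (name, ai)
        if key not in cache:
            label, flags = match_drug(name, ai, lexicons)
            cache[key] = None if "ambiguous" in flags else label
        labels.append(cache[key])
    return pd.Series(labels, index=drug.index, dtype=object)


def primary_suspect_reports(
    store: CaseStore,
    label: str,
    lexicons: tuple[DrugLexicon, ...] = DEFAULT_LEXICONS,
) -> set[str]:
    """Primaryids of deduplicated reports naming ``label`` as primary suspect."""
    drug = store.drug
    if len(drug) == 0:
        return set()
    ps = drug[drug.get("role_cod", pd.Series("", index=drug.index)).fillna("").str.strip().str.upper() == "PS"]
    if len(ps) == 0:
        return set()
    matched = _match_drug_table(ps, lexicons)
    return set(ps.loc[matched == label, "primaryid"])


def all_target_cohorts(
    store: CaseStore, lexicons: tuple[DrugLexicon, ...] = DEFAULT_LEXICONS
) -> dict[str, set[str]]:
    """PS report-id sets for every lexicon ingredient (a report PS for two
    target insulins appears in both cohorts)."""
    return {lex.ingredient: primary_suspect_reports(store, lex.ingredient, lexicons) for lex in lexicons}


@dataclass(frozen=True)
class ContingencyTable:
    """Fourfold report counts for one (drug, event-set) pair.

    ``a``: target-drug reports with the event, ``b``: without; ``c``/``d``
    the same over the comparator universe.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected count in cell a under row/column independence: (a+b)(a+c)/n."""
        if self.n == 0:
            return float("nan")
        return (self.a + self.b) * (self.a + self.c) / self.n

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


def reports_with_event(store: CaseStore, pt_set: PTSet) -> set[str]:
    """Primaryids with at least one reaction PT in the set."""
    reac = store.reac
    if len(reac) == 0 or "pt" not in reac.columns:
        return set()
    norm = reac["pt"].map(normalize_name)
    return set(reac.loc[norm.isin(set(pt_set.terms)), "primaryid"])


def build_contingency(
    store: CaseStore,
    label: str,
    pt_set: PTSet,
    lexicons: tuple[DrugLexicon, ...] = DEFAULT_LEXICONS,
    comparator_exclude: set[str] | None = None,
) -> ContingencyTable:
    """Fourfold table for one target drug against all other reports.

    The universe is every report in the (deduplicated) store; the comparator
    is the universe minus the target cohort minus ``comparator_exclude``
    (used to keep reports PS for a *different* target insulin out of this
    drug's comparator when desired).
    """
    universe = set(store.demo["primaryid"])
    target = primary_suspect_reports(store, label, lexicons) & universe
    comparator = universe - target - (comparator_exclude or set())
    if not comparator:
        raise ValueError("comparator universe empty")
    event = reports_with_event(store, pt_set)
    a = len(target & event)
    b = len(target) - a
    c = len(comparator & event)
    d = len(comparator) - c
    return ContingencyTable(a, b, c, d)


def pair_count_universe(
    store: CaseStore, lexicons: tuple[DrugLexicon, ...] = DEFAULT_LEXICONS
) -> pd.DataFrame:
    """Observed/expected counts for every (PS drug, PT) pair in the store.

    The counting unit is the report: each report contributes its
    primary-suspect drug (canonical label where a lexicon matches, otherwise
    the normalized free-text name) crossed with its distinct reaction PTs.
    ``expected`` is the row/column independence value (a+b)(a+c)/n.  This is
    the universe over which empirical-Bayes (MGPS) hyperparameters are fit.
    """
    drug = store.drug
    ps = drug[drug.get("role_cod", pd.Series("", index=drug.index)).fillna("").str.strip().str.upper() == "PS"]
    matched = _match_drug_table(ps, lexicons)
    names = matched.where(matched.notna(), ps["drugname"].map(normalize_name))
    report_drug = (
        pd.DataFrame({"primaryid": ps["primaryid"], "drug": names})
        .drop_duplicates()
    )
    reac = store.reac[["primaryid", "pt"]].copy()
    reac["pt"] = reac["pt"].map(normalize_name)
    reac = reac[reac["pt"] != ""].drop_duplicates()

    pairs = report_drug.merge(reac, on="primaryid")
    observed = pairs.groupby(["drug", "pt"]).size().rename("observed").reset_index()
    n_total = store.n_reports
    n_drug = report_drug.groupby("drug")["primaryid"].nunique()
    n_pt = reac.groupby("pt")["primaryid"].nunique()
    observed["expected"] = (
        observed["drug"].map(n_drug) * observed["pt"].map(n_pt) / n_total
    )
    return observed


# --- demographics -----------------------------------------------------------

#: multiplicative factors converting an age value to years, by unit code
AGE_UNIT_TO_YEARS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1 / 12.0,
    "WK": 1 / 52.14,
    "DY": 1 / 365.25,
    "HR": 1 / 8766.0,
}

COUNTRY_DISPLAY = {
    "US": "United States",
    "JP": "Japan",
    "GB": "United Kingdom",
    "CN": "China",
}

AGE_GROUPS = ("<18", "18-64", ">65", "NA")


def age_in_years(age, age_cod) -> float:
    """Convert a FAERS age value + unit code to years; NaN when unusable."""
    try:
        v = float(age)
    except (TypeError, ValueError):
        return float("nan")
    factor = AGE_UNIT_TO_YEARS.get(str(age_cod).strip().upper(), 1.0 if str(age_cod).strip() == "" else None)
    if factor is None:
        return float("nan")
    return v * factor


def age_group(years: float) -> str:
    """Age bucket; the >=65 boundary goes to '>65' (the published labels leave
    65 itself ambiguous — documented choice)."""
    if years is None or np.isnan(years):
        return "NA"
    if years < 18:
        return "<18"
    if years < 65:
        return "18-64"
    return ">65"


def weight_in_kg(wt, wt_cod) -> float:
    try:
        v = float(wt)
    except (TypeError, ValueError):
        return float("nan")
    code = str(wt_cod).strip().upper()
    if code == "LBS":
        return v * 0.453592
    if code in ("KG", "KGS", ""):
        return v
    return float("nan")


def summarize_demographics(store: CaseStore, report_ids: set[str]) -> pd.DataFrame:
    """Counts and percentages by sex, country, age group and report year.

    Returns a tidy frame ``(variable, level, count, percent)`` whose counts
    within each variable sum to the cohort size (an explicit ``NA`` level
    absorbs missing values, so nothing is dropped).
    """
    demo = store.demo[store.demo["primaryid"].isin(report_ids)]
    n = len(demo)
    rows: list[tuple[str, str, int]] = []

    sex = demo.get("sex", pd.Series("", index=demo.index)).fillna("").str.strip().str.upper()
    sex_lab = sex.map({"F": "Female", "M": "Male"}).fillna("NA").replace({"": "NA"})
    for level in ("Female", "Male", "NA"):
        rows.append(("sex", level, int((sex_lab == level).sum())))

    country = demo.get("occr_country", pd.Series("", index=demo.index)).fillna("").str.strip().str.upper()
    disp = country.map(COUNTRY_DISPLAY)
    disp[country == ""] = "Others"
    disp = disp.fillna("Others")
    for level in ("United States", "Japan", "United Kingdom", "China", "Others"):
        rows.append(("country", level, int((disp == level).sum())))

    ages = demo.apply(
        lambda r: age_in_years(r.get("age", ""), r.get("age_cod", "")), axis=1
    ) if n else pd.Series(dtype=float)
    groups = ages.map(age_group) if n else pd.Series(dtype=object)
    for level in AGE_GROUPS:
        rows.append(("age_group", level, int((groups == level).sum()) if n else 0))

    years = demo.get("fda_dt", pd.Series("", index=demo.index)).fillna("").str.slice(0, 4)
    year_counts = years[years.str.fullmatch(r"\d{4}")].value_counts().sort_index()
    for year, count in year_counts.items():
        rows.append(("year", year, int(count)))
    n_bad_year = n - int(year_counts.sum())
    if n_bad_year:
        rows.append(("year", "NA", n_bad_year))

    out = pd.DataFrame(rows, columns=["variable", "level", "count"])
    out["percent"] = np.where(n > 0, 100.0 * out["count"] / max(n, 1), 0.0)
    out.attrs["n"] = n
    return out
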