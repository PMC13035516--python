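"""Reading and cleaning FAERS quarterly ASCII extracts.

FAERS quarters ship as ``$``-delimited text tables (DEMO, DRUG, REAC, INDI,
THER, OUTC) with a header line naming the columns.  The schema drifts across
years (columns appear and disappear), so everything here is read by header
name, never by position, and all fields are kept as strings until a later
stage normalizes them.

Case-level deduplication follows standard FDA practice: a case (``caseid``)
accumulates follow-up versions (``primaryid``); rows with identical
``(caseid, fda_dt)`` beyond the first are dropped, then only the highest
``primaryid`` per case is kept, and cases on the official deleted list are
removed entirely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

log = logging.getLogger(__name__)

TABLE_NAMES = ("demo", "drug", "reac", "ther", "indi", "outc")

#: columns that must be present in every table
MANDATORY_COLUMNS = ("primaryid", "caseid")


class FaersFormatError(ValueError):
    """A quarterly file is structurally unusable (e.g. missing a key column)."""


@dataclass
class CaseStore:
    """Joined view of one or more ingested quarters, keyed by ``primaryid``.

    Each attribute is a string-typed :class:`pandas.DataFrame` holding one
    FAERS table; ``provenance`` records the quarter labels ingested and
    ``tallies`` accumulates row/exclusion counts from the cleaning steps.
    """

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    indi: pd.DataFrame = field(default_factory=pd.DataFrame)
    outc: pd.DataFrame = field(default_factory=pd.DataFrame)
    provenance: set = field(default_factory=set)
    tallies: dict = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in TABLE_NAMES}

    @property
    def n_reports(self) -> int:
        return len(self.demo)

    def filter_primaryids(self, keep: Iterable[str]) -> "CaseStore":
        """New store restricted to the given primaryids (child tables follow DEMO)."""
        keep = set(keep)
        kw = {
            name: tab[tab["primaryid"].isin(keep)].reset_index(drop=True)
            if len(tab)
            else tab
            for name, tab in self.tables().items()
        }
        return CaseStore(**kw, provenance=set(self.provenance), tallies=dict(self.tallies))


def _read_dollar_table(path: Path) -> pd.DataFrame:
    """Read one ``$``-delimited table, reconciling rows with stray ``$`` signs.

    Free-text fields (drug names, verbatim reactions) occasionally contain a
    literal ``$``.  Overlong rows are repaired best-effort by folding the
    surplus splits back into the last column; short rows are padded with
    empty strings.  Both repairs are counted and logged.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        header_line = fh.readline().rstrip("\n").rstrip("\r")
        columns = [c.strip().lower() for c in header_line.split("$")]
        ncol = len(columns)
        rows: list[list[str]] = []
        repaired = skipped = 0
        for raw in fh:
            raw = raw.rstrip("\n").rstrip("\r")
            if not raw:
                continue
            parts = raw.split("$")
            if len(parts) > ncol:
                parts = parts[: ncol - 1] + ["$".join(parts[ncol - 1:])]
                repaired += 1
            elif len(parts) < ncol:
                if len(parts) <= 1:  # junk line, nothing to anchor on
                    skipped += 1
                    continue
                parts = parts + [""] * (ncol - len(parts))
                repaired += 1
            rows.append(parts)
    frame = pd.DataFrame(rows, columns=columns, dtype=str)
    log.info("read %s: %d rows (%d repaired, %d skipped)", path.name, len(frame), repaired, skipped)
    for col in MANDATORY_COLUMNS:
        if col not in frame.columns:
            raise FaersFormatError(f"{path}: mandatory column {col!r} missing from header")
    frame.attrs["skipped_rows"] = skipped
    frame.attrs["repaired_rows"] = repaired
    return frame


def read_quarter(paths: Mapping[str, Path | str], quarter: str = "") -> CaseStore:
    """Parse one quarter's table files into a :class:`CaseStore` fragment.

    Parameters
    ----------
    paths
        Mapping from table name (``demo``, ``drug``, ``reac``, ``ther``,
        optionally ``indi``/``outc``) to the file path.  DEMO, DRUG and REAC
        are required for any downstream analysis; missing optional tables
        become empty frames.
    quarter
        Label recorded in the store's provenance (e.g. ``"2024q1"``).
    """
    tabs: dict[str, pd.DataFrame] = {}
    for name in TABLE_NAMES:
        if name in paths:
            tabs[name] = _read_dollar_table(Path(paths[name]))
        else:
            tabs[name] = pd.DataFrame(columns=list(MANDATORY_COLUMNS), dtype=str)
    store = CaseStore(**tabs, provenance={quarter} if quarter else set())
    store.tallies["rows_read"] = {n: len(t) for n, t in store.tables().items()}
    return store


def read_deleted_list(path: Path | str) -> list[str]:
    """Deleted-case list: one caseid per line, blanks and header-ish lines ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.lower().startswith("caseid"):
            out.append(line)
    return out


def concat_stores(stores: Iterable[CaseStore]) -> CaseStore:
    """Stack multiple quarter fragments into one store (no dedup applied)."""
    stores = list(stores)
    kw = {
        name: pd.concat([s.tables()[name] for s in stores], ignore_index=True)
        for name in TABLE_NAMES
    }
    prov = set().union(*(s.provenance for s in stores))
    return CaseStore(**kw, provenance=prov)


def _primaryid_sort_key(series: pd.Series) -> pd.Series:
    """Numeric primaryid ordering, falling back to zero-padded lexicographic."""
    numeric = pd.to_numeric(series, errors="coerce")
    if numeric.isna().any():
        bad = series[numeric.isna()].unique()[:5]
        log.warning("non-numeric primaryid values (e.g. %s); using padded string order", list(bad))
        width = series.str.len().max()
        return series.str.zfill(int(width))
    return numeric


def deduplicate(store: CaseStore, deleted: Iterable[str] | None = None) -> CaseStore:
    """Reduce the store to the latest version of each case.

    Three rules, applied in order (the composite is order-invariant and
    idempotent, which the test suite asserts on adversarial fixtures):

    1. among rows sharing both ``caseid`` and ``fda_dt``, keep one;
    2. among remaining versions of a ``caseid``, keep the highest
       ``primaryid`` (numeric comparison, padded-string fallback);
    3. drop every record whose ``caseid`` is on the deleted-case list.

    Child tables are filtered to the surviving primaryids.
    """
    demo = store.demo
    n0 = len(demo)
    if n0 == 0:
        return store

    key = _primaryid_sort_key(demo["primaryid"])
    demo = demo.assign(_pid_order=key)

    # rule 1: identical (caseid, fda_dt) duplicates — keep the highest-primaryid row
    # so the composite result does not depend on input row order
    fda = demo["fda_dt"] if "fda_dt" in demo.columns else pd.Series("", index=demo.index)
    demo = (
        demo.assign(_fda=fda.fillna(""))
        .sort_values(["caseid", "_fda", "_pid_order"], kind="mergesort")
        .drop_duplicates(subset=["caseid", "_fda"], keep="last")
    )
    n_dupdate = n0 - len(demo)

    # rule 2: latest case version
    demo = demo.sort_values(["caseid", "_pid_order"], kind="mergesort").drop_duplicates(
        subset=["caseid"], keep="last"
    )
    n_versions = n0 - n_dupdate - len(demo)

    # rule 3: officially deleted cases
    n_deleted = 0
    if deleted:
        deleted = {str(c) for c in deleted}
        before = len(demo)
        demo = demo[~demo["caseid"].isin(deleted)]
        n_deleted = before - len(demo)
    elif deleted is None:
        log.warning("no deleted-case list supplied; deletion step is a no-op")

    demo = demo.drop(columns=["_pid_order", "_fda"]).sort_values("caseid", kind="mergesort")
    out = store.filter_primaryids(demo["primaryid"])
    out.demo = demo.reset_index(drop=True)
    out.tallies = dict(store.tallies)
    out.tallies["dedup"] = {
        "input_rows": n0,
        "duplicate_date_rows": n_dupdate,
        "superseded_versions": n_versions,
        "deleted_cases": n_deleted,
        "surviving_reports": len(demo),
    }
    log.info("dedup: %s", out.tallies["dedup"])
    return out


def is_full_date(value) -> bool:
    """True for a complete 8-digit calendar date (partial 4/6-digit dates fail)."""
    s = str(value).strip() if value is not None else ""
    if len(s) != 8 or not s.isdigit():
        return False
    return parse_date8(s) is not None


def parse_date8(value) -> pd.Timestamp | None:
    """Parse an 8-digit FAERS date; None when partial, blank, or invalid."""
    s = str(value).strip() if value is not None else ""
    if len(s) != 8 or not s.isdigit():
        return None
    ts = pd.to_datetime(s, format="%Y%m%d", errors="coerce")
    return None if pd.isna(ts) else ts


def exclude_incomplete(store: CaseStore, stage: str = "signal") -> tuple[CaseStore, dict]:
    """Drop reports lacking the clinical information a given stage needs.

    ``signal``
        requires at least one reaction row and one drug row (an adverse-event
        description and a drug exposure).
    ``tto``
        additionally requires a full 8-digit event date and at least one full
        therapy start date.
    ``regression``
        no extra requirement — missing covariates become explicit
        "missing" categories downstream.

    Returns the filtered store and a tally of exclusions per reason.
    """
    if stage not in ("signal", "tto", "regression"):
        raise ValueError(f"unknown stage {stage!r}")
    demo = store.demo
    keep = pd.Series(True, index=demo.index)
    tally: dict[str, int] = {}

    if stage in ("signal", "tto"):
        with_reac = set(store.reac.loc[store.reac["pt"].fillna("").str.strip() != "", "primaryid"]) \
            if "pt" in store.reac.columns else set()
        with_drug = set(store.drug["primaryid"])
        no_reac = ~demo["primaryid"].isin(with_reac)
        tally["no adverse event description"] = int((keep & no_reac).sum())
        keep &= ~no_reac
        no_drug = ~demo["primaryid"].isin(with_drug)
        tally["no drug record"] = int((keep & no_drug).sum())
        keep &= ~no_drug

    if stage == "tto":
        ev_full = demo.get("event_dt", pd.Series("", index=demo.index)).map(is_full_date)
        tally["partial or missing event date"] = int((keep & ~ev_full).sum())
        keep &= ev_full
        if "start_dt" in store.ther.columns and len(store.ther):
            full_start = set(
                store.ther.loc[store.ther["start_dt"].map(is_full_date), "primaryid"]
            )
        else:
            full_start = set()
        has_start = demo["primaryid"].isin(full_start)
        tally["partial or missing therapy start date"] = int((keep & ~has_start).sum())
        keep &= has_start

    out = store.filter_primaryids(demo.loc[keep, "primaryid"])
    out.tallies = dict(store.tallies)
    out.tallies[f"completeness_{stage}"] = {**tally, "surviving_reports": int(keep.sum())}
    return out, tally
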