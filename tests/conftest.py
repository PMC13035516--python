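"""Shared fixtures: handcrafted micro-stores and desk-scale synthetic quarters."""

from dataclasses import replace

import pandas as pd
import pytest

from basalvig.faers_io import CaseStore
from basalvig.synthetic_data import SyntheticConfig, generate


def small_config(seed=0, **overrides) -> SyntheticConfig:
    """Desk-scale generator config: same conditions, smaller cohorts."""
    base = SyntheticConfig()
    drugs = tuple(
        replace(d, n_reports=n) for d, n in zip(base.drugs, (400, 500, 1600))
    )
    return SyntheticConfig(seed=seed, drugs=drugs, n_background=8000, **overrides)


@pytest.fixture(scope="session")
def small_quarter():
    return generate(small_config(seed=7))


@pytest.fixture(scope="session")
def small_store(small_quarter):
    from basalvig.faers_io import deduplicate

    return deduplicate(small_quarter.to_store(), deleted=small_quarter.deleted)


def frame(rows, columns):
    return pd.DataFrame(rows, columns=columns, dtype=str)


@pytest.fixture
def micro_store() -> CaseStore:
    """Five-case handcrafted store exercising versions, duplicates, roles."""
    demo = frame(
        [
            # case 1: three versions — only primaryid 1003 must survive
            ("1001", "1", "20200101", "20191230", "65", "YR", "F", "70", "KG", "US"),
            ("1002", "1", "20200201", "20191230", "65", "YR", "F", "70", "KG", "US"),
            ("1003", "1", "20200301", "20191230", "65", "YR", "F", "70", "KG", "US"),
            # case 2: two rows with identical caseid+fda_dt
            ("2001", "2", "20210101", "202012", "", "", "M", "150", "LBS", "GB"),
            ("2002", "2", "20210101", "202012", "", "", "M", "150", "LBS", "GB"),
            # case 3: deleted downstream
            ("3001", "3", "20220101", "20211215", "6.5", "DEC", "F", "", "", "US"),
            # case 4: clean single version
            ("4001", "4", "20230101", "20221201", "40", "YR", "", "80", "KG", "FR"),
            # case 5: no reactions (incomplete at signal stage)
            ("5001", "5", "20230601", "", "55", "YR", "M", "", "", "US"),
        ],
        ["primaryid", "caseid", "fda_dt", "event_dt", "age", "age_cod", "sex", "wt", "wt_cod", "occr_country"],
    )
    drug = frame(
        [
            ("1003", "1", "1", "PS", "TRESIBA", "INSULIN DEGLUDEC"),
            ("1003", "1", "2", "C", "METFORMIN", "METFORMIN"),
            ("2002", "2", "1", "PS", "LEVEMIR FLEXPEN", "INSULIN DETEMIR"),
            ("3001", "3", "1", "PS", "LANTUS", "INSULIN GLARGINE"),
            ("4001", "4", "1", "SS", "LEVEMIR", "INSULIN DETEMIR"),
            ("4001", "4", "2", "PS", "OZEMPIC", "SEMAGLUTIDE"),
            ("5001", "5", "1", "PS", "TRESIBA", "INSULIN DEGLUDEC"),
            ("1001", "1", "1", "PS", "TRESIBA", "INSULIN DEGLUDEC"),
        ],
        ["primaryid", "caseid", "drug_seq", "role_cod", "drugname", "prod_ai"],
    )
    reac = frame(
        [
            ("1003", "1", "Visual impairment"),
            ("1003", "1", "CATARACT"),
            ("2002", "2", "VISUAL IMPAIRMENT"),
            ("3001", "3", "NAUSEA"),
            ("4001", "4", "VISUAL IMPAIRMENT"),
            ("1001", "1", "VISUAL IMPAIRMENT"),
        ],
        ["primaryid", "caseid", "pt"],
    )
    ther = frame(
        [
            ("1003", "1", "1", "20191201"),
            ("2002", "2", "1", "202011"),
            ("4001", "4", "2", "20221101"),
        ],
        ["primaryid", "caseid", "dsg_drug_seq", "start_dt"],
    )
    return CaseStore(demo=demo, drug=drug, reac=reac, ther=ther)
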