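"""Generate the reference synthetic FAERS corpus used by the downstream
analysis scripts.

Emits a quarter of $-delimited tables (three basal-insulin cohorts with
planted ocular signal strengths plus a 40,000-report background), the
deleted-case list and the ground-truth JSON under results/synthetic_corpus/.
"""

from pathlib import Path

from basalvig.synthetic_data import SyntheticConfig, generate

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic_corpus"
SEED = 0

if __name__ == "__main__":
    quarter = generate(SyntheticConfig(seed=SEED))
    paths = quarter.write(OUT)
    gt = quarter.ground_truth
    print(f"wrote {len(paths)} files to {OUT}")
    print(f"unique non-deleted cases: {gt.n_cases}")
    print(f"target cohorts: {gt.case_counts}")
    print(f"planted duplicates: {len(gt.duplicate_caseids)}, deleted: {len(gt.deleted_caseids)}")
    a, b, c, d = gt.contingency[("insulin_glargine", "VISUAL IMPAIRMENT")]
    print(f"glargine visual-impairment fourfold (a,b,c,d) = {(a, b, c, d)}")
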