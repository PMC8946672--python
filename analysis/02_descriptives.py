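"""Item-level descriptive statistics by return-to-sport stratum.

Reads the cohort CSV written by 01_simulate_cohort.py (or any cohort file
with the same layout) and writes per-item mean/SD/count for the whole
cohort and both strata.
"""

import argparse
from pathlib import Path

from rsinet.cohort import read_cohort, summarize


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", default="results/synthetic_cohort.csv")
    ap.add_argument("--results-dir", default="results")
    args = ap.parse_args()

    cohort = read_cohort(args.cohort)
    summary = summarize(cohort)
    out = Path(args.results_dir) / "item_summary.csv"
    summary.to_csv(out, index=False)

    wide = summary.pivot(index="item", columns="stratum", values="mean")
    print(f"n = {cohort.n}; wrote {out}")
    print("item means by stratum:")
    print(wide.round(1).to_string())


if __name__ == "__main__":
    main()
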