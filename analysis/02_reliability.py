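"""Pairwise consistency ICCs among the four (method, hemisphere) channels.

Reads results/cohort.csv; writes results/icc.csv. The headline contrast: the
amygdala's cross-method consistency lands in the "poor" band while the
hippocampus is "good" — the pattern that motivates the rest of the pipeline.
"""

import argparse
from pathlib import Path

import pandas as pd

from volconsist.config import cohort_spec_from_config, load_config
from volconsist.reliability import pairwise_consistency
from volconsist.reporting import format_estimate, write_table

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--config", default=ROOT / "configs" / "demo.yaml")
    ap.add_argument("--cohort-csv", default=ROOT / "results" / "cohort.csv")
    ap.add_argument("--out-dir", default=ROOT / "results")
    args = ap.parse_args()

    cfg = load_config(args.config)
    spec = cohort_spec_from_config(cfg)
    cohort = pd.read_csv(args.cohort_csv)
    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    tables = []
    for region in spec.regions:
        cols = [(m, h) for m in spec.methods for h in ("left", "right")]
        tables.append(pairwise_consistency(cohort, region.name, cols))
    icc = pd.concat(tables, ignore_index=True)
    write_table(icc, out / "icc.csv")

    print(f"wrote {out/'icc.csv'} ({len(icc)} pairwise estimates)")
    for _, row in icc.iterrows():
        print(
            f"  {row.column_a} vs {row.column_b}: "
            f"{format_estimate(row.value, row.ci_low, row.ci_high)} ({row.category})"
        )


if __name__ == "__main__":
    main()
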