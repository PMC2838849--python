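"""Library-level statistics: coverage, redundancy, locus bounds, enrichment.

Recomputes the headline library numbers from printed inputs via the
`reproduce` pipeline, and groups the synthetic screen's clone intervals by
F/M/R hybridization pattern.
"""

import json
from pathlib import Path

import pandas as pd

from bacrichness.librarystats import classify_intervals, group_patterns
from bacrichness.pipeline import run_reproduce

ROOT = Path(__file__).resolve().parents[1] / "results"

def main() -> None:
    out = ROOT / "librarystats"
    out.mkdir(parents=True, exist_ok=True)

    rep = run_reproduce()
    (out / "reproduce.json").write_text(json.dumps(rep, indent=2) + "\n")
    print(f"richness: theta_hat={rep['richness']['theta_hat']}, "
          f"95% CI {rep['richness']['ci_95']}, 90% CI {rep['richness']['ci_90']}")
    print(f"loci: {rep['loci']}")
    print(f"coverage: {rep['library']['coverage_fold']}x full library, "
          f"{rep['library']['genotyping_subset_coverage_fold']}x genotyping subset")
    print(f"redundancy: {rep['redundancy']['positive_percent']}% probe-positive; "
          f"GGTTA enrichment {rep['ggtta_enrichment_fold']:.2f}-fold")

    df = pd.read_csv(ROOT / "synthetic" / "screen.tsv", sep="\t")
    g = group_patterns(classify_intervals(
        list(zip(df["start"], df["end"])), clone_ids=list(df["clone_id"].astype(str))
    ))
    (out / "hybridization_patterns.json").write_text(json.dumps(g, indent=2) + "\n")
    print(f"synthetic screen patterns: {g['counts']} "
          f"({g['positive_percent']}% positive)")

if __name__ == "__main__":
    main()
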