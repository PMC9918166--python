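"""Build the three cohort report tables from the per-subject descriptors.

Reads results/per_subject_descriptors.csv (written by 02) and recomputes:
the median/IQR summary with girls-vs-boys Mann-Whitney p, the phenotype
prevalence table with binomial and Fisher tests, and the Spearman
age-correlation table with SE of rho.  This demonstrates stage
separability: the tables depend only on the saved record set.
"""

import argparse
from pathlib import Path

import pandas as pd

from hrasym import reports_from_records


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--descriptors", type=Path,
                    default=Path("results/per_subject_descriptors.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    records = pd.read_csv(args.descriptors)
    tables = reports_from_records(records)
    args.out.mkdir(parents=True, exist_ok=True)
    for name, tab in tables.items():
        tab.to_csv(args.out / f"{name}.csv")

    summary = tables["table1_summary"]
    prev = tables["table2_prevalence"]
    corr = tables["table3_age_correlation"]
    print("summary (all children):")
    print(summary[["all_median", "all_q25", "all_q75", "p_girls_vs_boys"]]
          .round(4).to_string())
    print("\nphenotype prevalence:")
    print(prev[["count", "n", "percent", "p_binomial", "p_fisher"]].round(4).to_string())
    print("\nage correlations:")
    print(corr.round(4).to_string())


if __name__ == "__main__":
    main()
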