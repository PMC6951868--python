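#!/usr/bin/env python
"""Label suspected infection, mortality and admission acuity.

Writes infection.csv (culture + IV antibiotic labels, death/hospice) and
acuity.csv (NEWS points/category, SIDa flag) for the generated cohort.
"""

import argparse
from pathlib import Path

from sepscreen import acuity_cohort, label_cohort, read_cohort, resolve_cohort


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cohort = read_cohort(args.cohort)
    labels = label_cohort(cohort)
    labels.to_csv(args.out / "infection.csv", index=False)
    acuity = acuity_cohort(cohort, resolve_cohort(cohort))
    acuity.to_csv(args.out / "acuity.csv", index=False)

    print(f"suspected infection: {int(labels['suspected_infection'].sum())} of {len(labels)}")
    print(f"died or hospice: {int(labels['died_or_hospice'].sum())}")
    print("NEWS categories:", acuity["news_category"].value_counts().sort_index().to_dict())
    print(f"SIDa flagged: {int(acuity['sida_flag'].sum())}")


if __name__ == "__main__":
    main()
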