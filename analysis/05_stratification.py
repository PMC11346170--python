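#!/usr/bin/env python
"""Score-based stratifications of the synthetic cohort.

Two analyses mirror the grading score's clinical readouts:
(1) conjunctival HLA-DR compared between low (IC-0..IC-2) and high (IC-3)
inflammatory-cell subscore strata, pooled and per group (Mann-Whitney);
(2) the extreme total-score groups (T-IVCM <= 2 vs >= 5), with the
significant sign-labelled clinical correlations inside each group.
Writes results/stratification/.
"""

from pathlib import Path

import pandas as pd

from ivcm_dryeye.cohort import generate_cohort_frame
from ivcm_dryeye.config import default_config
from ivcm_dryeye.stats import (
    compare_hla_by_icsc,
    stratify_extreme_tivcm,
    within_group_correlations,
)

SEED = 1
CLINICAL = ("age", "osdi_total", "oxford", "schirmer_mm", "tbut_s")
OUT = Path("results/stratification")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort_frame(default_config(), seed=SEED)

    print("HLA-DR by inflammatory-cell subscore stratum:")
    comparisons = []
    for label, table in (
        ("all DED", cohort),
        ("AIDED", cohort[cohort["group"] == "AIDED"]),
        ("NAIDED", cohort[cohort["group"] == "NAIDED"]),
    ):
        comp = compare_hla_by_icsc(table)
        if comp is None:
            print(f"  {label}: a stratum is empty, not computable")
            continue
        comparisons.append({"population": label, **comp.__dict__})
        print(
            f"  {label:>8}: low n={comp.n_a} mean {comp.mean_a:9.0f} | "
            f"high n={comp.n_b} mean {comp.mean_b:9.0f} | "
            f"U={comp.u_statistic:7.1f} p={comp.p_value:.2e}"
        )
    pd.DataFrame(comparisons).to_csv(OUT / "icsc_hla.tsv", sep="\t", index=False)

    low, high = stratify_extreme_tivcm(cohort)
    print(
        f"\nextreme total-score groups: {len(low)} eyes with T-IVCM <= 2, "
        f"{len(high)} eyes with T-IVCM >= 5 "
        f"({len(cohort) - len(low) - len(high)} intermediate excluded)"
    )
    for name, group in (("low", low), ("high", high)):
        _res, edges = within_group_correlations(group, variables=CLINICAL)
        edges.to_csv(OUT / f"tivcm_{name}_edges.tsv", sep="\t", index=False)
        print(f"  {name} group significant clinical correlations:")
        if len(edges) == 0:
            print("    (none)")
        for _, row in edges.iterrows():
            print(
                f"    {row['var_a']:>12} ~ {row['var_b']:<12} "
                f"rho = {row['rho']:+.2f}  p = {row['p']:.3f}"
            )
    print(f"\nwrote tables under {OUT}/")


if __name__ == "__main__":
    main()
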