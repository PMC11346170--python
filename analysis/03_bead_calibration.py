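#!/usr/bin/env python
"""Fit the bead calibration line and convert cohort HLA-DR levels.

Builds a five-population calibration bead set, fits the log-log line,
synthesises raw MFIs for every cohort eye by inverting the line, converts
them back to arbitrary units of fluorescence, and confirms the round trip.
Writes results/bead_calibration.tsv and results/hla_dr_auf.tsv.
"""

import numpy as np
import pandas as pd

from ivcm_dryeye.cohort import generate_cohort_frame
from ivcm_dryeye.config import default_config
from ivcm_dryeye.cytometry import auf_to_mfi, fit_bead_calibration, mfi_to_auf
from ivcm_dryeye.pipeline import DEMO_BEADS

SEED = 1


def main() -> None:
    cal = fit_bead_calibration(DEMO_BEADS)
    print(
        f"bead line: log10(ABC) = {cal.intercept:.4f} + {cal.slope:.4f} log10(MFI), "
        f"r2 = {cal.r_squared:.5f} over {cal.n_beads} beads"
    )
    pd.DataFrame(
        [{"slope": cal.slope, "intercept": cal.intercept,
          "r_squared": cal.r_squared, "n_beads": cal.n_beads}]
    ).to_csv("results/bead_calibration.tsv", sep="\t", index=False)

    cohort = generate_cohort_frame(default_config(), seed=SEED)
    mfis = np.array([auf_to_mfi(cal, auf) for auf in cohort["hla_dr_auf"]])
    converted = np.array([mfi_to_auf(cal, m)[0] for m in mfis])
    rel_err = np.max(np.abs(converted - cohort["hla_dr_auf"]) / cohort["hla_dr_auf"])
    print(f"converted {len(cohort)} samples; worst round-trip error {rel_err:.2e}")
    print(
        f"MFI range {mfis.min():.0f}-{mfis.max():.0f} -> "
        f"AUF mean {converted.mean():.0f} (published 70,000)"
    )
    out = pd.DataFrame(
        {"eye_id": cohort["patient_id"], "sample_mfi": mfis, "hla_dr_auf": converted}
    )
    out.to_csv("results/hla_dr_auf.tsv", sep="\t", index=False)
    print("wrote results/bead_calibration.tsv and results/hla_dr_auf.tsv")


if __name__ == "__main__":
    main()
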