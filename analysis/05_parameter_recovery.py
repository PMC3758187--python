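#!/usr/bin/env python
"""Parameter recovery: can the estimator find a 130 Ma integration?

Simulates 30 independent two-species datasets (500 bp LTRs, host split
104 Ma, neutral rate 4.5e-9/site/yr, provirus integrated at 130 Ma),
runs the full dating pipeline on each and compares the estimates with
truth.  Estimation uses position-wise LTR comparison and Jukes-Cantor
multiple-hit correction — the configuration expected to be unbiased at
these divergences.
"""

import numpy as np
import pandas as pd

from ervclock.validation import recover_integration_dates

SEED = 11
TRUTH = 130.0


def main() -> None:
    results = recover_integration_dates(30, seed=SEED, t_integration=TRUTH)
    dates = np.array([r.t_integration for r in results])
    lo, hi = np.percentile(dates, [2.5, 97.5])
    pd.DataFrame(
        {
            "replicate": np.arange(len(dates)),
            "t_integration_Ma": np.round(dates, 2),
            "d_pre_pct": [round(r.d_pre, 2) for r in results],
            "clamped": [r.clamped for r in results],
        }
    ).to_csv("results/parameter_recovery.tsv", sep="\t", index=False)
    print(f"30 replicates, truth {TRUTH:.0f} Ma:")
    print(f"  mean estimate {dates.mean():.1f} Ma (bias {dates.mean() - TRUTH:+.1f} Myr)")
    print(f"  sd {dates.std(ddof=1):.1f} Myr; empirical 95% band [{lo:.1f}, {hi:.1f}] Ma")
    print(f"  truth inside band: {lo <= TRUTH <= hi}")


if __name__ == "__main__":
    main()
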