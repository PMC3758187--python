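#!/usr/bin/env python
"""Date the integration event: reference inputs and simulated pairs.

Part 1 runs the pure arithmetic on the reference human/elephant LTR
divergences (cross 53%, same 31%, host split 104 Ma, mouse neutral
rate 4.5e-9/site/yr).  Part 2 runs the full sequence pipeline on the
simulated human/elephant orthologues from the fixture (truth: 130 Ma),
in both raw and multiple-hit-corrected modes.  Run
01_simulate_fixture.py first.
"""

import pandas as pd

from ervclock.core_io import NucSequence, read_fasta, read_gff3
from ervclock.ltr_dating import (
    DatingInputs,
    date_from_sequences,
    estimate_integration_date,
    excess_over_host,
)
from ervclock.pairwise_align import UNGAPPED_PARAMS

FIXTURE = "results/fixture"


def _ltr(seqs, feats, species, label):
    seq = next(s for s in seqs if s.id == species)
    f = next(f for f in feats[species] if f.label == label)
    return NucSequence(f"{species}:{label}", seq.residues[f.start : f.end])


def main() -> None:
    rows = []

    # part 1: the reference divergences
    r = estimate_integration_date(DatingInputs(53.0, 31.0, 104.0, 4.5e-9))
    print(
        f"Reference human/elephant inputs: pre-split divergence "
        f"{r.d_pre:.0f}% -> integration {r.t_integration:.1f} Ma "
        f"({excess_over_host(r):.1f} Myr before the placental radiation)"
    )
    rows.append(
        {
            "inputs": "reference (53/31)",
            "mode": "raw",
            "d_pre_pct": r.d_pre,
            "t_integration_Ma": round(r.t_integration, 2),
            "excess_Myr": round(excess_over_host(r), 2),
        }
    )

    # part 2: simulated human/elephant orthologues, truth 130 Ma
    seqs = read_fasta(f"{FIXTURE}/elements.fasta")
    feats = read_gff3(f"{FIXTURE}/annotations.gff3")
    h5, h3 = _ltr(seqs, feats, "human", "5'LTR"), _ltr(seqs, feats, "human", "3'LTR")
    e5, e3 = _ltr(seqs, feats, "elephant", "5'LTR"), _ltr(seqs, feats, "elephant", "3'LTR")
    for corrected, mode in ((False, "raw"), (True, "jc_corrected")):
        res = date_from_sequences(
            h5, h3, e5, e3, t_host=104.0, mu=4.5e-9,
            params=UNGAPPED_PARAMS, correct_multiple_hits=corrected,
        )
        print(
            f"Simulated human/elephant ({mode}): d_cross-d_same={res.d_pre:.1f}% "
            f"-> {res.t_integration:.1f} Ma (truth 130)"
        )
        rows.append(
            {
                "inputs": "simulated fixture (truth 130 Ma)",
                "mode": mode,
                "d_pre_pct": round(res.d_pre, 2),
                "t_integration_Ma": round(res.t_integration, 2),
                "excess_Myr": round(excess_over_host(res), 2),
            }
        )
    pd.DataFrame(rows).to_csv("results/dating.tsv", sep="\t", index=False)
    print(
        "Note: at these divergences the raw estimator saturates low; the "
        "corrected mode is the one expected to recover deep truth."
    )


if __name__ == "__main__":
    main()
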