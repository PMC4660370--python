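#!/usr/bin/env python
"""Guanine-nucleotide inhibition of IMPDH: mechanism and constants.

Simulates IMP-saturation grids (19.5–5000 μM IMP, six inhibitor levels,
3 replicates, 2% velocity noise) for GMP, GDP and GTP at the published
wild-type parameter sets, runs the global mixed-inhibition regression on
each, and tabulates the selected mechanism with Km, Ki, α and β.

Finding: GMP comes out purely competitive (Ki ≈ 0.6 mM) while GDP and GTP
come out mixed-type with Ki ≈ 0.21 and 0.16 mM, strong substrate–inhibitor
coupling (α > 4) and a nearly dead ternary complex (β ≪ 1) — the kinetic
signature of allosteric inhibition through the Bateman domain.
"""

import argparse
from pathlib import Path

import pandas as pd

from allokin import kinetics as K
from allokin import synth

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main(seed: int):
    rows = []
    for inhibitor, truth in synth.KINETICS_TRUTHS.items():
        data = synth.gen_kinetics_dataset(
            truth, synth.NoiseSpec(seed=seed), inhibitor_id=inhibitor)
        fit = K.fit_inhibition_global(data)
        hw = K.hanes_woolf(data)
        rows.append({
            "inhibitor": inhibitor,
            "mechanism": fit.mechanism.value,
            "Km_uM": round(fit.km, 1),
            "Ki_mM": round(fit.ki / 1000.0, 3) if fit.ki else None,
            "alpha": round(fit.alpha, 2) if fit.alpha else None,
            "beta": round(fit.beta, 3) if fit.beta is not None else None,
            "hanes_woolf_slope_equality_p": round(hw.slope_equality_p, 4),
            "ambiguous": fit.ambiguous,
        })
        print(f"{inhibitor}: {fit.mechanism.value:12s} "
              f"Km={fit.km:5.1f} uM  Ki={fit.ki / 1000:.3f} mM"
              + (f"  alpha={fit.alpha:.2f} beta={fit.beta:.3f}"
                 if fit.mechanism is K.Mechanism.MIXED else ""))
    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "kinetics_inhibition.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"\nparallel Hanes–Woolf lines (high slope-equality p) mark the "
          f"competitive case;\nwrote {out}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
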