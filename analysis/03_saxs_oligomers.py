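#!/usr/bin/env python
"""Oligomeric state of IMPDH from solution scattering.

Generates concentration series (2.5–10 mg/mL, q to 0.35 Å⁻¹) from the
calibrated tetramer and octamer bead models, runs the full hydrodynamics
chain — infinite-dilution extrapolation, Guinier Rg, P(r)-based Dmax,
Porod volume and mass estimate — and classifies each particle.

Finding: the octamer model's curve yields roughly twice the Porod volume
of the tetramer's at nearly unchanged Dmax and only ~5 Å larger Rg, i.e.
the compact tail-to-tail dimer of tetramers, and the mass-ratio test
assigns both states correctly.  A theoretical-vs-synthetic profile fit
gives reduced χ² ≈ 1 for the generating model.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from allokin import saxs as S
from allokin import synth

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main(seed: int):
    rows = []
    for state in ("tetramer", "octamer"):
        model = synth.gen_bead_assembly(state)
        curves = synth.gen_saxs_series(
            model, concentrations=(2.5, 5.0, 10.0),
            noise=synth.NoiseSpec(proportional_sd=0.01, seed=seed))
        curve = S.extrapolate_infinite_dilution(curves)
        gui = S.guinier_fit(curve)
        dmax = S.estimate_dmax(curve)
        pr = S.ift_pofr(curve, dmax)
        por = S.porod_volume(curve, gui)
        call = S.classify_oligomer(por.mw_est_kDa,
                                   synth.BEAD_MONOMER_MASS_KDA)
        theo = S.debye_profile(model, curve.q)
        _, chi2 = S.fit_profile_scale(curve, theo)
        rows.append({
            "model": state,
            "Rg_A": round(gui.Rg, 1),
            "Rg_pr_A": round(pr.Rg_pr, 1),
            "Dmax_A": round(dmax, 0),
            "porod_volume_A3": round(por.Vp, 0),
            "mw_est_kDa": por.mw_est_kDa,
            "mw_ratio_vs_tetramer": round(call.mw_ratio, 2),
            "call": call.state.value,
            "profile_fit_red_chi2": round(chi2, 2),
        })
        print(f"{state:8s}: Rg={gui.Rg:5.1f} A  Dmax={dmax:5.0f} A  "
              f"Vp={por.Vp:9.0f} A^3  MW={por.mw_est_kDa:4.0f} kDa  "
              f"-> {call.state.value} (chi2={chi2:.2f})")
    ratio = rows[1]["porod_volume_A3"] / rows[0]["porod_volume_A3"]
    print(f"\nvolume ratio octamer/tetramer = {ratio:.2f} "
          f"(doubling of the scattering particle)")
    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "saxs_oligomers.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
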