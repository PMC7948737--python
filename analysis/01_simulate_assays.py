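#!/usr/bin/env python
"""Generate every synthetic raw-data table the downstream analyses consume.

Emulates the study's wet-lab assays under the printed designs:
  * a UDP standard curve (6 levels incl. background, duplicate);
  * luminescent progress curves for the 5×5 substrate grid at 1.25 nM enzyme
    (common 0-120 min clock, 5 min reads, 2% CV luminescence noise);
  * an initial-velocity table (3 replicates/cell, 5% CV);
  * SPR sensorgram families (1:3 series, 2.5-200 uM; 60 s association,
    120 s dissociation) for a KD=140 uM analyte (donor scenario), a 260 uM
    analyte (product scenario) and a 5 mM analyte (weak acceptor scenario);
  * the SEC calibration standards plus one unknown eluting as an 84 kDa species.

Writes CSVs under results/data/.
"""

import argparse
from pathlib import Path

import numpy as np

from glycokinetics.data import NoiseSpec
from glycokinetics.io import (
    write_progress_csv,
    write_sec_csv,
    write_sensorgram_csv,
    write_standard_curve_csv,
    write_velocity_csv,
)
from glycokinetics.synthetic_data import (
    DONOR_LEVELS_UM,
    ACCEPTOR_LEVELS_UM,
    REPORTED_PARAMS,
    SEC_STANDARDS,
    SPR_SERIES_UM,
    simulate_progress_curves,
    simulate_sec_elution,
    simulate_sensorgram_family,
    simulate_standard_curve,
    simulate_velocity_dataset,
)

SEC_TRUTH = (4.0, -0.25)  # log10(MW kDa) = 4.0 - 0.25 V(ml)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)
    seed = args.seed

    write_standard_curve_csv(
        simulate_standard_curve(noise=NoiseSpec(cv=0.01, seed=seed)), out / "udp_standard.csv"
    )

    times = np.arange(0.0, 121.0, 5.0)
    curves = []
    for i, a in enumerate(DONOR_LEVELS_UM):
        for j, b in enumerate(ACCEPTOR_LEVELS_UM):
            curves.append(
                simulate_progress_curves(
                    REPORTED_PARAMS, a, b, times,
                    noise=NoiseSpec(cv=0.02, seed=seed + 100 + 5 * i + j),
                    well_id=f"A{a:g}_B{b:g}",
                )
            )
    write_progress_csv(curves, out / "plate_curves.csv")

    velocities = simulate_velocity_dataset(
        REPORTED_PARAMS, replicates=3, noise=NoiseSpec(cv=0.05, seed=seed + 1)
    )
    write_velocity_csv(velocities, out / "velocities_direct.csv")

    scenarios = {"udp_glcnac": 140.0, "udp": 260.0, "lacnac": 5000.0}
    for k, (name, kd) in enumerate(scenarios.items()):
        fam = simulate_sensorgram_family(
            kd=kd, kon=1e4, rmax=40.0, conc_series=SPR_SERIES_UM,
            bulk_ri=5.0, drift=0.01,
            noise=NoiseSpec(cv=0.0, additive_sd=0.05, seed=seed + 200 + k),
        )
        write_sensorgram_csv(fam, out / f"spr_{name}.csv")

    rows = [
        (name, mw, simulate_sec_elution(SEC_TRUTH, mw, NoiseSpec(additive_sd=0.02, seed=seed + 300 + i)))
        for i, (name, mw) in enumerate(SEC_STANDARDS)
    ]
    write_sec_csv(rows, out / "sec_standards.csv")
    unknown_vol = simulate_sec_elution(SEC_TRUTH, 84.0, NoiseSpec(additive_sd=0.02, seed=seed + 310))
    import json

    (out / "sec_unknown.json").write_text(
        json.dumps({"peak": "enzyme", "elution_ml": unknown_vol}) + "\n", encoding="utf-8"
    )

    print(f"wrote {len(curves)} progress curves, {len(velocities)} velocities, "
          f"{len(scenarios)} SPR families, {len(rows)} SEC standards -> {out}")


if __name__ == "__main__":
    main()
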