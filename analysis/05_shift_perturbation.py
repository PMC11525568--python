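#!/usr/bin/env python
"""Chemical-shift perturbation: binding CSP, temperature series, and the
correlation between dispersion delta-omega and binding CSP.

Computes the weighted composite CSP (alpha_N = 0.14, alpha_C' = 0.35)
between the simulated apo and holo shift tables, flags residues that
vanish in the holo spectrum, summarizes the cumulative temperature CSP,
and correlates the dispersion-fitted |delta omega| with the binding CSP
over shared residues (weak in the study: R^2 ~ 0.4-0.5).
"""

import argparse
from pathlib import Path

import numpy as np

from relaxkit import data_io
from relaxkit.dispersion import MODEL_CR, fit_dispersion
from relaxkit.shift_analysis import (
    correlate_dw_csp,
    csp_between_tables,
    temperature_csp_series,
)
from relaxkit.synthetic_data import (
    PerturbationSpec,
    SimulationConfig,
    generate_dispersion_dataset,
    generate_ground_truth,
    generate_shift_tables,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--n-residues", type=int, default=80)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = SimulationConfig(seed=args.seed, n_residues=args.n_residues)
    truth = generate_ground_truth(cfg)
    apo, holo, temps = generate_shift_tables(truth, cfg, PerturbationSpec())

    results = csp_between_tables(apo, holo)
    lines = ["residue\tcsp_ppm\tstatus"]
    for c in results:
        val = f"{c.delta_composite:.5f}" if c.status == "ok" else "NA"
        lines.append(f"{c.residue.label}\t{val}\t{c.status}")
    args.out.mkdir(parents=True, exist_ok=True)
    (args.out / "csp_apo_holo.tsv").write_text("\n".join(lines) + "\n")
    lost = [c.residue.label for c in results if c.status != "ok"]
    print(f"binding CSP for {len(results)} residues; {len(lost)} undetectable "
          f"in holo (red-bar residues): {lost[:6]}{'...' if len(lost) > 6 else ''}")

    temp_df = temperature_csp_series(temps, temps[0].temperature_K)
    temp_df.to_csv(args.out / "csp_temperature.tsv", sep="\t",
                   float_format="%.6g", na_rep="NA")
    final_col = temp_df.columns[-2]  # last temperature before the flag column
    print(f"cumulative temperature CSP at {final_col} K: "
          f"median {np.nanmedian(temp_df[final_col].to_numpy(float)):.4f} ppm")

    # delta-omega from dispersion vs binding CSP over exchange residues
    disp = generate_dispersion_dataset(truth, cfg)
    dw = {}
    for i, t in enumerate(truth):
        if t.region_label != "active_site_patch":
            continue
        fit = fit_dispersion([disp[f][i] for f in cfg.fields_MHz],
                             MODEL_CR, mc_reps=0, seed=args.seed)
        dw[t.residue] = fit.delta_omega_ppm
    corr = correlate_dw_csp(dw, results)
    print(f"|delta omega| vs binding CSP over n = {corr.n} residues: "
          f"R^2 = {corr.r_squared:.2f}")


if __name__ == "__main__":
    main()
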