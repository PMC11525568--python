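#!/usr/bin/env python
"""CPMG relaxation-dispersion analysis with F-test model selection.

Refits the simulated two-field dispersion dataset residue by residue:
an exchange-free null model against the Carver-Richards two-site model,
selected by F-test at a P cut-off of 0.1.  Writes results/dispersion.tsv
with the fitted kex, pA, delta-omega and per-field Rex, and reports how
many residues show significant millisecond-microsecond exchange.
"""

import argparse
from pathlib import Path

from relaxkit.dispersion import MODEL_CR, fit_dispersion, fit_no_exchange, select_model
from relaxkit.synthetic_data import (
    SimulationConfig,
    generate_dispersion_dataset,
    generate_ground_truth,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--n-residues", type=int, default=80)
    ap.add_argument("--noise", type=float, default=0.02)
    ap.add_argument("--p-cutoff", type=float, default=0.1)
    ap.add_argument("--out", type=Path, default=Path("results/dispersion.tsv"))
    args = ap.parse_args()

    cfg = SimulationConfig(seed=args.seed, n_residues=args.n_residues,
                           noise=args.noise)
    truth = generate_ground_truth(cfg)
    disp = generate_dispersion_dataset(truth, cfg)

    lines = ["residue\tregion\tmodel\tkex\tpA\tdw_ppm\tRex600\tF\tP"]
    n_sel, n_true = 0, 0
    for i, t in enumerate(truth):
        profiles = [disp[f][i] for f in cfg.fields_MHz]
        null = fit_no_exchange(profiles)
        alt = fit_dispersion(profiles, MODEL_CR, mc_reps=0, seed=args.seed)
        choice = select_model(null, alt, alt.n_points, args.p_cutoff)
        exchanging = choice.chosen == MODEL_CR
        n_sel += exchanging
        n_true += t.region_label == "active_site_patch"
        lines.append("\t".join([
            t.residue.label, t.region_label, choice.chosen,
            f"{alt.k_ex:.1f}", f"{alt.p_a:.4f}", f"{alt.delta_omega_ppm:.3f}",
            f"{alt.r_ex[600.0]:.2f}", f"{choice.f_statistic:.3g}",
            f"{choice.p_value:.3g}"]))
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text("\n".join(lines) + "\n")

    print(f"exchange model selected for {n_sel}/{len(truth)} residues "
          f"at P < {args.p_cutoff} ({n_true} residues truly exchange-bearing)")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
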