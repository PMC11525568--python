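#!/usr/bin/env python
"""Holo - apo difference report.

Simulates a 'holo' condition in which substrate binding abolishes the
exchange contribution to R2 (the patch residues lose their Rex) and a
fraction of arm residues become undetectable, then builds the
per-residue difference table for R1, R2 and NOE.  Patch residues show
negative dR2; undetectable residues are flagged rather than silently
dropped.  Writes results/difference_report.tsv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from relaxkit.pipeline import difference_report
from relaxkit.synthetic_data import (
    SimulationConfig,
    generate_ground_truth,
    true_rates,
)


def _bundle(truth, cfg, include_rex, drop=()):
    rows = {}
    for t in truth:
        if t.residue in drop:
            continue
        r1, r2, noe = true_rates(t, cfg, 600.0, include_rex=include_rex)
        rows[t.residue.label] = {"R1": r1, "R2": r2, "NOE": noe}
    return pd.DataFrame.from_dict(rows, orient="index")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--n-residues", type=int, default=80)
    ap.add_argument("--out", type=Path, default=Path("results/difference_report.tsv"))
    args = ap.parse_args()

    cfg = SimulationConfig(seed=args.seed, n_residues=args.n_residues)
    truth = generate_ground_truth(cfg)
    rng = np.random.default_rng(args.seed)
    arm = [t.residue for t in truth if t.region_label == "c_terminal_arm"]
    lost = [r for r in arm if rng.uniform() < 0.3]

    apo = _bundle(truth, cfg, include_rex=True)
    holo = _bundle(truth, cfg, include_rex=False, drop=lost)
    report = difference_report(apo, holo)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    report.to_csv(args.out, sep="\t", float_format="%.6g", na_rep="NA")

    patch = [t.residue.label for t in truth if t.region_label == "active_site_patch"]
    dr2 = report.loc[report.index.isin(patch), "dR2"]
    print(f"binding abolishes Rex: dR2 over the {len(dr2)} exchange residues "
          f"is {dr2.mean():.2f} 1/s on average (all negative: {(dr2 < 0).all()})")
    print(f"{len(lost)} arm residues undetectable in holo -> flagged rows")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
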