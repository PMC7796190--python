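#!/usr/bin/env python
"""Seeded conformational ensemble of the heterochiral complex: violin-style
conformer statistics and per-region backbone RMSD series.

Generates a multi-model ensemble of the L-RNA/D-Rz model in which each
residue's pseudorotation phase and glycosidic chi fluctuate around the
model's own values, then computes (i) the per-residue circular statistics
of P and chi with S-type and syn fractions (the table behind violin plots)
and (ii) ribose-phosphate-backbone RMSD trajectories per region (helices
1-3, catalytic core, each strand, everything).  Writes CSVs under
results/ensemble/.
"""

import argparse
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from mirrorhh.compare_analyze import conformer_distribution, region_rmsd_series
from mirrorhh.complex_model import hammerhead_pairing
from mirrorhh.conformation import complex_records, records_to_frame
from mirrorhh.pipeline import region_selections
from mirrorhh.structure_io import read_pdb, sequence_of
from mirrorhh.synthetic import EnsembleSpec, generate_ensemble


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--frames", type=int, default=60)
    ap.add_argument("--out-root", type=Path, default=Path("results"))
    args = ap.parse_args()

    src = args.out_root / "complexes" / "LD.pdb"
    if not src.exists():
        print("run analysis/01_build_complexes.py first", file=sys.stderr)
        return 1
    outdir = args.out_root / "ensemble"
    outdir.mkdir(parents=True, exist_ok=True)

    ld = read_pdb(src, model_policy="first")[0]
    ref = records_to_frame(complex_records(ld))
    # fluctuate around the model's own per-residue conformation
    spec = EnsembleSpec(
        n_models=args.frames,
        p_mean=ref["P"].to_numpy(float).tolist(),
        p_sd=8.0,
        chi_mean=ref["chi"].to_numpy(float).tolist(),
        chi_sd=8.0,
        noise_sd=0.05,
        seed=args.seed,
    )
    ens = generate_ensemble(ld, spec)

    summary = conformer_distribution(ens)
    summary.to_csv(outdir / "conformer_distribution_LD.csv")
    tab = summary.table
    n_s = int((tab["frac_S"] > 0.5).sum())
    n_syn = int((tab["frac_syn"] > 0.5).sum())
    print(f"{args.frames}-frame ensemble of the L-RNA/D-Rz model "
          f"({len(tab)} residues): {n_s} predominantly S-type sugars, "
          f"{n_syn} predominantly syn bases")

    pairing = hammerhead_pairing(sequence_of(ld.chain("R")),
                                 sequence_of(ld.chain("S")))
    regions = region_selections(pairing, len(ld.chain("R").residues),
                                len(ld.chain("S").residues))
    series = region_rmsd_series(ens, regions)
    series.to_csv(outdir / "region_rmsd_series_LD.csv", index=False,
                  float_format="%.4f")
    means = series.groupby("region")["rmsd"].mean().round(3)
    print("mean backbone RMSD to frame 0 by region (angstrom):")
    print(means.to_string())
    print("-> fluctuations here reflect only the prescribed sugar/chi "
          "resampling plus Cartesian noise, so all regions move on the same "
          "scale; a physical trajectory would differentiate them further")
    print(f"wrote {outdir}/")
    return 0


if __name__ == "__main__":
    sys.exit(main())
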