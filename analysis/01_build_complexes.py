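#!/usr/bin/env python
"""Build the four homo/heterochiral hammerhead complexes and validate them.

Derives the pairing topology (helices 1-3, GAAA loop, GUC|N cleavage site)
from the two sequences, builds the D-RNA/D-Rz scaffold, produces
L-RNA/L-Rz by the mirror operation, L-RNA/D-Rz by base-anchored
enantiomerization of the substrate strand plus Watson-Crick-restrained
refinement, and D-RNA/L-Rz by mirroring that.  Writes PDBs, per-residue
conformational tables, chirality reports and the heavy-atom accounting
under results/complexes/.
"""

import argparse
import sys
from pathlib import Path

from mirrorhh.pipeline import PipelineConfig, run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-root", type=Path, default=Path("results"))
    args = ap.parse_args()

    outdir = args.out_root / "complexes"
    manifest = run_pipeline(PipelineConfig(output_dir=str(outdir),
                                           seed=args.seed))

    print(f"wrote {outdir}/")
    print(f"cleavage site: substrate position {manifest['cleavage_site'][1]} "
          f"(the C of the GUC|N motif)")
    print(f"helix pair counts: {manifest['helix_pair_counts']} "
          f"(helix 2 is the 4 G-C stem closing the GAAA loop)")
    print(f"heavy atoms: {manifest['heavy_atoms']}")
    print(f"chirality verdicts: {manifest['chirality_verdicts']}")
    print(f"heterochiral H1/H3 Watson-Crick pairs detected after "
          f"enantiomerization + refinement: "
          f"{manifest['heterochiral_wc_detected']}/"
          f"{manifest['heterochiral_wc_expected']}")
    sym = manifest["mirror_symmetry_max_dev_deg"]
    print(f"mirror symmetry (max P/chi deviation, deg): "
          f"D/D vs L/L {sym['DD vs LL']:.2e}, L/D vs D/L {sym['LD vs DL']:.2e} "
          f"-- the homochiral and heterochiral pairs are exact mirror images")


if __name__ == "__main__":
    sys.exit(main())
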