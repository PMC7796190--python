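"""End-to-end workflow: from the two sequences to the four homo- and
heterochiral complex models and their conformational reports.

Stages (all deterministic under the config seed):

1. pairing map + cleavage site from the sequences
2. D-RNA/D-Rz scaffold build (+ restrained refinement)
3. L-RNA/L-Rz by the mirror operation
4. L-RNA/D-Rz by base-anchored enantiomerization of the substrate + refine
5. D-RNA/L-Rz by mirroring L-RNA/D-Rz
6. chirality validation of all four complexes
7. conformational records, torsion-difference profiles, circular summary
8. (optional) ensemble generation + conformer/RMSD-series analyses
9. heavy-atom accounting table

Outputs are PDB + CSV/JSON files plus a machine-readable manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import RIBOZYME_33NT, SUBSTRATE_14NT
from .chirality import mirror_structure, validate_chirality
from .compare_analyze import (
    circular_summary,
    conformer_distribution,
    region_rmsd_series,
    rmsd_selection,
)
from .complex_model import (
    RefinementSettings,
    build_heterochiral,
    count_heavy_atoms,
    detect_wc_pairs_3d,
    hammerhead_pairing,
    restrained_refine,
)
from .conformation import complex_records, records_to_frame
from .structure_io import write_pdb
from .synthetic import EnsembleSpec, build_hammerhead_scaffold, generate_ensemble

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "region_selections"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    ribozyme: str = RIBOZYME_33NT
    substrate: str = SUBSTRATE_14NT
    enantiomerize_strand: str = "S"     # strand flipped to make the L/D complex
    refinement: RefinementSettings = field(default_factory=RefinementSettings)
    ensemble: EnsembleSpec | None = None
    output_dir: str = "pipeline_out"
    seed: int = 0
    write_pdbs: bool = True

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        payload = dict(payload)
        if "refinement" in payload and isinstance(payload["refinement"], dict):
            payload["refinement"] = RefinementSettings(**payload["refinement"])
        if "ensemble" in payload and isinstance(payload["ensemble"], dict):
            payload["ensemble"] = EnsembleSpec(**payload["ensemble"])
        return cls(**payload)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out


def region_selections(pairing, ribozyme_len: int, substrate_len: int) -> dict:
    """Default named regions: the three helices, the catalytic core, each
    strand, and everything."""
    regions = {}
    for h in ("H1", "H2", "H3"):
        refs = []
        for p in pairing.helix_pairs(h):
            refs.extend(p.residues())
        regions[{"H1": "helix1", "H2": "helix2", "H3": "helix3"}[h]] = sorted(set(refs))
    core = sorted(ref for ref in pairing.unpaired if ref[0] == "R")
    if pairing.cleavage_site:
        core.append(pairing.cleavage_site)
    regions["core"] = sorted(set(core))
    regions["substrate"] = "S"
    regions["ribozyme"] = "R"
    regions["all"] = None
    return regions


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest (also written to disk)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": [], "files": {}}
    if manifest["config"].get("ensemble") and config.ensemble is not None:
        manifest["config"]["ensemble"]["seed"] = int(config.seed)
    (outdir / "config.json").write_text(json.dumps(manifest["config"], indent=2,
                                                   default=str))

    def persist_partial(stage, exc):
        manifest["aborted_at"] = stage
        manifest["error"] = str(exc)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                         default=str))

    def record(path: Path):
        manifest["files"][path.name] = _sha256(path)

    # stage 1: pairing
    stage = "pairing"
    try:
        pairing = hammerhead_pairing(config.ribozyme, config.substrate)
    except Exception as exc:
        persist_partial(stage, exc)
        raise PipelineError(stage, str(exc)) from exc
    manifest["stages"].append(stage)
    manifest["cleavage_site"] = list(pairing.cleavage_site)
    manifest["helix_pair_counts"] = {h: len(pairing.helix_pairs(h))
                                     for h in ("H1", "H2", "H3")}
    p_path = outdir / "pairing.json"
    p_path.write_text(pairing.to_json())
    record(p_path)
    (outdir / "pairing.dbn").write_text(
        pairing.to_dot_bracket(len(config.ribozyme), len(config.substrate)) + "\n")
    record(outdir / "pairing.dbn")

    complexes: dict[str, object] = {}
    try:
        # stage 2: D/D scaffold + refinement
        stage = "build-DD"
        scaffold = build_hammerhead_scaffold(config.ribozyme, config.substrate,
                                             pairing)
        dd, _trace = restrained_refine(scaffold, pairing, config.refinement)
        complexes["DD"] = dd
        manifest["stages"].append(stage)

        # stage 3: L/L by mirror
        stage = "mirror-LL"
        complexes["LL"] = mirror_structure(dd)
        manifest["stages"].append(stage)

        # stage 4: L/D by enantiomerization + refine
        stage = "heterochiral-LD"
        complexes["LD"] = build_heterochiral(dd, config.enantiomerize_strand,
                                             pairing, config.refinement)
        manifest["stages"].append(stage)

        # stage 5: D/L by mirror of L/D
        stage = "mirror-DL"
        complexes["DL"] = mirror_structure(complexes["LD"])
        manifest["stages"].append(stage)

        # stage 6: chirality validation
        stage = "validate-chirality"
        verdicts = {}
        for name, cx in complexes.items():
            report = validate_chirality(cx)
            verdicts[name] = report.verdict
            vp = outdir / f"chirality_{name}.json"
            vp.write_text(report.to_json())
            record(vp)
        manifest["chirality_verdicts"] = verdicts
        manifest["stages"].append(stage)

        if config.write_pdbs:
            for name, cx in complexes.items():
                pp = outdir / f"{name}.pdb"
                write_pdb(cx, pp)
                record(pp)

        # stage 7: conformational analyses
        stage = "conformation"
        for name, cx in complexes.items():
            df = records_to_frame(complex_records(cx))
            cp = outdir / f"conformation_{name}.csv"
            df.to_csv(cp, index=False, float_format="%.6f")
            record(cp)
        from .compare_analyze import torsion_difference_profile
        diff = torsion_difference_profile(complexes["LD"], complexes["DD"])
        dp = outdir / "torsion_difference_LD_vs_DD.csv"
        diff.to_csv(dp, index=False, float_format="%.6f")
        record(dp)
        table, symmetry = circular_summary(list(complexes.items()))
        tp = outdir / "circular_summary.csv"
        table.to_csv(tp, index=False, float_format="%.6f")
        record(tp)
        manifest["mirror_symmetry_max_dev_deg"] = symmetry
        wc = detect_wc_pairs_3d(complexes["LD"])
        wanted = {frozenset(p.residues()) for p in pairing.pairs
                  if p.res_a[0] != p.res_b[0]}
        got = {frozenset(p.residues()) for p in wc}
        manifest["heterochiral_wc_detected"] = len(wanted & got)
        manifest["heterochiral_wc_expected"] = len(wanted)
        manifest["stages"].append(stage)

        # stage 8: optional ensemble analyses
        if config.ensemble is not None:
            stage = "ensemble"
            spec = dataclasses.replace(config.ensemble, seed=int(config.seed))
            ens = generate_ensemble(complexes["LD"], spec)
            summary = conformer_distribution(ens)
            sp = outdir / "conformer_distribution_LD.csv"
            summary.to_csv(sp)
            record(sp)
            regions = region_selections(pairing, len(config.ribozyme),
                                        len(config.substrate))
            series = region_rmsd_series(ens, regions)
            rp = outdir / "region_rmsd_series_LD.csv"
            series.to_csv(rp, index=False, float_format="%.6f")
            record(rp)
            manifest["stages"].append(stage)

        # stage 9: heavy-atom accounting
        stage = "heavy-atoms"
        acct = pd.DataFrame([
            {"selection": "substrate", "n_heavy": count_heavy_atoms(config.substrate)},
            {"selection": "ribozyme", "n_heavy": count_heavy_atoms(config.ribozyme)},
            {"selection": "complex",
             "n_heavy": count_heavy_atoms(config.substrate)
             + count_heavy_atoms(config.ribozyme)},
            {"selection": "built DD structure", "n_heavy": dd.atom_count()},
        ])
        ap = outdir / "heavy_atoms.csv"
        acct.to_csv(ap, index=False)
        record(ap)
        manifest["heavy_atoms"] = {r["selection"]: int(r["n_heavy"])
                                   for r in acct.to_dict("records")}
        manifest["stages"].append(stage)
    except PipelineError:
        raise
    except Exception as exc:
        persist_partial(stage, exc)
        raise PipelineError(stage, str(exc)) from exc

    payload = json.dumps(manifest, indent=2, sort_keys=True, default=str)
    manifest["manifest_sha256"] = hashlib.sha256(payload.encode()).hexdigest()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True, default=str))
    return manifest
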