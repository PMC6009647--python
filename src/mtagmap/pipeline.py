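"""End-to-end orchestration of the synthetic labeling experiment.

A YAML config drives seeded runs of the pipeline stages — reference-map
construction, molecule simulation, alignment, consensus / off-site
statistics, plasmid-field counting, kinetics — writing each stage's outputs
plus a manifest (config echo, seed, package version) so any run can be
reproduced bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .blinkcount import MaskParams, count_labels, reconstruct_masks
from .consensus import build_consensus, offsite_stats, place_labels, remove_dual_strand
from .mapalign import AlignmentParams, align_best_orientation
from .refmap import ReferenceMap, find_sites, read_fasta, write_map
from .sequences import AMPLICON_SITE_LAYOUT, synthetic_sequence
from .simulate import SimConfig, simulate_molecules, simulate_plasmid_field, traces_to_frame
from .stats import fit_pseudo_first_order

__all__ = ["run_pipeline", "load_config", "COMBED_FRAGMENT_REGIME"]

# The combed-fragment study regime: a 9-site, 5 kb map observed on 180
# molecules at per-site efficiency 0.92 and 0.46 off-target labels per kb.
COMBED_FRAGMENT_REGIME = {
    "map": {"length": 5000, "motif": "TCGA",
            "site_layout": list(AMPLICON_SITE_LAYOUT)},
    "simulate": {"p_site": 0.92, "rho_off": 0.46, "sigma_loc": 100.0,
                 "stretch_mean": 1.6, "stretch_tol": 0.1,
                 "n_molecules": 180},
    "align": {},
    "consensus": {"bin_width": 50.0},
    "stages": ["map", "molecules", "align", "consensus"],
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if cfg.get("preset") == "combed-fragment":
        merged = json.loads(json.dumps(COMBED_FRAGMENT_REGIME))
        for key, val in cfg.items():
            if isinstance(val, dict) and isinstance(merged.get(key), dict):
                merged[key].update(val)
            else:
                merged[key] = val
        cfg = merged
    return cfg


def _build_map(cfg: dict, seed: int) -> ReferenceMap:
    mc = cfg.get("map", {})
    if "fasta" in mc:
        seqs = read_fasta(mc["fasta"])
        name = mc.get("sequence", next(iter(seqs)))
        return find_sites(seqs[name], mc.get("motif", "TCGA"), name=name)
    layout = mc.get("site_layout", list(AMPLICON_SITE_LAYOUT))
    seq = synthetic_sequence(
        mc.get("length", 5000), mc.get("motif", "TCGA"), layout,
        seed=seed, name=mc.get("name", "synthetic-fragment"))
    return find_sites(seq, mc.get("motif", "TCGA"),
                      name=mc.get("name", "synthetic-fragment"))


def run_pipeline(config: str | Path | dict, outdir: str | Path,
                 seed: int | None = None) -> dict:
    """Run the configured stages in dependency order; returns the manifest.

    ``seed`` overrides the config's master seed.  Each enabled stage writes
    its outputs under ``outdir``; the manifest echoes the resolved config.
    """
    cfg = load_config(config) if not isinstance(config, dict) else dict(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        cfg["seed"] = int(seed)
    master_seed = int(cfg.get("seed", 0))
    stages = cfg.get("stages", ["map", "molecules", "align", "consensus"])
    rng_map, rng_mol, rng_field, rng_kin = [
        np.random.default_rng(s)
        for s in np.random.SeedSequence(master_seed).generate_state(4)
    ]

    manifest: dict = {"config": cfg, "seed": master_seed,
                      "version": __version__, "outputs": {}}

    refmap = _build_map(cfg, master_seed)
    if "map" in stages:
        write_map(refmap, outdir / "sites.bed")
        manifest["outputs"]["map"] = "sites.bed"

    traces = truths = None
    sim_cfg = SimConfig(**{**cfg.get("simulate", {}), "seed": master_seed})
    if "molecules" in stages:
        traces, truths = simulate_molecules(refmap, sim_cfg, rng=rng_mol)
        traces_to_frame(traces).to_csv(outdir / "traces.csv", index=False)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(
                [{"stretch": t.stretch, "flipped": t.flipped,
                  "n_on": len(t.on_site_labels),
                  "n_off": len(t.off_site_labels)} for t in truths], fh)
        manifest["outputs"]["molecules"] = "traces.csv"

    placed_all = []
    if "align" in stages and traces is not None:
        params = AlignmentParams(**cfg.get("align", {}))
        with open(outdir / "alignments.jsonl", "w") as fh:
            for tr in traces:
                aln = align_best_orientation(tr, refmap, params)
                fh.write(json.dumps({
                    "molecule_id": tr.molecule_id,
                    "orientation": aln.orientation,
                    "stretch": aln.fitted_stretch,
                    "offset": aln.fitted_offset,
                    "score": aln.score,
                    "pairs": aln.pairs,
                    "unmatched": aln.unmatched_labels,
                }) + "\n")
                placed = remove_dual_strand(place_labels(aln, tr, refmap, params))
                placed_all.extend(placed)
        pd.DataFrame(
            [{"molecule_id": p.molecule_id, "position_bp": p.position,
              "status": p.status, "site": p.site} for p in placed_all]
        ).to_csv(outdir / "placed_labels.csv", index=False)
        manifest["outputs"]["align"] = "alignments.jsonl"

    if "consensus" in stages and placed_all:
        ccfg = cfg.get("consensus", {})
        hist = build_consensus(placed_all, refmap,
                               bin_width=ccfg.get("bin_width", 50.0),
                               n_molecules=sim_cfg.n_molecules)
        pd.DataFrame({"bin_start": hist.edges[:-1], "count": hist.counts}
                     ).to_csv(outdir / "consensus.csv", index=False)
        stats = offsite_stats(placed_all, refmap, sim_cfg.n_molecules,
                              sigma_loc=sim_cfg.sigma_loc)
        with open(outdir / "offsite_stats.json", "w") as fh:
            json.dump({k: (v if not isinstance(v, float) or np.isfinite(v)
                           else None)
                       for k, v in asdict(stats).items()}, fh, indent=2)
        manifest["outputs"]["consensus"] = "consensus.csv"

    if "counting" in stages:
        ccfg = cfg.get("counting", {})
        field = simulate_plasmid_field(
            refmap, sim_cfg, ccfg.get("n_plasmids", 100),
            field_size=ccfg.get("field_size", 256),
            decoy_fraction=ccfg.get("decoy_fraction", 0.0), rng=rng_field)
        masks = reconstruct_masks(field.backbone_points, field.field_size,
                                  MaskParams(**ccfg.get("masks", {})))
        summary = count_labels(masks, field.label_positions)
        with open(outdir / "label_counts.json", "w") as fh:
            json.dump({"mean": summary.mean, "sem": summary.sem,
                       "n_plasmids": summary.n_plasmids,
                       "histogram": summary.histogram}, fh, indent=2)
        manifest["outputs"]["counting"] = "label_counts.json"

    if "kinetics" in stages:
        from .simulate import simulate_kinetics

        kcfg = cfg.get("kinetics", {})
        times = kcfg.get("times", [2, 5, 10, 20, 30, 60])
        samples, truth = simulate_kinetics(
            times, kcfg.get("k", 0.28), kcfg.get("p_inf", 0.875),
            refmap, sim_cfg, n_per_time=kcfg.get("n_per_time", 300),
            rng=rng_kin)
        means = [float(np.mean(s)) for s in samples]
        fit = fit_pseudo_first_order(times, means)
        with open(outdir / "kinetics.json", "w") as fh:
            json.dump({"times": list(times), "means": means,
                       "k_prime": fit.k_prime, "plateau": fit.plateau,
                       "truth": truth}, fh, indent=2)
        manifest["outputs"]["kinetics"] = "kinetics.json"

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
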