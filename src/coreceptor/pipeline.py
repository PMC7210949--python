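"""Umbrella pipeline runner: chain annotate → restraints → scan → energetics.

Each stage reads the inputs named in the config, runs the corresponding
library module and returns a JSON-serializable report. Writers are
deterministic: sorted keys, fixed float formatting, no timestamps in data
outputs (stage wall-times go to the log only).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

from . import binding, energetics, seqann, xlink
from .io import PipelineConfig, read_disorder_tsv, read_fasta

log = logging.getLogger("coreceptor")


def _stage_annotate(cfg: PipelineConfig) -> dict:
    records = read_fasta(cfg.paths["fasta"], offsets=cfg.paths.get("offsets"))
    report: dict = {}
    for rec in records:
        ann = seqann.segment_domains(rec)
        entry: dict = {
            "canonical": ann.canonical,
            "spans": {k: list(v) for k, v in sorted(ann.spans.items())},
            "kr_position": ann.kr_position,
        }
        if ann.canonical:
            entry["degron_tail_length"] = seqann.degron_tail_length(ann)
        if "disorder" in cfg.paths:
            prof = read_disorder_tsv(cfg.paths["disorder"], protein_id=rec.id)
            if len(prof.scores) == len(rec.sequence):
                _, fractions = seqann.classify_disorder(
                    prof, lo=cfg.disorder_lo, hi=cfg.disorder_hi
                )
                entry["disorder_fractions"] = {
                    k: round(v, 6) for k, v in sorted(fractions.items())
                }
        report[rec.id] = entry
    return report


def _stage_restraints(cfg: PipelineConfig) -> dict:
    links = xlink.load_xl_table(cfg.paths["xl_table"], offsets=cfg.paths.get("offsets"))
    net = xlink.build_network(links)
    filtered, classes = xlink.replicate_filter(net, cfg.paths.get("min_support", 2))
    table = xlink.export_circular_map(filtered, classes)
    out = Path(cfg.paths.get("out_dir", "."))
    table.to_csv(out / "xl_map.tsv", sep="\t", index=False)
    intra, inter = xlink.classify_links(filtered)
    return {
        "n_links_raw": len(net.support),
        "n_links_filtered": len(filtered.support),
        "n_intra": len(intra),
        "n_inter": len(inter),
    }


def _stage_bindfit(cfg: PipelineConfig) -> dict:
    import numpy as np
    import pandas as pd

    df = pd.read_csv(cfg.paths["binding"])
    pivot_t = df.pivot_table(index="ligand_nM", columns="replicate", values="total")
    pivot_n = df.pivot_table(index="ligand_nM", columns="replicate", values="nonspecific")
    ds = binding.BindingDataset(
        ligand_nM=np.asarray(pivot_t.index),
        total_counts=pivot_t.to_numpy(),
        nonspecific_counts=pivot_n.to_numpy(),
    )
    fit = binding.fit_one_site(ds, mode=cfg.paths.get("bind_mode", "joint"))
    return {
        "kd_nM": round(fit.kd_nM, 6),
        "bmax": round(fit.bmax, 6),
        "ns_slope": round(fit.ns_slope, 8),
        "se_kd": round(fit.se_kd, 6) if fit.se_kd == fit.se_kd else None,
        "converged": fit.converged,
    }


def _stage_energetics(cfg: PipelineConfig) -> dict:
    traj = energetics.read_energy_csv(cfg.paths["traj"])
    t_eq = cfg.paths.get("t_eq_ps", traj.times[len(traj.times) // 2])
    mean, sem, n = energetics.equilibrated_stats(traj, t_eq)
    report = {"dg_mean": round(mean, 6), "dg_sem": round(sem, 6), "n_frames": n}
    if "decomp" in cfg.paths:
        table = energetics.read_decomposition_csv(cfg.paths["decomp"])
        report["hotspots"] = energetics.call_hotspots(table, cfg.hotspot_threshold)
    return report


_STAGES = {
    "annotate": _stage_annotate,
    "restraints": _stage_restraints,
    "bindfit": _stage_bindfit,
    "energetics": _stage_energetics,
}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the configured stages in order; raises on any stage failure.

    Missing input paths raise ``KeyError`` naming the path key. Identical
    config and seed give identical report content.
    """
    cfg.validate()
    report: dict = {"config": cfg.to_dict(), "stages": {}}
    for stage in cfg.stages:
        if stage not in _STAGES:
            raise ValueError(f"unknown stage {stage!r}; known: {sorted(_STAGES)}")
        t0 = time.perf_counter()
        report["stages"][stage] = _STAGES[stage](cfg)
        log.info("stage %s finished in %.2fs", stage, time.perf_counter() - t0)
    out_dir = cfg.paths.get("out_dir")
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
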