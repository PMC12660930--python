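"""End-to-end orchestration: simulate -> QC -> assignment -> methylome stats.

Filters apply in order: basic RNA/WGBS QC, coverage-based doublet
censoring, organelle filter, cluster assignment, VN/SN marker-ratio
reassignment, then conversion QC (which censors nuclei from methylome
analyses only). Every stage reports attrition counts into a run manifest;
stage outputs are cached keyed by a config/input checksum so partial reruns
only recompute downstream of a change. All randomness flows from the
config seed, and two identical runs produce byte-identical TSV outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .cluster_assign import (assign_clusters, normalize_expression,
                             vn_sn_doublet_reassign, VN_AND_SN)
from .io_formats import (read_bed, read_chrom_sizes, read_counts,
                         read_meth_calls, read_sample_sheet, write_bedgraph)
from .methylome_stats import effect_grid, pool_cluster, region_means_table
from .nucleus_qc import QCThresholds, records_to_frame, run_qc
from .synthetic_data import (SimConfig, preset_config, simulate_dataset,
                             write_fixture, ConfigError)


def _canonical_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def validate_config(cfg: Mapping) -> dict:
    cfg = dict(cfg)
    if "simulate" not in cfg and "input_dir" not in cfg:
        raise ConfigError("config needs a 'simulate' section or an 'input_dir'")
    if "simulate" in cfg:
        sim = cfg["simulate"]
        if not isinstance(sim, Mapping) or not ({"preset", "config"} & set(sim)):
            raise ConfigError("'simulate' needs a 'preset' name or a 'config' mapping")
    cfg.setdefault("seed", 0)
    if not isinstance(cfg["seed"], int):
        raise ConfigError("seed must be an integer")
    cfg.setdefault("qc", {})
    cfg.setdefault("effects", {})
    unknown = set(cfg["qc"]) - {f.name for f in QCThresholds.__dataclass_fields__.values()}
    if unknown:
        raise ConfigError(f"unknown qc threshold(s): {sorted(unknown)}")
    return cfg


def _load_fixture(path: Path):
    meth = {}
    for f in sorted((path / "meth").glob("*.tsv")):
        meth[f.stem] = read_meth_calls(f)
    organelle = []
    org_file = path / "organelle_genes.txt"
    if org_file.exists():
        organelle = [l.strip() for l in open(org_file) if l.strip()]
    counts = read_counts(path / "counts.tsv", organelle)
    regions = {f.stem: read_bed(f) for f in sorted((path / "regions").glob("*.bed"))}
    sheet = read_sample_sheet(path / "sample_sheet.tsv")
    sizes = read_chrom_sizes(path / "chrom.sizes")
    markers = yaml.safe_load(open(path / "markers.yaml"))
    return meth, counts, regions, sheet, sizes, markers


class _StageCache:
    def __init__(self, out_dir: Path):
        self.dir = out_dir / ".cache"
        self.dir.mkdir(parents=True, exist_ok=True)

    def fresh(self, stage: str, key: str, outputs: list[Path]) -> bool:
        stamp = self.dir / f"{stage}.json"
        if not stamp.exists() or not all(p.exists() for p in outputs):
            return False
        return json.loads(stamp.read_text()).get("key") == key

    def store(self, stage: str, key: str) -> None:
        (self.dir / f"{stage}.json").write_text(json.dumps({"key": key}))


def run_pipeline(config: Mapping | str | Path, out_dir: str | Path) -> dict:
    """Run every stage; returns the run manifest (also written as JSON)."""
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(open(config))
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cache = _StageCache(out)
    manifest: dict = {
        "tool": "snmctkit", "version": __version__,
        "config_hash": _canonical_hash(cfg), "seed": cfg["seed"],
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }

    # ---- stage: inputs -------------------------------------------------
    sim_key = _canonical_hash({"sim": cfg.get("simulate"), "seed": cfg["seed"],
                               "input": cfg.get("input_dir")})
    data_dir = out / "data"
    if "simulate" in cfg:
        if not cache.fresh("simulate", sim_key, [data_dir / "counts.tsv"]):
            sim = cfg["simulate"]
            simconf = (preset_config(sim["preset"], seed=cfg["seed"])
                       if "preset" in sim
                       else SimConfig.from_dict({**sim["config"], "seed": cfg["seed"]}))
            write_fixture(simulate_dataset(simconf), data_dir)
            cache.store("simulate", sim_key)
        source = data_dir
    else:
        source = Path(cfg["input_dir"])
    meth, counts, regions, sheet, sizes, markers = _load_fixture(source)
    manifest["stages"]["inputs"] = {
        "nuclei": len(meth), "genes": len(counts.genes),
        "region_sets": {k: len(v) for k, v in regions.items()},
        "source_checksum": _canonical_hash(sorted(t.nucleus_id for t in meth.values())),
    }

    # ---- stage: QC -----------------------------------------------------
    th = QCThresholds(**cfg["qc"])
    records = run_qc(meth, counts, sizes, th)
    qc_df = records_to_frame(records).sort_index()
    qc_path = out / "qc_report.tsv"
    qc_df.to_csv(qc_path, sep="\t")
    attrition = {flag: int(qc_df[flag].sum())
                 for flag in ("fail_rna", "fail_wgbs", "fail_organelle",
                              "doublet_coverage", "fail_conversion")}
    rna_pass = qc_df.index[~(qc_df["fail_rna"] | qc_df["fail_wgbs"]
                             | qc_df["fail_organelle"] | qc_df["doublet_coverage"])]
    manifest["stages"]["qc"] = {"in": len(qc_df), "out": len(rna_pass),
                                "censored": attrition,
                                "thresholds": {k: getattr(th, k) for k in cfg["qc"]} or "defaults"}

    # ---- stage: cluster assignment ------------------------------------
    norm = normalize_expression(counts).loc[:, list(rna_pass)]
    assignment = assign_clusters(norm, markers)
    assignment = vn_sn_doublet_reassign(norm, assignment, markers)
    clusters_df = assignment.to_frame().sort_index()
    clusters_df.to_csv(out / "clusters.tsv", sep="\t")
    manifest["stages"]["assign"] = {
        "in": len(clusters_df),
        "reassigned_vn_sn": int(clusters_df["reassigned_vn_sn"].sum()),
        "per_cluster": clusters_df["cluster"].value_counts().sort_index().to_dict(),
    }

    # ---- stage: methylome ----------------------------------------------
    meth_ok = [n for n in rna_pass
               if not qc_df.at[n, "fail_conversion"]
               and clusters_df.at[n, "cluster"] != VN_AND_SN]
    labels = clusters_df["cluster"].to_dict()
    genotype_of = sheet["genotype"].to_dict()
    tracks = pool_cluster(meth, labels, genotype_of, include=meth_ok)
    track_dir = out / "tracks"
    track_dir.mkdir(exist_ok=True)
    for (cluster, genotype), track in tracks.items():
        write_bedgraph(track, track_dir / f"{cluster}.{genotype}.CG.bedgraph",
                       context="CG")
    means = region_means_table({n: meth[n] for n in meth_ok}, regions,
                               contexts=tuple(cfg["effects"].get("contexts", ("CG",))))
    means.to_csv(out / "region_means.tsv", sep="\t", index=False)
    genos = sorted({genotype_of[n] for n in meth_ok})
    pairs = [tuple(p) for p in cfg["effects"].get(
        "pairs", [[genos[0], g] for g in genos[1:]])]
    if pairs:
        grid = effect_grid(means, labels, genotype_of, pairs)
        grid.to_csv(out / "effects.tsv", sep="\t", index=False)
        manifest["stages"]["effects"] = {"rows": len(grid), "pairs": [list(p) for p in pairs]}
    manifest["stages"]["methylome"] = {"nuclei": len(meth_ok),
                                       "tracks": len(tracks)}

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
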