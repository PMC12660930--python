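"""Synthetic single-nucleus joint methylome + transcriptome fixtures.

The generator emulates the statistical structure of pollen snmCT-seq data:

* haploid nuclei — after deduplication each singleton carries at most one
  read per cytosine, so per-site coverage is 0/1 and a methylation call is a
  single Bernoulli draw from the regional methylation level;
* a developmental trajectory (MN -> MNtoVN -> VN1..VN5, with a GN/SN branch)
  in which designated "CG hypo DMR" regions progressively lose CG
  methylation and pericentromeric "CHH hyper DMR" regions progressively gain
  CHH methylation along VN maturation;
* genotype effects: extra demethylation at target regions in a mutant
  (``mutA``), cancelled at a flagged "rescued" subset of regions in a second
  mutant (``mutAB``);
* physical doublets modelled as the union of two complete nuclei's read
  sets (mature-VN + SN pairs preferentially), giving both >1x site coverage
  and mixed marker expression from one mechanism;
* bisulfite-conversion failures as false-methylated calls at a fixed rate on
  every site, chloroplast included (the chloroplast is truly unmethylated,
  so apparent chloroplast mC estimates 1 - conversion);
* marker-driven RNA counts: negative-binomial counts with stage-graded
  marker programs (mature-VN markers shared across VN4/VN5, germline genes
  shared between GN and SN) plus organelle-read contamination.

All randomness flows from one seed; per-nucleus substreams are keyed by a
CRC32 of the nucleus id so output is byte-stable across runs and processes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io_formats import (
    CountMatrix,
    MethCallTable,
    RegionSet,
    write_bed,
    write_chrom_sizes,
    write_counts,
    write_meth_calls,
    write_sample_sheet,
)

CONTEXTS = ("CG", "CHG", "CHH")

#: default developmental ordering; GN/SN form the germline branch
DEFAULT_CLUSTER_ORDER = (
    "MN", "MNtoVN", "VN1", "VN1to2", "VN2", "VN3", "VN4", "VN5", "GN", "SN",
)
VN_CLUSTERS = ("VN1", "VN1to2", "VN2", "VN3", "VN4", "VN5")
MATURE_VN = ("VN4", "VN5")

PLANTED_CATEGORIES = (
    "low_rna", "few_genes", "low_wgbs", "high_organelle", "conversion",
)


class ConfigError(ValueError):
    """Impossible or inconsistent simulation configuration."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class RegionModel:
    """One named region set plus the methylation model over it.

    ``cluster_deltas``/``genotype_deltas`` map context -> {cluster|genotype
    -> additive delta on the methylation fraction}; genotype deltas apply
    only in ``genotype_delta_clusters`` and are cancelled for
    ``rescued_genotypes`` at the ``rescue_fraction`` of regions flagged
    rescued. Resulting fractions are clipped to [0, 1].
    """

    name: str
    n: int = 30
    length: int = 1000
    baseline: dict = field(default_factory=lambda: {"CG": 0.8, "CHG": 0.3, "CHH": 0.05})
    site_density: dict = field(default_factory=lambda: {"CG": 20.0, "CHG": 6.0, "CHH": 10.0})
    cluster_deltas: dict = field(default_factory=dict)
    genotype_deltas: dict = field(default_factory=dict)
    genotype_delta_clusters: tuple = VN_CLUSTERS
    rescue_fraction: float = 0.0
    rescued_genotypes: tuple = ("mutAB",)
    placement: str = "arms"  # "arms" or "pericentromere"


@dataclass
class RnaModel:
    n_genes: int = 1000
    n_organelle: int = 20
    markers_per_cluster: int = 8
    marker_fold: float = 8.0
    #: fold for stage-graded expression of a marker outside its home cluster
    adjacent_fold: float = 2.5
    baseline_mean: float = 2.0
    #: negative-binomial size parameter (variance = mu + mu^2 / dispersion)
    dispersion: float = 10.0
    organelle_fraction_mean: float = 0.03
    organelle_fraction_shape: float = 5.0
    libsize_sigma: float = 0.2


def default_region_models() -> list[RegionModel]:
    order = ("MN", "MNtoVN", "VN1", "VN1to2", "VN2", "VN3", "VN4", "VN5")
    cg_hypo = {c: d for c, d in zip(order, (0.0, -0.10, -0.30, -0.42, -0.50,
                                            -0.55, -0.57, -0.58))}
    cg_hypo.update({"GN": 0.0, "SN": 0.03})
    chh_hyper = {c: d for c, d in zip(order, (0.0, 0.03, 0.08, 0.12, 0.18,
                                              0.24, 0.30, 0.34))}
    return [
        RegionModel(
            name="cg_hypo_dmr", n=40, length=1000,
            baseline={"CG": 0.85, "CHG": 0.35, "CHH": 0.08},
            cluster_deltas={"CG": dict(cg_hypo),
                            "CHG": {k: v * 0.4 for k, v in cg_hypo.items()}},
        ),
        RegionModel(
            name="chh_hyper_dmr", n=20, length=2000,
            baseline={"CG": 0.90, "CHG": 0.60, "CHH": 0.05},
            site_density={"CG": 8.0, "CHG": 8.0, "CHH": 25.0},
            cluster_deltas={"CHH": chh_hyper},
            placement="pericentromere",
        ),
        RegionModel(name="control_regions", n=30, length=1000),
    ]


@dataclass
class SimConfig:
    seed: int = 0
    n_chrom: int = 2
    chrom_len: int = 300_000
    chloro_len: int = 50_000
    chloro_chrom: str = "ChrC"
    cluster_order: tuple = DEFAULT_CLUSTER_ORDER
    clusters: tuple | None = None  # subset to simulate; default = cluster_order
    genotypes: tuple = ("WT", "mutA", "mutAB")
    n_nuclei_per_cluster_per_genotype: int = 20
    #: background sites per kb per context (outside modelled regions)
    site_density: float = 3.0
    background_meth: dict = field(default_factory=lambda: {"CG": 0.30, "CHG": 0.12, "CHH": 0.04})
    region_models: list = field(default_factory=default_region_models)
    capture_prob: float = 0.05
    chloro_capture_prob: float = 0.5
    doublet_rate: float = 0.0
    doublet_pairing: str = "vn_sn"  # or "random"
    conversion_failure_rate: float = 0.0
    conversion_failure_level: float = 0.3
    gn_diploid: bool = False
    rna: RnaModel = field(default_factory=RnaModel)
    #: planted QC failures, category -> count (assigned to leading singletons)
    planted_failures: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.clusters is None:
            self.clusters = tuple(self.cluster_order)
        self.cluster_order = tuple(self.cluster_order)
        self.clusters = tuple(self.clusters)
        self.genotypes = tuple(self.genotypes)
        self.validate()

    def validate(self) -> None:
        for name, p in [("capture_prob", self.capture_prob),
                        ("chloro_capture_prob", self.chloro_capture_prob),
                        ("doublet_rate", self.doublet_rate),
                        ("conversion_failure_rate", self.conversion_failure_rate),
                        ("conversion_failure_level", self.conversion_failure_level)]:
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}={p} outside [0, 1]")
        if self.doublet_rate >= 1.0:
            raise ConfigError("doublet_rate must be < 1")
        for c in self.clusters:
            if c not in self.cluster_order:
                raise ConfigError(f"cluster {c!r} not in cluster_order")
        for m in self.region_models:
            if not 0.0 <= m.rescue_fraction <= 1.0:
                raise ConfigError(f"{m.name}: rescue_fraction outside [0, 1]")
            for ctx, v in m.baseline.items():
                if not 0.0 <= v <= 1.0:
                    raise ConfigError(f"{m.name}: baseline[{ctx}]={v} outside [0, 1]")
        bad = set(self.planted_failures) - set(PLANTED_CATEGORIES)
        if bad:
            raise ConfigError(f"unknown planted failure categories: {sorted(bad)}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "rna" in d and isinstance(d["rna"], Mapping):
            d["rna"] = RnaModel(**d["rna"])
        if "region_models" in d:
            d["region_models"] = [
                m if isinstance(m, RegionModel) else RegionModel(**m)
                for m in d["region_models"]
            ]
        for key in ("cluster_order", "clusters", "genotypes"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """Everything the generator knows that downstream modules must recover."""

    nuclei: pd.DataFrame      # nucleus_id, cluster, genotype, is_doublet, ...
    regions: pd.DataFrame     # region_set, id, chrom, start, end, rescued
    expected: pd.DataFrame    # region_set, context, cluster, genotype, true_meth


@dataclass
class SimResult:
    config: SimConfig
    meth: dict                 # nucleus_id -> MethCallTable
    counts: CountMatrix
    regions: dict              # region set name -> RegionSet
    markers: dict              # cluster -> list of marker gene ids
    sample_sheet: pd.DataFrame
    chrom_sizes: dict
    truth: GroundTruth


# ---------------------------------------------------------------------------
# internal world: sites, regions, expression programs
# ---------------------------------------------------------------------------

def _nucleus_rng(seed: int, nucleus_id: str, stream: int) -> np.random.Generator:
    key = zlib.crc32(nucleus_id.encode())
    return np.random.default_rng(np.random.SeedSequence([seed, key, stream]))


class _World:
    """Deterministic genome layout shared by every nucleus of a run."""

    def __init__(self, config: SimConfig):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0FFEE]))
        self.chrom_sizes = {f"Chr{i + 1}": config.chrom_len for i in range(config.n_chrom)}
        self.chrom_sizes[config.chloro_chrom] = config.chloro_len
        self.nuclear_chroms = [c for c in self.chrom_sizes if c != config.chloro_chrom]

        self._place_regions(rng)
        self._build_sites(rng)
        self._site_membership()
        self._build_expression(rng)
        self._p_cache: dict[tuple[str, str], np.ndarray] = {}

    # -- regions ----------------------------------------------------------
    def _place_regions(self, rng: np.random.Generator) -> None:
        occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in self.nuclear_chroms}
        region_rows = []
        self.region_sets: dict[str, RegionSet] = {}
        self.rescued: dict[str, np.ndarray] = {}
        for model in self.config.region_models:
            rows = []
            for i in range(model.n):
                chrom = self.nuclear_chroms[i % len(self.nuclear_chroms)]
                size = self.chrom_sizes[chrom]
                if model.placement == "pericentromere":
                    lo, hi = int(size * 0.35), int(size * 0.65) - model.length
                else:
                    lo, hi = 0, size - model.length
                if hi <= lo:
                    raise ConfigError(f"{model.name}: chromosome too short for placement")
                for _ in range(2000):
                    start = int(rng.integers(lo, hi))
                    end = start + model.length
                    if all(end <= s or start >= e for s, e in occupied[chrom]):
                        occupied[chrom].append((start, end))
                        break
                else:
                    raise ConfigError(f"{model.name}: could not place interval {i} "
                                      "(region packing infeasible)")
                rows.append((chrom, start, end, f"{model.name}_{i:03d}", "."))
            df = pd.DataFrame(rows, columns=["chrom", "start", "end", "id", "strand"])
            rs = RegionSet(model.name, df)
            self.region_sets[model.name] = rs
            n_rescued = int(round(model.rescue_fraction * model.n))
            rescued_ids = set(rng.choice(
                [f"{model.name}_{i:03d}" for i in range(model.n)],
                size=n_rescued, replace=False)) if n_rescued else set()
            flags = rs.df["id"].isin(rescued_ids).to_numpy()
            self.rescued[model.name] = flags
            for (_, r), resc in zip(rs.df.iterrows(), flags):
                region_rows.append((model.name, r["id"], r["chrom"], r["start"],
                                    r["end"], bool(resc)))
        self.region_truth = pd.DataFrame(
            region_rows,
            columns=["region_set", "id", "chrom", "start", "end", "rescued"])

    # -- sites ------------------------------------------------------------
    def _build_sites(self, rng: np.random.Generator) -> None:
        cfg = self.config
        frames = []
        for chrom, size in self.chrom_sizes.items():
            parts = []
            n_per_ctx = int(cfg.site_density * size / 1000)
            for ctx in CONTEXTS:
                pos = rng.choice(size, size=n_per_ctx, replace=False)
                parts.append(pd.DataFrame({"pos": pos, "context": ctx}))
            if chrom != cfg.chloro_chrom:
                for model in cfg.region_models:
                    sub = self.region_sets[model.name].df
                    sub = sub[sub["chrom"] == chrom]
                    for _, reg in sub.iterrows():
                        length = reg["end"] - reg["start"]
                        for ctx in CONTEXTS:
                            n = int(model.site_density.get(ctx, 0.0) * length / 1000)
                            if n == 0:
                                continue
                            pos = reg["start"] + rng.choice(length, size=n, replace=False)
                            parts.append(pd.DataFrame({"pos": pos, "context": ctx}))
            df = pd.concat(parts, ignore_index=True)
            df = df[~df["pos"].duplicated(keep="last")]
            df = df.sort_values("pos", kind="mergesort").reset_index(drop=True)
            df["strand"] = np.where(rng.random(len(df)) < 0.5, "+", "-")
            df.insert(0, "chrom", chrom)
            frames.append(df)
        sites = pd.concat(frames, ignore_index=True)
        self.sites = sites[["chrom", "pos", "strand", "context"]]
        self.n_sites = len(sites)
        self.is_chloro = (sites["chrom"] == cfg.chloro_chrom).to_numpy()
        self.ctx_code = sites["context"].map({c: i for i, c in enumerate(CONTEXTS)}).to_numpy()

    def _site_membership(self) -> None:
        """For every region set: per-site region index (-1 outside)."""
        self.membership: dict[str, np.ndarray] = {}
        pos = self.sites["pos"].to_numpy()
        chroms = self.sites["chrom"].to_numpy()
        for name, rs in self.region_sets.items():
            member = np.full(self.n_sites, -1, dtype=np.int64)
            for chrom, sub in rs.df.groupby("chrom"):
                sel = chroms == chrom
                if not sel.any():
                    continue
                starts = sub["start"].to_numpy()
                ends = sub["end"].to_numpy()
                idx = np.searchsorted(starts, pos[sel], side="right") - 1
                ok = (idx >= 0) & (pos[sel] < ends[np.clip(idx, 0, len(ends) - 1)])
                out = np.where(ok, sub.index.to_numpy()[np.clip(idx, 0, len(ends) - 1)], -1)
                member[sel] = out
            self.membership[name] = member

    # -- methylation ------------------------------------------------------
    def true_p(self, cluster: str, genotype: str) -> np.ndarray:
        key = (cluster, genotype)
        if key in self._p_cache:
            return self._p_cache[key]
        cfg = self.config
        bg = np.array([cfg.background_meth[c] for c in CONTEXTS])
        p = bg[self.ctx_code].astype(float)
        p[self.is_chloro] = 0.0  # chloroplast truly unmethylated
        for model in cfg.region_models:
            member = self.membership[model.name]
            inside = member >= 0
            if not inside.any():
                continue
            rescued_flags = self.rescued[model.name]
            for ci, ctx in enumerate(CONTEXTS):
                sel = inside & (self.ctx_code == ci)
                if not sel.any():
                    continue
                val = model.baseline.get(ctx, cfg.background_meth[ctx])
                val = val + model.cluster_deltas.get(ctx, {}).get(cluster, 0.0)
                gdelta = 0.0
                if cluster in model.genotype_delta_clusters:
                    gdelta = model.genotype_deltas.get(ctx, {}).get(genotype, 0.0)
                pv = np.full(sel.sum(), val + gdelta)
                if gdelta and genotype in model.rescued_genotypes:
                    resc_site = rescued_flags[member[sel]]
                    pv[resc_site] = val
                p[sel] = pv
        p = np.clip(p, 0.0, 1.0)
        self._p_cache[key] = p
        return p

    def expected_region_meth(self, clusters: Sequence[str],
                             genotypes: Sequence[str]) -> pd.DataFrame:
        rows = []
        for model in self.config.region_models:
            member = self.membership[model.name]
            inside = member >= 0
            for cluster in clusters:
                for genotype in genotypes:
                    p = self.true_p(cluster, genotype)
                    for ci, ctx in enumerate(CONTEXTS):
                        sel = inside & (self.ctx_code == ci)
                        if sel.any():
                            rows.append((model.name, ctx, cluster, genotype,
                                         float(p[sel].mean())))
        return pd.DataFrame(rows, columns=["region_set", "context", "cluster",
                                           "genotype", "true_meth"])

    # -- expression -------------------------------------------------------
    def _build_expression(self, rng: np.random.Generator) -> None:
        cfg = self.config
        rna = cfg.rna
        order = list(cfg.cluster_order)
        n_marker_genes = rna.markers_per_cluster * len(order)
        if rna.n_genes < n_marker_genes + rna.n_organelle + 10:
            raise ConfigError("rna.n_genes too small for the marker panels")
        genes = [f"G{i:04d}" for i in range(rna.n_genes - rna.n_organelle)]
        organelle = [f"ORG{i:02d}" for i in range(rna.n_organelle)]
        self.genes = genes + organelle
        self.organelle_genes = frozenset(organelle)
        self.n_genes = len(self.genes)

        fold = np.ones((self.n_genes, len(order)))
        cidx = {c: i for i, c in enumerate(order)}
        panels: dict[str, list[str]] = {}
        cursor = 0

        def take(n: int) -> list[int]:
            nonlocal cursor
            out = list(range(cursor, cursor + n))
            cursor += n
            return out

        k = rna.markers_per_cluster
        n_shared = max(1, k - 2)  # stage-shared portion of mature/germline panels
        n_spec = k - n_shared
        chain = [c for c in order if c not in ("GN", "SN", "VN4", "VN5")]
        # simple trajectory clusters: own panel at full fold, graded in neighbours
        for c in chain:
            gi = take(k)
            panels[c] = [genes[i] for i in gi]
            fold[gi, cidx[c]] = rna.marker_fold
            j = order.index(c)
            for nb in (j - 1, j + 1):
                if 0 <= nb < len(order) and order[nb] in chain:
                    fold[gi, nb] = rna.adjacent_fold
        # mature VN: a shared core expressed in VN4 and VN5, plus stage-specific
        core = take(n_shared)
        s4 = take(n_spec)
        s5 = take(n_spec)
        panels["VN4"] = [genes[i] for i in core + s4]
        panels["VN5"] = [genes[i] for i in core + s5]
        for gi in core:
            fold[gi, cidx["VN4"]] = fold[gi, cidx["VN5"]] = rna.marker_fold
        for gi in s4:
            fold[gi, cidx["VN4"]] = rna.marker_fold
            fold[gi, cidx["VN5"]] = rna.adjacent_fold
        for gi in s5:
            fold[gi, cidx["VN5"]] = rna.marker_fold
            fold[gi, cidx["VN4"]] = rna.adjacent_fold
        # germline branch: SN core plus germline genes shared with GN
        sn_core = take(n_shared)
        germ = take(n_spec)
        gn_spec = take(n_shared)
        panels["SN"] = [genes[i] for i in sn_core + germ]
        panels["GN"] = [genes[i] for i in gn_spec + germ]
        for gi in sn_core:
            fold[gi, cidx["SN"]] = rna.marker_fold
        for gi in germ:
            fold[gi, cidx["GN"]] = rna.marker_fold
            fold[gi, cidx["SN"]] = rna.adjacent_fold
        for gi in gn_spec:
            fold[gi, cidx["GN"]] = rna.marker_fold

        self.fold = fold
        self.panels = panels
        self.cluster_index = cidx
        base_mu = np.full(self.n_genes, rna.baseline_mean)
        base_mu[len(genes):] = 0.0  # organelle genes handled separately
        self.base_mu = base_mu
        self.organelle_slice = slice(len(genes), self.n_genes)


# ---------------------------------------------------------------------------
# per-nucleus sampling
# ---------------------------------------------------------------------------

def _sample_methylome(world: _World, cluster: str, genotype: str,
                      rng: np.random.Generator, capture_scale: float,
                      conv_level: float, ploidy: int = 1
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Return (cov, mc) over all world sites for one complete nucleus."""
    cfg = world.config
    p_cap = np.where(world.is_chloro, cfg.chloro_capture_prob,
                     cfg.capture_prob) * capture_scale
    p = world.true_p(cluster, genotype)
    if conv_level > 0:
        p = p + (1.0 - p) * conv_level
    cov = np.zeros(world.n_sites, dtype=np.int64)
    mc = np.zeros(world.n_sites, dtype=np.int64)
    for _ in range(ploidy):
        cap = rng.random(world.n_sites) < p_cap
        cov += cap
        idx = np.flatnonzero(cap)
        mc[idx] += rng.random(idx.size) < p[idx]
    return cov, mc


def _meth_table(world: _World, nucleus_id: str, cov: np.ndarray,
                mc: np.ndarray) -> MethCallTable:
    keep = cov > 0
    df = world.sites.loc[keep, ["chrom", "pos", "strand", "context"]].copy()
    df["mc"] = mc[keep]
    df["cov"] = cov[keep]
    return MethCallTable(nucleus_id, df.reset_index(drop=True))


def _sample_counts(world: _World, cluster: str, rng: np.random.Generator,
                   planted: str | None) -> np.ndarray:
    cfg = world.config
    rna = cfg.rna
    mu = world.base_mu * world.fold[:, world.cluster_index[cluster]]
    if planted == "few_genes":
        nuclear = np.flatnonzero(mu > 0)
        keep = rng.choice(nuclear, size=min(150, nuclear.size), replace=False)
        total = mu.sum()
        mask = np.zeros_like(mu)
        mask[keep] = 1.0
        mu = mu * mask
        mu *= total / mu.sum()
    if planted == "low_rna":
        mu = mu * 0.05
    mu = mu * rng.lognormal(0.0, rna.libsize_sigma)
    if planted == "high_organelle":
        frac = 0.25
    else:
        a = rna.organelle_fraction_shape
        m = rna.organelle_fraction_mean
        frac = rng.beta(a, a * (1.0 - m) / m) if m > 0 else 0.0
    mu = mu.copy()
    if rna.n_organelle:
        mu[world.organelle_slice] = frac / (1.0 - frac) * mu.sum() / rna.n_organelle
    size = rna.dispersion
    pnb = size / (size + mu)
    return rng.negative_binomial(size, pnb).astype(np.int64)


# ---------------------------------------------------------------------------
# main entry points
# ---------------------------------------------------------------------------

def _doublet_partners(config: SimConfig, j: int,
                      rng: np.random.Generator) -> tuple[str, str]:
    clusters = config.clusters
    if (config.doublet_pairing == "vn_sn" and "SN" in clusters
            and any(c in clusters for c in MATURE_VN)):
        mature = [c for c in MATURE_VN if c in clusters]
        return mature[j % len(mature)], "SN"
    a, b = rng.choice(len(clusters), size=2, replace=True)
    return clusters[int(a)], clusters[int(b)]


def simulate_dataset(config: SimConfig) -> SimResult:
    """Generate a full joint methylome + transcriptome dataset.

    Singleton nuclei are haploid (cov in {0, 1} at every site); doublets are
    unions of two independently sampled complete nuclei, so sites captured
    by both partners have cov = 2.
    """
    config.validate()
    world = _World(config)
    seed = config.seed

    # roster of singleton nuclei
    roster: list[dict] = []
    for genotype in config.genotypes:
        for cluster in config.clusters:
            for i in range(config.n_nuclei_per_cluster_per_genotype):
                roster.append({
                    "nucleus_id": f"{genotype}_{cluster}_{i:03d}",
                    "cluster": cluster, "genotype": genotype,
                    "is_doublet": False, "partner_clusters": "",
                    "planted": "ok", "conversion_ok": True,
                })
    # planted QC failures on the leading singletons, in category order
    cursor = 0
    for cat in PLANTED_CATEGORIES:
        for _ in range(int(config.planted_failures.get(cat, 0))):
            if cursor >= len(roster):
                raise ConfigError("more planted failures than singleton nuclei")
            roster[cursor]["planted"] = cat
            if cat == "conversion":
                roster[cursor]["conversion_ok"] = False
            cursor += 1
    # random conversion failures on the remainder
    if config.conversion_failure_rate > 0:
        conv_rng = np.random.default_rng(np.random.SeedSequence([seed, 0xBEEF]))
        for row in roster[cursor:]:
            if conv_rng.random() < config.conversion_failure_rate:
                row["planted"] = "conversion"
                row["conversion_ok"] = False

    # doublets are additional wells
    n_doublets = int(round(config.doublet_rate * len(roster)))
    pair_rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD0B]))
    for j in range(n_doublets):
        genotype = config.genotypes[j % len(config.genotypes)]
        ca, cb = _doublet_partners(config, j, pair_rng)
        roster.append({
            "nucleus_id": f"{genotype}_DBL_{j:03d}",
            "cluster": "doublet", "genotype": genotype,
            "is_doublet": True, "partner_clusters": f"{ca}+{cb}",
            "planted": "doublet", "conversion_ok": True,
        })

    meth: dict[str, MethCallTable] = {}
    count_cols: dict[str, np.ndarray] = {}
    for row in roster:
        nid = row["nucleus_id"]
        meth_rng = _nucleus_rng(seed, nid, 0)
        rna_rng = _nucleus_rng(seed, nid, 1)
        if row["is_doublet"]:
            ca, cb = row["partner_clusters"].split("+")
            cov_a, mc_a = _sample_methylome(world, ca, row["genotype"],
                                            _nucleus_rng(seed, nid + ":a", 0),
                                            1.0, 0.0)
            cov_b, mc_b = _sample_methylome(world, cb, row["genotype"],
                                            _nucleus_rng(seed, nid + ":b", 0),
                                            1.0, 0.0)
            cov, mc = cov_a + cov_b, mc_a + mc_b
            counts = (_sample_counts(world, ca, _nucleus_rng(seed, nid + ":a", 1), None)
                      + _sample_counts(world, cb, _nucleus_rng(seed, nid + ":b", 1), None))
        else:
            capture_scale = 0.002 if row["planted"] == "low_wgbs" else 1.0
            conv = config.conversion_failure_level if row["planted"] == "conversion" else 0.0
            ploidy = 2 if (config.gn_diploid and row["cluster"] == "GN") else 1
            cov, mc = _sample_methylome(world, row["cluster"], row["genotype"],
                                        meth_rng, capture_scale, conv, ploidy)
            counts = _sample_counts(world, row["cluster"], rna_rng, row["planted"])
        meth[nid] = _meth_table(world, nid, cov, mc)
        count_cols[nid] = counts

    counts_df = pd.DataFrame(count_cols, index=world.genes)
    cm = CountMatrix(counts_df, world.organelle_genes)

    sheet = pd.DataFrame({
        "nucleus_id": [r["nucleus_id"] for r in roster],
        "genotype": [r["genotype"] for r in roster],
        "experiment": "expt1",
        "plate": [f"P{i // 384 + 1}" for i in range(len(roster))],
        "well": [f"{chr(65 + (i % 384) // 24)}{(i % 384) % 24 + 1}" for i in range(len(roster))],
    }).set_index("nucleus_id")

    truth = GroundTruth(
        nuclei=pd.DataFrame(roster),
        regions=world.region_truth,
        expected=world.expected_region_meth(config.clusters, config.genotypes),
    )
    return SimResult(config=config, meth=meth, counts=cm,
                     regions=dict(world.region_sets), markers=dict(world.panels),
                     sample_sheet=sheet, chrom_sizes=dict(world.chrom_sizes),
                     truth=truth)


# ---------------------------------------------------------------------------
# fixture presets
# ---------------------------------------------------------------------------

def preset_config(name: str, seed: int = 0) -> SimConfig:
    """Named study-condition presets used throughout the test-suite."""
    if name == "tiny":
        return SimConfig(
            seed=seed, n_chrom=1, chrom_len=120_000, chloro_len=30_000,
            clusters=("MN", "VN2", "SN"), genotypes=("WT", "mutA"),
            n_nuclei_per_cluster_per_genotype=6, doublet_rate=0.1,
            site_density=2.0,
            region_models=[RegionModel(name="cg_hypo_dmr", n=10, length=800,
                                       baseline={"CG": 0.85, "CHG": 0.35, "CHH": 0.08},
                                       cluster_deltas={"CG": {"VN2": -0.5}})],
        )
    if name == "qc_stress":
        return SimConfig(
            seed=seed, n_chrom=2, chrom_len=200_000, chloro_len=40_000,
            clusters=("MN", "VN2", "VN4", "SN"), genotypes=("WT",),
            n_nuclei_per_cluster_per_genotype=30, capture_prob=0.3,
            doublet_rate=0.05,
            planted_failures={"low_rna": 5, "few_genes": 5, "low_wgbs": 5,
                              "high_organelle": 5, "conversion": 6},
        )
    if name == "trajectory":
        return SimConfig(
            seed=seed, n_chrom=2, chrom_len=200_000, chloro_len=40_000,
            genotypes=("WT",), n_nuclei_per_cluster_per_genotype=100,
            capture_prob=0.03, doublet_rate=0.03,
        )
    if name == "rescue":
        models = default_region_models()
        for m in models:
            if m.name == "cg_hypo_dmr":
                m.genotype_deltas = {"CG": {"mutA": -0.25, "mutAB": -0.25}}
                m.rescue_fraction = 0.5
        return SimConfig(
            seed=seed, n_chrom=2, chrom_len=300_000, chloro_len=40_000,
            clusters=("MN", "MNtoVN", "VN1", "VN2", "VN4", "SN"),
            genotypes=("WT", "mutA", "mutAB"),
            n_nuclei_per_cluster_per_genotype=100,
            region_models=models,
        )
    raise ConfigError(f"unknown preset {name!r}")


def write_fixture(result: SimResult, out_dir: str | Path) -> Path:
    """Write a self-describing fixture directory (formats from io_formats)."""
    out = Path(out_dir)
    (out / "meth").mkdir(parents=True, exist_ok=True)
    (out / "regions").mkdir(exist_ok=True)
    for nid, table in result.meth.items():
        write_meth_calls(table, out / "meth" / f"{nid}.tsv")
    write_counts(result.counts, out / "counts.tsv")
    with open(out / "organelle_genes.txt", "w") as fh:
        for g in sorted(result.counts.organelle_genes):
            fh.write(g + "\n")
    for name, rs in result.regions.items():
        write_bed(rs, out / "regions" / f"{name}.bed")
    write_sample_sheet(result.sample_sheet, out / "sample_sheet.tsv")
    write_chrom_sizes(result.chrom_sizes, out / "chrom.sizes")
    with open(out / "markers.yaml", "w") as fh:
        yaml.safe_dump({k: list(v) for k, v in result.markers.items()}, fh)
    result.truth.nuclei.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    result.truth.regions.to_csv(out / "regions_truth.tsv", sep="\t", index=False)
    result.truth.expected.to_csv(out / "expected_methylation.tsv", sep="\t", index=False)
    with open(out / "config.resolved.yaml", "w") as fh:
        yaml.safe_dump(result.config.to_dict(), fh, sort_keys=False)
    return out


def make_fixture(name: str, out_dir: str | Path, seed: int = 0) -> Path:
    """Generate a preset fixture on disk; returns the directory written."""
    result = simulate_dataset(preset_config(name, seed=seed))
    return write_fixture(result, out_dir)


def simulate_rescue_tpm(n_transcripts: int = 200,
                        proportions: Mapping[str, float] | None = None,
                        fold: float = 4.0, n_reps: int = 6,
                        noise_sigma: float = 0.15, seed: int = 0
                        ) -> tuple[pd.DataFrame, dict, pd.Series]:
    """Synthetic TPM cohort for the rescue classifier.

    Transcripts upregulated ``fold``-times in ``mutA`` are planted in four
    classes: rescued (double mutant back at WT), partially_rescued
    (half the log fold-change retained), not_rescued (unchanged from
    ``mutA``) and other (non-monotone: double mutant overshoots below WT).
    Returns (TPM matrix, sample -> genotype map, true labels). Default
    proportions mirror a 50/17/26/7 percent split.
    """
    props = dict(proportions or {"rescued": 0.50, "partially_rescued": 0.17,
                                 "not_rescued": 0.26, "other": 0.07})
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7E5C]))
    counts = {k: int(round(v * n_transcripts)) for k, v in props.items()}
    counts["rescued"] += n_transcripts - sum(counts.values())  # rounding drift
    labels = []
    for k in ("rescued", "partially_rescued", "not_rescued", "other"):
        labels += [k] * counts[k]
    base = rng.lognormal(np.log(20.0), 0.5, size=n_transcripts)
    lab = np.array(labels)
    mutab = base.copy()
    mutab[lab == "partially_rescued"] = base[lab == "partially_rescued"] * fold ** 0.5
    mutab[lab == "not_rescued"] = base[lab == "not_rescued"] * fold
    mutab[lab == "other"] = base[lab == "other"] * fold ** 0.5
    # "other" transcripts do not fall cleanly into the rescue pattern:
    # they are also misregulated in the single mutant mutB
    mutb = base.copy()
    mutb[lab == "other"] = base[lab == "other"] * fold
    level = {"WT": base, "mutA": base * fold, "mutAB": mutab, "mutB": mutb}
    cols = {}
    genotype_of = {}
    for geno in ("WT", "mutA", "mutAB", "mutB"):
        for r in range(n_reps):
            s = f"{geno}_r{r + 1}"
            cols[s] = level[geno] * rng.lognormal(0.0, noise_sigma, size=n_transcripts)
            genotype_of[s] = geno
    tpm = pd.DataFrame(cols, index=[f"T{i:04d}" for i in range(n_transcripts)])
    truth = pd.Series(labels, index=tpm.index, name="true_label")
    return tpm, genotype_of, truth


def planted_conversion_table(nucleus_id: str, n_sites: int, n_methylated: int,
                             chrom: str = "ChrC") -> MethCallTable:
    """Deterministic chloroplast call table with an exact methylated count.

    Synthetic planting helper for conversion-QC checks: ``n_methylated`` of
    ``n_sites`` single-read chloroplast calls read as methylated, i.e. an
    apparent conversion rate of exactly 1 - n_methylated/n_sites.
    """
    if n_methylated > n_sites:
        raise ConfigError("n_methylated > n_sites")
    df = pd.DataFrame({
        "chrom": chrom,
        "pos": np.arange(n_sites, dtype=np.int64) * 3,
        "strand": "+",
        "context": "CG",
        "mc": (np.arange(n_sites) < n_methylated).astype(np.int64),
        "cov": 1,
    })
    return MethCallTable(nucleus_id, df)
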