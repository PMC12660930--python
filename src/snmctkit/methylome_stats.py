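"""Methylation statistics: region averages, pseudobulk pooling, profiles,
mC-density bins, and the Cohen's d effect-size grid.

Conventions
-----------
* Per-nucleus region methylation is the weighted mean
  sum(mc) / sum(cov) over covered in-region cytosines of the requested
  context (a nucleus with no covered in-region site is missing, not 0).
* Pseudobulk tracks are element-wise sums of member nuclei's (mc, cov), so
  the pooled fraction equals the coverage-weighted mean of per-nucleus
  fractions exactly.
* Bulk-style analyses (mC density) default to a >= 5 read per-cytosine
  filter; single-nucleus statistics use min_cov = 1 since haploid nuclei
  rarely exceed 1x.
* Effect sizes are pooled-SD Cohen's d with a star code:
  n.e. |d| < 0.2, * >= 0.2, ** >= 0.5, *** >= 0.9, **** >= 1.5
  (half-open intervals closed on the left); p-values are Welch two-sided
  t-tests.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import MethCallTable, RegionSet, ValidationError

STAR_THRESHOLDS = ((1.5, "****"), (0.9, "***"), (0.5, "**"), (0.2, "*"))


# ---------------------------------------------------------------------------
# region membership helper
# ---------------------------------------------------------------------------

def _in_region_mask(df: pd.DataFrame, regions: RegionSet) -> np.ndarray:
    mask = np.zeros(len(df), dtype=bool)
    pos = df["pos"].to_numpy()
    chroms = df["chrom"].to_numpy()
    for chrom, sub in regions.df.groupby("chrom"):
        sel = chroms == chrom
        if not sel.any():
            continue
        starts = sub["start"].to_numpy()
        # running max of ends handles abutting/nested intervals correctly
        ends = np.maximum.accumulate(sub["end"].to_numpy())
        idx = np.searchsorted(starts, pos[sel], side="right") - 1
        ok = idx >= 0
        idx_c = np.clip(idx, 0, len(ends) - 1)
        ok &= pos[sel] < ends[idx_c]
        mask[sel] = ok
    return mask


def region_mean_per_nucleus(meth: MethCallTable, regions: RegionSet,
                            context: str, min_cov: int = 1,
                            min_sites: int = 1) -> float:
    """Weighted mean methylation sum(mc)/sum(cov) over in-region sites.

    NaN when fewer than ``min_sites`` covered in-region sites of the
    context qualify.
    """
    if context not in ("CG", "CHG", "CHH"):
        raise ValueError(f"unknown context {context!r}")
    df = meth.df
    df = df[(df["context"] == context) & (df["cov"] >= min_cov)]
    if not len(df):
        return float("nan")
    df = df[_in_region_mask(df, regions)]
    if len(df) < min_sites or df["cov"].sum() == 0:
        return float("nan")
    return float(df["mc"].sum() / df["cov"].sum())


def region_means_table(meth_tables: Mapping[str, MethCallTable],
                       region_sets: Mapping[str, RegionSet],
                       contexts: Sequence[str] = ("CG", "CHG", "CHH"),
                       min_cov: int = 1, min_sites: int = 1) -> pd.DataFrame:
    """Tidy per-nucleus region means: one row per
    (nucleus, region_set, context), NaN mean when uncovered."""
    rows = []
    for nid, table in meth_tables.items():
        for name, rs in region_sets.items():
            df = table.df[table.df["cov"] >= min_cov]
            inside = df[_in_region_mask(df, rs)]
            for ctx in contexts:
                sub = inside[inside["context"] == ctx]
                cov = int(sub["cov"].sum())
                mean = (float(sub["mc"].sum() / cov)
                        if len(sub) >= min_sites and cov > 0 else float("nan"))
                rows.append((nid, name, ctx, mean, len(sub)))
    return pd.DataFrame(rows, columns=["nucleus_id", "region_set", "context",
                                       "mean_methylation", "n_sites"])


# ---------------------------------------------------------------------------
# pseudobulk pooling
# ---------------------------------------------------------------------------

def pool_cluster(meth_tables: Mapping[str, MethCallTable],
                 labels: Mapping[str, str],
                 genotypes: Mapping[str, str] | None = None,
                 include: Iterable[str] | None = None
                 ) -> dict[tuple[str, str], pd.DataFrame]:
    """Pool per-site methylation across the nuclei of each (cluster, genotype).

    ``labels`` maps nucleus id -> final cluster label (post QC and
    censoring); ``include`` restricts to the given nuclei (e.g. QC
    survivors). Returns (cluster, genotype) -> per-site frame with summed
    mc/cov; genotype is "all" when no genotype map is given.
    """
    keep = set(include) if include is not None else set(meth_tables)
    groups: dict[tuple[str, str], list[pd.DataFrame]] = {}
    for nid, table in meth_tables.items():
        if nid not in keep or nid not in labels:
            continue
        geno = genotypes.get(nid, "all") if genotypes else "all"
        groups.setdefault((labels[nid], geno), []).append(table.df)
    out = {}
    for key, frames in sorted(groups.items()):
        df = pd.concat(frames, ignore_index=True)
        pooled = (df.groupby(["chrom", "pos", "strand", "context"], sort=True)
                  [["mc", "cov"]].sum().reset_index())
        out[key] = pooled.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    if not out:
        warnings.warn("pool_cluster: no nuclei pooled (empty cluster?)")
    return out


def pooled_fraction(track: pd.DataFrame, regions: RegionSet | None = None,
                    context: str | None = None, min_cov: int = 1) -> float:
    """sum(mc)/sum(cov) of a pooled track, optionally restricted."""
    df = track
    if context is not None:
        df = df[df["context"] == context]
    df = df[df["cov"] >= min_cov]
    if regions is not None:
        df = df[_in_region_mask(df, regions)]
    cov = df["cov"].sum()
    return float(df["mc"].sum() / cov) if cov else float("nan")


# ---------------------------------------------------------------------------
# TSS windows, profiles, density bins
# ---------------------------------------------------------------------------

def tss_window_regions(tss: RegionSet, chrom_sizes: Mapping[str, int],
                       flank: int = 400) -> RegionSet:
    """+/- flank windows around stranded TSS anchors, clipped to bounds.

    The anchor is the interval start on '+' and end-1 on '-'.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    rows = []
    for _, r in tss.df.iterrows():
        if r["strand"] not in ("+", "-"):
            raise ValidationError(f"TSS {r['id']} lacks strand")
        size = chrom_sizes[r["chrom"]]
        anchor = int(r["start"]) if r["strand"] == "+" else int(r["end"]) - 1
        if not 0 <= anchor < size:
            raise ValidationError(f"TSS anchor {anchor} outside {r['chrom']}")
        rows.append((r["chrom"], max(0, anchor - flank),
                     min(size, anchor + flank), r["id"], r["strand"]))
    return RegionSet(f"{tss.name}_tss{flank}",
                     pd.DataFrame(rows, columns=["chrom", "start", "end", "id", "strand"]))


def profile_matrix(track: pd.DataFrame, regions: RegionSet,
                   mode: str = "reference_point", flank: int = 1000,
                   n_bins: int = 50, context: str | None = None,
                   min_cov: int = 1) -> pd.DataFrame:
    """Strand-aware average methylation profile over a region set.

    reference_point: bins tile [-flank, flank) around each region's anchor
    (start on '+', end-1 on '-'); scale_regions: each region body is mapped
    linearly onto ``n_bins``. Values are weighted means sum(mc)/sum(cov)
    over all region-aligned sites per bin; empty bins are NaN.
    """
    df = track[track["cov"] >= min_cov]
    if context is not None:
        df = df[df["context"] == context]
    mc = np.zeros(n_bins)
    cov = np.zeros(n_bins)
    for _, r in regions.df.iterrows():
        sub = df[df["chrom"] == r["chrom"]]
        strand = r["strand"] if r["strand"] in ("+", "-") else "+"
        if mode == "reference_point":
            anchor = int(r["start"]) if strand == "+" else int(r["end"]) - 1
            rel = sub["pos"].to_numpy() - anchor
            if strand == "-":
                rel = -rel
            sel = (rel >= -flank) & (rel < flank)
            b = ((rel[sel] + flank) * n_bins // (2 * flank)).astype(int)
        elif mode == "scale_regions":
            length = int(r["end"]) - int(r["start"])
            if length < 1:
                raise ValueError(f"region {r['id']} shorter than 1 bp")
            pos = sub["pos"].to_numpy()
            sel = (pos >= r["start"]) & (pos < r["end"])
            frac = (pos[sel] - r["start"]) / length
            if strand == "-":
                frac = 1.0 - frac - 1.0 / length  # orient 5'->3'
            b = np.clip((frac * n_bins).astype(int), 0, n_bins - 1)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        np.add.at(mc, b, sub["mc"].to_numpy()[sel])
        np.add.at(cov, b, sub["cov"].to_numpy()[sel])
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(cov > 0, mc / np.where(cov > 0, cov, 1), np.nan)
    if mode == "reference_point":
        centers = -flank + (np.arange(n_bins) + 0.5) * (2 * flank / n_bins)
    else:
        centers = (np.arange(n_bins) + 0.5) / n_bins
    return pd.DataFrame({"bin_center": centers, "methylation": vals,
                         "coverage": cov})


def mc_density_bins(track: pd.DataFrame, bin_size: int = 400,
                    mode: str = "tiled", centers: RegionSet | None = None,
                    min_cov: int = 5,
                    contexts: Sequence[str] = ("CG", "CHG", "CHH"),
                    chrom_sizes: Mapping[str, int] | None = None
                    ) -> pd.DataFrame:
    """mC density per fixed-width bin: the sum over qualifying cytosines of
    100 * mc/cov (summed percent methylation), per context.

    mode "tiled": non-overlapping genome bins of ``bin_size``; mode
    "peak_centered": one window of width ``bin_size`` centered on the
    midpoint of each interval of ``centers`` ([m - w/2, m + w/2)).
    Empty bins report 0 (tiled mode lists them when ``chrom_sizes`` is
    given, otherwise only covered bins appear).
    """
    df = track[track["cov"] >= min_cov].copy()
    df = df[df["context"].isin(contexts)]
    df["pct"] = 100.0 * df["mc"] / df["cov"]
    if mode == "tiled":
        df["bin_start"] = (df["pos"] // bin_size) * bin_size
        agg = (df.pivot_table(index=["chrom", "bin_start"], columns="context",
                              values="pct", aggfunc="sum", fill_value=0.0)
               .reindex(columns=list(contexts), fill_value=0.0))
        if chrom_sizes is not None:
            full = pd.MultiIndex.from_tuples(
                [(c, b) for c, size in chrom_sizes.items()
                 for b in range(0, size, bin_size)],
                names=["chrom", "bin_start"])
            agg = agg.reindex(full, fill_value=0.0)
        agg = agg.reset_index()
        agg.columns.name = None
        return agg
    if mode == "peak_centered":
        if centers is None:
            raise ValueError("peak_centered mode requires centers")
        half = bin_size // 2
        rows = []
        for _, r in centers.df.iterrows():
            m = (int(r["start"]) + int(r["end"])) // 2
            sub = df[(df["chrom"] == r["chrom"]) & (df["pos"] >= m - half)
                     & (df["pos"] < m + half)]
            vals = {ctx: float(sub.loc[sub["context"] == ctx, "pct"].sum())
                    for ctx in contexts}
            rows.append({"id": r["id"], "chrom": r["chrom"],
                         "window_start": m - half, "window_end": m + half, **vals})
        return pd.DataFrame(rows)
    raise ValueError(f"unknown mode {mode!r}")


def smooth_chromosome_profile(track: pd.DataFrame, chrom: str, context: str,
                              chrom_size: int, window: int = 100_000,
                              step: int = 10_000, min_cov: int = 1) -> pd.DataFrame:
    """Rolling weighted-mean methylation along one chromosome."""
    df = track[(track["chrom"] == chrom) & (track["context"] == context)
               & (track["cov"] >= min_cov)]
    pos = df["pos"].to_numpy()
    rows = []
    for start in range(0, max(1, chrom_size - window + step), step):
        sel = (pos >= start) & (pos < start + window)
        cov = df["cov"].to_numpy()[sel].sum()
        val = df["mc"].to_numpy()[sel].sum() / cov if cov else np.nan
        rows.append((start + window // 2, val, cov))
    return pd.DataFrame(rows, columns=["center", "methylation", "coverage"])


# ---------------------------------------------------------------------------
# effect sizes
# ---------------------------------------------------------------------------

def cohens_d(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Pooled-SD Cohen's d, (mean_a - mean_b) / s_p, NaNs dropped.

    s_p = 0 with equal means gives 0; s_p = 0 with different means returns
    a signed infinity sentinel.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("cohens_d requires >= 2 values per group")
    diff = a.mean() - b.mean()
    sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) \
        / (len(a) + len(b) - 2)
    if sp2 == 0:
        return 0.0 if diff == 0 else float(np.sign(diff)) * float("inf")
    return float(diff / np.sqrt(sp2))


def star_category(d: float) -> str:
    """Map |d| to the effect-size star code (n.e., *, **, ***, ****)."""
    if np.isnan(d):
        return "n.e."
    mag = abs(d)
    for threshold, label in STAR_THRESHOLDS:
        if mag >= threshold:
            return label
    return "n.e."


def effect_grid(means: pd.DataFrame, labels: Mapping[str, str],
                genotypes: Mapping[str, str],
                pairs: Sequence[tuple[str, str]],
                min_n: int = 2) -> pd.DataFrame:
    """Stratified Cohen's d grid over (region_set x context x cluster x pair).

    ``means`` is the tidy frame from :func:`region_means_table`. Rows with
    fewer than ``min_n`` non-missing nuclei in either group are marked
    insufficient (NaN d, star "insufficient"). p-values are Welch
    two-sided t-tests on the same per-nucleus values.
    """
    df = means.copy()
    df["cluster"] = df["nucleus_id"].map(lambda n: labels.get(n))
    df["genotype"] = df["nucleus_id"].map(lambda n: genotypes.get(n))
    df = df[df["cluster"].notna() & df["genotype"].notna()]
    rows = []
    grouped = df.groupby(["region_set", "context", "cluster"], sort=True)
    for (rs, ctx, cluster), sub in grouped:
        for ga, gb in pairs:
            va = sub.loc[sub["genotype"] == ga, "mean_methylation"].dropna().to_numpy()
            vb = sub.loc[sub["genotype"] == gb, "mean_methylation"].dropna().to_numpy()
            row = {"region_set": rs, "context": ctx, "cluster": cluster,
                   "genotype_a": ga, "genotype_b": gb,
                   "n_a": len(va), "n_b": len(vb),
                   "mean_a": va.mean() if len(va) else np.nan,
                   "mean_b": vb.mean() if len(vb) else np.nan,
                   "sd_a": va.std(ddof=1) if len(va) > 1 else np.nan,
                   "sd_b": vb.std(ddof=1) if len(vb) > 1 else np.nan}
            if len(va) < min_n or len(vb) < min_n:
                row.update({"cohens_d": np.nan, "star": "insufficient",
                            "t_pvalue": np.nan})
            else:
                d = cohens_d(va, vb)
                p = float(stats.ttest_ind(va, vb, equal_var=False).pvalue) \
                    if (row["sd_a"] > 0 or row["sd_b"] > 0) else 1.0
                row.update({"cohens_d": d,
                            "star": star_category(d if np.isfinite(d) else 1.5),
                            "t_pvalue": p})
            rows.append(row)
    return pd.DataFrame(rows)
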