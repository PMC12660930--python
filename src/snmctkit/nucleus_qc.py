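"""Nucleus-level quality control for joint methylome + transcriptome wells.

Filters implemented, in pipeline order:

1. basic RNA/WGBS QC — keep wells with >= 1000 RNA reads over >= 200 genes
   and >= 10% of genome-wide 1-kb bins covered by at least one WGBS read;
2. organelle filter — censor wells with > 10% of RNA reads on
   chloroplast/mitochondrial genes (strict inequality);
3. coverage-based doublet censoring — haploid, deduplicated nuclei should
   never show a site covered more than once, so the fraction of covered
   sites with coverage > 1 is a doublet statistic; nuclei are binned into
   coverage quantiles and flagged as outliers by a robust median + k*MAD
   rule within each bin (the rate of >1x sites grows with total coverage,
   so the rule conditions on it);
4. bisulfite-conversion QC — the chloroplast genome is unmethylated, so the
   apparent chloroplast mC fraction estimates 1 - conversion rate; wells
   above ``max_chloro_mc`` with sufficient chloroplast evidence are
   censored before methylome analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io_formats import MethCallTable, ORGANELLE_CHROMS

QC_FLAGS = ("fail_rna", "fail_wgbs", "fail_organelle", "doublet_coverage",
            "fail_conversion")


@dataclass
class QCThresholds:
    min_rna_reads: int = 1000
    min_genes: int = 200
    min_bin_fraction: float = 0.10
    bin_size: int = 1000
    max_organelle_fraction: float = 0.10
    max_chloro_mc: float = 0.03
    min_chloro_cov: int = 100
    doublet_k_mad: float = 5.0
    doublet_coverage_bins: int = 10


@dataclass
class NucleusQCRecord:
    nucleus_id: str
    rna_reads: int = 0
    genes_detected: int = 0
    wgbs_bin_fraction: float = 0.0
    organelle_fraction: float = 0.0
    n_cov1: int = 0
    n_covmulti: int = 0
    multi_fraction: float = 0.0
    chloro_cov: int = 0
    chloro_mc_fraction: float = float("nan")
    conversion_estimate: float = float("nan")
    flags: set = field(default_factory=set)

    @property
    def passed(self) -> bool:
        return not self.flags

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "nucleus_id", "rna_reads", "genes_detected", "wgbs_bin_fraction",
            "organelle_fraction", "n_cov1", "n_covmulti", "multi_fraction",
            "chloro_cov", "chloro_mc_fraction", "conversion_estimate")}
        for f in QC_FLAGS:
            d[f] = f in self.flags
        d["passed"] = self.passed
        return d


def records_to_frame(records: Iterable[NucleusQCRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in records]).set_index("nucleus_id")


# ---------------------------------------------------------------------------
# individual filters
# ---------------------------------------------------------------------------

def basic_qc(meth: MethCallTable, counts_column: pd.Series,
             chrom_sizes: Mapping[str, int],
             thresholds: QCThresholds | None = None,
             organelle_chroms: frozenset = ORGANELLE_CHROMS) -> NucleusQCRecord:
    """RNA read/gene filter plus genome-wide 1-kb WGBS bin coverage filter.

    The bin grid tiles each nuclear chromosome from 0 in fixed ``bin_size``
    steps, the last partial bin included. Boundary semantics follow "at
    least": values equal to the threshold pass.
    """
    th = thresholds or QCThresholds()
    rec = NucleusQCRecord(meth.nucleus_id)
    rec.rna_reads = int(counts_column.sum()) if len(counts_column) else 0
    rec.genes_detected = int((counts_column > 0).sum()) if len(counts_column) else 0
    if rec.rna_reads < th.min_rna_reads or rec.genes_detected < th.min_genes:
        rec.flags.add("fail_rna")

    nuclear = {c: s for c, s in chrom_sizes.items() if c not in organelle_chroms}
    total_bins = sum(-(-size // th.bin_size) for size in nuclear.values())
    df = meth.df
    df = df[df["chrom"].isin(nuclear)]
    if total_bins > 0 and len(df):
        covered = df.groupby("chrom")["pos"].apply(
            lambda p: (p // th.bin_size).nunique()).sum()
        rec.wgbs_bin_fraction = float(covered) / total_bins
    if rec.wgbs_bin_fraction < th.min_bin_fraction:
        rec.flags.add("fail_wgbs")
    return rec


def organelle_filter(counts_column: pd.Series, organelle_genes: Iterable[str],
                     threshold: float = 0.10) -> tuple[float, bool]:
    """Fraction of RNA reads on organelle genes; flagged when strictly > threshold.

    A zero-read column yields fraction 0 and no flag (fail_rna governs it).
    """
    organelle_genes = set(organelle_genes)
    total = float(counts_column.sum())
    if total == 0:
        return 0.0, False
    org = float(counts_column[counts_column.index.isin(organelle_genes)].sum())
    frac = org / total
    return frac, frac > threshold


def coverage_doublet_stats(meth: MethCallTable) -> tuple[int, int, float]:
    """(sites covered exactly once, sites covered more than once, multi fraction)."""
    cov = meth.df["cov"]
    n1 = int((cov == 1).sum())
    nm = int((cov > 1).sum())
    denom = n1 + nm
    return n1, nm, (nm / denom if denom else 0.0)


def censor_coverage_doublets(records: list[NucleusQCRecord],
                             k_mad: float = 5.0,
                             n_coverage_bins: int = 10,
                             eps: float = 1e-6) -> set[str]:
    """Cohort-level doublet censor on the >1x-coverage fraction.

    Nuclei are split into quantile bins of total covered sites; within each
    bin a nucleus is flagged when its multi_fraction exceeds
    median + k_mad * 1.4826 * MAD. In degenerate bins (MAD = 0) only values
    strictly above both median + eps and every unflagged member are flagged,
    so bins of identical values never self-censor. Flags the records in
    place (``doublet_coverage``) and returns the flagged id set.
    """
    if len(records) < 20:
        warnings.warn("fewer than 20 nuclei: coverage-doublet censoring skipped")
        return set()
    total = np.array([r.n_cov1 + r.n_covmulti for r in records], dtype=float)
    frac = np.array([r.multi_fraction for r in records], dtype=float)
    # value-based quantile bins: tied coverage values share a bin, so the
    # flagged set is invariant under permutation of the input order and a
    # cohort of identical totals is judged against one joint median
    edges = np.unique(np.quantile(total, np.linspace(0, 1, n_coverage_bins + 1)))
    bins = (np.searchsorted(edges, total, side="right") - 1
            if len(edges) > 2 else np.zeros(len(records), dtype=int))
    bins = np.clip(bins, 0, max(len(edges) - 2, 0))
    flagged: set[str] = set()
    for b in range(int(bins.max()) + 1):
        sel = np.flatnonzero(bins == b)
        if sel.size == 0:
            continue
        vals = frac[sel]
        med = float(np.median(vals))
        mad = float(np.median(np.abs(vals - med))) * 1.4826
        if mad > 0:
            hit = vals > med + k_mad * mad
        else:
            cand = vals > med + eps
            if cand.all() or not cand.any():
                hit = np.zeros_like(cand)
            else:
                ceiling = vals[~cand].max()
                hit = cand & (vals > ceiling)
        for i in sel[hit]:
            flagged.add(records[i].nucleus_id)
            records[i].flags.add("doublet_coverage")
    return flagged


def conversion_qc(meth: MethCallTable,
                  chloro_chroms: Iterable[str] = ("ChrC",),
                  max_chloro_mc: float = 0.03,
                  min_chloro_cov: int = 100) -> tuple[float, float, bool]:
    """Chloroplast-based conversion estimate: (mC fraction, 1 - fraction, flag).

    The flag requires both an elevated apparent chloroplast methylation and
    at least ``min_chloro_cov`` chloroplast read coverage; with less
    evidence the fraction is still reported but never flagged.
    """
    df = meth.df[meth.df["chrom"].isin(set(chloro_chroms))]
    cov = int(df["cov"].sum())
    if cov == 0:
        return float("nan"), float("nan"), False
    frac = float(df["mc"].sum()) / cov
    flag = frac > max_chloro_mc and cov >= min_chloro_cov
    if cov < min_chloro_cov:
        warnings.warn(
            f"{meth.nucleus_id}: chloroplast coverage {cov} < {min_chloro_cov}; "
            "conversion flag withheld")
    return frac, 1.0 - frac, flag


# ---------------------------------------------------------------------------
# cohort driver
# ---------------------------------------------------------------------------

def run_qc(meth_tables: Mapping[str, MethCallTable], counts,
           chrom_sizes: Mapping[str, int],
           thresholds: QCThresholds | None = None,
           chloro_chroms: Iterable[str] = ("ChrC",),
           organelle_chroms: frozenset = ORGANELLE_CHROMS
           ) -> list[NucleusQCRecord]:
    """All per-nucleus filters plus the cohort-level doublet censor.

    ``counts`` is a CountMatrix; nuclei present in ``meth_tables`` but
    absent from the matrix are treated as zero-count wells.
    """
    th = thresholds or QCThresholds()
    records = []
    empty = pd.Series(dtype=np.int64)
    for nid, table in meth_tables.items():
        col = counts.column(nid) if nid in counts.counts.columns else empty
        rec = basic_qc(table, col, chrom_sizes, th, organelle_chroms)
        frac, flagged = organelle_filter(col, counts.organelle_genes,
                                         th.max_organelle_fraction)
        rec.organelle_fraction = frac
        if flagged:
            rec.flags.add("fail_organelle")
        rec.n_cov1, rec.n_covmulti, rec.multi_fraction = coverage_doublet_stats(table)
        mc_frac, conv, cflag = conversion_qc(table, chloro_chroms,
                                             th.max_chloro_mc, th.min_chloro_cov)
        rec.chloro_cov = int(table.df[table.df["chrom"].isin(set(chloro_chroms))]["cov"].sum())
        rec.chloro_mc_fraction = mc_frac
        rec.conversion_estimate = conv
        if cflag:
            rec.flags.add("fail_conversion")
        records.append(rec)
    censor_coverage_doublets(records, th.doublet_k_mad, th.doublet_coverage_bins)
    return records
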