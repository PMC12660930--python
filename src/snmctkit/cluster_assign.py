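"""Marker-score cluster assignment and the VN/SN doublet reassignment.

Graph clustering and embedding (the usual droplet-style workflow) are
deliberately out of scope here: pollen nucleus types are few and have
well-validated marker genes, so nuclei are assigned by supervised marker
scoring — the per-cluster mean of gene-wise z-scored log-normalized marker
expression, argmax over clusters. A projection hook freezes the z-score
parameters of a reference cohort so that a later experiment can be scored
against the same scale, and `methylome_feature_matrix`/`to_anndata` export
matrices for external embedding tools.

Mature VN and SN nuclei frequently stick together during sorting; wells
with balanced mature-VN and SN marker expression (|log2 ratio| <= 0.2) are
relabelled "VN_and_SN" and treated as likely physical doublets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CountMatrix, MethCallTable
from .synthetic_data import DEFAULT_CLUSTER_ORDER, MATURE_VN

VN_AND_SN = "VN_and_SN"


@dataclass
class ZParams:
    """Frozen per-gene z-score parameters of a reference cohort."""
    mean: pd.Series
    sd: pd.Series


@dataclass
class ClusterAssignment:
    labels: pd.Series            # nucleus_id -> cluster label
    scores: pd.DataFrame         # nuclei x clusters marker scores
    reassigned: pd.Series        # nucleus_id -> bool (VN/SN doublet relabel)
    zparams: ZParams | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"cluster": self.labels, "reassigned_vn_sn": self.reassigned})
        df.index.name = "nucleus_id"
        return df


def normalize_expression(counts: CountMatrix, target: float = 1e4) -> pd.DataFrame:
    """Counts-per-10k log1p normalization, organelle genes excluded first.

    Returns genes x nuclei; scale-invariant per nucleus (doubling a
    nucleus's counts leaves its normalized profile unchanged).
    """
    mat = counts.counts.drop(index=list(counts.organelle_genes), errors="ignore")
    libs = mat.sum(axis=0)
    if (libs == 0).any():
        bad = list(libs.index[libs == 0])[:5]
        raise ValueError(f"all-zero nucleus column(s) {bad}: should have failed QC")
    return np.log1p(mat / libs * target)


def _zscore(norm: pd.DataFrame, zparams: ZParams | None) -> pd.DataFrame:
    if zparams is None:
        mu = norm.mean(axis=1)
        sd = norm.std(axis=1, ddof=0)
    else:
        mu = zparams.mean.reindex(norm.index).fillna(0.0)
        sd = zparams.sd.reindex(norm.index).fillna(0.0)
    sd_safe = sd.replace(0.0, np.inf)  # constant genes contribute z = 0
    z = norm.sub(mu, axis=0).div(sd_safe, axis=0)
    return z


def _surviving_panel(panel: Mapping[str, Sequence[str]],
                     genes: pd.Index) -> dict[str, list[str]]:
    out = {}
    for cluster, markers in panel.items():
        present = [g for g in markers if g in genes]
        missing = set(markers) - set(present)
        if missing:
            warnings.warn(f"{cluster}: dropping absent marker(s) {sorted(missing)}")
        if not present:
            raise ValueError(f"cluster {cluster!r} lost all markers")
        out[cluster] = present
    return out


def assign_clusters(norm: pd.DataFrame, panel: Mapping[str, Sequence[str]],
                    cluster_order: Sequence[str] = DEFAULT_CLUSTER_ORDER,
                    zparams: ZParams | None = None) -> ClusterAssignment:
    """Label each nucleus by its best marker score.

    score(c) = mean over c's markers of gene-wise z-scored normalized
    expression; ties broken by ``cluster_order`` priority. Passing
    ``zparams`` scores against a frozen reference scale (projection of a
    new experiment onto an existing cohort).
    """
    surviving = _surviving_panel(panel, norm.index)
    z = _zscore(norm, zparams)
    ordered = [c for c in cluster_order if c in surviving]
    ordered += [c for c in surviving if c not in ordered]
    scores = pd.DataFrame(
        {c: z.loc[surviving[c]].mean(axis=0) for c in ordered})
    arr = scores.to_numpy()
    best = np.argmax(arr, axis=1)  # first occurrence wins -> cluster_order priority
    labels = pd.Series([ordered[i] for i in best], index=scores.index, name="cluster")
    fitted = zparams or ZParams(norm.mean(axis=1), norm.std(axis=1, ddof=0))
    return ClusterAssignment(
        labels=labels, scores=scores,
        reassigned=pd.Series(False, index=scores.index, name="reassigned_vn_sn"),
        zparams=fitted)


def vn_sn_doublet_reassign(norm: pd.DataFrame, assignment: ClusterAssignment,
                           panel: Mapping[str, Sequence[str]],
                           mature_vn: Sequence[str] = MATURE_VN,
                           sn: str = "SN", window: float = 0.2,
                           eps: float = 1e-9) -> ClusterAssignment:
    """Relabel balanced mature-VN/SN wells as the "VN_and_SN" doublet class.

    For every nucleus currently labelled VN4, VN5 or SN, compute
    r = log2((mean SN-marker expr + eps) / (mean mature-VN-marker expr + eps))
    on normalized expression; nuclei with r inside [-window, window]
    (inclusive) are reassigned. All other labels are fixed points.
    """
    sn_markers = [g for g in panel[sn] if g in norm.index]
    vn_markers = sorted({g for c in mature_vn for g in panel.get(c, ())
                         if g in norm.index})
    if not sn_markers or not vn_markers:
        raise ValueError("empty SN or mature-VN marker set")
    labels = assignment.labels.copy()
    reassigned = assignment.reassigned.copy()
    candidates = labels.index[labels.isin(list(mature_vn) + [sn])]
    if len(candidates):
        sn_mean = norm.loc[sn_markers, candidates].mean(axis=0)
        vn_mean = norm.loc[vn_markers, candidates].mean(axis=0)
        r = np.log2((sn_mean + eps) / (vn_mean + eps))
        hit = r.index[(r >= -window) & (r <= window)]
        labels.loc[hit] = VN_AND_SN
        reassigned.loc[hit] = True
    return ClusterAssignment(labels=labels, scores=assignment.scores,
                             reassigned=reassigned, zparams=assignment.zparams)


def log2_sn_vn_ratio(norm: pd.DataFrame, panel: Mapping[str, Sequence[str]],
                     mature_vn: Sequence[str] = MATURE_VN, sn: str = "SN",
                     eps: float = 1e-9) -> pd.Series:
    """The SN/mature-VN marker log2 ratio for every nucleus (diagnostics)."""
    sn_markers = [g for g in panel[sn] if g in norm.index]
    vn_markers = sorted({g for c in mature_vn for g in panel.get(c, ())
                         if g in norm.index})
    sn_mean = norm.loc[sn_markers].mean(axis=0)
    vn_mean = norm.loc[vn_markers].mean(axis=0)
    return np.log2((sn_mean + eps) / (vn_mean + eps))


# ---------------------------------------------------------------------------
# methylome feature matrix (for external embedding)
# ---------------------------------------------------------------------------

def methylome_feature_matrix(meth_tables: Mapping[str, MethCallTable],
                             chrom_sizes: Mapping[str, int],
                             bin_size: int = 25_000,
                             contexts: Sequence[str] = ("CG", "CHG", "CHH")
                             ) -> pd.DataFrame:
    """Nuclei x (25-kb bin x context) methylation-fraction feature matrix.

    Each entry is sum(mc)/sum(cov) over the bin's cytosines of that
    context; bins with no covered cytosine are NaN (missing), never 0.
    """
    columns = []
    for chrom, size in chrom_sizes.items():
        for start in range(0, size, bin_size):
            for ctx in contexts:
                columns.append(f"{chrom}:{start}-{min(start + bin_size, size)}:{ctx}")
    col_index = {c: i for i, c in enumerate(columns)}
    out = np.full((len(meth_tables), len(columns)), np.nan)
    nuclei = list(meth_tables)
    for row, nid in enumerate(nuclei):
        df = meth_tables[nid].df
        df = df[df["context"].isin(contexts)]
        if not len(df):
            continue
        binned = df.assign(bin=(df["pos"] // bin_size) * bin_size)
        agg = binned.groupby(["chrom", "bin", "context"])[["mc", "cov"]].sum()
        for (chrom, start, ctx), vals in agg.iterrows():
            if chrom not in chrom_sizes:
                continue
            key = f"{chrom}:{start}-{min(start + bin_size, chrom_sizes[chrom])}:{ctx}"
            j = col_index.get(key)
            if j is not None and vals["cov"] > 0:
                out[row, j] = vals["mc"] / vals["cov"]
    return pd.DataFrame(out, index=pd.Index(nuclei, name="nucleus_id"),
                        columns=columns)


def to_anndata(norm: pd.DataFrame, assignment: ClusterAssignment | None = None):
    """Export normalized expression (nuclei x genes) as AnnData for external
    embedding/integration tools."""
    import anndata as ad

    adata = ad.AnnData(norm.T.to_numpy())
    adata.obs_names = list(norm.columns)
    adata.var_names = list(norm.index)
    if assignment is not None:
        adata.obs["cluster"] = assignment.labels.reindex(adata.obs_names).to_numpy()
    return adata
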