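"""Expression-side statistics: TPM, a simple differential-expression test,
and the rescue / activation-timing classifiers.

The DE test here is a deliberately simple, clearly-named stand-in (Welch
t-test on log2(CPM + 1) with Benjamini-Hochberg correction, cutoff
padj < 0.05 and |log2FC| > 1); it is not a count-model fit and outputs are
tagged with the method name so they are never mistaken for one.

The rescue classifier reproduces the three-way rescued / partially rescued /
not rescued split over mutant-upregulated transcripts (plus an "other" bin
for transcripts that do not fall cleanly into the monotone pattern):
transcripts are hierarchically clustered on row-z-scored TPM and each
cluster is labelled by its centroid's rescue ratio

    r = (log2(mutAB + 1) - log2(WT + 1)) / (log2(mutA + 1) - log2(WT + 1)),

i.e. the fraction of the mutant log-fold-change retained in the double
mutant: r ~ 0 means fully restored to wild type, r ~ 1 means unchanged
from the single mutant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

DE_METHOD = "welch_log2cpm_bh"

RESCUE_LABELS = ("rescued", "partially_rescued", "not_rescued", "other")


def tpm(counts: pd.Series | pd.DataFrame,
        lengths: pd.Series) -> pd.Series | pd.DataFrame:
    """Transcripts-per-million from counts and transcript lengths (bp).

    rate_g = count_g / length_g; TPM_g = 1e6 * rate_g / sum(rate). Columns
    of a DataFrame are normalized independently and each sums to 1e6.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive length")
    rate = counts.div(lengths, axis=0)
    total = rate.sum(axis=0) if isinstance(rate, pd.DataFrame) else rate.sum()
    if np.any(np.asarray(total) == 0):
        raise ValueError("zero library: no reads to normalize")
    return rate / total * 1e6


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    libs = counts.sum(axis=0)
    if (libs == 0).any():
        raise ValueError("zero library")
    return counts / libs * 1e6


def de_standin(counts_a: pd.DataFrame, counts_b: pd.DataFrame,
               alpha: float = 0.05, lfc: float = 1.0) -> pd.DataFrame:
    """Per-transcript A-vs-B test: Welch t on log2(CPM+1), BH-adjusted.

    log2FC is computed from group-mean CPM with pseudocount 1 (positive =
    higher in A). Significant iff padj < alpha and |log2FC| > lfc.
    """
    if counts_a.shape[1] < 2 or counts_b.shape[1] < 2:
        raise ValueError("need >= 2 replicates per group")
    genes = counts_a.index
    if not genes.equals(counts_b.index):
        raise ValueError("gene sets differ between groups")
    la = np.log2(cpm(counts_a) + 1.0)
    lb = np.log2(cpm(counts_b) + 1.0)
    res = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    padj = multipletests(p, method="fdr_bh")[1]
    log2fc = np.log2(cpm(counts_a).mean(axis=1) + 1.0) \
        - np.log2(cpm(counts_b).mean(axis=1) + 1.0)
    out = pd.DataFrame({
        "log2fc": log2fc, "pvalue": p, "padj": padj,
        "significant": (padj < alpha) & (np.abs(log2fc) > lfc),
    }, index=genes)
    out.attrs["method"] = DE_METHOD
    return out


# ---------------------------------------------------------------------------
# rescue classification
# ---------------------------------------------------------------------------

@dataclass
class RescueClassification:
    labels: pd.Series           # transcript -> label
    cluster_ids: pd.Series      # transcript -> dendrogram cluster
    centroids: pd.DataFrame     # cluster x genotype mean TPM
    ratios: pd.Series           # cluster -> rescue ratio r


def _rescue_ratio(centroid: Mapping[str, float], wt: str, mut: str,
                  double: str) -> tuple[float, float]:
    denom = np.log2(centroid[mut] + 1.0) - np.log2(centroid[wt] + 1.0)
    numer = np.log2(centroid[double] + 1.0) - np.log2(centroid[wt] + 1.0)
    return (numer / denom if denom != 0 else np.nan), denom


def rescue_classify(tpm_matrix: pd.DataFrame,
                    genotype_of: Mapping[str, str],
                    upregulated: Sequence[str],
                    k: int = 8, wt: str = "WT", mut: str = "mutA",
                    double: str = "mutAB",
                    control_genotypes: Sequence[str] = ("mutB",),
                    ratio_rescued: float = 0.25,
                    ratio_partial: float = 0.75,
                    ratio_overshoot: float = 1.5,
                    min_signal: float = 0.5,
                    max_control_shift: float = 0.5) -> RescueClassification:
    """Classify mutant-upregulated transcripts by extent of rescue.

    Rows (restricted to ``upregulated``) are z-scored across samples and
    clustered with average-linkage Euclidean hierarchical clustering cut to
    ``k`` clusters; ``k`` deliberately exceeds the number of labels
    (over-cluster, then label each cluster by its centroid) because cutting
    exactly at the class count is brittle under replicate noise. Each cluster's centroid rescue ratio r maps to a label:
    r <= ratio_rescued -> rescued; <= ratio_partial -> partially_rescued;
    otherwise not_rescued. Clusters that do not fall cleanly into that
    monotone pattern are "other": weak mutant upregulation
    (|log2FC| < min_signal), a non-monotone centroid (r < -ratio_rescued
    or r > ratio_overshoot), or misregulation in a control genotype
    (|log2FC vs WT| > max_control_shift in any of ``control_genotypes``).
    Degenerate all-equal rows are dropped with a warning.
    """
    missing = [t for t in upregulated if t not in tpm_matrix.index]
    if missing:
        raise KeyError(f"transcript(s) not in TPM matrix: {missing[:5]}")
    sub = tpm_matrix.loc[list(upregulated)]
    sd = sub.std(axis=1, ddof=0)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(f"dropping {int(degenerate.sum())} all-equal transcript row(s)")
        sub = sub[~degenerate]
        sd = sd[~degenerate]
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    if len(z) < k:
        raise ValueError(f"fewer transcripts ({len(z)}) than clusters ({k})")
    link = hierarchy.linkage(z.to_numpy(), method="average", metric="euclidean")
    cluster_ids = pd.Series(hierarchy.fcluster(link, t=k, criterion="maxclust"),
                            index=z.index, name="cluster")
    geno = pd.Series({s: genotype_of[s] for s in tpm_matrix.columns})
    geno_means = sub.T.groupby(geno).mean().T  # transcripts x genotypes
    centroids = geno_means.groupby(cluster_ids).mean()

    labels = {}
    ratios = {}
    for cid, centroid in centroids.iterrows():
        r, denom = _rescue_ratio(centroid, wt, mut, double)
        ratios[cid] = r
        control_shift = max(
            (abs(np.log2(centroid[g] + 1.0) - np.log2(centroid[wt] + 1.0))
             for g in control_genotypes if g in centroid), default=0.0)
        if abs(denom) < min_signal or np.isnan(r) \
                or r < -ratio_rescued or r > ratio_overshoot \
                or control_shift > max_control_shift:
            labels[cid] = "other"
        elif r <= ratio_rescued:
            labels[cid] = "rescued"
        elif r <= ratio_partial:
            labels[cid] = "partially_rescued"
        else:
            labels[cid] = "not_rescued"
    return RescueClassification(
        labels=cluster_ids.map(labels).rename("label"),
        cluster_ids=cluster_ids,
        centroids=centroids,
        ratios=pd.Series(ratios, name="rescue_ratio"),
    )


# ---------------------------------------------------------------------------
# activation timing
# ---------------------------------------------------------------------------

IMMATURE_VN = ("VN1", "VN1to2", "VN2", "VN3")
MATURE_VN_TIMING = ("VN4", "VN5")


@dataclass
class TimingClassification:
    labels: pd.Series              # transcript -> immature_VN / mature_VN / none
    activation_cluster: pd.Series  # transcript -> earliest activating cluster


def timing_classify(wt_means: pd.DataFrame, mut_means: pd.DataFrame,
                    vn_order: Sequence[str] = IMMATURE_VN + MATURE_VN_TIMING,
                    lfc_threshold: float = 1.0,
                    min_expr: float = 0.5) -> TimingClassification:
    """Classify transcripts by where along VN maturation they first become
    upregulated in the mutant.

    Inputs are transcripts x cluster mean-expression matrices; the earliest
    cluster (in ``vn_order``) with log2((mut+1)/(wt+1)) > lfc_threshold and
    mutant mean > min_expr determines the class: immature VN (VN1-VN3),
    mature VN (VN4-VN5), or none.
    """
    for c in vn_order:
        if c not in wt_means.columns or c not in mut_means.columns:
            raise KeyError(f"cluster {c!r} missing from mean-expression input")
    labels = {}
    activation = {}
    for t in wt_means.index:
        first = None
        for c in vn_order:
            lfc = np.log2(mut_means.at[t, c] + 1.0) - np.log2(wt_means.at[t, c] + 1.0)
            if lfc > lfc_threshold and mut_means.at[t, c] > min_expr:
                first = c
                break
        activation[t] = first
        if first is None:
            labels[t] = "none"
        elif first in IMMATURE_VN:
            labels[t] = "immature_VN"
        else:
            labels[t] = "mature_VN"
    return TimingClassification(
        labels=pd.Series(labels, name="timing"),
        activation_cluster=pd.Series(activation, name="activation_cluster"),
    )
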