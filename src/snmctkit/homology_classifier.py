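"""Classify loci as TE-like, gene-like, ambiguous or neither from BLAST hits.

Each locus is summarized by its best (maximum) bitscore against a gene
annotation and against TE/TE-gene annotations. Significance is screened
first — a bitscore must be strictly greater than ``min_bitscore`` (default
100) to count as homology at all — then, when both classes are significant,
the locus goes to the class with the >= ``ratio`` (default 3x) higher
bitscore, or is called ambiguous when neither dominates. Loci with no
significant homology to either class are "neither".
"""

from __future__ import annotations

import pandas as pd

GENE_CLASSES = frozenset({"gene"})
TE_CLASSES = frozenset({"TE", "TEgene"})
LABELS = ("TE", "gene", "ambiguous", "neither")


def best_scores(hits: pd.DataFrame, loci: list[str] | None = None) -> pd.DataFrame:
    """Per-locus best gene and TE bitscores (0 when a class has no hit).

    ``hits`` needs columns query_id, bitscore, subject_class; ``loci``
    optionally forces rows for loci with no hits at all.
    """
    if len(hits) and (hits["bitscore"] < 0).any():
        raise ValueError("negative bitscore")
    gene = hits[hits["subject_class"].isin(GENE_CLASSES)] \
        .groupby("query_id")["bitscore"].max()
    te = hits[hits["subject_class"].isin(TE_CLASSES)] \
        .groupby("query_id")["bitscore"].max()
    index = sorted(set(hits["query_id"]) | set(loci or ()))
    return pd.DataFrame({
        "best_gene_bitscore": gene.reindex(index).fillna(0.0),
        "best_TE_bitscore": te.reindex(index).fillna(0.0),
    }, index=pd.Index(index, name="locus_id"))


def classify_scores(best_gene: float, best_te: float,
                    min_bitscore: float = 100.0, ratio: float = 3.0) -> str:
    """Label one locus from its two best bitscores (significance before ratio)."""
    sig_gene = best_gene > min_bitscore
    sig_te = best_te > min_bitscore
    if sig_gene and sig_te:
        hi, lo = max(best_gene, best_te), min(best_gene, best_te)
        if lo > 0 and hi / lo >= ratio:
            return "gene" if best_gene > best_te else "TE"
        return "ambiguous"
    if sig_gene:
        return "gene"
    if sig_te:
        return "TE"
    return "neither"


def classify_homology(hits: pd.DataFrame, min_bitscore: float = 100.0,
                      ratio: float = 3.0,
                      loci: list[str] | None = None) -> pd.DataFrame:
    """Classify every locus in a BLAST outfmt-6 hit table.

    Returns a frame indexed by locus with best scores and the label in
    {TE, gene, ambiguous, neither}. Duplicate hit rows are harmless (max
    aggregation is idempotent).
    """
    scores = best_scores(hits, loci)
    scores["label"] = [
        classify_scores(g, t, min_bitscore, ratio)
        for g, t in zip(scores["best_gene_bitscore"], scores["best_TE_bitscore"])
    ]
    return scores
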