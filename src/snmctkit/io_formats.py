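"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates are 0-based half-open internally (BED convention).
Per-site methylation call tables on disk are allc-style 1-based by default;
the reader/writer pair converts with an explicit ``position_base`` switch so
both dialects round-trip without silent off-by-one shifts.

Chloroplast and mitochondrial sequences are identified by chromosome name
(default ``{"ChrC", "ChrM"}``); there is no reference-FASTA dependency, and
sequence context (CG/CHG/CHH) is carried in the file rather than recomputed.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CONTEXTS = ("CG", "CHG", "CHH")
ORGANELLE_CHROMS = frozenset({"ChrC", "ChrM"})

METH_COLUMNS = ["chrom", "pos", "strand", "context", "mc", "cov"]
BLAST6_COLUMNS = [
    "query_id", "subject_id", "pct_identity", "aln_len", "mismatches",
    "gaps", "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


class ParseError(ValueError):
    """Malformed input file (reported with a line number where possible)."""


class ValidationError(ValueError):
    """Structurally parseable input that violates a domain invariant."""


# ---------------------------------------------------------------------------
# MethCallTable
# ---------------------------------------------------------------------------

@dataclass
class MethCallTable:
    """Per-nucleus per-site methylation calls.

    ``df`` columns: chrom (str), pos (int, 0-based), strand (+/-),
    context (CG/CHG/CHH), mc (methylated reads), cov (total reads >= 1).
    """

    nucleus_id: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.df
        missing = [c for c in METH_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"missing columns: {missing}")
        if len(df) == 0:
            return
        if (df["pos"] < 0).any():
            raise ValidationError("negative position")
        if not df["strand"].isin(["+", "-"]).all():
            raise ValidationError("strand must be '+' or '-'")
        if not df["context"].isin(CONTEXTS).all():
            bad = sorted(set(df["context"]) - set(CONTEXTS))
            raise ValidationError(f"unknown context(s): {bad}")
        if (df["cov"] < 1).any():
            raise ValidationError("cov must be >= 1")
        if (df["mc"] < 0).any():
            raise ValidationError("mc must be >= 0")
        if (df["mc"] > df["cov"]).any():
            i = int((df["mc"] > df["cov"]).idxmax())
            raise ValidationError(
                f"mc > cov at {df.at[i, 'chrom']}:{df.at[i, 'pos']}"
            )
        if df.duplicated(subset=["chrom", "pos", "strand"]).any():
            raise ValidationError("duplicate (chrom, pos, strand) record")
        # positions sorted within chromosome
        for _, sub in df.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing:
                raise ValidationError("positions not sorted within chromosome")

    def __len__(self) -> int:
        return len(self.df)

    def subset_chroms(self, chroms: Iterable[str]) -> "MethCallTable":
        keep = self.df["chrom"].isin(set(chroms))
        return MethCallTable(self.nucleus_id, self.df[keep].copy())


def _canonical_meth_frame(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["pos"] = out["pos"].astype(np.int64)
    out["mc"] = out["mc"].astype(np.int64)
    out["cov"] = out["cov"].astype(np.int64)
    return out.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)


def read_meth_calls(path: str | Path, nucleus_id: str | None = None,
                    position_base: int = 1) -> MethCallTable:
    """Read a 6-column tab-separated per-site methylation call table.

    Columns: chrom, pos, strand, context, mc, cov (no header). ``position_base``
    declares the file's coordinate dialect; positions are stored 0-based.
    """
    if position_base not in (0, 1):
        raise ValueError("position_base must be 0 or 1")
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ParseError(f"{path.name}:{lineno}: expected 6 fields, got {len(parts)}")
            try:
                rows.append((parts[0], int(parts[1]), parts[2], parts[3],
                             int(parts[4]), int(parts[5])))
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from None
    df = pd.DataFrame(rows, columns=METH_COLUMNS)
    if len(df):
        df["pos"] = df["pos"] - position_base
    df = _canonical_meth_frame(df) if len(df) else df
    nid = nucleus_id if nucleus_id is not None else path.stem
    return MethCallTable(nid, df)


def write_meth_calls(table: MethCallTable, path: str | Path,
                     position_base: int = 1) -> None:
    if position_base not in (0, 1):
        raise ValueError("position_base must be 0 or 1")
    df = _canonical_meth_frame(table.df)
    df["pos"] = df["pos"] + position_base
    df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# RegionSet
# ---------------------------------------------------------------------------

@dataclass
class RegionSet:
    """Named ordered set of 0-based half-open genomic intervals.

    ``df`` columns: chrom, start, end, id, strand ('+', '-' or '.').
    """

    name: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        if "strand" not in df.columns:
            df["strand"] = "."
        if "id" not in df.columns:
            df["id"] = [f"{self.name}_{i}" for i in range(len(df))]
        df = df[["chrom", "start", "end", "id", "strand"]]
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        self.df = df
        self.validate()

    def validate(self) -> None:
        df = self.df
        if len(df) == 0:
            return
        if (df["start"] < 0).any():
            raise ValidationError(f"{self.name}: negative start")
        if (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise ValidationError(
                f"{self.name}: empty/inverted interval {bad['chrom']}:{bad['start']}-{bad['end']}"
            )
        if df["id"].duplicated().any():
            raise ValidationError(f"{self.name}: duplicate interval ids")
        if not df["strand"].isin(["+", "-", "."]).all():
            raise ValidationError(f"{self.name}: bad strand value")

    def __len__(self) -> int:
        return len(self.df)

    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def total_bases(self) -> int:
        return int(self.lengths().sum())


def read_bed(path: str | Path, name: str | None = None) -> RegionSet:
    """Read BED3/BED4/BED6 into a RegionSet (coordinates preserved exactly)."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path.name}:{lineno}: expected >=3 fields")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from None
            rid = parts[3] if len(parts) >= 4 else f"region_{len(rows)}"
            strand = parts[5] if len(parts) >= 6 else "."
            rows.append((chrom, start, end, rid, strand))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "id", "strand"])
    return RegionSet(name or path.stem, df)


def write_bed(rs: RegionSet, path: str | Path) -> None:
    df = rs.df.copy()
    if (df["strand"] == ".").all():
        out = df[["chrom", "start", "end", "id"]].copy()
        out["score"] = "."
        out["strand"] = "."
    else:
        out = df[["chrom", "start", "end", "id"]].copy()
        out["score"] = "."
        out["strand"] = df["strand"]
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# CountMatrix
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Genes x nuclei non-negative integer RNA counts.

    ``counts``: DataFrame indexed by gene id with nucleus ids as columns.
    ``organelle_genes``: gene ids flagged chloroplast/mitochondrial.
    """

    counts: pd.DataFrame
    organelle_genes: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.organelle_genes = frozenset(self.organelle_genes)
        self.validate()

    def validate(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            raise ValidationError("duplicate gene ids")
        if c.columns.duplicated().any():
            raise ValidationError("duplicate nucleus ids")
        vals = c.to_numpy()
        if vals.size and (vals < 0).any():
            raise ValidationError("negative counts")
        if vals.size and not np.allclose(vals, np.round(vals)):
            raise ValidationError("non-integral counts")
        extra = self.organelle_genes - set(c.index)
        if extra:
            raise ValidationError(f"organelle genes absent from matrix: {sorted(extra)[:5]}")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def nuclei(self) -> list[str]:
        return list(self.counts.columns)

    def column(self, nucleus_id: str) -> pd.Series:
        return self.counts[nucleus_id]


def read_counts(path: str | Path, organelle_genes: Iterable[str] = (),
                genes_path: str | Path | None = None,
                nuclei_path: str | Path | None = None) -> CountMatrix:
    """Read a count matrix from TSV (genes x nuclei, header row) or MTX.

    MTX requires sidecar id files (one id per line) for genes and nuclei.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        if genes_path is None or nuclei_path is None:
            raise ValueError("MTX input requires genes_path and nuclei_path sidecars")
        mat = mmread(path).toarray()
        genes = [l.strip() for l in open(genes_path) if l.strip()]
        nuclei = [l.strip() for l in open(nuclei_path) if l.strip()]
        if mat.shape != (len(genes), len(nuclei)):
            raise ValidationError(
                f"MTX shape {mat.shape} does not match sidecars ({len(genes)}, {len(nuclei)})"
            )
        df = pd.DataFrame(mat.astype(np.int64), index=genes, columns=nuclei)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.index.name = None
        df.columns = df.columns.astype(str)
    return CountMatrix(df, frozenset(organelle_genes) & set(df.index))


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    out = cm.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# BLAST outfmt 6
# ---------------------------------------------------------------------------

def read_blast6(path: str | Path, subject_class: str | None = None) -> pd.DataFrame:
    """Read BLAST tabular output (outfmt 6; 12 fields, or 13 with a
    subject_class column). ``subject_class`` sets the class for every row
    of a 12-field file (one annotation source per file)."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (12, 13):
                raise ParseError(
                    f"{path.name}:{lineno}: expected 12 (or 13) fields, got {len(parts)}"
                )
            try:
                row = [parts[0], parts[1], float(parts[2]), int(parts[3]),
                       int(parts[4]), int(parts[5]), int(parts[6]), int(parts[7]),
                       int(parts[8]), int(parts[9]), float(parts[10]), float(parts[11])]
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from None
            cls = parts[12] if len(parts) == 13 else subject_class
            rows.append(row + [cls])
    df = pd.DataFrame(rows, columns=BLAST6_COLUMNS + ["subject_class"])
    if len(df):
        if df["subject_class"].isna().any():
            raise ValidationError("subject_class missing; pass subject_class= or use 13-column input")
        if (df["bitscore"] < 0).any():
            raise ValidationError("negative bitscore")
        bad = set(df["subject_class"]) - {"gene", "TE", "TEgene"}
        if bad:
            raise ValidationError(f"unknown subject_class: {sorted(bad)}")
    return df


# ---------------------------------------------------------------------------
# SampleSheet
# ---------------------------------------------------------------------------

SAMPLESHEET_COLUMNS = ["nucleus_id", "genotype", "experiment", "plate", "well"]


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """TSV with header nucleus_id/genotype/experiment/plate/well, indexed by nucleus."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SAMPLESHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"sample sheet missing columns: {missing}")
    if df["nucleus_id"].duplicated().any():
        raise ValidationError("duplicate nucleus_id in sample sheet")
    return df.set_index("nucleus_id")


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    out = sheet.reset_index()
    if out.columns[0] != "nucleus_id":
        out = out.rename(columns={out.columns[0]: "nucleus_id"})
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# bedGraph export of pooled tracks
# ---------------------------------------------------------------------------

def write_bedgraph(track: pd.DataFrame, path: str | Path,
                   bin_size: int | None = None, context: str | None = None) -> None:
    """Write a pooled (chrom, pos, context, mc, cov) track as bedGraph.

    Per covered position by default (interval [pos, pos+1)); with
    ``bin_size`` set, positions are pooled into fixed-width bins and the
    value is the binwise fraction methylated sum(mc)/sum(cov).
    """
    df = track
    if context is not None:
        df = df[df["context"] == context]
    if bin_size is None:
        g = df.groupby(["chrom", "pos"], sort=True)[["mc", "cov"]].sum().reset_index()
        g["start"] = g["pos"]
        g["end"] = g["pos"] + 1
    else:
        tmp = df.copy()
        tmp["start"] = (tmp["pos"] // bin_size) * bin_size
        g = tmp.groupby(["chrom", "start"], sort=True)[["mc", "cov"]].sum().reset_index()
        g["end"] = g["start"] + bin_size
    g = g[g["cov"] > 0]
    g["value"] = g["mc"] / g["cov"]
    g[["chrom", "start", "end", "value"]].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# misc plumbing
# ---------------------------------------------------------------------------

def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"chrom sizes line {lineno}: expected 2 fields")
            sizes[parts[0]] = int(parts[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def combine_meth_tables(tables: Iterable[MethCallTable]) -> pd.DataFrame:
    """Concatenate per-nucleus call tables into one long frame with a
    ``nucleus_id`` column (the workhorse layout for pooling)."""
    frames = []
    for t in tables:
        df = t.df.copy()
        df.insert(0, "nucleus_id", t.nucleus_id)
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["nucleus_id"] + METH_COLUMNS)
    return pd.concat(frames, ignore_index=True)
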