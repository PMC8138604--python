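"""Readers and writers for the file formats the pipeline touches.

Bismark coverage files (6-column TSV), array beta/detection-p matrices,
BED6 gene annotation, ortholog candidate tables, signed BedGraph tracks
and Table-style DMR reports. No statistics happen here.

Coordinate convention: positions are 1-based inclusive everywhere inside
the package; the BedGraph/BED writers convert to 0-based half-open on the
way out, and the BED reader converts on the way in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CpGCountTable",
    "ArrayDataset",
    "GeneAnnotation",
    "read_bismark_coverage",
    "write_bismark_coverage",
    "read_array_dataset",
    "read_gene_annotation_bed",
    "write_gene_annotation_bed",
    "read_ortholog_candidates",
    "write_ortholog_candidates",
    "write_signed_bedgraph",
    "write_dmr_table",
    "DMR_TABLE_COLUMNS",
]


@dataclass
class CpGCountTable:
    """Per-sample CpG methylation counts with genomic coordinates.

    ``records`` has columns ``chrom``, ``pos`` (1-based), ``n_meth``,
    ``n_total`` with one row per covered CpG.
    """

    sample_id: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        required = ["chrom", "pos", "n_meth", "n_total"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"CpGCountTable missing columns: {missing}")
        if len(df):
            if (df["pos"] < 1).any():
                raise ValueError("positions must be >= 1 (1-based coordinates)")
            if (df["n_meth"] < 0).any() or (df["n_total"] < 1).any():
                raise ValueError("counts must satisfy n_meth >= 0 and n_total >= 1")
            if (df["n_meth"] > df["n_total"]).any():
                raise ValueError("n_meth exceeds n_total at some locus")
            if df.duplicated(subset=["chrom", "pos"]).any():
                raise ValueError(f"duplicate (chrom, pos) in sample {self.sample_id}")

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class ArrayDataset:
    """Bead-array methylation data: beta values, detection p-values, probe annotation.

    ``beta`` and ``detection_p`` are probe x sample frames sharing identical
    indices; ``probe_annotation`` maps probe -> (chrom, pos, gene), with
    gene == "" when unannotated.
    """

    beta: pd.DataFrame
    detection_p: pd.DataFrame
    probe_annotation: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.beta.index.equals(self.detection_p.index):
            raise ValueError("beta and detection_p probe indices differ")
        if list(self.beta.columns) != list(self.detection_p.columns):
            raise ValueError("beta and detection_p sample sets differ")
        b = self.beta.to_numpy(dtype=float)
        if len(b) and (np.nanmin(b) < 0 or np.nanmax(b) > 1):
            raise ValueError("beta values outside [0, 1]")
        p = self.detection_p.to_numpy(dtype=float)
        if len(p) and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
            raise ValueError("detection p-values outside [0, 1]")
        for col in ("chrom", "pos", "gene"):
            if col not in self.probe_annotation.columns:
                raise ValueError(f"probe_annotation missing column {col!r}")

    @property
    def n_probes(self) -> int:
        return self.beta.shape[0]

    @property
    def samples(self) -> list[str]:
        return list(self.beta.columns)


@dataclass
class GeneAnnotation:
    """Gene intervals: one row per gene with chrom, start, end (1-based
    inclusive), strand and a unique symbol."""

    genes: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        df = self.genes
        required = ["chrom", "start", "end", "strand", "symbol"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"GeneAnnotation missing columns: {missing}")
        if len(df):
            if (df["start"] > df["end"]).any():
                raise ValueError("gene start > end")
            if df["symbol"].duplicated().any():
                dupes = df.loc[df["symbol"].duplicated(), "symbol"].unique()
                raise ValueError(f"duplicate gene symbols: {list(dupes)[:5]}")

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# Bismark coverage format
# ---------------------------------------------------------------------------

_COVERAGE_COLS = ["chrom", "start", "end", "meth_pct", "count_meth", "count_unmeth"]


def read_bismark_coverage(path: str | Path, sample_id: str) -> CpGCountTable:
    """Read a Bismark coverage file (chrom, start, end, meth%, #meth, #unmeth).

    The start column is taken as the CpG position (1-based). Records with
    zero total reads are dropped with a logged count; malformed lines raise
    with the offending line number.
    """
    path = Path(path)
    chroms: list[str] = []
    pos: list[int] = []
    n_meth: list[int] = []
    n_total: list[int] = []
    n_zero = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ValueError(
                    f"{path}:{lineno}: expected 6 tab-separated fields, got {len(parts)}"
                )
            try:
                p = int(parts[1])
                cm = int(parts[4])
                cu = int(parts[5])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer field ({exc})") from exc
            if cm < 0 or cu < 0:
                raise ValueError(f"{path}:{lineno}: negative read count")
            if p < 1:
                raise ValueError(f"{path}:{lineno}: position {p} < 1")
            total = cm + cu
            if total == 0:
                n_zero += 1
                continue
            chroms.append(parts[0])
            pos.append(p)
            n_meth.append(cm)
            n_total.append(total)
    if n_zero:
        logger.warning("%s: dropped %d zero-coverage records", path, n_zero)
    if not chroms:
        logger.warning("%s: no usable records (empty coverage file)", path)
    records = pd.DataFrame(
        {
            "chrom": pd.Series(chroms, dtype=str),
            "pos": pd.Series(pos, dtype=np.int64),
            "n_meth": pd.Series(n_meth, dtype=np.int64),
            "n_total": pd.Series(n_total, dtype=np.int64),
        }
    )
    return CpGCountTable(sample_id=sample_id, records=records)


def write_bismark_coverage(table: CpGCountTable, path: str | Path) -> None:
    """Write a CpGCountTable back out in 6-column Bismark coverage format."""
    df = table.records
    with open(path, "w") as fh:
        for chrom, pos, nm, nt in zip(df["chrom"], df["pos"], df["n_meth"], df["n_total"]):
            pct = 100.0 * nm / nt
            fh.write(f"{chrom}\t{pos}\t{pos}\t{pct:g}\t{nm}\t{nt - nm}\n")


# ---------------------------------------------------------------------------
# Array dataset (beta matrix + detection p matrix + probe annotation)
# ---------------------------------------------------------------------------


def read_array_dataset(
    beta_path: str | Path, detp_path: str | Path, annot_path: str | Path
) -> ArrayDataset:
    """Read an array-style dataset from three TSVs.

    Beta and detection-p matrices are probe x sample with a probe-id index
    column; the annotation TSV has columns probe, chrom, pos, gene. Probes
    missing from the annotation are retained with an empty gene symbol.
    """
    beta = pd.read_csv(beta_path, sep="\t", index_col=0)
    detp = pd.read_csv(detp_path, sep="\t", index_col=0)
    if set(beta.columns) != set(detp.columns):
        only_b = sorted(set(beta.columns) - set(detp.columns))
        only_d = sorted(set(detp.columns) - set(beta.columns))
        raise ValueError(
            "sample sets differ between beta and detection-p matrices: "
            f"only in beta {only_b}, only in detection-p {only_d}"
        )
    detp = detp.loc[beta.index, beta.columns]
    annot = pd.read_csv(
        annot_path, sep="\t", dtype={"probe": str, "chrom": str, "gene": str}
    ).set_index("probe")
    annot["gene"] = annot["gene"].fillna("")
    full = annot.reindex(beta.index)
    full["gene"] = full["gene"].fillna("")
    full["chrom"] = full["chrom"].fillna("")
    return ArrayDataset(beta=beta, detection_p=detp, probe_annotation=full)


# ---------------------------------------------------------------------------
# Gene annotation (BED6)
# ---------------------------------------------------------------------------


def read_gene_annotation_bed(path: str | Path) -> GeneAnnotation:
    """Read BED6 gene annotation (0-based half-open on disk -> 1-based inclusive)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start0", "end0", "symbol", "score", "strand"],
        dtype={"chrom": str, "symbol": str, "strand": str},
    )
    genes = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start0"] + 1,
            "end": df["end0"],
            "strand": df["strand"],
            "symbol": df["symbol"],
        }
    )
    return GeneAnnotation(genes=genes)


def write_gene_annotation_bed(annotation: GeneAnnotation, path: str | Path) -> None:
    df = annotation.genes
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\t{row.symbol}\t0\t{row.strand}\n")


# ---------------------------------------------------------------------------
# Ortholog candidate tables
# ---------------------------------------------------------------------------


def read_ortholog_candidates(path: str | Path) -> pd.DataFrame:
    """Read an ortholog candidate TSV: mouse_gene, human_gene, confidence, homology_pct."""
    df = pd.read_csv(path, sep="\t", dtype={"mouse_gene": str, "human_gene": str, "confidence": str})
    required = ["mouse_gene", "human_gene", "confidence", "homology_pct"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"ortholog table missing columns: {missing}")
    bad_conf = set(df["confidence"]) - {"high", "low"}
    if bad_conf:
        raise ValueError(f"confidence must be 'high' or 'low', got {sorted(bad_conf)}")
    if ((df["homology_pct"] < 0) | (df["homology_pct"] > 100)).any():
        raise ValueError("homology_pct outside [0, 100]")
    if df.duplicated().any():
        df = df.drop_duplicates().reset_index(drop=True)
    return df


def write_ortholog_candidates(candidates: pd.DataFrame, path: str | Path) -> None:
    candidates.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Signed BedGraph
# ---------------------------------------------------------------------------


def write_signed_bedgraph(
    dm,
    group_mean_beta: pd.Series,
    path: str | Path,
    track_name: str = "methylation",
) -> None:
    """Write a BedGraph where value sign encodes per-CpG significance.

    Significant loci get +beta (in [0, 1]); nonsignificant loci get -beta,
    so a genome browser shows calls above the axis and the rest, in a
    second colour, below it. A nonsignificant beta of exactly 0 is emitted
    as the literal ``-0`` to preserve the flag. Internal 1-based positions
    become 0-based half-open intervals per the BedGraph standard.

    ``dm`` is a :class:`~crossmeth.dm_cpg.DMResult` (or any object with a
    ``table`` frame carrying a ``significant`` column indexed by (chrom, pos)).
    """
    table = dm.table if hasattr(dm, "table") else dm
    sig = table["significant"]
    beta = group_mean_beta.reindex(sig.index)
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track_name}"\n')
        for (chrom, pos), is_sig in sig.items():
            b = beta.loc[(chrom, pos)]
            if np.isnan(b):
                continue
            value = f"{b:.6f}" if is_sig else f"-{b:.6f}"
            fh.write(f"{chrom}\t{pos - 1}\t{pos}\t{value}\n")


# ---------------------------------------------------------------------------
# DMR report table
# ---------------------------------------------------------------------------

DMR_TABLE_COLUMNS = [
    "gene(s)",
    "type",
    "chrom",
    "start",
    "end",
    "width",
    "n_cpgs",
    "median_p",
    "fdr",
    "control_median",
    "tumour_median",
    "median_difference",
]


def write_dmr_table(regions: Sequence, path: str | Path) -> None:
    """Write Table-style DMR summaries as TSV; width = end - start + 1."""
    rows = []
    for r in regions:
        rows.append(
            {
                "gene(s)": r.gene_symbols,
                "type": r.gene_context,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "width": r.end - r.start + 1,
                "n_cpgs": r.n_cpgs,
                "median_p": r.median_p,
                "fdr": r.fdr,
                "control_median": r.control_median,
                "tumour_median": r.tumour_median,
                "median_difference": r.median_difference,
            }
        )
    pd.DataFrame(rows, columns=DMR_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)
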