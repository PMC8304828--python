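"""Locus-to-gene mapping from a local gene annotation table.

Annotations are 1-based, fully-closed intervals (NCBI convention), one
row per gene symbol: ``symbol``, ``chrom``, ``start``, ``end``,
``strand``.  Strand is carried but ignored for overlap and distance;
candidate-gene mapping is positional.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

ANNOTATION_COLUMNS = ("symbol", "chrom", "start", "end", "strand")


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation missing columns: {missing}")
    if (ann["end"] < ann["start"]).any():
        bad = ann.index[ann["end"] < ann["start"]][0]
        raise ValueError(f"annotation row {bad}: end < start")
    if ann["symbol"].duplicated().any():
        dup = ann.loc[ann["symbol"].duplicated(), "symbol"].iloc[0]
        raise ValueError(f"duplicate gene symbol: {dup}")
    return ann


def genes_in_region(
    ann: pd.DataFrame, chrom: str, start: int, end: int
) -> pd.DataFrame:
    """Genes whose interval overlaps ``[start, end]`` by at least 1 bp.

    Both the query and annotation are 1-based inclusive.  An unknown
    chromosome yields an empty frame, not an error, so sparse
    annotations can be queried locus by locus.  Result sorted by gene
    start.
    """
    if end < start:
        raise ValueError(f"query end {end} < start {start}")
    validate_annotation(ann)
    sub = ann[ann["chrom"].astype(str) == str(chrom)]
    hit = sub[(sub["start"] <= end) & (sub["end"] >= start)]
    return hit.sort_values(["start", "symbol"], kind="mergesort").reset_index(drop=True)


def nearest_genes(ann: pd.DataFrame, chrom: str, pos: int, k: int = 1) -> pd.DataFrame:
    """The ``k`` genes nearest to ``pos`` on ``chrom``, closest first.

    Distance is 0 inside a gene and otherwise the bp gap to the nearer
    boundary; ties break alphabetically by symbol.  Returns at most the
    number of genes annotated on the chromosome, with a ``distance``
    column added.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    validate_annotation(ann)
    sub = ann[ann["chrom"].astype(str) == str(chrom)].copy()
    if sub.empty:
        return sub.assign(distance=pd.Series(dtype=int)).reset_index(drop=True)
    start = sub["start"].to_numpy(dtype=np.int64)
    end = sub["end"].to_numpy(dtype=np.int64)
    dist = np.maximum.reduce([start - pos, pos - end, np.zeros_like(start)])
    sub["distance"] = dist
    sub = sub.sort_values(["distance", "symbol"], kind="mergesort")
    return sub.head(k).reset_index(drop=True)


def genes_for_loci(ann: pd.DataFrame, loci) -> dict[str, pd.DataFrame]:
    """Map each locus (keyed ``chrom:start-end``) to its overlapping genes.

    Locus windows are half-open ``[start, end)``; the inclusive query
    therefore runs to ``end - 1``.
    """
    out: dict[str, pd.DataFrame] = {}
    for locus in loci:
        key = f"{locus.chrom}:{locus.start}-{locus.end}"
        out[key] = genes_in_region(ann, locus.chrom, locus.start, locus.end - 1)
    return out


def read_bed4(path) -> pd.DataFrame:
    """Read a BED4 file (0-based half-open) into the 1-based annotation frame."""
    bed = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "symbol"], usecols=range(4),
    )
    return pd.DataFrame(
        {
            "symbol": bed["symbol"].astype(str),
            "chrom": bed["chrom"].astype(str),
            "start": bed["start"].astype(np.int64) + 1,
            "end": bed["end"].astype(np.int64),
            "strand": "unknown",
        }
    )
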