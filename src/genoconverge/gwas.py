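"""Window-based composite scoring of GWAS summary statistics.

Association tables carry one row per SNP (``snp_id``, ``chrom``, ``pos``,
``p``) with 1-based positions.  The chromosome is tiled with fixed,
non-overlapping windows anchored at bp 1; each window is scored by a
composite that combines the strength of its best association with the
number of nominally significant SNPs it contains.  Windows clearing a
score threshold are merged into loci.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SNP_COLUMNS = ("snp_id", "chrom", "pos", "p")


@dataclass(frozen=True)
class WindowScore:
    """One scored tiling window, half-open on ``[start, end)``."""

    chrom: str
    start: int
    end: int
    n_snps: int
    n_sig: int
    min_p: float
    top_snp: str
    top_pos: int
    score: float


@dataclass(frozen=True)
class Locus:
    """A merged run of high-scoring windows on one chromosome."""

    chrom: str
    start: int
    end: int
    windows: tuple[WindowScore, ...]
    best_window: WindowScore = field(repr=False, default=None)  # type: ignore[assignment]
    index_snp: str = ""
    index_p: float = math.nan

    @property
    def score(self) -> float:
        return self.best_window.score


def validate_assocs(assocs: pd.DataFrame) -> pd.DataFrame:
    """Check required columns, positions and p-value ranges.

    Raises ``ValueError`` naming the first offending row when a p-value
    falls outside ``(0, 1]`` or a position is below 1.
    """
    missing = [c for c in SNP_COLUMNS if c not in assocs.columns]
    if missing:
        raise ValueError(f"association table missing columns: {missing}")
    p = assocs["p"].to_numpy(dtype=float)
    bad = np.flatnonzero(~((p > 0.0) & (p <= 1.0)))
    if bad.size:
        i = int(bad[0])
        raise ValueError(f"p-value out of (0, 1] at row {i}: p={p[i]!r}")
    pos = assocs["pos"].to_numpy()
    bad = np.flatnonzero(pos < 1)
    if bad.size:
        i = int(bad[0])
        raise ValueError(f"position < 1 at row {i}: pos={pos[i]!r}")
    return assocs


def composite_score(n_sig: int, min_p: float, weight: float = 1.0) -> float:
    """Composite window score: -log10(min_p) + weight * n_sig.

    Zero when the window holds no nominally significant SNP, so empty
    and null windows never outrank a genuine association cluster.  The
    score grows both with the best single-SNP association and with the
    number of co-significant (LD-clustered) SNPs around it.
    """
    if n_sig == 0:
        return 0.0
    return float(-math.log10(min_p) + weight * n_sig)


def scan_windows(
    assocs: pd.DataFrame,
    window_bp: int = 20_000,
    alpha: float = 0.05,
    weight: float = 1.0,
) -> list[WindowScore]:
    """Tile each chromosome with ``window_bp`` windows and score them.

    Windows are anchored at bp 1 (the k-th window is
    ``[1 + k*window_bp, 1 + (k+1)*window_bp)``), so every SNP belongs to
    exactly one window.  Windows containing no SNPs are omitted.  The
    result is independent of the input row order; the top SNP of a
    window is the one with the smallest p, ties broken by lower
    position, then ``snp_id``.
    """
    if len(assocs) == 0:
        raise ValueError("association table is empty")
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    validate_assocs(assocs)

    df = assocs.copy()
    df["_win"] = (df["pos"].to_numpy(dtype=np.int64) - 1) // int(window_bp)
    # canonical order makes the scan independent of input row order
    df = df.sort_values(["chrom", "_win", "p", "pos", "snp_id"], kind="mergesort")

    out: list[WindowScore] = []
    for (chrom, win), grp in df.groupby(["chrom", "_win"], sort=True):
        start = int(win) * window_bp + 1
        top = grp.iloc[0]
        n_sig = int((grp["p"].to_numpy() < alpha).sum())
        out.append(
            WindowScore(
                chrom=str(chrom),
                start=start,
                end=start + window_bp,
                n_snps=len(grp),
                n_sig=n_sig,
                min_p=float(top["p"]),
                top_snp=str(top["snp_id"]),
                top_pos=int(top["pos"]),
                score=composite_score(n_sig, float(top["p"]), weight),
            )
        )
    out.sort(key=lambda w: (w.chrom, w.start))
    return out


def merge_loci(
    windows: list[WindowScore],
    score_threshold: float,
    max_gap_bp: int | None = None,
) -> list[Locus]:
    """Merge windows with ``score >= score_threshold`` into loci.

    Flagged windows on the same chromosome merge when the gap between
    them (end of one to start of the next) is at most ``max_gap_bp``;
    the default gap is one window width.  Each locus reports its best
    window (highest score) and an index SNP: the top SNP of the member
    window with the globally smallest p.
    """
    flagged = sorted(
        (w for w in windows if w.score >= score_threshold),
        key=lambda w: (w.chrom, w.start),
    )
    if not flagged:
        return []
    if max_gap_bp is None:
        max_gap_bp = flagged[0].end - flagged[0].start

    loci: list[Locus] = []
    run: list[WindowScore] = [flagged[0]]
    for w in flagged[1:]:
        prev = run[-1]
        if w.chrom == prev.chrom and (w.start - prev.end) <= max_gap_bp:
            run.append(w)
        else:
            loci.append(_finish_locus(run))
            run = [w]
    loci.append(_finish_locus(run))
    return loci


def _finish_locus(run: list[WindowScore]) -> Locus:
    best = max(run, key=lambda w: w.score)
    idx = min(run, key=lambda w: (w.min_p, w.start))
    return Locus(
        chrom=run[0].chrom,
        start=run[0].start,
        end=run[-1].end,
        windows=tuple(run),
        best_window=best,
        index_snp=idx.top_snp,
        index_p=idx.min_p,
    )


def export_top_snps(windows: list[WindowScore]) -> pd.DataFrame:
    """One row per window: its most significant SNP, sorted by position.

    The output (``snp_id``, ``chrom``, ``pos``, ``p``) mirrors the
    reduced tables fed to locus-plotting tools when full summary
    statistics are too dense to draw.
    """
    if not windows:
        raise ValueError("no windows to export")
    rows = [
        {"snp_id": w.top_snp, "chrom": w.chrom, "pos": w.top_pos, "p": w.min_p}
        for w in sorted(windows, key=lambda w: (w.chrom, w.start))
    ]
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "p"])


def windows_frame(windows: list[WindowScore]) -> pd.DataFrame:
    """Tabular view of scored windows for TSV export."""
    return pd.DataFrame(
        [
            {
                "chrom": w.chrom,
                "start": w.start,
                "end": w.end,
                "n_snps": w.n_snps,
                "n_sig": w.n_sig,
                "min_p": w.min_p,
                "top_snp": w.top_snp,
                "score": w.score,
            }
            for w in windows
        ],
        columns=["chrom", "start", "end", "n_snps", "n_sig", "min_p", "top_snp", "score"],
    )


def loci_frame(loci: list[Locus]) -> pd.DataFrame:
    """Tabular view of merged loci for TSV export."""
    return pd.DataFrame(
        [
            {
                "chrom": l.chrom,
                "start": l.start,
                "end": l.end,
                "n_windows": len(l.windows),
                "best_score": l.score,
                "index_snp": l.index_snp,
                "index_p": l.index_p,
            }
            for l in loci
        ],
        columns=["chrom", "start", "end", "n_windows", "best_score", "index_snp", "index_p"],
    )
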