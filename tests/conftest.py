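"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library code paths they check:
Welch's t is written out from its textbook formula, BH step-up is a
literal sort-and-scan, U and AUC are O(n^2) pair counts, window
statistics are per-SNP scans, locus merging is an interval union, and
graph distance comes from networkx BFS.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats


@pytest.fixture
def rng():
    return np.random.default_rng(20210716)


# ---------------------------------------------------------------- oracles


def welch_oracle(x, y):
    """Textbook Welch unequal-variance t-test (two-sided)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx_, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx_ + vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx_) ** 2 / (nx_ - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, p


def bh_oracle(pvals, alpha=0.05):
    """Benjamini-Hochberg step-up by literal sort-and-scan."""
    pvals = np.asarray(pvals, float)
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if pvals[idx] <= rank * alpha / m:
            k_max = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_max]] = True
    return reject


def u_oracle(x, y):
    """Mann-Whitney U for x: count of (x > y) pairs, ties at 1/2."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    gt = (x[:, None] > y[None, :]).sum()
    ties = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(ties)


def auc_oracle(values, labels):
    """ROC AUC as the normalized correct-ordering pair count."""
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    case, ctrl = values[labels == 1], values[labels == 0]
    return u_oracle(case, ctrl) / (len(case) * len(ctrl))


def window_stats_oracle(assocs: pd.DataFrame, window_bp: int, alpha: float):
    """Per-window (n_snps, n_sig, min_p, top_snp) by scanning every SNP."""
    out = {}
    for row in assocs.itertuples(index=False):
        key = (str(row.chrom), (int(row.pos) - 1) // window_bp)
        out.setdefault(key, []).append(row)
    stats_ = {}
    for key, rows in out.items():
        best = min(rows, key=lambda r: (r.p, r.pos, r.snp_id))
        stats_[key] = {
            "n_snps": len(rows),
            "n_sig": sum(r.p < alpha for r in rows),
            "min_p": float(best.p),
            "top_snp": str(best.snp_id),
        }
    return stats_


def merge_oracle(intervals, max_gap):
    """Union of [start, end) intervals allowing gaps up to max_gap.

    ``intervals`` is a list of (chrom, start, end); returns merged
    (chrom, start, end) triples sorted by position.
    """
    merged = []
    for chrom, start, end in sorted(intervals):
        if merged and merged[-1][0] == chrom and start - merged[-1][2] <= max_gap:
            prev = merged[-1]
            merged[-1] = (chrom, prev[1], max(prev[2], end))
        else:
            merged.append((chrom, start, end))
    return merged


def bfs_distance_oracle(graph: nx.Graph, a, b):
    lengths = nx.single_source_shortest_path_length(graph, a)
    return lengths.get(b)
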