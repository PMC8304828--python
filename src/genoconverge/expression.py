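"""Differential-expression convergence across independent datasets.

Each dataset is a probe x sample matrix with case/control labels and a
probe-to-gene map.  Probes are tested individually (Welch two-sided t);
a gene converges when it is significant in at least ``min_datasets``
datasets, every one of its probes in those datasets agrees on the
direction of change, and the gene belongs to the reference list coming
from the association loci.  Convergent genes then face
Benjamini-Hochberg and Bonferroni gates on a gene-level summary p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class ExpressionDataset:
    """Probe x sample expression matrix with labels and probe map."""

    dataset_id: str
    values: pd.DataFrame            # probes as rows, samples as columns
    groups: pd.Series               # sample -> {"case", "control"}
    probe_gene: pd.Series           # probe -> gene symbol

    def __post_init__(self) -> None:
        unmapped = self.values.index.difference(self.probe_gene.index)
        if len(unmapped):
            raise ValueError(
                f"{self.dataset_id}: probes without gene mapping: "
                f"{list(unmapped[:5])}"
            )
        counts = self.groups.value_counts()
        for grp in ("case", "control"):
            if counts.get(grp, 0) < 2:
                raise ValueError(f"{self.dataset_id}: fewer than 2 '{grp}' samples")


@dataclass(frozen=True)
class ProbeTestResult:
    dataset_id: str
    probe: str
    gene: str
    t: float
    p: float
    direction: int  # sign(mean_case - mean_control)


@dataclass(frozen=True)
class ConvergenceCall:
    gene: str
    n_datasets_significant: int
    datasets_significant: tuple[str, ...]
    aligned: bool
    called: bool
    gene_p: float
    fdr_pass: bool = False
    bonferroni_pass: bool = False


def probe_tests(ds: ExpressionDataset, alpha: float = 0.05) -> list[ProbeTestResult]:
    """Welch unequal-variance two-sided t-test for every probe.

    Direction is the sign of (case mean - control mean).  A probe with
    zero variance in both groups and equal means is reported as t=0,
    p=1 rather than NaN.  Missing values are an error naming the probe:
    imputation policy belongs upstream of testing.
    """
    case_cols = ds.groups.index[ds.groups == "case"]
    ctrl_cols = ds.groups.index[ds.groups == "control"]
    x = ds.values[case_cols].to_numpy(dtype=float)
    y = ds.values[ctrl_cols].to_numpy(dtype=float)
    nan_rows = np.flatnonzero(np.isnan(x).any(axis=1) | np.isnan(y).any(axis=1))
    if nan_rows.size:
        probe = ds.values.index[nan_rows[0]]
        raise ValueError(f"{ds.dataset_id}: missing values in probe {probe!r}")

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # constant probes trigger a precision warning; handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(x, y, axis=1, equal_var=False)
    diff = x.mean(axis=1) - y.mean(axis=1)
    # degenerate probes: both groups constant and equal -> no evidence
    degenerate = ~np.isfinite(t)
    t = np.where(degenerate & (diff == 0), 0.0, t)
    p = np.where(degenerate & (diff == 0), 1.0, p)

    results = []
    for i, probe in enumerate(ds.values.index):
        results.append(
            ProbeTestResult(
                dataset_id=ds.dataset_id,
                probe=str(probe),
                gene=str(ds.probe_gene.loc[probe]),
                t=float(t[i]),
                p=float(p[i]),
                direction=int(np.sign(diff[i])),
            )
        )
    return results


def converge(
    results: dict[str, list[ProbeTestResult]],
    reference_genes,
    min_datasets: int = 2,
    alpha: float = 0.05,
) -> list[ConvergenceCall]:
    """Gene-level convergence with directional alignment.

    A gene is significant in a dataset when at least one of its probes
    has p < alpha there.  It is *called* when significant in at least
    ``min_datasets`` datasets, all of its probes in those significant
    datasets share one direction (direction-0 probes are neutral), and
    it appears in ``reference_genes`` — the intersection with the
    association loci is the convergence step itself.  The gene-level
    summary p is the minimum probe p over the significant datasets.
    """
    if len(results) < 2:
        raise ValueError("convergence needs at least 2 datasets")
    reference = set(map(str, reference_genes))
    if not reference:
        raise ValueError("reference gene list is empty")

    by_gene: dict[str, dict[str, list[ProbeTestResult]]] = {}
    for ds_id, res in results.items():
        for r in res:
            by_gene.setdefault(r.gene, {}).setdefault(ds_id, []).append(r)

    calls = []
    for gene in sorted(by_gene):
        per_ds = by_gene[gene]
        sig_ds = tuple(
            sorted(ds for ds, rs in per_ds.items() if any(r.p < alpha for r in rs))
        )
        sig_probes = [r for ds in sig_ds for r in per_ds[ds]]
        dirs = {r.direction for r in sig_probes} - {0}
        aligned = len(dirs) <= 1 and len(sig_ds) > 0
        gene_p = min((r.p for r in sig_probes), default=float("nan"))
        called = (
            len(sig_ds) >= min_datasets and aligned and gene in reference
        )
        calls.append(
            ConvergenceCall(
                gene=gene,
                n_datasets_significant=len(sig_ds),
                datasets_significant=sig_ds,
                aligned=aligned,
                called=called,
                gene_p=gene_p,
            )
        )
    return calls


def adjust(calls: list[ConvergenceCall], alpha: float = 0.05) -> list[ConvergenceCall]:
    """Set FDR (Benjamini-Hochberg step-up) and Bonferroni flags.

    Both corrections run over the called genes' summary p-values only;
    genes that failed convergence keep both flags false.  Bonferroni
    passing implies FDR passing.
    """
    called = [c for c in calls if c.called]
    if called:
        pvals = np.array([c.gene_p for c in called])
        fdr = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
        bonf = multipletests(pvals, alpha=alpha, method="bonferroni")[0]
        flags = {
            c.gene: (bool(f), bool(b)) for c, f, b in zip(called, fdr, bonf)
        }
    else:
        flags = {}
    return [
        replace(c, fdr_pass=flags.get(c.gene, (False, False))[0],
                bonferroni_pass=flags.get(c.gene, (False, False))[1])
        for c in calls
    ]


def probe_results_frame(results: list[ProbeTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"dataset_id": r.dataset_id, "probe": r.probe, "gene": r.gene,
             "t": r.t, "p": r.p, "direction": r.direction}
            for r in results
        ],
        columns=["dataset_id", "probe", "gene", "t", "p", "direction"],
    )


def calls_frame(calls: list[ConvergenceCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": c.gene,
                "n_datasets_significant": c.n_datasets_significant,
                "datasets_significant": ",".join(c.datasets_significant),
                "aligned": c.aligned,
                "called": c.called,
                "gene_p": c.gene_p,
                "fdr_pass": c.fdr_pass,
                "bonferroni_pass": c.bonferroni_pass,
            }
            for c in calls
        ],
        columns=["gene", "n_datasets_significant", "datasets_significant",
                 "aligned", "called", "gene_p", "fdr_pass", "bonferroni_pass"],
    )
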