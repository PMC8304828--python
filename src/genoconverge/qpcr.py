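"""qPCR relative quantification and validation statistics.

Implements the 2^-ddCt method: technical replicates are averaged per
(sample, gene); each sample's target Ct is normalized against the
arithmetic mean of its housekeeping-gene Ct values (equivalent to the
geometric average of housekeeping expression, since Ct is a log2
scale); dCt is referenced to the control-group mean so control
relative expression has geometric mean 1.  Group comparison reports
both a Welch t-test on log2 values and a Mann-Whitney rank-sum test.
Discrimination is summarised by the ROC AUC with the Hanley-McNeil
standard error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ("sample", "group", "gene", "replicate", "ct")


@dataclass(frozen=True)
class RocResult:
    auc: float
    se: float
    ci_low: float
    ci_high: float
    p_vs_half: float


def relative_expression(
    ct: pd.DataFrame,
    target: str,
    housekeeping,
    reference_group: str = "control",
) -> pd.DataFrame:
    """Per-sample 2^-ddCt relative expression of ``target``.

    Returns a frame (``sample``, ``group``, ``gene``, ``value``) where
    ``value`` is fold expression relative to the reference-group
    average; the reference group has geometric mean exactly 1 by
    construction.  Raises if a sample lacks any housekeeping gene or a
    target measurement.
    """
    housekeeping = list(housekeeping)
    if not housekeeping:
        raise ValueError("housekeeping gene list is empty")
    missing = [c for c in CT_COLUMNS if c not in ct.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if (ct["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")

    mean_ct = ct.groupby(["sample", "group", "gene"], sort=True)["ct"].mean()
    mean_ct = mean_ct.reset_index()
    wide = mean_ct.pivot(index=["sample", "group"], columns="gene", values="ct")

    for hk in housekeeping:
        if hk not in wide.columns or wide[hk].isna().any():
            bad = (
                wide.index[wide[hk].isna()][0][0]
                if hk in wide.columns
                else wide.index[0][0]
            )
            raise ValueError(f"sample {bad!r} missing housekeeping gene {hk!r}")
    if target not in wide.columns or wide[target].isna().any():
        raise ValueError(f"missing target {target!r} measurements")

    # arithmetic mean of Ct == geometric average on the expression scale
    hk_ct = wide[housekeeping].mean(axis=1)
    dct = wide[target] - hk_ct
    ref = dct.xs(reference_group, level="group")
    if ref.empty:
        raise ValueError(f"no samples in reference group {reference_group!r}")
    ddct = dct - ref.mean()
    out = ddct.reset_index()
    out.columns = ["sample", "group", "ddct"]
    out["gene"] = target
    out["value"] = np.power(2.0, -out["ddct"])
    return out[["sample", "group", "gene", "value"]]


def compare_groups(values: pd.DataFrame, log_transform: bool = True) -> dict:
    """Two-group comparison of relative expression values.

    Reports a Welch two-sided t-test (on log2 values by default, since
    fold changes are log-normal-ish) and the Mann-Whitney U statistic
    with its two-sided p.  ``u`` counts (case > control) pairs with
    ties at half weight.
    """
    case = values.loc[values["group"] == "case", "value"].to_numpy(dtype=float)
    ctrl = values.loc[values["group"] == "control", "value"].to_numpy(dtype=float)
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError("need >= 2 samples per group")
    if log_transform:
        if (case <= 0).any() or (ctrl <= 0).any():
            raise ValueError("nonpositive value under log transform")
        x, y = np.log2(case), np.log2(ctrl)
    else:
        x, y = case, ctrl
    t, p_t = stats.ttest_ind(x, y, equal_var=False)
    u, p_u = stats.mannwhitneyu(x, y, alternative="two-sided")
    return {"t": float(t), "p_t": float(p_t), "u": float(u), "p_u": float(p_u)}


def roc_auc(values: np.ndarray, labels: np.ndarray) -> RocResult:
    """Rank-based ROC AUC with Hanley-McNeil standard error.

    AUC is the probability that a random case outranks a random
    control (ties count 1/2), i.e. U / (n1 * n2).  The 95% CI is the
    normal approximation AUC +/- 1.96 * SE truncated to [0, 1];
    ``p_vs_half`` tests AUC = 0.5 with the same normal approximation.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    case = values[labels == 1]
    ctrl = values[labels == 0]
    n1, n2 = len(case), len(ctrl)
    if n1 == 0 or n2 == 0:
        raise ValueError("both classes must be present")

    u = stats.mannwhitneyu(case, ctrl, alternative="two-sided").statistic
    auc = float(u) / (n1 * n2)

    # Hanley & McNeil (1982) variance under the exponential approximation
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n2 - 1) * (q2 - auc**2)) / (
        n1 * n2
    )
    se = math.sqrt(max(var, 0.0))
    if se > 0:
        zstat = (auc - 0.5) / se
        p = float(stats.norm.sf(abs(zstat)) * 2.0)
    else:
        p = 0.0 if auc != 0.5 else 1.0
    return RocResult(
        auc=auc,
        se=se,
        ci_low=max(0.0, auc - 1.96 * se),
        ci_high=min(1.0, auc + 1.96 * se),
        p_vs_half=p,
    )


def pp_points(values: np.ndarray) -> pd.DataFrame:
    """Normal P-P plot coordinates for a sample.

    Values are standardized; the empirical cumulative probability uses
    plotting positions (i - 0.5) / n against the standard-normal CDF of
    the sorted standardized values.  Both coordinates are in (0, 1) and
    monotone, ready for plotting as TSV.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 1:
        raise ValueError("need at least one value")
    sd = values.std(ddof=1) if n > 1 else 0.0
    if n > 1 and sd == 0:
        raise ValueError("zero variance sample")
    z = np.zeros(n) if n == 1 else (np.sort(values) - values.mean()) / sd
    theoretical = stats.norm.cdf(z)
    empirical = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame({"theoretical": theoretical, "empirical": empirical})
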