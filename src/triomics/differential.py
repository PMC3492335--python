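"""Differentially methylated / expressed genes versus controls.

Methylation is tested on M-values, M = log2(beta / (1 - beta)) (with beta
clamped away from 0 and 1), expression on the vst-like scale. Per probe, a
two-sample t-test (pooled variance by default; Welch optional) compares
cases against controls; Benjamini-Hochberg-adjusted p < alpha combined
with an absolute mean-difference cut (6 on the M scale, 0.5 on the vst
scale) defines a pass. Probes collapse to genes by inclusion: a gene
passes if any of its probes passes.

These are plain t-tests, not moderated (empirical-Bayes) ones; with very
small control groups the per-probe variance is unstable, which the pooled
default and an optional variance floor mitigate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, MissingControlError
from .types import OmicsMatrix
from .dependency import adjust

#: Default absolute mean-difference cuts per platform scale.
FC_CUT_METH = 6.0
FC_CUT_EXPR = 0.5


def beta_to_m(beta: pd.DataFrame, epsilon: float = 1e-6) -> pd.DataFrame:
    """M-value transform, strictly increasing in beta, finite via clamping."""
    if not 0 < epsilon < 0.5:
        raise ConfigurationError("epsilon must be in (0, 0.5)")
    clamped = beta.clip(lower=epsilon, upper=1 - epsilon)
    return np.log2(clamped / (1 - clamped))


def two_group_ttest(
    case: pd.DataFrame,
    control: pd.DataFrame,
    equal_var: bool = True,
    min_variance: float = 0.0,
) -> pd.DataFrame:
    """Per-row two-sample t-test; returns mean_diff, t, p, zero_variance.

    Rows with zero variance in both groups are flagged and assigned
    t = 0, p = 1. ``min_variance`` floors each group's variance to guard
    degenerate probes when the control group is tiny.
    """
    if case.shape[1] < 2 or control.shape[1] < 2:
        raise ConfigurationError("each group needs >= 2 columns")
    x = case.to_numpy(dtype=float)
    y = control.reindex(case.index).to_numpy(dtype=float)
    mean_diff = x.mean(axis=1) - y.mean(axis=1)
    zero_var = (x.var(axis=1) == 0) & (y.var(axis=1) == 0)
    if min_variance > 0:
        # floor by inflating rows whose pooled spread is below the floor
        def _floor(arr):
            sd = arr.std(axis=1, ddof=1, keepdims=True)
            scale = np.maximum(np.sqrt(min_variance) / np.where(sd > 0, sd, np.inf), 1.0)
            centered = arr - arr.mean(axis=1, keepdims=True)
            return arr.mean(axis=1, keepdims=True) + centered * scale
        x = _floor(x)
        y = _floor(y)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(x, y, axis=1, equal_var=equal_var)
    t = np.where(zero_var, 0.0, t)
    p = np.where(zero_var | ~np.isfinite(p), 1.0, p)
    return pd.DataFrame(
        dict(mean_diff=mean_diff, t=t, p=p, zero_variance=zero_var),
        index=case.index,
    )


def differential_analysis(
    matrix: OmicsMatrix,
    alpha: float = 0.05,
    fc_cut: float | None = None,
    equal_var: bool = True,
    min_variance: float = 0.0,
    probe_map: pd.Series | None = None,
) -> dict:
    """Full differential stage for one platform.

    Beta matrices are transformed to M-values first and tested with the
    methylation cut (|dM| > 6); vst matrices use the expression cut
    (|d vst| > 0.5). Returns per-probe results and, when a probe map is
    given, a gene table collapsed by the inclusion rule.
    """
    if not matrix.controls:
        raise MissingControlError("differential analysis requires controls")
    values = matrix.values
    if matrix.role == "beta":
        values = beta_to_m(values)
        if fc_cut is None:
            fc_cut = FC_CUT_METH
    elif matrix.role in ("vst", "mvalue"):
        if fc_cut is None:
            fc_cut = FC_CUT_EXPR
    else:
        raise ConfigurationError(
            f"differential analysis undefined for role {matrix.role!r}"
        )
    case = values[matrix.case_columns]
    ctrl = values[list(matrix.controls)]
    res = two_group_ttest(case, ctrl, equal_var=equal_var, min_variance=min_variance)
    res["p_adj"] = adjust(res["p"].to_numpy(), "bh")
    res["passed"] = (res["p_adj"] < alpha) & (res["mean_diff"].abs() > fc_cut)
    out = dict(probes=res, alpha=alpha, fc_cut=fc_cut)
    if probe_map is not None:
        mapped = res.index.isin(probe_map.index)
        sub = res.loc[mapped]
        genes = probe_map.reindex(sub.index)
        gene_table = sub.groupby(genes.to_numpy()).agg(
            n_probes=("passed", "size"),
            n_passed=("passed", "sum"),
            best_p_adj=("p_adj", "min"),
            max_abs_diff=("mean_diff", lambda s: float(s.abs().max())),
        )
        gene_table["passed"] = gene_table["n_passed"] > 0
        gene_table.index.name = "gene"
        out["genes"] = gene_table
    return out
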