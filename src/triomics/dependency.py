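"""Per-sample dependency statistics between aberration channels.

For each cell line, every cross-platform channel pair is cross-tabulated
over the shared gene universe into a 2x2 table; the odds ratio measures
the strength of association (OR > 1 positive, < 1 negative) and a Pearson
chi-square test (1 df, no continuity correction by default) measures
significance. p-values are corrected within each sample's family of
combinations (Benjamini-Hochberg by default, Bonferroni available).

The three-way analysis conditions on copy-number state: within each CN
stratum (gain / normal / loss), hyper-methylation is cross-tabulated
against each expression state (over / normal / under).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from statsmodels.stats.multitest import multipletests

from .errors import NotEstimableError, ValidationError
from .types import CHANNEL_PLATFORM, CallMatrix, ContingencyTable
from .integration import combo_label, enumerate_combos


def make_table(
    calls: CallMatrix, sample: str, channel_a: str, channel_b: str
) -> ContingencyTable:
    """Exact 2x2 cross-tabulation of two channels in one sample."""
    if CHANNEL_PLATFORM[channel_a] == CHANNEL_PLATFORM[channel_b]:
        raise ValidationError(
            f"channels {channel_a!r} and {channel_b!r} are from the same platform"
        )
    sj = calls.samples.get_loc(sample)
    a_vec = calls.values[:, sj, :][:, _channel_index(channel_a)]
    b_vec = calls.values[:, sj, :][:, _channel_index(channel_b)]
    return _cross_tab(a_vec, b_vec)


def _channel_index(name: str) -> int:
    from .types import CHANNELS

    return CHANNELS.index(name)


def _cross_tab(a_vec: np.ndarray, b_vec: np.ndarray) -> ContingencyTable:
    a = int(np.sum(a_vec & b_vec))
    b = int(np.sum(a_vec & ~b_vec))
    c = int(np.sum(~a_vec & b_vec))
    d = int(np.sum(~a_vec & ~b_vec))
    return ContingencyTable(a, b, c, d)


def odds_ratio(table: ContingencyTable, zero_cell_policy: str = "haldane") -> float:
    """(a*d)/(b*c), with the Haldane +1/2 correction when any cell is zero.

    With ``zero_cell_policy='none'`` a zero denominator yields ``inf``
    (or ``nan`` for 0/0); callers should flag such values.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if zero_cell_policy == "haldane":
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return (a * d) / (b * c)
    if zero_cell_policy == "none":
        num, den = a * d, b * c
        if den == 0:
            return float("nan") if num == 0 else float("inf")
        return num / den
    raise ValidationError(f"unknown zero_cell_policy {zero_cell_policy!r}")


def chi_square_p(
    table: ContingencyTable, correction: bool = False
) -> tuple[float, float, bool]:
    """Pearson chi-square (1 df) on a 2x2 table.

    Returns (statistic, p, degenerate). A degenerate margin (an all-zero
    row or column) makes the test undefined; it is reported as statistic
    0, p 1 with the flag set.
    """
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return 0.0, 1.0, True
    res = chi2_contingency(arr, correction=correction)
    return float(res.statistic), float(res.pvalue), False


def adjust(pvalues, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment: 'bh' step-up or 'bonferroni'."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValidationError("adjust: empty p-value list")
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("adjust: p-values must lie in [0, 1]")
    key = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValidationError(f"unknown correction method {method!r}")
    return multipletests(p, method=key)[1]


def pairwise_dependency(
    calls: CallMatrix,
    method: str = "bh",
    zero_cell_policy: str = "haldane",
    correction: bool = False,
) -> pd.DataFrame:
    """OR + corrected chi-square p for all 12 combos in every sample.

    The correction family is the 12 combinations within one sample,
    matching the per-sample presentation of the dependency heat maps.
    """
    two_way, _ = enumerate_combos()
    rows = []
    for sample in calls.samples:
        ps = []
        for ca, cb in two_way:
            t = make_table(calls, sample, ca, cb)
            or_ = odds_ratio(t, zero_cell_policy)
            stat, p, degen = chi_square_p(t, correction=correction)
            ps.append(p)
            rows.append(
                dict(
                    sample=sample, combo=combo_label((ca, cb)),
                    a=t.a, b=t.b, c=t.c, d=t.d,
                    odds_ratio=or_, chi2=stat, p=p, degenerate=degen,
                )
            )
        adj = adjust(ps, method)
        for i, r in enumerate(rows[-len(two_way):]):
            r["p_adj"] = float(adj[i])
            r["method"] = method
    return pd.DataFrame(rows)


def three_state_assignments(calls: CallMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per gene/sample CN and expression three-state labels.

    CN: +1 gain, 0 normal, -1 loss. Expression: +1 over, 0 normal,
    -1 under. Genes whose probes put them in both directions at once
    (CN conflict, or both over and under) cannot be placed in a single
    stratum; they are masked out (``valid`` False) and counted by the
    caller.
    """
    gain = calls.channel("gain")
    loss = calls.channel("loss")
    over = calls.channel("over")
    under = calls.channel("under")
    cn = gain.astype(np.int8) - loss.astype(np.int8)
    expr = over.astype(np.int8) - under.astype(np.int8)
    valid = ~((gain & loss) | (over & under))
    return cn, expr, valid


def conditional_dependency(
    calls: CallMatrix,
    method: str = "bh",
    zero_cell_policy: str = "haldane",
    correction: bool = False,
) -> pd.DataFrame:
    """Hyper-methylation vs expression state within each CN stratum.

    For every sample, genes are stratified by CN state; within a stratum
    each expression state is tested against hyper-methylation via a 2x2
    table (that state vs the rest of the stratum). Empty strata and
    degenerate margins are flagged not-estimable. The correction family
    is the strata x states tests within one sample.
    """
    cn, expr, valid = three_state_assignments(calls)
    hyper = calls.channel("hyper")
    strata = [("gain", 1), ("normal", 0), ("loss", -1)]
    states = [("over", 1), ("normal", 0), ("under", -1)]
    rows = []
    for sj, sample in enumerate(calls.samples):
        ps = []
        sample_rows = []
        v = valid[:, sj]
        n_excluded = int((~v).sum())
        for stratum_name, stratum_val in strata:
            in_stratum = v & (cn[:, sj] == stratum_val)
            n_stratum = int(in_stratum.sum())
            for state_name, state_val in states:
                if n_stratum == 0:
                    rows_entry = dict(
                        sample=sample, stratum=stratum_name, expr_state=state_name,
                        a=0, b=0, c=0, d=0, n_stratum=0,
                        odds_ratio=np.nan, chi2=np.nan, p=1.0,
                        not_estimable=True, n_excluded=n_excluded,
                    )
                    ps.append(1.0)
                    sample_rows.append(rows_entry)
                    continue
                h = hyper[in_stratum, sj]
                e = expr[in_stratum, sj] == state_val
                t = _cross_tab(h, e)
                stat, p, degen = chi_square_p(t, correction=correction)
                or_ = odds_ratio(t, zero_cell_policy) if not degen else np.nan
                ps.append(p)
                sample_rows.append(
                    dict(
                        sample=sample, stratum=stratum_name, expr_state=state_name,
                        a=t.a, b=t.b, c=t.c, d=t.d, n_stratum=n_stratum,
                        odds_ratio=or_, chi2=stat, p=p,
                        not_estimable=degen, n_excluded=n_excluded,
                    )
                )
        adj = adjust(ps, method)
        for i, r in enumerate(sample_rows):
            r["p_adj"] = float(adj[i])
            r["method"] = method
        rows.extend(sample_rows)
    return pd.DataFrame(rows)
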