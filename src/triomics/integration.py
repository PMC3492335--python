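"""Multi-way combination enumeration, recurrence counting and selection.

With two aberration channels per platform (gain/loss, hyper/hypo,
over/under) there are exactly 12 cross-platform two-way combinations and
8 three-way combinations. Recurrently altered genes are those carrying an
expression-consistent pair (gain+over, hypo+over, loss+under, hyper+under)
in at least k of n samples (default 6 of 19, i.e. >30%); the union rule
additionally admits genes whose over-expression co-occurs with *either*
gain or hypo-methylation (and under-expression with either loss or
hyper-methylation) in a total of k or more samples.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd

from .errors import ValidationError
from .types import CallMatrix

_CN = ("gain", "loss")
_METH = ("hyper", "hypo")
_EXPR = ("over", "under")

#: The four expression-consistent two-way combinations.
EXPRESSION_CONSISTENT: tuple[tuple[str, str], ...] = (
    ("gain", "over"),
    ("hypo", "over"),
    ("loss", "under"),
    ("hyper", "under"),
)


def combo_label(channels) -> str:
    return "+".join(channels)


def enumerate_combos() -> tuple[list[tuple[str, str]], list[tuple[str, str, str]]]:
    """All 12 two-way and 8 three-way cross-platform combinations.

    Deterministic order: platform pairs (cn, meth), (cn, expr),
    (meth, expr), channels in (up, down) order within each platform.
    """
    two_way = (
        list(product(_CN, _METH))
        + list(product(_CN, _EXPR))
        + list(product(_METH, _EXPR))
    )
    three_way = list(product(_CN, _METH, _EXPR))
    return two_way, three_way


def recurrence(calls: CallMatrix) -> pd.DataFrame:
    """Per-gene sample counts for every combination and single channel.

    Columns are combo labels ('gain', 'gain+hyper', 'gain+hyper+over',
    ...); values are the number of samples in which the gene carries all
    channels of the combo simultaneously.
    """
    if calls.n_genes == 0:
        raise ValidationError("recurrence: empty gene universe")
    two_way, three_way = enumerate_combos()
    out = {}
    for ch in ("gain", "loss", "hyper", "hypo", "over", "under"):
        out[ch] = calls.channel(ch).sum(axis=1)
    for combo in two_way:
        a, b = combo
        out[combo_label(combo)] = (calls.channel(a) & calls.channel(b)).sum(axis=1)
    for combo in three_way:
        a, b, c = combo
        out[combo_label(combo)] = (
            calls.channel(a) & calls.channel(b) & calls.channel(c)
        ).sum(axis=1)
    return pd.DataFrame(out, index=calls.genes)


def recurrence_curve(table: pd.DataFrame, n_samples: int) -> pd.DataFrame:
    """Number of genes with count >= k, per combo, for k = 1..n_samples."""
    ks = np.arange(1, n_samples + 1)
    data = {
        col: [(table[col] >= k).sum() for k in ks] for col in table.columns
    }
    return pd.DataFrame(data, index=pd.Index(ks, name="k"))


def select_recurrent(
    table: pd.DataFrame,
    k: int = 6,
    combos=EXPRESSION_CONSISTENT,
) -> pd.DataFrame:
    """Genes recurrent (count >= k) in any of the given combinations.

    Every qualifying combination is listed (one row per gene x combo),
    so a gene altered through several mechanisms keeps all its labels.
    """
    if k < 1:
        raise ValidationError("recurrence threshold k must be >= 1")
    rows = []
    for combo in combos:
        label = combo_label(combo)
        hits = table.index[table[label] >= k]
        for g in hits:
            rows.append(dict(gene=g, combo=label, count=int(table.at[g, label])))
    return (
        pd.DataFrame(rows, columns=["gene", "combo", "count"])
        .sort_values(["gene", "combo"], kind="stable")
        .reset_index(drop=True)
    )


def select_union(
    calls: CallMatrix, k: int = 6, already_selected=None
) -> pd.DataFrame:
    """Either-mechanism union rule: additional recurrently altered genes.

    Per sample, a gene scores when it is over-expressed and (gained or
    hypo-methylated), or under-expressed and (lost or hyper-methylated);
    genes whose score over samples reaches k through the union, minus
    genes already selected by the pairwise rule, are returned.
    """
    if k < 1:
        raise ValidationError("recurrence threshold k must be >= 1")
    over_any = calls.channel("over") & (calls.channel("gain") | calls.channel("hypo"))
    under_any = calls.channel("under") & (
        calls.channel("loss") | calls.channel("hyper")
    )
    over_count = over_any.sum(axis=1)
    under_count = under_any.sum(axis=1)
    sel = (over_count >= k) | (under_count >= k)
    genes = calls.genes[sel]
    direction = np.where(
        over_count[sel] >= k,
        "over/(gain|hypo)",
        "under/(loss|hyper)",
    )
    both = (over_count[sel] >= k) & (under_count[sel] >= k)
    direction = np.where(both, "both", direction)
    out = pd.DataFrame(
        {
            "gene": genes,
            "rule": direction,
            "count": np.maximum(over_count[sel], under_count[sel]),
        }
    )
    if already_selected is not None:
        out = out[~out["gene"].isin(set(already_selected))]
    return out.sort_values("gene", kind="stable").reset_index(drop=True)


def integrate(calls: CallMatrix, k: int = 6) -> dict:
    """Full integration stage: recurrence table, curve and selections."""
    table = recurrence(calls)
    curve = recurrence_curve(table, calls.n_samples)
    selected = select_recurrent(table, k=k)
    additional = select_union(calls, k=k, already_selected=selected["gene"])
    return dict(
        table=table,
        curve=curve,
        selected=selected,
        additional=additional,
        n_selected=selected["gene"].nunique(),
        n_additional=additional["gene"].nunique(),
        n_total=selected["gene"].nunique() + additional["gene"].nunique(),
    )
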