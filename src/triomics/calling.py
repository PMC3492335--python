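"""Per-gene binary aberration calls from the three platforms.

Copy-number gene states come from segment mean log-ratios (inclusive cuts
0.2 / -0.2, with high-gain 0.6 merged into gain and homozygous loss -1.0
merged into loss). Methylation and expression probes are called against
the mean of the designated control samples with strict cuts: deltaBeta
> 0.4 / < -0.4 and vst ratio > 1 / < -1 (a value exactly at the cut is
not called). Probe calls collapse to genes by inclusion: a gene is listed
in every category any of its probes reaches.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, MissingControlError, ValidationError
from .types import CallMatrix, GeneAnnotation, OmicsMatrix, SegmentTrack

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Thresholds:
    """Calling thresholds in the native units of each platform."""

    cn_high_gain: float = 0.6
    cn_gain: float = 0.2
    cn_loss: float = -0.2
    cn_homozygous_loss: float = -1.0
    delta_beta: float = 0.4
    vst_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not (
            self.cn_high_gain > self.cn_gain > 0 > self.cn_loss
            > self.cn_homozygous_loss
        ):
            raise ConfigurationError(
                "require cn_high_gain > cn_gain > 0 > cn_loss > cn_homozygous_loss"
            )
        if not 0 < self.delta_beta < 1:
            raise ConfigurationError("delta_beta must be in (0, 1)")
        if self.vst_ratio <= 0:
            raise ConfigurationError("vst_ratio must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "Thresholds":
        import yaml

        with open(path, encoding="utf-8") as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def quantile_normalize(matrix: OmicsMatrix) -> OmicsMatrix:
    """Force every column onto the mean-of-sorted-columns distribution.

    Ties within a column receive the mean of the reference values they
    span (rank-average interpolation).
    """
    vals = matrix.values.to_numpy(dtype=float)
    if vals.shape[1] < 2:
        raise ValidationError("quantile normalization needs >= 2 columns")
    ref = np.sort(vals, axis=0).mean(axis=1)
    n = vals.shape[0]
    out = np.empty_like(vals)
    from scipy.stats import rankdata

    for j in range(vals.shape[1]):
        r = rankdata(vals[:, j], method="average")
        out[:, j] = np.interp(r, np.arange(1, n + 1), ref)
    return OmicsMatrix(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        role=matrix.role,
        controls=matrix.controls,
    )


def call_copy_number(
    segments: dict[str, SegmentTrack],
    annotation: GeneAnnotation,
    thresholds: Thresholds = Thresholds(),
    missing_chromosome: str = "skip",
):
    """Per-gene CN state in {-1, 0, +1} per sample, with conflict flags.

    A gene overlapping any segment with value >= cn_gain is gained and any
    segment with value <= cn_loss is lost; a boundary-spanning gene
    overlapping both is listed in both states and flagged (the segment
    analogue of the probe inclusion rule). Genes on chromosomes absent
    from a sample's track are skipped with a warning (``missing`` mask
    True) or raise, per ``missing_chromosome``.

    Returns
    -------
    (gain, loss, conflict, missing) : DataFrames/bool frames gene x sample.
    """
    if missing_chromosome not in ("skip", "error"):
        raise ConfigurationError("missing_chromosome must be 'skip' or 'error'")
    genes = annotation.df
    samples = list(segments)
    n_g, n_s = len(genes), len(samples)
    gain = np.zeros((n_g, n_s), dtype=bool)
    loss = np.zeros((n_g, n_s), dtype=bool)
    missing = np.zeros((n_g, n_s), dtype=bool)

    for sj, sample in enumerate(samples):
        track = segments[sample].df
        by_chrom = {c: grp for c, grp in track.groupby("chrom")}
        for chrom, grp in genes.groupby("chrom"):
            seg = by_chrom.get(chrom)
            gidx = grp.index.to_numpy()
            if seg is None:
                if missing_chromosome == "error":
                    raise ValidationError(
                        f"sample {sample!r}: no segments on chromosome {chrom}"
                    )
                missing[gidx, sj] = True
                continue
            seg_start = seg["start"].to_numpy()
            seg_end = seg["end"].to_numpy()
            seg_val = seg["value"].to_numpy()
            g_start = grp["start"].to_numpy()
            g_end = grp["end"].to_numpy()
            # overlapping segments: those with end > gene start and
            # start < gene end (segments sorted, non-overlapping)
            lo = np.searchsorted(seg_end, g_start, side="right")
            hi = np.searchsorted(seg_start, g_end, side="left")
            for k in range(len(gidx)):
                if lo[k] >= hi[k]:
                    if missing_chromosome == "error":
                        raise ValidationError(
                            f"sample {sample!r}: gene "
                            f"{grp['gene_id'].iloc[k]!r} covered by no segment"
                        )
                    missing[gidx[k], sj] = True
                    continue
                vals = seg_val[lo[k]:hi[k]]
                if (vals >= thresholds.cn_gain).any():
                    gain[gidx[k], sj] = True
                if (vals <= thresholds.cn_loss).any():
                    loss[gidx[k], sj] = True

    if missing.any():
        n_miss = int(missing.any(axis=1).sum())
        warnings.warn(
            f"{n_miss} gene(s) not covered by segments in at least one sample; "
            "skipped for copy number",
            stacklevel=2,
        )
    conflict = gain & loss
    idx = pd.Index(genes["gene_id"], name="gene_id")
    cols = pd.Index(samples, name="sample")
    return (
        pd.DataFrame(gain, index=idx, columns=cols),
        pd.DataFrame(loss, index=idx, columns=cols),
        pd.DataFrame(conflict, index=idx, columns=cols),
        pd.DataFrame(missing, index=idx, columns=cols),
    )


def compute_delta(matrix: OmicsMatrix) -> pd.DataFrame:
    """Case value minus mean control value, probe x case-sample.

    The study phrases this as a "ratio", but both platforms are on a
    log-like scale where the printed negative cuts only make sense for a
    difference; deltaBeta is likewise defined with +/- cuts.
    """
    if not matrix.controls:
        raise MissingControlError("compute_delta requires designated controls")
    ctrl_mean = matrix.values[list(matrix.controls)].mean(axis=1)
    cases = matrix.case_columns
    return matrix.values[cases].sub(ctrl_mean, axis=0)


def call_probes(
    delta: pd.DataFrame, role: str, thresholds: Thresholds = Thresholds()
) -> dict[str, pd.DataFrame]:
    """Strict-threshold probe calls: hyper/hypo (beta) or over/under (vst)."""
    if role == "beta":
        cut = thresholds.delta_beta
        up, down = "hyper", "hypo"
    elif role == "vst":
        cut = thresholds.vst_ratio
        up, down = "over", "under"
    else:
        raise ValidationError(f"call_probes: unsupported role {role!r}")
    return {up: delta > cut, down: delta < -cut}


def collapse_to_genes(
    probe_calls: dict[str, pd.DataFrame], probe_map: pd.Series
) -> tuple[dict[str, pd.DataFrame], int]:
    """OR probe calls up to gene level (inclusion rule).

    Probes absent from ``probe_map`` are excluded with a warning; the
    count of excluded probes is returned alongside the per-channel gene
    frames.
    """
    out: dict[str, pd.DataFrame] = {}
    n_unmapped = 0
    for channel, frame in probe_calls.items():
        mapped = frame.index.isin(probe_map.index)
        n_unmapped = max(n_unmapped, int((~mapped).sum()))
        sub = frame.loc[mapped]
        genes = probe_map.reindex(sub.index)
        out[channel] = sub.groupby(genes.to_numpy()).any()
        out[channel].index.name = "gene_id"
    if n_unmapped:
        warnings.warn(
            f"{n_unmapped} probe(s) without a gene mapping excluded", stacklevel=2
        )
    return out, n_unmapped


def shared_universe(
    annotation: GeneAnnotation,
    meth_probe_map: pd.Series,
    expr_probe_map: pd.Series,
    cn_missing: pd.DataFrame | None = None,
) -> pd.Index:
    """Genes represented on all three platforms (autosomes by construction).

    A gene needs >= 1 methylation probe, >= 1 expression probe and a CN
    state in every sample (no missing coverage).
    """
    genes = annotation.gene_ids
    with_meth = genes.isin(set(meth_probe_map))
    with_expr = genes.isin(set(expr_probe_map))
    keep = with_meth & with_expr
    if cn_missing is not None:
        covered = ~cn_missing.reindex(genes).fillna(True).any(axis=1)
        keep &= covered.to_numpy()
    return genes[keep]


def build_call_matrix(
    segments: dict[str, SegmentTrack],
    beta: OmicsMatrix,
    expression: OmicsMatrix,
    annotation: GeneAnnotation,
    meth_probe_map: pd.Series,
    expr_probe_map: pd.Series,
    thresholds: Thresholds = Thresholds(),
    universe: pd.Index | None = None,
) -> CallMatrix:
    """Run the full calling stage and assemble one CallMatrix.

    Samples are the case samples shared by the segment tracks and both
    matrices; the gene universe defaults to genes represented on all
    three platforms.
    """
    gain, loss, conflict, missing = call_copy_number(
        segments, annotation, thresholds
    )
    meth_calls, _ = collapse_to_genes(
        call_probes(compute_delta(beta), "beta", thresholds), meth_probe_map
    )
    expr_calls, _ = collapse_to_genes(
        call_probes(compute_delta(expression), "vst", thresholds), expr_probe_map
    )
    if universe is None:
        universe = shared_universe(
            annotation, meth_probe_map, expr_probe_map, missing
        )
    samples = [s for s in segments if s in beta.case_columns]
    samples = [s for s in samples if s in expression.case_columns]
    calls = CallMatrix(universe, samples)
    calls.set_channel("gain", gain.reindex(index=universe, columns=samples))
    calls.set_channel("loss", loss.reindex(index=universe, columns=samples))
    calls.cn_conflict = (
        conflict.reindex(index=universe, columns=samples)
        .fillna(False)
        .to_numpy(dtype=bool)
    )
    for ch in ("hyper", "hypo"):
        calls.set_channel(ch, meth_calls[ch].reindex(index=universe, columns=samples))
    for ch in ("over", "under"):
        calls.set_channel(ch, expr_calls[ch].reindex(index=universe, columns=samples))
    for ch in ("gain", "loss", "hyper", "hypo", "over", "under"):
        logger.info(
            "channel %s: %d calls across %d samples",
            ch, int(calls.channel(ch).sum()), len(samples),
        )
    return calls


def channel_counts(calls: CallMatrix) -> pd.DataFrame:
    """Number of called genes per channel per sample (summary-table layout)."""
    return pd.DataFrame(
        {ch: calls.frame(ch).sum(axis=0) for ch in
         ("gain", "loss", "hyper", "hypo", "over", "under")}
    )
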