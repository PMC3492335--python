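"""Readers and writers for every on-disk artifact.

All formats are tab-separated UTF-8 with a header row; lines starting with
'#' are comments. Coordinates are 0-based half-open. Writers and readers
round-trip exactly (modulo row order).

Formats
-------
annotation : chrom, start, end, gene_id, arm          (BED-like)
segments   : sample, chrom, start, end, value         (one row per segment)
matrix     : id, <sample1>, <sample2>, ...            (numeric body)
probe map  : probe, gene                              (two columns)
calls      : gene, sample, channel, value, conflict   (long; 1-rows only,
             with '#genes:' and '#samples:' comment lines preserving the
             full universe)
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import MalformedRowError, ValidationError
from .types import CHANNELS, CallMatrix, GeneAnnotation, OmicsMatrix, SegmentTrack


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", **kwargs)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise MalformedRowError(f"{path}: {exc}") from exc


# -- gene annotation -------------------------------------------------------

def read_annotation(path) -> GeneAnnotation:
    df = _read_tsv(path, dtype={"chrom": str})
    required = ["chrom", "start", "end", "gene_id", "arm"]
    if list(df.columns[:5]) != required:
        raise MalformedRowError(
            f"{path}: expected columns {required}, got {list(df.columns[:5])}"
        )
    try:
        return GeneAnnotation(df[required])
    except ValidationError as exc:
        raise type(exc)(f"{path}: {exc}") from exc


def write_annotation(ann: GeneAnnotation, path) -> None:
    ann.df[["chrom", "start", "end", "gene_id", "arm"]].to_csv(
        path, sep="\t", index=False
    )


# -- per-sample segments ---------------------------------------------------

def read_segments(path) -> dict[str, SegmentTrack]:
    """Read a multi-sample segment file into one track per sample."""
    df = _read_tsv(path, dtype={"sample": str, "chrom": str})
    required = ["sample", "chrom", "start", "end", "value"]
    if list(df.columns[:5]) != required:
        raise MalformedRowError(
            f"{path}: expected columns {required}, got {list(df.columns[:5])}"
        )
    tracks: dict[str, SegmentTrack] = {}
    for sample, grp in df.groupby("sample", sort=True):
        try:
            tracks[str(sample)] = SegmentTrack(
                grp[["chrom", "start", "end", "value"]].reset_index(drop=True)
            )
        except ValidationError as exc:
            raise type(exc)(f"{path}: sample {sample!r}: {exc}") from exc
    return tracks


def write_segments(tracks: Mapping[str, SegmentTrack], path) -> None:
    parts = []
    for sample in tracks:
        part = tracks[sample].df.copy()
        part.insert(0, "sample", sample)
        parts.append(part)
    pd.concat(parts, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_frequency_track(path) -> SegmentTrack:
    """Read a single cohort frequency track (chrom, start, end, value)."""
    df = _read_tsv(path, dtype={"chrom": str})
    if "sample" in df.columns:
        df = df.drop(columns=["sample"])
    track = SegmentTrack(df[["chrom", "start", "end", "value"]])
    return track.check_frequency()


def write_track(track: SegmentTrack, path) -> None:
    track.df.to_csv(path, sep="\t", index=False)


def read_bedgraph(path) -> SegmentTrack:
    """Read a headerless bedGraph (chrom, start, end, value) track."""
    df = _read_tsv(
        path, header=None, names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    return SegmentTrack(df)


# -- omics matrices --------------------------------------------------------

def read_matrix(path, role: str, controls=()) -> OmicsMatrix:
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise MalformedRowError(f"{path}: matrix needs an id column + samples")
    id_col = df.columns[0]
    body = df.set_index(id_col)
    body.index = body.index.astype(str)
    body.columns = body.columns.astype(str)
    try:
        body = body.astype(float)
    except ValueError as exc:
        raise MalformedRowError(f"{path}: non-numeric matrix value: {exc}") from exc
    try:
        return OmicsMatrix(body, role=role, controls=tuple(controls))
    except ValidationError as exc:
        raise type(exc)(f"{path}: {exc}") from exc


def write_matrix(matrix: OmicsMatrix, path, id_label: str = "id") -> None:
    out = matrix.values.copy()
    out.index.name = id_label
    out.to_csv(path, sep="\t")


def read_probe_map(path) -> pd.Series:
    """probe -> gene mapping as a Series indexed by probe id."""
    df = _read_tsv(path, dtype=str)
    if list(df.columns[:2]) != ["probe", "gene"]:
        raise MalformedRowError(
            f"{path}: expected columns ['probe', 'gene'], got {list(df.columns[:2])}"
        )
    if df["probe"].duplicated().any():
        raise ValidationError(f"{path}: duplicate probe id in map")
    return df.set_index("probe")["gene"]


def write_probe_map(mapping: pd.Series, path) -> None:
    df = mapping.rename("gene").rename_axis("probe").reset_index()
    df.to_csv(path, sep="\t", index=False)


# -- call matrices ---------------------------------------------------------

def write_calls(calls: CallMatrix, path) -> None:
    long = calls.to_long()
    conflict = [
        int(calls.cn_conflict[calls.genes.get_loc(g), calls.samples.get_loc(s)])
        if ch in ("gain", "loss")
        else 0
        for g, s, ch in zip(long["gene"], long["sample"], long["channel"])
    ]
    long["conflict"] = conflict
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#genes:\t" + "\t".join(calls.genes) + "\n")
        fh.write("#samples:\t" + "\t".join(calls.samples) + "\n")
        fh.write("gene\tsample\tchannel\tvalue\tconflict\n")
        for row in long.itertuples(index=False):
            fh.write(
                f"{row.gene}\t{row.sample}\t{row.channel}\t{row.value}\t"
                f"{row.conflict}\n"
            )


def read_calls(path) -> CallMatrix:
    genes: list[str] | None = None
    samples: list[str] | None = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#genes:"):
                genes = line.rstrip("\n").split("\t")[1:]
            elif line.startswith("#samples:"):
                samples = line.rstrip("\n").split("\t")[1:]
            elif not line.startswith("#"):
                break
    df = _read_tsv(path, dtype={"gene": str, "sample": str, "channel": str})
    required = ["gene", "sample", "channel", "value"]
    if list(df.columns[: len(required)]) != required:
        raise MalformedRowError(
            f"{path}: expected columns {required}, got {list(df.columns)}"
        )
    if genes is None:
        genes = sorted(df["gene"].unique())
    if samples is None:
        samples = sorted(df["sample"].unique())
    bad = ~df["channel"].isin(CHANNELS)
    if bad.any():
        raise MalformedRowError(
            f"{path}: unknown channel {df.loc[bad, 'channel'].iloc[0]!r}"
        )
    calls = CallMatrix(genes, samples)
    gi = calls.genes.get_indexer(df["gene"])
    si = calls.samples.get_indexer(df["sample"])
    if (gi < 0).any() or (si < 0).any():
        raise ValidationError(f"{path}: call row outside declared universe")
    ci = np.array([CHANNELS.index(c) for c in df["channel"]])
    on = df["value"].astype(int).to_numpy() != 0
    calls.values[gi[on], si[on], ci[on]] = True
    if "conflict" in df.columns:
        cf = df["conflict"].astype(int).to_numpy() != 0
        calls.cn_conflict[gi[cf & on], si[cf & on]] = True
    return calls


def write_calls_per_sample(calls: CallMatrix, directory) -> list[str]:
    """Compatibility writer: six binary files per channel, genes x samples.

    Each file is a gene x sample 0/1 matrix named ``calls_<channel>.tsv``.
    """
    os.makedirs(directory, exist_ok=True)
    paths = []
    for ch in CHANNELS:
        frame = calls.frame(ch).astype(int)
        frame.index.name = "gene"
        p = os.path.join(directory, f"calls_{ch}.tsv")
        frame.to_csv(p, sep="\t")
        paths.append(p)
    return paths
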