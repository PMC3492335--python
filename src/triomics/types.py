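"""Shared in-memory containers for the three-platform analysis.

All genomic coordinates are 0-based, half-open. Only autosomes 1-22 are
admitted anywhere; sex chromosomes are rejected at validation time, never
silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    BetaRangeError,
    CoordinateError,
    DuplicateIdError,
    MissingControlError,
    SegmentOverlapError,
    SexChromosomeError,
    ValidationError,
)

#: Aberration channels, one up/down pair per platform, in canonical order.
CHANNELS: tuple[str, ...] = ("gain", "loss", "hyper", "hypo", "over", "under")

#: Platform owning each channel.
CHANNEL_PLATFORM: dict[str, str] = {
    "gain": "cn",
    "loss": "cn",
    "hyper": "meth",
    "hypo": "meth",
    "over": "expr",
    "under": "expr",
}

#: Matrix roles understood by the I/O layer and the calling stage.
MATRIX_ROLES = ("beta", "mvalue", "vst", "logratio")


def _check_chromosome(values: Iterable, context: str) -> np.ndarray:
    """Normalize chromosome labels to ints 1-22, rejecting anything else."""
    out = []
    for v in values:
        s = str(v)
        if s.lower().startswith("chr"):
            s = s[3:]
        if not s.isdigit() or not (1 <= int(s) <= 22):
            raise SexChromosomeError(
                f"{context}: chromosome {v!r} is not an autosome 1-22"
            )
        out.append(int(s))
    return np.asarray(out, dtype=np.int64)


@dataclass
class GeneAnnotation:
    """Gene universe: id, autosome, arm and a 0-based half-open interval.

    ``df`` has columns gene_id, chrom (int 1-22), start, end, arm ('p'/'q'),
    sorted by (chrom, start).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["gene_id", "chrom", "start", "end", "arm"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValidationError(f"annotation missing columns {missing}")
        df = self.df.copy()
        df["chrom"] = _check_chromosome(df["chrom"], "annotation")
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["end"] <= df["start"]).any():
            bad = df.loc[df["end"] <= df["start"], "gene_id"].iloc[0]
            raise CoordinateError(f"annotation: gene {bad!r} has end <= start")
        if (df["start"] < 0).any():
            raise CoordinateError("annotation: negative start coordinate")
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise DuplicateIdError(f"annotation: duplicate gene_id {dup!r}")
        bad_arm = ~df["arm"].isin(["p", "q"])
        if bad_arm.any():
            raise ValidationError(
                f"annotation: arm must be 'p' or 'q', got "
                f"{df.loc[bad_arm, 'arm'].iloc[0]!r}"
            )
        df = df[required].sort_values(
            ["chrom", "start"], kind="stable"
        ).reset_index(drop=True)
        # overlap check within chromosome (sorted by start)
        for chrom, grp in df.groupby("chrom"):
            if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
                raise SegmentOverlapError(
                    f"annotation: overlapping gene intervals on chromosome {chrom}"
                )
        self.df = df

    @property
    def gene_ids(self) -> pd.Index:
        return pd.Index(self.df["gene_id"])

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, gene_ids: Iterable[str]) -> "GeneAnnotation":
        keep = self.df["gene_id"].isin(set(gene_ids))
        return GeneAnnotation(self.df.loc[keep].reset_index(drop=True))


@dataclass
class SegmentTrack:
    """Ordered non-overlapping intervals with one numeric value each.

    ``df`` has columns chrom, start, end, value. Used both for a single
    sample's segmented log-ratios and for a cohort frequency track (values
    then restricted to [0, 1] via ``check_frequency``).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["chrom", "start", "end", "value"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValidationError(f"segment track missing columns {missing}")
        df = self.df.copy()
        df["chrom"] = _check_chromosome(df["chrom"], "segments")
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["value"] = df["value"].astype(float)
        if (df["end"] <= df["start"]).any():
            raise CoordinateError("segments: interval with end <= start")
        if not np.isfinite(df["value"]).all():
            raise ValidationError("segments: non-finite value")
        df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        for chrom, grp in df.groupby("chrom"):
            if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
                raise SegmentOverlapError(
                    f"segments: overlapping intervals on chromosome {chrom}"
                )
        self.df = df

    def check_frequency(self) -> "SegmentTrack":
        v = self.df["value"]
        if ((v < 0) | (v > 1)).any():
            raise ValidationError("frequency track: values outside [0, 1]")
        return self

    def chromosomes(self) -> list[int]:
        return sorted(self.df["chrom"].unique().tolist())

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class OmicsMatrix:
    """Probe/gene x sample numeric matrix with a role tag and controls.

    ``values``: DataFrame indexed by probe/gene id, columns = sample ids.
    ``controls``: designated control sample columns (may be empty for roles
    that never need them, e.g. a delta matrix).
    """

    values: pd.DataFrame
    role: str
    controls: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.role not in MATRIX_ROLES:
            raise ValidationError(
                f"matrix role {self.role!r} not in {MATRIX_ROLES}"
            )
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise DuplicateIdError(f"matrix: duplicate row id {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise DuplicateIdError(f"matrix: duplicate sample id {dup!r}")
        vals = self.values.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            r, c = np.argwhere(~np.isfinite(vals))[0]
            raise ValidationError(
                f"matrix: non-finite value at row {self.values.index[r]!r}, "
                f"column {self.values.columns[c]!r}"
            )
        if self.role == "beta":
            bad = np.argwhere((vals < 0) | (vals > 1))
            if len(bad):
                r, c = bad[0]
                raise BetaRangeError(
                    f"beta matrix: value {vals[r, c]!r} outside [0, 1] at row "
                    f"{self.values.index[r]!r}, column {self.values.columns[c]!r}"
                )
        self.controls = tuple(self.controls)
        missing = [c for c in self.controls if c not in self.values.columns]
        if missing:
            raise MissingControlError(
                f"matrix: control column(s) {missing} absent"
            )

    @property
    def case_columns(self) -> list[str]:
        ctrl = set(self.controls)
        return [c for c in self.values.columns if c not in ctrl]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"OmicsMatrix(role={self.role!r}, shape={self.values.shape}, "
            f"controls={list(self.controls)})"
        )


class CallMatrix:
    """Gene x sample x channel binary aberration indicators.

    Internally a boolean array of shape (n_genes, n_samples, 6) with the
    channel order of :data:`CHANNELS`, plus a gain/loss conflict flag per
    gene and sample (a gene overlapping both a gained and a lost segment
    is listed in both states, mirroring the multi-probe inclusion rule).
    """

    def __init__(
        self,
        genes: Sequence[str],
        samples: Sequence[str],
        values: np.ndarray | None = None,
        cn_conflict: np.ndarray | None = None,
    ) -> None:
        self.genes = pd.Index(genes, name="gene_id")
        self.samples = pd.Index(samples, name="sample")
        if self.genes.duplicated().any():
            raise DuplicateIdError("call matrix: duplicate gene ids")
        if self.samples.duplicated().any():
            raise DuplicateIdError("call matrix: duplicate sample ids")
        shape = (len(self.genes), len(self.samples), len(CHANNELS))
        if values is None:
            values = np.zeros(shape, dtype=bool)
        values = np.asarray(values, dtype=bool)
        if values.shape != shape:
            raise ValidationError(
                f"call matrix: values shape {values.shape} != {shape}"
            )
        self.values = values
        if cn_conflict is None:
            cn_conflict = np.zeros(shape[:2], dtype=bool)
        self.cn_conflict = np.asarray(cn_conflict, dtype=bool)
        if self.cn_conflict.shape != shape[:2]:
            raise ValidationError("call matrix: conflict flag shape mismatch")
        both = self.values[:, :, CHANNELS.index("gain")] & self.values[
            :, :, CHANNELS.index("loss")
        ]
        if (both & ~self.cn_conflict).any():
            raise ValidationError(
                "call matrix: gain and loss both set without conflict flag"
            )

    # -- accessors ---------------------------------------------------------
    def channel(self, name: str) -> np.ndarray:
        """Boolean (genes x samples) view of one channel."""
        return self.values[:, :, CHANNELS.index(name)]

    def frame(self, name: str) -> pd.DataFrame:
        return pd.DataFrame(
            self.channel(name), index=self.genes, columns=self.samples
        )

    def set_channel(self, name: str, frame: pd.DataFrame | np.ndarray) -> None:
        if isinstance(frame, pd.DataFrame):
            frame = frame.reindex(index=self.genes, columns=self.samples).fillna(
                False
            )
            arr = frame.to_numpy(dtype=bool)
        else:
            arr = np.asarray(frame, dtype=bool)
        self.values[:, :, CHANNELS.index(name)] = arr

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset_genes(self, gene_ids: Sequence[str]) -> "CallMatrix":
        idx = self.genes.get_indexer(pd.Index(gene_ids))
        if (idx < 0).any():
            raise ValidationError("call matrix: unknown gene in subset")
        return CallMatrix(
            pd.Index(gene_ids),
            self.samples,
            self.values[idx],
            self.cn_conflict[idx],
        )

    def to_long(self) -> pd.DataFrame:
        """Long-format frame: gene, sample, channel, value (1 rows only)."""
        g, s, c = np.nonzero(self.values)
        return pd.DataFrame(
            {
                "gene": self.genes[g],
                "sample": self.samples[s],
                "channel": [CHANNELS[i] for i in c],
                "value": 1,
            }
        )

    def equals(self, other: "CallMatrix") -> bool:
        return (
            self.genes.equals(other.genes)
            and self.samples.equals(other.samples)
            and np.array_equal(self.values, other.values)
            and np.array_equal(self.cn_conflict, other.cn_conflict)
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CallMatrix({self.n_genes} genes x {self.n_samples} samples, "
            f"{int(self.values.sum())} calls)"
        )


@dataclass
class ContingencyTable:
    """2x2 cross-tabulation (a, b, c, d) = (A&B, A&~B, ~A&B, ~A&~B)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0:
                raise ValidationError(f"contingency cell {name} negative: {v}")
            setattr(self, name, int(v))

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)
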