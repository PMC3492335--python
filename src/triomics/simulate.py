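"""Synthetic three-platform dataset generator with known planted truth.

Emulates the study design this pipeline targets: ~19 case samples and 2
control samples (cultured osteoblast-like references), thousands of genes
on 22 autosomes, multi-probe methylation/expression arrays, segmented
copy-number profiles, planted recurrent multi-channel aberrations,
copy-number->expression and methylation->expression coupling, and
gene-density-biased placement of copy-number gains.

Generative model
----------------
* Genome: each chromosome is a row of fixed-length tiles; a latent
  Gamma(2, 1) density field per tile drives both gene placement and
  (when ``density_bias > 0``) background gain placement. The centromere
  sits at a fixed fraction of the chromosome (default 0.4), aligned to a
  tile boundary.
* Copy number: per case sample each tile is independently gained / lost /
  normal; segment mean log-ratios are the planted state value plus
  Gaussian noise. Planted genes force their tile's state in the affected
  samples, and background events are cleared from planted tiles so the
  planted truth is exact.
* Methylation: probe beta values arise from a latent normal through the
  logistic map, so beta stays strictly in (0, 1) and deltaBeta thresholds
  are meaningful at both ends of the range. Controls carry no shift.
* Expression: vst-like scale; case value = probe baseline
  + cn_coef * CN state + meth_coef * (methylation shift in beta units)
  + planted expression effect + noise.

One RNG stream per platform, all spawned from the master seed, so adding
probes to one platform never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .errors import ConfigurationError
from .types import CHANNELS, CHANNEL_PLATFORM, CallMatrix, GeneAnnotation, OmicsMatrix, SegmentTrack


@dataclass(frozen=True)
class PlantedSet:
    """A set of genes planted with one aberration combination.

    ``combo`` is channels joined by '+', e.g. ``"gain+over"`` or
    ``"gain+hyper+under"``; each channel must come from a distinct
    platform. The combination is planted jointly in ``n_affected`` case
    samples (a random subset per gene).
    """

    combo: str
    n_genes: int
    n_affected: int

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.combo.split("+"))

    def validate(self, n_case_samples: int) -> None:
        chans = self.channels
        if not chans or any(c not in CHANNELS for c in chans):
            raise ConfigurationError(f"planted combo {self.combo!r}: unknown channel")
        platforms = [CHANNEL_PLATFORM[c] for c in chans]
        if len(set(platforms)) != len(platforms):
            raise ConfigurationError(
                f"planted combo {self.combo!r}: one channel per platform"
            )
        if self.n_genes < 1:
            raise ConfigurationError("planted set: n_genes must be >= 1")
        if not (1 <= self.n_affected <= n_case_samples):
            raise ConfigurationError(
                f"planted set: n_affected {self.n_affected} not in "
                f"[1, {n_case_samples}]"
            )


@dataclass
class SimulationConfig:
    """All knobs of the generator; the seed fully determines the output."""

    seed: int = 0
    n_case_samples: int = 19
    n_control_samples: int = 2
    n_chromosomes: int = 22
    genes_per_chromosome: int = 100
    tiles_per_chromosome: int = 20
    tile_length: int = 1_000_000
    centromere_fraction: float = 0.4
    probes_per_gene_meth: tuple[int, int] = (1, 3)
    probes_per_gene_expr: tuple[int, int] = (1, 2)
    density_bias: float = 0.0
    planted: tuple[PlantedSet, ...] = ()
    # background aberration rates (per tile per case sample)
    gain_rate: float = 0.2
    loss_rate: float = 0.1
    # effect sizes
    cn_gain_value: float = 0.5
    cn_loss_value: float = -0.5
    meth_effect: float = 3.5        # latent logit shift for hyper/hypo
    expr_effect: float = 2.0        # vst-scale shift for over/under
    cn_coef: float = 0.5            # expression response per CN state unit
    meth_coef: float = -0.5         # expression response per unit beta shift
    # baselines
    meth_baseline_mu: float = -1.2  # logit scale; beta ~ 0.23
    meth_baseline_sd: float = 0.6
    meth_probe_sd: float = 0.2
    expr_baseline_mu: float = 7.0
    expr_baseline_sd: float = 1.0
    # noise scales
    cn_noise: float = 0.05
    meth_noise: float = 0.3         # latent logit scale
    expr_noise: float = 0.3

    def __post_init__(self) -> None:
        self.planted = tuple(
            p if isinstance(p, PlantedSet) else PlantedSet(**p) for p in self.planted
        )
        self.probes_per_gene_meth = tuple(self.probes_per_gene_meth)
        self.probes_per_gene_expr = tuple(self.probes_per_gene_expr)
        self.validate()

    def validate(self) -> None:
        for name in (
            "n_case_samples", "n_control_samples", "n_chromosomes",
            "genes_per_chromosome", "tiles_per_chromosome", "tile_length",
        ):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if not 0.0 <= self.density_bias <= 1.0:
            raise ConfigurationError("density_bias must be in [0, 1]")
        if not 0.0 < self.centromere_fraction < 1.0:
            raise ConfigurationError("centromere_fraction must be in (0, 1)")
        for lo, hi in (self.probes_per_gene_meth, self.probes_per_gene_expr):
            if lo < 1 or hi < lo:
                raise ConfigurationError("probe count range must satisfy 1 <= lo <= hi")
        for p in self.planted:
            p.validate(self.n_case_samples)
        total_planted = sum(p.n_genes for p in self.planted)
        if total_planted > self.n_chromosomes * self.genes_per_chromosome:
            raise ConfigurationError("more planted genes than genes in genome")

    # thresholds used downstream; feasibility of the planted channels is
    # checked against them so an unsatisfiable configuration fails fast.
    def check_feasible(
        self, cn_gain_cut: float = 0.2, delta_beta_cut: float = 0.4,
        vst_cut: float = 1.0,
    ) -> None:
        planted_channels = {c for p in self.planted for c in p.channels}
        if "gain" in planted_channels and (
            self.cn_gain_value - 2 * self.cn_noise <= cn_gain_cut
        ):
            raise ConfigurationError(
                "planted gain value cannot clear the gain threshold given cn_noise"
            )
        if "loss" in planted_channels and (
            abs(self.cn_loss_value) - 2 * self.cn_noise <= cn_gain_cut
        ):
            raise ConfigurationError(
                "planted loss value cannot clear the loss threshold given cn_noise"
            )
        if planted_channels & {"hyper", "hypo"}:
            mu = self.meth_baseline_mu
            delta = expit(mu + self.meth_effect) - expit(mu)
            # logistic slope <= 1/4: latent noise maps to <= noise/4 in beta
            noise_beta = (self.meth_noise + self.meth_probe_sd) / 4.0
            if delta - 2 * noise_beta <= delta_beta_cut:
                raise ConfigurationError(
                    "planted methylation effect cannot clear the deltaBeta "
                    "threshold given meth_noise"
                )
        if planted_channels & {"over", "under"}:
            margin = 2 * self.expr_noise * np.sqrt(
                1.0 + 1.0 / max(self.n_control_samples, 1)
            )
            if self.expr_effect - margin <= vst_cut:
                raise ConfigurationError(
                    "planted expression effect cannot clear the vst-ratio "
                    "threshold given expr_noise"
                )

    @classmethod
    def null(cls, seed: int = 0, **overrides) -> "SimulationConfig":
        """Null preset: no planted effects, no density bias, no coupling.

        Noise scales are raised so that every channel produces calls at
        workable marginal rates; contingency-table margins then stay away
        from degeneracy, which is what a calibration study needs.
        """
        params = dict(
            seed=seed, density_bias=0.0, planted=(),
            cn_coef=0.0, meth_coef=0.0,
            meth_noise=1.0, expr_noise=0.8,
        )
        params.update(overrides)
        return cls(**params)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["planted"] = [asdict(p) for p in self.planted]
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        data["planted"] = tuple(PlantedSet(**p) for p in data.get("planted", []))
        for key in ("probes_per_gene_meth", "probes_per_gene_expr"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class SyntheticGenome:
    """Gene annotation plus the latent tile structure that generated it."""

    annotation: GeneAnnotation
    tiles: pd.DataFrame          # chrom, start, end, density, n_genes
    centromeres: dict[int, int]  # chrom -> centromere coordinate

    @property
    def n_genes(self) -> int:
        return len(self.annotation)


@dataclass
class GroundTruth:
    """Planted truth: channel indicators and per-cell numeric shifts.

    ``calls`` holds the exact aberration indicators implied by the
    noise-free part of the generative model (thresholds applied to the
    deterministic effect components), over all genes and case samples.
    """

    calls: CallMatrix
    cn_state: pd.DataFrame        # gene x case sample in {-1, 0, 1}
    meth_shift_beta: pd.DataFrame  # gene x case sample, beta units
    expr_shift: pd.DataFrame       # gene x case sample, vst units
    planted_genes: pd.DataFrame    # gene, combo, n_affected, samples


@dataclass
class SyntheticDataset:
    segments: dict[str, SegmentTrack]
    beta: OmicsMatrix
    expression: OmicsMatrix
    meth_probe_map: pd.Series
    expr_probe_map: pd.Series
    truth: GroundTruth
    case_samples: list[str]
    control_samples: list[str]


def _streams(seed: int, n: int = 5) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_genome(config: SimulationConfig) -> SyntheticGenome:
    """Lay out genes on tiled chromosomes with a latent density field."""
    rng = _streams(config.seed)[0]
    db = config.density_bias
    tile_len = config.tile_length
    n_tiles = config.tiles_per_chromosome
    cent_tile = int(round(config.centromere_fraction * n_tiles))
    cent_tile = min(max(cent_tile, 1), n_tiles - 1) if n_tiles > 1 else 1

    rows = []
    tile_rows = []
    centromeres: dict[int, int] = {}
    for chrom in range(1, config.n_chromosomes + 1):
        density = rng.gamma(2.0, 1.0, size=n_tiles)
        dn = density / density.mean()
        weights = (1.0 - db) + db * dn
        probs = weights / weights.sum()
        counts = rng.multinomial(config.genes_per_chromosome, probs)
        centromeres[chrom] = cent_tile * tile_len if n_tiles > 1 else tile_len
        for t in range(n_tiles):
            t_start = t * tile_len
            tile_rows.append(
                dict(chrom=chrom, start=t_start, end=t_start + tile_len,
                     density=density[t], n_genes=int(counts[t]))
            )
            k = int(counts[t])
            if k == 0:
                continue
            slot = tile_len // k
            gene_len = max(1, slot // 2)
            for j in range(k):
                start = t_start + j * slot
                end = start + gene_len
                rows.append(
                    dict(chrom=chrom, start=start, end=end, gene_id="", arm="")
                )
    ann = pd.DataFrame(rows)
    ann = ann.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    ann["gene_id"] = [
        f"g{c:02d}_{i:04d}"
        for c, i in zip(ann["chrom"], ann.groupby("chrom").cumcount())
    ]
    ann["arm"] = np.where(
        ann["end"].to_numpy() <= np.array([centromeres[c] for c in ann["chrom"]]),
        "p", "q",
    )
    annotation = GeneAnnotation(ann[["gene_id", "chrom", "start", "end", "arm"]])
    return SyntheticGenome(annotation, pd.DataFrame(tile_rows), centromeres)


def _assign_plants(
    config: SimulationConfig, genome: SyntheticGenome, rng: np.random.Generator
) -> pd.DataFrame:
    """Choose planted genes and their affected case samples."""
    gene_ids = genome.annotation.gene_ids.to_numpy()
    pool = rng.permutation(len(gene_ids))
    cursor = 0
    records = []
    for pset in config.planted:
        chosen = pool[cursor:cursor + pset.n_genes]
        cursor += pset.n_genes
        for gi in chosen:
            samples = np.sort(
                rng.choice(config.n_case_samples, size=pset.n_affected, replace=False)
            )
            records.append(
                dict(
                    gene=gene_ids[gi],
                    combo=pset.combo,
                    n_affected=pset.n_affected,
                    samples=",".join(f"s{j + 1:02d}" for j in samples),
                    sample_idx=samples,
                )
            )
    return pd.DataFrame(
        records, columns=["gene", "combo", "n_affected", "samples", "sample_idx"]
    )


def simulate_dataset(
    config: SimulationConfig, genome: SyntheticGenome | None = None
) -> SyntheticDataset:
    """Generate segments, beta and expression matrices plus ground truth."""
    config.check_feasible()
    if genome is None:
        genome = simulate_genome(config)
    _, plant_rng, cn_rng, meth_rng, expr_rng = _streams(config.seed)

    ann = genome.annotation.df
    n_genes = len(ann)
    gene_ids = genome.annotation.gene_ids
    n_case = config.n_case_samples
    case_samples = [f"s{j + 1:02d}" for j in range(n_case)]
    control_samples = [f"c{j + 1:02d}" for j in range(config.n_control_samples)]

    plants = _assign_plants(config, genome, plant_rng)

    # per-gene/sample planted indicator per channel
    planted_ch = {ch: np.zeros((n_genes, n_case), dtype=bool) for ch in CHANNELS}
    gene_pos = pd.Series(np.arange(n_genes), index=gene_ids)
    for rec in plants.itertuples(index=False):
        gi = gene_pos[rec.gene]
        for ch in rec.combo.split("+"):
            planted_ch[ch][gi, rec.sample_idx] = True

    # ---- copy number -----------------------------------------------------
    tiles = genome.tiles
    n_tiles_total = len(tiles)
    tile_index = {
        (c, s): i
        for i, (c, s) in enumerate(zip(tiles["chrom"], tiles["start"]))
    }
    tile_len = config.tile_length
    gene_tile = np.array(
        [
            tile_index[(c, (st // tile_len) * tile_len)]
            for c, st in zip(ann["chrom"], ann["start"])
        ]
    )
    db = config.density_bias
    dn = np.concatenate(
        [
            grp["density"].to_numpy() / grp["density"].mean()
            for _, grp in tiles.groupby("chrom")
        ]
    )
    p_gain = np.clip(config.gain_rate * ((1 - db) + db * dn), 0.0, 0.9)
    p_loss = np.clip(
        config.loss_rate * ((1 - db) + db * np.clip(2.0 - dn, 0.05, None)), 0.0, 0.9
    )

    u = cn_rng.random((n_tiles_total, n_case))
    tile_state = np.zeros((n_tiles_total, n_case), dtype=np.int8)
    tile_state[u < p_gain[:, None]] = 1
    tile_state[(u >= p_gain[:, None]) & (u < (p_gain + p_loss)[:, None])] = -1

    # clear background events on tiles that carry CN-planted genes, then
    # impose the planted states: the planted truth is exact by construction
    cn_planted = planted_ch["gain"] | planted_ch["loss"]
    protected = np.unique(gene_tile[cn_planted.any(axis=1)])
    tile_state[protected, :] = 0
    for rec in plants.itertuples(index=False):
        chans = rec.combo.split("+")
        gi = gene_pos[rec.gene]
        if "gain" in chans:
            tile_state[gene_tile[gi], rec.sample_idx] = 1
        elif "loss" in chans:
            tile_state[gene_tile[gi], rec.sample_idx] = -1

    level = np.zeros_like(tile_state, dtype=float)
    level[tile_state == 1] = config.cn_gain_value
    level[tile_state == -1] = config.cn_loss_value
    seg_values = level + cn_rng.normal(0.0, config.cn_noise, size=level.shape)

    segments: dict[str, SegmentTrack] = {}
    base = tiles[["chrom", "start", "end"]]
    for j, sample in enumerate(case_samples):
        df = base.copy()
        df["value"] = seg_values[:, j]
        segments[sample] = SegmentTrack(df)

    cn_state = pd.DataFrame(
        tile_state[gene_tile, :], index=gene_ids, columns=case_samples, dtype=np.int8
    )

    # ---- methylation -----------------------------------------------------
    pmin, pmax = config.probes_per_gene_meth
    n_probes_m = meth_rng.integers(pmin, pmax + 1, size=n_genes)
    mu_gene = meth_rng.normal(
        config.meth_baseline_mu, config.meth_baseline_sd, size=n_genes
    )
    # planted-hypo genes start high so a downward shift is visible; planted
    # hyper genes start low for the same reason
    hypo_genes = planted_ch["hypo"].any(axis=1)
    hyper_genes = planted_ch["hyper"].any(axis=1)
    mu_gene[hypo_genes] = meth_rng.normal(1.2, 0.3, size=int(hypo_genes.sum()))
    mu_gene[hyper_genes] = meth_rng.normal(
        config.meth_baseline_mu, 0.3, size=int(hyper_genes.sum())
    )

    meth_shift_latent = (
        planted_ch["hyper"].astype(float) - planted_ch["hypo"].astype(float)
    ) * config.meth_effect

    probe_gene_m = np.repeat(np.arange(n_genes), n_probes_m)
    n_mp = len(probe_gene_m)
    probe_off = meth_rng.normal(0.0, config.meth_probe_sd, size=n_mp)
    probe_base = mu_gene[probe_gene_m] + probe_off

    latent_case = (
        probe_base[:, None]
        + meth_shift_latent[probe_gene_m, :]
        + meth_rng.normal(0.0, config.meth_noise, size=(n_mp, n_case))
    )
    latent_ctrl = probe_base[:, None] + meth_rng.normal(
        0.0, config.meth_noise, size=(n_mp, len(control_samples))
    )
    beta_vals = expit(np.concatenate([latent_case, latent_ctrl], axis=1))
    meth_probe_ids = pd.Index(
        [f"mp{i:06d}" for i in range(n_mp)], name="probe"
    )
    beta = OmicsMatrix(
        pd.DataFrame(
            beta_vals, index=meth_probe_ids, columns=case_samples + control_samples
        ),
        role="beta",
        controls=tuple(control_samples),
    )
    meth_probe_map = pd.Series(
        gene_ids.to_numpy()[probe_gene_m], index=meth_probe_ids, name="gene"
    )

    # exact deltaBeta of the deterministic part, probe-wise
    probe_delta = expit(
        probe_base[:, None] + meth_shift_latent[probe_gene_m, :]
    ) - expit(probe_base)[:, None]
    # gene-level shift in beta units (used for expression coupling)
    meth_shift_beta = expit(mu_gene[:, None] + meth_shift_latent) - expit(mu_gene)[
        :, None
    ]

    # ---- expression ------------------------------------------------------
    emin, emax = config.probes_per_gene_expr
    n_probes_e = expr_rng.integers(emin, emax + 1, size=n_genes)
    probe_gene_e = np.repeat(np.arange(n_genes), n_probes_e)
    n_ep = len(probe_gene_e)
    expr_base = expr_rng.normal(
        config.expr_baseline_mu, config.expr_baseline_sd, size=n_ep
    )
    expr_planted_shift = (
        planted_ch["over"].astype(float) - planted_ch["under"].astype(float)
    ) * config.expr_effect
    expr_shift = (
        config.cn_coef * cn_state.to_numpy(dtype=float)
        + config.meth_coef * meth_shift_beta
        + expr_planted_shift
    )
    expr_case = (
        expr_base[:, None]
        + expr_shift[probe_gene_e, :]
        + expr_rng.normal(0.0, config.expr_noise, size=(n_ep, n_case))
    )
    expr_ctrl = expr_base[:, None] + expr_rng.normal(
        0.0, config.expr_noise, size=(n_ep, len(control_samples))
    )
    expr_probe_ids = pd.Index([f"ep{i:06d}" for i in range(n_ep)], name="probe")
    expression = OmicsMatrix(
        pd.DataFrame(
            np.concatenate([expr_case, expr_ctrl], axis=1),
            index=expr_probe_ids,
            columns=case_samples + control_samples,
        ),
        role="vst",
        controls=tuple(control_samples),
    )
    expr_probe_map = pd.Series(
        gene_ids.to_numpy()[probe_gene_e], index=expr_probe_ids, name="gene"
    )

    # ---- ground truth ----------------------------------------------------
    truth_calls = CallMatrix(gene_ids, case_samples)
    truth_calls.set_channel("gain", cn_state.to_numpy() == 1)
    truth_calls.set_channel("loss", cn_state.to_numpy() == -1)
    # gene-level probe inclusion rule applied to the exact deltas
    hyper_probe = probe_delta > 0.4
    hypo_probe = probe_delta < -0.4
    truth_calls.set_channel(
        "hyper",
        np.logical_or.reduceat(
            hyper_probe, np.r_[0, np.cumsum(n_probes_m)[:-1]], axis=0
        ),
    )
    truth_calls.set_channel(
        "hypo",
        np.logical_or.reduceat(
            hypo_probe, np.r_[0, np.cumsum(n_probes_m)[:-1]], axis=0
        ),
    )
    truth_calls.set_channel("over", expr_shift > 1.0)
    truth_calls.set_channel("under", expr_shift < -1.0)

    truth = GroundTruth(
        calls=truth_calls,
        cn_state=cn_state,
        meth_shift_beta=pd.DataFrame(
            meth_shift_beta, index=gene_ids, columns=case_samples
        ),
        expr_shift=pd.DataFrame(expr_shift, index=gene_ids, columns=case_samples),
        planted_genes=plants.drop(columns=["sample_idx"]),
    )
    return SyntheticDataset(
        segments=segments,
        beta=beta,
        expression=expression,
        meth_probe_map=meth_probe_map,
        expr_probe_map=expr_probe_map,
        truth=truth,
        case_samples=case_samples,
        control_samples=control_samples,
    )
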