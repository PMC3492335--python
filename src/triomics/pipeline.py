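"""End-to-end pipeline: simulate -> call -> integrate -> depend ->
density-test -> diff -> cluster, with a reproducible run manifest.

Each stage reads only its declared inputs and writes TSV outputs under
the run directory; the manifest records seeds, input hashes and per-stage
row counts, so a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import calling, cluster, density, dependency, differential, integration, io
from .errors import ConfigurationError, TriomicsError
from .simulate import SimulationConfig, simulate_dataset, simulate_genome

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "simulate", "call", "integrate", "depend", "density-test", "diff", "cluster",
)


@dataclass
class PipelineConfig:
    """Configuration of a full run (synthetic-input mode)."""

    out_dir: str
    seed: int = 0
    simulation: SimulationConfig | None = None
    thresholds: calling.Thresholds = field(default_factory=calling.Thresholds)
    recurrence_k: int = 6
    correction_method: str = "bh"
    n_permutations: int = 1000
    per_arm: bool = True
    cluster_distance: str = "spearman"
    stages: tuple[str, ...] = ALL_STAGES

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stage(s): {sorted(unknown)}")
        if self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Execute the configured stages; return (and write) the run manifest."""
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": {}}
    p = lambda name: os.path.join(config.out_dir, name)

    state: dict = {}

    def record(stage: str, started: float, **info) -> None:
        manifest["stages"][stage] = dict(
            status="done", wall_time_s=round(time.time() - started, 3), **info
        )

    try:
        for stage in ALL_STAGES:
            if stage not in config.stages:
                manifest["stages"][stage] = dict(status="skipped")
                continue
            t0 = time.time()
            if stage == "simulate":
                genome = simulate_genome(config.simulation)
                data = simulate_dataset(config.simulation, genome)
                state.update(genome=genome, data=data)
                io.write_annotation(genome.annotation, p("annotation.tsv"))
                io.write_segments(data.segments, p("segments.tsv"))
                io.write_matrix(data.beta, p("beta.tsv"), id_label="probe")
                io.write_matrix(data.expression, p("expression.tsv"), id_label="probe")
                io.write_probe_map(data.meth_probe_map, p("meth_probe_map.tsv"))
                io.write_probe_map(data.expr_probe_map, p("expr_probe_map.tsv"))
                io.write_calls(data.truth.calls, p("truth_calls.tsv"))
                data.truth.planted_genes.to_csv(
                    p("planted_genes.tsv"), sep="\t", index=False
                )
                record(
                    "simulate", t0, n_genes=len(genome.annotation),
                    n_case_samples=len(data.case_samples),
                )
            elif stage == "call":
                data, genome = state["data"], state["genome"]
                calls = calling.build_call_matrix(
                    data.segments, data.beta, data.expression,
                    genome.annotation, data.meth_probe_map, data.expr_probe_map,
                    thresholds=config.thresholds,
                )
                state["calls"] = calls
                io.write_calls(calls, p("calls.tsv"))
                counts = calling.channel_counts(calls)
                counts.to_csv(p("channel_counts.tsv"), sep="\t")
                record("call", t0, n_universe=calls.n_genes,
                       n_calls=int(calls.values.sum()))
            elif stage == "integrate":
                result = integration.integrate(state["calls"], k=config.recurrence_k)
                state["integration"] = result
                result["table"].to_csv(p("recurrence_table.tsv"), sep="\t")
                result["curve"].to_csv(p("recurrence_curve.tsv"), sep="\t")
                result["selected"].to_csv(p("selected_genes.tsv"), sep="\t", index=False)
                result["additional"].to_csv(
                    p("additional_union_genes.tsv"), sep="\t", index=False
                )
                record("integrate", t0, n_selected=result["n_selected"],
                       n_additional=result["n_additional"])
            elif stage == "depend":
                dep = dependency.pairwise_dependency(
                    state["calls"], method=config.correction_method
                )
                cond = dependency.conditional_dependency(
                    state["calls"], method=config.correction_method
                )
                state["dependency"] = dep
                dep.to_csv(p("dependency.tsv"), sep="\t", index=False)
                cond.to_csv(p("dependency_conditional.tsv"), sep="\t", index=False)
                record("depend", t0, n_rows=len(dep) + len(cond))
            elif stage == "density-test":
                data, genome = state["data"], state["genome"]
                rows = []
                for direction, alternative in (("gain", "greater"), ("loss", "less")):
                    track = density.build_frequency_track(
                        data.segments, direction, config.thresholds
                    )
                    io.write_track(track, p(f"frequency_{direction}.tsv"))
                    res = density.permutation_test(
                        track, genome.annotation, n_perm=config.n_permutations,
                        alternative=alternative, seed=config.seed,
                    )
                    rows.append(dict(direction=direction, scope="genome",
                                     observed=res.observed, p_value=res.p_value))
                    if config.per_arm:
                        arm_df, summary = density.per_arm_tests(
                            track, genome.annotation,
                            centromeres=genome.centromeres,
                            n_perm=config.n_permutations,
                            alternative=alternative, seed=config.seed,
                        )
                        arm_df.insert(0, "direction", direction)
                        arm_df.to_csv(
                            p(f"density_arms_{direction}.tsv"), sep="\t", index=False
                        )
                        rows[-1]["n_arms_significant"] = summary["n_significant"]
                        rows[-1]["n_arms_tested"] = summary["n_tested"]
                pd.DataFrame(rows).to_csv(p("density_tests.tsv"), sep="\t", index=False)
                record("density-test", t0, n_tests=len(rows))
            elif stage == "diff":
                data = state["data"]
                meth = differential.differential_analysis(
                    data.beta, probe_map=data.meth_probe_map
                )
                expr = differential.differential_analysis(
                    data.expression, probe_map=data.expr_probe_map
                )
                meth["probes"].to_csv(p("differential_methylation.tsv"), sep="\t")
                expr["probes"].to_csv(p("differential_expression.tsv"), sep="\t")
                record(
                    "diff", t0,
                    n_meth_passed=int(meth["probes"]["passed"].sum()),
                    n_expr_passed=int(expr["probes"]["passed"].sum()),
                )
            elif stage == "cluster":
                data = state["data"]
                dend, labels = cluster.cluster_samples(
                    data.expression.values, distance=config.cluster_distance, cut_k=2
                )
                with open(p("dendrogram_expression.nwk"), "w", encoding="utf-8") as fh:
                    fh.write(dend.to_newick() + "\n")
                labels.rename_axis("sample").to_frame().to_csv(
                    p("cluster_labels.tsv"), sep="\t"
                )
                record("cluster", t0, n_leaves=len(dend.labels))
    except TriomicsError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise TriomicsError(f"stage {stage!r} failed: {exc}") from exc

    for name in sorted(os.listdir(config.out_dir)):
        path = os.path.join(config.out_dir, name)
        if os.path.isfile(path) and name != "manifest.json":
            manifest["outputs"][name] = _sha256(path)
    with open(p("manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
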