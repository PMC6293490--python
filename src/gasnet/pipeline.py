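"""Stage-wise pipeline with TSV artifact handoff.

Each stage reads its predecessors' files from the working directory and
writes its own, so externally produced tables (an edgeR differential-
expression table, a CHASM driver table) can replace the corresponding
artifact at the documented interface. ``run_all`` chains
simulate -> select-genes -> candidates -> ga -> core -> significance.
Every artifact carries the configuration and seed in ``#`` header lines.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .candidates import build_candidate_set, neighborhood_shells
from .coreextract import (
    build_core,
    gene_frequency,
    label_permutation_test,
    random_members_test,
    require_driver,
)
from .datatypes import ValidationError
from .ga import FitnessEvaluator, GAConfig, collect_optima, evolve
from .selection import (
    differential_expression,
    filter_drivers,
    filter_unexpressed_by_count,
    select_invasive_specific,
)
from .simulate import PlantedModule, SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)

ARTIFACTS = {
    "expression": "expression.tsv",
    "counts": "counts.tsv",
    "labels": "labels.tsv",
    "graph": "graph.tsv",
    "drivers": "drivers.tsv",
    "truth": "truth.tsv",
    "de_case_vs_intermediate": "de_case_vs_intermediate.tsv",
    "de_case_vs_control": "de_case_vs_control.tsv",
    "seeds": "seeds.tsv",
    "driver_genes": "driver_genes.txt",
    "candidates": "candidates.tsv",
    "optima": "ga_optima.tsv",
    "ga_log": "ga_log.tsv",
    "cores": "cores",
    "significance": "significance.tsv",
}


@dataclass
class PipelineConfig:
    """All pipeline settings, pre-filled with the method's defaults:
    fold change 2, FDR 0.05, median-FPKM threshold 1.0, radius 3,
    top 200 lncRNA targets, mutation rate 0.05, zeroToOneRate 19,
    500 generations, 5% elite, 50% frequency cutoff, driver score 0.8
    with p < 0.05, and 1000 permutations per significance test."""

    # synthetic-data stage
    n_genes: int = 400
    n_tfs: int = 20
    n_lncrnas: int = 5
    n_samples_per_class: int = 50
    mean_degree: float = 4.0
    n_modules: int = 1
    module_size: int = 5
    module_effect_size: float = 3.0
    noise_sd: float = 0.5
    n_driver_genes: int = 10
    driver_overlap_with_module: float = 0.1
    fraction_unexpressed: float = 0.1
    three_classes: bool = False
    # gene selection
    fc_threshold: float = 2.0
    fdr_threshold: float = 0.05
    fpkm_threshold: float = 1.0
    driver_score_threshold: float = 0.8
    driver_p_threshold: float = 0.05
    control_class: str = "normal"
    case_class: str = "invasive"
    intermediate_class: str = "ais"
    # candidate expansion
    radius: int = 3
    top_k_lnc: int = 200
    # GA
    population_size: int = 200
    generations: int = 500
    mutation_rate: float = 0.05
    zero_to_one_rate: float = 19
    elite_fraction: float = 0.05
    n_bins: Union[int, str] = "auto"
    # core + significance
    frequency_cutoff: float = 0.5
    n_perm: int = 1000
    # global
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def with_overrides(self, overrides: dict) -> "PipelineConfig":
        merged = {**dataclasses.asdict(self)}
        for key, value in overrides.items():
            if key not in merged:
                raise ValidationError(f"unknown config key {key!r}")
            merged[key] = _coerce(value, type(merged[key]))
        return PipelineConfig(**merged)

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(
            n_genes=self.n_genes,
            n_tfs=self.n_tfs,
            n_lncrnas=self.n_lncrnas,
            n_samples_per_class=self.n_samples_per_class,
            mean_degree=self.mean_degree,
            planted_modules=tuple(
                PlantedModule(self.module_size, self.module_effect_size)
                for _ in range(self.n_modules)
            ),
            noise_sd=self.noise_sd,
            n_driver_genes=self.n_driver_genes,
            driver_overlap_with_module=self.driver_overlap_with_module,
            fraction_unexpressed=self.fraction_unexpressed,
            three_classes=self.three_classes,
            rng_seed=self.rng_seed,
        )

    def ga_config(self, rng_seed: Optional[int] = None) -> GAConfig:
        return GAConfig(
            population_size=self.population_size,
            generations=self.generations,
            mutation_rate=self.mutation_rate,
            zero_to_one_rate=self.zero_to_one_rate,
            elite_fraction=self.elite_fraction,
            n_bins=self.n_bins,
            rng_seed=self.rng_seed if rng_seed is None else rng_seed,
        )

    def header_comments(self) -> list[str]:
        return [
            f"seed: {self.rng_seed}",
            "config: " + json.dumps(dataclasses.asdict(self), sort_keys=True),
        ]


def _coerce(value, target_type):
    if isinstance(value, str) and target_type is not str:
        if target_type is bool:
            return value.lower() in ("1", "true", "yes")
        try:
            return target_type(value)
        except (TypeError, ValueError):
            return value  # e.g. n_bins="auto"
    return value


def _require(out_dir: Path, key: str, producer: str) -> Path:
    path = out_dir / ARTIFACTS[key]
    if not path.exists():
        raise ValidationError(
            f"missing artifact {path.name}; run the {producer!r} stage first"
        )
    return path


def _derive(base: int, *stream: int) -> int:
    return int(np.random.default_rng([base, *stream]).integers(2**31 - 1))


def stage_simulate(config: PipelineConfig, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ds = simulate_dataset(config.simulation_config())
    hdr = config.header_comments()
    gio.write_expression(ds.expr, out_dir / ARTIFACTS["expression"],
                         counts_path=out_dir / ARTIFACTS["counts"],
                         header_comments=hdr)
    gio.write_labels(ds.labels, out_dir / ARTIFACTS["labels"], hdr)
    gio.write_graph(ds.graph, out_dir / ARTIFACTS["graph"], hdr)
    gio.write_drivers(ds.drivers, out_dir / ARTIFACTS["drivers"], hdr)
    gio._write_tsv(ds.truth, out_dir / ARTIFACTS["truth"], hdr, index=False)


def stage_select_genes(config: PipelineConfig, out_dir) -> None:
    out_dir = Path(out_dir)
    expr = gio.read_expression(
        _require(out_dir, "expression", "simulate"),
        counts_path=out_dir / ARTIFACTS["counts"]
        if (out_dir / ARTIFACTS["counts"]).exists() else None,
    )
    labels_path = _require(out_dir, "labels", "simulate")
    if expr.raw_counts is not None:
        expr = filter_unexpressed_by_count(expr)
    hdr = config.header_comments()

    labels_cc = gio.read_labels(
        labels_path, comparison=(config.control_class, config.case_class)
    )
    de_control = differential_expression(expr, labels_cc)
    gio.write_de_table(de_control, out_dir / ARTIFACTS["de_case_vs_control"], hdr)
    classes = set(labels_cc.assignments.unique())
    if config.intermediate_class in classes:
        labels_ic = gio.read_labels(
            labels_path,
            comparison=(config.intermediate_class, config.case_class),
        )
        de_intermediate = differential_expression(expr, labels_ic)
    else:
        # two-class design: the single comparison plays both roles
        de_intermediate = de_control
    gio.write_de_table(
        de_intermediate, out_dir / ARTIFACTS["de_case_vs_intermediate"], hdr
    )
    seeds = select_invasive_specific(
        de_intermediate, de_control,
        fc_threshold=config.fc_threshold,
        fdr_threshold=config.fdr_threshold,
    )
    gio._write_tsv(seeds, out_dir / ARTIFACTS["seeds"], hdr, index=False)

    drivers = gio.read_drivers(_require(out_dir, "drivers", "simulate"))
    driver_genes = sorted(
        filter_drivers(drivers, config.driver_score_threshold,
                       config.driver_p_threshold)
    )
    with open(out_dir / ARTIFACTS["driver_genes"], "w") as fh:
        for c in hdr:
            fh.write(f"# {c}\n")
        fh.write("\n".join(driver_genes) + "\n")


def stage_candidates(config: PipelineConfig, out_dir) -> None:
    out_dir = Path(out_dir)
    expr = gio.read_expression(_require(out_dir, "expression", "simulate"))
    graph = gio.read_graph(_require(out_dir, "graph", "simulate"))
    seeds = pd.read_csv(
        _require(out_dir, "seeds", "select-genes"), sep="\t", comment="#"
    )["gene"].tolist()
    rows = []
    for i, seed in enumerate(seeds):
        try:
            cand = build_candidate_set(
                graph, expr, seed,
                radius=config.radius,
                fpkm_threshold=config.fpkm_threshold,
                top_k_lnc=config.top_k_lnc,
                rng_seed=_derive(config.rng_seed, 11, i),
            )
        except ValidationError as exc:
            logger.warning("seed %s skipped: %s", seed, exc)
            continue
        shells = neighborhood_shells(graph, seed, config.radius)
        for gene in cand.genes:
            rows.append({"seed": seed, "gene": gene,
                         "shell": shells.get(gene, 1)})
        if not cand.genes:   # edge-less seed: keep a marker row
            rows.append({"seed": seed, "gene": "", "shell": 0})
    frame = pd.DataFrame(rows, columns=["seed", "gene", "shell"])
    gio._write_tsv(frame, out_dir / ARTIFACTS["candidates"],
                   config.header_comments(), index=False)


def stage_ga(config: PipelineConfig, out_dir) -> None:
    from .candidates import CandidateSet

    out_dir = Path(out_dir)
    expr = gio.read_expression(_require(out_dir, "expression", "simulate"))
    labels = gio.read_labels(
        _require(out_dir, "labels", "simulate"),
        comparison=(config.control_class, config.case_class),
    )
    cand_frame = pd.read_csv(
        _require(out_dir, "candidates", "candidates"), sep="\t", comment="#",
        keep_default_na=False,
    )
    ev = FitnessEvaluator(expr, labels, n_bins=config.n_bins)
    optima_rows, log_rows = [], []
    for i, (seed, grp) in enumerate(cand_frame.groupby("seed", sort=True)):
        genes = tuple(sorted(g for g in grp["gene"] if g))
        cand = CandidateSet(seed=seed, genes=genes, radius_used=config.radius)
        t0 = time.perf_counter()
        run = evolve(cand, expr, labels,
                     config.ga_config(rng_seed=_derive(config.rng_seed, 13, i)),
                     evaluator=ev)
        logger.info("GA for seed %s (%d candidates): %.1fs",
                    seed, len(genes), time.perf_counter() - t0)
        for members in collect_optima(run):
            optima_rows.append({
                "seed": seed,
                "fitness": run.best_fitness,
                "members": ",".join(sorted(members)),
            })
        for gen, (b, m) in enumerate(
            zip(run.best_per_generation, run.mean_per_generation)
        ):
            log_rows.append({
                "seed": seed, "generation": gen, "best_fitness": b,
                "mean_fitness": m, "elite_size": run.config.n_elite,
            })
    hdr = config.header_comments()
    gio._write_tsv(pd.DataFrame(optima_rows,
                                columns=["seed", "fitness", "members"]),
                   out_dir / ARTIFACTS["optima"], hdr, index=False)
    gio._write_tsv(pd.DataFrame(log_rows, columns=["seed", "generation",
                                                   "best_fitness",
                                                   "mean_fitness",
                                                   "elite_size"]),
                   out_dir / ARTIFACTS["ga_log"], hdr, index=False)


def _read_driver_genes(path) -> set[str]:
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.add(line)
    return out


def stage_core(config: PipelineConfig, out_dir) -> None:
    out_dir = Path(out_dir)
    graph = gio.read_graph(_require(out_dir, "graph", "simulate"))
    driver_genes = _read_driver_genes(
        _require(out_dir, "driver_genes", "select-genes")
    )
    optima = pd.read_csv(
        _require(out_dir, "optima", "ga"), sep="\t", comment="#",
        keep_default_na=False,
    )
    cores = []
    for seed, grp in optima.groupby("seed", sort=True):
        member_sets = [
            frozenset(m.split(",")) for m in grp["members"] if m
        ]
        surviving = require_driver(member_sets, driver_genes)
        if not surviving:
            continue
        core = build_core(
            gene_frequency(surviving), seed=seed, graph=graph,
            drivers=driver_genes, cutoff=config.frequency_cutoff,
            n_optima=len(member_sets),
        )
        if core is not None:
            cores.append(core)
    if cores:
        gio.write_subnetworks(cores, out_dir / ARTIFACTS["cores"],
                              header_comments=config.header_comments())
    else:
        logger.warning("no core subnetworks produced")
        (out_dir / ARTIFACTS["cores"]).mkdir(parents=True, exist_ok=True)
        with open(out_dir / ARTIFACTS["cores"] / "cores.json", "w") as fh:
            fh.write("[]\n")


def stage_significance(config: PipelineConfig, out_dir) -> None:
    out_dir = Path(out_dir)
    expr = gio.read_expression(_require(out_dir, "expression", "simulate"))
    labels = gio.read_labels(
        _require(out_dir, "labels", "simulate"),
        comparison=(config.control_class, config.case_class),
    )
    cores_dir = out_dir / ARTIFACTS["cores"]
    if not (cores_dir / "cores.json").exists():
        raise ValidationError(
            "missing artifact cores/cores.json; run the 'core' stage first"
        )
    cores = gio.read_subnetworks(cores_dir)
    ev = FitnessEvaluator(expr, labels, n_bins=config.n_bins)
    expressed = expr.expressed_genes(config.fpkm_threshold)
    out = []
    for i, core in enumerate(sorted(cores, key=lambda c: c.seed)):
        fitness = ev.fitness_of_members(core.members)
        p_label = label_permutation_test(
            core, expr, labels, n_perm=config.n_perm,
            rng_seed=_derive(config.rng_seed, 17, i), evaluator=ev,
        )
        p_rand = random_members_test(
            core, expr, labels, gene_universe=expressed,
            n_perm=config.n_perm,
            rng_seed=_derive(config.rng_seed, 19, i), evaluator=ev,
        )
        out.append(core.with_stats(fitness=float(fitness),
                                   p_label_perm=p_label,
                                   p_random_members=p_rand))
    if out:
        gio.write_subnetworks(out, cores_dir,
                              header_comments=config.header_comments())
    gio._write_tsv(gio.core_summary_frame(out),
                   out_dir / ARTIFACTS["significance"],
                   config.header_comments(), index=False)


STAGES = {
    "simulate": stage_simulate,
    "select-genes": stage_select_genes,
    "candidates": stage_candidates,
    "ga": stage_ga,
    "core": stage_core,
    "significance": stage_significance,
}
STAGE_ORDER = ["simulate", "select-genes", "candidates", "ga", "core",
               "significance"]


def run_stage(command: str, config: PipelineConfig, out_dir) -> None:
    if command == "run-all":
        return run_all(config, out_dir)
    if command not in STAGES:
        raise ValidationError(f"unknown stage {command!r}")
    STAGES[command](config, out_dir)


def run_all(config: PipelineConfig, out_dir) -> None:
    for name in STAGE_ORDER:
        t0 = time.perf_counter()
        STAGES[name](config, out_dir)
        logger.info("stage %s: %.1fs", name, time.perf_counter() - t0)
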