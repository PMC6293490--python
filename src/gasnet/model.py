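"""Model/results interface to the subnetwork search.

:class:`SubnetworkSearch` bundles the data (expression, phenotype labels,
interaction graph, driver table) with the search settings; ``fit()`` runs
the per-seed genetic-algorithm searches, driver filtering, frequency
voting, and permutation tests, returning a
:class:`SubnetworkSearchResults` carrying the core subnetworks, their
fitnesses and empirical p-values, the per-seed diagnostics, and a
``summary()`` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as gio
from .candidates import build_candidate_set
from .coreextract import (
    build_core,
    gene_frequency,
    label_permutation_test,
    random_members_test,
    require_driver,
)
from .datatypes import (
    CoreSubnetwork,
    DriverTable,
    ExpressionMatrix,
    InteractionGraph,
    PhenotypeLabels,
    ValidationError,
)
from .ga import FitnessEvaluator, GAConfig, GARun, collect_optima, evolve
from .selection import filter_drivers

logger = logging.getLogger(__name__)


def _derive_seed(base: int, *stream: int) -> int:
    """Deterministic per-stage RNG seed below 2**31."""
    return int(np.random.default_rng([base, *stream]).integers(2**31 - 1))


class SubnetworkSearch:
    """Search for phenotype-discriminative subnetworks around seed genes.

    Parameters
    ----------
    expr : ExpressionMatrix
        FPKM-like abundances; fitness uses the samples of the labels'
        binary comparison only.
    labels : PhenotypeLabels
    graph : InteractionGraph
    drivers : DriverTable
        CHASM-style per-gene (score, p-value) table.
    seeds : sequence of gene ids
        One GA search is rooted at each seed (typically the
        invasion-specific differentially expressed genes).
    ga_config : GAConfig, optional
        Search parameters; per-seed RNG streams are derived from its
        ``rng_seed``.
    radius : int
        Maximum graph distance from the seed for candidate genes.
    fpkm_threshold : float
        Median-abundance cutoff below which genes are unexpressed.
    frequency_cutoff : float
        Gene-frequency vote threshold for core membership (inclusive).
    n_perm : int
        Permutations for each significance test.
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        labels: PhenotypeLabels,
        graph: InteractionGraph,
        drivers: DriverTable,
        seeds: Sequence[str],
        ga_config: Optional[GAConfig] = None,
        radius: int = 3,
        fpkm_threshold: float = 1.0,
        top_k_lnc: int = 200,
        frequency_cutoff: float = 0.5,
        driver_score_threshold: float = 0.8,
        driver_p_threshold: float = 0.05,
        n_perm: int = 1000,
    ):
        labels.validate_against(expr)
        self.expr = expr
        self.labels = labels
        self.graph = graph
        self.drivers = drivers
        self.seeds = list(seeds)
        self.ga_config = ga_config or GAConfig()
        self.radius = radius
        self.fpkm_threshold = fpkm_threshold
        self.top_k_lnc = top_k_lnc
        self.frequency_cutoff = frequency_cutoff
        self.driver_score_threshold = driver_score_threshold
        self.driver_p_threshold = driver_p_threshold
        self.n_perm = n_perm

    @classmethod
    def from_files(
        cls,
        expression_path,
        labels_path,
        graph_path,
        drivers_path,
        seeds: Sequence[str],
        comparison: Optional[tuple[str, str]] = None,
        **kwargs,
    ) -> "SubnetworkSearch":
        return cls(
            expr=gio.read_expression(expression_path),
            labels=gio.read_labels(labels_path, comparison=comparison),
            graph=gio.read_graph(graph_path),
            drivers=gio.read_drivers(drivers_path),
            seeds=seeds,
            **kwargs,
        )

    def fit(self) -> "SubnetworkSearchResults":
        cfg = self.ga_config
        ev = FitnessEvaluator(self.expr, self.labels, n_bins=cfg.n_bins)
        driver_set = filter_drivers(
            self.drivers, self.driver_score_threshold, self.driver_p_threshold
        )
        expressed = self.expr.expressed_genes(self.fpkm_threshold)
        cores: list[CoreSubnetwork] = []
        records = []
        runs: dict[str, GARun] = {}
        for i, seed in enumerate(self.seeds):
            rec = {"seed": seed, "n_candidates": 0, "n_optima": 0,
                   "best_fitness": np.nan, "core_size": 0}
            try:
                cand = build_candidate_set(
                    self.graph, self.expr, seed,
                    radius=self.radius,
                    fpkm_threshold=self.fpkm_threshold,
                    top_k_lnc=self.top_k_lnc,
                    rng_seed=_derive_seed(cfg.rng_seed, 11, i),
                )
            except ValidationError as exc:
                logger.warning("skipping seed %s: %s", seed, exc)
                records.append(rec)
                continue
            seed_cfg = GAConfig(
                **{**cfg.__dict__, "rng_seed": _derive_seed(cfg.rng_seed, 13, i)}
            )
            run = evolve(cand, self.expr, self.labels, seed_cfg, evaluator=ev)
            runs[seed] = run
            optima = collect_optima(run)
            rec.update(
                n_candidates=len(cand),
                n_optima=len(optima),
                best_fitness=run.best_fitness,
            )
            surviving = require_driver(optima, driver_set)
            core = None
            if surviving:
                freq = gene_frequency(surviving)
                core = build_core(
                    freq, seed=seed, graph=self.graph, drivers=driver_set,
                    cutoff=self.frequency_cutoff, n_optima=len(optima),
                )
            if core is not None:
                fitness = ev.fitness_of_members(core.members)
                p_label = label_permutation_test(
                    core, self.expr, self.labels, n_perm=self.n_perm,
                    rng_seed=_derive_seed(cfg.rng_seed, 17, i), evaluator=ev,
                )
                p_rand = random_members_test(
                    core, self.expr, self.labels, gene_universe=expressed,
                    n_perm=self.n_perm,
                    rng_seed=_derive_seed(cfg.rng_seed, 19, i), evaluator=ev,
                )
                core = core.with_stats(
                    fitness=float(fitness),
                    p_label_perm=p_label,
                    p_random_members=p_rand,
                )
                cores.append(core)
                rec["core_size"] = core.size
            records.append(rec)
        return SubnetworkSearchResults(
            model=self,
            cores=cores,
            seed_records=pd.DataFrame(
                records,
                columns=["seed", "n_candidates", "n_optima",
                         "best_fitness", "core_size"],
            ),
            runs=runs,
        )


@dataclass
class SubnetworkSearchResults:
    """Fitted search results.

    Attributes
    ----------
    cores : list of CoreSubnetwork
        One consensus subnetwork per seed that survived the driver filter
        and the frequency vote, with fitness and both empirical p-values.
    seed_records : DataFrame
        Per-seed diagnostics (candidate-set size, number of equally
        optimal subnetworks, best fitness, core size; 0 = no core).
    runs : dict seed -> GARun
        Full GA runs, including best/mean fitness trajectories.
    """

    model: SubnetworkSearch
    cores: list
    seed_records: pd.DataFrame
    runs: dict = field(default_factory=dict)

    @property
    def n_cores(self) -> int:
        return len(self.cores)

    def significance_frame(self) -> pd.DataFrame:
        return gio.core_summary_frame(self.cores)

    def optima_count_distribution(self) -> pd.Series:
        """How many equally optimal subnetworks each seed produced."""
        return self.seed_records.set_index("seed")["n_optima"]

    def summary(self) -> str:
        lines = [
            "Discriminative subnetwork search",
            "=" * 48,
            f"seeds searched:        {len(self.model.seeds)}",
            f"comparison:            {self.model.labels.comparison[0]} vs "
            f"{self.model.labels.comparison[1]}",
            f"core subnetworks:      {self.n_cores}",
            "",
            "seed       size  n_optima   fitness  p_label  p_random  drivers",
        ]
        for c in sorted(self.cores, key=lambda c: c.seed):
            lines.append(
                f"{c.seed:<10} {c.size:>4}  {c.n_optima or 0:>8}  "
                f"{c.fitness:>8.4f}  {c.p_label_perm:>7.4f}  "
                f"{c.p_random_members:>8.4f}  {','.join(sorted(c.drivers))}"
            )
        if not self.cores:
            lines.append("(none)")
        return "\n".join(lines)

    def save(self, out_dir, header_comments: Sequence[str] = ()) -> None:
        gio.write_subnetworks(self.cores, out_dir,
                              header_comments=header_comments)

    def plot_trajectories(self, ax=None):
        """Best-fitness-per-generation curves, one line per seed."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for seed, run in sorted(self.runs.items()):
            ax.plot(run.best_per_generation, label=seed)
        ax.set_xlabel("generation")
        ax.set_ylabel("best fitness (-MI, bits)")
        ax.legend(fontsize="x-small")
        return ax
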