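# Methods

## Model

`gasnet` treats discriminative-subnetwork discovery as a combinatorial
feature-selection problem per seed gene. Given an expression matrix
X ∈ R_{≥0}^{G×S}, a binary phenotype contrast y over the samples, an
interaction graph, and a seed s, the search space is the power set of the
seed's candidate genes (expressed genes within graph radius 3). A member
set M (always containing s) is scored by

    fitness(M) = − I( disc(a_M) ; y ),   a_M(j) = mean_{g∈M} z_g(j)

where z_g is gene g's expression z-scored across the comparison samples
(a zero-variance gene contributes zeros), disc(·) bins the activity into
equal-width bins over its observed range, and I is plug-in mutual
information in bits. Fitness is negated MI so that the genetic algorithm,
which keeps the *smallest* values, maximizes discrimination. The attainable
range is [−log2(min(bins, classes)), 0]; with a binary contrast the floor
is −1 bit.

**Aggregation is an assumption.** How member genes are combined before MI
is the one step of the procedure with no canonical definition; the
z-score-mean activity used here is the standard choice in the
discriminative-subnetwork literature and is deterministic, but it is
deliberately isolated behind `subnetwork_activity`/`FitnessEvaluator`
so an alternative statistic can be plugged in.

## Genetic algorithm

Binary chromosomes of length L = |candidates|; the seed is implicit and
unconditional. Defaults (all configurable in `GAConfig`):

| parameter | default | meaning |
|---|---|---|
| population_size | 200 | chromosomes per generation |
| generations | 500 | search length; improvement typically stops by ~300 |
| mutation_rate | 0.05 | per-bit mutation probability |
| zero_to_one_rate | 19 | a mutated/initial bit is 1 w.p. 1/(rate+1) = 0.05 |
| elite_fraction | 0.05 | top fraction copied unchanged (elitism) |
| immigrant_fraction | 0.05 | fraction replaced by fresh random chromosomes |
| n_bins | "auto" | Sturges' rule: ceil(log2 S) + 1 |

The zeroToOneRate semantics — both initialization density and the value a
mutated bit takes — encode a sparsity prior: larger rates leave fewer
genes selected, which is what makes 18,000-gene candidate sets
searchable. Elite ordering breaks fitness ties by fewer selected genes,
then lexicographic bit pattern, so runs are fully deterministic under a
seed.

Selection and crossover are not dictated by the sparsity prior and were
chosen for robustness: rank-weighted parent sampling (linear weights)
with uniform crossover. Because an extinct 1-bit re-enters only with
probability 0.0025 per child under the mutation semantics, each
generation also receives 5% *random immigrants* whose bit density is
drawn uniformly between the sparse prior and 0.5; this keeps denser
optima reachable without touching the published mutation/elitism rules.
All equally optimal member sets (within 1e−12) are collected from the
final population; this tie tolerance also governs the plateau comparison,
since two populations at the MI floor can differ by summation round-off.

## Pipeline around the search

- **Expression filters.** Genes with median raw count 0 are dropped before
  differential expression; genes with median abundance < 1 (FPKM units)
  are removed from candidate sets *after* traversal — an unexpressed gene
  cannot be a member but does not block paths.
- **Differential expression** is pluggable. The built-in test is a
  two-sample t-test on log2(x+1) with BH-FDR and log2 fold changes using
  a pseudocount of 1; its TSV interface matches an edgeR table, which can
  be substituted verbatim. Phenotype-specific genes must pass
  |FC| > 2 and FDR < 0.05 in *both* configured comparisons
  (case-vs-intermediate and case-vs-control); genes with discordant
  fold-change signs between comparisons are dropped with a warning.
- **Drivers.** A gene is a putative driver when score > 0.8 (strict; a
  non-strict variant is available) and p < 0.05.
- **Core extraction.** Optimal subnetworks without any driver are removed;
  remaining genes are voted by frequency, and the 50% cutoff is inclusive
  (the rule removes *low*-frequency genes). A seed whose surviving members
  contain no driver yields no core.
- **Significance.** Both permutation nulls compare the core's fitness on
  unpermuted data against 1000 resampled fitnesses, with the add-one
  estimator p = (1 + #{null ≤ observed})/(N + 1), so p ∈ [1/(N+1), 1].
  When fewer distinct label assignments than permutations exist, the
  label null is enumerated exhaustively and p is the exact tail fraction.
  The random-members null draws from the expressed genome rather than the
  seed's candidate set (a genomic-background null; candidate-set nulls
  are a configurable alternative).

## Synthetic benchmark

The generator emulates the statistical structure the pipeline assumes,
not any real dataset: a gnm random graph (mean degree 4) with typed
nodes, lognormal background expression (log2 baselines U[2,7], noise SD
0.5 in log2 units) identical across classes, planted modules wired as
shallow trees within radius 3 of their seed and shifted by d·(noise SD)
on the log2 scale in the case class (d/2 in the optional intermediate
class, mirroring a normal/in-situ/invasive design), Poisson raw counts,
~10% unexpressed genes, and a driver table whose super-threshold genes
overlap the planted modules by a configurable fraction — by default most
drivers are background genes, i.e. not differentially expressed. Effect
sizes on the log scale make the |FC| > 2 threshold analytic: at noise SD
0.5, d = 3 is a true fold change of 2^1.5 ≈ 2.8.

The standard benchmark is one 5-gene module at d = 3 with 50 samples per
class among 400 genes, one of the 10 drivers inside the module. What the
generator does *not* model: count-level mean–variance coupling (no
negative-binomial dispersion), correlated background co-expression,
batch effects, or realistic graph topology (no scale-free hubs). Passing
tests therefore demonstrate correctness and calibration of the machinery
under the planted model, not performance on real tumor data.

Problem sizes in the test and reproduction suites (enumerable instances
of ≤ 15 candidates; 10 pipeline replicates; 200 calibration repetitions
with 99 permutations; 5 plateau runs) were chosen so the whole suite
completes in minutes on a single core while keeping every binomial
acceptance band meaningful.

## Numerical and design notes

- MI saturates at H(y) = 1 bit for a binary contrast, so several member
  sets often tie at the floor; the frequency vote across ties
  is what turns them into one core. A consequence: a single core tends to
  be a *minimal* separating subset, and module recovery is assessed on
  the best core across the module's seeds.
- Equal-width binning maps a constant activity vector to a single bin
  (MI 0); bin index floor((v−min)/range·k) is clipped to k−1 so the
  maximum lands in the last bin.
- Per-seed, per-stage RNG streams are derived from one base seed via
  seed sequences, so every artifact is a pure function of (inputs,
  config, seed) and reruns are byte-identical.
- Degenerate cases: a seed with no interactions skips the GA and is
  scored as a seed-only subnetwork; an all-constant gene set yields
  fitness 0; empty driver sets legally yield zero cores.

## Known limitations

- The GA guarantees nothing outside the sparse-optimum regime its prior
  encodes: on data where the empirical-MI optimum is a dense
  noise-overfit subset (very small samples, weak effects), it will —
  by design — return a sparse near-optimum instead.
- The lncRNA target ranking regresses each candidate target on the
  lncRNA plus 50 random co-regulators; it preserves GENIE3's
  relative-importance semantics at desk scale but is not a reproduction
  of genome-wide GENIE3 output.
- No multiple-testing correction is applied across seeds; the two
  p-values are per-core.
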