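# Methods

## Model overview

`clonetrace` simulates a cellular-barcoding experiment as four sequential
stochastic stages and scores how well the final clustering recovers the
ground-truth clonal structure. Ground truth is the founder id carried by
every cell; nothing in the dynamics reads a barcode set, so the dynamics are
strictly neutral.

### Integration

Uniform mode: each of the `B` barcode types integrates into each of the `S`
cells independently with probability `p_in`, giving set sizes
`L ~ Binomial(B, p_in)` and mean `M = p_in B` (the MOI). Sampling draws `L`
first and then `L` distinct type ids (rejection sampling, O(L) per cell for
`L ≪ B`), which is distribution-identical to `B` Bernoulli trials but scales
to `B = 10⁶`. Cells with `L = 0` are kept: the labeled fraction
`1 − (1 − p_in)^B → 1 − e^{−M}` is part of the design trade-off, and the MOI
estimator `M = −ln(1 − f)` inverts it.

Biased mode: per-cell exposure is `u·M` with `u ~ Gamma(shape k, mean 1)`;
the integration-event count is Poisson at that exposure, and each event picks
a type from a log-normally skewed abundance vector (σ = `abundance_skew`).
Event counts then have variance `M + M²/k`, reproducing the reported
over-dispersion, and the model degenerates to the uniform Poisson limit as
`k → ∞` with σ = 0. This concrete compound construction is the package's own
choice of a mechanism with the right qualitative properties (over-dispersion,
uniform limit); no claim is made that real libraries follow exactly a
Gamma/log-normal law.

### Propagation

Default engine (`synchronized_doubling`): every generation each cell divides
into two daughters (ids `2i`, `2i+1` — bit-reproducible given a seed), and
the culture is uniformly subsampled without replacement back to `target_size`
every `passaging_period` generations (default: every generation, back to
`S`). This is the most aggressive passaging schedule consistent with a
fixed-size culture; both knobs are exposed for sweeps. Passaging is skipped
while the culture is still below the target, so small seed cultures first
grow into the target size.

The `wright_fisher` engine replaces double-then-subsample by multinomial
resampling of parents. The two engines are *not* interchangeable per
generation: offspring variance is 1/2 for double-then-halve (hypergeometric
thinning of two daughters) versus ≈1 for Wright-Fisher, so lineage loss —
governed for critical branching processes by variance × time — runs about
twice as fast under Wright-Fisher. They agree on the drift time scale (WF at
`t` generations ≈ doubling-splitting at `2t`), which is what the test suite
asserts; at equal generation counts they agree only to within that factor.

Snapshots (default generations 0, 5, 10, 15) are nondestructive reads of the
post-passage population, so each snapshot holds exactly `S` cells;
`snapshot_fraction < 1` optionally records a random subsample.

### Observation

Each integrated barcode of each snapshot cell is read with probability
`1 − p_drop`, independently across barcodes, cells and snapshots (each
snapshot uses a spawned RNG substream, so the same surviving cell re-observed
later sees fresh noise). Dropout is deliberately homogeneous — no
cell-state, batch or expression-level dependence — matching the scalar-rate
abstraction the model is built on. Unlabeled and fully-dropped cells remain
in the observed table; they are excluded from clustering but counted, since
the labeled/unlabeled split carries design information.

### Reconstruction

Observed cells from all snapshots are pooled. Pairwise Jaccard dissimilarity
is computed through a sparse cell×barcode boolean product (dense pairwise
vectors over `B = 10⁶` types would be infeasible), cells ordered
deterministically by (generation, cell_id). Single linkage is not a free
choice: its flat clusters at height `h` are exactly the connected components
of the graph with edges `{d ≤ h}`, which is what the "any non-zero overlap"
threshold means. The three cuts:

* `any_overlap` — threshold `1 − 10⁻⁹`. Jaccard values below 1 are rationals
  bounded away from 1 by at least `1/|X∪Y|` ≥ 2.5·10⁻⁷ at the largest
  supported problem sizes, so the epsilon cannot misclassify a pair.
* `min_d` — threshold 0: only identical observed sets merge. This realizes
  the maximal cluster count the dendrogram supports, so it coincides with
  scanning thresholds against the cell count (cells as the upper proxy for
  the lineage count); both readings are implemented
  (`cut_min`, `cut_by_target_count(target=n_cells)`).
* `true_count` — scans 0 plus all merge heights and picks the cut whose
  cluster count is closest to the known lineage count; ties prefer the
  smaller threshold (more clusters), a deterministic and conservative rule.

### Scoring

A *true propagated lineage* is a labeled founder with ≥1 descendant in ≥1
analyzed snapshot. The accurate-lineage ratio counts lineages whose observed
labeled cells equal some inferred cluster *exactly* — the strictest reading;
founders whose every observed descendant dropped to an empty set stay in the
denominator (they propagated but cannot be recovered — this is how high
dropout depresses the ratio). A relaxed majority-overlap rule is available
behind a flag but is not the default. Cell-level partition agreement is
reported as the Fowlkes–Mallows index (pair counting; defined as 1 when both
partitions are all singletons, undefined when only one is) and the v-measure
(entropy-based, β = 1).

## Closed-form analytics

With per-barcode cell counts ≈ Poisson((S/B)M), the probability that a given
barcode avoids multiple integration is `(1 + (S/B)M)·e^{−(S/B)M}`; requiring
the complement to stay below ~1/S yields the library-size rule
`B ≳ S^{3/2} M`. After dropout at rate `p`, two cells sharing an integrated
`L`-set read identically with probability `(2p² − 2p + 1)^L − p^{2L}`
(the `L = 0` case evaluates to 0 — empty-vs-empty comparisons are excluded by
convention), and Poisson-averaging over `L` gives
`e^{−2p(1−p)M} − e^{−(1−p²)M}`. The interior maximizer in `M` is located by
bounded scalar minimization (xatol 10⁻⁶) on (0, 50]; the formulas involve no
exponents large enough to need log-space evaluation in the supported
parameter ranges (|exponent| < 30 everywhere the calculators accept).

## Randomness and reproducibility

Every stochastic routine takes an explicit `numpy.random.Generator`.
Sweeps derive the stream for replicate `r` at grid point `g` from
`SeedSequence([root_seed, g, r])`, so results are byte-identical across
reruns and invariant to removing other grid points. Snapshot observation
spawns one child stream per snapshot.

## Problem sizes used in the test suite

The suite checks distributional identities at `n = 10⁵` draws (binomial/
Poisson fits, thinning identities, over-dispersion), clustering-vs-components
equivalence on 200 random instances of up to 40 cells, and pipeline-level
contrasts at `S = 10³` (MOI contrast, 20 replicates), `S = 500` (complexity
saturation, 20 replicates) and `S = 10⁴, B = 10⁶` (the worked design
example, 10 replicates). These sizes give Monte-Carlo standard errors well
inside the asserted 3σ bands while keeping the full suite under a minute of
simulation time; the assertions are against pre-stated analytic values or
independent brute-force oracles, never against previously recorded outputs.

## What the generator does and does not emulate

The synthetic data reproduce the mechanisms the model isolates: random
multi-integration, neutral drift through passaging bottlenecks, and
homogeneous dropout. They do not include barcode swapping between cells,
epigenetic silencing, batch- or cell-state-dependent dropout, sequence-level
errors in barcode calling, or selective (non-neutral) clone dynamics.
Passing tests therefore validate the reconstruction machinery and the design
trade-offs *within this model class*, not the behavior of any specific
experimental platform.

## Known limitations

* The biased-integration mechanism is one plausible over-dispersed model;
  fitted susceptibility/abundance parameters from a real library would be
  needed for quantitative predictions in the biased regime.
* The accurate-lineage ratio's exact-set-equality rule is strict; pipelines
  tolerating small impurities will score higher than this default reports.
* `integration_probability_exact` enumerates subsets and is limited to pools
  of ≤ 20 types; it exists as an oracle, not a production path.
* Continuous-time (Gillespie) growth, cell death, and fitness differences
  are out of scope; the propagation engines are synchronous.
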