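# clonetrace

Simulation and design analytics for **cellular barcoding lineage-tracing
experiments** — for experimentalists choosing a multiplicity of infection
(MOI), barcode library complexity and sequencing depth before committing
cells and reagents, and for computational biologists who want a ground-truthed
sandbox for lineage-reconstruction pipelines.

## The problem

In lentiviral barcoding, a library of `B` distinct barcode types is delivered
to `S` cells; each cell integrates a random *set* of barcodes, divides, and
its clone is re-identified later by matching observed barcode sets across
sequencing snapshots. Two error sources corrupt the reconstruction:

* **overlap** — at MOI `M`, the number of cells carrying a given barcode is
  ≈ Poisson((S/B)·M), so the same barcode lands in multiple founder cells;
* **dropout** — each integrated barcode is read with probability `1 − p_drop`
  (typical scRNA-seq dropout rates are 10–50%), so cells of the same clone can
  be read with different sets, and cells of different clones with identical
  ones.

## The model

* **Integration.** Under uniform integration each of the `B` types enters a
  cell independently with probability `p_in`, so the set size is
  `L ~ Binomial(B, p_in)` with mean `M = p_in·B`; for `p_in ≪ 1`, `B ≫ 1` this
  is `Poisson(M)`, and the labeled fraction is `1 − e^{−M}` (which inverts to
  the standard MOI estimator `M = −ln(1 − f)`). A biased mode draws per-cell
  susceptibility from a mean-1 Gamma and barcode types from a log-normally
  skewed pool, giving the over-dispersed set sizes seen in real libraries.
* **Propagation.** Neutral dynamics: cells double each generation and the
  culture is passaged (uniformly subsampled) back to `S`; snapshots are taken
  at generations 0/5/10/15 by default. A Wright-Fisher resampling engine is
  included as a variant.
* **Observation.** Each integrated barcode survives reading with probability
  `1 − p_drop`, independently per cell and per snapshot; the observed set size
  stays binomial with `p_in → p_in(1 − p_drop)`.
* **Reconstruction.** All observed cells are pooled, pairwise Jaccard
  dissimilarity `d(X,Y) = 1 − |X∩Y|/|X∪Y|` feeds single-linkage agglomerative
  clustering, and the dendrogram is cut at one of three thresholds:
  `D = 1⁻` (any non-zero overlap merges), `minD` (only identical sets merge),
  or `D*` (cut matching the true lineage count).
* **Closed forms.** The per-barcode no-overlap probability
  `(1 + (S/B)M)·e^{−(S/B)M}`, the identical-readout probability
  `e^{−2p(1−p)M} − e^{−(1−p²)M}` (a concave function of `M` with an interior
  maximum), and the library-size rule of thumb `B ≳ S^{3/2}·M` are provided
  as calculators and used as Monte-Carlo test oracles.

Accuracy is scored as the fraction of true propagated lineages whose observed
cells are recovered as an inferred cluster *exactly*, alongside the
Fowlkes–Mallows index and v-measure at the cell level.

## Worked example

Plan the design discussed above — track ≥100 lineages starting from
`S = 10⁴` cells at MOI 0.1 with a 100-fold library and 10% dropout:

```sh
$ clonetrace analytics -S 10000 -B 1000000 -M 0.1 --p-drop 0.1
{
  "p_no_overlap": 0.9999995003332083,
  "p_any_overlap": 4.996667917200881e-07,
  "p_identical_after_dropout": 0.07641832433475226,
  "labeled_fraction": 0.09516258196404043,
  "effective_moi": 0.09000000000000001,
  "min_complexity_bound": 100000.0,
  "p_identical_peak_moi": 2.1046273038531402
}
```

The overlap probability is negligible (`B = 10⁶` is far above the
`S^{3/2}·M = 10⁵` bound) and ~9.5% of cells will carry a readable barcode.
Simulating the full experiment:

```python
import numpy as np
import clonetrace as ct
from clonetrace.propagation import PropagationConfig

rng = np.random.default_rng(42)
report = ct.run_pipeline(S=10_000, B=1_000_000, moi=0.1, p_drop=0.1,
                         strategy="any_overlap",
                         propagation_config=PropagationConfig(), rng=rng)
print(report)
```

```
AccuracyReport(accurate_lineage_ratio=0.9436769394261424,
    accurate_lineage_count=888, accurate_per_initial_cell=0.0888,
    labeled_fraction_empirical=0.0829, fm_index=1.0,
    v_measure=1.0000000000000002, n_true_lineages=941,
    n_inferred_clusters=888, n_excluded_empty_cells=36684)
```

Of the 941 labeled founder lineages that propagated, 888 (94%) are recovered
exactly — comfortably above the 100-lineage goal; the perfect cell-level
indices confirm that at this MOI and complexity the only losses come from
dropout erasing whole single-barcode readouts, not from mis-clustering.

The CLI also provides `simulate` (trajectory → observed-table CSV), `infer`
(observed-table CSV → lineage assignment CSV, so externally produced barcode
calls can be clustered) and `sweep` (JSON config → tidy results table over a
grid of M, B/S, p_drop and threshold strategy).

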