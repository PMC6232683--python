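# Methods

## The model

The predictor treats association inference as a path-counting problem on a
heterogeneous graph. Nodes are lncRNAs and diseases; edges come in three
classes: known associations (weight 1), lncRNA–lncRNA similarity, and
disease–disease similarity (both thresholded). The score of a candidate pair
sums, over every simple path of at most τ edges connecting them, the product
of the traversed edge weights times a length decay:

    score(l, d) = Σ_w (Π p_w) · α^(−len(p_w))

The underlying assumption is guilt by association, twice over: an lncRNA
tends to be involved in diseases similar to the ones it is already known to
affect, and in diseases affected by lncRNAs functionally similar to it.
Path products compose these two hops (and one more, at τ = 3); the decay
makes a direct association edge worth α ≈ 2.26 times a two-edge detour of
the same total weight, so long speculative chains cannot swamp short strong
evidence.

### Decay form

The geometric decay α^(−len) is the package default because it is the form
under which longer paths contribute *less*, which is the stated intent of a
length penalty; a multiplicative-exponent alternative
(Π p_w)^(α·len), which instead shrinks weak paths faster than strong ones,
is available as `NetworkConfig(decay_form="product_power")` for sensitivity
analysis. At τ = 1 both reduce to a rescaling of LD, so the choice does not
affect the degenerate limit used in tests.

### Similarity layers

- **SS** (disease semantic similarity) is an *input*: a labelled symmetric
  matrix in [0, 1], in practice derived from the Disease Ontology. The
  package validates symmetry to 1e−9 and never computes SS itself.
- **FS** (lncRNA functional similarity) uses best-match aggregation:
  SIM(d, D) = max_{d′∈D} SS(d, d′), averaged in both directions over m + n
  terms. The maximum (rather than the mean) is the convention under which
  two lncRNAs with identical disease sets get FS = 1; a mean variant sits
  behind `agg="mean"`.
- **GL/GD** (interaction-profile kernels) use bandwidth
  γ = γ′ / mean(‖IP‖²) with the mean taken over *all* entities of the class,
  zero rows included, and γ′ = 1. Entries are strictly positive, so kernel
  fallback always reduces the number of exact zeros.
- **DS/LS** substitute the kernel for any entity whose SS (resp. FS) row is
  all-zero off the diagonal (sets NS/NF). An lncRNA that loses its last
  association inside a cross-validation fold has an empty disease set, gets
  an all-zero FS row, and is thereby swept into NF — the kernel is then its
  only similarity signal.

## Parameters

| parameter | default | meaning |
|---|---|---|
| T | 0.2 | similarity-edge weight threshold; edges with weight ≥ T are kept (a `strict_threshold` switch gives > T). Applies only to similarity edges, never to association edges. |
| τ | 3 | maximum path length in edges; τ = 1 keeps only direct edges, τ = 4 is roughly an order of magnitude slower per pair. |
| α | 2.26 | decay factor, > 1; larger values discount long paths harder. |
| γ′_l, γ′_d | 1 | kernel bandwidth regulators (dimensionless). |

These defaults are the package's reference operating point throughout the
tests and the acceptance script.

## Cross-validation protocol

Global LOOCV holds out each known association once. Within a fold the
*entire* similarity stage — FS, GL, GD, NS/NF, DS, LS — and the network are
recomputed from the training matrix, because FS and both kernels are
functions of LD and would otherwise leak the held-out label. Negatives (all
LD = 0 pairs) are scored once on the full-data network: their own labels are
never held out, so their fold networks would differ from the full network
only by one unrelated edge.

Local LOOCV (novel-lncRNA / novel-disease) zeroes an entity's whole LD
row/column per fold and scores it against every entity of the other class.

A `reuse_similarities=True` variant freezes the full-data similarities and
only deletes the held-out edge(s) from the network. It is cheaper and
reproduces the common published protocol, but the kernels then carry the
held-out information. The difference matters most for novel-lncRNA
evaluation: with full recomputation the held-out lncRNA's FS row is
identically zero (lncRNA similarity is derived entirely from LD), so its
ranking rests on a degree-driven kernel row — and because each of its true
diseases has also lost exactly one association relative to matched
negatives, the measured AUC on synthetic data sits slightly *below* 0.5
(≈ 0.40–0.49). With reused similarities the same data give ≈ 0.86–0.88.
Novel-disease evaluation is robust either way (≈ 0.77 recomputed) because
disease similarity comes from the external SS, which a fold cannot erase.
Both numbers are reported by the acceptance script; neither is gated.

AUC is the Mann–Whitney statistic with half-credit ties, computed from
midranks; the ROC curve sweeps the threshold over distinct scores, and its
trapezoidal area equals the statistic exactly (asserted in tests).
Precision-by-score-bin tables assign every scored pair (positive and
negative) to [lo, hi) intervals, the last interval closed.

## Synthetic data

The generator plants matching block structure in LD and SS: entities are
partitioned into equal contiguous blocks; associations occur with
probability 0.3 within a block and 0.01 between; positive SS values are
Beta-distributed (fixed concentration 8, mean 0.6 within / 0.1 between);
58% of off-diagonal SS pairs are then symmetrically zeroed, emulating the
sparsity of ontology-derived similarity; every lncRNA is guaranteed at
least one association (empty rows redrawn). The default size is 40 × 40
with 4 blocks — large enough for stable AUC estimates, small enough that a
20-replicate LOOCV study runs in about a minute.

`structureless()` produces the matched-density null: the same overall
association rate and SS mean with the within/between distinction removed.
Mean global-LOOCV AUC over 10 seeds is ≈ 0.80 for the structured
configuration and ≈ 0.48–0.50 for the null.

What the generator does **not** emulate: the Disease Ontology DAG topology
(SS entries are exchangeable within a block relation, real semantic
similarity is not), the heavy-tailed degree distribution of curated
catalogues, and name noise. Passing tests therefore demonstrate that the
pipeline recovers planted neighbourhood structure, not that it attains any
particular AUC on a real catalogue — runs on real data additionally depend
on the externally supplied SS matrix. `synthetic_reference_dataset()`
separately provides a degree-profile stand-in (156 lncRNAs, 190 diseases,
352 associations, max degrees 41/15, min 1, via bipartite Havel–Hakimi)
used to exercise the summary-statistics path at realistic scale.

## Numerical choices

- Similarity matrices are float64, validated symmetric *exactly* (each entry
  computed once and mirrored); file input tolerates 1e−9 asymmetry and
  averages it away.
- Path scores are plain float64 sums; with ≤ O(10⁵) non-negative terms per
  pair the summation-order error is far below every tolerance used.
- `score_all` runs one depth-limited DFS per lncRNA, depositing each path's
  contribution at its terminal disease node; this is algebraically identical
  to per-pair enumeration (asserted) and is what makes LOOCV affordable.
- Thresholding at equality keeps the edge (≥ T); the boundary case is
  config-switchable and tested.
- Degenerate inputs: an all-zero profile set makes the kernel bandwidth
  undefined (error); an empty disease group has no best match (error);
  empty path sets score 0; an empty dataset yields all-zero statistics with
  a warning.

## Known limitations

- lncRNA similarity is wholly LD-derived, so the leakage-free novel-lncRNA
  protocol has no signal path for a truly novel lncRNA beyond its kernel
  degree profile (see above); attaching an external lncRNA similarity
  (expression- or sequence-based) would be the principled fix.
- Exact simple-path enumeration is exponential in τ; τ ≤ 3 is comfortable at
  a few hundred nodes, τ = 4 on dense similarity graphs is not (the sweep
  driver accepts a time budget and reports skipped cells).
- The negative set for global LOOCV is all unlabelled pairs; some are
  presumably true-but-unknown associations, so measured AUCs are
  conservative.
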