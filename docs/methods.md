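# Methods

## Scope and data model

`repomatch` implements the computational core of a transcriptomics-plus-
networks drug-repositioning workflow. It deliberately starts *after*
microarray normalisation and linear-model differential-expression fitting:
the signatures module consumes a per-contrast table of
`(gene_id, log_fc, p_value)` rows and re-applies the Benjamini–Hochberg
step-up correction itself, so tables assembled from different pipelines
are put on a common FDR scale. Likewise it ends *before* clinical triage:
the pipeline's final artefact is the combined ranked candidate table, and
any shortlisting against safety, formulation or regulatory criteria is a
manual step outside the package.

## Disease signatures

Two signature configurations are supported: *split* (top `n_up` = 250
up-regulated and `n_down` = 250 down-regulated genes) and *combined* (top
`n_combined` = 500 genes by |log FC| regardless of direction, with
per-gene direction metadata retained). Genes are eligible when their
BH-adjusted p-value falls below a cutoff, default 0.05 — the cutoff is a
package default, exposed in every API, since "significantly regulated" is
conventionally but not universally tied to FDR 0.05. Within a direction,
genes are ranked by log-fold-change magnitude (the configurations are
"top N regulated genes", a fold-change notion) and ties break
lexicographically by gene id so outputs are bit-stable. Zero log-FC genes
are excluded: they carry no direction.

## Connectivity scoring (DGEM)

The weighted KS enrichment of a tag set against a drug's full gene
ranking uses the two running deviations

    a = max_j ( j/t − V(j)/n ),   b = max_j ( V(j)/n − (j−1)/t ),

returning `a` if `a > b` else `−b`. In split mode the raw connectivity
score is `ks_up − ks_down` when the two components differ in sign and 0
when they strictly share one (`ks_up·ks_down > 0`); a zero component does
not zero the score. In combined mode the single tag list is scored
directly and `ks_down` is recorded as 0 — the direction-free list cannot
support a subtraction, so a single KS statistic is the only consistent
reading; this is the module's main interpretive choice.

Raw scores are scaled per batch: positive scores divided by the maximum
positive, negative by the magnitude of the minimum negative. This bounds
scores in [−1, 1] and is what the downstream |score| ≥ 0.5 overlap filter
operates on. Scaling is performed per contrast (one batch per disease
signature), not globally across contrasts.

**Ranking uses raw magnitudes.** Two-sided scaling maps the extreme of
*each sign* to ±1, so scaled magnitudes are comparable only within a
sign: in any batch the best positive score becomes exactly +1 even when
it is noise. Condensation (one score per drug = the condition with the
largest |raw|, sign retained) and the final descending-|score| ranking
therefore operate on raw scores, while the chosen condition's scaled
score is reported alongside for filtering and interpretation.

Configuration selection scores every library instance under each
candidate configuration, condenses the control drug(s), aggregates
controls by the mean of their |scaled| condensed scores and picks the
argmax; exact ties prefer the split configuration (the original
connectivity-mapping convention), then input order. A therapeutic control
connects in the reversal direction, so magnitude — not signed value — is
the quantity "highest connectivity score for the control" can sensibly
mean under this sign convention.

## Overlap genes and pathway consensus

The genes "driving" a connection are defined as the KS leading edge: for
each tag set, the tags at or before the first argmax of the dominant
running deviation (for negative enrichments, the trailing block at or
after the argmax). Leading edges of the up- and down-sets are pooled,
ordered by rank extremity `min(rank, n+1−rank)` in the drug signature,
and truncated to 100 genes, direction ignored. A pair with exactly zero
raw score contributes nothing. Per-drug amalgamation keeps conditions
with |scaled score| ≥ 0.5 (inclusive), merges gene lists by each gene's
best position across conditions, and truncates to the cap *after*
merging; truncating per condition first is available behind the same API
by pre-capping the inputs.

Enrichment is a local one-sided hypergeometric (Fisher exact) tail test
against any GMT collection, intersected with a background universe
(default: the drug library's gene universe), BH-adjusted once per query
and ranked by ascending p with lexicographic tie-breaks. Consensus across
disease contrasts is the mean of per-contrast ranks over the contrasts in
which a pathway was tested. Note that BH adjustment is *not* idempotent —
re-adjusting an adjusted vector inflates any value not pinned by a
downstream plateau (e.g. BH([1, .25]) = [1, .5] but BH([1, .5]) = [1, 1])
— so adjusted values must never be fed back through the correction.

## Hetnet treatment prediction

The degree-weighted path count between a drug and a disease along a
metapath sums, over metapath-conforming *simple* (node-disjoint) paths,
the product over traversed edges of `(d_src · d_tgt)^(−w)`, where the
degrees are metaedge-specific: the number of same-relation edges the
source node has toward the target's type and vice versa. `w = 0.4` and a
metapath length cap of 3 follow the convention of the path-based hetnet
edge-prediction literature this method derives from; both are
configurable, and `w = 0` recovers the raw path count. Metapaths are
enumerated from the graph schema (all type-consistent DRUG→…→DISEASE
sequences up to the cap, traversable in either orientation).

Leakage control is structural: each labelled pair's own `treats` edge is
removed from the graph while that pair's features are computed, and
k-fold evaluation additionally removes the *entire test fold's* treat
edges before featurising that fold, refitting the classifier on the
remaining folds each time. Negatives are non-treat drug–disease pairs
sampled at 4:1 with endpoint frequencies proportional to the positives'
(+1 smoothing), a lightweight degree matching.

The classifier is one 16-unit ReLU hidden layer with a logistic output on
standardised features, trained with adam (learning rate 0.01) to loss
convergence (tol 1e−5, iteration cap 2000, default L2 penalty). Early
stopping on a held-back validation split was evaluated and rejected at
this data scale: scikit-learn restores the best-validation-score weight
snapshot, and a 10–20-sample split saturates within ~20 iterations,
freezing an underfit model. Training is deterministic given the seed.

## Interactome diffusion profiles

The multiscale interactome joins drugs, diseases, proteins and biological
functions with five undirected edge classes. The walk steps from node *u*
to neighbour *v* with probability `w_type(v) / Σ_{v'∈N(u)} w_type(v')`;
the published defaults w_drug = 3.21, w_disease = 3.54, w_protein = 4.40,
w_function = 6.58 and continuation probability α = 0.859 are taken as
given, not re-optimised. Only weight ratios matter: rescaling all four by
a common constant leaves the operator unchanged. The diffusion profile is
the fixed point `r = (1−α)·e_start + α·Tᵀ·r`, found by power iteration
from the uniform vector to max-norm tolerance 1e−10 (the map is an
α-contraction, so the start vector is immaterial); it agrees with the
dense linear solve to 1e−8 on every graph the suite checks.

Relevance ranking combines the drug and disease profiles by geometric
mean (a node prominent in only one walk scores 0), with arithmetic-mean
and minimum selectable; top-k is pooled across proteins and functions by
default with a per-type option, k = 10. Mechanism subgraphs are the union
of all simple drug→disease paths of length ≤ 6 whose interior nodes lie
in the top-k set. Edge-class filtering of paths is not applied by
default; the allowed-node set is the only filter.

## Synthetic study design

All generators are pure functions of a `SimulationSpec`; independent
seeded streams per generator make each output byte-reproducible.

* **Expression**: per-gene planted effects (|N(3.0, 0.5)|, signed by
  direction; 300 up + 300 down among 2000 genes) observed through a
  two-group t-model with 10 samples per arm at noise SD 1.0, so p-values
  and BH behaviour are realistic. The effect-size defaults are set so
  that planted genes are recovered at ≥ 95% under the default cutoff,
  the regime the workflow assumes: clearly dysregulated disease genes.
* **Drug library**: 50 drugs × 3 concentrations over the same universe.
  Background rankings are uniform permutations; each planted therapeutic
  drug displaces each signature gene with probability ρ = 0.8 into the
  extreme 5% band of the ranking (up-genes to the bottom, down-genes to
  the top) — planting acts on ranks, not expression, because matching
  consumes only ranks. The asymmetric variant reverses only the
  down-genes while *mimicking* the up-genes (both sets driven toward the
  top): this makes the split configuration self-cancel (same-sign KS
  components) deterministically, which is the scenario configuration
  selection exists for.
* **Hetnet**: 500 nodes over 8 types. True treatment pairs (5% of
  drug×disease) each receive 3 dedicated shared-gene bridges
  (drug–targets–gene, gene–assoc–disease) rather than any feature on the
  treat edge itself, forcing the classifier to learn path evidence; 25%
  of true pairs are held out with no treat edge in the graph.
* **Interactome**: a connected protein backbone with a function
  hierarchy, plus one planted drug–protein–function–protein–disease path
  whose bridge proteins also touch both endpoints, so mechanism nodes are
  elevated in *both* diffusion profiles — the signature that separates
  them from start-adjacent noise.

What passing these benchmarks shows — and does not. Planted recovery
demonstrates that each statistic responds to the structure it is designed
to detect at realistic noise, and that the plumbing (scaling, masking,
condensation) does not leak or invert signals. It does not demonstrate
performance on real libraries or curated graphs, whose confounders
(correlated drug signatures, hub diseases, literature bias, batch
effects) the generators intentionally omit.

## Numerical and engineering notes

* DWPC accumulates path products over lexicographically sorted neighbour
  lists so float summation order is independent of container state;
  without this, repeated runs drift at ULP level and cascade through the
  classifier.
* Tie-breaks are lexicographic throughout (gene id, drug id, pathway id,
  node id) so every ranking is bit-stable.
* The pipeline manifest records the seed and SHA-256 of every output
  file; two runs with the same configuration are byte-identical.
* Default problem sizes (2000-gene universe, 500-node hetnet, ~130-node
  interactome) keep a full discovery run under ten seconds on one core
  while leaving every statistic in a regime where its asymptotics are
  visible; all sizes scale up through the spec.

## Known limitations

* Combined-mode scoring has no published reference treatment for
  direction-free tag lists; the single-KS choice is documented above and
  isolated behind `connectivity_score`.
* The hetnet classifier approximates "training on similar diseases" by
  training on all treat edges; a disease-similarity weighting would
  require a similarity measure the workflow does not define.
* Whether condensation should precede scaling, and whether scaling should
  be global across contrasts, are unresolved in the source workflow;
  per-contrast scaling with post-scaling condensation is implemented and
  flagged at the API.
* `evaluate_holdout` refits the classifier per fold; reported AUC/F1
  dispersion is across folds, not across graph realisations.
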