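# Methods

This note records the model behind `termscape`, the choices made where
the design was genuinely open, and what the synthetic benchmark does
and does not establish.

## Counting under the true-path rule

All counts are distinct-protein counts after true-path propagation: a
protein annotated to a term is counted at that term and at every
ancestor reachable over `is_a` and `part_of` edges (the `regulates`
relation is excluded from propagation by default, following the common
convention; the relation set is configurable everywhere). A protein
annotated to several descendants of a term contributes once. For a
dataset, `N_exp` is the number of assigned proteins carrying at least
one annotation in the namespace under analysis — unannotated proteins
cannot contribute to any term count and would only deflate every score
by the same factor; a switch (`count_unannotated=True`) restores
"all detected proteins" semantics.

## Fraction assignment

A protein's enrichment of fraction A over B is `I_A/I_B − 1` (infinite
when `I_B = 0 < I_A`, zero when both vanish). A protein joins fraction
F iff its enrichment over *every* other fraction meets the margin
configured for that pair; otherwise it is "non-specific". The default
margins are the fractionation protocol's 30% (nucleus/cytosolic,
membrane/nucleus) and 50% (membrane/cytosolic); unknown pairs default
to 30%. Margins are symmetric per pair: this is the weakest rule
consistent with the three stated pairwise comparisons that yields a
unique label, and it generalizes to any number of fractions. An
alternative reading of "30% enrichment" — a share of summed intensity
30 points above an even split — is available as `mode="share"`.

## The representation score

The default (`bounded`) variant is

    R_i = (x_i / N_exp)^2 · sqrt(y_i / M_GOA).

Its three structural properties are used throughout: `R ∈ [0, 1]`;
`R = 0` iff `x = 0`; and `R` never increases from parent to child,
because propagated counts are edge-monotone and both factors are
monotone in their counts. `R` is invariant to duplicating the
experiment (`x, N_exp → 2x, 2N_exp`) and depends on the background only
through `y/M_GOA`.

A literal `reciprocal` variant, `(x/N)² · sqrt(M_GOA/y_i)`, is also
shipped; since it is unbounded it is min–max rescaled to (0, 1] per
dataset (zeros stay zero) so downstream log handling is shared. The
rescaling convention is ours; the bounded variant is the default
because it alone delivers all three structural properties by
construction.

## The score matrix and the absence placeholder

Rows are the terms present (`x > 0`) in at least one dataset — an
ancestor-closed set, since propagation makes ancestor counts at least
as large — columns the datasets, cells `log2 R`. A term absent from a
dataset receives a finite placeholder and is flagged in a mask.

The placeholder is the one genuinely scale-dependent tuning knob. Two
regimes exist:

* at the **finite floor** (below the smallest finite `log2 R`;
  `placeholder_floor()` computes it, `strict=True` in `build_matrix`
  enforces it), absence sorts strictly below presence, and
  absence/presence contrasts dominate the PCA variance;
* at a **soft mid-range value**, absence ranks as "moderately rare",
  and the specificity gradient of the present values dominates, which
  is what keeps PC1 on term specificity.

With `N_exp` in the tens-to-hundreds and a background of a few thousand
proteins, finite scores reach ≈ −20, so the classical starting value
−10 is well inside the bulk. The analysis default is −16 — between
bulk and floor — which on the synthetic benchmark preserves both the
PC1–specificity association and the separability of the dataset-specific
components. A silhouette-based grid search
(`select_placeholder`, descending grid from −10) is available; note
that maximizing silhouette alone drives the placeholder far below the
floor, trading the specificity gradient for maximal group separation —
the paper trail of any analysis should state which policy was used.

## PCA and the contribution table

Columns are standardized to mean 0 and unit sample variance (divisor
N−1); the principal axes come from the SVD of the standardized matrix,
with eigenvalues `s_k²/(N−1)` and a fixed sign convention (each
loading's largest-magnitude coefficient positive) so results are
reproducible across linear-algebra backends. Matrix orientation is
fixed: terms are rows (observations), datasets columns (variables) —
the only orientation in which one loading per dataset and thousands of
term points are both meaningful.

The contribution table reports `100 · α_fk²` — squared loading
coefficients. Because the eigenvector matrix is orthogonal this table
is doubly stochastic (rows *and* columns sum to 100), the structure
fraction-by-component tables of fractionation studies exhibit. The
eigenvalue-weighted variant `100 · α_fk² λ_k / Σ_j α_fj² λ_j` — the
squared correlation between variable and component for standardized
input — is available as `weighted=True` (its rows sum to 100, its
columns do not).

## Group extraction

The bi-plot reading "terms accumulate along a dataset's arrow" is made
deterministic as follows. Scores and loadings are restricted to a
component subset — by default PC2..PCp, since PC1 encodes specificity,
not dataset identity. Terms whose restricted score magnitude falls
below the 0.5 quantile of all magnitudes stay unassigned. A term
receives every dataset label whose restricted loading *arrow* — the
loading in bi-plot display scaling, coefficient × √eigenvalue — has
cosine ≥ 0.8 with the term's score vector. The √λ scaling matters:
score coordinates spread with each component's standard deviation, so
the arrow, not the unit eigenvector, is the direction along which
aligned terms actually lie; cosines against unit loadings
systematically under-measure alignment on low-variance components.
One label makes a clean group, several a mixed group (labeled by the
unordered label set), none leaves the term unassigned. A k-means
alternative (`method="kmeans"`, one center per dataset, centers labeled
by nearest arrow) exists for comparison.

For k datasets the number of possible categories is `k(k−1)` under the
ordered-pair convention (12 for four datasets) and `k + k(k−1)/2`
under the unordered convention the cosine rule can actually emit for
pair-limited mixing (10 for four); both are exposed in
`paper_group_bound`.

## Enrichment comparison

The hypergeometric upper tail `P(X ≥ k)` (including `k` itself, the
standard over-representation convention) is evaluated through
`scipy.stats.hypergeom`; Benjamini–Hochberg is the default adjustment
(Bonferroni behind a flag). Targets and backgrounds are propagated
distinct-protein counts, mirroring the scoring side. The comparison
statistic is the Pearson correlation between `100·R` and `−log10 p_raw`
(raw, not adjusted, p-values; a flag switches) over terms present in
both inputs; a degenerate (constant) side raises instead of silently
returning 0.

## The synthetic benchmark

The generator emulates the fractionated-proteome study design at half
scale: three fractions of 90 (cytosolic), 164 (membrane) and 22
(nucleus) proteins plus 642 non-specific proteins — the 179:328:45:1284
proportions of the motivating study — drawn from a background corpus of
2000 annotated proteins over a 200-term, depth-6 ontology. Halving
keeps the detected experiment a minority subset of the background, as a
detected proteome is of a full annotation corpus. One integer seed
drives three documented stages (DAG, background, experiment), each on
its own `default_rng([seed, stage])` stream, so outputs are
byte-reproducible and adding draws to one stage never perturbs another.

Structural choices, each mirroring a property of real corpora:

* **DAG**: layer sizes double per level (most terms are specific
  leaves) and children spread evenly over parents, so subtree mass —
  and hence propagated counts — decays regularly with depth; extra
  parents (p = 0.15) prefer nearby layers and the same branch.
* **Background annotations**: each protein has `Poisson(3) + 1` direct
  annotations; the first is a depth-weighted "home", extras stay in the
  home's ancestor/descendant neighbourhood with probability 0.8
  (annotation coherence). Direct-annotation weight is
  `depth²/ancestors`: deeper terms carry more direct annotation (the
  most specific applicable term gets curated), but heavily
  cross-classified terms are the rarest. Every term keeps propagated
  support ≥ 1 by swapping, never adding, annotations.
* **Planted branches**: each fraction receives signature terms — the
  best-supported spine of one or more compact subtrees rooted near
  depth 3, with pairwise-disjoint down-closures and, where possible,
  distinct top-level families. Branch annotators are exclusive to
  their fraction; proteins touching several branches stay out of the
  experiment. The non-specific dataset is itself concentrated in
  "housekeeping" branches of its own rather than sampled diffusely —
  like the real internal standard, it has structure, and this is what
  decouples it from the fraction columns.
* **Asymmetry**: per-fraction `(signature_terms, signal_prob)` defaults
  are (5, 0.15) cytosolic, (12, 0.85) membrane, (10, 0.9) nucleus. The
  cytosol is by far the least annotation-specific compartment — most of
  its proteins carry generic terms — which makes its column align with
  the shared specificity gradient while membrane and nucleus carry
  strong dataset-specific factors; this asymmetry, not any analysis
  parameter, is what yields distinct per-fraction components.
* **Intensities**: a fraction's proteins exceed every pairwise
  assignment threshold by at least `ratio_margin` (default 0.3) even
  against the ±5% jitter of the other columns; all other profiles are
  flat within ±5%, far below the 30% margin.

What passing tests on this benchmark show: the pipeline recovers
planted, branch-exclusive signal into the correct clean groups
(≥ 90% across the five fixed seeds 0–4, typically ≈ 100%), keeps PC1 on
the specificity gradient (|Spearman| ≥ 0.6 against ancestor counts),
separates the planted fractions onto distinct components, and ranks
terms consistently with hypergeometric significance (pooled Pearson
> 0 over planted terms). What they do not show: behaviour under
annotation incompleteness and bias of real GOA releases, identifier
mapping noise, correlated fraction contamination, or intensity error
models of real mass spectrometry — none of which the generator
attempts.

## Numerical details and degenerate inputs

Zero-variance matrix columns are a hard error naming the dataset (they
standardize to NaN). Components beyond the matrix rank carry zero
eigenvalues; group extraction rejects component indices beyond the
model. Ties in the placeholder grid resolve toward the start of the
grid (closest to −10). The cosine rule skips datasets with zero
restricted loading norm; zero-magnitude terms are unassigned. The
hypergeometric tail at `k = 0` is exactly 1. BH adjustment restores the
input order and caps at 1. Problem sizes throughout the test suite and
the acceptance script (200-term DAGs, 2000-protein corpora, five seeds)
run in seconds on one CPU.

## Known limitations

* The reciprocal score variant's rescaling to (0, 1] is a convention,
  not derived; cross-dataset comparability under that variant is
  limited.
* Group labels are limited in practice to the patterns the cosine rule
  can emit; three-way mixed groups are possible but rare at the default
  threshold.
* The placeholder default (−16) is calibrated to the corpus scale the
  generator emulates; corpora with very different `N_exp`/`M_GOA`
  ratios warrant re-inspection of the finite-score distribution.
* One namespace per run; cross-namespace edges are dropped under a
  namespace filter.
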