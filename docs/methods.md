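# Methods

## Model

`lncbayes` predicts lncRNA–disease associations on a tripartite
lncRNA–miRNA–disease network under two assumptions: (i) association evidence
flows through shared miRNA mediators — a lncRNA and a disease that are both
regulated by the same miRNAs are likely associated; and (ii) the observed
network is an incomplete sample, so a collaborative-filtering step may add
plausible miRNA–user edges before evidence is counted.

### Collaborative filtering

With miRNAs as items and lncRNAs/diseases as users, the binary adjacency
`R⁰` (miRNA × [lncRNAs ∥ diseases]) gives the miRNA–miRNA cosine similarity
`R'` on binary neighbor sets. The diagonal of `R'` is held at zero — including
self-similarity in the product `R¹ = R' R⁰` would add 1 to every known entry,
which contradicts the worked example's values, so this is forced, not chosen.
Zero-degree miRNAs receive similarity 0 everywhere (the 0/0 convention).

For each user with at least one known miRNA, the recommendation threshold `p̄`
is the mean of the user's `R¹` entries **over its known miRNAs only**, and a
candidate miRNA is recommended iff its score strictly exceeds `p̄`. Both
details are forced by the worked example (the mean (0.81+0.81)/2 averages the
two known miRNAs; a candidate scoring exactly `p̄` is not recommended).
Recommendation candidates exclude miRNAs already linked to the user.
By default the full product is used; a finite top-K similarity neighborhood is
available (`top_k`), with ties on similarity broken by row position. The CF
step is applied once, not iterated, and recommended edges are binary, flagged
by provenance rather than weighted.

### Naïve Bayes scoring

Every common-neighbor miRNA m of a pair (l, d) on the densified network
contributes one factor to the posterior odds:

    S(l, d) = φ · ∏_{m ∈ CN₁} φ⁻¹ r_m · ∏_{m ∈ CN₂} φ⁻¹ r_m^α ,
    r_m = (N⁺_m + 1) / (N⁻_m + 1)

CN₁ are neighbors reached by two original edges, CN₂ those with at least one
recommended edge. φ is the global prior odds of an association, computed from
the association table's own entity universe (|known| / (n_l n_d), matching a
curated snapshot of 407 associations over 77 lncRNAs × 95 diseases giving
p ≈ 0.056). N⁺_m counts known associations whose endpoints are both adjacent
to m (adjacency including recommended edges); N⁻_m = N_l N_d − N⁺_m. Laplace
(+1) smoothing keeps every factor positive. A degenerate prior (no known
associations, or all pairs known) is rejected.

A formulation note: writing the evidence term as a *nested* double product
over CN₁ × CN₂ with φ⁻² inside is degenerate whenever either set is empty (the
whole term vanishes). The per-neighbor form above is the unique reading
consistent with deriving the odds ratio neighbor-by-neighbor from Bayes
inversion of the conditional probabilities, reproduces the nested form when
|CN₁| = |CN₂|, and degrades gracefully otherwise. The unit tests pin this
against an oracle that composes the conditional probabilities literally.

The decay exponent α ∈ (0, 1] (default 0.05, the value at which the reference
sweep of α from 0.05 to 0.9 performed best) damps the evidence ratio of
recommended neighbors; as α → 0 each CN₂ factor tends to the constant φ⁻¹, so
recommended neighbors then contribute their presence but not their evidence.

Raw odds are normalized resource-allocation style,
`S' = log S / ∏_{m ∈ CN₁∪CN₂} k_m`, with k_m the neighbor's degree on the
densified network and an empty product of 1, so a pair with no common
neighbors scores `S = φ`, `S' = log φ` — ranked below any pair with positive
evidence in sparse settings rather than being unscorable. The log is natural
by default (`log_base` configurable). Two caveats are documented rather than
patched: when S < 1, log S < 0 and a larger degree product moves S' toward
zero, i.e. *raises* it — the degree penalty inverts in sign; and because the
denominator is a product over all common neighbors, it grows exponentially
with neighborhood size while log S grows linearly, so the normalization
compresses heavily-connected pairs. Both are properties of the formula as
stated.

### Disease semantic similarity

Diseases present in an ontology (parent–child edge list, e.g. pre-extracted
MeSH descriptors) get Wang-measure profiles: the disease itself contributes 1
and each ancestor t contributes `max(δ · D(ct))` over its children ct within
the disease's ancestor closure, with contribution factor δ = 0.5 by default.
Pairwise similarity is the shared contribution mass over the two semantic
values; it is symmetric, 1 on the diagonal, and in [0, 1]. The final score is
the matrix product `S' · SD` over the disease dimension (an element-wise
reading is dimensionally impossible; using only SD's diagonal would be a
no-op). Diseases absent from the ontology fall back to an identity row/column,
so the stage degrades per-disease instead of failing, and the whole stage is
optional.

## Evaluation protocol

LOOCV holds out each known association in turn and retrains the full pipeline
on the rest. The CF stage consumes only the miRNA–lncRNA and miRNA–disease
layers — never the association table — so no stage can observe the held-out
edge; retraining CF per fold is therefore identical to computing it once, but
the implementation retrains anyway (the cost is negligible at the scales
used). Candidates for a fold's disease are all lncRNAs not associated with it
in the training fold; the pooled ROC uses held-out pairs as positives and
never-known pairs as negatives (positives of other folds are excluded from
the negatives). A per-disease-averaged AUC is available as an option; the
pooled AUC is the default headline number. The ROC is computed by threshold
sweep with trapezoidal integration, which equals the rank-statistic
(concordance) AUC with ties at 1/2 — asserted against an O(n²) pair-counting
oracle. Top-k F1 uses a seeded 80/20 split of the known associations, a pooled
ranking of all non-training pairs, and hits among the held-out 20%. The paired
t-test on matched F1 series is the classical two-sided test with n−1 degrees
of freedom; identical series return (t, p) = (0, 1) and constant non-zero
differences are rejected.

## Synthetic data

The generator emulates a scaled-down curated-database snapshot. Defaults:
30 lncRNAs, 40 miRNAs, 25 diseases — sized so a full LOOCV takes about a
second on one CPU — organised into 5 latent functional groups. Both
miRNA-layer adjacencies are stochastic block samples with mean density 0.10
and within/between-group odds (`concentration`) of 30, giving sparse layers
with strong module structure, the regime in which real miRNA association
tables sit (curated layers are a few percent dense, with miRNAs clustering
into disease-specific modules). lncRNA–disease associations are planted with
probability 0.5 on pairs bridged by ≥ 2 miRNA mediators and 0.02 otherwise,
so roughly half the associations are mediator-driven signal and the rest are
noise. Group structure matters: on structureless uniform layers the
similarity matrix — and therefore the recommendation step — carries no
information, and a recommender-dependent scorer cannot beat a degree baseline
by construction.

What passing the planted-signal property does and does not show: it
demonstrates that the pipeline recovers mediator-driven associations well
above chance (pooled LOOCV AUC > 0.70 over 10 generator seeds) and above a
miRNA-degree-product baseline. It does not certify performance on real curated
data, whose degree distributions, name ambiguities and annotation biases the
generator does not model; real-data AUCs can be computed by supplying the
three TSVs to the CLI. Within the generator, bridged-but-unassociated pairs
are statistically exchangeable with bridged positives once the held-out edge
is removed, which caps the attainable AUC well below 1 by design.

The random ontology generator produces rooted DAGs (each node parented by an
earlier node, occasionally two) for exercising the semantic stage. Its
topology is unrelated to the latent groups that carry the planted signal, so
enabling semantic mixing with such an ontology *degrades* synthetic ranking —
the planted-signal property is therefore evaluated on the network-only
pipeline, and the semantic stage is validated separately against closed-form
values and structural invariants.

## Numerical and design choices

- Entity labels are matched case-insensitively after trimming, stored in
  first-seen spelling; indices order entities lexicographically by casefolded
  label, so matrix layouts are deterministic.
- Harmonization keeps miRNAs present in both miRNA layers, then filters the
  association table to surviving lncRNAs/diseases; it is idempotent, applied
  by default, and can be disabled (`harmonize=False`) for inputs that are
  already one coherent network, such as the packaged toy example whose m4/m5
  have no lncRNA edges.
- Alias substitution (optional two-column file) is exact-string,
  case-insensitive, applied before filtering — a reproducible stand-in for
  manual disease-name unification.
- The 80/20 split, the synthetic generator and the ontology generator take
  explicit integer seeds; identical inputs and seeds reproduce every reported
  number bit-for-bit.
- Evidence counts include the scored pair itself when it is known; LOOCV
  removes the test edge from the data entirely, which eliminates that leak
  where it matters.
- Score matrices use vectorized log-space accumulation; equality with the
  scalar per-pair formula is pinned by tests at ≤ 1e-9 relative tolerance.

## Known limitations

- The score is dominated at small α by the *count* of recommended common
  neighbors (each contributes ≈ φ⁻¹ regardless of evidence), so the method is
  sensitive to how aggressively the mean-threshold rule densifies the network;
  on weakly structured data the added edges are noise and can hurt ranking.
- The sign inversion of the degree normalization for S < 1 (above) is kept as
  specified.
- No identifier normalization beyond exact alias substitution; no ontology
  download or XML parsing — the semantic stage consumes pre-extracted
  parent–child edge lists.
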