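# Methods

## Binding-site catalogs and what "a site" means

The unit of evidence for every CB condition is the number of *distinct merged
3′UTR binding sites* a miRNA has on a gene. Catalog rows arrive from
database-style exports (miRTarBase-like, TarBase-like; 1-based inclusive
coordinates) or the package's generic TSV (0-based half-open). Internally all
coordinates are 0-based half-open, which keeps interval arithmetic
unambiguous.

Pooled databases report overlapping and duplicate sites, and sites on
different transcripts of one gene. Neither cross-database deduplication nor
the transcript/gene level of counting is standardized in the source
databases, so the package takes explicit positions on both:

* two sites of the same (miRNA, gene) pair on the same chromosome and strand
  that overlap by ≥ 1 base are merged into one site spanning their union
  (`merge_overlapping=False` disables this and counts raw rows);
* sites are pooled to the gene across transcripts, because the CB conditions
  reason about "gene A" and "gene B", not transcripts.

Only `region == 3UTR` sites are indexed and counted; CDS/5′UTR sites are
retained for reporting. Evidence tiers (strong/weak/direct) are carried
through and not filtered by default; `min_evidence` restricts when needed.

## Triad enumeration

A triad (miRNA-1, gene A, miRNA-2, gene B) qualifies iff

* n(miRNA-1, gene A) ≥ 2,
* 1 ≤ n(miRNA-2, gene A) < n(miRNA-1, gene A)  (strict "fewer"; a secondary
  with zero gene-A sites is not "in tandem" with anything),
* n(miRNA-2, gene B) ≥ 2 and n(miRNA-1, gene B) = 0,
* miRNA-1 ≠ miRNA-2 and gene A ≠ gene B.

"In tandem" imposes no distance or ordering constraint by default —
co-occurrence on the same 3′UTR suffices; an optional `max_gap` (bases
between the closest miRNA-1/miRNA-2 site pair on gene A) is available but
off by default. Enumeration is index-driven (genes per miRNA, miRNAs per
gene); the naive quadruple loop exists only as the independent test oracle.
Output order is lexicographic, making runs reproducible byte-for-byte.

Pair prevalence counts *distinct genes A* per (regulator, secondary) pair,
ignoring gene-B multiplicity. The conservation law used in tests: the sum of
prevalences equals the number of distinct (regulator, secondary, gene A)
triples in the triad set.

## Expression contextualization

Two thresholding conventions, matching how the respective assay tables are
normally read:

* **mRNA**: symmetric linear fold change — up iff 2^log2fc ≥ 1.5, down iff
  2^log2fc ≤ 1/1.5, both at P ≤ 0.05. Inputs are declared log2; the 1.5
  threshold is applied on the linear scale.
* **miRNA**: sign of the log fold change at P ≤ 0.05; a zero log fold change
  is not significant.

Raw P values are used, not adjusted ones (the convention of the upstream DE
tables this consumes); an adjusted-P column can be substituted upstream.

`down_down` mode keeps triads whose gene A *and* gene B are called down —
the coordinated-repression signature when the study design guarantees the
regulator is induced; the secondary miRNA's upregulation is additionally
required whenever a miRNA table is supplied. Unmeasured target genes drop
the triad (conservative). `full_pattern` mode keeps everything and assigns
tiers: **high confidence** = regulator up, secondary up, gene A down, gene B
down, or the fully mirrored pattern; **low confidence** = all four features
significantly changed in any other arrangement; otherwise **unsupported**.

The transcription-factor filter removes triads where gene A directly
regulates gene B (edge gene A → gene B), since there the gene-B change need
not reflect miRNA-2 biogenesis. It is directional by default
(`bidirectional=True` widens it). All filters are contractive and
idempotent, and the pipeline logs per-stage row counts because the
scientifically interesting output of a run is largely those deltas.

## Over-representation analysis

The ORA P value is the upper tail P(X ≥ k) for X ~ Hypergeometric(N, K, n):
k query hits in a set of K background members, query size n after
restriction to the N-gene background. The tail is accumulated in log space
(log-pmf + logsumexp) so deep tails of large universes do not underflow; the
test oracle is exact rational arithmetic. Query genes outside the background
are dropped (logged) *before* n is fixed, which is what the "gene ratio"
denominator reports. Benjamini–Hochberg is the only adjustment offered. The
background universe is always an explicit input — whether it should be an
annotation universe or an expressed-gene universe is a study-level decision
the package refuses to default.

## The progressive-dampening model

The layered model is this package's concrete instantiation of the
progressive-dampening idea; its three functional forms are deliberately
simple and pluggable:

1. **Response curve**: a least-squares polynomial (default degree 2, the
   smallest nonlinearity consistent with an empirically curved response)
   relating a secondary miRNA's level to the primary's.
2. **Layer propagation**: level(0) = primary dose; level(n) = c_n·level(n−1)
   with coupling c_n ∈ [0, 1]. c_n = 1 is the conservation limit, c_n = 0
   decouples the cascade.
3. **Target prediction**: an mRNA in layer t has
   level = baseline · exp(−Σ_{m≤t} β·w^(t−m)·level_m), with attenuation base
   w ∈ (0, 1) (default 0.5 for simulations) and same-layer repression
   strength β ≥ 0. The log-linear form keeps targets in (0, baseline],
   makes repression additive in the exponent, and gives the monotone
   dampening property: the influence of a miRNA layer decays as w^distance.

Parameter recovery (`recover_params`) refits (baseline, β, w) by bounded
trust-region least squares on linear-scale target levels (so noisy
measurements near zero never hit a logarithm), plus the layer-0→1 response
curve. w only enters through cross-layer distances, so single-layer series
are refused as non-identifiable. On noiseless input recovery is exact to
numerical precision; under additive Gaussian measurement noise the mean
recovery error grows with σ, which the tests verify by Monte Carlo.

## Synthetic data: what it emulates, and what it does not

`generate_catalog` plants triads on dedicated identifier blocks — each triad
has its own regulator, secondary, gene A and gene B; each decoy its own
identifiers. This makes planted/decoy separation provable: a planted
secondary has at most one site on its gene A (never ≥ 2), and its gene B
carries no other miRNA's sites, so no unintended regulator or secondary role
can arise; each decoy class violates exactly one CB condition (count tie on
gene A, single site on gene B, regulator site on gene B, missing gene-A
site, self-pair, non-3′UTR region). Sites live on a fictitious genome with
one chromosome per gene, exercising interval merging without real
annotation.

`generate_expression` centres planted regulator/secondary miRNAs at
+1.0 log2 units, planted genes A/B at −1.0 (so the linear fold change 2.0
clears the 1.5 threshold), and all other features at 0. With σ > 0, each
feature gets 3 vs 3 simulated replicates with Gaussian noise and a Welch
t-test supplies the P value, so the joint (log2fc, P) structure is realistic;
at σ = 0 the t-test is degenerate (zero within-group variance) and planted
features are assigned p = 1e-6, null features p = 1.0.

What passing tests on these inputs demonstrate: the conditions, filters and
estimators recover exactly what they are defined to recover, with zero false
positives, under inputs that satisfy the model's assumptions. What they do
not demonstrate: performance on real catalogs, where site annotations are
noisy and incomplete, identifiers collide across databases, expression
effects are correlated across genes, and the true generating process is
unknown. Headline counts from any specific database snapshot are
snapshot-dependent and are not reproduced here.

## Problem sizes and numerical choices

* Oracle-equivalence checks use catalogs up to 12 miRNAs × 12 genes, where
  the quadruple-loop oracle is exact and fast; 200 catalogs per sweep.
* Planted-truth recovery runs 20 seeded bundles of 5 triads over a
  30-miRNA × 40-gene namespace, through the full file-based pipeline.
* Hypergeometric exactness is exhaustive over all (k, n, K, N) with N ≤ 18
  and systematic over a 5×5 (K, n) grid per N up to 60; agreement tolerance
  1e-12 (observed max deviation ~8e-15).
* Dampening recovery uses 3 layers × 8 doses in [0, 4]; the noise sweep is
  σ ∈ {0, 0.02, 0.05} × 100 seeds.
* Polynomial fits use `numpy.polynomial.Polynomial.fit` (scaled domain) and
  convert back to raw coefficients; r² is clipped to [0, 1] and defined as 1
  for zero-variance targets (exact fit of a constant).
* All randomness flows through `numpy.random.default_rng(seed)`; generators
  are pure functions of (parameters, seed).

## Known limitations

* Cross-database site merging is a modelling choice (≥ 1-base overlap), not
  a ground truth; counts change if the off-switch is used.
* The dampening model is phenomenological: it does not model Dicer
  processivity, site occupancy thermodynamics, or transcriptional feedback.
* `full_pattern` tiers treat the four calls symmetrically and ignore effect
  sizes beyond the thresholds.
* Enrichment assumes the query is an unordered set; no ranked (GSEA-style)
  statistics are provided.
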