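# Methods

This document describes the statistical model, the synthetic-study generator,
the default parameters, and the design choices behind `metaconcord`.

## 1. Data model

A study consists of one `AssayDataset` per assay: `vir_mngs` (viral
metagenomics), `s16` (16S rRNA gene sequencing, genus-level), `mrna`
(host mRNA-Seq, gene-level), and `metarna` (metatranscriptomics, all three
kingdoms). Each dataset holds a features × samples integer `CountTable`,
per-feature metadata (kingdom, rank, genome type, phage host type), and
per-sample metadata (role: specimen / NTC / control, assay, total mapped
reads, optional external quantification such as RT-qPCR Ct values). The
viral assays carry an internal control (IC) feature — a fixed quantity of an
exogenous RNA phage spiked into every library, including the negative
template controls (NTCs).

## 2. Normalization

- **RPM**: `count / denominator × 10⁶` per sample. The denominator is the
  column sum by default, or the recorded total mapped reads.
- **Relative abundance (RA)**: counts over a feature subset, each column
  rescaled to sum to 1.
- **log2 RPM**: `log2(RPM)` with zero-count cells left as NaN. Zeros mean
  "not detected", and imputing them would manufacture expression values;
  presence calls on host genes are exactly "the gene has reads".
- **ALR (viral load)**: `log10(RPM_feature / RPM_IC + pc)` with pseudocount
  `pc = 10⁻⁵`. Anchoring on the spiked IC converts compositional read counts
  into a quantity comparable across libraries of different depth and
  background. Consequences of the pseudocount placement (at the ratio level,
  not the count level):
  - zero reads map to exactly `log10(pc) = −5`, a recognizable floor;
  - a feature at one-tenth of the IC level maps to ≈ −1, the **positive**
    detection threshold (inclusive, `ALR ≥ −1`);
  - `ALR > 0` (more reads than the IC) is the **confident** threshold.

  Samples whose IC has zero reads cannot be anchored; they are excluded from
  the ALR table with the machine-readable reason `IC_ZERO` rather than
  imputed, mirroring the IC quality gate.

## 3. Decontamination

Features are removed when flagged by the union of three rules, computed on
RPM over columns that have reads:

1. **Prevalence rule**: one-sided Fisher exact test (greater prevalence in
   NTCs than specimens), α = 0.05. When no NTC column has any reads the
   prevalence and ratio rules are skipped with a `SKIPPED_PREVALENCE`
   finding (this is the normal state for mRNA-Seq, which has no expected
   NTC signal) and only the blacklist applies.
2. **Ratio rule**: mean RPM across NTCs **strictly greater** than 5× the
   mean RPM across specimens. A feature at exactly 5× is not removed.
3. **Blacklist**: named features (e.g. a known reagent-borne phage) removed
   unconditionally.

The IC is never removed even if a rule fires on it — it is by construction
NTC-enriched — but the event is recorded as an `IC_FLAGGED` warning.
Decontamination is idempotent: re-running it on cleaned data removes nothing.

## 4. Quality gates

All gates are inclusive (≥). Per assay:

| assay    | gates                                                          |
|----------|----------------------------------------------------------------|
| vir_mngs | IC ≥ 1 read                                                    |
| s16      | ≥ 10,000 mapped reads; rarefaction plateau                     |
| mrna     | ≥ 10,000 mapped reads                                          |
| metarna  | IC ≥ 1 read (viral); ≥ 1,000 bacterial reads + plateau (bacterial); ≥ 100,000 host reads (host/endotype) |

**Rarefaction** uses the exact expected richness under hypergeometric
subsampling, `E[S(d)] = Σᵢ [1 − C(N−nᵢ, d)/C(N, d)]`, computed with
`gammaln` for numerical stability (a seeded Monte Carlo estimator is also
available). **Plateau** is operationalized as: expected richness at full
depth minus interpolated richness at 90% depth < ε, with ε = 1.0 taxon.
The ε rule is an explicit, config-exposed choice; "reached a plateau" has no
single canonical definition.

**Saturation analysis** asks at what sequencing depth the test assay's
per-sample detection fraction (relative to the reference assay) stops
improving: the plateau depth is the smallest observed depth whose fraction
reaches 95% of the maximum across samples.

## 5. Concordance

A **hit** is a (sample, feature) pair called positive under a threshold rule
(`ALR ≥ t`, `RA > 0`, `RA ≥ t`, or presence). Given reference and test call
sets over shared samples:

- sensitivity = shared / (shared + ref_only); missed rate is its complement;
- Jaccard = shared / (shared + ref_only + test_only);
- the **confident-union Jaccard** recomputes the union after removing
  test-only hits that fall below the confident threshold, so the index is
  not deflated by sub-threshold test-exclusive calls;
- **stratified sensitivity** bins reference hits by reference RA
  (strictly > 0.5% and > 10% by default) and reports the detected fraction
  per stratum;
- **DNA–RNA discordance** lists features detected by the DNA-based
  reference in ≥ 5 samples yet never called in the RNA-based test assay —
  the operational definition of "present but transcriptionally silent";
- paired Pearson correlations use either all shared hits or both-detected
  cells only (masking the ALR floor), and external quantification
  (e.g. Ct values) is correlated against ALR per feature.

## 6. Endotype analysis

1. **Views**: per-assay feature × sample matrices (viral ALR, bacterial
   genus/species RA, host log2(RPM+1)), filtered to features present in
   ≥ 30% of samples (≥ 50% for host), optionally with an explicit presence
   mask — needed for ALR views, whose floor (−5) is a finite value — plus
   diversity rows; each retained row is z-scored. Host views use
   log2(RPM+1) rather than the NaN-bearing log2 RPM because z-scoring and
   SVD require complete matrices.
2. **Factorization**: each view is Frobenius-normalized (block scaling, so
   no view dominates by size), the blocks are stacked, and a single SVD
   yields shared sample factors `U·S` with per-view loadings. With one view
   this reduces exactly to PCA; at full rank reconstruction is exact. The
   sign convention (largest-magnitude loading positive) makes output
   deterministic.
3. **Clustering**: k-means (Lloyd, seeded restarts) on the factor scores;
   labels are canonicalized by cluster size. `k` is chosen by majority vote
   of the gap statistic (uniform reference, B = 20), silhouette, and a WSS
   elbow; ties go to the smallest k. The pipeline reports both the voted k
   and the k actually used (default: forced k = 2).
4. **Agreement** between two labelings is the best-bijection matching
   fraction (exhaustive for ≤ 6 clusters, Hungarian assignment otherwise).
5. **PERMANOVA**: R² = SS_between / SS_total on Euclidean distances in
   factor space. The p-value uses full enumeration of label permutations
   (via multiset permutations) whenever the number of distinct arrangements
   is ≤ the permutation budget; otherwise it samples B permutations and
   reports p = (#{R²_perm ≥ R²_obs} + 1)/(B + 1), counting the identity.
   Under the null, E[R²] = (k−1)/(n−1).

## 7. Synthetic-study generator

`generate_study(params, seed)` draws a ground truth and then per-assay count
tables, so every downstream claim can be checked against known truth.

**Truth**: each of 20 specimens gets a binary endotype (balanced);
log-normal viral concentrations per family with endotype-dependent
detection/activity probabilities; bacterial genomic abundance (log-normal)
and a separate transcriptional activity multiplier — three genera have
activity fixed at zero in both endotypes (genomically present, never
transcribing); host gene expression with a 40-gene block fold-changed (4×)
between endotypes; kitome contaminants whose expected NTC intensity is 10×
their specimen intensity; a blacklisted reagent phage; an IC spiked at a
fixed low concentration (0.3) so IC reads sit near the limit of detection.

**Capture rules per assay**: vir-mNGS sees viral nucleic acid plus the IC;
16S sees bacterial DNA only (genus-level); mRNA-Seq sees host genes only;
metaRNA sees RNA viruses, *active* DNA viruses (transcription), bacterial
activity = genomic abundance × activity multiplier, host expression, and
the IC, combined with kingdom weights 2.5 / 3.0 / 0.2
(viral / bacterial / host). NTCs contain only contaminants (plus IC in
viral assays); mRNA-Seq NTCs are empty.

**Counts**: expected compositions are converted to multinomial draws at a
per-sample depth drawn log-normally; defaults
(log10 mean, sd): vir_mngs (5.5, 0.25), s16 (4.7, 0.2), mrna (6.0, 0.2),
metarna (6.0, 0.25), NTC (3.7, 0.2). RT-qPCR-like external quantification is
emulated as Ct = 45 − 3.32·log10(concentration) + N(0, 0.5). All draws flow
from a single `SeedSequence(seed)`; derived seeds are < 2³¹.

Defaults (key subset):

| parameter | default | parameter | default |
|---|---|---|---|
| n_specimens | 20 | ic_concentration | 0.3 |
| n_ntc | vir 10 / 16S 7 / mrna 3 / metarna 3 | contaminant_specimen_fraction | 0.1 |
| n_host_genes / block | 160 / 40 | host_fold_change | 4.0 |
| rna/dna virus families | 4 / 6 | bacteria (3 silent) | 12 |
| metarna weights v/b/h | 2.5 / 3.0 / 0.2 | ct model | 45 − 3.32·log10, sd 0.5 |

## 8. Pipeline and determinism

`run_all` chains simulate (or load) → decontaminate → QC → concordance →
endotype, writing TSVs per stage, a sorted-key JSON manifest (no
timestamps), and a plain-text report. Stage seeds are spawned from one
`SeedSequence(seed)` and reduced mod 2³¹−1; floats are written with `%.10g`.
Two runs with the same seed produce byte-identical output trees.
`scripts/acceptance.py --seed S --out F` emits the headline quantities of a
full simulated run as JSON.

## 9. Limitations

- The generator uses multinomial sampling at log-normal depth; it does not
  model PCR duplication, mapping ambiguity, or taxonomic misassignment.
- The plateau ε and the saturation 95% fraction are pragmatic
  operationalizations, not estimators with known sampling distributions.
- The confident-union Jaccard depends on the confident threshold; it is
  reported alongside, never instead of, the raw Jaccard.
- PERMANOVA on factor scores inherits the factorization's view weighting;
  R² values are descriptive effect sizes, not variance components of the
  raw data.
- k-means assumes roughly isotropic clusters in factor space; the forced
  k = 2 default encodes a two-endotype design and should be revisited for
  other cohorts (the voted k is always reported).
- Synthetic defaults describe one plausible cohort; none of the numeric
  outputs in the README are claims about any real dataset.
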