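# metaconcord

Cross-assay concordance analysis for nasopharyngeal metatranscriptomics.

Metatranscriptomics (metaRNA-Seq) sequences all RNA in a respiratory sample
and, in principle, profiles three kingdoms at once: RNA (and transcriptionally
active DNA) viruses, the transcribing fraction of the bacteriome, and the host
transcriptome. `metaconcord` quantifies how well a single metaRNA-Seq library
recapitulates three dedicated single-target assays on the same specimens:

- **viral metagenomics (vir-mNGS)** for the virome,
- **16S rRNA gene sequencing (16S-Seq)** for the bacteriome,
- **mRNA-Seq** for host gene expression.

The package implements the full analysis chain: count-table ingestion and
validation, normalization (RPM, relative abundance, log2 RPM, and an
internal-control-anchored additive log-ratio (ALR) for viral loads),
NTC-based decontamination, per-assay quality gates with exact rarefaction,
hit-level concordance statistics, a multi-omics endotype analysis
(block-scaled SVD factorization, k-means, PERMANOVA), and a synthetic study
generator whose defaults emulate a 20-infant nasopharyngeal cohort, so the
whole pipeline runs end-to-end without external data.

## Quick start (CLI)

Simulate a study and run every stage:

```
metaconcord run-all --simulate --seed 7 --outdir demo
cat demo/report.txt
```

Output (abridged, actual output for seed 7):

```
metaconcord v0.1.0 — seed 7
============================================================

[RNA viruses] (test vs vir-mNGS, ALR w/ internal control)
  sensitivity 100.0% (30/30); missed 0.0%
  Jaccard raw 1, confident-union 1
  ALR Pearson r 0.981 (n=30, p=1.39e-21)

[DNA viruses] captured 43.1% (22/51)
  eukaryotic: 20.0% (1/5)
  prokaryotic: 45.7% (21/46)
  Pneumoviridae vs Ct(rsv): r -0.872

[Bacteria] (metaRNA active genera vs 16S, relative abundance)
  co-detected hits 131/181 (Jaccard 0.724); 16S-detected captured 72.4%
  RA > 0.5%: 130/170 (76.5%) detected
  RA > 10%: 60/61 (98.4%) detected
  present-but-never-active genera: Actinobacillus, Granulicatella, Bergeyella

[Host transcriptome] (metaRNA vs mRNA-Seq, log2 RPM)
  transcript hits Jaccard 0.998 (3193/3200)
  unique genes captured 160/160 (100.0%)
  ...

[Endotypes] (multi-omics vs metaRNA-only integration)
  n = 20 samples; k used: multi-omics 2 (voted 2), metaRNA 2 (voted 3)
  cluster agreement: 95.0%
  ...
```

The pattern in this report is the package's central scientific point:
metaRNA-Seq captures RNA viruses and abundant bacteria with high fidelity but
systematically misses transcriptionally silent DNA viruses and
present-but-inactive bacterial genera, because it measures activity rather
than genomic presence.

Individual stages are also available as subcommands (`simulate`, `decontam`,
`normalize`, `qc`, `concord`, `endotype`, `report`); see
`metaconcord --help`.

## Worked example (Python API)

How many DNA-virus detections made by viral metagenomics does
metatranscriptomics reproduce? A detection ("hit") is a (sample, family) pair
with ALR ≥ −1, where ALR = log10(RPM_family / RPM_internal-control + 1e-5).

```python
from metaconcord import (
    Assay, Config, GeneratorParams, ThresholdRule, RuleKind,
    alr_transform, apply_decontamination, call_detections,
    concordance_summary, generate_study, normalize_rpm,
)

config = Config()
datasets, truth = generate_study(GeneratorParams(), seed=7)
vir, _, _ = apply_decontamination(datasets[Assay.VIR_MNGS], config)
met, _, _ = apply_decontamination(datasets[Assay.METARNA], config)

rule = ThresholdRule(RuleKind.ALR_GE, config.alr_positive_threshold)
dna_families = [f for f, m in vir.features.items()
                if m.kingdom.value == "viral" and m.genome_type.value == "DNA"]

calls = {}
for name, d in [("vir_mngs", vir), ("metarna", met)]:
    table = d.table.subset_samples(truth.specimen_ids)
    alr = alr_transform(normalize_rpm(table), d.ic_feature_id, config.pseudocount)
    calls[name] = call_detections(alr, rule, name, features=dna_families)

summary = concordance_summary(calls["vir_mngs"], calls["metarna"])
print(f"shared={summary.shared} ref_only={summary.ref_only} "
      f"test_only={summary.test_only}")
print(f"sensitivity={summary.sensitivity:.3f} jaccard={summary.jaccard:.3f}")
```

Actual printed output:

```
shared=23 ref_only=31 test_only=0
sensitivity=0.426 jaccard=0.426
```

Less than half of the DNA-virus hits seen by vir-mNGS are recovered — the
missing ones are families the generator planted as genomically present but
transcriptionally silent. Running the same code with RNA-virus families
instead yields sensitivity 1.000 (35/35 hits shared).

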