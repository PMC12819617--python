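"""End-to-end orchestration: load or simulate the four assay views, then
decontaminate, normalize, QC-gate, compute per-kingdom concordance, and run
the two endotype integrations (multi-omics and metatranscriptomics-only)
with cluster agreement and per-view effect sizes.

The run is a pure function of (inputs, config, seed): every source of
randomness is derived from one root seed split per stage, outputs use fixed
number formatting, and the manifest records the attrition of every excluded
sample with a machine-readable reason.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .core_tables import (
    Assay,
    AssayDataset,
    Config,
    CountTable,
    Kingdom,
    Role,
    aggregate,
    read_count_table,
    read_feature_meta,
    read_sample_meta,
    validate_dataset,
    write_count_table,
    write_feature_meta,
    write_sample_meta,
)
from .concordance import (
    RuleKind,
    ThresholdRule,
    call_detections,
    concordance_summary,
    dna_rna_discordance,
    exclusive_detections,
    external_quant_correlation,
    paired_correlation,
    read_gene_set,
    stratified_sensitivity,
)
from .decontamination import apply_decontamination, write_reports
from .endotype import (
    build_views,
    cluster_agreement,
    factorize,
    kmeans_cluster,
    permanova_r2,
    select_k,
)
from .normalization import (
    NormalizedTable,
    alr_transform,
    diversity,
    log2_rpm,
    normalize_rpm,
    relative_abundance,
)
from .qc import gate_dataset, qc_report_frame, saturation_analysis
from .synthetic import (
    GeneratorParams,
    generate_study,
    species_to_genus_mapping,
)

__all__ = ["RunManifest", "run_all", "report"]

_ASSAYS = [Assay.VIR_MNGS, Assay.S16, Assay.MRNA, Assay.METARNA]


@dataclass
class RunManifest:
    seed: int
    version: str
    config: dict
    inputs: dict[str, str] = field(default_factory=dict)       # path -> sha256
    stages: list[str] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)      # label -> path
    sample_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    exclusions: list[dict] = field(default_factory=list)       # sample/assay/stage/reason
    summary: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))


def _log(level: str, stage: str, code: str, message: str, logfile=None) -> None:
    line = f"{level}\t{stage}\t{code}\t{message}"
    print(line, file=sys.stderr)
    if logfile is not None:
        logfile.write(line + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_df(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def _load_inputs(input_dir: Path) -> dict[Assay, AssayDataset]:
    datasets = {}
    for assay in _ASSAYS:
        counts = read_count_table(input_dir / f"{assay.value}_counts.tsv")
        feats = read_feature_meta(input_dir / f"{assay.value}_features.tsv")
        samps = read_sample_meta(input_dir / f"{assay.value}_samples.tsv")
        ic = None
        for f, m in feats.items():
            if m.kingdom is Kingdom.CONTROL and f in counts.df.index:
                ic = f
        datasets[assay] = AssayDataset(counts, feats, samps, ic_feature_id=ic)
    return datasets


def _write_study(datasets, truth, outdir: Path) -> None:
    simdir = outdir / "simulate"
    simdir.mkdir(parents=True, exist_ok=True)
    for assay, d in datasets.items():
        write_count_table(d.table, simdir / f"{assay.value}_counts.tsv")
        write_feature_meta(d.features, simdir / f"{assay.value}_features.tsv")
        write_sample_meta(d.samples, simdir / f"{assay.value}_samples.tsv")
    _write_df(truth.to_frame(), simdir / "truth.tsv")
    (simdir / "gene_set.txt").write_text(
        "# planted antiviral/inflammatory program genes\n"
        + "\n".join(truth.inflammatory_genes) + "\n"
    )


def _summary_entry(summary) -> dict:
    return {
        "shared": summary.shared,
        "ref_only": summary.ref_only,
        "test_only": summary.test_only,
        "sensitivity": summary.sensitivity,
        "missed_rate": summary.missed_rate,
        "jaccard": summary.jaccard,
    }


def _viral_concordance(clean, qc, config, outdir, manifest, logfile):
    """RNA- and DNA-virus detection/abundance concordance (vir-mNGS vs
    metaRNA), on samples passing the IC gate in both assays."""
    out: dict = {}
    cdir = outdir / "concordance"
    cdir.mkdir(exist_ok=True)
    ref_d, test_d = clean[Assay.VIR_MNGS], clean[Assay.METARNA]
    ref_ok = {s for s, r in qc[Assay.VIR_MNGS].items() if "viral" in r.eligible_for}
    test_ok = {s for s, r in qc[Assay.METARNA].items() if "viral" in r.eligible_for}
    samples = sorted(ref_ok & test_ok)
    for s in sorted(set(ref_d.specimen_ids()) - set(samples)):
        manifest.exclusions.append(
            {"sample": s, "assay": "viral_concordance", "stage": "qc", "reason": "IC_GATE"})
    if len(samples) < 2:
        _log("WARN", "concord", "VIRAL_SKIPPED", "fewer than 2 IC-positive samples", logfile)
        return {"skipped": "fewer than 2 IC-positive samples"}

    def _alr(d: AssayDataset) -> NormalizedTable:
        rpm = normalize_rpm(d.table.subset_samples(samples))
        return alr_transform(rpm, d.ic_feature_id, config.pseudocount)

    alr_ref, alr_test = _alr(ref_d), _alr(test_d)
    rule = ThresholdRule(RuleKind.ALR_GE, config.alr_positive_threshold)
    viral = lambda d: d.feature_ids_by_kingdom(Kingdom.VIRAL)  # noqa: E731
    rna = [f for f in viral(ref_d) if ref_d.features[f].genome_type.value == "RNA"]
    dna = [f for f in viral(ref_d) if ref_d.features[f].genome_type.value == "DNA"]

    for label, fams in (("rna_viruses", rna), ("dna_viruses", dna)):
        ref_calls = call_detections(alr_ref, rule, "vir_mngs", features=fams)
        test_calls = call_detections(alr_test, rule, "metarna", features=fams)
        summ = concordance_summary(ref_calls, test_calls)
        sub_threshold = {
            (s, f)
            for s, f, sc, pos in test_calls.calls.itertuples(index=False)
            if pos and sc <= config.alr_confident_threshold
        }
        confident = concordance_summary(ref_calls, test_calls, test_exclusion=sub_threshold)
        excl = exclusive_detections(ref_calls, test_calls, ref_d.features)
        _write_df(excl, cdir / f"{label}_exclusive.tsv")
        entry = {
            "raw": _summary_entry(summ),
            "confident_union": _summary_entry(confident),
            "n_samples": len(samples),
        }
        try:
            corr = paired_correlation(alr_ref, alr_test, "both-detected", subset=fams)
            entry["alr_pearson"] = {"r": corr.r, "p": corr.p, "n": corr.n}
        except ValueError as e:
            entry["alr_pearson"] = {"error": str(e)}
        out[label] = entry

    # eukaryotic / prokaryotic split of DNA-virus capture
    for ht in ("eukaryotic", "prokaryotic"):
        fams = [f for f in dna if ref_d.features[f].host_type.value == ht]
        if not fams:
            continue
        ref_calls = call_detections(alr_ref, rule, "vir_mngs", features=fams)
        test_calls = call_detections(alr_test, rule, "metarna", features=fams)
        out[f"dna_viruses_{ht}"] = _summary_entry(concordance_summary(ref_calls, test_calls))

    # external quantification (RT-PCR style Ct) against the dominant RNA virus
    quant_keys = sorted({k for m in test_d.samples.values() for k in m.external_quant})
    if quant_keys and rna:
        dominant = max(
            rna, key=lambda f: float((alr_test.values.loc[f] > 0).sum())
            if f in alr_test.values.index else -1.0,
        )
        try:
            cr = external_quant_correlation(alr_test, dominant, quant_keys[0], test_d.samples)
            out["external_quant"] = {
                "feature": dominant, "quant": quant_keys[0], "r": cr.r, "p": cr.p, "n": cr.n}
        except (ValueError, KeyError) as e:
            out["external_quant"] = {"error": str(e)}
    return out


def _bacterial_concordance(clean, qc, config, outdir, manifest, logfile):
    """16S genus detection vs transcriptionally active genera in metaRNA."""
    cdir = outdir / "concordance"
    cdir.mkdir(exist_ok=True)
    ref_d, test_d = clean[Assay.S16], clean[Assay.METARNA]
    ref_ok = {s for s, r in qc[Assay.S16].items() if "bacterial" in r.eligible_for}
    test_ok = {s for s, r in qc[Assay.METARNA].items() if "bacterial" in r.eligible_for}
    samples = sorted(ref_ok & test_ok)
    for s in sorted(set(ref_d.specimen_ids()) - set(samples)):
        manifest.exclusions.append(
            {"sample": s, "assay": "bacterial_concordance", "stage": "qc",
             "reason": "BACTERIAL_DEPTH_OR_PLATEAU"})
    if len(samples) < 2:
        _log("WARN", "concord", "BACT_SKIPPED", "fewer than 2 eligible samples", logfile)
        return {"skipped": "fewer than 2 eligible samples"}

    ref_ra = relative_abundance(ref_d.table.subset_samples(samples))
    mapping = species_to_genus_mapping(test_d)
    genus_table = aggregate(test_d.table.subset_samples(samples), mapping)
    test_ra = relative_abundance(genus_table)
    rule = ThresholdRule(RuleKind.RA_POSITIVE)
    ref_calls = call_detections(ref_ra, rule, "s16")
    test_calls = call_detections(test_ra, rule, "metarna")
    summ = concordance_summary(ref_calls, test_calls)
    strat = stratified_sensitivity(ref_ra, test_calls, config.ra_thresholds)
    _write_df(strat, cdir / "bacterial_stratified_sensitivity.tsv")
    silent = dna_rna_discordance(ref_ra, test_calls, config.dna_rna_min_samples)
    excl = exclusive_detections(ref_calls, test_calls, ref_d.features)
    _write_df(excl, cdir / "bacterial_exclusive.tsv")
    out = {
        "genus_hits": _summary_entry(summ),
        "stratified": strat.to_dict("records"),
        "never_active_genera": silent,
        "n_samples": len(samples),
    }
    try:
        corr = paired_correlation(ref_ra, test_ra, "both-detected")
        out["ra_pearson"] = {"r": corr.r, "p": corr.p, "n": corr.n}
    except ValueError as e:
        out["ra_pearson"] = {"error": str(e)}
    return out


def _host_concordance(clean, qc, config, outdir, manifest, gene_set, logfile):
    """Host coding-gene detection and expression concordance (mRNA-Seq vs
    metaRNA host fraction), restricted to genes consistently detected by the
    reference assay."""
    cdir = outdir / "concordance"
    cdir.mkdir(exist_ok=True)
    ref_d, test_d = clean[Assay.MRNA], clean[Assay.METARNA]
    ref_ok = {s for s, r in qc[Assay.MRNA].items() if "host" in r.eligible_for}
    test_ok = {s for s, r in qc[Assay.METARNA].items() if "host" in r.eligible_for}
    samples = sorted(ref_ok & test_ok)
    for s in sorted(set(ref_d.specimen_ids()) - set(samples)):
        manifest.exclusions.append(
            {"sample": s, "assay": "host_concordance", "stage": "qc", "reason": "HOST_DEPTH"})
    if len(samples) < 3:
        _log("WARN", "concord", "HOST_SKIPPED", "fewer than 3 eligible samples", logfile)
        return {"skipped": "fewer than 3 eligible samples"}

    host_ref = ref_d.table.subset_samples(samples)
    host_genes = [f for f in test_d.table.feature_ids
                  if test_d.features.get(f) and test_d.features[f].kingdom is Kingdom.HOST]
    host_test = test_d.table.subset_features(host_genes).subset_samples(samples)
    # reference gene universe: genes seen by the reference assay in a
    # consistent fraction of samples
    prev = (host_ref.df > 0).mean(axis=1)
    universe = [g for g in host_ref.feature_ids if prev[g] >= config.host_ref_prevalence]
    if not universe:
        return {"skipped": "no genes pass the reference prevalence filter"}
    if host_test.df.to_numpy().sum() == 0:
        return {"skipped": "no host reads in the test assay"}
    ref_log = log2_rpm(normalize_rpm(host_ref.subset_features(universe)))
    test_log = log2_rpm(normalize_rpm(host_test))
    rule = ThresholdRule(RuleKind.PRESENCE)
    ref_calls = call_detections(ref_log, rule, "mrna")
    test_calls = call_detections(test_log, rule, "metarna", features=universe)
    summ = concordance_summary(ref_calls, test_calls)
    ref_genes = {f for _, f in ref_calls.positive_pairs()}
    test_genes = {f for _, f in test_calls.positive_pairs()}
    out = {
        "transcript_hits": _summary_entry(summ),
        "unique_genes_ref": len(ref_genes),
        "unique_genes_shared": len(ref_genes & test_genes),
        "gene_fraction": len(ref_genes & test_genes) / len(ref_genes) if ref_genes else None,
        "n_samples": len(samples),
    }
    try:
        corr = paired_correlation(ref_log, test_log, "both-detected")
        out["log2rpm_pearson"] = {"r": corr.r, "p": corr.p, "n": corr.n}
    except ValueError as e:
        out["log2rpm_pearson"] = {"error": str(e)}
    if gene_set:
        try:
            corr = paired_correlation(ref_log, test_log, "both-detected", subset=gene_set)
            out["gene_set_pearson"] = {"r": corr.r, "p": corr.p, "n": corr.n,
                                       "n_genes": len(gene_set)}
        except ValueError as e:
            out["gene_set_pearson"] = {"error": str(e)}
    # depth-saturation of gene detection in the test assay
    detected = {s: {f for f in test_log.values.index
                    if pd.notna(test_log.values.loc[f, s])} for s in samples}
    reference = {s: {f for f in ref_log.values.index
                     if pd.notna(ref_log.values.loc[f, s])} for s in samples}
    depths = {s: qc[Assay.METARNA][s].kingdom_reads.get("host", 0) for s in samples}
    try:
        sat = saturation_analysis(detected, reference, depths, config.saturation_fraction)
        _write_df(pd.DataFrame(sat.points, columns=["depth", "fraction"]),
                  cdir / "host_saturation.tsv")
        out["saturation_plateau_depth"] = sat.plateau_depth
    except ValueError as e:
        out["saturation_plateau_depth"] = None
        out["saturation_error"] = str(e)
    return out


def _endotype_views(clean, qc, config, which: str, samples: list[str]):
    """Assemble z-scored views for one integration run."""
    sources: dict[str, pd.DataFrame] = {}
    presence: dict[str, pd.DataFrame] = {}
    div_rows: dict[str, pd.DataFrame] = {}

    def _viral_view(d: AssayDataset) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
        rpm = normalize_rpm(d.table.subset_samples(samples))
        alr = alr_transform(rpm, d.ic_feature_id, config.pseudocount)
        fams = d.feature_ids_by_kingdom(Kingdom.VIRAL)
        vals = alr.values.loc[[f for f in fams if f in alr.values.index]]
        floor = np.log10(config.pseudocount)
        pres = vals > floor + 1e-12
        ra = relative_abundance(d.table.subset_samples(samples),
                                feature_subset=fams)
        div = pd.DataFrame(
            {p.sample_id: {"shannon": p.shannon, "richness": float(p.richness)}
             for p in diversity(ra)}
        )
        return vals, pres, div[vals.columns]

    def _bacterial_views(d: AssayDataset, genus_only: bool):
        if d.assay is Assay.S16:
            genus = d.table.subset_samples(samples)
            species = None
        else:
            bact = d.feature_ids_by_kingdom(Kingdom.BACTERIAL)
            species_t = d.table.subset_features(bact).subset_samples(samples)
            genus = aggregate(species_t, species_to_genus_mapping(d))
            species = None if genus_only else species_t
        ra_g = relative_abundance(genus)
        div = pd.DataFrame(
            {p.sample_id: {"shannon": p.shannon, "richness": float(p.richness)}
             for p in diversity(ra_g)}
        )
        ra_s = relative_abundance(species) if species is not None else None
        return ra_g.values, div[ra_g.values.columns], (ra_s.values if ra_s is not None else None)

    def _host_view(d: AssayDataset) -> pd.DataFrame:
        genes = d.feature_ids_by_kingdom(Kingdom.HOST) or d.table.feature_ids
        t = d.table.subset_features(genes).subset_samples(samples)
        rpm = normalize_rpm(t)
        return np.log2(rpm.values + 1.0)

    if which == "multiomics":
        v, vp, vdiv = _viral_view(clean[Assay.VIR_MNGS])
        bg, bdiv, _ = _bacterial_views(clean[Assay.S16], genus_only=True)
        host = _host_view(clean[Assay.MRNA])
        sources = {"viral": v, "bacterial_genus": bg, "host": host}
        presence = {"viral": vp}
        div_rows = {"viral": vdiv, "bacterial_genus": bdiv}
    elif which == "metarna":
        d = clean[Assay.METARNA]
        v, vp, vdiv = _viral_view(d)
        bg, bdiv, bs = _bacterial_views(d, genus_only=False)
        host = _host_view(d)
        sources = {"viral": v, "bacterial_genus": bg, "bacterial_species": bs, "host": host}
        presence = {"viral": vp}
        div_rows = {"viral": vdiv, "bacterial_genus": bdiv}
    else:
        raise ValueError(which)
    return build_views(
        sources,
        microbe_prevalence=config.endotype.microbe_prevalence,
        host_prevalence=config.endotype.host_prevalence,
        diversity_rows=div_rows,
        presence=presence,
    )


def _endotype_stage(clean, qc, config, outdir, seed, manifest, logfile):
    edir = outdir / "endotype"
    edir.mkdir(exist_ok=True)
    eligible = None
    for assay in _ASSAYS:
        ok = {s for s, r in qc[assay].items() if "endotype" in r.eligible_for}
        eligible = ok if eligible is None else (eligible & ok)
    samples = sorted(eligible or set())
    for assay in _ASSAYS:
        for s in sorted(set(clean[assay].specimen_ids()) - set(samples)):
            manifest.exclusions.append(
                {"sample": s, "assay": assay.value, "stage": "endotype",
                 "reason": "QC_GATE_FAILED"})
    if len(samples) < 4:
        _log("WARN", "endotype", "SKIPPED", f"only {len(samples)} eligible samples", logfile)
        return {"skipped": f"only {len(samples)} eligible samples"}

    results = {"n_samples": len(samples)}
    clusterings = {}
    for which, n_f in (("multiomics", config.endotype.n_factors_multiomics),
                       ("metarna", config.endotype.n_factors_metarna)):
        views = _endotype_views(clean, qc, config, which, samples)
        n_factors = min(n_f, len(samples) - 1)
        model = factorize(views, n_factors)
        _write_df(model.factors, edir / f"{which}_factors.tsv", index=True)
        _write_df(model.variance_explained, edir / f"{which}_variance_explained.tsv", index=True)
        voted_k, diag = select_k(
            model.factors, config.endotype.k_range, seed=seed,
            restarts=config.endotype.kmeans_restarts,
        )
        _write_df(diag, edir / f"{which}_k_diagnostics.tsv")
        k = config.endotype.k or voted_k
        clust = kmeans_cluster(model.factors, k, config.endotype.kmeans_restarts, seed)
        clusterings[which] = clust
        _write_df(
            pd.DataFrame({"sample_id": list(clust.labels),
                          "cluster": [f"C{c + 1}" for c in clust.labels.values()]}),
            edir / f"{which}_clusters.tsv",
        )
        effects = []
        for v in views:
            es = permanova_r2(v.matrix.T, clust.labels,
                              config.endotype.permutations, seed=seed, view=v.name)
            effects.append({"view": v.name, "r_squared": es.r_squared, "p": es.p,
                            "pseudo_f": es.pseudo_f, "n_permutations": es.n_permutations})
        _write_df(pd.DataFrame(effects), edir / f"{which}_effect_sizes.tsv")
        results[which] = {
            "voted_k": voted_k,
            "k_used": k,
            "effect_sizes": effects,
            "variance_explained_total": model.variance_explained.sum(axis=1).to_dict(),
        }
    frac, mapping = cluster_agreement(clusterings["multiomics"], clusterings["metarna"])
    results["agreement"] = {"fraction": frac,
                            "mapping": {str(k): v for k, v in mapping.items()}}
    return results


def run_all(
    config: Optional[Config] = None,
    input_dir: Optional[str | Path] = None,
    simulate: bool = False,
    seed: int = 0,
    outdir: str | Path = "metaconcord_out",
    generator_params: Optional[GeneratorParams] = None,
    gene_set_path: Optional[str | Path] = None,
) -> RunManifest:
    """Run every stage in order and write all outputs under ``outdir``."""
    config = config or Config()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=seed, version=__version__, config=config.to_dict())
    logfile = open(outdir / "run.log", "w")

    root = np.random.SeedSequence(seed)
    stage_seeds = {name: int(s.generate_state(1)[0] % (2**31 - 1))
                   for name, s in zip(["simulate", "endotype"], root.spawn(2))}
    try:
        # ---- load / simulate -------------------------------------------------
        truth = None
        if simulate:
            _log("INFO", "simulate", "START", f"seed={stage_seeds['simulate']}", logfile)
            datasets, truth = generate_study(generator_params, stage_seeds["simulate"])
            _write_study(datasets, truth, outdir)
            manifest.stages.append("simulate")
        else:
            if input_dir is None:
                raise ValueError("need input_dir or simulate=True")
            input_dir = Path(input_dir)
            datasets = _load_inputs(input_dir)
            for p in sorted(input_dir.glob("*.tsv")):
                manifest.inputs[p.name] = _sha256(p)
            manifest.stages.append("load")
        for assay, d in datasets.items():
            findings = validate_dataset(d)
            for f in findings:
                _log("WARN", "validate", f.code, f"{assay.value}:{f.location} {f.message}",
                     logfile)
            if findings:
                raise ValueError(
                    f"dataset {assay.value} failed validation: "
                    + "; ".join(f"{f.code}@{f.location}" for f in findings)
                )
        gene_set = None
        if gene_set_path:
            gene_set = read_gene_set(gene_set_path)
        elif truth is not None:
            gene_set = truth.inflammatory_genes

        # ---- decontamination -------------------------------------------------
        ddir = outdir / "decontam"
        ddir.mkdir(exist_ok=True)
        clean: dict[Assay, AssayDataset] = {}
        for assay, d in datasets.items():
            cleaned, reports, findings = apply_decontamination(d, config)
            for f in findings:
                _log("WARN", "decontam", f.code, f"{assay.value}: {f.message}", logfile)
            write_reports(reports, ddir / f"{assay.value}_contaminants.tsv")
            removed = sum(r.removed for r in reports)
            _log("INFO", "decontam", "REMOVED", f"{assay.value}: {removed} features", logfile)
            clean[assay] = cleaned
            manifest.sample_counts.setdefault(assay.value, {})["features_removed"] = removed
        manifest.stages.append("decontaminate")

        # ---- QC gating -------------------------------------------------------
        qdir = outdir / "qc"
        qdir.mkdir(exist_ok=True)
        qc = {}
        for assay, d in clean.items():
            reports = gate_dataset(d, config)
            qc[assay] = reports
            _write_df(qc_report_frame(reports), qdir / f"{assay.value}_qc.tsv")
            n_ok = sum(1 for s in d.specimen_ids() if reports[s].eligible_for)
            manifest.sample_counts[assay.value]["specimens"] = len(d.specimen_ids())
            manifest.sample_counts[assay.value]["specimens_eligible"] = n_ok
            for s in d.specimen_ids():
                failed = [g for g, ok in reports[s].gates.items() if not ok]
                if failed:
                    manifest.exclusions.append(
                        {"sample": s, "assay": assay.value, "stage": "qc",
                         "reason": "GATE_FAIL:" + ",".join(sorted(failed))})
        manifest.stages.append("qc")

        # ---- concordance -----------------------------------------------------
        manifest.summary["viral"] = _viral_concordance(clean, qc, config, outdir,
                                                       manifest, logfile)
        manifest.summary["bacterial"] = _bacterial_concordance(clean, qc, config, outdir,
                                                               manifest, logfile)
        manifest.summary["host"] = _host_concordance(clean, qc, config, outdir,
                                                     manifest, gene_set, logfile)
        manifest.stages.append("concordance")

        # ---- endotype --------------------------------------------------------
        manifest.summary["endotype"] = _endotype_stage(
            clean, qc, config, outdir, stage_seeds["endotype"], manifest, logfile)
        manifest.stages.append("endotype")
    finally:
        logfile.close()

    (outdir / "manifest.json").write_text(manifest.to_json() + "\n")
    (outdir / "report.txt").write_text(report(manifest))
    return manifest


def _fmt(x, pct: bool = False) -> str:
    if x is None:
        return "NA"
    if isinstance(x, str):
        return x
    return f"{100 * x:.1f}%" if pct else f"{x:.3g}"


def report(manifest: RunManifest) -> str:
    """Human-readable per-kingdom summary regenerated purely from a manifest."""
    missing = [s for s in ("viral", "bacterial", "host", "endotype")
               if s not in manifest.summary]
    if missing:
        raise ValueError(f"manifest incomplete; missing stages: {', '.join(missing)}")
    lines = [
        f"metaconcord v{manifest.version} — seed {manifest.seed}",
        "=" * 60,
    ]
    sv = manifest.summary["viral"]
    lines.append("\n[RNA viruses] (test vs vir-mNGS, ALR w/ internal control)")
    if "skipped" in sv:
        lines.append(f"  NA: {sv['skipped']}")
    else:
        r = sv["rna_viruses"]["raw"]
        c = sv["rna_viruses"]["confident_union"]
        lines.append(f"  sensitivity {_fmt(r['sensitivity'], pct=True)} "
                     f"({r['shared']}/{r['shared'] + r['ref_only']}); "
                     f"missed {_fmt(r['missed_rate'], pct=True)}")
        lines.append(f"  Jaccard raw {_fmt(r['jaccard'])}, confident-union {_fmt(c['jaccard'])}")
        ap = sv["rna_viruses"].get("alr_pearson", {})
        if "r" in ap:
            lines.append(f"  ALR Pearson r {_fmt(ap['r'])} (n={ap['n']}, p={_fmt(ap['p'])})")
        d = sv.get("dna_viruses", {}).get("raw")
        if d:
            lines.append(f"\n[DNA viruses] captured {_fmt(d['sensitivity'], pct=True)} "
                         f"({d['shared']}/{d['shared'] + d['ref_only']})")
        for ht in ("eukaryotic", "prokaryotic"):
            e = sv.get(f"dna_viruses_{ht}")
            if e:
                lines.append(f"  {ht}: {_fmt(e['sensitivity'], pct=True)} "
                             f"({e['shared']}/{e['shared'] + e['ref_only']})")
        eq = sv.get("external_quant")
        if eq and "r" in eq:
            lines.append(f"  {eq['feature']} vs Ct({eq['quant']}): r {_fmt(eq['r'])}")
    sb = manifest.summary["bacterial"]
    lines.append("\n[Bacteria] (metaRNA active genera vs 16S, relative abundance)")
    if "skipped" in sb:
        lines.append(f"  NA: {sb['skipped']}")
    else:
        g = sb["genus_hits"]
        lines.append(f"  co-detected hits {g['shared']}/"
                     f"{g['shared'] + g['ref_only'] + g['test_only']} "
                     f"(Jaccard {_fmt(g['jaccard'])}); "
                     f"16S-detected captured {_fmt(g['sensitivity'], pct=True)}")
        for row in sb["stratified"]:
            lines.append(f"  RA > {row['threshold'] * 100:g}%: "
                         f"{row['detected']}/{row['total']} "
                         f"({_fmt(row['fraction'], pct=True)}) detected")
        if sb["never_active_genera"]:
            lines.append("  present-but-never-active genera: "
                         + ", ".join(sb["never_active_genera"]))
    sh = manifest.summary["host"]
    lines.append("\n[Host transcriptome] (metaRNA vs mRNA-Seq, log2 RPM)")
    if "skipped" in sh:
        lines.append(f"  NA: {sh['skipped']}")
    else:
        t = sh["transcript_hits"]
        lines.append(f"  transcript hits Jaccard {_fmt(t['jaccard'])} "
                     f"({t['shared']}/{t['shared'] + t['ref_only'] + t['test_only']})")
        lines.append(f"  unique genes captured {sh['unique_genes_shared']}/"
                     f"{sh['unique_genes_ref']} ({_fmt(sh['gene_fraction'], pct=True)})")
        lp = sh.get("log2rpm_pearson", {})
        if "r" in lp:
            lines.append(f"  expression Pearson r {_fmt(lp['r'])} (n={lp['n']})")
        gp = sh.get("gene_set_pearson", {})
        if "r" in gp:
            lines.append(f"  gene-set Pearson r {_fmt(gp['r'])} ({gp['n_genes']} genes)")
        if sh.get("saturation_plateau_depth") is not None:
            lines.append(f"  detection plateau at >= {sh['saturation_plateau_depth']} host reads")
    se = manifest.summary["endotype"]
    lines.append("\n[Endotypes] (multi-omics vs metaRNA-only integration)")
    if "skipped" in se:
        lines.append(f"  NA: {se['skipped']}")
    else:
        lines.append(f"  n = {se['n_samples']} samples; "
                     f"k used: multi-omics {se['multiomics']['k_used']} "
                     f"(voted {se['multiomics']['voted_k']}), "
                     f"metaRNA {se['metarna']['k_used']} (voted {se['metarna']['voted_k']})")
        lines.append(f"  cluster agreement: {_fmt(se['agreement']['fraction'], pct=True)}")
        for which in ("multiomics", "metarna"):
            for es in se[which]["effect_sizes"]:
                lines.append(f"  {which} {es['view']}: R2 {_fmt(es['r_squared'])} "
                             f"(p {_fmt(es['p'])})")
    if manifest.exclusions:
        lines.append("\n[Attrition]")
        for e in manifest.exclusions:
            lines.append(f"  {e['sample']} [{e['assay']}] at {e['stage']}: {e['reason']}")
    return "\n".join(lines) + "\n"
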