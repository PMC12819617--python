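"""Seeded generator of ground-truth communities and four assay views.

The generator emulates a nasopharyngeal cohort profiled in parallel by four
sequencing assays:

* ``vir_mngs``  — virus-enriched shotgun sequencing of extracellular viral
  particles: sees DNA and RNA viral families in proportion to particle
  concentration, plus the spiked MS2-like internal control (IC).
* ``s16``      — 16S amplicon profiling: sees bacterial genera in proportion
  to genomic DNA abundance; transcription is invisible.
* ``mrna``     — poly(A) host mRNA capture: sees host coding genes.
* ``metarna``  — bulk metatranscriptomics: sees host genes (expression),
  bacterial species (DNA abundance x transcriptional activity), RNA-virus
  families (concentration), DNA-virus families only when transcriptionally
  active, plus the IC.

Planted structure: an RSV-like dominant RNA virus with sporadic
co-infections; DNA viruses split into transcriptionally active and silent;
bacterial species whose DNA abundance and activity are decoupled (including
fully silent genera); host genes organised in two endotype expression
programs (an "inflammatory" block up in endotype C2, an RNA-metabolism
block up in C1, with the designated active species boosted in C2 and phage
activity boosted in C1); reagent contaminants present in both specimens and
no-template controls (NTCs) with a much higher NTC intensity; and an IC
spiked at a fixed concentration near the limit of detection.

Counts are multinomial draws conditional on a log-normally drawn total
depth; the whole study is a pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .core_tables import (
    Assay,
    AssayDataset,
    CountTable,
    FeatureMeta,
    GenomeType,
    HostType,
    Kingdom,
    Rank,
    Role,
    SampleMeta,
    genus_of,
)

__all__ = [
    "RnaVirusSpec",
    "DnaVirusSpec",
    "BacteriumSpec",
    "GeneratorParams",
    "SyntheticTruth",
    "generate_truth",
    "expected_composition",
    "sample_counts",
    "generate_study",
]

IC_FEATURE_ID = "MS2_internal_control"


@dataclass(frozen=True)
class RnaVirusSpec:
    family: str
    prevalence: float           # probability a specimen carries the virus
    log10_conc: float           # log10 median concentration (arbitrary units)
    log10_sd: float = 0.5
    host_type: HostType = HostType.EUKARYOTIC


@dataclass(frozen=True)
class DnaVirusSpec:
    family: str
    prevalence: float
    log10_conc: float
    log10_sd: float = 0.5
    host_type: HostType = HostType.EUKARYOTIC
    active_prob_c1: float = 0.5  # probability of transcriptional activity
    active_prob_c2: float = 0.5


@dataclass(frozen=True)
class BacteriumSpec:
    species: str                 # "Genus_species"; genus = leading token
    prevalence: float
    log10_dna: float             # log10 median genomic abundance
    log10_sd: float = 0.4
    activity_c1: float = 1.0     # median transcripts per genome copy
    activity_c2: float = 1.0     # 0.0 in both endotypes = silent genus


_DEFAULT_RNA_VIRUSES = (
    RnaVirusSpec("Pneumoviridae", 1.00, 3.0, 0.4),
    RnaVirusSpec("Picornaviridae", 0.25, 2.0, 0.5),
    RnaVirusSpec("Coronaviridae", 0.25, 1.5, 0.5),
    RnaVirusSpec("Orthomyxoviridae", 0.10, 2.5, 0.5),
)

_DEFAULT_DNA_VIRUSES = (
    DnaVirusSpec("Herpesviridae", 0.20, 2.0, 0.5, HostType.EUKARYOTIC, 0.3, 0.3),
    DnaVirusSpec("Anelloviridae", 0.40, 1.5, 0.5, HostType.EUKARYOTIC, 0.2, 0.2),
    DnaVirusSpec("Siphoviridae", 0.80, 1.5, 0.5, HostType.PROKARYOTIC, 0.6, 0.4),
    DnaVirusSpec("Myoviridae", 0.40, 1.2, 0.5, HostType.PROKARYOTIC, 0.5, 0.4),
    DnaVirusSpec("Streptococcus_phage", 0.70, 1.5, 0.5, HostType.PROKARYOTIC, 0.8, 0.3),
    DnaVirusSpec("Moraxella_phage", 0.50, 1.3, 0.5, HostType.PROKARYOTIC, 0.5, 0.5),
)

_DEFAULT_BACTERIA = (
    BacteriumSpec("Streptococcus_pneumoniae", 0.9, 2.5, 0.4, 0.5, 8.0),
    BacteriumSpec("Streptococcus_mitis", 0.9, 2.4, 0.4, 1.5, 1.5),
    BacteriumSpec("Moraxella_catarrhalis", 0.9, 3.0, 0.4, 0.1, 0.1),
    BacteriumSpec("Haemophilus_influenzae", 0.8, 2.5, 0.4, 2.0, 2.0),
    BacteriumSpec("Staphylococcus_aureus", 0.7, 2.2, 0.4, 0.1, 0.1),
    BacteriumSpec("Veillonella_parvula", 0.8, 2.0, 0.4, 1.0, 1.0),
    BacteriumSpec("Gemella_haemolysans", 0.7, 1.8, 0.4, 1.0, 1.0),
    BacteriumSpec("Prevotella_melaninogenica", 0.8, 2.0, 0.4, 0.8, 0.8),
    BacteriumSpec("Dolosigranulum_pigrum", 0.6, 2.0, 0.5, 1.0, 1.0),
    # silent genera: DNA present, zero transcription in every specimen
    BacteriumSpec("Actinobacillus_unclassified", 0.9, 1.8, 0.5, 0.0, 0.0),
    BacteriumSpec("Granulicatella_adiacens", 0.9, 1.5, 0.5, 0.0, 0.0),
    BacteriumSpec("Bergeyella_unclassified", 0.8, 1.2, 0.5, 0.0, 0.0),
)

# classic reagent "kitome" genera and low-level viral database artefacts
_DEFAULT_BACT_CONTAMINANTS = (
    "Ralstonia_contaminans", "Sphingomonas_reagens", "Bradyrhizobium_kitense",
    "Methylobacterium_aquae", "Cutibacterium_acnes", "Delftia_acidovorans",
)
_DEFAULT_VIRAL_CONTAMINANTS = (
    "Circoviridae", "Genomoviridae", "Microviridae", "Inoviridae",
)

BLACKLISTED_PHAGE = "Proteus_phage_VB_PmiS_Isfahan"


@dataclass
class GeneratorParams:
    """Study conditions for the synthetic cohort."""

    n_specimens: int = 20
    n_ntc: Mapping[str, int] = field(
        default_factory=lambda: {"vir_mngs": 10, "s16": 7, "mrna": 3, "metarna": 3}
    )
    endotype_mixing: float = 0.5          # P(endotype C2)
    rna_viruses: tuple[RnaVirusSpec, ...] = _DEFAULT_RNA_VIRUSES
    dna_viruses: tuple[DnaVirusSpec, ...] = _DEFAULT_DNA_VIRUSES
    bacteria: tuple[BacteriumSpec, ...] = _DEFAULT_BACTERIA
    activity_noise_sd: float = 0.3        # log10 sd on realised activity
    n_host_genes: int = 160
    n_block_genes: int = 40               # genes per endotype program block
    host_fold_change: float = 4.0         # endotype block fold change
    host_base_log10: float = 1.5
    host_base_sd: float = 0.8
    host_noise_sd: float = 0.15           # per-sample log10 expression noise
    ic_concentration: float = 0.3         # spiked near limit of detection
    n_viral_contaminants: int = 4
    n_bacterial_contaminants: int = 6
    contaminant_ntc_log10: float = 1.0    # log10 median NTC intensity
    contaminant_ntc_sd: float = 0.3
    contaminant_specimen_fraction: float = 0.1   # specimen/NTC intensity ratio
    include_blacklisted_phage: bool = True
    blacklisted_phage_conc: float = 0.5
    # kingdom scale factors for the metatranscriptome mixture; chosen so the
    # median viral/bacterial/host split lands near 8/48/40 percent
    metarna_viral_weight: float = 2.5
    metarna_bacterial_weight: float = 3.0
    metarna_host_weight: float = 0.20
    # log10 (median, sd) of total reads per assay
    depths: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "vir_mngs": (5.5, 0.25),
            "s16": (4.7, 0.20),
            "mrna": (6.0, 0.20),
            "metarna": (6.0, 0.25),
            "ntc": (3.7, 0.20),
        }
    )
    dirichlet_overdispersion: Optional[float] = None  # None = pure multinomial
    ct_intercept: float = 45.0            # RT-PCR emulation for the RSV-like virus
    ct_slope: float = 3.32                # Ct per log10 concentration
    ct_noise_sd: float = 0.5

    def validated(self) -> "GeneratorParams":
        if self.n_specimens < 2:
            raise ValueError("n_specimens must be >= 2")
        if self.ic_concentration <= 0:
            raise ValueError("ic_concentration must be positive")
        for b in self.bacteria:
            if b.activity_c1 < 0 or b.activity_c2 < 0 or b.log10_dna != b.log10_dna:
                raise ValueError(f"negative intensity for {b.species}")
        if not 0 <= self.endotype_mixing <= 1:
            raise ValueError("endotype_mixing must be in [0,1]")
        if self.contaminant_specimen_fraction < 0:
            raise ValueError("contaminant_specimen_fraction must be >= 0")
        return self


@dataclass
class SyntheticTruth:
    """Per-specimen ground truth for every planted signal."""

    specimen_ids: list[str]
    endotype: dict[str, str]                                # sample -> C1/C2
    viral_concentration: dict[str, dict[str, float]]        # sample -> family -> conc
    dna_virus_active: dict[str, dict[str, bool]]            # sample -> family -> active
    bacterial_dna: dict[str, dict[str, float]]              # sample -> species -> abundance
    bacterial_activity: dict[str, dict[str, float]]         # sample -> species -> txn/genome
    host_expression: dict[str, dict[str, float]]            # sample -> gene -> expression
    ic_concentration: float
    contaminants: dict[str, tuple[float, float]]            # feature -> (specimen, ntc)
    inflammatory_genes: list[str]
    rna_metabolism_genes: list[str]
    params: GeneratorParams

    @property
    def host_genes(self) -> list[str]:
        first = self.specimen_ids[0]
        return list(self.host_expression[first])

    def to_frame(self) -> pd.DataFrame:
        """Long-format truth table: sample_id, feature_id, truth_kind, value."""
        rows: list[tuple[str, str, str, object]] = []
        for s in self.specimen_ids:
            rows.append((s, "", "endotype", self.endotype[s]))
            for fam, c in self.viral_concentration[s].items():
                rows.append((s, fam, "viral_concentration", c))
            for fam, a in self.dna_virus_active[s].items():
                rows.append((s, fam, "dna_virus_active", int(a)))
            for sp, v in self.bacterial_dna[s].items():
                rows.append((s, sp, "bacterial_dna_abundance", v))
            for sp, v in self.bacterial_activity[s].items():
                rows.append((s, sp, "bacterial_activity", v))
            for g, v in self.host_expression[s].items():
                rows.append((s, g, "host_expression", v))
        for f, (si, ni) in self.contaminants.items():
            rows.append(("", f, "contaminant_specimen_intensity", si))
            rows.append(("", f, "contaminant_ntc_intensity", ni))
        rows.append(("", IC_FEATURE_ID, "ic_concentration", self.ic_concentration))
        return pd.DataFrame(rows, columns=["sample_id", "feature_id", "truth_kind", "value"])


def _lognormal(rng: np.random.Generator, log10_median: float, log10_sd: float) -> float:
    return float(10.0 ** rng.normal(log10_median, log10_sd))


def generate_truth(
    n_specimens: int, seed: int, params: Optional[GeneratorParams] = None
) -> SyntheticTruth:
    """Draw per-specimen ground truth; deterministic under a fixed seed."""
    params = (params or GeneratorParams()).validated()
    if n_specimens != params.n_specimens:
        params = replace(params, n_specimens=n_specimens)
    rng = np.random.default_rng(seed)
    ids = [f"S{i + 1:02d}" for i in range(n_specimens)]

    endotype = {s: ("C2" if rng.random() < params.endotype_mixing else "C1") for s in ids}

    genes = [f"GENE{i + 1:04d}" for i in range(params.n_host_genes)]
    nb = min(params.n_block_genes, params.n_host_genes // 2)
    inflam = genes[:nb]
    rnamet = genes[nb: 2 * nb]
    gene_base = {g: _lognormal(rng, params.host_base_log10, params.host_base_sd) for g in genes}

    viral_conc: dict[str, dict[str, float]] = {}
    dna_active: dict[str, dict[str, bool]] = {}
    bact_dna: dict[str, dict[str, float]] = {}
    bact_act: dict[str, dict[str, float]] = {}
    host_expr: dict[str, dict[str, float]] = {}
    for s in ids:
        c2 = endotype[s] == "C2"
        vc: dict[str, float] = {}
        for v in params.rna_viruses:
            vc[v.family] = (
                _lognormal(rng, v.log10_conc, v.log10_sd) if rng.random() < v.prevalence else 0.0
            )
        act: dict[str, bool] = {}
        for v in params.dna_viruses:
            present = rng.random() < v.prevalence
            vc[v.family] = _lognormal(rng, v.log10_conc, v.log10_sd) if present else 0.0
            p_act = v.active_prob_c2 if c2 else v.active_prob_c1
            act[v.family] = bool(present and rng.random() < p_act)
        if params.include_blacklisted_phage:
            vc[BLACKLISTED_PHAGE] = params.blacklisted_phage_conc
            act[BLACKLISTED_PHAGE] = True
        viral_conc[s] = vc
        dna_virus_active = act
        dna_active[s] = dna_virus_active

        bd: dict[str, float] = {}
        ba: dict[str, float] = {}
        for b in params.bacteria:
            present = rng.random() < b.prevalence
            bd[b.species] = _lognormal(rng, b.log10_dna, b.log10_sd) if present else 0.0
            mean_act = b.activity_c2 if c2 else b.activity_c1
            if mean_act == 0.0 or bd[b.species] == 0.0:
                ba[b.species] = 0.0
            else:
                ba[b.species] = mean_act * _lognormal(rng, 0.0, params.activity_noise_sd)
        bact_dna[s] = bd
        bact_act[s] = ba

        he: dict[str, float] = {}
        for g in genes:
            fold = 1.0
            if g in inflam and c2:
                fold = params.host_fold_change
            elif g in rnamet and not c2:
                fold = params.host_fold_change
            he[g] = gene_base[g] * fold * _lognormal(rng, 0.0, params.host_noise_sd)
        host_expr[s] = he

    contaminants: dict[str, tuple[float, float]] = {}
    for name in _DEFAULT_VIRAL_CONTAMINANTS[: params.n_viral_contaminants]:
        ntc = _lognormal(rng, params.contaminant_ntc_log10, params.contaminant_ntc_sd)
        contaminants[name] = (ntc * params.contaminant_specimen_fraction, ntc)
    for name in _DEFAULT_BACT_CONTAMINANTS[: params.n_bacterial_contaminants]:
        ntc = _lognormal(rng, params.contaminant_ntc_log10, params.contaminant_ntc_sd)
        contaminants[name] = (ntc * params.contaminant_specimen_fraction, ntc)

    return SyntheticTruth(
        specimen_ids=ids,
        endotype=endotype,
        viral_concentration=viral_conc,
        dna_virus_active=dna_active,
        bacterial_dna=bact_dna,
        bacterial_activity=bact_act,
        host_expression=host_expr,
        ic_concentration=params.ic_concentration,
        contaminants=contaminants,
        inflammatory_genes=inflam,
        rna_metabolism_genes=rnamet,
        params=params,
    )


def _viral_contaminant_ids(truth: SyntheticTruth) -> list[str]:
    return [f for f in truth.contaminants if f in _DEFAULT_VIRAL_CONTAMINANTS]


def _bacterial_contaminant_ids(truth: SyntheticTruth) -> list[str]:
    return [f for f in truth.contaminants if f in _DEFAULT_BACT_CONTAMINANTS]


def expected_composition(
    truth: SyntheticTruth, assay: Assay | str, sample_id: str, role: Role | str = Role.SPECIMEN
) -> pd.Series:
    """Expected per-feature read probabilities under the assay's capture rule.

    Returns a Series over the assay's feature universe summing to 1 (or all
    zero when nothing is captured, e.g. a no-template control of an assay
    with no contaminants and no IC).
    """
    assay = Assay(assay)
    role = Role(role)
    if role is Role.SPECIMEN and sample_id not in truth.endotype:
        raise KeyError(f"unknown specimen {sample_id!r}")
    p = truth.params
    intensity: dict[str, float] = {}

    def _contaminant(feature: str) -> float:
        si, ni = truth.contaminants[feature]
        return ni if role is Role.NTC else si

    if assay is Assay.VIR_MNGS:
        if role is Role.SPECIMEN:
            for fam, c in truth.viral_concentration[sample_id].items():
                intensity[fam] = c
        else:
            for fam in truth.viral_concentration[truth.specimen_ids[0]]:
                intensity[fam] = 0.0
        for f in _viral_contaminant_ids(truth):
            intensity[f] = _contaminant(f)
        intensity[IC_FEATURE_ID] = truth.ic_concentration
    elif assay is Assay.S16:
        genera: dict[str, float] = {}
        first = truth.specimen_ids[0]
        for sp in truth.bacterial_dna[first]:
            g = genus_of(sp)
            dna = truth.bacterial_dna[sample_id][sp] if role is Role.SPECIMEN else 0.0
            genera[g] = genera.get(g, 0.0) + dna
        intensity.update(genera)
        for f in _bacterial_contaminant_ids(truth):
            intensity[genus_of(f)] = intensity.get(genus_of(f), 0.0) + _contaminant(f)
    elif assay is Assay.MRNA:
        for g in truth.host_genes:
            intensity[g] = truth.host_expression[sample_id][g] if role is Role.SPECIMEN else 0.0
    elif assay is Assay.METARNA:
        rna_families = {v.family for v in p.rna_viruses}
        first = truth.specimen_ids[0]
        for fam in truth.viral_concentration[first]:
            if role is Role.NTC:
                intensity[fam] = 0.0
            elif fam in rna_families:
                intensity[fam] = p.metarna_viral_weight * truth.viral_concentration[sample_id][fam]
            else:  # DNA virus: RNA reads only when transcriptionally active
                active = truth.dna_virus_active[sample_id].get(fam, False)
                intensity[fam] = (
                    p.metarna_viral_weight * truth.viral_concentration[sample_id][fam]
                    if active else 0.0
                )
        for sp in truth.bacterial_dna[first]:
            if role is Role.NTC:
                intensity[sp] = 0.0
            else:
                intensity[sp] = (
                    p.metarna_bacterial_weight
                    * truth.bacterial_dna[sample_id][sp]
                    * truth.bacterial_activity[sample_id][sp]
                )
        for g in truth.host_genes:
            intensity[g] = (
                p.metarna_host_weight * truth.host_expression[sample_id][g]
                if role is Role.SPECIMEN
                else 0.0
            )
        for f in truth.contaminants:
            intensity[f] = _contaminant(f)
        intensity[IC_FEATURE_ID] = truth.ic_concentration
    else:  # pragma: no cover - Assay() above rejects unknowns
        raise ValueError(f"unknown assay {assay!r}")

    ser = pd.Series(intensity, dtype=float)
    if (ser < 0).any():
        raise ValueError("negative expected intensity")
    total = ser.sum()
    return ser / total if total > 0 else ser


def sample_counts(
    probabilities: pd.Series | np.ndarray, depth: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Multinomial count draw; sum of counts equals ``depth`` exactly."""
    p = np.asarray(probabilities, dtype=float)
    if (p < 0).any():
        raise ValueError("negative probability")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if depth == 0 or p.sum() == 0:
        return np.zeros(len(p), dtype=np.int64)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities sum to {p.sum()}, expected 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.multinomial(depth, p / p.sum()).astype(np.int64)


def _feature_meta_for(truth: SyntheticTruth, assay: Assay) -> dict[str, FeatureMeta]:
    p = truth.params
    metas: dict[str, FeatureMeta] = {}
    rna_families = {v.family for v in p.rna_viruses}
    vhost = {v.family: v.host_type for v in p.rna_viruses}
    vhost.update({v.family: v.host_type for v in p.dna_viruses})

    def viral_meta(fam: str) -> FeatureMeta:
        gt = GenomeType.RNA if fam in rna_families else GenomeType.DNA
        if fam in _DEFAULT_VIRAL_CONTAMINANTS:
            gt, ht = GenomeType.DNA, HostType.EUKARYOTIC
        elif fam == BLACKLISTED_PHAGE:
            gt, ht = GenomeType.DNA, HostType.PROKARYOTIC
        else:
            ht = vhost[fam]
        return FeatureMeta(fam, Kingdom.VIRAL, Rank.FAMILY, gt, ht,
                           blacklisted=(fam == BLACKLISTED_PHAGE))

    first = truth.specimen_ids[0]
    if assay in (Assay.VIR_MNGS, Assay.METARNA):
        for fam in truth.viral_concentration[first]:
            metas[fam] = viral_meta(fam)
        for f in _viral_contaminant_ids(truth):
            metas[f] = viral_meta(f)
        metas[IC_FEATURE_ID] = FeatureMeta(
            IC_FEATURE_ID, Kingdom.CONTROL, Rank.SPECIES, GenomeType.RNA, HostType.PROKARYOTIC
        )
    if assay is Assay.S16:
        genera = sorted(
            {genus_of(sp) for sp in truth.bacterial_dna[first]}
            | {genus_of(f) for f in _bacterial_contaminant_ids(truth)}
        )
        for g in genera:
            metas[g] = FeatureMeta(g, Kingdom.BACTERIAL, Rank.GENUS, GenomeType.DNA, HostType.NA)
    if assay is Assay.METARNA:
        for sp in list(truth.bacterial_dna[first]) + _bacterial_contaminant_ids(truth):
            metas[sp] = FeatureMeta(sp, Kingdom.BACTERIAL, Rank.SPECIES, GenomeType.DNA, HostType.NA)
    if assay in (Assay.MRNA, Assay.METARNA):
        for g in truth.host_genes:
            metas[g] = FeatureMeta(g, Kingdom.HOST, Rank.GENE, GenomeType.NA, HostType.NA)
    return metas


def generate_study(
    params: Optional[GeneratorParams] = None, seed: int = 0
) -> tuple[dict[Assay, AssayDataset], SyntheticTruth]:
    """Generate the four assay views (specimens + NTCs) and the truth.

    Sample ids are shared across assays; NTC counts come only from
    contaminant and IC intensities. All randomness derives from ``seed``.
    """
    params = (params or GeneratorParams()).validated()
    root = np.random.default_rng(seed)
    truth_seed = int(root.integers(2**31 - 1))
    truth = generate_truth(params.n_specimens, truth_seed, params)
    datasets: dict[Assay, AssayDataset] = {}

    for assay in (Assay.VIR_MNGS, Assay.S16, Assay.MRNA, Assay.METARNA):
        arng = np.random.default_rng(root.integers(2**31 - 1))
        metas = _feature_meta_for(truth, assay)
        log10_med, log10_sd = params.depths[assay.value]
        ntc_med, ntc_sd = params.depths["ntc"]
        columns: dict[str, np.ndarray] = {}
        samples: dict[str, SampleMeta] = {}
        feature_index: Optional[pd.Index] = None

        sample_plan = [(s, Role.SPECIMEN) for s in truth.specimen_ids]
        sample_plan += [
            (f"NTC_{assay.value}_{i + 1}", Role.NTC)
            for i in range(params.n_ntc.get(assay.value, 0))
        ]
        for sid, role in sample_plan:
            probs = expected_composition(truth, assay, sid, role)
            if feature_index is None:
                feature_index = probs.index
            if probs.sum() == 0:
                depth = 0
            else:
                med = log10_med if role is Role.SPECIMEN else ntc_med
                sd = log10_sd if role is Role.SPECIMEN else ntc_sd
                depth = max(0, int(round(10.0 ** arng.normal(med, sd))))
            pvec = probs.to_numpy()
            if params.dirichlet_overdispersion and probs.sum() > 0:
                alpha = pvec * params.dirichlet_overdispersion
                mask = alpha > 0
                pert = np.zeros_like(pvec)
                pert[mask] = arng.dirichlet(alpha[mask])
                pvec = pert
            columns[sid] = sample_counts(pvec, depth, arng)
            quant: dict[str, float] = {}
            if role is Role.SPECIMEN and assay is Assay.METARNA:
                rsv = truth.viral_concentration[sid].get("Pneumoviridae", 0.0)
                if rsv > 0:
                    quant["rsv"] = float(
                        params.ct_intercept
                        - params.ct_slope * np.log10(rsv)
                        + arng.normal(0.0, params.ct_noise_sd)
                    )
            samples[sid] = SampleMeta(sid, role, assay, total_reads=int(depth), external_quant=quant)

        df = pd.DataFrame(columns, index=feature_index).astype(np.int64)
        df.index.name = "feature_id"
        ic = IC_FEATURE_ID if assay in (Assay.VIR_MNGS, Assay.METARNA) else None
        datasets[assay] = AssayDataset(
            table=CountTable(df), features=metas, samples=samples, ic_feature_id=ic
        )
    return datasets, truth


def planted_contaminant_ids(truth: SyntheticTruth, assay: Assay | str) -> set[str]:
    """Feature ids of planted contaminants as they appear in a given assay
    (bacterial contaminants surface at genus level in 16S, species level in
    metatranscriptomics)."""
    assay = Assay(assay)
    viral = set(_viral_contaminant_ids(truth))
    bact = set(_bacterial_contaminant_ids(truth))
    if assay is Assay.VIR_MNGS:
        return viral
    if assay is Assay.S16:
        return {genus_of(f) for f in bact}
    if assay is Assay.METARNA:
        return viral | bact
    return set()


def species_to_genus_mapping(d: AssayDataset) -> dict[str, str]:
    """Mapping from bacterial species features to genus groups."""
    return {
        f: genus_of(f)
        for f in d.table.feature_ids
        if f in d.features
        and d.features[f].kingdom is Kingdom.BACTERIAL
        and d.features[f].rank is Rank.SPECIES
    }
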