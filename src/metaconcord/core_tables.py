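"""Shared domain types, TSV I/O, config loading and dataset validation.

The pipeline operates on per-assay count tables (features x samples,
non-negative integers) plus feature and sample metadata. Counts stay
integral until normalization so that conservation checks are exact.

TSV dialect: UTF-8, tab-separated, header row = sample ids, first column =
feature ids, no quoting — the layout of common taxonomic-profile exports.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Kingdom",
    "Rank",
    "GenomeType",
    "HostType",
    "Role",
    "Assay",
    "CountTable",
    "FeatureMeta",
    "SampleMeta",
    "AssayDataset",
    "Finding",
    "EndotypeConfig",
    "Config",
    "read_count_table",
    "write_count_table",
    "aggregate",
    "validate_dataset",
    "read_feature_meta",
    "write_feature_meta",
    "read_sample_meta",
    "write_sample_meta",
    "genus_of",
]


class Kingdom(str, enum.Enum):
    VIRAL = "viral"
    BACTERIAL = "bacterial"
    HOST = "host"
    CONTROL = "control"


class Rank(str, enum.Enum):
    FAMILY = "family"
    GENUS = "genus"
    SPECIES = "species"
    GENE = "gene"
    ASV = "asv"


class GenomeType(str, enum.Enum):
    DNA = "DNA"
    RNA = "RNA"
    NA = "NA"


class HostType(str, enum.Enum):
    EUKARYOTIC = "eukaryotic"
    PROKARYOTIC = "prokaryotic"
    NA = "NA"


class Role(str, enum.Enum):
    SPECIMEN = "specimen"
    NTC = "ntc"


class Assay(str, enum.Enum):
    VIR_MNGS = "vir_mngs"
    S16 = "s16"
    MRNA = "mrna"
    METARNA = "metarna"


class ValidationError(ValueError):
    """Raised when a table or dataset violates a structural invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class CountTable:
    """Integer count matrix, features x samples.

    ``df`` is a pandas DataFrame with feature ids as the index and sample
    ids as the columns; every cell is a non-negative integer.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        _check_unique(list(df.index), "feature")
        _check_unique(list(df.columns), "sample")
        if not all(np.issubdtype(dt, np.integer) for dt in df.dtypes):
            # locate the offending cell for a useful message
            for s in df.columns:
                col = df[s]
                if np.issubdtype(col.dtype, np.integer):
                    continue
                for f, v in col.items():
                    if float(v) != int(v):
                        raise ValidationError(
                            f"non-integer count at feature {f!r}, sample {s!r}: {v!r}"
                        )
            self.df = df = df.astype(np.int64)
        if (df.to_numpy() < 0).any():
            fi, si = np.argwhere(df.to_numpy() < 0)[0]
            raise ValidationError(
                f"negative count at feature {df.index[fi]!r}, sample {df.columns[si]!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.df.to_numpy()

    def column_sums(self) -> pd.Series:
        return self.df.sum(axis=0)

    def subset_features(self, ids: Iterable[str]) -> "CountTable":
        ids = [i for i in ids if i in self.df.index]
        return CountTable(self.df.loc[ids].copy())

    def subset_samples(self, ids: Iterable[str]) -> "CountTable":
        ids = [i for i in ids if i in self.df.columns]
        return CountTable(self.df[ids].copy())


def read_count_table(path: str | Path, orientation: str = "features_by_samples") -> CountTable:
    """Read a TSV count table; ``orientation`` may be ``features_by_samples``
    (default) or ``samples_by_features`` (transposed on read)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if orientation == "samples_by_features":
        raw = raw.T
    elif orientation != "features_by_samples":
        raise ValueError(f"unknown orientation {orientation!r}")
    _check_unique(list(raw.index), "feature")
    _check_unique(list(raw.columns), "sample")
    out = pd.DataFrame(index=raw.index.astype(str), columns=raw.columns.astype(str), dtype=np.int64)
    for s in raw.columns:
        for f, v in raw[s].items():
            try:
                iv = int(v)
            except ValueError:
                raise ValidationError(
                    f"non-integer count at feature {f!r}, sample {s!r}: {v!r}"
                ) from None
            if iv < 0:
                raise ValidationError(f"negative count at feature {f!r}, sample {s!r}: {v!r}")
            out.loc[f, s] = iv
    out.index.name = "feature_id"
    return CountTable(out)


def write_count_table(t: CountTable, path: str | Path) -> None:
    df = t.df.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


def aggregate(t: CountTable, mapping: Mapping[str, str]) -> CountTable:
    """Sum features into groups (e.g. species -> genus).

    Features without a mapping entry are dropped; per-sample totals of the
    mapped features are conserved exactly.
    """
    if not mapping:
        raise ValueError("empty aggregation mapping")
    kept = [f for f in t.feature_ids if f in mapping]
    df = t.df.loc[kept]
    groups = pd.Series({f: mapping[f] for f in kept}, name="group")
    agg = df.groupby(groups, sort=False).sum()
    agg.index.name = "feature_id"
    return CountTable(agg.astype(np.int64))


@dataclass(frozen=True)
class FeatureMeta:
    feature_id: str
    kingdom: Kingdom
    rank: Rank
    genome_type: GenomeType = GenomeType.NA
    host_type: HostType = HostType.NA
    blacklisted: bool = False


@dataclass
class SampleMeta:
    sample_id: str
    role: Role
    assay: Assay
    total_reads: int = 0
    external_quant: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class Finding:
    """Machine-readable validation finding."""

    code: str
    location: str
    message: str


@dataclass
class AssayDataset:
    """One assay view: counts + feature metadata + sample metadata."""

    table: CountTable
    features: dict[str, FeatureMeta]
    samples: dict[str, SampleMeta]
    ic_feature_id: Optional[str] = None

    @property
    def assay(self) -> Assay:
        return next(iter(self.samples.values())).assay

    def specimen_ids(self) -> list[str]:
        return [s for s in self.table.sample_ids if self.samples[s].role is Role.SPECIMEN]

    def ntc_ids(self) -> list[str]:
        return [s for s in self.table.sample_ids if self.samples[s].role is Role.NTC]

    def feature_ids_by_kingdom(self, kingdom: Kingdom) -> list[str]:
        return [
            f for f in self.table.feature_ids
            if f in self.features and self.features[f].kingdom is kingdom
        ]


def validate_dataset(d: AssayDataset) -> list[Finding]:
    """Check every structural invariant; returns findings, never raises."""
    findings: list[Finding] = []
    fids = set(d.table.feature_ids)
    sids = set(d.table.sample_ids)
    for f in d.table.feature_ids:
        if f not in d.features:
            findings.append(Finding("FEATURE_META_MISSING", f, "feature has no metadata"))
    for s in d.table.sample_ids:
        if s not in d.samples:
            findings.append(Finding("SAMPLE_META_MISSING", s, "sample has no metadata"))
    if d.ic_feature_id is not None:
        if d.ic_feature_id not in fids:
            findings.append(Finding("IC_MISSING", d.ic_feature_id, "IC feature not in table"))
        elif (
            d.ic_feature_id in d.features
            and d.features[d.ic_feature_id].kingdom is not Kingdom.CONTROL
        ):
            findings.append(Finding("IC_NOT_CONTROL", d.ic_feature_id, "IC kingdom != control"))
    assays = {m.assay for s, m in d.samples.items() if s in sids}
    if len(assays) > 1:
        findings.append(
            Finding("ASSAY_MIXED", ",".join(sorted(m.value for m in assays)), "samples span multiple assays")
        )
    colsum = d.table.column_sums()
    for s in d.table.sample_ids:
        m = d.samples.get(s)
        if m is not None and m.total_reads and m.total_reads < int(colsum[s]):
            findings.append(
                Finding("TOTAL_READS_LT_COLUMN_SUM", s,
                        f"total_reads {m.total_reads} < column sum {int(colsum[s])}")
            )
    for f, meta in d.features.items():
        if meta.kingdom is Kingdom.CONTROL and meta.genome_type is not GenomeType.RNA:
            findings.append(Finding("CONTROL_NOT_RNA", f, "control features are RNA by definition"))
        if meta.kingdom is Kingdom.HOST and meta.genome_type is not GenomeType.NA:
            findings.append(Finding("HOST_GENOME_TYPE", f, "host features carry genome_type NA"))
    return findings


# ---------------------------------------------------------------------------
# metadata I/O

_FEATURE_COLS = ["feature_id", "kingdom", "rank", "genome_type", "host_type", "blacklisted"]


def write_feature_meta(features: Mapping[str, FeatureMeta], path: str | Path) -> None:
    rows = [
        {
            "feature_id": m.feature_id,
            "kingdom": m.kingdom.value,
            "rank": m.rank.value,
            "genome_type": m.genome_type.value,
            "host_type": m.host_type.value,
            "blacklisted": str(m.blacklisted).lower(),
        }
        for m in features.values()
    ]
    pd.DataFrame(rows, columns=_FEATURE_COLS).to_csv(path, sep="\t", index=False)


def read_feature_meta(path: str | Path) -> dict[str, FeatureMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: dict[str, FeatureMeta] = {}
    for _, r in df.iterrows():
        out[r["feature_id"]] = FeatureMeta(
            feature_id=r["feature_id"],
            kingdom=Kingdom(r["kingdom"]),
            rank=Rank(r["rank"]),
            genome_type=GenomeType(r.get("genome_type", "NA") or "NA"),
            host_type=HostType(r.get("host_type", "NA") or "NA"),
            blacklisted=str(r.get("blacklisted", "false")).lower() in ("true", "1", "yes"),
        )
    return out


def write_sample_meta(samples: Mapping[str, SampleMeta], path: str | Path) -> None:
    quant_keys = sorted({k for m in samples.values() for k in m.external_quant})
    rows = []
    for m in samples.values():
        row: dict[str, object] = {
            "sample_id": m.sample_id,
            "role": m.role.value,
            "assay": m.assay.value,
            "total_reads": m.total_reads,
        }
        for k in quant_keys:
            row[f"ct_{k}"] = m.external_quant.get(k, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_sample_meta(path: str | Path) -> dict[str, SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: dict[str, SampleMeta] = {}
    quant_cols = [c for c in df.columns if c.startswith("ct_")]
    for _, r in df.iterrows():
        quant = {}
        for c in quant_cols:
            if r[c] != "":
                quant[c[3:]] = float(r[c])
        out[r["sample_id"]] = SampleMeta(
            sample_id=r["sample_id"],
            role=Role(r["role"]),
            assay=Assay(r["assay"]),
            total_reads=int(r["total_reads"] or 0),
            external_quant=quant,
        )
    return out


def genus_of(species_id: str) -> str:
    """Genus by the leading token of an underscore-delimited species id."""
    return species_id.split("_", 1)[0]


# ---------------------------------------------------------------------------
# configuration


@dataclass
class EndotypeConfig:
    microbe_prevalence: float = 0.30
    host_prevalence: float = 0.50
    n_factors_multiomics: int = 15
    n_factors_metarna: int = 10
    k: Optional[int] = 2           # forced cluster count; None -> voted k
    k_range: tuple[int, int] = (2, 6)
    kmeans_restarts: int = 10
    embedding: str = "factors"     # "factors" | "umap" (plug-in)
    permutations: int = 999


@dataclass
class Config:
    pseudocount: float = 1e-5
    alr_positive_threshold: float = -1.0
    alr_confident_threshold: float = 0.0
    ntc_ratio_threshold: float = 5.0
    prevalence_alpha: float = 0.05
    ra_thresholds: tuple[float, ...] = (0.005, 0.10)
    min_ic_reads: int = 1
    min_mapped_reads: int = 10_000
    min_bacterial_reads: int = 1_000
    min_human_reads: int = 100_000
    plateau_epsilon: float = 1.0
    saturation_fraction: float = 0.95
    host_ref_prevalence: float = 0.85
    dna_rna_min_samples: int = 5
    rpm_denominator: str = "column_sum"
    endotype: EndotypeConfig = field(default_factory=EndotypeConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.ntc_ratio_threshold <= 0:
            raise ValueError("ntc_ratio_threshold must be positive")
        if not 0 < self.prevalence_alpha < 1:
            raise ValueError("prevalence_alpha must be in (0,1)")
        for t in self.ra_thresholds:
            if not 0 < t < 1:
                raise ValueError("ra_thresholds must be in (0,1)")
        for name in ("alr_positive_threshold", "alr_confident_threshold"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @classmethod
    def from_dict(cls, d: Mapping) -> "Config":
        d = dict(d)
        endo = d.pop("endotype", {})
        if isinstance(endo, Mapping):
            endo = dict(endo)
            if "k_range" in endo:
                endo["k_range"] = tuple(endo["k_range"])
            endo = EndotypeConfig(**endo)
        if "ra_thresholds" in d:
            d["ra_thresholds"] = tuple(d["ra_thresholds"])
        return cls(endotype=endo, **d)

    @classmethod
    def from_file(cls, path: str | Path) -> "Config":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ra_thresholds"] = list(self.ra_thresholds)
        d["endotype"]["k_range"] = list(self.endotype.k_range)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)
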