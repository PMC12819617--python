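"""Detection- and abundance-level concordance between a test assay
(metatranscriptomics) and a kingdom-specific reference assay.

The unit of counting is the "hit": one feature detected in one sample.
Given two call sets the summary reports shared, reference-only and
test-only hits, from which sensitivity = shared/(shared+ref_only),
missed rate = 1 - sensitivity and Jaccard = shared/union derive.

Abundance agreement uses Pearson correlation on paired normalized values
(ALR for viruses, relative abundance for bacteria, log2 RPM for host
genes), optionally restricted to a user-supplied gene set.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .core_tables import FeatureMeta, SampleMeta
from .normalization import Norm, NormalizedTable

__all__ = [
    "ThresholdRule",
    "DetectionCallSet",
    "ConcordanceSummary",
    "CorrelationResult",
    "call_detections",
    "concordance_summary",
    "stratified_sensitivity",
    "paired_correlation",
    "external_quant_correlation",
    "exclusive_detections",
    "dna_rna_discordance",
    "read_gene_set",
]


class RuleKind(str, enum.Enum):
    ALR_GE = "alr_ge"          # score >= threshold on an ALR table
    RA_POSITIVE = "ra_positive"  # relative abundance > 0
    RA_GE = "ra_ge"            # relative abundance >= threshold
    PRESENCE = "presence"      # non-missing cell on a LOG2RPM table


@dataclass(frozen=True)
class ThresholdRule:
    kind: RuleKind
    threshold: Optional[float] = None

    @property
    def expected_norm(self) -> Norm:
        return {
            RuleKind.ALR_GE: Norm.ALR,
            RuleKind.RA_POSITIVE: Norm.RA,
            RuleKind.RA_GE: Norm.RA,
            RuleKind.PRESENCE: Norm.LOG2RPM,
        }[self.kind]

    def describe(self) -> str:
        if self.kind is RuleKind.ALR_GE:
            return f"ALR >= {self.threshold}"
        if self.kind is RuleKind.RA_GE:
            return f"RA >= {self.threshold}"
        if self.kind is RuleKind.RA_POSITIVE:
            return "RA > 0"
        return "detected (log2RPM present)"


@dataclass
class DetectionCallSet:
    """Per-(sample, feature) detection calls with their scores."""

    assay: str
    unit: str                       # e.g. "feature-sample pair"
    calls: pd.DataFrame             # columns: sample_id, feature_id, score, positive
    rule: str

    def positive_pairs(self) -> set[tuple[str, str]]:
        pos = self.calls[self.calls["positive"]]
        return set(zip(pos["sample_id"], pos["feature_id"]))

    def score_of(self, sample_id: str, feature_id: str) -> float:
        m = self.calls[
            (self.calls["sample_id"] == sample_id) & (self.calls["feature_id"] == feature_id)
        ]
        return float(m["score"].iloc[0]) if len(m) else float("nan")


@dataclass(frozen=True)
class ConcordanceSummary:
    shared: int
    ref_only: int
    test_only: int

    @property
    def sensitivity(self) -> float:
        denom = self.shared + self.ref_only
        return self.shared / denom if denom else float("nan")

    @property
    def missed_rate(self) -> float:
        return 1.0 - self.sensitivity

    @property
    def jaccard(self) -> float:
        union = self.shared + self.ref_only + self.test_only
        return self.shared / union if union else float("nan")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    pairing: str


def call_detections(
    norm: NormalizedTable,
    rule: ThresholdRule,
    assay: str = "",
    features: Optional[Iterable[str]] = None,
    unit: str = "feature-sample pair",
) -> DetectionCallSet:
    """Apply a threshold rule to every (sample, feature) cell."""
    if norm.norm is not rule.expected_norm:
        raise ValueError(
            f"rule {rule.kind.value} expects {rule.expected_norm.value}, got {norm.norm.value}"
        )
    vals = norm.values
    if features is not None:
        keep = [f for f in vals.index if f in set(features)]
        vals = vals.loc[keep]
    long = vals.reset_index().melt(id_vars=vals.index.name or "index",
                                   var_name="sample_id", value_name="score")
    long = long.rename(columns={vals.index.name or "index": "feature_id"})
    if rule.kind is RuleKind.ALR_GE:
        pos = long["score"] >= rule.threshold
    elif rule.kind is RuleKind.RA_POSITIVE:
        pos = long["score"] > 0
    elif rule.kind is RuleKind.RA_GE:
        pos = long["score"] >= rule.threshold
    else:  # PRESENCE
        pos = long["score"].notna()
    long["positive"] = pos.fillna(False)
    return DetectionCallSet(assay=assay, unit=unit,
                            calls=long[["sample_id", "feature_id", "score", "positive"]],
                            rule=rule.describe())


def concordance_summary(
    ref: DetectionCallSet,
    test: DetectionCallSet,
    restrict_to_shared_samples: bool = True,
    test_exclusion: Optional[set[tuple[str, str]]] = None,
) -> ConcordanceSummary:
    """Shared / ref-only / test-only hit counts over the union of positive
    calls.

    ``test_exclusion`` drops the given test-only pairs from the union (used
    to report the confident-threshold Jaccard where sub-threshold
    test-exclusive hits are excluded).
    """
    if ref.unit != test.unit:
        raise ValueError(f"unit mismatch: {ref.unit!r} vs {test.unit!r}")
    rpos = ref.positive_pairs()
    tpos = test.positive_pairs()
    if restrict_to_shared_samples:
        shared_samples = set(ref.calls["sample_id"]) & set(test.calls["sample_id"])
        rpos = {p for p in rpos if p[0] in shared_samples}
        tpos = {p for p in tpos if p[0] in shared_samples}
    if test_exclusion:
        tpos = {p for p in tpos if p in rpos or p not in test_exclusion}
    return ConcordanceSummary(
        shared=len(rpos & tpos),
        ref_only=len(rpos - tpos),
        test_only=len(tpos - rpos),
    )


def stratified_sensitivity(
    ref_ra: NormalizedTable,
    test_calls: DetectionCallSet,
    thresholds: Iterable[float],
    features: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Detection fraction of the test assay among reference hits exceeding
    each relative-abundance threshold.

    For each threshold t: total = #{(sample, feature): ref RA > t};
    detected = those with a positive test call; fraction = detected/total
    (NaN for an empty stratum).
    """
    if ref_ra.norm is not Norm.RA:
        raise ValueError("stratified_sensitivity expects a reference RA table")
    vals = ref_ra.values
    if features is not None:
        vals = vals.loc[[f for f in vals.index if f in set(features)]]
    shared_samples = sorted(set(vals.columns) & set(test_calls.calls["sample_id"]))
    vals = vals[shared_samples]
    tpos = test_calls.positive_pairs()
    rows = []
    for t in thresholds:
        if not 0 < t < 1:
            raise ValueError(f"threshold {t} outside (0,1)")
        total = 0
        detected = 0
        for f in vals.index:
            for s in shared_samples:
                if vals.loc[f, s] > t:
                    total += 1
                    if (s, f) in tpos:
                        detected += 1
        rows.append({
            "threshold": t,
            "detected": detected,
            "total": total,
            "fraction": detected / total if total else float("nan"),
        })
    return pd.DataFrame(rows)


def _detected_mask(norm: NormalizedTable) -> pd.DataFrame:
    """Cells with read evidence, per normalization semantics."""
    if norm.norm is Norm.ALR:
        floor = np.log10(norm.pseudocount) if norm.pseudocount else -np.inf
        return norm.values > floor + 1e-12
    if norm.norm is Norm.LOG2RPM:
        return norm.values.notna()
    return norm.values > 0


def paired_correlation(
    x: NormalizedTable,
    y: NormalizedTable,
    pairing: str = "both-detected",
    subset: Optional[Iterable[str]] = None,
) -> CorrelationResult:
    """Pearson correlation over paired (sample, feature) cells of two tables.

    ``pairing='both-detected'`` keeps cells with read evidence in both
    tables; ``'all-shared-cells'`` keeps every shared finite cell.
    """
    feats = [f for f in x.values.index if f in set(y.values.index)]
    if subset is not None:
        feats = [f for f in feats if f in set(subset)]
    samples = [s for s in x.values.columns if s in set(y.values.columns)]
    xv = x.values.loc[feats, samples]
    yv = y.values.loc[feats, samples]
    if pairing == "both-detected":
        mask = _detected_mask(NormalizedTable(xv, x.norm, x.denominator, x.pseudocount)) & \
            _detected_mask(NormalizedTable(yv, y.norm, y.denominator, y.pseudocount))
    elif pairing == "all-shared-cells":
        mask = xv.notna() & yv.notna()
    else:
        raise ValueError(f"unknown pairing {pairing!r}")
    xs = xv.to_numpy()[mask.to_numpy()]
    ys = yv.to_numpy()[mask.to_numpy()]
    if len(xs) < 3:
        raise ValueError(f"need >= 3 pairs, got {len(xs)}")
    if np.std(xs) == 0 or np.std(ys) == 0:
        raise ValueError("DEGENERATE: constant values, correlation undefined")
    r, p = pearsonr(xs, ys)
    return CorrelationResult(float(r), float(p), int(len(xs)), pairing)


def external_quant_correlation(
    norm: NormalizedTable,
    feature: str,
    quant_key: str,
    samples: dict[str, SampleMeta],
) -> CorrelationResult:
    """Pearson correlation between one feature's normalized values and an
    external quantity (e.g. an RT-PCR Ct) stored in the sample metadata."""
    if feature not in norm.values.index:
        raise KeyError(f"feature {feature!r} not in table")
    xs, ys = [], []
    for s in norm.sample_ids:
        meta = samples.get(s)
        if meta is None or quant_key not in meta.external_quant:
            continue
        xs.append(float(norm.values.loc[feature, s]))
        ys.append(float(meta.external_quant[quant_key]))
    if len(xs) < 3:
        raise ValueError(f"need >= 3 samples with both values, got {len(xs)}")
    if np.std(xs) == 0 or np.std(ys) == 0:
        raise ValueError("DEGENERATE: constant values, correlation undefined")
    r, p = pearsonr(xs, ys)
    return CorrelationResult(float(r), float(p), len(xs), f"{feature} vs {quant_key}")


def exclusive_detections(
    ref: DetectionCallSet,
    test: DetectionCallSet,
    annotations: Optional[dict[str, FeatureMeta]] = None,
) -> pd.DataFrame:
    """List every hit seen by exactly one technique, with its score in that
    technique and feature annotations."""
    if ref.unit != test.unit:
        raise ValueError(f"unit mismatch: {ref.unit!r} vs {test.unit!r}")
    shared_samples = set(ref.calls["sample_id"]) & set(test.calls["sample_id"])
    rpos = {p for p in ref.positive_pairs() if p[0] in shared_samples}
    tpos = {p for p in test.positive_pairs() if p[0] in shared_samples}
    rows = []
    for side, pairs, callset, other in (
        ("ref_only", rpos - tpos, ref, test),
        ("test_only", tpos - rpos, test, ref),
    ):
        for s, f in sorted(pairs):
            meta = (annotations or {}).get(f)
            rows.append({
                "side": side,
                "sample_id": s,
                "feature_id": f,
                "score": callset.score_of(s, f),
                "other_score": other.score_of(s, f),
                "genome_type": meta.genome_type.value if meta else "",
                "host_type": meta.host_type.value if meta else "",
            })
    return pd.DataFrame(
        rows, columns=["side", "sample_id", "feature_id", "score", "other_score",
                       "genome_type", "host_type"]
    )


def dna_rna_discordance(
    ref_ra: NormalizedTable,
    test_calls: DetectionCallSet,
    min_samples: int = 5,
) -> list[str]:
    """Features detected by the DNA-level reference in >= ``min_samples``
    samples but never called positive by the test assay anywhere — the
    signature of taxa that are present but transcriptionally silent."""
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    shared_samples = sorted(set(ref_ra.values.columns) & set(test_calls.calls["sample_id"]))
    detected = (ref_ra.values[shared_samples] > 0).sum(axis=1)
    tpos_features = {f for _, f in test_calls.positive_pairs()}
    return [f for f in ref_ra.values.index
            if int(detected[f]) >= min_samples and f not in tpos_features]


def read_gene_set(path: str | Path) -> list[str]:
    """Gene-set file: one gene id per line, '#' comments allowed."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    return genes
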