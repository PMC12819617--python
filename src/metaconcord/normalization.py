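"""Normalizations used by the cross-assay comparison.

* RPM — reads per million, count / denominator * 1e6.
* RA  — relative abundance within a feature subset (columns sum to 1).
* LOG2RPM — log2 of RPM for detected cells; zero-count cells are left as
  missing (NaN), i.e. treated as non-detections rather than imputed.
* ALR — additive log-ratio against the spiked internal control (IC):
  log10(RPM_feature / RPM_IC + pseudocount). The pseudocount is added to
  the ratio itself, so a feature with no reads maps exactly to
  log10(pseudocount) (-5 at the default 1e-5), which anchors the
  "undetected" floor of the scale.

Shannon diversity is reported in natural-log units.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core_tables import CountTable, SampleMeta

__all__ = [
    "Norm",
    "NormalizedTable",
    "DiversityProfile",
    "normalize_rpm",
    "alr_transform",
    "relative_abundance",
    "log2_rpm",
    "diversity",
]


class Norm(str, enum.Enum):
    RPM = "RPM"
    RA = "RA"
    LOG2RPM = "LOG2RPM"
    ALR = "ALR"


@dataclass
class NormalizedTable:
    """Real-valued table tagged with the normalization that produced it."""

    values: pd.DataFrame            # features x samples
    norm: Norm
    denominator: str                # "column_sum" | "total_reads" | IC feature id
    pseudocount: Optional[float] = None
    excluded_samples: dict[str, str] = field(default_factory=dict)  # id -> reason

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# norm={self.norm.value}\tdenominator={self.denominator}"
                f"\tpseudocount={self.pseudocount}\n"
            )
            df = self.values.copy()
            df.index.name = "feature_id"
            df.to_csv(fh, sep="\t", float_format="%.10g")


def normalize_rpm(
    t: CountTable,
    denominator: str = "column_sum",
    sample_meta: Optional[dict[str, SampleMeta]] = None,
) -> NormalizedTable:
    """Reads-per-million: count / denominator * 1e6.

    ``denominator`` is ``column_sum`` (default) or ``total_reads`` taken from
    the sample metadata.
    """
    if denominator == "column_sum":
        denom = t.column_sums().astype(float)
    elif denominator == "total_reads":
        if sample_meta is None:
            raise ValueError("total_reads denominator requires sample metadata")
        denom = pd.Series({s: float(sample_meta[s].total_reads) for s in t.sample_ids})
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    zero = denom[denom <= 0]
    if len(zero):
        raise ValueError(f"zero read denominator for sample {zero.index[0]!r}")
    values = t.df.astype(float).div(denom, axis=1) * 1e6
    return NormalizedTable(values, Norm.RPM, denominator)


def alr_transform(
    rpm: NormalizedTable, ic: str, pseudocount: float = 1e-5
) -> NormalizedTable:
    """Additive log-ratio against the internal control.

    Samples where the IC has zero reads cannot be anchored and are excluded,
    with the reason recorded in ``excluded_samples`` (this mirrors the
    IC-detection quality gate).
    """
    if rpm.norm is not Norm.RPM:
        raise ValueError("alr_transform expects an RPM table")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if ic not in rpm.values.index:
        raise KeyError(f"IC feature {ic!r} not in table")
    ic_row = rpm.values.loc[ic]
    excluded = {s: "IC_ZERO" for s in rpm.sample_ids if ic_row[s] <= 0}
    keep = [s for s in rpm.sample_ids if s not in excluded]
    sub = rpm.values[keep]
    alr = np.log10(sub.div(sub.loc[ic], axis=1) + pseudocount)
    return NormalizedTable(alr, Norm.ALR, denominator=ic, pseudocount=pseudocount,
                           excluded_samples=excluded)


def relative_abundance(
    t: CountTable, feature_subset: Optional[list[str]] = None
) -> NormalizedTable:
    """Within-subset relative abundance; columns sum to 1.

    A sample whose subset column is all zero has no composition to report
    and raises, naming the sample (such samples must be excluded upstream).
    """
    sub = t.df if feature_subset is None else t.df.loc[[f for f in t.feature_ids if f in set(feature_subset)]]
    colsum = sub.sum(axis=0).astype(float)
    zero = colsum[colsum <= 0]
    if len(zero):
        raise ValueError(f"all-zero subset column for sample {zero.index[0]!r}")
    return NormalizedTable(sub.astype(float).div(colsum, axis=1), Norm.RA, "subset_column_sum")


def log2_rpm(rpm: NormalizedTable) -> NormalizedTable:
    """log2(RPM) with zero-count cells marked absent (NaN), not imputed."""
    if rpm.norm is not Norm.RPM:
        raise ValueError("log2_rpm expects an RPM table")
    vals = rpm.values.where(rpm.values > 0)
    return NormalizedTable(np.log2(vals), Norm.LOG2RPM, rpm.denominator)


@dataclass(frozen=True)
class DiversityProfile:
    sample_id: str
    shannon: float     # natural-log units
    richness: int


def diversity(ra: NormalizedTable) -> list[DiversityProfile]:
    """Shannon index (-sum p ln p over p>0) and richness per sample."""
    if ra.norm is not Norm.RA:
        raise ValueError("diversity expects a relative-abundance table")
    out = []
    for s in ra.sample_ids:
        p = ra.values[s].to_numpy()
        p = p[p > 0]
        shannon = float(-(p * np.log(p)).sum()) if len(p) else 0.0
        out.append(DiversityProfile(s, max(shannon, 0.0), int(len(p))))
    return out
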