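"""Negative-control based contaminant flagging and removal.

Two complementary rules, applied per assay dataset on RPM-normalized counts:

* prevalence rule — one-sided Fisher exact test on the 2x2 presence table
  (present/absent x NTC/specimen), flagging features significantly more
  prevalent in no-template controls than in specimens;
* ratio rule — flag features whose mean RPM across NTCs is strictly more
  than k times (default 5x) the mean RPM across specimens.

A configured blacklist (features marked ``blacklisted`` in the metadata)
is removed unconditionally. The spiked internal control is never removed,
even if a rule fires on it; removal is idempotent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .core_tables import AssayDataset, Config, CountTable, Finding, Role
from .normalization import NormalizedTable, normalize_rpm

__all__ = [
    "ContaminantReport",
    "prevalence_flag",
    "ratio_flag",
    "apply_decontamination",
    "write_reports",
]


@dataclass
class ContaminantReport:
    feature_id: str
    mean_rpm_specimens: float
    mean_rpm_ntcs: float
    ntc_ratio: float
    prevalence_p: float
    flagged_by: frozenset[str]      # subset of {"prevalence", "ratio5x", "blacklist"}
    removed: bool


def _split_roles(rpm: NormalizedTable, roles: dict[str, Role]) -> tuple[list[str], list[str]]:
    ntcs = [s for s in rpm.sample_ids if roles.get(s) is Role.NTC]
    specimens = [s for s in rpm.sample_ids if roles.get(s) is Role.SPECIMEN]
    return specimens, ntcs


def prevalence_flag(
    rpm: NormalizedTable, roles: dict[str, Role], alpha: float = 0.05
) -> pd.DataFrame:
    """One-sided Fisher exact test of greater prevalence in NTCs.

    Presence = RPM > 0. Returns a frame indexed by feature with columns
    ``p`` and ``flag`` (p < alpha).
    """
    specimens, ntcs = _split_roles(rpm, roles)
    if not ntcs or not specimens:
        raise ValueError("prevalence_flag needs at least one NTC and one specimen; "
                         "skip the prevalence rule when no NTCs were sequenced")
    present = rpm.values > 0
    rows = {}
    for f in rpm.feature_ids:
        a = int(present.loc[f, ntcs].sum())          # present in NTCs
        b = len(ntcs) - a
        c = int(present.loc[f, specimens].sum())     # present in specimens
        d = len(specimens) - c
        _, p = fisher_exact([[a, b], [c, d]], alternative="greater")
        rows[f] = {"p": float(p), "flag": bool(p < alpha)}
    return pd.DataFrame.from_dict(rows, orient="index")


def ratio_flag(
    rpm: NormalizedTable, roles: dict[str, Role], k: float = 5.0
) -> pd.DataFrame:
    """Flag features whose mean NTC RPM strictly exceeds k x mean specimen RPM.

    A feature absent from all specimens but present in NTCs is flagged
    (ratio +inf); a feature absent from all NTCs is never flagged (ratio 0).
    """
    specimens, ntcs = _split_roles(rpm, roles)
    if not ntcs or not specimens:
        raise ValueError("ratio_flag needs at least one NTC and one specimen")
    mean_spec = rpm.values[specimens].mean(axis=1)
    mean_ntc = rpm.values[ntcs].mean(axis=1)
    ratio = pd.Series(
        np.where(mean_spec > 0, mean_ntc / mean_spec.replace(0, np.nan),
                 np.where(mean_ntc > 0, np.inf, 0.0)),
        index=rpm.values.index,
    )
    flag = mean_ntc > k * mean_spec   # strict inequality at the boundary
    return pd.DataFrame(
        {"mean_rpm_specimens": mean_spec, "mean_rpm_ntcs": mean_ntc,
         "ratio": ratio, "flag": flag}
    )


def apply_decontamination(
    d: AssayDataset, config: Optional[Config] = None
) -> tuple[AssayDataset, list[ContaminantReport], list[Finding]]:
    """Remove the union of prevalence-flagged, ratio-flagged and blacklisted
    features from the dataset.

    NTC columns are retained for reporting; the internal control is never
    removed (a warning finding is emitted if a rule fired on it). Applying
    the operation twice removes nothing further. When the dataset has no
    NTCs, only the blacklist applies and a SKIPPED_PREVALENCE finding is
    recorded.
    """
    config = config or Config()
    roles = {s: m.role for s, m in d.samples.items()}
    findings: list[Finding] = []
    # guard the degenerate case of all-zero NTC columns in RPM: normalize on
    # columns with reads only; all-zero columns contribute zero presence/RPM
    live_cols = [s for s in d.table.sample_ids if d.table.df[s].sum() > 0]
    have_ntc = any(roles.get(s) is Role.NTC for s in live_cols)
    have_spec = any(roles.get(s) is Role.SPECIMEN for s in live_cols)

    if have_ntc and have_spec:
        rpm = normalize_rpm(d.table.subset_samples(live_cols))
        prev = prevalence_flag(rpm, roles, config.prevalence_alpha)
        rat = ratio_flag(rpm, roles, config.ntc_ratio_threshold)
        # re-index over the full feature set (all-zero samples removed only)
        prev = prev.reindex(d.table.feature_ids)
        rat = rat.reindex(d.table.feature_ids)
    else:
        findings.append(Finding("SKIPPED_PREVALENCE", d.assay.value,
                                "no NTCs with reads; blacklist rule only"))
        prev = pd.DataFrame(
            {"p": 1.0, "flag": False}, index=pd.Index(d.table.feature_ids)
        )
        rat = pd.DataFrame(
            {"mean_rpm_specimens": np.nan, "mean_rpm_ntcs": np.nan,
             "ratio": np.nan, "flag": False},
            index=pd.Index(d.table.feature_ids),
        )

    reports: list[ContaminantReport] = []
    to_remove: list[str] = []
    for f in d.table.feature_ids:
        flagged: set[str] = set()
        if bool(prev.loc[f, "flag"]):
            flagged.add("prevalence")
        if bool(rat.loc[f, "flag"]):
            flagged.add("ratio5x")
        meta = d.features.get(f)
        if meta is not None and meta.blacklisted:
            flagged.add("blacklist")
        removed = bool(flagged)
        if f == d.ic_feature_id and removed:
            findings.append(Finding("IC_FLAGGED", f,
                                    f"rules {sorted(flagged)} fired on the IC; not removed"))
            removed = False
        if removed:
            to_remove.append(f)
        mean_spec = float(rat.loc[f, "mean_rpm_specimens"]) if not math.isnan(
            float(rat.loc[f, "mean_rpm_specimens"])) else 0.0
        mean_ntc = float(rat.loc[f, "mean_rpm_ntcs"]) if not math.isnan(
            float(rat.loc[f, "mean_rpm_ntcs"])) else 0.0
        ratio = float(rat.loc[f, "ratio"]) if not math.isnan(float(rat.loc[f, "ratio"])) else 0.0
        reports.append(ContaminantReport(
            feature_id=f,
            mean_rpm_specimens=mean_spec,
            mean_rpm_ntcs=mean_ntc,
            ntc_ratio=ratio,
            prevalence_p=float(prev.loc[f, "p"]),
            flagged_by=frozenset(flagged),
            removed=removed,
        ))

    keep = [f for f in d.table.feature_ids if f not in set(to_remove)]
    cleaned = AssayDataset(
        table=CountTable(d.table.df.loc[keep].copy()),
        features={f: m for f, m in d.features.items() if f in set(keep)},
        samples=dict(d.samples),
        ic_feature_id=d.ic_feature_id,
    )
    return cleaned, reports, findings


def write_reports(reports: list[ContaminantReport], path: str | Path) -> None:
    rows = [
        {
            "feature_id": r.feature_id,
            "mean_rpm_specimens": r.mean_rpm_specimens,
            "mean_rpm_ntcs": r.mean_rpm_ntcs,
            "ntc_ratio": r.ntc_ratio,
            "prevalence_p": r.prevalence_p,
            "flagged_by": ",".join(sorted(r.flagged_by)),
            "removed": str(r.removed).lower(),
        }
        for r in reports
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")
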