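"""Sample- and analysis-level quality gates.

Gates follow the comparison design: viral analyses require detection of the
spiked internal control (>= 1 read); 16S and mRNA assays require >= 10,000
mapped reads; the 16S bacteriome additionally requires a reached
rarefaction plateau; within metatranscriptomics the bacterial analysis
requires >= 1,000 bacterial reads (plus a plateau) and the host analysis
>= 100,000 host reads. All "at least" thresholds are inclusive.

Rarefaction uses the exact hypergeometric expectation of observed richness
by default (seed-free), with a Monte-Carlo subsampling option. The plateau
criterion — richness gain from the 90%-depth point to full depth below
epsilon (default one taxon) — is an explicit, config-exposed
operationalisation of "the curve reached a plateau".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .core_tables import Assay, AssayDataset, Config, Kingdom, Role

__all__ = [
    "QCReport",
    "SaturationCurve",
    "rarefaction_curve",
    "expected_richness",
    "plateau_reached",
    "gate_sample",
    "gate_dataset",
    "saturation_analysis",
]


@dataclass
class QCReport:
    sample_id: str
    assay: Assay
    ic_reads: int
    mapped_reads: int
    kingdom_reads: dict[str, int]
    plateau_reached: Optional[bool]
    gates: dict[str, bool]
    eligible_for: set[str] = field(default_factory=set)   # {"viral","bacterial","host","endotype"}


@dataclass
class SaturationCurve:
    points: list[tuple[int, float]]        # (depth, detection fraction), depths increasing
    plateau_depth: Optional[int]


def _log_comb(n: np.ndarray | float, k: np.ndarray | float) -> np.ndarray:
    return gammaln(np.asarray(n) + 1) - gammaln(np.asarray(k) + 1) - gammaln(
        np.asarray(n) - np.asarray(k) + 1
    )


def expected_richness(counts: np.ndarray, depth: int) -> float:
    """Exact expected observed richness of a uniform subsample without
    replacement: sum_i 1 - C(N - n_i, d) / C(N, d)."""
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    total = int(counts.sum())
    if depth > total:
        raise ValueError(f"depth {depth} exceeds total count {total}")
    if depth == 0 or len(counts) == 0:
        return 0.0
    rest = total - counts
    with np.errstate(invalid="ignore"):
        log_miss = np.where(
            rest >= depth, _log_comb(rest, depth) - _log_comb(total, depth), -np.inf
        )
    return float(np.sum(1.0 - np.exp(log_miss)))


def rarefaction_curve(
    counts: Sequence[int],
    depths: Sequence[int],
    reps: int = 1,
    seed: int = 0,
    method: str = "exact",
) -> list[tuple[int, float]]:
    """Mean observed richness at each subsampling depth.

    ``method='exact'`` (default) evaluates the hypergeometric expectation in
    closed form; ``method='montecarlo'`` averages ``reps`` random subsamples
    without replacement, deterministic under ``seed``.
    """
    counts = np.asarray(list(counts), dtype=np.int64)
    total = int(counts.sum())
    out: list[tuple[int, float]] = []
    if method == "exact":
        for d in depths:
            out.append((int(d), expected_richness(counts, int(d))))
        return out
    if method != "montecarlo":
        raise ValueError(f"unknown rarefaction method {method!r}")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    pool = np.repeat(np.arange(len(counts)), counts)
    for d in depths:
        d = int(d)
        if d > total:
            raise ValueError(f"depth {d} exceeds total count {total}")
        rich = []
        for _ in range(reps):
            take = rng.choice(pool, size=d, replace=False)
            rich.append(len(np.unique(take)))
        out.append((d, float(np.mean(rich))))
    return out


def plateau_reached(curve: Sequence[tuple[int, float]], epsilon: float = 1.0) -> bool:
    """True when the richness gain from the 90%-of-max-depth point (linear
    interpolation) to full depth is below ``epsilon`` taxa."""
    if len(curve) < 3:
        raise ValueError("plateau check needs at least 3 rarefaction points")
    depths = np.array([d for d, _ in curve], dtype=float)
    rich = np.array([r for _, r in curve], dtype=float)
    if not np.all(np.diff(depths) > 0):
        raise ValueError("depths must be strictly increasing")
    r90 = float(np.interp(0.9 * depths[-1], depths, rich))
    return bool(rich[-1] - r90 < epsilon)


def _bacterial_plateau(d: AssayDataset, sample: str, config: Config) -> Optional[bool]:
    bact = d.feature_ids_by_kingdom(Kingdom.BACTERIAL)
    if d.assay is Assay.S16:
        counts = d.table.df[sample].to_numpy()
    else:
        counts = d.table.df.loc[bact, sample].to_numpy()
    total = int(counts.sum())
    if total < 10:
        return False
    grid = np.unique(np.maximum(1, (total * np.linspace(0.1, 1.0, 10)).astype(int)))
    if len(grid) < 3:
        return False
    curve = rarefaction_curve(counts, grid, method="exact")
    return plateau_reached(curve, config.plateau_epsilon)


def gate_sample(d: AssayDataset, sample: str, config: Optional[Config] = None) -> QCReport:
    """Evaluate every gate for one sample; pure and side-effect free."""
    config = config or Config()
    if sample not in d.table.df.columns:
        raise KeyError(f"unknown sample {sample!r}")
    col = d.table.df[sample]
    mapped = int(col.sum())
    ic_reads = int(col[d.ic_feature_id]) if d.ic_feature_id in col.index else 0
    kingdom_reads: dict[str, int] = {}
    for k in Kingdom:
        fids = d.feature_ids_by_kingdom(k)
        if fids:
            kingdom_reads[k.value] = int(col[fids].sum())

    assay = d.assay
    gates: dict[str, bool] = {}
    plateau: Optional[bool] = None
    if assay in (Assay.VIR_MNGS, Assay.METARNA):
        gates["ic"] = ic_reads >= config.min_ic_reads
    if assay in (Assay.S16, Assay.MRNA):
        gates["depth"] = mapped >= config.min_mapped_reads
    if assay is Assay.S16:
        plateau = _bacterial_plateau(d, sample, config)
        gates["plateau"] = bool(plateau)
    if assay is Assay.METARNA:
        gates["bacterial_depth"] = kingdom_reads.get("bacterial", 0) >= config.min_bacterial_reads
        gates["host_depth"] = kingdom_reads.get("host", 0) >= config.min_human_reads
        plateau = _bacterial_plateau(d, sample, config)
        gates["plateau"] = bool(plateau)

    eligible: set[str] = set()
    if assay in (Assay.VIR_MNGS, Assay.METARNA) and gates.get("ic"):
        eligible.add("viral")
    if assay is Assay.S16 and gates.get("depth") and gates.get("plateau"):
        eligible.add("bacterial")
    if assay is Assay.METARNA and gates.get("bacterial_depth") and gates.get("plateau"):
        eligible.add("bacterial")
    if assay is Assay.MRNA and gates.get("depth"):
        eligible.add("host")
    if assay is Assay.METARNA and gates.get("host_depth"):
        eligible.add("host")
    if all(gates.values()):
        eligible.add("endotype")
    return QCReport(
        sample_id=sample,
        assay=assay,
        ic_reads=ic_reads,
        mapped_reads=mapped,
        kingdom_reads=kingdom_reads,
        plateau_reached=plateau,
        gates=gates,
        eligible_for=eligible,
    )


def gate_dataset(d: AssayDataset, config: Optional[Config] = None) -> dict[str, QCReport]:
    """Gate every specimen (NTCs are reported but never analysis-eligible)."""
    config = config or Config()
    out: dict[str, QCReport] = {}
    for s in d.table.sample_ids:
        rep = gate_sample(d, s, config)
        if d.samples[s].role is Role.NTC:
            rep.eligible_for = set()
        out[s] = rep
    return out


def saturation_analysis(
    detected: dict[str, set[str]],
    reference: dict[str, set[str]],
    depths: dict[str, int],
    plateau_fraction: float = 0.95,
) -> SaturationCurve:
    """Detection fraction vs depth, with the plateau depth.

    Per sample the fraction is |detected & reference| / |reference|; the
    plateau depth is the smallest depth whose fraction reaches
    ``plateau_fraction`` of the maximum observed fraction.
    """
    shared = sorted(set(detected) & set(reference) & set(depths), key=lambda s: depths[s])
    if len({depths[s] for s in shared}) < 3:
        raise ValueError("saturation analysis needs >= 3 samples with distinct depths")
    points: list[tuple[int, float]] = []
    for s in shared:
        if not reference[s]:
            raise ValueError(f"empty reference gene set for sample {s!r}")
        frac = len(detected[s] & reference[s]) / len(reference[s])
        points.append((int(depths[s]), float(frac)))
    # collapse ties in depth so the curve is strictly increasing in depth
    by_depth: dict[int, list[float]] = {}
    for dpt, f in points:
        by_depth.setdefault(dpt, []).append(f)
    points = [(dpt, float(np.mean(fs))) for dpt, fs in sorted(by_depth.items())]
    fmax = max(f for _, f in points)
    plateau_depth = None
    for dpt, f in points:
        if f >= plateau_fraction * fmax:
            plateau_depth = dpt
            break
    return SaturationCurve(points=points, plateau_depth=plateau_depth)


def qc_report_frame(reports: dict[str, QCReport]) -> pd.DataFrame:
    rows = []
    for s, r in reports.items():
        rows.append({
            "sample_id": s,
            "assay": r.assay.value,
            "ic_reads": r.ic_reads,
            "mapped_reads": r.mapped_reads,
            **{f"reads_{k}": v for k, v in sorted(r.kingdom_reads.items())},
            "plateau_reached": "" if r.plateau_reached is None else str(r.plateau_reached).lower(),
            "gates": ";".join(f"{g}={'pass' if ok else 'fail'}" for g, ok in sorted(r.gates.items())),
            "eligible_for": ",".join(sorted(r.eligible_for)),
        })
    return pd.DataFrame(rows)
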