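import math

import numpy as np
import pandas as pd
import pytest

from metaconcord import (
    ConcordanceSummary,
    RuleKind,
    ThresholdRule,
    call_detections,
    concordance_summary,
    dna_rna_discordance,
    exclusive_detections,
    paired_correlation,
    stratified_sensitivity,
)
from metaconcord.concordance import external_quant_correlation, read_gene_set
from metaconcord.core_tables import Assay, Role, SampleMeta
from metaconcord.normalization import Norm, NormalizedTable


def _table(values: dict[str, list[float]], features: list[str], norm: Norm,
           pseudocount=None) -> NormalizedTable:
    df = pd.DataFrame(values, index=features, dtype=float)
    df.index.name = "feature_id"
    return NormalizedTable(df, norm, "x", pseudocount=pseudocount)


def pearson_oracle(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


class TestCallDetections:
    def test_alr_threshold_inclusive(self):
        t = _table({"S1": [-1.0, -1.0001, 0.5]}, ["a", "b", "c"], Norm.ALR, 1e-5)
        calls = call_detections(t, ThresholdRule(RuleKind.ALR_GE, -1.0))
        pos = calls.positive_pairs()
        assert ("S1", "a") in pos          # exactly at threshold counts
        assert ("S1", "b") not in pos
        assert ("S1", "c") in pos

    def test_ra_positive_and_ra_ge(self):
        t = _table({"S1": [0.0, 0.004, 0.2]}, ["a", "b", "c"], Norm.RA)
        pos = call_detections(t, ThresholdRule(RuleKind.RA_POSITIVE)).positive_pairs()
        assert pos == {("S1", "b"), ("S1", "c")}
        ge = call_detections(t, ThresholdRule(RuleKind.RA_GE, 0.005)).positive_pairs()
        assert ge == {("S1", "c")}

    def test_presence_on_log2rpm(self):
        t = _table({"S1": [np.nan, 3.2]}, ["a", "b"], Norm.LOG2RPM)
        pos = call_detections(t, ThresholdRule(RuleKind.PRESENCE)).positive_pairs()
        assert pos == {("S1", "b")}

    def test_norm_mismatch_raises(self):
        t = _table({"S1": [1.0]}, ["a"], Norm.RA)
        with pytest.raises(ValueError, match="expects"):
            call_detections(t, ThresholdRule(RuleKind.ALR_GE, -1.0))

    def test_feature_subset(self):
        t = _table({"S1": [0.5, 0.5]}, ["a", "b"], Norm.RA)
        calls = call_detections(t, ThresholdRule(RuleKind.RA_POSITIVE), features=["a"])
        assert calls.positive_pairs() == {("S1", "a")}


class TestConcordanceSummary:
    def test_hit_counting(self):
        ref = _table({"S1": [0.5, 0.5, 0.0], "S2": [1.0, 0.0, 0.0]},
                     ["a", "b", "c"], Norm.RA)
        test = _table({"S1": [0.5, 0.0, 0.5], "S2": [1.0, 0.0, 0.0]},
                      ["a", "b", "c"], Norm.RA)
        rule = ThresholdRule(RuleKind.RA_POSITIVE)
        s = concordance_summary(call_detections(ref, rule), call_detections(test, rule))
        assert (s.shared, s.ref_only, s.test_only) == (2, 1, 1)
        assert s.sensitivity == pytest.approx(2 / 3)
        assert s.jaccard == pytest.approx(2 / 4)

    def test_restricted_to_shared_samples(self):
        ref = _table({"S1": [1.0], "S2": [1.0]}, ["a"], Norm.RA)
        test = _table({"S1": [1.0]}, ["a"], Norm.RA)
        rule = ThresholdRule(RuleKind.RA_POSITIVE)
        s = concordance_summary(call_detections(ref, rule), call_detections(test, rule))
        assert (s.shared, s.ref_only, s.test_only) == (1, 0, 0)

    def test_test_exclusion_drops_only_test_exclusive(self):
        ref = _table({"S1": [1.0, 0.0]}, ["a", "b"], Norm.RA)
        test = _table({"S1": [1.0, 1.0]}, ["a", "b"], Norm.RA)
        rule = ThresholdRule(RuleKind.RA_POSITIVE)
        rc, tc = call_detections(ref, rule), call_detections(test, rule)
        # excluding a shared pair has no effect; excluding a test-only pair does
        s = concordance_summary(rc, tc, test_exclusion={("S1", "a"), ("S1", "b")})
        assert (s.shared, s.ref_only, s.test_only) == (1, 0, 0)

    def test_jaccard_never_exceeds_sensitivity(self):
        for shared, ref_only, test_only in [(5, 2, 3), (0, 4, 1), (7, 0, 0)]:
            s = ConcordanceSummary(shared, ref_only, test_only)
            if not math.isnan(s.sensitivity):
                assert s.jaccard <= s.sensitivity + 1e-12

    def test_empty_is_nan(self):
        s = ConcordanceSummary(0, 0, 0)
        assert math.isnan(s.sensitivity) and math.isnan(s.jaccard)

    def test_unit_mismatch_raises(self):
        ref = call_detections(_table({"S1": [1.0]}, ["a"], Norm.RA),
                              ThresholdRule(RuleKind.RA_POSITIVE), unit="genus hit")
        test = call_detections(_table({"S1": [1.0]}, ["a"], Norm.RA),
                               ThresholdRule(RuleKind.RA_POSITIVE), unit="gene hit")
        with pytest.raises(ValueError, match="unit"):
            concordance_summary(ref, test)


class TestStratifiedSensitivity:
    def test_strict_threshold_and_counts(self):
        ref = _table({"S1": [0.005, 0.20, 0.40], "S2": [0.01, 0.0, 0.99]},
                     ["a", "b", "c"], Norm.RA)
        test = _table({"S1": [0.0, 0.5, 0.5], "S2": [0.5, 0.0, 0.5]},
                      ["a", "b", "c"], Norm.RA)
        calls = call_detections(test, ThresholdRule(RuleKind.RA_POSITIVE))
        out = stratified_sensitivity(ref, calls, [0.005, 0.10])
        row1 = out[out["threshold"] == 0.005].iloc[0]
        # ref RA > 0.005: (S1,b),(S1,c),(S2,a),(S2,c) -> a@S1 at exactly 0.005 excluded
        assert (row1["total"], row1["detected"]) == (4, 4)
        row2 = out[out["threshold"] == 0.10].iloc[0]
        assert (row2["total"], row2["detected"]) == (3, 3)

    def test_empty_stratum_nan(self):
        ref = _table({"S1": [0.01]}, ["a"], Norm.RA)
        calls = call_detections(ref, ThresholdRule(RuleKind.RA_POSITIVE))
        out = stratified_sensitivity(ref, calls, [0.5])
        assert math.isnan(out["fraction"].iloc[0])

    def test_threshold_bounds(self):
        ref = _table({"S1": [0.01]}, ["a"], Norm.RA)
        calls = call_detections(ref, ThresholdRule(RuleKind.RA_POSITIVE))
        with pytest.raises(ValueError, match="outside"):
            stratified_sensitivity(ref, calls, [1.5])


class TestPairedCorrelation:
    def test_matches_closed_form_oracle(self):
        xs = [1.0, 2.0, 3.0, 4.0, 5.0]
        ys = [1.1, 1.9, 3.2, 3.8, 5.3]
        x = _table({f"S{i}": [v] for i, v in enumerate(xs)}, ["f"], Norm.RA)
        y = _table({f"S{i}": [v] for i, v in enumerate(ys)}, ["f"], Norm.RA)
        res = paired_correlation(x, y, "all-shared-cells")
        assert res.r == pytest.approx(pearson_oracle(xs, ys), abs=1e-12)
        assert res.n == 5

    def test_both_detected_skips_alr_floor(self):
        # pseudocount 1e-5 -> floor -5; the floored cell must not pair
        x = _table({"S1": [-5.0, 1.0], "S2": [0.5, 2.0]}, ["a", "b"],
                   Norm.ALR, pseudocount=1e-5)
        y = _table({"S1": [0.2, 1.1], "S2": [0.4, 2.2]}, ["a", "b"],
                   Norm.ALR, pseudocount=1e-5)
        res = paired_correlation(x, y, "both-detected")
        assert res.n == 3

    def test_too_few_pairs(self):
        x = _table({"S1": [1.0], "S2": [2.0]}, ["a"], Norm.RA)
        with pytest.raises(ValueError, match=">= 3"):
            paired_correlation(x, x, "all-shared-cells")

    def test_degenerate_constant(self):
        x = _table({"S1": [1.0], "S2": [1.0], "S3": [1.0]}, ["a"], Norm.RA)
        y = _table({"S1": [1.0], "S2": [2.0], "S3": [3.0]}, ["a"], Norm.RA)
        with pytest.raises(ValueError, match="DEGENERATE"):
            paired_correlation(x, y, "all-shared-cells")


class TestExternalQuant:
    def test_negative_correlation_with_ct(self):
        vals = {"S1": [1.0], "S2": [2.0], "S3": [3.0], "S4": [4.0]}
        alr = _table(vals, ["rsv"], Norm.ALR, 1e-5)
        samples = {
            s: SampleMeta(s, Role.SPECIMEN, Assay.METARNA,
                          external_quant={"rsv": 40.0 - 3.3 * v[0]})
            for s, v in vals.items()
        }
        res = external_quant_correlation(alr, "rsv", "rsv", samples)
        assert res.r == pytest.approx(-1.0, abs=1e-9)

    def test_samples_without_quant_skipped(self):
        alr = _table({"S1": [1.0], "S2": [2.0], "S3": [3.0], "S4": [4.0]},
                     ["rsv"], Norm.ALR, 1e-5)
        samples = {s: SampleMeta(s, Role.SPECIMEN, Assay.METARNA,
                                 external_quant=({"rsv": 30.0 - i} if i < 3 else {}))
                   for i, s in enumerate(["S1", "S2", "S3", "S4"])}
        res = external_quant_correlation(alr, "rsv", "rsv", samples)
        assert res.n == 3


class TestExclusivesAndDiscordance:
    def test_exclusive_sides_and_scores(self):
        ref = _table({"S1": [0.7, 0.3, 0.0]}, ["a", "b", "c"], Norm.RA)
        test = _table({"S1": [0.5, 0.0, 0.5]}, ["a", "b", "c"], Norm.RA)
        rule = ThresholdRule(RuleKind.RA_POSITIVE)
        out = exclusive_detections(call_detections(ref, rule),
                                   call_detections(test, rule))
        assert set(zip(out["side"], out["feature_id"])) == {
            ("ref_only", "b"), ("test_only", "c")}
        b = out[out["feature_id"] == "b"].iloc[0]
        assert b["score"] == 0.3 and b["other_score"] == 0.0

    def test_dna_rna_discordance(self):
        # "silent" detected in 5 ref samples, never test-positive;
        # "active" detected everywhere in both
        ref = _table({f"S{i}": [0.5, 0.5] for i in range(5)},
                     ["silent", "active"], Norm.RA)
        test = _table({f"S{i}": [0.0, 1.0] for i in range(5)},
                      ["silent", "active"], Norm.RA)
        calls = call_detections(test, ThresholdRule(RuleKind.RA_POSITIVE))
        assert dna_rna_discordance(ref, calls, min_samples=5) == ["silent"]
        assert dna_rna_discordance(ref, calls, min_samples=6) == []

    def test_min_samples_validation(self):
        ref = _table({"S1": [1.0]}, ["a"], Norm.RA)
        calls = call_detections(ref, ThresholdRule(RuleKind.RA_POSITIVE))
        with pytest.raises(ValueError):
            dna_rna_discordance(ref, calls, min_samples=0)


def test_read_gene_set(tmp_path):
    p = tmp_path / "genes.txt"
    p.write_text("# header comment\nGENE1\n\nGENE2\n  GENE3  \n")
    assert read_gene_set(p) == ["GENE1", "GENE2", "GENE3"]
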