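import numpy as np
import pandas as pd
import pytest

from metaconcord import (
    Assay,
    GeneratorParams,
    Kingdom,
    expected_composition,
    generate_study,
    generate_truth,
    sample_counts,
)
from metaconcord.core_tables import Role, genus_of
from metaconcord.synthetic import (
    BLACKLISTED_PHAGE,
    IC_FEATURE_ID,
    planted_contaminant_ids,
    species_to_genus_mapping,
)


class TestTruth:
    def test_deterministic(self):
        t1 = generate_truth(10, seed=42)
        t2 = generate_truth(10, seed=42)
        pd.testing.assert_frame_equal(t1.to_frame(), t2.to_frame())

    def test_seed_changes_output(self):
        t1 = generate_truth(10, seed=1)
        t2 = generate_truth(10, seed=2)
        assert not t1.to_frame().equals(t2.to_frame())

    def test_silent_species_have_zero_activity_everywhere(self):
        t = generate_truth(20, seed=5)
        silent = [b.species for b in t.params.bacteria
                  if b.activity_c1 == 0 and b.activity_c2 == 0]
        assert len(silent) == 3
        for s in t.specimen_ids:
            for sp in silent:
                assert t.bacterial_activity[s][sp] == 0.0

    def test_endotypes_are_binary(self):
        t = generate_truth(20, seed=5)
        assert set(t.endotype.values()) <= {"C1", "C2"}

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            GeneratorParams(n_specimens=1).validated()
        with pytest.raises(ValueError):
            GeneratorParams(ic_concentration=0.0).validated()


class TestExpectedComposition:
    def test_probabilities_sum_to_one(self):
        t = generate_truth(5, seed=3)
        for assay in Assay:
            p = expected_composition(t, assay, "S01")
            assert p.sum() == pytest.approx(1.0)
            assert (p >= 0).all()

    def test_mrna_ntc_is_all_zero(self):
        t = generate_truth(5, seed=3)
        p = expected_composition(t, Assay.MRNA, "NTC_x", role=Role.NTC)
        assert p.sum() == 0.0

    def test_ntc_sees_only_contaminants_and_ic(self):
        t = generate_truth(5, seed=3)
        p = expected_composition(t, Assay.METARNA, "NTC_x", role=Role.NTC)
        nonzero = set(p[p > 0].index)
        assert nonzero <= set(t.contaminants) | {IC_FEATURE_ID}

    def test_silent_species_invisible_to_metarna(self):
        t = generate_truth(10, seed=7)
        silent = [b.species for b in t.params.bacteria
                  if b.activity_c1 == 0 and b.activity_c2 == 0]
        for s in t.specimen_ids:
            p = expected_composition(t, Assay.METARNA, s)
            assert (p[silent] == 0).all()
            # but 16S sees their DNA when present
            p16 = expected_composition(t, Assay.S16, s)
            for sp in silent:
                if t.bacterial_dna[s][sp] > 0:
                    assert p16[genus_of(sp)] > 0

    def test_inactive_dna_virus_invisible_to_metarna(self):
        t = generate_truth(10, seed=7)
        dna_fams = [v.family for v in t.params.dna_viruses]
        for s in t.specimen_ids:
            p = expected_composition(t, Assay.METARNA, s)
            for fam in dna_fams:
                if not t.dna_virus_active[s][fam]:
                    assert p[fam] == 0.0
                elif t.viral_concentration[s][fam] > 0:
                    assert p[fam] > 0

    def test_unknown_specimen_raises(self):
        t = generate_truth(3, seed=0)
        with pytest.raises(KeyError):
            expected_composition(t, Assay.S16, "S99")


class TestSampleCounts:
    def test_sums_to_depth(self):
        p = np.array([0.2, 0.3, 0.5])
        c = sample_counts(p, 1000, seed=0)
        assert c.sum() == 1000 and (c >= 0).all()

    def test_zero_depth_and_zero_probs(self):
        assert sample_counts(np.array([1.0]), 0, 0).tolist() == [0]
        assert sample_counts(np.array([0.0, 0.0]), 100, 0).tolist() == [0, 0]

    def test_law_of_large_numbers(self):
        p = np.array([0.1, 0.9])
        depth = 200_000
        c = sample_counts(p, depth, seed=11)
        sd = np.sqrt(depth * 0.1 * 0.9)
        assert abs(c[0] - depth * 0.1) < 5 * sd

    def test_validation(self):
        with pytest.raises(ValueError, match="negative"):
            sample_counts(np.array([-0.1, 1.1]), 10, 0)
        with pytest.raises(ValueError, match="sum"):
            sample_counts(np.array([0.3, 0.3]), 10, 0)
        with pytest.raises(ValueError, match="depth"):
            sample_counts(np.array([1.0]), -1, 0)


class TestGenerateStudy:
    def test_deterministic(self):
        d1, _ = generate_study(seed=9)
        d2, _ = generate_study(seed=9)
        for assay in Assay:
            pd.testing.assert_frame_equal(d1[assay].table.df, d2[assay].table.df)

    def test_column_sums_match_recorded_depth(self, default_study):
        datasets, _ = default_study
        for assay, d in datasets.items():
            sums = d.table.column_sums()
            for s, meta in d.samples.items():
                assert int(sums[s]) == meta.total_reads

    def test_study_layout(self, default_study):
        datasets, truth = default_study
        assert len(truth.specimen_ids) == 20
        assert len(datasets[Assay.VIR_MNGS].ntc_ids()) == 10
        assert len(datasets[Assay.S16].ntc_ids()) == 7
        assert len(datasets[Assay.MRNA].ntc_ids()) == 3
        assert len(datasets[Assay.METARNA].ntc_ids()) == 3
        for assay in (Assay.VIR_MNGS, Assay.METARNA):
            assert datasets[assay].ic_feature_id == IC_FEATURE_ID

    def test_ntc_reads_only_from_contaminants_and_ic(self, default_study):
        datasets, truth = default_study
        for assay in (Assay.VIR_MNGS, Assay.S16, Assay.METARNA):
            d = datasets[assay]
            allowed = planted_contaminant_ids(truth, assay) | {IC_FEATURE_ID}
            for ntc in d.ntc_ids():
                col = d.table.df[ntc]
                assert set(col[col > 0].index) <= allowed

    def test_blacklisted_phage_flagged_in_metadata(self, default_study):
        datasets, _ = default_study
        feats = datasets[Assay.VIR_MNGS].features
        assert feats[BLACKLISTED_PHAGE].blacklisted
        assert not feats["Pneumoviridae"].blacklisted

    def test_metarna_ct_quant_present(self, default_study):
        datasets, truth = default_study
        d = datasets[Assay.METARNA]
        with_ct = [s for s in d.specimen_ids() if "rsv" in d.samples[s].external_quant]
        expected = [s for s in truth.specimen_ids
                    if truth.viral_concentration[s]["Pneumoviridae"] > 0]
        assert with_ct == expected

    def test_species_to_genus_mapping(self, default_study):
        datasets, _ = default_study
        mapping = species_to_genus_mapping(datasets[Assay.METARNA])
        assert mapping["Streptococcus_pneumoniae"] == "Streptococcus"
        assert IC_FEATURE_ID not in mapping
        assert "GENE0001" not in mapping

    def test_observed_composition_near_expected(self, default_study):
        # LLN on a real study column: observed fraction within 5 binomial sd
        datasets, truth = default_study
        d = datasets[Assay.MRNA]
        s = truth.specimen_ids[0]
        probs = expected_composition(truth, Assay.MRNA, s)
        depth = d.samples[s].total_reads
        col = d.table.df[s]
        for g in probs.index[:20]:
            p = probs[g]
            sd = np.sqrt(depth * p * (1 - p))
            assert abs(col[g] - depth * p) <= 5 * sd + 1

    def test_contaminant_ids_per_assay(self, default_study):
        _, truth = default_study
        s16_ids = planted_contaminant_ids(truth, Assay.S16)
        meta_ids = planted_contaminant_ids(truth, Assay.METARNA)
        assert "Ralstonia" in s16_ids                      # genus level
        assert "Ralstonia_contaminans" in meta_ids         # species level
        assert "Circoviridae" in planted_contaminant_ids(truth, Assay.VIR_MNGS)
        assert planted_contaminant_ids(truth, Assay.MRNA) == set()
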