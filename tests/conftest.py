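import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from metaconcord import Assay, AssayDataset, CountTable, Kingdom, Role, SampleMeta
from metaconcord.core_tables import FeatureMeta, GenomeType, HostType, Rank

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_count_table(data: dict[str, list[int]], features: list[str]) -> CountTable:
    """Columns = samples, rows = features."""
    df = pd.DataFrame(data, index=features).astype(np.int64)
    df.index.name = "feature_id"
    return CountTable(df)


@pytest.fixture
def tiny_viral_dataset() -> AssayDataset:
    """Hand-built viral dataset: 3 specimens, 2 NTCs, one IC, one contaminant."""
    features = ["Pneumoviridae", "Picornaviridae", "Circoviridae", "MS2_internal_control"]
    table = make_count_table(
        {
            "S01": [900, 50, 10, 40],
            "S02": [700, 0, 12, 30],
            "S03": [980, 0, 8, 12],
            "NTC1": [0, 0, 600, 20],
            "NTC2": [0, 0, 700, 25],
        },
        features,
    )
    metas = {
        "Pneumoviridae": FeatureMeta("Pneumoviridae", Kingdom.VIRAL, Rank.FAMILY,
                                     GenomeType.RNA, HostType.EUKARYOTIC),
        "Picornaviridae": FeatureMeta("Picornaviridae", Kingdom.VIRAL, Rank.FAMILY,
                                      GenomeType.RNA, HostType.EUKARYOTIC),
        "Circoviridae": FeatureMeta("Circoviridae", Kingdom.VIRAL, Rank.FAMILY,
                                    GenomeType.DNA, HostType.EUKARYOTIC),
        "MS2_internal_control": FeatureMeta("MS2_internal_control", Kingdom.CONTROL,
                                            Rank.SPECIES, GenomeType.RNA,
                                            HostType.PROKARYOTIC),
    }
    samples = {
        s: SampleMeta(s, Role.SPECIMEN if s.startswith("S") else Role.NTC,
                      Assay.VIR_MNGS, total_reads=2000)
        for s in table.sample_ids
    }
    return AssayDataset(table, metas, samples, ic_feature_id="MS2_internal_control")


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study, shared read-only across tests."""
    from metaconcord import generate_study

    return generate_study(seed=11)
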