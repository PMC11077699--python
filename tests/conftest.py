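import pytest

from pcfam.synthetic import FamilySimConfig, generate_family


@pytest.fixture(scope="session")
def small_family():
    """40-gene synthetic family with three divergent duplicate pairs."""
    cfg = FamilySimConfig(
        n_genes=40,
        subfamily_mix={"ENODL": 0.5, "SCL": 0.25, "UCL": 0.15, "PLCL": 0.10},
        seed=7,
    )
    return generate_family(cfg)


@pytest.fixture(scope="session")
def small_family_annotations(small_family):
    return small_family.truth_annotations()
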