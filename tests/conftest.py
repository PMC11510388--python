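import pandas as pd
import pytest

from asdgm.features import FeatureTable, TaxonomyMap
from asdgm.synth import PlantedEffect, SynthConfig, generate_cohort


@pytest.fixture
def toy_counts() -> FeatureTable:
    """4 features x 3 samples with hand-set counts."""
    data = pd.DataFrame(
        {
            "s1": [5.0, 5.0, 0.0, 10.0],
            "s2": [8.0, 0.0, 4.0, 4.0],
            "s3": [1.0, 1.0, 1.0, 1.0],
        },
        index=["f1", "f2", "f3", "f4"],
    )
    return FeatureTable(data, mode="counts")


@pytest.fixture
def toy_taxonomy() -> TaxonomyMap:
    frame = pd.DataFrame(
        {
            "domain": ["Bacteria"] * 4,
            "phylum": ["P1", "P1", "P2", "P2"],
            "class": ["C1", "C1", "C2", "C2"],
            "order": ["O1", "O1", "O2", "O2"],
            "family": ["F1", "F1", "F2", "F3"],
            "genus": ["G1", "G1", "G2", ""],
            "species": ["sp1", "sp2", "", ""],
        },
        index=["f1", "f2", "f3", "f4"],
    )
    return TaxonomyMap(frame)


@pytest.fixture(scope="session")
def small_cohort():
    """Session-scoped synthetic cohort with two planted severity effects."""
    cfg = SynthConfig(
        n_cases=40,
        n_controls=30,
        n_asv=100,
        seed=11,
        css_mean=7.5,
        planted_effects=(
            PlantedEffect("auto:1", "CSS", "severe", 1.5),
            PlantedEffect("auto:4", "CSS", "severe", -1.5),
        ),
    )
    return generate_cohort(cfg)
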