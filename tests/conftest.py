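import numpy as np
import pytest

from vocamap import (
    ContourCollection,
    FrequencyContour,
    RepertoireConfig,
    generate_repertoire,
)


def make_contour(
    freqs,
    syllable_id="s1",
    individual_id="i1",
    group="WT",
    hop=1e-3,
    start_time=0.0,
    clipped=False,
):
    return FrequencyContour(
        syllable_id=syllable_id,
        individual_id=individual_id,
        group=group,
        start_time=start_time,
        hop=hop,
        frequencies=np.asarray(freqs, dtype=float),
        clipped=clipped,
    )


@pytest.fixture
def tiny_collection():
    """Three syllables, two individuals, two groups."""
    return ContourCollection(
        [
            make_contour([60, 61, 62], "a", "i1", "WT"),
            make_contour([70, 75, 80, 85], "b", "i1", "WT"),
            make_contour([50, 50, 50], "c", "i2", "HT"),
        ]
    )


@pytest.fixture(scope="session")
def small_repertoire():
    """2 groups x 2 individuals x 30 calls with contrasting step prevalence."""
    cfg = RepertoireConfig(
        n_individuals_per_group=2,
        calls_per_individual=30,
        step_probability={"WT": 0.7, "HT": 0.2},
        seed=42,
    )
    return generate_repertoire(cfg)
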