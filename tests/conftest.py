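import numpy as np
import pytest

from rdnanet.annotation import default_annotation
from rdnanet.occupancy import OccupancyProfile
from rdnanet.simulate import SimulationTruth, StrainEffects, simulate_template


@pytest.fixture(scope="session")
def ann():
    return default_annotation()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_profile(values, strain="S", replicate="r1", normalized=False):
    return OccupancyProfile(
        strain=strain, replicate=replicate, values=np.asarray(values, dtype=float),
        normalized=normalized,
    )


@pytest.fixture
def flat_truth_factory(ann):
    """Truths with uniform dwell (no sequence effects), for recovery tests."""

    def make(strains: dict[str, StrainEffects], seed=0, **kwargs):
        template = simulate_template(ann.repeat_length, seed=seed)
        return SimulationTruth(
            template=template,
            strains=strains,
            sequence_coefficients={},
            seed=seed,
            **kwargs,
        )

    return make
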