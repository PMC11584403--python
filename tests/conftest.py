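import numpy as np
import pytest

from bclineage.synthetic import CohortSpec, generate_expression_cohort

SUBTYPE_MIX = {"LumA": 12, "LumB": 12, "Her2": 12, "Basal": 12, "Normal": 12}


@pytest.fixture(scope="session")
def cohort_bundle():
    """A 60-sample bulk cohort with strong subtype structure."""
    spec = CohortSpec(n_samples=60, subtype_mix=SUBTYPE_MIX, effect_size=5.0, seed=11)
    return generate_expression_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
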