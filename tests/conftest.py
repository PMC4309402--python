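import numpy as np
import pandas as pd
import pytest

from stressmet import (
    canonical_comparisons,
    generate_study,
    preset_paper_like,
    scale_and_impute,
    strip_effects,
)
from stressmet.direction import direction_profiles


@pytest.fixture(scope="session")
def paper_like_study():
    """One paper-shaped synthetic study (seed 1), preprocessed."""
    matrix, design, pathways, truth = generate_study(preset_paper_like(1))
    return scale_and_impute(matrix), design, pathways, truth


@pytest.fixture(scope="session")
def null_study():
    """Effect-free variant of the paper-shaped study (seed 7)."""
    matrix, design, pathways, truth = generate_study(strip_effects(preset_paper_like(7)))
    assert truth.empty
    return scale_and_impute(matrix), design, pathways


@pytest.fixture(scope="session")
def null_profiles(null_study):
    matrix, design, pathways = null_study
    return direction_profiles(matrix, canonical_comparisons(design))


@pytest.fixture
def small_matrix():
    """4 samples x 3 metabolites, no missing values."""
    from stressmet import MetaboliteMatrix

    data = pd.DataFrame(
        [[1.0, 10.0, 5.0], [2.0, 20.0, 5.5], [3.0, 30.0, 4.5], [4.0, 40.0, 5.2]],
        index=["s1", "s2", "s3", "s4"],
        columns=["m1", "m2", "m3"],
    )
    return MetaboliteMatrix(data)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
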