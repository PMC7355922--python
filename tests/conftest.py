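import dataclasses

import pytest

import ramanscreen as rs


@pytest.fixture(scope="session")
def default_cohort():
    """Raw study-scale cohort (53 pigmented + 7 melanoma lesions), seed 0."""
    return rs.generate_cohort(rs.SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def default_preprocessed(default_cohort):
    ds, _ = default_cohort
    pre, flags = rs.preprocess_dataset(ds)
    return pre, flags


@pytest.fixture(scope="session")
def default_fold(default_preprocessed):
    pre, _ = default_preprocessed
    return rs.lolo_fold_scores(pre, n_pcs=15)


@pytest.fixture(scope="session")
def small_cohort_preprocessed():
    """A 10-lesion cohort small enough for naive-oracle recomputation."""
    cfg = rs.SyntheticConfig(seed=11)
    cfg = dataclasses.replace(
        cfg, n_pigmented_lesions=7, n_melanoma_lesions=3, n_patients=10
    )
    ds, _ = rs.generate_cohort(cfg)
    pre, _ = rs.preprocess_dataset(ds)
    return pre


def fast_config(**overrides) -> rs.SyntheticConfig:
    """A coarse-grid config for tests that only need generator mechanics."""
    defaults = dict(
        seed=0,
        n_pigmented_lesions=4,
        n_melanoma_lesions=2,
        n_patients=6,
        n_points=300,
    )
    defaults.update(overrides)
    return rs.SyntheticConfig(**defaults)
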