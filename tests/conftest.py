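"""Shared fixtures: small synthetic cohorts and a cohort-from-arrays factory."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from scnet import (
    CohortTable,
    SyntheticConfig,
    default_atlas,
    generate_cohort,
    normalize_volumes,
)


@pytest.fixture(scope="session")
def atlas():
    return default_atlas()


@pytest.fixture(scope="session")
def small_cohort():
    """Absolute-volume synthetic cohort, 8 + 8 subjects."""
    return generate_cohort(SyntheticConfig(n_per_group=(8, 8), seed=42))


@pytest.fixture(scope="session")
def small_normalized(small_cohort):
    return normalize_volumes(small_cohort)


@pytest.fixture(scope="session")
def study_cohort():
    """Study-sized (35/34) null cohort, normalized."""
    return normalize_volumes(generate_cohort(SyntheticConfig(seed=7)))


@pytest.fixture
def make_cohort(atlas):
    """Factory: build a normalized CohortTable directly from arrays.

    ``volumes`` is subjects x regions (percent-of-TIV scale); missing
    regions are padded with independent noise so the table always covers
    the full atlas.
    """

    def _make(volumes, age, sex, groups, normalized=True, pad_seed=123):
        volumes = np.asarray(volumes, dtype=float)
        n = volumes.shape[0]
        rng = np.random.default_rng(pad_seed)
        full = np.empty((n, len(atlas)))
        full[:, : volumes.shape[1]] = volumes
        if volumes.shape[1] < len(atlas):
            full[:, volumes.shape[1]:] = rng.normal(
                0.5, 0.05, size=(n, len(atlas) - volumes.shape[1])
            )
        data = {
            "subject_id": [f"s{i:03d}" for i in range(n)],
            "group": list(groups),
            "age": np.asarray(age, dtype=float),
            "sex": np.asarray(sex, dtype=int),
            "tiv": np.full(n, 1.5e6),
        }
        data.update({name: full[:, k]
                     for k, name in enumerate(atlas.names)})
        return CohortTable(atlas=atlas, data=pd.DataFrame(data),
                           normalized=normalized)

    return _make
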