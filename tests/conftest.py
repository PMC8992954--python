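"""Shared fixtures: synthetic studies and cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from mrdqc.phantom import PhantomParams, make_cohort, make_phantom_study


@pytest.fixture(scope="session")
def clean_study(tmp_path_factory):
    """One clean default phantom study: (StudyRecord, truth dict)."""
    d = tmp_path_factory.mktemp("clean_study")
    return make_phantom_study(PhantomParams(seed=11), d, "clean011")


@pytest.fixture(scope="session")
def cohort60(tmp_path_factory):
    """Seeded 60-study cohort, three failure modes injected at rate 0.2 each.

    Returns (manifest_path, truth_path).
    """
    d = tmp_path_factory.mktemp("cohort60")
    rates = {"normalization_break": 0.2, "cropped_fov": 0.2, "corrupt_seg": 0.2}
    return make_cohort(60, rates, seed=2024, out_dir=d)


def small_params(n: int = 24, seed: int = 0, **kw) -> PhantomParams:
    """Phantom params on an n^3 grid with the default 192 mm field of view."""
    s = 192.0 / n
    return PhantomParams(shape=(n, n, n), spacing=(s, s, s), seed=seed, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
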