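"""Shared fixtures: small hand-built panels plus session-scoped
synthetic bundles reused by the heavier statistical tests."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import eqtlclust as ec

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from eqtlclust.types import GenotypeMatrix, Marker


@pytest.fixture()
def toy_genotypes() -> GenotypeMatrix:
    """4 strains x 3 markers; m2 is monomorphic (all A)."""
    markers = [
        Marker("m1", "chr1", 100),
        Marker("m2", "chr1", 200),
        Marker("m3", "chr2", 50),
    ]
    calls = np.array(
        [
            [0, 0, 0],
            [1, 0, 1],
            [0, 0, 1],
            [1, 0, 0],
        ],
        dtype=float,
    )
    return GenotypeMatrix(["s1", "s2", "s3", "s4"], markers, calls)


@pytest.fixture()
def toy_expression() -> ec.ExpressionMatrix:
    rng = np.random.default_rng(7)
    values = pd.DataFrame(
        rng.normal(9, 1, (5, 4)),
        index=[f"g{i}" for i in range(1, 6)],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ec.ExpressionMatrix(values)


def _bundle_and_result(seed: int):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bundle = ec.simulate_bundle(seed=seed)
        result = ec.run_pipeline_on_bundle(bundle)
    return bundle, result


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic bundle (seed 11) with its pipeline result."""
    return _bundle_and_result(11)


N_REPLICATE_SEEDS = 20


@pytest.fixture(scope="session")
def replicate_runs():
    """Pipeline results on the default study conditions over 20 seeds.

    Shared by the planted-recovery, coexpression-separation and
    enrichment-recovery tests so the bundles are simulated once.
    """
    return [_bundle_and_result(seed) for seed in range(N_REPLICATE_SEEDS)]
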