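import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from structpls import (
    CodingScheme,
    EffectSpec,
    FactorBlock,
    FactorEffect,
    generate,
    packaged_scheme,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def riboswitch_scheme() -> CodingScheme:
    return packaged_scheme("riboswitch")


@pytest.fixture(scope="session")
def propranolol_scheme() -> CodingScheme:
    return packaged_scheme("propranolol")


@pytest.fixture(scope="session")
def riboswitch_design(riboswitch_scheme) -> pd.DataFrame:
    """Full 5x4 design, 3 replicates per cell (60 rows)."""
    rows = []
    i = 0
    for s in riboswitch_scheme.block("strain").levels:
        for ind in riboswitch_scheme.block("inducer").levels:
            for r in range(1, 4):
                i += 1
                rows.append((f"s{i:03d}", f"r{r}", s, ind))
    return pd.DataFrame(rows, columns=["sample_id", "replicate_id", "strain", "inducer"])


def small_two_factor(
    effect_a=3.0, effect_b=3.0, noise_sd=0.05, n_features=20, replicates=3, seed=0
):
    """Tiny 2x2 factorial used by validation tests."""
    spec = EffectSpec(
        factors=(
            FactorEffect(
                name="A", levels=("a1", "a2"), effect_size=effect_a, affected_fraction=0.5
            ),
            FactorEffect(
                name="B", levels=("b1", "b2"), effect_size=effect_b, affected_fraction=0.5
            ),
        ),
        n_features=n_features,
        replicates=replicates,
        noise_sd=noise_sd,
    )
    return generate(spec, seed)


def two_factor_scheme() -> CodingScheme:
    return CodingScheme(
        blocks=(
            FactorBlock("A", "categorical", ("a1", "a2"), (0.0, 1.0)),
            FactorBlock("B", "categorical", ("b1", "b2"), (0.0, 1.0)),
        )
    )


@pytest.fixture()
def tiny_dataset():
    return small_two_factor()


@pytest.fixture()
def tiny_scheme():
    return two_factor_scheme()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
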