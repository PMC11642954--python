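import numpy as np
import pytest

from ccp import ExpressionMatrix, generate_synthetic, preprocess, worked_example_fixture


@pytest.fixture
def fixture3() -> ExpressionMatrix:
    """3-cell hand-checkable fixture (signal gene values 0, 1, 3)."""
    return worked_example_fixture()


@pytest.fixture(scope="session")
def small_dataset():
    """A small but non-trivial labelled dataset for fast integration tests."""
    return generate_synthetic(M=120, I=300, k=3, module_count=6, seed=11)


@pytest.fixture(scope="session")
def small_log(small_dataset) -> ExpressionMatrix:
    return preprocess(small_dataset.x)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_expression(
    rng: np.random.Generator, m: int = 20, i: int = 50, stage: str = "log_normalized"
) -> ExpressionMatrix:
    return ExpressionMatrix(rng.gamma(2.0, 1.0, size=(m, i)), stage=stage)
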