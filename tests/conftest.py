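import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from migrainechain import Cohort, Diary, worked_example

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def flags_strategy(min_size: int = 1, max_size: int = 40):
    return st.lists(st.booleans(), min_size=min_size, max_size=max_size)


def diary_strategy(min_size: int = 1, max_size: int = 40):
    return st.builds(
        lambda flags, first: Diary("h", np.array(flags, dtype=bool), first_day=first),
        flags_strategy(min_size, max_size),
        st.integers(min_value=1, max_value=200),
    )


@pytest.fixture
def worked() -> Diary:
    return worked_example()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


def random_cohort(
    rng: np.random.Generator,
    n_patients: int = 8,
    length_range: tuple[int, int] = (20, 60),
    p_migraine: float = 0.3,
) -> Cohort:
    """Cohort of i.i.d.-Bernoulli diaries (no chain structure; for plumbing tests)."""
    diaries = []
    for j in range(n_patients):
        n = int(rng.integers(*length_range))
        diaries.append(Diary(f"p{j}", rng.random(n) < p_migraine))
    return Cohort(diaries)
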