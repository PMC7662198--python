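import numpy as np
import pytest
from hypothesis import settings

from ecoturn.types import AnnualAssemblage

settings.register_profile("default", derandomize=True, max_examples=60)
settings.load_profile("default")


def make_assemblage(abundances: dict[str, float], series_id: str = "s1",
                    year: int = 2000) -> AnnualAssemblage:
    return AnnualAssemblage(series_id=series_id, year=year,
                            abundances=dict(abundances))


@pytest.fixture
def assemblage_factory():
    return make_assemblage


@pytest.fixture
def random_assemblage_pairs():
    """Random assemblage pairs over a shared taxon pool for oracle checks."""

    def _make(n_pairs: int, seed: int = 0, pool: int = 40):
        rng = np.random.default_rng(seed)
        taxa = [f"t{i}" for i in range(pool)]
        pairs = []
        for j in range(n_pairs):
            out = []
            for year in (2000, 2001):
                k = int(rng.integers(1, pool))
                chosen = rng.choice(pool, size=k, replace=False)
                ab = {taxa[i]: float(rng.lognormal(0, 1)) for i in chosen}
                out.append(make_assemblage(ab, series_id=f"p{j}", year=year))
            pairs.append(tuple(out))
        return pairs

    return _make
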