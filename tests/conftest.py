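import dataclasses

import numpy as np
import pytest

from tauquant import tau_model as tm
from tauquant.synthetic_data import (
    ModelDesign,
    NoiseModel,
    ScenarioConfig,
)


@pytest.fixture(scope="session")
def iso2n4r():
    return tm.load_isoform("2N4R")


@pytest.fixture(scope="session")
def iso0n4r():
    return tm.load_isoform("0N4R")


@pytest.fixture(scope="session")
def species_set():
    return tm.default_species_set("P301S")


@pytest.fixture(scope="session")
def panel():
    return tm.build_panel("P301S")


def small_model(**overrides) -> ModelDesign:
    base = dict(
        name="P301S",
        mutation="P301S",
        timepoints=(2.0, 3.0, 4.0, 5.0),
        regions=("cortex",),
        n_replicates=3,
        onset_time=4.0,
        burden_plateau=250.0,
        animal_cv=0.2,
    )
    base.update(overrides)
    return ModelDesign(**base)


def small_config(**overrides) -> ScenarioConfig:
    base = dict(
        models=(small_model(),),
        noise=NoiseModel(area_cv=0.0),
        seed=11,
    )
    base.update(overrides)
    return dataclasses.replace(ScenarioConfig(), **base)


@pytest.fixture
def noise_free_config():
    return small_config()


def brute_force_digest(sequence: str) -> list[tuple[int, int, str]]:
    """Independent oracle: position scan implementing 'cleave after K/R
    unless the next residue is P', 0 missed cleavages. 1-based local coords."""
    peptides = []
    start = 0
    for i in range(len(sequence)):
        last = i == len(sequence) - 1
        blocked = sequence[i] in "KR" and not last and sequence[i + 1] == "P"
        is_site = sequence[i] in "KR" and not blocked
        if last or is_site:
            peptides.append((start + 1, i + 1, sequence[start : i + 1]))
            start = i + 1
    return peptides


def naive_complete_linkage_heights(X: np.ndarray) -> list[float]:
    """Independent O(n^3) agglomerative complete-linkage oracle; returns the
    sorted multiset of merge heights."""
    import itertools

    n = len(X)
    clusters = {i: [i] for i in range(n)}
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    active = list(range(n))
    heights = []
    next_id = n
    while len(active) > 1:
        best = None
        for a, b in itertools.combinations(active, 2):
            d = max(D[i, j] for i in clusters[a] for j in clusters[b])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        heights.append(float(d))
        clusters[next_id] = clusters[a] + clusters[b]
        active.remove(a)
        active.remove(b)
        active.append(next_id)
        next_id += 1
    return sorted(heights)


def random_protein(rng: np.random.Generator, max_len: int = 60) -> str:
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    n = int(rng.integers(1, max_len + 1))
    return "".join(rng.choice(alphabet, size=n))
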