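import numpy as np
import pytest

from aflp_delimit import (
    AflpSimConfig,
    CallMatrix,
    CallThresholds,
    ReplicateMap,
    simulate_aflp,
)
from aflp_delimit.synthetic_data import score_simulated


def call_matrix_from_strings(rows: dict[str, str]) -> CallMatrix:
    """Build a CallMatrix from {'sample': '01?1...'} rows; bins are b0, b1, ..."""
    samples = list(rows)
    chars = [list(rows[s]) for s in samples]
    code = {"0": 0, "1": 1, "?": -1}
    states = np.array([[code[c] for c in r] for r in chars], dtype=np.int8)
    return CallMatrix(
        samples=samples,
        bins=[f"b{j}" for j in range(states.shape[1])],
        states=states,
        thresholds=CallThresholds(),
    )


@pytest.fixture(scope="session")
def small_cfg() -> AflpSimConfig:
    """A desk-scale study-like simulation: 3 clusters, 2 samples each, 2
    channels of 120 fragments, every sample duplicated."""
    return AflpSimConfig(samples_per_cluster=2, fragment_pool_size=120, seed=5)


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    table, reps, truth = simulate_aflp(small_cfg)
    calls = score_simulated(table, small_cfg)
    return table, reps, truth, calls


@pytest.fixture
def noise_free_cfg() -> AflpSimConfig:
    """All measurement noise off: replicates must score identically."""
    return AflpSimConfig(
        samples_per_cluster=2,
        fragment_pool_size=80,
        size_jitter_sd=0.0,
        intensity_jitter_cv=0.0,
        dropout_band=(0.0, 0.0),
        seed=9,
    )


def random_call_matrix(rng: np.random.Generator, n_samples=8, n_bins=40,
                       p_ambiguous=0.08) -> CallMatrix:
    states = rng.choice([0, 1], size=(n_samples, n_bins)).astype(np.int8)
    amb = rng.random((n_samples, n_bins)) < p_ambiguous
    states[amb] = -1
    return CallMatrix(
        samples=[f"s{i}" for i in range(n_samples)],
        bins=[f"b{j}" for j in range(n_bins)],
        states=states,
    )


def paired_replicate_map(samples: list[str]) -> ReplicateMap:
    """Consecutive pairs of samples as replicate groups."""
    groups = {
        f"g{i // 2}": samples[i : i + 2] for i in range(0, len(samples) - 1, 2)
    }
    return ReplicateMap(groups=groups)
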