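"""Shared fixtures: benchmark recordings and an exhaustive partition oracle."""

import numpy as np
import pytest

from funcsig import (
    SyntheticConfig,
    benchmark_config,
    detect_modules,
    generate_grouped_oscillators,
    generate_nested_groups,
    generate_pure_noise,
)


@pytest.fixture(scope="session")
def benchmark_no_trend():
    return generate_grouped_oscillators(benchmark_config(with_trend=False, seed=11))


@pytest.fixture(scope="session")
def benchmark_with_trend():
    return generate_grouped_oscillators(benchmark_config(with_trend=True, seed=11))


@pytest.fixture(scope="session")
def detection_no_trend(benchmark_no_trend):
    rec, _ = benchmark_no_trend
    return detect_modules(rec, seed=23, n_restarts=20)


@pytest.fixture(scope="session")
def detection_with_trend(benchmark_with_trend):
    rec, _ = benchmark_with_trend
    return detect_modules(rec, seed=23, n_restarts=20)


@pytest.fixture(scope="session")
def noise_recording():
    return generate_pure_noise(100, 1000, seed=7)


def nested_config(seed):
    return SyntheticConfig(
        n_groups=2,
        group_sizes=(100, 100),
        n_timepoints=500,
        group_phase_offsets=(0.0, np.pi),
        phase_spread=np.pi / 12,
        noise_sd=0.2,
        seed=seed,
    )


@pytest.fixture(scope="session")
def nested_benchmark():
    return generate_nested_groups(nested_config(5), sub_phase_spread=np.pi / 3)


def iter_partitions(n):
    """All set partitions of range(n) as label arrays (restricted growth strings)."""
    labels = np.zeros(n, dtype=int)

    def go(i, m):
        if i == n:
            yield labels.copy()
            return
        for c in range(m + 1):
            labels[i] = c
            yield from go(i + 1, max(m, c + 1))

    if n == 1:
        yield labels.copy()
    else:
        yield from go(1, 1)


def brute_force_best(b):
    """Exhaustive maximum of the within-module weight over all partitions."""
    best_w, best_labels = -np.inf, None
    for labels in iter_partitions(b.shape[0]):
        w = b[labels[:, None] == labels[None, :]].sum()
        if w > best_w:
            best_w, best_labels = w, labels
    return best_w, best_labels
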