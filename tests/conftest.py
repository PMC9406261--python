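"""Shared fixtures: reference phantoms and a brute-force Huang oracle."""

from __future__ import annotations

import math

import numpy as np
import pytest

from eosinquant import (
    EllipseRegion,
    NoiseModel,
    PhantomSpec,
    render_phantom,
)


def small_spec(seed: int, **overrides) -> PhantomSpec:
    """A fast 160x160 scene with one vessel; noise off unless overridden."""
    params = dict(
        seed=seed,
        width_px=160,
        height_px=160,
        rbc_count=12,
        vessel_regions=(EllipseRegion(center=(80.0, 80.0), axes=(60.0, 45.0), angle_deg=15.0),),
        noise=NoiseModel(0, 0),
    )
    params.update(overrides)
    return PhantomSpec(**params)


@pytest.fixture(scope="session")
def noise_free_phantom():
    """Default-geometry phantom at full size with noise disabled."""
    return render_phantom(PhantomSpec(seed=123, noise=NoiseModel(0, 0)))


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default phantom including the default shot + read noise."""
    return render_phantom(PhantomSpec(seed=123))


@pytest.fixture(scope="session")
def small_phantom():
    return render_phantom(small_spec(seed=42))


def huang_entropy_oracle(counts: np.ndarray, t: int) -> float:
    """Fuzzy entropy E(t) computed naively, level by level."""
    counts = np.asarray(counts)
    occupied = np.flatnonzero(counts)
    g_min, g_max = int(occupied[0]), int(occupied[-1])
    c_norm = g_max - g_min
    total = counts.sum()

    low = [(g, counts[g]) for g in occupied if g <= t]
    high = [(g, counts[g]) for g in occupied if g > t]
    mu0 = sum(g * n for g, n in low) / sum(n for _, n in low)
    mu1 = sum(g * n for g, n in high) / sum(n for _, n in high)

    def shannon(u: float) -> float:
        if u in (0.0, 1.0):
            return 0.0
        return -u * math.log(u) - (1 - u) * math.log(1 - u)

    acc = 0.0
    for g, n in low:
        acc += n * shannon(1.0 / (1.0 + abs(g - mu0) / c_norm))
    for g, n in high:
        acc += n * shannon(1.0 / (1.0 + abs(g - mu1) / c_norm))
    return acc / total


def huang_threshold_oracle(counts: np.ndarray) -> tuple[int, float]:
    """Exhaustive minimisation of E(t) over all candidate thresholds."""
    counts = np.asarray(counts)
    occupied = np.flatnonzero(counts)
    best_t, best_e = None, math.inf
    for t in range(int(occupied[0]), int(occupied[-1])):
        e = huang_entropy_oracle(counts, t)
        if e < best_e - 1e-15:
            best_t, best_e = t, e
    return best_t, best_e


def random_histogram(rng: np.random.Generator) -> np.ndarray:
    """A random sparse-to-dense 256-bin histogram with >= 2 occupied levels."""
    kind = rng.integers(3)
    counts = np.zeros(256, dtype=np.int64)
    if kind == 0:  # a few isolated spikes
        levels = rng.choice(256, size=rng.integers(2, 8), replace=False)
        counts[levels] = rng.integers(1, 1000, size=levels.size)
    elif kind == 1:  # truncated Gaussian mixture
        n = int(rng.integers(500, 5000))
        means = rng.uniform(20, 235, size=2)
        samples = np.concatenate(
            [rng.normal(m, rng.uniform(3, 30), size=n // 2) for m in means]
        )
        binned = np.clip(np.rint(samples), 0, 255).astype(int)
        counts += np.bincount(binned, minlength=256)
    else:  # uniform occupancy over a random range
        lo, hi = sorted(rng.choice(256, size=2, replace=False))
        counts[lo : hi + 1] = rng.integers(0, 50, size=hi - lo + 1)
        counts[lo] += 1
        counts[hi] += 1
    return counts
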