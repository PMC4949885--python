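"""Random label noise: flipping a fixed fraction of binary labels.

Flipping is exact-count: round(p * n) distinct observations are sampled
without replacement and their labels inverted (0 -> 1, 1 -> 0), matching a
protocol in which a fraction of the observations is drawn and mislabelled,
rather than an independent per-label Bernoulli corruption.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NoiseLadder",
    "DEFAULT_PROPORTIONS",
    "flip_labels",
    "n_flips",
    "expected_minority_frequency",
    "minority_class_frequency",
]

DEFAULT_PROPORTIONS: tuple = (
    0.0, 0.01, 0.025, 0.05, 0.075, 0.10, 0.125,
    0.15, 0.175, 0.20, 0.25, 0.30, 0.40, 0.50,
)


@dataclass(frozen=True)
class NoiseLadder:
    """Ordered mislabel proportions, from 0 (clean) to 0.5 (maximal noise)."""

    proportions: tuple = DEFAULT_PROPORTIONS

    def __post_init__(self):
        p = tuple(float(x) for x in self.proportions)
        if not p:
            raise ValueError("ladder must be non-empty")
        if any(not 0 <= x <= 0.5 for x in p):
            raise ValueError("proportions must lie in [0, 0.5]")
        if any(b <= a for a, b in zip(p, p[1:])):
            raise ValueError("proportions must be strictly increasing")
        object.__setattr__(self, "proportions", p)

    def __iter__(self):
        return iter(self.proportions)

    def __len__(self):
        return len(self.proportions)


def n_flips(n: int, p: float) -> int:
    """Number of labels flipped: round(p*n), half away from zero (123 * 0.5 -> 62)."""
    return int(np.floor(p * n + 0.5))


def flip_labels(y, p: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Invert the labels of round(p*n) uniformly sampled observations.

    Returns ``(noisy_labels, flipped_indices)``; the input is not modified and
    flipping the returned index set again restores the original vector.
    """
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("label vector must be non-empty")
    if not set(np.unique(y)).issubset({0, 1}):
        raise ValueError("labels must be binary 0/1")
    if not 0 <= p <= 0.5:
        raise ValueError("flip proportion must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    k = n_flips(len(y), p)
    idx = np.sort(rng.choice(len(y), size=k, replace=False))
    noisy = y.copy()
    noisy[idx] = 1 - noisy[idx]
    return noisy, idx


def expected_minority_frequency(f: float, p: float) -> float:
    """Expected frequency of the original minority class after flipping.

    With minority frequency f and flip proportion p, a minority label stays
    with probability 1-p and a majority label joins with probability p:
    f (1-p) + (1-f) p = f + p (1 - 2f).

    ``p`` may exceed 0.5: exact-count flipping rounds 0.5 * 123 up to 62, so
    the realized fraction 62/123 lies slightly above the nominal maximum, and
    the closed form remains the exact expectation for any p in [0, 1].
    """
    if not 0 <= f <= 0.5 or not 0 <= p <= 1:
        raise ValueError("f must lie in [0, 0.5] and p in [0, 1]")
    return f + p * (1.0 - 2.0 * f)


def minority_class_frequency(y_reference, y) -> float:
    """Frequency in ``y`` of the class that is the minority in ``y_reference``."""
    y_reference = np.asarray(y_reference)
    y = np.asarray(y)
    minority = 1 if y_reference.mean() < 0.5 else 0
    return float((y == minority).mean())
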