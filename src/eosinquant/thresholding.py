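"""Huang-Wang fuzzy-entropy automatic thresholding.

The threshold is chosen by minimising an index of fuzziness of the binarised
image.  For a candidate threshold ``t`` the grey levels are split into a
"background" class (levels <= t, mean mu0) and a "foreground" class
(levels > t, mean mu1).  Each level ``g`` is given a fuzzy membership

    u(g) = 1 / (1 + |g - mu_class| / C),        C = g_max - g_min,

so u = 1 when a level sits exactly at its class mean and decays towards 1/2
as it moves away.  The fuzziness of the partition is the mean Shannon
entropy of the memberships,

    E(t) = (1/N) * sum_g counts[g] * S(u(g)),
    S(u) = -u ln u - (1 - u) ln(1 - u),   S(1) = 0,

and the returned threshold is the smallest ``t`` attaining the minimum of
E(t) over t in [g_min, g_max - 1] (both classes always non-empty).

Images are reduced to a 256-bin grey-level histogram first: 8-bit images are
binned directly, everything else is linearly rescaled by its own min/max to
[0, 255].  Foreground is the strict inequality ``binned level > t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy

__all__ = [
    "Histogram256",
    "ThresholdResult",
    "quantize256",
    "histogram256",
    "huang_threshold",
    "mean_threshold",
    "apply_threshold",
    "threshold_image",
]

N_LEVELS = 256


@dataclass(frozen=True)
class Histogram256:
    """256-bin grey-level histogram of an image.

    ``counts[g]`` is the number of pixels binned at grey level ``g``;
    ``total`` is the pixel count.  ``degenerate`` flags a single occupied
    level (a constant image), for which no threshold exists.
    """

    counts: np.ndarray
    total: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (N_LEVELS,):
            raise ValueError(f"counts must have {N_LEVELS} bins, got {counts.shape}")
        if np.any(counts < 0):
            raise ValueError("histogram counts must be non-negative")
        if counts.sum() != self.total or self.total <= 0:
            raise ValueError("total must equal the sum of counts and be positive")
        object.__setattr__(self, "counts", counts)

    @property
    def occupied(self) -> np.ndarray:
        """Grey levels with at least one pixel."""
        return np.flatnonzero(self.counts)

    @property
    def degenerate(self) -> bool:
        return self.occupied.size < 2


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of automatic threshold selection.

    ``threshold`` is the grey level minimising the fuzzy entropy,
    ``fuzziness`` the minimal entropy value, ``candidates``/``entropy_curve``
    the full E(t) profile over the candidate range [g_min, g_max - 1].
    """

    threshold: int
    fuzziness: float
    candidates: np.ndarray = field(repr=False)
    entropy_curve: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if not 0 <= self.threshold < N_LEVELS:
            raise ValueError("threshold outside [0, 255]")
        if self.fuzziness < 0:
            raise ValueError("fuzziness must be non-negative")


def quantize256(image: np.ndarray) -> np.ndarray:
    """Bin an image onto the 256 grey levels used for thresholding.

    uint8 input is taken as-is; any other dtype is rescaled linearly by its
    own min/max onto [0, 255] and rounded to the nearest level.  A constant
    image maps entirely to level 0.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if image.dtype == np.uint8:
        return image
    img = image.astype(np.float64)
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        return np.zeros(image.shape, dtype=np.uint8)
    scaled = (img - lo) / (hi - lo) * 255.0
    return np.rint(scaled).astype(np.uint8)


def histogram256(image: np.ndarray) -> Histogram256:
    """256-bin histogram of an image (after :func:`quantize256` binning)."""
    binned = quantize256(image)
    counts = np.bincount(binned.ravel(), minlength=N_LEVELS)
    return Histogram256(counts=counts, total=int(binned.size))


def _entropy_terms(u: np.ndarray) -> np.ndarray:
    # S(u) = -u ln u - (1-u) ln(1-u); xlogy handles S(1) = 0 exactly.
    return -(xlogy(u, u) + xlogy(1.0 - u, 1.0 - u))


def huang_threshold(hist: Histogram256) -> ThresholdResult:
    """Select the fuzzy-entropy-minimising threshold for a histogram.

    Candidates run over [g_min, g_max - 1] so that both classes are
    non-empty; ties are broken toward the smallest t.

    Raises
    ------
    ValueError
        If the histogram occupies a single grey level
        ("degenerate histogram: no threshold exists").
    """
    if hist.degenerate:
        raise ValueError("degenerate histogram: no threshold exists")
    occupied = hist.occupied
    g_min, g_max = int(occupied[0]), int(occupied[-1])
    c_norm = float(g_max - g_min)

    g = np.arange(N_LEVELS, dtype=np.float64)
    counts = hist.counts.astype(np.float64)
    cum_n = np.cumsum(counts)
    cum_gn = np.cumsum(g * counts)
    total_n, total_gn = cum_n[-1], cum_gn[-1]

    # E(t) depends only on which occupied levels fall below the split, so it
    # is piecewise constant between occupied levels: evaluate one t per
    # stretch (its smallest member) and broadcast.  This keeps the
    # smallest-t tie-break exact instead of at the mercy of float jitter.
    starts = occupied[:-1].astype(np.int64)
    n0 = cum_n[starts]
    s0 = cum_gn[starts]
    mu0 = s0 / n0  # n0 > 0 for t >= g_min
    mu1 = (total_gn - s0) / (total_n - n0)  # > 0 pixels for t < g_max

    # membership matrix over (stretch, grey level g)
    mu = np.where(g[None, :] <= starts[:, None], mu0[:, None], mu1[:, None])
    u = 1.0 / (1.0 + np.abs(g[None, :] - mu) / c_norm)
    entropy = _entropy_terms(u) @ counts / total_n

    best = int(np.argmin(entropy))  # first minimum -> smallest t
    candidates = np.arange(g_min, g_max)  # inclusive of g_max - 1
    stretch_of = np.searchsorted(starts, candidates, side="right") - 1
    return ThresholdResult(
        threshold=int(starts[best]),
        fuzziness=float(entropy[best]),
        candidates=candidates,
        entropy_curve=entropy[stretch_of],
    )


def mean_threshold(hist: Histogram256) -> ThresholdResult:
    """Threshold at the floor of the histogram's mean grey level.

    A deliberately simple alternative used for cross-checks; the curve
    reported is the fuzzy entropy so results stay comparable.
    """
    if hist.degenerate:
        raise ValueError("degenerate histogram: no threshold exists")
    g = np.arange(N_LEVELS, dtype=np.float64)
    mean = float((g * hist.counts).sum() / hist.total)
    occupied = hist.occupied
    t = int(np.clip(np.floor(mean), occupied[0], occupied[-1] - 1))
    huang = huang_threshold(hist)
    idx = int(np.searchsorted(huang.candidates, t))
    return ThresholdResult(
        threshold=t,
        fuzziness=float(huang.entropy_curve[idx]),
        candidates=huang.candidates,
        entropy_curve=huang.entropy_curve,
    )


THRESHOLD_METHODS = {
    "huang": huang_threshold,
    "mean": mean_threshold,
}


def apply_threshold(image: np.ndarray, t: int) -> np.ndarray:
    """Binarise an image at grey level ``t`` (strict inequality).

    The image is binned exactly as in :func:`histogram256`; foreground is
    the set of pixels whose binned level is strictly greater than ``t``.
    Returns a boolean mask.
    """
    t = int(t)
    if not 0 <= t < N_LEVELS:
        raise ValueError(f"threshold {t} outside [0, 255]")
    return quantize256(image) > t


def threshold_image(image: np.ndarray, method: str = "huang") -> tuple[ThresholdResult, np.ndarray]:
    """Histogram, threshold and binarise an image in one step."""
    try:
        select = THRESHOLD_METHODS[method]
    except KeyError:
        raise ValueError(
            f"unknown threshold method {method!r}; available: {sorted(THRESHOLD_METHODS)}"
        ) from None
    result = select(histogram256(image))
    return result, apply_threshold(image, result.threshold)
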