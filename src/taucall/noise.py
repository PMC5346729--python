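"""Local sequencing background-noise estimation via the modified Thompson Tau test.

The caller's central statistic: in a window (default 200 bp) centred on a
candidate position, the per-position counts of alternative-allele reads form a
sample of the local error level.  Zeros are stripped (error-free positions
carry no information about the error magnitude), then a suspected outlier —
the point with the largest absolute deviation from the sample mean — is tested
with the modified Thompson Tau rule and removed if rejected, iterating until
the most-suspect point is retained.  Real variants are exactly such outliers,
so trimming them leaves a sample describing the background error process; its
maximum is the local noise count.

The rejection threshold is ``tau * S`` where ``S`` is the sample standard
deviation and

    tau = t * (n - 1) / ( sqrt(n) * sqrt(n - 2 + t^2) )

with ``t`` the upper ``alpha/2`` critical value of Student's t at ``n - 2``
degrees of freedom.  ``alpha`` defaults to 0.001.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "NoiseEstimate",
    "modified_thompson_tau",
    "detect_outliers",
    "local_background_noise",
]


@lru_cache(maxsize=None)
def _t_critical(df: int, alpha: float) -> float:
    return float(stats.t.ppf(1.0 - alpha / 2.0, df))


def modified_thompson_tau(n: int, alpha: float = 0.001) -> float:
    """Rejection coefficient tau for a sample of size ``n`` at two-tailed risk ``alpha``.

    Requires ``n >= 3`` so that the degrees of freedom ``n - 2`` are at least 1.
    For large ``n`` tau approaches the standard-normal upper ``alpha/2``
    quantile.
    """
    if n < 3:
        raise ValueError(f"modified Thompson tau needs n >= 3, got {n}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    t = _t_critical(n - 2, float(alpha))
    return t * (n - 1) / (math.sqrt(n) * math.sqrt(n - 2 + t * t))


def detect_outliers(
    values: Sequence[int], alpha: float = 0.001
) -> tuple[list[int], list[int]]:
    """Iteratively trim outliers from a sample of counts.

    Each iteration computes the sample mean and standard deviation S (n-1
    denominator), finds the point(s) with maximal absolute deviation
    ``delta = |x - mean|`` and removes them when ``delta > tau * S``.
    Iteration stops when the most-suspect point is retained, when S is zero,
    or when fewer than 3 points remain (the test is undefined there and the
    sample is kept as-is).  Points tied at the maximal deviation are tested
    and removed as one group, which makes the result independent of input
    order.

    Returns ``(kept, removed)``; together they restore the input multiset.
    """
    vals = [int(v) for v in values]
    if not vals:
        raise ValueError("detect_outliers needs a nonempty sample")
    x = np.asarray(vals, dtype=float)
    removed: list[int] = []
    while x.size >= 3:
        mean = x.mean()
        s = x.std(ddof=1)
        if s == 0.0:
            break
        d = np.abs(x - mean)
        dmax = d.max()
        tau = modified_thompson_tau(int(x.size), alpha)
        if dmax > tau * s:
            hit = d == dmax
            removed.extend(int(v) for v in x[hit])
            x = x[~hit]
        else:
            break
    kept = [int(v) for v in x]
    return kept, removed


@dataclass
class NoiseEstimate:
    """Background-noise summary for one window.

    ``noise_count`` is the largest per-position alternative-read count that
    survived outlier trimming (0 when the window carries no alternative
    reads); ``noise_rate`` expresses it as a fraction of the mean read depth
    over the window.
    """

    noise_count: int
    noise_rate: float
    kept: list[int]
    removed: list[int]
    window_start: int
    window_end: int
    mean_depth: float
    alpha: float


def local_background_noise(
    profile,
    center_pos: int,
    window_bp: int = 200,
    alpha: float = 0.001,
    center_exclusion: int | None = None,
) -> NoiseEstimate:
    """Estimate background noise in a window centred on ``center_pos``.

    The window spans ``window_bp`` total base pairs (±``window_bp // 2``),
    clipped at the region boundaries.  The sample is the per-position total
    alternative-read count over the window.  ``center_exclusion`` controls how
    much of the centre position's own alternative count is removed before
    sampling: ``None`` removes all of it (used when no specific candidate
    allele is in play, e.g. detection-limit reports), an integer removes that
    many reads (the candidate allele's count, so co-occurring alleles at the
    centre still contribute), and 0 keeps everything.

    Raises ``ValueError`` when the centre lies outside the region or the
    window covers no pileup positions.
    """
    region = profile.region
    if not (region.start <= center_pos <= region.end):
        raise ValueError(
            f"position {center_pos} outside region {region.chrom}:"
            f"{region.start}-{region.end}"
        )
    half = window_bp // 2
    lo = max(region.start, center_pos - half)
    hi = min(region.end, center_pos + half)
    positions = profile.positions
    i0 = int(np.searchsorted(positions, lo, side="left"))
    i1 = int(np.searchsorted(positions, hi, side="right"))
    if i1 <= i0:
        raise ValueError(
            f"window {region.chrom}:{lo}-{hi} contains no pileup positions"
        )
    depths = profile.depths[i0:i1]
    alts = profile.alt_counts[i0:i1].copy()
    ci = profile.index_of(center_pos)
    if ci is not None and i0 <= ci < i1:
        if center_exclusion is None:
            alts[ci - i0] = 0
        else:
            alts[ci - i0] = max(0, alts[ci - i0] - int(center_exclusion))
    sample = alts[alts > 0]
    if sample.size == 0:
        kept: list[int] = []
        removed: list[int] = []
    else:
        kept, removed = detect_outliers(sample.tolist(), alpha)
    noise_count = max(kept) if kept else 0
    mean_depth = float(depths.mean())
    noise_rate = min(1.0, noise_count / mean_depth) if mean_depth > 0 else 0.0
    return NoiseEstimate(
        noise_count=noise_count,
        noise_rate=noise_rate,
        kept=kept,
        removed=removed,
        window_start=lo,
        window_end=hi,
        mean_depth=mean_depth,
        alpha=alpha,
    )
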