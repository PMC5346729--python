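"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately avoid the code paths they check: the Student-t
critical value is obtained by bisecting the t CDF expressed through the
regularized incomplete beta function (scipy.special.betainc), not through
``scipy.stats.t.ppf``; the outlier-trimming oracle is a literal step-by-step
transcription of the procedure using ``statistics`` module arithmetic.
"""

from __future__ import annotations

import math
import statistics

import pytest
from scipy import special

import taucall as tc


# ---------------------------------------------------------------------------
# independent oracles


def t_cdf_via_betainc(x: float, df: int) -> float:
    """Student-t CDF from the regularized incomplete beta function."""
    if x == 0.0:
        return 0.5
    ib = special.betainc(df / 2.0, 0.5, df / (df + x * x))
    return 1.0 - 0.5 * ib if x > 0 else 0.5 * ib


def t_quantile_oracle(p: float, df: int) -> float:
    """Upper-tail-free quantile: smallest x with CDF(x) >= p, by bisection."""
    lo, hi = 0.0, 10.0
    while t_cdf_via_betainc(hi, df) < p:
        hi *= 2.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if t_cdf_via_betainc(mid, df) < p:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def tau_oracle(n: int, alpha: float) -> float:
    t = t_quantile_oracle(1.0 - alpha / 2.0, n - 2)
    return t * (n - 1) / (math.sqrt(n) * math.sqrt(n - 2 + t * t))


def trim_oracle(values, alpha):
    """Literal reimplementation of iterative Thompson-Tau trimming."""
    sample = [int(v) for v in values]
    removed = []
    while len(sample) >= 3:
        mean = statistics.fmean(sample)
        s = statistics.stdev(sample)
        if s == 0.0:
            break
        deltas = [abs(x - mean) for x in sample]
        dmax = max(deltas)
        tau = tau_oracle(len(sample), alpha)
        if dmax > tau * s:
            hits = [x for x, d in zip(sample, deltas) if d == dmax]
            removed.extend(hits)
            sample = [x for x, d in zip(sample, deltas) if d != dmax]
        else:
            break
    return sample, removed


@pytest.fixture
def oracles():
    return {
        "t_quantile": t_quantile_oracle,
        "tau": tau_oracle,
        "trim": trim_oracle,
    }


# ---------------------------------------------------------------------------
# reusable simulated data


@pytest.fixture(scope="session")
def clean_variant_sim():
    """Depth-1000 region with one 5% SNV injected at the centre, seed fixed."""
    cfg = tc.SimulationConfig(
        regions=[tc.GenomicRegion("chr1", 1, 201, label="exon1")],
        depth=1000,
        error_rate=0.001,
        variants=[tc.InjectedVariant("chr1", 101, "T", 0.05)],
        seed=7,
    )
    profiles, truth = tc.simulate_profiles(cfg)
    return cfg, profiles, truth


def make_column(
    chrom: str,
    pos: int,
    ref: str = "A",
    depth: int = 1000,
    alt: str | None = None,
    alt_fwd: int = 0,
    alt_rev: int = 0,
    alt_qual: int = 35,
    ref_qual: int = 35,
):
    """Hand-built pileup column with the given alt support, ref filling the rest."""
    col = tc.PileupColumn(chrom=chrom, pos=pos, ref_base=ref, depth=depth)
    if alt is not None and (alt_fwd or alt_rev):
        col.alts[alt] = tc.AlleleObservation(
            alt, [alt_qual] * alt_fwd, [alt_qual] * alt_rev
        )
    n_ref = depth - alt_fwd - alt_rev
    col.ref_quals_fwd = [ref_qual] * (n_ref // 2)
    col.ref_quals_rev = [ref_qual] * (n_ref - n_ref // 2)
    return col


@pytest.fixture
def column_factory():
    return make_column
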