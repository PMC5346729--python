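"""Synthetic pileup generation with known truth, in-silico downsampling, and
the coverage-vs-sensitivity benchmark harness.

The generator emulates targeted amplicon/capture sequencing of a tumor sample
at the pileup level: per position a read depth (fixed or Poisson), uniform
independent substitution errors at a configurable per-base rate spread over
the non-reference bases with random strands, and injected variants whose
supporting-read counts are binomial at the target allele fraction.  Injected
variants receive a controlled strand split (their forward-strand fraction is
applied deterministically by rounding) and a configurable quality profile, so
truth-driven evaluations probe the statistical machinery rather than strand
sampling noise; error reads keep fully random strands.  Base qualities are
drawn from clipped normal distributions: true bases around Phred 35 (SD 3),
error bases around Phred 25 (SD 6), both clipped to [2, 41] — Illumina-like
ranges that exercise the quality filters without deciding calls by
themselves.

A fixed seed makes the emitted pileup text byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .caller import FilterConfig, call_variants
from .pileup_io import (
    AlleleObservation,
    GenomicRegion,
    PileupColumn,
    RegionProfile,
    write_pileup,
)

__all__ = [
    "InjectedVariant",
    "SimulationConfig",
    "simulate_profiles",
    "simulate_pileup",
    "downsample_pileup",
    "sensitivity_harness",
    "DEPTH_BINS",
]

_BASES = ("A", "C", "G", "T")

#: Representative simulated depth for each coverage bin of the
#: coverage-vs-sensitivity benchmark.
DEPTH_BINS: Mapping[str, int] = {
    "<150": 100,
    "150-300": 225,
    "300-600": 450,
    "600-1000": 800,
    ">1000": 1500,
}


@dataclass(frozen=True)
class InjectedVariant:
    """A ground-truth variant to spike into the simulation.

    ``alt`` is a substitution base, ``+SEQ`` insertion or ``-SEQ`` deletion.
    ``strand_fraction`` is the forward-strand share of supporting reads,
    realized deterministically (rounded); ``qual_mean`` / ``qual_sd``
    override the true-base quality model for this variant's reads.
    """

    chrom: str
    pos: int
    alt: str
    vaf: float
    strand_fraction: float = 0.5
    qual_mean: float | None = None
    qual_sd: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.vaf <= 1.0:
            raise ValueError(f"variant VAF must be in (0, 1], got {self.vaf}")
        if not 0.0 <= self.strand_fraction <= 1.0:
            raise ValueError("strand_fraction must be in [0, 1]")
        allele = self.alt.upper()
        if allele[:1] in "+-":
            if not allele[1:] or not set(allele[1:]) <= set("ACGT"):
                raise ValueError(f"malformed indel allele {self.alt!r}")
        elif allele not in _BASES:
            raise ValueError(f"malformed substitution allele {self.alt!r}")
        object.__setattr__(self, "alt", allele)


@dataclass
class SimulationConfig:
    """Study conditions for one simulated sample."""

    regions: list[GenomicRegion]
    depth: int = 1000
    depth_model: str = "fixed"  # "fixed" | "poisson"
    error_rate: float = 0.001
    true_qual_mean: float = 35.0
    true_qual_sd: float = 3.0
    error_qual_mean: float = 25.0
    error_qual_sd: float = 6.0
    variants: list[InjectedVariant] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate < 0.05:
            raise ValueError("error_rate must be in [0, 0.05)")
        if self.depth_model not in ("fixed", "poisson"):
            raise ValueError(f"unknown depth model {self.depth_model!r}")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        for v in self.variants:
            if not any(r.contains(v.chrom, v.pos) for r in self.regions):
                raise ValueError(
                    f"injected variant at {v.chrom}:{v.pos} is outside every region"
                )


def _draw_quals(rng, n: int, mean: float, sd: float) -> list[int]:
    if n == 0:
        return []
    q = np.rint(rng.normal(mean, sd, size=n))
    return np.clip(q, 2, 41).astype(int).tolist()


def simulate_profiles(
    config: SimulationConfig,
) -> tuple[list[RegionProfile], pd.DataFrame]:
    """Simulate region profiles plus a truth table of injected variants.

    The truth table records the realized (not target) supporting-read count
    of every injected variant, which by construction equals the count
    recovered by re-parsing the emitted pileup.  At an injected SNV's
    position, sequencing errors are spread over the bases that are neither
    the reference nor an injected allele, so truth counts stay exact.
    """
    rng = np.random.default_rng(config.seed)
    variants_at: dict[tuple[str, int], list[InjectedVariant]] = {}
    for v in config.variants:
        variants_at.setdefault((v.chrom, v.pos), []).append(v)

    profiles = []
    truth_rows = []
    for region in config.regions:
        ref_seq = rng.choice(_BASES, size=region.span)
        # an injected SNV's alt must differ from the reference; nudge the
        # reference deterministically when the draw collides
        for v in config.variants:
            if v.chrom == region.chrom and region.start <= v.pos <= region.end:
                i = v.pos - region.start
                if not v.alt.startswith(("+", "-")) and ref_seq[i] == v.alt:
                    ref_seq[i] = _BASES[(_BASES.index(v.alt) + 1) % 4]
        columns = []
        for offset in range(region.span):
            pos = region.start + offset
            ref_base = str(ref_seq[offset])
            depth = (
                config.depth
                if config.depth_model == "fixed"
                else int(rng.poisson(config.depth))
            )
            col = PileupColumn(
                chrom=region.chrom, pos=pos, ref_base=ref_base, depth=depth
            )
            remaining = depth
            injected_snv_bases = set()
            for v in variants_at.get((region.chrom, pos), ()):
                n_v = int(rng.binomial(depth, v.vaf)) if depth else 0
                n_v = min(n_v, remaining)
                remaining -= n_v
                qm = config.true_qual_mean if v.qual_mean is None else v.qual_mean
                qs = config.true_qual_sd if v.qual_sd is None else v.qual_sd
                quals = _draw_quals(rng, n_v, qm, qs)
                n_fwd = int(round(v.strand_fraction * n_v))
                if n_v:
                    obs = col.alts.setdefault(v.alt, AlleleObservation(v.alt))
                    obs.quals_fwd.extend(quals[:n_fwd])
                    obs.quals_rev.extend(quals[n_fwd:])
                if not v.alt.startswith(("+", "-")):
                    injected_snv_bases.add(v.alt)
                truth_rows.append(
                    {
                        "chrom": region.chrom,
                        "pos": pos,
                        "ref": ref_base,
                        "alt": v.alt,
                        "target_vaf": v.vaf,
                        "depth": depth,
                        "alt_count": n_v,
                        "vaf": n_v / depth if depth else 0.0,
                    }
                )
            error_pool = [
                b
                for b in _BASES
                if b != ref_base and b not in injected_snv_bases
            ]
            n_err = (
                int(rng.binomial(remaining, config.error_rate))
                if remaining and config.error_rate > 0 and error_pool
                else 0
            )
            remaining -= n_err
            if n_err:
                split = rng.multinomial(
                    n_err, [1.0 / len(error_pool)] * len(error_pool)
                )
                for base, k in zip(error_pool, split):
                    if not k:
                        continue
                    quals = _draw_quals(
                        rng, int(k), config.error_qual_mean, config.error_qual_sd
                    )
                    fwd_mask = rng.integers(0, 2, size=int(k)).astype(bool)
                    obs = col.alts.setdefault(base, AlleleObservation(base))
                    for q, fwd in zip(quals, fwd_mask):
                        (obs.quals_fwd if fwd else obs.quals_rev).append(q)
            n_ref = remaining
            n_ref_fwd = int(rng.binomial(n_ref, 0.5)) if n_ref else 0
            quals = _draw_quals(
                rng, n_ref, config.true_qual_mean, config.true_qual_sd
            )
            col.ref_quals_fwd.extend(quals[:n_ref_fwd])
            col.ref_quals_rev.extend(quals[n_ref_fwd:])
            columns.append(col)
        profiles.append(RegionProfile(region, columns))
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "chrom",
            "pos",
            "ref",
            "alt",
            "target_vaf",
            "depth",
            "alt_count",
            "vaf",
        ],
    )
    return profiles, truth


def simulate_pileup(config: SimulationConfig) -> tuple[str, pd.DataFrame]:
    """Simulate and serialize: returns (pileup text, truth table)."""
    profiles, truth = simulate_profiles(config)
    return write_pileup(profiles), truth


# ---------------------------------------------------------------------------
# in-silico downsampling


def downsample_pileup(
    profile: RegionProfile, fraction: float, seed: int = 0
) -> RegionProfile:
    """Thin a profile by keeping each read independently with probability
    ``fraction``, preserving strand and quality of retained reads.

    ``fraction`` 1 returns an identical copy.  Used to emulate lower
    sequencing depth from the same library when benchmarking sensitivity
    against coverage.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    rng = np.random.default_rng(seed)

    def thin(quals: Sequence[int]) -> list[int]:
        if fraction == 1.0 or not quals:
            return list(quals)
        keep = rng.random(len(quals)) < fraction
        return [q for q, k in zip(quals, keep) if k]

    columns = []
    for col in profile.columns:
        new = PileupColumn(
            chrom=col.chrom,
            pos=col.pos,
            ref_base=col.ref_base,
            depth=0,
            ref_quals_fwd=thin(col.ref_quals_fwd),
            ref_quals_rev=thin(col.ref_quals_rev),
            star_quals=thin(col.star_quals),
        )
        for allele in sorted(col.alts):
            obs = col.alts[allele]
            kept = AlleleObservation(
                allele, thin(obs.quals_fwd), thin(obs.quals_rev)
            )
            if kept.count:
                new.alts[allele] = kept
        new.depth = (
            new.ref_count
            + len(new.star_quals)
            + sum(o.count for o in new.alts.values())
        )
        columns.append(new)
    return RegionProfile(profile.region, columns)


# ---------------------------------------------------------------------------
# coverage-vs-sensitivity benchmark


def _replicate_seed(seed: int, *indices: int) -> int:
    ss = np.random.SeedSequence((int(seed),) + tuple(int(i) for i in indices))
    return int(ss.generate_state(1)[0] % (2**31))


def sensitivity_harness(
    vafs: Sequence[float] = (0.01, 0.02, 0.05),
    depth_bins: Mapping[str, int] = DEPTH_BINS,
    replicates: int = 100,
    seed: int = 0,
    error_rate: float = 0.001,
    filter_config: FilterConfig | None = None,
    region_length: int = 201,
) -> pd.DataFrame:
    """Estimate calling sensitivity on a grid of coverage bins x allele fractions.

    Each replicate simulates one region of ``region_length`` positions at the
    bin's representative depth with a single variant injected at the centre,
    runs the caller, and scores a hit when the injected allele is a PASS call
    at the injected position.  Returns a tidy table with columns
    ``depth_bin, depth, vaf, replicates, sensitivity``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    filter_config = filter_config or FilterConfig()
    rows = []
    for bi, (bin_name, depth) in enumerate(depth_bins.items()):
        for vi, vaf in enumerate(vafs):
            hits = 0
            for rep in range(replicates):
                rep_seed = _replicate_seed(seed, bi, vi, rep)
                center = 1 + region_length // 2
                region = GenomicRegion("sim", 1, region_length)
                cfg = SimulationConfig(
                    regions=[region],
                    depth=depth,
                    error_rate=error_rate,
                    variants=[
                        InjectedVariant("sim", center, "T", vaf)
                    ],
                    seed=rep_seed,
                )
                profiles, truth = simulate_profiles(cfg)
                calls = call_variants(profiles, filter_config)
                alt = truth.iloc[0]["alt"]
                if any(
                    c.pos == center and c.alt == alt and c.is_pass
                    for c in calls
                ):
                    hits += 1
            rows.append(
                {
                    "depth_bin": bin_name,
                    "depth": depth,
                    "vaf": vaf,
                    "replicates": replicates,
                    "sensitivity": hits / replicates,
                }
            )
    return pd.DataFrame(rows)
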