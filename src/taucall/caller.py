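"""Variant calling on top of the local background-noise estimate.

Pipeline per candidate (any alternative allele with at least one supporting
read): estimate the local background noise in a window around the position,
promote the candidate past the *statistical step* if its supporting-read
count strictly exceeds the local noise count, then evaluate four quality
filters:

  (i)   allele fraction greater than ``noise_multiplier`` times the local
        noise rate (default: twice),
  (ii)  mean Phred quality of supporting bases greater than 20,
  (iii) standard deviation of those qualities below 7,
  (iv)  forward-strand fraction of supporting reads between 30% and 70%
        (inclusive).

Candidates failing the statistical step are treated as background noise and
produce no call; candidates failing filters are emitted with FILTER tags so
the VCF documents why they were demoted (a pass-only switch restores
calls-only output).

Two auxiliary modes reuse the same noise machinery: a per-region /
per-position limit-of-detection report (the minimum allele fraction the run
could have detected), and a single-position metrics query.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .noise import NoiseEstimate, local_background_noise
from .pileup_io import AlleleObservation, GenomicRegion, RegionProfile

__all__ = [
    "FilterConfig",
    "VariantCall",
    "LODReport",
    "PositionReport",
    "FILTER_LOW_RATIO",
    "FILTER_LOW_MEAN_QUAL",
    "FILTER_HIGH_QUAL_SD",
    "FILTER_STRAND_IMBALANCE",
    "collect_candidates",
    "statistical_step",
    "apply_filters",
    "call_variants",
    "lod_report",
    "lod_table_to_tsv",
    "position_report",
]

FILTER_LOW_RATIO = "low_ratio_vs_noise"
FILTER_LOW_MEAN_QUAL = "low_mean_qual"
FILTER_HIGH_QUAL_SD = "high_qual_sd"
FILTER_STRAND_IMBALANCE = "strand_imbalance"
FILTER_BELOW_CUTOFF = "below_reporting_cutoff"


@dataclass
class FilterConfig:
    """Tunable parameters of the statistical step and quality filters.

    Defaults are the method's standard operating point: ``alpha`` 0.001 for
    the outlier test, a 200 bp noise window, allele fraction required to beat
    twice the noise rate, mean Phred > 20, Phred SD < 7, and a forward-strand
    fraction within [0.30, 0.70].  ``vaf_min_snv`` / ``vaf_min_indel`` are
    optional reporting cutoffs (off by default) used when comparing call sets
    at a fixed limit of detection; they tag rather than suppress calls.
    ``include_candidate_in_noise`` keeps the candidate's own reads in the
    noise sample before trimming (default: excluded).
    """

    alpha: float = 0.001
    window_bp: int = 200
    noise_multiplier: float = 2.0
    min_mean_phred: float = 20.0
    max_phred_sd: float = 7.0
    strand_balance_low: float = 0.30
    strand_balance_high: float = 0.70
    vaf_min_snv: float | None = None
    vaf_min_indel: float | None = None
    include_candidate_in_noise: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.window_bp < 1:
            raise ValueError("window_bp must be positive")
        if not (
            0.0 <= self.strand_balance_low < self.strand_balance_high <= 1.0
        ):
            raise ValueError(
                "need 0 <= strand_balance_low < strand_balance_high <= 1"
            )

    def as_dict(self) -> dict:
        d = {
            "alpha": self.alpha,
            "window_bp": self.window_bp,
            "noise_multiplier": self.noise_multiplier,
            "min_mean_phred": self.min_mean_phred,
            "max_phred_sd": self.max_phred_sd,
            "strand_balance_low": self.strand_balance_low,
            "strand_balance_high": self.strand_balance_high,
            "include_candidate_in_noise": self.include_candidate_in_noise,
        }
        if self.vaf_min_snv is not None:
            d["vaf_min_snv"] = self.vaf_min_snv
        if self.vaf_min_indel is not None:
            d["vaf_min_indel"] = self.vaf_min_indel
        return d


@dataclass
class VariantCall:
    """A candidate that cleared the statistical step, with filter verdicts."""

    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int
    alt_count: int
    vaf: float
    fwd_count: int
    rev_count: int
    mean_qual: float
    sd_qual: float
    noise: NoiseEstimate
    filters: list[str] = field(default_factory=list)

    @property
    def filter_status(self) -> str:
        return "PASS" if not self.filters else ";".join(self.filters)

    @property
    def is_pass(self) -> bool:
        return not self.filters


@dataclass
class LODReport:
    """Minimum detectable allele fraction for a region or single position.

    Per position the limit of detection is the smallest allele fraction that
    would clear both the statistical step and the noise-ratio filter:

        lod(p) = max( noise_multiplier * noise_rate(p),
                      (noise_count(p) + 1) / depth(p) )

    For a region, ``lod_mean`` averages per-position limits and ``lod_max``
    is the worst case; ``min_detectable_ratio`` reports the worst case, the
    fraction guaranteed detectable anywhere in the target.
    """

    chrom: str
    start: int
    end: int
    label: str | None
    mean_depth: float
    mean_noise_rate: float
    lod_mean: float
    lod_max: float
    per_position: list[tuple[int, float]] | None = None

    @property
    def min_detectable_ratio(self) -> float:
        return self.lod_max

    @property
    def target(self) -> str:
        if self.start == self.end:
            return f"{self.chrom}:{self.start}"
        name = self.label or f"{self.chrom}:{self.start}-{self.end}"
        return name


@dataclass
class PositionReport:
    """Raw sequencing metrics at one position: depth, alleles, strand counts,
    mean quality and the local background-noise estimate."""

    chrom: str
    pos: int
    depth: int
    ref_base: str
    alt_allele: str | None
    alt_count: int
    alt_fwd: int
    alt_rev: int
    vaf: float
    mean_qual: float
    noise: NoiseEstimate


# ---------------------------------------------------------------------------


def collect_candidates(
    profile: RegionProfile,
) -> list[tuple[int, AlleleObservation]]:
    """Enumerate every (position, alternative allele) with >= 1 supporting read.

    Each alternative allele at a multi-allelic position is an independent
    candidate; ordering is by position then allele string.
    """
    out = []
    for col in profile.columns:
        for allele in sorted(col.alts):
            obs = col.alts[allele]
            if obs.count >= 1:
                out.append((col.pos, obs))
    return out


def statistical_step(alt_count: int, noise: NoiseEstimate) -> bool:
    """Candidate survives iff its read support strictly exceeds the noise count."""
    return alt_count > noise.noise_count


def _qual_stats(qualities: Sequence[int]) -> tuple[float, float]:
    q = np.asarray(qualities, dtype=float)
    if q.size == 0:
        return 0.0, 0.0
    # population SD; a single supporting read has SD 0 by convention
    return float(q.mean()), float(q.std(ddof=0))


def apply_filters(
    obs: AlleleObservation,
    depth: int,
    noise: NoiseEstimate,
    config: FilterConfig,
) -> list[str]:
    """Evaluate the quality filters; returns the list of failed-filter tags.

    All criteria are checked (a failing candidate carries every tag it
    earned).  Boundaries follow the criteria as worded: mean quality must be
    strictly greater than the floor, the SD strictly below the ceiling, and
    the strand fraction within the inclusive band.
    """
    fails: list[str] = []
    vaf = obs.count / depth
    mean_q, sd_q = _qual_stats(obs.qualities)
    if not vaf > config.noise_multiplier * noise.noise_rate:
        fails.append(FILTER_LOW_RATIO)
    if not mean_q > config.min_mean_phred:
        fails.append(FILTER_LOW_MEAN_QUAL)
    if not sd_q < config.max_phred_sd:
        fails.append(FILTER_HIGH_QUAL_SD)
    fwd_frac = obs.fwd_count / obs.count
    if not (
        config.strand_balance_low <= fwd_frac <= config.strand_balance_high
    ):
        fails.append(FILTER_STRAND_IMBALANCE)
    cutoff = config.vaf_min_indel if obs.is_indel else config.vaf_min_snv
    if cutoff is not None and vaf < cutoff:
        fails.append(FILTER_BELOW_CUTOFF)
    return fails


def call_variants(
    profiles: Sequence[RegionProfile],
    config: FilterConfig | None = None,
) -> list[VariantCall]:
    """Run the full calling pipeline over parsed regions.

    Returns calls sorted by (chrom, pos, alt).  Candidates failing the
    statistical step are silently absorbed into the background; candidates
    failing quality filters are returned with their failed-filter tags.
    """
    config = config or FilterConfig()
    calls: list[VariantCall] = []
    for profile in profiles:
        if len(profile) == 0:
            continue
        for pos, obs in collect_candidates(profile):
            exclusion = 0 if config.include_candidate_in_noise else obs.count
            noise = local_background_noise(
                profile,
                pos,
                window_bp=config.window_bp,
                alpha=config.alpha,
                center_exclusion=exclusion,
            )
            if not statistical_step(obs.count, noise):
                continue
            col = profile.column_at(pos)
            mean_q, sd_q = _qual_stats(obs.qualities)
            calls.append(
                VariantCall(
                    chrom=col.chrom,
                    pos=pos,
                    ref=col.ref_base,
                    alt=obs.allele,
                    depth=col.depth,
                    alt_count=obs.count,
                    vaf=obs.count / col.depth,
                    fwd_count=obs.fwd_count,
                    rev_count=obs.rev_count,
                    mean_qual=mean_q,
                    sd_qual=sd_q,
                    noise=noise,
                    filters=apply_filters(obs, col.depth, noise, config),
                )
            )
    calls.sort(key=lambda c: (c.chrom, c.pos, c.alt))
    return calls


# ---------------------------------------------------------------------------
# limit-of-detection reporting


def _position_lod(
    profile: RegionProfile, pos: int, config: FilterConfig
) -> tuple[float, NoiseEstimate]:
    noise = local_background_noise(
        profile,
        pos,
        window_bp=config.window_bp,
        alpha=config.alpha,
        center_exclusion=None,
    )
    col = profile.column_at(pos)
    if col is None or col.depth == 0:
        return 1.0, noise
    lod = max(
        config.noise_multiplier * noise.noise_rate,
        (noise.noise_count + 1) / col.depth,
    )
    return min(1.0, lod), noise


def _find_profile(
    profiles: Sequence[RegionProfile], chrom: str, pos: int
) -> RegionProfile:
    for profile in profiles:
        if profile.region.contains(chrom, pos):
            return profile
    raise ValueError(f"position {chrom}:{pos} not covered by any region")


def lod_report(
    profiles: Sequence[RegionProfile],
    config: FilterConfig | None = None,
    targets: Sequence[GenomicRegion | tuple[str, int]] | None = None,
    per_position: bool = False,
) -> list[LODReport]:
    """Minimum detectable allele fraction per target region or position.

    ``targets`` may mix :class:`GenomicRegion` objects and ``(chrom, pos)``
    tuples; by default every profiled region is reported.  Positions without
    pileup coverage inside a target region are skipped; a target with no
    covered position at all is an error.
    """
    config = config or FilterConfig()
    if targets is None:
        targets = [p.region for p in profiles]
    reports = []
    for target in targets:
        if isinstance(target, GenomicRegion):
            profile = None
            for p in profiles:
                if (
                    p.region.chrom == target.chrom
                    and p.region.start <= target.start
                    and target.end <= p.region.end
                ):
                    profile = p
                    break
            if profile is None:
                raise ValueError(f"target {target} not covered by any region")
            pos_list = [
                int(p)
                for p in profile.positions
                if target.start <= p <= target.end
            ]
            chrom, start, end, label = (
                target.chrom,
                target.start,
                target.end,
                target.label,
            )
        else:
            chrom, pos = target
            profile = _find_profile(profiles, chrom, pos)
            if profile.column_at(pos) is None:
                raise ValueError(f"position {chrom}:{pos} has no pileup data")
            pos_list = [pos]
            start = end = pos
            label = None
        if not pos_list:
            raise ValueError(f"target {chrom}:{start}-{end} has no pileup data")
        lods, rates, depths, per_pos = [], [], [], []
        for p in pos_list:
            lod, noise = _position_lod(profile, p, config)
            lods.append(lod)
            rates.append(noise.noise_rate)
            depths.append(profile.column_at(p).depth)
            if per_position:
                per_pos.append((p, lod))
        reports.append(
            LODReport(
                chrom=chrom,
                start=start,
                end=end,
                label=label,
                mean_depth=float(np.mean(depths)),
                mean_noise_rate=float(np.mean(rates)),
                lod_mean=float(np.mean(lods)),
                lod_max=float(np.max(lods)),
                per_position=per_pos if per_position else None,
            )
        )
    return reports


def lod_table_to_tsv(reports: Sequence[LODReport]) -> str:
    lines = ["target\tmean_depth\tmean_noise_rate\tlod_mean\tlod_max"]
    for r in reports:
        lines.append(
            f"{r.target}\t{r.mean_depth:.1f}\t{r.mean_noise_rate:.6g}\t"
            f"{r.lod_mean:.6g}\t{r.lod_max:.6g}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# single-position query


def position_report(
    profiles: Sequence[RegionProfile],
    chrom: str,
    pos: int,
    config: FilterConfig | None = None,
) -> PositionReport:
    """Raw metrics at one position: depth, major alternative allele with
    strand counts, mean quality and local background noise.

    The reported mean quality is that of the alternative-allele reads when an
    alternative exists, otherwise of all bases at the position.  Raises
    ``ValueError`` when the position is not covered.
    """
    config = config or FilterConfig()
    profile = _find_profile(profiles, chrom, pos)
    col = profile.column_at(pos)
    if col is None:
        raise ValueError(f"position {chrom}:{pos} not covered by pileup data")
    noise = local_background_noise(
        profile,
        pos,
        window_bp=config.window_bp,
        alpha=config.alpha,
        center_exclusion=None,
    )
    if col.alts:
        allele = max(sorted(col.alts), key=lambda a: col.alts[a].count)
        obs = col.alts[allele]
        mean_q, _ = _qual_stats(obs.qualities)
        return PositionReport(
            chrom=chrom,
            pos=pos,
            depth=col.depth,
            ref_base=col.ref_base,
            alt_allele=allele,
            alt_count=obs.count,
            alt_fwd=obs.fwd_count,
            alt_rev=obs.rev_count,
            vaf=obs.count / col.depth if col.depth else 0.0,
            mean_qual=mean_q,
            noise=noise,
        )
    mean_q, _ = _qual_stats(col.all_base_quals)
    return PositionReport(
        chrom=chrom,
        pos=pos,
        depth=col.depth,
        ref_base=col.ref_base,
        alt_allele=None,
        alt_count=0,
        alt_fwd=0,
        alt_rev=0,
        vaf=0.0,
        mean_qual=mean_q,
        noise=noise,
    )
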