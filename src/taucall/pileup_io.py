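"""Text-format boundary of the caller: samtools-style pileup, BED targets, VCF output.

The caller consumes the single-sample, six-column ``samtools mpileup`` dialect
(chrom, 1-based position, reference base, depth, encoded base calls, Phred+33
base qualities).  Base-call codes are decoded into per-allele observations that
keep strand and base quality per supporting read, which the downstream noise
estimation and quality filters need.

Coordinate conventions: pileup and VCF are 1-based inclusive; BED is 0-based
half-open and is converted at this boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomicRegion",
    "AlleleObservation",
    "PileupColumn",
    "RegionProfile",
    "PileupParseError",
    "BedParseError",
    "parse_pileup",
    "parse_bed",
    "write_pileup",
    "write_vcf",
]

_VALID_REF = set("ACGTN")
_SUB_CODES = set("ACGTacgt")


class PileupParseError(ValueError):
    """Raised on malformed pileup input; message names the offending line."""


class BedParseError(ValueError):
    """Raised on malformed BED input."""


@dataclass(frozen=True)
class GenomicRegion:
    """A 1-based inclusive genomic interval analysed as one unit (e.g. an exon)."""

    chrom: str
    start: int
    end: int
    label: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"region start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"region end ({self.end}) must be >= start ({self.start})"
            )

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        name = f" ({self.label})" if self.label else ""
        return f"{self.chrom}:{self.start}-{self.end}{name}"


@dataclass
class AlleleObservation:
    """All reads supporting one alternative allele at one position.

    ``allele`` is one of ``A/C/G/T`` for substitutions, ``+SEQ`` for an
    insertion after the position, or ``-SEQ`` for a deletion of the following
    bases.  Per-read Phred qualities are kept split by strand; for indels the
    quality is the anchor base's quality (the pileup format carries no
    indel-specific quality).
    """

    allele: str
    quals_fwd: list[int] = field(default_factory=list)
    quals_rev: list[int] = field(default_factory=list)

    @property
    def fwd_count(self) -> int:
        return len(self.quals_fwd)

    @property
    def rev_count(self) -> int:
        return len(self.quals_rev)

    @property
    def count(self) -> int:
        return self.fwd_count + self.rev_count

    @property
    def qualities(self) -> list[int]:
        return self.quals_fwd + self.quals_rev

    @property
    def is_indel(self) -> bool:
        return self.allele[:1] in "+-"


@dataclass
class PileupColumn:
    """Decoded observations at one genomic position."""

    chrom: str
    pos: int
    ref_base: str
    depth: int
    ref_quals_fwd: list[int] = field(default_factory=list)
    ref_quals_rev: list[int] = field(default_factory=list)
    star_quals: list[int] = field(default_factory=list)
    alts: dict[str, AlleleObservation] = field(default_factory=dict)

    @property
    def ref_count(self) -> int:
        return len(self.ref_quals_fwd) + len(self.ref_quals_rev)

    @property
    def alt_count(self) -> int:
        return sum(o.count for o in self.alts.values())

    @property
    def all_base_quals(self) -> list[int]:
        quals = self.ref_quals_fwd + self.ref_quals_rev + list(self.star_quals)
        for obs in self.alts.values():
            quals.extend(obs.qualities)
        return quals


class RegionProfile:
    """Ordered pileup columns for one region plus cached per-position vectors.

    ``alt_counts[i]`` is the total alternative-read count at ``columns[i]``
    (all alternative alleles pooled, indels included) — the per-position value
    fed to the background-noise estimator.
    """

    def __init__(self, region: GenomicRegion, columns: Sequence[PileupColumn]):
        self.region = region
        self.columns = list(columns)
        last = None
        for col in self.columns:
            if col.chrom != region.chrom:
                raise ValueError(
                    f"column {col.chrom}:{col.pos} outside region chrom {region.chrom}"
                )
            if not (region.start <= col.pos <= region.end):
                raise ValueError(
                    f"column position {col.pos} outside region {region}"
                )
            if last is not None and col.pos <= last:
                raise ValueError(
                    f"positions must be strictly increasing ({col.pos} after {last})"
                )
            last = col.pos
        self._index: dict[int, int] = {c.pos: i for i, c in enumerate(self.columns)}
        self.positions = np.array([c.pos for c in self.columns], dtype=np.int64)
        self.depths = np.array([c.depth for c in self.columns], dtype=np.int64)
        self.alt_counts = np.array(
            [c.alt_count for c in self.columns], dtype=np.int64
        )

    def __len__(self) -> int:
        return len(self.columns)

    def index_of(self, pos: int) -> int | None:
        return self._index.get(pos)

    def column_at(self, pos: int) -> PileupColumn | None:
        i = self._index.get(pos)
        return None if i is None else self.columns[i]


# ---------------------------------------------------------------------------
# pileup parsing


def _decode_events(bases: str, quals: str, lineno: int):
    """Decode an mpileup base string into (kind, allele, is_fwd, qual) events.

    kind is one of 'ref', 'sub', 'indel', 'star'.  Read-start (``^`` + mapping
    quality) and read-end (``$``) markers carry no observation and are skipped.
    An indel code (``+N<seq>`` / ``-N<seq>``) reclassifies the read event it is
    attached to: the read supports the indel allele and the anchor base's
    quality stands in for the indel quality.
    """
    events: list[tuple[str, str | None, bool, int]] = []
    i, qi, n = 0, 0, len(bases)

    def next_qual() -> int:
        nonlocal qi
        if qi >= len(quals):
            raise PileupParseError(
                f"line {lineno}: quality string shorter than decoded base events"
            )
        q = ord(quals[qi]) - 33
        qi += 1
        if q < 0:
            raise PileupParseError(f"line {lineno}: invalid quality character")
        return q

    while i < n:
        c = bases[i]
        if c == "^":
            if i + 1 >= n:
                raise PileupParseError(f"line {lineno}: dangling '^' marker")
            i += 2  # skip the mapping-quality character
            continue
        if c == "$":
            i += 1
            continue
        if c in ".," or c in _SUB_CODES or c in "*#" or c in "Nn":
            is_fwd = c == "." or c == "*" or c.isupper()
            q = next_qual()
            i += 1
            if i < n and bases[i] in "+-":
                sign = bases[i]
                i += 1
                j = i
                while j < n and bases[j].isdigit():
                    j += 1
                if j == i:
                    raise PileupParseError(
                        f"line {lineno}: indel code without length"
                    )
                length = int(bases[i:j])
                seq = bases[j : j + length]
                if len(seq) < length or not set(seq) <= set("ACGTNacgtn"):
                    raise PileupParseError(
                        f"line {lineno}: malformed indel sequence {seq!r}"
                    )
                i = j + length
                fwd = seq.isupper() if seq else is_fwd
                events.append(("indel", sign + seq.upper(), fwd, q))
            elif c in ".,":
                events.append(("ref", None, c == ".", q))
            elif c in "*#":
                events.append(("star", None, True, q))
            elif c in "Nn":
                # ambiguous call: occupies depth but supports no allele
                events.append(("star", None, c == "N", q))
            else:
                events.append(("sub", c.upper(), c.isupper(), q))
        else:
            raise PileupParseError(f"line {lineno}: unknown base code {c!r}")
    if qi != len(quals):
        raise PileupParseError(
            f"line {lineno}: base/quality length mismatch "
            f"({qi} events vs {len(quals)} qualities)"
        )
    return events


def _column_from_line(cols: list[str], lineno: int) -> PileupColumn:
    chrom, pos_s, ref, depth_s = cols[0], cols[1], cols[2], cols[3]
    try:
        pos = int(pos_s)
        depth = int(depth_s)
    except ValueError:
        raise PileupParseError(
            f"line {lineno}: non-integer position or depth"
        ) from None
    ref_base = ref.upper()
    if len(ref_base) != 1 or ref_base not in _VALID_REF:
        raise PileupParseError(f"line {lineno}: invalid reference base {ref!r}")
    col = PileupColumn(chrom=chrom, pos=pos, ref_base=ref_base, depth=depth)
    if depth == 0:
        return col
    if len(cols) < 6:
        raise PileupParseError(
            f"line {lineno}: expected 6 columns, got {len(cols)}"
        )
    events = _decode_events(cols[4], cols[5], lineno)
    if len(events) != depth:
        raise PileupParseError(
            f"line {lineno}: declared depth {depth} but decoded "
            f"{len(events)} read observations"
        )
    for kind, allele, is_fwd, q in events:
        if kind == "ref":
            (col.ref_quals_fwd if is_fwd else col.ref_quals_rev).append(q)
        elif kind == "star":
            col.star_quals.append(q)
        else:
            if kind == "sub" and allele == col.ref_base:
                # explicit base identical to the reference: count as reference
                (col.ref_quals_fwd if is_fwd else col.ref_quals_rev).append(q)
                continue
            obs = col.alts.setdefault(allele, AlleleObservation(allele))
            (obs.quals_fwd if is_fwd else obs.quals_rev).append(q)
    return col


def parse_pileup(
    stream: Iterable[str],
    regions: Sequence[GenomicRegion] | None = None,
) -> list[RegionProfile]:
    """Parse mpileup text into one :class:`RegionProfile` per region.

    With ``regions`` given, each line is assigned to the first region covering
    its position and lines outside every region are dropped; every requested
    region yields a profile (possibly empty).  Without ``regions``, each
    chromosome becomes one region spanning its observed positions.
    """
    if regions is not None:
        buckets: list[list[PileupColumn]] = [[] for _ in regions]
    else:
        by_chrom: dict[str, list[PileupColumn]] = {}

    for lineno, raw in enumerate(stream, 1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        cols = line.split()
        if len(cols) < 4:
            raise PileupParseError(
                f"line {lineno}: expected 6 columns, got {len(cols)}"
            )
        col = _column_from_line(cols, lineno)
        if regions is not None:
            for i, region in enumerate(regions):
                if region.contains(col.chrom, col.pos):
                    buckets[i].append(col)
                    break
        else:
            by_chrom.setdefault(col.chrom, []).append(col)

    if regions is not None:
        return [RegionProfile(r, cols) for r, cols in zip(regions, buckets)]
    profiles = []
    for chrom, cols in by_chrom.items():
        region = GenomicRegion(chrom, cols[0].pos, cols[-1].pos, label=chrom)
        profiles.append(RegionProfile(region, cols))
    return profiles


# ---------------------------------------------------------------------------
# BED parsing


def parse_bed(stream: Iterable[str]) -> list[GenomicRegion]:
    """Parse BED3+ (0-based half-open) into 1-based inclusive regions."""
    regions = []
    for lineno, raw in enumerate(stream, 1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split()
        if len(cols) < 3:
            raise BedParseError(f"line {lineno}: BED needs at least 3 columns")
        try:
            start0, end0 = int(cols[1]), int(cols[2])
        except ValueError:
            raise BedParseError(
                f"line {lineno}: non-integer BED coordinates"
            ) from None
        if end0 <= start0:
            raise BedParseError(
                f"line {lineno}: empty or inverted interval "
                f"[{start0}, {end0})"
            )
        label = cols[3] if len(cols) > 3 else None
        regions.append(GenomicRegion(cols[0], start0 + 1, end0, label=label))
    return regions


# ---------------------------------------------------------------------------
# pileup writing (round-trip of simulated profiles, debugging aid)


def _qual_char(q: int) -> str:
    return chr(min(int(q), 93) + 33)


def write_pileup(profiles: Sequence[RegionProfile]) -> str:
    """Serialize profiles back to six-column mpileup text.

    Emission order within a column is fixed (reference forward, reference
    reverse, alternative alleles sorted by allele string with forward before
    reverse, deleted-base placeholders last) so output is deterministic.
    """
    lines = []
    for profile in profiles:
        for col in profile.columns:
            entries: list[tuple[str, int]] = []
            entries += [(".", q) for q in col.ref_quals_fwd]
            entries += [(",", q) for q in col.ref_quals_rev]
            for allele in sorted(col.alts):
                obs = col.alts[allele]
                if obs.is_indel:
                    sign, seq = allele[0], allele[1:]
                    code_f = f".{sign}{len(seq)}{seq}"
                    code_r = f",{sign}{len(seq)}{seq.lower()}"
                else:
                    code_f, code_r = allele, allele.lower()
                entries += [(code_f, q) for q in obs.quals_fwd]
                entries += [(code_r, q) for q in obs.quals_rev]
            entries += [("*", q) for q in col.star_quals]
            depth = len(entries)
            bases = "".join(e[0] for e in entries) or "*"
            quals = "".join(_qual_char(e[1]) for e in entries) or "*"
            lines.append(
                f"{col.chrom}\t{col.pos}\t{col.ref_base}\t{depth}\t{bases}\t{quals}"
            )
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# VCF output

_FILTER_DESCRIPTIONS = {
    "low_ratio_vs_noise": "Allele fraction not greater than noise_multiplier x local noise rate",
    "low_mean_qual": "Mean Phred quality of supporting bases not greater than min_mean_phred",
    "high_qual_sd": "Phred quality standard deviation not below max_phred_sd",
    "strand_imbalance": "Forward-strand fraction outside [strand_balance_low, strand_balance_high]",
    "below_reporting_cutoff": "Allele fraction below the optional reporting cutoff",
}


def _vcf_alleles(ref_base: str, alt: str) -> tuple[str, str]:
    """Left-anchored VCF REF/ALT for a substitution or pileup-style indel."""
    if alt.startswith("+"):
        return ref_base, ref_base + alt[1:]
    if alt.startswith("-"):
        return ref_base + alt[1:], ref_base
    return ref_base, alt


def write_vcf(
    calls: Sequence,
    sample_name: str = "SAMPLE",
    params: dict | None = None,
    pass_only: bool = False,
) -> str:
    """Render variant calls as VCF 4.2 text.

    Calls must be sorted by (chrom, pos); the effective parameter set is
    echoed in ``##taucall_param`` header lines so a VCF documents the run that
    produced it.
    """
    keys = [(c.chrom, c.pos) for c in calls]
    if keys != sorted(keys):
        raise ValueError("calls must be sorted by (chrom, pos)")

    from . import __version__

    header = [
        "##fileformat=VCFv4.2",
        f"##source=taucall {__version__}",
    ]
    for key, value in sorted((params or {}).items()):
        header.append(f"##taucall_param=<{key}={value}>")
    header += [
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth at the position">',
        '##INFO=<ID=AO,Number=1,Type=Integer,Description="Reads supporting the alternative allele">',
        '##INFO=<ID=AF,Number=1,Type=Float,Description="Alternative allele fraction (AO/DP)">',
        '##INFO=<ID=SAF,Number=1,Type=Integer,Description="Alternative reads on the forward strand">',
        '##INFO=<ID=SAR,Number=1,Type=Integer,Description="Alternative reads on the reverse strand">',
        '##INFO=<ID=QMEAN,Number=1,Type=Float,Description="Mean Phred quality of supporting bases">',
        '##INFO=<ID=QSD,Number=1,Type=Float,Description="Standard deviation of supporting base qualities">',
        '##INFO=<ID=NC,Number=1,Type=Integer,Description="Local background-noise read count">',
        '##INFO=<ID=NR,Number=1,Type=Float,Description="Local background-noise rate (NC / mean window depth)">',
    ]
    for tag, desc in _FILTER_DESCRIPTIONS.items():
        header.append(f'##FILTER=<ID={tag},Description="{desc}">')
    header += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype (tumor-only placeholder)">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AO,Number=1,Type=Integer,Description="Alternative read count">',
        '##FORMAT=<ID=AF,Number=1,Type=Float,Description="Alternative allele fraction">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_name,
    ]
    body = []
    for call in calls:
        status = call.filter_status
        if pass_only and status != "PASS":
            continue
        ref, alt = _vcf_alleles(call.ref, call.alt)
        info = (
            f"DP={call.depth};AO={call.alt_count};AF={call.vaf:.6g};"
            f"SAF={call.fwd_count};SAR={call.rev_count};"
            f"QMEAN={call.mean_qual:.2f};QSD={call.sd_qual:.2f};"
            f"NC={call.noise.noise_count};NR={call.noise.noise_rate:.6g}"
        )
        body.append(
            f"{call.chrom}\t{call.pos}\t.\t{ref}\t{alt}\t.\t{status}\t{info}\t"
            f"GT:DP:AO:AF\t0/1:{call.depth}:{call.alt_count}:{call.vaf:.6g}"
        )
    return "\n".join(header + body) + "\n"
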