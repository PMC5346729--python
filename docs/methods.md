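# Methods

## Model and procedure

`taucall` treats variant detection in a tumor-only sample as an outlier
problem on local error counts. The unit of analysis is a target region (an
exon-sized interval from a BED file). For every position the parser records
the read depth and, per alternative allele, the supporting reads split by
strand with their Phred base qualities; the per-position *total*
alternative-read count (all alleles pooled, indels included) is the noise
observable.

For a candidate (position, allele) the noise sample is the set of nonzero
alternative-read counts at the positions of a `window_bp` window centred on
the candidate, clipped at region boundaries. Zeros are removed first: an
error-free position says nothing about the magnitude of the error process,
and keeping zeros would deflate the mean and standard deviation and make the
trimming rule reject ordinary error counts. The sample is then trimmed by
iterating the modified Thompson Tau test — single most-deviant point per
iteration, rejected when its absolute deviation exceeds `τ·S` — and the
maximum of the surviving values is the local noise count `N`; the noise rate
is `r = N / d̄` with `d̄` the mean depth over the window. The candidate is
promoted iff its supporting-read count strictly exceeds `N`, then passes
four quality filters (allele fraction > `noise_multiplier · r`; mean Phred
strictly > `min_mean_phred`; Phred SD strictly < `max_phred_sd`;
forward-strand fraction inside the inclusive
`[strand_balance_low, strand_balance_high]` band).

### Assumptions

* Errors are locally stationary: positions within ~100 bp of the candidate
  experience a similar error process, so their alternative-read counts are
  exchangeable draws from it.
* True variants are rare within a window, so after trimming the sample
  describes errors only. A window dense with true variants would inflate the
  noise estimate and cost sensitivity (conservative failure mode).
* One sample, one pileup: no matched normal is used anywhere.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `alpha` | 0.001 | two-tailed risk | strict rejection keeps genuine error counts in the sample; only strong outliers (real variants) are trimmed |
| `window_bp` | 200 | bp (total span, ±100) | large enough for a stable sample at typical error rates, small enough to stay local |
| `noise_multiplier` | 2 | — | the allele fraction must clearly beat the noise rate, not just the noise count |
| `min_mean_phred` | 20 | Phred | strictly greater than; mean of supporting bases |
| `max_phred_sd` | 7 | Phred | strictly below; a high spread marks heterogeneous, artifact-prone support |
| `strand_balance_low/high` | 0.30 / 0.70 | fraction | inclusive band on the forward-strand share of supporting reads |
| `vaf_min_snv` / `vaf_min_indel` | off | fraction | optional reporting cutoffs (e.g. 1% / 2%) used when comparing call sets at a fixed detection limit; they tag calls rather than drop them |
| `include_candidate_in_noise` | false | — | see below |

Degrees of freedom for the t critical value are `n − 2`; the test therefore
needs `n ≥ 3`. When zero-stripping leaves fewer than 3 values the test is
skipped and the noise count is the sample maximum (0 for an empty sample) —
a conservative fallback. `S` is the sample standard deviation (n−1
denominator), the standard convention for this test. Ties at the maximal
deviation are tested and removed as one group, which makes the trimming
deterministic and invariant under permutation of the input.

### Candidate exclusion from its own noise sample

The noise sample characterises the candidate's *surroundings*; a strong true
variant included in its own sample would inflate the noise estimate before
trimming has a chance to remove it. By default the candidate allele's count
is subtracted from the centre position's contribution (other alleles at the
same position still count as noise). The original behaviour of pooling
everything is available via `include_candidate_in_noise`. For
limit-of-detection and position reports, where no specific candidate allele
exists, the centre position's whole alternative count is excluded.

### Limit of detection

The per-position LOD is the direct inversion of the calling criteria that
depend on counts rather than qualities: a variant is callable iff
`AO > N` and `AO/DP > noise_multiplier · r`, so the smallest callable
fraction is `max(noise_multiplier · r, (N+1)/DP)`. Per region the report
gives the mean and the maximum (worst case) over covered positions;
positions with zero depth report LOD 1 (nothing is detectable).

## Pileup dialect and numerical conventions

* Input is single-sample `samtools mpileup` six-column text with Phred+33
  base qualities; a seventh (mapping-quality) column is ignored. The parser
  is not given a quality floor: if reads below some base quality should be
  excluded, apply it upstream (`samtools mpileup -Q`).
* An indel code (`+N<seq>` / `-N<seq>`) reclassifies the read it is attached
  to: the read supports the indel allele, and the anchor base's quality
  stands in for the indel (the format carries no per-indel quality). This
  also keeps depth conserved: reference + alternative + deleted-base
  placeholders (`*`) equals the declared depth on every line.
* At reference-`N` positions every called base counts as alternative.
  Ambiguous `N` base calls occupy depth but support no allele.
* BED input is 0-based half-open and converted to 1-based inclusive at the
  parsing boundary; pileup and VCF are 1-based. VCF indels are left-anchored
  on the preceding reference base.
* The Phred SD in filter (iii) is the population standard deviation, which
  gives the stipulated SD of 0 for a single supporting read without a
  special case. A single read still ordinarily fails the strand-balance
  filter (fraction 0 or 1) — users probing singletons should widen the band.
* Multi-allelic positions yield one candidate (and up to one VCF record) per
  alternative allele, judged independently.

## The simulator

The generator emulates targeted capture/amplicon sequencing at the pileup
level, which is exactly the caller's input granularity:

* depth per position fixed or Poisson around the target mean (default
  1000×);
* substitution errors independent per read and position at `error_rate`
  (default 0.1%, a realistic post-alignment mismatch rate for Illumina
  data), spread uniformly over the non-reference bases with uniformly random
  strands;
* injected variants with binomially drawn supporting-read counts at their
  target VAF; their forward-strand share is applied deterministically by
  rounding, and their qualities follow the true-base model unless
  overridden. The deterministic strand split is a deliberate design choice:
  truth-driven evaluations are meant to probe the noise statistics, and a
  Bernoulli strand draw would dominate the outcome at small supporting-read
  counts (a 5% variant at 225× has ~11 reads, for which a random split
  leaves the 30–70% band roughly a quarter of the time);
* base qualities from clipped normal distributions — true bases
  Phred ~ N(35, 3), error bases ~ N(25, 6), clipped to [2, 41] — so the
  quality filters are exercised but do not decide calls by themselves.

What it does **not** emulate: FFPE deamination artifacts, PCR duplicate
structure, mapping-induced recurrent errors, strand-biased error processes,
indel slippage errors, or correlated errors along reads. Passing tests on
simulated data therefore demonstrate the statistical behaviour of the
method, not robustness to alignment artifacts; on real data the recurrent
mapping artifact is the main residual false-positive source and shows up as
a locally elevated noise estimate.

In-silico downsampling thins every read independently with probability
`fraction`, preserving strand and quality — the pileup-level analogue of
subsampling a BAM — and preserves allele fractions in expectation.

## Problem sizes used in validation

The bundled validation runs at desk scale, chosen to finish in minutes on
one CPU while keeping Monte-Carlo error small: the τ statistic is checked
against an independent quantile oracle over n ∈ [3, 200] at three risk
levels; trimming against a literal reimplementation on 1000 random samples;
calling on simulated regions of 2,000–10,000 positions at 1000×; and the
coverage grid over five depth bins × three VAFs × 100 replicates
(binomial SE ≤ 0.05 per cell). Sensitivity claims at a given depth bin are
measured at a single representative depth per bin (100, 225, 450, 800,
1500×).

## Known limitations

* The noise model pools all alternative alleles per position; an
  allele-specific noise model (e.g. per substitution class) could sharpen
  specificity for transition-heavy artifact processes.
* The strand-balance filter, as specified, always fails single-read
  candidates.
* Windows at region edges are clipped, not padded, so edge positions use
  down to half a window of evidence.
* LOD inverts only the count-based criteria; a variant just above LOD can
  still fail the quality or strand filters if its reads are poor.
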