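# taucall

Tumor-only variant calling of low allele-fraction mutations from targeted
sequencing, without a matched normal sample.

## The problem

Tumor samples are heterogeneous: a clinically decisive mutation may be
carried by a small cell subpopulation, or diluted by healthy tissue, so its
variant allele fraction (VAF) in the sequencing data can be a few percent or
less — the same order as the background of PCR and sequencer errors. Callers
designed for germline genotyping miss such variants; somatic callers that
recover them usually want a matched normal sample, which diagnostic
laboratories often cannot obtain. `taucall` adjudicates candidates the way a
biologist inspects an alignment: by comparing each one to the *locally
estimated* error level of the surrounding sequence.

## The method

For each genomic position of a target region the number of alternative-base
reads is recorded. In a window of `w` bp (default 200) centred on a candidate
position, the nonzero per-position alternative-read counts `x_1..x_n` form a
sample of the local error process. Suspected outliers — which is what real
variants are — are trimmed iteratively with the modified Thompson Tau test:
with sample mean x̄ and standard deviation `S`, the point with maximal
deviation `δ_i = |x_i − x̄|` is rejected when `δ_i > τ·S`, where

    τ = t_{α/2, n−2} · (n − 1) / ( √n · √(n − 2 + t²_{α/2, n−2}) )

and `t_{α/2, n−2}` is the Student-t critical value at two-tailed risk `α`
(default 0.001). The maximum of the surviving sample is the **local noise
count** `N`; divided by the mean window depth it gives the **noise rate**
`r = N / d̄`.

A candidate with `AO` supporting reads is called when `AO > N`
(*statistical step*), then filtered on: (i) `AO/DP > 2·r`, (ii) mean Phred of
supporting bases > 20, (iii) Phred SD < 7, (iv) forward-strand fraction
within [30%, 70%]. All thresholds are configurable; failing candidates are
written to the VCF with FILTER tags (`--pass-only` suppresses them).

Two companion modes reuse the noise machinery:

* **LOD report** — the minimum detectable allele fraction per BED region or
  position, `max(2·r, (N+1)/DP)`: the smallest VAF that would have cleared
  both the statistical step and filter (i).
* **Position query** — depth, reference/alternative allele, strand counts,
  mean quality and local noise at one position.

A bundled simulator generates pileups with known truth (configurable depth,
error rate, injected variants) plus read-level downsampling, so sensitivity
against coverage can be benchmarked without external data.

## Worked example

```python
import taucall as tc

cfg = tc.SimulationConfig(
    regions=[tc.GenomicRegion("chr17", 41_200_001, 41_200_300, label="exon")],
    depth=1000, error_rate=0.001,
    variants=[tc.InjectedVariant("chr17", 41_200_080, "T", vaf=0.03)],
    seed=11,
)
profiles, truth = tc.simulate_profiles(cfg)
for c in tc.call_variants(profiles):
    print(c.chrom, c.pos, f"{c.ref}>{c.alt}", c.alt_count, c.noise.noise_count,
          round(c.vaf, 3), c.filter_status)
```

prints

```
chr17 41200080 A>T 26 3 0.026 PASS
```

— the injected 3% SNV was sequenced by 26 of 1000 reads; the window's
trimmed noise count is 3 reads (noise rate 0.003), so 26 > 3 clears the
statistical step and 0.026 > 2×0.003 clears the ratio filter: a PASS call.
More narrative walk-throughs are in `examples/` (calling, LOD + query,
coverage-vs-sensitivity with downsampling).

The same pipeline from a shell, starting from a BAM:

```
samtools mpileup -B -d 100000 -l targets.bed sample.bam > sample.pileup
taucall call --pileup sample.pileup --bed targets.bed --out sample.vcf
taucall lod  --pileup sample.pileup --bed targets.bed --out sample.lod.tsv
taucall query --pileup sample.pileup --position chr12:25398300
```

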