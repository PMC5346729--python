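"""Coverage-vs-sensitivity benchmark and in-silico downsampling.

Sensitivity to a variant of given allele fraction depends strongly on depth:
each grid cell simulates replicates with one injected variant and scores the
fraction recovered as PASS calls.  Downsampling thins an existing profile
read-by-read to emulate lower coverage from the same library.

Uses 25 replicates per cell to stay quick; increase for smoother estimates.
"""

import taucall as tc

table = tc.sensitivity_harness(
    vafs=(0.01, 0.02, 0.05), replicates=25, seed=0
)
print("sensitivity (fraction of injected variants recovered as PASS):")
print(table.pivot(index="vaf", columns="depth_bin", values="sensitivity"))
print(
    "\nReading the table: a 5% variant is reliably found from ~150-300x up,\n"
    "while a 1-2% variant needs coverage around 1000x or more.\n"
)

cfg = tc.SimulationConfig(
    regions=[tc.GenomicRegion("chr1", 1, 201)],
    depth=1000,
    error_rate=0.001,
    variants=[tc.InjectedVariant("chr1", 101, "T", vaf=0.02)],
    seed=8,
)
(profile,), truth = tc.simulate_profiles(cfg)
print("downsampling the same 2% variant library:")
for fraction in (1.0, 0.5, 0.25, 0.1):
    thinned = tc.downsample_pileup(profile, fraction, seed=3)
    calls = [c for c in tc.call_variants([thinned]) if c.is_pass and c.pos == 101]
    depth = thinned.column_at(101).depth
    status = "PASS" if calls else "missed"
    print(f"  fraction={fraction:<5} depth={depth:<5} -> {status}")
print(
    "\nThe call survives moderate thinning but is lost at a tenth of the\n"
    "original depth, mirroring the benchmark table."
)
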