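"""Filter reads and cluster them into candidate insertion loci.

Consumes the cohort written by 01_simulate_cohort.py: ME reads are
thresholded at the family bit-score cutoff, flanking reads reduced to
their best mapping and MQ-filtered, and the surviving junction
positions clustered in 500-bp windows into loci with per-sample
read count / TPM / UR evidence.
"""

from mescan import MEFamily
from mescan.formats_io import read_manifest
from mescan.pipeline import call_cohort

manifest = read_manifest("example_output/sim/manifest.tsv")
family = MEFamily(name="L1HS", bit_cutoff=56.0)

from pathlib import Path

loci, libraries, results = call_cohort(
    manifest, family, window=500, min_mq=30,
    base_dir=Path("example_output/sim"),
)

print(f"called {len(loci)} candidate loci from {len(libraries)} samples")
for result in results[:2]:
    c = result.stage_counts
    print(
        f"  {result.sample_id}: {c['me_reads_scored']} ME reads -> "
        f"{c['me_reads_pass']} pass bit score; {c['flank_mapped_reads']} "
        f"flanks -> {c['flank_mq_pass']} pass MQ; {c['joined']} joined pairs"
    )
print("first three loci (position = most ME-proximal junction):")
for locus in loci[:3]:
    ev = {s: (e.read_count, round(e.tpm, 1), e.ur)
          for s, e in sorted(locus.per_sample.items())}
    print(f"  {locus.locus_id} {locus.chrom}:{locus.position}({locus.strand})"
          f" evidence(count, TPM, UR) = {ev}")
# TPM normalizes counts by library depth; UR collapses PCR duplicates
# by counting distinct alignment start positions.
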