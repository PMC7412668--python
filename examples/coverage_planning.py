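"""How many reads will fully overlap a region, given library parameters?

A read only contributes to a region if it covers all of the region's
context sites, so longer regions see fewer usable reads:
expected reads = coverage * (1 - region_size / read_length).
"""

from srmeth import expected_reads

print("coverage  region_bp  read_bp  expected_full_overlap_reads")
for coverage in (5, 10, 20):
    for region_size in (30, 50, 100):
        value = expected_reads(coverage, region_size, read_length=100)
        print(f"{coverage:8d}  {region_size:9d}  {100:7d}  {value:10.1f}")

# At 10x coverage and 100 bp reads, a 30 bp region keeps an expected 7
# fully-overlapping reads; stretching the region to the read length
# leaves none, which is why small fixed-site-count regions are used.
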