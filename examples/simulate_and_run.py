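"""Generate a synthetic two-regime methylome and run the full pipeline.

Builds a 100 kb genome with 25 TEs, half methylated CMT2-like (per-site
Bernoulli noise) and half DRM2-like (a fully-methylated / background read
mixture), simulates directional bisulfite reads at 10x per strand, and
runs region building, vector extraction and feature aggregation.
"""

from srmeth import analyze, simulate_dataset

dataset = simulate_dataset(seed=1)
result = analyze(
    {dataset.genome.name: dataset.genome}, dataset.elements, dataset.reads
)

print(f"genome: {len(dataset.genome.bases)} bp, {len(dataset.elements)} TEs")
print(f"reads simulated: {len(dataset.reads)}")
for key, value in sorted(result.counts.items()):
    print(f"  {key}: {value}")

f = result.passing_features()[0]
print(
    f"example region {f.region_id}: {f.n_reads} reads, "
    f"meth {f.mean_read_meth:.2f}, read-SD {f.sd_read_meth:.2f}, "
    f"stochasticity {f.mean_stochasticity:.2f}, site-SD {f.sd_site_meth:.2f}"
)

# regions_passing_filters counts regions with >= 4 reads and >= 10%
# methylation; those are the ones elements aggregate and the classifier
# consumes.
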