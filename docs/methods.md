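# Methods

## Region definition

Functional elements are read from GFF3 (converted to 0-based half-open
coordinates at the boundary) and scanned for context sites on the
reference sequence, per strand — CHH is asymmetric, so a plus-strand site
has no minus-strand partner. A site is a cytosine whose 5'→3'
trinucleotide on its own strand classifies as CG (CxG at position 2), CHG
(G at position 3 only), or CHH (no G at positions 2–3); CHH splits into
CWA (CAA/CTA) and non-CWA. `CH` (= CHG ∪ CHH) is available for
mammalian-style non-CG analyses. Trinucleotides that would run past a
sequence end or contain an N are skipped (context unknowable). Unstranded
annotations — the normal case for TEs — are scanned on both strands;
stranded annotations only on their own.

Regions are built by a greedy left-to-right scan over each strand's site
list: a window of consecutive sites grows by one site at a time, drops its
leftmost site while the C-to-C span (last − first + 1) exceeds `max_span`,
and emits a region the moment it holds exactly `n_sites` sites; the scan
then restarts after the emitted sites, so regions never overlap or share
sites. Because candidate windows are runs of consecutive sites, emitting
the earliest feasible window is the earliest-deadline interval rule and
provably maximises region count (the test suite checks this against
brute-force enumeration). Span is measured C-to-C rather than including
the trailing two context bases; the two readings differ only in boundary
cases and C-to-C is the minimal consistent one.

Defaults: 5 CHH sites in ≤ 30 bp (the working point that balances region
capture against the requirement that a read plus slack covers the whole
region); 50 bp for CWA-only analyses (CWA sites are 4–5× sparser); 100 bp
for the 5/10/15-site read-pattern summaries.

## Read vectors

Input is SAM with ungapped end-to-end alignments; unmapped, secondary and
gapped/clipped records are dropped (counted), and exact duplicates —
identical (chrom, pos, orientation, sequence) — are collapsed. The
bisulfite strand of a directional library is taken from FLAG bit 16
(forward = original-top) unless a Bismark-style `XG` tag overrides it.

A read yields a vector for a region only if it covers **all** the region's
sites on the matching strand. Plus-strand sites read C→1/T→0; minus-strand
sites read G→1/A→0 on the reference-forward sequence. Any other base at a
site makes the read uninformative for that region and the whole read is
discarded there — features require complete vectors, and with no-mismatch
alignments this is rare. Paired mates are treated as independent reads.

## Features and aggregation

All SDs are population (uncorrected) SDs, keeping minimum-coverage regions
well defined. For a complete read × site matrix, mean read methylation
equals mean per-site methylation (exchange of summation), so the
methylation filter is unambiguous. Regions enter element aggregation with
≥ 4 reads and ≥ 10% mean methylation; elements need ≥ 2 surviving regions
and average their regions' features unweighted (low- and high-coverage
regions count equally; weighting would re-introduce the coverage bias the
region filter removes). Hypermethylation between samples means a strictly
> 10% methylation increase on matched region ids.

## Stochastic null

The null for a region is independent per-site, per-read Bernoulli(p) with
p equal to the region's mean methylation. Closed forms: stochasticity
2p(1−p) (each adjacent pair disagrees independently at that rate) and
asymptotic read-methylation SD √(p(1−p)/n). Matched simulations reuse each
observed region's read count so finite-sample SD inflation is shared
between observed and null features, and are computed through the same
feature code path. Replicate count per region is configurable (default 1).

## Classifier

The classifier is an ordinary least-squares fit of a 0/1 label (0 =
DRM2-like reference set, 1 = CMT2-like) on the four region features, i.e.
a linear probability model, not logistic regression. Constant features are
dropped with a warning (singular design). The raw predictor is mapped to
the 0–1 pattern score by an affine min/max rescaling over the training
data — the simplest map that pins training scores to exactly [0, 1] — and
unseen scores outside the range are clipped. The scaling bounds are stored
in the plain-text model file, making scoring reproducible. Marginal r² of
each feature against the label is recorded per fit. The feature list is
configurable and defaults to all four features.

ROC curves use the standard threshold sweep with trapezoidal AUC (verified
in tests against Mann-Whitney pair counting). Genome-level peak counting
evaluates a Gaussian KDE (Scott's bandwidth, σ̂·n^(−1/5)) on a 512-point
grid over [0, 1] and calls peaks at local maxima with prominence above 5%
of the global maximum; the density is padded below its minimum before peak
finding so a boundary maximum (clipped scores piling at 0 or 1) still
counts. Grid size and prominence are configurable; fewer than 10 values is
an error, and a zero-variance sample degenerates to one peak by
convention.

## Synthetic data

The generator emulates a compact TE methylome: a single random chromosome
(default 100 kb at GC 0.36, Arabidopsis-like) with 25 evenly spaced,
unstranded 2 kb TEs covering half the sequence, flanked by gaps larger
than a read so no region suffers edge effects. Each TE draws one regime:

* `cmt2_like` — per-site Bernoulli p = 0.3, plus `cwa_boost` = 0.2 at CWA
  sites (the CAA/CTA preference);
* `drm2_like` — read mixture with `f_full` = 0.3 fully methylated reads
  and background p_bg = 0.05, overall mean 0.335 by the mixture identity.

Effect sizes were chosen once as a realistic qualitative separation —
near-matched means, strongly different variation structure — and are
configuration-exposed, not tuned. Reads are single-end 100 bp, uniformly
placed, half on each bisulfite strand; `coverage` (default 10) is the
**per-bisulfite-strand** depth, so the expected number of same-strand reads
fully covering a region of span s is the planning formula
coverage·(1 − s/read_length) directly. Cytosines outside regions are
emitted unmethylated, isolating signal in defined regions. The truth
tables carry, per region, the regime, the analytic mean read methylation
and per-read methylation variance (for exact-SE recovery checks), and per
(read, region) pair the drawn state vector.

What the generator does **not** emulate: sequencing errors and quality
scores, PCR duplicates, paired-end mates, non-uniform (mappability- or
GC-biased) coverage, partial-element methylation mosaics, and background
methylation outside regions. Passing tests therefore demonstrate
correctness of the measurement and classification machinery under the
stated generative regimes, not robustness to real-library artefacts.

## Numerical choices and problem sizes

Seeds are threaded through `numpy.random.SeedSequence` spawning, so every
simulation is reproducible and independent per component. The default
test/acceptance problem sizes — 100 kb genome (~1,700 regions, 20,000
reads), 10⁴-read null simulations, 2,000 regions per class for classifier
recovery — run the full suite in well under a minute while leaving
estimator noise far below the tested tolerances. Exact duplicate removal
on dense synthetic coverage removes a few percent of genuinely identical
reads (most likely in low-entropy DRM2 background); recovery checks use
analytic SEs large enough that this bias (≲0.01 in mean methylation) is
immaterial, and the coverage-formula check counts pre-deduplication reads
since the formula is a sequencing-depth planning identity, not a
post-filter property.

## Known limitations

* The bisulfite strand is inferred from the FLAG (or `XG` tag); libraries
  that are not directional will mis-assign strands.
* BAM input is not read directly; convert to SAM (`samtools view`) first.
* The classifier is two-class by construction; a third methylation
  activity would fold into the nearest regime's score.
* Pattern scores are relative to the training pair's feature ranges;
  scoring a sample far outside them saturates at 0/1 (clipping is flagged
  by the score itself sitting at an endpoint).
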