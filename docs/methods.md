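# Methods

This note documents the models, defaults and numerical choices behind
`sagscope`, and what its synthetic-data validations do and do not establish.

## The problem and the pipeline

A metatranscriptome of a host animal contains mRNA from the host and from a
complex microbial community. Retrieving the transcriptome of one
uncultivated taxon means mapping the mixed read set against that taxon's
reference genomes (single amplified genomes, SAGs) and keeping only reads
that can be attributed confidently. Because no ground truth exists for real
data, the pipeline is validated on simulation: reads with recorded origins
are pushed through the identical code path and retrieval is scored as
precision/recall per genome.

Stages: read QC → paired assignment → union-mode counting → FPKM /
housekeeping-relative profiling → coverage-based polycistron inference.
A quantitative-microscopy arm (co-localization statistics, 3D granule
morphometry) operates on labelled images and is independent of the
sequence stages.

## Synthetic community and read simulator

The generator emulates the stated input world rather than any particular
dataset:

- **Geometry.** 101 bp paired-end reads; insert length ~ Normal(149, 30)
  rounded, clipped to [read length, CDS length] — with these defaults mates
  overlap, as in short-insert Illumina libraries. Fragments are placed
  uniformly within a CDS sampled ~ Multinomial(expression weights).
- **Expression.** Per-CDS log-normal weights (default σ = 1.0–1.5 in the
  examples) normalised over the whole community; heavy-tailed so that a
  "highly expressed" tail exists. σ = 0 degenerates to equal weights.
- **Host background.** One extra genome labelled `host` participates in
  the simulation but is excluded from the retrieval target set.
- **Errors and qualities.** Independent per-base substitutions (no indels,
  matching the mismatch-only aligner; a documented limitation for real
  data). Quality model: constant Phred 38, or a decay mode (linear drop of
  2 Phred per base after a seeded breakpoint) whose only purpose is to
  exercise threshold-based truncation — the QC rules are threshold
  crossings, so finer quality structure would be untestable decoration.
- **One contig per genome.** Multi-contig references are read and handled
  throughout the pipeline, but the generator emits one contig per genome;
  none of the validated behaviours depend on contig count.
- **Short CDS.** A CDS shorter than the read length yields truncated reads
  equal to the whole CDS, keeping every simulated read a genomic substring.
- **Intergenic transcription** is off by default (`intergenic_rate = 0`);
  switching it on draws that fraction of fragments uniformly from whole
  contigs, to exercise read-through across gene boundaries.

Determinism: every sampler takes a NumPy `default_rng` seed and all file
writers are byte-deterministic.

What a green simulation test does **not** establish: real libraries have
indels, quality-correlated errors, rRNA carry-over, amplification bias and
cross-taxon homology; none are modelled, so measured precision/recall are
upper bounds for real data.

## Read QC

Truncate each read at the first base with Phred < 20 (strict; the
surviving prefix contains no failing base, hence idempotence), then remove
pairs in which either mate is shorter than 16 bp. Both thresholds are
parameters (`QcParams`).

## Paired assignment

Exact k-mer seeds (default k = 21, well above the ~16 bp uniqueness scale
of random megabase-sized references) are taken at every non-overlapping
offset plus the read tail, on both strands; candidates are extended
ungapped, counting mismatches with an early-exit cap. Seeding positions do
not depend on the mismatch budget, so raising `max_mismatch` can only admit
placements — this makes recall provably monotone in the budget and keeps
grid searches interpretable.

A pair placement requires one contig, forward–reverse orientation with the
plus-strand mate leftmost, and an inferred fragment length (rightmost mate
end − leftmost mate start, the TLEN magnitude) within `[min_frag,
max_frag]` = [20, 450] by default. The best placement minimises total
mismatches; exactly one best → `unique`, ties → `multi` (discarded
downstream, never broken by randomness), no in-bounds placement but an
out-of-bounds FR placement → `frag_out_of_bounds`, otherwise `unmapped`.

The aligner is deliberately minimal — it implements the contractual
semantics (bounds + uniqueness) rather than any production mapper's scoring
model; SAM import (`read_sam`) is the path for external mapper output, and
SAM export writes unique pairs as proper pairs and every other status as an
unmapped pair tagged `ZS:<status>`, so round trips conserve the input.

## Counting and expression

Union mode, fragment-level, non-stranded: the feature set of a pair is the
union over both aligned mate intervals of all CDS overlapping ≥ 1 base
(the unsequenced inner gap contributes nothing; a `fragment_span` coverage
mode exists but counting is read-based). One feature → count; zero →
`no_feature`; several → `ambiguous`; `multi`/`unmapped`/out-of-bounds/QC
classes are tallied so that counts + tallies always equal the evaluated
pairs (a conservation invariant tested on every fixture).

FPKM uses N = fragments assigned to the *target genome's* CDS in that
replicate, not the whole metatranscriptome — the only reading under which
per-genome expression tables are internally consistent; the conservation
identity Σ FPKM·len_kb = 10⁶ per replicate follows and is asserted in the
tests. The housekeeping baseline is the mean of replicate-averaged FPKM
over the housekeeping set (replicate-mean-then-gene-mean); *highly
expressed* is strict `mean FPKM > baseline`, so a gene exactly at the
baseline (fold 1.0) is excluded. Percentile ranks are the fraction of CDS
with strictly smaller value × 100 (all-tied values share percentile 0);
ties therefore never inflate a gene's standing.

## Polycistron inference

Coverage is per-base depth from unique alignments (each mate adds 1;
overlapping mates of one pair count twice, matching what genome browsers
display). CDS with all-zero coverage are excluded; consecutive covered CDS
merge iff every base strictly between them has depth ≥ `min_depth`
(default 1 — the literal zero-coverage reading; raise it for noisy data)
and, by default, they share a strand (`same_strand_required=True`, the
operon-biology prior; configurable because non-stranded libraries cannot
observe transcript strand directly). Zero-coverage flanking loci within a
`flank_window` (default 50 bp) are reported as evidence flags, not
required for a call: flanking darkness supports, but does not define, a
polycistron. Calls partition the covered CDS; adding alignments can only
merge calls, never split them.

## Quantitative microscopy

**Co-localization.** An object (connected label) is positive for a mask
when ≥ `min_overlap_fraction` (default 0.25) of its pixels lie on it —
fraction-of-object rather than any-pixel, to be robust to mask dilation;
the threshold is configurable because no principled value exists. Protein
positivity uses probe-positive objects as its denominator. Field summaries
are unweighted per-area means ± sample sd (n−1); pooled counts are also
available because pooled ratios and per-area means legitimately differ
when fields vary — both are reported, neither is forced to match the
other.

**Morphometry.** Volume = voxel count × voxel volume (anisotropic voxels
supported; z defaults to the 0.1 µm section spacing). Equivalent spherical
diameter = (6V/π)^(1/3). The bipolarity score projects granule centroids
onto the cell's principal axis (eigenvector of the coordinate covariance
in physical units): 1 if the two largest granules fall on opposite sides
of the cell centroid, else 0; undefined below two granules. "Bipolar" has
no standard metric; this is the simplest scale-free formalisation.

**Fixture generators.** Label fields place non-overlapping discs on a
jittered grid with exactly the requested object/overlap counts (capacity
errors otherwise), so quantifiers are validated in a closed loop. The
voxel-cell generator defaults to an ovoid of 1.85 × 1.05 µm (the midrange
of the observed symbiont morphotype) with two 168 nm granules at ±0.75 of
the long semi-axis. Digitised-sphere volume converges to the analytic
value with voxel size (≈ 1.4 % error at 10 nm); voxel-centre digitisation
is not strictly monotone in general, so convergence is checked at the
three resolutions 40/20/10 nm.

## Numerical conventions

- Coordinates 0-based half-open internally; GFF3 1-based inclusive on
  disk; FASTQ Phred+33.
- Precision and recall use the 0/0 := 1 convention (no opportunities to
  err is a perfect score), making the duplicated-reference degenerate case
  well-defined (recall 0, precision 1).
- Undefined statistics (sd of one field, correlation of a zero-variance
  replicate, ratio with zero host cells, polarity with < 2 granules) are
  flagged as NaN/None, never silently zeroed, and only structurally
  invalid inputs raise.
- Label/voxel arrays persist in a documented plain-text container
  (`sagscope.arrayio`): header lines with shape and dtype, then integer
  rows — lossless and diff-friendly.

## Known limitations

Mismatch-only alignment (no indels or clipping); no rRNA/contamination
modelling; no TPM or differential-expression statistics (out of scope);
polycistron calls are candidates, not transcription-unit proof — coverage
continuity cannot distinguish overlapping monocistronic transcription from
a shared mRNA; microscopy consumes already-labelled masks and does no
segmentation or registration.
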