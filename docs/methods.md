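# Methods

## Scope and data model

`linkstr` genotypes large (> 1 kb) STR expansions in barcode linked-read
sequencing (BLRS) data. Inputs are a coordinate-sorted, indexed BAM/SAM with
molecular barcodes (BX tags, or stLFR-style read-name suffixes after `#`),
the matching paired FASTQ files, a BED4+ of target loci (column 4 = motif)
and the reference FASTA. Haplotype (HP) tags, when present, are consumed —
phasing is never computed here. All internal coordinates are 0-based
half-open; region strings are 1-based inclusive. The null stLFR barcode
`0_0_0` and empty strings are treated as missing barcodes everywhere.

## Barcode selection and molecule reconstruction (`linkstr.barcodes`)

Alignments within a 250-kb window on either side of a target locus are
screened; a record is retained only if it is properly paired and its CIGAR
consumes the full read as aligned match (no soft/hard clips, insertions or
deletions — the strictest reading of "alignment length equals sequence
length", keeping only confidently placed reads). Per barcode, the sorted
alignment coordinates define molecule spans (min start to max end). Two
non-default behaviours:

* **Collision guard.** One barcode can tag several distinct molecules. A
  coordinate gap > 50 kb between consecutive reads of a barcode splits it
  into separate molecules; without this a collision inside the window would
  produce a pseudo-molecule spanning most of it. The threshold is
  configurable; collisions are rare within a 250-kb window at realistic
  barcode pool sizes.
* **Phasing consensus.** A molecule takes the HP value shared by all its
  tagged reads; any conflict demotes it to unphased, which is conservative —
  an IRR attributed to the wrong haplotype is worse than an unphased one.

Barcodes are selected when they have at least one molecule ≥ 1 kb long with
span within 10 kb of either locus boundary (distance 0 when overlapping).
These defaults are the method's standard operating constants and are all
overridable in `RunConfig`.

## IRR classification and sizing (`linkstr.irr`)

All FASTQ pairs carrying selected barcodes are screened:

* **Purity.** A mate is *pure repeat* iff it matches a substring of the
  infinite motif concatenation, at any phase, on either strand, with at most
  `max_impurity × length` mismatches (default 0 — "composed entirely").
  The matcher is exact and deterministic; no external tandem-repeat finder
  is involved.
* **IRR pair**: both mates pure. **IRR anchor**: exactly one mate pure and
  the other mate's non-repeat portion (after trimming maximal pure-motif
  prefix/suffix on either strand) aligns unambiguously to one of the two
  500-bp reference flanks. Anchor verification is an internal local
  alignment (match +1, mismatch −2, gap −2.5); "unambiguous" means best
  score ≥ 0.9 × portion length *and* ≥ 1.2 × the second-best flank score.
  Portions shorter than 20 bp are not alignable with confidence and the
  pair is discarded. All thresholds are exposed in `AnchorParams`.

The tally is *i* = 2 × pairs + anchors: each pure mate contributes one
repeat read (a pair has two, an anchor one). An alternative convention,
*i* = 2 × (pairs + anchors), circulates for this quantity and is available
as `i_definition="2(p+a)"`; the default is the physically coherent count
that the size formula expects.

**Depth.** *d* is the mean of the median per-base depths of two 1-kb
windows offset 500 bp from the locus boundaries (margins avoid the coverage
distortion right at the repeat). Depth uses the same retention filter as
molecule reconstruction. Windows truncated at contig ends are computed on
the remaining portion with a logged warning; *d* = 0 is a hard error (the
locus sits in a coverage hole and cannot be sized).

**Size.** *N* = *r*(1 + *i*/*d*) estimates the allele length in bp, because
the expected number of reads wholly inside a tract of length *T* at
per-allele depth *d* is ≈ (*T* − *r*) *d*/*r*. Repeat copies = *N*/|motif|.
Platform presets set *r*: stLFR 100 bp, TELL-Seq 146 bp, and 10x both 128
and 151 bp (read 1 loses its 16-bp barcode + 7-bp adaptor), the two values
forming the lower/upper bounds with their mean as the point estimate.

**Haplotype-specific depth.** When an estimate is haplotype-resolved, the
formula's *d* must be the coverage of *that* allele. The default
(`haplotype_depth="haplotype"`) therefore computes the flank depth from
reads carrying the matching HP tag; any unphased-read loss affects *i* and
*d* equally, so the bias cancels. Two alternatives are provided:
`"diploid"` (total depth as printed in the formula — halves heterozygous
estimates, shown by the "all" row of the worked example) and `"half"`
(total/2, which over-corrects where phasing is incomplete). This is a
deliberate design choice where the printed formula is silent.

## Jaccard-index size estimation (`linkstr.ji`)

For an interval, the flanks are the 1-kb regions immediately up/downstream.
Barcodes are collected from *all* mapped alignments within 5 kb of each
flank (no pairing filter — bridging is a property of every read of a
molecule), barcode spans are the first-to-last coordinates of those local
alignments, and a barcode enters BC_L / BC_R when its span fully contains
the flank. Containment (rather than any-overlap) is the default because the
bridging premise requires the molecule to traverse the flank; an
any-overlap mode is available (`containment=False`).
JI = |BC_L ∩ BC_R| / |BC_L ∪ BC_R|, defined as 0 when both sets are empty.

**Database.** `build_database` samples `n_positions` positions uniformly
without replacement from the contigs minus an exclusion BED (sequence gaps,
segmental duplications, pericentromeres on real genomes; the expansion
neighbourhood on simulated ones) and minus margins so each interval plus
flanks and collection windows fits. At each position one profile is
computed per grid size. Grid presets: **small** 200–4,000 bp step 100
(sub-4-kb alleles) and **large** 5–40 kb step 500 (multi-kb expansions);
custom grids are accepted (`START:STOP:STEP` on the CLI). In phased mode
profiles are computed per haplotype from HP-tagged alignments only; the
coverage loss from unphased alignments is real and logged. The database is
serialized as headered TSV plus a YAML metadata sidecar (greppable,
diffable) and is sample- and mode-specific — never reuse across samples.

**Query.** The test tuple (|BC_L|, |BC_R|, JI) is compared by Euclidean
distance on the raw, unscaled components; the printed thresholds (*F* = 4
small grid, 200 large grid) are only meaningful on the raw count scale,
where JI contributes ≤ 1. Up to *E* = 200 profiles with distance < *F* are
retained, taking the smallest distances; if fewer qualify, *F* doubles, up
to five times. Ties at the *E*-th distance break toward the smaller
interval size, then database order, making output deterministic. The
estimate is the median of the retained sizes; the IQR is the range. Zero
profiles within the final *F* yield an explicit no-estimate result, never a
number. Because counts are integers, profiles with exactly matching counts
sort first and JI orders them — the estimator effectively conditions on
local molecule coverage and then inverts the JI-versus-distance curve, so
its resolution improves with database density (see *Problem sizes* below).

A target locus is queried with its reference interval as the gap; the
returned interval size is the allele-length estimate in bp (copies =
bp/|motif|). Estimates at or below the grid floor are flagged: alleles
under ~1 kb are beneath the resolution of molecule bridging, whose
variability over short gaps is too small to measure.

## The simulator (`linkstr.sim`)

The generator emulates exactly the data properties the two methods consume:

* a random-sequence diploid toy chromosome (default 2 Mb) whose STR
  interval is filled with motif copies, with each haplotype's tract
  replaced by its configured copy number. The bases adjacent to the tract
  are constrained not to extend the motif concatenation, so the repeat has
  well-defined boundaries and "pure read ⇔ read inside the tract" holds
  exactly at zero error rate;
* barcoded molecules with uniform starts and lognormal (default, shape
  σ = 0.35, mean 50 kb) or exponential lengths, each assigned a haplotype
  at random; `molecules_per_barcode` controls barcode reuse (default 1 —
  within a single-locus window, real-pool collisions are negligible);
* FR read pairs sampled uniformly along molecules at a rate yielding the
  target total depth (default 30x), insert 350 ± 50 bp, constant base
  quality, optional uniform substitution errors (default 0);
* truth alignments written directly, without an external aligner: correct
  reference coordinates and proper-pair flags for reads in unique sequence,
  soft-clipping at the repeat edge for boundary-straddling reads
  (clip = bases inside the tract), and unmapped-with-barcode records for
  reads wholly inside an altered tract — the signature a real aligner
  produces at an expansion. A read spanning an entire (short) altered
  tract keeps its left-flank alignment with the remainder clipped.
  `fastq_only=True` skips the BAM for users who prefer a real aligner;
* a per-mate truth table (barcode, haplotype, molecule, source coordinates,
  `is_irr` = read wholly inside the repeat tract) — the ground truth for
  sensitivity/specificity scoring;
* 10% of molecules carry no HP tags (`unphased_molecule_fraction`),
  mimicking incomplete phasing.

Outputs are byte-identical under a fixed seed (gzip members carry zeroed
timestamps; the BAM is emitted directly in coordinate order rather than
re-sorted). What the generator does *not* model — GC-dependent coverage
dropout (the known failure mode for extremely GC-rich loci), PCR
duplicates, chimeric molecules, indel errors, mismapping between off-target
repeat loci — bounds what green tests mean: they validate the algorithms
under their stated premises, not robustness to platform-specific coverage
pathologies.

## Evaluation harness and problem sizes (`linkstr.evaluate`)

The reference evaluation sample is a 2-Mb chromosome with a heterozygous
ATTCT expansion (15 vs 4,000 copies, i.e. a 20-kb allele) at the midpoint,
8,000 barcodes × 1 molecule (molecule coverage ≈ 160x, per-molecule read
depth ≈ 0.2x — the canonical linked-read regime), 100-bp stLFR-style pairs
at 30x and zero error. Scoring:

* **IRR**: specificity = fraction of classified IRR reads whose truth
  record lies inside the expanded tract; sensitivity = fraction of true
  in-repeat reads recovered; haplotype purity = no IRR-associated barcode
  assigned to, or originating from, the non-expanded haplotype; accuracy =
  estimated/true copy number for the expanded haplotype.
* **JI**: a database at 12,000 positions × the large grid (expansion
  neighbourhood excluded), then 200 held-out random intervals with sizes
  uniform in 5–40 kb, scored by Pearson correlation of estimate vs truth.
  The database is deliberately dense: with *E* = 200 retained neighbours,
  the pool of count-compatible profiles must be several times *E* for the
  JI component to select sizes; 12,000 positions × 71 grid sizes achieves
  that on a 2-Mb genome while keeping the build to ~2 minutes on one core
  (genome-scale runs would use tens of thousands of positions for the same
  reason).

## Numerical and degenerate-input conventions

* Purity checking is exact string matching over all phases and strands —
  O(2·|motif|·|read|) per read, no heuristics.
* `jaccard` returns 0 for two empty sets; a flank with zero spanning
  barcodes gives JI 0.
* Depth windows and collection windows are truncated at contig bounds;
  zero-length loci, non-ACGT motifs, `start ≥ end` BED lines, unindexed
  BAMs and absent contigs are hard errors with explicit messages.
* Database position sampling, molecule generation and read sampling each
  use a `numpy` `default_rng` seeded from the configured seed, so every
  stage is independently reproducible.
* The estimator's percentiles use numpy's linear interpolation; medians of
  even-sized retained sets are midpoints.

## Known limitations

* Alleles shorter than the read length produce no IRRs, and alleles under
  ~1 kb are below the JI method's resolution; neither method replaces
  spanning-read genotypers for small alleles.
* Without phasing, heterozygous IRR estimates based on total flank depth
  undercount by about half — visible in the worked example and inherent to
  the formula.
* JI databases do not transfer between samples, platforms or haplotype
  modes.
* The simulator's uniform-coverage premise means measured operating
  characteristics (e.g. 100% specificity at zero error) are upper bounds
  for real libraries with coverage bias or repeat interruptions.
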