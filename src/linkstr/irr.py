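"""In-repeat-read (IRR) extraction, classification, and repeat sizing.

An IRR is a read composed entirely of concatenated copies of the target
repeat motif — the signature of an allele longer than the read length.  Read
pairs with both mates pure repeat are *IRR pairs*; pairs with exactly one
pure mate whose partner maps unambiguously to a 500-bp locus flank are *IRR
anchors*.  The tallied IRR count ``i``, together with the read length ``r``
and the local read depth ``d``, converts to a repeat-size estimate through

    N = r * (1 + i / d)

which expresses the expected relationship between the number of reads wholly
inside a repeat tract and the tract length, given uniform coverage ``d`` of
the allele being sized.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pysam
from Bio import Align

from .barcodes import (
    UNPHASED,
    BarcodeSelection,
    alignment_is_clean,
    parse_barcode_fastq,
)
from .loci import StrLocus
from .sim import revcomp

logger = logging.getLogger(__name__)

#: per-platform read length(s) used in the sizing formula and the default
#: barcode encoding.  10x reports two lengths because mate 1 loses the 16-bp
#: barcode and 7-bp adaptor; sizes computed at each r form the bounds.
PLATFORM_PRESETS: dict[str, dict] = {
    "10x": {"read_lengths": (128, 151), "barcode_encoding": "bx-tag"},
    "stlfr": {"read_lengths": (100,), "barcode_encoding": "read-name-suffix"},
    "tellseq": {"read_lengths": (146,), "barcode_encoding": "bx-tag"},
}

MIN_ANCHOR_BASES = 20  # shortest non-repeat portion considered alignable


class PairClass(Enum):
    IRR_PAIR = "irr_pair"
    IRR_ANCHOR = "irr_anchor"
    NONE = "none"


# ---------------------------------------------------------------------------
# repeat purity

def _hamming_ok(seq: str, template: str, max_mm: int) -> bool:
    mm = 0
    for a, b in zip(seq, template):
        if a != b:
            mm += 1
            if mm > max_mm:
                return False
    return True


def is_pure_repeat(seq: str, motif: str, max_impurity: float = 0.0) -> bool:
    """True iff ``seq`` is a substring of an infinite concatenation of
    ``motif`` (any phase) on either strand, allowing at most
    ``max_impurity * len(seq)`` mismatching bases."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    m = len(motif)
    max_mm = int(max_impurity * len(seq))
    reps = motif * (len(seq) // m + 2)
    for s in (seq, revcomp(seq)):
        for phase in range(m):
            if _hamming_ok(s, reps[phase : phase + len(s)], max_mm):
                return True
    return False


def _pure_run_from_start(seq: str, motif: str) -> int:
    """Longest prefix of ``seq`` that continues a motif concatenation
    (best over phases and strands)."""
    m = len(motif)
    best = 0
    for mot in (motif, revcomp(motif)):
        reps = mot * (len(seq) // m + 2)
        for phase in range(m):
            run = 0
            tpl = reps[phase:]
            for a, b in zip(seq, tpl):
                if a != b:
                    break
                run += 1
            best = max(best, run)
    return best


def non_repeat_portion(seq: str, motif: str) -> str:
    """Trim the maximal pure-motif prefix and suffix (either strand) and
    return the remaining non-repeat portion of an anchor-candidate mate."""
    seq = seq.upper()
    pre = _pure_run_from_start(seq, motif)
    suf = _pure_run_from_start(seq[::-1], motif[::-1])
    if pre + suf >= len(seq):
        return ""
    return seq[pre : len(seq) - suf]


# ---------------------------------------------------------------------------
# anchor verification (internal local alignment of the non-repeat portion
# against the two 500-bp locus flanks)

@dataclass
class AnchorParams:
    match_score: float = 1.0
    mismatch_score: float = -2.0
    gap_score: float = -2.5
    min_score_fraction: float = 0.9   # best score >= fraction * portion length
    ambiguity_ratio: float = 1.2      # best >= ratio * second best
    min_anchor_bases: int = MIN_ANCHOR_BASES


def _make_aligner(params: AnchorParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.match_score
    aligner.mismatch_score = params.mismatch_score
    aligner.open_gap_score = params.gap_score
    aligner.extend_gap_score = params.gap_score
    return aligner


def classify_pair(seq1: str, seq2: str, motif: str,
                  flank_up: str, flank_down: str,
                  max_impurity: float = 0.0,
                  anchor_params: AnchorParams | None = None) -> PairClass:
    """Classify a read pair as IRR pair, IRR anchor, or neither.

    ``flank_up``/``flank_down`` are the 500-bp reference sequences
    immediately up- and downstream of the locus.  An anchor requires the
    non-pure mate's non-repeat portion to align to exactly one flank above
    the score threshold (ambiguous double-flank hits are rejected).
    """
    if anchor_params is None:
        anchor_params = AnchorParams()
    p1 = is_pure_repeat(seq1, motif, max_impurity)
    p2 = is_pure_repeat(seq2, motif, max_impurity)
    if p1 and p2:
        return PairClass.IRR_PAIR
    if not p1 and not p2:
        return PairClass.NONE
    other = seq2 if p1 else seq1
    portion = non_repeat_portion(other, motif)
    if len(portion) < anchor_params.min_anchor_bases:
        return PairClass.NONE
    aligner = _make_aligner(anchor_params)
    scores = []
    for flank in (flank_up, flank_down):
        best = 0.0
        if flank:
            for query in (portion, revcomp(portion)):
                best = max(best, aligner.score(flank, query))
        scores.append(best)
    best, second = max(scores), min(scores)
    if best < anchor_params.min_score_fraction * len(portion):
        return PairClass.NONE
    if second > 0 and best < anchor_params.ambiguity_ratio * second:
        return PairClass.NONE  # matches both flanks comparably: ambiguous
    return PairClass.IRR_ANCHOR


# ---------------------------------------------------------------------------
# FASTQ extraction by barcode

@dataclass
class ReadPair:
    name: str
    seq1: str
    seq2: str
    barcode: str
    haplotype: int = UNPHASED


def _strip_mate_suffix(name: str) -> str:
    return name[:-2] if name.endswith(("/1", "/2")) else name


def extract_reads_by_barcode(fastq1: str, fastq2: str,
                             selection: BarcodeSelection | dict[str, int],
                             encoding: str):
    """Yield the read pairs whose barcode belongs to the selection, annotated
    with the barcode's haplotype assignment.

    The two FASTQ files must list mates in the same order; a mate-count
    mismatch raises :class:`ValueError`.
    """
    barcodes = selection.barcodes if isinstance(selection, BarcodeSelection) else selection
    with pysam.FastxFile(fastq1) as fq1, pysam.FastxFile(fastq2) as fq2:
        for rec1, rec2 in itertools.zip_longest(fq1, fq2):
            if rec1 is None or rec2 is None:
                raise ValueError(
                    f"mate-count mismatch between {fastq1} and {fastq2}"
                )
            name = _strip_mate_suffix(rec1.name)
            if name != _strip_mate_suffix(rec2.name):
                raise ValueError(
                    f"mate name mismatch: {rec1.name!r} vs {rec2.name!r}"
                )
            bc = parse_barcode_fastq(rec1.name, rec1.comment, encoding)
            if bc is None or bc not in barcodes:
                continue
            yield ReadPair(
                name=name, seq1=rec1.sequence, seq2=rec2.sequence,
                barcode=bc, haplotype=barcodes[bc],
            )


# ---------------------------------------------------------------------------
# tallies and sizing

@dataclass
class IrrTally:
    """Counts of IRR pairs and anchors, overall and per haplotype."""

    pairs: dict[int, int] = field(default_factory=lambda: {UNPHASED: 0, 1: 0, 2: 0})
    anchors: dict[int, int] = field(default_factory=lambda: {UNPHASED: 0, 1: 0, 2: 0})

    @property
    def n_irr_pairs(self) -> int:
        return sum(self.pairs.values())

    @property
    def n_irr_anchors(self) -> int:
        return sum(self.anchors.values())

    def i(self, haplotype: int | None = None,
          definition: str = "2p+a") -> int:
        """IRR count feeding the sizing formula.

        ``"2p+a"`` (default): i = 2 x pairs + anchors — each IRR-pair mate
        and each pure anchor mate contributes one repeat read.
        ``"2(p+a)"``: i = 2 x (pairs + anchors), an alternative tallying
        convention in circulation.
        """
        if haplotype is None:
            p, a = self.n_irr_pairs, self.n_irr_anchors
        else:
            p, a = self.pairs[haplotype], self.anchors[haplotype]
        if definition == "2p+a":
            return 2 * p + a
        if definition == "2(p+a)":
            return 2 * (p + a)
        raise ValueError(f"unknown IRR count definition {definition!r}")

    def add(self, cls: PairClass, haplotype: int) -> None:
        if cls is PairClass.IRR_PAIR:
            self.pairs[haplotype] += 1
        elif cls is PairClass.IRR_ANCHOR:
            self.anchors[haplotype] += 1


def tally_irrs(classified) -> IrrTally:
    """Aggregate ``(PairClass, haplotype)`` pairs into an :class:`IrrTally`."""
    tally = IrrTally()
    for cls, hap in classified:
        tally.add(cls, hap)
    return tally


@dataclass
class DepthEstimate:
    """Mean of the median read depths in two offset 1-kb flank windows."""

    d: float
    left_window: tuple[int, int]
    right_window: tuple[int, int]
    left_median: float
    right_median: float
    haplotype: int | None = None


def estimate_depth(bam_path: str, locus: StrLocus,
                   window_bp: int = 1000, margin_bp: int = 500,
                   haplotype: int | None = None) -> DepthEstimate:
    """Local read depth ``d`` for the sizing formula.

    Depth is the mean of the median per-base depths of two ``window_bp``
    windows offset ``margin_bp`` from the locus boundaries — the margins
    avoid coverage abnormalities right at the repeat.  Only clean alignments
    (the molecule-reconstruction filter) are counted; ``haplotype``
    restricts to reads carrying that HP tag.
    """
    windows = [
        (locus.start - margin_bp - window_bp, locus.start - margin_bp),
        (locus.end + margin_bp, locus.end + margin_bp + window_bp),
    ]
    medians = []
    with pysam.AlignmentFile(bam_path) as af:
        chrom_len = af.get_reference_length(locus.chrom)
        for ws, we in windows:
            cws, cwe = max(0, ws), min(chrom_len, we)
            if (cws, cwe) != (ws, we):
                logger.warning(
                    "depth window [%d, %d) truncated to contig bounds", ws, we
                )
            cov = np.zeros(cwe - cws, dtype=np.int32)
            for read in af.fetch(locus.chrom, cws, cwe):
                if not alignment_is_clean(read):
                    continue
                if haplotype is not None:
                    if not read.has_tag("HP") or read.get_tag("HP") != haplotype:
                        continue
                s = max(read.reference_start, cws) - cws
                e = min(read.reference_end, cwe) - cws
                if e > s:
                    cov[s:e] += 1
            medians.append(float(np.median(cov)) if cov.size else 0.0)
    return DepthEstimate(
        d=float(np.mean(medians)),
        left_window=windows[0], right_window=windows[1],
        left_median=medians[0], right_median=medians[1],
        haplotype=haplotype,
    )


@dataclass
class SizeEstimate:
    """Point estimate and range of a repeat size, in bp and motif copies."""

    method: str                      # "irr" or "ji"
    haplotype: int | None            # 1, 2, or None (all reads)
    size_bp: float | None            # point estimate, bp
    lower_bp: float | None = None
    upper_bp: float | None = None
    motif_length: int | None = None
    read_lengths_used: tuple[int, ...] = ()
    extra: dict = field(default_factory=dict)

    @property
    def repeat_count_estimate(self) -> float | None:
        if self.size_bp is None or not self.motif_length:
            return None
        return self.size_bp / self.motif_length

    @property
    def lower(self) -> float | None:
        if self.lower_bp is None or not self.motif_length:
            return None
        return self.lower_bp / self.motif_length

    @property
    def upper(self) -> float | None:
        if self.upper_bp is None or not self.motif_length:
            return None
        return self.upper_bp / self.motif_length


def estimate_size_irr(tally: IrrTally, depth: DepthEstimate, motif_length: int,
                      platform: str | None = None,
                      read_lengths: tuple[int, ...] | None = None,
                      haplotype: int | None = None,
                      i_definition: str = "2p+a") -> SizeEstimate:
    """Convert an IRR tally into a repeat-size estimate, N = r(1 + i/d).

    N is on the bp scale (``r`` in bp); dividing by the motif length gives
    repeat copies.  For platforms reporting two read lengths (10x) the
    formula is evaluated at each r and the two values form the bounds; the
    point estimate is their mean.
    """
    if read_lengths is None:
        if platform is None:
            raise ValueError("either platform or read_lengths must be given")
        try:
            read_lengths = PLATFORM_PRESETS[platform]["read_lengths"]
        except KeyError:
            raise ValueError(f"unknown platform {platform!r}") from None
    if depth.d <= 0:
        raise ValueError(
            "read depth is zero at the locus flanks (coverage hole); cannot size"
        )
    i = tally.i(haplotype, definition=i_definition)
    sizes = [r * (1.0 + i / depth.d) for r in read_lengths]
    return SizeEstimate(
        method="irr", haplotype=haplotype,
        size_bp=float(np.mean(sizes)),
        lower_bp=min(sizes), upper_bp=max(sizes),
        motif_length=motif_length,
        read_lengths_used=tuple(read_lengths),
        extra={"i": i, "d": depth.d,
               "n_irr_pairs": tally.n_irr_pairs if haplotype is None else tally.pairs[haplotype],
               "n_irr_anchors": tally.n_irr_anchors if haplotype is None else tally.anchors[haplotype]},
    )


# ---------------------------------------------------------------------------
# locus-level pipeline

@dataclass
class LocusIrrResult:
    locus: StrLocus
    tally: IrrTally
    depths: dict[int | None, DepthEstimate]
    estimates: list[SizeEstimate]
    classified_pairs: list[tuple[str, PairClass, int]]  # (read name, class, hap)


def genotype_locus_irr(bam_path: str, fastq1: str, fastq2: str,
                       locus: StrLocus, ref_fasta: str,
                       platform: str | None = None,
                       read_lengths: tuple[int, ...] | None = None,
                       encoding: str | None = None,
                       window_bp: int = 250_000,
                       min_molecule_bp: int = 1_000,
                       max_boundary_distance_bp: int = 10_000,
                       max_impurity: float = 0.0,
                       i_definition: str = "2p+a",
                       haplotype_depth: str = "haplotype",
                       anchor_params: AnchorParams | None = None) -> LocusIrrResult:
    """Full barcode-based IRR genotyping of one locus.

    ``haplotype_depth`` controls the ``d`` used for haplotype-specific
    estimates: ``"haplotype"`` (default) computes the flank depth from reads
    carrying the matching HP tag — the coverage of the allele actually being
    sized; ``"diploid"`` uses total depth (halving heterozygous estimates);
    ``"half"`` uses total depth / 2.
    """
    from .barcodes import collect_molecules, detect_encoding, select_target_barcodes

    if encoding is None:
        encoding = detect_encoding(bam_path)
    if read_lengths is None and platform is None:
        raise ValueError("either platform or read_lengths must be given")
    molecules = collect_molecules(bam_path, locus, window_bp=window_bp,
                                  encoding=encoding)
    selection = select_target_barcodes(
        molecules, locus, min_molecule_bp=min_molecule_bp,
        max_boundary_distance_bp=max_boundary_distance_bp, window_bp=window_bp,
    )
    with pysam.FastaFile(ref_fasta) as fa:
        flank_up = fa.fetch(locus.chrom, max(0, locus.start - 500), locus.start).upper()
        flank_down = fa.fetch(locus.chrom, locus.end, locus.end + 500).upper()

    tally = IrrTally()
    classified: list[tuple[str, PairClass, int]] = []
    for pair in extract_reads_by_barcode(fastq1, fastq2, selection, encoding):
        cls = classify_pair(pair.seq1, pair.seq2, locus.motif,
                            flank_up, flank_down, max_impurity=max_impurity,
                            anchor_params=anchor_params)
        if cls is not PairClass.NONE:
            tally.add(cls, pair.haplotype)
            classified.append((pair.name, cls, pair.haplotype))

    depths: dict[int | None, DepthEstimate] = {
        None: estimate_depth(bam_path, locus)
    }
    estimates = [
        estimate_size_irr(tally, depths[None], len(locus.motif),
                          platform=platform, read_lengths=read_lengths,
                          haplotype=None, i_definition=i_definition)
    ]
    phased_haps = [h for h in (1, 2) if tally.pairs[h] + tally.anchors[h] > 0]
    for h in phased_haps:
        if haplotype_depth == "haplotype":
            dep = estimate_depth(bam_path, locus, haplotype=h)
        elif haplotype_depth == "half":
            base = depths[None]
            dep = DepthEstimate(d=base.d / 2, left_window=base.left_window,
                                right_window=base.right_window,
                                left_median=base.left_median,
                                right_median=base.right_median, haplotype=h)
        elif haplotype_depth == "diploid":
            dep = depths[None]
        else:
            raise ValueError(f"unknown haplotype_depth mode {haplotype_depth!r}")
        depths[h] = dep
        estimates.append(
            estimate_size_irr(tally, dep, len(locus.motif), platform=platform,
                              read_lengths=read_lengths, haplotype=h,
                              i_definition=i_definition)
        )
    return LocusIrrResult(locus=locus, tally=tally, depths=depths,
                          estimates=estimates, classified_pairs=classified)
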