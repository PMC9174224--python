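"""Barcode parsing, molecule-span reconstruction and target-barcode selection.

Reads sharing a molecular barcode originate from the same long DNA molecule;
the molecule's span is reconstructed as the min-max of its reads' alignment
coordinates.  Barcodes whose molecules plausibly traverse a target STR locus
are then selected, so that *all* reads carrying those barcodes — including
repeat reads that failed to map — can be recovered from the FASTQ files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pysam

from .loci import StrLocus

logger = logging.getLogger(__name__)

UNPHASED = 0

#: barcodes treated as absent everywhere ("0_0_0" is the conventional null
#: stLFR barcode emitted for reads whose barcode could not be resolved)
NULL_BARCODES = frozenset({"", "0_0_0"})

DEFAULT_WINDOW_BP = 250_000
DEFAULT_MIN_MOLECULE_BP = 1_000
DEFAULT_MAX_BOUNDARY_DISTANCE_BP = 10_000
DEFAULT_SPLIT_GAP_BP = 50_000


def parse_barcode(read, encoding: str) -> str | None:
    """Extract the molecular barcode from an alignment record.

    ``bx-tag`` reads the BX tag (10x / TELL-Seq convention);
    ``read-name-suffix`` takes the portion of the read name after the final
    ``#`` (stLFR convention).  Null barcodes ("" and "0_0_0") and records
    without a barcode yield ``None`` — a missing barcode is a value, not an
    error.
    """
    if encoding == "bx-tag":
        try:
            bc = read.get_tag("BX")
        except KeyError:
            return None
    elif encoding == "read-name-suffix":
        name = read.query_name
        if name is None or "#" not in name:
            return None
        bc = name.rsplit("#", 1)[1]
    else:
        raise ValueError(f"unknown barcode encoding {encoding!r}")
    return None if bc in NULL_BARCODES else bc


def parse_barcode_fastq(name: str, comment: str | None, encoding: str) -> str | None:
    """Barcode of a FASTQ record: BX:Z: token in the comment, or read-name
    suffix after ``#``."""
    if encoding == "bx-tag":
        if comment:
            for token in comment.split():
                if token.startswith("BX:Z:"):
                    bc = token[5:]
                    return None if bc in NULL_BARCODES else bc
        return None
    if encoding == "read-name-suffix":
        if "#" not in name:
            return None
        bc = name.rsplit("#", 1)[1]
        return None if bc in NULL_BARCODES else bc
    raise ValueError(f"unknown barcode encoding {encoding!r}")


def detect_encoding(bam: "pysam.AlignmentFile | str", n_probe: int = 1000) -> str:
    """Auto-detect the barcode encoding from the first records of a BAM."""
    own = isinstance(bam, str)
    af = pysam.AlignmentFile(bam) if own else bam
    try:
        for i, read in enumerate(af.head(n_probe)):
            if read.has_tag("BX"):
                return "bx-tag"
            if read.query_name and "#" in read.query_name:
                return "read-name-suffix"
            if i >= n_probe:
                break
    finally:
        if own:
            af.close()
    raise ValueError("could not detect barcode encoding (no BX tags or #-suffixed names)")


@dataclass
class Molecule:
    """A reconstructed barcoded DNA fragment span on the reference."""

    barcode: str
    chrom: str
    start: int
    end: int
    haplotype: int = UNPHASED  # 1, 2, or 0 (unphased)
    n_reads: int = 1

    @property
    def length(self) -> int:
        return self.end - self.start

    def distance_to(self, locus: StrLocus) -> int:
        """Distance from the span to the nearer locus boundary (0 on overlap)."""
        if self.end <= locus.start:
            return locus.start - self.end
        if self.start >= locus.end:
            return self.start - locus.end
        return 0


@dataclass
class BarcodeSelection:
    """Barcodes whose molecules plausibly traverse the target locus."""

    locus: StrLocus
    barcodes: dict[str, int]  # barcode -> haplotype (0 = unphased)
    window_bp: int = DEFAULT_WINDOW_BP
    min_molecule_bp: int = DEFAULT_MIN_MOLECULE_BP
    max_boundary_distance_bp: int = DEFAULT_MAX_BOUNDARY_DISTANCE_BP
    molecules: list[Molecule] = field(default_factory=list)

    def __contains__(self, barcode: str) -> bool:
        return barcode in self.barcodes

    def __len__(self) -> int:
        return len(self.barcodes)

    def haplotype_of(self, barcode: str) -> int:
        return self.barcodes[barcode]


def alignment_is_clean(read) -> bool:
    """Retention filter for molecule reconstruction: a confidently placed
    read is properly paired and consumes its full length as alignment match
    (no soft/hard clips, insertions or deletions)."""
    if (read.is_unmapped or read.is_secondary or read.is_supplementary
            or read.is_duplicate or not read.is_proper_pair):
        return False
    cig = read.cigartuples
    if not cig:
        return False
    return all(op in (0, 7, 8) for op, _ in cig)


def collect_molecules(bam_path: str, locus: StrLocus,
                      window_bp: int = DEFAULT_WINDOW_BP,
                      encoding: str | None = None,
                      split_gap_bp: int = DEFAULT_SPLIT_GAP_BP) -> list[Molecule]:
    """Reconstruct molecule spans per barcode around a target locus.

    Examines alignments within ``window_bp`` of either side of the locus;
    retains clean alignments (see :func:`alignment_is_clean`); per barcode the
    sorted alignment coordinates define the molecule span.  A coordinate gap
    larger than ``split_gap_bp`` between consecutive reads of a barcode splits
    it into separate molecules (barcode collision guard).  Haplotype is the
    HP tag when all tagged reads of a molecule agree, else unphased.
    """
    with pysam.AlignmentFile(bam_path) as af:
        if locus.chrom not in af.references:
            raise ValueError(f"locus chromosome {locus.chrom!r} absent from BAM header")
        if not af.has_index():
            raise ValueError(f"{bam_path} has no index; coordinate-sorted, indexed input required")
        if encoding is None:
            encoding = detect_encoding(bam_path)
        chrom_len = af.get_reference_length(locus.chrom)
        wstart = max(0, locus.start - window_bp)
        wend = min(chrom_len, locus.end + window_bp)
        per_barcode: dict[str, list[tuple[int, int, int | None]]] = {}
        for read in af.fetch(locus.chrom, wstart, wend):
            if not alignment_is_clean(read):
                continue
            bc = parse_barcode(read, encoding)
            if bc is None:
                continue
            hp = read.get_tag("HP") if read.has_tag("HP") else None
            per_barcode.setdefault(bc, []).append(
                (read.reference_start, read.reference_end, hp)
            )
    molecules: list[Molecule] = []
    for bc, coords in per_barcode.items():
        coords.sort()
        groups: list[list[tuple[int, int, int | None]]] = [[coords[0]]]
        for rec in coords[1:]:
            if rec[0] - groups[-1][-1][1] > split_gap_bp:
                groups.append([rec])
            else:
                groups[-1].append(rec)
        for grp in groups:
            hps = {h for _, _, h in grp if h is not None}
            hap = hps.pop() if len(hps) == 1 else UNPHASED
            molecules.append(
                Molecule(
                    barcode=bc,
                    chrom=locus.chrom,
                    start=grp[0][0],
                    end=max(e for _, e, _ in grp),
                    haplotype=hap,
                    n_reads=len(grp),
                )
            )
    return molecules


def select_target_barcodes(
    molecules: list[Molecule], locus: StrLocus,
    min_molecule_bp: int = DEFAULT_MIN_MOLECULE_BP,
    max_boundary_distance_bp: int = DEFAULT_MAX_BOUNDARY_DISTANCE_BP,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> BarcodeSelection:
    """Keep barcodes of molecules at least ``min_molecule_bp`` long whose
    span lies within ``max_boundary_distance_bp`` of either locus boundary.

    When a barcode has several passing molecules, the haplotype is the
    consensus of the phased ones (conflicts -> unphased).
    """
    haps_seen: dict[str, set[int]] = {}
    kept: list[Molecule] = []
    for mol in sorted(molecules, key=lambda m: (m.barcode, m.start, m.end)):
        if mol.length < min_molecule_bp:
            continue
        if mol.distance_to(locus) > max_boundary_distance_bp:
            continue
        kept.append(mol)
        haps_seen.setdefault(mol.barcode, set()).add(mol.haplotype)
    selected: dict[str, int] = {}
    for bc, haps in haps_seen.items():
        phased = haps - {UNPHASED}
        selected[bc] = phased.pop() if len(phased) == 1 else UNPHASED
    logger.info(
        "selected %d barcodes (%d molecules) for %s", len(selected), len(kept),
        locus.region,
    )
    return BarcodeSelection(
        locus=locus, barcodes=selected,
        min_molecule_bp=min_molecule_bp,
        max_boundary_distance_bp=max_boundary_distance_bp,
        window_bp=window_bp, molecules=kept,
    )


def write_molecules_tsv(molecules: list[Molecule], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("barcode\tchrom\tstart\tend\thaplotype\tn_reads\n")
        for m in molecules:
            fh.write(
                f"{m.barcode}\t{m.chrom}\t{m.start}\t{m.end}\t{m.haplotype}\t{m.n_reads}\n"
            )
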