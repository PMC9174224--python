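"""Synthetic barcode linked-read (BLRS) datasets with known STR expansions.

The simulator emulates the generative process the barcode-based genotyping
methods rely on: long DNA molecules are drawn from two haplotypes of a diploid
toy genome, each molecule carries a molecular barcode, and short paired-end
reads are sampled sparsely along each molecule.  One STR locus is replaced on
each haplotype by a configurable number of motif copies, so heterozygous or
homozygous expansions (or contractions) can be produced with exact ground
truth.

Truth alignments are emitted directly instead of routing reads through an
external aligner: mapped records carry the correct reference coordinates,
proper-pair flags and BX/HP tags, reads that lie wholly inside an expanded
repeat tract are emitted as unmapped-with-barcode, and reads straddling an
expansion boundary are soft-clipped at the repeat edge.  These are exactly the
alignment properties the downstream methods consume.  A ``fastq_only`` flag
is available for users who prefer to run a real aligner.
"""

from __future__ import annotations

import dataclasses
import gzip
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .loci import StrLocus, write_loci_bed

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _default_locus() -> StrLocus:
    # toy genome default: one 2-Mb chromosome with the STR at the midpoint
    return StrLocus("chrS", 1_000_000, 1_000_075, "ATTCT", name="simSTR")


@dataclass
class SimConfig:
    """Parameters of one simulated linked-read sample.

    Defaults describe the reference scenario used throughout the test suite:
    a 2-Mb chromosome carrying a heterozygous ATTCT expansion (15 vs 4000
    copies) at its midpoint, lognormal molecules averaging 50 kb, one molecule
    per barcode, and ~30x total paired 100-bp read coverage with no
    sequencing error.
    """

    reference_length: int = 2_000_000
    str_locus: StrLocus = field(default_factory=_default_locus)
    allele_repeat_counts: tuple[int, int] = (15, 4000)
    molecule_length_mean: float = 50_000.0
    molecule_length_model: str = "lognormal"
    molecule_length_sigma: float = 0.35  # lognormal shape (log-scale sd)
    molecules_per_barcode: int = 1
    barcode_pool_size: int = 8_000
    read_length: int = 100
    insert_size_mean: float = 350.0
    insert_size_sd: float = 50.0
    target_depth: float = 30.0
    substitution_error_rate: float = 0.0
    barcode_encoding: str = "bx-tag"  # or "read-name-suffix"
    unphased_molecule_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        loc = self.str_locus
        if loc.end > self.reference_length:
            raise ValueError("STR locus extends past the reference end")
        if loc.start < 1 or loc.end >= self.reference_length:
            raise ValueError("STR locus must leave at least 1 bp of flank")
        if any(c < 0 for c in self.allele_repeat_counts):
            raise ValueError("allele_repeat_counts must be >= 0")
        if len(self.allele_repeat_counts) != 2:
            raise ValueError("allele_repeat_counts must be a pair (one per haplotype)")
        if self.read_length < len(loc.motif):
            raise ValueError("read_length must be >= motif length")
        if self.target_depth <= 0:
            raise ValueError("target_depth must be > 0")
        if self.molecule_length_mean < self.read_length:
            raise ValueError("molecule_length_mean must be >= read_length")
        if self.molecule_length_model not in ("lognormal", "exponential"):
            raise ValueError(
                f"unsupported molecule_length_model {self.molecule_length_model!r}"
            )
        if self.barcode_encoding not in ("bx-tag", "read-name-suffix"):
            raise ValueError(f"unsupported barcode_encoding {self.barcode_encoding!r}")
        if not 0 <= self.substitution_error_rate < 1:
            raise ValueError("substitution_error_rate must be in [0, 1)")
        if not 0 <= self.unphased_molecule_fraction <= 1:
            raise ValueError("unphased_molecule_fraction must be in [0, 1]")
        if self.molecules_per_barcode < 1 or self.barcode_pool_size < 1:
            raise ValueError("molecules_per_barcode and barcode_pool_size must be >= 1")

    @property
    def n_molecules(self) -> int:
        return self.barcode_pool_size * self.molecules_per_barcode

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "str_locus" in d and isinstance(d["str_locus"], dict):
            d["str_locus"] = StrLocus(**d["str_locus"])
        if "allele_repeat_counts" in d:
            d["allele_repeat_counts"] = tuple(d["allele_repeat_counts"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["allele_repeat_counts"] = list(self.allele_repeat_counts)
        return d


@dataclass
class HaplotypePair:
    """Two haplotype sequences plus the coordinate lift onto the reference.

    Haplotype ``h`` equals the reference with the STR interval replaced by
    ``allele_repeat_counts[h]`` motif copies.  ``tract_start`` is shared;
    ``tract_end[h]`` and ``delta[h]`` (length change vs the reference
    interval) define a piecewise-linear lift from haplotype to reference
    coordinates.
    """

    reference: str
    haplotypes: tuple[str, str]
    locus: StrLocus
    tract_start: int
    tract_end: tuple[int, int]
    delta: tuple[int, int]

    def hap_to_ref(self, hap: int, pos: int) -> int:
        """Lift a haplotype coordinate to the reference (positions inside the
        tract lift to the tract start)."""
        h = hap - 1
        if pos < self.tract_start:
            return pos
        if pos >= self.tract_end[h]:
            return pos - self.delta[h]
        return self.tract_start


def _random_sequence(rng: np.random.Generator, n: int) -> np.ndarray:
    return np.frombuffer(b"ACGT", dtype="S1")[rng.integers(0, 4, size=n)].copy()


def build_reference(config: SimConfig, rng: np.random.Generator) -> str:
    """Random toy chromosome with a motif-filled repeat tract at the locus.

    The bases immediately flanking the tract are constrained not to continue
    the motif concatenation, so the repeat has well-defined boundaries (as a
    curated locus definition does): a read is pure repeat iff it lies wholly
    inside the tract.
    """
    loc = config.str_locus
    arr = _random_sequence(rng, config.reference_length)
    m = len(loc.motif)
    fill = (loc.motif * (loc.length // m + 1))[: loc.length]
    arr[loc.start : loc.end] = np.frombuffer(fill.encode(), dtype="S1")
    # guard bases: left neighbour must not extend the motif leftwards,
    # right neighbour must not extend it rightwards on either allele phase
    left_excl = {loc.motif[-1]}
    right_excl = {loc.motif[0], loc.motif[loc.length % m]}
    left_ok = sorted(set("ACGT") - left_excl)
    right_ok = sorted(set("ACGT") - right_excl)
    arr[loc.start - 1] = left_ok[rng.integers(len(left_ok))].encode()
    if loc.end < config.reference_length:
        arr[loc.end] = right_ok[rng.integers(len(right_ok))].encode()
    return arr.tobytes().decode()


def build_haplotypes(config: SimConfig, reference: str | None = None,
                     rng: np.random.Generator | None = None) -> HaplotypePair:
    """Construct the two haplotype sequences and the coordinate lift table."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if reference is None:
        reference = build_reference(config, rng)
    loc = config.str_locus
    m = len(loc.motif)
    haps, tract_end, delta = [], [], []
    for count in config.allele_repeat_counts:
        tract = loc.motif * count
        haps.append(reference[: loc.start] + tract + reference[loc.end :])
        tract_end.append(loc.start + count * m)
        delta.append(count * m - loc.length)
    return HaplotypePair(
        reference=reference,
        haplotypes=(haps[0], haps[1]),
        locus=loc,
        tract_start=loc.start,
        tract_end=(tract_end[0], tract_end[1]),
        delta=(delta[0], delta[1]),
    )


@dataclass
class TrueMolecule:
    """A simulated barcoded DNA fragment (coordinates on its haplotype)."""

    molecule_id: int
    barcode: str
    haplotype: int  # 1 or 2
    start: int
    end: int
    phased: bool  # whether reads of this molecule carry an HP tag

    @property
    def length(self) -> int:
        return self.end - self.start


def _barcode_pool(config: SimConfig) -> list[str]:
    n = config.barcode_pool_size
    if config.barcode_encoding == "read-name-suffix":
        # stLFR-style triplets, 1-based so the null barcode 0_0_0 never occurs
        return [
            f"{i % 1536 + 1}_{i // 1536 % 1536 + 1}_{i // 1536 ** 2 + 1}"
            for i in range(n)
        ]
    digits = max(8, int(np.ceil(np.log(max(n, 2)) / np.log(4))))
    bases = "ACGT"
    pool = []
    for i in range(n):
        code = [bases[(i >> (2 * k)) & 3] for k in range(digits)]
        pool.append("".join(reversed(code)) + "-1")
    return pool


def simulate_molecules(config: SimConfig, haplotypes: HaplotypePair,
                       rng: np.random.Generator | None = None) -> list[TrueMolecule]:
    """Draw barcoded molecules: uniform starts, configured length model,
    random haplotype of origin, ``molecules_per_barcode`` molecules per
    barcode placed independently."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = config.n_molecules
    if config.molecule_length_model == "lognormal":
        sigma = config.molecule_length_sigma
        mu = np.log(config.molecule_length_mean) - sigma**2 / 2
        lengths = rng.lognormal(mu, sigma, size=n)
    else:
        lengths = rng.exponential(config.molecule_length_mean, size=n)
    lengths = np.maximum(lengths.astype(np.int64), config.read_length)
    hap = rng.integers(1, 3, size=n)
    phased = rng.random(size=n) >= config.unphased_molecule_fraction
    pool = _barcode_pool(config)
    hap_lens = np.array([len(h) for h in haplotypes.haplotypes])
    lengths = np.minimum(lengths, hap_lens[hap - 1])
    starts = (rng.random(size=n) * (hap_lens[hap - 1] - lengths + 1)).astype(np.int64)
    return [
        TrueMolecule(
            molecule_id=i,
            barcode=pool[i // config.molecules_per_barcode],
            haplotype=int(hap[i]),
            start=int(starts[i]),
            end=int(starts[i] + lengths[i]),
            phased=bool(phased[i]),
        )
        for i in range(n)
    ]


@dataclass
class SimOutput:
    """File paths and in-memory truth for one simulated dataset."""

    config: SimConfig
    reference_fasta: str
    locus_bed: str
    fastq1: str
    fastq2: str
    bam: str | None
    truth_tsv: str
    truth: pd.DataFrame
    haplotypes: HaplotypePair
    molecules: list[TrueMolecule]


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    if hits.size == 0:
        return seq
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return arr.tobytes().decode()


def simulate_reads(config: SimConfig, haplotypes: HaplotypePair,
                   molecules: list[TrueMolecule], outdir: str,
                   prefix: str = "sim", fastq_only: bool = False,
                   rng: np.random.Generator | None = None) -> SimOutput:
    """Sample FR read pairs along molecules and write FASTQ + truth BAM + TSV.

    Pairs are placed uniformly along each molecule at a rate that yields
    ``target_depth`` total coverage of the reference.  Read 1 is the
    leftmost (forward) mate.  With the seed fixed the outputs are
    byte-identical across runs (gzip members are written with zeroed
    timestamps and the BAM is emitted directly in coordinate order).
    """
    config.validate()
    if not molecules:
        raise ValueError("no molecules to sample reads from")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    os.makedirs(outdir, exist_ok=True)
    loc = config.str_locus
    r = config.read_length

    mol_start = np.array([m.start for m in molecules], dtype=np.int64)
    mol_end = np.array([m.end for m in molecules], dtype=np.int64)
    mol_hap = np.array([m.haplotype for m in molecules], dtype=np.int8)
    mol_phased = np.array([m.phased for m in molecules], dtype=bool)
    mol_len = mol_end - mol_start
    total_mol_bases = int(mol_len.sum())

    pair_rate = (config.target_depth * config.reference_length
                 / (2.0 * r) / total_mol_bases)
    n_pairs_per_mol = rng.poisson(mol_len * pair_rate)
    n_pairs = int(n_pairs_per_mol.sum())
    if n_pairs == 0:
        raise ValueError("configuration yields zero read pairs")
    midx = np.repeat(np.arange(len(molecules)), n_pairs_per_mol)

    frag = rng.normal(config.insert_size_mean, config.insert_size_sd, size=n_pairs)
    frag = np.clip(np.rint(frag).astype(np.int64), r, mol_len[midx])
    fstart = mol_start[midx] + (
        rng.random(n_pairs) * (mol_len[midx] - frag + 1)
    ).astype(np.int64)
    fend = fstart + frag

    hapidx = mol_hap[midx] - 1  # 0/1
    ts = haplotypes.tract_start
    te = np.array(haplotypes.tract_end, dtype=np.int64)[hapidx]
    dl = np.array(haplotypes.delta, dtype=np.int64)[hapidx]

    def _map(s: np.ndarray, e: np.ndarray):
        """Truth-alignment geometry for reads [s, e) on their haplotype."""
        nontriv = dl != 0
        irr = (s >= ts) & (e <= te)
        unmapped = irr & nontriv
        pos = np.where(s >= te, s - dl, s).astype(np.int64)
        mlen = (e - s).astype(np.int64)
        slen = np.zeros_like(mlen)
        sfirst = np.zeros(len(s), dtype=bool)
        left = nontriv & (s < ts) & (e > ts)  # includes reads spanning the tract
        pos[left] = s[left]
        mlen[left] = ts - s[left]
        slen[left] = e[left] - ts
        right = nontriv & (s >= ts) & (s < te) & (e > te)
        pos[right] = (te - dl)[right]  # == locus.end on the reference
        mlen[right] = (e - te)[right]
        slen[right] = (te - s)[right]
        sfirst[right] = True
        return pos, mlen, slen, sfirst, unmapped, irr

    s1, e1 = fstart, fstart + r
    s2, e2 = fend - r, fend
    pos1, m1, sl1, sf1, un1, irr1 = _map(s1, e1)
    pos2, m2, sl2, sf2, un2, irr2 = _map(s2, e2)

    barcodes = np.array([m.barcode for m in molecules])
    bx_mode = config.barcode_encoding == "bx-tag"
    if bx_mode:
        names = [f"{prefix}{k:08d}" for k in range(n_pairs)]
    else:
        bc_by_pair = barcodes[midx]
        names = [f"{prefix}{k:08d}#{bc_by_pair[k]}" for k in range(n_pairs)]

    haps = haplotypes.haplotypes
    err = config.substitution_error_rate
    fwd1: list[str] = []
    fwd2: list[str] = []
    for k in range(n_pairs):
        h = hapidx[k]
        a = haps[h][s1[k] : e1[k]]
        b = haps[h][s2[k] : e2[k]]
        if err > 0:
            a = _mutate(a, err, rng)
            b = _mutate(b, err, rng)
        fwd1.append(a)
        fwd2.append(b)

    qual = "I" * r
    fq1_path = os.path.join(outdir, f"{prefix}_R1.fastq.gz")
    fq2_path = os.path.join(outdir, f"{prefix}_R2.fastq.gz")
    pair_bc = barcodes[midx]
    for path, seqs, rc in ((fq1_path, fwd1, False), (fq2_path, fwd2, True)):
        with open(path, "wb") as raw, gzip.GzipFile(
            filename="", mode="wb", fileobj=raw, mtime=0, compresslevel=4
        ) as gz:
            chunk: list[str] = []
            for k in range(n_pairs):
                seq = revcomp(seqs[k]) if rc else seqs[k]
                header = f"@{names[k]}"
                if bx_mode:
                    header += f" BX:Z:{pair_bc[k]}"
                chunk.append(f"{header}\n{seq}\n+\n{qual}\n")
                if len(chunk) >= 20_000:
                    gz.write("".join(chunk).encode())
                    chunk = []
            gz.write("".join(chunk).encode())

    # truth table: one record per mate
    truth = pd.DataFrame(
        {
            "read_id": np.repeat(names, 2),
            "mate": np.tile([1, 2], n_pairs),
            "barcode": np.repeat(pair_bc, 2),
            "haplotype": np.repeat(mol_hap[midx], 2),
            "phased": np.repeat(mol_phased[midx], 2),
            "molecule_id": np.repeat(midx, 2),
            "hap_start": np.stack([s1, s2], axis=1).ravel(),
            "hap_end": np.stack([e1, e2], axis=1).ravel(),
            "ref_start": np.stack(
                [np.where(un1, -1, pos1), np.where(un2, -1, pos2)], axis=1
            ).ravel(),
            "is_irr": np.stack([irr1, irr2], axis=1).ravel(),
        }
    )
    truth_path = os.path.join(outdir, f"{prefix}_truth.tsv")
    truth.to_csv(truth_path, sep="\t", index=False)

    bam_path = None
    if not fastq_only:
        bam_path = os.path.join(outdir, f"{prefix}.bam")
        _write_truth_bam(
            bam_path, config, names, fwd1, fwd2, pair_bc,
            mol_phased[midx], mol_hap[midx], midx,
            pos1, m1, sl1, sf1, un1, pos2, m2, sl2, sf2, un2, qual,
        )

    ref_path = os.path.join(outdir, "ref.fa")
    write_reference_fasta(haplotypes.reference, loc.chrom, ref_path)
    bed_path = os.path.join(outdir, "target.bed")
    write_loci_bed([loc], bed_path)

    return SimOutput(
        config=config, reference_fasta=ref_path, locus_bed=bed_path,
        fastq1=fq1_path, fastq2=fq2_path, bam=bam_path,
        truth_tsv=truth_path, truth=truth,
        haplotypes=haplotypes, molecules=molecules,
    )


def write_reference_fasta(reference: str, chrom: str, path: str,
                          width: int = 60) -> None:
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(reference), width):
            fh.write(reference[i : i + width] + "\n")
    pysam.faidx(path)


def _write_truth_bam(bam_path, config, names, fwd1, fwd2, pair_bc,
                     pair_phased, pair_hap, midx,
                     pos1, m1, sl1, sf1, un1, pos2, m2, sl2, sf2, un2, qual):
    n_pairs = len(names)
    r = config.read_length
    bx_mode = config.barcode_encoding == "bx-tag"
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": config.str_locus.chrom, "LN": config.reference_length}],
        }
    )
    # effective sort position: unmapped reads sit at their mapped mate's
    # coordinate; fully unmapped pairs go to the end of the file
    big = np.int64(1) << 42
    eff1 = np.where(un1, np.where(un2, big, pos2), pos1)
    eff2 = np.where(un2, np.where(un1, big, pos1), pos2)
    serial = np.arange(2 * n_pairs)
    eff = np.stack([eff1, eff2], axis=1).ravel()
    order = np.lexsort((serial, eff))

    with pysam.AlignmentFile(bam_path, "wb", header=header) as bam:
        for idx in order:
            k, mate = divmod(idx, 2)
            if mate == 0:
                pos, mlen, slen, sfirst, unm = pos1[k], m1[k], sl1[k], sf1[k], un1[k]
                mate_pos, mate_unm = pos2[k], un2[k]
                seq = fwd1[k]
                reverse = False
            else:
                pos, mlen, slen, sfirst, unm = pos2[k], m2[k], sl2[k], sf2[k], un2[k]
                mate_pos, mate_unm = pos1[k], un1[k]
                seq = fwd2[k]
                reverse = True
            a = pysam.AlignedSegment(header)
            a.query_name = names[k]
            flag = 0x1 | (0x40 if mate == 0 else 0x80)
            if unm:
                flag |= 0x4
                if reverse:
                    seq = revcomp(seq)  # unmapped: stored as sequenced
            else:
                if reverse:
                    flag |= 0x10
            if mate_unm:
                flag |= 0x8
            elif mate == 0:
                flag |= 0x20  # mate (read 2) on reverse strand
            if not unm and not mate_unm:
                flag |= 0x2  # proper pair
            a.flag = flag
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array(qual)
            if unm:
                a.reference_id = 0 if not mate_unm else -1
                a.reference_start = int(mate_pos) if not mate_unm else -1
                a.mapping_quality = 0
            else:
                a.reference_id = 0
                a.reference_start = int(pos)
                a.mapping_quality = 60
                if slen > 0:
                    cig = [(4, int(slen)), (0, int(mlen))] if sfirst else [
                        (0, int(mlen)), (4, int(slen))]
                else:
                    cig = [(0, int(mlen))]
                a.cigartuples = cig
            if mate_unm:
                a.next_reference_id = a.reference_id
                a.next_reference_start = a.reference_start
            else:
                a.next_reference_id = 0
                a.next_reference_start = int(mate_pos)
            if not unm and not mate_unm:
                left = min(int(pos), int(mate_pos))
                right = max(int(pos) + r, int(mate_pos) + r)
                a.template_length = (right - left) if int(pos) <= int(mate_pos) else -(right - left)
            tags = []
            if bx_mode:
                tags.append(("BX", str(pair_bc[k])))
            if pair_phased[k]:
                tags.append(("HP", int(pair_hap[k])))
            tags.append(("MI", int(midx[k])))
            a.set_tags(tags)
            bam.write(a)
    pysam.index(bam_path)


def simulate_dataset(config: SimConfig, outdir: str, prefix: str = "sim",
                     fastq_only: bool = False) -> SimOutput:
    """Run the full simulation: reference + haplotypes, molecules, reads."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    haplotypes = build_haplotypes(config, rng=rng)
    molecules = simulate_molecules(config, haplotypes, rng=rng)
    return simulate_reads(config, haplotypes, molecules, outdir,
                          prefix=prefix, fastq_only=fastq_only, rng=rng)
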