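"""Jaccard-index barcode-sharing size estimation of genomic intervals.

Large DNA molecules bridge genomic intervals stochastically: the shorter an
interval, the more molecules span both of its flanks.  For an interval we
take the 1-kb flanking regions immediately up- and downstream, collect the
barcodes whose reconstructed spans encompass each flank (BC_L, BC_R), and
summarise barcode sharing with the Jaccard index

    JI = |BC_L ∩ BC_R| / |BC_L ∪ BC_R|.

A database of (|BC_L|, |BC_R|, JI) profiles over many random positions and a
grid of interval sizes turns this into a size estimator: a test interval's
profile is matched against the database by Euclidean distance and the median
size of the nearest profiles is the estimate.  The method is sequence-free,
so it works where repeat reads cannot be recruited, but its resolution is
limited to kb-scale intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pysam
import yaml

from .barcodes import NULL_BARCODES, UNPHASED, parse_barcode, detect_encoding
from .irr import SizeEstimate
from .loci import StrLocus

logger = logging.getLogger(__name__)

DEFAULT_FLANK_BP = 1_000
DEFAULT_COLLECT_BP = 5_000

#: interval-size grids (bp): "small" suits sub-4-kb alleles, "large" suits
#: multi-kb expansions
GRID_PRESETS: dict[str, np.ndarray] = {
    "small": np.arange(200, 4_001, 100),
    "large": np.arange(5_000, 40_001, 500),
}

#: default nearest-profile distance thresholds, matched to the count scale
#: of each grid
F_DEFAULTS = {"small": 4.0, "large": 200.0}


@dataclass
class FlankProfile:
    """The (|BC_L|, |BC_R|, JI) tuple for one genomic interval."""

    chrom: str
    start: int
    end: int
    n_left: int
    n_right: int
    ji: float
    haplotype: int = UNPHASED  # 0 = all alignments

    @property
    def size(self) -> int:
        return self.end - self.start

    @property
    def tuple(self) -> tuple[int, int, float]:
        return (self.n_left, self.n_right, self.ji)


def jaccard(bc_left, bc_right) -> float:
    """Jaccard index of two barcode collections; 0 when both are empty."""
    a, b = set(bc_left), set(bc_right)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


class BarcodeSpanIndex:
    """In-memory index of all barcoded alignments of one sample.

    Holds per-chromosome arrays of alignment (start, end, barcode code,
    HP tag) sorted by start so that barcode spans over arbitrary collection
    windows can be recomputed quickly.  Built once per BAM; all alignments
    with a barcode count (no pairing/clipping filter — molecule bridging is
    a property of every mapped read).
    """

    def __init__(self, chrom_data: dict[str, dict[str, np.ndarray]],
                 chrom_lengths: dict[str, int], max_read_len: int):
        self._data = chrom_data
        self.chrom_lengths = chrom_lengths
        self._max_read_len = max_read_len

    @classmethod
    def from_bam(cls, bam_path: str, encoding: str | None = None) -> "BarcodeSpanIndex":
        with pysam.AlignmentFile(bam_path) as af:
            if encoding is None:
                encoding = detect_encoding(bam_path)
            chrom_lengths = dict(zip(af.references, af.lengths))
            bc_codes: dict[str, int] = {}
            per_chrom: dict[str, list[list[int]]] = {
                c: [[], [], [], []] for c in af.references
            }
            max_len = 1
            for read in af.fetch(until_eof=False):
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    continue
                bc = parse_barcode(read, encoding)
                if bc is None:
                    continue
                code = bc_codes.setdefault(bc, len(bc_codes))
                hp = read.get_tag("HP") if read.has_tag("HP") else UNPHASED
                cols = per_chrom[read.reference_name]
                cols[0].append(read.reference_start)
                cols[1].append(read.reference_end)
                cols[2].append(code)
                cols[3].append(hp)
                max_len = max(max_len, read.reference_end - read.reference_start)
        data = {}
        for chrom, cols in per_chrom.items():
            starts = np.asarray(cols[0], dtype=np.int64)
            order = np.argsort(starts, kind="stable")
            data[chrom] = {
                "start": starts[order],
                "end": np.asarray(cols[1], dtype=np.int64)[order],
                "bc": np.asarray(cols[2], dtype=np.int64)[order],
                "hp": np.asarray(cols[3], dtype=np.int8)[order],
            }
        return cls(data, chrom_lengths, max_len)

    def reads_in(self, chrom: str, ws: int, we: int,
                 haplotype: int | None = None):
        """Alignments overlapping [ws, we) as (start, end, barcode-code)."""
        if chrom not in self._data:
            raise ValueError(f"contig {chrom!r} absent from index")
        d = self._data[chrom]
        lo = np.searchsorted(d["start"], ws - self._max_read_len, side="left")
        hi = np.searchsorted(d["start"], we, side="left")
        s, e, bc = d["start"][lo:hi], d["end"][lo:hi], d["bc"][lo:hi]
        mask = e > ws
        if haplotype is not None and haplotype != UNPHASED:
            mask &= d["hp"][lo:hi] == haplotype
        return s[mask], e[mask], bc[mask]

    def flank_set(self, chrom: str, flank_start: int, flank_end: int,
                  collect_bp: int = DEFAULT_COLLECT_BP,
                  haplotype: int | None = None,
                  containment: bool = True) -> np.ndarray:
        """Barcode codes whose span (within the collection window around the
        flank) encompasses the flank.

        The span of each barcode is the first/last alignment coordinate among
        alignments collected within ``collect_bp`` of the flank.  With
        ``containment=False`` any span overlapping the flank qualifies.
        """
        if chrom not in self._data:
            raise ValueError(f"contig {chrom!r} absent from index")
        ws = max(0, flank_start - collect_bp)
        we = min(self.chrom_lengths[chrom], flank_end + collect_bp)
        s, e, bc = self.reads_in(chrom, ws, we, haplotype)
        if bc.size == 0:
            return np.empty(0, dtype=np.int64)
        # group by barcode keeping starts ascending within each group: one
        # unstable sort on the composite (barcode, start-offset) key
        base = ws - self._max_read_len
        order = np.argsort((bc << 32) | (s - base))
        bs = bc[order]
        ss = s[order]
        boundaries = np.flatnonzero(np.diff(bs)) + 1
        first = np.empty(boundaries.size + 1, dtype=np.int64)
        first[0] = 0
        first[1:] = boundaries
        codes = bs[first]
        span_min = ss[first]
        span_max = np.maximum.reduceat(e[order], first)
        if containment:
            keep = (span_min <= flank_start) & (span_max >= flank_end)
        else:
            keep = (span_min < flank_end) & (span_max > flank_start)
        return codes[keep]


def flank_barcodes(alignments, chrom: str, start: int, end: int,
                   flank_bp: int = DEFAULT_FLANK_BP,
                   collect_bp: int = DEFAULT_COLLECT_BP,
                   haplotype: int | None = None,
                   containment: bool = True):
    """Barcode sets spanning the left/right flanks of the interval [start, end).

    ``alignments`` may be a :class:`BarcodeSpanIndex` (fast path) or a path
    to an indexed BAM (a transient index is built).
    """
    index = (alignments if isinstance(alignments, BarcodeSpanIndex)
             else BarcodeSpanIndex.from_bam(alignments))
    bc_l = index.flank_set(chrom, max(0, start - flank_bp), start,
                           collect_bp, haplotype, containment)
    bc_r = index.flank_set(chrom, end, min(index.chrom_lengths[chrom], end + flank_bp),
                           collect_bp, haplotype, containment)
    return bc_l, bc_r


def interval_profile(index: BarcodeSpanIndex, chrom: str, start: int, end: int,
                     flank_bp: int = DEFAULT_FLANK_BP,
                     collect_bp: int = DEFAULT_COLLECT_BP,
                     haplotype: int | None = None,
                     containment: bool = True) -> FlankProfile:
    bc_l, bc_r = flank_barcodes(index, chrom, start, end, flank_bp,
                                collect_bp, haplotype, containment)
    ji = 0.0
    if bc_l.size and bc_r.size:
        shared = np.intersect1d(bc_l, bc_r, assume_unique=True).size
        ji = shared / (bc_l.size + bc_r.size - shared)
    return FlankProfile(
        chrom=chrom, start=start, end=end,
        n_left=int(bc_l.size), n_right=int(bc_r.size), ji=float(ji),
        haplotype=haplotype if haplotype is not None else UNPHASED,
    )


# ---------------------------------------------------------------------------
# database

@dataclass
class IntervalDatabase:
    """Flank profiles at random positions x a grid of interval sizes."""

    chrom: np.ndarray       # str array
    pos: np.ndarray         # int64, interval start
    size: np.ndarray        # int64
    n_left: np.ndarray      # int64
    n_right: np.ndarray     # int64
    ji: np.ndarray          # float64
    haplotype: np.ndarray   # int8
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.pos.size

    def subset_haplotype(self, haplotype: int) -> "IntervalDatabase":
        m = self.haplotype == haplotype
        return IntervalDatabase(self.chrom[m], self.pos[m], self.size[m],
                                self.n_left[m], self.n_right[m], self.ji[m],
                                self.haplotype[m], self.metadata)

    def save(self, path: str) -> None:
        """Headered TSV plus a YAML metadata sidecar (``<path>.meta.yaml``)."""
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tsize\tn_left\tn_right\tji\thaplotype\n")
            for i in range(len(self)):
                fh.write(
                    f"{self.chrom[i]}\t{self.pos[i]}\t{self.size[i]}\t"
                    f"{self.n_left[i]}\t{self.n_right[i]}\t"
                    f"{self.ji[i]:.6g}\t{self.haplotype[i]}\n"
                )
        with open(path + ".meta.yaml", "w") as fh:
            yaml.safe_dump(self.metadata, fh, sort_keys=True)

    @classmethod
    def load(cls, path: str) -> "IntervalDatabase":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        metadata = {}
        try:
            with open(path + ".meta.yaml") as fh:
                metadata = yaml.safe_load(fh) or {}
        except FileNotFoundError:
            pass
        return cls(
            chrom=df["chrom"].to_numpy(dtype=object),
            pos=df["pos"].to_numpy(dtype=np.int64),
            size=df["size"].to_numpy(dtype=np.int64),
            n_left=df["n_left"].to_numpy(dtype=np.int64),
            n_right=df["n_right"].to_numpy(dtype=np.int64),
            ji=df["ji"].to_numpy(dtype=float),
            haplotype=df["haplotype"].to_numpy(dtype=np.int8),
            metadata=metadata,
        )


def _read_bed_intervals(path: str) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.setdefault(f[0], []).append((int(f[1]), int(f[2])))
    return out


def _allowed_positions(chrom_lengths: dict[str, int], margin_left: int,
                       margin_right: int,
                       exclusion: dict[str, list[tuple[int, int]]] | None):
    """Per-chromosome allowed start ranges after margins and exclusions."""
    ranges: list[tuple[str, int, int]] = []
    for chrom, clen in chrom_lengths.items():
        lo, hi = margin_left, clen - margin_right
        if hi <= lo:
            continue
        segs = [(lo, hi)]
        for (es, ee) in sorted((exclusion or {}).get(chrom, [])):
            nxt = []
            for (s, e) in segs:
                if ee <= s or es >= e:
                    nxt.append((s, e))
                    continue
                if es > s:
                    nxt.append((s, es))
                if ee < e:
                    nxt.append((ee, e))
            segs = nxt
        ranges.extend((chrom, s, e) for s, e in segs)
    return ranges


def build_database(alignments, n_positions: int,
                   grid: "str | np.ndarray" = "large",
                   seed: int = 0,
                   exclusion_bed: str | None = None,
                   haplotype_mode: str = "all",
                   flank_bp: int = DEFAULT_FLANK_BP,
                   collect_bp: int = DEFAULT_COLLECT_BP,
                   containment: bool = True) -> IntervalDatabase:
    """Profile ``n_positions`` random genome positions over a size grid.

    Positions are drawn uniformly without replacement from the allowed
    regions (contigs minus the exclusion BED, minus margins so every
    interval plus flanks and collection windows fits).  In
    ``haplotype_mode="phased"`` a profile is computed per haplotype from
    HP-tagged alignments only.  Deterministic under a fixed seed.
    """
    index = (alignments if isinstance(alignments, BarcodeSpanIndex)
             else BarcodeSpanIndex.from_bam(alignments))
    grid_name = grid if isinstance(grid, str) else "custom"
    sizes = np.asarray(GRID_PRESETS[grid] if isinstance(grid, str) else grid,
                       dtype=np.int64)
    if sizes.size == 0 or np.any(np.diff(sizes) <= 0):
        raise ValueError("grid must be a strictly increasing, non-empty size list")
    exclusion = _read_bed_intervals(exclusion_bed) if exclusion_bed else None
    margin = flank_bp + collect_bp
    ranges = _allowed_positions(index.chrom_lengths, margin,
                                int(sizes.max()) + margin, exclusion)
    total = sum(e - s for _, s, e in ranges)
    if total < n_positions:
        raise ValueError(
            f"allowed region ({total} bp) too small for {n_positions} positions"
        )
    rng = np.random.default_rng(seed)
    draws = np.sort(rng.choice(total, size=n_positions, replace=False))
    positions: list[tuple[str, int]] = []
    offset = 0
    it = iter(ranges)
    chrom, s, e = next(it)
    for d in draws:
        while d >= offset + (e - s):
            offset += e - s
            chrom, s, e = next(it)
        positions.append((chrom, s + int(d - offset)))

    haplotypes = [UNPHASED] if haplotype_mode == "all" else [1, 2]
    cols: dict[str, list] = {k: [] for k in
                             ("chrom", "pos", "size", "n_left", "n_right", "ji", "hap")}
    for hap in haplotypes:
        hap_arg = None if hap == UNPHASED else hap
        for chrom, pos in positions:
            # the left flank is shared across the size grid at one position
            bc_l = index.flank_set(chrom, pos - flank_bp, pos, collect_bp,
                                   hap_arg, containment)
            for size in sizes:
                end = pos + int(size)
                bc_r = index.flank_set(chrom, end, end + flank_bp, collect_bp,
                                       hap_arg, containment)
                ji = 0.0
                if bc_l.size and bc_r.size:
                    shared = np.intersect1d(bc_l, bc_r, assume_unique=True).size
                    ji = shared / (bc_l.size + bc_r.size - shared)
                cols["chrom"].append(chrom)
                cols["pos"].append(pos)
                cols["size"].append(int(size))
                cols["n_left"].append(int(bc_l.size))
                cols["n_right"].append(int(bc_r.size))
                cols["ji"].append(float(ji))
                cols["hap"].append(hap)
    metadata = {
        "n_positions": n_positions,
        "grid": grid_name,
        "grid_sizes": [int(x) for x in sizes],
        "flank_bp": flank_bp,
        "collect_bp": collect_bp,
        "haplotype_mode": haplotype_mode,
        "containment": bool(containment),
        "exclusion_bed": exclusion_bed,
        "seed": seed,
    }
    return IntervalDatabase(
        chrom=np.asarray(cols["chrom"], dtype=object),
        pos=np.asarray(cols["pos"], dtype=np.int64),
        size=np.asarray(cols["size"], dtype=np.int64),
        n_left=np.asarray(cols["n_left"], dtype=np.int64),
        n_right=np.asarray(cols["n_right"], dtype=np.int64),
        ji=np.asarray(cols["ji"], dtype=float),
        haplotype=np.asarray(cols["hap"], dtype=np.int8),
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# nearest-profile size estimation

@dataclass
class JiQueryParams:
    """Nearest-profile retrieval parameters.

    ``e``: number of most-similar database profiles retained.  ``f``:
    Euclidean distance threshold on the raw (n_left, n_right, ji) tuple;
    when fewer than ``e`` profiles fall within ``f`` it is enlarged by
    ``f_growth`` up to ``f_max_doublings`` times (progressive search).
    """

    e: int = 200
    f: float = 200.0
    f_growth: float = 2.0
    f_max_doublings: int = 5

    def __post_init__(self) -> None:
        if self.e < 1 or self.f <= 0:
            raise ValueError("require E >= 1 and F > 0")


def estimate_size_ji(profile: FlankProfile, db: IntervalDatabase,
                     params: JiQueryParams | None = None,
                     haplotype: int | None = None) -> SizeEstimate:
    """Median (+ inter-quartile range) size of the database profiles nearest
    to the test profile.

    Returns a :class:`SizeEstimate` with ``size_bp=None`` when no database
    profile lies within the final distance threshold (an explicit
    "no estimate" outcome).  Ties at the E-th distance break toward the
    smaller interval size, then database order, for deterministic output.
    """
    if params is None:
        params = JiQueryParams()
    if len(db) == 0:
        raise ValueError("empty interval database")
    if haplotype is not None:
        db = db.subset_haplotype(haplotype)
        if len(db) == 0:
            raise ValueError(f"database holds no haplotype-{haplotype} profiles")
    q = np.array([profile.n_left, profile.n_right, profile.ji], dtype=float)
    dist = np.sqrt(
        (db.n_left - q[0]) ** 2 + (db.n_right - q[1]) ** 2 + (db.ji - q[2]) ** 2
    )
    f = params.f
    within = np.nonzero(dist < f)[0]
    trials = 0
    while within.size < params.e and trials < params.f_max_doublings:
        f *= params.f_growth
        trials += 1
        within = np.nonzero(dist < f)[0]
    f_final = f
    if within.size == 0:
        return SizeEstimate(method="ji", haplotype=haplotype, size_bp=None,
                            extra={"n_retained": 0, "f_final": f_final,
                                   "profile": profile.tuple})
    order = np.lexsort((within, db.size[within], dist[within]))
    retained = within[order][: params.e]
    sizes = db.size[retained].astype(float)
    return SizeEstimate(
        method="ji", haplotype=haplotype,
        size_bp=float(np.median(sizes)),
        lower_bp=float(np.percentile(sizes, 25)),
        upper_bp=float(np.percentile(sizes, 75)),
        extra={"n_retained": int(retained.size), "f_final": float(f_final),
               "profile": profile.tuple},
    )


def genotype_locus_ji(alignments, locus: StrLocus, db: IntervalDatabase,
                      params: JiQueryParams | None = None,
                      haplotype_mode: str = "all",
                      flank_bp: int = DEFAULT_FLANK_BP,
                      collect_bp: int = DEFAULT_COLLECT_BP,
                      containment: bool = True) -> list[SizeEstimate]:
    """JI size estimate(s) of a target locus: the locus interval is the gap.

    Returns one estimate in ``"all"`` mode, or one per haplotype in
    ``"phased"`` mode.  The returned interval size (bp) is the allele-length
    estimate; dividing by the motif length gives repeat copies.  Alleles
    below the grid floor are beneath the method's resolution and are
    reported at the floor with a warning.
    """
    index = (alignments if isinstance(alignments, BarcodeSpanIndex)
             else BarcodeSpanIndex.from_bam(alignments))
    haps = [None] if haplotype_mode == "all" else [1, 2]
    grid_floor = int(db.size.min())
    out: list[SizeEstimate] = []
    for hap in haps:
        prof = interval_profile(index, locus.chrom, locus.start, locus.end,
                                flank_bp, collect_bp, hap, containment)
        est = estimate_size_ji(prof, db, params, haplotype=hap)
        est.motif_length = len(locus.motif)
        if est.size_bp is not None and est.size_bp <= grid_floor:
            logger.warning(
                "%s: estimate at the database grid floor (%d bp); alleles "
                "below ~1 kb are beneath the resolution of barcode-sharing "
                "size estimation", locus.region, grid_floor,
            )
        out.append(est)
    return out
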