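import math

import numpy as np
import pysam
import pytest
from scipy.stats import spearmanr

from linkstr.ji import (
    BarcodeSpanIndex,
    FlankProfile,
    IntervalDatabase,
    JiQueryParams,
    build_database,
    estimate_size_ji,
    flank_barcodes,
    genotype_locus_ji,
    interval_profile,
    jaccard,
)


class TestJaccard:
    def test_set_identities(self):
        assert jaccard({"a", "b", "c"}, {"b", "c", "d"}) == 0.5
        assert jaccard({"a", "b"}, {"a", "b"}) == 1.0
        assert jaccard({"a"}, {"b"}) == 0.0
        assert jaccard(set(), set()) == 0.0
        assert jaccard(set(), {"a"}) == 0.0

    def test_symmetric_and_bounded(self, rng):
        universe = np.arange(50)
        for _ in range(50):
            a = set(rng.choice(universe, rng.integers(0, 30), replace=False))
            b = set(rng.choice(universe, rng.integers(0, 30), replace=False))
            ji = jaccard(a, b)
            assert ji == jaccard(b, a)
            assert 0.0 <= ji <= 1.0


def brute_force_flank_sets(bam_path, chrom, start, end, flank_bp=1000,
                           collect_bp=5000, haplotype=None):
    """Nested-loop reconstruction of BC_L / BC_R from raw alignment records."""
    out = []
    for fs, fe in ((start - flank_bp, start), (end, end + flank_bp)):
        spans = {}
        with pysam.AlignmentFile(bam_path) as af:
            ws, we = max(0, fs - collect_bp), fe + collect_bp
            for r in af.fetch(chrom, max(0, ws - 500), we + 500):
                if r.is_unmapped or r.is_secondary or r.is_supplementary:
                    continue
                if r.reference_end <= ws or r.reference_start >= we:
                    continue
                if haplotype is not None and (
                        not r.has_tag("HP") or r.get_tag("HP") != haplotype):
                    continue
                bc = r.get_tag("BX") if r.has_tag("BX") else None
                if bc is None:
                    continue
                s, e = spans.get(bc, (math.inf, 0))
                spans[bc] = (min(s, r.reference_start), max(e, r.reference_end))
        out.append({bc for bc, (s, e) in spans.items() if s <= fs and e >= fe})
    return out


class TestFlankBarcodes:
    @pytest.mark.parametrize("start,end", [(80_000, 95_000), (220_000, 228_000)])
    def test_matches_brute_force(self, small_sim, start, end):
        idx = BarcodeSpanIndex.from_bam(small_sim.bam)
        bc_l, bc_r = flank_barcodes(idx, "chrS", start, end)
        exp_l, exp_r = brute_force_flank_sets(small_sim.bam, "chrS", start, end)
        got_l = {idx_code_to_barcode(small_sim, idx, c) for c in bc_l}
        got_r = {idx_code_to_barcode(small_sim, idx, c) for c in bc_r}
        assert (len(bc_l), len(bc_r)) == (len(exp_l), len(exp_r))
        assert got_l == exp_l and got_r == exp_r

    def test_haplotype_restriction_matches_brute_force(self, small_sim):
        idx = BarcodeSpanIndex.from_bam(small_sim.bam)
        bc_l, bc_r = flank_barcodes(idx, "chrS", 100_000, 110_000, haplotype=1)
        exp_l, exp_r = brute_force_flank_sets(small_sim.bam, "chrS",
                                              100_000, 110_000, haplotype=1)
        assert (len(bc_l), len(bc_r)) == (len(exp_l), len(exp_r))

    def test_containment_vs_overlap_modes(self, small_sim):
        idx = BarcodeSpanIndex.from_bam(small_sim.bam)
        strict = idx.flank_set("chrS", 80_000, 81_000, containment=True)
        loose = idx.flank_set("chrS", 80_000, 81_000, containment=False)
        assert set(strict) <= set(loose)

    def test_absent_contig_raises(self, small_sim):
        idx = BarcodeSpanIndex.from_bam(small_sim.bam)
        with pytest.raises(ValueError, match="absent"):
            idx.flank_set("chrZ", 0, 1000)


def idx_code_to_barcode(small_sim, idx, code):
    # code order is insertion order over the BAM; rebuild the mapping once
    if not hasattr(idx, "_code2bc"):
        mapping = {}
        with pysam.AlignmentFile(small_sim.bam) as af:
            codes = {}
            for r in af.fetch(until_eof=False):
                if r.is_unmapped or r.is_secondary or r.is_supplementary:
                    continue
                if r.has_tag("BX"):
                    bc = r.get_tag("BX")
                    if bc not in codes:
                        codes[bc] = len(codes)
                        mapping[codes[bc]] = bc
        idx._code2bc = mapping
    return idx._code2bc[code]


def toy_db(rows):
    """rows: (size, n_left, n_right, ji)"""
    n = len(rows)
    return IntervalDatabase(
        chrom=np.array(["c"] * n, dtype=object),
        pos=np.arange(n, dtype=np.int64),
        size=np.array([r[0] for r in rows], dtype=np.int64),
        n_left=np.array([r[1] for r in rows], dtype=np.int64),
        n_right=np.array([r[2] for r in rows], dtype=np.int64),
        ji=np.array([r[3] for r in rows], dtype=float),
        haplotype=np.zeros(n, dtype=np.int8),
    )


class TestEstimateSizeJi:
    def test_exact_match_dominates(self):
        db = toy_db([(1000, 50, 50, 0.8), (2000, 40, 42, 0.5), (3000, 30, 31, 0.3)])
        prof = FlankProfile("c", 0, 2000, 40, 42, 0.5)
        est = estimate_size_ji(prof, db, JiQueryParams(e=1, f=4.0))
        assert (est.size_bp, est.lower_bp, est.upper_bp) == (2000.0, 2000.0, 2000.0)

    def test_retains_e_nearest_within_f(self):
        # distances from query (10,10,0.5): 1, 1, 2, 9
        db = toy_db([(1000, 11, 10, 0.5), (2000, 10, 11, 0.5),
                     (3000, 10, 12, 0.5), (4000, 10, 19, 0.5)])
        est = estimate_size_ji(FlankProfile("c", 0, 0, 10, 10, 0.5), db,
                               JiQueryParams(e=3, f=4.0))
        assert est.extra["n_retained"] == 3
        assert est.size_bp == 2000.0  # median of {1000, 2000, 3000}

    def test_progressive_f_doubling(self):
        db = toy_db([(1000, 16, 10, 0.5), (2000, 10, 10, 0.5)])
        # nearest at distance 0, second at 6 > f=4: one doubling needed for E=2
        est = estimate_size_ji(FlankProfile("c", 0, 0, 10, 10, 0.5), db,
                               JiQueryParams(e=2, f=4.0))
        assert est.extra["n_retained"] == 2
        assert est.extra["f_final"] == 8.0

    def test_no_profile_within_final_f_gives_no_estimate(self):
        db = toy_db([(1000, 500, 500, 0.5)])
        est = estimate_size_ji(FlankProfile("c", 0, 0, 10, 10, 0.5), db,
                               JiQueryParams(e=1, f=4.0, f_max_doublings=2))
        assert est.size_bp is None
        assert est.extra["n_retained"] == 0

    def test_agrees_with_brute_force_search(self, rng):
        """Nearest-profile retrieval equals an independent nested-loop oracle
        (distances, progressive F, E-truncation with size/order tie-break)."""
        for _ in range(20):
            n = int(rng.integers(5, 400))
            rows = [(int(rng.integers(1, 50)) * 100, int(rng.integers(0, 40)),
                     int(rng.integers(0, 40)), float(rng.random())) for _ in range(n)]
            db = toy_db(rows)
            q = (int(rng.integers(0, 40)), int(rng.integers(0, 40)), float(rng.random()))
            params = JiQueryParams(e=int(rng.integers(1, 20)), f=4.0)
            est = estimate_size_ji(FlankProfile("c", 0, 0, *q), db, params)
            # oracle
            dists = [math.dist(q, (nl, nr, ji)) for _, nl, nr, ji in rows]
            f = params.f
            for _ in range(params.f_max_doublings + 1):
                within = [i for i, d in enumerate(dists) if d < f]
                if len(within) >= params.e:
                    break
                f *= params.f_growth
            within = [i for i, d in enumerate(dists) if d < f]
            within.sort(key=lambda i: (dists[i], rows[i][0], i))
            kept = [rows[i][0] for i in within[: params.e]]
            if not kept:
                assert est.size_bp is None
            else:
                assert est.size_bp == float(np.median(kept))
                assert est.extra["n_retained"] == len(kept)


class TestDatabase:
    def test_profile_count_is_positions_times_grid(self, small_sim):
        grid = np.array([2000, 4000, 6000, 8000, 10000])
        db = build_database(small_sim.bam, n_positions=10, grid=grid, seed=3)
        assert len(db) == 50
        for s in grid:
            assert (db.size == s).sum() == 10

    def test_deterministic_under_fixed_seed(self, small_sim, tmp_path):
        grid = np.array([2000, 5000, 8000])
        dbs = []
        for run in ("x", "y"):
            db = build_database(small_sim.bam, n_positions=25, grid=grid, seed=9)
            path = tmp_path / f"{run}.tsv"
            db.save(str(path))
            dbs.append(path.read_bytes())
        assert dbs[0] == dbs[1]

    def test_save_load_round_trip(self, small_sim, tmp_path):
        db = build_database(small_sim.bam, n_positions=5,
                            grid=np.array([2000, 4000]), seed=2)
        path = str(tmp_path / "db.tsv")
        db.save(path)
        back = IntervalDatabase.load(path)
        np.testing.assert_array_equal(db.pos, back.pos)
        np.testing.assert_array_equal(db.size, back.size)
        np.testing.assert_allclose(db.ji, back.ji, atol=1e-6)
        assert back.metadata["n_positions"] == 5

    def test_mean_ji_non_increasing_with_interval_size(self, small_sim):
        """Barcode sharing decays with genomic distance: over >= 200 random
        positions the mean JI is monotone non-increasing across the grid."""
        grid = np.arange(2000, 20_001, 2_000)
        with open(small_sim.truth_tsv + ".excl.bed", "w") as fh:
            fh.write("chrS\t110000\t190000\n")
        db = build_database(small_sim.bam, n_positions=220, grid=grid, seed=4,
                            exclusion_bed=small_sim.truth_tsv + ".excl.bed")
        means = [db.ji[db.size == s].mean() for s in grid]
        assert all(a >= b for a, b in zip(means, means[1:]))
        rho = spearmanr(grid, means).statistic
        assert rho < -0.99

    def test_too_small_allowed_region_raises(self, small_sim):
        with pytest.raises(ValueError, match="too small"):
            build_database(small_sim.bam, n_positions=10**6,
                           grid=np.array([2000]), seed=0)

    def test_grid_must_increase(self, small_sim):
        with pytest.raises(ValueError, match="grid"):
            build_database(small_sim.bam, n_positions=5,
                           grid=np.array([3000, 2000]), seed=0)


@pytest.fixture(scope="module")
def phased_db(small_sim):
    grid = np.arange(2000, 20_001, 1_000)
    with open(small_sim.truth_tsv + ".jexcl.bed", "w") as fh:
        fh.write("chrS\t110000\t190000\n")
    idx = BarcodeSpanIndex.from_bam(small_sim.bam)
    db = build_database(idx, n_positions=280, grid=grid, seed=6,
                        exclusion_bed=small_sim.truth_tsv + ".jexcl.bed",
                        haplotype_mode="phased")
    return idx, db


class TestGenotypeLocusJi:

    def test_expanded_haplotype_sized_near_truth(self, small_sim, phased_db):
        """Heterozygous 800-copy ATTCT allele (4 kb): the phased JI estimate
        of the expanded haplotype recovers the kb scale of the expansion."""
        idx, db = phased_db
        ests = genotype_locus_ji(idx, small_sim.config.str_locus, db,
                                 JiQueryParams(e=30, f=200.0),
                                 haplotype_mode="phased")
        by_hap = {e.haplotype: e for e in ests}
        est2 = by_hap[2].size_bp
        assert est2 is not None
        assert 2_000 <= est2 <= 8_000  # truth 4,000 bp
        assert by_hap[2].repeat_count_estimate == pytest.approx(est2 / 5)

    def test_all_mode_returns_single_estimate(self, small_sim, phased_db):
        idx, _ = phased_db
        grid = np.arange(2000, 20_001, 1_000)
        db = build_database(idx, n_positions=120, grid=grid, seed=8,
                            exclusion_bed=small_sim.truth_tsv + ".jexcl.bed")
        (est,) = genotype_locus_ji(idx, small_sim.config.str_locus, db,
                                   JiQueryParams(e=30, f=200.0))
        assert est.haplotype is None and est.size_bp is not None
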