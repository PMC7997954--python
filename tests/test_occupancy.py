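import numpy as np
import pandas as pd
import pytest

import oracle_utils as oracle
from conftest import make_fragment_set, make_tss_table
from nucleofoot import (
    SimulatorConfig,
    compute_metagene_profile,
    compute_ndr_depth,
    compute_tss_rpkm,
    fragment_length_summary,
    simulate_landscape,
    simulate_sample,
)
from nucleofoot.errors import ParameterError
from nucleofoot.io import FragmentSet, TssRecord, TssTable


def fragset(intervals, sample_id="s1"):
    return FragmentSet(
        sample_id=sample_id,
        chroms=np.array([c for c, _, _ in intervals], dtype=object),
        starts=np.array([s for _, s, _ in intervals], dtype=np.int64),
        ends=np.array([e for _, _, e in intervals], dtype=np.int64),
    )


def tss_of(*records):
    return TssTable.from_records([TssRecord(*r) for r in records])


class TestRpkm:
    def test_closed_form_normalization(self):
        """10 midpoints in a 2 kb window of a million-fragment library: RPKM 5."""
        inside = [("chr1", 9_000 + i, 9_166 + i) for i in range(10)]
        outside = [("chr2", 100, 266)] * (1_000_000 - 10)
        fs = fragset(inside + outside)
        tss = tss_of(("G1", "chr1", 10_000, "+"))
        rpkm = compute_tss_rpkm(fs, tss, flank=1000)
        assert rpkm["G1"] == pytest.approx(5.0)

    def test_no_overlap_gives_zero(self):
        fs = fragset([("chr1", 50_000, 50_166)])
        tss = tss_of(("G1", "chr1", 10_000, "+"))
        assert compute_tss_rpkm(fs, tss)["G1"] == 0.0

    def test_empty_sample_rejected(self):
        fs = fragset([])
        tss = tss_of(("G1", "chr1", 10_000, "+"))
        with pytest.raises(ParameterError, match="RPKM undefined"):
            compute_tss_rpkm(fs, tss)

    def test_counts_match_bruteforce_oracle(self, rng):
        fs = make_fragment_set(rng, 500, chroms=("chr1", "chr2"))
        tss = make_tss_table(rng, 20, chroms=("chr1", "chr2"))
        rpkm = compute_tss_rpkm(fs, tss, flank=1000)
        expected = oracle.brute_window_midpoint_counts(fs, tss, flank=1000)
        norm = (2.0) * (fs.total_count / 1e6)
        for gid, count in expected.items():
            assert rpkm[gid] == pytest.approx(count / norm)

    def test_duplicating_every_fragment_leaves_rpkm_unchanged(self, rng):
        fs = make_fragment_set(rng, 300)
        tss = make_tss_table(rng, 10)
        doubled = FragmentSet(
            "s2",
            np.concatenate([fs.chroms, fs.chroms]),
            np.concatenate([fs.starts, fs.starts]),
            np.concatenate([fs.ends, fs.ends]),
        )
        pd.testing.assert_series_equal(
            compute_tss_rpkm(fs, tss),
            compute_tss_rpkm(doubled, tss),
            check_names=False,
        )

    def test_adding_in_window_fragment_never_decreases_rpkm(self, rng):
        fs = make_fragment_set(rng, 300)
        tss = make_tss_table(rng, 10)
        before = compute_tss_rpkm(fs, tss)
        target = next(tss.records)
        extra = FragmentSet(
            "s3",
            np.concatenate([fs.chroms, np.array([target.chrom], dtype=object)]),
            np.concatenate([fs.starts, [target.tss - 80]]),
            np.concatenate([fs.ends, [target.tss + 80]]),
        )
        after = compute_tss_rpkm(extra, tss)
        assert after[target.gene_id] >= before[target.gene_id] * (
            fs.total_count / extra.total_count
        )
        # raw count itself can only grow
        assert after[target.gene_id] * extra.total_count >= (
            before[target.gene_id] * fs.total_count
        )


class TestMetagene:
    def test_single_fragment_plus_strand_geometry(self):
        fs = fragset([("chr1", 100, 266)])
        tss = tss_of(("G1", "chr1", 150, "+"))
        prof = compute_metagene_profile(fs, tss, ["G1"], flank=200)
        by_offset = dict(zip(prof.positions, prof.mean_depth))
        for off in range(-200, 200):
            expected = 1.0 if -50 <= off <= 115 else 0.0
            assert by_offset[off] == expected

    def test_single_fragment_minus_strand_mirrors(self):
        fs = fragset([("chr1", 100, 266)])
        tss = tss_of(("G1", "chr1", 150, "-"))
        prof = compute_metagene_profile(fs, tss, ["G1"], flank=200)
        by_offset = dict(zip(prof.positions, prof.mean_depth))
        for off in range(-200, 200):
            expected = 1.0 if -115 <= off <= 50 else 0.0
            assert by_offset[off] == expected

    def test_matches_per_base_oracle(self, rng):
        fs = make_fragment_set(rng, 200, span=30_000)
        tss = make_tss_table(rng, 6, span=30_000)
        subset = tss.gene_ids[:4]
        prof = compute_metagene_profile([fs], tss, subset, flank=150)
        expected = oracle.brute_metagene([fs], tss, subset, flank=150)
        np.testing.assert_allclose(prof.mean_depth, expected)

    def test_empty_subset_rejected(self, rng):
        fs = make_fragment_set(rng, 10)
        tss = make_tss_table(rng, 4)
        with pytest.raises(ParameterError, match="non-empty"):
            compute_metagene_profile(fs, tss, [])

    def test_mirror_symmetry_of_profiles(self, rng):
        """Reflecting all fragments and TSSs about a fixed point while
        flipping strands leaves the strand-oriented profile unchanged."""
        pivot = 50_000
        fs = make_fragment_set(rng, 300, span=40_000)
        tss = make_tss_table(rng, 8, span=40_000)
        # reflection of half-open [s, e) about P covers [2P - e + 1, 2P - s + 1)
        mirrored_fs = FragmentSet("m", fs.chroms.copy(),
                                  2 * pivot - fs.ends + 1,
                                  2 * pivot - fs.starts + 1)
        flipped = tss.df.copy()
        flipped["tss"] = 2 * pivot - flipped["tss"]
        flipped["strand"] = flipped["strand"].map({"+": "-", "-": "+"})
        mirrored_tss = TssTable(flipped)
        p1 = compute_metagene_profile(fs, tss, tss.gene_ids, flank=200)
        p2 = compute_metagene_profile(mirrored_fs, mirrored_tss, tss.gene_ids,
                                      flank=200)
        np.testing.assert_allclose(p1.mean_depth, p2.mean_depth)


class TestNdrDepth:
    def test_fragment_spanning_whole_window(self):
        fs = fragset([("chr1", 9_000, 11_000)])
        tss = tss_of(("G1", "chr1", 10_000, "+"))
        assert compute_ndr_depth(fs, tss)["G1"] == 200

    def test_no_fragments_gives_zero(self):
        fs = fragset([("chr2", 0, 100)])
        tss = tss_of(("G1", "chr1", 10_000, "+"))
        assert compute_ndr_depth(fs, tss)["G1"] == 0

    def test_matches_per_base_oracle_both_strands(self, rng):
        fs = make_fragment_set(rng, 400, span=20_000)
        tss = make_tss_table(rng, 8, span=20_000)
        depth = compute_ndr_depth(fs, tss)
        for rec in tss.records:
            assert depth[rec.gene_id] == oracle.brute_ndr_depth(
                fs, rec, (-150, 50)), rec.strand

    def test_invalid_window_rejected(self, rng):
        fs = make_fragment_set(rng, 10)
        tss = make_tss_table(rng, 4)
        with pytest.raises(ParameterError):
            compute_ndr_depth(fs, tss, window=(50, -150))


class TestLengthSummary:
    def test_exact_moments(self):
        fs = fragset([("chr1", 0, 166), ("chr1", 10, 176)])
        s = fragment_length_summary(fs)
        assert s.mean == 166 and s.sd == 0
        fs2 = fragset([("chr1", 0, 100), ("chr1", 0, 200)])
        assert fragment_length_summary(fs2).mean == 150

    def test_histogram_counts(self):
        fs = fragset([("chr1", 0, 100)] * 3 + [("chr1", 0, 150)])
        hist = fragment_length_summary(fs).histogram
        assert hist[100] == 3 and hist[150] == 1

    def test_empty_set_rejected(self):
        with pytest.raises(ParameterError):
            fragment_length_summary(fragset([]))

    def test_simulated_cfdna_mean_length(self):
        cfg = SimulatorConfig(n_chroms=1, chrom_length=1_500_000, n_genes=300,
                              fragments_per_sample=50_000, seed=21)
        land = simulate_landscape(cfg)
        fs = simulate_sample(land, cfg, "cfdna", sample_seed=5)
        assert abs(fragment_length_summary(fs).mean - 166.0) < 1.0


def test_expressed_promoter_profile_minimum_falls_in_ndr_window():
    """Under coupled simulation the expressed-gene metagene dips at the
    promoter: depth at offset 0 is below the unexpressed-gene profile and
    the profile minimum lies within the NDR window."""
    cfg = SimulatorConfig(n_chroms=1, chrom_length=1_500_000, n_genes=300,
                          fragments_per_sample=100_000, seed=22,
                          depletion_strength=0.9)
    land = simulate_landscape(cfg)
    fs = simulate_sample(land, cfg, "cfdna", sample_seed=30)
    heg = land.expression.index[land.expression > 10]
    ueg = land.expression.index[land.expression == 0]
    ph = compute_metagene_profile(fs, land.tss, heg, flank=400)
    pu = compute_metagene_profile(fs, land.tss, ueg, flank=400)
    at0 = list(ph.positions).index(0)
    assert ph.mean_depth[at0] < pu.mean_depth[at0]
    min_offset = ph.positions[np.argmin(ph.mean_depth)]
    assert -150 <= min_offset < 50
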