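import numpy as np
import pytest

from pigdiv import roh, synthetic
from pigdiv.io_formats import MISSING
from conftest import build_dataset
from oracles import roh_oracle


def one_sample_ds(genos, positions=None, spacing=20_000):
    g = np.asarray(genos, dtype=np.int8)[None, :]
    if positions is None:
        positions = [(k + 1) * spacing for k in range(g.shape[1])]
    return build_dataset(g, positions=positions)


class TestDetect:
    def test_clean_long_run(self):
        ds = one_sample_ds([0] * 60)  # spans 59*20kb = 1.18 Mb
        segs = roh.detect_roh(ds, min_snps=50, min_length_kb=1000, window=50)
        assert len(segs) == 1
        seg = segs[0]
        assert (seg.start_snp_index, seg.end_snp_index) == (0, 59)
        assert seg.n_snps == 60
        assert seg.n_het == 0 and seg.n_missing == 0
        assert seg.length_bp == seg.end_bp - seg.start_bp + 1

    def test_49_snps_fails_min_snps(self):
        ds = one_sample_ds([2] * 49, spacing=45_000)  # ~2.2 Mb span
        segs = roh.detect_roh(ds, min_snps=50, min_length_kb=1000, window=49)
        assert segs == []

    def test_one_het_allowed_two_not(self):
        g = [0] * 30 + [1] + [0] * 40
        ds = one_sample_ds(g)
        segs = roh.detect_roh(ds, min_snps=50, min_length_kb=500, window=50,
                              max_het_per_window=1)
        assert len(segs) == 1 and segs[0].n_het == 1
        g2 = [0] * 30 + [1] + [0] * 5 + [1] + [0] * 40
        segs2 = roh.detect_roh(one_sample_ds(g2), min_snps=50, min_length_kb=500, window=50)
        assert segs2 == []

    def test_unsorted_positions_error(self):
        ds = one_sample_ds([0] * 60)
        ds.snps.loc[5, "position_bp"] = ds.snps.loc[4, "position_bp"]  # break sortedness
        with pytest.raises(ValueError, match="sorted"):
            roh.detect_roh(ds, min_snps=50, min_length_kb=100, window=50)

    def test_window_gt_min_snps_rejected(self):
        ds = one_sample_ds([0] * 60)
        with pytest.raises(ValueError, match="window"):
            roh.detect_roh(ds, min_snps=10, window=20)

    def test_short_chromosome_skipped(self, caplog):
        ds = one_sample_ds([0] * 10)
        with caplog.at_level("INFO"):
            segs = roh.detect_roh(ds, min_snps=50, min_length_kb=1, window=50)
        assert segs == []

    @pytest.mark.parametrize("seed", range(12))
    def test_bruteforce_oracle_random(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(60, 500))
        g = rng.choice([0, 1, 2, MISSING], p=[0.55, 0.07, 0.3, 0.08], size=n).astype(np.int8)
        pos = np.cumsum(rng.integers(1_000, 60_000, n))
        window = int(rng.integers(5, 25))
        min_snps = window + int(rng.integers(0, 20))
        min_len_kb = float(rng.integers(1, 400))
        ds = one_sample_ds(g, positions=pos.tolist())
        segs = roh.detect_roh(
            ds, min_snps=min_snps, min_length_kb=min_len_kb, window=window,
            max_het_per_window=1, max_missing_per_window=1,
        )
        got = [(s.start_snp_index, s.end_snp_index) for s in segs]
        want = roh_oracle(g.tolist(), pos.tolist(), min_snps, min_len_kb, window, 1, 1)
        assert got == want

    def test_monotone_in_thresholds(self, rng):
        g = rng.choice([0, 1, 2, MISSING], p=[0.5, 0.1, 0.3, 0.1], size=400).astype(np.int8)
        ds = one_sample_ds(g)
        base = {(s.start_snp_index, s.end_snp_index)
                for s in roh.detect_roh(ds, min_snps=20, min_length_kb=10, window=20)}
        stricter = {(s.start_snp_index, s.end_snp_index)
                    for s in roh.detect_roh(ds, min_snps=40, min_length_kb=300, window=20)}
        assert stricter <= base

    def test_deterministic(self, rng):
        g = rng.choice([0, 1, 2], size=(5, 300)).astype(np.int8)
        ds = build_dataset(g)
        a = roh.detect_roh(ds, min_snps=10, min_length_kb=10, window=10)
        b = roh.detect_roh(ds, min_snps=10, min_length_kb=10, window=10)
        assert a == b


class TestPostFilters:
    def test_gap_filter_drops_spanning_segment(self):
        pos = [(k + 1) * 20_000 for k in range(30)] + [2_000_000 + (k + 1) * 20_000 for k in range(30)]
        ds = one_sample_ds([0] * 60, positions=pos)
        segs = roh.detect_roh(ds, min_snps=50, min_length_kb=1000, window=50)
        assert len(segs) == 1  # the 1.4 Mb gap sits inside one clean run
        kept = roh.apply_roh_post_filters(segs, ds, max_gap_kb=1000)
        assert kept == []
        kept2 = roh.apply_roh_post_filters(segs, ds, max_gap_kb=2000)
        assert kept2 == segs

    def test_density_filter(self):
        ds = one_sample_ds([0] * 60, spacing=50_000)  # 2 SNPs / 100 kb
        segs = roh.detect_roh(ds, min_snps=50, min_length_kb=1000, window=50)
        assert len(segs) == 1
        assert roh.apply_roh_post_filters(segs, ds, min_snps_per_100kb=5.0) == []
        assert roh.apply_roh_post_filters(segs, ds, min_snps_per_100kb=1.0) == segs

    def test_no_filters_identity(self, small_sim):
        ds, _ = small_sim
        segs = roh.detect_roh(ds, min_snps=10, min_length_kb=100, window=10)
        assert roh.apply_roh_post_filters(segs, ds) == segs


class TestFroh:
    def test_no_roh_zero(self):
        v = roh.f_roh([], ["s0"], genome_length_kb=2_808_525)
        assert v.values["s0"] == 0.0
        assert v.method == "roh"

    def test_whole_genome_one(self):
        seg = roh.RohSegment("s0", "1", 0, 9, 1, 2_808_525_000, 10, 0, 0)
        v = roh.f_roh([seg], ["s0"], genome_length_kb=2_808_525)
        assert v.values["s0"] == pytest.approx(1.0)

    def test_tenth_of_genome(self):
        seg = roh.RohSegment("s0", "1", 0, 9, 1, 280_852_500, 10, 0, 0)
        v = roh.f_roh([seg], ["s0"], genome_length_kb=2_808_525)
        assert v.values["s0"] == pytest.approx(0.1)

    def test_overlong_total_errors(self):
        seg = roh.RohSegment("s0", "1", 0, 9, 1, 2_000_000, 10, 0, 0)
        with pytest.raises(ValueError, match="exceeds"):
            roh.f_roh([seg], ["s0"], genome_length_kb=1000)


class TestFsnp:
    def test_all_homozygous(self):
        v = roh.f_snp(build_dataset([[0, 2, 0, 2]]))
        assert v.values["s0"] == 1.0

    def test_half_het(self):
        v = roh.f_snp(build_dataset([[0, 1, 2, 1]]))
        assert v.values["s0"] == 0.5

    def test_with_missing(self):
        v = roh.f_snp(build_dataset([[0, 2, 0, 1, MISSING]]))
        assert v.values["s0"] == pytest.approx(0.75)

    def test_all_missing_nan(self):
        v = roh.f_snp(build_dataset([[MISSING, MISSING]]))
        assert np.isnan(v.values["s0"])

    def test_equals_one_minus_het_rate(self, rng):
        g = rng.choice([0, 1, 2, MISSING], size=(10, 200)).astype(np.int8)
        ds = build_dataset(g)
        v = roh.f_snp(ds)
        for i, sid in enumerate(ds.sample_ids):
            nm = g[i] != MISSING
            het = (g[i] == 1)[nm].mean()
            assert v.values[sid] == pytest.approx(1 - het)


class TestSummary:
    def _seg(self, sid, length_bp, chrom="1", start=1):
        return roh.RohSegment(sid, chrom, 0, 9, start, start + length_bp - 1, 10, 0, 0)

    def test_basic_counts(self):
        segs = [self._seg("s0", 1_000_000), self._seg("s0", 3_000_000, start=50_000_000)]
        out = roh.summarize_roh(segs, ["s0"], genome_length_kb=100_000)
        ps = out["per_sample"].set_index("sample_id")
        assert ps.loc["s0", "n_roh"] == 2
        assert ps.loc["s0", "mean_length_bp"] == pytest.approx(2_000_000)
        assert out["n_segments_short"] == 2 and out["n_segments_long"] == 0

    def test_five_mb_boundary_is_long(self):
        segs = [self._seg("s0", 5_000_000)]
        out = roh.summarize_roh(segs, ["s0"], genome_length_kb=100_000)
        assert out["n_segments_long"] == 1

    def test_reaggregation_oracle(self, small_sim):
        ds, truth = small_sim
        segs = roh.detect_roh(ds, min_snps=10, min_length_kb=100, window=10)
        out = roh.summarize_roh(segs, list(ds.sample_ids), genome_length_kb=100_000)
        totals = {}
        counts = {}
        for s in segs:
            totals[s.sample_id] = totals.get(s.sample_id, 0) + s.length_bp
            counts[s.sample_id] = counts.get(s.sample_id, 0) + 1
        ps = out["per_sample"].set_index("sample_id")
        for sid in ds.sample_ids:
            assert ps.loc[sid, "total_length_bp"] == totals.get(sid, 0)
            assert ps.loc[sid, "n_roh"] == counts.get(sid, 0)

    def test_empty_warns(self, caplog):
        with caplog.at_level("WARNING"):
            out = roh.summarize_roh([], ["s0"], genome_length_kb=1000)
        assert out["per_sample"]["n_roh"].sum() == 0


class TestShared:
    def _seg(self, sid, chrom, start, end):
        return roh.RohSegment(sid, chrom, 0, 9, start, end, 10, 0, 0)

    def test_within_identical(self):
        segs = {"p": [self._seg("a", "1", 100, 200), self._seg("b", "1", 100, 200)]}
        regions, table = roh.shared_roh(segs, {"p": 4}, mode="within", match="exact")
        assert len(regions) == 1
        assert sorted(regions[0].carriers["p"]) == ["a", "b"]
        assert regions[0].carrier_fraction["p"] == pytest.approx(0.5)
        assert int(table["n_shared_regions"].iloc[-1]) == 1

    def test_between_identical(self):
        segs = {
            "la": [self._seg("a", "3", 100, 200)],
            "lw": [self._seg("b", "3", 100, 200)],
        }
        regions, table = roh.shared_roh(
            segs, {"la": 1, "lw": 1}, mode="between", match="exact", populations=("la", "lw")
        )
        assert len(regions) == 1
        assert set(regions[0].carriers) == {"la", "lw"}

    def test_between_requires_same_coordinates(self):
        segs = {
            "la": [self._seg("a", "3", 100, 200)],
            "lw": [self._seg("b", "3", 101, 200)],
        }
        regions, _ = roh.shared_roh(segs, {"la": 1, "lw": 1}, mode="between", match="exact")
        assert regions == []

    def test_overlap_mode_groups(self):
        segs = {
            "la": [self._seg("a", "1", 1, 1_000_000)],
            "lw": [self._seg("b", "1", 400_000, 1_500_000)],
        }
        regions, _ = roh.shared_roh(
            segs, {"la": 1, "lw": 1}, mode="between", match="overlap", min_overlap_bp=500_000
        )
        assert len(regions) == 1
        regions2, _ = roh.shared_roh(
            segs, {"la": 1, "lw": 1}, mode="between", match="overlap", min_overlap_bp=700_000
        )
        assert regions2 == []

    def test_unknown_population_error(self):
        with pytest.raises(ValueError, match="unknown population"):
            roh.shared_roh({"p": []}, {"p": 1}, mode="between", populations=("p", "q"))

    def test_planted_shared_region_recovered(self):
        # force near-identical haplotypes via tiny founder pool -> many shared exact ROH
        cfg = synthetic.SimConfig(seed=21, n_generations=6, pop_size=8,
                                  n_chromosomes=1, chrom_length_morgan=0.3, n_snps=300)
        ds, _ = synthetic.simulate(cfg)
        segs = roh.detect_roh(ds, min_snps=20, min_length_kb=100, window=20)
        by_pop = {"pop": segs}
        regions, _ = roh.shared_roh(by_pop, {"pop": ds.n_samples}, mode="within", match="overlap",
                                    min_overlap_bp=200_000)
        # some sharing must exist in a drifted population of 8
        assert len(regions) >= 1
        for r in regions:
            assert 0 < r.carrier_fraction["pop"] <= 1


class TestConsensus:
    def _seg(self, sid, start, end):
        return roh.RohSegment(sid, "1", 0, 9, start, end, 10, 0, 0)

    def _ds(self, n_samples, m=20):
        return build_dataset(np.zeros((n_samples, m), dtype=np.int8),
                             positions=[(k + 1) * 1000 for k in range(m)])

    def test_all_share_one_region(self):
        ds = self._ds(3)
        segs = [self._seg(s, 5000, 12000) for s in ("s0", "s1", "s2")]
        regions = roh.consensus_regions(segs, ds, ["s0", "s1", "s2"], 0.5)
        assert len(regions) == 1
        assert regions[0].start_bp == 5000 and regions[0].end_bp == 12000
        assert regions[0].mean_incidence == pytest.approx(1.0)

    def test_impossible_threshold_empty(self):
        ds = self._ds(2)
        segs = [self._seg("s0", 5000, 12000)]
        assert roh.consensus_regions(segs, ds, ["s0", "s1"], 1.01) == []

    def test_staggered_matches_per_snp_scan(self):
        ds = self._ds(4)
        segs = [
            self._seg("s0", 1000, 10000),
            self._seg("s1", 4000, 14000),
            self._seg("s2", 6000, 20000),
        ]
        regions = roh.consensus_regions(segs, ds, ["s0", "s1", "s2", "s3"], 0.5)
        # direct per-SNP incidence oracle
        pos = ds.positions
        incidence = np.zeros(len(pos))
        for seg in segs:
            incidence += (pos >= seg.start_bp) & (pos <= seg.end_bp)
        incidence /= 4
        covered = incidence >= 0.5
        runs = []
        k = 0
        while k < len(pos):
            if covered[k]:
                j = k
                while j + 1 < len(pos) and covered[j + 1]:
                    j += 1
                runs.append((pos[k], pos[j]))
                k = j + 1
            else:
                k += 1
        assert [(r.start_bp, r.end_bp) for r in regions] == runs


class TestFrohTruthCorrelation:
    def test_simulated_froh_tracks_truth(self):
        cfg = synthetic.SimConfig(seed=13, n_generations=12, pop_size=24,
                                  n_chromosomes=3, chrom_length_morgan=1.0, n_snps=3000,
                                  maf_range=(0.2, 0.5))
        ds, truth = synthetic.simulate(cfg)
        segs = roh.detect_roh(ds, min_snps=50, min_length_kb=1000, window=50)
        genome_kb = sum(truth.chrom_lengths) * 1e5  # Morgan -> kb at 100 Mb/M
        fr = roh.f_roh(segs, list(ds.sample_ids), genome_kb)
        ta = {a: synthetic.true_autozygosity(truth, a)[0] for a in ds.sample_ids}
        x = np.array([fr.values[a] for a in ds.sample_ids])
        y = np.array([ta[a] for a in ds.sample_ids])
        r = np.corrcoef(x, y)[0, 1]
        assert r > 0.8
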