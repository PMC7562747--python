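"""Pausing-index pipeline: RPKM arithmetic, windows, filters, ranking, profiles."""

import numpy as np
import pytest

from pausescape.core_io import CoverageTrack, GeneModel, GenomicInterval, ValidationError
from pausescape.pausing import (
    PausingConfig,
    compare_pausing_groups,
    define_windows,
    filter_expressed,
    filter_rnapii_bound,
    metagene_profile,
    pausing_index,
    rank_by_chd7,
    region_rpkm,
    run_pausing_pipeline,
    PausingRecord,
)
from pausescape.synthetic import (
    SimulationConfig,
    generate_gene_models,
    simulate_chd7_track,
    simulate_polii_track,
)

CFG = PausingConfig()


def make_gene(gene_id="g", start=1000, end=3000, strand="+", fpkm=5.0, chrom="chr1"):
    return GeneModel(gene_id, GenomicInterval(chrom, start, end, strand), fpkm=fpkm)


def uniform_track(n=10_000, value=1, chrom="chr1"):
    return CoverageTrack({chrom: np.full(n, value, dtype=np.int64)})


class TestRegionRpkm:
    def test_hand_formula(self):
        # 100 read starts in a 1,000 bp region out of 10,000,000 reads -> 10.0
        arr = np.zeros(1000, dtype=np.int64)
        arr[:100] = 1
        filler = np.full(999_990, 10, dtype=np.int64)  # 9,999,900 reads elsewhere
        track = CoverageTrack({"chr1": arr, "chrFill": filler})
        assert track.total_reads == 10_000_000
        assert region_rpkm(track, GenomicInterval("chr1", 0, 1000)) == pytest.approx(10.0)

    def test_empty_region_zero(self):
        track = uniform_track(1000, 1)
        assert region_rpkm(track, GenomicInterval("chr1", 5000, 6000)) == 0.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        arr = rng.poisson(2, size=5000)
        region = GenomicInterval("chr1", 100, 700)
        r1 = region_rpkm(CoverageTrack({"chr1": arr}), region)
        r2 = region_rpkm(CoverageTrack({"chr1": arr * 2}), region)
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_zero_total_reads_error(self):
        with pytest.raises(ValidationError):
            region_rpkm(CoverageTrack({"chr1": np.zeros(10, dtype=np.int64)}), GenomicInterval("chr1", 0, 5))


class TestWindows:
    def test_plus_strand_coordinates(self):
        gene = make_gene(start=1000, end=3000, strand="+")  # TSS 1000, TTS 2999
        tssw, body = define_windows(gene, CFG)
        assert (tssw.start, tssw.end) == (950, 1200)
        assert (body.start, body.end) == (1500, 3000)

    def test_minus_strand_mirrors(self):
        gene = make_gene(start=1000, end=3000, strand="-")  # TSS 2999, TTS 1000
        tssw, body = define_windows(gene, CFG)
        assert (tssw.start, tssw.end) == (2800, 3050)
        assert (body.start, body.end) == (1000, 2500)
        # mirror of the + strand windows about the gene midpoint
        plus_tssw, plus_body = define_windows(make_gene(strand="+"), CFG)
        assert len(tssw) == len(plus_tssw) and len(body) == len(plus_body)

    def test_minimal_length_gene_has_positive_body(self):
        gene = make_gene(start=0, end=751, strand="+")
        _, body = define_windows(gene, CFG)
        assert len(body) == 251

    def test_too_short_gene_rejected(self):
        gene = make_gene(start=0, end=500)
        with pytest.raises(ValidationError):
            define_windows(gene, CFG)


class TestFilters:
    def test_expression_filter_boundaries(self):
        genes = [
            make_gene("keep_exact", 0, 751, fpkm=1.0),
            make_gene("drop_fpkm", 0, 751, fpkm=0.99),
            make_gene("drop_len", 0, 750, fpkm=5.0),
        ]
        kept = filter_expressed(genes, CFG)
        assert [g.gene_id for g in kept] == ["keep_exact"]

    def test_missing_fpkm_names_gene(self):
        gene = GeneModel("anon", GenomicInterval("chr1", 0, 1000, "+"))
        with pytest.raises(ValidationError, match="anon"):
            filter_expressed([gene], CFG)

    def test_rnapii_threshold_is_strict(self):
        gene = make_gene(start=1000, end=3000)
        tssw, body = define_windows(gene, CFG)
        # build a track whose TSS RPKM is exactly 1.6: reads*1e9/(250*total)=1.6
        total = 10_000_000
        tss_reads = int(1.6 * len(tssw) * total / 1e9)  # 4 reads
        assert tss_reads * 1e9 / (len(tssw) * total) == pytest.approx(1.6)
        arr = np.zeros(4000, dtype=np.int64)
        arr[tssw.start : tssw.start + tss_reads] = 1
        arr[body.start : body.end] = 2  # body comfortably above 0.5
        filler = np.full(total - int(arr.sum()), 1, dtype=np.int64)
        track = CoverageTrack({"chr1": arr, "chrFill": filler})
        assert track.total_reads == total
        assert filter_rnapii_bound([gene], track, CFG) == []

    def test_zero_coverage_gene_excluded(self):
        gene = make_gene()
        track = CoverageTrack({"chr1": np.zeros(4000, dtype=np.int64), "chr2": np.ones(100, dtype=np.int64)})
        assert filter_rnapii_bound([gene], track, CFG) == []


class TestRanking:
    @staticmethod
    def _genes_with_occupancy(n, seed=0):
        cfg = SimulationConfig(n_genes=n, seed=seed)
        genes = generate_gene_models(cfg)
        return genes

    def test_top_and_bottom_by_occupancy(self):
        genes = self._genes_with_occupancy(20)
        levels = np.linspace(0.1, 10.0, 20)
        track = simulate_chd7_track(genes, levels, seed=1)
        cfg = PausingConfig(k_extremes=5)
        top, bottom = rank_by_chd7(genes, track, cfg)
        assert len(top) == len(bottom) == 5
        assert set(g.gene_id for g in top).isdisjoint(g.gene_id for g in bottom)

    def test_all_tied_breaks_by_gene_id(self):
        genes = self._genes_with_occupancy(10)
        track = CoverageTrack({"chr1": np.ones(genes[-1].interval.end + 100, dtype=np.int64)})
        cfg = PausingConfig(k_extremes=3)
        top, bottom = rank_by_chd7(genes, track, cfg)
        # occupancy RPKM differs by length here; force exact ties with zero track + pseudo total
        # instead check determinism across repeated calls
        top2, bottom2 = rank_by_chd7(genes, track, cfg)
        assert [g.gene_id for g in top] == [g.gene_id for g in top2]
        assert [g.gene_id for g in bottom] == [g.gene_id for g in bottom2]

    def test_exact_ties_follow_sort_oracle(self):
        # equal-length genes with identical coverage: pure gene_id tie-break
        genes = [make_gene(f"g{i:02d}", 1000 + 5000 * i, 3000 + 5000 * i) for i in range(8)]
        track = CoverageTrack({"chr1": np.ones(50_000, dtype=np.int64)})
        cfg = PausingConfig(k_extremes=2)
        top, bottom = rank_by_chd7(genes, track, cfg)
        ids = sorted(g.gene_id for g in genes)
        assert [g.gene_id for g in top] == ids[:2]
        assert [g.gene_id for g in bottom] == ids[2:4]

    def test_k_too_large_error(self):
        genes = self._genes_with_occupancy(6)
        track = simulate_chd7_track(genes, [1.0] * 6, seed=2)
        with pytest.raises(ValidationError):
            rank_by_chd7(genes, track, PausingConfig(k_extremes=4))


class TestPausingIndex:
    def test_uniform_coverage_gives_one(self):
        gene = make_gene(start=1000, end=3000)
        track = uniform_track(10_000, 2)
        assert pausing_index(gene, track, CFG) == pytest.approx(1.0)

    def test_ratio_of_rpkms(self):
        gene = make_gene(start=1000, end=3000)
        tssw, body = define_windows(gene, CFG)
        arr = np.zeros(10_000, dtype=np.int64)
        arr[tssw.start : tssw.end] = 8
        arr[body.start : body.end] = 2
        track = CoverageTrack({"chr1": arr})
        assert pausing_index(gene, track, CFG) == pytest.approx(4.0)

    def test_minus_strand_matches_brute_force(self):
        """TSS-concentrated coverage on a - strand gene: index > 1 and equal to
        raw-count recomputation through independent window arithmetic."""
        gene = make_gene(start=1000, end=3000, strand="-")  # TSS at 2999
        arr = np.ones(10_000, dtype=np.int64)
        arr[2800:3050] = 9
        track = CoverageTrack({"chr1": arr})
        got = pausing_index(gene, track, CFG)
        # oracle: windows derived from scratch for the minus strand
        tss = gene.interval.end - 1
        tss_lo, tss_hi = tss - 200 + 1, tss + 50 + 1
        body_lo, body_hi = gene.interval.start, tss - 500 + 1
        total = track.total_reads
        rpkm = lambda lo, hi: arr[lo:hi].sum() / (((hi - lo) / 1000) * (total / 1e6))
        assert got == rpkm(tss_lo, tss_hi) / rpkm(body_lo, body_hi)
        assert got > 1

    def test_zero_body_error(self):
        gene = make_gene(start=1000, end=3000)
        arr = np.zeros(10_000, dtype=np.int64)
        arr[950:1200] = 3
        with pytest.raises(ValidationError):
            pausing_index(gene, CoverageTrack({"chr1": arr}), CFG)


class TestMetagene:
    def test_constant_coverage_all_ones(self):
        genes = [make_gene("a", 1000, 3000, "+"), make_gene("b", 5000, 8000, "-")]
        profile = metagene_profile(genes, uniform_track(20_000, 3), CFG)
        np.testing.assert_allclose(profile, np.ones(150))

    def test_first_tenth_signal_lands_in_first_15_bins(self):
        gene = make_gene("a", 0, 3000, "+")
        arr = np.zeros(5000, dtype=np.int64)
        arr[0:300] = 10
        profile = metagene_profile([gene], CoverageTrack({"chr1": arr}), CFG)
        assert profile[:15].sum() == pytest.approx(profile.sum())
        assert profile[15:].sum() == 0
        # brute-force binning oracle
        cov = arr[0:3000].astype(float)
        edges = np.floor(np.linspace(0, 3000, 151)).astype(int)
        oracle = np.array([cov[edges[i]:edges[i+1]].mean() for i in range(150)])
        oracle /= oracle.mean()
        np.testing.assert_allclose(profile, oracle)

    def test_minus_strand_profile_is_reversed_mirror(self):
        rng = np.random.default_rng(1)
        arr = rng.poisson(3, size=3000).astype(np.int64)
        plus = make_gene("p", 0, 3000, "+")
        minus = make_gene("m", 0, 3000, "-")
        track = CoverageTrack({"chr1": arr})
        p_plus = metagene_profile([plus], track, CFG)
        p_minus = metagene_profile([minus], track, CFG)
        np.testing.assert_allclose(p_minus, p_plus[::-1])

    def test_invariant_to_uniform_scaling(self):
        rng = np.random.default_rng(2)
        arr = rng.poisson(2, size=3000).astype(np.int64)
        gene = make_gene("a", 0, 3000, "+")
        p1 = metagene_profile([gene], CoverageTrack({"chr1": arr}), CFG)
        p2 = metagene_profile([gene], CoverageTrack({"chr1": arr * 7}), CFG)
        np.testing.assert_allclose(p1, p2)

    def test_zero_coverage_gene_excluded_with_warning(self):
        genes = [make_gene("a", 0, 3000, "+"), make_gene("z", 10_000, 13_000, "+")]
        arr = np.zeros(20_000, dtype=np.int64)
        arr[0:3000] = 2
        with pytest.warns(UserWarning, match="zero coverage"):
            profile = metagene_profile(genes, CoverageTrack({"chr1": arr}), CFG)
        np.testing.assert_allclose(profile, np.ones(150))


class TestGroupComparison:
    def test_identical_groups(self):
        recs = [PausingRecord(f"g{i}", 2.0, 1.0, 2.0) for i in range(30)]
        r = compare_pausing_groups(recs, list(recs))
        assert r.p == 1.0

    def test_swap_symmetry(self):
        rng = np.random.default_rng(3)
        high = [PausingRecord(f"h{i}", 0, 0, v) for i, v in enumerate(rng.lognormal(0.4, 0.3, 50))]
        low = [PausingRecord(f"l{i}", 0, 0, v) for i, v in enumerate(rng.lognormal(1.8, 0.3, 50))]
        r1 = compare_pausing_groups(high, low)
        r2 = compare_pausing_groups(low, high)
        assert r1.p == pytest.approx(r2.p, rel=1e-12)
        assert r1.extra["median_high_chd7"] == r2.extra["median_low_chd7"]

    def test_empty_group_error(self):
        with pytest.raises(ValidationError):
            compare_pausing_groups([], [PausingRecord("g", 1, 1, 1)])


def test_pipeline_stages_only_shrink_and_recover_direction():
    """Expressed -> bound -> ranked shrinks monotonically; with true pausing
    separation the high-CHD7 group shows the lower median index."""
    cfg = SimulationConfig(n_genes=120, seed=21, fpkm_lognorm=(1.5, 1.0))
    genes = generate_gene_models(cfg)
    groups = ["high_chd7" if i % 2 == 0 else "low_chd7" for i in range(len(genes))]
    track, _ = simulate_polii_track(genes, cfg, groups=groups)
    levels = [cfg.chd7_levels[g] for g in groups]
    chd7 = simulate_chd7_track(genes, levels, seed=21)
    pcfg = PausingConfig(k_extremes=20)
    res = run_pausing_pipeline(genes, track, chd7, pcfg)
    assert res.n_input >= res.n_expressed >= res.n_rnapii_bound >= 2 * pcfg.k_extremes
    assert res.group_test.extra["median_high_chd7"] < res.group_test.extra["median_low_chd7"]
    assert len(res.profile_high) == len(res.profile_low) == 150
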