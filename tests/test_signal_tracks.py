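"""Spike-in calibration, enrichment regions, intersection, metagene."""

import numpy as np
import pandas as pd
import pytest

from pasfactory.genome import GeneModel
from pasfactory.signal_tracks import (
    EnrichedRegionSet,
    SignalTrack,
    build_metagene,
    calibrate_spikein,
    call_enriched_regions,
    classify_gene_enrichment,
    depth_normalize,
    intersect_antibodies,
    read_peak_file,
)
from pasfactory.synthetic import SimConfig, simulate_global_change_pair


def region_set(intervals, antibody="ab", q=1e-4, fdr=0.01):
    df = pd.DataFrame([("c", s, e, q) for s, e in intervals],
                      columns=["chrom", "start", "end", "qvalue"])
    return EnrichedRegionSet(antibody, df, fdr)


def test_bedgraph_round_trip(tmp_path):
    from pasfactory.signal_tracks import read_bedgraph, write_bedgraph

    rng = np.random.default_rng(9)
    v = rng.poisson(2, 5_000).astype(float)
    t = SignalTrack({"c": v}, bin_size=1)
    p = tmp_path / "t.bedgraph"
    write_bedgraph(t, str(p))
    back = read_bedgraph(str(p), {"c": 5_000})
    assert np.allclose(back.values["c"], v)


class TestCalibration:
    def test_million_spike_reads_is_identity(self):
        t = SignalTrack({"c": np.arange(10.0)}, total_reads=100)
        out = calibrate_spikein(t, spike_reads=10 ** 6)
        assert np.allclose(out.values["c"], t.values["c"])

    def test_zero_spike_reads_rejected(self):
        t = SignalTrack({"c": np.ones(4)})
        with pytest.raises(ValueError, match="depth"):
            calibrate_spikein(t, spike_reads=0)

    def test_identical_biology_different_spike_depth(self):
        rng = np.random.default_rng(0)
        lam = rng.gamma(2, 5, 20_000)
        a = SignalTrack({"c": rng.poisson(lam * 4).astype(float)}, spike_reads=1_000_000)
        b = SignalTrack({"c": rng.poisson(lam * 2).astype(float)}, spike_reads=500_000)
        ca, cb = calibrate_spikein(a), calibrate_spikein(b)
        assert ca.genome_mean() / cb.genome_mean() == pytest.approx(1.0, rel=0.01)

    def test_global_twofold_loss_detected_only_with_spikein(self):
        pair = simulate_global_change_pair(SimConfig(seed=0), global_fold=2.0, seed=0)
        cal = {k: calibrate_spikein(v) for k, v in pair.items()}
        dep = {k: depth_normalize(v) for k, v in pair.items()}
        cal_ratio = cal["high"].genome_mean() / cal["low"].genome_mean()
        dep_ratio = dep["high"].genome_mean() / dep["low"].genome_mean()
        assert cal_ratio == pytest.approx(2.0, rel=0.10)
        assert dep_ratio == pytest.approx(1.0, rel=0.10)

    def test_scalar_commutes_with_metagene(self):
        rng = np.random.default_rng(1)
        t = SignalTrack({"c": rng.gamma(2, 3, 120_000)}, spike_reads=777)
        genes = [GeneModel("g", "c", 40_000, 60_001, "+")]
        a = build_metagene(calibrate_spikein(t), genes).matrix.to_numpy()
        b = build_metagene(t, genes).matrix.to_numpy() * (1e6 / 777)
        assert np.allclose(a, b, equal_nan=True)


class TestCallEnrichedRegions:
    def test_ip_equal_to_input_yields_nothing(self):
        rng = np.random.default_rng(2)
        v = rng.poisson(10, 50_000).astype(float)
        ip = SignalTrack({"c": v.copy()}, bin_size=50)
        inp = SignalTrack({"c": v.copy()}, bin_size=50)
        assert call_enriched_regions(ip, inp).regions.empty

    def test_planted_blocks_recovered_with_few_false_bins(self):
        rng = np.random.default_rng(3)
        nb = 60_000
        lam = np.full(nb, 10.0)
        blocks = [(s, s + 40) for s in range(1_000, 59_000, 3_000)]
        for s, e in blocks:
            lam[s:e] *= 10
        ip = SignalTrack({"c": rng.poisson(lam).astype(float)}, bin_size=50)
        inp = SignalTrack({"c": rng.poisson(10.0, nb).astype(float)}, bin_size=50)
        regs = call_enriched_regions(ip, inp, fdr=0.01)
        hit = sum(
            any(r.start < e * 50 and s * 50 < r.end
                for r in regs.regions.itertuples())
            for s, e in blocks)
        assert hit / len(blocks) >= 0.95
        outside = sum(
            max(0, min(r.end, nb * 50) - r.start)
            - sum(max(0, min(r.end, e * 50) - max(r.start, s * 50))
                  for s, e in blocks)
            for r in regs.regions.itertuples())
        assert outside / (nb * 50) <= 0.01

    def test_pure_noise_fdr_controlled(self):
        rng = np.random.default_rng(4)
        nb = 100_000
        ip = SignalTrack({"c": rng.poisson(10.0, nb).astype(float)}, bin_size=50)
        inp = SignalTrack({"c": rng.poisson(10.0, nb).astype(float)}, bin_size=50)
        regs = call_enriched_regions(ip, inp, fdr=0.01)
        sig_bins = regs.total_bp() / 50
        se = np.sqrt(0.01 * 0.99 / nb)
        assert sig_bins / nb <= 0.01 + 2 * se

    def test_zero_input_falls_back_to_genome_mean(self):
        rng = np.random.default_rng(5)
        ip = SignalTrack({"c": rng.poisson(10.0, 10_000).astype(float)}, bin_size=50)
        inp = SignalTrack({"c": np.zeros(10_000)}, bin_size=50)
        regs = call_enriched_regions(ip, inp)
        assert regs.total_bp() / (10_000 * 50) <= 0.01


class TestIntersectAntibodies:
    def test_disjoint_sets_empty(self):
        a = region_set([(0, 100)])
        b = region_set([(200, 300)])
        assert intersect_antibodies(a, b).regions.empty

    def test_identical_sets_preserved(self):
        a = region_set([(0, 100), (500, 900)])
        out = intersect_antibodies(a, a)
        assert out.regions[["start", "end"]].values.tolist() == [[0, 100], [500, 900]]

    def test_partial_overlap_clipped(self):
        a = region_set([(0, 150)])
        b = region_set([(100, 300)])
        out = intersect_antibodies(a, b)
        assert out.regions[["start", "end"]].values.tolist() == [[100, 150]]

    def test_commutative_and_idempotent(self):
        rng = np.random.default_rng(6)
        mk = lambda seed: region_set(
            sorted((int(s), int(s) + int(rng.integers(50, 500)))
                   for s in rng.integers(0, 50_000, 20)))
        a, b = mk(0), mk(1)
        ab = intersect_antibodies(a, b).regions
        ba = intersect_antibodies(b, a).regions
        pd.testing.assert_frame_equal(ab[["chrom", "start", "end"]],
                                      ba[["chrom", "start", "end"]])
        aa = intersect_antibodies(a, a)
        total = intersect_antibodies(aa, a).total_bp()
        assert total == aa.total_bp()

    def test_peak_file_adapter_round_trip(self, tmp_path):
        a = region_set([(100, 400), (1000, 1200)])
        p = tmp_path / "peaks.bed"
        a.to_bed(str(p))
        back = read_peak_file(str(p), antibody="ext")
        assert back.regions[["start", "end"]].values.tolist() == [[100, 400], [1000, 1200]]


class TestClassifyGeneEnrichment:
    gene = GeneModel("g", "c", 10_000, 30_001, "+")  # TSS 10000, PAS 30000

    def classify(self, intervals):
        out = classify_gene_enrichment([self.gene], region_set(intervals))
        return out.loc["g", "class"]

    def test_tss_only_is_tss_gene_body(self):
        assert self.classify([(9_900, 10_200)]) == "tss_gene_body"

    def test_pas_window_dominates_even_with_tss_peak(self):
        assert self.classify([(9_900, 10_200), (29_000, 31_000)]) == "three_prime"

    def test_no_overlap_not_enriched(self):
        assert self.classify([(50_000, 51_000)]) == "not_enriched"

    def test_downstream_window_counts_as_enriched(self):
        assert self.classify([(33_000, 34_000)]) == "three_prime"

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        genes = []
        for i in range(100):
            s = int(rng.integers(0, 400_000))
            length = int(rng.integers(6_000, 30_000))
            genes.append(GeneModel(f"g{i}", "c", s, s + length,
                                   "+" if rng.random() < 0.5 else "-"))
        regions = sorted((int(s), int(s) + int(rng.integers(100, 3_000)))
                         for s in rng.integers(0, 420_000, 60))
        got = classify_gene_enrichment(genes, region_set(regions))
        for g in genes:
            pas, tss = g.annotated_end, g.tss
            if g.strand == "+":
                pas_win = (pas - 2_000, pas + 5_000)
                down = (pas, pas + 5_000)
            else:
                pas_win = (pas - 5_000, pas + 2_000)
                down = (pas - 5_000, pas)
            body = (min(tss, pas), max(tss, pas))

            def any_overlap(lo, hi):
                return any(s <= hi and lo <= e - 1 for s, e in regions)

            if any_overlap(*pas_win):
                expect = "three_prime"
            elif any_overlap(*body) or any_overlap(*down):
                expect = "tss_gene_body"
            else:
                expect = "not_enriched"
            assert got.loc[g.gene_id, "class"] == expect, g.gene_id


class TestMetagene:
    def test_constant_signal_gives_flat_379_columns(self):
        t = SignalTrack({"c": np.ones(300_000)})
        genes = [GeneModel("gp", "c", 50_000, 70_001, "+"),
                 GeneModel("gm", "c", 150_000, 170_001, "-")]
        mg = build_metagene(t, genes)
        assert mg.matrix.shape == (2, 379)
        assert np.allclose(mg.matrix.to_numpy(), 1.0)
        assert np.allclose(mg.mean_profile, 1.0)

    def test_strand_reversal_contract(self):
        # a signal step at the TSS lands in the same composite column for a
        # plus-strand gene and its minus-strand mirror image
        n = 400_000
        plus = np.zeros(n)
        gp = GeneModel("gp", "c", 100_000, 130_001, "+")
        plus[: gp.tss] = 5.0  # upstream of the + TSS
        minus = np.zeros(n)
        gm = GeneModel("gm", "c", 200_000, 230_001, "-")
        minus[gm.tss + 1:] = 5.0  # upstream of the - TSS
        mg_p = build_metagene(SignalTrack({"c": plus}), [gp]).matrix.to_numpy()[0]
        mg_m = build_metagene(SignalTrack({"c": minus}), [gm]).matrix.to_numpy()[0]
        assert np.allclose(mg_p, mg_m, equal_nan=True)

    def test_chromosome_edge_padded_with_nan(self):
        t = SignalTrack({"c": np.ones(40_000)})
        g = GeneModel("g", "c", 2_000, 32_001, "+")  # TSS-5kb out of range
        mg = build_metagene(t, [g])
        row = mg.matrix.to_numpy()[0]
        assert np.isnan(row[:20]).all()      # first 1 kb of the TSS window
        assert np.nanmax(row) == 1.0

    def test_rows_sorted_by_descending_mean(self):
        t = SignalTrack({"c": np.concatenate([np.ones(150_000) * 3,
                                              np.ones(150_000)])})
        genes = [GeneModel("lo", "c", 200_000, 220_001, "+"),
                 GeneModel("hi", "c", 50_000, 70_001, "+")]
        mg = build_metagene(t, genes)
        assert list(mg.matrix.index) == ["hi", "lo"]

    def test_replicates_averaged(self):
        a = SignalTrack({"c": np.ones(300_000)})
        b = SignalTrack({"c": np.ones(300_000) * 3})
        genes = [GeneModel("g", "c", 50_000, 70_001, "+")]
        mg = build_metagene([a, b], genes)
        assert np.allclose(mg.matrix.to_numpy(), 2.0)
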