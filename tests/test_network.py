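"""Peak filtering, regulatory domains and network statistics vs oracles."""

from collections import Counter
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from conftest import random_bed
from tfinet import network as net
from tfinet import simulate as sim
from tfinet.intervals import (count_overlaps, to_one_based_closed,
                              to_zero_based_half_open)


def bed(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                       "score", "strand"])


def reads_at(chrom, positions, length=10):
    return bed([(chrom, p, p + length, ".", 0.0, "+") for p in positions])


class TestRegionRpkm:
    def test_hand_arithmetic(self):
        region = bed([("chr1", 0, 1000, "r", 0.0, ".")])
        reads = reads_at("chr1", range(100, 200, 10))  # 10 reads inside
        rpkm = net.region_rpkm(reads, region, library_size=1_000_000)
        assert rpkm[0] == pytest.approx(10.0)

    def test_no_overlap_zero(self):
        region = bed([("chr1", 5000, 6000, "r", 0.0, ".")])
        reads = reads_at("chr1", [0, 100])
        assert net.region_rpkm(reads, region)[0] == 0.0

    def test_doubling_length_halves_rpkm(self):
        reads = reads_at("chr1", range(0, 500, 10))
        r1 = net.region_rpkm(reads, bed([("chr1", 0, 1000, "a", 0.0, ".")]))
        r2 = net.region_rpkm(reads, bed([("chr1", 0, 2000, "b", 0.0, ".")]))
        assert r2[0] == pytest.approx(r1[0] / 2)

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(5)
        regions = random_bed(rng, 40)
        reads = random_bed(rng, 300, width=(10, 60))
        fast = count_overlaps(regions, reads)
        for i, reg in regions.iterrows():
            brute = sum((r["chrom"] == reg["chrom"]) and
                        (r["start"] < reg["end"]) and (r["end"] > reg["start"])
                        for _, r in reads.iterrows())
            assert fast[i] == brute


class TestFilterPeaks:
    def _tiled_peaks(self, n=100, width=1000):
        return bed([("chr1", i * 10_000, i * 10_000 + width, f"p{i}", 0.0, ".")
                    for i in range(n)])

    def test_single_enriched_peak_retained(self):
        peaks = self._tiled_peaks()
        # input: exactly 5 reads per peak region -> flat RPKM vector
        inp = pd.concat([reads_at("chr1", range(s, s + 50, 10))
                         for s in peaks["start"]], ignore_index=True)
        extra = reads_at("chr1", range(0, 900, 10))  # 90 extra reads in p0
        chip = pd.concat([inp, extra], ignore_index=True)
        kept = net.filter_peaks(peaks, chip, inp, percentile=99)
        assert list(kept["name"]) == ["p0"]

    def test_chip_identical_to_input_keeps_about_one_percent(self):
        rng = np.random.default_rng(1)
        peaks = self._tiled_peaks(n=500)
        track = random_bed(rng, 20_000, chroms=("chr1",),
                           span=5_000_000, width=(50, 51))
        kept = net.filter_peaks(peaks, track, track, percentile=99)
        assert len(kept) <= 0.02 * len(peaks)

    def test_percentile_zero_boundary(self):
        peaks = self._tiled_peaks(n=10)
        inp = pd.concat([reads_at("chr1", range(s, s + (i + 1) * 10, 10))
                         for i, s in enumerate(peaks["start"])],
                        ignore_index=True)
        kept = net.filter_peaks(peaks, inp, inp, percentile=0)
        # everything above the minimum input RPKM survives
        rpkm = net.region_rpkm(inp, peaks)
        assert len(kept) == (rpkm > rpkm.min()).sum()

    def test_monotone_in_percentile(self):
        rng = np.random.default_rng(2)
        peaks = self._tiled_peaks(n=60)
        chip = random_bed(rng, 5000, chroms=("chr1",), span=600_000)
        inp = random_bed(rng, 5000, chroms=("chr1",), span=600_000)
        prev = None
        for pct in (0, 25, 50, 75, 90, 99, 100):
            kept = set(net.filter_peaks(peaks, chip, inp, percentile=pct)["name"])
            if prev is not None:
                assert kept <= prev
            prev = kept

    def test_per_region_mode(self):
        peaks = self._tiled_peaks(n=3)
        inp = pd.concat([reads_at("chr1", range(s, s + 100, 10))
                         for s in peaks["start"]], ignore_index=True)
        chip = pd.concat([inp, reads_at("chr1", range(0, 500, 10))],
                         ignore_index=True)
        kept = net.filter_peaks(peaks, chip, inp, percentile=99,
                                mode="per-region")
        assert list(kept["name"]) == ["p0"]

    def test_all_filtered_warns_not_raises(self):
        peaks = self._tiled_peaks(n=5)
        inp = pd.concat([reads_at("chr1", range(s, s + 100, 10))
                         for s in peaks["start"]], ignore_index=True)
        empty_chip = reads_at("chr1", [999_999])
        with pytest.warns(UserWarning, match="all peaks removed"):
            kept = net.filter_peaks(peaks, empty_chip, inp)
        assert len(kept) == 0


def brute_force_domains(genes, basal_up=5000, basal_down=1000,
                        max_ext=1_000_000, chrom_sizes=None):
    """Reference: O(n^2) scan over all other genes' basal domains."""
    chrom_sizes = chrom_sizes or {}
    rows = []
    recs = genes.to_dict("records")
    basal = []
    for g in recs:
        size = chrom_sizes.get(g["chrom"], 2**62)
        tss = g["start"] if g["strand"] == "+" else g["end"]
        if g["strand"] == "+":
            bs, be = tss - basal_up, tss + basal_down
        else:
            bs, be = tss - basal_down, tss + basal_up
        basal.append((g["chrom"], max(0, min(bs, size)),
                      max(0, min(be, size)), tss, size))
    for i, g in enumerate(recs):
        chrom, bs, be, tss, size = basal[i]
        left = max(0, tss - max_ext)
        right = min(size, tss + max_ext)
        for j, h in enumerate(recs):
            if i == j or basal[j][0] != chrom:
                continue
            _, hbs, hbe, _, _ = basal[j]
            if hbs < bs:  # neighbor to the left: its basal end blocks us
                left = max(left, hbe)
            if hbs > bs:  # neighbor to the right: its basal start blocks us
                right = min(right, hbs)
        rows.append({"name": g["name"], "basal_start": bs, "basal_end": be,
                     "ext_start": min(bs, left), "ext_end": max(be, right)})
    return pd.DataFrame(rows).set_index("name")


class TestRegulatoryDomains:
    def test_lone_gene_capped_by_max_ext_and_chromosome(self):
        genes = bed([("chr1", 100_000, 105_000, "g1", 0.0, "+")])
        dom = net.regulatory_domains(genes, chrom_sizes={"chr1": 1_000_000})
        row = dom.iloc[0]
        assert (row["basal_start"], row["basal_end"]) == (95_000, 101_000)
        assert (row["ext_start"], row["ext_end"]) == (0, 1_000_000)

    def test_two_close_genes_stop_at_neighbor_basal(self):
        genes = bed([("chr1", 100_000, 102_000, "g1", 0.0, "+"),
                     ("chr1", 103_000, 105_000, "g2", 0.0, "+")])
        dom = net.regulatory_domains(genes).set_index("name")
        # g2 basal starts at 98000, inside g1's basal: g1 cannot extend
        # right beyond its own basal end
        assert dom.loc["g1", "ext_end"] == 101_000
        # and g1's basal (95000..101000) blocks g2's leftward extension,
        # but never below g2's own basal start
        assert dom.loc["g2", "ext_start"] == 98_000

    def test_tss_near_chromosome_start_clipped(self):
        genes = bed([("chr1", 2000, 9000, "g1", 0.0, "+")])
        dom = net.regulatory_domains(genes, chrom_sizes={"chr1": 500_000})
        assert dom.iloc[0]["basal_start"] == 0
        assert dom.iloc[0]["basal_end"] == 3000

    def test_unstranded_gene_errors(self):
        genes = bed([("chr1", 100, 200, "g1", 0.0, ".")])
        with pytest.raises(ValueError, match="unstranded"):
            net.regulatory_domains(genes)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_annotations(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 25))
        genes = random_bed(rng, n, span=200_000, width=(500, 5000))
        genes["strand"] = rng.choice(["+", "-"], size=n)
        sizes = {"chr1": 250_000, "chr2": 250_000}
        got = net.regulatory_domains(
            genes, basal_up=5000, basal_down=1000, max_ext=50_000,
            chrom_sizes=sizes).set_index("name")
        want = brute_force_domains(genes, basal_up=5000, basal_down=1000,
                                   max_ext=50_000, chrom_sizes=sizes)
        for name, w in want.iterrows():
            g = got.loc[name]
            assert (g["ext_start"], g["ext_end"]) == \
                (w["ext_start"], w["ext_end"]), name
            # invariants: extension never crosses a neighbor basal domain
            assert g["ext_start"] <= g["basal_start"]
            assert g["ext_end"] >= g["basal_end"]

    def test_roundtrip_base_conventions(self):
        rng = np.random.default_rng(3)
        df = random_bed(rng, 20)
        back = to_zero_based_half_open(to_one_based_closed(df))
        pd.testing.assert_frame_equal(df, back)


def brute_force_assign(peaks_by_tf, domains):
    edges = set()
    for tf, peaks in peaks_by_tf.items():
        for _, p in peaks.iterrows():
            for _, d in domains.iterrows():
                if p["chrom"] == d["chrom"] and \
                   p["start"] < d["ext_end"] and p["end"] > d["ext_start"]:
                    edges.add((tf, d["name"]))
    return pd.DataFrame(sorted(edges), columns=["tf", "gene"])


class TestAssignPeaks:
    def _domains(self):
        genes = bed([("chr1", 50_000, 60_000, "gA", 0.0, "+"),
                     ("chr1", 80_000, 90_000, "gB", 0.0, "-")])
        return net.regulatory_domains(genes, chrom_sizes={"chr1": 200_000})

    def test_peak_in_single_basal_domain(self):
        dom = self._domains()
        peaks = {"T": bed([("chr1", 49_000, 49_400, "p", 0.0, ".")])}
        edges = net.assign_peaks(peaks, dom)
        assert list(edges.itertuples(index=False, name=None)) == [("T", "gA")]

    def test_peak_in_two_overlapping_domains(self):
        genes = bed([("chr1", 50_000, 52_000, "gA", 0.0, "+"),
                     ("chr1", 53_000, 55_000, "gB", 0.0, "+")])
        dom = net.regulatory_domains(genes)
        peaks = {"T": bed([("chr1", 49_500, 49_900, "p", 0.0, ".")])}
        edges = net.assign_peaks(peaks, dom)
        assert set(edges.itertuples(index=False, name=None)) == \
            {("T", "gA"), ("T", "gB")}

    def test_peak_outside_all_domains(self):
        genes = bed([("chr1", 50_000, 60_000, "gA", 0.0, "+")])
        dom = net.regulatory_domains(genes, max_ext=10_000,
                                     chrom_sizes={"chr1": 500_000})
        peaks = {"T": bed([("chr1", 300_000, 300_400, "p", 0.0, ".")])}
        assert len(net.assign_peaks(peaks, dom)) == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_fixtures(self, seed):
        rng = np.random.default_rng(100 + seed)
        genes = random_bed(rng, int(rng.integers(3, 15)), span=300_000)
        genes["strand"] = rng.choice(["+", "-"], size=len(genes))
        dom = net.regulatory_domains(genes, max_ext=30_000,
                                     chrom_sizes={"chr1": 350_000,
                                                  "chr2": 350_000})
        peaks_by_tf = {f"TF{i}": random_bed(rng, int(rng.integers(1, 20)),
                                            span=340_000, width=(100, 500))
                       for i in range(3)}
        got = net.assign_peaks(peaks_by_tf, dom)
        want = brute_force_assign(peaks_by_tf, dom)
        pd.testing.assert_frame_equal(got, want)


class TestNetworkStatistics:
    def _edges(self, pairs):
        return pd.DataFrame(pairs, columns=["tf", "gene"])

    def test_binding_combinations(self):
        edges = self._edges([("A", "g1"), ("B", "g1"), ("A", "g2"),
                             ("B", "g2"), ("A", "g3")])
        combos = net.binding_combinations(edges, ["g1", "g2", "g3", "g4"])
        assert combos[frozenset("AB")] == 2
        assert combos[frozenset("A")] == 1
        assert combos[frozenset()] == 1

    def test_empty_network_all_empty_combos(self):
        combos = net.binding_combinations(self._edges([]), ["g1", "g2"])
        assert combos == Counter({frozenset(): 2})

    def test_any_of_fraction_matches_truth(self, chip_fixture):
        ann, specs, peaks, reads, inp, truth = chip_fixture
        edges, _ = net.build_network(peaks, reads, inp, ann)
        targets = sorted({g for s in specs.values() for g in s.targets})
        four = list(specs)[:4]
        from_truth = np.mean([
            bool(truth.regulators.get(g, set()) & set(four))
            for g in targets])
        assert net.any_of_fraction(edges, targets, four) == pytest.approx(
            from_truth)

    def test_indegree_distribution(self):
        edges = self._edges([(f"TF{i}", "hub") for i in range(6)]
                            + [("TF0", "g1")])
        h_set, h_bg = net.indegree_distribution(edges, ["hub"],
                                                ["hub", "g1", "g2"], n_tfs=6)
        assert h_set[6] == 1.0
        assert h_set.sum() == pytest.approx(1.0)
        assert h_bg.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(h_bg, [1 / 3, 1 / 3, 0, 0, 0, 0, 1 / 3])

    def test_planted_high_indegree_dominates_background(self, chip_fixture):
        ann, specs, peaks, reads, inp, truth = chip_fixture
        edges, _ = net.build_network(peaks, reads, inp, ann)
        targets = sorted({g for s in specs.values() for g in s.targets})
        allg = list(ann["name"])
        h_set, h_bg = net.indegree_distribution(edges, targets, allg, n_tfs=6)
        # stochastic dominance of the planted-target CDF
        assert (np.cumsum(h_set) <= np.cumsum(h_bg) + 1e-12).all()

    def test_bound_set_enrichment_disjoint(self):
        edges = self._edges([("A", "g1")])
        res = net.bound_set_enrichment(edges, "A", ["g2", "g3"],
                                       ["g1", "g2", "g3", "g4"])
        assert res.p == 1.0


def brute_force_triads(edge_set, tf_gene_map):
    tfs = sorted(tf_gene_map)
    triads = []
    for trio in combinations(tfs, 3):
        ok = True
        for a in trio:
            for b in trio:
                if (a, tf_gene_map[b]) not in edge_set:
                    ok = False
        if ok:
            triads.append(trio)
    return triads


class TestCoreCircuitry:
    def _map(self, tfs):
        return {tf: f"gene_{tf}" for tf in tfs}

    def _edges_df(self, edge_set):
        return pd.DataFrame(sorted(edge_set), columns=["tf", "gene"])

    def test_full_triad_detected(self):
        tfs = ["A", "B", "C"]
        m = self._map(tfs)
        edges = {(a, m[b]) for a in tfs for b in tfs}
        rep = net.core_circuitry(self._edges_df(edges), m)
        assert rep["fully_connected_triads"] == [("A", "B", "C")]
        assert all(rep["autoregulatory"].values())

    def test_missing_autoregulation_breaks_triad(self):
        tfs = ["A", "B", "C"]
        m = self._map(tfs)
        edges = {(a, m[b]) for a in tfs for b in tfs} - {("A", m["A"])}
        rep = net.core_circuitry(self._edges_df(edges), m)
        assert rep["fully_connected_triads"] == []

    def test_two_overlapping_triads(self):
        tfs = ["A", "B", "C", "D"]
        m = self._map(tfs)
        edges = ({(a, m[b]) for a in "ABC" for b in "ABC"}
                 | {(a, m[b]) for a in "BCD" for b in "BCD"})
        rep = net.core_circuitry(self._edges_df(edges), m)
        assert rep["fully_connected_triads"] == [("A", "B", "C"),
                                                 ("B", "C", "D")]

    def test_unmapped_tf_warns(self):
        edges = self._edges_df({("A", "gene_A"), ("X", "gene_A")})
        with pytest.warns(UserWarning, match="X"):
            rep = net.core_circuitry(edges, {"A": "gene_A"})
        assert "X" not in rep["autoregulatory"]

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_exhaustive_on_random_networks(self, seed):
        rng = np.random.default_rng(seed)
        n_tf = int(rng.integers(3, 7))
        tfs = [f"T{i}" for i in range(n_tf)]
        m = self._map(tfs)
        edges = {(a, m[b]) for a in tfs for b in tfs
                 if rng.random() < 0.6}
        rep = net.core_circuitry(self._edges_df(edges), m)
        assert rep["fully_connected_triads"] == brute_force_triads(edges, m)
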