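"""Consensus building, quantification, region assignment, integration."""
import numpy as np
import pandas as pd
import pytest

from runxpipe.annotation import GeneModel, GenomeAnnotation
from runxpipe.config import SimulationConfig
from runxpipe.peaks import (annotate_peaks, build_consensus, cpm_log2,
                            density_profile, filter_low_count,
                            integrate_with_degs, peak_log2fc)
from runxpipe.simulate import (PeakCallSet, simulate_annotation,
                               simulate_expression, simulate_peak_calls)


def callset(pair_id, ivals, genotype="WT", library=10**6, sample_id=None):
    df = pd.DataFrame(ivals, columns=["chrom", "start", "end", "read_count"])
    df.insert(3, "name", [f"p{i}" for i in range(len(df))])
    return PeakCallSet(sample_id=sample_id or pair_id, pair_id=pair_id,
                       genotype=genotype, library_size=library, intervals=df)


def brute_force_consensus(call_sets, min_support=2):
    """O(n^2) union-find over pairwise per-base overlaps; oracle only."""
    rows = []
    for cs in call_sets:
        for r in cs.intervals.itertuples():
            rows.append((r.chrom, r.start, r.end, cs.pair_id))
    parent = list(range(len(rows)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            a, b = rows[i], rows[j]
            if a[0] == b[0] and set(range(a[1], a[2])) & set(range(b[1], b[2])):
                parent[find(i)] = find(j)
    comps = {}
    for i in range(len(rows)):
        comps.setdefault(find(i), []).append(rows[i])
    out = []
    for members in comps.values():
        pairs = {m[3] for m in members}
        if len(pairs) >= min_support:
            out.append((members[0][0], min(m[1] for m in members),
                        max(m[2] for m in members), len(pairs)))
    return sorted(out)


class TestFilterLowCount:
    def test_retains_strictly_above_twenty_reads(self):
        cs = callset("w1", [("chr1", i * 100, i * 100 + 50, c)
                            for i, c in enumerate([5, 20, 21, 100])])
        kept = filter_low_count(cs)
        assert kept.intervals["read_count"].tolist() == [21, 100]

    def test_all_zero_counts_empties_the_set(self):
        cs = callset("w1", [("chr1", 0, 50, 0), ("chr1", 100, 150, 0)])
        assert len(filter_low_count(cs).intervals) == 0

    def test_no_low_counts_is_identity(self):
        ivals = [("chr1", 0, 50, 30), ("chr1", 100, 150, 99)]
        cs = callset("w1", ivals)
        pd.testing.assert_frame_equal(filter_low_count(cs).intervals,
                                      cs.intervals)


class TestBuildConsensus:
    def test_identical_interval_everywhere_gives_support_six(self):
        sets = [callset(f"p{i}", [("chr1", 100, 200, 30)]) for i in range(6)]
        table = build_consensus(sets)
        assert len(table) == 1
        row = table.peaks.iloc[0]
        assert (row.start, row.end, row.support) == (100, 200, 6)
        assert table.counts.iloc[0].tolist() == [30] * 6

    def test_disjoint_singletons_yield_nothing(self):
        sets = [callset("p1", [("chr1", 0, 100, 30)]),
                callset("p2", [("chr1", 500, 600, 30)])]
        assert len(build_consensus(sets, min_support=2)) == 0

    def test_overlap_merges_to_the_union_interval(self):
        sets = [callset("p1", [("chr1", 100, 200, 30)]),
                callset("p2", [("chr1", 150, 250, 40)])]
        table = build_consensus(sets, min_support=2)
        row = table.peaks.iloc[0]
        assert (row.start, row.end, row.support) == (100, 250, 2)

    def test_touching_intervals_do_not_merge(self):
        # half-open [100,200) and [200,300) share no base
        sets = [callset("p1", [("chr1", 100, 200, 30)]),
                callset("p2", [("chr1", 200, 300, 40)])]
        assert len(build_consensus(sets, min_support=2)) == 0

    def test_same_pair_alone_never_reaches_support_two(self):
        sets = [callset("p1", [("chr1", 100, 200, 30)], sample_id="chip"),
                callset("p1", [("chr1", 150, 250, 40)], sample_id="chip2")]
        assert len(build_consensus(sets, min_support=2)) == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sets = []
        for p in range(4):
            n = rng.integers(3, 9)
            starts = rng.integers(0, 9500, size=n)
            ivals = [("chr1", int(s), int(s + rng.integers(50, 400)),
                      int(rng.integers(21, 200))) for s in starts]
            sets.append(callset(f"pair{p}", ivals))
        table = build_consensus(sets, min_support=2)
        got = sorted((r.chrom, r.start, r.end, r.support)
                     for r in table.peaks.itertuples())
        assert got == brute_force_consensus(sets, min_support=2)


class TestQuantification:
    def test_cpm_and_log2_cpm_formulas(self):
        sets = [callset(f"p{i}", [("chr1", 0, 100, 10), ("chr1", 500, 600, 0)])
                for i in range(2)]
        table = cpm_log2(build_consensus(sets))
        assert table.cpm.iloc[0, 0] == pytest.approx(10.0)
        assert table.log2_cpm.iloc[0, 0] == pytest.approx(np.log2(11),
                                                          abs=1e-9)
        assert table.log2_cpm.iloc[1, 0] == 0.0  # log2(0 cpm + 1)

    def test_cpm_is_scale_invariant(self):
        a = [callset(f"p{i}", [("chr1", 0, 100, 50)], library=10**6)
             for i in range(2)]
        b = [callset(f"p{i}", [("chr1", 0, 100, 100)], library=2 * 10**6)
             for i in range(2)]
        ta, tb = cpm_log2(build_consensus(a)), cpm_log2(build_consensus(b))
        assert np.allclose(ta.cpm.to_numpy(), tb.cpm.to_numpy())

    def test_log2fc_of_constant_groups(self):
        sets = []
        for geno, count in (("WT", 100), ("K129R", 100)):
            for r in range(2):
                sets.append(callset(f"{geno}_{r}",
                                    [("chr1", 0, 100, count)],
                                    genotype=geno, library=10**5))
        table = cpm_log2(build_consensus(sets))
        assert peak_log2fc(table, "K129R").iloc[0] == pytest.approx(0.0)
        # doubling mutant counts: log2((2000+1)/(1000+1)) on the cpm scale
        for cs in sets[2:]:
            cs.intervals["read_count"] *= 2
        table = cpm_log2(build_consensus(sets))
        expected = np.log2(2001) - np.log2(1001)
        assert peak_log2fc(table, "K129R").iloc[0] == pytest.approx(expected)

    def test_unknown_genotype_rejected(self):
        sets = [callset(f"p{i}", [("chr1", 0, 100, 10)]) for i in range(2)]
        table = cpm_log2(build_consensus(sets))
        with pytest.raises(ValueError, match="absent"):
            peak_log2fc(table, "K999R")


def hand_annotation():
    """Two-exon genes on both strands for strand-flip assignment checks."""
    plus = GeneModel(gene_id="gA", chrom="chrS", start=10_000, end=15_999,
                     strand="+",
                     exons=[(10_000, 10_999), (14_000, 15_999)],
                     five_utr=[(10_000, 10_199)],
                     cds=[(10_200, 10_999), (14_000, 14_999)],
                     three_utr=[(15_000, 15_999)])
    minus = GeneModel(gene_id="gB", chrom="chrS", start=40_000, end=45_999,
                      strand="-",
                      exons=[(40_000, 41_999), (45_000, 45_999)],
                      five_utr=[(45_800, 45_999)],
                      cds=[(45_000, 45_799), (40_200, 41_999)],
                      three_utr=[(40_000, 40_199)])
    return GenomeAnnotation(genes=[plus, minus], chrom="chrS",
                            chrom_length=100_000)


class TestRegionAssignment:
    @pytest.mark.parametrize("pos,expected", [
        (9_900, ("promoter", "gA")),        # 100 bp upstream of + TSS
        (10_100, ("promoter", "gA")),       # inside 5'UTR but promoter wins
        (10_700, ("CDS", "gA")),
        (12_000, ("first_intron", "gA")),
        (15_500, ("three_prime_UTR", "gA")),
        (16_500, ("downstream", "gA")),
        (30_000, ("intergenic", None)),     # ~14 kb from either gene
        (46_100, ("promoter", "gB")),       # upstream on the - strand
        (43_000, ("first_intron", "gB")),   # intron nearest the - TSS
        (39_000, ("downstream", "gB")),
        (40_100, ("three_prime_UTR", "gB")),
    ])
    def test_center_classification_with_strand_awareness(self, pos, expected):
        assert hand_annotation().assign(pos) == expected

    def test_position_outside_chromosome_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            hand_annotation().assign(200_000)

    def test_equidistant_tss_tie_breaks_lexicographically(self):
        a = GeneModel(gene_id="gA", chrom="c", start=10_000, end=16_000,
                      strand="+", exons=[(10_000, 11_000), (15_000, 16_000)],
                      five_utr=[], cds=[], three_utr=[])
        b = GeneModel(gene_id="gB", chrom="c", start=6_000, end=8_200,
                      strand="-", exons=[(6_000, 7_000), (8_000, 8_200)],
                      five_utr=[], cds=[], three_utr=[])
        ann = GenomeAnnotation(genes=[a, b], chrom="c", chrom_length=30_000)
        # position 9100: 900 bp from both TSSs (8200 and 10000), promoter of both
        label, gene = ann.assign(9_100)
        assert label == "promoter" and gene == "gA"

    def test_every_consensus_peak_gets_exactly_one_label(self, small_config):
        m, truth = simulate_expression(small_config)
        ann = simulate_annotation(small_config)
        sets = simulate_peak_calls(small_config, ann, truth)
        table = annotate_peaks(build_consensus(sets), ann)
        labels = table.peaks["region_label"]
        assert labels.notna().all()
        valid = {"promoter", "five_prime_UTR", "CDS", "first_intron",
                 "other_introns", "three_prime_UTR", "downstream",
                 "intergenic"}
        assert set(labels) <= valid


class TestDensityProfile:
    def test_uniform_coverage_fills_all_bins(self):
        prof = density_profile(np.full(4000, 3.0), library_size=10**6)
        assert prof.shape == (80,)
        assert np.allclose(prof, 3.0)

    def test_delta_at_center_hits_bin_forty(self):
        cov = np.zeros(4000)
        cov[2000] = 50.0
        prof = density_profile(cov, library_size=10**6)
        assert np.flatnonzero(prof).tolist() == [40]

    def test_bin_must_divide_window(self):
        with pytest.raises(ValueError, match="divide"):
            density_profile(np.zeros(4000), 10**6, bin_size=33)


class TestIntegrateWithDegs:
    def _pipeline(self, cfg):
        m, truth = simulate_expression(cfg)
        ann = simulate_annotation(cfg)
        sets = simulate_peak_calls(cfg, ann, truth)
        table = cpm_log2(build_consensus(sets))
        peak_log2fc(table, "K129R")
        return annotate_peaks(table, ann), truth

    def test_empty_deg_table_puts_every_peak_in_non_deg(self, small_config):
        table, _ = self._pipeline(small_config)
        rc = integrate_with_degs(table, pd.DataFrame(columns=["call"]),
                                 comparison="K129R_vs_WT")
        n_promoter = (table.peaks["region_label"] == "promoter").sum()
        assert len(rc.class_values["non_deg"]) == n_promoter
        assert len(rc.class_values["up"]) == 0

    def test_planted_promoter_effect_orders_the_class_means(self):
        cfg = SimulationConfig(n_genes=120, n_peaks=120, deg_fraction=0.3,
                               peak_effect_log2=1.0, library_size=120_000,
                               seed=17)
        table, truth = self._pipeline(cfg)
        degs = truth.deg_labels.rename(columns={"K129R_vs_WT": "call"})
        degs["call"] = degs["call"].replace({"null": "non_deg"})
        rc = integrate_with_degs(table, degs[["call"]],
                                 comparison="K129R_vs_WT")
        assert rc.class_means["up"] > rc.class_means["non_deg"] \
            > rc.class_means["down"]
        assert rc.anova_p < 0.001
        assert rc.tukey is not None and len(rc.tukey) == 3
        # the intersection table lists DEGs whose promoter binding rose
        assert set(rc.deg_increased_binding["call"]) <= {"up", "down"}
        up_genes = set(degs.index[degs["call"] == "up"])
        listed_up = set(rc.deg_increased_binding.loc[
            rc.deg_increased_binding["call"] == "up", "gene_id"])
        assert len(listed_up & up_genes) >= 0.8 * len(up_genes)

    def test_single_class_emits_warning_but_still_reports_ecdf(self):
        cfg = SimulationConfig(n_genes=30, n_peaks=30, deg_fraction=0.0,
                               library_size=30_000, seed=3)
        table, _ = self._pipeline(cfg)
        with pytest.warns(UserWarning, match="ANOVA skipped"):
            rc = integrate_with_degs(table, pd.DataFrame(columns=["call"]),
                                     comparison="K129R_vs_WT")
        assert rc.anova_p is None and "non_deg" in rc.ecdf
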