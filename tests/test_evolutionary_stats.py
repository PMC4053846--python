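import numpy as np
import pytest
from scipy import stats as sps

from editoscreen.conservation_screen import GenomicWindow, extract_window
from editoscreen.evolutionary_stats import (
    accumulation_curve,
    classify_regions,
    find_ecs,
    fisher_exact_2x2,
    motif_matrix,
    parse_aa_change,
    reversion_analysis,
)
from editoscreen.io_formats import SiteRecord, reverse_complement
from editoscreen.synthetic_data import (
    SimulationConfig,
    simulate_motif_windows,
    simulate_ortholog_pair,
)
from oracles import fisher_exact_enumeration, minimal_addition_order


class TestAccumulationCurve:
    def test_worked_example(self):
        curve = accumulation_curve(
            {"s1": {"a"}, "s2": {"a", "b"}, "s3": {"c", "d", "e"}}
        )
        assert curve.ordered_samples == ["s1", "s2", "s3"]
        assert curve.cumulative_counts == [1, 2, 5]

    def test_single_sample(self):
        curve = accumulation_curve({"s1": {"a", "b"}})
        assert curve.ordered_samples == ["s1"]
        assert curve.cumulative_counts == [2]

    def test_identical_sets_add_nothing(self):
        curve = accumulation_curve({"s1": set(range(5)),
                                    "s2": set(range(5))})
        assert curve.cumulative_counts == [5, 5]

    def test_greedy_equals_exhaustive_search(self):
        """Greedy order matches the permutation-filter oracle on random
        instances with <= 6 samples."""
        rng = np.random.default_rng(31)
        for _ in range(100):
            n_samples = int(rng.integers(2, 7))
            sets = {
                f"s{k}": {
                    int(x) for x in rng.choice(8, size=rng.integers(0, 8),
                                               replace=False)
                }
                for k in range(n_samples)
            }
            if not any(sets.values()):
                sets["s0"] = {0}
            got = accumulation_curve(sets)
            order, cum = minimal_addition_order(sets)
            assert got.ordered_samples == order
            assert got.cumulative_counts == cum

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            accumulation_curve({})


class TestMotifMatrix:
    @staticmethod
    def _uniform_windows(n, seed=0):
        return simulate_motif_windows(n, p_up_g=0.25, p_down_g=0.25,
                                      seed=seed)

    def test_identical_windows_are_degenerate(self):
        w = simulate_motif_windows(1, 0.0, 1.0, seed=5)[0]
        mm = motif_matrix([w] * 10)
        assert (mm.frequencies.max(axis=1) == 1.0).all()

    def test_rows_are_probability_vectors_and_center_is_a(self):
        mm = motif_matrix(self._uniform_windows(500))
        sums = mm.frequencies.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)
        assert mm.frequencies.loc[0, "A"] == 1.0

    def test_uniform_windows_near_quarter(self):
        mm = motif_matrix(self._uniform_windows(10_000, seed=2))
        off_center = mm.frequencies.drop(index=0)
        assert ((off_center - 0.25).abs() < 0.02).all().all()

    def test_planted_neighbor_bias_recovered(self):
        windows = simulate_motif_windows(5000, p_up_g=0.05, p_down_g=0.45,
                                         seed=3)
        mm = motif_matrix(windows)
        assert mm.frequencies.loc[-1, "G"] == pytest.approx(0.05, abs=0.02)
        assert mm.frequencies.loc[1, "G"] == pytest.approx(0.45, abs=0.02)

    def test_information_content_range(self):
        mm = motif_matrix(self._uniform_windows(200))
        ic = mm.information_content()
        assert ic.loc[0] == pytest.approx(2.0)
        assert ((ic >= -1e-9) & (ic <= 2 + 1e-9)).all()


class TestClassifyRegions:
    def test_aa_change_semantics(self):
        assert parse_aa_change("NM_032195:c.A1782G:p.L594L") == ("L", "L")
        assert parse_aa_change("NM_000384:c.C6538G:p.Q2180stop") == \
            ("Q", "stop")
        assert parse_aa_change(None) is None
        assert parse_aa_change("NM_000826") is None
        r = classify_regions([
            SiteRecord(species="h", chrom="c", pos1=1, strand="+", gene="g",
                       region="CDS", substitution="x:c.A1G:p.L594L"),
            SiteRecord(species="h", chrom="c", pos1=2, strand="+", gene="g",
                       region="CDS", substitution="x:c.A2G:p.Q2180stop"),
            SiteRecord(species="h", chrom="c", pos1=3, strand="+", gene="g",
                       region="CDS", substitution="x:c.A3G:p.Q607R"),
        ])
        assert r.synonymous == 1
        assert r.nonsynonymous == 2

    def test_table1_region_counts(self, ess_table1):
        r = classify_regions(ess_table1)
        assert r.total == 59
        assert r.intronic == 17
        assert r.region_counts["microRNA"] == 2
        assert r.region_counts["3UTR"] == 2
        assert r.cds_rows == 38
        assert r.annotated_cds == 37

    def test_table1_recoding_statistics(self, ess_table1):
        r = classify_regions(ess_table1)
        assert r.nonsynonymous == 35
        assert r.synonymous == 2  # SON p.L594L and AZIN1 p.E366E
        assert r.intronic_in_recoding_genes == 13

    def test_per_gene_grouping(self, ess_table1):
        r = classify_regions(ess_table1)
        assert r.per_gene["GRIA4"] == {"CDS": 1, "intron": 5}
        assert r.per_gene["SLC9A6"] == {"intron": 2}


class TestFisherExact:
    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 101, size=4))
            table = [[a, b], [c, d]]
            assert fisher_exact_2x2(table) == pytest.approx(
                fisher_exact_enumeration(table), abs=1e-12
            )

    def test_matches_scipy_on_non_tie_table(self):
        table = [[26, 74], [18, 82]]
        assert fisher_exact_2x2(table) == pytest.approx(
            sps.fisher_exact(table)[1], rel=1e-9
        )

    def test_degenerate_margins(self):
        assert fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0
        assert fisher_exact_2x2([[5, 0], [7, 0]]) == 1.0


class TestReversion:
    def test_worked_contingency_arithmetic(self):
        table = [[26, 74], [18, 82]]
        odds = (26 * 82) / (74 * 18)
        assert odds == pytest.approx(1.6006006, abs=1e-6)
        assert fisher_exact_2x2(table) == pytest.approx(
            fisher_exact_enumeration(table), abs=1e-12
        )

    def test_planted_fractions_recovered(self):
        cfg = SimulationConfig(
            seed=41, n_conserved_sites=5, n_query_only_sites=250,
            n_subject_only_sites=250, n_snps_per_species=0,
            n_shared_snps=0, n_strains=2, chrom_length=40_000,
        )
        qg, sg, truth = simulate_ortholog_pair(cfg)
        rev = reversion_analysis(truth.query_sites, truth.subject_sites,
                                 qg, sg)
        # matched counterparts reproduce the planted truth exactly
        planted_g = sum(
            1 for s in truth.query_sites
            if truth.counterpart_query_to_subject[s.key] == "G"
        )
        assert rev.forward.counterpart_base_counts.get("G", 0) == planted_g
        assert rev.forward.matched_sites + rev.forward.unmatched_sites == \
            len(truth.query_sites)
        assert rev.forward.fraction_g == pytest.approx(
            planted_g / rev.forward.matched_sites
        )
        # control As sit in diverged background; G fraction stays near d/3
        assert rev.forward.control_fraction_g < 0.1

    def test_symmetric_null_covers_one(self):
        """With equal planted reversion rates the odds-ratio CI straddles 1."""
        tables = []
        for seed in range(3):
            cfg = SimulationConfig(
                seed=100 + seed, n_conserved_sites=5,
                n_query_only_sites=120, n_subject_only_sites=120,
                n_snps_per_species=0, n_shared_snps=0, n_strains=2,
                reversion_fraction_query=0.2,
                reversion_fraction_subject=0.2, chrom_length=35_000,
            )
            qg, sg, truth = simulate_ortholog_pair(cfg)
            rev = reversion_analysis(truth.query_sites, truth.subject_sites,
                                     qg, sg)
            tables.append(np.array(rev.contingency))
        pooled = sum(tables)
        ci = sps.contingency.odds_ratio(pooled).confidence_interval(0.95)
        assert ci.low <= 1.0 <= ci.high


class TestFindEcs:
    @staticmethod
    def _window(seed=9, flank=40):
        rng = np.random.default_rng(seed)
        seq = list(rng.choice(list("ACGT"), size=2 * flank + 1))
        seq[flank] = "A"
        site = SiteRecord(species="h", chrom="c", pos1=1000, strand="+")
        return GenomicWindow(site=site, seq="".join(seq), center_index=flank)

    @staticmethod
    def _random_seq(rng, n):
        return "".join(rng.choice(list("ACGT"), size=n))

    def test_planted_perfect_complement_found(self):
        rng = np.random.default_rng(10)
        w = self._window()
        search = w.seq + self._random_seq(rng, 500) + \
            reverse_complement(w.seq)
        hits = find_ecs(w.site, search, w, window_start0=0)
        assert len(hits) == 1
        h = hits[0]
        assert h.identical == 81
        assert (h.start0, h.end0) == (581, 662)

    def test_planted_complement_with_8_substitutions(self):
        rng = np.random.default_rng(11)
        w = self._window(seed=12)
        ecs = list(reverse_complement(w.seq))
        for p in (5, 15, 25, 35, 45, 55, 65, 75):
            ecs[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[ecs[p]]
        search = w.seq + self._random_seq(rng, 300) + "".join(ecs)
        hits = find_ecs(w.site, search, w, window_start0=0)
        assert hits and hits[0].identical == 73

    def test_no_plant_means_no_hit(self):
        w = self._window(seed=13)
        for seed in range(30):
            rng = np.random.default_rng(1000 + seed)
            search = w.seq + self._random_seq(rng, 2000)
            assert find_ecs(w.site, search, w, window_start0=0) == []

    def test_lowering_threshold_never_removes_hits(self):
        rng = np.random.default_rng(14)
        w = self._window(seed=15)
        ecs = list(reverse_complement(w.seq))
        for p in (5, 15, 25, 35, 45, 55, 65, 75):
            ecs[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[ecs[p]]
        search = w.seq + self._random_seq(rng, 400) + "".join(ecs)
        strict = find_ecs(w.site, search, w, min_identical=73,
                          window_start0=0)
        relaxed = find_ecs(w.site, search, w, min_identical=60,
                           window_start0=0)
        strict_ivs = {(h.start0, h.end0) for h in strict}
        relaxed_ivs = {(h.start0, h.end0) for h in relaxed}
        assert strict_ivs <= relaxed_ivs

    def test_short_search_seq_rejected(self):
        w = self._window(seed=16)
        with pytest.raises(ValueError):
            find_ecs(w.site, "ACGT", w)
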