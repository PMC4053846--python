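import numpy as np
import pytest

from editoscreen.conservation_screen import (
    GenomicWindow,
    SignalNoiseReport,
    align_windows,
    control_signal_to_noise,
    evaluate_hit,
    extract_window,
    run_screen,
)
from editoscreen.io_formats import GenomeAssembly, SiteRecord
from editoscreen.synthetic_data import SimulationConfig, simulate_ortholog_pair

RNG = np.random.default_rng(5150)


def _window_from(seq, center=40, species="h"):
    site = SiteRecord(species=species, chrom="c", pos1=center + 1,
                      strand="+")
    return GenomicWindow(site=site, seq=seq, center_index=center)


def random_window(rng, flank=40):
    seq = list(rng.choice(list("ACGT"), size=2 * flank + 1))
    seq[flank] = "A"
    return _window_from("".join(seq), flank)


class TestExtractWindow:
    def _genome(self):
        rng = np.random.default_rng(3)
        seq = list(rng.choice(list("ACGT"), size=100))
        seq[40] = "A"   # plus-strand site at pos1=41
        seq[50] = "T"   # minus-strand site at pos1=51 (edited-strand A)
        return GenomeAssembly("g", {"c1": "".join(seq)})

    def test_plus_strand_window(self):
        g = self._genome()
        site = SiteRecord(species="h", chrom="c1", pos1=41, strand="+")
        w = extract_window(g, site)
        assert len(w.seq) == 81
        assert w.center_index == 40
        assert w.seq == g.fetch("c1", 0, 81)
        assert w.seq[40] == "A"

    def test_minus_strand_center_is_a_after_rc(self):
        g = self._genome()
        site = SiteRecord(species="h", chrom="c1", pos1=51, strand="-")
        w = extract_window(g, site)
        assert w.seq[40] == "A"

    def test_site_too_close_to_contig_end(self):
        g = self._genome()
        site = SiteRecord(species="h", chrom="c1", pos1=10, strand="+")
        with pytest.raises(IndexError):
            extract_window(g, site, flank=40)

    def test_non_a_center_rejected_for_editing_sites(self):
        g = self._genome()
        # pos1=42 is whatever the rng drew; force a site whose center != A
        seq = g.sequences["c1"]
        pos = next(i for i in range(41, 60) if seq[i] != "A")
        site = SiteRecord(species="h", chrom="c1", pos1=pos + 1, strand="+")
        with pytest.raises(ValueError, match="expected 'A'"):
            extract_window(g, site)
        # the same window extracts fine for SNP controls
        extract_window(g, site, require_center_a=False)


class TestEvaluateHit:
    def test_self_alignment_passes(self):
        w = random_window(RNG)
        aln = align_windows(w, w)
        assert aln.identical == 81 and aln.centers_paired
        assert evaluate_hit(aln)

    def test_70_passes_69_fails(self):
        w = random_window(RNG)
        # substitute 11 scattered positions away from center and ends
        positions = [5, 11, 17, 23, 29, 35, 45, 51, 57, 63, 69]
        seq = list(w.seq)
        for p in positions:
            seq[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[p]]
        s70 = _window_from("".join(seq))
        aln = align_windows(w, s70)
        assert aln.identical == 70
        assert evaluate_hit(aln)
        seq[74] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[74]]
        s69 = _window_from("".join(seq))
        aln69 = align_windows(w, s69)
        assert aln69.identical == 69
        assert not evaluate_hit(aln69)

    def test_center_mismatch_fails_despite_high_identity(self):
        w = random_window(RNG)
        seq = list(w.seq)
        seq[40] = "C"
        s = _window_from("".join(seq))
        aln = align_windows(w, s)
        assert aln.identical == 80
        assert aln.centers_paired and not aln.center_match
        assert not evaluate_hit(aln)

    def test_raising_threshold_never_adds_hits(self):
        """|conserved| is non-increasing in min_identical."""
        rng = np.random.default_rng(99)
        w = random_window(rng)
        alns = []
        for n_subs in (0, 5, 9, 11, 14):
            seq = list(w.seq)
            subs = rng.choice(
                [i for i in range(4, 77) if i != 40], size=n_subs,
                replace=False,
            )
            for p in subs:
                seq[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[p]]
            alns.append(align_windows(w, _window_from("".join(seq))))
        counts = [sum(evaluate_hit(a, t) for a in alns)
                  for t in range(60, 82)]
        assert counts == sorted(counts, reverse=True)


class TestRunScreen:
    def test_recovers_planted_sites(self, default_ortholog_pair):
        cfg, qg, sg, truth = default_ortholog_pair
        res = run_screen(truth.query_sites, truth.subject_sites, qg, sg)
        found = {s.key for s in res.conserved_query_sites}
        planted = truth.conserved_query_keys
        assert found == planted
        assert all(p.identical >= 70 for p in res.conserved_pairs)

    def test_self_screen_matches_everything(self, default_ortholog_pair):
        _, qg, _, truth = default_ortholog_pair
        sites = truth.query_sites[:20]
        res = run_screen(sites, sites, qg, qg)
        assert res.n_conserved == len(sites)

    def test_unrelated_windows_never_pass(self):
        """Random 81-mers share no >=70/81 local identity."""
        rng = np.random.default_rng(42)

        def genome(name, seed):
            r = np.random.default_rng(seed)
            seq = list(r.choice(list("ACGT"), size=12_000))
            sites = []
            for k in range(50):
                pos0 = 40 + 120 * k
                seq[pos0] = "A"
                sites.append(SiteRecord(species=name, chrom="c1",
                                        pos1=pos0 + 1, strand="+"))
            return GenomeAssembly(name, {"c1": "".join(seq)}), sites

        g1, s1 = genome("a", 1)
        g2, s2 = genome("b", 2)
        res = run_screen(s1, s2, g1, g2)
        assert res.n_conserved == 0

    def test_empty_site_list_rejected(self, default_ortholog_pair):
        _, qg, sg, truth = default_ortholog_pair
        with pytest.raises(ValueError):
            run_screen([], truth.subject_sites, qg, sg)


class TestSignalToNoise:
    def test_normalization_arithmetic(self):
        """ratio = hits / (raw * size corrections); worked example."""
        report = SignalNoiseReport(
            editing_hits=16, control_raw_hits=4,
            n_edit_query=50_000, n_edit_subject=25_000,
            n_control_query=100_000, n_control_subject=100_000,
            control_normalized=4 * 0.5 * 0.25, ratio=16 / 0.5,
            ratio_is_infinite=False,
        )
        assert report.control_normalized == pytest.approx(0.5)
        assert report.ratio == pytest.approx(32.0)

    def test_end_to_end_control(self, default_ortholog_pair):
        cfg, qg, sg, truth = default_ortholog_pair
        res = run_screen(truth.query_sites, truth.subject_sites, qg, sg)
        rep = control_signal_to_noise(res, truth.query_snps,
                                      truth.subject_snps, qg, sg)
        # only the shared SNP pairs can produce control hits
        assert rep.control_raw_hits <= len(truth.shared_snp_pairs)
        expected_norm = rep.control_raw_hits * \
            (rep.n_edit_query / rep.n_control_query) * \
            (rep.n_edit_subject / rep.n_control_subject)
        assert rep.control_normalized == pytest.approx(expected_norm)
        if rep.control_raw_hits:
            assert rep.ratio == pytest.approx(
                rep.editing_hits / rep.control_normalized
            )
        else:
            assert rep.ratio_is_infinite

    def test_sizes_override(self, default_ortholog_pair):
        cfg, qg, sg, truth = default_ortholog_pair
        res = run_screen(truth.query_sites[:10], truth.subject_sites[:10],
                         qg, sg)
        rep = control_signal_to_noise(
            res, truth.query_snps, truth.subject_snps, qg, sg,
            sizes=(1000, 1000, 2000, 2000),
        )
        assert rep.n_control_query == 2000
        assert rep.control_normalized == pytest.approx(
            rep.control_raw_hits * 0.25
        )
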