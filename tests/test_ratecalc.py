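import itertools
import math

import numpy as np
import pytest

from mitodyn import genomecomp as gc
from mitodyn import ratecalc as rc
from mitodyn import synthforge as sf
from mitodyn.core_io import GenomeRecord

from conftest import random_seq

SENSE = sorted(c for c, aa in rc.CODON_TABLE.items() if aa != "*")


class TestCountEvents:
    def test_identical_pair_all_zero(self):
        ev = rc.count_events("ACGT", "ACGT")
        assert (ev.ts, ev.tv, ev.indels, ev.sites) == (0, 0, 0, 4)

    @pytest.mark.parametrize("a,b,ts,tv", [
        ("ACGT", "GCGT", 1, 0),   # A<->G transition
        ("ACGT", "TCGT", 0, 1),   # A<->T transversion
        ("ACGT", "ATGT", 1, 0),   # C<->T transition
        ("AAAA", "GCTA", 1, 2),
    ])
    def test_transition_transversion_classification(self, a, b, ts, tv):
        ev = rc.count_events(a, b)
        assert (ev.ts, ev.tv) == (ts, tv)

    def test_short_gap_run_is_one_event(self):
        ev = rc.count_events("AC---GTACGT", "ACGTAGTACGT")
        assert ev.indels == 1
        assert ev.sites == 8

    def test_long_gap_run_excluded_entirely(self):
        gap = "-" * 25
        a = "ACGT" + gap + "ACGT"
        b = "ACGT" + random_seq(np.random.default_rng(0), 25) + "ACGT"
        ev = rc.count_events(a, b)
        assert ev.indels == 0
        assert ev.sites == 8

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            rc.count_events("ACG", "ACGT")

    def test_planted_poisson_events_recovered_exactly(self, rng):
        seq = random_seq(rng, 10_000)
        b = list(seq)
        ts_map = {"A": "G", "G": "A", "C": "T", "T": "C"}
        n_ts, n_tv = 60, 25
        pos = rng.choice(10_000, size=n_ts + n_tv, replace=False)
        for p in pos[:n_ts]:
            b[p] = ts_map[b[p]]
        for p in pos[n_ts:]:
            choices = [x for x in "ACGT" if x != b[p] and x != ts_map[b[p]]]
            b[p] = rng.choice(choices)
        ev = rc.count_events(seq, "".join(b))
        assert (ev.ts, ev.tv) == (n_ts, n_tv)

    def test_adding_substitutions_never_decreases_total(self, rng):
        seq = random_seq(rng, 2000)
        b = list(seq)
        prev = 0
        for p in rng.choice(2000, size=50, replace=False):
            b[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[b[p]]
            ev = rc.count_events(seq, "".join(b))
            assert ev.ts + ev.tv >= prev
            prev = ev.ts + ev.tv


class TestTn93:
    def test_identical_sequences_zero(self, rng):
        s = random_seq(rng, 1000)
        assert rc.tn93_distance(s, s) == pytest.approx(0.0, abs=1e-12)

    def test_recovers_simulated_divergence(self):
        # strand-symmetric evolution with equal transversion flows is a
        # TN93 special case at uniform composition
        _, aln, _ = sf.simulate_evolution(
            "(A:0.025,B:0.025);", 10_000,
            [0.4, 0.2, 0.1, 0.1, 0.1, 0.1], seed=99, gc=0.5)
        d = rc.tn93_distance(aln["A"], aln["B"])
        assert d == pytest.approx(0.05, abs=0.005)

    def test_low_divergence_approaches_p_distance(self, rng):
        seq = random_seq(rng, 20_000)
        b = list(seq)
        for p in rng.choice(20_000, size=40, replace=False):
            b[p] = rng.choice([x for x in "ACGT" if x != b[p]])
        b = "".join(b)
        p_dist = sum(1 for x, y in zip(seq, b) if x != y) / len(seq)
        d = rc.tn93_distance(seq, b)
        assert abs(d - p_dist) / p_dist < 0.05

    def test_saturation_returns_missing(self):
        # complementary strands: every aligned site is a difference
        a = "AG" * 300 + "CT" * 300
        b = "GA" * 300 + "TC" * 300
        assert rc.tn93_distance(a, b) is None


class TestDnDs:
    def test_identical_pair_zero(self, rng):
        a = "".join(rng.choice(SENSE, 100))
        res = rc.dnds(a, a)
        assert res.dn == 0 and res.ds == 0 and res.omega is None

    def test_fourfold_site_change_is_synonymous(self, rng):
        codons = list(rng.choice(SENSE, 300))
        codons[137] = "GGA"
        a = "".join(codons)
        codons[137] = "GGG"
        b = "".join(codons)
        res = rc.dnds(a, b)
        assert res.ds > 0 and res.dn == 0

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            rc.dnds("ATGTAAGGG", "ATGTAAGGG")

    def test_matches_pathway_oracle_on_all_two_difference_codon_pairs(self):
        """Site and difference counts equal exhaustive pathway enumeration."""
        for c1 in SENSE:
            for c2 in SENSE:
                ndiff = sum(x != y for x, y in zip(c1, c2))
                if ndiff == 0 or ndiff > 2:
                    continue
                sd, nd = rc._pathway_differences(c1, c2)
                # oracle: enumerate orders independently
                orders = list(itertools.permutations(
                    [i for i in range(3) if c1[i] != c2[i]]))
                tallies = []
                for order in orders:
                    cur, s, n, stop = c1, 0, 0, False
                    for posn in order:
                        nxt = cur[:posn] + c2[posn] + cur[posn + 1:]
                        if rc.CODON_TABLE[nxt] == "*":
                            stop = True
                        if rc.CODON_TABLE[cur] == rc.CODON_TABLE[nxt]:
                            s += 1
                        else:
                            n += 1
                        cur = nxt
                    tallies.append((stop, s, n))
                valid = [(s, n) for stop, s, n in tallies if not stop]
                if not valid:
                    valid = [(s, n) for _, s, n in tallies]
                exp_sd = sum(s for s, _ in valid) / len(valid)
                exp_nd = sum(n for _, n in valid) / len(valid)
                assert sd == pytest.approx(exp_sd)
                assert nd == pytest.approx(exp_nd)
                assert sd + nd == pytest.approx(ndiff)

    def test_matches_reference_implementation(self, rng):
        """Dual-route check against Biopython's NG86 on a diverged pair."""
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        a = "".join(rng.choice(SENSE, 200))
        b = list(a)
        changed = 0
        while changed < 25:
            p = int(rng.integers(0, len(b)))
            new = rng.choice([x for x in "ACGT" if x != b[p]])
            start = (p // 3) * 3
            trial = b[:start] + list(b[start:start + 3]) + b[start + 3:]
            trial[p] = new
            if rc.CODON_TABLE["".join(trial[start:start + 3])] != "*":
                b[p] = new
                changed += 1
        b = "".join(b)
        mine = rc.dnds(a, b)
        dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
        assert mine.dn == pytest.approx(dn, abs=1e-9)
        assert mine.ds == pytest.approx(ds, abs=1e-9)


class TestPartitionAndRates:
    def _evolved_pair(self, seed=21, n_genes=6, length=50_000, branch=0.01):
        cfg = sf.SimConfig(seed=seed, genome_length=length, n_genes=n_genes,
                           topology="linear")
        genome, truth = sf.simulate_genome(cfg)
        _, aln, _ = sf.simulate_evolution(
            f"(A:{branch},B:{branch});", genome["mt1"].sequence,
            [0.4, 0.2, 0.1, 0.1, 0.1, 0.1], seed=seed + 1)
        ga = {"mt1": GenomeRecord("mt1", aln["A"], "linear")}
        gb = {"mtB": GenomeRecord("mtB", aln["B"], "linear")}
        fa = truth.features
        fb = truth.features.copy()
        fb["contig_id"] = "mtB"
        return ga, gb, fa, fb

    def test_class_partition_matches_annotation_lengths(self):
        ga, gb, fa, fb = self._evolved_pair()
        blocks = gc.synteny_blocks(ga, gb).blocks
        segs = rc.partition_classes(blocks, ga, gb, fa, fb)
        sites = {}
        for seg in segs:
            ev = rc.count_events(seg.aligned_a, seg.aligned_b)
            sites[seg.seq_class] = sites.get(seg.seq_class, 0) + ev.sites
        exon_truth = int((fa["feature_class"] == "exon").sum()) * 300
        intron_truth = int((fa["feature_class"] == "intron").sum()) * 150
        assert sites["exon"] == pytest.approx(exon_truth, rel=0.01)
        assert sites["intron"] == pytest.approx(intron_truth, rel=0.01)

    def test_exclusion_mask_drops_columns(self):
        ga, gb, fa, fb = self._evolved_pair()
        blocks = gc.synteny_blocks(ga, gb).blocks
        exon = fa[fa["feature_class"] == "exon"].iloc[0]
        mask = [(exon.contig_id, int(exon.start), int(exon.end))]
        segs_all = rc.partition_classes(blocks, ga, gb, fa, fb)
        segs_masked = rc.partition_classes(blocks, ga, gb, fa, fb, mask)

        def exon_sites(segs):
            return sum(rc.count_events(s.aligned_a, s.aligned_b).sites
                       for s in segs if s.seq_class == "exon")

        assert exon_sites(segs_masked) == pytest.approx(
            exon_sites(segs_all) - 300, abs=5)

    def test_rates_recover_planted_divergence(self):
        ga, gb, fa, fb = self._evolved_pair()
        blocks = gc.synteny_blocks(ga, gb).blocks
        rates = rc.pairwise_rates(
            rc.partition_classes(blocks, ga, gb, fa, fb))
        for cls, r in rates.items():
            assert r.total == pytest.approx(r.ts + r.tv, abs=1e-12)
        # expected pairwise divergence 0.02, uniform across classes
        assert rates["intergenic"].total == pytest.approx(0.02, rel=0.10)
        assert rates["exon"].ds is not None and rates["exon"].ds > 0

    def test_identical_genomes_zero_rates(self, rng):
        seq = random_seq(rng, 20_000)
        from mitodyn.core_io import make_features

        ga = {"a": GenomeRecord("a", seq)}
        gb = {"b": GenomeRecord("b", seq)}
        feats_a = make_features([("a", 1000, 1300, "+", "exon", "g1")])
        feats_b = make_features([("b", 1000, 1300, "+", "exon", "g1")])
        blocks = gc.synteny_blocks(ga, gb).blocks
        rates = rc.pairwise_rates(
            rc.partition_classes(blocks, ga, gb, feats_a, feats_b))
        for r in rates.values():
            assert r.total == 0 and r.indel_rate == 0

    def test_compare_rates_detects_shift(self, rng):
        a = rng.normal(2e-3, 1e-4, 12)
        b = rng.normal(1e-3, 1e-4, 12)
        _, p = rc.compare_rates(a, b)
        assert p < 0.01
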