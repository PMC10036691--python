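import numpy as np
import pytest

from mitodyn import recombveri as rv
from mitodyn import synthforge as sf
from mitodyn.core_io import GenomeRecord, reverse_complement
from mitodyn.repeatscan import Copy, RepeatPair

from conftest import random_seq


def _planted_genome(rng, orientation="direct", rep_len=100, topology="linear"):
    """Genome built by explicit concatenation so flanks are known strings."""
    up_a = random_seq(rng, 800)
    rep = random_seq(rng, rep_len)
    mid = random_seq(rng, 1200)
    down_b = random_seq(rng, 800)
    copy_b = rep if orientation == "direct" else reverse_complement(rep)
    seq = up_a + rep + mid + copy_b + down_b
    a0 = len(up_a)
    b0 = a0 + rep_len + len(mid)
    pair = RepeatPair(Copy("c", a0, a0 + rep_len), Copy("c", b0, b0 + rep_len),
                      orientation, rep_len, 100.0)
    return {"c": GenomeRecord("c", seq, topology)}, pair, dict(
        up_a=up_a, rep=rep, mid=mid, down_b=down_b, copy_b=copy_b)


class TestBuildConformations:
    def test_direct_pair_matches_string_construction(self, rng):
        genome, pair, parts = _planted_genome(rng)
        conf = rv.build_conformations(genome, pair, flank=300)
        up_a = parts["up_a"][-300:]
        down_a = parts["mid"][:300]
        up_b = parts["mid"][-300:]
        down_b = parts["down_b"][:300]
        rep = parts["rep"]
        assert conf.sequences["R1"] == up_a + rep + down_a
        assert conf.sequences["R2"] == up_b + rep + down_b
        assert conf.sequences["A1"] == up_a + rep + down_b
        assert conf.sequences["A2"] == up_b + rep + down_a
        assert all(len(s) == 700 for s in conf.sequences.values())
        assert conf.repeat_span["R1"] == (300, 400)
        assert len(set(conf.sequences.values())) == 4

    def test_inverted_pair_swaps_reverse_complemented_flanks(self, rng):
        genome, pair, parts = _planted_genome(rng, orientation="inverted")
        conf = rv.build_conformations(genome, pair, flank=300)
        up_a = parts["up_a"][-300:]
        rep = parts["rep"]
        copy_b_up = parts["mid"][-300:]      # genomic upstream flank of copy B
        copy_b_down = parts["down_b"][:300]
        assert conf.sequences["R1"] == up_a + rep + parts["mid"][:300]
        # A1 carries the reverse complement of copy B's upstream flank
        assert conf.sequences["A1"] == up_a + rep + reverse_complement(copy_b_up)
        assert conf.sequences["R2"] == (reverse_complement(copy_b_down) + rep +
                                        reverse_complement(copy_b_up))
        assert conf.sequences["A2"] == (reverse_complement(copy_b_down) + rep +
                                        parts["mid"][:300])

    def test_origin_spanning_copy_equals_rotation_oracle(self, rng):
        genome, pair, _ = _planted_genome(rng, topology="circular")
        seq = genome["c"].sequence
        n = len(seq)
        # rotate so copy A spans the origin
        shift = pair.copy_a.start + 50
        rotated = seq[shift:] + seq[:shift]
        a0 = (pair.copy_a.start - shift) % n
        b0 = (pair.copy_b.start - shift) % n
        rot_pair = RepeatPair(
            Copy("c", a0, a0 + pair.length if a0 + pair.length <= n
                 else a0 + pair.length),
            Copy("c", b0, b0 + pair.length), "direct", pair.length, 100.0)
        conf_orig = rv.build_conformations(genome, pair, flank=300)
        conf_rot = rv.build_conformations(
            {"c": GenomeRecord("c", rotated, "circular")}, rot_pair, flank=300)
        assert conf_rot.sequences == conf_orig.sequences

    def test_close_copies_truncate_inner_flanks(self, rng):
        up = random_seq(rng, 500)
        rep = random_seq(rng, 80)
        mid = random_seq(rng, 100)          # gap smaller than flank
        down = random_seq(rng, 500)
        seq = up + rep + mid + rep + down
        pair = RepeatPair(Copy("c", 500, 580), Copy("c", 680, 760),
                          "direct", 80, 100.0)
        conf = rv.build_conformations({"c": GenomeRecord("c", seq, "linear")},
                                      pair, flank=300)
        assert conf.sequences["R1"] == up[-300:] + rep + mid
        assert conf.truncated["R1"] == (0, 200)


def _simulate_from(conf_seq, rng, n, read_len=150, insert=350):
    pairs = []
    for _ in range(n):
        start = rng.integers(0, len(conf_seq) - insert + 1)
        frag = conf_seq[start:start + insert]
        m1, m2 = frag[:read_len], reverse_complement(frag)[:read_len]
        if rng.random() < 0.5:
            m1, m2 = m2, m1
        pairs.append((m1, m2))
    return pairs


class TestClassifyReadPairs:
    def test_reads_from_r1_only_support_r1(self, rng):
        genome, pair, _ = _planted_genome(rng)
        conf = rv.build_conformations(genome, pair, flank=300)
        reads = _simulate_from(conf.sequences["R1"], rng, 500)
        tally = rv.classify_read_pairs(conf, reads)
        assert tally.n_a1 == 0 and tally.n_a2 == 0
        assert tally.n_r1 > 0
        # conservation: every aligned pair lands in exactly one bucket
        assert tally.informative + tally.n_ambiguous <= 500

    def test_pair_inside_repeat_copy_is_ambiguous(self, rng):
        genome, pair, parts = _planted_genome(rng, rep_len=700)
        conf = rv.build_conformations(genome, pair, flank=300)
        rep = parts["rep"]
        frag = rep[100:450]                 # entirely within the repeat copy
        reads = [(frag[:150], reverse_complement(frag)[:150])]
        tally = rv.classify_read_pairs(conf, reads)
        assert tally.informative == 0
        assert tally.n_ambiguous == 1

    def test_balanced_mixture_splits_evenly(self, rng):
        genome, pair, _ = _planted_genome(rng)
        conf = rv.build_conformations(genome, pair, flank=300)
        reads = (_simulate_from(conf.sequences["R1"], rng, 250) +
                 _simulate_from(conf.sequences["A1"], rng, 250))
        tally = rv.classify_read_pairs(conf, reads)
        assert tally.parental > 0 and tally.alternative > 0
        frac = tally.alternative / tally.informative
        assert 0.35 <= frac <= 0.65        # binomial tolerance at n >= 100

    def test_copy_relabelling_permutes_tallies_not_frequency(self, rng):
        genome, pair, _ = _planted_genome(rng)
        swapped = RepeatPair(pair.copy_b, pair.copy_a, pair.orientation,
                             pair.length, pair.identity)
        conf = rv.build_conformations(genome, pair, flank=300)
        conf_sw = rv.build_conformations(genome, swapped, flank=300)
        reads = (_simulate_from(conf.sequences["R1"], rng, 150) +
                 _simulate_from(conf.sequences["A1"], rng, 60))
        t1 = rv.classify_read_pairs(conf, reads)
        t2 = rv.classify_read_pairs(conf_sw, reads)
        assert (t1.n_r1, t1.n_r2) == (t2.n_r2, t2.n_r1)
        assert (t1.n_a1, t1.n_a2) == (t2.n_a2, t2.n_a1)
        f1 = rv.estimate_recombination(t1).frequency
        f2 = rv.estimate_recombination(t2).frequency
        assert f1 == pytest.approx(f2)

    def test_repeat_longer_than_insert_gives_no_informative_pairs(self, rng):
        genome, pair, _ = _planted_genome(rng, rep_len=400)
        conf = rv.build_conformations(genome, pair, flank=300)
        reads = _simulate_from(conf.sequences["R1"], rng, 300)
        tally = rv.classify_read_pairs(conf, reads)
        # 350 bp inserts cannot bridge a 400 bp repeat with 20 bp anchors
        assert tally.informative == 0


class TestEstimateRecombination:
    def test_frequency_arithmetic(self):
        tally = rv.ReadSupportTally(n_r1=40, n_r2=30, n_a1=20, n_a2=10)
        est = rv.estimate_recombination(tally)
        assert est.frequency == pytest.approx(0.30)
        assert est.active
        assert est.ci_low < 0.30 < est.ci_high

    def test_zero_alternative_inactive(self):
        est = rv.estimate_recombination(rv.ReadSupportTally(n_r1=60, n_r2=40))
        assert est.frequency == 0.0 and not est.active

    def test_no_informative_reads_reported_missing(self):
        est = rv.estimate_recombination(rv.ReadSupportTally())
        assert est.frequency is None and not est.active

    def test_single_alternative_read_not_called_active(self):
        est = rv.estimate_recombination(rv.ReadSupportTally(n_r1=10, n_a1=1))
        assert not est.active

    def test_simulated_mixture_estimate_within_wilson_interval(self, rng):
        genome, pair, _ = _planted_genome(rng)
        conf = rv.build_conformations(genome, pair, flank=300)
        n_alt = 300
        reads = (_simulate_from(conf.sequences["R1"], rng, 350) +
                 _simulate_from(conf.sequences["R2"], rng, 350) +
                 _simulate_from(conf.sequences["A1"], rng, n_alt // 2) +
                 _simulate_from(conf.sequences["A2"], rng, n_alt // 2))
        tally = rv.classify_read_pairs(conf, reads)
        est = rv.estimate_recombination(tally)
        assert est.ci_low <= 0.3 <= est.ci_high


class TestSurvey:
    def test_survey_recovers_planted_activity(self, rng):
        plans = [sf.RepeatPlan(length=100,
                               alt_fraction=(0.2 if i < 3 else 0.0))
                 for i in range(10)]
        cfg = sf.SimConfig(seed=17, genome_length=26_000, repeats=plans,
                           reads=sf.ReadPlan(coverage=60))
        genome, truth = sf.simulate_genome(cfg)
        reads = sf.simulate_reads(genome, truth, cfg.reads, seed=18)
        survey = rv.recombination_survey(
            genome, truth.catalog, [(r.seq1, r.seq2) for r in reads])
        active = survey.sort_values("pair_id")["active"].tolist()
        expected = [f > 0 for f in truth.alt_fractions]
        assert active == expected
        assert rv.survey_summary(survey)["active_fraction"] == pytest.approx(0.3)

    def test_no_reads_everything_not_evaluated(self, rng):
        genome, pair, _ = _planted_genome(rng)
        from mitodyn.repeatscan import RepeatCatalog
        survey = rv.recombination_survey(
            genome, RepeatCatalog([pair], []), read_pairs=None)
        assert (survey["method"] == "not-evaluated").all()
        assert survey["frequency"].isna().all()

    def test_long_repeats_need_long_reads(self, rng):
        genome, pair, _ = _planted_genome(rng, rep_len=500)
        from mitodyn.repeatscan import RepeatCatalog
        catalog = RepeatCatalog([pair], [])
        survey = rv.recombination_survey(genome, catalog, read_pairs=[])
        assert survey.loc[0, "method"] == "not-evaluated"
        # with long reads from R1, the pair is evaluated and inactive
        conf = rv.build_conformations(genome, pair, flank=1000)
        long_reads = []
        r1 = conf.sequences["R1"]
        for _ in range(200):
            start = rng.integers(0, len(r1) - 1500 + 1)
            long_reads.append(r1[start:start + 1500])
        survey2 = rv.recombination_survey(genome, catalog, read_pairs=[],
                                          long_reads=long_reads)
        assert survey2.loc[0, "method"] == "long"
        assert survey2.loc[0, "n_r1"] > 0 and not survey2.loc[0, "active"]
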