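import numpy as np
import pytest

from tandemdup.fraglen import FragmentLengthModel
from tandemdup.geometry import build_trapezoid, contains, implied_fragment_length
from tandemdup.simulate import (
    SimulationConfig,
    SimulationError,
    generate_read_pairs,
    insert_duplications,
    make_reference,
    oracle_map,
    read_fasta,
    simulate_read_layout,
    spike_duplications,
    write_fasta,
)


def small_cfg(**kw):
    defaults = dict(reference_length=50_000, n_duplications=3,
                    dup_size_mean=3000, dup_size_sd=50, coverage=10,
                    base_error_rate=0.0, seed=11)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestReference:
    def test_deterministic_for_fixed_seed(self):
        assert make_reference(100, seed=3) == make_reference(100, seed=3)
        assert make_reference(100, seed=3) != make_reference(100, seed=4)

    def test_gc_one_yields_only_gc(self):
        assert set(make_reference(500, gc=1.0, seed=1)) <= {"G", "C"}

    def test_gc_fraction_concentrates(self):
        seq = make_reference(1_000_000, gc=0.41, seed=5)
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert gc == pytest.approx(0.41, abs=0.01)


class TestSpike:
    def test_hand_checked_insertion(self):
        donor, truth = insert_duplications("ACGTACGTAC", [(3, 5)])
        assert donor == "ACGTAGTACGTAC"
        (d,) = truth.duplications
        assert (d.start, d.end, d.size, d.donor_fusion) == (3, 5, 3, 5)

    def test_zero_duplications_is_identity(self):
        ref = make_reference(1000, seed=1)
        donor, truth = insert_duplications(ref, [])
        assert donor == ref and truth.duplications == []

    def test_second_duplication_shifted_by_first_insertion(self):
        ref = make_reference(1000, seed=2)
        donor, truth = insert_duplications(ref, [(101, 200), (501, 650)])
        d1, d2 = truth.duplications
        assert d1.donor_fusion == 200
        assert d2.donor_start == 501 + 100      # shifted by first copy
        assert d2.donor_fusion == 650 + 100
        assert len(donor) == 1000 + 100 + 150
        # donor sequence around each fusion point repeats the segment start
        assert donor[d1.donor_fusion:d1.donor_fusion + 3] == ref[100:103]

    def test_donor_to_ref_mapping_round_trip(self):
        ref = make_reference(2000, seed=3)
        donor, truth = insert_duplications(ref, [(201, 400), (1001, 1300)])
        dm = truth.donor_map
        for donor_pos in [1, 200, 400, 401, 600, 601, 1500, len(donor)]:
            ref_pos = int(dm.donor_to_ref(np.array([donor_pos]))[0])
            assert donor[donor_pos - 1] == ref[ref_pos - 1]

    def test_sampled_duplications_respect_bounds_and_disjointness(self):
        cfg = small_cfg()
        ref = make_reference(cfg.reference_length, seed=cfg.seed)
        donor, truth = spike_duplications(ref, cfg)
        ivs = sorted(truth.intervals)
        assert len(ivs) == 3
        assert all(1 <= a <= b <= cfg.reference_length for a, b in ivs)
        assert all(c > b for (a, b), (c, d) in zip(ivs, ivs[1:]))
        assert len(donor) == len(ref) + sum(b - a + 1 for a, b in ivs)

    def test_impossible_placement_raises(self):
        cfg = small_cfg(reference_length=25_000, n_duplications=20)
        ref = make_reference(cfg.reference_length, seed=1)
        with pytest.raises(SimulationError, match="placed only"):
            spike_duplications(ref, cfg, max_attempts_per_dup=50)


class TestReadLayout:
    def test_pair_count_follows_coverage(self):
        cfg = small_cfg(coverage=20)
        layout = simulate_read_layout(100_000, cfg)
        assert len(layout) == round(20 * 100_000 / 150)
        emitted = 2 * cfg.read_length * len(layout)
        assert emitted / 100_000 == pytest.approx(20, rel=0.01)

    def test_zero_sd_gives_constant_fragment_length(self):
        layout = simulate_read_layout(50_000, small_cfg(frag_sd=0))
        assert np.all(layout.frag_len == 200)

    def test_fragments_fit_on_contig(self):
        layout = simulate_read_layout(10_000, small_cfg())
        assert np.all(layout.v >= 1)
        assert np.all(layout.v + layout.frag_len - 1 <= 10_000)

    def test_error_counts_match_binomial_rate(self):
        cfg = small_cfg(base_error_rate=0.07, coverage=31)
        layout = simulate_read_layout(50_000, cfg)  # ~10000 pairs
        mean_err = float(np.concatenate([layout.err_left, layout.err_right]).mean())
        assert mean_err == pytest.approx(75 * 0.07, abs=0.15)

    def test_error_free_mode_has_no_errors(self):
        layout = simulate_read_layout(20_000, small_cfg())
        assert layout.err_left.sum() == 0 and layout.err_right.sum() == 0


class TestSequences:
    def test_error_free_reads_match_donor(self):
        cfg = small_cfg(reference_length=5_000, n_duplications=1,
                        dup_size_mean=500, dup_size_sd=10, coverage=2)
        ref = make_reference(cfg.reference_length, seed=cfg.seed)
        donor, truth = spike_duplications(ref, cfg)
        layout, seqs = generate_read_pairs(donor, cfg)
        comp = str.maketrans("ACGT", "TGCA")
        for i in range(len(layout)):
            v, l = int(layout.v[i]), int(layout.frag_len[i])
            left, right = seqs[i]
            assert left == donor[v - 1: v - 1 + 75]
            # right end: reverse complement of the fragment's last r bases
            assert right == donor[v + l - 75 - 1: v + l - 1][::-1].translate(comp)

    def test_injected_error_counts_realized_exactly(self):
        cfg = small_cfg(reference_length=5_000, n_duplications=1,
                        dup_size_mean=500, dup_size_sd=10, coverage=2,
                        base_error_rate=0.05)
        ref = make_reference(cfg.reference_length, seed=cfg.seed)
        donor, truth = spike_duplications(ref, cfg)
        layout, seqs = generate_read_pairs(donor, cfg)
        comp = str.maketrans("ACGT", "TGCA")
        for i in range(len(layout)):
            v, l = int(layout.v[i]), int(layout.frag_len[i])
            left, right = seqs[i]
            clean_left = donor[v - 1: v - 1 + 75]
            clean_right = donor[v + l - 76: v + l - 1][::-1].translate(comp)
            diff_left = sum(a != b for a, b in zip(left, clean_left))
            diff_right = sum(a != b for a, b in zip(right, clean_right))
            assert diff_left == int(layout.err_left[i])
            assert diff_right == int(layout.err_right[i])

    def test_fastq_determinism(self, tmp_path):
        cfg = small_cfg(reference_length=5_000, n_duplications=1,
                        dup_size_mean=500, dup_size_sd=10, coverage=2,
                        base_error_rate=0.02)
        ref = make_reference(cfg.reference_length, seed=cfg.seed)
        donor, _ = spike_duplications(ref, cfg)
        generate_read_pairs(donor, cfg, fastq_prefix=tmp_path / "a")
        generate_read_pairs(donor, cfg, fastq_prefix=tmp_path / "b")
        assert (tmp_path / "a_1.fastq").read_bytes() == (tmp_path / "b_1.fastq").read_bytes()
        assert (tmp_path / "a_2.fastq").read_bytes() == (tmp_path / "b_2.fastq").read_bytes()


class TestOracleMap:
    def test_pair_away_from_duplications_is_concordant(self):
        ref = make_reference(10_000, seed=1)
        donor, truth = insert_duplications(ref, [(8_001, 8_400)])
        from tandemdup.simulate import ReadLayout
        layout = ReadLayout(v=np.array([1000]), frag_len=np.array([210]),
                            err_left=np.array([0]), err_right=np.array([0]),
                            read_length=75)
        ps = oracle_map(layout, truth.donor_map)
        assert len(ps) == 1 and bool(ps.is_fr[0])
        assert int(ps.spans[0]) == 210

    def test_straddling_pair_is_everted_and_length_consistent(self):
        """A clean fusion-straddling fragment yields an RF pair whose implied
        fragment length at the true breakpoints equals the true length."""
        ref = make_reference(10_000, seed=1)
        x0, y0 = 3_001, 5_000
        donor, truth = insert_duplications(ref, [(x0, y0)])
        from tandemdup.simulate import ReadLayout
        l = 200
        # fragment starts so both reads flank the fusion at donor pos y0
        v = y0 - l + 75 + 20 + 1
        layout = ReadLayout(v=np.array([v]), frag_len=np.array([l]),
                            err_left=np.array([0]), err_right=np.array([0]),
                            read_length=75)
        ps = oracle_map(layout, truth.donor_map)
        assert len(ps) == 1 and bool(ps.is_rf[0])
        (rec,) = list(ps.records())
        model = FragmentLengthModel(l, l, counts=np.array([1.0]), pseudocount=0.5)
        t = build_trapezoid(rec, model)
        assert implied_fragment_length(t, x0, y0) == l
        assert contains(t, x0, y0)

    def test_error_budget_drops_whole_pair(self):
        ref = make_reference(2_000, seed=1)
        _, truth = insert_duplications(ref, [])
        from tandemdup.simulate import ReadLayout
        layout = ReadLayout(v=np.array([100, 200]), frag_len=np.array([200, 200]),
                            err_left=np.array([5, 4]), err_right=np.array([0, 4]),
                            read_length=75)
        ps = oracle_map(layout, truth.donor_map, max_mismatches=4)
        assert len(ps) == 1 and int(ps.s[0]) == 200

    def test_truth_lies_in_every_flanking_trapezoid(self):
        """Error-free RF pairs whose reads flank a fusion point always induce
        trapezoids containing the true breakpoint-pair."""
        cfg = small_cfg(coverage=30)
        ref = make_reference(cfg.reference_length, seed=cfg.seed)
        donor, truth = spike_duplications(ref, cfg)
        layout = simulate_read_layout(truth.donor_length, cfg)
        # restrict to pairs with both reads cleanly flanking some fusion point
        dm = truth.donor_map
        _, over_l = dm.map_read_starts(layout.v, 75)
        _, over_r = dm.map_read_starts(layout.v + layout.frag_len - 75, 75)
        flanking = (over_l == 0) & (over_r == 0)
        from tandemdup.simulate import ReadLayout
        sub = ReadLayout(v=layout.v[flanking], frag_len=layout.frag_len[flanking],
                         err_left=layout.err_left[flanking],
                         err_right=layout.err_right[flanking], read_length=75)
        ps = oracle_map(sub, dm)
        rf = ps.subset(ps.is_rf)
        assert len(rf) >= 10
        l_lo, l_hi = int(sub.frag_len.min()), int(sub.frag_len.max())
        model = FragmentLengthModel(l_lo, l_hi,
                                    counts=np.ones(l_hi - l_lo + 1), pseudocount=0.5)
        fusions = {d.donor_fusion for d in truth.duplications}
        by_truth = {(d.start, d.end) for d in truth.duplications}
        for rec in rf.records():
            t = build_trapezoid(rec, model)
            assert any(contains(t, x0, y0) for x0, y0 in by_truth)

    def test_map_is_deterministic_given_seed(self):
        cfg = small_cfg(base_error_rate=0.05)
        ref = make_reference(cfg.reference_length, seed=cfg.seed)
        donor, truth = spike_duplications(ref, cfg)
        layout = simulate_read_layout(truth.donor_length, cfg)
        a = oracle_map(layout, truth.donor_map, seed=9)
        b = oracle_map(layout, truth.donor_map, seed=9)
        assert np.array_equal(a.s, b.s) and np.array_equal(a.e, b.e)
        assert len(a) == len(b)


def test_fasta_round_trip(tmp_path):
    seq = make_reference(333, seed=1)
    write_fasta(tmp_path / "x.fasta", "sim1", seq)
    assert read_fasta(tmp_path / "x.fasta") == [("sim1", seq)]
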