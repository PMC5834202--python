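import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import ty1kit as tk
from ty1kit.fragments import FragmentAlignment


def frag(fid, length, cands, assigned=None):
    return FragmentAlignment(fid, "s", length, tuple(cands), assigned=assigned)


class TestDedup:
    def test_identical_candidate_sets_collapse(self):
        a = frag("a", 300, [("chrI", 10, "+"), ("chrI", 900, "+")])
        b = frag("b", 300, [("chrI", 900, "+"), ("chrI", 10, "+")])  # same set
        c = frag("c", 310, [("chrI", 10, "+")])
        out = tk.dedup_fragments([a, b, c])
        assert out == [a, c]

    def test_empty_input(self):
        assert tk.dedup_fragments([]) == []

    def test_distinct_fragments_preserved_in_order(self):
        frags = [frag(f"f{i}", 200 + i, [("chrI", i * 10, "+")]) for i in range(100)]
        assert tk.dedup_fragments(frags) == frags

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 5), st.integers(0, 3)), max_size=30))
    def test_idempotent(self, keys):
        # small key space forces duplicates
        frags = [
            frag(f"f{i}", 200 + l, [("chrI", 100 * s, "+"), ("chrI", 5000 + 100 * s, "+")])
            for i, (s, l) in enumerate(keys)
        ]
        once = tk.dedup_fragments(frags)
        assert tk.dedup_fragments(once) == once


class TestAssign:
    def test_single_candidate_assigned_to_it(self):
        out = tk.assign_multimappers([frag("a", 200, [("chrI", 5, "+")])], seed=0)
        assert out[0].assigned == 0

    def test_deterministic_and_nonmutating(self):
        frags = [frag(f"f{i}", 200, [("chrI", 0, "+"), ("chrI", 999, "+")])
                 for i in range(50)]
        a = tk.assign_multimappers(frags, seed=3)
        b = tk.assign_multimappers(frags, seed=3)
        assert a == b
        assert all(f.assigned is None for f in frags)

    def test_two_candidate_assignment_is_binomial(self):
        """Per-candidate counts fall in the central 99% band of Binomial(n, 1/2)."""
        n = 10_000
        frags = [frag(f"f{i}", 200, [("chrI", 0, "+"), ("chrI", 999, "+")])
                 for i in range(n)]
        out = tk.assign_multimappers(frags, seed=7)
        k = sum(f.assigned == 0 for f in out)
        lo = stats.binom.ppf(0.005, n, 0.5)
        hi = stats.binom.ppf(0.995, n, 0.5)
        assert lo <= k <= hi

    def test_empty_candidates_impossible_by_contract(self):
        with pytest.raises(ValueError, match="candidate list is empty"):
            FragmentAlignment("bad", "s", 200, ())


class TestCoverage:
    def test_single_fragment_pileup(self):
        t = tk.compute_coverage([frag("a", 300, [("chrI", 100, "+")], assigned=0)],
                                {"chrI": 1000})
        v = t.data["chrI"]
        assert (v[100:400] == 1).all()
        assert v.sum() == 300
        assert v[99] == 0 and v[400] == 0

    def test_overlapping_fragments_stack(self):
        frags = [frag("a", 300, [("chrI", 100, "+")], assigned=0),
                 frag("b", 150, [("chrI", 250, "+")], assigned=0)]
        v = tk.compute_coverage(frags, {"chrI": 1000}).data["chrI"]
        assert (v[250:400] == 2).all()

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            tk.compute_coverage([frag("a", 300, [("chrI", 900, "+")], assigned=0)],
                                {"chrI": 1000})

    def test_mass_conservation_on_simulated_set(self, small_genome):
        model, _ = small_genome
        frags = tk.simulate_fragments(
            model,
            tk.EnrichmentSpec((tk.EnrichmentComponent(238, 1.0, 50),), 1.0),
            5000, seed=21,
        )
        track, assigned = tk.process_fragments(frags, model, seed=22)
        assert track.sum() == pytest.approx(sum(f.length for f in assigned))
        assert track.total_fragments == len(assigned)


class TestNormalize:
    def _const_track(self, value, n=1000, total=100, sample="t"):
        return tk.CoverageTrack({"chrI": np.full(n, float(value))}, sample, total, "raw")

    def test_self_ratio_is_one_for_any_pseudocount(self):
        x = self._const_track(5.0)
        for eps in (0.0, 0.5, 2.0):
            r = tk.normalize_to_control(x, x, pseudocount=eps)
            assert np.allclose(r.data["chrI"], 1.0)
            assert r.scale == "ratio"

    def test_depth_scaled_doubling(self):
        # ip = 2 x control after depth scaling
        ip = self._const_track(8.0, total=100)
        ct = self._const_track(4.0, total=100)
        r = tk.normalize_to_control(ip, ct, pseudocount=0.0)
        assert np.allclose(r.data["chrI"], 2.0)

    def test_zero_control_needs_pseudocount(self):
        ip = self._const_track(1.0)
        ct = tk.CoverageTrack({"chrI": np.zeros(1000)}, "c", 100, "raw")
        with pytest.raises(ValueError, match="pseudocount"):
            tk.normalize_to_control(ip, ct, pseudocount=0.0)
        eps = 0.25
        r = tk.normalize_to_control(ip, ct, pseudocount=eps)
        ip_scaled = 1.0 * 1e6 / 100
        assert np.allclose(r.data["chrI"], (ip_scaled + eps) / eps)

    def test_mismatched_chromosomes_rejected(self):
        ip = self._const_track(1.0)
        ct = tk.CoverageTrack({"chrII": np.ones(1000)}, "c", 100, "raw")
        with pytest.raises(ValueError, match="chromosomes"):
            tk.normalize_to_control(ip, ct)

    def test_subtract_mode(self):
        ip = self._const_track(8.0, total=100)
        ct = self._const_track(4.0, total=100)
        r = tk.normalize_to_control(ip, ct, mode="subtract")
        assert np.allclose(r.data["chrI"], (8.0 - 4.0) * 1e6 / 100)


class TestTwoCopyBalance:
    def test_identical_copies_receive_equal_coverage(self):
        """Uniform fragments over two identical copies: the multimapper split
        is Binomial(n_ambiguous, 1/2); observed split within 3 s.e."""
        model, _ = tk.build_toy_genome(n_full=2, n_solo=0, element_len=5000,
                                       ltr_len=334, seed=31)
        frags = tk.simulate_control(model, 50_000, seed=32)
        _, assigned = tk.process_fragments(frags, model, seed=33)
        c1, c2 = model.full_copies
        ambiguous = [f for f in assigned if len(f.candidates) > 1]
        n = len(ambiguous)
        k = sum(
            c1.start <= f.assigned_locus[1] < c1.end for f in ambiguous
        )
        assert n > 500
        assert abs(k - n / 2) <= 3 * np.sqrt(n / 4)


class TestBedgraph:
    def test_roundtrip(self, small_genome):
        model, _ = small_genome
        frags = tk.simulate_control(model, 2000, seed=41)
        track, _ = tk.process_fragments(frags, model, seed=42)
        import io, tempfile, os
        from pathlib import Path
        with tempfile.TemporaryDirectory() as d:
            p = Path(d) / "t.bedGraph"
            tk.write_bedgraph(track, p)
            back = tk.read_bedgraph(p, model.chrom_lengths)
            for chrom in track.data:
                assert np.allclose(back.data[chrom], track.data[chrom])
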