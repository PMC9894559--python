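import numpy as np
import pytest

from endosym.io import GeneAnnotation, GenomeRecord, revcomp
from endosym.metrics import (
    gc_content,
    rotate_to_anchor,
    skew_index,
    skew_profile,
    SkewProfile,
)

from conftest import random_sequence


class TestRotate:
    def test_anchor_already_at_origin(self):
        g = GenomeRecord("x", "ACGTACGT", circular=True)
        ann = [GeneAnnotation("x", "a", 0, 4, "+", family_id="F")]
        rot, ra = rotate_to_anchor(g, ann, "F")
        assert rot.sequence == g.sequence
        assert (ra[0].start, ra[0].end) == (0, 4)

    def test_rotation_arithmetic(self):
        g = GenomeRecord("x", "AAAACCGGTT", circular=True)
        ann = [GeneAnnotation("x", "a", 4, 6, "+", family_id="F")]
        rot, ra = rotate_to_anchor(g, ann, "F")
        assert rot.sequence == "CCGGTTAAAA"
        assert (ra[0].start, ra[0].end) == (0, 2)

    def test_minus_strand_anchor_round_trip(self):
        rng = np.random.default_rng(0)
        seq = random_sequence(rng, 1000)
        g = GenomeRecord("x", seq, circular=True)
        ann = [
            GeneAnnotation("x", "anchor", 300, 360, "-", family_id="F"),
            GeneAnnotation("x", "other", 500, 620, "+", family_id="G"),
        ]
        rot, ra = rotate_to_anchor(g, ann, "F")
        anchor = next(a for a in ra if a.family_id == "F")
        assert anchor.start == 0 and anchor.strand == "+"
        # anchor sequence preserved as its reverse complement
        assert rot.sequence[0:60] == revcomp(seq[300:360])
        # idempotence
        rot2, ra2 = rotate_to_anchor(rot, ra, "F")
        assert rot2.sequence == rot.sequence
        assert ra2 == sorted(ra, key=lambda a: (a.start, a.end, a.gene_id))

    def test_anchor_absent_or_duplicated(self):
        g = GenomeRecord("x", "ACGTACGT", circular=True)
        with pytest.raises(ValueError, match="absent"):
            rotate_to_anchor(g, [], "F")
        ann = [
            GeneAnnotation("x", "a", 0, 2, "+", family_id="F"),
            GeneAnnotation("x", "b", 4, 6, "+", family_id="F"),
        ]
        with pytest.raises(ValueError, match="2x"):
            rotate_to_anchor(g, ann, "F")

    def test_wraparound_gene_split(self):
        g = GenomeRecord("x", "AAAACCGGTT", circular=True)
        ann = [
            GeneAnnotation("x", "anchor", 4, 6, "+", family_id="F"),
            GeneAnnotation("x", "wrap", 2, 5, "+", family_id="G"),
        ]
        _rot, ra = rotate_to_anchor(g, ann, "F")
        parts = [a for a in ra if a.gene_id == "wrap"]
        assert len(parts) == 2
        assert sum(p.length for p in parts) == 3


class TestGc:
    @pytest.mark.parametrize(
        "seq,expected", [("GGCC", 100.0), ("ATAT", 0.0), ("GCAT", 50.0)]
    )
    def test_examples(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_n_excluded(self):
        assert gc_content("GCNN") == pytest.approx(100.0)

    def test_all_n_rejected(self):
        with pytest.raises(ValueError):
            gc_content("NNNN")

    def test_revcomp_invariance(self):
        rng = np.random.default_rng(3)
        seq = random_sequence(rng, 5000)
        assert gc_content(seq) == pytest.approx(gc_content(revcomp(seq)))


class TestSkewProfile:
    def test_all_g(self):
        prof = skew_profile("G" * 1000, window=100)
        assert all(v == 1.0 for v in prof.values)

    def test_balanced(self):
        prof = skew_profile("GC" * 500, window=100)
        assert all(v == 0.0 for v in prof.values)

    def test_missing_windows(self):
        prof = skew_profile("A" * 200 + "G" * 200, window=100)
        assert prof.values[0] is None and prof.values[-1] == 1.0

    def test_bad_window(self):
        with pytest.raises(ValueError):
            skew_profile("ACGT", window=0)
        with pytest.raises(ValueError):
            skew_profile("ACGT", window=10)


def _brute_skew_index(values):
    """Exhaustive split enumeration oracle (independent of the package's
    prefix-sum implementation)."""
    vals = [v for v in values]
    n = len(vals)
    ok = [v is not None for v in vals]
    n_ok = sum(ok)
    best = -1.0
    for i in range(n):
        for arc in range(1, n):
            in_arc = set((i + t) % n for t in range(arc))
            a = sum(
                1 for w in range(n) if ok[w] and (
                    (w in in_arc and vals[w] > 0) or (w not in in_arc and vals[w] < 0)
                )
            )
            b = sum(
                1 for w in range(n) if ok[w] and (
                    (w in in_arc and vals[w] < 0) or (w not in in_arc and vals[w] > 0)
                )
            )
            best = max(best, max(a, b) / n_ok)
    return 2 * max(best, 1 - best) - 1


class TestSkewIndex:
    def test_perfect_bipartition(self):
        prof = skew_profile("G" * 5000 + "C" * 5000, window=500)
        assert skew_index(prof).skew_index == pytest.approx(1.0)

    def test_alternating_matches_exhaustive_oracle(self):
        values = [0.5 if i % 2 == 0 else -0.5 for i in range(10)]
        prof = SkewProfile(window=10, step=10, values=values, n_windows=10)
        assert skew_index(prof).skew_index == pytest.approx(
            _brute_skew_index(values)
        )

    def test_random_profiles_match_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            values = [float(v) for v in rng.normal(size=12)]
            prof = SkewProfile(window=10, step=10, values=values, n_windows=12)
            assert skew_index(prof).skew_index == pytest.approx(
                _brute_skew_index(values)
            )

    def test_rotation_invariance(self):
        rng = np.random.default_rng(4)
        seq = random_sequence(rng, 20_000)
        base = skew_index(skew_profile(seq, window=1000)).skew_index
        for shift in (2000, 7000, 13_000):
            rot = seq[shift:] + seq[:shift]
            assert skew_index(skew_profile(rot, window=1000)).skew_index == (
                pytest.approx(base)
            )

    def test_revcomp_invariance(self):
        rng = np.random.default_rng(5)
        seq = random_sequence(rng, 20_000)
        a = skew_index(skew_profile(seq, window=1000)).skew_index
        b = skew_index(skew_profile(revcomp(seq), window=1000)).skew_index
        assert a == pytest.approx(b)

    def test_bounded_and_needs_four_windows(self):
        with pytest.raises(ValueError):
            skew_index(SkewProfile(10, 10, [0.1, -0.1, 0.3], 3))

    def test_random_sequence_low_index(self):
        rng = np.random.default_rng(6)
        vals = []
        for _ in range(30):
            seq = random_sequence(rng, 10_000)
            vals.append(skew_index(skew_profile(seq, window=200)).skew_index)
        assert 0.0 <= min(vals) and max(vals) <= 1.0
        assert float(np.mean(vals)) < 0.35

    def test_planted_skew_sign_flips_at_terminus(self, strain_set):
        genomes, _, _ = strain_set
        g = genomes[0]
        prof = skew_profile(g.sequence, window=len(g) // 20)
        vals = [v for v in prof.values if v is not None]
        first, second = vals[: len(vals) // 3], vals[-len(vals) // 3 :]
        assert np.mean(first) > 0 > np.mean(second)
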