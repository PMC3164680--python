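"""Conserved k-mer detection, blocks, summaries and length correlations."""

import numpy as np
import pytest

from igsfootprint.align import MultipleAlignment
from igsfootprint.conservation import (
    UndefinedCorrelation,
    compare_correlations,
    conservation_summary,
    find_conserved_kmers,
    group_into_blocks,
    length_correlation,
    nested_kmer_partition,
)


def oracle_kmers(rows, min_k=5):
    """Independent oracle: test every (start, length) window directly."""
    L = len(rows[0])
    conserved = [
        all(r[c] == rows[0][c] and r[c] != "-" for r in rows) for c in range(L)
    ]
    out = []
    for s in range(L):
        if conserved[s] and (s == 0 or not conserved[s - 1]):
            e = s
            while e < L and conserved[e]:
                e += 1
            if e - s >= min_k:
                out.append((s, e - s, rows[0][s:e]))
    return out


def random_alignment(rng, n_rows, n_cols, gap_frac=0.1, alphabet="ACGT"):
    chars = list(alphabet) + ["-"]
    p = [(1 - gap_frac) / len(alphabet)] * len(alphabet) + [gap_frac]
    rows = [
        "".join(rng.choice(chars, size=n_cols, p=p)) for _ in range(n_rows)
    ]
    return MultipleAlignment("rand", [f"t{i}" for i in range(n_rows)], rows)


class TestFindConservedKmers:
    def test_identity_alignment_single_maximal_run(self):
        aln = MultipleAlignment("k", list("abcd"), ["AGGAGGTTTT"] * 4)
        (km,) = find_conserved_kmers(aln)
        assert (km.start_col, km.k, km.sequence) == (0, 10, "AGGAGGTTTT")
        assert not km.at_only and km.gc_fraction == pytest.approx(0.4)

    def test_periodic_mismatches_leave_nothing(self):
        a = "AAAAAAAAAAAAAAAAAAAA"
        b = "".join("T" if i % 5 == 4 else "A" for i in range(20))
        aln = MultipleAlignment("k", ["a", "b"], [a, b])
        assert find_conserved_kmers(aln) == []

    def test_equals_window_oracle_on_random_alignments(self, rng):
        for _ in range(40):
            aln = random_alignment(rng, int(rng.integers(2, 5)), 200)
            got = [(k.start_col, k.k, k.sequence) for k in find_conserved_kmers(aln)]
            assert got == oracle_kmers(aln.rows)

    def test_maximality(self, rng):
        for _ in range(20):
            aln = random_alignment(rng, 3, 300, gap_frac=0.05, alphabet="AT")
            cols = aln.rows
            for km in find_conserved_kmers(aln, min_k=3):
                for c in (km.start_col - 1, km.end_col):
                    if 0 <= c < aln.n_columns:
                        chars = {r[c] for r in cols}
                        assert len(chars) > 1 or "-" in chars

    def test_subset_monotonicity(self, rng):
        """Adding a taxon never increases total conserved columns."""
        aln = random_alignment(rng, 5, 300, alphabet="AT")
        taxa = aln.taxa
        prev = None
        for n in range(2, 6):
            total = sum(k.k for k in find_conserved_kmers(aln, taxa[:n], min_k=1))
            if prev is not None:
                assert total <= prev
            prev = total

    def test_empty_subset_rejected(self):
        aln = MultipleAlignment("k", ["a", "b"], ["AAAA", "AAAA"])
        with pytest.raises(ValueError):
            find_conserved_kmers(aln, ["a"])


class TestNestedPartition:
    def _planted(self):
        # three 10-column regions split by separator columns that differ
        # between a and b; region 1 conserved in all four taxa, region 2
        # mutated in d (no 4-taxon run >= 5 left), region 3 mutated in c and d
        region = "ACGTACGTAC"
        sep_a, sep_b = "G", "T"
        rows = {t: [] for t in "abcd"}
        for ri in range(3):
            for t in "abcd":
                block = list(region)
                if (ri == 1 and t == "d") or (ri == 2 and t in "cd"):
                    block[2] = "T"
                    block[7] = "G"
                rows[t].extend(block)
                rows[t].append(sep_a if t == "a" else sep_b)
        return MultipleAlignment(
            "k", list("abcd"), ["".join(rows[t]) for t in "abcd"]
        )

    def test_deepest_assignment(self):
        aln = self._planted()
        subsets = [list("abcd"), list("abc"), list("ab")]
        part = nested_kmer_partition(aln, subsets, min_k=5)
        spans = {
            frozenset(s): sorted((k.start_col, k.end_col) for k in v)
            for s, v in part.items()
        }
        assert spans[frozenset("abcd")] == [(0, 10)]
        assert spans[frozenset("abc")] == [(11, 21)]
        assert spans[frozenset("ab")] == [(22, 32)]

    def test_partition_property(self, rng):
        """Depth lists are disjoint; union equals the shallowest scan."""
        for _ in range(15):
            aln = random_alignment(rng, 4, 250, alphabet="AT", gap_frac=0.05)
            subsets = [aln.taxa, aln.taxa[:3], aln.taxa[:2]]
            part = nested_kmer_partition(aln, subsets, min_k=4)
            union = sorted(
                (k.start_col, k.k) for v in part.values() for k in v
            )
            shallow = sorted(
                (k.start_col, k.k)
                for k in find_conserved_kmers(aln, aln.taxa[:2], min_k=4)
            )
            assert union == shallow
            assert len(union) == len(set(union))

    def test_non_nested_rejected(self):
        aln = MultipleAlignment("k", list("abcd"), ["AAAA"] * 4)
        with pytest.raises(ValueError):
            nested_kmer_partition(aln, [list("abc"), list("abd")])


class TestBlocks:
    def _km(self, start, k):
        from igsfootprint.conservation import ConservedKmer

        return ConservedKmer("x", start, k, "A" * k, frozenset("ab"), 0.0, True)

    def test_pair_within_30(self):
        blocks = group_into_blocks([self._km(0, 6), self._km(26, 6)])
        assert len(blocks) == 1 and blocks[0].qualifying_rule == "pair_within_30"

    def test_single_long_kmer(self):
        (b,) = group_into_blocks([self._km(0, 10)])
        assert b.qualifying_rule == "single_ge_10"

    def test_isolated_short_kmer_dropped(self):
        assert group_into_blocks([self._km(0, 6)]) == []

    def test_gap_of_exactly_30_splits(self):
        blocks = group_into_blocks([self._km(0, 10), self._km(40, 10)])
        assert len(blocks) == 2

    def test_transitive_chaining(self):
        kms = [self._km(0, 6), self._km(20, 6), self._km(46, 6)]
        (b,) = group_into_blocks(kms)
        assert len(b.members) == 3 and b.span == (0, 52)


class TestSummary:
    def test_density_arithmetic(self):
        aln = MultipleAlignment("a|b", ["x", "y"], ["A" * 100, "A" * 100])
        kms = find_conserved_kmers(aln, min_k=5)
        # one 100-column k-mer in one 100-column alignment: 1 per 100 nt
        summary = conservation_summary({("a", "b"): aln}, {("a", "b"): kms})
        assert summary["per_category"]["all"]["kmer_density_per_100nt"] == 1.0
        assert summary["n_igs_with_kmer"] == 1

    def test_empty(self):
        aln = MultipleAlignment("a|b", ["x", "y"], ["ACGT" * 5, "TGCA" * 5])
        s = conservation_summary({("a", "b"): aln}, {("a", "b"): []})
        assert s["n_kmers"] == 0 and s["histogram"] == {}
        assert s["coverage_fraction"] == 0.0


class TestCorrelations:
    def test_perfect_order(self):
        c = length_correlation([10, 20, 30, 40], [1, 2, 3, 4])
        assert c.r == pytest.approx(1.0)

    def test_perfect_anti_order(self):
        c = length_correlation([10, 20, 30, 40], [40, 30, 20, 10])
        assert c.r == pytest.approx(-1.0)

    def test_matches_definitional_covariance(self, rng):
        x = rng.normal(100, 20, size=50)
        y = 0.5 * x + rng.normal(0, 10, size=50)
        c = length_correlation(x, y)
        manual = float(
            np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
        )
        assert c.r == pytest.approx(manual, abs=1e-12)
        assert c.fisher_z == pytest.approx(np.arctanh(manual))

    def test_zero_variance_signalled(self):
        with pytest.raises(UndefinedCorrelation):
            length_correlation([5, 5, 5, 5], [1, 2, 3, 4])

    def test_equal_correlations_give_zero_z(self):
        z, p = compare_correlations(0.5, 50, 0.5, 50)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_large_difference_is_significant(self):
        # closed form: z = (atanh(.9)-atanh(.3))/sqrt(2/100) = ~7.2
        z, p = compare_correlations(0.9, 103, 0.3, 103)
        assert p < 1e-4
        expect = (np.arctanh(0.9) - np.arctanh(0.3)) / np.sqrt(2 / 100)
        assert z == pytest.approx(expect)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            compare_correlations(0.5, 3, 0.5, 50)

    def test_boundary_r_signalled(self):
        with pytest.raises(UndefinedCorrelation):
            compare_correlations(1.0, 50, 0.5, 50)
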