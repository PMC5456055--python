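"""Divergence statistics, the percent-variability formula on the published
tables, the hotspot screen, and the built-in aligner."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastome_compare import reference_tables as rt
from plastome_compare._pairwise import (GAP_EXTEND, GAP_OPEN, MATCH, MISMATCH,
                                        pairwise_align, progressive_align)
from plastome_compare.divergence import (RegionAlignment, align_region,
                                         divergence_stats, hotspot_screen,
                                         overall_identity,
                                         percent_variability, round2_half_up)


# ---------------------------------------------------------------------------
# independent column-scan oracle

def oracle_stats(rows):
    """Brute-force per-column reimplementation of (S, V, I, G)."""
    L = len(rows[0])
    S = V = 0
    for i in range(L):
        col = [r[i] for r in rows]
        if "-" in col:
            V += 1
        elif len(set(col)) > 1:
            S += 1
            V += 1
    events = set()
    for r in rows:
        i = 0
        while i < L:
            if r[i] == "-":
                j = i
                while j < L and r[j] == "-":
                    j += 1
                events.add((i, j))
                i = j
            else:
                i += 1
    return S, V, len(events), sum(j - i for i, j in events)


def random_alignment(rng, n_rows, L):
    rows = []
    for _ in range(n_rows):
        chars = rng.choice(list("ACGT-"), size=L, p=[0.24, 0.24, 0.24, 0.24, 0.04])
        rows.append("".join(chars))
    return rows


class TestStats:
    def test_toy_example_one_substitution_one_shared_gap(self):
        rows = ["ACGTACGTAC", "ACGTACGTAC", "AC--ACGTAT"]
        aln = RegionAlignment(name="toy", taxa=["a", "b", "c"], rows=rows)
        st_ = divergence_stats(aln)
        assert (st_.substitutions, st_.indel_events, st_.indel_length) == (1, 1, 2)
        assert st_.variable_positions == 3
        assert st_.percent_variability == 20.00

    def test_gap_adjacent_substitution_counts_only_via_gap_term(self):
        rows = ["AAAA", "A-CA"]
        aln = RegionAlignment(name="x", taxa=["a", "b"], rows=rows)
        st_ = divergence_stats(aln)
        assert st_.substitutions == 1  # column 3 (C vs A); column 2 is a gap column
        assert st_.variable_positions == 2

    def test_shared_vs_shifted_gap_runs(self):
        shared = RegionAlignment(name="s", taxa=list("abc"),
                                 rows=["AC--GT", "AC--GT", "ACTTGT"])
        shifted = RegionAlignment(name="s", taxa=list("abc"),
                                  rows=["A--CGT", "AC--GT", "ACTTGT"])
        assert divergence_stats(shared).indel_events == 1
        assert divergence_stats(shifted).indel_events == 2

    def test_matches_oracle_on_random_alignments(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            rows = random_alignment(rng, int(rng.integers(2, 8)), int(rng.integers(5, 60)))
            aln = RegionAlignment(name="r", taxa=[f"t{i}" for i in range(len(rows))], rows=rows)
            st_ = divergence_stats(aln)
            S, V, I, G = oracle_stats(rows)
            assert (st_.substitutions, st_.variable_positions,
                    st_.indel_events, st_.indel_length) == (S, V, I, G)

    @given(st.permutations(range(4)))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_invariant_under_row_permutation(self, perm):
        rows = ["ACGTAC-TAC", "ACCTACGTAC", "AC--ACGTAT", "ACGTACGAAC"]
        taxa = list("abcd")
        base = divergence_stats(RegionAlignment(name="p", taxa=taxa, rows=rows))
        shuf = divergence_stats(RegionAlignment(
            name="p", taxa=[taxa[i] for i in perm], rows=[rows[i] for i in perm]))
        assert (base.substitutions, base.variable_positions, base.indel_events,
                base.indel_length, base.percent_variability) == (
            shuf.substitutions, shuf.variable_positions, shuf.indel_events,
            shuf.indel_length, shuf.percent_variability)

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            divergence_stats(RegionAlignment(name="x", taxa=["a"], rows=["ACGT"]))


class TestFormulaAudit:
    """P = round2(100*(S+I)/L) and V = S + G against every published row."""

    @pytest.mark.parametrize("table", ["coding", "noncoding"])
    def test_percent_variability_reproduced_on_all_rows(self, table):
        df = (rt.coding_divergence_table() if table == "coding"
              else rt.noncoding_divergence_table())
        for _, row in df.iterrows():
            assert percent_variability(row.substitutions, row.indels,
                                       row.aligned_length) == row.percent_variability, row.region

    @pytest.mark.parametrize("table", ["coding", "noncoding"])
    def test_variable_positions_reproduced_on_all_rows(self, table):
        df = (rt.coding_divergence_table() if table == "coding"
              else rt.noncoding_divergence_table())
        assert (df.variable_positions == df.substitutions + df.indel_length).all()

    def test_rounding_is_half_up(self):
        assert round2_half_up(2.857) == 2.86
        assert round2_half_up(0.005) == 0.01
        assert percent_variability(4, 1, 175) == 2.86


class TestHotspots:
    def test_strict_threshold(self):
        stats = [RegionAlignment(name=n, taxa=["a", "b"], rows=["A", "A"]) for n in "xyz"]
        ds = []
        for name, p in zip("xyz", (1.9, 2.0, 2.5)):
            d = divergence_stats(RegionAlignment(name=name, taxa=["a", "b"], rows=["AA", "AA"]))
            d.percent_variability = p
            ds.append(d)
        hits = hotspot_screen(ds, threshold=2.0)
        assert [h.region for h in hits] == ["z"]

    def test_empty_input(self):
        assert hotspot_screen([]) == []

    def test_published_rows_give_exactly_eight(self):
        df = rt.noncoding_divergence_table()
        ds = []
        for _, row in df.iterrows():
            d = divergence_stats(RegionAlignment(name=row.region, taxa=["a", "b"],
                                                 rows=["AA", "AA"]))
            d.percent_variability = percent_variability(
                row.substitutions, row.indels, row.aligned_length)
            ds.append(d)
        hits = hotspot_screen(ds)
        assert len(hits) == 8
        assert {h.region for h in hits} == {
            "trnW (CCA)-trnP (UGG)", "trnT (UGU)-trnL (UAA)",
            "trnG (UCC)-trnfM (CAU)", "petD-rpoA", "psbB-psbT",
            "ndhE-ndhG", "ndhC-trnV (UAC)", "rpl32-trnL (UAG)"}


class TestIdentity:
    def test_identical_rows_are_100(self):
        aln = RegionAlignment(name="i", taxa=["a", "b"], rows=["ACGTACGTAC"] * 2)
        assert overall_identity(aln) == 100.0

    def test_one_difference_in_ten_columns(self):
        aln = RegionAlignment(name="i", taxa=["a", "b"], rows=["ACGTACGTAC", "ACGTACGTAT"])
        assert overall_identity(aln) == 90.0

    def test_matches_pairwise_counting_oracle(self, concat_alignment):
        rows, taxa = concat_alignment.rows, concat_alignment.taxa
        vals = []
        for i, j in itertools.combinations(range(len(rows)), 2):
            same = tot = 0
            for a, b in zip(rows[i], rows[j]):
                if a != "-" and b != "-":
                    tot += 1
                    same += a == b
            vals.append(same / tot)
        assert overall_identity(concat_alignment) == round(100 * sum(vals) / len(vals), 1)


# ---------------------------------------------------------------------------
# built-in aligner

def oracle_best_score(a, b):
    """Exhaustive affine-gap global alignment score by enumeration over all
    monotone alignment paths (tiny inputs only)."""
    best = [-1e30]

    def rec(i, j, prev, score):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            s = MATCH if a[i] == b[j] else MISMATCH
            rec(i + 1, j + 1, "D", score + s)
        if i < len(a):
            rec(i + 1, j, "U", score + (GAP_EXTEND if prev == "U" else GAP_OPEN))
        if j < len(b):
            rec(i, j + 1, "L", score + (GAP_EXTEND if prev == "L" else GAP_OPEN))

    rec(0, 0, "", 0.0)
    return best[0]


def alignment_score(ra, rb):
    score = 0.0
    prev = ""
    for x, y in zip(ra, rb):
        if x == "-" or y == "-":
            state = "U" if y == "-" else "L"
            score += GAP_EXTEND if prev == state else GAP_OPEN
            prev = state
        else:
            score += MATCH if x == y else MISMATCH
            prev = "D"
    return score


class TestBuiltinAligner:
    def test_identical_sequences_align_without_gaps(self):
        aln = align_region({"a": "ACGTACGT", "b": "ACGTACGT"}, method="builtin")
        assert aln.rows == ["ACGTACGT", "ACGTACGT"]

    def test_single_deletion_recovered(self):
        aln = align_region({"a": "ACGTACGT", "b": "ACGACGT"}, method="builtin")
        short = aln.rows[1]
        assert short.count("-") == 1 and short.replace("-", "") == "ACGACGT"

    @pytest.mark.parametrize("pair", [("ACGT", "AT"), ("AAAA", "AACA"),
                                      ("ACGTAC", "GTAC"), ("AGGT", "AT"),
                                      ("ACACAC", "ACGCAC"), ("TTTT", "GGGG")])
    def test_pairwise_score_is_optimal_by_enumeration(self, pair):
        a, b = pair
        ra, rb = pairwise_align(a, b)
        assert ra.replace("-", "") == a and rb.replace("-", "") == b
        assert alignment_score(ra, rb) == pytest.approx(oracle_best_score(a, b))

    def test_progressive_rows_reproduce_inputs(self):
        seqs = {"a": "ACGTACGTGG", "b": "ACGACGTGG", "c": "ACGTACGAGG", "d": "CGTACGTGG"}
        out = progressive_align(seqs)
        assert len({len(r) for r in out.values()}) == 1
        for k, v in seqs.items():
            assert out[k].replace("-", "") == v
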