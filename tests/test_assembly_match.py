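"""Canonical k-mer indexing and cross-assembly containment matching."""

import numpy as np
import pytest

from bsaseq.assembly_match import (
    ContigSet,
    canonical_kmers,
    containment,
    index_kmers,
    match_assemblies,
    n_kmer_positions,
)
from bsaseq.simdata import random_dna

_RC = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def substring_match_oracle(x: str, y: str) -> bool:
    """Brute-force decision: do the sequences match as copy/fragment?

    Slides the shorter sequence (either strand) along the longer with 0
    mismatches; any full-length placement is a match.  Mirrors what the
    k-mer containment criterion must decide for exact copies,
    truncations and split halves.
    """
    short, long_ = (x, y) if len(x) <= len(y) else (y, x)
    for probe in (short, revcomp(short)):
        if probe in long_:
            return True
    return False


def test_kmer_position_count():
    assert n_kmer_positions("ACGTACGTACGTACG", 11) == 5  # L - k + 1


def test_reverse_complement_has_identical_canonical_set(rng):
    seq = random_dna(rng, 300)
    assert np.array_equal(canonical_kmers(seq, 21), canonical_kmers(revcomp(seq), 21))


def test_self_containment_is_exactly_one(rng):
    seq = random_dna(rng, 500)
    assert containment(seq, seq, 21) == 1.0


def test_disjoint_random_contigs_share_no_kmers():
    """Two independent random 1 kb sequences collide on a canonical
    21-mer with probability ~ 2 * 980^2 / 4^21 ~ 4e-7; over 20 seeds we
    should never observe a shared k-mer."""
    for seed in range(20):
        rng = np.random.default_rng(seed)
        a, b = random_dna(rng, 1000), random_dna(rng, 1000)
        assert containment(a, b, 21) == 0.0


def test_ambiguous_bases_are_skipped(rng):
    seq = random_dna(rng, 100)
    polluted = seq[:50] + "N" + seq[51:]
    km = canonical_kmers(polluted, 21)
    # the N removes exactly the k windows covering position 50
    assert km.size <= canonical_kmers(seq, 21).size - 1
    assert n_kmer_positions(polluted, 21) == 100 - 21 + 1 - 21


def test_short_contig_recorded_unindexable(rng):
    cs = ContigSet("A", [("ok", random_dna(rng, 100)), ("tiny", "ACGTACGT")])
    idx = index_kmers(cs, 21)
    assert idx.unindexable == ["tiny"]
    assert idx.contig_ids == ["ok"]


@pytest.mark.parametrize("k", [10, 12, 20])
def test_even_or_small_k_rejected(k, rng):
    with pytest.raises(ValueError):
        index_kmers(ContigSet("A", [("c", random_dna(rng, 100))]), k)


def test_exact_copy_matches_both_directions(rng):
    seq = random_dna(rng, 400)
    a = ContigSet("A", [("a1", seq)])
    b = ContigSet("B", [("b1", seq)])
    table = match_assemblies(a, b)
    row = table.pairs.iloc[0]
    assert row.containment_ab == 1.0 and row.containment_ba == 1.0
    assert row.reciprocal_best == 1


def test_half_fragment_has_full_reverse_containment(rng):
    seq = random_dna(rng, 400)
    a = ContigSet("A", [("a1", seq)])
    b = ContigSet("B", [("b1", seq[:200])])
    table = match_assemblies(a, b)
    row = table.pairs.iloc[0]
    assert row.containment_ba == 1.0
    assert 0.3 < row.containment_ab < 0.6


def test_empty_set_yields_empty_table(rng):
    a = ContigSet("A", [("a1", random_dna(rng, 100))])
    assert match_assemblies(a, ContigSet("B", [])).pairs.empty


def test_match_decisions_equal_substring_oracle(rng):
    """On 50 copy / truncation / split / unrelated cases the k-mer
    containment decision must equal the exhaustive sliding-window
    0-mismatch oracle."""
    cases = []
    for i in range(50):
        src = random_dna(rng, int(rng.integers(100, 201)))
        kind = i % 4
        if kind == 0:
            other = src
        elif kind == 1:  # truncation keeping >= 50%
            keep = int(len(src) * rng.uniform(0.5, 0.9))
            other = src[:keep]
        elif kind == 2:  # one half of a split, reverse strand
            point = len(src) // 2
            other = revcomp(src[:point])
        else:  # unrelated
            other = random_dna(rng, int(rng.integers(100, 201)))
        cases.append((src, other))
    for src, other in cases:
        a = ContigSet("A", [("a1", src)])
        b = ContigSet("B", [("b1", other)])
        got = len(match_assemblies(a, b).pairs) > 0
        assert got == substring_match_oracle(src, other), (src[:30], other[:30])


def test_pair_set_symmetric_and_order_invariant(rng):
    seqs = [random_dna(rng, 300) for _ in range(6)]
    a = ContigSet("A", [(f"a{i}", s) for i, s in enumerate(seqs)])
    # B: copies of a subset plus novels
    b_contigs = [("b0", seqs[0]), ("b1", seqs[1][:150]), ("b2", random_dna(rng, 300))]
    b = ContigSet("B", b_contigs)
    fwd = match_assemblies(a, b)
    rev = match_assemblies(b, a)
    fwd_pairs = {(r.id_a, r.id_b) for r in fwd.pairs.itertuples(index=False)}
    rev_pairs = {(r.id_b, r.id_a) for r in rev.pairs.itertuples(index=False)}
    assert fwd_pairs == rev_pairs
    # shuffled contig order gives an identical table
    b_shuffled = ContigSet("B", list(reversed(b_contigs)))
    assert fwd.pairs.equals(match_assemblies(a, b_shuffled).pairs)
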