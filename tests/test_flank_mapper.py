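"""Flank extraction and Hamming-distance flank classification."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from numpy.random import default_rng

from tncall import ReferenceSet, classify_flank, extract_flanks, hamming_best_match
from tncall._util import random_dna, revcomp
from tncall.flank_mapper import Flank, FlankClassifier, HammingIndex
from tncall.tn_finder import MiniTnHit

from _oracles import brute_flank_label, brute_hamming_scan


def _hit(start, end, read_id="r", rank=1):
    return MiniTnHit(read_id, start, end, "+", end - start, 0.0, 0, rank)


@pytest.fixture(scope="module")
def genome():
    return random_dna(default_rng(21), 5_000)


@pytest.fixture(scope="module")
def plasmid():
    return random_dna(default_rng(22), 3_000)


# --- extraction -----------------------------------------------------------


def test_centered_hit_yields_both_50bp_flanks():
    read = random_dna(default_rng(23), 2_000)
    flanks = extract_flanks("r", read, [_hit(900, 1100)])
    assert [(f.side, len(f.sequence)) for f in flanks] == [("left", 50), ("right", 50)]
    assert flanks[0].sequence == read[850:900]
    assert flanks[1].sequence == read[1100:1150]


def test_truncated_flank_near_read_edge_is_discarded():
    read = random_dna(default_rng(24), 500)
    # only 30 bases upstream of the hit: left flank discarded, right kept
    flanks = extract_flanks("r", read, [_hit(30, 230)])
    assert [f.side for f in flanks] == ["right"]
    # and symmetrically at the 3' edge
    flanks = extract_flanks("r", read, [_hit(270, 470)])
    assert [f.side for f in flanks] == ["left"]


def test_two_hits_separated_by_exactly_100bp():
    read = random_dna(default_rng(25), 1_000)
    h1, h2 = _hit(200, 400, rank=1), _hit(500, 700, rank=2)
    flanks = extract_flanks("r", read, [h1, h2])
    assert [(f.hit_rank, f.side) for f in flanks] == [
        (1, "left"), (1, "right"), (2, "left"), (2, "right"),
    ]
    # the inter-hit region yields two adjacent non-overlapping 50-mers
    assert flanks[1].sequence == read[400:450]
    assert flanks[2].sequence == read[450:500]


def test_window_crossing_adjacent_hit_is_discarded():
    read = random_dna(default_rng(26), 1_000)
    # 40-bp inter-hit gap: both inner windows would cross the other hit
    flanks = extract_flanks("r", read, [_hit(200, 400, rank=1), _hit(440, 640, rank=2)])
    assert [(f.hit_rank, f.side) for f in flanks] == [(1, "left"), (2, "right")]
    # a 60-bp gap fits both inner windows (they may overlap each other)
    flanks = extract_flanks("r", read, [_hit(200, 400, rank=1), _hit(460, 660, rank=2)])
    assert [(f.hit_rank, f.side) for f in flanks] == [
        (1, "left"), (1, "right"), (2, "left"), (2, "right"),
    ]


# --- Hamming search -------------------------------------------------------


def test_exact_substring_found_at_distance_zero(genome):
    d, pos, strand = hamming_best_match(genome[1000:1050], genome)
    assert (d, pos, strand) == (0, [1000], "+")


def test_reverse_complement_found_on_minus_strand(genome):
    d, pos, strand = hamming_best_match(revcomp(genome[1000:1050]), genome)
    assert (d, pos, strand) == (0, [1000], "-")


def test_circular_wrap_placement_found(genome):
    wrap = genome[-20:] + genome[:30]
    assert hamming_best_match(wrap, genome, circular=True)[0] == 0
    assert hamming_best_match(wrap, genome, circular=False)[0] == 3  # clipped > max


@pytest.mark.parametrize("n_mismatches", [0, 1, 2, 3])
def test_planted_mismatches_agree_with_brute_force(genome, n_mismatches):
    rng = default_rng(30 + n_mismatches)
    for _ in range(20):
        p = int(rng.integers(0, len(genome) - 50))
        q = list(genome[p : p + 50])
        for j in rng.choice(50, size=n_mismatches, replace=False):
            q[j] = {"A": "C", "C": "G", "G": "T", "T": "A"}[q[j]]
        q = "".join(q)
        got = hamming_best_match(q, genome)
        exp_d, exp_pos, exp_strand = brute_hamming_scan(q, genome)
        if exp_d > 2:
            assert got == (3, [], None)
        else:
            assert got == (exp_d, exp_pos, exp_strand)


def test_random_queries_agree_with_brute_force(genome):
    rng = default_rng(40)
    for _ in range(30):
        q = random_dna(rng, 50)
        got = hamming_best_match(q, genome)
        exp_d, _, _ = brute_hamming_scan(q, genome)
        assert got[0] == min(exp_d, 3)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.integers(0, 4_950), st.lists(st.integers(0, 49), max_size=4, unique=True))
def test_strand_symmetry_property(genome, start, mut_positions):
    """d(q, ref) == d(revcomp(q), ref) with the strand label flipped."""
    q = list(genome[start : start + 50])
    for j in mut_positions:
        q[j] = {"A": "C", "C": "G", "G": "T", "T": "A"}[q[j]]
    q = "".join(q)
    d1, p1, s1 = hamming_best_match(q, genome)
    d2, p2, s2 = hamming_best_match(revcomp(q), genome)
    assert d1 == d2
    assert p1 == p2
    if d1 <= 2:
        assert {s1, s2} == {"+", "-"}


def test_index_rejects_wrong_query_length(genome):
    idx = HammingIndex(genome, query_length=50)
    with pytest.raises(ValueError):
        idx.search("ACGT")


# --- classification -------------------------------------------------------


def _refs(genome, plasmid):
    return ReferenceSet(genome, plasmid, (0, 1_000), target_sites=[])


def test_clear_genomic_winner(genome, plasmid):
    refs = _refs(genome, plasmid)
    fl = Flank("r", 1, "left", genome[700:750])
    call = classify_flank(fl, refs)
    assert call.label == "genomic"
    assert call.min_distance_genome == 0
    assert call.min_distance_plasmid == 3  # clipped ">2"
    assert (call.best_position, call.best_strand) == (700, "+")


def test_lower_distance_wins_even_when_both_within_limit(genome, plasmid):
    refs = _refs(genome, plasmid)
    # plant the same 50-mer in both references, then add one mismatch to
    # the genome copy only: plasmid (distance 0) must win over genome (1)
    core = plasmid[100:150]
    g = genome[:2000] + core + genome[2050:]
    g = g[:2010] + ("A" if g[2010] != "A" else "C") + g[2011:]
    call = classify_flank(Flank("r", 1, "left", core), _refs(g, plasmid))
    assert call.label == "plasmid"
    assert call.min_distance_plasmid == 0
    assert call.min_distance_genome == 1


def test_distance_above_two_on_both_references_unclassified(genome, plasmid):
    refs = _refs(genome, plasmid)
    rng = default_rng(41)
    q = random_dna(rng, 50)  # random 50-mer: far from both references
    call = classify_flank(Flank("r", 1, "left", q), refs)
    assert call.label == "unclassified"
    assert not call.tie
    assert call.best_position is None


def test_exact_tie_is_unclassified_with_tie_flag(genome, plasmid):
    core = genome[600:650]
    p = plasmid[:500] + core + plasmid[550:]  # same 50-mer in both: 0 vs 0
    call = classify_flank(Flank("r", 1, "left", core), _refs(genome, p))
    assert call.label == "unclassified"
    assert call.tie


def test_monotonicity_in_max_hamming(genome, plasmid):
    """Raising max_hamming can only convert unclassified calls to
    classified ones, never flip genomic <-> plasmid."""
    rng = default_rng(42)
    refs = _refs(genome, plasmid)
    for _ in range(15):
        p = int(rng.integers(0, len(genome) - 50))
        q = list(genome[p : p + 50])
        for j in rng.choice(50, size=int(rng.integers(0, 4)), replace=False):
            q[j] = {"A": "C", "C": "G", "G": "T", "T": "A"}[q[j]]
        fl = Flank("r", 1, "left", "".join(q))
        labels = [classify_flank(fl, refs, max_hamming=m).label for m in (0, 1, 2, 3)]
        seen = [lab for lab in labels if lab != "unclassified"]
        assert len(set(seen)) <= 1
        if seen:
            first = labels.index(seen[0])
            assert all(lab == seen[0] for lab in labels[first:])


def test_classifier_agrees_with_brute_force_oracle(genome, plasmid):
    refs = _refs(genome, plasmid)
    clf = FlankClassifier(refs)
    rng = default_rng(43)
    for i in range(40):
        if i % 2:
            src = genome if i % 4 == 1 else plasmid
            p = int(rng.integers(0, len(src) - 50))
            q = list(src[p : p + 50])
            for j in rng.choice(50, size=int(rng.integers(0, 4)), replace=False):
                q[j] = {"A": "C", "C": "G", "G": "T", "T": "A"}[q[j]]
            q = "".join(q)
        else:
            q = random_dna(rng, 50)
        call = clf.classify(Flank("r", 1, "left", q))
        label, dg, dp, pos, strand = brute_flank_label(q, genome, plasmid)
        assert call.label == label
        assert call.min_distance_genome == dg
        assert call.min_distance_plasmid == dp
        if label != "unclassified":
            assert call.best_position == pos[0]
            assert call.best_strand == strand
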