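"""Insertion coordinates, on-target windows, binning, summaries."""

import numpy as np
import pandas as pd
import pytest

from tncall import (
    TargetSite,
    bin_insertions,
    classify_reads,
    generate_reads,
    insertion_coordinate,
    is_on_target,
    summarize,
)
from tncall._util import revcomp
from tncall.site_analysis import InsertionEvent, make_events


# --- on-target window -----------------------------------------------------


def test_window_center_offset_is_strand_aware():
    assert TargetSite(1_000, "+", 49).center() == 1_049
    assert TargetSite(1_000, "-", 49).center() == 951
    assert TargetSite(1_000, "+", 40).center() == 1_040


def test_window_is_inclusive_at_both_edges():
    t = TargetSite(1_000, "+", 49)  # center 1049
    assert is_on_target(1_049, t)
    assert is_on_target(1_049 + 50, t)
    assert not is_on_target(1_049 + 51, t)
    assert is_on_target(1_049 - 50, t)
    assert not is_on_target(1_049 - 51, t)


def test_window_wraps_on_circular_genome():
    t = TargetSite(10, "-", 49)  # center at -39 -> 9961 on a 10 kb circle
    assert is_on_target(9_961, t, genome_length=10_000, circular=True)
    assert not is_on_target(9_961, t, genome_length=10_000, circular=False)


# --- binning --------------------------------------------------------------


def test_binning_boundaries_and_conservation():
    counts = bin_insertions([0, 4_999, 5_000, 12_345], 20_000, 5_000)
    assert counts.tolist() == [2, 1, 1, 0]
    rng = np.random.default_rng(5)
    coords = rng.integers(0, 19_999, size=100)
    assert bin_insertions(coords, 20_000, 5_000).sum() == 100
    # ragged final bin: ceil(10500 / 5000) = 3 bins
    assert bin_insertions([], 10_500, 5_000).shape == (3,)


def test_binning_rejects_out_of_range_coordinates():
    with pytest.raises(ValueError):
        bin_insertions([20_000], 20_000, 5_000)


# --- coordinate recovery on synthetic reads -------------------------------


@pytest.fixture(scope="module")
def classified(small_config, small_refs, small_run):
    reads, manifest = small_run
    result = classify_reads(((r.id, str(r.seq)) for r in reads), small_refs)
    return result, manifest


def test_insertion_coordinates_match_truth_exactly(classified, small_config):
    """Error-free reads: the junction coordinate of the first genomic
    flank equals the generator's recorded truth for every scored read."""
    result, manifest = classified
    truth = manifest.set_index("read_id")["true_insertion_site"]
    scored = 0
    for rc in result.read_calls:
        coord = insertion_coordinate(rc, small_config.genome_length)
        if coord is None:
            continue
        assert coord == truth[rc.read_id]
        scored += 1
    assert scored > 20


def test_coordinate_strand_symmetry(classified, small_refs, small_config, small_run):
    """A read and its reverse complement give the same junction, because
    the first genomic flank is re-evaluated in the flipped frame."""
    reads, manifest = small_run
    result, _ = classified
    by_id = {rc.read_id: rc for rc in result.read_calls}
    picked = [r for r in reads if by_id[r.id].read_class == "simple_insertion"][:5]
    assert picked
    for rec in picked:
        flipped = classify_reads([(rec.id, revcomp(str(rec.seq)))], small_refs)
        rc = flipped.read_calls[0]
        assert rc.read_class == "simple_insertion"
        c_fwd = insertion_coordinate(by_id[rec.id], small_config.genome_length)
        c_rev = insertion_coordinate(rc, small_config.genome_length)
        # junctions on either side of one insertion differ by the TSD
        assert abs(c_fwd - c_rev) in (0, small_config.tsd_length - 1)


def test_cointegrate_uses_first_genomic_flank_ignoring_plasmid(classified, small_config):
    result, manifest = classified
    truth = manifest.set_index("read_id")
    n = 0
    for rc in result.read_calls:
        if rc.read_class != "cointegrate":
            continue
        coord = insertion_coordinate(rc, small_config.genome_length)
        assert coord == truth.loc[rc.read_id, "true_insertion_site"]
        n += 1
    assert n > 5


# --- summary --------------------------------------------------------------


def _ev(coord, on, cls="simple_insertion", rid="e"):
    return InsertionEvent(rid, cls, coord, on)


def test_summary_fractions_arithmetic(classified, small_config):
    result, _ = classified
    s = result.summary
    assert s.n_reads_total == small_config.n_reads
    total = s.n_plasmid + s.n_simple + s.n_cointegrate + s.n_removed
    assert total == s.n_reads_total
    prods = s.n_simple + s.n_cointegrate
    assert s.fraction_simple == pytest.approx(s.n_simple / prods)
    assert s.fraction_simple + s.fraction_cointegrate == pytest.approx(1.0)
    assert s.histogram.sum() == s.n_events


def test_summary_empty_denominators_are_null():
    s = summarize([], [], genome_length=10_000)
    assert s.fraction_simple is None
    assert s.fraction_cointegrate is None
    assert s.fraction_on_target is None


def test_on_target_fraction_matches_manifest(classified):
    result, manifest = classified
    truth = manifest.set_index("read_id")
    scored = [e.read_id for e in result.events]
    expected = truth.loc[scored, "on_target"].mean()
    assert result.summary.fraction_on_target == pytest.approx(expected)
    for e in result.events:
        assert e.on_target == bool(truth.loc[e.read_id, "on_target"])
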