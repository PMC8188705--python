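"""Insertion coordinates, on-target scoring, binning, and run summaries.

For every read called simple insertion or cointegrate, the genomic
insertion coordinate is taken from the first genome-mapping flank in the
read (5'->3').  The reported coordinate is the junction base — the flank
base adjacent to the mini-Tn — mapped through the flank's best placement;
note that because of the target-site duplication the left and right
junctions of one physical insertion differ by ``tsd_length`` bases, and
coordinates are reported per read without TSD collapsing (the 100-bp
on-target window absorbs the offset).

An event is on-target when its coordinate lies within a window (100 bp by
default, inclusive at both ends) centred ``offset_x`` bp downstream of
the protospacer 3' end, strand-aware, with modular arithmetic on circular
genomes.  Events are also grouped into fixed-size bins (5 kb by default)
for genome-wide histograms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .flank_mapper import LABEL_GENOMIC
from .read_classifier import CLASS_COINTEGRATE, CLASS_SIMPLE, ReadCall
from .references import TargetSite

DEFAULT_WINDOW = 100
DEFAULT_BIN_SIZE = 5000


@dataclass(frozen=True)
class InsertionEvent:
    read_id: str
    read_class: str
    genome_coordinate: int
    on_target: bool


def insertion_coordinate(
    read_call: ReadCall,
    genome_length: int | None = None,
    circular: bool = True,
    convention: str = "junction",
) -> int | None:
    """Genomic coordinate of the first genome-mapping flank of the read.

    ``convention="junction"`` (default) reports the flank base adjacent
    to the mini-Tn; ``"flank_start"`` reports the leftmost mapped base of
    the flank.  Returns None when the read has no genomic flank.
    """
    if read_call.read_class not in (CLASS_SIMPLE, CLASS_COINTEGRATE):
        return None
    for fc in read_call.flank_calls:
        if fc.label != LABEL_GENOMIC:
            continue
        if convention == "flank_start":
            coord = fc.best_position
        else:
            f = len(fc.flank.sequence)
            i = f - 1 if fc.flank.side == "left" else 0
            coord = fc.best_position + (i if fc.best_strand == "+" else f - 1 - i)
        if circular and genome_length:
            coord %= genome_length
        return coord
    return None


def is_on_target(
    coordinate: int,
    target: TargetSite,
    window: int = DEFAULT_WINDOW,
    genome_length: int | None = None,
    circular: bool = True,
) -> bool:
    """Inclusive symmetric window test around the expected insertion point."""
    if window <= 0:
        raise ValueError("window must be > 0")
    center = target.center()
    delta = abs(coordinate - center)
    if circular and genome_length:
        delta = min(delta, genome_length - delta)
    return delta <= window / 2


def bin_insertions(
    coordinates, genome_length: int, bin_size: int = DEFAULT_BIN_SIZE
) -> np.ndarray:
    """Counts per fixed-size bin; bin index = coordinate // bin_size."""
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    n_bins = -(-genome_length // bin_size)  # ceil
    coords = np.asarray(list(coordinates), dtype=np.int64)
    if coords.size == 0:
        return np.zeros(n_bins, dtype=np.int64)
    if coords.min() < 0 or coords.max() >= genome_length:
        raise ValueError("coordinate outside the genome")
    return np.bincount(coords // bin_size, minlength=n_bins).astype(np.int64)


def make_events(
    read_calls: list[ReadCall],
    targets: list[TargetSite],
    genome_length: int,
    window: int = DEFAULT_WINDOW,
    circular: bool = True,
    convention: str = "junction",
) -> list[InsertionEvent]:
    """Insertion events for all scoreable reads (simple + cointegrate)."""
    events = []
    for rc in read_calls:
        coord = insertion_coordinate(rc, genome_length, circular, convention)
        if coord is None:
            continue
        on = any(is_on_target(coord, t, window, genome_length, circular) for t in targets)
        events.append(InsertionEvent(rc.read_id, rc.read_class, coord, on))
    return events


@dataclass
class SummaryReport:
    """Population-level run summary.

    ``fraction_simple`` / ``fraction_cointegrate`` are over transposition
    products (simple + cointegrate).  ``fraction_on_target`` is over
    insertion events; ``fraction_on_target_of_transposon_reads`` uses all
    transposon-containing reads as the denominator, since the headline
    specificity figure can be quoted either way.  Fractions are None (not
    zero) when their denominator is empty.
    """

    n_reads_total: int
    n_transposon_reads: int
    n_plasmid: int
    n_simple: int
    n_cointegrate: int
    n_removed: int
    removal_breakdown: dict[str, int]
    fraction_simple: float | None
    fraction_cointegrate: float | None
    n_events: int
    n_on_target: int
    fraction_on_target: float | None
    fraction_on_target_of_transposon_reads: float | None
    histogram: np.ndarray = field(repr=False)
    bin_size: int = DEFAULT_BIN_SIZE

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "n_reads_total", "n_transposon_reads", "n_plasmid", "n_simple",
            "n_cointegrate", "n_removed", "fraction_simple", "fraction_cointegrate",
            "n_events", "n_on_target", "fraction_on_target",
            "fraction_on_target_of_transposon_reads",
        )}
        d.update({f"n_removed_{k}": v for k, v in self.removal_breakdown.items()})
        return d


def summarize(
    read_calls: list[ReadCall],
    events: list[InsertionEvent],
    genome_length: int,
    n_reads_total: int | None = None,
    bin_size: int = DEFAULT_BIN_SIZE,
) -> SummaryReport:
    from .read_classifier import CLASS_PLASMID, CLASS_REMOVED, REMOVAL_REASONS

    n_plasmid = sum(rc.read_class == CLASS_PLASMID for rc in read_calls)
    n_simple = sum(rc.read_class == CLASS_SIMPLE for rc in read_calls)
    n_coint = sum(rc.read_class == CLASS_COINTEGRATE for rc in read_calls)
    n_removed = sum(rc.read_class == CLASS_REMOVED for rc in read_calls)
    breakdown = {r: 0 for r in REMOVAL_REASONS}
    for rc in read_calls:
        if rc.removal_reason is not None:
            breakdown[rc.removal_reason] += 1
    from .read_classifier import REASON_NO_HIT

    # reads without any retained hit are not transposon-containing
    n_tn = len(read_calls) - breakdown[REASON_NO_HIT]
    n_products = n_simple + n_coint
    n_on = sum(e.on_target for e in events)
    hist = bin_insertions([e.genome_coordinate for e in events], genome_length, bin_size)
    return SummaryReport(
        n_reads_total=n_reads_total if n_reads_total is not None else n_tn,
        n_transposon_reads=n_tn,
        n_plasmid=n_plasmid,
        n_simple=n_simple,
        n_cointegrate=n_coint,
        n_removed=n_removed,
        removal_breakdown=breakdown,
        fraction_simple=n_simple / n_products if n_products else None,
        fraction_cointegrate=n_coint / n_products if n_products else None,
        n_events=len(events),
        n_on_target=n_on,
        fraction_on_target=n_on / len(events) if events else None,
        fraction_on_target_of_transposon_reads=n_on / n_tn if n_tn else None,
        histogram=hist,
        bin_size=bin_size,
    )
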