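"""Per-read product calls from classified flanks.

The published three-way rule: a read whose surviving flanks are all
plasmid-derived is a plasmid read; all genomic — a simple insertion; a
mixture — a cointegrate.  Any unclassified flank removes the read.  Two
QC checks run alongside: cointegrate geometry (the gap between
consecutive mini-Tn hits must equal the donor backbone length, the
signature of a full plasmid integrated between duplicated mini-Tn
copies) and tandem-insertion detection (hits within a few bp of each
other).  Both are reported flags, not reclassification gates, mirroring
the post-hoc inspection in the original analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .flank_mapper import LABEL_GENOMIC, LABEL_PLASMID, LABEL_UNCLASSIFIED, FlankCall
from .tn_finder import MiniTnHit

CLASS_PLASMID = "plasmid"
CLASS_SIMPLE = "simple_insertion"
CLASS_COINTEGRATE = "cointegrate"
CLASS_REMOVED = "removed"

REASON_NO_HIT = "no_valid_hit"
REASON_NO_FLANKS = "no_valid_flanks"
REASON_UNCLASSIFIED = "unclassified_flank"
REASON_TIE = "ambiguous_tie"

REMOVAL_REASONS = (REASON_NO_HIT, REASON_NO_FLANKS, REASON_UNCLASSIFIED, REASON_TIE)

DEFAULT_TANDEM_PROXIMITY = 10
DEFAULT_BACKBONE_TOLERANCE = 10


@dataclass
class ReadCall:
    read_id: str
    read_class: str
    removal_reason: str | None
    hits: list[MiniTnHit] = field(default_factory=list)
    flank_calls: list[FlankCall] = field(default_factory=list)
    inter_hit_distances: list[int] = field(default_factory=list)
    tandem: bool = False
    backbone_validated: bool | None = None

    def __post_init__(self) -> None:
        if (self.read_class == CLASS_REMOVED) != (self.removal_reason is not None):
            raise ValueError("removal_reason must be set exactly for removed reads")


def classify_read(flank_calls: list[FlankCall]) -> tuple[str, str | None]:
    """Three-way rule on surviving flank labels; (class, removal_reason)."""
    if not flank_calls:
        return CLASS_REMOVED, REASON_NO_FLANKS
    labels = [fc.label for fc in flank_calls]
    for fc in flank_calls:
        if fc.label == LABEL_UNCLASSIFIED:
            return CLASS_REMOVED, REASON_TIE if fc.tie else REASON_UNCLASSIFIED
    if all(lab == LABEL_GENOMIC for lab in labels):
        return CLASS_SIMPLE, None
    if all(lab == LABEL_PLASMID for lab in labels):
        return CLASS_PLASMID, None
    return CLASS_COINTEGRATE, None


def inter_hit_gaps(hits: list[MiniTnHit]) -> list[int]:
    """Gaps (start of next minus end of previous) between consecutive hits."""
    hits = sorted(hits, key=lambda h: h.start)
    return [b.start - a.end for a, b in zip(hits, hits[1:])]


def validate_cointegrate(
    hits: list[MiniTnHit],
    backbone_length: int,
    tolerance: int = DEFAULT_BACKBONE_TOLERANCE,
) -> bool | None:
    """True iff every inter-hit gap equals the backbone length within the
    tolerance; None when fewer than two hits (not applicable)."""
    gaps = inter_hit_gaps(hits)
    if not gaps:
        return None
    return all(abs(g - backbone_length) <= tolerance for g in gaps)


def detect_tandem(
    hits: list[MiniTnHit], proximity: int = DEFAULT_TANDEM_PROXIMITY
) -> bool:
    """True iff any two consecutive hits sit within ``proximity`` bp."""
    return any(g <= proximity for g in inter_hit_gaps(hits))


def build_read_call(
    read_id: str,
    hits: list[MiniTnHit],
    flank_calls: list[FlankCall],
    backbone_length: int,
    tandem_proximity: int = DEFAULT_TANDEM_PROXIMITY,
    backbone_tolerance: int = DEFAULT_BACKBONE_TOLERANCE,
) -> ReadCall:
    """Assemble the full per-read record, including the QC flags."""
    if not hits:
        return ReadCall(read_id, CLASS_REMOVED, REASON_NO_HIT)
    read_class, reason = classify_read(flank_calls)
    gaps = inter_hit_gaps(hits)
    backbone_ok = None
    if read_class == CLASS_COINTEGRATE:
        backbone_ok = validate_cointegrate(hits, backbone_length, backbone_tolerance)
    return ReadCall(
        read_id=read_id,
        read_class=read_class,
        removal_reason=reason,
        hits=sorted(hits, key=lambda h: h.start),
        flank_calls=flank_calls,
        inter_hit_distances=gaps,
        tandem=detect_tandem(hits, tandem_proximity),
        backbone_validated=backbone_ok,
    )
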