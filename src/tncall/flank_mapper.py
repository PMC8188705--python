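"""Extract and classify the 50-bp flanks of each mini-Tn hit.

Each retained hit contributes a left and a right flank: the 50 bases of
the read immediately adjacent to the hit interval.  A window truncated by
the read edge or by an adjacent hit is discarded, never padded.  Every
flank is then classified as genome-derived or plasmid-derived by minimum
Hamming distance over all ungapped placements of the flank and its
reverse complement against the full genome and the full donor plasmid
(wrap-around placements included for circular references), with a maximum
allowed distance of 2.  Distance ties between the two references are
deliberately left unclassified: ambiguity must not silently inflate
either product class.

The search is exact but fast: by the pigeonhole principle a 50-bp query
within Hamming distance 2 of a placement must share one of three ~17-bp
chunks with the reference at the matching offset, so a k-mer index over
the reference enumerates every placement at distance <= 2.  Distances
above the maximum are reported as ``max_hamming + 1`` without an exact
value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import revcomp
from .references import ReferenceSet
from .tn_finder import MiniTnHit

DEFAULT_FLANK_LENGTH = 50
DEFAULT_MAX_HAMMING = 2

LABEL_GENOMIC = "genomic"
LABEL_PLASMID = "plasmid"
LABEL_UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class Flank:
    read_id: str
    hit_rank: int
    side: str  # "left" | "right", in read 5'->3' frame
    sequence: str


@dataclass(frozen=True)
class FlankCall:
    flank: Flank
    label: str
    best_position: int | None  # leftmost base of the placement, + strand frame
    best_strand: str | None
    min_distance_genome: int  # clipped at max_hamming + 1
    min_distance_plasmid: int
    tie: bool = False  # equal distances <= max_hamming on both references


def extract_flanks(
    read_id: str,
    read_seq: str,
    hits: list[MiniTnHit],
    flank_length: int = DEFAULT_FLANK_LENGTH,
) -> list[Flank]:
    """Full-length flanking windows for each hit, 5'->3', left then right."""
    hits = sorted(hits, key=lambda h: h.start)
    flanks: list[Flank] = []
    for i, h in enumerate(hits):
        rank = h.rank if h.rank is not None else i + 1
        lo = hits[i - 1].end if i > 0 else 0
        hi = hits[i + 1].start if i + 1 < len(hits) else len(read_seq)
        ls = h.start - flank_length
        if ls >= lo and ls >= 0:
            flanks.append(Flank(read_id, rank, "left", read_seq[ls : h.start]))
        re_ = h.end + flank_length
        if re_ <= hi and re_ <= len(read_seq):
            flanks.append(Flank(read_id, rank, "right", read_seq[h.end : re_]))
    return flanks


class HammingIndex:
    """Pigeonhole k-mer index for exhaustive ungapped matching.

    Finds every placement of a fixed-length query (and its reverse
    complement) within ``max_distance`` mismatches of the reference,
    including origin-wrapping placements when the reference is circular.
    """

    def __init__(
        self,
        reference: str,
        circular: bool = True,
        query_length: int = DEFAULT_FLANK_LENGTH,
        max_distance: int = DEFAULT_MAX_HAMMING,
    ) -> None:
        if query_length > len(reference):
            raise ValueError("query_length exceeds reference length")
        self.n = len(reference)
        self.query_length = query_length
        self.max_distance = max_distance
        self.circular = circular
        ext = reference + reference[: query_length - 1] if circular else reference
        self._ext = ext
        self._ext_arr = np.frombuffer(ext.encode("ascii"), dtype=np.uint8)
        # split the query into max_distance + 1 chunks: at distance <= d,
        # at least one chunk matches the reference exactly at its offset
        n_chunks = max_distance + 1
        base, rem = divmod(query_length, n_chunks)
        self._chunks: list[tuple[int, int]] = []
        off = 0
        for i in range(n_chunks):
            ln = base + (1 if i < rem else 0)
            self._chunks.append((off, ln))
            off += ln
        self._tables: list[dict[str, list[int]]] = []
        for off, ln in self._chunks:
            table: dict[str, list[int]] = {}
            for p in range(len(ext) - ln + 1):
                table.setdefault(ext[p : p + ln], []).append(p)
            self._tables.append(table)

    def _scan_strand(self, query: str) -> tuple[int, list[int]]:
        q = np.frombuffer(query.encode("ascii"), dtype=np.uint8)
        limit = len(self._ext) - self.query_length
        candidates: set[int] = set()
        for (off, ln), table in zip(self._chunks, self._tables):
            for p in table.get(query[off : off + ln], ()):
                c = p - off
                if 0 <= c <= limit:
                    candidates.add(c)
        best = self.max_distance + 1
        argmin: list[int] = []
        for c in candidates:
            d = int((self._ext_arr[c : c + self.query_length] != q).sum())
            if d < best:
                best, argmin = d, [c]
            elif d == best:
                argmin.append(c)
        return best, sorted(argmin)

    def search(self, query: str) -> tuple[int, list[int], str | None]:
        """(min_distance, argmin positions, strand) for the query.

        ``min_distance`` is clipped to ``max_distance + 1``. Positions are
        leftmost placement bases on the + strand of the reference, already
        reduced modulo the reference length. On a cross-strand distance
        tie the + strand is reported.
        """
        if len(query) != self.query_length:
            raise ValueError("query length does not match index")
        d_plus, pos_plus = self._scan_strand(query)
        d_minus, pos_minus = self._scan_strand(revcomp(query))
        if d_plus <= d_minus:
            d, pos, strand = d_plus, pos_plus, "+"
        else:
            d, pos, strand = d_minus, pos_minus, "-"
        if d > self.max_distance:
            return self.max_distance + 1, [], None
        return d, pos, strand


def hamming_best_match(
    query: str,
    reference: str,
    circular: bool = True,
    max_distance: int = DEFAULT_MAX_HAMMING,
) -> tuple[int, list[int], str | None]:
    """One-shot exhaustive Hamming search (builds a transient index)."""
    idx = HammingIndex(reference, circular, len(query), max_distance)
    return idx.search(query)


class FlankClassifier:
    """Classifies flanks against a fixed reference pair, reusing indices."""

    def __init__(
        self,
        refs: ReferenceSet,
        max_hamming: int = DEFAULT_MAX_HAMMING,
        flank_length: int = DEFAULT_FLANK_LENGTH,
    ) -> None:
        self.max_hamming = max_hamming
        self.genome_index = HammingIndex(
            refs.genome_seq, refs.genome_circular, flank_length, max_hamming
        )
        self.plasmid_index = HammingIndex(
            refs.plasmid_seq, refs.plasmid_circular, flank_length, max_hamming
        )

    def classify(self, flank: Flank) -> FlankCall:
        dg, pos_g, strand_g = self.genome_index.search(flank.sequence)
        dp, pos_p, strand_p = self.plasmid_index.search(flank.sequence)
        m = self.max_hamming
        if dg <= m and dg < dp:
            return FlankCall(flank, LABEL_GENOMIC, pos_g[0], strand_g, dg, dp)
        if dp <= m and dp < dg:
            return FlankCall(flank, LABEL_PLASMID, pos_p[0], strand_p, dg, dp)
        tie = dg == dp and dg <= m
        return FlankCall(flank, LABEL_UNCLASSIFIED, None, None, dg, dp, tie=tie)


def classify_flank(
    flank: Flank, refs: ReferenceSet, max_hamming: int = DEFAULT_MAX_HAMMING
) -> FlankCall:
    """Spec-level convenience wrapper; builds indices per call.

    Use :class:`FlankClassifier` when classifying many flanks against the
    same references.
    """
    return FlankClassifier(refs, max_hamming, len(flank.sequence)).classify(flank)
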