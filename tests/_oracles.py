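"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations, kept free of any code path they
check: exhaustive Hamming scans over every placement and both strands,
and a from-scratch flank labelling rule.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_hamming_scan(query: str, reference: str, circular: bool = True):
    """(min_distance, argmin positions, strand) over all ungapped placements.

    Positions are leftmost placement bases on the + strand of the
    reference, modulo its length; on a cross-strand tie '+' wins.
    """
    q = len(query)
    ext = reference + reference[: q - 1] if circular and len(reference) >= q else reference
    ext_a = np.frombuffer(ext.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(ext_a, q)
    best = (q + 1, [], None)
    for strand, qs in (("+", query), ("-", rc(query))):
        qa = np.frombuffer(qs.encode(), dtype=np.uint8)
        dists = (windows != qa).sum(axis=1)
        d = int(dists.min())
        pos = sorted(int(p) % len(reference) for p in np.nonzero(dists == d)[0])
        if d < best[0]:
            best = (d, pos, strand)
    return best


def brute_flank_label(query: str, genome: str, plasmid: str, max_hamming: int = 2,
                      genome_circular: bool = True, plasmid_circular: bool = True):
    """Label + clipped distances + winning argmin positions, from scratch."""
    dg, pg, sg = brute_hamming_scan(query, genome, genome_circular)
    dp, pp, sp = brute_hamming_scan(query, plasmid, plasmid_circular)
    cg = min(dg, max_hamming + 1)
    cp = min(dp, max_hamming + 1)
    if cg <= max_hamming and cg < cp:
        return "genomic", cg, cp, pg, sg
    if cp <= max_hamming and cp < cg:
        return "plasmid", cg, cp, pp, sp
    return "unclassified", cg, cp, [], None


def shared_kmers(a: str, b: str, k: int, circular_a: bool = False, circular_b: bool = False):
    def kmers(s, circ):
        s2 = s + s[: k - 1] if circ and len(s) >= k else s
        return {s2[i : i + k] for i in range(len(s2) - k + 1)}

    return kmers(a, circular_a) & kmers(b, circular_b)
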