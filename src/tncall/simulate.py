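"""Synthetic CCS-like reads with a per-read ground-truth manifest.

The generator emulates demultiplexed, high-accuracy (>Q20) long reads
drawn from a pooled population of cells in which RNA-guided transposition
has produced a mixture of products:

* ``simple_insertion``       — mini-Tn at the target site with a 5-bp TSD;
* ``off_target_simple``      — the same structure at a random genomic site;
* ``cointegrate``            — full donor plasmid integrated at the target
  site, mini-Tn duplicated on both sides of the backbone;
* ``concatemer_cointegrate`` — cointegrate from a multimeric donor;
* ``plasmid``                — reads of free (multimeric) donor plasmid.

Each read carries a :class:`GroundTruthRecord` so every downstream stage
can be checked by parameter recovery.  ``true_insertion_site`` records the
genomic junction coordinate (the genomic base adjacent to the mini-Tn) of
the first genome-derived flank in read orientation — the quantity the
site-calling stage reports — and is null for plasmid reads.  The manifest
also records the read-frame intervals of every fully contained mini-Tn
copy, which is the oracle for the hit finder.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from numpy.random import default_rng

from ._util import random_dna, revcomp
from .references import (
    ORIENT_T_LR,
    ORIENT_T_RL,
    ReferenceSet,
    cointegrate_insert_length,
    make_cointegrate_allele,
    make_simple_insertion_allele,
    mini_tn_offsets,
)

CLASS_NAMES = (
    "simple_insertion",
    "cointegrate",
    "plasmid",
    "off_target_simple",
    "concatemer_cointegrate",
)

MANIFEST_COLUMNS = [
    "read_id",
    "true_class",
    "true_insertion_site",
    "on_target",
    "orientation",
    "read_strand",
    "tn_read_intervals",
]


@dataclass
class SyntheticConfig:
    """Study conditions for one simulated sequencing run.

    Defaults are a desk-scale rendering of the real experiment: a ~1-kb
    mini-Tn on a donor plasmid, reads averaging ~10 kb, CCS-grade error
    rates, and integration expected 49 bp downstream of the protospacer
    3' end.  The genome is shrunk to 100 kb so that whole runs complete
    in seconds while every decision rule is still exercised.
    """

    genome_length: int = 100_000
    plasmid_backbone_length: int = 3_000
    mini_tn_length: int = 1_000
    tsd_length: int = 5
    target_site_position: int = 50_000  # protospacer 3' end, 0-based
    offset_x: int = 49
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "simple_insertion": 0.6,
            "cointegrate": 0.3,
            "plasmid": 0.1,
        }
    )
    orientation_bias: float = 0.5  # fraction of T-RL among insertions
    read_length_mean: int = 10_000
    read_length_sd: float = 500.0
    substitution_rate: float = 0.001
    indel_rate: float = 0.0005
    n_reads: int = 500
    seed: int = 0
    # fraction of non-plasmid reads placed to span a mini-Tn with full flanks
    span_fraction: float = 0.9
    background_genomic: float = 0.0  # fraction of transposon-free genomic reads
    concatemer_units: int = 2  # plasmid units per concatemer cointegrate
    flank_length: int = 50

    def __post_init__(self) -> None:
        for name in self.class_proportions:
            if name not in CLASS_NAMES:
                raise ValueError(f"unknown class {name!r}")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_proportions sum to {total}, expected 1")
        if any(p < 0 for p in self.class_proportions.values()):
            raise ValueError("class_proportions must be non-negative")
        if self.tsd_length < 0:
            raise ValueError("tsd_length must be >= 0")
        for name in ("genome_length", "plasmid_backbone_length", "mini_tn_length", "read_length_mean", "n_reads"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("substitution_rate", "indel_rate", "span_fraction", "orientation_bias", "background_genomic"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.mini_tn_length + 2 * self.flank_length > self.read_length_mean:
            raise ValueError("reads too short to span a mini-Tn with full flanks")

    def proportions(self) -> tuple[list[str], list[float]]:
        names = [n for n in CLASS_NAMES if self.class_proportions.get(n, 0.0) > 0]
        probs = [self.class_proportions[n] for n in names]
        if self.background_genomic > 0:
            scale = 1.0 - self.background_genomic
            probs = [p * scale for p in probs]
            names.append("genomic_background")
            probs.append(self.background_genomic)
        return names, probs


@dataclass(frozen=True)
class GroundTruthRecord:
    read_id: str
    true_class: str
    true_insertion_site: int | None
    on_target: bool
    orientation: str | None
    read_strand: str
    tn_read_intervals: str  # "start-end:strand;..." of fully contained copies

    def __post_init__(self) -> None:
        if (self.true_insertion_site is None) != (
            self.true_class in ("plasmid", "genomic_background")
        ):
            raise ValueError("true_insertion_site must be null exactly for plasmid reads")


def apply_errors(seq: str, rng: np.random.Generator, substitution_rate: float, indel_rate: float) -> str:
    """i.i.d. per-base substitutions and single-base indels.

    An indel event is a deletion or an insertion (of one random base after
    the position) with equal probability. No homopolymer-aware model.
    """
    if substitution_rate <= 0 and indel_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    n = arr.size
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    sub_pos = np.nonzero(rng.random(n) < substitution_rate)[0]
    for p in sub_pos:
        choices = bases[bases != arr[p]]
        arr[p] = choices[rng.integers(0, len(choices))]
    out = arr
    indel_pos = np.nonzero(rng.random(n) < indel_rate)[0]
    if indel_pos.size:
        pieces: list[np.ndarray] = []
        prev = 0
        for p in indel_pos:
            if rng.random() < 0.5:  # deletion
                pieces.append(out[prev:p])
                prev = p + 1
            else:  # insertion after p
                pieces.append(out[prev : p + 1])
                pieces.append(bases[[rng.integers(0, 4)]])
                prev = p + 1
        pieces.append(out[prev:])
        out = np.concatenate(pieces)
    return out.tobytes().decode("ascii")


def _format_intervals(copies: list[tuple[int, int, str]]) -> str:
    return ";".join(f"{s}-{e}:{st}" for s, e, st in copies)


def _read_frame_copies(
    copies_src: list[tuple[int, int, str]], a: int, b: int, strand: str,
    clip_tolerance: int = 5,
) -> list[tuple[int, int, str]]:
    """Map source-frame mini-Tn intervals into read coordinates.

    Copies contained in the window [a, b) are kept, including copies
    clipped by up to ``clip_tolerance`` bases at a window edge — those
    still pass the downstream full-length hit filter, so they are part of
    the ground truth (with clipped coordinates).  A minus-strand read
    flips coordinates and copy strands.
    """
    out = []
    length = b - a
    for s, e, st in copies_src:
        cs, ce = max(s, a), min(e, b)
        if ce - cs >= (e - s) - clip_tolerance:
            ws, we = cs - a, ce - a
            if strand == "-":
                ws, we = length - we, length - ws
                st = "+" if st == "-" else "-"
            out.append((ws, we, st))
    out.sort()
    return out


def _draw_length(cfg: SyntheticConfig, rng: np.random.Generator, max_len: int) -> int:
    length = int(round(rng.normal(cfg.read_length_mean, cfg.read_length_sd)))
    length = max(length, cfg.mini_tn_length + 2 * cfg.flank_length)
    return min(length, max_len)


def _sample_offtarget_site(cfg: SyntheticConfig, rng: np.random.Generator, center: int) -> int:
    """Uniform genomic site outside the on-target neighbourhood and away
    from the genome edges (alleles are built on the linearized genome)."""
    margin = int(cfg.read_length_mean + 5 * cfg.read_length_sd)
    lo, hi = margin, cfg.genome_length - margin
    if hi <= lo:
        raise ValueError("genome too small for off-target site sampling")
    exclusion = 100 + cfg.tsd_length
    while True:
        site = int(rng.integers(lo, hi))
        if abs(site - center) > exclusion:
            return site


def generate_reads(
    config: SyntheticConfig, refs: ReferenceSet
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Draw ``n_reads`` reads and their ground-truth manifest.

    Placement rule: with probability ``span_fraction`` a non-plasmid read
    is positioned to span the whole insert (or, if the read is too short,
    one randomly chosen mini-Tn copy) with at least ``flank_length`` bases
    on both sides; otherwise the window is uniform over the allele,
    producing edge cases with truncated flanks.  Plasmid reads are drawn
    from a tandemly tiled (multimeric) plasmid at a uniform phase.
    Deterministic under a fixed seed.
    """
    rng = default_rng([int(config.seed), 1])
    names, probs = config.proportions()
    target = refs.target_sites[0]
    center = target.center()
    f = config.flank_length
    tsd = config.tsd_length

    records: list[SeqRecord] = []
    rows: list[GroundTruthRecord] = []

    for i in range(config.n_reads):
        read_id = f"sr{i:06d}"
        cls = names[int(rng.choice(len(names), p=probs))]
        strand = "+" if rng.random() < 0.5 else "-"

        if cls == "plasmid":
            seq, copies = _plasmid_window(config, refs, rng, strand)
            rows.append(
                GroundTruthRecord(read_id, cls, None, False, None, strand, _format_intervals(copies))
            )
        elif cls == "genomic_background":
            g = refs.genome_seq
            length = _draw_length(config, rng, len(g))
            a = int(rng.integers(0, len(g) - length + 1))
            window = g[a : a + length]
            seq = window if strand == "+" else revcomp(window)
            rows.append(GroundTruthRecord(read_id, cls, None, False, None, strand, ""))
        else:
            on_target = cls in ("simple_insertion", "cointegrate", "concatemer_cointegrate")
            site = center if on_target else _sample_offtarget_site(config, rng, center)
            orientation = ORIENT_T_RL if rng.random() < config.orientation_bias else ORIENT_T_LR
            if cls in ("simple_insertion", "off_target_simple"):
                allele = make_simple_insertion_allele(refs, site, orientation, tsd)
                offsets = [0]
                ins_len = refs.mini_tn_length
            else:
                n_units = 1 if cls == "cointegrate" else config.concatemer_units
                allele = make_cointegrate_allele(refs, site, tsd, n_units, orientation)
                offsets = mini_tn_offsets(refs, n_units)
                ins_len = cointegrate_insert_length(refs, n_units)
            copies_src = [
                (site + off, site + off + refs.mini_tn_length, "+" if orientation == ORIENT_T_RL else "-")
                for off in offsets
            ]
            length = _draw_length(config, rng, len(allele))
            a = _place_window(config, rng, len(allele), site, ins_len, copies_src, length)
            b = a + length
            window = allele[a:b]
            seq = window if strand == "+" else revcomp(window)
            truth_site = _truth_junction(site, ins_len, refs.mini_tn_length, tsd, f, a, b, strand)
            copies = _read_frame_copies(copies_src, a, b, strand)
            rows.append(
                GroundTruthRecord(
                    read_id, cls, truth_site, on_target, orientation, strand, _format_intervals(copies)
                )
            )

        seq = apply_errors(seq, rng, config.substitution_rate, config.indel_rate)
        rec = SeqRecord(Seq(seq), id=read_id, description="")
        rec.letter_annotations["phred_quality"] = [30] * len(seq)
        records.append(rec)

    manifest = pd.DataFrame(
        [
            {
                "read_id": r.read_id,
                "true_class": r.true_class,
                "true_insertion_site": r.true_insertion_site,
                "on_target": r.on_target,
                "orientation": r.orientation,
                "read_strand": r.read_strand,
                "tn_read_intervals": r.tn_read_intervals,
            }
            for r in rows
        ],
        columns=MANIFEST_COLUMNS,
    )
    manifest["true_insertion_site"] = manifest["true_insertion_site"].astype("Int64")
    return records, manifest


def _plasmid_window(
    config: SyntheticConfig, refs: ReferenceSet, rng: np.random.Generator, strand: str
) -> tuple[str, list[tuple[int, int, str]]]:
    plen = len(refs.plasmid_seq)
    length = max(
        config.mini_tn_length + 2 * config.flank_length,
        min(
            int(round(rng.normal(config.read_length_mean, config.read_length_sd))),
            plen * 50,
        ),
    )
    tiles = refs.plasmid_seq * (length // plen + 2)
    phase = int(rng.integers(0, plen))
    window = tiles[phase : phase + length]
    tn_s, tn_e = refs.mini_tn_interval
    copies_src = []
    j = 0
    while tn_s + j * plen < phase + length:
        copies_src.append((tn_s + j * plen, tn_e + j * plen, "+"))
        j += 1
    copies = _read_frame_copies(copies_src, phase, phase + length, strand)
    seq = window if strand == "+" else revcomp(window)
    return seq, copies


def _place_window(
    config: SyntheticConfig,
    rng: np.random.Generator,
    allele_len: int,
    site: int,
    ins_len: int,
    copies_src: list[tuple[int, int, str]],
    length: int,
) -> int:
    f = config.flank_length
    if rng.random() < config.span_fraction:
        lo = max(0, site + ins_len + f - length)
        hi = min(site - f, allele_len - length)
        if length >= ins_len + 2 * f and lo <= hi:
            return int(rng.integers(lo, hi + 1))
        # read too short for the whole insert: span one mini-Tn copy
        cs, ce, _ = copies_src[int(rng.integers(0, len(copies_src)))]
        lo = max(0, ce + f - length)
        hi = min(cs - f, allele_len - length)
        if lo <= hi:
            return int(rng.integers(lo, hi + 1))
    return int(rng.integers(0, allele_len - length + 1))


def _truth_junction(
    site: int, ins_len: int, tn_len: int, tsd: int, flank: int, a: int, b: int, strand: str
) -> int:
    """Junction coordinate the classifier should report for this read.

    The left genomic junction base is ``site - 1`` and the right one is
    ``site - tsd`` (the TSD makes them differ).  A junction counts as
    recoverable when the window covers its 50-bp genomic flank and the
    adjacent mini-Tn copy in full; the first recoverable junction in read
    orientation is recorded.  Falls back to the left junction when the
    window covers neither (such reads are not scored downstream).
    """
    left_ok = a <= site - flank and b >= site + tn_len
    right_ok = b >= site + ins_len + flank and a <= site + ins_len - tn_len
    order = [("L", left_ok), ("R", right_ok)]
    if strand == "-":
        order.reverse()
    for side, ok in order:
        if ok:
            return site - 1 if side == "L" else site - tsd
    return site - 1


# ---------------------------------------------------------------------------
# on-disk formats


def write_reads_fastq(records: Iterable[SeqRecord], path) -> None:
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")


def write_reads_fasta(records: Iterable[SeqRecord], path) -> None:
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta-2line")


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    df["true_insertion_site"] = df["true_insertion_site"].astype("Int64")
    df["on_target"] = df["on_target"].astype(bool)
    df["tn_read_intervals"] = df["tn_read_intervals"].fillna("")
    return df


def manifest_to_string(manifest: pd.DataFrame) -> str:
    buf = io.StringIO()
    manifest.to_csv(buf, sep="\t", index=False, na_rep="NA")
    return buf.getvalue()
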