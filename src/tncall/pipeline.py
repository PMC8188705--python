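"""End-to-end orchestration: simulate, classify, report.

``classify_reads`` is the in-memory pipeline (hit finding -> flank
extraction -> flank classification -> read calls -> insertion events ->
summary); ``run_classify`` wraps it with file I/O and writes TSV/BED
tables plus a machine-readable run manifest.  Every run asserts the
attrition invariant: input reads = removed (per reason) + plasmid +
simple + cointegrate.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .flank_mapper import FlankClassifier, extract_flanks
from .read_classifier import ReadCall, build_read_call
from .references import ReferenceSet, TargetSite, generate_references
from .simulate import SyntheticConfig, generate_reads, write_manifest, write_reads_fastq
from .site_analysis import (
    InsertionEvent,
    SummaryReport,
    make_events,
    summarize,
)
from .tn_finder import filter_hits, find_hits

logger = logging.getLogger(__name__)


@dataclass
class RunParams:
    """Tunables of the classification pipeline (published defaults)."""

    flank_length: int = 50
    max_hamming: int = 2
    length_tolerance: int = 5
    max_evalue: float = 1e-6
    window: int = 100
    bin_size: int = 5000
    tandem_proximity: int = 10
    backbone_tolerance: int = 10
    coordinate_convention: str = "junction"  # or "flank_start"

    def __post_init__(self) -> None:
        for name in ("flank_length", "window", "bin_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("max_hamming", "length_tolerance", "tandem_proximity", "backbone_tolerance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ClassifyResult:
    read_calls: list[ReadCall]
    events: list[InsertionEvent]
    summary: SummaryReport
    n_reads_total: int


def classify_reads(
    reads,
    refs: ReferenceSet,
    params: RunParams | None = None,
) -> ClassifyResult:
    """Classify an iterable of ``(read_id, sequence)`` pairs.

    Returns per-read calls for every input read (reads without a retained
    mini-Tn hit are recorded as removed), insertion events, and the
    population summary.
    """
    params = params or RunParams()
    mini_tn = refs.mini_tn_seq
    classifier = FlankClassifier(refs, params.max_hamming, params.flank_length)
    calls: list[ReadCall] = []
    n_total = 0
    for read_id, seq in reads:
        n_total += 1
        hits = filter_hits(
            find_hits(read_id, seq, mini_tn),
            refs.mini_tn_length,
            params.max_evalue,
            params.length_tolerance,
        )
        flanks = extract_flanks(read_id, seq, hits, params.flank_length)
        flank_calls = [classifier.classify(fl) for fl in flanks]
        calls.append(
            build_read_call(
                read_id,
                hits,
                flank_calls,
                refs.backbone_length,
                params.tandem_proximity,
                params.backbone_tolerance,
            )
        )
    events = make_events(
        calls,
        refs.target_sites,
        len(refs.genome_seq),
        params.window,
        refs.genome_circular,
        params.coordinate_convention,
    )
    summary = summarize(calls, events, len(refs.genome_seq), n_total, params.bin_size)
    _assert_attrition(summary)
    logger.info(
        "classified %d reads: %d simple, %d cointegrate, %d plasmid, %d removed",
        n_total, summary.n_simple, summary.n_cointegrate, summary.n_plasmid, summary.n_removed,
    )
    return ClassifyResult(calls, events, summary, n_total)


def _assert_attrition(s: SummaryReport) -> None:
    total = s.n_plasmid + s.n_simple + s.n_cointegrate + s.n_removed
    if total != s.n_reads_total:
        raise AssertionError(
            f"attrition not conserved: {total} classified+removed vs {s.n_reads_total} input reads"
        )


# ---------------------------------------------------------------------------
# file-level entry points


def run_simulate(config: SyntheticConfig, outdir) -> dict[str, Path]:
    """Generate references + reads and write the simulation bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    refs = generate_references(config)
    records, manifest = generate_reads(config, refs)
    paths = {
        "genome": outdir / "genome.fasta",
        "plasmid": outdir / "plasmid.fasta",
        "reads": outdir / "reads.fastq",
        "truth": outdir / "truth.tsv",
        "references": outdir / "references.yml",
        "config": outdir / "sim_config.yml",
    }
    _write_fasta(paths["genome"], "genome", refs.genome_seq)
    _write_fasta(paths["plasmid"], "plasmid", refs.plasmid_seq)
    write_reads_fastq(records, paths["reads"])
    write_manifest(manifest, paths["truth"])
    with open(paths["references"], "w") as fh:
        yaml.safe_dump(references_metadata(refs), fh, sort_keys=True)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
    logger.info("simulated %d reads into %s", config.n_reads, outdir)
    return paths


def references_metadata(refs: ReferenceSet) -> dict:
    return {
        "mini_tn_interval": list(refs.mini_tn_interval),
        "genome_circular": refs.genome_circular,
        "plasmid_circular": refs.plasmid_circular,
        "targets": [
            {"position": t.position, "strand": t.strand, "offset_x": t.offset_x}
            for t in refs.target_sites
        ],
    }


def load_references(genome_fasta, plasmid_fasta, references_yml) -> ReferenceSet:
    genome = str(next(SeqIO.parse(str(genome_fasta), "fasta")).seq)
    plasmid = str(next(SeqIO.parse(str(plasmid_fasta), "fasta")).seq)
    with open(references_yml) as fh:
        meta = yaml.safe_load(fh)
    return ReferenceSet(
        genome_seq=genome,
        plasmid_seq=plasmid,
        mini_tn_interval=tuple(meta["mini_tn_interval"]),
        genome_circular=bool(meta.get("genome_circular", True)),
        plasmid_circular=bool(meta.get("plasmid_circular", True)),
        target_sites=[
            TargetSite(t["position"], t.get("strand", "+"), t.get("offset_x", 49))
            for t in meta.get("targets", [])
        ],
    )


def iter_reads(path):
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    for rec in SeqIO.parse(str(path), fmt):
        yield rec.id, str(rec.seq)


def run_classify(
    reads_path,
    genome_fasta,
    plasmid_fasta,
    references_yml,
    outdir,
    params: RunParams | None = None,
) -> ClassifyResult:
    """File-level pipeline: read inputs, classify, write all tables."""
    params = params or RunParams()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    refs = load_references(genome_fasta, plasmid_fasta, references_yml)
    result = classify_reads(iter_reads(reads_path), refs, params)
    write_tables(result, refs, outdir, params)
    manifest = {
        "tncall_version": __version__,
        "parameters": asdict(params),
        "inputs": {
            str(p): _sha256(p) for p in (reads_path, genome_fasta, plasmid_fasta, references_yml)
        },
        "counts": result.summary.to_dict(),
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return result


def write_tables(result: ClassifyResult, refs: ReferenceSet, outdir, params: RunParams) -> None:
    outdir = Path(outdir)
    hits_rows, flank_rows, call_rows = [], [], []
    for rc in result.read_calls:
        for h in rc.hits:
            hits_rows.append(
                {
                    "read_id": h.read_id, "start": h.start, "end": h.end,
                    "strand": h.strand, "matched_length": h.matched_length,
                    "significance": h.significance, "rank": h.rank,
                }
            )
        for fc in rc.flank_calls:
            flank_rows.append(
                {
                    "read_id": fc.flank.read_id, "hit_rank": fc.flank.hit_rank,
                    "side": fc.flank.side, "label": fc.label,
                    "distance_genome": fc.min_distance_genome,
                    "distance_plasmid": fc.min_distance_plasmid,
                    "best_position": fc.best_position, "best_strand": fc.best_strand,
                }
            )
        call_rows.append(
            {
                "read_id": rc.read_id, "class": rc.read_class,
                "removal_reason": rc.removal_reason, "n_hits": len(rc.hits),
                "inter_hit_distances": ";".join(map(str, rc.inter_hit_distances)),
                "tandem": rc.tandem, "backbone_validated": rc.backbone_validated,
            }
        )
    pd.DataFrame(hits_rows, columns=["read_id", "start", "end", "strand", "matched_length", "significance", "rank"]).to_csv(outdir / "hits.tsv", sep="\t", index=False, na_rep="NA")
    pd.DataFrame(flank_rows, columns=["read_id", "hit_rank", "side", "label", "distance_genome", "distance_plasmid", "best_position", "best_strand"]).to_csv(outdir / "flank_calls.tsv", sep="\t", index=False, na_rep="NA")
    pd.DataFrame(call_rows, columns=["read_id", "class", "removal_reason", "n_hits", "inter_hit_distances", "tandem", "backbone_validated"]).to_csv(outdir / "read_calls.tsv", sep="\t", index=False, na_rep="NA")

    with open(outdir / "insertions.bed", "w") as fh:
        for e in result.events:
            fh.write(f"genome\t{e.genome_coordinate}\t{e.genome_coordinate + 1}\t{e.read_id}\t0\t+\n")

    hist = result.summary.histogram
    with open(outdir / "histogram.tsv", "w") as fh:
        fh.write("bin_start\tbin_end\tcount\n")
        for i, c in enumerate(hist):
            lo = i * params.bin_size
            hi = min((i + 1) * params.bin_size, len(refs.genome_seq))
            fh.write(f"{lo}\t{hi}\t{int(c)}\n")

    with open(outdir / "summary.tsv", "w") as fh:
        fh.write("key\tvalue\n")
        for k, v in result.summary.to_dict().items():
            fh.write(f"{k}\t{'NA' if v is None else v}\n")


def render_report(outdir) -> str:
    """Human-readable summary from a classify output directory."""
    outdir = Path(outdir)
    summary_path = outdir / "summary.tsv"
    calls_path = outdir / "read_calls.tsv"
    if not summary_path.exists() or not calls_path.exists():
        raise FileNotFoundError(f"classify outputs not found in {outdir}")
    kv = dict(
        pd.read_csv(summary_path, sep="\t", dtype=str, na_values=[], keep_default_na=False).values
    )

    def num(key):
        return kv.get(key, "NA")

    def pct(key):
        v = kv.get(key)
        return "n/a" if v in (None, "NA") else f"{float(v) * 100:.1f}%"

    lines = [
        "tncall classification report",
        "============================",
        f"input reads:              {num('n_reads_total')}",
        f"transposon-containing:    {num('n_transposon_reads')}",
        "",
        "read classes",
        f"  simple insertion:       {num('n_simple')}",
        f"  cointegrate:            {num('n_cointegrate')}",
        f"  plasmid:                {num('n_plasmid')}",
        f"  removed:                {num('n_removed')}",
        "",
        "of transposition products (simple + cointegrate):",
        f"  simple insertion:       {pct('fraction_simple')}",
        f"  cointegrate:            {pct('fraction_cointegrate')}",
        "",
        f"insertion events:         {num('n_events')} ({num('n_on_target')} on-target)",
        f"on-target (of events):    {pct('fraction_on_target')}",
        f"on-target (of tn reads):  {pct('fraction_on_target_of_transposon_reads')}",
        "",
        "attrition",
        f"  no valid mini-Tn hit:   {num('n_removed_no_valid_hit')}",
        f"  no full-length flanks:  {num('n_removed_no_valid_flanks')}",
        f"  unclassified flank:     {num('n_removed_unclassified_flank')}",
        f"  ambiguous tie:          {num('n_removed_ambiguous_tie')}",
    ]
    return "\n".join(lines) + "\n"


def _write_fasta(path, name, seq) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), 80):
            fh.write(seq[i : i + 80] + "\n")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
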