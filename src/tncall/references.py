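"""Reference sequences and transposition-product alleles.

A run is anchored on a :class:`ReferenceSet`: the target genome (usually a
circular bacterial chromosome), the circular donor plasmid carrying the
mini-transposon (mini-Tn), and the coordinates of the RNA-guided target
site(s). Synthetic references are random sequences constrained so that the
genome and the plasmid share no exact flank-length k-mer, which makes
flank classification unambiguous on error-free reads.

Allele builders assemble the two transposition-product structures:

* simple insertion  — ``genome | mini-Tn | genome`` with a target-site
  duplication (TSD): the ``tsd_length`` bases 5' of the insertion point are
  repeated 3' of the mini-Tn;
* cointegrate       — ``genome | mini-Tn | backbone | mini-Tn | genome``
  (the whole donor plasmid integrated, mini-Tn duplicated), again with a
  TSD.  Concatemer cointegrates carry k plasmid units: k+1 mini-Tn copies
  separated by k backbones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from numpy.random import default_rng

from ._util import kmer_set, normalize, random_dna, revcomp

ORIENT_T_RL = "T-RL"
ORIENT_T_LR = "T-LR"


class ReferenceGenerationError(RuntimeError):
    """No collision-free reference pair found within the attempt budget."""


@dataclass(frozen=True)
class TargetSite:
    """An RNA-guided target: 0-based coordinate of the protospacer 3' end.

    ``offset_x`` is the system-specific distance (bp) downstream of the
    protospacer 3' end at which integration is expected (49 for the
    V. cholerae-type system, 40 for the S. hofmannii-type system).
    """

    position: int
    strand: str = "+"
    offset_x: int = 49

    def center(self) -> int:
        """Expected insertion point: offset_x bp downstream, strand-aware."""
        if self.strand == "+":
            return self.position + self.offset_x
        return self.position - self.offset_x


@dataclass
class ReferenceSet:
    genome_seq: str
    plasmid_seq: str
    mini_tn_interval: tuple[int, int]  # 0-based half-open, on the plasmid
    genome_circular: bool = True
    plasmid_circular: bool = True
    target_sites: list[TargetSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genome_seq = normalize(self.genome_seq)
        self.plasmid_seq = normalize(self.plasmid_seq)
        s, e = self.mini_tn_interval
        if not (0 <= s < e <= len(self.plasmid_seq)):
            raise ValueError(f"mini_tn_interval {self.mini_tn_interval} outside plasmid bounds")

    @property
    def mini_tn_seq(self) -> str:
        s, e = self.mini_tn_interval
        return self.plasmid_seq[s:e]

    @property
    def mini_tn_length(self) -> int:
        s, e = self.mini_tn_interval
        return e - s

    @property
    def backbone_length(self) -> int:
        return len(self.plasmid_seq) - self.mini_tn_length

    @property
    def backbone_seq(self) -> str:
        # the plasmid minus the mini-Tn, in plasmid order
        s, e = self.mini_tn_interval
        return self.plasmid_seq[e:] + self.plasmid_seq[:s]


def generate_references(config, max_attempts: int = 50, kmer: int = 50) -> ReferenceSet:
    """Random genome + donor plasmid with a disjoint k-mer guarantee.

    The plasmid is laid out as ``backbone + mini-Tn`` and treated as
    circular.  The pair is resampled until genome and plasmid share no
    exact ``kmer``-mer (wrap-around k-mers included), so that a
    flank-length window drawn from one reference can never map to the
    other at Hamming distance 0.

    Deterministic for a fixed ``config.seed``.
    """
    rng = default_rng([int(config.seed), 0])
    genome = random_dna(rng, config.genome_length)
    genome_kmers = kmer_set(genome, kmer, circular=True)
    for _ in range(max_attempts):
        backbone = random_dna(rng, config.plasmid_backbone_length)
        mini_tn = random_dna(rng, config.mini_tn_length)
        plasmid = backbone + mini_tn
        if genome_kmers.isdisjoint(kmer_set(plasmid, kmer, circular=True)):
            return ReferenceSet(
                genome_seq=genome,
                plasmid_seq=plasmid,
                mini_tn_interval=(len(backbone), len(plasmid)),
                target_sites=[
                    TargetSite(config.target_site_position, "+", config.offset_x)
                ],
            )
    raise ReferenceGenerationError(
        "no collision-free genome/plasmid pair found; genome_length is likely too small"
    )


def _check_site(refs: ReferenceSet, site: int, tsd_length: int) -> None:
    if tsd_length < 0:
        raise ValueError("tsd_length must be >= 0")
    if not (tsd_length <= site <= len(refs.genome_seq)):
        raise ValueError(f"insertion site {site} outside usable genome range")


def make_simple_insertion_allele(
    refs: ReferenceSet,
    site: int,
    orientation: str = ORIENT_T_RL,
    tsd_length: int = 5,
) -> str:
    """Genome with the mini-Tn inserted at ``site`` plus a TSD.

    ``site`` is the 0-based insertion point: the mini-Tn lands between
    ``genome[site-1]`` and ``genome[site]``, and the ``tsd_length`` bases
    immediately 5' of the insertion point reappear immediately 3' of the
    mini-Tn.  ``orientation`` T-LR reverse-complements the mini-Tn.
    """
    _check_site(refs, site, tsd_length)
    tn = refs.mini_tn_seq if orientation == ORIENT_T_RL else revcomp(refs.mini_tn_seq)
    g = refs.genome_seq
    return g[:site] + tn + g[site - tsd_length :]


def make_cointegrate_allele(
    refs: ReferenceSet,
    site: int,
    tsd_length: int = 5,
    n_units: int = 1,
    orientation: str = ORIENT_T_RL,
) -> str:
    """Genome with the full donor plasmid integrated at ``site``.

    The insert is ``mini-Tn (backbone mini-Tn) x n_units``: n_units+1
    mini-Tn copies separated by n_units backbones, so the gap between
    consecutive copies equals the backbone length exactly.  ``n_units > 1``
    models concatemer cointegrates arising from multimeric donor plasmids.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    _check_site(refs, site, tsd_length)
    insert = refs.mini_tn_seq + (refs.backbone_seq + refs.mini_tn_seq) * n_units
    if orientation == ORIENT_T_LR:
        insert = revcomp(insert)
    g = refs.genome_seq
    return g[:site] + insert + g[site - tsd_length :]


def cointegrate_insert_length(refs: ReferenceSet, n_units: int = 1) -> int:
    return (n_units + 1) * refs.mini_tn_length + n_units * refs.backbone_length


def mini_tn_offsets(refs: ReferenceSet, n_units: int) -> list[int]:
    """Start offsets of each mini-Tn copy within a cointegrate insert."""
    period = refs.mini_tn_length + refs.backbone_length
    return [i * period for i in range(n_units + 1)]
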