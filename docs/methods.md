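# Methods

## The problem

CRISPR-associated transposons insert a mini-transposon (mini-Tn) carried on a
donor plasmid (pDonor) into an RNA-guided genomic target site. Two product
structures are possible. Cut-and-paste transposition (TnsA + TnsB cleaving
both strands at both transposon ends) excises the mini-Tn and yields a
**simple insertion**: mini-Tn flanked by genomic sequence and a short
target-site duplication (TSD, 5 bp here). Replicative transposition (3'
cleavage only) proceeds through a Shapiro intermediate and yields a
**cointegrate**: the entire donor plasmid integrated into the genome, with
the mini-Tn duplicated on both sides of the vector backbone. Junction-PCR
assays are structurally biased and can miss cointegrates entirely; unbiased
whole-genome long-read (CCS) sequencing resolves the full-length product on
every molecule. `tncall` implements the read-level decision procedure for
such data, plus a generator of structure-known synthetic reads so every stage
is testable by exact parameter recovery.

## Classification procedure

For each CCS read:

1. **Mini-Tn hit search** (`tn_finder`). All local occurrences of the mini-Tn
   on either strand are located. The contract is: find every occurrence at
   >= 95% identity spanning at least the mini-Tn length minus the length
   tolerance. The implementation aligns the mini-Tn (and its reverse
   complement) to the read in infix mode with banded edit distance (edlib),
   accepting the best-scoring placement(s) and masking them before
   re-searching, so duplicated copies (cointegrates, plasmid multimers) are
   all recovered. Overlapping candidates resolve to the higher-scoring
   placement, ties to the more 5' one. A significance value is attached to
   each hit: the expected number of equally good placements in a
   uniform-random read, `2 n (1/4)^(matched_length - edits)`; with
   near-full-length hits this is astronomically small, so the effective
   filter is the length window.
2. **Hit filter**. Hits whose matched length differs from the mini-Tn length
   by more than 5 bp (inclusive window), or with significance above 1e-6,
   are removed; survivors are ranked 5' to 3'. Reads with no surviving hit
   are removed (`no_valid_hit`).
3. **Flank extraction** (`flank_mapper`). Each hit contributes the 50-bp read
   windows immediately left and right of the hit interval. Windows truncated
   by a read edge or crossing an adjacent hit are discarded, never padded.
4. **Flank classification**. Each flank is compared against the full genome
   and the full donor plasmid (mini-Tn included) by minimum Hamming distance
   over **all** ungapped placements of the flank and its reverse complement,
   including origin-wrapping placements on circular references. The flank is
   labelled by whichever reference has the lower distance, with a maximum
   allowed distance of 2; if both distances exceed 2 the flank is
   unclassified and the read is removed (`unclassified_flank`). An exact
   distance tie at <= 2 is also unclassified (`ambiguous_tie`): ambiguity
   must not silently inflate either product class.
5. **Read call** (`read_classifier`). Over all surviving flanks of a read:
   all plasmid -> plasmid read; all genomic -> simple insertion; mixed ->
   cointegrate. Two QC flags are computed, not used for reclassification:
   `backbone_validated` (every inter-hit gap equals the backbone length
   within a tolerance — the geometric signature of a full plasmid between
   duplicated mini-Tn copies) and `tandem` (consecutive hits within 10 bp,
   the signature of tandem insertions).
6. **Site analysis** (`site_analysis`). For simple-insertion and cointegrate
   reads, the genomic coordinate is taken from the first genome-mapping
   flank in the read (5' to 3'): the junction base (flank base adjacent to
   the mini-Tn) mapped through the flank's best placement. An event is
   on-target when it falls within a 100-bp window (inclusive at both ends,
   modular on circular genomes) centred `offset_x` bp downstream of the
   protospacer 3' end (49 for the V. cholerae-type system, 40 for the
   S. hofmannii-type system). Events are binned at 5 kb for genome-wide
   histograms. Summary fractions: simple and cointegrate fractions are over
   transposition products (simple + cointegrate); the on-target fraction is
   reported both over insertion events and over all transposon-containing
   reads, since the headline specificity number can be quoted either way.

### Hamming search: exactness and speed

Pure ungapped (Hamming) matching is the normative flank semantics — it is
tool-independent and oracle-checkable. By the pigeonhole principle, a 50-bp
query within Hamming distance 2 of a placement must match the reference
exactly in at least one of three ~17-bp chunks at the corresponding offset,
so a per-chunk k-mer table over the (circularly extended) reference
enumerates *every* placement at distance <= 2; candidates are then verified
by vectorised comparison. The search is therefore exact up to the distance
cap; distances above the cap are reported as "greater than 2" without an
exact value. The test suite checks this implementation against a brute-force
scan over all placements and both strands (`tests/_oracles.py`), including
planted 0/1/2/3-mismatch variants.

### Coordinate conventions

0-based, half-open everywhere; BED output is 0-based half-open single-base
intervals. `best_position` is the leftmost base of a placement on the +
strand of the winning reference. Because of the TSD, the left and right
genomic junctions of one insertion differ by `tsd_length` bases; coordinates
are reported per read without TSD collapsing (the 100-bp window absorbs the
5-bp offset). The junction convention is configurable
(`junction` | `flank_start`).

## Synthetic data generator

`synthetic` reads emulate demultiplexed CCS reads from a pooled
transposition experiment. Structures: simple insertions (on- and off-target),
cointegrates, concatemer cointegrates (k plasmid units -> k+1 mini-Tn
copies), and free-plasmid reads drawn from a tandemly tiled (multimeric)
plasmid at uniform phase — which also reproduces the multiple-consecutive-
plasmid-flank pattern of concatemer plasmids. Off-target sites are uniform
over the genome outside the on-target neighbourhood (no positional model is
assumed for off-target events).

Defaults and rationale (units of bases unless stated):

| parameter | default | why |
|---|---|---|
| genome_length | 100 000 | desk-scale stand-in for a bacterial chromosome; large enough that random 50-mers are unambiguous |
| plasmid_backbone_length / mini_tn_length | 3 000 / 1 000 | ~1-kb mini-Tn on a small vector, matching the experimental construct scale |
| tsd_length | 5 | the expected TSD of these systems |
| offset_x | 49 | V. cholerae-type spacing from protospacer 3' end |
| read_length_mean / sd | 10 000 / 500 | CCS reads in the 10–12-kb range |
| substitution_rate / indel_rate | 0.001 / 0.0005 | approximates >Q20 CCS accuracy; i.i.d., single-base indels, no homopolymer model |
| class_proportions | 0.6 / 0.3 / 0.1 simple/cointegrate/plasmid | the standard verification mixture used throughout the tests |
| orientation_bias | 0.5 | no orientation preference is asserted; the classifier is orientation-agnostic |
| span_fraction | 0.9 | fraction of non-plasmid reads placed to span a mini-Tn with >= 50 bp on both sides; the remainder is uniform, producing the truncated-flank edge cases the classifier must discard. Recovery tests use 1.0 so that 100% accuracy is well-defined |
| quality strings | constant Q30 | placeholder; the classifier never reads qualities |

The truth manifest records, per read: class, orientation, read strand, the
read-frame intervals of every mini-Tn copy recoverable by the full-length
hit filter (copies clipped by <= 5 bp at a read edge included, clipped), and
`true_insertion_site` — the junction coordinate of the first recoverable
genomic flank in read orientation. The last convention is deliberate: the
TSD makes the two junctions differ by `tsd_length`, so a single canonical
coordinate would disagree with a correct call by tsd-1 bases on half the
reads; recording the strand-aware junction makes "coordinate within +/- 2 bp
of truth" a meaningful recovery criterion.

What the generator does **not** model: polymerase-pass-dependent quality,
barcodes/demultiplexing, chimeric reads, homopolymer error clustering,
structural variation beyond the transposition products themselves. Passing
recovery tests therefore demonstrates correctness of the decision procedure
under the stated error model, not robustness to every artefact of real
SMRT-seq libraries.

## qPCR module

Junction-qPCR integration efficiency per orientation is
`100 * 2^(Cq_reference - Cq_orientation)` percent; total efficiency is the
sum over the T-RL and T-LR orientations. Replicates are transformed first
and averaged after (the transform is nonlinear); values above 100% are
flagged, not clipped.

## Numerical/design choices

- "Within 5 bp of the mini-Tn length" is inclusive (|delta| <= 5).
- Tandem proximity defaults to 10 bp: well below any plausible backbone
  length, tolerant of small alignment slop.
- Backbone tolerance defaults to 10 bp (absorbs indel drift in noisy reads);
  error-free recovery tests use 0.
- The genome is treated as circular by default (toggleable); wrap-around
  flank placements are allowed.
- Flanks landing in the mini-Tn portion of the plasmid are plasmid-mapping
  (the full plasmid is the reference); this matters only for pathological
  hits.
- N bases count as mismatches everywhere.
- The pipeline is deterministic by construction; randomness enters only
  through the generator's seed.

## Problem sizes

The standard verification runs use 500 reads on a 100-kb genome (whole
pipeline in a few seconds); unit tests use a 20-kb genome with an 80-read
mixture covering all five product classes. These sizes are chosen so the
multinomial recounts are informative while whole-suite runs stay fast.

## Known limitations

- The classifier removes any read with an unclassified flank, as specified;
  under the default error model an indel landing more than ~3 bp inside a
  flank usually pushes its Hamming distance past 2, so the classified
  fraction falls with the number of flanks per read (cointegrate and
  plasmid-multimer reads carry 4–6). Accuracy of classified reads is
  unaffected.
- Gapped flank alignment and quality-aware weighting are out of scope.
- Cointegrate resolution products, large deletions and other nuclease
  byproducts are not modelled or detected.
- A read spanning only a middle mini-Tn copy of a concatemer cointegrate
  carries plasmid flanks only and is (correctly, given the rule) classified
  as a plasmid read; concatemer identity is only visible from reads reaching
  a genomic junction.
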