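# Methods

## The screen

A candidate interaction site in a SYDE protein is a motif-class match
that passes three filters.

**Background match probability.** Each motif class is a regular
expression restricted to a finite grammar: every position is a residue
class (a literal, `.`, or a `[...]` set), optionally with a bounded
quantifier.  The pattern expands into fixed-length variants, and the
class score is the probability that a random position in a
background-composition sequence begins a match:

    P(class) = Σ_variants  Π_positions  Σ_{a ∈ allowed set} p_bg(a)

The default background is a Swiss-Prot-like amino-acid composition
(configurable).  A match is score-eligible when `P < 10⁻²`.
Modification-site classes (MOD_CK1_1, MOD_CK2_1, MOD_GSK3_1) and the two
SH3 classes are whitelisted: phosphosite-type motifs are selected on
disorder propensity and annotated sites rather than on rarity, and their
published scores sit above the cutoff while still being reported as
retained.  This two-track rule reproduces the published retained set.
The analytic score is an internal analogue of a published per-class
probability; it is not a reproduction of any external server's number
(the server's background tables are not public), which is why the
published scores are stored as metadata and never recomputed to
equality.

**Disorder.** Intervals come either from imported predictor output
(annotation TSV, the faithful route) or from a windowed fold-index
surrogate: per residue,

    score = 2.785·⟨H⟩ − |⟨R⟩| − 1.151

with `⟨H⟩` the mean Kyte–Doolittle hydropathy rescaled to [0, 1] via
`(KD + 4.5)/9` and `⟨R⟩` the mean net charge (K, R: +1; D, E: −1;
H: +0.5) over a 51-residue window, truncated at the termini.  Negative
score marks disorder; maximal negative runs of ≥ 5 residues are regions,
and runs separated by fewer than 3 residues merge.  The surrogate is a
published-style fold index, adequate for compositionally biased
segments; it is not an energy-model predictor, and no acceptance result
depends on exact disorder boundaries.  When both routes are available
their union is used.

**Conservation.** A reference match is mapped to alignment columns of an
ortholog family, the window is widened by ±5 columns (slack for small
alignment wobble), and each ortholog counts as conserved when the class
pattern matches inside its ungapped residues under that window.  Matches
with a conserved fraction below 0.8 are dropped; matches with no
conservation data are retained but flagged, so the audit trail is
explicit.  Orthologs enter as a user-supplied aligned FASTA (e.g. from
MAFFT) or through a built-in star-progressive aligner centered on the
reference — sufficient for close families, not a general MSA method.

## Domain identity

"Domain homology" figures are computed as global-alignment percent
identity: Needleman–Wunsch with affine gaps (BLOSUM62, open 10, extend
0.5), identity = identical columns / all alignment columns, reported to
0.1%.  Whether the published percentages are identity or similarity, and
over which exact boundaries, is not stated in the source material, so a
±1.5 percentage-point tolerance is attached to those comparisons.  Ties
among co-optimal tracebacks are broken by taking the aligner's first
reported optimum, which is deterministic.  Domain boundaries are inputs
(a packaged annotation table), never computed.

## Phylogeny

The ortholog tree is a deliberate distance-based surrogate for a
maximum-likelihood protein tree (which is out of scope): pairwise
Kimura-corrected distances `d = −ln(1 − p − 0.2p²)` over shared ungapped
columns (saturated pairs capped at 10.0 with a warning), standard
neighbor joining with a lexicographic tie-break and negative branch
estimates clamped to zero, and supports from resampling alignment
columns with replacement (500 replicates by default; replicate *r* draws
from the seed stream `(seed, r)`, making supports independent of taxa
order).  NJ is exact on additive matrices — the property the tests
check — so the acceptance surface is synthetic-clade recovery, not any
published topology.

## Network

Curated interactions (a packaged transcription of the published
low-throughput/high-throughput table) and retained SLiM candidates merge
into one network.  Edge tiers: `curated-low-throughput` when any method
is coIP/pull-down/Y2H/ITC/FLAP; `high-throughput-or-predicted` for AP-MS
rows and motif predictions; `conserved-inferred` for the GSK3 site,
whose partner evidence comes from a lower-organism ortholog;
`structural-prediction` for the docking-derived RhoA/RhoB substrate
edges, which bypass the SLiM audit.  Entities listed together in one row
("Cyclin B/CDK1") are one node; rows sharing a first-named protein merge
into one node named by that protein — this rule yields 11 predicted
SYDE1 entities and, by collapsing the two Crk rows, 8 predicted SYDE2
entities.  Exports are a lossless node/edge TSV pair and GML.

## Synthetic families

The generator emulates exactly the features the screen relies on: a root
sequence with disorder-biased segments (E/S/P/K/Q/R enriched ×2.2;
W/F/I/L/V/C/M depleted ×0.25, relative to the Swiss-Prot composition)
and globular segments (hydrophobics enriched ×1.8, charged/P/Q/S
depleted ×0.5); implanted motif peptides sampled from their class
patterns; orthologs derived by per-site substitution at `q_bg` (default
0.2) with a lower `q_motif` (default 0) inside conserved implants, and
deliberate single-position disruption of non-conserved implants.  The
expected fold-index score of the disordered composition is ≈ −0.40 and
of the globular composition ≈ +0.60, so the surrogate separates the two
segment classes by construction.  Substitutions are drawn from the
background composition, not a rate matrix — adequate for motif-retention
testing; the generator is not a molecular-evolution simulator (no
JTT/Gamma, no selection, and indels are not simulated — the `indel_rate`
field is validated to zero so column mapping can be exercised on real
alignments instead).  Ground truth is recomputed from the emitted
sequences by pattern matching: a background mutation that happens to
create a new match is labelled *incidental* and counts as neither true
nor false positive.

What passing synthetic tests shows: the machinery (scanning, disorder
calling, column mapping, selection logic, bookkeeping) is correct under
controlled conditions.  What it does not show: performance on real
disorder predictors, real alignment error, or real motif divergence,
all of which are noisier than the generator.

## Packaged stand-in scaffolds

The study sequences are UniProt entries that this package does not
redistribute; users supply them as FASTA.  For self-contained runs, the
package constructs deterministic **synthetic scaffolds** for SYDE1
(735 aa), SYDE2 (1194 aa) and DmSyd1 that embed every published motif
peptide at its published 1-based coordinate, place the SYDE1
palmitoylation cysteine at 734 (and make it the last cysteine), include
both published NES candidate peptides and the validated RVLSVP
calcineurin site, and reserve ordered domain blocks of the published
lengths (C2 118/120, RhoGAP 207/216).  Two published coordinate facts
are internally inconsistent and are handled explicitly:

- the DOC_Cyclin_RxL instance RLSIKMKKLPE is an 11-mer but its printed
  interval spans 10 residues; the start and peptide are taken as
  authoritative (end recomputed to 166+11−1 = 176);
- the printed SYDE1 intervals 641–647 (PEVVTRP) and 645–651 (SPPSNRY)
  overlap with contradictory residues, so no sequence can satisfy both;
  the scaffold keeps PEVVTRP at 641 and places SPPSNRY at 655, and the
  catalog validator reports the 645 coordinate as unverifiable (18 of
  19 instances verify by position).

Scaffold domain residues are random background, deliberately *not*
modelled on the real domains: computing domain identity on scaffolds
gives background-level values, and the domain-identity check therefore
requires the genuine sequences.  Calibrating scaffold divergence to
reproduce the published identity percentages would make that comparison
circular, so it is not done.

## Numerical and design notes

- Coordinates are 1-based inclusive everywhere; conversion to 0-based
  half-open happens only at Python slicing boundaries.
- `X` is tolerated in sequences, contributes a neutral hydropathy of 0.5
  to the fold index, and matches no motif residue class.
- Scanning enumerates the same fixed-length variants that define the
  analytic score, so scanner and score agree by construction; the test
  suite cross-checks both against Python's `re` engine and a Monte-Carlo
  frequency estimate.
- Overlapping matches are all reported (no greedy consumption); order is
  ascending start, then shortest first.
- The candidate table carries all three filter verdicts per row, so any
  retained or rejected call can be audited.
- The command-line layer is a thin wrapper; every operation is available
  as a library function with the same defaults.
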