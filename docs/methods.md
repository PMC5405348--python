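# Methods

## The screen

The package mines bacterial contigs for nitrilase candidates. The model of a
"convincing candidate" is conjunctive: it must (i) be a plausible gene — an
open reading frame of at least 100 codons; (ii) be a plausible homolog —
30–80 % identity to a characterised reference nitrilase; (iii) carry the
family's sequence signature — the class-specific manually designed motifs
(MDMs) with the Glu/Lys/Cys catalytic triad at the tagged positions; and
(iv) look like a nitrilase physicochemically. Class (aliphatic vs aromatic
substrate preference) is then assigned from the same motif and property
evidence, and the candidate is placed in a Neighbor-Joining tree among
labelled references as an independent, reported-but-not-deciding line of
evidence.

## ORF calling

Gene calling is an exhaustive six-frame scan rather than a statistical gene
model: every span from a start codon (ATG/GTG/TTG) to the next in-frame stop
under NCBI translation table 11 is a candidate ORF, the longest ORF per
(strand, frame, stop) is kept, and proteins shorter than `min_aa = 100`
residues are discarded. This is deliberately simple and fully reproducible;
it over-calls relative to a trained gene finder (any random stretch of
~300+ nt without an in-frame stop can surface), which is acceptable because
the downstream homology and motif filters are the real discriminators.
Alternative starts are rendered as Met in the pipeline (`start_as_met`),
matching how sequence databases report translations. Coordinates are 0-based
half-open on the forward strand internally; human-facing tables print
1-based inclusive spans.

## Homology window

BLAST is replaced by exact Smith–Waterman local alignment (BLOSUM62, gap
open 11, extend 1 — the classic BLASTP parameterisation). At candidate scale
(hundreds of residues, dozens of candidates) exactness is affordable and
removes an external binary. Percent identity is computed over the local
alignment with gap columns in the denominator; the window bounds [30, 80]
are inclusive. Two consequences of the local-alignment convention are worth
knowing: a short, well-matching region can put an otherwise unrelated
protein inside the window (such impostors are removed by the motif screen),
and an alignment with no positive-scoring extension is reported as empty
with identity 0 and a flag.

## Motif matching

The eight packaged patterns are transcribed verbatim from the published
motif set (four per class; emphasis markers stripped). Syntax: a single
letter is a fixed residue, `[...]` lists alternatives, `X` matches anything.
One bracketed group contains `X` and is therefore treated as a wildcard —
`X` means "any residue" everywhere in the notation. The catalytic tags sit
on motifs 1 (E), 2 (K) and 3 (C) of each class; motif 4 carries no tag.

Strict matching requires every element to accept its residue. Fuzzy matching
aligns a protein window against any contiguous block of at least
`min_elements = 8` pattern elements at any offset and reports it when
`mismatches / elements_covered <= 0.3`; overlapping reports are deduplicated
keeping the lowest mismatch fraction (ties: widest coverage, then leftmost),
and full-coverage zero-mismatch matches are never suppressed by one another
so the strict results are always a subset of the fuzzy results. The
packaged observed-match snippets show that real homologs' motif regions
range from perfect copies to heavily diverged remnants; the most diverged
of them register only below the default thresholds, which is reported
honestly by the matcher rather than papered over by loosening the defaults.

Triad location takes, per tagged pattern, the best match (strict preferred,
else lowest mismatch fraction, then widest, then leftmost), maps the tagged
element through the match offset, and accepts the position only if the
residue there is literally E, K or C. "Complete" means all three verified.

## Physicochemical descriptors

All nine descriptors are computed from the published constant tables
(vendored in `_tables.py`): average residue masses and one water for
molecular weight; the Bjellqvist pK set with residue-specific terminal
corrections for pI, solved by bisection of the Henderson–Hasselbalch net
charge on [0, 14] to 0.005 pH; D+E and K+R counts (His excluded by
convention); Gill–von Hippel 280 nm coefficients, with the cystine form
adding 125 M⁻¹cm⁻¹ per cysteine pair; the Guruprasad dipeptide weight sum
scaled by 10/L; Ikai's aliphatic index; and mean Kyte–Doolittle hydropathy.
Instability below 40 is labelled "stable". The published consensus chart
reports a single extinction column without stating reduced vs cystine, so
comparisons use whichever computed form is nearer.

## Classification

Motif evidence: count patterns per class with a strict hit, then with any
hit. The class winning on (strict, total) is labelled provided its total
reaches `min_required = 3` of 4 patterns; equal evidence gives no motif
label. The 3-of-4 default reflects that only three motifs carry triad tags;
it is configurable.

Property evidence: distance to each class's consensus vector,
`sqrt(sum_f ((x_f - mean_{c,f}) / scale_f)^2)`, with `scale_f` the absolute
difference between the two class means for that field. The two consensus
vectors share an identical pI mean, so pI has zero between-class separation;
fields with (near-)zero separation are **excluded** from the distance
rather than floored, because a floored near-zero scale would inflate both
distances by the same huge term and drive the decision margin to zero for
any protein whose pI deviates at all — making the property route vacuous.
A margin below 0.05 between the two distances gives no property label.

Combination: motif label if decisive, else property label, else
"unclassified". Motifs take precedence because they were designed to be
class-specific; tree placement is reported but never drives the label, since
the published screen presents the three lines of evidence side by side
without stating a combination rule.

## Tree placement

Distances are p-distances (1 − identity fraction) on pairwise global
alignments (Needleman–Wunsch, BLOSUM62, 11/1) — a deliberate simplification
of a progressive multiple alignment, adequate for distance-level clustering
and fully deterministic. Neighbor-Joining is implemented directly from the
Saitou–Nei formulation: join the pair minimising
`Q(i,j) = (r-2) d(i,j) - R_i - R_j` (ties to the smallest index pair),
two-point branch-length formulas, negative estimates clamped to zero and
counted (the MEGA convention). On additive matrices the algorithm provably
recovers the generating topology; the tests confirm this against brute-force
topology enumeration with least-squares additivity fits. Concordance scores
each query by its nearest labelled reference in path length; ties break
toward the earliest reference in matrix order and are flagged, and a query
whose nearest reference is farther than the 95th percentile of
reference–reference distances is flagged as a long branch.

## Synthetic data

The generator emulates the screen's study conditions: contigs of 40 kb
carrying 3 aliphatic + 2 aromatic implants (lengths drawn from 260–342 aa,
the span reported for characterised candidates), 3 background genes
(120–200 aa) that pass the length filter but carry no motifs, and 5 short
decoys (30–60 aa) that the length filter must remove. Implanted nitrilase
proteins strictly match all four class motifs in order with random spacers
(or reference-derived spacers when a reference is supplied), so the triad is
present by construction; when a reference is given, non-motif positions are
point-mutated to a designed ~50 % identity — the middle of the 30–50 % band
reported for real novel homologs — with motif spans frozen. Proteins are
back-translated with uniform synonymous codons (no codon-usage model; the
screen operates on translations), given an ATG start and TAA stop, placed on
a random strand at random non-overlapping loci, and insulated by a 12-nt
palindromic cassette that stops translation in all six frames, so
neighbouring sequence cannot extend an implant's ORF. All randomness flows
from one numpy Generator per call; identical (config, seed) pairs are
byte-identical.

What the generator does **not** emulate: sequencing error, assembly
artifacts, operon structure, codon bias, genuinely homologous background
(its background genes are uniform-random protein). Passing the end-to-end
tests therefore demonstrates the pipeline's correctness and determinism on
idealised inputs, not its precision on real genomes — on real data the
homology window admits short-local-alignment impostors and the six-frame
caller over-calls, both by design, with the motif screen doing the heavy
lifting.

## Problem sizes and numerical choices

The end-to-end suites and the acceptance script run on one 40-kb contig
with 13 implants, 20 random additive matrices of 4–8 taxa for the NJ sweep,
and 100 random sequences for the descriptor cross-check — sizes chosen so
the whole suite completes in seconds while exercising every code path.
pI bisection tolerance is 0.005 pH; fuzzy-match thresholds are compared
with a 1e-9 absolute tolerance so an exact boundary fraction (e.g. 3
mismatches over 10 elements at threshold 0.3) is accepted; distance
matrices are validated for symmetry, zero diagonal and non-negativity on
construction.

## Known limitations

- The full published screen (2000 genomes, 138 candidates) and the exact
  published tree topology are out of scope: they require external genome
  databases and a reference set that is not printed in the source tables.
- Identity is computed on local alignments (convention chosen; the
  published screen does not state full-length vs local).
- The six-frame caller reports only the longest ORF per stop; nested
  alternative starts are deliberately collapsed.
- Property-based classification is a weak fallback: with the published
  consensus vectors, several fields separate the classes only slightly, and
  the pI field not at all.
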