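# Methods

This note records the models, algorithms and parameter choices behind
`cascreen`, the assumptions they make, and what the synthetic-data
tests do and do not establish about real data.

## PAM depletion screen

### Read processing

Reads are kept when their arithmetic mean Phred score is at least 20
(inclusive). The degenerate region is recovered by **anchored
extraction**: a read (or its reverse complement) must contain the left
and right anchor sequences, each within a Hamming-distance budget
(default 1 mismatch), separated by exactly the degenerate length with
no ambiguous base; the enclosed 7-mer is counted. For amplicon reads
this is equivalent to mapping against the reference construct and
extracting the randomized window, but it is deterministic and
dependency-free; SAM input is also accepted for parity with
aligner-based workflows. Anchors must be ≥ 12 nt so the false-anchor
probability is negligible. Paired mates are not merged; whichever mate
anchors contributes, and read-name deduplication prevents a molecule
from being counted twice.

### Depletion statistics

Per variant, the 2×2 table (variant vs rest-of-library, selected vs
control) gives a Pearson chi-square; this construction uses all reads
and reduces to the standard two-proportion test. One-sidedness is
obtained by signing the square root of the statistic by the direction
of the frequency difference and taking the normal upper tail, so
variants enriched in the selected sample get p ≥ 0.5. Frequencies and
the log2 depletion score use a symmetric Jeffreys-style pseudocount of
0.5; the chi-square uses raw counts. Zero-information tables (empty
row/column margins) are assigned χ² = 0, p = 0.5.

The significance regime is a hard p-value cutoff with no further
multiple-testing machinery, matching how such screens are typically
read out. The canonical cutoff of 10⁻¹² presumes full screen depth
(≳100× per library member); the desk-scale read-level demonstrations
run at ~12× and use a depth-matched 10⁻⁴ cutoff instead. Both settings
are exercised: the 10⁻¹² regime at the count layer at full depth, the
read-level loop at 12×.

### Positional depletion and consensus

Positional depletion values are defined as the log2 ratio of
pseudocounted, count-weighted positional base frequencies
(control/selected). The published description of this quantity points
to prior work without restating a formula; this definition is
documented precisely so an alternative can be swapped in, and it
reproduces the expected qualitative structure (the required position
dominates the profile; a preferred position shows a weaker signal).

The IUPAC consensus collects, per position, bases in descending
depleted-set frequency until a dominance threshold (default 0.75) is
reached. A literal greedy stop is ill-posed at near-uniform positions:
the top-3 frequency sum is ≥ 0.75 by construction, so noise would
always terminate the greedy at three bases and N could never be
emitted. An ambiguity guard therefore also includes any excluded base
whose frequency is at least half that of the last included base —
a base carrying a comparable share of the depleted set is not evidence
of specificity. Ties in the greedy ordering break alphabetically.

### Report artifacts

The logo matrix is computed from the depleted set, each variant counted
once (as a logo over a sequence list), information content 2 − H bits
without small-sample correction (negligible at depleted-set sizes in
the hundreds, and off to keep the matrix exactly reproducible).
Optional per-variant weights are supported.

The PAM wheel is emitted as geometry, not pixels: nested annular
sectors over an ordered subset of positions (inner ring = first listed
position). Weights default to relative depletion max(0, f_ctrl −
f_exp), normalized globally; a log-ratio weighting is available behind
a switch, as is a per-ring layout in which each ring independently
shows the marginal weight of its position (the nested, globally
normalized layout is the default since sector areas then compare
across rings). Children partition their parent's angular span in fixed
base order A,C,G,T, and ring radii grow as √(ring/k) so every annulus
has equal area — sector area is then globally proportional to
aggregated weight.

Fixed-library fraction tables restrict counts to the declared members,
aggregate everything else into an `other` row, and normalize over the
member+other total.

## Locus annotation

Array detection nominates candidate repeats from recurring 8-mers
whose occurrence gaps fit the repeat+spacer period band, then extends
the aligned copies column by column. A column is accepted when at most
one copy deviates from the column consensus, no copy exceeds the
per-copy mismatch budget (default 3 vs the run consensus), and — when
the column does carry an outlier — the next column outward is fully
conserved. The look-ahead keeps boundaries crisp against random spacer
sequence while still crossing isolated substitutions inside degenerate
copies. Defaults (repeat 23–50 nt, spacer 20–60 nt, ≥ 3 units) are wide
enough to find a 36/31 architecture without hard-coding it. Candidate
runs are deduplicated by span, preferring more units. Coordinates are
0-based half-open internally; TSV/GFF3 exports are 1-based inclusive.
The seed-based nomination assumes each repeat copy shares at least one
exact 8-mer with the others, which holds for the mismatch budgets the
bands imply but would miss arrays whose copies diverge much further.

Anti-repeat (tracrRNA) candidates are local alignments of the repeat
consensus against both strands of the locus (match +1, mismatch −1,
gap open/extend −2/−1, via Biopython's pairwise aligner), outside the
array's own repeat intervals, thresholded on aligned length (≥ 15 nt)
and identity (≥ 0.8). Terminal mismatching columns are trimmed so
co-optimal alignments have a canonical representative. Hits are found
iteratively by masking; the iteration stops below a score floor of
`min_matched_len × (2·min_identity − 1)`, a bound that a passing
gap-free hit cannot undercut (strongly gapped passing hits below the
floor would be missed; at these thresholds that case is pathological).

Promoter-like elements are scored by counting matches to the non-N
positions of an extended −10 model (default `TGNTATAAT`; the motif is
configurable since reported consensus strings vary) over every 9-nt
window of the repeat, optionally restricted to a terminal region; ties
go to the window nearest the repeat 3′ end.

## Small-RNA profiling

Each primary alignment contributes one 5′ and one 3′ end (strand
aware; soft-clipped bases are excluded by using aligned coordinates).
Processing sites are windowed local maxima of the end histograms: a
coordinate with count ≥ min_support (default 5) and no larger count
within ± end_window (default 3 nt; ties to the smaller coordinate).
Each 5′ site pairs with every downstream 3′ site on the same strand
whose implied length lies in the 40–130 nt band and whose joint
support — reads with both ends within the window of the respective
sites — reaches min_support. Pairing by joint support is the simplest
faithful reconstruction of species from end coordinates; it assumes
processing sites of distinct species are separated by more than the
window, which holds for crRNA spacing in an array but could merge
genuinely overlapping isoforms.

Annotation is interval arithmetic against the array: a species
overlapping exactly one spacer is a crRNA (index counted from the
transcription-proximal end per the array strand; spacer/DR part
lengths are its overlaps with that spacer and the flanking repeats);
a species overlapping ≥ 2 spacers is flagged `other` with a warning;
species overlapping the tracrRNA region are tracr products. Observed
segment-length ranges are reported, never enforced. Orientation is the
majority strand of array-overlapping reads, with confidence
max/(sense+antisense) and an abstention margin (uncalled at
confidence ≤ 0.55 by default).

## Synthetic data generator

The generator is the study's stand-in for deposited sequencing data
and defines the conditions the tests assert under.

**Recognition model.** Each variant's survival (colony-forming
fraction in vivo, uncleaved fraction in vitro — one abstraction, two
parameterizations) is `base + d·(recognized − base)`, where the
recognition degree d is 0 unless all *required* rules match and each
unmatched *preferred* rule multiplies d by (1 − strength). The default
planted model — G required at position 5, A preferred at position 7
with strength 2/3, base survival 1.0, recognized survival 0.05 — gives
G5·A7 variants 3× the depletion of G5-only variants, a planted analog
of a strict fifth-position requirement with a weaker seventh-position
preference.

**Sampling.** Control counts are multinomial over a uniform library;
selected counts are multinomial with weights proportional to survival.
The count layer is exposed directly (`simulate_screen_counts`) and is
what the statistical studies run on at full scale (10⁶ molecules for
null/representation checks; 100× ≈ 1.64·10⁶ for recovery, ten seeds).
The read layer wraps each molecule into a backbone/anchor/7N/anchor
cassette (fixed synthetic construct; no real plasmid sequence), with
random window offsets, 50% reverse-complemented reads, per-base Phred
qualities from a clipped normal (mean 30, sd 3), and substitution
errors at probability 10^(−Q/10). Read-level runs are kept to 2·10⁵
molecules per sample — enough to exercise QC, anchoring, strand
handling and error tolerance end to end, since the read layer is
count-preserving plumbing over the molecule layer. All draws flow from
one explicit seed; gzip output pins the archive timestamp, so
identical seeds give byte-identical files.

**What it does not model:** PCR bias, chimeras, index hopping, adapter
read-through, positional quality decay, or library-construction skew
(the uniform control is idealized; real libraries showed > 15,000 of
16,384 variants, which the multinomial control reproduces only as a
coverage floor). Passing tests therefore establish the correctness of
the statistics and reconstruction logic under the stated noise model,
not robustness to every artifact of real sequencing.

**Toy locus.** 10 direct repeats of 36 bp interleaved with nine 31-bp
random spacers, repeat ending in an extended −10-like element; an
upstream tracrRNA region carrying the reverse complement of 24 nt of
the repeat with 2 substitutions; planted species: one mature crRNA per
spacer (25 nt spacer part + 26 nt DR part, on the array's transcription
strand, which runs opposite to the flanking genes), and tracrRNA
products of 70/90/107 nt sharing a 5′ end. End jitter is uniform and
independent per read end.

## Numerical and degenerate-input conventions

- Pseudocounts keep all logs finite; frequencies over a union of
  observed variants sum to 1 within 1e-9.
- χ² of empty margins is 0 (p = 0.5); p-values may underflow to 0.0
  for extreme depletion, which only strengthens a call.
- Empty depleted sets: logo and consensus are input errors / skipped;
  an all-zero wheel is an input error ("nothing depleted to draw").
- Array detection on sequences shorter than the minimum architecture
  returns an empty list, not an error; invalid alphabets are errors.
- IUPAC greedy ties break alphabetically; site-calling ties go to the
  smaller coordinate; promoter-window ties go to the 3′-most window.

## Known limitations

- The hard p-cutoff regime ignores multiplicity beyond the cutoff
  itself; reproducing a specific published depleted-set size on real
  deposited reads would additionally require matching unstated
  pseudocount and zero-count conventions.
- Anchored extraction is designed for amplicon-style screen reads; for
  shotgun data, use the SAM ingestion path.
- The profiler reconstructs species only from end coordinates; it does
  not model coverage along the molecule and cannot separate co-ending
  isoforms.
- ORF calling, protein domain annotation and RNA secondary-structure
  prediction are out of scope; the anti-repeat is evidence for a
  tracrRNA locus, not a structure prediction.
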