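"""Small-RNA profiling: processing-site calling and species reconstruction.

Mature crRNAs and tracrRNA products have defined processed ends, so the
5' and 3' end coordinates of aligned small-RNA reads pile up at the
processing sites. The profiler collects strand-specific end histograms,
calls sites as windowed local maxima, pairs 5' with downstream 3' sites
sharing joint read support, filters products by length (40-130 nt by
default), annotates species against the CRISPR array (crRNA with spacer
and repeat-derived segment lengths, tracrRNA, other) and infers the
transcription orientation of the array.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple

from cascreen.errors import InputError
from cascreen.locus import CrisprArray
from cascreen.seqio import FastqRead, revcomp

logger = logging.getLogger(__name__)


class Alignment(NamedTuple):
    """A placed read: 0-based half-open locus interval and strand."""

    name: str
    start: int
    end: int
    strand: str


@dataclass
class EndHistogram:
    """Strand-specific 5'/3' end counts plus joint (5', 3') pair counts.

    For a read aligned on '+' the 5' end is the leftmost aligned base
    and the 3' end the rightmost (half-open end - 1); on '-' the roles
    swap. Soft-clipped bases are never part of the aligned interval.
    """

    locus_len: int
    pair_counts: dict = field(default_factory=lambda: {"+": Counter(),
                                                       "-": Counter()})

    def five_prime(self, strand: str) -> Counter:
        out = Counter()
        for (five, _three), c in self.pair_counts[strand].items():
            out[five] += c
        return out

    def three_prime(self, strand: str) -> Counter:
        out = Counter()
        for (_five, three), c in self.pair_counts[strand].items():
            out[three] += c
        return out

    def n_alignments(self, strand: str) -> int:
        return sum(self.pair_counts[strand].values())


def collect_ends(alignments: Iterable[Alignment], locus_len: int
                 ) -> EndHistogram:
    """Accumulate 5'/3' end coordinates of primary alignments."""
    hist = EndHistogram(locus_len=locus_len)
    for aln in alignments:
        if not (0 <= aln.start < aln.end <= locus_len) or \
                aln.strand not in ("+", "-"):
            logger.warning("skipping malformed alignment %s", (aln,))
            continue
        if aln.strand == "+":
            five, three = aln.start, aln.end - 1
        else:
            five, three = aln.end - 1, aln.start
        hist.pair_counts[aln.strand][(five, three)] += 1
    return hist


def load_alignments_sam(path: str) -> tuple[list[Alignment], dict[str, int]]:
    """Primary mapped alignments (and reference lengths) from SAM/BAM."""
    import pysam

    alignments = []
    with pysam.AlignmentFile(path, check_sq=False) as sam:
        ref_lens = dict(zip(sam.references, sam.lengths))
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            alignments.append(Alignment(
                rec.query_name, rec.reference_start, rec.reference_end,
                "-" if rec.is_reverse else "+"))
    return alignments, ref_lens


def place_reads_exact(reads: Iterable[FastqRead], locus_seq: str
                      ) -> list[Alignment]:
    """Exact-substring placement of reads on a locus (both strands).

    A desk-scale stand-in for read alignment of error-free synthetic
    reads; reads absent from the locus are skipped with a warning, and
    multi-mapping reads take their leftmost placement.
    """
    placements = []
    n_missed = 0
    for read in reads:
        pos = locus_seq.find(read.seq)
        if pos >= 0:
            placements.append(Alignment(read.name, pos, pos + len(read.seq), "+"))
            continue
        rc = revcomp(read.seq)
        pos = locus_seq.find(rc)
        if pos >= 0:
            placements.append(Alignment(read.name, pos, pos + len(rc), "-"))
        else:
            n_missed += 1
    if n_missed:
        logger.warning("%d reads had no exact placement on the locus", n_missed)
    return placements


@dataclass(frozen=True)
class RnaAnnotation:
    kind: str  # crRNA | tracrRNA | other
    index: int | None = None
    spacer_part_len: int | None = None
    dr_part_len: int | None = None
    product_len: int | None = None


@dataclass(frozen=True)
class RnaSpecies:
    """A reconstructed small-RNA product."""

    start: int
    end: int
    strand: str
    support: int
    annotation: RnaAnnotation | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


def _call_sites(counts: Counter, min_support: int, window: int) -> list[int]:
    """Windowed local maxima of an end histogram.

    A coordinate is a site if its count reaches ``min_support`` and no
    coordinate within +/- ``window`` has a larger count (ties go to the
    smaller coordinate).
    """
    sites = []
    for pos, count in counts.items():
        if count < min_support:
            continue
        dominated = False
        for other in range(pos - window, pos + window + 1):
            oc = counts.get(other, 0)
            if oc > count or (oc == count and other < pos):
                dominated = True
                break
        if not dominated:
            sites.append(pos)
    return sorted(sites)


def reconstruct_species(hist: EndHistogram, min_support: int = 5,
                        end_window: int = 3,
                        len_band: tuple[int, int] = (40, 130)
                        ) -> list[RnaSpecies]:
    """Reconstruct RNA species from called 5' and 3' processing sites.

    Each 5' site is paired with every downstream 3' site on the same
    strand whose implied product length falls inside ``len_band`` and
    whose joint support (reads with both ends within ``end_window`` of
    the respective sites) reaches ``min_support``.
    """
    if min_support < 1:
        raise InputError("min_support must be >= 1")
    lmin, lmax = len_band
    species = []
    for strand in ("+", "-"):
        pairs = hist.pair_counts[strand]
        if not pairs:
            continue
        five_sites = _call_sites(hist.five_prime(strand), min_support,
                                 end_window)
        three_sites = _call_sites(hist.three_prime(strand), min_support,
                                  end_window)
        for f in five_sites:
            for t in three_sites:
                if strand == "+":
                    if t < f:
                        continue
                    length = t - f + 1
                else:
                    if t > f:
                        continue
                    length = f - t + 1
                if not (lmin <= length <= lmax):
                    continue
                support = sum(
                    c for (pf, pt), c in pairs.items()
                    if abs(pf - f) <= end_window and abs(pt - t) <= end_window)
                if support < min_support:
                    continue
                start, end = (f, t + 1) if strand == "+" else (t, f + 1)
                species.append(RnaSpecies(start=start, end=end, strand=strand,
                                          support=support))
    species.sort(key=lambda s: (s.start, s.end, s.strand))
    return species


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def annotate_species(species: list[RnaSpecies], array: CrisprArray,
                     tracr_interval: tuple[int, int] | None = None
                     ) -> list[RnaSpecies]:
    """Annotate species as crRNA / tracrRNA / other against the array.

    A species overlapping exactly one spacer becomes a crRNA; its index
    counts spacers from the transcription-proximal end (per the array's
    strand), and the spacer/DR part lengths are its overlaps with that
    spacer and with the flanking repeats. Species overlapping the tracr
    region become tracrRNA products; anything else is 'other'.
    """
    spacer_ivs = array.spacer_intervals
    n_spacers = len(spacer_ivs)
    repeat_ivs = array.repeat_intervals
    out = []
    for sp in species:
        overlapping = [i for i, (s0, s1) in enumerate(spacer_ivs)
                       if _overlap(sp.start, sp.end, s0, s1) > 0]
        ann = None
        if len(overlapping) == 1:
            i = overlapping[0]
            index = (n_spacers - i) if array.strand == "-" else (i + 1)
            s0, s1 = spacer_ivs[i]
            spacer_part = _overlap(sp.start, sp.end, s0, s1)
            dr_part = sum(_overlap(sp.start, sp.end, r0, r1)
                          for r0, r1 in repeat_ivs)
            ann = RnaAnnotation(kind="crRNA", index=index,
                                spacer_part_len=spacer_part,
                                dr_part_len=dr_part)
        elif len(overlapping) >= 2:
            logger.warning("species %d-%d overlaps %d spacers; "
                           "annotated 'other'", sp.start, sp.end,
                           len(overlapping))
            ann = RnaAnnotation(kind="other")
        elif tracr_interval is not None and \
                _overlap(sp.start, sp.end, *tracr_interval) > 0:
            ann = RnaAnnotation(kind="tracrRNA", product_len=sp.length)
        else:
            ann = RnaAnnotation(kind="other")
        out.append(replace(sp, annotation=ann))
    return out


@dataclass(frozen=True)
class OrientationCall:
    """Transcription orientation of the CRISPR array from read strand bias."""

    array_strand: str | None
    read_count_sense: int
    read_count_antisense: int
    confidence: float
    status: str  # called | uncalled

    @property
    def called(self) -> bool:
        return self.status == "called"


def call_orientation(hist: EndHistogram, array: CrisprArray,
                     margin: float = 0.05) -> OrientationCall:
    """Majority strand of array-overlapping reads decides orientation.

    Confidence is max/(sense + antisense); the call is withheld
    (status 'uncalled') when confidence <= 0.5 + margin or when no read
    overlaps the array.
    """
    a0, a1 = array.span
    counts = {"+": 0, "-": 0}
    for strand in ("+", "-"):
        for (five, three), c in hist.pair_counts[strand].items():
            lo, hi = min(five, three), max(five, three) + 1
            if _overlap(lo, hi, a0, a1) > 0:
                counts[strand] += c
    total = counts["+"] + counts["-"]
    if total == 0:
        return OrientationCall(None, 0, 0, 0.0, "uncalled")
    winner = "+" if counts["+"] >= counts["-"] else "-"
    confidence = counts[winner] / total
    if confidence <= 0.5 + margin:
        return OrientationCall(None, counts["+"], counts["-"], confidence,
                               "uncalled")
    return OrientationCall(winner, counts[winner], counts["+" if winner == "-"
                                                          else "-"],
                           confidence, "called")
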