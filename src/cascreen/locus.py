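"""CRISPR locus annotation: repeat-spacer arrays, anti-repeats, promoters.

Array detection re-implements the classic repeat-finding task: nominate
candidate repeat runs from recurring seed k-mers whose occurrence gaps
fit the repeat+spacer period band, then greedily extend the aligned
copies column by column under a per-copy mismatch budget. Anti-repeat
(tracrRNA) candidates are found by local alignment of the repeat
consensus against both strands of the locus, and a small position-count
scorer flags extended -10 promoter-like elements inside repeats (Type
II-C arrays can be transcribed from promoters embedded in the repeats).

Coordinates are 0-based half-open throughout; human-readable exports
convert to 1-based inclusive.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import Align

from cascreen.errors import InputError
from cascreen.seqio import revcomp

logger = logging.getLogger(__name__)

_DNA = frozenset("ACGT")

#: default extended -10 promoter consensus (TG dinucleotide + spacer N +
#: TATAAT box); configurable because reported motifs vary by study
EXTENDED_MINUS10 = "TGNTATAAT"


@dataclass(frozen=True)
class RepeatUnit:
    """One repeat (+ following spacer) of an array; last unit may lack a
    spacer, in which case spacer_start/spacer_end are None."""

    repeat_start: int
    repeat_end: int
    spacer_start: int | None = None
    spacer_end: int | None = None

    @property
    def spacer_length(self) -> int | None:
        if self.spacer_start is None:
            return None
        return self.spacer_end - self.spacer_start


@dataclass
class CrisprArray:
    """An ordered repeat-spacer array on a contig.

    ``strand`` is the strand the array was reported on; the direction of
    transcription is decided downstream from small-RNA evidence.
    """

    contig_id: str
    strand: str
    units: list[RepeatUnit]
    repeat_consensus: str

    @property
    def n_repeats(self) -> int:
        return len(self.units)

    @property
    def spacer_lengths(self) -> list[int]:
        return [u.spacer_length for u in self.units if u.spacer_length is not None]

    @property
    def repeat_intervals(self) -> list[tuple[int, int]]:
        return [(u.repeat_start, u.repeat_end) for u in self.units]

    @property
    def spacer_intervals(self) -> list[tuple[int, int]]:
        return [(u.spacer_start, u.spacer_end) for u in self.units
                if u.spacer_start is not None]

    @property
    def span(self) -> tuple[int, int]:
        return self.units[0].repeat_start, self.units[-1].repeat_end

    def validate(self) -> None:
        prev_end = -1
        for u in self.units:
            if not (u.repeat_start < u.repeat_end):
                raise InputError("empty repeat interval")
            if u.repeat_start < prev_end:
                raise InputError("array units overlap or are unsorted")
            prev_end = u.repeat_end
            if u.spacer_start is not None:
                if u.spacer_start != u.repeat_end or u.spacer_end <= u.spacer_start:
                    raise InputError("spacer must directly follow its repeat")
                prev_end = u.spacer_end


@dataclass(frozen=True)
class AntiRepeatHit:
    """A partial reverse-complement match of the repeat outside the array."""

    start: int
    end: int
    strand: str
    matched_len: int
    identity_fraction: float
    alignment_score: float


@dataclass(frozen=True)
class PromoterMotifScore:
    """Best extended -10-like window within a repeat."""

    repeat_index: int
    window_start_in_repeat: int
    score: int
    matched_window: str


def _check_dna(sequence: str) -> str:
    if not sequence:
        raise InputError("empty sequence")
    seq = sequence.upper()
    bad = set(seq) - _DNA
    if bad:
        raise InputError(f"invalid DNA characters: {sorted(bad)}")
    return seq


# ---------------------------------------------------------------------------
# array detection
# ---------------------------------------------------------------------------

def _seed_chains(seq: str, k: int, gap_band: tuple[int, int],
                 min_units: int) -> list[list[int]]:
    """Maximal chains of recurring k-mer positions with period-band gaps."""
    positions: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        positions[seq[i:i + k]].append(i)
    lo, hi = gap_band
    chains = []
    for pos_list in positions.values():
        if len(pos_list) < min_units:
            continue
        chain = [pos_list[0]]
        for p in pos_list[1:]:
            if lo <= p - chain[-1] <= hi:
                chain.append(p)
            else:
                if len(chain) >= min_units:
                    chains.append(chain)
                chain = [p]
        if len(chain) >= min_units:
            chains.append(chain)
    return chains


def _column(seq: str, anchors: Sequence[int], offset: int) -> list[str]:
    return [seq[a + offset] for a in anchors]


def _consensus_base(column: Iterable[str]) -> str:
    counts = Counter(column)
    best = max(counts.items(), key=lambda kv: (kv[1], -ord(kv[0])))
    # ties broken alphabetically
    top = best[1]
    return min(b for b, c in counts.items() if c == top)


def _extend_run(seq: str, anchors: list[int], k: int,
                repeat_band: tuple[int, int], spacer_band: tuple[int, int],
                max_mm: int) -> tuple[int, int, list[int]] | None:
    """Greedy left/right extension of the seeded repeat copies.

    Returns (left_ext, right_ext, per-copy mismatch counts) or None if
    the result violates the bands. A column is accepted when at most one
    copy deviates from its consensus and no copy exceeds the mismatch
    budget; a column carrying an outlier is additionally required to be
    followed (further out) by a fully conserved column, which keeps
    boundaries crisp against random spacer sequence while still crossing
    isolated substitutions inside degenerate repeat copies.
    """
    m = len(anchors)
    rmin, rmax = repeat_band
    smin, _smax = spacer_band
    mismatches = [0] * m
    left, right = 0, 0

    def gap_ok(replen: int) -> bool:
        return all(anchors[i + 1] - anchors[i] - replen >= smin
                   for i in range(m - 1))

    def column_outliers(offset: int) -> list[int] | None:
        if anchors[0] + offset < 0 or anchors[-1] + offset >= len(seq):
            return None
        col = _column(seq, anchors, offset)
        cons = _consensus_base(col)
        return [i for i, b in enumerate(col) if b != cons]

    def try_side(offset: int, step: int) -> list[int] | None:
        outliers = column_outliers(offset)
        if outliers is None or len(outliers) > 1:
            return None
        if any(mismatches[i] + 1 > max_mm for i in outliers):
            return None
        if outliers:
            lookahead = column_outliers(offset + step)
            if lookahead is None or lookahead:
                return None
        return outliers

    while left + k + right < rmax:
        replen = left + k + right + 1
        if not gap_ok(replen):
            break
        out_l = try_side(-left - 1, -1)
        out_r = try_side(k + right, +1)
        if out_l is not None and (out_r is None or len(out_l) <= len(out_r)):
            for i in out_l:
                mismatches[i] += 1
            left += 1
        elif out_r is not None:
            for i in out_r:
                mismatches[i] += 1
            right += 1
        else:
            break
    replen = left + k + right
    if not (rmin <= replen <= rmax):
        return None
    return left, right, mismatches


def detect_array(sequence: str, repeat_len_band: tuple[int, int] = (23, 50),
                 spacer_len_band: tuple[int, int] = (20, 60),
                 min_units: int = 3, max_repeat_mismatches: int = 3,
                 contig_id: str = "contig", k: int = 8,
                 strand: str = "+") -> list[CrisprArray]:
    """Detect repeat-spacer arrays in a locus sequence.

    Every maximal run of >= ``min_units`` near-identical repeats (each
    within ``max_repeat_mismatches`` of the run consensus) separated by
    spacers within the spacer band is reported, on the strand as given.
    A sequence with no array yields an empty list.
    """
    seq = _check_dna(sequence)
    rmin, rmax = repeat_len_band
    smin, smax = spacer_len_band
    if rmin > rmax or smin > smax or rmin < k:
        raise InputError("length bands are inconsistent (and repeat min >= k)")
    if len(seq) < min_units * (rmin + smin):
        return []

    gap_band = (rmin + smin, rmax + smax)
    candidates = []
    for chain in _seed_chains(seq, k, gap_band, min_units):
        ext = _extend_run(seq, chain, k, repeat_len_band, spacer_len_band,
                          max_repeat_mismatches)
        if ext is None:
            continue
        left, right, _mm = ext
        replen = left + k + right
        starts = [a - left for a in chain]
        spacer_lens = [starts[i + 1] - starts[i] - replen
                       for i in range(len(starts) - 1)]
        if not all(smin <= s <= smax for s in spacer_lens):
            continue
        candidates.append((starts, replen))

    # prefer candidates with more units, then longer repeats, then position;
    # accept greedily without span overlap (one array per region)
    candidates.sort(key=lambda c: (-len(c[0]), -c[1], c[0][0]))
    accepted: list[tuple[list[int], int]] = []
    spans: list[tuple[int, int]] = []
    for starts, replen in candidates:
        lo, hi = starts[0], starts[-1] + replen
        if any(lo < e and s < hi for s, e in spans):
            continue
        accepted.append((starts, replen))
        spans.append((lo, hi))

    arrays = []
    for starts, replen in sorted(accepted, key=lambda c: c[0][0]):
        units = []
        for i, s in enumerate(starts):
            if i < len(starts) - 1:
                units.append(RepeatUnit(s, s + replen, s + replen,
                                        starts[i + 1]))
            else:
                units.append(RepeatUnit(s, s + replen))
        consensus = "".join(
            _consensus_base([seq[s + off] for s in starts])
            for off in range(replen))
        arr = CrisprArray(contig_id=contig_id, strand=strand, units=units,
                          repeat_consensus=consensus)
        arr.validate()
        arrays.append(arr)
    return arrays


# ---------------------------------------------------------------------------
# anti-repeat discovery
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner


def _alignment_stats(alignment, target: str, query: str
                     ) -> tuple[int, int, int, int]:
    """(target_start, target_end, matched_len, n_matches) of a local hit.

    Terminal mismatching columns are trimmed: co-optimal local
    alignments can end in a mismatch (a +1/-1 pair is score-neutral),
    and the trimmed form is the canonical representative.
    """
    t_blocks, q_blocks = alignment.aligned
    columns: list[tuple[int, bool]] = []  # (target index, is_match)
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        for i in range(te - ts):
            columns.append((ts + i, target[ts + i] == query[qs + i]))
    while columns and not columns[0][1]:
        columns.pop(0)
    while columns and not columns[-1][1]:
        columns.pop()
    if not columns:
        return 0, 0, 0, 0
    matched = len(columns)
    matches = sum(1 for _, ok in columns if ok)
    return columns[0][0], columns[-1][0] + 1, matched, matches


def _mask(seq: list[str], start: int, end: int) -> None:
    for i in range(start, end):
        seq[i] = "x"


def find_anti_repeat(sequence: str, repeat_consensus: str,
                     exclude: Sequence[tuple[int, int]] = (),
                     min_matched_len: int = 15,
                     min_identity: float = 0.8,
                     max_hits: int = 50) -> list[AntiRepeatHit]:
    """Find partial (reverse-)complement matches of the repeat consensus.

    The consensus is locally aligned (match +1, mismatch -1, gap open/
    extend -2/-1) against the sequence and its reverse complement,
    outside the excluded intervals (which should cover the array's own
    repeats). Hits passing both the matched-length and identity
    thresholds are returned sorted by descending alignment score; a hit
    on strand '-' means the anti-repeat is the reverse complement of the
    repeat on the forward sequence.
    """
    seq = _check_dna(sequence)
    if not repeat_consensus:
        raise InputError("repeat_consensus must be non-empty")
    query = _check_dna(repeat_consensus)
    if not (0 < min_identity <= 1):
        raise InputError("min_identity must be in (0, 1]")
    if min_matched_len < 1:
        raise InputError("min_matched_len must be >= 1")
    aligner = _make_aligner()
    n = len(seq)
    score_floor = max(1.0, min_matched_len * (2 * min_identity - 1))

    hits: list[AntiRepeatHit] = []
    for strand in ("+", "-"):
        chars = list(seq)
        for s, e in exclude:
            _mask(chars, max(0, s), min(n, e))
        masked = "".join(chars)
        # 'x' has no complement and passes through revcomp unchanged
        target_seq = masked if strand == "+" else revcomp(masked)
        for _ in range(max_hits):
            alignments = aligner.align(target_seq, query)
            if not len(alignments):
                break
            best = alignments[0]
            if best.score < score_floor:
                break
            ts, te, matched, matches = _alignment_stats(best, target_seq, query)
            identity = matches / matched if matched else 0.0
            if strand == "+":
                start, end = ts, te
            else:
                start, end = n - te, n - ts
            if matched >= min_matched_len and identity >= min_identity:
                hits.append(AntiRepeatHit(start=int(start), end=int(end),
                                          strand=strand,
                                          matched_len=int(matched),
                                          identity_fraction=float(identity),
                                          alignment_score=float(best.score)))
            chars2 = list(target_seq)
            _mask(chars2, ts, te)
            target_seq = "".join(chars2)
    hits.sort(key=lambda h: (-h.alignment_score, h.start))
    return hits


# ---------------------------------------------------------------------------
# promoter-like motif scoring
# ---------------------------------------------------------------------------

def score_promoter_motif(repeat_consensus: str,
                         consensus_model: str = EXTENDED_MINUS10,
                         terminal_region: int | None = None,
                         repeat_index: int = 0) -> PromoterMotifScore:
    """Score the best extended -10-like window of a repeat.

    Every window of ``len(consensus_model)`` nt (optionally restricted to
    the terminal ``terminal_region`` nt of the repeat, the 3' end) is
    scored as the number of non-N model positions it matches; N positions
    are wildcards. On ties the window closest to the repeat 3' terminus
    wins.
    """
    repeat = _check_dna(repeat_consensus)
    model = consensus_model.upper()
    w = len(model)
    if len(repeat) < w:
        raise InputError("repeat shorter than the motif window")
    lo = 0 if terminal_region is None else max(0, len(repeat) - terminal_region)
    best: tuple[int, int] | None = None  # (score, start)
    for start in range(lo, len(repeat) - w + 1):
        window = repeat[start:start + w]
        score = sum(1 for a, b in zip(window, model)
                    if b != "N" and a == b)
        if best is None or score > best[0] or (score == best[0]
                                               and start > best[1]):
            best = (score, start)
    score, start = best
    return PromoterMotifScore(repeat_index=repeat_index,
                              window_start_in_repeat=start,
                              score=score,
                              matched_window=repeat[start:start + w])
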