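"""Core statistics of the 7N PAM depletion screen.

A degenerate PAM library (4^7 = 16,384 members for the default 7-nt
region) is subjected to negative selection — in vivo plasmid interference
or in vitro cleavage — and sequenced alongside an unselected control.
This module turns the raw reads into per-PAM counts, per-PAM depletion
statistics (log2 frequency ratio, one-sided Pearson chi-square),
significance calls at a hard p-value cutoff, positional depletion values
and an IUPAC consensus of the depleted set.

The chi-square for each PAM variant is computed on the 2x2 table

    [[count_exp, n_exp - count_exp],
     [count_ctrl, n_ctrl - count_ctrl]]

(variant vs rest-of-library, experiment vs control), which reduces to the
standard two-proportion test. One-sidedness is obtained from the normal
upper tail of the signed square root of the chi-square statistic, signed
positive when the variant is rarer in the experiment than in the control;
variants *enriched* in the experiment therefore get p >= 0.5.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from cascreen.errors import InputError
from cascreen.seqio import FastqRead, mean_quality, revcomp

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_SET = frozenset(BASES)

#: minimal IUPAC nucleotide codes, keyed by the base set they denote
IUPAC_CODES: dict[frozenset, str] = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y",
    frozenset("CG"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}


def all_pams(length: int = 7) -> list[str]:
    """Enumerate the full degenerate library (4**length variants)."""
    return ["".join(p) for p in itertools.product(BASES, repeat=length)]


@dataclass(frozen=True)
class ScreenDesign:
    """Geometry of the screen construct around the degenerate region.

    The PAM is read on the non-target strand immediately downstream (3')
    of the protospacer; ``left_anchor`` and ``right_anchor`` are the fixed
    construct sequences flanking the randomized stretch.
    """

    left_anchor: str
    right_anchor: str
    degenerate_len: int = 7
    pam_side: str = "3prime"

    def __post_init__(self):
        for name in ("left_anchor", "right_anchor"):
            anchor = getattr(self, name)
            if not anchor or set(anchor) - _BASE_SET:
                raise InputError(f"{name} must be a non-empty ACGT string")
        if self.degenerate_len < 1:
            raise InputError("degenerate_len must be >= 1")
        if self.pam_side not in ("3prime", "5prime"):
            raise InputError("pam_side must be '3prime' or '5prime'")

    def to_dict(self) -> dict:
        return {
            "left_anchor": self.left_anchor,
            "right_anchor": self.right_anchor,
            "degenerate_len": self.degenerate_len,
            "pam_side": self.pam_side,
        }


@dataclass
class PamCountTable:
    """Per-sample counts of PAM variants with read-accounting metadata."""

    sample_id: str
    counts: Counter = field(default_factory=Counter)
    n_reads_total: int = 0
    n_reads_pass_qc: int = 0
    n_reads_anchored: int = 0
    degenerate_len: int = 7

    @property
    def distinct_variants(self) -> int:
        return sum(1 for c in self.counts.values() if c > 0)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def validate(self) -> None:
        if self.total != self.n_reads_anchored:
            raise InputError("sum(counts) != n_reads_anchored")
        if not (self.n_reads_anchored <= self.n_reads_pass_qc <= self.n_reads_total):
            raise InputError("read accounting violated: anchored <= pass_qc <= total")
        for pam in self.counts:
            if len(pam) != self.degenerate_len or set(pam) - _BASE_SET:
                raise InputError(f"invalid PAM key {pam!r}")

    @classmethod
    def from_counts(cls, counts: Mapping[str, int], sample_id: str = "sample",
                    degenerate_len: int = 7) -> "PamCountTable":
        """Build a table straight from molecule counts (no read layer)."""
        c = Counter({k: int(v) for k, v in counts.items() if v > 0})
        n = sum(c.values())
        tab = cls(sample_id=sample_id, counts=c, n_reads_total=n,
                  n_reads_pass_qc=n, n_reads_anchored=n,
                  degenerate_len=degenerate_len)
        tab.validate()
        return tab

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"pam": list(self.counts), "count": list(self.counts.values())}
        ).sort_values("pam", ignore_index=True)
        return df


def qc_filter_reads(reads: Iterable[FastqRead], min_mean_q: float = 20.0
                    ) -> Iterator[FastqRead]:
    """Keep reads whose mean Phred quality is >= ``min_mean_q`` (inclusive)."""
    for read in reads:
        if mean_quality(read.qual) >= min_mean_q:
            yield read


def _hamming_le(a: str, b: str, limit: int) -> bool:
    """True if Hamming(a, b) <= limit (equal lengths assumed)."""
    mismatches = 0
    for x, y in zip(a, b):
        if x != y:
            mismatches += 1
            if mismatches > limit:
                return False
    return True


def _find_approx(seq: str, pattern: str, max_mm: int) -> int:
    """Leftmost position where ``pattern`` occurs in ``seq`` with <= max_mm
    mismatches; -1 if absent. Exact ``str.find`` is the fast path."""
    pos = seq.find(pattern)
    if pos >= 0:
        return pos
    if max_mm == 0:
        return -1
    m = len(pattern)
    for i in range(len(seq) - m + 1):
        if _hamming_le(seq[i:i + m], pattern, max_mm):
            return i
    return -1


def _extract_one(seq: str, design: ScreenDesign, max_mm: int) -> str | None:
    """Pull the degenerate region out of one read orientation, or None."""
    k = design.degenerate_len
    left, right = design.left_anchor, design.right_anchor
    pos = _find_approx(seq, left, max_mm)
    while pos >= 0:
        pam_start = pos + len(left)
        pam_end = pam_start + k
        if pam_end + len(right) <= len(seq):
            if _hamming_le(seq[pam_end:pam_end + len(right)], right, max_mm):
                pam = seq[pam_start:pam_end]
                if not set(pam) - _BASE_SET:
                    return pam
        # exact left-anchor hit may be a coincidence; try the next one
        nxt = seq.find(left, pos + 1)
        pos = nxt
    return None


def extract_pam_regions(reads: Iterable[FastqRead], design: ScreenDesign,
                        max_anchor_mismatches: int = 1, *,
                        sample_id: str = "sample",
                        n_reads_total: int | None = None,
                        dedup_names: bool = True,
                        min_anchored_fraction: float = 0.5) -> PamCountTable:
    """Count PAM variants by anchored extraction of the degenerate region.

    Each (QC-passing) read, or its reverse complement, must contain the
    left anchor and the right anchor with at most ``max_anchor_mismatches``
    each, separated by exactly ``degenerate_len`` unambiguous bases; that
    7-mer is counted. Paired mates carry the same read name, so name-level
    deduplication prevents double counting of a molecule.
    """
    if min(len(design.left_anchor), len(design.right_anchor)) < 12:
        raise InputError("anchors must each be >= 12 nt for reliable anchoring")
    counts: Counter = Counter()
    seen: set[str] = set()
    n_pass = 0
    n_anchored = 0
    for read in reads:
        n_pass += 1
        if dedup_names:
            if read.name in seen:
                continue
            seen.add(read.name)
        pam = _extract_one(read.seq, design, max_anchor_mismatches)
        if pam is None:
            pam = _extract_one(revcomp(read.seq), design, max_anchor_mismatches)
        if pam is not None:
            counts[pam] += 1
            n_anchored += 1
    total = n_pass if n_reads_total is None else n_reads_total
    if n_pass and n_anchored / n_pass < min_anchored_fraction:
        logger.warning(
            "sample %s: only %d/%d QC-passing reads anchored (< %.0f%%); "
            "check the screen design anchors", sample_id, n_anchored, n_pass,
            100 * min_anchored_fraction)
    table = PamCountTable(sample_id=sample_id, counts=counts,
                          n_reads_total=total, n_reads_pass_qc=n_pass,
                          n_reads_anchored=n_anchored,
                          degenerate_len=design.degenerate_len)
    table.validate()
    return table


# ---------------------------------------------------------------------------
# depletion statistics
# ---------------------------------------------------------------------------

#: fixed column order of the depletion table
DEPLETION_COLUMNS = ["count_exp", "count_ctrl", "freq_exp", "freq_ctrl",
                     "depletion_score", "chi2", "p_one_sided", "depleted_flag"]


def compute_depletion(exp: PamCountTable, ctrl: PamCountTable,
                      pseudocount: float = 0.5) -> pd.DataFrame:
    """Join experiment and control counts into per-PAM depletion statistics.

    Returns a DataFrame indexed by PAM 7-mer with columns
    ``count_exp, count_ctrl, freq_exp, freq_ctrl, depletion_score, chi2,
    p_one_sided, depleted_flag``. Frequencies are pseudocounted over the
    union of observed variants and each sum to 1; ``depletion_score`` is
    log2(freq_ctrl / freq_exp). The chi-square and its one-sided p-value
    use the raw counts (see module docstring for the construction).
    """
    if pseudocount <= 0:
        raise InputError("pseudocount must be > 0")
    if not ctrl.counts:
        raise InputError("control count table is empty")
    if not exp.counts:
        raise InputError("experimental count table is empty")
    keys = sorted(set(exp.counts) | set(ctrl.counts))
    c_exp = np.array([exp.counts.get(k, 0) for k in keys], dtype=np.float64)
    c_ctrl = np.array([ctrl.counts.get(k, 0) for k in keys], dtype=np.float64)
    n_exp, n_ctrl = c_exp.sum(), c_ctrl.sum()
    if n_exp == 0 or n_ctrl == 0:
        raise InputError("zero total counts")

    freq_exp = (c_exp + pseudocount) / (n_exp + pseudocount * len(keys))
    freq_ctrl = (c_ctrl + pseudocount) / (n_ctrl + pseudocount * len(keys))
    depletion_score = np.log2(freq_ctrl / freq_exp)

    chi2 = _chi2_two_proportion(c_exp, n_exp, c_ctrl, n_ctrl)
    sign = np.sign(c_ctrl / n_ctrl - c_exp / n_exp)
    z = sign * np.sqrt(chi2)
    p_one_sided = stats.norm.sf(z)

    df = pd.DataFrame(
        {
            "count_exp": c_exp.astype(np.int64),
            "count_ctrl": c_ctrl.astype(np.int64),
            "freq_exp": freq_exp,
            "freq_ctrl": freq_ctrl,
            "depletion_score": depletion_score,
            "chi2": chi2,
            "p_one_sided": p_one_sided,
            "depleted_flag": np.zeros(len(keys), dtype=bool),
        },
        index=pd.Index(keys, name="pam"),
    )
    return df


def _chi2_two_proportion(c_exp: np.ndarray, n_exp: float,
                         c_ctrl: np.ndarray, n_ctrl: float) -> np.ndarray:
    """Vectorized Pearson chi-square of [[a, n_exp-a], [c, n_ctrl-c]]."""
    a, b = c_exp, n_exp - c_exp
    c, d = c_ctrl, n_ctrl - c_ctrl
    n = n_exp + n_ctrl
    row1 = a + c
    row2 = b + d
    denom = row1 * row2 * n_exp * n_ctrl
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = n * (a * d - b * c) ** 2 / denom
    chi2 = np.where(denom == 0, 0.0, chi2)
    return chi2


def call_depleted(table: pd.DataFrame, p_threshold: float = 1e-12) -> set[str]:
    """Variants rarer in the experiment with one-sided p below threshold.

    Sets ``depleted_flag`` in place and returns the set of called PAMs.
    """
    if not (0 < p_threshold < 1):
        raise InputError("p_threshold must be in (0, 1)")
    mask = (table["freq_exp"] < table["freq_ctrl"]) & \
           (table["p_one_sided"] < p_threshold)
    table["depleted_flag"] = mask.to_numpy()
    return set(table.index[mask])


@dataclass
class PositionProfile:
    """Per-position, per-base depletion values and frequencies.

    Arrays are (positions x 4) with base columns ordered A, C, G, T and
    rows for PAM positions 1..k (moving away from the protospacer).
    ``freq_depleted`` is the unweighted base frequency within the depleted
    set (each depleted PAM counted once, as for a sequence-list logo); it
    is None when no depleted set was supplied.
    """

    depletion_value: np.ndarray
    freq_exp: np.ndarray
    freq_ctrl: np.ndarray
    freq_depleted: np.ndarray | None = None

    @property
    def k(self) -> int:
        return self.depletion_value.shape[0]

    def argmax_cell(self) -> tuple[int, str]:
        """(position 1..k, base) of the largest depletion value."""
        i, j = np.unravel_index(np.argmax(self.depletion_value),
                                self.depletion_value.shape)
        return int(i) + 1, BASES[int(j)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(self.k):
            for j, base in enumerate(BASES):
                row = {
                    "position": i + 1,
                    "base": base,
                    "depletion_value": self.depletion_value[i, j],
                    "freq_exp": self.freq_exp[i, j],
                    "freq_ctrl": self.freq_ctrl[i, j],
                }
                if self.freq_depleted is not None:
                    row["freq_depleted"] = self.freq_depleted[i, j]
                rows.append(row)
        return pd.DataFrame(rows)


def _position_base_counts(pams: Sequence[str], weights: np.ndarray, k: int
                          ) -> np.ndarray:
    """Sum of ``weights`` per (position, base) over the PAM strings."""
    out = np.zeros((k, 4), dtype=np.float64)
    index = {b: j for j, b in enumerate(BASES)}
    for pam, w in zip(pams, weights):
        for i in range(k):
            out[i, index[pam[i]]] += w
    return out


def position_depletion(table: pd.DataFrame, depleted: set[str] | None = None,
                       pseudocount: float = 0.5) -> PositionProfile:
    """Positional depletion values from the joined count table.

    For position i and base b, the depletion value is
    ``log2(F_ctrl(i, b) / F_exp(i, b))`` where ``F_s`` is the
    count-weighted (pseudocounted) frequency of base b at position i in
    sample s. Base frequencies within the depleted set are reported
    alongside when ``depleted`` is given.
    """
    pams = list(table.index)
    k = len(pams[0])
    cnt_exp = _position_base_counts(pams, table["count_exp"].to_numpy(float), k)
    cnt_ctrl = _position_base_counts(pams, table["count_ctrl"].to_numpy(float), k)
    f_exp = (cnt_exp + pseudocount) / (cnt_exp + pseudocount).sum(axis=1, keepdims=True)
    f_ctrl = (cnt_ctrl + pseudocount) / (cnt_ctrl + pseudocount).sum(axis=1, keepdims=True)
    depletion = np.log2(f_ctrl / f_exp)
    freq_depleted = None
    if depleted:
        dep = sorted(depleted)
        cnt_dep = _position_base_counts(dep, np.ones(len(dep)), k)
        freq_depleted = cnt_dep / cnt_dep.sum(axis=1, keepdims=True)
    return PositionProfile(depletion_value=depletion, freq_exp=f_exp,
                           freq_ctrl=f_ctrl, freq_depleted=freq_depleted)


@dataclass(frozen=True)
class PamConsensus:
    """IUPAC consensus of the depleted set with the thresholds used."""

    iupac: str
    dominance_threshold: float
    per_position_sets: tuple[frozenset, ...]

    def __str__(self) -> str:
        return self.iupac


def call_consensus(depleted_set_freqs: np.ndarray,
                   dominance_threshold: float = 0.75) -> PamConsensus:
    """Greedy per-position IUPAC consensus of depleted-set base frequencies.

    At each position, bases are added in order of descending frequency
    (ties broken alphabetically) until their summed frequency reaches the
    dominance threshold, and the IUPAC code of that set is emitted (all
    four bases -> N). An ambiguity guard then also includes any excluded
    base whose frequency is at least half that of the last included base:
    a base carrying a comparable share of the depleted set is not
    evidence of specificity, so near-uniform positions robustly yield N
    instead of an arbitrary three-base code.
    """
    if not (0.25 < dominance_threshold <= 1):
        raise InputError("dominance_threshold must be in (0.25, 1]")
    freqs = np.asarray(depleted_set_freqs, dtype=float)
    codes = []
    sets = []
    for i in range(freqs.shape[0]):
        order = sorted(range(4), key=lambda j: (-freqs[i, j], BASES[j]))
        chosen: list[str] = []
        acc = 0.0
        last = 0.0
        for j in order:
            chosen.append(BASES[j])
            acc += freqs[i, j]
            last = freqs[i, j]
            if acc >= dominance_threshold - 1e-12:
                break
        for j in order[len(chosen):]:
            if freqs[i, j] >= 0.5 * last:
                chosen.append(BASES[j])
        key = frozenset(chosen)
        sets.append(key)
        codes.append(IUPAC_CODES[key])
    return PamConsensus(iupac="".join(codes),
                        dominance_threshold=dominance_threshold,
                        per_position_sets=tuple(sets))
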