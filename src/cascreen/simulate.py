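"""Synthetic data generators for the screen and small-RNA analyses.

The generators produce inputs with the statistical structure the pipeline
assumes, plus a machine-readable truth record, so every downstream claim
can be checked against a planted ground truth:

* a 4^7-member degenerate PAM library sampled multinomially into control
  and selected (experimental) pools, where each variant's survival is
  given by a planted recognition model;
* screen reads built as backbone / left anchor / 7N / right anchor
  cassettes with per-base Phred qualities and quality-derived
  substitution errors;
* small-RNA reads drawn from planted RNA species on a toy CRISPR locus,
  with uniform end jitter.

Interference (in vivo) and cleavage (in vitro) screens share the survival
abstraction: survival is the colony-forming fraction in vivo and the
non-cleaved fraction in vitro — one code path, two parameterizations.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from cascreen.errors import InputError
from cascreen.locus import CrisprArray, RepeatUnit
from cascreen.screen import BASES, PamCountTable, ScreenDesign, all_pams
from cascreen.seqio import FastqRead, revcomp, write_fastq

# Fixed synthetic construct context. The cassette mirrors the screen
# layout — protospacer 3' end as the left anchor, vector sequence as the
# right anchor — without copying any real plasmid sequence.
BACKBONE_5 = ("ATGACCATGATTACGCCAAGCTTGCATGCCTGCAGGTCGACT"
              "CTAGAGGATCCCCGGGTAC")  # 60 nt
LEFT_ANCHOR = "GATTCAGGCTGCGCAACTGT"     # 20 nt, protospacer 3' side
RIGHT_ANCHOR = "CCAGTCACGACGTTGTAAAA"    # 20 nt, vector side
BACKBONE_3 = "CGACGGCCAGTGAATTCGAGCTCGGTACCCGGGGATCCTC"  # 40 nt

#: the five-member fixed-PAM library used for the temperature-dependence
#: interference assay: four functional NNNNGNA-type PAMs and a no-PAM control
FIVE_MEMBER_LIBRARY: list[tuple[str, str]] = [
    ("PAM 1", "ACAGGTA"),
    ("PAM 2", "CGGTGTA"),
    ("PAM 3", "TGAAGAA"),
    ("PAM 4", "ATTGGAA"),
    ("no PAM", "TTCATAT"),
]

_BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}
_CODE_TO_ASCII = np.frombuffer(BASES.encode(), dtype=np.uint8)
_COMP_CODE = np.array([3, 2, 1, 0], dtype=np.uint8)  # A<->T, C<->G


def default_design() -> ScreenDesign:
    return ScreenDesign(left_anchor=LEFT_ANCHOR, right_anchor=RIGHT_ANCHOR,
                        degenerate_len=7)


@dataclass(frozen=True)
class Rule:
    """One positional PAM-recognition rule.

    ``required`` rules veto recognition when unmatched; ``preferred``
    rules attenuate it: an unmatched preferred rule multiplies the
    recognition degree by (1 - strength), so strength 1 behaves like a
    requirement and strength 0 is a no-op.
    """

    position: int  # 1-based PAM position
    bases: frozenset
    mode: str = "required"  # or "preferred"
    strength: float = 1.0

    def __post_init__(self):
        if self.mode not in ("required", "preferred"):
            raise InputError("rule mode must be 'required' or 'preferred'")
        if not (0.0 <= self.strength <= 1.0):
            raise InputError("rule strength must be in [0, 1]")
        if not self.bases or set(self.bases) - set(BASES):
            raise InputError("rule bases must be a non-empty subset of ACGT")
        if self.position < 1:
            raise InputError("rule position is 1-based")

    def matches(self, pam: str) -> bool:
        return pam[self.position - 1] in self.bases


@dataclass(frozen=True)
class RecognitionModel:
    """Planted PAM-recognition model mapping each variant to a survival.

    ``base_survival`` is the survival of unrecognized variants,
    ``recognized_survival`` that of fully recognized ones (lower —
    recognized PAMs are depleted). The recognition degree d of a PAM is

        d = [all required rules match] * prod_preferred (1 if matched
                                                         else 1 - strength)

    and survival = base + d * (recognized - base).
    """

    rules: tuple[Rule, ...] = ()
    base_survival: float = 1.0
    recognized_survival: float = 0.05

    def __post_init__(self):
        if not (0.0 <= self.recognized_survival <= self.base_survival <= 1.0):
            raise InputError(
                "need 0 <= recognized_survival <= base_survival <= 1")

    def describe(self) -> dict:
        return {
            "base_survival": self.base_survival,
            "recognized_survival": self.recognized_survival,
            "rules": [
                {"position": r.position, "bases": sorted(r.bases),
                 "mode": r.mode, "strength": r.strength}
                for r in self.rules
            ],
        }


def planted_nnnngna_model(base_survival: float = 1.0,
                          recognized_survival: float = 0.05,
                          a7_strength: float = 2.0 / 3.0) -> RecognitionModel:
    """The default planted model: G required at position 5, A preferred at
    position 7. With strength 2/3 the depletion (1 - survival) of G5 PAMs
    with A at 7 is 3x that of G5 PAMs without it — a 3:1 preference."""
    return RecognitionModel(
        rules=(Rule(5, frozenset("G"), "required"),
               Rule(7, frozenset("A"), "preferred", a7_strength)),
        base_survival=base_survival,
        recognized_survival=recognized_survival,
    )


def null_model(survival: float = 1.0) -> RecognitionModel:
    """No selection: every variant survives equally."""
    return RecognitionModel(rules=(), base_survival=survival,
                            recognized_survival=survival)


def survival_probability(pam: str, model: RecognitionModel) -> float:
    """Survival (non-depleted) probability of one PAM under the model."""
    if set(pam) - set(BASES):
        raise InputError(f"invalid PAM {pam!r}")
    for rule in model.rules:
        if rule.position > len(pam):
            raise InputError("rule position beyond PAM length")
    degree = 1.0
    for rule in model.rules:
        if rule.mode == "required":
            if not rule.matches(pam):
                return model.base_survival
        else:
            if not rule.matches(pam):
                degree *= 1.0 - rule.strength
    return model.base_survival + degree * (model.recognized_survival
                                           - model.base_survival)


def survival_vector(library: Sequence[str], model: RecognitionModel
                    ) -> np.ndarray:
    return np.array([survival_probability(p, model) for p in library])


@dataclass(frozen=True)
class ReadModel:
    """Sequencing-read plumbing: lengths, qualities, substitution errors."""

    read_len: int = 75
    mean_q: float = 30.0
    q_sd: float = 3.0
    sub_error_from_q: bool = True
    paired: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.read_len < 1:
            raise InputError("read_len must be positive")


# ---------------------------------------------------------------------------
# PAM screen simulation
# ---------------------------------------------------------------------------

def _multinomial_counts(rng: np.random.Generator, n: int,
                        weights: np.ndarray) -> np.ndarray:
    p = weights / weights.sum()
    return rng.multinomial(n, p)


def simulate_screen_counts(model: RecognitionModel, n_molecules_exp: int,
                           n_molecules_ctrl: int, seed: int,
                           library: Sequence[str] | None = None
                           ) -> tuple[PamCountTable, PamCountTable, dict]:
    """Molecule-level screen: multinomial counts without the read layer.

    Control counts are multinomial over a uniform library; experimental
    counts are multinomial with weights proportional to each variant's
    survival under the planted model. Returns (exp, ctrl, truth).
    """
    if library is None:
        library = all_pams()
    library = list(library)
    rng = np.random.default_rng(seed)
    surv = survival_vector(library, model)
    ctrl_counts = _multinomial_counts(rng, n_molecules_ctrl,
                                      np.ones(len(library)))
    exp_counts = _multinomial_counts(rng, n_molecules_exp, surv)
    exp = PamCountTable.from_counts(
        dict(zip(library, exp_counts)), sample_id="exp",
        degenerate_len=len(library[0]))
    ctrl = PamCountTable.from_counts(
        dict(zip(library, ctrl_counts)), sample_id="ctrl",
        degenerate_len=len(library[0]))
    truth = {
        "seed": int(seed),
        "n_molecules_exp": int(n_molecules_exp),
        "n_molecules_ctrl": int(n_molecules_ctrl),
        "library_size": len(library),
        "model": model.describe(),
        "survival": {p: float(s) for p, s in zip(library, surv)},
    }
    return exp, ctrl, truth


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8).copy()


def _construct_matrix(library: Sequence[str]) -> tuple[np.ndarray, int, int]:
    """(L x construct_len) base-code matrix, plus cassette start/end."""
    prefix = BACKBONE_5 + LEFT_ANCHOR
    suffix = RIGHT_ANCHOR + BACKBONE_3
    k = len(library[0])
    cass_start = len(BACKBONE_5)
    cass_end = cass_start + len(LEFT_ANCHOR) + k + len(RIGHT_ANCHOR)
    codes = np.empty((len(library), len(prefix) + k + len(suffix)),
                     dtype=np.uint8)
    pre = np.array([_BASE_TO_CODE[b] for b in prefix], dtype=np.uint8)
    suf = np.array([_BASE_TO_CODE[b] for b in suffix], dtype=np.uint8)
    codes[:, :len(prefix)] = pre
    codes[:, len(prefix) + k:] = suf
    for i, pam in enumerate(library):
        codes[i, len(prefix):len(prefix) + k] = [_BASE_TO_CODE[b] for b in pam]
    return codes, cass_start, cass_end


def _sample_reads(rng: np.random.Generator, counts: np.ndarray,
                  library: Sequence[str], read_model: ReadModel,
                  sample_id: str) -> list[FastqRead]:
    """Vectorized read synthesis for one sample from per-variant counts."""
    codes, cass_start, cass_end = _construct_matrix(library)
    rl = read_model.read_len
    if rl < cass_end - cass_start:
        raise InputError("read_len shorter than the anchored cassette")
    pam_idx = np.repeat(np.arange(len(library)), counts)
    rng.shuffle(pam_idx)
    n = len(pam_idx)
    if n == 0:
        return []
    lo = max(0, cass_end - rl)
    hi = min(cass_start, codes.shape[1] - rl)
    starts = rng.integers(lo, hi + 1, size=n)
    cols = starts[:, None] + np.arange(rl)[None, :]
    reads = codes[pam_idx[:, None], cols]

    # strand flip for half the reads
    flip = rng.random(n) < 0.5
    reads[flip] = _COMP_CODE[reads[flip]][:, ::-1]

    quals = np.clip(np.rint(rng.normal(read_model.mean_q, read_model.q_sd,
                                       size=(n, rl))), 2, 41).astype(np.uint8)
    if read_model.sub_error_from_q:
        p_err = 10.0 ** (-quals.astype(np.float64) / 10.0)
        err = rng.random((n, rl)) < p_err
        shift = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
        reads[err] = (reads[err] + shift) % 4

    seq_bytes = _CODE_TO_ASCII[reads].tobytes()
    qual_bytes = (quals + 33).tobytes()
    out = []
    for i in range(n):
        name = f"{sample_id}_{i}"
        seq = seq_bytes[i * rl:(i + 1) * rl].decode("ascii")
        qual = qual_bytes[i * rl:(i + 1) * rl].decode("ascii")
        out.append(FastqRead(name, seq, qual))
        if read_model.paired:
            out.append(FastqRead(name, revcomp(seq), qual[::-1]))
    return out


@dataclass
class ScreenSimResult:
    exp_path: Path
    ctrl_path: Path
    truth_path: Path | None
    truth: dict


def simulate_screen(model: RecognitionModel, n_molecules_exp: int,
                    n_molecules_ctrl: int, *,
                    library: Sequence[str] | None = None,
                    design: ScreenDesign | None = None,
                    read_model: ReadModel | None = None,
                    out_exp: str | Path, out_ctrl: str | Path,
                    out_truth: str | Path | None = None,
                    seed: int | None = None) -> ScreenSimResult:
    """Full read-level screen simulation to FASTQ (gzip by extension).

    Control molecules are drawn multinomially from a uniform library,
    experimental molecules with weights proportional to planted survival;
    each molecule becomes one read (or mate pair) on the anchored
    cassette, with Phred qualities and quality-derived substitution
    errors. The truth JSON records the seed and per-PAM survival.
    """
    read_model = read_model or ReadModel()
    design = design or default_design()
    if seed is None:
        seed = read_model.seed
    if library is None:
        library = all_pams(design.degenerate_len)
    library = list(library)
    if design.left_anchor != LEFT_ANCHOR or design.right_anchor != RIGHT_ANCHOR:
        raise InputError(
            "read simulation uses the package's fixed construct; "
            "pass design=default_design()")

    exp_tab, ctrl_tab, truth = simulate_screen_counts(
        model, n_molecules_exp, n_molecules_ctrl, seed, library)
    rng = np.random.default_rng([seed, 0xC0FFEE])
    exp_counts = np.array([exp_tab.counts.get(p, 0) for p in library])
    ctrl_counts = np.array([ctrl_tab.counts.get(p, 0) for p in library])
    exp_reads = _sample_reads(rng, exp_counts, library, read_model, "exp")
    ctrl_reads = _sample_reads(rng, ctrl_counts, library, read_model, "ctrl")

    out_exp, out_ctrl = Path(out_exp), Path(out_ctrl)
    write_fastq(out_exp, exp_reads)
    write_fastq(out_ctrl, ctrl_reads)
    truth["read_model"] = {
        "read_len": read_model.read_len, "mean_q": read_model.mean_q,
        "q_sd": read_model.q_sd,
        "sub_error_from_q": read_model.sub_error_from_q,
        "paired": read_model.paired,
    }
    truth["design"] = design.to_dict()
    truth_path = None
    if out_truth is not None:
        truth_path = Path(out_truth)
        truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True))
    return ScreenSimResult(exp_path=out_exp, ctrl_path=out_ctrl,
                           truth_path=truth_path, truth=truth)


# ---------------------------------------------------------------------------
# toy locus and small-RNA simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedSpecies:
    """Ground-truth RNA species on the toy locus."""

    start: int
    end: int
    strand: str
    depth: int
    label: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ToyLocus:
    """Synthetic CRISPR locus with known array, tracrRNA and RNA species."""

    sequence: str
    array: CrisprArray
    tracr_interval: tuple[int, int]
    anti_repeat_interval: tuple[int, int]
    repeat_consensus: str
    species: list[PlantedSpecies] = field(default_factory=list)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


def make_toy_locus(n_spacers: int = 9, repeat_len: int = 36,
                   spacer_len: int = 31, seed: int = 0,
                   spacer_part_len: int = 25, dr_part_len: int = 26,
                   crrna_depth: int = 50,
                   tracr_product_lens: Sequence[int] = (70, 90, 107),
                   tracr_depth: int = 40,
                   add_short_species: bool = False,
                   array_strand: str = "-") -> ToyLocus:
    """Build a synthetic locus mirroring the studied architecture.

    ``n_spacers + 1`` direct repeats interleaved with ``n_spacers``
    spacers, a tracrRNA region upstream carrying an anti-repeat
    (reverse-complement of 24 nt of the repeat with 2 substitutions), and
    planted mature RNA species: one crRNA per spacer (a 5' spacer part
    plus a 3' DR part, on the array's transcription strand) and tracrRNA
    products sharing a 5' end with variable 3' ends. The repeat's
    terminal nine nucleotides carry an extended -10-like element.
    """
    rng = np.random.default_rng(seed)
    n_repeats = n_spacers + 1
    repeat = _random_dna(rng, repeat_len - 9) + "TGCTATAAT"

    tracr_flank = _random_dna(rng, 120)
    tracr_len = max(tracr_product_lens) + 10
    anti = list(revcomp(repeat[:24]))
    for pos in rng.choice(24, size=2, replace=False):
        anti[pos] = BASES[(_BASE_TO_CODE[anti[pos]] + 2) % 4]
    anti = "".join(anti)
    tracr_inner = _random_dna(rng, tracr_len - 24 - 10)
    tracr_seq = _random_dna(rng, 10) + anti + tracr_inner

    mid_flank = _random_dna(rng, 150)
    spacers = [_random_dna(rng, spacer_len) for _ in range(n_spacers)]
    array_seq = repeat + "".join(s + repeat for s in spacers)
    right_flank = _random_dna(rng, 200)

    tracr_start = len(tracr_flank)
    tracr_end = tracr_start + tracr_len
    anti_start = tracr_start + 10
    array_start = tracr_end + len(mid_flank)
    sequence = tracr_flank + tracr_seq + mid_flank + array_seq + right_flank

    units = []
    pos = array_start
    for i in range(n_repeats):
        r0, r1 = pos, pos + repeat_len
        if i < n_spacers:
            s0, s1 = r1, r1 + spacer_len
            pos = s1
        else:
            s0 = s1 = None
        units.append(RepeatUnit(r0, r1, s0, s1))
    array = CrisprArray(contig_id="toy_locus", strand=array_strand,
                        units=units, repeat_consensus=repeat)

    species: list[PlantedSpecies] = []
    spacer_ivs = [(u.spacer_start, u.spacer_end) for u in units
                  if u.spacer_start is not None]
    # transcription-proximal spacer first: for '-' transcription the
    # rightmost spacer is transcribed first
    order = list(reversed(range(n_spacers))) if array_strand == "-" \
        else list(range(n_spacers))
    for rank, si in enumerate(order, start=1):
        s0, s1 = spacer_ivs[si]
        if array_strand == "-":
            # 5' spacer part at high coordinates, 3' DR part in the
            # repeat left of the spacer
            start, end = s0 - dr_part_len, s0 + spacer_part_len
        else:
            start, end = s1 - spacer_part_len, s1 + dr_part_len
        species.append(PlantedSpecies(start, end, array_strand, crrna_depth,
                                      label=f"crRNA_{rank}"))
    tr_end5 = tracr_end - 2  # common tracr 5' end (on '-' strand)
    for ln in tracr_product_lens:
        species.append(PlantedSpecies(tr_end5 - ln, tr_end5, "-", tracr_depth,
                                      label=f"tracrRNA_{ln}"))
    if add_short_species:
        short_start = array_start - len(mid_flank) + 40
        species.append(PlantedSpecies(short_start, short_start + 30, "+",
                                      crrna_depth, label="short_30nt"))
    return ToyLocus(sequence=sequence, array=array,
                    tracr_interval=(tracr_start, tracr_end),
                    anti_repeat_interval=(anti_start, anti_start + 24),
                    repeat_consensus=repeat, species=species)


@dataclass
class SmallRnaSim:
    reads: list[FastqRead]
    placements: list  # smallrna.Alignment per read, truth placement
    truth: dict


def simulate_small_rna(locus: ToyLocus, end_jitter: int = 0, seed: int = 0,
                       mean_q: float = 32.0, max_read_len: int = 150
                       ) -> SmallRnaSim:
    """Sample small-RNA reads from the planted species of a toy locus.

    Each species yields ``depth`` reads; both ends are jittered
    independently and uniformly within +/- ``end_jitter`` nt. Molecules
    longer than ``max_read_len`` are truncated from the 3' end and
    flagged partial in the truth record.
    """
    from cascreen.smallrna import Alignment

    rng = np.random.default_rng(seed)
    n_locus = len(locus.sequence)
    reads: list[FastqRead] = []
    placements: list[Alignment] = []
    truth_species = []
    idx = 0
    for sp in locus.species:
        if not (0 <= sp.start < sp.end <= n_locus):
            raise InputError(f"species {sp.label} outside locus bounds")
        partial = sp.length > max_read_len
        truth_species.append({
            "label": sp.label, "start": sp.start, "end": sp.end,
            "strand": sp.strand, "depth": sp.depth, "length": sp.length,
            "partial": partial,
        })
        for _ in range(sp.depth):
            s = sp.start + int(rng.integers(-end_jitter, end_jitter + 1)) \
                if end_jitter else sp.start
            e = sp.end + int(rng.integers(-end_jitter, end_jitter + 1)) \
                if end_jitter else sp.end
            s, e = max(0, s), min(n_locus, e)
            if e - s < 1:
                continue
            if e - s > max_read_len:  # truncate from the 3' end
                if sp.strand == "+":
                    e = s + max_read_len
                else:
                    s = e - max_read_len
            seq = locus.sequence[s:e]
            if sp.strand == "-":
                seq = revcomp(seq)
            name = f"sr_{idx}_{sp.label}"
            qual = chr(int(mean_q) + 33) * len(seq)
            reads.append(FastqRead(name, seq, qual))
            placements.append(Alignment(name, s, e, sp.strand))
            idx += 1
    truth = {
        "seed": int(seed), "end_jitter": int(end_jitter),
        "species": truth_species,
        "locus_sha1": hashlib.sha1(locus.sequence.encode()).hexdigest(),
    }
    return SmallRnaSim(reads=reads, placements=placements, truth=truth)


def write_small_rna_sam(sim: SmallRnaSim, locus: ToyLocus, path: str | Path,
                        contig: str = "toy_locus") -> None:
    """Write the simulated placements as a plain-text SAM file."""
    import pysam

    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": contig, "LN": len(locus.sequence)}]}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read, aln in zip(sim.reads, sim.placements):
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = read.name
            rec.reference_id = 0
            rec.reference_start = aln.start
            rec.mapping_quality = 60
            rec.cigarstring = f"{len(read.seq)}M"
            rec.flag = 16 if aln.strand == "-" else 0
            # SAM stores reference-strand sequence
            rec.query_sequence = read.seq if aln.strand == "+" \
                else revcomp(read.seq)
            rec.query_qualities = pysam.qualitystring_to_array(
                read.qual if aln.strand == "+" else read.qual[::-1])
            out.write(rec)
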