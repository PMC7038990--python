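"""Writers for the pipeline's machine-readable outputs.

Tables are TSV with fixed, documented columns; interval features go to
GFF3 (1-based inclusive, per the format) and end histograms to BedGraph.
Human-readable coordinates in TSVs are 1-based inclusive; the JSON
summaries keep the internal 0-based half-open convention.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from cascreen.locus import AntiRepeatHit, CrisprArray, PromoterMotifScore
from cascreen.smallrna import EndHistogram, OrientationCall, RnaSpecies


def arrays_to_frame(arrays: Sequence[CrisprArray]) -> pd.DataFrame:
    """One row per array unit, 1-based inclusive coordinates."""
    rows = []
    for ai, arr in enumerate(arrays):
        for ui, unit in enumerate(arr.units):
            rows.append({
                "array": ai + 1,
                "contig": arr.contig_id,
                "strand": arr.strand,
                "unit": ui + 1,
                "repeat_start": unit.repeat_start + 1,
                "repeat_end": unit.repeat_end,
                "spacer_start": None if unit.spacer_start is None
                else unit.spacer_start + 1,
                "spacer_end": unit.spacer_end,
                "repeat_consensus": arr.repeat_consensus,
            })
    return pd.DataFrame(rows)


def write_gff3(path: str | Path, arrays: Sequence[CrisprArray],
               anti_hits: Sequence[AntiRepeatHit] = ()) -> None:
    lines = ["##gff-version 3"]
    for ai, arr in enumerate(arrays, start=1):
        for ui, unit in enumerate(arr.units, start=1):
            lines.append("\t".join(map(str, [
                arr.contig_id, "cascreen", "repeat_unit",
                unit.repeat_start + 1, unit.repeat_end, ".", arr.strand, ".",
                f"ID=array{ai}.repeat{ui}"])))
            if unit.spacer_start is not None:
                lines.append("\t".join(map(str, [
                    arr.contig_id, "cascreen", "spacer",
                    unit.spacer_start + 1, unit.spacer_end, ".", arr.strand,
                    ".", f"ID=array{ai}.spacer{ui}"])))
    contig = arrays[0].contig_id if arrays else "contig"
    for hi, hit in enumerate(anti_hits, start=1):
        lines.append("\t".join(map(str, [
            contig, "cascreen", "anti_repeat", hit.start + 1, hit.end,
            f"{hit.alignment_score:g}", hit.strand, ".",
            f"ID=anti_repeat{hi};identity={hit.identity_fraction:.3f}"])))
    Path(path).write_text("\n".join(lines) + "\n")


def annotation_summary(arrays: Sequence[CrisprArray],
                       anti_hits: Sequence[AntiRepeatHit],
                       promoter_scores: Sequence[PromoterMotifScore]) -> dict:
    return {
        "n_arrays": len(arrays),
        "arrays": [
            {
                "contig": arr.contig_id,
                "strand": arr.strand,
                "n_repeats": arr.n_repeats,
                "repeat_consensus": arr.repeat_consensus,
                "spacer_lengths": arr.spacer_lengths,
                "span": list(arr.span),
            }
            for arr in arrays
        ],
        "anti_repeat_hits": [
            {"start": h.start, "end": h.end, "strand": h.strand,
             "matched_len": h.matched_len,
             "identity_fraction": round(h.identity_fraction, 4),
             "alignment_score": h.alignment_score}
            for h in anti_hits
        ],
        "promoter_scores": [
            {"repeat_index": p.repeat_index,
             "window_start_in_repeat": p.window_start_in_repeat,
             "score": p.score, "matched_window": p.matched_window}
            for p in promoter_scores
        ],
    }


def species_to_frame(species: Sequence[RnaSpecies]) -> pd.DataFrame:
    rows = []
    for sp in species:
        ann = sp.annotation
        rows.append({
            "start": sp.start + 1,
            "end": sp.end,
            "strand": sp.strand,
            "length": sp.length,
            "support": sp.support,
            "annotation": ann.kind if ann else "",
            "crRNA_index": ann.index if ann else None,
            "spacer_part_len": ann.spacer_part_len if ann else None,
            "dr_part_len": ann.dr_part_len if ann else None,
            "product_len": ann.product_len if ann else None,
        })
    return pd.DataFrame(rows)


def write_bedgraph(path: str | Path, hist: EndHistogram, which: str,
                   strand: str, contig: str = "locus") -> None:
    """One strand's 5' or 3' end histogram as BedGraph."""
    counts = hist.five_prime(strand) if which == "5p" else \
        hist.three_prime(strand)
    lines = [f'track type=bedGraph name="{which}_ends_{strand}"']
    for pos in sorted(counts):
        lines.append(f"{contig}\t{pos}\t{pos + 1}\t{counts[pos]}")
    Path(path).write_text("\n".join(lines) + "\n")


def orientation_to_dict(call: OrientationCall) -> dict:
    return {
        "array_strand": call.array_strand,
        "read_count_sense": call.read_count_sense,
        "read_count_antisense": call.read_count_antisense,
        "confidence": call.confidence,
        "status": call.status,
    }


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
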