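"""Visualization-ready artifacts of the PAM screen.

All outputs are numeric tables, not pixels: a sequence-logo matrix
(per-position base probabilities and information content in bits over
the depleted set), the hierarchical PAM wheel (nested annular sectors
whose areas are proportional to depletion-weighted frequencies of base
combinations), and fraction tables for fixed small libraries (the data
behind pie charts). Rendering, where wanted, is a thin layer elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from cascreen.errors import InputError
from cascreen.screen import BASES, PamCountTable

FULL_CIRCLE = 360.0


@dataclass
class LogoMatrix:
    """Per-position base probabilities and information content (bits)."""

    probabilities: np.ndarray  # (k, 4), bases A,C,G,T
    information_bits: np.ndarray  # (k,)

    @property
    def k(self) -> int:
        return self.probabilities.shape[0]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(self.k):
            for j, base in enumerate(BASES):
                rows.append({"position": i + 1, "base": base,
                             "probability": self.probabilities[i, j],
                             "information_bits": self.information_bits[i]})
        return pd.DataFrame(rows)


def build_logo_matrix(depleted: Iterable[str],
                      weights: Mapping[str, float] | None = None
                      ) -> LogoMatrix:
    """Logo matrix over the depleted PAM set.

    Unweighted by default — each depleted PAM counts once, as a logo
    built from a sequence list. Information content per position is
    2 - H bits (Shannon entropy in bits, no small-sample correction).
    """
    pams = sorted(set(depleted))
    if not pams:
        raise InputError("depleted set is empty")
    k = len(pams[0])
    index = {b: j for j, b in enumerate(BASES)}
    counts = np.zeros((k, 4))
    for pam in pams:
        if len(pam) != k:
            raise InputError("depleted PAMs have inconsistent lengths")
        w = 1.0 if weights is None else float(weights[pam])
        for i, b in enumerate(pam):
            counts[i, index[b]] += w
    probs = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(probs > 0, probs * np.log2(probs), 0.0)
    entropy = -plogp.sum(axis=1)
    return LogoMatrix(probabilities=probs, information_bits=2.0 - entropy)


@dataclass(frozen=True)
class WheelSector:
    """One annular sector of the PAM wheel geometry table."""

    ring_index: int  # 0 = innermost
    position: int  # PAM position shown on this ring
    base_path: str  # bases from the innermost ring to this sector
    start_angle: float
    end_angle: float
    r_inner: float
    r_outer: float
    weight: float

    @property
    def span(self) -> float:
        return self.end_angle - self.start_angle


@dataclass
class PamWheel:
    positions: tuple[int, ...]
    sectors: list[WheelSector]
    normalization: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "ring_index": s.ring_index, "position": s.position,
            "base_path": s.base_path, "start_angle": s.start_angle,
            "end_angle": s.end_angle, "r_inner": s.r_inner,
            "r_outer": s.r_outer, "weight": s.weight,
        } for s in self.sectors])


def pam_weights(table: pd.DataFrame, weight_def: str = "depletion_fraction"
                ) -> pd.Series:
    """Per-PAM relative depletion weights from a depletion table.

    ``depletion_fraction`` (default): max(0, freq_ctrl - freq_exp),
    normalized to sum to 1. ``log_ratio``: max(0, depletion_score),
    normalized — an alternative reading of 'relative depletion'.
    """
    if weight_def == "depletion_fraction":
        raw = (table["freq_ctrl"] - table["freq_exp"]).clip(lower=0.0)
    elif weight_def == "log_ratio":
        raw = table["depletion_score"].clip(lower=0.0)
    else:
        raise InputError(f"unknown weight_def {weight_def!r}")
    total = raw.sum()
    if total <= 0:
        raise InputError("all-zero weights: nothing depleted to draw")
    return raw / total


def build_pam_wheel(table: pd.DataFrame, positions: Sequence[int] = (5, 6, 7),
                    weight_def: str = "depletion_fraction",
                    normalization: str = "nested",
                    weights: pd.Series | None = None) -> PamWheel:
    """Hierarchical PAM wheel geometry over the selected positions.

    Rings run inner to outer in the order of ``positions`` (inner ring =
    position closest to the protospacer among those shown, per the given
    order). In the default nested layout, the children of each sector
    partition its angular span proportionally to their aggregated
    weights, in fixed base order A,C,G,T; ring radii grow as sqrt so
    every annulus has equal area and sector area is globally
    proportional to aggregated weight. The alternative ``per_ring``
    layout divides each full ring independently by the marginal weight
    of the base at that ring's position.
    """
    positions = tuple(positions)
    if not positions or any(p < 1 or p > 7 for p in positions):
        raise InputError("positions must be a non-empty subset of 1..7")
    if weights is None:
        weights = pam_weights(table, weight_def)
    elif weights.sum() <= 0:
        raise InputError("all-zero weights: nothing depleted to draw")
    else:
        weights = weights / weights.sum()
    k = len(positions)
    radii = [np.sqrt(i / k) for i in range(k + 1)]

    # aggregate weights by base-combination prefix over the chosen positions
    combos: dict[str, float] = {}
    for pam, wt in zip(weights.index, weights.to_numpy()):
        key = "".join(pam[p - 1] for p in positions)
        combos[key] = combos.get(key, 0.0) + float(wt)

    def prefix_weight(prefix: str) -> float:
        return sum(v for key, v in combos.items()
                   if key.startswith(prefix))

    sectors: list[WheelSector] = []
    if normalization == "nested":
        frontier = [("", 0.0, FULL_CIRCLE, 1.0)]
        for ring in range(k):
            nxt = []
            for prefix, a0, a1, pw in frontier:
                child_ws = [prefix_weight(prefix + b) for b in BASES]
                total = sum(child_ws)
                angle = a0
                for b, cw in zip(BASES, child_ws):
                    span = (a1 - a0) * (cw / total) if total > 0 else 0.0
                    sectors.append(WheelSector(
                        ring_index=ring, position=positions[ring],
                        base_path=prefix + b, start_angle=angle,
                        end_angle=angle + span, r_inner=radii[ring],
                        r_outer=radii[ring + 1], weight=cw))
                    nxt.append((prefix + b, angle, angle + span, cw))
                    angle += span
            frontier = nxt
    elif normalization == "per_ring":
        for ring in range(k):
            marg = {b: 0.0 for b in BASES}
            for key, v in combos.items():
                marg[key[ring]] += v
            total = sum(marg.values())
            angle = 0.0
            for b in BASES:
                span = FULL_CIRCLE * marg[b] / total if total > 0 else 0.0
                sectors.append(WheelSector(
                    ring_index=ring, position=positions[ring], base_path=b,
                    start_angle=angle, end_angle=angle + span,
                    r_inner=radii[ring], r_outer=radii[ring + 1],
                    weight=marg[b]))
                angle += span
    else:
        raise InputError(f"unknown normalization {normalization!r}")
    return PamWheel(positions=positions, sectors=sectors,
                    normalization=normalization)


def fixed_library_fractions(counts: PamCountTable,
                            members: Sequence[tuple[str, str]]
                            ) -> pd.DataFrame:
    """Fractions of each member of a fixed small PAM library.

    Counts are restricted to the member sequences; any other anchored
    reads are aggregated into an 'other' row. Fractions are over the
    member + other total and sum to 1.
    """
    seqs = [s for _label, s in members]
    if len(set(seqs)) != len(seqs):
        raise InputError("duplicate member sequences")
    if any(len(s) != counts.degenerate_len for s in seqs):
        raise InputError("member sequences must match the degenerate length")
    rows = [{"label": label, "sequence": seq,
             "count": counts.counts.get(seq, 0)}
            for label, seq in members]
    other = sum(c for pam, c in counts.counts.items() if pam not in set(seqs))
    rows.append({"label": "other", "sequence": "", "count": other})
    df = pd.DataFrame(rows)
    total = df["count"].sum()
    if total == 0:
        raise InputError("no counts to compute fractions from")
    df["fraction"] = df["count"] / total
    return df
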