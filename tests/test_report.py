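"""Logo matrices, PAM wheel geometry and fixed-library fractions."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cascreen.errors import InputError
from cascreen.report import (
    build_logo_matrix,
    build_pam_wheel,
    fixed_library_fractions,
    pam_weights,
)
from cascreen.screen import PamCountTable, all_pams, compute_depletion


class TestLogoMatrix:
    def test_single_sequence_has_two_bits_everywhere(self):
        logo = build_logo_matrix({"AAAAAAA"})
        assert np.allclose(logo.information_bits, 2.0)
        assert np.allclose(logo.probabilities[:, 0], 1.0)

    def test_full_library_has_zero_information(self):
        logo = build_logo_matrix(all_pams(7))
        assert np.allclose(logo.information_bits, 0.0, atol=1e-12)
        assert np.allclose(logo.probabilities, 0.25)

    def test_nnnngna_expansion_information_content(self):
        # all 1024 expansions of NNNNGNA: fixed positions carry 2 bits,
        # degenerate positions 0
        members = {"".join(p[:4]) + "G" + p[4] + "A"
                   for p in itertools.product("ACGT", repeat=5)}
        assert len(members) == 1024
        logo = build_logo_matrix(members)
        assert logo.information_bits[4] == pytest.approx(2.0)
        assert logo.information_bits[6] == pytest.approx(2.0)
        for i in (0, 1, 2, 3, 5):
            assert logo.information_bits[i] == pytest.approx(0.0, abs=1e-12)

    def test_information_equals_two_minus_entropy(self):
        # hand-computable distribution: p = (1/2, 1/4, 1/8, 1/8) has
        # H = 1.75 bits -> IC = 0.25
        weights = {"AAAAAAA": 4, "CAAAAAA": 2, "GAAAAAA": 1, "TAAAAAA": 1}
        logo = build_logo_matrix(weights.keys(), weights=weights)
        assert logo.information_bits[0] == pytest.approx(0.25)

    def test_empty_set_rejected(self):
        with pytest.raises(InputError):
            build_logo_matrix(set())


def _table_from_counts(exp_counts, ctrl_counts):
    return compute_depletion(PamCountTable.from_counts(exp_counts),
                             PamCountTable.from_counts(ctrl_counts))


def _span_sum(frame, ring, prefix=""):
    rows = frame[(frame["ring_index"] == ring)
                 & frame["base_path"].str.startswith(prefix)]
    return (rows["end_angle"] - rows["start_angle"]).sum()


class TestPamWheel:
    def test_inner_ring_single_base(self):
        # only G-at-inner-position variants are depleted
        pams = all_pams(3)
        exp = {p: (10 if p[0] == "G" else 100) for p in pams}
        ctrl = {p: 100 for p in pams}
        table = compute_depletion(
            PamCountTable.from_counts(exp, degenerate_len=3),
            PamCountTable.from_counts(ctrl, degenerate_len=3))
        wheel = build_pam_wheel(table, positions=(1, 2, 3))
        frame = wheel.to_frame()
        inner = frame[frame["ring_index"] == 0].set_index("base_path")
        g_span = inner.loc["G", "end_angle"] - inner.loc["G", "start_angle"]
        assert g_span == pytest.approx(360.0, abs=1e-9)

    def test_uniform_weights_give_equal_quarters(self):
        pams = all_pams(3)
        ctrl = {p: 100 for p in pams}
        table = compute_depletion(
            PamCountTable.from_counts({p: 50 for p in pams}, degenerate_len=3),
            PamCountTable.from_counts(ctrl, degenerate_len=3))
        wheel = build_pam_wheel(table, positions=(1, 2, 3),
                                weights=pd.Series(1.0, index=pams))
        for sector in wheel.sectors:
            parent_span = 360.0 / 4 ** sector.ring_index
            assert sector.span == pytest.approx(parent_span / 4, abs=1e-9)

    def test_hand_assigned_weights_reproduce_allocation(self):
        # 3-position toy with weights w(combo) = product of per-base
        # hand weights; spans must equal the analytic proportional layout
        base_w = {"A": 1.0, "C": 2.0, "G": 3.0, "T": 4.0}
        pams = all_pams(3)
        ctrl = {p: 1000 for p in pams}
        exp = {}
        for p in pams:
            w = base_w[p[0]] * base_w[p[1]] * base_w[p[2]] / 64.0
            exp[p] = int(round(1000 - w * 10))
        table = compute_depletion(
            PamCountTable.from_counts(exp, degenerate_len=3),
            PamCountTable.from_counts(ctrl, degenerate_len=3))
        weights = pam_weights(table)
        wheel = build_pam_wheel(table, positions=(1, 2, 3))
        frame = wheel.to_frame().set_index("base_path")
        for combo in ("".join(c) for c in itertools.product("ACGT", repeat=3)):
            expected = 360.0 * sum(
                weights[p] for p in pams if p.startswith(combo))
            got = frame.loc[combo, "end_angle"] - frame.loc[combo,
                                                            "start_angle"]
            assert got == pytest.approx(expected, abs=1e-6)

    def test_children_partition_parent_span(self):
        pams = all_pams(3)
        rng = np.random.default_rng(7)
        exp = {p: int(rng.integers(10, 100)) for p in pams}
        ctrl = {p: 100 for p in pams}
        table = compute_depletion(
            PamCountTable.from_counts(exp, degenerate_len=3),
            PamCountTable.from_counts(ctrl, degenerate_len=3))
        wheel = build_pam_wheel(table, positions=(1, 2, 3))
        frame = wheel.to_frame()
        assert _span_sum(frame, 0) == pytest.approx(360.0, abs=1e-9)
        for ring in (1, 2):
            parents = frame[frame["ring_index"] == ring - 1]
            for _, parent in parents.iterrows():
                child_sum = _span_sum(frame, ring, parent["base_path"])
                assert child_sum == pytest.approx(parent["end_angle"]
                                                  - parent["start_angle"],
                                                  abs=1e-9)

    def test_per_ring_layout_covers_circle(self):
        pams = all_pams(2)
        exp = {p: (10 if p[0] == "G" else 100) for p in pams}
        ctrl = {p: 100 for p in pams}
        table = compute_depletion(
            PamCountTable.from_counts(exp, degenerate_len=2),
            PamCountTable.from_counts(ctrl, degenerate_len=2))
        wheel = build_pam_wheel(table, positions=(1, 2),
                                normalization="per_ring")
        frame = wheel.to_frame()
        for ring in (0, 1):
            assert _span_sum(frame, ring) == pytest.approx(360.0, abs=1e-9)

    def test_equal_area_radii(self):
        pams = all_pams(2)
        table = compute_depletion(
            PamCountTable.from_counts({p: 50 for p in pams}, degenerate_len=2),
            PamCountTable.from_counts({p: 100 for p in pams}, degenerate_len=2))
        wheel = build_pam_wheel(table, positions=(1, 2),
                                weights=pd.Series(1.0, index=pams))
        ring_areas = {s.ring_index: s.r_outer ** 2 - s.r_inner ** 2
                      for s in wheel.sectors}
        areas = list(ring_areas.values())
        assert all(a == pytest.approx(areas[0], abs=1e-12) for a in areas)

    def test_nothing_depleted_is_an_error(self):
        pams = all_pams(2)
        counts = {p: 100 for p in pams}
        table = compute_depletion(
            PamCountTable.from_counts(counts, degenerate_len=2),
            PamCountTable.from_counts(counts, degenerate_len=2))
        with pytest.raises(InputError):
            build_pam_wheel(table, positions=(1, 2))


MEMBERS = [("PAM 1", "ACAGGTA"), ("PAM 2", "CGGTGTA"), ("PAM 3", "TGAAGAA"),
           ("PAM 4", "ATTGGAA"), ("no PAM", "TTCATAT")]


class TestFixedLibraryFractions:
    def test_single_member_takes_all(self):
        counts = PamCountTable.from_counts({"TTCATAT": 500})
        frame = fixed_library_fractions(counts, MEMBERS)
        assert frame.set_index("label").loc["no PAM", "fraction"] == 1.0

    def test_equal_counts_give_equal_fractions(self):
        counts = PamCountTable.from_counts({s: 1000 for _, s in MEMBERS})
        frame = fixed_library_fractions(counts, MEMBERS)
        member_rows = frame[frame["label"] != "other"]
        assert np.allclose(member_rows["fraction"], 0.2)
        assert frame["fraction"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_member_order_permutation_invariant(self):
        rng = np.random.default_rng(5)
        counts = PamCountTable.from_counts(
            {s: int(rng.integers(10, 1000)) for _, s in MEMBERS})
        a = fixed_library_fractions(counts, MEMBERS)
        b = fixed_library_fractions(counts, MEMBERS[::-1])
        merged = a.set_index("label").join(b.set_index("label"),
                                           rsuffix="_b")
        assert np.allclose(merged["fraction"], merged["fraction_b"])

    def test_non_members_go_to_other(self):
        counts = PamCountTable.from_counts({"ACAGGTA": 60, "GGGGGGG": 40})
        frame = fixed_library_fractions(counts, MEMBERS).set_index("label")
        assert frame.loc["other", "fraction"] == pytest.approx(0.4)

    def test_duplicate_members_rejected(self):
        counts = PamCountTable.from_counts({"ACAGGTA": 1})
        with pytest.raises(InputError):
            fixed_library_fractions(counts, MEMBERS + [("dup", "ACAGGTA")])
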