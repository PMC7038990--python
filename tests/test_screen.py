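"""QC, anchored PAM extraction and the depletion statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cascreen.errors import InputError
from cascreen.screen import (
    PamCountTable,
    ScreenDesign,
    all_pams,
    call_consensus,
    call_depleted,
    compute_depletion,
    extract_pam_regions,
    position_depletion,
    qc_filter_reads,
)
from cascreen.seqio import FastqRead, revcomp
from cascreen import simulate as sim

DESIGN = ScreenDesign(left_anchor="GATTCAGGCTGCGCAACTGT",
                      right_anchor="CCAGTCACGACGTTGTAAAA")


def q(scores):
    return "".join(chr(s + 33) for s in scores)


class TestQcFilter:
    def test_boundary_is_inclusive(self):
        read = FastqRead("r", "ACGTACGTAC", q([20] * 10))
        assert list(qc_filter_reads([read], 20.0)) == [read]

    def test_mean_just_below_threshold_is_discarded(self):
        read = FastqRead("r", "ACGTACGTAC", q([20] * 9 + [19]))  # mean 19.9
        assert list(qc_filter_reads([read], 20.0)) == []

    def test_empty_input(self):
        assert list(qc_filter_reads([], 20.0)) == []

    def test_order_preserved(self):
        reads = [FastqRead(f"r{i}", "ACGT", q([30] * 4)) for i in range(5)]
        assert [r.name for r in qc_filter_reads(reads, 20.0)] == \
            [f"r{i}" for i in range(5)]


def _read(seq, name="r1"):
    return FastqRead(name, seq, "I" * len(seq))


class TestExtractPamRegions:
    def test_forward_and_reverse_reads_count_identically(self):
        cassette = DESIGN.left_anchor + "ACAGGTA" + DESIGN.right_anchor
        fwd = extract_pam_regions([_read(cassette)], DESIGN, 1)
        rev = extract_pam_regions([_read(revcomp(cassette))], DESIGN, 1)
        assert fwd.counts == rev.counts == {"ACAGGTA": 1}
        assert fwd.n_reads_anchored == 1

    def test_anchor_mismatch_budget(self):
        left = list(DESIGN.left_anchor)
        for pos in (2, 8, 15):
            left[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[left[pos]]
        cassette = "".join(left) + "ACAGGTA" + DESIGN.right_anchor
        table = extract_pam_regions([_read(cassette)], DESIGN,
                                    max_anchor_mismatches=2)
        assert table.counts == {}
        assert table.n_reads_anchored == 0
        table = extract_pam_regions([_read(cassette)], DESIGN,
                                    max_anchor_mismatches=3)
        assert table.counts == {"ACAGGTA": 1}

    def test_paired_mates_deduplicated_by_name(self):
        cassette = DESIGN.left_anchor + "ACAGGTA" + DESIGN.right_anchor
        mates = [_read(cassette, "m1"), _read(revcomp(cassette), "m1")]
        table = extract_pam_regions(mates, DESIGN, 1)
        assert table.counts["ACAGGTA"] == 1

    def test_accounting_chain(self):
        cassette = DESIGN.left_anchor + "ACAGGTA" + DESIGN.right_anchor
        reads = [_read(cassette, "a"), _read("ACGT" * 20, "b")]
        table = extract_pam_regions(reads, DESIGN, 1, n_reads_total=5)
        assert (table.n_reads_anchored, table.n_reads_pass_qc,
                table.n_reads_total) == (1, 2, 5)
        table.validate()

    def test_short_anchor_rejected(self):
        with pytest.raises(InputError):
            extract_pam_regions([], ScreenDesign("ACGTACGTACG",  # 11 nt
                                                 DESIGN.right_anchor), 1)


def brute_chi2(a, n1, c, n2):
    """Textbook Pearson chi-square on the 2x2 table, cell by cell."""
    obs = np.array([[a, n1 - a], [c, n2 - c]], dtype=float)
    total = obs.sum()
    chi2 = 0.0
    for i in range(2):
        for j in range(2):
            e = obs[i].sum() * obs[:, j].sum() / total
            if e > 0:
                chi2 += (obs[i, j] - e) ** 2 / e
    return chi2


class TestComputeDepletion:
    def test_null_variant_has_zero_score_and_large_p(self):
        exp = PamCountTable.from_counts({"AAAAAAA": 50, "CCCCCCC": 50})
        ctrl = PamCountTable.from_counts({"AAAAAAA": 50, "CCCCCCC": 50})
        table = compute_depletion(exp, ctrl)
        assert table["depletion_score"].abs().max() == 0.0
        assert (table["p_one_sided"] >= 0.5).all()
        assert table["freq_exp"].sum() == pytest.approx(1.0, abs=1e-9)
        assert table["freq_ctrl"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_four_variant_toy_against_oracle(self):
        pams = ["AAAAAAA", "CCCCCCC", "GGGGGGG", "TTTTTTT"]
        exp_counts = dict(zip(pams, [10, 100, 100, 100]))
        ctrl_counts = dict(zip(pams, [100, 70, 70, 70]))
        table = compute_depletion(PamCountTable.from_counts(exp_counts),
                                  PamCountTable.from_counts(ctrl_counts))
        for pam in pams:
            expected = brute_chi2(exp_counts[pam], 310, ctrl_counts[pam], 310)
            assert table.loc[pam, "chi2"] == pytest.approx(expected,
                                                           rel=1e-9)
        assert table["chi2"].idxmax() == "AAAAAAA"
        assert table["p_one_sided"].idxmin() == "AAAAAAA"

    def test_pseudocount_keeps_zero_counts_finite(self):
        exp = PamCountTable.from_counts({"CCCCCCC": 100})
        ctrl = PamCountTable.from_counts({"AAAAAAA": 50, "CCCCCCC": 50})
        table = compute_depletion(exp, ctrl, pseudocount=0.5)
        score = table.loc["AAAAAAA", "depletion_score"]
        assert np.isfinite(score) and score > 0

    def test_empty_control_rejected(self):
        exp = PamCountTable.from_counts({"AAAAAAA": 1})
        with pytest.raises(InputError):
            compute_depletion(exp, PamCountTable("ctrl"))

    def test_chi2_matches_oracles_on_random_tables(self):
        rng = np.random.default_rng(99)
        exp_counts = {}
        ctrl_counts = {}
        pams = all_pams(7)[:1000]
        for pam in pams:
            exp_counts[pam] = int(rng.integers(0, 500))
            ctrl_counts[pam] = int(rng.integers(1, 500))
        table = compute_depletion(PamCountTable.from_counts(exp_counts),
                                  PamCountTable.from_counts(ctrl_counts))
        n_exp = sum(exp_counts.values())
        n_ctrl = sum(ctrl_counts.values())
        for pam in rng.choice(pams, size=60, replace=False):
            a, c = exp_counts.get(pam, 0), ctrl_counts[pam]
            expected = brute_chi2(a, n_exp, c, n_ctrl)
            got = table.loc[pam, "chi2"]
            assert got == pytest.approx(expected, rel=1e-9, abs=1e-12)
            # scipy as a second, independent implementation
            obs = np.array([[a, n_exp - a], [c, n_ctrl - c]])
            sp = stats.chi2_contingency(obs, correction=False).statistic
            assert got == pytest.approx(sp, rel=1e-9, abs=1e-12)
            # one-sided p is the normal upper tail of signed sqrt(chi2)
            sign = 1.0 if c / n_ctrl > a / n_exp else -1.0
            assert table.loc[pam, "p_one_sided"] == pytest.approx(
                stats.norm.sf(sign * np.sqrt(expected)), rel=1e-9)

    def test_monotonicity_in_experimental_count(self):
        ctrl = PamCountTable.from_counts({"AAAAAAA": 200, "CCCCCCC": 800})
        prev_chi2, prev_p = -np.inf, np.inf
        for a in (150, 120, 80, 40, 10, 0):
            exp = PamCountTable.from_counts({"AAAAAAA": a, "CCCCCCC": 800})
            row = compute_depletion(exp, ctrl).loc["AAAAAAA"]
            assert row["chi2"] >= prev_chi2 - 1e-12 or a == 150
            if a < 150:
                assert row["p_one_sided"] <= prev_p + 1e-12
            prev_chi2, prev_p = row["chi2"], row["p_one_sided"]


class TestChiSquareProperties:
    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(a=st.integers(0, 5000), c=st.integers(0, 5000),
           rest_e=st.integers(1, 5000), rest_c=st.integers(1, 5000))
    def test_chi2_nonnegative_and_matches_oracle(self, a, c, rest_e, rest_c):
        from cascreen.screen import _chi2_two_proportion
        n1, n2 = a + rest_e, c + rest_c
        got = float(_chi2_two_proportion(np.array([a], float), n1,
                                         np.array([c], float), n2)[0])
        assert got >= 0.0
        assert got == pytest.approx(brute_chi2(a, n1, c, n2), rel=1e-9,
                                    abs=1e-12)


class TestConsensusProperties:
    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.lists(st.floats(0.001, 1.0), min_size=4, max_size=4),
                    min_size=7, max_size=7),
           st.floats(0.3, 1.0))
    def test_consensus_is_always_valid_iupac(self, raw, threshold):
        from cascreen.screen import IUPAC_CODES
        freqs = np.array(raw)
        freqs /= freqs.sum(axis=1, keepdims=True)
        cons = call_consensus(freqs, threshold)
        assert len(cons.iupac) == 7
        assert all(ch in set(IUPAC_CODES.values()) for ch in cons.iupac)


class TestCallDepleted:
    def test_identical_samples_give_no_calls(self):
        counts = {p: 100 for p in all_pams(7)[:256]}
        table = compute_depletion(PamCountTable.from_counts(counts),
                                  PamCountTable.from_counts(counts))
        assert call_depleted(table, 1e-12) == set()
        assert not table["depleted_flag"].any()

    def test_flag_matches_returned_set(self, planted_screen_counts):
        exp, ctrl, _ = planted_screen_counts
        table = compute_depletion(exp, ctrl)
        depleted = call_depleted(table, 1e-12)
        assert set(table.index[table["depleted_flag"]]) == depleted
        # the planted rule requires G at position 5
        g5 = sum(1 for p in depleted if p[4] == "G")
        assert g5 / len(depleted) >= 0.95

    def test_threshold_validation(self, planted_screen_counts):
        exp, ctrl, _ = planted_screen_counts
        table = compute_depletion(exp, ctrl)
        with pytest.raises(InputError):
            call_depleted(table, 1.5)


class TestPositionDepletion:
    def test_identical_samples_zero_everywhere(self):
        counts = {p: 50 for p in all_pams(4)}
        table = compute_depletion(PamCountTable.from_counts(counts, degenerate_len=4),
                                  PamCountTable.from_counts(counts, degenerate_len=4))
        profile = position_depletion(table)
        assert np.allclose(profile.depletion_value, 0.0)

    def test_single_position_difference_is_localized(self):
        # experimental sample loses G at position 3 only; all other
        # positions keep identical base usage between samples
        pams = all_pams(4)
        ctrl_counts = {p: 64 for p in pams}
        exp_counts = {p: (16 if p[2] == "G" else 80) for p in pams}
        table = compute_depletion(
            PamCountTable.from_counts(exp_counts, degenerate_len=4),
            PamCountTable.from_counts(ctrl_counts, degenerate_len=4))
        profile = position_depletion(table)
        off_target = np.delete(profile.depletion_value, 2, axis=0)
        assert np.abs(off_target).max() < 1e-6
        i, base = profile.argmax_cell()
        assert (i, base) == (3, "G")

    def test_planted_model_argmax_is_g5(self, planted_screen_counts):
        exp, ctrl, _ = planted_screen_counts
        table = compute_depletion(exp, ctrl)
        depleted = call_depleted(table, 1e-12)
        profile = position_depletion(table, depleted)
        assert profile.argmax_cell() == (5, "G")
        # depleted-set frequencies present and normalized per position
        assert profile.freq_depleted.sum(axis=1) == pytest.approx(
            np.ones(7), abs=1e-9)


class TestCallConsensus:
    def test_uniform_frequencies_give_all_n(self):
        freqs = np.full((7, 4), 0.25)
        assert call_consensus(freqs, 0.75).iupac == "NNNNNNN"

    def test_two_base_dominance_gives_r(self):
        freqs = np.full((7, 4), 0.25)
        freqs[2] = [0.45, 0.03, 0.5, 0.02]  # A, C, G, T
        cons = call_consensus(freqs, 0.9)
        assert cons.iupac[2] == "R"

    def test_planted_profile_gives_nnnngna(self):
        freqs = np.full((7, 4), 0.25)
        freqs[4] = [0.0, 0.0, 1.0, 0.0]
        freqs[6] = [0.9, 0.04, 0.03, 0.03]
        assert call_consensus(freqs, 0.75).iupac == "NNNNGNA"

    def test_threshold_validation(self):
        with pytest.raises(InputError):
            call_consensus(np.full((7, 4), 0.25), 0.2)


class TestParameterRecovery:
    def test_consensus_recovered_across_seeds(self):
        """Planted NNNNGNA model at 100x depth: the full pipeline recovers
        the consensus in >= 9 of 10 seeded simulations."""
        model = sim.planted_nnnngna_model()
        hits = 0
        for seed in range(10):
            exp, ctrl, _ = sim.simulate_screen_counts(
                model, 1_638_400, 1_638_400, seed=seed)
            table = compute_depletion(exp, ctrl)
            depleted = call_depleted(table, 1e-12)
            profile = position_depletion(table, depleted)
            cons = call_consensus(profile.freq_depleted, 0.75)
            hits += cons.iupac == "NNNNGNA"
        assert hits >= 9
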