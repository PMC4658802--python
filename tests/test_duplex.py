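"""Duplex alignment DP, seed detection, pattern encoding."""

import itertools

import numpy as np
import pytest

from mircurve._kernels import duplex_min_energy
from mircurve.duplex import (GU, MATCH, MISMATCH, Column, DuplexAlignment,
                             align_duplex, best_seed_region, detect_seed_match,
                             duplex_delta_g, encode_pattern,
                             reverse_complement)
from mircurve.energy import encode_sequence, pair_kind

from conftest import random_rna


def enumerate_min_energy(q, w, model):
    """Exhaustive-enumeration oracle: min energy over all monotone pairings.

    Scores every increasing matching of pairable (guide, reversed-window)
    positions directly from the energy-model definition; independent of the
    DP recurrences.
    """
    m, n = len(q), len(w)
    rev = w[::-1]
    cells = [(i, j) for i in range(m) for j in range(n)
             if pair_kind(q[i], rev[j])]
    best = [None]

    def score(pairing):
        e = (model.end_penalty * (pairing[0][0] + (m - 1 - pairing[-1][0]))
             + model.duplex_init)
        for (a, b), (c, d) in zip(pairing, pairing[1:]):
            di, dj = c - a - 1, d - b - 1
            if di == 0 and dj == 0:
                e += model.stack_energy(q[a], rev[b], q[c], rev[d])
            else:
                if di > model.loop_max or dj > model.loop_max:
                    return None
                e += model.loop_init + model.loop_ext * (max(di, dj) - 1)
        return e

    def rec(start, pairing):
        if pairing:
            s = score(pairing)
            if s is not None and (best[0] is None or s < best[0]):
                best[0] = s
        for k in range(start, len(cells)):
            i, j = cells[k]
            if not pairing or (i > pairing[-1][0] and j > pairing[-1][1]):
                pairing.append((i, j))
                rec(k + 1, pairing)
                pairing.pop()

    rec(0, [])
    return 0.0 if best[0] is None else best[0]


def kernel_energy(q, w, model):
    pairable, stack = model.arrays()
    return duplex_min_energy(encode_sequence(q), encode_sequence(w)[::-1],
                             pairable, stack, model.loop_init, model.loop_ext,
                             model.loop_max, model.end_penalty,
                             model.duplex_init)


class TestAlignmentEnergy:
    def test_dp_matches_exhaustive_enumeration(self, model, rng):
        """Fast kernel and traceback DP both equal the enumeration oracle."""
        for _ in range(60):
            q = random_rna(rng, int(rng.integers(4, 7)))
            w = random_rna(rng, int(rng.integers(6, 9)))
            expected = enumerate_min_energy(q, w, model)
            assert kernel_energy(q, w, model) == pytest.approx(expected, abs=1e-9)
            aln = align_duplex(q, w, model)
            got = aln.delta_g if aln is not None else 0.0
            if expected < 0.0 or aln is not None:
                assert got == pytest.approx(expected, abs=1e-9)

    def test_perfect_complement_is_all_match_stack_sum(self, model):
        mir = "UGAGGUAGUAGGUUGUAUAGUU"
        win = reverse_complement(mir)
        aln = align_duplex(mir, win, model)
        assert set(aln.pair_states) == {MATCH}
        expected = sum(model.stack_energy(mir[i], win[::-1][i],
                                          mir[i + 1], win[::-1][i + 1])
                       for i in range(len(mir) - 1))
        assert aln.delta_g == pytest.approx(expected)
        assert aln.site == (0, len(mir))

    def test_poly_a_window_has_no_favorable_duplex(self, model):
        aln = align_duplex("UGAGGUAGUAGGUUGUAUAGUU", "A" * 30, model)
        # isolated pairs only: nothing below zero, rejected by any threshold
        assert aln is None or aln.delta_g >= 0.0

    def test_gu_wobble_column_state(self, model):
        # window complementary except G opposite U at guide position 4 (G)
        mir = "ACGGACGU"
        win = list(reverse_complement(mir))
        pos = len(mir) - 1 - 3          # window base pairing guide index 3
        win[pos] = "U"                  # G:U wobble instead of G:C
        aln = align_duplex(mir, "".join(win), model,
                           anchor=[(i, len(mir) - 1 - i) for i in range(8)])
        assert aln.pair_states[3] == GU
        assert [s for k, s in enumerate(aln.pair_states) if k != 3] == [MATCH] * 7

    def test_short_window_returns_sentinel(self, model):
        assert align_duplex("ACGGACGU", "ACG", model) is None

    def test_fast_path_clamps_at_zero(self, model):
        assert duplex_delta_g("ACGGACGU", "AAAAAAAA", model) <= 0.0


class TestSeedDetection:
    @staticmethod
    def _aln_from_states(states):
        cols = [Column(i, 7 - i, s) for i, s in enumerate(states)]
        return DuplexAlignment("m", "t", (0, 8), cols, -1.0, (0, 8))

    def test_seed_kind_matches_run_length_oracle(self, rng):
        """Kind over random 8-state strings equals a direct run-length scan."""
        states = [MATCH, MISMATCH, GU]
        for combo in itertools.product(states, repeat=8):
            sm = detect_seed_match(self._aln_from_states(combo))
            run = best = 0
            for s in combo:
                run = run + 1 if s == MATCH else 0
                best = max(best, run)
            expected = "none" if best < 6 else f"{min(best, 8)}mer"
            assert sm.kind == expected

    def test_6mer_at_positions_2_to_7(self):
        states = [MISMATCH] + [MATCH] * 6 + [MISMATCH]
        sm = detect_seed_match(self._aln_from_states(states))
        assert sm.kind == "6mer"
        assert sm.mirna_positions == (2, 7)

    def test_full_8mer(self):
        sm = detect_seed_match(self._aln_from_states([MATCH] * 8))
        assert sm.kind == "8mer"
        assert sm.mirna_positions == (1, 8)

    def test_gu_breaks_the_run(self):
        states = [MISMATCH] + [MATCH] * 5 + [GU, MISMATCH]
        assert detect_seed_match(self._aln_from_states(states)).kind == "none"


class TestPatternEncoding:
    def test_perfect_seed_pattern(self, model):
        mir = "ACGGACGU"
        aln = align_duplex(mir, reverse_complement(mir), model)
        assert encode_pattern(aln) == (1,) * 8

    def test_mismatch_flanked_6mer_pattern(self, model):
        mir = "ACGGACGU"
        win = list(reverse_complement(mir))
        win[0] = mir[7]   # guide position 8 opposite an identical base
        win[7] = mir[0]   # guide position 1 likewise
        aln = align_duplex(mir, "".join(win), model,
                           anchor=[(i, 7 - i) for i in range(1, 7)])
        assert encode_pattern(aln) == (2, 1, 1, 1, 1, 1, 1, 2)

    def test_bulge_adds_gap_coded_column(self, model):
        mir = "GACGACGU"
        win = reverse_complement(mir)
        # insert one target bulge base between guide positions 4 and 5
        win = win[:4] + "A" + win[4:]
        anchor = [(i, 8 - i) for i in range(4)] + [(i, 7 - i) for i in range(4, 8)]
        aln = align_duplex(mir, win, model, anchor=anchor)
        pat = encode_pattern(aln)
        assert len(pat) == 9
        assert pat.count(3) == 1
        assert pat == (1, 1, 1, 1, 3, 1, 1, 1, 1)


class TestBestSeedRegion:
    def test_matches_exhaustive_scan(self, model, rng):
        mir = random_rna(rng, 22)
        site_seq = random_rna(rng, 30)
        got = best_seed_region((0, 30), site_seq, mir, model)
        energies = [duplex_delta_g(mir[:8], site_seq[s:s + 8], model)
                    for s in range(23)]
        expected = int(np.argmin(energies))  # argmin returns 5'-most tie
        assert got == (expected, expected + 8)

    def test_uniform_sequence_takes_5prime_window(self, model):
        assert best_seed_region((10, 40), "A" * 50, "U" * 22, model) == (10, 18)

    def test_short_site_returned_whole(self, model):
        assert best_seed_region((3, 9), "ACGUACGUACG", "ACGUACGU", model) == (3, 9)

    def test_canonical_site_consistent_with_alignment(self, model):
        mir = "UGAGGUAGUAGGUUGUAUAGUU"
        win = reverse_complement(mir)
        aln = align_duplex(mir, win, model)
        s, e = best_seed_region(aln.site, win, mir, model)
        assert (s, e) == aln.seed_region
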