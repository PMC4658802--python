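"""Windowed spatial profiles: spans, AU, duplex energy, accessibility."""

from types import SimpleNamespace

import numpy as np
import pytest

from mircurve.duplex import align_duplex, reverse_complement
from mircurve.energy import encode_sequence, pair_kind
from mircurve.profiles import (PROFILE_LEN, SEED_WIDTH, SITE_WIDTH, W,
                               au_profile, ddg_profile, dg_profile,
                               open_energy, site_profiles, window_spans)

from conftest import random_rna


class TestWindowSpans:
    def test_abutting_arithmetic(self):
        spans, mask = window_spans((500, 520), 46, 2000)
        assert spans[W] == (500, 520)          # t = 0
        assert spans[W - 1] == (454, 500)      # t = -1
        assert spans[W + 1] == (520, 566)      # t = +1
        # far ends: 500 - 13*46 < 0, masked; all interior spans are live
        spans2, mask2 = window_spans((700, 720), 46, 2000)
        assert not mask2.any()
        assert spans2[0] == (700 - 13 * 46, 700 - 12 * 46)

    def test_brute_force_tiling(self, rng):
        """Spans equal an independently tiled layout for random centers."""
        for _ in range(25):
            width = int(rng.choice([SEED_WIDTH, SITE_WIDTH]))
            a = int(rng.integers(0, 1500))
            b = a + int(rng.integers(8, 60))
            spans, _ = window_spans((a, b), width, 2000)
            left = [(a - k * width, a - (k - 1) * width) for k in range(13, 0, -1)]
            right = [(b + (k - 1) * width, b + k * width) for k in range(1, 14)]
            assert spans == left + [(a, b)] + right

    def test_masking_at_transcript_start(self):
        spans, mask = window_spans((0, 20), 46, 2000)
        assert mask[:W].all() and not mask[W:].any()

    def test_partial_overhang_masked(self):
        _, mask = window_spans((30, 50), 46, 2000)
        assert mask[W - 1]  # [-16, 30) pokes past position 0


class TestAuProfile:
    def test_extreme_compositions(self):
        spans = [(0, 4)] + [(4, 8)] * 26
        mask = np.zeros(PROFILE_LEN, bool)
        prof = au_profile("AUAUGCGC", spans, mask)
        assert prof.values[0] == 1.0
        assert prof.values[1] == 0.0

    def test_counting_oracle(self, rng):
        seq = random_rna(rng, 2000)
        spans, mask = window_spans((800, 846), 46, len(seq))
        prof = au_profile(seq, spans, mask)
        for k, (s, e) in enumerate(spans):
            expected = sum(c in "AU" for c in seq[s:e]) / (e - s)
            assert prof.values[k] == pytest.approx(expected)

    def test_masked_positions_zero(self):
        seq = "AU" * 300
        spans, mask = window_spans((0, 20), 46, len(seq))
        prof = au_profile(seq, spans, mask)
        assert (prof.values[mask] == 0).all()


class TestDgProfile:
    def test_each_window_matches_standalone_alignment(self, model, rng):
        seq = random_rna(rng, 400)
        mir = random_rna(rng, 22)
        spans, mask = window_spans((180, 200), SEED_WIDTH, len(seq))
        prof = dg_profile(mir, seq, spans, mask, model)
        for k, ((s, e), m) in enumerate(zip(spans, mask)):
            if m:
                assert prof.values[k] == 0.0
                continue
            aln = align_duplex(mir, seq[s:e], model)
            expected = min(0.0, aln.delta_g) if aln else 0.0
            assert prof.values[k] == pytest.approx(expected, abs=1e-9)

    def test_perfect_complement_span_is_profile_minimum(self, model, rng):
        mir = random_rna(rng, 22)
        seq = list(random_rna(rng, 2000))
        comp = reverse_complement(mir)
        center = (900, 900 + len(comp))
        seq[center[0]:center[1]] = comp
        seq = "".join(seq)
        spans, mask = window_spans(center, SITE_WIDTH, len(seq))
        prof = dg_profile(mir, seq, spans, mask, model)
        assert np.argmin(prof.values) == W


def brute_fold_min(seq, can_pair, model):
    """Exhaustive enumeration of nested structures (oracle for small n)."""
    codes = seq
    pairE = model.fold_pair_energies()
    h = model.fold_min_hairpin

    def rec(i, j):
        if j - i < h + 1:
            return 0.0
        best = rec(i + 1, j)
        if can_pair[i]:
            for k in range(i + h + 1, j + 1):
                if can_pair[k] and pair_kind(codes[i], codes[k]):
                    best = min(best,
                               pairE[encode_sequence(codes[i])[0],
                                     encode_sequence(codes[k])[0]]
                               + rec(i + 1, k - 1) + rec(k + 1, j))
        return best

    return rec(0, len(seq) - 1)


class TestOpenEnergy:
    def test_unstructured_context_costs_nothing(self, model):
        seq = "A" * 120
        assert open_energy(seq, (40, 60), model) == 0.0

    def test_hairpin_stem_pays_its_pairing_energy(self, model):
        # 6-bp stem, 4-nt loop: forcing one stem arm open loses 6 WC pairs;
        # poly-G/poly-C arms in poly-A flanks have no alternative partners
        stem = "GGGGGG"
        seq = "A" * 20 + stem + "AAAA" + reverse_complement(stem) + "A" * 20
        span = (20, 26)
        assert open_energy(seq, span, model, fold_context=100) == pytest.approx(
            6 * abs(model.fold_wc))

    def test_matches_enumeration_oracle_small(self, model, rng):
        from mircurve._kernels import fold_min_energy
        for _ in range(15):
            seq = random_rna(rng, int(rng.integers(8, 15)))
            can = np.ones(len(seq), bool)
            got = fold_min_energy(encode_sequence(seq), can,
                                  model.fold_pair_energies(),
                                  model.fold_min_hairpin)
            assert got == pytest.approx(brute_fold_min(seq, can, model))

    def test_constraint_monotone_nonnegative(self, model, rng):
        for _ in range(10):
            seq = random_rna(rng, 120)
            s = int(rng.integers(10, 80))
            assert open_energy(seq, (s, s + 20), model) >= 0.0


class TestDdgProfile:
    def test_componentwise_composition(self, model, rng):
        seq = random_rna(rng, 500)
        mir = random_rna(rng, 22)
        spans, mask = window_spans((220, 240), SEED_WIDTH, len(seq))
        dg = dg_profile(mir, seq, spans, mask, model)
        ddg = ddg_profile(mir, seq, spans, mask, model, fold_context=60)
        for k, ((s, e), m) in enumerate(zip(spans, mask)):
            if m:
                assert ddg.values[k] == 0.0
            else:
                opened = open_energy(seq, (s, e), model, fold_context=60)
                assert ddg.values[k] == pytest.approx(dg.values[k] - opened)
                assert ddg.values[k] <= dg.values[k] + 1e-12

    def test_identity_when_nothing_to_open(self, model):
        seq = "A" * 400
        spans, mask = window_spans((180, 200), SEED_WIDTH, len(seq))
        mir = "U" * 22
        dg = dg_profile(mir, seq, spans, mask, model)
        ddg = ddg_profile(mir, seq, spans, mask, model)
        assert np.allclose(dg.values, ddg.values)


class TestProfileInvariants:
    def test_shared_masks_per_resolution(self, model, rng):
        seq = random_rna(rng, 300)
        site = SimpleNamespace(start=20, end=45, seed_region=(30, 38))
        profs = site_profiles(site, seq, random_rna(rng, 22), model,
                              fold_context=50)
        assert (profs["dg_site"].mask == profs["au_site"].mask).all()
        assert (profs["dg_site"].mask == profs["ddg_site"].mask).all()
        assert (profs["dg_seed"].mask == profs["au_seed"].mask).all()

    def test_reversal_flips_orientation_insensitive_profiles(self, model, rng):
        """AU and opening-energy values at t map to -t on the reversed
        transcript (duplex dG is antiparallel, hence excluded)."""
        seq = random_rna(rng, 600)
        a, b = 250, 270
        spans, mask = window_spans((a, b), SEED_WIDTH, len(seq))
        au = au_profile(seq, spans, mask)
        rseq = seq[::-1]
        ra, rb = len(seq) - b, len(seq) - a
        rspans, rmask = window_spans((ra, rb), SEED_WIDTH, len(rseq))
        rau = au_profile(rseq, rspans, rmask)
        assert np.allclose(au.values, rau.values[::-1])
        assert (mask == rmask[::-1]).all()
        for t in (-3, 0, 5):
            s, e = spans[W + t]
            rs, re = rspans[W - t]
            assert open_energy(seq, (s, e), model, fold_context=40) == \
                pytest.approx(open_energy(rseq, (rs, re), model,
                                          fold_context=40))
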