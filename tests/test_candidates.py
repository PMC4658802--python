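"""Candidate-set generation: two-filter rule, dedup, labeling."""

import numpy as np

from mircurve._kernels import scan_window_energies
from mircurve.duplex import (TargetSite, align_duplex, candidates_for_pair,
                             find_seed_hits, generate_candidates, label_sites,
                             reverse_complement)
from mircurve.energy import encode_sequence
from mircurve.io import ClipRegion, MirnaRecord, TranscriptRecord
from mircurve.simulate import worked_example


def oracle_candidates(mirna, transcript, model, dg_threshold=-15.0,
                      window_extra=15, seed_flank=3):
    """Independent re-derivation of the candidate set for one pair.

    Scans every stride-1 window with the (separately verified) energy
    kernel, collapses threshold-passing runs to their energy argmin, scans
    for canonical seed complements by direct string comparison, aligns both
    kinds of loci and applies greedy lower-energy overlap dedup.
    """
    seq = transcript.sequence
    L = len(seq)
    wl = min(len(mirna.sequence) + window_extra, L)
    pairable, stack = model.arrays()
    energies = scan_window_energies(
        encode_sequence(mirna.sequence), encode_sequence(seq)[::-1], wl,
        pairable, stack, model.loop_init, model.loop_ext, model.loop_max,
        model.end_penalty, model.duplex_init)
    sites = []
    k = 0
    n_win = len(energies)
    while k < n_win:
        if energies[k] >= dg_threshold:
            k += 1
            continue
        run = [k]
        while k + 1 < n_win and energies[k + 1] < dg_threshold:
            k += 1
            run.append(k)
        k += 1
        start = run[int(np.argmin(energies[run]))]
        aln = align_duplex(mirna, seq[start:start + wl], model)
        if aln and aln.delta_g < dg_threshold:
            from mircurve.duplex import detect_seed_match, encode_pattern
            sh = aln.shifted(start, transcript.id)
            sites.append((sh.site[0], sh.site[1],
                          detect_seed_match(sh).kind != "none", sh.delta_g))
    rc8 = reverse_complement(mirna.sequence[:8])
    for j in range(L - 7):
        matches = [seq[j + t] == rc8[t] for t in range(8)]
        best, run_len, k0 = 0, 0, 0
        for t, m in enumerate(matches):
            run_len = run_len + 1 if m else 0
            if run_len > best:
                best, k0 = run_len, t - run_len + 1
        if best < 6:
            continue
        w_end = min(L, j + 8 + seed_flank)
        w_start = max(0, w_end - wl)
        anchor = [(7 - t, j + t - w_start) for t in range(k0, k0 + best)]
        aln = align_duplex(mirna, seq[w_start:w_end], model, anchor=anchor)
        sh = aln.shifted(w_start, transcript.id)
        sites.append((sh.site[0], sh.site[1], True, sh.delta_g))
    kept = []
    for s in sorted(sites, key=lambda s: (s[3], s[0], s[1])):
        clash = [c for c in kept if c[0] < s[1] and s[0] < c[1]]
        if clash:
            if s[2]:
                for i, c in enumerate(kept):
                    if c[0] < s[1] and s[0] < c[1]:
                        kept[i] = (c[0], c[1], True, c[3])
            continue
        kept.append(s)
    return {(s, e, flag, round(dg, 6)) for s, e, flag, dg in kept}


class TestWorkedExample:
    def test_partition_matches_exhaustive_scan(self, model):
        """Algorithm output on the micro-dataset equals the oracle exactly."""
        fx = worked_example()
        got = generate_candidates(fx.mirnas, fx.transcripts, model)
        for mir in fx.mirnas:
            for tx in fx.transcripts:
                expected = oracle_candidates(mir, tx, model)
                mine = {(s.start, s.end, s.seed, round(s.delta_g, 6))
                        for s in got if s.mirna_id == mir.id
                        and s.transcript_id == tx.id}
                assert mine == expected

    def test_partition_is_exact(self, model):
        fx = worked_example()
        sites = generate_candidates(fx.mirnas, fx.transcripts, model)
        keys = [(s.mirna_id, s.transcript_id, s.start, s.end) for s in sites]
        assert len(keys) == len(set(keys))  # no site in both partitions

    def test_input_order_invariance(self, model):
        fx = worked_example()
        a = generate_candidates(fx.mirnas, fx.transcripts, model)
        b = generate_candidates(list(reversed(fx.mirnas)),
                                list(reversed(fx.transcripts)), model)
        key = lambda s: (s.mirna_id, s.transcript_id, s.start, s.end,
                         s.seed, round(s.delta_g, 9))
        assert [key(s) for s in a] == [key(s) for s in b]

    def test_planted_sites_recovered(self, model):
        fx = worked_example()
        sites = generate_candidates(fx.mirnas, fx.transcripts, model)
        for row in fx.truth.itertuples():
            hit = [s for s in sites if s.mirna_id == row.mirna_id
                   and s.transcript_id == row.transcript_id
                   and s.start < row.end and row.start < s.end]
            assert hit, f"planted site {row} not recovered"


class TestFilters:
    def test_strong_energy_seedless_site_included(self, model, rng):
        """dG below threshold without a canonical seed -> seedless flag."""
        mir = MirnaRecord(id="m", sequence="UGAGGUAGUAGGUUGUAUAGUU")
        insert = list(reverse_complement(mir.sequence[:16]))
        insert[-2] = mir.sequence[1]  # break seed run at guide position 2
        insert[-5] = mir.sequence[4]  # and at position 5
        seq = ("A" * 60 + "".join(insert) + "A" * 60)
        tx = TranscriptRecord(id="t", sequence=seq)
        sites = candidates_for_pair(mir, tx, model)
        strong = [s for s in sites if s.delta_g < -15.0]
        assert strong and not strong[0].seed

    def test_weak_seed_site_included_without_energy(self, model):
        """7-mer canonical match alone qualifies even with mild dG."""
        mir = MirnaRecord(id="m", sequence="UGAGGUAGUAGGUUGUAUAGUU")
        seed7 = reverse_complement(mir.sequence[:7])
        seq = "C" * 80 + seed7 + "C" * 80
        tx = TranscriptRecord(id="t", sequence=seq)
        sites = candidates_for_pair(mir, tx, model)
        assert any(s.seed and s.delta_g > -15.0 for s in sites)

    def test_no_filter_passed_no_site(self, model):
        mir = MirnaRecord(id="m", sequence="UGAGGUAGUAGGUUGUAUAGUU")
        tx = TranscriptRecord(id="t", sequence="A" * 200)
        assert candidates_for_pair(mir, tx, model) == []

    def test_seed_hits_found_at_planted_positions(self, model):
        mir = MirnaRecord(id="m", sequence="ACGGACGUACGGACGUACGGAC")
        rc8 = reverse_complement(mir.sequence[:8])
        seq = "A" * 50 + rc8 + "A" * 50
        hits = find_seed_hits(mir, "A" * 50 + rc8 + "A" * 50)
        assert any(j == 50 and rl == 8 for j, k0, rl in hits)


class TestLabeling:
    @staticmethod
    def _site(start, end, tx="t1"):
        return TargetSite(mirna_id="m", transcript_id=tx, start=start,
                          end=end, seed=True, delta_g=-20.0,
                          pattern=(1,) * 8, seed_region=(end - 8, end))

    def test_containment_rules(self):
        clip = [ClipRegion("t1", 10, 50)]
        sites = [self._site(12, 30), self._site(45, 60), self._site(5, 9)]
        label_sites(sites, clip)
        assert [s.label for s in sites] == [1, -1, -1]

    def test_transcript_without_clip_all_negative(self):
        sites = [self._site(12, 30, tx="t9")]
        label_sites(sites, [ClipRegion("t1", 0, 100)])
        assert sites[0].label == -1

    def test_merged_clip_containment(self):
        # two overlapping CLIP rows merge; containment judged on the union
        clip = [ClipRegion("t1", 10, 30), ClipRegion("t1", 25, 60)]
        sites = [self._site(20, 40)]
        label_sites(sites, clip)
        assert sites[0].label == 1
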