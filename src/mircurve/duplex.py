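"""Intermolecular miRNA:mRNA duplex alignment and candidate-site generation.

The duplex model is a gapped, antiparallel alignment of the full guide
against a target window, scored with nearest-neighbor helix stacks,
interior-loop/bulge penalties and a per-base cost for unpaired guide ends.
No intramolecular pairs are formed.  A dynamic program over base pairings
finds the minimum-energy duplex; ties are broken by fewer gap columns, then
the 5'-most target-site start.

Candidate generation follows a two-filter rule: a window enters the
candidate set if its duplex energy beats a threshold (default -15 kcal/mol)
OR it contains a canonical seed match (>= 6 consecutive Watson-Crick pairs
within guide positions 1-8); G:U wobbles never count toward a seed run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .energy import EnergyModel, encode_sequence, pair_kind
from .io import MirnaRecord, TranscriptRecord, clip_by_transcript

MATCH, MISMATCH, GAP, GU = "MATCH", "MISMATCH", "GAP", "GU"
PATTERN_CODE = {MATCH: 1, MISMATCH: 2, GAP: 3, GU: 4}

_TOL = 1e-9

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT.get(c, "N") for c in reversed(seq))


@dataclass
class Column:
    """One aligned duplex column: guide index, target index (or None), state."""

    mirna_index: int | None
    mrna_index: int | None
    state: str


@dataclass
class DuplexAlignment:
    """An aligned guide:target duplex over one window.

    ``site`` is the half-open interval of consumed target nucleotides in the
    coordinate system of the window (shift with :meth:`shifted`).
    """

    mirna_id: str
    transcript_id: str
    site: tuple[int, int]
    columns: list[Column]
    delta_g: float
    seed_region: tuple[int, int]

    @property
    def pair_states(self) -> list[str]:
        return [c.state for c in self.columns]

    def shifted(self, offset: int, transcript_id: str | None = None) -> "DuplexAlignment":
        cols = [Column(c.mirna_index,
                       None if c.mrna_index is None else c.mrna_index + offset,
                       c.state) for c in self.columns]
        return DuplexAlignment(
            mirna_id=self.mirna_id,
            transcript_id=transcript_id or self.transcript_id,
            site=(self.site[0] + offset, self.site[1] + offset),
            columns=cols,
            delta_g=self.delta_g,
            seed_region=(self.seed_region[0] + offset, self.seed_region[1] + offset),
        )


@dataclass(frozen=True)
class SeedMatch:
    kind: str  # "6mer" | "7mer" | "8mer" | "none"
    mirna_positions: tuple[int, int]  # 1-based closed interval, (0, 0) if none


@dataclass
class TargetSite:
    """A candidate target site on one transcript for one miRNA."""

    mirna_id: str
    transcript_id: str
    start: int
    end: int
    seed: bool
    delta_g: float
    pattern: tuple[int, ...]
    seed_region: tuple[int, int]
    label: int = 0
    alignment: DuplexAlignment | None = field(default=None, repr=False, compare=False)


# ---------------------------------------------------------------------------
# pairing DP (pure Python, with traceback; agrees with the numba fast path)
# ---------------------------------------------------------------------------

def _better(a, b):
    """Pick the better of two (energy, gaps, ...) candidates; None loses."""
    if a is None:
        return b
    if b is None:
        return a
    if b[0] < a[0] - _TOL:
        return b
    if b[0] > a[0] + _TOL:
        return a
    return b if b[1:-1] < a[1:-1] else a


def _min_energy_pairing(qc, rc, model: EnergyModel, anchor_rev=None):
    """Minimum-energy monotone pairing of guide codes vs reversed-window codes.

    Returns (pairing, energy, gaps) or None; pairing is a list of (i, jr)
    with both coordinates strictly increasing.  ``anchor_rev`` maps guide
    indices to forced reversed-window partners; anchored guide indices must
    all be paired as given.
    """
    m, n = len(qc), len(rc)
    pairable, stack = model.arrays()
    lm, li, le = model.loop_max, model.loop_init, model.loop_ext
    ep = model.end_penalty
    anchors = sorted(anchor_rev) if anchor_rev else []
    B: dict[tuple[int, int], tuple] = {}
    for i in range(m):
        for jr in range(n):
            if not pairable[qc[i], rc[jr]]:
                continue
            if anchor_rev and i in anchor_rev and anchor_rev[i] != jr:
                continue
            best = None
            if not anchors or anchors[0] >= i:
                # open the duplex here; leading guide bases unpaired
                best = (ep * i, max(0, i - jr), None)
            if i > 0 and jr > 0 and (i - 1, jr - 1) in B:
                pe, pg, _ = B[(i - 1, jr - 1)]
                best = _better(best, (pe + stack[qc[i - 1], rc[jr - 1], qc[i], rc[jr]],
                                      pg, (i - 1, jr - 1)))
            for di in range(lm + 1):
                ii = i - 1 - di
                if ii < 0:
                    break
                for dj in range(lm + 1):
                    jj = jr - 1 - dj
                    if jj < 0:
                        break
                    if di == 0 and dj == 0:
                        continue
                    prev = B.get((ii, jj))
                    if prev is None:
                        continue
                    if anchors and any(ii < a < i for a in anchors):
                        continue  # a forced pair may not sit inside a loop
                    L = max(di, dj)
                    best = _better(best, (prev[0] + li + le * (L - 1),
                                          prev[1] + abs(di - dj), (ii, jj)))
            if best is not None:
                B[(i, jr)] = best
    final = None  # (energy, gaps, site_start_key, cell)
    for (i, jr), (e, g, _) in B.items():
        if anchors and anchors[-1] > i:
            continue
        trail = m - 1 - i
        avail = n - 1 - jr
        trail_mm = min(trail, avail)
        cand = (e + ep * trail + model.duplex_init,
                g + max(0, trail - avail),
                n - 1 - jr - trail_mm,  # site start in original window coords
                (i, jr))
        final = _better(final, cand)
    if final is None:
        return None
    pairing = []
    cell = final[3]
    while cell is not None:
        pairing.append(cell)
        cell = B[cell][2]
    pairing.reverse()
    return pairing, final[0], final[1]


def _columns_from_pairing(pairing, q: str, w: str):
    """Expand a pairing into duplex columns (guide order, 5'->3')."""
    m, n = len(q), len(w)
    rev = w[::-1]
    cols: list[Column] = []

    def orig(jr):
        return n - 1 - jr

    i1, jr1 = pairing[0]
    lead_mm = min(i1, jr1)
    for i in range(i1):
        offset = i1 - i
        if offset <= lead_mm:
            cols.append(Column(i, orig(jr1 - offset), MISMATCH))
        else:
            cols.append(Column(i, None, GAP))
    for idx, (i, jr) in enumerate(pairing):
        kind = pair_kind(q[i], rev[jr])
        cols.append(Column(i, orig(jr), MATCH if kind == "wc" else GU))
        if idx + 1 < len(pairing):
            ni, njr = pairing[idx + 1]
            di, dj = ni - i - 1, njr - jr - 1
            mm = min(di, dj)
            for t in range(mm):
                cols.append(Column(i + 1 + t, orig(jr + 1 + t), MISMATCH))
            for t in range(di - mm):
                cols.append(Column(i + 1 + mm + t, None, GAP))
            for t in range(dj - mm):
                cols.append(Column(None, orig(jr + 1 + mm + t), GAP))
    ik, jrk = pairing[-1]
    trail_mm = min(m - 1 - ik, n - 1 - jrk)
    for t in range(1, m - ik):
        if t <= trail_mm:
            cols.append(Column(ik + t, orig(jrk + t), MISMATCH))
        else:
            cols.append(Column(ik + t, None, GAP))
    return cols


def _seed_span_columns(columns):
    """Columns aligned to guide positions 1-8, including interior bulges."""
    idx = [k for k, c in enumerate(columns) if c.mirna_index is not None
           and c.mirna_index <= 7]
    if not idx:
        return []
    return columns[idx[0]:idx[-1] + 1]


def align_duplex(mirna, window: str, model: EnergyModel | None = None,
                 anchor=None) -> DuplexAlignment | None:
    """Minimum-energy duplex of a guide against one target window.

    Parameters
    ----------
    mirna : MirnaRecord or str
    window : str
        Target window, 5'->3'.  Shorter than 6 nt -> ``None`` (no-alignment
        sentinel), as is any window with no possible base pair.
    anchor : list of (guide_index, window_index), optional
        Base pairs forced into the duplex (used to pin seed matches).
    """
    model = model or EnergyModel.default()
    mid = mirna.id if isinstance(mirna, MirnaRecord) else "mirna"
    q = mirna.sequence if isinstance(mirna, MirnaRecord) else mirna
    if len(window) < 6:
        return None
    qc = encode_sequence(q)
    rc = encode_sequence(window)[::-1]
    anchor_rev = None
    if anchor:
        n = len(window)
        anchor_rev = {i: n - 1 - j for i, j in anchor}
    res = _min_energy_pairing(qc, rc, model, anchor_rev)
    if res is None:
        return None
    pairing, energy, _ = res
    cols = _columns_from_pairing(pairing, q, window)
    js = [c.mrna_index for c in cols if c.mrna_index is not None]
    site = (min(js), max(js) + 1)
    seed_cols = _seed_span_columns(cols)
    sjs = [c.mrna_index for c in seed_cols if c.mrna_index is not None]
    seed_region = (min(sjs), max(sjs) + 1) if sjs else (site[0], site[0])
    return DuplexAlignment(mirna_id=mid, transcript_id="", site=site,
                           columns=cols, delta_g=float(energy),
                           seed_region=seed_region)


def duplex_delta_g(mirna, window: str, model: EnergyModel | None = None) -> float:
    """Fast window free energy: min(0, best duplex energy)."""
    model = model or EnergyModel.default()
    q = mirna.sequence if isinstance(mirna, MirnaRecord) else mirna
    if len(window) < 1:
        return 0.0
    pairable, stack = model.arrays()
    e = _kernels.duplex_min_energy(
        encode_sequence(q), encode_sequence(window)[::-1], pairable, stack,
        model.loop_init, model.loop_ext, model.loop_max, model.end_penalty,
        model.duplex_init)
    return min(0.0, float(e))


# ---------------------------------------------------------------------------
# seed detection and pattern encoding
# ---------------------------------------------------------------------------

def detect_seed_match(aln: DuplexAlignment) -> SeedMatch:
    """Longest run of consecutive Watson-Crick pairs within guide nt 1-8.

    A run of >= 6 is a canonical seed; G:U wobbles and bulge columns break
    the run.  Run length is capped at "8mer".
    """
    best_len, best_start = 0, None
    run_len, run_start = 0, None
    for col in _seed_span_columns(aln.columns):
        if col.state == MATCH:
            if run_len == 0:
                run_start = col.mirna_index
            run_len += 1
            if run_len > best_len:
                best_len, best_start = run_len, run_start
        else:
            run_len = 0
    if best_len < 6:
        return SeedMatch("none", (0, 0))
    kind = f"{min(best_len, 8)}mer"
    return SeedMatch(kind, (best_start + 1, best_start + best_len))


def encode_pattern(aln: DuplexAlignment) -> tuple[int, ...]:
    """Alignment pattern of guide nt 1-8: 1 match, 2 mismatch, 3 gap, 4 GU.

    Columns run from guide position 1 leftward; target bulges inside the
    span appear as their own gap-coded columns, so the vector has length
    >= 8.
    """
    return tuple(PATTERN_CODE[c.state] for c in _seed_span_columns(aln.columns))


def best_seed_region(site_interval, transcript, mirna,
                     model: EnergyModel | None = None) -> tuple[int, int]:
    """Target 8-window inside the site with the best guide nt 1-8 duplex.

    Used for seedless sites, where no canonical seed pins the seed-resolution
    curves.  Ties go to the 5'-most window; sites shorter than 8 nt are
    returned whole.
    """
    model = model or EnergyModel.default()
    seq = transcript.sequence if isinstance(transcript, TranscriptRecord) else transcript
    start, end = site_interval
    if end - start < 8:
        return (start, end)
    mir8 = (mirna.sequence if isinstance(mirna, MirnaRecord) else mirna)[:8]
    best = (np.inf, None)
    for s in range(start, end - 7):
        e = duplex_delta_g(mir8, seq[s:s + 8], model)
        if e < best[0] - _TOL:
            best = (e, s)
    if best[1] is None:
        return (start, start + 8)
    return (best[1], best[1] + 8)


# ---------------------------------------------------------------------------
# Candidate-set generation
# ---------------------------------------------------------------------------

def _scan_energy_loci(mirna, transcript, model, dg_threshold, window_extra):
    """Window starts worth aligning: per run of threshold-passing stride-1
    windows, the argmin-energy start (tie -> 5'-most)."""
    L = len(transcript.sequence)
    wl = min(len(mirna.sequence) + window_extra, L)
    if wl < 6:
        return wl, []
    pairable, stack = model.arrays()
    energies = _kernels.scan_window_energies(
        encode_sequence(mirna.sequence),
        encode_sequence(transcript.sequence)[::-1], wl, pairable, stack,
        model.loop_init, model.loop_ext, model.loop_max, model.end_penalty,
        model.duplex_init)
    passing = np.flatnonzero(energies < dg_threshold)
    loci = []
    run: list[int] = []
    for k in passing:
        if run and k != run[-1] + 1:
            loci.append(int(run[int(np.argmin(energies[run]))]))
            run = []
        run.append(int(k))
    if run:
        loci.append(int(run[int(np.argmin(energies[run]))]))
    return wl, loci


def find_seed_hits(mirna, transcript):
    """All canonical seed complements: (window8_start, run_k0, run_len).

    ``window8_start`` is the transcript position pairing guide position 8;
    the run covers window offsets [run_k0, run_k0 + run_len) where offset k
    pairs guide position 8 - k.
    """
    seq = transcript.sequence if isinstance(transcript, TranscriptRecord) else transcript
    rc8 = reverse_complement(
        (mirna.sequence if isinstance(mirna, MirnaRecord) else mirna)[:8])
    hits = []
    for j in range(len(seq) - 7):
        best_len, best_k0 = 0, 0
        run = 0
        for k in range(8):
            if seq[j + k] == rc8[k]:
                run += 1
                if run > best_len:
                    best_len, best_k0 = run, k - run + 1
            else:
                run = 0
        if best_len >= 6:
            hits.append((j, best_k0, best_len))
    return hits


def _sites_overlap(a: TargetSite, b: TargetSite) -> bool:
    return a.start < b.end and b.start < a.end


def _dedup_overlapping(sites):
    """Greedy per-(miRNA, transcript) dedup keeping the lower-energy site.

    A discarded overlapping seed site passes its seed flag to the kept one
    (the locus has a canonical match even if the kept minimum-energy duplex
    does not use it).
    """
    kept: list[TargetSite] = []
    for site in sorted(sites, key=lambda s: (s.delta_g, s.start, s.end)):
        clash = [k for k in kept if _sites_overlap(k, site)]
        if clash:
            if site.seed:
                for k in clash:
                    k.seed = True
            continue
        kept.append(site)
    kept.sort(key=lambda s: s.start)
    return kept


def _make_site(aln: DuplexAlignment, offset: int, mirna, transcript,
               forced_seed: bool = False) -> TargetSite:
    shifted = aln.shifted(offset, transcript.id)
    shifted.mirna_id = mirna.id
    seed = forced_seed or detect_seed_match(shifted).kind != "none"
    return TargetSite(
        mirna_id=mirna.id, transcript_id=transcript.id,
        start=shifted.site[0], end=shifted.site[1], seed=seed,
        delta_g=shifted.delta_g, pattern=encode_pattern(shifted),
        seed_region=shifted.seed_region, alignment=shifted)


def candidates_for_pair(mirna: MirnaRecord, transcript: TranscriptRecord,
                        model: EnergyModel, dg_threshold: float = -15.0,
                        window_extra: int = 15, seed_flank: int = 3):
    """Candidate sites for one (miRNA, transcript) pair.

    Energy filter: stride-1 windows of length ``len(miRNA) + window_extra``
    with duplex energy below ``dg_threshold``.  Seed filter: every canonical
    >= 6-mer Watson-Crick seed complement, aligned with the seed pairs
    pinned, regardless of energy.  Overlapping sites are deduplicated
    keeping the lower-energy one.
    """
    L = len(transcript.sequence)
    sites: list[TargetSite] = []
    wl, loci = _scan_energy_loci(mirna, transcript, model, dg_threshold,
                                 window_extra)
    for start in loci:
        aln = align_duplex(mirna, transcript.sequence[start:start + wl], model)
        if aln is not None and aln.delta_g < dg_threshold:
            sites.append(_make_site(aln, start, mirna, transcript))
    for (j, k0, rl) in find_seed_hits(mirna, transcript):
        w_end = min(L, j + 8 + seed_flank)
        w_start = max(0, w_end - wl)
        anchor = [(7 - k, j + k - w_start) for k in range(k0, k0 + rl)]
        aln = align_duplex(mirna, transcript.sequence[w_start:w_end], model,
                           anchor=anchor)
        if aln is not None:
            sites.append(_make_site(aln, w_start, mirna, transcript,
                                    forced_seed=True))
    return _dedup_overlapping(sites)


def generate_candidates(mirnas, transcripts, model: EnergyModel | None = None,
                        dg_threshold: float = -15.0, window_extra: int = 15,
                        seed_flank: int = 3) -> list[TargetSite]:
    """Candidate set over all (miRNA, transcript) pairs.

    Output order is deterministic (sorted by transcript id, miRNA id, site
    start) and independent of input order.
    """
    model = model or EnergyModel.default()
    sites: list[TargetSite] = []
    for tx in sorted(transcripts, key=lambda t: t.id):
        for mir in sorted(mirnas, key=lambda m: m.id):
            sites.extend(candidates_for_pair(mir, tx, model, dg_threshold,
                                             window_extra, seed_flank))
    return sites


def label_sites(candidates, clip_regions) -> list[TargetSite]:
    """Label each site +1 iff contained in a merged CLIP interval, else -1."""
    by_tx = clip_by_transcript(clip_regions)
    for site in candidates:
        intervals = by_tx.get(site.transcript_id, [])
        site.label = 1 if any(s <= site.start and site.end <= e
                              for s, e in intervals) else -1
    return candidates
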