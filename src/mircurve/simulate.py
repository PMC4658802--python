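"""Synthetic fixtures: transcripts, miRNAs, CLIP regions, conservation.

The generator embeds near-complementary target sites for known guides into
i.i.d. random background transcripts and (optionally) wraps them in
AGO-crosslink-style CLIP regions, so every pipeline stage can be exercised
and calibrated without external downloads.  Signal toggles control which
real-data signatures the fixture reproduces:

``plant_seed_complement``
    On: CLIP regions wrap the embedded sites (labels carry signal) and the
    embedded sites get elevated conservation.  Off: the embeddings still
    exist, but CLIP regions wrap a fair-coin random subset of all candidate
    loci instead — labels are then a random subset of the candidate
    population, uncorrelated with every feature: the null condition.
``au_elevation``
    AU-rich flanks (target AU fraction ``au_site_frac``) around embedded
    sites, the local-AU signature of functional sites.
``structure_free_site``
    Flanks around embedded sites are redrawn to suppress secondary
    structure over the site (low opening energy, i.e. accessible sites).
``enrich_patterns``
    A subset of embedded sites uses the listed non-canonical seed-alignment
    patterns instead of a perfect match, over-representing them among
    positives.

Background bases are i.i.d. (uniform by default, configurable GC bias), so
the 0.25^|a| chance model of the enrichment score is exact on unplanted
sequence.  Output is deterministic per seed, byte-identical on re-runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .energy import EnergyModel
from .io import ClipRegion, MirnaRecord, TranscriptRecord, write_fasta
from .profiles import open_energy

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WOBBLE = {"G": "U", "U": "G"}

DEFAULT_ENRICH_PATTERNS = (
    (2, 1, 1, 1, 1, 1, 1, 2),      # canonical 6mer, positions 2-7
    (1, 1, 1, 4, 1, 1, 1, 2),      # seedless: wobble-interrupted run
)


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic dataset."""

    n_transcripts: int = 50
    transcript_length: tuple[int, int] = (900, 1100)
    region_fracs: tuple[float, float, float] = (0.15, 0.45, 0.40)
    n_mirnas: int = 4
    mirna_length: int = 22
    mirna_au: float = 0.7           # miRNAs (hence embedded sites) AU-rich
    sites_per_transcript: int = 3
    plant_length: int = 18          # guide nt complemented by an embedding;
                                    # long enough that even non-canonical
                                    # patterns clear the energy filter
    clip_width: tuple[int, int] = (46, 60)
    clip_coverage: float = 1.0      # fraction of embedded sites CLIP-wrapped
    noise: float = 0.0              # per-site CLIP misplacement probability
    null_wrap_prob: float = 0.45    # per-locus wrap probability, null mode
    gc_content: float = 0.5
    plant_seed_complement: bool = True
    au_elevation: bool = True
    au_site_frac: float = 0.8
    au_flank: int = 20
    structure_free_site: bool = True
    enrich_patterns: tuple = DEFAULT_ENRICH_PATTERNS
    enrich_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.region_fracs) - 1.0) > 1e-9:
            raise ValueError("region fractions must sum to 1")


@dataclass
class Fixture:
    """Generated records plus ground truth."""

    spec: FixtureSpec
    transcripts: list[TranscriptRecord]
    mirnas: list[MirnaRecord]
    clip_regions: list[ClipRegion]
    truth: pd.DataFrame
    conservation_rows: list = field(repr=False, default_factory=list)

    def write(self, out_dir) -> dict[str, Path]:
        """Write the standard input files; deterministic byte-for-byte."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {k: out / f"{k}.{ext}" for k, ext in
                 (("transcripts", "fa"), ("mirnas", "fa"), ("clip", "bed"),
                  ("conservation", "tsv"), ("regions", "tsv"),
                  ("truth", "tsv"))}
        write_fasta(self.transcripts, paths["transcripts"])
        write_fasta(self.mirnas, paths["mirnas"])
        with open(paths["clip"], "w") as fh:
            for r in self.clip_regions:
                fh.write(f"{r.transcript_id}\t{r.start}\t{r.end}\n")
        with open(paths["conservation"], "w") as fh:
            for tx_id, s, e, score in self.conservation_rows:
                fh.write(f"{tx_id}\t{s}\t{e}\t{score:.3f}\n")
        with open(paths["regions"], "w") as fh:
            for t in self.transcripts:
                fh.write(f"{t.id}\t{t.regions['five_utr'][1]}"
                         f"\t{t.regions['cds'][1]}\n")
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _draw_bases(rng, n, gc: float) -> list[str]:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return ["ACGU"[i] for i in rng.choice(4, size=n, p=p)]


def _draw_au_rich(rng, n, au_frac: float) -> list[str]:
    p = np.array([au_frac / 2, (1 - au_frac) / 2, (1 - au_frac) / 2,
                  au_frac / 2])
    return ["ACGU"[i] for i in rng.choice(4, size=n, p=p)]


def _seed_segment(mir_seq: str, pattern, rng) -> str:
    """Target seed-region sequence (5'->3') realizing one alignment pattern."""
    if sum(1 for c in pattern if c != 3) != 8:
        raise ValueError("pattern must cover exactly guide positions 1-8")
    bases = []
    mir_pos = 8
    for code in reversed(pattern):
        if code == 3:
            bases.append("ACGU"[rng.integers(4)])
            continue
        b = mir_seq[mir_pos - 1]
        if code == 1:
            bases.append(_COMP[b])
        elif code == 4:
            bases.append(_WOBBLE.get(b, b))
        else:
            bases.append(b)  # identical base can never pair
        mir_pos -= 1
    return "".join(bases)


def _site_sequence(mir_seq: str, pattern, plant_length: int, rng) -> str:
    """Embedded target sequence: 3' complement + patterned seed segment."""
    tail = "".join(_COMP[mir_seq[i]] for i in range(plant_length - 1, 7, -1))
    return tail + _seed_segment(mir_seq, pattern, rng)


def generate(spec: FixtureSpec, model: EnergyModel | None = None) -> Fixture:
    """Generate one fixture dataset according to ``spec``."""
    model = model or EnergyModel.default()
    root = np.random.SeedSequence(spec.seed)
    ss = {name: np.random.default_rng(s) for name, s in
          zip(("mirna", "background", "plant", "clip", "cons"), root.spawn(5))}
    # AU-biased guides: complementation preserves AU fraction, so embedded
    # sites inherit the elevated AU content of functional target regions
    mirnas = [MirnaRecord(id=f"mir{i + 1}",
                          sequence="".join(_draw_au_rich(ss["mirna"],
                                                         spec.mirna_length,
                                                         spec.mirna_au)))
              for i in range(spec.n_mirnas)]
    transcripts: list[TranscriptRecord] = []
    clip_regions: list[ClipRegion] = []
    truth_rows = []
    cons_rows = []
    site_counter = 0
    rng_p, rng_c = ss["plant"], ss["clip"]
    for t in range(spec.n_transcripts):
        lo, hi = spec.transcript_length
        L = int(ss["background"].integers(lo, hi + 1))
        seq = _draw_bases(ss["background"], L, spec.gc_content)
        a = int(round(spec.region_fracs[0] * L))
        b = int(round((spec.region_fracs[0] + spec.region_fracs[1]) * L))
        tx_id = f"tx{t + 1:03d}"
        planted = []  # (start, end, mirna, pattern)
        occupied: list[tuple[int, int]] = []
        for _ in range(spec.sites_per_transcript):
            mir = mirnas[site_counter % spec.n_mirnas]
            site_counter += 1
            if spec.enrich_patterns and rng_p.random() < spec.enrich_fraction:
                pattern = tuple(spec.enrich_patterns[
                    rng_p.integers(len(spec.enrich_patterns))])
            else:
                pattern = (1,) * 8
            site_seq = _site_sequence(mir.sequence, pattern,
                                      spec.plant_length, rng_p)
            for _try in range(50):
                start = int(rng_p.integers(70, L - 70 - len(site_seq)))
                span = (start - 70, start + len(site_seq) + 70)
                if all(span[1] <= s or span[0] >= e for s, e in occupied):
                    break
            else:
                continue  # no room left on this transcript
            occupied.append((start - 70, start + len(site_seq) + 70))
            seq[start:start + len(site_seq)] = list(site_seq)
            planted.append((start, start + len(site_seq), mir, pattern))
        # flank signals
        for (s, e, mir, pattern) in planted:
            if spec.au_elevation:
                for lo_f, hi_f in ((max(0, s - spec.au_flank), s),
                                   (e, min(L, e + spec.au_flank))):
                    seq[lo_f:hi_f] = _draw_au_rich(rng_p, hi_f - lo_f,
                                                   spec.au_site_frac)
        tx = TranscriptRecord(id=tx_id, sequence="".join(seq),
                              regions={"five_utr": (0, a), "cds": (a, b),
                                       "three_utr": (b, L)})
        if spec.structure_free_site:
            for (s, e, mir, pattern) in planted:
                tx = _relax_structure(tx, (s, e), spec, rng_p, model)
        transcripts.append(tx)
        # CLIP placement
        def _wrap(ws, we):
            width = int(rng_c.integers(spec.clip_width[0],
                                       spec.clip_width[1] + 1))
            width = max(width, we - ws)
            lo_c = max(0, we - width)
            hi_c = min(ws, L - width)
            c_start = (int(rng_c.integers(lo_c, hi_c + 1)) if hi_c >= lo_c
                       else max(0, ws))
            clip_regions.append(ClipRegion(tx_id, c_start, c_start + width))

        if spec.plant_seed_complement:
            for (s, e, mir, pattern) in planted:
                # the AGO footprint must cover the whole duplex, which
                # extends 5' of the embedding when the full guide aligns
                ws = max(0, s - (spec.mirna_length - spec.plant_length) - 6)
                we = min(L, e + 4)
                wrapped = (rng_c.random() < spec.clip_coverage
                           and rng_c.random() >= spec.noise)
                if wrapped:
                    _wrap(ws, we)
                else:
                    width = int(rng_c.integers(spec.clip_width[0],
                                               spec.clip_width[1] + 1))
                    c_start = int(rng_c.integers(0, L - width))
                    clip_regions.append(ClipRegion(tx_id, c_start,
                                                   c_start + width))
                truth_rows.append({
                    "transcript_id": tx_id, "mirna_id": mir.id, "start": s,
                    "end": e, "pattern": "-".join(map(str, pattern)),
                    "planted": True, "clip_wrapped": wrapped})
        else:
            # null condition: wrap a fair-coin random subset of candidate
            # loci (embeddings, seed-complement hits and energy-scan loci,
            # merged so each locus gets exactly one coin).  Positives become
            # a random subset of the whole candidate population, independent
            # of every sequence feature by construction.
            from .duplex import _scan_energy_loci, find_seed_hits
            from .io import merge_intervals

            tx_seq = tx.sequence
            wl = spec.mirna_length + 15
            spans = [(max(0, s - (spec.mirna_length - spec.plant_length) - 6),
                      min(L, e + 4)) for (s, e, _m, _p) in planted]
            for mir in mirnas:
                for (j, _k0, _rl) in find_seed_hits(mir, tx_seq):
                    we = min(L, j + 8 + 5)
                    ws = max(0, we - wl - 4)
                    spans.append((ws, we))
                _wle, eloci = _scan_energy_loci(mir, tx, model, -15.0, 15)
                for k in eloci:
                    spans.append((max(0, k - 2), min(L, k + _wle + 2)))
            for (ws, we) in merge_intervals(spans):
                if rng_c.random() < spec.null_wrap_prob:
                    _wrap(ws, we)
            for (s, e, mir, pattern) in planted:
                truth_rows.append({
                    "transcript_id": tx_id, "mirna_id": mir.id, "start": s,
                    "end": e, "pattern": "-".join(map(str, pattern)),
                    "planted": False, "clip_wrapped": False})
        # conservation: low blocks, elevated over wrapped planted sites
        pos = 0
        while pos < L:
            end = min(L, pos + 25)
            cons_rows.append((tx_id, pos, end,
                              round(float(ss["cons"].uniform(0.0, 0.4)), 3)))
            pos = end
        if spec.plant_seed_complement:
            for (s, e, mir, pattern) in planted:
                cons_rows.append((tx_id, s, e,
                                  round(float(ss["cons"].uniform(0.6, 1.0)), 3)))
    # paint conservation onto records (same painting as read_conservation)
    by_id = {t.id: t for t in transcripts}
    for tx_id, s, e, score in cons_rows:
        by_id[tx_id].conservation[s:e] = score
    truth = pd.DataFrame(truth_rows, columns=[
        "transcript_id", "mirna_id", "start", "end", "pattern", "planted",
        "clip_wrapped"])
    return Fixture(spec=spec, transcripts=transcripts, mirnas=mirnas,
                   clip_regions=sorted(clip_regions,
                                       key=lambda r: (r.transcript_id, r.start)),
                   truth=truth, conservation_rows=cons_rows)


def _relax_structure(tx: TranscriptRecord, site: tuple[int, int],
                     spec: FixtureSpec, rng, model: EnergyModel,
                     flank: int = 60, tries: int = 6,
                     target: float = 1.0) -> TranscriptRecord:
    """Redraw site flanks until the site's opening energy is near zero."""
    s, e = site
    L = len(tx.sequence)
    best_seq, best_open = tx.sequence, open_energy(tx, site, model)
    for _ in range(tries):
        if best_open <= target:
            break
        seq = list(best_seq)
        for lo, hi in ((max(0, s - flank), s), (e, min(L, e + flank))):
            for i in range(lo, hi):
                au_zone = (s - spec.au_flank <= i < s) or (e <= i < e + spec.au_flank)
                if spec.au_elevation and au_zone:
                    seq[i] = _draw_au_rich(rng, 1, spec.au_site_frac)[0]
                else:
                    seq[i] = _draw_bases(rng, 1, spec.gc_content)[0]
        cand = TranscriptRecord(id=tx.id, sequence="".join(seq),
                                regions=tx.regions,
                                conservation=tx.conservation)
        cand_open = open_energy(cand, site, model)
        if cand_open < best_open:
            best_seq, best_open = cand.sequence, cand_open
    return TranscriptRecord(id=tx.id, sequence=best_seq, regions=tx.regions,
                            conservation=tx.conservation)


def worked_example(seed: int = 7) -> Fixture:
    """A hand-enumerable micro-dataset: 2 transcripts, 2 miRNAs, 3 sites."""
    spec = FixtureSpec(n_transcripts=2, transcript_length=(600, 600),
                       n_mirnas=2, sites_per_transcript=2,
                       clip_coverage=1.0, noise=0.0, seed=seed)
    fx = generate(spec)
    # trim to exactly 3 planted sites: drop the second site of transcript 2
    keep = fx.truth.index[:3]
    dropped = fx.truth.loc[~fx.truth.index.isin(keep)]
    truth = fx.truth.loc[keep].reset_index(drop=True)
    drop_keys = {(r.transcript_id, r.start) for r in dropped.itertuples()}
    clip = [c for c in fx.clip_regions
            if not any(c.transcript_id == t and c.start <= s < c.end
                       for t, s in drop_keys)]
    return Fixture(spec=spec, transcripts=fx.transcripts, mirnas=fx.mirnas,
                   clip_regions=clip, truth=truth,
                   conservation_rows=fx.conservation_rows)
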