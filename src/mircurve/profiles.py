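"""Spatial feature profiles around a target site.

Each candidate site gets six 27-point profiles: duplex energy (dG),
accessibility (ddG = dG - dG_open) and local AU content, each at site
resolution (window width 46, the approximate AGO footprint) and seed
resolution (width 9).  Position t = 0 is the site (or seed-matched) region
itself; t = +/-1..13 are consecutive non-overlapping windows abutting it.
Windows falling off the transcript are masked and carry the value 0.

Opening energies come from a simplified intramolecular fold (weighted
base-pair maximization): dG_open = E(context with the window forced
unpaired) - E(context unconstrained) >= 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .duplex import duplex_delta_g
from .energy import EnergyModel, encode_sequence
from .io import MirnaRecord, TranscriptRecord

W = 13                 # flanking windows per side
PROFILE_LEN = 2 * W + 1
SITE_WIDTH = 46        # AGO-footprint-scale resolution
SEED_WIDTH = 9         # seed-scale resolution
DEFAULT_FOLD_CONTEXT = 100

PROFILE_FEATURES = ("dg_site", "dg_seed", "ddg_site", "ddg_seed",
                    "au_site", "au_seed")


@dataclass
class CurveProfile:
    """A 27-point windowed feature vector with an off-transcript mask."""

    feature: str
    values: np.ndarray  # length 27, index t + 13 for t in [-13, 13]
    mask: np.ndarray    # True where the window fell off the transcript

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != (PROFILE_LEN,) or self.mask.shape != (PROFILE_LEN,):
            raise ValueError(f"profile must have length {PROFILE_LEN}")
        if np.any(self.values[self.mask] != 0.0):
            raise ValueError("masked positions must hold 0")


def window_spans(center: tuple[int, int], width: int, transcript_len: int):
    """The 27 half-open spans at offsets t = -13..13 around ``center``.

    Span t = 0 is the center interval itself (its own, possibly different,
    width); flanking spans are consecutive width-wide blocks abutting it.
    Returns (spans, mask) where masked spans extend past [0, transcript_len).
    """
    a, b = center
    spans, mask = [], []
    for t in range(-W, W + 1):
        if t == 0:
            s, e = a, b
        elif t < 0:
            s, e = a + t * width, a + (t + 1) * width
        else:
            s, e = b + (t - 1) * width, b + t * width
        spans.append((s, e))
        mask.append(s < 0 or e > transcript_len or s >= e)
    return spans, np.array(mask, dtype=bool)


def au_profile(transcript, spans, mask) -> CurveProfile:
    """Fraction of A/U nucleotides per span; masked spans are 0."""
    seq = transcript.sequence if isinstance(transcript, TranscriptRecord) else transcript
    values = np.zeros(PROFILE_LEN)
    for k, ((s, e), m) in enumerate(zip(spans, mask)):
        if m:
            continue
        block = seq[s:e]
        values[k] = sum(c in "AU" for c in block) / len(block)
    return CurveProfile("au", values, mask.copy())


def dg_profile(mirna, transcript, spans, mask,
               model: EnergyModel | None = None) -> CurveProfile:
    """Minimum duplex energy of the guide against each span; masked -> 0."""
    model = model or EnergyModel.default()
    seq = transcript.sequence if isinstance(transcript, TranscriptRecord) else transcript
    values = np.zeros(PROFILE_LEN)
    for k, ((s, e), m) in enumerate(zip(spans, mask)):
        if m:
            continue
        values[k] = duplex_delta_g(mirna, seq[s:e], model)
    return CurveProfile("dg", values, mask.copy())


def open_energy(transcript, span: tuple[int, int],
                model: EnergyModel | None = None,
                fold_context: int = DEFAULT_FOLD_CONTEXT) -> float:
    """Energy cost of forcing ``span`` single-stranded in its local context.

    The folding context is the span extended by ``fold_context`` nt on each
    side (clipped to the transcript).  Non-negative by construction.
    """
    model = model or EnergyModel.default()
    seq = transcript.sequence if isinstance(transcript, TranscriptRecord) else transcript
    s, e = span
    lo, hi = max(0, s - fold_context), min(len(seq), e + fold_context)
    codes = encode_sequence(seq[lo:hi])
    pairE = model.fold_pair_energies()
    free = np.ones(len(codes), dtype=np.bool_)
    e_unconstrained = _kernels.fold_min_energy(codes, free, pairE,
                                               model.fold_min_hairpin)
    constrained = free.copy()
    constrained[s - lo:e - lo] = False
    e_constrained = _kernels.fold_min_energy(codes, constrained, pairE,
                                             model.fold_min_hairpin)
    return float(max(0.0, e_constrained - e_unconstrained))


def ddg_profile(mirna, transcript, spans, mask,
                model: EnergyModel | None = None,
                fold_context: int = DEFAULT_FOLD_CONTEXT,
                dg: CurveProfile | None = None) -> CurveProfile:
    """Accessibility profile ddG = dG - dG_open per span; masked -> 0."""
    model = model or EnergyModel.default()
    if dg is None:
        dg = dg_profile(mirna, transcript, spans, mask, model)
    values = np.zeros(PROFILE_LEN)
    for k, ((s, e), m) in enumerate(zip(spans, mask)):
        if m:
            continue
        values[k] = dg.values[k] - open_energy(transcript, (s, e), model,
                                               fold_context)
    return CurveProfile("ddg", values, mask.copy())


def site_profiles(site, transcript, mirna, model: EnergyModel | None = None,
                  fold_context: int = DEFAULT_FOLD_CONTEXT) -> dict[str, CurveProfile]:
    """All six profiles for one candidate site.

    Site-resolution curves are centered on the site interval and use the
    full guide; seed-resolution curves are centered on the seed-matched
    region and use guide nt 1-8 (the seed-scale thermodynamic signature).
    """
    model = model or EnergyModel.default()
    seq = transcript.sequence if isinstance(transcript, TranscriptRecord) else transcript
    L = len(seq)
    mir_seq = mirna.sequence if isinstance(mirna, MirnaRecord) else mirna
    out: dict[str, CurveProfile] = {}
    for res, width, center, guide in (
            ("site", SITE_WIDTH, (site.start, site.end), mir_seq),
            ("seed", SEED_WIDTH, site.seed_region, mir_seq[:8])):
        spans, mask = window_spans(center, width, L)
        dg = dg_profile(guide, transcript, spans, mask, model)
        out[f"dg_{res}"] = dg
        out[f"ddg_{res}"] = ddg_profile(guide, transcript, spans, mask, model,
                                        fold_context, dg=dg)
        out[f"au_{res}"] = au_profile(transcript, spans, mask)
        for key in (f"dg_{res}", f"ddg_{res}", f"au_{res}"):
            out[key].feature = key
    return out
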