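"""Readers/writers and domain records for transcripts, miRNAs and CLIP data.

All coordinates in the package are 0-based, half-open, in transcript space.
Sequences are normalized to uppercase RNA (``T`` -> ``U``); ``N`` is accepted
in mRNA and never pairs downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

REGION_NAMES = ("five_utr", "cds", "three_utr")
_VALID_MRNA = set("ACGUN")
_VALID_MIRNA = set("ACGU")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class TranscriptRecord:
    """An mRNA: sequence, optional region annotation, conservation track."""

    id: str
    sequence: str
    regions: dict[str, tuple[int, int]] = field(default_factory=dict)
    conservation: np.ndarray | None = None

    def __post_init__(self):
        bad = set(self.sequence) - _VALID_MRNA
        if bad:
            raise FormatError(
                f"transcript {self.id}: invalid characters {sorted(bad)}")
        if self.conservation is None:
            self.conservation = np.zeros(len(self.sequence))
        self.conservation = np.asarray(self.conservation, dtype=float)
        if len(self.conservation) != len(self.sequence):
            raise FormatError(
                f"transcript {self.id}: conservation length "
                f"{len(self.conservation)} != sequence length {len(self.sequence)}")
        self._check_regions()

    def _check_regions(self):
        prev_end = 0
        for name in REGION_NAMES:
            if name not in self.regions:
                continue
            start, end = self.regions[name]
            if not (0 <= start <= end <= len(self.sequence)):
                raise FormatError(
                    f"transcript {self.id}: region {name} [{start},{end}) "
                    f"outside [0,{len(self.sequence)})")
            if start < prev_end:
                raise FormatError(
                    f"transcript {self.id}: region {name} overlaps or is out of order")
            prev_end = end
        if all(n in self.regions for n in REGION_NAMES):
            spans = [self.regions[n] for n in REGION_NAMES]
            if spans[0][0] != 0 or spans[2][1] != len(self.sequence) or \
                    spans[0][1] != spans[1][0] or spans[1][1] != spans[2][0]:
                raise FormatError(
                    f"transcript {self.id}: regions must tile the transcript")

    def __len__(self):
        return len(self.sequence)


@dataclass
class MirnaRecord:
    """A mature miRNA sequence, 5'->3'."""

    id: str
    sequence: str
    family: str = ""

    def __post_init__(self):
        bad = set(self.sequence) - _VALID_MIRNA
        if bad:
            raise FormatError(f"miRNA {self.id}: invalid characters {sorted(bad)}")
        if len(self.sequence) < 8:
            raise FormatError(
                f"miRNA {self.id}: length {len(self.sequence)} < 8 (no seed region)")
        if not self.family:
            self.family = self.id

    def __len__(self):
        return len(self.sequence)


@dataclass(frozen=True)
class ClipRegion:
    """An AGO-crosslinked interval on a transcript, half-open."""

    transcript_id: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"CLIP region {self.transcript_id}:[{self.start},{self.end}) "
                "requires 0 <= start < end")


def _normalize(seq: str) -> str:
    return seq.upper().replace("T", "U")


def read_fasta(path, kind: str = "transcript"):
    """Read a FASTA file into transcript or miRNA records.

    Sequences are uppercased with ``T -> U``; ids are the header token up to
    the first whitespace.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: FASTA record with empty header")
        seq = _normalize(str(rec.seq))
        if kind == "mirna":
            records.append(MirnaRecord(id=rec.id, sequence=seq))
        else:
            records.append(TranscriptRecord(id=rec.id, sequence=seq))
    return records


def write_fasta(records, path, width: int = 70) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def merge_intervals(intervals):
    """Union of half-open intervals as maximal disjoint sorted intervals."""
    out = []
    for start, end in sorted(intervals):
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


def read_bed(path):
    """Read BED3+ CLIP regions; overlapping rows per transcript are merged."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2], names=["tx", "start", "end"],
                         dtype={"tx": str})
    except pd.errors.EmptyDataError:
        return []
    regions = []
    for row in df.itertuples(index=False):
        try:
            start, end = int(row.start), int(row.end)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: non-integer BED coordinates: {row}") from exc
        if start >= end:
            raise FormatError(f"{path}: BED start >= end in {row.tx} {start} {end}")
        regions.append((row.tx, start, end))
    out = []
    for tx in sorted({r[0] for r in regions}):
        merged = merge_intervals([(s, e) for t, s, e in regions if t == tx])
        out.extend(ClipRegion(tx, s, e) for s, e in merged)
    return out


def clip_by_transcript(clip_regions) -> dict[str, list[tuple[int, int]]]:
    """Group (already merged) CLIP regions by transcript id."""
    by_tx: dict[str, list[tuple[int, int]]] = {}
    for r in clip_regions:
        by_tx.setdefault(r.transcript_id, []).append((r.start, r.end))
    return {tx: merge_intervals(iv) for tx, iv in by_tx.items()}


def read_conservation(path, transcripts) -> None:
    """Fill per-nucleotide conservation from a bedGraph-like TSV, in place.

    Rows are ``(transcript_id, start, end, score)``; uncovered positions stay
    0 and overlapping rows are painted in file order (last wins).  Scores
    outside [0, 1] trigger a warning and are clamped.
    """
    by_id = {t.id: t for t in transcripts}
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["tx", "start", "end", "score"],
                         dtype={"tx": str})
    except pd.errors.EmptyDataError:
        return
    for row in df.itertuples(index=False):
        tx = by_id.get(row.tx)
        if tx is None:
            continue
        start, end, score = int(row.start), int(row.end), float(row.score)
        if not (0 <= start < end <= len(tx)):
            raise FormatError(
                f"{path}: conservation interval [{start},{end}) outside {row.tx}")
        if score < 0.0 or score > 1.0:
            warnings.warn(
                f"conservation score {score} outside [0,1] on {row.tx}; clamped")
            score = min(1.0, max(0.0, score))
        tx.conservation[start:end] = score


def read_regions(path, transcripts) -> None:
    """Attach 5'UTR/CDS/3'UTR extents from a TSV, in place.

    Columns: ``transcript_id, five_utr_end, cds_end``; the 3' UTR runs to the
    end of the sequence.
    """
    by_id = {t.id: t for t in transcripts}
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["tx", "five_utr_end", "cds_end"],
                     dtype={"tx": str})
    for row in df.itertuples(index=False):
        tx = by_id.get(row.tx)
        if tx is None:
            continue
        a, b = int(row.five_utr_end), int(row.cds_end)
        if not (0 <= a <= b <= len(tx)):
            raise FormatError(
                f"{path}: region bounds ({a},{b}) invalid for {row.tx}")
        tx.regions = {"five_utr": (0, a), "cds": (a, b),
                      "three_utr": (b, len(tx))}
        tx._check_regions()


def load_transcripts(fasta_path, regions_path=None, conservation_path=None):
    """Convenience loader combining FASTA, region and conservation inputs."""
    transcripts = read_fasta(fasta_path, kind="transcript")
    if regions_path is not None:
        read_regions(regions_path, transcripts)
    if conservation_path is not None:
        read_conservation(conservation_path, transcripts)
    return transcripts
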