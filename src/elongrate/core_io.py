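"""Data model and readers/writers for genes, per-nucleotide tracks, and intervals.

Coordinates are 0-based half-open throughout, matching BED/bedGraph.  Counts
attached to a :class:`TranscriptionUnit` are stored 5'->3' in transcription
order, i.e. reversed relative to genomic order for minus-strand genes.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio.Seq import reverse_complement

__all__ = [
    "TranscriptionUnit",
    "GenomeSequence",
    "IntervalSet",
    "read_counts_track",
    "read_fasta",
    "write_bedgraph",
]

_VALID_ALPHABET = set("ACGTN")


@dataclass
class TranscriptionUnit:
    """One gene body with per-nucleotide adjusted read counts.

    ``counts[0]`` is the 5'-most nucleotide of the body in transcription
    order: for minus-strand genes this corresponds to genomic coordinate
    ``body_end - 1``.  ``mask`` is True at sites usable for inference.
    """

    id: str
    chrom: str
    strand: str
    body_start: int
    body_end: int
    counts: np.ndarray = None
    mask: np.ndarray = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.body_end <= self.body_start:
            raise ValueError(f"empty interval for TU {self.id}")
        n = self.length
        if self.counts is None:
            self.counts = np.zeros(n)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (n,):
            raise ValueError(
                f"TU {self.id}: counts length {self.counts.size} != body length {n}"
            )
        if np.any(self.counts < 0):
            raise ValueError(f"TU {self.id}: negative read counts")
        if self.mask is None:
            self.mask = np.ones(n, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (n,):
            raise ValueError(f"TU {self.id}: mask length mismatch")

    @property
    def length(self) -> int:
        return self.body_end - self.body_start

    def genomic_to_local(self, pos: int) -> int:
        """Map a genomic coordinate inside the body to a 5'->3' index."""
        if not self.body_start <= pos < self.body_end:
            raise IndexError(f"position {pos} outside TU {self.id}")
        if self.strand == "+":
            return pos - self.body_start
        return self.body_end - 1 - pos


class GenomeSequence:
    """Mapping of contig name -> uppercase A/C/G/T/N sequence."""

    def __init__(self, seqs: dict[str, str]):
        self._seqs = {}
        for name, s in seqs.items():
            s = s.upper()
            if set(s) - _VALID_ALPHABET:
                s = "".join(c if c in _VALID_ALPHABET else "N" for c in s)
            self._seqs[name] = s

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def contigs(self) -> list[str]:
        return list(self._seqs)

    def slice(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of ``[start, end)``; reverse-complemented for ``-``."""
        if chrom not in self._seqs:
            raise KeyError(f"contig {chrom!r} not in genome")
        s = self._seqs[chrom]
        if start < 0 or end > len(s):
            raise IndexError(f"interval [{start}, {end}) outside contig {chrom}")
        sub = s[start:end]
        if strand == "-":
            sub = reverse_complement(sub)
        return sub

    def tu_sequence(self, tu: TranscriptionUnit) -> str:
        """Transcription-strand sequence of a TU body (5'->3')."""
        return self.slice(tu.chrom, tu.body_start, tu.body_end, tu.strand)


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int
    strand: str | None = None
    score: float | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"interval start {self.start} >= end {self.end}")


class IntervalSet:
    """Sorted collection of genomic intervals with optional strand/score."""

    def __init__(self, intervals: Iterable[tuple | Interval] = ()):
        items = []
        for iv in intervals:
            if not isinstance(iv, Interval):
                iv = Interval(*iv)
            items.append(iv)
        items.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
        self._by_chrom: dict[str, list[Interval]] = {}
        for iv in items:
            self._by_chrom.setdefault(iv.chrom, []).append(iv)
        self._items = items

    def __len__(self) -> int:
        return len(self._items)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self._items)

    def overlapping(self, chrom: str, start: int, end: int) -> list[Interval]:
        """All intervals intersecting ``[start, end)`` on ``chrom``."""
        out = []
        for iv in self._by_chrom.get(chrom, []):
            if iv.start < end and iv.end > start:
                out.append(iv)
        return out

    @classmethod
    def from_bed(cls, path: str | Path) -> "IntervalSet":
        """Read a BED3/BED6 file (tab- or space-separated)."""
        items = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            f = line.split()
            strand = f[5] if len(f) > 5 else None
            score = float(f[4]) if len(f) > 4 and f[4] != "." else None
            items.append(Interval(f[0], int(f[1]), int(f[2]), strand, score))
        return cls(items)


def _iter_bedgraph(path: str | Path):
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith(("track", "browser", "#")):
            continue
        f = line.split()
        if len(f) < 4:
            raise ValueError(f"{path}:{ln}: malformed bedGraph line: {line!r}")
        yield f[0], int(f[1]), int(f[2]), float(f[3])


def _read_bigwig_tu(path, tu):
    try:
        import pyBigWig
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading bigWig requires the optional pyBigWig dependency"
        ) from exc
    bw = pyBigWig.open(str(path))
    try:
        if tu.chrom not in bw.chroms():
            raise ValueError(f"contig {tu.chrom!r} not present in {path}")
        vals = np.nan_to_num(
            np.asarray(bw.values(tu.chrom, tu.body_start, tu.body_end), dtype=float)
        )
    finally:
        bw.close()
    return vals


def read_counts_track(
    path: str | Path, tus: Sequence[TranscriptionUnit], signed: bool = False
) -> dict[str, np.ndarray]:
    """Read per-base values for each TU from a bedGraph (or bigWig) file.

    Returns a dict TU id -> counts oriented 5'->3' along transcription.
    Positions absent from the file are 0.  Negative values raise unless
    ``signed=True``, in which case absolute values are returned (for reading
    back minus-strand tracks written with the negative-value convention).
    """
    path = Path(path)
    if path.suffix.lower() in (".bw", ".bigwig"):
        out = {}
        for tu in tus:
            vals = _read_bigwig_tu(path, tu)
            if not signed and np.any(vals < 0):
                raise ValueError(f"negative values in {path} over TU {tu.id}")
            vals = np.abs(vals)
            out[tu.id] = vals[::-1].copy() if tu.strand == "-" else vals
        return out

    records: dict[str, list[tuple[int, int, float]]] = {}
    for chrom, start, end, value in _iter_bedgraph(path):
        if value < 0 and not signed:
            raise ValueError(f"negative value {value} in {path} on {chrom}:{start}")
        records.setdefault(chrom, []).append((start, end, value))

    known_contigs = set(records)
    out = {}
    for tu in tus:
        vals = np.zeros(tu.length)
        if known_contigs and tu.chrom not in known_contigs:
            # an empty file legitimately yields all-zero counts, but a
            # populated file lacking the TU's contig is a naming mismatch
            raise ValueError(
                f"contig {tu.chrom!r} not present in {path} "
                f"(has: {sorted(known_contigs)[:5]}...)"
            )
        for start, end, value in records.get(tu.chrom, []):
            lo = max(start, tu.body_start)
            hi = min(end, tu.body_end)
            if lo < hi:
                vals[lo - tu.body_start : hi - tu.body_start] = abs(value)
        out[tu.id] = vals[::-1].copy() if tu.strand == "-" else vals
    return out


def read_fasta(path: str | Path) -> GenomeSequence:
    """Parse a FASTA file into a :class:`GenomeSequence`.

    Case-folds to uppercase and maps non-ACGT characters to N.  Duplicate
    headers are an error.
    """
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA header {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq)
    return GenomeSequence(seqs)


def _runs(values: np.ndarray):
    """Yield (start, end, value) runs of equal value."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return
    change = np.flatnonzero(values[1:] != values[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [values.size]))
    for s, e in zip(starts, ends):
        yield int(s), int(e), float(values[s])


def write_bedgraph(
    values: dict[str, np.ndarray],
    tus: Sequence[TranscriptionUnit],
    path: str | Path,
    omit_zero: bool = False,
) -> None:
    """Write per-nucleotide values for TUs as bedGraph.

    ``values`` maps TU id -> one value per nucleotide in transcription order.
    Runs of equal value are merged.  Minus-strand values are emitted as
    negative numbers (positive values = plus strand, negative = minus).
    """
    by_strand: dict[str, list[TranscriptionUnit]] = {"+": [], "-": []}
    for tu in tus:
        by_strand[tu.strand].append(tu)
    for strand, group in by_strand.items():
        group.sort(key=lambda t: (t.chrom, t.body_start))
        for a, b in zip(group, group[1:]):
            if a.chrom == b.chrom and a.body_end > b.body_start:
                raise ValueError(
                    f"overlapping TUs {a.id} and {b.id} on strand {strand}"
                )

    lines = []
    for tu in sorted(tus, key=lambda t: (t.chrom, t.body_start)):
        v = np.asarray(values[tu.id], dtype=float)
        if v.shape != (tu.length,):
            raise ValueError(f"TU {tu.id}: need one value per nucleotide")
        genomic = v[::-1] if tu.strand == "-" else v
        if tu.strand == "-":
            genomic = -genomic
        for s, e, val in _runs(genomic):
            if omit_zero and val == 0:
                continue
            lines.append(
                f"{tu.chrom}\t{tu.body_start + s}\t{tu.body_start + e}\t{val:g}"
            )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
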