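"""On-disk formats and the coordinate currency shared by every pipeline stage.

All coordinates are 0-based half-open (BED convention) everywhere in memory;
1-based values appear only in log messages.  CpG dinucleotides are indexed by
the position of the C on the forward strand; the reverse-strand G belongs to
the same symmetric dyad and is never counted separately.

Formats handled: BED3/BED6 intervals, a BED6+1 dialect for RepeatMasker-style
repeats (milliDiv in column 7), bedGraph coverage (with a header comment
carrying contig length and total mapped fragments so round trips are exact),
FASTA, and tab-separated per-CpG methylation calls.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ParseError",
    "GenomicInterval",
    "CoverageTrack",
    "RepeatElement",
    "MethCall",
    "load_intervals",
    "save_intervals",
    "load_repeats",
    "save_repeats",
    "load_coverage",
    "save_coverage",
    "load_fasta",
    "save_fasta",
    "load_methcalls",
    "save_methcalls",
    "cpg_positions",
]


class ParseError(ValueError):
    """Malformed record in an on-disk file; carries file and line number."""

    def __init__(self, path, line_no: int, message: str):
        self.path = str(path)
        self.line_no = line_no
        super().__init__(f"{path}:{line_no}: {message}")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A located span on a named contig, 0-based half-open."""

    contig: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)
    strand: str = field(default=".", compare=False)

    def __post_init__(self):
        if not self.contig:
            raise ValueError("contig name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def contains_position(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class CoverageTrack:
    """Per-base fragment coverage for one contig.

    ``total_reads`` is the sample-wide mapped-fragment count; the mean
    fragment length implied by the track is ``values.sum() / total_reads``
    and is the conversion factor between coverage sums and estimated
    fragment counts over an interval.
    """

    contig: str
    values: np.ndarray
    total_reads: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("coverage values must be one-dimensional")
        if self.values.size and self.values.min() < 0:
            raise ValueError("coverage values must be non-negative")
        if self.total_reads < 0:
            raise ValueError("total_reads must be non-negative")

    def __len__(self) -> int:
        return self.values.size

    @property
    def mean_fragment_length(self) -> float:
        if self.total_reads == 0:
            return float("nan")
        return float(self.values.sum() / self.total_reads)

    def estimate_fragments(self, start: int, end: int) -> float:
        """Estimated number of fragments overlapping [start, end).

        Coverage-sum over the interval divided by the track's mean fragment
        length: the standard estimator when only per-base coverage (not the
        fragment list) is on disk.
        """
        if not (0 <= start < end <= self.values.size):
            raise ValueError(f"interval [{start},{end}) outside contig")
        fl = self.mean_fragment_length
        if not np.isfinite(fl) or fl == 0:
            return 0.0
        return float(self.values[start:end].sum() / fl)


@dataclass(frozen=True)
class RepeatElement:
    """A repeat annotation with its divergence from consensus (milliDiv)."""

    interval: GenomicInterval
    family: str
    milli_div: int

    def __post_init__(self):
        if self.milli_div < 0:
            raise ValueError("milliDiv must be non-negative")


@dataclass(frozen=True)
class MethCall:
    """Bisulfite counts for one CpG (C of the dyad, forward strand)."""

    contig: str
    position: int
    meth_count: int
    unmeth_count: int

    def __post_init__(self):
        if self.meth_count < 0 or self.unmeth_count < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def depth(self) -> int:
        return self.meth_count + self.unmeth_count


# ---------------------------------------------------------------------------
# BED intervals


def _split_line(raw: str) -> list[str]:
    return raw.rstrip("\n").split("\t")


def load_intervals(path) -> list[GenomicInterval]:
    """Read BED3/BED6 into GenomicInterval records (extra columns ignored)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith(("#", "track", "browser")):
                continue
            fields = _split_line(raw)
            if len(fields) < 3:
                raise ParseError(path, line_no, "fewer than 3 BED columns")
            contig = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(path, line_no, "non-integer coordinate") from None
            if start >= end or start < 0:
                raise ParseError(path, line_no, f"bad span {start}-{end}")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError:
                    raise ParseError(path, line_no, "non-numeric score") from None
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in ("+", "-", "."):
                raise ParseError(path, line_no, f"bad strand {strand!r}")
            out.append(GenomicInterval(contig, start, end, name, score, strand))
    return out


def save_intervals(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            score = "." if iv.score is None else format(iv.score, "g")
            name = iv.name if iv.name is not None else "."
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )


def load_repeats(path) -> list[RepeatElement]:
    """Read a BED6+1 repeat file; column 7 is milliDiv (int, >= 0)."""
    out: list[RepeatElement] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith("#"):
                continue
            fields = _split_line(raw)
            if len(fields) < 7:
                raise ParseError(path, line_no, "repeat line needs 7 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
                milli_div = int(fields[6])
            except ValueError:
                raise ParseError(path, line_no, "non-integer field") from None
            if start >= end or start < 0:
                raise ParseError(path, line_no, f"bad span {start}-{end}")
            if milli_div < 0:
                raise ParseError(path, line_no, "negative milliDiv")
            strand = fields[5] if fields[5] in ("+", "-", ".") else "."
            iv = GenomicInterval(fields[0], start, end, fields[3], None, strand)
            out.append(RepeatElement(iv, family=fields[3], milli_div=milli_div))
    return out


def save_repeats(repeats: Iterable[RepeatElement], path) -> None:
    with open(path, "w") as fh:
        for rep in repeats:
            iv = rep.interval
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t{rep.family}\t.\t"
                f"{iv.strand}\t{rep.milli_div}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph coverage


def save_coverage(track: CoverageTrack, path) -> None:
    """Write run-length bedGraph; zero runs omitted, metadata in a header."""
    values = track.values
    with open(path, "w") as fh:
        fh.write(
            f"# contig={track.contig} length={values.size} "
            f"total_reads={track.total_reads:.6g}\n"
        )
        if values.size == 0:
            return
        # run boundaries where the value changes
        change = np.flatnonzero(np.diff(values)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [values.size]))
        for s, e in zip(starts, ends):
            v = values[s]
            if v != 0:
                fh.write(f"{track.contig}\t{s}\t{e}\t{v:.10g}\n")


def load_coverage(path, contig_length: int | None = None) -> CoverageTrack:
    """Read bedGraph into a per-base track, zero-filling gaps.

    Records must be sorted and non-overlapping.  The contig length and
    total-fragment count are taken from the header comment written by
    :func:`save_coverage`; ``contig_length`` overrides the header.
    """
    contig = None
    length = contig_length
    total_reads = 0.0
    records: list[tuple[int, int, float]] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            if raw.startswith("#"):
                for token in raw[1:].split():
                    if token.startswith("contig="):
                        contig = token[7:]
                    elif token.startswith("length=") and contig_length is None:
                        length = int(token[7:])
                    elif token.startswith("total_reads="):
                        total_reads = float(token[12:])
                continue
            if raw.startswith(("track", "browser")):
                continue
            fields = _split_line(raw)
            if len(fields) < 4:
                raise ParseError(path, line_no, "bedGraph line needs 4 columns")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError:
                raise ParseError(path, line_no, "malformed bedGraph record") from None
            if start >= end or start < 0:
                raise ParseError(path, line_no, f"bad span {start}-{end}")
            if contig is None:
                contig = fields[0]
            elif fields[0] != contig:
                raise ParseError(path, line_no, "multiple contigs in one track")
            if records and start < records[-1][1]:
                raise ParseError(path, line_no, "overlapping/unsorted records")
            records.append((start, end, value))
    if contig is None:
        contig = "unknown"
    if length is None:
        length = records[-1][1] if records else 0
    values = np.zeros(length, dtype=np.float64)
    for start, end, value in records:
        if end > length:
            raise ParseError(path, 0, f"record [{start},{end}) beyond contig length {length}")
        values[start:end] = value
    return CoverageTrack(contig=contig, values=values, total_reads=total_reads)


# ---------------------------------------------------------------------------
# FASTA


def load_fasta(path) -> dict[str, str]:
    """Read FASTA into {name: uppercase sequence}; headers must be unique."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ParseError(path, 0, f"duplicate FASTA header {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def save_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Methylation-call TSV


_METHCALL_COLUMNS = ["contig", "position", "meth_count", "unmeth_count"]


def save_methcalls(calls: Sequence[MethCall], path) -> None:
    df = pd.DataFrame(
        [(c.contig, c.position, c.meth_count, c.unmeth_count) for c in calls],
        columns=_METHCALL_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def load_methcalls(path) -> list[MethCall]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _METHCALL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(path, 1, f"missing columns {missing}")
    return [
        MethCall(str(row.contig), int(row.position), int(row.meth_count), int(row.unmeth_count))
        for row in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Sequence helpers


def cpg_positions(seq: str) -> np.ndarray:
    """Positions of the C of each forward-strand CpG dyad.

    Dinucleotides containing a non-ACGT letter (e.g. N) never match and are
    therefore silently skipped.
    """
    if len(seq) < 2:
        return np.empty(0, dtype=np.int64)
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    return np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G"))).astype(np.int64)
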