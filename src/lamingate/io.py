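"""Readers and writers for the plain-text interchange formats.

FASTA goes through Biopython; bedGraph and BED are line-oriented and
validated against a GenomeSpec on read. Writers accept an optional header
comment block (lines starting with '#'), which readers skip, along with
'track' lines.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import AnnotationSet, BinnedTrack, GenomeSpec, Interval

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_bedgraph",
    "write_bedgraph",
    "read_bed",
    "write_bed",
    "ParseError",
]


class ParseError(ValueError):
    """A malformed input file; carries the file and line number."""

    def __init__(self, path: str | Path, line_no: int, message: str) -> None:
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = str(path)
        self.line_no = line_no


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs; sequences are uppercased."""
    records = [
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ParseError(path, 1, "no FASTA records found")
    return records


def write_fasta(
    path: str | Path, records: Iterable[tuple[str, str]], width: int = 70
) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def _data_lines(path: str | Path):
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            yield i, line


def read_bedgraph(path: str | Path, genome: GenomeSpec) -> BinnedTrack:
    """Read a fixed-step bedGraph (one line per bin) into a BinnedTrack."""
    counts = {
        chrom: np.zeros(n, dtype=np.int64)
        for chrom, n in zip(genome.chromosomes, genome.lengths)
    }
    seen = {chrom: np.zeros(len(arr), dtype=bool) for chrom, arr in counts.items()}
    bs = genome.bin_size
    for line_no, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) != 4:
            raise ParseError(path, line_no, f"expected 4 columns, got {len(parts)}")
        chrom, start_s, end_s, value_s = parts
        if chrom not in counts:
            raise ParseError(path, line_no, f"unknown chromosome {chrom!r}")
        try:
            start, end = int(start_s), int(end_s)
            value = float(value_s)
        except ValueError:
            raise ParseError(path, line_no, "non-numeric coordinates or value")
        if start % bs != 0 or end - start != bs:
            raise ParseError(
                path, line_no, f"interval is not one {bs} bp bin: {start}-{end}"
            )
        idx = start // bs
        if idx >= len(counts[chrom]):
            raise ParseError(path, line_no, f"bin {idx} beyond {chrom} length")
        if value < 0 or value != int(value):
            raise ParseError(path, line_no, f"count must be a non-negative integer")
        counts[chrom][idx] = int(value)
        seen[chrom][idx] = True
    for chrom, flags in seen.items():
        if not flags.all():
            missing = int((~flags).sum())
            raise ParseError(path, 0, f"{chrom}: {missing} bins missing")
    return BinnedTrack(genome, counts)


def write_bedgraph(
    path: str | Path, track: BinnedTrack, header: Sequence[str] = ()
) -> None:
    bs = track.genome.bin_size
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        for chrom in track.genome.chromosomes:
            for i, v in enumerate(track.counts[chrom]):
                fh.write(f"{chrom}\t{i * bs}\t{(i + 1) * bs}\t{int(v)}\n")


def read_bed(path: str | Path, genome: GenomeSpec | None = None) -> AnnotationSet:
    """Read BED3+ intervals (0-based half-open); extra columns ignored."""
    intervals: list[Interval] = []
    for line_no, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError(path, line_no, f"expected >=3 columns, got {len(parts)}")
        chrom = parts[0]
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError:
            raise ParseError(path, line_no, "non-integer coordinates")
        if end <= start:
            raise ParseError(path, line_no, f"empty or inverted interval {start}-{end}")
        name = parts[3] if len(parts) > 3 else "."
        intervals.append(Interval(chrom, start, end, name))
    annot = AnnotationSet(intervals)
    if genome is not None:
        annot.validate_against(genome)
    return annot


def write_bed(
    path: str | Path,
    annotation: AnnotationSet | Iterable[Interval],
    header: Sequence[str] = (),
    extra_columns: dict[str, list] | None = None,
) -> None:
    intervals = list(annotation)
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        for i, iv in enumerate(intervals):
            cols = [iv.chrom, str(iv.start), str(iv.end), iv.name]
            if extra_columns:
                cols += [str(vals[i]) for vals in extra_columns.values()]
            fh.write("\t".join(cols) + "\n")
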