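"""File formats: BED6+1 reads, bedGraph tracks, FASTA, TSV tables.

BED6+1 dialect: tab-separated chrom/start/end/name/score/strand plus column
7 holding the non-templated 3' soft-clip sequence ("." for none).  The
score column is taken as the read multiplicity when it is an integer >= 1.
All readers and writers are gzip-capable (by filename suffix).
"""

from __future__ import annotations

import gzip
import io as _io
import re
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .read_profiles import ProfileTrack
from .synthetic_data import READ_COLUMNS

__all__ = ["read_bed_reads", "write_bed_reads", "write_bed",
           "write_bedgraph", "read_bedgraph", "write_fasta", "read_fasta",
           "write_tsv"]

_TAIL_RE = re.compile(r"^[ACGTN]*$")


def _open(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_bed_reads(path) -> pd.DataFrame:
    """Parse BED6+1 read records; errors carry the offending line number."""
    rows = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected >= 6 "
                                 f"tab-separated fields, got {len(parts)}")
            chrom, start, end, name, score, strand = parts[:6]
            tail = parts[6] if len(parts) > 6 else "."
            try:
                start, end = int(start), int(end)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer interval")
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end "
                                 f"({start} >= {end})")
            if strand not in "+-":
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            if tail == ".":
                tail = ""
            elif not _TAIL_RE.match(tail):
                raise ValueError(f"{path}:{lineno}: tail must be ACGTN "
                                 f"or '.'")
            try:
                count = int(score)
                if count < 1:
                    count = 1
            except ValueError:
                count = 1
            rows.append((chrom, start, end, name, count, strand, tail))
    return pd.DataFrame(rows, columns=READ_COLUMNS)


def write_bed_reads(reads: pd.DataFrame, path) -> None:
    df = reads.copy()
    df["tail"] = df["tail"].map(lambda t: t if t else ".")
    df = df[["chrom", "start", "end", "name", "count", "strand", "tail"]]
    with _open(path, "wt") as fh:
        df.to_csv(fh, sep="\t", header=False, index=False)


def write_bed(annotation: pd.DataFrame, path) -> None:
    with _open(path, "wt") as fh:
        annotation.to_csv(fh, sep="\t", header=False, index=False)


def write_bedgraph(track: ProfileTrack, path, name: Optional[str] = None,
                   header: bool = True) -> None:
    """0-based half-open bedGraph; adjacent equal values are run-length
    merged; zero and undefined (NaN) positions are omitted."""
    chrom = name or track.name
    v = track.values
    with _open(path, "wt") as fh:
        if header:
            fh.write(f'track type=bedGraph name="{chrom}"\n')
        i = 0
        n = len(v)
        while i < n:
            x = v[i]
            if not np.isfinite(x) or x == 0:
                i += 1
                continue
            j = i + 1
            while j < n and np.isfinite(v[j]) and v[j] == x:
                j += 1
            fh.write(f"{chrom}\t{i}\t{j}\t{x:.10g}\n")
            i = j


def read_bedgraph(path, length: int, unit_start: int = 0,
                  unit_length: Optional[int] = None) -> ProfileTrack:
    values = np.zeros(length)
    chrom = "ref"
    with _open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            c, s, e, x = line.split("\t")
            chrom = c
            values[int(s):int(e)] = float(x)
    return ProfileTrack(values, unit_start=unit_start,
                        unit_length=unit_length, name=chrom)


def write_fasta(sequence: str, path, name: str = "rdna_unit",
                description: str = "synthetic rDNA-like reference") -> None:
    rec = SeqRecord(Seq(sequence), id=name, description=description)
    with _open(path, "wt") as fh:
        SeqIO.write([rec], fh, "fasta")


def read_fasta(path) -> dict:
    with _open(path) as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


def write_tsv(df: pd.DataFrame, path) -> None:
    with _open(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False)
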