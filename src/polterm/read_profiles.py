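"""Per-nucleotide profile computations for nascent-transcript CRAC reads.

Conventions: reads are 0-based half-open intervals; on the plus strand the
5' end is ``start`` and the 3' end is ``end - 1`` (swapped on the minus
strand).  Tracks cover the full reference (unit plus flanks); unit
normalization divides by the total over the unit window and then adds a
1e-7 pseudocount to every position.  Reported positions are 1-based unit
coordinates relative to the TSS.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import READ_COLUMNS

__all__ = [
    "ReadRecord", "ProfileTrack", "ReplicateBundle",
    "end_profile", "normalize_unit", "smooth_blackman",
    "aggregate_replicates", "difference_and_cumulative",
    "readthrough_fraction", "readthrough_test",
    "select_polyA", "terminal_a_run", "read_length_stats",
]

_TAIL_RE = re.compile(r"^[ACGTN]*$")


@dataclass
class ReadRecord:
    """One aligned read with its non-templated 3' soft-clip sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    tail: str = ""
    count: int = 1
    name: str = "read"

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"read {self.name}: start >= end "
                             f"({self.start} >= {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"read {self.name}: bad strand {self.strand!r}")
        if self.tail and not _TAIL_RE.match(self.tail):
            raise ValueError(f"read {self.name}: tail must be ACGTN")
        if self.count < 1:
            raise ValueError(f"read {self.name}: count must be >= 1")


Reads = Union[pd.DataFrame, Iterable[ReadRecord]]


def _as_frame(reads: Reads) -> pd.DataFrame:
    if isinstance(reads, pd.DataFrame):
        return reads
    rows = [{"chrom": r.chrom, "start": r.start, "end": r.end,
             "name": r.name, "count": r.count, "strand": r.strand,
             "tail": r.tail} for r in reads]
    return pd.DataFrame(rows, columns=READ_COLUMNS)


@dataclass
class ProfileTrack:
    """Per-nt signal over the reference.  ``unit_start`` is the 0-based
    index of unit position 1; ``unit_length`` defaults to the whole track."""

    values: np.ndarray
    unit_start: int = 0
    unit_length: Optional[int] = None
    normalized: bool = False
    smoothing: Optional[str] = None
    name: str = "ref"

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.unit_length is None:
            self.unit_length = len(self.values) - self.unit_start
        if not (0 <= self.unit_start
                and self.unit_start + self.unit_length <= len(self.values)):
            raise ValueError("unit window outside the track")

    def __len__(self):
        return len(self.values)

    @property
    def unit_slice(self) -> slice:
        return slice(self.unit_start, self.unit_start + self.unit_length)

    def unit_values(self) -> np.ndarray:
        return self.values[self.unit_slice]

    def index(self, unit_pos: int) -> int:
        """0-based track index of a 1-based unit coordinate."""
        return self.unit_start + unit_pos - 1

    def unit_pos(self, index: int) -> int:
        return index - self.unit_start + 1

    def like(self, values, **kw) -> "ProfileTrack":
        return replace(self, values=np.asarray(values, float), **kw)


def end_profile(reads: Reads, mode: str, length: int,
                unit_start: int = 0, unit_length: Optional[int] = None,
                name: str = "ref") -> ProfileTrack:
    """Count read ends (or full coverage) per position, weighted by
    multiplicity.  mode: 'five_prime' | 'three_prime' | 'coverage'."""
    if mode not in ("five_prime", "three_prime", "coverage"):
        raise ValueError(f"unknown mode {mode!r}")
    df = _as_frame(reads)
    values = np.zeros(length)
    if len(df):
        start = df["start"].to_numpy(np.int64)
        end = df["end"].to_numpy(np.int64)
        count = df["count"].to_numpy(float)
        bad = (start < 0) | (end > length) | (start >= end)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            rec = df.iloc[i]
            raise ValueError(f"read {rec['name']} [{rec['start']}, "
                             f"{rec['end']}) is off the reference "
                             f"(length {length})")
        minus = df["strand"].to_numpy() == "-"
        if mode == "coverage":
            delta = np.zeros(length + 1)
            np.add.at(delta, start, count)
            np.add.at(delta, end, -count)
            values = np.cumsum(delta)[:-1]
        else:
            if mode == "five_prime":
                pos = np.where(minus, end - 1, start)
            else:
                pos = np.where(minus, start, end - 1)
            np.add.at(values, pos, count)
    return ProfileTrack(values, unit_start=unit_start,
                        unit_length=unit_length, name=name)


def normalize_unit(track: ProfileTrack, pseudo: float = 1e-7) -> ProfileTrack:
    """Divide by the total over the unit window, then add the pseudocount
    to every position.  Refuses to normalize twice."""
    if track.normalized:
        raise ValueError("track is already normalized")
    total = track.unit_values().sum()
    if total <= 0:
        raise ValueError("zero total over the unit: cannot normalize")
    return track.like(track.values / total + pseudo, normalized=True)


def smooth_blackman(track: ProfileTrack, window: int = 10) -> ProfileTrack:
    """Centered Blackman smoothing; kernel normalized to sum 1, edges use
    the truncated, renormalized kernel (output length unchanged)."""
    if window < 2:
        raise ValueError("window must be >= 2")
    if window > len(track):
        raise ValueError("window exceeds track length")
    kernel = np.blackman(window)
    kernel = kernel / kernel.sum()
    num = np.convolve(track.values, kernel, mode="same")
    den = np.convolve(np.ones(len(track)), kernel, mode="same")
    return track.like(num / den, smoothing=f"blackman{window}")


@dataclass
class ReplicateBundle:
    """Replicate tracks on identical coordinates."""

    tracks: List[ProfileTrack]

    def __post_init__(self):
        if not self.tracks:
            raise ValueError("need at least one track")
        n = len(self.tracks[0])
        if any(len(t) != n or t.unit_start != self.tracks[0].unit_start
               for t in self.tracks):
            raise ValueError("replicate tracks have mismatched coordinates")

    def matrix(self) -> np.ndarray:
        return np.vstack([t.values for t in self.tracks])


def aggregate_replicates(bundle: Union[ReplicateBundle, Sequence[ProfileTrack]]
                         ) -> pd.DataFrame:
    """Per-position median, quartile band (linear-interpolation
    percentiles) and min-max band across replicates."""
    if not isinstance(bundle, ReplicateBundle):
        bundle = ReplicateBundle(list(bundle))
    m = bundle.matrix()
    return pd.DataFrame({
        "median": np.median(m, axis=0),
        "q25": np.percentile(m, 25, axis=0),
        "q75": np.percentile(m, 75, axis=0),
        "min": m.min(axis=0),
        "max": m.max(axis=0),
    })


def difference_and_cumulative(a: pd.DataFrame, b: pd.DataFrame):
    """Median difference, per-dataset cumulative sums of the medians, and a
    mask of positions where the quartile bands of a and b do not overlap."""
    if len(a) != len(b):
        raise ValueError("summaries have mismatched coordinates")
    diff = a["median"].to_numpy() - b["median"].to_numpy()
    cum_a = np.cumsum(a["median"].to_numpy())
    cum_b = np.cumsum(b["median"].to_numpy())
    mask = (a["q75"].to_numpy() < b["q25"].to_numpy()) | \
           (b["q75"].to_numpy() < a["q25"].to_numpy())
    return diff, (cum_a, cum_b), mask


def readthrough_fraction(track: ProfileTrack, site: int) -> float:
    """Fraction of unit signal strictly downstream of ``site`` (1-based
    unit coordinate), e.g. 3'-end signal past the terminator."""
    unit = track.unit_values()
    if not 1 <= site <= track.unit_length:
        raise ValueError("site outside the unit")
    total = unit.sum()
    if total <= 0:
        raise ValueError("zero total signal")
    return float(unit[site:].sum() / total)


def readthrough_test(fractions_a: Sequence[float],
                     fractions_b: Sequence[float]) -> Tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of per-replicate readthrough
    fractions (exact for small groups, normal approximation otherwise).
    Returns (statistic, p-value)."""
    method = "exact" if max(len(fractions_a), len(fractions_b)) <= 25 \
        else "asymptotic"
    res = stats.mannwhitneyu(fractions_a, fractions_b,
                             alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def terminal_a_run(tail: str) -> int:
    """Length of the run of A at the extreme 3' end of the tail."""
    if not tail or tail == ".":
        return 0
    return len(tail) - len(tail.rstrip("A"))


def select_polyA(reads: Reads, min_a: int = 3, length: Optional[int] = None,
                 unit_start: int = 0, unit_length: Optional[int] = None,
                 whole_tail: bool = False):
    """Oligo(A)+ selection: a read qualifies iff its non-templated tail
    ends in >= min_a consecutive A (``whole_tail=True`` additionally
    requires the entire tail to be A).

    Returns (selected reads, adenylated-fraction track) when ``length`` is
    given, else (selected reads, None).  The fraction track is selected
    3'-end counts over all 3'-end counts, 0 where no reads end.
    """
    df = _as_frame(reads)
    tails = df["tail"].fillna("").astype(str) if len(df) else pd.Series([], dtype=str)
    runs = tails.map(terminal_a_run)
    sel = runs >= min_a
    if whole_tail:
        stripped = tails.map(lambda t: "" if t == "." else t)
        sel &= stripped.map(lambda t: t == "A" * len(t))
    selected = df[sel.to_numpy()] if len(df) else df
    if length is None:
        return selected, None
    all3 = end_profile(df, "three_prime", length, unit_start, unit_length)
    sel3 = end_profile(selected, "three_prime", length, unit_start,
                       unit_length)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(all3.values > 0, sel3.values /
                        np.where(all3.values > 0, all3.values, 1.0), 0.0)
    return selected, all3.like(frac)


def read_length_stats(reads: Reads, anchor_5p: Optional[int] = None,
                      unit_start: int = 0, bins: int = 30):
    """Median and histogram of read lengths, optionally restricted to reads
    whose 5' end sits at ``anchor_5p`` (1-based unit coordinate)."""
    df = _as_frame(reads)
    if anchor_5p is not None and len(df):
        minus = df["strand"] == "-"
        five = np.where(minus, df["end"].to_numpy() - 1,
                        df["start"].to_numpy())
        df = df[five == unit_start + anchor_5p - 1]
    if not len(df):
        raise ValueError("no reads match the selection")
    lengths = np.repeat((df["end"] - df["start"]).to_numpy(),
                        df["count"].to_numpy(np.int64))
    hist, edges = np.histogram(lengths, bins=bins)
    return {"median": float(np.median(lengths)), "n": int(lengths.size),
            "lengths": lengths, "histogram": (hist, edges)}
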