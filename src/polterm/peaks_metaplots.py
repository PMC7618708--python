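"""Peak calling on profile tracks and peak-anchored metaplots.

A position is a peak of the moving-average-smoothed track (window 80 by
default) iff it is greater than every smoothed value within ``order`` nt
(45 by default) on both sides — strictly greater to the left,
greater-or-equal to the right, which breaks plateau ties to the leftmost
position — and at least ``min_height`` times the smoothed-track mean.
Positions within ``order`` of the track boundary are not callable.
Troughs can be called by negating the track.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np

from .read_profiles import ProfileTrack

__all__ = ["PeakSet", "find_peaks", "metaplot", "align_tracks_at_peaks",
           "Metaplot"]

log = logging.getLogger(__name__)


@dataclass
class PeakSet:
    """Called peaks: 1-based unit coordinates, smoothed-track heights and
    the (order, window) used."""

    positions: np.ndarray
    scores: np.ndarray
    order: int
    window: int

    def __post_init__(self):
        self.positions = np.asarray(self.positions, int)
        self.scores = np.asarray(self.scores, float)
        if np.any(np.diff(self.positions) <= self.order):
            raise ValueError("peaks must be sorted and > order apart")
        if np.any(self.scores <= 0):
            raise ValueError("peak scores must be > 0")

    def __len__(self):
        return len(self.positions)

    def without(self, excluded: Sequence[int], tol: int = 0) -> "PeakSet":
        """Blacklist peaks at (or within tol nt of) the given unit
        coordinates."""
        keep = np.ones(len(self.positions), bool)
        for x in excluded:
            keep &= np.abs(self.positions - x) > tol
        return replace(self, positions=self.positions[keep],
                       scores=self.scores[keep])


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    kernel = np.ones(window) / window
    num = np.convolve(values, kernel, mode="same")
    den = np.convolve(np.ones(len(values)), kernel, mode="same")
    return num / den


def find_peaks(track: ProfileTrack, order: int = 45, window: int = 80,
               min_height: float = 1.0) -> PeakSet:
    """Local-maximum peak calling on the smoothed track.

    ``min_height`` is a fraction of the smoothed-track mean; peaks below it
    are discarded.  Peak positions are reported in 1-based unit
    coordinates.
    """
    values = track.values
    n = len(values)
    if order >= n:
        raise ValueError("order must be smaller than the track length")
    if n <= window:
        raise ValueError("track must be longer than the smoothing window")
    s = _moving_average(values, window) if window > 1 else values.astype(float)
    floor = min_height * s.mean()
    pad = np.full(order, -np.inf)
    sp = np.concatenate([pad, s, pad])
    from numpy.lib.stride_tricks import sliding_window_view
    left = sliding_window_view(sp, order)[:n].max(axis=1)
    right = sliding_window_view(sp, order)[order + 1:order + 1 + n].max(axis=1)
    cand = (s > left) & (s >= right) & (s >= floor) & (s > 0)
    cand[:order] = False
    cand[n - order:] = False
    idx = np.flatnonzero(cand)
    positions = np.array([track.unit_pos(i) for i in idx], int)
    return PeakSet(positions=positions, scores=s[idx], order=order,
                   window=window)


@dataclass
class Metaplot:
    offsets: np.ndarray
    mean: np.ndarray
    n_peaks: int

    @property
    def offset_of_max(self) -> int:
        return int(self.offsets[int(np.argmax(self.mean))])


def metaplot(track: ProfileTrack, peaks: PeakSet, flank: int,
             exclude: Sequence[int] = (), exclude_tol: int = 0) -> Metaplot:
    """Mean of the track in a [-flank, +flank] window superimposed across
    peaks; peaks whose window falls off the track are dropped (counted in
    the log)."""
    if exclude:
        peaks = peaks.without(exclude, exclude_tol)
    windows = []
    dropped = 0
    for pos in peaks.positions:
        i = track.index(int(pos))
        if i - flank < 0 or i + flank + 1 > len(track):
            dropped += 1
            continue
        windows.append(track.values[i - flank:i + flank + 1])
    if dropped:
        log.warning("metaplot: dropped %d peak(s) with incomplete windows",
                    dropped)
    if not windows:
        raise ValueError("no peak has a full window inside the track")
    return Metaplot(offsets=np.arange(-flank, flank + 1),
                    mean=np.mean(windows, axis=0), n_peaks=len(windows))


def align_tracks_at_peaks(anchor_peaks: PeakSet, other_track: ProfileTrack,
                          flank: int, exclude: Sequence[int] = (),
                          exclude_tol: int = 0) -> Tuple[Metaplot, int]:
    """Metaplot of a second track around another track's peaks, plus the
    offset of the second track's maximum (negative = upstream of the
    anchor)."""
    mp = metaplot(other_track, anchor_peaks, flank, exclude, exclude_tol)
    return mp, mp.offset_of_max
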