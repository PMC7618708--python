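"""Rolling folding-energy track of the nascent transcript.

For each template position the score is the folding free energy of the 65
nt of extruded RNA behind the polymerase, offset by 15 nt (the region still
inside the enzyme).  The bundled fallback engine is a maximum base-pairing
dynamic program (Nussinov-style, minimum loop 3, Watson-Crick + GU wobble,
-1 kcal/mol per pair): deterministic and dependency-free, not
thermodynamically exact.  A production engine (e.g. ViennaRNA's RNAfold)
can be plugged in by name or as a callable; the simulator consumes only the
min-max-normalized relative signal, so engine units cancel.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np
from numba import njit

__all__ = ["FoldingTrack", "window_dg", "fallback_dg", "pairing_signal"]

log = logging.getLogger(__name__)

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}


@njit(cache=False)
def _nussinov_pairs(seq: np.ndarray) -> int:
    """Maximum number of nested base pairs (AU/GC/GU), min loop 3."""
    n = seq.shape[0]
    dp = np.zeros((n, n), np.int32)
    for span in range(4, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i + 1, j] if i + 1 <= j else 0
            if j - 1 >= i:
                v = dp[i, j - 1]
                if v > best:
                    best = v
            a, b = seq[i], seq[j]
            paired = (a == 0 and b == 3) or (a == 3 and b == 0) or \
                     (a == 1 and b == 2) or (a == 2 and b == 1) or \
                     (a == 2 and b == 3) or (a == 3 and b == 2)
            if paired:
                inner = dp[i + 1, j - 1] if i + 1 <= j - 1 else 0
                if inner + 1 > best:
                    best = inner + 1
            for k in range(i + 1, j):
                v = dp[i, k] + dp[k + 1, j]
                if v > best:
                    best = v
            dp[i, j] = best
    return int(dp[0, n - 1]) if n > 1 else 0


def fallback_dg(sequence: str) -> float:
    """Fallback engine: -1 kcal/mol per base pair of the max-pairing
    structure; always <= 0."""
    enc = np.array([_ENC.get(b, 4) for b in sequence.upper()], np.int8)
    if enc.size < 5:
        return 0.0
    return -1.0 * _nussinov_pairs(enc)


def _rnafold_dg(sequence: str) -> float:
    rna = sequence.upper().replace("T", "U")
    out = subprocess.run(["RNAfold", "--noPS"], input=rna + "\n",
                         capture_output=True, text=True, check=True)
    last = out.stdout.strip().splitlines()[-1]
    dg = float(last[last.rindex("(") + 1:last.rindex(")")])
    return min(dg, 0.0)


def _resolve_engine(engine: Union[str, Callable[[str], float]]):
    if callable(engine):
        return engine, getattr(engine, "__name__", "callable")
    if engine == "fallback":
        return fallback_dg, "fallback"
    if engine in ("rnafold", "vienna"):
        if shutil.which("RNAfold") is None:
            raise RuntimeError("RNAfold not found on PATH")
        return _rnafold_dg, "rnafold"
    raise ValueError(f"unknown folding engine {engine!r}")


@dataclass
class FoldingTrack:
    """Per-position ΔG (kcal/mol, <= 0); NaN where the trailing window is
    incomplete (positions < window + offset)."""

    values: np.ndarray
    window: int = 65
    offset: int = 15
    engine: str = "fallback"

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)


def window_dg(sequence: str,
              engine: Union[str, Callable[[str], float]] = "fallback",
              window: int = 65, offset: int = 15) -> FoldingTrack:
    """ΔG of the ``window`` nt of nascent RNA ending ``offset`` nt behind
    each position (1-based position i scores sequence
    [i-offset-window+1 .. i-offset])."""
    if window < 1 or offset < 0:
        raise ValueError("window >= 1 and offset >= 0 required")
    fn, name = _resolve_engine(engine)
    n = len(sequence)
    values = np.full(n, np.nan)
    failures = 0
    for i in range(window + offset, n + 1):
        sub = sequence[i - offset - window:i - offset]
        try:
            dg = float(fn(sub))
        except Exception:
            failures += 1
            continue
        values[i - 1] = min(dg, 0.0)
    if failures:
        log.warning("folding engine failed on %d window(s)", failures)
    return FoldingTrack(values=values, window=window, offset=offset,
                        engine=name)


def pairing_signal(track: FoldingTrack,
                   length: Optional[int] = None) -> np.ndarray:
    """Min-max-normalized pairing signal in [0, 1] for the simulator:
    0 at the weakest folding in the track, 1 at the strongest; undefined
    positions are 0.  Optionally cropped/padded to ``length``."""
    v = track.values
    defined = ~np.isnan(v)
    out = np.zeros(len(v))
    if defined.any():
        lo, hi = np.nanmin(v), np.nanmax(v)
        if hi > lo:
            out[defined] = (hi - v[defined]) / (hi - lo)
    if length is not None:
        if len(out) >= length:
            out = out[:length]
        else:
            out = np.pad(out, (0, length - len(out)))
    return out
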