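"""Synthetic rDNA-like reference and synthetic nascent-transcript reads.

The generator emulates the statistical structure of RNAPI CRAC libraries on
the 35S pre-rRNA unit so the whole analysis pipeline runs without any
deposited data: a 7000-nt unit with 1300-nt flanks; 3'-ETS landmarks (Rnt1
cleavage sites B0-1/B0-2 at +14/15 and +49/50 past the 25S 3' end B2, the
T-rich terminator T1 ~93 nt downstream of B2, the Nsi1 site 12-20 nt past
T1); a mixture-of-peaks 3'-end occupancy over a uniform background; a
dominant 5'-end cleavage class pinned at B0-2 with a planted median read
length of 25 nt; and position-dependent non-templated oligo(A) tailing
enriched near peaks (TRAMP-like), with replicates differing by seed only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .util import spawn_rng

__all__ = ["ElementMap", "ReadSimSpec", "make_reference", "simulate_reads",
           "READ_COLUMNS"]

READ_COLUMNS = ["chrom", "start", "end", "name", "count", "strand", "tail"]


@dataclass
class ElementMap:
    """Landmark positions in 1-based unit coordinates (TSS = 1)."""

    tss: int = 1
    a0: int = 610                 # strongest 5'-ETS peak position
    boundary_2kb: int = 2000
    b2: int = 6700                # 25S 3' end (synthetic placement)
    unit_length: int = 7000
    flank: int = 1300
    chrom: str = "rdna_unit"

    def __post_init__(self):
        order = [self.tss, self.a0, self.boundary_2kb, self.b2,
                 self.b0_1, self.b0_2, self.t1, self.nsi1_site[1]]
        if any(b <= a for a, b in zip(order, order[1:])):
            raise ValueError("element positions must be strictly increasing")
        if self.nsi1_site[1] > self.unit_length:
            raise ValueError("elements extend past the unit")
        if self.flank < 0:
            raise ValueError("flank must be >= 0")

    @property
    def b0_1(self) -> int:
        return self.b2 + 14

    @property
    def b0_2(self) -> int:
        return self.b2 + 49

    @property
    def t1(self) -> int:
        return self.b2 + 93

    @property
    def nsi1_site(self) -> Tuple[int, int]:
        return (self.t1 + 12, self.t1 + 20)

    @property
    def ref_length(self) -> int:
        return self.unit_length + 2 * self.flank

    def ref_index(self, unit_pos: int) -> int:
        """0-based reference index of a 1-based unit coordinate."""
        return self.flank + unit_pos - 1


_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(s: str) -> str:
    return "".join(_COMP[b] for b in reversed(s))


def make_reference(element_map: Optional[ElementMap] = None,
                   seed: int = 0) -> Tuple[str, pd.DataFrame]:
    """Random-composition reference with the element geometry planted.

    A palindromic cassette spans B0-1..B0-2 so any pairing-based folding
    engine sees a strong hairpin there (the Rnt1 stem), and a T-rich run
    marks the terminator T1.  Returns (sequence, BED6 annotation).
    """
    em = element_map or ElementMap()
    rng = spawn_rng(seed, 11)
    seq = rng.choice(_BASES, size=em.ref_length)
    # hairpin cassette: stem-loop exactly filling B0-1..B0-2 (36 nt)
    span = em.b0_2 - em.b0_1 + 1
    loop = 4
    stem = (span - loop) // 2
    stem_seq = "".join(rng.choice(list("GC"), size=stem))
    cassette = stem_seq + "".join(rng.choice(_BASES, size=span - 2 * stem)) \
        + _revcomp(stem_seq)
    i0 = em.ref_index(em.b0_1)
    seq[i0:i0 + span] = list(cassette)
    # T-rich terminator element around T1
    t0 = em.ref_index(em.t1)
    seq[t0 - 3:t0 + 9] = "T"
    sequence = "".join(seq)
    rows = []

    def bed(name, start_pos, end_pos):
        rows.append({"chrom": em.chrom, "start": em.ref_index(start_pos),
                     "end": em.ref_index(end_pos) + 1, "name": name,
                     "score": 0, "strand": "+"})

    bed("TSS", em.tss, em.tss)
    bed("A0", em.a0, em.a0)
    bed("boundary_2kb", em.boundary_2kb, em.boundary_2kb)
    bed("B2", em.b2, em.b2)
    bed("B0_1", em.b0_1, em.b0_1)
    bed("B0_2", em.b0_2, em.b0_2)
    bed("T1", em.t1, em.t1)
    bed("Nsi1", em.nsi1_site[0], em.nsi1_site[1])
    bed("unit", em.tss, em.unit_length)
    return sequence, pd.DataFrame(rows)


@dataclass
class ReadSimSpec:
    """Statistical design of one synthetic CRAC library (per replicate).

    peak_mixture: (center [unit coords], width [nt], weight) components of
    the 3'-end distribution; weights plus background_weight sum to 1.
    cleavage5p_fraction of reads belong to the co-transcriptional-cleavage
    class: 5' end pinned at B0-2, length with median cleaved_length_median.
    Oligo(A) tails (>= 3 nt, geometric) are appended with a probability
    interpolating between polyA_base_rate and polyA_peak_rate by proximity
    to the planted peaks.
    """

    n_reads: int = 20_000
    peak_mixture: Sequence[Tuple[int, float, float]] = None
    background_weight: float = 0.10
    cleavage5p_fraction: float = 0.15
    cleaved_length_median: int = 25
    length_min: int = 18
    length_nbinom_r: float = 6.0
    length_nbinom_mean: float = 22.0     # mean of the NB part added to length_min
    polyA_base_rate: float = 0.02
    polyA_peak_rate: float = 0.25
    polyA_geom_p: float = 0.4
    junk_tail_rate: float = 0.01         # non-A-terminal soft-clips
    n_replicates: int = 6
    strand: str = "+"
    seed: int = 0

    def __post_init__(self):
        if self.peak_mixture is None:
            em = ElementMap()
            self.peak_mixture = [
                (em.a0, 15.0, 0.30),
                (1250, 20.0, 0.15),
                (3500, 30.0, 0.15),
                (5500, 30.0, 0.10),
                (em.b0_2 + self.cleaved_length_median, 12.0, 0.20),
            ]
        w = sum(wt for _, _, wt in self.peak_mixture) + self.background_weight
        if abs(w - 1.0) > 1e-6:
            raise ValueError(f"mixture weights + background must sum to 1 "
                             f"(got {w})")
        for frac in (self.background_weight, self.cleavage5p_fraction,
                     self.polyA_base_rate, self.polyA_peak_rate,
                     self.junk_tail_rate):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must be in [0, 1]")
        if self.cleaved_length_median < 1 or self.length_min < 1:
            raise ValueError("lengths must be >= 1")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


def _polya_prob(three_prime: np.ndarray, spec: ReadSimSpec) -> np.ndarray:
    """Per-read oligo(A) probability: base rate lifted toward the peak rate
    by Gaussian proximity to the nearest planted peak."""
    prox = np.zeros(three_prime.shape, float)
    for center, width, _ in spec.peak_mixture:
        d = (three_prime - center) / max(width, 1.0)
        np.maximum(prox, np.exp(-0.5 * d * d), out=prox)
    return spec.polyA_base_rate + \
        (spec.polyA_peak_rate - spec.polyA_base_rate) * prox


def _one_replicate(spec: ReadSimSpec, em: ElementMap, rep: int,
                   rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n_reads
    if n == 0:
        return pd.DataFrame(columns=READ_COLUMNS)
    is_cleaved = rng.random(n) < spec.cleavage5p_fraction
    n_cle = int(is_cleaved.sum())
    n_ord = n - n_cle

    # ordinary reads: 3' end from the peak mixture + uniform background
    weights = np.array([wt for _, _, wt in spec.peak_mixture]
                       + [spec.background_weight])
    comp = rng.choice(len(weights), size=n_ord, p=weights / weights.sum())
    three_p = np.empty(n_ord, np.int64)
    for k, (center, width, _) in enumerate(spec.peak_mixture):
        m = comp == k
        three_p[m] = np.rint(rng.normal(center, width, m.sum()))
    bg = comp == len(spec.peak_mixture)
    three_p[bg] = rng.integers(1, em.unit_length + 1, bg.sum())
    np.clip(three_p, 1, em.unit_length, out=three_p)
    nb_p = spec.length_nbinom_r / (spec.length_nbinom_r
                                   + spec.length_nbinom_mean)
    lengths = spec.length_min + rng.negative_binomial(
        spec.length_nbinom_r, nb_p, n_ord)
    five_p = three_p - lengths + 1
    np.clip(five_p, 1 - em.flank, None, out=five_p)

    # cleavage class: 5' pinned at B0-2, symmetric length noise about the
    # planted median
    cl_len = spec.cleaved_length_median + np.rint(
        rng.normal(0.0, 2.0, n_cle)).astype(np.int64)
    np.clip(cl_len, 1, None, out=cl_len)
    cl_five = np.full(n_cle, em.b0_2, np.int64)
    cl_three = cl_five + cl_len - 1
    np.clip(cl_three, None, em.unit_length + em.flank, out=cl_three)

    five = np.concatenate([five_p, cl_five])
    three = np.concatenate([three_p, cl_three])

    # non-templated tails
    p_a = _polya_prob(three, spec)
    has_a = rng.random(n) < p_a
    a_len = 3 + rng.geometric(spec.polyA_geom_p, n) - 1
    junk = (~has_a) & (rng.random(n) < spec.junk_tail_rate)
    tails = np.full(n, "", object)
    for i in np.flatnonzero(has_a):
        tails[i] = "A" * int(a_len[i])
    junk_idx = np.flatnonzero(junk)
    if junk_idx.size:
        junk_bases = rng.choice(list("CGT"), size=junk_idx.size)
        for i, b in zip(junk_idx, junk_bases):
            tails[i] = "A" * int(rng.integers(0, 3)) + b

    start = em.flank + five - 1
    end = em.flank + three          # 0-based half-open
    df = pd.DataFrame({
        "chrom": em.chrom,
        "start": start,
        "end": end,
        "name": [f"rep{rep}_read{i}" for i in range(n)],
        "count": 1,
        "strand": spec.strand,
        "tail": tails,
    })
    return df[READ_COLUMNS]


def simulate_reads(spec: Optional[ReadSimSpec] = None,
                   element_map: Optional[ElementMap] = None,
                   seed: Optional[int] = None) -> List[pd.DataFrame]:
    """One read collection per replicate; replicates differ by seed only."""
    spec = spec or ReadSimSpec()
    em = element_map or ElementMap()
    if any(c > em.unit_length or c < 1 for c, _, _ in spec.peak_mixture):
        raise ValueError("planted peaks must lie within the unit")
    master = spec.seed if seed is None else seed
    return [_one_replicate(spec, em, r, spawn_rng(master, 101, r))
            for r in range(spec.n_replicates)]
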