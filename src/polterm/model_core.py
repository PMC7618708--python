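"""Stochastic lattice model of RNA polymerase I transcription.

One rDNA transcription unit is a 1-nt lattice of length ``gene_length``.
Polymerases initiate at position 1, translocate by a Brownian-ratchet rule
biased by nascent-RNA folding, the RNA:DNA hybrid and inter-polymerase DNA
torsion (one turn per 10.3 nt, coupling scaled by each partner's
entrainment factor), exclude each other sterically over a 38-nt footprint,
may terminate prematurely with a constant hazard over the first
``pt_distance`` nt, and are released as productive upon reaching the end of
the unit.

The premature-termination hazard implements a total per-transit probability
``p_pt`` spread uniformly over the transit time of the PT region:
``hazard = p_pt * v_bar / pt_distance`` (per second), so that the cumulative
hazard of a polymerase crossing the whole region at the mean velocity is
exactly ``p_pt``.  Processivity is ``productive / (productive +
non_productive)``; with termination active it approximates ``exp(-p_pt)``
rather than ``1 - p_pt``, which is why ``p_pt`` and processivity are
related but not identical quantities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Optional, Sequence

import numpy as np

from . import _kernel
from ._kernel import NT_PER_TURN

__all__ = [
    "SimParams", "PolState", "SimCounters", "UnitState", "SimOutput",
    "pt_hazard", "entrainment_factor", "step_probabilities",
    "advance_unit", "simulate_unit", "processivity",
    "rotations_per_transcript", "rotation_rate_rpm", "NT_PER_TURN",
]


@dataclass
class SimParams:
    """Full parameterization of the transcription-unit simulator.

    Defaults reproduce the study conditions: a 7000-nt unit, 38-nt
    polymerase footprint, 11-nt RNA:DNA hybrid, mean velocity 50 nt/s,
    4-ms time step, 6000-s (one generation) runs, initiation probability
    0.8 per attempt with attempts every 2 s (calibrated to ~50 engaged
    polymerases per unit at steady state).
    """

    gene_length: int = 7000
    footprint: int = 38
    hybrid_length: int = 11
    dt: float = 0.004
    sim_time: float = 6000.0
    initiation_prob: float = 0.8
    initiation_interval: float = 2.0
    v_bar: float = 50.0
    dg_structure: float = 1.25
    dg_hybrid_ratio: float = 0.48
    structure_window: int = 11
    torsion_stiffness_c: float = 0.5
    p_pt: float = 0.0
    pt_distance: int = 2000
    ler_length: int = 2000
    n_replicates: int = 16
    seed: int = 0
    # ratchet mobility: baseline probability of attempting a move per tick;
    # the forward/backward split around it carries all biases.
    move_attempt_prob: float = 0.5
    # constant-velocity control: deterministic forward stepping at v_bar,
    # no backtracking or biases (used for closed-form hazard checks).
    constant_velocity: bool = False

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.gene_length <= 0 or self.footprint <= 0 \
                or self.hybrid_length <= 0 or self.structure_window <= 0:
            raise ValueError("all lengths must be > 0")
        if self.dt <= 0 or self.sim_time <= 0 or self.v_bar <= 0:
            raise ValueError("dt, sim_time and v_bar must be > 0")
        if not 0.0 <= self.initiation_prob <= 1.0:
            raise ValueError("initiation_prob must be in [0, 1]")
        if not 0.0 <= self.p_pt <= 1.0:
            raise ValueError("p_pt must be in [0, 1]")
        if self.pt_distance > self.gene_length:
            raise ValueError("pt_distance must not exceed gene_length")
        if self.footprint >= self.gene_length:
            raise ValueError("footprint must be smaller than gene_length")
        if self.ler_length < 0 or self.pt_distance <= 0:
            raise ValueError("ler_length >= 0 and pt_distance > 0 required")

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimParams keys: {sorted(unknown)}")
        return cls(**d)

    def replace(self, **kw) -> "SimParams":
        return replace(self, **kw)

    @property
    def capacity(self) -> int:
        return self.gene_length // self.footprint + 2

    @property
    def init_every_steps(self) -> int:
        return max(1, int(round(self.initiation_interval / self.dt)))

    @property
    def k_det_steps(self) -> int:
        return max(1, int(round(1.0 / (self.v_bar * self.dt))))

    @property
    def transit_time(self) -> float:
        """One transit of the unit at the mean velocity, in seconds."""
        return self.gene_length / self.v_bar


@dataclass
class PolState:
    """One engaged polymerase: active-site position (1-based), the
    furthest position reached (backtrack depth = max_position - position)
    and time of initiation."""

    position: int
    max_position: int
    birth_time: float

    def __post_init__(self):
        if not 1 <= self.position <= self.max_position:
            raise ValueError("require 1 <= position <= max_position")


@dataclass
class SimCounters:
    productive: int = 0
    non_productive: int = 0
    initiations: int = 0

    def as_array(self) -> np.ndarray:
        a = np.zeros(6, np.int64)
        a[0], a[1], a[2] = self.initiations, self.productive, self.non_productive
        return a


@dataclass
class UnitState:
    """Mutable state of one transcription unit: engaged polymerases sorted
    downstream->upstream (strictly decreasing position, pairwise gaps >=
    footprint), pairwise twist imbalances (turns), elapsed time, counters
    and accumulated per-nt residence time."""

    params: SimParams
    polymerases: list = field(default_factory=list)
    twist: list = field(default_factory=list)   # gap i: pol i vs pol i+1
    time: float = 0.0
    step_index: int = 0
    counters: SimCounters = field(default_factory=SimCounters)
    occupancy: np.ndarray = None
    clamp_warnings: int = 0

    def __post_init__(self):
        if self.occupancy is None:
            self.occupancy = np.zeros(self.params.gene_length)
        self.check()

    def check(self) -> None:
        pos = [p.position for p in self.polymerases]
        for down, up in zip(pos, pos[1:]):
            if down - up < self.params.footprint:
                raise AssertionError(
                    f"steric violation: positions {down} and {up}")
            if down <= up:
                raise AssertionError("polymerases out of order")
        if len(self.twist) != max(0, len(self.polymerases) - 1):
            raise AssertionError("twist gap count mismatch")


@dataclass
class SimOutput:
    """Result of one simulated unit."""

    counters: SimCounters
    occupancy_profile: np.ndarray          # normalized to sum 1
    mean_pol_count: float                  # time-averaged, after burn-in
    processivity: Optional[float]          # None when no pol finished/terminated
    raw_occupancy: np.ndarray = None       # seconds of residence per nt
    productive_after_burn: int = 0
    non_productive_after_burn: int = 0
    engaged_final: int = 0
    clamp_warnings: int = 0
    sim_time: float = 0.0
    burn_in: float = 0.0
    seed: int = 0


def pt_hazard(params: SimParams) -> float:
    """Per-second premature-termination hazard.

    The total per-transit probability ``p_pt`` divided by the time a
    polymerase spends in the PT region at the mean velocity
    (``pt_distance / v_bar``): hazard = p_pt * v_bar / pt_distance.
    The stepper applies hazard*dt per tick to polymerases at positions
    <= pt_distance.
    """
    if params.p_pt == 0:
        return 0.0
    return params.p_pt * params.v_bar / params.pt_distance


def entrainment_factor(transcript_length: float, params: SimParams) -> float:
    """Torsional-coupling factor in [0, 1]: 0 for a naked polymerase, a
    linear ramp over the low-entrainment region, 1 once the nascent
    pre-ribosome is large enough to block rotation."""
    if transcript_length < 0:
        raise ValueError("transcript_length must be >= 0")
    return float(_kernel.entrain.py_func(transcript_length, params.ler_length))


def _signals(position: int, fold: np.ndarray, params: SimParams):
    lo = max(0, position - 1 - params.structure_window)
    hi = position - 1
    s = float(fold[lo:hi].mean()) if hi > lo else 0.0
    return s, float(fold[position - 1])


def step_probabilities(pol: PolState, unit: UnitState,
                       folding: Optional[np.ndarray],
                       params: SimParams):
    """(p_forward, p_backward, p_stay) for one polymerase in its current
    context (neighbours, folding signal, accumulated twist)."""
    pols = unit.polymerases
    try:
        i = pols.index(pol)
    except ValueError:
        raise ValueError("polymerase is not part of the unit")
    fold = np.zeros(params.gene_length) if folding is None \
        else np.asarray(folding, float)
    p = pol.position
    blocked_f = p >= params.gene_length or \
        (i > 0 and pols[i - 1].position - p <= params.footprint)
    blocked_b = p <= 1 or \
        (i < len(pols) - 1 and p - pols[i + 1].position <= params.footprint)
    s_sig, h_sig = _signals(p, fold, params)
    e_i = entrainment_factor(p, params)
    torsion = 0.0
    if i < len(pols) - 1:
        torsion += params.torsion_stiffness_c * unit.twist[i] * e_i * \
            entrainment_factor(pols[i + 1].position, params)
    if i > 0:
        torsion -= params.torsion_stiffness_c * unit.twist[i - 1] * e_i * \
            entrainment_factor(pols[i - 1].position, params)
    pf, pb, _ = _kernel.step_probs.py_func(
        blocked_f, blocked_b, s_sig, h_sig, torsion,
        params.v_bar, params.dt, params.move_attempt_prob,
        params.dg_structure, params.dg_hybrid_ratio)
    return pf, pb, 1.0 - pf - pb


def advance_unit(unit: UnitState, folding: Optional[np.ndarray],
                 params: SimParams, rng) -> UnitState:
    """Advance the unit by one dt tick in place (and return it).

    ``rng`` must provide ``random()`` and ``random(size)`` (a
    numpy Generator does); it supplies, in order, the initiation draw
    (only on attempt ticks), the per-polymerase move draws and the
    per-polymerase termination draws.
    """
    n = len(unit.polymerases)
    cap = params.capacity
    positions = np.zeros(cap, np.int64)
    maxpos = np.zeros(cap, np.int64)
    birth = np.zeros(cap, np.int64)
    twist = np.zeros(cap, np.float64)
    for i, pol in enumerate(unit.polymerases):
        positions[i] = pol.position
        maxpos[i] = pol.max_position
        birth[i] = int(round(pol.birth_time / params.dt))
    for i, t in enumerate(unit.twist):
        twist[i] = t
    fold = np.zeros(params.gene_length) if folding is None \
        else np.ascontiguousarray(folding, dtype=np.float64)
    attempt = (unit.step_index % params.init_every_steps) == 0
    init_draw = float(rng.random()) if attempt else 2.0
    m = min(n + 1, cap)
    move_draws = np.asarray(rng.random(m), np.float64).copy()
    pt_draws = np.asarray(rng.random(m), np.float64).copy()
    move_buf = np.zeros(cap)
    pt_buf = np.zeros(cap)
    move_buf[:m] = move_draws
    pt_buf[:m] = pt_draws
    counters = unit.counters.as_array()
    counters[3] = unit.clamp_warnings
    n_new = _kernel.advance(
        positions, maxpos, birth, twist, n, fold, unit.occupancy,
        params.gene_length, params.footprint, params.dt, params.v_bar,
        params.move_attempt_prob, params.dg_structure,
        params.dg_hybrid_ratio, params.structure_window,
        params.torsion_stiffness_c, params.ler_length,
        pt_hazard(params), params.pt_distance,
        params.constant_velocity, params.k_det_steps, unit.step_index,
        attempt, params.initiation_prob, init_draw, move_buf, pt_buf,
        counters, False)
    unit.polymerases = [
        PolState(int(positions[i]), int(maxpos[i]), birth[i] * params.dt)
        for i in range(n_new)]
    unit.twist = [float(twist[i]) for i in range(max(0, n_new - 1))]
    unit.counters = SimCounters(productive=int(counters[1]),
                                non_productive=int(counters[2]),
                                initiations=int(counters[0]))
    unit.clamp_warnings = int(counters[3])
    unit.step_index += 1
    unit.time = unit.step_index * params.dt
    return unit


def simulate_unit(params: SimParams, seed: Optional[int] = None,
                  folding: Optional[np.ndarray] = None,
                  burn_in: float = 0.0) -> SimOutput:
    """Simulate one transcription unit for ``params.sim_time`` seconds.

    Deterministic for a given (params, seed); ``seed`` defaults to
    ``params.seed``.  ``burn_in`` seconds are excluded from the
    steady-state statistics (mean polymerase count, after-burn counters)
    but not from the occupancy profile or the totals.
    """
    if seed is None:
        seed = params.seed
    seed = int(seed) % (2 ** 31)
    n_steps_f = params.sim_time / params.dt
    if abs(n_steps_f - round(n_steps_f)) <= 1e-6 * max(1.0, n_steps_f):
        n_steps = int(round(n_steps_f))
    else:
        import warnings
        warnings.warn("sim_time is not an integer number of steps; "
                      "rounding down")
        n_steps = int(math.floor(n_steps_f))
    burn_steps = min(n_steps, int(round(burn_in / params.dt)))
    fold = np.zeros(params.gene_length) if folding is None \
        else np.ascontiguousarray(folding, dtype=np.float64)
    if fold.shape[0] != params.gene_length:
        raise ValueError("folding track must cover gene_length")
    counters, occupancy, n_final, pol_steps = _kernel.run_sim(
        seed, n_steps, burn_steps, fold,
        params.gene_length, params.footprint, params.dt, params.v_bar,
        params.move_attempt_prob, params.dg_structure,
        params.dg_hybrid_ratio, params.structure_window,
        params.torsion_stiffness_c, params.ler_length,
        pt_hazard(params), params.pt_distance,
        params.constant_velocity, params.k_det_steps,
        params.init_every_steps, params.initiation_prob, params.capacity)
    sc = SimCounters(productive=int(counters[1]),
                     non_productive=int(counters[2]),
                     initiations=int(counters[0]))
    total = occupancy.sum()
    profile = occupancy / total if total > 0 else occupancy.copy()
    finished = sc.productive + sc.non_productive
    proc = sc.productive / finished if finished > 0 else None
    steps_after = max(1, n_steps - burn_steps)
    return SimOutput(
        counters=sc,
        occupancy_profile=profile,
        mean_pol_count=pol_steps / steps_after,
        processivity=proc,
        raw_occupancy=occupancy,
        productive_after_burn=int(counters[4]),
        non_productive_after_burn=int(counters[5]),
        engaged_final=int(n_final),
        clamp_warnings=int(counters[3]),
        sim_time=n_steps * params.dt,
        burn_in=burn_steps * params.dt,
        seed=seed,
    )


def processivity(counters: SimCounters) -> float:
    """Fraction of finished polymerases that reached the end of the unit:
    productive / (productive + non_productive)."""
    total = counters.productive + counters.non_productive
    if total == 0:
        raise ValueError("processivity undefined: no polymerase has "
                         "terminated or completed")
    return counters.productive / total


def rotations_per_transcript(gene_length: int = 7000,
                             nt_per_turn: float = NT_PER_TURN) -> float:
    """Complete DNA rotations required to transcribe the unit once
    (one turn per ~10.3 nt)."""
    return gene_length / nt_per_turn


def rotation_rate_rpm(velocity: float = 40.0,
                      nt_per_turn: float = NT_PER_TURN) -> float:
    """DNA rotation rate (rpm) of a polymerase elongating at ``velocity``
    nt/s."""
    return velocity / nt_per_turn * 60.0
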