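"""Parameter sweeps over the premature-termination probability and the
demand calculus that converts simulated per-unit transcript counts into
per-generation ribosome output for a cell with ~75 active rDNA repeats.

The demand model encodes the literature values used to interpret the
simulations: 75 transcriptionally active repeats out of 150, a 100-min
(6000 s) generation, demand of 200,000 ribosomes per generation, with
output below 150,000 classed as decreased and below 100,000 as
insufficient.  Output simulated on n parallel units is scaled to 75
repeats (the printed factor 4.7 for the 16-unit design, exact 75/n
otherwise) and extrapolated linearly in time from the post-burn-in
steady-state flux.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .model_core import SimParams, SimOutput, simulate_unit
from .util import spawn_seed

__all__ = ["DemandModel", "GridSpec", "GridResult", "run_grid",
           "ribosome_output", "ppt_threshold", "five_prime_bias"]


@dataclass
class DemandModel:
    active_repeats: int = 75
    total_repeats: int = 150
    generation_time: float = 6000.0
    demand: float = 200_000.0
    decreased_threshold: float = 150_000.0
    insufficient_threshold: float = 100_000.0
    scale_factor: float = 4.7          # printed scaling for the 16-unit design

    def __post_init__(self):
        if not (self.insufficient_threshold <= self.decreased_threshold
                <= self.demand):
            raise ValueError("demand thresholds must be ordered")

    def repeat_scale(self, n_units: int) -> float:
        """Scale from n simulated units to the active repeats: the printed
        4.7 when n matches the 16-unit design, exact 75/n otherwise."""
        if n_units <= 0:
            raise ValueError("need at least one simulated unit")
        if n_units == 16:
            return self.scale_factor
        return self.active_repeats / n_units


def ribosome_output(per_unit_counts: Sequence[float],
                    demand: Optional[DemandModel] = None,
                    measured_time: Optional[float] = None) -> float:
    """Per-generation full-length transcript output across the active
    repeats, from counts on n parallel simulated units.

    ``measured_time`` is the window (s) over which the counts were
    accumulated; shorter-than-generation runs are extrapolated linearly
    (counts * generation_time / measured_time).  Omit it for counts that
    already span a full generation.
    """
    demand = demand or DemandModel()
    counts = list(per_unit_counts)
    if not counts:
        raise ValueError("per_unit_counts is empty")
    total = float(sum(counts))
    scale = demand.repeat_scale(len(counts))
    if measured_time is not None:
        if measured_time <= 0:
            raise ValueError("measured_time must be > 0")
        total *= demand.generation_time / measured_time
    return total * scale


def five_prime_bias(occupancy_profile: np.ndarray, boundary: int = 2000,
                    pseudo: float = 1e-12) -> float:
    """Mean occupancy over the first ``boundary`` nt divided by the mean
    over the remainder of the unit (the 5' excess statistic)."""
    prof = np.asarray(occupancy_profile, float)
    if prof.size < boundary + 1:
        raise ValueError("profile shorter than boundary + 1")
    if prof.sum() <= 0:
        raise ValueError("all-zero profile: bias undefined")
    head = prof[:boundary].mean()
    tail = prof[boundary:].mean()
    return head / (tail + pseudo)


@dataclass
class GridSpec:
    """A sweep over premature-termination settings.

    Each cell = (p_pt, pt_distance, structure on/off).  For every master
    seed, ``replicates_per_cell`` parallel units are simulated (the paper's
    design: 16 units x 6000 s; the scaled-down default used in tests is
    fewer units over shorter runs, extrapolated)."""

    base_params: SimParams
    p_pt_values: Sequence[float]
    pt_distances: Sequence[int] = None
    structure_toggles: Sequence[bool] = (False,)
    replicates_per_cell: int = 4
    seeds: Sequence[int] = (1, 2)
    folding_signal: Optional[np.ndarray] = None
    burn_in: Optional[float] = None     # default: one transit

    def __post_init__(self):
        if self.pt_distances is None:
            self.pt_distances = [self.base_params.pt_distance]
        if not len(self.p_pt_values) or not len(self.pt_distances):
            raise ValueError("empty sweep")
        if any(not 0 <= p <= 1 for p in self.p_pt_values):
            raise ValueError("p_pt values must be in [0, 1]")
        if self.replicates_per_cell < 1 or not len(self.seeds):
            raise ValueError("need >= 1 replicate and >= 1 seed")


@dataclass
class GridResult:
    table: pd.DataFrame
    demand: DemandModel = field(default_factory=DemandModel)


def _cell_measurement(params: SimParams, n_units: int, master_seed: int,
                      folding, burn_in: float, demand: DemandModel):
    """One measurement of a grid cell: n_units parallel units under one
    master seed; returns per-unit outputs and the extrapolated
    per-generation ribosome count."""
    outs: list[SimOutput] = []
    for u in range(n_units):
        child = spawn_seed(master_seed, u)
        outs.append(simulate_unit(params, seed=child, folding=folding,
                                  burn_in=burn_in))
    window = outs[0].sim_time - outs[0].burn_in
    ribo = ribosome_output([o.productive_after_burn for o in outs],
                           demand, measured_time=window)
    return outs, ribo


def run_grid(grid: GridSpec, demand: Optional[DemandModel] = None) -> GridResult:
    """Simulate every cell of the sweep; deterministic given the seeds.

    Means and standard deviations are taken over the master seeds; a cell
    that raises is recorded with an ``error`` marker instead of being
    dropped.
    """
    demand = demand or DemandModel()
    base = grid.base_params
    burn_in = grid.burn_in if grid.burn_in is not None else base.transit_time
    rows = []
    for structure_on in grid.structure_toggles:
        folding = grid.folding_signal if structure_on else None
        for pt_dist in grid.pt_distances:
            for p_pt in grid.p_pt_values:
                row = {"p_pt": float(p_pt), "pt_distance": int(pt_dist),
                       "structure": bool(structure_on),
                       "n_seeds": len(grid.seeds),
                       "n_units": grid.replicates_per_cell,
                       "error": ""}
                try:
                    params = base.replace(p_pt=float(p_pt),
                                          pt_distance=int(pt_dist))
                    prod, proc, npol, ribo, bias = [], [], [], [], []
                    for s in grid.seeds:
                        outs, r = _cell_measurement(
                            params, grid.replicates_per_cell, int(s),
                            folding, burn_in, demand)
                        prod.append(np.mean(
                            [o.counters.productive for o in outs]))
                        pr = [o.processivity for o in outs
                              if o.processivity is not None]
                        proc.append(np.mean(pr) if pr else np.nan)
                        npol.append(np.mean([o.mean_pol_count for o in outs]))
                        ribo.append(r)
                        pooled = np.sum([o.raw_occupancy for o in outs],
                                        axis=0)
                        bias.append(five_prime_bias(pooled))
                    for name, vals in [("productive", prod),
                                       ("processivity", proc),
                                       ("mean_pol_count", npol),
                                       ("ribosomes_per_generation", ribo),
                                       ("five_prime_bias", bias)]:
                        row[f"{name}_mean"] = float(np.nanmean(vals))
                        row[f"{name}_sd"] = float(np.nanstd(vals, ddof=0))
                except Exception as exc:   # record, do not drop
                    row["error"] = f"{type(exc).__name__}: {exc}"
                rows.append(row)
    return GridResult(table=pd.DataFrame(rows), demand=demand)


def ppt_threshold(result: Union[GridResult, Mapping[float, float]],
                  demand: Optional[DemandModel] = None):
    """Smallest swept p_pt whose mean per-generation ribosome output falls
    below the 'decreased' boundary; None if all cells meet demand.

    Accepts a GridResult (rows with pt_distance == gene_length, i.e. the
    whole-unit sweep, are used when several PT regions are present) or a
    plain {p_pt: output} mapping.
    """
    demand = demand or (result.demand if isinstance(result, GridResult)
                        else DemandModel())
    if isinstance(result, GridResult):
        t = result.table[result.table["error"] == ""]
        if t.empty:
            raise ValueError("empty sweep")
        if t["pt_distance"].nunique() > 1:
            t = t[t["pt_distance"] == t["pt_distance"].max()]
        pairs = (t.groupby("p_pt")["ribosomes_per_generation_mean"]
                 .mean().sort_index().items())
    else:
        if not result:
            raise ValueError("empty sweep")
        pairs = sorted(result.items())
    for p_pt, output in pairs:
        if output < demand.decreased_threshold:
            return float(p_pt)
    return None
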