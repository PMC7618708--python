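# Methods

## The lattice model

A transcription unit is a 1-nt lattice of length `gene_length` (default
7000). The simulator advances in fixed steps of `dt = 0.004` s. State per
engaged polymerase: active-site position (1-based), furthest position
reached (their difference is the backtrack depth), and birth step.
Polymerases are kept sorted downstream→upstream; the pairwise gap must
stay ≥ `footprint` (38 nt).

Each step, in order:

1. **Initiation.** On attempt ticks (every `initiation_interval` s) a
   polymerase is loaded at position 1 with probability `initiation_prob`
   (0.8), provided positions 1..footprint are free.
2. **Translocation.** Each polymerase (downstream first, so same-step
   pass-through collisions are impossible) draws one move from
   (p_f, p_b, p_stay). A baseline mobility `move_attempt_prob` (0.5) is
   split as p_f = (m + bias)/2, p_b = (m − bias)/2 with

   bias = V̄·dt·(1 + w_s·s + w_s·r·h) + c·Σ twist·e_i·e_j,

   where `s` is the mean pairing signal over the `structure_window`
   (11 nt) of nascent RNA behind the active site, `h` the signal at the
   active site (RNA:DNA hybrid), w_s = `dg_structure` = 1.25,
   r = `dg_hybrid_ratio` = 0.48, c = `torsion_stiffness_c` = 0.5.
   On a neutral template with no neighbours, p_f − p_b = V̄·dt exactly
   (the velocity-calibration contract; verified to 5% empirically).
   Forward moves are blocked by a downstream neighbour within
   footprint+1; backward moves by position 1 or an upstream neighbour.
   Probabilities pushed outside [0,1] by large biases are clamped and
   counted (`clamp_warnings`); with the default parameters ~1% of updates
   clamp, an intended property of the bounded ratchet rather than an
   error.
3. **Premature termination.** Polymerases at positions ≤ `pt_distance`
   terminate with probability hazard·dt, hazard = p_pt·V̄/pt_distance.
   The cumulative hazard over one transit of the PT region at V̄ is then
   exactly p_pt. Terminated transcripts are discarded (no surveillance
   kinetics submodel).
4. **Completion.** A polymerase at `gene_length` is removed and counted
   productive.
5. **Occupancy.** Every engaged polymerase accrues dt at its position.

**Twist bookkeeping.** Each adjacent pair carries a relative-twist
accumulator (turns); a forward step of the upstream partner adds 1/10.3
turn, of the downstream partner subtracts it (backward steps invert).
The torsion bias is linear in the accumulated difference (stiffness c)
and scaled by both partners' entrainment factors
e = min(1, position/ler_length) — a linear ramp over the low-entrainment
region (2000 nt; `ler_length = 0` disables the ramp entirely). When a
polymerase leaves (termination or completion), the merged gap's twist
relaxes to 0, abstracting topoisomerase swivelling. This is a deliberate
re-design of the torsional-entrainment force with the same qualitative
behaviour as the published MATLAB lineage model; no bit-compatibility with
that code is claimed.

**Constant-velocity control.** `constant_velocity=True` replaces the
ratchet by deterministic forward stepping at V̄ (1 nt every 5 ticks) with
no backtracking or biases. In this mode the terminated fraction of
finished polymerases equals 1 − exp(−p_pt) up to Monte-Carlo error, the
closed form used to test the hazard implementation (and the precise sense
in which p_pt "approximates" 1 − processivity).

**Initiation schedule.** Only the per-attempt probability (0.8) is fixed
by the source model; an attempt every 4-ms step would saturate the
lattice. The attempt interval is the package's calibration knob: at the
default 2.0 s the steady-state loading is ≈54 engaged polymerases per
unit (target ≈50), and the steady-state initiation flux is ≈0.4 s⁻¹.

**Determinism.** `simulate_unit` is bit-reproducible for a given
(params, seed); the compiled kernel uses numba's Mersenne Twister seeded
per run. The object-level `advance_unit` path shares the same compiled
single-step kernel but takes an injectable draw source, so forced-outcome
unit tests exercise the identical update rule.

## Demand calculus and sweeps

Per-generation ribosome output = Σ productive over n units ×
(generation_time / measured_window) × repeat scale. The repeat scale is
the printed 4.7 for the 16-unit design and exactly 75/n otherwise.
Thresholds: 200,000 demand, 150,000 "decreased", 100,000 "insufficient".
The "reported range" criterion for the p_pt threshold is operationalized
as output ≥ 150,000 (the "decreased" boundary).

Scaled-down execution: default sweeps measure 600 s of steady state after
a 140-s burn-in (one transit) on 4 parallel units per measurement and
extrapolate linearly; this choice makes a desk-scale run statistically
adequate because the post-burn-in productive flux is time-homogeneous
(tested: doubling the window doubles counts within Monte-Carlo error).
The p_pt = 0.2 cell sits close to the 150k boundary (long-run mean
≈148.5k), so the threshold sweep in `scripts/acceptance.py` averages 16
seed replicates per cell to keep the boundary decision stable.

## Synthetic reads

`make_reference` plants, in a random-composition sequence of
7000 + 2×1300 nt: a palindromic stem-loop filling B0-1..B0-2 (so any
pairing-based folding engine shows the Rnt1 stem as a ΔG dip) and a
T-rich run at T1 (B2+93). B2 defaults to unit position 6700 — a synthetic
placement chosen so the terminator region sits inside the unit with room
for readthrough signal downstream.

`simulate_reads` draws 3′ ends from a Gaussian peak mixture plus uniform
background; ordinary read lengths are shifted negative-binomial
(min 18 nt, NB mean 22, r = 6 — a right-skewed 20–60 nt distribution
typical of protein-protected fragments); the cleavage class (15% by
default) has its 5′ end pinned at B0-2 with lengths symmetric about the
planted median 25. Oligo(A) tails (≥3 nt, geometric) are appended with
probability interpolating from 2% (background) to 25% (at peaks) by
Gaussian proximity; 1% of reads get a non-A-terminal soft-clip to
exercise the selector's rejection path. Replicates differ by seed only.

What this does *not* emulate: sequencing error, PCR duplication,
multi-copy rDNA mapping ambiguity, or any sequence-dependence of peak
positions. Passing round-trip tests therefore show the *analysis* is
correct and self-consistent, not that it would be robust to those
artifacts in real libraries.

## Profile computations

- Ends: + strand 5′ = start, 3′ = end−1 (0-based half-open), swapped on −.
- Unit normalization: divide by the unit-window total, then add the 1e-7
  pseudocount to every position (order exposed as config; the flag
  prevents double application).
- Smoothing: Blackman kernel (window 10) normalized to sum 1; edges use
  the truncated renormalized kernel, so a constant track is invariant and
  total signal is conserved away from edges.
- Replicate bands: median, 25/75 percentiles (linear interpolation — the
  common default, exposed as a documented choice), min/max.
- Readthrough: fraction of unit 3′-end signal strictly downstream of the
  terminator; group comparison by two-sided Wilcoxon rank-sum
  (exact ≤ 25 per group, normal approximation above).
- Oligo(A) rule: the A-run must terminate the non-templated tail
  (a tail ending in non-A disqualifies), the stringent reading of
  "AAA or longer" given that TRAMP adds to the 3′ end; `whole_tail=True`
  gives the stricter all-A mode.

## Peak calling

The track is pre-smoothed with a centered moving average (window 80); a
position is a peak iff its smoothed value is strictly greater than every
value within 45 nt to its left and ≥ every value within 45 nt to its
right (ties therefore resolve to the leftmost position), and ≥
`min_height` × smoothed mean. The height floor default (1.0 × mean) is a
documented choice — the upstream implementation states no floor.
Edge positions within `order` of the boundary are not callable. Troughs:
negate the track. Metaplots superimpose ±flank windows across peaks and
average; peaks with incomplete windows are dropped with a logged count,
and a blacklist supports excluding designated peaks.

## Folding track

Position i (1-based) scores the `window` = 65 nt of nascent RNA ending
`offset` = 15 nt behind the active site (the region still inside the
enzyme is skipped): values[i] = engine(seq[i−offset−window+1 .. i−offset]),
NA where the trailing window is incomplete. The bundled fallback engine is
a Nussinov-style maximum base-pairing dynamic program (WC + GU pairs,
minimum loop 3) scored at −1 kcal/mol per pair — deterministic and
monotone under added complementarity, but not thermodynamically exact;
RNAfold is pluggable by name, and any callable sequence→ΔG works.
Absolute ΔG values are engine-dependent and deliberately not asserted
anywhere; the simulator consumes only the min-max-normalized signal in
[0, 1].

## Known limitations

- No backtrack-resolution (Rpa12 cleavage), topoisomerase recruitment or
  exosome kinetics; termination is a memoryless hazard.
- The ratchet's functional form (additive biases around a baseline
  mobility of 0.5/step) is this package's own; quantities that depend
  only on mean drift, steric exclusion and the hazard are robust to it,
  local occupancy shapes are not.
- Occupancy profiles include the start-up transient; steady-state
  statistics exclude the burn-in but totals do not.
- The minus-strand read mode only mirrors strand semantics for
  coordinate tests; the generator's geometry is plus-strand.
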