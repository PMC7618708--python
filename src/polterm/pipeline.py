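"""Configuration handling and the stage pipeline with a run manifest.

A run config is a mapping of stage name -> stage parameters (YAML on disk).
Stages execute in dependency order (synth -> fold -> simulate -> grid ->
threshold -> profile -> polya -> readthrough -> peaks -> metaplot); each
stage validates its own keys, derives its randomness from the single
top-level seed through named substreams, and records its outputs (with
checksums) in the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .experiments import DemandModel, GridSpec, ppt_threshold, run_grid
from .folding_track import pairing_signal, window_dg
from .model_core import SimParams, simulate_unit
from .peaks_metaplots import PeakSet, find_peaks, metaplot
from .read_profiles import (ProfileTrack, aggregate_replicates, end_profile,
                            normalize_unit, readthrough_fraction,
                            readthrough_test, select_polyA, smooth_blackman)
from .synthetic_data import ElementMap, ReadSimSpec, make_reference, \
    simulate_reads
from .util import spawn_seed

__all__ = ["load_config", "run_pipeline", "STAGE_ORDER"]

STAGE_ORDER = ["synth", "fold", "simulate", "grid", "threshold",
               "profile", "polya", "readthrough", "peaks", "metaplot"]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping of stage -> parameters")
    unknown = set(cfg) - set(STAGE_ORDER) - {"seed"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _filter_keys(d: dict, cls) -> dict:
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return d


def _element_map(cfg: dict) -> ElementMap:
    return ElementMap(**_filter_keys(cfg.get("element_map", {}), ElementMap))


def _load_tracks(ctx, paths, length, em):
    tracks = []
    for p in paths:
        reads = pio.read_bed_reads(p)
        tracks.append((p, reads))
    return tracks


def run_pipeline(config: dict, seed: int, out_dir) -> dict:
    """Execute the requested stages; returns (and writes) the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", seed))
    manifest = {"seed": seed, "stages": []}
    ctx: dict = {}

    def record(name, params, outputs):
        manifest["stages"].append({
            "stage": name,
            "params": params,
            "outputs": {str(p): _sha256(Path(p)) for p in outputs},
        })

    for stage in STAGE_ORDER:
        if stage not in config:
            continue
        params = dict(config[stage] or {})
        outputs = []
        if stage == "synth":
            em = _element_map(params)
            spec_kw = _filter_keys(params.get("reads", {}), ReadSimSpec)
            spec = ReadSimSpec(**{**spec_kw, "seed": spawn_seed(seed, 1)})
            sequence, annot = make_reference(em, seed=spawn_seed(seed, 2))
            fa = out / "reference.fa"
            pio.write_fasta(sequence, fa, name=em.chrom)
            bed = out / "annotation.bed"
            pio.write_bed(annot, bed)
            outputs += [fa, bed]
            reps = simulate_reads(spec, em)
            for r, df in enumerate(reps):
                p = out / f"reads_rep{r}.bed"
                pio.write_bed_reads(df, p)
                outputs.append(p)
            ctx.update(element_map=em, reference=sequence,
                       read_paths=[out / f"reads_rep{r}.bed"
                                   for r in range(len(reps))])
        elif stage == "fold":
            ref = ctx.get("reference")
            if ref is None:
                fa = params.get("reference")
                if not fa or not Path(fa).exists():
                    raise FileNotFoundError(
                        f"fold: missing reference FASTA {fa!r}")
                ref = next(iter(pio.read_fasta(fa).values()))
            ft = window_dg(ref, engine=params.get("engine", "fallback"),
                           window=int(params.get("window", 65)),
                           offset=int(params.get("offset", 15)))
            em = ctx.get("element_map", ElementMap())
            track = ProfileTrack(ft.values, unit_start=em.flank,
                                 unit_length=em.unit_length, name=em.chrom)
            p = out / "folding.bedgraph"
            pio.write_bedgraph(track, p)
            outputs.append(p)
            ctx["folding"] = ft
        elif stage == "simulate":
            kw = _filter_keys({k: v for k, v in params.items()
                               if k not in ("n_runs", "burn_in",
                                            "occupancy_bedgraph")},
                              SimParams)
            sp = SimParams(**kw)
            n_runs = int(params.get("n_runs", sp.n_replicates))
            burn = float(params.get("burn_in", 0.0))
            fold = None
            if ctx.get("folding") is not None:
                fold = pairing_signal(ctx["folding"], length=sp.gene_length)
            rows = []
            occ = np.zeros(sp.gene_length)
            for r in range(n_runs):
                s = spawn_seed(seed, 3, r)
                o = simulate_unit(sp, seed=s, folding=fold, burn_in=burn)
                occ += o.raw_occupancy
                rows.append({
                    "seed": s, "productive": o.counters.productive,
                    "non_productive": o.counters.non_productive,
                    "initiations": o.counters.initiations,
                    "processivity": o.processivity,
                    "mean_pol_count": o.mean_pol_count,
                })
            p = out / "simulate.tsv"
            pio.write_tsv(pd.DataFrame(rows), p)
            outputs.append(p)
            if params.get("occupancy_bedgraph", True):
                track = ProfileTrack(occ / max(occ.sum(), 1e-300))
                pb = out / "occupancy.bedgraph"
                pio.write_bedgraph(track, pb)
                outputs.append(pb)
            ctx["simulate_table"] = pd.DataFrame(rows)
        elif stage == "grid":
            base = SimParams(**_filter_keys(params.get("base_params", {}),
                                            SimParams))
            gs = GridSpec(
                base_params=base,
                p_pt_values=params.get("p_pt_values", [0.0, 0.1, 0.2]),
                pt_distances=params.get("pt_distances"),
                replicates_per_cell=int(params.get("replicates_per_cell", 4)),
                seeds=[spawn_seed(seed, 4, i) for i in
                       range(int(params.get("n_seeds", 2)))],
            )
            res = run_grid(gs)
            p = out / "grid.tsv"
            pio.write_tsv(res.table, p)
            outputs.append(p)
            ctx["grid_result"] = res
        elif stage == "threshold":
            res = ctx.get("grid_result")
            if res is None:
                raise RuntimeError("threshold stage requires the grid stage")
            demand = DemandModel(**_filter_keys(params.get("demand", {}),
                                                DemandModel))
            thr = ppt_threshold(res, demand)
            p = out / "threshold.json"
            p.write_text(json.dumps(
                {"p_pt_threshold": thr,
                 "decreased_threshold": demand.decreased_threshold}) + "\n")
            outputs.append(p)
        elif stage == "profile":
            em = ctx.get("element_map", _element_map(params))
            paths = params.get("reads") or [str(p) for p in
                                            ctx.get("read_paths", [])]
            if not paths:
                raise FileNotFoundError("profile: no read files")
            mode = params.get("mode", "three_prime")
            tracks = []
            for i, rp in enumerate(paths):
                if not Path(rp).exists():
                    raise FileNotFoundError(f"profile: missing reads {rp}")
                reads = pio.read_bed_reads(rp)
                t = end_profile(reads, mode, em.ref_length,
                                unit_start=em.flank,
                                unit_length=em.unit_length, name=em.chrom)
                if params.get("normalize", True):
                    t = normalize_unit(t)
                sm = int(params.get("smooth", 0))
                if sm:
                    t = smooth_blackman(t, sm)
                pb = out / f"profile_{mode}_rep{i}.bedgraph"
                pio.write_bedgraph(t, pb)
                outputs.append(pb)
                tracks.append(t)
            summary = aggregate_replicates(tracks)
            ps = out / f"profile_{mode}_summary.tsv"
            pio.write_tsv(summary, ps)
            outputs.append(ps)
            ctx["profile_tracks"] = tracks
            ctx["profile_summary"] = summary
        elif stage == "polya":
            em = ctx.get("element_map", _element_map(params))
            paths = params.get("reads") or [str(p) for p in
                                            ctx.get("read_paths", [])]
            min_a = int(params.get("min_a", 3))
            frames = [pio.read_bed_reads(p) for p in paths]
            reads = pd.concat(frames, ignore_index=True)
            selected, frac = select_polyA(
                reads, min_a=min_a, length=em.ref_length,
                unit_start=em.flank, unit_length=em.unit_length,
                whole_tail=bool(params.get("tail_all_a", False)))
            pb = out / "polya_selected.bed"
            pio.write_bed_reads(selected, pb)
            pf = out / "polya_fraction.bedgraph"
            pio.write_bedgraph(frac, pf)
            outputs += [pb, pf]
        elif stage == "readthrough":
            em = ctx.get("element_map", _element_map(params))
            site = int(params.get("site", em.t1))
            groups = {}
            for gname in ("reads", "reads_b"):
                paths = params.get(gname) or (
                    [str(p) for p in ctx.get("read_paths", [])]
                    if gname == "reads" else [])
                fr = []
                for rp in paths:
                    reads = pio.read_bed_reads(rp)
                    t = normalize_unit(end_profile(
                        reads, "three_prime", em.ref_length,
                        unit_start=em.flank, unit_length=em.unit_length))
                    fr.append(readthrough_fraction(t, site))
                groups[gname] = fr
            result = {"site": site, "fractions": groups["reads"]}
            if groups["reads_b"]:
                stat, pval = readthrough_test(groups["reads"],
                                              groups["reads_b"])
                result.update(fractions_b=groups["reads_b"],
                              wilcoxon_stat=stat, p_value=pval)
            p = out / "readthrough.json"
            p.write_text(json.dumps(result) + "\n")
            outputs.append(p)
        elif stage == "peaks":
            tracks = ctx.get("profile_tracks")
            if tracks is None:
                raise RuntimeError("peaks stage requires the profile stage")
            summary = ctx["profile_summary"]
            med = tracks[0].like(summary["median"].to_numpy(),
                                 normalized=True)
            ps = find_peaks(med, order=int(params.get("order", 45)),
                            window=int(params.get("window", 80)),
                            min_height=float(params.get("min_height", 1.0)))
            rows = pd.DataFrame({
                "chrom": med.name, "start": [med.index(p) for p in
                                             ps.positions],
                "end": [med.index(p) + 1 for p in ps.positions],
                "name": [f"peak_{p:+d}" for p in ps.positions],
                "score": ps.scores, "strand": "+"})
            pb = out / "peaks.bed"
            pio.write_bed(rows, pb)
            outputs.append(pb)
            ctx["peaks"] = ps
            ctx["peaks_track"] = med
        elif stage == "metaplot":
            ps = ctx.get("peaks")
            if ps is None:
                raise RuntimeError("metaplot stage requires the peaks stage")
            mp = metaplot(ctx["peaks_track"], ps,
                          flank=int(params.get("flank", 200)),
                          exclude=params.get("exclude", ()),
                          exclude_tol=int(params.get("exclude_tol", 2)))
            p = out / "metaplot.tsv"
            pio.write_tsv(pd.DataFrame({"offset": mp.offsets,
                                        "mean": mp.mean}), p)
            outputs.append(p)
        record(stage, params, outputs)

    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, default=str) + "\n")
    return manifest
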