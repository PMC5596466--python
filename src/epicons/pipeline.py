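"""End-to-end orchestration over a three-species bundle.

Glue that runs the full comparative analysis on a simulated (or identically
laid-out real-data) bundle: window methylation scoring and tsDMR calling in
the reference species, pairwise liftover, EC/ENC classification against both
other species, three-way orthology and evolutionary grouping,
conserved-element overlap, motif turnover calls, and the conservation-score
binned EC curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .conservation import (
    EC,
    ENC,
    ConservationCall,
    assign_group,
    classify_region,
    tabulate,
)
from .genetic import GeneticConservationCall, genetic_call, phylop_ec_curve
from .intervals import tile_genome
from .motifs import classify_turnover, scan_region
from .orthology import LiftoverResult, build_threeway, liftover_interval
from .simulate import TrioBundle
from .tsdmr import TsDMR, call_all, scores_from_tracks

__all__ = ["PipelineResult", "run_trio"]


@dataclass
class PipelineResult:
    tissues: tuple
    calls: dict                      # tissue -> list[TsDMR]
    lifts: dict                      # pair -> {source interval -> LiftoverResult}
    conservation: dict               # pair -> list[ConservationCall]
    tables: dict = field(default_factory=dict)   # pair -> DataFrame
    threeway: list = field(default_factory=list)
    groups: dict = field(default_factory=dict)   # group -> count
    genetic: dict = field(default_factory=dict)  # (chrom, start) -> call
    turnover: list = field(default_factory=list)
    curve: pd.DataFrame | None = None

    def all_dmrs(self) -> list[TsDMR]:
        return [d for dmrs in self.calls.values() for d in dmrs]


def run_trio(
    bundle: TrioBundle,
    with_curve: bool = True,
    with_motifs: bool = True,
    curve_bins: int = 100,
) -> PipelineResult:
    cfg = bundle.config
    tissues = tuple(cfg.tissues)

    # 1. reference tsDMR calls
    tiles = tile_genome(bundle.chrom_sizes("rat"), 500)
    rat_tracks = bundle.methylomes("rat")
    windows = scores_from_tracks(rat_tracks, tiles)
    calls = call_all(windows, tissues, species="rat")
    dmrs = [d for t in tissues for d in calls[t]]

    # 2. pairwise liftover + EC/ENC classification
    chains = {
        "rat_to_mouse": bundle.chains("rat_to_mouse"),
        "rat_to_human": bundle.chains("rat_to_human"),
        "mouse_to_human": bundle.chains("mouse_to_human"),
    }
    sp_tracks = {sp: bundle.methylomes(sp) for sp in ("mouse", "human")}
    lifts: dict[str, dict] = {}
    conservation: dict[str, list[ConservationCall]] = {}
    tables: dict[str, pd.DataFrame] = {}
    for sp in ("mouse", "human"):
        pair = f"rat_to_{sp}"
        pair_lifts = {d.interval: liftover_interval(chains[pair], d.interval)
                      for d in dmrs}
        pair_calls = [
            classify_region(d, pair_lifts[d.interval], sp_tracks[sp], pair)
            for d in dmrs
        ]
        lifts[pair] = pair_lifts
        conservation[pair] = pair_calls
        totals = {t: len(calls[t]) for t in tissues if calls[t]}
        if totals:
            tables[pair] = tabulate(pair_calls, totals)

    # 3. three-way orthologs and evolutionary groups
    threeway = build_threeway(lifts["rat_to_mouse"], lifts["rat_to_human"],
                              chains["mouse_to_human"])
    status_by_key = {
        pair: {
            (c.dmr.interval.chrom, c.dmr.interval.start): c.status
            for c in conservation[pair]
        }
        for pair in conservation
    }
    groups: dict[str, int] = {}
    for orth in threeway:
        key = (orth.rat.chrom, orth.rat.start)
        sm = status_by_key["rat_to_mouse"].get(key)
        sh = status_by_key["rat_to_human"].get(key)
        if sm in (EC, ENC) and sh in (EC, ENC):
            g = assign_group(sm, sh)
            groups[g] = groups.get(g, 0) + 1

    # 4. genetic conservation of the reference tsDMRs
    elements = bundle.elements()
    genetic: dict[tuple, GeneticConservationCall] = {
        (d.interval.chrom, d.interval.start): genetic_call(d.interval, elements)
        for d in dmrs
    }

    # 5. motif turnover against each species
    turnover: list[dict] = []
    if with_motifs:
        motifs = cfg.motif_models()
        rat_genome = bundle.genome("rat")
        for sp in ("mouse", "human"):
            pair = f"rat_to_{sp}"
            sp_genome = bundle.genome(sp)
            for d in dmrs:
                lift = lifts[pair][d.interval]
                if not lift.mapped:
                    continue
                src_seq = str(rat_genome[d.interval.chrom]
                              [d.interval.start:d.interval.end]).upper()
                dst_seq = str(sp_genome[lift.target.chrom]
                              [lift.target.start:lift.target.end]).upper()
                for motif in motifs:
                    src_hits = scan_region(src_seq, motif, d.interval)
                    dst_hits = scan_region(dst_seq, motif, lift.target)
                    call = classify_turnover(
                        d.interval, src_hits, lift.target, dst_hits,
                        chains[pair], check_orthology=False)
                    turnover.append({
                        "dmr_key": (d.interval.chrom, d.interval.start,
                                    d.target_tissue),
                        "species": sp, "motif": motif.name, "call": call,
                    })

    # 6. conservation-score binned EC curve (rat-mouse)
    curve = None
    if with_curve:
        curve = phylop_ec_curve(
            dmrs, bundle.score_track("mouse"), chains["rat_to_mouse"],
            sp_tracks["mouse"], n_bins=curve_bins)

    return PipelineResult(
        tissues=tissues, calls=calls, lifts=lifts, conservation=conservation,
        tables=tables, threeway=threeway, groups=groups, genetic=genetic,
        turnover=turnover, curve=curve,
    )
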