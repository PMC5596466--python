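"""Epigenetic-conservation (EC/ENC) classification and its tabulations.

A tissue-specific DMR called in the reference species is epigenetically
conserved (EC) in another species when the orthologous region repeats the
tissue-specific methylation pattern there.  With the three-state methylation
status (0 unmethylated / 1 intermediate / 2 methylated), the rule is:

  EC  iff  (target tissue status = 0 and both other tissues in {1, 2})
        or (target tissue status = 1 and both other tissues = 2);
  ENC otherwise.

Regions whose ortholog is unmapped (NO_ORTHOLOG) or lacks CpGs in some tissue
track (NO_CPG) receive neither label but still count in percentage
denominators, which use the full per-tissue tsDMR totals.

The enrichment test is an upper-tail hypergeometric: the urn pools the tsDMRs
with a large random-region background classified by the same pipeline
(population N = background size + n tsDMRs, successes K = background EC +
observed EC, draws n = n tsDMRs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .intervals import GenomicInterval
from .methylome import MethylomeTrack, categorize
from .orthology import LiftoverResult
from .tsdmr import TsDMR

__all__ = [
    "EC",
    "ENC",
    "NO_ORTHOLOG",
    "NO_CPG",
    "GROUPS",
    "ConservationCall",
    "classify_ec",
    "classify_region",
    "tabulate",
    "assign_group",
    "group_totals",
    "ec_enrichment_test",
]

EC = "EC"
ENC = "ENC"
NO_ORTHOLOG = "NO_ORTHOLOG"
NO_CPG = "NO_CPG"

# three-way evolutionary groups (reference = rat)
RMH_EC = "RMH_EC"   # EC in both mouse and human
RM_EC = "RM_EC"     # EC in mouse only
RH_EC = "RH_EC"     # EC in human only
RMH_ENC = "RMH_ENC"  # EC in neither
GROUPS = (RMH_EC, RM_EC, RH_EC, RMH_ENC)


@dataclass(frozen=True)
class ConservationCall:
    dmr: TsDMR
    species_pair: str
    status: str
    ortholog: GenomicInterval | None = None
    statuses: tuple | None = None  # per-tissue methylation statuses, if known

    @property
    def target_tissue(self) -> str:
        return self.dmr.target_tissue


def classify_ec(statuses: Mapping[str, int], target: str) -> str:
    """EC/ENC from per-tissue methylation statuses in the other species."""
    if len(statuses) != 3:
        raise ValueError("exactly 3 tissue statuses required")
    if target not in statuses:
        raise ValueError(f"target tissue {target!r} missing from statuses")
    for tissue, st in statuses.items():
        if st not in (0, 1, 2):
            raise ValueError(f"invalid status {st} for {tissue}")
    ts = statuses[target]
    others = [st for tissue, st in statuses.items() if tissue != target]
    if ts == 0 and all(o in (1, 2) for o in others):
        return EC
    if ts == 1 and all(o == 2 for o in others):
        return EC
    return ENC


def classify_region(
    dmr: TsDMR,
    lift: LiftoverResult,
    tracks: Mapping[str, MethylomeTrack],
    species_pair: str = "",
) -> ConservationCall:
    """Full classification of one tsDMR against one species.

    NO_ORTHOLOG when the liftover is unmapped; NO_CPG when any tissue track
    has zero CpGs in the ortholog; otherwise EC/ENC via :func:`classify_ec`.
    """
    if not lift.mapped:
        return ConservationCall(dmr, species_pair, NO_ORTHOLOG)
    statuses: dict[str, int] = {}
    for tissue, track in tracks.items():
        rm = track.region_mean(lift.target)
        if rm.n_cpg == 0:
            return ConservationCall(dmr, species_pair, NO_CPG, lift.target)
        statuses[tissue] = categorize(rm.mean_level)
    status = classify_ec(statuses, dmr.target_tissue)
    return ConservationCall(
        dmr, species_pair, status, lift.target,
        tuple(sorted(statuses.items())),
    )


def _round_percent(x: float) -> int:
    # round half away from zero, as printed tables do
    return int(np.floor(x + 0.5))


def tabulate(
    calls: Iterable,
    totals: Mapping[str, int],
    background: Mapping[str, tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Per-tissue conservation table.

    ``calls`` yields :class:`ConservationCall` objects or plain
    ``(tissue, status)`` pairs.  ``totals`` gives the full tsDMR count per
    tissue (the percentage denominator).  ``background``, when supplied, maps
    tissue to (background EC count, background size) and enables the
    hypergeometric p-value plus a BH-adjusted q across tissues.
    """
    counts: dict[str, dict[str, int]] = {t: {EC: 0, ENC: 0} for t in totals}
    for item in calls:
        if isinstance(item, ConservationCall):
            tissue, status = item.target_tissue, item.status
        else:
            tissue, status = item
        if status in (EC, ENC):
            counts.setdefault(tissue, {EC: 0, ENC: 0})
            counts[tissue][status] = counts[tissue].get(status, 0) + 1
    rows = []
    for tissue, total in totals.items():
        if total <= 0:
            raise ValueError(f"tissue {tissue!r}: total tsDMR count must be positive")
        n_ec = counts.get(tissue, {}).get(EC, 0)
        n_enc = counts.get(tissue, {}).get(ENC, 0)
        if n_ec + n_enc > total:
            raise ValueError(f"tissue {tissue!r}: EC+ENC exceeds total")
        row = {
            "tissue": tissue,
            "n_tsdmr": total,
            "n_ec": n_ec,
            "n_enc": n_enc,
            "percent_ec": _round_percent(100.0 * n_ec / total),
        }
        if background is not None and tissue in background:
            bg_ec, bg_n = background[tissue]
            row["p_value"] = ec_enrichment_test(n_ec, total, bg_ec=bg_ec, bg_n=bg_n)
        rows.append(row)
    df = pd.DataFrame(rows)
    if "p_value" in df.columns:
        from .enrichment import bh_fdr

        df["q_value"] = bh_fdr(df["p_value"].to_numpy())
    return df


def assign_group(mouse_status: str, human_status: str) -> str:
    """Three-way evolutionary group from the two pairwise EC/ENC calls."""
    for st in (mouse_status, human_status):
        if st not in (EC, ENC):
            raise ValueError(
                f"three-way grouping requires EC/ENC calls, got {st!r}"
            )
    if mouse_status == EC and human_status == EC:
        return RMH_EC
    if mouse_status == EC:
        return RM_EC
    if human_status == EC:
        return RH_EC
    return RMH_ENC


def group_totals(per_tissue: Mapping[str, Mapping[str, int]]) -> dict[str, int]:
    """Aggregate per-tissue three-way group counts into group totals plus a
    grand total under the key 'total'."""
    totals = {g: 0 for g in GROUPS}
    for tissue, counts in per_tissue.items():
        for g, n in counts.items():
            if g not in totals:
                raise ValueError(f"unknown group {g!r} for tissue {tissue!r}")
            totals[g] += int(n)
    totals["total"] = sum(totals[g] for g in GROUPS)
    return totals


def ec_enrichment_test(
    observed_ec: int,
    n_tsdmr: int,
    background_calls: Sequence | None = None,
    bg_ec: int | None = None,
    bg_n: int | None = None,
) -> float:
    """Upper-tail hypergeometric probability of >= observed EC calls.

    The background may be given either as a sequence of classification calls
    (statuses or :class:`ConservationCall`) or as precomputed (bg_ec, bg_n).
    """
    if background_calls is not None:
        statuses = [
            c.status if isinstance(c, ConservationCall) else c
            for c in background_calls
        ]
        if not statuses:
            raise ValueError("background sample is empty")
        bg_ec = sum(1 for s in statuses if s == EC)
        bg_n = len(statuses)
    if bg_ec is None or bg_n is None or bg_n <= 0:
        raise ValueError("background sample is empty")
    N = bg_n + n_tsdmr
    K = bg_ec + observed_ec
    return float(hypergeom.sf(observed_ec - 1, N, K, n_tsdmr))
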