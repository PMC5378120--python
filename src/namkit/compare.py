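"""Diversity statistics comparing biparental maps with the consensus map.

Two statistics per (population, chromosome): the marker-distance ratio
MDR = MD_bip / MD_cons, where each MD is the span of the common markers
divided by the number of common-marker intervals on that map's own scale;
and the Spearman rank correlation of common-marker order, classified as
incongruent (|rho| <= 0.6), near-incongruent (0.6 < |rho| <= 0.7) or
congruent.  MDR outliers are flagged per chromosome by Tukey fences
(1.5 x IQR beyond the quartiles, quartiles by linear interpolation), and
"expanded" groups are high outliers supported by at least six common
markers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .linkage import LinkageGroup

__all__ = [
    "MDRRecord",
    "OrderComparison",
    "mean_marker_distance",
    "mdr",
    "flag_mdr_outliers",
    "order_correlation",
    "compare_maps",
]


@dataclass
class MDRRecord:
    population: str
    chromosome: str
    n_common: int
    md_bip: float
    md_cons: float
    mdr: float  # may be inf when the consensus span is 0
    outlier: str = "none"  # low / none / high
    expanded: bool = False


@dataclass
class OrderComparison:
    population: str
    chromosome: str
    n_common: int
    rho: float
    category: str  # congruent / near_incongruent / incongruent / insufficient


def _common(bip: LinkageGroup, cons) -> list:
    cset = set(cons.markers)
    return [m for m in bip.markers if m in cset]


def mean_marker_distance(lg, common_markers) -> float:
    """Span of the common markers on ``lg``'s own scale divided by the
    number of intervals between them (first-to-last over n-1)."""
    if len(common_markers) < 2:
        raise ValueError("mean marker distance needs at least 2 common markers")
    pos = [lg.positions[lg.markers.index(m)] for m in common_markers]
    return float((max(pos) - min(pos)) / (len(common_markers) - 1))


def mdr(bip_lg: LinkageGroup, consensus_lg, population=None) -> MDRRecord | None:
    """Marker-distance ratio of a biparental group against the consensus.

    Returns None when fewer than 2 common markers exist or the biparental
    group has length 0 cM (zero-length groups are excluded from the
    analysis).  A zero consensus span with positive biparental span yields
    an infinite MDR, excluded later from the fences.
    """
    common = _common(bip_lg, consensus_lg)
    if len(common) < 2 or bip_lg.length_cM == 0:
        return None
    md_b = mean_marker_distance(bip_lg, common)
    md_c = mean_marker_distance(consensus_lg, common)
    ratio = np.inf if md_c == 0 and md_b > 0 else (md_b / md_c if md_c > 0 else 1.0)
    chrom = bip_lg.chromosome or getattr(consensus_lg, "chromosome", "")
    return MDRRecord(
        population=population or "", chromosome=chrom, n_common=len(common),
        md_bip=md_b, md_cons=md_c, mdr=float(ratio),
    )


def flag_mdr_outliers(records, min_group=4, min_markers_expanded=6):
    """Apply Tukey fences per chromosome group, in place.

    Records with infinite MDR never enter the fence computation.  Groups
    smaller than ``min_group`` get no flags.  Returns the records.
    """
    by_chrom = {}
    for rec in records:
        by_chrom.setdefault(rec.chromosome, []).append(rec)
    for chrom, group in by_chrom.items():
        finite = [r for r in group if np.isfinite(r.mdr)]
        if len(finite) < min_group:
            continue
        vals = np.array([r.mdr for r in finite])
        q1, q3 = np.quantile(vals, [0.25, 0.75])  # linear interpolation
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        for r in finite:
            if r.mdr > hi:
                r.outlier = "high"
                r.expanded = r.n_common >= min_markers_expanded
            elif r.mdr < lo:
                r.outlier = "low"
    return records


def order_correlation(bip_lg: LinkageGroup, consensus_lg, min_common=7,
                      population=None) -> OrderComparison:
    """Spearman rank correlation of common-marker order, with incongruence
    classification on |rho| (orientation is normalised upstream, so a pure
    reversal counts as congruent)."""
    common = _common(bip_lg, consensus_lg)
    chrom = bip_lg.chromosome or getattr(consensus_lg, "chromosome", "")
    n = len(common)
    if n < max(3, min_common):
        return OrderComparison(population or "", chrom, n, np.nan, "insufficient")
    rb = [bip_lg.markers.index(m) for m in common]
    rc = [consensus_lg.markers.index(m) for m in common]
    rho = float(spearmanr(rb, rc).statistic)
    a = abs(rho)
    if a <= 0.6:
        cat = "incongruent"
    elif a <= 0.7:
        cat = "near_incongruent"
    else:
        cat = "congruent"
    return OrderComparison(population or "", chrom, n, rho, cat)


def compare_maps(maps, consensus: dict, min_common=7):
    """All MDR and order-comparison records for a panel.

    ``maps``: iterable of GeneticMap; ``consensus``: {chromosome:
    ConsensusMap}.  Returns (mdr_df, order_df) DataFrames, with Tukey
    fences already applied per chromosome.
    """
    mdr_records, order_records = [], []
    for gmap in maps:
        for lg in gmap.lgs:
            cons = consensus.get(lg.chromosome)
            if cons is None:
                continue
            rec = mdr(lg, cons, population=gmap.population_id)
            if rec is not None:
                mdr_records.append(rec)
            order_records.append(
                order_correlation(lg, cons, min_common=min_common,
                                  population=gmap.population_id)
            )
    flag_mdr_outliers(mdr_records)
    mdr_df = pd.DataFrame([vars(r) for r in mdr_records])
    order_df = pd.DataFrame([vars(r) for r in order_records])
    return mdr_df, order_df
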