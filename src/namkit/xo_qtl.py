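"""Crossover-count trait and QTL mapping.

The per-line trait is the number of obligate crossovers implied by ordered
genotypes along each linkage group: a transition between consecutive
non-missing calls counts one crossover for AA<->AB or AB<->BB and two for
AA<->BB; missing calls are skipped.  This undercounts the true number of
junctions when markers are sparse, and is exactly the junction count in the
dense noiseless limit.

QTL mapping regresses the trait on the expected additive allele dosage from
imputation posteriors (Haley-Knott): LOD = (n/2) log10(RSS0/RSS1) at each
marker, putative QTL are local maxima with LOD >= 2.0, and a final
multiple-QTL model retains peaks whose drop-one LOD clears either a seeded
permutation threshold (95th percentile of genome-wide max LODs) or the
fixed 2.0 default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, CODE_NA
from .linkage import GeneticMap
from .segdist import ImputedMatrix

__all__ = [
    "CrossoverTrait",
    "QTLRecord",
    "count_crossovers",
    "xo_trait",
    "qtl_scan",
    "multiple_qtl_model",
    "project_common_qtl",
]


@dataclass
class CrossoverTrait:
    population: str
    individuals: list
    counts: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.counts))

    @property
    def sd(self) -> float:
        return float(np.std(self.counts, ddof=1)) if len(self.counts) > 1 else 0.0


@dataclass
class QTLRecord:
    population: str
    chromosome: str
    peak_marker: str
    position_cM: float
    lod: float
    effect: float  # additive effect in crossovers, always >= 0
    source_parent: str  # parent contributing the increasing allele
    ci_markers: list = field(default_factory=list)  # 1.5-LOD support interval


def count_crossovers(ordered_calls) -> int:
    """Obligate crossovers in one line's genotype vector along one linkage
    group: sum of |g_t+1 - g_t| over consecutive non-missing calls (AA<->BB
    counts 2)."""
    g = np.asarray(ordered_calls)
    g = g[g != CODE_NA]
    if len(g) < 2:
        return 0
    return int(np.abs(np.diff(g.astype(int))).sum())


def xo_trait(matrix: GenotypeMatrix, gmap: GeneticMap,
             imputed: ImputedMatrix | None = None) -> CrossoverTrait:
    """Per-individual crossover counts summed over linkage groups.

    When an imputed matrix is given its hard calls are used (mis-scored
    singletons otherwise inflate the count)."""
    if matrix.n_individuals == 0:
        raise ValueError("empty population")
    if imputed is not None:
        index = {m: i for i, m in enumerate(imputed.markers)}
        calls = imputed.calls
    else:
        index = {m: i for i, m in enumerate(matrix.marker_names)}
        calls = matrix.calls
    counts = np.zeros(matrix.n_individuals, dtype=int)
    for lg in gmap.lgs:
        rows = [index[m] for m in lg.markers if m in index]
        if len(rows) < 2:
            continue
        block = calls[rows]
        for j in range(block.shape[1]):
            counts[j] += count_crossovers(block[:, j])
    return CrossoverTrait(matrix.population_id, list(matrix.individuals), counts)


def _dosage(imputed: ImputedMatrix):
    """Expected additive coding in [-1, 1]: P(BB) - P(AA) per call."""
    return imputed.posteriors[..., 2] - imputed.posteriors[..., 0]


def _lod_curve(y, dosage):
    """Haley-Knott regression LOD and effect at every marker (vectorised)."""
    n = len(y)
    yc = y - y.mean()
    rss0 = float(yc @ yc)
    x = dosage
    xc = x - x.mean(axis=1, keepdims=True)
    sxx = np.sum(xc**2, axis=1)
    sxy = xc @ yc
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
    rss1 = rss0 - beta * sxy
    rss1 = np.maximum(rss1, 1e-12)
    if rss0 <= 1e-12:
        return np.zeros(x.shape[0]), beta
    lod = (n / 2.0) * np.log10(rss0 / rss1)
    return lod, beta


def qtl_scan(trait: CrossoverTrait, imputed: ImputedMatrix, gmap: GeneticMap,
             lod_min=2.0, parents=("Par", "other")) -> tuple:
    """Single-QTL genome scan.

    Returns (curve_df, putative) where curve_df has one row per mapped
    marker (chromosome, position, lod, effect) and ``putative`` is a list of
    QTLRecord at local maxima with LOD >= ``lod_min`` (one peak per
    linkage group per maximal run; nearby shoulders are absorbed within the
    1.5-LOD support interval).
    """
    y = np.asarray(trait.counts, dtype=float)
    dosage = _dosage(imputed)
    lod, beta = _lod_curve(y, dosage)
    index = {m: i for i, m in enumerate(imputed.markers)}
    rows, putative = [], []
    for lg in gmap.lgs:
        ids = [index[m] for m in lg.markers if m in index]
        if not ids:
            continue
        llod = lod[ids]
        for m, pos, l, b in zip(lg.markers, lg.positions, llod, beta[ids]):
            rows.append(dict(marker=m, lg=lg.lg_id, chromosome=lg.chromosome,
                             position_cM=float(pos), lod=float(l),
                             effect=float(b)))
        # local maxima at or above threshold
        for t in range(len(ids)):
            l = llod[t]
            if l < lod_min:
                continue
            left = llod[t - 1] if t > 0 else -np.inf
            right = llod[t + 1] if t < len(ids) - 1 else -np.inf
            if l >= left and l > right or (l >= left and t == len(ids) - 1):
                ci = [lg.markers[u] for u in range(len(ids))
                      if llod[u] >= l - 1.5]
                b = beta[ids[t]]
                putative.append(QTLRecord(
                    population=trait.population,
                    chromosome=lg.chromosome or lg.lg_id,
                    peak_marker=lg.markers[t],
                    position_cM=float(lg.positions[t]),
                    lod=float(l), effect=float(abs(b)),
                    source_parent=parents[0] if b < 0 else parents[1],
                    ci_markers=ci))
    # collapse peaks whose support intervals overlap, keeping the strongest
    collapsed = []
    for q in sorted(putative, key=lambda q: -q.lod):
        if any(set(q.ci_markers) & set(p.ci_markers) and q.chromosome == p.chromosome
               for p in collapsed):
            continue
        collapsed.append(q)
    return pd.DataFrame(rows), collapsed


def multiple_qtl_model(putative, trait: CrossoverTrait, imputed: ImputedMatrix,
                       threshold=None, n_permutations=0, seed=0,
                       merge_cM=10.0, gmap: GeneticMap | None = None):
    """Joint multiple-QTL confirmation by drop-one LOD.

    All putative QTL enter one linear model on their dosages; each is
    refitted out and retained when its drop-one LOD is at or above the
    threshold.  ``threshold=None`` uses the 95th percentile of
    ``n_permutations`` seeded genome-wide max-LOD permutations when
    requested, else the fixed 2.0.  Putative QTL on the same chromosome
    closer than ``merge_cM`` are merged beforehand (keeping the higher
    peak).
    """
    if not putative:
        return []
    # merge near-collinear peaks
    merged = []
    for q in sorted(putative, key=lambda q: -q.lod):
        if any(p.chromosome == q.chromosome and
               abs(p.position_cM - q.position_cM) < merge_cM for p in merged):
            continue
        merged.append(q)
    y = np.asarray(trait.counts, dtype=float)
    n = len(y)
    dosage = _dosage(imputed)
    index = {m: i for i, m in enumerate(imputed.markers)}
    cols = [dosage[index[q.peak_marker]] for q in merged]
    X_full = np.column_stack([np.ones(n)] + cols)

    def rss(X):
        coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        return float(r @ r)

    rss_full = rss(X_full)
    if threshold is None:
        if n_permutations > 0:
            rng = np.random.default_rng(seed)
            maxlods = np.empty(n_permutations)
            for b in range(n_permutations):
                yp = rng.permutation(y)
                lodp, _ = _lod_curve(yp, dosage)
                maxlods[b] = lodp.max() if len(lodp) else 0.0
            threshold = float(np.quantile(maxlods, 0.95))
        else:
            threshold = 2.0
    final = []
    for i, q in enumerate(merged):
        X_red = np.delete(X_full, i + 1, axis=1)
        lod_drop = (n / 2.0) * math.log10(max(rss(X_red), 1e-12) /
                                          max(rss_full, 1e-12))
        if lod_drop >= threshold:
            q = QTLRecord(**{**vars(q)})
            q.lod = float(lod_drop)
            final.append(q)
    return final


def project_common_qtl(qtl_by_population: dict, consensus: dict, min_pops=4):
    """Cross-population common-QTL regions on the consensus map.

    ``qtl_by_population``: {population: list of QTLRecord}; a consensus
    marker belongs to a common QTL when it lies in the support interval of
    QTL from at least ``min_pops`` different populations; maximal runs of
    such markers form the reported regions.  Returns a DataFrame with one
    row per region.
    """
    support = {}  # (chrom, marker) -> set of populations
    for pop, qtls in qtl_by_population.items():
        for q in qtls:
            for m in q.ci_markers:
                support.setdefault(m, set()).add(pop)
    regions = []
    for chrom, cmap in sorted(consensus.items()):
        counts = [len(support.get(m, ())) for m in cmap.markers]
        run = None
        for i, (m, c) in enumerate(zip(cmap.markers, counts)):
            if c >= min_pops:
                if run is None:
                    run = dict(chromosome=chrom, start_cM=float(cmap.positions[i]),
                               markers=[], populations=set())
                run["markers"].append(m)
                run["end_cM"] = float(cmap.positions[i])
                run["populations"] |= support.get(m, set())
            elif run is not None:
                regions.append(run)
                run = None
        if run is not None:
            regions.append(run)
    rows = [dict(chromosome=r["chromosome"], start_cM=r["start_cM"],
                 end_cM=r["end_cM"], n_markers=len(r["markers"]),
                 markers=r["markers"],
                 n_populations=len(r["populations"]),
                 populations=sorted(r["populations"]))
            for r in regions]
    return pd.DataFrame(rows, columns=["chromosome", "start_cM", "end_cM",
                                       "n_markers", "markers",
                                       "n_populations", "populations"])
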