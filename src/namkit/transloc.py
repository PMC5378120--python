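"""Translocation detection from linkage maps and estRF matrices.

Two complementary callers:

* **mapped** — a linkage group whose majority a-priori chromosome
  assignment disagrees with the assignment of some of its markers implies
  that those minority markers moved: one call per (population, chromosome
  pair), reciprocal when the mirror-image case also occurs;
* **estRF** — pairs of markers assigned to different chromosomes but
  showing a two-point linkage LOD strictly above a threshold (default 7.0,
  with an optional stricter screening pass at LOD 10) indicate a segment
  segregating away from its home chromosome.

Calls from both methods are merged per (population, chromosome pair),
classified into types "T<chrA>:<chrB>" (sorted labels), and each type's
carrier distribution can be tested for enrichment in the panel's ancestral
groups with a chi-square test (with Monte-Carlo p-values when expected
counts are small).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .linkage import EstRFMatrix, GeneticMap

__all__ = [
    "TranslocationCall",
    "mapped_translocations",
    "estrf_translocations",
    "classify_and_merge",
    "ancestral_enrichment",
]


@dataclass
class TranslocationCall:
    population: str
    method: str  # "mapped" or "estrf"
    chromosomes: tuple  # sorted pair
    markers: list
    statistic: float  # max inter-group LOD (estrf) or minority-marker count (mapped)
    reciprocal: bool = False

    @property
    def type_label(self) -> str:
        a, b = sorted(self.chromosomes)
        return f"T{a}:{b}"


def mapped_translocations(gmap: GeneticMap, assignments: dict, min_minority=1):
    """Calls from chromosome-assignment conflicts inside linkage groups.

    ``assignments`` maps marker name -> a-priori chromosome.  For every
    linkage group, markers whose assignment differs from the group majority
    produce one call per (minority chromosome, majority chromosome) pair
    when at least ``min_minority`` markers support it.  The reciprocal flag
    is set when the mirror-image conflict exists in the same map.
    """
    raw = []
    for lg in gmap.lgs:
        major = lg.chromosome
        if not major:
            continue
        minority = {}
        for m in lg.markers:
            a = assignments.get(m)
            if a and a != major:
                minority.setdefault(a, []).append(m)
        for chrom, markers in minority.items():
            if len(markers) >= min_minority:
                raw.append((chrom, major, markers))
    pairs = {(c, m) for c, m, _ in raw}
    calls = []
    seen = set()
    for chrom, major, markers in raw:
        key = tuple(sorted((chrom, major)))
        reciprocal = (major, chrom) in pairs
        if key in seen:
            for c in calls:
                if c.chromosomes == key:
                    c.markers = sorted(set(c.markers) | set(markers))
                    c.statistic = float(len(c.markers))
                    c.reciprocal = c.reciprocal or reciprocal
            continue
        seen.add(key)
        calls.append(
            TranslocationCall(
                population=gmap.population_id, method="mapped",
                chromosomes=key, markers=sorted(markers),
                statistic=float(len(markers)), reciprocal=reciprocal,
            )
        )
    return calls


def estrf_translocations(est: EstRFMatrix, chromosome_of: dict,
                         lod_threshold=7.0, screen_lod=None, population=""):
    """Calls from inter-chromosome linkage in the estRF matrix.

    ``chromosome_of`` maps marker name -> chromosome (the mapped/assigned
    location).  Marker pairs on different chromosomes with LOD strictly
    above ``lod_threshold`` are aggregated into one call per chromosome
    pair, reporting the maximum LOD and the supporting markers.  Only
    het-informative markers participate.  ``screen_lod`` applies an
    additional initial screen: pairs must also exceed it (use 10.0 for the
    two-stage workflow).
    """
    markers = est.markers
    n = len(markers)
    chroms = np.array([chromosome_of.get(m) for m in markers], dtype=object)
    valid = np.array([c is not None for c in chroms]) & est.informative
    thr = float(lod_threshold)
    if screen_lod is not None:
        thr = max(thr, float(screen_lod))
    by_pair = {}
    lod = est.lod
    for i in range(n):
        if not valid[i]:
            continue
        for j in range(i + 1, n):
            if not valid[j] or chroms[i] == chroms[j]:
                continue
            if lod[i, j] > thr:  # strictly greater
                key = tuple(sorted((chroms[i], chroms[j])))
                rec = by_pair.setdefault(key, {"lod": 0.0, "markers": set()})
                rec["lod"] = max(rec["lod"], float(lod[i, j]))
                rec["markers"].update((markers[i], markers[j]))
    return [
        TranslocationCall(population=population, method="estrf",
                          chromosomes=key, markers=sorted(rec["markers"]),
                          statistic=rec["lod"])
        for key, rec in sorted(by_pair.items())
    ]


def classify_and_merge(calls):
    """Union of calls across methods and populations.

    Returns (merged_df, types_df, per_population_counts).  Calls for the
    same (population, chromosome pair) found by both methods are counted
    once (method "both").
    """
    merged = {}
    for c in calls:
        key = (c.population, c.chromosomes)
        if key in merged:
            prev = merged[key]
            if prev.method != c.method:
                prev.method = "both"
            prev.markers = sorted(set(prev.markers) | set(c.markers))
            prev.statistic = max(prev.statistic, c.statistic)
            prev.reciprocal = prev.reciprocal or c.reciprocal
        else:
            merged[key] = TranslocationCall(
                population=c.population, method=c.method,
                chromosomes=c.chromosomes, markers=list(c.markers),
                statistic=c.statistic, reciprocal=c.reciprocal,
            )
    rows = [
        dict(population=c.population, type=c.type_label, method=c.method,
             chrom_a=c.chromosomes[0], chrom_b=c.chromosomes[1],
             n_markers=len(c.markers), statistic=c.statistic,
             reciprocal=c.reciprocal)
        for c in merged.values()
    ]
    merged_df = pd.DataFrame(rows, columns=["population", "type", "method",
                                            "chrom_a", "chrom_b", "n_markers",
                                            "statistic", "reciprocal"])
    if len(merged_df):
        types_df = (
            merged_df.groupby("type")
            .agg(carrier_count=("population", "nunique"),
                 carriers=("population", lambda s: sorted(set(s))))
            .reset_index()
            .sort_values(["carrier_count", "type"], ascending=[False, True])
            .reset_index(drop=True)
        )
        pop_counts = merged_df.groupby("population").size().rename("n_translocations")
    else:
        types_df = pd.DataFrame(columns=["type", "carrier_count", "carriers"])
        pop_counts = pd.Series(dtype=int, name="n_translocations")
    return merged_df, types_df, pop_counts


def ancestral_enrichment(carriers, groups: dict, alpha=0.05,
                         monte_carlo=True, n_draws=10_000, seed=0):
    """Test whether a translocation type's carriers cluster in ancestral
    groups.

    ``carriers``: iterable of carrier population/accession ids; ``groups``:
    {accession: ancestral group} over the whole panel.  A 2 x G
    carrier/non-carrier contingency table is tested by chi-square; when any
    expected cell is below 5 and ``monte_carlo`` is set, the p-value is
    obtained by permuting group labels (``n_draws`` draws, seeded).
    Returns a dict with chi2, p_asymptotic, p_monte_carlo (or None),
    and the observed-vs-expected carrier count per group.
    """
    carriers = set(carriers)
    if len(carriers) < 2:
        raise ValueError("enrichment test needs at least 2 carriers")
    accessions = sorted(groups)
    labels = np.array([groups[a] for a in accessions])
    is_carrier = np.array([a in carriers for a in accessions])
    cats = np.unique(labels)
    if len(cats) < 2:
        raise ValueError("only one ancestral group represented")
    table = np.array([
        [np.sum(is_carrier & (labels == g)) for g in cats],
        [np.sum(~is_carrier & (labels == g)) for g in cats],
    ], dtype=float)
    n = table.sum()
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / n
    chi2 = float(np.sum((table - expected) ** 2 / expected))
    dof = len(cats) - 1
    p_asym = float(stats.chi2.sf(chi2, dof))
    p_mc = None
    if monte_carlo and (expected < 5).any():
        rng = np.random.default_rng(seed)
        hits = 0
        k = int(is_carrier.sum())
        for _ in range(n_draws):
            perm = rng.permutation(labels)
            t = np.array([
                [np.sum(perm[:k] == g) for g in cats],
                [np.sum(perm[k:] == g) for g in cats],
            ], dtype=float)
            e = t.sum(axis=1, keepdims=True) @ t.sum(axis=0, keepdims=True) / n
            c = np.sum((t - e) ** 2 / np.where(e > 0, e, 1))
            if c >= chi2 - 1e-12:
                hits += 1
        p_mc = (hits + 1) / (n_draws + 1)
    per_group = {
        str(g): dict(observed=int(table[0, i]), expected=float(expected[0, i]))
        for i, g in enumerate(cats)
    }
    return dict(chi2=chi2, dof=dof, p_asymptotic=p_asym, p_monte_carlo=p_mc,
                per_group=per_group,
                significant=(p_mc if p_mc is not None else p_asym) <= alpha)
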